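# Methods

## Scope and model

`canopybird` estimates the relative importance of habitat variables
for six bird-diversity responses measured on compartment groups
(pooled forest stands). The statistical core is ordinary least
squares: for each response the full nine-variable model

    y_g = β0 + β·X_g + ε_g,    ε_g ~ N(0, σ²)

is never interpreted directly; instead its goodness of fit is
decomposed by hierarchical partitioning, and a reduced model over a
collinearity-feasible subset of variables is fitted and tested with a
type-2 ANOVA. The nine candidate variables are two categorical
factors (simplified management type, baseline conifer; simplified age
class, baseline mixed ages), six continuous structural metrics, and
log total group area, which is always forced into the final model as a
confounder control.

Assumptions: groups are independent observations (no spatial
correlation between groups is modelled); effects are main effects only
(no interactions); responses are approximately normal after the
optional Box-Cox step.

## Hierarchical partitioning

For k ≤ 9 predictors the R² of all 2^k subsets is computed (one
centered Gram matrix, one small solve per subset; rank-deficient
subsets use the minimum-norm solution, which leaves R² unchanged).
The independent effect of variable j averages its R² increment over
hierarchy levels:

    I_j = (1/k) Σ_h  mean_{|S|=h, j∉S} [R²(S∪{j}) − R²(S)]

and J_j = R²({j}) − I_j. Two identities hold to numerical precision
and are enforced in tests: Σ_j I_j = R²(full) and I_j + J_j = R²({j}).
Negative I_j (suppression) is reported, never clipped. A categorical
factor enters as its whole dummy block. The 9-variable cap keeps the
subset enumeration and its statistical behaviour sound.

Scale optimization: for each response and each multi-resolution metric
(top canopy height, gap fraction, horizontal heterogeneity), the
partition is re-run with the focal variable at each candidate
resolution (0.5, 2, 5, 10 m) while the other multi-resolution
variables sit at the coarsest (10 m) reference; the resolution with
the highest percentage of independent effects wins, ties going to the
coarser resolution (smoother fields, cheaper data). The run structure
for this step was an open design choice; holding non-focal variables
at a fixed reference keeps the nine-variable frame identical across
candidates so the percentages are comparable.

## Structural metrics

The CHM rasterizer takes the maximum return height per cell and fills
empty cells from the nearest populated cell within a 3-cell radius
(0 beyond); this replaces pit-free interpolation, which needs the raw
multi-return cloud. Aggregation to coarser grids is the block mean,
which preserves the stand mean exactly on complete grids — so top
canopy height is resolution-invariant while gap fraction and Moran's I
are not, matching how these metrics behave on real canopies.

The plant-area profile uses the MacArthur–Horn attenuation estimator
on 10-m columns and 1-m bins with extinction coefficient k = 1. The
choice of k rescales all PAD values by a constant, so Pielou evenness
is unaffected and shrub/canopy density are in consistent relative
units. Pielou's denominator counts segments up to the highest
vegetated bin (zero bins inside the canopy count toward m but add no
entropy); an all-zero or single-segment profile has undefined
evenness. Shrub density sums bins [1,2) … [4,5) m; canopy density
sums bins entirely inside [⅔·top, top] with top = mean + 2 sample SD
of the CHM. Moran's I uses binary rook contiguity with missing cells
excluded pairwise; its permutation-null mean −1/(n−1) is verified in
the acceptance checks. Gap fraction uses a strict "<" and returns 0
on an all-zero grid.

## Diversity metrics

Richness counts species with positive (possibly fractional,
detectability-corrected) abundance; Shannon diversity is in nats.
The functional metrics follow the standard hull/MST/centroid
formulations in a principal-coordinates embedding of Gower
dissimilarities (numeric traits range-scaled, categorical traits 0/1,
unweighted trait mean). If the Gower matrix is non-Euclidean the
square-root transform is embedded instead — the usual correction in
trait-based FD software. The number of retained axes is
m = min(4, S_min − 1) with S_min the smallest community richness, so
FRic's S > m precondition holds for every group; quality is the
retained share of positive eigenvalues. FRic is undefined (missing,
with a warning) for degenerate hulls, FEve needs S ≥ 3, FDiv returns
missing when all species coincide.

Box-Cox normalization is applied per metric across the group table
(the grain at which models are fitted), only when Shapiro–Wilk rejects
at α = 0.05, with λ maximizing the profile log-likelihood over
[−2, 2] in 0.01 steps; nonpositive metrics are shifted to positive
support first and the shift recorded.

## Collinearity and selection

All pairwise associations are mapped to [0, 1] so one |0.7| threshold
applies: |Pearson r| (continuous–continuous), correlation ratio
√(SSB/SST) (continuous–categorical) and Cramér's V
(categorical–categorical). The correlation-ratio and Cramér's V
choices stand in for an unspecified mixed-type "correlation"; both are
the standard measures for those pairings. Selection enumerates all
subsets containing the forced variables, discards any containing a
collinearity edge, and maximizes Σ I_j; ties prefer the smaller
subset, then lexicographic order, so the choice is deterministic.

The final OLS dummy-codes factors against the stated baselines and
drops aliased columns by a greedy rank filter, reporting them: with
open/other management the age class is necessarily "not applicable",
so the two factors share an identical indicator column and only the
first occurrence is kept — the same aliasing arises in real
management databases. The type-2 ANOVA computes each term's sum of
squares as SSE(model without the term) − SSE(full), tested against the
full model's residual mean square; with main effects only this is
order-invariant and reduces to sequential sums of squares on balanced
orthogonal designs.

## Synthetic landscapes

The generator emulates a conifer-majority managed plantation:

- **Compartments.** Areas are log-normal with mean 2.35 ha and
  SD 2.53 ha (right-skewed, median < mean, like real stand registers).
  Detailed management types (four conifer monocultures, two
  broadleaved, two mixtures, four open/other classes) and age bands
  (restock 0–6, pre-thicket 7–11, thicket 12–21, pole 22–45, mature
  46+, mixed ages) are drawn independently, except that open/other
  management forces the "not applicable" age class. Prevalences are
  kept broadly comparable across detailed types so that group size is
  not a proxy for crop identity.
- **Canopy.** Each stand draws latent structure around its age-class
  values — height mean/SD (restock ≈ 1 m to mature ≈ 20 m), gap
  probability, shrub level — and renders a clipped-Gaussian height
  field at 0.5 m with near-zero gap cells, plus a PAD profile placing
  canopy mass in the top third of each column and a 1–5 m shrub
  layer. LiDAR-like returns (default 24 points/m², Poisson in number,
  with a configurable ground-return fraction) exercise the rasterizer
  and PAD estimator.
- **Birds.** 48 species carry log-normal body mass, categorical
  migratory status / nest site / diet / foraging strata, detectability
  uniform on (0.3, 0.9), and Poisson log-linear responses: true count
  ~ Poisson(exp(baseline + β·covariates + log-area offset)), thinned
  Binomially per visit. Age-class coefficients (per-species SD 0.8
  around class means that dip in thicket/pole and rise in open and
  early stands) dominate the weak direct structure effects (SD 0.15),
  so age class is the encoded dominant driver. The baseline
  log-abundance distribution (mean −2, SD 1.5) yields many rare
  species, producing the species–area accumulation seen in real
  surveys.

The truth bundle (latent structure, expected counts, dominant driver)
is emitted alongside the data and consumed only by recovery
experiments, never by pipeline stages.

What the generator does **not** emulate: territoriality and species
interactions, edge and landscape-context effects, observer and
weather variation, multi-year dynamics, sensor physics, and spatial
autocorrelation between neighbouring compartments. Passing recovery
tests therefore show that the pipeline attributes variance correctly
under its own assumptions, not that those assumptions hold in any
particular forest.

## Problem sizes and numerical choices

The end-to-end recovery experiment uses 20 landscapes of 1000
compartments (≈ 36–41 groups each, the same order as a real
stand-register analysis); the species–area experiment runs the
generator and assembly stages only (structural metrics do not enter
that regression). Identities are asserted at 1e-8, oracle agreement
at 1e-10, closed forms at 1e-10 or printed precision. Degenerate
inputs follow documented conventions: empty landscapes return empty
tables; all-zero grids have gap fraction 0 and undefined Moran's I;
detectability constants outside (0, 1] and duplicate survey records
are hard errors, never silently defaulted.

## Known limitations

- The CHM simplification (max + nearest-neighbour fill) understates
  canopy tops in sparse clouds relative to pit-free interpolation.
- Group covariates are unweighted member means; an area-weighted
  variant would emphasize large stands and is not implemented.
- Compartment geometries are squares in the generator; clipping to
  arbitrary polygons is supported for real data but not exercised by
  the synthetic path.
- No correction for multiple testing across the six responses, and no
  spatial or mixed-effects extensions.
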