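# canopybird

Forest managers shape bird communities through the structure their
management creates: stand age, canopy height and density, gaps, shrub
layers. `canopybird` implements a stand-scale analysis that links
canopy structure measured by airborne laser scanning (LiDAR) to six
bird-diversity responses — species richness *S*, Shannon diversity
*H′*, and the four trait-based metrics FRic, FEve, FDiv and FDis — and
asks which habitat variables matter most, and at which raster
resolution they are best measured.

It is written for ecologists working with plantation-forest bird
surveys and LiDAR canopy products, and ships with a seeded synthetic
landscape generator so the entire pipeline can be exercised and
validated end to end without any field data.

## The analysis

1. **Structure.** Height-normalized returns become a canopy height
   model (cellwise maximum, 0.5 m) and a MacArthur–Horn plant-area
   density profile (10 m columns, 1 m bins):
   `PAD[z, z+Δz) = ln(N(z+Δz)/N(z)) / (kΔz)` with `N(z)` the returns at
   or below height z. Six stand metrics follow: top canopy height
   (mean cell value), gap fraction (share of cells below ⅔ of the mean
   height), horizontal heterogeneity (Moran's *I*, rook contiguity),
   vertical evenness (Pielou's *J* of the PAD profile), shrub density
   (PAD sum over 1–5 m) and canopy density (PAD sum over the top third
   of the canopy, top = mean + 2 SD). CHM metrics are computed at
   0.5, 2, 5 and 10 m.
2. **Assembly.** Counts collapse to the maximum of two survey visits,
   compartments pool into management × age-class groups (≥ 10 members,
   ≥ 0.05 ha each), and group mean maximum counts are divided by
   species detectability constants. Group covariates are unweighted
   means of member metrics plus log total area.
3. **Diversity.** *S* and *H′* from the corrected abundances; FRic,
   FEve, FDiv, FDis in a principal-coordinates embedding of Gower
   trait dissimilarities; Shapiro–Wilk check with Box-Cox
   normalization (λ by profile likelihood on [−2, 2]).
4. **Partitioning.** Hierarchical partitioning decomposes the OLS R²
   over all 2^k predictor subsets (k ≤ 9) into per-variable independent
   effects `I_j` and joint effects `J_j = R²({j}) − I_j`, with
   `Σ I_j = R²(full)`. It also picks, per response and multi-resolution
   variable, the resolution with the highest share of independent
   effects.
5. **Models.** Pairwise associations (|Pearson r|, correlation ratio,
   Cramér's V) above |0.7| define collinearity; the feasible variable
   subset maximizing total independent effects (log area always forced)
   enters an OLS fit with aliasing-aware dummy coding and a type-2
   ANOVA.

## Worked example

```python
import canopybird as cb
from canopybird.pipeline import PipelineConfig
from canopybird.synthetic import LandscapeConfig

cfg = PipelineConfig(landscape=LandscapeConfig(n_compartments=1000), seed=5)
result = cb.run_full_analysis(cfg)
print("groups:", len(result.groups))
print(result.summary_frame()[["hp_r2_all", "model_r2", "top_nonarea_variable"]].round(2))
```

```
groups: 41
                  hp_r2_all  model_r2 top_nonarea_variable
metric
species_richness       0.86      0.82       age_simplified
shannon                0.89      0.88       age_simplified
fric                   0.82      0.80       age_simplified
feve                   0.71      0.69       age_simplified
fdiv                   0.63      0.58       age_simplified
fdis                   0.72      0.68       age_simplified
```

1000 simulated compartments collapse to 41 analysis groups. For every
diversity metric, stand age class carries the largest independent
effects among the non-area variables — exactly the driver the
generator encoded — while log total area dominates overall (the
species–area relationship). `result.model_results["species_richness"].summary()`
prints the fitted coefficients against the conifer / mixed-ages
baselines, the type-2 ANOVA and the partitioning table; for this seed
the richness model keeps gap fraction and horizontal heterogeneity
instead of age class because age is collinear with them and the
feasible combination carries more summed independent effects
(`Σ I`), with R² = 0.82 on 41 groups and log total area at
p ≈ 1.2 × 10⁻⁷.

The same stages run from the shell:

```bash
canopybird run-all --seed 5 --out results/run5
canopybird simulate --seed 3 --out sim/       # stage-by-stage variant
```

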