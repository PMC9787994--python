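"""Taxonomic and functional diversity metrics per compartment group.

Six response metrics: species richness, Shannon diversity (nats), and
four trait-based metrics computed in a principal-coordinates (PCoA)
embedding of Gower dissimilarities — functional richness (convex-hull
volume), functional evenness (regularity of abundance along the minimum
spanning tree), functional divergence (abundance-weighted deviation
from the mean distance to the hull-vertex centroid), and functional
dispersion (abundance-weighted mean distance to the abundance-weighted
centroid).  A Shapiro-Wilk check with Box-Cox normalization prepares
each metric for linear modelling.

Abundances may be fractional (detectability-corrected); richness uses
strict positivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "METRIC_NAMES",
    "TraitSpace",
    "taxonomic_diversity",
    "gower_distance",
    "build_trait_space",
    "functional_richness",
    "functional_evenness",
    "functional_divergence",
    "functional_dispersion",
    "normalize_metric",
    "compute_diversity_profile",
]

METRIC_NAMES = (
    "species_richness",
    "shannon",
    "fric",
    "feve",
    "fdiv",
    "fdis",
)


def taxonomic_diversity(abundances) -> tuple[int, float]:
    """Species richness and Shannon diversity H' (nats).

    Richness counts species with abundance > 0; H' = -sum p ln p over
    those species.  An all-zero community has richness 0 and undefined
    (nan) H'.
    """
    a = np.asarray(abundances, dtype=float)
    if (a < 0).any():
        raise ValueError("abundances must be >= 0")
    pos = a[a > 0]
    if pos.size == 0:
        return 0, float("nan")
    p = pos / pos.sum()
    return int(pos.size), float(-np.sum(p * np.log(p)))


def gower_distance(traits: pd.DataFrame) -> pd.DataFrame:
    """Gower dissimilarity for mixed-type trait tables.

    Per trait: |difference| / range for numeric traits, 0/1 mismatch for
    categorical ones; the distance is the unweighted mean over traits
    with both values present.  Numeric traits with zero range are
    dropped with a warning.
    """
    if len(traits) < 2:
        raise ValueError("need at least two species")
    n = len(traits)
    total = np.zeros((n, n))
    counts = np.zeros((n, n))
    used_any = False
    for col in traits.columns:
        s = traits[col]
        valid = s.notna().to_numpy()
        if not valid.any():
            raise ValueError(f"trait {col!r} has no non-missing values")
        pair_ok = np.outer(valid, valid)
        if pd.api.types.is_numeric_dtype(s):
            v = s.to_numpy(dtype=float)
            rng = np.nanmax(v) - np.nanmin(v)
            if rng == 0:
                warnings.warn(f"trait {col!r} has zero range; dropped")
                continue
            with np.errstate(invalid="ignore"):
                d = np.abs(v[:, None] - v[None, :]) / rng
            d = np.where(pair_ok, d, 0.0)
        else:
            v = s.to_numpy()
            d = (v[:, None] != v[None, :]).astype(float)
            d = np.where(pair_ok, d, 0.0)
        total += d
        counts += pair_ok
        used_any = True
    if not used_any:
        raise ValueError("no usable traits")
    if (counts == 0).any():
        raise ValueError("some species pairs share no non-missing trait")
    out = total / counts
    np.fill_diagonal(out, 0.0)
    return pd.DataFrame(out, index=traits.index, columns=traits.index)


@dataclass
class TraitSpace:
    """Species coordinates in a reduced trait ordination.

    ``coords``: species × m axes; ``quality``: share of positive PCoA
    eigenvalues captured by the retained axes (an R²-like ratio);
    ``sqrt_corrected``: whether dissimilarities were square-root
    transformed to remove negative eigenvalues.
    """

    coords: pd.DataFrame
    quality: float
    sqrt_corrected: bool
    eigenvalues: np.ndarray

    @property
    def m(self) -> int:
        return self.coords.shape[1]


def _pcoa(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Classical principal-coordinates eigendecomposition."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def build_trait_space(
    dissimilarity: pd.DataFrame,
    max_axes: int = 4,
    min_richness: int | None = None,
) -> TraitSpace:
    """Embed a dissimilarity matrix by principal coordinates.

    If the matrix is non-Euclidean (negative eigenvalues beyond
    numerical noise), the square-root transform of the dissimilarities
    is embedded instead.  ``m = min(max_axes, min_richness - 1)`` axes
    are retained — functional richness needs more species than axes in
    every community — and the quality is the retained share of positive
    eigenvalues.
    """
    d = np.asarray(dissimilarity, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least two species")
    tol = 1e-8 * max(np.abs(d).max(), 1.0)
    vals, vecs = _pcoa(d)
    corrected = False
    if vals.min() < -tol:
        vals, vecs = _pcoa(np.sqrt(d))
        corrected = True
    pos = vals > tol
    m = int(min(max_axes, n - 1, max(pos.sum(), 1)))
    if min_richness is not None:
        m = max(min(m, min_richness - 1), 1)
    lead = vals[:m].clip(min=0.0)
    coords = vecs[:, :m] * np.sqrt(lead)
    quality = float(lead.sum() / vals[pos].sum()) if pos.any() else 1.0
    return TraitSpace(
        coords=pd.DataFrame(
            coords,
            index=dissimilarity.index,
            columns=[f"pc{i + 1}" for i in range(m)],
        ),
        quality=min(quality, 1.0),
        sqrt_corrected=corrected,
        eigenvalues=vals,
    )


def _present(space: TraitSpace, abundances: pd.Series):
    a = abundances.reindex(space.coords.index).fillna(0.0)
    mask = a > 0
    return space.coords.to_numpy()[mask.to_numpy()], a[mask].to_numpy()


def functional_richness(space: TraitSpace, abundances: pd.Series) -> float:
    """Convex-hull volume of the species present, in trait-space units.

    Undefined (nan) when the number of species present does not exceed
    the space dimension or the configuration is degenerate.
    """
    x, _ = _present(space, abundances)
    if len(x) <= space.m:
        warnings.warn("functional richness undefined: S <= m")
        return float("nan")
    try:
        return float(ConvexHull(x).volume)
    except QhullError:
        warnings.warn("functional richness undefined: degenerate hull")
        return float("nan")


def functional_evenness(space: TraitSpace, abundances: pd.Series) -> float:
    """Regularity of abundance along the minimum spanning tree (0-1).

    Each MST branch gets weight EW = length / (w_i + w_j) with w the
    relative abundances; FEve rescales the partial weights so that a
    perfectly regular tree with even abundances scores 1.
    """
    x, w = _present(space, abundances)
    s = len(x)
    if s < 3:
        return float("nan")
    w = w / w.sum()
    dist = squareform(pdist(x))
    mst = minimum_spanning_tree(dist).tocoo()
    ew = mst.data / (w[mst.row] + w[mst.col])
    pew = ew / ew.sum()
    thr = 1.0 / (s - 1)
    return float((np.minimum(pew, thr).sum() - thr) / (1.0 - thr))


def functional_divergence(space: TraitSpace, abundances: pd.Series) -> float:
    """Abundance-weighted divergence from the hull-centroid distance (0-1).

    G is the centroid of the convex-hull vertices; with d_i the species
    distances to G and dG their unweighted mean,
    FDiv = (sum w (d - dG) + dG) / (sum w |d - dG| + dG).
    """
    x, w = _present(space, abundances)
    s = len(x)
    if s < 3:
        return float("nan")
    w = w / w.sum()
    if x.shape[1] == 1 or s <= x.shape[1]:
        vertices = x[[int(np.argmin(x[:, 0])), int(np.argmax(x[:, 0]))]] \
            if x.shape[1] == 1 else x
    else:
        try:
            vertices = x[ConvexHull(x).vertices]
        except QhullError:
            warnings.warn("functional divergence undefined: degenerate hull")
            return float("nan")
    g = vertices.mean(axis=0)
    d = np.linalg.norm(x - g, axis=1)
    dg = d.mean()
    if dg == 0:
        return float("nan")
    delta = float(np.sum(w * (d - dg)))
    delta_abs = float(np.sum(w * np.abs(d - dg)))
    return (delta + dg) / (delta_abs + dg)


def functional_dispersion(space: TraitSpace, abundances: pd.Series) -> float:
    """Abundance-weighted mean distance to the abundance-weighted centroid."""
    x, w = _present(space, abundances)
    if len(x) == 0:
        return float("nan")
    if len(x) == 1:
        return 0.0
    w = w / w.sum()
    c = w @ x
    return float(np.sum(w * np.linalg.norm(x - c, axis=1)))


def normalize_metric(
    values, alpha: float = 0.05
) -> tuple[np.ndarray, float | None, float]:
    """Shapiro-Wilk check, then Box-Cox normalization if needed.

    If the normality test is not rejected at ``alpha`` the values pass
    through unchanged (lambda None).  Otherwise lambda maximizes the
    Box-Cox profile log-likelihood over the grid [-2, 2] in steps of
    0.01; values must then be strictly positive.

    Returns ``(transformed, lambda, shapiro_p)``.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 3:
        raise ValueError("need at least three finite values")
    p = float(stats.shapiro(v).pvalue)
    if p >= alpha:
        return v, None, p
    if (v <= 0).any():
        raise ValueError(
            "Box-Cox requires positive values; shift the metric by a "
            "documented constant before normalizing"
        )
    grid = np.arange(-2.0, 2.0 + 1e-9, 0.01)
    ll = np.array([stats.boxcox_llf(lam, v) for lam in grid])
    lam = float(grid[int(np.argmax(ll))])
    return stats.boxcox(v, lmbda=lam), lam, p


def compute_diversity_profile(
    abundance: pd.DataFrame,
    traits: pd.DataFrame,
    max_axes: int = 4,
    normalize: bool = True,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """All six metrics for a group × species abundance matrix.

    Builds one Gower/PCoA trait space for the species pool (axes capped
    at the smallest community richness minus one), computes the six
    metrics per group, and optionally Box-Cox-normalizes each metric
    across groups, recording lambda per metric.

    Returns ``(profile, meta)`` where meta holds the trait-space quality
    and the per-metric transform lambdas.
    """
    observed = abundance.columns[(abundance > 0).any(axis=0)]
    missing = set(observed) - set(traits.index)
    if missing:
        raise ValueError(f"species without traits: {sorted(missing)[:5]}")
    richness = (abundance > 0).sum(axis=1)
    min_rich = int(richness[richness > 0].min()) if (richness > 0).any() else 2
    d = gower_distance(traits.loc[sorted(set(observed) | set(traits.index))])
    space = build_trait_space(d, max_axes=max_axes, min_richness=max(min_rich, 2))

    rows = {}
    for gid, ab in abundance.iterrows():
        s, h = taxonomic_diversity(ab.to_numpy())
        rows[gid] = {
            "species_richness": s,
            "shannon": h,
            "fric": functional_richness(space, ab),
            "feve": functional_evenness(space, ab),
            "fdiv": functional_divergence(space, ab),
            "fdis": functional_dispersion(space, ab),
        }
    profile = pd.DataFrame.from_dict(rows, orient="index")[list(METRIC_NAMES)]
    meta = {
        "trait_space_quality": space.quality,
        "trait_space_axes": space.m,
        "sqrt_corrected": space.sqrt_corrected,
        "lambdas": {},
        "shapiro_p": {},
    }
    if normalize:
        for name in METRIC_NAMES:
            col = profile[name].to_numpy(dtype=float)
            finite = np.isfinite(col)
            if finite.sum() < 3:
                continue
            vals = col[finite]
            try:
                transformed, lam, p = normalize_metric(vals, alpha=alpha)
            except ValueError:
                # nonpositive values: shift to positive support first
                shift = float(vals.min()) - 1e-6 if (vals <= 0).any() else 0.0
                transformed, lam, p = normalize_metric(vals - shift, alpha=alpha)
            out = col.copy()
            out[finite] = transformed
            profile[name + "_norm"] = out
            meta["lambdas"][name] = lam
            meta["shapiro_p"][name] = p
    return profile, meta
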