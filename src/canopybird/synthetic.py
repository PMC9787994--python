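"""Seeded synthetic landscapes, LiDAR-like canopy data, and bird surveys.

Emulates a managed plantation forest: compartments (stands) with
management type and age class drawn from the categories practitioners
use, age-dependent canopy structure rendered as canopy-height grids and
plant-area profiles, LiDAR-like returns at a configurable point
density, and two-visit breeding-bird surveys generated by a Poisson
log-linear abundance model with binomial detection thinning.

Every generator is a pure function of (config, seed).  The ground truth
(latent stand structure, per-species expected counts) is emitted
alongside the data so that recovery experiments can score the analysis
pipeline against it; the pipeline itself never reads the truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .categories import (
    AGE_BANDS,
    DETAILED_AGE_CLASSES,
    DETAILED_MANAGEMENT,
    NOT_APPLICABLE,
    simplify_age,
    simplify_management,
)
from .structure import CanopyGrid, PADProfile

__all__ = [
    "LandscapeConfig",
    "SpeciesPool",
    "SyntheticTruth",
    "generate_landscape",
    "generate_canopy",
    "simulate_lidar_returns",
    "simulate_bird_counts",
    "make_species_pool",
]

# Latent structural covariates species may respond to, standardized to
# roughly unit scale across a landscape before use.
CONTINUOUS_COVARIATES = ("height", "gap", "shrub")
AGE_DUMMY_COVARIATES = (
    "age_restock",   # restock/pre-thicket
    "age_thicket",   # thicket/pole
    "age_mature",
    "age_open",      # not applicable (open/other)
)  # baseline: mixed ages

_SIMPLIFIED_TO_DUMMY = {
    "Restock/pre-thicket": "age_restock",
    "Thicket/pole": "age_thicket",
    "Mature": "age_mature",
    NOT_APPLICABLE: "age_open",
    "Mixed": None,
}


def _default_management_probs() -> dict[str, float]:
    # conifer-majority plantation, as in UK lowland pine forests; the
    # detailed types are kept broadly comparable in prevalence so that
    # group sizes are not a proxy for crop identity
    return {
        "Corsican pine monoculture": 0.22,
        "Scots pine monoculture": 0.14,
        "Douglas fir monoculture": 0.07,
        "Other conifer monoculture": 0.05,
        "Birch monoculture": 0.07,
        "Other broadleaved monoculture": 0.09,
        "Conifer/broadleaved mixture (conifer)": 0.10,
        "Conifer/broadleaved mixture (broadleaved)": 0.08,
        "Open": 0.05,
        "Open with trees": 0.05,
        "Other": 0.04,
        "Felled": 0.04,
    }


def _default_age_probs() -> dict[str, float]:
    # detailed age bands for treed stands; a rotation-managed forest has
    # most area in pole and mature stages
    return {
        "Restock": 0.12,
        "Pre-thicket": 0.10,
        "Thicket": 0.15,
        "Pole": 0.25,
        "Mature": 0.28,
        "Mixed ages": 0.10,
    }


@dataclass
class LandscapeConfig:
    """Configuration of a synthetic landscape.

    Defaults mirror the study system: compartments average 2.35 ha
    (SD 2.53, right-skewed), canopy grids at 0.5 m, LiDAR at
    24 points/m².  ``height_by_age``, ``gap_prob_by_age`` and
    ``shrub_level_by_age`` are keyed by simplified age class and set the
    latent stand structure each age class produces.
    """

    n_compartments: int = 1000
    mean_area: float = 2.35
    area_sd: float = 2.53
    management_probs: dict[str, float] = field(default_factory=_default_management_probs)
    age_probs: dict[str, float] = field(default_factory=_default_age_probs)
    height_by_age: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "Restock/pre-thicket": (1.0, 0.8),
            "Thicket/pole": (9.0, 2.5),
            "Mature": (20.0, 2.5),
            "Mixed": (12.0, 5.0),
            NOT_APPLICABLE: (0.3, 0.4),
        }
    )
    gap_prob_by_age: dict[str, float] = field(
        default_factory=lambda: {
            "Restock/pre-thicket": 0.35,
            "Thicket/pole": 0.10,
            "Mature": 0.08,
            "Mixed": 0.20,
            NOT_APPLICABLE: 0.80,
        }
    )
    shrub_level_by_age: dict[str, float] = field(
        default_factory=lambda: {
            "Restock/pre-thicket": 0.45,
            "Thicket/pole": 0.15,
            "Mature": 0.08,
            "Mixed": 0.30,
            NOT_APPLICABLE: 0.10,
        }
    )
    grid_resolution: float = 0.5
    point_density: float = 24.0
    ground_return_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name, probs in (
            ("management_probs", self.management_probs),
            ("age_probs", self.age_probs),
        ):
            if abs(sum(probs.values()) - 1.0) > 1e-8 or min(probs.values()) < 0:
                raise ValueError(f"{name} must be non-negative and sum to 1")
        unknown = set(self.management_probs) - set(DETAILED_MANAGEMENT)
        if unknown:
            raise ValueError(f"unknown management types: {sorted(unknown)}")
        unknown = set(self.age_probs) - set(DETAILED_AGE_CLASSES)
        if unknown:
            raise ValueError(f"unknown age classes: {sorted(unknown)}")
        if self.mean_area <= 0 or self.area_sd <= 0:
            raise ValueError("areas must be positive")
        if self.point_density <= 0:
            raise ValueError("point_density must be positive")
        if not 0 <= self.ground_return_fraction <= 1:
            raise ValueError("ground_return_fraction must be in [0, 1]")


@dataclass
class SpeciesPool:
    """Species with traits, detectability, and habitat responses.

    ``traits`` is a species-indexed table of body mass (g) and the
    categorical traits (migratory status, nest site, diet, foraging
    strata).  ``response_coefficients`` holds each species' real effect
    on its log expected count per covariate; ``detectability`` the
    per-visit detection probability.
    """

    traits: pd.DataFrame
    detectability: pd.Series
    response_coefficients: pd.DataFrame
    baseline_log_abundance: pd.Series

    def __post_init__(self) -> None:
        d = self.detectability
        if ((d <= 0) | (d > 1)).any():
            raise ValueError("detectability must be in (0, 1]")
        if self.traits.isna().any().any():
            raise ValueError("every species needs a value for every trait")
        missing = set(self.traits.index) - set(self.response_coefficients.index)
        if missing:
            raise ValueError(f"species missing coefficients: {sorted(missing)}")

    @property
    def species(self) -> pd.Index:
        return self.traits.index


@dataclass
class SyntheticTruth:
    """Ground truth emitted with the data, never consumed by the pipeline.

    ``structure``: per-compartment latent stand parameters (height mean
    and sd, gap probability, shrub level).  ``covariates``: the values
    species respond to (age dummies + standardized structure).
    ``expected_counts``: species × compartment Poisson means (filled by
    :func:`simulate_bird_counts`).  ``dominant_driver``: name of the
    covariate group simulated strongest.
    """

    structure: pd.DataFrame
    covariates: pd.DataFrame
    expected_counts: pd.DataFrame | None = None
    dominant_driver: str = "age_class"


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------

def generate_landscape(
    config: LandscapeConfig,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw a compartment table and its ground truth.

    Areas are log-normal with the configured mean and SD (matching the
    right-skewed sizes of real compartments); management types and age
    classes are drawn from the configured detailed categories, with
    open/other management always paired with the "not applicable" age
    class.  Latent stand structure (canopy height mean/sd, gap
    probability, shrub level) is drawn per compartment around its
    age-class values and recorded in the truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_compartments
    cols = ["compartment_id", "management", "age_class", "age_years", "area_ha"]
    if n == 0:
        empty = pd.DataFrame(columns=cols)
        truth = SyntheticTruth(
            structure=pd.DataFrame(), covariates=pd.DataFrame()
        )
        return empty, truth

    # log-normal parameterized by its mean and sd
    sigma2 = math.log(1.0 + (config.area_sd / config.mean_area) ** 2)
    mu = math.log(config.mean_area) - sigma2 / 2.0
    areas = rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)

    mgmt_names = list(config.management_probs)
    mgmt = rng.choice(mgmt_names, size=n, p=list(config.management_probs.values()))
    age_names = list(config.age_probs)
    ages = rng.choice(age_names, size=n, p=list(config.age_probs.values()))
    # open/other management has no meaningful stand age
    open_mask = np.array(
        [simplify_management(m) == "Open/other" for m in mgmt]
    )
    ages = np.where(open_mask, NOT_APPLICABLE, ages)

    age_years = np.full(n, np.nan)
    for band, (lo, hi) in AGE_BANDS.items():
        sel = ages == band
        if sel.any():
            age_years[sel] = rng.integers(lo, hi + 1, size=int(sel.sum()))

    compartments = pd.DataFrame(
        {
            "compartment_id": [f"C{i:05d}" for i in range(n)],
            "management": mgmt,
            "age_class": ages,
            "age_years": age_years,
            "area_ha": areas,
        }
    )

    simplified_age = compartments["age_class"].map(simplify_age)
    h_mean = np.empty(n)
    h_sd = np.empty(n)
    gap_p = np.empty(n)
    shrub = np.empty(n)
    for i, sa in enumerate(simplified_age):
        m, s = config.height_by_age[sa]
        h_mean[i] = max(rng.normal(m, s / 2.0), 0.05)
        h_sd[i] = max(s * rng.uniform(0.7, 1.3), 0.05)
        gap_p[i] = float(np.clip(rng.normal(config.gap_prob_by_age[sa], 0.05), 0, 1))
        shrub[i] = max(rng.normal(config.shrub_level_by_age[sa], 0.08), 0.0)
    structure = pd.DataFrame(
        {
            "height_mean": h_mean,
            "height_sd": h_sd,
            "gap_prob": gap_p,
            "shrub_level": shrub,
        },
        index=compartments["compartment_id"],
    )

    covariates = pd.DataFrame(
        0.0,
        index=compartments["compartment_id"],
        columns=list(AGE_DUMMY_COVARIATES) + list(CONTINUOUS_COVARIATES),
    )
    for cid, sa in zip(compartments["compartment_id"], simplified_age):
        dummy = _SIMPLIFIED_TO_DUMMY[sa]
        if dummy is not None:
            covariates.loc[cid, dummy] = 1.0
    # standardized latent structure
    for name, values in (
        ("height", h_mean),
        ("gap", gap_p),
        ("shrub", shrub),
    ):
        sd = values.std()
        covariates[name] = (values - values.mean()) / (sd if sd > 0 else 1.0)

    truth = SyntheticTruth(structure=structure, covariates=covariates)
    return compartments, truth


# ---------------------------------------------------------------------------
# Canopy and returns
# ---------------------------------------------------------------------------

def generate_canopy(
    compartment: pd.Series,
    config: LandscapeConfig,
    structure_params: pd.Series | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[CanopyGrid, PADProfile]:
    """Render one compartment's canopy grid and plant-area profile.

    The compartment footprint is a square of its area.  Cell heights are
    a clipped Gaussian field around the stand's latent mean; a fraction
    of cells are near-zero gaps; the PAD profile places canopy mass just
    below each column's mean height plus a shrub layer at 1–5 m whose
    mass follows the stand's shrub level.

    ``structure_params`` (height_mean, height_sd, gap_prob, shrub_level)
    may come from the landscape truth; by default they are the age-class
    values from the config.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sa = simplify_age(compartment["age_class"])
    if structure_params is not None:
        h_mean = float(structure_params["height_mean"])
        h_sd = float(structure_params["height_sd"])
        gap_p = float(structure_params["gap_prob"])
        shrub_level = float(structure_params["shrub_level"])
    else:
        h_mean, h_sd = config.height_by_age[sa]
        gap_p = config.gap_prob_by_age[sa]
        shrub_level = config.shrub_level_by_age[sa]

    side = math.sqrt(float(compartment["area_ha"]) * 1e4)
    res = config.grid_resolution
    n_cells = max(int(round(side / res)), 1)
    cells = np.clip(rng.normal(h_mean, h_sd, size=(n_cells, n_cells)), 0.0, None)
    if gap_p > 0:
        gaps = rng.random((n_cells, n_cells)) < gap_p
        cells[gaps] = rng.uniform(0.0, 0.2, size=int(gaps.sum()))
    grid = CanopyGrid(resolution=res, origin=(0.0, side), cells=cells)

    profile = _profile_from_grid(grid, shrub_level, column_resolution=10.0)
    return grid, profile


def _profile_from_grid(
    grid: CanopyGrid, shrub_level: float, column_resolution: float = 10.0
) -> PADProfile:
    """Deterministic PAD profile consistent with a canopy height grid."""
    cells = grid.cells
    ny, nx = cells.shape
    step = max(int(round(column_resolution / grid.resolution)), 1)
    n_cy = max(ny // step, 1)
    n_cx = max(nx // step, 1)
    zmax = float(np.nanmax(cells)) if cells.size else 0.0
    n_bins = max(int(math.ceil(max(zmax, 5.0))) + 1, 6)
    edges = np.arange(n_bins + 1, dtype=float)

    # mean canopy height per 10-m column (block-reduced)
    sub = cells[: n_cy * step, : n_cx * step]
    h = np.nanmean(
        sub.reshape(n_cy, step, n_cx, step), axis=(1, 3)
    ).ravel()
    # canopy mass spread uniformly over the top third of each column
    lo = np.maximum(np.floor(2.0 * h / 3.0), 0.0)
    hi = np.maximum(np.ceil(h), lo + 1.0)
    bins = np.arange(n_bins, dtype=float)
    canopy = (bins >= lo[:, None]) & (bins < hi[:, None])
    pad = canopy / (hi - lo)[:, None]
    pad[h < 1.0] = 0.0
    pad[:, 1:5] += shrub_level / 4.0  # shrub layer between 1 and 5 m

    x0, y0 = grid.origin
    cx = x0 + (np.arange(n_cx) + 0.5) * column_resolution
    cy = y0 - (np.arange(n_cy) + 0.5) * column_resolution
    gx, gy = np.meshgrid(cx, cy)
    xy = np.column_stack([gx.ravel(), gy.ravel()])
    return PADProfile(column_xy=xy, bin_edges=edges, pad=pad)


def simulate_lidar_returns(
    canopy: CanopyGrid,
    point_density: float,
    rng: np.random.Generator | None = None,
    ground_return_fraction: float = 0.05,
    noise_sd: float = 0.15,
) -> np.ndarray:
    """Simulate LiDAR returns over a canopy grid.

    Return count is Poisson(density × area) with uniform positions;
    each return takes its cell's canopy height plus small Gaussian
    noise, except a configurable fraction of ground returns at ~0.
    Returns an (n, 3) array of x, y, height.
    """
    if point_density <= 0:
        raise ValueError("point_density must be positive")
    if rng is None:
        rng = np.random.default_rng(0)
    ny, nx = canopy.cells.shape
    if ny == 0 or nx == 0:
        return np.empty((0, 3))
    width = nx * canopy.resolution
    height = ny * canopy.resolution
    n = rng.poisson(point_density * width * height)
    if n == 0:
        return np.empty((0, 3))
    x0, y0 = canopy.origin
    x = x0 + rng.uniform(0, width, size=n)
    y = y0 - rng.uniform(0, height, size=n)
    ix = np.minimum((x - x0) / canopy.resolution, nx - 1).astype(int)
    iy = np.minimum((y0 - y) / canopy.resolution, ny - 1).astype(int)
    z = canopy.cells[iy, ix] + rng.normal(0, noise_sd, size=n)
    z = np.clip(z, 0.0, None)
    ground = rng.random(n) < ground_return_fraction
    z[ground] = np.abs(rng.normal(0, 0.02, size=int(ground.sum())))
    return np.column_stack([x, y, z])


# ---------------------------------------------------------------------------
# Species pool and surveys
# ---------------------------------------------------------------------------

TRAIT_LEVELS = {
    "migratory_status": ("resident", "short_distance", "long_distance"),
    "nest_site": ("ground", "shrub", "canopy", "cavity"),
    "diet": ("invertebrates", "seeds", "omnivore", "vertebrates"),
    "foraging_strata": ("ground", "understorey", "canopy", "aerial"),
}

#: age-class mean effects on log abundance (added to each species' own
#: random coefficient): open and early-successional stands richer than
#: the intermediate thicket/pole stage, as in temperate plantations.
DEFAULT_AGE_CLASS_MEANS = {
    "age_restock": 0.3,
    "age_thicket": -0.5,
    "age_mature": 0.1,
    "age_open": 0.3,
}


@dataclass
class PoolConfig:
    """Distributions for :func:`make_species_pool`.

    ``age_effect_sd`` controls species turnover between age classes (the
    dominant simulated driver); ``structure_effect_sd`` the (weaker)
    direct response to continuous structure.
    """

    body_mass_log_mean: float = math.log(20.0)
    body_mass_log_sd: float = 0.9
    detectability_range: tuple[float, float] = (0.3, 0.9)
    # a log-normal species-abundance distribution with many rare species:
    # per-compartment expected counts mostly well below 1, so group
    # richness accumulates with group size (species-area sampling)
    baseline_log_mean: float = -2.0
    baseline_log_sd: float = 1.5
    age_effect_sd: float = 0.8
    structure_effect_sd: float = 0.15
    age_class_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_CLASS_MEANS)
    )


def make_species_pool(
    n_species: int = 48,
    trait_config: PoolConfig | None = None,
    seed: int = 0,
) -> SpeciesPool:
    """Draw a species pool with traits, detectabilities, and responses.

    Body mass is log-normal; categorical traits uniform over their
    levels; detectability uniform on the configured interval.  Response
    coefficients are Gaussian: per-species age-class effects (centered
    on the age-class means, SD ``age_effect_sd``) plus weaker effects on
    the continuous structural covariates.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    cfg = trait_config or PoolConfig()
    rng = np.random.default_rng(seed)
    idx = pd.Index([f"sp{i:03d}" for i in range(n_species)], name="species_id")

    traits = pd.DataFrame(index=idx)
    traits["body_mass_g"] = rng.lognormal(
        cfg.body_mass_log_mean, cfg.body_mass_log_sd, size=n_species
    )
    for trait, levels in TRAIT_LEVELS.items():
        traits[trait] = rng.choice(levels, size=n_species)

    detectability = pd.Series(
        rng.uniform(*cfg.detectability_range, size=n_species), index=idx,
        name="detectability",
    )
    coef = pd.DataFrame(
        0.0, index=idx,
        columns=list(AGE_DUMMY_COVARIATES) + list(CONTINUOUS_COVARIATES),
    )
    for dummy in AGE_DUMMY_COVARIATES:
        coef[dummy] = rng.normal(
            cfg.age_class_means.get(dummy, 0.0), cfg.age_effect_sd, size=n_species
        )
    for cov in CONTINUOUS_COVARIATES:
        coef[cov] = rng.normal(0.0, cfg.structure_effect_sd, size=n_species)
    baseline = pd.Series(
        rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=n_species),
        index=idx, name="baseline_log_abundance",
    )
    return SpeciesPool(
        traits=traits,
        detectability=detectability,
        response_coefficients=coef,
        baseline_log_abundance=baseline,
    )


def simulate_bird_counts(
    compartments: pd.DataFrame,
    truth: SyntheticTruth,
    pool: SpeciesPool,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-visit survey counts from the Poisson log-linear model.

    True count per species × compartment is Poisson with
    ``log E = baseline + coefficients · covariates + log-area offset``;
    the offset (compartment area over the landscape geometric mean)
    makes expected counts proportional to surveyed area, so larger
    stands hold more birds at equal density.  Each of the two visits
    records a Binomial(true count, detectability) thinning.  Returns a
    long table (compartment_id, species_id, visit, count) with zero
    counts omitted.  ``truth.expected_counts`` is filled.
    """
    missing = set(pool.response_coefficients.columns) - set(truth.covariates.columns)
    if missing:
        raise ValueError(f"covariates named by coefficients not in truth: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    cov = truth.covariates.loc[
        compartments["compartment_id"], pool.response_coefficients.columns
    ].to_numpy()  # (n_comp, n_cov)
    beta = pool.response_coefficients.to_numpy()  # (n_sp, n_cov)
    log_area = np.log(compartments["area_ha"].to_numpy(dtype=float))
    offset = log_area - log_area.mean()
    log_lambda = (
        pool.baseline_log_abundance.to_numpy()[:, None]
        + beta @ cov.T
        + offset[None, :]
    )
    lam = np.exp(np.clip(log_lambda, None, 10.0))  # (n_sp, n_comp)
    true_counts = rng.poisson(lam)
    det = pool.detectability.to_numpy()[:, None]
    records = []
    for visit in (1, 2):
        seen = rng.binomial(true_counts, det)
        sp_i, comp_i = np.nonzero(seen)
        records.append(
            pd.DataFrame(
                {
                    "compartment_id": compartments["compartment_id"].to_numpy()[comp_i],
                    "species_id": pool.species.to_numpy()[sp_i],
                    "visit": visit,
                    "count": seen[sp_i, comp_i],
                }
            )
        )
    truth.expected_counts = pd.DataFrame(
        lam, index=pool.species, columns=compartments["compartment_id"]
    )
    survey = pd.concat(records, ignore_index=True)
    return survey.sort_values(
        ["compartment_id", "species_id", "visit"], ignore_index=True
    )
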