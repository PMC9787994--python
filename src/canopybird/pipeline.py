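"""End-to-end orchestration: simulate → structure → assemble → diversity
→ partition → fit.

Each stage is a function over plain tables so any stage can be re-run
in isolation from files; :func:`run_full_analysis` wires them together,
writes per-stage CSV outputs and a manifest (config hash, seed, output
checksums), and returns the result bundle in memory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assembly, diversity, io, structure
from .hierpart import Predictor, hier_part, select_resolution
from .models import HabitatModel, HabitatResults
from .structure import CHM_METRICS, PROFILE_METRICS, _res_tag
from .synthetic import (
    LandscapeConfig,
    PoolConfig,
    SpeciesPool,
    SyntheticTruth,
    generate_canopy,
    generate_landscape,
    make_species_pool,
    simulate_bird_counts,
)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "simulate_stage",
    "structure_stage",
    "partition_stage",
    "run_full_analysis",
]

logger = logging.getLogger("canopybird")

#: the six non-multiresolution analysis variables
BASE_VARIABLES = (
    "management_simplified",
    "age_simplified",
    "vertical_evenness",
    "shrub_density",
    "canopy_density",
    "log_total_area",
)
MULTIRES_VARIABLES = {
    "top_canopy_height": "top_canopy_height",
    "gap_fraction": "gap_fraction",
    "horizontal_heterogeneity": "horizontal_heterogeneity",
}


@dataclass
class PipelineConfig:
    """Thresholds, sizes, and seed for one full analysis run."""

    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    pool: PoolConfig = field(default_factory=PoolConfig)
    n_species: int = 48
    resolutions: tuple[float, ...] = (0.5, 2.0, 5.0, 10.0)
    collinearity_threshold: float = 0.7
    min_group_members: int = 10
    min_area_ha: float = 0.05
    max_hp_variables: int = 9
    alpha: float = 0.05
    seed: int = 0
    group_by: str = "detailed"
    output_dir: str | None = None
    write_rasters: bool = False

    def __post_init__(self) -> None:
        if sorted(self.resolutions) != list(self.resolutions):
            raise ValueError("resolutions must be sorted ascending")
        for name in ("collinearity_threshold", "min_group_members",
                     "min_area_ha", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "landscape" in raw:
            raw["landscape"] = LandscapeConfig(**raw["landscape"])
        if "pool" in raw:
            raw["pool"] = PoolConfig(**raw["pool"])
        if "resolutions" in raw:
            raw["resolutions"] = tuple(raw["resolutions"])
        return cls(**raw)


@dataclass
class PipelineResult:
    """Everything one run produces, keyed the way the CSV outputs are."""

    config: PipelineConfig
    compartments: pd.DataFrame
    truth: SyntheticTruth
    pool: SpeciesPool
    survey: pd.DataFrame
    metrics: pd.DataFrame
    groups: pd.DataFrame
    abundance: pd.DataFrame
    audit: dict
    diversity_profile: pd.DataFrame
    diversity_meta: dict
    resolution_choices: pd.DataFrame
    hp_tables: dict[str, pd.DataFrame]
    model_results: dict[str, HabitatResults]
    manifest: dict = field(default_factory=dict)

    def top_nonarea_variable(self, metric: str) -> str:
        """Variable with the largest independent effect, excluding area."""
        hp = self.hp_tables[metric]
        return hp.drop(index="log_total_area")["independent"].idxmax()

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for metric, res in self.model_results.items():
            rows.append(
                {
                    "metric": metric,
                    "hp_r2_all": res.hp.r2_full,
                    "model_r2": res.rsquared,
                    "model_r2_adj": res.rsquared_adj,
                    "selected": "+".join(res.selected),
                    "top_nonarea_variable": self.top_nonarea_variable(metric),
                }
            )
        return pd.DataFrame(rows).set_index("metric")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def simulate_stage(config: PipelineConfig):
    """Generate the landscape, species pool, and two-visit survey."""
    land = dataclasses.replace(config.landscape, seed=config.seed)
    compartments, truth = generate_landscape(land)
    pool = make_species_pool(
        config.n_species, config.pool, seed=config.seed + 1
    )
    survey = simulate_bird_counts(compartments, truth, pool, seed=config.seed + 2)
    return compartments, truth, pool, survey


def structure_stage(
    compartments: pd.DataFrame,
    config: PipelineConfig,
    truth: SyntheticTruth | None = None,
    raster_dir=None,
) -> pd.DataFrame:
    """Render each compartment's canopy and compute the six metrics.

    Canopy grids are generated and reduced to metrics one compartment at
    a time (grids for a full landscape would not fit in memory); the
    truth's latent stand parameters drive the rendering when given.
    """
    land = dataclasses.replace(config.landscape, seed=config.seed)
    rng = np.random.default_rng(config.seed + 3)
    rows = {}
    for _, comp in compartments.iterrows():
        params = None
        if truth is not None and len(truth.structure):
            params = truth.structure.loc[comp["compartment_id"]]
        grid, profile = generate_canopy(comp, land, structure_params=params, rng=rng)
        rows[comp["compartment_id"]] = structure.compute_structural_metrics(
            grid, profile, resolutions=config.resolutions
        )
        if raster_dir is not None:
            io.write_esri_ascii(
                grid, Path(raster_dir) / f"{comp['compartment_id']}_chm.asc"
            )
    metrics = pd.DataFrame.from_dict(rows, orient="index")
    metrics.index.name = "compartment_id"
    # a stand whose PAD profile is empty has no vegetation: evenness is
    # undefined there; treat as 0 for group averaging
    metrics["vertical_evenness"] = metrics["vertical_evenness"].fillna(0.0)
    hh = [c for c in metrics.columns if c.startswith("horizontal_heterogeneity")]
    metrics[hh] = metrics[hh].fillna(0.0)  # zero-variance grids: no structure
    return metrics


def _metric_columns(groups: pd.DataFrame, config: PipelineConfig):
    """Predictor builders over the group table."""
    def numeric(name, col):
        return Predictor.numeric(name, groups[col])

    base = [
        Predictor.categorical("management_simplified", groups["management_simplified"]),
        Predictor.categorical("age_simplified", groups["age_simplified"]),
        numeric("vertical_evenness", "vertical_evenness"),
        numeric("shrub_density", "shrub_density"),
        numeric("canopy_density", "canopy_density"),
        numeric("log_total_area", "log_total_area"),
    ]
    multires = {
        var: {
            res: numeric(var, f"{var}_{_res_tag(res)}")
            for res in config.resolutions
        }
        for var in MULTIRES_VARIABLES
    }
    return base, multires


def partition_stage(
    groups: pd.DataFrame,
    profile: pd.DataFrame,
    config: PipelineConfig,
):
    """Scale optimization plus the final nine-variable partition per metric.

    For each diversity metric and each multi-resolution structural
    variable, hierarchical partitioning picks the resolution with the
    highest percentage of independent effects (other multi-resolution
    variables held at the coarsest resolution); the final partition then
    runs on the nine analysis variables at their chosen resolutions.
    """
    import warnings

    choices = []
    hp_tables: dict[str, pd.DataFrame] = {}
    per_metric_frames: dict[str, pd.DataFrame] = {}
    warnings.filterwarnings(
        "once", message="rank-deficient predictor subset"
    )  # open/other vs not-applicable aliasing recurs in every subset scan
    for metric in diversity.METRIC_NAMES:
        response_col = (
            metric + "_norm" if metric + "_norm" in profile.columns else metric
        )
        y_all = profile[response_col]
        ok = y_all.notna()
        if ok.sum() < 12:
            logger.warning("metric %s: too few groups with defined values", metric)
        sub = groups.loc[ok[ok].index]
        y = y_all[ok].to_numpy(dtype=float)
        base, multires = _metric_columns(sub, config)
        chosen: dict[str, float] = {}
        for var in MULTIRES_VARIABLES:
            others = {v: c for v, c in multires.items() if v != var}
            res, diag = select_resolution(
                y, base, var, multires[var], other_multires=others
            )
            chosen[var] = res
            for r, row in diag.iterrows():
                choices.append(
                    {
                        "metric": metric,
                        "variable": var,
                        "resolution": r,
                        "percent_independent": row["percent_independent"],
                        "chosen": r == res,
                    }
                )
        predictors = [multires[var][chosen[var]] for var in MULTIRES_VARIABLES]
        predictors += base
        hp = hier_part(y, predictors)
        hp_tables[metric] = hp.to_frame().assign(r2_full=hp.r2_full)

        frame = sub[
            [
                "management_simplified",
                "age_simplified",
                "vertical_evenness",
                "shrub_density",
                "canopy_density",
                "log_total_area",
            ]
        ].copy()
        for var, res in chosen.items():
            frame[var] = sub[f"{var}_{_res_tag(res)}"]
        frame[response_col] = y
        per_metric_frames[metric] = frame
    return pd.DataFrame(choices), hp_tables, per_metric_frames


def fit_stage(
    per_metric_frames: dict[str, pd.DataFrame], config: PipelineConfig
) -> dict[str, HabitatResults]:
    """Collinearity screen, subset selection, and final model per metric."""
    results = {}
    for metric, frame in per_metric_frames.items():
        response = frame.columns[-1]
        variables = [c for c in frame.columns if c != response]
        model = HabitatModel(
            frame,
            response,
            variables,
            threshold=config.collinearity_threshold,
        )
        results[metric] = model.fit(select=True)
    return results


def run_full_analysis(config: PipelineConfig) -> PipelineResult:
    """Execute all stages in order and (optionally) write the outputs."""
    stage = "simulate"
    try:
        compartments, truth, pool, survey = simulate_stage(config)
        stage = "structure"
        out = Path(config.output_dir) if config.output_dir else None
        raster_dir = None
        if out is not None and config.write_rasters:
            raster_dir = io.ensure_dir(out / "rasters")
        metrics = structure_stage(
            compartments, config, truth=truth, raster_dir=raster_dir
        )
        stage = "assemble"
        groups, abundance, audit = assembly.build_group_table(
            compartments,
            survey,
            pool.detectability,
            metrics,
            min_members=config.min_group_members,
            min_area_ha=config.min_area_ha,
            by=config.group_by,
        )
        stage = "diversity"
        profile, meta = diversity.compute_diversity_profile(
            abundance, pool.traits, alpha=config.alpha
        )
        stage = "partition"
        choices, hp_tables, frames = partition_stage(groups, profile, config)
        stage = "fit"
        model_results = fit_stage(frames, config)
    except Exception as err:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err

    result = PipelineResult(
        config=config,
        compartments=compartments,
        truth=truth,
        pool=pool,
        survey=survey,
        metrics=metrics,
        groups=groups,
        abundance=abundance,
        audit=audit,
        diversity_profile=profile,
        diversity_meta=meta,
        resolution_choices=choices,
        hp_tables=hp_tables,
        model_results=model_results,
    )
    if config.output_dir:
        write_outputs(result, config.output_dir)
    return result


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_outputs(result: PipelineResult, output_dir) -> dict:
    """Write every stage's tables plus a run manifest; returns the manifest."""
    out = io.ensure_dir(output_dir)
    tables = {
        "compartments.csv": result.compartments,
        "survey.csv": result.survey,
        "traits.csv": result.pool.traits.reset_index(),
        "detectability.csv": result.pool.detectability.reset_index(),
        "structural_metrics.csv": result.metrics.reset_index(),
        "groups.csv": result.groups.reset_index(),
        "group_abundance.csv": result.abundance.reset_index(),
        "diversity.csv": result.diversity_profile.rename_axis("group_id").reset_index(),
        "resolution_choices.csv": result.resolution_choices,
        "summary.csv": result.summary_frame().reset_index(),
    }
    hp_long = pd.concat(
        {m: t for m, t in result.hp_tables.items()}, names=["metric", "variable"]
    ).reset_index()
    tables["hp_results.csv"] = hp_long
    coef_rows, anova_rows, selected_rows, collin = [], [], [], []
    diagnostics_text = []
    for metric, res in result.model_results.items():
        coef = pd.DataFrame(
            {"estimate": res.params, "se": res.bse, "p": res.pvalues}
        ).rename_axis("coefficient").reset_index()
        coef.insert(0, "metric", metric)
        coef_rows.append(coef)
        an = res.anova.reset_index()
        an.insert(0, "metric", metric)
        anova_rows.append(an)
        selected_rows.append(
            {"metric": metric, "selected": "+".join(res.selected),
             "aliased": "+".join(res.aliased)}
        )
        if res.graph is not None:
            c = res.graph.matrix.rename_axis("variable").reset_index()
            c.insert(0, "metric", metric)
            collin.append(c)
        diagnostics_text.append(f"[{metric}] {res.diagnostics}")
    tables["model_coefficients.csv"] = pd.concat(coef_rows, ignore_index=True)
    tables["anova.csv"] = pd.concat(anova_rows, ignore_index=True)
    tables["selected_variables.csv"] = pd.DataFrame(selected_rows)
    if collin:
        tables["collinearity.csv"] = pd.concat(collin, ignore_index=True)

    checksums = {}
    for name, df in tables.items():
        path = out / name
        df.to_csv(path, index=False)
        checksums[name] = _sha256(path)
    (out / "diagnostics.txt").write_text("\n".join(diagnostics_text))
    truth_payload = {
        "dominant_driver": result.truth.dominant_driver,
        "structure": result.truth.structure.reset_index().to_dict("list"),
        "covariates": result.truth.covariates.reset_index().to_dict("list"),
    }
    (out / "truth.json").write_text(json.dumps(truth_payload))
    cfg = result.config.to_dict()
    manifest = {
        "seed": result.config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "audit": result.audit,
        "checksums": checksums,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    result.manifest = manifest
    return manifest
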