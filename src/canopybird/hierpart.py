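"""Hierarchical partitioning of regression goodness of fit.

Decomposes the R² of an OLS regression into per-variable independent
and joint contributions by averaging the R² increment a variable brings
to every subset of the remaining variables, level by level (Chevan &
Sutherland's scheme).  The independent effects sum to the full-model
R², and a variable's independent plus joint effect equals its
single-variable R².  Categorical variables enter as an atomic dummy
block.  The variable count is capped at nine, past which the 2^k model
space becomes statistically fragile.

Also implements scale optimization: choosing, per response and
multi-resolution predictor, the raster resolution at which the
predictor carries the highest percentage of independent effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Predictor",
    "HPResult",
    "fit_all_subsets_r2",
    "hierarchical_partition",
    "hier_part",
    "select_resolution",
    "MAX_VARIABLES",
]

MAX_VARIABLES = 9


@dataclass(frozen=True)
class Predictor:
    """A named predictor: one numeric column or a categorical dummy block."""

    name: str
    columns: np.ndarray  # (n, p) design columns, no intercept

    @staticmethod
    def numeric(name: str, values) -> "Predictor":
        return Predictor(name, np.asarray(values, dtype=float).reshape(-1, 1))

    @staticmethod
    def categorical(name: str, values) -> "Predictor":
        dummies = pd.get_dummies(pd.Series(values), drop_first=True)
        return Predictor(name, dummies.to_numpy(dtype=float))


@dataclass
class HPResult:
    """Independent and joint effects per variable (R² units)."""

    names: list[str]
    independent: np.ndarray
    joint: np.ndarray
    r2_full: float
    percent_independent: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        total = self.independent.sum()
        self.percent_independent = (
            100.0 * self.independent / total if total != 0 else
            np.full_like(self.independent, np.nan)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "independent": self.independent,
                "joint": self.joint,
                "percent_independent": self.percent_independent,
            },
            index=pd.Index(self.names, name="variable"),
        )


def fit_all_subsets_r2(response, predictors: list[Predictor]) -> np.ndarray:
    """R² of every predictor subset, indexed by bitmask.

    Entry ``s`` of the returned array is the OLS R² (with intercept) of
    the model whose predictors are those with bit ``j`` set in ``s``;
    the empty model is 0.  Limited to nine predictors.

    All models share one centered Gram matrix, so each subset costs a
    small p × p solve rather than an n-row regression.  Rank-deficient
    subsets use the minimum-norm solution (R² is unaffected by the
    choice of solution) with an aliasing warning.
    """
    k = len(predictors)
    if k > MAX_VARIABLES:
        raise ValueError(
            f"{k} variables exceed the {MAX_VARIABLES}-variable limit for "
            "hierarchical partitioning"
        )
    y = np.asarray(response, dtype=float).ravel()
    yc = y - y.mean()
    syy = float(yc @ yc)
    if syy == 0:
        raise ValueError("response has zero variance")
    blocks = []
    col_of: list[np.ndarray] = []
    start = 0
    for p in predictors:
        z = p.columns - p.columns.mean(axis=0)
        if z.shape[0] != y.shape[0]:
            raise ValueError(f"predictor {p.name!r} has wrong length")
        blocks.append(z)
        col_of.append(np.arange(start, start + z.shape[1]))
        start += z.shape[1]
    z = np.hstack(blocks)
    gram = z.T @ z
    gy = z.T @ yc

    table = np.zeros(1 << k)
    warned = False
    for s in range(1, 1 << k):
        idx = np.concatenate([col_of[j] for j in range(k) if s >> j & 1])
        g = gram[np.ix_(idx, idx)]
        b = gy[idx]
        try:
            coef = np.linalg.solve(g, b)
        except np.linalg.LinAlgError:
            coef = np.linalg.lstsq(g, b, rcond=None)[0]
            if not warned:
                warnings.warn("rank-deficient predictor subset; aliased fit")
                warned = True
        table[s] = min(max(float(coef @ b) / syy, 0.0), 1.0)
    return table


def hierarchical_partition(
    table: np.ndarray, names: list[str] | None = None
) -> HPResult:
    """Partition a complete subset-R² table into independent and joint effects.

    For variable j, the independent effect averages, over hierarchy
    levels h = 0..k-1, the mean R² increment of adding j to a subset of
    size h not containing j:

        I_j = (1/k) * sum_h  mean_{|S|=h, j not in S} [R²(S+j) - R²(S)]

    The joint effect is J_j = R²({j}) - I_j.  Negative independent
    effects (suppression) are reported as-is.
    """
    table = np.asarray(table, dtype=float)
    size = table.shape[0]
    k = size.bit_length() - 1
    if size != 1 << k or k < 1:
        raise ValueError("subset table must have 2^k entries, k >= 1")
    if table[0] != 0.0:
        raise ValueError("R² of the empty model must be 0")
    names = names or [f"x{j + 1}" for j in range(k)]
    popcount = np.array([bin(s).count("1") for s in range(size)])

    independent = np.zeros(k)
    for j in range(k):
        bit = 1 << j
        level_sum = np.zeros(k)
        level_n = np.zeros(k)
        for s in range(size):
            if s & bit:
                continue
            h = popcount[s]
            level_sum[h] += table[s | bit] - table[s]
            level_n[h] += 1
        independent[j] = float(np.mean(level_sum / level_n))
    joint = np.array([table[1 << j] for j in range(k)]) - independent
    return HPResult(
        names=list(names),
        independent=independent,
        joint=joint,
        r2_full=float(table[-1]),
    )


def hier_part(response, predictors: list[Predictor]) -> HPResult:
    """All-subset fits followed by hierarchical partitioning."""
    table = fit_all_subsets_r2(response, predictors)
    return hierarchical_partition(table, [p.name for p in predictors])


def select_resolution(
    response,
    base_predictors: list[Predictor],
    focal_name: str,
    focal_candidates: dict[float, Predictor],
    other_multires: dict[str, dict[float, Predictor]] | None = None,
    reference_resolution: float | None = None,
) -> tuple[float, pd.DataFrame]:
    """Choose the raster resolution maximizing a predictor's independent share.

    For each candidate resolution the full partition is run with the
    focal variable at that resolution and any other multi-resolution
    variables held at the reference resolution (the coarsest candidate
    by default).  The winner has the highest percentage of independent
    effects; ties break to the coarser resolution.
    """
    if not focal_candidates:
        raise ValueError("no candidate resolutions")
    other_multires = other_multires or {}
    others = []
    for name, cands in other_multires.items():
        ref = reference_resolution if reference_resolution is not None else max(cands)
        others.append(cands[ref])
    diagnostics = []
    for res in sorted(focal_candidates):
        predictors = [focal_candidates[res]] + others + list(base_predictors)
        hp = hier_part(response, predictors)
        diagnostics.append(
            {
                "resolution": res,
                "independent": hp.independent[0],
                "percent_independent": hp.percent_independent[0],
                "r2_full": hp.r2_full,
            }
        )
    diag = pd.DataFrame(diagnostics).set_index("resolution")
    # argmax; ties break to the coarser resolution by scanning coarse-to-fine
    chosen_res = None
    chosen_val = -np.inf
    for res in sorted(diag.index, reverse=True):
        val = float(diag.loc[res, "percent_independent"])
        if val > chosen_val + 1e-12:
            chosen_val = val
            chosen_res = res
    return float(chosen_res), diag
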