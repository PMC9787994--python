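"""Collinearity screening, variable selection, and the final linear models.

The final stage of the analysis: pairwise associations among candidate
predictors (|Pearson r|, correlation ratio, or Cramér's V, all mapped
to [0, 1] so one |0.7| threshold applies), exhaustive selection of the
mutually-independent subset with the greatest total independent effects
from the hierarchical partitioning, and an OLS fit with a type-2 ANOVA
(each term tested after all others, so term order is irrelevant).

:class:`HabitatModel` wraps the stage in a statsmodels-style interface:
build the model from the group table, call :meth:`HabitatModel.fit`,
and read estimates, ANOVA table, and diagnostics off the returned
:class:`HabitatResults` (or print ``results.summary()``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .hierpart import HPResult, Predictor, hier_part

__all__ = [
    "CollinearityGraph",
    "pairwise_association",
    "select_final_variables",
    "fit_ols",
    "anova_type2",
    "residual_diagnostics",
    "HabitatModel",
    "HabitatResults",
    "DEFAULT_BASELINES",
]

#: reference levels for the categorical factors
DEFAULT_BASELINES = {
    "management_simplified": "Conifer",
    "age_simplified": "Mixed",
}


@dataclass
class CollinearityGraph:
    """Pairwise absolute associations with a collinearity threshold."""

    matrix: pd.DataFrame
    threshold: float = 0.7

    def __post_init__(self) -> None:
        m = self.matrix
        if not np.allclose(m.to_numpy(), m.to_numpy().T, equal_nan=True):
            raise ValueError("association matrix must be symmetric")

    @property
    def edges(self) -> list[tuple[str, str]]:
        out = []
        names = list(self.matrix.index)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if self.matrix.loc[a, b] > self.threshold:
                    out.append((a, b))
        return out

    def conflicts(self, subset) -> list[tuple[str, str]]:
        s = set(subset)
        return [(a, b) for a, b in self.edges if a in s and b in s]


def _correlation_ratio(categories, values) -> float:
    """sqrt of the between-group share of variance (one-way ANOVA R²)."""
    df = pd.DataFrame({"g": categories, "v": values}).dropna()
    grand = df["v"].mean()
    sst = float(((df["v"] - grand) ** 2).sum())
    if sst == 0:
        raise ValueError("zero-variance variable in association test")
    ssb = float(
        (df.groupby("g")["v"].count() * (df.groupby("g")["v"].mean() - grand) ** 2).sum()
    )
    return float(np.sqrt(ssb / sst))


def _cramers_v(a, b) -> float:
    tab = pd.crosstab(pd.Series(a), pd.Series(b))
    chi2 = stats.chi2_contingency(tab, correction=False)[0]
    n = tab.to_numpy().sum()
    k = min(tab.shape) - 1
    if k == 0:
        raise ValueError("categorical variable with a single level")
    return float(np.sqrt(chi2 / (n * k)))


def pairwise_association(
    data: pd.DataFrame, variables: list[str] | None = None, threshold: float = 0.7
) -> CollinearityGraph:
    """Absolute pairwise association among candidate predictors.

    Continuous-continuous pairs use |Pearson r|; continuous-categorical
    the correlation ratio; categorical-categorical Cramér's V.  All lie
    in [0, 1]; pairs above the threshold form collinearity edges.
    """
    variables = variables or list(data.columns)
    if len(variables) < 2:
        raise ValueError("need at least two variables")
    numeric = {
        v: pd.api.types.is_numeric_dtype(data[v]) for v in variables
    }
    for v, is_num in numeric.items():
        if is_num and float(data[v].std()) == 0.0:
            raise ValueError(f"zero-variance variable: {v!r}")
        if not is_num and data[v].nunique() < 2:
            raise ValueError(f"single-level categorical variable: {v!r}")
    mat = pd.DataFrame(1.0, index=variables, columns=variables)
    for a, b in itertools.combinations(variables, 2):
        if numeric[a] and numeric[b]:
            val = abs(float(np.corrcoef(data[a], data[b])[0, 1]))
        elif numeric[a] != numeric[b]:
            cat, num = (a, b) if not numeric[a] else (b, a)
            val = _correlation_ratio(data[cat], data[num])
        else:
            val = _cramers_v(data[a], data[b])
        mat.loc[a, b] = mat.loc[b, a] = val
    return CollinearityGraph(matrix=mat, threshold=threshold)


def select_final_variables(
    hp: HPResult | pd.Series,
    graph: CollinearityGraph,
    forced: tuple[str, ...] = ("log_total_area",),
) -> list[str]:
    """Feasible variable subset maximizing total independent effects.

    Exhaustive search over subsets that contain every forced variable
    and no collinearity edge; the score is the summed independent
    effects.  Ties prefer the smaller subset, then lexicographic order.
    """
    effects = (
        pd.Series(hp.independent, index=hp.names)
        if isinstance(hp, HPResult)
        else pd.Series(hp)
    )
    names = list(effects.index)
    missing = set(forced) - set(names)
    if missing:
        raise ValueError(f"forced variables not among candidates: {sorted(missing)}")
    if graph.conflicts(forced):
        raise ValueError(
            f"forced variables are mutually collinear: {graph.conflicts(forced)}"
        )
    free = [v for v in names if v not in forced]
    best: tuple | None = None
    for r in range(len(free) + 1):
        for combo in itertools.combinations(free, r):
            subset = list(forced) + list(combo)
            if graph.conflicts(subset):
                continue
            score = float(effects[subset].sum())
            key = (-score, len(subset), tuple(sorted(subset)))
            if best is None or key < best[0]:
                best = (key, subset)
    assert best is not None  # forced alone is always feasible
    return [v for v in names if v in set(best[1])]


# ---------------------------------------------------------------------------
# OLS with aliasing-aware dummy coding and type-2 ANOVA
# ---------------------------------------------------------------------------

@dataclass
class _Design:
    columns: list[str]           # retained column names
    matrix: np.ndarray           # (n, p) incl. intercept
    term_of_column: list[str]    # variable each column belongs to
    aliased: list[str]           # dropped column names


def _build_design(
    data: pd.DataFrame,
    variables: list[str],
    baselines: dict[str, str],
) -> _Design:
    n = len(data)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["Intercept"]
    terms = ["Intercept"]
    for v in variables:
        s = data[v]
        if pd.api.types.is_numeric_dtype(s):
            cols.append(s.to_numpy(dtype=float))
            names.append(v)
            terms.append(v)
        else:
            levels = [str(x) for x in pd.unique(s.astype(str))]
            base = baselines.get(v)
            if base is None or base not in levels:
                base = sorted(levels)[0]
            for level in sorted(lv for lv in levels if lv != base):
                cols.append((s.astype(str) == level).to_numpy(dtype=float))
                names.append(f"{v}[{level}]")
                terms.append(v)
    full = np.column_stack(cols)
    # greedy rank filter: drop columns linearly dependent on earlier ones
    keep: list[int] = []
    aliased: list[str] = []
    rank = 0
    for j in range(full.shape[1]):
        trial = full[:, keep + [j]]
        r = np.linalg.matrix_rank(trial)
        if r > rank:
            keep.append(j)
            rank = r
        else:
            aliased.append(names[j])
    return _Design(
        columns=[names[j] for j in keep],
        matrix=full[:, keep],
        term_of_column=[terms[j] for j in keep],
        aliased=aliased,
    )


@dataclass
class ModelFit:
    """A fitted linear model with its design bookkeeping."""

    response: str
    variables: list[str]
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    rsquared: float
    rsquared_adj: float
    f_pvalue: float
    sse: float
    sst: float
    df_resid: int
    design: _Design = field(repr=False)
    data: pd.DataFrame = field(repr=False)
    baselines: dict[str, str] = field(repr=False, default_factory=dict)
    y: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def aliased(self) -> list[str]:
        return self.design.aliased

    @property
    def resid(self) -> np.ndarray:
        return self.y - self.fittedvalues

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.design.matrix @ self.params.to_numpy()


def fit_ols(
    data: pd.DataFrame,
    response: str,
    variables: list[str],
    baselines: dict[str, str] | None = None,
) -> ModelFit:
    """Least-squares fit of a diversity metric on selected variables.

    Categorical variables are dummy-coded against the stated baselines.
    Columns made redundant by aliasing between factors (e.g. the
    open/other category appearing in both the age-class and management
    factors) are dropped and reported, not silently absorbed.
    """
    baselines = dict(DEFAULT_BASELINES if baselines is None else baselines)
    design = _build_design(data, variables, baselines)
    y = data[response].to_numpy(dtype=float)
    x = design.matrix
    n, p = x.shape
    if n <= p:
        raise ValueError(
            f"{n} rows cannot identify {p} parameters for response {response!r}"
        )
    xtx = x.T @ x
    if np.linalg.cond(xtx) > 1e12:
        raise ValueError("perfect collinearity remains after aliasing removal")
    beta = np.linalg.solve(xtx, x.T @ y)
    resid = y - x @ beta
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    df_resid = n - p
    mse = sse / df_resid
    cov = mse * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf)
    pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)
    r2 = 1.0 - sse / sst
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / df_resid
    if p > 1 and mse > 0:
        f = ((sst - sse) / (p - 1)) / mse
        f_p = float(stats.f.sf(f, p - 1, df_resid))
    elif p > 1:
        f_p = 0.0  # perfect fit
    else:
        f_p = float("nan")
    idx = pd.Index(design.columns)
    return ModelFit(
        response=response,
        variables=list(variables),
        params=pd.Series(beta, index=idx),
        bse=pd.Series(se, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        rsquared=r2,
        rsquared_adj=r2_adj,
        f_pvalue=f_p,
        sse=sse,
        sst=sst,
        df_resid=df_resid,
        design=design,
        data=data,
        baselines=baselines,
        y=y,
    )


def anova_type2(fit: ModelFit) -> pd.DataFrame:
    """Type-2 ANOVA: each term tested after all other terms.

    Per term, SS = SSE(model without the term's columns) - SSE(full);
    F is tested against the full model's residual mean square.  With
    main effects only, the table is invariant to term order.
    """
    x = fit.design.matrix
    y = fit.y
    terms = [t for t in dict.fromkeys(fit.design.term_of_column) if t != "Intercept"]
    mse = fit.sse / fit.df_resid
    rows = []
    for term in terms:
        keep = [j for j, t in enumerate(fit.design.term_of_column) if t != term]
        xr = x[:, keep]
        beta_r, *_ = np.linalg.lstsq(xr, y, rcond=None)
        sse_r = float(np.sum((y - xr @ beta_r) ** 2))
        df = x.shape[1] - np.linalg.matrix_rank(xr)
        ss = max(sse_r - fit.sse, 0.0)
        if df == 0:
            # term fully aliased with the rest of the model
            rows.append({"term": term, "sum_sq": 0.0, "df": 0,
                         "F": np.nan, "p": np.nan})
            continue
        f = (ss / df) / mse
        rows.append(
            {
                "term": term,
                "sum_sq": ss,
                "df": int(df),
                "F": f,
                "p": float(stats.f.sf(f, df, fit.df_resid)),
            }
        )
    rows.append(
        {
            "term": "Residuals",
            "sum_sq": fit.sse,
            "df": fit.df_resid,
            "F": np.nan,
            "p": np.nan,
        }
    )
    return pd.DataFrame(rows).set_index("term")


def residual_diagnostics(fit: ModelFit) -> dict:
    """Advisory residual checks: normality, heteroscedasticity, leverage."""
    resid = fit.resid
    n = resid.size
    if n < 5:
        return {"status": "insufficient data", "n": int(n)}
    from statsmodels.stats.diagnostic import het_breuschpagan

    shapiro_p = float(stats.shapiro(resid).pvalue)
    _, bp_p, _, _ = het_breuschpagan(resid, fit.design.matrix)
    x = fit.design.matrix
    hat = np.einsum(
        "ij,jk,ik->i", x, np.linalg.inv(x.T @ x), x
    )
    p = x.shape[1]
    flagged = np.nonzero(hat > 2 * p / n)[0]
    return {
        "status": "ok",
        "n": int(n),
        "shapiro_p": shapiro_p,
        "breusch_pagan_p": float(bp_p),
        "normality_ok": shapiro_p >= 0.05,
        "homoscedastic_ok": float(bp_p) >= 0.05,
        "high_leverage_rows": flagged.tolist(),
    }


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class HabitatModel:
    """Linear model of one diversity metric on habitat variables.

    Built from the group table (one row per compartment group).  ``fit``
    optionally runs the full selection protocol — hierarchical
    partitioning of the candidate variables, collinearity screening,
    and exhaustive subset selection with the area term forced in —
    before the OLS fit and type-2 ANOVA.

    Parameters
    ----------
    data : DataFrame
        Group table containing the response and all candidate variables.
    response : str
        Column holding the (possibly Box-Cox transformed) metric.
    variables : list of str
        Candidate predictor columns (categoricals by dtype).
    baselines : dict, optional
        Reference level per categorical variable.
    threshold : float
        Collinearity threshold on absolute association (default 0.7).
    forced : tuple of str
        Variables always kept in the final model (default log area).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response: str,
        variables: list[str],
        baselines: dict[str, str] | None = None,
        threshold: float = 0.7,
        forced: tuple[str, ...] = ("log_total_area",),
    ) -> None:
        missing = {response, *variables} - set(data.columns)
        if missing:
            raise ValueError(f"columns not in data: {sorted(missing)}")
        self.data = data
        self.response = response
        self.variables = list(variables)
        self.baselines = dict(DEFAULT_BASELINES if baselines is None else baselines)
        self.threshold = threshold
        self.forced = forced

    @classmethod
    def from_group_table(cls, groups: pd.DataFrame, response: str, **kwargs):
        """Build from an assembled group table, inferring candidates."""
        exclude = {response, "n_members", "total_area_ha", "management",
                   "age_class"}
        variables = [c for c in groups.columns if c not in exclude
                     and not c.endswith("_norm") and c != response]
        return cls(groups, response, variables, **kwargs)

    def _predictors(self, names) -> list[Predictor]:
        out = []
        for v in names:
            s = self.data[v]
            if pd.api.types.is_numeric_dtype(s):
                out.append(Predictor.numeric(v, s))
            else:
                out.append(Predictor.categorical(v, s.astype(str)))
        return out

    def fit(self, select: bool = True) -> "HabitatResults":
        y = self.data[self.response].to_numpy(dtype=float)
        hp = hier_part(y, self._predictors(self.variables))
        if select:
            graph = pairwise_association(
                self.data, self.variables, threshold=self.threshold
            )
            selected = select_final_variables(hp, graph, forced=self.forced)
        else:
            graph = None
            selected = list(self.variables)
        fitted = fit_ols(self.data, self.response, selected, self.baselines)
        return HabitatResults(
            model=self,
            hp=hp,
            graph=graph,
            selected=selected,
            fit=fitted,
            anova=anova_type2(fitted),
            diagnostics=residual_diagnostics(fitted),
        )


@dataclass
class HabitatResults:
    """Results of :meth:`HabitatModel.fit`.

    Exposes estimates (``params``, ``bse``, ``pvalues``), fit quality
    (``rsquared``, ``rsquared_adj``), the type-2 ANOVA table, the
    hierarchical-partitioning table, the collinearity graph, and
    residual diagnostics.
    """

    model: HabitatModel
    hp: HPResult
    graph: CollinearityGraph | None
    selected: list[str]
    fit: ModelFit
    anova: pd.DataFrame
    diagnostics: dict

    params = property(lambda self: self.fit.params)
    bse = property(lambda self: self.fit.bse)
    pvalues = property(lambda self: self.fit.pvalues)
    rsquared = property(lambda self: self.fit.rsquared)
    rsquared_adj = property(lambda self: self.fit.rsquared_adj)
    aliased = property(lambda self: self.fit.aliased)

    def predict(self, data: pd.DataFrame | None = None) -> np.ndarray:
        if data is None:
            return self.fit.fittedvalues
        design = _build_design(data, self.selected, self.model.baselines)
        cols = [design.columns.index(c) for c in self.fit.design.columns]
        return design.matrix[:, cols] @ self.fit.params.to_numpy()

    def summary(self) -> str:
        f = self.fit
        lines = [
            f"Habitat linear model: {f.response}",
            f"  n groups: {len(self.model.data)}   "
            f"R² = {f.rsquared:.3f}   adj. R² = {f.rsquared_adj:.3f}   "
            f"model p = {f.f_pvalue:.3g}",
            f"  selected variables: {', '.join(self.selected)}",
        ]
        if f.aliased:
            lines.append(f"  aliased columns dropped: {', '.join(f.aliased)}")
        coef = pd.DataFrame(
            {"estimate": f.params, "se": f.bse, "p": f.pvalues}
        )
        lines.append(coef.to_string(float_format=lambda v: f"{v: .4g}"))
        lines.append("Type-2 ANOVA:")
        lines.append(self.anova.to_string(float_format=lambda v: f"{v: .4g}"))
        lines.append(
            "Hierarchical partitioning (% independent effects):"
        )
        lines.append(
            self.hp.to_frame().to_string(float_format=lambda v: f"{v: .4g}")
        )
        return "\n".join(lines)

    def plot_effects(self, ax=None):
        """Bar plot of independent and joint effects per variable."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        frame = self.hp.to_frame().sort_values("independent", ascending=False)
        idx = np.arange(len(frame))
        ax.bar(idx, frame["independent"], label="independent")
        ax.bar(idx, frame["joint"], bottom=frame["independent"], label="joint")
        ax.set_xticks(idx)
        ax.set_xticklabels(frame.index, rotation=45, ha="right")
        ax.set_ylabel("R² attributed")
        ax.set_title(f"{self.fit.response}: effects per variable")
        ax.legend()
        return ax
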