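"""Compartment grouping and detectability-corrected community assembly.

Individual compartments are too small to hold meaningful bird
communities, so compartments are pooled into groups sharing the same
management type and age class.  Counts are collapsed to the maximum of
the two survey visits, group mean maximum counts are divided by
species-specific detectability constants, and structural covariates are
averaged (unweighted) over member compartments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .categories import simplify_categories

__all__ = [
    "collapse_visits_max",
    "assign_groups",
    "detectability_correct",
    "summarize_group_covariates",
    "build_group_table",
]


def collapse_visits_max(survey: pd.DataFrame) -> pd.DataFrame:
    """Maximum count over the two visits per (compartment, species).

    Standard practice for two-visit breeding-bird surveys: the maximum
    accounts for species whose activity peaks early or late in the
    season.  Species recorded on one visit only keep that visit's count.
    Returns a compartment × species matrix (absent species are 0).
    """
    required = {"compartment_id", "species_id", "visit", "count"}
    missing = required - set(survey.columns)
    if missing:
        raise ValueError(f"survey table missing columns: {sorted(missing)}")
    if not survey["visit"].isin([1, 2]).all():
        raise ValueError("visit must be 1 or 2")
    if (survey["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    dup = survey.duplicated(["compartment_id", "species_id", "visit"])
    if dup.any():
        rows = survey.loc[dup, ["compartment_id", "species_id", "visit"]]
        raise ValueError(
            f"duplicate (compartment, species, visit) records:\n{rows.head()}"
        )
    mat = survey.pivot_table(
        index="compartment_id",
        columns="species_id",
        values="count",
        aggfunc="max",
        fill_value=0,
    )
    mat.columns.name = "species_id"
    return mat


def assign_groups(
    compartments: pd.DataFrame,
    min_members: int = 10,
    min_area_ha: float = 0.05,
    by: str = "detailed",
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Form analysis groups of compartments.

    Compartments below ``min_area_ha`` are dropped first; the rest are
    grouped by their (management, age class) combination — detailed
    categories by default, so a group's members share the same crop
    species and age band while the simplified labels become the model
    covariates.  Groups with fewer than ``min_members`` compartments are
    excluded.

    Returns ``(groups, membership, audit)``: one row per group
    (simplified labels, member count, total and log-total area), a
    compartment_id -> group_id series, and a conservation audit of
    retained/dropped compartments.
    """
    if by not in ("detailed", "simplified"):
        raise ValueError("by must be 'detailed' or 'simplified'")
    comp = compartments.copy()
    n_input = len(comp)
    small = comp["area_ha"] < min_area_ha
    comp = comp.loc[~small]

    simplified = [
        simplify_categories(m, a if pd.notna(a) else None)
        for m, a in zip(comp["management"], comp["age_class"])
    ]
    comp = comp.assign(
        management_simplified=[s[0] for s in simplified],
        age_simplified=[s[1] for s in simplified],
    )
    if by == "detailed":
        keys = ["management", "age_class"]
    else:
        keys = ["management_simplified", "age_simplified"]

    rows = []
    membership = {}
    n_dropped_small_groups = 0
    for i, (key, members) in enumerate(sorted(comp.groupby(keys, dropna=False))):
        if len(members) < min_members:
            n_dropped_small_groups += len(members)
            continue
        gid = f"G{len(rows):03d}"
        total_area = float(members["area_ha"].sum())
        rows.append(
            {
                "group_id": gid,
                "management": key[0] if by == "detailed" else None,
                "age_class": key[1] if by == "detailed" else None,
                "management_simplified": members["management_simplified"].iloc[0],
                "age_simplified": members["age_simplified"].iloc[0],
                "n_members": len(members),
                "total_area_ha": total_area,
                "log_total_area": float(np.log(total_area)),
            }
        )
        for cid in members["compartment_id"]:
            membership[cid] = gid
    if not rows:
        raise ValueError("no group satisfies the membership threshold")
    groups = pd.DataFrame(rows).set_index("group_id")
    audit = {
        "n_input": n_input,
        "n_dropped_small_area": int(small.sum()),
        "n_dropped_small_groups": n_dropped_small_groups,
        "n_retained": int(sum(groups["n_members"])),
    }
    assert (
        audit["n_retained"]
        + audit["n_dropped_small_area"]
        + audit["n_dropped_small_groups"]
        == n_input
    )
    return groups, pd.Series(membership, name="group_id"), audit


def detectability_correct(
    mean_max_counts: pd.DataFrame, detectability: pd.Series
) -> pd.DataFrame:
    """Divide group mean maximum counts by detectability constants.

    Every observed species must have a constant in (0, 1]; there is no
    silent default.
    """
    observed = mean_max_counts.columns[(mean_max_counts > 0).any(axis=0)]
    missing = set(observed) - set(detectability.index)
    if missing:
        raise ValueError(
            f"no detectability constant for species: {sorted(missing)}"
        )
    d = detectability.reindex(mean_max_counts.columns)
    bad = d.notna() & ((d <= 0) | (d > 1))
    if bad.any():
        raise ValueError(
            f"detectability constants outside (0, 1]: {sorted(d.index[bad])}"
        )
    return mean_max_counts.div(d.fillna(1.0), axis=1)


def summarize_group_covariates(
    membership: pd.Series, metrics: pd.DataFrame
) -> pd.DataFrame:
    """Unweighted mean of each structural metric over group members.

    ``metrics`` is indexed by compartment_id.  A member compartment with
    a missing metric raises, naming the compartment.
    """
    member_ids = membership.index
    absent = set(member_ids) - set(metrics.index)
    if absent:
        raise ValueError(f"no structural metrics for compartments: {sorted(absent)[:5]}")
    sub = metrics.loc[member_ids]
    nan_rows = sub.index[sub.isna().any(axis=1)]
    if len(nan_rows):
        raise ValueError(
            f"missing metric values for compartments: {sorted(set(nan_rows))[:5]}"
        )
    return sub.groupby(membership).mean()


def build_group_table(
    compartments: pd.DataFrame,
    survey: pd.DataFrame,
    detectability: pd.Series,
    metrics: pd.DataFrame,
    min_members: int = 10,
    min_area_ha: float = 0.05,
    by: str = "detailed",
):
    """Run the whole assembly stage.

    Returns ``(groups, abundance, audit)``: the group table with
    covariates appended, the detectability-corrected group × species
    abundance matrix, and the conservation audit.
    """
    groups, membership, audit = assign_groups(
        compartments, min_members=min_members, min_area_ha=min_area_ha, by=by
    )
    max_counts = collapse_visits_max(survey)
    # compartments with no records at all still count as all-zero rows
    max_counts = max_counts.reindex(membership.index, fill_value=0)
    mean_max = max_counts.groupby(membership).mean()
    abundance = detectability_correct(mean_max, detectability)
    covariates = summarize_group_covariates(membership, metrics)
    groups = groups.join(covariates)
    return groups, abundance.loc[groups.index], audit
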