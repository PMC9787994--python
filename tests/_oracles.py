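"""Independent oracle implementations used only by the test suite.

These deliberately take different algorithmic routes from the package:
hierarchical partitioning via the permutation (Shapley) average of
sequential R² increments, subset R² via full-design least squares, and
variable selection via a plain filtered enumeration.  They must never
import from the module they check beyond plain data containers.
"""

from __future__ import annotations

import itertools

import numpy as np


def r2_direct(y: np.ndarray, x: np.ndarray | None) -> float:
    """OLS R² with intercept, computed on the raw design matrix."""
    y = np.asarray(y, dtype=float)
    n = y.size
    sst = float(np.sum((y - y.mean()) ** 2))
    if x is None or x.shape[1] == 0:
        return 0.0
    design = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    sse = float(np.sum((y - design @ beta) ** 2))
    return 1.0 - sse / sst


def subset_r2_table(y: np.ndarray, blocks: list[np.ndarray]) -> np.ndarray:
    """R² for every subset of predictor blocks, indexed by bitmask."""
    k = len(blocks)
    table = np.zeros(1 << k)
    for s in range(1, 1 << k):
        cols = [blocks[j] for j in range(k) if s >> j & 1]
        table[s] = r2_direct(y, np.hstack(cols))
    return table


def hp_by_permutations(table: np.ndarray) -> np.ndarray:
    """Independent effects as the Shapley value over variable orderings.

    For every ordering of the k variables, record the R² increment when
    each variable enters; the independent effect is the average over
    all k! orderings.  Equivalent to the level-averaged subset formula,
    reached by a different computation.
    """
    k = (table.shape[0]).bit_length() - 1
    totals = np.zeros(k)
    count = 0
    for order in itertools.permutations(range(k)):
        mask = 0
        for j in order:
            totals[j] += table[mask | (1 << j)] - table[mask]
            mask |= 1 << j
        count += 1
    return totals / count


def brute_force_selection(
    effects: dict[str, float],
    edges: set[frozenset],
    forced: tuple[str, ...],
) -> list[str]:
    """Best feasible subset by filtered enumeration (independent coding)."""
    names = list(effects)
    best_key, best = None, None
    for r in range(len(names) + 1):
        for combo in itertools.combinations(names, r):
            if not set(forced) <= set(combo):
                continue
            if any(frozenset(p) <= set(combo) for p in edges):
                continue
            score = sum(effects[v] for v in combo)
            key = (-score, len(combo), tuple(sorted(combo)))
            if best_key is None or key < best_key:
                best_key, best = key, combo
    return [v for v in names if v in set(best)]
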