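"""Non-parametric group comparisons across tasks within a category.

Plantar-pressure summary metrics (e.g. per-participant mean contact
area) are heavily non-normal, so tasks are compared with a
Kruskal--Wallis test followed by Bonferroni-corrected pairwise
Mann--Whitney U tests.  The observation unit is one scalar per
participant per task (a per-participant mean), not raw frames, to avoid
pseudo-replication.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GroupComparison", "kruskal_wallis", "pairwise_mwu_bonferroni",
           "compare_groups"]


@dataclass
class GroupComparison:
    groups: dict[str, np.ndarray]
    h_statistic: float
    p_value: float
    pairwise: pd.DataFrame


def _as_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    out = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {name!r} is empty")
        out[str(name)] = arr
    return out


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Kruskal--Wallis H (tie-corrected) with chi-square p, df = k - 1."""
    g = _as_groups(groups)
    if len(g) < 2:
        raise ValueError("need at least 2 groups")
    for name, arr in g.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    h, p = stats.kruskal(*g.values())
    return float(h), float(p)


def pairwise_mwu_bonferroni(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided Mann--Whitney U for every unordered pair of groups.

    The Bonferroni factor is the number of pairs; corrected p values are
    capped at 1.  Columns: task_i, task_j, U, p_raw, p_bonferroni,
    significant.
    """
    g = _as_groups(groups)
    if len(g) < 2:
        raise ValueError("need at least 2 groups")
    pairs = list(combinations(g.keys(), 2))
    n_comparisons = len(pairs)
    rows = []
    for a, b in pairs:
        res = stats.mannwhitneyu(g[a], g[b], alternative="two-sided",
                                 method="auto")
        p_bonf = min(1.0, float(res.pvalue) * n_comparisons)
        rows.append({
            "task_i": a, "task_j": b,
            "U": float(res.statistic),
            "p_raw": float(res.pvalue),
            "p_bonferroni": p_bonf,
            "significant": p_bonf < alpha,
        })
    return pd.DataFrame(rows)


def compare_groups(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> GroupComparison:
    """Omnibus Kruskal--Wallis plus Bonferroni-corrected post hoc table."""
    g = _as_groups(groups)
    h, p = kruskal_wallis(g)
    pairwise = pairwise_mwu_bonferroni(g, alpha=alpha)
    return GroupComparison(groups=g, h_statistic=h, p_value=p, pairwise=pairwise)
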