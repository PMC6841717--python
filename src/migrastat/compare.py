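"""Per-cell metric rows, two-group contrasts, and summary tables.

One tracked cell yields one :class:`CellMetrics` row — the rmsf exponent α,
correlation duration M, DFA exponent γ, MSD exponents β (direct and RGO),
global directionality ratio, average speed and total distance — mirroring
the study-style summary-table layout. Groups (e.g. non-enucleated vs
enucleated) are contrasted metric-by-metric with the two-sided Wilcoxon
rank-sum test: exact enumeration for small samples (pooled size ≤ 12, ties
handled by mid-ranks), otherwise the normal approximation with tie-corrected
variance and continuity correction. No multiple-testing adjustment is
applied; per-metric p-values are reported raw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ConfigurationError, DegenerateInputError, InsufficientDataError

__all__ = ["CellMetrics", "GroupComparison", "analyze_cell", "wilcoxon_ranksum", "group_summary"]

#: Metric fields of a CellMetrics row, in summary-table order.
METRIC_FIELDS = ("alpha", "m_steps", "gamma", "beta_dc", "beta_rgo", "dr", "as_mm_per_s", "td_mm")


@dataclass
class CellMetrics:
    """One summary-table row for a single cell.

    Fields left ``None`` mark metrics whose estimation failed (degenerate or
    insufficient data) — the failure reasons live on the originating results
    object, not here.
    """

    cell_id: str
    group: str | None = None
    alpha: float | None = None
    m_steps: float | None = None
    gamma: float | None = None
    beta_dc: float | None = None
    beta_rgo: float | None = None
    dr: float | None = None
    as_mm_per_s: float | None = None
    td_mm: float | None = None

    def to_dict(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "group": self.group,
            **{name: getattr(self, name) for name in METRIC_FIELDS},
        }


@dataclass
class GroupComparison:
    """Rank-sum contrast of one metric between two groups."""

    metric: str
    group_a: str
    group_b: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    statistic: float
    p_value: float
    method: str = ""


def analyze_cell(traj, config: dict | None = None) -> CellMetrics:
    """Run the full estimator pipeline on one trajectory.

    Thin wrapper over :class:`migrastat.model.CellMigrationModel`; stages
    whose input is degenerate leave their field ``None`` and the remaining
    metrics are still computed.
    """
    from .model import CellMigrationModel  # deferred to avoid an import cycle

    return CellMigrationModel(traj, **(config or {})).fit().to_metrics()


def _exact_ranksum_p(ranks: np.ndarray, n_a: int, observed: float) -> float:
    """Two-sided exact p by enumerating all C(N, n_a) rank assignments."""
    total = 0
    le = ge = 0
    tol = 1e-9
    for combo in combinations(range(len(ranks)), n_a):
        w = ranks[list(combo)].sum()
        total += 1
        if w <= observed + tol:
            le += 1
        if w >= observed - tol:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)


def wilcoxon_ranksum(
    a: Sequence[float],
    b: Sequence[float],
    *,
    metric: str = "",
    group_a: str = "a",
    group_b: str = "b",
    exact_threshold: int = 12,
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum test on pooled mid-ranks.

    The statistic is the rank sum of the first sample. For pooled sizes up
    to ``exact_threshold`` the p-value enumerates every rank assignment
    (mid-ranks make this valid under ties); larger samples use the normal
    approximation with tie-corrected variance and a 0.5 continuity
    correction. Two identical samples give p = 1.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise InsufficientDataError("both samples must be non-empty")
    n_a, n_b = len(a), len(b)
    total = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:n_a].sum())

    if np.ptp(pooled) == 0.0:
        p, method = 1.0, "degenerate (all values identical)"
    elif total <= exact_threshold:
        p, method = _exact_ranksum_p(ranks, n_a, w), "exact enumeration"
    else:
        expected = n_a * (total + 1) / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (total * (total - 1))
        var = n_a * n_b / 12.0 * ((total + 1) - tie_term)
        if var <= 0:
            p, method = 1.0, "degenerate (zero variance)"
        else:
            z = max(abs(w - expected) - 0.5, 0.0) / math.sqrt(var)
            p, method = math.erfc(z / math.sqrt(2.0)), "normal approximation"
    return GroupComparison(
        metric=metric,
        group_a=group_a,
        group_b=group_b,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)) if n_a > 1 else float("nan"),
        n_a=n_a,
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)) if n_b > 1 else float("nan"),
        n_b=n_b,
        statistic=w,
        p_value=float(p),
        method=method,
    )


def group_summary(
    rows: Sequence[CellMetrics],
    metrics: Sequence[str] = METRIC_FIELDS,
) -> tuple[pd.DataFrame, list[GroupComparison]]:
    """Per-metric group means ± SD (sample SD, n−1 divisor) and rank-sum p.

    ``rows`` must span exactly two groups. Cells with a missing value for a
    metric are excluded from that metric's contrast only. Returns the
    summary table and the list of comparison objects.
    """
    groups = sorted({r.group for r in rows if r.group is not None})
    if len(groups) != 2:
        raise ConfigurationError(
            f"rows must span exactly two groups, found {groups or 'none'}"
        )
    ga, gb = groups
    comparisons: list[GroupComparison] = []
    records = []
    for name in metrics:
        va = [getattr(r, name) for r in rows if r.group == ga and getattr(r, name) is not None]
        vb = [getattr(r, name) for r in rows if r.group == gb and getattr(r, name) is not None]
        if not va or not vb:
            raise ConfigurationError(f"metric {name!r} has an empty group")
        cmp_ = wilcoxon_ranksum(va, vb, metric=name, group_a=ga, group_b=gb)
        comparisons.append(cmp_)
        records.append(
            {
                "metric": name,
                f"mean_{ga}": cmp_.mean_a,
                f"sd_{ga}": cmp_.sd_a,
                f"n_{ga}": cmp_.n_a,
                f"mean_{gb}": cmp_.mean_b,
                f"sd_{gb}": cmp_.sd_b,
                f"n_{gb}": cmp_.n_b,
                "ranksum_W": cmp_.statistic,
                "p_value": cmp_.p_value,
            }
        )
    return pd.DataFrame.from_records(records), comparisons
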