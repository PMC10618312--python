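"""Statistical comparison layer.

Open-probability summaries across recordings, the Mann-Whitney U test
(exact enumeration for small samples, normal approximation with tie
correction otherwise), occupancy classification of clusters, and an
optional Holm step-down correction for families of comparisons.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .idealization import DwellTimeSeries, open_probability

__all__ = [
    "ConditionSummary",
    "MannWhitneyResult",
    "sem",
    "mann_whitney_u",
    "occupancy_class",
    "condition_summary",
    "holm_adjust",
]

_EXACT_LIMIT = 8
ALPHA = 0.05


@dataclass
class ConditionSummary:
    """Open-state probability of one condition over repeat recordings."""

    condition: str
    concentration_uM: float | None
    p_op_mean: float
    p_op_sem: float | None  # None when only one recording is available
    n_recordings: int


@dataclass
class MannWhitneyResult:
    U: float  # number of (a, b) pairs with a < b, + 1/2 per tie
    p_value: float  # two-sided
    method: str  # "exact" | "asymptotic"
    significant: bool  # at alpha = 0.05


def sem(values) -> float:
    """Standard error of the mean: SD(ddof=1) / sqrt(n); needs n >= 2."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("SEM requires at least two values")
    return float(v.std(ddof=1) / math.sqrt(v.size))


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    less = (a[:, None] < b[None, :]).sum()
    ties = (a[:, None] == b[None, :]).sum()
    return float(less) + 0.5 * float(ties)


def _exact_p(a: np.ndarray, b: np.ndarray, u: float) -> float:
    """Two-sided exact p by enumerating all label assignments of the pool."""
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    nab = a.size * b.size
    # U under relabelings: count of (a', b') pairs with a' < b'
    count_le = 0
    count_ge = 0
    total = 0
    idx = np.arange(n)
    for combo in itertools.combinations(idx, na):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        u_perm = _u_statistic(pooled[mask], pooled[~mask])
        count_le += u_perm <= u
        count_ge += u_perm >= u
        total += 1
    p = 2.0 * min(count_le, count_ge) / total
    return min(p, 1.0)


def _asymptotic_p(a: np.ndarray, b: np.ndarray, u: float) -> float:
    """Normal approximation with tie correction and continuity correction."""
    na, nb = a.size, b.size
    n = na + nb
    mean = na * nb / 2.0
    pooled = np.concatenate([a, b])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / (n * (n - 1)) if n > 1 else 0.0
    var = na * nb / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (abs(u - mean) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return float(2.0 * (1.0 - 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))))


def mann_whitney_u(
    sample_a, sample_b, method: str = "auto", alpha: float = ALPHA
) -> MannWhitneyResult:
    """Mann-Whitney U test, two-sided.

    U counts the (a, b) pairs with a < b (half a count per tie).  The
    p-value is exact (full enumeration of label assignments) when the
    smaller sample has at most 8 observations and there are no ties,
    otherwise a normal approximation with tie and continuity corrections
    is used.  ``method`` forces "exact" or "asymptotic".
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    u = _u_statistic(a, b)
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if method == "auto":
        method = (
            "exact" if min(a.size, b.size) <= _EXACT_LIMIT and not has_ties
            else "asymptotic"
        )
    if method == "exact":
        p = _exact_p(a, b, u)
    elif method == "asymptotic":
        p = _asymptotic_p(a, b, u)
    else:
        raise ValueError("method must be 'auto', 'exact' or 'asymptotic'")
    return MannWhitneyResult(U=u, p_value=p, method=method, significant=p < alpha)


# Occupancy classes as annotated on the phase-space comparison figures.
# The two triplet kinds use different upper bands and are kept separate.
_OCO_CLASSES = [(0.10, "VERY LOW"), (0.35, "LOW"), (np.inf, "MEDIUM")]
_COC_CLASSES = [(0.10, "VERY LOW"), (0.35, "LOW"), (0.55, "MEDIUM"), (np.inf, "HIGH")]


def occupancy_class(occupancy: float, scheme: str) -> str:
    """Qualitative occupancy band of a cluster.

    OCO scheme: <10% VERY LOW, 10-35% LOW, >35% MEDIUM.
    COC scheme: <10% VERY LOW, 10-35% LOW, 35-55% MEDIUM, >55% HIGH.
    A value exactly on a boundary falls in the lower class.
    """
    if not 0.0 <= occupancy <= 1.0:
        raise ValueError("occupancy must lie in [0, 1]")
    table = {"OCO": _OCO_CLASSES, "COC": _COC_CLASSES}.get(scheme)
    if table is None:
        raise ValueError("scheme must be 'OCO' or 'COC'")
    for bound, label in table:
        if occupancy <= bound:
            return label
    raise AssertionError("unreachable")


def condition_summary(
    series_list: list[DwellTimeSeries],
    condition: str,
    concentration_uM: float | None = None,
) -> ConditionSummary:
    """p_op mean +/- SEM over repeat recordings of one condition."""
    if not series_list:
        raise ValueError("need at least one recording")
    pops = [open_probability(s) for s in series_list]
    return ConditionSummary(
        condition=condition,
        concentration_uM=concentration_uM,
        p_op_mean=float(np.mean(pops)),
        p_op_sem=sem(pops) if len(pops) >= 2 else None,
        n_recordings=len(pops),
    )


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (optional multiplicity control)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(running, 1.0)
    return adj
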