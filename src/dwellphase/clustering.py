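"""Cross-correlation clustering of dwell-time triplets.

A dwell-time series is decomposed into overlapping three-element
subsequences that start and end in the same functional state (O-C-O or
C-O-C triplets).  Triplets are partitioned into sets of mutually
cross-correlated sequences: the Pearson correlation of two length-3
vectors measures whether two stretches of gating activity share the same
temporal *shape*, and a set is grown greedily around a running
"comparative" (weighted-average) sequence, then refined by reassignment
sweeps until every member correlates at least R0 with its set's
comparative sequence.

With mean-centred 3-vectors the correlation is invariant to positive
affine transforms, so sets separate primarily by triplet shape; the
product-ordered greedy pass introduces the magnitude ordering observed
in practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

from .idealization import DwellTimeSeries

__all__ = [
    "Triplet",
    "Cluster",
    "ClusterSet",
    "DegenerateSequenceError",
    "build_triplets",
    "cross_correlation",
    "sort_by_product",
    "preliminary_grouping",
    "optimize_partition",
    "select_R0",
    "cluster_summary",
    "cluster_triplets",
]

_FLAT_RTOL = 1e-12


class DegenerateSequenceError(ValueError):
    """Correlation undefined: one of the sequences has zero variance."""


@dataclass
class Triplet:
    """One O-C-O or C-O-C subsequence of three consecutive dwell-times."""

    kind: str  # "OCO" | "COC"
    tau: np.ndarray  # (3,) dwell-times, ms
    index: int  # position of the first event in the source series

    def __post_init__(self) -> None:
        if self.kind not in ("OCO", "COC"):
            raise ValueError("kind must be 'OCO' or 'COC'")
        self.tau = np.asarray(self.tau, dtype=float)
        if self.tau.shape != (3,):
            raise ValueError("tau must be a 3-vector")
        if np.any(self.tau <= 0):
            raise ValueError("dwell-times must be positive")


@dataclass
class Cluster:
    """A set of cross-correlated triplets.

    ``comparative`` is the final weighted-average (running-mean) sequence
    the members were matched against; ``center`` the coordinate-wise mean
    of member tau vectors with standard errors ``se``; ``occupancy`` the
    cardinality normalized over the parent ClusterSet.
    """

    members: list[int]
    comparative: np.ndarray
    center: np.ndarray | None = None
    se: np.ndarray | None = None
    occupancy: float = 0.0
    id: int = -1
    flat: bool = False
    se_degenerate: bool = False  # singleton: SE reported as 0 with this flag

    @property
    def cardinality(self) -> int:
        return len(self.members)


@dataclass
class ClusterSet:
    """Partition of all triplets of one kind under one condition."""

    kind: str
    r0: float
    clusters: list[Cluster]
    condition: str | None = None
    converged: bool = True
    n_triplets: int = 0

    def occupancies(self) -> np.ndarray:
        return np.array([c.occupancy for c in self.clusters])

    def centers(self) -> np.ndarray:
        return np.vstack([c.center for c in self.clusters])


def build_triplets(series: DwellTimeSeries, kind: str) -> list[Triplet]:
    """Construct the list of same-kind triplets from a dwell-time series.

    One triplet starts at every occurrence of the start state that is
    followed by at least two more events; consecutive triplets of the same
    kind therefore slide by one full open-closed cycle and share one
    boundary event.
    """
    start_state = "O" if kind == "OCO" else "C"
    triplets: list[Triplet] = []
    n = len(series)
    for i in range(n - 2):
        if series.states[i] == start_state:
            triplets.append(Triplet(kind, series.durations[i : i + 3].copy(), i))
    return triplets


def cross_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation of two 3-vectors.

    Covariance of the mean-centred vectors over the root of the product
    of their variances; lies in [-1, 1] and is invariant under positive
    affine transforms of either argument.

    Raises
    ------
    DegenerateSequenceError
        If either vector is constant (zero variance).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    nx = float(np.sqrt(xc @ xc))
    ny = float(np.sqrt(yc @ yc))
    if nx <= _FLAT_RTOL * max(1.0, float(np.abs(x).max())) or ny <= _FLAT_RTOL * max(
        1.0, float(np.abs(y).max())
    ):
        raise DegenerateSequenceError("constant sequence: correlation undefined")
    return float(np.clip(xc @ yc / (nx * ny), -1.0, 1.0))


def sort_by_product(triplets: list[Triplet]) -> list[int]:
    """Indices ordered by descending product of the three dwell-times.

    Ties keep the original (ascending source index) order.
    """
    products = np.array([float(np.prod(t.tau)) for t in triplets])
    return list(np.argsort(-products, kind="stable"))


def _centered_unit(tau: np.ndarray) -> np.ndarray | None:
    """Mean-centred, unit-norm tau vector, or None for a flat triplet."""
    c = tau - tau.mean()
    n = float(np.sqrt(c @ c))
    if n <= _FLAT_RTOL * max(1.0, float(np.abs(tau).max())):
        return None
    return c / n


def _corr_to(comparative: np.ndarray, unit: np.ndarray) -> float:
    """Correlation of a comparative sequence with a pre-normalized triplet."""
    c = comparative - comparative.mean()
    n = float(np.sqrt(c @ c))
    if n <= _FLAT_RTOL * max(1.0, float(np.abs(comparative).max())):
        return -np.inf  # flat comparative absorbs nothing
    return float(np.clip(c @ unit / n, -1.0, 1.0))


def preliminary_grouping(triplets: list[Triplet], r0: float) -> list[Cluster]:
    """Greedy grouping of product-sorted triplets around comparative series.

    The first unexcluded triplet of the product-sorted list seeds a
    comparative sequence; every later unexcluded triplet correlating at
    least ``r0`` with the *current* comparative sequence is absorbed, and
    the comparative sequence becomes the cardinality-weighted mean of
    itself (weight = member count) and the newcomer (weight 1), i.e. the
    running mean of the members.  The pass restarts on the remaining
    triplets until all are assigned.  Constant (zero-variance) triplets
    are collected into a dedicated flat cluster.
    """
    if not triplets:
        return []
    if not (0.0 < r0 < 1.0):
        raise ValueError("r0 must lie in (0, 1)")
    taus = np.vstack([t.tau for t in triplets])
    units = [_centered_unit(t.tau) for t in triplets]
    order = sort_by_product(triplets)
    flat = [i for i in order if units[i] is None]
    remaining = [i for i in order if units[i] is not None]
    clusters: list[Cluster] = []
    while remaining:
        seed, rest = remaining[0], remaining[1:]
        comparative = taus[seed].copy()
        members = [seed]
        leftover: list[int] = []
        for i in rest:
            if _corr_to(comparative, units[i]) >= r0:
                k = len(members)
                comparative = (k * comparative + taus[i]) / (k + 1)
                members.append(i)
            else:
                leftover.append(i)
        clusters.append(Cluster(members=members, comparative=comparative))
        remaining = leftover
    if flat:
        clusters.append(
            Cluster(members=flat, comparative=taus[flat].mean(axis=0), flat=True)
        )
    return clusters


def optimize_partition(
    partition: list[Cluster],
    triplets: list[Triplet],
    r0: float,
    max_rounds: int = 100,
) -> tuple[list[Cluster], bool]:
    """Reassignment sweeps until every member matches its comparative.

    Members are visited in ascending triplet index.  A member correlating
    below ``r0`` with its cluster's comparative sequence is removed and
    either added to the best other cluster it matches at >= r0 (ties:
    highest correlation, then largest cardinality, then lowest cluster
    id) or seeds a new cluster.  Comparative sequences are recomputed
    (mean of members) after every move.  Stops at a fixed point — one full
    sweep with no moves — or after ``max_rounds`` sweeps with a warning.

    Returns the stable partition and a convergence flag.
    """
    taus = np.vstack([t.tau for t in triplets]) if triplets else np.empty((0, 3))
    units = [_centered_unit(t.tau) for t in triplets]
    clusters = [
        Cluster(members=list(c.members), comparative=c.comparative.copy(), flat=c.flat)
        for c in partition
    ]

    def recompute(c: Cluster) -> None:
        c.comparative = taus[c.members].mean(axis=0)

    converged = False
    for _ in range(max_rounds):
        moved = False
        for idx in sorted(i for c in clusters if not c.flat for i in c.members):
            home = next(c for c in clusters if not c.flat and idx in c.members)
            if _corr_to(home.comparative, units[idx]) >= r0:
                continue
            # remove from current cluster
            home.members.remove(idx)
            if home.members:
                recompute(home)
            else:
                clusters.remove(home)
            # best-matching other cluster at >= r0
            best: Cluster | None = None
            best_key: tuple[float, int, int] | None = None
            for cid, c in enumerate(clusters):
                if c.flat:
                    continue
                r = _corr_to(c.comparative, units[idx])
                if r < r0:
                    continue
                key = (r, c.cardinality, -cid)
                if best_key is None or key > best_key:
                    best, best_key = c, key
            if best is not None:
                best.members.append(idx)
                recompute(best)
            else:
                clusters.append(Cluster(members=[idx], comparative=taus[idx].copy()))
            moved = True
        if not moved:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"partition optimization did not converge in {max_rounds} rounds",
            RuntimeWarning,
        )
    return clusters, converged


def cluster_summary(
    partition: list[Cluster],
    triplets: list[Triplet],
    kind: str,
    r0: float,
    condition: str | None = None,
    converged: bool = True,
) -> ClusterSet:
    """Summarize a partition: centers, standard errors, occupancies.

    Clusters are ordered by descending occupancy and numbered from 1.
    A singleton's standard error is reported as 0 and flagged.
    """
    taus = np.vstack([t.tau for t in triplets]) if triplets else np.empty((0, 3))
    total = sum(c.cardinality for c in partition)
    out: list[Cluster] = []
    for c in partition:
        m = taus[c.members]
        center = m.mean(axis=0)
        if c.cardinality > 1:
            se = m.std(axis=0, ddof=1) / np.sqrt(c.cardinality)
            se_degenerate = False
        else:
            se = np.zeros(3)
            se_degenerate = True
        out.append(
            Cluster(
                members=list(c.members),
                comparative=c.comparative.copy(),
                center=center,
                se=se,
                occupancy=c.cardinality / total,
                flat=c.flat,
                se_degenerate=se_degenerate,
            )
        )
    out.sort(key=lambda c: -c.occupancy)
    for i, c in enumerate(out):
        c.id = i + 1
    return ClusterSet(
        kind=kind,
        r0=r0,
        clusters=out,
        condition=condition,
        converged=converged,
        n_triplets=total,
    )


def cluster_triplets(
    triplets: list[Triplet],
    r0: float,
    kind: str | None = None,
    condition: str | None = None,
    max_rounds: int = 100,
) -> ClusterSet:
    """Full two-phase clustering: preliminary grouping then optimization."""
    if kind is None:
        kind = triplets[0].kind if triplets else "OCO"
    prelim = preliminary_grouping(triplets, r0)
    optimized, converged = optimize_partition(prelim, triplets, r0, max_rounds)
    return cluster_summary(optimized, triplets, kind, r0, condition, converged)


def _single_exponential_pass(
    taus: np.ndarray, members: list[int], alpha: float
) -> bool:
    """KS test of each coordinate population against Exp(sample mean)."""
    m = taus[members]
    for k in range(3):
        coord = m[:, k]
        p = _sps.kstest(coord, "expon", args=(0.0, float(coord.mean()))).pvalue
        if p < alpha:
            return False
    return True


def select_R0(
    triplets: list[Triplet],
    grid: list[float],
    alpha: float = 0.05,
    pass_fraction: float = 0.9,
    min_members: int = 20,
) -> tuple[float, dict[float, float]]:
    """Choose the correlation threshold by the single-exponential rule.

    For each candidate threshold the full clustering is run; a cluster of
    at least ``min_members`` triplets passes if each of its three
    coordinate dwell-time populations is compatible with a
    single-exponential distribution (one-sample KS against an exponential
    with the population mean, level ``alpha``).  The chosen R0 is the
    highest candidate whose pass rate reaches ``pass_fraction``; if none
    qualifies, the highest-pass-rate candidate (ties to the highest
    threshold) is returned with a warning.

    Returns (chosen R0, {candidate: pass rate}).
    """
    grid = sorted(grid)
    if not grid or not all(0.0 < g < 1.0 for g in grid):
        raise ValueError("grid must contain thresholds in (0, 1)")
    taus = np.vstack([t.tau for t in triplets])
    rates: dict[float, float] = {}
    for g in grid:
        cs = cluster_triplets(triplets, g)
        eligible = [c for c in cs.clusters if c.cardinality >= min_members and not c.flat]
        if not eligible:
            rates[g] = 0.0
            continue
        passed = sum(
            _single_exponential_pass(taus, c.members, alpha) for c in eligible
        )
        rates[g] = passed / len(eligible)
    qualifying = [g for g in grid if rates[g] >= pass_fraction]
    if qualifying:
        return max(qualifying), rates
    best = max(grid, key=lambda g: (rates[g], g))
    warnings.warn(
        "no candidate threshold reached the required single-exponential pass "
        f"fraction {pass_fraction}; returning best candidate {best}",
        RuntimeWarning,
    )
    return best, rates
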