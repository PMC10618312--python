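"""Phase-space comparison of cluster sets across conditions.

Cluster sets live in the 3-D dwell-time space (tau1, tau2, tau3, ms).
This module matches clusters between a condition and its control,
measures displacements of cluster centers, translates sets to a common
control, and quantifies the overall spread of a set by the dispersion
statistic <dist_tau>: the minimal closed tour through all cluster
centers divided by the cluster count, with an uncertainty propagated
from the per-coordinate center standard errors by the total-differential
rule.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linear_sum_assignment

from .clustering import Cluster, ClusterSet

__all__ = [
    "ClusterMatch",
    "DeltaTau",
    "DispersionResult",
    "match_clusters",
    "delta_tau",
    "member_distances",
    "radial_relative_change",
    "common_control_centers",
    "translate_to_common_control",
    "dispersion",
    "render_phase_diagram",
]

_MAX_EXACT_TOUR = 12


@dataclass
class ClusterMatch:
    """One-to-one pairing of cluster ids between two sets."""

    pairs: list[tuple[int, int]]  # (id in set A, id in set B)
    unmatched_a: list[int] = field(default_factory=list)
    unmatched_b: list[int] = field(default_factory=list)

    def partner_of(self, a_id: int) -> int | None:
        for a, b in self.pairs:
            if a == a_id:
                return b
        return None


@dataclass
class DeltaTau:
    """Displacement of a cluster center from its control."""

    delta: np.ndarray  # (tau1, tau2, tau3) condition - control, ms
    distance: float  # Euclidean norm, ms


@dataclass
class DispersionResult:
    """<dist_tau>: minimal closed tour length / cluster count."""

    value: float  # ms
    error: float  # ms, total-differential propagation
    tour: list[int]  # cluster ids in optimal loop order


def _cluster_by_id(cset: ClusterSet, cid: int) -> Cluster:
    for c in cset.clusters:
        if c.id == cid:
            return c
    raise KeyError(f"no cluster with id {cid}")


def match_clusters(set_a: ClusterSet, set_b: ClusterSet) -> ClusterMatch:
    """Optimal one-to-one assignment of clusters between two sets.

    Minimizes the total Euclidean distance between matched centers in
    log-duration coordinates (so fast and slow dwell components weigh
    comparably); surplus clusters on the larger side stay unmatched.
    """
    if set_a.kind != set_b.kind:
        raise ValueError("cluster sets must be of the same triplet kind")
    if not set_a.clusters or not set_b.clusters:
        return ClusterMatch(
            pairs=[],
            unmatched_a=[c.id for c in set_a.clusters],
            unmatched_b=[c.id for c in set_b.clusters],
        )
    la = np.log(set_a.centers())
    lb = np.log(set_b.centers())
    cost = np.linalg.norm(la[:, None, :] - lb[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    ids_a = [c.id for c in set_a.clusters]
    ids_b = [c.id for c in set_b.clusters]
    pairs = [(ids_a[i], ids_b[j]) for i, j in zip(rows, cols)]
    matched_a = {a for a, _ in pairs}
    matched_b = {b for _, b in pairs}
    return ClusterMatch(
        pairs=pairs,
        unmatched_a=[i for i in ids_a if i not in matched_a],
        unmatched_b=[i for i in ids_b if i not in matched_b],
    )


def delta_tau(cluster: Cluster, control_cluster: Cluster) -> DeltaTau:
    """Coordinate displacement (condition - control) and its norm."""
    d = np.asarray(cluster.center, dtype=float) - np.asarray(
        control_cluster.center, dtype=float
    )
    return DeltaTau(delta=d, distance=float(np.linalg.norm(d)))


def member_distances(
    cluster: Cluster, control_cluster: Cluster, taus: np.ndarray
) -> np.ndarray:
    """Per-member distances from the control center (Delta-tau samples)."""
    return np.linalg.norm(taus[cluster.members] - control_cluster.center, axis=1)


def radial_relative_change(
    set_a: ClusterSet,
    control: ClusterSet,
    match: ClusterMatch | None = None,
    on: str = "center",
) -> float:
    """Average relative radial difference of matched cluster centers.

    For each matched pair, |r_A - r_ctrl| / r_ctrl with r the Euclidean
    norm of the center from the origin (``on="center"``), or the same
    ratio on occupancies (``on="occupancy"``).  Pairs with a zero control
    value are skipped with a warning.
    """
    if match is None:
        match = match_clusters(set_a, control)
    ratios = []
    for a_id, c_id in match.pairs:
        ca = _cluster_by_id(set_a, a_id)
        cc = _cluster_by_id(control, c_id)
        if on == "center":
            va = float(np.linalg.norm(ca.center))
            vc = float(np.linalg.norm(cc.center))
        elif on == "occupancy":
            va, vc = ca.occupancy, cc.occupancy
        else:
            raise ValueError("on must be 'center' or 'occupancy'")
        if vc == 0.0:
            warnings.warn("zero control radius: pair skipped", RuntimeWarning)
            continue
        ratios.append(abs(va - vc) / vc)
    return float(np.mean(ratios)) if ratios else 0.0


def common_control_centers(
    control_a: ClusterSet, control_b: ClusterSet
) -> tuple[ClusterMatch, dict[int, np.ndarray], dict[int, np.ndarray]]:
    """Common-control centers: per-coordinate means of matched controls.

    Returns the control-to-control match and, for each control set, a map
    from its cluster ids to the common-control center of the matched
    pair.  Unmatched control clusters keep their own center as the common
    one (no counterpart to average with).
    """
    m = match_clusters(control_a, control_b)
    common_a: dict[int, np.ndarray] = {}
    common_b: dict[int, np.ndarray] = {}
    for a_id, b_id in m.pairs:
        mean = 0.5 * (
            _cluster_by_id(control_a, a_id).center
            + _cluster_by_id(control_b, b_id).center
        )
        common_a[a_id] = mean
        common_b[b_id] = mean
    for a_id in m.unmatched_a:
        common_a[a_id] = np.asarray(_cluster_by_id(control_a, a_id).center)
    for b_id in m.unmatched_b:
        common_b[b_id] = np.asarray(_cluster_by_id(control_b, b_id).center)
    return m, common_a, common_b


def translate_to_common_control(
    cset: ClusterSet,
    own_control: ClusterSet,
    common_centers: dict[int, np.ndarray],
    match: ClusterMatch | None = None,
) -> ClusterSet:
    """Shift every cluster by its matched control's common-control vector.

    Each cluster matched to control cluster j moves by
    (common_center_j - own_control_center_j); occupancies are unchanged.
    Unmatched clusters are translated by the mean translation vector and
    the result is flagged via a warning.
    """
    if match is None:
        match = match_clusters(cset, own_control)
    shifts: dict[int, np.ndarray] = {}
    for a_id, ctrl_id in match.pairs:
        ctrl_center = np.asarray(_cluster_by_id(own_control, ctrl_id).center)
        shifts[a_id] = np.asarray(common_centers[ctrl_id]) - ctrl_center
    mean_shift = (
        np.mean(list(shifts.values()), axis=0) if shifts else np.zeros(3)
    )
    new_clusters = []
    for c in cset.clusters:
        if c.id in shifts:
            shift = shifts[c.id]
        else:
            shift = mean_shift
            warnings.warn(
                f"cluster {c.id} has no matched control; translated by the "
                "mean translation vector",
                RuntimeWarning,
            )
        new_clusters.append(replace(c, center=np.asarray(c.center) + shift))
    return replace(cset, clusters=new_clusters)


def _held_karp_tour(dist: np.ndarray) -> tuple[float, list[int]]:
    """Exact minimal closed tour by Held-Karp dynamic programming."""
    n = dist.shape[0]
    # dp[(subset, j)] = (cost of best path 0 -> ... -> j over subset, parent)
    dp: dict[tuple[int, int], tuple[float, int]] = {}
    for j in range(1, n):
        dp[(1 << j, j)] = (dist[0, j], 0)
    for size in range(2, n):
        for subset in itertools.combinations(range(1, n), size):
            bits = 0
            for j in subset:
                bits |= 1 << j
            for j in subset:
                prev_bits = bits & ~(1 << j)
                best = (np.inf, -1)
                for k in subset:
                    if k == j:
                        continue
                    cand = dp[(prev_bits, k)][0] + dist[k, j]
                    if cand < best[0]:
                        best = (cand, k)
                dp[(bits, j)] = best
    full = (1 << n) - 2  # all nodes except 0
    best_cost, best_j = np.inf, -1
    for j in range(1, n):
        cand = dp[(full, j)][0] + dist[j, 0]
        if cand < best_cost:
            best_cost, best_j = cand, j
    # reconstruct
    tour = [0]
    bits, j = full, best_j
    path = []
    while j != 0:
        path.append(j)
        bits2 = bits & ~(1 << j)
        j = dp[(bits, j)][1]
        bits = bits2
    tour += path[::-1]
    return float(best_cost), tour


def dispersion(cset: ClusterSet) -> DispersionResult:
    """Dispersion <dist_tau> of a cluster set with propagated error.

    The minimal closed loop visiting every cluster center once (Euclidean
    distances in ms), divided by the number of clusters.  The error is
    the total differential of the tour length along the optimal loop:
    the sum over centers and coordinates of |d<dist>/d coordinate| times
    the per-coordinate standard error of that center.

    A single cluster yields 0 (degenerate loop); more than 12 clusters
    exceed the exact-search limit and raise an error.
    """
    n = len(cset.clusters)
    if n == 0:
        raise ValueError("empty cluster set")
    if n > _MAX_EXACT_TOUR:
        raise ValueError(f"exact search infeasible for {n} > {_MAX_EXACT_TOUR} clusters")
    ids = [c.id for c in cset.clusters]
    centers = cset.centers()
    ses = np.vstack(
        [c.se if c.se is not None else np.zeros(3) for c in cset.clusters]
    )
    if n == 1:
        return DispersionResult(value=0.0, error=0.0, tour=[ids[0]])
    if n == 2:
        length = 2.0 * float(np.linalg.norm(centers[0] - centers[1]))
        order = [0, 1]
    else:
        dist = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
        length, order = _held_karp_tour(dist)
    # total-differential error: gradient of the tour length w.r.t. each
    # center coordinate along the fixed optimal loop
    grad = np.zeros_like(centers)
    m = len(order)
    for pos, i in enumerate(order):
        for nb in (order[(pos - 1) % m], order[(pos + 1) % m]):
            edge = centers[i] - centers[nb]
            norm = float(np.linalg.norm(edge))
            if norm > 0:
                grad[i] += edge / norm
    error = float(np.sum(np.abs(grad) * ses)) / n
    return DispersionResult(value=length / n, error=error, tour=[ids[i] for i in order])


def render_phase_diagram(
    sets: list[ClusterSet],
    path: str,
    base_diameter: float = 60.0,
    title: str | None = None,
) -> None:
    """3-D phase diagram: one marker per cluster, diameter ~ occupancy.

    Axes are the three consecutive dwell-times (ms); each condition gets
    its own color; the marker diameter is proportional to the cluster's
    occupancy.  Written to ``path`` (format from the extension).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not sets:
        raise ValueError("need at least one cluster set")
    fig = plt.figure(figsize=(7, 6))
    ax = fig.add_subplot(projection="3d")
    cmap = plt.get_cmap("tab10")
    for k, cset in enumerate(sets):
        centers = cset.centers()
        occ = cset.occupancies()
        # marker size is an area: square the occupancy-proportional diameter
        sizes = (base_diameter * occ) ** 2
        label = cset.condition or f"set {k + 1}"
        ax.scatter(
            centers[:, 0], centers[:, 1], centers[:, 2],
            s=sizes, color=cmap(k % 10), alpha=0.7, label=label,
            depthshade=False,
        )
    ax.set_xlabel(r"$\tau_1$ (ms)")
    ax.set_ylabel(r"$\tau_2$ (ms)")
    ax.set_zlabel(r"$\tau_3$ (ms)")
    if title:
        ax.set_title(title)
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
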