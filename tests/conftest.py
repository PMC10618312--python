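import numpy as np
import pytest

from dwellphase.clustering import Cluster, ClusterSet, Triplet


def make_cluster_set(centers, ses=None, occupancies=None, kind="OCO", r0=0.75):
    """ClusterSet straight from center coordinates (test plumbing)."""
    centers = np.asarray(centers, dtype=float)
    n = centers.shape[0]
    if ses is None:
        ses = np.zeros_like(centers)
    if occupancies is None:
        occupancies = np.full(n, 1.0 / n)
    clusters = [
        Cluster(
            members=[i],
            comparative=centers[i].copy(),
            center=centers[i].copy(),
            se=np.asarray(ses[i], dtype=float),
            occupancy=float(occupancies[i]),
            id=i + 1,
        )
        for i in range(n)
    ]
    return ClusterSet(kind=kind, r0=r0, clusters=clusters, n_triplets=n)


def two_family_triplets(n_per_family=10, seed=0):
    """Two well-separated shape families with known labels.

    Family shapes are opposite directions in the centred plane, so
    within-family correlations are ~1 and cross-family ~-1.
    """
    rng = np.random.default_rng(seed)
    base_a = np.array([4.0, 1.0, 4.0])
    base_b = np.array([1.0, 4.0, 1.0])
    triplets, labels = [], []
    for i in range(2 * n_per_family):
        base = base_a if i % 2 == 0 else base_b
        scale = rng.lognormal(0.0, 0.15)
        tau = base * scale * (1.0 + rng.normal(0.0, 0.02, 3))
        triplets.append(Triplet("OCO", np.abs(tau) + 1e-6, i))
        labels.append(i % 2)
    return triplets, np.array(labels)


@pytest.fixture
def cluster_set_factory():
    return make_cluster_set
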