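"""Text I/O for traces, dwell-time series and cluster reports.

Traces travel as two-column CSV (``time_s,current_pA``) or as a
headerless single column of pA values with the sampling rate supplied
separately; dwell-time series as ``state,duration_ms`` CSV (optionally
with a ground-truth sidecar column); cluster sets as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import Cluster, ClusterSet
from .idealization import CurrentTrace, DwellTimeSeries

__all__ = [
    "read_trace",
    "write_trace",
    "read_dwells",
    "write_dwells",
    "read_cluster_set",
    "write_cluster_set",
]


def read_trace(path: str | Path, fs: float | None = None) -> CurrentTrace:
    """Read a current trace from delimited text.

    With a ``time_s,current_pA`` header the sampling rate is inferred
    from the time column (a uniform grid is required); a headerless
    single column needs ``fs`` explicitly.
    """
    path = Path(path)
    first = path.open().readline()
    if "current_pA" in first:
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy()
        if t.size < 2:
            raise ValueError("need at least two samples to infer the rate")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("time column is not a uniform grid")
        return CurrentTrace(df["current_pA"].to_numpy(), fs=1.0 / dt[0])
    if fs is None:
        raise ValueError("headerless trace input requires fs")
    samples = pd.read_csv(path, header=None)[0].to_numpy()
    return CurrentTrace(samples, fs=fs)


def write_trace(trace: CurrentTrace, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": trace.times_s, "current_pA": trace.samples}
    ).to_csv(path, index=False)


def read_dwells(path: str | Path) -> DwellTimeSeries:
    df = pd.read_csv(path)
    return DwellTimeSeries(
        df["state"].to_numpy(dtype="<U1"),
        df["duration_ms"].to_numpy(dtype=float),
        provenance=str(path),
    )


def write_dwells(
    series: DwellTimeSeries,
    path: str | Path,
    hidden_labels: np.ndarray | None = None,
) -> None:
    """Write a dwell series; an optional ground-truth label sidecar column."""
    data = {"state": series.states, "duration_ms": series.durations}
    if hidden_labels is not None:
        data["ground_truth_label"] = hidden_labels
    pd.DataFrame(data).to_csv(path, index=False)


def _cluster_to_dict(c: Cluster) -> dict:
    return {
        "id": c.id,
        "members": list(map(int, c.members)),
        "cardinality": c.cardinality,
        "occupancy": c.occupancy,
        "center_ms": [float(v) for v in c.center],
        "se_ms": [float(v) for v in c.se],
        "comparative_ms": [float(v) for v in c.comparative],
        "flat": c.flat,
        "se_degenerate": c.se_degenerate,
    }


def write_cluster_set(cset: ClusterSet, path: str | Path) -> None:
    payload = {
        "kind": cset.kind,
        "r0": cset.r0,
        "condition": cset.condition,
        "converged": cset.converged,
        "n_triplets": cset.n_triplets,
        "clusters": [_cluster_to_dict(c) for c in cset.clusters],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_cluster_set(path: str | Path) -> ClusterSet:
    payload = json.loads(Path(path).read_text())
    clusters = [
        Cluster(
            members=list(d["members"]),
            comparative=np.array(d["comparative_ms"]),
            center=np.array(d["center_ms"]),
            se=np.array(d["se_ms"]),
            occupancy=d["occupancy"],
            id=d["id"],
            flat=d.get("flat", False),
            se_degenerate=d.get("se_degenerate", False),
        )
        for d in payload["clusters"]
    ]
    return ClusterSet(
        kind=payload["kind"],
        r0=payload["r0"],
        clusters=clusters,
        condition=payload.get("condition"),
        converged=payload.get("converged", True),
        n_triplets=payload.get("n_triplets", sum(c.cardinality for c in clusters)),
    )
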