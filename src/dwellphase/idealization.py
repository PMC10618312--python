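"""Idealization of single-channel current traces.

Converts a noisy patch-clamp current recording into a discrete
open/closed state sequence by amplitude thresholding, extracts the
dwell-time series (durations of the successive sojourns in each state)
and computes macroscopic summaries such as the open-state probability.

The threshold separating the two conductance levels is estimated from a
two-component normal mixture fitted to the amplitude histogram; the
threshold is the midpoint between the two component means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CurrentTrace",
    "DwellTimeSeries",
    "LevelsNotSeparableError",
    "InsufficientEventsError",
    "estimate_threshold",
    "idealize",
    "extract_dwell_times",
    "open_probability",
    "apply_dead_time",
]

OPEN = "O"
CLOSED = "C"


class LevelsNotSeparableError(ValueError):
    """The amplitude histogram does not resolve two conductance levels."""


class InsufficientEventsError(ValueError):
    """Too few complete sojourns to form a dwell-time series."""


@dataclass
class CurrentTrace:
    """Uniformly sampled single-channel current.

    Parameters
    ----------
    samples : array of current values in pA, in recording order.
    fs : sampling frequency in Hz.
    fc : nominal low-pass cutoff in Hz (metadata only), optional.
    meta : free-form recording metadata, e.g. membrane potential ``U_m``
        in mV, condition label, modulator concentration in µM.
    """

    samples: np.ndarray
    fs: float
    fc: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        if self.samples.size == 0:
            raise ValueError("trace must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass
class DwellTimeSeries:
    """Strictly alternating sequence of (state, duration) sojourns.

    ``states`` holds ``"O"`` / ``"C"`` labels and ``durations`` the
    matching sojourn lengths in milliseconds.
    """

    states: np.ndarray
    durations: np.ndarray
    provenance: str | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype="<U1")
        self.durations = np.asarray(self.durations, dtype=float)
        if self.states.shape != self.durations.shape:
            raise ValueError("states and durations must have equal length")
        if self.states.size and not np.all(np.isin(self.states, [OPEN, CLOSED])):
            raise ValueError("states must be 'O' or 'C'")
        if np.any(self.durations <= 0):
            raise ValueError("all durations must be positive")
        if self.states.size > 1 and np.any(self.states[1:] == self.states[:-1]):
            raise ValueError("states must strictly alternate")

    def __len__(self) -> int:
        return int(self.states.size)

    @property
    def total_duration_ms(self) -> float:
        return float(self.durations.sum())


def _fit_two_normal_mixture(
    x: np.ndarray, rtol: float = 1e-8, max_iter: int = 500
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """EM fit of a two-component 1-D normal mixture.

    Means are initialized at the 10th and 90th amplitude percentiles.
    Returns (weights, means, variances).
    """
    x = np.asarray(x, dtype=float)
    span = float(np.ptp(x))
    if span == 0.0:
        raise LevelsNotSeparableError("constant trace: levels not separable")
    # variance floor keeps EM stable on (near-)noiseless two-level data
    var_floor = max((1e-6 * span) ** 2, 1e-300)
    mu = np.percentile(x, [10.0, 90.0]).astype(float)
    var = np.full(2, max(np.var(x) / 4.0, var_floor))
    w = np.array([0.5, 0.5])
    prev = np.concatenate([w, mu, var])
    for _ in range(max_iter):
        # E-step: responsibilities
        log_p = (
            -0.5 * (x[:, None] - mu) ** 2 / var
            - 0.5 * np.log(2 * np.pi * var)
            + np.log(w)
        )
        log_p -= log_p.max(axis=1, keepdims=True)
        resp = np.exp(log_p)
        resp /= resp.sum(axis=1, keepdims=True)
        # M-step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        w = nk / x.size
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu) ** 2).sum(axis=0) / nk
        var = np.maximum(var, var_floor)
        params = np.concatenate([w, mu, var])
        scale = np.maximum(np.abs(prev), 1e-12)
        if np.max(np.abs(params - prev) / scale) < rtol:
            break
        prev = params
    return w, mu, var


def estimate_threshold(trace: CurrentTrace) -> float:
    """Estimate the current threshold separating open and shut levels.

    Fits a two-component normal mixture to the amplitude distribution and
    returns the midpoint between the two component means.

    Raises
    ------
    LevelsNotSeparableError
        If the two mixture means are closer than three pooled noise
        standard deviations (effectively unimodal amplitude histogram).
    """
    w, mu, var = _fit_two_normal_mixture(trace.samples)
    pooled_sd = math.sqrt(float(w @ var))
    if abs(mu[1] - mu[0]) < 3.0 * pooled_sd:
        raise LevelsNotSeparableError(
            "levels not separable: mixture means closer than 3x pooled noise SD"
        )
    return float(mu.mean())


def idealize(
    trace: CurrentTrace, threshold: float, open_above: bool = True
) -> np.ndarray:
    """Label each sample O or C relative to ``threshold``.

    A sample exactly at the threshold is assigned to the closed state.
    ``open_above`` selects which side of the threshold is conducting.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if open_above:
        is_open = trace.samples > threshold
    else:
        is_open = trace.samples < threshold
    return np.where(is_open, OPEN, CLOSED).astype("<U1")


def _run_lengths(states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    states = np.asarray(states)
    if states.size == 0:
        raise ValueError("empty state sequence")
    change = np.flatnonzero(states[1:] != states[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [states.size]])
    return states[starts], (ends - starts).astype(int)


def extract_dwell_times(
    states: np.ndarray,
    fs: float,
    drop_edges: bool = True,
    provenance: str | None = None,
) -> DwellTimeSeries:
    """Run-length encode a per-sample state sequence into dwell times.

    Durations are run length / ``fs``, in milliseconds.  With
    ``drop_edges`` (default) the first and last sojourns are discarded as
    censored: their true onset/offset fell outside the recording.

    Raises
    ------
    InsufficientEventsError
        If fewer than three sojourns remain.
    """
    run_states, run_lens = _run_lengths(states)
    if drop_edges:
        run_states = run_states[1:-1]
        run_lens = run_lens[1:-1]
    if run_states.size < 3:
        raise InsufficientEventsError(
            f"insufficient events: {run_states.size} sojourn(s) after "
            f"edge handling, need at least 3"
        )
    durations = run_lens / fs * 1000.0
    return DwellTimeSeries(run_states, durations, provenance=provenance)


def open_probability(series: DwellTimeSeries) -> float:
    """Fraction of total time spent in the open state (p_op)."""
    if len(series) == 0:
        raise ValueError("empty dwell-time series")
    open_time = series.durations[series.states == OPEN].sum()
    return float(open_time / series.total_duration_ms)


def apply_dead_time(series: DwellTimeSeries, min_duration_ms: float) -> DwellTimeSeries:
    """Impose a temporal resolution: merge sojourns shorter than the limit.

    Events shorter than ``min_duration_ms`` are treated as unresolved and
    absorbed into their neighbours: an interior short event bridges its two
    (same-state) neighbours into one sojourn; a short edge event is absorbed
    by its single neighbour.  Applied iteratively, shortest event first,
    until every remaining sojourn meets the limit.
    """
    states = list(series.states)
    durations = list(series.durations)
    while len(states) > 1:
        i = int(np.argmin(durations))
        if durations[i] >= min_duration_ms:
            break
        if i == 0:
            durations[1] += durations[0]
            del states[0], durations[0]
        elif i == len(states) - 1:
            durations[-2] += durations[-1]
            del states[-1], durations[-1]
        else:
            durations[i - 1] += durations[i] + durations[i + 1]
            del states[i : i + 2], durations[i : i + 2]
    return DwellTimeSeries(
        np.array(states, dtype="<U1"),
        np.array(durations, dtype=float),
        provenance=series.provenance,
    )
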