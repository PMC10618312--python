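"""Synthetic gating data: Markov simulators, traces, triplet mixtures.

Three generators cover the inputs of the analysis pipeline:

* aggregated-Markov gating simulation — a multi-state kinetic scheme
  whose substates are observed only through their open/closed class;
  sojourns are exponential with the state's exit rate, and consecutive
  same-class sojourns aggregate into one observed dwell-time;
* current-trace synthesis — a two-level rectangular signal sampled at a
  fixed rate, low-pass filtered and corrupted by Gaussian noise, the way
  a patch-clamp amplifier records single-channel activity;
* labelled triplet mixtures — dwell-time triplets drawn from a small
  number of shape components in the plane orthogonal to (1,1,1), used as
  ground-truthed fixtures for cluster recovery.

Named presets bundle the study conditions: two-state schemes matching
the published open-state probabilities for control/flavonoid conditions,
a 4-open/5-closed ladder scheme, and the six-component shape mixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

from .clustering import Triplet
from .idealization import CurrentTrace, DwellTimeSeries

__all__ = [
    "GatingModel",
    "SimulatedGating",
    "MixtureComponent",
    "TripletMixture",
    "simulate_gating",
    "synthesize_trace",
    "generate_triplet_mixture",
    "shape_angle",
    "stationary_open_probability",
    "preset",
    "PRESETS",
    "two_state_model",
]

# orthonormal basis of the plane orthogonal to (1, 1, 1)
_E1 = np.array([1.0, -1.0, 0.0]) / np.sqrt(2.0)
_E2 = np.array([1.0, 1.0, -2.0]) / np.sqrt(6.0)


@dataclass
class GatingModel:
    """Aggregated Markov gating scheme.

    Each substate has a label, a functional class ('O' or 'C') and an
    exit rate in 1/ms (mean sojourn = 1/rate).  ``jump`` is the embedded
    jump-probability matrix (row-stochastic, zero diagonal); transitions
    between same-class substates are allowed — the observable aggregates
    them into a single dwell.
    """

    labels: list[str]
    classes: np.ndarray  # '<U1' array of 'O'/'C'
    exit_rates: np.ndarray  # 1/ms
    jump: np.ndarray  # (n, n) row-stochastic, zero diagonal
    initial: np.ndarray | None = None  # default: stationary of embedded chain

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype="<U1")
        self.exit_rates = np.asarray(self.exit_rates, dtype=float)
        self.jump = np.asarray(self.jump, dtype=float)
        n = len(self.labels)
        if self.classes.shape != (n,) or self.exit_rates.shape != (n,):
            raise ValueError("labels, classes and exit_rates must align")
        if self.jump.shape != (n, n):
            raise ValueError("jump matrix shape mismatch")
        if np.any(self.exit_rates <= 0):
            raise ValueError("exit rates must be positive")
        if np.any(np.diag(self.jump) != 0):
            raise ValueError("jump matrix must have zero diagonal")
        if not np.allclose(self.jump.sum(axis=1), 1.0):
            raise ValueError("jump matrix rows must sum to 1")
        if "O" not in self.classes or "C" not in self.classes:
            raise ValueError("model needs at least one open and one closed state")
        n_comp, _ = connected_components(
            csr_matrix(self.jump > 0), directed=True, connection="strong"
        )
        if n_comp != 1:
            raise ValueError("model has absorbing/unreachable states")
        if self.initial is not None:
            self.initial = np.asarray(self.initial, dtype=float)
            if self.initial.shape != (n,) or not np.isclose(self.initial.sum(), 1.0):
                raise ValueError("initial distribution must sum to 1")

    @property
    def n_states(self) -> int:
        return len(self.labels)


@dataclass
class SimulatedGating:
    """Observed dwell-time series plus the hidden trajectory behind it."""

    series: DwellTimeSeries
    hidden_states: np.ndarray  # substate index per hidden sojourn
    hidden_durations: np.ndarray  # ms
    event_of_sojourn: np.ndarray  # observed-event index per hidden sojourn


def stationary_open_probability(model: GatingModel) -> float:
    """Analytic stationary p_op of the scheme.

    Solves pi Q = 0 for the continuous-time generator Q (off-diagonal
    rate_i * P_ij) and sums the stationary occupation of the open class.
    """
    r = model.exit_rates
    q = r[:, None] * model.jump
    np.fill_diagonal(q, -r)
    n = model.n_states
    # replace one balance equation by the normalization constraint
    a = np.vstack([q.T[:-1], np.ones(n)])
    b = np.zeros(n)
    b[-1] = 1.0
    pi = np.linalg.lstsq(a, b, rcond=None)[0]
    return float(pi[model.classes == "O"].sum())


def _embedded_stationary(model: GatingModel) -> np.ndarray:
    """Stationary distribution of the embedded jump chain."""
    n = model.n_states
    a = np.vstack([(model.jump.T - np.eye(n))[:-1], np.ones(n)])
    b = np.zeros(n)
    b[-1] = 1.0
    pi = np.linalg.lstsq(a, b, rcond=None)[0]
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def simulate_gating(
    model: GatingModel, n_events: int, seed: int | np.random.Generator
) -> SimulatedGating:
    """Simulate the scheme and aggregate it into an observed dwell series.

    The embedded Markov chain jumps between substates; each sojourn is
    exponential with the substate's mean (1/exit rate, ms).  Consecutive
    sojourns of the same functional class merge into one observed event,
    so the observed series strictly alternates O/C.  Exactly ``n_events``
    complete observed events are returned (an event completes when the
    class switches), together with the hidden trajectory.
    """
    if n_events < 3:
        raise ValueError("need at least 3 observed events")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    init = model.initial if model.initial is not None else _embedded_stationary(model)
    cum_rows = np.cumsum(model.jump, axis=1)
    means = 1.0 / model.exit_rates
    s = int(np.searchsorted(np.cumsum(init), rng.random()))
    obs_states: list[str] = []
    obs_durs: list[float] = []
    hid_states: list[int] = []
    hid_durs: list[float] = []
    hid_event: list[int] = []
    run_class = str(model.classes[s])
    run_dur = 0.0
    while len(obs_states) < n_events:
        d = rng.exponential(means[s])
        hid_states.append(s)
        hid_durs.append(d)
        hid_event.append(len(obs_states))
        run_dur += d
        s_next = int(np.searchsorted(cum_rows[s], rng.random(), side="right"))
        if model.classes[s_next] != run_class:
            obs_states.append(run_class)
            obs_durs.append(run_dur)
            run_class = str(model.classes[s_next])
            run_dur = 0.0
        s = s_next
    series = DwellTimeSeries(
        np.array(obs_states, dtype="<U1"),
        np.array(obs_durs, dtype=float),
        provenance=f"simulate_gating(seed={seed})"
        if not isinstance(seed, np.random.Generator)
        else "simulate_gating(rng)",
    )
    return SimulatedGating(
        series=series,
        hidden_states=np.array(hid_states, dtype=int),
        hidden_durations=np.array(hid_durs, dtype=float),
        event_of_sojourn=np.array(hid_event, dtype=int),
    )


def synthesize_trace(
    series: DwellTimeSeries,
    i_closed: float = 0.0,
    i_open: float = 10.0,
    noise_sd: float = 0.5,
    fs: float = 10_000.0,
    fc: float | None = 1_000.0,
    seed: int | np.random.Generator = 0,
    meta: dict | None = None,
) -> CurrentTrace:
    """Render a dwell-time series as a noisy sampled current trace.

    A rectangular two-level signal (pA) is sampled at ``fs``; if ``fc``
    is below the Nyquist frequency a causal 4-pole Butterworth low-pass
    is applied; Gaussian noise of ``noise_sd`` pA is added afterwards.
    Every dwell must span at least one sampling interval.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if np.any(series.durations < 1000.0 / fs):
        raise ValueError("every dwell must last at least one sampling interval")
    boundaries = np.rint(np.cumsum(series.durations) * fs / 1000.0).astype(int)
    counts = np.diff(np.concatenate([[0], boundaries]))
    levels = np.where(series.states == "O", i_open, i_closed)
    x = np.repeat(levels, counts).astype(float)
    if fc is not None and fc < fs / 2.0:
        sos = _signal.butter(4, fc, btype="low", fs=fs, output="sos")
        zi = _signal.sosfilt_zi(sos) * x[0]
        x, _ = _signal.sosfilt(sos, x, zi=zi)
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=x.size)
    trace_meta = dict(meta or {})
    trace_meta.setdefault("provenance", series.provenance)
    return CurrentTrace(samples=x, fs=fs, fc=fc, meta=trace_meta)


@dataclass
class MixtureComponent:
    """One shape component of a triplet mixture."""

    weight: float
    scale_ms: float  # log-normal median of the triplet magnitude
    angle_deg: float  # shape angle in the plane orthogonal to (1,1,1)
    jitter_deg: float = 6.0  # SD of the angular jitter
    log_sd: float = 0.2  # SD of log-magnitude


@dataclass
class TripletMixture:
    """Mixture of shape components generating labelled triplets."""

    components: list[MixtureComponent]
    kind: str = "OCO"
    amplitude: float = 0.5  # shape modulation depth

    def __post_init__(self) -> None:
        w = np.array([c.weight for c in self.components])
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("component weights must sum to 1")
        if np.any(np.array([c.scale_ms for c in self.components]) <= 0):
            raise ValueError("magnitude scales must be positive")


def _shape_vector(angle_rad: np.ndarray) -> np.ndarray:
    """Unit vector at the given angle in the plane orthogonal to (1,1,1)."""
    return np.outer(np.cos(angle_rad), _E1) + np.outer(np.sin(angle_rad), _E2)


def shape_angle(tau: np.ndarray) -> float:
    """Angle (degrees) of a triplet's centred shape in the (e1, e2) plane."""
    c = np.asarray(tau, dtype=float)
    c = c - c.mean()
    return float(np.degrees(np.arctan2(c @ _E2, c @ _E1)))


def generate_triplet_mixture(
    mix: TripletMixture, n: int, seed: int | np.random.Generator
) -> tuple[list[Triplet], np.ndarray]:
    """Draw ``n`` labelled triplets from a shape mixture.

    Each triplet picks a component by weight; its dwell-time vector is
    tau = m * (1 + a * shape(theta + eps)) with shape(.) the unit vector
    at the jittered component angle in the plane orthogonal to (1,1,1),
    a the fixed modulation amplitude and m log-normal about the
    component's magnitude scale.  Non-positive coordinates (possible only
    for amplitude > ~0.6) are redrawn.  Returns the triplets and their
    generator labels.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n < 1:
        raise ValueError("n must be at least 1")
    weights = np.array([c.weight for c in mix.components])
    labels = rng.choice(len(mix.components), size=n, p=weights)
    angles = np.array([mix.components[k].angle_deg for k in labels])
    jitters = np.array([mix.components[k].jitter_deg for k in labels])
    scales = np.array([mix.components[k].scale_ms for k in labels])
    log_sds = np.array([mix.components[k].log_sd for k in labels])
    taus = np.empty((n, 3))
    todo = np.arange(n)
    while todo.size:
        eps = rng.normal(0.0, jitters[todo])
        theta = np.radians(angles[todo] + eps)
        m = scales[todo] * np.exp(rng.normal(0.0, log_sds[todo]))
        cand = m[:, None] * (1.0 + mix.amplitude * _shape_vector(theta))
        taus[todo] = cand
        todo = todo[np.any(cand <= 0, axis=1)]
    triplets = [Triplet(mix.kind, taus[i], i) for i in range(n)]
    return triplets, labels


def two_state_model(
    p_op: float, mean_cycle_ms: float = 3.0, label: str = ""
) -> GatingModel:
    """Two-state O/C scheme with the given stationary open probability.

    Mean open and closed dwells partition ``mean_cycle_ms`` so that
    p_op = tau_O / (tau_O + tau_C).
    """
    if not 0.0 < p_op < 1.0:
        raise ValueError("p_op must lie strictly in (0, 1)")
    tau_o = mean_cycle_ms * p_op
    tau_c = mean_cycle_ms * (1.0 - p_op)
    return GatingModel(
        labels=[f"O{label}", f"C{label}"],
        classes=np.array(["O", "C"]),
        exit_rates=np.array([1.0 / tau_o, 1.0 / tau_c]),
        jump=np.array([[0.0, 1.0], [1.0, 0.0]]),
    )


def _fig2_nine_state() -> GatingModel:
    """4-open/5-closed ladder scheme with distinct time constants.

    Rate constants are illustrative: O and C substates sit on two coupled
    ladders (O_i - O_{i+1}, C_i - C_{i+1}, O_i - C_i) with mean sojourns
    ranging from 1 to 8 ms, mimicking the spread of fast and slow
    substates of large-conductance channel gating.
    """
    labels = ["O1", "O2", "O3", "O4", "C1", "C2", "C3", "C4", "C5"]
    classes = np.array(["O"] * 4 + ["C"] * 5)
    means = np.array([1.5, 2.5, 4.0, 6.0, 1.0, 2.0, 3.0, 5.0, 8.0])  # ms
    idx = {lab: i for i, lab in enumerate(labels)}
    edges = [
        ("O1", "O2"), ("O2", "O3"), ("O3", "O4"),
        ("C1", "C2"), ("C2", "C3"), ("C3", "C4"), ("C4", "C5"),
        ("O1", "C1"), ("O2", "C2"), ("O3", "C3"), ("O4", "C4"),
    ]
    jump = np.zeros((9, 9))
    for a, b in edges:
        jump[idx[a], idx[b]] = 1.0
        jump[idx[b], idx[a]] = 1.0
    jump /= jump.sum(axis=1, keepdims=True)
    return GatingModel(
        labels=labels, classes=classes, exit_rates=1.0 / means, jump=jump
    )


def _phase_portrait_6() -> TripletMixture:
    """Six equal-weight shape components at 60-degree spacing.

    Adjacent component shapes correlate at cos 60 deg = 0.5, below the
    working threshold R0 = 0.75, so the components are separable by
    cross-correlation clustering; the 6-degree angular jitter keeps
    within-component correlations near 1.
    """
    scales = [2.0, 3.0, 1.5, 4.0, 2.5, 3.5]
    comps = [
        MixtureComponent(weight=1.0 / 6.0, scale_ms=scales[k], angle_deg=60.0 * k)
        for k in range(6)
    ]
    return TripletMixture(components=comps)


# Named parameter bundles.  The two-state entries reproduce the measured
# stationary open probabilities of the control and flavonoid conditions.
_TABLE1_POP = {
    ("que", "control"): 0.58,
    ("que", "3uM"): 0.80,
    ("que", "10uM"): 0.85,
    ("nar", "control"): 0.56,
    ("nar", "3uM"): 0.63,
    ("nar", "10uM"): 0.66,
}

PRESETS: dict[str, object] = {
    **{
        f"table1-{drug}-{cond}": p
        for (drug, cond), p in _TABLE1_POP.items()
    },
    "fig2-9state": None,
    "phase-portrait-6": None,
}


def preset(name: str) -> GatingModel | TripletMixture:
    """Return a named, versioned parameter bundle.

    Known presets: ``table1-{que,nar}-{control,3uM,10uM}`` (two-state
    schemes with the measured stationary p_op), ``fig2-9state`` (the
    4-open/5-closed ladder) and ``phase-portrait-6`` (the six-component
    triplet shape mixture).
    """
    if name == "fig2-9state":
        return _fig2_nine_state()
    if name == "phase-portrait-6":
        return _phase_portrait_6()
    if name in PRESETS:
        drug, cond = name.split("-")[1:]
        return two_state_model(_TABLE1_POP[(drug, cond)], label=f"-{drug}-{cond}")
    raise KeyError(
        f"unknown preset {name!r}; available: {sorted(PRESETS)}"
    )
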