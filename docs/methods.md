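# Methods

This note documents the models, algorithms and numerical choices behind
`dwellphase`, and what the synthetic generators do and do not emulate.

## Idealization

A single-channel current trace is reduced to a two-state (open/closed)
sequence by amplitude thresholding. The threshold is the midpoint
between the means of a two-component normal mixture fitted to the
amplitude distribution by EM: means initialized at the 10th and 90th
amplitude percentiles, shared-scale variance floor of (10⁻⁶ × amplitude
range)², fixed-point iteration to a relative parameter tolerance of
1e-8, at most 500 iterations. If the fitted means are closer than three
pooled noise standard deviations the levels are declared not separable
— thresholding a unimodal histogram would only label noise. A sample
exactly at the threshold is assigned to the closed state
(deterministic, conservative for conduction).

Dwell-times are the run lengths of the labelled sequence divided by the
sampling rate, in milliseconds. The first and last sojourns are dropped
by default: their onsets/offsets fall outside the recording, so their
durations are censored. No missed-event correction is applied by
default; `apply_dead_time` optionally imposes a temporal resolution by
absorbing sojourns shorter than a limit into their neighbours (an
interior short event bridges its two same-state neighbours; a short
edge event is absorbed by its single neighbour), shortest event first.
Imposing the *same* resolution on a reference series and on a
reconstruction makes them comparable event-by-event — the standard
symmetric resolution treatment in single-channel analysis. Only
single-channel (one open level) activity is modelled; multi-level
traces are out of scope.

The open-state probability p_op is the fraction of total time spent
open; it is invariant under uniform rescaling of all durations, and the
threshold estimate shifts exactly with a constant offset of the trace —
both properties are asserted in the tests.

## Triplet clustering

Triplets are built by taking every occurrence of the start state that
has two successors, so consecutive same-kind triplets slide by one full
open–closed cycle and share one boundary event. This maximizes the
statistics available from ~20 s recordings; a larger stride would
discard half of the switching events.

The correlation is the plain Pearson coefficient of the two raw
3-vectors of dwell-times (not log-times). Mean-centred 3-vectors make
the coefficient scale-free, so clusters separate by triplet *shape*;
magnitude segregation enters through the product-ordered greedy pass,
which seeds clusters from the slowest (largest-product) triplets first.
Observed behaviour on the six-component mixture: shape separation alone
already determines the partition; the product ordering fixes the seed
identity and hence determinism.

Preliminary grouping follows the greedy scheme described in the
package docstrings; the "weighted average" comparative sequence uses
cardinality weights (absorbing one triplet into a k-member set weighs k
against 1), which makes the comparative sequence exactly the running
mean of its members — after any sequence of absorptions the comparative
sequence equals the member mean, so the optimization stage can
recompute it from scratch without history.

Optimization sweeps members in ascending triplet index. A member
correlating below R₀ with its own set's comparative sequence is moved
to the best other set it matches at ≥ R₀ (ties: highest correlation,
then largest cardinality, then lowest cluster id) or seeds a singleton.
The sweep repeats until a full pass makes no move (fixed point) or
`max_rounds = 100` is reached, in which case the result is flagged
non-converged with a warning. At a fixed point every member correlates
≥ R₀ with its final comparative sequence — asserted as an invariant for
every fixture in the test suite.

Degenerate triplets (all three dwell-times equal, possible after
discretization) have zero variance and an undefined correlation; they
are collected into a dedicated "flat" cluster rather than silently
dropped or force-assigned.

R₀ selection: for each candidate on a grid, the full clustering is run
and each cluster with ≥ 20 members is checked for single-exponential
coordinate populations (one-sample KS against an exponential with the
population mean, α = 0.05; the estimated-mean correction is ignored —
plain KS is conservative here). The chosen R₀ is the highest candidate
whose pass rate reaches 0.9; failing that, the highest-pass-rate
candidate (ties towards the higher threshold) with a warning. The 0.9
pass fraction operationalizes "most, ideally all" sets; it is a package
default, not a measured constant. Note that the fallback path is the
common one on strongly non-exponential fixtures (e.g. log-normal
magnitude mixtures), where no candidate passes and the highest
candidate wins by pass rate.

Determinism: there is no internal randomness anywhere in the clustering
path; identical inputs give bit-identical partitions.

## Phase-space comparison

Cluster matching across conditions uses an optimal one-to-one
assignment (Hungarian algorithm) minimizing total Euclidean distance
between centers in log-duration coordinates; the log metric balances
fast and slow dwell components that differ by orders of magnitude.
Displacements Δτ and the dispersion tour, by contrast, are measured in
linear milliseconds — the coordinates of the phase diagram itself. Both
metrics are deliberate and documented rather than configurable switches
hidden in defaults.

The dispersion ⟨dist_τ⟩ is the minimal closed loop through all cluster
centers divided by the cluster count. The tour is computed exactly by
Held–Karp dynamic programming, practical to 12 clusters (the instances
of interest have 6); the test suite cross-checks it against brute-force
enumeration of all (n−1)! tours for n ≤ 8. Degenerate loops follow the
same formula: one cluster gives 0, two clusters give 2d/2 = d. The
uncertainty is propagated by the total-differential rule along the
fixed optimal tour: the gradient of the tour length with respect to
each center coordinate is the sum of the unit vectors of the two
adjacent edges, and the error is Σ |∂⟨dist⟩/∂c| · SE(c). This ignores
the discrete sensitivity of the tour itself to center perturbations, as
a first-order method should.

The common control is the unweighted per-coordinate mean of the two
control sets' matched centers; condition clusters translate by the
vector from their matched control cluster to its common-control
position. An unmatched cluster is translated by the mean translation
vector and flagged — dropping it would silently change occupancies.

## Energetics

Kramers escape rate r = D/(2π k_B T) · √(U″(a)U″(b)) ·
exp(−(U(b)−U(a))/k_B T). With the constant-steepness assumption
(curvatures and well spacing unchanged by modulator binding) the
prefactor cancels between conditions and Δ(U(b)−U(a)) =
k_B T ln(τ_cond/τ_ctrl). Energies are reported in k_BT first and joules
second, because only barrier *changes* are identifiable — the reference
potential is unknown. Default temperature 295 K (room-temperature
recording), configurable. Barrier changes are computed per triplet
coordinate; which coordinate maps to which physical transition is left
to interpretation in the report, since a triplet straddles two
switching events.

## Statistics

SEM = SD(ddof = 1)/√n. The Mann–Whitney U statistic counts (a, b) pairs
with a < b, plus half a count per tie; the two-sided p-value is exact
(full enumeration of the C(n, n_A) label assignments) when the smaller
sample has ≤ 8 observations and there are no ties, otherwise a normal
approximation with tie and continuity corrections. Occupancy classes
keep two deliberately distinct schemes keyed by triplet kind (the O–C–O
scheme tops out at MEDIUM > 35%; the C–O–C scheme splits MEDIUM 35–55%
and HIGH > 55%), with boundary values falling into the lower class. No
multiplicity correction is applied by default; `holm_adjust` is
available when a family of cluster-wise comparisons warrants it.

The Δτ samples entering a U test default to per-member distances from
the matched control center (`member_distances`); per-recording center
distances are the natural alternative when several recordings per
condition exist.

## Synthetic generators

`simulate_gating` draws the embedded Markov chain of an aggregated
scheme with exponential sojourns (mean 1/exit-rate). Transitions
between same-class substates are allowed and invisible: consecutive
same-class sojourns merge into one observed dwell, the defining feature
of aggregated Markov gating. The observed series therefore always
alternates O/C. Hidden substate labels and sojourns are retained for
validation. The analytic stationary p_op comes from the continuous-time
generator's stationary distribution.

Presets: `table1-{que,nar}-{control,3uM,10uM}` are two-state schemes
whose stationary p_op equals the measured open probabilities of the
corresponding experimental conditions (Que 0.58/0.80/0.85, Nar
0.56/0.63/0.66), with a 3 ms mean gating cycle; `fig2-9state` is a
4-open/5-closed double-ladder scheme (O_i–O_{i+1}, C_i–C_{i+1}, O_i–C_i
edges, uniform jump probabilities over neighbours) with mean sojourns
1–8 ms. Its rate constants are illustrative — no published rate set
exists for these channels — chosen so that substate time constants are
distinct and dwell statistics fall in the experimentally typical
millisecond range.

`synthesize_trace` renders a dwell series as a rectangular two-level
signal (default 0 and 10 pA), sampled at 10 kHz, causally filtered by a
4-pole Butterworth low-pass at 1 kHz when the cutoff is below Nyquist,
plus white Gaussian noise. Event boundaries are rounded to the sample
grid, so durations survive a round trip to within ±1 sample. Noise is
added after the filter; filtered (coloured) noise, baseline drift,
capacitive transients and multi-channel patches are *not* emulated —
round-trip tests therefore validate the thresholding logic, not
robustness to every artefact of real recordings.

`generate_triplet_mixture` draws labelled triplets as
τ = m · (1 + a · s(θ + ε)) with s(·) the unit vector at angle θ in the
plane orthogonal to (1,1,1), modulation depth a = 0.5, angular jitter
ε ~ N(0, 6°) and log-normal magnitude m (σ_log = 0.2). Centred triplet
vectors lie along s(θ), so the cross-correlation of two triplets is
exactly cos(θ₁ − θ₂): component geometry maps directly to correlation
structure. The `phase-portrait-6` preset places six equal-weight
components 60° apart (adjacent-shape correlation 0.5 < R₀ = 0.75, i.e.
separable) with distinct magnitude scales (1.5–4 ms). The 6° jitter
keeps within-component correlations ≈ 1 while leaving a vanishing
(≈ 4 σ) probability of cross-component confusion — so recovery of
exactly six clusters at ≥ 90% purity is the designed behaviour, and
failures would indicate an algorithmic regression, not sampling bad
luck. These mixture parameters are generator design choices that define
the package's reference test conditions; they are not measured
constants.

## Problem sizes and numerical conventions

Test and acceptance runs use 1,000 triplets per clustering run, 5,000
events per gating round trip and 10⁴ samples per Monte-Carlo mean;
these sizes put sampling error well below the asserted tolerances while
keeping a full run in seconds. The round-trip test imposes a 0.5 ms
(5-sample) resolution on both the reference and the reconstructed
series before comparing, because exponential sojourn distributions
place positive mass below any sampling interval and the trace
synthesizer requires dwells of at least one sample. All random draws
flow from explicit per-call seeds (`numpy.random.default_rng`); no
global random state is touched. Correlations are clipped to [−1, 1]
against rounding; a triplet counts as flat when its centred norm is
below 10⁻¹² relative to its magnitude.

## Known limitations

- Thresholding assumes one conducting level and a roughly symmetric
  noise split; heavily filtered short events bias durations (classical
  missed-event problem) and only the dead-time merge addresses it.
- The KS single-exponentiality check ignores the estimated-mean
  correction, making R₀ selection mildly conservative.
- The total-differential dispersion error is first-order and ignores
  tour switching under perturbation.
- The optimal-assignment cluster matching is a pragmatic convention;
  biological identity of clusters across conditions is an
  interpretation, not a computed fact.
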