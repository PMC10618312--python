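# dwellphase

Phase-space analysis of ion-channel conformational dynamics from
single-channel patch-clamp recordings.

A gating channel switches stochastically between open (O) and closed (C)
conformations. A thresholded current recording yields the *dwell-time
series* — the durations τ of the successive sojourns in each functional
state. Beyond the classical macroscopic summaries (open-state
probability p_op, mean dwell-times), the *sequence* of dwell-times
carries information about the hidden substate structure: energetically
favourable substates recur, so short subsequences of dwell-times repeat
with similar temporal shapes. `dwellphase` extracts and analyses this
repetitive structure. It is aimed at electrophysiologists and
biophysicists comparing channel gating across pharmacological
conditions (e.g. flavonoid modulators of mitochondrial BK channels).

## Method

**Triplets and cross-correlation.** The dwell-time series is cut into
overlapping 3-element subsequences starting and ending in the same
state (O–C–O and C–O–C triplets). Two triplets X, Y are compared by the
Pearson cross-correlation

    R_XY = Σ (X_t − X̄)(Y_t − Ȳ) / sqrt( Σ (X_t − X̄)² · Σ (Y_t − Ȳ)² ),

which measures shared temporal shape independently of scale.

**Clustering.** Triplets are sorted by the descending product
τ₁·τ₂·τ₃; the first unassigned triplet seeds a *comparative sequence*
and every later triplet with R ≥ R₀ to the running comparative sequence
is absorbed (the comparative sequence is the running cardinality-weighted
mean of its members); passes repeat until all triplets are grouped.
A reassignment-optimization stage then moves any member whose
correlation with its set's comparative sequence has fallen below R₀ to
the best matching set (or a new one) until a fixed point is reached.
The working threshold R₀ = 0.75 is selected as the largest value for
which the per-coordinate dwell-time populations inside the sets remain
single-exponential (one-sample Kolmogorov–Smirnov).

**Phase space.** Each cluster is drawn at its mean dwell-time vector
(τ₁, τ₂, τ₃) with marker diameter proportional to its occupancy.
Conditions are compared through optimal cluster matching, per-cluster
displacements Δτ and their Mann–Whitney U tests, translation to a
common control, and the dispersion statistic

    ⟨dist_τ⟩ = (minimal closed tour through all cluster centers) / (number of clusters),

with an uncertainty propagated from the cluster-center standard errors
by the total-differential rule.

**Energetics.** Under Kramers escape-rate theory, r = D/(2π k_B T) ·
sqrt(U″(a)U″(b)) · exp(−(U(b)−U(a))/k_B T), and with well/barrier
curvatures unchanged by a modulator, a dwell-time ratio maps to a
barrier-height change Δ(U(b)−U(a)) = k_B T · ln(τ_condition/τ_control).

**Synthetic data.** An aggregated-Markov generator (multi-state schemes
with exponential sojourns, same-class sojourns merged in the
observable), a two-level trace synthesizer (sampling, 4-pole low-pass,
Gaussian noise), and a labelled triplet-mixture generator with
controllable cluster structure provide ground-truthed inputs for every
stage.

## Worked example

```python
import numpy as np
import dwellphase as dp

# 1. simulate gating and measure the open probability
model = dp.preset("table1-que-10uM")
sim = dp.simulate_gating(model, n_events=10_000, seed=7)
print(f"analytic p_op = {dp.stationary_open_probability(model):.3f}, "
      f"empirical p_op = {dp.open_probability(sim.series):.3f}")

# 2. cluster O-C-O triplets from a six-component shape mixture
mix = dp.preset("phase-portrait-6")
triplets, labels = dp.generate_triplet_mixture(mix, 1000, seed=42)
cs = dp.cluster_triplets(triplets, r0=0.75)
print(f"{len(cs.clusters)} clusters; occupancies:",
      np.round(cs.occupancies(), 3))

# 3. dispersion of the cluster set
disp = dp.dispersion(cs)
print(f"<dist_tau> = {disp.value:.3f} +/- {disp.error:.3f} ms")

# 4. barrier change for a doubled mean open dwell-time
b = dp.barrier_change(2.0, 1.0)
print(f"delta barrier = {b.delta_kbt:.4f} k_BT")
```

prints

```
analytic p_op = 0.850, empirical p_op = 0.850
6 clusters; occupancies: [0.188 0.168 0.165 0.164 0.158 0.157]
<dist_tau> = 2.682 +/- 0.100 ms
delta barrier = 0.6931 k_BT
```

The `table1-que-10uM` preset is a two-state scheme whose stationary
open probability equals the measured value for the 10 µM quercetin
condition; the simulated recording reproduces it. The six-component
triplet mixture is recovered as exactly six clusters of near-equal
occupancy at R₀ = 0.75; ⟨dist_τ⟩ summarizes how spread out those
clusters are in dwell-time space; and doubling a dwell-time corresponds
to raising the escape barrier by ln 2 ≈ 0.69 k_BT.

A command-line interface mirrors the library:

```sh
dwellphase simulate --preset fig2-9state --n-events 20000 --seed 42 \
    --output dwells.csv --trace trace.csv --noise-sd 0.5
dwellphase idealize --input trace.csv --output ideal.csv
dwellphase cluster --dwells ideal.csv --kind both --r0 0.75 --output clusters.json
dwellphase phase --clusters cond.json --control ctrl.json --output summary.json
dwellphase energy --clusters cond.json --control ctrl.json --output energy.json
dwellphase plot --clusters clusters_oco.json --out phase.png
```

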