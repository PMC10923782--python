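# Methods

## Scope

`optoctrl` is a desk-scale, fully in-silico implementation of deep model
predictive control of optogenetic gene expression in single cells. The
package contains the complete control stack — data model, forecaster,
baselines, strategy search, receding-horizon loop, and error analytics —
plus a stochastic simulator that replaces the microscope/microfluidics
plant. Everything below is computed by the package's own tests and
acceptance script; no empirical claim here goes beyond what those runs
measure.

## The simulated plant

The simulator is deliberately minimal: the smallest stochastic model that
reproduces the phenomenology a forecaster must cope with in a
mother-machine optogenetics experiment. Per cell:

- **Promoter activation** a ∈ [0, 1]:
  da/dt = k_on·u·(1−a) − k_off·(1−u)·a, with u the binary light input.
  Defaults k_on = 0.2 min⁻¹, k_off = 0.1 min⁻¹ give minutes-scale
  activation, matching green/red two-component switching.
- **Production noise** η: an Ornstein–Uhlenbeck process (σ_η = 0.3,
  τ = 30 min) entering as a clipped multiplier max(0, 1+η) on the
  production rate — a cheap, continuous stand-in for bursty expression.
- **Fluorophore concentration** g:
  dg/dt = β_cell·β₀·(leak + (1−leak)·a)·max(0, 1+η) − (γ_m + µ)·g.
  Loss is dominated by growth dilution µ (stable reporter), with
  γ_m = 0.01 min⁻¹ maturation/degradation. β₀ = 85 a.u./min and
  leak = 0.06 set the off state near 150 a.u. and the full-green steady
  state near 2500 a.u., bracketing the 800–1800 a.u. objective band used
  in control studies.
- **Growth and division**: area grows exponentially at
  µ = µ_cell·µ₀·exp(−k_age·age)/60 (µ₀ = 1.4 h⁻¹, aging decay
  k_age = 0.02 h⁻¹); crossing A_div = 3 µm² halves the area and leaves
  the concentration unchanged. Area is reported in pixels
  (1 px = 0.0044 µm²).
- **Heterogeneity**: per-cell multipliers β_cell, µ_cell are log-normal
  with median 1 and CV 0.2.
- **Rare events**: per-5-min death probability 5·10⁻⁴ (freezes area,
  decays g at γ_m), filamentation probability 10⁻³ (suppresses division
  for an exponential duration, mean 2 h), sharpness-glitch probability
  0.01. These create the hard-to-predict outliers that dominate the upper
  error percentiles.
- **Measurement**: 5-min sampling; fluorescence read with 5% relative
  Gaussian noise; chamber mean/SD channels are mother-derived surrogates
  (mother ± 5% noise, SD proportional to mean) since daughters are not
  tracked individually.

Integration is Euler–Maruyama with dt = 0.5 min substeps (area updates use
the exact exponential). Tests verify first-order convergence against a
10× finer reference and the closed-form steady states and decays.

What the simulator does **not** emulate: real segmentation artifacts and
their correlation structure, daughter-lineage statistics, drug response,
spatial effects, and any quantitative match to real *E. coli* rate
constants. Passing tests therefore demonstrate that the control stack
works against a plant with the right qualitative structure — not that the
specific error magnitudes transfer to live cells.

## Forecaster

Two stacked LSTM layers (64 then 16 units) consume the normalized 8×P past
block (P ∈ [36, 144] timepoints, i.e. 3–12 h). The 32-d latent vector is
the concatenation of the second layer's final hidden and cell states
(16 + 16); this is the natural fixed-size summary exposed by a recurrent
layer and matches both the stated layer sizes and latent dimension. The
decoder is an MLP with 5 hidden layers of 32 rectified-linear units and a
linear output of H units (H = 12·L for an L-hour horizon). Training:
mean squared error, Adam at 10⁻³, samples drawn by picking a random cell,
a random past length P and a random split index; batches are bucketed at a
single P so the recurrent layers never see padding.

The layers (LSTM with full backpropagation through time, dense stack,
Adam) are implemented in NumPy inside the package with float32 weights;
gradients are unit-tested against finite differences in float64. All
randomness flows from one `numpy.random.Generator` seed, so training is
bit-reproducible.

**Normalization**: per-channel robust bounds (0.1/99.9 percentiles of the
training corpus) rather than raw min/max, so glitch spikes do not compress
the usable range; binary channels are pinned to (0, 1); a degenerate
constant channel maps to 0. The fitted bounds are persisted with the model
and reused verbatim at control time.

**Training profiles.** The full recipe (hundreds of epochs of 200 × 100
batches) is available as the `evaluation`/`final` presets but is not used
in the test suite. The package's desk-scale study conditions are:

- reference model: 100 epochs × 50 steps × batch 64 on 500 simulated
  cells (~320k samples). Chosen because validation error against the
  persistence floor was still improving markedly between 50 and 100
  epochs and saturated thereafter for the 1-h horizon;
- horizon family (1–4 h): 30 × 50 × 64 each;
- ablation trio: 15 × 30 × 64 each.

## Baselines

**Linear regression**: one linear map from the flattened most-recent
8 × 36 past window plus the H future light bits to the H future
fluorescence values, fitted by (lightly ridge-regularized) least squares.
The 36-point window is the minimum past any sample is guaranteed to have,
so every sample is usable without padding.

**ODE + hybrid Kalman filter**: the classic two-state light-switched
model da/dt = k_a·u − k_d·a, dp/dt = β·a − γ·p. Design choices:

- *Identifiability*: only the product β·k_a is identifiable from
  input/output data (a is latent up to scale), so fitting constrains
  k_a = k_d, normalizing a to [0, 1] with steady state u. Rates are
  bounded above by 1 min⁻¹ — faster kinetics are indistinguishable at
  5-min sampling and would otherwise drive a degenerate instantaneous fit.
- *Basal offset*: the plant has a leaky nonzero floor, while the two-state
  ODE decays to zero. A fitted offset parameter makes the dynamics act on
  the fluorescence above that floor; without it the baseline carries a
  systematic bias at low expression.
- *Filtering*: between measurements, mean and covariance propagate in
  closed form through the continuous LTI system (matrix exponential /
  van Loan discretization — exact, not approximate); each 5-min
  measurement of p triggers a standard discrete update. Noise intensities
  (q_a, q_p, r) are selected on the fitting traces by multi-step
  predictive error; q_a is what lets the filter absorb per-cell
  production differences into its activation estimate.

Both baselines expose the same `encode` / `predict_candidates` surface as
the deep model, so the controller is predictor-agnostic.

## Control

Canonical binary particle swarm optimization: velocities
v ← w·v + c₁r₁(pbest−x) + c₂r₂(gbest−x), clamped to ±v_max, per-bit
sampling probability logistic(v). Hyperparameters w = 0.7,
c₁ = c₂ = 1.5, v_max = 4, positions initialized Bernoulli(0.5) —
standard Kennedy–Eberhart values, exposed in `ControlConfig`. The budget
is exactly 40 particles × 25 iterations = 1000 cost evaluations per cell
per step; on the 4096-strategy 1-h space the swarm recovers the exhaustive
optimum in ≥95/100 seeded runs and matches it to ≤1% median cost gap on
trained-decoder costs.

The receding-horizon step encodes the past once (pasts capped at the 144
most recent points, the training maximum), plans with the decoder as a
batched cost oracle, applies the first bit, and re-plans cold at the next
measurement (no warm-starting — the measured swarm quality makes carrying
state across steps unnecessary). Ties between equal-cost strategies break
toward the lowest integer encoding. If a predictor fails mid-campaign the
previous bit is repeated and flagged. Objective segments shorter than the
horizon are padded by holding the last value; campaign objective tracks
are generated one horizon longer than the experiment so this padding only
triggers for genuinely short tracks (edge-held targets measurably degrade
long-horizon planning).

The batch planner vectorizes both the encoder (all cells share one
recurrent pass in closed loop, where pasts have equal length) and each
swarm iteration (all cells × particles in one decoder call).

## Error analytics

RMSE_time(n) and RMSE_cells(t) follow the standard definitions with
pairwise NaN deletion (never imputation). Growth is
(area(t+1) − area(t))/area(t) per 5-min interval, divided by 1/12 h to
report h⁻¹; the artifact filters set area to NaN below 0.44 µm² or below
100 a.u. fluorescence, and growth values below −2.4 h⁻¹ (division steps,
−6 h⁻¹ for a clean halving) to NaN — positions are preserved, never
dropped. The filters are applied to raw growth; smoothing (13-point
median for the one-hour window, or a Savitzky–Golay filter of length 15
and order 2 realized as a NaN-aware local quadratic fit with shrinking
edge windows) is applied afterwards for display and for the
growing/dying partition at the 0.3 h⁻¹ threshold. Conditioned error
tables bin per-(cell, timepoint) errors by objective value (linear bins),
objective time-derivative (signed-log bins, since derivatives span both
signs across orders of magnitude), or growth percentile (percentiles
1–100).

## Findings specific to the simulated conditions

These are desk-scale observations the test suite asserts; they qualify
how far the in-silico results mirror the full-scale experiment:

- **Ablations**: the chamber-mean channel is, by construction, a noisy
  copy of mother fluorescence, so masking mother fluorescence *alone* is
  nearly free and the effect is below training noise at these model
  sizes. The tested ablation tiers are therefore full features →
  fluorescence-blind (both fluorescence channels masked) → all channels
  masked, which degrade in that order. The all-masked model does *not*
  fall to the unconditional-mean error level: with random-walk
  stimulation design the future light bits correlate with the cell's
  recent state, so a model seeing only future stimulations retains real
  skill. The tests assert the collapse as ≥1.5× the full-model error and
  bounded by the unconditional-mean error.
- **Horizon robustness**: with equally-but-partially-trained models, the
  closed-loop tracking error grows with the planning horizon (the 4-h
  controller's median is ~1.5–2× the 1-h controller's) because
  far-future prediction error dilutes the first-bit decision; a 4×
  search budget changes this by ~2%, ruling out the optimizer. The same
  effect appears in open loop: RMSE_cells(t) of the 1-h and 2-h models
  differ by up to ~45% at matched early timepoints. Horizon equivalence
  is a property of near-fully-trained forecasters and is not reproduced
  at the desk-scale training profiles; the corresponding test documents
  and asserts the full-scale property and is expected to fail at these
  problem sizes.
- The forecaster accuracy ordering deep < ODE+Kalman < linear, the
  deep-vs-persistence margin, the 1.5-h truncation plateau, and the
  ≤0.5× closed-loop-vs-random tracking ratio all hold at the stated
  profiles.

## Numerical choices and degenerate inputs

- Euler–Maruyama substep 0.5 min (first-order; tested against a refined
  step); area updated with the exact exponential so doubling times are
  exact.
- Normalizer: constant channels map to 0; out-of-range values clip.
- Kalman covariance is re-symmetrized each step and eigenvalue-floored at
  zero if roundoff pushes it off the PSD cone (logged).
- Exhaustive search refuses horizons above 16 bits; it is an oracle, not
  a production path.
- Sample extraction raises a skip signal for traces shorter than
  36 + H points; callers resample.
- Seeds: every public entry point takes an explicit seed or Generator;
  experiment records are reproducible from their config snapshot alone.

## Known limitations

- The plant is invented plumbing: quantitative mismatches with real
  *E. coli* optogenetics are by design, and nothing here was fitted to
  published single-cell data.
- Chamber statistics are mother-derived surrogates; models that exploit
  genuine daughter-cell information cannot be studied with this
  simulator.
- Training at the paper-scale recipe (≈4M samples per model) is
  supported by the presets but takes ~an hour per model on one CPU in
  NumPy; all shipped results use the scaled profiles above.
- No prediction-uncertainty estimation, no on-line retraining, no
  continuous-intensity actuation.
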