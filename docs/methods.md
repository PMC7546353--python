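# Methods

This note records the models, numerical choices and known limitations of
`impactkin`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and conventions

A head impact is 100 ms of 6-DoF kinematics at 1 kHz (m = 100 samples):
linear acceleration in m/s² (anterior–posterior, inferior–superior,
lateral; indices 0/1/2) and angular velocity in rad/s (coronal, sagittal,
axial; indices 0/1/2). Time is 0-based seconds on a uniform grid.
Angular acceleration is a derived quantity: first-order forward divided
differences, `α[i] = (ω[i+1] − ω[i])·fs`, with the last value replicated so
all QoIs share the m×n data-matrix shape. The matched inverse (cumulative
rectangle rule) reproduces ω − ω[0] exactly, which the tests exploit as an
oracle. Approximation data sets that reduce angular acceleration as its own
QoI carry it as an explicit channel (`gx,gy,gz` columns in the trace files);
`derive_angular_acceleration` returns the stored channel when present.

On disk a data set is one CSV per impact (`t,ax,ay,az,wx,wy,wz[,gx,gy,gz]`)
plus a JSON manifest; floats are written at `repr` precision so the round
trip is bit-exact.

## Dimension reduction

Each QoI/direction matrix is factored by an economy SVD without mean
centering — the first mode then absorbs the mean impact shape — with an
opt-in `center=True` for exploration. Mode count selection uses the
**first-power** singular-value fraction η(k) (not the squared-energy
variant; that is deliberate and matches how the reduction criterion is
conventionally quoted for this problem; a squared variant would saturate
faster). `min_modes` uses the inclusive rule: smallest k with η(k) ≥ target,
so σ = (9, 1) at target 0.90 gives k = 1.

Determinism: each temporal mode is sign-flipped so its largest-magnitude
element is positive (scores flipped accordingly), making repeated
decompositions bit-identical. Truncation error is checked against the
Eckart–Young closed form √(Σ_{i>k} σᵢ²) for every k.

The convergence analysis redraws record subsets without replacement
(seeded per size/repeat via `SeedSequence` spawning) and reports the
minimal mode count per subset size; the acceptance run uses sizes
100…500 with 21 repeats so the medians are stable.

## Stochastic emulator

`fit_emulator` keeps the k leading modes and the empirical mean/sd of each
score vector; `emulate` draws scores independently per mode and column from
the matching Gaussians. In-sample SVD scores are exactly uncorrelated, so
independent marginals are the minimal faithful sampling law; no joint
copula is fitted. A bootstrap option (`scores="empirical"`) resamples
observed scores per mode for visibly non-Gaussian data. Feeding the
empirical scores back through the emulator reproduces the rank-k
reconstruction exactly (tested to 1e-12).

Emulated populations are validated against a reference by two-sample
Kolmogorov–Smirnov tests (α = 0.01 by default) on per-record peak
magnitude, peak time, and pulse duration, plus projections of the leading
reference modes onto both populations. Pulse duration is measured with the
same boundary-detection rule used for the biphasic fits, applied to the
acceleration-like signal (angular-velocity columns are forward-differenced
first).

**Limitation (visible as one deliberately red end-to-end test).** The
independent-Gaussian score law reproduces nonlinear waveform functionals
(peaks, fitted durations) only when the data itself is close to a low-rank
Gaussian process — the regime reported for on-field measurements, and the
regime in which the companion test on Gaussian-score low-rank data passes
every feature. The realistic synthetic stand-in below is deliberately a
*nonlinearly parameterized* pulse family (random onset, carrier, damping,
log-normal amplitude); its modal scores are strongly non-Gaussian and
cross-mode dependent, and at the η ≥ 0.90 truncation even the deterministic
rank-k reconstruction does not preserve fitted pulse durations (the onset
kink that defines them is a high-order feature). Consequently the
feature-KS check on the stand-in fails for peak magnitude, peak time and
pulse duration, while the second-order check — emulated column covariance
against U_k diag(σᵢ²·sdᵢ²) U_kᵀ, within 5% Frobenius at n = 10⁴ — passes.
Passing tests on the stand-in therefore demonstrate second-order and
machinery correctness; they do not demonstrate feature-level fidelity on
data outside the Gaussian-score class.

## Biphasic pulse parameterization

Peak at the maximum absolute acceleration; boundaries t₀/t₁ where the
trace's sign or its convexity (3-point central second difference) first
changes while scanning outward; Δω by trapezoidal quadrature over
[t₀, t₁]; amplitudes α_tri = 2Δω/Δt and α_hs = (π/2)·Δω/Δt. Both shapes,
and their one-sided halves (ramp / quarter-wave, used when the peak sits
within one sample of a record edge), integrate exactly to Δω.

Numerical choices:

* a change is flagged between a pair of consecutive samples; the boundary
  is the pair's lower-index sample (last pre-pulse sample on the left,
  last in-pulse sample on the right) — with continuously distributed true
  boundaries this makes the duration estimator unbiased;
* "whichever comes first" is resolved per pair during one outward scan, so
  a simultaneous sign and convexity change is the same sample; zeros count
  as a sign change; convexity requires a strict flip, and second
  differences below 1e-9 of the trace's peak are snapped to zero so
  floating-point residue on straight segments is not a convexity change;
* the scan excludes the peak sample itself; if no change occurs before the
  record edge the boundary is clamped there and the window flagged
  (`clamped=True`) rather than guessed;
* Δω uses trapezoid quadrature (a rectangle-rule variant is not offered;
  the integration pairs with the trapezoidal synthesis checks).

Velocity traces of a biphasic data set come from direct temporal
integration of the synthesized acceleration pulse from rest; lacking any
restitutive deceleration they plateau at Δω, which is the mechanism behind
the baseline's characteristic metric biases.

## Injury metrics

* **HIC₁₅ / RIC₃₆** — maximum over all sample-aligned windows (≤ 15 ms /
  ≤ 36 ms) of `(t₂−t₁)·[mean resultant acceleration]^2.5`, with linear
  acceleration in g (g = 9.80665 m/s²) and angular acceleration in rad/s².
  Window endpoints are sample instants, integrals trapezoidal, minimum
  window one sample step; the implementation is O(m·w) over cumulative
  integrals and is tested against an O(m²) brute-force search.
* **BrIC** — √Σ_d (max_t |ω_d| / ω_crit,d)², per-axis peaks taken
  independently; default criticals (66.25, 56.45, 42.87) rad/s for
  coronal/sagittal/axial, from the metric's standard automotive
  calibration; all criticals configurable.
* **BAM** — per-axis base-excitation oscillator
  `θ̈ = −α(t) − (c/I)θ̇ − (k/I)θ` integrated from rest by fixed-step RK4 at
  the sample step divided by `substeps` (default 4), forcing linearly
  interpolated at half steps; the metric is the maximum over time of
  ‖(θ_cor, θ_sag, θ_ax)‖. Published lumped-model calibrations vary, so
  inertia/stiffness/damping are **required** configuration with no silent
  defaults; tests and the acceptance script use a documented synthetic
  plausible-scale set (I = 0.016 kg·m², k = 142 N·m/rad → ≈15 Hz natural
  frequency, c = 0.9 N·m·s/rad). RK4 is conditionally stable: the stiff
  rigid-coupling check (k × 10⁶) uses substeps sized to the natural
  frequency, and a diverging integration raises with diagnostics instead
  of returning numbers.
* **Accuracy harness** — percent error |approx − gt|/|gt|·100 (zero-GT
  records excluded and counted), a directly implemented Friedman test
  (within-record mid-ranks, standard tie correction, χ² with k−1 df;
  cross-checked against an independent statistical implementation to
  1e-8; fully tied input warns and returns (0, 1)), and
  sensitivity/specificity at the published 50%-risk thresholds
  HIC 240/667, RIC 10.3×10⁶, BrIC 0.5 (all overridable). Strain-based
  thresholds (MPS/FS) can be supplied to `classify_and_confuse` by users
  who bring their own strain values; no strain computation is provided.

## Spectral analysis

100-sample modes at 1 kHz have 10 Hz raw resolution; dominant frequencies
use a rectangular-window periodogram zero-padded to 1024 points (Welch
available behind a flag). The two-sided spectrum's non-negative half is
used so the one-sided factor-2 scaling cannot let leakage sidelobes
outweigh the DC bin for near-constant modes. Band contributions weight
modes by first-power σᵢ — the same weighting as η(k) — over half-open
bands [lo, hi), so contributions over a disjoint partition of [0, Nyquist]
sum to one.

## Synthetic ground truth

`generate_impact_dataset` emulates processed on-field recordings: per
channel one damped-sinusoid pulse `A·e^{−λ(t−t_on)}·sin(2πf(t−t_on))`,
zero before onset. Angular velocity is the running integral of the pulse
(starts at rest, plateaus with decaying ringing; a `decay` mode returns to
zero instead), linear acceleration is the pulse itself. Defaults define
the study conditions and are not tuned per experiment:

* **Peak angular velocity**: log-normal, medians (5.75, 10.4, 5.4) rad/s
  for coronal/sagittal/axial, shape 0.8 — derived from published
  per-direction angular-acceleration magnitudes and durations via
  Δω ≈ (2/π)·α·Δt with the mean→median conversion for that shape.
* **Peak linear acceleration**: log-normal, medians (200, 170, 148) m/s²,
  shape 0.8. The published per-direction linear means are internally
  inconsistent with the published HIC₁₅ distribution; the medians keep the
  reported AP:IS:LAT ratio at the scale (~20 g) that reproduces the
  reported HIC regime, so the concussion/fracture thresholds are actually
  exercised.
* **Pulse duration**: log-normal parameterized by its mean (15 ms) and sd
  (7 ms), matching reported duration statistics; the carrier frequency is
  solved per draw so the first acceleration lobe — up to the convexity
  flip of the damped sinusoid, φ = atan2(2λω, ω²−λ²) — lasts the drawn
  duration, then clipped to the 10–100 Hz carrier range. The solve targets
  the drawn duration plus 1.35 samples, cancelling two discretization
  offsets of the downstream fitting rule (the onset-kink convexity flip
  ~1 sample inside t₀ and the forward-difference midpoint shift at t₁), so
  the fitted-duration mean matches the configured one.
* **Onset**: uniform in [10, 40] ms (edge presets force the peak against
  either record edge to exercise the half-pulse rule); **damping** uniform
  in [20, 60] s⁻¹, capped per draw at 1.2/duration to keep the lobe
  equation solvable.
* **Noise**: `noise_sd` defaults to 0 — the emulated inputs are
  post-processed (filtered) recordings, and broadband noise makes the
  strict sign/convexity boundary rule walk randomly through the noise
  floor; nonzero noise is supported and tested.
* **Randomness**: one integer seed, split per record via `SeedSequence`
  spawning; identical config + seed is bit-identical.

What the generator does **not** emulate: cross-channel correlation
(directions are treated as separate QoIs), helmet/neck dynamics,
sport-specific direction statistics, multi-pulse impacts, and — by
construction — the Gaussian-score structure of real on-field ensembles
(see the emulator limitation above). Passing tests on this stand-in
validate the algorithms and their contracts, not claims about real data.

`generate_lowrank_matrix` builds Σσᵢuᵢyᵢᵀ from QR-orthonormalized Gaussian
factors: exact rank, prescribed spectrum, Gaussian-sphere scores — the
oracle for decomposition, mode counting and emulator-fidelity tests.

## Problem sizes

Tests and the acceptance script use the full n = 537 analog for pipeline
runs, n = 10⁴ for Monte-Carlo covariance checks, 21 repeats for the
convergence medians, and n = 60 for structural unit tests — sizes chosen
to keep the statistical checks well-powered while the whole suite runs in
a few minutes on one CPU.
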