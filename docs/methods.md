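# Methods

This note documents the models, estimators, and design choices behind
`sdleeg`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Signal model and preprocessing

Epochs are 19-channel, 256 Hz, 4 s (1024-sample) scalp EEG segments in µV
(10–20 montage, earlobe reference assumed already applied). The clinical
acquisition chain — 0.1–70 Hz analog bandwidth plus a 50 Hz mains notch —
is reproduced digitally: per channel, the mean is removed and the *squared
magnitude response* of a 4th-order Butterworth band-pass and a Q≈30 notch
(i.e., the steady-state zero-phase forward–backward response) is applied in
the frequency domain. A time-domain forward–backward IIR pass was rejected:
on a 4 s epoch the 0.1 Hz edge and the narrow notch have transients longer
than the epoch itself, which corrupt both band energies and the phase-space
geometry. The spectral application has the identical transfer function and
no transient; its cost is the implicit periodic extension of the epoch,
negligible for signals with mean removed.

"Strongest channels" (both the PSD and SDLE stages use the 10 strongest of
19) means largest per-channel variance of the filtered epoch — signal
energy after DC removal — with deterministic ties broken by channel name.
Strength is judged per epoch.

## PSD feature

Single 4 s epochs are too short for averaged-segment spectral estimation,
so the PSD is a one-sided single-segment periodogram with a Hann taper,
renormalized so that its integral over frequency equals the channel
variance exactly (Parseval; band energies thus carry µV² units regardless
of taper). The classification feature is the trapezoidal integral over
0.5–25 Hz, averaged over the selected channels. Conventional clinical
bands (delta 0.5–3, theta 4–7, alpha 8–13, beta 14–30, gamma >30 Hz) are
available as auxiliary outputs.

## Phase-space reconstruction and embedding selection

Delay embedding `V_i = [x(i), x(i+L), …, x(i+(m−1)L)]` with defaults
m = 2, L = 1 at 256 Hz. Automatic selection follows the
divergence-minimization idea: embed with each candidate, collect vector
pairs whose initial separation lies in a broad band (0.1–0.4 of the signal
SD, scaled by √(m/2) so random-pair distances are comparable across
dimensions), evolve them, and summarize the mean log-separation growth
over the first `min(dominant period, 32)` samples.

- **Delay**: the candidate minimizing the *magnitude* of the summary wins
  (uniform motion neither diverges nor converges at short times; for a
  sinusoid this recovers L = period/4, where the embedded ellipse becomes
  a circle). Candidates within 5% of the minimum are tied and the smallest
  delay is taken, so i.i.d. noise — equal scores up to sampling error —
  selects the smallest candidate.
- **Dimension**: the smallest m whose score is near-minimal across
  candidates (5% relative, or 0.01 nats absolute for the degenerate case
  where noise-free periodic signals drive scores to zero). Past
  sufficiency, extra dimensions leave the divergence essentially
  unchanged.

Two details matter numerically. A *broad* band is used instead of a thin
estimation shell because commensurately sampled periodic signals quantize
pair distances and can leave a thin shell empty. And the pair ensemble is
pre-filtered to pairs that survive the whole evolution window: pairs
dropping out at late times would otherwise shift the average without any
actual divergence.

## SDLE estimation

Per channel:

1. **Shells.** Four distance shells; shell k has inner diameter
   0.1 · SD(x) · 2⁻ᵏ and equal thickness (one-octave shells, so the ×½
   cascade tiles the scale axis contiguously). An ε = 0 ball variant for
   the smallest shell is available but off by default. Shells scale with
   the signal SD, making the estimator amplitude-equivariant: scaling the
   input by k shifts SDLE curves by ln k in abscissa and leaves λ
   unchanged (property-tested).
2. **Pairs.** All (i, j), i < j, with the Euclidean pair distance inside
   the shell and |i − j| > Theiler window (default (m−1)L + 1), in
   deterministic lexicographic order. Shells with fewer than 10 pairs are
   dropped (logged). For speed, pair lists are capped at 200 per shell by
   deterministic evenly-spaced thinning — the growth curve is a mean over
   pairs, and 200 log-distances estimate it amply; the cap is a
   configuration knob (`max_pairs`, set to `None` for exhaustive pairs, as
   the oracle-equivalence tests do).
3. **Growth and differencing.** ln ε_t is the mean (log before average)
   of evolved pair separations at t = 0…64 samples, Δt = 1; pairs whose
   evolved indices run off the trajectory are dropped at each t, with
   surviving counts recorded. λ = Δ ln ε_t / Δt is attached to the
   abscissa ln ε_t; the finite differences telescope, so cumulative λ·Δt
   reproduces ln ε_t − ln ε₀ exactly, and integrating λ to the first
   crossing of 2ε₀ returns ln 2 up to interpolation (both property-tested).
4. **Averaging.** The four per-shell SDLE curves are interpolated onto the
   union of their abscissae clipped to the common overlap and averaged
   (plain arithmetic mean by default; pair-count weighting available).
   The 10 per-channel curves are then averaged the same way on an 80-point
   uniform grid (a fixed-size grid keeps the subsequent window scan
   O(80²) instead of growing with the union of ~2500 channel abscissae).

**Scaling fit.** λ = −γ ln ε + c is fitted by least squares over the
longest contiguous window of at least 40% of the curve with r² ≥ 0.95
(ties resolve toward larger scales; an all-flat window counts as r² = 1;
if nothing qualifies the full curve is fitted and flagged `degraded`).
γ is reported as the slope magnitude.

**Features.** ε₁ and ε₃ are the region's smallest and boundary scales, ε₂
the midpoint in ln ε; λ(ε₁), λ(ε₂), λ(ε₃) are read off the averaged curve
by interpolation and λ̄ is their mean. ε_∞ (attractor size) is the
geometric mean over channels of the largest shell's growth-curve plateau
(mean of its last quarter); the error-doubling time T_db is the mean over
channels of the first 2ε₀ crossing of the smallest usable shell's curve.

## Classification and evaluation

Feature vectors (PSD, λ(ε₁), λ(ε₂), λ(ε₃), λ̄, optional ε_∞, T_db) are
split stratified per class with a per-class test count of
⌈class_n / 3⌉ — which reproduces the canonical 66/34 + 360/180 bookkeeping
of a 100 + 540 dataset — shuffled by a seeded generator. Classifiers are
scikit-learn's RandomForestClassifier (100 trees, unlimited depth, seeded)
and RBF-kernel SVC (C = 1, gamma = "scale"); features are z-scored with
train-split statistics. These defaults are recorded in every report; no
hyperparameter search is performed, since the point of the feature space
is that the classifier choice should not matter. ROC curves sweep the
continuous score (RF vote fraction; SVM margin) over unique thresholds
with ties stepping together; AUC is trapezoidal and equals the
Mann–Whitney statistic (property-tested). Metrics are reported in percent,
rounded to two decimals only at the reporting layer.

**Regularity ratio.** PSD/λ(ε₁) measures signal regularity (large spectral
energy + slow divergence = predictable signal). Epochs with λ(ε₁) ≤ 0 are
flagged and excluded. For the class-overlap analysis, Gaussian KDEs
(Silverman bandwidth widened ×1.5 — mild oversmoothing is bias-free for
locating a crossing between near-symmetric modes and stabilizes it) are
crossed between the class medians; each class's tail mass on the wrong
side of the crossing is estimated by the *empirical* class fraction rather
than the smoothed-density integral, which carries an upward kernel-width
bias of order +1% absolute at n ≈ 2000. On two unit Gaussians 2 SD apart
the estimator is centered on the closed form Φ(−1) ≈ 15.9% per tail with
a single-draw SD of about 0.9% at n = 2000 per class — the residual
variance of one draw, not estimator bias.

## Synthetic data: what it emulates and what it does not

The generator stands in for undeposited clinical recordings.

- **Healthy-control background**: per-channel 1/f^α colored noise
  (α = 1, spectrum flattened below 1 Hz), 50% mixed with a shared source
  (scalp channels are strongly correlated), plus an alpha rhythm at a
  common epoch frequency in 8–13 Hz with per-channel phase jitter;
  channel RMS drawn from 20–60 µV, typical of adult scalp EEG.
- **Discharges**: biphasic difference-of-Gaussians transients (negative
  leading phase), half-sine slow waves. Subtype parameters follow the
  standard clinical definitions — spike 20–70 ms, >50 µV (drawn
  55–150 µV); sharp 70–200 ms, 100–200 µV; *-and-slow-wave complexes with
  the slow wave 1.1–1.6× the transient; polyspike = 2–5 spikes;
  spike rhythm 10–25 Hz at 100–200 µV lasting 1.2–3 s. Durations are
  drawn in samples strictly inside the printed bounds. Templates repeat
  at 2–4 Hz through the epoch (the classic spike-and-wave train picture)
  and are injected on 10–19 of the 19 channels with gains 0.7–1.2, so
  strongest-channel selection predominantly captures discharge-bearing
  channels.
- **Patient-like background for discharge epochs**: 1/f slope 1.6 and RMS
  30–70 µV. Interictal EEG of epilepsy patients shows background slowing
  and stronger synchronization relative to healthy controls; a brief
  transient alone barely moves either whole-epoch feature, and treating
  the class difference as purely additive would misrepresent the clinical
  contrast, which is between patient recordings and healthy-control
  recordings.
- **Class balance**: 100 normal / 540 epileptiform, subtype counts
  69/82/174/72/64/77/2.

Not emulated: eye-blink/EMG/ECG artifacts, electrode drift, dipole
forward-modeled topographies, inter-subject variability beyond the drawn
parameter ranges, and multi-label epochs (each synthetic discharge epoch
carries one subtype). Classification results on this generator therefore
demonstrate that the feature pipeline separates regular high-energy
discharge activity from irregular background under realistic amplitudes
and class imbalance — not that clinical-grade accuracy transfers to real
recordings with artifacts.

## Problem sizes and numerical choices

Default estimation sizes: 1023 phase points per channel, ≤200 pairs per
shell, 64-step evolution, 80-point common grid — about 0.2–0.3 s per epoch,
so the full 640-epoch benchmark runs in a few minutes on one core. Log of
zero distances is floored at the smallest positive double (identical
evolved vectors are astronomically unlikely for continuous data but must
not produce −inf). Degenerate inputs raise typed errors: constant series
(shells cannot be sized), too-short series (embedding names the required
minimum), empty shells (estimation error carrying the shell bounds).
Curve points with duplicated abscissae after the growth→SDLE differencing
are merged by averaging so interpolation grids stay strictly increasing.

## Known limitations

- The scaling-region search is a window scan with an r² threshold; curves
  that are nowhere locally linear fall back to a flagged full-curve fit
  rather than failing.
- ε_∞ assumes the largest-shell curve actually plateaus within the 64-step
  window; for strongly nonstationary epochs the plateau estimate is an
  underestimate of attractor size.
- The three-parameter variant (PSD, λ̄, ε_∞) is exposed through the feature
  table (`eps_inf` column and custom feature sets) but deliberately not
  tuned or benchmarked.
- EDF writing covers plain 16-bit EDF only (no EDF+ annotations); reading
  accepts both and ignores annotation channels.
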