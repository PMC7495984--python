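# Methods

This note documents the models, the parameter choices, the synthetic-data
design, and the numerical decisions behind `eeggc`, in the spirit of a
methods appendix.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model and estimators

**Preprocessing.**  The pipeline order is fixed: average re-reference →
decimation to 125 Hz → Hjorth spatial filter → 4-s segmentation with 200 µV
rejection → per-segment z-normalization.  Decimation keeps every k-th sample
with *no* anti-alias filter: temporal filtering redistributes information
across time and biases autoregressive coefficient estimates, which matters
more here than aliasing of the (weak) supra-Nyquist content of scalp EEG.  An
`anti_alias=True` flag (zero-phase FIR) exists for sensitivity analyses.  The
aliasing risk of the default is real and documented: high-frequency EMG can
fold into the analysis band, which is one reason for the spatial filter and
the beta-band caution below.

**Hjorth filter.**  Each channel minus the unweighted mean of its three
nearest neighbors (2-D scalp geometry, deterministic name-order tie-break).
Three neighbors rather than the classical four-neighbor Laplacian keeps the
operation well-defined at boundary electrodes on a 31-channel cap.  The
filter exactly cancels signals common to all channels, and it can *spread* a
large artifact into its neighbors at −1/3 amplitude; rejection is therefore
applied after filtering, and a neighbor of an artifact channel may
legitimately also be rejected in the same segment.

**Artifact rejection scope.**  The 200 µV threshold (strictly above; applied
to absolute amplitude) is evaluated per channel per segment, which maximizes
data retention; a `reject_whole_segment` switch drops the entire segment
instead.  Zero-variance blocks cannot be z-normalized and are marked invalid.

**VAR fitting.**  Each unordered channel pair in each valid segment gets one
bivariate VAR(3) fit by the Morf (Vieira–Morf) modified lattice recursion —
the geometric-mean variant of the Levinson–Wiggins–Robinson multichannel
algorithm — computed from forward/backward prediction errors.  One fit serves
both directions.  Model order 3 (24 ms of history at 125 Hz) is the default;
`select_order_bic` reproduces the choice by minimizing mean BIC over sampled
windows (the AIC curve is reported alongside and often lacks an interior
minimum on near-white data).  The lattice is implemented twice: a generic
vectorized numpy version for any channel count, and a compiled (numba)
bivariate kernel used for whole-session scans; the two agree to machine
precision and the equivalence is asserted in the tests.

**Residual gating.**  The Durbin–Watson statistic d = Σ(Δe)²/Σe² is computed
per residual channel and converted to a two-sided p-value with the normal
approximation E[d]=2, Var[d]=4/n; a fit is excluded when any channel has
p < 0.05.  *Known limitation:* on residuals of a well-fitted AR model the
lag-1 autocorrelation is annihilated by the fit itself (the classical
lagged-dependent-variable caveat), so under a correctly specified null the
gate excludes far fewer than the nominal 5% — in our simulations essentially
0%.  The gate's practical role is to discard segments the VAR(3) cannot
whiten (nonstationary or strongly narrowband epochs), not to enforce a
calibrated false-positive rate.  The acceptance suite contains an
intentionally failing check documenting this gap.

**Spectral Granger causality.**  The standard bivariate Geweke decomposition:
with transfer function H(f) and innovation covariance Σ, the intrinsic part
of the target spectrum is isolated by the covariance-normalizing rotation
H̃_xx = H_xx + (Σ_xy/Σ_xx)H_xy, and GC(y→x, f) = ln(S_xx / (Σ_xx |H̃_xx|²)).
This form is validated against a frequency-free oracle: the dense-grid
average of the spectrum equals the time-domain GC obtained from the exact
autocovariance sequence (discrete Lyapunov equation) and a high-order
Levinson–Durbin reduced model, to well under 2%.  Values are clipped at zero
from below (clip events are counted; they arise only from rounding).  No
small-sample bias is subtracted: estimates sit on a positive floor
(≈0.005–0.008 per direction at n = 500, p = 3) that decreases with segment
length, is stable across seeds, and — importantly — *increases* when the
signals are strongly autocorrelated, because slow components reduce the
effective sample count.  Trajectory *shapes* are the object of interest, so
the floor is documented rather than removed.

**Coherence.**  Amplitude-product-weighted phase locking of the analytic
signals after zero-phase (forward–backward) third-order Butterworth
high-/low-pass at f0 ∓/± 0.8 Hz.  The verbal definition "mean phase
difference weighted by power" admits several readings; weighted PLV is used
because it is symmetric, bounded in [0, 1], equals 1 for any constant phase
relation, and is invariant to per-channel amplitude rescaling.  A
cosine-of-mean-difference variant (which distinguishes constant antiphase
from phase inconsistency) and a squared-amplitude weighting are deliberately
out of the default path; all group results use the weighted-PLV reading.
Note the ±0.8 Hz cutoffs put the center frequency inside the filter's
transition band, so the center tone is attenuated (|H(f0)|² ≈ 0.4
forward–backward); this is irrelevant to coherence, which normalizes
amplitudes, but matters if the narrowband signals are reused for power
analyses.  For f0 = 0.5 Hz the lower edge is clamped to 0.05 Hz.  Filtering
runs over the continuous recording before segmentation to avoid edge
transients, and no exclusions are applied to coherence.

**Trajectories.**  Band means (delta 0.5–1 Hz = 2 bins, alpha 8–14 Hz = 7,
beta 21–30 Hz = 10) are smoothed by Nadaraya–Watson regression with a
Gaussian kernel, bandwidth 50 s, with missing values excluded from numerator
and denominator; the estimate is a convex combination of observations, so
constants are preserved and the output is bounded by the input range.
Smoothing is applied to the band means rather than to each of the 31
frequency bins; because invalid fits remove whole spectra, the two orders
commute and the cheaper one is used.  GC series are then normalized per pair
and band to the 95th centile (linear interpolation between order statistics)
of the first 2 min after infusion start; values above 1 mean "more flow than
at the start of the infusion".  Normalizing per pair rather than by one
subject-global divisor makes that statement meaningful pair-wise and the
pipeline exactly scale-free; the subject-global alternative is available via
`scope="subject"`.  A pair whose baseline percentile is zero is flagged and
excluded from group summaries.  Coherence is not normalized.  Group curves
are event-aligned by nearest-segment lookup on a 4-s offset grid (windows
truncated, never padded, for subjects with short post-event coverage) and
summarized by the log-mean across subjects — GC is positively skewed, so the
geometric mean is the appropriate center — with values floored at 1e−12
before the log (floor events counted).

**Pair selection.**  Per category (delta/alpha × LOBR/ROBR for GC), the
aligned group-curve matrix (time offsets × pairs, complete rows only) is
column-centered and decomposed by SVD; PC1 loadings rank the pairs.  The PC1
sign is intrinsically arbitrary, and the obvious fix — require positive
correlation between loadings and per-pair |change| — turns out to be fragile:
when many pairs drift slightly in one direction while a few change strongly
in the other, that correlation hovers near zero and the orientation becomes a
coin toss.  The implemented rule is sharper and carries the same intent: the
orientation is chosen so that the top-5%-loading pairs have the larger mean
|value(+2 min) − value(−2 min)| across the event, with the correlation sign
as tie-break.  Quantile-boundary ties are all included.  GC selections keep
pairs in the top (or bottom) 5% in at least 3 of the 4 categories; beta is
excluded from selection because its changes are small and EMG-prone.
Coherence selections first split pairs by the sign of their change across
LOBR, run the PCA within each sign group and band independently, and require
top-5% membership at both LOBR and ROBR.

## The synthetic-data generator

`simulate_session` produces a piecewise-stationary 31-channel VAR(3) at
250 Hz (decimated to 125 Hz in preprocessing; the pre-decimation rate is a
parameter).  The state vector is continuous across regime switches, so there
are no amplitude discontinuities beyond the injected artifacts.  Defaults
define the study-like conditions and were fixed once:

- **Strong directed edges** (the scored ground truth): 12 edges from lateral
  frontal/prefrontal sources (F7, F8, FC5, FC6, Fp1, Fp2) to 12 distinct
  medial/central targets, lag-1 weight 0.45 plus 0.15 of that at lag 2,
  active only while responsive.  Distinct targets keep any single channel's
  driven power moderate, which in turn keeps the per-channel band-power
  contrasts unambiguous.
- **Weak background network**: 10 feedforward edges (left→right
  interhemispheric mirrors plus two midline links), weight 0.18, also
  collapsing at LOBR.  This gives a substantial fraction of pairs a nonzero
  baseline information flow that disappears with unresponsiveness, emulating
  the *global* character of the collapse; an acyclic structure can never
  destabilize the VAR.  Both regimes are stability-checked at construction
  (companion spectral radius < 1).
- **Band oscillators**: independent per-channel damped AR(2) oscillators
  (delta 1.0 Hz, alpha 10 Hz, beta 24 Hz; pole radius exp(−π·bw/fs)), with
  state-dependent amplitudes — responsive (0.35, 0.45, 0.25) and
  unresponsive (0.50, 0.60, 0.15) in units of the VAR noise SD.  This yields
  the expected ~2× delta/alpha power increase and beta decrease during
  unresponsiveness while keeping the segment-level autocorrelation, and
  hence the GC bias floor, comparable between states.  Oscillators are added
  *after* the VAR so the ground-truth directed flow remains attributable to
  the coupling edges alone.
- **Transitions** are abrupt by default (`transition_ramp_s = 0`, i.e.,
  within one 4-s segment), with a configurable linear ramp for sensitivity
  tests.
- **Artifacts**: Poisson events (default 0.5/min), 0.3-s half-sine bumps of
  280–400 µV on random channels, positions returned as ground truth.
- **Muscle noise**: 20–45 Hz bandpass noise (SD 0.15) on ten outer
  electrodes, present only while responsive.
- **Sessions**: a 2-h "full" plan (10-min rest, infusion at 10 min, LOBR
  ≈ 28 min, ROBR ≈ 88 min) and a 20-min "short" plan with the same structure
  (infusion 2 min, LOBR ≈ 8 min, ROBR ≈ 14 min, ±30 s per-subject jitter).
  Group-level results in the tests and the acceptance script use 16 subjects
  × 20-min sessions, a size at which every stage's signal is comfortably
  detectable on a single CPU.
- **Determinism**: one session seed is split via `SeedSequence.spawn` into
  four streams consumed in a fixed order (VAR innovations, oscillators,
  artifacts, muscle noise); multi-subject studies spawn per-subject seeds
  from the study seed.

`shared_driver_plan` is the dissociation configuration: no directed edges at
all, plus one alpha oscillator mixed with zero lag into F7 and F8 during
unresponsiveness.  Synchrony (alpha coherence) rises sharply for that pair
while bivariate GC stays near the bias floor — the latent-confounder regime
in which functional and effective connectivity disagree.  A shared driver
does create a small amount of genuine bivariate GC (each channel is a second
noisy observation of the driver's past); at the default driver amplitude
(0.6) this stays an order of magnitude below coupled-pair GC.

**What the generator does not emulate.**  No volume-conduction forward model
(channels mix only through the Hjorth/average-reference filters and explicit
coupling), no pharmacokinetics (state changes are step-like at the event
times rather than concentration-driven), no eye-blink/EOG artifacts, no
nonstationary drift within states, and no nonlinear coupling.  Passing tests
therefore show that the *pipeline* recovers the structures it assumes, under
noise, artifacts, spatial mixing and state switching — not that those
structures are identifiable in arbitrary real EEG.

## Numerical choices

- Percentiles use linear interpolation between order statistics everywhere.
- The log-mean floor is 1e−12 (of the normalized scale; equivalently 1e−12
  of the per-pair baseline divisor on the raw scale).
- Lattice fits hitting a non-positive-definite intermediate are flagged
  invalid (never silently zeroed); invalid fits propagate as NaN.
- Durbin–Watson warnings are emitted below n = 40 residuals, where the
  normal approximation degrades; the gate is still applied.
- Whole-session scans chunk segments (default 16 × 465 pairs per batch);
  results are independent of chunking, asserted in tests.
- GC values are clipped at 0 from below; clip events are counted in the
  tensor's stats.

## Known limitations

- Bivariate GC measures total (direct + indirect) flow and is inflated by
  latent confounders; this is a design choice (global effects are the
  target), demonstrated explicitly by the shared-driver configuration.
- The DW gate is uncalibrated under the well-specified null (see above).
- The small-sample GC floor is state-dependent: strong slow oscillations
  raise it.  After baseline normalization this appears as a mild upward
  drift of no-flow pairs during unresponsiveness; the selection stage's
  orientation rule is designed to remain decisive in that regime.
- EDF output is a minimal 16-bit writer (1-s records, symmetric physical
  scaling); reading uses MNE.
- The net-GC export (GC(a→b) − GC(b→a)) is provided but unused by the
  default analysis path.
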