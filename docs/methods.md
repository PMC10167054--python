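# Methods

This note records the models, parameter choices, numerical decisions and
known limitations behind `corticoflow`. Empirical statements here are
limited to what the test suite and `scripts/acceptance.py` themselves
compute.

## Protocol and containers

A session is one condition (force level × arm side) of an isometric
elbow-contraction experiment: 180 s relaxation, then five cycles of 15 s
task + 30 s rest (405 s total). EMG (biceps BIC, triceps TRI) is sampled
at 1000 Hz, optics at 11 Hz; both modalities share wall-clock block
boundaries, mapped to half-open, 0-based sample intervals per rate. The
default condition grid is {20%, 80% MVC} × {dominant, non-dominant}, and
the default cohort has 21 subjects. All subjects are modeled right-hand
dominant, so the contralateral motor cortex is LMC for the dominant arm
and RMC for the non-dominant arm.

## EMG feature chain

**Filtering.** The acquisition chain applies a causal 4th-order
Butterworth band-pass (20–450 Hz); offline analysis uses a zero-phase
(forward–backward) 4th-order 10–490 Hz band-pass. Corners at or above
Nyquist are clamped to 0.99 × Nyquist with a logged warning. The 50 Hz
power-line notch is implemented by sinusoidal regression
("spectrum-fit": least-squares fit and subtraction of a 50 Hz
sine/cosine pair), applied before the band-pass. We chose this over a
narrow IIR notch deliberately: a Q = 30 biquad rings with a ~0.2 s time
constant and its startup transient alone contributes several percent RMS
on records up to minutes long, while the regression notch removes a
stationary line component exactly, at the cost of 2 degrees of freedom
of broadband content and insensitivity to line-amplitude drift within a
record.

**Steady segment.** The analysis window (5 s = N/rate at the default
N = 5000) slides inside task blocks in 0.1-s steps; the window minimizing
the coefficient of variation of the 250-ms moving-RMS envelope is
selected, ties going to the earliest start. This operationalizes a
"steady, flat response" criterion that is otherwise a manual judgment.

**Fuzzy approximate entropy.** Segments are standardized to zero mean
and unit variance before the tolerance applies, making fApEn exactly
invariant to amplitude scaling and letting r = 0.15 act as a universal
constant. Both embedding orders m and m+1 use the same N − m vectors, so
the j ≠ i sum has exactly N − m − 1 terms matching its divisor. The
kernel is a numba-compiled O(N²) double loop with Kahan-compensated
accumulation (agreement with a literal transcription of the definition
is asserted to 1e-10; observed ~5e-15), with a chunked-numpy fallback
when numba is unavailable. A zero-variance segment returns 0 with a
warning (all vectors identical). Defaults m = 2 and n = 2 follow the
fuzzy-entropy convention; the similarity kernel is exp(−d^n / r) with d
the Chebyshev distance of baseline-removed vectors. Mean similarities
are bounded below by exp(−max d^n / r) > 0, so the logarithm is safe; a
defensive clamp at 1e-300 remains. The parameter-sweep helper evaluates
the fApEn surface over N = 100…5000 (step 100) × r = 0.02…1 (step 0.02)
by default.

**MVC and CCI.** The MVC reference is the maximum over three 5-s
maximal-effort trials of the peak 250-ms moving-RMS envelope (fewer
trials are accepted with a warning). CCI uses Winter's form on linear
envelopes — full-wave rectification, zero-phase 4th-order 6 Hz low-pass,
normalization by the muscle's MVC amplitude — integrated by the
trapezoid rule over the agonist's steady window. Identical envelopes
give exactly 100, disjoint supports exactly 0; both-zero envelopes are
an error rather than 0, since the ratio is undefined.

## fNIRS chain

**MBLL.** ΔOD(λ) = [ε_HbO2(λ)·ΔHbO2 + ε_HbR(λ)·ΔHbR]·d·DPF, inverted
per channel via the 2×2 extinction system. Bundled molar extinction
coefficients (cm⁻¹/M, Gratzer/Prahl compilation): 730 nm → (390.0,
1102.2), 850 nm → (1058.0, 691.32) for (HbO2, HbR); d = 3 cm,
DPF = 6.0 at both wavelengths; all configurable. Concentrations are in
µM. HbR is carried in containers but all downstream analysis uses HbO2.

**Quality control and artifacts.** A channel is invalid if its OD is
flat (variance < 1e-12) or the implied raw intensity (10^−OD) has
CV > 15%. Motion artifacts are samples whose 1-s moving SD exceeds 5×
its median; they are replaced by shape-preserving cubic (PCHIP)
interpolation from flanking samples — an ordinary cubic spline
overshoots badly across gaps anchored in noise — and a channel whose
artifact span exceeds 20% of the record is invalidated instead. Invalid
channels are masked everywhere (region means, FC rows/columns, graph
nodes), never silently dropped.

**Band-pass and activation.** HbO2 is band-passed 0.01–0.2 Hz
(zero-phase 4th-order Butterworth, generous reflection padding). Edge
ring-in of the slow high-pass poles is unavoidable at record edges; the
designed zero-phase response at 1.1 Hz is ~6e-7 in power, and contracts
are asserted on the steady-state interior. The GLM design is [task
boxcar ⊗ canonical double-gamma HRF (peak 6 s, undershoot 16 s, ratio
1/6), constant, linear drift]; betas by least squares. The "HbO2
integral" is defined here as the trapezoidal integral over the 15-s task
window of the across-block-averaged HbO2, baseline-corrected by the mean
of the 2 s preceding each block, in µM·s; region values average the
region's valid channels. This definition is declared because integration
window, baseline and averaging are not standardized.

## Connectivity and graphs

**FC.** Pearson correlation between channel series or region means over
the concatenated task blocks (rest / relaxation / whole-session windows
selectable); p-values from the t transform; BH-FDR at q = 0.05 over the
off-diagonal family. Matrix averaging uses Fisher z. Note the t-based
p-values treat samples as independent; band-limited series have fewer
effective dof, so FC significance on filtered data is optimistic — group
comparisons (which test across subjects) are unaffected.

**EC.** Pairwise Granger causality between region means. Three
numerical decisions matter, all found the hard way on synthetic data:
(1) the 0.01–0.2 Hz series are grossly oversampled at 11 Hz, making lag
columns near-collinear and the nested F-test degenerate — the series are
decimated to ~1 Hz (safe: band-limited far below the new Nyquist);
(2) the shared task-evoked response is deterministic and
cross-predictable, so the HRF task regressor is partialled out (with
mean and linear trend) before fitting; (3) the lag order is chosen by
BIC of the full bivariate model (selecting on the reduced model would
ignore pure cross-lag structure), bounded by max_lag = 12 s — beyond the
~10-s Mayer-wave period, since shorter AR horizons underfit narrowband
autocorrelation and inflate false positives. The F-test is exactly
calibrated on white-noise nulls (asserted); on narrowband filtered
hemodynamics pairwise GC remains somewhat anti-conservative — a known
property of filtered-signal causality analysis, shared by practice, and
the reason cohort-level claims are phrased as programmed-edge recovery
and side contrasts rather than edge-count specificity.

**Graph metrics.** FC weights with negatives zeroed, zero diagonal,
normalized by the maximum weight (no binarization or thresholding by
default). Clustering is Onnela's cube-root triangle intensity; local
efficiency of node i is the global efficiency of the subgraph induced by
its neighbors; global efficiency is the mean inverse shortest-path
length on distance = 1/weight. With weights in [0, 1] all three lie in
[0, 1]. Region-level values are means over the region's channel nodes.
Implementations are verified against exhaustive enumeration on ≤8-node
graphs and against networkx's weighted clustering.

## Group statistics

All tests two-sided at α = 0.05. FDR families are declared per analysis
panel: the strata of one paired comparison, the edges of one matrix
comparison, one correlation panel; every result row carries its family
size. Paired t-tests compare force levels within subject per side;
independent-samples t and one-way ANOVA are available for cross-side and
multi-group contrasts; a sign-flip permutation fallback is provided for
paired designs where normality is in doubt. Cross-modal correlations
pool subjects × force levels within a side (matched rows only, n ≥ 3
required).

## Synthetic cohort: what it emulates and what it does not

**EMG.** Each muscle is a 120-unit motor-unit pool. Units fire as
jittered renewal processes during task blocks (rate = 8 Hz + 40 Hz ×
supra-threshold drive, ISI CV 0.2, refractory floor at 0.2× the mean
ISI), each convolved with a Ricker (second-derivative-of-Gaussian)
action potential; white sensor noise (3 µV RMS) covers the whole record,
rest blocks are noise-only. Amplitudes grow exponentially with
recruitment index (0.08→0.6 mV); durations *shrink* (15→8 ms), because
later-recruited large units innervate faster-conducting fibers — with
the opposite gradient the 80%-MVC spectrum is dominated by large slow
units and the complexity ordering inverts. Agonist thresholds are
exponentially spaced over [0.1, 0.75) of MVC (≈41 units active at 20%,
all at 80%, nonempty down to the weakest per-subject drive); antagonist
thresholds are *linearly* spaced over [0.015, 0.3) so that co-activation
drives (1.8–25% of its own MVC) recruit a nonempty set that grows
steeply with force — exponential low-end spacing recruits so many units
at 20% MVC that the co-contraction ordering inverts. Co-activation
fractions default to 0.15 (20% MVC) and 0.25 (80% MVC), programming the
CCI increase.

**fNIRS.** Region HbO2 = drive × gain × (boxcar ⊗ HRF) +
correlation-structured white latents (Cholesky of I + C, programming
FC) + a stable lagged recursion on slow innovations (lag 2 s,
companion-matrix spectral radius checked < 1 at construction,
programming EC) + quasi-periodic physiological noise (narrowband,
region-independent: cardiac 1.1 Hz, respiration 0.25 Hz, Mayer 0.1 Hz)
+ random linear drift + channel white noise (0.05 µM). Channels carry
their region signal plus sensor noise; HbR = −0.3 × HbO2 (used only to
make the optical-density inversion well-posed); the pair is pushed
through the inverse MBLL so the pipeline's forward conversion is
exercised end to end. Default condition structure: contralateral-MC
gain 0.5/1.0 µM (20/80%), graded smaller gains for ipsilateral MC,
PFC and OL; latent coupling LMC–RMC at both forces plus
prefrontal/motor couplings at 80% only; directed edges LMC→RMC and
LMC→LOL on the dominant side only.

**Cross-modal drive.** Each subject has a latent drive ~ N(1, 0.2²)
clipped to [0.6, 1.4] that multiplies both motor excitation
(force × drive) and all task gains, inducing the positive fApEn ↔ HbO2
coupling across the cohort. Setting the drive SD to 0 (the null
configuration) removes it.

**Not emulated:** volume-conduction and electrode geometry, motor-unit
synchronization and fatigue, photon transport and partial-volume
effects, systemic (shared-across-region) physiological confounds,
motion artifacts beyond injected spikes, task learning effects. Passing
tests therefore show that the pipeline recovers effects of the
programmed kinds at realistic magnitudes — not that it is robust to
every failure mode of real recordings.

**Determinism.** Every stochastic operation takes an explicit seed; the
cohort derives per-dataset seeds from (cohort seed, subject, condition,
stream) via `numpy` SeedSequence, so identical seed + configuration is
byte-identical, including written files.

## Problem sizes in the default test run

The acceptance tests run the full default cohort (21 subjects × 4
conditions, 405-s sessions) through the complete pipeline once (shared
fixture, a few minutes on one CPU); calibration nulls use 100–500
replicates at n = 300 samples (Granger false-positive rate), 10 matrices
per group × 100 repetitions (edge-comparison FDR), and 500 draws of
n = 20 (Pearson null). Oracle comparisons use N ≤ 1000 entropy windows
and ≤8-node graphs. The CLI round-trip test uses 3 subjects with a
shortened (60 s relaxation, 2-cycle) session.

## Known limitations

- The regression notch assumes a stationary line component per record;
  slowly drifting line amplitude is only removed in the mean.
- FC p-values on band-limited series overstate per-record significance
  (effective-dof issue); use group-level comparisons for inference.
- Pairwise GC on narrowband filtered hemodynamics is anti-conservative;
  conditional (multivariate) GC and frequency-domain variants are out of
  scope.
- The HbO2-integral definition (window, baseline, block averaging) is a
  declared convention; other software's "integral" values need not
  match numerically.
- SNIRF I/O is not provided; the on-disk format is the documented
  CSV + JSON dialect.
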