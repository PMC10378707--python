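# Methods

This note documents the models, conventions and design choices behind
`mwl_eeg`, in the spirit of a package's own methods appendix. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Problem setting

A pilot flying an airfield traffic pattern passes through three phases —
take-off, cruise, landing — that induce middle, low and high mental
workload (MWL). A 5-channel wireless headset (AF3, AF4 frontal; T7, T8
temporal; Pz occipital midline; 128 Hz) records EEG; NASA-TLX surveys per
phase provide the workload labels. The package implements the complete
chain from raw signal + surveys to a cross-validated three-class
classifier, plus a synthetic generator that emulates the statistical
structure the chain assumes.

## Synthetic data generator

The generator is first-class, tested code, not a fixture. It emulates:

* **Background:** 1/f noise (spectral exponent 1.0 by default,
  configurable), RMS 5 μV, synthesized by shaping complex Gaussian spectral
  coefficients with an $f^{-\beta/2}$ amplitude envelope.
* **Oscillations:** per band, narrowband-filtered Gaussian noise realized
  the same way — complex Gaussian coefficients under a Tukey-tapered
  envelope confined to the band. A filtered-noise oscillation (rather than
  a pure tone) keeps periodogram estimates at their natural chi-squared
  variance, so band-power tests exercise realistic estimation error; the
  strictly band-limited envelope puts essentially all oscillation power
  inside the band, which causal IIR band-pass skirts would not.
* **Workload structure:** a `band_gain[level][region][band]` table of RMS
  amplitudes. The default pattern follows the qualitative physiology the
  system exploits: frontal/temporal slow-wave (δ, θ) power grows with
  workload, the occipital α rhythm dominates at rest, and the strongest
  gain (frontal δ at high workload, 10 μV) is twice the background RMS.
  Each phase carries the gains of its induced level
  (take-off→middle, cruise→low, landing→high).
* **Artifacts:** eye-blink-like transients on frontal channels only —
  0.5-s Hann pulses, 150 μV peak, 4 per minute — giving the rejection
  stage something real to reject.
* **Surveys:** subscale ratings drawn per participant × phase around the
  published phase-wise means, truncated to [0, 100]. The published
  dispersions are printed as "mean ± value" without stating SD or SE; the
  default reads them as standard errors of the 21-participant mean
  (per-participant SD = value × √21), with the SD reading available via
  `dispersion_kind="sd"`. Pairwise weights default to tallies
  (mental 5, effort 4, frustration 3, physical 2, temporal 1,
  performance 0): the flight task loads the mental/effort/frustration
  subscales most heavily, and weighting toward the subscales whose phase
  contrasts agree in sign is what makes the label map recoverable at the
  published means and dispersions — an equal-weights scheme provably is
  not, because two subscales (temporal demand, perceived performance) rank
  the phases in the opposite order.

What it does **not** emulate: volume conduction / inter-channel
correlation, non-stationarity within a phase, inter-participant
variability beyond independent noise, or simulator-vs-real-flight
differences. Passing tests therefore demonstrate that the chain recovers
structure that is present, not that real cockpit EEG contains that
structure.

Determinism: identical (config, seed) gives bit-identical output; the RNG
consumes the same number of draws regardless of amplitude settings, so
changing a gain does not silently reshuffle everything else.

## Preprocessing

* **Low-pass filter:** zero-phase FIR, Hamming-window design, 385 taps
  (clamped for short recordings), cutoff centered in the transition band
  [cut − 2, cut + 10] Hz. The contract is < 1 dB passband loss at
  cut − 2 Hz and > 20 dB stopband attenuation at cut + 10 Hz under
  forward-backward application. A low-order Butterworth cannot meet this
  contract zero-phase (filtfilt doubles its attenuation in the passband as
  well; the transition ratio 50/38 needs ≥ 8th order), and a sharp linear-
  phase FIR is also what keeps repeated filtering nearly idempotent.
  An optional 0.5 Hz drift high-pass is exposed, off by default.
* **Bad channels:** variance below 0.01 μV² (flat) or any |sample| above
  500 μV (clipped) drops the channel, with the removal logged.
* **Epoching:** 2-s windows, 50 % overlap, aligned to each annotated
  phase's start, half-open sample windows; trailing partial windows
  discarded; no window crosses a phase boundary, so labels stay pure. An
  integer n-second phase yields n − 1 windows.
* **Artifact rejection:** peak-to-peak threshold 150 μV on any channel.
  This replaces manual ICA-based ocular cleanup, which requires
  map-guided component selection that cannot be reproduced from a written
  description; amplitude rejection is deterministic and auditable.

## Features

Per channel and epoch: 6 band powers, 10 time-domain features, 2
entropies; 90 total for the 5-channel montage.

* **PSD convention:** one-sided periodogram of the rectangular-windowed
  epoch, $|f_k|^2/(f_s N)$ with doubling of interior bins; band power sums
  PSD × bin width over bins inside the closed interval [low, high]. Bins
  in the printed gaps between bands (e.g. 3.5 Hz) belong to no band —
  the printed table is followed literally. A Hann taper is exposed
  (`taper="hann"`) for users who read the windowing as a taper; the
  rectangular default matches a plain FFT of the epoch.
* **Time domain:** population variance (ddof 0); excess kurtosis; zero
  crossings count strict sign changes with exact zeros inheriting the
  previous sign; Hjorth mobility $\sqrt{\mathrm{var}(\Delta x)/\mathrm{var}(x)}$
  and complexity $\mathrm{hm}(\Delta x)/\mathrm{hm}(x)$. Mobility is
  dimensionally frequency-like (per sample); the μV/Hz unit sometimes
  printed for it does not match the standard definition, which is what is
  implemented.
* **Entropies:** sample entropy $-\ln(A/B)$ (Chebyshev distance, template
  lengths m and m+1, self-matches excluded, N − m templates both lengths)
  and approximate entropy $\Phi_m - \Phi_{m+1}$ (self-matches included).
  Defaults m = 2, r = 0.2 × epoch SD — the field-standard setting. When no
  template pair matches, SampEn returns the maximum resolvable value
  ln(number of template pairs), flagged, rather than raising: downstream
  selection must never see missing values. Zero-variance inputs yield 0
  for all scale-free features, flagged.

## Labeling

Weighted TLX score $S = \sum_i w_i r_i / 15$ (bounded by the 0–100 rating
scale). Published phase-level scores above 100 cannot arise from this
form, and the aggregation behind them is not documented; a raw weighted-sum
aggregator ($\times 15$) is therefore provided as an explicit alternative,
with the standard form kept as the default — a standard instrument should
not be silently redefined. Phase differences: one-way ANOVA plus pairwise
Welch t-tests (the unequal-variance form, since equal variances are not
established) at the Bonferroni-corrected threshold α/3, reported to three
decimals (0.05 → 0.017). Labels follow the rank order of phase mean
scores; a tie raises and demands an explicit override. Labels are constant
within a phase.

## Selection

* **Filter route:** Shapiro-Wilk normality per feature at α = 0.05 (the
  test is not named in the source description; Shapiro-Wilk is the
  standard default at these sample sizes); on rejection, tie-corrected
  Kruskal-Wallis H across the three classes with a χ²(2) p-value;
  selected sets at α = 0.05 and 0.01; z-scoring standardizes features,
  fitted on training rows by default (leakage-safe) with a global mode
  available for compatibility with analyses that standardize everything
  first.
* **Wrapper route (SFFS):** forward inclusion of the CV-accuracy-
  maximizing feature, then conditional exclusion of any feature whose
  removal strictly improves the best known criterion at the smaller size.
  Ties break toward the lowest column index (determinism). A cycle check
  on the full state history skips exclusions that would revisit a previous
  subset; comparing full states rather than criterion values is the
  stricter and unambiguous reading. CV folds are stratified with a fixed
  seed. The PSD and calculative pools are selectable separately, mirroring
  the practice of treating band powers as the primary input and the rest
  as supplements.

## Modeling

* SVM kernels run one-vs-rest (the binary decision function needs an
  explicit multi-class scheme; one-vs-rest keeps per-class precision/
  recall interpretable). RBF width σ maps to gamma = 1/σ².
* KNN k = 1, Euclidean; random forest 500 trees, √p features per split,
  bootstrap of training-set size — standard settings where the source
  description leaves them open.
* **BNN:** MC-dropout variational approximation, implemented in numpy
  (the architecture — 90→200→200→3, ReLU, dropout 0.2 — is small enough
  for full-batch CPU training). Loss = cross-entropy + 0.05 × KL to the
  N(0, 0.1²) weight prior; for a fixed-form dropout posterior the KL
  reduces to a squared-norm penalty, so kl_weight = 0 recovers a plain
  dropout MLP. Adam lr 0.001 with reduce-on-plateau. The desk-scale
  default is 500 epochs (the reference setting of 10 000 is available by
  config); predictions average 50 stochastic forward passes. More MC
  samples stabilize the predicted label (lower variability across
  repeated predictions); note the entropy of the *averaged* probability
  vector itself is non-decreasing in the number of samples by Jensen's
  inequality — the stabilization claim is about prediction variability,
  and that is what the test measures.
* **Metrics:** computed from first principles via per-class one-vs-rest
  confusion counts; precision/recall macro-averaged (micro averaging
  would force precision = accuracy in the multi-class single-label
  setting, which contradicts reported tables where precision exceeds
  accuracy), F1 = 2PR/(P+R) from the macro averages. A literal variant
  substituting accuracy for precision in F1 exists behind
  `f1_variant="accuracy"` because the printed formula reads that way;
  the standard form is the default. Undefined ratios (empty predicted or
  true class) count as 0 and are flagged.
* **Evaluation:** stratified 10-fold CV, z-scoring fitted inside each
  training fold (global in paper-mode), mean ± SD over folds. A fixed
  70/30 split is not used for reporting; 10-fold CV over all rows is the
  single reporting convention, which avoids the ambiguity of combining
  both.
* **Region × band harness:** for each region (frontal, temporal,
  occipital, all) × band (six bands + mix), the matching PSD columns feed
  KNN k = 1 under the same CV.

## Problem sizes and numerical choices

Defaults were chosen once as the study conditions: 60-s phases (59 epochs
per phase per participant), 10 virtual participants in the end-to-end
recovery run, 21 participants in TLX surveys (the study's sample size),
1000 null simulations for Kruskal-Wallis calibration, 200 for the
normality screen, 250 seeded surveys for label recovery, 20 seeded runs
(2 participants each) for screen-retention. The windowing law is checked
for every integer phase length from 2 to 120 s. Brute-force entropy
oracles run at n ≤ 300. Tolerances: oracle equivalences at 1e-10
absolute; calibration rates within [0.03, 0.07] at α = 0.05.

## Known limitations

* The generator's independence assumptions (channels, participants) make
  classification easier than on real EEG; reported synthetic accuracies
  are upper bounds on what the same chain would achieve in the cockpit.
* EDF output is plain EDF (16-bit, 1-s records, zero-padded to whole
  records); annotations travel in a sidecar CSV rather than EDF+.
* The BNN is a variational approximation by MC dropout, not full
  posterior inference; its uncertainty estimates inherit dropout's known
  miscalibration.
* SFFS is greedy: its best subset matches exhaustive search on the
  constructed test sets, but carries no general optimality guarantee.
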