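# Methods

## Signal model and conversion

Continuous-wave fNIRS measures light attenuation at 760 and 850 nm over an
18-channel multi-distance montage (channels 1–6 over the SMA, 7–18 over S1;
channels 2 and 10 are ~11 mm short-separation channels, long channels span
25–45 mm). Intensities are converted to optical density against a reference
intensity — by default the mean over the 5 min rest baseline; median or
first-N-seconds references are selectable, because acquisition systems differ
in whether they pre-reference OD and only intensity ratios matter downstream.

The modified Beer–Lambert law is solved per channel as a 2×2 linear system

    ΔOD_λ = (ε_λ,O₂Hb ΔC_O₂Hb + ε_λ,HHb ΔC_HHb) · d · DPF(λ, age)

with base-10 extinction coefficients from the standard compiled hemoglobin
spectra (760 nm: 0.5860/1.5485; 850 nm: 1.0580/0.6913 mM⁻¹cm⁻¹ for
O₂Hb/HHb; swappable via `OpticalConstants`), the per-channel source–detector
separation `d` in cm, and the general closed-form differential pathlength
factor

    DPF(λ, A) = 223.3 + 0.05624·A^0.8493 − 5.723·10⁻⁷λ³ + 0.001245λ² − 0.9025λ

valid for 690–900 nm (extrapolation refused unless overridden). Outputs are
relative concentration changes in µM; no partial-volume correction is
applied. All channel ids in I/O and reports are 1-based.

## Filtering and epoching

Both filters are 3rd-order Savitzky–Golay stages; window lengths in samples
are the nearest odd integer to `window_s × fs` (4 s → 31 samples, 80 s → 625
samples at 7.81 Hz). Filter edges are handled by fitting the polynomial over
the terminal window and evaluating it across the half-window: this keeps
polynomials up to the filter order exactly invariant everywhere, whereas
mirror padding would break that exactness at the boundaries. The smoothing
stage suppresses the cardiac band (gain ≈ 0.035 at 1 Hz); the detrending
stage subtracts the long-window trend and suppresses slow drift below
~0.016 Hz.

A measured caveat worth stating explicitly: the 80 s detrend does **not**
attenuate the ~0.1 Hz Mayer band as a frequency-response matter (the residual
gain |1−H| at 0.1 Hz is ≈ 1.01), and a 25 s block loses roughly 65% of its
amplitude to the trend estimate. What actually protects the block averages
from Mayer waves in this design is the combination of per-trial
normalization and medians over 15 trials whose phases drift relative to the
20 s trial grid. The tests assert the oracle-computed filter behaviour, not
the nominal design intent.

Trials are cut at `floor(onset × fs)` with a fixed epoch length of
`round(12.8 s × fs)` = 100 samples (3.9 s pre-window, 5 s stimulus, 3.9 s
post-window), so all trial stacks are rectangular. Each epoch is linearly
detrended (least-squares line over the whole epoch) and normalized by
subtracting the median of its pre-window; the pre-window median is zero to
float precision afterwards (exactly zero only for odd pre-window sample
counts, since an even-count median averages two order statistics).

## Short-separation regression

Each long channel is corrected by `long − β·short` with the least-squares
`β = ⟨long, short⟩/⟨short, short⟩`, using channel 2 for channels 1, 3–6 and
channel 10 for 7–9, 11–18; the corrected series is orthogonal to the
regressor, and short channels pass through flagged as excluded from cortical
statistics. Two regimes are implemented:

* **continuous** (default): one β per channel fit on the filtered recording
  before segmentation;
* **per_epoch**: a trial-local β fit on each normalized 100-sample epoch.

The default is continuous because the per-epoch regression is measurably
biased: within a 12.8 s epoch the scalp regressor has only a handful of
effective degrees of freedom, so the trial-local β absorbs chance correlation
with the evoked response and removes a substantial share of it (~35% of the
injected amplitude at negligible noise in our measurements, with trial-local
βs scattered over several units around a true coupling of 0.34). The
per-epoch regime remains available (`ssr.scope = per_epoch`) and is the one
probed by the scalp-suppression validation study, under scalp-dominated
conditions where its β is accurate.

## Summaries and statistics

The block average is the median over the middle 2.5 s of the stimulus window
(samples with time-from-onset in [1.25 s, 3.75 s)) pooled across the 15
trials of a condition (`pooled_median`); the median of per-trial medians is
available by config. Grand averages are medians across the subjects of a
group with SEMed = 1.2533·SD/√n (the asymptotic Gaussian form; a bootstrap
estimator is provided and agrees within sampling error).

All tests are nonparametric. Wilcoxon signed-rank p-values are exact for
n ≤ 15 and rank-sum p-values exact for min(n, m) ≤ 10; exactness is achieved
with a subset-sum convolution over (doubled, midrank-tied) ranks, which
equals full enumeration over sign assignments / group assignments while
handling ties that closed-form tables cannot. Larger samples use the normal
approximation with continuity and tie corrections. Zero differences are
dropped (classic treatment; Pratt handling selectable). The Friedman test
uses the tie-corrected rank statistic with a χ²(k−1) reference. Families of
channel-wise p-values — the 16 long channels within one test type ×
condition × chromophore × group — are corrected with Benjamini–Hochberg;
`significant` means q < 0.05.

Two group-level modes mirror the dual analysis approach. *All* enters every
long channel. *Responders* first screens each (subject, channel, condition,
chromophore) with a single-subject signed-rank test of the 15 per-trial
middle-window medians against zero at uncorrected p < 0.05 — the only
within-subject sample of size > 1 the pipeline produces — and only
screened-in cells enter the group statistics; channels with fewer than five
surviving subjects are reported untested. Post-hoc condition contrasts are
paired signed-rank tests on within-subject condition differences (the
samples are paired by subject), and between-group comparisons are unpaired
rank-sum tests. Vs-baseline tests compare block averages against zero, since
signals are normalized to a zero pre-stimulus median. Single-patient
deviation maps test each patient's 15 per-trial values against the
healthy-control grand-average scalar per channel (BH across channels), with
the deviation direction given by the sign of the median difference.

## Heart rate and behavior

Heart rate is analyzed at 1 s resolution with half-open windows [start, end)
so the boundary sample between stimulus and post-ISI is never counted twice.
Condition-level HRmax is the mean of per-trial maxima (max-of-max
selectable). ΔHRmax = HRmax(stimulus) − HRmax(post-ISI) and is antisymmetric
under exchanging the two windows. Group tests: paired signed-rank of
stimulus vs post-ISI maxima per condition (BH over the three conditions) and
a Friedman test over the conditions' ΔHRmax.

Behavioral summaries reproduce the published patient table layout: per
column the arithmetic mean and sample SD (n−1), displayed with half-up
rounding to the table's printed precision (integer Newtons for the
pressure-pain threshold, one decimal for questionnaire scores; half-up
because the PPT column mean is exactly 44.5 and prints as 45). The final PPT
is the mean of 3–4 repeated threshold readings; the group comparison is a
one-sided (patients lower) unpaired rank-sum test.

## Synthetic-data generator

Signals are built in concentration space per channel and chromophore:

* **Evoked response** — a peak-normalized single-gamma impulse response
  convolved with each condition's 5 s stimulus train. The default kernel is
  fast and compact (peak 2 s, shape 9): the trial response rises within
  ~2 s, peaks near stimulus offset and returns toward baseline during the
  post-window, matching the waveform this event-related pipeline is designed
  to summarize. This matters because any response still rising at the epoch
  end has its middle-window value inverted by the per-trial linear detrend —
  a slow canonical kernel (6 s peak) maps to a *negative* processed value of
  −0.34 per unit peak. Amplitude semantics: a configured amplitude is the
  *realized* block value of a clean trial after the full filtering chain;
  the generator calibrates the regressor scale once per protocol by pushing
  a unit train through the pipeline. Defaults: 0.4 / 0.3 / 0.1 µM Δ[O₂Hb]
  for painful pressure / non-painful pressure / brushing, HHb at −⅓ of O₂Hb.
* **Systemic oscillations** — Mayer (~0.1 Hz), respiratory (~0.25 Hz) and
  cardiac (~1.1 Hz) sinusoids (0.08/0.04/0.06 µM) with per-subject frequency
  spread (±15%) and slow phase diffusion, in every channel with random
  per-channel gains. The drift is essential realism: perfectly periodic
  oscillators would be phase-locked to the 20 s trial grid and would neither
  average out of block medians nor behave like physiology.
* **Scalp component** — band-limited noise (~0.5 Hz low-pass, 0.15 µM),
  entering short channels at unit weight and long channels at per-channel
  couplings drawn from U(0.3, 0.9); recorded in the ground truth.
* **Drift and noise** — a per-channel random walk (0.004 µM/√sample) and
  white noise (0.1 µM per sample at the default SNR; 0.005 µM in the
  high-SNR preset, which keeps the scalp component so that the SSR still has
  signal to regress on).

Concentrations are forward-converted through the same MBLL model to optical
densities and intensities (I = I₀·10^(−ΔOD)), making the generator the exact
inverse of the analysis front-end. Heart rate is a per-subject baseline
(62 ± 8 bpm) plus a small bump peaking ~7 s after onset (so post-ISI maxima
slightly exceed stimulus maxima, the observed pattern) and noise. Behavioral
records draw PPTs from the group distributions (patients 45 ± 18 N, controls
57 ± 7.3 N, truncated positive), ages from the group demographics, and a
30 N (controls) or individualized lower (patients) non-painful force. A
`responder_fraction` knob nulls a subset of channels (channel scope by
default, per-subject selectable), and a bimodal patient-amplitude multiplier
(off by default) emulates patient-subgroup heterogeneity.

What the generator does **not** emulate: motion artifacts, optode-coupling
changes, heterogeneous per-channel HRF shapes and latencies, non-sinusoidal
physiology, or anatomical variability in sensitivity. Passing validation
therefore demonstrates the pipeline's correctness under its own statistical
assumptions, not robustness to every artifact class in real recordings.

## Validation studies

Because the original recordings are not publicly deposited, group-level
result tables cannot be recomputed; the pipeline is instead validated by its
operating characteristics on synthetic cohorts (see
`nirspress/validation.py`, exercised by both the test suite and
`scripts/acceptance.py`):

* **FDR control** — 200 fully null cohorts (20+12 subjects, full pipeline
  from raw intensities), pooled fraction of q < 0.05 channel tests compared
  against 0.05 plus three binomial standard errors.
* **Amplitude recovery** — cohort-median block average of an injected
  0.5 µM O₂Hb amplitude; relative error at high and default SNR.
* **SSR efficacy** — residual variance of the injected scalp component after
  per-epoch SSR, measured by regressing corrected epochs on the identically
  processed true scalp contribution, under scalp-dominated null conditions.
* **Responder specificity** — 100 mixed cohorts with half the channels null;
  false-positive channel rates of the two analysis modes compared.
* **Protocol validity** — 1000 generated sequences against an independent
  count/run-length checker.

The Monte-Carlo studies use full 32-subject cohorts but a shortened
recording (30 s baseline; 5 trials per condition for the null study, 8 for
the responder study so that single-subject screening at n ≥ 6 trials can
reach p < 0.05). These sizes are the package's simulation-study design,
keeping hundreds of full-pipeline cohort replicates tractable on one CPU
while preserving every pipeline stage.

## Known limitations

* The SNIRF reader/writer covers a documented continuous-wave subset
  (intensity block, measurement list, wavelengths, stim events), not the
  full standard; long-format CSV is the canonical text interchange.
* Exact optode coordinates and the left/right channel assignment within each
  region are conventions (configurable), as only ROI membership is
  standardized in this montage description.
* Grand-average SEMed uses the Gaussian asymptotic constant; for strongly
  non-Gaussian subject distributions the bootstrap option is preferable.
* Motion-artifact correction is deliberately out of scope (none is applied
  in this processing lineage); band-pass IIR/FIR filtering is likewise
  excluded in favour of the Savitzky–Golay stages.
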