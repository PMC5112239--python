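"""Synthetic cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes, in
concentration space (uM) and per channel:

* stimulus-locked hemodynamic responses: a single-gamma impulse response
  (peak ~6 s) convolved with the 5 s stimulus trains, O2Hb positive and HHb
  a scaled negative copy by default;
* systemic oscillations: Mayer waves (~0.1 Hz), respiration (~0.25 Hz) and
  cardiac pulsation (~1.1 Hz) with randomized phases, present in every
  channel;
* a superficial (scalp) component - band-limited noise common to short and
  long channels, entering short channels at unit weight and long channels at
  per-channel coupling weights;
* random-walk drift and white measurement noise.

The concentration signal is pushed through the forward modified
Beer-Lambert model to optical densities and then to raw two-wavelength
intensities (I = I0 * 10**(-dOD)), i.e. exactly the inverse of the analysis
front-end, so that round-trip recovery is testable.

Amplitude semantics: a configured amplitude is the *realized* block value of
a clean (noise-free) trial after the full filtering chain - the generator
calibrates the regressor scale per protocol by running a unit-amplitude
clean train through the pipeline.  This keeps "injected amplitude" directly
comparable with the pipeline's block averages.

Heart rate is simulated at 1 Hz as a subject baseline plus a small
stimulus-locked bump peaking shortly after stimulus offset (so post-ISI
maxima slightly exceed stimulus maxima, as observed) plus noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .behavior import HRSeries, SubjectRecord
from .optics import (HbSeries, OpticalConstants, RawIntensityRecording,
                     SubjectMeta, compute_dpf)
from .preprocess import PreprocessConfig
from .protocol import (ProbeLayout, StimulusProtocol, build_default_layout,
                       generate_stimulus_sequence)
from .stats import block_average
from . import preprocess as pp


@dataclass(frozen=True)
class HRFParams:
    """Single-gamma impulse response, peak-normalized.

    The default is a fast, compact kernel (peak 2 s, SD ~0.75 s): convolved
    with the 5 s stimulus it rises within ~2 s, peaks near stimulus offset
    and returns toward baseline during the post-window - the waveform this
    event-related pipeline is built to summarize.  Slower canonical kernels
    (e.g. peak 6 s) are available via config but note that a response still
    rising at the epoch end inverts its sign under per-trial linear
    detrending.
    """

    peak_delay_s: float = 2.0
    shape: float = 9.0  # gamma shape a; scale = peak_delay / (a - 1)
    duration_s: float = 20.0

    def kernel(self, fs: float) -> np.ndarray:
        t = np.arange(0.0, self.duration_s, 1.0 / fs)
        scale = self.peak_delay_s / (self.shape - 1.0)
        h = t ** (self.shape - 1.0) * np.exp(-t / scale)
        return h / h.max()


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the emulated experiment.

    Defaults reproduce the study configuration: 20 healthy controls and 12
    patients, the 5 min baseline / 3 x 15 trial protocol at 7.81 Hz, and
    group PPT distributions of mean 45 / SD 18 N (patients) vs 57 / 7.3 N
    (controls).
    """

    seed: int = 0
    n_hc: int = 20
    n_clbp: int = 12
    baseline_s: float = 300.0
    trials_per_condition: int = 15
    hrf: HRFParams = field(default_factory=HRFParams)
    #: realized O2Hb block amplitude per condition, uM
    amplitude_uM: dict = field(default_factory=lambda: {
        "PAPain": 0.4, "PAnP": 0.3, "Brush": 0.1,
    })
    hhb_ratio: float = -1.0 / 3.0
    #: systemic sinusoid (amplitude uM, frequency Hz) triples
    mayer: tuple[float, float] = (0.08, 0.1)
    respiration: tuple[float, float] = (0.04, 0.25)
    cardiac: tuple[float, float] = (0.06, 1.1)
    systemic_hhb_ratio: float = 0.3
    scalp_amplitude_uM: float = 0.15
    scalp_coupling_range: tuple[float, float] = (0.3, 0.9)
    drift_scale_uM: float = 0.004  # random-walk step SD per sample
    noise_sd_uM: float = 0.1
    responder_fraction: float = 1.0
    responder_scope: str = "channel"  # or "subject"
    clbp_heterogeneity: bool = False  # bimodal amplitude multipliers
    age_mean: dict = field(default_factory=lambda: {"HC": 33.6, "CLBP": 32.0})
    age_sd: dict = field(default_factory=lambda: {"HC": 10.7, "CLBP": 6.1})
    ppt_mean: dict = field(default_factory=lambda: {"HC": 57.0, "CLBP": 45.0})
    ppt_sd: dict = field(default_factory=lambda: {"HC": 7.3, "CLBP": 18.0})
    hr_baseline_mean: float = 62.0
    hr_baseline_sd: float = 8.0
    hr_bump_bpm: float = 0.8
    hr_noise_sd: float = 1.2
    onset_jitter_s: float = 0.0  # manual stopwatch jitter for HR markers, off
    i0: float = 1.0

    def protocol_template(self) -> StimulusProtocol:
        return StimulusProtocol(baseline_s=self.baseline_s,
                                trials_per_condition=self.trials_per_condition)

    def null(self) -> "SimulationConfig":
        """Zero-amplitude variant: no evoked response anywhere."""
        return replace(self, amplitude_uM={c: 0.0 for c in self.amplitude_uM})

    def high_snr(self) -> "SimulationConfig":
        """Low-noise variant: measurement noise, drift and systemic
        oscillations scaled down; the scalp component is kept (the short
        channels must still carry signal for SSR to regress on)."""
        return replace(
            self,
            mayer=(self.mayer[0] * 0.1, self.mayer[1]),
            respiration=(self.respiration[0] * 0.1, self.respiration[1]),
            cardiac=(self.cardiac[0] * 0.1, self.cardiac[1]),
            drift_scale_uM=self.drift_scale_uM * 0.1,
            noise_sd_uM=0.005,
        )

    def validate(self, fs: float) -> None:
        nyquist = fs / 2.0
        for amp, f in (self.mayer, self.respiration, self.cardiac):
            if f >= nyquist:
                raise ValueError(f"systemic frequency {f} Hz >= Nyquist {nyquist} Hz")
            if not np.isfinite(amp):
                raise ValueError("systemic amplitude must be finite")


@dataclass
class GroundTruth:
    """What was injected, for parameter-recovery and specificity tests."""

    amplitudes: dict  # {condition: {chromo: per-channel array (nominal uM)}}
    responder_mask: np.ndarray  # (n_channels,) bool, True where HRF injected
    scalp_series: dict  # {chromo: (n_samples,) array}
    scalp_coupling: np.ndarray  # (n_channels,) weights
    onsets_s: np.ndarray
    calibration: dict  # {condition: block value of a unit clean trial}


@dataclass
class SubjectSimulation:
    recording: RawIntensityRecording
    hr: HRSeries
    record: SubjectRecord
    truth: GroundTruth


@dataclass
class Cohort:
    subjects: list[SubjectSimulation]
    config: SimulationConfig
    layout: ProbeLayout

    def group(self, name: str) -> list[SubjectSimulation]:
        return [s for s in self.subjects if s.record.group == name]


def _stimulus_train(protocol: StimulusProtocol, condition: str, n: int,
                    fs: float) -> np.ndarray:
    train = np.zeros(n)
    dur = int(round(protocol.stimulus_s * fs))
    for onset, cond in zip(protocol.onsets(), protocol.sequence):
        if cond == condition:
            i = int(np.floor(onset * fs))
            train[i:i + dur] = 1.0
    return train


def calibrate_unit_block(protocol: StimulusProtocol, layout: ProbeLayout,
                         hrf: HRFParams,
                         pp_config: PreprocessConfig | None = None) -> dict:
    """Block value per condition of a clean unit-peak response train after the
    full filtering chain (no SSR, no noise).  Used to scale regressors so
    that configured amplitudes equal realized block values."""
    fs = layout.sampling_rate
    n = int(round(protocol.total_duration_s * fs))
    kernel = hrf.kernel(fs)
    o2hb = np.zeros((len(layout.channels), n))
    for j, cond in enumerate(protocol.conditions):
        reg = np.convolve(_stimulus_train(protocol, cond, n, fs), kernel)[:n]
        o2hb[j] = reg  # one probe channel per condition
    series = HbSeries(
        o2hb=o2hb, hhb=np.zeros_like(o2hb),
        time=np.arange(n) / fs, layout=layout, protocol=protocol,
        subject=SubjectMeta("calibration", "HC", 30.0),
    )
    cfg = pp_config or PreprocessConfig()
    s = pp.sg_smooth(series, cfg.smooth_window_s, cfg.sg_order)
    s = pp.sg_detrend(s, cfg.detrend_window_s, cfg.sg_order)
    epochs = pp.segment_trials(s, pre_s=cfg.pre_s, post_s=cfg.post_s)
    epochs.epochs = [pp.detrend_normalize_epoch(e) for e in epochs.epochs]
    blocks = block_average(epochs)
    out = {}
    for j, cond in enumerate(protocol.conditions):
        cid = layout.channel_ids[j]
        val = blocks.query("condition == @cond and channel == @cid and "
                           "chromophore == 'o2hb'")["value"].item()
        if val <= 0:
            raise ValueError(f"calibration failed for condition {cond}")
        out[cond] = float(val)
    return out


def forward_model(hb: HbSeries, constants: OpticalConstants | None = None,
                  age_years: float | None = None, i0: float = 1.0
                  ) -> RawIntensityRecording:
    """Exact inverse of the analysis front-end: Hb -> dOD -> intensities."""
    constants = constants or OpticalConstants()
    layout = hb.layout
    age = age_years if age_years is not None else hb.subject.age
    E = constants.extinction_matrix(layout.wavelengths)
    dpf = np.array([compute_dpf(w, age, constants) for w in layout.wavelengths])
    n_ch = len(layout.channels)
    n_t = hb.o2hb.shape[-1]
    od = np.empty((n_ch, len(layout.wavelengths), n_t))
    conc_mM = np.stack([hb.o2hb, hb.hhb]) * 1e-3  # (2, n_ch, n_t)
    for i, cid in enumerate(layout.channel_ids):
        d_cm = layout.separation_cm(cid)
        A = E * (d_cm * dpf)[:, None]
        od[i] = A @ conc_mM[:, i]
    intensity = i0 * 10.0 ** (-od)
    return RawIntensityRecording(
        intensity=intensity, time=hb.time, layout=layout,
        protocol=hb.protocol, subject=hb.subject,
    )


def _truncated_normal(rng, mean, sd, lo, hi=np.inf):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return float(x)
    raise RuntimeError("truncated normal sampling failed")


def _scalp_component(rng, n: int, fs: float, amplitude: float) -> np.ndarray:
    """Band-limited superficial signal: smoothed noise dominated by the
    Mayer/respiratory band, scaled to the requested SD."""
    white = rng.standard_normal(n + int(10 * fs))
    # simple two-pass moving average ~ low-pass around 0.25 Hz
    w = max(int(round(fs / 0.5)), 1)
    kernel = np.ones(w) / w
    smooth = np.convolve(np.convolve(white, kernel, mode="same"), kernel,
                         mode="same")[: n]
    sd = smooth.std()
    return amplitude * smooth / sd if sd > 0 else np.zeros(n)


def simulate_subject(
    config: SimulationConfig,
    group: str,
    subject_index: int,
    *,
    layout: ProbeLayout | None = None,
    rng: np.random.Generator | None = None,
    calibration: dict | None = None,
    responder_mask: np.ndarray | None = None,
) -> SubjectSimulation:
    """One subject: raw intensities, 1 Hz heart rate, behavioral record, truth."""
    layout = layout or build_default_layout()
    fs = layout.sampling_rate
    config.validate(fs)
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    protocol = generate_stimulus_sequence(
        config.protocol_template(), seed=int(rng.integers(2**31 - 1))
    )
    if calibration is None:
        calibration = calibrate_unit_block(protocol, layout, config.hrf)
    n = int(round(protocol.total_duration_s * fs))
    time = np.arange(n) / fs
    n_ch = len(layout.channels)
    long_idx = np.array([layout.index(c) for c in layout.long_channel_ids])
    short_idx = np.array([layout.index(c) for c in layout.short_channel_ids])

    # responder mask over channels (True = channel carries an evoked response)
    if responder_mask is None:
        if config.responder_scope not in ("channel", "subject"):
            raise ValueError(f"unknown responder_scope {config.responder_scope!r}")
        responder_mask = np.zeros(n_ch, dtype=bool)
        responder_mask[long_idx] = rng.random(long_idx.size) < config.responder_fraction
    amp_mult = 1.0
    if config.clbp_heterogeneity and group == "CLBP":
        amp_mult = rng.choice([0.3, 1.7])  # bimodal subgrouping knob

    kernel = config.hrf.kernel(fs)
    hb = {c: np.zeros((n_ch, n)) for c in ("o2hb", "hhb")}
    amplitudes = {cond: {"o2hb": np.zeros(n_ch), "hhb": np.zeros(n_ch)}
                  for cond in protocol.conditions}
    for cond in protocol.conditions:
        reg = np.convolve(_stimulus_train(protocol, cond, n, fs), kernel)[:n]
        reg /= calibration[cond]
        a_o2 = config.amplitude_uM[cond] * amp_mult
        for i in long_idx:
            if responder_mask[i]:
                amplitudes[cond]["o2hb"][i] = a_o2
                amplitudes[cond]["hhb"][i] = a_o2 * config.hhb_ratio
                hb["o2hb"][i] += a_o2 * reg
                hb["hhb"][i] += a_o2 * config.hhb_ratio * reg

    # systemic oscillations in every channel: per-subject frequency spread and
    # slow phase diffusion (real oscillators drift; without drift the waves
    # would be exactly periodic with the 20 s trial spacing and phase-locked
    # to every epoch)
    for amp, freq in (config.mayer, config.respiration, config.cardiac):
        f = freq * rng.uniform(0.85, 1.15)
        phase0 = rng.uniform(0, 2 * np.pi)
        phase_walk = np.cumsum(rng.normal(0.0, 0.02, n))
        gains = rng.uniform(0.5, 1.5, size=n_ch)
        wave = np.sin(2 * np.pi * f * time + phase0 + phase_walk)
        hb["o2hb"] += amp * gains[:, None] * wave
        hb["hhb"] += amp * config.systemic_hhb_ratio * gains[:, None] * wave

    # superficial (scalp) component: unit weight on shorts, coupled to longs
    scalp = {c: _scalp_component(rng, n, fs, config.scalp_amplitude_uM)
             for c in ("o2hb", "hhb")}
    scalp["hhb"] = scalp["hhb"] * config.systemic_hhb_ratio
    coupling = np.zeros(n_ch)
    coupling[short_idx] = 1.0
    coupling[long_idx] = rng.uniform(*config.scalp_coupling_range,
                                     size=long_idx.size)
    for c in ("o2hb", "hhb"):
        hb[c] += coupling[:, None] * scalp[c][None, :]

    # drift + white noise
    for c in ("o2hb", "hhb"):
        hb[c] += np.cumsum(rng.normal(0.0, config.drift_scale_uM, (n_ch, n)),
                           axis=-1)
        hb[c] += rng.normal(0.0, config.noise_sd_uM, (n_ch, n))

    age = _truncated_normal(rng, config.age_mean[group], config.age_sd[group],
                            18.0, 80.0)
    subject = SubjectMeta(id=f"{group}{subject_index + 1:02d}", group=group,
                          age=age)
    series = HbSeries(o2hb=hb["o2hb"], hhb=hb["hhb"], time=time, layout=layout,
                      protocol=protocol, subject=subject)
    recording = forward_model(series, age_years=age, i0=config.i0)

    # heart rate at 1 Hz: baseline + post-offset bump + noise
    t_hr = np.arange(0.0, protocol.total_duration_s, 1.0)
    base = _truncated_normal(rng, config.hr_baseline_mean, config.hr_baseline_sd,
                             40.0, 120.0)
    bump = np.zeros_like(t_hr)
    for onset in protocol.onsets():
        o = onset + rng.uniform(-config.onset_jitter_s, config.onset_jitter_s) \
            if config.onset_jitter_s else onset
        bump += config.hr_bump_bpm * np.exp(-0.5 * ((t_hr - (o + 7.0)) / 3.0) ** 2)
    hr = base + bump + rng.normal(0.0, config.hr_noise_sd, t_hr.size)
    hr = np.clip(hr, 30.0, None)
    hr_series = HRSeries(time_s=t_hr, hr=hr, protocol=protocol)

    ppt = _truncated_normal(rng, config.ppt_mean[group], config.ppt_sd[group],
                            10.0)
    nonpain = 30.0 if group == "HC" else min(30.0, 0.6 * ppt)
    if group == "HC" and ppt <= nonpain:
        ppt = nonpain + 5.0
    record = SubjectRecord(
        id=subject.id, group=group, age=age, ppt=ppt, nonpainful_force=nonpain,
        pain_detect_current=float(rng.integers(0, 4)) if group == "CLBP" else float("nan"),
        pain_detect_ave4w=round(_truncated_normal(rng, 4.0, 0.7, 0.0, 10.0), 1)
        if group == "CLBP" else float("nan"),
        pain_detect_total=float(rng.integers(1, 15)) if group == "CLBP" else float("nan"),
        rmd=float(rng.integers(1, 12)) if group == "CLBP" else float("nan"),
    )
    truth = GroundTruth(
        amplitudes=amplitudes, responder_mask=responder_mask,
        scalp_series=scalp, scalp_coupling=coupling,
        onsets_s=protocol.onsets(), calibration=calibration,
    )
    return SubjectSimulation(recording=recording, hr=hr_series, record=record,
                             truth=truth)


def simulate_cohort(config: SimulationConfig,
                    layout: ProbeLayout | None = None) -> Cohort:
    """Both groups; seeded and bit-reproducible for a fixed config."""
    layout = layout or build_default_layout()
    rng = np.random.default_rng(config.seed)
    protocol = generate_stimulus_sequence(config.protocol_template(),
                                          seed=config.seed)
    calibration = calibrate_unit_block(protocol, layout, config.hrf)
    subjects = []
    for group, count in (("HC", config.n_hc), ("CLBP", config.n_clbp)):
        if count < 1:
            raise ValueError(f"group {group} must have at least one subject")
        # channel-scope responder mask is shared within a group
        mask = None
        if config.responder_scope == "channel":
            n_ch = len(layout.channels)
            long_idx = np.array([layout.index(c) for c in layout.long_channel_ids])
            mask = np.zeros(n_ch, dtype=bool)
            mask[long_idx] = rng.random(long_idx.size) < config.responder_fraction
        for i in range(count):
            subjects.append(
                simulate_subject(config, group, i, layout=layout, rng=rng,
                                 calibration=calibration,
                                 responder_mask=mask)
            )
    return Cohort(subjects=subjects, config=config, layout=layout)
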