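"""Light intensity -> optical density -> hemoglobin concentration changes.

Continuous-wave fNIRS measures light attenuation at two wavelengths (760 and
850 nm here).  Attenuation changes are expressed as optical density,

    dOD(t) = -log10( I(t) / I_ref ),

and converted to relative concentration changes of oxy- and deoxyhemoglobin
with the modified Beer-Lambert law

    dOD_lambda = ( eps_lambda,O2Hb * dC_O2Hb + eps_lambda,HHb * dC_HHb )
                 * d * DPF(lambda, age),

where ``d`` is the source-detector separation (cm), ``eps`` the base-10
extinction coefficients (mM^-1 cm^-1) and DPF the differential pathlength
factor, which converts the geometric separation into an effective photon path
and depends on wavelength and subject age.  With two wavelengths this is a
2x2 linear system per channel and sample; outputs are relative (delta)
concentrations in micromolar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .protocol import ProbeLayout, StimulusProtocol

#: Base-10 extinction coefficients in mM^-1 cm^-1, (O2Hb, HHb), from the
#: widely used compiled hemoglobin spectra.
DEFAULT_EXTINCTION = {
    760.0: (0.5860, 1.5485),
    850.0: (1.0580, 0.6913),
}

#: Coefficients of the general DPF(wavelength, age) closed form:
#: DPF = a + b*age**c + d3*l**3 + d2*l**2 + d1*l  (l in nm, age in years).
DEFAULT_DPF_COEFFICIENTS = (223.3, 0.05624, 0.8493, -5.723e-7, 0.001245, -0.9025)


@dataclass(frozen=True)
class SubjectMeta:
    id: str
    group: str  # "CLBP" or "HC"
    age: float  # years


@dataclass(frozen=True)
class OpticalConstants:
    """Extinction table and DPF polynomial coefficients."""

    extinction: dict[float, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EXTINCTION)
    )
    dpf_coefficients: tuple[float, ...] = DEFAULT_DPF_COEFFICIENTS

    def extinction_matrix(self, wavelengths) -> np.ndarray:
        """Rows = wavelengths, columns = (O2Hb, HHb)."""
        try:
            E = np.array([self.extinction[float(w)] for w in wavelengths], dtype=float)
        except KeyError as err:
            raise KeyError(f"no extinction coefficients for wavelength {err}") from None
        if E.shape[0] != 2:
            raise ValueError("exactly two wavelengths are required")
        if np.linalg.cond(E) > 1e8:
            raise ValueError("extinction matrix is singular or ill-conditioned")
        return E


def compute_dpf(
    wavelength_nm: float,
    age_years: float,
    constants: OpticalConstants | None = None,
    *,
    allow_extrapolation: bool = False,
) -> float:
    """Differential pathlength factor from the general closed-form equation.

    Valid for wavelengths in 690-900 nm; strictly increasing in age at a
    fixed wavelength.  Out-of-range wavelengths raise unless
    ``allow_extrapolation`` is set.
    """
    c = (constants or OpticalConstants()).dpf_coefficients
    if age_years <= 0:
        raise ValueError("age must be positive")
    if not (690.0 <= wavelength_nm <= 900.0) and not allow_extrapolation:
        raise ValueError(
            f"wavelength {wavelength_nm} nm outside 690-900 nm validity range"
        )
    a, b, g, d3, d2, d1 = c
    lam = float(wavelength_nm)
    dpf = a + b * float(age_years) ** g + d3 * lam**3 + d2 * lam**2 + d1 * lam
    if dpf <= 0:
        raise ValueError("DPF evaluated non-positive; check coefficients")
    return dpf


@dataclass
class RawIntensityRecording:
    """Per-channel, per-wavelength light intensities with protocol markers.

    ``intensity`` has shape (n_channels, n_wavelengths, n_samples) in
    arbitrary detector units (strictly positive).
    """

    intensity: np.ndarray
    time: np.ndarray  # seconds, uniform
    layout: ProbeLayout
    protocol: StimulusProtocol
    subject: SubjectMeta

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        n_ch, n_wl, n_t = self.intensity.shape
        if n_ch != len(self.layout.channels):
            raise ValueError("intensity channel axis does not match layout")
        if n_wl != len(self.layout.wavelengths):
            raise ValueError("intensity wavelength axis does not match layout")
        if n_t != self.time.size:
            raise ValueError("intensity time axis does not match time vector")
        if not np.all(self.intensity > 0):
            c, w, t = np.unravel_index(
                int(np.argmin(self.intensity)), self.intensity.shape
            )
            raise ValueError(
                "non-positive intensity at channel "
                f"{self.layout.channel_ids[c]}, wavelength "
                f"{self.layout.wavelengths[w]} nm, sample {t}"
            )


@dataclass
class ODSeries:
    """Optical density changes (base-10, dimensionless)."""

    od: np.ndarray  # (n_channels, n_wavelengths, n_samples)
    time: np.ndarray
    layout: ProbeLayout
    protocol: StimulusProtocol
    subject: SubjectMeta


@dataclass
class HbSeries:
    """Relative hemoglobin concentration changes in uM; the pipeline currency."""

    o2hb: np.ndarray  # (n_channels, n_samples)
    hhb: np.ndarray
    time: np.ndarray
    layout: ProbeLayout
    protocol: StimulusProtocol
    subject: SubjectMeta
    filtered: bool = False
    ssr_applied: bool = False

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.o2hb)) and np.all(np.isfinite(self.hhb))):
            raise ValueError("HbSeries contains non-finite values")

    def copy_with(self, o2hb=None, hhb=None, **flags) -> "HbSeries":
        return HbSeries(
            o2hb=self.o2hb if o2hb is None else o2hb,
            hhb=self.hhb if hhb is None else hhb,
            time=self.time,
            layout=self.layout,
            protocol=self.protocol,
            subject=self.subject,
            filtered=flags.get("filtered", self.filtered),
            ssr_applied=flags.get("ssr_applied", self.ssr_applied),
        )


def _reference_window(recording: RawIntensityRecording, reference: str, seconds: float | None):
    t = recording.time
    if reference == "first_n_seconds":
        if seconds is None or seconds <= 0:
            raise ValueError("reference='first_n_seconds' requires positive seconds")
        mask = t < t[0] + seconds
    else:
        # default: the pre-stimulation rest baseline
        baseline = recording.protocol.baseline_s if recording.protocol else None
        if baseline and baseline > 0:
            mask = t < t[0] + baseline
        else:
            mask = np.ones_like(t, dtype=bool)
    if not mask.any():
        raise ValueError("reference window contains no samples")
    return mask


def intensity_to_od(
    recording: RawIntensityRecording,
    reference: str = "mean",
    seconds: float | None = None,
) -> ODSeries:
    """dOD[c,w,t] = -log10( I[c,w,t] / I_ref[c,w] ).

    ``reference`` selects how I_ref is formed: "mean" or "median" over the
    rest baseline (whole recording if no baseline is defined), or
    "first_n_seconds" with an explicit window.
    """
    if reference not in ("mean", "median", "first_n_seconds"):
        raise ValueError(f"unknown reference {reference!r}")
    mask = _reference_window(recording, reference, seconds)
    window = recording.intensity[:, :, mask]
    i_ref = np.median(window, axis=-1) if reference == "median" else window.mean(axis=-1)
    od = -np.log10(recording.intensity / i_ref[:, :, None])
    return ODSeries(
        od=od,
        time=recording.time,
        layout=recording.layout,
        protocol=recording.protocol,
        subject=recording.subject,
    )


def mbll_convert(
    od: ODSeries,
    constants: OpticalConstants | None = None,
    age_years: float | None = None,
) -> HbSeries:
    """Solve the per-channel 2x2 MBLL system for dO2Hb and dHHb (uM).

    Each channel uses its own source-detector separation; the DPF uses the
    subject's age and the channel wavelength.
    """
    constants = constants or OpticalConstants()
    age = age_years if age_years is not None else od.subject.age
    layout = od.layout
    E = constants.extinction_matrix(layout.wavelengths)  # (2 wl, 2 chromo)
    dpf = np.array([compute_dpf(w, age, constants) for w in layout.wavelengths])

    n_ch, n_wl, n_t = od.od.shape
    o2hb = np.empty((n_ch, n_t))
    hhb = np.empty((n_ch, n_t))
    for i, cid in enumerate(layout.channel_ids):
        d_cm = layout.separation_cm(cid)
        if d_cm <= 0:
            raise ValueError(f"channel {cid} has no valid separation")
        # dOD_w = E @ dC * d * dpf_w  ->  dC = solve(E * (d*dpf)[:,None], dOD)
        A = E * (d_cm * dpf)[:, None]
        conc_mM = np.linalg.solve(A, od.od[i])  # (2, n_t)
        o2hb[i] = conc_mM[0] * 1e3
        hhb[i] = conc_mM[1] * 1e3
    return HbSeries(
        o2hb=o2hb,
        hhb=hhb,
        time=od.time,
        layout=layout,
        protocol=od.protocol,
        subject=od.subject,
    )
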