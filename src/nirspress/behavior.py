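"""Heart-rate trial analysis and behavioral (questionnaire / PPT) summaries.

Heart rate is sampled at 1 Hz by a chest-belt monitor and analyzed per
manually clocked trial: mean and maximum HR during each 5 s stimulus and
during the surrounding 15 s inter-stimulus intervals (pre-ISI before, post-ISI
after a stimulus).  The condition-level contrast of interest is
``delta_hr_max`` = HRmax(stimulus) - HRmax(post-ISI).

Behavioral data comprise the patients' questionnaire scores (Pain Detect,
Roland-Morris disability) and the pressure-pain thresholds (PPT, Newtons)
of both groups.  The packaged ``table1`` fixture carries the published
patient table; ``behavioral_summary`` reproduces its MEAN/SD rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd

from .protocol import StimulusProtocol
from .stats import TestResult, adjust_family, friedman_test, wilcoxon_rank_sum, \
    wilcoxon_signed_rank

TABLE1_SCORE_COLUMNS = ("pain_detect_current", "pain_detect_ave4w",
                        "pain_detect_total", "rmd")
TABLE1_INTEGER_COLUMNS = ("ppt",)


@dataclass(frozen=True)
class SubjectRecord:
    """Behavioral record of one participant."""

    id: str
    group: str  # "CLBP" or "HC"
    age: float
    ppt: float  # Newtons
    nonpainful_force: float  # Newtons; 30 N for HC, individualized lower for patients
    pain_detect_current: float = float("nan")
    pain_detect_ave4w: float = float("nan")
    pain_detect_total: float = float("nan")
    rmd: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.ppt > self.nonpainful_force > 0):
            raise ValueError(
                f"subject {self.id}: require ppt > nonpainful_force > 0 "
                f"(got {self.ppt}, {self.nonpainful_force})"
            )


def load_table1() -> pd.DataFrame:
    """The packaged published patient behavioral table (n = 12)."""
    with resources.files("nirspress.data").joinpath("table1_clbp.csv").open() as fh:
        return pd.read_csv(fh)


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def behavioral_summary(records: pd.DataFrame, display: bool = True) -> pd.DataFrame:
    """Column-wise MEAN and sample SD (n-1) in the published table layout.

    With ``display=True`` values are rounded half-up to the table's printed
    precision: integer Newtons for the PPT, one decimal for scores.  Raw
    unrounded values are returned with ``display=False``.
    """
    numeric = records.select_dtypes("number")
    if len(records) < 2:
        raise ValueError("need at least two records for a summary")
    mean = numeric.mean()
    sd = numeric.std(ddof=1)
    out = pd.DataFrame([mean, sd], index=["MEAN", "SD"])
    if display:
        for col in out.columns:
            dec = 0 if col in TABLE1_INTEGER_COLUMNS else 1
            out[col] = [_round_half_up(v, dec) for v in out[col]]
    return out


def ppt_protocol_average(readings) -> float:
    """Final PPT = arithmetic mean of the 3-4 repeated threshold readings."""
    r = np.asarray(readings, dtype=float)
    if r.size < 3:
        warnings.warn(f"only {r.size} PPT readings; protocol specifies 3-4")
    if r.size > 4:
        warnings.warn(f"{r.size} PPT readings; protocol specifies 3-4")
    return float(r.mean())


def ppt_group_compare(clbp_ppt, hc_ppt) -> TestResult:
    """One-sided unpaired rank-sum test of CLBP < HC pressure-pain thresholds."""
    res = wilcoxon_rank_sum(clbp_ppt, hc_ppt, alternative="less")
    res.extras.update(
        clbp_mean=float(np.mean(clbp_ppt)), clbp_sd=float(np.std(clbp_ppt, ddof=1)),
        hc_mean=float(np.mean(hc_ppt)), hc_sd=float(np.std(hc_ppt, ddof=1)),
    )
    return res


# --------------------------------------------------------------------------
# heart rate
# --------------------------------------------------------------------------

@dataclass
class HRSeries:
    """Beats-per-minute samples at a 1 s update interval with trial markers."""

    time_s: np.ndarray
    hr: np.ndarray
    protocol: StimulusProtocol

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.hr = np.asarray(self.hr, dtype=float)
        if self.time_s.shape != self.hr.shape:
            raise ValueError("time and hr vectors must align")
        if not np.all(self.hr > 0):
            raise ValueError("heart rate samples must be positive")


def _window_stats(t: np.ndarray, hr: np.ndarray, start: float, stop: float):
    """Mean/max over samples with timestamp in the half-open [start, stop)."""
    mask = (t >= start) & (t < stop)
    if not mask.any():
        raise ValueError(f"HR window [{start}, {stop}) contains no samples")
    return float(hr[mask].mean()), float(hr[mask].max())


def hr_trial_summaries(series: HRSeries, max_of_max: bool = False) -> pd.DataFrame:
    """Condition-level HR summaries.

    Per trial: mean and max HR during the stimulus, the pre-ISI and the
    post-ISI windows (half-open [start, end) at 1 s resolution).  Condition
    values average the per-trial numbers (including the per-trial maxima;
    set ``max_of_max`` for max-of-max instead), and
    ``delta_hr_max`` = HRmax(stimulus) - HRmax(post-ISI).
    """
    proto = series.protocol
    if not proto.sequence:
        raise ValueError("protocol carries no stimulus sequence")
    t, hr = series.time_s, series.hr
    rows = []
    onsets = proto.onsets()
    for k, (onset, cond) in enumerate(zip(onsets, proto.sequence)):
        stim = _window_stats(t, hr, onset, onset + proto.stimulus_s)
        post = _window_stats(t, hr, onset + proto.stimulus_s,
                             onset + proto.stimulus_s + proto.isi_s)
        pre_start = onset - proto.isi_s
        pre = _window_stats(t, hr, max(pre_start, t[0]), onset)
        rows.append((cond, k, stim[0], stim[1], pre[0], pre[1], post[0], post[1]))
    trials = pd.DataFrame(rows, columns=[
        "condition", "trial", "hr_mean_stim", "hr_max_stim",
        "hr_mean_pre", "hr_max_pre", "hr_mean_post", "hr_max_post",
    ])
    agg = "max" if max_of_max else "mean"
    cond_level = trials.groupby("condition").agg(
        hr_mean_stim=("hr_mean_stim", "mean"),
        hr_max_stim=("hr_max_stim", agg),
        hr_mean_pre=("hr_mean_pre", "mean"),
        hr_max_pre=("hr_max_pre", agg),
        hr_mean_post=("hr_mean_post", "mean"),
        hr_max_post=("hr_max_post", agg),
        n_trials=("trial", "size"),
    ).reset_index()
    cond_level["delta_hr_max"] = cond_level["hr_max_stim"] - cond_level["hr_max_post"]
    return cond_level


def hr_statistics(summaries: pd.DataFrame, q_threshold: float = 0.05) -> pd.DataFrame:
    """Group-level HR tests across subjects.

    Per condition: paired signed-rank of stimulus HRmax vs post-ISI HRmax
    (BH-corrected over the three conditions); plus a Friedman test over the
    three conditions' delta_hr_max.
    ``summaries`` must carry a ``subject`` column (one row per subject x
    condition, as produced by :func:`hr_trial_summaries` per subject).
    """
    conds = sorted(summaries["condition"].unique())
    results = []
    for cond in conds:
        sub = summaries[summaries["condition"] == cond].sort_values("subject")
        r = wilcoxon_signed_rank(sub["hr_max_stim"].to_numpy(),
                                 sub["hr_max_post"].to_numpy(),
                                 family="hr_stim_vs_post")
        r.extras["condition"] = cond
        results.append(r)
    adjust_family(results, q_threshold)
    wide = summaries.pivot_table(index="subject", columns="condition",
                                 values="delta_hr_max")[conds].dropna()
    fr = friedman_test(wide.to_numpy(), family="hr_delta_max")
    fr.extras["condition"] = "all"
    adjust_family([fr], q_threshold)
    rows = []
    for r in results + [fr]:
        rows.append({
            "test": r.test, "condition": r.extras.get("condition"),
            "statistic_name": r.statistic_name, "statistic": r.statistic,
            "p": r.p, "q": r.q, "significant": r.significant,
            "family": r.family, "n": r.n,
        })
    return pd.DataFrame(rows)
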