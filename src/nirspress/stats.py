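"""Block/grand averages and the nonparametric channel-wise statistics.

Summaries
---------
The *block average* is one scalar per subject, channel, condition and
chromophore: the median over the middle 2.5 s of the 5 s stimulus window,
pooled across the 15 normalized trials.  *Grand averages* are medians of the
block averages across the subjects of a group, with dispersion expressed as
the standard error of the median (SEMed = 1.2533 * SD / sqrt(n), with a
bootstrap alternative).

Tests
-----
All inference is nonparametric: Wilcoxon signed-rank (exact by enumeration
for n <= 15; the enumeration is evaluated with a subset-sum convolution,
which handles ties and is identical to summing over all 2^n sign
assignments), Wilcoxon rank-sum (exact for min(n, m) <= 10, same device over
all C(n+m, n) group assignments), the tie-corrected Friedman test, and
Spearman rank correlation.  Families of channel-wise p-values are corrected
with the Benjamini-Hochberg step-up FDR procedure; ``significant`` means
q < 0.05.

Two analysis modes mirror the dual group-level approach: ``All`` enters every
long channel into the group tests; ``Responders`` first screens each
(subject, channel, condition) with a single-subject signed-rank test on the
per-trial values (uncorrected p < 0.05) and only screened-in data enter the
group statistics, trading power for specificity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .preprocess import CHROMOPHORES, Epoch, EpochSet

SEMED_FACTOR = 1.2533  # asymptotic SE(median) = 1.2533 * SD / sqrt(n), Gaussian


@dataclass
class TestResult:
    test: str
    statistic_name: str
    statistic: float
    p: float
    q: float | None = None
    significant: bool | None = None
    family: str | None = None
    mode: str | None = None
    n: int | None = None
    extras: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# exact null distributions via subset-sum convolution
# --------------------------------------------------------------------------

def _subset_sum_counts(weights: tuple[int, ...]) -> np.ndarray:
    """counts[s] = number of subsets of ``weights`` summing to s."""
    total = int(sum(weights))
    c = np.zeros(total + 1)
    c[0] = 1.0
    for w in weights:
        if w > 0:
            c[w:] += c[:-w]
    return c


@lru_cache(maxsize=512)
def _signed_rank_cdf(doubled_ranks: tuple[int, ...]) -> np.ndarray:
    """CDF of W+ (on doubled-rank integer scale) under random signs."""
    counts = _subset_sum_counts(doubled_ranks)
    return np.cumsum(counts) / counts.sum()


@lru_cache(maxsize=512)
def _rank_sum_cdf(doubled_ranks: tuple[int, ...], n1: int) -> np.ndarray:
    """CDF of the rank sum of a random n1-subset of the combined ranks."""
    total = int(sum(doubled_ranks))
    counts = np.zeros((n1 + 1, total + 1))
    counts[0, 0] = 1.0
    for w in doubled_ranks:
        for k in range(min(n1, 1_000_000), 0, -1):
            counts[k, w:] += counts[k - 1, : counts.shape[1] - w]
    pmf = counts[n1]
    return np.cumsum(pmf) / pmf.sum()


def _two_sided_from_cdf(cdf: np.ndarray, stat2: int) -> float:
    lower = cdf[stat2]
    upper = 1.0 - (cdf[stat2 - 1] if stat2 > 0 else 0.0)
    return float(min(1.0, 2.0 * min(lower, upper)))


def _one_sided_from_cdf(cdf: np.ndarray, stat2: int, alternative: str) -> float:
    if alternative == "less":
        return float(min(1.0, cdf[stat2]))
    return float(min(1.0, 1.0 - (cdf[stat2 - 1] if stat2 > 0 else 0.0)))


def wilcoxon_signed_rank(
    x,
    y=None,
    *,
    zero_method: str = "wilcox",
    exact_max: int = 15,
    alternative: str = "two-sided",
    mode: str | None = None,
    family: str | None = None,
) -> TestResult:
    """Wilcoxon signed-rank test of ``x`` (or ``x - y``) against zero.

    Exact p by enumeration over all sign assignments for n <= ``exact_max``
    (ties in |d| handled through midranks); normal approximation with
    continuity and tie correction otherwise.  Zero differences are discarded
    by default ("wilcox"); ``zero_method="pratt"`` keeps them in the ranking.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError(f"unknown zero_method {zero_method!r}")
    nonzero = d != 0
    if not nonzero.any():
        warnings.warn("all differences are zero; signed-rank test degenerate (p=1)")
        return TestResult("wilcoxon_signed_rank", "W", 0.0, 1.0,
                          mode=mode, family=family, n=0)
    if zero_method == "wilcox":
        d = d[nonzero]
    ranks = sps.rankdata(np.abs(d))
    if zero_method == "pratt":
        keep = d != 0
        w_plus = float(ranks[(d > 0)].sum())
        ranks = ranks[keep]
        d = d[keep]
    else:
        w_plus = float(ranks[d > 0].sum())
    n = d.size
    doubled = tuple(sorted(int(round(2 * r)) for r in ranks))
    if n <= exact_max:
        cdf = _signed_rank_cdf(doubled)
        stat2 = int(round(2 * w_plus))
        if alternative == "two-sided":
            p = _two_sided_from_cdf(cdf, stat2)
        else:
            p = _one_sided_from_cdf(cdf, stat2, alternative)
        extras = {"exact": True}
    else:
        mu = sum(doubled) / 4.0  # sum(ranks)/2
        var = float(np.sum((np.asarray(doubled) / 2.0) ** 2)) / 4.0
        sd = np.sqrt(var)
        cc = 0.5 * np.sign(w_plus - mu)
        z = (w_plus - mu - cc) / sd if sd > 0 else 0.0
        if alternative == "two-sided":
            p = float(2 * sps.norm.sf(abs(z)))
        elif alternative == "greater":
            p = float(sps.norm.sf(z))
        else:
            p = float(sps.norm.cdf(z))
        extras = {"exact": False, "z": float(z)}
    return TestResult("wilcoxon_signed_rank", "W", w_plus, min(p, 1.0),
                      mode=mode, family=family, n=n, extras=extras)


def wilcoxon_rank_sum(
    a,
    b,
    *,
    exact_max: int = 10,
    alternative: str = "two-sided",
    mode: str | None = None,
    family: str | None = None,
) -> TestResult:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) test.

    Statistic is the rank sum of the first sample.  Exact enumeration over
    group assignments for min(n, m) <= ``exact_max`` (tie-aware); otherwise
    normal approximation with tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    w = float(ranks[:n1].sum())
    doubled = tuple(sorted(int(round(2 * r)) for r in ranks))
    if min(n1, n2) <= exact_max:
        if n1 <= n2:
            cdf = _rank_sum_cdf(doubled, n1)
            stat2 = int(round(2 * w))
            alt = alternative
        else:
            # enumerate the smaller group for speed
            cdf = _rank_sum_cdf(doubled, n2)
            stat2 = int(round(2 * float(ranks[n1:].sum())))
            alt = {"less": "greater", "greater": "less"}.get(alternative, alternative)
        if alternative == "two-sided":
            p = _two_sided_from_cdf(cdf, stat2)
        else:
            p = _one_sided_from_cdf(cdf, stat2, alt)
        extras = {"exact": True}
    else:
        n = n1 + n2
        mu = n1 * (n + 1) / 2.0
        _, tie_counts = np.unique(combined, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        sd = np.sqrt(var)
        cc = 0.5 * np.sign(w - mu)
        z = (w - mu - cc) / sd if sd > 0 else 0.0
        if alternative == "two-sided":
            p = float(2 * sps.norm.sf(abs(z)))
        elif alternative == "greater":
            p = float(sps.norm.sf(z))
        else:
            p = float(sps.norm.cdf(z))
        extras = {"exact": False, "z": float(z)}
    return TestResult("wilcoxon_rank_sum", "W", w, min(p, 1.0),
                      mode=mode, family=family, n=n1 + n2, extras=extras)


def friedman_test(values: np.ndarray, *, mode: str | None = None,
                  family: str | None = None) -> TestResult:
    """Friedman test on a complete (subjects x conditions) block table.

    Tie-corrected chi-square on within-block ranks; p from the chi-square
    distribution with k-1 degrees of freedom.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need a complete table with >=2 subjects and >=2 conditions")
    if not np.all(np.isfinite(X)):
        raise ValueError("incomplete block (non-finite values)")
    n, k = X.shape
    r = np.apply_along_axis(sps.rankdata, 1, X)
    col_sums = r.sum(axis=0)
    num = (k - 1) * float(np.sum(col_sums**2) - n**2 * k * (k + 1) ** 2 / 4.0)
    den = float(np.sum(r**2) - n * k * (k + 1) ** 2 / 4.0)
    if den == 0.0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = num / den
        p = float(sps.chi2.sf(chi2, k - 1))
    return TestResult("friedman", "chi2", chi2, p, mode=mode, family=family, n=n)


def spearman_correlation(x, y, *, mode: str | None = None,
                         family: str | None = None) -> TestResult:
    """Spearman rank correlation with tie-corrected ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need paired vectors of length >= 5")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return TestResult("spearman", "rho", float("nan"), float("nan"),
                          mode=mode, family=family, n=x.size,
                          extras={"degenerate": "constant input, rho undefined"})
    rho, p = sps.spearmanr(x, y)
    return TestResult("spearman", "rho", float(rho), float(p),
                      mode=mode, family=family, n=x.size)


def bh_fdr(p_values, q_threshold: float = 0.05):
    """Benjamini-Hochberg step-up adjusted q-values and the rejection set."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, alpha=q_threshold, method="fdr_bh")
    return q, q < q_threshold


def adjust_family(results: list[TestResult], q_threshold: float = 0.05) -> list[TestResult]:
    """Apply BH across a family of TestResults in place (skips NaN p)."""
    idx = [i for i, r in enumerate(results) if np.isfinite(r.p)]
    if idx:
        q, rej = bh_fdr([results[i].p for i in idx], q_threshold)
        for j, i in enumerate(idx):
            results[i].q = float(q[j])
            results[i].significant = bool(rej[j])
    return results


# --------------------------------------------------------------------------
# trial summaries
# --------------------------------------------------------------------------

def middle_window_slice(epoch: Epoch, start_s: float = 1.25, stop_s: float = 3.75):
    """Samples with time-from-onset in [start_s, stop_s) - the middle 2.5 s."""
    fs = epoch.fs
    start = epoch.onset_index + int(np.floor(start_s * fs))
    stop = epoch.onset_index + int(np.floor(stop_s * fs))
    if stop <= start:
        raise ValueError("middle stimulus window is empty at this sampling rate")
    return slice(start, stop)


def per_trial_values(epoch_set: EpochSet, chromophores=CHROMOPHORES) -> pd.DataFrame:
    """Median of each trial's middle 2.5 s, per channel/condition/chromophore.

    The single-subject sample: 15 values per channel and condition.
    """
    rows = []
    layout = epoch_set.layout
    for epoch in epoch_set.epochs:
        win = middle_window_slice(epoch)
        for chromo in chromophores:
            med = np.median(epoch.data(chromo)[:, win], axis=-1)
            for i, cid in enumerate(layout.channel_ids):
                rows.append((epoch.condition, epoch.trial_index, cid, chromo, med[i]))
    return pd.DataFrame(rows, columns=["condition", "trial", "channel",
                                       "chromophore", "value"])


def block_average(epoch_set: EpochSet, mode: str = "pooled_median",
                  chromophores=CHROMOPHORES) -> pd.DataFrame:
    """One scalar per channel/condition/chromophore.

    ``pooled_median`` (default): median over all middle-window samples of all
    trials.  ``median_of_trial_medians``: median of the per-trial medians.
    """
    if mode not in ("pooled_median", "median_of_trial_medians"):
        raise ValueError(f"unknown block-average mode {mode!r}")
    layout = epoch_set.layout
    rows = []
    for cond in epoch_set.conditions:
        trials = epoch_set.by_condition(cond)
        if not trials:
            raise ValueError(f"no epochs for condition {cond}")
        for chromo in chromophores:
            if mode == "pooled_median":
                stacked = np.concatenate(
                    [e.data(chromo)[:, middle_window_slice(e)] for e in trials],
                    axis=-1,
                )
                vals = np.median(stacked, axis=-1)
            else:
                per_trial = np.stack(
                    [np.median(e.data(chromo)[:, middle_window_slice(e)], axis=-1)
                     for e in trials]
                )
                vals = np.median(per_trial, axis=0)
            for i, cid in enumerate(layout.channel_ids):
                rows.append((cond, cid, chromo, vals[i], len(trials)))
    return pd.DataFrame(rows, columns=["condition", "channel", "chromophore",
                                       "value", "n_trials"])


def semed(values, method: str = "asymptotic", n_boot: int = 2000,
          seed: int | None = None) -> float:
    """Standard error of the median: 1.2533*SD/sqrt(n), or a bootstrap SE."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("SEMed needs at least two observations")
    if method == "asymptotic":
        return float(SEMED_FACTOR * np.std(x, ddof=1) / np.sqrt(x.size))
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        meds = np.median(rng.choice(x, size=(n_boot, x.size), replace=True), axis=1)
        return float(np.std(meds, ddof=1))
    raise ValueError(f"unknown SEMed method {method!r}")


def grand_average(blocks: pd.DataFrame, group: str | None = None,
                  semed_method: str = "asymptotic") -> pd.DataFrame:
    """Median across subjects per channel/condition/chromophore, with SEMed."""
    df = blocks if group is None else blocks[blocks["group"] == group]
    if df.empty:
        raise ValueError(f"no block averages for group {group!r}")
    rows = []
    for (cond, ch, chromo), sub in df.groupby(["condition", "channel", "chromophore"]):
        v = sub["value"].to_numpy()
        rows.append((group, cond, ch, chromo, float(np.median(v)),
                     semed(v, semed_method), v.size))
    return pd.DataFrame(rows, columns=["group", "condition", "channel",
                                       "chromophore", "median", "semed",
                                       "n_subjects"])


# --------------------------------------------------------------------------
# cohort-level analyses
# --------------------------------------------------------------------------

def _results_frame(results: list[TestResult], **keys) -> pd.DataFrame:
    rows = []
    for r in results:
        row = dict(keys)
        row.update(
            test=r.test, statistic_name=r.statistic_name, statistic=r.statistic,
            p=r.p, q=r.q, significant=r.significant, family=r.family,
            mode=r.mode, n=r.n,
        )
        row.update({k: v for k, v in r.extras.items() if np.isscalar(v)})
        rows.append(row)
    frame = pd.DataFrame(rows)
    # stable dtypes so concatenating all-untested families stays warning-free
    for col in ("statistic", "p", "q"):
        frame[col] = frame[col].astype(float)
    frame["significant"] = frame["significant"].astype("boolean")
    return frame


def screen_responders(per_trial: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Single-subject screening: signed-rank of per-trial values against zero.

    One row per (subject, channel, condition, chromophore) with the
    uncorrected p and the responder flag (p < alpha).
    """
    rows = []
    for (subj, ch, cond, chromo), sub in per_trial.groupby(
        ["subject", "channel", "condition", "chromophore"]
    ):
        res = wilcoxon_signed_rank(sub["value"].to_numpy())
        rows.append((subj, ch, cond, chromo, res.p, res.p < alpha))
    return pd.DataFrame(rows, columns=["subject", "channel", "condition",
                                       "chromophore", "p", "responder"])


def _filter_responders(blocks: pd.DataFrame, screening: pd.DataFrame) -> pd.DataFrame:
    key = ["subject", "channel", "condition", "chromophore"]
    merged = blocks.merge(screening[key + ["responder"]], on=key, how="left")
    return merged[merged["responder"].fillna(False)].drop(columns="responder")


def vs_baseline_tests(
    blocks: pd.DataFrame,
    layout,
    q_threshold: float = 0.05,
    mode: str = "All",
    min_n: int = 5,
) -> pd.DataFrame:
    """Group-level signed-rank of subject block averages against zero.

    One family (BH across the long channels) per group x condition x
    chromophore.  Channels with fewer than ``min_n`` contributing subjects
    are reported with NaN p and excluded from the correction.
    """
    long_ids = layout.long_channel_ids
    frames = []
    for (group, cond, chromo), sub in blocks.groupby(["group", "condition",
                                                      "chromophore"]):
        fam = f"vs_baseline/{group}/{cond}/{chromo}"
        results, meta = [], []
        for ch in long_ids:
            v = sub.loc[sub["channel"] == ch, "value"].to_numpy()
            if v.size >= min_n:
                r = wilcoxon_signed_rank(v, mode=mode, family=fam)
            else:
                r = TestResult("wilcoxon_signed_rank", "W", float("nan"),
                               float("nan"), family=fam, mode=mode, n=v.size)
            results.append(r)
            meta.append(ch)
        adjust_family(results, q_threshold)
        frame = _results_frame(results, group=group, condition=cond,
                               chromophore=chromo)
        frame["channel"] = meta
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def condition_contrasts(
    blocks: pd.DataFrame,
    layout,
    q_threshold: float = 0.05,
    mode: str = "All",
    min_n: int = 5,
) -> pd.DataFrame:
    """Friedman main effect per channel plus the three paired post-hoc
    contrasts, each BH-corrected across the long channels.

    Post-hoc contrasts are paired signed-rank tests on within-subject
    condition differences (the data are paired by subject).
    """
    long_ids = layout.long_channel_ids
    conds = sorted(blocks["condition"].unique())
    pairs = [(a, b) for i, a in enumerate(conds) for b in conds[i + 1:]]
    frames = []
    for (group, chromo), sub in blocks.groupby(["group", "chromophore"]):
        wide = sub.pivot_table(index=["subject", "channel"], columns="condition",
                               values="value")
        # Friedman needs complete triplets
        complete = wide.dropna()
        fam = f"friedman/{group}/{chromo}"
        results, meta = [], []
        for ch in long_ids:
            try:
                table = complete.xs(ch, level="channel")[list(conds)].to_numpy()
            except KeyError:
                table = np.empty((0, len(conds)))
            if table.shape[0] >= max(2, min_n):
                r = friedman_test(table, mode=mode, family=fam)
            else:
                r = TestResult("friedman", "chi2", float("nan"), float("nan"),
                               family=fam, mode=mode, n=table.shape[0])
            results.append(r)
            meta.append(ch)
        adjust_family(results, q_threshold)
        frame = _results_frame(results, group=group, chromophore=chromo,
                               contrast="main_effect")
        frame["channel"] = meta
        frames.append(frame)
        for c1, c2 in pairs:
            fam = f"posthoc/{group}/{chromo}/{c1}_vs_{c2}"
            results, meta = [], []
            for ch in long_ids:
                try:
                    w = complete.xs(ch, level="channel")
                    d = (w[c1] - w[c2]).to_numpy()
                except KeyError:
                    d = np.empty(0)
                if d.size >= min_n:
                    r = wilcoxon_signed_rank(d, mode=mode, family=fam)
                else:
                    r = TestResult("wilcoxon_signed_rank", "W", float("nan"),
                                   float("nan"), family=fam, mode=mode, n=d.size)
                results.append(r)
                meta.append(ch)
            adjust_family(results, q_threshold)
            frame = _results_frame(results, group=group, chromophore=chromo,
                                   contrast=f"{c1}_vs_{c2}")
            frame["channel"] = meta
            frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def run_analysis(
    mode: str,
    blocks: pd.DataFrame,
    per_trial: pd.DataFrame | None = None,
    *,
    layout,
    q_threshold: float = 0.05,
    screening_alpha: float = 0.05,
    min_n: int = 5,
) -> dict[str, pd.DataFrame]:
    """Group-level battery in one analysis mode.

    ``blocks``/``per_trial`` are tidy tables with columns (subject, group,
    channel, condition, chromophore, [trial,] value).  In ``Responders``
    mode a (subject, channel, condition, chromophore) cell enters the group
    tests only if its single-subject screening test was significant.
    """
    if mode not in ("All", "Responders"):
        raise ValueError(f"unknown analysis mode {mode!r}")
    screening = None
    use_blocks = blocks
    if mode == "Responders":
        if per_trial is None:
            raise ValueError("Responders mode requires per-trial values for screening")
        screening = screen_responders(per_trial, screening_alpha)
        use_blocks = _filter_responders(blocks, screening)
        if use_blocks.empty:
            warnings.warn("no channel survived responder screening; empty result set")
            return {"vs_baseline": pd.DataFrame(), "contrasts": pd.DataFrame(),
                    "screening": screening}
    out = {
        "vs_baseline": vs_baseline_tests(use_blocks, layout, q_threshold, mode, min_n),
        "contrasts": condition_contrasts(use_blocks, layout, q_threshold, mode, min_n),
    }
    if screening is not None:
        out["screening"] = screening
    return out


def between_group_compare(hc_blocks: pd.DataFrame, clbp_blocks: pd.DataFrame,
                          layout, q_threshold: float = 0.05) -> pd.DataFrame:
    """Unpaired rank-sum HC vs CLBP per channel; BH across channels within
    each condition x chromophore family."""
    long_ids = layout.long_channel_ids
    frames = []
    keys = set(map(tuple, hc_blocks[["condition", "chromophore"]].drop_duplicates()
                   .to_numpy()))
    for cond, chromo in sorted(keys):
        fam = f"between_group/{cond}/{chromo}"
        results, meta = [], []
        for ch in long_ids:
            a = hc_blocks.query("condition == @cond and chromophore == @chromo "
                                "and channel == @ch")["value"].to_numpy()
            b = clbp_blocks.query("condition == @cond and chromophore == @chromo "
                                  "and channel == @ch")["value"].to_numpy()
            if a.size and b.size:
                results.append(wilcoxon_rank_sum(a, b, family=fam))
            else:
                results.append(TestResult("wilcoxon_rank_sum", "W",
                                          float("nan"), float("nan"),
                                          family=fam, n=a.size + b.size))
            meta.append(ch)
        adjust_family(results, q_threshold)
        frame = _results_frame(results, condition=cond, chromophore=chromo)
        frame["channel"] = meta
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def patient_vs_norm(patient_per_trial: pd.DataFrame, hc_grand: pd.DataFrame,
                    layout, q_threshold: float = 0.05) -> pd.DataFrame:
    """Deviation map of one patient against the healthy-norm grand averages.

    Per channel: signed-rank of the patient's per-trial values against the HC
    grand-average scalar; BH across the long channels per condition x
    chromophore; direction = sign(patient median - HC median):
    "stronger", "weaker" or "none" when not significant.
    """
    long_ids = layout.long_channel_ids
    hc_idx = hc_grand.set_index(["condition", "channel", "chromophore"])["median"]
    frames = []
    for (cond, chromo), sub in patient_per_trial.groupby(["condition",
                                                          "chromophore"]):
        fam = f"patient_vs_norm/{cond}/{chromo}"
        results, meta = [], []
        for ch in long_ids:
            v = sub.loc[sub["channel"] == ch, "value"].to_numpy()
            ref = float(hc_idx.loc[(cond, ch, chromo)])
            r = wilcoxon_signed_rank(v - ref, family=fam)
            r.extras["delta_median"] = float(np.median(v) - ref)
            results.append(r)
            meta.append(ch)
        adjust_family(results, q_threshold)
        frame = _results_frame(results, condition=cond, chromophore=chromo)
        frame["channel"] = meta
        frame["direction"] = [
            ("stronger" if r.extras["delta_median"] > 0 else "weaker")
            if r.significant else "none"
            for r in results
        ]
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def spearman_ppt_correlation(ppt: pd.DataFrame, blocks: pd.DataFrame, layout,
                             chromophore: str = "o2hb",
                             q_threshold: float = 0.05) -> pd.DataFrame:
    """Correlate individual pressure-pain thresholds with response magnitude.

    ``ppt`` has columns (subject, ppt); correlation per channel within each
    condition, BH across the long channels.
    """
    long_ids = layout.long_channel_ids
    merged = blocks[blocks["chromophore"] == chromophore].merge(ppt, on="subject")
    frames = []
    for cond, sub in merged.groupby("condition"):
        fam = f"spearman_ppt/{cond}/{chromophore}"
        results, meta = [], []
        for ch in long_ids:
            s = sub[sub["channel"] == ch]
            if len(s) >= 5:
                results.append(spearman_correlation(s["ppt"].to_numpy(),
                                                    s["value"].to_numpy(),
                                                    family=fam))
            else:
                results.append(TestResult("spearman", "rho", float("nan"),
                                          float("nan"), family=fam, n=len(s)))
            meta.append(ch)
        adjust_family(results, q_threshold)
        frame = _results_frame(results, condition=cond, chromophore=chromophore)
        frame["channel"] = meta
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
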