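import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from nirspress.preprocess import detrend_normalize_epoch, segment_trials
from nirspress.stats import (bh_fdr, block_average, friedman_test,
                             grand_average, per_trial_values,
                             screen_responders, semed, spearman_correlation,
                             wilcoxon_rank_sum,
                             wilcoxon_signed_rank, _filter_responders,
                             run_analysis)

from conftest import make_series


# --------------------------------------------------------------------------
# enumeration oracles (independent of the package's subset-sum implementation)
# --------------------------------------------------------------------------

def signed_rank_p_enumeration(d, alternative="two-sided"):
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = d.size
    ws = np.array([
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ])
    lower = np.mean(ws <= w_obs + 1e-9)
    upper = np.mean(ws >= w_obs - 1e-9)
    if alternative == "two-sided":
        return min(1.0, 2 * min(lower, upper))
    return lower if alternative == "less" else upper


def rank_sum_p_enumeration(a, b, alternative="two-sided"):
    a, b = np.asarray(a, float), np.asarray(b, float)
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    w_obs = ranks[: a.size].sum()
    n = combined.size
    ws = np.array([
        ranks[list(idx)].sum()
        for idx in itertools.combinations(range(n), a.size)
    ])
    lower = np.mean(ws <= w_obs + 1e-9)
    upper = np.mean(ws >= w_obs - 1e-9)
    if alternative == "two-sided":
        return min(1.0, 2 * min(lower, upper))
    return lower if alternative == "less" else upper


def bh_oracle(p):
    """Hand-stepped BH: q_i = min_{j>=i} (m * p_(j) / j), step-up."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    q_sorted = p[order] * m / (np.arange(m) + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# --------------------------------------------------------------------------
# summaries
# --------------------------------------------------------------------------

@pytest.fixture(scope="module")
def epoch_set(layout, short_protocol):
    rng = np.random.default_rng(77)
    s = make_series(layout, short_protocol, rng=rng)
    es = segment_trials(s)
    es.epochs = [detrend_normalize_epoch(e) for e in es.epochs]
    return es


class TestTrialSummaries:
    def test_constant_epochs_give_constant(self, layout, short_protocol):
        s = make_series(layout, short_protocol, rng=np.random.default_rng(1))
        es = segment_trials(s)
        for e in es.epochs:
            e.o2hb = np.full_like(e.o2hb, 2.5)
            e.hhb = np.full_like(e.hhb, -1.0)
        for mode in ("pooled_median", "median_of_trial_medians"):
            blocks = block_average(es, mode=mode)
            o2 = blocks[blocks["chromophore"] == "o2hb"]["value"]
            assert (o2 == 2.5).all()

    def test_per_trial_count(self, epoch_set, short_protocol):
        pt = per_trial_values(epoch_set)
        counts = pt.groupby(["condition", "channel", "chromophore"]).size()
        assert (counts == short_protocol.trials_per_condition).all()

    def test_block_average_matches_sort_oracle(self, epoch_set, layout):
        from nirspress.stats import middle_window_slice
        blocks = block_average(epoch_set, mode="pooled_median")
        cond = "PAPain"
        for cid in (1, 9, 18):
            i = layout.index(cid)
            samples = np.sort(np.concatenate([
                e.o2hb[i, middle_window_slice(e)]
                for e in epoch_set.by_condition(cond)
            ]))
            k = samples.size
            expected = (samples[(k - 1) // 2] + samples[k // 2]) / 2.0
            got = blocks.query("condition == @cond and channel == @cid and "
                               "chromophore == 'o2hb'")["value"].item()
            assert got == pytest.approx(expected, rel=1e-12)

    def test_trial_median_mode_matches_oracle(self, epoch_set, layout):
        from nirspress.stats import middle_window_slice
        blocks = block_average(epoch_set, mode="median_of_trial_medians")
        i = layout.index(7)
        meds = sorted(
            np.median(e.o2hb[i, middle_window_slice(e)])
            for e in epoch_set.by_condition("Brush")
        )
        expected = meds[len(meds) // 2]  # odd count
        got = blocks.query("condition == 'Brush' and channel == 7 and "
                           "chromophore == 'o2hb'")["value"].item()
        assert got == pytest.approx(expected, rel=1e-12)

    def test_single_trial_modes_coincide(self, layout):
        from nirspress.protocol import StimulusProtocol, generate_stimulus_sequence
        proto = generate_stimulus_sequence(
            StimulusProtocol(baseline_s=20.0, trials_per_condition=1), seed=2
        )
        s = make_series(layout, proto, rng=np.random.default_rng(3))
        es = segment_trials(s)
        a = block_average(es, mode="pooled_median")
        b = block_average(es, mode="median_of_trial_medians")
        pd.testing.assert_frame_equal(a, b)


class TestGrandAverage:
    def test_identical_subjects(self):
        blocks = pd.DataFrame({
            "subject": [f"s{i}" for i in range(5)],
            "group": "HC", "condition": "PAPain", "channel": 1,
            "chromophore": "o2hb", "value": 0.7,
        })
        ga = grand_average(blocks, "HC")
        assert ga["median"].item() == 0.7
        assert ga["semed"].item() == 0.0

    def test_odd_n_median_is_middle_order_statistic(self):
        vals = [3.0, 1.0, 2.0, 9.0, 5.0]
        blocks = pd.DataFrame({
            "subject": [f"s{i}" for i in range(5)], "group": "HC",
            "condition": "PAPain", "channel": 1, "chromophore": "o2hb",
            "value": vals,
        })
        assert grand_average(blocks, "HC")["median"].item() == 3.0

    def test_semed_close_to_bootstrap_oracle(self, rng):
        # large n so both the sample SD and the bootstrap are stable
        x = rng.normal(0.0, 1.0, 1500)
        closed_form = semed(x)
        boots = np.median(
            rng.choice(x, size=(10_000, x.size), replace=True), axis=1
        )
        assert closed_form == pytest.approx(np.std(boots, ddof=1), rel=0.15)

    def test_semed_needs_two(self):
        with pytest.raises(ValueError):
            semed([1.0])

    def test_median_invariant_to_subject_order(self, rng):
        vals = rng.normal(0, 1, 9)
        rows = pd.DataFrame({
            "subject": [f"s{i}" for i in range(9)], "group": "HC",
            "condition": "Brush", "channel": 4, "chromophore": "o2hb",
            "value": vals,
        })
        shuffled = rows.sample(frac=1.0, random_state=1)
        assert (grand_average(rows, "HC")["median"].item()
                == grand_average(shuffled, "HC")["median"].item())


# --------------------------------------------------------------------------
# tests
# --------------------------------------------------------------------------

class TestSignedRank:
    def test_matches_enumeration_on_random_instances(self, rng):
        for _ in range(60):
            n = int(rng.integers(5, 13))
            d = rng.integers(-5, 6, n).astype(float)  # ties and zeros likely
            if np.all(d == 0):
                continue
            res = wilcoxon_signed_rank(d)
            assert res.p == pytest.approx(signed_rank_p_enumeration(d),
                                          abs=1e-12)

    def test_matches_scipy_exact_without_ties(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 13))
            d = rng.normal(0, 1, n)
            res = wilcoxon_signed_rank(d)
            ref = sps.wilcoxon(d, method="exact").pvalue
            assert res.p == pytest.approx(ref, abs=1e-12)

    def test_all_positive_minimal_p(self):
        res = wilcoxon_signed_rank(np.arange(1.0, 16.0))
        assert res.p == pytest.approx(2.0 / 2**15, abs=1e-15)

    def test_degenerate_all_zero(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = wilcoxon_signed_rank(np.zeros(8))
        assert res.p == 1.0

    def test_symmetric_sample_not_significant(self):
        res = wilcoxon_signed_rank(np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0]))
        assert res.p == 1.0

    def test_normal_approximation_close_to_exact_at_boundary(self, rng):
        d = rng.normal(0.5, 1.0, 15)
        exact = wilcoxon_signed_rank(d, exact_max=15)
        approx = wilcoxon_signed_rank(d, exact_max=10)
        assert approx.p == pytest.approx(exact.p, abs=0.02)


class TestRankSum:
    def test_matches_enumeration_on_random_instances(self, rng):
        for _ in range(40):
            n1 = int(rng.integers(3, 8))
            n2 = int(rng.integers(3, 8))
            a = rng.integers(0, 6, n1).astype(float)
            b = rng.integers(0, 6, n2).astype(float)
            res = wilcoxon_rank_sum(a, b)
            assert res.p == pytest.approx(rank_sum_p_enumeration(a, b),
                                          abs=1e-12)

    def test_matches_scipy_exact_without_ties(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, int(rng.integers(4, 9)))
            b = rng.normal(0, 1, int(rng.integers(4, 9)))
            res = wilcoxon_rank_sum(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method="exact").pvalue
            assert res.p == pytest.approx(ref, abs=1e-12)

    def test_complete_separation_minimal_p(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = a + 10.0
        res = wilcoxon_rank_sum(a, b)
        from math import comb
        assert res.p == pytest.approx(2.0 / comb(10, 5), abs=1e-15)

    def test_identical_constant_samples(self):
        res = wilcoxon_rank_sum(np.ones(6), np.ones(6))
        assert res.p == 1.0

    def test_one_sided_identical_samples_near_half(self, rng):
        x = rng.normal(0, 1, 8)
        res = wilcoxon_rank_sum(x, x, alternative="less")
        assert 0.5 <= res.p <= 0.75

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestFriedman:
    def test_identical_columns(self):
        X = np.tile(np.arange(6.0)[:, None], (1, 3))
        res = friedman_test(X)
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_maximal_effect_12_subjects(self):
        """Strictly ordered condition effect in every block: chi2 = 24,
        the maximum for k=3, n=12 without ties (closed-form rank arithmetic:
        rank sums 12/24/36)."""
        rng = np.random.default_rng(0)
        X = np.sort(rng.normal(0, 1, (12, 3)), axis=1)
        res = friedman_test(X)
        assert res.statistic == pytest.approx(24.0, abs=1e-12)
        assert res.p == pytest.approx(float(sps.chi2.sf(24.0, 2)), rel=1e-12)

    def test_matches_scipy_oracle(self, rng):
        for _ in range(20):
            X = rng.normal(0, 1, (int(rng.integers(5, 15)), 3))
            res = friedman_test(X)
            chi2, p = sps.friedmanchisquare(*(X[:, j] for j in range(3)))
            assert res.statistic == pytest.approx(chi2, rel=1e-10)
            assert res.p == pytest.approx(p, rel=1e-10)

    def test_consistent_with_permutation_oracle(self, rng):
        """Small-table p consistent with a within-block permutation null."""
        X = rng.normal(0, 1, (8, 3)) + np.array([0.0, 0.4, 0.8])
        res = friedman_test(X)
        n_perm = 4000
        count = 0
        for _ in range(n_perm):
            Xp = np.array([rng.permutation(row) for row in X])
            if friedman_test(Xp).statistic >= res.statistic - 1e-12:
                count += 1
        perm_p = count / n_perm
        assert res.p == pytest.approx(perm_p, abs=0.03)

    def test_incomplete_block_raises(self):
        X = np.array([[1.0, 2.0, np.nan], [0.0, 1.0, 2.0]])
        with pytest.raises(ValueError):
            friedman_test(X)


class TestBHFDR:
    def test_single_p_equals_q(self):
        q, rej = bh_fdr([0.03])
        assert q[0] == pytest.approx(0.03)
        assert rej[0]

    def test_hand_stepped_example(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        q, _ = bh_fdr(p)
        np.testing.assert_allclose(q, bh_oracle(p), rtol=1e-12)
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], rtol=1e-12)

    def test_all_equal_p(self):
        q, _ = bh_fdr([0.2] * 7)
        np.testing.assert_allclose(q, 0.2, rtol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=30))
    def test_matches_oracle_and_is_monotone(self, p):
        q, rej = bh_fdr(p)
        np.testing.assert_allclose(q, bh_oracle(p), rtol=1e-9, atol=1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)  # order-preserving
        assert np.all(q >= np.asarray(p) - 1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2,
                    max_size=25))
    def test_rejections_superset_of_bonferroni(self, p):
        p = np.asarray(p)
        _, bh_rej = bh_fdr(p, 0.05)
        bonf_rej = p < 0.05 / p.size
        assert np.all(bh_rej[bonf_rej])

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert spearman_correlation(x, np.exp(x)).statistic == pytest.approx(1.0)
        assert spearman_correlation(x, -x).statistic == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self, rng):
        for _ in range(15):
            x = rng.integers(0, 5, 20).astype(float)
            y = rng.integers(0, 5, 20).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            res = spearman_correlation(x, y)
            rx, ry = sps.rankdata(x), sps.rankdata(y)
            expected = np.corrcoef(rx, ry)[0, 1]
            assert res.statistic == pytest.approx(expected, rel=1e-9)

    def test_constant_input_reported_undefined(self):
        res = spearman_correlation(np.ones(8), np.arange(8.0))
        assert np.isnan(res.statistic)
        assert "degenerate" in res.extras


# --------------------------------------------------------------------------
# analysis modes
# --------------------------------------------------------------------------

def _toy_cohort_tables(rng, n_subjects=8, effect=0.0):
    """Minimal tidy tables: 3 long channels suffice for mode logic."""
    rows_b, rows_t = [], []
    for s in range(n_subjects):
        for ch in (1, 3, 4):
            for cond in ("PAPain", "PAnP", "Brush"):
                mu = effect if ch != 4 else 0.0  # channel 4 null
                trials = rng.normal(mu, 1.0, 15)
                for k, v in enumerate(trials):
                    rows_t.append((f"s{s}", "HC", ch, cond, "o2hb", k, v))
                rows_b.append((f"s{s}", "HC", ch, cond, "o2hb",
                               np.median(trials)))
    blocks = pd.DataFrame(rows_b, columns=["subject", "group", "channel",
                                           "condition", "chromophore", "value"])
    per_trial = pd.DataFrame(rows_t, columns=["subject", "group", "channel",
                                              "condition", "chromophore",
                                              "trial", "value"])
    return blocks, per_trial


class TestAnalysisModes:
    def test_responders_never_keeps_screened_out_cells(self, rng):
        blocks, per_trial = _toy_cohort_tables(rng, effect=0.5)
        screening = screen_responders(per_trial)
        kept = _filter_responders(blocks, screening)
        merged = kept.merge(
            screening, on=["subject", "channel", "condition", "chromophore"]
        )
        assert (merged["p"] < 0.05).all()

    def test_all_mode_keeps_everything(self, rng, layout):
        blocks, per_trial = _toy_cohort_tables(rng, effect=2.0)
        res = run_analysis("All", blocks, per_trial, layout=layout)
        vb = res["vs_baseline"]
        tested = vb[vb["n"] >= 5]
        assert set(tested["channel"]) == {1, 3, 4}

    def test_strong_effect_detected_null_channel_not(self, rng, layout):
        blocks, per_trial = _toy_cohort_tables(rng, n_subjects=12, effect=2.0)
        res = run_analysis("All", blocks, per_trial, layout=layout)
        vb = res["vs_baseline"].query("n >= 5")
        sig = vb[vb["significant"] == True]  # noqa: E712
        assert set(sig["channel"]) == {1, 3}

    def test_responders_empty_warns(self, rng, layout):
        blocks, per_trial = _toy_cohort_tables(rng, n_subjects=3, effect=0.0)
        # screening with pure-null tiny cohort may keep a few cells; force none
        per_trial["value"] = 0.0
        blocks["value"] = 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_analysis("Responders", blocks, per_trial, layout=layout)
        assert res["vs_baseline"].empty

    def test_unknown_mode_raises(self, rng, layout):
        blocks, per_trial = _toy_cohort_tables(rng)
        with pytest.raises(ValueError):
            run_analysis("Both", blocks, per_trial, layout=layout)


class TestGroupComparisons:
    def test_between_group_single_channel_family(self, layout, rng):
        from nirspress.stats import between_group_compare
        rows = []
        for g, n in (("HC", 10), ("CLBP", 8)):
            for s in range(n):
                rows.append((f"{g}{s}", g, 1, "PAPain", "o2hb",
                             rng.normal(0, 1)))
        blocks = pd.DataFrame(rows, columns=["subject", "group", "channel",
                                             "condition", "chromophore",
                                             "value"])
        # restrict the layout's family to one channel via a single-channel table
        hc = blocks[blocks["group"] == "HC"]
        clbp = blocks[blocks["group"] == "CLBP"]
        out = between_group_compare(hc, clbp, layout)
        row = out[out["channel"] == 1].iloc[0]
        # family members without data are NaN; channel 1 is the only tested one
        tested = out[np.isfinite(out["p"])] if out["p"].isna().any() else out
        assert row["q"] >= row["p"] - 1e-12

    def test_patient_vs_norm_identical_patient(self, layout, rng):
        from nirspress.stats import patient_vs_norm
        hc_grand = pd.DataFrame([
            (cond, ch, chromo, 0.4, 0.1, 20)
            for cond in ("PAPain", "PAnP", "Brush")
            for ch in layout.channel_ids
            for chromo in ("o2hb", "hhb")
        ], columns=["condition", "channel", "chromophore", "median", "semed",
                    "n_subjects"])
        rows = []
        for cond in ("PAPain", "PAnP", "Brush"):
            for ch in layout.channel_ids:
                for chromo in ("o2hb", "hhb"):
                    for k in range(15):
                        # symmetric around the HC median -> no deviation
                        rows.append(("p1", "CLBP", ch, cond, chromo, k,
                                     0.4 + 0.01 * (-1) ** k * (1 + k % 7)))
        pt = pd.DataFrame(rows, columns=["subject", "group", "channel",
                                         "condition", "chromophore", "trial",
                                         "value"])
        out = patient_vs_norm(pt, hc_grand, layout)
        assert (out["direction"] == "none").all()
        # map covers 16 long channels x 3 conditions x 2 chromophores
        assert len(out) == 16 * 3 * 2

    def test_spearman_ppt_family_correction(self, layout, rng):
        from nirspress.stats import spearman_ppt_correlation
        subjects = [f"s{i}" for i in range(12)]
        ppt = pd.DataFrame({"subject": subjects,
                            "ppt": rng.uniform(20, 80, 12)})
        rows = []
        for s_i, s in enumerate(subjects):
            for ch in layout.channel_ids:
                rows.append((s, "HC", ch, "PAPain", "o2hb", rng.normal()))
        blocks = pd.DataFrame(rows, columns=["subject", "group", "channel",
                                             "condition", "chromophore",
                                             "value"])
        out = spearman_ppt_correlation(ppt, blocks, layout)
        assert len(out) == 16
        assert (out["q"] >= out["p"] - 1e-12).all()
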