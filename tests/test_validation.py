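import numpy as np
import pytest

from emaplink import (
    EMapMatrix,
    EpistasisThresholds,
    accuracy_report,
    leave_one_out,
    precision_recall,
    threshold_sweep,
)
from emaplink.validation import PairedRecord, PairedScores, evaluate_candidates, loo_candidates, pearson
from ._oracles import bf_leave_one_out, random_screens


def paired(obs, pred, t=0.6):
    return PairedScores(
        [
            PairedRecord(o, p, (f"a{k}", f"b{k}"), t)
            for k, (o, p) in enumerate(zip(obs, pred))
        ]
    )


class TestAccuracyReport:
    def test_perfect_prediction(self):
        rep = accuracy_report(paired([-3.0, 0.0, 4.0, 1.0], [-3.0, 0.0, 4.0, 1.0]))
        assert rep.r_obs_pred == 1.0
        assert rep.nrmse == 0.0
        off_diag = rep.confusion.to_numpy().sum() - np.trace(rep.confusion.to_numpy())
        assert off_diag == 0

    def test_hand_computed_r_and_nrmse(self):
        # r and NRMSE from their definitions evaluated directly
        obs = np.array([0.0, 2.0, 4.0])
        pred = np.array([0.0, 2.0, 10.0])
        rep = accuracy_report(paired(obs, pred))
        cov = ((obs - obs.mean()) * (pred - pred.mean())).sum()
        r_direct = cov / np.sqrt(
            ((obs - obs.mean()) ** 2).sum() * ((pred - pred.mean()) ** 2).sum()
        )
        assert rep.r_obs_pred == pytest.approx(r_direct, abs=1e-12)
        assert rep.r_obs_pred == pytest.approx(0.9449, abs=1e-4)
        nrmse_direct = np.sqrt(np.mean((pred - obs) ** 2)) / obs.std(ddof=1)
        assert rep.nrmse == pytest.approx(nrmse_direct, abs=1e-12)
        assert rep.nrmse == pytest.approx(np.sqrt(12.0) / 2.0, abs=1e-12)

    def test_polarity_switch_lands_in_corner_cell(self):
        rep = accuracy_report(paired([-3.0, -4.0, 1.0], [3.0, -4.0, 1.0]))
        assert rep.confusion.at["negative", "positive"] == 1

    def test_confusion_total_equals_record_count(self):
        rng = np.random.default_rng(0)
        obs = rng.normal(0, 3, 50)
        pred = obs + rng.normal(0, 1, 50)
        rep = accuracy_report(paired(obs, pred))
        assert rep.confusion.to_numpy().sum() == rep.n == 50

    def test_constant_observed_vector_degenerates(self):
        rep = accuracy_report(paired([1.0, 1.0, 1.0], [0.0, 1.0, 2.0]))
        assert rep.r_obs_pred is None
        assert rep.nrmse is None

    def test_nrmse_shift_and_scale_invariance(self):
        rng = np.random.default_rng(1)
        obs = rng.normal(0, 2, 30)
        pred = obs + rng.normal(0, 1, 30)
        base = accuracy_report(paired(obs, pred)).nrmse
        shifted = accuracy_report(paired(obs + 7.0, pred + 7.0)).nrmse
        scaled = accuracy_report(paired(obs * 3.0, pred * 3.0)).nrmse
        assert shifted == pytest.approx(base, rel=1e-9)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_pearson_helper_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(2)
        x = rng.normal(size=25)
        y = 0.3 * x + rng.normal(size=25)
        assert pearson(x, y) == pytest.approx(stats.pearsonr(x, y).statistic, abs=1e-12)


class TestLeaveOneOut:
    def test_duplicate_profile_fixture_recovers_exactly(self, dup_truth):
        loo = leave_one_out(
            dup_truth.screen_a, dup_truth.screen_b, threshold=1.0, min_support=5
        )
        assert len(loo) > 100
        assert all(r.predicted == r.observed for r in loo.records)
        rep = accuracy_report(loo)
        assert rep.r_obs_pred == 1.0
        assert rep.nrmse == 0.0

    def test_no_record_when_no_anchor_qualifies(self, dup_truth):
        # impossible support requirement leaves nothing predictable
        loo = leave_one_out(
            dup_truth.screen_a, dup_truth.screen_b, threshold=0.5, min_support=10_000
        )
        assert len(loo) == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_incremental_downdate_matches_brute_force(self, seed):
        # the O(k) withholding update must agree with full recomputation
        a, b = random_screens(seed, n_shared=6, n_a=5, n_b=5, missing=0.25)
        loo = leave_one_out(a, b, threshold=0.3, min_support=3)
        oracle = bf_leave_one_out(a, b, 0.3, 3)
        got = {}
        for r in loo.records:
            gene, anchor = r.pair
            screen = "A" if gene in set(a.alleles) - set(b.alleles) else "B"
            got[(screen, gene, anchor)] = r.predicted
        assert set(got) == set(oracle)
        for key, value in got.items():
            assert value == pytest.approx(oracle[key], abs=1e-10)


class TestThresholdSweep:
    @pytest.mark.parametrize("seed", range(3))
    def test_identical_to_independent_runs(self, seed):
        a, b = random_screens(seed, n_shared=7, n_a=6, n_b=6, missing=0.2)
        thresholds = [0.2, 0.4, 0.6, 0.8]
        reports = threshold_sweep(a, b, thresholds, min_support=3)
        for t, rep in zip(thresholds, reports):
            solo = accuracy_report(leave_one_out(a, b, t, min_support=3))
            assert rep.n == solo.n
            assert rep.r_obs_pred == solo.r_obs_pred
            assert rep.nrmse == solo.nrmse
            assert rep.confusion.equals(solo.confusion)

    def test_record_count_non_increasing_in_threshold(self, dup_truth):
        reports = threshold_sweep(
            dup_truth.screen_a, dup_truth.screen_b, [0.2, 0.6, 0.95], min_support=5
        )
        ns = [r.n for r in reports]
        assert ns == sorted(ns, reverse=True)

    def test_duplicate_fixture_perfect_at_every_threshold(self, dup_truth):
        reports = threshold_sweep(
            dup_truth.screen_a, dup_truth.screen_b, [0.9, 0.95, 1.0], min_support=5
        )
        for rep in reports:
            assert rep.r_obs_pred == 1.0
            assert rep.nrmse == 0.0


class TestPrecisionRecall:
    def gold(self):
        return EMapMatrix.from_pairs(
            ["a1", "b1", "a2", "b2", "a3", "b3"],
            {
                ("a1", "b1"): -5.0,
                ("a2", "b2"): -4.0,
                ("a3", "b3"): 0.0,
            },
            name="gold",
        )

    def test_perfect_match(self):
        pairs = paired([0.0], [0.0])
        pairs.records = [
            PairedRecord(-5.0, -5.0, ("a1", "b1"), 0.6),
            PairedRecord(0.0, 0.0, ("a3", "b3"), 0.6),
        ]
        pr = precision_recall(pairs, self.gold())
        assert pr["negative"].precision == 1.0
        assert pr["negative"].recall == 1.0
        assert pr["neutral"].precision == 1.0

    def test_half_precision_half_recall(self):
        # two predicted negatives, one truly negative; one further true
        # negative predicted neutral -> precision 0.5, recall 0.5
        pairs = PairedScores(
            [
                PairedRecord(-5.0, -6.0, ("a1", "b1"), 0.6),
                PairedRecord(0.0, -3.0, ("a3", "b3"), 0.6),
                PairedRecord(-4.0, 0.0, ("a2", "b2"), 0.6),
            ]
        )
        pr = precision_recall(pairs, self.gold())
        assert pr["negative"].precision == 0.5
        assert pr["negative"].recall == 0.5

    def test_degenerate_positive_class(self):
        gold = EMapMatrix.from_pairs(
            ["a1", "b1"], {("a1", "b1"): 5.0}, name="gold"
        )
        pairs = PairedScores([PairedRecord(5.0, 0.0, ("a1", "b1"), 0.6)])
        pr = precision_recall(pairs, gold)
        assert pr["positive"].precision is None
        assert pr["positive"].recall == 0.0

    def test_zero_overlap_warns_and_returns_empty(self):
        gold = EMapMatrix.from_pairs(["x", "y"], {("x", "y"): 1.0}, name="gold")
        pairs = PairedScores([PairedRecord(0.0, 0.0, ("a1", "b1"), 0.6)])
        with pytest.warns(UserWarning):
            assert precision_recall(pairs, gold) == {}
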