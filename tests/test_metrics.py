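import numpy as np
import pytest

from splicescan.genome_scanner import PredictionTrack
from splicescan.metrics import (
    GeneSiteEvaluation,
    aggregate_rows,
    as_percent,
    classification_report,
    evaluate_gene_sites,
    false_positive_pct,
    site_level_accuracy,
    top_k_accuracy,
    top_percent_accuracy,
)


def track_from_donor_probs(donor, gene_id="t"):
    donor = np.asarray(donor, dtype=float)
    rest = 1.0 - donor
    return PredictionTrack(
        gene_id=gene_id,
        probabilities=np.stack([donor, rest * 0.25, rest * 0.75], axis=1),
    )


def synthetic_call_track(length, called_positions, call_probs=None, gene_id="t"):
    """Track where exactly ``called_positions`` have donor argmax."""
    probs = np.tile([0.01, 0.01, 0.98], (length, 1))
    called_positions = list(called_positions)
    if call_probs is None:
        call_probs = [0.9 - 1e-6 * i for i in range(len(called_positions))]
    for pos, p in zip(called_positions, call_probs):
        probs[pos] = [p, (1 - p) * 0.1, (1 - p) * 0.9]
    return PredictionTrack(gene_id=gene_id, probabilities=probs)


class TestClassificationReport:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        probs = np.eye(3)[y] * 0.97 + 0.01
        report = classification_report(y, probs)
        assert report.accuracy == 1.0
        for stats in report.per_class.values():
            assert stats.recall == 1.0
            assert stats.precision == 1.0
            assert stats.specificity == 1.0
            assert stats.f1 == 1.0
        assert report.roc_auc == 1.0
        assert report.pr_auc == 1.0

    def test_hand_counted_confusion_on_12_windows(self):
        # true: 4 donor, 4 acceptor, 4 other
        # predicted: donors -> 3 donor, 1 acceptor; acceptors -> 2 acceptor,
        # 2 other; others -> 4 other
        y = np.array([0] * 4 + [1] * 4 + [2] * 4)
        pred = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2, 2, 2, 2])
        probs = np.eye(3)[pred] * 0.85 + 0.05
        report = classification_report(y, probs)
        np.testing.assert_array_equal(
            report.confusion, [[3, 1, 0], [0, 2, 2], [0, 0, 4]]
        )
        assert report.accuracy == pytest.approx(9 / 12)
        donor = report.per_class["donor"]
        assert donor.recall == pytest.approx(3 / 4)
        assert donor.precision == pytest.approx(1.0)
        assert donor.specificity == pytest.approx(1.0)
        assert donor.f1 == pytest.approx(6 / 7)
        acceptor = report.per_class["acceptor"]
        assert acceptor.recall == pytest.approx(1 / 2)
        assert acceptor.precision == pytest.approx(2 / 3)
        assert acceptor.specificity == pytest.approx(7 / 8)
        other = report.per_class["other"]
        assert other.recall == pytest.approx(1.0)
        assert other.precision == pytest.approx(4 / 6)
        assert other.specificity == pytest.approx(6 / 8)

    def test_absent_class_auc_undefined_not_zero(self):
        y = np.array([0, 0, 2, 2])
        probs = np.array([[0.8, 0.1, 0.1]] * 2 + [[0.1, 0.1, 0.8]] * 2)
        report = classification_report(y, probs)
        assert report.per_class_roc_auc["acceptor"] is None
        assert report.per_class_pr_auc["acceptor"] is None
        assert report.roc_auc is not None

    def test_random_classifier_macro_auc_near_half(self):
        rng = np.random.default_rng(0)
        n = 3000
        y = rng.integers(0, 3, n)
        raw = rng.random((n, 3))
        probs = raw / raw.sum(axis=1, keepdims=True)
        report = classification_report(y, probs)
        assert report.roc_auc == pytest.approx(0.5, abs=0.05)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classification_report([0, 1], np.array([[1.0, 0.0, 0.0]]))


class TestTopK:
    def test_all_true_sites_ranked_first(self):
        track = track_from_donor_probs([0.9, 0.95, 0.1, 0.2, 0.05])
        assert top_k_accuracy(track, [0, 1], "donor") == 1.0

    def test_six_of_seven_in_top_seven(self):
        # 7 true sites; 6 occupy the top ranks, rank 7 is a non-site
        donor = np.concatenate([
            np.linspace(0.99, 0.94, 6),    # true sites 0..5
            [0.93],                         # position 6: non-site in top 7
            [0.5],                          # position 7: the 7th true site
            np.full(12, 0.01),
        ])
        track = track_from_donor_probs(donor)
        truth = [0, 1, 2, 3, 4, 5, 7]
        value = top_k_accuracy(track, truth, "donor")
        assert value == pytest.approx(6 / 7)
        assert as_percent(value, decimals=0) == 86

    def test_k_zero_reported_undefined(self):
        track = track_from_donor_probs([0.5, 0.5])
        assert top_k_accuracy(track, [], "donor") is None

    def test_explicit_k_override(self):
        track = track_from_donor_probs([0.9, 0.8, 0.7, 0.1])
        assert top_k_accuracy(track, [0], "donor", k=3) == pytest.approx(1 / 3)

    def test_uniform_probabilities_match_hypergeometric_mean(self):
        # E[top-k hit fraction] under a random ranking = k / N
        rng = np.random.default_rng(42)
        n_positions, k, reps = 1000, 10, 400
        values = []
        truth = list(range(k))  # position labels are exchangeable
        for _ in range(reps):
            donor = rng.random(n_positions) * 0.5
            track = track_from_donor_probs(donor)
            values.append(top_k_accuracy(track, truth, "donor"))
        expected = k / n_positions
        se = np.sqrt(expected * (1 - expected) / (k * reps))
        assert np.mean(values) == pytest.approx(expected, abs=5 * se)


class TestTopPercent:
    def test_percent_100_always_one(self):
        track = track_from_donor_probs(np.linspace(0.9, 0.1, 20))
        assert top_percent_accuracy(track, [3, 17], "donor", 100) == 1.0

    def test_monotone_in_percent(self):
        rng = np.random.default_rng(1)
        track = track_from_donor_probs(rng.random(200) * 0.8)
        truth = rng.choice(200, 20, replace=False).tolist()
        v25 = top_percent_accuracy(track, truth, "donor", 25)
        v50 = top_percent_accuracy(track, truth, "donor", 50)
        assert v25 <= v50

    def test_brute_force_oracle_200_positions(self):
        rng = np.random.default_rng(2)
        donor = rng.random(200) * 0.9
        track = track_from_donor_probs(donor)
        truth = rng.choice(200, 15, replace=False).tolist()
        for percent in (10, 25, 50, 65, 75, 85, 95):
            m = int(np.floor(percent / 100 * 200))
            ranked = sorted(range(200), key=lambda p: (-donor[p], p))[:m]
            expected = len(set(ranked) & set(truth)) / len(truth)
            assert top_percent_accuracy(track, truth, "donor", percent) == pytest.approx(expected)

    def test_m_zero_undefined(self):
        track = track_from_donor_probs([0.5, 0.6])
        assert top_percent_accuracy(track, [0], "donor", 10) is None

    def test_percent_out_of_range(self):
        track = track_from_donor_probs([0.5])
        with pytest.raises(ValueError):
            top_percent_accuracy(track, [0], "donor", 0)


class TestFalsePositivePct:
    def test_published_row_31816(self):
        # 43 donor calls on a 31,816-nt gene, 7 true donors all recovered
        truth = list(range(100, 107))
        extra = list(range(200, 236))
        track = synthetic_call_track(31_816, truth + extra)
        assert as_percent(false_positive_pct(track, truth, "donor")) == 0.11
        assert len(track.called_positions("donor")) == 43

    def test_published_row_94761(self):
        # 86 donor calls, 26 true donors of which 25 recovered
        truth = list(range(100, 126))
        recovered = truth[:25]
        extra = list(range(500, 561))
        track = synthetic_call_track(94_761, recovered + extra)
        assert len(track.called_positions("donor")) == 86
        assert as_percent(false_positive_pct(track, truth, "donor")) == 0.06

    def test_zero_calls_gives_zero(self):
        track = synthetic_call_track(500, [])
        assert false_positive_pct(track, [5, 10], "donor") == 0.0

    def test_bounded_by_calls_over_length(self):
        track = synthetic_call_track(1000, range(0, 50))
        value = false_positive_pct(track, [1, 2, 3], "donor")
        assert 0.0 <= value <= 50 / 1000

    def test_invariant_to_call_order(self):
        calls = [5, 50, 200, 300]
        a = synthetic_call_track(400, calls, call_probs=[0.9, 0.8, 0.7, 0.6])
        b = synthetic_call_track(400, calls, call_probs=[0.6, 0.7, 0.8, 0.9])
        truth = [50]
        assert false_positive_pct(a, truth, "donor") == false_positive_pct(b, truth, "donor")


class TestSiteLevelAccuracy:
    def test_25_of_26_gives_96_15(self):
        truth = list(range(0, 260, 10))
        recovered = truth[:25]
        track = synthetic_call_track(1000, recovered)
        assert as_percent(site_level_accuracy(track, truth, "donor")) == 96.15

    def test_all_called_gives_100(self):
        truth = [10, 20, 30]
        track = synthetic_call_track(100, truth)
        assert as_percent(site_level_accuracy(track, truth, "donor")) == 100.0

    def test_brute_force_membership(self):
        rng = np.random.default_rng(3)
        calls = rng.choice(300, 40, replace=False).tolist()
        truth = rng.choice(300, 25, replace=False).tolist()
        track = synthetic_call_track(300, calls)
        expected = len(set(calls) & set(truth)) / len(set(truth))
        assert site_level_accuracy(track, truth, "donor") == pytest.approx(expected)

    def test_empty_truth_undefined(self):
        track = synthetic_call_track(100, [5])
        assert site_level_accuracy(track, [], "donor") is None


class TestEvaluationRows:
    def test_evaluate_gene_sites_fields(self):
        truth = [10, 20, 30]
        track = synthetic_call_track(200, truth + [50, 60], gene_id="geneA")
        row = evaluate_gene_sites(track, truth, "donor", percents=(50,))
        assert row.gene_id == "geneA"
        assert row.length == 200
        assert row.n_true_sites == 3
        assert row.n_predicted_sites == 5
        assert row.accuracy_pct == 100.0
        assert row.false_positive_pct == 1.0  # (5 - 3) / 200

    def test_aggregate_published_human_means(self):
        fp = [0.11, 0.14, 0.08, 0.12, 0.06, 0.13, 0.09, 0.15]
        acc = [100, 100, 100, 96.15, 96.15, 100, 100, 100]
        topk = [86, 86, 73, 77, 73, 81, 88, 86]
        rows = [
            GeneSiteEvaluation(
                gene_id=f"g{i}", length=1, n_true_sites=1, site_type="donor",
                accuracy_pct=a, top_k_pct=t, top_percent_pct={}, n_predicted_sites=0,
                false_positive_pct=f,
            )
            for i, (f, a, t) in enumerate(zip(fp, acc, topk))
        ]
        agg = aggregate_rows(rows)
        assert agg["false_positive_pct"] == 0.11
        assert agg["accuracy_pct"] == 99.04
        assert agg["top_k_pct"] == 81.25

    def test_aggregate_published_other_species_means(self):
        acc = [100, 100, 100, 100, 100, 100, 81.82, 72.73, 100, 100]
        topk = [50, 50, 79, 79, 50, 50, 55, 45, 60, 60]
        rows = [
            GeneSiteEvaluation(
                gene_id=f"g{i}", length=1, n_true_sites=1, site_type="donor",
                accuracy_pct=a, top_k_pct=t, top_percent_pct={}, n_predicted_sites=0,
                false_positive_pct=0.0,
            )
            for i, (a, t) in enumerate(zip(acc, topk))
        ]
        agg = aggregate_rows(rows)
        assert agg["accuracy_pct"] == 95.45
        assert agg["top_k_pct"] == 57.8

    def test_aggregate_skips_undefined(self):
        rows = [
            GeneSiteEvaluation(
                gene_id="a", length=1, n_true_sites=0, site_type="donor",
                accuracy_pct=None, top_k_pct=None, top_percent_pct={}, n_predicted_sites=0,
                false_positive_pct=0.5,
            ),
            GeneSiteEvaluation(
                gene_id="b", length=1, n_true_sites=1, site_type="donor",
                accuracy_pct=80.0, top_k_pct=50, top_percent_pct={}, n_predicted_sites=1,
                false_positive_pct=0.3,
            ),
        ]
        agg = aggregate_rows(rows)
        assert agg["accuracy_pct"] == 80.0
        assert agg["false_positive_pct"] == 0.4
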