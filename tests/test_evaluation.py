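import numpy as np
import pytest

from oracles import brute_confusion, brute_nearest_origin_distance
from nanofork import evaluation
from nanofork.detect import DetectRecord
from nanofork.evaluation import (
    ConfusionCounts,
    EvaluationError,
    balanced_accuracy,
    confusion_at_threshold,
    median_profile,
    origin_distance_distribution,
    pileup,
    roc_auc,
    roc_curve,
    specificity,
)
from nanofork.forks import FeatureCall


def _record(probs, read_id="r", contig="c"):
    probs = np.asarray(probs, dtype=float)
    return DetectRecord(
        read_id=read_id, contig=contig, ref_start=0, ref_end=10_000, strand="+",
        positions=np.arange(probs.size) * 4 + 8, probabilities=probs,
        sixmers=["TACGTA"] * probs.size,
    )


def _call(start, end, contig="c"):
    return FeatureCall(kind="origin", contig=contig, start=start, end=end,
                       read_id="r", score=1.0)


class TestConfusion:
    def test_hand_counted_case(self):
        c = confusion_at_threshold([_record([0.9, 0.2])], [np.array([True, False])], 0.5)
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 0, 1, 0)

    def test_threshold_one_has_no_positives(self):
        c = confusion_at_threshold([_record([0.9, 1.0])], [np.array([True, False])], 1.0)
        assert c.tp == 0 and c.fp == 0

    def test_matches_brute_force_on_random_data(self, rng):
        probs = rng.random(500)
        truths = rng.random(500) < 0.4
        for threshold in (0.1, 0.5, 0.9):
            c = confusion_at_threshold([_record(probs)], [truths], threshold)
            assert (c.tp, c.fp, c.tn, c.fn) == brute_confusion(probs, truths, threshold)

    def test_label_length_mismatch_rejected(self):
        with pytest.raises(EvaluationError, match="labels"):
            confusion_at_threshold([_record([0.5, 0.5])], [np.array([True])], 0.5)


class TestSummaryMetrics:
    def test_balanced_accuracy_hand_case(self):
        c = ConfusionCounts(tp=9, fn=1, tn=8, fp=2)
        assert balanced_accuracy(c) == pytest.approx(0.85)

    def test_specificity_is_one_without_false_positives(self):
        assert specificity(ConfusionCounts(tp=1, fn=1, tn=7, fp=0)) == 1.0

    def test_undefined_denominators_raise(self):
        with pytest.raises(EvaluationError):
            balanced_accuracy(ConfusionCounts(tp=0, fn=0, tn=5, fp=5))
        with pytest.raises(EvaluationError):
            specificity(ConfusionCounts(tp=5, fn=5, tn=0, fp=0))

    def test_negative_counts_rejected(self):
        with pytest.raises(EvaluationError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)


class TestRoc:
    def test_perfect_classifier_has_unit_area(self, rng):
        truths = rng.random(200) < 0.5
        probs = np.where(truths, 0.9, 0.1)
        points = roc_curve([_record(probs)], [truths])
        assert roc_auc(points) == pytest.approx(1.0)

    def test_random_probabilities_give_half_area(self, rng):
        probs = rng.random(20_000)
        truths = rng.random(20_000) < 0.5
        records = [_record(probs[i : i + 500]) for i in range(0, 20_000, 500)]
        labels = [truths[i : i + 500] for i in range(0, 20_000, 500)]
        assert roc_auc(roc_curve(records, labels)) == pytest.approx(0.5, abs=0.02)

    def test_endpoints_and_monotonicity(self, rng):
        probs = rng.random(300)
        truths = rng.random(300) < 0.3
        points = roc_curve([_record(probs)], [truths])
        thresholds = [p[0] for p in points]
        assert thresholds == sorted(thresholds)
        assert points[0][1:] == (1.0, 1.0)  # threshold 0: everything > 0 called
        assert points[-1][1:] == (0.0, 0.0)  # threshold 1: nothing called
        by_fpr = sorted((fpr, tpr) for _t, fpr, tpr in points)
        tprs = [t for _f, t in by_fpr]
        assert all(a <= b + 1e-12 for a, b in zip(tprs[:-1], tprs[1:]))

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        probs = rng.random(2_000)
        truths = (rng.random(2_000) < probs).astype(bool)  # informative scores
        ours = roc_auc(roc_curve([_record(probs)], [truths]))
        assert ours == pytest.approx(roc_auc_score(truths, probs), abs=1e-3)

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            roc_curve([_record([0.1, 0.9])], [np.array([True, True])])


class TestMedianProfile:
    def test_identical_records_reproduce_the_record(self):
        probs = [0.1, 0.8, 0.3]
        records = [_record(probs) for _ in range(5)]
        profile = median_profile(records)
        positions = records[0].positions + 1  # 1-based report
        assert list(profile) == positions.tolist()
        assert list(profile.values()) == pytest.approx(probs)

    def test_single_read_profile_is_that_read(self):
        record = _record([0.4, 0.6])
        profile = median_profile([record])
        assert list(profile.values()) == pytest.approx([0.4, 0.6])

    def test_mixed_constructs_rejected(self):
        with pytest.raises(EvaluationError, match="multiple"):
            median_profile([_record([0.5], contig="a"), _record([0.5], contig="b")])

    def test_empty_cohort_rejected(self):
        with pytest.raises(EvaluationError):
            median_profile([])


class TestOriginDistances:
    def test_overlapping_call_has_zero_distance(self):
        distances, skipped = origin_distance_distribution(
            [_call(100, 300)], [("c", 200, 600)]
        )
        assert distances == [0.0] and skipped == 0

    def test_hand_computed_midpoint_distance(self):
        # call midpoint 10,000; nearest origin [12,000, 12,500) starts 2 kb away
        distances, _ = origin_distance_distribution(
            [_call(9_900, 10_100)], [("c", 12_000, 12_500)]
        )
        assert distances == [2_000.0]

    def test_matches_linear_scan_oracle(self, rng):
        origins = [("c", int(s), int(s) + int(rng.integers(100, 600)))
                   for s in rng.choice(100_000, size=30, replace=False)]
        calls = [_call(int(s), int(s) + 200) for s in rng.choice(100_000, size=50)]
        distances, _ = origin_distance_distribution(calls, origins)
        expected = [
            brute_nearest_origin_distance(c.start, c.end, [(a, b) for _x, a, b in origins])
            for c in calls
        ]
        assert distances == pytest.approx(expected)

    def test_unknown_contig_skipped_and_counted(self):
        distances, skipped = origin_distance_distribution(
            [_call(0, 100, contig="other")], [("c", 10, 20)]
        )
        assert distances == [] and skipped == 1

    def test_empty_call_set_yields_empty_distribution(self):
        distances, skipped = origin_distance_distribution([], [("c", 0, 10)])
        assert distances == [] and skipped == 0

    def test_empty_known_origins_rejected(self):
        with pytest.raises(EvaluationError):
            origin_distance_distribution([_call(0, 10)], [])


class TestPileup:
    def test_call_spanning_two_bins_increments_both(self):
        counts = pileup([_call(900, 1_100)], contig_length=3_000, bin_bp=1_000)
        assert counts.tolist() == [1, 1, 0]

    def test_no_calls_gives_zero_track(self):
        assert pileup([], 5_000, 500).sum() == 0

    def test_planted_loci_are_the_highest_bins(self, rng):
        loci = [10_500, 50_500, 90_500]  # mid-bin to keep the cluster in one bin
        calls = []
        for locus in loci:
            for _ in range(20):
                jitter = int(rng.integers(-200, 200))
                calls.append(_call(locus + jitter - 200, locus + jitter + 200))
        for _ in range(10):  # background
            s = int(rng.integers(0, 99_000))
            calls.append(_call(s, s + 500))
        counts = pileup(calls, 100_000, 1_000)
        top3 = set(np.argsort(counts)[-3:].tolist())
        assert top3 == {locus // 1_000 for locus in loci}
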