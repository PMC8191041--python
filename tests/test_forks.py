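import numpy as np
import pytest

from oracles import brute_merge_runs
from nanofork.detect import DetectRecord
from nanofork.forks import (
    FeatureCall,
    ForkNetConfig,
    ForkTrack,
    bin_track,
    build_fork_model,
    call_fork_segments,
    filter_reads_for_calling,
    match_forks,
    train_forks,
)


def _track(positions, p_left, p_right):
    return ForkTrack(read_id="r", contig="c", strand="+",
                     positions=np.asarray(positions, dtype=np.int64),
                     p_left=np.asarray(p_left, dtype=float),
                     p_right=np.asarray(p_right, dtype=float))


def _segment(kind, start, end):
    return FeatureCall(kind=kind, contig="c", start=start, end=end, read_id="r", score=0.9)


def _record(read_id, length, mapq=60, n_positions=50):
    positions = np.linspace(10, length - 10, n_positions).astype(np.int64)
    positions = np.unique(positions)
    return DetectRecord(
        read_id=read_id, contig="c", ref_start=0, ref_end=length, strand="+",
        positions=positions, probabilities=np.full(positions.size, 0.1),
        sixmers=["TAAAAA"] * positions.size, mapq=mapq,
    )


class TestCallForkSegments:
    def test_all_zero_track_has_no_segments(self):
        positions = np.arange(0, 30_000, 4)
        track = _track(positions, np.zeros(positions.size), np.zeros(positions.size))
        assert call_fork_segments(track) == []

    def test_single_block_is_one_segment(self):
        positions = np.arange(0, 30_000, 4)
        p_right = ((positions >= 10_000) & (positions < 20_000)).astype(float)
        track = _track(positions, np.zeros(positions.size), p_right)
        calls = call_fork_segments(track)
        assert len(calls) == 1
        call = calls[0]
        assert call.kind == "fork_right"
        assert call.start == 10_000 and abs(call.end - 20_000) <= 4

    def test_gap_merging_matches_brute_force(self):
        rng = np.random.default_rng(3)
        positions = np.sort(rng.choice(50_000, size=4000, replace=False))
        probs = rng.random(positions.size)
        track = _track(positions, probs, np.zeros(positions.size))
        for gap_tol, min_len in [(500, 1000), (499, 1), (100, 2000)]:
            calls = call_fork_segments(track, threshold=0.7, min_length_bp=min_len,
                                       gap_tolerance=gap_tol)
            expected = brute_merge_runs(positions, probs > 0.7, gap_tol, min_len)
            assert [(c.start, c.end) for c in calls] == expected

    def test_sub_tolerance_gap_is_merged(self):
        positions = np.arange(0, 12_000, 4)
        p = (((positions < 5_000) | (positions >= 5_000 + 400)) & (positions < 12_000)).astype(float)
        track = _track(positions, p, np.zeros(positions.size))
        calls = call_fork_segments(track, gap_tolerance=500)
        assert len(calls) == 1

    def test_invalid_threshold_rejected(self):
        track = _track([0], [0.0], [0.0])
        with pytest.raises(ValueError):
            call_fork_segments(track, threshold=0.0)


class TestMatchForks:
    def test_diverging_forks_call_an_origin(self):
        calls = match_forks([_segment("fork_left", 0, 5000), _segment("fork_right", 7000, 12000)])
        assert len(calls) == 1
        assert calls[0].kind == "origin"
        assert (calls[0].start, calls[0].end) == (5000, 7000)

    def test_converging_forks_call_a_termination(self):
        calls = match_forks([_segment("fork_right", 0, 5000), _segment("fork_left", 7000, 12000)])
        assert len(calls) == 1
        assert calls[0].kind == "termination"
        assert (calls[0].start, calls[0].end) == (5000, 7000)

    def test_single_fork_yields_nothing(self):
        assert match_forks([_segment("fork_right", 0, 5000)]) == []

    def test_overlapping_diverging_segments_collapse_to_midpoint(self):
        calls = match_forks([_segment("fork_left", 0, 6000), _segment("fork_right", 5000, 12000)])
        assert len(calls) == 1
        mid = (5000 + 6000) // 2
        assert (calls[0].start, calls[0].end) == (mid - 1, mid + 1)

    def test_origin_interval_is_disjoint_from_flanking_segments(self):
        left = _segment("fork_left", 100, 5000)
        right = _segment("fork_right", 7000, 12000)
        (origin,) = match_forks([left, right])
        assert origin.start >= left.end and origin.end <= right.start


class TestReadFilter:
    def test_length_boundary_is_inclusive_at_20kb(self):
        short = _record("short", 19_999, mapq=60)
        exact = _record("exact", 20_000, mapq=20)
        kept = filter_reads_for_calling([short, exact])
        assert [r.read_id for r in kept] == ["exact"]

    def test_mapq_boundary_is_inclusive_at_20(self):
        low = _record("low", 25_000, mapq=19)
        ok = _record("ok", 25_000, mapq=20)
        kept = filter_reads_for_calling([low, ok])
        assert [r.read_id for r in kept] == ["ok"]

    def test_empty_input_yields_empty_output(self):
        assert filter_reads_for_calling([]) == []


class TestForkModel:
    def test_same_seed_builds_identical_weights(self):
        a = build_fork_model(ForkNetConfig(seed=3))
        b = build_fork_model(ForkNetConfig(seed=3))
        for (pa, _), (pb, _) in zip(a.net.params(), b.net.params()):
            np.testing.assert_array_equal(pa, pb)

    def test_fully_convolutional_over_track_lengths(self):
        model = build_fork_model()
        for n_bins in (64, 100, 257):
            x = np.random.default_rng(0).random((1, 2, n_bins))
            out = model.forward_bins(x)
            assert out.shape == (1, 2, n_bins)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ForkNetConfig(kernel=4)
        with pytest.raises(ValueError):
            ForkNetConfig(channels=0)

    def test_training_without_positive_labels_rejected(self):
        rec = _record("r", 30_000)
        truth = np.zeros(30_000, dtype=np.int8)
        model = build_fork_model()
        with pytest.raises(ValueError, match="no positive fork labels"):
            train_forks(model, [(rec, truth)])

    def test_bin_track_summarises_probabilities(self):
        rec = _record("r", 1000, n_positions=10)
        x, mask = bin_track(rec, bin_bp=100)
        assert x.shape == (2, 10)
        assert mask.sum() >= 1
        occupied = x[0][mask]
        np.testing.assert_allclose(occupied, 0.1, atol=1e-9)
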