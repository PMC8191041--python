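import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_viterbi
from nanofork.signal_align import (
    DEFAULT_TRANSITIONS,
    EMISSION_EXTRA_SD,
    Event,
    align_events,
    build_input_tensors,
    segment_events,
)
from nanofork.pore_model import expected_levels
from nanofork.simulate import SimConfig, random_sequence, simulate_read


def _noise_free_read(pore_model, length=300, rate=0.0, seed=0):
    contig = random_sequence(length + 10, np.random.default_rng(seed))
    cfg = SimConfig(substitution_rate=rate, seed=seed, noise_sd_scale=0.0, dwell_mean=1.0)
    return simulate_read(contig, (0, length), cfg, pore_model, read_index=seed)


class TestSegmentEvents:
    def test_constant_signal_is_one_event(self):
        events = segment_events(np.full(100, 95.0))
        assert len(events) == 1
        assert (events[0].start_sample, events[0].end_sample) == (0, 100)

    def test_step_boundary_location(self):
        signal = np.concatenate([np.full(50, 90.0), np.full(50, 100.0)])
        events = segment_events(signal)
        assert len(events) == 2
        assert abs(events[0].end_sample - 50) <= 2
        assert events[0].mean_current == pytest.approx(90.0)
        assert events[1].mean_current == pytest.approx(100.0)

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            segment_events(np.array([]))

    def test_events_partition_the_signal(self, rng):
        signal = rng.normal(90, 8, size=400)
        events = segment_events(signal)
        assert events[0].start_sample == 0
        assert events[-1].end_sample == 400
        for a, b in zip(events[:-1], events[1:]):
            assert a.end_sample == b.start_sample


class TestAlignEvents:
    @staticmethod
    def _perfect_events(read, pore_model):
        means, _ = expected_levels(read.sequence, read.truth_brdu, pore_model)
        return [Event(i, i + 1, float(m), 0.0) for i, m in enumerate(means)]

    def test_one_event_per_kmer_aligns_to_identity(self, pore_model):
        read = _noise_free_read(pore_model, seed=3)
        events = self._perfect_events(read, pore_model)
        alignment = align_events(events, read.sequence, pore_model)
        assert alignment.pairs == [(i, i) for i in range(len(events))]
        assert alignment.skipped_kmers == []

    def test_duplicated_event_uses_insert_state(self, pore_model):
        read = _noise_free_read(pore_model, seed=5)
        events = self._perfect_events(read, pore_model)
        ev = events[10]
        dup = (
            events[:11]
            + [Event(ev.start_sample, ev.end_sample, ev.mean_current, ev.sd_current)]
            + events[11:]
        )
        alignment = align_events(dup, read.sequence, pore_model)
        kmers = alignment.kmer_of_event().tolist()
        # the extra event stays on k-mer 10 (insert); all other pairs identity
        assert kmers == list(range(11)) + list(range(10, len(events)))
        assert alignment.skipped_kmers == []

    def test_banded_equals_exhaustive_brute_force(self, pore_model, rng):
        """Banded Viterbi reproduces an independent full dynamic programme."""
        for trial in range(8):
            length = int(rng.integers(60, 400))
            read = _noise_free_read(pore_model, length=length, rate=0.3, seed=100 + trial)
            # perturb the signal so the alignment is non-trivial
            signal = read.signal + rng.normal(0, 1.0, read.signal.size)
            events = segment_events(signal)
            alignment = align_events(events, read.sequence, pore_model, band_width=50)
            mu, sd = expected_levels(
                read.sequence, np.zeros(read.truth_brdu.size, dtype=bool), pore_model
            )
            sig = np.sqrt(sd**2 + EMISSION_EXTRA_SD**2)
            ev_means = [e.mean_current for e in events]
            logs = [float(np.log(t)) for t in DEFAULT_TRANSITIONS]
            expected_assign, _ = brute_viterbi(ev_means, mu, sig, *logs)
            assert [j for _, j in alignment.pairs] == expected_assign

    def test_unalignable_read_raises(self, pore_model):
        events = [Event(0, 10, 1000.0, 0.1)]  # current far outside any level
        alignment = align_events(events, "ACGTACGTAC", pore_model)
        assert len(alignment.pairs) == 1  # single event still places somewhere
        with pytest.raises(ValueError):
            align_events([], "ACGTACGTAC", pore_model)

    @given(seed=st.integers(0, 50))
    @settings(max_examples=10, deadline=None)
    def test_alignment_pairs_are_monotone(self, seed):
        from nanofork.pore_model import default_pore_model

        pore_model = default_pore_model()
        rng = np.random.default_rng(seed)
        read = _noise_free_read(pore_model, length=int(rng.integers(50, 200)),
                                rate=0.5, seed=seed)
        signal = read.signal + rng.normal(0, 1.5, read.signal.size)
        events = segment_events(signal)
        alignment = align_events(events, read.sequence, pore_model)
        ev_idx = [e for e, _ in alignment.pairs]
        km_idx = [k for _, k in alignment.pairs]
        assert ev_idx == sorted(ev_idx) and len(set(ev_idx)) == len(ev_idx)
        assert km_idx == sorted(km_idx)
        assert all(0 <= k < len(read.sequence) - 5 for k in km_idx)


class TestInputTensors:
    def test_edge_thymidines_are_excluded_and_counted(self, pore_model):
        read = _noise_free_read(pore_model, seed=7)
        events = segment_events(read.signal, threshold=0.5)
        alignment = align_events(events, read.sequence, pore_model)
        t_pos = read.t_positions - read.ref_start
        tensors = build_input_tensors(alignment, events, read.sequence, t_pos, pore_model)
        n_kmers = len(read.sequence) - 5
        inside = ((t_pos >= 7) & (t_pos <= n_kmers - 8)).sum()
        assert len(tensors) == inside
        assert tensors.n_excluded == t_pos.size - inside

    def test_no_thymidine_read_yields_empty_set(self, pore_model):
        seq = "ACGACGACGACGACGACGACGACGACG"
        events = [Event(i, i + 1, 90.0, 0.0) for i in range(len(seq) - 5)]
        alignment = align_events(events, seq, pore_model)
        tensors = build_input_tensors(alignment, events, seq, np.array([], dtype=int), pore_model)
        assert len(tensors) == 0

    def test_residual_features_localise_substitution(self, pore_model):
        """On a noise-free read with one BrdU, the canonical residual is zero
        outside the windows covering the analogue and non-zero at it, and the
        analogue-hypothesis residual vanishes at the substituted centre."""
        contig = random_sequence(400, np.random.default_rng(21))
        cfg = SimConfig(substitution_rate=0.0, seed=21, noise_sd_scale=0.0, dwell_mean=1.0)
        read = simulate_read(contig, (0, 300), cfg, pore_model)
        mid_t = read.t_positions[len(read.t_positions) // 2]
        read.truth_brdu[np.where(read.t_positions == mid_t)[0][0]] = True
        means, _ = expected_levels(read.sequence, read.truth_brdu, pore_model)
        events = [Event(i, i + 1, float(m), 0.0) for i, m in enumerate(means)]
        alignment = align_events(events, read.sequence, pore_model)
        t_pos = read.t_positions - read.ref_start
        tensors = build_input_tensors(alignment, events, read.sequence, t_pos, pore_model)
        centre_row = tensors.window // 2
        for i, pos in enumerate(tensors.centre_positions):
            feats = tensors.features[i]
            present = feats[:, 9] > 0
            if pos == mid_t:
                assert np.abs(feats[present, 0]).max() > 0  # canonical residual sees shift
                if present[centre_row]:
                    assert feats[centre_row, 10] == pytest.approx(0.0, abs=1e-9)
            elif abs(int(pos) - int(mid_t)) > 13:  # window rows cannot reach the analogue
                assert np.abs(feats[present, 0]).max() == pytest.approx(0.0, abs=1e-9)

    def test_tensor_shape_is_constant(self, pore_model):
        shapes = set()
        for seed in (31, 32):
            read = _noise_free_read(pore_model, seed=seed)
            events = segment_events(read.signal, threshold=0.5)
            alignment = align_events(events, read.sequence, pore_model)
            tensors = build_input_tensors(
                alignment, events, read.sequence, read.t_positions - read.ref_start, pore_model
            )
            shapes.add(tensors.features.shape[1:])
        assert len(shapes) == 1

    def test_even_window_rejected(self, pore_model):
        read = _noise_free_read(pore_model, seed=33)
        events = segment_events(read.signal, threshold=0.5)
        alignment = align_events(events, read.sequence, pore_model)
        with pytest.raises(ValueError):
            build_input_tensors(alignment, events, read.sequence,
                                read.t_positions, pore_model, window_W=14)
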