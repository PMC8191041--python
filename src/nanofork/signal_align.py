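"""Hidden Markov alignment of raw signal to the reference 6-mer sequence.

The detection network never sees raw samples directly.  For each read the
signal is first segmented into events (contiguous runs of samples from one
pore translocation state), the events are aligned to the read's reference
6-mer sequence by banded Viterbi through a linear profile HMM, and a
fixed-shape feature tensor is extracted around every candidate thymidine.

The HMM's match emissions use *canonical* expected levels only: the HMM's job
is to localise events on the reference, while discriminating BrdU from
thymidine is left entirely to the network.  Topology is a linear profile with
three moves per cell — match (next event, next k-mer), insert (extra event on
the same k-mer), and skip (k-mer with no event) — with fixed log-space
transition weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from nanofork.pore_model import PoreModel, encode_sequence, expected_levels

DEFAULT_BAND_WIDTH = 100
DEFAULT_WINDOW = 15
#: match / insert / skip transition probabilities (fixed, not trained)
DEFAULT_TRANSITIONS = (0.89, 0.05, 0.05)
#: extra emission spread (pA) pooled into every k-mer's sd so that analogue
#: shifts do not derail the alignment
EMISSION_EXTRA_SD = 2.0

N_FEATURES = 13
_SENTINEL = 0.0  # value of every feature in a missing (skipped) k-mer row
#: fixed emission spread (pA) of the aggregated event mean used by the local
#: likelihood-ratio feature; miscalibration is absorbed by the network
LLR_SIGMA = 0.6
#: neighbour thymidines marginalised by the likelihood-ratio feature (nearest
#: first; bounds the 2^m hypothesis enumeration)
LLR_MAX_NEIGHBOURS = 8


class AlignmentError(RuntimeError):
    """Raised when a read cannot be aligned (band exhausted / no valid path)."""


@dataclass
class Event:
    """A contiguous run of raw samples attributed to one translocation state."""

    start_sample: int
    end_sample: int
    mean_current: float
    sd_current: float

    @property
    def duration(self) -> int:
        return self.end_sample - self.start_sample


@dataclass
class EventAlignment:
    """Monotone assignment of events to reference k-mer indices."""

    read_id: str
    pairs: list[tuple[int, int]]
    skipped_kmers: list[int]

    def kmer_of_event(self) -> np.ndarray:
        out = np.empty(len(self.pairs), dtype=np.int64)
        for e, k in self.pairs:
            out[e] = k
        return out


@dataclass
class TensorSet:
    """Fixed-shape feature tensors for the candidate thymidines of one read.

    ``features`` has shape (n_candidates, window_W, N_FEATURES); row ``w`` of
    tensor ``i`` describes the k-mer at offset ``w - window_W//2`` from the
    k-mer starting at the candidate thymidine.  Candidates whose window falls
    off the aligned span are excluded and counted in ``n_excluded``.
    """

    centre_positions: np.ndarray
    features: np.ndarray
    window: int
    n_excluded: int

    def __len__(self) -> int:
        return len(self.centre_positions)


def segment_events(signal: np.ndarray, window: int = 2, threshold: float = 1.5) -> list[Event]:
    """Partition a signal into events at mean-shift boundaries.

    A boundary is placed between samples ``i-1`` and ``i`` where the absolute
    difference between the means of the ``window`` samples on either side
    exceeds ``threshold`` (pA) and is a local maximum of that statistic.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.size == 0:
        raise ValueError("cannot segment an empty signal")
    if signal.size < 2:
        return [Event(0, 1, float(signal[0]), 0.0)]
    n = signal.size
    w = min(window, n // 2) or 1
    cs = np.concatenate([[0.0], np.cumsum(signal)])
    # stat[i]: boundary candidate between i-1 and i, valid for i in [w, n-w]
    stat = np.zeros(n + 1)
    idx = np.arange(w, n - w + 1)
    left = (cs[idx] - cs[idx - w]) / w
    right = (cs[idx + w] - cs[idx]) / w
    stat[idx] = np.abs(right - left)
    above = stat > threshold
    # local-maximum test over a 2w-1 neighbourhood
    boundaries = []
    cand = np.flatnonzero(above)
    for i in cand:
        lo, hi = max(0, i - w + 1), min(stat.size, i + w)
        if stat[i] == stat[lo:hi].max() and (not boundaries or i - boundaries[-1] >= w):
            boundaries.append(int(i))
    edges = [0] + boundaries + [n]
    events = []
    for a, b in zip(edges[:-1], edges[1:]):
        seg = signal[a:b]
        events.append(Event(a, b, float(seg.mean()), float(seg.std())))
    return events


@njit(cache=True)
def _viterbi_band(ev_means, mu, sig, lo, hi, log_m, log_i, log_s):  # pragma: no cover
    n_events = ev_means.shape[0]
    n_kmers = mu.shape[0]
    width = 0
    for i in range(n_events):
        if hi[i] - lo[i] > width:
            width = hi[i] - lo[i]
    NEG = -1.0e30
    v_prev = np.full(width, NEG)
    v_cur = np.full(width, NEG)
    s_prev = np.full(width, NEG)
    s_arg = np.zeros(width, dtype=np.int64)
    move = np.zeros((n_events, width), dtype=np.uint8)  # 1=match 2=insert
    match_src = np.zeros((n_events, width), dtype=np.int64)

    for i in range(n_events):
        any_valid = False
        for b in range(hi[i] - lo[i]):
            j = lo[i] + b
            z = (ev_means[i] - mu[j]) / sig[j]
            emis = -0.5 * z * z - np.log(sig[j])
            if i == 0:
                val = emis + j * log_s
                v_cur[b] = val
                move[i, b] = 1
                match_src[i, b] = -1
                any_valid = True
            else:
                best = NEG
                mv = 0
                src = -1
                # match via skip-chain from previous row, predecessor k-mer < j
                jm = j - 1
                if lo[i - 1] <= jm < hi[i - 1]:
                    bm = jm - lo[i - 1]
                    if s_prev[bm] > NEG / 2:
                        cand = s_prev[bm] + log_m
                        if cand > best:
                            best = cand
                            mv = 1
                            src = s_arg[bm]
                if lo[i - 1] <= j < hi[i - 1]:
                    bi = j - lo[i - 1]
                    if v_prev[bi] > NEG / 2:
                        cand = v_prev[bi] + log_i
                        if cand > best:
                            best = cand
                            mv = 2
                            src = j
                if best > NEG / 2:
                    v_cur[b] = emis + best
                    move[i, b] = mv
                    match_src[i, b] = src
                    any_valid = True
                else:
                    v_cur[b] = NEG
        if not any_valid:
            return np.empty(0, dtype=np.int64), move, match_src, NEG
        # skip-chain for the next row: best v_cur[j'] + (j - j') * log_s
        run = NEG
        arg = -1
        for b in range(hi[i] - lo[i]):
            run = run + log_s
            if v_cur[b] > run:
                run = v_cur[b]
                arg = lo[i] + b
            s_prev[b] = run
            s_arg[b] = arg
        tmp = v_prev
        v_prev = v_cur
        v_cur = tmp

    # terminate: remaining k-mers after the last event are skipped
    best = NEG
    bestj = -1
    for b in range(hi[n_events - 1] - lo[n_events - 1]):
        j = lo[n_events - 1] + b
        val = v_prev[b] + (n_kmers - 1 - j) * log_s
        if val > best:
            best = val
            bestj = j
    if bestj < 0:
        return np.empty(0, dtype=np.int64), move, match_src, NEG

    assign = np.empty(n_events, dtype=np.int64)
    j = bestj
    for i in range(n_events - 1, -1, -1):
        assign[i] = j
        b = j - lo[i]
        if move[i, b] == 1:
            j = match_src[i, b]
        # insert keeps j
    return assign, move, match_src, best


def align_events(
    events: list[Event],
    ref_seq: str,
    model: PoreModel,
    read_id: str = "read",
    band_width: int | None = DEFAULT_BAND_WIDTH,
    transitions: tuple[float, float, float] = DEFAULT_TRANSITIONS,
) -> EventAlignment:
    """Banded Viterbi alignment of events to the reference k-mer sequence.

    ``band_width=None`` runs the exhaustive (unbanded) dynamic programme.
    Raises :class:`AlignmentError` when no monotone path survives the band.
    """
    if len(ref_seq) < 6:
        raise ValueError("reference sequence shorter than the 6-mer length")
    if not events:
        raise ValueError("cannot align an empty event list")
    n_t = ref_seq.upper().count("T")
    mu, sd = expected_levels(ref_seq.upper(), np.zeros(n_t, dtype=bool), model)
    sig = np.sqrt(sd**2 + EMISSION_EXTRA_SD**2)
    ev_means = np.array([e.mean_current for e in events], dtype=np.float64)
    n_events, n_kmers = ev_means.size, mu.size

    if band_width is None:
        band = n_kmers
    else:
        band = int(band_width)
    centre = np.round(
        np.arange(n_events) * (n_kmers - 1) / max(n_events - 1, 1)
    ).astype(np.int64)
    lo = np.maximum(centre - band, 0)
    hi = np.minimum(centre + band + 1, n_kmers)

    log_m, log_i, log_s = (float(np.log(t)) for t in transitions)
    assign, _, _, score = _viterbi_band(ev_means, mu, sig, lo, hi, log_m, log_i, log_s)
    if assign.size == 0 or score <= -1.0e29:
        raise AlignmentError(f"read {read_id!r}: no valid alignment path within the band")
    pairs = [(int(i), int(j)) for i, j in enumerate(assign)]
    used = np.zeros(n_kmers, dtype=bool)
    used[assign] = True
    skipped = [int(j) for j in np.flatnonzero(~used)]
    return EventAlignment(read_id=read_id, pairs=pairs, skipped_kmers=skipped)


@njit(cache=True)
def _local_llr(
    codes, ev_mean, present, is_t, candidates, mean_table, sigma, max_neighbours
):  # pragma: no cover - exercised via build_input_tensors
    """Per-candidate log-likelihood ratio of BrdU vs T at the centre thymidine.

    Both hypotheses marginalise the substitution state of neighbouring
    thymidines inside the six covering 6-mers (flat prior), scoring observed
    event means against the pore-model level of every joint configuration.
    """
    n_kmers = codes.shape[0]
    seq_len = is_t.shape[0]
    out = np.zeros(candidates.shape[0])
    pow5 = np.empty(6, dtype=np.int64)
    for o in range(6):
        pow5[o] = 5 ** (5 - o)
    for ci in range(candidates.shape[0]):
        p = candidates[ci]
        # neighbour thymidines within reach of a covering window, nearest first
        neigh = np.empty(max_neighbours, dtype=np.int64)
        m = 0
        for d in range(1, 6):
            for q in (p - d, p + d):
                if 0 <= q < seq_len and is_t[q] and m < max_neighbours:
                    neigh[m] = q
                    m += 1
        ll = np.full(2, -1.0e30)  # logsumexp accumulators: [T, BrdU] hypotheses
        for hyp in range(2):
            best = -1.0e30
            acc = 0.0
            # two-pass logsumexp over 2^m neighbour configurations
            scores = np.empty(1 << m)
            for combo in range(1 << m):
                s = 0.0
                for j in range(p - 5, p + 1):
                    if j < 0 or j >= n_kmers or not present[j]:
                        continue
                    code = codes[j]
                    if hyp == 1:
                        code += pow5[p - j]
                    for b in range(m):
                        q = neigh[b]
                        if (combo >> b) & 1 and j <= q <= j + 5:
                            code += pow5[q - j]
                    level = mean_table[code]
                    if level != level:  # undefined table entry (partial model)
                        continue
                    z = (ev_mean[j] - level) / sigma
                    # heavy-tailed emission: outlier component guards against
                    # misassigned or contaminated events
                    core = 0.93 * np.exp(-0.5 * z * z) / (sigma * 2.5066282746310002)
                    s += np.log(core + 0.07 / 40.0)
                scores[combo] = s
                if s > best:
                    best = s
            for combo in range(1 << m):
                acc += np.exp(scores[combo] - best)
            ll[hyp] = best + np.log(acc)
        out[ci] = ll[1] - ll[0]
    return out


def _aggregate_kmer_features(
    alignment: EventAlignment, events: list[Event], n_kmers: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Duration-weighted event mean, pooled sd, summed dwell, presence per k-mer."""
    mean = np.zeros(n_kmers)
    m2 = np.zeros(n_kmers)
    dwell = np.zeros(n_kmers)
    for e_idx, k_idx in alignment.pairs:
        ev = events[e_idx]
        d = ev.duration
        dwell[k_idx] += d
        mean[k_idx] += d * ev.mean_current
        m2[k_idx] += d * (ev.sd_current**2 + ev.mean_current**2)
    present = dwell > 0
    mean[present] /= dwell[present]
    var = np.zeros(n_kmers)
    var[present] = np.maximum(m2[present] / dwell[present] - mean[present] ** 2, 0.0)
    return mean, np.sqrt(var), dwell, present


def build_input_tensors(
    alignment: EventAlignment,
    events: list[Event],
    ref_seq: str,
    candidate_positions: np.ndarray,
    model: PoreModel,
    window_W: int = DEFAULT_WINDOW,
) -> TensorSet:
    """Fixed-shape per-thymidine feature tensors from an event alignment.

    ``candidate_positions`` are 0-based offsets into ``ref_seq`` (normally its
    thymidines).  Each tensor covers ``window_W`` consecutive k-mers centred
    on the k-mer starting at the candidate; candidates whose window does not
    fit inside the aligned span are excluded and counted.

    Per-k-mer feature rows: [canonical current difference (event - expected,
    pA), event sd (pA), log1p(dwell), scaled expected level, expected sd,
    one-hot base at the k-mer start (4), presence flag, analogue-hypothesis
    current difference (event - expected with the centre T as BrdU; only for
    the six k-mers covering the centre), covers-centre flag].

    The paired canonical/analogue residuals let the network discriminate by
    model comparison: at a substituted centre the analogue residual of the
    covering k-mers is near zero while the canonical one carries the shift,
    and vice versa at a canonical centre.
    """
    if window_W % 2 != 1:
        raise ValueError("window_W must be odd")
    ref_seq = ref_seq.upper()
    symbols = encode_sequence(ref_seq)
    n_kmers = len(ref_seq) - 5
    codes = np.zeros(n_kmers, dtype=np.int64)
    for j in range(6):
        codes += symbols[j : j + n_kmers] * 5 ** (5 - j)
    exp_mean = model.mean[codes]
    exp_sd = model.sd[codes]
    if np.isnan(exp_mean).any():
        raise ValueError("pore model incomplete for this reference sequence")
    ev_mean, ev_sd, dwell, present = _aggregate_kmer_features(alignment, events, n_kmers)

    feat = np.zeros((n_kmers, N_FEATURES), dtype=np.float64)
    feat[present, 0] = ev_mean[present] - exp_mean[present]
    feat[present, 1] = ev_sd[present]
    feat[present, 2] = np.log1p(dwell[present])
    feat[present, 3] = (exp_mean[present] - 90.0) / 30.0
    feat[present, 4] = exp_sd[present]
    base_idx = {"A": 5, "C": 6, "G": 7, "T": 8}
    starts = np.frombuffer(ref_seq[:n_kmers].encode(), dtype=np.uint8)
    for base, col in base_idx.items():
        feat[present & (starts == ord(base)), col] = 1.0
    feat[present, 9] = 1.0

    half = window_W // 2
    candidates = np.asarray(candidate_positions, dtype=np.int64)
    ok = (candidates - half >= 0) & (candidates + half <= n_kmers - 1)
    kept = candidates[ok]
    n_excluded = int((~ok).sum())
    if kept.size == 0:
        return TensorSet(kept, np.zeros((0, window_W, N_FEATURES)), window_W, n_excluded)
    if (symbols[kept] != 3).any():
        bad = int(kept[int(np.argmax(symbols[kept] != 3))])
        raise ValueError(f"candidate position {bad} is not a thymidine")
    windows = kept[:, None] + np.arange(-half, half + 1)[None, :]
    features = feat[windows]

    # analogue-hypothesis residual for the 6 k-mers covering the centre T
    for offset in range(6):
        j = kept - offset  # k-mer starting offset bases left of the centre
        w = half - offset
        alt_codes = codes[j] + 5 ** (5 - offset)  # digit T -> B at the centre
        alt_mean = model.mean[alt_codes]
        features[:, w, 10] = (ev_mean[j] - alt_mean) * present[j]
        features[:, w, 11] = 1.0

    # centre-row feature 12: marginalised BrdU-vs-T log-likelihood ratio
    llr = _local_llr(
        codes,
        ev_mean,
        present,
        symbols == 3,
        kept,
        model.mean,
        LLR_SIGMA,
        LLR_MAX_NEIGHBOURS,
    )
    features[:, half, 12] = np.clip(llr, -30.0, 30.0) / 10.0
    return TensorSet(kept, features, window_W, n_excluded)
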