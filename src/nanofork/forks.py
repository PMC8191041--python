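"""Replication-fork direction, origin and termination calling from BrdU tracks.

A convolutional encoder-decoder reads each molecule's per-thymidine BrdU
probability track and outputs, per position, the probability that a
leftward-moving and a rightward-moving replication fork passed during the
BrdU pulse.  Fork direction is encoded in the changing BrdU frequency along
the molecule (a rising ramp in G1-release experiments, a plateau followed by
an exponential chase decay in pulse-chase experiments), so the network is a
sequence-to-sequence labeller trained supervised on simulator truth.

Internally the track is summarised into fixed-width genomic bins (mean BrdU
probability + thymidine occupancy per bin) before entering the network; the
per-position probabilities of the :class:`ForkTrack` are restored by
expansion.  Binning gives the network a multi-kilobase receptive field at
desk-scale cost.

Origins are called as the interval between a leftward-fork segment and the
rightward-fork segment diverging from it; termination sites as the interval
between converging fork segments.  Calling has no required tuning: the
segment threshold (0.5), minimum segment span (1 kb) and gap tolerance
(500 bp) are frozen defaults, reachable only through keyword arguments.
A read filter (mapping length >= 20 kb, MAPQ >= 20) gates which reads are
used for calling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from nanofork import _nn
from nanofork.detect import DetectRecord
from nanofork.simulate import FORK_LABEL_LEFT, FORK_LABEL_RIGHT

BIN_BP = 100
#: frozen calling defaults (deliberately not surfaced as CLI flags)
CALL_THRESHOLD = 0.5
MIN_SEGMENT_BP = 1000
GAP_TOLERANCE_BP = 500

MIN_MAPPING_LENGTH = 20_000
MIN_MAPQ = 20


@dataclass
class ForkTrack:
    """Per-position left/right fork-passage probabilities for one read."""

    read_id: str
    contig: str
    strand: str
    positions: np.ndarray
    p_left: np.ndarray
    p_right: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.positions) == len(self.p_left) == len(self.p_right)):
            raise ValueError("positions, p_left and p_right must share a length")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class FeatureCall:
    """An origin/termination/fork interval called on a single read."""

    kind: str  # origin | termination | fork_left | fork_right
    contig: str
    start: int
    end: int
    read_id: str
    score: float

    def __post_init__(self) -> None:
        if self.kind not in ("origin", "termination", "fork_left", "fork_right"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.end <= self.start:
            raise ValueError(f"empty interval [{self.start}, {self.end})")


@dataclass
class ForkNetConfig:
    """Architecture of the fork-direction encoder-decoder."""

    channels: int = 24
    kernel: int = 5
    seed: int = 7
    bin_bp: int = BIN_BP

    def __post_init__(self) -> None:
        if self.kernel % 2 != 1:
            raise ValueError("kernel must be odd")
        if self.channels < 1 or self.bin_bp < 1:
            raise ValueError("channels and bin_bp must be >= 1")


class ForkModel:
    """Fully convolutional encoder-decoder over binned BrdU tracks.

    Two input channels (mean BrdU probability, thymidine occupancy) map to
    two per-bin sigmoid outputs (leftward / rightward fork passage).  The
    encoder downsamples by 4; dilated middle blocks widen the receptive field
    to ~15 kb; the decoder restores bin resolution.
    """

    DOWN_FACTOR = 4

    def __init__(self, config: ForkNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c, k = config.channels, config.kernel

        def block(dilation=1, stride=1, c_in=c):
            return [
                _nn.Conv1D(c_in, c, k, rng, stride=stride, dilation=dilation),
                _nn.BatchNorm1D(c),
                _nn.ReLU(),
            ]

        def res_block(dilation):
            return _nn.Residual(
                _nn.Sequential(
                    [
                        _nn.Conv1D(c, c, k, rng, dilation=dilation),
                        _nn.Conv1D(c, c, 1, rng),
                        _nn.BatchNorm1D(c),
                        _nn.ReLU(),
                    ]
                )
            )

        self.net = _nn.Sequential(
            block(c_in=2)
            + block(stride=2)
            + block(stride=2)
            + [res_block(1), res_block(2), res_block(4), res_block(8)]
            + [_nn.UpsampleNearest(2)]
            + block()
            + [_nn.UpsampleNearest(2)]
            + block()
            + [_nn.Conv1D(c, 2, 1, rng)]
        )
        self.meta: dict = {"seed": config.seed, "trained": False}

    def forward_bins(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(B, 2, Lb) binned tracks -> (B, 2, Lb) per-bin logits."""
        l = x.shape[2]
        pad = (-l) % self.DOWN_FACTOR
        if pad:
            x = np.pad(x, ((0, 0), (0, 0), (0, pad)))
        out = self.net.forward(x, train)
        return out[:, :, :l]

    @property
    def parameter_count(self) -> int:
        return _nn.parameter_count(self.net)

    def save(self, path) -> None:
        meta = dict(self.meta)
        meta["config"] = vars(self.config)
        _nn.save_state(self.net, path, meta)

    @classmethod
    def load(cls, path) -> "ForkModel":
        import json

        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
        model = cls(ForkNetConfig(**meta.pop("config")))
        _nn.load_state(model.net, path)
        model.meta = meta
        return model


def build_fork_model(config: ForkNetConfig | None = None) -> ForkModel:
    """Deterministically initialised fork-direction network."""
    return ForkModel(config or ForkNetConfig())


def bin_track(record: DetectRecord, bin_bp: int = BIN_BP) -> tuple[np.ndarray, np.ndarray]:
    """Summarise a detect record into (2, Lb) features and a per-bin mask.

    Channel 0 is the mean BrdU probability of the thymidines in the bin,
    channel 1 the (capped) thymidine occupancy; the mask marks bins holding
    at least one thymidine.
    """
    span = record.ref_end - record.ref_start
    n_bins = max(1, -(-span // bin_bp))
    idx = np.clip((record.positions - record.ref_start) // bin_bp, 0, n_bins - 1)
    count = np.bincount(idx, minlength=n_bins).astype(np.float64)
    psum = np.bincount(idx, weights=record.probabilities, minlength=n_bins)
    mask = count > 0
    mean = np.zeros(n_bins)
    mean[mask] = psum[mask] / count[mask]
    occupancy = np.minimum(count, 40.0) / 40.0
    return np.stack([mean, occupancy]), mask


def bin_fork_labels(
    record: DetectRecord, truth_forks: np.ndarray, bin_bp: int = BIN_BP
) -> np.ndarray:
    """(2, Lb) per-bin fractions of left/right fork labels over the span."""
    span = record.ref_end - record.ref_start
    n_bins = max(1, -(-span // bin_bp))
    pos = np.arange(span)
    idx = pos // bin_bp
    count = np.bincount(idx, minlength=n_bins).astype(np.float64)
    left = np.bincount(idx, weights=(truth_forks == FORK_LABEL_LEFT), minlength=n_bins)
    right = np.bincount(idx, weights=(truth_forks == FORK_LABEL_RIGHT), minlength=n_bins)
    with np.errstate(invalid="ignore"):
        out = np.stack([left, right]) / np.maximum(count, 1.0)
    return out


def predict_track(model: ForkModel, record: DetectRecord) -> ForkTrack:
    """Per-position fork probabilities for one detect record."""
    x, _ = bin_track(record, model.config.bin_bp)
    logits = model.forward_bins(x[None])
    p = _nn.sigmoid(logits[0])
    idx = np.clip((record.positions - record.ref_start) // model.config.bin_bp, 0, p.shape[1] - 1)
    return ForkTrack(
        read_id=record.read_id,
        contig=record.contig,
        strand=record.strand,
        positions=record.positions.copy(),
        p_left=p[0, idx],
        p_right=p[1, idx],
    )


@dataclass
class ForkTrainConfig:
    epochs: int = 25
    batch_size: int = 16
    crop_bins: int = 256
    crops_per_track: int = 2
    learning_rate: float = 2e-3
    val_fraction: float = 0.15
    patience: int = 4
    seed: int = 7


def train_forks(
    model: ForkModel,
    pairs: list[tuple[DetectRecord, np.ndarray]],
    config: ForkTrainConfig | None = None,
) -> dict:
    """Train on (detect record, per-position truth fork labels) pairs.

    Loss is per-bin binary cross-entropy on both channels, masked to bins
    that contain thymidines; training samples fixed-length random crops so
    tracks of any length batch together.  Raises if the training material
    contains no positive fork labels.
    """
    config = config or ForkTrainConfig()
    bin_bp = model.config.bin_bp
    tracks = []
    any_positive = False
    for record, truth in pairs:
        if truth is None or len(truth) != record.ref_end - record.ref_start:
            raise ValueError("each record needs per-position truth fork labels over its span")
        x, mask = bin_track(record, bin_bp)
        y = bin_fork_labels(record, truth, bin_bp)
        any_positive = any_positive or bool((y > 0).any())
        tracks.append((x, y, mask.astype(np.float64)))
    if not any_positive:
        raise ValueError("no positive fork labels in the training data")

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(tracks))
    n_val = max(1, int(round(config.val_fraction * len(tracks))))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if train_idx.size == 0:
        raise ValueError("not enough tracks to split off a validation set")

    def crops(indices, rng):
        xs, ys, ms = [], [], []
        for i in indices:
            x, y, m = tracks[i]
            lb = x.shape[1]
            for _ in range(config.crops_per_track):
                if lb <= config.crop_bins:
                    pad = config.crop_bins - lb
                    xs.append(np.pad(x, ((0, 0), (0, pad))))
                    ys.append(np.pad(y, ((0, 0), (0, pad))))
                    ms.append(np.pad(m, (0, pad)))
                else:
                    s = int(rng.integers(0, lb - config.crop_bins + 1))
                    xs.append(x[:, s : s + config.crop_bins])
                    ys.append(y[:, s : s + config.crop_bins])
                    ms.append(m[s : s + config.crop_bins])
        return np.stack(xs), np.stack(ys), np.stack(ms)

    x_va, y_va, m_va = crops(val_idx, np.random.default_rng(config.seed + 99))
    opt = _nn.Adam(model.net.params(), lr=config.learning_rate)
    history = {"train_loss": [], "val_loss": [], "best_epoch": -1}
    best_loss, best_state, bad = np.inf, None, 0
    for epoch in range(config.epochs):
        x_tr, y_tr, m_tr = crops(train_idx, rng)
        perm = rng.permutation(x_tr.shape[0])
        total, nb = 0.0, 0
        for i in range(0, perm.size, config.batch_size):
            idx = perm[i : i + config.batch_size]
            opt.zero_grad()
            logits = model.forward_bins(x_tr[idx], train=True)
            loss, grad = _nn.bce_logits_loss(logits, y_tr[idx], m_tr[idx][:, None, :])
            pad = (-grad.shape[2]) % ForkModel.DOWN_FACTOR
            if pad:
                grad = np.pad(grad, ((0, 0), (0, 0), (0, pad)))
            model.net.backward(grad)
            opt.step()
            total += loss
            nb += 1
        val_logits = model.forward_bins(x_va)
        val_loss, _ = _nn.bce_logits_loss(val_logits, y_va, m_va[:, None, :])
        history["train_loss"].append(total / max(nb, 1))
        history["val_loss"].append(val_loss)
        if val_loss < best_loss - 1e-5:
            best_loss, bad = val_loss, 0
            best_state = [a.copy() for a in _nn.state_arrays(model.net)]
            history["best_epoch"] = epoch
        else:
            bad += 1
            if bad >= config.patience:
                break
    if best_state is not None:
        for a, saved in zip(_nn.state_arrays(model.net), best_state):
            a[...] = saved
    model.meta.update(trained=True, epochs=len(history["train_loss"]),
                      train_seed=config.seed, best_epoch=history["best_epoch"])
    return history


def call_fork_segments(
    track: ForkTrack,
    threshold: float = CALL_THRESHOLD,
    min_length_bp: int = MIN_SEGMENT_BP,
    gap_tolerance: int = GAP_TOLERANCE_BP,
) -> list[FeatureCall]:
    """Maximal fork segments: runs of supra-threshold probability per channel.

    Runs separated by gaps of at most ``gap_tolerance`` bp are merged;
    segments spanning less than ``min_length_bp`` are discarded.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    calls = []
    for kind, probs in (("fork_left", track.p_left), ("fork_right", track.p_right)):
        sel = np.flatnonzero(probs > threshold)
        if sel.size == 0:
            continue
        pos = track.positions[sel]
        breaks = np.flatnonzero(np.diff(pos) > gap_tolerance)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [sel.size - 1]])
        for a, b in zip(starts, ends):
            s, e = int(pos[a]), int(pos[b]) + 1
            if e - s >= min_length_bp:
                calls.append(
                    FeatureCall(
                        kind=kind,
                        contig=track.contig,
                        start=s,
                        end=e,
                        read_id=track.read_id,
                        score=float(probs[sel[a : b + 1]].mean()),
                    )
                )
    calls.sort(key=lambda c: (c.start, c.end))
    return calls


def _between(a: FeatureCall, b: FeatureCall, kind: str) -> FeatureCall:
    """Interval between two fork segments; overlap collapses to midpoint +/- 1."""
    if a.end < b.start:
        start, end = a.end, b.start
    else:
        mid = (b.start + min(a.end, b.end)) // 2
        start, end = mid - 1, mid + 1
    return FeatureCall(
        kind=kind,
        contig=a.contig,
        start=start,
        end=end,
        read_id=a.read_id,
        score=float((a.score + b.score) / 2.0),
    )


def match_forks(segments: list[FeatureCall]) -> list[FeatureCall]:
    """Match diverging/converging fork segments into origin/termination calls.

    Segments must come from one read.  For consecutive segments (sorted by
    position) a leftward fork followed by a rightward fork diverges from an
    origin between them; a rightward fork followed by a leftward fork
    converges on a termination site.  Unmatched single forks yield nothing.
    """
    segs = sorted(
        (s for s in segments if s.kind in ("fork_left", "fork_right")),
        key=lambda c: (c.start, c.end),
    )
    out = []
    for a, b in zip(segs[:-1], segs[1:]):
        if a.kind == "fork_left" and b.kind == "fork_right":
            out.append(_between(a, b, "origin"))
        elif a.kind == "fork_right" and b.kind == "fork_left":
            out.append(_between(a, b, "termination"))
    return out


def filter_reads_for_calling(
    records: list[DetectRecord],
    min_mapping_length: int = MIN_MAPPING_LENGTH,
    min_mapq: int = MIN_MAPQ,
) -> list[DetectRecord]:
    """Reads eligible for origin/termination calling (>= 20 kb, MAPQ >= 20)."""
    return [
        r
        for r in records
        if r.mapping_length >= min_mapping_length and r.mapq >= min_mapq
    ]


def call_read(
    model: ForkModel,
    record: DetectRecord,
    threshold: float = CALL_THRESHOLD,
    min_length_bp: int = MIN_SEGMENT_BP,
    gap_tolerance: int = GAP_TOLERANCE_BP,
) -> tuple[ForkTrack, list[FeatureCall]]:
    """Fork track plus all fork/origin/termination calls for one read."""
    track = predict_track(model, record)
    segments = call_fork_segments(track, threshold, min_length_bp, gap_tolerance)
    return track, segments + match_forks(segments)
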