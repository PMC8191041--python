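"""Residual network mapping per-thymidine signal tensors to BrdU probability.

The classifier is a small 1-D residual network over the fixed-shape feature
window produced by :mod:`nanofork.signal_align`: a pointwise stem, a stack of
residual blocks (depthwise convolution -> pointwise convolution -> batch
normalisation -> ReLU, with an identity shortcut), global average pooling and
a two-way softmax head.  The two outputs are the probabilities that the
centre thymidine is canonical T or BrdU; they sum to one by construction.

Training material is simulated unsubstituted DNA together with DNA at 80%
BrdU-for-thymidine substitution, labelled per thymidine from simulator truth
(under 80% substitution the remaining canonical thymidines are negative
examples).  Cross-entropy with a held-out validation split and early
stopping; all randomness is seeded.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from nanofork import _nn
from nanofork.pore_model import PoreModel
from nanofork.signal_align import (
    DEFAULT_WINDOW,
    N_FEATURES,
    TensorSet,
    align_events,
    build_input_tensors,
    segment_events,
)
from nanofork.simulate import SimRead


@dataclass
class DetectConfig:
    """Architecture hyper-parameters of the detection network."""

    blocks: int = 6
    channels: int = 32
    kernel: int = 5
    window: int = DEFAULT_WINDOW
    n_features: int = N_FEATURES
    seed: int = 1

    def __post_init__(self) -> None:
        if self.blocks < 1 or self.channels < 1:
            raise ValueError("blocks and channels must be >= 1")
        if self.kernel % 2 != 1 or self.window % 2 != 1:
            raise ValueError("kernel and window must be odd")
        if self.kernel > self.window:
            raise ValueError("kernel cannot exceed the tensor window")


@dataclass
class TrainConfig:
    """Training-loop settings for the detection network."""

    epochs: int = 15
    batch_size: int = 256
    learning_rate: float = 1e-3
    val_fraction: float = 0.15
    patience: int = 3
    max_tensors_per_read: int | None = 30
    #: loss weight of (canonical T, BrdU) samples; the default favours
    #: specificity, since downstream fork calling tolerates missed BrdU far
    #: better than false positives on unsubstituted DNA
    class_weights: tuple[float, float] = (1.5, 1.0)
    seed: int = 1


class DetectModel:
    """The detection network plus its build/training metadata."""

    def __init__(self, config: DetectConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config.channels
        blocks = []
        for _ in range(config.blocks):
            blocks.append(
                _nn.Residual(
                    _nn.Sequential(
                        [
                            _nn.Conv1D(c, c, config.kernel, rng, depthwise=True),
                            _nn.Conv1D(c, c, 1, rng),
                            _nn.BatchNorm1D(c),
                            _nn.ReLU(),
                        ]
                    )
                )
            )
        self.net = _nn.Sequential(
            [_nn.Conv1D(config.n_features, c, 1, rng), _nn.BatchNorm1D(c), _nn.ReLU()]
            + blocks
            + [_nn.GlobalAvgPool(), _nn.Dense(c, 2, rng)]
        )
        self.meta: dict = {"seed": config.seed, "trained": False}

    # -- inference -----------------------------------------------------------
    def logits(self, features: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(np.transpose(features, (0, 2, 1)))  # (N, F, W)
        return self.net.forward(x, train)

    def predict_proba(self, features: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        """(N, 2) array of (p_T, p_BrdU); rows sum to one."""
        if features.shape[0] == 0:
            return np.zeros((0, 2))
        out = []
        for i in range(0, features.shape[0], batch_size):
            out.append(_nn.softmax(self.logits(features[i : i + batch_size])))
        return np.concatenate(out, axis=0)

    @property
    def parameter_count(self) -> int:
        return _nn.parameter_count(self.net)

    def weights_hash(self) -> str:
        h = 0
        for a in _nn.state_arrays(self.net):
            h = zlib.crc32(np.ascontiguousarray(a).tobytes(), h)
        return f"{h:08x}"

    def save(self, path) -> None:
        meta = dict(self.meta)
        meta["config"] = vars(self.config)
        _nn.save_state(self.net, path, meta)

    @classmethod
    def load(cls, path) -> "DetectModel":
        import json

        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
        model = cls(DetectConfig(**meta.pop("config")))
        _nn.load_state(model.net, path)
        model.meta = meta
        return model


def build_detect_model(config: DetectConfig | None = None) -> DetectModel:
    """Deterministically initialised detection network (fixed seed in config)."""
    return DetectModel(config or DetectConfig())


@dataclass
class DetectRecord:
    """Per-read table of (thymidine reference position, BrdU probability, 6-mer)."""

    read_id: str
    contig: str
    ref_start: int
    ref_end: int
    strand: str
    positions: np.ndarray
    probabilities: np.ndarray
    sixmers: list[str]
    mapq: int = 60

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64)
        if self.positions.size != self.probabilities.size or len(self.sixmers) != self.positions.size:
            raise ValueError("positions, probabilities and sixmers must have equal length")
        if self.positions.size and (np.diff(self.positions) <= 0).any():
            raise ValueError("positions must be strictly increasing")
        if ((self.probabilities < 0) | (self.probabilities > 1)).any():
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def mapping_length(self) -> int:
        return self.ref_end - self.ref_start

    def __len__(self) -> int:
        return self.positions.size


def prepare_read_tensors(
    read: SimRead,
    pore_model: PoreModel,
    window: int = DEFAULT_WINDOW,
    band_width: int | None = 100,
) -> TensorSet:
    """Run the signal stage (events -> HMM alignment -> tensors) for one read."""
    events = segment_events(read.signal)
    alignment = align_events(events, read.sequence, pore_model, read_id=read.read_id,
                             band_width=band_width)
    candidates = read.t_positions - read.ref_start
    return build_input_tensors(alignment, events, read.sequence, candidates, pore_model, window)


def detect_read(
    model: DetectModel,
    tensors: TensorSet,
    *,
    read_id: str,
    contig: str,
    ref_start: int,
    ref_end: int,
    strand: str,
    sequence: str,
    mapq: int = 60,
) -> DetectRecord:
    """Per-thymidine BrdU probabilities for one read's tensor set."""
    probs = model.predict_proba(tensors.features)[:, 1] if len(tensors) else np.zeros(0)
    sixmers = [sequence[int(p) : int(p) + 6].ljust(6, "N") for p in tensors.centre_positions]
    return DetectRecord(
        read_id=read_id,
        contig=contig,
        ref_start=ref_start,
        ref_end=ref_end,
        strand=strand,
        positions=tensors.centre_positions + ref_start,
        probabilities=probs,
        sixmers=sixmers,
        mapq=mapq,
    )


def detect_sim_read(model: DetectModel, read: SimRead, pore_model: PoreModel) -> DetectRecord:
    """Convenience wrapper: full signal stage plus network for one simulated read."""
    tensors = prepare_read_tensors(read, pore_model, window=model.config.window)
    return detect_read(
        model,
        tensors,
        read_id=read.read_id,
        contig=read.contig,
        ref_start=read.ref_start,
        ref_end=read.ref_end,
        strand=read.strand,
        sequence=read.sequence,
        mapq=read.mapq,
    )


def classify_at_threshold(record: DetectRecord, threshold: float) -> np.ndarray:
    """Boolean BrdU calls: probability strictly greater than the threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return record.probabilities > threshold


@dataclass
class TrainingData:
    features: np.ndarray  # (N, W, F)
    labels: np.ndarray  # (N,) 0=T 1=BrdU
    read_index: np.ndarray  # (N,) which read each tensor came from


def collect_training_data(
    reads: list[SimRead],
    pore_model: PoreModel,
    config: TrainConfig,
    window: int = DEFAULT_WINDOW,
) -> TrainingData:
    """Tensorise labelled reads, subsampling thymidines per read."""
    rng = np.random.default_rng(config.seed)
    feats, labels, ridx = [], [], []
    for i, read in enumerate(reads):
        tensors = prepare_read_tensors(read, pore_model, window=window)
        if len(tensors) == 0:
            continue
        kept = np.searchsorted(read.t_positions, tensors.centre_positions + read.ref_start)
        y = read.truth_brdu[kept].astype(np.int64)
        take = np.arange(len(tensors))
        if config.max_tensors_per_read is not None and take.size > config.max_tensors_per_read:
            take = rng.choice(take.size, size=config.max_tensors_per_read, replace=False)
        feats.append(tensors.features[take])
        labels.append(y[take])
        ridx.append(np.full(take.size, i))
    if not feats:
        raise ValueError("no usable tensors in the training reads")
    return TrainingData(
        np.concatenate(feats), np.concatenate(labels), np.concatenate(ridx)
    )


def train_detect(
    model: DetectModel,
    reads: list[SimRead],
    pore_model: PoreModel,
    config: TrainConfig | None = None,
) -> dict:
    """Train the detection network on labelled simulated reads.

    Requires both classes (canonical and substituted thymidines) to be
    present.  The validation split is by read; training stops early when the
    validation loss has not improved for ``patience`` epochs and the best
    weights are restored.  Returns the training history.
    """
    config = config or TrainConfig()
    data = collect_training_data(reads, pore_model, config)
    if np.unique(data.labels).size < 2:
        raise ValueError(
            "training data contains a single class; both unsubstituted and "
            "substituted thymidines are required"
        )
    rng = np.random.default_rng(config.seed + 1)
    n_reads = int(data.read_index.max()) + 1
    order = rng.permutation(n_reads)
    n_val = max(1, int(round(config.val_fraction * n_reads)))
    val_reads = set(order[:n_val].tolist())
    is_val = np.isin(data.read_index, list(val_reads))
    x_tr, y_tr = data.features[~is_val], data.labels[~is_val]
    x_va, y_va = data.features[is_val], data.labels[is_val]
    if np.unique(y_tr).size < 2:
        raise ValueError("training split contains a single class")

    opt = _nn.Adam(model.net.params(), lr=config.learning_rate)
    history = {"train_loss": [], "val_loss": [], "best_epoch": -1}
    best_loss, best_state, bad = np.inf, None, 0
    for epoch in range(config.epochs):
        perm = rng.permutation(x_tr.shape[0])
        total, nb = 0.0, 0
        for i in range(0, perm.size, config.batch_size):
            idx = perm[i : i + config.batch_size]
            opt.zero_grad()
            logits = model.logits(x_tr[idx], train=True)
            loss, grad = _nn.softmax_ce_loss(logits, y_tr[idx], config.class_weights)
            model.net.backward(grad)
            opt.step()
            total += loss
            nb += 1
        val_logits = model.logits(x_va)
        val_loss, _ = _nn.softmax_ce_loss(val_logits, y_va, config.class_weights)
        history["train_loss"].append(total / max(nb, 1))
        history["val_loss"].append(val_loss)
        if val_loss < best_loss - 1e-5:
            best_loss = val_loss
            best_state = [a.copy() for a in _nn.state_arrays(model.net)]
            history["best_epoch"] = epoch
            bad = 0
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
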