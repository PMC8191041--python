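"""Synthetic nanopore reads with per-thymidine BrdU ground truth.

The generator stands in for the sequencing experiments the pipeline is built
for.  It emulates four labelling protocols:

``uniform``
    Genome-wide BrdU-for-thymidine substitution at a fixed rate (the regime of
    substitution-titration experiments at 0/26/38/49/69/80%).
``primer_extension``
    A fixed ~80 bp forward-strand construct whose thymidines at 1-based
    positions 30 and 36 always carry BrdU and all others never do.
``g1_release``
    Cells synchronised in G1 and released into BrdU: all origins fire at the
    pulse start, and the local substitution probability ramps from 0 to a
    plateau ``p_max`` over ``rise_length`` bp of fork travel (the analogue
    pool equilibrates as the fork moves), then stays constant.
``pulse_chase``
    Asynchronous cells, a short BrdU pulse followed by a thymidine chase:
    forks fired before the pulse carry a plateau of length
    ``fork_speed * pulse_duration`` followed by an exponential decay with
    characteristic length ``chase_decay_length`` along the direction of
    travel.

Raw current is synthesised from the 6-mer pore model: each k-mer position
contributes a geometric dwell (mean ``dwell_mean`` samples, minimum 1) of its
expected level plus Gaussian noise scaled by ``noise_sd_scale``.  Seeded runs
are bit-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from nanofork.pore_model import PoreModel, expected_levels

PROTOCOLS = ("uniform", "g1_release", "pulse_chase", "primer_extension")

#: Fixed forward-strand primer-extension construct.  The two BrdU positions
#: are the thymidines at 1-based coordinates 30 and 36; every other thymidine
#: is never substituted.
PRIMER_CONSTRUCT = (
    "GCAGACGCATCGGATCAGCCGAAGCGCAGTCGACGTCGGAAGCCTGACCAGGCAACGGCTCAGGACTCGGCAAGGCACGG"
)
PRIMER_BRDU_POSITIONS_1BASED = (30, 36)

FORK_LABEL_NONE, FORK_LABEL_LEFT, FORK_LABEL_RIGHT = 0, 1, 2

#: Half-width (bp) of truth origin/termination intervals.
TRUTH_INTERVAL_HALF_WIDTH = 500


class SimulationError(ValueError):
    """Raised for invalid simulation configurations or geometries."""


@dataclass
class SimConfig:
    """Parameters of one simulated labelling experiment.

    Units: ``fork_speed`` bp/min, ``pulse_duration`` min, ``chase_decay_length``
    and ``rise_length`` bp, ``dwell_mean`` samples/base, ``firing_offset_max``
    min (how long before the pulse an asynchronous molecule's origins may have
    fired).
    """

    substitution_rate: float = 0.0
    protocol: str = "uniform"
    fork_speed: float = 1800.0
    pulse_duration: float = 4.0
    chase_decay_length: float = 5000.0
    noise_sd_scale: float = 1.0
    dwell_mean: float = 8.0
    seed: int = 0
    p_max: float = 0.8
    rise_length: float = 10000.0
    firing_offset_max: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise SimulationError(f"substitution_rate {self.substitution_rate} outside [0, 1]")
        if self.protocol not in PROTOCOLS:
            raise SimulationError(f"unknown protocol {self.protocol!r}; expected one of {PROTOCOLS}")
        if self.fork_speed <= 0:
            raise SimulationError("fork_speed must be > 0")
        if self.dwell_mean < 1:
            raise SimulationError("dwell_mean must be >= 1 sample/base")
        if self.noise_sd_scale < 0:
            raise SimulationError("noise_sd_scale must be >= 0")
        if not 0.0 < self.p_max <= 1.0:
            raise SimulationError("p_max must be in (0, 1]")


@dataclass
class SimRead:
    """One simulated molecule: sequence, raw signal, and truth labels.

    ``truth_brdu`` holds one boolean per thymidine of the aligned reference
    span, in coordinate order; ``t_positions`` gives their absolute reference
    coordinates.  ``truth_forks`` (optional) labels every spanned position
    0=none / 1=leftward fork / 2=rightward fork; origin and termination truth
    intervals are 0-based half-open.
    """

    read_id: str
    contig: str
    ref_start: int
    ref_end: int
    strand: str
    sequence: str
    signal: np.ndarray
    truth_brdu: np.ndarray
    t_positions: np.ndarray
    mapq: int = 60
    truth_forks: np.ndarray | None = None
    truth_origins: list[tuple[int, int]] = field(default_factory=list)
    truth_terms: list[tuple[int, int]] = field(default_factory=list)

    @property
    def mapping_length(self) -> int:
        return self.ref_end - self.ref_start


def random_sequence(length: int, rng: np.random.Generator, t_fraction: float = 0.3) -> str:
    """Random reference sequence with a realistic thymidine density."""
    other = (1.0 - t_fraction) / 3.0
    symbols = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length,
                         p=[other, other, other, t_fraction])
    return symbols.tobytes().decode("ascii")


def _read_rng(config: SimConfig, read_index: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), int(read_index)])


def _synthesise_signal(
    means: np.ndarray, sds: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Geometric dwell per k-mer position plus level-proportional Gaussian noise."""
    dwell = rng.geometric(1.0 / config.dwell_mean, size=means.size)
    level = np.repeat(means, dwell)
    noise_sd = np.repeat(sds, dwell) * config.noise_sd_scale
    if config.noise_sd_scale > 0:
        level = level + rng.normal(0.0, 1.0, size=level.size) * noise_sd
    return level.astype(np.float64)


def _build_read(
    read_id: str,
    contig: str,
    window: tuple[int, int],
    seq: str,
    mask: np.ndarray,
    t_rel: np.ndarray,
    config: SimConfig,
    model: PoreModel,
    rng: np.random.Generator,
) -> SimRead:
    means, sds = expected_levels(seq, mask, model)
    signal = _synthesise_signal(means, sds, config, rng)
    return SimRead(
        read_id=read_id,
        contig=contig,
        ref_start=window[0],
        ref_end=window[1],
        strand="+",
        sequence=seq,
        signal=signal,
        truth_brdu=mask.copy(),
        t_positions=t_rel + window[0],
    )


def simulate_read(
    contig_seq: str,
    window: tuple[int, int],
    config: SimConfig,
    model: PoreModel,
    read_id: str = "read0",
    contig: str = "contig0",
    read_index: int = 0,
) -> SimRead:
    """Simulate one uniformly substituted read over ``window`` of a contig.

    Each reference-strand thymidine carries BrdU independently with
    probability ``config.substitution_rate``.
    """
    start, end = int(window[0]), int(window[1])
    if end - start < 6:
        raise SimulationError(f"window [{start}, {end}) shorter than the 6-mer length")
    if start < 0 or end > len(contig_seq):
        raise SimulationError(f"window [{start}, {end}) outside contig of length {len(contig_seq)}")
    rng = _read_rng(config, read_index)
    seq = contig_seq[start:end].upper()
    t_rel = np.flatnonzero(np.frombuffer(seq.encode(), dtype=np.uint8) == ord("T"))
    mask = rng.random(t_rel.size) < config.substitution_rate
    return _build_read(read_id, contig, (start, end), seq, mask, t_rel, config, model, rng)


def simulate_primer_extension(
    n_reads: int, config: SimConfig, model: PoreModel
) -> list[SimRead]:
    """Reads of the fixed primer-extension construct (BrdU at 30 and 36 bp)."""
    if n_reads < 1:
        raise SimulationError("n_reads must be >= 1")
    seq = PRIMER_CONSTRUCT
    t_rel = np.flatnonzero(np.frombuffer(seq.encode(), dtype=np.uint8) == ord("T"))
    brdu_rel = {p - 1 for p in PRIMER_BRDU_POSITIONS_1BASED}
    if not brdu_rel <= set(t_rel.tolist()):
        raise SimulationError("construct lacks thymidine at a declared BrdU position")
    mask = np.isin(t_rel, sorted(brdu_rel))
    reads = []
    for i in range(n_reads):
        rng = _read_rng(config, i)
        reads.append(
            _build_read(
                f"pe_{i:04d}", "pe_construct", (0, len(seq)), seq, mask, t_rel, config, model, rng
            )
        )
    return reads


def _substitution_profile(
    positions: np.ndarray, origins: np.ndarray, t_fire: float, config: SimConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Local substitution probability and fork-direction label per position.

    Forks from all origins of a molecule fire simultaneously at ``t_fire``
    (minutes relative to the pulse start; <= 0 means before the pulse) and
    travel at equal speed, so each position is replicated by the fork from its
    nearest origin and converging forks stop at the midpoint between adjacent
    origins.
    """
    v = config.fork_speed
    # nearest origin and signed distance
    idx = np.searchsorted(origins, positions)
    left_o = origins[np.clip(idx - 1, 0, origins.size - 1)]
    right_o = origins[np.clip(idx, 0, origins.size - 1)]
    use_right = np.abs(positions - right_o) < np.abs(positions - left_o)
    origin = np.where(use_right, right_o, left_o)
    dist = np.abs(positions - origin)
    direction = np.where(positions < origin, FORK_LABEL_LEFT,
                         np.where(positions > origin, FORK_LABEL_RIGHT, FORK_LABEL_NONE))

    t_rep = t_fire + dist / v  # minutes after pulse start when replicated
    if config.protocol == "g1_release":
        # pulse starts at release; analogue uptake ramps over rise_length of travel
        p = config.p_max * np.clip(dist / config.rise_length, 0.0, 1.0)
    elif config.protocol == "pulse_chase":
        p = np.zeros_like(dist, dtype=float)
        in_pulse = (t_rep >= 0) & (t_rep <= config.pulse_duration)
        after = t_rep > config.pulse_duration
        p[in_pulse] = config.p_max
        p[after] = config.p_max * np.exp(
            -(t_rep[after] - config.pulse_duration) * v / config.chase_decay_length
        )
    else:  # pragma: no cover - guarded by caller
        raise SimulationError(f"protocol {config.protocol!r} has no fork footprint")
    labels = np.where(p >= 0.05 * config.p_max, direction, FORK_LABEL_NONE).astype(np.int8)
    return p, labels


def simulate_fork_footprints(
    contig_seq: str,
    molecule_windows: list[tuple[int, int]],
    origin_sites: list[int],
    config: SimConfig,
    model: PoreModel,
    contig: str = "contig0",
) -> list[SimRead]:
    """Simulate molecules carrying replication-fork BrdU footprints.

    Each origin inside a molecule launches a leftward and a rightward fork;
    truth fork-direction labels, origin intervals, and termination intervals
    (midpoints of converging forks) are recorded on every read.  Molecules
    containing no origin are unreplicated during the pulse and carry no BrdU
    (they serve as negative controls for origin calling).
    """
    if config.protocol not in ("g1_release", "pulse_chase"):
        raise SimulationError("fork footprints require protocol g1_release or pulse_chase")
    origin_sites = sorted(int(o) for o in origin_sites)
    for o in origin_sites:
        if not any(w[0] <= o < w[1] for w in molecule_windows):
            raise SimulationError(f"origin {o} lies outside every molecule window")
    reads = []
    half = TRUTH_INTERVAL_HALF_WIDTH
    for i, (start, end) in enumerate(molecule_windows):
        start, end = int(start), int(end)
        if end - start < 6:
            raise SimulationError(f"molecule window [{start}, {end}) shorter than 6 bp")
        rng = _read_rng(config, i)
        seq = contig_seq[start:end].upper()
        t_rel = np.flatnonzero(np.frombuffer(seq.encode(), dtype=np.uint8) == ord("T"))
        origins = np.array([o for o in origin_sites if start <= o < end], dtype=np.int64)
        positions = np.arange(start, end, dtype=np.int64)
        if origins.size:
            t_fire = 0.0
            if config.protocol == "pulse_chase":
                t_fire = -float(rng.uniform(0.0, config.firing_offset_max))
            p, labels = _substitution_profile(positions, origins, t_fire, config)
            mask = rng.random(t_rel.size) < p[t_rel]
        else:
            labels = np.zeros(end - start, dtype=np.int8)
            mask = np.zeros(t_rel.size, dtype=bool)
        read = _build_read(
            f"mol_{i:04d}", contig, (start, end), seq, mask, t_rel, config, model, rng
        )
        read.truth_forks = labels

        def _has(label: int, lo: int, hi: int) -> bool:
            lo, hi = max(lo, start), min(hi, end)
            return lo < hi and bool((labels[lo - start : hi - start] == label).any())

        # an origin/termination is ground truth on this molecule only when both
        # of its fork footprints are visible (labelled) on the molecule
        bounds = [start] + [
            (int(a) + int(b)) // 2 for a, b in zip(origins[:-1], origins[1:])
        ] + [end]
        read.truth_origins = [
            (max(start, int(o) - half), min(end, int(o) + half))
            for k, o in enumerate(origins)
            if _has(FORK_LABEL_LEFT, bounds[k], int(o)) and _has(FORK_LABEL_RIGHT, int(o) + 1, bounds[k + 1])
        ]
        read.truth_terms = [
            (max(start, m - half), min(end, m + half))
            for a, b in zip(origins[:-1], origins[1:])
            for m in [(int(a) + int(b)) // 2]
            if _has(FORK_LABEL_RIGHT, int(a), m) and _has(FORK_LABEL_LEFT, m, int(b))
        ]
        reads.append(read)
    return reads


def emulate_detection(
    read: SimRead,
    seed: int = 0,
    pos_beta: tuple[float, float] = (8.0, 2.0),
    neg_beta: tuple[float, float] = (1.0, 12.0),
):
    """Synthetic detector output for a simulated read.

    Draws per-thymidine BrdU probabilities from class-conditional Beta
    distributions (substituted thymidines from ``pos_beta``, canonical from
    ``neg_beta``), emulating the calibration of a trained detection network.
    Used to train and evaluate the fork-calling stage at scales where running
    the full raw-signal pipeline would be wasteful; the calibration constants
    are documented in the methods note.
    """
    from nanofork.detect import DetectRecord

    rng = np.random.default_rng([int(seed), zlib.crc32(read.read_id.encode()) % (2**31)])
    probs = np.where(
        read.truth_brdu,
        rng.beta(*pos_beta, size=read.truth_brdu.size),
        rng.beta(*neg_beta, size=read.truth_brdu.size),
    )
    sixmers = [read.sequence[p - read.ref_start : p - read.ref_start + 6].ljust(6, "N")
               for p in read.t_positions]
    return DetectRecord(
        read_id=read.read_id,
        contig=read.contig,
        ref_start=read.ref_start,
        ref_end=read.ref_end,
        strand=read.strand,
        mapq=read.mapq,
        positions=read.t_positions.astype(np.int64),
        probabilities=probs.astype(np.float64),
        sixmers=sixmers,
    )
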