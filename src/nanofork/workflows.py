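"""End-to-end study workflows at desk scale.

These functions wire the simulator, signal stage, networks and evaluation
into the standard benchmark runs of the package: detection accuracy on
held-out uniform-substitution cohorts, single-nucleotide resolution on the
primer-extension construct, and origin/termination recovery on fork-footprint
cohorts.  They are used by the test suite and the reproduction script alike;
every source of randomness derives from the single ``seed`` argument.

Problem sizes (read counts, read lengths, genome sizes) are the package's
standard desk-scale defaults, chosen so a full run completes in minutes on
one CPU core; see the methods note for the rationale.
"""

from __future__ import annotations

import numpy as np

from nanofork import evaluation
from nanofork.detect import (
    DetectConfig,
    DetectModel,
    TrainConfig,
    build_detect_model,
    detect_sim_read,
    prepare_read_tensors,
    train_detect,
)
from nanofork.forks import (
    ForkModel,
    ForkTrainConfig,
    build_fork_model,
    call_read,
    filter_reads_for_calling,
    train_forks,
)
from nanofork.pore_model import PoreModel, default_pore_model
from nanofork.simulate import (
    SimConfig,
    SimRead,
    emulate_detection,
    random_sequence,
    simulate_fork_footprints,
    simulate_primer_extension,
    simulate_read,
)

#: substitution rate of the substituted half of the detection training set
TRAIN_SUBSTITUTION_RATE = 0.8


def _subseed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


def simulate_uniform_cohort(
    n_reads: int,
    rates: tuple[float, ...],
    seed: int,
    pore_model: PoreModel,
    read_length: int = 800,
    genome_length: int = 120_000,
) -> list[SimRead]:
    """Reads with substitution rates cycling through ``rates``."""
    rng = np.random.default_rng(seed)
    contig = random_sequence(genome_length, rng)
    reads = []
    for i in range(n_reads):
        rate = rates[i % len(rates)]
        config = SimConfig(substitution_rate=rate, seed=_subseed(seed, 1))
        start = int(rng.integers(0, genome_length - read_length + 1))
        reads.append(
            simulate_read(contig, (start, start + read_length), config, pore_model,
                          read_id=f"read_{i:05d}", read_index=i)
        )
    return reads


def train_detection_model(
    seed: int,
    pore_model: PoreModel | None = None,
    n_train_reads: int = 2000,
    read_length: int = 800,
    epochs: int = 15,
) -> tuple[DetectModel, dict]:
    """Train the detection network on a fresh 0% / 80% cohort."""
    pore_model = pore_model or default_pore_model()
    reads = simulate_uniform_cohort(
        n_train_reads, (0.0, TRAIN_SUBSTITUTION_RATE), _subseed(seed, 10), pore_model,
        read_length=read_length,
    )
    model = build_detect_model(DetectConfig(seed=_subseed(seed, 11)))
    history = train_detect(
        model, reads, pore_model,
        TrainConfig(epochs=epochs, seed=_subseed(seed, 12)),
    )
    return model, history


def detection_benchmark(
    model: DetectModel,
    seed: int,
    pore_model: PoreModel | None = None,
    n_test_reads: int = 300,
    read_length: int = 800,
    threshold: float = 0.5,
) -> dict:
    """Held-out per-thymidine detection metrics at the default threshold.

    Balanced accuracy pools thymidines of the whole held-out cohort;
    specificity is computed over the unsubstituted reads, mirroring the use
    of unsubstituted DNA to measure false positives.
    """
    pore_model = pore_model or default_pore_model()
    reads = simulate_uniform_cohort(
        n_test_reads, (0.0, TRAIN_SUBSTITUTION_RATE), _subseed(seed, 20), pore_model,
        read_length=read_length,
    )
    records, truths = [], []
    for read in reads:
        tensors = prepare_read_tensors(read, pore_model)
        kept = np.searchsorted(read.t_positions, tensors.centre_positions + read.ref_start)
        rec = detect_sim_read(model, read, pore_model)
        records.append(rec)
        truths.append(read.truth_brdu[kept])
    confusion = evaluation.confusion_at_threshold(records, truths, threshold)
    unsub = [i for i, t in enumerate(truths) if not t.any()]
    spec_conf = evaluation.confusion_at_threshold(
        [records[i] for i in unsub], [truths[i] for i in unsub], threshold
    )
    return {
        "n_thymidines": confusion.total,
        "n_unsubstituted": spec_conf.tn + spec_conf.fp,
        "balanced_accuracy": evaluation.balanced_accuracy(confusion),
        "specificity": spec_conf.tn / (spec_conf.tn + spec_conf.fp),
        "sensitivity": confusion.tp / (confusion.tp + confusion.fn),
        "confusion": confusion,
        "records": records,
        "truths": truths,
    }


def primer_extension_benchmark(
    model: DetectModel,
    seed: int,
    pore_model: PoreModel | None = None,
    n_reads: int = 273,
) -> dict:
    """Median per-position BrdU probability profile over primer-extension reads."""
    pore_model = pore_model or default_pore_model()
    config = SimConfig(protocol="primer_extension", seed=_subseed(seed, 30))
    reads = simulate_primer_extension(n_reads, config, pore_model)
    records = [detect_sim_read(model, read, pore_model) for read in reads]
    profile = evaluation.median_profile(records)
    top2 = sorted(sorted(profile, key=profile.get, reverse=True)[:2])
    return {"profile": profile, "top2_positions": top2, "n_reads": len(records)}


def simulate_fork_cohort(
    protocol: str,
    n_molecules: int,
    seed: int,
    pore_model: PoreModel,
    genome_length: int = 300_000,
    n_origins: int = 6,
    min_length: int = 25_000,
    max_length: int = 50_000,
    origin_free_fraction: float = 0.2,
    min_origin_spacing: int = 12_000,
) -> tuple[list[SimRead], list[int]]:
    """Molecules with fork footprints plus origin-free negative molecules.

    Origins keep a realistic minimum spacing (budding-yeast origins are
    typically tens of kilobases apart); origin-free molecules are drawn from
    a separate region of the genome with no origins, emulating unreplicated
    DNA.
    """
    rng = np.random.default_rng(seed)
    contig = random_sequence(genome_length, rng)
    margin = max_length
    n_neg = int(round(origin_free_fraction * n_molecules))
    # origins confined to the first part of the genome; the tail is origin-free
    region_end = genome_length * 7 // 10
    origins: list[int] = []
    candidates = np.arange(margin, region_end - margin, 500)
    while len(origins) < n_origins:
        o = int(rng.choice(candidates))
        if all(abs(o - x) >= min_origin_spacing for x in origins):
            origins.append(o)
    origins = sorted(origins)
    windows = []
    for i in range(n_molecules):
        length = int(rng.integers(min_length, max_length))
        if i < n_molecules - n_neg:
            start = int(rng.integers(0, region_end - length))
        else:
            start = int(rng.integers(region_end, genome_length - length))
        windows.append((start, start + length))
    config = SimConfig(
        protocol=protocol, seed=_subseed(seed, 40), noise_sd_scale=0.0, dwell_mean=1.0
    )
    reads = simulate_fork_footprints(contig, windows, origins, config, pore_model)
    return reads, origins


def train_fork_model(
    seed: int,
    pore_model: PoreModel | None = None,
    n_molecules_per_protocol: int = 150,
    epochs: int = 30,
) -> tuple[ForkModel, dict]:
    """Train the fork-direction network on both labelling protocols."""
    pore_model = pore_model or default_pore_model()
    reads = []
    for k, protocol in enumerate(("g1_release", "pulse_chase")):
        cohort, _ = simulate_fork_cohort(
            protocol, n_molecules_per_protocol, _subseed(seed, 50 + k), pore_model
        )
        reads.extend(cohort)
    pairs = [(emulate_detection(r, seed=_subseed(seed, 52)), r.truth_forks) for r in reads]
    model = build_fork_model()
    history = train_forks(model, pairs, ForkTrainConfig(epochs=epochs, seed=_subseed(seed, 53)))
    return model, history


def fork_benchmark(
    model: ForkModel,
    protocol: str,
    seed: int,
    pore_model: PoreModel | None = None,
    n_molecules: int = 200,
) -> dict:
    """Origin recovery and per-read origin specificity on a held-out cohort.

    Recovery: fraction of truth origins (on filter-passing reads) covered by
    a called origin confidence interval that also contains the true origin
    midpoint.  Specificity: fraction of origin-free passing reads with zero
    origin calls.
    """
    pore_model = pore_model or default_pore_model()
    reads, _origins = simulate_fork_cohort(protocol, n_molecules, _subseed(seed, 60), pore_model)
    records = {r.read_id: emulate_detection(r, seed=_subseed(seed, 61)) for r in reads}
    passing_ids = {
        r.read_id for r in filter_reads_for_calling(list(records.values()))
    }
    n_truth = n_recovered = 0
    n_negative_reads = n_clean_negative_reads = 0
    n_origin_calls = 0
    for read in reads:
        if read.read_id not in passing_ids:
            continue
        _track, calls = call_read(model, records[read.read_id])
        origin_calls = [c for c in calls if c.kind == "origin"]
        n_origin_calls += len(origin_calls)
        if not read.truth_origins and read.truth_forks is not None and not read.truth_forks.any():
            n_negative_reads += 1
            if not origin_calls:
                n_clean_negative_reads += 1
        for start, end in read.truth_origins:
            n_truth += 1
            mid = (start + end) // 2
            if any(c.start <= mid < c.end or (c.end > start and c.start < end)
                   for c in origin_calls):
                n_recovered += 1
    return {
        "protocol": protocol,
        "n_truth_origins": n_truth,
        "n_recovered": n_recovered,
        "origin_recovery": n_recovered / n_truth if n_truth else float("nan"),
        "n_negative_reads": n_negative_reads,
        "read_specificity": (
            n_clean_negative_reads / n_negative_reads if n_negative_reads else float("nan")
        ),
        "n_origin_calls": n_origin_calls,
    }
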