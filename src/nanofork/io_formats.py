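"""Readers and writers for every on-disk format the pipeline touches.

Inputs mirror a standard nanopore workflow: a reference genome (FASTA), read
alignments (BAM, consumed via pysam), and raw signal in a simple hierarchical
container (HDF5: one group per read holding the signal array, basecalled
sequence, and mapping attributes).  Outputs are the per-read BrdU probability
table (a line-oriented TSV dialect designed to be trivially parseable), BED4+
interval files for fork/origin/termination calls, and per-read bedgraphs for
genome-browser visualisation.

All writers are deterministic byte-for-byte given identical inputs; interval
formats are 0-based half-open throughout.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import h5py
import numpy as np
import pysam
from Bio import SeqIO

from nanofork import __version__
from nanofork.detect import DetectRecord
from nanofork.forks import FeatureCall, ForkTrack
from nanofork.simulate import SimRead


class FormatError(ValueError):
    """Raised for malformed or invalid on-disk data."""


# ---------------------------------------------------------------------------
# reference FASTA
# ---------------------------------------------------------------------------

def load_reference(path) -> dict[str, str]:
    """FASTA -> {contig: uppercase sequence}; duplicates and non-ACGTN error."""
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise FormatError(f"duplicate contig name {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise FormatError(
                f"contig {rec.id!r} contains non-ACGTN character(s): {sorted(bad)}"
            )
        contigs[rec.id] = seq
    if not contigs:
        raise FormatError(f"no FASTA records found in {path}")
    return contigs


def write_reference(contigs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in contigs:
            fh.write(f">{name}\n")
            seq = contigs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# signal container (HDF5, one group per read)
# ---------------------------------------------------------------------------

def write_signal_container(reads: list[SimRead], path) -> None:
    with h5py.File(path, "w") as fh:
        for read in sorted(reads, key=lambda r: r.read_id):
            grp = fh.create_group(read.read_id)
            grp.create_dataset("signal", data=np.asarray(read.signal, dtype=np.float32))
            grp.attrs["sequence"] = read.sequence
            grp.attrs["contig"] = read.contig
            grp.attrs["ref_start"] = read.ref_start
            grp.attrs["ref_end"] = read.ref_end
            grp.attrs["strand"] = read.strand
            grp.attrs["mapq"] = read.mapq


def iter_signal_container(path):
    """Yield (read_id, signal, sequence, attrs) in container order."""
    with h5py.File(path, "r") as fh:
        for read_id in fh:
            grp = fh[read_id]
            attrs = {k: grp.attrs[k] for k in grp.attrs}
            yield read_id, np.asarray(grp["signal"], dtype=np.float64), str(
                attrs.pop("sequence")
            ), attrs


# ---------------------------------------------------------------------------
# BAM (simulator writes perfect single-run-match alignments; pipeline reads)
# ---------------------------------------------------------------------------

def write_alignments(reads: list[SimRead], reference_lengths: dict[str, int], path) -> None:
    """Sorted, indexed BAM of perfect (single M run) simulated alignments."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in reference_lengths.items()],
    }
    tids = {name: i for i, name in enumerate(reference_lengths)}
    tmp = str(path) + ".unsorted"
    with pysam.AlignmentFile(tmp, "wb", header=header) as bam:
        for read in sorted(reads, key=lambda r: (tids[r.contig], r.ref_start, r.read_id)):
            a = pysam.AlignedSegment(bam.header)
            a.query_name = read.read_id
            a.query_sequence = read.sequence
            a.reference_id = tids[read.contig]
            a.reference_start = read.ref_start
            a.mapping_quality = read.mapq
            a.cigartuples = [(0, len(read.sequence))]
            a.flag = 0 if read.strand == "+" else 16
            bam.write(a)
    pysam.sort("-o", str(path), tmp)
    os.remove(tmp)
    pysam.index(str(path))


@dataclass
class ReadBundle:
    """One read joined across signal container, BAM and reference."""

    read_id: str
    signal: np.ndarray
    sequence: str
    contig: str
    ref_start: int
    ref_end: int
    strand: str
    mapq: int


def load_read_bundles(
    container_path, bam_path, reference: dict[str, str]
) -> tuple[list[ReadBundle], dict]:
    """Join container reads with primary mapped BAM alignments.

    Returns the bundles plus a report counting unmatched container reads and
    skipped (secondary/supplementary/unmapped) alignments.  Zero joined reads
    is a hard error.
    """
    alignments = {}
    skipped = 0
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                skipped += 1
                continue
            if aln.reference_name not in reference:
                raise FormatError(
                    f"alignment contig {aln.reference_name!r} missing from the reference"
                )
            alignments[aln.query_name] = aln.to_dict() | {
                "contig": aln.reference_name,
                "ref_start": aln.reference_start,
                "ref_end": aln.reference_end,
                "strand": "-" if aln.is_reverse else "+",
                "mapq": aln.mapping_quality,
            }
    bundles = []
    unmatched = 0
    for read_id, signal, sequence, _attrs in iter_signal_container(container_path):
        aln = alignments.get(read_id)
        if aln is None:
            unmatched += 1
            continue
        bundles.append(
            ReadBundle(
                read_id=read_id,
                signal=signal,
                sequence=sequence,
                contig=aln["contig"],
                ref_start=int(aln["ref_start"]),
                ref_end=int(aln["ref_end"]),
                strand=aln["strand"],
                mapq=int(aln["mapq"]),
            )
        )
    if not bundles:
        raise FormatError("no reads joined between the signal container and the BAM")
    return bundles, {"joined": len(bundles), "unmatched": unmatched, "skipped_alignments": skipped}


# ---------------------------------------------------------------------------
# detect table dialect
# ---------------------------------------------------------------------------

def write_detect_table(records: list[DetectRecord], path, header: dict | None = None) -> None:
    """Write the per-read BrdU probability table.

    Dialect: '#key value' header lines; per read a
    '>read_id<TAB>contig<TAB>start<TAB>end<TAB>strand<TAB>mapq' line followed
    by 'position<TAB>probability(6dp)<TAB>sixmer' rows.
    """
    with open(path, "w") as fh:
        fh.write(f"#software nanofork {__version__}\n")
        for key, value in (header or {}).items():
            fh.write(f"#{key} {value}\n")
        for rec in records:
            fh.write(
                f">{rec.read_id}\t{rec.contig}\t{rec.ref_start}\t{rec.ref_end}"
                f"\t{rec.strand}\t{rec.mapq}\n"
            )
            for pos, prob, sixmer in zip(rec.positions, rec.probabilities, rec.sixmers):
                fh.write(f"{pos}\t{prob:.6f}\t{sixmer}\n")


def parse_detect_table(path) -> tuple[list[DetectRecord], dict]:
    """Exact inverse of :func:`write_detect_table`; malformed rows error with
    their line number, and unknown header keys are preserved."""
    records: list[DetectRecord] = []
    header: dict[str, str] = {}
    meta = None
    positions: list[int] = []
    probs: list[float] = []
    sixmers: list[str] = []

    def flush():
        if meta is not None:
            records.append(
                DetectRecord(
                    read_id=meta[0],
                    contig=meta[1],
                    ref_start=int(meta[2]),
                    ref_end=int(meta[3]),
                    strand=meta[4],
                    mapq=int(meta[5]),
                    positions=np.array(positions, dtype=np.int64),
                    probabilities=np.array(probs, dtype=np.float64),
                    sixmers=list(sixmers),
                )
            )

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition(" ")
                header[key] = value
                continue
            if line.startswith(">"):
                flush()
                meta = line[1:].split("\t")
                if len(meta) != 6:
                    raise FormatError(f"{path}:{lineno}: read header needs 6 fields")
                positions, probs, sixmers = [], [], []
                continue
            parts = line.split("\t")
            if meta is None or len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: malformed data row")
            try:
                pos = int(parts[0])
                prob = float(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field") from exc
            if not 0.0 <= prob <= 1.0:
                raise FormatError(f"{path}:{lineno}: probability {prob} outside [0, 1]")
            if len(parts[2]) != 6 or set(parts[2]) - set("ACGTN"):
                raise FormatError(f"{path}:{lineno}: invalid 6-mer {parts[2]!r}")
            positions.append(pos)
            probs.append(prob)
            sixmers.append(parts[2])
    flush()
    return records, header


# ---------------------------------------------------------------------------
# bedgraph + BED
# ---------------------------------------------------------------------------

def _bedgraph_lines(name, contig, positions, values):
    yield f'track type=bedGraph name="{name}"\n'
    for pos, val in zip(positions, values):
        yield f"{contig}\t{pos}\t{pos + 1}\t{val:.6f}\n"


def write_bedgraphs(item: DetectRecord | ForkTrack, out_dir) -> list[str]:
    """Per-read bedgraph file(s): one per probability channel.

    A detect record yields ``<read_id>.brdu.bedgraph``; a fork track yields
    ``<read_id>.leftFork.bedgraph`` and ``<read_id>.rightFork.bedgraph``.
    Intervals are [position, position + 1) with the probability as value.
    """
    os.makedirs(out_dir, exist_ok=True)
    written = []
    if isinstance(item, DetectRecord):
        channels = [("brdu", item.probabilities)]
    else:
        channels = [("leftFork", item.p_left), ("rightFork", item.p_right)]
    for channel, values in channels:
        fname = os.path.join(out_dir, f"{item.read_id}.{channel}.bedgraph")
        with open(fname, "w") as fh:
            fh.writelines(
                _bedgraph_lines(f"{item.read_id} {channel}", item.contig, item.positions, values)
            )
        written.append(fname)
    return written


def parse_bedgraph(path) -> tuple[str, str, np.ndarray, np.ndarray]:
    """(track name, contig, positions, values) from one bedgraph file."""
    name = ""
    contig = ""
    positions, values = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("track"):
                _, _, rest = line.partition("name=")
                name = rest.strip('"')
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: malformed bedgraph row")
            contig = parts[0]
            start, end = int(parts[1]), int(parts[2])
            if not (0 <= start < end):
                raise FormatError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            positions.append(start)
            values.append(float(parts[3]))
    return name, contig, np.array(positions, dtype=np.int64), np.array(values)


def write_bed(calls: list[FeatureCall], path) -> None:
    """BED4+ (chrom, start, end, read_id, score), 0-based half-open."""
    with open(path, "w") as fh:
        for call in sorted(calls, key=lambda c: (c.contig, c.start, c.end, c.read_id)):
            fh.write(f"{call.contig}\t{call.start}\t{call.end}\t{call.read_id}\t{call.score:.4f}\n")


def parse_bed(path) -> list[tuple[str, int, int, str, float]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: malformed BED row")
            start, end = int(parts[1]), int(parts[2])
            if not (0 <= start < end):
                raise FormatError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            name = parts[3] if len(parts) > 3 else ""
            score = float(parts[4]) if len(parts) > 4 else 0.0
            rows.append((parts[0], start, end, name, score))
    return rows


def write_fork_tracks(tracks: list[ForkTrack], path) -> None:
    """Per-read fork-probability dump in the detect-table dialect (two columns)."""
    with open(path, "w") as fh:
        fh.write(f"#software nanofork {__version__}\n")
        fh.write("#channels p_left p_right\n")
        for track in tracks:
            fh.write(f">{track.read_id}\t{track.contig}\t{track.strand}\n")
            for pos, pl, pr in zip(track.positions, track.p_left, track.p_right):
                fh.write(f"{pos}\t{pl:.6f}\t{pr:.6f}\n")
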