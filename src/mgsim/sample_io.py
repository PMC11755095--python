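"""Per-sample deliverables: shuffled anonymized FASTQ and ground-truth SAM.

Streams are lists of fragments (1-tuples of reads for single-end data,
(mate1, mate2) 2-tuples for paired). Shuffling permutes fragments so mates
always travel together; anonymization replaces read names with 1-based
fragment indices so no output header reveals its source genome or contig.
"""

from __future__ import annotations

import dataclasses
import gzip
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from .genome_store import Genome
from .read_sim import Fragment, SimulatedRead, TruthRecord, revcomp

__all__ = [
    "StreamError",
    "GenomeStat",
    "concatenate_streams",
    "shuffle_reads",
    "anonymize_reads",
    "write_fastq",
    "read_fastq",
    "write_truth_alignment",
    "realized_stats",
    "write_name_map",
    "cigar_string",
]


class StreamError(ValueError):
    """Raised for inconsistent read streams or truth records."""


@dataclass(frozen=True)
class GenomeStat:
    """Realized per-genome statistics extracted from truth records."""

    genome_id: str
    read_count: int
    mean_depth: float


def concatenate_streams(streams: list[list[Fragment]]) -> list[Fragment]:
    """Concatenate per-contig streams in order; modes must not be mixed."""
    arities = {len(frag) for stream in streams for frag in stream}
    if len(arities) > 1:
        raise StreamError(f"mixed single/paired streams (fragment arities {sorted(arities)})")
    out: list[Fragment] = []
    for stream in streams:
        out.extend(stream)
    return out


def shuffle_reads(fragments: list[Fragment], seed: int) -> list[Fragment]:
    """Deterministic permutation of fragments (mates stay together)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(fragments))
    return [fragments[i] for i in perm]


def anonymize_reads(
    fragments: list[Fragment],
) -> tuple[list[Fragment], dict[str, str]]:
    """Replace read names with 1-based fragment indices.

    Single reads are named "<i>"; paired reads "<i>/1" and "<i>/2" in the
    FASTQ while the shared truth/SAM name is "<i>". Returns the anonymized
    stream and a map original name -> anonymous FASTQ name.
    """
    out: list[Fragment] = []
    name_map: dict[str, str] = {}
    for i, frag in enumerate(fragments, start=1):
        new_frag = []
        for read in frag:
            if read.truth.mate:
                anon = f"{i}/{read.truth.mate}"
            else:
                anon = str(i)
            name_map[f"{read.name}" + (f"/{read.truth.mate}" if read.truth.mate else "")] = anon
            truth = dataclasses.replace(read.truth, read_name=str(i))
            new_frag.append(dataclasses.replace(read, name=anon, truth=truth))
        out.append(tuple(new_frag))
    return out, name_map


def _open_out(path: Path, compress: bool):
    if compress:
        return gzip.open(path, "wt")
    return open(path, "w")


def write_fastq(
    fragments: list[Fragment], paths: list[str | Path], compress: bool = True
) -> list[Path]:
    """Write fragments as Phred+33 FASTQ (one file single, two paired)."""
    paths = [Path(p) for p in paths]
    arity = len(fragments[0]) if fragments else 1
    if len(paths) != arity:
        raise StreamError(f"{arity} file(s) expected for this stream, got {len(paths)}")
    handles = [_open_out(p, compress) for p in paths]
    try:
        for frag in fragments:
            if len(frag) != arity:
                raise StreamError("inconsistent fragment arity in stream")
            for read, fh in zip(frag, handles):
                fh.write(f"@{read.name}\n{read.sequence}\n+\n{read.qualities}\n")
    finally:
        for fh in handles:
            fh.close()
    return paths


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a (possibly gzipped) FASTQ into (name, sequence, qualities)."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    opener = gzip.open if magic == b"\x1f\x8b" else open
    records = []
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+"):
                raise StreamError(f"malformed FASTQ record in {path}")
            records.append((header[1:].rstrip("\n"), seq, qual))
    return records


_CIGAR_CODE = {"match": 0, "sub": 0, "ins": 1, "del": 2}  # M/I/D


def cigar_string(edit_ops) -> str:
    """CIGAR from edit ops; match and sub both map to M, runs merged."""
    merged: list[tuple[int, int]] = []
    for op, length, _alt in edit_ops:
        code = _CIGAR_CODE[op]
        if merged and merged[-1][0] == code:
            merged[-1] = (code, merged[-1][1] + length)
        else:
            merged.append((code, length))
    return "".join(f"{l}{'MID'[c]}" for c, l in merged)


def _cigar_tuples(edit_ops) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for op, length, _alt in edit_ops:
        code = _CIGAR_CODE[op]
        if merged and merged[-1][0] == code:
            merged[-1] = (code, merged[-1][1] + length)
        else:
            merged.append((code, length))
    return merged


def write_truth_alignment(
    fragments: list[Fragment],
    genomes: dict[str, Genome],
    path: str | Path,
    bam: bool = False,
    separator: str = "|",
) -> Path:
    """Write ground-truth alignments as SAM (or coordinate-sorted BAM).

    One reference per contig, named ``genome_id<separator>contig_id`` to
    avoid cross-genome contig-name collisions. POS is 1-based; SEQ is
    stored reference-forward (minus-strand reads are reverse-complemented
    back with flag 0x10); CIGAR comes from the truth edit operations.
    """
    path = Path(path)
    ref_names: list[str] = []
    ref_lengths: list[int] = []
    tid: dict[tuple[str, str], int] = {}
    contig_len: dict[tuple[str, str], int] = {}
    for gid, genome in genomes.items():
        for contig in genome.contigs:
            tid[(gid, contig.id)] = len(ref_names)
            contig_len[(gid, contig.id)] = contig.length
            ref_names.append(f"{gid}{separator}{contig.id}")
            ref_lengths.append(contig.length)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate" if bam else "unsorted"},
            "SQ": [
                {"SN": n, "LN": l} for n, l in zip(ref_names, ref_lengths)
            ],
        }
    )

    segments: list[pysam.AlignedSegment] = []
    for frag in fragments:
        paired = len(frag) == 2
        for k, read in enumerate(frag):
            t = read.truth
            key = (t.genome_id, t.contig_id)
            if key not in tid:
                raise StreamError(
                    f"truth record references unknown contig {t.genome_id}"
                    f"{separator}{t.contig_id}"
                )
            if t.start + t.aligned_length > contig_len[key]:
                raise StreamError(
                    f"read {t.read_name} overruns contig {t.contig_id}"
                )
            a = pysam.AlignedSegment(header)
            a.query_name = t.read_name
            flag = 0
            if t.strand == "-":
                flag |= 0x10
            if paired:
                mate = frag[1 - k]
                flag |= 0x1 | 0x2
                flag |= 0x40 if t.mate == 1 else 0x80
                if mate.truth.strand == "-":
                    flag |= 0x20
            a.flag = flag
            a.reference_id = tid[key]
            a.reference_start = t.start
            a.mapping_quality = 60
            a.cigartuples = _cigar_tuples(t.edit_ops)
            if t.strand == "-":
                a.query_sequence = revcomp(read.sequence)
                a.query_qualities = pysam.qualitystring_to_array(read.qualities[::-1])
            else:
                a.query_sequence = read.sequence
                a.query_qualities = pysam.qualitystring_to_array(read.qualities)
            if paired:
                mate_t = frag[1 - k].truth
                a.next_reference_id = tid[(mate_t.genome_id, mate_t.contig_id)]
                a.next_reference_start = mate_t.start
                left = min(t.start, mate_t.start)
                right = max(
                    t.start + t.aligned_length, mate_t.start + mate_t.aligned_length
                )
                tlen = right - left
                a.template_length = tlen if t.start <= mate_t.start else -tlen
            segments.append(a)

    if bam:
        segments.sort(key=lambda s: (s.reference_id, s.reference_start))
        with pysam.AlignmentFile(str(path), "wb", header=header) as out:
            for s in segments:
                out.write(s)
    else:
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for s in segments:
                out.write(s)
    return path


def realized_stats(
    truths: list[TruthRecord], genome_lengths: dict[str, int]
) -> dict[str, GenomeStat]:
    """Read counts and mean fold coverage per genome from truth records.

    mean_depth counts reference-consumed bases (match + sub + del) divided
    by genome length; genomes present in ``genome_lengths`` but absent from
    the truth set are retained with zero counts.
    """
    counts: dict[str, int] = {g: 0 for g in genome_lengths}
    bases: dict[str, int] = {g: 0 for g in genome_lengths}
    for t in truths:
        if t.genome_id not in counts:
            raise StreamError(f"truth record for unknown genome {t.genome_id!r}")
        counts[t.genome_id] += 1
        bases[t.genome_id] += t.aligned_length
    return {
        g: GenomeStat(
            genome_id=g,
            read_count=counts[g],
            mean_depth=bases[g] / genome_lengths[g],
        )
        for g in genome_lengths
    }


def write_name_map(name_map: dict[str, str], path: str | Path) -> Path:
    """Write the original -> anonymous name map as a two-column TSV."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("original\tanonymous\n")
        for orig, anon in name_map.items():
            fh.write(f"{orig}\t{anon}\n")
    return path
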