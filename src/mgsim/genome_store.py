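"""Genome and contig containers, FASTA ingestion, and synthetic genome fixtures.

Genomes are held in memory as ordered lists of contigs. Multi-contig genomes
are decomposed into contigs before simulation so read sampling is uniform
across the whole genome rather than biased toward any single sequence.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Contig",
    "Genome",
    "FastaFormatError",
    "read_fasta",
    "write_fasta",
    "load_genome",
    "split_contigs",
    "make_synthetic_genome",
    "read_manifest",
    "write_manifest",
    "load_genomes",
]

_VALID_BASES = frozenset("ACGTN")
# IUPAC ambiguity codes beyond N (and RNA U) that may be mapped to N on request.
_AMBIGUOUS = "RYSWKMBDHVU"
_AMBIGUOUS_TO_N = str.maketrans(_AMBIGUOUS, "N" * len(_AMBIGUOUS))


class FastaFormatError(ValueError):
    """Raised for malformed or empty FASTA input."""


@dataclass(frozen=True)
class Contig:
    """A single contiguous sequence; the unit of read simulation."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Genome:
    """An assembly: ordered contigs plus the taxon it represents."""

    genome_id: str
    taxid: int
    contigs: list[Contig] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.taxid <= 0:
            raise ValueError(f"taxid must be positive, got {self.taxid}")
        if not self.contigs:
            raise ValueError(f"genome {self.genome_id!r} has no contigs")
        ids = [c.id for c in self.contigs]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate contig ids in genome {self.genome_id!r}")

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.contigs)


def _open_text(path: str | Path, mode: str = "rt"):
    """Open plain or gzip-compressed text transparently (sniffs magic bytes)."""
    path = Path(path)
    if "r" in mode:
        with open(path, "rb") as fh:
            magic = fh.read(2)
        if magic == b"\x1f\x8b":
            return gzip.open(path, mode)
        return open(path, mode)
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _clean_sequence(raw: str, record_id: str, ambiguous: str) -> str:
    seq = raw.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        if ambiguous == "to_n":
            seq = seq.translate(_AMBIGUOUS_TO_N)
            bad = set(seq) - _VALID_BASES
        if bad:
            raise FastaFormatError(
                f"record {record_id!r} contains invalid characters: "
                f"{sorted(bad)} (ambiguity policy: {ambiguous!r})"
            )
    return seq


def read_fasta(path: str | Path, ambiguous: str = "error") -> list[Contig]:
    """Read a (possibly gzipped) FASTA file into a list of contigs.

    Sequences are uppercased; soft-masking is not preserved. ``ambiguous``
    controls characters outside {A,C,G,T,N}: ``"error"`` rejects them,
    ``"to_n"`` maps IUPAC codes to N.
    """
    if ambiguous not in ("error", "to_n"):
        raise ValueError(f"unknown ambiguity policy {ambiguous!r}")
    with _open_text(path) as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    if not records:
        raise FastaFormatError(f"no FASTA records in {path}")
    contigs: list[Contig] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FastaFormatError(f"duplicate FASTA header {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = _clean_sequence(str(rec.seq), rec.id, ambiguous)
        if not seq:
            raise FastaFormatError(f"empty sequence under header {rec.id!r} in {path}")
        contigs.append(Contig(id=rec.id, sequence=seq))
    return contigs


def write_fasta(contigs: list[Contig], path: str | Path, compress: bool = False) -> Path:
    """Write contigs to FASTA (gzip when requested or path ends in .gz)."""
    path = Path(path)
    records = [
        SeqRecord(Seq(c.sequence), id=c.id, description="") for c in contigs
    ]
    if compress or str(path).endswith(".gz"):
        with gzip.open(path, "wt") as fh:
            SeqIO.write(records, fh, "fasta")
    else:
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")
    return path


def load_genome(
    path: str | Path, genome_id: str, taxid: int, ambiguous: str = "error"
) -> Genome:
    """Read one FASTA file as a Genome with the given identity."""
    return Genome(genome_id=genome_id, taxid=taxid, contigs=read_fasta(path, ambiguous))


def split_contigs(genome: Genome) -> list[tuple[str, Contig]]:
    """Order-preserving decomposition of a genome into (contig_id, Contig)."""
    return [(c.id, c) for c in genome.contigs]


def make_synthetic_genome(
    length: int,
    gc: float = 0.5,
    n_contigs: int = 1,
    seed: int = 0,
    genome_id: str = "synthetic",
    taxid: int = 1,
) -> Genome:
    """Generate a random genome with the requested GC content.

    Bases are drawn i.i.d. with P(G) = P(C) = gc/2. Contig boundaries are
    drawn uniformly without replacement so contig lengths partition
    ``length``. Deterministic for a fixed seed.
    """
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    if length < n_contigs:
        raise ValueError(f"length {length} < n_contigs {n_contigs}")
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc must be in [0, 1], got {gc}")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    base_idx = rng.choice(4, size=length, p=probs)
    seq = alphabet[base_idx].tobytes().decode("ascii")
    if n_contigs == 1:
        cuts: list[int] = []
    else:
        cuts = sorted(rng.choice(np.arange(1, length), size=n_contigs - 1, replace=False))
    bounds = [0, *cuts, length]
    contigs = [
        Contig(id=f"{genome_id}_c{i + 1}", sequence=seq[bounds[i] : bounds[i + 1]])
        for i in range(n_contigs)
    ]
    return Genome(genome_id=genome_id, taxid=taxid, contigs=contigs)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a genome manifest TSV with columns genome_id, taxid, fasta_path."""
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str})
    required = {"genome_id", "taxid", "fasta_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    if df["genome_id"].duplicated().any():
        dupes = df.loc[df["genome_id"].duplicated(), "genome_id"].tolist()
        raise ValueError(f"duplicate genome_ids in manifest: {dupes}")
    return df


def write_manifest(rows: list[tuple[str, int, str]], path: str | Path) -> Path:
    df = pd.DataFrame(rows, columns=["genome_id", "taxid", "fasta_path"])
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def load_genomes(
    manifest: pd.DataFrame, base_dir: str | Path | None = None, ambiguous: str = "error"
) -> dict[str, Genome]:
    """Load every genome listed in a manifest, resolving relative paths."""
    base = Path(base_dir) if base_dir is not None else None
    genomes: dict[str, Genome] = {}
    for row in manifest.itertuples(index=False):
        fasta = Path(row.fasta_path)
        if base is not None and not fasta.is_absolute():
            fasta = base / fasta
        genomes[row.genome_id] = load_genome(
            fasta, genome_id=row.genome_id, taxid=int(row.taxid), ambiguous=ambiguous
        )
    return genomes
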