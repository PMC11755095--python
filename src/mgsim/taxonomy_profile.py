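"""Taxonomic lineage resolution and CAMI biobox profile output.

Profiles come in two flavors that differ whenever genome sizes differ:

* **sequence abundance** — a taxon's share of sequenced reads; scales with
  genome size at a fixed organism count.
* **taxonomic abundance** — a taxon's share of organisms, proxied by its
  share of coverage depth; genome-size-normalized.

Conflating the two biases benchmarking, so both are emitted for every
sample in the CAMI biobox profiling format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "RANKS",
    "TaxonomyError",
    "TaxNode",
    "TaxonomyTable",
    "ProfileRow",
    "Profile",
    "GenomeAbundance",
    "lineage",
    "build_profiles",
    "write_biobox",
    "read_biobox",
]

#: Canonical profiled ranks, root-most first ("kingdom" maps to superkingdom).
RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus", "species")
_RANK_INDEX = {r: i for i, r in enumerate(RANKS)}

BIOBOX_VERSION = "0.9.1"


class TaxonomyError(ValueError):
    """Raised for unknown taxids, cycles, or malformed taxonomy tables."""


@dataclass(frozen=True)
class TaxNode:
    parent: int
    rank: str
    name: str


class TaxonomyTable:
    """taxid -> (parent, rank, name) map with NCBI-dump-like TSV I/O.

    The root node is its own parent (taxid 1 by convention). Ranks outside
    the recognized set are traversed but never profiled.
    """

    def __init__(self, nodes: dict[int, TaxNode]):
        self.nodes = nodes

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def __getitem__(self, taxid: int) -> TaxNode:
        try:
            return self.nodes[taxid]
        except KeyError:
            raise TaxonomyError(f"taxid {taxid} not in taxonomy") from None

    def name(self, taxid: int) -> str:
        return self[taxid].name

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyTable":
        df = pd.read_csv(path, sep="\t")
        required = {"taxid", "parent", "rank", "name"}
        missing = required - set(df.columns)
        if missing:
            raise TaxonomyError(f"taxonomy {path} missing columns: {sorted(missing)}")
        nodes = {
            int(r.taxid): TaxNode(parent=int(r.parent), rank=str(r.rank), name=str(r.name))
            for r in df.itertuples(index=False)
        }
        return cls(nodes)

    def to_tsv(self, path: str | Path) -> Path:
        rows = [
            (taxid, n.parent, n.rank, n.name) for taxid, n in sorted(self.nodes.items())
        ]
        pd.DataFrame(rows, columns=["taxid", "parent", "rank", "name"]).to_csv(
            path, sep="\t", index=False
        )
        return Path(path)


def lineage(taxid: int, taxonomy: TaxonomyTable) -> list[tuple[str, int, str]]:
    """Recognized-rank lineage of a taxid, ordered root -> leaf.

    Missing intermediate ranks are simply absent (no placeholder nodes).
    Raises on unknown taxids and on parent-chain cycles.
    """
    if taxid not in taxonomy:
        raise TaxonomyError(f"taxid {taxid} not in taxonomy")
    chain: list[tuple[str, int, str]] = []
    seen: set[int] = set()
    current = taxid
    while True:
        if current in seen:
            raise TaxonomyError(f"cycle in taxonomy at taxid {current}")
        seen.add(current)
        node = taxonomy[current]
        if node.rank in _RANK_INDEX:
            chain.append((node.rank, current, node.name))
        if node.parent == current:  # root is its own parent
            break
        current = node.parent
    chain.reverse()
    return chain


@dataclass(frozen=True)
class ProfileRow:
    taxid: int
    rank: str
    taxpath: str  # pipe-joined taxids, root -> taxon
    taxpathsn: str  # pipe-joined names, same elements
    percentage: float


@dataclass
class Profile:
    sample_id: str
    flavor: str  # "sequence" or "taxonomic"
    rows: list[ProfileRow] = field(default_factory=list)

    def at_rank(self, rank: str) -> list[ProfileRow]:
        return [r for r in self.rows if r.rank == rank]

    def percentage(self, taxid: int) -> float:
        for r in self.rows:
            if r.taxid == taxid:
                return r.percentage
        raise KeyError(taxid)


@dataclass(frozen=True)
class GenomeAbundance:
    """Per-genome realized quantities feeding profile construction."""

    genome_id: str
    taxid: int
    read_count: int
    mean_depth: float


def _aggregate(
    stats: list[GenomeAbundance], taxonomy: TaxonomyTable, weight_attr: str
) -> dict[str, dict[int, float]]:
    """Sum a per-genome weight up every recognized rank of each lineage."""
    weights: dict[str, dict[int, float]] = {r: {} for r in RANKS}
    for s in stats:
        w = float(getattr(s, weight_attr))
        if w == 0:
            continue
        for rank, taxid, _name in lineage(s.taxid, taxonomy):
            weights[rank][taxid] = weights[rank].get(taxid, 0.0) + w
    return weights


def build_profiles(
    stats: list[GenomeAbundance], taxonomy: TaxonomyTable, sample_id: str = "sample"
) -> tuple[Profile, Profile]:
    """Build (sequence-flavor, taxonomic-flavor) profiles from genome stats.

    Sequence percentages weight each genome by its read count; taxonomic
    percentages weight by mean coverage depth. Genomes sharing a taxid
    aggregate; both flavors share identical taxpaths.
    """
    if not stats:
        raise TaxonomyError("no genome stats to profile")
    missing = sorted({s.taxid for s in stats if s.taxid not in taxonomy})
    if missing:
        raise TaxonomyError(f"taxids absent from taxonomy: {missing}")
    if all(s.read_count == 0 for s in stats):
        raise TaxonomyError("all read counts are zero; nothing to profile")

    # taxpath per taxid is shared across flavors
    paths: dict[int, tuple[str, str]] = {}
    for s in stats:
        for i, (rank, taxid, _name) in enumerate(chain := lineage(s.taxid, taxonomy)):
            if taxid not in paths:
                prefix = chain[: i + 1]
                paths[taxid] = (
                    "|".join(str(t) for _r, t, _n in prefix),
                    "|".join(n for _r, _t, n in prefix),
                )

    profiles = []
    for flavor, attr in (("sequence", "read_count"), ("taxonomic", "mean_depth")):
        weights = _aggregate(stats, taxonomy, attr)
        total = sum(float(getattr(s, attr)) for s in stats)
        rows: list[ProfileRow] = []
        for rank in RANKS:
            rank_rows = [
                ProfileRow(
                    taxid=taxid,
                    rank=rank,
                    taxpath=paths[taxid][0],
                    taxpathsn=paths[taxid][1],
                    percentage=100.0 * w / total,
                )
                for taxid, w in weights[rank].items()
                if w > 0
            ]
            rank_rows.sort(key=lambda r: (-r.percentage, r.taxid))
            rows.extend(rank_rows)
        profiles.append(Profile(sample_id=sample_id, flavor=flavor, rows=rows))
    return profiles[0], profiles[1]


def write_biobox(profile: Profile, path: str | Path, version: str = BIOBOX_VERSION) -> Path:
    """Write a profile in the CAMI biobox profiling format.

    Rows are ordered by rank (root -> species) then descending percentage;
    percentages carry six decimal places. Zero-abundance taxa are omitted.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"@SampleID:{profile.sample_id}\n")
        fh.write(f"@Version:{version}\n")
        fh.write(f"@Ranks:{'|'.join(RANKS)}\n")
        fh.write("@@TAXID\tRANK\tTAXPATH\tTAXPATHSN\tPERCENTAGE\n")
        for rank in RANKS:
            for row in profile.at_rank(rank):
                fh.write(
                    f"{row.taxid}\t{row.rank}\t{row.taxpath}\t{row.taxpathsn}\t"
                    f"{row.percentage:.6f}\n"
                )
    return path


def read_biobox(path: str | Path) -> Profile:
    """Parse a biobox profile file written by :func:`write_biobox`."""
    sample_id = "sample"
    rows: list[ProfileRow] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("@SampleID:"):
                sample_id = line.split(":", 1)[1]
            elif line.startswith("@"):
                continue
            else:
                taxid, rank, taxpath, taxpathsn, pct = line.split("\t")
                rows.append(
                    ProfileRow(
                        taxid=int(taxid),
                        rank=rank,
                        taxpath=taxpath,
                        taxpathsn=taxpathsn,
                        percentage=float(pct),
                    )
                )
    return Profile(sample_id=sample_id, flavor="unknown", rows=rows)
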