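"""Offline assembly ranking and selection from metadata tables.

Assemblies are ordered by a configurable policy; the default prefers NCBI
reference over representative genomes, more complete assembly levels, then
higher BUSCO and checkM completeness, with the accession as a final
tie-break so the order is total and stable. Selection can be capped per
taxonomic group (e.g. the ten best-ranking genomes per genus).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .taxonomy_profile import TaxonomyTable, lineage

__all__ = [
    "CATEGORY_ORDER",
    "STATUS_ORDER",
    "AssemblyRecord",
    "RankingPolicy",
    "MetadataError",
    "rank_assemblies",
    "top_n_per_rank",
    "filter_assemblies",
    "read_assembly_table",
    "write_ranked_table",
]

log = logging.getLogger(__name__)

CATEGORY_ORDER = {"reference": 0, "representative": 1, "na": 2}
STATUS_ORDER = {"complete": 0, "chromosome": 1, "scaffold": 2, "contig": 3}


class MetadataError(ValueError):
    """Raised for malformed assembly metadata rows."""


@dataclass(frozen=True)
class AssemblyRecord:
    accession: str
    taxid: int
    refseq_category: str = "na"
    assembly_status: str = "contig"
    busco_completeness: float | None = None
    checkm_completeness: float | None = None

    def __post_init__(self) -> None:
        if self.refseq_category not in CATEGORY_ORDER:
            raise MetadataError(
                f"{self.accession}: unknown refseq_category {self.refseq_category!r}"
            )
        if self.assembly_status not in STATUS_ORDER:
            raise MetadataError(
                f"{self.accession}: unknown assembly_status {self.assembly_status!r}"
            )
        for name in ("busco_completeness", "checkm_completeness"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 100.0:
                raise MetadataError(f"{self.accession}: {name} out of [0, 100]: {v}")


@dataclass(frozen=True)
class RankingPolicy:
    """Ordered sort keys; the accession is always the terminal tie-break.

    Keys: "category" (reference < representative < na), "status"
    (complete < chromosome < scaffold < contig), "busco" and "checkm"
    (descending, missing scores after any present value).
    """

    keys: tuple[str, ...] = ("category", "status", "busco", "checkm")

    def __post_init__(self) -> None:
        allowed = {"category", "status", "busco", "checkm"}
        unknown = set(self.keys) - allowed
        if unknown:
            raise ValueError(f"unknown policy keys: {sorted(unknown)}")

    def sort_key(self, rec: AssemblyRecord) -> tuple:
        parts: list = []
        for key in self.keys:
            if key == "category":
                parts.append(CATEGORY_ORDER[rec.refseq_category])
            elif key == "status":
                parts.append(STATUS_ORDER[rec.assembly_status])
            elif key == "busco":
                v = rec.busco_completeness
                parts.append((v is None, -(v if v is not None else 0.0)))
            elif key == "checkm":
                v = rec.checkm_completeness
                parts.append((v is None, -(v if v is not None else 0.0)))
        parts.append(rec.accession)
        return tuple(parts)


def rank_assemblies(
    records: list[AssemblyRecord], policy: RankingPolicy | None = None
) -> list[AssemblyRecord]:
    """Return records in best-first order under the policy (stable, total)."""
    if not records:
        raise ValueError("no assembly records to rank")
    policy = policy or RankingPolicy()
    return sorted(records, key=policy.sort_key)


def top_n_per_rank(
    records: list[AssemblyRecord],
    taxonomy: TaxonomyTable,
    rank: str,
    n: int,
    policy: RankingPolicy | None = None,
) -> dict[int | str, list[AssemblyRecord]]:
    """Group records by their ancestor at ``rank``; keep the n best of each.

    Records whose lineage lacks the requested rank group under
    ``"unresolved"``. Each group is ranked independently.
    """
    from .taxonomy_profile import RANKS

    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    if n < 1:
        raise ValueError("n must be >= 1")
    policy = policy or RankingPolicy()
    groups: dict[int | str, list[AssemblyRecord]] = {}
    for rec in records:
        ancestor: int | str = "unresolved"
        for lin_rank, taxid, _name in lineage(rec.taxid, taxonomy):
            if lin_rank == rank:
                ancestor = taxid
                break
        groups.setdefault(ancestor, []).append(rec)
    return {
        g: rank_assemblies(members, policy)[:n] for g, members in groups.items()
    }


def filter_assemblies(
    records: list[AssemblyRecord],
    min_status: str | None = None,
    categories: set[str] | None = None,
    min_busco: float | None = None,
    min_checkm: float | None = None,
    drop_missing: bool = True,
) -> list[AssemblyRecord]:
    """Order-preserving subset of records meeting the constraints.

    ``min_status`` keeps assemblies at that level or better (complete is
    best). Completeness thresholds drop records with missing scores when
    ``drop_missing`` is true, otherwise keep them.
    """
    if min_status is not None and min_status not in STATUS_ORDER:
        raise MetadataError(f"unknown assembly_status {min_status!r}")
    out = []
    for rec in records:
        if min_status is not None and STATUS_ORDER[rec.assembly_status] > STATUS_ORDER[min_status]:
            continue
        if categories is not None and rec.refseq_category not in categories:
            continue
        keep = True
        for threshold, value in (
            (min_busco, rec.busco_completeness),
            (min_checkm, rec.checkm_completeness),
        ):
            if threshold is None:
                continue
            if value is None:
                if drop_missing:
                    keep = False
            elif value < threshold:
                keep = False
        if keep:
            out.append(rec)
    if not out:
        log.warning("assembly filter produced an empty selection")
    return out


def read_assembly_table(path: str | Path) -> list[AssemblyRecord]:
    """Read an assembly metadata TSV into records.

    Columns: accession, taxid, refseq_category, assembly_status,
    busco_completeness, checkm_completeness (completeness may be empty).
    Parse errors name the offending row.
    """
    df = pd.read_csv(path, sep="\t", dtype={"accession": str})
    required = {"accession", "taxid", "refseq_category", "assembly_status"}
    missing = required - set(df.columns)
    if missing:
        raise MetadataError(f"metadata {path} missing columns: {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        try:
            records.append(
                AssemblyRecord(
                    accession=row.accession,
                    taxid=int(row.taxid),
                    refseq_category=str(row.refseq_category),
                    assembly_status=str(row.assembly_status),
                    busco_completeness=_opt_float(getattr(row, "busco_completeness", None)),
                    checkm_completeness=_opt_float(getattr(row, "checkm_completeness", None)),
                )
            )
        except MetadataError as exc:
            raise MetadataError(f"{path} line {i}: {exc}") from None
    return records


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    return float(value)


def write_ranked_table(records: list[AssemblyRecord], path: str | Path) -> Path:
    """Write ranked records as TSV with a 1-based rank column prepended."""
    rows = [
        (
            i,
            r.accession,
            r.taxid,
            r.refseq_category,
            r.assembly_status,
            r.busco_completeness,
            r.checkm_completeness,
        )
        for i, r in enumerate(records, start=1)
    ]
    pd.DataFrame(
        rows,
        columns=[
            "rank",
            "accession",
            "taxid",
            "refseq_category",
            "assembly_status",
            "busco_completeness",
            "checkm_completeness",
        ],
    ).to_csv(path, sep="\t", index=False)
    return Path(path)
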