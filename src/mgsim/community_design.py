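"""Community design: abundances, unit conversion, and replicate expansion.

A community is a list of per-genome quantities in one of five units —
read counts, base counts, fold coverage, sequence abundance (share of reads)
or taxonomic abundance (share of organisms). All units are converted to
per-genome coverage depths by normalizing to genome sizes; integer read
budgets are then apportioned with largest-remainder rounding so sample
totals are met exactly.

The distinction between the two abundance flavors is central: at equal
taxonomic abundance a genome twice as long receives twice the reads
(sequence abundance scales with genome size), whereas equal sequence
abundance implies fewer organisms of the longer genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .seeds import child_seed, rng_for

__all__ = [
    "UNITS",
    "DesignError",
    "CommunityEntry",
    "CommunityDesign",
    "GenomeCoverage",
    "CoveragePlan",
    "largest_remainder",
    "draw_even",
    "draw_lognormal",
    "lognormal_raw",
    "to_coverage",
    "expand_replicates",
    "read_community_table",
]

UNITS = ("reads", "bases", "coverage", "seq_abundance", "tax_abundance")
_ABUNDANCE_UNITS = ("seq_abundance", "tax_abundance")


class DesignError(ValueError):
    """Raised when a community design is internally inconsistent."""


@dataclass(frozen=True)
class CommunityEntry:
    genome_id: str
    quantity: float
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise DesignError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if self.quantity < 0:
            raise DesignError(
                f"quantity for {self.genome_id!r} must be >= 0, got {self.quantity}"
            )


@dataclass
class CommunityDesign:
    """One sample's input contract: entries plus budgets and replicate spec."""

    sample_id: str
    entries: list[CommunityEntry]
    total_reads: int | None = None
    total_bases: int | None = None
    seed: int = 0
    n_replicates: int = 1
    replicate_sd: float = 0.0

    def __post_init__(self) -> None:
        if not self.entries:
            raise DesignError(f"sample {self.sample_id!r} has no entries")
        if self.n_replicates < 1:
            raise DesignError("n_replicates must be >= 1")
        if self.replicate_sd < 0:
            raise DesignError("replicate_sd must be >= 0")
        units = {e.unit for e in self.entries}
        for ab in _ABUNDANCE_UNITS:
            if ab in units and len(units) > 1:
                raise DesignError(
                    f"abundance unit {ab!r} cannot be mixed with other units"
                )


@dataclass(frozen=True)
class GenomeCoverage:
    genome_id: str
    coverage_depth: float
    expected_reads: int
    expected_bases: int


@dataclass
class CoveragePlan:
    """Resolved per-genome depths and integer read budgets for one replicate."""

    sample_id: str
    replicate_index: int
    seed: int
    genomes: list[GenomeCoverage]

    @property
    def total_reads(self) -> int:
        return sum(g.expected_reads for g in self.genomes)

    @property
    def total_bases(self) -> int:
        return sum(g.expected_bases for g in self.genomes)

    def depth(self, genome_id: str) -> float:
        for g in self.genomes:
            if g.genome_id == genome_id:
                return g.coverage_depth
        raise KeyError(genome_id)


def largest_remainder(weights, total: int) -> list[int]:
    """Apportion ``total`` integer units proportionally to ``weights``.

    Hamilton's method: floor the exact shares, then hand the remaining units
    to the largest fractional parts (ties broken by input order). Preserves
    the total exactly and is deterministic.
    """
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise DesignError("cannot apportion over an empty weight list")
    if np.any(w < 0):
        raise DesignError("weights must be non-negative")
    if total < 0:
        raise DesignError("total must be >= 0")
    s = w.sum()
    if s == 0:
        if total == 0:
            return [0] * w.size
        raise DesignError("all weights are zero but total > 0")
    exact = w / s * total
    floors = np.floor(exact).astype(int)
    remainder = total - int(floors.sum())
    if remainder > 0:
        frac = exact - floors
        # stable argsort descending on fraction; ties fall back to input order
        order = np.argsort(-frac, kind="stable")
        floors[order[:remainder]] += 1
    return floors.tolist()


def draw_even(genome_ids: list[str]) -> list[float]:
    """Equal proportions: 1/n for each of n genomes."""
    if not genome_ids:
        raise DesignError("cannot draw abundances for an empty genome list")
    n = len(genome_ids)
    return [1.0 / n] * n


def lognormal_raw(n: int, mu: float, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Raw (unnormalized) lognormal abundance draws exp(Normal(mu, sigma))."""
    if sigma <= 0:
        raise DesignError(f"sigma must be > 0, got {sigma}")
    return np.exp(rng.normal(mu, sigma, size=n))


def draw_lognormal(
    genome_ids: list[str], mu: float = 1.0, sigma: float = 2.0, seed: int = 0
) -> list[float]:
    """Lognormal community abundances, normalized to sum 1.

    The lognormal species-abundance distribution is the conventional model
    for uneven microbial communities; mu/sigma parameterize the underlying
    normal on the log scale.
    """
    if not genome_ids:
        raise DesignError("cannot draw abundances for an empty genome list")
    raw = lognormal_raw(len(genome_ids), mu, sigma, np.random.default_rng(seed))
    return (raw / raw.sum()).tolist()


def _resolve_depths(
    design: CommunityDesign,
    genome_lengths: dict[str, int],
    read_footprint: int,
) -> list[float]:
    for e in design.entries:
        if e.genome_id not in genome_lengths:
            raise KeyError(f"no genome length for {e.genome_id!r}")
    units = {e.unit for e in design.entries}
    quantities = np.array([e.quantity for e in design.entries], dtype=float)
    if quantities.sum() == 0:
        raise DesignError(f"sample {design.sample_id!r}: all quantities are zero")
    lengths = np.array(
        [genome_lengths[e.genome_id] for e in design.entries], dtype=float
    )

    if units == {"seq_abundance"}:
        if design.total_reads is None:
            raise DesignError("seq_abundance requires total_reads")
        frac = quantities / quantities.sum()
        reads = frac * design.total_reads
        return (reads * read_footprint / lengths).tolist()

    if units == {"tax_abundance"}:
        total_bases = design.total_bases
        if total_bases is None:
            if design.total_reads is None:
                raise DesignError(
                    "tax_abundance requires total_bases (or total_reads "
                    "with a read length)"
                )
            total_bases = design.total_reads * read_footprint
        frac = quantities / quantities.sum()
        # depth_i = frac_i * C_tot with C_tot chosen so sum(depth_i * L_i)
        # equals the base budget exactly.
        c_tot = total_bases / float((frac * lengths).sum())
        return (frac * c_tot).tolist()

    depths = []
    for e, length in zip(design.entries, lengths):
        if e.unit == "coverage":
            depths.append(e.quantity)
        elif e.unit == "bases":
            depths.append(e.quantity / length)
        elif e.unit == "reads":
            depths.append(e.quantity * read_footprint / length)
        else:  # pragma: no cover - excluded by CommunityDesign validation
            raise DesignError(f"unit {e.unit!r} cannot be mixed")
    return depths


def to_coverage(
    design: CommunityDesign,
    genome_lengths: dict[str, int],
    read_footprint: int,
    paired: bool = False,
    replicate_index: int = 0,
    seed: int | None = None,
) -> CoveragePlan:
    """Convert a community design to per-genome depths and read budgets.

    ``read_footprint`` is the length of one read (one mate for paired data;
    read counts always count individual reads, not pairs). Integer reads are
    apportioned by largest remainder so the sample total matches the budget
    when one was given; paired budgets are apportioned in fragment units so
    per-genome counts stay even.
    """
    if read_footprint <= 0:
        raise DesignError("read_footprint must be positive")
    depths = _resolve_depths(design, genome_lengths, read_footprint)
    lengths = [genome_lengths[e.genome_id] for e in design.entries]
    exact_reads = [d * L / read_footprint for d, L in zip(depths, lengths)]

    units = {e.unit for e in design.entries}
    if units == {"seq_abundance"}:
        budget = int(design.total_reads)
    elif units == {"tax_abundance"}:
        total_bases = design.total_bases
        if total_bases is None:
            total_bases = design.total_reads * read_footprint
        budget = int(round(total_bases / read_footprint))
    elif design.total_reads is not None:
        budget = int(design.total_reads)
    else:
        budget = int(round(sum(exact_reads)))

    if paired:
        frags = largest_remainder([r / 2 for r in exact_reads], budget // 2)
        reads = [2 * f for f in frags]
    else:
        reads = largest_remainder(exact_reads, budget)

    genomes = [
        GenomeCoverage(
            genome_id=e.genome_id,
            coverage_depth=float(d),
            expected_reads=int(r),
            expected_bases=int(r) * read_footprint,
        )
        for e, d, r in zip(design.entries, depths, reads)
    ]
    return CoveragePlan(
        sample_id=design.sample_id,
        replicate_index=replicate_index,
        seed=design.seed if seed is None else seed,
        genomes=genomes,
    )


def expand_replicates(
    design: CommunityDesign,
    genome_lengths: dict[str, int],
    read_footprint: int,
    paired: bool = False,
) -> list[CoveragePlan]:
    """Expand a design into one coverage plan per technical replicate.

    Replicate r perturbs each entry's quantity with independent additive
    Normal(0, replicate_sd) noise, truncated at zero, before unit
    conversion. With replicate_sd = 0 all replicates share identical depths
    and differ only through their child seeds (distinct read sampling).
    """
    plans: list[CoveragePlan] = []
    for r in range(design.n_replicates):
        if design.replicate_sd > 0:
            entries = []
            for e in design.entries:
                rng = rng_for(design.seed, design.sample_id, r, e.genome_id)
                q = max(0.0, e.quantity + rng.normal(0.0, design.replicate_sd))
                entries.append(replace(e, quantity=q))
            rep_design = replace(design, entries=entries)
        else:
            rep_design = design
        rep_seed = child_seed(design.seed, design.sample_id, r)
        if all(e.quantity == 0 for e in rep_design.entries):
            # extreme noise truncated everything to zero: an empty replicate
            plans.append(
                CoveragePlan(
                    sample_id=design.sample_id,
                    replicate_index=r,
                    seed=rep_seed,
                    genomes=[
                        GenomeCoverage(e.genome_id, 0.0, 0, 0)
                        for e in rep_design.entries
                    ],
                )
            )
            continue
        plans.append(
            to_coverage(
                rep_design,
                genome_lengths,
                read_footprint,
                paired=paired,
                replicate_index=r,
                seed=rep_seed,
            )
        )
    return plans


def read_community_table(path) -> dict[str, list[CommunityEntry]]:
    """Read a community TSV (sample_id, genome_id, quantity, unit) by sample."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "genome_id": str})
    required = {"sample_id", "genome_id", "quantity", "unit"}
    missing = required - set(df.columns)
    if missing:
        raise DesignError(f"community table {path} missing columns: {sorted(missing)}")
    samples: dict[str, list[CommunityEntry]] = {}
    for row in df.itertuples(index=False):
        samples.setdefault(row.sample_id, []).append(
            CommunityEntry(
                genome_id=row.genome_id, quantity=float(row.quantity), unit=row.unit
            )
        )
    return samples
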