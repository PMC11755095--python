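"""In-process pipeline: design -> allocation -> simulation -> deliverables.

One call runs every sample and replicate of a configured study: community
quantities are converted to coverage plans, reads are simulated per contig
under hierarchical child seeds, then concatenated, shuffled, anonymized and
written as FASTQ alongside a ground-truth SAM, a realized-stats table and
sequence/taxonomic biobox profiles. A machine-readable run manifest records
inputs, seeds and versions so any run can be replayed exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .community_design import (
    CommunityDesign,
    CoveragePlan,
    expand_replicates,
    read_community_table,
)
from .genome_store import Genome, load_genomes, read_manifest
from .read_sim import (
    Fragment,
    LongReadParams,
    ShortReadParams,
    simulate_long,
    simulate_short,
    truncated_lognormal_mean,
)
from .sample_io import (
    anonymize_reads,
    concatenate_streams,
    realized_stats,
    shuffle_reads,
    write_fastq,
    write_name_map,
    write_truth_alignment,
)
from .seeds import child_seed
from .taxonomy_profile import (
    GenomeAbundance,
    TaxonomyTable,
    build_profiles,
    write_biobox,
)

__all__ = ["ConfigError", "RunConfig", "SampleResult", "run_simulation", "replay"]

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised when a run configuration fails validation (before simulation)."""


@dataclass
class RunConfig:
    """Validated run configuration (usually parsed from YAML)."""

    community: Path
    manifest: Path
    taxonomy: Path
    output: Path
    tech: str = "short"
    short: ShortReadParams = field(default_factory=ShortReadParams)
    long: LongReadParams = field(default_factory=LongReadParams)
    total_reads: int | None = None
    total_bases: int | None = None
    seed: int = 0
    replicates: int = 1
    replicate_sd: float = 0.0
    compress: bool = True
    emit_bam: bool = False
    emit_name_map: bool = False
    threads: int = 1
    ambiguous: str = "error"
    separator: str = "|"

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path | None = None) -> "RunConfig":
        raw = dict(raw)
        base = base_dir or Path.cwd()

        def resolve(key: str) -> Path:
            if key not in raw or raw[key] is None:
                raise ConfigError(f"config is missing required key {key!r}")
            p = Path(raw.pop(key))
            return p if p.is_absolute() else base / p

        community = resolve("community")
        manifest = resolve("manifest")
        taxonomy = resolve("taxonomy")
        output = resolve("output")
        tech = raw.pop("tech", "short")
        if tech not in ("short", "long"):
            raise ConfigError(f"tech must be 'short' or 'long', got {tech!r}")
        try:
            short = ShortReadParams(**raw.pop("short", {}))
            long_ = LongReadParams(**raw.pop("long", {}))
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid simulator parameters: {exc}") from None
        known = {
            "total_reads", "total_bases", "seed", "replicates", "replicate_sd",
            "compress", "emit_bam", "emit_name_map", "threads", "ambiguous",
            "separator",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(
            community=community,
            manifest=manifest,
            taxonomy=taxonomy,
            output=output,
            tech=tech,
            short=short,
            long=long_,
            **{k: raw[k] for k in known if k in raw and raw[k] is not None},
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} is not a YAML mapping")
        return cls.from_dict(raw, base_dir=path.parent)

    def validate(self) -> None:
        """Fail fast on missing inputs, before any simulation starts."""
        for key in ("community", "manifest", "taxonomy"):
            p = getattr(self, key)
            if not Path(p).exists():
                raise ConfigError(f"{key} file does not exist: {p}")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if self.replicate_sd < 0:
            raise ConfigError("replicate_sd must be >= 0")
        if self.threads < 1:
            raise ConfigError("threads must be >= 1")

    def to_dict(self) -> dict:
        return {
            "community": str(self.community),
            "manifest": str(self.manifest),
            "taxonomy": str(self.taxonomy),
            "output": str(self.output),
            "tech": self.tech,
            "short": dataclasses.asdict(self.short),
            "long": dataclasses.asdict(self.long),
            "total_reads": self.total_reads,
            "total_bases": self.total_bases,
            "seed": self.seed,
            "replicates": self.replicates,
            "replicate_sd": self.replicate_sd,
            "compress": self.compress,
            "emit_bam": self.emit_bam,
            "emit_name_map": self.emit_name_map,
            "threads": self.threads,
            "ambiguous": self.ambiguous,
            "separator": self.separator,
        }


@dataclass
class SampleResult:
    """Paths and realized counts for one sample replicate."""

    sample_id: str
    replicate: int
    fastq_paths: list[Path]
    truth_path: Path
    stats_path: Path
    profile_paths: dict[str, Path]
    n_reads: int
    name_map_path: Path | None = None


def _read_footprint(config: RunConfig) -> int:
    if config.tech == "short":
        return config.short.read_length
    return int(
        round(
            truncated_lognormal_mean(
                config.long.length_log_mean,
                config.long.length_log_sd,
                config.long.min_length,
            )
        )
    )


def _min_contig_length(config: RunConfig) -> int:
    return config.short.read_length if config.tech == "short" else config.long.min_length


def _simulate_genome(
    genome: Genome, n_reads: int, config: RunConfig, plan_seed: int
) -> list[list[Fragment]]:
    """Allocate a genome's read budget over its contigs and simulate each."""
    from .read_sim import allocate_reads_per_contig

    paired = config.tech == "short" and config.short.paired
    min_len = _min_contig_length(config)
    eligible = [c for c in genome.contigs if c.length >= min_len]
    skipped = len(genome.contigs) - len(eligible)
    if skipped:
        log.warning(
            "genome %s: %d contig(s) shorter than %d bp excluded from allocation",
            genome.genome_id,
            skipped,
            min_len,
        )
    if not eligible:
        log.warning("genome %s has no eligible contigs; zero reads", genome.genome_id)
        return []
    units = n_reads // 2 if paired else n_reads
    alloc = allocate_reads_per_contig(units, [c.length for c in eligible])

    def task(contig, k):
        seed = child_seed(plan_seed, genome.genome_id, contig.id)
        if config.tech == "short":
            return simulate_short(
                contig, k * 2 if paired else k, config.short, seed, genome.genome_id
            )
        return simulate_long(contig, k, config.long, seed, genome.genome_id)

    pairs = [(c, k) for c, k in zip(eligible, alloc) if k > 0]
    if config.threads > 1 and len(pairs) > 1:
        with ThreadPoolExecutor(max_workers=config.threads) as pool:
            return list(pool.map(lambda ck: task(*ck), pairs))
    return [task(c, k) for c, k in pairs]


def _run_replicate(
    plan: CoveragePlan,
    genomes: dict[str, Genome],
    taxonomy: TaxonomyTable,
    config: RunConfig,
    outdir: Path,
) -> SampleResult:
    paired = config.tech == "short" and config.short.paired
    streams: list[list[Fragment]] = []
    for gc in plan.genomes:
        if gc.expected_reads == 0:
            continue
        streams.extend(
            _simulate_genome(genomes[gc.genome_id], gc.expected_reads, config, plan.seed)
        )
    fragments = concatenate_streams(streams)
    fragments = shuffle_reads(fragments, child_seed(plan.seed, "shuffle"))
    fragments, name_map = anonymize_reads(fragments)

    tag = f"{plan.sample_id}_rep{plan.replicate_index + 1}"
    ext = ".fastq.gz" if config.compress else ".fastq"
    if paired:
        fastq_paths = [outdir / f"{tag}_R1{ext}", outdir / f"{tag}_R2{ext}"]
    else:
        fastq_paths = [outdir / f"{tag}{ext}"]
    write_fastq(fragments, fastq_paths, compress=config.compress)

    sample_genomes = {gc.genome_id: genomes[gc.genome_id] for gc in plan.genomes}
    truth_path = outdir / f"{tag}.truth.sam"
    write_truth_alignment(
        fragments, sample_genomes, truth_path, bam=False, separator=config.separator
    )
    if config.emit_bam:
        write_truth_alignment(
            fragments,
            sample_genomes,
            outdir / f"{tag}.truth.bam",
            bam=True,
            separator=config.separator,
        )

    truths = [read.truth for frag in fragments for read in frag]
    lengths = {g.genome_id: g.total_length for g in sample_genomes.values()}
    stats = realized_stats(truths, lengths)

    stats_path = outdir / f"{tag}.stats.tsv"
    with open(stats_path, "w") as fh:
        fh.write(
            "genome_id\ttaxid\tplanned_depth\texpected_reads\tread_count\tmean_depth\n"
        )
        for gc in plan.genomes:
            s = stats[gc.genome_id]
            fh.write(
                f"{gc.genome_id}\t{sample_genomes[gc.genome_id].taxid}\t"
                f"{gc.coverage_depth:.6f}\t{gc.expected_reads}\t"
                f"{s.read_count}\t{s.mean_depth:.6f}\n"
            )

    abundances = [
        GenomeAbundance(
            genome_id=g,
            taxid=sample_genomes[g].taxid,
            read_count=stats[g].read_count,
            mean_depth=stats[g].mean_depth,
        )
        for g in lengths
    ]
    seq_prof, tax_prof = build_profiles(abundances, taxonomy, sample_id=tag)
    profile_paths = {
        "sequence": write_biobox(seq_prof, outdir / f"{tag}.sequence_abundance.profile"),
        "taxonomic": write_biobox(tax_prof, outdir / f"{tag}.taxonomic_abundance.profile"),
    }

    name_map_path = None
    if config.emit_name_map:
        name_map_path = write_name_map(name_map, outdir / f"{tag}.name_map.tsv")

    return SampleResult(
        sample_id=plan.sample_id,
        replicate=plan.replicate_index,
        fastq_paths=fastq_paths,
        truth_path=truth_path,
        stats_path=stats_path,
        profile_paths=profile_paths,
        n_reads=sum(len(f) for f in fragments),
        name_map_path=name_map_path,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_simulation(config: RunConfig) -> list[SampleResult]:
    """Run the full pipeline for every sample/replicate in the config."""
    config.validate()
    outdir = Path(config.output)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest = read_manifest(config.manifest)
    genomes = load_genomes(
        manifest, base_dir=Path(config.manifest).parent, ambiguous=config.ambiguous
    )
    taxonomy = TaxonomyTable.from_tsv(config.taxonomy)
    samples = read_community_table(config.community)
    lengths = {g.genome_id: g.total_length for g in genomes.values()}
    footprint = _read_footprint(config)
    paired = config.tech == "short" and config.short.paired

    results: list[SampleResult] = []
    for sample_id, entries in samples.items():
        for e in entries:
            if e.genome_id not in genomes:
                raise ConfigError(
                    f"sample {sample_id!r}: genome {e.genome_id!r} not in manifest"
                )
        design = CommunityDesign(
            sample_id=sample_id,
            entries=entries,
            total_reads=config.total_reads,
            total_bases=config.total_bases,
            seed=config.seed,
            n_replicates=config.replicates,
            replicate_sd=config.replicate_sd,
        )
        plans = expand_replicates(design, lengths, footprint, paired=paired)
        for plan in plans:
            results.append(_run_replicate(plan, genomes, taxonomy, config, outdir))

    manifest_payload = {
        "package": "mgsim",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "input_sha256": {
            str(p): _sha256(Path(p))
            for p in (config.community, config.manifest, config.taxonomy)
        },
        "samples": [
            {
                "sample_id": r.sample_id,
                "replicate": r.replicate,
                "fastq": [str(p) for p in r.fastq_paths],
                "truth": str(r.truth_path),
                "stats": str(r.stats_path),
                "profiles": {k: str(v) for k, v in r.profile_paths.items()},
                "n_reads": r.n_reads,
            }
            for r in results
        ],
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest_payload, fh, indent=2)
    return results


def replay(manifest_path: str | Path, output: str | Path) -> list[SampleResult]:
    """Re-run a simulation exactly as recorded in its run manifest."""
    with open(manifest_path) as fh:
        payload = json.load(fh)
    raw = dict(payload["config"])
    raw["output"] = str(output)
    config = RunConfig.from_dict(raw)
    return run_simulation(config)
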