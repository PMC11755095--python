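"""Synthetic test-world generation: genomes, taxonomy, metadata, communities.

Everything a simulation run needs — genome FASTAs, a taxonomy dump, an
assembly-metadata table, community tables and miniature body-site-style
template tables — is generated deterministically from a seed, so no
download is ever required. The taxonomy is a complete seven-rank tree
(superkingdom through species) and genomes carry species-level taxids.

The template tables are explicitly artificial stand-ins shaped like real
body-site communities (taxid + taxonomic abundance summing to one), not
curated from any survey data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .assembly_rank import AssemblyRecord
from .community_design import draw_lognormal
from .genome_store import Genome, make_synthetic_genome, write_fasta, write_manifest
from .seeds import rng_for
from .taxonomy_profile import TaxNode, TaxonomyTable

__all__ = [
    "FixtureWorld",
    "build_taxonomy",
    "build_world",
    "random_assembly_records",
    "write_fixture_set",
]

_CATEGORIES = ["reference", "representative", "na"]
_STATUSES = ["complete", "chromosome", "scaffold", "contig"]


@dataclass
class FixtureWorld:
    """An in-memory synthetic study system."""

    taxonomy: TaxonomyTable
    genomes: list[Genome]
    species_taxids: list[int] = field(default_factory=list)

    def genome_by_id(self, genome_id: str) -> Genome:
        for g in self.genomes:
            if g.genome_id == genome_id:
                return g
        raise KeyError(genome_id)


def build_taxonomy(n_genera: int = 2, species_per_genus: int = 2) -> TaxonomyTable:
    """A complete 7-rank taxonomy with the requested genus/species counts.

    Genera are split across two phyla (each with its own class, order and
    family chain) so profiles have non-trivial structure at every rank.
    Species taxids are 1000, 1001, ... in genus order.
    """
    if n_genera < 1 or species_per_genus < 1:
        raise ValueError("need at least one genus and one species per genus")
    nodes: dict[int, TaxNode] = {
        1: TaxNode(parent=1, rank="no rank", name="root"),
        2: TaxNode(parent=1, rank="superkingdom", name="Bacteria"),
    }
    n_phyla = min(2, n_genera)
    next_id = 10
    family_ids = []
    for p in range(n_phyla):
        phylum, cls, order, family = next_id, next_id + 1, next_id + 2, next_id + 3
        next_id += 4
        nodes[phylum] = TaxNode(parent=2, rank="phylum", name=f"Phylum{chr(65 + p)}")
        nodes[cls] = TaxNode(parent=phylum, rank="class", name=f"Class{chr(65 + p)}")
        nodes[order] = TaxNode(parent=cls, rank="order", name=f"Order{chr(65 + p)}")
        nodes[family] = TaxNode(parent=order, rank="family", name=f"Family{chr(65 + p)}")
        family_ids.append(family)
    genus_ids = []
    for g in range(n_genera):
        gid = next_id
        next_id += 1
        nodes[gid] = TaxNode(
            parent=family_ids[g % n_phyla], rank="genus", name=f"Genus{g + 1}"
        )
        genus_ids.append(gid)
    sp = 1000
    for g, gid in enumerate(genus_ids):
        for s in range(species_per_genus):
            nodes[sp] = TaxNode(
                parent=gid, rank="species", name=f"Genus{g + 1} species{s + 1}"
            )
            sp += 1
    return TaxonomyTable(nodes)


def build_world(
    n_genera: int = 2,
    species_per_genus: int = 2,
    genome_length: int = 20000,
    n_contigs: int = 2,
    seed: int = 0,
) -> FixtureWorld:
    """Build a taxonomy plus one synthetic genome per species.

    Genome lengths vary around ``genome_length`` (0.5x to 1.5x) and GC
    content varies in [0.3, 0.7] so sequence and taxonomic abundances
    genuinely differ.
    """
    taxonomy = build_taxonomy(n_genera, species_per_genus)
    species = sorted(
        t for t, node in taxonomy.nodes.items() if node.rank == "species"
    )
    rng = rng_for(seed, "fixture-world")
    genomes = []
    for i, taxid in enumerate(species):
        length = int(genome_length * (0.5 + rng.random()))
        gc = 0.3 + 0.4 * rng.random()
        genomes.append(
            make_synthetic_genome(
                length=length,
                gc=gc,
                n_contigs=n_contigs,
                seed=int(rng.integers(0, 2**31)),
                genome_id=f"GCF_{i + 1:08d}.1",
                taxid=taxid,
            )
        )
    return FixtureWorld(taxonomy=taxonomy, genomes=genomes, species_taxids=species)


def random_assembly_records(
    n: int, species_taxids: list[int], seed: int = 0
) -> list[AssemblyRecord]:
    """Random but reproducible assembly metadata rows for ranking tests.

    Categories, statuses and completeness scores are drawn independently;
    roughly 20% of BUSCO/checkM scores are missing.
    """
    rng = rng_for(seed, "assembly-metadata")
    records = []
    for i in range(n):
        busco = None if rng.random() < 0.2 else float(np.round(rng.uniform(50, 100), 2))
        checkm = None if rng.random() < 0.2 else float(np.round(rng.uniform(50, 100), 2))
        records.append(
            AssemblyRecord(
                accession=f"GCA_{i + 1:08d}.1",
                taxid=int(rng.choice(species_taxids)),
                refseq_category=_CATEGORIES[rng.integers(0, 3)],
                assembly_status=_STATUSES[rng.integers(0, 4)],
                busco_completeness=busco,
                checkm_completeness=checkm,
            )
        )
    return records


_TEMPLATE_SITES = ("gut", "buccal_mucosa", "throat", "vagina")


def write_fixture_set(
    outdir: str | Path,
    n_genera: int = 2,
    species_per_genus: int = 2,
    genome_length: int = 20000,
    n_contigs: int = 2,
    n_metadata: int = 40,
    seed: int = 0,
) -> dict[str, Path]:
    """Write a complete runnable fixture set under ``outdir``.

    Emits genome FASTAs, a genome manifest, a taxonomy TSV, an assembly
    metadata TSV, even and lognormal community tables, four artificial
    body-site-style template tables (taxid + tax_abundance summing to 1)
    and an example YAML run config. Byte-identical for a fixed seed.
    """
    outdir = Path(outdir)
    (outdir / "genomes").mkdir(parents=True, exist_ok=True)
    (outdir / "templates").mkdir(parents=True, exist_ok=True)
    world = build_world(n_genera, species_per_genus, genome_length, n_contigs, seed)

    paths: dict[str, Path] = {}
    manifest_rows = []
    for genome in world.genomes:
        fasta = outdir / "genomes" / f"{genome.genome_id}.fasta"
        write_fasta(genome.contigs, fasta)
        # paths relative to the manifest so the fixture set is relocatable
        manifest_rows.append((genome.genome_id, genome.taxid, f"genomes/{genome.genome_id}.fasta"))
    paths["manifest"] = write_manifest(manifest_rows, outdir / "manifest.tsv")
    paths["taxonomy"] = world.taxonomy.to_tsv(outdir / "taxonomy.tsv")

    from .assembly_rank import write_ranked_table

    records = random_assembly_records(n_metadata, world.species_taxids, seed=seed)
    meta_path = outdir / "assemblies.tsv"
    # unranked metadata table: same columns, no rank column
    import pandas as pd

    pd.DataFrame(
        [
            (
                r.accession,
                r.taxid,
                r.refseq_category,
                r.assembly_status,
                r.busco_completeness,
                r.checkm_completeness,
            )
            for r in records
        ],
        columns=[
            "accession",
            "taxid",
            "refseq_category",
            "assembly_status",
            "busco_completeness",
            "checkm_completeness",
        ],
    ).to_csv(meta_path, sep="\t", index=False)
    paths["assemblies"] = meta_path

    ids = [g.genome_id for g in world.genomes]
    even_rows = ["sample_id\tgenome_id\tquantity\tunit"]
    for gid in ids:
        even_rows.append(f"even\t{gid}\t{1.0 / len(ids)}\ttax_abundance")
    (outdir / "community_even.tsv").write_text("\n".join(even_rows) + "\n")
    paths["community_even"] = outdir / "community_even.tsv"

    fracs = draw_lognormal(ids, mu=1.0, sigma=2.0, seed=seed)
    ln_rows = ["sample_id\tgenome_id\tquantity\tunit"]
    for gid, f in zip(ids, fracs):
        ln_rows.append(f"lognormal\t{gid}\t{f:.8f}\ttax_abundance")
    (outdir / "community_lognormal.tsv").write_text("\n".join(ln_rows) + "\n")
    paths["community_lognormal"] = outdir / "community_lognormal.tsv"

    # artificial body-site-style templates: synthetic stand-ins, not survey data
    for s, site in enumerate(_TEMPLATE_SITES):
        rng = rng_for(seed, "template", site)
        k = max(2, len(world.species_taxids) // 2)
        taxids = sorted(
            rng.choice(world.species_taxids, size=min(k, len(world.species_taxids)), replace=False).tolist()
        )
        raw = np.exp(rng.normal(1.0, 1.0, size=len(taxids)))
        frac = raw / raw.sum()
        lines = ["taxid\ttax_abundance"]
        for t, f in zip(taxids, frac):
            lines.append(f"{t}\t{f:.8f}")
        tpath = outdir / "templates" / f"{site}.tsv"
        tpath.write_text("\n".join(lines) + "\n")
        paths[f"template_{site}"] = tpath

    config = {
        "community": "community_even.tsv",
        "manifest": "manifest.tsv",
        "taxonomy": "taxonomy.tsv",
        "output": "run",
        "tech": "short",
        "short": {"read_length": 100, "paired": True, "insert_mean": 250.0,
                  "insert_sd": 20.0, "sub_rate": 0.001},
        "total_bases": 200000,
        "seed": seed,
        "replicates": 1,
        "replicate_sd": 0.0,
        "compress": True,
    }
    cfg_path = outdir / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    paths["config"] = cfg_path
    return paths
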