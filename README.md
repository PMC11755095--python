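# mgsim

Simulation of shotgun metagenomic sequencing experiments with exact ground
truth. `mgsim` designs microbial communities from abundance specifications,
simulates short (Illumina-like) or long (Nanopore/PacBio-like) reads, and
emits everything a benchmarking study needs: shuffled, anonymized,
compressed FASTQ; a ground-truth SAM recording each read's true origin and
edits; and CAMI biobox taxonomic profiles carrying **both** sequence and
taxonomic abundances. It also ranks genome assemblies from offline metadata
tables (RefSeq category, assembly level, BUSCO/checkM completeness) so the
best genome per taxon can be selected without touching the network.

It is aimed at people who benchmark metagenomic software — taxonomic
profilers, read mappers, assemblers — and need controlled communities where
the right answer is known exactly, and at method developers validating
clinical or environmental workflows with spike-in style scenarios.

## The model

A community is a list of per-genome quantities in one of five units: read
counts, base counts, fold coverage, sequence abundance, or taxonomic
abundance. All units are converted to per-genome coverage depths by
normalizing to genome sizes L_i:

- coverage: d_i = q_i
- bases: d_i = q_i / L_i
- reads: d_i = q_i · r / L_i (r = read length; counts are individual reads)
- sequence abundance: fractions w_i allocate a read budget R,
  n_i = w_i · R, then as reads
- taxonomic abundance: d_i = w_i · C with C = B / Σ_j w_j L_j, so the
  total simulated bases equal the base budget B exactly

The distinction between the last two matters: at equal **taxonomic**
abundance (equal organism share, hence equal depth) a genome twice as long
receives twice the **sequence** abundance (read share). Conflating the two
biases profiler benchmarks, so both flavors are written for every sample.

Integer read budgets are apportioned with largest-remainder (Hamilton)
rounding — per genome, and within each genome per contig proportionally to
contig length — so sample totals are met exactly and sampling is uniform
across multi-contig genomes. Abundances can also be drawn from an even or a
lognormal distribution (exp(Normal(mu, sigma)), normalized), the standard
model for uneven microbial communities. Technical replicates perturb
quantities with truncated Normal(0, sd) noise before conversion; every
stochastic step draws from a child seed derived from (master seed, sample,
replicate, genome, contig), so runs are bit-reproducible regardless of
execution order or thread count.

The read simulator is parametric: uniform per-base substitution with a
linear Phred quality ramp for short reads (FR paired orientation,
truncated-Normal insert), and lognormal read spans with position-wise
substitution/insertion/deletion errors for long reads. Every read carries
its exact origin (contig, 0-based start, strand) and edit operations, from
which the emitted sequence can be reconstructed byte-for-byte.

## Worked example

Generate a self-contained synthetic study system (four genomes across two
genera, taxonomy, metadata, community tables, run config) and simulate it:

```bash
mgsim fixtures --output fx --seed 3
mgsim simulate --config fx/config.yaml
```

which prints

```
even rep1: 2000 reads -> fx/run/even_rep1_R1.fastq.gz, fx/run/even_rep1_R2.fastq.gz
```

The four genomes were requested at equal taxonomic abundance with a 200 kb
base budget of 2×100 bp pairs; `fx/run/even_rep1.stats.tsv` shows the
realized per-genome coverage (depths equal by design, read counts scaling
with genome length, totals exact):

```
genome_id       taxid  planned_depth  expected_reads  read_count  mean_depth
GCF_00000001.1  1000   2.075249       516             516         2.077880
GCF_00000002.1  1001   2.075249       506             506         2.076238
GCF_00000003.1  1002   2.075249       448             448         2.073594
GCF_00000004.1  1003   2.075249       530             530         2.073147
```

Because genome sizes differ, the sequence-abundance profile
(`even_rep1.sequence_abundance.profile`) deviates from the even 50/50
split per phylum that the taxonomic-abundance profile shows:

```
@SampleID:even_rep1
@Version:0.9.1
@Ranks:superkingdom|phylum|class|order|family|genus|species
@@TAXID RANK    TAXPATH TAXPATHSN       PERCENTAGE
2       superkingdom    2       Bacteria        100.000000
10      phylum  2|10    Bacteria|PhylumA        51.100000
14      phylum  2|14    Bacteria|PhylumB        48.900000
...
```

51.1% of reads versus exactly 50% of organisms for PhylumA: the genome-size
effect the dual profiles exist to expose. The accompanying
`even_rep1.truth.sam` holds one alignment per read with the true position
and CIGAR, usable directly to score any mapper or profiler.

Assembly selection works from a metadata TSV alone:

```bash
mgsim rank --metadata fx/assemblies.tsv --taxonomy fx/taxonomy.tsv \
           --rank genus --n 3 --output ranked.tsv
```

keeping the three best assemblies per genus (reference before
representative, complete before chromosome/scaffold/contig, then BUSCO and
checkM completeness descending).

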