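# Methods

## Community model and unit conversion

A sample is a set of genomes with quantities q_i in one unit per sample
(count units — reads, bases, coverage — may be mixed; the two abundance
units may not, since abundances are normalized jointly). Conversion to
fold coverage d_i normalizes by genome length L_i as described in the
README. For taxonomic abundance the scaling constant C = B / Σ w_j L_j is
chosen so that Σ d_i L_i equals the base budget B exactly; consequently
the depth *ratios* equal the input fractions to machine precision, which
is the property the taxonomic-abundance profile inherits.

Integer read counts are apportioned by largest-remainder (Hamilton)
rounding, ties broken by input order. This preserves totals exactly and
keeps each genome within one read of its exact share. In paired mode
apportionment happens in fragment units (two reads per fragment), so
per-genome read counts are always even while sample totals remain exact;
a requested odd total loses its last read to the floor at budget level.
"Reads" always count individual reads, not pairs — this matches FASTQ
record counting.

Replicates perturb each quantity independently with additive
Normal(0, sd) noise truncated at zero, before unit conversion.
Multiplicative lognormal noise was considered and rejected for the
simpler additive contract; the sd is in the unit of the quantity itself.
Truncation means extreme noise (sd ≫ q) can zero an entire replicate; such
a replicate is emitted as a valid empty sample rather than an error, since
it is a legitimate outcome of the specified noise model. The per-genome
noise is independent (a joint perturbation was the alternative; nothing in
the replicate contract requires correlated noise, and independence is the
simpler default).

Default lognormal abundance parameters are mu = 1, sigma = 2 — conventional
values for modeling uneven microbial communities; both are exposed.

## Read simulation

Short reads: fragment start positions are uniform over the valid range,
strand is a fair coin. Each base is substituted independently with
probability `sub_rate`, uniformly among the three alternatives; N bases are
never substituted and remain N in the read, with ordinary qualities.
Qualities are a linear Phred ramp from `q_start` (38) to `q_end` (28),
defaults chosen to resemble a modern Illumina profile in shape; qualities
do not influence error placement — the two models are deliberately
decoupled, and empirical quality-profile tables are an extension point, not
a feature. Paired mode is forward–reverse (innie): the insert length is
Normal(insert_mean, insert_sd) truncated to [read_length, contig_length]
by rejection (clamped after 100 tries), mate 2 is reverse-complemented.
Fragments never span contig ends; contigs shorter than the read length are
excluded from allocation with a logged warning.

Long reads: the **reference span** of each read is drawn
exp(Normal(length_log_mean, length_log_sd)), truncated to
[min_length, contig_length]. Errors are applied position-wise along the
span: substitution with probability s, deletion with probability d per
reference base, and a single-base insertion before each position with
probability i (s + i + d < 1 enforced). Tying the lognormal to the
reference span (rather than the query length) makes the deleted fraction
of reference-consumed bases exactly binomial(d) and keeps truth records
trivially consistent; the query length then deviates from the drawn span
by the realized (i − d) fraction, a second-order effect at the few-percent
rates typical of long reads.

Truth records store edit operations in reference order as
(op, length, alt) with the query bases of substitutions and insertions in
`alt`; this makes the emitted read exactly reconstructible from
(contig, truth), which the test suite verifies read-by-read. CIGAR uses
only (op, length), with match and substitution both mapping to M.

Reads-per-depth uses the read length as footprint for short reads (even
count enforced in paired mode) and the closed-form mean of the
left-truncated lognormal for long reads.

## Seeding

All randomness flows through numpy `SeedSequence` spawning. Scope tokens
(sample id, replicate index, genome id, contig id, purpose strings) are
hashed to 31-bit keys via SHA-256; a child generator for a scope is
independent of every other scope. Per-contig simulation is therefore
reproducible under any execution order, which is what makes the thread
pool safe and output byte-stable.

## Outputs

Per-contig streams are concatenated in plan order, shuffled as fragments
(mates move together; independently shuffled mates would break pairing),
then anonymized: fragment k (1-based) becomes FASTQ header `k` (or `k/1`,
`k/2`) and SAM name `k`. The name map (original → anonymous) is written
only on request, since it de-anonymizes the sample. FASTQ is Phred+33,
gzip by default. The truth SAM has one reference per contig named
`genome_id|contig_id` (separator configurable), 1-based POS, SEQ stored
reference-forward with flag 0x10 for minus-strand reads, proper-pair and
mate flags set, coordinate-sorted when BAM is requested. Realized
statistics count reference-consumed bases (match + sub + del) per genome.

## Profiles

Lineages are resolved over the seven canonical ranks (superkingdom —
"kingdom" in informal usage — down to species); ranks missing from a
lineage are skipped, not padded, and taxpaths contain only present ranks.
A taxon's sequence percentage at a rank is 100 × (reads of genomes whose
lineage passes through it) / (all reads); the taxonomic flavor replaces
reads with mean depth. With complete lineages every rank sums to 100, and
a parent's percentage equals the sum of its children's — both properties
are tested. Genomes below species rank aggregate to species; strain rows
are not emitted. Zero-abundance taxa are omitted. The biobox version
string is 0.9.1; percentages are printed with six decimals.

## Assembly ranking

The default policy compares, in order: RefSeq category (reference <
representative < na), assembly status (complete < chromosome < scaffold <
contig), BUSCO completeness (descending), checkM completeness
(descending), accession (ascending) — a total, stable order. BUSCO is
compared before checkM; the key order is configurable. Missing
completeness scores sort after any present value (absence of evidence is
not zero completeness); whether completeness *filters* drop missing-score
rows is a flag, default drop. Genome download is out of scope: the module
consumes offline metadata tables.

## Synthetic study systems

The fixture generator builds a complete seven-rank taxonomy (genera split
across two phyla), one random genome per species with lengths varying
0.5–1.5× around the requested size and GC in [0.3, 0.7], random assembly
metadata (~20% missing completeness scores), even and lognormal community
tables, and four artificial body-site-style template tables (taxid +
taxonomic abundance summing to 1). The templates are explicit stand-ins
shaped like body-site communities, not curated survey data. Synthetic
genomes are i.i.d. base draws: they have realistic size and GC but no
repeats, conserved regions, or shared k-mer structure between related
species — so passing tests demonstrate the simulator's accounting and
calibration, not profiler performance on realistically confusable
genomes.

## Problem sizes and tolerances

The shipped tests and the acceptance script run at desk scale: genomes of
20 kb–2 Mb, budgets of 0.2–5 Mb, 10–50 k reads per check. Calibration
checks use 3σ binomial bands at ≥ 10^6 simulated bases; moment-recovery
checks use 10^4 draws at 5% relative tolerance; conversion identities are
checked at 1e-9; conservation and determinism are exact. Larger
communities scale linearly in total bases; shuffling is an in-memory
permutation, so a sample must fit in RAM (an external-merge shuffle is out
of scope).

## Known limitations

No GC bias, chimeras, PCR duplicates, or empirical (position- and
context-dependent) error profiles; no circular-genome fragments spanning
contig ends; no strain-level mutation or time-series modeling; profile
comparison metrics are out of scope. The parametric error model is
deliberately simple so that every rate is testable against its binomial
expectation.
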