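"""Parametric short- and long-read simulation with exact ground truth.

Short reads use a uniform per-base substitution rate and a linear Phred
quality ramp; paired mode is forward-reverse (innie) with a truncated-Normal
insert size. Long reads draw their reference span from a lognormal and apply
position-wise substitution/insertion/deletion errors. Every read carries a
truth record (contig, 0-based start, strand, edit operations) from which the
emitted sequence can be reconstructed exactly.

Edit operations are (op, length, alt) tuples where ``alt`` holds the query
bases introduced by substitutions/insertions (empty for match/del); CIGAR
strings use only op and length.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .community_design import largest_remainder
from .genome_store import Contig

__all__ = [
    "ShortReadParams",
    "LongReadParams",
    "TruthRecord",
    "SimulatedRead",
    "Fragment",
    "revcomp",
    "allocate_reads_per_contig",
    "simulate_short",
    "simulate_long",
    "reads_for_depth",
    "truncated_lognormal_mean",
    "reconstruct_read",
    "quality_ramp",
]

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)
# byte -> base index (A=0 C=1 G=2 T=3, everything else 255)
_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ShortReadParams:
    """Illumina-like read parameters.

    read_length in bases; insert_mean/insert_sd parameterize the fragment
    (outer) length for paired mode; sub_rate is the per-base substitution
    probability; q_start/q_end are Phred scores interpolated linearly from
    5' to 3' along each read.
    """

    read_length: int = 150
    paired: bool = False
    insert_mean: float = 350.0
    insert_sd: float = 25.0
    sub_rate: float = 0.001
    q_start: int = 38
    q_end: int = 28

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if not 0.0 <= self.sub_rate < 1.0:
            raise ValueError("sub_rate must be in [0, 1)")
        if self.paired and self.insert_mean < self.read_length:
            raise ValueError("paired mode requires insert_mean >= read_length")
        if self.insert_sd < 0:
            raise ValueError("insert_sd must be >= 0")


@dataclass(frozen=True)
class LongReadParams:
    """Nanopore/PacBio-like read parameters.

    Read reference spans are lognormal: exp(Normal(length_log_mean,
    length_log_sd)), truncated to [min_length, contig length]. Error rates
    are per reference position; qualities are a constant Phred score.
    """

    length_log_mean: float = 8.5
    length_log_sd: float = 0.5
    sub_rate: float = 0.01
    ins_rate: float = 0.01
    del_rate: float = 0.01
    min_length: int = 100
    quality: int = 12

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sub_rate + self.ins_rate + self.del_rate >= 1.0:
            raise ValueError("sub_rate + ins_rate + del_rate must be < 1")
        if self.length_log_sd <= 0:
            raise ValueError("length_log_sd must be > 0")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


EditOp = tuple[str, int, str]


@dataclass
class TruthRecord:
    """A read's true genomic origin and edit structure.

    ``start`` is the 0-based leftmost reference coordinate; ``edit_ops``
    are recorded in reference order (before any reverse-complementing of
    the emitted read); ``aligned_length`` counts reference-consumed bases
    (match + sub + del). ``mate`` is 0 for single reads, 1 or 2 for pairs.
    """

    read_name: str
    genome_id: str
    contig_id: str
    start: int
    strand: str
    aligned_length: int
    edit_ops: list[EditOp] = field(default_factory=list)
    mate: int = 0


@dataclass
class SimulatedRead:
    name: str
    sequence: str
    qualities: str
    truth: TruthRecord


#: A sequencing unit: a 1-tuple for single reads, (mate1, mate2) for pairs.
Fragment = tuple[SimulatedRead, ...]


def quality_ramp(read_length: int, q_start: int, q_end: int) -> str:
    """Phred+33 string interpolating linearly from q_start to q_end."""
    if read_length == 1:
        qs = [q_start]
    else:
        qs = [
            int(round(q_start + (q_end - q_start) * i / (read_length - 1)))
            for i in range(read_length)
        ]
    return "".join(chr(33 + max(0, min(93, q))) for q in qs)


def allocate_reads_per_contig(total_reads: int, contig_lengths: list[int]) -> list[int]:
    """Apportion a genome's read budget across contigs by length.

    Largest-remainder rounding: sums exactly to total_reads, deterministic,
    proportional to contig length.
    """
    if not contig_lengths:
        raise ValueError("contig_lengths must be non-empty")
    if any(l <= 0 for l in contig_lengths):
        raise ValueError("contig lengths must be positive")
    if total_reads < 0:
        raise ValueError("total_reads must be >= 0")
    return largest_remainder(contig_lengths, total_reads)


def _apply_substitutions(
    ref: str, rate: float, rng: np.random.Generator
) -> tuple[str, list[EditOp]]:
    """Substitute each A/C/G/T base independently with probability ``rate``.

    Returns the mutated sequence and reference-order edit ops. N positions
    are never substituted and stay N in the read.
    """
    n = len(ref)
    if rate == 0.0:
        return ref, [("match", n, "")]
    arr = np.frombuffer(ref.encode("ascii"), dtype=np.uint8).copy()
    idx = _BASE_INDEX[arr]
    mask = (rng.random(n) < rate) & (idx != 255)
    k = int(mask.sum())
    if k:
        offsets = rng.integers(1, 4, size=k)
        arr[mask] = _ALPHABET[(idx[mask] + offsets) % 4]
    seq = arr.tobytes().decode("ascii")
    if not k:
        return seq, [("match", n, "")]
    ops: list[EditOp] = []
    pos = 0
    # run-length encode the substitution mask
    changes = np.flatnonzero(np.diff(mask.astype(np.int8)))
    bounds = [0, *(changes + 1).tolist(), n]
    for a, b in zip(bounds[:-1], bounds[1:]):
        if mask[a]:
            ops.append(("sub", b - a, seq[a:b]))
        else:
            ops.append(("match", b - a, ""))
        pos = b
    return seq, ops


def _draw_truncated(
    rng: np.random.Generator, draw, lo: float, hi: float, max_tries: int = 100
) -> float:
    """Rejection-sample ``draw(rng)`` into [lo, hi]; clamp after max_tries."""
    for _ in range(max_tries):
        x = draw(rng)
        if lo <= x <= hi:
            return x
    return min(hi, max(lo, x))


def simulate_short(
    contig: Contig,
    n_reads: int,
    params: ShortReadParams,
    seed: int,
    genome_id: str = "genome",
) -> list[Fragment]:
    """Simulate short reads from one contig.

    Fragment starts are uniform over the valid range, strands are a fair
    coin. In paired mode ``n_reads`` counts individual reads (two per
    fragment); mate 2 is reverse-complemented (FR orientation) and the
    insert length is Normal(insert_mean, insert_sd) truncated to
    [read_length, contig length]. Contigs shorter than the read length
    yield an empty stream with a warning.
    """
    rl = params.read_length
    if contig.length < rl:
        log.warning(
            "contig %s (%d bp) shorter than read length %d; skipping",
            contig.id,
            contig.length,
            rl,
        )
        return []
    rng = np.random.default_rng(seed)
    qual = quality_ramp(rl, params.q_start, params.q_end)
    fragments: list[Fragment] = []

    if not params.paired:
        for i in range(n_reads):
            start = int(rng.integers(0, contig.length - rl + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            ref = contig.sequence[start : start + rl]
            seq, ops = _apply_substitutions(ref, params.sub_rate, rng)
            if strand == "-":
                seq = revcomp(seq)
            name = f"{genome_id}|{contig.id}|{i}"
            truth = TruthRecord(
                read_name=name,
                genome_id=genome_id,
                contig_id=contig.id,
                start=start,
                strand=strand,
                aligned_length=rl,
                edit_ops=ops,
                mate=0,
            )
            fragments.append((SimulatedRead(name, seq, qual, truth),))
        return fragments

    n_frag = n_reads // 2
    if n_reads % 2:
        log.warning("odd paired read count %d; simulating %d pairs", n_reads, n_frag)
    for i in range(n_frag):
        insert = int(
            round(
                _draw_truncated(
                    rng,
                    lambda r: r.normal(params.insert_mean, params.insert_sd),
                    rl,
                    contig.length,
                )
            )
        )
        insert = min(contig.length, max(rl, insert))
        start = int(rng.integers(0, contig.length - insert + 1))
        frag_fwd = rng.random() < 0.5
        left_ref = contig.sequence[start : start + rl]
        right_start = start + insert - rl
        right_ref = contig.sequence[right_start : right_start + rl]
        left_seq, left_ops = _apply_substitutions(left_ref, params.sub_rate, rng)
        right_seq, right_ops = _apply_substitutions(right_ref, params.sub_rate, rng)
        name = f"{genome_id}|{contig.id}|{i}"
        left = SimulatedRead(
            name,
            left_seq,
            qual,
            TruthRecord(name, genome_id, contig.id, start, "+", rl, left_ops),
        )
        right = SimulatedRead(
            name,
            revcomp(right_seq),
            qual,
            TruthRecord(name, genome_id, contig.id, right_start, "-", rl, right_ops),
        )
        mate1, mate2 = (left, right) if frag_fwd else (right, left)
        mate1.truth.mate = 1
        mate2.truth.mate = 2
        fragments.append((mate1, mate2))
    return fragments


def simulate_long(
    contig: Contig,
    n_reads: int,
    params: LongReadParams,
    seed: int,
    genome_id: str = "genome",
) -> list[Fragment]:
    """Simulate long reads from one contig.

    The reference span of each read is lognormal, truncated to
    [min_length, contig length]; errors are applied position-wise along the
    span (substitution or deletion per reference base, single-base insertion
    before a reference base with probability ins_rate). All-zero rates give
    perfect reads.
    """
    if contig.length < params.min_length:
        log.warning(
            "contig %s (%d bp) shorter than min_length %d; skipping",
            contig.id,
            contig.length,
            params.min_length,
        )
        return []
    rng = np.random.default_rng(seed)
    error_free = params.sub_rate == 0 and params.ins_rate == 0 and params.del_rate == 0
    fragments: list[Fragment] = []
    for i in range(n_reads):
        span = int(
            round(
                _draw_truncated(
                    rng,
                    lambda r: math.exp(
                        r.normal(params.length_log_mean, params.length_log_sd)
                    ),
                    params.min_length,
                    contig.length,
                )
            )
        )
        span = min(contig.length, max(params.min_length, span))
        start = int(rng.integers(0, contig.length - span + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        ref = contig.sequence[start : start + span]
        if error_free:
            seq, ops = ref, [("match", span, "")]
        else:
            seq, ops = _mutate_long(ref, params, rng)
        if not seq:
            log.warning("read %d on %s fully deleted; skipping", i, contig.id)
            continue
        if strand == "-":
            seq = revcomp(seq)
        name = f"{genome_id}|{contig.id}|{i}"
        truth = TruthRecord(
            read_name=name,
            genome_id=genome_id,
            contig_id=contig.id,
            start=start,
            strand=strand,
            aligned_length=span,
            edit_ops=ops,
            mate=0,
        )
        fragments.append((SimulatedRead(name, seq, chr(33 + params.quality) * len(seq), truth),))
    return fragments


def _mutate_long(
    ref: str, params: LongReadParams, rng: np.random.Generator
) -> tuple[str, list[EditOp]]:
    """Apply sub/ins/del errors along a reference span; ops in ref order."""
    n = len(ref)
    ev = rng.random(n)
    ins_mask = rng.random(n) < params.ins_rate
    sub_cut = params.sub_rate
    del_cut = params.sub_rate + params.del_rate
    n_ins = int(ins_mask.sum())
    ins_bases = _ALPHABET[rng.integers(0, 4, size=n_ins)].tobytes().decode("ascii")
    sub_offsets = rng.integers(1, 4, size=n)  # draw for all; used where needed

    query: list[str] = []
    ops: list[EditOp] = []

    def push(op: str, length: int, alt: str) -> None:
        if ops and ops[-1][0] == op:
            prev = ops[-1]
            ops[-1] = (op, prev[1] + length, prev[2] + alt)
        else:
            ops.append((op, length, alt))

    ins_i = 0
    for j in range(n):
        if ins_mask[j]:
            b = ins_bases[ins_i]
            ins_i += 1
            query.append(b)
            push("ins", 1, b)
        base = ref[j]
        if ev[j] < sub_cut:
            bi = _BASE_INDEX[ord(base)]
            if bi == 255:  # N positions stay N, uncounted as substitutions
                query.append(base)
                push("match", 1, "")
            else:
                alt = chr(_ALPHABET[(bi + sub_offsets[j]) % 4])
                query.append(alt)
                push("sub", 1, alt)
        elif ev[j] < del_cut:
            push("del", 1, "")
        else:
            query.append(base)
            push("match", 1, "")
    return "".join(query), ops


def truncated_lognormal_mean(log_mean: float, log_sd: float, lower: float) -> float:
    """Mean of a lognormal left-truncated at ``lower`` (closed form)."""
    if lower <= 0:
        return math.exp(log_mean + log_sd**2 / 2)
    a = (math.log(lower) - log_mean) / log_sd
    tail = norm.sf(a)
    if tail <= 0:
        return lower
    return math.exp(log_mean + log_sd**2 / 2) * norm.sf(a - log_sd) / tail


def reads_for_depth(
    depth: float, genome_length: int, params: ShortReadParams | LongReadParams
) -> int:
    """Number of reads needed for a target fold coverage on one genome.

    Short reads: round(depth * L / read_length), rounded down to an even
    count in paired mode. Long reads: the footprint is the truncated-
    lognormal mean reference span.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if isinstance(params, ShortReadParams):
        n = int(round(depth * genome_length / params.read_length))
        if params.paired:
            n -= n % 2
        return n
    footprint = truncated_lognormal_mean(
        params.length_log_mean, params.length_log_sd, params.min_length
    )
    return int(round(depth * genome_length / footprint))


def reconstruct_read(contig_sequence: str, truth: TruthRecord) -> str:
    """Rebuild a read's emitted sequence from its truth record.

    Walks the edit operations over the reference segment (match copies,
    sub/ins take their recorded alt bases, del skips reference) and
    reverse-complements for minus-strand reads. Used to verify truth
    fidelity.
    """
    pos = truth.start
    out: list[str] = []
    for op, length, alt in truth.edit_ops:
        if op == "match":
            out.append(contig_sequence[pos : pos + length])
            pos += length
        elif op == "sub":
            out.append(alt)
            pos += length
        elif op == "ins":
            out.append(alt)
        elif op == "del":
            pos += length
        else:
            raise ValueError(f"unknown edit op {op!r}")
    if pos - truth.start != truth.aligned_length:
        raise ValueError(
            f"edit ops consume {pos - truth.start} reference bases, "
            f"truth says {truth.aligned_length}"
        )
    seq = "".join(out)
    return revcomp(seq) if truth.strand == "-" else seq
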