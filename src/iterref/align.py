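"""A small deterministic read mapper: k-mer seeding + ungapped Hamming extension.

The mapper exists to realize the mechanism that makes iterative reference
substitution work: a read spanning a run of consecutive mismatches is
unmappable until earlier rounds flatten the flanking mismatches, after which
its best Hamming distance drops below the allowance.  Seeding uses
``max_mismatches + 1`` disjoint k-mer seeds per strand (pigeonhole: any
alignment with at most ``max_mismatches`` mismatches leaves at least one seed
exact), which finds exactly the same alignments as querying every read k-mer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io_formats import Genome, ReadRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MapperParams:
    """Mapper configuration.

    k=17 keeps random seed hits rare at desk-scale genome sizes;
    max_mismatches=3 per ~100 bp read tolerates breed divergence while
    preserving the unmappable-HVR effect; require_unique_best discards reads
    whose best score is achieved at more than one locus.
    """

    k: int = 17
    max_mismatches: int = 3
    require_unique_best: bool = True

    def __post_init__(self) -> None:
        if self.k < 8:
            raise ValueError("seed length k must be >= 8")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass
class AlignmentRecord:
    """One read's mapping outcome; ``pos`` is 0-based leftmost on the reference.

    ``sequence`` is the read in reference orientation (reverse-complemented
    for strand '-'), which is what pileup and SAM output need.
    """

    read_id: str
    chrom: str | None
    pos: int
    strand: str
    n_mismatches: int
    mapped: bool
    sequence: str = ""


@dataclass
class KmerIndex:
    """Exact k-mer → positions index over the forward strand of a genome.

    k-mers containing N are not indexed.  Reverse-strand hits are found at
    query time by seeding with the reverse complement of the read.
    """

    k: int
    positions: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    encoded: dict[str, np.ndarray] = field(default_factory=dict)
    lengths: dict[str, int] = field(default_factory=dict)


def build_index(genome: Genome, k: int) -> KmerIndex:
    """Index every N-free k-mer position of every chromosome."""
    if not genome.sequences:
        raise ValueError("cannot index an empty genome")
    shortest = min(len(s) for s in genome.sequences.values())
    if k > shortest:
        raise ValueError(f"k={k} exceeds shortest chromosome length {shortest}")
    index = KmerIndex(k=k)
    for name, seq in genome.sequences.items():
        index.lengths[name] = len(seq)
        index.encoded[name] = np.frombuffer(seq.encode(), dtype=np.uint8)
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            index.positions.setdefault(kmer, []).append((name, i))
    return index


def _seed_offsets(read_len: int, k: int, n_seeds: int) -> list[int]:
    # Disjoint seeds when they fit; otherwise every offset (short reads).
    if n_seeds * k <= read_len:
        stride = read_len // n_seeds
        return [j * stride for j in range(n_seeds)]
    return list(range(read_len - k + 1))


def _hamming(ref_arr: np.ndarray, pos: int, read_arr: np.ndarray) -> int:
    window = ref_arr[pos : pos + read_arr.size]
    return int(np.count_nonzero(window != read_arr))


def map_read(
    read: ReadRecord,
    index: KmerIndex,
    genome: Genome,
    params: MapperParams,
) -> AlignmentRecord:
    """Map one read; ties on best score break to the lowest (chrom, pos, strand).

    With ``require_unique_best`` an ambiguous best locus yields an unmapped
    record instead.
    """
    L = len(read.sequence)
    unmapped = AlignmentRecord(
        read_id=read.id, chrom=None, pos=-1, strand="+",
        n_mismatches=-1, mapped=False, sequence=read.sequence,
    )
    if L < index.k:
        return unmapped

    n_seeds = params.max_mismatches + 1
    offsets = _seed_offsets(L, index.k, n_seeds)
    best_score = params.max_mismatches + 1
    best: list[tuple[str, int, int]] = []  # (chrom, pos, strand_order)
    seen: set[tuple[str, int, int]] = set()
    oriented = {0: read.sequence, 1: reverse_complement(read.sequence)}

    for strand_order, seq in oriented.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for off in offsets:
            kmer = seq[off : off + index.k]
            for chrom, hit in index.positions.get(kmer, ()):
                pos = hit - off
                if pos < 0 or pos + L > index.lengths[chrom]:
                    continue
                key = (chrom, pos, strand_order)
                if key in seen:
                    continue
                seen.add(key)
                score = _hamming(index.encoded[chrom], pos, arr)
                if score < best_score:
                    best_score = score
                    best = [key]
                elif score == best_score:
                    best.append(key)

    if best_score > params.max_mismatches or not best:
        return unmapped
    if params.require_unique_best and len(best) > 1:
        return unmapped
    chrom, pos, strand_order = min(best)
    return AlignmentRecord(
        read_id=read.id,
        chrom=chrom,
        pos=pos,
        strand="-" if strand_order else "+",
        n_mismatches=best_score,
        mapped=True,
        sequence=oriented[strand_order],
    )


def map_reads(
    reads: Iterable[ReadRecord],
    genome: Genome,
    params: MapperParams | None = None,
    index: KmerIndex | None = None,
) -> list[AlignmentRecord]:
    """Map a batch of reads against ``genome`` (builds the index if absent)."""
    params = params or MapperParams()
    if index is None:
        index = build_index(genome, params.k)
    return [map_read(r, index, genome, params) for r in reads]


def mapping_rate(records: Sequence[AlignmentRecord]) -> float:
    """Mapped reads / total reads."""
    if not records:
        raise ValueError("mapping_rate of an empty record set is undefined")
    return sum(r.mapped for r in records) / len(records)


def coverage_ratio(records: Sequence[AlignmentRecord], genome: Genome) -> float:
    """Fraction of reference positions covered by at least one mapped read."""
    covered = 0
    masks = {name: np.zeros(len(seq), dtype=bool) for name, seq in genome.sequences.items()}
    for rec in records:
        if rec.mapped:
            masks[rec.chrom][rec.pos : rec.pos + len(rec.sequence)] = True
    covered = sum(int(m.sum()) for m in masks.values())
    total = genome.total_length
    return covered / total if total else 0.0
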