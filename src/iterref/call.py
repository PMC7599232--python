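"""Pileup-based SNP genotyping and callset benchmarking.

The caller applies hard allele-fraction cutoffs to per-position base counts
from ungapped alignments.  Benchmarking implements the standard gold-standard
comparison: TP are variants called with the same genotype as the gold set,
FP are called variants absent from the gold set (or genotype-discordant),
FN are gold variants not recovered; precision = TP/(TP+FP) and
sensitivity = TP/(TP+FN).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .align import AlignmentRecord
from .io_formats import Callset, Genome, VariantCall

_BASES = "ACGT"
_CODE = {ord(b): i for i, b in enumerate(_BASES)}


@dataclass
class CallerParams:
    """Hard-cutoff genotyping thresholds.

    A position is considered when depth >= min_depth.  The candidate alternate
    allele is the most frequent non-reference base (ties alphabetical); its
    fraction f of the total depth decides the genotype:
    f >= hom_threshold -> hom_alt, het_band[0] <= f < het_band[1] -> het,
    otherwise no call.
    """

    min_depth: int = 3
    hom_threshold: float = 0.8
    het_band: tuple[float, float] = (0.2, 0.8)

    def __post_init__(self) -> None:
        low, high = self.het_band
        if not (0 < low < high <= self.hom_threshold <= 1):
            raise ValueError(
                f"require 0 < {low} < {high} <= hom_threshold={self.hom_threshold} <= 1"
            )


def _base_counts(alignments: Sequence[AlignmentRecord], genome: Genome) -> dict[str, np.ndarray]:
    """Per-chromosome (length, 4) base-count matrices from mapped alignments."""
    counts = {
        name: np.zeros((len(seq), 4), dtype=np.int32)
        for name, seq in genome.sequences.items()
    }
    for aln in alignments:
        if not aln.mapped:
            continue
        arr = np.frombuffer(aln.sequence.encode(), dtype=np.uint8)
        codes = np.full(arr.size, -1, dtype=np.int8)
        for byte, code in _CODE.items():
            codes[arr == byte] = code
        valid = codes >= 0  # N in the read contributes nothing
        positions = aln.pos + np.nonzero(valid)[0]
        np.add.at(counts[aln.chrom], (positions, codes[valid].astype(np.int64)), 1)
    return counts


def pileup_and_call(
    alignments: Sequence[AlignmentRecord],
    genome: Genome,
    params: CallerParams | None = None,
) -> Callset:
    """Genotype SNPs from an ungapped pileup; output sorted by (chrom, pos)."""
    params = params or CallerParams()
    low, high = params.het_band
    calls: list[VariantCall] = []
    counts = _base_counts(alignments, genome)
    for chrom in genome.sequences:
        seq = genome.sequences[chrom]
        mat = counts[chrom]
        depth = mat.sum(axis=1)
        ref_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        ref_codes = np.full(ref_arr.size, -1, dtype=np.int8)
        for byte, code in _CODE.items():
            ref_codes[ref_arr == byte] = code
        alt_mat = mat.copy()
        idx = np.arange(ref_arr.size)
        known_ref = ref_codes >= 0
        alt_mat[idx[known_ref], ref_codes[known_ref].astype(np.int64)] = 0
        alt_code = alt_mat.argmax(axis=1)  # argmax ties -> lowest code = alphabetical
        alt_count = alt_mat.max(axis=1)
        candidates = np.nonzero((depth >= params.min_depth) & (alt_count > 0) & known_ref)[0]
        for pos in candidates:
            f = alt_count[pos] / depth[pos]
            if f >= params.hom_threshold:
                genotype = "hom_alt"
            elif low <= f < high:
                genotype = "het"
            else:
                continue
            calls.append(
                VariantCall(
                    chrom=chrom,
                    pos=int(pos) + 1,
                    ref_base=seq[pos],
                    alt_base=_BASES[alt_code[pos]],
                    genotype=genotype,
                    depth=int(depth[pos]),
                    alt_fraction=float(f),
                )
            )
    callset = Callset(calls)
    callset.sort()
    return callset


@dataclass
class CallsetComparison:
    """TP/FP/FN counts with the derived precision and sensitivity."""

    TP: int
    FP: int
    FN: int

    @property
    def precision(self) -> float:
        return self.TP / (self.TP + self.FP) if self.TP + self.FP else float("nan")

    @property
    def sensitivity(self) -> float:
        return self.TP / (self.TP + self.FN) if self.TP + self.FN else float("nan")


def compare_callsets(
    test: Callset, gold: Callset, genotype_aware: bool = True
) -> CallsetComparison:
    """Compare a callset against a gold standard.

    A test call is TP when a gold record shares (chrom, pos, ref, alt) and —
    with ``genotype_aware`` (default) — the genotype class.  A call matching
    position and alleles but not genotype counts as FP, and the gold record
    as FN.
    """
    for name, cs in (("test", test), ("gold", gold)):
        if not cs.is_sorted():
            raise ValueError(f"{name} callset is not sorted by (chrom, pos)")

    def key(c: VariantCall):
        base = (c.chrom, c.pos, c.ref_base, c.alt_base)
        return base + (c.genotype,) if genotype_aware else base

    test_keys = {key(c) for c in test}
    gold_keys = {key(c) for c in gold}
    tp = len(test_keys & gold_keys)
    return CallsetComparison(TP=tp, FP=len(test_keys - gold_keys), FN=len(gold_keys - test_keys))


def count_variants(callset: Callset, type_filter: str = "all") -> int:
    """Count records by class: all | snp | indel | hom | het."""
    if type_filter == "all":
        return len(callset)
    if type_filter == "snp":
        return sum(c.is_snp for c in callset)
    if type_filter == "indel":
        return sum(not c.is_snp for c in callset)
    if type_filter == "hom":
        return sum(c.genotype == "hom_alt" for c in callset)
    if type_filter == "het":
        return sum(c.genotype == "het" for c in callset)
    raise ValueError(f"unknown type_filter {type_filter!r}")
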