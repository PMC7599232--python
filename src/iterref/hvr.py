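"""Highly-variable-region detection, annotation, and genome similarity.

Because the substitution step is SNP-only, the original and alternative
references share coordinates, so an HVR — a maximal run of three or more
consecutive mismatching positions — is found by a positional scan.  N never
matches and never mismatches; a run is broken at N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree

from .io_formats import AnnotationFeature, Genome


@dataclass
class HVRegion:
    """A maximal mismatch run, 0-based half-open, with annotation flags."""

    chrom: str
    start: int
    end: int
    overlaps_gene: bool = False
    overlaps_cds: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


def _mismatch_mask(a: str, b: str) -> np.ndarray:
    x = np.frombuffer(a.encode(), dtype=np.uint8)
    y = np.frombuffer(b.encode(), dtype=np.uint8)
    n = ord("N")
    return (x != y) & (x != n) & (y != n)


def find_hvr(original: Genome, alternative: Genome, min_run: int = 3) -> list[HVRegion]:
    """Maximal runs of >= min_run consecutive mismatches, per chromosome, sorted."""
    if not original.same_shape(alternative):
        raise ValueError("genomes differ in chromosome names or lengths")
    regions: list[HVRegion] = []
    for chrom in original.sequences:
        mask = _mismatch_mask(original.sequences[chrom], alternative.sequences[chrom])
        padded = np.concatenate(([False], mask, [False]))
        changes = np.nonzero(np.diff(padded.astype(np.int8)))[0]
        for s, e in zip(changes[::2], changes[1::2]):
            if e - s >= min_run:
                regions.append(HVRegion(chrom=chrom, start=int(s), end=int(e)))
    return regions


@dataclass
class HVRSummary:
    """Per-chromosome and total HVR counts with gene/CDS overlap tallies."""

    per_chrom: dict[str, tuple[int, int, int]]  # chrom -> (n_hvr, n_gene, n_cds)
    total: int
    total_gene_overlap: int
    total_cds_overlap: int

    @property
    def gene_fraction(self) -> float:
        return self.total_gene_overlap / self.total if self.total else 0.0

    @property
    def cds_fraction(self) -> float:
        return self.total_cds_overlap / self.total if self.total else 0.0


def annotate_hvr(
    regions: list[HVRegion], features: list[AnnotationFeature]
) -> tuple[list[HVRegion], HVRSummary]:
    """Flag each region that shares >= 1 base with a gene / CDS interval."""
    trees: dict[tuple[str, str], IntervalTree] = {}
    for f in features:
        trees.setdefault((f.chrom, f.kind), IntervalTree()).addi(f.start, f.end)
    per_chrom: dict[str, list[int]] = {}
    for region in regions:
        gene_tree = trees.get((region.chrom, "gene"))
        cds_tree = trees.get((region.chrom, "CDS"))
        region.overlaps_gene = bool(gene_tree.overlap(region.start, region.end)) if gene_tree else False
        region.overlaps_cds = bool(cds_tree.overlap(region.start, region.end)) if cds_tree else False
        tally = per_chrom.setdefault(region.chrom, [0, 0, 0])
        tally[0] += 1
        tally[1] += region.overlaps_gene
        tally[2] += region.overlaps_cds
    summary = HVRSummary(
        per_chrom={c: tuple(v) for c, v in per_chrom.items()},
        total=len(regions),
        total_gene_overlap=sum(r.overlaps_gene for r in regions),
        total_cds_overlap=sum(r.overlaps_cds for r in regions),
    )
    return regions, summary


def genome_similarity(a: Genome, b: Genome) -> float:
    """Matched (non-N) bases divided by total genome size."""
    if not a.same_shape(b):
        raise ValueError("genomes differ in chromosome names or lengths")
    matched = 0
    for chrom in a.sequences:
        x = np.frombuffer(a.sequences[chrom].encode(), dtype=np.uint8)
        y = np.frombuffer(b.sequences[chrom].encode(), dtype=np.uint8)
        n = ord("N")
        matched += int(np.count_nonzero((x == y) & (x != n)))
    total = a.total_length
    return matched / total if total else 0.0
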