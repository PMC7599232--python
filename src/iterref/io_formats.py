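"""Minimal, dialect-pinned readers and writers for the formats the pipeline touches.

Internally every coordinate is 0-based half-open; VCF and GTF are 1-based on
disk and converted exactly once, here, at the format boundary.  Writers are
deterministic: identical inputs produce byte-identical files.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")
SUBSTITUTABLE_BASES = frozenset("ACGT")


class FormatError(ValueError):
    """Raised when a file violates the dialect this pipeline pins."""


# ---------------------------------------------------------------------------
# Genome

@dataclass
class Genome:
    """Named chromosome sequences over the {A,C,G,T,N} alphabet.

    ``sequences`` preserves insertion order (chromosome order on disk).
    """

    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not name:
                raise FormatError("empty chromosome name")
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(
                    f"chromosome {name!r} contains illegal characters: {sorted(bad)}"
                )
            if not seq:
                raise FormatError(f"chromosome {name!r} has an empty sequence")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def __len__(self) -> int:
        return len(self.sequences)

    def same_shape(self, other: "Genome") -> bool:
        return (
            list(self.sequences) == list(other.sequences)
            and all(len(self.sequences[c]) == len(other.sequences[c]) for c in self.sequences)
        )


@dataclass
class ReadRecord:
    """A sequencing read: id, sequence, optional per-base qualities."""

    id: str
    sequence: str
    qualities: str | None = None

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise FormatError(
                f"read {self.id!r}: quality length {len(self.qualities)} != "
                f"sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class AnnotationFeature:
    """A gene or CDS interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    kind: str  # "gene" or "CDS"
    feature_id: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"feature {self.feature_id!r}: bad interval [{self.start},{self.end})"
            )


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> Genome:
    """Read a FASTA file into a :class:`Genome`.

    The chromosome name is the header token before the first whitespace;
    lowercase bases are uppercased.  Duplicate names, empty sequences and
    characters outside {A,C,G,T,N} are hard errors naming the record.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if name in sequences:
            raise FormatError(f"duplicate FASTA record name {name!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"FASTA record {name!r} has an empty sequence")
        bad = set(seq) - VALID_BASES
        if bad:
            raise FormatError(
                f"FASTA record {name!r} contains illegal characters: {sorted(bad)}"
            )
        sequences[name] = seq
    if not sequences:
        raise FormatError(f"no FASTA records in {path}")
    return Genome(sequences)


def write_fasta(genome: Genome, path: str | Path, width: int = 60) -> None:
    """Write a genome as FASTA, wrapped at ``width`` columns."""
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# FASTQ

def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream 4-line FASTQ records in file order.

    A truncated trailing record raises :class:`FormatError` with the record
    index.
    """
    with open(path) as fh:
        index = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lines = [fh.readline() for _ in range(3)]
            if any(not ln for ln in lines):
                raise FormatError(f"truncated FASTQ record #{index} in {path}")
            if not header.startswith("@"):
                raise FormatError(f"FASTQ record #{index}: header must start with '@'")
            seq = lines[0].strip().upper()
            qual = lines[2].strip()
            yield ReadRecord(id=header[1:].split()[0], sequence=seq, qualities=qual)
            index += 1


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            qual = read.qualities if read.qualities is not None else "I" * len(read.sequence)
            fh.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# VCF

@dataclass(frozen=True)
class VariantCall:
    """A single-sample SNP call; ``pos`` is 1-based as in VCF.

    ``substitutable`` is False for records read from VCF that are not simple
    SNPs (indels, symbolic alleles); the internal caller never produces those.
    """

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    genotype: str  # "hom_alt" | "het"
    depth: int | None = None
    alt_fraction: float | None = None
    substitutable: bool = True

    @property
    def is_snp(self) -> bool:
        return (
            len(self.ref_base) == 1
            and len(self.alt_base) == 1
            and self.ref_base in SUBSTITUTABLE_BASES
            and self.alt_base in SUBSTITUTABLE_BASES
        )


@dataclass
class Callset:
    """An ordered collection of variant calls, sorted by (chrom, pos)."""

    calls: list[VariantCall] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self) -> Iterator[VariantCall]:
        return iter(self.calls)

    def is_sorted(self) -> bool:
        keys = [(c.chrom, c.pos) for c in self.calls]
        return keys == sorted(keys)

    def sort(self) -> None:
        self.calls.sort(key=lambda c: (c.chrom, c.pos, c.ref_base, c.alt_base))


_HOM_GTS = {(1, 1)}
_HET_GTS = {(0, 1), (1, 0)}


def read_vcf(path: str | Path) -> Callset:
    """Read a single-sample VCF into a :class:`Callset`.

    GT 1/1 maps to hom_alt, 0/1 and 1/0 to het.  Multi-allelic records and
    records without GT are rejected; non-SNP records (indels) are kept but
    flagged non-substitutable.
    """
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        if not list(vcf.header.samples):
            raise FormatError(f"{path}: VCF has no sample column (GT required)")
        sample = list(vcf.header.samples)[0]
        for rec in vcf:
            if rec.alts is None or len(rec.alts) == 0:
                raise FormatError(f"{path}: record at {rec.chrom}:{rec.pos} has no ALT")
            if len(rec.alts) > 1:
                raise FormatError(
                    f"{path}: multi-allelic record at {rec.chrom}:{rec.pos} is not supported"
                )
            gt = rec.samples[sample].get("GT")
            if gt is None or any(a is None for a in gt):
                raise FormatError(f"{path}: missing GT at {rec.chrom}:{rec.pos}")
            gt = tuple(gt)
            if gt in _HOM_GTS:
                genotype = "hom_alt"
            elif gt in _HET_GTS:
                genotype = "het"
            else:
                raise FormatError(
                    f"{path}: unsupported GT {gt} at {rec.chrom}:{rec.pos}"
                )
            ref, alt = rec.ref, rec.alts[0]
            depth = rec.samples[sample].get("DP")
            snp = len(ref) == 1 and len(alt) == 1 and ref in SUBSTITUTABLE_BASES and alt in SUBSTITUTABLE_BASES
            calls.append(
                VariantCall(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_base=ref,
                    alt_base=alt,
                    genotype=genotype,
                    depth=depth,
                    substitutable=snp,
                )
            )
    return Callset(calls)


_GT_OF = {"hom_alt": "1/1", "het": "0/1"}


def write_vcf(
    callset: Callset,
    path: str | Path,
    contigs: dict[str, int] | None = None,
    sample: str = "SAMPLE",
    source: str = "iterref",
) -> None:
    """Write a minimal deterministic VCF 4.2 with GT (and DP when known)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for c in callset:
            if c.depth is not None:
                fmt, val = "GT:DP", f"{_GT_OF[c.genotype]}:{c.depth}"
            else:
                fmt, val = "GT", _GT_OF[c.genotype]
            fh.write(
                f"{c.chrom}\t{c.pos}\t.\t{c.ref_base}\t{c.alt_base}\t.\tPASS\t.\t{fmt}\t{val}\n"
            )


# ---------------------------------------------------------------------------
# GTF

def read_gtf(path: str | Path) -> list[AnnotationFeature]:
    """Read gene and CDS features from an Ensembl-dialect GTF.

    GTF is 1-based inclusive on disk; intervals come back 0-based half-open.
    Feature types other than gene/CDS are skipped.
    """
    features: list[AnnotationFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _src, kind, start_s, end_s = cols[0], cols[1], cols[2], cols[3], cols[4]
            if kind not in ("gene", "CDS"):
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed coordinates") from exc
            if start1 < 1 or end1 < start1:
                raise FormatError(f"{path}:{lineno}: bad interval {start1}-{end1}")
            feature_id = _gtf_attribute(cols[8], "gene_id") or f"{kind}:{lineno}"
            features.append(
                AnnotationFeature(chrom=chrom, start=start1 - 1, end=end1, kind=kind, feature_id=feature_id)
            )
    return features


def _gtf_attribute(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + " "):
            return part.split(" ", 1)[1].strip().strip('"')
    return None


# ---------------------------------------------------------------------------
# BED

def write_bed(regions: Iterable[tuple[str, int, int, str]], path: str | Path) -> None:
    """Write (chrom, start, end, name) tuples as 4-column BED (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom, start, end, name in regions:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    out: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed coordinates") from exc
            name = cols[3].strip() if len(cols) > 3 else "."
            out.append((cols[0], start, end, name))
    return out


# ---------------------------------------------------------------------------
# SAM — minimal dialect: @SQ header, columns 1–11, NM tag.

def write_sam(alignments, genome: Genome, path: str | Path) -> None:
    """Write alignment records as SAM (ungapped: CIGAR is <len>M, NM tag set).

    ``alignments`` is a sequence of :class:`iterref.align.AlignmentRecord`;
    unmapped reads are emitted with flag 4.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": name, "LN": len(seq)} for name, seq in genome.sequences.items()
        ],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = aln.read_id
            seg.query_sequence = aln.sequence
            seg.query_qualities = None
            if aln.mapped:
                seg.flag = 16 if aln.strand == "-" else 0
                seg.reference_name = aln.chrom
                seg.reference_start = aln.pos
                seg.mapping_quality = 60
                seg.cigarstring = f"{len(aln.sequence)}M"
                seg.set_tag("NM", aln.n_mismatches)
            else:
                seg.flag = 4
                seg.mapping_quality = 0
            out.write(seg)


def read_sam(path: str | Path):
    """Read SAM back into :class:`iterref.align.AlignmentRecord` objects."""
    from .align import AlignmentRecord  # local import: avoid cycle

    records = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for seg in sam:
            if seg.is_unmapped:
                records.append(
                    AlignmentRecord(
                        read_id=seg.query_name,
                        chrom=None,
                        pos=-1,
                        strand="+",
                        n_mismatches=-1,
                        mapped=False,
                        sequence=seg.query_sequence or "",
                    )
                )
            else:
                records.append(
                    AlignmentRecord(
                        read_id=seg.query_name,
                        chrom=seg.reference_name,
                        pos=seg.reference_start,
                        strand="-" if seg.is_reverse else "+",
                        n_mismatches=int(seg.get_tag("NM")) if seg.has_tag("NM") else 0,
                        mapped=True,
                        sequence=seg.query_sequence or "",
                    )
                )
    return records
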