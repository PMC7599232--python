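"""Apply a callset to a reference to produce the next alternative reference.

Substitution is SNP-only and therefore coordinate-preserving: every round's
genome has the same chromosome names and lengths, which lets highly-variable-
region detection and genome similarity be computed positionally across rounds
with no liftover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import Callset, Genome


@dataclass
class SubstitutionLog:
    """Record of every base replaced: (chrom, pos 1-based, old, new, round)."""

    entries: list[tuple[str, int, str, str, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)


def apply_substitutions(
    genome: Genome,
    callset: Callset,
    hom_only: bool = True,
    round_index: int = 1,
) -> tuple[Genome, SubstitutionLog]:
    """Substitute eligible SNP alleles into a copy of ``genome``.

    Eligible calls are hom_alt SNPs (plus het SNPs when ``hom_only`` is
    False).  Heterozygous substitution is retained only to demonstrate the
    allele flip-flop it causes across rounds; homozygous-only is the default
    because replacing a reference base is only meaningful where the sample is
    homozygous for the alternate.  A call whose ref_base does not match the
    genome is a hard error: it means the callset was produced against a
    different round's reference.
    """
    arrays = {name: bytearray(seq.encode()) for name, seq in genome.sequences.items()}
    log = SubstitutionLog()
    for call in callset:
        if not call.substitutable or not call.is_snp:
            continue
        if call.genotype == "het" and hom_only:
            continue
        if call.chrom not in arrays:
            raise ValueError(f"call on unknown chromosome {call.chrom!r}")
        arr = arrays[call.chrom]
        i = call.pos - 1
        if not (0 <= i < len(arr)):
            raise ValueError(f"call at {call.chrom}:{call.pos} outside chromosome")
        current = chr(arr[i])
        if current != call.ref_base:
            raise ValueError(
                f"ref mismatch at {call.chrom}:{call.pos}: genome has {current!r}, "
                f"call expects {call.ref_base!r} — callset and reference are out of sync"
            )
        arr[i] = ord(call.alt_base)
        log.entries.append((call.chrom, call.pos, call.ref_base, call.alt_base, round_index))
    new_genome = Genome({name: arr.decode() for name, arr in arrays.items()})
    return new_genome, log


def diff_genomes(a: Genome, b: Genome) -> list[tuple[str, int, str, str]]:
    """All positions (0-based) where two same-shape genomes differ.

    Positions where either base is N are excluded: assembly gaps are not
    variation.
    """
    if not a.same_shape(b):
        raise ValueError("genomes differ in chromosome names or lengths")
    out: list[tuple[str, int, str, str]] = []
    for chrom in a.sequences:
        sa, sb = a.sequences[chrom], b.sequences[chrom]
        for i, (x, y) in enumerate(zip(sa, sb)):
            if x != y and x != "N" and y != "N":
                out.append((chrom, i, x, y))
    return out
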