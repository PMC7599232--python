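"""Synthetic substrate for the pipeline: a diverged breed genome and shotgun reads.

The generator emulates the situation the pipeline targets: a breed genetically
distant from the reference breed, carrying (i) background SNPs at a uniform
per-base rate, a fraction of them heterozygous, and (ii) clustered highly
variable regions (HVRs) — short intervals of dense homozygous substitution
whose runs of three or more consecutive mismatches defeat direct read mapping.
Error-bearing shotgun reads are drawn uniformly from the two haplotypes.

Divergence is substitution-only (no indels), matching the SNP-only
substitution step; coordinates are therefore shared between reference, breed
and every iteration's alternative reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import Callset, Genome, ReadRecord, VariantCall

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class BreedSimParams:
    """Divergence model for the simulated breed.

    snp_rate is the per-base background substitution probability (0.005
    default — a plausible between-breed divergence, deliberately modest);
    het_fraction the fraction of background variant sites that are
    heterozygous; HVR intervals are non-overlapping, each base inside one
    substituted independently with probability hvr_divergence (0.4 default,
    dense enough that runs of >=3 consecutive substitutions are common).
    """

    genome_length: int = 100_000
    n_chroms: int = 1
    snp_rate: float = 0.005
    het_fraction: float = 0.2
    n_hvr: int = 20
    hvr_length_range: tuple[int, int] = (3, 18)
    hvr_divergence: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("snp_rate", "het_fraction", "hvr_divergence"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.hvr_length_range[0] < 3:
            raise ValueError("hvr_length_range minimum must be >= 3")


@dataclass
class ReadSimParams:
    """Shotgun read model: uniform starts, per-base miscalls, constant quality.

    read_length defaults to 36, a standard short-read length chosen so that,
    at the default mapper mismatch allowance and HVR divergence, reads
    overlapping the edge of an unfixed highly variable region are numerous
    enough for the iterative walk to advance (see the methods note).
    """

    read_length: int = 36
    coverage: float = 30.0
    error_rate: float = 0.0
    paired: bool = False
    insert_size: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0 <= self.error_rate < 0.25:
            raise ValueError("error_rate must be in [0, 0.25)")


@dataclass
class TruthSet:
    """The simulated breed: consensus genome, haplotypes, truth calls, HVRs.

    ``breed_genome`` is the homozygous consensus (het sites keep the reference
    base, stored with both alleles in ``het_table``); ``haplotypes`` are the
    two full sequences reads are drawn from; ``truth_calls`` lists every
    planted variant with its genotype class; ``planted_hvrs`` are the realized
    maximal runs of >=3 consecutive substitutions inside the sampled HVR
    intervals — the ground truth the HVR detector is benchmarked against.
    """

    reference: Genome
    breed_genome: Genome
    haplotypes: tuple[Genome, Genome]
    truth_calls: Callset
    planted_hvrs: list[tuple[str, int, int]]  # (chrom, start, end) 0-based half-open
    hvr_intervals: list[tuple[str, int, int]] = field(default_factory=list)


def random_reference(
    genome_length: int = 100_000, n_chroms: int = 1, seed: int = 0, n_fraction: float = 0.0
) -> Genome:
    """A uniform-random reference genome, optionally with N-gap positions."""
    rng = np.random.default_rng(seed)
    per = [genome_length // n_chroms] * n_chroms
    per[-1] += genome_length - sum(per)
    sequences = {}
    for i, length in enumerate(per, 1):
        arr = _BASES[rng.integers(0, 4, size=length)]
        if n_fraction > 0:
            mask = rng.random(length) < n_fraction
            arr = arr.copy()
            arr[mask] = ord("N")
        sequences[f"chr{i}"] = arr.tobytes().decode()
    return Genome(sequences)


def _other_base(rng: np.random.Generator, base_codes: np.ndarray) -> np.ndarray:
    """Uniform random base different from each input base (codes 0-3)."""
    shift = rng.integers(1, 4, size=base_codes.size)
    return (base_codes + shift) % 4


def simulate_breed(reference: Genome, params: BreedSimParams) -> TruthSet:
    """Plant background SNPs, het sites, and clustered HVRs into a reference."""
    rng = np.random.default_rng(params.seed)
    hap1: dict[str, np.ndarray] = {}
    hap2: dict[str, np.ndarray] = {}
    consensus: dict[str, np.ndarray] = {}
    calls: list[VariantCall] = []
    planted_hvrs: list[tuple[str, int, int]] = []
    hvr_intervals: list[tuple[str, int, int]] = []

    # Distribute the requested HVR count over chromosomes by length.
    chrom_names = list(reference.sequences)
    lengths = np.array([len(reference.sequences[c]) for c in chrom_names], dtype=float)
    hvr_per_chrom = _split_counts(params.n_hvr, lengths / lengths.sum(), rng)

    for chrom, n_hvr_here in zip(chrom_names, hvr_per_chrom):
        ref_arr = np.frombuffer(reference.sequences[chrom].encode(), dtype=np.uint8).copy()
        L = ref_arr.size
        codes = _encode(ref_arr)
        valid = codes >= 0  # N positions never vary

        intervals = _place_intervals(L, n_hvr_here, params.hvr_length_range, rng, chrom, params.n_hvr)
        in_hvr = np.zeros(L, dtype=bool)
        for s, e in intervals:
            in_hvr[s:e] = True
            hvr_intervals.append((chrom, s, e))

        h1 = ref_arr.copy()
        h2 = ref_arr.copy()
        cons = ref_arr.copy()

        # Background SNPs outside HVRs.
        bg_sites = np.nonzero((rng.random(L) < params.snp_rate) & valid & ~in_hvr)[0]
        het_mask = rng.random(bg_sites.size) < params.het_fraction
        alt_codes = _other_base(rng, codes[bg_sites])
        for pos, is_het, alt_code in zip(bg_sites, het_mask, alt_codes):
            alt = _BASES[alt_code]
            if is_het:
                h2[pos] = alt  # consensus and hap1 keep the reference base
                genotype = "het"
            else:
                h1[pos] = alt
                h2[pos] = alt
                cons[pos] = alt
                genotype = "hom_alt"
            calls.append(
                VariantCall(
                    chrom=chrom, pos=int(pos) + 1,
                    ref_base=chr(ref_arr[pos]), alt_base=chr(alt), genotype=genotype,
                )
            )

        # Dense homozygous substitution inside HVRs.
        hvr_sub = np.zeros(L, dtype=bool)
        for s, e in intervals:
            span = np.arange(s, e)
            span = span[valid[s:e]]
            hit = span[rng.random(span.size) < params.hvr_divergence]
            alt_codes = _other_base(rng, codes[hit])
            for pos, alt_code in zip(hit, alt_codes):
                alt = _BASES[alt_code]
                h1[pos] = alt
                h2[pos] = alt
                cons[pos] = alt
                hvr_sub[pos] = True
                calls.append(
                    VariantCall(
                        chrom=chrom, pos=int(pos) + 1,
                        ref_base=chr(ref_arr[pos]), alt_base=chr(alt), genotype="hom_alt",
                    )
                )
            planted_hvrs.extend(
                (chrom, int(rs), int(re_)) for rs, re_ in _runs(hvr_sub[s:e], offset=s, min_len=3)
            )

        hap1[chrom] = h1
        hap2[chrom] = h2
        consensus[chrom] = cons

    truth = Callset(calls)
    truth.sort()
    return TruthSet(
        reference=reference,
        breed_genome=Genome({c: a.tobytes().decode() for c, a in consensus.items()}),
        haplotypes=(
            Genome({c: a.tobytes().decode() for c, a in hap1.items()}),
            Genome({c: a.tobytes().decode() for c, a in hap2.items()}),
        ),
        truth_calls=truth,
        planted_hvrs=sorted(planted_hvrs),
        hvr_intervals=sorted(hvr_intervals),
    )


def _encode(arr: np.ndarray) -> np.ndarray:
    codes = np.full(arr.size, -1, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        codes[arr == b] = i
    return codes


def _split_counts(total: int, weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if total == 0:
        return np.zeros(weights.size, dtype=int)
    return rng.multinomial(total, weights)


def _place_intervals(
    L: int,
    n: int,
    length_range: tuple[int, int],
    rng: np.random.Generator,
    chrom: str,
    n_requested: int,
) -> list[tuple[int, int]]:
    """Sample n non-overlapping intervals; rejection sampling with a retry cap."""
    intervals: list[tuple[int, int]] = []
    attempts = 0
    while len(intervals) < n:
        attempts += 1
        if attempts > 200 * max(n, 1):
            raise ValueError(
                f"could not place {n} non-overlapping HVR intervals on {chrom} "
                f"(length {L}); reduce n_hvr below {n_requested}"
            )
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        if length >= L:
            raise ValueError(f"HVR length {length} exceeds chromosome {chrom} length {L}")
        start = int(rng.integers(0, L - length + 1))
        end = start + length
        if all(end <= s or start >= e for s, e in intervals):
            intervals.append((start, end))
    return sorted(intervals)


def _runs(mask: np.ndarray, offset: int = 0, min_len: int = 3) -> list[tuple[int, int]]:
    """Maximal True-runs of length >= min_len, as half-open intervals."""
    out = []
    padded = np.concatenate(([False], mask, [False]))
    changes = np.nonzero(np.diff(padded.astype(np.int8)))[0]
    for s, e in zip(changes[::2], changes[1::2]):
        if e - s >= min_len:
            out.append((offset + int(s), offset + int(e)))
    return out


def simulate_reads(truth: TruthSet, params: ReadSimParams) -> list[ReadRecord]:
    """Draw shotgun reads from the breed haplotypes.

    Read count = round(coverage * genome_length / read_length); each read
    picks a chromosome (length-weighted), a haplotype (probability 1/2), a
    uniform start, a strand (1/2, emitted as the reverse complement), and
    independent per-base miscalls at error_rate.
    """
    rng = np.random.default_rng(params.seed)
    hap_arrays = [
        {c: np.frombuffer(s.encode(), dtype=np.uint8) for c, s in hap.sequences.items()}
        for hap in truth.haplotypes
    ]
    chroms = list(truth.reference.sequences)
    lengths = np.array([len(truth.reference.sequences[c]) for c in chroms])
    if params.read_length > lengths.min():
        raise ValueError("read_length exceeds the shortest chromosome")
    G = int(lengths.sum())
    n_reads = int(round(params.coverage * G / params.read_length))
    if params.paired:
        return _simulate_paired(truth, params, rng, hap_arrays, chroms, lengths, n_reads)
    chrom_idx = rng.choice(len(chroms), size=n_reads, p=lengths / lengths.sum())
    hap_idx = rng.integers(0, 2, size=n_reads)
    rev = rng.random(n_reads) < 0.5
    reads: list[ReadRecord] = []
    comp = np.zeros(256, dtype=np.uint8)
    for x, y in zip(b"ACGTN", b"TGCAN"):
        comp[x] = y
    for i in range(n_reads):
        chrom = chroms[chrom_idx[i]]
        L = lengths[chrom_idx[i]]
        start = int(rng.integers(0, L - params.read_length + 1))
        arr = hap_arrays[hap_idx[i]][chrom][start : start + params.read_length].copy()
        if params.error_rate > 0:
            errs = np.nonzero(rng.random(params.read_length) < params.error_rate)[0]
            if errs.size:
                codes = _encode(arr)
                ok = errs[codes[errs] >= 0]  # never miscall into/out of N
                arr[ok] = _BASES[_other_base(rng, codes[ok])]
        if rev[i]:
            arr = comp[arr][::-1]
        reads.append(
            ReadRecord(
                id=f"r{i:07d}",
                sequence=arr.tobytes().decode(),
                qualities="I" * params.read_length,
            )
        )
    return reads


def _simulate_paired(truth, params, rng, hap_arrays, chroms, lengths, n_reads):
    """Paired mode: fragments of insert_size, read1 forward / read2 reverse."""
    n_pairs = (n_reads + 1) // 2
    insert = max(params.insert_size, params.read_length)
    if insert > lengths.min():
        raise ValueError("insert_size exceeds the shortest chromosome")
    comp = np.zeros(256, dtype=np.uint8)
    for x, y in zip(b"ACGTN", b"TGCAN"):
        comp[x] = y
    reads: list[ReadRecord] = []
    chrom_idx = rng.choice(len(chroms), size=n_pairs, p=lengths / lengths.sum())
    hap_idx = rng.integers(0, 2, size=n_pairs)
    for i in range(n_pairs):
        chrom = chroms[chrom_idx[i]]
        L = lengths[chrom_idx[i]]
        start = int(rng.integers(0, L - insert + 1))
        frag = hap_arrays[hap_idx[i]][chrom][start : start + insert]
        for mate, arr in (("1", frag[: params.read_length].copy()),
                          ("2", comp[frag[-params.read_length :]][::-1].copy())):
            if params.error_rate > 0:
                errs = np.nonzero(rng.random(params.read_length) < params.error_rate)[0]
                if errs.size:
                    codes = _encode(arr)
                    ok = errs[codes[errs] >= 0]
                    arr[ok] = _BASES[_other_base(rng, codes[ok])]
            reads.append(
                ReadRecord(
                    id=f"p{i:07d}/{mate}",
                    sequence=arr.tobytes().decode(),
                    qualities="I" * params.read_length,
                )
            )
    return reads


def downsample_reads(
    reads: list[ReadRecord],
    target_coverage: float,
    genome_length: int,
    read_length: int,
    seed: int = 0,
) -> list[ReadRecord]:
    """Uniform subset without replacement of round(target·G/L) reads."""
    n_target = int(round(target_coverage * genome_length / read_length))
    if n_target > len(reads):
        raise ValueError(
            f"requested {n_target} reads for {target_coverage}× but only "
            f"{len(reads)} are available"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(reads), size=n_target, replace=False))
    return [reads[i] for i in idx]
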