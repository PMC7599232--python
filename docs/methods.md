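# Methods

## The model

`iterref` treats alternative-reference construction as a fixed-point
iteration on the reference sequence. Let `R₀` be the public reference and
`S` a fixed set of shotgun reads from the target breed. Round `r` computes

    A_r  = map(S, R_{r−1})          ungapped k-mer-seeded alignment
    C_r  = call(A_r, R_{r−1})       pileup SNP genotyping
    R_r  = subst(R_{r−1}, hom(C_r)) homozygous-alternate alleles only

Because substitution is SNP-only, every `R_r` shares coordinates with `R₀`;
all cross-round comparisons (variant counts, genome similarity, highly
variable regions) are positional and need no liftover. The loop stops at a
configured round limit or as soon as a round substitutes nothing — the
system is deterministic, so a zero-substitution round proves a fixed point.

The scientific content of the iteration is the rescue of consecutive
mismatches. A read overlapping `m` unfixed mismatches maps only if
`m ≤ max_mismatches`; reads overlapping just the edge of a dense cluster
map, their alleles get substituted, and the mappable frontier advances a few
bases per round until the cluster is absorbed. Heterozygous calls are
excluded from substitution by default: substituting a het allele makes the
other allele the variant next round, and the reference enters an exact
period-2 cycle (the package reproduces this with `hom_only=False`; see the
oscillation test).

## Saturation curves and the stopping rules

Variant counts along a coverage titration (1×…30×) or along iteration
rounds saturate. On log₂ counts the package fits

    rising:  y = a/(1 + b·e^(−cx))        falling:  y = a/(1 − b·e^(−cx))

by nonlinear least squares (`scipy.optimize.curve_fit`, positivity bounds,
`b < 1` for the falling form so the curve is defined on `x ≥ 1`).
Initialization linearizes the model: `|a/y − 1| = b·e^(−cx)` gives `c` and
`b` from a log-linear regression after anchoring `a` just beyond the extreme
observation; up to 20 random-restart perturbations handle non-convergence.
Log base 2 is the default because the fitted asymptotes then equal the log₂
of the terminal variant counts; the base is configurable.

Decisions use the analytic tangent slope
`dy/dx = ±abc·e^(−cx)/(1 ± b·e^(−cx))²` with threshold `τ = 10⁻⁴`
(log₂-counts per unit x):

* optimal coverage: the root of `slope(x) = τ` right of the inflection
  `x = ln(b)/c`, bracketed geometrically and solved by Brent's method to
  `|Δx| ≤ 10⁻⁴`, then **rounded up**; a slope that never exceeds `τ` returns
  the domain edge with a warning flag rather than an error. Across breeds
  the maximum crossing wins.
* optimal iterations: the smallest integer `n ≥ 2` with `|slope(n)| ≤ τ`.

Two goodness-of-fit statistics are reported. `r_squared` is the coefficient
of determination `1 − SS_res/SS_tot` on the log scale. `correlation` is the
Pearson correlation between observed and fitted values — the statistic that
desktop curve-fitting tools conventionally print, and therefore the number
comparable against published fit tables: refitting the bundled 30-point
coverage series converges to the published parameters with
`correlation = 0.9954` while the true `r_squared` is 0.9907 (= 0.9954²).

## Components around the core

* **Mapper** (`align`): exact k-mer index over the forward strand; per read,
  `max_mismatches + 1` disjoint seeds per strand (pigeonhole: any alignment
  within the allowance leaves one seed exact, so results are identical to
  seeding with every read k-mer, which the oracle tests verify); candidates
  scored by full-read Hamming distance, ties broken to the lowest
  (chromosome, position, strand), ambiguous best optionally unmapped.
  Defaults `k = 17`, `max_mismatches = 3`, unique-best required. Ungapped
  only — the substitution step is SNP-only, so gapped alignment would add
  machinery without adding testable behavior.
* **Caller** (`call`): per-position base counts from mapped reads; the
  candidate alternate is the most frequent non-reference base (ties
  alphabetical) with fraction `f` of total depth; `f ≥ 0.8` → hom-alt,
  `0.2 ≤ f < 0.8` → het, depth ≥ `min_depth` required (default 3).
  Positions are independent; no phasing, no base qualities.
* **Benchmarking** (`call.compare_callsets`): TP requires matching
  (chrom, pos, ref, alt) *and* genotype class; a genotype-discordant match
  counts as FP plus FN. `precision = TP/(TP+FP)`,
  `sensitivity = TP/(TP+FN)`.
* **HVR detection** (`hvr`): maximal runs of ≥ 3 consecutive mismatching
  positions between two same-coordinate genomes. N never matches and never
  mismatches; runs break at N. Overlap with gene/CDS intervals counts from
  one shared base (intervals half-open). Genome similarity is matched
  non-N bases over total length.

## The simulator and what it does (not) emulate

`simulate` generates the study conditions: a uniform-random reference, a
breed genome carrying background SNPs at `snp_rate` (default 0.005/bp, a
modest between-breed divergence), a `het_fraction` (default 0.2) of
background sites heterozygous (reference allele on one haplotype), and
`n_hvr` (default 20) non-overlapping highly-variable intervals, lengths
3–18 bp, each base inside substituted homozygously with probability
`hvr_divergence` (default 0.4). The ground truth for HVR benchmarking is the
set of realized maximal runs of ≥ 3 consecutive substitutions inside those
intervals. Reads: uniform starts, haplotype chosen with probability ½ per
read, strand with probability ½, independent per-base miscalls, constant
quality strings (the method never uses qualities), read count
`round(coverage·G/L)`.

Default read length is 36 bp, and the choice is load-bearing. The frontier
of a dense cluster advances only through reads whose overlap with the
unfixed region carries ≤ `max_mismatches` mismatches; the expected number of
such reads per side is roughly
`coverage · (max_mismatches + 1) / (hvr_divergence · L)` and, for runs of
consecutive substitutions, at most `coverage · (max_mismatches) / L`
(≈ 2.5 at 30× with `L = 100`, ≈ 7 at `L = 36`). With 100 bp reads the walk
starves below any usable calling depth and recovery of dense clusters is
geometrically impossible at 30×; at 36 bp it proceeds comfortably. For the
same reason the error-free end-to-end scenarios (acceptance run, demo,
examples) configure the caller with `min_depth = 1`: a noiseless observation
is sufficient evidence, and demanding three reads at a frontier whose
expected eligible depth is ~2.5 would again forbid the mechanism the
pipeline exists to demonstrate. The `min_depth = 3` default stands for
error-bearing data.

Not emulated: indels and structural variants (substitution-only divergence,
matching the SNP-only consensus step), quality decay, GC/coverage bias, and
chimeric or duplicate reads. Consequences worth noting: with homogeneous
coverage and error-free reads the coverage titration saturates *completely*
(the plateau is exactly flat, unlike published real-data tables whose counts
creep upward through 30×), and passing tests demonstrate the mechanism and
the decision machinery, not aligner-grade performance on real noisy data.
Real-data mapping rates from production aligners are trends this desk-scale
analog mimics, not numbers it matches.

## Numerical and design choices

* Coordinates are 0-based half-open internally; VCF/GTF converted once at
  the format boundary. Multi-allelic VCF records are rejected (one base, one
  alternate is the substitution model); indel records survive VCF
  round-trips but are never substituted.
* A substitution whose expected reference base disagrees with the genome is
  a hard error: it means the callset was produced against a different
  round's reference, and applying the same callset twice triggers it by
  design.
* Per-operation RNGs are `numpy` generators seeded explicitly; iteration
  derives per-coverage seeds from the run seed, so every table is
  reproducible byte-for-byte.
* The reported "final" alternative reference is the genome after the
  *optimal* round, not the last round run; all intermediate genomes are
  retained by default at desk scale.
* Early stopping on a zero-substitution round is safe by determinism and
  keeps converged runs short; the falling-logistic fit then simply has fewer
  points, and runs that converge in under four rounds report no optimal
  iteration count rather than a fabricated one.

## Known limitations

The mapper's uniqueness rule discards reads tied between repeats, so
repeat-dense genomes depress mapping rate and coverage ratio. The caller's
hard fraction cutoffs misgenotype extreme allele-sampling skews
(binomially rare at 30×). HVR detection requires same-coordinate genomes —
it is deliberately not an alignment-based comparator for unequal-length
assemblies. The titration's gold standard defaults to the deep-coverage
callset from the same pool, so its sensitivity is relative, not absolute.
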