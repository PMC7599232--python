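"""Detect highly variable regions and annotate them against gene/CDS intervals.

Runs the pipeline end to end on a 30 kb synthetic breed, compares the final
alternative reference with the original positionally, reports maximal runs of
three or more consecutive mismatches, and overlaps them with a toy
annotation.  Planted runs recovered by the iterative strategy show up as
detected HVRs.
"""

import iterref as ir

reference = ir.random_reference(30_000, seed=5)
truth = ir.simulate_breed(reference, ir.BreedSimParams(genome_length=30_000, seed=5))
reads = ir.simulate_reads(truth, ir.ReadSimParams(coverage=30.0, seed=5))
config = ir.IterationConfig(max_rounds=8, caller=ir.CallerParams(min_depth=1), seed=5)
result = ir.run_iterations(reference, reads, config)

regions = ir.find_hvr(reference, result.genomes[-1])
features = [
    ir.AnnotationFeature("chr1", s, s + 2_000, "gene", f"gene_{i}")
    for i, s in enumerate(range(0, 30_000, 6_000))
] + [
    ir.AnnotationFeature("chr1", s + 500, s + 1_500, "CDS", f"cds_{i}")
    for i, s in enumerate(range(0, 30_000, 6_000))
]
regions, summary = ir.annotate_hvr(regions, features)

recovered = sum(
    any(r.chrom == c and r.start < e and r.end > s for r in regions)
    for c, s, e in truth.planted_hvrs
)
print(f"planted highly variable runs: {len(truth.planted_hvrs)}, "
      f"recovered by the pipeline: {recovered}")
print(f"detected HVRs: {summary.total}; "
      f"{summary.gene_fraction:.0%} overlap a gene, "
      f"{summary.cds_fraction:.0%} overlap a CDS")
for r in regions[:5]:
    print(f"  {r.chrom}:{r.start}-{r.end} (len {r.length}) "
          f"gene={r.overlaps_gene} cds={r.overlaps_cds}")
print("each region is a run of >=3 consecutive substitutions the public "
      "reference would have hidden as apparently conserved sequence.")
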