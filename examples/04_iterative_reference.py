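"""Run the full iterative strategy on synthetic data and pick the optimal round.

Each round maps the reads to the previous reference, calls SNPs, and
substitutes homozygous-alternate alleles.  The per-round variant count drops
steeply after round 1 (fixed between-breed differences get absorbed) and then
flattens; refitting the bundled 30-round pig series shows the tangent-slope
rule selecting seven rounds on real published counts.
"""

import iterref as ir
from iterref.datasets import wzs_iteration_series

reference = ir.random_reference(50_000, seed=3)
truth = ir.simulate_breed(reference, ir.BreedSimParams(genome_length=50_000, seed=3))
reads = ir.simulate_reads(truth, ir.ReadSimParams(coverage=30.0, seed=3))

config = ir.IterationConfig(
    max_rounds=10,
    caller=ir.CallerParams(min_depth=1),  # error-free reads
    seed=3,
)
result = ir.run_iterations(reference, reads, config, truth_genome=truth.breed_genome)

print(result.trace.to_frame().to_string(index=False))
print(f"\nearly stop after {len(result.trace.rounds)} rounds "
      f"(a round that substitutes nothing cannot change later rounds)")
print(f"similarity to the true breed genome rose from "
      f"{result.trace.rounds[0].genome_similarity_to_truth:.5f} to "
      f"{result.trace.rounds[-1].genome_similarity_to_truth:.5f}")

fit = ir.fit_logistic(wzs_iteration_series(), "falling")
n = ir.optimal_iterations(fit, tau=1e-4)
print(f"\npublished 30-round pig series refit: r = {fit.correlation:.4f}, "
      f"optimal iteration count = {n}")
print("past that round the per-round change in log2 variant count is below "
      "1e-4 — further iterations cost compute and change nothing material.")
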