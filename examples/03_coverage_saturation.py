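"""Decide the optimal sequencing coverage from a variant-count saturation curve.

Refits the bundled 1..30x WZS pig SNP-count titration with a rising logistic
on log2 counts, then finds where the tangent slope decays to 1e-4.  Across
the five published pig breed fits the slowest-saturating breed (Duroc) sets
the recommendation: 18.2x-18.3x, rounded up to 19x.
"""

import iterref as ir
from iterref.datasets import PIG_COVERAGE_FITS, wzs_coverage_series

fit = ir.fit_logistic(wzs_coverage_series(), "rising")
print(f"WZS refit: y = {fit.a:.2f} / (1 + {fit.b:.4f} * exp(-{fit.c:.4f} x)),  "
      f"r = {fit.correlation:.4f}")

crossing = ir.threshold_coverage(fit, tau=1e-4)
print(f"tangent slope reaches 1e-4 at {crossing.x_star:.1f}x "
      f"-> recommend {crossing.recommendation}x for this breed")

fits = [f for f, _ in PIG_COVERAGE_FITS.values()]
overall = ir.multi_breed_recommendation(fits, tau=1e-4)
print(f"across the five published pig fits the slowest breed crosses at "
      f"{overall.x_star:.1f}x -> sequence at {overall.recommendation}x")
print("below this coverage extra depth still buys new variants; above it the "
      "count curve is flat on the log scale and extra sequencing is wasted.")
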