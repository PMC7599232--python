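"""Bundled published series and fitted parameters used as worked-example inputs.

These are printed summary statistics from a pig/chicken resequencing study of
alternative-reference construction: per-coverage SNP counts and per-round
variant counts for the Wuzhishan (WZS) pig, the published logistic-fit
parameters for five pig breeds' coverage titrations and for the WZS iteration
series, and NA12878/GIAB benchmark counts for the FPGA-accelerated caller
(GTX) versus the BWA+GATK best-practice workflow (GBP).  They let the curve
machinery and the benchmark arithmetic be exercised on real published numbers
without any external download.
"""

from __future__ import annotations

from .curves import CurveSeries, LogisticFit

# SNP counts for WZS reads downsampled to 1..30x coverage and mapped to
# Sscrofa11.1 (coverage titration of a single Chinese indigenous pig).
WZS_COVERAGE_SNP_COUNTS: list[int] = [
    1_944_247, 4_712_874, 6_889_545, 8_395_125, 9_379_364,
    10_055_111, 10_493_413, 10_785_210, 11_057_014, 11_212_461,
    11_384_781, 11_475_145, 11_539_920, 11_653_799, 11_694_650,
    11_782_668, 11_805_726, 11_827_889, 11_898_117, 11_908_403,
    11_970_269, 11_974_123, 11_978_131, 12_029_145, 12_030_019,
    12_075_970, 12_073_458, 12_071_291, 12_113_790, 12_108_531,
]

# Variant counts called against the updated reference in each of 30 rounds of
# iterative substitution for the WZS individual used to build the
# alternative reference.
WZS_ITERATION_VARIANT_COUNTS: list[int] = [
    14_311_513, 3_295_192, 2_766_075, 2_682_333, 2_663_703,
    2_654_321, 2_648_887, 2_646_651, 2_644_442, 2_643_524,
    2_643_077, 2_642_597, 2_642_070, 2_642_098, 2_642_033,
    2_641_897, 2_641_860, 2_641_655, 2_641_151, 2_641_564,
    2_641_376, 2_641_402, 2_641_172, 2_641_227, 2_641_079,
    2_641_212, 2_640_874, 2_640_890, 2_641_280, 2_641_270,
]

# Published logistic fits (log2 variant counts vs coverage) per pig breed,
# with the published R².
PIG_COVERAGE_FITS: dict[str, tuple[LogisticFit, float]] = {
    "WZS": (LogisticFit(a=23.48, b=0.2202, c=0.6047, orientation="rising"), 0.9954),
    "BMX": (LogisticFit(a=23.23, b=0.2204, c=0.6587, orientation="rising"), 0.9947),
    "SZL": (LogisticFit(a=23.25, b=0.2057, c=0.6595, orientation="rising"), 0.9953),
    "LD": (LogisticFit(a=22.54, b=0.2362, c=0.6831, orientation="rising"), 0.9965),
    "DU": (LogisticFit(a=22.02, b=0.2063, c=0.5551, orientation="rising"), 0.9479),
}

# Published logistic fit of log2 variant counts vs iteration round for WZS,
# with the published R².
WZS_ITERATION_FIT: tuple[LogisticFit, float] = (
    LogisticFit(a=21.34, b=0.7039, c=1.9272, orientation="falling"),
    0.9999,
)

# NA12878 (GIAB gold standard) benchmark counts: (FP, FN, TP) per caller and
# variant type.
NA12878_BENCHMARK_COUNTS: dict[tuple[str, str], tuple[int, int, int]] = {
    ("GTX", "InDel"): (8_711, 15_999, 464_578),
    ("GTX", "SNP"): (14_706, 20_601, 3_188_714),
    ("GBP", "InDel"): (6_339, 11_312, 469_265),
    ("GBP", "SNP"): (9_312, 31_760, 3_177_555),
}


def wzs_coverage_series(log_base: float = 2.0) -> CurveSeries:
    """The 1..30x WZS SNP-count titration as a CurveSeries."""
    return CurveSeries(
        x=list(range(1, 31)), y_raw=WZS_COVERAGE_SNP_COUNTS, log_base=log_base
    )


def wzs_iteration_series(log_base: float = 2.0) -> CurveSeries:
    """The 30-round WZS variant-count series as a CurveSeries."""
    return CurveSeries(
        x=list(range(1, 31)), y_raw=WZS_ITERATION_VARIANT_COUNTS, log_base=log_base
    )
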