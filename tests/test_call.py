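"""Caller genotyping rules and gold-standard benchmarking arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import iterref as ir
from iterref.datasets import NA12878_BENCHMARK_COUNTS


def _alignments_for(genome, reads_at):
    """Build fake perfect alignments: list of (pos, sequence)."""
    return [
        ir.AlignmentRecord(f"r{i}", "c", pos, "+", 0, True, seq)
        for i, (pos, seq) in enumerate(reads_at)
    ]


class TestPileupAndCall:
    def test_unanimous_alt_is_hom(self):
        g = ir.Genome({"c": "AACAA"})
        alns = _alignments_for(g, [(0, "AATAA")] * 10)
        cs = ir.pileup_and_call(alns, g, ir.CallerParams())
        assert len(cs) == 1
        c = cs.calls[0]
        assert (c.pos, c.ref_base, c.alt_base, c.genotype) == (3, "C", "T", "hom_alt")
        assert c.alt_fraction == 1.0 and c.depth == 10

    def test_balanced_alt_is_het(self):
        g = ir.Genome({"c": "AACAA"})
        alns = _alignments_for(g, [(0, "AATAA")] * 5 + [(0, "AACAA")] * 5)
        cs = ir.pileup_and_call(alns, g, ir.CallerParams())
        assert len(cs) == 1 and cs.calls[0].genotype == "het"
        assert cs.calls[0].alt_fraction == 0.5

    def test_below_min_depth_no_call(self):
        g = ir.Genome({"c": "AACAA"})
        alns = _alignments_for(g, [(0, "AATAA")] * 2)
        assert len(ir.pileup_and_call(alns, g, ir.CallerParams(min_depth=3))) == 0

    def test_low_fraction_no_call(self):
        g = ir.Genome({"c": "AACAA"})
        alns = _alignments_for(g, [(0, "AATAA")] + [(0, "AACAA")] * 9)
        assert len(ir.pileup_and_call(alns, g, ir.CallerParams())) == 0

    def test_calls_match_truth_on_simulated_breed(self, small_truth):
        """Error-free 30x reads: every call correct; background hom recovered."""
        ref, truth, reads = small_truth
        alns = ir.map_reads(reads, ref)
        cs = ir.pileup_and_call(alns, ref, ir.CallerParams())
        truth_by_locus = {
            (c.chrom, c.pos): c for c in truth.truth_calls
        }
        correct = sum(
            1
            for c in cs
            if (c.chrom, c.pos) in truth_by_locus
            and truth_by_locus[(c.chrom, c.pos)].alt_base == c.alt_base
            and truth_by_locus[(c.chrom, c.pos)].genotype == c.genotype
        )
        assert correct / len(cs) >= 0.99  # precision of the caller
        hvr_intervals = truth.hvr_intervals
        background_hom = {
            (c.chrom, c.pos)
            for c in truth.truth_calls
            if c.genotype == "hom_alt"
            and not any(
                ch == c.chrom and s < c.pos <= e for ch, s, e in hvr_intervals
            )
        }
        called_hom = {(c.chrom, c.pos) for c in cs if c.genotype == "hom_alt"}
        assert len(background_hom & called_hom) / len(background_hom) >= 0.99


class TestCompareCallsets:
    @pytest.mark.parametrize(
        "caller,vtype,expected_precision,expected_sensitivity",
        [
            ("GTX", "SNP", 0.9954, 0.9936),
            ("GTX", "InDel", 0.9816, 0.9667),
            ("GBP", "SNP", 0.9971, 0.9901),
            ("GBP", "InDel", 0.9867, 0.9765),
        ],
    )
    def test_published_benchmark_arithmetic(
        self, caller, vtype, expected_precision, expected_sensitivity
    ):
        """TP/FP/FN published for the NA12878 benchmark reproduce the printed
        precision and sensitivity to 4 decimals."""
        fp, fn, tp = NA12878_BENCHMARK_COUNTS[(caller, vtype)]
        cmp_ = ir.CallsetComparison(TP=tp, FP=fp, FN=fn)
        assert round(cmp_.precision, 4) == expected_precision
        assert round(cmp_.sensitivity, 4) == expected_sensitivity

    def test_identical_callsets_perfect_scores(self):
        cs = ir.Callset([ir.VariantCall("c", 5, "A", "T", "hom_alt")])
        cmp_ = ir.compare_callsets(cs, cs)
        assert (cmp_.TP, cmp_.FP, cmp_.FN) == (1, 0, 0)
        assert cmp_.precision == cmp_.sensitivity == 1.0

    def test_genotype_mismatch_counts_fp_and_fn(self):
        a = ir.Callset([ir.VariantCall("c", 5, "A", "T", "hom_alt")])
        b = ir.Callset([ir.VariantCall("c", 5, "A", "T", "het")])
        cmp_ = ir.compare_callsets(a, b)
        assert (cmp_.TP, cmp_.FP, cmp_.FN) == (0, 1, 1)
        relaxed = ir.compare_callsets(a, b, genotype_aware=False)
        assert (relaxed.TP, relaxed.FP, relaxed.FN) == (1, 0, 0)

    def test_unsorted_input_rejected(self):
        a = ir.Callset(
            [ir.VariantCall("c", 9, "A", "T", "het"), ir.VariantCall("c", 5, "A", "T", "het")]
        )
        with pytest.raises(ValueError, match="sorted"):
            ir.compare_callsets(a, ir.Callset([]))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.data())
    def test_counts_equal_brute_force_set_comparison(self, data):
        """Randomized small callsets: TP/FP/FN equal an exhaustive comparison."""
        def callset(draw_label):
            n = data.draw(st.integers(0, 30), label=f"n_{draw_label}")
            seen = set()
            calls = []
            for i in range(n):
                pos = data.draw(st.integers(1, 40), label=f"pos_{draw_label}_{i}")
                ref, alt = data.draw(
                    st.sampled_from([("A", "T"), ("C", "G"), ("G", "A")]),
                    label=f"al_{draw_label}_{i}",
                )
                gt = data.draw(
                    st.sampled_from(["hom_alt", "het"]), label=f"gt_{draw_label}_{i}"
                )
                if (pos, ref, alt, gt) in seen:
                    continue
                seen.add((pos, ref, alt, gt))
                calls.append(ir.VariantCall("c", pos, ref, alt, gt))
            cs = ir.Callset(calls)
            cs.sort()
            return cs

        test_cs, gold_cs = callset("t"), callset("g")
        cmp_ = ir.compare_callsets(test_cs, gold_cs)
        gold_keys = {(c.chrom, c.pos, c.ref_base, c.alt_base, c.genotype) for c in gold_cs}
        test_keys = {(c.chrom, c.pos, c.ref_base, c.alt_base, c.genotype) for c in test_cs}
        tp = sum(1 for k in test_keys if k in gold_keys)
        assert cmp_.TP == tp
        assert cmp_.FP == len(test_keys) - tp
        assert cmp_.FN == len(gold_keys) - tp
        # swapping test and gold swaps FP and FN, keeps TP
        swapped = ir.compare_callsets(gold_cs, test_cs)
        assert (swapped.TP, swapped.FP, swapped.FN) == (cmp_.TP, cmp_.FN, cmp_.FP)


class TestCountVariants:
    def test_filters(self):
        cs = ir.Callset(
            [
                ir.VariantCall("c", 1, "A", "T", "hom_alt"),
                ir.VariantCall("c", 2, "A", "T", "het"),
                ir.VariantCall("c", 3, "A", "T", "hom_alt"),
                ir.VariantCall("c", 4, "AT", "A", "hom_alt", substitutable=False),
            ]
        )
        assert ir.count_variants(ir.Callset([]), "all") == 0
        assert ir.count_variants(cs, "all") == 4
        assert ir.count_variants(cs, "snp") == 3
        assert ir.count_variants(cs, "indel") == 1
        assert ir.count_variants(cs, "hom") == 3
        assert ir.count_variants(cs, "het") == 1

    def test_count_equals_vcf_body_lines(self, tmp_path):
        cs = ir.Callset([ir.VariantCall("c", i, "A", "T", "het") for i in range(1, 8)])
        p = tmp_path / "x.vcf"
        ir.write_vcf(cs, p, contigs={"c": 100})
        body = [l for l in p.read_text().splitlines() if not l.startswith("#")]
        assert ir.count_variants(cs) == len(body)
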