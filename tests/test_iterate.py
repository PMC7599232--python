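"""Iteration loop: the consecutive-mismatch mechanism, convergence, titration."""

import numpy as np
import pytest

import iterref as ir


def fig2_scenario():
    """A toy reference and three reads staging the consecutive-mismatch rescue.

    The breed differs from the reference at three adjacent positions
    30,31,32.  With a one-mismatch allowance: read1 (covers only position 30)
    maps immediately; read2 (covers 30-31) maps once 30 is substituted; readX
    (covers all three) maps only after two substitution rounds.
    """
    rng = np.random.default_rng(99)
    seq = "".join(rng.choice(list("ACGT"), size=120))
    flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
    breed = list(seq)
    for pos in (30, 31, 32):
        breed[pos] = flip[breed[pos]]
    breed = "".join(breed)
    reference = ir.Genome({"chr1": seq})
    reads = [
        ir.ReadRecord("read1", breed[11:31]),
        ir.ReadRecord("read2", breed[12:32]),
        ir.ReadRecord("readX", breed[20:40]),
    ]
    params = ir.MapperParams(k=8, max_mismatches=1)
    caller = ir.CallerParams(min_depth=1, hom_threshold=0.8, het_band=(0.2, 0.8))
    return reference, breed, reads, params, caller


class TestConsecutiveMismatchRescue:
    def test_read_with_consecutive_mismatches_rescued_after_two_rounds(self):
        reference, breed, reads, params, caller = fig2_scenario()
        config = ir.IterationConfig(max_rounds=5, mapper=params, caller=caller)
        result = ir.run_iterations(reference, reads, config)
        rates = [r.mapping_rate for r in result.trace.rounds[:3]]
        assert rates == [pytest.approx(1 / 3), pytest.approx(2 / 3), pytest.approx(1.0)]
        readx = reads[2]
        for round_genome, expect_mapped in zip(result.genomes[:3], [False, True, True]):
            index = ir.build_index(round_genome, params.k)
            rec = ir.map_read(readx, index, round_genome, params)
            assert rec.mapped == expect_mapped
        # against the original reference readX is unmappable
        rec0 = ir.map_read(readx, ir.build_index(reference, params.k), reference, params)
        assert not rec0.mapped
        # the three substitutions leave exactly the breed alleles in place
        final = result.genomes[2].sequences["chr1"]
        assert final[30:33] == breed[30:33]

    def test_rescued_region_is_reported_as_hvr(self):
        reference, breed, reads, params, caller = fig2_scenario()
        config = ir.IterationConfig(max_rounds=5, mapper=params, caller=caller)
        result = ir.run_iterations(reference, reads, config)
        regions = ir.find_hvr(reference, result.genomes[2])
        assert any(r.start <= 30 and r.end >= 33 for r in regions)


class TestRunIterations:
    def test_undiverged_reads_stop_after_one_round(self):
        ref = ir.random_reference(5_000, seed=20)
        truth = ir.simulate_breed(ref, ir.BreedSimParams(snp_rate=0, n_hvr=0, seed=20))
        reads = ir.simulate_reads(truth, ir.ReadSimParams(coverage=5.0, seed=20))
        result = ir.run_iterations(ref, reads, ir.IterationConfig(max_rounds=10))
        assert len(result.trace.rounds) == 1
        assert result.trace.rounds[0].n_substitutions == 0
        assert result.final_genome.sequences == ref.sequences

    def test_synthetic_breed_run_converges_and_improves(self, small_truth):
        ref, truth, reads = small_truth
        config = ir.IterationConfig(
            max_rounds=8, caller=ir.CallerParams(min_depth=1), seed=42
        )
        result = ir.run_iterations(ref, reads, config, truth_genome=truth.breed_genome)
        df = result.trace.to_frame()
        hom = df["hom_variant_count"].tolist()
        assert all(hom[i] >= hom[i + 1] for i in range(1, len(hom) - 1))
        sims = df["genome_similarity_to_truth"].tolist()
        assert all(sims[i] <= sims[i + 1] + 1e-12 for i in range(len(sims) - 1))
        rates = df["mapping_rate"].tolist()
        assert all(rates[i] <= rates[i + 1] + 1e-12 for i in range(len(rates) - 1))
        # every round's reference keeps the original coordinates
        assert all(g.same_shape(ref) for g in result.genomes)

    def test_eval_reads_tracked_but_never_substituted(self, small_truth):
        ref, truth, reads = small_truth
        eval_reads = ir.simulate_reads(truth, ir.ReadSimParams(coverage=2.0, seed=77))
        config = ir.IterationConfig(max_rounds=3, caller=ir.CallerParams(min_depth=1), seed=1)
        with_eval = ir.run_iterations(ref, reads, config, eval_reads=eval_reads)
        without = ir.run_iterations(ref, reads, config)
        assert all(r.eval_mapping_rate is not None for r in with_eval.trace.rounds)
        assert [g.sequences for g in with_eval.genomes] == [g.sequences for g in without.genomes]

    def test_trace_tsv_round_trip(self, tmp_path, small_truth):
        ref, truth, reads = small_truth
        config = ir.IterationConfig(max_rounds=3, caller=ir.CallerParams(min_depth=1))
        result = ir.run_iterations(ref, reads[:5000], config)
        p = tmp_path / "trace.tsv"
        result.trace.write_tsv(p)
        back = ir.IterationTrace.read_tsv(p)
        assert back.to_frame().equals(result.trace.to_frame())


class TestHetOscillation:
    def test_het_substitution_cycles_with_period_two(self):
        """Het-inclusive substitution flip-flops alleles: the alternative
        reference enters a period-2 cycle, substitutions never cease, and the
        variant-count series is non-monotone — while hom-only substitution on
        the same data converges."""
        ref = ir.random_reference(20_000, seed=11)
        truth = ir.simulate_breed(
            ref,
            ir.BreedSimParams(
                genome_length=20_000, snp_rate=0.03, het_fraction=0.8, n_hvr=0, seed=11
            ),
        )
        reads = ir.simulate_reads(truth, ir.ReadSimParams(coverage=30.0, seed=11))
        caller = ir.CallerParams(min_depth=1)
        het_cfg = ir.IterationConfig(max_rounds=8, hom_only=False, caller=caller)
        het = ir.run_iterations(ref, reads, het_cfg)
        subs = [r.n_substitutions for r in het.trace.rounds]
        assert len(subs) == 8 and all(s > 0 for s in subs)
        g = het.genomes
        assert g[4].sequences == g[6].sequences  # period-2 cycle
        assert g[4].sequences != g[5].sequences
        counts = [r.variant_count for r in het.trace.rounds]
        diffs = np.diff(counts)
        assert (diffs < 0).any() and (diffs > 0).any()  # up-and-down, not monotone
        # alleles switch over between consecutive rounds
        late, later = het.callsets[5], het.callsets[6]
        by_locus = {(c.chrom, c.pos): c for c in late}
        switched = sum(
            1
            for c in later
            if (c.chrom, c.pos) in by_locus
            and by_locus[(c.chrom, c.pos)].alt_base == c.ref_base
            and by_locus[(c.chrom, c.pos)].ref_base == c.alt_base
        )
        assert switched / len(later) > 0.95
        hom_cfg = ir.IterationConfig(max_rounds=8, hom_only=True, caller=caller)
        hom = ir.run_iterations(ref, reads, hom_cfg)
        assert hom.trace.rounds[-1].n_substitutions == 0


class TestCoverageTitration:
    def test_counts_grow_and_sensitivity_saturates(self, small_truth):
        """Variant counts rise with coverage on the pre-saturation branch and
        hold steady once every variant site is callable; sensitivity reaches
        1 against the deep-coverage gold standard; mapping rate is flat."""
        ref, truth, reads = small_truth
        coverages = list(range(1, 13)) + [20, 30]
        result = ir.run_coverage_titration(ref, reads, coverages, seed=42)
        counts = result.metrics["variant_count"].to_numpy()
        from scipy.stats import spearmanr

        rho = spearmanr(coverages[:12], counts[:12]).statistic
        assert rho > 0.95
        assert abs(counts[-1] - counts[-2]) <= 0.02 * counts[-1]  # plateau
        sens = result.metrics["sensitivity"].to_numpy()
        assert sens[-1] > sens[0]
        assert sens[-1] == pytest.approx(1.0, abs=1e-9)  # full pool vs itself
        rates = result.metrics["mapping_rate"].to_numpy()
        assert rates.max() - rates.min() < 0.005  # ~constant across coverages

    def test_requesting_more_than_pool_rejected(self, small_truth):
        ref, truth, reads = small_truth
        with pytest.raises(ValueError, match="exceeds"):
            ir.run_coverage_titration(ref, reads, [60.0], seed=0)
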