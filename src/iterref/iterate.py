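"""The iterative strategy: rounds of map → call → substitute, plus coverage titration.

Each round maps the (fixed) read set to the previous round's reference, calls
SNPs from the pileup, and substitutes eligible alleles to produce the next
alternative reference.  Consecutive-mismatch regions that defeat the mapper
are recovered stepwise: every round flattens the mismatches reachable from
already-mappable flanks, letting previously unmappable reads map in later
rounds.  After the rounds, a falling logistic fitted to the log variant
counts gives the optimal iteration count via the tangent-slope threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import align, call, consensus, curves
from .io_formats import Callset, Genome, ReadRecord
from .simulate import downsample_reads

logger = logging.getLogger(__name__)


@dataclass
class IterationConfig:
    """Controls for the iteration loop.

    max_rounds defaults to 30 (the full titration used to characterize
    convergence); tau is the tangent-slope magnitude at which extra rounds
    stop paying; hom_only keeps heterozygous calls out of the substitution
    step (het substitution causes allele flip-flop between rounds).
    """

    max_rounds: int = 30
    hom_only: bool = True
    tau: float = 1e-4
    mapper: align.MapperParams = field(default_factory=align.MapperParams)
    caller: call.CallerParams = field(default_factory=call.CallerParams)
    log_base: float = 2.0
    keep_genomes: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_rounds < 2:
            raise ValueError("max_rounds must be >= 2")


@dataclass
class RoundRecord:
    round_index: int
    variant_count: int
    hom_variant_count: int
    mapping_rate: float
    coverage_ratio: float
    n_substitutions: int
    genome_similarity_to_truth: float | None = None
    eval_mapping_rate: float | None = None


@dataclass
class IterationTrace:
    """Per-round metrics; the pipeline's primary output table."""

    rounds: list[RoundRecord] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(r) for r in self.rounds])
        for col in ("genome_similarity_to_truth", "eval_mapping_rate"):
            df[col] = df[col].astype(float)  # None -> NaN, stable dtype
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @staticmethod
    def read_tsv(path: str | Path) -> "IterationTrace":
        df = pd.read_csv(path, sep="\t")
        rounds = []
        for row in df.to_dict("records"):
            for k in ("round_index", "variant_count", "hom_variant_count", "n_substitutions"):
                row[k] = int(row[k])
            for k in ("genome_similarity_to_truth", "eval_mapping_rate"):
                if pd.isna(row.get(k)):
                    row[k] = None
            rounds.append(RoundRecord(**row))
        return IterationTrace(rounds)


@dataclass
class IterationResult:
    final_genome: Genome
    trace: IterationTrace
    optimal_n: int | None
    fit: curves.LogisticFit | None
    genomes: list[Genome] = field(default_factory=list)  # index r-1 = after round r
    callsets: list[Callset] = field(default_factory=list)
    warning: str | None = None


def run_iterations(
    reference: Genome,
    reads: Sequence[ReadRecord],
    config: IterationConfig | None = None,
    truth_genome: Genome | None = None,
    eval_reads: Sequence[ReadRecord] | None = None,
) -> IterationResult:
    """Run the map → call → substitute loop and pick the optimal round.

    ``truth_genome``, when given (synthetic runs), adds a per-round genome
    similarity column.  ``eval_reads`` are mapped to each round's updated
    reference for an independent mapping-rate curve; they never influence
    substitution.  Stops early when a round substitutes nothing (subsequent
    rounds would be identical).  The reported final genome is the reference
    after the optimal round — not after the last round run.
    """
    if not reads:
        raise ValueError("no reads supplied")
    config = config or IterationConfig()
    current = reference
    trace = IterationTrace()
    genomes: list[Genome] = []
    callsets: list[Callset] = []

    for round_index in range(1, config.max_rounds + 1):
        index = align.build_index(current, config.mapper.k)
        alignments = align.map_reads(reads, current, config.mapper, index=index)
        callset = call.pileup_and_call(alignments, current, config.caller)
        new_genome, log = consensus.apply_substitutions(
            current, callset, hom_only=config.hom_only, round_index=round_index
        )
        record = RoundRecord(
            round_index=round_index,
            variant_count=len(callset),
            hom_variant_count=call.count_variants(callset, "hom"),
            mapping_rate=align.mapping_rate(alignments),
            coverage_ratio=align.coverage_ratio(alignments, current),
            n_substitutions=len(log),
        )
        if truth_genome is not None:
            from .hvr import genome_similarity

            record.genome_similarity_to_truth = genome_similarity(new_genome, truth_genome)
        if eval_reads is not None:
            eval_aln = align.map_reads(eval_reads, new_genome, config.mapper)
            record.eval_mapping_rate = align.mapping_rate(eval_aln)
        trace.rounds.append(record)
        callsets.append(callset)
        current = new_genome
        if config.keep_genomes:
            genomes.append(new_genome)
        logger.info(
            "round %d: %d variants (%d hom), mapping rate %.4f, %d substitutions",
            round_index, record.variant_count, record.hom_variant_count,
            record.mapping_rate, record.n_substitutions,
        )
        if record.n_substitutions == 0:
            logger.info("round %d substituted nothing; stopping early", round_index)
            break

    fit = None
    optimal_n = None
    warning = None
    counts = [r.variant_count for r in trace.rounds]
    try:
        series = curves.CurveSeries(
            x=[r.round_index for r in trace.rounds], y_raw=counts, log_base=config.log_base
        )
        fit = curves.fit_logistic(series, "falling", seed=config.seed)
        optimal_n = curves.optimal_iterations(fit, config.tau)
        optimal_n = min(optimal_n, len(trace.rounds))
    except (ValueError, RuntimeError) as exc:
        warning = f"no optimal iteration count: {exc}"
        logger.warning(warning)

    if optimal_n is not None and genomes:
        final = genomes[optimal_n - 1]
    else:
        final = current
    return IterationResult(
        final_genome=final,
        trace=trace,
        optimal_n=optimal_n,
        fit=fit,
        genomes=genomes,
        callsets=callsets,
        warning=warning,
    )


@dataclass
class TitrationResult:
    series: curves.CurveSeries
    metrics: pd.DataFrame  # coverage, variant_count, mapping_rate, coverage_ratio, sensitivity
    gold: Callset


def run_coverage_titration(
    reference: Genome,
    read_pool: Sequence[ReadRecord],
    coverages: Sequence[float],
    mapper: align.MapperParams | None = None,
    caller: call.CallerParams | None = None,
    seed: int = 0,
    gold: Callset | None = None,
    log_base: float = 2.0,
) -> TitrationResult:
    """Downsample → map → call at each coverage; record counts and metrics.

    The gold standard defaults to the callset from the full read pool (the
    deep-coverage calls), against which per-coverage sensitivity is computed.
    """
    mapper = mapper or align.MapperParams()
    caller = caller or call.CallerParams()
    if not read_pool:
        raise ValueError("empty read pool")
    G = reference.total_length
    read_length = len(read_pool[0].sequence)
    pool_coverage = len(read_pool) * read_length / G
    if max(coverages) > pool_coverage * (1 + 1e-9):
        raise ValueError(
            f"max requested coverage {max(coverages)} exceeds pool coverage {pool_coverage:.2f}"
        )
    index = align.build_index(reference, mapper.k)
    if gold is None:
        full_aln = align.map_reads(read_pool, reference, mapper, index=index)
        gold = call.pileup_and_call(full_aln, reference, caller)

    rows = []
    rng = np.random.default_rng(seed)
    for cov in coverages:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        subset = downsample_reads(list(read_pool), cov, G, read_length, seed=sub_seed)
        alignments = align.map_reads(subset, reference, mapper, index=index)
        callset = call.pileup_and_call(alignments, reference, caller)
        comparison = call.compare_callsets(callset, gold)
        rows.append(
            {
                "coverage": cov,
                "variant_count": len(callset),
                "mapping_rate": align.mapping_rate(alignments),
                "coverage_ratio": align.coverage_ratio(alignments, reference),
                "sensitivity": comparison.sensitivity,
            }
        )
        logger.info("coverage %.1fx: %d variants", cov, rows[-1]["variant_count"])
    metrics = pd.DataFrame(rows)
    positive = metrics["variant_count"] > 0
    series = curves.CurveSeries(
        x=metrics.loc[positive, "coverage"].to_numpy(),
        y_raw=metrics.loc[positive, "variant_count"].to_numpy(),
        log_base=log_base,
    )
    return TitrationResult(series=series, metrics=metrics, gold=gold)
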