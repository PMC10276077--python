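"""Reproducible benchmark harnesses composing the library end to end.

``run_correction_benchmark`` regenerates the error-correction benchmark —
a three-tier exponential library of random 20-mers, Poisson read depth,
0.4%/base substitutions and run-dependent indels — runs Deletion-Correct on
the resulting count table and scores it against the ground truth.  The
default scale (10^4 barcodes, ~2.5M expected reads) keeps the mixture
proportions of the full 10^5-barcode / 25M-read experiment while running in
minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

from .correction import CorrectionParams, deletion_correct, evaluate_correction
from .read_sim import ErrorModel, scaled_tier_counts, simulate_reads, simulate_true_library
from .utils import derive_seed


@dataclass
class BenchmarkResult:
    n_barcodes: int
    total_reads: int
    n_unique_observed: int
    report: "object"  # EvaluationReport


def run_correction_benchmark(
    n_barcodes: int = 10_000,
    expected_reads: float = 2.5e6,
    params: CorrectionParams | None = None,
    model: ErrorModel | None = None,
    seed: int = 0,
) -> BenchmarkResult:
    n_low, n_mid, n_high = scaled_tier_counts(n_barcodes)
    lib = simulate_true_library(
        n_low, n_mid, n_high, seed=derive_seed(seed, "benchmark_library")
    )
    sim = simulate_reads(
        lib, expected_reads, model or ErrorModel(), seed=derive_seed(seed, "benchmark_reads")
    )
    counts = sim.counts
    clusters = deletion_correct(counts, params or CorrectionParams())
    clusters.validate(counts)
    report = evaluate_correction(sim, clusters)
    return BenchmarkResult(
        n_barcodes=len(lib),
        total_reads=sim.total_reads,
        n_unique_observed=len(counts),
        report=report,
    )
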