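"""Library, read-error, UMI and transformation simulations."""

import math

import numpy as np
import pandas as pd
import pytest

from barcodekit.design_eval import max_run, parse_design
from barcodekit.extraction import AmpliconLayout, build_regex_ladder, extract_regex
from barcodekit.io import write_fastq
from barcodekit.read_sim import (
    ErrorModel,
    TrueLibrary,
    render_fastq,
    scaled_tier_counts,
    simulate_reads,
    simulate_true_library,
    simulate_umi_experiment,
    transformation_sampling,
)
from conftest import random_barcode


def run_free_library(rng, n, length=20, min_run=5):
    """A library whose barcodes carry no indel-prone runs."""
    barcodes = []
    while len(barcodes) < n:
        bc = random_barcode(rng, length)
        if max_run(bc, 1) < min_run and bc not in barcodes:
            barcodes.append(bc)
    return TrueLibrary(
        barcodes=barcodes, abundances=rng.exponential(1.0, size=n) + 1e-9, seed=0
    )


class TestTrueLibrary:
    def test_tier_counts_and_uniqueness(self):
        lib = simulate_true_library(500, 10, 2, seed=1)
        assert len(lib) == 512
        assert len(set(lib.barcodes)) == 512
        assert lib.frequencies.sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_barcode(self):
        lib = simulate_true_library(1, 0, 0, seed=2)
        assert len(lib) == 1 and lib.frequencies[0] == pytest.approx(1.0)

    def test_design_space_too_small(self):
        with pytest.raises(ValueError, match="design space"):
            simulate_true_library(20, 0, 0, design=parse_design("NN"), seed=3)

    def test_tier_mean_ratio(self):
        """High tier abundances are ~1000x the low tier (law of large numbers)."""
        lib = simulate_true_library(4000, 0, 4000, seed=4, design=parse_design("N" * 15))
        low = lib.abundances[:4000].mean()
        high = lib.abundances[4000:].mean()
        assert high / low == pytest.approx(1000.0, rel=0.1)

    def test_scaled_tier_counts(self):
        assert scaled_tier_counts(100_000) == (99_895, 100, 5)
        assert sum(scaled_tier_counts(10_000)) == 10_000
        assert scaled_tier_counts(10_000)[2] >= 1  # outlier tier represented


class TestSimulateReads:
    def test_error_free_identity(self, rng):
        lib = run_free_library(rng, 50)
        sim = simulate_reads(lib, 20_000, ErrorModel(substitution_rate=0.0), seed=5)
        assert set(sim.table["observed"]) <= set(lib.barcodes)
        assert set(sim.table["error_class"]) == {"none"}
        # per-barcode counts equal the Poisson draws exactly (no reads moved)
        assert sim.counts.sum() == sim.total_reads

    def test_conservation_and_truth_map_complete(self, rng):
        lib = simulate_true_library(300, 3, 1, seed=6)
        sim = simulate_reads(lib, 100_000, ErrorModel(), seed=7)
        # every observed sequence has a truth entry; totals add up
        assert set(sim.truth_map.index) == set(sim.table["observed"])
        assert sim.counts.sum() == sim.total_reads
        assert set(sim.table["parent"]) <= set(lib.barcodes)

    def test_substitution_fraction_matches_binomial(self, rng):
        lib = run_free_library(rng, 40)
        sim = simulate_reads(lib, 300_000, ErrorModel(), seed=8)
        errored = sim.table.loc[sim.table["error_class"] != "none", "reads"].sum()
        frac = errored / sim.total_reads
        expect = 1 - (1 - 0.004) ** 20
        sigma = math.sqrt(expect * (1 - expect) / sim.total_reads)
        assert abs(frac - expect) < 5 * sigma

    def test_recursive_indels_extend_runs(self):
        """Single-step +1 events chained by recursion produce +2 products."""
        bc = "AAAAA" + "CGTCGACGTGACTAG"
        lib = TrueLibrary(barcodes=[bc], abundances=np.array([1.0]), seed=0)
        model = ErrorModel(
            substitution_rate=0.0,
            rate_table={5: 0.4, 6: 0.4, 7: 0.4},
            event_shares={+1: 1.0, -1: 0.0, +2: 0.0, -2: 0.0},
        )
        sim = simulate_reads(lib, 50_000, model, seed=9)
        runs = {max_run(s, 1) for s in sim.table["observed"]}
        assert {5, 6, 7} <= runs  # 7 only reachable via recursion
        indel = sim.table[sim.table["error_class"] == "indel"]
        assert (indel["parent"] == bc).all()

    def test_indel_events_cover_pm_two_repeats(self):
        bc = "T" * 6 + "ACGCATGCAGACGA"
        lib = TrueLibrary(barcodes=[bc], abundances=np.array([1.0]), seed=0)
        model = ErrorModel(substitution_rate=0.0, rate_table={i: 0.3 for i in range(4, 9)})
        sim = simulate_reads(lib, 40_000, model, seed=10)
        lengths = {len(s) for s in sim.table["observed"]}
        assert {len(bc) - 2, len(bc) - 1, len(bc), len(bc) + 1, len(bc) + 2} <= lengths

    def test_deterministic_given_seed(self, rng):
        lib = simulate_true_library(100, 2, 0, seed=11)
        a = simulate_reads(lib, 30_000, ErrorModel(), seed=12)
        b = simulate_reads(lib, 30_000, ErrorModel(), seed=12)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_rejects_nonpositive_depth(self, rng):
        lib = run_free_library(rng, 5)
        with pytest.raises(ValueError):
            simulate_reads(lib, 0.0, ErrorModel(), seed=13)


class TestErrorModel:
    def test_rate_monotone_in_run_length(self):
        m = ErrorModel()
        rates = [m.total_indel_rate(n) for n in range(5, 20)]
        assert all(b >= a for a, b in zip(rates, rates[1:]))
        assert m.total_indel_rate(4) == 0.0

    def test_calibration_anchors(self):
        m = ErrorModel()
        assert m.total_indel_rate(10) == pytest.approx(0.05, rel=0.02)
        assert m.total_indel_rate(13) == pytest.approx(0.30, rel=0.02)

    def test_lookup_table_override(self):
        m = ErrorModel(rate_table={6: 0.125})
        assert m.total_indel_rate(6) == 0.125
        assert m.total_indel_rate(7) == 0.0
        assert sum(m.event_rates(6).values()) == pytest.approx(0.125)


class TestUMISimulation:
    def test_read_limited_regime(self):
        r = simulate_umi_experiment(10**7, 0.05, bias=1.0, n_reads=10**5, seed=14)
        assert r.duplicate_fraction < 0.02
        assert r.dedup_estimate == pytest.approx(0.05, abs=0.01)
        assert r.naive_estimate == pytest.approx(0.05, abs=0.01)

    def test_two_reads_per_template_gives_half_duplicates(self):
        r = simulate_umi_experiment(50_000, 0.25, mode="two_per_template", seed=15)
        assert r.duplicate_fraction == 0.5

    def test_template_limited_regime(self):
        r = simulate_umi_experiment(100, 0.05, bias=1.0, n_reads=10**6, seed=16)
        assert r.duplicate_fraction > 0.999

    def test_duplicate_fraction_monotone_in_depth_ratio(self):
        fracs = [
            simulate_umi_experiment(10**5, 0.05, n_reads=n, seed=17).duplicate_fraction
            for n in (10**3, 10**5, 10**7)
        ]
        assert fracs[0] < fracs[1] < fracs[2]

    def test_dedup_partially_corrects_bias(self):
        r = simulate_umi_experiment(10**6, 0.25, bias=1.5, n_reads=10**6, seed=18)
        assert r.naive_estimate > r.dedup_estimate > r.focal_frequency
        assert 0.0 < r.bias_corrected_fraction < 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_umi_experiment(100, 1.5)
        with pytest.raises(ValueError):
            simulate_umi_experiment(100, 0.5, bias=0.0)


class TestTransformation:
    def test_single_cell(self, rng):
        lib = simulate_true_library(10, 0, 0, seed=19)
        res = transformation_sampling(lib, 1, seed=20)
        assert res.cell_counts.sum() == 1
        assert res.n_transformed_barcodes == 1
        assert res.fraction_multi_cell == 0.0

    def test_uniform_occupancy_matches_poisson_oracle(self):
        """K = N uniform: P(count>1 | count>0) -> (1 - 2/e) / (1 - 1/e)."""
        import itertools

        N = 2000
        barcodes = [
            "".join(t) for t in itertools.islice(itertools.product("ACGT", repeat=6), N)
        ]
        lib = TrueLibrary(barcodes=barcodes, abundances=np.ones(N), seed=0)
        fracs = [
            transformation_sampling(lib, N, seed=s).fraction_multi_cell
            for s in range(20)
        ]
        expect = (1 - 2 / math.e) / (1 - 1 / math.e)
        assert np.mean(fracs) == pytest.approx(expect, abs=0.01)

    def test_low_k_fmax_keeps_singletons(self):
        lib = simulate_true_library(10_000, 0, 0, seed=21)
        # K chosen so K * fmax ~ 0.01 << 1
        K = 10
        n_multi = n_present = 0
        for s in range(50):
            res = transformation_sampling(lib, K, seed=s)
            n_multi += int((res.cell_counts > 1).sum())
            n_present += res.n_transformed_barcodes
        # almost no barcode lands in more than one cell
        assert n_multi / n_present < 0.01


class TestRenderFastq:
    def test_read_multiplicity_preserved(self, layout):
        table = pd.DataFrame(
            [("ACGTACGTACGTACGTACGT", "ACGTACGTACGTACGTACGT", "none", 3)],
            columns=["observed", "parent", "error_class", "reads"],
        )
        from barcodekit.read_sim import SimulatedReads

        recs = list(render_fastq(SimulatedReads(table=table, seed=0), layout, seed=22))
        assert len(recs) == 3
        assert all(layout.upstream in seq for _, seq, _ in recs)

    def test_offsets_change_read_length(self, layout):
        from dataclasses import replace

        from barcodekit.read_sim import SimulatedReads

        table = pd.DataFrame(
            [("A" * 20, "A" * 20, "none", 50)],
            columns=["observed", "parent", "error_class", "reads"],
        )
        sim = SimulatedReads(table=table, seed=0)
        lay = replace(layout, offset_lengths=(0, 2))
        lengths = {len(seq) for _, seq, _ in render_fastq(sim, lay, seed=23)}
        base = len(layout.upstream) + 20 + len(layout.downstream)
        assert lengths == {base, base + 2}

    def test_roundtrip_with_extraction(self, rng, layout, tmp_path):
        """Rendered error-free reads re-extract to identical counts."""
        lib = run_free_library(rng, 30)
        sim = simulate_reads(lib, 3_000, ErrorModel(substitution_rate=0.0), seed=24)
        path = tmp_path / "reads.fastq"
        write_fastq(render_fastq(sim, layout, seed=25), path)
        ladder = build_regex_ladder(layout)
        counts: dict[str, int] = {}
        from barcodekit.io import read_fastq

        for read in read_fastq(path):
            res = extract_regex(read, ladder)
            assert res.status == "extracted" and res.level == 1
            counts[res.barcode] = counts.get(res.barcode, 0) + 1
        assert counts == sim.counts.to_dict()
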