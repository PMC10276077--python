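"""Regex-ladder and alignment extraction, demultiplexing, UMI handling."""

import numpy as np
import pandas as pd
import pytest

from barcodekit.extraction import (
    AmpliconLayout,
    ExtractionResult,
    IndexScheme,
    QualityPolicy,
    ReadRecord,
    build_regex_ladder,
    compare_methods,
    demultiplex,
    demultiplex_batch,
    extract_by_alignment,
    extract_regex,
    length_distribution,
    umi_dedup,
    umi_duplicate_stats,
)
from barcodekit.read_sim import ErrorModel, render_fastq, simulate_reads, simulate_true_library
from conftest import random_barcode

BC = "ACTGTCAGCCAGTTCAGATC"  # 20-mer with no flank-like content


def make_read(layout, barcode, up=None, down=None, prefix="", suffix="", qual=None):
    seq = prefix + (up or layout.upstream) + barcode + (down or layout.downstream) + suffix
    quals = tuple([qual or 37] * len(seq))
    return ReadRecord("r", seq, quals)


class TestLadder:
    def test_five_levels_by_default(self, layout):
        ladder = build_regex_ladder(layout)
        assert [r.level for r in ladder] == [1, 2, 3, 4, 5]

    def test_short_flanks_rejected(self):
        lay = AmpliconLayout("ACGT", "TGCA", 10)
        with pytest.raises(ValueError, match="anchor_width"):
            build_regex_ladder(lay)

    @pytest.mark.parametrize(
        "mutate, expected_level",
        [
            (lambda bc, lay: (bc, lay.upstream, lay.downstream), 1),
            (lambda bc, lay: (bc[:-1], lay.upstream, lay.downstream), 2),  # 1-bp del
            (lambda bc, lay: (bc + "GT", lay.upstream, lay.downstream), 3),  # 2-bp ins
            (
                lambda bc, lay: (
                    bc,
                    lay.upstream[:-3] + "T" + lay.upstream[-2:],  # sub in anchor
                    lay.downstream,
                ),
                4,
            ),
        ],
    )
    def test_first_matching_level(self, layout, mutate, expected_level):
        barcode, up, down = mutate(BC, layout)
        res = extract_regex(make_read(layout, barcode, up=up, down=down),
                            build_regex_ladder(layout))
        assert res.status == "extracted"
        assert res.level == expected_level

    def test_leniency_nesting(self, layout, rng):
        """Any read matched at level k is matched by every higher level."""
        ladder = build_regex_ladder(layout)
        for _ in range(200):
            bc = random_barcode(rng, int(rng.integers(18, 23)))
            up = list(layout.upstream)
            if rng.random() < 0.5:
                up[int(rng.integers(len(up)))] = "ACGT"[int(rng.integers(4))]
            seq = "".join(up) + bc + layout.downstream
            matched = [bool(r.pattern.search(seq)) for r in ladder]
            first = next((i for i, m in enumerate(matched) if m), None)
            if first is not None:
                assert all(matched[first:])

    def test_length_free_pattern(self, layout):
        ladder = build_regex_ladder(layout, include_length_free=True)
        assert ladder[-1].level == 6
        long_bc = BC + "ACGTACGTAC"  # +10 bp
        res = extract_regex(make_read(layout, long_bc), ladder)
        assert res.level == 6 and res.barcode == long_bc


class TestExtractRegex:
    def test_missing_flanks(self, layout):
        res = extract_regex(ReadRecord("r", BC), build_regex_ladder(layout))
        assert res.status == "no_match" and res.barcode is None

    def test_low_quality_read(self, layout):
        read = make_read(layout, BC, qual=10)  # mean Phred 10 < 20
        res = extract_regex(read, build_regex_ladder(layout))
        assert res.status == "low_quality"

    def test_level3_records_length(self, layout):
        res = extract_regex(make_read(layout, BC + "CA"), build_regex_ladder(layout))
        assert res.level == 3 and res.barcode_length == 22

    def test_error_free_batch_fully_extracted(self, layout, rng):
        ladder = build_regex_ladder(layout)
        reads = [make_read(layout, random_barcode(rng)) for _ in range(300)]
        results = [extract_regex(r, ladder) for r in reads]
        assert all(r.status == "extracted" and r.level == 1 for r in results)


class TestExtractAlignment:
    def test_agrees_with_regex_on_clean_read(self, layout):
        read = make_read(layout, BC, prefix="GGA", suffix="TTC")
        reg = extract_regex(read, build_regex_ladder(layout))
        aln = extract_by_alignment(read, layout)
        assert aln.status == "extracted"
        assert aln.barcode == reg.barcode == BC

    def test_tolerates_abnormal_length(self, layout):
        long_bc = BC[:10] + "GGACT" + BC[10:]  # +5 bp insertion
        read = make_read(layout, long_bc)
        aln = extract_by_alignment(read, layout)
        assert aln.status == "extracted"
        assert aln.barcode_length == 25
        reg = extract_regex(read, build_regex_ladder(layout))
        # the +-2-capped ladder cannot extract the correct 25-mer
        assert reg.status != "extracted" or reg.barcode != long_bc

    def test_scrambled_flank_order(self, layout):
        read = ReadRecord("r", layout.downstream + BC + layout.upstream)
        assert extract_by_alignment(read, layout).status == "no_match"

    def test_identity_threshold_enforced(self, layout):
        mutated_up = layout.upstream[:5] + "A" + layout.upstream[6:]
        read = ReadRecord("r", mutated_up + BC + layout.downstream)
        strict = extract_by_alignment(read, layout, min_flank_identity=1.0)
        assert strict.status == "no_match"
        lenient = extract_by_alignment(read, layout, min_flank_identity=0.8)
        assert lenient.status == "extracted" and lenient.barcode == BC


class TestSimulatedReadConcordance:
    def test_extraction_and_agreement_bounds(self, layout, rng):
        """On simulated error-bearing reads both methods extract >= 94% and
        agree on >= 97% of jointly extracted reads."""
        lib = simulate_true_library(80, 2, 0, seed=31)
        sim = simulate_reads(lib, 2_000, ErrorModel(), seed=32)
        reads = [
            ReadRecord(rid, seq, tuple([37] * len(seq)))
            for rid, seq, _ in render_fastq(sim, layout, seed=33)
        ]
        ladder = build_regex_ladder(layout)
        reg = [extract_regex(r, ladder) for r in reads]
        aln = [extract_by_alignment(r, layout) for r in reads]
        frac_reg = sum(r.status == "extracted" for r in reg) / len(reads)
        frac_aln = sum(r.status == "extracted" for r in aln) / len(reads)
        assert frac_reg >= 0.94
        assert frac_aln >= 0.94
        table = compare_methods(reg, aln)
        assert table.agreement_fraction >= 0.97


class TestLengthDistribution:
    def test_all_expected_length(self):
        dist = length_distribution({"A" * 20: 100, "C" * 20: 50}, 20)
        assert dist[0] == 100.0
        assert dist.drop(0).sum() == 0.0

    def test_count_filter(self):
        counts = {"A" * 20: 30, "C" * 19: 25, "G" * 18: 5}
        dist = length_distribution(counts, 20, min_reads=20)
        assert dist[0] == 50.0 and dist[-1] == 50.0 and dist[-2] == 0.0

    def test_empty_warns(self):
        with pytest.warns(UserWarning):
            dist = length_distribution({}, 20)
        assert dist.sum() == 0.0


def scheme():
    return IndexScheme(
        {
            "s1": ("AACCGG", "TTGGCC", "ACAC", "GTGT"),
            "s2": ("CCGGAA", "GGCCTT", "CGCG", "TATA"),
            "s3": ("GGTTCC", "CCAATT", "GAGA", "CTCT"),
        }
    )


class TestDemultiplex:
    def test_admissible_tuple(self):
        assert demultiplex(("AACCGG", "TTGGCC", "ACAC", "GTGT"), scheme()) == "s1"

    def test_one_mismatch_resolves(self):
        assert demultiplex(("AACCGT", "TTGGCC", "ACAC", "GTGT"), scheme()) == "s1"

    def test_single_swap_is_chimera(self):
        # sample 1's inline5 with sample 2's i7
        assert demultiplex(("AACCGG", "GGCCTT", "ACAC", "GTGT"), scheme()) == "chimera"

    def test_unresolvable_index_is_unknown(self):
        assert demultiplex(("AATTTT", "TTGGCC", "ACAC", "GTGT"), scheme()) == "unknown"

    def test_redundant_scheme_flags_all_single_swaps(self):
        sch = scheme()
        assert sch.is_redundant()
        samples = list(sch.samples.values())
        flagged = total = 0
        for a in samples:
            for b in samples:
                if a == b:
                    continue
                for slot in range(4):
                    t = list(a)
                    t[slot] = b[slot]
                    total += 1
                    flagged += demultiplex(tuple(t), sch) == "chimera"
        assert flagged == total

    def test_batch_chimera_fraction(self):
        tuples = [
            ("AACCGG", "TTGGCC", "ACAC", "GTGT"),
            ("AACCGG", "GGCCTT", "ACAC", "GTGT"),
        ]
        df = demultiplex_batch(tuples, scheme())
        assert df.attrs["chimera_fraction"] == 0.5

    def test_duplicate_tuples_rejected(self):
        with pytest.raises(ValueError):
            IndexScheme({"a": ("A", "C", "G", "T"), "b": ("A", "C", "G", "T")})


class TestUMIs:
    def test_duplicate_stats(self):
        pairs = (
            [("bc1", f"U{i}") for i in range(5)]  # all distinct -> 0
            + [("bc2", "UX")] * 10  # one UMI -> 0.9
            + [("bc3", "UA")] * 2
            + [("bc3", "UB")] * 2  # 4 reads 2 UMIs -> 0.5
        )
        stats = umi_duplicate_stats(pairs)
        assert stats.loc["bc1", "duplicate_fraction"] == 0.0
        assert stats.loc["bc2", "duplicate_fraction"] == pytest.approx(0.9)
        assert stats.loc["bc3", "duplicate_fraction"] == pytest.approx(0.5)

    def test_dedup_refused_when_umi_space_small(self):
        counts = {"bc": {f"U{i}": 10 for i in range(1000)}}  # 10^4 reads
        res = umi_dedup(counts, umi_length=6)
        assert not res.performed and "4^6" in res.reason

    def test_dedup_performed(self):
        counts = {"bc": {f"U{i}": 2 for i in range(500)}}  # 10^3 reads, 4^10 UMIs
        res = umi_dedup(counts, umi_length=10)
        assert res.performed and res.counts["bc"] == 500

    def test_all_unique_unchanged(self):
        counts = {"bc": {f"U{i}": 1 for i in range(50)}}
        res = umi_dedup(counts, umi_length=10)
        assert res.counts["bc"] == 50


class TestCompareMethods:
    def e(self, bc):
        return ExtractionResult(status="extracted", barcode=bc)

    def miss(self):
        return ExtractionResult(status="no_match")

    def test_identical_sets(self):
        a = [self.e("AAA"), self.e("CCC")]
        table = compare_methods(a, list(a))
        assert table.agreement_fraction == 1.0 and table.both_equal == 2

    def test_only_one_extracted(self):
        table = compare_methods([self.miss()], [self.e("AAA")])
        assert table.only_second == 1 and table.agreement_fraction is None

    def test_empty(self):
        table = compare_methods([], [])
        assert table.both_equal == 0 and table.agreement_fraction is None

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_methods([self.miss()], [])
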