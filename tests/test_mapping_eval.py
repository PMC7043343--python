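"""Read cleaning, outlier filtering, coverage, improvement, enrichment."""

import math

import numpy as np
import pysam
import pytest
from scipy.stats import hypergeom

from conftest import random_dna
from oracles import clean_read_oracle, coverage_oracle, hypergeom_tail_oracle

from strainprio.mapping_eval import (
    CoverageProfile,
    clean_reads,
    coverage_profiles,
    enrichment_test,
    filter_sample_outliers,
    high_representation,
    improvement_summary,
)


def _write_fastq(path, reads):
    with open(path, "w") as fh:
        for rid, seq, quals in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{''.join(chr(q + 33) for q in quals)}\n")


class TestCleanReads:
    def test_high_quality_read_kept_unmodified(self, tmp_path):
        seq = "ACGT" * 25
        _write_fastq(tmp_path / "r.fastq", [("r1", seq, [30] * 100)])
        kept, counts = clean_reads(tmp_path / "r.fastq")
        assert counts == {"input": 1, "kept": 1, "dropped": 0}
        assert kept[0][1] == seq

    def test_low_quality_tail_trims_below_floor_and_drops(self, tmp_path):
        seq = "A" * 110
        quals = [30] * 50 + [2] * 60
        _write_fastq(tmp_path / "r.fastq", [("r1", seq, quals)])
        kept, counts = clean_reads(tmp_path / "r.fastq")
        assert counts["dropped"] == 1 and kept == []

    def test_interior_low_quality_not_trimmed(self, tmp_path):
        quals = [30] * 40 + [1] * 5 + [30] * 55
        _write_fastq(tmp_path / "r.fastq", [("r1", "C" * 100, quals)])
        kept, _ = clean_reads(tmp_path / "r.fastq")
        assert len(kept[0][1]) == 100

    def test_n_runs_gate_survival(self, tmp_path):
        # 59 non-N bases max -> dropped; 60 -> kept
        seq_bad = "A" * 59 + "N" + "A" * 40
        seq_ok = "A" * 60 + "N" + "A" * 39
        _write_fastq(
            tmp_path / "r.fastq",
            [("bad", seq_bad, [30] * 100), ("ok", seq_ok, [30] * 100)],
        )
        kept, _ = clean_reads(tmp_path / "r.fastq")
        assert [r[0] for r in kept] == ["ok"]

    def test_randomized_reads_match_brute_force_oracle(self, tmp_path):
        rng = np.random.default_rng(5)
        reads = []
        for i in range(120):
            length = int(rng.integers(40, 150))
            seq = "".join(
                "N" if rng.random() < 0.03 else "ACGT"[int(rng.integers(0, 4))]
                for _ in range(length)
            )
            quals = [int(q) for q in rng.integers(0, 41, size=length)]
            reads.append((f"r{i}", seq, quals))
        _write_fastq(tmp_path / "r.fastq", reads)
        kept, counts = clean_reads(tmp_path / "r.fastq")
        expected = {}
        for rid, seq, quals in reads:
            result = clean_read_oracle(seq, quals)
            if result is not None:
                expected[rid] = result[0]
        assert {rid: seq for rid, seq, _ in kept} == expected
        assert counts["kept"] + counts["dropped"] == counts["input"]

    def test_never_lengthens_reads(self, tmp_path):
        rng = np.random.default_rng(6)
        reads = [
            (f"r{i}", random_dna(rng, 80), [int(q) for q in rng.integers(0, 41, size=80)])
            for i in range(30)
        ]
        _write_fastq(tmp_path / "r.fastq", reads)
        kept, counts = clean_reads(tmp_path / "r.fastq")
        assert counts["kept"] <= counts["input"]
        assert all(len(seq) <= 80 for _, seq, _ in kept)

    def test_malformed_fastq_reports_record_index(self, tmp_path):
        path = tmp_path / "bad.fastq"
        path.write_text("@r1\nACGT\n+\n!!\n")  # quality length mismatch
        with pytest.raises(ValueError, match="record index"):
            clean_reads(path)


class TestFilterSampleOutliers:
    def test_identical_counts_drop_nothing(self):
        counts = {f"s{i}": 100 for i in range(10)}
        sites = {s: "Feces" for s in counts}
        assert filter_sample_outliers(counts, sites) == sorted(counts)

    def test_three_sd_rule_drops_extreme_sample(self):
        counts = {f"s{i}": 10 for i in range(10)}
        counts["big"] = 10000
        sites = {s: "Feces" for s in counts}
        # direct computation: mean 918.2, SD 2871.7, upper bound 9533.4
        mean = np.mean(list(counts.values()))
        upper = mean + 3 * np.std(list(counts.values()))
        assert counts["big"] > upper
        retained = filter_sample_outliers(counts, sites)
        assert "big" not in retained
        assert len(retained) == 10

    def test_lower_quantile_drops_floor_fraction(self):
        counts = {f"s{i:02d}": 1000 + i for i in range(40)}
        sites = {s: "Feces" for s in counts}
        retained = filter_sample_outliers(counts, sites)
        assert len(retained) == 38  # floor(0.05 * 40) == 2
        assert "s00" not in retained and "s01" not in retained

    def test_sites_filtered_independently(self):
        counts = {"a1": 10, "a2": 10, "b1": 10, "b2": 10000}
        sites = {"a1": "Feces", "a2": "Feces", "b1": "Skin", "b2": "Skin"}
        retained = filter_sample_outliers(counts, sites)
        # b2 inflates only Skin's SD envelope; with two samples nothing
        # exceeds mean + 3 SD, and floor(0.05 * 2) = 0
        assert retained == ["a1", "a2", "b1", "b2"]


def _write_sam(path, genome_lengths, alignments):
    """alignments: (read_id, genome, start0, seq)"""
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": g, "LN": length} for g, length in sorted(genome_lengths.items())],
    }
    tid = {g: i for i, g in enumerate(sorted(genome_lengths))}
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for rid, genome, start, seq in alignments:
            a = pysam.AlignedSegment(sam.header)
            a.query_name = rid
            a.flag = 0
            a.reference_id = tid[genome]
            a.reference_start = start
            a.mapping_quality = 60
            a.cigarstring = f"{len(seq)}M"
            a.query_sequence = seq
            sam.write(a)


class TestCoverageProfiles:
    def test_single_alignment_breadth_and_depth(self, tmp_path):
        _write_sam(tmp_path / "a.sam", {"G1": 1000}, [("r1", "G1", 100, "A" * 100)])
        (profile,) = coverage_profiles(tmp_path / "a.sam")
        assert profile.breadth == pytest.approx(0.10)
        assert profile.mean_depth == pytest.approx(0.10)
        assert profile.n_reads == 1

    def test_overlapping_duplicates_change_depth_not_breadth(self, tmp_path):
        alns = [("r1", "G1", 100, "A" * 100), ("r2", "G1", 100, "A" * 100)]
        _write_sam(tmp_path / "a.sam", {"G1": 1000}, alns)
        (profile,) = coverage_profiles(tmp_path / "a.sam")
        assert profile.breadth == pytest.approx(0.10)
        assert profile.mean_depth == pytest.approx(0.20)

    def test_unknown_genome_is_hard_error(self, tmp_path):
        _write_sam(tmp_path / "a.sam", {"G1": 1000}, [("r1", "G1", 0, "A" * 50)])
        with pytest.raises(ValueError, match="unknown genome"):
            coverage_profiles(tmp_path / "a.sam", genome_lengths={"G2": 500})

    def test_matches_per_base_counting_oracle(self, tmp_path):
        rng = np.random.default_rng(9)
        genome_lengths = {"G1": 2000, "G2": 1500, "G3": 800}
        alignments = []
        truth = []
        for i in range(200):
            g = ["G1", "G2", "G3"][int(rng.integers(0, 3))]
            length = int(rng.integers(30, 120))
            start = int(rng.integers(0, genome_lengths[g] - length))
            alignments.append((f"r{i}", g, start, "A" * length))
            truth.append((g, start, length))
        _write_sam(tmp_path / "a.sam", genome_lengths, alignments)
        expected = coverage_oracle(truth, genome_lengths)
        for profile in coverage_profiles(tmp_path / "a.sam"):
            breadth, depth, n = expected[profile.genome_id]
            assert profile.breadth == pytest.approx(breadth, abs=1e-12)
            assert profile.mean_depth == pytest.approx(depth, abs=1e-12)
            assert profile.n_reads == n

    @pytest.mark.parametrize(
        "breadth,depth,expected",
        [(0.50, 1.0, True), (0.49, 5.0, False), (1.0, 0.99, False), (0.9, 2.0, True)],
    )
    def test_high_representation_thresholds_inclusive(self, breadth, depth, expected):
        profile = CoverageProfile("G1", 1000, breadth, depth, 10)
        assert high_representation(profile) is expected


class TestImprovementSummary:
    def _summary(self, sid, site, base, aug, cleaned=10000):
        from strainprio.mapping_eval import MappingSummary

        return MappingSummary(sid, site, cleaned, base, aug)

    def test_equal_databases_give_zero_increase(self):
        summaries = [self._summary(f"s{i}", "Feces", 500, 500) for i in range(4)]
        df = improvement_summary(summaries, "body_site")
        assert (df["relative_increase_pct"] == 0).all()

    def test_thirty_percent_increase(self):
        df = improvement_summary([self._summary("s1", "Feces", 1000, 1300)], "body_site")
        assert df.loc[0, "relative_increase_pct"] == pytest.approx(30.0)

    def test_zero_baseline_marked_undefined(self):
        df = improvement_summary([self._summary("s1", "Feces", 0, 10)], "sample")
        assert math.isnan(df.loc[0, "relative_increase_pct"])

    def test_unknown_grouping_rejected(self):
        with pytest.raises(ValueError):
            improvement_summary([], "genus")


class TestEnrichmentTest:
    def test_no_signal_gives_p_one(self):
        assert enrichment_test(0, 10, 0, 10) == pytest.approx(1.0)

    def test_counts_exceeding_totals_rejected(self):
        with pytest.raises(ValueError):
            enrichment_test(11, 10, 0, 10)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration_on_small_tables(self, seed):
        rng = np.random.default_rng(seed)
        total_novel = int(rng.integers(1, 7))
        total_public = int(rng.integers(1, 13 - total_novel))
        high_novel = int(rng.integers(0, total_novel + 1))
        high_public = int(rng.integers(0, total_public + 1))
        p = enrichment_test(high_novel, total_novel, high_public, total_public)
        expected = hypergeom_tail_oracle(high_novel, total_novel, high_public, total_public)
        assert p == pytest.approx(expected, rel=1e-12)

    def test_group_swap_tail_duality(self):
        """Over-representation in one group equals under-representation of
        the complementary count in the other."""
        high_novel, total_novel, high_public, total_public = 5, 12, 3, 20
        p_over = enrichment_test(high_novel, total_novel, high_public, total_public)
        population = total_novel + total_public
        successes = high_novel + high_public
        p_under_swapped = float(
            hypergeom.cdf(high_public, population, successes, total_public)
        )
        assert p_over == pytest.approx(p_under_swapped, rel=1e-12)
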