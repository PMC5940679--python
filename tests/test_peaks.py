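"""Tests for ChIP-seq peak post-processing and the TF-association score."""

import math

import numpy as np
import pytest

from osmochrom.peaks import (
    GeneRecord,
    NewPeaksConfig,
    PeakRecord,
    PeakSet,
    assign_peaks_to_genes,
    association_score,
    containment_fraction,
    new_peaks,
    peak_count_ratio,
    read_peaks,
    subtract_background,
    write_peaks,
)


def _peak(chrom, start, end, fe=10.0, p=1e-5, name="pk"):
    return PeakRecord(chrom, start, end, name=name, fold_enrichment=fe, p_value=p)


def _brute_overlaps_any(peaks, targets, min_overlap=1):
    """Independent all-pairs interval-overlap oracle."""
    out = []
    for r in peaks:
        hit = any(
            t.chrom == r.chrom and min(r.end, t.end) - max(r.start, t.start) >= min_overlap
            for t in targets
        )
        out.append(hit)
    return out


def _hypergeom_tail_enumerated(o, n, big_k, k):
    """Exhaustive upper-tail hypergeometric sum via binomial coefficients."""
    denom = math.comb(n, k)
    return sum(
        math.comb(big_k, i) * math.comb(n - big_k, k - i)
        for i in range(o, min(big_k, k) + 1)
    ) / denom


class TestRecordValidation:
    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError, match="start must be"):
            PeakRecord("chr1", 100, 100)

    def test_p_value_range_enforced(self):
        with pytest.raises(ValueError, match="p_value"):
            PeakRecord("chr1", 0, 10, p_value=0.0)

    def test_peakset_sorted(self):
        ps = PeakSet([_peak("chr2", 5, 10), _peak("chr1", 50, 60), _peak("chr1", 5, 10)])
        keys = [(r.chrom, r.start) for r in ps]
        assert keys == sorted(keys)


class TestIO:
    def test_empty_file_gives_empty_set(self, tmp_path):
        f = tmp_path / "empty.narrowPeak"
        f.write_text("")
        assert len(read_peaks(f)) == 0

    def test_round_trip_identical_records(self, tmp_path):
        records = [
            _peak("chr1", 100, 300, fe=31.5, p=1e-12, name="a"),
            _peak("chr2", 50, 450, fe=8.0, p=1e-4, name="b"),
        ]
        ps = PeakSet(records)
        f = tmp_path / "rt.narrowPeak"
        write_peaks(ps, f)
        assert read_peaks(f).records == ps.records

    def test_bed6_fe_p_dialect_round_trip(self, tmp_path):
        ps = PeakSet([_peak("chr1", 10, 20, fe=42.0, p=0.125)])
        f = tmp_path / "rt.bed"
        write_peaks(ps, f, dialect="bed6+FE+P")
        got = read_peaks(f, dialect="bed6+FE+P")
        assert got.records[0].p_value == 0.125
        assert got.records[0].fold_enrichment == 42.0

    def test_neg_log10_p_convention(self, tmp_path):
        f = tmp_path / "p.narrowPeak"
        f.write_text("chr1\t0\t100\tpk\t0\t.\t12.0\t9.0\t-1\t50\n")
        assert read_peaks(f).records[0].p_value == pytest.approx(1e-9)

    def test_malformed_line_names_line_number(self, tmp_path):
        f = tmp_path / "bad.narrowPeak"
        f.write_text("chr1\t0\t100\tpk\t0\t.\t12.0\t9.0\t-1\t50\nchr1\tnope\n")
        with pytest.raises(ValueError, match=":2"):
            read_peaks(f)

    def test_invalid_interval_dropped_with_notice(self, tmp_path, caplog):
        f = tmp_path / "inv.narrowPeak"
        f.write_text(
            "chr1\t200\t100\tpk\t0\t.\t12.0\t9.0\t-1\t50\n"
            "chr1\t0\t100\tok\t0\t.\t12.0\t9.0\t-1\t50\n"
        )
        with caplog.at_level("WARNING"):
            ps = read_peaks(f)
        assert len(ps) == 1 and "dropped 1" in caplog.text


class TestSubtractBackground:
    def test_empty_igg_returns_input(self):
        sample = PeakSet([_peak("chr1", 100, 200), _peak("chr1", 300, 400)])
        assert subtract_background(sample, PeakSet([])).records == sample.records

    def test_igg_equal_sample_empties(self):
        sample = PeakSet([_peak("chr1", 100, 200)])
        assert len(subtract_background(sample, sample)) == 0

    def test_manual_interval_check(self):
        sample = PeakSet([_peak("chr1", 100, 200), _peak("chr1", 300, 400)])
        igg = PeakSet([_peak("chr1", 150, 160)])
        out = subtract_background(sample, igg)
        assert [(r.start, r.end) for r in out] == [(300, 400)]

    def test_idempotent_and_subset(self):
        sample = PeakSet([_peak("chr1", i * 1000, i * 1000 + 200) for i in range(20)])
        igg = PeakSet([_peak("chr1", 1500, 2100), _peak("chr1", 9000, 9100)])
        once = subtract_background(sample, igg)
        twice = subtract_background(once, igg)
        assert once.records == twice.records
        assert set((r.chrom, r.start) for r in once) <= set((r.chrom, r.start) for r in sample)


class TestNewPeaks:
    def test_condition_equals_control_gives_empty(self):
        ps = PeakSet([_peak("chr1", 100, 200, fe=50.0, p=1e-12)])
        assert len(new_peaks(ps, ps)) == 0

    def test_threshold_evaluation_default_config(self):
        cond = PeakSet(
            [
                _peak("chr1", 100, 200, fe=35.0, p=1e-12, name="keep"),
                _peak("chr1", 500, 600, fe=20.0, p=1e-12, name="weak_fe"),
                _peak("chr1", 900, 1000, fe=35.0, p=1e-6, name="weak_p"),
            ]
        )
        out = new_peaks(cond, PeakSet([]))
        assert [r.name for r in out] == ["keep"]

    def test_phospho_s2_config_lowers_fe_threshold(self):
        cond = PeakSet(
            [
                _peak("chr1", 100, 200, fe=35.0, p=1e-12),
                _peak("chr1", 500, 600, fe=20.0, p=1e-12),
            ]
        )
        out = new_peaks(cond, PeakSet([]), NewPeaksConfig.phospho_s2())
        assert len(out) == 2

    def test_idempotence_and_subset(self):
        rng = np.random.default_rng(0)
        cond = PeakSet(
            [
                _peak("chr1", s, s + 100, fe=float(rng.uniform(1, 60)),
                      p=float(10.0 ** -rng.uniform(3, 20)))
                for s in range(0, 20000, 500)
            ]
        )
        ctrl = PeakSet([_peak("chr1", 1000, 1100), _peak("chr1", 5000, 5050)])
        once = new_peaks(cond, ctrl)
        twice = new_peaks(once, ctrl)
        assert once.records == twice.records
        assert set(r.name for r in once) <= set(r.name for r in cond)


class TestContainmentAndRatio:
    def test_identical_sets_fully_contained(self):
        ps = PeakSet([_peak("chr1", 0, 100), _peak("chr2", 5, 50)])
        assert containment_fraction(ps, ps) == 100.0

    def test_disjoint_sets_zero(self):
        a = PeakSet([_peak("chr1", 0, 100)])
        b = PeakSet([_peak("chr1", 200, 300)])
        assert containment_fraction(a, b) == 0.0

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="empty subset"):
            containment_fraction(PeakSet([]), PeakSet([_peak("chr1", 0, 10)]))

    def test_count_ratio(self):
        a = PeakSet([_peak("chr1", i * 100, i * 100 + 50) for i in range(3)])
        b = PeakSet([_peak("chr1", i * 100, i * 100 + 50) for i in range(2)])
        assert peak_count_ratio(a, b) == pytest.approx(1.5)
        assert peak_count_ratio(a, a) == 1.0
        with pytest.raises(ValueError, match="empty"):
            peak_count_ratio(a, PeakSet([]))


class TestOverlapEngineOracle:
    def test_engine_agrees_with_brute_force_on_random_sets(self):
        # the interval engine vs an all-pairs checker, 100 random set pairs
        rng = np.random.default_rng(12345)
        for trial in range(100):
            n_a, n_b = rng.integers(1, 200, 2)
            min_ov = int(rng.integers(1, 30))

            def random_set(n):
                recs = []
                for i in range(n):
                    chrom = f"chr{rng.integers(1, 4)}"
                    start = int(rng.integers(0, 5000))
                    end = start + int(rng.integers(1, 300))
                    recs.append(_peak(chrom, start, end, name=f"p{i}"))
                return PeakSet(recs)

            a, b = random_set(int(n_a)), random_set(int(n_b))
            kept = {(r.chrom, r.start, r.end, r.name) for r in subtract_background(a, b, min_ov)}
            expect = {
                (r.chrom, r.start, r.end, r.name)
                for r, hit in zip(a, _brute_overlaps_any(a, b, min_ov))
                if not hit
            }
            assert kept == expect, f"trial {trial}"


class TestGeneAssignment:
    GENES = [
        GeneRecord("chr1", 1000, 3000, "geneA", "+"),
        GeneRecord("chr1", 5000, 8000, "geneB", "+"),
        GeneRecord("chr1", 9000, 12000, "geneC", "-"),
    ]

    def test_midpoint_on_tss(self):
        peaks = PeakSet([_peak("chr1", 900, 1100)])  # midpoint 1000 = geneA TSS
        assert assign_peaks_to_genes(peaks, self.GENES) == {"geneA"}

    def test_nearest_tss_wins(self):
        peaks = PeakSet([_peak("chr1", 1700, 1900)])  # midpoint 1800: 800 vs 3200
        assert assign_peaks_to_genes(peaks, self.GENES) == {"geneA"}

    def test_minus_strand_tss_is_interval_end(self):
        peaks = PeakSet([_peak("chr1", 11900, 12100)])  # midpoint 12000 = geneC TSS
        assert assign_peaks_to_genes(peaks, self.GENES) == {"geneC"}

    def test_empty_peakset_gives_empty_gene_set(self):
        assert assign_peaks_to_genes(PeakSet([]), self.GENES) == set()

    def test_unknown_chromosome_logged(self, caplog):
        peaks = PeakSet([_peak("chrX", 0, 100)])
        with caplog.at_level("WARNING"):
            out = assign_peaks_to_genes(peaks, self.GENES)
        assert out == set() and "absent" in caplog.text


class TestAssociationScore:
    def test_full_overlap_closed_form(self):
        # target = exactly the top-3 of 10 genes: p = 1/C(10,3) = 1/120
        ranking = [f"g{i}" for i in range(10)]
        score = association_score(ranking, ranking[:3], [3])
        assert score.p_value == pytest.approx(1 / 120)
        assert score.score == pytest.approx(math.log10(120))
        assert score.best_cutoff == 3 and score.overlap_at_best == 3

    def test_whole_ranking_cutoff_scores_zero(self):
        ranking = [f"g{i}" for i in range(10)]
        score = association_score(ranking, ranking[:3], [10])
        assert score.p_value == 1.0 and score.score == 0.0

    def test_agrees_with_exhaustive_enumeration(self):
        # sweep every (N <= 20, targets <= 6, cutoff, overlap) configuration
        for n in range(2, 21):
            genes = [f"g{i}" for i in range(n)]
            for big_k in range(1, min(6, n) + 1):
                for k in range(1, n + 1):
                    for o in range(max(0, big_k + k - n), min(big_k, k) + 1):
                        # build a ranking with exactly o targets in the top k
                        targets = genes[:o] + genes[k : k + (big_k - o)]
                        got = association_score(genes, targets, [k])
                        want = _hypergeom_tail_enumerated(o, n, big_k, k)
                        assert got.p_value == pytest.approx(want, rel=1e-9), (n, big_k, k, o)

    def test_empty_target_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            association_score(["a", "b"], [], [1])

    def test_duplicate_ranking_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            association_score(["a", "a", "b"], ["a"], [1])

    def test_score_antimonotone_in_target_enrichment(self):
        # adding a top-ranked gene to the target set never lowers the score
        ranking = [f"g{i}" for i in range(50)]
        targets = ranking[10:15]
        base = association_score(ranking, targets, [20]).score
        enriched = association_score(ranking, targets + [ranking[0]], [20]).score
        assert enriched >= base

    def test_null_calibration_monte_carlo(self):
        # random target sets: the 95th percentile of the score stays within
        # the Bonferroni band -log10(0.05/|grid|) + 1
        rng = np.random.default_rng(77)
        n, big_k = 200, 15
        ranking = [f"g{i}" for i in range(n)]
        grid = [10, 25, 50, 100]
        scores = []
        for _ in range(1000):
            targets = list(rng.choice(ranking, size=big_k, replace=False))
            scores.append(association_score(ranking, targets, grid).score)
        assert np.percentile(scores, 95) <= -math.log10(0.05 / len(grid)) + 1

    def test_natural_log_switch(self):
        ranking = [f"g{i}" for i in range(10)]
        s10 = association_score(ranking, ranking[:3], [3], log_base=10.0)
        se = association_score(ranking, ranking[:3], [3], log_base=math.e)
        assert se.score == pytest.approx(s10.score * math.log(10))
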