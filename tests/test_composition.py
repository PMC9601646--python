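"""Composition statistics: skews, codon usage, tRNA lengths, overlaps."""

import math

import pytest

from mitorearrange.composition import (
    CompositionError,
    codon_usage,
    composition,
    overlap_report,
    pcg_composition,
    trna_length_table,
)
from mitorearrange.records import FeatureSpan, MitogenomeRecord, reverse_complement
from mitorearrange.synthetic import SyntheticConfig, random_sequence, synthetic_record


class TestComposition:
    def test_symmetric_at_only_sequence(self):
        s = composition("AATT")
        assert s.at_fraction == 1.0
        assert s.at_skew == 0.0

    def test_analytic_example(self):
        s = composition("AAATGCCC")
        assert s.at_skew == pytest.approx((3 - 1) / (3 + 1))
        assert s.gc_skew == pytest.approx((1 - 3) / (1 + 3))

    def test_n_excluded_from_denominators(self):
        assert composition("AATTGGCCNN").at_fraction == pytest.approx(0.5)

    def test_empty_sequence_rejected(self):
        with pytest.raises(CompositionError, match="empty"):
            composition("")
        with pytest.raises(CompositionError, match="unambiguous"):
            composition("NNN")

    def test_degenerate_skews_identified_on_access(self):
        # a pure-GC sequence has no AT skew, and vice versa; the defined
        # statistics stay available
        gc_only = composition("GGCC")
        with pytest.raises(CompositionError, match="A\\+T"):
            gc_only.at_skew
        assert gc_only.gc_skew == 0.0
        at_only = composition("AATT" * 3)
        with pytest.raises(CompositionError, match="G\\+C"):
            at_only.gc_skew
        assert at_only.at_fraction == 1.0

    def test_rejects_non_acgtn(self):
        with pytest.raises(CompositionError, match="W"):
            composition("ACGTW")

    def test_table_row_rounding(self):
        row = composition("AAATGCCC").table_row()
        assert row == {"A+T (%)": 50.0, "AT skew": 0.5, "GC skew": -0.5}

    def test_estimates_converge_on_synthetic_sequence(self):
        # three binomial standard errors at L = 100,000 around the
        # configured targets (the typical chilopod whole-genome row)
        cfg = SyntheticConfig(seed=11)
        L = 100_000
        s = composition(random_sequence(cfg, length=L))
        p, q, r = cfg.at_fraction, cfg.at_skew, cfg.gc_skew
        assert abs(s.at_fraction - p) < 3 * math.sqrt(p * (1 - p) / L)
        assert abs(s.at_skew - q) < 3 * math.sqrt((1 - q * q) / (L * p))
        assert abs(s.gc_skew - r) < 3 * math.sqrt((1 - r * r) / (L * (1 - p)))


class TestPcgComposition:
    def test_single_majority_pcg_counts_equal_codon_string(self):
        coding = "ATGAAATAA"
        rec = MitogenomeRecord("toy", coding + "GGCC", [
            FeatureSpan("cox1", 0, 9, "+")])
        s = pcg_composition(rec)
        assert s.counts["A"] == coding.count("A")
        assert s.counts["T"] == coding.count("T")

    def test_minority_strand_pcg_gives_identical_stats(self):
        coding = "ATGAAATAA"
        fwd = MitogenomeRecord("f", coding + "GGCC", [FeatureSpan("cox1", 0, 9, "+")])
        rev = MitogenomeRecord("r", reverse_complement(coding) + "GGCC",
                               [FeatureSpan("cox1", 0, 9, "-")])
        assert pcg_composition(fwd) == pcg_composition(rev)

    def test_missing_pcgs_is_an_error(self):
        rec = MitogenomeRecord("toy", "ACGTACGT", [FeatureSpan("trnK", 0, 4, "+")])
        with pytest.raises(CompositionError, match="PCG"):
            pcg_composition(rec)


class TestCodonUsage:
    def test_start_and_stop_report(self, mini_record):
        table, report = codon_usage(mini_record)
        assert set(report["start_codon"]) == {"ATG"}
        assert report.loc["cox1", "stop_codon"] == "TAA"
        # engineered truncated stops: length % 3 == 1 -> "T", == 2 -> "TA"
        assert report.loc["nad2", "stop_codon"] == "T"
        assert report.loc["cox3", "stop_codon"] == "TA"
        assert report.loc["nad2", "incomplete_stop"]
        assert table.frequencies.sum() == pytest.approx(1.0)
        assert table.total == sum(
            length // 3 for length in report["length_nt"])

    def test_short_pcg_rejected(self):
        rec = MitogenomeRecord("toy", "ATGTAAGC", [FeatureSpan("cox1", 0, 5, "+")])
        with pytest.raises(CompositionError, match="shorter"):
            codon_usage(rec)


class TestTrnaLengths:
    def test_engineered_extremes(self, mini_record):
        df = trna_length_table(mini_record)
        assert len(df) == 22
        assert df.attrs["min"] == ("trnS1", 52)
        assert df.attrs["max"] == ("trnW", 79)

    def test_missing_trnas_flagged_not_errors(self):
        rec = MitogenomeRecord("toy", "ACGT" * 30, [
            FeatureSpan("cox1", 0, 30, "+"), FeatureSpan("trnK", 30, 90, "+")])
        df = trna_length_table(rec)
        assert df.loc["trnK", "length_bp"] == 60
        assert not df.loc["trnA", "present"]
        assert df.attrs["min"] == ("trnK", 60) == df.attrs["max"]


class TestOverlaps:
    def test_abutting_features_gap_zero_is_not_overlap(self):
        rec = MitogenomeRecord("toy", "ACGT" * 10, [
            FeatureSpan("cox1", 0, 10, "+"), FeatureSpan("trnK", 10, 20, "+")])
        df = overlap_report(rec)
        assert df.loc[0, "gap_bp"] == 0 and not df.loc[0, "overlap"]

    def test_two_base_overlap_detected(self):
        rec = MitogenomeRecord("toy", "ACGT" * 10, [
            FeatureSpan("cox1", 0, 10, "+"), FeatureSpan("trnK", 8, 20, "+")])
        df = overlap_report(rec)
        assert df.loc[0, "gap_bp"] == -2 and df.loc[0, "overlap"]

    def test_engineered_overlap_census_on_synthetic_record(self, mini_record):
        df = overlap_report(mini_record)
        assert len(df) == 38                      # wrap is an ordinary boundary
        assert df.attrs["overlap_count"] == 3
        assert df.attrs["overlap_fraction"] == pytest.approx(3 / 38)


def test_composition_invariant_under_rotation(mini_record):
    seq = mini_record.sequence
    rotated = seq[100:] + seq[:100]
    assert composition(seq) == composition(rotated)


def test_skews_antisymmetric_under_reverse_complement():
    cfg = SyntheticConfig(seed=5)
    seq = random_sequence(cfg, length=2_000)
    s, rc = composition(seq), composition(reverse_complement(seq))
    assert rc.at_skew == pytest.approx(-s.at_skew)
    assert rc.gc_skew == pytest.approx(-s.gc_skew)
    assert rc.at_fraction == pytest.approx(s.at_fraction)
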