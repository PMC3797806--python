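"""Conservation tracks: parsing, per-transcript summaries and the
conserved-base criterion (score >= 0.5, boundary inclusive)."""

import numpy as np
import pytest

from lncvsd.conservation import (
    ConservationTrack,
    category_median,
    conservation_filter,
    read_elements_bed,
    read_track,
    summarize_transcript,
    write_track,
)
from lncvsd.genomic_context import ClassifiedLncRNA, TranscriptModel
from lncvsd.synthetic import SimulationConfig, generate_annotation, generate_conservation_track

from _oracles import brute_force_conserved_fraction


def lnc(tid, start, end, chrom="chr1"):
    return TranscriptModel(tid, chrom, "+", start, end, ((start, end),), "lncRNA")


class TestTrackIO:
    def test_fixedstep_one_based_conversion(self, tmp_path):
        p = tmp_path / "t.wig"
        p.write_text("fixedStep chrom=chr1 start=1 step=1\n0.1\n0.9\n")
        track = read_track(str(p), "fixedStep_wig")
        pos, sc = track.data["chr1"]
        assert list(pos) == [0, 1] and list(sc) == [0.1, 0.9]

    def test_step_and_span(self, tmp_path):
        p = tmp_path / "t.wig"
        p.write_text("fixedStep chrom=chr1 start=11 step=5 span=2\n0.4\n0.6\n")
        track = read_track(str(p), "fixedStep_wig")
        pos, sc = track.data["chr1"]
        assert list(pos) == [10, 11, 15, 16]
        assert list(sc) == [0.4, 0.4, 0.6, 0.6]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "t.wig"
        p.write_text("")
        assert read_track(str(p), "fixedStep_wig").n_covered() == 0

    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(3)
        pos = np.sort(rng.choice(10_000, size=500, replace=False))
        sc = rng.uniform(0, 1, 500)
        track = ConservationTrack({"chr1": (pos, sc)})
        path = tmp_path / "out.wig"
        write_track(track, str(path))
        back = read_track(str(path), "fixedStep_wig")
        assert np.array_equal(back.data["chr1"][0], pos)
        assert np.allclose(back.data["chr1"][1], sc, atol=5e-7)

    def test_bedgraph(self, tmp_path):
        p = tmp_path / "t.bg"
        p.write_text("chr1\t0\t3\t0.25\nchr1\t5\t6\t0.75\n")
        track = read_track(str(p), "bedGraph")
        pos, sc = track.data["chr1"]
        assert list(pos) == [0, 1, 2, 5]
        assert list(sc) == [0.25, 0.25, 0.25, 0.75]

    def test_malformed_header_reports_line(self, tmp_path):
        p = tmp_path / "t.wig"
        p.write_text("fixedStep chrom=chr1\n0.5\n")
        with pytest.raises(ValueError, match=":1"):
            read_track(str(p), "fixedStep_wig")

    def test_score_out_of_range_rejected(self, tmp_path):
        p = tmp_path / "t.wig"
        p.write_text("fixedStep chrom=chr1 start=1 step=1\n1.5\n")
        with pytest.raises(ValueError, match="outside"):
            read_track(str(p), "fixedStep_wig")


class TestSummaries:
    def test_uniform_score(self):
        t = lnc("x", 10, 20)
        track = ConservationTrack({"chr1": (np.arange(10, 20), np.full(10, 0.7))})
        s = summarize_transcript(t, track)
        assert s.n_bases_covered == 10
        assert s.median_score == pytest.approx(0.7)
        assert s.conserved_fraction == 1.0

    def test_boundary_score_half_counts_conserved(self):
        t = lnc("x", 0, 5)
        track = ConservationTrack({"chr1": (np.arange(5), np.full(5, 0.5))})
        assert summarize_transcript(t, track).conserved_fraction == 1.0

    def test_uncovered_bases_excluded_from_denominator(self):
        t = lnc("x", 0, 10)
        track = ConservationTrack({"chr1": (np.arange(4), np.array([0.9, 0.9, 0.1, 0.1]))})
        s = summarize_transcript(t, track)
        assert s.n_bases_covered == 4
        assert s.conserved_fraction == 0.5

    def test_zero_coverage_flagged(self):
        s = summarize_transcript(lnc("x", 0, 10), ConservationTrack())
        assert s.n_bases_covered == 0 and s.median_score is None

    def test_exonic_bases_only(self):
        t = TranscriptModel("x", "chr1", "+", 0, 100, ((0, 10), (90, 100)), "lncRNA")
        pos = np.arange(100)
        sc = np.where(pos < 50, 0.9, 0.1)  # intron [10,90) mostly high
        s = summarize_transcript(t, ConservationTrack({"chr1": (pos, sc)}))
        assert s.n_bases_covered == 20
        assert s.conserved_fraction == 0.5

    def test_element_overlap_flag(self, tmp_path):
        bed = tmp_path / "e.bed"
        bed.write_text("chr1\t5\t8\n")
        elements = read_elements_bed(str(bed))
        track = ConservationTrack({"chr1": (np.arange(20), np.full(20, 0.2))})
        assert summarize_transcript(lnc("x", 0, 10), track, elements).overlaps_conserved_element
        assert not summarize_transcript(lnc("y", 10, 20), track, elements).overlaps_conserved_element

    def test_invariant_under_block_split(self, tmp_path):
        one = tmp_path / "one.wig"
        two = tmp_path / "two.wig"
        one.write_text("fixedStep chrom=chr1 start=1 step=1\n0.6\n0.7\n0.8\n0.4\n")
        two.write_text("fixedStep chrom=chr1 start=1 step=1\n0.6\n0.7\n"
                       "fixedStep chrom=chr1 start=3 step=1\n0.8\n0.4\n")
        t = lnc("x", 0, 4)
        s1 = summarize_transcript(t, read_track(str(one)))
        s2 = summarize_transcript(t, read_track(str(two)))
        assert (s1.n_bases_covered, s1.median_score, s1.conserved_fraction) == \
            (s2.n_bases_covered, s2.median_score, s2.conserved_fraction)

    def test_planted_fraction_matches_wig_oracle(self, tmp_path):
        config = SimulationConfig(seed=7, n_coding_genes=12, n_lncrna_per_class=2,
                                  conserved_element_density=1.0)
        annotation, truth = generate_annotation(config)
        track, _, truth = generate_conservation_track(config, annotation, truth)
        wig = tmp_path / "phast.wig"
        write_track(track, str(wig))
        checked = 0
        for t in annotation:
            if t.biotype != "lncRNA":
                continue
            covered, frac = brute_force_conserved_fraction(t, str(wig))
            assert covered == t.exonic_length
            assert frac == pytest.approx(truth.true_conserved_fraction[t.id], abs=1e-12)
            s = summarize_transcript(t, track)
            assert s.conserved_fraction == pytest.approx(frac, abs=1e-12)
            checked += 1
        assert checked == 12


class TestCategoryMedian:
    def _summary(self, tid, median):
        track = ConservationTrack({"chr1": (np.arange(3), np.full(3, median))})
        return summarize_transcript(lnc(tid, 0, 3), track)

    def test_median_of_medians(self):
        summaries = [self._summary("a", 0.1), self._summary("b", 0.2), self._summary("c", 0.9)]
        classified = [ClassifiedLncRNA(i, "intergenic", None, None) for i in "abc"]
        out = category_median(summaries, classified)
        assert out["intergenic"] == pytest.approx(0.2)

    def test_empty_class_is_none(self):
        classified = [ClassifiedLncRNA("a", "bidirectional", "g", 10)]
        s = summarize_transcript(lnc("a", 0, 10), ConservationTrack())  # no coverage
        assert category_median([s], classified)["bidirectional"] is None

    def test_bounded_by_member_range(self):
        rng = np.random.default_rng(4)
        meds = rng.uniform(0, 1, 9)
        summaries = [self._summary(f"t{i}", m) for i, m in enumerate(meds)]
        classified = [ClassifiedLncRNA(f"t{i}", "intergenic" if i < 5 else "bidirectional",
                                       None, None) for i in range(9)]
        out = category_median(summaries, classified)
        assert meds[:5].min() <= out["intergenic"] <= meds[:5].max()
        assert meds[5:].min() <= out["bidirectional"] <= meds[5:].max()


class TestConservationFilter:
    def _mixture(self):
        hi = [self._s(f"hi{i}", 0.9) for i in range(3)]
        lo = [self._s(f"lo{i}", 0.1) for i in range(3)]
        return hi + lo

    def _s(self, tid, score):
        track = ConservationTrack({"chr1": (np.arange(4), np.full(4, score))})
        return summarize_transcript(lnc(tid, 0, 4), track)

    def test_threshold_zero_is_identity(self):
        summaries = self._mixture()
        ids = [s.transcript_id for s in summaries]
        assert conservation_filter(ids, summaries, 0.0) == ids

    def test_mixture_split_at_half(self):
        summaries = self._mixture()
        ids = [s.transcript_id for s in summaries]
        assert conservation_filter(ids, summaries, 0.5) == ["hi0", "hi1", "hi2"]

    def test_monotone_in_threshold(self):
        summaries = self._mixture()
        ids = [s.transcript_id for s in summaries]
        prev = ids
        for thr in (0.0, 0.3, 0.6, 1.0):
            kept = conservation_filter(ids, summaries, thr)
            assert set(kept) <= set(prev)
            prev = kept

    def test_missing_summary_names_candidate(self):
        with pytest.raises(KeyError, match="ghost"):
            conservation_filter(["ghost"], self._mixture(), 0.1)
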