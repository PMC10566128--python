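import numpy as np
import pandas as pd
import pytest

from scfrag import (
    ElementAnnotation,
    GenomeModel,
    PeakSet,
    SampleFragments,
    annotate_peaks,
    element_coverage_profile,
    load_narrowpeak,
    observed_expected,
    peaks_per_read,
)


@pytest.fixture()
def small_genome():
    return GenomeModel({"chr1": 1_000_000}, bin_size=1_000_000)


def _peakset(rows):
    return PeakSet(pd.DataFrame(rows, columns=["contig", "start", "end"]), "p")


class TestLoadNarrowpeak:
    def test_ten_column_format(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr1\t100\t300\tpeak1\t500\t.\t4.5\t10.0\t8.0\t75\n")
        ps = load_narrowpeak(p)
        assert ps.n_peaks == 1
        assert ps.peaks.iloc[0]["summit"] == 75
        assert ps.midpoints[0] == 200

    def test_bed3_accepted(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t10\nchr1\t50\t80\n")
        assert load_narrowpeak(p).n_peaks == 2


class TestAnnotatePeaks:
    def test_priority_promoter_over_intron(self, small_genome):
        ann = ElementAnnotation.from_intervals(
            {"promoter": [("chr1", 100, 300, "GENE1")],
             "intron": [("chr1", 0, 1000, "GENE1")]},
            small_genome,
        )
        counts, per_gene = annotate_peaks(_peakset([("chr1", 150, 250)]), ann)
        assert counts["promoter"] == 1 and counts["intron"] == 0

    def test_no_overlap_is_intergenic(self, small_genome):
        ann = ElementAnnotation.from_intervals(
            {"exon": [("chr1", 0, 100, "G")]}, small_genome
        )
        counts, _ = annotate_peaks(_peakset([("chr1", 5000, 5100)]), ann)
        assert counts["intergenic"] == 1

    def test_midpoint_rule(self, small_genome):
        # peak overlaps the exon but its midpoint lies outside
        ann = ElementAnnotation.from_intervals(
            {"exon": [("chr1", 0, 100, "G")]}, small_genome
        )
        counts, _ = annotate_peaks(_peakset([("chr1", 90, 400)]), ann)
        assert counts["intergenic"] == 1

    def test_every_peak_assigned_once(self, small_genome, rng):
        ann = ElementAnnotation.from_intervals(
            {"promoter": [("chr1", 1000, 3000, "A")],
             "exon": [("chr1", 10_000, 20_000, "B")],
             "intron": [("chr1", 20_000, 40_000, "B")]},
            small_genome,
        )
        starts = rng.integers(0, 900_000, size=200)
        ps = _peakset([("chr1", int(s), int(s) + 200) for s in starts])
        counts, _ = annotate_peaks(ps, ann)
        assert counts.sum() == ps.n_peaks

    def test_planted_labels_recovered(self, small_genome, rng):
        regions = {
            "promoter": (0, 100_000),
            "exon": (200_000, 300_000),
            "intron": (400_000, 500_000),
        }
        ann = ElementAnnotation.from_intervals(
            {cat: [("chr1", lo, hi, f"G_{cat}")] for cat, (lo, hi) in regions.items()},
            small_genome,
        )
        rows, labels = [], []
        for cat, (lo, hi) in regions.items():
            for _ in range(30):
                mid = int(rng.integers(lo + 500, hi - 500))
                rows.append(("chr1", mid - 100, mid + 100))
                labels.append(cat)
        for _ in range(10):
            mid = int(rng.integers(700_000, 990_000))
            rows.append(("chr1", mid - 100, mid + 100))
            labels.append("intergenic")
        counts, per_gene = annotate_peaks(_peakset(rows), ann)
        expected = pd.Series(labels).value_counts()
        for cat in expected.index:
            assert counts[cat] == expected[cat]

    def test_contig_mismatch_errors(self, small_genome):
        ann = ElementAnnotation.from_intervals(
            {"exon": [("chr1", 0, 100, "G")]}, small_genome
        )
        with pytest.raises(ValueError, match="chr9"):
            annotate_peaks(_peakset([("chr9", 0, 100)]), ann)


class TestPeaksPerRead:
    def test_zero_peaks(self):
        s = SampleFragments("s", ["chr1"], [0], [100])
        empty = PeakSet(pd.DataFrame(columns=["contig", "start", "end"]))
        assert peaks_per_read(empty, s) == 0.0

    def test_ratio_and_homogeneity(self):
        n = 10_000
        s = SampleFragments("s", ["chr1"] * n, np.arange(n), np.arange(n) + 100)
        ps = _peakset([("chr1", i * 100, i * 100 + 50) for i in range(20)])
        assert peaks_per_read(ps, s) == pytest.approx(0.002)
        s2 = SampleFragments("s", ["chr1"] * (2 * n), np.arange(2 * n),
                             np.arange(2 * n) + 100)
        ps2 = _peakset([("chr1", i * 100, i * 100 + 50) for i in range(40)])
        assert peaks_per_read(ps2, s2) == pytest.approx(0.002)


class TestObservedExpected:
    def test_proportional_counts_give_unit_ratios(self, small_genome):
        ann = ElementAnnotation.from_intervals(
            {"exon": [("chr1", 0, 250_000, "G")],
             "intron": [("chr1", 250_000, 1_000_000, "G")]},
            small_genome,
        )
        counts = pd.Series({"exon": 25, "intron": 75, "intergenic": 0,
                            "promoter": 0, "5UTR": 0, "3UTR": 0, "TTS": 0})
        oe = observed_expected(counts, ann)
        assert oe["exon"] == pytest.approx(1.0)
        assert oe["intron"] == pytest.approx(1.0)

    def test_zero_fraction_flagged_nan(self, small_genome):
        ann = ElementAnnotation.from_intervals(
            {"exon": [("chr1", 0, 1_000_000, "G")]}, small_genome
        )
        counts = pd.Series({"exon": 5, "promoter": 1})
        oe = observed_expected(counts, ann)
        assert np.isnan(oe["promoter"])

    def test_fraction_weighted_mean_is_one(self, small_genome, rng):
        ann = ElementAnnotation.from_intervals(
            {"exon": [("chr1", 0, 300_000, "G")],
             "intron": [("chr1", 300_000, 800_000, "G")]},
            small_genome,
        )
        counts = pd.Series({"exon": int(rng.integers(1, 50)),
                            "intron": int(rng.integers(1, 50)),
                            "intergenic": int(rng.integers(1, 50))})
        oe = observed_expected(counts, ann)
        total = sum(
            oe[c] * ann.genome_fraction[c]
            for c in oe.index
            if not np.isnan(oe[c])
        )
        assert total == pytest.approx(1.0)

    def test_planted_promoter_enrichment_recovered(self, small_genome, rng):
        # promoters occupy 10% of the genome but receive 30% of peaks → O/E ≈ 3
        ann = ElementAnnotation.from_intervals(
            {"promoter": [("chr1", 0, 100_000, "G")]}, small_genome
        )
        n = 3000
        in_prom = rng.random(n) < 0.3
        mids = np.where(
            in_prom,
            rng.integers(500, 99_500, size=n),
            rng.integers(100_500, 999_000, size=n),
        )
        ps = _peakset([("chr1", int(m) - 50, int(m) + 50) for m in mids])
        counts, _ = annotate_peaks(ps, ann)
        oe = observed_expected(counts, ann)
        sigma = 3.0 * np.sqrt((1 - 0.3) / (n * 0.3))
        assert abs(oe["promoter"] - 3.0) <= 3 * sigma


class TestElementCoverageProfile:
    def test_uniform_coverage_gives_flat_unit_profile(self):
        # fragments tile chr1 densely and evenly
        starts = np.arange(0, 100_000, 10)
        s = SampleFragments("s", ["chr1"] * len(starts), starts, starts + 100)
        prof = element_coverage_profile(s, [("chr1", 50_000)], flank=500)
        assert prof["relative_coverage"].mean() == pytest.approx(1.0, abs=1e-9)
        assert prof["relative_coverage"].std() < 0.05

    def test_support_bound(self):
        # fragments only within ±10 bp of the center
        center = 5_000
        starts = np.arange(center - 10, center + 10)
        s = SampleFragments("s", ["chr1"] * len(starts), starts, starts + 30)
        prof = element_coverage_profile(s, [("chr1", center)], flank=200)
        rc = prof.set_index("offset")["relative_coverage"]
        # support is [center-10, center+10+30): max inside, zero beyond
        assert rc.idxmax() in range(-10, 40)
        assert (rc.loc[45:] == 0).all()  # beyond ±(10 + max length)
        assert (rc.loc[:-45] == 0).all()

    def test_planted_dip_recovered(self, rng):
        # deplete coverage in a 100 bp window around the centers
        starts = []
        for s0 in range(0, 200_000, 25):
            if 99_800 <= s0 <= 100_100:
                continue
            starts.append(s0)
        arr = np.array(starts)
        s = SampleFragments("s", ["chr1"] * len(arr), arr, arr + 50)
        prof = element_coverage_profile(s, [("chr1", 100_000)], flank=1000)
        rc = prof.set_index("offset")["relative_coverage"]
        assert rc.loc[-20:20].mean() < 0.5 * rc.loc[500:900].mean()

    def test_no_centers_errors(self):
        s = SampleFragments("s", ["chr1"], [0], [100])
        with pytest.raises(ValueError):
            element_coverage_profile(s, [], flank=100)

    def test_no_coverage_errors(self):
        s = SampleFragments("s", ["chr1"], [0], [100])
        with pytest.raises(ValueError):
            element_coverage_profile(s, [("chr5", 1_000_000)], flank=100)


def test_gene_bed12_annotation_builds_all_categories(tmp_path, small_genome):
    # one 2-exon gene on + strand: UTRs from thick limits, intron between blocks
    bed12 = (
        "chr1\t10000\t20000\tGENE1\t0\t+\t11000\t19000\t0\t2\t3000,3000\t0,7000\n"
    )
    p = tmp_path / "genes.bed"
    p.write_text(bed12)
    ann = ElementAnnotation.from_gene_bed12(p, small_genome, promoter_flank=1000)
    assert ann.intervals["promoter"]["chr1"]
    assert ann.intervals["exon"]["chr1"]
    assert ann.intervals["intron"]["chr1"]
    assert ann.intervals["5UTR"]["chr1"]
    assert ann.intervals["3UTR"]["chr1"]
    # 5'UTR of a + gene precedes thickStart
    utr5 = sorted(ann.intervals["5UTR"]["chr1"])[0]
    assert utr5.begin == 10000 and utr5.end == 11000
    counts, _ = annotate_peaks(_peakset([("chr1", 8_900, 9_300)]), ann)
    assert counts["promoter"] == 1
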