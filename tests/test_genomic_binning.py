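"""TSS/isoform selection, locus zone partitioning, fragment classification."""

import numpy as np
import pytest

from crmscreen.genomic_binning import (
    BINS,
    DISTAL,
    INTRON1,
    PROXIMAL,
    BinCounts,
    ExpressionEvidence,
    FragmentRecord,
    GeneModel,
    classify_fragment,
    fragment_size_stats,
    locus_zones,
    select_tss_isoform,
    tally_bins,
)


def ev(**flags):
    return ExpressionEvidence(
        {
            iso: {"early": bool(v), "mid": bool(v), "late": bool(v)}
            for iso, v in flags.items()
        }
    )


@pytest.fixture
def plus_gene():
    # exon1=[1000,1200), exon2=[5000,5400): tss=1000, b1=1200, b2=5000
    return GeneModel("gA", "chr1", "+", {"gA.RA": ((1000, 1200), (5000, 5400))})


@pytest.fixture
def minus_gene():
    # 5'-most exon [8000,8200), exon2 [4000,4300): tss=8200, b1=8000, b2=4300
    return GeneModel("gB", "chr1", "-", {"gB.RA": ((4000, 4300), (8000, 8200))})


class TestTssSelection:
    def test_unexpressed_decoy_skipped(self):
        # decoy RC has larger span and a distinct first exon but no evidence
        model = GeneModel(
            "ana",
            "chr1",
            "+",
            {
                "ana.RA": ((2000, 2200), (6000, 6500)),
                "ana.RC": ((500, 700), (6000, 6500)),
            },
        )
        iso, tss = select_tss_isoform(model, ev(**{"ana.RA": 1, "ana.RC": 0}))
        assert iso == "ana.RA"
        assert tss == 2000

    def test_single_expressed_isoform_own_5prime(self, plus_gene):
        iso, tss = select_tss_isoform(plus_gene, ev(**{"gA.RA": 1}))
        assert (iso, tss) == ("gA.RA", 1000)

    def test_longest_span_wins(self):
        model = GeneModel(
            "g",
            "chr1",
            "+",
            {
                "g.R5": ((1000, 1500), (5500, 6000)),  # span 5 kb
                "g.R3": ((2000, 2500), (4500, 5000)),  # span 3 kb
            },
        )
        iso, tss = select_tss_isoform(model, ev(**{"g.R5": 1, "g.R3": 1}))
        assert (iso, tss) == ("g.R5", 1000)

    def test_minus_strand_tss_is_rightmost(self, minus_gene):
        iso, tss = select_tss_isoform(minus_gene, ev(**{"gB.RA": 1}))
        assert tss == 8200

    def test_no_expressed_isoform_errors_with_override_hint(self, plus_gene):
        with pytest.raises(ValueError, match="override"):
            select_tss_isoform(plus_gene, ev(**{"gA.RA": 0}))
        iso, tss = select_tss_isoform(plus_gene, ev(**{"gA.RA": 0}), override="gA.RA")
        assert tss == 1000

    def test_invariant_to_isoform_listing_order(self):
        isoA = ((1000, 1500), (5500, 6000))
        isoB = ((2000, 2500), (4500, 5000))
        m1 = GeneModel("g", "chr1", "+", {"g.RA": isoA, "g.RB": isoB})
        m2 = GeneModel("g", "chr1", "+", {"g.RB": isoB, "g.RA": isoA})
        e = ev(**{"g.RA": 1, "g.RB": 1})
        assert select_tss_isoform(m1, e) == select_tss_isoform(m2, e)


class TestLocusZones:
    def test_plus_strand_boundaries(self, plus_gene):
        z = locus_zones(plus_gene, "gA.RA")
        assert (z.tss, z.b1, z.b2, z.has_intron1) == (1000, 1200, 5000, True)

    def test_minus_strand_boundaries(self, minus_gene):
        z = locus_zones(minus_gene, "gB.RA")
        assert (z.tss, z.b1, z.b2, z.has_intron1) == (8200, 8000, 4300, True)
        # oriented order tss <= b1 <= b2 holds on the gene axis
        assert z.oriented(z.tss) <= z.oriented(z.b1) <= z.oriented(z.b2)

    def test_single_exon_no_intron1(self):
        m = GeneModel("g", "chr1", "+", {"g.RA": ((1000, 2000),)})
        assert not locus_zones(m, "g.RA").has_intron1

    def test_short_first_intron_excluded(self):
        m = GeneModel("g", "chr1", "+", {"g.RA": ((1000, 1200), (1400, 1800))})
        assert not locus_zones(m, "g.RA").has_intron1  # 200 bp < 300 bp
        assert locus_zones(m, "g.RA", min_intron_bp=150).has_intron1


def frag(start, end, chrom="chr1", gene="gA"):
    return FragmentRecord(f"f_{start}_{end}", f"L_{start}", chrom, start, end, gene)


class TestClassify:
    def test_fragment_downstream_of_exon2_is_distal(self, plus_gene):
        z = locus_zones(plus_gene, "gA.RA")
        assert classify_fragment(frag(6000, 9000), z) == DISTAL

    def test_fragment_upstream_of_tss_is_proximal(self, plus_gene):
        z = locus_zones(plus_gene, "gA.RA")
        assert classify_fragment(frag(0, 900), z) == PROXIMAL

    def test_straddling_fragment_by_midpoint(self, plus_gene):
        z = locus_zones(plus_gene, "gA.RA")
        # [1100,5100) spans exon1 + intron1; midpoint 3100 in [1200,5000)
        assert classify_fragment(frag(1100, 5100), z) == INTRON1

    def test_minus_strand_mirror(self, minus_gene):
        z = locus_zones(minus_gene, "gB.RA")
        assert classify_fragment(frag(8300, 9000), z) == PROXIMAL
        assert classify_fragment(frag(5000, 7000), z) == INTRON1
        assert classify_fragment(frag(1000, 4000), z) == DISTAL

    def test_no_intron1_midpoints_split_proximal_distal(self):
        m = GeneModel("g", "chr1", "+", {"g.RA": ((1000, 2000),)}, )
        z = locus_zones(m, "g.RA")
        assert classify_fragment(frag(0, 1000, gene="g"), z) == PROXIMAL
        assert classify_fragment(frag(2500, 5000, gene="g"), z) == DISTAL

    def test_wrong_chrom_errors(self, plus_gene):
        z = locus_zones(plus_gene, "gA.RA")
        with pytest.raises(ValueError):
            classify_fragment(frag(0, 900, chrom="chr2"), z)

    def test_zero_length_fragment_rejected(self):
        with pytest.raises(ValueError):
            FragmentRecord("f", "L", "chr1", 100, 100, "g")

    def test_strand_reflection_invariance(self, plus_gene):
        """Mirroring the whole locus (x -> C-x, strand flip) keeps bins."""
        C = 100_000
        z_plus = locus_zones(plus_gene, "gA.RA")
        mirrored = GeneModel(
            "gA",
            "chr1",
            "-",
            {"gA.RA": tuple((C - b, C - a) for a, b in plus_gene.isoforms["gA.RA"])},
        )
        z_minus = locus_zones(mirrored, "gA.RA")
        rng = np.random.default_rng(7)
        for _ in range(200):
            s = int(rng.integers(0, 9_000))
            e = s + int(rng.integers(100, 4_000))
            b_plus = classify_fragment(frag(s, e), z_plus)
            b_minus = classify_fragment(frag(C - e, C - s), z_minus)
            assert b_plus == b_minus

    def test_midpoint_agrees_with_per_base_majority_on_contained(self, plus_gene):
        """Brute-force oracle: classify each base, take the majority."""
        z = locus_zones(plus_gene, "gA.RA")

        def per_base_zone(pos):
            if pos < 1200:
                return PROXIMAL
            if pos < 5000:
                return INTRON1
            return DISTAL

        rng = np.random.default_rng(11)
        checked = 0
        for _ in range(300):
            s = int(rng.integers(0, 9_000))
            e = s + int(rng.integers(50, 2_000))
            zones = {per_base_zone(p) for p in range(s, e)}
            if len(zones) != 1:
                continue  # not cleanly contained
            assert classify_fragment(frag(s, e), z) == zones.pop()
            checked += 1
        assert checked > 50


class TestTally:
    def test_published_counts_fixture(self):
        from crmscreen.simulate import paper_fixture

        counts = paper_fixture().bin_counts
        tot, pos = counts.as_vectors()
        assert tot.tolist() == [140, 72, 69]
        assert pos.tolist() == [23, 22, 9]
        assert (counts.N, counts.K) == (281, 54)

    def test_empty_input_all_zero(self):
        counts = tally_bins([])
        assert counts.N == 0 and counts.K == 0

    def test_hand_count(self, plus_gene):
        z = locus_zones(plus_gene, "gA.RA")
        frags = [frag(0, 900), frag(1300, 4900), frag(6000, 9000)]
        for f in frags:
            classify_fragment(f, z)
        frags[1].gfp_positive = True
        counts = tally_bins(frags)
        tot, pos = counts.as_vectors()
        assert tot.tolist() == [1, 1, 1]
        assert pos.tolist() == [0, 1, 0]

    def test_unclassified_fragment_errors(self):
        with pytest.raises(ValueError, match="not yet classified"):
            tally_bins([frag(0, 900)])

    def test_partition_totals_conserved(self, plus_gene):
        z = locus_zones(plus_gene, "gA.RA")
        rng = np.random.default_rng(3)
        frags = []
        for _ in range(500):
            s = int(rng.integers(0, 9_000))
            frags.append(frag(s, s + int(rng.integers(100, 4_000))))
        for f in frags:
            classify_fragment(f, z)
        counts = tally_bins(frags)
        assert counts.N == 500
        assert all(f.bin in BINS for f in frags)


class TestSizeStats:
    def _classified(self, sizes_by_bin):
        out = []
        for b, sizes in sizes_by_bin.items():
            for i, s in enumerate(sizes):
                f = FragmentRecord(f"{b}_{i}", "L", "chr1", 0, s, "g")
                f.bin = b
                out.append(f)
        return out

    def test_constant_sizes(self):
        frags = self._classified({b: [3000, 3000] for b in BINS})
        st = fragment_size_stats(frags)
        for b in BINS:
            assert st.mean_kb[b] == pytest.approx(3.0)
            assert st.se_kb[b] == 0.0
        for p in st.pairwise_p.values():
            assert np.isnan(p) or p == pytest.approx(1.0)

    def test_closed_form_se(self):
        st = fragment_size_stats(self._classified({PROXIMAL: [2000, 4000]}))
        assert st.mean_kb[PROXIMAL] == pytest.approx(3.0)
        # sd/sqrt(n) with sample sd: sd=sqrt(2), se=1
        assert st.se_kb[PROXIMAL] == pytest.approx(1.0)

    def test_identical_bins_p_near_one(self):
        st = fragment_size_stats(
            self._classified({PROXIMAL: [2000, 3000, 4000], INTRON1: [2000, 3000, 4000]})
        )
        assert st.pairwise_p[(PROXIMAL, INTRON1)] == pytest.approx(1.0)

    def test_small_bin_skipped_with_warning(self):
        frags = self._classified({PROXIMAL: [2000, 3000], INTRON1: [2500]})
        with pytest.warns(UserWarning):
            st = fragment_size_stats(frags)
        assert np.isnan(st.pairwise_p[(PROXIMAL, INTRON1)])


def test_bincounts_validates_positives():
    with pytest.raises(ValueError):
        BinCounts({PROXIMAL: 5}, {PROXIMAL: 6})
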