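import numpy as np
import pytest

from regevo.intervals import GenomicInterval
from regevo.regulome import (
    Regulome,
    RegulatoryRegion,
    assign_nearest_gene,
    associate_enhancers,
    call_regulatory_regions,
    cross_tissue_classify,
    merge_reproducible_peaks,
)
from oracles import classify_brute_force, cross_tissue_brute_force


def iv(start, end, seq="chr1"):
    return GenomicInterval(seq, start, end)


def spans(regions):
    return {(r.interval.start, r.interval.end) for r in regions}


class TestReproduciblePeaks:
    def test_reciprocal_half_overlap_merges_to_union_span(self):
        # 50/100 of each peak: reciprocal rule satisfied both ways
        out = merge_reproducible_peaks([[iv(100, 200)], [iv(150, 250)]])
        assert out == [iv(100, 250)]

    def test_sub_threshold_overlap_discards_both(self):
        # 10/100 and 10/110: neither reaches half its own length
        out = merge_reproducible_peaks([[iv(100, 200)], [iv(190, 300)]])
        assert out == []

    def test_identical_peak_in_three_replicates(self):
        out = merge_reproducible_peaks([[iv(5, 55)]] * 3)
        assert out == [iv(5, 55)]

    def test_one_sided_half_overlap_is_not_enough(self):
        # small peak inside large: 100% of small, 20% of large
        out = merge_reproducible_peaks([[iv(0, 500)], [iv(0, 100)]])
        assert out == []

    def test_requires_min_replicate_lists(self):
        with pytest.raises(ValueError, match="replicate"):
            merge_reproducible_peaks([[iv(0, 10)]])

    def test_peak_without_partner_in_other_replicate_dropped(self):
        out = merge_reproducible_peaks(
            [[iv(100, 200), iv(1000, 1100)], [iv(100, 200)]]
        )
        assert out == [iv(100, 200)]


class TestSignatureCalling:
    def test_promoter_consumes_acetylation_block(self):
        """K4me3+K27ac make an AP; the overlapped K27ac cannot seed an AE and
        a K4me1 touching raw K27ac cannot become a PE."""
        regions, unclassified = call_regulatory_regions(
            [iv(100, 300)], [iv(150, 400)], [iv(350, 500)], "sp", "liver"
        )
        assert spans(regions["AP"]) == {(100, 300)}
        assert regions["AE"] == [] and regions["PE"] == []
        assert {(x.start, x.end) for x in unclassified} == {(350, 500)}

    def test_active_enhancer_without_promoter(self):
        regions, _ = call_regulatory_regions(
            [], [iv(0, 100)], [iv(40, 200)], "sp", "liver"
        )
        assert spans(regions["AE"]) == {(0, 100)}
        assert regions["PE"] == []

    def test_lone_k4me1_is_primed(self):
        regions, _ = call_regulatory_regions([], [], [iv(0, 100)], "sp", "liver")
        assert spans(regions["PE"]) == {(0, 100)}

    def test_k4me3_below_half_coverage_not_promoter(self):
        regions, unclassified = call_regulatory_regions(
            [iv(0, 100)], [iv(80, 300)], [], "sp", "liver"
        )
        assert regions["AP"] == []
        assert (0, 100) in {(x.start, x.end) for x in unclassified}

    def test_ae_overlap_subject_flag_switches_side(self):
        # overlap 60 bases: 60/200 of K27ac (<50%) but 60/80 of K4me1 (>=50%)
        k27, k41 = [iv(0, 200)], [iv(140, 220)]
        default, _ = call_regulatory_regions([], k27, k41, "sp", "liver")
        flipped, _ = call_regulatory_regions(
            [], k27, k41, "sp", "liver", ae_overlap_subject="k4me1"
        )
        assert default["AE"] == []
        assert spans(flipped["AE"]) == {(0, 200)}

    def test_matches_per_base_brute_force_on_random_toys(self):
        """Interval-based calling equals the per-base oracle on 100 kb toys."""
        length = 30_000
        for seed in range(20):
            rng = np.random.default_rng(seed)

            def peaks(n_lo, n_hi):
                out = []
                for _ in range(int(rng.integers(n_lo, n_hi))):
                    s = int(rng.integers(0, length - 900))
                    out.append(iv(s, s + int(rng.integers(100, 800))))
                return out

            k3, kac, k1 = peaks(5, 20), peaks(5, 25), peaks(5, 25)
            regions, _ = call_regulatory_regions(k3, kac, k1, "sp", "liver")
            ap, ae, pe = classify_brute_force(k3, kac, k1, length)
            assert spans(regions["AP"]) == ap
            assert spans(regions["AE"]) == ae
            assert spans(regions["PE"]) == pe

    def test_no_base_in_two_signature_sets(self):
        rng = np.random.default_rng(42)
        length = 20_000
        mk = lambda n: [
            iv(int(s), int(s) + int(l))
            for s, l in zip(
                rng.integers(0, length - 600, n), rng.integers(100, 500, n)
            )
        ]
        regions, _ = call_regulatory_regions(mk(15), mk(20), mk(20), "sp", "t")
        cov = np.zeros(length, dtype=int)
        for sig in ("AP", "AE", "PE"):
            mask = np.zeros(length, dtype=bool)
            for r in regions[sig]:
                mask[r.interval.start : r.interval.end] = True
            cov += mask
        assert cov.max() <= 1

    def test_invariant_to_input_ordering(self):
        rng = np.random.default_rng(3)
        mk = lambda n: [
            iv(int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 9000, n), rng.integers(100, 500, n))
        ]
        k3, kac, k1 = mk(8), mk(10), mk(10)
        a, _ = call_regulatory_regions(k3, kac, k1, "sp", "t")
        b, _ = call_regulatory_regions(k3[::-1], kac[::-1], k1[::-1], "sp", "t")
        for sig in ("AP", "AE", "PE"):
            assert spans(a[sig]) == spans(b[sig])


def build_regulome_from(spec):
    """spec: dict tissue -> list of (signature, interval)."""
    reg = Regulome(species="sp")
    for tissue, lst in spec.items():
        per_sig = {"AP": [], "AE": [], "PE": []}
        for sig, interval in lst:
            per_sig[sig].append(RegulatoryRegion(interval, sig, "sp", tissue))
        reg.add_tissue(tissue, per_sig)
    return reg


class TestCrossTissue:
    def test_same_signature_half_overlap_links_tissues(self):
        reg = build_regulome_from(
            {"liver": [("AP", iv(0, 100))], "brain": [("AP", iv(50, 160))]}
        )
        cross_tissue_classify(reg)
        for r in reg.regions():
            assert r.activity_tissues == frozenset({"liver", "brain"})
            assert r.specificity == "tissue_shared"

    def test_promoter_enhancer_overlap_marks_both_dynamic(self):
        reg = build_regulome_from(
            {"liver": [("AP", iv(0, 100))], "testis": [("AE", iv(0, 100))]}
        )
        cross_tissue_classify(reg)
        assert all(r.intra_dynamic == "dynamic_PE" for r in reg.regions())

    def test_isolated_region_stays_tissue_specific(self):
        reg = build_regulome_from(
            {"liver": [("AE", iv(0, 100))], "brain": [("AE", iv(5000, 5100))]}
        )
        cross_tissue_classify(reg)
        for r in reg.regions():
            assert r.specificity == "tissue_specific"
            assert r.activity_tissues == frozenset({r.home_tissue})

    def test_active_primed_overlap_is_dynamic_e(self):
        reg = build_regulome_from(
            {"liver": [("AE", iv(0, 100))], "brain": [("PE", iv(20, 110))]}
        )
        cross_tissue_classify(reg)
        assert all(r.intra_dynamic == "dynamic_E" for r in reg.regions())

    def test_four_tissue_shared_category(self):
        reg = build_regulome_from(
            {t: [("AP", iv(0, 100))] for t in ("liver", "muscle", "brain", "testis")}
        )
        cross_tissue_classify(reg)
        assert all(r.specificity == "four_tissue_shared" for r in reg.regions())

    def test_linking_is_symmetric_and_matches_brute_force(self):
        length = 20_000
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            spec = {}
            for tissue in ("liver", "brain", "testis"):
                lst = []
                for _ in range(15):
                    s = int(rng.integers(0, length - 400))
                    sig = ("AP", "AE", "PE")[int(rng.integers(3))]
                    lst.append((sig, iv(s, s + int(rng.integers(80, 350)))))
                spec[tissue] = lst
            reg = build_regulome_from(spec)
            cross_tissue_classify(reg)
            oracle = cross_tissue_brute_force(spec, length)
            for r in reg.regions():
                want_active, want_dynamic = oracle[
                    (r.home_tissue, r.interval.start, r.interval.end)
                ]
                assert r.activity_tissues == want_active
                assert r.intra_dynamic == want_dynamic


class TestEnhancerAssociation:
    def _slice(self, aps, enhancers):
        return {
            "AP": [RegulatoryRegion(a, "AP", "sp", "liver") for a in aps],
            "AE": [RegulatoryRegion(e, "AE", "sp", "liver") for e in enhancers],
            "PE": [],
        }

    def test_picks_nearer_promoter_by_edge_distance(self):
        tissue = self._slice([iv(0, 200), iv(9000, 9200)], [iv(5000, 5400)])
        (a,) = associate_enhancers(tissue)
        assert a.promoter.interval == iv(9000, 9200)
        assert a.distance == 3600

    def test_beyond_one_megabase_unassigned(self):
        tissue = self._slice([iv(1_300_000, 1_300_200)], [iv(0, 400)])
        (a,) = associate_enhancers(tissue)
        assert a.promoter is None and a.distance is None

    def test_overlapping_promoter_distance_zero(self):
        tissue = self._slice([iv(100, 300)], [iv(250, 600)])
        (a,) = associate_enhancers(tissue)
        assert a.distance == 0

    def test_tie_breaks_to_lower_start(self):
        tissue = self._slice([iv(0, 100), iv(400, 500)], [iv(200, 300)])
        (a,) = associate_enhancers(tissue)
        assert a.promoter.interval == iv(0, 100)


class TestNearestGene:
    def test_containment_gives_distance_zero_assignment(self):
        p = RegulatoryRegion(iv(1000, 1200), "AP", "sp", "liver")
        mapping = assign_nearest_gene([p], [(iv(1100, 1101), "geneA")])
        assert mapping[p] == "geneA"

    def test_beyond_one_megabase_is_none(self):
        p = RegulatoryRegion(iv(0, 200), "AP", "sp", "liver")
        mapping = assign_nearest_gene([p], [(iv(2_100_000, 2_100_001), "geneA")])
        assert mapping[p] is None

    def test_equidistant_tss_breaks_to_lower_coordinate(self):
        p = RegulatoryRegion(iv(1000, 1100), "AP", "sp", "liver")
        tss = [(iv(1200, 1201), "right"), (iv(899, 900), "left")]
        assert assign_nearest_gene([p], tss)[p] == "left"

    def test_enhancer_inherits_promoter_gene(self):
        p = RegulatoryRegion(iv(1000, 1200), "AP", "sp", "liver")
        e = RegulatoryRegion(iv(3000, 3200), "AE", "sp", "liver")
        assignments = associate_enhancers({"AP": [p], "AE": [e], "PE": []})
        mapping = assign_nearest_gene(
            [p], [(iv(1100, 1101), "geneA")], assignments=assignments
        )
        assert mapping[e] == "geneA"
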