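import numpy as np
import pytest

from regevo.evolution import (
    AlignmentMap,
    PairProjection,
    fit_rate,
    project_region,
    replicate_zero_point,
    signature_decomposition,
    summarize_pair,
)
from regevo.intervals import GenomicInterval, IntervalIndex
from regevo.io import AlignmentBlock
from regevo.regulome import Regulome, RegulatoryRegion
from oracles import normal_equations_fit


def iv(start, end, seq="chr1"):
    return GenomicInterval(seq, start, end)


def block(s_a, e_a, s_b, e_b, seq_a="chr1", seq_b="chr1", sp=("mouse", "rat")):
    return AlignmentBlock(iv(s_a, e_a, seq_a), iv(s_b, e_b, seq_b), sp[0], sp[1])


def regulome_of(species, tissue_regions):
    """tissue_regions: dict tissue -> list of (signature, interval)."""
    reg = Regulome(species=species)
    for tissue, lst in tissue_regions.items():
        per_sig = {"AP": [], "AE": [], "PE": []}
        for sig, interval, *flags in lst:
            r = RegulatoryRegion(interval, sig, species, tissue)
            if flags:
                r.intra_dynamic = flags[0]
            per_sig[sig].append(r)
        reg.add_tissue(tissue, per_sig)
    return reg


def region(interval, sig="AP", species="mouse", tissue="liver"):
    return RegulatoryRegion(interval, sig, species, tissue)


def target_index(regulome):
    return IntervalIndex([(r.interval, r) for r in regulome.regions()])


class TestProjection:
    def setup_method(self):
        self.amap = AlignmentMap([block(0, 1000, 5000, 6000)])

    def test_single_base_overlap_is_maintained(self):
        target = regulome_of("rat", {"liver": [("AE", iv(5999, 6200))]})
        res = project_region(region(iv(900, 1000)), self.amap, target_index(target))
        assert res.status == "maintained"
        assert len(res.partners) == 1

    def test_region_outside_blocks_is_unaligned(self):
        target = regulome_of("rat", {"liver": [("AE", iv(5000, 5100))]})
        res = project_region(region(iv(4000, 4100)), self.amap, target_index(target))
        assert res.status == "unaligned"

    def test_aligned_without_partner_is_regulation_loss(self):
        target = regulome_of("rat", {"liver": [("AE", iv(9000, 9100))]})
        res = project_region(region(iv(100, 200)), self.amap, target_index(target))
        assert res.status == "aligned_no_regulation"

    def test_distant_split_projection_excluded_as_multi_mapped(self):
        amap = AlignmentMap(
            [block(0, 100, 5000, 5100), block(100, 200, 2_000_000, 2_000_100)]
        )
        target = regulome_of("rat", {"liver": [("AE", iv(5000, 5100))]})
        res = project_region(region(iv(50, 150)), amap, target_index(target))
        assert res.status == "multi_mapped_excluded"

    def test_nearby_split_projection_kept(self):
        amap = AlignmentMap([block(0, 100, 5000, 5100), block(100, 200, 5600, 5700)])
        target = regulome_of("rat", {"liver": [("AE", iv(5000, 5100))]})
        res = project_region(region(iv(50, 150)), amap, target_index(target))
        assert res.status == "maintained"

    def test_unknown_species_rejected(self):
        target = regulome_of("rat", {})
        with pytest.raises(ValueError, match="species"):
            project_region(
                region(iv(0, 10), species="horse"), self.amap, target_index(target)
            )


def two_species_setup():
    """Asymmetric maintenance: i -> j gives P_M=8, P_L=2; j -> i gives P_M=6, P_L=4.

    Slots 0 and 1 each hold two mouse promoters overlapping one rat promoter,
    so two mouse regions are maintained against a single rat partner; rat
    additionally has four aligned slots with no mouse regulation.
    """
    blocks = [block(k * 1000, k * 1000 + 1000, k * 1000, k * 1000 + 1000) for k in range(30)]
    regions_i = []
    for k in (0, 1):  # two promoters per slot
        regions_i.append(("AP", iv(k * 1000, k * 1000 + 200)))
        regions_i.append(("AP", iv(k * 1000 + 300, k * 1000 + 500)))
    for k in (2, 3, 4, 5):  # one promoter per slot
        regions_i.append(("AP", iv(k * 1000, k * 1000 + 500)))
    for k in (20, 21):  # aligned but no rat regulation
        regions_i.append(("AP", iv(k * 1000, k * 1000 + 500)))
    regions_j = [("AP", iv(k * 1000, k * 1000 + 500)) for k in range(6)]
    regions_j += [("AP", iv(k * 1000, k * 1000 + 500)) for k in (10, 11, 12, 13)]
    reg_i = regulome_of("mouse", {"liver": regions_i})
    reg_j = regulome_of("rat", {"liver": regions_j})
    return reg_i, reg_j, AlignmentMap(blocks)


class TestSummarizePair:
    def test_partition_identity_and_mean_fraction(self):
        """8/10 maintained one way, 6/10 the other: fraction = mean(80, 60)."""
        reg_i, reg_j, amap = two_species_setup()
        pair = PairProjection(reg_i, reg_j, amap)
        summary = summarize_pair(pair, divergence_mya=30.0)
        cc = summary.classes["AP"]
        for d in cc.p_a:
            assert cc.p_a[d] == cc.p_n[d] + cc.p_l[d] + cc.p_m[d]
        assert cc.p_m["mouse->rat"] == 8
        assert cc.p_m["rat->mouse"] == 6
        assert cc.maintenance_fraction_pct() == pytest.approx(70.0)

    def test_everything_maintained_gives_hundred(self):
        blocks = [block(k * 1000, k * 1000 + 1000, k * 1000, k * 1000 + 1000) for k in range(5)]
        regions = [("AP", iv(k * 1000, k * 1000 + 500)) for k in range(5)]
        reg_i = regulome_of("mouse", {"liver": regions})
        reg_j = regulome_of("rat", {"liver": regions})
        summary = summarize_pair(PairProjection(reg_i, reg_j, AlignmentMap(blocks)), 10.0)
        assert summary.classes["AP"].maintenance_fraction_pct() == pytest.approx(100.0)

    def test_dynamic_queries_excluded_but_count_as_partners(self):
        reg_i = regulome_of(
            "mouse", {"liver": [("AP", iv(0, 500)), ("AE", iv(1000, 1500), "dynamic_E")]}
        )
        reg_j = regulome_of(
            "rat", {"liver": [("AP", iv(0, 500)), ("AE", iv(1000, 1500), "dynamic_E")]}
        )
        amap = AlignmentMap([block(0, 2000, 0, 2000)])
        summary = summarize_pair(PairProjection(reg_i, reg_j, amap), 10.0)
        assert "AE" not in summary.classes  # dynamic region not a query
        assert summary.classes["AP"].p_m["mouse->rat"] == 1


class TestReplicateZeroPoint:
    def test_mean_of_directional_fractions(self):
        """k: 9 of 10 APs overlap l; l: 8 of 8 overlap k -> mean(90,100)=95."""
        regions_k = [("AP", iv(k * 1000, k * 1000 + 500)) for k in range(10)]
        # l's regions overlap k's first 8 footprints (shifted but overlapping);
        # k's last AP (slot 9) overlaps nothing in l
        regions_l = [("AP", iv(k * 1000 + 100, k * 1000 + 600)) for k in range(8)]
        # one extra l-region overlapping k slot 8 gives k 9 hits total
        regions_l.append(("AP", iv(8_000, 8_200)))
        reg_k = regulome_of("mouse", {"liver": regions_k})
        reg_l = regulome_of("mouse", {"liver": regions_l})
        zero = replicate_zero_point(reg_k, reg_l)
        assert zero.fraction_pct["AP"] == pytest.approx(95.0)

    def test_identical_regulomes_reach_hundred(self):
        regions = [("AE", iv(0, 300)), ("AE", iv(1000, 1300))]
        reg = regulome_of("cat", {"liver": regions})
        reg2 = regulome_of("cat", {"liver": regions})
        assert replicate_zero_point(reg, reg2).fraction_pct["AE"] == pytest.approx(100.0)

    def test_disjoint_regulomes_are_zero(self):
        reg_k = regulome_of("cat", {"liver": [("PE", iv(0, 100))]})
        reg_l = regulome_of("cat", {"liver": [("PE", iv(5000, 5100))]})
        assert replicate_zero_point(reg_k, reg_l).fraction_pct["PE"] == pytest.approx(0.0)


class TestRateFit:
    def test_two_points_define_the_line(self):
        fits, _ = fit_rate([(0.0, 95.0, "a"), (100.0, 45.0, "a")])
        assert fits["a"].slope == pytest.approx(-0.5)
        assert fits["a"].intercept == pytest.approx(95.0)

    def test_identical_categories_show_no_interaction(self):
        pts = []
        for t in (0, 20, 40, 60, 80):
            for cat in ("x", "y"):
                pts.append((float(t), 90.0 - 0.2 * t, cat))
        _, interactions = fit_rate(pts)
        assert interactions[("x", "y")] > 0.99

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(11)
        xs = rng.uniform(0, 100, 30)
        ys = 88.0 - 0.31 * xs + rng.normal(0, 3, 30)
        fits, _ = fit_rate([(float(x), float(y), "c") for x, y in zip(xs, ys)])
        slope, intercept = normal_equations_fit(xs, ys)
        assert fits["c"].slope == pytest.approx(slope, abs=1e-9)
        assert fits["c"].intercept == pytest.approx(intercept, abs=1e-9)

    def test_distinct_slopes_detected(self):
        rng = np.random.default_rng(5)
        pts = []
        for t in np.linspace(0, 100, 12):
            pts.append((float(t), 95 - 0.5 * t + rng.normal(0, 1), "steep"))
            pts.append((float(t), 95 - 0.1 * t + rng.normal(0, 1), "shallow"))
        fits, interactions = fit_rate(pts)
        assert interactions[("shallow", "steep")] < 1e-6
        assert fits["steep"].slope < fits["shallow"].slope

    def test_singular_design_rejected(self):
        with pytest.raises(ValueError, match="singular|points"):
            fit_rate([(10.0, 90.0, "a"), (10.0, 80.0, "a")])


class TestSignatureDecomposition:
    def _pair(self, partner_sigs):
        """10 mouse APs each 1-to-1 aligned to a rat region of given signature."""
        n = len(partner_sigs)
        blocks = [block(k * 1000, k * 1000 + 1000, k * 1000, k * 1000 + 1000) for k in range(n)]
        regions_i = [("AP", iv(k * 1000, k * 1000 + 500)) for k in range(n)]
        regions_j = [
            (sig, iv(k * 1000, k * 1000 + 500)) for k, sig in enumerate(partner_sigs)
        ]
        reg_i = regulome_of("mouse", {"liver": regions_i})
        reg_j = regulome_of("rat", {"liver": regions_j})
        return PairProjection(reg_i, reg_j, AlignmentMap(blocks))

    def test_promoter_switch_fraction(self):
        """8 AP->AP, 1 AP->AE, 1 AP->PE in both directions: 20% switching."""
        sig_pairs = [("AP", "AP")] * 8 + [
            ("AP", "AE"), ("AP", "PE"), ("AE", "AP"), ("PE", "AP"),
        ]
        blocks = [block(k * 1000, k * 1000 + 1000, k * 1000, k * 1000 + 1000) for k in range(12)]
        reg_i = regulome_of(
            "mouse",
            {"liver": [(s, iv(k * 1000, k * 1000 + 500)) for k, (s, _) in enumerate(sig_pairs)]},
        )
        reg_j = regulome_of(
            "rat",
            {"liver": [(s, iv(k * 1000, k * 1000 + 500)) for k, (_, s) in enumerate(sig_pairs)]},
        )
        pair = PairProjection(reg_i, reg_j, AlignmentMap(blocks))
        table = signature_decomposition(pair)
        d = "mouse->rat"
        assert table.partner_counts[d]["AP"] == {
            "P": 8, "AE": 1, "PE": 1, "DP": 0, "DE": 0,
        }
        assert table.np_m(d, "AP") == 10
        assert table.np_m("rat->mouse", "AP") == 10
        assert table.promoter_switch_pct == pytest.approx(20.0)

    def test_no_switching_gives_zero(self):
        pair = self._pair(["AP"] * 10)
        table = signature_decomposition(pair)
        assert table.promoter_switch_pct == pytest.approx(0.0)

    def test_decomposition_identity_on_simulated_pair(self, tiny_regulomes, tiny_sim):
        """NP_M equals the independently counted 1-to-1 maintained regions."""
        (pair_key,) = tiny_sim.maps.keys()
        a, b = sorted(pair_key)
        pair = PairProjection(
            tiny_regulomes[a], tiny_regulomes[b], AlignmentMap(tiny_sim.maps[pair_key])
        )
        table = signature_decomposition(pair)
        for direction, results in (
            (f"{a}->{b}", pair.forward),
            (f"{b}->{a}", pair.backward),
        ):
            for sig in ("AP", "AE", "PE"):
                independent = sum(
                    1
                    for region, res in results.items()
                    if region.signature == sig and res.one_to_one
                )
                assert table.np_m(direction, sig) == independent

    def test_maintenance_fraction_symmetric_under_species_swap(
        self, tiny_regulomes, tiny_sim
    ):
        (pair_key,) = tiny_sim.maps.keys()
        a, b = sorted(pair_key)
        amap = AlignmentMap(tiny_sim.maps[pair_key])
        s_ab = summarize_pair(PairProjection(tiny_regulomes[a], tiny_regulomes[b], amap), 40.0)
        s_ba = summarize_pair(PairProjection(tiny_regulomes[b], tiny_regulomes[a], amap), 40.0)
        for sig in s_ab.classes:
            f1 = s_ab.classes[sig].maintenance_fraction_pct()
            f2 = s_ba.classes[sig].maintenance_fraction_pct()
            assert f1 == pytest.approx(f2)
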