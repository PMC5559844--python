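"""Region filters, epiallele calls, feature assignment and centromeres."""

import numpy as np
import pytest

from epigenotype.regions import (
    FeatureMap,
    Region,
    assign_features,
    call_epialleles,
    define_centromere,
    filter_regions,
    parent_dmr_filter,
    retain_methylated_regions,
    sibling_specific_dmrs,
    ztest_level_difference,
)


def region(start, end, levels, total=100, chrom="Chr1", n_cyt=12, name=""):
    """Region with per-sample levels encoded as counts over `total` reads."""
    samples = {k: (int(round(v * total)), total) for k, v in levels.items()}
    return Region(chrom=chrom, start=start, end=end, samples=samples,
                  n_cytosines_covered=n_cyt, name=name)


class TestFilterRegions:
    def test_short_region_removed(self):
        r = region(0, 39, {"a": 0.8, "b": 0.5})
        assert filter_regions([r]) == []

    def test_too_few_cytosines_removed(self):
        r = region(0, 100, {"a": 0.8, "b": 0.5}, n_cyt=9)
        assert filter_regions([r]) == []

    def test_small_span_removed(self):
        r = region(0, 100, {"a": 0.50, "b": 0.35})
        assert filter_regions([r]) == []

    def test_qualifying_region_retained(self):
        r = region(0, 100, {"a": 0.50, "b": 0.25})
        assert filter_regions([r]) == [r]


class TestZTest:
    def test_formula_on_strong_difference(self):
        # diff 0.8, delta 0.25: z = 0.55 / sqrt(2 * 0.9*0.1/100) = 12.96
        res = ztest_level_difference(90, 100, 10, 100)
        assert res.z == pytest.approx(12.9636, abs=1e-3)
        assert res.p < 1e-12

    def test_equal_levels_not_significant(self):
        res = ztest_level_difference(50, 100, 50, 100)
        assert res.z < 0 and res.p > 0.5

    def test_more_reads_increase_statistic(self):
        z1 = ztest_level_difference(60, 100, 20, 100).z
        z2 = ztest_level_difference(120, 200, 40, 200).z
        assert z2 > z1

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            ztest_level_difference(0, 0, 5, 10)


class TestEpialleles:
    GENS = ["G1", "G2", "G3", "G4"]

    def test_single_change_is_epilocus(self):
        stable = region(0, 100, {g: 0.75 for g in self.GENS}, name="stable")
        jump = region(200, 300, {"G1": 0.9, "G2": 0.9, "G3": 0.1, "G4": 0.1},
                      name="jump")
        calls, summary = call_epialleles([stable, jump], self.GENS)
        js = summary[summary["name"] == "jump"].iloc[0]
        ss = summary[summary["name"] == "stable"].iloc[0]
        assert js.n_epialleles == 1 and js.is_epilocus and not js.is_hotspot
        assert ss.n_epialleles == 0 and not ss.is_epilocus

    def test_multiple_changes_flag_hotspot(self):
        hot = region(0, 100, {"G1": 0.95, "G2": 0.05, "G3": 0.95, "G4": 0.05},
                     name="hot")
        _, summary = call_epialleles([hot], self.GENS)
        assert summary.iloc[0].n_epialleles == 3
        assert bool(summary.iloc[0].is_hotspot)

    def test_requires_two_generations(self):
        with pytest.raises(ValueError):
            call_epialleles([region(0, 100, {"G1": 0.5})], ["G1"])

    def test_adjusted_p_never_below_raw(self):
        regions = [region(i * 200, i * 200 + 100,
                          {"G1": 0.9, "G2": 0.1 + 0.05 * i, "G3": 0.5, "G4": 0.5})
                   for i in range(5)]
        calls, _ = call_epialleles(regions, self.GENS)
        for c in calls:
            assert c.p_adjusted >= c.p - 1e-15


class TestParentDmrFilter:
    def test_one_bp_overlap_eliminates(self):
        dmr = region(100, 200, {"m": 0.9, "f": 0.1})
        sib = region(199, 300, {"m": 0.5, "f": 0.5})
        assert parent_dmr_filter([dmr], [sib]) == []

    def test_weak_difference_removed(self):
        dmr = region(100, 200, {"m": 0.5, "f": 0.3})  # 20% < 25%
        assert parent_dmr_filter([dmr], []) == []

    def test_toy_cohort_exact_survivor_count(self):
        # 107-candidate toy set; 7 overlap sibling-specific DMRs
        dmrs = [region(i * 1000, i * 1000 + 100, {"m": 0.9, "f": 0.1},
                       name=f"d{i}") for i in range(107)]
        sibs = [region(i * 1000 + 50, i * 1000 + 150, {"m": 0.5, "f": 0.5})
                for i in range(7)]
        kept = parent_dmr_filter(dmrs, sibs)
        assert len(kept) == 100
        assert all(int(r.name[1:]) >= 7 for r in kept)

    def test_sibling_specific_detection(self):
        variable = region(0, 100, {"p": 0.9, "s1": 0.1, "s2": 0.9}, name="v")
        stable = region(200, 300, {"p": 0.9, "s1": 0.85, "s2": 0.9}, name="s")
        out = sibling_specific_dmrs([variable, stable], "p", ["s1", "s2"])
        assert [r.name for r in out] == ["v"]


class TestRetainMethylatedRegions:
    def test_methylated_region_retained_unmethylated_dropped(self):
        gens = [f"G{i}" for i in range(8)]
        high = region(0, 100, {g: 0.6 for g in gens}, total=300, name="high")
        zero = region(200, 300, {g: 0.0 for g in gens}, total=300, name="zero")
        out = retain_methylated_regions([high, zero], gens)
        assert [r.name for r in out] == ["high"]

    def test_low_level_everywhere_removed(self):
        gens = [f"G{i}" for i in range(8)]
        # passes the 25%/8 = 3.125% test but is below 10% in every generation
        dim = region(0, 100, {g: 0.08 for g in gens}, total=2000)
        assert retain_methylated_regions([dim], gens) == []


class TestAssignFeatures:
    @pytest.fixture()
    def fmap(self):
        return FeatureMap([
            ("Chr1", 0, 60, "promoter"),
            ("Chr1", 100, 200, "CDS"),
            ("Chr1", 150, 250, "TE"),       # overlaps CDS: CDS wins
            ("Chr1", 300, 320, "ncRNA"),
            ("Chr1", 300, 320, "intron"),   # ncRNA outranks intron
        ])

    def test_priority_cds_over_te(self, fmap):
        out = assign_features(Region("Chr1", 100, 200, {"s": (1, 2)}), fmap)
        assert out["CDS"] == 1.0 and out["TE"] == 0.0

    def test_ncrna_highest_priority(self, fmap):
        out = assign_features(Region("Chr1", 300, 320, {"s": (1, 2)}), fmap)
        assert out["ncRNA"] == 1.0

    def test_unannotated_bases_intergenic(self, fmap):
        out = assign_features(Region("Chr1", 0, 100, {"s": (1, 2)}), fmap)
        assert out["promoter"] == pytest.approx(0.6)
        assert out["intergenic"] == pytest.approx(0.4)

    def test_proportions_sum_to_one(self, fmap):
        out = assign_features(Region("Chr1", 0, 400, {"s": (1, 2)}), fmap)
        assert sum(out.values()) == pytest.approx(1.0)

    def test_from_gff3(self, tmp_path):
        gff = tmp_path / "toy.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "Chr1\ttoy\tgene\t2001\t4000\t.\t+\t.\tID=g1\n"
            "Chr1\ttoy\tmRNA\t2001\t4000\t.\t+\t.\tID=m1;Parent=g1\n"
            "Chr1\ttoy\texon\t2001\t2500\t.\t+\t.\tParent=m1\n"
            "Chr1\ttoy\texon\t3001\t4000\t.\t+\t.\tParent=m1\n"
            "Chr1\ttoy\tCDS\t2101\t2500\t.\t+\t.\tParent=m1\n"
            "Chr1\ttoy\ttransposable_element\t5001\t6000\t.\t+\t.\tID=te1\n"
        )
        fmap = FeatureMap.from_gff3(gff)
        # promoter: 1 kb upstream of TSS (bases 1000-2000, 0-based)
        out = assign_features(Region("Chr1", 1000, 2000, {"s": (1, 2)}), fmap)
        assert out["promoter"] == pytest.approx(1.0)
        # intron between the exons
        out = assign_features(Region("Chr1", 2500, 3000, {"s": (1, 2)}), fmap)
        assert out["intron"] == pytest.approx(1.0)
        out = assign_features(Region("Chr1", 5000, 6000, {"s": (1, 2)}), fmap)
        assert out["TE"] == pytest.approx(1.0)


class TestDefineCentromere:
    def test_v_shaped_density_centers_on_vertex(self):
        centers = (np.arange(300) + 0.5) * 100_000
        density = np.abs(centers - 14_800_000) / 1000.0
        interval = define_centromere(density)
        assert interval is not None
        start, end = interval[0]
        assert start == pytest.approx(13_300_000, abs=100_000)
        assert end == pytest.approx(16_300_000, abs=100_000)

    def test_override_returned_unchanged(self):
        override = [(1_600_000, 1_900_000), (2_900_000, 5_000_000)]
        assert define_centromere(np.ones(10), override=override) == override

    def test_flat_density_warns_and_returns_none(self):
        with pytest.warns(UserWarning):
            assert define_centromere(np.ones(50)) is None
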