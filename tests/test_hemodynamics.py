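"""Backbone perfusion arithmetic and network solving."""

import numpy as np
import pytest

import vasodose as vd
from vasodose.hemodynamics import MLMIN_TO_M3S, MMHG_TO_PA


@pytest.mark.parametrize(
    "mass_g,expect",
    [(1450, 725.0), (1300, 650.0), (100, 50.0)],
)
def test_total_flow_from_specific_perfusion(mass_g, expect):
    spec = vd.PerfusionSpec(tissue_mass_g=mass_g, specific_flow_ml_min_100g=50.0)
    assert vd.total_cerebral_flow(spec) == expect


class TestPoiseuille:
    def test_no_flow_no_drop(self):
        assert vd.poiseuille_pressure_drop(0.0, 1e-3, 0.1, 3.5e-3) == 0.0

    def test_hand_computed_value(self):
        dp = vd.poiseuille_pressure_drop(1e-6, 1e-3, 0.1, 3.5e-3)
        assert dp == pytest.approx(891.3, rel=1e-3)

    def test_fourth_power_radius_scaling(self):
        d1 = vd.poiseuille_pressure_drop(1e-6, 1e-3, 0.1, 3.5e-3)
        d2 = vd.poiseuille_pressure_drop(1e-6, 2e-3, 0.1, 3.5e-3)
        assert d1 / d2 == pytest.approx(16.0)

    def test_bad_radius(self):
        with pytest.raises(ValueError):
            vd.poiseuille_pressure_drop(1e-6, 0.0, 0.1, 3.5e-3)


class TestSolveBackbone:
    def test_flow_conservation_everywhere(self, fixture13):
        vd.solve_backbone(
            fixture13.backbone, fixture13.perfusion, fixture13.region_fractions
        )
        by_name = {v.name: v for v in fixture13.backbone}
        for v in fixture13.backbone:
            kids = [w for w in fixture13.backbone if w.parent == v.name]
            if kids:
                assert v.flow_ml_min == pytest.approx(
                    sum(k.flow_ml_min for k in kids), rel=1e-12
                )
        assert by_name["artery_root"].flow_ml_min == pytest.approx(650.0)
        assert by_name["vein_root"].flow_ml_min == pytest.approx(650.0)

    def test_artificial_artery_flows_sum_to_cerebral_flow(self, fixture13):
        vd.solve_backbone(
            fixture13.backbone, fixture13.perfusion, fixture13.region_fractions
        )
        leaves = [v for v in fixture13.backbone if v.region and v.side == "artery"]
        assert len(leaves) == 13
        assert sum(v.flow_ml_min for v in leaves) == pytest.approx(650.0)

    def test_arterial_pressure_decreases_to_leaves(self, fixture13):
        vd.solve_backbone(
            fixture13.backbone, fixture13.perfusion, fixture13.region_fractions
        )
        for v in fixture13.backbone:
            if v.side == "artery":
                assert v.pressure_out_mmhg < v.pressure_in_mmhg

    def test_perturbing_one_region_preserves_total(self, fixture13):
        fr = dict(fixture13.region_fractions)
        fr["frontal_L"] *= 1.3
        vd.solve_backbone(fixture13.backbone, fixture13.perfusion, fr)
        leaves = [v for v in fixture13.backbone if v.region and v.side == "vein"]
        assert sum(v.flow_ml_min for v in leaves) == pytest.approx(650.0)

    def test_poiseuille_consistency_per_segment(self, fixture13):
        vd.solve_backbone(
            fixture13.backbone, fixture13.perfusion, fixture13.region_fractions
        )
        v = next(x for x in fixture13.backbone if x.name == "artery_root")
        dp = vd.poiseuille_pressure_drop(
            v.flow_ml_min * MLMIN_TO_M3S,
            v.radius_mm * 1e-3,
            v.length_mm * 1e-3,
            fixture13.perfusion.blood_viscosity_pa_s,
        )
        assert v.pressure_in_mmhg - v.pressure_out_mmhg == pytest.approx(
            dp / MMHG_TO_PA, rel=1e-9
        )


class TestRadiusScaling:
    def test_linear_factor(self):
        vs = [vd.BackboneVessel("ts", "vein", 3.0, 10.0)]
        vd.scale_radii_for_sex(vs, ["ts"], 1.02)
        assert vs[0].radius_mm == pytest.approx(3.06)

    def test_identity(self):
        vs = [vd.BackboneVessel("a", "artery", 2.0, 5.0)]
        vd.scale_radii_for_sex(vs, ["a"], 1.0)
        assert vs[0].radius_mm == 2.0

    def test_volumetric_mode_uses_cube_root(self):
        vs = [vd.BackboneVessel("a", "artery", 2.0, 5.0)]
        vd.scale_radii_for_sex(vs, ["a"], 1.1, mode="volumetric")
        assert vs[0].radius_mm == pytest.approx(2.0 * 1.1 ** (1 / 3))

    def test_subset_only(self):
        vs = [
            vd.BackboneVessel("a", "artery", 2.0, 5.0),
            vd.BackboneVessel("b", "artery", 2.0, 5.0),
        ]
        vd.scale_radii_for_sex(vs, ["a"], 1.02)
        assert vs[1].radius_mm == 2.0
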