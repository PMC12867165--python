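"""SAF algebra, interpolation, decay schemes and S-values."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vasodose as vd
from vasodose.dosimetry import (
    MEV_PER_DECAY_TO_MGY_PER_MBQ_S,
    Emission,
    SafCurve,
)


class TestSafAlgebra:
    @pytest.mark.parametrize(
        "af,mass,expect",
        [(1.0, 1.350, 0.7407), (0.0, 1.0, 0.0), (0.5, 2.0, 0.25)],
    )
    def test_single_region(self, af, mass, expect):
        assert vd.saf_single(af, mass) == pytest.approx(expect, abs=1e-4)

    def test_dual_cross_local_deposition(self):
        """With all blood energy trapped in the vessels, the cross SAF is
        (1-f_BV)/m_BOBV = 0.44/1.322 = 0.3328."""
        val = vd.saf_dual_cross(0.0, 1.0, 0.56, 1.322)
        assert val == pytest.approx(0.3328, abs=1e-4)
        ratio = vd.saf_single(1.0, 1.350) / val
        assert ratio == pytest.approx(2.23, abs=0.01)

    def test_fbv_zero_limit_reduces_to_self_form(self):
        a = vd.saf_dual_cross(0.2, 0.8, 1e-9, 1.322)
        assert a == pytest.approx(vd.saf_dual_self(0.8, 1.322), rel=1e-6)

    def test_equal_afs_cancel_fbv(self):
        for f in (0.2, 0.56, 0.9):
            assert vd.saf_dual_cross(0.7, 0.7, f, 1.322) == pytest.approx(
                0.7 / 1.322
            )

    def test_mass_bookkeeping_invariants(self):
        afb = vd.DualRegionModel.afb()
        assert afb.m_B == afb.m_BIBV + afb.m_BOBV
        amb = vd.DualRegionModel.amb()
        assert abs(amb.m_B - (amb.m_BIBV + amb.m_BOBV)) <= 0.001 + 1e-12
        with pytest.raises(ValueError):
            vd.DualRegionModel(m_B=1.0, m_BIBV=0.5, m_BOBV=0.6, f_BV=0.5)

    def test_self_dose_mass_ratio(self):
        """At full containment the single/dual self-dose SAF ratio is
        m_BOBV/m_B ~ 0.979 for the female brain."""
        afb = vd.DualRegionModel.afb()
        ratio = vd.saf_single(1.0, afb.m_B) / vd.saf_dual_self(1.0, afb.m_BOBV)
        assert ratio == pytest.approx(0.979, abs=0.001)


class TestInterpolation:
    def test_exact_at_knots(self):
        e = np.array([0.01, 0.1, 1.0, 10.0])
        v = np.array([2.0, 1.1, 0.4, 0.05])
        curve = SafCurve(e, v)
        np.testing.assert_allclose(curve(e), v, rtol=1e-12)
        assert vd.interpolate_saf(curve, 0.1) == pytest.approx(1.1)

    def test_monotone_data_monotone_interpolant(self):
        e = np.logspace(-2, 1, 8)
        v = 1.0 / e
        curve = SafCurve(e, v)
        dense = curve(np.logspace(-2, 1, 300))
        assert (np.diff(dense) <= 1e-12).all()

    def test_power_law_midpoint_error(self):
        """Sampling a power law on a coarse grid and interpolating at
        midpoints stays within 0.5% of the dense reference."""
        e = np.logspace(-2, 1, 10)
        curve = SafCurve(e, 0.7 * e**-1.3)
        mids = np.sqrt(e[:-1] * e[1:])
        np.testing.assert_allclose(curve(mids), 0.7 * mids**-1.3, rtol=5e-3)

    def test_extrapolation_refused(self):
        curve = SafCurve(np.array([0.1, 1.0, 5.0]), np.array([1.0, 0.5, 0.2]))
        with pytest.raises(ValueError, match="outside"):
            curve(20.0)


def _flat_curves(phi=0.5):
    c = SafCurve.constant(phi, span=(1e-3, 12.0))
    return {"photon": c, "electron": c, "alpha": c}


class TestSValue:
    def test_unit_conversion_worked_example(self):
        """1 MeV emission, yield 1, SAF 0.5/kg -> 8.01e-5 mGy/(MBq s)."""
        scheme = vd.DecayScheme("toy", [Emission("photon", 1.0, 1.0)])
        s = vd.s_value(scheme, _flat_curves(0.5))
        assert s == pytest.approx(8.011e-5, rel=1e-3)
        assert MEV_PER_DECAY_TO_MGY_PER_MBQ_S == pytest.approx(1.602e-4, rel=1e-3)

    def test_zero_yield_zero_svalue(self):
        scheme = vd.DecayScheme("toy", [Emission("alpha", 5.0, 0.0)])
        assert vd.s_value(scheme, _flat_curves()) == 0.0

    def test_additive_over_emissions(self):
        e1 = Emission("photon", 0.5, 0.3)
        e2 = Emission("electron", 1.5, 0.7)
        s_both = vd.s_value(vd.DecayScheme("x", [e1, e2]), _flat_curves())
        s_1 = vd.s_value(vd.DecayScheme("x", [e1]), _flat_curves())
        s_2 = vd.s_value(vd.DecayScheme("x", [e2]), _flat_curves())
        assert s_both == pytest.approx(s_1 + s_2, rel=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(0.1, 5.0), st.floats(0.0, 2.0))
    def test_linear_in_yield_and_saf(self, energy, yld):
        scheme = vd.DecayScheme("h", [Emission("electron", energy, yld)])
        s1 = vd.s_value(scheme, _flat_curves(0.25))
        s2 = vd.s_value(scheme, _flat_curves(0.5))
        assert s2 == pytest.approx(2 * s1, rel=1e-9, abs=1e-30)

    def test_beta_spectrum_trapezoid(self):
        e = np.linspace(0.1, 1.0, 10)
        n = np.ones_like(e) / 0.9  # flat, unit integral
        scheme = vd.DecayScheme("b", [Emission("beta-", None, 1.0, (e, n))])
        s = vd.s_value(scheme, _flat_curves(0.5))
        expect = 0.5 * np.trapezoid(e * n, e) * MEV_PER_DECAY_TO_MGY_PER_MBQ_S
        assert s == pytest.approx(expect, rel=1e-9)

    def test_recoil_uses_two_mev_alpha_saf(self):
        e = np.array([0.5, 2.0, 8.0])
        alpha = SafCurve(e, np.array([0.9, 0.5, 0.1]))
        curves = {"alpha": alpha}
        scheme = vd.DecayScheme("r", [Emission("alpha_recoil", 0.1, 1.0)])
        s = vd.s_value(scheme, curves)
        # energy carried 0.1 MeV, SAF read at 2 MeV
        assert s == pytest.approx(0.1 * 0.5 * MEV_PER_DECAY_TO_MGY_PER_MBQ_S)

    def test_missing_curve_names_emission(self):
        scheme = vd.DecayScheme("x", [Emission("alpha", 5.0, 1.0)])
        with pytest.raises(ValueError, match="alpha"):
            vd.s_value(scheme, {"photon": SafCurve.constant(0.5)})


class TestDecaySchemes:
    def test_packaged_astatine_chain_loads(self):
        for name in ("At-211", "Po-211", "Bi-207"):
            scheme = vd.load_packaged_scheme(name)
            assert scheme.nuclide == name
            assert all(em.yield_per_decay >= 0 for em in scheme.emissions)

    def test_reader_roundtrip(self, tmp_path):
        p = tmp_path / "X-99.tsv"
        p.write_text("# nuclide: X-99\nalpha\t5.0\t0.9\nphoton\t0.2\t0.1\n")
        scheme = vd.read_decay_scheme(p)
        assert scheme.nuclide == "X-99"
        assert len(scheme.emissions) == 2

    def test_unknown_kind_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("neutrino\t1.0\t1.0\n")
        with pytest.raises(ValueError):
            vd.read_decay_scheme(p)


class TestChainTable:
    def test_astatine_chain_rows_and_ratios(self):
        """Parent plus progeny appear as individual rows in the table
        layout, progeny parenthesized, with internally consistent ratios."""
        schemes = [vd.load_packaged_scheme(n) for n in ("At-211", "Po-211", "Bi-207")]
        single = _flat_curves(1 / 1.350)
        cross = _flat_curves(0.44 / 1.322)
        self_ = _flat_curves(1 / 1.322)
        table = vd.decay_chain_table(
            schemes, single, cross, self_, progeny={"Po-211", "Bi-207"}
        )
        assert table.nuclide.tolist() == ["At-211", "(Po-211)", "(Bi-207)"]
        for _, row in table.iterrows():
            assert row["ratio_cross"] == pytest.approx(
                row["S(B<-B)"] / row["S(BOBV<-BB)"], rel=1e-9
            )
            assert row["ratio_self"] == pytest.approx(
                row["S(B<-B)"] / row["S(BOBV<-BOBV)"], rel=1e-9
            )
        # flat curves realize the analytic local-deposition ratio
        assert table.ratio_cross.iloc[0] == pytest.approx(2.226, abs=0.01)

    def test_single_nuclide_single_row(self):
        schemes = [vd.load_packaged_scheme("At-211")]
        t = vd.decay_chain_table(schemes, _flat_curves(), _flat_curves(), _flat_curves())
        assert len(t) == 1
        assert t.nuclide.iloc[0] == "At-211"


def test_local_deposition_limits_match_reference_ratios():
    assert vd.af_ratio_local_deposition(0.56) == pytest.approx(2.27, abs=0.01)
    assert round(vd.af_ratio_local_deposition(0.56), 1) == 2.3
    amb = vd.DualRegionModel.amb()
    assert vd.saf_ratio_local_deposition(amb) == pytest.approx(1.85, abs=0.005)
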