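"""Materials, physics tables and the simplified Monte Carlo transport."""

import numpy as np
import pytest
from scipy import integrate

import vasodose as vd
from vasodose.transport import (
    ICRU_BLOOD,
    ICRU_BRAIN,
    CapsuleSet,
    Ellipsoid,
    Slab,
    TransportConfig,
    TransportGeometry,
    tables,
)


class TestMaterials:
    def test_homogeneous_female_brain_row(self):
        """1300 g brain + 50 g blood reproduce the homogenized organ:
        H 10.68 %, density 1.0407 g/cm^3."""
        mixed = vd.mix_material(ICRU_BRAIN, ICRU_BLOOD, 50.0 / 1350.0)
        assert round(mixed.fractions["H"], 2) == 10.68
        assert round(mixed.density_g_cm3, 4) == 1.0407

    def test_zero_admixture_is_identity(self):
        m = vd.mix_material(ICRU_BRAIN, ICRU_BLOOD, 0.0)
        assert m.fractions == ICRU_BRAIN.fractions
        assert m.density_g_cm3 == ICRU_BRAIN.density_g_cm3

    def test_fractions_always_sum_to_100(self):
        for f in (0.0, 0.037, 0.5, 1.0):
            m = vd.mix_material(ICRU_BRAIN, ICRU_BLOOD, f)
            assert sum(m.fractions.values()) == pytest.approx(100.0, abs=1e-9)

    def test_brain_materials_masses(self):
        mats = vd.brain_materials("male")
        assert mats["B"].mass_kg == pytest.approx(1.517)
        assert mats["BIBV"].mass_kg == pytest.approx(0.47 * 0.067, abs=5e-4)


class TestTables:
    def test_energy_grids(self):
        a = vd.alpha_energy_grid()
        assert len(a) == 24 and a[0] == 0.5 and a[-1] == 12.0
        assert np.allclose(np.diff(a), 0.5)
        e = vd.photon_electron_grid()
        assert len(e) == 26
        assert e[0] == pytest.approx(0.01) and e[-1] == pytest.approx(10.0)
        assert np.allclose(np.diff(np.log(e)), np.diff(np.log(e))[0])

    def test_range_tables_monotone_and_invertible(self):
        tab = tables()
        for particle, grid in (("alpha", vd.alpha_energy_grid()),
                               ("electron", vd.photon_electron_grid())):
            r = tab.csda_range(grid, particle)
            assert (np.diff(r) > 0).all()
            # forward and inverse interpolants are built from the same
            # knots but are not exact inverses off-knot: consistency to 2%
            e_back = tab.energy_at_residual_range(r, particle)
            np.testing.assert_allclose(e_back, grid, rtol=0.02)

    def test_residual_energy_vanishes_at_zero_range(self):
        tab = tables()
        assert tab.energy_at_residual_range(0.0, "alpha") == 0.0
        small = tab.energy_at_residual_range(1e-9, "electron")
        assert 0 < small < 1e-3

    def test_absorb_probability_limits(self):
        tab = tables()
        assert tab.absorb_probability(0.01) > 0.8  # photoelectric regime
        assert tab.absorb_probability(1.0) < 0.1  # Compton regime


def _sphere_geom(n_caps=30, organ_r=25.0, cap_r=0.4, seed=0):
    mats = vd.brain_materials("female")
    rng = np.random.default_rng(seed)
    p0 = rng.normal(size=(n_caps, 3))
    p0 = p0 / np.linalg.norm(p0, axis=1, keepdims=True) * rng.uniform(0, 14, (n_caps, 1))
    d = rng.normal(size=(n_caps, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    p1 = p0 + d * rng.uniform(3, 6, (n_caps, 1))
    caps = CapsuleSet(p0, p1, np.full(n_caps, cap_r))
    return TransportGeometry(Ellipsoid([organ_r] * 3), caps, mats)


CFG = TransportConfig(max_histories=4000, min_histories=4000)


class TestChargedTransport:
    def test_energy_conserved_per_history(self):
        geom = _sphere_geom()
        res = vd.transport_alpha(geom, "BIBV", 5.0, CFG, np.random.default_rng(1))
        assert res.max_residual < 1e-6

    def test_alpha_self_absorption_in_vessels(self):
        """5 MeV alphas (range ~50 um in water) from inside 0.4 mm vessels
        stay there: the cross AF to tissue is nearly zero."""
        geom = _sphere_geom()
        res = vd.transport_alpha(geom, "BIBV", 5.0, CFG, np.random.default_rng(1))
        assert res.af["BOBV"] < 0.05
        assert res.af["BIBV"] > 0.93

    def test_short_range_self_af_approaches_one(self):
        mats = vd.brain_materials("female")
        geom = TransportGeometry(Ellipsoid([25.0] * 3), None, mats)
        res = vd.transport_alpha(geom, "B", 0.5, CFG, np.random.default_rng(2))
        assert res.af["B"] > 0.999

    def test_low_energy_electron_blood_self_dose(self):
        geom = _sphere_geom()
        res = vd.transport_electron(geom, "BIBV", 0.01, CFG, np.random.default_rng(3))
        assert res.af["BIBV"] > 0.95

    def test_positron_reuses_electron_physics(self):
        geom = _sphere_geom()
        e = vd.transport_electron(geom, "BIBV", 1.0, CFG, np.random.default_rng(5))
        p = vd.transport_electron(
            geom, "BIBV", 1.0, CFG, np.random.default_rng(5), positron=True
        )
        assert p.af["BIBV"] == pytest.approx(e.af["BIBV"], rel=5e-3)

    def test_slab_af_matches_quadrature(self):
        """MC electron AF in a 2 mm slab agrees with the closed-form
        escape integral within 3 sigma."""
        mats = vd.brain_materials("female")
        geom = TransportGeometry(Slab(2.0), None, {"B": mats["B"]})
        tab = tables()
        e0 = 0.5
        r0 = float(tab.csda_range(e0, "electron"))
        rho = mats["B"].density_g_cm3

        def escape(mu, z):
            if abs(mu) < 1e-12:
                return 0.0
            d_mm = (2.0 - z) / mu if mu > 0 else z / (-mu)
            tau = rho * d_mm / 10.0
            if tau >= r0:
                return 0.0
            return float(tab.energy_at_residual_range(r0 - tau, "electron"))

        val, _ = integrate.dblquad(escape, 0, 2.0, -1, 1, epsabs=1e-9)
        af_ref = 1.0 - val / (2.0 * 2.0 * e0)
        cfg = TransportConfig(max_histories=20000, min_histories=20000)
        res = vd.transport_electron(geom, "B", e0, cfg, np.random.default_rng(7))
        sigma = res.af["B"] * res.rel_err["B"]
        assert abs(res.af["B"] - af_ref) < 3 * sigma


class TestPhotonTransport:
    def test_optically_thick_low_energy(self):
        mats = vd.brain_materials("female")
        geom = TransportGeometry(Ellipsoid([40.0] * 3), None, mats)
        res = vd.transport_photon(geom, "B", 0.01, CFG, np.random.default_rng(1))
        assert res.af["B"] > 0.95
        assert res.max_residual < 1e-6

    def test_first_flight_lower_bound(self):
        """The MC AF exceeds the analytic first-collision absorption bound
        (energy deposited at the first interaction alone)."""
        mats = vd.brain_materials("female")
        R = 25.0
        geom = TransportGeometry(Ellipsoid([R] * 3), None, mats)
        e0 = 0.1
        tab = tables()
        rho = mats["B"].density_g_cm3
        mu = float(tab.mu_over_rho(e0)) * rho / 10.0  # 1/mm
        muen = float(tab.muen_over_rho(e0)) * rho / 10.0
        # lower bound: uniform+isotropic first-flight energy absorption
        rng = np.random.default_rng(0)
        pts = geom.organ.sample(20000, rng)
        dirs = rng.normal(size=(20000, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        b = np.einsum("ij,ij->i", pts, dirs)
        chord = -b + np.sqrt(b**2 + (R**2 - (pts**2).sum(axis=1)))
        bound = (muen / mu * (1 - np.exp(-mu * chord))).mean()
        res = vd.transport_photon(geom, "B", e0, CFG, np.random.default_rng(9))
        assert res.af["B"] >= 0.9 * bound

    def test_reciprocity_in_homogeneous_geometry(self):
        """AF(A<-B) m_B ~ AF(B<-A) m_A for photons when both regions share
        one material (pure geometry symmetry)."""
        mats = vd.brain_materials("female")
        same = {
            "BIBV": mats["B"],
            "BOBV": mats["B"],
        }
        rng = np.random.default_rng(4)
        p0 = rng.uniform(-10, 10, (20, 3))
        d = rng.normal(size=(20, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        caps = CapsuleSet(p0, p0 + 4 * d, np.full(20, 1.5))
        geom = TransportGeometry(Ellipsoid([25.0] * 3), caps, same)
        cfg = TransportConfig(max_histories=30000, min_histories=30000)
        ab = vd.transport_photon(geom, "BIBV", 0.05, cfg, np.random.default_rng(11))
        ba = vd.transport_photon(geom, "BOBV", 0.05, cfg, np.random.default_rng(12))
        v_caps = caps.volumes_mm3().sum()
        v_organ = geom.organ.volume_mm3()
        lhs = ab.af["BOBV"] * v_caps       # AF(BOBV<-BIBV) * m_BIBV
        rhs = ba.af["BIBV"] * (v_organ - v_caps)
        sigma = 3 * (
            ab.af["BOBV"] * ab.rel_err["BOBV"] * v_caps
            + ba.af["BIBV"] * ba.rel_err["BIBV"] * (v_organ - v_caps)
        )
        assert abs(lhs - rhs) < max(sigma, 0.02 * max(lhs, rhs))

    def test_af_sums_to_unity_with_escape(self):
        geom = _sphere_geom()
        res = vd.transport_photon(geom, "BOBV", 0.5, CFG, np.random.default_rng(2))
        total = sum(res.af.values()) + res.escape_fraction
        assert total == pytest.approx(1.0, abs=1e-9)


class TestTallyStatistics:
    def test_relative_error_matches_batch_variance(self):
        """The per-history error estimator agrees with the spread of
        independent batch means over 10 batches."""
        mats = vd.brain_materials("female")
        geom = TransportGeometry(Ellipsoid([25.0] * 3), None, mats)
        cfg = TransportConfig(max_histories=2000, min_histories=2000)
        afs = []
        for k in range(10):
            r = vd.transport_photon(geom, "B", 0.1, cfg, np.random.default_rng(100 + k))
            afs.append(r.af["B"])
        batch_rel = np.std(afs, ddof=1) / np.mean(afs)
        est_rel = r.rel_err["B"]
        assert est_rel == pytest.approx(batch_rel, rel=0.8)


def test_capsule_sampling_stays_inside():
    rng = np.random.default_rng(0)
    caps = CapsuleSet(
        np.array([[0.0, 0, 0], [5, 5, 5]]),
        np.array([[0.0, 0, 10], [9, 5, 5]]),
        np.array([0.5, 1.0]),
    )
    pts = caps.sample(5000, rng)
    assert caps.contains(pts).all()
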