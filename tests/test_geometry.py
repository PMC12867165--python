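"""Region sampling, terminal budgeting and the marching-tet mesher."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import vasodose as vd
from vasodose.geometry import TetModel, clip_tets, ellipsoid_slab_mesh, tet_volumes


class TestSampling:
    def test_points_inside_unit_sphere(self, sphere_region):
        pts = vd.sample_points_in_region(sphere_region, 100, seed=0)
        assert pts.shape == (100, 3)
        assert (np.linalg.norm(pts, axis=1) < 1.0).all()

    def test_shell_density_matches_volume_ratio(self):
        """Points in a shell are uniform: the fraction inside r<0.8 matches
        the closed-form volume ratio (0.8^3-0.5^3)/(1-0.5^3) = 0.4423."""

        def inside(p):
            r = np.linalg.norm(np.atleast_2d(p), axis=1)
            return (r < 1.0) & (r > 0.5)

        shell = vd.RegionDomain(
            name="shell", inside_fn=inside,
            margin_fn=lambda p: np.minimum(
                1.0 - np.linalg.norm(np.atleast_2d(p), axis=1),
                np.linalg.norm(np.atleast_2d(p), axis=1) - 0.5,
            ),
            bounds=np.array([[-1.0, -1.0, -1.0], [1.0, 1.0, 1.0]]),
        )
        pts = vd.sample_points_in_region(shell, 4000, seed=3)
        frac = (np.linalg.norm(pts, axis=1) < 0.8).mean()
        expect = (0.8**3 - 0.5**3) / (1 - 0.5**3)
        # 4 sigma binomial band
        assert abs(frac - expect) < 4 * np.sqrt(expect * (1 - expect) / 4000)

    def test_same_seed_reproduces_points(self, sphere_region):
        a = vd.sample_points_in_region(sphere_region, 50, seed=11)
        b = vd.sample_points_in_region(sphere_region, 50, seed=11)
        np.testing.assert_array_equal(a, b)

    def test_uniformity_chi_square_octants(self, sphere_region):
        pts = vd.sample_points_in_region(sphere_region, 10_000, seed=5)
        octant = (
            (pts[:, 0] > 0).astype(int) * 4
            + (pts[:, 1] > 0).astype(int) * 2
            + (pts[:, 2] > 0).astype(int)
        )
        counts = np.bincount(octant, minlength=8)
        _, p = stats.chisquare(counts)
        assert p > 0.01

    def test_infeasible_region_raises(self):
        region = vd.RegionDomain(
            name="void",
            inside_fn=lambda p: np.zeros(len(np.atleast_2d(p)), bool),
            bounds=np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0]]),
        )
        with pytest.raises(RuntimeError):
            vd.sample_points_in_region(region, 10, seed=0, max_retries=3)


class TestBudget:
    @pytest.mark.parametrize(
        "fracs,total,expect",
        [
            ([0.5, 0.5], 10, [5, 5]),
            ([0.5, 0.3, 0.2], 7, [4, 2, 1]),  # largest remainder by hand
        ],
    )
    def test_examples(self, fracs, total, expect):
        assert vd.allocate_terminal_budget(fracs, total).tolist() == expect

    def test_reference_territory_fractions_conserve_total(self):
        from vasodose.fixtures import AFB_PTBV, _bilateral_fractions

        fracs = list(_bilateral_fractions(AFB_PTBV).values())
        counts = vd.allocate_terminal_budget(fracs, 1000)
        assert counts.sum() == 1000
        assert len(counts) == 13

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(0.01, 1.0), min_size=1, max_size=12),
        st.integers(0, 500),
    )
    def test_total_always_conserved(self, fracs, total):
        counts = vd.allocate_terminal_budget(fracs, total)
        assert counts.sum() == total
        assert (counts >= 0).all()


def _cyl(p):
    p = np.atleast_2d(p)
    return (p[:, 0] ** 2 + p[:, 1] ** 2 < 1.0) & (np.abs(p[:, 2]) < 5.0)


def _box(p):
    p = np.atleast_2d(p)
    return (np.abs(p[:, 0]) < 2) & (np.abs(p[:, 1]) < 2) & (np.abs(p[:, 2]) < 6)


class TestTetrahedralize:
    def test_clip_pieces_tile_each_tet_exactly(self):
        """Marching-tet decomposition conserves volume tet by tet."""
        rng = np.random.default_rng(0)
        verts = rng.normal(size=(40, 3))
        tets = rng.integers(0, 40, size=(25, 4))
        tets = tets[tet_volumes(verts, tets) > 1e-6]
        plane = lambda p: np.atleast_2d(p)[:, 0] + 0.3 * np.atleast_2d(p)[:, 1] < 0.1
        v2, t_in, t_out = clip_tets(verts, tets, plane)
        before = tet_volumes(verts, tets).sum()
        after = tet_volumes(v2, t_in).sum() + tet_volumes(v2, t_out).sum()
        assert after == pytest.approx(before, rel=1e-9)

    def test_cylinder_volume_within_half_percent(self):
        tm = vd.tetrahedralize(
            _box, _cyl, np.array([[-2.2, -2.2, -6.2], [2.2, 2.2, 6.2]]), 0.15
        )
        v = tm.volume(TetModel.TAG_BIBV)
        assert v == pytest.approx(np.pi * 10.0, rel=5e-3)
        v2 = tm.volume(TetModel.TAG_BOBV)
        assert v2 == pytest.approx(4 * 4 * 12 - np.pi * 10.0, rel=5e-3)
        assert (tm.tet_volumes() > 0).all()

    def test_empty_vessel_set_tags_everything_bobv(self):
        def sph(p):
            return (np.atleast_2d(p) ** 2).sum(axis=1) < 25.0

        tm = vd.tetrahedralize(
            sph, None, np.array([[-5.5, -5.5, -5.5], [5.5, 5.5, 5.5]]), 0.4
        )
        assert (tm.tags == TetModel.TAG_BOBV).all()
        assert tm.volume() == pytest.approx(4 / 3 * np.pi * 125, rel=5e-3)

    def test_writers_roundtrip_counts(self, tmp_path):
        def sph(p):
            return (np.atleast_2d(p) ** 2).sum(axis=1) < 4.0

        tm = vd.tetrahedralize(
            sph, None, np.array([[-2.3, -2.3, -2.3], [2.3, 2.3, 2.3]]), 0.5
        )
        tm.write_msh(str(tmp_path / "m.msh"))
        tm.write_tetgen(str(tmp_path / "m"))
        msh = (tmp_path / "m.msh").read_text().splitlines()
        assert msh[msh.index("$Nodes") + 1] == str(len(tm.nodes))
        ele = (tmp_path / "m.ele").read_text().splitlines()
        assert ele[0].split()[0] == str(len(tm.tets))

    def test_non_watertight_mesh_rejected(self):
        import trimesh

        from vasodose.geometry import tetrahedralize_mesh

        mesh = trimesh.creation.icosphere(subdivisions=1)
        mesh.faces = mesh.faces[:-2]  # open it up
        with pytest.raises(ValueError, match="open edges"):
            tetrahedralize_mesh(mesh, None, 0.5)


def test_ellipsoid_slab_mesh_watertight_and_volumetric():
    semi = (10.0, 8.0, 6.0)
    mesh = ellipsoid_slab_mesh(semi, -3.0, 4.0, n_theta=96, n_x=24)
    assert mesh.is_watertight
    a = 10.0

    def cdf(x):
        return ((x + a) - (x**3 + a**3) / (3 * a**2)) / (4 * a / 3)

    expect = 4 / 3 * np.pi * 10 * 8 * 6 * (cdf(4.0) - cdf(-3.0))
    assert mesh.volume == pytest.approx(expect, rel=5e-3)
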