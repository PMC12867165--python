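"""CCO tree growth: Murray radii, constraints, determinism, repair."""

import numpy as np
import pytest

import vasodose as vd
from vasodose.cco import (
    EntrySpec,
    Tree,
    candidate_connection,
    repair_intersections,
    seg_seg_distance,
)
from vasodose.hemodynamics import MLMIN_TO_M3S, MM_TO_M


class TestMurray:
    def test_symmetric_bifurcation(self):
        assert vd.murray_parent_radius(1.0, 1.0) == pytest.approx(2 ** (1 / 3))

    def test_hand_value(self):
        assert vd.murray_parent_radius(0.5, 0.3) == pytest.approx(0.5337, abs=1e-4)

    def test_single_daughter_passthrough(self):
        assert vd.murray_parent_radius(0.7) == 0.7

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            vd.murray_parent_radius(0.0, 0.3)


def _toy_entry(flow=4.0):
    return EntrySpec(
        point=np.array([0.0, 0.0, 0.0]),
        radius_mm=1.0,
        flow_ml_min=flow,
        entry_pressure_mmhg=90.0,
        terminal_pressure_mmhg=60.0,
    )


class TestTreeStructure:
    def test_single_terminal_single_segment(self, sphere_region):
        entry = _toy_entry(1.0)
        entry.point = np.array([0.0, 0.0, -1.0])
        tree = vd.grow_tree(
            sphere_region, entry, np.array([[0.0, 0.0, 0.0]]), None,
            vd.GrowthConfig(terminal_margin_mm=0.0),
        )
        assert tree.n == 1
        assert tree.n_terminals == 1

    def test_balanced_four_terminal_root_radius(self):
        """Splitting down to 4 equal terminals gives root radius 4^(1/3) r_t."""
        tree = Tree("toy", "artery", _toy_entry(), q_t_ml_min=1.0)
        tree.add_root(np.array([0.0, 0.0, 40.0]))
        tree.split_attach(0, np.array([0.0, 0.0, 20.0]), np.array([20.0, 0.0, 30.0]))
        tree.split_attach(1, np.array([0.0, 0.0, 30.0]), np.array([-20.0, 0.0, 40.0]))
        tree.split_attach(2, np.array([10.0, 0.0, 25.0]), np.array([25.0, 10.0, 25.0]))
        assert tree.n_terminals == 4
        assert tree.n == 2 * 4 - 1
        r = tree.radii()
        assert r[0] / tree.r_t == pytest.approx(4 ** (1 / 3))

    def test_radius_proportional_to_cube_root_of_flow(self, small_vasculature):
        """Within a tree, Murray's law makes radius scale as flow^(1/3)."""
        tree = small_vasculature.trees[0]
        r = tree.radii()
        q = tree.flows()
        np.testing.assert_allclose(r, tree.r_t * (q / tree.q_t) ** (1 / 3), rtol=1e-12)

    def test_segment_count_identity_all_trees(self, small_vasculature):
        for tree in small_vasculature.trees:
            assert tree.n == 2 * tree.n_terminals - 1


class TestCalibration:
    def test_mean_path_pressure_drop_matches_boundary(self, small_vasculature):
        """Flow-weighted mean root-terminal Poiseuille drop equals the
        entry-terminal pressure difference within 1%."""
        tree = small_vasculature.trees[0]
        mu = tree.viscosity
        L = tree.lengths() * MM_TO_M
        r = tree.radii() * MM_TO_M
        q = tree.flows() * MLMIN_TO_M3S
        seg_dp = 8 * mu * L * q / (np.pi * r**4)
        # accumulate drop along each root->terminal path, average over terminals
        drops = np.zeros(tree.n)
        order = [i for i in range(tree.n) if tree.parent[i] < 0]
        stack = list(order)
        while stack:
            i = stack.pop()
            p = tree.parent[i]
            drops[i] = (drops[p] if p >= 0 else 0.0) + seg_dp[i]
            stack.extend(int(c) for c in tree.child[i] if c >= 0)
        mean_drop = drops[tree.is_terminal()].mean()
        assert mean_drop == pytest.approx(tree.entry.delta_p_pa, rel=0.01)

    def test_update_radii_requires_positive_flow(self):
        tree = Tree("toy", "artery", _toy_entry(), q_t_ml_min=-1.0)
        tree.add_root(np.array([0, 0, 30.0]))
        with pytest.raises(ValueError):
            vd.update_radii(tree)


class TestGrowth:
    def test_full_audit_clean_on_grown_fixture(self, fixture4, small_vasculature):
        report = vd.audit_vasculature(small_vasculature, fixture4)
        assert report.ok, report.as_dict()
        assert report.min_bifurcation_angle_deg >= 30.0

    def test_murray_residual_negligible(self, fixture4, small_vasculature):
        report = vd.audit_vasculature(small_vasculature, fixture4)
        murray = next(c for c in report.checks if c.name == "murray_law")
        assert murray.worst < 1e-9

    def test_artery_and_vein_share_terminal_points(self, small_vasculature):
        trees = {(t.region_name, t.side): t for t in small_vasculature.trees}
        for (region, side), tree in trees.items():
            if side != "artery":
                continue
            vein = trees[(region, "vein")]
            vt = vein.dist[: vein.n][vein.is_terminal()]
            at = tree.dist[: tree.n][tree.is_terminal()]
            # every arterial terminal coincides with a venous terminal
            d = np.linalg.norm(at[:, None, :] - vt[None, :, :], axis=2).min(axis=1)
            assert (d < 1e-9).sum() >= 0.9 * len(at)

    def test_deterministic_regrowth_byte_identical(self, fixture4, tmp_path):
        kw = dict(total_terminals=40, cfg=vd.GrowthConfig(seed=7))
        a = vd.build_organ_vasculature(fixture4, kw["total_terminals"], kw["cfg"])
        b = vd.build_organ_vasculature(fixture4, kw["total_terminals"], kw["cfg"])
        fa, fb = tmp_path / "a.csv", tmp_path / "b.csv"
        a.to_csv(str(fa))
        b.to_csv(str(fb))
        assert fa.read_bytes() == fb.read_bytes()


class TestCandidateConnection:
    def test_matches_exhaustive_search_on_toy_tree(self):
        R = 30.0

        def inside(p):
            return (np.atleast_2d(p) ** 2).sum(axis=1) < R**2

        def margin(p):
            return R - np.linalg.norm(np.atleast_2d(p), axis=1)

        region = vd.RegionDomain(
            name="ball", inside_fn=inside, margin_fn=margin,
            bounds=np.array([[-R] * 3, [R] * 3]),
        )
        entry = EntrySpec(
            point=np.array([0.0, 0.0, -R]),
            radius_mm=1.0,
            flow_ml_min=5.0,
            entry_pressure_mmhg=90.0,
            terminal_pressure_mmhg=60.0,
        )
        pts = vd.sample_points_in_region(region, 6, seed=9) * 0.8
        cfg = vd.GrowthConfig(terminal_margin_mm=0.0, clearance_mm=0.001)
        tree = vd.grow_tree(region, entry, pts, None, cfg)
        new_terminal = np.array([9.0, -6.0, 12.0])
        sphere_region = region
        res_k = candidate_connection(tree, sphere_region, new_terminal, vd.ObstacleSet(), cfg)
        res_all = candidate_connection(
            tree, sphere_region, new_terminal, vd.ObstacleSet(), cfg,
            k_nearest=tree.n,
        )
        assert res_k is not None and res_all is not None
        assert res_k[0] == res_all[0]
        assert res_k[2] == pytest.approx(res_all[2])

    def test_unconnectable_terminal_dropped_with_warning(self, sphere_region, caplog):
        entry = _toy_entry(1.0)
        entry.point = np.array([0.0, 0.0, -1.0])
        # second terminal identical to the first: zero-length candidate
        pts = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        import logging

        with caplog.at_level(logging.WARNING, logger="vasodose.cco"):
            tree = vd.grow_tree(
                sphere_region, entry, pts, None, vd.GrowthConfig(terminal_margin_mm=0.0)
            )
        assert len(tree.dropped) == 1
        assert any("dropped" in r.message for r in caplog.records)


class TestRepair:
    def _two_crossing_trees(self, depth=0.1):
        r = 0.3
        ta = Tree("r", "artery", _toy_entry(1.0), 1.0)
        ta.entry.point = np.array([0.0, 0.0, 0.0])
        ta.add_root(np.array([0.0, 0.0, 10.0]))
        tb = Tree("r", "vein", _toy_entry(1.0), 1.0)
        tb.entry.point = np.array([-5.0, 2 * r - depth, 5.0])
        tb.add_root(np.array([5.0, 2 * r - depth, 5.0]))
        # pin radii so the capsules overlap by `depth`
        ta.r_t = tb.r_t = r
        ta.calibrate = lambda: None
        tb.calibrate = lambda: None
        return ta, tb

    def test_translation_resolves_shallow_crossing(self):
        ta, tb = self._two_crossing_trees(0.1)
        report = repair_intersections([ta, tb], None, vd.GrowthConfig())
        assert report["violations_before"] == 1
        assert report["violations_after"] == 0
        assert report["flagged"] == []

    def test_identity_on_clean_input(self):
        ta, tb = self._two_crossing_trees(-0.5)  # well separated
        before = tb.dist[0].copy()
        report = repair_intersections([ta, tb], None, vd.GrowthConfig())
        assert report["violations_before"] == 0
        np.testing.assert_array_equal(tb.dist[0], before)

    def test_repair_preserves_murray(self, fixture4, small_vasculature):
        report = vd.audit_vasculature(small_vasculature, fixture4)
        murray = next(c for c in report.checks if c.name == "murray_law")
        assert murray.passed


def test_seg_seg_distance_known_cases():
    d = seg_seg_distance(
        np.array([0.0, 0.0, 0.0]), np.array([1.0, 0.0, 0.0]),
        np.array([[0.0, 1.0, 1.0], [2.0, 0.0, 0.0]]),
        np.array([[1.0, 1.0, 1.0], [3.0, 0.0, 0.0]]),
    )
    assert d[0] == pytest.approx(np.sqrt(2.0))
    assert d[1] == pytest.approx(1.0)
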