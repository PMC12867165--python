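"""Strahler-order morphometry and regression analyses of generated trees.

Terminal segments have order 1; a bifurcation's order increments only
when both daughters share the same order, otherwise it inherits the
larger daughter order.  For counting, maximal chains of same-order
segments are collapsed into one *vessel* (the standard Strahler
convention); both the collapsed-vessel and raw-segment statistics are
reported, the collapsed one being primary.

Three regressions mirror the customary morphometric analyses: log10 of
the vessel count against order, log10 of the mean vessel diameter
against order, and the along-centerline curve path of each terminal
endpoint against its Euclidean distance to the tree entry.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "strahler_order",
    "collapse_vessels",
    "FitResult",
    "fit_loglinear",
    "StrahlerSummary",
    "strahler_summary",
    "path_vs_euclidean",
]


def strahler_order(tree) -> np.ndarray:
    """Per-segment Strahler order of a binary tree."""
    n = tree.n
    child = tree.child[:n]
    order = np.zeros(n, dtype=int)
    # process children before parents: sort by decreasing depth
    depth = np.zeros(n, dtype=int)
    for i in range(n):
        p = tree.parent[i]
        depth[i] = depth[p] + 1 if p >= 0 else 0
    for i in sorted(range(n), key=lambda k: -depth[k]):
        c1, c2 = child[i]
        if c1 < 0 and c2 < 0:
            order[i] = 1
        elif c1 >= 0 and c2 >= 0:
            o1, o2 = order[c1], order[c2]
            order[i] = o1 + 1 if o1 == o2 else max(o1, o2)
        else:
            raise ValueError(f"segment {i}: non-binary node")
    return order


def collapse_vessels(tree, order: np.ndarray) -> np.ndarray:
    """Vessel id per segment: same-order parent-child chains share an id."""
    n = tree.n
    vessel = np.full(n, -1, dtype=int)
    next_id = 0
    depth_order = sorted(range(n), key=lambda k: _depth(tree, k))
    for i in depth_order:
        p = tree.parent[i]
        if p >= 0 and order[p] == order[i]:
            vessel[i] = vessel[p]
        else:
            vessel[i] = next_id
            next_id += 1
    return vessel


def _depth(tree, i: int) -> int:
    d = 0
    while tree.parent[i] >= 0:
        i = tree.parent[i]
        d += 1
    return d


@dataclasses.dataclass
class FitResult:
    slope: float
    intercept: float
    r2: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, float)


def fit_loglinear(orders: np.ndarray, y: np.ndarray) -> FitResult:
    """Ordinary least squares of log10(y) against the Strahler order."""
    orders = np.asarray(orders, float)
    y = np.asarray(y, float)
    if len(np.unique(orders)) < 3:
        raise ValueError("need at least 3 distinct orders for a fit")
    if np.any(y <= 0):
        raise ValueError("log fit requires positive values")
    res = stats.linregress(orders, np.log10(y))
    return FitResult(float(res.slope), float(res.intercept), float(res.rvalue**2))


@dataclasses.dataclass
class StrahlerSummary:
    """Pooled per-order statistics plus the two log-linear fits."""

    orders: np.ndarray
    vessel_counts: np.ndarray
    segment_counts: np.ndarray
    mean_diameter_vessels_mm: np.ndarray
    mean_diameter_segments_mm: np.ndarray
    count_fit: FitResult
    diameter_fit: FitResult

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "order": self.orders,
                "vessel_count": self.vessel_counts,
                "segment_count": self.segment_counts,
                "mean_diameter_vessels_mm": self.mean_diameter_vessels_mm,
                "mean_diameter_segments_mm": self.mean_diameter_segments_mm,
            }
        )

    def as_dict(self) -> dict:
        return {
            "orders": self.orders.tolist(),
            "vessel_counts": self.vessel_counts.tolist(),
            "segment_counts": self.segment_counts.tolist(),
            "mean_diameter_vessels_mm": self.mean_diameter_vessels_mm.tolist(),
            "mean_diameter_segments_mm": self.mean_diameter_segments_mm.tolist(),
            "count_fit": dataclasses.asdict(self.count_fit),
            "diameter_fit": dataclasses.asdict(self.diameter_fit),
        }


def strahler_summary(trees) -> StrahlerSummary:
    """Pool Strahler statistics over a list of trees and fit both laws."""
    per_order_vessels: dict[int, int] = {}
    per_order_segments: dict[int, int] = {}
    diam_v: dict[int, list[float]] = {}
    diam_s: dict[int, list[float]] = {}
    total_segments = 0
    for tree in trees:
        order = strahler_order(tree)
        vessel = collapse_vessels(tree, order)
        radii = tree.radii()
        total_segments += tree.n
        for o in np.unique(order):
            sel = order == o
            vids = np.unique(vessel[sel])
            per_order_vessels[o] = per_order_vessels.get(o, 0) + len(vids)
            per_order_segments[o] = per_order_segments.get(o, 0) + int(sel.sum())
            diam_s.setdefault(o, []).extend((2 * radii[sel]).tolist())
            for v in vids:
                diam_v.setdefault(o, []).append(
                    float(np.mean(2 * radii[vessel == v]))
                )
    orders = np.array(sorted(per_order_vessels))
    vc = np.array([per_order_vessels[o] for o in orders])
    sc = np.array([per_order_segments[o] for o in orders])
    assert sc.sum() == total_segments
    dv = np.array([np.mean(diam_v[o]) for o in orders])
    ds = np.array([np.mean(diam_s[o]) for o in orders])
    return StrahlerSummary(
        orders=orders,
        vessel_counts=vc,
        segment_counts=sc,
        mean_diameter_vessels_mm=dv,
        mean_diameter_segments_mm=ds,
        count_fit=fit_loglinear(orders, vc),
        diameter_fit=fit_loglinear(orders, dv),
    )


def path_vs_euclidean(
    trees, terminals_only: bool = False
) -> tuple[np.ndarray, np.ndarray, FitResult]:
    """Curve-path vs Euclidean distance of vessel endpoints to the entry.

    Every generated vessel contributes the along-centerline distance of
    its distal endpoint to the tree entry against the corresponding
    straight-line distance (``terminals_only`` restricts the analysis to
    terminal endpoints).  Returns the pooled ``(path, euclidean)`` pairs
    and the least-squares line ``path = a + b * euclidean``; the path
    can never be shorter than the chord.
    """
    paths, euclids = [], []
    for tree in trees:
        sel = tree.is_terminal() if terminals_only else np.ones(tree.n, dtype=bool)
        pl = tree.path_lengths_to_entry()[sel]
        entry = tree.entry.point
        eu = np.linalg.norm(tree.dist[: tree.n][sel] - entry[None, :], axis=1)
        paths.append(pl)
        euclids.append(eu)
    path = np.concatenate(paths)
    euclid = np.concatenate(euclids)
    if len(path) < 3 or np.allclose(euclid, euclid[0]):
        return path, euclid, FitResult(1.0, 0.0, 1.0)
    res = stats.linregress(euclid, path)
    return path, euclid, FitResult(
        float(res.slope), float(res.intercept), float(res.rvalue**2)
    )
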