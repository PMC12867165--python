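"""Closed-mesh region domains, point sampling, and tetrahedral export.

Geometry lives in millimetres in a right-handed frame.  A region of an
organ is described by a closed triangular surface plus an optional fast
analytic containment predicate (the synthetic fixtures provide one; for
arbitrary meshes the predicate falls back to ray-parity containment via
``trimesh``).  The tetrahedralizer is predicate based: it builds a Kuhn
lattice over the bounding box and clips boundary-crossing tetrahedra with
a marching-tetrahedra decomposition, locating surface crossings by
bisection.  The clip is exact for the piecewise-linear approximation, so
per-tag volumes converge as O(h^2) with the lattice spacing h.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
import trimesh

__all__ = [
    "RegionDomain",
    "TetModel",
    "sample_points_in_region",
    "allocate_terminal_budget",
    "tetrahedralize",
    "ellipsoid_slab_mesh",
    "load_surface",
    "save_surface",
]

PointPredicate = Callable[[np.ndarray], np.ndarray]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RegionDomain:
    """A named closed volume in which one vascular tree per side is grown.

    Parameters
    ----------
    name:
        Region label (e.g. ``"frontal_lobe_L"``).
    surface:
        Closed 2-manifold triangular mesh bounding the region (mm).
    voids:
        Meshes to exclude from the region interior.
    volume_fraction_target:
        Dimensionless fraction of total organ volume this region should
        occupy (the PTBV bookkeeping value).
    entry_points:
        Mapping ``side -> 3-vector`` of tree entry points on the region
        boundary, with sides ``"artery"`` and ``"vein"``.
    inside_fn, margin_fn:
        Optional analytic containment predicate and interior-margin
        function (a conservative lower bound on the distance to the
        region boundary, positive inside).  Supplied by the synthetic
        fixture; when absent, mesh-based fallbacks are used.
    """

    name: str
    surface: trimesh.Trimesh | None = None
    voids: list = dataclasses.field(default_factory=list)
    volume_fraction_target: float | None = None
    entry_points: dict = dataclasses.field(default_factory=dict)
    inside_fn: PointPredicate | None = None
    margin_fn: Callable[[np.ndarray], np.ndarray] | None = None
    void_fns: list = dataclasses.field(default_factory=list)
    bounds: np.ndarray | None = None

    @property
    def entry_point(self) -> np.ndarray | None:
        if "artery" in self.entry_points:
            return np.asarray(self.entry_points["artery"], float)
        if self.entry_points:
            return np.asarray(next(iter(self.entry_points.values())), float)
        return None

    def validate(self) -> None:
        if self.surface is not None:
            if not self.surface.is_watertight:
                raise ValueError(f"region {self.name}: surface is not watertight")
            if self.surface.volume <= 0:
                raise ValueError(f"region {self.name}: non-positive volume")
        if self.volume_fraction_target is not None and not (
            0 < self.volume_fraction_target <= 1
        ):
            raise ValueError(f"region {self.name}: volume fraction out of range")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorized containment: inside the surface, outside all voids."""
        points = np.atleast_2d(np.asarray(points, float))
        if self.inside_fn is not None:
            ok = np.asarray(self.inside_fn(points), bool)
        elif self.surface is not None:
            ok = self.surface.contains(points)
        else:
            raise ValueError(f"region {self.name}: no containment information")
        for fn in self.void_fns:
            ok &= ~np.asarray(fn(points), bool)
        for void in self.voids:
            ok &= ~void.contains(points)
        return ok

    def interior_margin(self, points: np.ndarray) -> np.ndarray:
        """Conservative distance-to-boundary (positive inside)."""
        points = np.atleast_2d(np.asarray(points, float))
        if self.margin_fn is not None:
            return np.asarray(self.margin_fn(points), float)
        if self.surface is None:
            raise ValueError(f"region {self.name}: no margin information")
        from trimesh.proximity import signed_distance

        # trimesh convention: positive inside
        return signed_distance(self.surface, points)

    def aabb(self) -> np.ndarray:
        if self.bounds is not None:
            return np.asarray(self.bounds, float)
        if self.surface is None:
            raise ValueError(f"region {self.name}: no bounds available")
        return np.asarray(self.surface.bounds, float)


@dataclasses.dataclass
class TetModel:
    """A tagged tetrahedral mesh (tags: 1 = BIBV vessel lumen, 2 = BOBV)."""

    nodes: np.ndarray
    tets: np.ndarray
    tags: np.ndarray

    TAG_BIBV = 1
    TAG_BOBV = 2

    def tet_volumes(self) -> np.ndarray:
        return tet_volumes(self.nodes, self.tets)

    def volume(self, tag: int | None = None) -> float:
        vols = self.tet_volumes()
        if tag is None:
            return float(vols.sum())
        return float(vols[self.tags == tag].sum())

    # -- text exports -------------------------------------------------------

    def write_msh(self, path: str) -> None:
        """Write Gmsh MSH 2.2 ASCII with the region tag as physical tag."""
        with open(path, "w") as fh:
            fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
            fh.write(f"$Nodes\n{len(self.nodes)}\n")
            for i, p in enumerate(self.nodes, start=1):
                fh.write(f"{i} {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
            fh.write("$EndNodes\n")
            fh.write(f"$Elements\n{len(self.tets)}\n")
            for i, (tet, tag) in enumerate(zip(self.tets, self.tags), start=1):
                a, b, c, d = (tet + 1).tolist()
                fh.write(f"{i} 4 2 {int(tag)} {int(tag)} {a} {b} {c} {d}\n")
            fh.write("$EndElements\n")

    def write_tetgen(self, prefix: str) -> None:
        """Write TetGen ``.node`` / ``.ele`` files (1-based indices)."""
        with open(prefix + ".node", "w") as fh:
            fh.write(f"{len(self.nodes)} 3 0 0\n")
            for i, p in enumerate(self.nodes, start=1):
                fh.write(f"{i} {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        with open(prefix + ".ele", "w") as fh:
            fh.write(f"{len(self.tets)} 4 1\n")
            for i, (tet, tag) in enumerate(zip(self.tets, self.tags), start=1):
                a, b, c, d = (tet + 1).tolist()
                fh.write(f"{i} {a} {b} {c} {d} {int(tag)}\n")


# ---------------------------------------------------------------------------
# surface I/O
# ---------------------------------------------------------------------------

def load_surface(path: str) -> trimesh.Trimesh:
    mesh = trimesh.load(path, force="mesh")
    if not isinstance(mesh, trimesh.Trimesh):
        raise ValueError(f"{path}: not a triangular surface")
    return mesh


def save_surface(mesh: trimesh.Trimesh, path: str) -> None:
    mesh.export(path)


# ---------------------------------------------------------------------------
# sampling and terminal budgeting
# ---------------------------------------------------------------------------

def sample_points_in_region(
    region: RegionDomain,
    n: int,
    seed: int,
    oversample: float = 4.0,
    max_retries: int = 10,
    min_margin_mm: float = 0.0,
) -> np.ndarray:
    """Draw exactly ``n`` uniform points inside a region.

    Rejection sampling from the axis-aligned bounding box: at each round
    ``oversample * n_missing`` candidates are drawn, mirroring the
    practice of generating more points than needed because many fall
    outside the region.  With ``min_margin_mm > 0`` the points are
    uniform over the region eroded by that margin, so that a vessel of
    that radius can terminate there without leaving the region.
    Reproducible given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    region.validate()
    rng = np.random.default_rng(seed)
    lo, hi = region.aabb()
    out: list[np.ndarray] = []
    got = 0
    for _ in range(max_retries):
        m = int(np.ceil(oversample * (n - got)))
        cand = rng.uniform(lo, hi, size=(m, 3))
        ok = region.contains(cand)
        if min_margin_mm > 0.0:
            ok &= region.interior_margin(cand) >= min_margin_mm
        keep = cand[ok]
        if len(keep):
            out.append(keep)
            got += len(keep)
        if got >= n:
            return np.concatenate(out)[:n]
    raise RuntimeError(
        f"region {region.name}: could not place {n} points in "
        f"{max_retries} rounds (region may be infeasible)"
    )


def allocate_terminal_budget(
    regions: Sequence[RegionDomain] | Sequence[float], total: int
) -> np.ndarray:
    """Split a terminal-point budget across regions proportionally to PTBV.

    Largest-remainder rounding conserves the total exactly; with the
    terminal flow fixed organ-wide this makes the per-terminal blood flow
    equal across regions.
    """
    if total == 0:
        return np.zeros(len(regions), dtype=int)
    fracs = np.array(
        [
            r.volume_fraction_target if isinstance(r, RegionDomain) else float(r)
            for r in regions
        ],
        dtype=float,
    )
    if np.any(np.isnan(fracs)):
        raise ValueError("volume fractions missing for some regions")
    fracs = fracs / fracs.sum()
    ideal = fracs * total
    counts = np.floor(ideal).astype(int)
    short = total - counts.sum()
    # largest remainders win the leftover seats; ties broken by index
    order = np.lexsort((np.arange(len(fracs)), -(ideal - counts)))
    counts[order[:short]] += 1
    assert counts.sum() == total
    return counts


# ---------------------------------------------------------------------------
# marching-tetrahedra clipping
# ---------------------------------------------------------------------------

def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    p = nodes[tets]
    return np.abs(
        np.einsum(
            "ij,ij->i",
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
            p[:, 3] - p[:, 0],
        )
    ) / 6.0


def _bisect_crossing(
    p_in: np.ndarray, p_out: np.ndarray, inside: PointPredicate, iters: int = 35
) -> np.ndarray:
    """Locate the boundary crossing on segments from inside to outside points."""
    a = p_in.astype(float).copy()
    b = p_out.astype(float).copy()
    for _ in range(iters):
        mid = 0.5 * (a + b)
        mi = np.asarray(inside(mid), bool)
        a[mi] = mid[mi]
        b[~mi] = mid[~mi]
    return 0.5 * (a + b)


def clip_tets(
    verts: np.ndarray, tets: np.ndarray, inside: PointPredicate
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split a tet set at an implicit boundary given by ``inside``.

    Returns ``(verts2, tets_in, tets_out)``: vertex-classified tets are
    kept whole; boundary tets are decomposed so the inside/outside pieces
    tile the original tet exactly (the cut quadrilateral is triangulated
    with the same diagonal on both sides).
    """
    verts = np.asarray(verts, float)
    tets = np.asarray(tets, int)
    flags = np.asarray(inside(verts), bool)
    s = flags[tets].sum(axis=1)
    all_in = tets[s == 4]
    all_out = tets[s == 0]
    mixed = tets[(s > 0) & (s < 4)]
    if len(mixed) == 0:
        return verts, all_in, all_out

    new_pts: list[np.ndarray] = []
    in_parts: list[np.ndarray] = []
    out_parts: list[np.ndarray] = []
    base = len(verts)

    def add_points(pi: np.ndarray, po: np.ndarray) -> np.ndarray:
        nonlocal base
        pts = _bisect_crossing(verts2_lookup(pi), verts2_lookup(po), inside)
        idx = np.arange(base, base + len(pts))
        base += len(pts)
        new_pts.append(pts)
        return idx

    def verts2_lookup(idx: np.ndarray) -> np.ndarray:
        return verts[idx]

    # reorder each mixed tet so inside vertices come first
    f = flags[mixed]
    order = np.argsort(~f, axis=1, kind="stable")
    mixed = np.take_along_axis(mixed, order, axis=1)
    smix = f.sum(axis=1)

    for count in (1, 2, 3):
        grp = mixed[smix == count]
        if len(grp) == 0:
            continue
        A, B, C, D = grp[:, 0], grp[:, 1], grp[:, 2], grp[:, 3]
        if count == 1:
            pAB = add_points(A, B)
            pAC = add_points(A, C)
            pAD = add_points(A, D)
            in_parts.append(np.stack([A, pAB, pAC, pAD], axis=1))
            out_parts.append(np.stack([pAB, pAC, pAD, B], axis=1))
            out_parts.append(np.stack([pAC, pAD, B, C], axis=1))
            out_parts.append(np.stack([pAD, B, C, D], axis=1))
        elif count == 3:
            pAD = add_points(A, D)
            pBD = add_points(B, D)
            pCD = add_points(C, D)
            out_parts.append(np.stack([D, pAD, pBD, pCD], axis=1))
            in_parts.append(np.stack([pAD, pBD, pCD, A], axis=1))
            in_parts.append(np.stack([pBD, pCD, A, B], axis=1))
            in_parts.append(np.stack([pCD, A, B, C], axis=1))
        else:  # two inside (A, B), two outside (C, D)
            pAC = add_points(A, C)
            pAD = add_points(A, D)
            pBC = add_points(B, C)
            pBD = add_points(B, D)
            in_parts.append(np.stack([A, pAC, pAD, B], axis=1))
            in_parts.append(np.stack([pAC, pAD, B, pBC], axis=1))
            in_parts.append(np.stack([pAD, B, pBC, pBD], axis=1))
            out_parts.append(np.stack([C, pAC, pBC, D], axis=1))
            out_parts.append(np.stack([pAC, pBC, D, pAD], axis=1))
            out_parts.append(np.stack([pBC, D, pAD, pBD], axis=1))

    verts2 = np.vstack([verts] + new_pts)
    tets_in = (
        np.vstack([all_in] + in_parts) if in_parts else all_in
    )
    tets_out = (
        np.vstack([all_out] + out_parts) if out_parts else all_out
    )
    return verts2, tets_in, tets_out


def _kuhn_lattice(bounds: np.ndarray, h: float) -> tuple[np.ndarray, np.ndarray]:
    """Structured lattice over ``bounds`` split into 6 tets per cube."""
    lo, hi = np.asarray(bounds, float)
    n = np.maximum(np.ceil((hi - lo) / h).astype(int), 1)
    axes = [np.linspace(lo[k], hi[k], n[k] + 1) for k in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    verts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def vid(i, j, k):
        return (i * (n[1] + 1) + j) * (n[2] + 1) + k

    I, J, K = np.meshgrid(
        np.arange(n[0]), np.arange(n[1]), np.arange(n[2]), indexing="ij"
    )
    I, J, K = I.ravel(), J.ravel(), K.ravel()
    c = [vid(I + (b >> 2 & 1), J + (b >> 1 & 1), K + (b & 1)) for b in range(8)]
    # six tets around the main diagonal c0 -> c7
    pattern = [(0, 4, 6, 7), (0, 6, 2, 7), (0, 2, 3, 7),
               (0, 3, 1, 7), (0, 1, 5, 7), (0, 5, 4, 7)]
    tets = np.vstack(
        [np.stack([c[a], c[b], c[cc], c[d]], axis=1) for a, b, cc, d in pattern]
    )
    return verts, tets


def tetrahedralize(
    inside_organ: PointPredicate,
    inside_vessel: PointPredicate | None,
    bounds: np.ndarray,
    h: float,
) -> TetModel:
    """Build a two-region tagged tet mesh from containment predicates.

    ``inside_vessel`` may be ``None`` (degenerate case: everything inside
    the organ is tagged BOBV).  Per-tag volumes conserve the predicate
    volumes to O(h^2); the 0.5 % contract is met by choosing ``h`` small
    against the smallest feature radius.
    """
    verts, tets = _kuhn_lattice(bounds, h)
    verts, tets_in, _ = clip_tets(verts, tets, inside_organ)
    if len(tets_in) == 0:
        raise ValueError("organ predicate is empty inside the given bounds")
    if inside_vessel is None:
        tets_bibv = np.zeros((0, 4), dtype=int)
        tets_bobv = tets_in
    else:
        verts, tets_bibv, tets_bobv = clip_tets(verts, tets_in, inside_vessel)
    tets_all = np.vstack([tets_bibv, tets_bobv])
    tags = np.concatenate(
        [
            np.full(len(tets_bibv), TetModel.TAG_BIBV, dtype=int),
            np.full(len(tets_bobv), TetModel.TAG_BOBV, dtype=int),
        ]
    )
    vols = tet_volumes(verts, tets_all)
    keep = vols > 1e-12
    tets_all, tags = tets_all[keep], tags[keep]
    # compact the vertex array to referenced nodes only
    used, inv = np.unique(tets_all, return_inverse=True)
    tets_all = inv.reshape(tets_all.shape)
    return TetModel(nodes=verts[used], tets=tets_all, tags=tags)


def tetrahedralize_mesh(
    organ: trimesh.Trimesh,
    vessel: trimesh.Trimesh | None,
    h: float,
) -> TetModel:
    """Mesh-input variant; fails with open-edge diagnostics if not watertight."""
    for label, mesh in (("organ", organ), ("vessel", vessel)):
        if mesh is not None and not mesh.is_watertight:
            edges = trimesh.grouping.group_rows(mesh.edges_sorted, require_count=1)
            raise ValueError(
                f"{label} mesh is not watertight; {len(edges)} open edges, "
                f"first few: {mesh.edges_sorted[edges[:5]].tolist()}"
            )
    bounds = organ.bounds + np.array([[-h], [h]])
    vessel_fn = (lambda p: vessel.contains(p)) if vessel is not None else None
    return tetrahedralize(lambda p: organ.contains(p), vessel_fn, bounds, h)


# ---------------------------------------------------------------------------
# watertight ellipsoid-slab surface (used by the synthetic fixture)
# ---------------------------------------------------------------------------

def ellipsoid_slab_mesh(
    semi_axes: Sequence[float],
    x0: float,
    x1: float,
    n_theta: int = 48,
    n_x: int = 12,
) -> trimesh.Trimesh:
    """Closed surface of an ellipsoid sliced by the planes x=x0 and x=x1.

    Built directly from elliptical cross-section rings plus planar cap
    fans, so it is watertight by construction (no boolean operations).
    """
    a, b, c = (float(v) for v in semi_axes)
    eps = 1e-9 * a
    x0 = max(x0, -a + eps)
    x1 = min(x1, a - eps)
    xs = np.linspace(x0, x1, n_x)
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    verts = []
    for x in xs:
        s = np.sqrt(max(1.0 - (x / a) ** 2, 0.0))
        ring = np.stack(
            [np.full(n_theta, x), b * s * np.cos(theta), c * s * np.sin(theta)],
            axis=1,
        )
        verts.append(ring)
    verts = np.vstack(verts)
    faces = []
    for i in range(n_x - 1):
        r0 = i * n_theta
        r1 = (i + 1) * n_theta
        for j in range(n_theta):
            jn = (j + 1) % n_theta
            faces.append([r0 + j, r1 + j, r1 + jn])
            faces.append([r0 + j, r1 + jn, r0 + jn])
    # cap centers
    c0 = len(verts)
    verts = np.vstack([verts, [[x0, 0, 0]], [[x1, 0, 0]]])
    c1 = c0 + 1
    for j in range(n_theta):
        jn = (j + 1) % n_theta
        faces.append([c0, jn, j])  # low-x cap, normal -x
        faces.append([c1, (n_x - 1) * n_theta + j, (n_x - 1) * n_theta + jn])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=True)
    mesh.fix_normals()
    if not mesh.is_watertight:  # pragma: no cover - construction guarantee
        raise RuntimeError("ellipsoid slab construction produced an open mesh")
    return mesh
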