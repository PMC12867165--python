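"""Synthetic brain fixture: an ellipsoidal organ cut into vascular territories.

The fixture emulates the study geometry without any licensed anatomy: a
closed ellipsoid whose volume matches the reference brain mass and
density is partitioned by planes perpendicular to the x axis into
sub-regions whose volume fractions reproduce the reference
percentage-of-total-brain-volume (PTBV) table, with one artificial entry
artery (on the inferior surface) and one entry vein (superior surface)
per sub-region feeding a simple two-level backbone on each side.

Because the slab cut positions are found by inverting the analytic
ellipsoid volume profile, the realized fractions match the requested
ones exactly in the analytic representation and to well under 1 % in the
exported surface meshes.  The geometry is deterministic; the seed only
steers downstream sampling.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import brentq

from .geometry import RegionDomain, ellipsoid_slab_mesh
from .hemodynamics import BackboneVessel, PerfusionSpec

__all__ = [
    "FixtureConfig",
    "BrainFixture",
    "generate_fixture_brain",
    "AFB_PTBV",
    "AMB_PTBV",
    "REFERENCE_BRAIN",
]

# PTBV per vascular territory (% of total brain volume, study segmentation
# values); bilateral structures are split evenly into left/right halves and
# the ventricles are excluded from the vascular partition.
AFB_PTBV = {
    "frontal": 31.0,
    "temporal": 20.8,
    "parietal": 20.2,
    "occipital": 8.7,
    "cerebellum": 10.5,
    "central": 4.6,
    "brainstem": 2.1,
}
AMB_PTBV = {
    "frontal": 31.5,
    "temporal": 21.0,
    "parietal": 20.5,
    "occipital": 7.9,
    "cerebellum": 10.3,
    "central": 5.1,
    "brainstem": 2.0,
}

# reference masses (kg), densities (g/cm^3) and explicitly-modeled blood
# fractions for the two adult reference brains
REFERENCE_BRAIN = {
    "female": {
        "tissue_mass_kg": 1.300,
        "organ_mass_kg": 1.350,
        "organ_density_g_cm3": 1.0407,
        "f_bv": 0.56,
    },
    "male": {
        "tissue_mass_kg": 1.450,
        "organ_mass_kg": 1.517,
        "organ_density_g_cm3": 1.0409,
        "f_bv": 0.47,
    },
}


@dataclasses.dataclass
class FixtureConfig:
    sex: str = "female"
    #: custom fraction map {region name: fraction}; None -> 13-region PTBV split
    fractions: dict[str, float] | None = None
    #: aspect of the ellipsoid (b/a, c/a)
    axis_ratio: tuple[float, float] = (0.78, 0.70)
    build_meshes: bool = False
    mesh_n_theta: int = 64
    mesh_n_x: int = 16
    root_radius_artery_mm: float = 3.0
    root_radius_vein_mm: float = 4.5


@dataclasses.dataclass
class BrainFixture:
    sex: str
    semi_axes: np.ndarray
    regions: list[RegionDomain]
    backbone: list[BackboneVessel]
    backbone_geometry: dict[str, tuple[np.ndarray, np.ndarray]]
    perfusion: PerfusionSpec
    region_fractions: dict[str, float]
    masses: dict[str, float]

    def organ_inside(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points) / self.semi_axes
        return (p**2).sum(axis=1) < 1.0

    @property
    def f_bv(self) -> float:
        return self.masses["f_bv"]


def _bilateral_fractions(table: dict[str, float]) -> dict[str, float]:
    """Split the PTBV table into 13 left/right territories, renormalized."""
    out: dict[str, float] = {}
    for name, val in table.items():
        if name == "brainstem":
            continue
        out[f"{name}_L"] = val / 2.0
    out["brainstem"] = table["brainstem"]
    for name, val in reversed(list(table.items())):
        if name == "brainstem":
            continue
        out[f"{name}_R"] = val / 2.0
    total = sum(out.values())
    return {k: v / total for k, v in out.items()}


def _slab_cuts(fractions: list[float], a: float) -> np.ndarray:
    """x-positions cutting an ellipsoid into slabs of given volume fractions.

    The cumulative slab volume of an ellipsoid up to x is
    pi*b*c*[(x+a) - (x^3+a^3)/(3 a^2)]; only the shape along x matters,
    so the cut positions are independent of b and c.
    """

    def cdf(x: float) -> float:
        return ((x + a) - (x**3 + a**3) / (3 * a**2)) / (4.0 * a / 3.0)

    cum = np.cumsum(fractions)[:-1]
    cuts = [brentq(lambda x, t=t: cdf(x) - t, -a, a, xtol=1e-12 * a) for t in cum]
    return np.concatenate([[-a], cuts, [a]])


#: an x-band thinner than this fraction of the organ cannot host a
#: vascular trunk, so consecutive regions are grouped into one band and
#: separated by y-plane cuts instead
_MIN_BAND_FRACTION = 0.065


def _band_partition(names: list[str], fracs: list[float]) -> list[list[int]]:
    """Group consecutive regions into x-bands of workable thickness."""
    bands: list[list[int]] = []
    current: list[int] = []
    acc = 0.0
    for i, f in enumerate(fracs):
        current.append(i)
        acc += f
        if acc >= _MIN_BAND_FRACTION:
            bands.append(current)
            current, acc = [], 0.0
    if current:
        if bands:
            bands[-1].extend(current)
        else:
            bands.append(current)
    return bands


def _ellipse_segment_area(bx: float, cx: float, y0: float) -> float:
    """Area of the ellipse cross-section with y < y0."""
    if bx <= 0:
        return 0.0
    u = np.clip(y0 / bx, -1.0, 1.0)
    return bx * cx * (np.pi / 2.0 + u * np.sqrt(1.0 - u * u) + np.arcsin(u))


def _y_cuts(
    semi: np.ndarray, x0: float, x1: float, fracs: list[float]
) -> np.ndarray:
    """y-plane positions splitting one x-band into given volume shares."""
    from scipy.integrate import quad

    a, b, c = semi

    def band_volume_below(y0: float) -> float:
        def area(x: float) -> float:
            s2 = max(1.0 - (x / a) ** 2, 0.0)
            s = np.sqrt(s2)
            return _ellipse_segment_area(b * s, c * s, y0)

        return quad(area, x0, x1, limit=100)[0]

    total = band_volume_below(float(semi[1]))
    cum = np.cumsum(fracs)[:-1] / sum(fracs)
    cuts = [
        brentq(lambda y, t=t: band_volume_below(y) - t * total, -b, b, xtol=1e-9)
        for t in cum
    ]
    return np.concatenate([[-b], cuts, [b]])


def _region_domain(
    name: str,
    semi: np.ndarray,
    x0: float,
    x1: float,
    y0: float,
    y1: float,
    frac: float,
    cfg: FixtureConfig,
) -> RegionDomain:
    a, b, c = semi
    min_axis = float(min(semi))
    full_width = y0 <= -b and y1 >= b

    def inside(p: np.ndarray, x0=x0, x1=x1, y0=y0, y1=y1) -> np.ndarray:
        p = np.atleast_2d(p)
        k2 = ((p / semi) ** 2).sum(axis=1)
        ok = (k2 < 1.0) & (p[:, 0] >= x0) & (p[:, 0] < x1)
        if not full_width:
            ok &= (p[:, 1] >= y0) & (p[:, 1] < y1)
        return ok

    def margin(p: np.ndarray, x0=x0, x1=x1, y0=y0, y1=y1) -> np.ndarray:
        # conservative interior distance: the normalized ellipsoid radius k
        # is (1/min_axis)-Lipschitz, so (1-k)*min_axis under-estimates the
        # distance to the ellipsoid; the plane distances are exact.
        p = np.atleast_2d(p)
        k = np.sqrt(((p / semi) ** 2).sum(axis=1))
        parts = [(1.0 - k) * min_axis, p[:, 0] - x0, x1 - p[:, 0]]
        if not full_width:
            parts += [p[:, 1] - y0, y1 - p[:, 1]]
        return np.minimum.reduce(parts)

    xm = 0.5 * (x0 + x1)
    s2 = max(1.0 - (xm / a) ** 2, 1e-9)
    s = np.sqrt(s2)
    # entry at the surface point over the region's footprint centre
    ylo = max(y0, -0.8 * b * s)
    yhi = min(y1, 0.8 * b * s)
    ym = 0.5 * (ylo + yhi)
    z_s = c * np.sqrt(max(s2 - (ym / b) ** 2, 1e-9))
    entry = {
        "artery": np.array([xm, ym, -z_s]),
        "vein": np.array([xm, ym, z_s]),
    }
    surface = None
    if cfg.build_meshes and full_width:
        surface = ellipsoid_slab_mesh(
            semi, x0, x1, n_theta=cfg.mesh_n_theta, n_x=cfg.mesh_n_x
        )
    lo = np.array([x0, max(y0, -b), -c])
    hi = np.array([x1, min(y1, b), c])
    return RegionDomain(
        name=name,
        surface=surface,
        volume_fraction_target=frac,
        entry_points=entry,
        inside_fn=inside,
        margin_fn=margin,
        bounds=np.stack([lo, hi]),
    )


def _backbone(
    regions: list[RegionDomain],
    fractions: dict[str, float],
    semi: np.ndarray,
    cfg: FixtureConfig,
) -> tuple[list[BackboneVessel], dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Two-level rooted backbone per side, radii split by Murray's law."""
    a, b, c = semi
    vessels: list[BackboneVessel] = []
    geometry: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    fr = np.array([fractions[r.name] for r in regions])
    fr = fr / fr.sum()
    for side, z_sign, r_root in (
        ("artery", -1.0, cfg.root_radius_artery_mm),
        ("vein", +1.0, cfg.root_radius_vein_mm),
    ):
        z0 = z_sign * (c + 50.0)
        z1 = z_sign * (c + 25.0)
        root_name = f"{side}_root"
        p_root0 = np.array([0.0, 0.0, z0])
        p_root1 = np.array([0.0, 0.0, z1])
        vessels.append(
            BackboneVessel(root_name, side, r_root, 25.0, parent=None)
        )
        geometry[root_name] = (p_root0, p_root1)
        halves = {"L": [], "R": []}
        for i, r in enumerate(regions):
            key = "L" if r.entry_points[side][0] <= 0 else "R"
            halves[key].append((i, r))
        branch_ends = {}
        for key, sign in (("L", -1.0), ("R", 1.0)):
            if not halves[key]:
                continue
            share = float(sum(fr[i] for i, _ in halves[key]))
            bname = f"{side}_branch_{key}"
            p0 = p_root1
            p1 = np.array([sign * a / 2.0, 0.0, z_sign * (c + 12.0)])
            vessels.append(
                BackboneVessel(
                    bname,
                    side,
                    r_root * share ** (1.0 / 3.0),
                    float(np.linalg.norm(p1 - p0)),
                    parent=root_name,
                )
            )
            geometry[bname] = (p0, p1)
            branch_ends[key] = (bname, p1)
        for key in ("L", "R"):
            if key not in branch_ends:
                continue
            bname, p1 = branch_ends[key]
            for i, r in halves[key]:
                p_entry = np.asarray(r.entry_points[side], float)
                # outward surface normal at the entry: feed each region
                # radially so the terminal dive stays clear of neighbours
                normal = p_entry / semi**2
                normal = normal / np.linalg.norm(normal)
                waypoint = p_entry + 14.0 * normal
                r_leaf = r_root * float(fr[i]) ** (1.0 / 3.0)
                fname = f"{side}_feed_{r.name}"
                vessels.append(
                    BackboneVessel(
                        fname, side, r_leaf,
                        float(np.linalg.norm(waypoint - p1)), parent=bname,
                    )
                )
                geometry[fname] = (p1, waypoint)
                vname = f"{side}_{r.name}"
                vessels.append(
                    BackboneVessel(
                        vname, side, r_leaf,
                        float(np.linalg.norm(p_entry - waypoint)),
                        parent=fname, region=r.name,
                    )
                )
                geometry[vname] = (waypoint, p_entry)
    return vessels, geometry


def generate_fixture_brain(
    config: FixtureConfig | None = None, seed: int = 0
) -> BrainFixture:
    """Build the deterministic synthetic brain fixture.

    ``seed`` is accepted for interface symmetry with the samplers but the
    geometry itself is deterministic; two seeds give identical regions.
    """
    cfg = config or FixtureConfig()
    if cfg.sex not in REFERENCE_BRAIN:
        raise ValueError(f"unknown sex {cfg.sex!r}")
    ref = REFERENCE_BRAIN[cfg.sex]
    if cfg.fractions is None:
        table = AFB_PTBV if cfg.sex == "female" else AMB_PTBV
        fractions = _bilateral_fractions(table)
    else:
        total = sum(cfg.fractions.values())
        fractions = {k: v / total for k, v in cfg.fractions.items()}

    volume_mm3 = ref["organ_mass_kg"] / ref["organ_density_g_cm3"] * 1e6
    rb, rc = cfg.axis_ratio
    a = (3.0 * volume_mm3 / (4.0 * np.pi * rb * rc)) ** (1.0 / 3.0)
    semi = np.array([a, rb * a, rc * a])

    names = list(fractions.keys())
    fracs = [fractions[n] for n in names]
    bands = _band_partition(names, fracs)
    band_fracs = [sum(fracs[i] for i in band) for band in bands]
    xcuts = _slab_cuts(band_fracs, a)
    regions: list[RegionDomain] = []
    for bi, band in enumerate(bands):
        x0, x1 = xcuts[bi], xcuts[bi + 1]
        if len(band) == 1:
            ycuts = np.array([-semi[1], semi[1]])
        else:
            ycuts = _y_cuts(semi, x0, x1, [fracs[i] for i in band])
        for k, i in enumerate(band):
            regions.append(
                _region_domain(
                    names[i], semi, x0, x1, ycuts[k], ycuts[k + 1], fracs[i], cfg
                )
            )
    regions.sort(key=lambda r: names.index(r.name))
    backbone, geometry = _backbone(regions, fractions, semi, cfg)

    blood_mass = ref["organ_mass_kg"] - ref["tissue_mass_kg"]
    m_bibv = ref["f_bv"] * blood_mass
    masses = {
        "m_B": ref["organ_mass_kg"],
        "m_BIBV": m_bibv,
        "m_BOBV": ref["organ_mass_kg"] - m_bibv,
        "blood_mass_kg": blood_mass,
        "f_bv": ref["f_bv"],
    }
    perfusion = PerfusionSpec(tissue_mass_g=ref["tissue_mass_kg"] * 1e3)
    return BrainFixture(
        sex=cfg.sex,
        semi_axes=semi,
        regions=regions,
        backbone=backbone,
        backbone_geometry=geometry,
        perfusion=perfusion,
        region_fractions=fractions,
        masses=masses,
    )
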