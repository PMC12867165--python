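"""Backbone ("main vessel") network solver.

The backbone carries blood from the organ entry vessels (internal
carotid-like roots on the arterial side, transverse-sinus-like roots on
the venous side) down to exactly one *artificial* artery and one
artificial vein per sub-region.  Flows follow conservation on a rooted
tree, region flows are proportional to their volume fractions, and
pressures drop segment by segment by Poiseuille's law.

Unit policy: clinical units at the interfaces (mmHg, ml/min, mm) and SI
internally; the conversion constants live here and are imported by the
other modules.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "MMHG_TO_PA",
    "MLMIN_TO_M3S",
    "BLOOD_VISCOSITY_PA_S",
    "PerfusionSpec",
    "BackboneVessel",
    "total_cerebral_flow",
    "poiseuille_pressure_drop",
    "solve_backbone",
    "scale_radii_for_sex",
    "network_to_frame",
]

MMHG_TO_PA = 133.322387415
MLMIN_TO_M3S = 1e-6 / 60.0
MM_TO_M = 1e-3
#: default large-vessel blood viscosity (Pa s); configurable, not printed
#: in the source anatomy references.
BLOOD_VISCOSITY_PA_S = 3.5e-3


@dataclasses.dataclass
class PerfusionSpec:
    """Organ perfusion bookkeeping.

    ``specific_flow`` is in ml/min per 100 g of tissue; the reference
    adult brain value is 50, which yields 725 ml/min for a 1450 g brain
    and 650 ml/min for a 1300 g brain.
    """

    tissue_mass_g: float
    specific_flow_ml_min_100g: float = 50.0
    blood_viscosity_pa_s: float = BLOOD_VISCOSITY_PA_S

    @property
    def total_flow_ml_min(self) -> float:
        return total_cerebral_flow(self)


@dataclasses.dataclass
class BackboneVessel:
    """One straight backbone conduit (clinical units)."""

    name: str
    side: str  # "artery" | "vein"
    radius_mm: float
    length_mm: float
    parent: str | None = None  # None marks the root of its side
    region: str | None = None  # set on artificial (leaf) vessels
    flow_ml_min: float = np.nan
    pressure_in_mmhg: float = np.nan
    pressure_out_mmhg: float = np.nan

    def validate(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError(f"{self.name}: radius must be positive")
        if self.length_mm <= 0:
            raise ValueError(f"{self.name}: length must be positive")
        if self.side not in ("artery", "vein"):
            raise ValueError(f"{self.name}: side must be artery or vein")


def total_cerebral_flow(spec: PerfusionSpec) -> float:
    """Total organ blood flow in ml/min: mass x specific flow / 100."""
    if spec.tissue_mass_g <= 0 or spec.specific_flow_ml_min_100g <= 0:
        raise ValueError("mass and specific flow must be positive")
    return spec.tissue_mass_g * spec.specific_flow_ml_min_100g / 100.0


def poiseuille_pressure_drop(
    flow_m3_s: float, radius_m: float, length_m: float, viscosity_pa_s: float
) -> float:
    """Hagen-Poiseuille pressure drop, SI units: 8 mu L Q / (pi r^4)."""
    radius_m = np.asarray(radius_m, float)
    if np.any(radius_m <= 0):
        raise ValueError("radius must be positive")
    if np.any(np.asarray(length_m) < 0) or viscosity_pa_s <= 0:
        raise ValueError("length and viscosity must be positive")
    return 8.0 * viscosity_pa_s * length_m * flow_m3_s / (np.pi * radius_m**4)


def _side_tree(vessels: Iterable[BackboneVessel], side: str) -> nx.DiGraph:
    g = nx.DiGraph()
    for v in vessels:
        if v.side != side:
            continue
        v.validate()
        g.add_node(v.name, vessel=v)
    for name, data in g.nodes(data=True):
        parent = data["vessel"].parent
        if parent is not None:
            if parent not in g:
                raise ValueError(f"{name}: parent {parent} missing from {side} side")
            g.add_edge(parent, name)
    roots = [n for n, d in g.in_degree() if d == 0]
    if len(roots) != 1:
        raise ValueError(f"{side} side must be a single rooted tree, roots={roots}")
    if not nx.is_arborescence(g):
        raise ValueError(f"{side} side is not a tree (cycle or re-merge present)")
    return g


def solve_backbone(
    vessels: list[BackboneVessel],
    spec: PerfusionSpec,
    region_fractions: dict[str, float],
    root_pressure_mmhg: dict[str, float] | None = None,
) -> list[BackboneVessel]:
    """Assign flows and pressures to a two-sided backbone network.

    Leaf (artificial) vessels carry their region's share of the total
    flow, ``total * fraction``; interior vessels carry the sum of their
    children (flow conservation), so each side's root carries the full
    organ flow and the venous outflow matches the arterial inflow
    exactly.  Pressures start from the root boundary value and drop (or,
    on the venous side, rise toward the terminals) by Poiseuille on each
    conduit.
    """
    root_pressure_mmhg = root_pressure_mmhg or {"artery": 95.0, "vein": 6.0}
    total = total_cerebral_flow(spec)
    fr = np.array(list(region_fractions.values()), float)
    fr = fr / fr.sum()
    share = dict(zip(region_fractions.keys(), fr))

    for side in ("artery", "vein"):
        g = _side_tree(vessels, side)
        leaves = [n for n, d in g.out_degree() if d == 0]
        for n in leaves:
            v = g.nodes[n]["vessel"]
            if v.region is None or v.region not in share:
                raise ValueError(f"leaf vessel {n} has no known region")
            v.flow_ml_min = total * share[v.region]
        for n in reversed(list(nx.topological_sort(g))):
            v = g.nodes[n]["vessel"]
            kids = list(g.successors(n))
            if kids:
                v.flow_ml_min = float(
                    sum(g.nodes[k]["vessel"].flow_ml_min for k in kids)
                )
        root = next(n for n, d in g.in_degree() if d == 0)
        g.nodes[root]["vessel"].pressure_in_mmhg = root_pressure_mmhg[side]
        for n in nx.topological_sort(g):
            v = g.nodes[n]["vessel"]
            if v.parent is not None:
                v.pressure_in_mmhg = g.nodes[v.parent]["vessel"].pressure_out_mmhg
            dp = poiseuille_pressure_drop(
                v.flow_ml_min * MLMIN_TO_M3S,
                v.radius_mm * MM_TO_M,
                v.length_mm * MM_TO_M,
                spec.blood_viscosity_pa_s,
            ) / MMHG_TO_PA
            # pressure falls in the direction of flow: root->leaf for
            # arteries, leaf->root for veins
            if v.side == "artery":
                v.pressure_out_mmhg = v.pressure_in_mmhg - dp
            else:
                v.pressure_out_mmhg = v.pressure_in_mmhg + dp
    return vessels


def scale_radii_for_sex(
    vessels: list[BackboneVessel],
    names: Iterable[str],
    factor: float,
    mode: str = "linear",
) -> list[BackboneVessel]:
    """Scale a configured subset of backbone radii.

    ``mode='linear'`` multiplies radii by ``factor`` (the venous-sinus
    1.02 scaling); ``mode='volumetric'`` interprets ``factor`` as a
    blood-volume ratio and scales radii by its cube root.
    """
    if factor < 1.0:
        raise ValueError("scaling factor must be >= 1")
    r_scale = factor if mode == "linear" else factor ** (1.0 / 3.0)
    names = set(names)
    for v in vessels:
        if v.name in names:
            v.radius_mm *= r_scale
    return vessels


def network_to_frame(vessels: list[BackboneVessel]) -> pd.DataFrame:
    """Solved network as a table (one row per vessel) for CSV export."""
    return pd.DataFrame(
        [
            {
                "name": v.name,
                "side": v.side,
                "region": v.region or "",
                "radius_mm": v.radius_mm,
                "length_mm": v.length_mm,
                "flow_ml_min": v.flow_ml_min,
                "pressure_in_mmhg": v.pressure_in_mmhg,
                "pressure_out_mmhg": v.pressure_out_mmhg,
            }
            for v in vessels
        ]
    )
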