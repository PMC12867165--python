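"""Independent brute-force constraint audit of a generated vasculature.

This module deliberately re-implements every check from scratch (O(n^2)
pairwise capsule separation, its own segment-distance minimization,
independent terminal recounting) so it can serve as an oracle for the
growth code rather than a restatement of it.  It operates on the
serialized segment table, so re-auditing written outputs reproduces the
in-memory report.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = ["AuditReport", "CheckResult", "audit_vasculature", "audit_frame"]


@dataclasses.dataclass
class CheckResult:
    name: str
    passed: bool
    n_violations: int = 0
    worst: float | None = None
    detail: str = ""


@dataclasses.dataclass
class AuditReport:
    checks: list[CheckResult]
    min_bifurcation_angle_deg: float
    min_separation_mm: float

    @property
    def ok(self) -> bool:
        return all(c.passed for c in self.checks)

    def as_dict(self) -> dict:
        return {
            "ok": bool(self.ok),
            "min_bifurcation_angle_deg": float(self.min_bifurcation_angle_deg),
            "min_separation_mm": float(self.min_separation_mm),
            "checks": {
                c.name: {
                    "passed": bool(c.passed),
                    "n_violations": int(c.n_violations),
                    "worst": None if c.worst is None else float(c.worst),
                    "detail": c.detail,
                }
                for c in self.checks
            },
        }


# ---------------------------------------------------------------------------
# an independent segment-segment distance: minimize the quadratic
# |p(s) - q(t)|^2 over the unit square via interior critical point + edges
# ---------------------------------------------------------------------------

def _seg_seg_dist_quadratic(p0, p1, q0, q1):
    u = p1 - p0
    v = q1 - q0
    w = p0 - q0
    a = np.einsum("...i,...i->...", u, u)
    b = np.einsum("...i,...i->...", u, v)
    c = np.einsum("...i,...i->...", v, v)
    d = np.einsum("...i,...i->...", u, w)
    e = np.einsum("...i,...i->...", v, w)
    det = a * c - b * b
    safe = np.where(np.abs(det) > 1e-14, det, 1.0)
    cand_s = [np.clip((b * e - c * d) / safe, 0.0, 1.0)]
    cand_t = [np.clip((a * e - b * d) / safe, 0.0, 1.0)]
    # four edges: s=0, s=1 (minimize over t), t=0, t=1 (minimize over s)
    c_safe = np.where(c > 1e-14, c, 1.0)
    a_safe = np.where(a > 1e-14, a, 1.0)
    for s_fix in (0.0, 1.0):
        cand_s.append(np.full_like(a, s_fix))
        cand_t.append(np.clip((e + b * s_fix) / c_safe, 0.0, 1.0))
    for t_fix in (0.0, 1.0):
        cand_t.append(np.full_like(a, t_fix))
        cand_s.append(np.clip((b * t_fix - d) / a_safe, 0.0, 1.0))
    best = None
    for s, t in zip(cand_s, cand_t):
        diff = w + s[..., None] * u - t[..., None] * v
        d2 = np.einsum("...i,...i->...", diff, diff)
        best = d2 if best is None else np.minimum(best, d2)
    return np.sqrt(best)


# ---------------------------------------------------------------------------
# audit
# ---------------------------------------------------------------------------

def _recount_terminals(parent: np.ndarray, terminal: np.ndarray) -> np.ndarray:
    n = len(parent)
    counts = np.where(terminal, 1, 0).astype(int)
    order = sorted(range(n), key=lambda i: -_depth(parent, i))
    for i in order:
        if parent[i] >= 0:
            counts[parent[i]] += counts[i]
    return counts


def _depth(parent: np.ndarray, i: int) -> int:
    d = 0
    while parent[i] >= 0:
        i = parent[i]
        d += 1
    return d


def audit_frame(
    frame: pd.DataFrame,
    regions_by_name: dict | None = None,
    backbone_capsules: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    min_angle_deg: float = 30.0,
    entry_exclusion_factor: float = 3.0,
    containment_step_mm: float = 1.0,
) -> AuditReport:
    """Audit a serialized vasculature table against all invariants."""
    checks: list[CheckResult] = []
    keys = list(frame.groupby(["region", "side"], sort=False).groups)

    all_p0, all_p1, all_r, all_keys = [], [], [], []
    min_angle = np.inf
    n_binary_bad = 0
    n_count_bad = 0
    murray_worst = 0.0
    flow_bad = 0
    mono_bad = 0
    contain_bad = 0

    for region_name, side in keys:
        sub = frame[(frame.region == region_name) & (frame.side == side)]
        sub = sub.sort_values("segment")
        parent = sub.parent.to_numpy()
        prox = sub[["prox_x", "prox_y", "prox_z"]].to_numpy()
        dist = sub[["dist_x", "dist_y", "dist_z"]].to_numpy()
        radius = sub.radius_mm.to_numpy()
        flow = sub.flow_ml_min.to_numpy()
        terminal = sub.terminal.to_numpy().astype(bool)
        n = len(sub)

        children: dict[int, list[int]] = {i: [] for i in range(n)}
        for i, p in enumerate(parent):
            if p >= 0:
                children[int(p)].append(i)
        # binary topology and the 2T-1 identity
        for i in range(n):
            k = len(children[i])
            if (terminal[i] and k != 0) or (not terminal[i] and k != 2):
                n_binary_bad += 1
        T = int(terminal.sum())
        if n != 2 * T - 1:
            n_count_bad += 1

        # independent terminal recount -> flow conservation and Murray law
        counts = _recount_terminals(parent, terminal)
        q_t = flow[terminal].mean() if terminal.any() else np.nan
        if not np.allclose(flow, q_t * counts, rtol=1e-9, atol=1e-12):
            flow_bad += 1
        for i in range(n):
            if len(children[i]) == 2:
                c1, c2 = children[i]
                resid = abs(
                    radius[i] ** 3 - radius[c1] ** 3 - radius[c2] ** 3
                ) / radius[i] ** 3
                murray_worst = max(murray_worst, resid)
                # bifurcation angle between the daughters
                u = dist[c1] - prox[c1]
                v = dist[c2] - prox[c2]
                cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
                min_angle = min(min_angle, np.degrees(np.arccos(np.clip(cosang, -1, 1))))
            if parent[i] >= 0 and radius[i] > radius[parent[i]] * (1 + 1e-9):
                mono_bad += 1

        # containment (needs region geometry); the exclusion ball around
        # the entry covers the surface breach where the feeding vessel
        # penetrates, so it scales with that vessel's radius too
        entry = prox[parent < 0][0] if (parent < 0).any() else prox[0]
        r_root = radius[parent < 0].max() if (parent < 0).any() else radius.max()
        r_feed = 0.0
        if backbone_capsules is not None and len(backbone_capsules) > 3:
            for lab, rr in zip(backbone_capsules[3], backbone_capsules[2]):
                if lab == f"{region_name}|{side}":
                    r_feed = max(r_feed, float(rr))
        r_excl = entry_exclusion_factor * max(r_root, r_feed)
        if regions_by_name and region_name in regions_by_name:
            region = regions_by_name[region_name]
            for i in range(n):
                L = np.linalg.norm(dist[i] - prox[i])
                m = max(3, int(np.ceil(L / containment_step_mm)) + 1)
                ts = np.linspace(0, 1, m)
                pts = prox[i][None, :] + ts[:, None] * (dist[i] - prox[i])[None, :]
                ok = region.interior_margin(pts) >= radius[i] - 1e-9
                ok |= np.linalg.norm(pts - entry[None, :], axis=1) < r_excl
                if not ok.all():
                    contain_bad += 1

        all_p0.append(prox)
        all_p1.append(dist)
        all_r.append(radius)
        all_keys.extend([f"{region_name}|{side}"] * n)

    checks.append(CheckResult("binary_topology", n_binary_bad == 0, n_binary_bad))
    checks.append(CheckResult("segment_count_2T_minus_1", n_count_bad == 0, n_count_bad))
    checks.append(CheckResult("flow_conservation", flow_bad == 0, flow_bad))
    checks.append(
        CheckResult("murray_law", murray_worst < 1e-9, 0, murray_worst)
    )
    checks.append(CheckResult("radius_monotonicity", mono_bad == 0, mono_bad))
    checks.append(CheckResult("containment", contain_bad == 0, contain_bad))
    checks.append(
        CheckResult(
            "bifurcation_angle",
            bool(min_angle >= min_angle_deg - 1e-9),
            0,
            float(min_angle),
        )
    )

    # global pairwise capsule separation, O(n^2), endpoint-sharing exempt
    P0 = np.vstack(all_p0)
    P1 = np.vstack(all_p1)
    R = np.concatenate(all_r)
    key = np.array(all_keys, dtype=object)
    is_backbone = np.zeros(len(R), dtype=bool)
    if backbone_capsules is not None:
        bp0, bp1, br = backbone_capsules[:3]
        labels = (
            backbone_capsules[3]
            if len(backbone_capsules) > 3
            else [""] * len(br)
        )
        P0 = np.vstack([P0, bp0])
        P1 = np.vstack([P1, bp1])
        R = np.concatenate([R, br])
        key = np.concatenate([key, np.array(labels, dtype=object)])
        is_backbone = np.concatenate(
            [is_backbone, np.ones(len(br), dtype=bool)]
        )
    n_all = len(R)
    min_sep = np.inf
    n_overlap = 0
    for i in range(n_all - 1):
        q0 = P0[i + 1 :]
        q1 = P1[i + 1 :]
        d = _seg_seg_dist_quadratic(
            np.broadcast_to(P0[i], q0.shape),
            np.broadcast_to(P1[i], q0.shape),
            q0,
            q1,
        )
        share = (
            (np.linalg.norm(q0 - P0[i], axis=1) < 1e-6)
            | (np.linalg.norm(q0 - P1[i], axis=1) < 1e-6)
            | (np.linalg.norm(q1 - P0[i], axis=1) < 1e-6)
            | (np.linalg.norm(q1 - P1[i], axis=1) < 1e-6)
        )
        # backbone-backbone pairs are fixture plumbing, not generated output
        share |= is_backbone[i] & is_backbone[i + 1 :]
        # a tree may hug its own feeding (artificial entry) vessel
        same_key = key[i + 1 :] == key[i]
        share |= (is_backbone[i] != is_backbone[i + 1 :]) & same_key & (key[i] != "")
        sep = d - (R[i] + R[i + 1 :])
        sep = sep[~share]
        if len(sep):
            min_sep = min(min_sep, float(sep.min()))
            n_overlap += int((sep < -1e-9).sum())
    checks.append(
        CheckResult(
            "capsule_clearance",
            n_overlap == 0,
            n_overlap,
            None if not np.isfinite(min_sep) else float(min_sep),
        )
    )
    return AuditReport(
        checks=checks,
        min_bifurcation_angle_deg=float(min_angle),
        min_separation_mm=float(min_sep) if np.isfinite(min_sep) else np.nan,
    )


def audit_vasculature(
    vasc,
    fixture=None,
    include_backbone: bool = True,
    **kwargs,
) -> AuditReport:
    """Audit an in-memory :class:`~vasodose.cco.Vasculature`."""
    frame = vasc.to_frame()
    regions_by_name = None
    backbone = None
    if fixture is not None:
        regions_by_name = {r.name: r for r in fixture.regions}
        if include_backbone:
            p0 = np.array([fixture.backbone_geometry[v.name][0] for v in fixture.backbone])
            p1 = np.array([fixture.backbone_geometry[v.name][1] for v in fixture.backbone])
            r = np.array([v.radius_mm for v in fixture.backbone])
            labels = [
                f"{v.region}|{v.side}" if v.region else "" for v in fixture.backbone
            ]
            backbone = (p0, p1, r, labels)
    return audit_frame(frame, regions_by_name, backbone, **kwargs)
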