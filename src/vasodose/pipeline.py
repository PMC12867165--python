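"""End-to-end pipeline: fixture -> backbone -> trees -> morphometry ->
transport -> S-values, with a manifest and an audit over the written
artifacts.

Every stage writes plain-text outputs (CSV/JSON) into the run directory;
``audit`` re-reads those files, so re-auditing written outputs
reproduces the in-memory report.  Warnings for dropped terminals are
logged as JSON lines, making runs auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .audit import audit_frame
from .cco import GrowthConfig, Vasculature, build_organ_vasculature
from .dosimetry import (
    DualRegionModel,
    decay_chain_table,
    load_packaged_scheme,
    saf_curves_from_af_table,
)
from .fixtures import FixtureConfig, generate_fixture_brain
from .hemodynamics import network_to_frame, solve_backbone
from .morphometry import path_vs_euclidean, strahler_summary
from .transport import (
    CapsuleSet,
    Ellipsoid,
    TransportConfig,
    TransportGeometry,
    brain_materials,
    compute_absorbed_fractions,
)

logger = logging.getLogger("vasodose.pipeline")

__all__ = ["RunConfig", "run_pipeline", "audit", "trees_from_frame"]


@dataclasses.dataclass
class RunConfig:
    outdir: str = "vasodose_run"
    seed: int = 1
    sex: str = "female"
    #: custom region fraction map; None -> the 13-territory reference split
    fractions: dict | None = None
    total_terminals: int = 200
    growth: dict = dataclasses.field(default_factory=dict)
    transport_enabled: bool = False
    transport_particles: tuple = ("alpha", "electron", "photon")
    transport_energies: dict | None = None  # particle -> list of MeV
    transport_histories: int = 5000
    #: user-supplied AF table consumed by the SAF stage when transport is off
    af_csv: str | None = None
    nuclides: tuple = ("At-211", "Po-211", "Bi-207")
    progeny: tuple = ("Po-211", "Bi-207")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        raw = yaml.safe_load(pathlib.Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _default_energies() -> dict:
    # a sparse demonstration grid; the full study grids are
    # vasodose.alpha_energy_grid() / photon_electron_grid()
    return {
        "alpha": [1.0, 4.0, 8.0, 12.0],
        "electron": [0.01, 0.1, 1.0],
        "photon": [0.01, 0.1, 0.5, 2.0],
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the result bundle with a manifest."""
    out = pathlib.Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log.jsonl", mode="w")
    handler.setFormatter(
        logging.Formatter('{"level": "%(levelname)s", "stage": "%(name)s", "msg": "%(message)s"}')
    )
    logging.getLogger("vasodose").addHandler(handler)
    stage = "fixture"
    try:
        fixture = generate_fixture_brain(
            FixtureConfig(sex=config.sex, fractions=config.fractions), config.seed
        )
        stage = "backbone"
        solve_backbone(fixture.backbone, fixture.perfusion, fixture.region_fractions)
        network_to_frame(fixture.backbone).to_csv(
            out / "backbone.csv", index=False, float_format="%.12g"
        )
        stage = "growth"
        gcfg = GrowthConfig(seed=config.seed, **config.growth)
        vasc = build_organ_vasculature(fixture, config.total_terminals, gcfg)
        vasc.to_csv(out / "vessels.csv")
        stage = "morphometry"
        arteries = [t for t in vasc.trees if t.side == "artery"]
        veins = [t for t in vasc.trees if t.side == "vein"]
        morpho = {}
        for label, trees in (("artery", arteries), ("vein", veins)):
            if trees:
                morpho[label] = strahler_summary(trees).as_dict()
        _, _, pe_fit = path_vs_euclidean(vasc.trees)
        morpho["path_vs_euclidean"] = dataclasses.asdict(pe_fit)
        (out / "morphometry.json").write_text(json.dumps(morpho, indent=1))
        stage = "audit"
        report = _audit_bundle(vasc.to_frame(), fixture, gcfg)
        (out / "audit.json").write_text(json.dumps(report.as_dict(), indent=1))
        stage = "transport"
        af_table = None
        if config.transport_enabled:
            geom = TransportGeometry(
                Ellipsoid(fixture.semi_axes),
                CapsuleSet.from_vasculature(vasc),
                brain_materials(config.sex),
            )
            energies = config.transport_energies or _default_energies()
            tcfg = TransportConfig(max_histories=config.transport_histories)
            af_dual = compute_absorbed_fractions(
                geom,
                {p: np.asarray(energies[p]) for p in config.transport_particles},
                ["BIBV", "BOBV"],
                tcfg,
                seed=config.seed,
            )
            geom_single = TransportGeometry(
                Ellipsoid(fixture.semi_axes), None, brain_materials(config.sex)
            )
            af_single = compute_absorbed_fractions(
                geom_single,
                {p: np.asarray(energies[p]) for p in config.transport_particles},
                ["B"],
                tcfg,
                seed=config.seed + 1,
            )
            af_table = pd.concat([af_single, af_dual], ignore_index=True)
            af_table.to_csv(out / "af.csv", index=False, float_format="%.12g")
        elif config.af_csv:
            af_table = pd.read_csv(config.af_csv)
            af_table.to_csv(out / "af.csv", index=False, float_format="%.12g")
        stage = "svalues"
        if af_table is not None:
            model = (
                DualRegionModel.afb() if config.sex == "female" else DualRegionModel.amb()
            )
            singles, crosses, selfs = saf_curves_from_af_table(af_table, model)
            schemes = [load_packaged_scheme(n) for n in config.nuclides]
            table = decay_chain_table(
                schemes, singles, crosses, selfs, progeny=set(config.progeny)
            )
            table.to_csv(out / "svalues.csv", index=False, float_format="%.6g")
        stage = "manifest"
        cfg_json = json.dumps(config.to_dict(), sort_keys=True)
        manifest = {
            "config": config.to_dict(),
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "seed": config.seed,
            "version": __version__,
            "numpy": np.__version__,
            "segments": vasc.segment_count(),
            "dropped_terminals": vasc.n_dropped,
            "audit_ok": report.ok,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    finally:
        logging.getLogger("vasodose").removeHandler(handler)
        handler.close()
    return {
        "outdir": str(out),
        "fixture": fixture,
        "vasculature": vasc,
        "morphometry": morpho,
        "audit": report,
        "af_table": af_table,
        "manifest": manifest,
    }


def _audit_bundle(frame: pd.DataFrame, fixture, gcfg: GrowthConfig):
    regions = {r.name: r for r in fixture.regions}
    p0 = np.array([fixture.backbone_geometry[v.name][0] for v in fixture.backbone])
    p1 = np.array([fixture.backbone_geometry[v.name][1] for v in fixture.backbone])
    rr = np.array([v.radius_mm for v in fixture.backbone])
    labels = [f"{v.region}|{v.side}" if v.region else "" for v in fixture.backbone]
    return audit_frame(
        frame,
        regions,
        (p0, p1, rr, labels),
        min_angle_deg=gcfg.min_bifurcation_angle_deg,
        entry_exclusion_factor=gcfg.entry_exclusion_factor,
    )


def audit(outdir: str) -> tuple[bool, dict]:
    """Re-audit a written result bundle; returns (ok, report dict)."""
    out = pathlib.Path(outdir)
    manifest = json.loads((out / "manifest.json").read_text())
    cfg = RunConfig(**{
        k: v for k, v in manifest["config"].items()
    })
    fixture = generate_fixture_brain(
        FixtureConfig(sex=cfg.sex, fractions=cfg.fractions), cfg.seed
    )
    solve_backbone(fixture.backbone, fixture.perfusion, fixture.region_fractions)
    frame = pd.read_csv(out / "vessels.csv")
    required = {
        "region", "side", "segment", "parent", "prox_x", "prox_y", "prox_z",
        "dist_x", "dist_y", "dist_z", "radius_mm", "flow_ml_min", "terminal",
    }
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"vessels.csv: missing columns {sorted(missing)}")
    gcfg = GrowthConfig(seed=cfg.seed, **cfg.growth)
    report = _audit_bundle(frame, fixture, gcfg)
    result = report.as_dict()
    af_path = out / "af.csv"
    if af_path.exists():
        af = pd.read_csv(af_path)
        in_range = bool(((af.af >= 0) & (af.af <= 1 + 1e-9)).all())
        sums = af.groupby(["particle", "energy_mev", "source"]).af.sum()
        balanced = bool(np.allclose(sums.to_numpy(), 1.0, atol=0.02))
        result["checks"]["af_range"] = {"passed": in_range, "n_violations": int((~((af.af >= 0) & (af.af <= 1 + 1e-9))).sum())}
        result["checks"]["af_balance"] = {"passed": balanced, "worst": float(np.abs(sums.to_numpy() - 1).max())}
        result["ok"] = result["ok"] and in_range and balanced
    return bool(result["ok"]), result


# ---------------------------------------------------------------------------
# light tree adapter for re-reading serialized vasculature
# ---------------------------------------------------------------------------

class _FrameTree:
    """Adapter exposing the Tree interface over a serialized segment table."""

    def __init__(self, sub: pd.DataFrame):
        sub = sub.sort_values("segment")
        self.region_name = sub.region.iloc[0]
        self.side = sub.side.iloc[0]
        self.n = len(sub)
        self.prox = sub[["prox_x", "prox_y", "prox_z"]].to_numpy()
        self.dist = sub[["dist_x", "dist_y", "dist_z"]].to_numpy()
        self.parent = sub.parent.to_numpy()
        self._radius = sub.radius_mm.to_numpy()
        self._terminal = sub.terminal.to_numpy().astype(bool)
        self.child = np.full((self.n, 2), -1, dtype=int)
        slot = np.zeros(self.n, dtype=int)
        for i, p in enumerate(self.parent):
            if p >= 0:
                self.child[p, slot[p]] = i
                slot[p] += 1
        root = int(np.nonzero(self.parent < 0)[0][0])
        entry_point = self.prox[root]
        self.entry = type("E", (), {"point": entry_point})()

    def radii(self) -> np.ndarray:
        return self._radius

    def is_terminal(self) -> np.ndarray:
        return self._terminal

    def lengths(self) -> np.ndarray:
        return np.linalg.norm(self.dist - self.prox, axis=1)

    def path_lengths_to_entry(self) -> np.ndarray:
        out = np.zeros(self.n)
        L = self.lengths()
        order = np.argsort([self._depth(i) for i in range(self.n)])
        for i in order:
            p = self.parent[i]
            out[i] = (out[p] if p >= 0 else 0.0) + L[i]
        return out

    def _depth(self, i: int) -> int:
        d = 0
        while self.parent[i] >= 0:
            i = self.parent[i]
            d += 1
        return d


def trees_from_frame(frame: pd.DataFrame) -> list[_FrameTree]:
    """Rebuild light tree objects (for morphometry) from a segment table."""
    return [
        _FrameTree(sub)
        for _, sub in frame.groupby(["region", "side"], sort=False)
    ]
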