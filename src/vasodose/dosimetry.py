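"""MIRD-schema dosimetry: SAF algebra and radionuclide S-values.

The single-region organ model treats parenchyma and blood as one
homogeneous mixture B, so SAF(B<-B) = AF(B<-B)/m_B approximates both the
parenchymal self-dose and the blood-to-parenchyma cross-dose.  The
dual-region model splits the organ into blood inside the modeled
vessels (BIBV) and everything else (BOBV = parenchyma plus residual
unmodeled blood); with f_BV the fraction of organ blood explicitly
modeled, the refined cross-dose SAF is

    SAF(BOBV <- BB) = [f_BV AF(BOBV<-BIBV) + (1-f_BV) AF(BOBV<-BOBV)] / m_BOBV

and the self-dose SAF is AF(BOBV<-BOBV)/m_BOBV.  In the local-deposition
limit (charged-particle range far below the vessel radius) the
single/dual AF ratio collapses to 1/(1-f_BV) and the SAF ratio to
m_BOBV / (m_B (1-f_BV)).

S-values sum emission energy x yield x SAF over a nuclide's decay
scheme, with full beta spectra integrated by trapezoid, positrons routed
to the electron curves, and alpha recoils evaluated on the alpha curve
at 2 MeV (the convention adopted for recoil nuclei).  SAF curves are
interpolated with shape-preserving piecewise cubic Hermite polynomials
(PCHIP) on log-log axes; queries outside the tabulated span raise
rather than extrapolate.
"""

from __future__ import annotations

import dataclasses
import pathlib
from importlib import resources

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

__all__ = [
    "MEV_PER_DECAY_TO_MGY_PER_MBQ_S",
    "DualRegionModel",
    "saf_single",
    "saf_dual_self",
    "saf_dual_cross",
    "af_ratio_local_deposition",
    "saf_ratio_local_deposition",
    "SafCurve",
    "interpolate_saf",
    "Emission",
    "DecayScheme",
    "read_decay_scheme",
    "load_packaged_scheme",
    "s_value",
    "decay_chain_table",
    "saf_curves_from_af_table",
]

# 1.602e-13 J/MeV x 1e6 decay/(MBq s) x 1e3 mGy/Gy, per kg in the SAF
MEV_PER_DECAY_TO_MGY_PER_MBQ_S = 1.602176634e-13 * 1e6 * 1e3
ALPHA_RECOIL_EVAL_MEV = 2.0


# ---------------------------------------------------------------------------
# dual-region model and SAF algebra
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DualRegionModel:
    """Masses and blood split of the dual-region organ model (kg)."""

    m_B: float
    m_BIBV: float
    m_BOBV: float
    f_BV: float

    def __post_init__(self) -> None:
        if not 0.0 < self.f_BV < 1.0:
            raise ValueError("f_BV must be in (0, 1)")
        if abs(self.m_B - (self.m_BIBV + self.m_BOBV)) > 0.001 + 1e-9:
            raise ValueError("masses must satisfy m_B = m_BIBV + m_BOBV")

    @classmethod
    def afb(cls) -> "DualRegionModel":
        """Reference adult female brain: 1.350 = 0.028 + 1.322 kg, f_BV 0.56."""
        return cls(m_B=1.350, m_BIBV=0.028, m_BOBV=1.322, f_BV=0.56)

    @classmethod
    def amb(cls) -> "DualRegionModel":
        """Reference adult male brain: 1.517 ~ 0.032 + 1.486 kg, f_BV 0.47."""
        return cls(m_B=1.517, m_BIBV=0.032, m_BOBV=1.486, f_BV=0.47)


def saf_single(af: float, m_b_kg: float) -> float:
    """Single-region SAF (1/kg): AF over the homogenized organ mass."""
    if m_b_kg <= 0:
        raise ValueError("mass must be positive")
    if not 0.0 <= af <= 1.0:
        raise ValueError("AF must lie in [0, 1]")
    return af / m_b_kg


def saf_dual_self(af_bobv_to_bobv: float, m_bobv_kg: float) -> float:
    """Dual-region self-dose SAF (1/kg)."""
    return saf_single(af_bobv_to_bobv, m_bobv_kg)


def saf_dual_cross(
    af_bibv_to_bobv: float,
    af_bobv_to_bobv: float,
    f_bv: float,
    m_bobv_kg: float,
) -> float:
    """Dual-region blood-to-parenchyma SAF (1/kg), fBV-weighted."""
    if not 0.0 < f_bv < 1.0:
        raise ValueError("f_BV must be in (0, 1)")
    if m_bobv_kg <= 0:
        raise ValueError("mass must be positive")
    num = f_bv * af_bibv_to_bobv + (1.0 - f_bv) * af_bobv_to_bobv
    return num / m_bobv_kg


def af_ratio_local_deposition(f_bv: float) -> float:
    """Single/dual AF ratio when all charged-particle energy stays put."""
    return 1.0 / (1.0 - f_bv)


def saf_ratio_local_deposition(model: DualRegionModel) -> float:
    """Single/dual SAF(parenchyma <- blood) ratio in the same limit."""
    return model.m_BOBV / (model.m_B * (1.0 - model.f_BV))


# ---------------------------------------------------------------------------
# SAF curves
# ---------------------------------------------------------------------------

class SafCurve:
    """A SAF(E) curve with log-log PCHIP interpolation, knot-exact."""

    def __init__(self, energies_mev: np.ndarray, saf_per_kg: np.ndarray):
        e = np.asarray(energies_mev, float)
        v = np.asarray(saf_per_kg, float)
        if len(e) < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("energies must be strictly increasing, >= 2 points")
        if np.any(v < 0):
            raise ValueError("SAF values must be non-negative")
        self.energies = e
        self.values = v
        tiny = 1e-300
        self._interp = PchipInterpolator(
            np.log(e), np.log(np.maximum(v, tiny)), extrapolate=False
        )

    @classmethod
    def constant(cls, value: float, span=(1e-3, 12.0)) -> "SafCurve":
        e = np.array([span[0], np.sqrt(span[0] * span[1]), span[1]])
        return cls(e, np.full(3, value))

    def __call__(self, energy_mev):
        e = np.asarray(energy_mev, float)
        lo, hi = self.energies[0], self.energies[-1]
        if np.any(e < lo * (1 - 1e-12)) or np.any(e > hi * (1 + 1e-12)):
            raise ValueError(
                f"energy {e} MeV outside the tabulated span [{lo}, {hi}]; "
                "extrapolation is not performed"
            )
        out = np.exp(self._interp(np.log(np.clip(e, lo, hi))))
        return float(out) if np.isscalar(energy_mev) else out


def interpolate_saf(curve: SafCurve, energy_mev):
    """PCHIP log-log evaluation of a SAF curve (knot-exact, monotone)."""
    return curve(energy_mev)


# ---------------------------------------------------------------------------
# decay schemes
# ---------------------------------------------------------------------------

#: emission kind -> SAF-curve family
KIND_TO_CURVE = {
    "photon": "photon",
    "electron": "electron",
    "positron": "electron",  # positron SAFs differ from electron by <~0.2 %
    "beta-": "electron",
    "beta+": "electron",
    "alpha": "alpha",
    "alpha_recoil": "alpha",
}


@dataclasses.dataclass
class Emission:
    kind: str
    energy_mev: float | None
    yield_per_decay: float
    spectrum: tuple[np.ndarray, np.ndarray] | None = None  # (E, n(E)/MeV), unit integral

    def validate(self) -> None:
        if self.kind not in KIND_TO_CURVE:
            raise ValueError(f"unknown emission kind {self.kind!r}")
        if self.yield_per_decay < 0:
            raise ValueError("yields must be non-negative")
        if self.spectrum is not None:
            e, n = self.spectrum
            if np.any(n < 0) or not np.all(np.diff(e) > 0):
                raise ValueError("spectrum must be non-negative on an increasing grid")
        elif self.energy_mev is None or self.energy_mev <= 0:
            raise ValueError("discrete emission needs a positive energy")


@dataclasses.dataclass
class DecayScheme:
    nuclide: str
    emissions: list[Emission]

    def validate(self) -> None:
        for em in self.emissions:
            em.validate()


def read_decay_scheme(path: str | pathlib.Path) -> DecayScheme:
    """Read the plain-text decay dialect.

    One emission per line: ``kind  energy_MeV|-  yield  [spectrum_file]``;
    ``#`` comments; a ``# nuclide:`` header names the nuclide.  Spectrum
    files are two-column TSV (E_MeV, n per MeV) resolved relative to the
    scheme file and normalized to unit integral on read.
    """
    path = pathlib.Path(path)
    nuclide = path.stem
    emissions: list[Emission] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if line.startswith("# nuclide:"):
            nuclide = line.split(":", 1)[1].strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        kind, e_str, y_str = parts[0], parts[1], parts[2]
        spectrum = None
        energy = None
        if len(parts) > 3 and parts[3] != "-":
            grid = np.loadtxt(path.parent / parts[3])
            e, n = grid[:, 0], grid[:, 1]
            integral = np.trapezoid(n, e)
            if integral <= 0:
                raise ValueError(f"{parts[3]}: empty spectrum")
            spectrum = (e, n / integral)
        if e_str != "-":
            energy = float(e_str)
        emissions.append(Emission(kind, energy, float(y_str), spectrum))
    scheme = DecayScheme(nuclide, emissions)
    scheme.validate()
    return scheme


def load_packaged_scheme(name: str) -> DecayScheme:
    """Load one of the packaged synthetic decay-scheme fixtures."""
    ref = resources.files("vasodose.data").joinpath(f"decay_{name}_synthetic.tsv")
    with resources.as_file(ref) as p:
        return read_decay_scheme(p)


# ---------------------------------------------------------------------------
# S-values
# ---------------------------------------------------------------------------

def s_value(
    scheme: DecayScheme,
    saf_curves: dict[str, SafCurve],
    recoil_eval_mev: float = ALPHA_RECOIL_EVAL_MEV,
) -> float:
    """S-value (mGy/MBq/s): sum over emissions of E x yield x SAF(E)."""
    scheme.validate()
    total_mev_per_kg = 0.0
    for em in scheme.emissions:
        if em.yield_per_decay == 0.0:
            continue
        family = KIND_TO_CURVE[em.kind]
        if family not in saf_curves:
            raise ValueError(
                f"{scheme.nuclide}: no SAF curve for emission kind {em.kind!r}"
            )
        curve = saf_curves[family]
        if em.spectrum is not None:
            e, n = em.spectrum
            try:
                phi = curve(e)
            except ValueError as err:
                raise ValueError(
                    f"{scheme.nuclide}: spectrum of {em.kind} outside SAF span"
                ) from err
            total_mev_per_kg += em.yield_per_decay * np.trapezoid(e * n * phi, e)
        else:
            e_eval = recoil_eval_mev if em.kind == "alpha_recoil" else em.energy_mev
            try:
                phi = curve(e_eval)
            except ValueError as err:
                raise ValueError(
                    f"{scheme.nuclide}: {em.kind} at {e_eval} MeV outside SAF span"
                ) from err
            # recoils carry their actual energy but use the 2 MeV alpha SAF
            total_mev_per_kg += em.yield_per_decay * em.energy_mev * phi
    return float(total_mev_per_kg * MEV_PER_DECAY_TO_MGY_PER_MBQ_S)


def decay_chain_table(
    schemes: list[DecayScheme],
    curves_single: dict[str, SafCurve],
    curves_cross: dict[str, SafCurve],
    curves_self: dict[str, SafCurve],
    progeny: set[str] | None = None,
) -> pd.DataFrame:
    """One S-value row per nuclide, progeny reported individually.

    No branching-ratio summation is applied across the chain: combining
    rows into a series S-value needs the branching ratios and the
    biokinetics, which are downstream concerns.
    """
    progeny = progeny or set()
    rows = []
    for scheme in schemes:
        s_bb = s_value(scheme, curves_single)
        s_cross = s_value(scheme, curves_cross)
        s_self = s_value(scheme, curves_self)
        label = f"({scheme.nuclide})" if scheme.nuclide in progeny else scheme.nuclide
        rows.append(
            {
                "nuclide": label,
                "S(B<-B)": s_bb,
                "S(BOBV<-BB)": s_cross,
                "ratio_cross": s_bb / s_cross if s_cross > 0 else np.inf,
                "S(BOBV<-BOBV)": s_self,
                "ratio_self": s_bb / s_self if s_self > 0 else np.inf,
            }
        )
    return pd.DataFrame(rows)


def saf_curves_from_af_table(
    af_table: pd.DataFrame, model: DualRegionModel
) -> tuple[dict[str, SafCurve], dict[str, SafCurve], dict[str, SafCurve]]:
    """Build (single, cross, self) SAF curve sets from a tidy AF table.

    The table needs columns particle/energy_mev/source/target/af with
    sources ``B`` (single-region) and ``BIBV``/``BOBV`` (dual-region).
    """
    singles: dict[str, SafCurve] = {}
    crosses: dict[str, SafCurve] = {}
    selfs: dict[str, SafCurve] = {}
    for particle in af_table.particle.unique():
        sub = af_table[af_table.particle == particle]

        def grab(source: str, target: str) -> tuple[np.ndarray, np.ndarray]:
            rows = sub[(sub.source == source) & (sub.target == target)]
            rows = rows.sort_values("energy_mev")
            return rows.energy_mev.to_numpy(), rows.af.to_numpy()

        e, af_bb = grab("B", "B")
        if len(e):
            singles[particle] = SafCurve(e, af_bb / model.m_B)
        e, af_cross = grab("BIBV", "BOBV")
        e2, af_self = grab("BOBV", "BOBV")
        if len(e) and len(e2):
            saf = np.array(
                [
                    saf_dual_cross(a, b, model.f_BV, model.m_BOBV)
                    for a, b in zip(af_cross, af_self)
                ]
            )
            crosses[particle] = SafCurve(e, saf)
            selfs[particle] = SafCurve(e2, af_self / model.m_BOBV)
    return singles, crosses, selfs
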