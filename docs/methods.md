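# Methods

This note records the models implemented in `vasodose`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic
fixture does and does not emulate. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The synthetic organ fixture

The fixture stands in for a reference adult brain surface. It is an
axis-aligned ellipsoid whose volume equals the reference organ mass over
its homogenized density (female: 1.350 kg at 1.0407 g cm⁻³ →
1.297 × 10⁶ mm³; male: 1.517 kg at 1.0409 g cm⁻³), with aspect ratio
(1 : 0.78 : 0.70), giving semi-axes of roughly 83 × 65 × 58 mm for the
female organ.

The 13 vascular territories (left/right frontal, temporal, parietal,
occipital, cerebellar and central territories plus the brainstem) carry
the reference percentage-of-total-brain-volume values of the study
segmentation, bilateral entries split evenly and renormalized after
excluding the ventricles. The partition uses exact planes on two
levels: territories are first grouped, in order, into bands perpendicular
to the long axis, closing a band once it reaches 6.5 % of the organ
volume (a thinner slab cannot host a trunk vessel of ~1 mm radius);
bands holding several territories are then subdivided by planes
perpendicular to the second axis. Cut positions invert the analytic
ellipsoid volume profile (and, for the in-band cuts, the band-volume
integral of elliptical segment areas), so the realized fractions match
the targets analytically; the tests verify them by Monte Carlo
integration to 1 %.

Each territory gets one entry artery (inferior surface) and one entry
vein (superior surface) at the surface point above its footprint centre.
The backbone is a two-level rooted tree per side — root conduit, two
lateral branches, then one feeder and one terminal *artificial vessel*
per territory — with radii split from the root radius (3.0 mm arterial,
4.5 mm venous) by Murray's law on the flow shares. The artificial
vessels approach their entry points radially (along the outward surface
normal, via a waypoint 14 mm above the surface) so neighbouring feeders
do not crowd the surface. Backbone flows follow conservation with
region flows proportional to territory volume; pressures drop by
Poiseuille per conduit from 95 mmHg (arterial root) and 6 mmHg (venous
root).

What the fixture does **not** emulate: real cortical folding and
sub-region shapes, the anastomotic ring at the organ base, asymmetric
feeding (several real arteries per territory are already collapsed into
one artificial vessel by design), and ventricles as explicit voids.
Consequently, passing tests demonstrate that the *algorithm* satisfies
its constraints and reproduces the morphometric regularities on a
realistic geometry — not that any individual's anatomy is reproduced.

## Hemodynamic boundary values

| quantity | default | provenance |
|---|---|---|
| specific perfusion | 50 ml min⁻¹ / 100 g | reference physiology |
| tissue mass | 1300 g (F) / 1450 g (M) | reference anatomy |
| blood viscosity | 3.5 mPa s | typical large-vessel value (not printed in the sources; configurable) |
| arterial terminal pressure | 60 mmHg | arteriolar value at ~0.1 mm radius (decision; configurable) |
| venous terminal pressure | 15 mmHg | venular trunk pressure |
| root pressures | 95 / 6 mmHg | typical entry values (decision; configurable) |

Units are clinical at the interfaces (mmHg, ml min⁻¹, mm) and SI
internally; the conversion constants live in `hemodynamics`.

## Tree growth (CCO)

One binary tree per (territory, side). Terminal points are sampled
uniformly over the territory eroded by a 1 mm margin (so a terminal
capsule can stay contained) and visited in order of proximity to the
entry. Each terminal is attached to one of the k = 5 nearest segments;
the bifurcation point starts at the segment's closest point to the
terminal and is refined over two rounds of a 3×3×3 local grid, choosing
the feasible candidate of minimum added volume π r²ΔL, ties broken by
segment id then grid index. If no candidate among the 5 nearest is
feasible the pool escalates (20, then all segments); a terminal that
still cannot be connected is dropped with a logged warning — the
automated counterpart of the original manual repair step. Veins are
grown first and registered as obstacles for the arteries; artery and
vein share the terminal point set, and capsules sharing an endpoint are
exempt from the clearance test, which sanctions exactly the
artery-meets-vein contact at a shared terminal.

Hard constraints at insertion:

* **Angles**: the daughter–daughter angle at the new junction, and the
  modified-segment vs. sibling angle at the junction above, must be
  ≥ 30° (enforced with a 0.05° guard so audited angles clear the
  threshold); daughters must not be retrograde (positive projection on
  the parent direction), re-checked at the junctions above and below.
* **Containment**: capsules must lie inside the territory, proven
  rigorously by sampling every 0.5 mm and requiring the (1-Lipschitz)
  interior margin to exceed the reserve plus half the sample spacing.
  A ball of 3 entry radii around the entry point is exempt — the feeding
  vessel physically penetrates the surface there.
* **Clearance**: capsule–capsule separation ≥ max(0.01 mm, 5 % of the
  summed radii) beyond tangency against the growing tree, the other
  trees and the backbone.

Because Murray radii grow as terminals accumulate (a segment feeding m
of the eventual T terminals has radius r_t·m^{1/3}, and r_t itself is
re-calibrated), clearance and containment are checked against *growth
envelopes* rather than current radii: an own-tree segment that currently
feeds m terminals with T_rem still unplaced can grow by at most
((m+T_rem)/m)^{1/3}, times a 1.3 allowance for terminal-radius drift.
Containment reserves are additionally anchored to the feeding-vessel
radius scale r_entry·(m_f/T)^{1/3}, tapering to the sampled margin at
terminal ends. Split pieces must be longer than 2.5× the enveloped
radius so segments two junctions apart cannot reach each other's
hemispherical end caps. After growth, any residual overlapping pair is
repaired by the translate-then-rotate-then-both sequence applied to the
shared terminal point (all segments ending there move together, radii
and hence Murray's law untouched); unrepairable pairs are flagged.

Radius law: with equal terminal flows q_t = Q_region/T, flows are
q_t × (downstream terminal count) and radii r = r_t N^{1/3}, which makes
Murray's law and flow conservation exact by construction. The terminal
radius solves, in closed form, the requirement that the flow-weighted
mean root→terminal Poiseuille drop equal the entry−terminal pressure
difference: ΔP = (8 μ q_t / π r_t⁴) Σᵢ Lᵢ Nᵢ^{2/3} / T. At the
reference budget (1000 terminals per side) the smallest radii come out
at 0.12–0.17 mm.

Determinism: growth is a pure function of the terminal order, the
configuration, and the seed (used only for point sampling); identical
seeds give byte-identical serializations. CSVs are written at 12
significant digits so the audit of written outputs reproduces the
in-memory report.

## The audit

`vasodose.audit` re-implements every invariant from scratch — its own
segment-distance minimization (interior critical point plus the four
edges of the unit square), an independent terminal recount, O(n²)
pairwise capsule separation — so it is an oracle for the growth code,
not a restatement. Exemptions mirror the model: endpoint-sharing pairs
(connected vessels), backbone–backbone pairs (fixture plumbing), a
tree against its own feeding vessel, and the entry ball for containment.

## Transport

Charged particles travel straight continuous-slowing-down tracks; the
track is stepped (step ≤ min(path/400, half the smallest vessel
radius)), the areal depth accumulates ρ·ds, and the energy deposited per
step is the difference of residual energies read from the CSDA range
table, so each history conserves energy to rounding (< 10⁻⁶ relative,
asserted). Photons do an analog Woodcock walk: collisions thinned by
μ/μ_max, photoelectric-like absorption with probability
1 − μ_incoh/μ_tot (μ_incoh from the analytic Klein–Nishina cross-section
at 3.343 × 10²³ electrons/g), otherwise Klein–Nishina scattering (Kahn
sampling) with the energy transfer deposited locally (kerma
approximation; secondaries and bremsstrahlung are not transported —
declared fidelity limits of the desk-scale code, and the reason the
production S-value tables are only approximated in structure, not
bit-reproduced).

Physics tables are water-based (alpha and electron CSDA ranges, photon
μ/ρ and μ_en/ρ), digitized approximately from the standard public
compilations and scaled by material density; elemental composition
differences between the brain mixtures are neglected, consistent with
their near-identical mass energy-absorption coefficients. Positrons
reuse the electron table. Interpolation is PCHIP in log–log; below the
first range knot a matched power-law tail carries the residual energy
smoothly to zero.

Grids follow the study protocol: 24 alpha energies (0.5–12 MeV, linear
0.5 MeV steps) and 26 photon/electron energies (logarithmic,
10 keV–10 MeV). A (particle, energy) run stops when every
non-negligible tally's relative error is below 1 % or at 10⁶ histories;
tallies carry per-history variance. Tests run the sanity properties at
2–30 × 10³ histories; the pipeline demo uses a sparse grid — sizes the
package chooses for a desk-scale demonstration.

Source sampling is exact per region: volume-weighted capsule sampling
(cylinder + end-cap decomposition) for BIBV, rejection over
organ-minus-capsules for BOBV. Capsule membership along tracks is
brute-force vectorized, which bounds practical capsule counts to a few
hundred; the full 4000-vessel organ is serialized for the tet pipeline
rather than transported directly.

## Tetrahedralization

The tet mesher is predicate-based: a Kuhn lattice (6 tets per cube) over
the bounding box, boundary tets split by marching-tetrahedra
decompositions with crossings located by bisection (35 iterations), the
cut quadrilateral triangulated with the same diagonal on both sides so
the pieces tile each tet exactly. Per-tag volumes converge as O(h²);
h ≤ 0.17 × the smallest feature radius meets the 0.5 % volume contract
(verified against analytic cylinder/sphere volumes). Export: Gmsh MSH
2.2 ASCII and TetGen .node/.ele.

## Dosimetry

SAF algebra as in the package docstrings; the analytic local-deposition
limits used in acceptance are 1/(1−f_BV) for the AF ratio and
m_BOBV/(m_B(1−f_BV)) for the SAF ratio. SAF(E) curves interpolate with
PCHIP on log–log axes (a decision — the interpolant family is standard,
the axes are ours); queries outside the tabulated span raise rather than
extrapolate. Decay schemes are a one-emission-per-line text dialect
(kind, energy or spectrum reference, yield); the packaged At-211,
Po-211 and Bi-207 files are synthetic fixtures carrying the main
emissions with approximate yields, not evaluated nuclear data. Beta
spectra are integrated by trapezoid on their grid; alpha recoils carry
their own energy but read the alpha SAF at 2 MeV; no branching-ratio
summation is applied across a chain (that requires biokinetics and is
out of scope, as are time-integrated activities).

## Known limitations

* Single-territory feeding (no anastomoses), no capillary or
  pre-capillary network: the modeled vessels carry f_BV = 0.56 (F) /
  0.47 (M) of the organ blood, the rest stays homogenized in BOBV.
* Straight-track electron transport (no multiple scattering detours) and
  the kerma approximation for photons bias absorbed fractions at the
  few-percent level against production Monte Carlo.
* The capsule representation forces exemptions at junctions and at the
  entry ball; the exported tet model inherits capsule-union geometry.
* The pooled curve-path regression R² is seed-dependent (≈ 0.86–0.90
  across seeds at the reference budget), as expected for a pooled
  statistic over 26 trees of very different sizes.
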