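# Methods

`trabflow` models the fluid mechanics of the trabeculated ventricle of the
3 dpf zebrafish embryo: a beating chamber, 30–50 μm across, whose outer
curvature carries muscular ridges (trabeculae) separated by
intra-trabecular spaces (grooves) a few μm deep and one to a few tens of
μm wide. Because no image data are distributed with the original study,
the package replaces microscopy, segmentation and motion tracking with a
seeded parametric generator whose geometry and motion statistics match
the values measured on the confocal sections; all downstream analyses
(flow, wall shear stress, OSI, endocardial strain, scenario comparisons)
operate on that synthetic moving boundary exactly as they would on a
tracked one.

## Flow model

At the relevant scales (length L ≈ 40 μm, wall speeds U ≲ 1 mm/s, cycle
T = 0.25 s, plasma viscosity μ = 1.5 mPa·s, density ρ = 1.025 kg/L) the
Reynolds number is ≈ 0.02 and the Womersley number ≈ 0.2. Both are far
below one, so inertia — steady and transient — is negligible and the flow
at each cardiac frame is the *steady Stokes* solution driven by the
instantaneous wall velocity:

    μ ∇²u = ∇p,   ∇·u = 0,
    u = v_wall            on wall segments,
    μ ∂u/∂n − p n = −p_ref n  on open segments (reference pressure, 0 by default).

This quasi-steady reduction is the package's single largest divergence
from a transient dynamic-mesh Navier–Stokes treatment. It is justified a
posteriori by the Reynolds/Womersley audit attached to every cycle
result, and it makes one reported observation *exact* rather than
approximate: for fixed kinematics the velocity (hence the shear-rate
field γ̇) is independent of viscosity, so WSS = μγ̇ scales by exactly the
viscosity ratio (7.35/1.5 = 4.9 between whole blood and plasma). The
solver exploits this by assembling at unit viscosity and solving for
p/μ, which also equilibrates the saddle-point system.

The pipeline is 2D: it operates on the mid-chamber optical-section
cross-section (the plane the measured groove dimensions come from).
Claims tied to 3D surfaces (area strain) use a prismatic out-of-plane
extrusion of the cross-section by the longitudinal groove dimension.
Consequences: absolute WSS magnitudes are smaller than in the imaged
embryos (a 2D section cannot carry the full 3D flow), and all 3D claims
are asserted as orderings, never as absolute values.

### Discretization

* Taylor–Hood triangles (quadratic velocity, linear pressure), inf-sup
  stable; element integrals with the mid-edge quadrature rule, exact for
  every entry of the P2/P1 system. Linear and quadratic exact solutions
  (Couette, Poiseuille) are reproduced to solver precision, which the
  test suite asserts at 1e-9 relative.
* The domain is re-meshed at every frame (Delaunay of the exact boundary
  polyline plus a hexagonal interior lattice kept 0.55·h clear of the
  boundary, Laplacian-smoothed; boundary edges are verified present and
  recovered by local thinning). Boundary nodes are never moved or added,
  so the persistent object across frames is the boundary node identity,
  onto which all wall quantities are mapped.
* Direct sparse LU (COLAMD ordering) on the reduced system; ~2·10⁴–10⁵
  unknowns per frame at the default resolutions.
* Wall shear rate: γ̇ = t·(∇u + ∇uᵀ)·n at each boundary vertex, with the
  element-wise P2 gradient averaged over incident elements; objective
  under rigid wall translation (the prescribed rotations, < 0.07 rad,
  contribute negligibly and are not subtracted, matching the source
  study's neglect of rotations).
* Wall velocities are periodic central differences of node positions,
  v_i = (x_i(f+1) − x_i(f−1))/(2Δt), Δt = T/n_frames.
* Open boundaries: the do-nothing condition with a reference pressure,
  the discrete realization of a "zero reference pressure" opening. Nodes
  where a wall meets an opening carry the wall velocity (a free
  transition corner would absorb the wall traction into its weak
  equation; this was verified to destroy the otherwise-exact Couette
  solution). Valve switching: the inlet is open while the chamber fills
  (dA/dt > 0, central-differenced), the outlet while it ejects; an
  isolated groove's mouth is always open. Phase-switch frames are thus
  the extrema of the enclosed-area waveform.
* Mass audit: incompressibility ties the open-segment flux *relative to
  the moving opening* to −dA/dt. The per-frame residual is reported
  normalized by |dA/dt|, floored at 5% of the cycle-peak rate so
  near-extremum frames (where dA/dt crosses zero) do not divide by zero.
  Default-resolution runs stay below 2%.

## Synthetic geometry and motion

Chamber envelope: an ellipse, short axis = `inner_diameter` (default
40 μm, valid 30–50 μm), elongation = 1/`curvature_ratio` (default
0.6). Grooves live only on the outer-curvature arc (ellipse parameter
15°–165°); inlet and outlet are 8 μm opening segments on the inner
curvature (their dimensions are not constrained by any measurement; the
defaults are a choice). If a seed's sampled grooves cannot pack on the
outer arc, the long semi-axis grows until they fit — never the measured
short axis — so realized dimension statistics stay unbiased.

Groove dimensions are sampled per groove from independent Gaussians with
the measured end-systolic statistics — longitudinal 12.5 ± 3.1 μm (used
as the extrusion height), radial (depth) 8.7 ± 0.8 μm, circumferential
21.7 ± 10.7 μm — truncated at ±2 sd so no non-physical negative length
can be drawn, with a 4 μm floor on the circumferential extent for
meshability. The "circumferential dimension" is realized as the full
mouth-to-mouth extent of the pocket (the measurement convention of the
source is not stated). A pocket is a flat-bottomed C1 radial offset
profile beyond the envelope; the end-systolic frame realizes the sampled
nominal dimensions exactly.

Motion over one cycle (phase 0 = end-diastole):

* Enclosed area follows a piecewise-cosine, C1-periodic waveform:
  ejection to 65% of the end-diastolic area at phase 0.36 (end-systole),
  early filling, diastasis, and a late-diastolic A-wave completing the
  refill — the two-transient structure of the measured WSS waveforms.
  The per-frame chamber scale factor enforces the waveform exactly
  (polygon area scales as s²), and equals one at end-systole.
* Groove squeeze: the pocket width factor tracks chamber filling,
  1 at end-systole to 1 + `groove_squeeze` (default 0.35, i.e. a
  factor 1.35) at end-diastole. Part of the stroke area is therefore absorbed by groove
  closure — the squeeze-film mechanism that drives intra-trabecular flow
  — and the envelope scale varies correspondingly less than in the
  smooth counterpart.
* Node kinematics: envelope nodes keep a fixed arclength coordinate;
  pocket nodes keep a fixed *fraction of the local pocket outline
  length*. As the pocket squeezes a wall node travels with the folding
  wall instead of sliding across it — the material-like motion of an
  endocardium that creases and uncreases without stretching. (A
  fixed-angle parameterization was tried first and rejected: it
  produces spurious tangential sliding worth ~10 percentage points of
  apparent wall strain.)
* Rigid translation (default amplitude 4 μm, contraction-locked plus a
  smaller out-of-axis component) and a small rigid rotation (default
  0.03 rad sinusoidal, always below the 0.07 rad bound the imaging
  resolved) ride on top; neither changes the enclosed area. Rotation is
  measured (2D Kabsch) and reported but never removed.
* 25 frames per cycle at T = 0.25 s, from the printed acquisition
  cadence (100 frames/s, ~25 frames per cycle); the cycle is periodic by
  construction (frame n ≡ frame 0).

Isolated grooves are produced the way the study produced them: the
pocket of groove 0 plus a 2.5 μm ridge collar is cropped from a whole
ventricle along a single chord, which becomes the zero-pressure "mouth"
opening. The isolated wall therefore moves exactly like the embedded
one. Motion decomposition splits node motion into the area-centroid
translation and the remainder (deformation); the recomposition identity
is exact by construction.

Trapped cells (hemogenic cells observed wobbling inside grooves) are
rigid circles, default diameter 7 μm (observed 6–8 μm), placed at the
position maximizing worst-frame wall clearance, moving with the mean
displacement of their host groove's wall plus a seeded period-1 wobble
(default amplitude 0.3 μm). Placement requires static clearance of
0.3 μm plus twice the wobble amplitude; a groove too small for that is
rejected — which is physical: cells are found only in spaces that can
hold them (the default cell-experiment replicates are the first seeds
whose grooves qualify).

The smooth (non-trabeculated) counterpart is the envelope over the ridge
crests, resampled to the same node count and driven by the *same*
enclosed-area series (per-frame match is exact, so stroke area is
preserved to machine precision).

## Wall metrics

* WSS: τ = μγ̇ per node per frame, signed along the loop tangent.
* Mixed viscosity: groove (and cell) surfaces use plasma viscosity —
  blood cells are excluded from the narrow spaces by size — ridges and
  everything else use whole blood. By linearity this equals combining
  two full solves, which is tested.
* TAWSS: periodic trapezoidal mean of |τ| (uniform frames).
* OSI = ½(1 − ‖∫τ dt‖ / ∫‖τ‖ dt): the standard vector definition is
  adopted (the source defers its formula to an unavailable supplement);
  range [0, 0.5], 0 unidirectional, 0.5 zero-mean, invariant under
  positive rescaling and hence viscosity-independent.
* Ridge/groove classification: the automated surrogate for manual
  delineation fits the crest envelope as a general conic by trimmed
  least squares (each pass drops the most recessed nodes) and labels
  nodes receding > 2 μm beyond it as groove; ≥ 90% of ground-truth
  groove nodes are recovered on generated fixtures. A manual mask is
  honoured verbatim.
* Area strain: per-element (A_ES − A_ED)/A_ED on the extruded surface at
  the area extrema; the summary is the area-weighted mean of |strain|
  (the source does not define its averaging; this choice is recorded in
  the strain object's metadata). Regional averages weight nodes by
  incident boundary segment half-lengths.
* Exact Wilcoxon signed-rank test: full enumeration of the 2ⁿ sign
  assignments via the subset-sum distribution of the rank sum; ties get
  average ranks, zeros are dropped with a warning. One-sided by default:
  the reported p = 0.0625 at n = 4 is attainable only one-sided (the
  two-sided floor is 0.125); sidedness is always explicit in the API.

## Scenario experiments and their thresholds

* Motion decomposition (n = 6 grooves): "drastically diminished" is
  operationalized as < 25% of the full-motion WSS; "insignificant
  change" as paired one-sided Wilcoxon p > 0.05. Both thresholds are
  package choices recorded in the comparison-table metadata. In practice
  the translation-only runs give WSS at numerical-noise level (a rigidly
  translating cavity with an opening admits the uniform co-moving
  velocity field, which is shear-free), and the squeeze-only runs are
  indistinguishable from full motion — the Galilean-invariance argument
  the source's finding amounts to.
* Baseline vs no-ventricle: the comparison averages TAWSS over the
  intra-trabecular (groove-labelled) surface proper. Including the
  exposed ridge collar in the average makes the embedded runs
  systematically higher (the collar feels the main-chamber sweep that an
  isolated space lacks), which is a statement about the collar, not
  about the space.
* Trabeculated vs smooth (n = 4 pairs): strain compared at matched
  stroke (tolerance 2%, achieved exactly); ridge/groove TAWSS and OSI
  contrasts under the mixed-viscosity scheme; whole-ventricle means at
  plasma viscosity, as in the source comparison.

## Problem sizes and defaults

| quantity | default | note |
| --- | --- | --- |
| frames per cycle | 25 | acquisition cadence of the study |
| boundary node spacing | 1.0 μm (ventricle), 0.45 μm (groove) | groove pockets need finer walls |
| mesh edge length | = node spacing; 1.2 μm for the 4-pair ventricle comparison | chosen problem sizes for the replicate experiments |
| viscosities | 1.5 / 7.35 mPa·s | plasma / whole blood |
| density | 1025 kg/m³ | inertially irrelevant in the Stokes limit |
| replicate counts | 6 grooves, 4 ventricle pairs, 2 cell pairs | the study's ns, configurable |

## What the synthetic data do and do not show

The generator reproduces the *statistics* of the measured geometry and
the *structure* of the measured motion, not any particular embryo. Tests
passing on it validate the mechanisms (squeeze-flow dominance, viscosity
scaling, sheltering, strain relief at matched stroke, OSI contrast) and
the numerics, but say nothing about absolute WSS levels in real embryos:
the reported 0.124/0.147 Pa means, the 3.1-fold ridge/groove shear-rate
contrast and the 25%→17% strain reduction depend on the four imaged
geometries, which are not available. The synthetic cross-sections give
the same *directions* with, e.g., mean |strain| of ~17% (trabeculated)
vs ~19% (smooth) and ridge/groove shear-rate ratios of ~3–5. Real
trabeculated boundaries are also rougher than the smooth-enveloped
pockets generated here, real motion contains out-of-plane components a
cross-section cannot carry, and wall contact during systole (which the
source's own tracking could not fully capture) is not resolved — pocket
width never drops below its end-systolic value.

## Known limitations

* 2D cross-section; extrusion is prismatic, not a revolved or imaged 3D
  surface.
* Quasi-steady: no transient inertia (Womersley effects ~2% at these
  parameters); no fluid–structure interaction; single-phase fluid (cells
  enter only as rigid moving walls).
* Re-meshing per frame makes volume fields frame-local; only boundary
  quantities have persistent identity.
* Near wall-contact (gap ≲ one edge length) is handled by the interior
  clearance logic but genuine contact/folding is out of scope.
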