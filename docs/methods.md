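# Methods

## Hydraulic model

The LCN is modelled as a hydraulic circuit. Nodes are junctions of
canaliculi, lacunae, vascular channels, or points on the endocortical/
periosteal surfaces; edges are canaliculi. Conservation of fluid at
every interior node (Kirchhoff's first law) combined with Darcy's law in
every canaliculus yields the weighted graph-Laplacian system

    AᵀCA · p = f,

where `A` is the directed edge–node incidence matrix (+1 at the node an
edge points toward, −1 at the other end), `C` the diagonal conductance
matrix and `f` the nodal fluid source rates. We report the pressure
drop along each edge's orientation (tail minus head), so a positive
flow `q_j = C_jj Δp_j` runs from high to low pressure along the edge
direction; the predictor only ever uses |v|, so this sign convention is
cosmetic.

**Sources.** A node's pore volume `V_i` is half the volume of its
incident canaliculi (length × cross-section) plus, for lacunae and
vascular channels, the body volume. Under a volumetric strain rate
ε̇_vol (compression negative) the node expels fluid at
`f_i = −V_i ε̇_vol,i` µm³/s. The cyclic loading waveform is triangular,
so the strain-rate amplitude is the constant ramp slope
`2·f·ε_peak` (defaults: 1,200 µε at 4 Hz → 9.6·10⁻³ 1/s axial). The
solve is quasi-static per load ramp; no time-resolved poroelasticity.

**Conductances.** Fluid flows in the fibre-filled annulus between the
osteocyte process and the canalicular wall. That microstructure is
collapsed into one effective permeability `k_p` acting over a constant
annulus area `A_cs = 0.045 µm²` (canalicular diameters are below the
optical resolution, so no per-edge area is ever estimated from images):
`C_jj = k_p A_cs/(µ l_j)` with defaults `k_p = 10⁻⁷ µm²`,
`µ = 10⁻³ Pa·s`. Because the surface predictor is affinely calibrated,
the absolute conductance scale cancels; only ratios matter.
`randomize_conductances` applies mean-1 lognormal factors of chosen CV
to probe robustness to unknown per-canaliculus permeability.

**Boundary conditions.** All surface and vascular nodes are Dirichlet
sinks at reference pressure 0; the slab's cut faces are no-flux. Each
connected component must contain a sink, otherwise the solve reports a
singular-system error naming the component. The sparse SPD system is
solved with a sparse LU factorization; the interior Kirchhoff residual
is checked against 1·10⁻⁹ of the source scale on every solve.

## Surface predictor

Both surfaces are discretized into 180 wedges of 2° about the section
centroid (half-open intervals, circular indexing). Each canaliculus is
assigned to the wedge of its midpoint angle and contributes to *both*
surfaces' profiles with its own distance `r` to each boundary polyline —
the exponential weight `w = exp(−r/R)` suppresses far contributions, so
no hard ownership rule is needed. The per-wedge flow predictor is the
weighted mean `(Σ w_j l_j)⁻¹ Σ |v_j| l_j w_j`; normalizing by `Σ w_j l_j`
makes a constant-velocity wedge return exactly that constant. Empty
wedges report 0 and are logged. The default decay length is
`R = 15 µm`; the parameter study (`r_sensitivity`) re-runs predictor,
smoothing, calibration and RMSE on a grid of R.

The strain predictor applies the same weighting to |ε̇_vol| sampled on a
regular 2-µm grid of points inside the cortex with uniform per-point
weights; it sees only the macroscopic strain field, never the network.

Profiles are smoothed with a circular triangular moving average of 30°
total width (kernel normalized to sum 1, hence mean-preserving), mapped
to µm of (re)modeling thickness by a single affine least-squares fit
per animal jointly over both surfaces (a negative slope is clipped to
zero — the predictor is a magnitude), and scored with
`RMSE = sqrt(Σ(pred−meas)²/N)`, N = 180.

## Image pipeline

Threshold → segment → skeletonize → graph, all deterministic:

* fixed global threshold (the acquisition-specific value is a required
  parameter);
* morphological opening with a 1-µm spherical element isolates bulky
  bodies, classified by volume: ≥ 1,000 µm³ together with a
  slab-spanning or >10 µm-thick check → vascular; ≥ 50 µm³ → lacuna;
  smaller bulky bodies stay canalicular (logged). Each body then absorbs
  the pore voxels within one opening radius ("expansion" into the
  canaliculi); the pre-expansion voxel set is kept as the body's core
  surface;
* the canalicular phase is thinned to a 1-voxel 3D skeleton
  (26-connectivity). Voxels with ≥3 neighbours form junction nodes;
  adjacent junction voxels are merged, and junction pairs closer than
  1.5 µm are fused, since thinning can split one anatomical intersection
  into nearby branch voxels. Skeleton endpoints within 4 µm of a body
  core attach to that body's node and the gap to the core surface is
  added back to the edge length (this restores the absorbed collar);
  unattached endpoints become boundary nodes (canaliculi leaving the
  imaged volume). Free-ending spurs shorter than 0.75 µm are pruned,
  sub-3-voxel cycles collapsed, longer self-cycles split at their
  midpoint.
* Edge lengths are summed chords over 5-voxel strides of the centerline
  path rather than single-step sums: stepwise summation systematically
  overestimates oblique digital lines by up to ~8%, while stride-chord
  summation stays within ~2 voxels of the true length on straight tubes
  and still follows genuine curvature.

Node positions use the voxel-centre convention: voxel (ix,iy,iz) sits at
((ix+0.5)·s, …) µm.

## Morphometry

Canalicular density (Ca.Dn, µm/µm³) is evaluated on cubic subvolumes,
default edge 8 µm (the subvolume size is exposed as a parameter; a
7.4-µm variant is a one-argument change). Segments are clipped exactly
at cell borders, so the map conserves total length to machine
precision. Pore density distributes each lacunar/vascular body volume
as an equivalent-volume sphere (the simplest shape with the correct
volume), voxelized deterministically and renormalized so the body's
volume is conserved exactly; canalicular volume is excluded.

## Synthetic data generator

The generator emulates the structural features of a murine cortical
cross-section at desk scale. Defaults: annulus of outer radius 150 µm,
inner radius 100 µm, slab thickness 50 µm, 150 lacunae of 200 µm³
(order-of-magnitude murine lacuna), 6 vascular channels of 2,000 µm³,
target Ca.Dn 0.27 µm/µm³ and a depleted angular band (Gaussian dip,
FWHM 60° at 120°, floor factor 0.2) with the vascular channels placed
inside it — reproducing the observed co-location of high porosity and
loose network. A real cross-section is an order of magnitude wider with
~2,300 lacunae; all radii and counts scale up through the spec if
wanted.

Construction: a cubic lattice with jittered node positions fills the
annular slab; edges are thinned with the band-modulated keep
probability, then dropped lattice edges are re-added Kruskal-style until
one connected component remains (guaranteed connectivity without
distorting density much). The lattice spacing is calibrated so the mean
Ca.Dn over the annulus hits the target: an initial spacing is predicted
from the band profile (length density 3/a² for spacing a), the achieved
density of a first draw is measured, and the network is regenerated once
with the corrected spacing — all driven by the spec's single seed, so
generation is a pure function of the spec. Note a spanning-connected
lattice cannot be thinned below ~1/3 of full density, which bounds the
achievable band contrast at roughly 3–5-fold; the qualitative
heterogeneity (not its exact contrast) is what the analysis exercises.

Responses: measured (re)modeling thickness per wedge is
`slope · (smoothed flow predictor at true R = 15 µm) + intercept +
N(0, σ)` with σ = 5 µm by default; when slope/intercept are unset they
are scaled so the response spans about [−10, 50] µm, the magnitude of
murine tibial (re)modeling, with bending about a neutral axis at 105°
so the response maxima fall near 15° and 195°. Images are rasterized
with canaliculi as ~3-voxel-wide tubes (2×2-voxel beams are degenerate
under 3D thinning), lacunae as volume-matched ellipsoids and vascular
channels as slab-spanning cylinders.

**What the synthetics do not emulate:** imaging noise statistics and
point-spread blur of real confocal data, curved canaliculi, realistic
degree distributions, woven-bone/calcified-cartilage microstructure, or
a biologically mechanistic remodeling rule. Passing tests therefore
demonstrate the correctness and internal consistency of the pipeline —
and that network architecture is recoverable *when it drives the
response* — not the biological truth of the fluid-flow hypothesis on
real tissue.

## Problem sizes and determinism

Replicate studies (predictor comparison, R recovery) use a desk-scale
animal: outer radius 100 µm, inner 70 µm, slab 20 µm, 40 lacunae, 3
vascular channels (~10⁴ nodes, ~3·10⁴ canaliculi), 100 seeded
replicates. The default-spec cross-section (~6·10⁴ nodes, ~1.6·10⁵
canaliculi) is used for morphometry. All randomness flows through
`numpy.random.default_rng` seeded from the spec or function argument;
repeated runs are bit-identical, and CSV exports use a float format that
round-trips IEEE doubles exactly.

## Known limitations

* The beam-bending surrogate is pure Euler–Bernoulli bending with a
  configurable compressive/tensile asymmetry (default 1.4) and
  volumetric conversion (1−2ν), ν = 0.3; it is not a validated FE field,
  and all properties are stated on the surrogate or imported fields.
* Whether the source amplitude should be the peak or a cycle-averaged
  strain rate is a modelling choice; the affine calibration absorbs the
  constant factor either way.
* The predictor-to-µm mapping is a fitted affine calibration; absolute
  predictor units are not interpretable.
* Exact-topology image round-trips are demonstrated on noise-free
  phantoms with well-separated tubes; real stacks with touching
  canaliculi will fragment or merge branches, and only statistical
  fidelity should be expected there.
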