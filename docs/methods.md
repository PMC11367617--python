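# Methods

`tfusnav` plans transcranial focused ultrasound (tFUS) dose delivery by
pre-computing skull-aware acoustic beams for many candidate transducer
placements on a subject's scalp ("model-based navigation", MBN) and
comparing the resulting per-nucleus doses against line-of-sight targeting
(LOST) and water-only propagation ("Water").

## Acoustic material model

CT (or pseudo-CT) Hounsfield units are scaled to bone porosity,

    phi = clip(1 - HU/1000, 0, 1),

and every acoustic variable x in {rho, c, alpha} is a porosity-weighted
mix of its soft-tissue (brain) and cortical-bone endpoints,

    x = phi * x_brain + (1 - phi) * x_bone.

Default endpoints follow the IT'IS material database values commonly
used for tFUS planning: rho = 1046/1908 kg/m³, c = 1546/3514 m/s,
alpha = 6.8/54.6 Np/m/MHz (brain/bone). Attenuation is stored per-MHz and
scaled by the solver as `alpha * f_MHz**exponent` with a linear default
(`exponent = 1`), matching the Np/(m·MHz) unit; the exponent is exposed
for power-law media. Voxels outside the head mask receive water
properties (1000 kg/m³, 1500 m/s, 0 Np/m) because the transducer couples
through a gel pad or water standoff. The head mask itself is a CT
threshold followed by largest-connected-component selection and hole
filling; the threshold is a required configuration value (≈ −200 HU for
typical CT) since no universal value exists across pseudo-CT methods.

## Scalp meshing and virtual transducers

The head mask is represented as the zero level set of a Gaussian-smoothed
signed distance field (sigma = 1 voxel). Marching cubes extracts a fine
triangulation; vertex-clustering decimation, with the cluster size tuned
by bisection, brings the face count within ±10% of the requested target
(the practical working range is ~1000–4000 faces per head; the test
phantoms use down-scaled meshes). Decimated vertices are relaxed
tangentially and re-projected onto the level set (damped Newton steps),
which equalizes triangle shapes, and each face's outward normal is taken
from the gradient of a more heavily smoothed copy of the distance field
(sigma = 3 voxels) rather than from the coarse triangle geometry. This
matters: at ~100 faces, raw triangle normals scatter several degrees
about the true surface normal, enough to swing the focal spot off a
deep target by millimetres; field-gradient normals stay within ~1°.

Each mesh face is a virtual transducer site: exit-plane center at
`face_center + standoff * normal`, beam axis along the inward normal.
The standoff models the gel-pad thickness; changing it moves every site,
so the beam library is stamped with a physics hash and a mismatch forces
a full re-computation rather than silently reusing stale beams. Faces
can be excluded (plane/box predicates or explicit lists, e.g. below the
eyes and ears); exclusion only flags validity, geometry and adjacency
are untouched.

## Beam solver

The solver is a one-way split-step (hybrid angular-spectrum) marcher for
the continuous-wave complex pressure on a transducer-aligned grid:
1.3·d transverse, 2·f axial (d = aperture diameter, f = focal distance),
lambda/5 isotropic spacing in water (0.46 mm at 650 kHz). The focused
bowl enters as a phased disk on the z = 0 exit plane — uniform amplitude
inside the aperture with the converging phase `−k(sqrt(r²+f²) − f)` —
the standard idiom for planar-marching solvers; it degrades for strongly
curved, low-f-number bowls.

Each marching step applies
1. the angular-spectrum transfer function `exp(i k_z Δz)`,
   `k_z = sqrt(k_ref² − k_x² − k_y²)` with water as the background
   (`c_ref` = 1500 m/s); evanescent components decay exponentially
   rather than being truncated or wrapped;
2. a real-space heterogeneity screen
   `exp(i (ω/c(r) − k_ref) Δz) · exp(−α(r) Δz)` from trilinearly
   resampled property volumes (out-of-volume points are water);
3. optionally (default on) a plane-wave transmission factor
   `2 Z₂/(Z₁+Z₂)` wherever the impedance ρc changes between consecutive
   planes — without it a one-way marcher conserves pressure amplitude
   across interfaces and overestimates transmission into bone;
4. an 8-voxel raised-cosine absorbing strip on the transverse edges
   against FFT wrap-around.

Intensity is `|p|²/(2ρc)` with the local resampled properties; all
doses are in arbitrary units (linear solver, unit source amplitude).
Fields are complex64 with float64 screen/impedance arithmetic and
float64 power accumulators. The scheme is validated against a
brute-force Rayleigh–Sommerfeld integral (independent oracle): on-axis
peak position agrees to < 0.1 mm and the focal-plane profile
cross-correlates ≥ 0.999 in water. Known limits, accepted by design:
no backscatter, reverberation or standing waves (one-way), no shear
conversion in bone, no nonlinearity, and the phased-disk source
approximation. A genuine physical effect worth knowing: a focused bowl's
on-axis intensity peak sits slightly proximal to the geometric focus
(diffraction focal shift); for the d = 61 mm, f = 65 mm, 650 kHz
geometry the shift is ≈ 2.2 mm (< 1 wavelength), for small test bowls
with low Fresnel number it can exceed a wavelength — tests compare
against the oracle's peak, not naively against f.

## Dose, scalp maps, navigation

The dose of a beam in a nucleus is the sum of beam intensity sampled at
the nucleus's voxel centers (trilinear, zero outside the beam domain)
times the voxel volume; sampling is beam→anatomy because the label map
is authoritative on the head grid. A scalp map holds one dose per mesh
face; excluded faces carry NaN, never zero. Raw maps are jagged at
coarse mesh resolution, so navigation uses a smoothed map: k iterations
(default 3) of area-weighted averaging over edge-adjacent faces, a
convex combination that cannot create new extrema. The exact smoothing
kernel used in clinical practice is not standardized; the stabilization
property (peak location robust to mesh resolution on smooth phantoms)
is what the tests pin down, not a specific kernel.

Navigation is a pure lookup: a tracked pose is matched to the nearest
virtual site under the metric `|Δposition| + w·(1 − cos θ)` (w = 10
mm/rad), implemented with a k-d tree plus a bounded candidate sweep so
it is exact with respect to a linear scan; poses farther than a 10 mm
gate from every site are flagged off-scalp rather than erroring.
Tracking streams are simulated with seeded jitter (2 mm / 1° by
default, the accuracy of typical optical cameras).

## Placement strategies

* **LOST** — the target centroid must lie on the device centerline at a
  water depth equal to f, i.e. pad thickness t = f − depth ∈ [0, t_max]
  (default t_max = 30 mm). Among feasible scalp entries the one with the
  most perpendicular incidence wins (ties: thinner pad, then lower face
  id); this operationalization of "line of sight" is this package's
  rule, since clinical practice varies. The reported LOST dose is a full
  skull-aware solve at that pose — LOST ignores the skull when *choosing*
  the pose, not when *scoring* it.
* **Water** — one water-only solve rigidly moved to every face (the
  source is radially symmetric, so a rigid transform of the local grid
  is exact); no per-face propagation.
* **MBN** — the face maximizing the smoothed scalp map; the reported
  dose is the raw dose at that face (the smoothed value is a display and
  stabilization device, not a physical dose).

Group comparisons report per-method min:max ratios (printed as "x:1"),
the percent change of means MBN vs LOST, and a two-sided two-sample
t-test (Welch by default; pooled variance available). A zero minimum
dose yields an infinite ratio with an explicit flag.

## Synthetic phantoms

Real subject MRI/pseudo-CT volumes are not distributable, so every
stage runs on layered-head phantoms: nested ellipsoids (scalp, skull
shell, brain) with ellipsoidal nuclei painted as integer labels.
Boundaries are anti-aliased (partial-volume fractions over a one-voxel
ramp), emulating CT partial-volume averaging; without this, the binary
staircase of the shell adds several percent of direction-dependent
dose noise that real, smoothly-sampled anatomy does not have. Skull
porosity is `mean + amplitude × smoothed seeded Gaussian noise`,
clipped to [0,1] (default mean 0.3, amplitude 0.15, 5 mm correlation
length — representative of adult skull porosity maps); HU values are
synthesized by inverting the porosity scaling so phantoms exercise the
real material pipeline. Phantoms are deterministic given their seed.

What the phantom does *not* emulate: realistic skull geometry (no
temporal-window thinning, no sutures), scalp/skin layering, CT noise
and beam-hardening artifacts, or anatomically shaped nuclei. Passing
the symmetry and equivalence tests therefore demonstrates correctness
of the machinery (solver, resampling, meshing, dose accounting), not
clinical accuracy on real heads.

## Problem sizes and numerical choices

Default test/example problem sizes are deliberately small: a 46 mm
spherical "head" with a 6 mm skull shell at 1.5 mm voxels, ~50–100
virtual transducers, and the 61 mm / F55 clinical transducer geometry
(grid 173×173×239 at 0.46 mm) — chosen so a complete pre-computation
and comparison runs on a single CPU in minutes while preserving the
geometry ratios of a human study. Verified properties at these sizes:
scalp-map coefficient of variation 2.5% on the symmetric phantom
(limit 5%), MBN vs LOST agreement within 0.1% (limit 2%), MBN/Water
map correlation > 0.999 in the no-skull limit.

Other numerical choices: beam libraries store per-face intensity as
scaled float16 (relative error ~10⁻³, far below the few-percent dose
tolerances) with gzip compression; pre-computation is order-independent
and resumable, so results are bit-identical for any worker count; ties
in argmax-style selections always break to the lowest face id; the
marching step guard rejects Δz > λ/2; degenerate inputs (empty masks,
all-excluded meshes, absent labels, NaN fields) raise informative
errors rather than propagating silently.
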