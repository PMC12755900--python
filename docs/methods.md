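# Methods

## The estimator

Membrane thickness is defined operationally as the distance between the two
phospholipid head-group density maxima along the membrane normal.  For a
triangle with centroid **c** and unit normal **n**, the density profile is

    p(u) = V(c + u·n),   u ∈ [−10, +10] nm in 0.25 nm steps (81 samples),

with V the trilinearly interpolated tomogram.  Samples falling outside the
volume are dropped, not clamped (clamping fabricates density); a profile
keeping fewer than 75 % of its samples is discarded, because asymmetric
truncation biases the fit.  Volumes flagged `heads_dark` are negated at
sampling time so all downstream code can assume head groups are maxima.

Profiles are averaged over geodesic neighbourhoods of the triangle graph
(triangles adjacent when they share ≥ 1 vertex, edge weight = centroid
distance).  The default radius is 12 nm with weight w(d) = 1/(1+d[nm]);
both are configurable.  Geodesic rather than Euclidean neighbourhoods are
essential: apposed membranes (the two faces of a crista, stacked ER
sheets) can sit closer than 12 nm in space, and a Euclidean ball would
average across distinct bilayers.  The same argument applies to patch
membership (below).

The averaged profile is fit with a dual Gaussian plus constant baseline,

    f(u) = a₁G(u−μ₁;σ₁) + a₂G(u−μ₂;σ₂) + c,   t = μ₂ − μ₁,

by bounded least squares (analytic Jacobian).  Initialisation: μ at the
argmax on each side of the midline, σ = 0.8 nm, amplitudes from peak
height minus the profile median, c at the median.  Bounds: |μ| ∈
[0.5, 6] nm (keeps the two Gaussians on opposite sides of the mid-surface
and inside plausible half-thicknesses), σ ∈ [0.2, 3] nm, a ≥ 0.  The
baseline is free although the minimal model is just two Gaussians:
tomogram profiles sit on a nonzero background, and fixing c would bias the
amplitudes; when the free-baseline fit fails, a fallback with c frozen at
the median is tried.  Solutions with a mean pinned at a box bound, or
profiles with no peak above the median on one side, are reported
non-converged and excluded from every downstream statistic — never
silently kept.  No correction is applied for defocus banding.

Global (whole-surface) thickness averages all valid scans (plain mean,
no area weighting) and fits once.

Edge exclusion removes triangles with geodesic boundary distance < 8 nm
(boundary = triangles owning an edge used by only one triangle); closed
surfaces lose nothing.  Exclusion only masks values, it never modifies
retained measurements.

## Statistics conventions

All distribution summaries are area-weighted: histogram heights are
relative membrane area per bin (right-closed bins: a value on an interior
right edge belongs to the lower bin; the last bin is closed), and the
median is the smallest value whose cumulative area reaches half the total.
The sampling unit for hypothesis tests is the per-connected-component
area-weighted median (components with < 10 valid triangles are dropped):
neighbouring triangles are strongly correlated, and per-triangle tests
would overstate significance wildly — the CLI requires an explicit
override to test raw triangles.  Group comparisons use the two-sided
Mann–Whitney U test, exact by enumeration when min(n) ≤ 8 without ties,
otherwise the normal approximation with tie and continuity corrections.
Curvedness quantile partitions (default edges 0/0.5/0.9/0.95/0.99/1) use
unweighted per-triangle quantiles with linear interpolation; an
area-weighted variant exists behind a flag.  2D histograms share the 1D
bin convention so marginals match exactly; curvedness is log₁₀-transformed
for display, with zero-curvedness triangles dropped and counted.

## Surface geometry

Curvedness is estimated per triangle by an osculating-jet fit: neighbour
centroids within an 8 nm geodesic radius are expressed in the triangle's
tangent frame and fit with a polynomial height function (full degree-4 jet
when ≥ 24 neighbours, degree-2 otherwise; < 6 neighbours → invalid).
Principal curvatures come from the shape operator of the fitted graph, and
curvedness = √((κ₁²+κ₂²)/2).  On the analytic test suite the estimator is
exact on planes and within 1 % on spheres (R = 20 nm) and cylinders.

Inter-surface distance is the exact point-to-triangle Euclidean distance
from each source centroid to the nearest target triangle (k-d-tree
candidate pruning with a circumradius bound guarantees exactness).  IMM
subcompartments use the excess over the modal OMM distance (area-weighted
histogram, 1 nm bins centred on integer multiples, ties to the lower bin):
IBM below 4 nm excess, crista junction 4–14 nm (both ends closed), crista
body above 14 nm.  The upper junction bound of 14 nm is used for the
crista-body threshold; rough vs smooth ER is an input label, no ribosome
detection is attempted.

## Patch analysis

Particles are assigned to their nearest valid triangle (k-d tree); a
particle farther than 24 nm — the height of ATP synthase — from any
triangle is excluded as a likely cross-assignment from another organelle.
Patches are all triangles within a 12 nm geodesic radius of the centre
triangle.  Randomized controls are count-matched and drawn uniformly over
an allowed region with pairwise Euclidean centre separation > 12 nm
(rejection sampling, seeded; failure after 10⁴·n attempts reports the
achievable count).  Member normals are curated to point toward the
particle (reference: the vector from the centre-triangle centroid to the
particle; randomized patches keep the centre triangle's stored side).
Extended profiles run from −10 to +30 nm (161 samples); per-patch profiles
average members with area weights — the centre-only alternative is a flag —
and ensembles report the pointwise mean and sd across patches.

## The 2D projection method

Vesicle contours (bilayer midplane) are resampled to polygons at 5 nm arc
length.  Per face, pixels in a 5 × 20 nm rectangle centred on the face are
binned at 0.1 nm along the outward normal (201 bins) and averaged across
the face; empty interior bins are interpolated.  The trough-to-trough
distance D_TT is estimated (i) model-free: 5-point Gaussian smoothing,
central peak located as the local maximum nearest the midline, absolute
minima on each side, 3-point parabolic refinement; and (ii) by fitting
four Gaussians (two negative troughs, two positive centre/flank
components) plus a quadratic background and reading the minima off the
fitted curve.  The raw segment value is the mean of the two estimates
(either alone if one fails, flagged), then smoothed along the closed
contour with a circular 4-point Gaussian kernel.  The n-point kernels use
σ = 1 tap; even tap counts are realised as zero-phase half-integer-offset
kernels applied through linear interpolation, since a literal 4-tap
integer kernel cannot be symmetric.  D_TT is invariant to global intensity
scale and offset.

Note the central peak of a projected vesicle profile sits slightly inside
the geometric mid-radius and the troughs slightly inside ±t/2 — a
tangent-ray effect of projecting a spherical shell.  The net bias on D_TT
is ≈ 1 % at R = 50 nm and shrinks with radius; it is a property of the 2D
observable itself, and is the main contribution to the residual 2D-vs-3D
median difference.

## The phantom generator

The synthetic bilayer is two positive Gaussian ridges (the head groups) on
a constant background: at signed distance d from the mid-surface the
continuous model is A·[G(d−t/2;σ) + G(d+t/2;σ)] + background.  Defaults:
t = 3.6 nm, σ_hg = 0.5 nm, amplitude 1, voxel 0.8 nm, mesh edge ≤ 2 nm.
There is no explicit tail trough and no CTF: the minimal generative model
isolates the estimator, and robustness is probed with the noise and
missing-wedge knobs.  The default noise level used in tests
(0.5 × amplitude) is a stand-in — tomographic SNR is not well
characterised — and results under it bound estimator behaviour, not
real-data behaviour.

Two rendering choices matter and are deliberate:

* **Anti-aliasing.**  Voxel values approximate the average of the model
  over the voxel, implemented by inflating the rendered ridge width to
  √(σ² + v²/12) (the cube's projected variance along any direction is
  v²/12, so this Gaussian equivalent is rotation-consistent).
  Point-sampling a 0.5 nm ridge on a 0.8 nm grid aliases: fitted peak
  separations shift by up to ±0.05 nm depending on grid phase, and no
  interpolator can undo it (a sinc resampler shows the same bias).  Real
  tomograms are band-limited by the imaging system, so the anti-aliased
  render is also the more faithful forward model.
* **Plane orientation.**  The default plane normal is +x, a membrane
  standing edge-on — the orientation a tilt series measures.  An infinite
  flat-lying plane (normal ∥ beam, `plane_normal="z"`) has its entire
  spectrum on the beam axis and is annihilated by the missing wedge: the
  extreme case of the invisible top/bottom-membrane artefact, reproducible
  but not a meaningful recovery target.

The missing wedge zeroes Fourier coefficients with |k_beam| > |k_⊥|·tan α
about the tilt axis (α the tilt half-range, beam along z), keeping DC and
enforcing a real output.  Noise is i.i.d. Gaussian, seeded.  Membrane
particles are spherical Gaussian blobs (default σ 2.5 nm, offset 12 nm
along the normal, pairwise separation > 2σ).  2D vesicle projections are
computed analytically per pixel by radial quadrature of the spherical
shell and negated so head groups project to dark troughs flanking a
relatively bright mid-contour, as in underfocus micrographs.

What the phantoms do *not* emulate: CTF oscillations and defocus banding,
dose-dependent and spatially correlated noise, segmentation/meshing error
(meshes are analytic), crowded multi-membrane scenes, and realistic
particle shapes.  Passing phantom tests therefore demonstrates estimator
correctness under a known forward model, not performance on cellular data.

## Problem sizes and numerics

The validation suite uses 60×60 nm planes (~1800 triangles), R = 20–60 nm
spheres, and for cross-modality runs 20 vesicles with a 4 nm mesh-edge
target (~5 k triangles each, ~100 k dual-Gaussian fits in total) — sizes
chosen so a full from-scratch run of every check completes in minutes on
one CPU while leaving per-triangle statistics well populated.  Fits use
`scipy.optimize.least_squares` (trust-region reflective) with xtol = ftol
= 1e-9 and ≤ 200 function evaluations; the convergence-or-masked rule
above means an occasional optimizer failure costs a triangle, never a
biased value.  Degenerate (zero-area) triangles keep their index
everywhere (masked, not deleted) so attribute columns stay aligned.
Geodesic queries run on `scipy.sparse.csgraph.dijkstra` with a radius
limit, chunked to bound memory.

## Known limitations

* Thickness is head-peak-to-head-peak; it coincides with the 2D
  trough-to-trough observable only for symmetric bilayer profiles (true
  for the phantom by construction, approximately true for real data).
* The curvedness estimator needs neighbourhood radii ≳ 2× the mesh edge;
  very coarse meshes degrade it before they degrade thickness.
* The wedge model is a binary mask — no CTF, no dose weighting, no
  reconstruction algorithm effects.
* Contours for the 2D method are trusted inputs; no automatic vesicle
  quality screening beyond an off-image check.
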