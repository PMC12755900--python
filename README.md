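# memthick

Local lipid-bilayer thickness measurement for cryo-electron tomography,
with the surrounding membrane morphometrics: curvature, orientation and
distance maps, subcompartment classification, particle-patch analysis, and
a companion 2D projection-image method for cross-modality validation.

## The measurement

A biological membrane imaged in a cryo-ET volume shows two parallel density
ridges — the phospholipid head groups (PHG) of the two leaflets.  Given a
triangulated mid-surface mesh of the membrane, `memthick` measures the
head-to-head distance *locally, per triangle*:

1. **Line scan.**  For each triangle, the tomogram density is interpolated
   (trilinearly) along the triangle normal from −10 nm to +10 nm in
   0.25 nm steps.
2. **Neighbourhood averaging.**  Each scan is averaged with the scans of
   all triangles within a 12 nm *geodesic* radius on the mesh, weighted by
   w(d) = 1 / (1 + d [nm]), to tame the low SNR of tomography data.
3. **Dual-Gaussian fit.**  The averaged profile is fit with
   a₁G(u−μ₁;σ₁) + a₂G(u−μ₂;σ₂) + c; the thickness is t = μ₂ − μ₁.
   Because Gaussian means are fit, resolution is sub-grid (≪ 0.25 nm).
4. **Edge exclusion.**  Triangles within 8 nm (geodesic) of an open mesh
   boundary are masked; fits there are unreliable.

Distribution summaries are *area-weighted* (each triangle counts by its
area, so triangulation density cannot bias results) and significance tests
operate on per-connected-component medians with the Mann–Whitney U test.

Additional machinery follows the same conventions: quadric-jet curvedness
√((κ₁²+κ₂²)/2), verticality arccos|n·ẑ|, inter-surface distances with the
modal-distance IMM subcompartment rule (IBM < 4 nm excess, crista junction
4–14 nm, crista body > 14 nm), particle-anchored 12 nm membrane patches
with count-matched randomized controls and extended −10…+30 nm profiles,
and a 2D method that measures trough-to-trough distances along vesicle
contours in untilted projection images.

A `phantom` module generates synthetic bilayer volumes (plane / sphere /
tube), meshes, particles and 2D vesicle projections with known ground
truth, including missing-wedge and noise corruption, so the entire chain
is testable without external data.

## Worked example

```python
import numpy as np
from memthick.phantom import PhantomSpec, make_bilayer_phantom, add_noise
from memthick.thickness import measure_local_thickness
from memthick.stats import area_weighted_median

spec = PhantomSpec(geometry="plane", extent=60.0, t_true=3.6,
                   sigma_hg=0.5, voxel_size=0.8)
vol, mesh, truth = make_bilayer_phantom(spec)
vol = add_noise(vol, 0.3, seed=1)

tmap = measure_local_thickness(vol, mesh)    # scan -> average -> fit
t = tmap.thickness[np.isfinite(tmap.thickness)]
print(f"{t.size} interior triangles, "
      f"median {area_weighted_median(tmap.thickness, mesh.areas):.3f} nm")
```

prints

```
925 interior triangles, median 3.637 nm
```

925 of the 1800 mesh triangles survive edge exclusion (the 60×60 nm patch
loses an 8 nm rim); the area-weighted median recovers the simulated
head-group separation of 3.6 nm to within a few hundredths of a
nanometre.  The same pipeline is exposed on the command line:

```bash
memthick phantom --config phantom.yaml --out-prefix scene
memthick scan --volume scene.mrc --mesh scene.ply --out thickness.csv
memthick thickness --volume scene.mrc --mesh scene.ply   # global fit
```

Every CSV artifact embeds the full parameter snapshot and package version
in commented header lines.

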