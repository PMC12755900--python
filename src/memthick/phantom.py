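"""Synthetic bilayer phantoms with known ground truth.

The bilayer is modelled as two parallel Gaussian density ridges — the two
phospholipid head-group layers — on a flat background: at signed distance
``d`` from the mid-surface the noise-free density is

    A * [G(d - t/2; sigma) + G(d + t/2; sigma)] + background

with ``G`` a unit-height Gaussian, ``t`` the head-group separation
("thickness") and ``sigma`` the ridge width.  There is no explicit
tail-region trough and no CTF: a minimal generative model isolates the
estimator, and robustness to imaging artefacts is probed through the noise
and missing-wedge knobs instead.

Rendering is anti-aliased: voxel values approximate the average of the
continuous model over the voxel (the ridge is rendered with an effective
width sqrt(sigma_hg^2 + voxel^2 / 12), the Gaussian equivalent of the voxel
box).  Point-sampling a ridge narrower than the voxel aliases and shifts
the apparent peak positions by up to ~0.05 nm depending on grid phase —
a bias no interpolator downstream can undo; real tomograms are band-limited
by the imaging system, so the anti-aliased render is also the more faithful
forward model.

Geometries: an axis-aligned plane, a sphere, and an open tube (axis y).
The default plane normal is +x — a membrane standing edge-on, the
orientation a tilt series measures well.  A flat-lying plane
(plane_normal="z") has its entire spectrum on the beam axis and is wiped
out by the missing wedge, the extreme of the well-known invisible
top/bottom-membrane artefact.  The returned mesh is the analytic
mid-surface, so estimator tests are decoupled from segmentation/meshing
error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .io import (DensityVolume, ParticleSet, SurfaceMesh,
                 compute_triangle_geometry, HEADS_BRIGHT, HEADS_DARK)

__all__ = [
    "PhantomSpec", "PhantomTruth", "make_bilayer_phantom",
    "apply_missing_wedge", "add_noise", "place_particles",
    "make_vesicle_projection",
]


@dataclass
class PhantomSpec:
    """Parameters of a synthetic bilayer scene.

    geometry : 'plane' | 'sphere' | 'tube'
    extent : in-plane side length of the plane patch / tube length (nm)
    radius : sphere or tube radius (nm); ignored for planes
    t_true : head-group separation (nm)
    sigma_hg : head-group ridge width (nm)
    amplitude, background : ridge height and constant offset (a.u.)
    noise_sigma : additive Gaussian noise sd (a.u.); 0 disables
    wedge_half_angle : tilt half-range in degrees; 0 disables the wedge
    voxel_size : nm per voxel
    grid_shape : (nx, ny, nz); None derives it from geometry + margin
    mesh_edge : target mesh edge length (nm)
    contrast : 'heads_bright' or 'heads_dark'
    """

    geometry: str = "plane"
    extent: float = 60.0
    radius: float = 50.0
    t_true: float = 3.6
    sigma_hg: float = 0.5
    amplitude: float = 1.0
    background: float = 0.0
    noise_sigma: float = 0.0
    wedge_half_angle: float = 0.0
    voxel_size: float = 0.8
    grid_shape: tuple[int, int, int] | None = None
    plane_normal: str = "x"
    mesh_edge: float = 2.0
    margin: float = 12.0
    seed: int = 0
    contrast: str = HEADS_BRIGHT

    def __post_init__(self) -> None:
        if self.t_true <= 0 or self.sigma_hg <= 0:
            raise ValueError("t_true and sigma_hg must be positive")
        if not 0 <= self.wedge_half_angle < 90:
            raise ValueError("wedge_half_angle must lie in [0, 90)")
        if self.geometry not in ("plane", "sphere", "tube"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.plane_normal not in ("x", "y", "z"):
            raise ValueError("plane_normal must be 'x', 'y' or 'z'")


@dataclass
class PhantomTruth:
    """Ground truth accompanying a phantom: what the estimators should find."""

    t_true: float
    curvedness: float                 # nm^-1, analytic, uniform per geometry
    normals: np.ndarray               # (nt, 3) analytic mid-surface normals
    spec: dict = field(default_factory=dict)


def _grid_coords(shape, voxel):
    ax = [np.arange(n) * voxel for n in shape]
    return np.meshgrid(*ax, indexing="ij")


def _plane_mesh(extent, edge, center, axis):
    # plane spans (u, v) = the two axes cyclically following ``axis`` so
    # that e_u x e_v = +e_axis (normals along +axis with this winding)
    ua, va = (axis + 1) % 3, (axis + 2) % 3
    n = max(2, int(np.ceil(extent / edge)) + 1)
    us = np.linspace(center[ua] - extent / 2, center[ua] + extent / 2, n)
    vs = np.linspace(center[va] - extent / 2, center[va] + extent / 2, n)
    gu, gv = np.meshgrid(us, vs, indexing="ij")
    verts = np.empty((gu.size, 3))
    verts[:, axis] = center[axis]
    verts[:, ua] = gu.ravel()
    verts[:, va] = gv.ravel()
    tris = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            b = (i + 1) * n + j
            tris.append([a, b, a + 1])
            tris.append([a + 1, b, b + 1])
    return SurfaceMesh(verts, np.array(tris))


def _sphere_mesh(radius, edge, center):
    import trimesh
    # icosphere edge length ~ 1.05 * R / 2**subdiv
    sub = int(np.clip(np.ceil(np.log2(1.05 * radius / edge)), 1, 7))
    ico = trimesh.creation.icosphere(subdivisions=sub, radius=radius)
    return SurfaceMesh(np.asarray(ico.vertices) + center,
                       np.asarray(ico.faces))


def _tube_mesh(radius, length, edge, center):
    ntheta = max(8, int(np.ceil(2 * np.pi * radius / edge)))
    ny = max(2, int(np.ceil(length / edge)) + 1)
    theta = np.linspace(0, 2 * np.pi, ntheta, endpoint=False)
    ys = np.linspace(-length / 2, length / 2, ny)
    verts = []
    for y in ys:
        for th in theta:
            verts.append([center[0] + radius * np.cos(th), center[1] + y,
                          center[2] + radius * np.sin(th)])
    verts = np.array(verts)
    tris = []
    for i in range(ny - 1):
        for j in range(ntheta):
            a = i * ntheta + j
            b = i * ntheta + (j + 1) % ntheta
            c = (i + 1) * ntheta + j
            d = (i + 1) * ntheta + (j + 1) % ntheta
            tris.append([a, d, b])
            tris.append([a, c, d])
    return SurfaceMesh(verts, np.array(tris))


def make_bilayer_phantom(spec: PhantomSpec):
    """Render the noise-free bilayer volume and its analytic mid-surface mesh.

    Returns (DensityVolume, SurfaceMesh, PhantomTruth).  Noise and the
    missing wedge are applied separately (``add_noise``,
    ``apply_missing_wedge``) so tests can compare clean and corrupted copies
    of the same scene.
    """
    import warnings
    if spec.t_true < 2 * spec.voxel_size:
        warnings.warn("bilayer under-resolved: t_true < 2 voxels",
                      stacklevel=2)
    axis = {"x": 0, "y": 1, "z": 2}[spec.plane_normal]
    if spec.grid_shape is not None:
        shape = tuple(spec.grid_shape)
    else:
        if spec.geometry == "plane":
            side = int(np.ceil((spec.extent + 2 * spec.margin)
                               / spec.voxel_size))
            thin = int(np.ceil((spec.t_true + 2 * spec.margin + 20.0)
                               / spec.voxel_size))
            shape = tuple(thin if k == axis else side for k in range(3))
        elif spec.geometry == "sphere":
            side = 2 * spec.radius + 2 * spec.margin + 20.0
            shape = (int(np.ceil(side / spec.voxel_size)),) * 3
        else:  # tube
            side = 2 * spec.radius + 2 * spec.margin + 20.0
            ylen = spec.extent + 2 * spec.margin
            n = int(np.ceil(side / spec.voxel_size))
            shape = (n, int(np.ceil(ylen / spec.voxel_size)), n)
    center = (np.array(shape) - 1) * spec.voxel_size / 2.0
    x, y, z = _grid_coords(shape, spec.voxel_size)

    if spec.geometry == "plane":
        d = (x, y, z)[axis] - center[axis]
        mesh = _plane_mesh(spec.extent, spec.mesh_edge, center, axis)
        curvedness = 0.0
    elif spec.geometry == "sphere":
        d = np.sqrt((x - center[0]) ** 2 + (y - center[1]) ** 2
                    + (z - center[2]) ** 2) - spec.radius
        mesh = _sphere_mesh(spec.radius, spec.mesh_edge, center)
        curvedness = 1.0 / spec.radius
    else:
        d = np.sqrt((x - center[0]) ** 2 + (z - center[2]) ** 2) - spec.radius
        mesh = _tube_mesh(spec.radius, spec.extent, spec.mesh_edge, center)
        curvedness = 1.0 / (spec.radius * np.sqrt(2.0))

    # anti-aliased render: ridge width inflated by the voxel box variance
    sigma_r = np.sqrt(spec.sigma_hg ** 2 + spec.voxel_size ** 2 / 12.0)
    s2 = 2.0 * sigma_r ** 2
    signal = spec.amplitude * (np.exp(-(d - spec.t_true / 2) ** 2 / s2)
                               + np.exp(-(d + spec.t_true / 2) ** 2 / s2))
    if spec.contrast == HEADS_DARK:
        grid = spec.background - signal
    else:
        grid = spec.background + signal
    vol = DensityVolume(grid, spec.voxel_size, contrast=spec.contrast)
    compute_triangle_geometry(mesh)
    truth = PhantomTruth(spec.t_true, curvedness, mesh.normals.copy(),
                         spec=asdict(spec))
    return vol, mesh, truth


def apply_missing_wedge(vol: DensityVolume, half_angle: float,
                        tilt_axis: str = "y") -> DensityVolume:
    """Zero the Fourier wedge left unsampled by a limited tilt range.

    The beam runs along z and the specimen tilts about ``tilt_axis`` through
    +-half_angle degrees.  Sampled planes cover directions within half_angle
    of the in-plane axis, so coefficients with |k_z| > |k_perp| *
    tan(half_angle) (k_perp the in-plane axis perpendicular to the tilt
    axis) are lost.  The DC term and the k_z = 0 plane survive.  Output is
    real (inverse FFT of the Hermitian-symmetric masked spectrum).
    """
    if not 0 < half_angle < 90:
        raise ValueError("half_angle must lie strictly between 0 and 90")
    if tilt_axis not in ("x", "y"):
        raise ValueError("tilt_axis must be 'x' or 'y' (beam is z)")
    nx, ny, nz = vol.grid.shape
    kx = np.fft.fftfreq(nx)
    ky = np.fft.fftfreq(ny)
    kz = np.fft.fftfreq(nz)
    KX, KY, KZ = np.meshgrid(kx, ky, kz, indexing="ij")
    kperp = np.abs(KY) if tilt_axis == "x" else np.abs(KX)
    tan = np.tan(np.deg2rad(half_angle))
    missing = np.abs(KZ) > kperp * tan
    missing &= ~((kperp == 0) & (KZ == 0))  # keep DC
    spec = np.fft.fftn(vol.grid)
    spec[missing] = 0.0
    out = np.fft.ifftn(spec).real
    return DensityVolume(out, vol.voxel_size, vol.origin.copy(), vol.contrast)


def add_noise(vol: DensityVolume, sigma: float, seed: int) -> DensityVolume:
    """Add i.i.d. Gaussian noise; deterministic under ``seed``."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return DensityVolume(vol.grid.copy(), vol.voxel_size,
                             vol.origin.copy(), vol.contrast)
    rng = np.random.default_rng(seed)
    noisy = vol.grid + rng.normal(0.0, sigma, vol.grid.shape)
    return DensityVolume(noisy, vol.voxel_size, vol.origin.copy(),
                         vol.contrast)


def place_particles(vol: DensityVolume, mesh: SurfaceMesh, n: int,
                    offset_along_normal: float = 12.0,
                    blob_sigma: float = 2.5, blob_amplitude: float = 1.5,
                    seed: int = 0, max_tries_factor: int = 200):
    """Add spherical Gaussian blobs above randomly chosen triangles.

    Blob centres sit ``offset_along_normal`` nm along the triangle normal
    from its centroid, with pairwise centre separation > 2 * blob_sigma.
    Returns the augmented volume and the ParticleSet of blob centres.
    """
    if n > mesh.n_triangles:
        raise ValueError("cannot place more particles than triangles")
    grid = vol.grid.copy()
    if n == 0:
        return (DensityVolume(grid, vol.voxel_size, vol.origin.copy(),
                              vol.contrast),
                ParticleSet(np.array([], dtype=int), np.zeros((0, 3))))
    rng = np.random.default_rng(seed)
    valid = np.flatnonzero(mesh.valid)
    centers: list[np.ndarray] = []
    tries = 0
    min_sep = 2.0 * blob_sigma
    while len(centers) < n:
        tries += 1
        if tries > max_tries_factor * n:
            raise RuntimeError(
                f"could not place {n} particles with separation {min_sep} nm; "
                f"achieved {len(centers)}")
        tri = rng.choice(valid)
        c = mesh.centroids[tri] + offset_along_normal * mesh.normals[tri]
        if centers and np.min(np.linalg.norm(np.array(centers) - c,
                                             axis=1)) <= min_sep:
            continue
        centers.append(c)
    centers = np.array(centers)
    sign = -1.0 if vol.contrast == HEADS_DARK else 1.0
    half = int(np.ceil(4 * blob_sigma / vol.voxel_size))
    shape = np.array(grid.shape)
    for c in centers:
        idx = np.round((c - vol.origin) / vol.voxel_size).astype(int)
        lo = np.maximum(idx - half, 0)
        hi = np.minimum(idx + half + 1, shape)
        sub = [np.arange(lo[k], hi[k]) * vol.voxel_size + vol.origin[k]
               for k in range(3)]
        gx, gy, gz = np.meshgrid(*sub, indexing="ij")
        r2 = (gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2
        grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += (
            sign * blob_amplitude * np.exp(-r2 / (2 * blob_sigma ** 2)))
    out = DensityVolume(grid, vol.voxel_size, vol.origin.copy(), vol.contrast)
    return out, ParticleSet(np.arange(n), centers)


def _shell_projection_profile(radii, radius, t_true, sigma_hg, zmax=None,
                              dz=0.05):
    """Line integral along z of the spherical-shell bilayer density, per
    in-plane radius (radial quadrature)."""
    if zmax is None:
        zmax = radius + t_true / 2 + 5 * sigma_hg
    z = np.arange(0.0, zmax, dz)
    r3d = np.sqrt(radii[:, None] ** 2 + z[None, :] ** 2)
    d = r3d - radius
    s2 = 2.0 * sigma_hg ** 2
    rho = (np.exp(-(d - t_true / 2) ** 2 / s2)
           + np.exp(-(d + t_true / 2) ** 2 / s2))
    return 2.0 * np.trapezoid(rho, dx=dz, axis=1)


def make_vesicle_projection(radius: float, t_true: float = 3.5,
                            sigma_hg: float = 0.5, pixel_size: float = 0.27,
                            noise: float = 0.0, seed: int = 0,
                            margin: float = 15.0, contour_spacing: float = 1.0):
    """Render an untilted 2D projection of a spherical vesicle bilayer.

    The image is the analytic line integral (radial quadrature) of the 3D
    shell density, negated so the head groups project to dark troughs
    flanking the relatively bright mid-contour — the contrast of an
    underfocus cryo-EM micrograph.  Returns (image, pixel_size, contour)
    with the contour a closed circle of points at the mid-surface radius.
    ``noise`` is the sd of additive Gaussian pixel noise in image units.
    """
    from .projection2d import Contour
    if radius <= t_true:
        raise ValueError("radius must exceed t_true")
    half = radius + margin
    n = int(np.ceil(2 * half / pixel_size)) + 1
    c = (n - 1) * pixel_size / 2.0
    ax = np.arange(n) * pixel_size
    gx, gy = np.meshgrid(ax, ax, indexing="ij")
    rpix = np.sqrt((gx - c) ** 2 + (gy - c) ** 2)
    rgrid = np.arange(0.0, rpix.max() + 2 * pixel_size, pixel_size / 4.0)
    prof = _shell_projection_profile(rgrid, radius, t_true, sigma_hg)
    image = -np.interp(rpix, rgrid, prof)
    if noise > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, noise, image.shape)
    npt = max(8, int(np.round(2 * np.pi * radius / contour_spacing)))
    th = np.linspace(0, 2 * np.pi, npt, endpoint=False)
    pts = np.column_stack([c + radius * np.cos(th), c + radius * np.sin(th)])
    return image, pixel_size, Contour(points=pts, closed=True,
                                      image_id="phantom_vesicle")
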