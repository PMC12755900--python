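"""Per-triangle surface geometry: curvedness, verticality, inter-surface
distances and the distance-based IMM subcompartment classifier.

Curvedness is estimated by fitting a local height function (osculating jet)
over the geodesic neighbourhood of each triangle, expressed in the
triangle's tangent frame; principal curvatures come from the shape operator
of the fitted patch and curvedness = sqrt((k1^2 + k2^2) / 2).  The
closed-form plane/sphere/cylinder values define correctness of the
estimator.

IMM subcompartments follow the excess-distance rule: with ``mode`` the
modal OMM distance of the surface (the OMM-to-IBM spacing), triangles whose
distance exceeds the mode by < 4 nm are inner boundary membrane, by
4-14 nm crista junctions, and by > 14 nm crista bodies.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .graph import MeshGraph
from .io import SurfaceMesh

__all__ = ["estimate_curvedness", "verticality", "surface_distance",
           "mode_distance", "classify_imm"]

IBM = "IBM"
JUNCTION = "junction"
CRISTA_BODY = "crista_body"


def _tangent_frame(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal (e1, e2) spanning the plane perpendicular to ``normal``."""
    a = np.array([1.0, 0.0, 0.0])
    if abs(normal[0]) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    return e1, e2


def _principal_curvatures(hx, hy, hxx, hxy, hyy):
    """Principal curvatures of a height graph from its first and second
    derivatives (shape operator eigenvalues)."""
    W = np.sqrt(1.0 + hx * hx + hy * hy)
    E, F, G = 1 + hx * hx, hx * hy, 1 + hy * hy
    L, M, N = hxx / W, hxy / W, hyy / W
    det_I = E * G - F * F
    # S = I^-1 II
    s11 = (G * L - F * M) / det_I
    s12 = (G * M - F * N) / det_I
    s21 = (E * M - F * L) / det_I
    s22 = (E * N - F * M) / det_I
    tr, det = s11 + s22, s11 * s22 - s12 * s21
    disc = np.sqrt(max(tr * tr / 4 - det, 0.0))
    return tr / 2 + disc, tr / 2 - disc


def estimate_curvedness(mesh: SurfaceMesh, graph: MeshGraph,
                        radius: float = 8.0, min_points: int = 6) -> np.ndarray:
    """Curvedness sqrt((k1^2 + k2^2)/2) in nm^-1 per triangle.

    Neighbour centroids within the geodesic ``radius`` are expressed in the
    triangle's tangent frame and fitted with a polynomial height function
    (degree 4 when >= 24 points are available, else degree 2); the Hessian
    at the origin gives the curvatures.  Neighbourhoods with fewer than
    ``min_points`` centroids yield NaN.
    """
    nt = mesh.n_triangles
    out = np.full(nt, np.nan)
    cent, norm = mesh.centroids, mesh.normals
    for idx, dist in graph.neighbors_within(radius):
        for row, i in enumerate(idx):
            if mesh.valid is not None and not mesh.valid[i]:
                continue
            nb = np.flatnonzero(np.isfinite(dist[row]))
            if nb.size < min_points:
                continue
            e1, e2 = _tangent_frame(norm[i])
            rel = cent[nb] - cent[i]
            x = rel @ e1
            y = rel @ e2
            h = rel @ norm[i]
            cols = [np.ones_like(x), x, y, x * x, x * y, y * y]
            if nb.size >= 24:
                cols += [x**3, x * x * y, x * y * y, y**3,
                         x**4, x**3 * y, x * x * y * y, x * y**3, y**4]
            A = np.column_stack(cols)
            coef, *_ = np.linalg.lstsq(A, h, rcond=None)
            hx, hy = coef[1], coef[2]
            hxx, hxy, hyy = 2 * coef[3], coef[4], 2 * coef[5]
            k1, k2 = _principal_curvatures(hx, hy, hxx, hxy, hyy)
            out[i] = np.sqrt((k1 * k1 + k2 * k2) / 2.0)
    return out


def verticality(mesh: SurfaceMesh) -> np.ndarray:
    """Angle in degrees between the membrane plane and the imaging (xy)
    plane: 0 for horizontal membranes (normal along the beam axis z), 90
    for vertical ones."""
    nz = np.abs(np.clip(mesh.normals[:, 2], -1.0, 1.0))
    return np.degrees(np.arccos(nz))


def _point_triangle_distance(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Distance from each point to one triangle (a, b, c) [Ericson]."""
    a, b, c = tri
    ab, ac = b - a, c - a
    ap = points - a
    d1 = ap @ ab
    d2 = ap @ ac
    bp = points - b
    d3 = bp @ ab
    d4 = bp @ ac
    cp = points - c
    d5 = cp @ ab
    d6 = cp @ ac
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    closest = np.empty_like(points)
    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    closest[m] = a
    m2 = (d3 >= 0) & (d4 <= d3)
    closest[m2] = b
    m3 = (d6 >= 0) & (d5 <= d6)
    closest[m3] = c
    done = m | m2 | m3
    # edge AB
    e = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    if np.any(e):
        v = (d1[e] / (d1[e] - d3[e]))[:, None]
        closest[e] = a + v * ab
    done |= e
    # edge AC
    e = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    if np.any(e):
        w = (d2[e] / (d2[e] - d6[e]))[:, None]
        closest[e] = a + w * ac
    done |= e
    # edge BC
    e = (~done) & (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    if np.any(e):
        w = ((d4[e] - d3[e]) / ((d4[e] - d3[e]) + (d5[e] - d6[e])))[:, None]
        closest[e] = b + w * (c - b)
    done |= e
    # face interior
    f = ~done
    if np.any(f):
        denom = va[f] + vb[f] + vc[f]
        v = (vb[f] / denom)[:, None]
        w = (vc[f] / denom)[:, None]
        closest[f] = a + v * ab + w * ac
    return np.linalg.norm(points - closest, axis=1)


def surface_distance(meshA: SurfaceMesh, meshB: SurfaceMesh,
                     k_candidates: int = 32) -> np.ndarray:
    """Minimum Euclidean distance (nm) from each triangle centroid of A to
    the surface of B (exact point-to-triangle, candidate-pruned).

    A k-d tree on B's centroids proposes candidates; exact distances are
    then evaluated over every B triangle whose centroid lies within the
    provisional best distance plus B's largest circumradius, which
    guarantees the true nearest triangle is among them.
    """
    if meshB.n_triangles == 0:
        raise ValueError("mesh B is empty")
    for m in (meshA, meshB):
        if m.centroids is None:
            from .io import compute_triangle_geometry
            compute_triangle_geometry(m)
    pts = meshA.centroids
    triB = meshB.vertices[meshB.triangles]          # (ntB, 3, 3)
    centB = meshB.centroids
    circum = np.linalg.norm(triB - centB[:, None, :], axis=2).max(axis=1)
    rmax = circum.max()
    tree = cKDTree(centB)
    k = min(k_candidates, meshB.n_triangles)
    d0, idx0 = tree.query(pts, k=k)
    d0 = np.atleast_2d(d0.T).T
    idx0 = np.atleast_2d(idx0.T).T
    out = np.empty(len(pts))
    for i, p in enumerate(pts):
        best = np.inf
        for j in idx0[i]:
            best = min(best, _point_triangle_distance(p[None], triB[j])[0])
        # widen until provably exact
        cand = tree.query_ball_point(p, best + rmax)
        for j in cand:
            if j in idx0[i]:
                continue
            best = min(best, _point_triangle_distance(p[None], triB[j])[0])
        out[i] = best
    return out


def mode_distance(distances: np.ndarray, areas: np.ndarray,
                  bin_width: float = 1.0) -> float:
    """Centre of the maximal bin of the area-weighted distance histogram;
    ties resolve to the smaller-distance bin."""
    d = np.asarray(distances, dtype=float)
    a = np.asarray(areas, dtype=float)
    ok = np.isfinite(d)
    d, a = d[ok], a[ok]
    if d.size == 0:
        raise ValueError("no valid distances")
    # bins centred on integer multiples of bin_width: [k-1/2, k+1/2)*w
    nbins = int(np.floor(d.max() / bin_width + 0.5)) + 1
    edges = bin_width * (np.arange(nbins + 1) - 0.5)
    hist, _ = np.histogram(d, bins=edges, weights=a)
    imax = int(np.argmax(hist))  # argmax returns the first (lowest) max bin
    return imax * bin_width


def classify_imm(distances: np.ndarray, mode: float,
                 t_ibm: float = 4.0, t_junction: float = 14.0) -> np.ndarray:
    """Label IMM triangles by excess distance over the modal OMM spacing:
    excess < t_ibm -> IBM; t_ibm <= excess <= t_junction -> crista
    junction; excess > t_junction -> crista body.  NaN distances get ''."""
    d = np.asarray(distances, dtype=float)
    excess = d - mode
    labels = np.full(d.shape, "", dtype=object)
    ok = np.isfinite(d)
    labels[ok & (excess < t_ibm)] = IBM
    labels[ok & (excess >= t_ibm) & (excess <= t_junction)] = JUNCTION
    labels[ok & (excess > t_junction)] = CRISTA_BODY
    return labels.astype(str)
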