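"""Area-weighted distribution statistics and hypothesis-testing conventions.

Every distribution summary weights triangles by their area, so triangulation
density cannot bias results: a histogram bin height is the relative membrane
area in that bin, and the median is the area-weighted median.  The sampling
unit for significance tests is the per-component (per-surface) median, not
the per-triangle value — neighbouring triangles are strongly correlated and
would wildly overstate the effective sample size.  Group comparisons use
the Mann-Whitney U test (distributions of morphometric summaries are
routinely non-normal).

Histogram bin convention: values on an interior right edge fall in the
lower bin; the last bin is closed on both sides.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = ["area_weighted_histogram", "area_weighted_median",
           "per_component_medians", "mann_whitney_u", "quantile_partition",
           "hist2d"]


def _bin_indices(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Right-closed binning: (e[i-1], e[i]] except the first bin, which is
    [e[0], e[1]].  Returns -1 for out-of-range values."""
    idx = np.searchsorted(edges, values, side="left") - 1
    idx[values == edges[0]] = 0
    idx[(values < edges[0]) | (values > edges[-1])] = -1
    return idx


def area_weighted_histogram(values, weights, edges):
    """Relative membrane area per bin.

    Returns (bin_centers, heights); heights sum to 1 over the in-range
    weight.  Raises when no finite value falls in range.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    edges = np.asarray(edges, dtype=float)
    ok = np.isfinite(v) & np.isfinite(w)
    v, w = v[ok], w[ok]
    idx = _bin_indices(v, edges)
    inr = idx >= 0
    if not np.any(inr):
        raise ValueError("no values fall inside the histogram range")
    heights = np.bincount(idx[inr], weights=w[inr],
                          minlength=len(edges) - 1)
    heights = heights / heights.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers, heights


def area_weighted_median(values, weights) -> float:
    """Smallest value whose cumulative weight reaches half the total."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    ok = np.isfinite(v) & np.isfinite(w) & (w > 0)
    v, w = v[ok], w[ok]
    if v.size == 0:
        raise ValueError("no valid values")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, cum[-1] / 2.0)])


def per_component_medians(component_id, values, weights,
                          min_triangles: int = 10):
    """Area-weighted median per connected component.

    Components with fewer than ``min_triangles`` valid triangles are
    dropped.  Returns (medians dict {component: median}, dropped ids).
    """
    comp = np.asarray(component_id)
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    medians, dropped = {}, []
    for c in np.unique(comp):
        sel = comp == c
        ok = sel & np.isfinite(v) & (w > 0)
        if ok.sum() < min_triangles:
            dropped.append(int(c))
            continue
        medians[int(c)] = area_weighted_median(v[ok], w[ok])
    return medians, dropped


def mann_whitney_u(group_a, group_b):
    """Two-sided Mann-Whitney U test.

    Exact enumeration when min(nA, nB) <= 8 and there are no ties across
    groups; otherwise the normal approximation with tie and continuity
    corrections.  Returns (U, p) with U = min(U_A, U_B).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need at least one observation")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (min(a.size, b.size) <= 8 and no_ties) \
        else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    u_a = float(res.statistic)
    u_min = min(u_a, a.size * b.size - u_a)
    return u_min, float(res.pvalue)


def quantile_partition(values, edges=(0.0, 0.5, 0.9, 0.95, 0.99, 1.0)):
    """Assign each value to a quantile band.

    Thresholds are unweighted per-triangle quantiles (linear
    interpolation); bands are [q_i, q_{i+1}) with the last band closed.
    Returns (labels, thresholds); labels like '0.5-0.9'.  NaNs get ''.
    """
    v = np.asarray(values, dtype=float)
    edges = np.asarray(edges, dtype=float)
    ok = np.isfinite(v)
    if not np.any(ok):
        raise ValueError("no valid values")
    thr = np.quantile(v[ok], edges)
    names = [f"{edges[i]:g}-{edges[i+1]:g}" for i in range(len(edges) - 1)]
    nb = len(names)
    vi = v[ok]
    idx = np.searchsorted(thr[1:], vi, side="right")
    idx = np.minimum(idx, nb - 1)  # last band closed
    # collapsed (zero-width) bands hand their edge values down to the first
    # band sharing that threshold, so constant data lands in band 0
    for _ in range(nb):
        down = (idx > 0) & (thr[idx] == thr[idx - 1]) & (vi <= thr[idx])
        idx = np.where(down, idx - 1, idx)
    labels = np.full(v.shape, "", dtype=object)
    labels[ok] = np.array(names, dtype=object)[idx]
    return labels.astype(str), thr


def hist2d(x, y, weights, x_edges, y_edges):
    """Area-normalized 2D histogram whose marginals reproduce the 1D
    area-weighted histograms (same right-closed bin convention)."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    x_edges = np.asarray(x_edges, dtype=float)
    y_edges = np.asarray(y_edges, dtype=float)
    ok = np.isfinite(xv) & np.isfinite(yv) & np.isfinite(w)
    xv, yv, w = xv[ok], yv[ok], w[ok]
    ix = _bin_indices(xv, x_edges)
    iy = _bin_indices(yv, y_edges)
    inr = (ix >= 0) & (iy >= 0)
    if not np.any(inr):
        raise ValueError("no points fall inside the histogram range")
    nx, ny = len(x_edges) - 1, len(y_edges) - 1
    flat = np.bincount(ix[inr] * ny + iy[inr], weights=w[inr],
                       minlength=nx * ny)
    H = flat.reshape(nx, ny)
    return H / H.sum()
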