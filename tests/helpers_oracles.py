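"""Independent brute-force oracles used to check the package's optimized paths.

These deliberately re-derive each quantity from first principles (exhaustive
scans, all-pairs distances, direct kernel evaluation) and share no code with
the implementation they verify.
"""

import numpy as np


def edge_by_column_scan(putamen: np.ndarray, lateral_sign: int) -> np.ndarray:
    """Per-column exhaustive scan for the extreme lateral putamen voxel."""
    nx, ny, nz = putamen.shape
    edge = np.zeros_like(putamen, dtype=bool)
    for j in range(ny):
        for k in range(nz):
            xs = [i for i in range(nx) if putamen[i, j, k]]
            if xs:
                edge[max(xs) if lateral_sign > 0 else min(xs), j, k] = True
    return edge


def csf_exclusion_all_pairs(roi: np.ndarray, csf: np.ndarray, margin: float) -> np.ndarray:
    """O(|ROI| * |CSF|) minimum-distance filtering in voxel units."""
    roi_pts = np.argwhere(roi)
    csf_pts = np.argwhere(csf)
    out = np.zeros_like(roi, dtype=bool)
    if csf_pts.size == 0:
        return roi.copy()
    for p in roi_pts:
        d2 = ((csf_pts - p) ** 2).sum(axis=1)
        if np.sqrt(d2.min()) > margin:
            out[tuple(p)] = True
    return out


def kmeans2_threshold_scan(values: np.ndarray):
    """Globally optimal 2-cluster split of scalars by naive threshold scan.

    Evaluates the within-cluster sum of squares of every split of the sorted
    order directly from the cluster definitions; first minimal split wins.
    Returns (lower-cluster boolean membership, lower centroid, upper centroid).
    """
    order = np.argsort(values, kind="stable")
    v = values[order]
    n = v.size
    best_sse, best_m = np.inf, None
    for m in range(1, n):
        lo, hi = v[:m], v[m:]
        sse = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if sse < best_sse:
            best_sse, best_m = sse, m
    lower = np.zeros(n, dtype=bool)
    lower[order[:best_m]] = True
    return lower, v[:best_m].mean(), v[best_m:].mean()


def gaussian_kernel_1d(sigma: float, truncate: float = 3.0) -> np.ndarray:
    """Normalized discrete Gaussian, direct evaluation of exp(-o^2/2s^2)."""
    r = int(truncate * sigma + 0.5)
    offsets = np.arange(-r, r + 1)
    w = np.exp(-(offsets**2) / (2.0 * sigma**2))
    return w / w.sum()
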