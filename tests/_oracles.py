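"""Independent brute-force oracles used only by the tests.

These deliberately avoid the code paths of the implementation: the
alphashape oracle enumerates every 4-point subset and applies the
empty-circumsphere definition of Delaunay tetrahedra directly; the Otsu
oracle evaluates the within-class variance of every candidate level with
plain loops.
"""

from itertools import combinations

import numpy as np


def alphashape_volume_bruteforce(points: np.ndarray, alpha: float) -> float:
    """Sum of volumes of Delaunay tetrahedra with circumradius <= alpha.

    A 4-point subset is a Delaunay tetrahedron iff its circumsphere
    contains no other point of the set (general position assumed).
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 4:
        return 0.0
    quads = np.array(list(combinations(range(n), 4)))
    t = pts[quads]
    a, b, c, d = t[:, 0], t[:, 1], t[:, 2], t[:, 3]
    m = np.stack([b - a, c - a, d - a], axis=1)
    det = np.linalg.det(m)
    nondeg = np.abs(det) > 1e-12
    rhs = 0.5 * np.stack(
        [
            (b * b).sum(1) - (a * a).sum(1),
            (c * c).sum(1) - (a * a).sum(1),
            (d * d).sum(1) - (a * a).sum(1),
        ],
        axis=1,
    )
    centers = np.full((len(t), 3), np.inf)
    centers[nondeg] = np.linalg.solve(m[nondeg], rhs[nondeg][..., None])[..., 0]
    radii = np.linalg.norm(centers - a, axis=1)
    keep = nondeg & (radii <= alpha)
    total = 0.0
    for qi in np.flatnonzero(keep):
        center, radius = centers[qi], radii[qi]
        others = np.setdiff1d(np.arange(n), quads[qi], assume_unique=True)
        dist = np.linalg.norm(pts[others] - center, axis=1)
        if np.all(dist >= radius - 1e-9):
            ta, tb, tc, td = pts[quads[qi]]
            total += abs(np.dot(np.cross(tb - ta, tc - ta), td - ta)) / 6.0
    return total


def otsu_threshold_bruteforce(values: np.ndarray, levels: int = 256) -> float:
    """Plain-loop exhaustive Otsu on min-max rescaled, quantized data."""
    vals = np.asarray(values, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    lo, hi = vals.min(), vals.max()
    assert hi > lo, "degenerate input"
    quant = np.minimum(((vals - lo) / (hi - lo) * levels).astype(int), levels - 1)
    grey = (quant + 0.5) / levels
    best_k, best_var = None, np.inf
    for k in range(levels - 1):
        left = grey[quant <= k]
        right = grey[quant > k]
        if len(left) == 0 or len(right) == 0:
            continue
        var = (len(left) * left.var() + len(right) * right.var()) / len(grey)
        if var < best_var:
            best_var, best_k = var, k
    return lo + (best_k + 1) / levels * (hi - lo)
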