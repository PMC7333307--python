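"""3D point-cloud pipeline: ground removal, alphashape volumes, gap counts.

Ground and canopy are separated by a robust consensus plane fit (random
3-point candidates scored by inlier count within ``max_distance`` of the
plane, the plane normal constrained within ``max_angular_distance`` of
vertical, refined by least squares).  The canopy points of each grid cell
are enveloped by an alphashape — the union of Delaunay tetrahedra whose
circumsphere radius is at most the alpha radius (0.5 m here), so small
alpha carves holes and pockets while large alpha approaches the convex
hull — and its volume is the cell's canopy volume.  Dividing by the
average vine volume (mean volume of gap-free reference cells divided by
the plants per cell) converts a cell's volume deficit into a missing-plant
count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import Polygon

from .gridding import GridCell, SiteConfig
from .io_formats import PointCloud3D

__all__ = [
    "PlaneModel",
    "CanopyMetrics3D",
    "AverageVineVolume",
    "fit_ground_plane",
    "split_ground_canopy",
    "clip_cell",
    "alphashape_volume",
    "average_vine_volume",
    "missing_plants_3d",
    "row_volume_map",
    "run_3d",
]


@dataclass
class PlaneModel:
    """Plane ``normal . x = offset`` with the fitting constraints used."""

    normal: np.ndarray  # unit vector, oriented upward
    offset: float  # m
    max_distance: float = 0.5  # m, inlier band half-width
    max_angular_distance: float = 5.0  # degrees from vertical
    reference_normal: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0])
    )

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(self.normal)
        if not norm > 0:
            raise ValueError("normal must be non-zero")
        self.normal = self.normal / norm
        if self.normal @ self.reference_normal < 0:
            self.normal = -self.normal
            self.offset = -self.offset
        if self.angle_to_vertical() > self.max_angular_distance + 1e-9:
            raise ValueError(
                f"plane tilt {self.angle_to_vertical():.2f} deg exceeds "
                f"max_angular_distance {self.max_angular_distance} deg"
            )

    def angle_to_vertical(self) -> float:
        cosang = float(np.clip(self.normal @ self.reference_normal, -1.0, 1.0))
        return math.degrees(math.acos(cosang))

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance (positive above the plane), meters."""
        return np.asarray(points, dtype=float) @ self.normal - self.offset


@dataclass
class CanopyMetrics3D:
    """Per-cell output of the alphashape method."""

    cell_id: int
    row_id: int
    canopy_points: int
    alpha_volume: float  # m^3
    n_missing: int = 0
    sparse: bool = False  # fewer than the point-count floor
    polygon: Optional[Polygon] = None
    method: str = "3D"

    def __post_init__(self) -> None:
        if self.alpha_volume < 0:
            raise ValueError("alpha_volume must be non-negative")

    @property
    def volume(self) -> float:
        return self.alpha_volume


@dataclass
class AverageVineVolume:
    """Reference per-vine volume from gap-free cells."""

    v_bar: float  # m^3 per vine
    n_reference_cells: int

    def __post_init__(self) -> None:
        if not self.v_bar > 0:
            raise ValueError("v_bar must be positive")


# ---------------------------------------------------------------------------
# Ground plane
# ---------------------------------------------------------------------------

def fit_ground_plane(
    cloud: PointCloud3D,
    *,
    max_distance: float = 0.5,
    max_angular_distance: float = 5.0,
    n_iterations: int = 1000,
    seed: int = 0,
    score_sample: int = 30000,
) -> tuple[PlaneModel, np.ndarray]:
    """Robust consensus fit of a near-horizontal ground plane.

    Repeatedly samples 3 points, keeps candidate planes whose normal is
    within ``max_angular_distance`` of vertical, and scores them by the
    number of points within ``max_distance``; near-best candidates are
    tie-broken toward the lowest plane (the ground, not a canopy stratum).
    The winner is refined by least squares on its inliers.  Deterministic
    given ``seed``.  Returns the plane and the inlier index array.

    Candidate scoring runs on a random subsample of at most
    ``score_sample`` points for speed; the final inlier classification
    always uses the full cloud.
    """
    pts = cloud.points
    n = len(pts)
    if n < 3:
        raise ValueError("need at least 3 points to fit a plane")
    rng = np.random.default_rng(seed)
    if n > score_sample:
        score_idx = rng.choice(n, score_sample, replace=False)
        score_pts = pts[score_idx]
    else:
        score_pts = pts
    cos_limit = math.cos(math.radians(max_angular_distance))
    vertical = np.array([0.0, 0.0, 1.0])

    # vectorized candidate generation
    idx = rng.integers(0, n, size=(n_iterations, 3))
    ok = (idx[:, 0] != idx[:, 1]) & (idx[:, 0] != idx[:, 2]) & (idx[:, 1] != idx[:, 2])
    a, b, c = pts[idx[:, 0]], pts[idx[:, 1]], pts[idx[:, 2]]
    normals = np.cross(b - a, c - a)
    norms = np.linalg.norm(normals, axis=1)
    ok &= norms > 1e-12
    normals[ok] /= norms[ok, None]
    normals[normals[:, 2] < 0] *= -1
    ok &= normals[:, 2] >= cos_limit
    if not ok.any():
        raise ValueError(
            "no admissible plane: no candidate within the angular constraint"
        )
    normals = normals[ok]
    offsets = np.einsum("ij,ij->i", normals, a[ok])
    scores = np.empty(len(normals))
    for lo in range(0, len(normals), 200):
        hi = lo + 200
        dist = score_pts @ normals[lo:hi].T - offsets[lo:hi]
        inband = (np.abs(dist) <= max_distance).sum(axis=0)
        below = (dist < -max_distance).sum(axis=0)
        # the ground bounds the scene from below: a true ground plane leaves
        # almost nothing under its inlier band, while canopy strata and
        # tilted "diagonal" planes leave large parts of the ground below
        # theirs, so points below the band count against a candidate
        scores[lo:hi] = inband - 2.0 * below
    pick = int(np.argmax(scores))
    normal, offset = normals[pick], float(offsets[pick])

    # iterative least-squares polishing pulls a near-ground candidate onto
    # the ground proper (its inlier band is dominated by ground points)
    inliers = np.flatnonzero(np.abs(pts @ normal - offset) <= max_distance)
    for _ in range(3):
        normal, offset = _lsq_plane(pts[inliers])
        new_inliers = np.flatnonzero(np.abs(pts @ normal - offset) <= max_distance)
        if len(new_inliers) == len(inliers) and np.array_equal(new_inliers, inliers):
            break
        inliers = new_inliers
    tilt = math.degrees(math.acos(float(np.clip(normal @ vertical, -1, 1))))
    if tilt > max_angular_distance:
        raise ValueError(
            f"refined plane tilt {tilt:.2f} deg violates the angular constraint"
        )
    plane = PlaneModel(
        normal=normal,
        offset=offset,
        max_distance=max_distance,
        max_angular_distance=max_angular_distance,
    )
    return plane, inliers


def _lsq_plane(pts: np.ndarray) -> tuple[np.ndarray, float]:
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    normal = vt[-1]
    if normal[2] < 0:
        normal = -normal
    return normal, float(normal @ centroid)


def split_ground_canopy(
    cloud: PointCloud3D, plane: PlaneModel, inliers: np.ndarray
) -> tuple[PointCloud3D, PointCloud3D]:
    """Partition the cloud into ground (inliers) and canopy (points above).

    Non-inlier points below the plane are reconstruction noise and are
    discarded; the discarded count is reported in a warning.  An empty
    canopy is legitimate (a cell with no vines) and only warns.
    """
    n = len(cloud.points)
    is_inlier = np.zeros(n, dtype=bool)
    is_inlier[np.asarray(inliers, dtype=int)] = True
    height = plane.signed_distance(cloud.points)
    canopy_mask = ~is_inlier & (height > 0)
    dropped = int(np.count_nonzero(~is_inlier & (height <= 0)))
    if dropped:
        warnings.warn(f"discarded {dropped} below-ground outlier points", stacklevel=2)
    ground = PointCloud3D(
        cloud.points[is_inlier],
        None if cloud.color is None else cloud.color[is_inlier],
    )
    if not canopy_mask.any():
        warnings.warn("canopy is empty after ground removal", stacklevel=2)
        canopy = PointCloud3D(np.empty((0, 3)))
    else:
        canopy = PointCloud3D(
            cloud.points[canopy_mask],
            None if cloud.color is None else cloud.color[canopy_mask],
        )
    return ground, canopy


def clip_cell(cloud: PointCloud3D, cell: GridCell) -> PointCloud3D:
    """Points whose (x, y) fall in the half-open cell rectangle."""
    if len(cloud.points) == 0:
        return PointCloud3D(np.empty((0, 3)))
    keep = cell.contains(cloud.points[:, :2])
    return PointCloud3D(
        cloud.points[keep],
        None if cloud.color is None else cloud.color[keep],
    )


# ---------------------------------------------------------------------------
# Alphashape
# ---------------------------------------------------------------------------

def alphashape_volume(points: PointCloud3D | np.ndarray, alpha: float) -> float:
    """Volume of the alpha complex of a 3D point set.

    The points are Delaunay-tetrahedralized and every tetrahedron whose
    circumsphere radius is at most ``alpha`` (a length, in meters — the
    MATLAB-style alpha radius, not the 1/alpha convention) is kept; the
    volume is the sum of kept tetrahedra.  ``alpha = inf`` therefore gives
    the convex-hull volume and fewer than 4 points give 0.  Coplanar or
    otherwise degenerate inputs yield volume 0 with a warning.
    """
    pts = points.points if isinstance(points, PointCloud3D) else np.asarray(points, float)
    pts = pts.reshape(-1, 3)
    if len(pts) < 4:
        return 0.0
    try:
        tri = Delaunay(pts)
    except QhullError:
        warnings.warn("degenerate point set: alphashape volume set to 0", stacklevel=2)
        return 0.0
    simplices = pts[tri.simplices]
    volumes, radii = _tetra_volumes_circumradii(simplices)
    keep = np.isfinite(radii) & (radii <= alpha)
    return float(volumes[keep].sum())


def _tetra_volumes_circumradii(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Volumes and circumsphere radii of tetrahedra ``t`` of shape (m,4,3)."""
    a, b, c, d = t[:, 0], t[:, 1], t[:, 2], t[:, 3]
    ab, ac, ad = b - a, c - a, d - a
    volumes = np.abs(np.einsum("ij,ij->i", np.cross(ab, ac), ad)) / 6.0
    m = np.stack([ab, ac, ad], axis=1)  # (m, 3, 3)
    rhs = 0.5 * np.stack(
        [
            np.einsum("ij,ij->i", b, b) - np.einsum("ij,ij->i", a, a),
            np.einsum("ij,ij->i", c, c) - np.einsum("ij,ij->i", a, a),
            np.einsum("ij,ij->i", d, d) - np.einsum("ij,ij->i", a, a),
        ],
        axis=1,
    )
    det = np.linalg.det(m)
    ok = np.abs(det) > 1e-14
    radii = np.full(len(t), np.inf)
    if ok.any():
        centers = np.linalg.solve(m[ok], rhs[ok][..., None])[..., 0]
        radii[ok] = np.linalg.norm(centers - a[ok], axis=1)
    return volumes, radii


# ---------------------------------------------------------------------------
# Missing plants from volume deficit
# ---------------------------------------------------------------------------

def average_vine_volume(
    cells: Sequence[CanopyMetrics3D],
    complete_cell_ids: Sequence[int],
    *,
    plants_per_cell: int = 3,
) -> AverageVineVolume:
    """Mean alphashape volume of complete cells divided by plants per cell."""
    ids = set(complete_cell_ids)
    ref = [c.alpha_volume for c in cells if c.cell_id in ids]
    if not ref:
        raise ValueError(
            "no reference cells without missing plants; supply v_bar manually"
        )
    return AverageVineVolume(
        v_bar=float(np.mean(ref)) / plants_per_cell, n_reference_cells=len(ref)
    )


def missing_plants_3d(
    cell_volume: float,
    v_bar: float,
    *,
    plants_per_cell: int = 3,
    rounding: str = "nearest",
) -> int:
    """Missing plants in a cell from its canopy-volume deficit.

    The number of plants present is ``cell_volume / v_bar`` rounded to an
    integer and clamped to ``[0, plants_per_cell]``; the missing count is
    the complement.  ``rounding`` is ``"nearest"`` (default: decision
    boundaries midway between plant-count hypotheses, robust to symmetric
    volume noise) or ``"ceil"`` (a cell below two average plant volumes is
    the first to flag one missing plant).
    """
    if not v_bar > 0:
        raise ValueError("v_bar must be positive")
    ratio = cell_volume / v_bar
    if rounding == "nearest":
        present = math.floor(ratio + 0.5)
    elif rounding == "ceil":
        present = math.ceil(ratio - 1e-12)
    else:
        raise ValueError("rounding must be 'nearest' or 'ceil'")
    present = max(0, min(plants_per_cell, int(present)))
    return plants_per_cell - present


def row_volume_map(
    cells: Sequence[CanopyMetrics3D],
    grid: Sequence[GridCell],
) -> dict[int, list[tuple[float, float]]]:
    """Per-row profile of (along-row cell midpoint, cell volume).

    Projects each cell's volume onto its row axis; the site map is the
    union of the per-row profiles.
    """
    by_id = {c.cell_id: c for c in grid}
    by_row: dict[int, list[CanopyMetrics3D]] = {}
    for m in cells:
        by_row.setdefault(m.row_id, []).append(m)
    out: dict[int, list[tuple[float, float]]] = {}
    for row_id, row_metrics in by_row.items():
        row_metrics.sort(key=lambda m: m.cell_id)  # cells tile the row in id order
        pos = 0.0
        profile = []
        for m in row_metrics:
            extent = by_id[m.cell_id].along_row_extent
            profile.append((pos + extent / 2.0, m.alpha_volume))
            pos += extent
        out[row_id] = profile
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_3d(
    cloud: PointCloud3D,
    cells: Sequence[GridCell],
    cfg: SiteConfig,
    *,
    seed: int = 0,
    v_bar: Optional[float] = None,
    complete_cell_ids: Optional[Sequence[int]] = None,
    max_distance: float = 0.5,
    max_angular_distance: float = 5.0,
    rounding: str = "nearest",
    sparse_floor: int = 20,
) -> list[CanopyMetrics3D]:
    """Full alphashape pipeline over a gridded site.

    The ground plane is fitted once for the whole site, canopy points are
    clipped per cell and enveloped at the configured alpha radius.  The
    reference per-vine volume comes from, in order of precedence: an
    explicit ``v_bar``; the mean volume of ``complete_cell_ids`` (e.g.
    cells where the surface method saw no gap); or an internal heuristic
    that takes cells near the top of the volume distribution as gap-free
    (volume at least 0.9 of one plant-share below the 90th percentile).
    """
    plane, inliers = fit_ground_plane(
        cloud,
        max_distance=max_distance,
        max_angular_distance=max_angular_distance,
        seed=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, canopy = split_ground_canopy(cloud, plane, inliers)

    cell_points = _bucket_points(canopy.points, cells)
    metrics: list[CanopyMetrics3D] = []
    for cell in cells:
        sub = cell_points[cell.cell_id]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vol = alphashape_volume(sub, cfg.alpha)
        metrics.append(
            CanopyMetrics3D(
                cell_id=cell.cell_id,
                row_id=cell.row_id,
                canopy_points=len(sub),
                alpha_volume=vol,
                sparse=len(sub) < sparse_floor,
                polygon=cell.polygon,
            )
        )

    if v_bar is None:
        if complete_cell_ids is None:
            complete_cell_ids = _heuristic_complete_cells(metrics)
        v_bar = average_vine_volume(
            metrics, complete_cell_ids, plants_per_cell=cfg.plants_per_cell
        ).v_bar
    for m in metrics:
        m.n_missing = missing_plants_3d(
            m.alpha_volume, v_bar,
            plants_per_cell=cfg.plants_per_cell, rounding=rounding,
        )
    return metrics


def _bucket_points(
    points: np.ndarray, cells: Sequence[GridCell]
) -> dict[int, np.ndarray]:
    """Assign points to cells in O(n log n) instead of O(n_cells * n).

    Equivalent to ``clip_cell`` per cell (same half-open rule): points are
    projected once onto the shared row frame, grouped into each cell's
    across-row band, then sliced along the row by binary search.
    """
    out: dict[int, np.ndarray] = {c.cell_id: np.empty((0, 3)) for c in cells}
    if len(points) == 0 or not cells:
        return out
    xy = points[:, :2]
    by_band: dict[tuple, list[GridCell]] = {}
    for c in cells:
        key = (round(c.u[0], 9), round(c.u[1], 9),
               round(float(c.origin @ c.v), 6), round(c.across_row_extent, 9))
        by_band.setdefault(key, []).append(c)
    for (_, _, t0, across), band_cells in by_band.items():
        u, v = band_cells[0].u, band_cells[0].v
        t = xy @ v
        in_band = (t >= t0) & (t < t0 + across)
        idx = np.flatnonzero(in_band)
        if not len(idx):
            continue
        s = xy[idx] @ u
        order = np.argsort(s, kind="stable")
        idx, s = idx[order], s[order]
        for c in band_cells:
            s0 = float(c.origin @ u)
            lo, hi = np.searchsorted(s, [s0, s0 + c.along_row_extent])
            out[c.cell_id] = points[idx[lo:hi]]
    return out


def _heuristic_complete_cells(metrics: Sequence[CanopyMetrics3D]) -> list[int]:
    """Cells plausibly free of missing plants, from the volume distribution.

    The 90th-percentile cell volume is taken as representative of a full
    cell; cells within 0.9 plant-shares of it (i.e. above ``p90 * (1 -
    0.9/3)``) are treated as complete.  With up to ~30% of plants missing
    the 90th percentile still falls on a gap-free cell.  The rule assumes a
    sizeable population of cells (dozens); on very small grids supply
    ``v_bar`` or ``complete_cell_ids`` instead.
    """
    vols = np.array([m.alpha_volume for m in metrics])
    if not len(vols) or vols.max() <= 0:
        raise ValueError("no canopy volume in any cell; supply v_bar manually")
    p90 = np.percentile(vols, 90)
    cutoff = p90 * (1.0 - 0.3)
    return [m.cell_id for m in metrics if m.alpha_volume >= cutoff]
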