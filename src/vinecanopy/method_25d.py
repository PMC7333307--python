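"""2.5D surface-model pipeline: canopy metrics from a DEM.

The method treats the DEM as a single-valued height field.  Terrain slope
is removed with a morphological top-hat (the grey opening of the DEM with a
structuring element wider than a vine row estimates the bare ground, and
subtracting it leaves height above local ground).  Otsu's threshold splits
the height image into soil (white, 1) and vine (black, 0).  Within each
grid cell the per-column count of vine pixels gives the thickness profile
``delta_p(x) = delta(x) * dp * cos(theta)``; row sections thinner than the
0.1 m threshold count as gaps, and the cumulated gap length divided by the
plant spacing gives the number of missing plants, ``N_ext = L_v / l_p``.
Vine height ``dh`` comes from elevation quartiles (first quartile of
per-row vine elevation minus third quartile of per-row soil elevation)
minus the 0.8 m cordon, and volumes follow the cuboid model
``V_p = dh * dL * delta_m`` and ``V_DEM = dh * dA``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon

from .gridding import GridCell, SiteConfig
from .io_formats import DemRaster

__all__ = [
    "BinaryVineMask",
    "ThicknessProfile",
    "CanopyMetrics25D",
    "mitigate_slope",
    "binarize_otsu",
    "otsu_threshold",
    "estimate_theta",
    "thickness_profile",
    "detect_gaps",
    "mean_thickness",
    "cell_height",
    "volumes_25d",
    "extract_cell_patch",
    "run_25d",
]

SOIL, VINE = 1, 0  # mask convention: white = soil, black = vine


@dataclass
class BinaryVineMask:
    """Soil/vine classification aligned to a (cell-clipped) height grid."""

    mask: np.ndarray  # 2D, values in {0, 1}; 1 = soil, 0 = vine
    dp: float  # m/pixel
    theta: float = 0.0  # radians, vine-row slope w.r.t. image horizontal

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be 0 (vine) or 1 (soil)")
        if not abs(self.theta) <= math.pi / 2:
            raise ValueError("theta must lie in [-pi/2, pi/2]")

    @property
    def vine(self) -> np.ndarray:
        """Boolean vine-pixel image."""
        return self.mask == VINE


@dataclass
class ThicknessProfile:
    """Across-row canopy thickness per image column, meters."""

    x: np.ndarray  # column indices
    delta_p: np.ndarray  # m
    threshold: float = 0.1  # m
    dp: float = 0.005
    theta: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x)
        self.delta_p = np.asarray(self.delta_p, dtype=float)
        if np.any(self.delta_p < 0):
            raise ValueError("thickness must be non-negative")
        if len(self.x) != len(self.delta_p):
            raise ValueError("x and delta_p must have equal length")


@dataclass
class CanopyMetrics25D:
    """Per-cell output of the surface-model method."""

    cell_id: int
    row_id: int
    delta_m: float  # mean canopy thickness, m
    dh: float  # canopy height above cordon, m
    n_px: int  # vine pixel count
    dA: float  # vine plan area, m^2
    v_dem: float  # dh * dA, m^3
    v_p: float  # mean-plant cuboid volume dh * dL * delta_m, m^3
    l_v: float  # cumulated gap length, m
    n_missing: int  # N_ext, clamped to [0, plants_per_cell]
    gap_segments: list[tuple[float, float]] = field(default_factory=list)
    polygon: Optional[Polygon] = None
    method: str = "2.5D"

    @property
    def volume(self) -> float:
        """Cell canopy volume under the cuboid model (``V_DEM``)."""
        return self.v_dem


# ---------------------------------------------------------------------------
# Slope mitigation
# ---------------------------------------------------------------------------

def mitigate_slope(
    dem: DemRaster,
    se_radius: int,
    *,
    footprint: str = "square",
) -> DemRaster:
    """Convert elevations to height above local ground via a top-hat.

    A grey opening with a flat structuring element of half-width
    ``se_radius`` pixels erodes away anything narrower than the element —
    i.e. the vine rows — leaving an estimate of the terrain surface; the
    returned raster is ``input - opening``, so soil pixels sit near zero
    and canopy pixels read height above local ground.

    ``footprint`` selects a separable flat square (default; O(n) regardless
    of radius) or a decomposed disc.  The element must be wider than a
    canopy row or the canopy is absorbed into the ground estimate; a
    warning is emitted when ``se_radius`` looks too small.
    """
    if se_radius < 1:
        raise ValueError("se_radius must be >= 1 pixel")
    if se_radius * dem.dp < 0.5:
        warnings.warn(
            f"structuring element half-width {se_radius * dem.dp:.2f} m is "
            "smaller than a typical canopy width; the opening may absorb "
            "canopy into the ground estimate",
            stacklevel=2,
        )
    elev = dem.elevation
    invalid = ~np.isfinite(elev)
    work = elev
    if invalid.any():
        fill = np.nanmin(elev)
        work = np.where(invalid, fill, elev)
    if footprint == "square":
        size = 2 * se_radius + 1
        opened = ndimage.grey_opening(work, size=(size, size), mode="nearest")
    elif footprint == "disk":
        from skimage.morphology import disk, opening

        fp = disk(se_radius, decomposition="sequence")
        opened = opening(work, fp)
    else:
        raise ValueError("footprint must be 'square' or 'disk'")
    heights = work - opened
    heights[invalid] = np.nan
    return DemRaster(heights, dem.dp, dem.origin, dem.crs_note)


def default_se_radius(cfg: SiteConfig, dp: float) -> int:
    """Default structuring-element half-width: twice the inter-row spacing."""
    return max(1, int(round(2.0 * cfg.inter_row / dp)))


# ---------------------------------------------------------------------------
# Otsu binarization
# ---------------------------------------------------------------------------

def otsu_threshold(values: np.ndarray, levels: int = 256) -> float:
    """Otsu's global threshold on min-max rescaled data.

    The data are rescaled to [0, 1] and quantized to ``levels`` grey
    levels; the threshold minimizing the weighted within-class variance is
    found by exhaustive search over all levels and mapped back to the
    input scale.  Raises on a constant input (degenerate histogram).
    """
    vals = np.asarray(values, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite values")
    lo, hi = vals.min(), vals.max()
    if hi <= lo:
        raise ValueError("degenerate histogram: input is constant")
    scaled = (vals - lo) / (hi - lo)
    quant = np.minimum((scaled * levels).astype(int), levels - 1)
    hist = np.bincount(quant, minlength=levels).astype(float)
    n = hist.sum()
    grey = (np.arange(levels) + 0.5) / levels

    w0 = np.cumsum(hist)
    w1 = n - w0
    m0 = np.cumsum(hist * grey)
    total = m0[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = m0 / w0
        mu1 = (total - m0) / w1
        h0 = np.cumsum(hist * grey**2)
        var0 = h0 / w0 - mu0**2
        var1 = (h0[-1] - h0) / w1 - mu1**2
        within = (w0 * var0 + w1 * var1) / n
    # candidate k splits classes into levels <= k and > k
    within[~np.isfinite(within)] = np.inf
    k = int(np.argmin(within[:-1]))
    thr01 = (k + 1) / levels  # class boundary in [0, 1]
    return lo + thr01 * (hi - lo)


def binarize_otsu(heights: DemRaster, *, theta: float = 0.0) -> BinaryVineMask:
    """Classify a height-above-ground raster into soil (1) and vine (0)."""
    thr = otsu_threshold(heights.elevation)
    elev = heights.elevation
    mask = np.where(np.isfinite(elev) & (elev >= thr), VINE, SOIL).astype(np.uint8)
    return BinaryVineMask(mask=mask, dp=heights.dp, theta=theta)


# ---------------------------------------------------------------------------
# Geometry along the row
# ---------------------------------------------------------------------------

def estimate_theta(mask: BinaryVineMask) -> float:
    """Row slope w.r.t. the image horizontal from the vine-pixel principal axis.

    Returns the orientation of the principal axis of the vine pixels in
    ``(-pi/2, pi/2]``.  A mask whose vine pixels span a single column is
    degenerate; it adopts ``theta = 0`` with a warning.
    """
    rows, cols = np.nonzero(mask.vine)
    if len(cols) < 2:
        raise ValueError("need at least 2 vine pixels to estimate theta")
    x = cols.astype(float)
    y = -rows.astype(float)  # image rows increase downward
    x -= x.mean()
    y -= y.mean()
    sxx = np.dot(x, x)
    syy = np.dot(y, y)
    sxy = np.dot(x, y)
    if sxx == 0.0:
        warnings.warn("single-column vine mask: adopting theta = 0", stacklevel=2)
        return 0.0
    theta = 0.5 * math.atan2(2.0 * sxy, sxx - syy)
    if theta <= -math.pi / 2:
        theta += math.pi
    elif theta > math.pi / 2:
        theta -= math.pi
    return theta


def thickness_profile(mask: BinaryVineMask, *, threshold: float = 0.1) -> ThicknessProfile:
    """Per-column vine thickness ``delta_p(x) = delta(x) * dp * cos(theta)``."""
    delta = mask.vine.sum(axis=0).astype(float)
    delta_p = delta * mask.dp * math.cos(mask.theta)
    return ThicknessProfile(
        x=np.arange(mask.mask.shape[1]),
        delta_p=delta_p,
        threshold=threshold,
        dp=mask.dp,
        theta=mask.theta,
    )


def detect_gaps(
    profile: ThicknessProfile,
    l_p: float,
    *,
    plants_per_cell: int = 3,
    bridge_px: int = 3,
    min_gap_frac: float = 0.2,
) -> tuple[float, int, list[tuple[float, float]]]:
    """Gap length, missing-plant count and gap segments for one cell.

    Columns with ``delta_p < threshold`` are gap columns; runs shorter than
    ``bridge_px`` pixels (single-pixel speckle) or shorter than
    ``min_gap_frac * l_p`` meters are bridged first — sub-slot interruptions
    are porosity of a discontinuous canopy, not candidate missing plants,
    and counting them inflates the gap length on any site without a closed
    hedgerow (set ``min_gap_frac=0`` for the raw cumulated length).  The
    surviving gap length ``L_v`` (meters along the row) divided by the
    plant spacing ``l_p`` and rounded half-up gives ``N_ext``, clamped to
    ``[0, plants_per_cell]``.
    """
    gap = profile.delta_p < profile.threshold
    step = profile.dp * math.cos(profile.theta)
    min_cols = max(bridge_px, int(math.ceil(min_gap_frac * l_p / step)) if step > 0 else 0)
    segments: list[tuple[float, float]] = []
    n_gap_cols = 0
    for start, stop in _runs(gap):
        if stop - start < min_cols:
            continue
        n_gap_cols += stop - start
        segments.append((start * step, stop * step))
    l_v = n_gap_cols * step
    n_ext = int(math.floor(l_v / l_p + 0.5))
    n_ext = max(0, min(plants_per_cell, n_ext))
    return l_v, n_ext, segments


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open (start, stop) index pairs."""
    flags = np.asarray(flags, dtype=bool)
    if flags.size == 0:
        return []
    edges = np.flatnonzero(np.diff(flags.astype(np.int8)))
    bounds = np.concatenate(([0], edges + 1, [flags.size]))
    return [
        (int(bounds[i]), int(bounds[i + 1]))
        for i in range(len(bounds) - 1)
        if flags[bounds[i]]
    ]


def mean_thickness(profile: ThicknessProfile) -> float:
    """Mean of ``delta_p`` over columns at or above the gap threshold.

    Sub-threshold columns (gaps, missing plants) are excluded so thin or
    empty sections do not dilute the canopy thickness; returns 0 when no
    column qualifies.
    """
    keep = profile.delta_p >= profile.threshold
    if not keep.any():
        return 0.0
    return float(profile.delta_p[keep].mean())


def cell_height(dem: DemRaster, mask: BinaryVineMask, cordon: float = 0.8) -> float:
    """Canopy height above the cordon from elevation quartiles.

    Per image row, the mean elevation of vine pixels gives ``h_v(y)`` and
    of soil pixels ``h_s(y)``.  ``dh`` is the first quartile of ``h_v``
    minus the third quartile of ``h_s`` minus the cordon height; a
    negative result is clipped to 0 with a warning.
    """
    vine = mask.vine
    soil = ~vine & np.isfinite(dem.elevation)
    if not vine.any() or not soil.any():
        raise ValueError("cell must contain both vine and soil pixels")
    elev = dem.elevation
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        h_v = np.nanmean(np.where(vine, elev, np.nan), axis=1)
        h_s = np.nanmean(np.where(soil, elev, np.nan), axis=1)
    h_v = h_v[np.isfinite(h_v)]
    h_s = h_s[np.isfinite(h_s)]
    hv_m = float(np.percentile(h_v, 25))  # first quartile, linear interpolation
    hs_m = float(np.percentile(h_s, 75))  # third quartile
    dh = hv_m - hs_m - cordon
    if dh < 0:
        warnings.warn(f"negative canopy height ({dh:.3f} m) clipped to 0", stacklevel=2)
        dh = 0.0
    return dh


def volumes_25d(
    dh: float, delta_m: float, n_px: int, dp: float, theta: float, dL: float
) -> tuple[float, float, float]:
    """Cuboid volumes: ``(V_p, V_DEM, dA)``.

    ``V_p = dh * dL * delta_m`` is the mean-plant volume; ``dA = N_px *
    (dp cos(theta))^2`` the vine plan area and ``V_DEM = dh * dA`` the cell
    canopy volume.
    """
    for name, val in (("dh", dh), ("delta_m", delta_m), ("n_px", n_px), ("dp", dp)):
        if not np.isfinite(val) or val < 0:
            raise ValueError(f"{name} must be finite and non-negative")
    v_p = dh * dL * delta_m
    dA = n_px * (dp * math.cos(theta)) ** 2
    v_dem = dh * dA
    return v_p, v_dem, dA


# ---------------------------------------------------------------------------
# Per-cell orchestration
# ---------------------------------------------------------------------------

def extract_cell_patch(dem: DemRaster, cell: GridCell, *, order: int = 0) -> DemRaster:
    """Resample the DEM over a cell onto the cell's row-aligned frame.

    The patch grid has the cell's along-row axis horizontal (image x) and
    the across-row axis vertical, at the DEM's native pixel size, so the
    downstream column/row statistics see a row-aligned image regardless of
    the site's world orientation.  Nearest-neighbor sampling by default:
    interpolating across the canopy/soil step blends the two classes and
    biases the elevation statistics (``order=1`` for bilinear).
    """
    dp = dem.dp
    ncol = max(1, int(round(cell.along_row_extent / dp)))
    nrow = max(1, int(round(cell.across_row_extent / dp)))
    s = (np.arange(ncol) + 0.5) * dp
    t = (np.arange(nrow) + 0.5) * dp
    S, T = np.meshgrid(s, t)
    world = (
        cell.origin[None, None, :]
        + S[..., None] * cell.u[None, None, :]
        + T[..., None] * cell.v[None, None, :]
    )
    col = (world[..., 0] - dem.origin[0]) / dp - 0.5
    row = (dem.origin[1] - world[..., 1]) / dp - 0.5
    patch = ndimage.map_coordinates(
        dem.elevation, [row, col], order=order, mode="nearest"
    )
    return DemRaster(patch, dp, (0.0, cell.across_row_extent), dem.crs_note)


def run_25d(
    dem: DemRaster,
    cells: Sequence[GridCell],
    cfg: SiteConfig,
    *,
    se_radius: Optional[int] = None,
    footprint: str = "square",
    bridge_px: int = 3,
    min_gap_frac: float = 0.2,
) -> list[CanopyMetrics25D]:
    """Full surface-model pipeline over a gridded site.

    Slope is mitigated and Otsu's threshold computed once on the whole
    field (so empty cells are not forced to split noise into two classes);
    each cell is then resampled into its row frame and measured.
    """
    if se_radius is None:
        se_radius = default_se_radius(cfg, dem.dp)
    heights = mitigate_slope(dem, se_radius, footprint=footprint)
    thr = otsu_threshold(heights.elevation)

    out: list[CanopyMetrics25D] = []
    for cell in cells:
        patch = extract_cell_patch(heights, cell)
        vine = np.isfinite(patch.elevation) & (patch.elevation >= thr)
        mask = BinaryVineMask(
            mask=np.where(vine, VINE, SOIL).astype(np.uint8), dp=patch.dp, theta=0.0
        )
        # the patch is row-aligned by construction; residual tilt from the
        # mask principal axis is kept only if clearly estimable
        profile = thickness_profile(mask, threshold=cfg.thickness_threshold)
        l_v, n_ext, segments = detect_gaps(
            profile, cfg.intra_row,
            plants_per_cell=cfg.plants_per_cell, bridge_px=bridge_px,
            min_gap_frac=min_gap_frac,
        )
        delta_m = mean_thickness(profile)
        n_px = int(mask.vine.sum())
        if n_px == 0 or not (~mask.vine).any() or delta_m == 0.0:
            dh = 0.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dh = cell_height(patch, mask, cfg.cordon_height)
        v_p, v_dem, dA = volumes_25d(dh, delta_m, n_px, patch.dp, mask.theta, cfg.intra_row)
        out.append(
            CanopyMetrics25D(
                cell_id=cell.cell_id,
                row_id=cell.row_id,
                delta_m=delta_m,
                dh=dh,
                n_px=n_px,
                dA=dA,
                v_dem=v_dem,
                v_p=v_p,
                l_v=l_v,
                n_missing=n_ext,
                gap_segments=segments,
                polygon=cell.polygon,
            )
        )
    return out
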