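"""Synthetic vineyard generator.

Emulates the geometric structure of a photogrammetric survey of a trellised
vineyard: parallel rows of slab-like canopies riding a cordon wire above
sloped, noisy terrain, with a known subset of plant slots empty.  The
generator produces the matching ground truth, a surface-sampled dense point
cloud, and a surface-model DEM (per pixel, the highest surface visible from
above), so both estimation pipelines can be exercised and scored against a
known answer without any field data.

Two canopy archetypes are provided:

* ``"slab"`` — foliage fills the whole box from the cordon to the canopy
  top (hedged canopies; this matches the cuboid convention of field
  measurements, so volume-recovery tests are exact).
* ``"top"`` — foliage concentrated in the top fraction of the canopy
  height, as under palissage where shoot tips are wrapped along the top
  catch wire and the fruit zone below is leaf-thin.  A nadir surface model
  sees only the canopy top and therefore overestimates such vines, while a
  3D reconstruction does not; this archetype exercises that bias.

Optionally, neighbours of a missing vine can extend a thin canopy bridge
into the empty slot at the top-wire level (``overhang_frac``), reproducing
the "hidden gap" condition where a surface model sees continuous canopy but
the space below the wire is empty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .io_formats import DemRaster, PointCloud3D

__all__ = ["SyntheticSiteSpec", "SyntheticTruth", "generate_site", "render_cloud",
           "render_dem", "site_rows"]

_GROUND_RGB = (134, 96, 67)
_CANOPY_RGB = (44, 120, 44)


@dataclass
class SyntheticSiteSpec:
    """Parameters of a synthetic vineyard site.

    Lengths in meters; ``row_azimuth`` in degrees clockwise from north.
    Defaults describe a Sangiovese-like planting (2.5 x 0.9 m spacing,
    0.8 m cordon, ~1.2 m canopy above the cordon) on gently sloped ground
    with centimeter-level reconstruction noise.
    """

    n_rows: int = 4
    row_length: float = 27.0
    inter_row: float = 2.5
    intra_row: float = 0.9  # l_p
    row_azimuth: float = 45.0  # NE/SW rows
    canopy_height: float = 1.2  # CH, m above the cordon
    cordon_height: float = 0.8  # m
    canopy_thickness: float = 0.4  # CT, m
    canopy_length_frac: float = 0.85  # fraction of l_p occupied per vine
    missing_fraction: float = 0.15
    per_vine_size_cv: float = 0.1
    terrain_slope: float = 0.03  # m/m, dip along world +x
    terrain_noise_sd: float = 0.01  # m
    point_density: float = 300.0  # points/m^2 on sampled surfaces
    ground_point_density: Optional[float] = None  # defaults to point_density
    dem_dp: float = 0.005  # m/pixel
    seed: int = 0
    canopy_profile: str = "slab"  # "slab" | "top"
    top_frac: float = 0.35  # vertical canopy fraction used by "top" profile
    overhang_frac: float = 0.0  # per-side slot fraction bridged next to a gap
    overhang_depth: float = 0.15  # m, vertical extent of the top bridge
    solid_canopy: bool = False  # volume-sample canopies instead of surfaces

    def __post_init__(self) -> None:
        if min(self.row_length, self.inter_row, self.intra_row,
               self.canopy_height, self.cordon_height, self.canopy_thickness,
               self.dem_dp) <= 0:
            raise ValueError("all lengths must be positive")
        if not (0.0 <= self.missing_fraction < 1.0):
            raise ValueError("missing_fraction must lie in [0, 1)")
        if self.point_density <= 0:
            raise ValueError("point_density must be positive")
        if self.canopy_profile not in ("slab", "top"):
            raise ValueError("canopy_profile must be 'slab' or 'top'")
        if not (0.0 < self.canopy_length_frac <= 1.0):
            raise ValueError("canopy_length_frac must lie in (0, 1]")
        if not (0.0 <= self.overhang_frac <= 0.5):
            raise ValueError("overhang_frac must lie in [0, 0.5]")

    # Row frame: u along the row, v across it (toward increasing row index).
    @property
    def u(self) -> np.ndarray:
        az = math.radians(self.row_azimuth)
        return np.array([math.sin(az), math.cos(az)])

    @property
    def v(self) -> np.ndarray:
        u = self.u
        return np.array([-u[1], u[0]])

    @property
    def vines_per_row(self) -> int:
        return int(math.floor(self.row_length / self.intra_row + 1e-9))

    def row_start(self, row_id: int) -> np.ndarray:
        return row_id * self.inter_row * self.v

    def ground_z(self, xy: np.ndarray) -> np.ndarray:
        """Noise-free terrain elevation at world xy."""
        xy = np.asarray(xy, dtype=float)
        return self.terrain_slope * xy[..., 0]


@dataclass
class SyntheticTruth:
    """Ground truth of a generated site."""

    vine_records: pd.DataFrame  # row_id, slot, s, x, y, present, CH, CT, CL, true_volume
    missing_plant_points: np.ndarray  # (n, 2) world xy of absent vines
    ground_plane: tuple[float, float, float]  # (gx, gy, z0): z = gx x + gy y + z0
    seed: int = 0

    @property
    def n_missing(self) -> int:
        return len(self.missing_plant_points)

    @property
    def n_present(self) -> int:
        return int(self.vine_records["present"].sum())


def generate_site(spec: SyntheticSiteSpec) -> SyntheticTruth:
    """Draw a vineyard realization: per-vine sizes and missing slots.

    Deterministic given ``spec.seed``.  Each vine is absent independently
    with probability ``missing_fraction``; canopy dimensions are drawn
    normal around the spec values with the stated coefficient of variation
    (clipped to stay positive and to keep CL within its plant slot).
    """
    rng = np.random.default_rng([spec.seed, 0])
    n_rows, n_vines = spec.n_rows, spec.vines_per_row
    rows = np.repeat(np.arange(n_rows), n_vines)
    slots = np.tile(np.arange(n_vines), n_rows)
    s = (slots + 0.5) * spec.intra_row
    n = len(rows)

    present = rng.random(n) >= spec.missing_fraction
    cv = spec.per_vine_size_cv

    def draw(mean: float) -> np.ndarray:
        if cv == 0:
            return np.full(n, mean)
        vals = rng.normal(mean, cv * mean, n)
        return np.clip(vals, 0.2 * mean, 1.8 * mean)

    ch = draw(spec.canopy_height)
    ct = draw(spec.canopy_thickness)
    cl = np.minimum(draw(spec.canopy_length_frac * spec.intra_row),
                    0.98 * spec.intra_row)

    u, v = spec.u, spec.v
    xy = (s[:, None] * u[None, :]
          + (rows * spec.inter_row)[:, None] * v[None, :])

    records = pd.DataFrame(
        {
            "row_id": rows,
            "slot": slots,
            "s": s,
            "x": xy[:, 0],
            "y": xy[:, 1],
            "present": present,
            "CH": ch,
            "CT": ct,
            "CL": cl,
            "true_volume": ch * ct * cl,
        }
    )
    missing = xy[~present]
    return SyntheticTruth(
        vine_records=records,
        missing_plant_points=missing,
        ground_plane=(spec.terrain_slope, 0.0, 0.0),
        seed=spec.seed,
    )


def site_rows(spec: SyntheticSiteSpec) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    """Row-axis endpoints for grid construction."""
    out = []
    for k in range(spec.n_rows):
        start = spec.row_start(k)
        end = start + spec.row_length * spec.u
        out.append((tuple(start), tuple(end)))
    return out


# ---------------------------------------------------------------------------
# Point cloud rendering
# ---------------------------------------------------------------------------

def render_cloud(truth: SyntheticTruth, spec: SyntheticSiteSpec) -> PointCloud3D:
    """Sample the site surfaces as an SfM-like dense point cloud.

    Ground is sampled uniformly over the site footprint (plus half an
    inter-row margin) on the noisy terrain plane; each present vine
    contributes points on the faces of its canopy box at ``point_density``
    per square meter.  Reproducible given the spec seed.
    """
    rng = np.random.default_rng([spec.seed, 1])
    chunks: list[np.ndarray] = []
    colors: list[tuple[int, int, int]] = []

    # Ground: rectangle in the row frame.
    g_density = spec.ground_point_density or spec.point_density
    t_lo = -spec.inter_row / 2.0
    t_hi = (spec.n_rows - 1) * spec.inter_row + spec.inter_row / 2.0
    area = spec.row_length * (t_hi - t_lo)
    n_ground = int(round(area * g_density))
    st = rng.random((n_ground, 2)) * [spec.row_length, t_hi - t_lo] + [0.0, t_lo]
    xy = st[:, 0:1] * spec.u[None, :] + st[:, 1:2] * spec.v[None, :]
    z = spec.ground_z(xy) + rng.normal(0.0, spec.terrain_noise_sd, n_ground)
    chunks.append(np.column_stack([xy, z]))
    colors.append(_GROUND_RGB)

    present = truth.vine_records[truth.vine_records["present"]]
    for rec in present.itertuples():
        chunks.append(_sample_canopy(rec, spec, rng))
        colors.append(_CANOPY_RGB)

    for bridge in _overhang_bridges(truth, spec):
        chunks.append(_sample_box(bridge, spec, rng))
        colors.append(_CANOPY_RGB)

    counts = [len(c) for c in chunks]
    pts = np.vstack(chunks)
    rgb = np.repeat(np.asarray(colors, dtype=np.uint8), counts, axis=0)
    return PointCloud3D(pts, rgb)


def _canopy_box(rec, spec: SyntheticSiteSpec) -> dict:
    """Canopy box of one vine in row-frame coordinates."""
    z_ground = spec.ground_z(np.array([rec.x, rec.y]))
    z_top = z_ground + spec.cordon_height + rec.CH
    if spec.canopy_profile == "top":
        z_base = z_top - spec.top_frac * rec.CH
    else:
        z_base = z_ground + spec.cordon_height
    return {
        "s0": rec.s - rec.CL / 2.0, "s1": rec.s + rec.CL / 2.0,
        "t0": rec.row_id * spec.inter_row - rec.CT / 2.0,
        "t1": rec.row_id * spec.inter_row + rec.CT / 2.0,
        "z0": z_base, "z1": z_top,
    }


def _sample_canopy(rec, spec: SyntheticSiteSpec, rng: np.random.Generator) -> np.ndarray:
    return _sample_box(_canopy_box(rec, spec), spec, rng)


def _sample_box(box: dict, spec: SyntheticSiteSpec, rng: np.random.Generator) -> np.ndarray:
    L = box["s1"] - box["s0"]
    W = box["t1"] - box["t0"]
    H = box["z1"] - box["z0"]
    pts_stz: list[np.ndarray] = []
    if spec.solid_canopy:
        n = max(4, int(round(L * W * H * spec.point_density)))
        p = rng.random((n, 3)) * [L, W, H]
        pts_stz.append(p + [box["s0"], box["t0"], box["z0"]])
    else:
        for zc, pair in ((box["z0"], None), (box["z1"], None)):
            n = int(round(L * W * spec.point_density))
            p = rng.random((n, 2)) * [L, W] + [box["s0"], box["t0"]]
            pts_stz.append(np.column_stack([p, np.full(n, zc)]))
        for tc in (box["t0"], box["t1"]):
            n = int(round(L * H * spec.point_density))
            p = rng.random((n, 2)) * [L, H] + [box["s0"], box["z0"]]
            pts_stz.append(np.column_stack([p[:, 0], np.full(n, tc), p[:, 1]]))
        for sc in (box["s0"], box["s1"]):
            n = int(round(W * H * spec.point_density))
            p = rng.random((n, 2)) * [W, H] + [box["t0"], box["z0"]]
            pts_stz.append(np.column_stack([np.full(n, sc), p[:, 0], p[:, 1]]))
    stz = np.vstack(pts_stz)
    xy = stz[:, 0:1] * spec.u[None, :] + stz[:, 1:2] * spec.v[None, :]
    z = stz[:, 2] + rng.normal(0.0, spec.terrain_noise_sd, len(stz))
    return np.column_stack([xy, z])


def _overhang_bridges(truth: SyntheticTruth, spec: SyntheticSiteSpec) -> list[dict]:
    """Top-wire canopy bridges reaching into missing slots from neighbours."""
    if spec.overhang_frac <= 0:
        return []
    bridges: list[dict] = []
    recs = truth.vine_records
    reach = spec.overhang_frac * spec.intra_row
    for row_id, group in recs.groupby("row_id"):
        group = group.sort_values("slot")
        present = group["present"].to_numpy()
        for i, rec in enumerate(group.itertuples()):
            if rec.present:
                continue
            slot_lo = rec.s - spec.intra_row / 2.0
            slot_hi = rec.s + spec.intra_row / 2.0
            t0 = row_id * spec.inter_row - spec.canopy_thickness / 2.0
            t1 = row_id * spec.inter_row + spec.canopy_thickness / 2.0
            z_ground = spec.ground_z(np.array([rec.x, rec.y]))
            z1 = z_ground + spec.cordon_height + spec.canopy_height
            z0 = z1 - spec.overhang_depth
            if i > 0 and present[i - 1]:
                bridges.append({"s0": slot_lo, "s1": slot_lo + reach,
                                "t0": t0, "t1": t1, "z0": z0, "z1": z1})
            if i < len(present) - 1 and present[i + 1]:
                bridges.append({"s0": slot_hi - reach, "s1": slot_hi,
                                "t0": t0, "t1": t1, "z0": z0, "z1": z1})
    return bridges


# ---------------------------------------------------------------------------
# DEM rendering
# ---------------------------------------------------------------------------

def render_dem(truth: SyntheticTruth, spec: SyntheticSiteSpec) -> DemRaster:
    """Rasterize the site as a surface model (highest surface per pixel).

    A pixel over a present vine reads ground + cordon + CH (the canopy top);
    anywhere else it reads the bare terrain.  Gaussian reconstruction noise
    is added to every pixel.
    """
    rng = np.random.default_rng([spec.seed, 2])
    dp = spec.dem_dp
    # World bounding box of the ground rectangle (row frame corners).
    t_lo = -spec.inter_row / 2.0
    t_hi = (spec.n_rows - 1) * spec.inter_row + spec.inter_row / 2.0
    corners_st = np.array(
        [[0, t_lo], [0, t_hi], [spec.row_length, t_lo], [spec.row_length, t_hi]]
    )
    corners = corners_st[:, 0:1] * spec.u[None, :] + corners_st[:, 1:2] * spec.v[None, :]
    x_min, y_min = corners.min(axis=0)
    x_max, y_max = corners.max(axis=0)
    ncols = int(math.ceil((x_max - x_min) / dp))
    nrows = int(math.ceil((y_max - y_min) / dp))
    origin = (x_min, y_max)

    xs = x_min + (np.arange(ncols) + 0.5) * dp
    ys = y_max - (np.arange(nrows) + 0.5) * dp
    elev = spec.terrain_slope * np.broadcast_to(xs, (nrows, ncols)).copy()

    boxes = [
        _canopy_box(rec, spec)
        for rec in truth.vine_records[truth.vine_records["present"]].itertuples()
    ]
    boxes.extend(_overhang_bridges(truth, spec))
    u, v = spec.u, spec.v
    for box in boxes:
        _stamp_box_top(elev, box, xs, ys, u, v, dp)

    elev += rng.normal(0.0, spec.terrain_noise_sd, elev.shape)
    return DemRaster(elev, dp, origin)


def _stamp_box_top(elev, box, xs, ys, u, v, dp) -> None:
    """Raise DEM pixels under a box footprint to the box top elevation."""
    corners_st = np.array(
        [[box["s0"], box["t0"]], [box["s0"], box["t1"]],
         [box["s1"], box["t0"]], [box["s1"], box["t1"]]]
    )
    corners = corners_st[:, 0:1] * u[None, :] + corners_st[:, 1:2] * v[None, :]
    x0, y0 = corners.min(axis=0) - dp
    x1, y1 = corners.max(axis=0) + dp
    c0, c1 = np.searchsorted(xs, [x0, x1])
    # ys decreases with row index
    r0 = np.searchsorted(-ys, -y1)
    r1 = np.searchsorted(-ys, -y0)
    if c1 <= c0 or r1 <= r0:
        return
    X, Y = np.meshgrid(xs[c0:c1], ys[r0:r1])
    s = X * u[0] + Y * u[1]
    t = X * v[0] + Y * v[1]
    inside = (s >= box["s0"]) & (s < box["s1"]) & (t >= box["t0"]) & (t < box["t1"])
    window = elev[r0:r1, c0:c1]
    window[inside] = np.maximum(window[inside], box["z1"])
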