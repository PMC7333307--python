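"""Uniform polygon grid construction over vine rows.

Each grid cell is a rectangle centered on a row axis that spans the full
inter-row width across the row (midpoint-to-midpoint between adjacent rows)
and ``plants_per_cell`` intra-row spacings along it, so a cell isolates a
fixed number of plant slots (three by default).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Polygon

__all__ = ["SiteConfig", "GridCell", "build_grid", "potential_plants"]


@dataclass
class SiteConfig:
    """Site geometry and method thresholds.

    Defaults follow common vertical-shoot-positioned vineyard practice: a
    0.8 m cordon, a 0.1 m canopy-thickness threshold below which a row
    section counts as a gap, and an alphashape radius of 0.5 m.
    """

    inter_row: float  # m between row axes
    intra_row: float  # l_p, m between plants along the row
    row_azimuth: float = 0.0  # degrees clockwise from north
    surface: Optional[float] = None  # ha
    density: Optional[float] = None  # plants/ha
    cordon_height: float = 0.8  # m
    thickness_threshold: float = 0.1  # m
    alpha: float = 0.5  # m, alphashape radius
    plants_per_cell: int = 3

    def __post_init__(self) -> None:
        if self.inter_row <= 0 or self.intra_row <= 0:
            raise ValueError("row spacings must be positive")
        if self.thickness_threshold <= 0:
            raise ValueError("thickness_threshold must be > 0")
        if self.plants_per_cell < 1:
            raise ValueError("plants_per_cell must be >= 1")
        if self.density is not None and self.surface is not None:
            geometric = 1e4 / (self.inter_row * self.intra_row)
            if abs(self.density - geometric) > 0.05 * geometric:
                warnings.warn(
                    f"declared density {self.density:.0f}/ha differs from the "
                    f"spacing-implied {geometric:.0f}/ha by more than 5%",
                    stacklevel=2,
                )

    @property
    def cell_length(self) -> float:
        """Along-row extent of one grid cell, m."""
        return self.plants_per_cell * self.intra_row


@dataclass
class GridCell:
    """Rectangular cell in world coordinates with its own row-aligned frame.

    ``origin`` is the cell corner at the start of the cell on the low-t side;
    ``u`` points along the row, ``v`` across it.  Membership uses half-open
    intervals (``0 <= s < along``, ``0 <= t < across``) so a point on a
    shared boundary belongs to exactly one cell.
    """

    cell_id: int
    row_id: int
    origin: np.ndarray  # (2,) world xy of the cell corner
    u: np.ndarray  # (2,) unit vector along the row
    along_row_extent: float  # m
    across_row_extent: float  # m
    expected_plants: int = 3

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.u = self.u / np.linalg.norm(self.u)

    @property
    def v(self) -> np.ndarray:
        """Across-row unit vector (90 deg counter-clockwise from u)."""
        return np.array([-self.u[1], self.u[0]])

    @property
    def polygon(self) -> Polygon:
        o, u, v = self.origin, self.u, self.v
        a, c = self.along_row_extent, self.across_row_extent
        return Polygon([tuple(o), tuple(o + a * u), tuple(o + a * u + c * v), tuple(o + c * v)])

    def to_local(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Project world points to (s, t) cell coordinates (along, across)."""
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        rel = xy - self.origin
        return rel @ self.u, rel @ self.v

    def contains(self, xy: np.ndarray) -> np.ndarray:
        s, t = self.to_local(xy)
        return (
            (s >= 0) & (s < self.along_row_extent)
            & (t >= 0) & (t < self.across_row_extent)
        )


def build_grid(
    rows: Sequence[tuple[tuple[float, float], tuple[float, float]]],
    cfg: SiteConfig,
    *,
    keep_partial: bool = False,
) -> list[GridCell]:
    """Tile each row with cells of ``plants_per_cell * intra_row`` length.

    ``rows`` are (start, end) world coordinates of each row axis.  Rows must
    be parallel within 1 degree.  A terminal remainder shorter than a full
    cell is dropped unless ``keep_partial`` is set, in which case it is kept
    with a prorated expected plant count (remainders shorter than one plant
    slot are always dropped).
    """
    if not rows:
        raise ValueError("at least one row is required")
    starts = np.asarray([r[0] for r in rows], dtype=float)
    ends = np.asarray([r[1] for r in rows], dtype=float)
    dirs = ends - starts
    lengths = np.linalg.norm(dirs, axis=1)
    if np.any(lengths <= 0):
        raise ValueError("zero-length row")
    units = dirs / lengths[:, None]
    ref = units[0]
    cosang = np.clip(units @ ref, -1.0, 1.0)
    if np.any(np.degrees(np.arccos(np.abs(cosang))) > 1.0):
        raise ValueError("rows are not parallel within 1 degree")

    cells: list[GridCell] = []
    cell_id = 0
    half = cfg.inter_row / 2.0
    cell_len = cfg.cell_length
    for row_id, (start, u, length) in enumerate(zip(starts, units, lengths)):
        v = np.array([-u[1], u[0]])
        n_full = int(math.floor(length / cell_len + 1e-9))
        extents = [cell_len] * n_full
        remainder = length - n_full * cell_len
        if keep_partial and remainder >= cfg.intra_row - 1e-9:
            extents.append(remainder)
        pos = 0.0
        for extent in extents:
            n_plants = int(_round_half_up(extent / cfg.intra_row))
            cells.append(
                GridCell(
                    cell_id=cell_id,
                    row_id=row_id,
                    origin=start + pos * u - half * v,
                    u=u,
                    along_row_extent=extent,
                    across_row_extent=cfg.inter_row,
                    expected_plants=min(n_plants, cfg.plants_per_cell),
                )
            )
            cell_id += 1
            pos += extent
    return cells


def potential_plants(density: float, surface: float) -> int:
    """Number of plant positions implied by planting density and site area.

    Rounds ``density * surface`` half-up to the nearest integer.
    """
    if density <= 0 or surface <= 0:
        raise ValueError("density and surface must both be positive")
    return int(_round_half_up(density * surface))


def _round_half_up(x: float) -> float:
    return math.floor(x + 0.5)
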