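"""Readers and writers for the raster, point-cloud, vector and tabular formats.

All coordinates live in a single local metric frame (meters); no geodetic
reprojection is performed.  Supported formats:

* DEM: ESRI ASCII grid (``.asc``) and GeoTIFF (``.tif``/``.tiff``) carrying
  the ``ModelPixelScale`` / ``ModelTiepoint`` tags.
* Point clouds: PLY (ascii or binary little-endian, double-precision
  vertices) and whitespace-delimited XYZ[RGB] text.
* Vector: GeoJSON (grid-cell polygons, missing-plant points).
* Tabular: CSV (per-cell reports, ground-truth vine measurements).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "DemRaster",
    "PointCloud3D",
    "GroundTruthSet",
    "read_dem",
    "write_dem",
    "read_cloud",
    "write_cloud",
    "write_cell_report",
    "read_cell_report",
    "write_points_geojson",
    "read_points_geojson",
    "read_ground_truth_csv",
    "write_ground_truth_csv",
]

_NODATA = -9999.0


@dataclass
class DemRaster:
    """Georeferenced elevation grid with square pixels.

    ``origin`` is the world coordinate of the *outer corner* of pixel
    ``(0, 0)``; the row index increases southward (north-up raster), so the
    center of pixel ``(r, c)`` sits at
    ``(origin_x + (c + 0.5) dp, origin_y - (r + 0.5) dp)``.

    No-data cells are carried as NaN in ``elevation``.
    """

    elevation: np.ndarray  # 2D float array, meters; NaN marks no-data
    dp: float  # pixel size, m/pixel
    origin: tuple[float, float]  # world (x, y) of outer corner of pixel (0,0)
    crs_note: str = "local metric frame"

    def __post_init__(self) -> None:
        self.elevation = np.asarray(self.elevation, dtype=float)
        if self.elevation.ndim != 2 or self.elevation.size == 0:
            raise ValueError("elevation grid must be a non-empty 2D array")
        if not (self.dp > 0):
            raise ValueError(f"pixel size dp must be > 0, got {self.dp}")
        finite = self.elevation[np.isfinite(self.elevation)]
        if finite.size and (finite.min() < -500.0 or finite.max() > 9000.0):
            raise ValueError("finite elevations must lie within [-500, 9000] m")

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevation.shape

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """World x (per column) and y (per row) coordinates of pixel centers."""
        nrow, ncol = self.elevation.shape
        x = self.origin[0] + (np.arange(ncol) + 0.5) * self.dp
        y = self.origin[1] - (np.arange(nrow) + 0.5) * self.dp
        return x, y


@dataclass
class PointCloud3D:
    """Unordered set of XYZ points in meters, optionally RGB-colored."""

    points: np.ndarray  # (n, 3) float
    color: Optional[np.ndarray] = None  # (n, 3) uint8 or None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must all be finite")
        if self.color is not None:
            self.color = np.asarray(self.color, dtype=np.uint8).reshape(-1, 3)
            if len(self.color) != len(self.points):
                raise ValueError("color array length must match point count")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class GroundTruthSet:
    """Field validation data: missing-plant positions and per-vine measures."""

    missing_plant_points: np.ndarray  # (n, 2) world xy
    vine_measurements: Optional[list[dict]] = None  # vine_id, CH, CT, CL, observed_volume

    def __post_init__(self) -> None:
        self.missing_plant_points = np.asarray(
            self.missing_plant_points, dtype=float
        ).reshape(-1, 2)
        for rec in self.vine_measurements or []:
            vol = rec.get("observed_volume")
            if vol is not None:
                expect = rec["CH"] * rec["CT"] * rec["CL"]
                if abs(vol - expect) > 1e-9:
                    raise ValueError(
                        f"vine {rec.get('vine_id')}: observed_volume {vol} != "
                        f"CH*CT*CL = {expect}"
                    )


# ---------------------------------------------------------------------------
# DEM I/O
# ---------------------------------------------------------------------------

def read_dem(path: str | Path) -> DemRaster:
    """Read a DEM from an ESRI ASCII grid or a GeoTIFF.

    Rejects rasters with non-square pixels or missing georeference.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".asc", ".agr", ".grd"):
        return _read_ascii_grid(path)
    if suffix in (".tif", ".tiff"):
        return _read_geotiff(path)
    raise ValueError(f"unsupported DEM format: {path.suffix!r} (use .asc or .tif)")


def write_dem(dem: DemRaster, path: str | Path) -> None:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".asc", ".agr", ".grd"):
        _write_ascii_grid(dem, path)
    elif suffix in (".tif", ".tiff"):
        _write_geotiff(dem, path)
    else:
        raise ValueError(f"unsupported DEM format: {path.suffix!r}")


def _read_ascii_grid(path: Path) -> DemRaster:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        data = np.loadtxt(fh, dtype=float, ndmin=2)
    required = {"ncols", "nrows", "cellsize"}
    if not required <= header.keys():
        raise ValueError(f"{path}: missing georeference keys {required - header.keys()}")
    if "dx" in header or "dy" in header:
        raise ValueError(f"{path}: rectangular pixels (dx/dy) are not supported")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (nrows, ncols):
        raise ValueError(f"{path}: grid shape {data.shape} != header ({nrows}, {ncols})")
    dp = header["cellsize"]
    nodata = header.get("nodata_value", _NODATA)
    data[data == nodata] = np.nan
    # header gives the lower-left corner; our origin is the upper-left corner
    xll = header.get("xllcorner", 0.0)
    yll = header.get("yllcorner", 0.0)
    return DemRaster(data, dp, (xll, yll + nrows * dp))


def _write_ascii_grid(dem: DemRaster, path: Path) -> None:
    nrows, ncols = dem.shape
    xll = dem.origin[0]
    yll = dem.origin[1] - nrows * dem.dp
    data = np.where(np.isfinite(dem.elevation), dem.elevation, _NODATA)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {float(xll)!r}\n")
        fh.write(f"yllcorner {float(yll)!r}\n")
        fh.write(f"cellsize {float(dem.dp)!r}\n")
        fh.write(f"NODATA_value {_NODATA}\n")
        np.savetxt(fh, data, fmt="%.6f")


_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_NODATA = 42113  # GDAL_NODATA


def _read_geotiff(path: Path) -> DemRaster:
    import tifffile

    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        scale_tag = page.tags.get(_TAG_PIXEL_SCALE)
        tie_tag = page.tags.get(_TAG_TIEPOINT)
        if scale_tag is None or tie_tag is None:
            raise ValueError(f"{path}: missing GeoTIFF georeference tags")
        sx, sy = scale_tag.value[0], scale_tag.value[1]
        if abs(sx - sy) > 1e-12 * max(sx, sy):
            raise ValueError(f"{path}: non-square pixels ({sx} x {sy}) not supported")
        tie = tie_tag.value
        # tiepoint maps raster (i, j) -> world (x, y); tie at pixel (0, 0) corner
        origin = (tie[3] - tie[0] * sx, tie[4] + tie[1] * sy)
        data = page.asarray().astype(float)
        nodata_tag = page.tags.get(_TAG_NODATA)
        if nodata_tag is not None:
            data[data == float(nodata_tag.value)] = np.nan
        return DemRaster(data, float(sx), origin)


def _write_geotiff(dem: DemRaster, path: Path) -> None:
    import tifffile  # noqa: F811 - local import keeps tifffile optional for ascii use

    data = np.where(np.isfinite(dem.elevation), dem.elevation, _NODATA)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (dem.dp, dem.dp, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, dem.origin[0], dem.origin[1], 0.0)),
        (_TAG_NODATA, "s", 0, str(_NODATA)),
    ]
    tifffile.imwrite(str(path), data.astype(np.float64), extratags=extratags)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# Point-cloud I/O
# ---------------------------------------------------------------------------

def read_cloud(path: str | Path) -> PointCloud3D:
    """Read a point cloud from PLY or XYZ[RGB] text.

    LAS/LAZ is not supported (no LAS codec available); a clear error points
    the user at PLY/XYZ conversion.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".ply":
        return _read_ply(path)
    if suffix in (".xyz", ".txt", ".pts"):
        return _read_xyz(path)
    if suffix in (".las", ".laz"):
        raise ValueError(
            "LAS/LAZ input is not supported; convert to PLY or XYZ text first"
        )
    raise ValueError(f"unknown point-cloud extension {path.suffix!r}")


def write_cloud(cloud: PointCloud3D, path: str | Path, *, encoding: str = "binary") -> None:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".ply":
        _write_ply(cloud, path, encoding=encoding)
    elif suffix in (".xyz", ".txt", ".pts"):
        _write_xyz(cloud, path)
    else:
        raise ValueError(f"unknown point-cloud extension {path.suffix!r}")


def _read_xyz(path: Path) -> PointCloud3D:
    pts: list[list[float]] = []
    colors: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) not in (3, 6):
                raise ValueError(f"{path}:{lineno}: expected 3 or 6 fields, got {len(parts)}")
            try:
                vals = [float(v) for v in parts]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed record: {exc}") from exc
            pts.append(vals[:3])
            if len(vals) == 6:
                colors.append(vals[3:])
    if not pts:
        raise ValueError(f"{path}: no points")
    color = np.asarray(colors, dtype=np.uint8) if len(colors) == len(pts) else None
    return PointCloud3D(np.asarray(pts), color)


def _write_xyz(cloud: PointCloud3D, path: Path) -> None:
    with open(path, "w") as fh:
        if cloud.color is None:
            for x, y, z in cloud.points:
                fh.write(f"{float(x)!r} {float(y)!r} {float(z)!r}\n")
        else:
            for (x, y, z), (r, g, b) in zip(cloud.points, cloud.color):
                fh.write(f"{float(x)!r} {float(y)!r} {float(z)!r} {r} {g} {b}\n")


# PLY with double-precision vertices (float32 would lose the sub-mm
# round-trip guarantee at kilometre-scale survey coordinates).

def _write_ply(cloud: PointCloud3D, path: Path, *, encoding: str = "binary") -> None:
    n = len(cloud.points)
    has_color = cloud.color is not None
    fmt = "binary_little_endian" if encoding == "binary" else "ascii"
    header = [
        "ply",
        f"format {fmt} 1.0",
        f"element vertex {n}",
        "property double x",
        "property double y",
        "property double z",
    ]
    if has_color:
        header += ["property uchar red", "property uchar green", "property uchar blue"]
    header += ["end_header"]
    if encoding == "binary":
        with open(path, "wb") as fh:
            fh.write(("\n".join(header) + "\n").encode("ascii"))
            if has_color:
                rec = np.zeros(n, dtype=[("xyz", "<f8", 3), ("rgb", "u1", 3)])
                rec["xyz"] = cloud.points
                rec["rgb"] = cloud.color
            else:
                rec = np.zeros(n, dtype=[("xyz", "<f8", 3)])
                rec["xyz"] = cloud.points
            fh.write(rec.tobytes())
    else:
        with open(path, "w") as fh:
            fh.write("\n".join(header) + "\n")
            if has_color:
                for (x, y, z), (r, g, b) in zip(cloud.points, cloud.color):
                    fh.write(f"{float(x)!r} {float(y)!r} {float(z)!r} {r} {g} {b}\n")
            else:
                for x, y, z in cloud.points:
                    fh.write(f"{float(x)!r} {float(y)!r} {float(z)!r}\n")


_PLY_TYPES = {
    "char": "i1", "uchar": "u1", "int8": "i1", "uint8": "u1",
    "short": "i2", "ushort": "u2", "int16": "i2", "uint16": "u2",
    "int": "i4", "uint": "u4", "int32": "i4", "uint32": "u4",
    "float": "f4", "float32": "f4", "double": "f8", "float64": "f8",
}


def _read_ply(path: Path) -> PointCloud3D:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise ValueError(f"{path}: not a PLY file")
        fmt = None
        n_vertex = 0
        props: list[tuple[str, str]] = []
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: truncated PLY header")
            tokens = line.decode("ascii", "replace").split()
            if not tokens:
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                in_vertex = tokens[1] == "vertex"
                if in_vertex:
                    n_vertex = int(tokens[2])
            elif tokens[0] == "property" and in_vertex:
                if tokens[1] == "list":
                    raise ValueError(f"{path}: list properties not supported on vertices")
                props.append((tokens[2], _PLY_TYPES[tokens[1]]))
            elif tokens[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise ValueError(f"{path}: unsupported PLY format {fmt!r}")
        if n_vertex == 0:
            raise ValueError(f"{path}: no points")
        names = [name for name, _ in props]
        for axis in ("x", "y", "z"):
            if axis not in names:
                raise ValueError(f"{path}: vertex element lacks property {axis!r}")
        if fmt == "ascii":
            rows = []
            for i in range(n_vertex):
                parts = fh.readline().split()
                if len(parts) != len(props):
                    raise ValueError(f"{path}: malformed vertex record {i}")
                rows.append([float(v) for v in parts])
            arr = np.asarray(rows, dtype=float)
            table = {name: arr[:, k] for k, (name, _) in enumerate(props)}
        else:
            dtype = np.dtype([(name, "<" + code) for name, code in props])
            raw = fh.read(dtype.itemsize * n_vertex)
            if len(raw) < dtype.itemsize * n_vertex:
                raise ValueError(f"{path}: truncated vertex data")
            rec = np.frombuffer(raw, dtype=dtype, count=n_vertex)
            table = {name: rec[name].astype(float) for name, _ in props}
    points = np.column_stack([table["x"], table["y"], table["z"]])
    color = None
    if all(c in table for c in ("red", "green", "blue")):
        color = np.column_stack(
            [table["red"], table["green"], table["blue"]]
        ).astype(np.uint8)
    return PointCloud3D(points, color)


# ---------------------------------------------------------------------------
# Reports, GeoJSON, ground truth
# ---------------------------------------------------------------------------

def write_cell_report(cells: Sequence, path: str | Path) -> None:
    """Write per-cell metrics as CSV plus a sibling GeoJSON of cell polygons.

    ``cells`` are CanopyMetrics25D/CanopyMetrics3D-like objects exposing
    ``cell_id``, ``row_id``, ``method``, ``volume``, ``n_missing`` and a
    ``polygon`` (shapely) attribute.
    """
    if not cells:
        raise ValueError("cells must be non-empty")
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cell_id", "row_id", "method", "volume_m3", "n_missing"])
        for cell in cells:
            writer.writerow(
                [cell.cell_id, cell.row_id, cell.method,
                 f"{cell.volume:.9g}", cell.n_missing]
            )
    features = []
    for cell in cells:
        features.append(
            {
                "type": "Feature",
                "geometry": _polygon_geojson(cell.polygon),
                "properties": {
                    "cell_id": cell.cell_id,
                    "row_id": cell.row_id,
                    "method": cell.method,
                    "volume_m3": cell.volume,
                    "n_missing": cell.n_missing,
                },
            }
        )
    geojson_path = path.with_suffix(".geojson")
    with open(geojson_path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_cell_report(path: str | Path) -> list[dict]:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    for row in rows:
        row["volume_m3"] = float(row["volume_m3"])
        row["n_missing"] = int(row["n_missing"])
    return rows


def _polygon_geojson(polygon) -> dict:
    from shapely.geometry import mapping

    return json.loads(json.dumps(mapping(polygon)))


def write_points_geojson(points: np.ndarray, path: str | Path, *, properties=None) -> None:
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    features = []
    for i, (x, y) in enumerate(points):
        props = dict(properties[i]) if properties else {}
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [x, y]},
                "properties": props,
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_points_geojson(path: str | Path) -> np.ndarray:
    with open(path) as fh:
        data = json.load(fh)
    pts = []
    for feature in data.get("features", []):
        geom = feature.get("geometry", {})
        if geom.get("type") == "Point":
            pts.append(geom["coordinates"][:2])
    return np.asarray(pts, dtype=float).reshape(-1, 2)


def write_ground_truth_csv(truth: GroundTruthSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["vine_id", "CH_m", "CT_m", "CL_m", "observed_volume_m3"])
        for rec in truth.vine_measurements or []:
            writer.writerow(
                [rec["vine_id"], rec["CH"], rec["CT"], rec["CL"],
                 rec.get("observed_volume", rec["CH"] * rec["CT"] * rec["CL"])]
            )


def read_ground_truth_csv(path: str | Path) -> list[dict]:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    out = []
    for row in rows:
        out.append(
            {
                "vine_id": row["vine_id"],
                "CH": float(row["CH_m"]),
                "CT": float(row["CT_m"]),
                "CL": float(row["CL_m"]),
                "observed_volume": float(row["observed_volume_m3"]),
            }
        )
    return out
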