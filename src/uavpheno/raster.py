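"""Georeferenced raster and plot-vector I/O.

Conventions used throughout the package:

* pixels are 0-based, row-major, origin at the top-left of the image;
* the affine transform maps a pixel index ``(col, row)`` to the world
  coordinates of that pixel's **center** (ESRI world-file semantics);
* polygon membership of a pixel is decided by the center-point rule.

Rasters are stored as GeoTIFF (via tifffile, with ``ModelPixelScale`` /
``ModelTiepoint`` / ``GDAL_NODATA`` tags for interoperability and a JSON
image description carrying the exact affine, units and nodata), or as PNG
with an ESRI ``.wld`` world-file sidecar.  Plot layers are GeoJSON.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon, shape as shapely_shape, mapping as shapely_mapping

from .errors import EmptyRegionWarning, FormatError, ValidationError

__all__ = [
    "Affine",
    "RasterGrid",
    "PlotPolygon",
    "PlotRecord",
    "read_raster",
    "write_raster",
    "read_plots",
    "write_plots",
    "rasterize_plot",
]

ZONES = ("density", "nitrogen", "potassium")
VARIETIES = ("Z3", "Z5")
_LEVELS = {
    "density": ("T0", "T1", "T2"),
    "nitrogen": ("N0", "N1", "N2", "N3"),
    "potassium": ("K0", "K2"),
}


class Affine(NamedTuple):
    """Affine pixel->world map: ``x = a*col + b*row + c``, ``y = d*col + e*row + f``.

    ``(c, f)`` is the world position of the center of pixel ``(0, 0)``.
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    @classmethod
    def identity(cls) -> "Affine":
        return cls(1.0, 0.0, 0.0, 0.0, 1.0, 0.0)

    @classmethod
    def north_up(cls, x0: float, y0: float, px: float) -> "Affine":
        """Square pixels of size ``px``; top-left pixel center at ``(x0, y0)``; y decreasing downward."""
        return cls(px, 0.0, x0, 0.0, -px, y0)

    @property
    def determinant(self) -> float:
        return self.a * self.e - self.b * self.d

    def xy(self, col, row):
        """World coordinates of pixel centers."""
        col = np.asarray(col, dtype=float)
        row = np.asarray(row, dtype=float)
        return self.a * col + self.b * row + self.c, self.d * col + self.e * row + self.f

    def colrow(self, x, y):
        """Fractional pixel index of world coordinates (inverse map)."""
        det = self.determinant
        if det == 0:
            raise ValidationError("affine transform is singular")
        x = np.asarray(x, dtype=float) - self.c
        y = np.asarray(y, dtype=float) - self.f
        col = (self.e * x - self.b * y) / det
        row = (-self.d * x + self.a * y) / det
        return col, row


@dataclass
class RasterGrid:
    """A georeferenced value grid: single band ``(h, w)`` or RGB ``(h, w, 3)``.

    ``units`` is free text; ``"DN8"`` marks 8-bit digital numbers, ``"m"``
    metres, ``"index"`` dimensionless vegetation-index values and
    ``"binary"`` a {0, 1} mask.
    """

    values: np.ndarray
    transform: Affine = field(default_factory=Affine.identity)
    nodata: float | None = None
    units: str = "unknown"

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if not isinstance(self.transform, Affine):
            self.transform = Affine(*self.transform)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        v = self.values
        if v.ndim not in (2, 3):
            raise ValidationError(f"raster must be 2-D or 3-band, got ndim={v.ndim}")
        if v.ndim == 3 and v.shape[2] != 3:
            raise ValidationError(f"3-D raster must have 3 bands last, got shape {v.shape}")
        if v.shape[0] < 1 or v.shape[1] < 1:
            raise ValidationError("raster must have positive row/column counts")
        if self.transform.determinant == 0:
            raise ValidationError("affine transform must have nonzero determinant")
        if self.units == "DN8":
            data = self._valid_values()
            if data.size and (data.min() < 0 or data.max() > 255):
                raise ValidationError("DN8 bands must lie in [0, 255]")
        if self.units == "binary":
            data = self._valid_values()
            if not np.isin(data, (0, 1)).all():
                raise ValidationError("mask rasters may contain only {0, 1, nodata}")

    def _valid_values(self) -> np.ndarray:
        v = self.values
        if self.nodata is not None:
            if np.isnan(self.nodata):
                return v[~np.isnan(v)]
            return v[v != self.nodata]
        if np.issubdtype(v.dtype, np.floating):
            return v[~np.isnan(v)]
        return v

    # -- convenience -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[:2]

    @property
    def n_bands(self) -> int:
        return 1 if self.values.ndim == 2 else self.values.shape[2]

    def valid_mask(self) -> np.ndarray:
        """Boolean (h, w) array of pixels that are not nodata (any band)."""
        v = self.values
        if self.nodata is None:
            if np.issubdtype(v.dtype, np.floating):
                bad = np.isnan(v)
            else:
                return np.ones(self.shape, dtype=bool)
        elif np.isnan(self.nodata):
            bad = np.isnan(v)
        else:
            bad = v == self.nodata
        if bad.ndim == 3:
            bad = bad.any(axis=2)
        return ~bad


@dataclass
class PlotPolygon:
    """One experimental plot's footprint in world coordinates."""

    plot_id: str
    ring: Polygon
    area_m2: float = 0.0

    def __post_init__(self):
        if not isinstance(self.ring, Polygon):
            self.ring = Polygon(self.ring)
        if not self.ring.is_valid or not self.ring.is_simple:
            raise ValidationError(f"plot {self.plot_id}: ring must be simple")
        if self.ring.area <= 0:
            raise ValidationError(f"plot {self.plot_id}: area must be positive")
        if not self.area_m2:
            self.area_m2 = float(self.ring.area)


@dataclass
class PlotRecord:
    """Treatment metadata and ground measurements for one plot.

    ``measured_H`` is plant height in cm, ``measured_CC`` canopy coverage as a
    fraction, ``measured_PNC`` plant nitrogen content in % of dry mass.
    """

    plot_id: str
    zone: str
    level: str
    variety: str
    replication: int
    measured_H: float | None = None
    measured_CC: float | None = None
    measured_PNC: float | None = None

    def __post_init__(self):
        if self.zone not in ZONES:
            raise ValidationError(f"plot {self.plot_id}: unknown zone {self.zone!r}")
        if self.level not in _LEVELS[self.zone]:
            raise ValidationError(
                f"plot {self.plot_id}: level {self.level!r} not valid for zone {self.zone!r}"
            )
        if self.variety not in VARIETIES:
            raise ValidationError(f"plot {self.plot_id}: unknown variety {self.variety!r}")
        if self.replication not in (1, 2, 3):
            raise ValidationError(f"plot {self.plot_id}: replication must be in {{1,2,3}}")
        if self.measured_CC is not None and not 0.0 <= self.measured_CC <= 1.0:
            raise ValidationError(f"plot {self.plot_id}: measured_CC must lie in [0, 1]")
        if self.measured_PNC is not None and self.measured_PNC <= 0:
            raise ValidationError(f"plot {self.plot_id}: measured_PNC must be positive")


# ---------------------------------------------------------------------------
# raster I/O
# ---------------------------------------------------------------------------

_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GDAL_NODATA = 42113


def _meta_description(grid: RasterGrid) -> str:
    return json.dumps(
        {
            "uavpheno": 1,
            "units": grid.units,
            "nodata": None if grid.nodata is None else repr(float(grid.nodata)),
            "transform": [repr(float(t)) for t in grid.transform],
        }
    )


def write_raster(grid: RasterGrid, path: str | Path) -> Path:
    """Write a grid to GeoTIFF (``.tif``/``.tiff``) or PNG + ``.wld`` sidecar.

    Round trip through :func:`read_raster` reproduces integer values
    bit-exactly and the affine to 1e-9.
    """
    import tifffile

    grid.validate()
    path = Path(path)
    t = grid.transform
    if path.suffix.lower() in (".tif", ".tiff"):
        extratags = []
        if t.b == 0 and t.d == 0:
            # GeoTIFF ties the raster point (0,0) to the *corner* of the
            # top-left pixel; our transform addresses pixel centers.
            corner_x = t.c - t.a / 2.0
            corner_y = t.f - t.e / 2.0
            extratags.append((_MODEL_PIXEL_SCALE, "d", 3, (abs(t.a), abs(t.e), 0.0)))
            extratags.append((_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, corner_x, corner_y, 0.0)))
        if grid.nodata is not None:
            nd = repr(float(grid.nodata)) + "\x00"
            extratags.append((_GDAL_NODATA, "s", len(nd), nd))
        photometric = "rgb" if grid.n_bands == 3 else "minisblack"
        tifffile.imwrite(
            path,
            grid.values,
            photometric=photometric,
            description=_meta_description(grid),
            extratags=extratags,
        )
    elif path.suffix.lower() == ".png":
        import imageio.v3 as iio

        if grid.values.dtype != np.uint8:
            raise FormatError("PNG output supports uint8 values only")
        iio.imwrite(path, grid.values)
        wld = path.with_suffix(".wld")
        lines = [t.a, t.d, t.b, t.e, t.c, t.f]
        wld.write_text("".join(f"{v!r}\n" for v in lines))
        meta = path.with_suffix(".json")
        meta.write_text(_meta_description(grid))
    else:
        raise FormatError(f"unsupported raster extension: {path.suffix!r}")
    return path


def _parse_meta(desc: str | None) -> dict | None:
    if not desc:
        return None
    try:
        meta = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        return None
    if not isinstance(meta, dict) or "uavpheno" not in meta:
        return None
    return meta


def read_raster(path: str | Path) -> RasterGrid:
    """Read a GeoTIFF or PNG(+``.wld``) raster into a :class:`RasterGrid`."""
    import tifffile

    path = Path(path)
    if not path.exists():
        raise FormatError(f"raster file not found: {path}")

    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            values = page.asarray()
            if values.ndim == 3 and values.shape[2] not in (1, 3):
                raise FormatError(f"{path}: band count {values.shape[2]} not in {{1, 3}}")
            desc = page.description
            meta = _parse_meta(desc)
            transform = None
            nodata = None
            units = None
            if meta is not None:
                transform = Affine(*(float(v) for v in meta["transform"]))
                nodata = None if meta["nodata"] is None else float(meta["nodata"])
                units = meta["units"]
            else:
                scale_tag = page.tags.get(_MODEL_PIXEL_SCALE)
                tie_tag = page.tags.get(_MODEL_TIEPOINT)
                if scale_tag is not None and tie_tag is not None:
                    sx, sy = float(scale_tag.value[0]), float(scale_tag.value[1])
                    tx, ty = float(tie_tag.value[3]), float(tie_tag.value[4])
                    transform = Affine(sx, 0.0, tx + sx / 2.0, 0.0, -sy, ty - sy / 2.0)
                nd_tag = page.tags.get(_GDAL_NODATA)
                if nd_tag is not None:
                    nodata = float(str(nd_tag.value).strip("\x00 "))
            if transform is None:
                raise FormatError(f"{path}: no readable affine georeference")
    elif path.suffix.lower() == ".png":
        import imageio.v3 as iio

        values = np.asarray(iio.imread(path))
        wld = path.with_suffix(".wld")
        if not wld.exists():
            raise FormatError(f"{path}: PNG raster requires a .wld sidecar")
        nums = [float(s) for s in wld.read_text().split()]
        if len(nums) != 6:
            raise FormatError(f"{wld}: world file must contain 6 numbers")
        a, d, b, e, c, f = nums
        transform = Affine(a, b, c, d, e, f)
        meta = _parse_meta(path.with_suffix(".json").read_text()) if path.with_suffix(".json").exists() else None
        nodata = None if meta is None or meta["nodata"] is None else float(meta["nodata"])
        units = meta["units"] if meta is not None else None
    else:
        raise FormatError(f"unsupported raster extension: {path.suffix!r}")

    if values.ndim == 3 and values.shape[2] not in (1, 3):
        raise FormatError(f"{path}: band count {values.shape[2]} not in {{1, 3}}")
    if values.ndim == 3 and values.shape[2] == 1:
        values = values[:, :, 0]
    if values.ndim not in (2, 3):
        raise FormatError(f"{path}: unsupported array dimensionality {values.ndim}")

    if units is None:
        units = "DN8" if values.dtype == np.uint8 else "unknown"
    return RasterGrid(values=values, transform=transform, nodata=nodata, units=units)


# ---------------------------------------------------------------------------
# plot vector I/O
# ---------------------------------------------------------------------------

_REQUIRED_PROPS = ("plot_id", "zone", "level", "variety", "replication")


def write_plots(plots: Sequence[tuple[PlotPolygon, PlotRecord]], path: str | Path) -> Path:
    """Write plots as a GeoJSON FeatureCollection."""
    path = Path(path)
    features = []
    for poly, rec in plots:
        props = {
            "plot_id": rec.plot_id,
            "zone": rec.zone,
            "level": rec.level,
            "variety": rec.variety,
            "replication": rec.replication,
            "area_m2": poly.area_m2,
        }
        for key in ("measured_H", "measured_CC", "measured_PNC"):
            val = getattr(rec, key)
            if val is not None:
                props[key] = val
        features.append(
            {"type": "Feature", "geometry": shapely_mapping(poly.ring), "properties": props}
        )
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}, indent=1))
    return path


def read_plots(path: str | Path) -> list[tuple[PlotPolygon, PlotRecord]]:
    """Read a GeoJSON FeatureCollection of plots; enforces all invariants."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"plot file not found: {path}")
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    if doc.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")

    out: list[tuple[PlotPolygon, PlotRecord]] = []
    seen: set[str] = set()
    for i, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties", {})
        for key in _REQUIRED_PROPS:
            if key not in props:
                raise ValidationError(f"feature {i}: missing required property {key!r}")
        pid = str(props["plot_id"])
        if pid in seen:
            raise ValidationError(f"duplicate plot_id {pid!r}")
        seen.add(pid)
        geom = shapely_shape(feat["geometry"])
        if not isinstance(geom, Polygon):
            raise ValidationError(f"plot {pid}: geometry must be a Polygon")
        poly = PlotPolygon(plot_id=pid, ring=geom, area_m2=float(props.get("area_m2", 0.0)))
        rec = PlotRecord(
            plot_id=pid,
            zone=props["zone"],
            level=props["level"],
            variety=props["variety"],
            replication=int(props["replication"]),
            measured_H=props.get("measured_H"),
            measured_CC=props.get("measured_CC"),
            measured_PNC=props.get("measured_PNC"),
        )
        out.append((poly, rec))
    return out


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


def rasterize_plot(polygon: PlotPolygon | Polygon, grid: RasterGrid) -> np.ndarray:
    """Pixels of ``grid`` whose center falls strictly inside the plot ring.

    Returns an ``(n, 2)`` integer array of ``(row, col)`` pairs, sorted
    row-major, and warns (without raising) if the intersection is empty.
    """
    ring = polygon.ring if isinstance(polygon, PlotPolygon) else polygon
    h, w = grid.shape
    # candidate window from the polygon bounds mapped to pixel space
    minx, miny, maxx, maxy = ring.bounds
    corners_x = np.array([minx, minx, maxx, maxx])
    corners_y = np.array([miny, maxy, miny, maxy])
    cols, rows = grid.transform.colrow(corners_x, corners_y)
    c0 = max(0, int(math.floor(cols.min())) - 1)
    c1 = min(w - 1, int(math.ceil(cols.max())) + 1)
    r0 = max(0, int(math.floor(rows.min())) - 1)
    r1 = min(h - 1, int(math.ceil(rows.max())) + 1)
    if c1 < c0 or r1 < r0:
        warnings.warn("plot polygon intersects no pixel centers", EmptyRegionWarning)
        return np.empty((0, 2), dtype=np.intp)

    cc, rr = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    xs, ys = grid.transform.xy(cc.ravel(), rr.ravel())
    inside = shapely.contains_xy(ring, xs, ys)
    if not inside.any():
        warnings.warn("plot polygon intersects no pixel centers", EmptyRegionWarning)
        return np.empty((0, 2), dtype=np.intp)
    out = np.column_stack([rr.ravel()[inside], cc.ravel()[inside]])
    order = np.lexsort((out[:, 1], out[:, 0]))
    return out[order]
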