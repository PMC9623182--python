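"""Visible-light vegetation indices and plot-level aggregation.

All chromaticity-based indices operate on the normalized coordinates
r = R/(R+G+B), g = G/(R+G+B), b = B/(R+G+B), which removes overall
brightness.  The registry holds exactly ten indices; R, G and B return the
raw digital-number band.

Note on GLA: it is implemented as ``(2g - r + b) / (2g + r + b)``, which
differs from GLI only in the sign of one numerator term.  Both forms are
kept as distinct registry entries rather than collapsed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyRegionWarning, ValidationError
from .raster import PlotPolygon, RasterGrid, rasterize_plot

__all__ = [
    "INDEX_ORDER",
    "VI_NAMES",
    "ChromaticityImage",
    "normalize_chromaticity",
    "compute_index",
    "plot_index_means",
    "feature_table",
]

#: Registry order; also the tie-break order for feature selection.
INDEX_ORDER = ("R", "G", "B", "GRRI", "GLA", "GLI", "GRVI", "VARI", "EXG", "NDI")
VI_NAMES = INDEX_ORDER

_EPS = 1e-12


@dataclass
class ChromaticityImage:
    """Per-pixel normalized (r, g, b) with a validity mask.

    Invalid pixels (band sum 0, or nodata in the source) carry 0 in all
    three coordinates and False in ``valid`` -- no NaN is emitted.
    """

    r: np.ndarray
    g: np.ndarray
    b: np.ndarray
    valid: np.ndarray


def normalize_chromaticity(rgb: RasterGrid) -> ChromaticityImage:
    """Normalize a 3-band DN raster to chromaticity coordinates."""
    if rgb.n_bands != 3:
        raise ValidationError(f"chromaticity requires a 3-band raster, got {rgb.n_bands} band(s)")
    v = rgb.values.astype(float)
    total = v.sum(axis=2)
    valid = rgb.valid_mask() & (total > 0)
    safe = np.where(total > 0, total, 1.0)
    r = np.where(valid, v[:, :, 0] / safe, 0.0)
    g = np.where(valid, v[:, :, 1] / safe, 0.0)
    b = np.where(valid, v[:, :, 2] / safe, 0.0)
    return ChromaticityImage(r=r, g=g, b=b, valid=valid)


def _index_values(name: str, chroma: ChromaticityImage) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate one chromaticity-based index; returns (values, valid)."""
    r, g, b = chroma.r, chroma.g, chroma.b
    valid = chroma.valid.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        if name == "GRRI":
            den = g
            out = np.where(np.abs(den) > _EPS, r / np.where(den == 0, 1, den), 0.0)
            valid &= np.abs(den) > _EPS
        elif name == "GLA":
            out = (2 * g - r + b) / (2 * g + r + b)
        elif name == "GLI":
            out = (2 * g - r - b) / (2 * g + r + b)
        elif name == "GRVI":
            den = g + r
            out = np.where(np.abs(den) > _EPS, (g - r) / np.where(den == 0, 1, den), 0.0)
            valid &= np.abs(den) > _EPS
        elif name == "VARI":
            den = g + r - b
            out = np.where(np.abs(den) > _EPS, (g - r) / np.where(np.abs(den) <= _EPS, 1, den), 0.0)
            valid &= np.abs(den) > _EPS
        elif name == "EXG":
            out = 2 * g - b - r
        elif name == "NDI":
            out = (r - g) / (r + g + 0.01)
        else:  # pragma: no cover - guarded by compute_index
            raise ValidationError(f"unknown index {name!r}")
    return out, valid


def compute_index(name: str, rgb: RasterGrid) -> RasterGrid:
    """Compute one registered index as a float raster (NaN where invalid).

    ``R``/``G``/``B`` return the raw band in DN; the remaining indices are
    evaluated per pixel on normalized chromaticities, with denominator-zero
    pixels (e.g. VARI where g + r = b) marked invalid.
    """
    if name not in INDEX_ORDER:
        raise ValidationError(f"unknown index {name!r}; registry: {INDEX_ORDER}")
    if rgb.n_bands != 3:
        raise ValidationError("index computation requires a 3-band raster")
    if name in ("R", "G", "B"):
        band = {"R": 0, "G": 1, "B": 2}[name]
        out = rgb.values[:, :, band].astype(float)
        out[~rgb.valid_mask()] = np.nan
        return RasterGrid(values=out, transform=rgb.transform, nodata=np.nan, units="DN")
    chroma = normalize_chromaticity(rgb)
    out, valid = _index_values(name, chroma)
    out = np.where(valid, out, np.nan)
    return RasterGrid(values=out, transform=rgb.transform, nodata=np.nan, units="index")


def plot_index_means(
    index: RasterGrid,
    plots: list[tuple[PlotPolygon, object]] | list[PlotPolygon],
    mask: RasterGrid | None = None,
) -> pd.DataFrame:
    """Mean index value over each plot's valid pixels.

    If ``mask`` is given (a {0,1} vegetation raster co-registered with the
    index), the mean is restricted to vegetation pixels.  Plots with no
    valid pixel get NaN and a warning.  Returns columns
    ``plot_id, mean, valid_px``.
    """
    if mask is not None and mask.shape != index.shape:
        raise ValidationError("mask and index rasters must share a shape")
    rows = []
    for item in plots:
        poly = item[0] if isinstance(item, tuple) else item
        pix = rasterize_plot(poly, index)
        vals = index.values[pix[:, 0], pix[:, 1]] if len(pix) else np.empty(0)
        keep = ~np.isnan(vals)
        if mask is not None and len(pix):
            keep &= mask.values[pix[:, 0], pix[:, 1]] == 1
        n_valid = int(keep.sum())
        if n_valid == 0:
            warnings.warn(f"plot {poly.plot_id}: no valid pixels for index mean", EmptyRegionWarning)
            rows.append((poly.plot_id, np.nan, 0))
        else:
            rows.append((poly.plot_id, float(vals[keep].mean()), n_valid))
    return pd.DataFrame(rows, columns=["plot_id", "mean", "valid_px"])


def feature_table(
    dom: RasterGrid,
    plots: list[tuple[PlotPolygon, object]],
    stage: str,
    mask: RasterGrid | None = None,
) -> pd.DataFrame:
    """Per-plot means of all ten indices for one stage.

    Columns: ``plot_id, stage, R, G, B, GRRI, GLA, GLI, GRVI, VARI, EXG,
    NDI, valid_px`` (one row per plot, fixed column order).
    """
    out: pd.DataFrame | None = None
    for name in INDEX_ORDER:
        grid = compute_index(name, dom)
        means = plot_index_means(grid, plots, mask=mask).rename(columns={"mean": name})
        if out is None:
            out = means[["plot_id", name, "valid_px"]]
        else:
            out = out.drop(columns="valid_px").merge(
                means[["plot_id", name, "valid_px"]], on="plot_id"
            )
    assert out is not None
    out.insert(1, "stage", stage)
    return out[["plot_id", "stage", *INDEX_ORDER, "valid_px"]]
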