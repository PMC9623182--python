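"""Vegetation segmentation and canopy morphological parameters.

Plant height H comes from canopy-height-model (CHM) differencing:
``CHM = DSM_stage - DSM_bare`` with negative values clamped to zero (they
are physically meaningless and arise from DSM noise).  Canopy coverage CC
is the fraction of a region's pixels classified as vegetation, either from
the orthomosaic (excess-green index + maximum inter-class-variance
threshold) or from nadir ground photos (HSI hue pre-filter, excess-green
threshold, then a connected-component area filter; the ground-photo route
serves as the measured reference).  Canopy volume is the product CV = CC * H.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import (
    DegenerateInputError,
    DegenerateSceneWarning,
    EmptyMaskWarning,
    ValidationError,
)
from .indices import compute_index
from .raster import PlotPolygon, RasterGrid, rasterize_plot

__all__ = [
    "HSIImage",
    "MorphologicalFeatures",
    "otsu_threshold",
    "segment_vegetation_uav",
    "rgb_to_hsi",
    "vcea_ground_mask",
    "coverage_from_mask",
    "canopy_height_model",
    "plot_height",
    "canopy_volume",
    "morphological_features",
]

FRAME_NODATA = 255  # sentinel marking white-frame pixels in ground-photo masks


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------


def otsu_threshold(values: np.ndarray, bins: int = 256) -> float:
    """Maximum inter-class-variance threshold over a 256-bin histogram.

    The histogram spans the input range; every cut between adjacent bins is
    scored by the between-class variance ``w0 * w1 * (mu0 - mu1)^2`` and the
    smallest maximizing cut wins (deterministic tie-break).  The returned
    threshold is the bin edge of that cut; classification is
    ``value > threshold -> foreground``.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise DegenerateInputError("otsu_threshold needs at least 2 finite values")
    vmin, vmax = float(v.min()), float(v.max())
    if vmin == vmax:
        raise DegenerateInputError("otsu_threshold is undefined on constant input")
    hist, edges = np.histogram(v, bins=bins, range=(vmin, vmax))
    p = hist.astype(float) / hist.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0
    w0 = np.cumsum(p)[:-1]  # cut after bin t, t = 0..bins-2
    w1 = 1.0 - w0
    m0 = np.cumsum(p * centers)[:-1]
    m_total = float((p * centers).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = np.where(w0 > 0, m0 / w0, 0.0)
        mu1 = np.where(w1 > 0, (m_total - m0) / w1, 0.0)
    bcv = w0 * w1 * (mu0 - mu1) ** 2
    # smallest maximizer; ties (e.g. plateaus across empty bins) resolved
    # with a relative tolerance so float round-off cannot shift the cut
    best = float(bcv.max())
    t = int(np.argmax(bcv >= best - 1e-9 * max(1.0, abs(best))))
    return float(edges[t + 1])


def segment_vegetation_uav(dom: RasterGrid, degenerate: str = "warn") -> RasterGrid:
    """Segment vegetation on an orthomosaic via excess green + Otsu.

    EXG is computed on chromaticities, a single global threshold is taken by
    maximum inter-class variance, and the mask is ``EXG > threshold``.  On a
    scene without contrast (constant EXG, e.g. bare soil rendered without
    noise) the result depends on ``degenerate``: ``"warn"`` returns an
    all-zero mask with a :class:`DegenerateSceneWarning`, ``"raise"``
    propagates :class:`DegenerateInputError`.
    """
    exg = compute_index("EXG", dom)
    finite = exg.values[np.isfinite(exg.values)]
    try:
        thr = otsu_threshold(finite)
    except DegenerateInputError:
        if degenerate == "raise":
            raise
        warnings.warn(
            "scene has no EXG contrast; returning an empty vegetation mask",
            DegenerateSceneWarning,
        )
        mask = np.zeros(dom.shape, dtype=np.uint8)
        return RasterGrid(values=mask, transform=dom.transform, units="binary")
    mask = (exg.values > thr).astype(np.uint8)
    mask[~np.isfinite(exg.values)] = 0
    return RasterGrid(values=mask, transform=dom.transform, units="binary")


# ---------------------------------------------------------------------------
# HSI color space and the ground-photo coverage algorithm
# ---------------------------------------------------------------------------


@dataclass
class HSIImage:
    """Hue (degrees, [0, 360)), saturation and intensity in [0, 1].

    ``hue_valid`` is False where hue is geometrically undefined (gray
    pixels, saturation 0)."""

    hue: np.ndarray
    saturation: np.ndarray
    intensity: np.ndarray
    hue_valid: np.ndarray


def rgb_to_hsi(rgb: RasterGrid) -> HSIImage:
    """Standard geometric RGB -> HSI conversion.

    I = (R+G+B) / (3*255); S = 1 - min(R,G,B)/mean(R,G,B) (0 for black);
    hue from the arccos formulation, reflected to (180, 360) where B > G.
    """
    if rgb.n_bands != 3:
        raise ValidationError("HSI conversion requires a 3-band image")
    v = rgb.values.astype(float)
    R, G, B = v[:, :, 0], v[:, :, 1], v[:, :, 2]
    total = R + G + B
    intensity = total / (3.0 * 255.0)
    mn = np.minimum(np.minimum(R, G), B)
    with np.errstate(divide="ignore", invalid="ignore"):
        saturation = np.where(total > 0, 1.0 - 3.0 * mn / np.where(total > 0, total, 1.0), 0.0)
    num = 0.5 * ((R - G) + (R - B))
    den = np.sqrt((R - G) ** 2 + (R - B) * (G - B))
    hue_valid = (den > 0) & (saturation > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cosang = np.clip(np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0), -1.0, 1.0)
    theta = np.degrees(np.arccos(cosang))
    hue = np.where(B > G, 360.0 - theta, theta)
    hue = np.where(hue_valid, hue, 0.0)
    return HSIImage(hue=hue, saturation=saturation, intensity=intensity, hue_valid=hue_valid)


def vcea_ground_mask(
    photo: RasterGrid,
    hue_window: tuple[float, float] = (60.0, 180.0),
    sat_floor: float = 0.1,
    min_area: int = 25,
    frame_intensity: float = 0.85,
    frame_max_sat: float = 0.15,
) -> RasterGrid:
    """Vegetation mask of a white-box ground photo.

    Three stages: (1) candidate pixels whose hue lies in the green window
    and whose saturation clears a small floor; (2) excess-green thresholded
    by maximum inter-class variance (the threshold is taken over the whole
    box interior so the histogram retains its soil/vegetation bimodality);
    (3) connected components smaller than ``min_area`` pixels removed (the
    morphological threshold).  Near-white frame pixels are excluded and
    marked nodata in the returned {0, 1} mask.
    """
    hsi = rgb_to_hsi(photo)
    frame = (hsi.intensity > frame_intensity) & (hsi.saturation < frame_max_sat)
    interior = ~frame

    candidates = (
        interior
        & hsi.hue_valid
        & (hsi.hue >= hue_window[0])
        & (hsi.hue <= hue_window[1])
        & (hsi.saturation >= sat_floor)
    )
    mask = np.zeros(photo.shape, dtype=np.uint8)
    if not candidates.any():
        warnings.warn("no vegetation-candidate pixels in ground photo", EmptyMaskWarning)
    else:
        exg = compute_index("EXG", photo).values
        exg_interior = exg[interior & np.isfinite(exg)]
        try:
            thr = otsu_threshold(exg_interior)
            mask[candidates & (exg > thr)] = 1
        except DegenerateInputError:
            warnings.warn("ground photo has no EXG contrast", DegenerateSceneWarning)
        labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
        if n:
            sizes = ndimage.sum_labels(np.ones_like(mask), labels, index=np.arange(1, n + 1))
            small = np.flatnonzero(sizes < min_area) + 1
            mask[np.isin(labels, small)] = 0
    mask_f = mask.astype(np.uint8)
    mask_f[frame] = FRAME_NODATA
    return RasterGrid(values=mask_f, transform=photo.transform, nodata=FRAME_NODATA, units="binary")


def coverage_from_mask(mask: RasterGrid, region: PlotPolygon | None = None) -> float:
    """Canopy coverage: vegetation pixels / valid pixels of the region.

    ``region=None`` uses the whole raster (e.g. a ground-photo box interior,
    with frame pixels excluded through nodata)."""
    if region is not None:
        pix = rasterize_plot(region, mask)
        vals = mask.values[pix[:, 0], pix[:, 1]] if len(pix) else np.empty(0)
    else:
        vals = mask.values.ravel()
    if mask.nodata is not None:
        vals = vals[vals != mask.nodata]
    if vals.size == 0:
        raise DegenerateInputError("coverage undefined: region has zero valid pixels")
    return float((vals == 1).sum() / vals.size)


# ---------------------------------------------------------------------------
# canopy height model and derived parameters
# ---------------------------------------------------------------------------


def canopy_height_model(dsm_stage: RasterGrid, dsm_bare: RasterGrid) -> RasterGrid:
    """CHM = DSM_stage - DSM_bare, clamped below at 0, in metres."""
    if dsm_stage.shape != dsm_bare.shape:
        raise ValidationError("DSM rasters must share a shape")
    if not np.allclose(dsm_stage.transform, dsm_bare.transform, atol=1e-9):
        raise ValidationError("DSM rasters must share a transform")
    chm = np.clip(dsm_stage.values.astype(float) - dsm_bare.values.astype(float), 0.0, None)
    bad = ~(dsm_stage.valid_mask() & dsm_bare.valid_mask())
    if bad.any():
        chm[bad] = np.nan
    return RasterGrid(values=chm, transform=dsm_stage.transform, nodata=np.nan, units="m")


def plot_height(
    chm: RasterGrid,
    plot: PlotPolygon,
    mask: RasterGrid | None = None,
    stat: str = "mean",
) -> float:
    """Average CHM over a plot's vegetation pixels, in cm.

    Falls back to the all-pixel average (with a warning) when the
    vegetation mask is empty inside the plot.  ``stat`` is ``"mean"`` or
    ``"p90"`` (90th percentile, for sensitivity analysis).
    """
    if stat not in ("mean", "p90"):
        raise ValidationError(f"stat must be 'mean' or 'p90', got {stat!r}")
    pix = rasterize_plot(plot, chm)
    if len(pix) == 0:
        raise DegenerateInputError(f"plot {plot.plot_id}: no pixels in CHM extent")
    vals = chm.values[pix[:, 0], pix[:, 1]]
    keep = np.isfinite(vals)
    if mask is not None:
        veg = mask.values[pix[:, 0], pix[:, 1]] == 1
        if not (veg & keep).any():
            warnings.warn(
                f"plot {plot.plot_id}: empty vegetation mask, averaging all pixels",
                EmptyMaskWarning,
            )
        else:
            keep &= veg
    if not keep.any():
        raise DegenerateInputError(f"plot {plot.plot_id}: no valid CHM pixels")
    sel = vals[keep]
    h_m = float(np.percentile(sel, 90)) if stat == "p90" else float(sel.mean())
    return h_m * 100.0


def canopy_volume(cc: float, h: float) -> float:
    """Canopy volume CV = CC * H (units of H, cm here)."""
    if not 0.0 <= cc <= 1.0:
        raise ValidationError(f"CC must lie in [0, 1], got {cc}")
    if h < 0:
        raise ValidationError(f"H must be non-negative, got {h}")
    return cc * h


@dataclass
class MorphologicalFeatures:
    """Per-plot canopy descriptors for one stage."""

    plot_id: str
    stage: str
    H: float  # cm
    CC: float  # fraction
    CV: float  # cm (coverage-weighted height)

    def __post_init__(self):
        if not 0.0 <= self.CC <= 1.0:
            raise ValidationError(f"plot {self.plot_id}: CC out of [0, 1]")
        if self.H < 0:
            raise ValidationError(f"plot {self.plot_id}: negative H")
        if abs(self.CV - self.CC * self.H) > 1e-9:
            raise ValidationError(f"plot {self.plot_id}: CV != CC * H")


def morphological_features(
    chm: RasterGrid,
    mask: RasterGrid,
    plots: list[tuple[PlotPolygon, object]],
    stage: str,
    height_stat: str = "mean",
) -> pd.DataFrame:
    """Extract H (cm), CC and CV for every plot of one stage.

    Returns a DataFrame with columns ``plot_id, stage, H_cm, CC, CV``.
    """
    rows = []
    for item in plots:
        poly = item[0] if isinstance(item, tuple) else item
        cc = coverage_from_mask(mask, region=poly)
        h = plot_height(chm, poly, mask=mask, stat=height_stat)
        feats = MorphologicalFeatures(plot_id=poly.plot_id, stage=stage, H=h, CC=cc, CV=canopy_volume(cc, h))
        rows.append((feats.plot_id, feats.stage, feats.H, feats.CC, feats.CV))
    return pd.DataFrame(rows, columns=["plot_id", "stage", "H_cm", "CC", "CV"])
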