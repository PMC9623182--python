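"""Synthetic field scenes for end-to-end testing of the phenotyping pipeline.

The generator emulates a 48-plot potato trial: a plant-density zone
(3 levels x 2 varieties x 3 replicates = 18 plots), a nitrogen zone
(4 levels x 2 varieties x 3 replicates = 24 plots) and a potassium zone
(2 levels x 1 variety x 3 replicates = 6 plots), each plot 32.5 m^2.
Per-plot ground truth (plant nitrogen content PNC in % dry mass, plant
height H in cm, canopy coverage CC as a fraction) is sampled with a
stage-dependent correlation structure: H and CC are linear in PNC with
independent noise, with the PNC coupling weakening from tuber formation
(S1) to starch accumulation (S3), while every vegetation pixel's green
chromaticity increases affinely with its plot's PNC, so a recoverable
index-PNC signal exists by construction.

Rendered products mirror a photogrammetric workflow's outputs: an RGB
orthomosaic (DOM), a digital surface model (DSM) in metres, the renderer's
own vegetation mask (the recovery oracle), and nadir ground photos framed
by a 1.3 m white box.  Canopy coverage is enforced by construction -- plant
disks are packed until the plot's vegetation-pixel count equals the target
exactly, and the stored truth is read back off the final mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .errors import PackingError, ValidationError
from .raster import Affine, PlotPolygon, PlotRecord, RasterGrid, rasterize_plot

__all__ = [
    "DesignConfig",
    "StageParams",
    "StageCoupling",
    "SceneConfig",
    "SceneTruth",
    "STAGES",
    "STAGE_DEFAULTS",
    "COUPLING_DEFAULTS",
    "DEFAULT_MASTER_SEED",
    "generate_design",
    "sample_truth",
    "render_scene",
    "render_bare_scene",
    "render_ground_photo",
    "linear_pnc_benchmark",
]

STAGES = ("S1", "S2", "S3")
DEFAULT_MASTER_SEED = 20190418
FRAME_SENTINEL = 255  # nodata marking white-frame pixels in photo masks


# ---------------------------------------------------------------------------
# experimental design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DesignConfig:
    """Factor structure and plot geometry of the trial."""

    density_levels: tuple[str, ...] = ("T0", "T1", "T2")
    nitrogen_levels: tuple[str, ...] = ("N0", "N1", "N2", "N3")
    potassium_levels: tuple[str, ...] = ("K0", "K2")
    varieties: tuple[str, ...] = ("Z3", "Z5")
    potassium_variety: str = "Z3"
    replications: int = 3
    plot_width_m: float = 6.5
    plot_depth_m: float = 5.0  # 6.5 x 5.0 = 32.5 m^2
    gap_m: float = 1.0
    n_cols: int = 8

    @property
    def plot_area_m2(self) -> float:
        return self.plot_width_m * self.plot_depth_m


def generate_design(config: DesignConfig | None = None) -> list[tuple[PlotPolygon, PlotRecord]]:
    """Lay the fully crossed design on a rectangular plot grid.

    Deterministic: plot order is density zone, then nitrogen, then potassium,
    each enumerated level-major, then variety, then replication.  Plot ids
    are ``s01``, ``s02``, ... in that order.
    """
    config = config or DesignConfig()
    combos: list[tuple[str, str, str, int]] = []
    for level in config.density_levels:
        for variety in config.varieties:
            for rep in range(1, config.replications + 1):
                combos.append(("density", level, variety, rep))
    for level in config.nitrogen_levels:
        for variety in config.varieties:
            for rep in range(1, config.replications + 1):
                combos.append(("nitrogen", level, variety, rep))
    for level in config.potassium_levels:
        for rep in range(1, config.replications + 1):
            combos.append(("potassium", level, config.potassium_variety, rep))

    out: list[tuple[PlotPolygon, PlotRecord]] = []
    pitch_x = config.plot_width_m + config.gap_m
    pitch_y = config.plot_depth_m + config.gap_m
    for i, (zone, level, variety, rep) in enumerate(combos):
        gcol, grow = i % config.n_cols, i // config.n_cols
        x0, y0 = gcol * pitch_x, -grow * pitch_y
        ring = Polygon(
            [
                (x0, y0),
                (x0 + config.plot_width_m, y0),
                (x0 + config.plot_width_m, y0 - config.plot_depth_m),
                (x0, y0 - config.plot_depth_m),
            ]
        )
        pid = f"s{i + 1:02d}"
        out.append(
            (
                PlotPolygon(plot_id=pid, ring=ring),
                PlotRecord(plot_id=pid, zone=zone, level=level, variety=variety, replication=rep),
            )
        )
    return out


# ---------------------------------------------------------------------------
# ground truth sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StageParams:
    """Per-stage value envelopes: (min, max, mean, sd) for H (cm) and PNC
    (% dry mass), and (mean, sd, lo, hi) for canopy coverage."""

    h: tuple[float, float, float, float]
    pnc: tuple[float, float, float, float]
    cc: tuple[float, float, float, float]


# H and PNC envelopes follow the trial's per-stage summary statistics;
# coverage envelopes follow the observed per-stage concentration of CC
# (S1 mostly 0.6-0.8, S2/S3 mostly 0.4-0.8).
STAGE_DEFAULTS: dict[str, StageParams] = {
    "S1": StageParams(h=(20.38, 40.50, 30.29, 4.76), pnc=(2.09, 4.50, 3.21, 0.61), cc=(0.70, 0.05, 0.55, 0.85)),
    "S2": StageParams(h=(20.42, 40.88, 27.72, 5.20), pnc=(1.61, 4.00, 2.69, 0.58), cc=(0.60, 0.09, 0.40, 0.80)),
    "S3": StageParams(h=(15.12, 40.35, 25.78, 5.15), pnc=(1.86, 3.74, 2.94, 0.46), cc=(0.55, 0.09, 0.35, 0.78)),
}


@dataclass(frozen=True)
class StageCoupling:
    """Links between PNC and the observable scene.

    ``r_h`` / ``r_cc`` are the target Pearson correlations of H and CC with
    PNC; ``g_ref``/``g_slope`` define the vegetation green chromaticity
    g = g_ref + g_slope * (PNC - pnc_ref); ``yellow_shift`` moves chromaticity
    from green toward red to emulate senescence.
    """

    r_h: float = 0.7
    r_cc: float = 0.7
    g_ref: float = 0.46
    g_slope: float = 0.025
    pnc_ref: float = 3.0
    g_clip: tuple[float, float] = (0.40, 0.50)
    yellow_shift: float = 0.0

    def __post_init__(self):
        for name in ("r_h", "r_cc"):
            r = getattr(self, name)
            if not -1.0 <= r <= 1.0:
                raise ValidationError(f"coupling correlation {name}={r} outside [-1, 1]")


COUPLING_DEFAULTS: dict[str, StageCoupling] = {
    "S1": StageCoupling(r_h=0.7, r_cc=0.7),
    "S2": StageCoupling(r_h=0.6, r_cc=0.6),
    "S3": StageCoupling(r_h=0.5, r_cc=0.5, yellow_shift=0.035),
}

# Treatment effects on plant nitrogen status, as z-score offsets before
# standardization over the design.  Nitrogen supply raises PNC monotonically;
# higher planting density dilutes it through competition; potassium and
# variety have minor effects.
_LEVEL_OFFSETS = {
    "N0": -1.4, "N1": -0.45, "N2": 0.45, "N3": 1.3,
    "T0": 0.3, "T1": 0.0, "T2": -0.3,
    "K0": 0.05, "K1": 0.0, "K2": -0.05,
}
_VARIETY_OFFSETS = {"Z3": 0.1, "Z5": -0.1}
_TREATMENT_SHARE = 0.75  # fraction of PNC z-variance explained by treatment


@dataclass
class SceneTruth:
    """Generator-side ground truth for one growth stage."""

    stage: str
    design: list[tuple[PlotPolygon, PlotRecord]]
    plots: pd.DataFrame  # plot_id, zone, level, variety, replication, true_pnc, true_h_cm, true_cc
    coupling: StageCoupling
    dn_jitter_sd: float = 8.0
    dsm_noise_sd: float = 0.01
    plants: dict[str, np.ndarray] = field(default_factory=dict)  # plot_id -> (n, 3): x, y, radius_m

    def polygon(self, plot_id: str) -> PlotPolygon:
        for poly, rec in self.design:
            if rec.plot_id == plot_id:
                return poly
        raise KeyError(plot_id)


def sample_truth(
    design: Sequence[tuple[PlotPolygon, PlotRecord]],
    stage: str,
    coupling: StageCoupling | None = None,
    seed: int = DEFAULT_MASTER_SEED,
    *,
    stage_params: StageParams | None = None,
    dn_jitter_sd: float = 8.0,
    dsm_noise_sd: float = 0.01,
) -> SceneTruth:
    """Draw per-plot true PNC, H and CC for one stage.

    PNC is treatment-driven (standardized treatment scores plus Gaussian
    plot noise) and clipped to the stage envelope; H and CC are then drawn as
    ``z_x = r * z_pnc + sqrt(1 - r^2) * eps`` in population-standardized
    coordinates, so the target correlation ``r`` is realized up to clipping
    and sampling noise.  Reproducible for a given seed.
    """
    if stage not in STAGES:
        raise ValidationError(f"stage must be one of {STAGES}, got {stage!r}")
    coupling = coupling if coupling is not None else COUPLING_DEFAULTS[stage]
    params = stage_params or STAGE_DEFAULTS[stage]
    rng = np.random.default_rng(seed)

    recs = [rec for _, rec in design]
    n = len(recs)
    z_treat = np.array(
        [_LEVEL_OFFSETS[r.level] + _VARIETY_OFFSETS[r.variety] for r in recs], dtype=float
    )
    sd = z_treat.std()
    z_treat = (z_treat - z_treat.mean()) / sd if sd > 0 else np.zeros(n)

    w = _TREATMENT_SHARE
    z_pnc = w * z_treat + math.sqrt(1.0 - w * w) * rng.normal(size=n)
    p_min, p_max, p_mean, p_sd = params.pnc
    pnc = np.clip(p_mean + p_sd * z_pnc, p_min, p_max)
    z = (pnc - p_mean) / p_sd  # population standardization

    e_h, e_cc = rng.normal(size=(2, n))
    h_min, h_max, h_mean, h_sd = params.h
    zh = coupling.r_h * z + math.sqrt(1.0 - coupling.r_h**2) * e_h
    h = np.clip(h_mean + h_sd * zh, h_min, h_max)

    cc_mean, cc_sd, cc_lo, cc_hi = params.cc
    zc = coupling.r_cc * z + math.sqrt(1.0 - coupling.r_cc**2) * e_cc
    cc = np.clip(cc_mean + cc_sd * zc, cc_lo, cc_hi)

    plots = pd.DataFrame(
        {
            "plot_id": [r.plot_id for r in recs],
            "zone": [r.zone for r in recs],
            "level": [r.level for r in recs],
            "variety": [r.variety for r in recs],
            "replication": [r.replication for r in recs],
            "true_pnc": pnc,
            "true_h_cm": h,
            "true_cc": cc,
        }
    )
    return SceneTruth(
        stage=stage,
        design=list(design),
        plots=plots,
        coupling=coupling,
        dn_jitter_sd=dn_jitter_sd,
        dsm_noise_sd=dsm_noise_sd,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SceneConfig:
    """Radiometric and geometric parameters of the renderer.

    Chromaticities are (r, g, b) with r+g+b=1; brightness is the DN band sum,
    so DN = chromaticity * brightness before jitter and quantization.
    """

    gsd: float = 0.10  # orthomosaic ground sample distance, m/pixel
    margin_m: float = 1.0
    soil_chroma: tuple[float, float, float] = (0.45, 0.32, 0.23)
    soil_brightness: float = 300.0
    veg_brightness: float = 260.0
    veg_rb_split: float = 0.55  # red share of the non-green chromaticity
    disk_radius_m: tuple[float, float] = (0.20, 0.40)
    # bare-soil elevation surface (metres, deterministic in world coords)
    base_elevation: float = 36.0
    slope_x: float = -0.004
    slope_y: float = 0.002
    relief_amp: float = 0.05
    relief_wavelength: tuple[float, float] = (37.0, 23.0)
    weed_blob_radius_m: float = 0.25
    n_weed_blobs: int = 20


def _field_grid(design: Sequence[tuple[PlotPolygon, PlotRecord]], cfg: SceneConfig) -> tuple[tuple[int, int], Affine]:
    xs, ys = [], []
    for poly, _ in design:
        minx, miny, maxx, maxy = poly.ring.bounds
        xs += [minx, maxx]
        ys += [miny, maxy]
    x_lo, x_hi = min(xs) - cfg.margin_m, max(xs) + cfg.margin_m
    y_lo, y_hi = min(ys) - cfg.margin_m, max(ys) + cfg.margin_m
    w = int(round((x_hi - x_lo) / cfg.gsd))
    h = int(round((y_hi - y_lo) / cfg.gsd))
    transform = Affine.north_up(x_lo + cfg.gsd / 2.0, y_hi - cfg.gsd / 2.0, cfg.gsd)
    return (h, w), transform


def _bare_surface(xs: np.ndarray, ys: np.ndarray, cfg: SceneConfig) -> np.ndarray:
    lx, ly = cfg.relief_wavelength
    return (
        cfg.base_elevation
        + cfg.slope_x * xs
        + cfg.slope_y * ys
        + cfg.relief_amp * np.sin(2 * np.pi * xs / lx) * np.cos(2 * np.pi * ys / ly)
    )


def _veg_chroma(pnc: float, coupling: StageCoupling, split: float) -> tuple[float, float, float]:
    g = coupling.g_ref + coupling.g_slope * (pnc - coupling.pnc_ref)
    g = float(np.clip(g, *coupling.g_clip))
    rest = 1.0 - g
    r = rest * split
    b = rest * (1.0 - split)
    # senescence moves chromaticity mass from green to red; the sum stays 1
    return r + coupling.yellow_shift, g - coupling.yellow_shift, b


def _pack_disks(
    centers_xy: np.ndarray,
    bounds: tuple[float, float, float, float],
    target: int,
    rng: np.random.Generator,
    radius_range: tuple[float, float],
    max_disks: int = 100_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Cover exactly ``target`` of the given pixel centers with random disks.

    Returns (boolean cover array aligned with ``centers_xy``, (n, 3) array of
    disk x, y, radius).  The last disk is trimmed to its pixels closest to
    its center so the covered count equals ``target`` exactly.
    """
    n_px = len(centers_xy)
    if target > 0.99 * n_px:
        raise PackingError(f"requested coverage {target}/{n_px} exceeds the packable fraction 0.99")
    covered = np.zeros(n_px, dtype=bool)
    disks: list[tuple[float, float, float]] = []
    minx, miny, maxx, maxy = bounds
    count = 0
    for _ in range(max_disks):
        if count >= target:
            break
        cx = rng.uniform(minx, maxx)
        cy = rng.uniform(miny, maxy)
        rad = rng.uniform(*radius_range)
        d2 = (centers_xy[:, 0] - cx) ** 2 + (centers_xy[:, 1] - cy) ** 2
        new = ~covered & (d2 <= rad * rad)
        n_new = int(new.sum())
        if n_new == 0:
            continue
        if count + n_new > target:
            keep = target - count
            idx = np.flatnonzero(new)
            order = np.argsort(d2[idx], kind="stable")
            covered[idx[order[:keep]]] = True
            count = target
        else:
            covered |= new
            count += n_new
        disks.append((cx, cy, rad))
    if count < target:
        raise PackingError(f"disk packing stalled at {count}/{target} pixels")
    return covered, np.array(disks, dtype=float).reshape(-1, 3)


def render_scene(
    truth: SceneTruth,
    seed: int = DEFAULT_MASTER_SEED,
    config: SceneConfig | None = None,
    *,
    weeds: bool = False,
) -> tuple[RasterGrid, RasterGrid, RasterGrid]:
    """Render (DOM, DSM, vegetation mask) for one stage.

    The DOM is 8-bit RGB; the DSM is metres; the mask is the renderer's own
    truth (1 = vegetation).  Every plot's vegetation-pixel fraction equals its
    ``true_cc`` exactly after rendering (``truth.plots`` is back-filled from
    the final mask, and the packed plant disks are stored in
    ``truth.plants``).  Bit-identical for identical seeds.
    """
    cfg = config or SceneConfig()
    rng = np.random.default_rng(seed)
    (h, w), transform = _field_grid(truth.design, cfg)

    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    xs, ys = transform.xy(cols, rows)

    chroma = np.empty((h, w, 3), dtype=float)
    for band, c in enumerate(cfg.soil_chroma):
        chroma[:, :, band] = c
    brightness = np.full((h, w), cfg.soil_brightness)
    mask = np.zeros((h, w), dtype=np.uint8)

    dummy = RasterGrid(values=mask, transform=transform, units="binary")
    achieved = {}
    for poly, rec in truth.design:
        row = truth.plots.loc[truth.plots["plot_id"] == rec.plot_id].iloc[0]
        pix = rasterize_plot(poly, dummy)
        if len(pix) == 0:
            continue
        target = int(round(float(row["true_cc"]) * len(pix)))
        px_xy = np.column_stack(transform.xy(pix[:, 1], pix[:, 0]))
        covered, disks = _pack_disks(px_xy, poly.ring.bounds, target, rng, cfg.disk_radius_m)
        truth.plants[rec.plot_id] = disks
        achieved[rec.plot_id] = target / len(pix)
        if target == 0:
            continue
        vr, vc = pix[covered, 0], pix[covered, 1]
        mask[vr, vc] = 1
        chroma[vr, vc, :] = _veg_chroma(float(row["true_pnc"]), truth.coupling, cfg.veg_rb_split)
        brightness[vr, vc] = cfg.veg_brightness

    if weeds:
        # small off-plot green blobs to exercise noise-robustness
        plot_union = None
        for poly, _ in truth.design:
            plot_union = poly.ring if plot_union is None else plot_union.union(poly.ring)
        import shapely

        for _ in range(cfg.n_weed_blobs):
            cx = rng.uniform(xs.min(), xs.max())
            cy = rng.uniform(ys.min(), ys.max())
            if plot_union is not None and shapely.contains_xy(plot_union, cx, cy):
                continue
            d2 = (xs - cx) ** 2 + (ys - cy) ** 2
            blob = d2 <= cfg.weed_blob_radius_m**2
            chroma[blob, :] = _veg_chroma(3.0, truth.coupling, cfg.veg_rb_split)
            brightness[blob] = cfg.veg_brightness

    dn = chroma * brightness[:, :, None]
    if truth.dn_jitter_sd > 0:
        dn = dn + rng.normal(0.0, truth.dn_jitter_sd, size=dn.shape)
    dom_values = np.clip(np.rint(dn), 0, 255).astype(np.uint8)

    dsm_values = _bare_surface(xs, ys, cfg)
    if truth.dsm_noise_sd > 0:
        dsm_values = dsm_values + rng.normal(0.0, truth.dsm_noise_sd, size=dsm_values.shape)
    veg = mask == 1
    heights = dict(zip(truth.plots["plot_id"], truth.plots["true_h_cm"]))
    for poly, rec in truth.design:
        if rec.plot_id not in achieved or achieved[rec.plot_id] == 0:
            continue
        pix = rasterize_plot(poly, dummy)
        vr, vc = pix[:, 0], pix[:, 1]
        sel = veg[vr, vc]
        dsm_values[vr[sel], vc[sel]] += heights[rec.plot_id] / 100.0

    truth.plots["true_cc"] = truth.plots["plot_id"].map(achieved).fillna(truth.plots["true_cc"])

    dom = RasterGrid(values=dom_values, transform=transform, units="DN8")
    dsm = RasterGrid(values=dsm_values, transform=transform, units="m")
    mask_grid = RasterGrid(values=mask, transform=transform, units="binary")
    return dom, dsm, mask_grid


def render_bare_scene(
    design: Sequence[tuple[PlotPolygon, PlotRecord]],
    seed: int = DEFAULT_MASTER_SEED,
    config: SceneConfig | None = None,
    *,
    dn_jitter_sd: float = 8.0,
    dsm_noise_sd: float = 0.01,
) -> tuple[RasterGrid, RasterGrid, RasterGrid]:
    """Render the bare-soil stage (S0): all-soil DOM, reference DSM, empty mask."""
    cfg = config or SceneConfig()
    empty = SceneTruth(
        stage="S1",
        design=list(design),
        plots=pd.DataFrame(
            {
                "plot_id": [r.plot_id for _, r in design],
                "zone": [r.zone for _, r in design],
                "level": [r.level for _, r in design],
                "variety": [r.variety for _, r in design],
                "replication": [r.replication for _, r in design],
                "true_pnc": np.full(len(design), COUPLING_DEFAULTS["S1"].pnc_ref),
                "true_h_cm": np.zeros(len(design)),
                "true_cc": np.zeros(len(design)),
            }
        ),
        coupling=COUPLING_DEFAULTS["S1"],
        dn_jitter_sd=dn_jitter_sd,
        dsm_noise_sd=dsm_noise_sd,
    )
    return render_scene(empty, seed=seed, config=cfg)


def render_ground_photo(
    truth: SceneTruth,
    plot_id: str,
    seed: int = DEFAULT_MASTER_SEED,
    config: SceneConfig | None = None,
    *,
    box_m: float = 1.3,
    frame_px: int = 4,
    resolution_factor: int = 4,
    n_weed_specks: int = 0,
    weed_speck_px: int = 5,
    return_mask: bool = False,
) -> RasterGrid | tuple[RasterGrid, RasterGrid]:
    """Render a nadir ground photo of one plot: a white 1.3 m box frame
    around a soil/vegetation interior at ``resolution_factor`` x the
    orthomosaic resolution.  The vegetation fraction inside the frame equals
    the plot's ``true_cc`` (up to one pixel of rounding)."""
    cfg = config or SceneConfig()
    row = truth.plots.loc[truth.plots["plot_id"] == plot_id]
    if row.empty:
        raise ValidationError(f"plot {plot_id!r} not present in truth")
    row = row.iloc[0]
    rng = np.random.default_rng(seed)

    gsd = cfg.gsd / resolution_factor
    interior = int(round(box_m / gsd))
    size = interior + 2 * frame_px
    poly = truth.polygon(plot_id)
    cx, cy = poly.ring.centroid.x, poly.ring.centroid.y
    x0 = cx - size * gsd / 2 + gsd / 2
    y0 = cy + size * gsd / 2 - gsd / 2
    transform = Affine.north_up(x0, y0, gsd)

    chroma = np.empty((size, size, 3), dtype=float)
    for band, c in enumerate(cfg.soil_chroma):
        chroma[:, :, band] = c
    brightness = np.full((size, size), cfg.soil_brightness)

    inner = np.zeros((size, size), dtype=bool)
    inner[frame_px : frame_px + interior, frame_px : frame_px + interior] = True

    rr, cc_idx = np.nonzero(inner)
    px_x, px_y = transform.xy(cc_idx, rr)
    centers = np.column_stack([px_x, px_y])
    target = int(round(float(row["true_cc"]) * len(centers)))
    bounds = (px_x.min(), px_y.min(), px_x.max(), px_y.max())
    covered, _ = _pack_disks(centers, bounds, target, rng, cfg.disk_radius_m)
    vr, vc = rr[covered], cc_idx[covered]
    chroma[vr, vc, :] = _veg_chroma(float(row["true_pnc"]), truth.coupling, cfg.veg_rb_split)
    brightness[vr, vc] = cfg.veg_brightness

    if n_weed_specks > 0:
        from scipy import ndimage

        veg_grid = np.zeros((size, size), dtype=bool)
        veg_grid[vr, vc] = True
        # weeds are isolated specks: keep them off the plants so the
        # component-area filter, not luck, decides their fate
        clear = ndimage.distance_transform_edt(~veg_grid) > 2.5
        for _ in range(n_weed_specks):
            soil_rc = np.column_stack(np.nonzero(inner & ~veg_grid & clear))
            if len(soil_rc) == 0:
                break
            anchor = soil_rc[rng.integers(len(soil_rc))]
            d = np.abs(soil_rc - anchor).sum(axis=1)
            speck = soil_rc[np.argsort(d, kind="stable")[:weed_speck_px]]
            chroma[speck[:, 0], speck[:, 1], :] = _veg_chroma(3.5, truth.coupling, cfg.veg_rb_split)
            brightness[speck[:, 0], speck[:, 1]] = cfg.veg_brightness
            clear[np.maximum(anchor[0] - 4, 0) : anchor[0] + 5, np.maximum(anchor[1] - 4, 0) : anchor[1] + 5] = False

    dn = chroma * brightness[:, :, None]
    if truth.dn_jitter_sd > 0:
        dn = dn + rng.normal(0.0, truth.dn_jitter_sd, size=dn.shape)
    values = np.clip(np.rint(dn), 0, 255).astype(np.uint8)
    values[~inner] = 255  # white box frame
    photo = RasterGrid(values=values, transform=transform, units="DN8")
    if not return_mask:
        return photo
    mask = np.zeros((size, size), dtype=np.uint8)
    mask[vr, vc] = 1
    mask[~inner] = FRAME_SENTINEL
    return photo, RasterGrid(values=mask, transform=transform, nodata=FRAME_SENTINEL, units="binary")


# ---------------------------------------------------------------------------
# linear-model recovery benchmark
# ---------------------------------------------------------------------------


def linear_pnc_benchmark(
    seed: int,
    n_features: int = 3,
    population_r2: float = 0.8,
    n_treatments: int = 16,
    replications: int = 3,
) -> pd.DataFrame:
    """A balanced replicated dataset with a known linear PNC model.

    ``n_treatments`` feature profiles are drawn once per seed and replicated
    across ``replications`` blocks (mirroring the trial's structure, where
    every replicate sees the same treatments).  The response is a linear
    combination of the features with empirical signal variance 1 plus
    Gaussian noise of variance ``(1 - R^2) / R^2``, so the population
    coefficient of determination equals ``population_r2``.

    Returns a DataFrame with columns ``x1..xp``, ``pnc``, ``replication``,
    ``plot_id``.
    """
    if not 0 < population_r2 < 1:
        raise ValidationError("population_r2 must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    profiles = rng.normal(size=(n_treatments, n_features))
    beta = rng.normal(size=n_features)
    beta /= np.linalg.norm(beta)
    X = np.vstack([profiles] * replications)
    signal = X @ beta
    signal = (signal - signal.mean()) / signal.std()
    noise_sd = math.sqrt((1.0 - population_r2) / population_r2)
    y = signal + rng.normal(0.0, noise_sd, size=len(X))
    df = pd.DataFrame(X, columns=[f"x{j + 1}" for j in range(n_features)])
    df["pnc"] = y
    df["replication"] = np.repeat(np.arange(1, replications + 1), n_treatments)
    df["plot_id"] = [f"b{i:02d}" for i in range(len(X))]
    return df
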