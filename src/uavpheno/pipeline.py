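"""End-to-end orchestration: scene synthesis or ingestion, index extraction,
canopy morphology, and PNC modeling, as one configured, reproducible run.

Every run writes a provenance block (full configuration, seed, package and
library versions) next to its outputs; identical configuration + seed yields
byte-identical feature tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import PipelineConfigError, StageFailure
from .indices import INDEX_ORDER, feature_table
from .modeling import METHODS, pearson_screen, run_model_suite
from .morphology import canopy_height_model, morphological_features, segment_vegetation_uav
from .raster import read_plots, read_raster, write_plots, write_raster
from .synth import (
    DEFAULT_MASTER_SEED,
    STAGES,
    SceneConfig,
    generate_design,
    render_bare_scene,
    render_scene,
    sample_truth,
)

__all__ = ["PipelineConfig", "run_pipeline", "validate_extraction"]


def _sub_seed(seed: int, *tags: int) -> int:
    """Deterministic child seed derived from the master seed."""
    return int(np.random.SeedSequence([int(seed), *tags]).generate_state(1)[0] % (2**31))


@dataclass
class SynthOptions:
    gsd: float = 0.10
    dn_jitter_sd: float = 8.0
    dsm_noise_sd: float = 0.01
    weeds: bool = False


@dataclass
class SegmentationOptions:
    min_area: int = 25
    hue_lo: float = 60.0
    hue_hi: float = 180.0
    sat_floor: float = 0.1
    height_stat: str = "mean"


@dataclass
class AggregationOptions:
    mask_vegetation: bool = False


@dataclass
class ModelingOptions:
    methods: tuple[str, ...] = METHODS
    feature_sets: tuple[str, ...] = ("VIs", "MPs", "VIs+MPs")
    knn_k: int = 5
    rf_trees: int = 500
    top_k: int = 5


@dataclass
class PipelineConfig:
    """Schema-validated run configuration; unknown keys are rejected."""

    seed: int = DEFAULT_MASTER_SEED
    out_dir: str = "uavpheno_run"
    stages: tuple[str, ...] = STAGES
    inputs: dict | None = None  # {"plots":..., "dsm_bare":..., "truth":..., "S1": {"dom":..., "dsm":...}, ...}
    synth: SynthOptions = field(default_factory=SynthOptions)
    segmentation: SegmentationOptions = field(default_factory=SegmentationOptions)
    aggregation: AggregationOptions = field(default_factory=AggregationOptions)
    modeling: ModelingOptions = field(default_factory=ModelingOptions)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineConfigError(f"unknown configuration keys: {sorted(unknown)}")
        for name, sub_cls in (
            ("synth", SynthOptions),
            ("segmentation", SegmentationOptions),
            ("aggregation", AggregationOptions),
            ("modeling", ModelingOptions),
        ):
            if name in data and isinstance(data[name], dict):
                sub_known = {f.name for f in dataclasses.fields(sub_cls)}
                sub_unknown = set(data[name]) - sub_known
                if sub_unknown:
                    raise PipelineConfigError(f"unknown keys in {name!r}: {sorted(sub_unknown)}")
                payload = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in data[name].items()
                }
                data[name] = sub_cls(**payload)
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
            bad = set(data["stages"]) - set(STAGES)
            if bad:
                raise PipelineConfigError(f"unknown stages: {sorted(bad)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise PipelineConfigError("configuration file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _provenance(config: PipelineConfig) -> dict:
    import scipy
    import shapely
    import sklearn

    return {
        "config": config.to_dict(),
        "seed": config.seed,
        "versions": {
            "uavpheno": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
            "shapely": shapely.__version__,
        },
    }


def _load_inputs(config: PipelineConfig, out: Path):
    inputs = config.inputs or {}
    if "plots" not in inputs:
        raise PipelineConfigError("inputs must provide a 'plots' GeoJSON path")
    if "dsm_bare" not in inputs:
        raise PipelineConfigError("inputs must provide a 'dsm_bare' raster path")
    for stage in config.stages:  # validate completeness before touching disk
        entry = inputs.get(stage)
        if not entry or "dom" not in entry or "dsm" not in entry:
            raise PipelineConfigError(f"inputs missing DOM/DSM for requested stage {stage}")
    plots = read_plots(inputs["plots"])
    dsm_bare = read_raster(inputs["dsm_bare"])
    scenes = {}
    for stage in config.stages:
        entry = inputs[stage]
        scenes[stage] = (read_raster(entry["dom"]), read_raster(entry["dsm"]), None)
    truth = pd.read_csv(inputs["truth"]) if "truth" in inputs else None
    return plots, dsm_bare, scenes, truth


def _synthesize(config: PipelineConfig, out: Path):
    scene_cfg = SceneConfig(gsd=config.synth.gsd)
    design = generate_design()
    write_plots(design, out / "plots.geojson")
    _, dsm_bare, _ = render_bare_scene(
        design,
        seed=_sub_seed(config.seed, 0),
        config=scene_cfg,
        dn_jitter_sd=config.synth.dn_jitter_sd,
        dsm_noise_sd=config.synth.dsm_noise_sd,
    )
    write_raster(dsm_bare, out / "dsm_S0.tif")
    scenes = {}
    truth_rows = []
    for i, stage in enumerate(config.stages, start=1):
        truth = sample_truth(
            design,
            stage,
            seed=_sub_seed(config.seed, i, 1),
            dn_jitter_sd=config.synth.dn_jitter_sd,
            dsm_noise_sd=config.synth.dsm_noise_sd,
        )
        dom, dsm, mask = render_scene(
            truth, seed=_sub_seed(config.seed, i, 2), config=scene_cfg, weeds=config.synth.weeds
        )
        write_raster(dom, out / f"dom_{stage}.tif")
        write_raster(dsm, out / f"dsm_{stage}.tif")
        write_raster(mask, out / f"mask_truth_{stage}.tif")
        scenes[stage] = (dom, dsm, mask)
        t = truth.plots.copy()
        t.insert(1, "stage", stage)
        truth_rows.append(t)
    truth_df = pd.concat(truth_rows, ignore_index=True)
    truth_df.to_csv(out / "truth.csv", index=False)
    return design, dsm_bare, scenes, truth_df


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Stages: scene acquisition (synthetic render or raster ingestion), index
    extraction, canopy morphology, extraction validation (when generator
    truth is available) and PNC modeling.  Any stage failure aborts with the
    stage name and the offending item.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        if config.inputs is None:
            plots, dsm_bare, scenes, truth_df = _synthesize(config, out)
        else:
            plots, dsm_bare, scenes, truth_df = _load_inputs(config, out)
    except PipelineConfigError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageFailure("acquire", str(exc)) from exc

    # -- indices ---------------------------------------------------------
    try:
        feats = []
        for stage, (dom, _, _) in scenes.items():
            mask_for_agg = None
            if config.aggregation.mask_vegetation:
                mask_for_agg = segment_vegetation_uav(dom)
            feats.append(feature_table(dom, plots, stage, mask=mask_for_agg))
        vi_df = pd.concat(feats, ignore_index=True)
        vi_df.to_csv(out / "vi_features.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("indices", str(exc)) from exc

    # -- morphology ------------------------------------------------------
    try:
        morphs = []
        for stage, (dom, dsm, _) in scenes.items():
            mask = segment_vegetation_uav(dom)
            write_raster(mask, out / f"mask_extracted_{stage}.tif")
            chm = canopy_height_model(dsm, dsm_bare)
            morphs.append(
                morphological_features(chm, mask, plots, stage, height_stat=config.segmentation.height_stat)
            )
        morph_df = pd.concat(morphs, ignore_index=True)
        morph_df.to_csv(out / "morphology.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("morphology", str(exc)) from exc

    features = vi_df.merge(morph_df, on=["plot_id", "stage"])
    features.to_csv(out / "plot_features.csv", index=False)

    if truth_df is None:
        return out

    # -- extraction validation -------------------------------------------
    try:
        report = validate_extraction(morph_df, truth_df)
        (out / "extraction_report.json").write_text(json.dumps(report, indent=1))
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("validate", str(exc)) from exc

    # -- modeling ---------------------------------------------------------
    try:
        truth_model = truth_df.rename(columns={"true_pnc": "pnc"})[
            ["plot_id", "stage", "replication", "pnc"]
        ]
        stages = tuple(s for s in config.stages if s in set(features["stage"]))
        corr_rows = []
        for stage in stages:
            sub = features[features["stage"] == stage].merge(
                truth_model[truth_model["stage"] == stage], on=["plot_id", "stage"]
            )
            screen = pearson_screen(sub[list(INDEX_ORDER) + ["H_cm", "CC", "CV"]], sub["pnc"])
            screen.insert(0, "stage", stage)
            corr_rows.append(screen)
        pd.concat(corr_rows, ignore_index=True).to_csv(out / "correlations.csv", index=False)

        reports = run_model_suite(
            features,
            truth_model,
            stages=stages,
            methods=tuple(config.modeling.methods),
            feature_sets=tuple(config.modeling.feature_sets),
            seed=_sub_seed(config.seed, 99),
            top_k=config.modeling.top_k,
            hyper={"k": config.modeling.knn_k, "n_trees": config.modeling.rf_trees},
        )
        (out / "model_report.json").write_text(
            json.dumps([r.to_dict() for r in reports], indent=1)
        )
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("model", str(exc)) from exc

    (out / "provenance.json").write_text(json.dumps(_provenance(config), indent=1))
    return out


def validate_extraction(extracted: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Agreement of extracted vs true plant height and coverage, per stage.

    R^2 here is the squared Pearson correlation of the extracted-vs-measured
    scatter (the 1:1-line comparison); RMSE is in the trait's units (cm for
    H, fraction for CC).
    """
    merged = extracted.merge(truth, on=["plot_id", "stage"], how="inner")
    if merged.empty:
        raise ValueError("join failure: no common plot_id x stage rows")
    report: dict = {}
    for stage in sorted(set(merged["stage"])):
        sub = merged[merged["stage"] == stage]
        entry = {}
        for trait, (ext_col, true_col) in {
            "H": ("H_cm", "true_h_cm"),
            "CC": ("CC", "true_cc"),
        }.items():
            x = sub[ext_col].to_numpy(float)
            y = sub[true_col].to_numpy(float)
            r = np.corrcoef(x, y)[0, 1] if np.std(x) > 0 and np.std(y) > 0 else np.nan
            entry[trait] = {
                "R2": float(r**2) if np.isfinite(r) else float("nan"),
                "RMSE": float(np.sqrt(np.mean((x - y) ** 2))),
                "n": int(len(sub)),
            }
        report[stage] = entry
    return report
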