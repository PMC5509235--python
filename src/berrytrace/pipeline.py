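"""End-to-end orchestration: synthesize → calibrate → segment → extract →
preprocess → select → split → train → evaluate → report.

Two composite runs mirror the two analysis views of a berry scene:

* :func:`run_pixelwise` — PCA over every foreground pixel spectrum, score
  images for the first five components, and 2-D score scatters of (PC3, PC4)
  and (PC5, PC4);
* :func:`run_objectwise` — per-berry mean spectra, truncated to the
  972-1609 nm fruit window, MA-smoothed, Kennard-Stone split 2:1, then the
  three discriminant models on each of three feature sets (full spectra,
  PCA-loadings selection, second-derivative selection), each evaluated on
  calibration and prediction sets.

Every run writes its resolved configuration next to its outputs so the run
can be regenerated exactly, and all stage outputs are serialized, so stages
are resumable from disk.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import hypercube as hc
from . import io as bio
from . import models as md
from . import preprocess as pp
from . import synthetic as syn
from . import wavesel as ws

logger = logging.getLogger("berrytrace")

__all__ = [
    "PipelineConfig",
    "ScoreImage",
    "PixelwiseResult",
    "ObjectwiseResult",
    "run_pixelwise",
    "run_objectwise",
    "report",
]


class AcquisitionConfig(BaseModel):
    n_rows: int = 120
    n_cols: int = 320
    n_bands: int = 256
    lambda_min_nm: float = 874.0
    lambda_max_nm: float = 1734.0
    bit_depth_max: float = 4095.0


class OriginConfig(BaseModel):
    n_objects_per_class: int = 6
    n_samples_per_class: int = 300
    offset_scale: float = 1.0
    noise_sd: float = 0.01


class PreprocessConfig(BaseModel):
    truncate_lo_nm: float = 972.0
    truncate_hi_nm: float = 1609.0
    ma_window: int = 5
    sg_window: int = 9
    sg_polyorder: int = 3


class SelectionConfig(BaseModel):
    n_components: int = 5
    loading_threshold: float = 0.0
    max_wavelengths: int | None = 20
    d2_threshold: float = 0.0
    d2_max_wavelengths: int | None = 9


class SplitConfig(BaseModel):
    ratio: float = 2.0
    per_class: bool = True


class ModelConfig(BaseModel):
    elm_h_max: int = 150
    svm_c_exponents: tuple[int, int] = (-5, 10)
    svm_g_exponents: tuple[int, int] = (-10, 5)
    cv_folds: int = 5
    rbf_spread_coarse: bool = False   # stride-10 spread grid for quick runs


class PipelineConfig(BaseModel):
    """Validated, serializable configuration for a full run."""

    seed: int = 0
    mask_threshold: float = 0.15
    min_object_pixels: int = 20
    acquisition: AcquisitionConfig = Field(default_factory=AcquisitionConfig)
    origins: OriginConfig = Field(default_factory=OriginConfig)
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    selection: SelectionConfig = Field(default_factory=SelectionConfig)
    split: SplitConfig = Field(default_factory=SplitConfig)
    models: ModelConfig = Field(default_factory=ModelConfig)

    @model_validator(mode="after")
    def _check(self):
        if self.acquisition.lambda_min_nm >= self.acquisition.lambda_max_nm:
            raise ValueError("lambda_min_nm must be below lambda_max_nm")
        if self.split.ratio <= 0:
            raise ValueError("split ratio must be positive")
        return self

    def acquisition_spec(self) -> syn.AcquisitionSpec:
        return syn.AcquisitionSpec(**self.acquisition.model_dump())

    def origin_models(self) -> list[syn.OriginModel]:
        return syn.default_origin_models(offset_scale=self.origins.offset_scale,
                                         noise_sd=self.origins.noise_sd)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.model_dump(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        import yaml
        text = Path(path).read_text()
        data = yaml.safe_load(text)   # YAML superset also parses JSON
        return cls.model_validate(data)


@dataclass
class ScoreImage:
    """Per-pixel scores of one principal component mapped back to the frame."""

    component: int               # 1-based PC index
    raster: np.ndarray           # NaN at background pixels

    def __post_init__(self) -> None:
        fg = ~np.isnan(self.raster)
        if not fg.any():
            raise ValueError("score image has no foreground")


@dataclass
class PixelwiseResult:
    pca: ws.PCAResult
    score_images: list[ScoreImage]
    scatter: dict[str, np.ndarray]       # e.g. {"pc3_pc4": (n, 2) array}
    pixel_classes: np.ndarray
    n_pixels: int
    cumulative_explained: float          # of the first 5 PCs, as a fraction


@dataclass
class ObjectwiseResult:
    reports: dict[tuple[str, str], dict[str, md.EvalReport]]
    # keyed (feature_set, model_name) -> {"calibration": ..., "prediction": ...}
    params: dict[tuple[str, str], object]
    selections: dict[str, ws.SelectedWavelengths]
    split: md.SplitResult

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for (feature_set, model_name), sets in self.reports.items():
            row = {"feature_set": feature_set, "model": model_name,
                   "parameter": repr(self.params[(feature_set, model_name)])}
            for set_name, rep in sets.items():
                for cls, acc in zip(rep.classes, rep.per_class_accuracy):
                    row[f"{set_name}_{cls}"] = round(float(acc), 2)
                row[f"{set_name}_mean"] = round(rep.mean_accuracy, 2)
            rows.append(row)
        return pd.DataFrame(rows)


def _stage(name: str):
    logger.info("stage %s", name)
    return time.perf_counter()


def synthesize_scene(cfg: PipelineConfig):
    """Render the configured synthetic scene (raw cube, references, truth)."""
    return syn.render_scene(cfg.acquisition_spec(), cfg.origin_models(),
                            cfg.origins.n_objects_per_class, cfg.seed)


def run_pixelwise(cfg: PipelineConfig, outdir: str | Path | None = None,
                  scene=None) -> PixelwiseResult:
    """Pixel-wise PCA visualization over all foreground pixel spectra."""
    t0 = _stage("pixelwise")
    if scene is None:
        scene = synthesize_scene(cfg)
    raw, refs, truth = scene
    cube = hc.calibrate_cube(raw, refs)
    mask = hc.mask_background(cube, threshold=cfg.mask_threshold)
    labeled, table = hc.segment_objects(mask, min_pixels=cfg.min_object_pixels)
    class_map = dict(zip(truth.object_table["object_id"],
                         truth.object_table["class_id"]))
    # rendered object ids match segmentation labels only for clean scenes, so
    # map each segmented object to the truth class covering its pixels
    seg_class_map = {}
    for object_id in table["object_id"]:
        sel = labeled == object_id
        classes = truth.label_image[sel]
        seg_class_map[object_id] = int(np.bincount(classes[classes > 0]).argmax())
    pixels = hc.extract_pixel_spectra(cube, labeled, class_map=seg_class_map)

    k = 5
    pca_est = ws.SpectralPCA(n_components=k).fit(pixels.spectra)
    pca = pca_est.result_()
    score_images = []
    for j in range(k):
        raster = np.full(cube.spatial_shape, np.nan)
        raster[pixels.rows, pixels.cols] = pca.scores[:, j]
        score_images.append(ScoreImage(component=j + 1, raster=raster))
    scatter = {
        "pc3_pc4": pca.scores[:, [2, 3]],
        "pc5_pc4": pca.scores[:, [4, 3]],
    }
    result = PixelwiseResult(
        pca=pca, score_images=score_images, scatter=scatter,
        pixel_classes=pixels.class_ids, n_pixels=len(pixels),
        cumulative_explained=float(pca.cumulative_explained[-1]))
    logger.info("pixelwise done: %d pixels, 5-PC cumulative %.4f (%.1fs)",
                result.n_pixels, result.cumulative_explained,
                time.perf_counter() - t0)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cfg.save(outdir / "config.json")
        pd.DataFrame({
            "pc": np.arange(1, k + 1),
            "explained_ratio": pca.explained_ratio,
            "cumulative": pca.cumulative_explained,
        }).to_csv(outdir / "pixelwise_explained.csv", index=False)
        for img in score_images:
            np.savetxt(outdir / f"score_pc{img.component}.csv", img.raster,
                       delimiter=",")
        for name, pts in scatter.items():
            pd.DataFrame(pts, columns=name.split("_")).assign(
                class_id=pixels.class_ids).to_csv(
                outdir / f"scatter_{name}.csv", index=False)
    return result


def _object_dataset(cfg: PipelineConfig) -> pp.SpectralDataset:
    """Object-wise sample library at the configured class structure."""
    axis = cfg.acquisition_spec().axis
    return syn.make_sample_library(cfg.origin_models(),
                                   cfg.origins.n_samples_per_class,
                                   axis, seed=cfg.seed)


MODEL_NAMES = ("svm", "nn-rbf", "elm")
FEATURE_SETS = ("full", "pca_loadings", "d2")


def run_objectwise(cfg: PipelineConfig, outdir: str | Path | None = None,
                   ds: pp.SpectralDataset | None = None) -> ObjectwiseResult:
    """Three discriminant models × three feature sets on object-wise spectra."""
    t0 = _stage("objectwise")
    if ds is None:
        ds = _object_dataset(cfg)
    ds = pp.truncate_band_range(ds, cfg.preprocess.truncate_lo_nm,
                                cfg.preprocess.truncate_hi_nm)
    ds = pp.moving_average(ds, cfg.preprocess.ma_window)

    split = md.kennard_stone_split(ds, ratio=cfg.split.ratio,
                                   per_class=cfg.split.per_class)
    id_to_row = {int(i): r for r, i in enumerate(ds.ids)}
    cal_rows = np.array([id_to_row[int(i)] for i in split.calibration_ids])
    pred_rows = np.array([id_to_row[int(i)] for i in split.prediction_ids])
    ds_cal, ds_pred = ds.subset(cal_rows), ds.subset(pred_rows)

    # feature selections are fitted on calibration data only
    sel_cfg = cfg.selection
    pca = ws.fit_pca(ds_cal, k=sel_cfg.n_components)
    sel_pca = ws.pick_loading_extrema(pca, ds.axis,
                                      n_components=sel_cfg.n_components,
                                      threshold=sel_cfg.loading_threshold,
                                      max_wavelengths=sel_cfg.max_wavelengths)
    ds_d2 = pp.savitzky_golay(ds_cal, cfg.preprocess.sg_window,
                              cfg.preprocess.sg_polyorder, deriv=2)
    sel_d2 = ws.pick_derivative_extrema(ds_d2, threshold=sel_cfg.d2_threshold,
                                        max_wavelengths=sel_cfg.d2_max_wavelengths)
    selections = {"pca_loadings": sel_pca, "d2": sel_d2}

    feature_data = {"full": (ds_cal, ds_pred)}
    for name, sel in selections.items():
        if len(sel) == 0:
            logger.warning("empty %s selection; skipping that feature set", name)
            continue
        feature_data[name] = (ws.apply_selection(ds_cal, sel),
                              ws.apply_selection(ds_pred, sel))

    mcfg = cfg.models
    svm_grid = {
        "svc__C": [2.0 ** p for p in range(mcfg.svm_c_exponents[0],
                                           mcfg.svm_c_exponents[1] + 1)],
        "svc__gamma": [2.0 ** p for p in range(mcfg.svm_g_exponents[0],
                                               mcfg.svm_g_exponents[1] + 1)],
    }
    spread_grid = md.DEFAULT_SPREAD_GRID
    if mcfg.rbf_spread_coarse:
        spread_grid = tuple(s for s in spread_grid
                            if s < 1 or int(s) % 10 == 0 or s == 1)

    reports, params = {}, {}
    for feature_set, (fcal, fpred) in feature_data.items():
        best_svm, svm = md.train_svm(fcal, grid=svm_grid, cv=mcfg.cv_folds,
                                     seed=cfg.seed)
        spread, rbf = md.train_rbf_net(fcal, spread_grid=spread_grid,
                                       cv=mcfg.cv_folds, seed=cfg.seed)
        h, elm = md.search_elm(fcal, h_range=range(1, mcfg.elm_h_max + 1),
                               seed=cfg.seed)
        for model_name, model, param in (("svm", svm, best_svm),
                                         ("nn-rbf", rbf, spread),
                                         ("elm", elm, h)):
            reports[(feature_set, model_name)] = {
                "calibration": md.evaluate(model, fcal, "calibration"),
                "prediction": md.evaluate(model, fpred, "prediction"),
            }
            params[(feature_set, model_name)] = param
        logger.info("feature set %s done (%.1fs)", feature_set,
                    time.perf_counter() - t0)

    result = ObjectwiseResult(reports=reports, params=params,
                              selections=selections, split=split)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cfg.save(outdir / "config.json")
        result.summary_frame().to_csv(outdir / "objectwise_results.csv",
                                      index=False)
        for name, sel in selections.items():
            bio.write_selection(sel, outdir / f"selection_{name}.json")
        pd.DataFrame({"set": (["calibration"] * len(split.calibration_ids)
                              + ["prediction"] * len(split.prediction_ids)),
                      "id": np.concatenate([split.calibration_ids,
                                            split.prediction_ids])}
                     ).to_csv(outdir / "split.csv", index=False)
    return result


def report(run_dir: str | Path) -> Path:
    """Render a Markdown summary (+ figures) from a completed run directory."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    lines = ["# berrytrace run report", ""]
    missing = []

    explained = run_dir / "pixelwise_explained.csv"
    if explained.exists():
        frame = pd.read_csv(explained)
        lines += ["## Pixel-wise PCA", "",
                  "```", frame.to_string(index=False), "```", "",
                  f"5-PC cumulative explained variance: "
                  f"{100 * frame['cumulative'].iloc[-1]:.2f}%", ""]
        score_files = sorted(run_dir.glob("score_pc*.csv"))
        if score_files:
            fig, axes = plt.subplots(1, len(score_files),
                                     figsize=(3 * len(score_files), 3))
            for ax, f in zip(np.atleast_1d(axes), score_files):
                raster = np.loadtxt(f, delimiter=",")
                ax.imshow(raster, cmap="coolwarm")
                ax.set_title(f.stem)
                ax.axis("off")
            fig.savefig(run_dir / "score_images.png", dpi=120,
                        bbox_inches="tight")
            plt.close(fig)
            lines += ["![score images](score_images.png)", ""]
    else:
        missing.append(str(explained.name))

    results = run_dir / "objectwise_results.csv"
    if results.exists():
        frame = pd.read_csv(results)
        lines += ["## Object-wise discriminant models", "",
                  "```", frame.to_string(index=False), "```", ""]
        for sel_file in sorted(run_dir.glob("selection_*.json")):
            sel = bio.read_selection(sel_file)
            nm = ", ".join(f"{v:.0f}" for v in sel.wavelengths_nm)
            lines += [f"Selected wavelengths ({sel.source}): {nm} nm", ""]
    else:
        missing.append(str(results.name))

    if missing:
        lines += ["## Missing stage outputs", ""] + [f"- {m}" for m in missing]
    out = run_dir / "report.md"
    out.write_text("\n".join(lines))
    return out
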