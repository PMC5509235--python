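"""Synthetic hyperspectral scenes with the statistical structure of berry imagery.

The generator emulates what the analysis pipeline assumes of real NIR fruit
cubes so that every downstream stage is testable offline:

* four origin classes whose clean reflectance spectra share a smooth baseline
  with Gaussian absorption dips near 995, 1200 and 1465 nm (N-H, C-H and
  water overtone bands) and differ only by a small additive offset and small
  dip-depth perturbations — similar curves, slightly different reflectance;
* berry-shaped objects (filled, non-overlapping ellipses) on a dark stage;
* raw counts, white and dark reference frames consistent with the
  reflectance calibration identity, so calibrating a rendered noise-free
  scene recovers the clean truth cube exactly;
* i.i.d. Gaussian pixel/band noise plus a per-object multiplicative scatter
  factor, reproducing both pixel-level spread and sample-level variability.

All randomness flows through one seeded generator: identical seeds give
bit-identical scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hypercube import HyperCube, ReferenceFrames, WavelengthAxis
from .preprocess import SpectralDataset

__all__ = [
    "AcquisitionSpec",
    "OriginModel",
    "SceneTruth",
    "default_origin_models",
    "make_endmember",
    "render_scene",
    "make_sample_library",
]

#: Absorption band centers (nm) shared by all origins: protein/amino-acid N-H
#: second overtone, C-H second stretch (starch/protein/lipid), water.
DEFAULT_ABSORPTION_CENTERS_NM = (995.0, 1200.0, 1465.0)
DEFAULT_ABSORPTION_DEPTHS = (0.06, 0.09, 0.14)
DEFAULT_ABSORPTION_WIDTHS_NM = (22.0, 30.0, 45.0)

#: Stage (background) reflectance — dark matte platform.
BACKGROUND_REFLECTANCE = 0.05


def _default_baseline(lam: np.ndarray) -> np.ndarray:
    """Smooth, gently arched fruit-tissue baseline reflectance in (0, 1)."""
    lam = np.asarray(lam, dtype=float)
    return 0.62 - 0.08 * ((lam - 1250.0) / 500.0) ** 2


@dataclass(frozen=True)
class AcquisitionSpec:
    """Geometry and radiometry of the simulated pushbroom acquisition.

    Defaults mirror the reference instrument: 256 spectral bands spanning
    874-1734 nm and a 320-pixel-wide frame.
    """

    n_rows: int = 120
    n_cols: int = 320
    n_bands: int = 256
    lambda_min_nm: float = 874.0
    lambda_max_nm: float = 1734.0
    bit_depth_max: float = 4095.0   # 12-bit sensor white level

    def __post_init__(self) -> None:
        if self.n_bands < 2:
            raise ValueError("need at least two bands")
        if self.lambda_min_nm >= self.lambda_max_nm:
            raise ValueError("lambda_min_nm must be below lambda_max_nm")
        if self.bit_depth_max <= 0:
            raise ValueError("bit_depth_max must be positive")

    @property
    def axis(self) -> WavelengthAxis:
        return WavelengthAxis(np.linspace(self.lambda_min_nm, self.lambda_max_nm,
                                          self.n_bands))


@dataclass
class OriginModel:
    """Spectral model of one geographic origin class.

    Classes differ only through ``offset_shift`` (small additive reflectance
    offset) and slightly perturbed absorption depths, matching fruit whose
    spectra share shape but differ subtly in level.
    """

    class_id: int
    baseline_reflectance: callable = _default_baseline
    absorption_centers_nm: tuple = DEFAULT_ABSORPTION_CENTERS_NM
    absorption_depths: tuple = DEFAULT_ABSORPTION_DEPTHS
    absorption_widths_nm: tuple = DEFAULT_ABSORPTION_WIDTHS_NM
    offset_shift: float = 0.0
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.class_id not in (1, 2, 3, 4):
            raise ValueError("class_id must be in {1, 2, 3, 4}")
        if not (len(self.absorption_centers_nm) == len(self.absorption_depths)
                == len(self.absorption_widths_nm)):
            raise ValueError("absorption center/depth/width lists must align")
        if any(w <= 0 for w in self.absorption_widths_nm):
            raise ValueError("absorption widths must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def default_origin_models(offset_scale: float = 1.0,
                          noise_sd: float = 0.01) -> list[OriginModel]:
    """The four default origin classes.

    ``offset_scale`` multiplies the between-class offsets and depth
    perturbations: 1 gives the default overlapping-but-clustered geometry,
    0 gives identical classes (a chance-level null), large values give
    well-separated classes.
    """
    offsets = np.array([0.000, -0.018, 0.014, -0.032]) * offset_scale
    depth_tweaks = np.array([0.000, 0.006, -0.005, 0.009]) * offset_scale
    models = []
    for k in range(4):
        depths = tuple(np.asarray(DEFAULT_ABSORPTION_DEPTHS) + depth_tweaks[k])
        models.append(OriginModel(class_id=k + 1, absorption_depths=depths,
                                  offset_shift=float(offsets[k]),
                                  noise_sd=noise_sd))
    return models


@dataclass
class SceneTruth:
    """Ground truth for one rendered scene."""

    label_image: np.ndarray            # 0 background, else class_id per pixel
    object_table: "pd.DataFrame"       # object_id, class_id, centroid, pixel_count
    clean_reflectance_cube: HyperCube
    object_id_image: np.ndarray        # 0 background, else object_id per pixel


def make_endmember(model: OriginModel, axis: WavelengthAxis) -> np.ndarray:
    """Clean class reflectance spectrum: baseline minus Gaussian absorption dips.

    The band-sampled spectrum stays in (0, 1); local minima fall at the bands
    nearest the absorption centers.
    """
    lam = axis.centers_nm
    spectrum = np.asarray(model.baseline_reflectance(lam), dtype=float).copy()
    spectrum += model.offset_shift
    for center, depth, width in zip(model.absorption_centers_nm,
                                    model.absorption_depths,
                                    model.absorption_widths_nm):
        spectrum -= depth * np.exp(-0.5 * ((lam - center) / width) ** 2)
    if np.any(spectrum <= 0.0) or np.any(spectrum >= 1.0):
        raise ValueError("endmember reflectance left (0, 1); "
                         "reduce absorption depths or offset")
    return spectrum


def _place_ellipses(rng: np.random.Generator, spec: AcquisitionSpec,
                    n_objects: int, max_attempts: int = 5000):
    """Non-overlapping filled ellipses inside the frame; returns boolean masks.

    Overlap is prevented via a center-distance test against the sum of the
    two major semi-axes, which is conservative (sufficient, not necessary).
    """
    placed = []   # (row0, col0, a, b)
    masks = []
    rr, cc = np.mgrid[0:spec.n_rows, 0:spec.n_cols]
    for _ in range(n_objects):
        for attempt in range(max_attempts):
            a = rng.uniform(4.0, 7.0)       # semi-axes in px — berry-sized
            b = rng.uniform(4.0, 7.0)
            r0 = rng.uniform(a + 1, spec.n_rows - a - 1)
            c0 = rng.uniform(b + 1, spec.n_cols - b - 1)
            big = max(a, b)
            ok = all((r0 - pr) ** 2 + (c0 - pc) ** 2 > (big + max(pa, pb) + 1) ** 2
                     for pr, pc, pa, pb in placed)
            if ok:
                placed.append((r0, c0, a, b))
                masks.append(((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2 <= 1.0)
                break
        else:
            raise RuntimeError(
                f"could not place object {len(placed) + 1}/{n_objects} without "
                f"overlap in {max_attempts} attempts; enlarge the frame"
            )
    return masks


def render_scene(spec: AcquisitionSpec, models: list[OriginModel],
                 n_objects_per_class: int, seed: int
                 ) -> tuple[HyperCube, ReferenceFrames, SceneTruth]:
    """Render a raw-count scene plus reference frames and ground truth.

    The raw cube is built by inverting the calibration identity:
    ``raw = dark + R * (white - dark)`` with ``R`` the clean reflectance plus
    per-object multiplicative scatter and per-pixel Gaussian noise.  With all
    noise terms at zero, calibrating the outputs reproduces the clean truth
    cube to machine precision.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    axis = spec.axis
    n_objects = n_objects_per_class * len(models)
    masks = _place_ellipses(rng, spec, n_objects)
    # round-robin class assignment keeps spatial placement class-balanced
    class_seq = [m.class_id for m in models] * n_objects_per_class
    model_by_class = {m.class_id: m for m in models}

    clean = np.full((spec.n_rows, spec.n_cols, spec.n_bands),
                    BACKGROUND_REFLECTANCE)
    label_image = np.zeros((spec.n_rows, spec.n_cols), dtype=int)
    object_id_image = np.zeros_like(label_image)
    noisy = None
    records = []
    noise_field = np.zeros_like(clean)

    for object_id, (mask, class_id) in enumerate(zip(masks, class_seq), start=1):
        model = model_by_class[class_id]
        endmember = make_endmember(model, axis)
        # per-object scatter: lognormal multiplicative factor, sd ~2%
        scatter = float(np.exp(rng.normal(0.0, 0.02))) if model.noise_sd > 0 else 1.0
        clean[mask] = endmember * scatter
        if model.noise_sd > 0:
            noise_field[mask] = rng.normal(0.0, model.noise_sd,
                                           size=(int(mask.sum()), spec.n_bands))
        label_image[mask] = class_id
        object_id_image[mask] = object_id
        r_idx, c_idx = np.nonzero(mask)
        records.append({"object_id": object_id, "class_id": class_id,
                        "centroid_row": float(r_idx.mean()),
                        "centroid_col": float(c_idx.mean()),
                        "pixel_count": int(mask.sum())})

    noisy = clean + noise_field
    # per-line reference frames (cols x bands), as a pushbroom camera records
    white = np.full((spec.n_cols, spec.n_bands), 0.92 * spec.bit_depth_max)
    dark = np.full((spec.n_cols, spec.n_bands), 0.04 * spec.bit_depth_max)
    raw_values = dark + noisy * (white - dark)
    raw = HyperCube(raw_values, axis, calibrated=False)
    truth = SceneTruth(label_image=label_image,
                       object_table=pd.DataFrame(records),
                       clean_reflectance_cube=HyperCube(clean, axis, calibrated=True),
                       object_id_image=object_id_image)
    return raw, ReferenceFrames(white=white, dark=dark), truth


def make_sample_library(models: list[OriginModel], n_per_class: int,
                        axis: WavelengthAxis, noise_sd: float | None = None,
                        seed: int = 0) -> SpectralDataset:
    """Object-wise shortcut generator: sample spectra without image rendering.

    Each sample is its class endmember times a lognormal scatter factor plus
    i.i.d. Gaussian band noise — the same per-object variability the scene
    renderer injects, at the mean-spectrum level.  ``noise_sd`` overrides the
    per-model noise when given.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for model in models:
        endmember = make_endmember(model, axis)
        sd = model.noise_sd if noise_sd is None else noise_sd
        for _ in range(n_per_class):
            scatter = float(np.exp(rng.normal(0.0, 0.02))) if sd > 0 else 1.0
            noise = rng.normal(0.0, sd, size=len(axis)) if sd > 0 else 0.0
            rows.append(endmember * scatter + noise)
            labels.append(model.class_id)
    return SpectralDataset(np.vstack(rows), axis, y=np.array(labels))
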