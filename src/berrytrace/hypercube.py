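"""Hypercube data model, reflectance calibration and spectrum extraction.

A pushbroom NIR imager delivers a 3-D raster (``rows x cols x bands``) of raw
sensor counts together with white and dark reference frames.  Relative
reflectance is obtained per pixel and band as

    R = (I_raw - I_dark) / (I_white - I_dark)

after which bright fruit pixels are separated from the dark stage, connected
foreground components become physical samples (one berry = one sample), and
either every foreground pixel spectrum (pixel-wise analysis) or the per-object
mean spectrum (object-wise analysis) is extracted.

Coordinates are row-major and 0-based; bands are indexed 0-based internally
and reported in nm externally.  Reflectance outside [0, 1] (possible under
noise) is kept, never clipped — clipping would bias derivative spectra — and
only flagged via :func:`out_of_range_fraction`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure

__all__ = [
    "WavelengthAxis",
    "HyperCube",
    "ReferenceFrames",
    "PixelSpectraTable",
    "SampleSpectrum",
    "CalibrationError",
    "calibrate_cube",
    "mask_background",
    "segment_objects",
    "extract_pixel_spectra",
    "mean_spectra",
    "out_of_range_fraction",
]


class CalibrationError(ValueError):
    """Raised when white - dark vanishes somewhere the calibration is evaluated."""


@dataclass(frozen=True)
class WavelengthAxis:
    """Strictly increasing band-center wavelengths in nm, one per band."""

    centers_nm: np.ndarray

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers_nm, dtype=float)
        if centers.ndim != 1 or centers.size < 1:
            raise ValueError("wavelength axis needs at least one band")
        if not np.all(np.diff(centers) > 0):
            raise ValueError("wavelength axis must be strictly increasing")
        object.__setattr__(self, "centers_nm", centers)

    def __len__(self) -> int:
        return self.centers_nm.size

    @property
    def spacing_nm(self) -> float:
        """Mean band spacing in nm (the default instrument axis is uniform)."""
        return float(np.mean(np.diff(self.centers_nm)))

    def nearest_band(self, wavelength_nm: float) -> int:
        """Index of the band whose center is nearest ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.centers_nm - wavelength_nm)))

    @classmethod
    def default_instrument(cls, n_bands: int = 256, lo_nm: float = 874.0,
                           hi_nm: float = 1734.0) -> "WavelengthAxis":
        """The 256-band 874-1734 nm axis of the reference instrument."""
        return cls(np.linspace(lo_nm, hi_nm, n_bands))


@dataclass
class HyperCube:
    """3-D raster ``rows x cols x bands`` of raw counts or reflectance."""

    values: np.ndarray
    axis: WavelengthAxis
    calibrated: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("cube must be rows x cols x bands")
        if self.values.shape[2] != len(self.axis):
            raise ValueError(
                f"band dimension {self.values.shape[2]} does not match "
                f"axis length {len(self.axis)}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.values.shape[:2]


@dataclass
class ReferenceFrames:
    """White and dark reference frames.

    Frames may be full rasters (``rows x cols x bands``) or per-line frames
    (``cols x bands``) broadcast along the scan direction, the natural shape
    for a pushbroom line camera.
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.white.shape != self.dark.shape:
            raise ValueError("white and dark frames must have the same shape")
        if self.white.ndim not in (2, 3):
            raise ValueError("reference frames must be 2-D (cols x bands) or 3-D")


@dataclass
class PixelSpectraTable:
    """One row per foreground pixel: coordinates, object id and full spectrum."""

    rows: np.ndarray              # (n,) pixel row coordinates
    cols: np.ndarray              # (n,) pixel col coordinates
    object_ids: np.ndarray        # (n,) labels > 0
    spectra: np.ndarray           # (n, b) reflectance
    axis: WavelengthAxis
    class_ids: np.ndarray | None = None   # (n,) origin labels when known

    def __len__(self) -> int:
        return self.spectra.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with one column per band, named by nm."""
        data = {"row": self.rows, "col": self.cols, "object_id": self.object_ids}
        if self.class_ids is not None:
            data["class_id"] = self.class_ids
        frame = pd.DataFrame(data)
        bands = pd.DataFrame(
            self.spectra,
            columns=[f"{nm:.2f}" for nm in self.axis.centers_nm],
        )
        return pd.concat([frame, bands], axis=1)


@dataclass
class SampleSpectrum:
    """Mean reflectance spectrum of one physical object (one berry)."""

    object_id: int
    spectrum: np.ndarray
    pixel_count: int
    class_id: int | None = None


def calibrate_cube(raw: HyperCube, refs: ReferenceFrames) -> HyperCube:
    """Convert raw counts to relative reflectance using the reference frames.

    Computes ``(raw - dark) / (white - dark)`` element-wise.  Any location
    where ``white == dark`` is an error listing the offending coordinates:
    silently propagating NaN would corrupt every downstream PCA.
    """
    if raw.calibrated:
        raise ValueError("cube is already calibrated")
    white, dark = refs.white, refs.dark
    if white.ndim == 2:
        if white.shape != raw.shape[1:]:
            raise ValueError(
                f"per-line reference shape {white.shape} does not match "
                f"cube (cols, bands) {raw.shape[1:]}"
            )
    elif white.shape != raw.shape:
        raise ValueError("3-D reference shape must match the cube shape")

    denom = white - dark
    bad = np.argwhere(denom == 0)
    if bad.size:
        coords = ", ".join(str(tuple(int(v) for v in row)) for row in bad[:10])
        raise CalibrationError(
            f"white - dark is zero at {bad.shape[0]} location(s): {coords}"
            + ("..." if bad.shape[0] > 10 else "")
        )
    reflectance = (raw.values - dark) / denom
    return HyperCube(reflectance, raw.axis, calibrated=True)


def out_of_range_fraction(cube: HyperCube) -> float:
    """Fraction of reflectance values outside [0, 1] (kept, only flagged)."""
    v = cube.values
    return float(np.mean((v < 0.0) | (v > 1.0)))


def mask_background(cube: HyperCube, threshold: float = 0.15,
                    window_nm: tuple[float, float] = (1000.0, 1300.0)) -> np.ndarray:
    """Foreground mask: mean reflectance over ``window_nm`` above ``threshold``.

    Berries are bright against the dark stage across 1000-1300 nm, so a mean
    over that window separates fruit from background robustly.  Raises if the
    mask is empty (a threshold above the cube maximum is a configuration
    error, not an empty result).
    """
    if not cube.calibrated:
        raise ValueError("background masking requires a calibrated cube")
    lo = cube.axis.nearest_band(window_nm[0])
    hi = cube.axis.nearest_band(window_nm[1])
    if hi < lo:
        lo, hi = hi, lo
    mean_img = cube.values[:, :, lo:hi + 1].mean(axis=2)
    mask = mean_img > threshold
    if not mask.any():
        raise ValueError(
            f"empty foreground: no pixel exceeds threshold {threshold} "
            f"over {window_nm[0]:.0f}-{window_nm[1]:.0f} nm"
        )
    return mask


def segment_objects(mask: np.ndarray, min_pixels: int = 20) -> tuple[np.ndarray, pd.DataFrame]:
    """Label 4-connected foreground components, dropping tiny ones.

    Returns a labeled image (0 background) plus an object table with one row
    per kept component (``object_id, pixel_count, centroid_row, centroid_col``).
    Labels are 1..K in raster-scan order of each component's first pixel, so
    segmentation is deterministic and stable under relabeling upstream.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    raw_labels = measure.label(mask, connectivity=1)
    records = []
    for region in measure.regionprops(raw_labels):
        if region.area < min_pixels:
            continue
        first_pixel = min(map(tuple, region.coords))   # raster-scan order key
        records.append((first_pixel, region.label, region.area, region.centroid))
    records.sort(key=lambda r: r[0])

    labeled = np.zeros_like(raw_labels)
    rows = []
    for new_id, (_, old_label, area, centroid) in enumerate(records, start=1):
        labeled[raw_labels == old_label] = new_id
        rows.append({
            "object_id": new_id,
            "pixel_count": int(area),
            "centroid_row": centroid[0],
            "centroid_col": centroid[1],
        })
    table = pd.DataFrame(rows, columns=["object_id", "pixel_count",
                                        "centroid_row", "centroid_col"])
    return labeled, table


def extract_pixel_spectra(cube: HyperCube, labeled: np.ndarray,
                          class_map: dict[int, int] | None = None) -> PixelSpectraTable:
    """One spectrum per labeled foreground pixel (copies, not views).

    ``class_map`` optionally attaches an origin label per object id.
    """
    labeled = np.asarray(labeled)
    if labeled.shape != cube.spatial_shape:
        raise ValueError(
            f"label image shape {labeled.shape} does not match cube "
            f"spatial shape {cube.spatial_shape}"
        )
    rr, cc = np.nonzero(labeled > 0)
    obj = labeled[rr, cc].astype(int)
    spectra = cube.values[rr, cc, :].copy()
    class_ids = None
    if class_map is not None:
        class_ids = np.array([class_map[o] for o in obj], dtype=int)
    return PixelSpectraTable(rows=rr, cols=cc, object_ids=obj,
                             spectra=spectra, axis=cube.axis, class_ids=class_ids)


def mean_spectra(table: PixelSpectraTable) -> list[SampleSpectrum]:
    """Arithmetic per-band mean over each object's pixels: one spectrum per berry."""
    if len(table) == 0:
        raise ValueError("empty pixel table")
    out: list[SampleSpectrum] = []
    for object_id in np.unique(table.object_ids):
        sel = table.object_ids == object_id
        spec = table.spectra[sel].mean(axis=0)
        class_id = None
        if table.class_ids is not None:
            cids = np.unique(table.class_ids[sel])
            if cids.size != 1:
                raise ValueError(f"object {object_id} spans multiple classes")
            class_id = int(cids[0])
        out.append(SampleSpectrum(object_id=int(object_id), spectrum=spec,
                                  pixel_count=int(sel.sum()), class_id=class_id))
    return out
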