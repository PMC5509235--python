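"""Spectral-axis truncation, smoothing and derivative transforms.

The transforms are exposed in two equivalent layers:

* sklearn-compatible transformers (:class:`BandSlicer`,
  :class:`MovingAverageSmoother`, :class:`SavitzkyGolayFilter`) operating on
  plain ``(n, b)`` arrays, composable with sklearn pipelines;
* thin dataset-level functions (:func:`truncate_band_range`,
  :func:`moving_average`, :func:`savitzky_golay`) operating on
  :class:`SpectralDataset`, which keep the wavelength axis and labels aligned.

All transforms act row-wise (per spectrum) and are independent of sample
order.  Derivatives are scaled by the band spacing so their units are
reflectance per nm^deriv.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .hypercube import SampleSpectrum, WavelengthAxis

__all__ = [
    "SpectralDataset",
    "BandSlicer",
    "MovingAverageSmoother",
    "SavitzkyGolayFilter",
    "truncate_band_range",
    "moving_average",
    "savitzky_golay",
    "dataset_from_samples",
]


@dataclass
class SpectralDataset:
    """``n x b`` reflectance matrix with wavelength axis and origin labels.

    Labels follow the 4-origin coding: 1 = Ningxia, 2 = Inner Mongolia,
    3 = Sinkiang, 4 = Qinghai.  ``deriv`` records how many spectral
    derivatives have been applied, so downstream peak picking can verify it
    receives second-derivative input.
    """

    X: np.ndarray
    axis: WavelengthAxis
    y: np.ndarray | None = None
    ids: np.ndarray | None = None
    deriv: int = 0

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[1] != len(self.axis):
            raise ValueError(
                f"{self.X.shape[1]} columns but axis has {len(self.axis)} bands"
            )
        if np.isnan(self.X).any():
            raise ValueError("spectra contain missing values")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=int)
            if self.y.shape[0] != self.X.shape[0]:
                raise ValueError("label length does not match sample count")
        if self.ids is None:
            self.ids = np.arange(self.X.shape[0])
        else:
            self.ids = np.asarray(self.ids)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_bands(self) -> int:
        return self.X.shape[1]

    def subset(self, row_idx: np.ndarray) -> "SpectralDataset":
        return SpectralDataset(
            self.X[row_idx], self.axis,
            None if self.y is None else self.y[row_idx],
            self.ids[row_idx], self.deriv,
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"id": self.ids}
        if self.y is not None:
            data["class_id"] = self.y
        frame = pd.DataFrame(data)
        bands = pd.DataFrame(self.X, columns=[f"{nm:.2f}" for nm in self.axis.centers_nm])
        return pd.concat([frame, bands], axis=1)


def dataset_from_samples(samples: list[SampleSpectrum], axis: WavelengthAxis) -> SpectralDataset:
    """Stack per-object mean spectra into an object-wise dataset."""
    X = np.vstack([s.spectrum for s in samples])
    ids = np.array([s.object_id for s in samples])
    y = None
    if all(s.class_id is not None for s in samples):
        y = np.array([s.class_id for s in samples])
    return SpectralDataset(X, axis, y=y, ids=ids)


class BandSlicer(BaseEstimator, TransformerMixin):
    """Retain the contiguous band run nearest a [lo_nm, hi_nm] window.

    The retained run spans the band nearest ``lo_nm`` through the band
    nearest ``hi_nm``, inclusive.  On the reference 256-band 874-1734 nm
    axis, the 972-1609 nm fruit window keeps 190 bands.
    """

    def __init__(self, lo_nm: float = 972.0, hi_nm: float = 1609.0, *,
                 axis: WavelengthAxis | None = None):
        self.lo_nm = lo_nm
        self.hi_nm = hi_nm
        self.axis = axis

    def fit(self, X, y=None):
        if self.axis is None:
            raise ValueError("BandSlicer requires a wavelength axis")
        if self.lo_nm > self.hi_nm:
            raise ValueError("lo_nm must not exceed hi_nm")
        centers = self.axis.centers_nm
        if self.hi_nm < centers[0] or self.lo_nm > centers[-1]:
            raise ValueError("window does not intersect the wavelength axis")
        # nearest band per endpoint; a distance tie resolves toward the
        # interior of the window, so the run never widens past the request
        d_lo = np.abs(centers - self.lo_nm)
        d_hi = np.abs(centers - self.hi_nm)
        lo_band = int(np.max(np.nonzero(d_lo == d_lo.min())[0]))
        hi_band = int(np.min(np.nonzero(d_hi == d_hi.min())[0]))
        if hi_band < lo_band:
            raise ValueError("empty band window")
        self.band_slice_ = slice(lo_band, hi_band + 1)
        self.axis_out_ = WavelengthAxis(centers[self.band_slice_])
        return self

    def transform(self, X):
        check_is_fitted(self, "band_slice_")
        X = check_array(X)
        return X[:, self.band_slice_]


class MovingAverageSmoother(BaseEstimator, TransformerMixin):
    """Centered boxcar mean per spectrum; edges use shrinking windows.

    Near the spectrum ends the window is truncated to the available bands and
    the mean taken over that shrunken window, so no padding value is invented.
    """

    def __init__(self, window: int = 5):
        self.window = window

    def fit(self, X, y=None):
        X = check_array(X)
        if self.window % 2 == 0 or self.window < 1:
            raise ValueError("window must be an odd integer >= 1")
        if self.window > X.shape[1]:
            raise ValueError("window exceeds the number of bands")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = check_array(X)
        if self.window == 1:
            return X.copy()
        kernel = np.ones(self.window)
        sums = np.apply_along_axis(
            lambda r: np.convolve(r, kernel, mode="same"), 1, X)
        counts = np.convolve(np.ones(X.shape[1]), kernel, mode="same")
        return sums / counts


class SavitzkyGolayFilter(BaseEstimator, TransformerMixin):
    """Savitzky-Golay local-polynomial smoothing / derivative filter.

    Least-squares polynomial convolution of order ``polyorder`` in a centered
    window; ``deriv`` in {0, 1, 2} returns the smoothed signal or its
    derivative.  Derivatives are divided by ``delta_nm**deriv`` (the band
    spacing) so the output is per nm^deriv.  Edges are handled by polynomial
    fit extension (the fit over the terminal window is evaluated at the edge
    bands).
    """

    def __init__(self, window: int = 9, polyorder: int = 3, deriv: int = 0, *,
                 delta_nm: float | None = None):
        self.window = window
        self.polyorder = polyorder
        self.deriv = deriv
        self.delta_nm = delta_nm

    def fit(self, X, y=None):
        X = check_array(X)
        if self.window % 2 == 0 or self.window < 3:
            raise ValueError("window must be an odd integer >= 3")
        if self.polyorder >= self.window:
            raise ValueError("polyorder must be smaller than window")
        if self.deriv not in (0, 1, 2):
            raise ValueError("deriv must be 0, 1 or 2")
        if self.deriv > self.polyorder:
            raise ValueError("deriv must not exceed polyorder")
        if self.window > X.shape[1]:
            raise ValueError("window exceeds the number of bands")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = check_array(X)
        delta = 1.0 if self.delta_nm is None else self.delta_nm
        return savgol_filter(X, self.window, self.polyorder, deriv=self.deriv,
                             delta=delta, axis=1, mode="interp")


def truncate_band_range(ds: SpectralDataset, lo_nm: float, hi_nm: float) -> SpectralDataset:
    """Truncate a dataset to the nearest-band-inclusive [lo_nm, hi_nm] window."""
    slicer = BandSlicer(lo_nm, hi_nm, axis=ds.axis).fit(ds.X)
    return SpectralDataset(slicer.transform(ds.X), slicer.axis_out_,
                           ds.y, ds.ids, ds.deriv)


def moving_average(ds: SpectralDataset, window: int = 5) -> SpectralDataset:
    """Moving-average (boxcar) smoothing with shrinking edge windows."""
    sm = MovingAverageSmoother(window).fit(ds.X)
    return replace(ds, X=sm.transform(ds.X))


def savitzky_golay(ds: SpectralDataset, window: int = 9, polyorder: int = 3,
                   deriv: int = 0) -> SpectralDataset:
    """Savitzky-Golay smoothing or derivative on a dataset, scaled per nm."""
    sg = SavitzkyGolayFilter(window, polyorder, deriv,
                             delta_nm=ds.axis.spacing_nm).fit(ds.X)
    return SpectralDataset(sg.transform(ds.X), ds.axis, ds.y, ds.ids,
                           deriv=ds.deriv + deriv)
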