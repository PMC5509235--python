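"""Characteristic-wavelength selection from PCA loadings and derivative spectra.

Two classical chemometrics routes to a reduced band subset:

* **PCA loadings** — fit a mean-centered PCA, overlay the loading curves of
  the leading components against wavelength, and keep the interior peaks and
  valleys whose |loading| clears a threshold.  Large |loading| marks bands
  that carry most of the spectral variance.
* **Second-derivative spectra** — Savitzky-Golay second derivatives sharpen
  overlapping absorption bands; the peaks and valleys of the mean
  second-derivative curve mark band centers and shoulders.

Both routes share one extremum rule: a strict local max/min against both
immediate neighbours, plateaus credited to their leftmost band, edge bands
excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_array, check_is_fitted

from .hypercube import WavelengthAxis
from .preprocess import SpectralDataset

__all__ = [
    "PCAResult",
    "SelectedWavelengths",
    "SpectralPCA",
    "fit_pca",
    "local_extrema_indices",
    "pick_loading_extrema",
    "pick_derivative_extrema",
    "apply_selection",
]


@dataclass
class PCAResult:
    """Loadings, scores and explained-variance ratios of a fitted PCA."""

    loadings: np.ndarray        # (b, k), orthonormal columns
    scores: np.ndarray          # (n, k) = centered X @ loadings
    explained_ratio: np.ndarray  # (k,) fractions, non-increasing
    mean_spectrum: np.ndarray   # (b,) centering vector

    @property
    def cumulative_explained(self) -> np.ndarray:
        return np.cumsum(self.explained_ratio)


@dataclass
class SelectedWavelengths:
    """Ordered, de-duplicated band subset chosen by a selection procedure."""

    band_indices: np.ndarray
    wavelengths_nm: np.ndarray
    source: str                 # "pca_loadings" or "second_derivative"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.band_indices = np.asarray(self.band_indices, dtype=int)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.band_indices.size != np.unique(self.band_indices).size:
            raise ValueError("duplicate band indices in selection")
        if not np.all(np.diff(self.band_indices) > 0):
            raise ValueError("band indices must be sorted ascending")

    def __len__(self) -> int:
        return self.band_indices.size


class SpectralPCA(BaseEstimator, TransformerMixin):
    """Mean-centered PCA with a deterministic sign convention.

    Centering only — no variance scaling, which would distort the loading
    curves read against wavelength.  Each loading column is flipped so its
    largest-magnitude entry is positive, making loadings reproducible across
    SVD implementations (PCA is otherwise determined only up to sign).
    """

    def __init__(self, n_components: int = 5):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = check_array(X)
        n, b = X.shape
        if n < 2:
            raise ValueError("PCA needs at least two samples")
        if self.n_components > min(n - 1, b):
            raise ValueError(
                f"n_components={self.n_components} exceeds min(n-1, b)="
                f"{min(n - 1, b)}"
            )
        if np.allclose(X, X[0]):
            raise ValueError("constant data has zero variance; PCA undefined")
        pca = PCA(n_components=self.n_components, svd_solver="full")
        scores = pca.fit_transform(X)
        loadings = pca.components_.T          # (b, k)
        for j in range(loadings.shape[1]):
            i = np.argmax(np.abs(loadings[:, j]))
            if loadings[i, j] < 0:
                loadings[:, j] *= -1
                scores[:, j] *= -1
        self.loadings_ = loadings
        self.scores_ = scores
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.mean_ = pca.mean_
        return self

    def transform(self, X):
        check_is_fitted(self, "loadings_")
        X = check_array(X)
        return (X - self.mean_) @ self.loadings_

    def result_(self) -> PCAResult:
        check_is_fitted(self, "loadings_")
        return PCAResult(loadings=self.loadings_, scores=self.scores_,
                         explained_ratio=self.explained_variance_ratio_,
                         mean_spectrum=self.mean_)


def fit_pca(ds: SpectralDataset, k: int = 5) -> PCAResult:
    """Fit a k-component mean-centered PCA to a spectral dataset."""
    return SpectralPCA(n_components=k).fit(ds.X).result_()


def local_extrema_indices(v: np.ndarray, rtol: float = 1e-9) -> np.ndarray:
    """Interior strict local maxima and minima of a 1-D signal.

    A band is an extremum when it is strictly above (below) both immediate
    neighbours.  A plateau — a run of equal values strictly above (below)
    both flanking values — is credited to its leftmost band.  The two edge
    bands are never extrema.  Differences below ``rtol * max|v|`` count as
    equal, so a numerically constant curve (e.g. the second derivative of a
    quadratic) yields no spurious extrema.
    """
    v = np.asarray(v, dtype=float)
    n = v.size
    tol = rtol * float(np.max(np.abs(v), initial=0.0))
    out = []
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and abs(v[j + 1] - v[i]) <= tol:
            j += 1                      # plateau run [i, j]
        if j + 1 < n:                   # plateau has a right neighbour
            left, right = v[i - 1], v[j + 1]
            if ((v[i] > left + tol and v[i] > right + tol)
                    or (v[i] < left - tol and v[i] < right - tol)):
                out.append(i)
        i = j + 1
    return np.array(out, dtype=int)


def _threshold_extrema(curve: np.ndarray, threshold: float,
                       max_wavelengths: int | None) -> np.ndarray:
    idx = local_extrema_indices(curve)
    idx = idx[np.abs(curve[idx]) >= threshold]
    if max_wavelengths is not None and idx.size > max_wavelengths:
        keep = np.argsort(np.abs(curve[idx]))[::-1][:max_wavelengths]
        idx = np.sort(idx[keep])
    return idx


def pick_loading_extrema(pca: PCAResult, axis: WavelengthAxis,
                         n_components: int = 5, threshold: float = 0.0,
                         max_wavelengths: int | None = None) -> SelectedWavelengths:
    """Peaks and valleys of the leading loading curves above |threshold|.

    Extrema are collected per component, unioned, de-duplicated and sorted.
    The threshold applies to |loading| so peaks and valleys are treated
    symmetrically; an optional ``max_wavelengths`` cap keeps the largest
    |loading| extrema of the union.
    """
    if n_components > pca.loadings.shape[1]:
        raise ValueError("n_components exceeds fitted components")
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    chosen: dict[int, float] = {}
    for j in range(n_components):
        curve = pca.loadings[:, j]
        for i in local_extrema_indices(curve):
            mag = abs(curve[i])
            if mag >= threshold:
                chosen[i] = max(mag, chosen.get(i, 0.0))
    idx = np.array(sorted(chosen), dtype=int)
    if max_wavelengths is not None and idx.size > max_wavelengths:
        mags = np.array([chosen[i] for i in idx])
        keep = np.argsort(mags)[::-1][:max_wavelengths]
        idx = np.sort(idx[keep])
    if idx.size == 0:
        warnings.warn("loading-extremum selection is empty", stacklevel=2)
    return SelectedWavelengths(
        band_indices=idx, wavelengths_nm=axis.centers_nm[idx],
        source="pca_loadings",
        params={"n_components": n_components, "threshold": threshold,
                "max_wavelengths": max_wavelengths})


def pick_derivative_extrema(ds_d2: SpectralDataset, threshold: float = 0.0,
                            max_wavelengths: int | None = None) -> SelectedWavelengths:
    """Peaks and valleys of the mean second-derivative spectrum.

    Operates on the grand-mean curve of a second-derivative dataset (the
    per-class option is obtained by subsetting the dataset first).
    """
    if ds_d2.deriv != 2:
        raise ValueError("expected a second-derivative dataset (deriv == 2)")
    curve = ds_d2.X.mean(axis=0)
    idx = _threshold_extrema(curve, threshold, max_wavelengths)
    if idx.size == 0:
        warnings.warn("derivative-extremum selection is empty", stacklevel=2)
    return SelectedWavelengths(
        band_indices=idx, wavelengths_nm=ds_d2.axis.centers_nm[idx],
        source="second_derivative",
        params={"threshold": threshold, "max_wavelengths": max_wavelengths})


def apply_selection(ds: SpectralDataset, sel: SelectedWavelengths) -> SpectralDataset:
    """Column-subset a dataset to the selected bands; labels unchanged."""
    if sel.band_indices.size and sel.band_indices.max() >= ds.n_bands:
        raise IndexError("selection index out of range for this dataset")
    X = ds.X[:, sel.band_indices]
    axis = WavelengthAxis(ds.axis.centers_nm[sel.band_indices])
    return SpectralDataset(X, axis, ds.y, ds.ids, ds.deriv)
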