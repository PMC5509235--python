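"""File I/O: ENVI-style cubes, CSV tables, XLSX spectra ingestion.

The ENVI format pairs a plain-text header (``.hdr``) carrying geometry,
interleave and the wavelength list with a headerless binary raster.  Only
the subset needed here is implemented: BSQ/BIL/BIP interleaves of 32-bit or
64-bit IEEE floats, byte order 0, with a wavelength block.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .hypercube import HyperCube, WavelengthAxis
from .preprocess import SpectralDataset
from .wavesel import SelectedWavelengths

__all__ = [
    "write_envi",
    "read_envi",
    "write_selection",
    "read_selection",
    "write_dataset_csv",
    "read_dataset_csv",
    "read_spectra_xlsx",
]

_DTYPE_CODES = {4: np.float32, 5: np.float64}
_CODE_FOR_DTYPE = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


def write_envi(cube: HyperCube, path: str | Path, interleave: str = "bsq",
               dtype=np.float32) -> Path:
    """Write a cube as ENVI raster + ``.hdr``; returns the raster path."""
    path = Path(path)
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError("interleave must be bsq, bil or bip")
    dtype = np.dtype(dtype)
    rows, cols, bands = cube.shape
    arr = cube.values.astype(dtype)
    if interleave == "bsq":
        data = np.transpose(arr, (2, 0, 1))      # band, row, col
    elif interleave == "bil":
        data = np.transpose(arr, (0, 2, 1))      # row, band, col
    else:
        data = arr                                # row, col, band
    path.write_bytes(data.tobytes())
    wl = ", ".join(f"{w:.4f}" for w in cube.axis.centers_nm)
    header = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_CODE_FOR_DTYPE[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    path.with_suffix(path.suffix + ".hdr").write_text(header)
    return path


def _parse_header(text: str) -> dict:
    # fold the brace blocks onto single lines first
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields = {}
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, value = line.split("=", 1)
        fields[key.strip().lower()] = value.strip()
    return fields


def read_envi(path: str | Path) -> HyperCube:
    """Read an ENVI raster written by :func:`write_envi` (float BSQ/BIL/BIP)."""
    path = Path(path)
    hdr_path = path.with_suffix(path.suffix + ".hdr")
    if not hdr_path.exists():
        hdr_path = path.with_suffix(".hdr")
    fields = _parse_header(hdr_path.read_text())
    rows = int(fields["lines"])
    cols = int(fields["samples"])
    bands = int(fields["bands"])
    code = int(fields["data type"])
    if code not in _DTYPE_CODES:
        raise ValueError(f"unsupported ENVI data type {code}")
    interleave = fields.get("interleave", "bsq").lower()
    wl_match = re.search(r"\{([^}]*)\}", fields["wavelength"])
    wavelengths = np.array([float(v) for v in wl_match.group(1).split(",")])
    data = np.fromfile(path, dtype=_DTYPE_CODES[code])
    if data.size != rows * cols * bands:
        raise ValueError("raster size does not match header geometry")
    if interleave == "bsq":
        arr = data.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        arr = data.reshape(rows, bands, cols).transpose(0, 2, 1)
    elif interleave == "bip":
        arr = data.reshape(rows, cols, bands)
    else:
        raise ValueError(f"unsupported interleave {interleave!r}")
    return HyperCube(arr.astype(float), WavelengthAxis(wavelengths))


def write_selection(sel: SelectedWavelengths, path: str | Path) -> Path:
    """Serialize a wavelength selection as JSON (indices, nm, source, params)."""
    path = Path(path)
    payload = {
        "band_indices": sel.band_indices.tolist(),
        "wavelengths_nm": sel.wavelengths_nm.tolist(),
        "source": sel.source,
        "params": sel.params,
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_selection(path: str | Path) -> SelectedWavelengths:
    payload = json.loads(Path(path).read_text())
    return SelectedWavelengths(
        band_indices=np.array(payload["band_indices"], dtype=int),
        wavelengths_nm=np.array(payload["wavelengths_nm"], dtype=float),
        source=payload["source"], params=payload.get("params", {}))


def write_dataset_csv(ds: SpectralDataset, path: str | Path) -> Path:
    """CSV with id / class_id columns then one column per band named by nm."""
    path = Path(path)
    ds.to_frame().to_csv(path, index=False)
    return path


def read_dataset_csv(path: str | Path) -> SpectralDataset:
    frame = pd.read_csv(path)
    meta_cols = [c for c in ("id", "class_id") if c in frame.columns]
    band_cols = [c for c in frame.columns if c not in meta_cols]
    axis = WavelengthAxis(np.array([float(c) for c in band_cols]))
    y = frame["class_id"].to_numpy() if "class_id" in frame.columns else None
    ids = frame["id"].to_numpy() if "id" in frame.columns else None
    return SpectralDataset(frame[band_cols].to_numpy(float), axis, y=y, ids=ids)


def read_spectra_xlsx(path: str | Path, label_column: str | int | None = 0,
                      sheet: str | int = 0,
                      wavelengths_from_header: bool = True) -> SpectralDataset:
    """Ingest a spreadsheet of spectra (rows = samples) into a dataset.

    ``label_column`` names or indexes the class-label column (None when the
    sheet has no labels); every remaining numeric column is a band.  Band
    wavelengths come from the column headers when they parse as numbers,
    else an index axis 0..b-1 is used.  This is the ingestion path for
    spreadsheet exports of calibration or pixel spectra tables.
    """
    frame = pd.read_excel(path, sheet_name=sheet)
    y = None
    if label_column is not None:
        col = (frame.columns[label_column] if isinstance(label_column, int)
               else label_column)
        y = frame[col].to_numpy(int)
        frame = frame.drop(columns=[col])
    if wavelengths_from_header:
        try:
            axis_vals = np.array([float(c) for c in frame.columns])
        except (TypeError, ValueError):
            axis_vals = np.arange(frame.shape[1], dtype=float)
    else:
        axis_vals = np.arange(frame.shape[1], dtype=float)
    return SpectralDataset(frame.to_numpy(float), WavelengthAxis(axis_vals), y=y)
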