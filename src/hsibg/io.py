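"""Readers and writers for hypercubes and spectra.

Hypercubes travel as HDF5 (datasets ``/data`` float32 x*y*lambda and
``/wavelengths`` float64, plus a ``kind`` attribute) or as multi-band TIFF
(one band per wavelength; the grid rides along in the image description).
Spectra are two-column CSV tables (``wavelength_nm``, ``intensity``).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .core import Hypercube, WavelengthGrid

__all__ = [
    "write_cube_h5",
    "read_cube_h5",
    "write_cube_tiff",
    "read_cube_tiff",
    "write_spectrum_csv",
    "read_spectrum_csv",
]


def write_cube_h5(path: str | Path, cube: Hypercube) -> None:
    with h5py.File(path, "w") as h5:
        dset = h5.create_dataset("data", data=cube.data.astype(np.float32))
        dset.attrs["kind"] = cube.kind
        h5.create_dataset("wavelengths", data=cube.grid.values.astype(np.float64))


def read_cube_h5(path: str | Path) -> Hypercube:
    with h5py.File(path, "r") as h5:
        data = np.asarray(h5["data"], dtype=float)
        kind = h5["data"].attrs.get("kind", "counts")
        grid = WavelengthGrid(np.asarray(h5["wavelengths"], dtype=float))
    return Hypercube(data, grid, kind=str(kind))


def write_cube_tiff(path: str | Path, cube: Hypercube) -> None:
    # band-major layout: page k is the spatial image at wavelength k
    bands = np.moveaxis(cube.data.astype(np.float32), -1, 0)
    meta = {"wavelengths_nm": cube.grid.values.tolist(), "kind": cube.kind}
    tifffile.imwrite(path, bands, description=json.dumps(meta))


def read_cube_tiff(path: str | Path) -> Hypercube:
    with tifffile.TiffFile(path) as tif:
        bands = tif.asarray()
        meta = json.loads(tif.pages[0].description)
    data = np.moveaxis(np.asarray(bands, dtype=float), 0, -1)
    grid = WavelengthGrid(np.asarray(meta["wavelengths_nm"], dtype=float))
    return Hypercube(data, grid, kind=meta.get("kind", "counts"))


def write_spectrum_csv(path: str | Path, grid: WavelengthGrid, intensity: np.ndarray) -> None:
    intensity = np.asarray(intensity, dtype=float)
    if intensity.shape != (grid.count,):
        raise ValueError("intensity must match the wavelength grid")
    pd.DataFrame({"wavelength_nm": grid.values, "intensity": intensity}).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_spectrum_csv(path: str | Path) -> tuple[WavelengthGrid, np.ndarray]:
    table = pd.read_csv(path, float_precision="round_trip")
    missing = {"wavelength_nm", "intensity"} - set(table.columns)
    if missing:
        raise ValueError(f"spectrum CSV missing columns: {sorted(missing)}")
    grid = WavelengthGrid(table["wavelength_nm"].to_numpy(dtype=float))
    return grid, table["intensity"].to_numpy(dtype=float)
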