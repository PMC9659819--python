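"""Reading and writing of fields, amplitudes, phases and previews.

Arrays are persisted in three portable forms: ``.npy`` (bit-exact, used for
reproducibility checks), 32-bit float TIFF (interchange with imaging tools),
and 8-bit PNG previews (human inspection).  Physical metadata (wavelength,
pixel pitch) travels in a JSON sidecar next to the arrays.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import FormatError
from .propagation import ComplexField

__all__ = [
    "read_image",
    "write_array",
    "write_float_tiff",
    "write_png_preview",
    "save_field",
    "load_field",
]


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG image as a numpy array (greyscale or H x W x 3)."""
    path = Path(path)
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[..., :3]
    if arr.ndim not in (2, 3):
        raise FormatError(f"unsupported image layout {arr.shape} in {path}")
    return arr


def write_array(path, values: np.ndarray) -> Path:
    """Bit-exact ``.npy`` dump (the canonical array for determinism checks)."""
    path = Path(path)
    np.save(path, np.ascontiguousarray(values))
    return path if path.suffix == ".npy" else path.with_suffix(path.suffix + ".npy")


def write_float_tiff(path, values: np.ndarray) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(values, dtype=np.float32))
    return path


def write_png_preview(path, values: np.ndarray) -> Path:
    """8-bit PNG preview; real arrays are min-max stretched to [0, 255]."""
    path = Path(path)
    values = np.asarray(values, dtype=float)
    lo, hi = float(values.min()), float(values.max())
    stretched = np.zeros_like(values) if hi == lo else (values - lo) / (hi - lo)
    iio.imwrite(path, np.round(stretched * 255.0).astype(np.uint8))
    return path


def save_field(directory, stem: str, fld: ComplexField) -> dict:
    """Persist a complex field as amplitude/phase float TIFFs + JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    amp_path = write_float_tiff(directory / f"{stem}_amplitude.tif", fld.amplitude)
    phase_path = write_float_tiff(directory / f"{stem}_phase.tif", fld.phase)
    sidecar = directory / f"{stem}_field.json"
    sidecar.write_text(
        json.dumps(
            {
                "wavelength_m": fld.wavelength,
                "pixel_pitch_m": fld.pixel_pitch,
                "amplitude": amp_path.name,
                "phase": phase_path.name,
            },
            indent=2,
        )
    )
    return {"amplitude": str(amp_path), "phase": str(phase_path), "sidecar": str(sidecar)}


def load_field(sidecar_path) -> ComplexField:
    """Rebuild a complex field from its JSON sidecar and TIFF pair."""
    sidecar_path = Path(sidecar_path)
    meta = json.loads(sidecar_path.read_text())
    amp = tifffile.imread(sidecar_path.parent / meta["amplitude"]).astype(float)
    phase = tifffile.imread(sidecar_path.parent / meta["phase"]).astype(float)
    return ComplexField(
        values=amp * np.exp(1j * phase),
        pixel_pitch=float(meta["pixel_pitch_m"]),
        wavelength=float(meta["wavelength_m"]),
    )
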