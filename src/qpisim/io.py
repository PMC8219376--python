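"""File formats and raw-sensor preprocessing.

Complex fields and phase plates are archived in HDF5 (lossless); intensity
images go to 16-bit TIFF or PNG with an explicit scale factor and a TOML
sidecar recording the physical pitch, so a written image can always be
restored to physical units.  Raw Bayer mosaics from 10-bit CMOS sensors
are reduced to the red-site subarray (linear response at the HeNe
wavelength, no gamma), with an optional nearest-neighbour demosaic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import tifffile

from qpisim.optics import Field, GridSpec
from qpisim.plate import PhasePlate

__all__ = [
    "RawMosaic",
    "ClippingError",
    "extract_bayer_red",
    "write_field",
    "read_field",
    "write_plate",
    "read_plate",
    "write_intensity",
    "read_intensity",
    "parse_length",
]

_BAYER_RED_OFFSET = {"RGGB": (0, 0), "BGGR": (1, 1), "GRBG": (0, 1), "GBRG": (1, 0)}


class ClippingError(ValueError):
    """Raised when an integer write would silently saturate."""


@dataclass
class RawMosaic:
    """Raw 10-bit Bayer mosaic straight off the sensor."""

    values: np.ndarray
    bayer_pattern: str = "RGGB"
    bit_depth: int = 10

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("raw mosaic must be an integer array")
        if self.bayer_pattern not in _BAYER_RED_OFFSET:
            raise ValueError(f"unknown Bayer pattern {self.bayer_pattern!r}")
        if self.values.ndim != 2 or any(s % 2 for s in self.values.shape):
            raise ValueError("mosaic must be 2D with even dimensions")
        top = 2**self.bit_depth - 1
        if self.values.min() < 0 or self.values.max() > top:
            raise ValueError(
                f"mosaic values outside the {self.bit_depth}-bit range [0, {top}]"
            )


def extract_bayer_red(raw: RawMosaic, demosaic: bool = False) -> np.ndarray:
    """Red-site intensities from a Bayer mosaic, as linear floats.

    By default the half-resolution red subarray is returned unsmoothed
    (phase retrieval wants linear, uninterpolated samples); ``demosaic``
    upsamples back to the full mosaic size by nearest neighbour.
    """
    r0, c0 = _BAYER_RED_OFFSET[raw.bayer_pattern]
    red = raw.values[r0::2, c0::2].astype(float)
    if demosaic:
        red = np.repeat(np.repeat(red, 2, axis=0), 2, axis=1)
    return red


def write_field(path: str | Path, field: Field) -> None:
    """Archive a complex field losslessly (real/imag datasets + grid attrs)."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("real", data=field.values.real)
        h5.create_dataset("imag", data=field.values.imag)
        h5.attrs["pitch_m"] = field.grid.pitch
        h5.attrs["wavelength_m"] = field.grid.wavelength
        h5.attrs["plane_label"] = field.plane_label


def read_field(path: str | Path) -> Field:
    with h5py.File(path, "r") as h5:
        values = h5["real"][()] + 1j * h5["imag"][()]
        grid = GridSpec(values.shape[0], float(h5.attrs["pitch_m"]), float(h5.attrs["wavelength_m"]))
        return Field(grid, values, str(h5.attrs["plane_label"]))


def write_plate(path: str | Path, plate: PhasePlate) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("phase", data=plate.phase_map)
        h5.attrs["pitch_m"] = plate.grid.pitch
        h5.attrs["wavelength_m"] = plate.grid.wavelength
        h5.attrs["design_kind"] = plate.design_kind
        h5.attrs["quantisation_factor"] = plate.quantisation_factor
        h5.attrs["seed"] = plate.seed


def read_plate(path: str | Path) -> PhasePlate:
    with h5py.File(path, "r") as h5:
        phase = h5["phase"][()]
        grid = GridSpec(phase.shape[0], float(h5.attrs["pitch_m"]), float(h5.attrs["wavelength_m"]))
        return PhasePlate(
            grid,
            phase,
            str(h5.attrs["design_kind"]),
            int(h5.attrs["quantisation_factor"]),
            int(h5.attrs["seed"]),
        )


def write_intensity(
    path: str | Path,
    image: np.ndarray,
    pitch: float,
    scale: float | None = None,
) -> None:
    """Write an intensity image as 16-bit TIFF/PNG plus a TOML sidecar.

    ``scale`` maps physical intensity to integer counts; by default the
    image maximum maps to 65535.  If the scaled image would exceed 16 bits
    a :class:`ClippingError` is raised rather than saturating silently.
    The sidecar ``<path>.toml`` records pitch and scale for exact reading.
    """
    path = Path(path)
    image = np.asarray(image, dtype=float)
    if np.any(image < 0):
        raise ValueError("intensity must be non-negative")
    if scale is None:
        scale = 65535.0 / image.max() if image.max() > 0 else 1.0
    scaled = image * scale
    if scaled.max() > 65535.0 * (1 + 1e-12):
        raise ClippingError(
            f"scaled maximum {scaled.max():.1f} exceeds 65535; pass a smaller scale"
        )
    counts = np.round(scaled).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, counts)
    elif path.suffix.lower() == ".png":
        iio.imwrite(path, counts)
    else:
        raise ValueError(f"unsupported intensity format {path.suffix!r}")
    sidecar = path.with_name(path.name + ".toml")
    sidecar.write_text(
        f"pitch_m = {float(pitch)!r}\nscale = {float(scale)!r}\n", encoding="utf-8"
    )


def read_intensity(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an intensity image and restore physical units from its sidecar."""
    import tomllib

    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        counts = tifffile.imread(path)
    else:
        counts = iio.imread(path)
    meta = tomllib.loads(path.with_name(path.name + ".toml").read_text(encoding="utf-8"))
    return counts.astype(float) / float(meta["scale"]), float(meta["pitch_m"])


_UNITS = {"m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "nm": 1e-9}


def parse_length(text: str | float) -> float:
    """Parse a length with unit suffix ('100mm', '1.12um', '632.8nm') to metres."""
    if isinstance(text, (int, float)):
        return float(text)
    match = re.fullmatch(r"\s*([0-9.eE+-]+)\s*(m|mm|um|µm|nm)?\s*", text)
    if not match:
        raise ValueError(f"cannot parse length {text!r}")
    value = float(match.group(1))
    unit = match.group(2) or "m"
    return value * _UNITS[unit]
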