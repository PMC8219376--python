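"""Physically scaled scalar-diffraction engine.

All propagation is paraxial and monochromatic.  Two primitives cover the
simulated architectures:

* :func:`scaled_fourier_transform` — the Fraunhofer/lens transform with
  explicit pixel-pitch bookkeeping, so that an array at the Fourier plane
  carries the physical element size ``lam * f / (N * dx)``.
* :func:`fresnel_propagate` — near-field propagation over a distance ``z``,
  using the transfer-function (convolutional) method below the critical
  distance ``z_crit = N * dx**2 / lam`` and the quadratic-phase (single
  transform) method above it.

Transforms are centred (shift–transform–shift) and orthonormal, so Parseval
holds exactly and every forward operation has an exact numerical inverse.
The optical axis sits at array index ``(N // 2, N // 2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np

__all__ = [
    "GridSpec",
    "Field",
    "SamplingViolationError",
    "scaled_fourier_transform",
    "critical_distance",
    "fresnel_propagate",
    "resample_intensity",
]

PLANE_LABELS = ("object", "plate", "fourier_2f", "image_4f", "sensor")


class SamplingViolationError(ValueError):
    """Raised when a propagation step would alias on the requested grid."""


@dataclass(frozen=True)
class GridSpec:
    """Sampling contract of a square complex-field array.

    Parameters
    ----------
    n_pixels:
        Number of samples per side (even, >= 8).
    pitch:
        Physical size of one array element in metres.
    wavelength:
        Illumination wavelength in metres.
    """

    n_pixels: int
    pitch: float
    wavelength: float

    def __post_init__(self) -> None:
        if self.n_pixels < 8 or self.n_pixels % 2 != 0:
            raise ValueError(f"n_pixels must be even and >= 8, got {self.n_pixels}")
        if not self.pitch > 0:
            raise ValueError(f"pitch must be positive, got {self.pitch}")
        if not self.wavelength > 0:
            raise ValueError(f"wavelength must be positive, got {self.wavelength}")

    @property
    def side_length(self) -> float:
        """Physical side length ``L = N * pitch`` in metres."""
        return self.n_pixels * self.pitch

    def with_pitch(self, pitch: float) -> "GridSpec":
        return replace(self, pitch=pitch)

    def coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """Centred physical coordinates (y, x) of every pixel centre, metres.

        The optical axis (0, 0) falls on index ``(N//2, N//2)``; the row
        coordinate increases downward.
        """
        idx = np.arange(self.n_pixels) - self.n_pixels // 2
        c = idx * self.pitch
        return c[:, None], c[None, :]

    def frequencies(self) -> tuple[np.ndarray, np.ndarray]:
        """Centred spatial frequencies (fy, fx) in cycles per metre."""
        f = np.fft.fftshift(np.fft.fftfreq(self.n_pixels, d=self.pitch))
        return f[:, None], f[None, :]


@dataclass
class Field:
    """A sampled complex optical field ``E = A * exp(i * phi)`` at one plane."""

    grid: GridSpec
    values: np.ndarray
    plane_label: str = "object"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        n = self.grid.n_pixels
        if self.values.shape != (n, n):
            raise ValueError(
                f"field array shape {self.values.shape} does not match grid ({n}, {n})"
            )
        if not np.all(np.isfinite(self.values.view(np.float64))):
            raise ValueError("field contains non-finite values")
        if self.plane_label not in PLANE_LABELS:
            raise ValueError(f"unknown plane label {self.plane_label!r}")

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.values)

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.values) ** 2

    @property
    def energy(self) -> float:
        """Total energy ``sum |E|^2`` (array units)."""
        return float(np.sum(np.abs(self.values) ** 2))

    def copy(self) -> "Field":
        return Field(self.grid, self.values.copy(), self.plane_label)


def _cfft2(values: np.ndarray) -> np.ndarray:
    """Centred orthonormal forward FFT."""
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(values), norm="ortho"))


def _cifft2(values: np.ndarray) -> np.ndarray:
    """Centred orthonormal inverse FFT."""
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(values), norm="ortho"))


def scaled_fourier_transform(
    field: Field,
    focal_length: float,
    inverse: bool = False,
    plane_label: str | None = None,
) -> Field:
    """Optical Fourier transform performed by a lens of given focal length.

    The output grid pitch follows the lens scaling law
    ``pitch_out = lam * f / (N * pitch_in)``: the array at the focal plane
    of a lens spans ``lam * f / pitch_in`` with element size ``pitch_out``.
    The transform is orthonormal (energy preserving) and centred, and
    ``inverse=True`` exactly undoes the forward transform, restoring the
    original grid.
    """
    if not focal_length > 0:
        raise ValueError(f"focal length must be positive, got {focal_length}")
    g = field.grid
    out_pitch = g.wavelength * focal_length / (g.n_pixels * g.pitch)
    values = _cifft2(field.values) if inverse else _cfft2(field.values)
    return Field(
        g.with_pitch(out_pitch),
        values,
        plane_label if plane_label is not None else field.plane_label,
    )


def critical_distance(grid: GridSpec) -> float:
    """Critical propagation distance ``z_crit = N * pitch**2 / wavelength``.

    Below this distance the convolutional Fresnel method is adequately
    sampled; above it the quadratic-phase method must be used.
    """
    return grid.n_pixels * grid.pitch**2 / grid.wavelength


def _fresnel_transfer(field: Field, distance: float, backward: bool) -> Field:
    """Transfer-function (convolutional) Fresnel propagation.

    Unimodular kernel in the frequency domain; preserves the grid and the
    total energy.  The backward direction applies the conjugated kernel so
    that backward(forward(E)) is numerically exact.
    """
    g = field.grid
    fy, fx = g.frequencies()
    kernel = np.exp(-1j * np.pi * g.wavelength * distance * (fx**2 + fy**2))
    if backward:
        kernel = np.conj(kernel)
    values = _cifft2(kernel * _cfft2(field.values))
    return Field(g, values, field.plane_label)


def _fresnel_single_ft(field: Field, distance: float, backward: bool) -> Field:
    """Quadratic-phase-factor (single-transform) Fresnel propagation.

    Rescales the grid to ``pitch_out = lam * z / (N * pitch_in)``; used for
    distances beyond the critical distance, where that pitch is no finer
    than the input pitch.  Constant prefactors (piston phase, 1/(i lam z))
    are dropped: the operation is kept unitary so that energy bookkeeping
    and exact inversion hold.
    """
    g = field.grid
    lam_z = g.wavelength * distance
    out_pitch = lam_z / (g.n_pixels * g.pitch)
    # the near (pre-propagation) plane carries the finer pitch; the far
    # plane must be no finer, i.e. z >= z_crit of the near grid
    near_pitch, far_pitch = (
        (out_pitch, g.pitch) if backward else (g.pitch, out_pitch)
    )
    if far_pitch < near_pitch * (1 - 1e-12):
        raise SamplingViolationError(
            "quadratic-phase Fresnel step under-samples the far plane: "
            f"far pitch {far_pitch:.4g} m < near pitch {near_pitch:.4g} m "
            f"(ratio {far_pitch / near_pitch:.4g}); use the convolutional "
            "method below the critical distance"
        )
    out_grid = g.with_pitch(out_pitch)
    yy, xx = g.coordinates()
    chirp_here = np.exp(1j * np.pi * (xx**2 + yy**2) / lam_z)
    uu, vv = out_grid.coordinates()
    chirp_there = np.exp(1j * np.pi * (uu**2 + vv**2) / lam_z)
    # the 1/i prefactor of the Fresnel integral is kept (as a global -i) so
    # that this branch agrees in phase with the transfer-function branch;
    # the 1/(lam z) magnitude is absorbed by the orthonormal FFT + rescaled
    # pitch, and the piston exp(ikz) is dropped in both branches alike
    if backward:
        # exact inverse of the forward chain: conjugate chirps, inverse FFT
        values = 1j * np.conj(chirp_there) * _cifft2(np.conj(chirp_here) * field.values)
    else:
        values = -1j * chirp_there * _cfft2(chirp_here * field.values)
    return Field(out_grid, values, field.plane_label)


def fresnel_propagate(
    field: Field,
    distance: float,
    direction: str = "forward",
    method: str | None = None,
) -> Field:
    """Paraxial (Fresnel) propagation over ``distance`` metres.

    ``distance`` at or below the critical distance of the grid uses the
    convolutional (transfer-function) method, which preserves the grid and
    energy; longer distances use the quadratic-phase method, which rescales
    the grid.  ``direction="backward"`` applies the conjugated kernels and
    exactly inverts the forward step at the same distance.

    ``method`` may force ``"transfer"`` or ``"single_ft"``; this is needed
    to invert a quadratic-phase step, because from the coarse far-plane
    grid the automatic pitch-based dispatch cannot tell the two regimes
    apart (the far grid's critical distance always exceeds the step).
    """
    if direction not in ("forward", "backward"):
        raise ValueError(f"direction must be 'forward' or 'backward', got {direction!r}")
    if distance < 0:
        raise ValueError(f"distance must be non-negative, got {distance}")
    if distance == 0:
        return field.copy()
    backward = direction == "backward"
    if method is None:
        method = "transfer" if distance <= critical_distance(field.grid) else "single_ft"
    if method == "transfer":
        return _fresnel_transfer(field, distance, backward)
    if method == "single_ft":
        return _fresnel_single_ft(field, distance, backward)
    raise ValueError(f"unknown Fresnel method {method!r}")


def resample_intensity(
    image: np.ndarray, pitch: float, target_pitch: float
) -> tuple[np.ndarray, float]:
    """Downsample an intensity image to a coarser sensor pitch.

    The target pitch must be an integer multiple of the source pitch.  Each
    block of ``k x k`` source pixels is summed (box average times block
    area), so the total energy is conserved exactly; a factor of 1 is the
    identity.
    """
    ratio = target_pitch / pitch
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9 or k < 1:
        raise ValueError(
            f"target pitch {target_pitch:.6g} m is not an integer multiple "
            f"of source pitch {pitch:.6g} m (ratio {ratio:.6g})"
        )
    if k == 1:
        return np.asarray(image, dtype=float).copy(), pitch
    n_r, n_c = image.shape
    if n_r % k or n_c % k:
        raise ValueError(f"image shape {image.shape} not divisible by factor {k}")
    blocked = np.asarray(image, dtype=float).reshape(n_r // k, k, n_c // k, k)
    return blocked.sum(axis=(1, 3)), target_pitch
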