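"""4f-correlator simulation, Gerchberg-Saxton retrieval and axial calibration.

The object field passes two lens Fourier transforms: object -> (f1) ->
Fourier (2f) plane -> (f2) -> image (4f) plane, with intensity sensors at
2f and 4f.  Axial sensor misalignment is modelled as an extra Fresnel step
of ``dz * f`` between the nominal plane and the sensor; lateral
misalignment as an integer pixel roll.

Phase retrieval from the two intensities uses the Gerchberg-Saxton
algorithm (alternating amplitude projections between the Fourier-related
planes).  When the axial offsets are known, a modified retrieval inserts
the corresponding Fresnel steps, ramping the assumed distance linearly
from zero to its true value over the early iterations to avoid the
stagnation that full Fresnel constraints cause from a cold start.

The offsets themselves are estimated from a known calibration field (a
pinhole) by minimising the round-trip reconstruction error with a
golden-section / Brent bounded search, as a one-off calibration step.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage, optimize

from qpisim.metrics import RecoveryReport
from qpisim.optics import (
    Field,
    GridSpec,
    fresnel_propagate,
    resample_intensity,
    scaled_fourier_transform,
)

__all__ = [
    "FourfGeometry",
    "RetrievalConfig",
    "CalibrationResult",
    "FourfIntensities",
    "simulate_fourf",
    "ideal_image_field",
    "gs_retrieve",
    "gs_retrieve_misaligned",
    "roundtrip_error",
    "calibrate_axial",
    "find_optical_centre",
    "symmetric_crop",
]

MAX_DZ_FRACTION = 0.5  # beyond this the paraxial misalignment model is out of range


@dataclass(frozen=True)
class FourfGeometry:
    """Focal lengths and sensor misalignment of a 4f correlator.

    Axial offsets ``dz_2f`` / ``dz_4f`` are signed fractions of the focal
    length (the convention used for all tolerance figures); lateral offsets
    are integer pixel rolls of the sensor image.
    """

    f1: float
    f2: float | None = None
    dz_2f: float = 0.0
    dz_4f: float = 0.0
    lateral_2f: tuple[int, int] = (0, 0)
    lateral_4f: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.f2 is None:
            object.__setattr__(self, "f2", self.f1)
        if not (self.f1 > 0 and self.f2 > 0):
            raise ValueError("focal lengths must be positive")
        for name in ("dz_2f", "dz_4f"):
            if abs(getattr(self, name)) > MAX_DZ_FRACTION:
                raise ValueError(
                    f"|{name}| = {abs(getattr(self, name))} exceeds the supported "
                    f"range of {MAX_DZ_FRACTION} focal lengths"
                )


@dataclass(frozen=True)
class RetrievalConfig:
    """Iteration control for the retrieval algorithms."""

    max_iterations: int = 200
    #: initial portion of iterations run with dz' = 0 (plain GS), letting the
    #: well-conditioned Fourier-pair problem converge before the Fresnel
    #: constraint is introduced
    hold_fraction: float = 0.4
    #: portion of iterations over which the assumed Fresnel distance then
    #: grows linearly from 0 to the true dz; it is held at dz afterwards
    ramp_fraction: float = 0.3
    #: stop when the relative change of the sensor-amplitude error falls
    #: below this
    tolerance: float = 1e-6
    initial_phase: str = "zeros"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not 0 <= self.ramp_fraction <= 1:
            raise ValueError("ramp_fraction must lie in [0, 1]")
        if not 0 <= self.hold_fraction <= 1 - self.ramp_fraction:
            raise ValueError("hold_fraction must lie in [0, 1 - ramp_fraction]")
        if self.tolerance < 0:
            raise ValueError("tolerance must be non-negative")
        if self.initial_phase not in ("zeros", "random"):
            raise ValueError("initial_phase must be 'zeros' or 'random'")


@dataclass
class CalibrationResult:
    """Outcome of the axial-misalignment calibration search."""

    dz_2f_hat: float
    dz_4f_hat: float
    epsilon_min: float
    epsilon_trace: list[tuple[float, float]] = dc_field(default_factory=list)
    bracket_width: float = np.nan
    flat_warning: bool = False


@dataclass(frozen=True)
class FourfIntensities:
    """The two recorded sensor images with their physical pitches."""

    i_2f: np.ndarray
    pitch_2f: float
    i_4f: np.ndarray
    pitch_4f: float


def _prop_signed(field: Field, distance: float) -> Field:
    """Fresnel step of signed distance (negative = toward the lens)."""
    if distance >= 0:
        return fresnel_propagate(field, distance, "forward")
    return fresnel_propagate(field, -distance, "backward")


def simulate_fourf(
    input_field: Field,
    geometry: FourfGeometry,
    sensor_grid: GridSpec | None = None,
) -> FourfIntensities:
    """Propagate an object field to both sensors of the 4f system.

    Returns the 2f (Fourier-plane) and 4f (image-plane) intensities,
    optionally box-downsampled to a coarser sensor pitch.  With zero
    misalignment the 4f intensity is the 180-degree-rotated object
    intensity and the 2f intensity the scaled Fourier intensity.
    """
    e_2f = scaled_fourier_transform(input_field, geometry.f1, plane_label="fourier_2f")
    e_2f_sensor = _prop_signed(e_2f, geometry.dz_2f * geometry.f1)
    i_2f = np.roll(e_2f_sensor.intensity, geometry.lateral_2f, axis=(0, 1))

    e_4f = scaled_fourier_transform(e_2f, geometry.f2, plane_label="image_4f")
    e_4f_sensor = _prop_signed(e_4f, geometry.dz_4f * geometry.f2)
    i_4f = np.roll(e_4f_sensor.intensity, geometry.lateral_4f, axis=(0, 1))

    pitch_2f, pitch_4f = e_2f_sensor.grid.pitch, e_4f_sensor.grid.pitch
    if sensor_grid is not None:
        i_2f, pitch_2f = resample_intensity(i_2f, pitch_2f, sensor_grid.pitch)
        i_4f, pitch_4f = resample_intensity(i_4f, pitch_4f, sensor_grid.pitch)
    return FourfIntensities(i_2f, pitch_2f, i_4f, pitch_4f)


def ideal_image_field(input_field: Field, geometry: FourfGeometry) -> Field:
    """Ground-truth field at the nominal 4f plane (the 180-deg rotated object)."""
    e_2f = scaled_fourier_transform(input_field, geometry.f1, plane_label="fourier_2f")
    return scaled_fourier_transform(e_2f, geometry.f2, plane_label="image_4f")


def _check_intensities(i_2f: np.ndarray, i_4f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    i_2f = np.asarray(i_2f, dtype=float)
    i_4f = np.asarray(i_4f, dtype=float)
    if i_2f.shape != i_4f.shape:
        raise ValueError(f"intensity shapes differ: {i_2f.shape} vs {i_4f.shape}")
    if np.any(i_2f < 0) or np.any(i_4f < 0):
        raise ValueError("intensities must be non-negative")
    if not (i_2f.any() and i_4f.any()):
        raise ValueError("all-zero intensity image")
    return i_2f, i_4f


def _grid_4f(i_4f: np.ndarray, pitch_4f: float, wavelength: float) -> GridSpec:
    return GridSpec(i_4f.shape[0], pitch_4f, wavelength)


def _initial_phase(shape: tuple[int, int], config: RetrievalConfig) -> np.ndarray:
    if config.initial_phase == "zeros":
        return np.zeros(shape)
    rng = np.random.default_rng(config.seed)
    return rng.uniform(0, 2 * np.pi, size=shape)


def gs_retrieve(
    intensities: FourfIntensities,
    geometry: FourfGeometry,
    config: RetrievalConfig = RetrievalConfig(),
    wavelength: float = 632.8e-9,
) -> tuple[Field, RecoveryReport]:
    """Plain Gerchberg-Saxton retrieval from the 2f and 4f intensities.

    Alternates between the two planes, enforcing the measured amplitude at
    each; the tracked sensor-amplitude error (at the 4f plane, before the
    projection) is non-increasing.  The returned field carries amplitude
    ``sqrt(I_4f)`` exactly, with the retrieved phase.
    """
    return gs_retrieve_misaligned(
        intensities,
        FourfGeometry(geometry.f1, geometry.f2),  # dz forced to zero
        config,
        wavelength,
    )


def gs_retrieve_misaligned(
    intensities: FourfIntensities,
    geometry: FourfGeometry,
    config: RetrievalConfig = RetrievalConfig(),
    wavelength: float = 632.8e-9,
) -> tuple[Field, RecoveryReport]:
    """Misalignment-corrected Gerchberg-Saxton retrieval.

    ``geometry`` carries the (calibrated) axial offsets.  The assumed
    Fresnel distance dz' is held at 0 for the first ``hold_fraction`` of
    the iterations (plain GS builds a good phase estimate first), then
    ramped linearly up to the true dz over the next ``ramp_fraction``, and
    held at dz for the remainder.  With dz = 0 the procedure is identical
    to :func:`gs_retrieve`.

    Returns the corrected field estimate at the *nominal* 4f plane (the
    final sensor-amplitude projection back-propagated by dz) and a report
    with the per-iteration error trace.
    """
    i_2f, i_4f = _check_intensities(intensities.i_2f, intensities.i_4f)
    a_2f, a_4f = np.sqrt(i_2f), np.sqrt(i_4f)
    grid4 = _grid_4f(i_4f, intensities.pitch_4f, wavelength)
    dz2 = geometry.dz_2f * geometry.f1
    dz4 = geometry.dz_4f * geometry.f2

    e_4s = Field(grid4, a_4f * np.exp(1j * _initial_phase(a_4f.shape, config)), "image_4f")
    hold_iters = int(round(config.hold_fraction * config.max_iterations))
    ramp_iters = max(1, int(round(config.ramp_fraction * config.max_iterations)))
    errors: list[float] = []
    converged = False
    norm4 = float(np.sum(i_4f))
    r = 0.0
    for it in range(1, config.max_iterations + 1):
        if dz2 or dz4:
            r = 0.0 if it <= hold_iters else min(1.0, (it - hold_iters) / ramp_iters)
        else:
            r = 0.0
        e_4 = _prop_signed(e_4s, -r * dz4)
        e_2 = scaled_fourier_transform(e_4, geometry.f2, inverse=True, plane_label="fourier_2f")
        e_2s = _prop_signed(e_2, r * dz2)
        e_2s = Field(e_2s.grid, a_2f * np.exp(1j * np.angle(e_2s.values)), "fourier_2f")
        e_2 = _prop_signed(e_2s, -r * dz2)
        e_4 = scaled_fourier_transform(e_2, geometry.f2, plane_label="image_4f")
        e_4s_new = _prop_signed(e_4, r * dz4)
        err = float(np.sum((np.abs(e_4s_new.values) - a_4f) ** 2) / norm4)
        errors.append(err)
        e_4s = Field(grid4, a_4f * np.exp(1j * np.angle(e_4s_new.values)), "image_4f")
        if err < 1e-15:
            converged = True
            break
        ramp_done = it >= hold_iters + ramp_iters or not (dz2 or dz4)
        if (
            len(errors) >= 2
            and ramp_done
            and abs(errors[-2] - errors[-1]) <= config.tolerance * max(errors[-2], 1e-300)
        ):
            converged = True
            break
    result = _prop_signed(e_4s, -r * dz4)
    report = RecoveryReport(
        mse_aligned=None,
        mse_raw=None,
        iterations_run=len(errors),
        error_trace=errors,
        converged=converged,
    )
    return result, report


def roundtrip_error(
    e_in: Field,
    intensities: FourfIntensities,
    geometry: FourfGeometry,
    dz_2f_candidate: float,
    dz_4f_candidate: float,
) -> float:
    """Round-trip reconstruction error for candidate axial offsets (metres).

    The known calibration field at the nominal 4f plane is propagated to
    each displaced sensor with the candidate distance, its amplitude is
    replaced by the measurement, and it is propagated back; after passing
    both planes the disagreement ``sum ||E_in - E_out||^2`` is returned.
    The error vanishes when the candidates equal the true offsets, because
    each amplitude replacement then leaves the field untouched.
    """
    if e_in.energy == 0:
        raise ValueError("calibration field has zero energy (degenerate minimum)")
    i_2f, i_4f = _check_intensities(intensities.i_2f, intensities.i_4f)
    a_2f, a_4f = np.sqrt(i_2f), np.sqrt(i_4f)

    e = _prop_signed(e_in, dz_4f_candidate)
    e = Field(e.grid, a_4f * np.exp(1j * np.angle(e.values)), e.plane_label)
    e = _prop_signed(e, -dz_4f_candidate)
    e = scaled_fourier_transform(e, geometry.f2, inverse=True, plane_label="fourier_2f")
    e = _prop_signed(e, dz_2f_candidate)
    e = Field(e.grid, a_2f * np.exp(1j * np.angle(e.values)), e.plane_label)
    e = _prop_signed(e, -dz_2f_candidate)
    e_out = scaled_fourier_transform(e, geometry.f2, plane_label="image_4f")
    return float(np.sum(np.abs(e_in.values - e_out.values) ** 2))


def calibrate_axial(
    e_in: Field,
    intensities: FourfIntensities,
    geometry: FourfGeometry,
    which: str = "sensor_2f",
    bounds: tuple[float, float] = (0.0, 0.2),
    xatol_fraction: float = 1e-4,
) -> CalibrationResult:
    """Estimate axial sensor offsets by minimising the round-trip error.

    A bounded golden-section/Brent search runs over non-negative dz
    (fractions of f within ``bounds``): +dz and -dz of the 4f sensor are
    degenerate up to a global parabolic phase, so only the magnitude is
    identifiable.  ``which`` selects ``sensor_2f``, ``sensor_4f`` (the
    other offset held at zero) or ``both`` (three alternating 1-D passes).
    """
    if which not in ("sensor_2f", "sensor_4f", "both"):
        raise ValueError(f"which must be sensor_2f, sensor_4f or both, got {which!r}")
    f = geometry.f1
    trace: list[tuple[float, float]] = []

    def eps_at(dz2_frac: float, dz4_frac: float) -> float:
        val = roundtrip_error(e_in, intensities, geometry, dz2_frac * f, dz4_frac * f)
        return val

    def minimise(objective) -> tuple[float, float]:
        # epsilon carries few-percent Fresnel ripples away from its global
        # minimum, so bracket the basin on a coarse grid first, then refine
        # with a bounded golden-section/Brent search inside the bracket
        grid_points = np.linspace(bounds[0], bounds[1], 33)
        values = [objective(x) for x in grid_points]
        best = int(np.argmin(values))
        lo = grid_points[max(best - 1, 0)]
        hi = grid_points[min(best + 1, len(grid_points) - 1)]
        res = optimize.minimize_scalar(
            objective,
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": xatol_fraction},
        )
        return float(res.x), float(res.fun)

    dz2_hat = dz4_hat = 0.0
    if which == "both":
        for _ in range(3):
            dz2_hat, _fun = minimise(lambda x: _traced(trace, x, eps_at(x, dz4_hat)))
            dz4_hat, eps_min = minimise(lambda x: _traced(trace, x, eps_at(dz2_hat, x)))
    elif which == "sensor_2f":
        dz2_hat, eps_min = minimise(lambda x: _traced(trace, x, eps_at(x, 0.0)))
    else:
        dz4_hat, eps_min = minimise(lambda x: _traced(trace, x, eps_at(0.0, x)))

    eps_values = [v for _, v in trace]
    spread = max(eps_values) - min(eps_values)
    flat = spread <= 1e-9 * max(max(eps_values), 1e-300)
    return CalibrationResult(
        dz_2f_hat=dz2_hat,
        dz_4f_hat=dz4_hat,
        epsilon_min=float(eps_min),
        epsilon_trace=trace,
        bracket_width=xatol_fraction,
        flat_warning=bool(flat),
    )


def _traced(trace: list[tuple[float, float]], x: float, value: float) -> float:
    trace.append((float(x), float(value)))
    return value


def find_optical_centre(image: np.ndarray) -> tuple[float, float]:
    """Intensity centroid of the dominant spot, after thresholding at 50% peak."""
    image = np.asarray(image, dtype=float)
    peak = image.max()
    if peak <= 0:
        raise ValueError("image has no positive pixels")
    masked = np.where(image >= 0.5 * peak, image, 0.0)
    row, col = ndimage.center_of_mass(masked)
    return float(row), float(col)


def symmetric_crop(
    images: list[np.ndarray], centres: list[tuple[float, float]]
) -> list[np.ndarray]:
    """Co-register sensor images by symmetric cropping about their centres.

    Each image is cropped to the largest even window centred on its optical
    centre that fits inside every image, so the returned arrays share one
    shape with their centres co-located at the array midpoint.
    """
    if len(images) != len(centres):
        raise ValueError("need one centre per image")
    rounded = [(int(round(r)), int(round(c))) for r, c in centres]
    half: list[int] = []
    for axis in (0, 1):
        h = min(
            min(centre[axis], image.shape[axis] - centre[axis])
            for image, centre in zip(images, rounded)
        )
        half.append(h)
    out = []
    for image, (r, c) in zip(images, rounded):
        out.append(image[r - half[0] : r + half[0], c - half[1] : c + half[1]].copy())
    return out
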