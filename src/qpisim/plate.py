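"""Phase-plate single-sensor architecture: design, forward model, recovery.

The object field propagates a short distance ``d``, is modulated by a known
phase plate, and a single lens forms the Fourier transform of the modulated
field on one intensity sensor.  Two plate designs are provided:

* **random** — i.i.d. uniform [0, 2pi) phase per plate pixel;
* **holographic** — a phase-only superposition of four component holograms
  (two random, one flat, one Fresnel lens), each offset by a blazed grating
  so its replay field lands in a different sensor quadrant.  The flat
  component replays the object's Fourier spectrum and the Fresnel-lens
  component an approximate image of the object plane, so the raw sensor
  image is interpretable without reconstruction.

Recovery iterates between the sensor (measured-amplitude constraint) and
the plate plane, where the plate phase is divided out and a resolution
constraint (central K x K spatial-frequency support) is applied: phase
becomes recoverable from a single intensity image at the cost of
resolution.  Manufacturing perturbations — phase quantisation to larger
plate pixels, Gaussian phase noise, lateral and axial translation — are
modelled so their impact on recovery can be swept.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np

from qpisim.metrics import RecoveryReport, recovery_mse
from qpisim.optics import (
    Field,
    GridSpec,
    fresnel_propagate,
    resample_intensity,
    scaled_fourier_transform,
    _cfft2,
    _cifft2,
)

__all__ = [
    "PhasePlate",
    "PlateGeometry",
    "PlateRecoveryConfig",
    "SensorImage",
    "design_random_plate",
    "design_holographic_plate",
    "quantise_plate",
    "perturb_plate",
    "lateral_fraction_to_pixels",
    "simulate_plate_system",
    "recover_plate",
    "phasor_mse",
]

TWO_PI = 2 * np.pi


@dataclass
class PhasePlate:
    """A transmissive plate imposing a known phase map (radians, [0, 2pi))."""

    grid: GridSpec
    phase_map: np.ndarray
    design_kind: str = "random"
    quantisation_factor: int = 1
    seed: int = 0
    component_params: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phase_map = np.asarray(self.phase_map, dtype=float)
        n = self.grid.n_pixels
        if self.phase_map.shape != (n, n):
            raise ValueError(
                f"phase map shape {self.phase_map.shape} does not match grid ({n}, {n})"
            )
        if np.any(self.phase_map < 0) or np.any(self.phase_map >= TWO_PI):
            raise ValueError("plate phases must lie in [0, 2*pi)")
        if self.quantisation_factor < 1 or n % self.quantisation_factor:
            raise ValueError("quantisation factor must be >= 1 and divide N")

    @property
    def transmission(self) -> np.ndarray:
        """Unit-amplitude complex transmission exp(i * phase)."""
        return np.exp(1j * self.phase_map)


@dataclass(frozen=True)
class PlateGeometry:
    """Distances and misalignments of the plate system, fractions of ``f``.

    ``d`` is the object-to-plate distance in metres and ``f`` the lens
    focal length.  ``plate_lateral`` is the in-plane plate offset as a
    (row, col) fraction of ``f`` — the convention used for all tolerance
    figures; :func:`lateral_fraction_to_pixels` converts it to (wrapped)
    plate pixels.  ``plate_axial`` and ``sensor_axial`` displace the plate
    and the sensor along the axis, again as fractions of ``f``.
    """

    d: float = 1e-3
    f: float = 10e-3
    plate_lateral: tuple[float, float] = (0.0, 0.0)
    plate_axial: float = 0.0
    sensor_axial: float = 0.0

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("object-to-plate distance d must be non-negative")
        if not self.f > 0:
            raise ValueError("focal length must be positive")
        if abs(self.plate_axial) > 0.1:
            raise ValueError("|plate_axial| beyond the studied range of 0.1 f")
        if abs(self.sensor_axial) > 0.5:
            raise ValueError("|sensor_axial| beyond the studied range of 0.5 f")


@dataclass(frozen=True)
class PlateRecoveryConfig:
    """Iteration control for single-sensor recovery."""

    resolution_k: int = 64
    max_iterations: int = 2000
    tolerance: float = 1e-9
    seed: int = 0
    #: record an MSE checkpoint against a supplied truth every this many
    #: iterations (when a truth field is given)
    checkpoint_every: int = 10

    def __post_init__(self) -> None:
        if self.resolution_k < 2 or self.resolution_k % 2:
            raise ValueError("resolution_k must be even and >= 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass(frozen=True)
class SensorImage:
    """Recorded intensity with its physical pitch."""

    intensity: np.ndarray
    pitch: float


def _wrap(phase: np.ndarray) -> np.ndarray:
    return np.mod(phase, TWO_PI)


def design_random_plate(grid: GridSpec, seed: int = 0) -> PhasePlate:
    """Uniform random plate: i.i.d. phases on [0, 2pi), reproducible per seed."""
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, TWO_PI, size=(grid.n_pixels, grid.n_pixels))
    return PhasePlate(grid, phases, "random", 1, seed)


def _blaze(grid: GridSpec, offset: tuple[int, int]) -> np.ndarray:
    """Linear phase ramp displacing a replay field by ``offset`` sensor pixels."""
    n = grid.n_pixels
    idx = np.arange(n) - n // 2
    rows, cols = idx[:, None], idx[None, :]
    return TWO_PI * (offset[0] * rows + offset[1] * cols) / n


def _fresnel_lens_phase(grid: GridSpec, focal_length: float) -> np.ndarray:
    yy, xx = grid.coordinates()
    return -np.pi * (xx**2 + yy**2) / (grid.wavelength * focal_length)


def _bandlimited_random_phase(grid: GridSpec, bandwidth: int, rng) -> np.ndarray:
    """Random hologram whose replay field is confined to a bandwidth x
    bandwidth window: phase of the inverse transform of white noise with
    that spectral support (phase-only clipping leaks a little outside)."""
    n = grid.n_pixels
    noise = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
    noise[~_lowpass_mask(n, bandwidth)] = 0.0
    return np.angle(_cifft2(noise))


def design_holographic_plate(
    grid: GridSpec,
    fresnel_focal: float | None = None,
    blaze_offsets: list[tuple[int, int]] | None = None,
    seed: int = 0,
    component_bandwidth: int | None = None,
) -> PhasePlate:
    """Composite holographic plate: phase-only superposition of four holograms.

    Components are two independent random holograms, a flat (blank) phase
    and a Fresnel lens.  Each component is offset by a blazed grating
    towards one sensor quadrant (defaults: the four quadrant centres at
    (+-N/4, +-N/4)), and the plate is ``arg(sum_j exp(i(h_j + blaze_j)))``
    mapped to [0, 2pi).

    So that each replay field actually occupies its own quadrant, the
    random components are band-limited to ``component_bandwidth`` replay
    pixels (default N/4), and the Fresnel-lens focal length defaults to
    ``4 N pitch^2 / lambda`` — four times the matched focal length — which
    confines the lens chirp's replay extent to N/4 pixels as well.  The
    flat component replays the object's Fourier spectrum and the lens
    component a reduced-resolution image of the object plane; phase-only
    clipping of the superposition leaves some overlap between quadrants.
    """
    n = grid.n_pixels
    if blaze_offsets is None:
        q = n // 4
        blaze_offsets = [(-q, -q), (-q, q), (q, -q), (q, q)]
    if len(blaze_offsets) != 4 or len(set(map(tuple, blaze_offsets))) != 4:
        raise ValueError("need four distinct blaze offsets, one per quadrant")
    if fresnel_focal is None:
        fresnel_focal = 4 * grid.n_pixels * grid.pitch**2 / grid.wavelength
    if component_bandwidth is None:
        component_bandwidth = n // 4
    rng = np.random.default_rng(seed)
    holograms = [
        _bandlimited_random_phase(grid, component_bandwidth, rng),
        _bandlimited_random_phase(grid, component_bandwidth, rng),
        np.zeros((n, n)),
        _fresnel_lens_phase(grid, fresnel_focal),
    ]
    total = np.zeros((n, n), dtype=complex)
    for hologram, offset in zip(holograms, blaze_offsets):
        total += np.exp(1j * (hologram + _blaze(grid, offset)))
    phase = np.where(np.abs(total) > 0, np.angle(total), 0.0)
    return PhasePlate(
        grid,
        _wrap(phase),
        "holographic",
        1,
        seed,
        {"fresnel_focal": fresnel_focal, "blaze_offsets": [tuple(o) for o in blaze_offsets]},
    )


def quantise_plate(plate: PhasePlate, k: int, mode: str = "circular") -> PhasePlate:
    """Coarsen the plate to k x k pixel blocks.

    Each block is replaced by the circular mean of its phases (argument of
    the block-mean phasor); ``mode="arithmetic"`` averages the raw phase
    values instead, for sensitivity analysis.  A block whose mean phasor
    vanishes gets phase 0.  ``k=1`` is the identity.
    """
    n = plate.grid.n_pixels
    if k < 1 or n % k:
        raise ValueError(f"quantisation factor {k} does not divide N={n}")
    if k == 1:
        return replace(plate, phase_map=plate.phase_map.copy(), quantisation_factor=1)
    blocks = plate.phase_map.reshape(n // k, k, n // k, k)
    if mode == "circular":
        mean_phasor = np.exp(1j * blocks).mean(axis=(1, 3))
        block_phase = np.where(np.abs(mean_phasor) > 1e-15, np.angle(mean_phasor), 0.0)
    elif mode == "arithmetic":
        block_phase = blocks.mean(axis=(1, 3))
    else:
        raise ValueError(f"unknown quantisation mode {mode!r}")
    coarse = np.repeat(np.repeat(block_phase, k, axis=0), k, axis=1)
    return replace(plate, phase_map=_wrap(coarse), quantisation_factor=k)


def lateral_fraction_to_pixels(fraction: float, f: float, pitch: float) -> int:
    """Convert a lateral offset given as a fraction of ``f`` to plate pixels.

    The physical shift ``fraction * f`` is divided by the plate pitch and
    rounded; shifts are applied wrapped (circularly), so only the residue
    modulo N matters.
    """
    return int(round(fraction * f / pitch))


def perturb_plate(
    plate: PhasePlate,
    noise_std: float = 0.0,
    lateral_px: tuple[int, int] = (0, 0),
    axial_frac: float = 0.0,
    seed: int = 0,
) -> tuple[PhasePlate, dict]:
    """Apply manufacturing/alignment perturbations to a plate.

    ``noise_std`` adds seeded i.i.d. Gaussian phase noise (radians, wrapped
    to [0, 2pi)); ``lateral_px`` rolls the phase map circularly; and
    ``axial_frac`` is a geometry-only change, returned in the delta dict
    for the forward model to consume as ``plate_axial``.
    """
    if noise_std < 0:
        raise ValueError("noise_std must be non-negative")
    phase = plate.phase_map
    if noise_std > 0:
        rng = np.random.default_rng(seed)
        phase = phase + rng.normal(0.0, noise_std, size=phase.shape)
    if lateral_px != (0, 0):
        phase = np.roll(phase, lateral_px, axis=(0, 1))
    delta = {"plate_axial": axial_frac, "lateral_px": tuple(lateral_px)}
    return replace(plate, phase_map=_wrap(phase)), delta


def phasor_mse(plate_a: PhasePlate, plate_b: PhasePlate) -> float:
    """Mean squared phasor distance ``mean |e^{i a} - e^{i b}|^2`` between plates.

    For i.i.d. Gaussian phase errors of standard deviation sigma the
    expectation is ``2 (1 - exp(-sigma^2 / 2))``, which is how a fabrication
    tolerance in radians maps onto this metric.
    """
    return float(np.mean(np.abs(np.exp(1j * plate_a.phase_map) - np.exp(1j * plate_b.phase_map)) ** 2))


def _shifted_transmission(plate: PhasePlate, geometry: PlateGeometry) -> np.ndarray:
    shift = (
        lateral_fraction_to_pixels(geometry.plate_lateral[0], geometry.f, plate.grid.pitch),
        lateral_fraction_to_pixels(geometry.plate_lateral[1], geometry.f, plate.grid.pitch),
    )
    phase = plate.phase_map
    if shift != (0, 0):
        phase = np.roll(phase, shift, axis=(0, 1))
    return np.exp(1j * phase)


def simulate_plate_system(
    input_field: Field,
    plate: PhasePlate,
    geometry: PlateGeometry,
    sensor_grid: GridSpec | None = None,
) -> SensorImage:
    """Forward model: object -> Fresnel(d) -> plate -> lens FT -> sensor.

    Axial plate misalignment moves the modulation plane: the field reaches
    the plate after ``d + plate_axial * f`` and the modulated field is
    referred back to the nominal front focal plane before the lens
    transform (the total object-to-lens distance is fixed by the mount).
    Axial sensor misalignment adds a Fresnel step of ``sensor_axial * f``
    after the lens; lateral plate offsets are wrapped pixel shifts of the
    phase map.  Pre-detection energy is conserved (every step is unitary);
    the returned intensity may be box resampled to a coarser sensor grid.
    """
    if input_field.grid.n_pixels != plate.grid.n_pixels or not np.isclose(
        input_field.grid.pitch, plate.grid.pitch
    ):
        raise ValueError("plate grid does not match the field grid")
    dz_plate = geometry.plate_axial * geometry.f
    e = _prop_signed(input_field, geometry.d + dz_plate)
    e = Field(e.grid, e.values * _shifted_transmission(plate, geometry), "plate")
    e = _prop_signed(e, -dz_plate)
    e = scaled_fourier_transform(e, geometry.f, plane_label="sensor")
    e = _prop_signed(e, geometry.sensor_axial * geometry.f)
    intensity, pitch = e.intensity, e.grid.pitch
    if sensor_grid is not None:
        intensity, pitch = resample_intensity(intensity, pitch, sensor_grid.pitch)
    return SensorImage(intensity, pitch)


def _prop_signed(field: Field, distance: float) -> Field:
    if distance == 0:
        return field
    if distance > 0:
        return fresnel_propagate(field, distance, "forward")
    return fresnel_propagate(field, -distance, "backward")


def _lowpass_mask(n: int, k: int) -> np.ndarray:
    mask = np.zeros((n, n), dtype=bool)
    half = k // 2
    centre = n // 2
    mask[centre - half : centre + half, centre - half : centre + half] = True
    return mask


def recover_plate(
    sensor: SensorImage,
    plate_design: PhasePlate,
    geometry: PlateGeometry,
    config: PlateRecoveryConfig = PlateRecoveryConfig(),
    ideal_object: Field | None = None,
) -> tuple[Field, RecoveryReport]:
    """Single-sensor phase recovery with a known plate design.

    Iterates: enforce the measured amplitude at the sensor; propagate back
    to the plate plane (inverse lens transform and axial corrections);
    divide out the assumed plate phase; apply the resolution constraint
    (keep the central K x K spatial-frequency support, zero the rest);
    re-apply the plate phase and propagate forward again.  The algorithm's
    internal propagation is exactly self-inverse, which is what makes the
    scheme tolerant of sensor-axial error in the *physical* system.

    ``plate_design`` and ``geometry`` are what the algorithm *believes*;
    mismatches with the plate that generated the data are the experiment.
    Returns the object-plane estimate (at resolution K) and a report with
    the per-iteration sensor-amplitude error; when ``ideal_object`` is
    given, energy-matched phase-aligned MSE checkpoints are recorded.
    """
    intensity = np.asarray(sensor.intensity, dtype=float)
    if not intensity.any():
        raise ValueError("all-zero sensor image")
    if np.any(intensity < 0):
        raise ValueError("sensor intensity must be non-negative")
    n = plate_design.grid.n_pixels
    if config.resolution_k > n:
        raise ValueError("resolution_k exceeds the grid size")
    if intensity.shape != (n, n):
        raise ValueError("sensor image shape does not match the plate grid")

    amplitude = np.sqrt(intensity)
    norm = float(np.sum(intensity))
    sensor_grid = GridSpec(n, sensor.pitch, plate_design.grid.wavelength)
    conj_design = np.conj(plate_design.transmission)
    design = plate_design.transmission
    mask = _lowpass_mask(n, config.resolution_k)
    dz_plate = geometry.plate_axial * geometry.f
    dz_sensor = geometry.sensor_axial * geometry.f

    def to_plate(e_s: Field) -> Field:
        e = _prop_signed(e_s, -dz_sensor)
        e = scaled_fourier_transform(e, geometry.f, inverse=True, plane_label="plate")
        return _prop_signed(e, dz_plate)

    def to_sensor(e_p: Field) -> Field:
        e = _prop_signed(e_p, -dz_plate)
        e = scaled_fourier_transform(e, geometry.f, plane_label="sensor")
        return _prop_signed(e, dz_sensor)

    e_s = Field(sensor_grid, amplitude.astype(complex), "sensor")
    errors: list[float] = []
    mse_trace: list[tuple[int, float]] = []
    converged = False
    e_corr = None
    for it in range(1, config.max_iterations + 1):
        e_p = to_plate(e_s)
        e_corr = Field(e_p.grid, e_p.values * conj_design, "plate")
        spectrum = _cfft2(e_corr.values)
        spectrum[~mask] = 0.0
        e_corr = Field(e_corr.grid, _cifft2(spectrum), "plate")
        e_p = Field(e_corr.grid, e_corr.values * design, "plate")
        e_model = to_sensor(e_p)
        err = float(np.sum((np.abs(e_model.values) - amplitude) ** 2) / norm)
        errors.append(err)
        e_s = Field(sensor_grid, amplitude * np.exp(1j * np.angle(e_model.values)), "sensor")
        if ideal_object is not None and (it % config.checkpoint_every == 0 or it == 1):
            est = _object_estimate(e_corr, geometry)
            mse_trace.append((it, recovery_mse(est, ideal_object)))
        if len(errors) >= 2 and abs(errors[-2] - errors[-1]) <= config.tolerance * max(
            errors[-2], 1e-300
        ):
            converged = True
            break
    estimate = _object_estimate(e_corr, geometry)
    mse_aligned = mse_raw = None
    if ideal_object is not None:
        mse_aligned = recovery_mse(estimate, ideal_object, align=True)
        mse_raw = recovery_mse(estimate, ideal_object, align=False)
    report = RecoveryReport(
        mse_aligned=mse_aligned,
        mse_raw=mse_raw,
        iterations_run=len(errors),
        error_trace=errors,
        converged=converged,
        mse_trace=mse_trace,
    )
    return estimate, report


def _object_estimate(e_corr: Field, geometry: PlateGeometry) -> Field:
    back = geometry.d + geometry.plate_axial * geometry.f
    est = fresnel_propagate(e_corr, back, "backward") if back else e_corr
    return Field(est.grid, est.values, "object")
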