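"""Error metrics and analytic design calculators.

The central figure of merit is the mean squared error between a recovered
and an ideal complex field,

    MSE = sum_xy ||E_rec - E_ideal||^2 / N_pixels,

optionally after removing the global (piston) phase, which is physically
unobservable in phase-contrast imaging.  Two small analytic helpers relate
grid sampling to the focal length at which Fourier-plane and image-plane
pixels match, and phase steps to physical etch depth of a glass plate.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from qpisim.optics import Field, GridSpec

__all__ = [
    "RecoveryReport",
    "field_mse",
    "align_global_phase",
    "recovery_mse",
    "matched_focal_length",
    "phase_to_thickness",
]


@dataclass
class RecoveryReport:
    """Outcome of an iterative phase-retrieval run."""

    mse_aligned: float | None
    mse_raw: float | None
    iterations_run: int
    error_trace: list[float] = dc_field(default_factory=list)
    converged: bool = False
    #: optional (iteration, mse) checkpoints recorded against a known truth
    mse_trace: list[tuple[int, float]] = dc_field(default_factory=list)


def _values(field_or_array) -> np.ndarray:
    if isinstance(field_or_array, Field):
        return field_or_array.values
    return np.asarray(field_or_array, dtype=np.complex128)


def align_global_phase(e_rec, e_ideal) -> np.ndarray:
    """Rotate ``e_rec`` by the constant phase that best matches ``e_ideal``.

    The optimal piston is ``theta* = arg(sum(e_rec * conj(e_ideal)))``; the
    returned array is ``e_rec * exp(-i theta*)``.
    """
    rec, ideal = _values(e_rec), _values(e_ideal)
    inner = np.sum(rec * np.conj(ideal))
    if inner == 0:
        return rec.copy()
    return rec * np.exp(-1j * np.angle(inner))


def field_mse(e_rec, e_ideal, align: bool = True) -> float:
    """Mean per-pixel squared modulus of the field difference.

    With ``align=True`` the global phase of ``e_rec`` is removed first, so
    that fields differing only by a piston score zero.
    """
    rec, ideal = _values(e_rec), _values(e_ideal)
    if rec.shape != ideal.shape:
        raise ValueError(f"field shapes differ: {rec.shape} vs {ideal.shape}")
    if align:
        rec = align_global_phase(rec, ideal)
    return float(np.mean(np.abs(rec - ideal) ** 2))


def recovery_mse(e_rec, e_ideal, align: bool = True, match_energy: bool = True) -> float:
    """MSE of a retrieval result against its known truth.

    Iterative retrieval fixes the field's amplitude from measured
    intensities, so its overall energy can differ from the reference (for
    example after a resolution constraint discards out-of-band energy).
    With ``match_energy=True`` the recovered field is rescaled to the
    reference energy before the comparison.
    """
    rec, ideal = _values(e_rec), _values(e_ideal)
    if match_energy:
        e_r = np.sum(np.abs(rec) ** 2)
        e_i = np.sum(np.abs(ideal) ** 2)
        if e_r > 0:
            rec = rec * np.sqrt(e_i / e_r)
    return field_mse(rec, ideal, align=align)


def matched_focal_length(grid: GridSpec) -> float:
    """Focal length at which Fourier-plane pixels equal image-plane pixels.

    Setting the lens-scaled pitch ``lam * f / (N * dx)`` equal to the
    native pitch ``dx`` and solving for ``f`` gives ``f = N * dx^2 / lam``.
    At this focal length both sensors of a 4f system can share one pixel
    size with no Fourier-plane downsampling.
    """
    return grid.n_pixels * grid.pitch**2 / grid.wavelength


def phase_to_thickness(delta_phi: float, wavelength: float, refractive_index: float) -> float:
    """Glass thickness step producing a phase step ``delta_phi`` in air.

    ``t = delta_phi * lam / (2 pi (n - 1))``.  Used to convert phase-plate
    tolerances (radians) into fabrication tolerances (metres).
    """
    if not refractive_index > 1:
        raise ValueError(
            f"refractive index must exceed 1 (plate in air), got {refractive_index}"
        )
    return delta_phi * wavelength / (2 * np.pi * (refractive_index - 1))
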