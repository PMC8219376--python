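"""Synthetic object-plane targets.

Three families of target are provided, matching what a bench QPI system
would be pointed at:

* a back-illuminated **pinhole** (binary amplitude disc) — the calibration
  target, whose Fourier plane has a closed analytic form;
* **phase-only glyphs** — unit amplitude with a stepped phase profile,
  including a built-in two-level digit and a multi-level "crest" emblem
  used as stand-ins for printed resolution targets;
* a **birefringent scene**: a retarding character region between three
  linear polarisers, modelled per-pixel with Jones calculus.  At suitable
  polariser angles the characters vanish in intensity but keep phase
  contrast, which is the interesting regime for phase imaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from qpisim.optics import Field, GridSpec

__all__ = [
    "PinholeSpec",
    "GlyphSpec",
    "BirefringentSceneSpec",
    "make_pinhole",
    "make_phase_glyph",
    "builtin_glyph_mask",
    "builtin_glyph",
    "illuminated_glyph",
    "fine_phase_texture",
    "jones_scene_scalars",
    "birefringent_scene",
    "find_phase_only_angles",
]


@dataclass(frozen=True)
class PinholeSpec:
    """Circular aperture of given physical diameter and transmission."""

    diameter: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise ValueError("amplitude must be positive")
        if not self.diameter > 0:
            raise ValueError("diameter must be positive")


@dataclass
class GlyphSpec:
    """Integer-labelled mask plus one phase level (radians) per label."""

    mask: np.ndarray
    phase_levels: dict[int, float]
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if not np.issubdtype(self.mask.dtype, np.integer):
            raise ValueError("glyph mask must be an integer-labelled array")
        for label, level in self.phase_levels.items():
            if abs(level) > 2 * np.pi:
                raise ValueError(f"phase level {level} for label {label} exceeds 2*pi")


@dataclass(frozen=True)
class BirefringentSceneSpec:
    """Retarding characters between three polarisers.

    ``theta1`` sets the illumination polarisation (the beam has already
    passed the first polariser); ``theta2`` and ``theta3`` are the two
    analysers after the target.  Character pixels retard by ``retardance``
    about ``fast_axis_angle``; background pixels do not.
    """

    polariser_angles: tuple[float, float, float]
    retardance: float = np.pi / 2
    #: 45 deg to the illumination polarisation by default, so the retarder
    #: genuinely mixes polarisation components (a parallel fast axis only
    #: pistons the phase)
    fast_axis_angle: float = np.pi / 4

    def __post_init__(self) -> None:
        if not 0 <= self.retardance <= 2 * np.pi:
            raise ValueError("retardance must lie in [0, 2*pi]")
        if not all(np.isfinite(self.polariser_angles)):
            raise ValueError("polariser angles must be finite")


def make_pinhole(grid: GridSpec, spec: PinholeSpec, antialias: bool = False) -> Field:
    """Binary (or area-weighted) disc of the given diameter, centred on axis.

    Pixels whose centres fall inside the radius carry ``amplitude``; phase
    is identically zero.  ``antialias=True`` weights edge pixels by their
    approximate covered area (4x4 subpixel sampling), which softens the
    staircase edge for convergence studies.
    """
    radius = spec.diameter / 2
    if spec.diameter < 2 * grid.pitch:
        raise ValueError(
            f"pinhole diameter {spec.diameter:.3g} m is degenerate on pitch {grid.pitch:.3g} m"
        )
    if spec.diameter >= grid.side_length:
        raise ValueError("pinhole diameter exceeds the grid side length")
    yy, xx = grid.coordinates()
    if not antialias:
        disc = (xx**2 + yy**2 <= radius**2).astype(float)
    else:
        sub = (np.arange(4) - 1.5) / 4 * grid.pitch
        cover = np.zeros((grid.n_pixels, grid.n_pixels))
        for dy in sub:
            for dx in sub:
                cover += (xx + dx) ** 2 + (yy + dy) ** 2 <= radius**2
        disc = cover / 16.0
    return Field(grid, spec.amplitude * disc, "object")


def make_phase_glyph(grid: GridSpec, spec: GlyphSpec) -> Field:
    """Phase-only field: constant amplitude, stepped phase per mask label."""
    n = grid.n_pixels
    if spec.mask.shape != (n, n):
        raise ValueError(f"mask shape {spec.mask.shape} does not match grid ({n}, {n})")
    labels = np.unique(spec.mask)
    missing = [int(l) for l in labels if int(l) not in spec.phase_levels]
    if missing:
        raise ValueError(f"mask labels without a phase level: {missing}")
    phase = np.zeros((n, n))
    for label, level in spec.phase_levels.items():
        phase[spec.mask == label] = level
    return Field(grid, spec.amplitude * np.exp(1j * phase), "object")


def _norm_coords(n: int) -> tuple[np.ndarray, np.ndarray]:
    """(v, u) in [-1, 1] over the full grid."""
    c = (np.arange(n) - n // 2) / (n / 2)
    return c[:, None], c[None, :]


def builtin_glyph_mask(name: str, n_pixels: int, scale: float = 1.0) -> np.ndarray:
    """Programmatic label masks for the packaged glyph targets.

    ``"five"`` is a two-level digit drawn from five bar segments (labels
    {0, 1}); ``"crest"`` is a multi-level shield emblem (labels {0, 1, 2,
    3}) with a field, a chevron band and a central roundel.  Both occupy
    roughly the central half of the grid at ``scale=1``; smaller scales
    shrink the glyph about the grid centre.
    """
    n = n_pixels
    vv, uu = _norm_coords(n)
    if scale != 1.0:
        vv, uu = vv / scale, uu / scale
    mask = np.zeros((n, n), dtype=np.int64)
    if name == "five":
        # bars of the digit 5 in a box u,v in [-0.35, 0.35]
        w = 0.09  # bar half-thickness
        box = 0.35
        bars = [
            (-box, -box + 2 * w, -box, box),      # top bar (v range, u range)
            (-box, 0.0, -box, -box + 2 * w),      # upper-left vertical
            (-w, w, -box, box),                   # middle bar
            (0.0, box, box - 2 * w, box),         # lower-right vertical
            (box - 2 * w, box, -box, box),        # bottom bar
        ]
        for v0, v1, u0, u1 in bars:
            mask[(vv >= v0) & (vv <= v1) & (uu >= u0) & (uu <= u1)] = 1
    elif name == "crest":
        # shield: flat top, sides tapering to a point at the bottom
        half_width = np.where(vv < 0.0, 0.45, 0.45 * (1 - (vv / 0.55) ** 2))
        shield = (np.abs(uu) <= half_width) & (vv >= -0.45) & (vv <= 0.55)
        mask[shield] = 1
        chevron = shield & (np.abs(vv - 0.12 - 0.35 * np.abs(uu)) <= 0.07)
        mask[chevron] = 2
        roundel = (uu**2 + (vv + 0.18) ** 2) <= 0.14**2
        mask[shield & roundel] = 3
    else:
        raise ValueError(f"unknown builtin glyph {name!r} (use 'five' or 'crest')")
    return mask


#: default phase levels (radians) per label for the builtin glyphs
DEFAULT_GLYPH_LEVELS = {
    "five": {0: 0.0, 1: np.pi / 2},
    "crest": {0: 0.0, 1: np.pi / 3, 2: 2 * np.pi / 3, 3: np.pi},
}


def builtin_glyph(name: str, grid: GridSpec, phase_levels: dict[int, float] | None = None) -> Field:
    """Phase-only field for a packaged glyph on the given grid."""
    mask = builtin_glyph_mask(name, grid.n_pixels)
    levels = dict(DEFAULT_GLYPH_LEVELS[name]) if phase_levels is None else phase_levels
    return make_phase_glyph(grid, GlyphSpec(mask, levels))


def illuminated_glyph(
    name: str,
    grid: GridSpec,
    beam_radius_fraction: float | None = 0.2,
    edge_sigma_px: float | None = None,
    phase_levels: dict[int, float] | None = None,
    glyph_scale: float = 1.0,
) -> Field:
    """Glyph target under a finite collimated illumination beam.

    This is the standard simulation scene for the two-sensor retrieval
    studies: the phase glyph sits inside a circular beam of radius
    ``beam_radius_fraction * side_length`` (zero amplitude outside), and
    the phase steps are band-limited by a Gaussian blur of
    ``edge_sigma_px`` pixels (default ``2 * N / 256``, scaling with grid
    resolution).

    Both features emulate the bench reality of a finite laser beam and a
    target imaged through finite-aperture optics, and both matter for
    retrieval: the beam keeps the field's autocorrelation inside the grid
    (so the sampled Fourier magnitude is not aliased) and provides the
    amplitude support that phase retrieval needs, while pixel-sharp phase
    steps would put target energy beyond the simulated sensor band.
    """
    from scipy import ndimage

    n = grid.n_pixels
    if edge_sigma_px is None:
        edge_sigma_px = 2.0 * n / 256.0
    levels = dict(DEFAULT_GLYPH_LEVELS[name]) if phase_levels is None else phase_levels
    mask = builtin_glyph_mask(name, n, glyph_scale)
    phase = np.zeros((n, n))
    for label, level in levels.items():
        phase[mask == label] = level
    if edge_sigma_px > 0:
        phase = ndimage.gaussian_filter(phase, edge_sigma_px)
    if beam_radius_fraction is None:
        beam = np.ones((n, n))  # uniform illumination (single-sensor system)
    else:
        yy, xx = grid.coordinates()
        radius = beam_radius_fraction * grid.side_length
        beam = (xx**2 + yy**2 <= radius**2).astype(float)
    return Field(grid, beam * np.exp(1j * phase), "object")


def fine_phase_texture(
    grid: GridSpec,
    rms: float = 0.07,
    seed: int = 12345,
    band_fraction: float = 0.75,
) -> np.ndarray:
    """High-spatial-frequency phase roughness (radians).

    White Gaussian noise restricted to spatial frequencies *outside* the
    central ``band_fraction * N`` square, scaled to the requested RMS.
    Emulates the fine surface texture of a physical printed or etched
    target: content beyond any resolution-constrained recovery band, so it
    sets a realistic reconstruction-error floor without interacting with
    plate-quantisation artefacts.
    """
    n = grid.n_pixels
    rng = np.random.default_rng(seed)
    spectrum = np.fft.fftshift(np.fft.fft2(rng.normal(size=(n, n))))
    half = int(round(band_fraction * n)) // 2
    centre = n // 2
    spectrum[centre - half : centre + half, centre - half : centre + half] = 0.0
    texture = np.fft.ifft2(np.fft.ifftshift(spectrum)).real
    sd = texture.std()
    return texture * (rms / sd) if sd > 0 else texture


def _polariser(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c * c, c * s], [c * s, s * s]], dtype=complex)


def _retarder(delta: float, alpha: float) -> np.ndarray:
    c, s = np.cos(alpha), np.sin(alpha)
    rot = np.array([[c, -s], [s, c]])
    core = np.diag([np.exp(-1j * delta / 2), np.exp(1j * delta / 2)])
    return rot @ core @ rot.T


def jones_scene_scalars(spec: BirefringentSceneSpec) -> tuple[complex, complex]:
    """Complex transmission of (character, background) regions.

    Unit-amplitude illumination polarised along ``theta1``; the chain
    ``P(theta3) P(theta2) W(delta) P(theta1)`` is applied and the complex
    coefficient along the final polariser axis is returned for a character
    pixel (retarder present) and a background pixel (no retarder).
    """
    t1, t2, t3 = spec.polariser_angles
    j_in = np.array([np.cos(t1), np.sin(t1)], dtype=complex)
    axis3 = np.array([np.cos(t3), np.sin(t3)])
    chain_bg = _polariser(t3) @ _polariser(t2)
    chain_ch = chain_bg @ _retarder(spec.retardance, spec.fast_axis_angle)
    char = complex(axis3 @ (chain_ch @ j_in))
    background = complex(axis3 @ (chain_bg @ j_in))
    return char, background


def birefringent_scene(
    grid: GridSpec, spec: BirefringentSceneSpec, character_mask: np.ndarray | None = None
) -> Field:
    """Scalar field leaving the final polariser of the birefringent scene.

    ``character_mask`` marks retarding pixels (default: the builtin digit
    mask).  Polarisers only project, so the scene energy never exceeds the
    illumination energy.
    """
    if character_mask is None:
        character_mask = builtin_glyph_mask("five", grid.n_pixels) > 0
    character_mask = np.asarray(character_mask, dtype=bool)
    n = grid.n_pixels
    if character_mask.shape != (n, n):
        raise ValueError("character mask does not match the grid")
    char, background = jones_scene_scalars(spec)
    values = np.where(character_mask, char, background)
    return Field(grid, values, "object")


def find_phase_only_angles(
    retardance: float,
    fast_axis_angle: float = np.pi / 4,
    step_deg: float = 1.0,
    amp_tol: float = 0.01,
    min_phase_contrast: float = 0.3,
) -> list[tuple[float, float, float]]:
    """Grid-search polariser triples giving phase-only character contrast.

    Scans ``theta2`` and ``theta3`` in ``step_deg`` steps with ``theta1 =
    0`` and returns triples where the character/background amplitude ratio
    is within ``amp_tol`` of unity while the phase difference exceeds
    ``min_phase_contrast`` radians — configurations in which the character
    is invisible in intensity yet visible in phase.
    """
    hits: list[tuple[float, float, float]] = []
    angles = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    for t2 in angles:
        for t3 in angles:
            spec = BirefringentSceneSpec((0.0, t2, t3), retardance, fast_axis_angle)
            char, bg = jones_scene_scalars(spec)
            if abs(bg) < 1e-6:
                continue
            ratio = abs(char) / abs(bg)
            if abs(ratio - 1.0) <= amp_tol:
                dphi = np.angle(char * np.conj(bg))
                if abs(dphi) > min_phase_contrast:
                    hits.append((0.0, float(t2), float(t3)))
    return hits
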