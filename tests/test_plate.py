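"""Plate designs, perturbations, single-sensor forward model and recovery."""

import numpy as np
import pytest
from scipy import stats

from qpisim.metrics import recovery_mse
from qpisim.optics import Field, GridSpec, scaled_fourier_transform
from qpisim.plate import (
    PhasePlate,
    PlateGeometry,
    PlateRecoveryConfig,
    design_holographic_plate,
    design_random_plate,
    lateral_fraction_to_pixels,
    perturb_plate,
    phasor_mse,
    quantise_plate,
    recover_plate,
    simulate_plate_system,
)
from qpisim.studies import plate_study_grid, plate_study_target

LAM = 632.8e-9
F = 10e-3


@pytest.fixture(scope="module")
def grid():
    return plate_study_grid(128, F, LAM)


@pytest.fixture(scope="module")
def geometry():
    return PlateGeometry(d=1e-3, f=F)


@pytest.fixture(scope="module")
def target(grid):
    return plate_study_target(grid)


class TestRandomPlate:
    def test_phases_in_range_and_deterministic(self, grid):
        a = design_random_plate(grid, seed=7)
        b = design_random_plate(grid, seed=7)
        assert np.all((a.phase_map >= 0) & (a.phase_map < 2 * np.pi))
        np.testing.assert_array_equal(a.phase_map, b.phase_map)

    def test_uniformity_kolmogorov_smirnov(self):
        g = plate_study_grid(256, F, LAM)
        plate = design_random_plate(g, seed=0)
        stat = stats.kstest(plate.phase_map.ravel() / (2 * np.pi), "uniform").statistic
        assert stat < 1.63 / 256  # 1% critical value for N^2 samples


class TestHolographicPlate:
    def test_replay_energy_concentrated_in_quadrants(self, grid):
        plate = design_holographic_plate(grid, seed=0)
        n = grid.n_pixels
        plane = Field(grid, np.ones((n, n)))
        image = simulate_plate_system(plane, plate, PlateGeometry(d=0.0, f=F)).intensity
        half = n // 8
        captured = 0.0
        for row, col in plate.component_params["blaze_offsets"]:
            r, c = n // 2 + row, n // 2 + col
            captured += image[r - half : r + half, c - half : c + half].sum()
        assert captured / image.sum() >= 0.6

    def test_flat_quadrant_replays_object_spectrum(self, grid, target, geometry):
        plate = design_holographic_plate(grid, seed=0)
        n = grid.n_pixels
        half = n // 8
        image = simulate_plate_system(target, plate, PlateGeometry(d=0.0, f=F)).intensity
        row, col = plate.component_params["blaze_offsets"][2]  # flat component
        r, c = n // 2 + row, n // 2 + col
        window = np.sqrt(image[r - half : r + half, c - half : c + half])
        spectrum = scaled_fourier_transform(target, F).intensity
        centre = np.sqrt(spectrum[n // 2 - half : n // 2 + half, n // 2 - half : n // 2 + half])
        rho = stats.pearsonr(window.ravel(), centre.ravel())[0]
        assert rho > 0.9

    def test_coincident_blaze_offsets_rejected(self, grid):
        with pytest.raises(ValueError, match="distinct"):
            design_holographic_plate(grid, blaze_offsets=[(0, 0)] * 4)


class TestQuantisation:
    def test_factor_one_is_identity(self, grid):
        plate = design_random_plate(grid, seed=1)
        np.testing.assert_array_equal(quantise_plate(plate, 1).phase_map, plate.phase_map)

    def test_constant_plate_unchanged(self, grid):
        n = grid.n_pixels
        plate = PhasePlate(grid, np.full((n, n), 1.25))
        for k in (2, 4, 8):
            np.testing.assert_allclose(quantise_plate(plate, k).phase_map, 1.25)

    def test_circular_mean_of_mixed_block(self, grid):
        # block {0, 0, pi/2, pi/2}: mean phasor (1+i)/sqrt(2) -> pi/4
        n = grid.n_pixels
        phases = np.zeros((n, n))
        phases[1::2, :] = np.pi / 2
        out = quantise_plate(PhasePlate(grid, phases), 2)
        np.testing.assert_allclose(out.phase_map, np.pi / 4, atol=1e-12)

    def test_wraparound_block_uses_circular_mean(self, grid):
        # {0.1, 2*pi - 0.1} straddles the wrap: circular mean 0, not pi
        n = grid.n_pixels
        phases = np.zeros((n, n))
        phases[0::2, :] = 0.1
        phases[1::2, :] = 2 * np.pi - 0.1
        out = quantise_plate(PhasePlate(grid, phases), 2)
        assert np.allclose(np.minimum(out.phase_map, 2 * np.pi - out.phase_map), 0, atol=1e-9)

    def test_non_divisor_rejected(self, grid):
        with pytest.raises(ValueError, match="divide"):
            quantise_plate(design_random_plate(grid, 0), 3)


class TestPerturbations:
    def test_zero_noise_is_identity(self, grid):
        plate = design_random_plate(grid, seed=2)
        out, delta = perturb_plate(plate, noise_std=0.0)
        np.testing.assert_array_equal(out.phase_map, plate.phase_map)
        assert delta["plate_axial"] == 0.0

    def test_phasor_mse_matches_gaussian_closed_form(self):
        # for N(0, sigma^2) phase noise, E|e^{i(a+n)} - e^{ia}|^2
        # = 2 (1 - exp(-sigma^2 / 2))
        g = plate_study_grid(512, F, LAM)
        plate = design_random_plate(g, seed=3)
        sigma = 0.5
        noisy, _ = perturb_plate(plate, noise_std=sigma, seed=4)
        expected = 2 * (1 - np.exp(-(sigma**2) / 2))
        assert phasor_mse(noisy, plate) == pytest.approx(expected, rel=0.02)

    def test_shift_and_unshift_restore_plate(self, grid):
        plate = design_random_plate(grid, seed=5)
        shifted, _ = perturb_plate(plate, lateral_px=(3, -5))
        restored, _ = perturb_plate(shifted, lateral_px=(-3, 5))
        np.testing.assert_allclose(restored.phase_map, plate.phase_map, atol=1e-12)

    def test_lateral_fraction_conversion(self):
        # 13% of a 10 mm lens on 5 um pitch: 260 plate pixels before wrap
        assert lateral_fraction_to_pixels(0.13, 10e-3, 5e-6) == 260


class TestForwardModel:
    def test_blank_plate_reduces_to_plain_2f_system(self, grid, target):
        n = grid.n_pixels
        blank = PhasePlate(grid, np.zeros((n, n)))
        image = simulate_plate_system(target, blank, PlateGeometry(d=0.0, f=F))
        expected = scaled_fourier_transform(target, F)
        np.testing.assert_allclose(image.intensity, expected.intensity, atol=1e-9)
        assert image.pitch == pytest.approx(expected.grid.pitch)

    def test_pre_detection_energy_conserved(self, grid, target, geometry):
        plate = design_holographic_plate(grid, seed=0)
        image = simulate_plate_system(target, plate, geometry)
        assert image.intensity.sum() == pytest.approx(target.energy, rel=1e-10)

    def test_sensor_blind_to_wrapped_lateral_shift(self, grid, geometry):
        # shifting plate and illumination together wraps the modulated
        # field, which the Fourier-plane intensity cannot see
        plate = design_holographic_plate(grid, seed=0)
        target = plate_study_target(grid)
        shifted_plate, _ = perturb_plate(plate, lateral_px=(0, 17))
        shifted_target = Field(grid, np.roll(target.values, (0, 17), axis=(0, 1)))
        a = simulate_plate_system(target, plate, geometry).intensity
        b = simulate_plate_system(shifted_target, shifted_plate, geometry).intensity
        rms = np.sqrt(np.mean((a - b) ** 2)) / np.sqrt(np.mean(a**2))
        assert rms < 0.01

    def test_grid_mismatch_rejected(self, grid, geometry):
        plate = design_random_plate(plate_study_grid(64, F, LAM), 0)
        target = plate_study_target(grid)
        with pytest.raises(ValueError, match="grid"):
            simulate_plate_system(target, plate, geometry)


class TestRecovery:
    def test_noiseless_holographic_recovery(self, grid, target, geometry):
        plate = design_holographic_plate(grid, seed=0)
        sensor = simulate_plate_system(target, plate, geometry)
        config = PlateRecoveryConfig(resolution_k=grid.n_pixels // 4, max_iterations=500)
        estimate, report = recover_plate(sensor, plate, geometry, config, ideal_object=target)
        assert report.mse_aligned < 0.25
        assert report.iterations_run <= 500

    def test_recovered_object_translates_with_plate_shift(self, grid, target, geometry):
        plate = design_holographic_plate(grid, seed=0)
        config = PlateRecoveryConfig(resolution_k=grid.n_pixels // 4, max_iterations=500)
        baseline = simulate_plate_system(target, plate, geometry)
        _, base_report = recover_plate(baseline, plate, geometry, config, ideal_object=target)
        shift = 9
        shifted_plate, _ = perturb_plate(plate, lateral_px=(0, shift))
        sensor = simulate_plate_system(target, shifted_plate, geometry)
        estimate, _ = recover_plate(sensor, plate, geometry, config)
        registered = np.roll(estimate.values, (0, shift), axis=(0, 1))
        mse = recovery_mse(registered, target.values)
        assert mse <= base_report.mse_aligned * 1.05

    def test_noise_degrades_monotonically_but_recovery_survives(self, grid, target, geometry):
        plate = design_holographic_plate(grid, seed=0)
        sensor = simulate_plate_system(target, plate, geometry)
        config = PlateRecoveryConfig(resolution_k=grid.n_pixels // 4, max_iterations=1500)
        mses = []
        for sigma in (0.0, 0.3, 0.9):
            believed, _ = perturb_plate(plate, noise_std=sigma, seed=11)
            _, report = recover_plate(sensor, believed, geometry, config, ideal_object=target)
            mses.append(report.mse_aligned)
        assert mses[0] < mses[1] < mses[2]
        # recovery still usable at the +-1 rad fabrication-tolerance
        # operating point (phasor MSE ~ 0.66); cf. acceptable retrievals
        # in the 0.2-0.4 MSE range
        assert mses[2] < 0.5

    def test_holographic_converges_faster_than_random(self, geometry):
        # the composite design focuses sensor power, so early iterations
        # move the error further; compared at 2x2 quantisation where the
        # contrast is pronounced
        big = plate_study_grid(256, F, LAM)
        target = plate_study_target(big)
        config = PlateRecoveryConfig(resolution_k=64, max_iterations=3000)
        for seed in (0, 1, 2):
            iters = {}
            for kind in ("holo", "random"):
                plate = (
                    design_holographic_plate(big, seed=seed)
                    if kind == "holo"
                    else design_random_plate(big, seed)
                )
                plate = quantise_plate(plate, 2)
                sensor = simulate_plate_system(target, plate, geometry)
                _, report = recover_plate(sensor, plate, geometry, config)
                iters[kind] = report.iterations_run
            assert iters["holo"] < iters["random"]

    def test_all_zero_sensor_rejected(self, grid, geometry):
        plate = design_random_plate(grid, 0)
        with pytest.raises(ValueError, match="zero"):
            recover_plate(
                type("S", (), {"intensity": np.zeros((128, 128)), "pitch": 5e-6})(),
                plate,
                geometry,
                PlateRecoveryConfig(resolution_k=32),
            )

    def test_resolution_k_larger_than_grid_rejected(self, grid, target, geometry):
        plate = design_random_plate(grid, 0)
        sensor = simulate_plate_system(target, plate, geometry)
        with pytest.raises(ValueError, match="resolution_k"):
            recover_plate(sensor, plate, geometry, PlateRecoveryConfig(resolution_k=256))
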