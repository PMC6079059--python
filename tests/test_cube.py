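"""Cube data model, I/O round-trips and the spectral preprocessing chain."""

import numpy as np
import pytest

from ramancharm.cube import (
    CellMask,
    HyperspectralCube,
    Spectrum,
    WavenumberAxis,
    average_spectrum,
    correct_baseline,
    normalize,
    read_cube,
    remove_cosmic_rays,
    subtract_background,
    write_cube,
)


class TestWavenumberAxis:
    def test_rejects_unsorted_and_short(self):
        with pytest.raises(ValueError):
            WavenumberAxis(np.array([1.0, 3.0, 2.0]))
        with pytest.raises(ValueError):
            WavenumberAxis(np.array([1.0]))

    def test_window_selects_channels(self, axis1024):
        sl = axis1024.window(750.0, 40.0)
        vals = axis1024.values[sl]
        assert vals.min() >= 710.0 and vals.max() <= 790.0
        assert vals.size > 5


class TestCubeIO:
    def test_hdf5_roundtrip_bit_exact(self, small_cube, tmp_path):
        cube32 = small_cube.copy_with(
            small_cube.intensities.astype(np.float32)
        )
        p = tmp_path / "cube.h5"
        write_cube(cube32, p)
        back = read_cube(p)
        np.testing.assert_array_equal(back.intensities, cube32.intensities)
        np.testing.assert_array_equal(back.axis.values, cube32.axis.values)

    def test_synthetic_shape_1024_points(self, axis1024, tmp_path):
        cube = HyperspectralCube(
            np.random.default_rng(0).random((8, 8, 1024), dtype=np.float32),
            axis1024,
        )
        p = tmp_path / "c.h5"
        write_cube(cube, p)
        assert read_cube(p).shape == (8, 8, 1024)

    def test_tiff_roundtrip(self, small_cube, tmp_path):
        p = tmp_path / "cube.tif"
        write_cube(small_cube, p, format="tiff_stack")
        back = read_cube(p, format="tiff_stack")
        np.testing.assert_allclose(back.intensities, small_cube.intensities)

    def test_tiff_axis_length_mismatch_is_format_error(self, small_cube, tmp_path):
        p = tmp_path / "cube.tif"
        write_cube(small_cube, p, format="tiff_stack")
        sidecar = p.with_suffix(p.suffix + ".wavenumbers.txt")
        vals = np.loadtxt(sidecar)
        np.savetxt(sidecar, vals[:-1])
        with pytest.raises(ValueError, match="sidecar"):
            read_cube(p, format="tiff_stack")

    def test_axis_mismatch_rejected_at_construction(self, axis1024):
        with pytest.raises(ValueError):
            HyperspectralCube(np.zeros((2, 2, 100)), axis1024)


class TestCosmicRays:
    @staticmethod
    def _cube_from_spectrum(y, axis):
        return HyperspectralCube(y[None, None, :].copy(), axis)

    def test_clean_spectrum_unchanged(self, gauss_spectrum):
        cube = self._cube_from_spectrum(
            gauss_spectrum.intensities, gauss_spectrum.axis
        )
        out, report = remove_cosmic_rays(cube, z_threshold=8.0, window=7)
        assert report.n_spikes_removed == 0
        np.testing.assert_array_equal(out.intensities, cube.intensities)

    def test_spike_removed_below_noise_level(self, gauss_spectrum):
        y = gauss_spectrum.intensities.copy()
        clean = y.copy()
        y[500] += 50.0 * max(abs(y[500]), 1.0)
        cube = self._cube_from_spectrum(y, gauss_spectrum.axis)
        out, report = remove_cosmic_rays(cube, z_threshold=8.0, window=7)
        assert report.n_spikes_removed == 1
        # repaired point within the pre-spike noise level (sd 0.05)
        assert np.max(np.abs(out.intensities[0, 0] - clean)) < 0.2

    def test_edge_spike_detected_matches_bruteforce(self, gauss_spectrum):
        y = gauss_spectrum.intensities.copy()
        y[0] += 100.0
        cube = self._cube_from_spectrum(y, gauss_spectrum.axis)
        out, report = remove_cosmic_rays(cube, z_threshold=8.0, window=7)
        assert report.n_spikes_removed >= 1
        # brute-force running median with reflected padding at the edge
        padded = np.concatenate([y[:3][::-1], y[:4]])
        expected = np.median(padded)
        assert out.intensities[0, 0, 0] == pytest.approx(expected)

    def test_idempotent(self, gauss_spectrum):
        y = gauss_spectrum.intensities.copy()
        y[[100, 900]] += 80.0
        cube = self._cube_from_spectrum(y, gauss_spectrum.axis)
        once, _ = remove_cosmic_rays(cube)
        twice, rep2 = remove_cosmic_rays(once)
        assert rep2.n_spikes_removed == 0
        np.testing.assert_array_equal(once.intensities, twice.intensities)

    def test_parameter_validation(self, small_cube):
        with pytest.raises(ValueError):
            remove_cosmic_rays(small_cube, window=4)
        with pytest.raises(ValueError):
            remove_cosmic_rays(small_cube, window=1025)


class TestBackground:
    def test_zero_background_is_identity(self, small_cube):
        zero = Spectrum(np.zeros(1024), small_cube.axis)
        out = subtract_background(small_cube, zero)
        np.testing.assert_allclose(out.intensities, small_cube.intensities)

    def test_constant_cube_self_subtracts_to_zero(self, axis1024, rng):
        s = rng.random(1024)
        cube = HyperspectralCube(np.tile(s, (3, 3, 1)), axis1024)
        region = np.zeros((3, 3), dtype=bool)
        region[0, :2] = True
        out = subtract_background(cube, region)
        np.testing.assert_allclose(out.intensities, 0.0, atol=1e-12)

    def test_blank_corner_recovers_signal(self, axis1024, rng):
        signal = np.zeros((4, 4, 1024))
        signal[2, 2] = rng.random(1024)
        offset = 3.7
        cube = HyperspectralCube(signal + offset, axis1024)
        region = np.zeros((4, 4), dtype=bool)
        region[0, 0] = True
        out = subtract_background(cube, region)
        np.testing.assert_allclose(out.intensities, signal, atol=1e-9)

    def test_empty_region_rejected(self, small_cube):
        with pytest.raises(ValueError, match="empty"):
            subtract_background(small_cube, np.zeros((4, 5), dtype=bool))


class TestBaseline:
    def test_flat_zero_unchanged(self, axis1024):
        cube = HyperspectralCube(np.zeros((1, 1, 1024)), axis1024)
        out, _ = correct_baseline(cube, "modpoly", {"degree": 3})
        np.testing.assert_allclose(out.intensities, 0.0, atol=1e-9)

    def test_exact_polynomial_removed(self, axis1024):
        t = np.linspace(-1, 1, 1024)
        poly = 5.0 + 2.0 * t - 3.0 * t ** 2 + 0.5 * t ** 3
        cube = HyperspectralCube(poly[None, None, :], axis1024)
        out, _ = correct_baseline(cube, "modpoly", {"degree": 3})
        assert np.max(np.abs(out.intensities)) < 1e-6 * np.max(np.abs(poly))

    @pytest.mark.parametrize("method,params", [
        ("modpoly", {"degree": 3}),
        ("als", {"lam": 1e5, "p": 0.01}),
    ])
    def test_peak_preserved_on_ramp(self, axis1024, method, params):
        nu = axis1024.values
        A = 4.0
        sigma = 4.0 * axis1024.spacing
        peak = A * np.exp(-((nu - 1400.0) ** 2) / (2.0 * sigma ** 2))
        ramp = 0.002 * (nu - nu[0]) + 1.0
        cube = HyperspectralCube((peak + ramp)[None, None, :], axis1024)
        out, _ = correct_baseline(cube, method, params)
        recovered = out.intensities[0, 0, axis1024.index_of(1400.0)]
        assert recovered == pytest.approx(A, rel=0.1)

    def test_unknown_method_rejected(self, small_cube):
        with pytest.raises(ValueError, match="unknown"):
            correct_baseline(small_cube, "magic")


class TestNormalize:
    def test_l2_scale_invariance(self, small_cube):
        scaled = small_cube.copy_with(small_cube.intensities * 7.0)
        a, _ = normalize(small_cube, "l2")
        b, _ = normalize(scaled, "l2")
        np.testing.assert_allclose(a.intensities, b.intensities, rtol=1e-10)

    def test_zero_pixel_left_unscaled_with_warning(self, axis1024):
        data = np.ones((2, 1, 1024))
        data[1, 0] = 0.0
        cube = HyperspectralCube(data, axis1024)
        with pytest.warns(UserWarning, match="zero"):
            out, report = normalize(cube, "l2")
        np.testing.assert_array_equal(out.intensities[1, 0], 0.0)
        assert report.parameters["n_zero_norm"] == 1

    def test_area_mode_closed_form(self, axis1024):
        cube = HyperspectralCube(np.ones((1, 1, 1024)), axis1024)
        out, _ = normalize(cube, "area")
        np.testing.assert_allclose(out.intensities, 1.0 / 1024.0)

    def test_peak_mode_uses_reference_band(self, gauss_spectrum):
        cube = HyperspectralCube(
            gauss_spectrum.intensities[None, None, :], gauss_spectrum.axis
        )
        out, _ = normalize(cube, "peak", reference_band=(710.0, 790.0))
        sl = gauss_spectrum.axis.window(750.0, 40.0)
        assert out.intensities[0, 0, sl].max() == pytest.approx(1.0)


class TestAverageSpectrum:
    def test_single_pixel_mask_exact(self, small_cube):
        mask = np.zeros((4, 5), dtype=bool)
        mask[2, 3] = True
        out = average_spectrum(small_cube, CellMask(mask))
        np.testing.assert_allclose(
            out.intensities, small_cube.intensities[2, 3]
        )

    def test_arithmetic_mean_of_s_and_3s(self, axis1024, rng):
        s = rng.random(1024)
        data = np.zeros((1, 2, 1024))
        data[0, 0], data[0, 1] = s, 3.0 * s
        cube = HyperspectralCube(data, axis1024)
        mask = CellMask(np.ones((1, 2), dtype=bool))
        np.testing.assert_allclose(
            average_spectrum(cube, mask).intensities, 2.0 * s
        )

    def test_union_of_disjoint_masks_is_weighted_mean(self, small_cube, rng):
        m1 = np.zeros((4, 5), dtype=bool)
        m2 = np.zeros((4, 5), dtype=bool)
        m1[:2] = True
        m2[2:, :3] = True
        s1 = average_spectrum(small_cube, CellMask(m1)).intensities
        s2 = average_spectrum(small_cube, CellMask(m2)).intensities
        union = average_spectrum(small_cube, CellMask(m1 | m2)).intensities
        n1, n2 = m1.sum(), m2.sum()
        np.testing.assert_allclose(
            union, (n1 * s1 + n2 * s2) / (n1 + n2), rtol=1e-12
        )

    def test_empty_mask_rejected(self, small_cube):
        with pytest.raises(ValueError, match="empty"):
            average_spectrum(small_cube, CellMask(np.zeros((4, 5), bool)))
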