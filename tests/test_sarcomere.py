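"""Sarcomere-length measurement: orientation, profiles, minima detection,
A-band exclusion, end-to-end recovery."""

import math

import numpy as np
import pytest

from myoshg import (
    GeometryError,
    Image,
    LatticeParams,
    LineProfile,
    ParameterError,
    SarcomereConfig,
    classify_minima,
    detect_minima,
    estimate_fiber_orientation,
    extract_line_profile,
    generate_lattice_image,
    measure_sarcomere_lengths,
)


def cosine_profile(period_um, length_um, step_um=0.02, amp=50.0, offset=100.0):
    pos = np.arange(0, length_um + step_um / 2, step_um)
    return LineProfile(
        positions_um=pos,
        intensities=offset - amp * np.cos(2 * np.pi * pos / period_um),
        step_um=step_um,
        source_line=((0.0, 0.0), (length_um / step_um, 0.0)),
    )


class TestOrientation:
    @pytest.mark.parametrize("angle", [0.0, 30.0, -45.0, 80.0])
    def test_recovers_generator_orientation(self, angle):
        img, _ = generate_lattice_image(
            LatticeParams(orientation_deg=angle, shape_px=(192, 192)),
            noiseless=True,
        )
        theta, coherence = estimate_fiber_orientation(img)
        assert theta == pytest.approx(angle, abs=1.0)
        assert coherence > 0.9

    def test_constant_image_raises(self):
        img = Image(np.full((32, 32), 7.0), 0.1)
        with pytest.raises(ParameterError, match="no orientation signal"):
            estimate_fiber_orientation(img)


class TestLineProfile:
    def test_linear_field_sampled_exactly(self):
        """Bilinear interpolation of I(x, y) = x is exact: slope 1/px."""
        x = np.tile(np.arange(64, dtype=float), (32, 1))
        img = Image(x, 0.1)
        prof = extract_line_profile(img, (31.5, 15.5), 0.0, 4.0, width_px=1)
        slopes = np.diff(prof.intensities) / np.diff(prof.positions_um)
        assert np.allclose(slopes, 1.0 / img.pixel_um)

    def test_width_averaging_of_arithmetic_rows(self):
        """Averaging rows r, r+10, r+20 returns the middle row."""
        base = np.tile(np.arange(64, dtype=float), (32, 1))
        img_arr = base + 10.0 * np.arange(32)[:, None]
        img = Image(img_arr, 0.1)
        wide = extract_line_profile(img, (31.5, 15.0), 0.0, 4.0, width_px=3)
        narrow = extract_line_profile(img, (31.5, 15.0), 0.0, 4.0, width_px=1)
        assert np.allclose(wide.intensities, narrow.intensities)

    def test_rotation_equivariance_against_generator(self):
        """Profile along a 30 deg lattice matches the axis-aligned one."""
        prof = {}
        for ang in (0.0, 30.0):
            img, _ = generate_lattice_image(
                LatticeParams(orientation_deg=ang, shape_px=(192, 192)),
                noiseless=True,
            )
            prof[ang] = extract_line_profile(
                img, (95.5, 95.5), ang, 6.0, width_px=1
            ).intensities
        a, b = prof[0.0], prof[30.0]
        # align phases by best integer shift, then compare RMS
        best = min(
            (
                float(np.sqrt(np.mean((a[s:] - b[: len(b) - s]) ** 2)))
                for s in range(0, 50)
            ),
        )
        dyn = a.max() - a.min()
        assert best <= 0.02 * dyn

    def test_line_outside_image_raises(self):
        img = Image(np.ones((32, 32)), 0.1)
        with pytest.raises(GeometryError):
            extract_line_profile(img, (16.0, 16.0), 0.0, 10.0, width_px=1)

    def test_even_width_rejected(self):
        img = Image(np.ones((32, 32)), 0.1)
        with pytest.raises(ParameterError):
            extract_line_profile(img, (16.0, 16.0), 0.0, 1.0, width_px=2)


class TestDetectMinima:
    def test_cosine_minima_positions_closed_form(self):
        """I(x) = 100 - 50 cos(2 pi x / 1.8): interior minima at k*1.8 um."""
        prof = cosine_profile(1.8, 9.0)
        minima = detect_minima(prof, smoothing_um=0.05, min_prominence_frac=0.05)
        expected = np.array([1.8, 3.6, 5.4, 7.2])
        assert len(minima) == len(expected)
        assert np.allclose(minima.positions_um, expected, atol=0.01)

    def test_cosine_minima_under_poisson_noise(self):
        """Monte-Carlo: minima within +-0.05 um of noiseless positions."""
        expected = np.array([1.8, 3.6, 5.4, 7.2])
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(100):
            pos = np.arange(0, 9.0 + 0.01, 0.02)
            clean = 100 - 50 * np.cos(2 * np.pi * pos / 1.8)
            noisy = rng.poisson(clean).astype(float)
            prof = LineProfile(pos, noisy, 0.02, ((0, 0), (450, 0)))
            minima = detect_minima(prof, smoothing_um=0.15, min_prominence_frac=0.1)
            assert len(minima) == len(expected)
            worst = max(worst, np.max(np.abs(minima.positions_um - expected)))
        assert worst <= 0.05

    def test_double_band_profile_has_iband_and_mline_minima(self):
        """Noiseless double-band lattice: minima at both I-band and M-line
        centres, i.e. spaced at half the period."""
        img, gt = generate_lattice_image(LatticeParams(), noiseless=True)
        prof = extract_line_profile(img, (191.5, 79.5), 0.0, 12.0, width_px=1)
        minima = detect_minima(prof)
        spacings = np.diff(minima.positions_um)
        assert gt.band_regime == "double"
        assert np.allclose(spacings, 1.84 / 2, atol=0.02)

    def test_flat_profile_yields_insufficient_flag(self):
        prof = LineProfile(
            np.arange(0, 1, 0.1), np.full(10, 5.0), 0.1, ((0, 0), (9, 0))
        )
        minima = detect_minima(prof)
        assert minima.insufficient
        assert len(minima) == 0


class TestClassifyMinima:
    def _lattice_minima(self, fwhm):
        img, gt = generate_lattice_image(
            LatticeParams(psf_fwhm_um=fwhm), noiseless=True
        )
        prof = extract_line_profile(img, (191.5, 79.5), 0.0, 14.0, width_px=5)
        return gt, prof, detect_minima(prof)

    def test_double_band_mline_minima_excluded(self):
        """M-line minima (shallower, alternating) are labelled
        aband_internal; retained minima sit on the true I-band grid."""
        gt, prof, minima = self._lattice_minima(0.25)
        out = classify_minima(minima, prof)
        retained = out.positions_um[out.retained]
        excluded = out.positions_um[~out.retained]
        assert len(excluded) > 0
        assert np.allclose(np.diff(retained), 1.84, atol=0.02)
        # excluded minima interleave: they sit half a period off the grid
        phase = np.mod(excluded - retained[0], 1.84)
        assert np.allclose(phase, 1.84 / 2, atol=0.05)

    def test_single_band_all_retained(self):
        gt, prof, minima = self._lattice_minima(1.2)
        assert gt.band_regime == "single"
        out = classify_minima(minima, prof)
        assert out.retained.all()

    def test_two_equal_minima_tie_retains_both(self):
        prof = cosine_profile(2.0, 4.0)
        minima = detect_minima(prof, smoothing_um=0.05)
        out = classify_minima(minima, prof)
        assert out.retained.all()


class TestMeasure:
    def test_recovery_at_study_period(self):
        """Recovery of the 1.84 um adult-murine-LV period, noiseless."""
        img, _ = generate_lattice_image(LatticeParams(), noiseless=True)
        m = measure_sarcomere_lengths(img)
        assert m.ok
        assert m.mean_um == pytest.approx(1.84, abs=0.02)
        assert m.band_regime_detected == "double"

    def test_cosine_lattice_exact_periodicity(self):
        """Pure cosine intensity: all intervals equal the period, SD ~ 0."""
        pos_x = np.arange(256) * 0.04
        row = 100 - 50 * np.cos(2 * np.pi * pos_x / 2.0)
        img = Image(np.tile(row, (64, 1)), 0.04)
        m = measure_sarcomere_lengths(
            img, line=(5.0, 31.5, 250.0, 31.5), config=SarcomereConfig()
        )
        assert m.ok
        assert np.allclose(m.lengths_um, 2.0, atol=0.01)
        assert m.sd_um <= 0.01

    def test_naive_estimator_halves_the_period(self):
        """Without A-band exclusion the double-band estimate collapses to
        about half the true period; with exclusion it is within one pixel."""
        img, _ = generate_lattice_image(LatticeParams(seed=2))
        naive = measure_sarcomere_lengths(
            img, config=SarcomereConfig(exclude_aband=False, sl_bounds_um=None)
        )
        excl = measure_sarcomere_lengths(img)
        assert naive.ok and excl.ok
        assert abs(naive.mean_um - 1.84) / 1.84 > 0.25
        assert abs(excl.mean_um - 1.84) <= 0.04

    @pytest.mark.parametrize("angle", [0.0, 17.0, 45.0, 90.0])
    def test_rotation_invariance(self, angle):
        img, _ = generate_lattice_image(
            LatticeParams(orientation_deg=angle, shape_px=(256, 256), seed=4)
        )
        m = measure_sarcomere_lengths(img)
        assert m.ok
        assert m.mean_um == pytest.approx(1.84, rel=0.02)

    def test_scale_consistency(self):
        """Doubling pixel_um with the same physical content leaves the
        recovered SL unchanged within localization error."""
        means = []
        for px, shape in ((0.04, (160, 384)), (0.08, (80, 192))):
            img, _ = generate_lattice_image(
                LatticeParams(pixel_um=px, shape_px=shape, seed=6)
            )
            m = measure_sarcomere_lengths(img)
            assert m.ok
            means.append(m.mean_um)
        assert abs(means[0] - means[1]) <= 0.08  # one coarse pixel

    def test_summary_recomputable_from_lengths(self):
        img, _ = generate_lattice_image(LatticeParams(seed=9))
        m = measure_sarcomere_lengths(img)
        assert m.n == len(m.lengths_um)
        assert m.mean_um == pytest.approx(float(np.mean(m.lengths_um)))
        assert m.sd_um == pytest.approx(float(np.std(m.lengths_um, ddof=1)))

    def test_failure_result_not_exception(self):
        """A structureless image yields n=0 with a reason, not a crash."""
        rng = np.random.default_rng(0)
        img = Image(rng.poisson(100, (64, 64)).astype(float), 0.04)
        m = measure_sarcomere_lengths(img)
        assert not m.ok
        assert m.n == 0
        assert m.failure_reason in ("insufficient_minima", "no_intervals_in_bounds")
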