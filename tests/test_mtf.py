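"""Edge-method MTF chain and bar-pattern modulation."""

import math

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d
from scipy.special import ndtr

from ctiq.mtf import (
    EdgeProfileSet,
    MTFCurve,
    aggregate_mtf,
    bar_pattern_modulation,
    esf_to_lsf,
    extract_edge_profiles,
    lsf_to_mtf,
    mtf_at_frequency,
)
from ctiq.phantoms import BarPattern, Ellipse, PhantomLayout, render_layout
from ctiq.simulate import AlgorithmModel, ScanCondition, simulate_stack

STEP = 0.35


class TestEsfToLsf:
    def test_unit_step_gives_impulse(self):
        esf = np.r_[np.zeros(10), np.ones(10)]
        lsf = esf_to_lsf(esf, STEP)
        # central difference spreads the unit step over two samples of 1/(2h)
        assert lsf.max() == pytest.approx(1.0 / (2 * STEP))
        assert lsf.sum() == pytest.approx(1.0 / STEP, rel=1e-9)
        assert lsf.size == esf.size

    def test_linear_ramp_gives_constant(self):
        esf = np.arange(20) * 3.0
        lsf = esf_to_lsf(esf, STEP)
        assert np.allclose(lsf, 3.0 / STEP)

    def test_erf_esf_gives_gaussian_lsf(self):
        sigma = 0.8
        x = np.arange(-8, 8, 0.1)
        esf = ndtr(x / sigma)
        lsf = esf_to_lsf(esf, 0.1)
        mean = np.sum(x * lsf) / lsf.sum()
        sd = math.sqrt(np.sum((x - mean) ** 2 * lsf) / lsf.sum())
        assert sd == pytest.approx(sigma, abs=0.02)

    def test_nonuniform_spacing_rejected(self):
        d = np.array([0.0, 0.1, 0.2, 0.35, 0.4])
        with pytest.raises(ValueError, match="uniform"):
            esf_to_lsf(np.ones(5), distances_mm=d)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            esf_to_lsf(np.ones(4), STEP)


class TestLsfToMtf:
    def test_impulse_gives_flat_unity(self):
        lsf = np.zeros(32)
        lsf[16] = 1.0
        curve = lsf_to_mtf(lsf, STEP)
        assert np.allclose(curve.modulation, 1.0)
        assert curve.modulation[0] == 1.0

    def test_gaussian_closed_form(self):
        sigma = 0.8
        x = np.arange(-10, 10, 0.1)
        lsf = np.exp(-(x**2) / (2 * sigma**2))
        curve = lsf_to_mtf(lsf, 0.1, pad_factor=8)
        f = curve.frequencies_lp_cm / 10.0
        analytic = np.exp(-2 * np.pi**2 * sigma**2 * f**2)
        m = analytic >= 0.05
        assert np.max(np.abs(curve.modulation[m] / analytic[m] - 1)) < 0.01

    def test_rectangle_gives_sinc(self):
        w = 2.0  # mm
        step = 0.05
        lsf = np.zeros(400)
        lsf[100:100 + int(w / step)] = 1.0
        curve = lsf_to_mtf(lsf, step, pad_factor=8)
        f = curve.frequencies_lp_cm / 10.0
        analytic = np.abs(np.sinc(f * w))
        before_null = f < 0.9 / w
        sel = before_null & (analytic > 0.05)
        assert np.max(np.abs(curve.modulation[sel] - analytic[sel])) < 0.02

    def test_zero_dc_rejected(self):
        lsf = np.r_[np.ones(8), -np.ones(8)]
        with pytest.raises(ValueError, match="DC"):
            lsf_to_mtf(lsf, STEP)


class TestMtfAtFrequency:
    def _curve(self):
        return MTFCurve(
            frequencies_lp_cm=np.array([0.0, 4.0, 6.0, 8.0]),
            modulation=np.array([1.0, 0.6, 0.4, 0.2]),
            nyquist_lp_cm=8.0,
        )

    def test_zero_frequency_is_unity(self):
        assert mtf_at_frequency(self._curve(), 0.0) == 1.0

    def test_midpoint_interpolation(self):
        assert mtf_at_frequency(self._curve(), 5.0) == pytest.approx(0.5)

    def test_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            mtf_at_frequency(self._curve(), 9.0)


@pytest.fixture(scope="module")
def edge_stack(ctp404):
    """Noiseless ctp404 with a 0.8 mm Gaussian system PSF."""
    model = AlgorithmModel("FBP", noise_ref=0.0, psf_sigma_points=((1.0, 0.8),))
    return simulate_stack(ctp404, ScanCondition("FBP", 24.0), model, 1, 0)


class TestExtractProfiles:
    def test_profile_geometry(self, ctp404, edge_stack):
        air = ctp404.feature("air")
        ps = extract_edge_profiles(edge_stack.images[0], edge_stack.pixel_spacing_mm, air.center)
        assert len(ps.profiles) == 4
        assert ps.step_mm == pytest.approx(edge_stack.pixel_spacing_mm / 2)
        # profiles start inside the air target
        for p in ps.profiles:
            assert p.values[0] == pytest.approx(-1000.0, abs=2.0)
            assert p.values[-1] == pytest.approx(100.0, abs=5.0)

    def test_opposite_orientations_mirror_on_symmetric_target(self):
        body = Ellipse("body", (0.0, 0.0), (60.0, 60.0), 100.0)
        from ctiq.phantoms import Disk

        lay = PhantomLayout("sym", body, (Disk("air", (0.0, 0.0), 6.1, -1000.0),))
        img, sp = render_layout(lay, 512, 18.0)
        ps = extract_edge_profiles(img, sp, (0.0, 0.0), orientations=(0.0, 180.0))
        a, b = ps.profiles
        assert np.allclose(a.values, b.values, atol=1e-6)

    def test_profile_leaving_image_reports_orientation(self, edge_stack):
        with pytest.raises(ValueError, match="90"):
            extract_edge_profiles(
                edge_stack.images[0], edge_stack.pixel_spacing_mm,
                (0.0, 170.0), orientations=(90.0,),
            )

    def test_step_larger_than_pixel_rejected(self, edge_stack):
        with pytest.raises(ValueError, match="step"):
            extract_edge_profiles(
                edge_stack.images[0], edge_stack.pixel_spacing_mm,
                (0.0, 58.4), step_mm=2.0,
            )


class TestAggregateMtf:
    def test_duplicated_profiles_change_nothing(self, ctp404, edge_stack):
        air = ctp404.feature("air")
        ps = extract_edge_profiles(edge_stack.images[0], edge_stack.pixel_spacing_mm, air.center)
        one = aggregate_mtf([ps], spacing_mm=edge_stack.pixel_spacing_mm, debias_noise=False)
        two = aggregate_mtf([ps, ps], spacing_mm=edge_stack.pixel_spacing_mm, debias_noise=False)
        assert np.allclose(one.modulation, two.modulation)

    def test_positive_scaling_invariance(self, ctp404, edge_stack):
        """Profiles with magnitudes M and 3M aggregate to the curve of M."""
        air = ctp404.feature("air")
        ps = extract_edge_profiles(edge_stack.images[0], edge_stack.pixel_spacing_mm, air.center)
        import copy

        ps3 = copy.deepcopy(ps)
        for p in ps3.profiles:
            p.values = 3.0 * p.values
        ref = aggregate_mtf([ps], spacing_mm=edge_stack.pixel_spacing_mm, debias_noise=False)
        mix = aggregate_mtf([ps, ps3], spacing_mm=edge_stack.pixel_spacing_mm, debias_noise=False)
        assert np.allclose(ref.modulation, mix.modulation, atol=1e-9)

    def test_sum_then_normalize_ordering(self, ctp404):
        """Aggregation must sum magnitudes before normalizing, which differs
        from normalizing each profile's spectrum first on heterogeneous data."""
        air = ctp404.feature("air")
        model = AlgorithmModel("FBP", noise_ref=30.0, psf_sigma_points=((1.0, 0.8),))
        st = simulate_stack(ctp404, ScanCondition("FBP", 24.0), model, 2, seed=13)
        sets = [
            extract_edge_profiles(st.images[k], st.pixel_spacing_mm, air.center, replicate=k)
            for k in range(2)
        ]
        agg = aggregate_mtf(sets, spacing_mm=st.pixel_spacing_mm,
                            debias_noise=False, correct_apertures=False)
        # manual normalize-then-average estimator over the same profiles
        step = sets[0].step_mm
        nfft = len(agg.frequencies_lp_cm) * 2 - 2
        per_profile = []
        summed = None
        for ps in sets:
            for p in ps.profiles:
                lsf = esf_to_lsf(p.values, step)
                lsf = lsf - lsf[-max(1, round(0.1 * lsf.size)):].mean()
                mag = np.abs(np.fft.rfft(lsf, nfft))
                per_profile.append(mag / mag[0])
                summed = mag if summed is None else summed + mag
        norm_then_avg = np.mean(per_profile, axis=0)
        sum_then_norm = summed / summed[0]
        assert np.allclose(agg.modulation, sum_then_norm, atol=1e-12)
        assert not np.allclose(agg.modulation, norm_then_avg, atol=1e-4)

    def test_recovers_analytic_gaussian_noiseless(self, ctp404, edge_stack):
        air = ctp404.feature("air")
        ps = extract_edge_profiles(edge_stack.images[0], edge_stack.pixel_spacing_mm, air.center)
        curve = aggregate_mtf([ps], spacing_mm=edge_stack.pixel_spacing_mm,
                              edge_radius_mm=air.radius)
        f = curve.frequencies_lp_cm / 10.0
        analytic = np.exp(-2 * np.pi**2 * 0.8**2 * f**2)
        m = analytic >= 0.1
        assert np.max(np.abs(curve.modulation[m] / analytic[m] - 1)) < 0.02

    def test_monotone_ordering_with_psf_width(self, ctp404):
        air = ctp404.feature("air")
        curves = []
        for sigma in (0.5, 0.9):
            model = AlgorithmModel("FBP", noise_ref=0.0, psf_sigma_points=((1.0, sigma),))
            st = simulate_stack(ctp404, ScanCondition("FBP", 24.0), model, 1, 0)
            ps = extract_edge_profiles(st.images[0], st.pixel_spacing_mm, air.center)
            curves.append(
                aggregate_mtf([ps], spacing_mm=st.pixel_spacing_mm, edge_radius_mm=air.radius)
            )
        f = curves[0].frequencies_lp_cm
        upto = f <= curves[0].nyquist_lp_cm / 2
        assert np.all(curves[0].modulation[upto] >= curves[1].modulation[upto] - 0.02)

    def test_affine_hu_invariance(self, ctp404, edge_stack):
        air = ctp404.feature("air")
        img = edge_stack.images[0]
        sp = edge_stack.pixel_spacing_mm
        a = aggregate_mtf(
            [extract_edge_profiles(img, sp, air.center)], spacing_mm=sp, debias_noise=False
        )
        b = aggregate_mtf(
            [extract_edge_profiles(2.5 * img + 300.0, sp, air.center)],
            spacing_mm=sp, debias_noise=False,
        )
        assert np.allclose(a.modulation, b.modulation, atol=1e-9)

    def test_mismatched_steps_rejected(self, ctp404, edge_stack):
        air = ctp404.feature("air")
        img = edge_stack.images[0]
        sp = edge_stack.pixel_spacing_mm
        a = extract_edge_profiles(img, sp, air.center, step_mm=sp / 2)
        b = extract_edge_profiles(img, sp, air.center, step_mm=sp / 4)
        with pytest.raises(ValueError, match="step"):
            aggregate_mtf([a, b])


class TestBarPattern:
    def _bar_layout(self, freq=3.0):
        body = Ellipse("body", (0.0, 0.0), (100.0, 100.0), 100.0)
        bp = BarPattern("bars", (0.0, 0.0), freq, n_bars=5, bar_length=12.0, hu=1000.0)
        return PhantomLayout("bars", body, (bp,)), bp

    def test_unblurred_render_fully_modulated(self):
        lay, bp = self._bar_layout(freq=3.0)
        img, sp = render_layout(lay, 512, 36.0)
        assert bar_pattern_modulation(img, sp, bp, 100.0) >= 0.95

    def test_wide_psf_washes_out(self):
        lay, bp = self._bar_layout(freq=7.0)
        m = AlgorithmModel("FBP", noise_ref=0.0, psf_sigma_points=((1.0, 3.0),))
        st = simulate_stack(lay, ScanCondition("FBP", 24.0), m, 1, 0, 512, 36.0)
        assert bar_pattern_modulation(st.images[0], st.pixel_spacing_mm, bp, 100.0) < 0.05

    def test_matches_square_wave_convolution_oracle(self):
        """Gaussian sigma = 0.5 mm on 7 lp/cm bars vs a brute-force 1-D
        square-wave convolution (Coltman-equivalent) oracle."""
        sigma = 0.5
        lay, bp = self._bar_layout(freq=7.0)
        m = AlgorithmModel("FBP", noise_ref=0.0, psf_sigma_points=((1.0, sigma),))
        st = simulate_stack(lay, ScanCondition("FBP", 24.0), m, 1, 0, 1024, 36.0)
        measured = bar_pattern_modulation(st.images[0], st.pixel_spacing_mm, bp, 100.0)
        dx = 0.001
        x = np.arange(-20, 20, dx)
        prof = np.zeros_like(x)
        p, w = bp.period_mm, bp.bar_width_mm
        centers = (np.arange(bp.n_bars) - (bp.n_bars - 1) / 2) * p
        for c in centers:
            prof[(x >= c - w / 2) & (x <= c + w / 2)] = 1.0
        blurred = gaussian_filter1d(prof, sigma / dx)
        peaks = [blurred[np.abs(x - c) <= p / 4].max() for c in centers]
        troughs = [blurred[np.abs(x - (c + p / 2)) <= p / 4].min() for c in centers[:-1]]
        oracle = np.mean(peaks) - np.mean(troughs)
        assert measured == pytest.approx(oracle, abs=0.05)

    def test_too_few_bars_rejected(self, ctp404):
        img, sp = render_layout(ctp404, 256, 36.0)
        bp = BarPattern("two", (0.0, 0.0), 5.0, n_bars=2)
        with pytest.raises(ValueError, match="3 bar"):
            bar_pattern_modulation(img, sp, bp, 100.0)
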