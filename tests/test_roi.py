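"""ROI metrics: noise statistic, CNR, insert HU, derived ratio tables."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_stack
from ctiq.roi import (
    ROISpec,
    fold_improvement,
    hu_difference_from_reference,
    insert_rois_for_layout,
    measure_cnr,
    measure_hu,
    measure_noise,
)

SPACING = 0.5  # mm, 128-pixel test images -> 64 mm field


def _roi(label="r", center=(0.0, 0.0), area=0.4):
    return ROISpec(label, center, area)


def _noise_image(rng, sigma=5.0, mean=0.0, n=128):
    return rng.normal(mean, sigma, (n, n))


class TestMeasureNoise:
    def test_constant_image_zero_noise(self):
        stack = make_stack(np.full((2, 128, 128), 42.0), SPACING)
        nm = measure_noise(stack, [_roi()])
        assert nm.summary == 0.0

    def test_mean_of_roi_sds(self):
        """The statistic equals the arithmetic mean of the per-ROI sample SDs
        (independently recomputed from the masks)."""
        rng = np.random.default_rng(0)
        img = _noise_image(rng)
        stack = make_stack(img, SPACING)
        rois = [_roi("a", (-15.0, 0.0)), _roi("b", (0.0, 15.0)), _roi("c", (15.0, 0.0))]
        nm = measure_noise(stack, rois)
        expected = np.mean(
            [img[r.mask((128, 128), SPACING)].std(ddof=1) for r in rois]
        )
        assert nm.summary == pytest.approx(expected)
        assert nm.n_rois == 3
        assert nm.summary == pytest.approx(np.mean(nm.per_replicate))

    def test_small_roi_rejected(self):
        stack = make_stack(np.zeros((1, 128, 128)), SPACING)
        with pytest.raises(ValueError, match="pixels"):
            measure_noise(stack, [ROISpec("tiny", (0, 0), 0.001)])

    def test_roi_outside_image_rejected(self):
        stack = make_stack(np.zeros((1, 128, 128)), SPACING)
        with pytest.raises(ValueError, match="inside"):
            measure_noise(stack, [_roi("edge", (31.0, 0.0))])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(c=st.floats(min_value=0.1, max_value=50.0))
    def test_scale_equivariance(self, c):
        rng = np.random.default_rng(1)
        img = _noise_image(rng)
        base = measure_noise(make_stack(img, SPACING), [_roi()]).summary
        scaled = measure_noise(make_stack(c * img, SPACING), [_roi()]).summary
        assert scaled == pytest.approx(c * base, rel=1e-9)

    def test_generator_sigma_recovered(self, uniform_layout):
        from ctiq.simulate import AlgorithmModel, ScanCondition, simulate_stack

        m = AlgorithmModel("FBP", noise_ref=10.0)
        stk = simulate_stack(uniform_layout, ScanCondition("FBP", 1.0), m, 10,
                             seed=4, matrix_size=256, dfov_cm=9.0)
        rois = [
            ROISpec(f"bg{i}", (15 * math.cos(math.radians(a)), 15 * math.sin(math.radians(a))), 0.4)
            for i, a in enumerate((90, 210, 330))
        ]
        nm = measure_noise(stk, rois)
        assert nm.summary == pytest.approx(10.0, abs=0.6)


class TestMeasureCNR:
    def test_direct_formula(self):
        """object 10, background 0, background SD 5 -> CNR 2.0."""
        rng = np.random.default_rng(2)
        img = np.zeros((128, 128))
        target = _roi("t", (0.0, 0.0))
        bgs = [_roi("b1", (-20.0, 0.0)), _roi("b2", (20.0, 0.0)), _roi("b3", (0.0, 20.0))]
        img[target.mask((128, 128), SPACING)] = 10.0
        # fill pooled background with noise then rescale to SD exactly 5
        bg_mask = np.zeros((128, 128), bool)
        for b in bgs:
            bg_mask |= b.mask((128, 128), SPACING)
        noise = rng.normal(0, 1, bg_mask.sum())
        img[bg_mask] = (noise - noise.mean()) / noise.std(ddof=1) * 5.0
        cm = measure_cnr(make_stack(img, SPACING), target, bgs)
        assert cm.summary == pytest.approx(2.0, rel=1e-6)

    def test_zero_contrast(self):
        """object mean == background mean -> CNR exactly 0."""
        rng = np.random.default_rng(3)
        img = np.zeros((128, 128))
        target = _roi("t", (0.0, 0.0))
        bgs = [_roi("b", (20.0, 0.0))]
        bg_mask = bgs[0].mask((128, 128), SPACING)
        noise = rng.normal(0, 1, bg_mask.sum())
        img[bg_mask] = (noise - noise.mean()) * 4.0  # mean 0, sd > 0
        cm = measure_cnr(make_stack(img, SPACING), target, bgs)
        assert cm.summary == pytest.approx(0.0, abs=1e-12)

    def test_printed_sensitometry_values_give_cnr_23(self):
        """Acrylic 126 HU vs background 103 HU with SD 1.0 -> CNR 23.0."""
        rng = np.random.default_rng(4)
        img = np.full((128, 128), 103.0)
        target = _roi("t", (0.0, 0.0))
        bgs = [_roi("b1", (-20.0, 0.0)), _roi("b2", (20.0, 0.0)), _roi("b3", (0.0, 20.0))]
        img[target.mask((128, 128), SPACING)] = 126.0
        bg_mask = np.zeros((128, 128), bool)
        for b in bgs:
            bg_mask |= b.mask((128, 128), SPACING)
        noise = rng.normal(0, 1, bg_mask.sum())
        img[bg_mask] = 103.0 + (noise - noise.mean()) / noise.std(ddof=1) * 1.0
        cm = measure_cnr(make_stack(img, SPACING), target, bgs)
        assert cm.summary == pytest.approx(23.0, rel=1e-6)

    def test_unequal_roi_areas_rejected(self):
        stack = make_stack(np.zeros((1, 128, 128)), SPACING)
        with pytest.raises(ValueError, match="identical area"):
            measure_cnr(stack, _roi("t", (0, 0), 0.4), [_roi("b", (20, 0), 0.8)])

    def test_noiseless_background_rejected(self):
        stack = make_stack(np.zeros((1, 128, 128)), SPACING)
        with pytest.raises(ValueError, match="noiseless"):
            measure_cnr(stack, _roi("t", (0, 0)), [_roi("b", (20, 0))])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(offset=st.floats(min_value=-500.0, max_value=500.0))
    def test_invariant_to_constant_hu_offset(self, offset):
        rng = np.random.default_rng(5)
        img = rng.normal(0, 5, (128, 128))
        img[_roi("t", (0, 0)).mask((128, 128), SPACING)] += 12.0
        t, bgs = _roi("t", (0, 0)), [_roi("b", (20, 0))]
        a = measure_cnr(make_stack(img, SPACING), t, bgs).summary
        b = measure_cnr(make_stack(img + offset, SPACING), t, bgs).summary
        assert b == pytest.approx(a, rel=1e-9)


class TestMeasureHU:
    def test_noiseless_truth_and_bias(self, ctp404):
        from ctiq.simulate import AlgorithmModel, ScanCondition, simulate_stack

        m = AlgorithmModel("FBP", noise_ref=0.0, psf_sigma_points=((1.0, 1e-3),))
        stk = simulate_stack(ctp404, ScanCondition("FBP", 24.0), m, 1, 0, matrix_size=512)
        rois = insert_rois_for_layout(ctp404)
        by_mat = {h.material: h.mean for h in measure_hu(stk, rois, ctp404)}
        assert by_mat["Teflon"] == pytest.approx(990.0)
        assert by_mat["air"] == pytest.approx(-1000.0)

    def test_unknown_label_rejected(self, ctp404):
        stack = make_stack(np.zeros((1, 512, 512)), 0.703125)
        with pytest.raises(KeyError):
            measure_hu(stack, {"gold": ROISpec("gold", (0, 0), 0.4)}, ctp404)

    def test_sd_recovers_generator_sigma(self, ctp404):
        from ctiq.simulate import AlgorithmModel, ScanCondition, simulate_stack

        m = AlgorithmModel("FBP", noise_ref=5.0, dose_exponent=0.0)
        stk = simulate_stack(ctp404, ScanCondition("FBP", 24.0), m, 10, 6, matrix_size=512)
        rois = insert_rois_for_layout(ctp404, labels=["water", "acrylic"])
        for h in measure_hu(stk, rois, ctp404):
            assert h.sd == pytest.approx(5.0, abs=0.5)


class TestFoldImprovement:
    def _summaries(self):
        return pd.DataFrame(
            [
                {"algorithm": "FBP", "dose": 1.0, "pitch": 0.984, "value": 66.5},
                {"algorithm": "MBIR", "dose": 1.0, "pitch": 0.984, "value": 13.3},
            ]
        )

    def test_reference_vs_itself_is_unity(self):
        out = fold_improvement(self._summaries(), "noise")
        fbp = out[out.algorithm == "FBP"]["fold_improvement"].iloc[0]
        assert fbp == 1.0

    def test_noise_ratio_is_inverted(self):
        out = fold_improvement(self._summaries(), "noise")
        mbir = out[out.algorithm == "MBIR"].iloc[0]
        assert mbir["fold_improvement"] == pytest.approx(5.0)
        assert mbir["orientation"] == "reference/value"

    def test_cnr_ratio_is_direct(self):
        df = self._summaries()  # reuse numbers as CNRs
        out = fold_improvement(df, "cnr")
        mbir = out[out.algorithm == "MBIR"].iloc[0]
        assert mbir["fold_improvement"] == pytest.approx(13.3 / 66.5)
        assert mbir["orientation"] == "value/reference"

    def test_missing_reference_cell(self):
        df = self._summaries()
        df.loc[1, "dose"] = 6.0  # MBIR cell without an FBP partner
        df = df[df.algorithm != "FBP"]
        with pytest.raises(ValueError, match="reference"):
            fold_improvement(df, "noise")


class TestHUDifference:
    def _printed(self):
        # means lifted from the published sensitometry table at 0.984 pitch
        return pd.DataFrame(
            [
                {"material": "acrylic", "algorithm": "FBP", "dose": 24.0, "mean": 126.0},
                {"material": "acrylic", "algorithm": "MBIR", "dose": 1.0, "mean": 120.0},
                {"material": "LDPE", "algorithm": "FBP", "dose": 24.0, "mean": -79.0},
                {"material": "LDPE", "algorithm": "MBIR", "dose": 3.0, "mean": -86.0},
            ]
        )

    def test_reference_differences(self):
        out = hu_difference_from_reference(self._printed(), ("FBP", 24.0))
        acr = out[(out.material == "acrylic") & (out.algorithm == "MBIR")]["delta_hu"].iloc[0]
        ldpe = out[(out.material == "LDPE") & (out.algorithm == "MBIR")]["delta_hu"].iloc[0]
        assert acr == pytest.approx(-6.0)
        assert ldpe == pytest.approx(-7.0)
        refs = out[(out.algorithm == "FBP") & (out.dose == 24.0)]["delta_hu"]
        assert (refs == 0.0).all()

    def test_missing_material_in_reference(self):
        df = self._printed()
        df = df[~((df.material == "LDPE") & (df.algorithm == "FBP"))]
        with pytest.raises(ValueError, match="missing"):
            hu_difference_from_reference(df, ("FBP", 24.0))
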