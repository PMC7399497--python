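"""Frame merging, scaling and infinite-dilution extrapolation."""

import numpy as np
import pytest

from pdzscaffold.saxs_model import ScatteringCurve, debye_curve
from pdzscaffold.saxs_reduce import (
    DilutionSeries,
    FrameSeries,
    extrapolate_to_zero,
    merge_frames,
    scale_to_reference,
)
from pdzscaffold.synthetic_data import (
    default_interference,
    make_dilution_series,
    make_frame_series,
    noisy_curve,
)


@pytest.fixture(scope="module")
def base_curve(q_grid, dumbbell):
    return debye_curve(dumbbell, q_grid)


class TestMergeFrames:
    def test_identical_frames_average_and_sigma(self, q_grid):
        I = np.full_like(q_grid, 100.0)
        sigma = np.full_like(q_grid, 4.0)
        frames = [ScatteringCurve(q_grid, I, sigma) for _ in range(4)]
        res = merge_frames(FrameSeries(frames))
        np.testing.assert_allclose(res.merged.I, 100.0)
        np.testing.assert_allclose(res.merged.sigma, 2.0)  # 4 / sqrt(4)
        assert res.excluded == []

    def test_damaged_frame_excluded(self, base_curve):
        series, truth = make_frame_series(
            base_curve, n_frames=6, damaged_frames=(4,), noise_level=0.003, seed=0
        )
        res = merge_frames(series)
        assert res.excluded == [4]

    def test_single_frame_passthrough(self, base_curve):
        res = merge_frames(FrameSeries([base_curve]))
        np.testing.assert_allclose(res.merged.I, base_curve.I)

    def test_all_excluded_raises(self, q_grid):
        clean = ScatteringCurve(q_grid, np.exp(-q_grid * 5) + 1.0)
        # first frame is the reference; make every later frame damaged and
        # shrink the threshold so even tiny deviations reject
        bad = ScatteringCurve(q_grid, clean.I * (1 + 10 * np.exp(-(q_grid / 0.05) ** 2)))
        with pytest.raises(ValueError, match="threshold"):
            # reference frame itself always survives, so force rejection of
            # everything by an impossible negative threshold
            merge_frames(FrameSeries([bad, clean]), damage_threshold=-2.0)

    def test_survivor_permutation_invariance(self, base_curve):
        """Averaging does not depend on the order of the surviving frames
        (the first frame stays first: it anchors the damage reference)."""
        rng = np.random.default_rng(1)
        frames = [noisy_curve(base_curve, 0.01, rng) for _ in range(5)]
        a = merge_frames(FrameSeries(frames))
        b = merge_frames(FrameSeries([frames[0]] + frames[1:][::-1]))
        np.testing.assert_allclose(a.merged.I, b.merged.I, rtol=1e-12)


class TestScaleToReference:
    def test_self_scale_is_unity(self, base_curve):
        c = ScatteringCurve(base_curve.q, base_curve.I, 0.01 * base_curve.I)
        _, s = scale_to_reference(c, c, (0.2, 0.4))
        assert s == pytest.approx(1.0, rel=1e-12)

    def test_half_curve_scales_by_two(self, base_curve):
        ref = ScatteringCurve(base_curve.q, base_curve.I, 0.01 * base_curve.I)
        halved = ref.scaled(0.5)
        scaled, s = scale_to_reference(halved, ref, (0.2, 0.4))
        assert s == pytest.approx(2.0, rel=1e-12)
        np.testing.assert_allclose(scaled.I, ref.I, rtol=1e-12)

    def test_roundtrip_property(self, base_curve):
        ref = ScatteringCurve(base_curve.q, base_curve.I, 0.01 * base_curve.I)
        for s0 in (0.3, 1.7, 12.0):
            _, s = scale_to_reference(ref.scaled(s0), ref, (0.2, 0.4))
            assert s * s0 == pytest.approx(1.0, rel=1e-10)

    def test_noisy_recovery_within_three_se(self, base_curve):
        rng = np.random.default_rng(11)
        ref = noisy_curve(base_curve, 0.01, rng)
        halved = noisy_curve(base_curve.scaled(0.5), 0.01, rng)
        n_mc = 50
        scales = []
        for k in range(n_mc):
            r = np.random.default_rng(100 + k)
            h = noisy_curve(base_curve.scaled(0.5), 0.01, r)
            _, s = scale_to_reference(h, ref, (0.2, 0.4))
            scales.append(s)
        scales = np.asarray(scales)
        se = scales.std(ddof=1) / np.sqrt(n_mc)
        assert abs(scales.mean() - 2.0) <= 3 * max(se, 1e-6) + 0.02

    def test_insufficient_overlap(self, base_curve):
        c = ScatteringCurve(base_curve.q, base_curve.I, 0.01 * base_curve.I)
        with pytest.raises(ValueError, match="overlap"):
            scale_to_reference(c, c, (0.9, 1.0))


class TestExtrapolation:
    def test_zero_slope_returns_input(self, q_grid):
        I = np.exp(-(q_grid**2) * 150)
        a = ScatteringCurve(q_grid, I, 0.01 * I + 1e-9, concentration=1.0)
        b = ScatteringCurve(q_grid, I, 0.01 * I + 1e-9, concentration=0.5)
        out = extrapolate_to_zero(DilutionSeries([a, b]))
        np.testing.assert_allclose(out.I, I, rtol=1e-12)

    def test_exact_linear_model_is_machine_precision(self, base_curve):
        beta = default_interference(base_curve.q)
        curves = []
        for c in (1.0, 0.5, 0.25):
            I = base_curve.I * (1 - beta * c)
            curves.append(
                ScatteringCurve(base_curve.q, I, np.full_like(I, 1.0),
                                concentration=c)
            )
        out = extrapolate_to_zero(DilutionSeries(curves))
        np.testing.assert_allclose(out.I, base_curve.I, rtol=1e-10)

    def test_degenerate_sigma_floor(self, q_grid):
        I = np.full_like(q_grid, 10.0)
        tiny = np.full_like(q_grid, 1e-30)
        a = ScatteringCurve(q_grid, I, tiny, concentration=1.0)
        b = ScatteringCurve(q_grid, 0.9 * I, tiny, concentration=0.5)
        out = extrapolate_to_zero(DilutionSeries([a, b]))
        assert np.all(np.isfinite(out.I))
        assert np.all(np.isfinite(out.sigma))

    def test_identical_concentrations_rejected(self, q_grid):
        I = np.full_like(q_grid, 10.0)
        a = ScatteringCurve(q_grid, I, concentration=1.0)
        b = ScatteringCurve(q_grid, I, concentration=1.0)
        with pytest.raises(ValueError):
            DilutionSeries([a, b])

    def test_output_labelled_zero_concentration(self, base_curve):
        series, _ = make_dilution_series(base_curve, (1.0, 0.5), seed=0)
        out = extrapolate_to_zero(series)
        assert "[0]" in out.label
        assert out.concentration == 0.0

    def test_interference_biases_apparent_size_downward(self, base_curve):
        """At finite concentration the low-q suppression lowers apparent
        I(0) and Rg; extrapolation removes the bias."""
        from pdzscaffold.saxs_model import guinier_fit

        series, _ = make_dilution_series(
            base_curve, (1.0, 0.5, 0.25), noise_level=0.002, seed=3
        )
        rg_conc = guinier_fit(series.curves[0]).rg
        out = extrapolate_to_zero(series)
        rg_ext = guinier_fit(out).rg
        rg_true = guinier_fit(base_curve).rg
        assert rg_conc < rg_true
        assert abs(rg_ext - rg_true) < abs(rg_conc - rg_true)
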