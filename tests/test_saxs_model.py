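"""Forward model and curve-analysis tests against closed forms."""

import numpy as np
import pytest

from pdzscaffold.saxs_model import (
    ScatteringCurve,
    debye_curve,
    guinier_fit,
    kratky_transform,
    pr_transform,
    read_dat,
    write_dat,
)
from pdzscaffold.structures import CoordinateSet, radius_of_gyration


def _sphere_beads(radius, n, seed=0):
    rng = np.random.default_rng(seed)
    pts = []
    while len(pts) < n:
        cand = rng.uniform(-radius, radius, (2 * n, 3))
        pts.extend(cand[(cand**2).sum(1) <= radius**2].tolist())
    return np.asarray(pts[:n])


class TestDebye:
    def test_single_scatterer_flat(self, q_grid):
        cs = CoordinateSet.from_points([[0, 0, 0]], weight=3.0)
        curve = debye_curve(cs, q_grid)
        np.testing.assert_allclose(curve.I, 9.0)

    def test_two_scatterers_closed_form(self, q_grid):
        r, f = 25.0, 2.0
        cs = CoordinateSet.from_points([[0, 0, 0], [r, 0, 0]], weight=f)
        curve = debye_curve(cs, q_grid)
        qr = q_grid * r
        expected = 2 * f**2 * (1 + np.sin(qr) / qr)
        np.testing.assert_allclose(curve.I, expected, rtol=1e-12)

    def test_forward_scattering_is_total_weight_squared(self, dumbbell):
        q = np.array([0.0, 0.01])
        curve = debye_curve(dumbbell, q)
        assert curve.I[0] == pytest.approx(float(dumbbell.weights.sum() ** 2))

    def test_rigid_motion_invariance(self, q_grid):
        rng = np.random.default_rng(2)
        coords = rng.normal(0, 15, (40, 3))
        cs = CoordinateSet.from_points(coords)
        rot = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(rot) < 0:
            rot[:, 0] *= -1
        moved = cs.with_coords(coords @ rot.T + 100.0)
        np.testing.assert_allclose(
            debye_curve(moved, q_grid).I, debye_curve(cs, q_grid).I, rtol=1e-9
        )

    def test_guinier_selfconsistency_on_bead_cloud(self):
        """Guinier Rg from the simulated curve matches the coordinate Rg."""
        coords = _sphere_beads(20.0, 500, seed=4)
        cs = CoordinateSet.from_points(coords)
        rg_true = radius_of_gyration(cs)
        q = np.linspace(0.002, 1.2 / rg_true, 80)
        res = guinier_fit(debye_curve(cs, q), qrg_limit=1.0)
        assert res.rg == pytest.approx(rg_true, rel=0.01)

    def test_decimation_preserves_forward_scattering(self):
        coords = _sphere_beads(20.0, 800, seed=5)
        cs = CoordinateSet.from_points(coords)
        curve = debye_curve(cs, np.array([0.0]), max_beads=200)
        assert curve.I[0] == pytest.approx(float(cs.weights.sum() ** 2), rel=1e-9)


class TestGuinier:
    def test_exact_gaussian_recovered(self):
        rg, i0 = 23.0, 1000.0
        q = np.linspace(0.001, 0.08, 60)
        curve = ScatteringCurve(q, i0 * np.exp(-(q**2) * rg**2 / 3.0))
        res = guinier_fit(curve)
        assert res.rg == pytest.approx(rg, rel=1e-9)
        assert res.i0 == pytest.approx(i0, rel=1e-9)
        assert not res.nonlinear and not res.positive_slope

    def test_scale_equivariance(self):
        rg = 23.0
        q = np.linspace(0.001, 0.08, 60)
        curve = ScatteringCurve(q, np.exp(-(q**2) * rg**2 / 3.0))
        a, b = guinier_fit(curve), guinier_fit(curve.scaled(2.0))
        assert b.rg == pytest.approx(a.rg, rel=1e-9)
        assert b.i0 == pytest.approx(2 * a.i0, rel=1e-9)

    def test_interference_suppression_flags_nonlinearity(self):
        rg = 23.0
        q = np.linspace(0.001, 0.08, 80)
        ideal = np.exp(-(q**2) * rg**2 / 3.0)
        structure_factor = 1.0 - 0.5 * np.exp(-((q / 0.03) ** 2))
        res = guinier_fit(ScatteringCurve(q, ideal * structure_factor))
        assert res.nonlinear

    def test_positive_slope_flagged_not_raised(self):
        q = np.linspace(0.001, 0.08, 30)
        res = guinier_fit(ScatteringCurve(q, np.exp(+(q**2) * 100.0)))
        assert res.positive_slope
        assert np.isnan(res.rg)


class TestKratky:
    def test_flat_curve_becomes_parabola(self, q_grid):
        curve = ScatteringCurve(q_grid, np.full_like(q_grid, 5.0))
        out = kratky_transform(curve)
        np.testing.assert_allclose(out.I, 5.0 * q_grid**2)

    def test_inverse(self, q_grid, dumbbell):
        curve = debye_curve(dumbbell, q_grid)
        out = kratky_transform(curve)
        np.testing.assert_allclose(out.I / q_grid**2, curve.I, rtol=1e-12)

    def test_globular_particle_peaks_then_decays(self):
        cs = CoordinateSet.from_points(_sphere_beads(15.0, 400, seed=1))
        q = np.linspace(0.005, 0.5, 200)
        out = kratky_transform(debye_curve(cs, q))
        peak = int(np.argmax(out.I))
        assert 0 < peak < len(q) - 1
        assert out.I[-1] < 0.5 * out.I[peak]


def _sphere_pr_closed_form(r, R):
    """Normalized distance distribution of a uniform sphere of radius R."""
    x = r / (2 * R)
    p = r**2 * (1 - 1.5 * x + 0.5 * x**3)
    p[r > 2 * R] = 0.0
    return p


class TestPofR:
    def test_two_point_particle(self):
        """The cross-pair distance appears as a sharp peak at r0.  (The
        point-scatterer self-term of the Debye sum is a constant in q and is
        absorbed at r -> 0, so the origin is excluded from the peak search.)"""
        r0 = 30.0
        cs = CoordinateSet.from_points([[0, 0, 0], [r0, 0, 0]])
        q = np.linspace(0.004, 0.6, 300)
        pr = pr_transform(debye_curve(cs, q), d_max=45.0, n_r=90)
        interior = pr.r > 5.0
        peak_r = pr.r[interior][int(np.argmax(pr.p[interior]))]
        assert peak_r == pytest.approx(r0, abs=1.5)

    def test_uniform_sphere_matches_closed_form(self):
        R = 20.0
        ax = np.arange(-R, R + 1.5, 3.0)
        grid = np.stack(np.meshgrid(ax, ax, ax), -1).reshape(-1, 3)
        cs = CoordinateSet.from_points(grid[(grid**2).sum(1) <= R**2])
        q = np.linspace(0.004, 0.5, 250)
        pr = pr_transform(debye_curve(cs, q), d_max=2 * R * 1.1, n_r=90)
        expected = _sphere_pr_closed_form(pr.r, R)
        expected *= pr.p.sum() / expected.sum()
        rms = np.sqrt(np.mean((pr.p - expected) ** 2)) / expected.max()
        assert rms <= 0.02

    def test_dumbbell_is_bimodal(self, dumbbell):
        q = np.linspace(0.004, 0.5, 250)
        pr = pr_transform(debye_curve(dumbbell, q), d_max=70.0, n_r=80)
        # two local maxima: intra-domain distances and the cross-domain peak
        p = pr.p
        maxima = [
            i for i in range(2, len(p) - 2)
            if p[i] >= p[i - 1] and p[i] >= p[i + 1]
            and p[i] > 0.15 * p.max()
            and (p[i] > p[i - 2] and p[i] > p[i + 2])
        ]
        assert len(maxima) >= 2

    def test_back_transform_reproduces_input(self, dumbbell):
        q = np.linspace(0.004, 0.5, 250)
        curve = debye_curve(dumbbell, q)
        sigma = np.maximum(1e-3 * curve.I.max(), 1e-4 * curve.I.max())
        curve = ScatteringCurve(q, curve.I, np.full_like(q, sigma))
        pr = pr_transform(curve, d_max=70.0, n_r=80)
        assert pr.chi2 <= 1.5

    def test_too_small_dmax_flags_misfit(self, dumbbell):
        q = np.linspace(0.004, 0.5, 250)
        curve = debye_curve(dumbbell, q)
        curve = ScatteringCurve(q, curve.I, 1e-4 * curve.I.max() * np.ones_like(q))
        pr = pr_transform(curve, d_max=30.0, n_r=60)
        assert pr.misfit_flag

    def test_nonnegative(self, dumbbell):
        q = np.linspace(0.004, 0.5, 200)
        pr = pr_transform(debye_curve(dumbbell, q), d_max=70.0)
        assert np.all(pr.p >= 0)


def test_dat_roundtrip(tmp_path, q_grid, dumbbell):
    curve = debye_curve(dumbbell, q_grid)
    curve = ScatteringCurve(q_grid, curve.I, 0.01 * curve.I, 0.72, "test")
    path = tmp_path / "c.dat"
    write_dat(curve, path)
    back = read_dat(path, concentration=0.72)
    np.testing.assert_allclose(back.q, curve.q, rtol=1e-6)
    np.testing.assert_allclose(back.I, curve.I, rtol=1e-6)
    np.testing.assert_allclose(back.sigma, curve.sigma, rtol=1e-6)
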