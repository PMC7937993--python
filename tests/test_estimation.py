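"""The WRMSE objective, grid search, and baseline estimators."""

import math

import numpy as np
import pytest

from optcc import (
    INFEASIBLE,
    OptimalColorModel,
    SceneDistribution,
    build_shell,
    candidate_grid,
    estimate_mean_chromaticity,
    estimate_mean_lms,
    luminance_statistics,
    normalize_scene,
    wrmse,
)
from optcc.io import fixture_generator


def _scene_from_shell(shell, idx, h, darken=None):
    """Surfaces lying exactly on ``shell`` at height ``h`` (optionally darkened)."""
    pts = shell.points[idx]
    y = pts[:, 2] * h
    if darken is not None:
        y = y * darken
    return SceneDistribution(l=pts[:, 0], s=pts[:, 1], Y=y)


def _wrmse_loop_oracle(lsi, loi):
    """Independent elementwise transcription of the weighted-RMSE formula."""
    num = den = 0.0
    for a, b in zip(lsi, loi):
        w = a / b
        num += w * (a - b) ** 2
        den += w
    return math.sqrt(num / den)


class TestNormalize:
    def test_definition_and_scale(self):
        scene = SceneDistribution(l=[0.7, 0.71], s=[1.0, 1.1], Y=[2.07, 4.14])
        norm, scale = normalize_scene(scene)
        assert scale == 4.14
        assert norm.Y.max() == 1.0
        assert np.array_equal(norm.l, scene.l) and np.array_equal(norm.s, scene.s)

    def test_idempotent_on_normalized_scene(self):
        scene = SceneDistribution(l=[0.7], s=[1.0], Y=[1.0])
        norm, scale = normalize_scene(scene)
        assert scale == 1.0 and norm is scene


class TestWrmse:
    def test_exact_fit_scene_scores_zero(self, shell_6500, rng):
        idx = rng.choice(shell_6500.n_points, 20, replace=False)
        idx[0] = shell_6500.white_index  # peak 1.0: normalization is identity
        scene = _scene_from_shell(shell_6500, idx, h=1.0)
        scene, scale = normalize_scene(scene)
        assert scale == 1.0
        assert wrmse(scene, shell_6500, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_loop(self, shell_6500, rng):
        idx = rng.choice(shell_6500.n_points, 3, replace=False)
        pts = shell_6500.points[idx]
        factors = np.array([0.9, 0.6, 0.3])
        scene, _ = normalize_scene(
            SceneDistribution(l=pts[:, 0], s=pts[:, 1], Y=pts[:, 2] * factors)
        )
        y0 = shell_6500.boundary_luminances(scene.chromaticities)
        h_test = 1.3 * float(np.max(scene.Y / y0))  # safely feasible
        got = wrmse(scene, shell_6500, h_test)
        assert got == pytest.approx(_wrmse_loop_oracle(scene.Y, h_test * y0), rel=1e-12)

    def test_surface_above_shell_is_infeasible(self, shell_6500):
        wp = shell_6500.white_point
        scene = SceneDistribution(l=[wp.l], s=[wp.s], Y=[1.0])
        # boundary at the white point is 1.0; height 0.83 puts the surface 20% above
        assert wrmse(scene, shell_6500, 1.0 / 1.2) == INFEASIBLE

    def test_chromaticity_outside_footprint_is_infeasible(self, shell_6500):
        scene = SceneDistribution(l=[0.05], s=[0.5], Y=[0.5])
        assert wrmse(scene, shell_6500, 2.0) == INFEASIBLE

    def test_feasibility_monotone_in_height(self, shell_6500, rng):
        idx = rng.choice(shell_6500.n_points, 10, replace=False)
        scene, _ = normalize_scene(_scene_from_shell(shell_6500, idx, 1.0))
        feasible = [not math.isinf(wrmse(scene, shell_6500, h))
                    for h in np.linspace(0.5, 3.0, 26)]
        # once feasible, always feasible for larger h
        first = feasible.index(True)
        assert all(feasible[first:])

    def test_bright_surfaces_weigh_more(self, shell_6500, rng):
        # same absolute luminance perturbation moves WRMSE more when applied
        # to a surface that is bright relative to its physical ceiling
        # (high Lsi/Loi, hence high weight) than to a dim one
        idx = rng.choice(shell_6500.n_points, 8, replace=False)
        pts = shell_6500.points[idx]
        y0 = shell_6500.boundary_luminances(pts[:, :2])
        h = 1.2
        ratios = np.full(8, 0.6)
        # two surfaces with nearly matched ceilings but opposite brightness
        near = np.argsort(y0)[3:5]
        bright, dim = int(near[0]), int(near[1])
        ratios[bright], ratios[dim] = 0.9, 0.3
        base = ratios * h * y0
        delta = 0.05 * base[dim]

        def score(y):
            return wrmse(SceneDistribution(l=pts[:, 0], s=pts[:, 1], Y=y),
                         shell_6500, h)

        ref = score(base)
        y_bright = base.copy(); y_bright[bright] -= delta
        y_dim = base.copy(); y_dim[dim] -= delta
        assert abs(score(y_bright) - ref) > abs(score(y_dim) - ref)


class TestGridSearchOracle:
    def test_agrees_with_exhaustive_double_loop(self, rng):
        # toy 3x3 grid, 6-surface scene: brute-force every candidate with the
        # plain formula and compare the argmin and value exactly
        grid = fixture_generator("toy_grid")
        shells = {float(T): build_shell(float(T)) for T in grid.temperatures}
        sh = shells[6500.0]
        idx = rng.choice(sh.n_points, 6, replace=False)
        scene = _scene_from_shell(sh, idx, h=1.4, darken=rng.uniform(0.3, 1.0, 6))
        norm, scale = normalize_scene(scene)

        best = (math.inf, None, None)
        for T in grid.temperatures:
            y0 = shells[float(T)].boundary_luminances(norm.chromaticities)
            for h in grid.heights:
                loi = h * y0
                if np.any(norm.Y > loi * (1 + 1e-6)):
                    continue
                val = _wrmse_loop_oracle(norm.Y, loi)
                if val < best[0]:
                    best = (val, float(h), float(T))

        fit = OptimalColorModel(scene, grid, shells=shells).fit()
        assert fit.T_hat == best[2]
        assert fit.h_hat_relative == best[1]
        assert fit.wrmse == pytest.approx(best[0], rel=1e-12)
        assert fit.intensity_hat == pytest.approx(best[1] * scale, rel=1e-12)

    def test_exact_recovery_of_generating_candidate(self, default_grid, rng):
        # pure optimal-color scene rendered under a grid candidate comes back
        # with zero error and the exact (T, h)
        T, h = 5500.0, 1.73
        sh = build_shell(T)
        idx = rng.choice(sh.n_points, 40, replace=False)
        idx[0] = sh.white_index  # include full white so the peak pins h
        scene = _scene_from_shell(sh, idx, h=h)
        fit = OptimalColorModel(scene, default_grid).fit()
        assert fit.T_hat == T
        assert fit.h_hat_relative == 1.0  # peak = full white
        assert fit.intensity_hat == pytest.approx(h, rel=1e-12)
        assert fit.wrmse < 1e-9

    def test_no_feasible_candidate_raises(self):
        scene = SceneDistribution(l=[0.05], s=[0.5], Y=[1.0])
        grid = fixture_generator("toy_grid")
        with pytest.raises(ValueError, match="height range|feasible"):
            OptimalColorModel(scene, grid).fit()

    def test_darkening_subset_preserves_estimate(self, default_grid, rng):
        T = 8000.0
        sh = build_shell(T)
        idx = rng.choice(sh.n_points, 30, replace=False)
        scene = _scene_from_shell(sh, idx, h=1.5)
        fit_full = OptimalColorModel(scene, default_grid).fit()
        dark = np.ones(30)
        dark[10:] = 0.4  # darken a strict subset; brightest surfaces still pin
        keep_peak = np.argmax(scene.Y)
        dark[keep_peak] = 1.0
        scene_dark = SceneDistribution(l=scene.l, s=scene.s, Y=scene.Y * dark)
        fit_dark = OptimalColorModel(scene_dark, default_grid).fit()
        assert fit_dark.T_hat == fit_full.T_hat

    def test_surface_table_has_grid_shape(self, rng):
        grid = fixture_generator("toy_grid")
        sh = build_shell(6500.0)
        idx = rng.choice(sh.n_points, 5, replace=False)
        scene = _scene_from_shell(sh, idx, h=1.5)
        fit = OptimalColorModel(scene, grid).fit(store_surface=True)
        assert fit.surface.shape == (3, 3)
        assert np.isfinite(fit.surface.to_numpy()).any()
        assert "Optimal-color" in fit.summary()


class TestBaselines:
    def test_mean_chromaticity_arithmetic(self):
        scene = SceneDistribution(l=[0.68, 0.72], s=[0.9, 1.1], Y=[5.0, 1.0])
        c = estimate_mean_chromaticity(scene)
        assert c.l == pytest.approx(0.70)
        assert c.s == pytest.approx(1.0)

    def test_mean_chromaticity_ignores_luminance(self, rng):
        l = rng.uniform(0.6, 0.8, 10)
        s = rng.uniform(0.5, 2.0, 10)
        a = estimate_mean_chromaticity(SceneDistribution(l=l, s=s, Y=np.ones(10)))
        b = estimate_mean_chromaticity(
            SceneDistribution(l=l, s=s, Y=rng.uniform(0.1, 5.0, 10))
        )
        assert b.l == pytest.approx(a.l) and b.s == pytest.approx(a.s)

    def test_mean_lms_is_luminance_weighted(self):
        scene = SceneDistribution(l=[0.68, 0.72], s=[1.0, 1.0], Y=[1.0, 3.0])
        c = estimate_mean_lms(scene)
        assert c.l == pytest.approx(0.71)

    def test_mean_lms_single_surface(self):
        scene = SceneDistribution(l=[0.7], s=[1.3], Y=[2.0])
        c = estimate_mean_lms(scene)
        assert (c.l, c.s) == (0.7, 1.3)

    def test_luminance_statistics(self):
        scene = SceneDistribution(l=[0.7] * 3, s=[1.0] * 3, Y=[1.0, 2.0, 3.0])
        stats = luminance_statistics(scene)
        assert stats == {"mean_Y": 2.0, "max_Y": 3.0}
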