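"""Stimulus-scene construction for the three experiment families."""

import numpy as np
import pytest

from optcc import (
    OptimalColorModel,
    build_exp1_scene,
    build_exp2_scene,
    build_exp3_scene,
    estimate_mean_lms,
    sample_natural_reflectances,
    triangle_chromaticities,
)
from optcc.spectral import render_reflectance_matrix
from optcc.fundamentals import EEW_L, EEW_S, equal_energy_white
from optcc.stimuli import EXCLUSION_L_RANGE, EXCLUSION_S_RANGE

EXP1_CONDITIONS = ("mountain", "reverse", "flat")
EXP2_CONDITIONS = ("red_reduced", "green_reduced", "blue_reduced")


class TestTriangleSet:
    def test_counts_are_12_12_6(self):
        cs = triangle_chromaticities()
        assert len(cs.chromaticities) == 30
        assert np.bincount(cs.levels).tolist() == [12, 12, 6]

    def test_inner_rings_are_similar_triangles(self):
        cs = triangle_chromaticities()
        w = np.asarray(cs.white)
        outer = cs.chromaticities[cs.levels == 0]
        for level, frac in ((1, 2 / 3), (2, 1 / 3)):
            rows = np.nonzero(cs.levels == level)[0]
            for r in rows:
                counterpart = outer[cs.outer_index[r]]
                expected = w + frac * (counterpart - w)
                assert np.allclose(cs.chromaticities[r], expected, atol=1e-12)

    def test_corner_adjacent_colors_carry_two_groups(self):
        cs = triangle_chromaticities()
        # vertices: one group; side points: exactly two adjacent groups
        for i, g in enumerate(cs.groups):
            assert len(g) == (1 if cs.outer_index[i] < 3 else 2)
        red = cs.group_mask("red")
        blue = cs.group_mask("blue")
        assert np.any(red & blue)  # magenta side members sit in both

    def test_degenerate_triangle_rejected(self):
        flat = {"red": (0.7, 1.0), "green": (0.72, 1.0), "blue": (0.74, 1.0)}
        with pytest.raises(ValueError, match="collinear|inside"):
            triangle_chromaticities(flat)


@pytest.mark.parametrize("condition", EXP1_CONDITIONS)
def test_exp1_mean_luminance_and_dark_pairing(condition):
    stim = build_exp1_scene(condition, 6500.0, target_mean_Y=1.2)
    scene = stim.scene
    assert scene.n_surfaces == 60
    assert scene.Y.mean() == pytest.approx(1.2, rel=1e-12)
    # dark copy i pairs bright surface i: same chromaticity, 20% luminance
    assert np.array_equal(scene.l[:30], scene.l[30:])
    assert np.array_equal(scene.s[:30], scene.s[30:])
    assert np.allclose(scene.Y[30:] / scene.Y[:30], 0.2, atol=1e-9)
    for r in stim.reflectances:
        assert np.all(r.values >= 0) and np.all(r.values <= 1)


def test_exp1_conditions_share_chromaticities_differ_in_luminance():
    scenes = {c: build_exp1_scene(c, 6500.0).scene for c in EXP1_CONDITIONS}
    base = scenes["mountain"]
    for c in ("reverse", "flat"):
        assert np.array_equal(scenes[c].l, base.l)
        assert np.array_equal(scenes[c].s, base.s)
        assert not np.allclose(scenes[c].Y, base.Y)


def test_mountain_peaks_inner_reverse_peaks_outer():
    cs = triangle_chromaticities()
    mountain = build_exp1_scene("mountain", 6500.0, cs)
    reverse = build_exp1_scene("reverse", 6500.0, cs)
    assert cs.levels[int(np.argmax(mountain.scene.Y[:30]))] == 2  # inner ring
    assert cs.levels[int(np.argmax(reverse.scene.Y[:30]))] == 0   # outer ring


def test_flat_luminances_between_mountain_and_reverse():
    m = build_exp1_scene("mountain", 6500.0).extras["reflectance_factors"]
    f = build_exp1_scene("flat", 6500.0).extras["reflectance_factors"]
    r = build_exp1_scene("reverse", 6500.0).extras["reflectance_factors"]
    assert np.all(f <= m + 1e-12)
    # outer ring stays optimal in every condition
    cs = triangle_chromaticities()
    outer = cs.levels == 0
    assert np.allclose(m[outer], 1) and np.allclose(f[outer], 1) and np.allclose(r[outer], 1)


@pytest.mark.parametrize("condition", EXP2_CONDITIONS)
def test_exp2_scene_construction(condition):
    stim = build_exp2_scene(condition, 6500.0)
    assert stim.scene.Y.mean() == pytest.approx(1.2, rel=1e-12)
    factors = stim.extras["reflectance_factors"]
    assert set(np.round(factors, 12)) <= {np.round(1 / 3, 12), 1.0}


def test_exp2_conditions_share_chromaticities():
    scenes = [build_exp2_scene(c, 3000.0).scene for c in EXP2_CONDITIONS]
    for other in scenes[1:]:
        assert np.array_equal(other.l, scenes[0].l)
        assert np.array_equal(other.s, scenes[0].s)


def test_exp2_mean_lms_shifts_against_the_reduced_group():
    red = estimate_mean_lms(build_exp2_scene("red_reduced", 6500.0).scene)
    green = estimate_mean_lms(build_exp2_scene("green_reduced", 6500.0).scene)
    blue = estimate_mean_lms(build_exp2_scene("blue_reduced", 6500.0).scene)
    assert red.l < green.l            # darkening red pushes the mean away from red
    assert blue.s < red.s             # darkening blue lowers the s average


@pytest.mark.parametrize("builder,conditions,T", [
    (build_exp1_scene, EXP1_CONDITIONS, 3000.0),
    (build_exp1_scene, EXP1_CONDITIONS, 20000.0),
    (build_exp2_scene, EXP2_CONDITIONS, 6500.0),
    (build_exp2_scene, EXP2_CONDITIONS, 20000.0),
])
def test_estimator_recovers_generating_illuminant_exactly(builder, conditions, T,
                                                          default_grid):
    for condition in conditions:
        stim = builder(condition, T)
        h_true = stim.illuminant.h / stim.scene.Y.max()
        fit = OptimalColorModel(stim.scene, default_grid.with_height(h_true)).fit()
        assert fit.T_hat == T, condition
        assert fit.h_hat_relative == h_true, condition
        assert fit.intensity_hat == pytest.approx(stim.illuminant.h, rel=1e-9)


class TestNaturalSampler:
    def test_range_and_determinism(self):
        a = sample_natural_reflectances(20, seed=5)
        b = sample_natural_reflectances(20, seed=5)
        c = sample_natural_reflectances(20, seed=6)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)
        assert np.all(a > 0) and np.all(a < 1)

    def test_samples_lie_strictly_inside_eew_shell(self, eew_shell, fundamentals):
        refl = sample_natural_reflectances(40, seed=3)
        l, s, y = render_reflectance_matrix(refl, equal_energy_white(), fundamentals)
        bound = eew_shell.boundary_luminances(np.column_stack([l, s]))
        assert np.all(y < bound)

    def test_mountain_like_cloud(self, fundamentals):
        # luminance should fall off with distance from the neutral point
        refl = sample_natural_reflectances(400, seed=9)
        l, s, y = render_reflectance_matrix(refl, equal_energy_white(), fundamentals)
        d = np.hypot(l - EEW_L, (s - EEW_S) / 3.0)
        near = y[d < np.median(d)]
        far = y[d >= np.median(d)]
        assert near.max() > far.max()


class TestExp3:
    def test_natural_scene_normalization_and_balance(self, fundamentals):
        stim = build_exp3_scene("natural", 6500.0, seed=1)
        scene = stim.scene
        assert scene.n_surfaces == 60
        assert scene.Y.mean() == pytest.approx(6.0, rel=1e-12)
        # balanced mean chromaticity under equal-energy white
        values = np.array([r.values for r in stim.reflectances])
        l, s, _ = render_reflectance_matrix(values, equal_energy_white(), fundamentals)
        assert np.hypot(l.mean() - EEW_L, s.mean() - EEW_S) <= 0.002 + 1e-9

    def test_near_neutral_reflectances_are_excluded(self, fundamentals):
        stim = build_exp3_scene("natural", 6500.0, seed=1)
        values = np.array([r.values for r in stim.reflectances])
        l, s, _ = render_reflectance_matrix(values, equal_energy_white(), fundamentals)
        inside = ((l >= EXCLUSION_L_RANGE[0]) & (l <= EXCLUSION_L_RANGE[1])
                  & (s >= EXCLUSION_S_RANGE[0]) & (s <= EXCLUSION_S_RANGE[1]))
        assert not np.any(inside)
        assert stim.extras["n_excluded"] > 0

    def test_skewed_reflectances_capped_at_unity(self):
        for condition in ("red_increased", "blue_increased"):
            stim = build_exp3_scene(condition, 6500.0, seed=1)
            values = np.array([r.values for r in stim.reflectances])
            assert np.all(values <= 1.0 + 1e-12)
            assert stim.scene.Y.mean() == pytest.approx(6.0, rel=1e-12)

    def test_conditions_share_the_same_reflectance_draw(self):
        nat = build_exp3_scene("natural", 6500.0, seed=2)
        red = build_exp3_scene("red_increased", 6500.0, seed=2)
        assert np.array_equal(nat.extras["selected_indices"],
                              red.extras["selected_indices"])

    def test_skew_biases_temperature_directionally_and_monotonically(self, default_grid):
        T = 6500.0
        nat = build_exp3_scene("natural", T, seed=1)
        t_nat = OptimalColorModel(nat.scene, default_grid).fit().T_hat
        red_hats, blue_hats = [], []
        for floor in (0.7, 0.5, 0.3):
            red = build_exp3_scene("red_increased", T, seed=1, skew_floor=floor)
            blue = build_exp3_scene("blue_increased", T, seed=1, skew_floor=floor)
            red_hats.append(OptimalColorModel(red.scene, default_grid).fit().T_hat)
            blue_hats.append(OptimalColorModel(blue.scene, default_grid).fit().T_hat)
        # strict bias at the default skew strength
        assert red_hats[1] < t_nat < blue_hats[1]
        # stronger skew never weakens the bias
        assert all(np.diff(red_hats) <= 0)
        assert all(np.diff(blue_hats) >= 0)
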