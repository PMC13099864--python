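"""Scene geometry: glint-delay conversions, presets, random scenes, files."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from batnav.scene import (BatState, Target, build_scene, heading_degrees,
                          heading_vector, load_scene, preset_scene,
                          projected_glint_delay, random_scene, save_scene,
                          spacing_to_meters, PRESET_NAMES)


def fixed_target(spacing_m, axis, pos=(0.0, 1.5)):
    return Target("T1", np.array(pos), spacing_m, np.asarray(axis, float))


class TestSpacingConversion:
    @pytest.mark.parametrize("dt, c, expected_m", [
        (100e-6, 340.0, 0.017),     # 100 us <-> 17 mm
        (1.0, 2.0, 1.0),            # identity of the formula
        (30e-6, 340.0, 0.0051),     # 30 us <-> 5.1 mm
        (1000e-6, 340.0, 0.17),     # 1000 us <-> 17 cm
    ])
    def test_end_on_delay_to_meters(self, dt, c, expected_m):
        assert spacing_to_meters(dt, c) == pytest.approx(expected_m)

    def test_build_scene_converts_via_sound_speed(self):
        sc = build_scene([((0.0, 1.5), 100e-6)])
        assert sc.targets[0].glint_spacing == pytest.approx(0.017)
        assert sc.targets[0].end_on_delay(sc.sound_speed) == pytest.approx(100e-6)

    def test_build_scene_rejects_bad_specs(self):
        with pytest.raises(ValueError):
            build_scene([((0.0, 1.0), -5e-6)])
        with pytest.raises(ValueError):
            build_scene([((0.0, 1.0), 1e-4), ((0.0, 1.0), 2e-4)])


class TestProjectedGlintDelay:
    def test_end_on_view_gives_full_delay(self):
        # 17 mm pair seen along its axis from afar: the classic 100 us
        t = fixed_target(0.017, (0.0, 1.0), pos=(0.0, 50.0))
        dt = projected_glint_delay(t, np.zeros(2), c=340.0)
        assert dt == pytest.approx(100e-6, rel=1e-4)

    def test_broadside_view_gives_zero(self):
        t = fixed_target(0.017, (1.0, 0.0), pos=(0.0, 50.0))
        assert projected_glint_delay(t, np.zeros(2), c=340.0) == pytest.approx(0.0, abs=1e-12)

    def test_oblique_view_matches_farfield_cosine(self):
        # 60 deg aspect: |cos| = 0.5 -> ~50 us for a 17 mm pair at 100 m
        axis = np.array([math.sin(math.radians(60)), math.cos(math.radians(60))])
        t = fixed_target(0.017, axis, pos=(0.0, 100.0))
        dt = projected_glint_delay(t, np.zeros(2), c=340.0)
        assert dt == pytest.approx(50e-6, rel=0.01)

    @settings(deadline=None, max_examples=50)
    @given(angle=st.floats(0, 2 * math.pi), spacing=st.floats(1e-3, 0.3),
           ox=st.floats(-5, 5), oy=st.floats(-5, -0.5))
    def test_axis_flip_invariance(self, angle, spacing, ox, oy):
        axis = np.array([math.cos(angle), math.sin(angle)])
        obs = np.array([ox, oy])
        a = projected_glint_delay(fixed_target(spacing, axis), obs)
        b = projected_glint_delay(fixed_target(spacing, -axis), obs)
        assert a == pytest.approx(b, abs=1e-15)

    @settings(deadline=None, max_examples=50)
    @given(angle=st.floats(0, 2 * math.pi), spacing=st.floats(1e-3, 0.02))
    def test_farfield_cosine_limit(self, angle, spacing):
        # range > 100x spacing: exact formula within 0.1 % of the cosine law
        axis = np.array([math.cos(angle), math.sin(angle)])
        t = fixed_target(spacing, axis, pos=(0.0, 0.0))
        obs = np.array([0.0, -150.0 * spacing])
        los = (obs - t.position) / np.linalg.norm(obs - t.position)
        expected = (2 * spacing / 340.0) * abs(float(np.dot(axis, los)))
        got = projected_glint_delay(t, obs, c=340.0)
        assert got == pytest.approx(expected, abs=2e-6 * spacing / 0.017 + 1e-12)

    def test_facing_mode_presents_end_on_delay_everywhere(self):
        sc = build_scene([((1.0, 2.0), 100e-6)])
        for obs in ([0, 0], [3, 1], [-2, 4]):
            dt = projected_glint_delay(sc.targets[0], np.array(obs, float))
            assert dt == pytest.approx(100e-6, rel=1e-3)


class TestPresets:
    @pytest.mark.parametrize("name, n", [
        ("single", 1), ("five", 5), ("eight", 8), ("twenty", 20), ("grid90", 90),
    ])
    def test_counts_and_unique_desired(self, name, n):
        sc = preset_scene(name)
        assert len(sc.targets) == n
        assert len(sc.desired_targets()) == 1
        sc.validate()

    def test_single_layout(self):
        sc = preset_scene("single")
        t = sc.targets[0]
        np.testing.assert_allclose(t.position, [0.0, 1.5])
        assert t.end_on_delay(sc.sound_speed) == pytest.approx(100e-6)
        np.testing.assert_allclose(sc.bat_init.position, [0.0, 0.0])

    def test_distractor_spacing_sets(self):
        five = {round(t.end_on_delay(340.0) * 1e6) for t in preset_scene("five").targets}
        assert five <= {50, 100, 300, 500, 1000} and 100 in five
        eight = sorted(round(t.end_on_delay(340.0) * 1e6)
                       for t in preset_scene("eight").targets)
        assert eight == [100, 300] + [1000] * 6

    def test_unknown_name_lists_presets(self):
        with pytest.raises(ValueError, match="single"):
            preset_scene("nonsense")


class TestRandomScene:
    def test_single_target_pool(self):
        sc = random_scene(1, spacing_pool=[100e-6], seed=0)
        assert len(sc.desired_targets()) == 1

    def test_deterministic_given_seed(self):
        a = random_scene(12, seed=42)
        b = random_scene(12, seed=42)
        for ta, tb in zip(a.targets, b.targets):
            np.testing.assert_array_equal(ta.position, tb.position)
            assert ta.glint_spacing == tb.glint_spacing

    @pytest.mark.parametrize("seed", range(1, 101))
    def test_exactly_one_desired_target(self, seed):
        sc = random_scene(20, seed=seed)
        assert len(sc.desired_targets()) == 1

    def test_minimum_separation_enforced(self):
        sc = random_scene(15, seed=3)
        pos = np.array([t.position for t in sc.targets])
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 0.30

    def test_infeasible_packing_raises(self):
        with pytest.raises(RuntimeError):
            random_scene(500, seed=0, arena=((-0.5, 0.5), (0.5, 1.5)))


class TestSceneFiles:
    def test_round_trip(self, tmp_path):
        sc = random_scene(6, seed=9)
        path = tmp_path / "scene.yaml"
        save_scene(sc, path)
        back = load_scene(path)
        assert len(back.targets) == len(sc.targets)
        for a, b in zip(sc.targets, back.targets):
            assert a.id == b.id
            np.testing.assert_allclose(a.position, b.position)
            assert a.glint_spacing == pytest.approx(b.glint_spacing)
            assert a.axis_mode == b.axis_mode
        assert back.sound_speed == sc.sound_speed
        assert back.ear_separation == sc.ear_separation
        np.testing.assert_allclose(back.bat_init.position, sc.bat_init.position)

    def test_fixed_axis_round_trip(self, tmp_path):
        sc = build_scene([((0.5, 2.0), 200e-6, (1.0, 1.0))])
        path = tmp_path / "scene.yaml"
        save_scene(sc, path)
        back = load_scene(path)
        assert back.targets[0].axis_mode == "fixed"
        np.testing.assert_allclose(back.targets[0].glint_axis,
                                   sc.targets[0].glint_axis, atol=1e-12)


def test_heading_vector_round_trip():
    for deg in (-170.0, -45.0, 0.0, 30.0, 90.0, 179.0):
        assert heading_degrees(heading_vector(deg)) == pytest.approx(deg)
    np.testing.assert_allclose(heading_vector(0.0), [0.0, 1.0], atol=1e-15)
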