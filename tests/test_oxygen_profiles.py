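import numpy as np
import pandas as pd
import pytest

from biofilmscape.exceptions import ValidationError
from biofilmscape.oxygen_profiles import (OxygenProfile, OxygenProfileSet,
                                          brown_forsythe_test, estimate_surface,
                                          grouped_depth_compare,
                                          light_dark_ratio, local_gradient,
                                          parse_profiles, welch_test)
from biofilmscape.synthetic_data import OxygenParams, closed_form_oxygen, gen_oxygen
from _oracles import brown_forsythe_formula, welch_formula


def profile(depths, conc, cond="dark", morph="SFM", pid="P1", wall=None):
    return OxygenProfile(depths=np.asarray(depths, float),
                         concentrations=np.asarray(conc, float),
                         condition=cond, morphotype=morph, profile_id=pid,
                         wall_distance_mm=wall)


class TestParsing:
    def test_unordered_depths_rejected(self):
        with pytest.raises(ValidationError):
            profile([0.0, 0.2, 0.1], [300, 290, 280])

    def test_missing_condition_rejected(self):
        with pytest.raises(ValidationError):
            profile([0, 0.1], [300, 290], cond="dusk")

    def test_surface_rezeroing_shifts_depths(self):
        df = profile(np.arange(0, 0.5, 0.1), np.linspace(300, 100, 5)).rezeroed(0.2)
        assert df.depths[0] == pytest.approx(-0.2)

    def test_csv_roundtrip_identical(self, tmp_path):
        z = np.arange(-0.1, 0.5, 0.05)
        pset = OxygenProfileSet([
            profile(z, np.linspace(300, 50, len(z)), pid="A"),
            profile(z, np.linspace(300, 400, len(z)), cond="light", pid="A"),
            profile(z, np.linspace(300, 120, len(z)), morph="FFM", pid="B",
                    wall=0.2),
        ])
        path = tmp_path / "o2.csv"
        pset.write_csv(path)
        back = parse_profiles(path)
        assert len(back) == len(pset)
        a = pset.to_frame().sort_values(["profile_id", "condition", "depth_mm"])
        b = back.to_frame().sort_values(["profile_id", "condition", "depth_mm"])
        pd.testing.assert_frame_equal(a.reset_index(drop=True),
                                      b.reset_index(drop=True))

    def test_estimate_surface_finds_steepest_gradient(self):
        z = np.arange(-0.2, 0.5, 0.01)
        c = closed_form_oxygen(z - 0.1, 300, 2080, 0.4)  # surface at z=0.1
        p = profile(z, c)
        assert estimate_surface(p) == pytest.approx(0.1, abs=0.05)


class TestGradients:
    def test_linear_profile_slope(self):
        z = np.arange(0, 0.3, 0.01)
        p = profile(z, 300 - 100 * z)
        assert local_gradient(p) == pytest.approx(-100.0)

    def test_constant_profile_zero_slope(self):
        z = np.arange(0, 0.3, 0.01)
        assert local_gradient(profile(z, np.full_like(z, 250))) == pytest.approx(0.0, abs=1e-9)

    def test_quadratic_profile_mean_derivative(self):
        # C(z) = C0 - (R/D)(Lz - z^2/2); OLS slope over the symmetric window
        # [0.05, 0.15] equals the derivative at 0.1: -(R/D)(L - 0.1) = -400
        z = np.arange(0.0, 0.5001, 0.01)
        c = 300 - 1000 * (0.5 * z - z ** 2 / 2)
        assert local_gradient(profile(z, c)) == pytest.approx(-400.0, abs=1e-6)

    def test_too_few_points_in_window(self):
        with pytest.raises(ValidationError):
            local_gradient(profile([0.0, 0.3], [300, 200]))

    def test_two_point_mode(self):
        z = np.array([0.05, 0.10, 0.15])
        p = profile(z, 300 - 100 * z)
        assert local_gradient(p, method="two-point") == pytest.approx(-100.0)


class TestLightDarkRatio:
    def _pair(self, p_rate, r_rate):
        z = np.arange(-0.1, 0.5, 0.01)
        dark = closed_form_oxygen(z, 300, r_rate, 0.5, mode="dark")
        light = closed_form_oxygen(z, 300, p_rate, 0.5, mode="light")
        return (profile(z, light, cond="light"), profile(z, dark))

    def test_balanced_rates_give_one(self):
        l, d = self._pair(1000, 1000)
        assert light_dark_ratio(l, d) == pytest.approx(1.0)

    def test_production_twice_consumption(self):
        l, d = self._pair(2000, 1000)
        assert light_dark_ratio(l, d) == pytest.approx(2.0)

    def test_zero_dark_gradient_undefined(self):
        z = np.arange(-0.1, 0.5, 0.01)
        d = profile(z, np.full_like(z, 300.0))
        l, _ = self._pair(1000, 1000)
        assert np.isnan(light_dark_ratio(l, d))

    def test_scale_invariance(self):
        l, d = self._pair(1500, 1000)
        r1 = light_dark_ratio(l, d)
        l2 = profile(l.depths, 3.7 * l.concentrations, cond="light")
        d2 = profile(d.depths, 3.7 * d.concentrations)
        assert light_dark_ratio(l2, d2) == pytest.approx(r1)

    def test_mismatched_locations_rejected(self):
        l, d = self._pair(1000, 1000)
        d2 = profile(d.depths, d.concentrations, pid="other")
        with pytest.raises(ValidationError):
            light_dark_ratio(l, d2)


class TestBrownForsythe:
    def test_identical_groups_degenerate(self):
        w, p = brown_forsythe_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (w, p) == (0.0, 1.0) or p == pytest.approx(1.0)

    def test_matches_hand_formula(self):
        groups = ([1, 2, 3, 4, 5], [3, 3, 3, 3, 3.0])
        w, _ = brown_forsythe_test(*groups)
        assert w == pytest.approx(brown_forsythe_formula(groups), abs=1e-10)

    def test_matches_formula_on_random_groups(self, rng):
        for _ in range(10):
            groups = [rng.normal(0, s, rng.integers(5, 20)) for s in (1.0, 2.5)]
            w, _ = brown_forsythe_test(*groups)
            assert w == pytest.approx(brown_forsythe_formula(groups), abs=1e-10)

    def test_detects_threefold_scale_difference(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(0, 3, 50)
        _, p = brown_forsythe_test(a, b)
        assert p < 0.01


class TestWelch:
    def test_hand_evaluated_example(self):
        t, df, _ = welch_test([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-np.sqrt(1.5), abs=1e-9)
        assert df == pytest.approx(4.0, abs=1e-9)

    def test_matches_formula_on_random_samples(self, rng):
        for _ in range(10):
            a = rng.normal(0, 1, rng.integers(5, 30))
            b = rng.normal(0.5, 2, rng.integers(5, 30))
            t, df, _ = welch_test(a, b)
            t0, df0 = welch_formula(a, b)
            assert t == pytest.approx(t0, abs=1e-10)
            assert df == pytest.approx(df0, abs=1e-10)

    def test_identical_samples_null(self):
        t, _, p = welch_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_large_shift_highly_significant(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(5, 1, 30)
        _, _, p = welch_test(a, b)
        assert p < 0.001


class TestGroupedDepthCompare:
    def test_planted_wall_replenishment_flagged(self):
        pset, _ = gen_oxygen(OxygenParams(), seed=7)
        wall = pset.select(condition="dark", wall_max_mm=0.2)
        core = pset.select(condition="dark", wall_min_mm=0.8)
        table = grouped_depth_compare(wall, core, bin_mm=0.1)
        target = table[(table["bin_lo_mm"] >= 0.1 - 1e-9)
                       & (table["bin_hi_mm"] <= 0.5 + 1e-9)
                       & (table["note"] == "ok")]
        assert len(target) >= 3
        assert (target["q"] < 0.01).all()
        # walls are less oxygen-depleted than cores at depth
        assert (target["mean_a"] > target["mean_b"]).all()

    def test_identical_sets_not_significant(self):
        z = np.arange(0, 0.5, 0.05)
        a = OxygenProfileSet([profile(z, 300 - 100 * z, pid=f"A{i}")
                              for i in range(3)])
        table = grouped_depth_compare(a, a, bin_mm=0.1)
        ok = table[table["note"] == "ok"]
        assert np.allclose(ok["p"], 1.0)

    def test_sparse_bin_skipped_with_note(self):
        a = OxygenProfileSet([profile([0.05, 0.15, 0.45], [200, 150, 90.0])])
        b = OxygenProfileSet([profile([0.05, 0.15], [210, 160.0], pid="P2")])
        table = grouped_depth_compare(a, b, bin_mm=0.1)
        assert (table.loc[table["bin_lo_mm"] == pytest.approx(0.4), "note"]
                == "skipped: n<2").all()

    def test_profile_level_pooling_mode(self):
        z = np.arange(0, 0.3, 0.02)
        a = OxygenProfileSet([profile(z, 300 - 100 * z + i, pid=f"A{i}")
                              for i in range(4)])
        b = OxygenProfileSet([profile(z, 250 - 100 * z + i, pid=f"B{i}")
                              for i in range(4)])
        t_points = grouped_depth_compare(a, b, bin_mm=0.1)
        t_prof = grouped_depth_compare(a, b, bin_mm=0.1, pooling="profiles")
        assert (t_prof.loc[t_prof["note"] == "ok", "n_a"] == 4).all()
        assert t_points.loc[0, "n_a"] > 4


class TestMorphotypeVariance:
    def test_sfm_dark_concentrations_more_variable(self):
        pset, _ = gen_oxygen(OxygenParams(), seed=1)
        def vals(m):
            sub = pset.select(condition="dark", morphotype=m)
            sub = OxygenProfileSet([p for p in sub if p.wall_distance_mm is None])
            return np.concatenate([p.concentrations[p.depths >= 0] for p in sub])
        v_sfm, v_ffm = vals("SFM"), vals("FFM")
        assert v_sfm.var() > v_ffm.var()
        _, p = brown_forsythe_test(v_sfm, v_ffm)
        assert p < 0.01
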