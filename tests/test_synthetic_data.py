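import numpy as np
import pytest

from biofilmscape.exceptions import ValidationError
from biofilmscape.landscape_metrics import biovolume
from biofilmscape.segmentation import segment_landscape, extract_clusters
from biofilmscape.temporal_dynamics import series_differences
from biofilmscape.synthetic_data import (LandscapeParams, OxygenParams,
                                         closed_form_oxygen, ffm_weight,
                                         gen_hydraulic_profile, gen_landscape,
                                         gen_oxygen, gen_timeseries)

SMALL = dict(extent_m=(0.015, 0.06), min_separation_mm=3.0)


class TestDeterminism:
    def test_same_seed_bitwise_identical_landscape(self):
        g1, _ = gen_landscape(LandscapeParams(**SMALL), seed=42)
        g2, _ = gen_landscape(LandscapeParams(**SMALL), seed=42)
        np.testing.assert_array_equal(g1.heights, g2.heights)

    def test_different_seeds_differ(self):
        g1, _ = gen_landscape(LandscapeParams(**SMALL), seed=1)
        g2, _ = gen_landscape(LandscapeParams(**SMALL), seed=2)
        assert (g1.heights != g2.heights).any()

    def test_same_seed_identical_timeseries_and_events(self):
        s1, t1 = gen_timeseries(LandscapeParams(**SMALL), seed=9, days=(0, 3, 6))
        s2, t2 = gen_timeseries(LandscapeParams(**SMALL), seed=9, days=(0, 3, 6))
        for g1, g2 in zip(s1, s2):
            np.testing.assert_array_equal(g1.heights, g2.heights)
        assert t1.events == t2.events

    def test_same_seed_identical_oxygen(self):
        p1, _ = gen_oxygen(OxygenParams(), seed=4)
        p2, _ = gen_oxygen(OxygenParams(), seed=4)
        import pandas.testing as pdt
        pdt.assert_frame_equal(p1.to_frame(), p2.to_frame())


class TestLandscape:
    def test_empty_parameters_give_zero_dem(self):
        p = LandscapeParams(cluster_density_mm2=0.0, carpet_mean_mm=0.0,
                            colony_density_mm2=0.0, floor_height_mm=0.0,
                            **SMALL)
        g, truth = gen_landscape(p, seed=5)
        assert not g.heights.any()
        assert len(truth.clusters) == 0

    def test_degenerate_extent_rejected(self):
        with pytest.raises(ValidationError):
            LandscapeParams(extent_m=(0.0, 0.1)).shape()

    def test_heights_quantized_and_clipped(self):
        p = LandscapeParams(cluster_amp_median_mm=1.4, cluster_amp_sigma=0.1,
                            amp_cap_mm=1.5, **SMALL)
        g, _ = gen_landscape(p, seed=8)
        q = g.z_quantum_mm
        np.testing.assert_allclose(np.round(g.heights / q) * q, g.heights,
                                   atol=1e-12)
        assert g.heights.max() <= p.clip_mm + 1e-12
        assert g.clipped_fraction() > 0

    def test_logistic_weight_splits_morphotypes(self):
        w = ffm_weight(np.array([0.04, 0.08, 0.13]), 0.08, 0.01)
        assert w[0] < 0.05 and w[1] == pytest.approx(0.5) and w[2] > 0.95

    def test_noiseless_segmentation_recovers_planted_count(self):
        p = LandscapeParams(extent_m=(0.025, 0.1), tau_start_pa=0.04,
                            tau_end_pa=0.05, cluster_density_mm2=0.005,
                            cluster_amp_median_mm=1.0, cluster_amp_sigma=0.1,
                            amp_cap_mm=1.1, carpet_mean_mm=0.0,
                            colony_density_mm2=0.0, floor_height_mm=0.0,
                            min_separation_mm=7.0)
        g, truth = gen_landscape(p, seed=13)
        assert len(truth.clusters) > 0
        segmap, _ = segment_landscape(g, local_window_mm=24.0)
        stats, _ = extract_clusters(segmap, g)
        assert len(stats) == len(truth.clusters)

    def test_hydraulic_profile_spans_study_ranges(self):
        prof = gen_hydraulic_profile()
        t = prof.table
        assert (t["tau_Pa"].iloc[0], t["tau_Pa"].iloc[-1]) == (0.04, 0.13)
        assert (t["U_m_s"].iloc[0], t["U_m_s"].iloc[-1]) == (0.06, 0.13)
        assert (t["Re"].iloc[0], t["Re"].iloc[-1]) == (793.0, 1407.0)


class TestTimeseries:
    def test_pure_growth_has_no_negative_volume(self):
        p = LandscapeParams(**SMALL)
        series, _ = gen_timeseries(p, seed=3, days=(0, 3, 6, 9),
                                   detach_prob=0.0, displace_prob=0.0)
        for d in series_differences(series):
            assert d.negative_volume == 0.0

    def test_detachment_removes_planted_volume(self):
        p = LandscapeParams(extent_m=(0.02, 0.08), tau_start_pa=0.04,
                            tau_end_pa=0.05, cluster_density_mm2=0.01,
                            cluster_amp_median_mm=0.9, cluster_amp_sigma=0.1,
                            amp_cap_mm=1.1, carpet_mean_mm=0.0,
                            colony_density_mm2=0.0, floor_height_mm=0.0,
                            min_separation_mm=5.0)
        series, truth = gen_timeseries(p, seed=21, days=(12, 15),
                                       growth_rate=0.0, detach_prob=1.0,
                                       displace_prob=0.0)
        assert len(truth.clusters) > 0
        assert all(e["event"] == "detach" for e in truth.events)
        dv = biovolume(series.grids[1]) - biovolume(series.grids[0])
        planted = truth.clusters["volume_mm3"].sum()
        assert dv == pytest.approx(-planted, rel=0.03)

    def test_displacement_conserves_total_volume(self):
        p = LandscapeParams(extent_m=(0.02, 0.12), tau_start_pa=0.04,
                            tau_end_pa=0.05, cluster_density_mm2=0.008,
                            cluster_amp_median_mm=0.9, cluster_amp_sigma=0.1,
                            amp_cap_mm=1.1, carpet_mean_mm=0.0,
                            colony_density_mm2=0.0, floor_height_mm=0.0,
                            min_separation_mm=6.0, edge_margin_mm=6.0)
        series, truth = gen_timeseries(p, seed=2, days=(12, 15),
                                       growth_rate=0.0, detach_prob=0.0,
                                       displace_prob=1.0, shift_px=50)
        assert len(truth.events) == len(truth.clusters) > 0
        d = series_differences(series)[0]
        v1 = biovolume(series.grids[0])
        # rigid displacement: volume conserved while negative growth is large
        assert abs(d.positive_volume - d.negative_volume) < 0.02 * v1
        assert d.negative_volume > 0.2 * v1

    def test_event_log_days_match_series(self):
        series, truth = gen_timeseries(LandscapeParams(**SMALL), seed=6,
                                       days=(0, 3, 6, 9, 12, 15))
        days = set(series.days)
        assert all(e["day"] in days and e["day"] > 0 for e in truth.events)


class TestOxygen:
    def test_zero_consumption_constant_profile(self):
        p = OxygenParams(sfm_rd=0.0, sfm_pd=0.0, sfm_spread=0.0, noise_umol=0.0,
                         sfm_n=1, ffm_n=0, wall_reps=0)
        pset, _ = gen_oxygen(p, seed=0)
        dark = pset.select(condition="dark", morphotype="SFM").profiles[0]
        np.testing.assert_allclose(dark.concentrations, 300.0)

    def test_closed_form_base_concentration(self):
        # C(L) = C0 - (R/D) L^2/2 = 300 - 2080*0.125 = 40
        assert closed_form_oxygen(0.5, 300, 2080, 0.5) == pytest.approx(40.0)
        p = OxygenParams(noise_umol=0.0, sfm_spread=0.0)
        pset, truth = gen_oxygen(p, seed=0)
        dark = pset.select(condition="dark", morphotype="SFM").profiles[0]
        assert dark.concentrations.min() == pytest.approx(40.0)
        assert truth.oxygen["sfm_dark_base"] == pytest.approx(40.0)
        assert truth.oxygen["ffm_dark_base"] == pytest.approx(178.0)

    def test_discrete_diffusion_reaction_balance(self):
        p = OxygenParams(noise_umol=0.0, sfm_spread=0.0, ffm_n=0, sfm_n=1,
                         wall_reps=0)
        pset, _ = gen_oxygen(p, seed=0)
        dark = pset.select(condition="dark").profiles[0]
        inside = (dark.depths > 1e-9) & (dark.depths < p.sfm_L_mm - 1e-9)
        z = dark.depths[inside]
        c = dark.concentrations[inside]
        dz = z[1] - z[0]
        curvature = np.diff(c, 2) / dz ** 2
        np.testing.assert_allclose(curvature, p.sfm_rd, atol=1e-8)

    def test_negative_closed_form_truncated_with_warning(self):
        p = OxygenParams(sfm_rd=6000.0, noise_umol=0.0, sfm_spread=0.0,
                         sfm_n=1, ffm_n=0, wall_reps=0)
        with pytest.warns(UserWarning, match="truncated"):
            pset, truth = gen_oxygen(p, seed=0)
        dark = pset.select(condition="dark").profiles[0]
        assert dark.concentrations.min() == 0.0
        assert truth.oxygen["truncated"]
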