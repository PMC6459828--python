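import numpy as np
import pandas as pd
import pytest

from cartiq import roizones
from cartiq.synthdata import (
    CohortConfig,
    StressStrainCurve,
    ZonalDistribution,
    deform,
    generate_cohort,
    render_series,
    sample_truth,
    simulate_measured_records,
    synth_stress_strain,
)


@pytest.fixture()
def zero_cfg():
    return CohortConfig.zero_noise(n_int=2, n_deg=1)


class TestSampleTruth:
    def test_zero_sd_hits_configured_means(self, zero_cfg, rng):
        ph = sample_truth(zero_cfg, "int", rng)
        assert ph.true_value("T2", "sf", "d0") == pytest.approx(46.4)
        assert ph.true_value("T2", "dp", "d0") == pytest.approx(35.1)
        assert ph.true_value("T1", "sf", "d0") == pytest.approx(784.1)

    def test_zero_sd_seed_independent(self, zero_cfg):
        a = sample_truth(zero_cfg, "deg", np.random.default_rng(1))
        b = sample_truth(zero_cfg, "deg", np.random.default_rng(999))
        assert a.true_fields == b.true_fields

    def test_monte_carlo_mean(self):
        cfg = CohortConfig()
        rng = np.random.default_rng(5)
        draws = np.array(
            [
                sample_truth(cfg, "int", rng).true_value("T1", "sf", "d0")
                for _ in range(1000)
            ]
        )
        se = 133.8 / np.sqrt(1000)
        assert abs(draws.mean() - 784.1) < 3 * se

    def test_mss_consistent_with_group(self):
        cfg = CohortConfig()
        rng = np.random.default_rng(3)
        for _ in range(50):
            assert 0 <= sample_truth(cfg, "int", rng).mss <= 4
            assert 5 <= sample_truth(cfg, "deg", rng).mss <= 8

    def test_subscores_within_ranges(self):
        cfg = CohortConfig()
        rng = np.random.default_rng(4)
        for _ in range(50):
            s = sample_truth(cfg, "deg", rng).mss_subscores
            assert 0 <= s.structure <= 6
            assert 0 <= s.cellularity <= 3
            assert 0 <= s.proteoglycan <= 4
            assert 0 <= s.tidemark <= 1

    def test_unknown_group_rejected(self, zero_cfg, rng):
        with pytest.raises(KeyError):
            sample_truth(zero_cfg, "healthy", rng)

    def test_positivity(self):
        cfg = CohortConfig()
        # absurdly wide SDs still cannot produce non-positive truths
        cfg.distributions = {
            k: ZonalDistribution(d.mean, d.mean * 5, d.shift_d25, d.shift_d50)
            for k, d in cfg.distributions.items()
        }
        rng = np.random.default_rng(8)
        ph = sample_truth(cfg, "int", rng)
        assert all(v > 0 for v in ph.true_fields.values())


class TestDeform:
    def test_identity_at_unloaded(self, zero_cfg, rng):
        ph = sample_truth(zero_cfg, "int", rng)
        assert deform(ph, "d0").height_mm == pytest.approx(ph.height_mm)

    def test_default_factors(self, zero_cfg, rng):
        ph = sample_truth(zero_cfg, "int", rng)
        assert ph.height_mm == pytest.approx(3.0)
        assert deform(ph, "d2.5").height_mm == pytest.approx(3.0 * 0.939)
        assert deform(ph, "d5.0").height_mm == pytest.approx(2.532)

    def test_width_unchanged(self, zero_cfg, rng):
        ph = sample_truth(zero_cfg, "int", rng)
        assert deform(ph, "d5.0").width_mm == ph.width_mm

    def test_monotone_heights(self, zero_cfg, rng):
        ph = sample_truth(zero_cfg, "deg", rng)
        h0, h25, h50 = (ph.height_at(d) for d in ("d0", "d2.5", "d5.0"))
        assert h0 >= h25 >= h50

    def test_unknown_displacement(self, zero_cfg, rng):
        ph = sample_truth(zero_cfg, "int", rng)
        with pytest.raises(KeyError):
            deform(ph, "d7.5")


class TestRenderSeries:
    def test_noiseless_t1rho_at_zero_lock_equals_s0(self, zero_cfg, rng, protocols):
        ph = sample_truth(zero_cfg, "int", rng)
        series, mask, _ = render_series(ph, protocols["T1rho"], "d0", rng)
        assert protocols["T1rho"].time_points[0] == 0.0
        assert np.allclose(series.data[0][mask], ph.proton_density)

    def test_noiseless_t2_decay_value(self, zero_cfg, rng, protocols):
        cfg = zero_cfg
        ph = sample_truth(cfg, "int", rng)
        series, mask, zones = render_series(ph, protocols["T2"], "d0", rng)
        i = list(protocols["T2"].time_points).index(36.04)
        sf_px = zones == 1
        expected = ph.proton_density * np.exp(-36.04 / ph.true_value("T2", "sf", "d0"))
        assert np.allclose(series.data[i][sf_px], expected)

    def test_background_rician_mean(self, zero_cfg, protocols):
        cfg = CohortConfig.zero_noise(n_int=1, n_deg=0)
        rng = np.random.default_rng(17)
        ph = sample_truth(cfg, "int", rng)
        ph.noise_sigma = 30.0
        series, mask, zones = render_series(ph, protocols["T2"], "d0", rng)
        # outer frame: pure noise, Rayleigh mean sigma * sqrt(pi/2)
        bg = np.ones(series.shape, dtype=bool)
        bg[10:70, 5:75] = False
        values = series.data[:, bg].ravel()
        assert values.size > 10_000
        assert np.mean(values) == pytest.approx(30.0 * np.sqrt(np.pi / 2), rel=0.02)

    def test_zone_labels_partition_mask(self, zero_cfg, rng, protocols):
        ph = sample_truth(zero_cfg, "deg", rng)
        _, mask, zones = render_series(ph, protocols["T2star"], "d5.0", rng)
        assert np.array_equal(zones > 0, mask)
        assert set(np.unique(zones)) == {0, 1, 2}

    def test_disc_pixel_count_matches_geometry(self, zero_cfg, rng, protocols):
        ph = sample_truth(zero_cfg, "int", rng)
        _, mask, _ = render_series(ph, protocols["T2"], "d0", rng)
        spacing = protocols["T2"].pixel_spacing
        h2 = ph.height_mm / 2
        area = ph.height_mm * (ph.width_mm - ph.height_mm) + np.pi * h2**2
        assert mask.sum() * spacing**2 == pytest.approx(area, rel=0.1)

    def test_eroded_pixel_count_near_reference(self, zero_cfg, rng, protocols):
        # reference unloaded whole-sample ROI: 108 +/- 34 pixels
        ph = sample_truth(zero_cfg, "int", rng)
        _, mask, _ = render_series(ph, protocols["T2"], "d0", rng)
        ecs = roizones.erode_boundary(mask).sum()
        assert abs(ecs - 108) <= 0.2 * 108

    def test_pixel_counts_non_increasing_under_loading(self, zero_cfg, rng, protocols):
        ph = sample_truth(zero_cfg, "int", rng)
        counts = []
        for d in ("d0", "d2.5", "d5.0"):
            _, mask, _ = render_series(ph, protocols["T2"], d, rng)
            counts.append(int(mask.sum()))
        assert counts[0] >= counts[1] >= counts[2]


class TestStressStrain:
    def test_linear_noiseless(self, rng):
        curve = synth_stress_strain(0.5, 0.0, rng)
        i = np.argmin(np.abs(curve.strain - 0.20))
        assert curve.stress[i] == pytest.approx(0.5 * curve.strain[i])
        assert curve.stress[i] == pytest.approx(0.10, abs=1e-3)

    def test_invariants(self, rng):
        curve = synth_stress_strain(0.46, 0.01, rng)
        assert np.all(np.diff(curve.strain) > 0)
        assert curve.strain.max() <= 0.21 + 1e-12
        assert np.all(curve.stress >= 0)

    def test_nonpositive_modulus_rejected(self, rng):
        with pytest.raises(ValueError):
            synth_stress_strain(0.0, 0.01, rng)

    def test_curve_validation(self):
        with pytest.raises(ValueError):
            StressStrainCurve(strain=np.array([0.0, 0.0, 0.1]), stress=np.zeros(3))
        with pytest.raises(ValueError):
            StressStrainCurve(strain=np.array([0.0, 0.1, 0.25]), stress=np.zeros(3))


class TestGenerateCohort:
    def test_counts(self):
        cfg = CohortConfig.zero_noise(n_int=2, n_deg=1)
        cohort = generate_cohort(cfg)
        assert len(cohort.phantoms) == 3
        assert len(cohort.series) == 3 * 4 * 3
        assert len(cohort.metadata) == 3

    def test_empty_cohort(self):
        cfg = CohortConfig(n_int=0, n_deg=0)
        cohort = generate_cohort(cfg)
        assert cohort.phantoms == []
        assert cohort.series == {}
        assert cohort.metadata.empty

    def test_determinism_byte_identical(self):
        cfg = CohortConfig(n_int=2, n_deg=2, seed=42)
        a = generate_cohort(cfg)
        b = generate_cohort(CohortConfig(n_int=2, n_deg=2, seed=42))
        assert a.metadata.to_csv(index=False) == b.metadata.to_csv(index=False)
        for key in a.series:
            sa, ma, za = a.series[key]
            sb, mb, zb = b.series[key]
            assert np.array_equal(sa.data, sb.data)
            assert np.array_equal(ma, mb)
            assert np.array_equal(za, zb)

    def test_different_seeds_differ(self):
        a = generate_cohort(CohortConfig(n_int=1, n_deg=0, seed=1), render_images=False)
        b = generate_cohort(CohortConfig(n_int=1, n_deg=0, seed=2), render_images=False)
        assert a.metadata["ym_true"][0] != b.metadata["ym_true"][0]


class TestMeasuredRecords:
    def test_record_count_and_schema(self):
        cfg = CohortConfig(n_int=5, n_deg=4, seed=0)
        records = simulate_measured_records(cfg)
        assert len(records) == 9
        rec = records[0]
        assert ("T2", "ECS", "d5.0") in rec.zonal_means
        assert np.isfinite(rec.young_modulus)

    def test_zero_noise_equals_truth(self):
        cfg = CohortConfig.zero_noise(n_int=1, n_deg=1)
        rec = simulate_measured_records(cfg)[0]
        d = cfg.distributions[("T2", "dp", "int")]
        assert rec.zonal_means[("T2", "dp", "d0")] == pytest.approx(d.mean)
        assert rec.delta("T2", "dp", "d2.5") == pytest.approx((d.shift_d25 - 1) * 100)


class TestConfigRoundTrip:
    def test_dict_round_trip(self):
        cfg = CohortConfig(n_int=3, n_deg=4, seed=9, noise_sigma=11.0)
        back = CohortConfig.from_dict(cfg.to_dict())
        assert back == cfg

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            CohortConfig(n_int=-1)
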