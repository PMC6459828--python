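import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cartiq.stats import (
    analyze_cohort_table,
    log_transform_check,
    longitudinal_block,
    rm_anova,
    rm_anova_tukey,
    sample_size_unpaired,
    significance_marker,
    spearman,
    two_sample_t_power,
    unpaired_t_log,
)


def brute_force_rm_f(x):
    """Independent sum-of-squares oracle for the within-subject F."""
    n, k = x.shape
    grand = x.mean()
    ss_cond = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_err = 0.0
    for i in range(n):
        for j in range(k):
            ss_err += (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
    return (ss_cond / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))


class TestLogTransform:
    def test_inverse_identity(self, rng):
        z = rng.normal(size=50)
        logged, _ = log_transform_check(np.exp(z))
        assert np.allclose(logged, z)

    def test_lognormal_passes_normality(self):
        passes = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            x = np.exp(r.normal(3.0, 0.4, size=500))
            _, p = log_transform_check(x)
            passes += p > 0.05
        assert passes >= 95

    def test_constant_vector_flagged(self):
        logged, p = log_transform_check(np.full(20, 5.0))
        assert np.isnan(p)
        assert np.allclose(logged, np.log(5.0))

    def test_small_n_flagged(self):
        _, p = log_transform_check([1.0, 2.0, 3.0])
        assert np.isnan(p)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            log_transform_check([1.0, 0.0, 2.0])


class TestRMAnova:
    def test_identical_columns(self, rng):
        col = rng.normal(size=(10, 1))
        res = rm_anova(np.repeat(col, 3, axis=1))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_brute_force_oracle(self, rng):
        x = rng.normal(size=(4, 3)) + np.array([0.0, 0.3, 0.8])
        res = rm_anova(x)
        assert res.statistic == pytest.approx(brute_force_rm_f(x), abs=1e-8)

    def test_brute_force_agreement_random_blocks(self):
        for seed in range(100):
            r = np.random.default_rng(seed)
            n = int(r.integers(3, 7))
            x = r.normal(size=(n, 3)) + r.normal(size=3)
            res = rm_anova(x)
            assert res.statistic == pytest.approx(brute_force_rm_f(x), rel=1e-8)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        x = rng.normal(size=(8, 3)) + np.array([0.0, 0.5, 1.0])
        res = rm_anova(x)
        df = pd.DataFrame(x, columns=["a", "b", "c"])
        df["subject"] = range(8)
        long = df.melt(id_vars="subject", var_name="cond", value_name="y")
        ref = pg.rm_anova(data=long, dv="y", within="cond", subject="subject")
        assert res.statistic == pytest.approx(float(ref["F"][0]), rel=1e-9)
        assert res.p_value == pytest.approx(float(ref["p_unc"][0]), rel=1e-9)

    def test_missing_values_rejected(self):
        x = np.ones((4, 3))
        x[0, 0] = np.nan
        with pytest.raises(ValueError):
            rm_anova(x)

    def test_tukey_pairwise_keys(self, rng):
        x = rng.normal(size=(6, 3)) + np.array([0.0, 1.0, 2.0])
        res = rm_anova_tukey(x, ("d0", "d2.5", "d5.0"))
        assert set(res.posthoc) == {"d0-d2.5", "d0-d5.0", "d2.5-d5.0"}
        assert all(0 <= p <= 1 for p in res.posthoc.values())

    def test_tukey_orders_pairwise_evidence(self, rng):
        x = rng.normal(scale=0.2, size=(10, 3)) + np.array([0.0, 0.2, 2.0])
        res = rm_anova_tukey(x, ("a", "b", "c"))
        assert res.posthoc["a-c"] < res.posthoc["a-b"]

    def test_gg_epsilon_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        from cartiq.stats import _gg_epsilon

        x = rng.normal(size=(8, 3)) + np.array([0.0, 0.5, 1.0])
        df = pd.DataFrame(x, columns=["a", "b", "c"])
        df["subject"] = range(8)
        long = df.melt(id_vars="subject", var_name="cond", value_name="y")
        ref = pg.rm_anova(data=long, dv="y", within="cond", subject="subject")
        assert _gg_epsilon(x) == pytest.approx(float(ref["eps"][0]), rel=1e-6)

    def test_gg_correction_weakens_clear_effects(self, rng):
        # with F >> 1, shrinking both dfs can only raise the p-value
        base = rng.normal(size=(12, 1))
        x = np.hstack([base, base + 1.0, base * 3 + 4])
        plain = rm_anova(x)
        corrected = rm_anova(x, gg_correction=True)
        assert plain.statistic > 10
        assert corrected.p_value >= plain.p_value

    def test_type_one_error_calibration(self):
        rejections = 0
        n_rep = 500
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            x = r.normal(size=(20, 3))
            rejections += rm_anova(x).p_value <= 0.05
        assert rejections / n_rep <= 0.075


class TestUnpairedT:
    def test_identical_groups(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = unpaired_t_log(x, x)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_closed_form(self, rng):
        a = np.exp(rng.normal(3.0, 0.2, 12))
        b = np.exp(rng.normal(3.3, 0.2, 15))
        res = unpaired_t_log(a, b)
        la, lb = np.log(a), np.log(b)
        na, nb = la.size, lb.size
        sp2 = ((na - 1) * la.var(ddof=1) + (nb - 1) * lb.var(ddof=1)) / (na + nb - 2)
        t = (la.mean() - lb.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        p = 2 * sps.t.sf(abs(t), na + nb - 2)
        assert res.statistic == pytest.approx(t, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-12)

    def test_scale_invariance_after_log(self, rng):
        a = np.exp(rng.normal(0, 1, 10))
        b = np.exp(rng.normal(1, 1, 10))
        r1 = unpaired_t_log(a, b)
        r2 = unpaired_t_log(7.7 * a, 7.7 * b)
        assert r2.statistic == pytest.approx(r1.statistic, rel=1e-9)

    def test_deep_zone_group_separation_power(self):
        # configured group difference 35.1 vs 39.9 (SDs 5.8 / 7.3, n 27/22)
        hits = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            a = np.clip(r.normal(35.1, 5.8, 27), 1, None)
            b = np.clip(r.normal(39.9, 7.3, 22), 1, None)
            hits += unpaired_t_log(a, b).p_value <= 0.05
        assert hits > 20

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            unpaired_t_log([1.0, -1.0], [1.0, 2.0])


class TestSpearman:
    def test_monotone_increasing(self):
        res = spearman([1, 2, 3, 4, 5], [10, 20, 25, 40, 80])
        assert res.statistic == pytest.approx(1.0)

    def test_reversed(self):
        res = spearman([1, 2, 3, 4, 5], [80, 40, 25, 20, 10])
        assert res.statistic == pytest.approx(-1.0)

    def test_ties_match_rank_formula(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 5.0, 5.0, 6.0, 7.0]
        y = [2.0, 1.0, 3.0, 3.0, 5.0, 4.0, 6.0, 6.0, 7.0, 9.0]
        res = spearman(x, y)
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert res.statistic == pytest.approx(expected, abs=1e-12)

    def test_constant_flagged(self):
        res = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(res.statistic)
        assert "constant input" in res.flags


class TestSampleSize:
    def test_reference_design(self):
        assert sample_size_unpaired(0.9, 0.05, 0.8) == 34

    def test_lower_power_design(self):
        # frozen from the noncentral-t oracle evaluated over n
        assert sample_size_unpaired(0.8, 0.05, 0.8) == 26

    def test_power_at_returned_n(self):
        n = sample_size_unpaired(0.9, 0.05, 0.8)
        assert two_sample_t_power(n, 0.8, 0.05) >= 0.9
        assert two_sample_t_power(n - 1, 0.8, 0.05) < 0.9

    def test_monotone_in_effect_size(self):
        sizes = [sample_size_unpaired(0.9, 0.05, d) for d in (0.3, 0.5, 0.8, 1.5, 10)]
        assert sizes == sorted(sizes, reverse=True)
        assert sizes[-1] == 2

    def test_monotone_in_power_and_alpha(self):
        assert sample_size_unpaired(0.95, 0.05, 0.8) >= sample_size_unpaired(
            0.8, 0.05, 0.8
        )
        assert sample_size_unpaired(0.9, 0.01, 0.8) >= sample_size_unpaired(
            0.9, 0.1, 0.8
        )

    def test_invalid_parameters(self):
        for bad in ((1.2, 0.05, 0.8), (0.9, 0.0, 0.8), (0.9, 0.05, -1.0)):
            with pytest.raises(ValueError):
                sample_size_unpaired(*bad)


class TestMarkers:
    @pytest.mark.parametrize(
        "p,marker",
        [(0.04, "*"), (0.009, "**"), (0.0005, "***"), (0.2, "ns"), (0.05, "*")],
    )
    def test_stratification(self, p, marker):
        assert significance_marker(p) == marker


class TestCohortBattery:
    def _table(self, seed=0):
        from cartiq.response import build_cohort_table
        from cartiq.synthdata import CohortConfig, simulate_measured_records

        cfg = CohortConfig(n_int=10, n_deg=8, seed=seed)
        return build_cohort_table(simulate_measured_records(cfg))

    def test_block_extraction(self):
        table = self._table()
        block = longitudinal_block(table, "T2", "dp", "deg")
        assert block.shape == (8, 3)
        assert np.all(block > 0)

    def test_battery_structure(self):
        results = analyze_cohort_table(self._table())
        assert set(results["family"]) == {
            "longitudinal",
            "group_comparison",
            "correlation",
        }
        assert ((results["p"] >= 0) & (results["p"] <= 1)).all()
        longi = results[results["family"] == "longitudinal"]
        assert {"all", "int", "deg"} <= set(longi["group"])
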