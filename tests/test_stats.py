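"""Cohort statistics: assumption checks, per-scale t tests, two-way ANOVA,
the base-0.05 log-p transform, and significance intervals."""

import math

import numpy as np
import pandas as pd
import pytest

import msptirr as mp
from msptirr import InvalidInputError, ParameterError
from msptirr.stats import CohortResult


class TestAssumptionChecks:
    def test_gaussian_samples_pass(self):
        rng = np.random.default_rng(1)
        res = mp.assumption_checks(rng.normal(size=300), rng.normal(size=300))
        assert res.normal_ok == (True, True)
        assert res.equal_variance_ok

    def test_heavy_tailed_sample_fails_normality(self):
        rng = np.random.default_rng(2)
        cauchy = rng.standard_cauchy(200)
        normal = rng.normal(size=200)
        res = mp.assumption_checks(cauchy, normal)
        assert not res.normal_ok[0]

    def test_identical_groups_pass_variance_check(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = mp.assumption_checks(g, g)
        assert res.f_statistic == 1.0
        assert res.equal_variance_ok

    def test_unequal_variances_flagged(self):
        rng = np.random.default_rng(3)
        res = mp.assumption_checks(
            rng.normal(scale=1.0, size=100), rng.normal(scale=5.0, size=100)
        )
        assert not res.equal_variance_ok

    def test_small_group_rejected(self):
        with pytest.raises(ParameterError, match="3"):
            mp.assumption_checks([1.0, 2.0], [1.0, 2.0, 3.0])


class TestPerScaleTTest:
    def test_large_shift_significant_everywhere(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(12, 10))
        b = a + 5.0  # shift far beyond the spread
        res = mp.per_scale_ttest(a, b)
        assert all(r.p_value < 0.05 for r in res)
        assert len(res) == 10

    def test_identical_groups_give_t0_p1(self):
        a = np.random.default_rng(5).normal(size=(8, 4))
        res = mp.per_scale_ttest(a, a.copy())
        for r in res:
            assert r.statistic == 0.0
            assert r.p_value == 1.0

    def test_group_summaries_match_numpy(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=(5, 3)), rng.normal(size=(7, 3))
        res = mp.per_scale_ttest(a, b, scales=(1, 2, 3))
        for k, r in enumerate(res):
            assert r.group_means[0] == pytest.approx(a[:, k].mean())
            assert r.group_sems[1] == pytest.approx(
                b[:, k].std(ddof=1) / math.sqrt(b.shape[0])
            )

    def test_mismatched_scales_rejected(self):
        a = np.zeros((4, 5))
        b = np.zeros((4, 6))
        with pytest.raises(InvalidInputError):
            mp.per_scale_ttest(a, b)

    def test_power_monotone_in_effect_size(self):
        """Rejection rate must grow with the injected group shift."""
        rng = np.random.default_rng(7)
        n_rep, n_a, n_b = 200, 15, 19
        rates = []
        for delta in (0.0, 0.5, 1.0):
            hits = 0
            for _ in range(n_rep):
                a = rng.normal(size=(n_a, 1))
                b = rng.normal(size=(n_b, 1)) + delta
                hits += mp.per_scale_ttest(a, b)[0].p_value < 0.05
            rates.append(hits / n_rep)
        assert rates[0] < rates[1] < rates[2]

    def test_profile_objects_accepted(self, rng):
        profs_a = [
            mp.profile(rng.normal(size=120), scales=(1, 2, 3), kind="pe")
            for _ in range(4)
        ]
        profs_b = [
            mp.profile(rng.normal(size=120), scales=(1, 2, 3), kind="pe")
            for _ in range(4)
        ]
        res = mp.per_scale_ttest(profs_a, profs_b)
        assert [r.scale for r in res] == [1, 2, 3]


def _two_way_frame(rng, group_shift=0.0, n_per_cell=6):
    rows = []
    for group, gdelta in (("HC", group_shift), ("SZ", 0.0)):
        for region in ("F", "O", "T"):
            for _ in range(n_per_cell):
                rows.append(
                    {"group": group, "region": region,
                     "value": rng.normal() + gdelta}
                )
    return pd.DataFrame(rows)


class TestTwoFactorAnova:
    def test_pure_group_effect_recovered(self):
        rng = np.random.default_rng(8)
        res = mp.two_factor_anova(_two_way_frame(rng, group_shift=2.0))
        assert res.p_values["group"] < 0.05
        assert res.p_values["interaction"] > 0.05

    def test_identical_cells_give_zero_f(self):
        rows = [
            {"group": g, "region": r, "value": 1.0}
            for g in ("HC", "SZ") for r in ("F", "O") for _ in range(3)
        ]
        res = mp.two_factor_anova(pd.DataFrame(rows))
        assert res.f_statistics == {"group": 0.0, "region": 0.0, "interaction": 0.0}
        assert all(p == 1.0 for p in res.p_values.values())

    def test_null_calibration(self):
        rng = np.random.default_rng(9)
        n_rep = 200
        hits = {"group": 0, "region": 0, "interaction": 0}
        for _ in range(n_rep):
            res = mp.two_factor_anova(_two_way_frame(rng), factor_name="region")
            for key in hits:
                hits[key] += res.p_values[key] < 0.05
        for key, h in hits.items():
            assert 0.01 <= h / n_rep <= 0.12, key

    def test_empty_cell_rejected(self):
        df = pd.DataFrame(
            {"group": ["HC"] * 4 + ["SZ"] * 2,
             "region": ["F", "F", "O", "O", "F", "F"],
             "value": np.arange(6.0)}
        )
        with pytest.raises(ParameterError):
            mp.two_factor_anova(df)


class TestLogPTransform:
    @pytest.mark.parametrize("p, expected", [(0.05, 1.0), (1.0, 0.0), (0.0025, 2.0)])
    def test_examples(self, p, expected):
        assert mp.log_p_transform(p) == pytest.approx(expected, abs=1e-12)

    def test_strictly_decreasing_and_invertible(self):
        ps = np.linspace(1e-6, 1.0, 50)
        out = mp.log_p_transform(ps)
        assert np.all(np.diff(out) < 0)
        recovered = 0.05**out
        np.testing.assert_allclose(recovered, ps, rtol=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ParameterError):
            mp.log_p_transform(0.0)
        with pytest.raises(ParameterError):
            mp.log_p_transform(1.5)


def _results(pvals, start_scale=1):
    return [
        CohortResult(scale=start_scale + i, statistic=0.0, p_value=p,
                     test="t-pooled", group_means=(0, 0), group_sems=(0, 0))
        for i, p in enumerate(pvals)
    ]


class TestSignificanceIntervals:
    def test_runs_detected(self):
        iv = mp.significance_intervals(_results([0.04, 0.03, 0.2, 0.01]))
        assert iv.intervals == ((1, 2), (4, 4))

    def test_all_nonsignificant(self):
        iv = mp.significance_intervals(_results([0.5, 0.9, 0.06]))
        assert iv.intervals == ()
        assert str(iv) == "No significant difference"

    def test_full_span(self):
        iv = mp.significance_intervals(_results([0.01] * 99, start_scale=2))
        assert iv.intervals == ((2, 100),)
        assert str(iv) == "[2,100]"
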