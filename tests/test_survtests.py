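"""Weighted logrank family, versatile (max-combo) and RMST combination tests."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from nphsim import (
    TrialDataset,
    cox_z_test,
    fit_cox,
    km_rmst,
    rmst_combination_test,
    sample_trial,
    versatile_test,
    weighted_logrank,
)
from nphsim.survtests import _max_z_pvalue


def _enumerated_weighted_logrank(time, event, arm, rho, gam):
    """Brute-force risk-set enumeration, independent of the package internals."""
    times = sorted({t for t, e in zip(time, event) if e == 1})
    s_left, s_run = [], 1.0
    terms = []
    for t in times:
        n = sum(1 for tt in time if tt >= t)
        n1 = sum(1 for tt, a in zip(time, arm) if tt >= t and a == 1)
        d = sum(1 for tt, e in zip(time, event) if tt == t and e == 1)
        d1 = sum(1 for tt, e, a in zip(time, event, arm) if tt == t and e == 1 and a == 1)
        w = s_run**rho * (1.0 - s_run) ** gam
        o_minus_e = d1 - d * n1 / n
        v = d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1) if n > 1 else 0.0
        terms.append((w, o_minus_e, v))
        s_run *= 1.0 - d / n
    num = sum(w * om for w, om, _ in terms)
    den = sum(w * w * v for w, _, v in terms)
    return num / math.sqrt(den)


SIX_SUBJECT = dict(
    time=np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]),
    event=np.array([1, 1, 1, 1, 1, 1]),
    arm=np.array([1, 0, 1, 0, 0, 1]),
)


class TestWeightedLogrank:
    @pytest.mark.parametrize("rho,gam", [(0, 0), (1, 0), (0, 1), (1, 1)])
    def test_six_subject_enumeration_oracle(self, rho, gam):
        data = TrialDataset(**SIX_SUBJECT)
        oracle = _enumerated_weighted_logrank(
            SIX_SUBJECT["time"], SIX_SUBJECT["event"], SIX_SUBJECT["arm"], rho, gam
        )
        assert weighted_logrank(data, rho, gam).statistic == pytest.approx(oracle, abs=1e-12)

    def test_fh00_is_plain_logrank(self, design_trial):
        ours = weighted_logrank(design_trial, 0, 0)
        oracle = _enumerated_weighted_logrank(
            design_trial.time, design_trial.event, design_trial.arm, 0, 0
        )
        assert ours.statistic == pytest.approx(oracle, abs=1e-12)
        assert ours.name == "logrank"

    def test_fh00_matches_lifelines(self, design_trial):
        from lifelines.statistics import logrank_test

        d = design_trial
        ll = logrank_test(
            d.time[d.arm == 1], d.time[d.arm == 0], d.event[d.arm == 1], d.event[d.arm == 0]
        )
        assert weighted_logrank(d, 0, 0).statistic ** 2 == pytest.approx(
            ll.test_statistic, rel=1e-10
        )

    def test_balanced_risk_sets_give_zero(self):
        data = TrialDataset(
            arm=np.array([0, 1, 0, 1]),
            time=np.array([1.0, 1.0, 2.0, 2.0]),
            event=np.array([1, 1, 1, 1]),
        )
        res = weighted_logrank(data, 0, 0)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_negative_weights_rejected(self, design_trial):
        with pytest.raises(ValueError):
            weighted_logrank(design_trial, -1.0, 0.0)


class TestVersatile:
    def test_identity_correlation_closed_form(self):
        """Independent components: p = 1 - (2*Phi(z) - 1)^3."""
        for z in (1.0, 2.0, 2.5):
            expected = 1.0 - (2.0 * stats.norm.cdf(z) - 1.0) ** 3
            assert _max_z_pvalue(z, np.eye(3)) == pytest.approx(expected, abs=2e-4)

    def test_perfect_correlation_limit_is_univariate(self):
        R = np.full((3, 3), 1.0 - 1e-12)
        np.fill_diagonal(R, 1.0)
        for z in (1.5, 2.2):
            assert _max_z_pvalue(z, R) == pytest.approx(2 * stats.norm.sf(z), abs=2e-4)

    def test_statistic_is_max_abs_component(self, design_trial):
        res = versatile_test(design_trial)
        assert res.statistic == pytest.approx(
            max(abs(v) for v in res.components.values()), abs=1e-12
        )

    def test_bonferroni_sandwich(self, design_cell):
        """best single-component p <= p_versatile <= 3 * best component p."""
        for seed in range(6):
            data = sample_trial(design_cell, 100 + seed)
            res = versatile_test(data)
            best = 2.0 * stats.norm.sf(res.statistic)
            assert res.p_value >= best - 1e-3
            assert res.p_value <= 3.0 * best + 1e-3

    def test_deterministic_p_value(self, design_trial):
        a = versatile_test(design_trial).p_value
        b = versatile_test(design_trial).p_value
        assert a == b


class TestKMRMST:
    def test_matches_lifelines_rmst(self, design_trial):
        from lifelines import KaplanMeierFitter
        from lifelines.utils import restricted_mean_survival_time

        d = design_trial
        sel = d.arm == 0
        km = KaplanMeierFitter().fit(d.time[sel], d.event[sel])
        expected = restricted_mean_survival_time(km, t=40.0)
        ours, var = km_rmst(d.time[sel], d.event[sel], 40.0)
        assert ours == pytest.approx(expected, rel=1e-10)
        assert var > 0


class TestCombination:
    def test_antisymmetric_data_gives_null_rmst_component(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(10.0, size=60).clip(max=50.0)
        e = (t < 50.0).astype(int)
        data = TrialDataset(
            arm=np.r_[np.zeros(60, int), np.ones(60, int)],
            time=np.r_[t, t],
            event=np.r_[e, e],
        )
        res = rmst_combination_test(data, n_permutations=300, rng=0)
        assert res.components["p_rmst"] > 0.9

    def test_deterministic_given_rng(self, design_trial):
        a = rmst_combination_test(design_trial, 300, rng=5)
        b = rmst_combination_test(design_trial, 300, rng=5)
        assert a.p_value == b.p_value

    def test_detects_design_effect(self, design_trial):
        res = rmst_combination_test(design_trial, 500, rng=1)
        assert res.p_value < 0.05

    def test_null_rejection_rate_controlled(self, by_id):
        """pCT is valid by construction: ~5% rejections under the null."""
        scen = by_id["null_constant"]
        rej = 0
        n = 150
        for r in range(n):
            data = sample_trial(scen, 5000 + r)
            rej += rmst_combination_test(data, 300, rng=r).p_value < 0.05
        se = math.sqrt(0.05 * 0.95 / n)
        assert rej / n < 0.05 + 3.5 * se

    def test_tracks_cox_power_under_ph(self, design_cell):
        """pCT retains most of the Cox test's power when PH holds.

        The nonparametric RMST component buys insurance against non-PH at the
        price of a few points of PH power, so the paired deficit should stay
        within ten percentage points of the Cox comparator.
        """
        n = 200
        rej_ct = rej_cox = 0
        for r in range(n):
            data = sample_trial(design_cell, 7000 + r)
            rej_ct += rmst_combination_test(data, 500, rng=r).p_value < 0.05
            rej_cox += cox_z_test(data).p_value < 0.05
        assert rej_ct / n > 0.6
        assert rej_cox / n - rej_ct / n <= 0.10

    def test_parameter_validation(self, design_trial):
        with pytest.raises(ValueError):
            rmst_combination_test(design_trial, n_permutations=50)
        with pytest.raises(ValueError):
            rmst_combination_test(design_trial, n_tstar=1)


class TestCoxZ:
    def test_p_equals_fit_cox(self, design_trial):
        assert cox_z_test(design_trial).p_value == fit_cox(design_trial).p_value

    def test_logrank_and_cox_decisions_agree_under_ph(self, design_cell):
        agree = 0
        n = 60
        for r in range(n):
            data = sample_trial(design_cell, 900 + r)
            agree += (weighted_logrank(data, 0, 0).p_value < 0.05) == (
                cox_z_test(data).p_value < 0.05
            )
        assert agree / n >= 0.95
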