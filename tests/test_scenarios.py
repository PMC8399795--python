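"""Data-generating model: closed-form hazards, sampling law, scenario grid."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from nphsim import (
    CANONICAL_RATES,
    CONSTANT,
    EffectProfile,
    EventRateSpec,
    ScenarioSpec,
    TrialDataset,
    cumulative_hazard,
    design_scenario,
    expected_event_fraction_before,
    read_trials_csv,
    sample_trial,
    scenario_grid,
    survival_probability,
    write_trials_csv,
)
from nphsim.scenarios import is_ph_cell


def _scenario(rate=CONSTANT, kind="ph", change=0.0, beta=-0.4, n=207):
    return ScenarioSpec(rate=rate, effect=EffectProfile(kind, change, beta), n_subjects=n)


class TestCumulativeHazard:
    @pytest.mark.parametrize(
        "scenario, arm, t, expected",
        [
            (_scenario(), 0, 50.0, 5.0),  # constant-rate control: 0.10 * 50
            (_scenario(kind="lag", change=3.0), 0, 0.0, 0.0),
            # lag profile, arm 1: 0.3 + exp(-0.4)*0.1*47
            (_scenario(kind="lag", change=3.0), 1, 50.0, 0.3 + math.exp(-0.4) * 0.1 * 47),
        ],
    )
    def test_closed_form_values(self, scenario, arm, t, expected):
        assert cumulative_hazard(scenario, arm, t) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("kind,change", [("lag", 3.0), ("early", 10.0), ("ph", 0.0)])
    @pytest.mark.parametrize("rate", CANONICAL_RATES)
    def test_matches_numerical_quadrature(self, rate, kind, change):
        """H(t) equals the integral of the piecewise hazard h(t)."""
        scen = _scenario(rate=rate, kind=kind, change=change)
        lam, gam, beta = rate.scale, rate.shape, -0.4

        def hazard(t):
            hr = 1.0
            if kind == "ph":
                hr = math.exp(beta)
            elif kind == "lag" and t > change:
                hr = math.exp(beta)
            elif kind == "early" and t <= change:
                hr = math.exp(beta)
            return lam * gam * t ** (gam - 1.0) * hr

        for t in (2.0, change + 0.5, 30.0, 50.0):
            num, _ = integrate.quad(hazard, 0, t, points=[change], limit=200)
            assert cumulative_hazard(scen, 1, t) == pytest.approx(num, rel=1e-6)

    @pytest.mark.parametrize("kind", ["lag", "early"])
    @given(change=st.floats(0.5, 40.0), eps=st.floats(1e-9, 1e-6))
    @settings(max_examples=25, deadline=None)
    def test_continuous_at_change_point(self, kind, change, eps):
        scen = _scenario(kind=kind, change=change)
        below = cumulative_hazard(scen, 1, change - eps)
        above = cumulative_hazard(scen, 1, change + eps)
        assert above - below == pytest.approx(0.0, abs=1e-5)
        assert above >= below  # non-decreasing

    def test_no_effect_period_equals_control(self):
        lag = _scenario(kind="lag", change=10.0)
        t_pre = np.linspace(0.0, 10.0, 7)
        np.testing.assert_allclose(
            cumulative_hazard(lag, 1, t_pre), cumulative_hazard(lag, 0, t_pre), rtol=1e-14
        )
        early = _scenario(kind="early", change=10.0)
        h1 = cumulative_hazard(early, 1, 30.0) - cumulative_hazard(early, 1, 10.0)
        h0 = cumulative_hazard(early, 0, 30.0) - cumulative_hazard(early, 0, 10.0)
        assert h1 == pytest.approx(h0, rel=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            cumulative_hazard(_scenario(), 0, -1.0)


class TestSurvival:
    @pytest.mark.parametrize(
        "rate, expected",
        [
            (EventRateSpec("decreasing", 0.15, 0.9), math.exp(-0.15 * 50**0.9)),
            (CONSTANT, math.exp(-5.0)),
            (EventRateSpec("increasing", 0.07, 1.1), math.exp(-0.07 * 50**1.1)),
        ],
    )
    def test_control_survival_at_horizon(self, rate, expected):
        assert survival_probability(_scenario(rate=rate), 0, 50.0) == pytest.approx(expected)

    def test_horizon_survival_calibrated_across_rates(self):
        """The three baseline shapes share S0(50) to within 0.002 by design."""
        s50 = [survival_probability(_scenario(rate=r), 0, 50.0) for r in CANONICAL_RATES]
        assert max(s50) - min(s50) < 0.002
        assert s50[1] < 0.007  # < 0.7% chance of survival without treatment

    def test_monotone_and_boundary(self):
        scen = _scenario(kind="lag", change=3.0)
        t = np.linspace(0.0, 50.0, 200)
        for arm in (0, 1):
            s = survival_probability(scen, arm, t)
            assert s[0] == 1.0
            assert np.all(np.diff(s) <= 1e-15)


class TestSampler:
    def test_event_times_follow_analytic_law(self):
        """PIT of sampled event times is uniform on (S(50), 1) per arm."""
        scen = replace(_scenario(kind="lag", change=3.0), n_subjects=20000)
        trial = sample_trial(scen, 123)
        for arm in (0, 1):
            sel = (trial.arm == arm) & (trial.event == 1)
            s = np.asarray(survival_probability(scen, arm, trial.time[sel]))
            s50 = survival_probability(scen, arm, 50.0)
            u = (s - s50) / (1.0 - s50)
            assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_null_arms_exchangeable(self):
        scen = replace(_scenario(kind="null", beta=0.0), n_subjects=20000)
        trial = sample_trial(scen, 5)
        res = stats.ks_2samp(trial.time[trial.arm == 0], trial.time[trial.arm == 1])
        assert res.pvalue > 0.01

    def test_censoring_invariants(self, design_trial):
        assert len(design_trial) == 207
        assert np.all(design_trial.time <= 50.0)
        assert np.all(design_trial.time[design_trial.event == 0] == 50.0)
        assert np.all(design_trial.time[design_trial.event == 1] < 50.0)

    def test_allocation_bernoulli_half(self):
        scen = replace(_scenario(), n_subjects=50000)
        trial = sample_trial(scen, 9)
        p = trial.arm.mean()
        assert abs(p - 0.5) < 3.0 * math.sqrt(0.25 / 50000)

    def test_restricted_mean_sample_moment(self):
        """Control-arm mean of min(T, 50) matches (1 - e^-5)/0.1 ~ 9.93."""
        scen = ScenarioSpec(
            rate=CONSTANT, effect=EffectProfile("null", 0.0, 0.0), n_subjects=100_000
        )
        trial = sample_trial(scen, 11)
        t0 = trial.time[trial.arm == 0]
        analytic = (1.0 - math.exp(-5.0)) / 0.1
        assert abs(t0.mean() - analytic) < 3.0 * t0.std(ddof=1) / math.sqrt(len(t0))

    def test_seeded_reproducibility(self, design_cell):
        a, b = sample_trial(design_cell, 77), sample_trial(design_cell, 77)
        np.testing.assert_array_equal(a.time, b.time)
        np.testing.assert_array_equal(a.arm, b.arm)


class TestEventFraction:
    def test_against_quadrature_oracle(self, by_id):
        """Closed-form event fraction equals the density-integral ratio."""
        for sid in ("lag_decreasing_t10", "lag_constant_t3", "early_constant_t10"):
            scen = by_id[sid]
            c = scen.effect.change_time

            def density(t, arm):
                h = 1e-8
                return (
                    np.asarray(survival_probability(scen, arm, t - h))
                    - np.asarray(survival_probability(scen, arm, t + h))
                ) / (2 * h)

            num = sum(integrate.quad(density, 0, c, args=(a,), limit=200)[0] for a in (0, 1))
            den = sum(integrate.quad(density, 0, 50.0, args=(a,), points=[c], limit=200)[0] for a in (0, 1))
            assert expected_event_fraction_before(scen) == pytest.approx(num / den, abs=1e-4)

    def test_known_values(self, by_id):
        assert expected_event_fraction_before(by_id["lag_decreasing_t10"]) == pytest.approx(0.706, abs=0.002)
        assert expected_event_fraction_before(by_id["lag_increasing_t3"]) == pytest.approx(0.213, abs=0.002)

    def test_vanishing_lag(self):
        assert expected_event_fraction_before(_scenario(kind="lag", change=0.0)) == 0.0

    def test_sample_agreement_constant_lag10(self, by_id):
        """Pooled sample fraction of pre-lag events ~ 0.64-0.65 (large n)."""
        scen = replace(by_id["lag_constant_t10"], n_subjects=50000)
        trial = sample_trial(scen, 21)
        ev = trial.event == 1
        frac = np.mean(trial.time[ev] <= 10.0)
        assert 0.63 < frac < 0.66
        assert frac == pytest.approx(expected_event_fraction_before(scen), abs=0.01)

    def test_undefined_for_ph(self):
        with pytest.raises(ValueError):
            expected_event_fraction_before(_scenario(kind="ph"))


class TestGrid:
    def test_structure(self, grid):
        assert len(grid) == 27
        assert len({s.scenario_id for s in grid}) == 27
        assert sum(is_ph_cell(s) for s in grid) == 6
        assert all(s.horizon == 50.0 for s in grid)
        assert all(s.allocation_prob == 0.5 for s in grid)

    def test_null_cells(self, grid):
        nulls = [s for s in grid if s.effect.kind == "null"]
        assert len(nulls) == 3
        assert all(s.effect.log_hr_active == 0.0 for s in nulls)

    def test_canonical_rate_parameters(self):
        assert [(r.scale, r.shape) for r in CANONICAL_RATES] == [
            (0.15, 0.9),
            (0.10, 1.0),
            (0.07, 1.1),
        ]

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            EventRateSpec("bad", -0.1, 1.0)
        with pytest.raises(ValueError):
            EffectProfile("sigmoid", 1.0)
        with pytest.raises(ValueError):
            ScenarioSpec(rate=CONSTANT, effect=EffectProfile("ph"), allocation_prob=1.5)


def test_csv_roundtrip(tmp_path, design_trial, by_id):
    other = sample_trial(by_id["lag_constant_t3"], 3)
    path = tmp_path / "trials.csv"
    write_trials_csv([design_trial, other], path)
    back = read_trials_csv(path)
    assert len(back) == 2
    np.testing.assert_allclose(back[0].time, design_trial.time)
    np.testing.assert_array_equal(back[1].arm, other.arm)
    assert back[0].seed == 42
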