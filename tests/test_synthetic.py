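"""Synthetic cohorts, closed-form oracles, and the digitization emulator."""

import numpy as np
import pytest

from kmgain import (
    SurvivalScenario,
    analytic_rmst,
    demo_scenarios,
    digitize_emulator,
    enforce_km_shape,
    km_from_ipd,
    median_survival,
    rmst_step_exact,
    rmst_trapezoid,
    simulate_cohort,
    to_step_function,
)
from kmgain.synthetic import write_scenario_yaml


def exp_scenario(n=200, lam=0.1, seed=0, censor=0.0, cutoff=18.0):
    return SurvivalScenario(model="exponential", rate=lam, n_subjects=n,
                            censor_rate=censor, admin_cutoff=cutoff, seed=seed)


class TestScenario:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(model="nonsense", n_subjects=10),
            dict(model="exponential", n_subjects=10),  # missing rate
            dict(model="exponential", rate=-1.0, n_subjects=10),
            dict(model="weibull", shape=1.2, n_subjects=10),  # missing scale
            dict(model="piecewise-exponential", breakpoints=(1.0, 2.0),
                 rates=(0.1, 0.2), n_subjects=10),  # must start at 0
            dict(model="exponential", rate=0.1, n_subjects=0),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SurvivalScenario(**kwargs)

    def test_yaml_round_trip(self, tmp_path):
        sc, _ = demo_scenarios(seed=3)
        p = tmp_path / "scenario.yaml"
        write_scenario_yaml(sc, p)
        assert SurvivalScenario.from_yaml(p) == sc


class TestSimulateCohort:
    def test_empirical_median_matches_target(self):
        """Large exponential cohorts: KM median within 5% of the true median."""
        for m in (3.5, 11.3):
            sc = exp_scenario(n=5000, lam=np.log(2) / m, seed=17, cutoff=60.0)
            km = km_from_ipd(simulate_cohort(sc))
            assert median_survival(km) == pytest.approx(m, rel=0.05)

    def test_no_censoring_all_events(self):
        sc = exp_scenario(n=100, censor=0.0, cutoff=1e9, seed=1)
        ipd = simulate_cohort(sc)
        assert ipd.n_events == 100

    def test_seeded_determinism(self):
        a, b = simulate_cohort(exp_scenario(seed=5)), simulate_cohort(exp_scenario(seed=5))
        assert np.array_equal(a.subject_times, b.subject_times)
        assert np.array_equal(a.event_flags, b.event_flags)

    def test_admin_cutoff_censors(self):
        sc = exp_scenario(n=500, lam=0.05, seed=2, cutoff=12.0)
        ipd = simulate_cohort(sc)
        assert ipd.subject_times.max() <= 12.0
        assert (~ipd.event_flags).sum() > 0


class TestAnalyticRmst:
    def test_exponential_closed_form(self):
        sc = exp_scenario(lam=0.1)
        assert analytic_rmst(sc, 18.0) == pytest.approx((1 - np.exp(-1.8)) / 0.1)

    def test_vanishing_rate_limit(self):
        sc = exp_scenario(lam=1e-15)
        assert analytic_rmst(sc, 18.0) == pytest.approx(18.0)

    def test_single_segment_piecewise_equals_exponential(self):
        pw = SurvivalScenario(model="piecewise-exponential", breakpoints=(0.0,),
                              rates=(0.1,), n_subjects=10)
        assert analytic_rmst(pw, 18.0) == pytest.approx(analytic_rmst(exp_scenario(lam=0.1), 18.0))

    def test_weibull_shape_one_is_exponential(self):
        wb = SurvivalScenario(model="weibull", shape=1.0, scale=10.0, n_subjects=10)
        assert analytic_rmst(wb, 18.0) == pytest.approx(
            analytic_rmst(exp_scenario(lam=0.1), 18.0), rel=1e-8
        )

    def test_piecewise_against_quadrature(self):
        from scipy import integrate

        sc = SurvivalScenario(model="piecewise-exponential",
                              breakpoints=(0.0, 4.0, 9.0),
                              rates=(0.15, 0.05, 0.02), n_subjects=10)
        bp, rates = np.array(sc.breakpoints), np.array(sc.rates)

        def surv(t):
            seg = np.searchsorted(bp, t, side="right") - 1
            h = np.sum(rates[:seg] * np.diff(bp)[:seg]) + rates[seg] * (t - bp[seg])
            return np.exp(-h)

        num, _ = integrate.quad(surv, 0, 18.0, limit=200)
        assert analytic_rmst(sc, 18.0) == pytest.approx(num, rel=1e-6)


class TestDigitizeEmulator:
    def test_noiseless_corner_digitization_is_trapezoid_exact(self, two_drop_step):
        dig = digitize_emulator(two_drop_step, n_points=20, jitter_sd=0.0,
                                seed=1, follow_up=12.0)
        clean = enforce_km_shape(dig)
        assert rmst_trapezoid(clean, 12.0).rmst == pytest.approx(
            rmst_step_exact(two_drop_step, 12.0), abs=1e-12
        )

    def test_seeded_determinism(self, two_drop_step):
        a = digitize_emulator(two_drop_step, 50, 0.02, seed=7, follow_up=12.0)
        b = digitize_emulator(two_drop_step, 50, 0.02, seed=7, follow_up=12.0)
        assert np.array_equal(a.times, b.times) and np.array_equal(a.probs, b.probs)

    def test_jitter_produces_monotonicity_violations(self, two_drop_step):
        """Raw digitizer output carries jitter the cleaner must repair."""
        dig = digitize_emulator(two_drop_step, 80, 0.02, seed=0, follow_up=12.0)
        assert np.any(np.diff(dig.probs) > 0)
        assert enforce_km_shape(dig).is_km_shaped()

    def test_jittered_rmst_close_to_step_exact(self):
        """sd=0.01, 75 points: trapezoid within 0.3 months of the exact AUC."""
        sc = exp_scenario(n=500, seed=42)
        km = km_from_ipd(simulate_cohort(sc))
        step = to_step_function(km)
        exact = rmst_step_exact(step, 18.0)
        for seed in range(20):
            dig = digitize_emulator(step, 75, 0.01, seed=seed,
                                    n_subjects=500, follow_up=km.follow_up)
            got = rmst_trapezoid(enforce_km_shape(dig), 18.0).rmst
            assert abs(got - exact) < 0.3

    def test_point_budget_respected(self, two_drop_step):
        dig = digitize_emulator(two_drop_step, 50, 0.0, seed=1, follow_up=12.0)
        assert dig.times.size == 50


class TestDemoScenarios:
    def test_two_arm_geometry(self):
        tr, ct = demo_scenarios(seed=0)
        assert (tr.n_subjects, ct.n_subjects) == (128, 190)
        assert tr.admin_cutoff == ct.admin_cutoff == 18.0
        # medians of the generating distributions land at the published anchors
        for sc, m in ((tr, 11.3), (ct, 3.5)):
            bp, rates = np.array(sc.breakpoints), np.array(sc.rates)
            edges = np.concatenate((bp, [np.inf]))
            h, median = 0.0, None
            for j, lam in enumerate(rates):
                need = np.log(2) - h
                seg = edges[j + 1] - edges[j]
                if lam * seg >= need:
                    median = edges[j] + need / lam
                    break
                h += lam * seg
            assert median == pytest.approx(m, abs=0.01)
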