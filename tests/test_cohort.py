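"""Cohort engine: event tree arithmetic, conservation, oracle agreement."""

import dataclasses

import numpy as np
import pytest

from htn_cea import (
    CohortState,
    EconSettings,
    ValidationError,
    acute_event_outcome,
    base_case,
    cycle_transition,
    discount,
    event_probability,
    run_cohort,
    run_cohort_draws,
    run_microsim,
)
from htn_cea.distributions import fixed
from htn_cea.params import acute_event_model
from htn_cea.psa import draw_inputs


def with_econ(ps, **kw):
    return dataclasses.replace(ps, econ=dataclasses.replace(ps.econ, **kw))


class TestEventProbability:
    def test_reference_risk_times_hazard_ratio(self):
        assert event_probability(0.0255, 0.6150) == pytest.approx(0.0156825)

    def test_identity_hazard(self):
        assert event_probability(0.37, 1.0) == 0.37

    def test_capped_at_one(self):
        assert event_probability(0.8, 2.0) == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            event_probability(1.2, 0.5)
        with pytest.raises(ValidationError):
            event_probability(0.5, 0.0)


class TestAcuteEventOutcome:
    def test_published_base_tree_under_75(self, params):
        out = acute_event_outcome(70, acute_event_model(params))
        assert out["unassisted_die"] == pytest.approx(0.10 + 0.90 * 0.367 * 0.30)
        assert out["assisted_die"] == pytest.approx(0.90 * 0.633 * 0.15)
        assert out["assisted_survive"] == pytest.approx(0.484245)
        assert out["unassisted_survive"] == pytest.approx(0.23121)
        assert sum(out.values()) == pytest.approx(1.0)

    def test_older_band_has_higher_fatality(self, params):
        aem = acute_event_model(params)
        young = acute_event_outcome(70, aem)
        old = acute_event_outcome(80, aem)
        die = lambda o: o["unassisted_die"] + o["assisted_die"]
        assert die(old) > die(young)

    def test_all_sudden_death_is_certain_unassisted_death(self, params):
        aem = dataclasses.replace(acute_event_model(params), p_sudden_death=1.0)
        out = acute_event_outcome(70, aem)
        assert out["unassisted_die"] == 1.0

    def test_benign_tree_has_no_deaths(self, params):
        aem = dataclasses.replace(
            acute_event_model(params), p_sudden_death=0.0,
            cfr_assisted_65_74=0.0, cfr_unassisted_65_74=0.0)
        out = acute_event_outcome(70, aem)
        assert out["unassisted_die"] + out["assisted_die"] == 0.0


class TestCycleTransition:
    def test_dead_cohort_is_absorbing(self, params, lifetable):
        state = CohortState(0.0, 0.0, 0.6, 0.4, 70)
        nxt, cost, lyg, events = cycle_transition(state, params, "usual", lifetable)
        assert (nxt.dead_cv, nxt.dead_other) == (0.6, 0.4)
        assert cost == lyg == events == 0.0

    def test_no_risk_no_mortality_preserves_occupancy(self, params):
        import numpy as np
        from htn_cea import LifeTable
        qx = np.zeros(36); qx[-1] = 1.0
        lt = LifeTable(ages=np.arange(65, 101), qx=qx)
        ps = params
        for name in ("risk_int_65_74", "risk_int_75plus", "risk_high_65_74",
                     "risk_high_75plus"):
            ps = ps.replace_spec(f"common.{name}", fixed(0.0))
        state = CohortState(0.7, 0.3, 0.0, 0.0, 70)
        nxt, _, lyg, _ = cycle_transition(state, ps, "usual", lt)
        assert (nxt.intermediate, nxt.high) == (0.7, 0.3)
        assert lyg == pytest.approx(1.0)

    def test_occupancy_is_conserved_every_cycle(self, params, lifetable):
        for strategy in ("usual", "programme"):
            trace = run_cohort(params, strategy, lt=lifetable).trace
            occ = trace[["intermediate", "high", "dead_cv", "dead_other"]].sum(axis=1)
            np.testing.assert_allclose(occ, 1.0, atol=1e-12)

    def test_transition_past_the_cap_rejected(self, params, lifetable):
        with pytest.raises(ValidationError):
            cycle_transition(CohortState(1, 0, 0, 0, 100), params, "usual", lifetable)


class TestRunCohort:
    def test_programme_gains_life_years(self, params, lifetable):
        u = run_cohort(params, "usual", lt=lifetable, keep_trace=False)
        p = run_cohort(params, "programme", lt=lifetable, keep_trace=False)
        assert p.disc_lyg > u.disc_lyg

    def test_life_years_monotone_in_discount_rate(self, params, lifetable):
        lygs = [run_cohort(with_econ(params, discount_rate=r), "usual",
                           lt=lifetable, keep_trace=False).disc_lyg
                for r in (0.0, 0.03, 0.05, 0.07, 0.12)]
        assert all(a >= b for a, b in zip(lygs, lygs[1:]))

    def test_life_years_monotone_in_event_risk(self, params, lifetable):
        riskier = params.replace_spec("common.risk_high_75plus", fixed(0.30))
        assert (run_cohort(riskier, "usual", lt=lifetable, keep_trace=False).disc_lyg
                < run_cohort(params, "usual", lt=lifetable, keep_trace=False).disc_lyg)

    def test_life_years_monotone_in_case_fatality(self, params, lifetable):
        deadlier = params.replace_spec("common.cfr_assisted_75plus", fixed(0.35))
        assert (run_cohort(deadlier, "usual", lt=lifetable, keep_trace=False).disc_lyg
                < run_cohort(params, "usual", lt=lifetable, keep_trace=False).disc_lyg)

    def test_lower_hazard_ratio_never_loses_life_years(self, params, lifetable):
        for hr_u, hr_p in [(0.9, 0.6), (0.615, 0.5124), (1.0, 1.0)]:
            ps = params.replace_spec("usual.hazard_ratio", fixed(hr_u))
            ps = ps.replace_spec("programme.hazard_ratio", fixed(hr_p))
            u = run_cohort(ps, "usual", lt=lifetable, keep_trace=False)
            p = run_cohort(ps, "programme", lt=lifetable, keep_trace=False)
            assert p.disc_lyg >= u.disc_lyg

    def test_invalid_start_age_rejected(self, params, lifetable):
        bad = params.replace_spec("common.start_age", fixed(100.0))
        with pytest.raises(ValidationError):
            run_cohort(bad, "usual", lt=lifetable)


class TestDiscount:
    @pytest.mark.parametrize("value, rate, t, expected", [
        (100.0, 0.05, 0, 100.0),
        (100.0, 0.05, 1, 100.0 / 1.05),
        (123.4, 0.0, 7, 123.4),
    ])
    def test_present_value(self, value, rate, t, expected):
        assert discount(value, rate, t) == pytest.approx(expected)


class TestVectorisedEngineMatchesScalar:
    def test_cohort_draws_equal_scalar_loop(self, params, lifetable):
        """The vectorised multi-draw engine and the traced scalar engine are
        the same model: identical outputs on 40 random parameter sets."""
        ps = dataclasses.replace(
            params, econ=dataclasses.replace(params.econ,
                                             sample_cohort_composition=True))
        rng = np.random.default_rng(7)
        draws = draw_inputs(ps, rng, 40)
        for strategy in ("usual", "programme"):
            vec_cost, vec_lyg = run_cohort_draws(
                draws, strategy, ps.econ.discount_rate, lifetable, ps.econ)
            for i in range(40):
                ps_i = ps
                for name, arr in draws.items():
                    ps_i = ps_i.replace_spec(name, fixed(float(arr[i])))
                res = run_cohort(ps_i, strategy, lt=lifetable, keep_trace=False)
                assert res.disc_cost == pytest.approx(vec_cost[i], rel=1e-10)
                assert res.disc_lyg == pytest.approx(vec_lyg[i], rel=1e-10)


class TestMicrosimOracle:
    def scenarios(self, params):
        yield "usual base", params, "usual"
        yield "programme base", params, "programme"
        yield "12% discount", with_econ(params, discount_rate=0.12), "usual"
        older = params.replace_spec("common.start_age", fixed(78.0))
        older = older.replace_spec("common.p_start_intermediate", fixed(0.30))
        yield "older high-risk cohort", older, "programme"
        hr = params.replace_spec("programme.hazard_ratio", fixed(0.45))
        yield "strong-effect scenario", hr, "programme"

    def test_cohort_expectation_matches_microsimulation(self, params, lifetable):
        """Brute-force oracle: individual simulation agrees with the cohort
        expectation within 3 Monte-Carlo SE on five scenarios."""
        for i, (label, ps, strategy) in enumerate(self.scenarios(params)):
            cohort = run_cohort(ps, strategy, lt=lifetable, keep_trace=False)
            sim = run_microsim(ps, strategy, lt=lifetable,
                               n_individuals=150_000, seed=1000 + i)
            assert abs(sim.disc_cost - cohort.disc_cost) < 3 * sim.se_cost, label
            assert abs(sim.disc_lyg - cohort.disc_lyg) < 3 * sim.se_lyg, label

    def test_microsim_reproducible_under_fixed_seed(self, params, lifetable):
        a = run_microsim(params, "usual", lt=lifetable, n_individuals=500, seed=3)
        b = run_microsim(params, "usual", lt=lifetable, n_individuals=500, seed=3)
        assert (a.disc_cost, a.disc_lyg) == (b.disc_cost, b.disc_lyg)

    def test_zero_risk_paths_are_identical(self, params):
        from htn_cea import LifeTable
        qx = np.zeros(36); qx[-1] = 1.0
        lt = LifeTable(ages=np.arange(65, 101), qx=qx)
        ps = params
        for name in ("risk_int_65_74", "risk_int_75plus", "risk_high_65_74",
                     "risk_high_75plus"):
            ps = ps.replace_spec(f"common.{name}", fixed(0.0))
        sim = run_microsim(ps, "usual", lt=lt, n_individuals=200, seed=9)
        assert sim.se_lyg == 0.0  # every path survives to the cap
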