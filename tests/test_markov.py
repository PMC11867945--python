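"""Cohort engine: baseline decision tree, transitions, conservation laws and
the collapsed constant-rate oracle."""

import numpy as np
import pytest

from crcscreen import (
    MarkovCohortModel,
    StrategySpec,
    apply_strategy,
    discount_factor,
    run_cohort,
)
from crcscreen.markov import _CF, _CS, _HN, HorizonSpec, N_STATES
from crcscreen.parameters import ValidationError


class TestDiscounting:
    @pytest.mark.parametrize("rate, cycle, expected",
                             [(0.05, 1, 1 / 1.05), (0.0, 7, 1.0),
                              (0.05, 10, 1.05 ** -10)])
    def test_closed_form(self, rate, cycle, expected):
        assert discount_factor(rate, cycle) == pytest.approx(expected,
                                                             abs=1e-12)

    def test_discounted_qalys_never_exceed_undiscounted(self, params):
        disc = run_cohort(params, StrategySpec("none"))
        undisc = run_cohort(params.with_values(discount=0.0),
                            StrategySpec("none"))
        assert disc.per_capita_qaly <= undisc.per_capita_qaly


class TestBaselineDecisionTree:
    def test_completed_colonoscopies_share_of_population(self, params):
        init = apply_strategy(params, StrategySpec("sequential", 0.422))
        assert init.colonoscopies == pytest.approx(0.203 * 0.422)
        assert init.colonoscopies == pytest.approx(0.0857, abs=5e-4)

    def test_zero_acceptance_matches_no_screening_except_fit_cost(self, params):
        none = apply_strategy(params, StrategySpec("none"))
        seq0 = apply_strategy(params, StrategySpec("sequential", 0.0))
        np.testing.assert_allclose(none.occupancy, seq0.occupancy)
        assert seq0.upfront_cost == pytest.approx(params.c_fit)
        assert none.upfront_cost == 0.0

    def test_full_uptake_colonoscopy(self, params):
        init = apply_strategy(params, StrategySpec("colonoscopy", 1.0))
        # all prevalent cancers found at baseline, everyone else post-colo
        assert init.diagnosed_self == 0.0
        assert init.diagnosed_screen == pytest.approx(params.prev_general)
        assert init.occupancy[_HN] == 0.0
        assert init.occupancy[1] == pytest.approx(1 - params.prev_general)

    def test_sequential_detection_limited_by_primary_sensitivity(self, params):
        init = apply_strategy(params, StrategySpec("sequential", 1.0))
        assert init.diagnosed_screen == pytest.approx(
            params.sens_primary * params.prev_general
        )

    def test_occupancy_sums_to_one(self, params):
        for name, a in (("none", 0.0), ("sequential", 0.7),
                        ("colonoscopy", 0.3)):
            init = apply_strategy(params, StrategySpec(name, a))
            assert init.occupancy.sum() == pytest.approx(1.0, abs=1e-12)


class TestTransitions:
    def test_rows_are_stochastic_every_cycle(self, params):
        model = MarkovCohortModel(params, StrategySpec("none"))
        for t in (1, 5, 25, 60):
            M = model.transition_matrix(t)
            np.testing.assert_allclose(M.sum(axis=1), np.ones(N_STATES),
                                       atol=1e-9)

    def test_incidence_by_state(self, params_flat):
        model = MarkovCohortModel(params_flat, StrategySpec("none"))
        M = model.transition_matrix(1)
        qx = params_flat.mort_bg
        # healthy-naive incidence
        assert M[_HN, _CF.start] == pytest.approx(0.002 * (1 - qx))
        # post-colonoscopy year 3 and year 8
        assert M[3, _CF.start] == pytest.approx(0.0002 * (1 - qx))
        assert M[8, _CF.start] == pytest.approx(0.00035 * (1 - qx))

    def test_named_transition_rows(self, params_flat):
        from crcscreen import build_transitions

        qx = params_flat.mort_bg
        row = build_transitions(params_flat, "healthy_naive")
        assert row["crc_self_1"] == pytest.approx(0.002 * (1 - qx))
        row = build_transitions(params_flat, "healthy_postcolo_3")
        assert row["crc_self_1"] == pytest.approx(0.0002 * (1 - qx))
        row = build_transitions(params_flat, "crc_self_1")
        assert row["dead_crc"] == pytest.approx(0.092)
        assert sum(row.values()) == pytest.approx(1.0, abs=1e-9)
        with pytest.raises(ValidationError):
            build_transitions(params_flat, "limbo")

    def test_self_referred_first_year_death(self, params_flat):
        model = MarkovCohortModel(params_flat, StrategySpec("none"))
        M = model.transition_matrix(1)
        assert M[_CF.start, -2] == pytest.approx(0.092)  # dead_crc column

    def test_mass_conserved_along_run(self, params):
        res = MarkovCohortModel(params, StrategySpec("sequential", 1.0)).run()
        states = res.trace.drop(columns=["cycle", "cycle_cost", "cycle_qaly"])
        np.testing.assert_allclose(states.sum(axis=1), 1.0, atol=1e-9)

    def test_total_mortality_absorbs_cohort(self, params_flat):
        res = run_cohort(params_flat.with_values(mort_bg=1.0),
                         StrategySpec("none"), "paper-10y")
        assert res.per_capita_qaly <= 1.0


class TestStrategyOrdering:
    def test_deaths_monotone_in_acceptance(self, params):
        deaths = [
            run_cohort(params, StrategySpec("colonoscopy", a)).cum_crc_deaths
            for a in np.linspace(0, 1, 11)
        ]
        assert all(b <= a + 1e-6 for a, b in zip(deaths, deaths[1:]))

    def test_screening_reduces_deaths(self, params):
        none = run_cohort(params, StrategySpec("none"))
        for a in (0.25, 0.6, 1.0):
            seq = run_cohort(params, StrategySpec("sequential", a))
            colo = run_cohort(params, StrategySpec("colonoscopy", 1.0))
            assert none.cum_crc_deaths >= seq.cum_crc_deaths
            assert seq.cum_crc_deaths >= colo.cum_crc_deaths


class TestCollapsedOracle:
    """With constant incidence, constant CRC death hazard and flat background
    mortality, no prevalent disease and no cure reachable inside the run, the
    tunnel model collapses to three states whose expectations have closed
    geometric forms."""

    I, Q, M_BG, R = 0.002, 0.05, 0.0063, 0.05

    def _params(self, params_flat):
        cum = tuple(1 - (1 - self.Q) ** y for y in (1, 3, 5, 10))
        return params_flat.with_values(
            prev_general=0.0,
            inc_postcolo_0_5=self.I,
            inc_postcolo_5_10=self.I,
            cumdeath_self=cum,
            cumdeath_screen=cum,
            mort_bg=self.M_BG,
            discount=self.R,
        )

    def _oracle(self, p):
        i, q, m, r = self.I, self.Q, self.M_BG, self.R
        u_h, u_c, c_crc = p.u_health, p.u_self, p.c_self_crc
        H = 1.0
        C = 0.0
        qaly = cost = deaths = new = 0.0
        for t in range(1, 11):
            new_flux = H * i                     # diagnosed during cycle t
            deaths += C * q                      # start-of-cycle CRC deaths
            C = C * (1 - q) * (1 - m) + new_flux * (1 - m)
            H = H * (1 - i) * (1 - m)
            d = (1 + r) ** (-t)
            new += new_flux
            cost += new_flux * c_crc * d
            qaly += (H * u_h + C * u_c) * d
        return qaly, cost, deaths, new

    def test_engine_matches_closed_form(self, params_flat):
        p = self._params(params_flat)
        out = run_cohort(p, StrategySpec("none"), "paper-10y")
        qaly, cost, deaths, new = self._oracle(p)
        assert out.per_capita_qaly == pytest.approx(qaly, abs=1e-9)
        assert out.per_capita_cost == pytest.approx(cost, abs=1e-9)
        assert out.cum_crc_deaths == pytest.approx(deaths * p.population,
                                                   abs=1e-9 * p.population)
        assert out.new_crc == pytest.approx(new * p.population,
                                            abs=1e-9 * p.population)


class TestResultsObject:
    def test_summary_mentions_strategy_and_counts(self, params):
        res = MarkovCohortModel(params, StrategySpec("colonoscopy", 0.203)).run()
        text = res.summary()
        assert "colonoscopy" in text
        assert "cum CRC deaths" in text
        assert f"{params.population:,}" in text

    def test_fit_alias(self, params):
        model = MarkovCohortModel(params, StrategySpec("none"))
        assert model.fit(trace=False).outputs == model.run(trace=False).outputs

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValidationError):
            StrategySpec("sigmoidoscopy", 0.5)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValidationError):
            HorizonSpec.preset("forever")
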