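"""Trajectory and cohort engine: ledgers, discounting, aggregation."""

import dataclasses
import math

import numpy as np
import pytest

from osteocea import run_cohort, simulate_individual, validate_no_intervention
from osteocea.engine import cycle_utility
from osteocea.natural_history import FractureHistory

HI = 0.999999  # scripted uniform that prevents an event
LO = 0.0       # scripted uniform that forces one


# --- cycle utility ---------------------------------------------------------


def test_utility_baseline_by_age_band(params):
    assert cycle_utility(72, False, False, FractureHistory(), False, params) == 0.810


def test_utility_first_year_hip_multiplier(params):
    hist = FractureHistory(n_hip=1, years_since_hip=0)
    u = cycle_utility(72, True, False, hist, False, params)
    assert u == pytest.approx(0.810 * 0.776)


def test_utility_lifelong_multipliers_combine(params):
    hist = FractureHistory(n_hip=1, n_vert=1, years_since_hip=3, years_since_vert=2)
    u = cycle_utility(86, False, False, hist, False, params)
    assert u == pytest.approx(0.684 * 0.855 * 0.868)


def test_death_cycle_contributes_zero_utility(params):
    assert cycle_utility(72, False, False, FractureHistory(), True, params) == 0.0


# --- scripted single trajectories -----------------------------------------


def test_teriparatide_first_year_costs(params, life_table, scripted_rng):
    # persist, no fracture, no death in cycle 0
    rng = scripted_rng([[LO, HI, HI, HI], [LO, HI, HI, LO]])
    ledgers = simulate_individual("sequential", 70, params, life_table, rng)
    led = ledgers[0]
    assert led.drug_cost == pytest.approx(333_400 * 0.702 + 1_100)
    assert led.visit_cost == 18_300 + 3 * 9_400
    assert led.test_cost == 2 * 2_900                    # no DXA in year 1
    assert led.fracture_medical_cost == 0 and led.ltc_cost == 0
    assert led.utility == 0.810


def test_dxa_charged_at_end_of_year_two(params, life_table, scripted_rng):
    rng = scripted_rng([[LO, HI, HI, HI], [LO, HI, HI, LO]])
    ledgers = simulate_individual("sequential", 70, params, life_table, rng)
    assert ledgers[1].test_cost == 2 * 2_900 + 4_500
    assert ledgers[1].drug_cost == pytest.approx(333_400 * 0.678 + 1_100)
    assert ledgers[1].visit_cost == 4 * 9_400            # first-visit fee already paid


def test_first_year_discontinuation_costs(params, life_table, scripted_rng):
    # u >= continuation prob -> discontinue in cycle 0: 3-month supply + one visit
    rng = scripted_rng([[HI, HI, HI, LO]])
    ledgers = simulate_individual("sequential", 70, params, life_table, rng)
    led = ledgers[0]
    assert led.drug_cost == pytest.approx(333_400 / 4)
    assert led.visit_cost == 18_300
    assert led.test_cost == 0


def test_sequential_switch_charges_alendronate_first_visit(params, life_table, scripted_rng):
    rows = [[LO, HI, HI, HI]] * 5 + [[LO, HI, HI, LO]]
    ledgers = simulate_individual("sequential", 70, params, life_table,
                                  scripted_rng(rows))
    led = ledgers[2]     # first alendronate year (strategy year 3)
    assert led.drug_cost == pytest.approx(8_700 * 0.706 + 1_700)
    assert led.visit_cost == 3_600 + 3 * 1_900
    # strategy year 5 = alendronate year 3: DXA due
    assert ledgers[4].test_cost == 2 * 2_900 + 4_500
    assert ledgers[3].test_cost == 2 * 2_900


def test_monotherapy_never_books_teriparatide_costs(params, life_table, scripted_rng):
    rows = [[LO, HI, HI, HI]] * 12
    ledgers = simulate_individual("alendronate_mono", 70, params, life_table,
                                  scripted_rng(rows))
    led = ledgers[0]
    assert led.drug_cost == pytest.approx(8_700 * 0.706 + 1_700)
    assert led.visit_cost == 3_600 + 3 * 1_900
    # after 10 years on drug, no further treatment costs (offset phase)
    assert ledgers[10].drug_cost == 0 and ledgers[10].visit_cost == 0
    assert ledgers[10].test_cost == 0


def test_hip_fracture_cycle_books_cost_and_half_ltc(params, life_table, scripted_rng):
    rng = scripted_rng([[HI, LO, HI, HI], [HI, HI, HI, LO]])
    ledgers = simulate_individual("no_intervention", 70, params, life_table, rng)
    assert ledgers[0].fracture_medical_cost == 1_726_000
    assert ledgers[0].ltc_cost == 876_000 / 2
    assert ledgers[0].utility == pytest.approx(0.810 * 0.776)
    # second post-hip year: full LTC, lifelong disutility multiplier
    assert ledgers[1].fracture_medical_cost == 0
    assert ledgers[1].ltc_cost == 876_000


def test_vertebral_fracture_costs_first_vs_subsequent(params, life_table, scripted_rng):
    rng = scripted_rng([[HI, HI, LO, HI], [HI, HI, LO, HI], [HI, HI, HI, LO]])
    ledgers = simulate_individual("no_intervention", 70, params, life_table, rng)
    assert ledgers[0].fracture_medical_cost == 420_000
    assert ledgers[0].ltc_cost == 213_000 / 2
    assert ledgers[1].fracture_medical_cost == 842_000
    assert ledgers[1].ltc_cost == 213_000


def test_hip_ltc_supersedes_vertebral_ltc(params, life_table, scripted_rng):
    rng = scripted_rng([[HI, HI, LO, HI], [HI, LO, HI, HI], [HI, HI, HI, LO]])
    ledgers = simulate_individual("no_intervention", 70, params, life_table, rng)
    assert ledgers[0].ltc_cost == 213_000 / 2
    assert ledgers[1].ltc_cost == 876_000 / 2   # first hip cycle: half hip LTC
    assert ledgers[2].ltc_cost == 876_000


def test_immediate_death_gives_single_cycle(params, life_table, scripted_rng):
    ledgers = simulate_individual("no_intervention", 70, params, life_table,
                                  scripted_rng([[HI, HI, HI, LO]]))
    assert len(ledgers) == 1
    assert ledgers[0].utility == 0.0


def test_off_treatment_no_fracture_ledger_is_all_zero(params, life_table, scripted_rng):
    rows = [[HI, HI, HI, HI]] * 3 + [[HI, HI, HI, LO]]
    ledgers = simulate_individual("no_intervention", 70, params, life_table,
                                  scripted_rng(rows))
    for led in ledgers[:3]:
        assert led.total_cost == 0
        assert led.utility == 0.810


# --- cohorts ---------------------------------------------------------------


def test_same_seed_is_bit_identical(params, life_table):
    a = run_cohort("sequential", 75, 300, 42, params, life_table)
    b = run_cohort("sequential", 75, 300, 42, params, life_table)
    assert dataclasses.asdict(a) == dataclasses.asdict(b)


def test_different_seed_differs(params, life_table):
    a = run_cohort("sequential", 75, 300, 42, params, life_table)
    b = run_cohort("sequential", 75, 300, 43, params, life_table)
    assert a.mean_qaly != b.mean_qaly


def test_cost_conservation_across_sectors(params, life_table):
    res = run_cohort("sequential", 80, 500, 7, params, life_table)
    rc = params.econ.discount_cost
    total = 0.0
    for i in range(500):
        rng = np.random.default_rng([7, i])
        ledgers = simulate_individual("sequential", 80, params, life_table, rng)
        total += sum(l.total_cost * (1 + rc) ** (-l.cycle_index) for l in ledgers)
    assert res.mean_cost_healthcare + res.mean_cost_ltc == pytest.approx(total / 500)


def test_qaly_bounded_by_discounted_baseline_annuity(params, life_table):
    rq = params.econ.discount_qaly
    for i in range(200):
        rng = np.random.default_rng([5, i])
        ledgers = simulate_individual("no_intervention", 70, params, life_table, rng)
        q = sum(l.utility * (1 + rq) ** (-l.cycle_index) for l in ledgers)
        bound = sum(params.utilities.baseline.lookup(70 + l.cycle_index)
                    * (1 + rq) ** (-l.cycle_index) for l in ledgers)
        assert q <= bound + 1e-9


def test_zero_incidence_matches_survival_annuity_oracle(params, life_table):
    """With no fractures the expected discounted QALY has a closed form:
    sum_t u(age+t) * P(alive through cycle t) * (1+r)^-t."""
    params.epidemiology.hip_rates = params.epidemiology.hip_rates.scaled(0.0)
    params.epidemiology.vert_rates = params.epidemiology.vert_rates.scaled(0.0)
    rq = params.econ.discount_qaly
    expected = 0.0
    for t in range(105 - 70):
        p_through = life_table.survival(70, 70 + t + 1)
        expected += params.utilities.baseline.lookup(70 + t) * p_through * (1 + rq) ** (-t)
    res = run_cohort("no_intervention", 70, 20_000, 11, params, life_table)
    assert res.lifetime_p_hip == 0.0 and res.lifetime_p_vert == 0.0
    assert abs(res.mean_qaly - expected) < 3 * res.se_qaly


def test_raising_incidence_raises_fracture_risk(params, life_table):
    lo = run_cohort("no_intervention", 70, 3_000, 9, params, life_table)
    params.epidemiology.hip_rates = params.epidemiology.hip_rates.scaled(1.5)
    params.epidemiology.vert_rates = params.epidemiology.vert_rates.scaled(1.5)
    hi = run_cohort("no_intervention", 70, 3_000, 9, params, life_table)
    assert hi.lifetime_p_hip >= lo.lifetime_p_hip
    assert hi.lifetime_p_vert >= lo.lifetime_p_vert


def test_validation_report_fields(params, life_table):
    rep = validate_no_intervention(75, 2_000, 21, params, life_table)
    assert set(rep) == {"start_age", "n", "p_dead_by_105",
                       "lifetime_p_hip", "lifetime_p_vert"}
    assert rep["p_dead_by_105"] > 0.99
    assert 0 < rep["lifetime_p_hip"] < 1
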