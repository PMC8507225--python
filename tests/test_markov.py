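"""Cohort engine: transitions, trace, accrual, and an independent oracle."""

import copy
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import asthma_cea as ac
from asthma_cea.markov import DEATH, EXAC_STATES, NONEXAC, ConfigurationError
from asthma_cea.parameters import ParameterError

from conftest import equal_arms_params, make_flat_life_table


# ---------------------------------------------------------------------------
# discounting and mortality building blocks
# ---------------------------------------------------------------------------

def test_discount_factor():
    assert ac.discount_factor(0, 0.015) == 1.0
    assert ac.discount_factor(52, 0.015) == pytest.approx(
        0.9852216748768474, abs=1e-12)
    assert ac.discount_factor(1234, 0.0) == 1.0
    with pytest.raises(ParameterError):
        ac.discount_factor(10, -1.0)
    with pytest.raises(ParameterError):
        ac.discount_factor(-1, 0.015)


def test_weekly_death_prob_additive_only_in_exacerbation(params):
    lt = make_flat_life_table(0.01, 0.03)
    bg = 0.5 * ac.annual_prob_to_weekly_prob(0.01) \
        + 0.5 * ac.annual_prob_to_weekly_prob(0.03)
    w_nonexac = ac.weekly_death_prob(41.0, 0.5, lt, NONEXAC, params.exac_types)
    assert w_nonexac == pytest.approx(bg, abs=1e-15)
    for state, t in zip(EXAC_STATES, params.exac_types):
        w = ac.weekly_death_prob(41.0, 0.5, lt, state, params.exac_types)
        assert w == pytest.approx(
            bg + ac.annual_prob_to_weekly_prob(t.annual_asthma_death_risk),
            abs=1e-15)


def test_weekly_death_prob_clamped_at_one(params):
    lt = make_flat_life_table(1.0, 1.0)
    assert ac.weekly_death_prob(41.0, 0.5, lt, NONEXAC,
                                params.exac_types) == 1.0


def test_life_table_age_clamp_warns(params, caplog):
    lt = make_flat_life_table(0.01, 0.01, max_age=60)
    with caplog.at_level("WARNING"):
        w = lt.weekly_background_prob(75.0, 0.5)
    assert w == pytest.approx(ac.annual_prob_to_weekly_prob(1.0))
    assert "terminal" in caplog.text


def test_life_table_rejects_bad_rows(tmp_path):
    path = tmp_path / "lt.csv"
    path.write_text("age,sex,qx\n0,F,0.001\n0,M,2.0\n")
    with pytest.raises(ParameterError, match="age 0"):
        ac.LifeTable.from_csv(path)
    path.write_text("age,sex,qx\n0,F,0.001\n0,X,0.001\n")
    with pytest.raises(ParameterError, match="sex"):
        ac.LifeTable.from_csv(path)


# ---------------------------------------------------------------------------
# transition structure
# ---------------------------------------------------------------------------

def test_transition_matrix_base_structure(params, zero_mortality_table):
    cfg = ac.RunConfig()
    P = ac.build_cycle_transition(params.intervention, params, cfg, 41.0,
                                  zero_mortality_table)
    expected_row = np.array([
        0.9978868512338127, 0.00173066883950739, 0.0002155411741511035,
        0.00016693875252879586, 0.0])
    # splitting p_exac = 1 - exp(-0.11/52) over the type shares
    assert P[0] == pytest.approx(expected_row, abs=1e-12)
    np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
    assert P[-1, -1] == 1.0 and P[-1, :-1].sum() == 0.0  # death absorbing
    # exacerbation states are transient: survivors return to NONEXAC
    for i in range(1, 4):
        assert P[i, 0] + P[i, -1] == pytest.approx(1.0, abs=1e-15)


def test_transition_identity_when_nothing_happens(zero_mortality_table):
    p = equal_arms_params()
    p.intervention.annual_severe_exac_rate = 0.0
    cfg = ac.RunConfig()
    P = ac.build_cycle_transition(p.intervention, p, cfg, 41.0,
                                  zero_mortality_table)
    assert P[0, 0] == 1.0


@given(seed=st.integers(0, 10_000), age=st.floats(0, 109),
       withdrawal=st.booleans(), moderate=st.booleans())
def test_transition_rows_stochastic_for_random_parameters(
        seed, age, withdrawal, moderate):
    p = ac.generate_random_parameter_set(seed)
    lt = make_flat_life_table(0.02, 0.04)
    cfg = ac.RunConfig(include_withdrawal=withdrawal,
                       include_moderate=moderate)
    for arm in (p.intervention, p.comparator):
        P = ac.build_cycle_transition(arm, p, cfg, age, lt)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(P >= 0)


def test_variant_flags_require_their_parameters(params):
    params.economics.stepup_daily_drug_cost = None
    with pytest.raises(ConfigurationError, match="stepup"):
        ac.apply_structure_variant(ac.RunConfig(include_withdrawal=True),
                                   params)
    params2 = ac.default_parameter_set()
    params2.intervention.annual_moderate_exac_rate = None
    with pytest.raises(ConfigurationError, match="moderate"):
        ac.apply_structure_variant(ac.RunConfig(include_moderate=True),
                                   params2)


# ---------------------------------------------------------------------------
# cohort trace
# ---------------------------------------------------------------------------

def test_cohort_stays_put_without_events(zero_mortality_table):
    p = equal_arms_params()
    p.intervention.annual_severe_exac_rate = 0.0
    cfg = ac.RunConfig(horizon_years=1.0)
    trace = ac.run_cohort(p.intervention, p, cfg, zero_mortality_table)
    assert np.all(trace.occupancy[:, 0] == 1.0)


def test_occupancy_conservation_over_full_horizon(params, life_table):
    cfg = ac.RunConfig()
    trace = ac.run_cohort(params.intervention, params, cfg, life_table)
    assert trace.occupancy.shape == (2601, 5)
    np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
    alive = trace.alive()
    assert np.all(np.diff(alive) <= 1e-15)
    assert alive[-1] < alive[0]
    trace.validate()


def test_conservation_with_structural_variants(params, life_table):
    cfg = ac.RunConfig(horizon_years=5.0, include_withdrawal=True,
                       include_moderate=True)
    trace = ac.run_cohort(params.intervention, params, cfg, life_table)
    assert trace.occupancy.shape[1] == 7
    np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
    # withdrawal state fills up and never empties back into NONEXAC
    wd = trace.occupancy[:, trace.state_index("WITHDRAWN")]
    assert wd[-1] > 0
    assert np.all(np.diff(wd) >= -1e-12)


# ---------------------------------------------------------------------------
# independent brute-force oracle
# ---------------------------------------------------------------------------

def _brute_force(arm, params, cfg, qf, qm):
    """Scalar re-implementation of trace + accrual from the stated rules.

    Pure-python floats, explicit per-state bookkeeping, no numpy, no shared
    code with the engine beyond the input objects.
    """
    cpy = cfg.cycles_per_year
    n = int(round(cfg.horizon_years * cpy))
    econ = params.economics
    u = econ.nonexac_utility

    def wk(p):
        return 1.0 - (1.0 - p) ** (1.0 / cpy)

    state = {"nonexac": 1.0, "e0": 0.0, "e1": 0.0, "e2": 0.0,
             "wd": 0.0, "mod": 0.0, "dead": 0.0}
    drug_day = sum(r.cost_per_inhaler / r.inhalations_per_inhaler
                   * r.inhalations_per_day * r.utilization_fraction
                   for r in arm.regimens)
    ae_cost_cycle = sum(a.annual_proportion / cpy * a.cost_per_event
                        for a in arm.adverse_events)
    totals = {"drugs": 0.0, "nonexac": 0.0, "severe_exac": 0.0,
              "adverse_events": 0.0, "moderate_exac": 0.0, "withdrawal": 0.0,
              "societal": 0.0, "qaly": 0.0}
    occupancy = [dict(state)]
    for t in range(n):
        age = cfg.start_age + t / cpy
        vc = (1.0 + cfg.discount_rate_costs) ** (-t / cpy)
        vo = (1.0 + cfg.discount_rate_outcomes) ** (-t / cpy)
        alive = 1.0 - state["dead"]
        on_rx = alive - state["wd"]
        totals["drugs"] += on_rx * drug_day * 7.0 * vc
        if econ.nonexac_cost_basis == "per_year":
            monitor = econ.nonexac_state_cost / cpy
        else:
            monitor = econ.nonexac_state_cost * 52.0 / cpy
        totals["nonexac"] += alive * monitor * vc
        for key, tp in zip(("e0", "e1", "e2"), params.exac_types):
            totals["severe_exac"] += state[key] * tp.direct_cost_per_event * vc
        if cfg.include_AEs:
            totals["adverse_events"] += state["nonexac"] * ae_cost_cycle * vc
        if cfg.include_moderate:
            totals["moderate_exac"] += (state["mod"] * econ.moderate_exac_cost
                                        * vc)
        if cfg.include_withdrawal:
            totals["withdrawal"] += (state["wd"] * econ.stepup_daily_drug_cost
                                     * 7.0 * vc)
        if cfg.perspective == "societal":
            totals["societal"] += (alive * econ.productivity_days_lost_per_year
                                   / cpy * econ.daily_wage * vc)
        q = state["nonexac"] * u + state["wd"] * u
        for key, tp in zip(("e0", "e1", "e2"), params.exac_types):
            q += state[key] * (u + tp.disutility)
        if cfg.include_moderate:
            q += state["mod"] * (u + econ.moderate_exac_disutility)
        totals["qaly"] += q / cpy * vo

        # transition
        a = int(math.floor(age))
        bg = 0.5 * wk(qf[a]) + 0.5 * wk(qm[a]) if cfg.sex_mix == 0.5 else (
            cfg.sex_mix * wk(qf[a]) + (1 - cfg.sex_mix) * wk(qm[a]))
        p_ex = 1.0 - math.exp(-arm.annual_severe_exac_rate / cpy)
        p_wd = wk(arm.annual_withdrawal_risk) if cfg.include_withdrawal else 0.0
        p_mod = (1.0 - math.exp(-arm.annual_moderate_exac_rate / cpy)
                 if cfg.include_moderate else 0.0)
        new = {k: 0.0 for k in state}
        stay = 1.0 - bg - p_wd - p_mod - p_ex * sum(arm.exac_type_shares)
        new["nonexac"] = state["nonexac"] * stay
        new["dead"] = state["dead"] + state["nonexac"] * bg
        for key, share, tp in zip(("e0", "e1", "e2"), arm.exac_type_shares,
                                  params.exac_types):
            new[key] = state["nonexac"] * p_ex * share
            p_die = min(bg + wk(tp.annual_asthma_death_risk), 1.0)
            new["dead"] += state[key] * p_die
            new["nonexac"] += state[key] * (1.0 - p_die)
        # withdrawal/moderate inflows come from the *old* nonexac occupancy
        new["wd"] = state["wd"] * (1.0 - bg) + state["nonexac"] * p_wd
        new["dead"] += state["wd"] * bg
        new["mod"] = state["nonexac"] * p_mod
        new["dead"] += state["mod"] * bg
        new["nonexac"] += state["mod"] * (1.0 - bg)
        state = new
        occupancy.append(dict(state))
    return totals, occupancy


def _toy_params():
    p = ac.default_parameter_set()
    p.distribution_specs = []
    p.dsa_ranges = {}
    # exaggerated rates so every pathway is exercised within 20 cycles
    p.intervention.annual_severe_exac_rate = 2.0
    p.intervention.annual_moderate_exac_rate = 1.5
    p.intervention.annual_withdrawal_risk = 0.3
    for t, risk in zip(p.exac_types, (0.1, 0.3, 0.6)):
        t.annual_asthma_death_risk = risk
    return p


@pytest.mark.parametrize("variant", ["base", "variants", "societal_per_week"])
def test_engine_matches_scalar_oracle(variant):
    p = _toy_params()
    kw = dict(horizon_years=20 / 52, start_age=64.9)  # crosses an integer age
    if variant == "variants":
        kw.update(include_withdrawal=True, include_moderate=True)
    if variant == "societal_per_week":
        kw.update(perspective="societal")
        p.economics.nonexac_cost_basis = "per_week"
    cfg = ac.RunConfig(**kw)
    qf, qm = [0.05 + 0.001 * a for a in range(111)], \
             [0.07 + 0.001 * a for a in range(111)]
    qf = [min(q, 1.0) for q in qf]
    qm = [min(q, 1.0) for q in qm]
    lt = ac.LifeTable(np.arange(111), np.array(qf), np.array(qm))

    outcome = ac.run_arm(p.intervention, p, cfg, lt, keep_trace=True)
    expected_totals, expected_occ = _brute_force(p.intervention, p, cfg, qf, qm)

    state_keys = {"NONEXAC": "nonexac", "EXAC_SCS": "e0", "EXAC_ED_SCS": "e1",
                  "EXAC_INPATIENT": "e2", "WITHDRAWN": "wd",
                  "MODERATE_EXAC": "mod", "DEATH": "dead"}
    for t, row in enumerate(expected_occ):
        for s in outcome.trace.states:
            got = outcome.trace.occupancy[t, outcome.trace.state_index(s)]
            assert got == pytest.approx(row[state_keys[s]], abs=1e-12), \
                f"cycle {t} state {s}"
    for cat in ac.markov.COST_CATEGORIES:
        assert outcome.cost_categories[cat] == pytest.approx(
            expected_totals[cat], abs=1e-12), cat
    assert outcome.total_qaly == pytest.approx(expected_totals["qaly"],
                                               abs=1e-12)


# ---------------------------------------------------------------------------
# accrual properties
# ---------------------------------------------------------------------------

def test_one_undiscounted_year_at_full_utility(zero_mortality_table):
    p = equal_arms_params()
    p.intervention.annual_severe_exac_rate = 0.0
    cfg = ac.RunConfig(horizon_years=1.0, discount_rate_costs=0.0,
                       discount_rate_outcomes=0.0)
    out = ac.run_arm(p.intervention, p, cfg, zero_mortality_table)
    assert out.total_qaly == pytest.approx(0.867, abs=1e-12)


def test_discounting_is_a_pure_per_cycle_factor(params, life_table):
    cfg0 = ac.RunConfig(horizon_years=2.0, discount_rate_costs=0.0,
                        discount_rate_outcomes=0.0)
    cfg = ac.RunConfig(horizon_years=2.0)
    out0 = ac.run_arm(params.intervention, params, cfg0, life_table)
    out = ac.run_arm(params.intervention, params, cfg, life_table)
    t = np.arange(cfg.n_cycles)
    vc = 1.015 ** (-t / 52)
    for cat in ("drugs", "nonexac", "severe_exac", "adverse_events"):
        np.testing.assert_allclose(out.streams[cat] / vc, out0.streams[cat],
                                   rtol=1e-9)
    # zero-discount totals equal plain stream sums
    for cat, total in out0.cost_categories.items():
        assert total == pytest.approx(float(out0.streams[cat].sum()), abs=1e-9)


def test_severe_exac_category_tracks_closed_form(params, zero_mortality_table):
    """With no mortality/discounting the category is rate x event cost x years."""
    cfg = ac.RunConfig(horizon_years=10.0, discount_rate_costs=0.0,
                       discount_rate_outcomes=0.0)
    out = ac.run_arm(params.intervention, params, cfg, zero_mortality_table)
    rate_weekly = ac.annual_rate_to_weekly_prob(0.11) * 52
    expected = rate_weekly * 919.71754 * 10.0
    assert out.cost_categories["severe_exac"] == pytest.approx(expected,
                                                               rel=5e-3)


def test_adverse_events_zero_when_disabled(params, life_table):
    cfg = ac.RunConfig(horizon_years=2.0, include_AEs=False)
    out = ac.run_arm(params.intervention, params, cfg, life_table)
    assert out.cost_categories["adverse_events"] == 0.0
    assert out.qaly_categories["adverse_events"] == 0.0


def test_horizon_additivity(params, life_table):
    cfg2 = ac.RunConfig(horizon_years=2.0)
    cfg50 = ac.RunConfig(horizon_years=50.0)
    out2 = ac.run_arm(params.intervention, params, cfg2, life_table)
    out50 = ac.run_arm(params.intervention, params, cfg50, life_table)
    for cat in ("drugs", "nonexac", "severe_exac", "adverse_events", "qaly"):
        assert float(out2.streams[cat].sum()) == pytest.approx(
            float(out50.streams[cat][:104].sum()), abs=1e-12)


def test_equal_arms_give_exactly_zero_increments(life_table):
    p = equal_arms_params()
    res = ac.evaluate(p, ac.RunConfig(), life_table)
    assert res.incremental_cost == 0.0
    assert res.incremental_qaly == 0.0
    assert res.label == "tie"


def test_qaly_monotone_in_disutility_and_rate(life_table):
    cfg = ac.RunConfig(horizon_years=5.0)
    base = ac.default_parameter_set()
    out = ac.run_arm(base.intervention, base, cfg, life_table)

    worse = ac.default_parameter_set()
    for t in worse.exac_types:
        t.disutility *= 2
    out_worse = ac.run_arm(worse.intervention, worse, cfg, life_table)
    assert out_worse.total_qaly < out.total_qaly

    faster = ac.default_parameter_set()
    faster.intervention.annual_severe_exac_rate = 0.5
    out_faster = ac.run_arm(faster.intervention, faster, cfg, life_table)
    assert out_faster.total_qaly < out.total_qaly


def test_half_cycle_correction_flag(params, life_table):
    cfg = ac.RunConfig(horizon_years=2.0, half_cycle_correction=True)
    out_hc = ac.run_arm(params.intervention, params, cfg, life_table)
    out = ac.run_arm(params.intervention, params,
                     ac.RunConfig(horizon_years=2.0), life_table)
    assert out_hc.total_cost != out.total_cost
    assert abs(out_hc.total_cost - out.total_cost) < 0.01 * out.total_cost


def test_withdrawal_risk_zero_reproduces_base_structure(params, life_table):
    """Enabling the withdrawal state with zero risk changes nothing."""
    p = copy.deepcopy(params)
    p.intervention.annual_withdrawal_risk = 0.0
    cfg_v = ac.RunConfig(horizon_years=3.0, include_withdrawal=True)
    cfg_b = ac.RunConfig(horizon_years=3.0)
    out_v = ac.run_arm(p.intervention, p, cfg_v, life_table)
    out_b = ac.run_arm(p.intervention, p, cfg_b, life_table)
    assert out_v.total_cost == pytest.approx(out_b.total_cost, abs=1e-9)
    assert out_v.total_qaly == pytest.approx(out_b.total_qaly, abs=1e-12)
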