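"""Markov cohort engine: states, transitions, trace, and outcome accrual.

The model runs a cohort of mild-asthma patients through weekly cycles over a
long horizon (default 50 years = 2600 cycles).  Health states:

* ``NONEXAC`` — the non-exacerbation state every patient starts in;
* ``EXAC_SCS`` / ``EXAC_ED_SCS`` / ``EXAC_INPATIENT`` — transient severe
  exacerbation states, one per management type; occupancy lasts exactly one
  cycle, after which survivors return to ``NONEXAC``;
* ``DEATH`` — absorbing;
* optionally ``WITHDRAWN`` (treatment-withdrawal variant, absorbing except to
  death) and ``MODERATE_EXAC`` (moderate-exacerbation variant, transient).

Mortality combines age- and sex-specific background risk from a life table
with an asthma-related risk that applies only while in an exacerbation state.
Costs and QALYs are accrued per cycle on start-of-cycle occupancy and
discounted at an annual rate compounded per cycle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .parameters import (
    EXAC_LABELS,
    ParameterError,
    ParameterSet,
    TreatmentArm,
    annual_prob_to_weekly_prob,
    annual_rate_to_weekly_prob,
    arm_drug_cost_per_day,
    weekly_ae_cost,
    weekly_ae_disutility,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NONEXAC", "EXAC_STATES", "DEATH", "WITHDRAWN", "MODERATE_EXAC",
    "ConfigurationError", "RunConfig", "LifeTable", "CohortTrace",
    "ArmOutcome", "state_space", "apply_structure_variant", "discount_factor",
    "weekly_death_prob", "build_cycle_transition", "run_cohort",
    "accrue_outcomes", "run_arm",
    "COST_CATEGORIES", "QALY_CATEGORIES",
]

NONEXAC = "NONEXAC"
EXAC_STATES = ("EXAC_SCS", "EXAC_ED_SCS", "EXAC_INPATIENT")
WITHDRAWN = "WITHDRAWN"
MODERATE_EXAC = "MODERATE_EXAC"
DEATH = "DEATH"

COST_CATEGORIES = ("nonexac", "severe_exac", "drugs", "adverse_events",
                   "moderate_exac", "withdrawal", "societal")
QALY_CATEGORIES = ("nonexac", "severe_exac", "adverse_events",
                   "moderate_exac", "withdrawal")


class ConfigurationError(ValueError):
    """A run configuration inconsistent with the supplied parameters."""


@dataclass(frozen=True)
class RunConfig:
    """Run configuration.

    Defaults follow the published base case: 50-year horizon, weekly cycles,
    1.5 %/year discounting of both costs and outcomes, cohort starting age
    41, public-payer perspective, adverse events included, no structural
    variants, no half-cycle correction.  The cohort is modelled as a
    sex-mix-weighted average (default 50 % female; the source trials do not
    report the mix).
    """

    horizon_years: float = 50.0
    cycles_per_year: int = 52
    discount_rate_costs: float = 0.015
    discount_rate_outcomes: float = 0.015
    start_age: float = 41.0
    sex_mix: float = 0.5            # proportion female
    perspective: str = "public_payer"  # or "societal"
    include_AEs: bool = True
    include_moderate: bool = False
    include_withdrawal: bool = False
    half_cycle_correction: bool = False

    def __post_init__(self):
        if self.horizon_years <= 0:
            raise ConfigurationError("horizon_years must be positive")
        if self.cycles_per_year < 1:
            raise ConfigurationError("cycles_per_year must be >= 1")
        if self.discount_rate_costs < 0 or self.discount_rate_outcomes < 0:
            raise ConfigurationError("discount rates must be >= 0")
        if not 0.0 <= self.sex_mix <= 1.0:
            raise ConfigurationError("sex_mix must be in [0, 1]")
        if self.perspective not in ("public_payer", "societal"):
            raise ConfigurationError(
                "perspective must be 'public_payer' or 'societal'")

    @property
    def n_cycles(self) -> int:
        return int(round(self.horizon_years * self.cycles_per_year))


# ---------------------------------------------------------------------------
# Life table
# ---------------------------------------------------------------------------

class LifeTable:
    """Age- and sex-indexed annual background death probabilities.

    Ages must be contiguous from 0 to a terminal age; ``qx`` in [0, 1].
    File format: delimited text with header ``age,sex,qx``; ``sex`` in
    {``F``, ``M``}.
    """

    def __init__(self, ages, qx_female, qx_male):
        self.ages = np.asarray(ages, dtype=int)
        self.qx_female = np.asarray(qx_female, dtype=float)
        self.qx_male = np.asarray(qx_male, dtype=float)
        self._warned_age_clamp = False
        if len(self.ages) == 0:
            raise ParameterError("life table is empty")
        if self.ages[0] != 0 or not np.all(np.diff(self.ages) == 1):
            raise ParameterError("life-table ages must be contiguous from 0")
        for sex, qx in (("F", self.qx_female), ("M", self.qx_male)):
            if len(qx) != len(self.ages):
                raise ParameterError(f"life table sex {sex}: wrong length")
            bad = np.where((qx < 0) | (qx > 1))[0]
            if bad.size:
                raise ParameterError(
                    f"life table sex {sex}, age {self.ages[bad[0]]}: "
                    f"qx {qx[bad[0]]!r} outside [0, 1]")

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LifeTable":
        missing = {"age", "sex", "qx"} - set(df.columns)
        if missing:
            raise ParameterError(
                f"life table missing column(s): {sorted(missing)}")
        bad_sex = df.loc[~df["sex"].isin(["F", "M"])]
        if len(bad_sex):
            row = bad_sex.iloc[0]
            raise ParameterError(
                f"life table row with age {row['age']!r}: sex must be 'F' or "
                f"'M' (got {row['sex']!r})")
        wide = df.pivot(index="age", columns="sex", values="qx").sort_index()
        if wide.isna().any().any():
            age = wide[wide.isna().any(axis=1)].index[0]
            raise ParameterError(f"life table age {age}: missing F or M row")
        return cls(wide.index.to_numpy(), wide["F"].to_numpy(),
                   wide["M"].to_numpy())

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        try:
            df = pd.read_csv(path)
        except Exception as exc:
            raise ParameterError(f"cannot read life table {path!r}: {exc}")
        return cls.from_frame(df)

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([
            pd.DataFrame({"age": self.ages, "sex": "F", "qx": self.qx_female}),
            pd.DataFrame({"age": self.ages, "sex": "M", "qx": self.qx_male}),
        ], ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def _row(self, age: float) -> int:
        a = int(math.floor(age))
        if a > self.max_age:
            if not self._warned_age_clamp:
                logger.warning(
                    "age %.1f beyond life-table terminal age %d; using the "
                    "terminal row", age, self.max_age)
                self._warned_age_clamp = True
            a = self.max_age
        return max(a, 0)

    def annual_qx(self, age: float, sex: str) -> float:
        a = self._row(age)
        return float((self.qx_female if sex == "F" else self.qx_male)[a])

    def weekly_background_prob(self, age: float, sex_mix: float,
                               cycles_per_year: int = 52) -> float:
        """Sex-mix-weighted per-cycle background death probability."""
        a = self._row(age)
        wf = annual_prob_to_weekly_prob(float(self.qx_female[a]),
                                        cycles_per_year)
        wm = annual_prob_to_weekly_prob(float(self.qx_male[a]),
                                        cycles_per_year)
        return sex_mix * wf + (1.0 - sex_mix) * wm


# ---------------------------------------------------------------------------
# State space and transitions
# ---------------------------------------------------------------------------

def state_space(config: RunConfig) -> list[str]:
    """Ordered state names for a configuration (``DEATH`` last)."""
    states = [NONEXAC, *EXAC_STATES]
    if config.include_withdrawal:
        states.append(WITHDRAWN)
    if config.include_moderate:
        states.append(MODERATE_EXAC)
    states.append(DEATH)
    return states


def apply_structure_variant(config: RunConfig, params: ParameterSet,
                            ) -> list[str]:
    """Validate variant flags against the parameters; return the state list.

    Raises :class:`ConfigurationError` when a structural variant is enabled
    without the optional parameters it needs.
    """
    if config.include_withdrawal:
        for arm in (params.intervention, params.comparator):
            if arm.annual_withdrawal_risk is None:
                raise ConfigurationError(
                    f"withdrawal variant enabled but arm {arm.name!r} has no "
                    "annual_withdrawal_risk")
        if params.economics.stepup_daily_drug_cost is None:
            raise ConfigurationError(
                "withdrawal variant enabled but economics.stepup_daily_drug_"
                "cost is unset")
    if config.include_moderate:
        for arm in (params.intervention, params.comparator):
            if arm.annual_moderate_exac_rate is None:
                raise ConfigurationError(
                    f"moderate-exacerbation variant enabled but arm "
                    f"{arm.name!r} has no annual_moderate_exac_rate")
        if params.economics.moderate_exac_cost is None:
            raise ConfigurationError(
                "moderate-exacerbation variant enabled but economics."
                "moderate_exac_cost is unset")
        if params.economics.moderate_exac_disutility is None:
            raise ConfigurationError(
                "moderate-exacerbation variant enabled but economics."
                "moderate_exac_disutility is unset")
    return state_space(config)


def discount_factor(cycle_index: int, annual_rate: float,
                    cycles_per_year: int = 52) -> float:
    """``(1 + rate) ** (-cycle_index / cycles_per_year)``; 1 at cycle 0."""
    if annual_rate <= -1:
        raise ParameterError("annual_rate must be > -1")
    if cycle_index < 0:
        raise ParameterError("cycle_index must be >= 0")
    return (1.0 + annual_rate) ** (-cycle_index / cycles_per_year)


def weekly_death_prob(age: float, sex_mix: float, life_table: LifeTable,
                      state: str, exac_types,
                      cycles_per_year: int = 52) -> float:
    """Per-cycle death probability in a given state.

    Background mortality applies everywhere; while in an exacerbation state
    the weekly-converted annual asthma-death risk of that type is added
    (asthma-related death can only occur from an exacerbation state).  The
    result is clamped to <= 1.
    """
    bg = life_table.weekly_background_prob(age, sex_mix, cycles_per_year)
    if state in EXAC_STATES:
        t = exac_types[EXAC_STATES.index(state)]
        bg += annual_prob_to_weekly_prob(t.annual_asthma_death_risk,
                                         cycles_per_year)
    return min(bg, 1.0)


def build_cycle_transition(arm: TreatmentArm, params: ParameterSet,
                           config: RunConfig, age: float,
                           life_table: LifeTable) -> np.ndarray:
    """Row-stochastic one-cycle transition matrix at a given age.

    From ``NONEXAC``: to each exacerbation sub-state with probability
    ``p_exac * share_i`` (``p_exac = 1 - exp(-rate/52)``), to death with the
    background weekly probability, optionally to the withdrawal or moderate
    state, remainder stays.  From an exacerbation sub-state: to death with
    background plus asthma-related weekly probability, remainder back to
    ``NONEXAC`` (exacerbation states are transient — no
    exacerbation-to-exacerbation persistence).  ``DEATH`` is absorbing.
    """
    states = state_space(config)
    idx = {s: i for i, s in enumerate(states)}
    n = len(states)
    cpy = config.cycles_per_year
    P = np.zeros((n, n))

    bg = life_table.weekly_background_prob(age, config.sex_mix, cpy)
    p_exac = annual_rate_to_weekly_prob(arm.annual_severe_exac_rate, cpy)

    i0 = idx[NONEXAC]
    row_used = bg
    P[i0, idx[DEATH]] = bg
    for share, s in zip(arm.exac_type_shares, EXAC_STATES):
        P[i0, idx[s]] = p_exac * share
        row_used += p_exac * share
    if config.include_withdrawal:
        p_wd = annual_prob_to_weekly_prob(arm.annual_withdrawal_risk, cpy)
        P[i0, idx[WITHDRAWN]] = p_wd
        row_used += p_wd
    if config.include_moderate:
        p_mod = annual_rate_to_weekly_prob(arm.annual_moderate_exac_rate, cpy)
        P[i0, idx[MODERATE_EXAC]] = p_mod
        row_used += p_mod
    P[i0, i0] = 1.0 - row_used

    for s in EXAC_STATES:
        p_die = weekly_death_prob(age, config.sex_mix, life_table, s,
                                  params.exac_types, cpy)
        P[idx[s], idx[DEATH]] = p_die
        P[idx[s], i0] = 1.0 - p_die
    if config.include_withdrawal:
        P[idx[WITHDRAWN], idx[DEATH]] = bg
        P[idx[WITHDRAWN], idx[WITHDRAWN]] = 1.0 - bg
    if config.include_moderate:
        P[idx[MODERATE_EXAC], idx[DEATH]] = bg
        P[idx[MODERATE_EXAC], i0] = 1.0 - bg
    P[idx[DEATH], idx[DEATH]] = 1.0

    rowsums = P.sum(axis=1)
    if np.any(np.abs(rowsums - 1.0) > 1e-9) or np.any(P < -1e-15):
        raise RuntimeError(
            f"internal error: transition rows not stochastic (sums {rowsums})")
    return P


# ---------------------------------------------------------------------------
# Cohort trace
# ---------------------------------------------------------------------------

@dataclass
class CohortTrace:
    """Per-cycle state occupancy for one arm.

    ``occupancy`` has ``n_cycles + 1`` rows: row ``t`` is the occupancy at
    the *start* of cycle ``t`` (row 0 = everyone in ``NONEXAC``).
    """

    states: list[str]
    occupancy: np.ndarray
    ages: np.ndarray            # age at the start of each cycle, length n_cycles
    config: RunConfig

    def state_index(self, state: str) -> int:
        return self.states.index(state)

    def alive(self) -> np.ndarray:
        return 1.0 - self.occupancy[:, self.state_index(DEATH)]

    def validate(self, tol: float = 1e-9) -> None:
        rows = self.occupancy.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > tol):
            raise RuntimeError("occupancy rows do not sum to 1")
        alive = self.alive()
        if np.any(np.diff(alive) > tol):
            raise RuntimeError("alive fraction increased over a cycle")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=self.states)
        df.insert(0, "cycle", np.arange(len(df)))
        return df


def run_cohort(arm: TreatmentArm, params: ParameterSet, config: RunConfig,
               life_table: LifeTable) -> CohortTrace:
    """Run the cohort trace: everyone starts in ``NONEXAC`` at ``start_age``.

    Age advances by one cycle length per cycle; the transition matrix is
    rebuilt whenever the integer age increments (the life-table row and hence
    background mortality change at integer ages).
    """
    states = apply_structure_variant(config, params)
    n = config.n_cycles
    cpy = config.cycles_per_year
    S = len(states)
    occ = np.zeros((n + 1, S))
    occ[0, 0] = 1.0
    ages = config.start_age + np.arange(n) / cpy

    P = None
    current_int_age = None
    for t in range(n):
        ia = int(math.floor(ages[t]))
        if ia != current_int_age:
            P = build_cycle_transition(arm, params, config, ages[t],
                                       life_table)
            current_int_age = ia
        occ[t + 1] = occ[t] @ P
    return CohortTrace(states=states, occupancy=occ, ages=ages, config=config)


# ---------------------------------------------------------------------------
# Outcome accrual
# ---------------------------------------------------------------------------

@dataclass
class ArmOutcome:
    """Discounted per-category cost and QALY totals for one arm.

    ``streams`` holds the per-cycle discounted accrual of every cost category
    plus ``qaly``, so report tables are re-derivable from the exported
    per-cycle data and horizon additivity can be checked directly.
    """

    arm_name: str
    config: RunConfig
    cost_categories: dict[str, float]
    qaly_categories: dict[str, float]
    streams: dict[str, np.ndarray]
    life_years_discounted: float
    trace: CohortTrace | None = None

    @property
    def total_cost(self) -> float:
        return float(sum(self.cost_categories.values()))

    @property
    def total_qaly(self) -> float:
        return float(sum(self.qaly_categories.values()))


def accrue_outcomes(trace: CohortTrace, arm: TreatmentArm,
                    params: ParameterSet, config: RunConfig,
                    keep_trace: bool = False) -> ArmOutcome:
    """Accrue discounted per-category costs and QALYs over a cohort trace.

    Per cycle (start-of-cycle occupancy, discount ``(1+r)^(-t/52)``):

    * drugs: on-treatment alive occupancy × per-day drug cost × 7;
    * non-exacerbation monitoring: all alive occupancy (exacerbating
      patients still incur weekly monitoring) × per-cycle monitoring cost;
    * severe exacerbations: per-type occupancy × direct event cost;
    * adverse events: ``NONEXAC`` occupancy × expected per-cycle AE cost
      (AEs apply only to the non-exacerbation state);
    * moderate exacerbations / withdrawal step-up drugs: variant occupancies;
    * societal: all alive occupancy × productivity loss (societal
      perspective only);
    * QALYs: utility-weighted occupancy / 52, with per-type disutilities in
      exacerbation cycles and (zero by default) AE disutilities in
      ``NONEXAC``.
    """
    states = trace.states
    idx = {s: i for i, s in enumerate(states)}
    n = config.n_cycles
    cpy = config.cycles_per_year
    econ = params.economics

    if config.half_cycle_correction:
        occ = 0.5 * (trace.occupancy[:n] + trace.occupancy[1:n + 1])
    else:
        occ = trace.occupancy[:n]

    t = np.arange(n)
    vc = (1.0 + config.discount_rate_costs) ** (-t / cpy)
    vo = (1.0 + config.discount_rate_outcomes) ** (-t / cpy)

    alive = 1.0 - occ[:, idx[DEATH]]
    nonexac_occ = occ[:, idx[NONEXAC]]
    exac_occ = occ[:, [idx[s] for s in EXAC_STATES]]
    withdrawn_occ = (occ[:, idx[WITHDRAWN]]
                     if config.include_withdrawal else np.zeros(n))
    moderate_occ = (occ[:, idx[MODERATE_EXAC]]
                    if config.include_moderate else np.zeros(n))

    streams: dict[str, np.ndarray] = {}
    drug_day = arm_drug_cost_per_day(arm)
    on_treatment = alive - withdrawn_occ
    streams["drugs"] = on_treatment * drug_day * 7.0 * vc
    streams["nonexac"] = alive * econ.nonexac_cost_per_cycle(cpy) * vc
    exac_costs = np.array([tp.direct_cost_per_event
                           for tp in params.exac_types])
    streams["severe_exac"] = (exac_occ @ exac_costs) * vc
    if config.include_AEs:
        streams["adverse_events"] = nonexac_occ * weekly_ae_cost(arm, cpy) * vc
    else:
        streams["adverse_events"] = np.zeros(n)
    if config.include_moderate:
        streams["moderate_exac"] = moderate_occ * econ.moderate_exac_cost * vc
    else:
        streams["moderate_exac"] = np.zeros(n)
    if config.include_withdrawal:
        streams["withdrawal"] = (withdrawn_occ * econ.stepup_daily_drug_cost
                                 * 7.0 * vc)
    else:
        streams["withdrawal"] = np.zeros(n)
    if config.perspective == "societal":
        streams["societal"] = (alive * econ.productivity_days_lost_per_year
                               / cpy * econ.daily_wage * vc)
    else:
        streams["societal"] = np.zeros(n)

    u = econ.nonexac_utility
    exac_du = np.array([tp.disutility for tp in params.exac_types])
    ae_du = weekly_ae_disutility(arm, cpy) if config.include_AEs else 0.0
    qaly_streams = {
        "nonexac": (nonexac_occ * u + withdrawn_occ * u) / cpy * vo,
        "severe_exac": (exac_occ @ (u + exac_du)) / cpy * vo,
        "adverse_events": nonexac_occ * ae_du / cpy * vo,
        "moderate_exac": (moderate_occ
                          * (u + (econ.moderate_exac_disutility or 0.0))
                          / cpy * vo),
        "withdrawal": np.zeros(n),  # withdrawn patients accrue u (in nonexac)
    }
    streams["qaly"] = sum(qaly_streams.values())

    cost_categories = {c: float(streams[c].sum()) for c in COST_CATEGORIES}
    qaly_categories = {c: float(qaly_streams[c].sum())
                       for c in QALY_CATEGORIES}
    return ArmOutcome(
        arm_name=arm.name,
        config=config,
        cost_categories=cost_categories,
        qaly_categories=qaly_categories,
        streams=streams,
        life_years_discounted=float((alive * vo).sum() / cpy),
        trace=trace if keep_trace else None,
    )


def run_arm(arm: TreatmentArm, params: ParameterSet, config: RunConfig,
            life_table: LifeTable, keep_trace: bool = False) -> ArmOutcome:
    """Run one arm end to end: cohort trace plus discounted accruals."""
    trace = run_cohort(arm, params, config, life_table)
    return accrue_outcomes(trace, arm, params, config, keep_trace=keep_trace)
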