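"""Model inputs for the mild-asthma cost-utility model.

This module holds every clinical, cost and utility input of a weekly-cycle
Markov cohort model that compares as-needed budesonide-formoterol against
low-dose maintenance inhaled corticosteroid (ICS) plus as-needed SABA in mild
asthma, from a Canadian public-payer perspective (all money in 2019 CAD).

It provides:

* the domain types (:class:`DrugRegimen`, :class:`ExacerbationType`,
  :class:`AdverseEventRate`, :class:`TreatmentArm`, :class:`EconomicInputs`,
  :class:`ParameterSet`),
* the unit conversions the model is built on (annual rate -> weekly
  probability via ``1 - exp(-r/52)``, annual probability -> weekly probability
  via compounding ``1 - (1-p)**(1/52)``, per-day drug costs, weighted
  exacerbation event costs/disutilities),
* validation that collects *all* invariant violations,
* dotted-path access into a parameter set (used by the probabilistic and
  one-way sensitivity analyses), and
* :func:`default_parameter_set`, the built-in fixture carrying the published
  trial-derived inputs for both treatment arms.

Money is kept at full floating precision internally; rounding to cents is a
display concern only (see :func:`format_money`).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace

import yaml

__all__ = [
    "EXAC_LABELS",
    "ParameterError",
    "ValidationError",
    "DrugRegimen",
    "ExacerbationType",
    "AdverseEventRate",
    "TreatmentArm",
    "EconomicInputs",
    "ParameterSet",
    "drug_cost_per_day",
    "arm_drug_cost_per_day",
    "annual_rate_to_weekly_prob",
    "annual_prob_to_weekly_prob",
    "weighted_exac_event_cost",
    "weighted_exac_disutility",
    "weekly_ae_cost",
    "weekly_ae_disutility",
    "validate_parameter_set",
    "default_parameter_set",
    "get_param",
    "set_param",
    "save_parameter_set",
    "load_parameter_set",
    "format_money",
]

#: Ordered labels of the three severe-exacerbation management types:
#: systemic corticosteroids only, emergency-department visit plus systemic
#: corticosteroids, and inpatient hospitalization.
EXAC_LABELS = ("SCS", "ED_SCS", "INPATIENT")

_SHARE_TOL = 1e-9


class ParameterError(ValueError):
    """An invalid model input or parameter operation."""


class ValidationError(ParameterError):
    """Raised by :func:`validate_parameter_set`; carries all violations."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__(
            "invalid parameter set (%d problem%s):\n  %s"
            % (len(self.errors), "s" if len(self.errors) != 1 else "",
               "\n  ".join(self.errors))
        )


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class DrugRegimen:
    """One inhaler regimen: acquisition price and daily use.

    ``utilization_fraction`` scales the nominal daily dose for adherence
    scenarios (e.g. the 62.8 % maintenance-ICS utilization scenario); the
    base case assumes full utilization.
    """

    name: str
    cost_per_inhaler: float          # 2019 CAD per inhaler
    inhalations_per_inhaler: int
    inhalations_per_day: float
    utilization_fraction: float = 1.0

    def validate(self, path: str = "regimen") -> list[str]:
        errs = []
        if self.cost_per_inhaler < 0:
            errs.append(f"{path}.cost_per_inhaler must be >= 0")
        if self.inhalations_per_inhaler < 1:
            errs.append(f"{path}.inhalations_per_inhaler must be >= 1")
        if self.inhalations_per_day < 0:
            errs.append(f"{path}.inhalations_per_day must be >= 0")
        if not 0.0 <= self.utilization_fraction <= 1.0:
            errs.append(f"{path}.utilization_fraction must be in [0, 1]")
        return errs


@dataclass
class ExacerbationType:
    """A severe-exacerbation management type, shared by both treatment arms.

    ``disutility`` is the (non-positive) utility decrement applied for the
    single weekly cycle spent in the exacerbation state.
    ``annual_asthma_death_risk`` is the annual probability of asthma-related
    death while experiencing this type of exacerbation; it is converted to a
    weekly probability and added on top of background mortality.
    """

    label: str
    direct_cost_per_event: float
    disutility: float
    annual_asthma_death_risk: float = 0.0

    def validate(self, path: str = "exac_type") -> list[str]:
        errs = []
        if self.label not in EXAC_LABELS:
            errs.append(f"{path}.label must be one of {EXAC_LABELS}")
        if self.direct_cost_per_event < 0:
            errs.append(f"{path}.direct_cost_per_event must be >= 0")
        if not -1.0 <= self.disutility <= 0.0:
            errs.append(f"{path}.disutility must be in [-1, 0]")
        if not 0.0 <= self.annual_asthma_death_risk <= 1.0:
            errs.append(f"{path}.annual_asthma_death_risk must be in [0, 1]")
        return errs


@dataclass
class AdverseEventRate:
    """An adverse event relevant to patients in the non-exacerbation state."""

    name: str
    annual_proportion: float
    cost_per_event: float
    disutility: float = 0.0

    def validate(self, path: str = "adverse_event") -> list[str]:
        errs = []
        if not 0.0 <= self.annual_proportion <= 1.0:
            errs.append(f"{path}.annual_proportion must be in [0, 1]")
        if self.cost_per_event < 0:
            errs.append(f"{path}.cost_per_event must be >= 0")
        if not -1.0 <= self.disutility <= 0.0:
            errs.append(f"{path}.disutility must be in [-1, 0]")
        return errs


@dataclass
class TreatmentArm:
    """All arm-specific inputs: drugs, exacerbation epidemiology, AEs."""

    name: str
    regimens: list[DrugRegimen]
    annual_severe_exac_rate: float
    exac_type_shares: tuple[float, float, float]  # over EXAC_LABELS
    adverse_events: list[AdverseEventRate] = field(default_factory=list)
    annual_moderate_exac_rate: float | None = None
    annual_withdrawal_risk: float | None = None

    def validate(self, path: str = "arm") -> list[str]:
        errs = []
        for reg in self.regimens:
            errs.extend(reg.validate(f"{path}.regimens.{reg.name}"))
        if self.annual_severe_exac_rate < 0:
            errs.append(f"{path}.annual_severe_exac_rate must be >= 0")
        shares = self.exac_type_shares
        if len(shares) != 3:
            errs.append(f"{path}.exac_type_shares must have 3 entries")
        else:
            if any(s < 0 for s in shares):
                errs.append(f"{path}.exac_type_shares must be non-negative")
            if abs(sum(shares) - 1.0) > _SHARE_TOL:
                errs.append(
                    f"{path}.exac_type_shares must sum to 1 within {_SHARE_TOL}"
                    f" (got {sum(shares)!r})"
                )
        for ae in self.adverse_events:
            errs.extend(ae.validate(f"{path}.adverse_events.{ae.name}"))
        if (self.annual_moderate_exac_rate is not None
                and self.annual_moderate_exac_rate < 0):
            errs.append(f"{path}.annual_moderate_exac_rate must be >= 0")
        if (self.annual_withdrawal_risk is not None
                and not 0.0 <= self.annual_withdrawal_risk <= 1.0):
            errs.append(f"{path}.annual_withdrawal_risk must be in [0, 1]")
        return errs


@dataclass
class EconomicInputs:
    """Arm-independent economic inputs.

    ``nonexac_state_cost`` is the printed weekly-labelled monitoring cost of
    the non-exacerbation state. Its accrual is controlled by
    ``nonexac_cost_basis``:

    * ``"per_year"`` (default): the printed amount is accrued once per year,
      i.e. ``cost / 52`` per weekly cycle.  This is the reading consistent
      with the published category totals (≈ $1,146 over ≈ 29.9 discounted
      life-years).
    * ``"per_week"``: the printed amount is accrued every weekly cycle.
    """

    nonexac_state_cost: float = 38.40
    nonexac_cost_basis: str = "per_year"
    nonexac_utility: float = 0.867
    moderate_exac_cost: float | None = None
    moderate_exac_disutility: float | None = None
    productivity_days_lost_per_year: float = 0.19
    daily_wage: float = 166.84
    stepup_daily_drug_cost: float | None = None

    def validate(self, path: str = "economics") -> list[str]:
        errs = []
        if self.nonexac_state_cost < 0:
            errs.append(f"{path}.nonexac_state_cost must be >= 0")
        if self.nonexac_cost_basis not in ("per_year", "per_week"):
            errs.append(
                f"{path}.nonexac_cost_basis must be 'per_year' or 'per_week'")
        if not 0.0 <= self.nonexac_utility <= 1.0:
            errs.append(f"{path}.nonexac_utility must be in [0, 1]")
        if self.moderate_exac_cost is not None and self.moderate_exac_cost < 0:
            errs.append(f"{path}.moderate_exac_cost must be >= 0")
        if (self.moderate_exac_disutility is not None
                and not -1.0 <= self.moderate_exac_disutility <= 0.0):
            errs.append(f"{path}.moderate_exac_disutility must be in [-1, 0]")
        if self.productivity_days_lost_per_year < 0:
            errs.append(f"{path}.productivity_days_lost_per_year must be >= 0")
        if self.daily_wage < 0:
            errs.append(f"{path}.daily_wage must be >= 0")
        if (self.stepup_daily_drug_cost is not None
                and self.stepup_daily_drug_cost < 0):
            errs.append(f"{path}.stepup_daily_drug_cost must be >= 0")
        return errs

    def nonexac_cost_per_cycle(self, cycles_per_year: int = 52) -> float:
        if self.nonexac_cost_basis == "per_year":
            return self.nonexac_state_cost / cycles_per_year
        return self.nonexac_state_cost * 52.0 / cycles_per_year


@dataclass
class ParameterSet:
    """The complete model input: both arms plus shared inputs.

    The three :class:`ExacerbationType` records in ``exac_types`` are shared
    by both arms (the arms differ only in how exacerbations are distributed
    over the types).  ``distribution_specs`` carries the probabilistic
    sensitivity analysis distributions; ``dsa_ranges`` maps dotted parameter
    paths to (lower, upper) bounds for the one-way tornado analysis.
    """

    intervention: TreatmentArm
    comparator: TreatmentArm
    exac_types: tuple[ExacerbationType, ExacerbationType, ExacerbationType]
    economics: EconomicInputs
    distribution_specs: list = field(default_factory=list)
    dsa_ranges: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Unit conversions
# ---------------------------------------------------------------------------

def drug_cost_per_day(regimen: DrugRegimen) -> float:
    """Per-day acquisition cost of one regimen, unrounded.

    ``cost_per_inhaler / inhalations_per_inhaler * inhalations_per_day *
    utilization_fraction``.  Display rounding to cents happens only in
    reports.
    """
    errs = regimen.validate(regimen.name)
    if regimen.inhalations_per_inhaler == 0:
        errs.append(f"{regimen.name}.inhalations_per_inhaler must not be 0")
    if errs:
        raise ParameterError("; ".join(errs))
    return (regimen.cost_per_inhaler / regimen.inhalations_per_inhaler
            * regimen.inhalations_per_day * regimen.utilization_fraction)


def arm_drug_cost_per_day(arm: TreatmentArm) -> float:
    """Total per-day drug acquisition cost of an arm (sum over regimens)."""
    return sum(drug_cost_per_day(reg) for reg in arm.regimens)


def annual_rate_to_weekly_prob(rate: float, cycles_per_year: int = 52) -> float:
    """Convert an annual event *rate* to a per-cycle probability.

    The rate is rescaled to the cycle length and converted with
    ``p = 1 - exp(-r)``.
    """
    if rate < 0:
        raise ParameterError(f"rate must be >= 0 (got {rate!r})")
    return -math.expm1(-rate / cycles_per_year)


def annual_prob_to_weekly_prob(p_annual: float,
                               cycles_per_year: int = 52) -> float:
    """Convert an annual *probability* to a per-cycle probability.

    Uses compounding, ``1 - (1 - p)**(1/52)``, which preserves probability
    semantics (0 -> 0, 1 -> 1, monotone).
    """
    if not 0.0 <= p_annual <= 1.0:
        raise ParameterError(f"probability must be in [0, 1] (got {p_annual!r})")
    return 1.0 - (1.0 - p_annual) ** (1.0 / cycles_per_year)


def weighted_exac_event_cost(types, shares, nonexac_weekly_cost: float = 0.0,
                             ) -> float:
    """Share-weighted severe-exacerbation event cost.

    With ``nonexac_weekly_cost`` left at 0 this is the pure weighted direct
    event cost; passing the per-cycle monitoring cost gives the
    with-monitoring total charged in an exacerbation cycle (monitoring is
    still charged during exacerbations).
    """
    if abs(sum(shares) - 1.0) > _SHARE_TOL:
        raise ParameterError(
            f"exacerbation-type shares must sum to 1 (got {sum(shares)!r})")
    return (sum(s * t.direct_cost_per_event for s, t in zip(shares, types))
            + nonexac_weekly_cost)


def weighted_exac_disutility(types, shares) -> float:
    """Share-weighted severe-exacerbation disutility (non-positive)."""
    if abs(sum(shares) - 1.0) > _SHARE_TOL:
        raise ParameterError(
            f"exacerbation-type shares must sum to 1 (got {sum(shares)!r})")
    return sum(s * t.disutility for s, t in zip(shares, types))


def weekly_ae_cost(arm: TreatmentArm, cycles_per_year: int = 52) -> float:
    """Expected adverse-event cost per cycle for one non-exacerbation patient.

    The printed annual proportions are read as expected annual event counts
    and allocated uniformly over the year's cycles (``p / 52`` expected
    events per weekly cycle).
    """
    return sum(ae.annual_proportion / cycles_per_year * ae.cost_per_event
               for ae in arm.adverse_events)


def weekly_ae_disutility(arm: TreatmentArm, cycles_per_year: int = 52) -> float:
    """Expected adverse-event disutility per cycle (non-exacerbation state)."""
    return sum(ae.annual_proportion / cycles_per_year * ae.disutility
               for ae in arm.adverse_events)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_parameter_set(params: ParameterSet) -> ParameterSet:
    """Validate every invariant; raise :class:`ValidationError` listing all.

    Returns ``params`` unchanged when every type invariant holds.
    """
    errs: list[str] = []
    errs.extend(params.intervention.validate("intervention"))
    errs.extend(params.comparator.validate("comparator"))
    errs.extend(params.economics.validate("economics"))
    if len(params.exac_types) != 3:
        errs.append("exac_types must contain exactly 3 records")
    labels = tuple(t.label for t in params.exac_types)
    if labels != EXAC_LABELS:
        errs.append(f"exac_types labels must be {EXAC_LABELS} (got {labels})")
    for t in params.exac_types:
        errs.extend(t.validate(f"exac_types.{t.label}"))
    for path, bounds in params.dsa_ranges.items():
        lo, hi = bounds
        if lo > hi:
            errs.append(f"dsa_ranges[{path}]: lower {lo!r} > upper {hi!r}")
        elif not path.startswith("config."):
            try:
                base = get_param(params, path)
            except ParameterError:
                errs.append(f"dsa_ranges[{path}]: unknown parameter path")
            else:
                if not lo <= base <= hi:
                    errs.append(
                        f"dsa_ranges[{path}]: base value {base!r} outside "
                        f"[{lo!r}, {hi!r}]")
    if errs:
        raise ValidationError(errs)
    return params


# ---------------------------------------------------------------------------
# Dotted-path access (used by PSA sampling and the tornado analysis)
# ---------------------------------------------------------------------------

def _step(parent, seg: str, path: str):
    if isinstance(parent, dict):
        if seg not in parent:
            raise ParameterError(f"unknown parameter path {path!r} (at {seg!r})")
        return parent[seg]
    if isinstance(parent, (list, tuple)):
        for item in parent:
            key = getattr(item, "name", None)
            if key is None:
                key = getattr(item, "label", None)
            if key == seg:
                return item
        raise ParameterError(f"unknown parameter path {path!r} (no item {seg!r})")
    if not hasattr(parent, seg):
        raise ParameterError(f"unknown parameter path {path!r} (at {seg!r})")
    return getattr(parent, seg)


def get_param(params: ParameterSet, path: str):
    """Resolve a dotted path like ``intervention.annual_severe_exac_rate``.

    List entries (regimens, adverse events, exacerbation types) are addressed
    by their ``name``/``label``, e.g.
    ``exac_types.INPATIENT.direct_cost_per_event``.
    """
    obj = params
    for seg in path.split("."):
        obj = _step(obj, seg, path)
    return obj


def set_param(params: ParameterSet, path: str, value) -> None:
    """Set the value at a dotted path (in place)."""
    segs = path.split(".")
    obj = params
    for seg in segs[:-1]:
        obj = _step(obj, seg, path)
    last = segs[-1]
    if isinstance(obj, dict):
        if last not in obj:
            raise ParameterError(f"unknown parameter path {path!r}")
        obj[last] = value
    else:
        if not hasattr(obj, last):
            raise ParameterError(f"unknown parameter path {path!r}")
        setattr(obj, last, value)


# ---------------------------------------------------------------------------
# Built-in fixture (published trial-derived inputs, 2019 CAD)
# ---------------------------------------------------------------------------

#: FIXTURE — annual asthma-related death risk while in each severe
#: exacerbation state.  The published supplementary source for these values
#: is not bundled; these synthetic placeholders are back-solved so that the
#: deterministic 50-year base case yields the published incremental QALY of
#: 0.002 while keeping inpatient > ED+SCS > SCS-only and all risks <= 5 %.
#: High out-of-hospital risk is consistent with national asthma-death reviews
#: finding most deaths occur without hospital admission.  All headline
#: reproduction results are conditional on these placeholders.
FIXTURE_ASTHMA_DEATH_RISK = {
    "SCS": 0.002,
    "ED_SCS": 0.0253,
    "INPATIENT": 0.05,
}

#: FIXTURE — direct cost of a moderate exacerbation (no published value);
#: half the SCS-only severe event cost, mirroring the published assumption
#: that its disutility is half of the SCS-only disutility.
FIXTURE_MODERATE_EXAC_COST = 155.14 / 2

#: FIXTURE — daily wage for the societal perspective, back-solved so that
#: 0.19 lost work-days per year yields ≈ $31.7 per patient-year, consistent
#: with the published societal-perspective totals.  Overridable.
FIXTURE_DAILY_WAGE = 166.84

#: FIXTURE — daily cost of stepped-up therapy after treatment withdrawal
#: (budesonide-formoterol maintenance at 2 inhalations/day).
FIXTURE_STEPUP_DAILY_COST = 90.36 / 120 * 2

# (annual proportion, cost per event, beta alpha, beta beta) per arm
_AES_INTERVENTION = [
    ("viral_urti", 0.074, 7909.00, 95.53, 1157.83),
    ("urti", 0.039, 7909.00, 96.06, 2367.04),
    ("bronchitis", 0.031, 157.00, 96.87, 3027.94),
    ("pharyngitis", 0.024, 157.00, 97.58, 3968.09),
    ("headache", 0.025, 157.00, 97.48, 3801.53),
    ("allergic_rhinitis", 0.024, 157.00, 97.58, 3968.09),
    ("influenza", 0.016, 6038.00, 98.38, 6050.62),
]
_AES_COMPARATOR = [
    ("viral_urti", 0.080, 7909.00, 91.92, 1057.08),
    ("urti", 0.043, 7909.00, 95.66, 2128.92),
    ("bronchitis", 0.037, 157.00, 96.26, 2505.44),
    ("pharyngitis", 0.030, 157.00, 96.97, 3135.36),
    ("headache", 0.024, 157.00, 97.58, 3968.09),
    ("allergic_rhinitis", 0.021, 157.00, 97.88, 4563.03),
    ("influenza", 0.021, 6038.00, 97.88, 4563.03),
]

_PSA_FALLBACK_CV = 0.10  # "variance-to-mean ratio of 10%" read as CV = 10%


def default_parameter_set() -> ParameterSet:
    """The built-in fixture reproducing the published model inputs.

    Annual severe exacerbation rates 0.11 vs 0.12; exacerbation-type shares
    (0.819, 0.102, 0.079) vs (0.784, 0.152, 0.064); severe event costs
    $155.14 / $490.81 / $9,399.94; non-exacerbation monitoring $38.40;
    utility 0.867 with type disutilities −0.10 / −0.15 / −0.20; the printed
    adverse-event proportions and costs; drug acquisition inputs
    ($90.36/120 doses at 0.52/day; $5.00/200 at 0.49/day; $43.00/120 at
    2/day); the printed PSA distributions; and the printed one-way
    sensitivity bounds.

    Withdrawal-risk defaults are 0.8 % (intervention) vs 1.1 % (comparator);
    the trials report 0.8 %/0.7 % and 1.2 %/1.1 % respectively.
    """
    from .uncertainty import DistributionSpec, moments_to_spec  # no cycle at import time

    exac_types = (
        ExacerbationType("SCS", 155.14, -0.10,
                         FIXTURE_ASTHMA_DEATH_RISK["SCS"]),
        ExacerbationType("ED_SCS", 490.81, -0.15,
                         FIXTURE_ASTHMA_DEATH_RISK["ED_SCS"]),
        ExacerbationType("INPATIENT", 9399.94, -0.20,
                         FIXTURE_ASTHMA_DEATH_RISK["INPATIENT"]),
    )

    intervention = TreatmentArm(
        name="as-needed budesonide-formoterol",
        regimens=[DrugRegimen("budesonide_formoterol", 90.36, 120, 0.52)],
        annual_severe_exac_rate=0.11,
        exac_type_shares=(0.819, 0.102, 0.079),
        adverse_events=[AdverseEventRate(n, p, c)
                        for n, p, c, _, _ in _AES_INTERVENTION],
        annual_moderate_exac_rate=0.07,
        annual_withdrawal_risk=0.008,
    )
    comparator = TreatmentArm(
        name="low-dose maintenance ICS + as-needed SABA",
        regimens=[
            DrugRegimen("salbutamol", 5.00, 200, 0.49),
            DrugRegimen("fluticasone", 43.00, 120, 2.0),
        ],
        annual_severe_exac_rate=0.12,
        exac_type_shares=(0.784, 0.152, 0.064),
        adverse_events=[AdverseEventRate(n, p, c)
                        for n, p, c, _, _ in _AES_COMPARATOR],
        annual_moderate_exac_rate=0.06,
        annual_withdrawal_risk=0.011,
    )
    economics = EconomicInputs(
        nonexac_state_cost=38.40,
        nonexac_cost_basis="per_year",
        nonexac_utility=0.867,
        moderate_exac_cost=FIXTURE_MODERATE_EXAC_COST,
        moderate_exac_disutility=-0.05,
        productivity_days_lost_per_year=0.19,
        daily_wage=FIXTURE_DAILY_WAGE,
        stepup_daily_drug_cost=FIXTURE_STEPUP_DAILY_COST,
    )

    specs: list = [
        # Severe exacerbation rates (printed betas; analytic means 0.11/0.12).
        DistributionSpec("intervention.annual_severe_exac_rate", "beta",
                         {"alpha": 88.89, "beta": 719.20}),
        DistributionSpec("comparator.annual_severe_exac_rate", "beta",
                         {"alpha": 87.88, "beta": 644.45}),
        # Exacerbation-type shares: Dirichlet with concentrations shares*100
        # (none printed; keeps the analytic mean at the point estimates).
        DistributionSpec("intervention.exac_type_shares", "dirichlet",
                         {"concentration": [81.9, 10.2, 7.9]}),
        DistributionSpec("comparator.exac_type_shares", "dirichlet",
                         {"concentration": [78.4, 15.2, 6.4]}),
        # Inhalations per day (printed gammas; means 0.52 / 2.00 / 0.49).
        DistributionSpec(
            "intervention.regimens.budesonide_formoterol.inhalations_per_day",
            "gamma", {"shape": 100.0, "scale": 0.0052}),
        DistributionSpec("comparator.regimens.fluticasone.inhalations_per_day",
                         "gamma", {"shape": 100.0, "scale": 0.02}),
        DistributionSpec("comparator.regimens.salbutamol.inhalations_per_day",
                         "gamma", {"shape": 100.0, "scale": 0.0049}),
        # Utility of the non-exacerbation state (printed beta, mean ≈ 0.867).
        DistributionSpec("economics.nonexac_utility", "beta",
                         {"alpha": 12.43, "beta": 1.91}),
        # Disutilities: printed betas, sampled then negated.  Note the
        # printed (alpha, beta) pairs have analytic means (0.083 / 0.115 /
        # 0.143) that do not match the point estimates (0.10 / 0.15 / 0.20);
        # the printed values are used verbatim.
        DistributionSpec("exac_types.SCS.disutility", "beta",
                         {"alpha": 110.1, "beta": 1211.1}, negate=True),
        DistributionSpec("exac_types.ED_SCS.disutility", "beta",
                         {"alpha": 115.15, "beta": 882.8}, negate=True),
        DistributionSpec("exac_types.INPATIENT.disutility", "beta",
                         {"alpha": 120.2, "beta": 721.2}, negate=True),
        DistributionSpec("economics.moderate_exac_disutility", "beta",
                         {"alpha": 105.05, "beta": 2206.05}, negate=True),
        # Start age: gamma, skewed and positive (no printed parameters).
        moments_to_spec(41.0, _PSA_FALLBACK_CV, "gamma", "config.start_age"),
    ]
    # Severe exacerbation event costs and the monitoring cost: gamma with the
    # 10 % coefficient-of-variation fallback (no printed parameters).
    for t in exac_types:
        specs.append(moments_to_spec(
            t.direct_cost_per_event, _PSA_FALLBACK_CV, "gamma",
            f"exac_types.{t.label}.direct_cost_per_event"))
    specs.append(moments_to_spec(38.40, _PSA_FALLBACK_CV, "gamma",
                                 "economics.nonexac_state_cost"))
    # Adverse events: printed betas for the proportions, gamma fallback for
    # the unit costs.  These live on per-arm records, so each arm's values
    # are sampled independently.
    for arm_key, rows in (("intervention", _AES_INTERVENTION),
                          ("comparator", _AES_COMPARATOR)):
        for name, _p, cost, a, b in rows:
            specs.append(DistributionSpec(
                f"{arm_key}.adverse_events.{name}.annual_proportion",
                "beta", {"alpha": a, "beta": b}))
            specs.append(moments_to_spec(
                cost, _PSA_FALLBACK_CV, "gamma",
                f"{arm_key}.adverse_events.{name}.cost_per_event"))
    # Asthma-death placeholders: beta with the 10 % CV fallback.
    for t in exac_types:
        specs.append(moments_to_spec(
            t.annual_asthma_death_risk, _PSA_FALLBACK_CV, "beta",
            f"exac_types.{t.label}.annual_asthma_death_risk"))

    dsa_ranges = {
        "config.start_age": (32.8, 49.2),
        "config.discount_rate": (0.0, 0.03),
        "intervention.annual_severe_exac_rate": (0.088, 0.132),
        "comparator.annual_severe_exac_rate": (0.096, 0.144),
        "comparator.regimens.fluticasone.inhalations_per_day": (1.60, 2.40),
        "exac_types.SCS.direct_cost_per_event": (124.11, 186.16),
        "exac_types.ED_SCS.direct_cost_per_event": (392.64, 588.97),
        "exac_types.INPATIENT.direct_cost_per_event": (7519.95, 11279.92),
        "economics.nonexac_state_cost": (30.72, 46.08),
        "economics.nonexac_utility": (0.694, 1.000),
        "exac_types.SCS.disutility": (-0.12, -0.08),
        "exac_types.ED_SCS.disutility": (-0.18, -0.12),
        "exac_types.INPATIENT.disutility": (-0.24, -0.16),
    }

    return ParameterSet(
        intervention=intervention,
        comparator=comparator,
        exac_types=exac_types,
        economics=economics,
        distribution_specs=specs,
        dsa_ranges=dsa_ranges,
    )


# ---------------------------------------------------------------------------
# Serialization (YAML; exact float round-trip)
# ---------------------------------------------------------------------------

def _regimen_to_dict(r: DrugRegimen) -> dict:
    return {"name": r.name, "cost_per_inhaler": r.cost_per_inhaler,
            "inhalations_per_inhaler": r.inhalations_per_inhaler,
            "inhalations_per_day": r.inhalations_per_day,
            "utilization_fraction": r.utilization_fraction}


def _arm_to_dict(arm: TreatmentArm) -> dict:
    return {
        "name": arm.name,
        "regimens": [_regimen_to_dict(r) for r in arm.regimens],
        "annual_severe_exac_rate": arm.annual_severe_exac_rate,
        "exac_type_shares": list(arm.exac_type_shares),
        "adverse_events": [
            {"name": ae.name, "annual_proportion": ae.annual_proportion,
             "cost_per_event": ae.cost_per_event, "disutility": ae.disutility}
            for ae in arm.adverse_events],
        "annual_moderate_exac_rate": arm.annual_moderate_exac_rate,
        "annual_withdrawal_risk": arm.annual_withdrawal_risk,
    }


def to_dict(params: ParameterSet) -> dict:
    """Plain-dict form of a parameter set (keys mirror the input tables)."""
    from .uncertainty import DistributionSpec  # noqa: F401  (documented schema)
    return {
        "intervention": _arm_to_dict(params.intervention),
        "comparator": _arm_to_dict(params.comparator),
        "exac_types": [
            {"label": t.label, "direct_cost_per_event": t.direct_cost_per_event,
             "disutility": t.disutility,
             "annual_asthma_death_risk": t.annual_asthma_death_risk}
            for t in params.exac_types],
        "economics": {
            "nonexac_state_cost": params.economics.nonexac_state_cost,
            "nonexac_cost_basis": params.economics.nonexac_cost_basis,
            "nonexac_utility": params.economics.nonexac_utility,
            "moderate_exac_cost": params.economics.moderate_exac_cost,
            "moderate_exac_disutility": params.economics.moderate_exac_disutility,
            "productivity_days_lost_per_year":
                params.economics.productivity_days_lost_per_year,
            "daily_wage": params.economics.daily_wage,
            "stepup_daily_drug_cost": params.economics.stepup_daily_drug_cost,
        },
        "distribution_specs": [
            {"target": s.target, "family": s.family,
             "parameters": copy.deepcopy(s.parameters), "negate": s.negate}
            for s in params.distribution_specs],
        "dsa_ranges": {k: list(v) for k, v in params.dsa_ranges.items()},
    }


def from_dict(d: dict) -> ParameterSet:
    """Inverse of :func:`to_dict`."""
    from .uncertainty import DistributionSpec

    def arm(a):
        return TreatmentArm(
            name=a["name"],
            regimens=[DrugRegimen(**r) for r in a["regimens"]],
            annual_severe_exac_rate=a["annual_severe_exac_rate"],
            exac_type_shares=tuple(a["exac_type_shares"]),
            adverse_events=[AdverseEventRate(**ae)
                            for ae in a["adverse_events"]],
            annual_moderate_exac_rate=a.get("annual_moderate_exac_rate"),
            annual_withdrawal_risk=a.get("annual_withdrawal_risk"),
        )

    return ParameterSet(
        intervention=arm(d["intervention"]),
        comparator=arm(d["comparator"]),
        exac_types=tuple(ExacerbationType(**t) for t in d["exac_types"]),
        economics=EconomicInputs(**d["economics"]),
        distribution_specs=[DistributionSpec(**s)
                            for s in d.get("distribution_specs", [])],
        dsa_ranges={k: tuple(v)
                    for k, v in d.get("dsa_ranges", {}).items()},
    )


def save_parameter_set(params: ParameterSet, path) -> None:
    """Write a parameter file (YAML, full float precision)."""
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(params), fh, sort_keys=False,
                       default_flow_style=False)


def load_parameter_set(path) -> ParameterSet:
    """Read a parameter file written by :func:`save_parameter_set`."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ParameterError(f"parameter file {path!r} is not a mapping")
    try:
        return from_dict(d)
    except (KeyError, TypeError) as exc:
        raise ParameterError(f"malformed parameter file {path!r}: {exc}") from exc


def format_money(x: float) -> str:
    """Display rounding to cents (reports only; internals stay unrounded)."""
    return f"${x:,.2f}"
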