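"""Parameter uncertainty: PSA sampling and one-way (tornado) analysis.

The probabilistic sensitivity analysis draws each uncertain input from the
distribution assigned to it (beta for probabilities and utilities, gamma for
costs, doses and age, Dirichlet for the exacerbation-type shares; disutilities
are drawn from a beta and negated), runs the Markov model deterministically
for both arms at each draw, and summarizes the joint distribution of
incremental costs and QALYs.  Where no distribution parameters are published
the fallback is a 10 % coefficient of variation (see
:func:`moments_to_spec`); drug acquisition costs are treated as known and
fixed and are never sampled.

Reproducibility: each PSA iteration gets its own random stream spawned from a
master seed sequence, so re-running with the same seed is bit-identical and
adding parameters to the model does not reshuffle other iterations' draws.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import economics
from .markov import LifeTable, RunConfig, run_arm
from .parameters import ParameterError, ParameterSet, get_param, set_param

__all__ = [
    "DistributionSpec", "PSAResult", "moments_to_spec",
    "sample_parameter_set", "run_psa", "run_one_way_dsa",
]


@dataclass
class DistributionSpec:
    """One sampled parameter: a dotted target path plus a distribution.

    Families: ``beta`` (parameters ``alpha``, ``beta``), ``gamma``
    (``shape``, ``scale``), ``dirichlet`` (``concentration`` vector over the
    three exacerbation-type shares) and ``fixed`` (no sampling).  With
    ``negate`` the draw's sign is flipped (used for disutilities, which are
    sampled from a beta and then negated).  Targets beginning with
    ``config.`` address the run configuration (e.g. the cohort start age)
    rather than the parameter set.
    """

    target: str
    family: str
    parameters: dict = field(default_factory=dict)
    negate: bool = False

    def __post_init__(self):
        if self.family not in ("beta", "gamma", "dirichlet", "fixed"):
            raise ParameterError(f"unknown distribution family {self.family!r}")
        if self.family == "beta":
            if self.parameters["alpha"] <= 0 or self.parameters["beta"] <= 0:
                raise ParameterError(f"{self.target}: beta needs alpha, beta > 0")
        elif self.family == "gamma":
            if self.parameters["shape"] <= 0 or self.parameters["scale"] <= 0:
                raise ParameterError(f"{self.target}: gamma needs shape, scale > 0")
        elif self.family == "dirichlet":
            conc = self.parameters["concentration"]
            if any(c <= 0 for c in conc):
                raise ParameterError(
                    f"{self.target}: dirichlet concentrations must be > 0")

    def mean(self) -> float:
        """Analytic mean of the distribution (sign included)."""
        if self.family == "beta":
            a, b = self.parameters["alpha"], self.parameters["beta"]
            m = a / (a + b)
        elif self.family == "gamma":
            m = self.parameters["shape"] * self.parameters["scale"]
        else:
            raise ParameterError(f"no scalar mean for family {self.family!r}")
        return -m if self.negate else m

    def draw(self, rng: np.random.Generator):
        if self.family == "fixed":
            return None
        if self.family == "beta":
            x = rng.beta(self.parameters["alpha"], self.parameters["beta"])
        elif self.family == "gamma":
            x = rng.gamma(self.parameters["shape"], self.parameters["scale"])
        else:  # dirichlet
            return tuple(rng.dirichlet(self.parameters["concentration"]))
        return -x if self.negate else x


def moments_to_spec(mean: float, cv: float, family: str,
                    target: str = "") -> DistributionSpec:
    """Distribution spec from a mean and coefficient of variation.

    Gamma: ``shape = 1/cv², scale = mean·cv²``.  Beta: method of moments
    with ``σ = cv·mean`` (requires ``mean < 1`` and a feasible variance).
    Either way the resulting analytic mean equals ``mean``.

    The 10 % "variance-to-mean" fallback of the source analysis is read as a
    10 % coefficient of variation — this reproduces the published
    ``Gamma(shape=100)`` specifications exactly.  (A literal variance/mean
    reading would use ``cv = sqrt(ratio/mean)``; callers wanting that can
    pass it explicitly.)
    """
    if mean <= 0:
        raise ParameterError("moments_to_spec needs mean > 0")
    if cv <= 0:
        raise ParameterError("moments_to_spec needs cv > 0")
    if family == "gamma":
        shape = 1.0 / cv ** 2
        return DistributionSpec(target, "gamma",
                                {"shape": shape, "scale": mean * cv ** 2})
    if family == "beta":
        if mean >= 1:
            raise ParameterError("beta target needs mean < 1")
        var = (cv * mean) ** 2
        if var >= mean * (1 - mean):
            raise ParameterError("infeasible beta variance for this mean")
        alpha = mean * (mean * (1 - mean) / var - 1)
        beta = alpha * (1 - mean) / mean
        return DistributionSpec(target, "beta", {"alpha": alpha, "beta": beta})
    raise ParameterError(f"moments_to_spec supports beta/gamma, not {family!r}")


def sample_parameter_set(base: ParameterSet, specs,
                         rng: np.random.Generator) -> ParameterSet:
    """One joint draw: a deep copy of ``base`` with sampled values set.

    ``fixed`` specs leave their target untouched; Dirichlet draws replace the
    whole share vector (and sum to 1 by construction).  Drug acquisition
    costs are contractually fixed — a spec targeting ``cost_per_inhaler``
    raises.  Specs targeting ``config.*`` are not applicable here and raise
    (see :func:`run_psa`, which handles them on the run configuration).
    """
    sampled = copy.deepcopy(base)
    for spec in specs:
        if spec.target.startswith("config."):
            raise ParameterError(
                f"{spec.target}: config-level targets are sampled by run_psa, "
                "not sample_parameter_set")
        if "cost_per_inhaler" in spec.target:
            raise ParameterError(
                f"{spec.target}: drug acquisition costs are fixed by design")
        if spec.family == "fixed":
            get_param(sampled, spec.target)  # still validate the path
            continue
        set_param(sampled, spec.target, spec.draw(rng))
    return sampled


def _sampled_config(config: RunConfig, specs,
                    rng: np.random.Generator) -> RunConfig:
    overrides = {}
    for spec in specs:
        if spec.family == "fixed":
            continue
        field_name = spec.target.split(".", 1)[1]
        if not hasattr(config, field_name):
            raise ParameterError(f"unknown config target {spec.target!r}")
        overrides[field_name] = spec.draw(rng)
    return replace(config, **overrides) if overrides else config


@dataclass
class PSAResult:
    """Per-iteration PSA outcomes plus summaries.

    ``cost_*``/``qaly_*`` are per-arm discounted totals per iteration;
    ``delta_cost``/``delta_qaly`` their differences (intervention minus
    comparator).  ``ceac`` is computed on the default willingness-to-pay
    grid.
    """

    n_iterations: int
    seed: int | None
    cost_intervention: np.ndarray
    cost_comparator: np.ndarray
    qaly_intervention: np.ndarray
    qaly_comparator: np.ndarray
    ceac: economics.CEACCurve

    @property
    def delta_cost(self) -> np.ndarray:
        return self.cost_intervention - self.cost_comparator

    @property
    def delta_qaly(self) -> np.ndarray:
        return self.qaly_intervention - self.qaly_comparator

    @property
    def mean_delta_cost(self) -> float:
        return float(self.delta_cost.mean())

    @property
    def mean_delta_qaly(self) -> float:
        return float(self.delta_qaly.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "iteration": np.arange(self.n_iterations),
            "cost_intervention": self.cost_intervention,
            "cost_comparator": self.cost_comparator,
            "qaly_intervention": self.qaly_intervention,
            "qaly_comparator": self.qaly_comparator,
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
        })


def run_psa(params: ParameterSet, config: RunConfig, life_table: LifeTable,
            n: int = 1000, seed: int | None = None,
            wtp_grid=None) -> PSAResult:
    """Monte Carlo propagation of parameter uncertainty.

    ``n`` joint parameter draws (from ``params.distribution_specs``), each
    run deterministically through the Markov engine for both arms.  Given the
    same ``seed`` the result is bit-identical.
    """
    if n < 1:
        raise ParameterError("PSA needs n >= 1 iterations")
    param_specs = [s for s in params.distribution_specs
                   if not s.target.startswith("config.")]
    config_specs = [s for s in params.distribution_specs
                    if s.target.startswith("config.")]
    streams = np.random.SeedSequence(seed).spawn(n)

    cost_i = np.empty(n)
    cost_c = np.empty(n)
    qaly_i = np.empty(n)
    qaly_c = np.empty(n)
    for k in range(n):
        rng = np.random.default_rng(streams[k])
        ps = sample_parameter_set(params, param_specs, rng)
        cfg = _sampled_config(config, config_specs, rng)
        iv = run_arm(ps.intervention, ps, cfg, life_table)
        cp = run_arm(ps.comparator, ps, cfg, life_table)
        cost_i[k] = iv.total_cost
        cost_c[k] = cp.total_cost
        qaly_i[k] = iv.total_qaly
        qaly_c[k] = cp.total_qaly

    curve = economics.ceac(cost_i - cost_c, qaly_i - qaly_c, wtp_grid)
    return PSAResult(n_iterations=n, seed=seed,
                     cost_intervention=cost_i, cost_comparator=cost_c,
                     qaly_intervention=qaly_i, qaly_comparator=qaly_c,
                     ceac=curve)


def _with_value(params: ParameterSet, config: RunConfig, path: str, value):
    """(params, config) with one parameter set to ``value``."""
    if path.startswith("config."):
        field_name = path.split(".", 1)[1]
        if field_name == "discount_rate":
            return params, replace(config, discount_rate_costs=value,
                                   discount_rate_outcomes=value)
        if not hasattr(config, field_name):
            raise ParameterError(f"unknown config target {path!r}")
        return params, replace(config, **{field_name: value})
    ps = copy.deepcopy(params)
    set_param(ps, path, value)
    return ps, config


def run_one_way_dsa(params: ParameterSet, config: RunConfig,
                    life_table: LifeTable, ranges: dict | None = None,
                    wtp_reference: float = 50_000.0) -> pd.DataFrame:
    """One-way deterministic sensitivity analysis (tornado).

    For each parameter path the model is re-run at the lower and upper bound
    with everything else at base.  Swings are reported on incremental cost
    and on net monetary benefit at ``wtp_reference``; rows are sorted by
    descending absolute cost swing.
    """
    if ranges is None:
        ranges = params.dsa_ranges
    rows = []
    for path, (lo, hi) in ranges.items():
        results = {}
        for which, value in (("low", lo), ("high", hi)):
            ps, cfg = _with_value(params, config, path, value)
            results[which] = economics.evaluate(ps, cfg, life_table)
        dc_lo = results["low"].incremental_cost
        dc_hi = results["high"].incremental_cost
        dq_lo = results["low"].incremental_qaly
        dq_hi = results["high"].incremental_qaly
        nmb_lo = economics.net_monetary_benefit(dc_lo, dq_lo, wtp_reference)
        nmb_hi = economics.net_monetary_benefit(dc_hi, dq_hi, wtp_reference)
        rows.append({
            "parameter": path, "lower": lo, "upper": hi,
            "delta_cost_low": dc_lo, "delta_cost_high": dc_hi,
            "delta_qaly_low": dq_lo, "delta_qaly_high": dq_hi,
            "cost_swing": abs(dc_hi - dc_lo),
            "nmb_low": nmb_lo, "nmb_high": nmb_hi,
            "nmb_swing": abs(nmb_hi - nmb_lo),
        })
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values("cost_swing", ascending=False,
                            kind="mergesort").reset_index(drop=True)
    return df
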