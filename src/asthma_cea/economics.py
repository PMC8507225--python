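"""Cost-effectiveness surface: incremental results, ICER/dominance, NMB,
cost-effectiveness plane and acceptability curve.

Conventions: incremental quantities are intervention minus comparator.  A
strategy is *dominant* when it is cheaper (ΔC < 0) and more effective
(ΔQ > 0), *dominated* in the mirror case; otherwise an ICER = ΔC/ΔQ is
reported together with its cost-effectiveness plane quadrant.  The
acceptability curve reports, at each willingness-to-pay λ, the fraction of
probabilistic draws with strictly positive net monetary benefit
``λ·ΔQ − ΔC`` (an NMB of exactly 0 counts as not cost-effective).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markov import ArmOutcome, COST_CATEGORIES, QALY_CATEGORIES, RunConfig, run_arm
from .parameters import ParameterSet

__all__ = [
    "CEResult", "CEACCurve", "incremental_result", "net_monetary_benefit",
    "ceac", "ce_plane_points", "default_wtp_grid", "evaluate",
    "summary_table",
]


@dataclass
class CEResult:
    """Deterministic cost-effectiveness comparison of two arms."""

    intervention: ArmOutcome
    comparator: ArmOutcome
    incremental_cost: float
    incremental_qaly: float
    label: str                 # dominant | dominated | icer | tie | cost-difference-only
    icer: float | None

    @property
    def quadrant(self) -> str:
        dq, dc = self.incremental_qaly, self.incremental_cost
        if dq > 0:
            return "SE" if dc < 0 else "NE"
        return "SW" if dc < 0 else "NW"

    @property
    def incremental_by_category(self) -> dict[str, float]:
        return {c: (self.intervention.cost_categories[c]
                    - self.comparator.cost_categories[c])
                for c in COST_CATEGORIES}


@dataclass
class CEACCurve:
    """Probability of cost-effectiveness over a willingness-to-pay grid."""

    wtp: np.ndarray
    probability: np.ndarray
    n_iterations: int

    def at(self, wtp_value: float) -> float:
        i = np.where(np.isclose(self.wtp, wtp_value))[0]
        if i.size == 0:
            raise ValueError(f"wtp {wtp_value!r} not on the grid")
        return float(self.probability[i[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp,
                             "probability": self.probability})


def incremental_result(intervention: ArmOutcome,
                       comparator: ArmOutcome) -> CEResult:
    """Incremental cost, QALY and dominance/ICER label.

    Raises ``ValueError`` when the two arm summaries were produced under
    different run configurations.
    """
    if intervention.config != comparator.config:
        raise ValueError("arm outcomes come from different run configurations")
    dc = intervention.total_cost - comparator.total_cost
    dq = intervention.total_qaly - comparator.total_qaly
    icer = None
    if dc < 0 and dq > 0:
        label = "dominant"
    elif dc > 0 and dq < 0:
        label = "dominated"
    elif dq == 0:
        label = "tie" if dc == 0 else "cost-difference-only"
    else:
        label = "icer"
        icer = dc / dq
    return CEResult(intervention=intervention, comparator=comparator,
                    incremental_cost=dc, incremental_qaly=dq,
                    label=label, icer=icer)


def net_monetary_benefit(delta_cost: float, delta_qaly: float,
                         wtp: float) -> float:
    """``wtp * ΔQALY − ΔCost``."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * delta_qaly - delta_cost


def default_wtp_grid() -> np.ndarray:
    """$0 to $200,000 in $1,000 steps (includes $50,000 and $100,000)."""
    return np.arange(0.0, 200_001.0, 1000.0)


def ceac(delta_costs, delta_qalys, wtp_grid=None) -> CEACCurve:
    """Cost-effectiveness acceptability curve from PSA draws.

    At each λ the probability is the fraction of draws with
    ``λ·ΔQ − ΔC > 0`` (strict; at λ = 0 this is the fraction with ΔC < 0).
    """
    dc = np.asarray(delta_costs, dtype=float)
    dq = np.asarray(delta_qalys, dtype=float)
    if dc.size == 0:
        raise ValueError("CEAC needs at least one draw")
    if dc.shape != dq.shape:
        raise ValueError("delta_costs and delta_qalys must have equal length")
    grid = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid,
                                                                  dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("wtp grid must be strictly ascending")
    nmb = grid[:, None] * dq[None, :] - dc[None, :]
    prob = (nmb > 0).mean(axis=1)
    return CEACCurve(wtp=grid, probability=prob, n_iterations=dc.size)


def ce_plane_points(delta_costs, delta_qalys) -> pd.DataFrame:
    """PSA draws as cost-effectiveness plane points with quadrant labels.

    Quadrants (x = ΔQALY, y = ΔCost): NE more effective & costlier, SE more
    effective & cheaper (dominant), SW less effective & cheaper, NW less
    effective & costlier (dominated).  Boundary draws (ΔQ = 0 or ΔC = 0) are
    assigned to the quadrant on their non-negative-ΔQ / negative-ΔC side so
    counts always partition the draws.
    """
    dc = np.asarray(delta_costs, dtype=float)
    dq = np.asarray(delta_qalys, dtype=float)
    if dc.size == 0:
        raise ValueError("CE plane needs at least one draw")
    east = dq > 0
    south = dc < 0
    quadrant = np.where(east, np.where(south, "SE", "NE"),
                        np.where(south, "SW", "NW"))
    return pd.DataFrame({"delta_qaly": dq, "delta_cost": dc,
                         "quadrant": quadrant})


def evaluate(params: ParameterSet, config: RunConfig, life_table,
             keep_traces: bool = False) -> CEResult:
    """Run both arms deterministically and form the incremental result."""
    iv = run_arm(params.intervention, params, config, life_table,
                 keep_trace=keep_traces)
    cp = run_arm(params.comparator, params, config, life_table,
                 keep_trace=keep_traces)
    return incremental_result(iv, cp)


def summary_table(result: CEResult) -> pd.DataFrame:
    """Category-by-arm cost/QALY decomposition (full precision).

    One row per cost category plus a total row; QALY columns carry the QALY
    decomposition where a category has one.
    """
    rows = []
    for cat in COST_CATEGORIES:
        ci = result.intervention.cost_categories[cat]
        cc = result.comparator.cost_categories[cat]
        if ci == 0.0 and cc == 0.0 and cat not in QALY_CATEGORIES:
            continue
        qi = result.intervention.qaly_categories.get(cat)
        qc = result.comparator.qaly_categories.get(cat)
        rows.append({
            "category": cat,
            "cost_intervention": ci,
            "cost_comparator": cc,
            "incremental_cost": ci - cc,
            "qaly_intervention": qi,
            "qaly_comparator": qc,
            "incremental_qaly": (qi - qc) if qi is not None else None,
        })
    rows.append({
        "category": "total",
        "cost_intervention": result.intervention.total_cost,
        "cost_comparator": result.comparator.total_cost,
        "incremental_cost": result.incremental_cost,
        "qaly_intervention": result.intervention.total_qaly,
        "qaly_comparator": result.comparator.total_qaly,
        "incremental_qaly": result.incremental_qaly,
    })
    return pd.DataFrame(rows)
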