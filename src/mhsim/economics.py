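"""QALY and cost accrual, aggregation and incremental cost-utility analysis.

Outcomes accrue in continuous time over the window from the accrual start
age (14, when the two-year school programme ends) to the 30-year horizon,
truncated at death.  QALYs integrate the stratum utility, which switches
permanently from the no-disorder to the with-disorder level at the first
onset; disease costs accrue per cluster at the annual per-patient rate
from (at earliest) the accrual start until death or horizon, additively
across co-occurring clusters.  Both are discounted at 3%/year by default.

Two discounting conventions are provided: continuous exponential
``exp(-r (t - a0))`` (the default, composing naturally with continuous
event times) and annual-step ``(1+r)^(-floor(t - a0))``; the two differ by
well under 2% at r = 0.03.

The intervention cost is charged once, undiscounted, per simulated
individual at the accrual start (a universal school-based programme).

Perspectives: ``healthcare`` counts healthcare costs plus the intervention
cost; ``societal`` adds direct non-medical and indirect costs.  The
incremental cost-utility ratio ΔC/ΔQ is reported when ΔC > 0 and ΔQ > 0;
an intervention with lower costs and higher QALYs is *dominant*, one with
higher costs and lower QALYs is *dominated*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .des_engine import PairedTrajectories, ScenarioArrays, Trajectory
from .parameters import (
    CLUSTERS,
    COST_CATEGORIES,
    GENDERS,
    SES_LEVELS,
    STRATA,
    CostTable,
    ParameterError,
    Stratum,
    UtilityTable,
)

__all__ = [
    "discounted_years",
    "accrue_qalys",
    "accrue_costs",
    "add_intervention_cost",
    "EconResult",
    "summarize_economics",
    "CUAResult",
    "cost_utility",
]

PERSPECTIVES = ("healthcare", "societal")
DISCOUNT_MODES = ("continuous", "annual")


# --------------------------------------------------------------------------
# Discounted time integrals
# --------------------------------------------------------------------------

def discounted_years(
    a: np.ndarray,
    b: np.ndarray,
    r: float,
    a0: float,
    mode: str = "continuous",
) -> np.ndarray:
    """Integral of the discount factor over [a, b] (0 where b <= a).

    Continuous mode: ∫_a^b e^{-r (t - a0)} dt, with the closed form
    (e^{-r(a-a0)} - e^{-r(b-a0)})/r.  Annual mode applies the factor
    (1+r)^{-k} on each whole year [a0+k, a0+k+1).
    """
    if mode not in DISCOUNT_MODES:
        raise ParameterError(f"unknown discount mode {mode!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = np.broadcast_arrays(a, b)
    lo = np.maximum(a, a0)
    hi = np.maximum(b, lo)
    if r == 0.0:
        # lo may be +inf (an interval that never starts): length 0
        with np.errstate(invalid="ignore"):
            return np.where(hi > lo, hi - lo, 0.0)
    if mode == "continuous":
        return (np.exp(-r * (lo - a0)) - np.exp(-r * (hi - a0))) / r
    # annual-step: constant factor (1+r)^{-k} on each year [a0+k, a0+k+1)
    out = np.zeros(lo.shape)
    hi_max = float(np.max(hi, initial=a0))
    k = 0
    while a0 + k < hi_max:
        overlap = np.clip(np.minimum(hi, a0 + k + 1.0) - np.maximum(lo, a0 + k), 0.0, None)
        out += (1.0 + r) ** (-k) * overlap
        k += 1
    return out


# --------------------------------------------------------------------------
# Per-trajectory accrual (scalar API) and vectorised counterparts
# --------------------------------------------------------------------------

def accrue_qalys(
    trajectory: Trajectory,
    utilities: UtilityTable,
    r: float = 0.03,
    window: tuple[float, float] = (14.0, 30.0),
    mode: str = "continuous",
) -> float:
    """Discounted QALYs of one trajectory over the accrual window.

    QALY = ∫ u(stratum, status(t)) e^{-r(t-a0)} dt over [a0, min(death, T)]
    with the utility switching at the first onset; both switch and death
    instants are handled exactly through the closed-form integral.
    """
    a0, T = window
    st = trajectory.stratum
    end = T if trajectory.death_age is None else min(trajectory.death_age, T)
    first = trajectory.first_onset_age
    switch = end if first is None else float(np.clip(first, a0, end))
    u_none = utilities(st.gender, st.ses, "none")
    u_any = utilities(st.gender, st.ses, "any")
    q = u_none * discounted_years(a0, switch, r, a0, mode)
    q += u_any * discounted_years(switch, end, r, a0, mode)
    return float(q)


def accrue_costs(
    trajectory: Trajectory,
    costs: CostTable,
    r: float = 0.03,
    window: tuple[float, float] = (14.0, 30.0),
    perspective: str = "societal",
) -> dict[str, float]:
    """Discounted disease costs of one trajectory, by category.

    Each cluster with onset before min(death, horizon) accrues its annual
    per-patient cost continuously from max(onset, a0) to min(death, T);
    categories are additive across co-occurring clusters.  The healthcare
    perspective reports the healthcare category only.
    """
    if perspective not in PERSPECTIVES:
        raise ParameterError(f"unknown perspective {perspective!r}")
    a0, T = window
    end = T if trajectory.death_age is None else min(trajectory.death_age, T)
    cats = ("healthcare",) if perspective == "healthcare" else COST_CATEGORIES
    out = {cat: 0.0 for cat in cats}
    for cluster in CLUSTERS:
        onset = trajectory.onset_age.get(cluster)
        if onset is None or onset >= end:
            continue
        years = float(discounted_years(max(onset, a0), end, r, a0, "continuous"))
        for cat in cats:
            out[cat] += costs.annual_cost(cluster, cat) * years
    return out


def add_intervention_cost(
    scenario_totals: dict[str, float],
    per_student: float,
    n: int,
) -> dict[str, float]:
    """Charge the one-off per-student cost to an intervention scenario's totals.

    The cost is undiscounted and universal: every simulated individual is a
    student of the programme, so the total is exactly ``per_student * n``.
    """
    out = dict(scenario_totals)
    out["intervention"] = out.get("intervention", 0.0) + per_student * n
    return out


def _vector_qalys(
    arrays: ScenarioArrays,
    gender_idx: np.ndarray,
    ses_idx: np.ndarray,
    utilities: UtilityTable,
    r: float,
    window: tuple[float, float],
    mode: str,
) -> np.ndarray:
    a0, T = window
    end = np.minimum(arrays.death, T)
    end = np.maximum(end, a0)
    first = arrays.first_onset
    switch = np.where(np.isnan(first), end, np.clip(first, a0, end))
    u_none = np.empty(len(end))
    u_any = np.empty(len(end))
    for gi, g in enumerate(GENDERS):
        for si, s in enumerate(SES_LEVELS):
            m = (gender_idx == gi) & (ses_idx == si)
            u_none[m] = utilities(g, s, "none")
            u_any[m] = utilities(g, s, "any")
    return u_none * discounted_years(a0, switch, r, a0, mode) + u_any * discounted_years(
        switch, end, r, a0, mode
    )


def _vector_costs(
    arrays: ScenarioArrays,
    costs: CostTable,
    r: float,
    window: tuple[float, float],
    mode: str,
) -> dict[str, np.ndarray]:
    a0, T = window
    end = np.minimum(arrays.death, T)
    end = np.maximum(end, a0)
    onset = arrays.onset
    start = np.maximum(np.where(np.isnan(onset), np.inf, onset), a0)
    years = discounted_years(start, end[:, None], r, a0, mode)
    return {
        cat: years @ costs.category_vector(cat) for cat in COST_CATEGORIES
    }


# --------------------------------------------------------------------------
# Aggregation
# --------------------------------------------------------------------------

@dataclass
class EconResult:
    """Mean per-person costs (€, by category) and QALYs per scenario/subgroup.

    ``table`` is indexed by (scenario, subgroup) with subgroup ``total`` or
    ``<gender>/<ses>``; columns: the three cost categories, the
    per-person intervention cost, and ``qaly``.  ``discounted`` records
    which discount rate was applied.
    """

    table: pd.DataFrame
    discount_rate: float
    n: int

    def row(self, scenario: str, subgroup: str = "total") -> pd.Series:
        return self.table.loc[(scenario, subgroup)]


def summarize_economics(
    paired: PairedTrajectories,
    utilities: UtilityTable,
    costs: CostTable,
    r: float = 0.03,
    window: tuple[float, float] = (14.0, 30.0),
    mode: str = "continuous",
) -> EconResult:
    """Accrue and aggregate QALYs and costs for both scenarios.

    The per-student intervention cost is charged to the intervention
    scenario only, once per simulated individual, undiscounted.
    """
    pop = paired.population
    rows = []
    for arrays, label in ((paired.base, "base"), (paired.intervention, "intervention")):
        qalys = _vector_qalys(arrays, pop.gender_idx, pop.ses_idx, utilities, r, window, mode)
        cost_vecs = _vector_costs(arrays, costs, r, window, mode)
        iv = costs.intervention_cost_per_student if label == "intervention" else 0.0
        subgroups: list[tuple[str, np.ndarray]] = [("total", np.ones(len(pop), dtype=bool))]
        subgroups += [(str(st), pop.stratum_mask(st)) for st in STRATA]
        for name, mask in subgroups:
            m = int(mask.sum())
            if m == 0:
                continue
            row = {"scenario": label, "subgroup": name, "n": m,
                   "intervention": iv, "qaly": float(qalys[mask].mean())}
            for cat in COST_CATEGORIES:
                row[cat] = float(cost_vecs[cat][mask].mean())
            rows.append(row)
    table = pd.DataFrame(rows).set_index(["scenario", "subgroup"])
    return EconResult(table=table, discount_rate=r, n=len(pop))


# --------------------------------------------------------------------------
# Incremental cost-utility
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CUAResult:
    """Incremental cost-utility result for one subgroup and perspective.

    ``icur`` (€/QALY) is populated only when both ΔC and ΔQ are positive;
    otherwise ``label`` reports dominance ("dominant": cheaper and more
    effective; "dominated": dearer and less effective) or why the ratio is
    undefined.
    """

    perspective: str
    subgroup: str
    base_cost: float
    intervention_cost: float
    base_qaly: float
    intervention_qaly: float
    delta_cost: float
    delta_qaly: float
    icur: float | None
    label: str


def _classify(delta_cost: float, delta_qaly: float) -> tuple[float | None, str]:
    if delta_cost < 0.0 and delta_qaly > 0.0:
        return None, "dominant"
    if delta_cost > 0.0 and delta_qaly < 0.0:
        return None, "dominated"
    if delta_qaly == 0.0:
        return None, "no QALY difference" if delta_cost != 0.0 else "no difference"
    if delta_cost > 0.0 and delta_qaly > 0.0:
        return delta_cost / delta_qaly, "icur"
    # cheaper and less effective: the ratio is a south-west quadrant
    # trade-off, not an ICUR in the usual sense
    return None, "less costly, less effective"


def _perspective_cost(row: pd.Series, perspective: str) -> float:
    if perspective == "healthcare":
        return float(row["healthcare"] + row["intervention"])
    return float(sum(row[cat] for cat in COST_CATEGORIES) + row["intervention"])


def cost_utility(
    base: EconResult,
    intervention: EconResult,
    perspective: str = "healthcare",
) -> list[CUAResult]:
    """Incremental cost-utility per subgroup for one perspective.

    ``base`` and ``intervention`` are usually the two scenario blocks of a
    single :class:`EconResult` from a cloned run; passing the same object
    twice selects the matching scenario rows.
    """
    if perspective not in PERSPECTIVES:
        raise ParameterError(f"unknown perspective {perspective!r}")
    results = []
    base_block = base.table.loc["base"]
    int_block = intervention.table.loc["intervention"]
    for subgroup in base_block.index:
        if subgroup not in int_block.index:
            continue
        b = base_block.loc[subgroup]
        u = int_block.loc[subgroup]
        bc = _perspective_cost(b, perspective)
        uc = _perspective_cost(u, perspective)
        dc = uc - bc
        dq = float(u["qaly"] - b["qaly"])
        icur, label = _classify(dc, dq)
        results.append(CUAResult(
            perspective=perspective, subgroup=str(subgroup),
            base_cost=bc, intervention_cost=uc,
            base_qaly=float(b["qaly"]), intervention_qaly=float(u["qaly"]),
            delta_cost=dc, delta_qaly=dq, icur=icur, label=label,
        ))
    return results
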