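"""Operational validation: goodness of fit of simulated vs observed incidence.

The simulator's age-specific cumulative incidence (counted from the base-
case trajectories) is compared with the input curves for every cluster and
stratum using a standard model-evaluation battery:

* ``r``    - Pearson correlation,
* ``NMSE`` - normalised mean square error, mean((O-P)^2)/(mean(O)·mean(P)),
* ``FB``   - fractional bias, 2·(mean(O)-mean(P))/(mean(O)+mean(P)),
* ``FV``   - fractional variance, 2·(sd(O)-sd(P))/(sd(O)+sd(P)),
* ``FAC2`` - fraction of predictions within a factor of two of the
  observation (boundaries inclusive; zero observations excluded from the
  ratio).

The default pass thresholds are the conventional model-evaluation bounds
(|FB| <= 0.3, NMSE <= 1.5, FAC2 >= 0.8, r >= 0.9, |FV| <= 0.5) and are
configurable.  At small simulated population sizes binomial sampling error
dominates every statistic, so the report carries a warning instead of a
meaningful verdict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .des_engine import PairedTrajectories
from .parameters import AGES, CLUSTERS, STRATA, CIFTable, ParameterError

__all__ = [
    "GofEntry",
    "GofReport",
    "DEFAULT_THRESHOLDS",
    "gof_stats",
    "simulated_cumulative_incidence",
    "operational_validation",
]


@dataclass(frozen=True)
class GofEntry:
    """Goodness-of-fit statistics for one observed/predicted series pair."""

    r: float  # Pearson correlation; NaN when either series is constant
    nmse: float
    fb: float
    fv: float
    fac2: float


DEFAULT_THRESHOLDS: dict[str, float] = {
    "abs_fb_max": 0.3,
    "nmse_max": 1.5,
    "fac2_min": 0.8,
    "r_min": 0.9,
    "abs_fv_max": 0.5,
}

#: Below this simulated population size, sampling error dominates the
#: statistics and the validation verdict is not meaningful.
SMALL_N_WARNING: int = 10_000


def gof_stats(observed, predicted, fac2_min_observed: float = 0.0) -> GofEntry:
    """Compute the five goodness-of-fit statistics for two series.

    Both series must be equal-length and non-negative; FAC2 ratios skip
    time points with a zero observation and, when ``fac2_min_observed`` is
    set, points below it (the usual sparse-data guard: a factor-of-two
    ratio is uninformative where almost no events are expected).  A
    constant series makes the Pearson correlation undefined (reported as
    NaN); zero means make NMSE and FB undefined and raise.
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.ndim != 1 or len(o) == 0:
        raise ParameterError("observed and predicted must be equal-length 1-d series")
    if np.any(o < 0) or np.any(p < 0):
        raise ParameterError("series must be non-negative")
    mo, mp = o.mean(), p.mean()
    if mo == 0.0 or mp == 0.0:
        raise ParameterError("zero mean series: NMSE and FB undefined")
    nmse = float(np.mean((o - p) ** 2) / (mo * mp))
    fb = float(2.0 * (mo - mp) / (mo + mp))
    so, sp = o.std(), p.std()
    fv = 0.0 if (so == 0.0 and sp == 0.0) else float(2.0 * (so - sp) / (so + sp))
    if so == 0.0 or sp == 0.0:
        r = math.nan
    else:
        r = float(np.corrcoef(o, p)[0, 1])
    nonzero = o > max(0.0, fac2_min_observed)
    if nonzero.any():
        ratio = p[nonzero] / o[nonzero]
        fac2 = float(np.mean((ratio >= 0.5) & (ratio <= 2.0)))
    else:
        fac2 = 1.0  # no informative points: vacuously within a factor of two
    return GofEntry(r=r, nmse=nmse, fb=fb, fv=fv, fac2=fac2)


def _passes(entry: GofEntry, thr: dict[str, float]) -> bool:
    checks = [
        abs(entry.fb) <= thr["abs_fb_max"],
        entry.nmse <= thr["nmse_max"],
        entry.fac2 >= thr["fac2_min"],
        abs(entry.fv) <= thr["abs_fv_max"],
    ]
    if not math.isnan(entry.r):
        checks.append(entry.r >= thr["r_min"])
    return all(checks)


@dataclass
class GofReport:
    """Per-cell and pooled goodness-of-fit with pass/fail verdicts."""

    table: pd.DataFrame
    pooled: GofEntry
    passed: bool
    thresholds: dict[str, float]
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return self.table


def simulated_cumulative_incidence(
    paired: PairedTrajectories, scenario: str = "base"
) -> CIFTable:
    """Cumulative incidence counted from simulated trajectories.

    For each cluster, stratum and integer age t: the fraction of the
    stratum with onset at or before t.  Onsets are censored at death in
    the trajectories, so at realistic (low) mortality this is directly
    comparable with the input cumulative incidence.
    """
    arrays = paired.base if scenario == "base" else paired.intervention
    pop = paired.population
    table = CIFTable.zeros()
    for st in STRATA:
        mask = pop.stratum_mask(st)
        m = int(mask.sum())
        if m == 0:
            raise ParameterError(f"empty stratum {st} in simulated run")
        onset = arrays.onset[mask]
        for k, cluster in enumerate(CLUSTERS):
            ages = onset[:, k]
            counts = np.array([np.sum(ages <= t) for t in AGES], dtype=float)
            table.set_curve(cluster, st, counts / m)
    return table


def operational_validation(
    paired: PairedTrajectories,
    input_cif: CIFTable,
    thresholds: dict[str, float] | None = None,
    fac2_min_expected_events: float = 10.0,
) -> GofReport:
    """Compare simulated base-case incidence against the input curves.

    One goodness-of-fit entry per cluster x stratum (observed = input
    curve, predicted = simulated curve on the annual grid) plus a pooled
    entry over all cells; the run passes when every cell meets every
    threshold.  FAC2 ratios are evaluated only at grid ages where the
    input curve implies at least ``fac2_min_expected_events`` onsets in
    the stratum, since the factor-of-two criterion carries no information
    where essentially no events are expected.
    """
    if len(paired.population) == 0:
        raise ParameterError("empty run")
    thr = dict(DEFAULT_THRESHOLDS)
    thr.update(thresholds or {})
    simulated = simulated_cumulative_incidence(paired, "base")
    rows = []
    all_obs: list[np.ndarray] = []
    all_pred: list[np.ndarray] = []
    for cluster in CLUSTERS:
        for st in STRATA:
            n_stratum = int(paired.population.stratum_mask(st).sum())
            o = np.asarray(input_cif.curve(cluster, st))
            p = np.asarray(simulated.curve(cluster, st))
            try:
                entry = gof_stats(
                    o, p,
                    fac2_min_observed=fac2_min_expected_events / max(n_stratum, 1),
                )
            except ParameterError:
                # no simulated (or no expected) events in this cell: the
                # statistics are undefined, which counts as a failure
                entry = GofEntry(math.nan, math.nan, math.nan, math.nan, math.nan)
            rows.append({
                "cluster": cluster, "gender": st.gender, "ses": st.ses,
                "r": entry.r, "nmse": entry.nmse, "fb": entry.fb,
                "fv": entry.fv, "fac2": entry.fac2,
                "pass": _passes(entry, thr),
            })
            all_obs.append(o)
            all_pred.append(p)
    pooled = gof_stats(np.concatenate(all_obs), np.concatenate(all_pred))
    table = pd.DataFrame(rows)
    warnings = []
    if len(paired.population) < SMALL_N_WARNING:
        warnings.append(
            f"simulated population n={len(paired.population)} < {SMALL_N_WARNING}: "
            "sampling error dominates the statistics; thresholds are not meaningful"
        )
    return GofReport(
        table=table,
        pooled=pooled,
        passed=bool(table["pass"].all()),
        thresholds=thr,
        warnings=warnings,
    )
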