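"""Cumulative incidence estimation under competing risks (Aalen–Johansen).

For each diagnostic cluster the event of interest (first onset) competes
with death and with file closure (censoring).  The Aalen–Johansen
estimator combines the all-cause Kaplan–Meier survivor with cause-specific
event fractions:

    CIF_k(t) = sum_{t_j <= t} S(t_j-) * d_kj / n_j

where n_j is the risk set at event time t_j, d_kj the number of type-k
events there, and S the left-limit of the all-cause Kaplan–Meier survivor.
With no censoring and no competing events the estimator reduces exactly to
the empirical CDF of the event ages.

A pointwise variance of Aalen type is computed and reported alongside the
point estimate; the downstream simulation consumes the point curves only.
Curves are read off the step function at integer ages (right-continuous);
beyond the last observed risk time the value is carried forward flat and
flagged as extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import (
    AGES,
    CLUSTERS,
    HORIZON,
    STRATA,
    CIFTable,
    ParameterError,
    Stratum,
    canonical_cluster,
)

__all__ = ["AJCurve", "aalen_johansen", "estimate_cif_table"]


@dataclass
class AJCurve:
    """An Aalen–Johansen cumulative-incidence step function.

    ``times`` are the distinct event/censoring times, ``cif`` the estimate
    just after each time, ``variance`` the Aalen-type pointwise variance,
    ``survival`` the all-cause Kaplan–Meier survivor just after each time.
    ``last_risk_time`` is the largest observed exit time; values read off
    beyond it are extrapolated (carried forward flat).
    """

    times: np.ndarray
    cif: np.ndarray
    variance: np.ndarray
    survival: np.ndarray
    last_risk_time: float

    def at(self, ages: np.ndarray) -> np.ndarray:
        """Right-continuous step-function value at each age (0 before the
        first event time, carried forward flat after the last)."""
        ages = np.asarray(ages, dtype=float)
        idx = np.searchsorted(self.times, ages, side="right") - 1
        out = np.where(idx >= 0, self.cif[np.clip(idx, 0, None)], 0.0)
        return out

    def variance_at(self, ages: np.ndarray) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        idx = np.searchsorted(self.times, ages, side="right") - 1
        return np.where(idx >= 0, self.variance[np.clip(idx, 0, None)], 0.0)

    def extrapolated(self, ages: np.ndarray) -> np.ndarray:
        """Boolean flag per age: True where the value is carried forward
        beyond the last observed risk time."""
        return np.asarray(ages, dtype=float) > self.last_risk_time


def _records_for_cluster(records: pd.DataFrame, target: str) -> pd.DataFrame:
    """Rows belonging to the target cluster's competing-risks picture."""
    if "cluster" in records.columns:
        return records[records["cluster"] == target]
    return records


def aalen_johansen(records: pd.DataFrame, target_cluster: str) -> AJCurve:
    """Aalen–Johansen estimate of one cluster's CIF from event records.

    ``records`` must carry ``exit_age`` and ``outcome`` columns (outcomes
    ``onset:<cluster>``, ``death`` or ``censored``); a ``cluster`` column,
    when present, selects the rows of the target cluster's picture.  All
    events sharing an exit time are processed against the same risk set.
    """
    target = canonical_cluster(target_cluster)
    sub = _records_for_cluster(records, target)
    if len(sub) == 0:
        raise ParameterError(f"no event records for cluster {target}")
    exit_age = sub["exit_age"].to_numpy(dtype=float)
    if np.any(exit_age <= 0):
        raise ParameterError("exit ages must be positive")
    outcome = sub["outcome"].to_numpy(dtype=object)
    is_target = outcome == f"onset:{target}"
    is_death = outcome == "death"
    is_other_onset = np.array(
        [str(o).startswith("onset:") for o in outcome]
    ) & ~is_target
    # any non-censored exit is an all-cause event; onsets of other clusters
    # present in a single-cluster picture act as competing events
    is_event = is_target | is_death | is_other_onset

    order = np.argsort(exit_age, kind="mergesort")
    t_sorted = exit_age[order]
    times, start = np.unique(t_sorted, return_index=True)
    m = len(times)
    counts_all = np.diff(np.append(start, len(t_sorted)))
    d_target = np.zeros(m)
    d_event = np.zeros(m)
    np.add.at(d_target, np.searchsorted(times, exit_age[is_target]), 1.0)
    np.add.at(d_event, np.searchsorted(times, exit_age[is_event]), 1.0)
    n_total = len(sub)
    # risk set just before each time (everyone with exit >= t)
    n_risk = n_total - np.concatenate(([0.0], np.cumsum(counts_all)[:-1]))

    s_prev = np.concatenate(([1.0], np.cumprod(1.0 - d_event / n_risk)[:-1]))
    increments = s_prev * d_target / n_risk
    cif = np.cumsum(increments)
    survival = s_prev * (1.0 - d_event / n_risk)

    variance = _aalen_variance(times, n_risk, d_event, d_target, s_prev, cif)
    return AJCurve(
        times=times,
        cif=cif,
        variance=variance,
        survival=survival,
        last_risk_time=float(times[-1]),
    )


def _aalen_variance(times, n_risk, d_event, d_target, s_prev, cif) -> np.ndarray:
    """Aalen-type pointwise variance of the CIF estimate.

    Var(t) = sum_{j<=t} (CIF(t)-CIF(t_j))^2 d_j / (n_j (n_j - d_j))
           + sum_{j<=t} s_prev_j^2 (n_j - d_kj)/n_j * d_kj / n_j^2
           - 2 sum_{j<=t} (CIF(t)-CIF(t_j)) s_prev_j d_kj / n_j^2
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(n_risk > d_event, d_event / (n_risk * (n_risk - d_event)), 0.0)
    b = s_prev**2 * (n_risk - d_target) / n_risk * d_target / n_risk**2
    c = s_prev * d_target / n_risk**2
    # cumulative sums let Var(t_i) be formed from prefix terms only
    ca, cb, cc = np.cumsum(a), np.cumsum(b), np.cumsum(c)
    ca_cif = np.cumsum(a * cif)
    ca_cif2 = np.cumsum(a * cif**2)
    cc_cif = np.cumsum(c * cif)
    var = (
        cif**2 * ca - 2.0 * cif * ca_cif + ca_cif2
        + cb
        - 2.0 * (cif * cc - cc_cif)
    )
    return np.clip(var, 0.0, None)


def estimate_cif_table(
    records: pd.DataFrame,
    clusters: tuple[str, ...] = CLUSTERS,
    strata: tuple[Stratum, ...] = STRATA,
) -> tuple[CIFTable, pd.DataFrame]:
    """Estimate a full CIF table from event records grouped by stratum.

    Returns the table (values at integer ages 1..30, right-continuous
    read-off) together with a flags frame marking (cluster, stratum, age)
    cells whose value is a flat extrapolation beyond the stratum's last
    observed risk time.  A requested stratum with no records raises a
    named error; strata outside ``strata`` are reported as absent in the
    flags frame and left at zero.
    """
    required = {"gender", "ses", "exit_age", "outcome"}
    missing = required - set(records.columns)
    if missing:
        raise ParameterError(f"event records missing columns: {sorted(missing)}")
    clusters = tuple(canonical_cluster(c) for c in clusters)
    table = CIFTable.zeros()
    flag_rows = []
    for stratum in STRATA:
        if stratum not in strata:
            flag_rows.append((None, stratum.gender, stratum.ses, None, "absent"))
            continue
        mask = (records["gender"] == stratum.gender) & (records["ses"] == stratum.ses)
        sub = records[mask]
        if len(sub) == 0:
            raise ParameterError(
                f"no event records for stratum gender={stratum.gender} "
                f"ses={stratum.ses}"
            )
        for cluster in clusters:
            curve = aalen_johansen(sub, cluster)
            table.set_curve(cluster, stratum, curve.at(AGES))
            for age, extra in zip(AGES, curve.extrapolated(AGES)):
                if extra:
                    flag_rows.append(
                        (cluster, stratum.gender, stratum.ses, int(age), "extrapolated")
                    )
    flags = pd.DataFrame(
        flag_rows, columns=["cluster", "gender", "ses", "age", "flag"]
    )
    return table, flags
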