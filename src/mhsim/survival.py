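"""Parametric survival for time until death.

All-cause mortality is modelled by a Gompertz distribution stratified by
gender and by disorder status (any mental disorder yet vs none); mortality
is not disaggregated by diagnostic cluster because deaths before age 30 are
rare.  The family is chosen by maximum likelihood with AIC-based selection
among exponential, Weibull and Gompertz candidates.

Death times are sampled by inverse-CDF from a piecewise hazard: the
no-disorder hazard applies before the first disorder onset and the
with-disorder hazard after it, with a survivor function continuous at the
switch.  Because the same uniform deviate maps deterministically to a death
time, the cloned base-case and intervention copies of an individual differ
only through their (possibly shifted) switch age.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .parameters import Gompertz, ParameterError

__all__ = [
    "ParametricFit",
    "fit_parametric",
    "select_by_aic",
    "sample_death_time",
    "sample_death_times",
    "gompertz_hazard",
    "gompertz_cumhaz",
    "gompertz_inv_cumhaz",
]

_SHAPE_EPS = 1e-12
FAMILIES = ("exponential", "weibull", "gompertz")
_N_PARAMS = {"exponential": 1, "weibull": 2, "gompertz": 2}


# --------------------------------------------------------------------------
# Gompertz primitives (shape may be ~0; the exponential limit is handled)
# --------------------------------------------------------------------------

def gompertz_hazard(t, shape: float, rate: float):
    """h(t) = rate * exp(shape * t)."""
    return rate * np.exp(shape * np.asarray(t, dtype=float))


def gompertz_cumhaz(t, shape: float, rate: float):
    """H(t) = rate/shape * (exp(shape*t) - 1); rate*t in the shape->0 limit."""
    t = np.asarray(t, dtype=float)
    if abs(shape) < _SHAPE_EPS:
        return rate * t
    return rate / shape * np.expm1(shape * t)


def gompertz_inv_cumhaz(L, shape: float, rate: float):
    """Inverse of the cumulative hazard: t with H(t) = L."""
    L = np.asarray(L, dtype=float)
    if abs(shape) < _SHAPE_EPS:
        return L / rate
    return np.log1p(shape * L / rate) / shape


# --------------------------------------------------------------------------
# Maximum-likelihood fitting with right censoring
# --------------------------------------------------------------------------

@dataclass
class ParametricFit:
    """A fitted parametric survival family over one or more groups.

    ``params`` maps each group label to its parameter dict; ``se`` holds the
    corresponding standard errors from the observed information.  ``aic`` is
    2k - 2 ln L with k the total number of free parameters across groups.
    """

    family: str
    params: dict[object, dict[str, float]]
    se: dict[object, dict[str, float]]
    log_likelihood: float
    n_params: int

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.log_likelihood


def _neg_loglik(family: str, theta: np.ndarray, t: np.ndarray, d: np.ndarray) -> float:
    """Negative log-likelihood with right censoring; theta on the log scale
    for positive parameters."""
    if family == "exponential":
        rate = np.exp(theta[0])
        ll = np.sum(d) * theta[0] - rate * np.sum(t)
    elif family == "weibull":
        # h(t) = (rho/lam) * (t/lam)^(rho-1); H(t) = (t/lam)^rho
        rho, lam = np.exp(theta)
        z = t / lam
        ll = np.sum(d * (np.log(rho / lam) + (rho - 1.0) * np.log(z))) - np.sum(z ** rho)
    elif family == "gompertz":
        shape = theta[0]  # shape may be negative
        rate = np.exp(theta[1])
        ll = np.sum(d * (theta[1] + shape * t)) - np.sum(gompertz_cumhaz(t, shape, rate))
    else:  # pragma: no cover
        raise ParameterError(f"unknown family {family!r}")
    return -float(ll)


def _hessian(f, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central finite-difference Hessian."""
    n = len(x)
    h = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            h[i, j] = h[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * eps * eps)
    return h


def _fit_one_group(family: str, t: np.ndarray, d: np.ndarray):
    n_events = int(d.sum())
    if n_events == 0:
        raise ParameterError("cannot fit a survival model with zero events")
    if n_events < 2:
        raise ParameterError("need at least 2 events per group")
    total_time = float(t.sum())
    rate0 = n_events / total_time
    if family == "exponential":
        x0 = np.array([np.log(rate0)])
    elif family == "weibull":
        x0 = np.array([0.0, np.log(1.0 / rate0)])
    else:  # gompertz
        x0 = np.array([0.01, np.log(rate0)])
    nll = lambda th: _neg_loglik(family, th, t, d)
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 5000})
    res = optimize.minimize(nll, res.x, method="BFGS",
                            options={"gtol": 1e-8, "maxiter": 500})
    if not np.all(np.isfinite(res.x)):
        raise ParameterError(f"{family} fit did not converge: {res.message}")
    theta = res.x
    # delta-method SEs on the natural scale
    try:
        hess = _hessian(nll, theta)
        cov = np.linalg.inv(hess)
        se_theta = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se_theta = np.full(len(theta), np.nan)
    if family == "exponential":
        rate = float(np.exp(theta[0]))
        params = {"rate": rate}
        se = {"rate": rate * float(se_theta[0])}
    elif family == "weibull":
        rho, lam = np.exp(theta)
        params = {"rho": float(rho), "lambda": float(lam)}
        se = {"rho": float(rho * se_theta[0]), "lambda": float(lam * se_theta[1])}
    else:
        shape = float(theta[0]); rate = float(np.exp(theta[1]))
        params = {"shape": shape, "rate": rate}
        se = {"shape": float(se_theta[0]), "rate": rate * float(se_theta[1])}
    return params, se, -float(res.fun)


def fit_parametric(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence[object] | None = None,
    family: str = "gompertz",
) -> ParametricFit:
    """Fit one parametric family by maximum likelihood, per group.

    Parameters
    ----------
    times, events
        Observation times and event indicators (1 = death observed,
        0 = right-censored).
    groups
        Optional group label per observation (e.g. (gender, status) pairs);
        parameters are estimated independently per group and the AIC counts
        all free parameters.
    family
        One of ``exponential``, ``weibull``, ``gompertz``.
    """
    if family not in FAMILIES:
        raise ParameterError(f"family must be one of {FAMILIES}, got {family!r}")
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=float)
    if t.shape != d.shape or t.ndim != 1 or len(t) == 0:
        raise ParameterError("times and events must be equal-length 1-d arrays")
    if np.any(t < 0):
        raise ParameterError("negative observation time")
    if groups is None:
        labels = np.zeros(len(t), dtype=int)
        group_keys: list[object] = [0]
    else:
        labels = np.asarray(groups, dtype=object)
        group_keys = sorted(set(labels.tolist()), key=repr)
    params: dict[object, dict[str, float]] = {}
    ses: dict[object, dict[str, float]] = {}
    total_ll = 0.0
    for key in group_keys:
        mask = labels == key if groups is not None else np.ones(len(t), dtype=bool)
        p, se, ll = _fit_one_group(family, t[mask], d[mask])
        params[key] = p
        ses[key] = se
        total_ll += ll
    if groups is None:
        params = params[0]  # type: ignore[assignment]
        ses = ses[0]  # type: ignore[assignment]
        params, ses = {None: params}, {None: ses}  # type: ignore[dict-item]
    return ParametricFit(
        family=family,
        params=params,
        se=ses,
        log_likelihood=total_ll,
        n_params=_N_PARAMS[family] * len(group_keys),
    )


def select_by_aic(fits: Sequence[ParametricFit]) -> ParametricFit:
    """Minimum-AIC fit; ties broken in favour of fewer free parameters."""
    fits = list(fits)
    if not fits:
        raise ParameterError("select_by_aic requires at least one fit")
    return min(fits, key=lambda f: (f.aic, f.n_params))


# --------------------------------------------------------------------------
# Death-time sampling with a mid-life status switch
# --------------------------------------------------------------------------

def sample_death_times(
    u: np.ndarray,
    no_disorder: Gompertz,
    with_disorder: Gompertz,
    switch_age: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorised inverse-CDF death-time draw from the piecewise hazard.

    ``switch_age`` gives the age at first disorder onset per individual
    (NaN = never).  The no-disorder hazard applies before the switch, the
    with-disorder hazard after, and the survivor function is continuous at
    the switch, so the cumulative hazard is

        H(t) = H0(t)                              t <  s
        H(t) = H0(s) + H1(t) - H1(s)              t >= s.

    The draw solves H(t) = -log(1 - u); it is monotone in ``u`` and
    continuous in ``s``.  Death ages may exceed the simulation horizon.
    """
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0.0) | (u >= 1.0)):
        raise ParameterError("uniforms must lie strictly inside (0, 1)")
    target = -np.log1p(-u)
    t0 = gompertz_inv_cumhaz(target, no_disorder.shape, no_disorder.rate)
    if switch_age is None:
        return t0
    s = np.asarray(switch_age, dtype=float)
    out = np.array(t0, dtype=float, copy=True)
    has_switch = ~np.isnan(s)
    h0s = gompertz_cumhaz(np.where(has_switch, s, 0.0), no_disorder.shape, no_disorder.rate)
    after = has_switch & (target > h0s)
    if np.any(after):
        h1s = gompertz_cumhaz(s[after], with_disorder.shape, with_disorder.rate)
        out[after] = gompertz_inv_cumhaz(
            target[after] - h0s[after] + h1s,
            with_disorder.shape, with_disorder.rate,
        )
    return out


def sample_death_time(
    u: float,
    by_status: Mapping[str, Gompertz],
    status_switch_age: float | None = None,
) -> float:
    """Scalar death-time draw; see :func:`sample_death_times`.

    ``by_status`` maps ``"none"`` and ``"any"`` to Gompertz parameters.
    """
    switch = None if status_switch_age is None else np.array([float(status_switch_age)])
    t = sample_death_times(
        np.array([float(u)]), by_status["none"], by_status["any"], switch
    )
    return float(t[0])
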