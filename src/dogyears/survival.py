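"""Survival and mortality-rate models.

The central parametric model is the Gompertz hazard

    mu(x) = alpha * exp(beta * x)

whose log is linear in age; the slope ``beta`` (per year) is the demographic
"rate of aging" and the main quantity compared across cohorts.  Fitting is by
direct likelihood maximization, either on exact ages at death or on binned
(interval-censored) ages, where an individual known to die in [lo, hi)
contributes S(lo) - S(hi) to the likelihood.

Also here: the Kaplan-Meier product-limit estimator, a kernel-smoothed
hazard-rate estimator (smoothed Nelson-Aalen increments, Epanechnikov kernel
with boundary renormalization), and a one-covariate proportional-hazards
contrast (Breslow partial likelihood with a Wald test) used for the
within-cohort sex effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from scipy import optimize, stats

__all__ = [
    "GompertzParams",
    "SurvivalCurve",
    "HazardCurve",
    "gompertz_survival",
    "gompertz_hazard",
    "fit_gompertz",
    "km_estimate",
    "smoothed_hazard",
    "two_group_hazard_ratio",
    "GompertzFitError",
]

_BETA_TINY = 1e-9  # below this |beta| the exponential limit is used


class GompertzFitError(RuntimeError):
    """Gompertz optimization failed; carries the last iterate."""

    def __init__(self, message: str, last_iterate: tuple[float, float] | None = None):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz hazard parameters: baseline ``alpha`` (per year, > 0) and
    slope ``beta`` (per year; may be negative for a declining hazard)."""

    alpha: float
    beta: float
    log_likelihood: float = float("nan")

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate: S(t) with at-risk and event counts."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def at(self, t: float) -> float:
        """Step-function evaluation of S at time t (S(0-) = 1)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class HazardCurve:
    grid: np.ndarray
    hazard: np.ndarray
    bandwidth: float


def _cumhaz(alpha: float, beta: float, x: np.ndarray) -> np.ndarray:
    """Integrated Gompertz hazard H(x) = (alpha/beta)(e^{beta x} - 1)."""
    x = np.asarray(x, dtype=float)
    if abs(beta) < _BETA_TINY:
        return alpha * x
    return (alpha / beta) * np.expm1(beta * x)


def gompertz_survival(params: GompertzParams, age) -> np.ndarray | float:
    """Closed-form survival S(x) = exp(-(alpha/beta)(e^{beta x} - 1))."""
    out = np.exp(-_cumhaz(params.alpha, params.beta, age))
    return float(out) if np.isscalar(age) else out


def gompertz_hazard(params: GompertzParams, age) -> np.ndarray | float:
    """Instantaneous mortality rate mu(x) = alpha * e^{beta x}."""
    out = params.alpha * np.exp(params.beta * np.asarray(age, dtype=float))
    return float(out) if np.isscalar(age) else out


def _gompertz_nll_exact(theta, times, events):
    log_alpha, beta = theta
    alpha = np.exp(log_alpha)
    cum = _cumhaz(alpha, beta, times)
    ll = np.sum(events * (log_alpha + beta * times)) - np.sum(cum)
    return -ll


def _gompertz_nll_interval(theta, lo, hi, events):
    """hi may be inf (open top bin); censored rows contribute S(lo)."""
    log_alpha, beta = theta
    alpha = np.exp(log_alpha)
    s_lo = np.exp(-_cumhaz(alpha, beta, lo))
    s_hi = np.where(np.isfinite(hi), np.exp(-_cumhaz(alpha, beta, np.where(np.isfinite(hi), hi, 0.0))), 0.0)
    prob = np.where(events, np.maximum(s_lo - s_hi, 1e-300), np.maximum(s_lo, 1e-300))
    return -np.sum(np.log(prob))


def _init_from_lifetable(times: np.ndarray, events: np.ndarray) -> tuple[float, float]:
    """Least-squares line through log occurrence/exposure hazard.

    Ages are cut into ~15 quantile bins; the empirical hazard in a bin is
    deaths / person-years of exposure; a line through log-hazard vs bin
    midpoint gives (log alpha, beta) starting values.
    """
    deaths = times[events.astype(bool)]
    if deaths.size < 2:
        return float(np.log(1.0 / max(times.mean(), 1e-6))), 0.01
    edges = np.unique(np.quantile(deaths, np.linspace(0, 1, 16)))
    if edges.size < 3:
        return float(np.log(1.0 / max(times.mean(), 1e-6))), 0.01
    mids, log_h = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        exposure = np.sum(np.clip(np.minimum(times, hi) - lo, 0.0, None))
        d = np.sum((deaths >= lo) & (deaths < hi))
        if d > 0 and exposure > 0:
            mids.append((lo + hi) / 2.0)
            log_h.append(np.log(d / exposure))
    if len(mids) < 2:
        return float(np.log(1.0 / max(times.mean(), 1e-6))), 0.01
    slope, intercept = np.polyfit(mids, log_h, 1)
    return float(intercept), float(slope)


def fit_gompertz(
    data,
    events=None,
    *,
    age_mode: str = "exact",
    init: tuple[float, float] | None = None,
) -> GompertzParams:
    """Maximum-likelihood Gompertz fit.

    Parameters
    ----------
    data
        Exact mode: array of ages at death/censoring (or DeathRecord list).
        Interval mode: (n, 2) array of [lo, hi) age bounds; ``hi = inf``
        denotes an open-ended top bin.
    events
        Boolean/0-1 indicator per row (True = death); defaults to all deaths.
    age_mode
        "exact" or "interval".
    init
        Optional (log alpha, beta) starting point; otherwise a least-squares
        line through the life-table log-hazard.

    The optimization is an unconstrained quasi-Newton search on
    (log alpha, beta); ``beta`` is deliberately not clamped positive.
    """
    if age_mode not in ("exact", "interval"):
        raise ValueError(f"unknown age_mode {age_mode!r}")

    if isinstance(data, (list, tuple)) and data and hasattr(data[0], "is_death"):
        records = data
        events = np.array([r.is_death for r in records])
        if age_mode == "exact":
            data = np.array([r.age for r in records])
        else:
            data = np.array(
                [
                    r.age_interval
                    if r.age_interval is not None
                    else (r.age_years, r.age_years + 1.0)
                    for r in records
                ]
            )

    if age_mode == "exact":
        times = np.asarray(data, dtype=float)
        ev = np.ones_like(times) if events is None else np.asarray(events, dtype=float)
        if np.unique(times[ev.astype(bool)]).size < 2:
            raise ValueError("need >= 2 distinct death ages")
        x0 = np.array(init if init is not None else _init_from_lifetable(times, ev))
        nll = lambda th: _gompertz_nll_exact(th, times, ev)
        mid_times = times
    else:
        iv = np.asarray(data, dtype=float)
        if iv.ndim != 2 or iv.shape[1] != 2:
            raise ValueError("interval mode needs an (n, 2) array of [lo, hi)")
        ev = np.ones(iv.shape[0]) if events is None else np.asarray(events, dtype=float)
        lo, hi = iv[:, 0], iv[:, 1]
        finite_deaths = ev.astype(bool) & np.isfinite(hi)
        if np.unique(lo[finite_deaths]).size < 2 and np.unique(lo[ev.astype(bool)]).size < 2:
            raise ValueError("need >= 2 occupied bins")
        mid_times = np.where(np.isfinite(hi), (lo + hi) / 2.0, lo + 1.0)
        x0 = np.array(init if init is not None else _init_from_lifetable(mid_times, ev))
        nll = lambda th: _gompertz_nll_interval(th, lo, hi, ev)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = optimize.minimize(nll, x0, method="BFGS", options={"maxiter": 500})
        if not res.success:  # Nelder-Mead polish as fallback
            res2 = optimize.minimize(nll, res.x, method="Nelder-Mead",
                                     options={"maxiter": 2000, "xatol": 1e-10, "fatol": 1e-10})
            if res2.fun <= res.fun:
                res = res2
    if not np.all(np.isfinite(res.x)):
        raise GompertzFitError("Gompertz fit did not converge", tuple(res.x))
    log_alpha, beta = res.x
    return GompertzParams(alpha=float(np.exp(log_alpha)), beta=float(beta),
                          log_likelihood=float(-res.fun))


def km_estimate(times, events=None) -> SurvivalCurve:
    """Kaplan-Meier product-limit survival estimate.

    With no censoring this equals the empirical survival function; S starts
    at 1 and is non-increasing.
    """
    times = np.asarray(times, dtype=float)
    ev = np.ones_like(times, dtype=bool) if events is None else np.asarray(events, dtype=bool)
    if times.shape != ev.shape:
        raise ValueError("times and events must have the same length")
    if not ev.any():
        raise ValueError("all records censored: no events to estimate from")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=ev)
    tab = kmf.event_table
    grid = np.asarray(tab.index, dtype=float)
    surv = np.asarray(kmf.survival_function_.iloc[:, 0], dtype=float)
    return SurvivalCurve(
        times=grid,
        survival=surv,
        at_risk=np.asarray(tab["at_risk"], dtype=float),
        events=np.asarray(tab["observed"], dtype=float),
    )


def smoothed_hazard(times, events=None, bandwidth: float | None = None,
                    grid=None) -> HazardCurve:
    """Kernel-smoothed hazard-rate estimate.

    Smooths the Nelson-Aalen increments d_j / Y(t_j) with an Epanechnikov
    kernel.  Near the data boundaries the kernel mass falling outside
    [min(grid_range)] is renormalized so each event contributes unit weight,
    which keeps the curve approximately unbiased at the edges.
    """
    times = np.asarray(times, dtype=float)
    ev = np.ones_like(times, dtype=bool) if events is None else np.asarray(events, dtype=bool)
    if grid is None:
        grid = np.linspace(times.min(), times.max(), 101)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty evaluation grid")
    if bandwidth is None:
        bandwidth = (times.max() - times.min()) / 10.0
    if not bandwidth > 0:
        raise ValueError("bandwidth must be positive")

    event_times = np.sort(times[ev])
    order = np.argsort(times)
    sorted_times = times[order]
    # at-risk count just before each event time
    at_risk = len(times) - np.searchsorted(sorted_times, event_times, side="left")
    increments = 1.0 / at_risk  # Nelson-Aalen jumps (ties contribute separately)

    lo_edge, hi_edge = times.min(), times.max()

    def epan(u):
        return np.where(np.abs(u) <= 1.0, 0.75 * (1.0 - u**2), 0.0)

    u = (grid[:, None] - event_times[None, :]) / bandwidth
    k = epan(u) / bandwidth
    # boundary renormalization: divide by the kernel mass inside the data range
    a = np.clip((lo_edge - event_times) / bandwidth, -1.0, 1.0)
    b = np.clip((hi_edge - event_times) / bandwidth, -1.0, 1.0)
    mass = (0.75 * (b - b**3 / 3.0) - 0.75 * (a - a**3 / 3.0))
    mass = np.maximum(mass, 1e-12)
    hz = (k / mass[None, :]) @ increments
    return HazardCurve(grid=grid, hazard=np.maximum(hz, 0.0), bandwidth=float(bandwidth))


def two_group_hazard_ratio(times, events, group) -> tuple[float, float]:
    """One-covariate proportional-hazards contrast.

    Maximizes the Cox partial likelihood with Breslow handling of ties by
    Newton's method and returns (log hazard ratio of group 1 vs group 0,
    two-sided Wald p-value).  The estimate depends on the data only through
    the ranks of the times.
    """
    times = np.asarray(times, dtype=float)
    ev = np.asarray(events, dtype=bool)
    g = np.asarray(group, dtype=float)
    for lab in (0.0, 1.0):
        if not ev[g == lab].any():
            raise ValueError(f"group {int(lab)} has no events")

    order = np.argsort(-times)  # decreasing: risk sets are cumulative sums
    t_s, e_s, g_s = times[order], ev[order], g[order]

    def derivs(b):
        w = np.exp(b * g_s)
        s0 = np.cumsum(w)
        s1 = np.cumsum(w * g_s)
        s2 = np.cumsum(w * g_s**2)
        ll = dll = d2ll = 0.0
        i = 0
        n = len(t_s)
        while i < n:
            j = i
            while j < n and t_s[j] == t_s[i]:
                j += 1
            d_idx = np.arange(i, j)[e_s[i:j]]
            d = len(d_idx)
            if d:
                k = j - 1  # risk set = everyone with time >= t_s[i]
                mean = s1[k] / s0[k]
                var = s2[k] / s0[k] - mean**2
                gsum = g_s[d_idx].sum()
                ll += b * gsum - d * np.log(s0[k])
                dll += gsum - d * mean
                d2ll -= d * var
            i = j
        return ll, dll, d2ll

    b = 0.0
    for _ in range(50):
        _, dll, d2ll = derivs(b)
        if abs(d2ll) < 1e-12:
            break
        step = -dll / d2ll
        b += np.clip(step, -2.0, 2.0)
        if abs(step) < 1e-10:
            break
    _, _, d2ll = derivs(b)
    se = 1.0 / np.sqrt(max(-d2ll, 1e-12))
    z = b / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(b), float(p)
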