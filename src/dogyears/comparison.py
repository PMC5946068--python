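"""Cross-cohort cause-of-death spectra and rank-correlation comparisons.

Per-cohort proportions of deaths are tabulated by pathophysiological
process, organ system, or — restricting to neoplastic deaths — the organ
system in which cancer occurred.  Spectra are compared with Spearman's rank
correlation over the categories shared by both cohorts (with optional
exclusions, e.g. vascular deaths); p-values use the exact permutation
distribution for eight or fewer categories, where the t approximation is
poor, and the t approximation above that.

A cause is classified *age-related* when the absolute number of deaths from
it rises with age.  That visual criterion is operationalized here as a
one-sided Mann-Kendall trend test on binned death counts, restricted to
ages past the cohort's first quartile of death ages so an early-life
(juvenile) mode does not mask a late-life rise; the output is flagged as a
surrogate for the visual judgement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .taxonomy import DeathRecord, PP_CATEGORIES, OS_CATEGORIES

__all__ = [
    "ProportionTable",
    "RankCorrelationResult",
    "AgeRelatednessResult",
    "proportion_table",
    "spearman",
    "age_relatedness",
    "shared_categories",
]

_AXES = ("pp", "os", "cancer_os")


@dataclass
class ProportionTable:
    """Per-cohort cause-of-death proportions on one axis."""

    axis: str
    table: pd.DataFrame  # index = categories, columns = cohorts; columns sum to 1

    def proportions(self, cohort: str) -> pd.Series:
        return self.table[cohort]


@dataclass
class RankCorrelationResult:
    rho: float
    p_value: float
    n_categories: int
    excluded: tuple[str, ...] = ()
    method: str = "exact"


@dataclass
class AgeRelatednessResult:
    cause: str
    age_related: bool
    counts: pd.Series          # deaths per age bin (bin left edge index)
    tau: float
    p_value: float             # one-sided (increasing trend)
    note: str = "surrogate: one-sided Mann-Kendall trend on late-life binned counts"


def _axis_category(rec: DeathRecord, axis: str) -> str | None:
    if axis == "pp":
        return rec.cause_pp
    if axis == "os":
        return rec.cause_os
    if axis == "cancer_os":  # organ system of neoplastic deaths only
        return rec.cause_os if rec.cause_pp == "neoplastic" else None
    raise ValueError(f"unknown axis {axis!r}; expected one of {_AXES}")


def shared_categories(
    records_by_cohort: dict[str, list[DeathRecord]], axis: str
) -> list[str]:
    """Categories with at least one death in every cohort, in taxonomy order."""
    sets = []
    for recs in records_by_cohort.values():
        cats = {_axis_category(r, axis) for r in recs if r.is_death}
        sets.append({c for c in cats if c is not None})
    common = set.intersection(*sets) if sets else set()
    order = PP_CATEGORIES if axis == "pp" else OS_CATEGORIES
    return [c for c in order if c in common] + sorted(common - set(order))


def proportion_table(
    records_by_cohort: dict[str, list[DeathRecord]],
    axis: str,
    shared: list[str] | None = None,
) -> ProportionTable:
    """Per-cohort death proportions restricted to shared categories.

    Proportions are renormalized over the shared set, so each cohort column
    sums to one.
    """
    if axis not in _AXES:
        raise ValueError(f"unknown axis {axis!r}; expected one of {_AXES}")
    if shared is None:
        shared = shared_categories(records_by_cohort, axis)
    if not shared:
        raise ValueError("no shared categories between cohorts")
    cols = {}
    for cohort, recs in records_by_cohort.items():
        counts = pd.Series(0.0, index=shared)
        for r in recs:
            if not r.is_death:
                continue
            cat = _axis_category(r, axis)
            if cat in counts.index:
                counts[cat] += 1.0
        total = counts.sum()
        if total == 0:
            raise ValueError(f"cohort {cohort!r} has no deaths in shared categories")
        cols[cohort] = counts / total
    return ProportionTable(axis=axis, table=pd.DataFrame(cols))


def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman(
    x, y, exclude: tuple[str, ...] = (), labels=None, exact_max_n: int = 8
) -> RankCorrelationResult:
    """Spearman rank correlation with optional category exclusion.

    ``x`` and ``y`` may be pandas Series indexed by category (then
    ``exclude`` drops by index label) or plain arrays with ``labels``.
    Ties take average ranks.  The two-sided p-value is exact (full
    permutation distribution of the rank vector) for n <= ``exact_max_n``
    and the usual t approximation above.
    """
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        common = [c for c in x.index if c in y.index and c not in exclude]
        xv = x.loc[common].to_numpy(dtype=float)
        yv = y.loc[common].to_numpy(dtype=float)
    else:
        xv = np.asarray(x, dtype=float)
        yv = np.asarray(y, dtype=float)
        if exclude:
            if labels is None:
                raise ValueError("exclusion by label needs labels")
            keep = [i for i, lab in enumerate(labels) if lab not in exclude]
            xv, yv = xv[keep], yv[keep]
    n = xv.size
    if n < 3:
        raise ValueError("need >= 3 categories after exclusion")
    if np.all(xv == xv[0]) or np.all(yv == yv[0]):
        raise ValueError("constant vector: correlation undefined")
    rx = stats.rankdata(xv)
    ry = stats.rankdata(yv)
    rho = _spearman_rho(rx, ry)
    if n <= exact_max_n:
        hits = total = 0
        target = abs(rho) - 1e-12
        for perm in permutations(range(n)):
            r = _spearman_rho(rx, ry[list(perm)])
            total += 1
            if abs(r) >= target:
                hits += 1
        p = hits / total
        method = "exact"
    else:
        p = float(stats.spearmanr(xv, yv).pvalue)
        method = "t-approx"
    return RankCorrelationResult(
        rho=rho, p_value=float(p), n_categories=n,
        excluded=tuple(exclude), method=method,
    )


def age_relatedness(
    records: list[DeathRecord],
    cause: str,
    age_grid,
    alpha: float = 0.05,
    min_deaths: int = 20,
) -> AgeRelatednessResult:
    """Classify one cause as age-related or not.

    Deaths from ``cause`` (matched on the process axis if the label is a
    process category, otherwise the organ-system axis) are counted in the
    half-open bins defined by ``age_grid`` edges.  The trend statistic is
    Kendall's tau between bin index and count over bins whose left edge is
    at or past the first quartile of the cohort's death ages; the cause is
    *age-related* when the trend is positive and the one-sided p-value is
    below ``alpha``.
    """
    import warnings

    axis = "pp" if cause in PP_CATEGORIES else "os"
    deaths = [r for r in records if r.is_death]
    ages_all = np.array([r.age for r in deaths])
    cause_ages = np.array(
        [r.age for r in deaths if _axis_category(r, axis) == cause]
    )
    if cause_ages.size < min_deaths:
        warnings.warn(f"only {cause_ages.size} deaths from {cause!r}")
    edges = np.asarray(age_grid, dtype=float)
    counts, _ = np.histogram(cause_ages, bins=edges)
    series = pd.Series(counts, index=edges[:-1])
    q1 = np.quantile(ages_all, 0.25) if ages_all.size else edges[0]
    late = series[series.index >= q1]
    if late.size < 3 or late.nunique() == 1:
        return AgeRelatednessResult(cause=cause, age_related=False, counts=series,
                                    tau=0.0, p_value=1.0)
    tau_res = stats.kendalltau(np.arange(late.size), late.to_numpy())
    tau = float(tau_res.statistic)
    p_two = float(tau_res.pvalue)
    p_one = p_two / 2.0 if tau > 0 else 1.0 - p_two / 2.0
    return AgeRelatednessResult(
        cause=cause,
        age_related=bool(tau > 0 and p_one < alpha),
        counts=series,
        tau=tau,
        p_value=p_one,
    )
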