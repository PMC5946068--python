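"""Multimorbidity and comorbidity count models.

*Multimorbidity* is the number of distinct diagnoses recorded for an
individual at death; *comorbidity* with respect to an index condition is the
same count excluding the index condition itself.  Every diagnosis counts
equally regardless of severity.  Counts are modelled with a log-link
negative-binomial regression (NB2: variance = mu + mu^2 / theta, with the
dispersion theta estimated jointly by maximum likelihood) on age, sex
(female = 0, male = 1), and optionally a categorical cause of death or a
binary index-condition flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.discrete.discrete_model import NegativeBinomial

from .taxonomy import DeathRecord, normalize_diagnosis

__all__ = [
    "CountModel",
    "fit_negbin",
    "multimorbidity_analysis",
    "comorbidity_analysis",
    "SEX_CODE",
]

SEX_CODE = {"female": 0.0, "male": 1.0}


@dataclass
class CountModel:
    """Fitted negative-binomial regression on the log-link scale."""

    params: pd.Series          # named coefficients (log scale)
    bse: pd.Series             # standard errors
    pvalues: pd.Series         # Wald two-sided p per coefficient
    dispersion: float          # theta; variance = mu + mu^2 / theta
    log_likelihood: float
    n: int
    adjusted_means: dict[str, float] = field(default_factory=dict)
    excluded_categories: list[str] = field(default_factory=list)

    def predict_mean(self, row: pd.Series | dict) -> float:
        """exp(linear predictor) for one covariate row (missing terms = 0)."""
        eta = 0.0
        for name, b in self.params.items():
            eta += b * (1.0 if name == "const" else float(row.get(name, 0.0)))
        return float(np.exp(eta))

    def summary_frame(self) -> pd.DataFrame:
        z = self.params / self.bse
        return pd.DataFrame(
            {"estimate": self.params, "se": self.bse, "z": z, "p": self.pvalues}
        )


def fit_negbin(response, design: pd.DataFrame) -> CountModel:
    """Joint MLE of a log-link NB2 regression (coefficients + dispersion).

    ``design`` must not contain a constant column; an intercept is added.
    Raises on a zero-variance response or non-convergence.
    """
    y = np.asarray(response, dtype=float)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if np.var(y) == 0:
        raise ValueError("zero-variance response")
    X = sm.add_constant(design.astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = NegativeBinomial(y, X, loglike_method="nb2")
        res = model.fit(disp=False, maxiter=200, method="bfgs")
        if not res.mle_retvals.get("converged", False):
            res = model.fit(disp=False, maxiter=500, method="nm",
                            start_params=res.params)
    if not np.all(np.isfinite(res.params)):
        raise RuntimeError("negative-binomial fit did not converge")
    alpha = float(res.params["alpha"])  # statsmodels alpha = 1 / theta
    if alpha < 1e-6 or not np.all(np.isfinite(res.bse)):
        # dispersion at the boundary (data no more dispersed than Poisson):
        # the NB Hessian is singular there, so use the Poisson limit
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        return CountModel(
            params=pois.params, bse=pois.bse, pvalues=pois.pvalues,
            dispersion=float("inf"), log_likelihood=float(pois.llf), n=len(y),
        )
    theta = 1.0 / alpha
    return CountModel(
        params=res.params.drop(labels=["alpha"]),
        bse=res.bse.drop(labels=["alpha"]),
        pvalues=res.pvalues.drop(labels=["alpha"]),
        dispersion=float(theta),
        log_likelihood=float(res.llf),
        n=len(y),
    )


def _records_frame(records: list[DeathRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        if not r.is_death:
            continue
        rows.append(
            {
                "count": r.n_diagnoses(),
                "age": r.age,
                "sex": SEX_CODE[r.sex],
                "cause_pp": r.cause_pp,
                "cause_os": r.cause_os,
                "diagnoses": frozenset(normalize_diagnosis(d) for d in r.diagnoses),
            }
        )
    return pd.DataFrame(rows)


def multimorbidity_analysis(
    records: list[DeathRecord], category_axis: str = "none"
) -> CountModel:
    """Model multimorbidity as a function of age, sex and (optionally) cause.

    ``category_axis`` in {"none", "pp", "os"} selects whether cause-of-death
    dummies (reference = most frequent category) enter the model.  Adjusted
    per-category mean counts — the predicted count at the sample-average age
    and sex mix — are attached to the result.  Categories with fewer than two
    records are excluded with a warning.
    """
    axis = category_axis.lower()
    if axis not in ("none", "pp", "os"):
        raise ValueError(f"unknown category axis {category_axis!r}")
    df = _records_frame(records)
    if df.empty:
        raise ValueError("no death records")
    design = df[["age", "sex"]].copy()
    excluded: list[str] = []
    if axis != "none":
        col = "cause_pp" if axis == "pp" else "cause_os"
        counts = df[col].value_counts()
        small = counts[counts < 2].index.tolist()
        if small:
            excluded = sorted(small)
            warnings.warn(f"excluding categories with < 2 records: {excluded}")
            keep = ~df[col].isin(small)
            df = df[keep].reset_index(drop=True)
            design = design[keep.to_numpy()].reset_index(drop=True)
        ref = df[col].value_counts().idxmax()
        dummies = pd.get_dummies(df[col], prefix=col).astype(float)
        dummies = dummies.drop(columns=[f"{col}_{ref}"])
        design = pd.concat([design, dummies], axis=1)
    model = fit_negbin(df["count"], design)
    model.excluded_categories = excluded
    base = {"age": df["age"].mean(), "sex": df["sex"].mean()}
    if axis != "none":
        col = "cause_pp" if axis == "pp" else "cause_os"
        for cat in sorted(df[col].unique()):
            row = dict(base)
            key = f"{col}_{cat}"
            if key in model.params.index:
                row[key] = 1.0
            model.adjusted_means[cat] = model.predict_mean(row)
    else:
        model.adjusted_means["overall"] = model.predict_mean(base)
    return model


def comorbidity_analysis(records: list[DeathRecord], condition: str) -> CountModel:
    """Comorbidity count model for one index condition.

    Response: distinct diagnoses excluding the index condition for cases
    (so a case's comorbidity is its multimorbidity minus one), full count
    for non-cases.  Fits count ~ condition flag + age + sex and attaches the
    adjusted mean comorbidity for cases and non-cases at the sample-average
    age and sex mix.
    """
    df = _records_frame(records)
    if df.empty:
        raise ValueError("no death records")
    key = normalize_diagnosis(condition)
    flag = df["diagnoses"].apply(lambda s: float(key in s))
    if flag.sum() == 0:
        raise ValueError(f"condition {condition!r} not present in any record")
    response = df["count"] - flag  # cases exclude the index diagnosis
    design = pd.DataFrame({"condition": flag, "age": df["age"], "sex": df["sex"]})
    model = fit_negbin(response, design)
    base = {"age": df["age"].mean(), "sex": df["sex"].mean()}
    model.adjusted_means["cases"] = model.predict_mean({**base, "condition": 1.0})
    model.adjusted_means["non_cases"] = model.predict_mean({**base, "condition": 0.0})
    return model
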