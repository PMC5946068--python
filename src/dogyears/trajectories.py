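"""Multinomial age-trajectories of causes of death and cross-cohort comparison.

Among individuals dying at age ``x``, the probability that the death is from
cause ``g`` is modelled with a softmax over per-cause fourth-order
polynomials in age:

    p_g(x) = softmax( a_g + sum_{i=1..4} b_{g,i} x^i )

Age is standardized (centered and scaled) before the polynomial expansion —
a numerically equivalent reparameterization that avoids x^4 overflow at
human ages — and the alphabetically-first cause is the reference group
(all its parameters fixed at 0), which makes the likelihood concave and the
fit unique.

Two cohorts are put on a common age axis by aligning their neoplastic-death
trajectories: the ratio of the ages at which each cohort's neoplastic
proportion peaks is the *age scale factor* (about 4.6 human years per dog
year for all-breed dog data).  On the rescaled axis, per-cause differences
are summarized by the base-2 log odds ratio

    log2 OR(x) = logit2(p_human(x)) - logit2(p_dog(x / scale)),

positive values meaning the cause is more likely in humans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import Polynomial
from scipy import optimize
from scipy.special import logsumexp

__all__ = [
    "MultinomialAgeModel",
    "AgeScale",
    "OddsRatioCurve",
    "PeakResult",
    "fit_cause_trajectory",
    "predict_proportions",
    "confidence_band",
    "find_peak_age",
    "compute_age_scale",
    "log2_odds_ratio",
    "odds_ratio_curve",
]


@dataclass(frozen=True)
class MultinomialAgeModel:
    """Fitted (or constructed) softmax age-trajectory model.

    ``coef`` has shape (K, degree + 1): per-cause intercept followed by the
    polynomial coefficients on the standardized-age scale
    ``z = (age - age_center) / age_scale``.  Row 0 (the reference cause,
    labels sorted) is identically zero for fitted models.
    """

    labels: tuple[str, ...]
    coef: np.ndarray
    age_center: float
    age_scale: float
    log_likelihood: float = float("nan")
    n: int = 0
    degree: int = 4

    def __post_init__(self) -> None:
        coef = np.asarray(self.coef, dtype=float)
        if coef.shape != (len(self.labels), self.degree + 1):
            raise ValueError("coef must be (n_causes, degree + 1)")
        object.__setattr__(self, "coef", coef)
        if not self.age_scale > 0:
            raise ValueError("age_scale must be positive")

    def index(self, cause: str) -> int:
        try:
            return self.labels.index(cause)
        except ValueError:
            raise KeyError(f"cause {cause!r} not in model") from None

    def linear_predictor(self, ages) -> np.ndarray:
        """(n_ages, K) matrix of per-cause scores at the given ages."""
        z = (np.atleast_1d(np.asarray(ages, dtype=float)) - self.age_center) / self.age_scale
        X = np.vander(z, self.degree + 1, increasing=True)  # 1, z, .., z^deg
        return X @ self.coef.T

    @classmethod
    def from_raw_polynomials(
        cls,
        labels,
        raw_coef,
        age_center: float,
        age_scale: float,
        degree: int = 4,
    ) -> "MultinomialAgeModel":
        """Build a model from polynomial coefficients on the *raw* age scale.

        ``raw_coef[g]`` = (c0, c1, ..., c_degree) so that cause ``g``'s score
        at age x is ``sum_i c_i x^i``.  Coefficients are re-expressed on the
        standardized scale via polynomial composition, so predictions equal
        the raw polynomial exactly.
        """
        labels = tuple(labels)
        raw = np.asarray(raw_coef, dtype=float)
        coef = np.empty_like(raw)
        shift = Polynomial([age_center, age_scale])  # age = center + scale * z
        for g in range(raw.shape[0]):
            composed = Polynomial(raw[g])(shift)
            c = composed.coef
            coef[g, : len(c)] = c
            coef[g, len(c):] = 0.0
        return cls(labels=labels, coef=coef, age_center=age_center,
                   age_scale=age_scale, degree=degree)


@dataclass(frozen=True)
class AgeScale:
    """Cross-cohort age mapping from neoplastic-peak alignment."""

    human_peak_age: float
    dog_peak_age: float

    def __post_init__(self) -> None:
        if not (self.human_peak_age > 0 and self.dog_peak_age > 0):
            raise ValueError("peak ages must be positive")

    @property
    def scale_factor(self) -> float:
        """Human-years per dog-year: human_peak / dog_peak."""
        return self.human_peak_age / self.dog_peak_age

    def to_human_age(self, dog_age) -> float:
        return dog_age * self.scale_factor

    def to_dog_age(self, human_age) -> float:
        return human_age / self.scale_factor


@dataclass(frozen=True)
class PeakResult:
    age: float
    proportion: float
    at_boundary: bool
    flat: bool = False


@dataclass(frozen=True)
class OddsRatioCurve:
    cause: str
    human_ages: np.ndarray
    log2_or: np.ndarray
    clipped: np.ndarray  # True where either probability hit the clip bound
    epsilon: float


def _nll_and_grad(theta, X, y_idx, K, ridge):
    """Negative log-likelihood of the softmax model and its gradient.

    theta packs the (K-1) non-reference rows of the coefficient matrix.
    """
    n, p = X.shape
    B = theta.reshape(K - 1, p)
    eta = np.zeros((n, K))
    eta[:, 1:] = X @ B.T
    logZ = logsumexp(eta, axis=1)
    nll = -(eta[np.arange(n), y_idx].sum() - logZ.sum())
    P = np.exp(eta - logZ[:, None])
    R = P.copy()
    R[np.arange(n), y_idx] -= 1.0
    grad = (R[:, 1:].T @ X).ravel()
    if ridge > 0:
        nll += 0.5 * ridge * np.dot(theta, theta)
        grad = grad + ridge * theta
    return nll, grad


def fit_cause_trajectory(
    ages,
    causes,
    degree: int = 4,
    ridge: float = 0.0,
    start: np.ndarray | None = None,
    _warn_small: int = 50,
) -> MultinomialAgeModel:
    """Maximum-likelihood fit of the softmax polynomial trajectory model.

    Causes with zero deaths are dropped with a warning; if the unpenalized
    fit diverges (complete separation of a cause along age), the fit is
    retried with a small ridge penalty and a warning.  Deterministic given
    the data: the likelihood is concave once the reference group is fixed.
    """
    ages = np.asarray(ages, dtype=float)
    causes = np.asarray(causes, dtype=object)
    if ages.shape[0] != causes.shape[0]:
        raise ValueError("ages and causes must align")
    present, counts = np.unique(causes, return_counts=True)
    labels = tuple(sorted(str(c) for c in present))
    if len(labels) < 2:
        raise ValueError("need >= 2 distinct causes")
    if ages.size < _warn_small:
        warnings.warn(f"only {ages.size} deaths; trajectory fit will be unstable")

    center = float(ages.mean())
    scale = float(ages.std())
    if scale <= 0:
        raise ValueError("all deaths at a single age: trajectory not identifiable")
    z = (ages - center) / scale
    X = np.vander(z, degree + 1, increasing=True)
    label_to_idx = {lab: i for i, lab in enumerate(labels)}
    y_idx = np.array([label_to_idx[str(c)] for c in causes])
    K, p = len(labels), degree + 1

    def solve(rdg):
        theta0 = (np.zeros((K - 1) * p) if start is None
                  else np.asarray(start, dtype=float).ravel())
        res = optimize.minimize(
            _nll_and_grad, theta0, args=(X, y_idx, K, rdg), jac=True,
            method="L-BFGS-B", options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-8},
        )
        return res

    res = solve(ridge)
    if ridge == 0.0 and (not np.all(np.isfinite(res.x)) or np.abs(res.x).max() > 50.0):
        warnings.warn("possible separation in trajectory fit; refitting with ridge penalty")
        res = solve(1e-4)
    coef = np.zeros((K, p))
    coef[1:] = res.x.reshape(K - 1, p)
    return MultinomialAgeModel(
        labels=labels, coef=coef, age_center=center, age_scale=scale,
        log_likelihood=float(-res.fun), n=int(ages.size), degree=degree,
    )


def predict_proportions(model: MultinomialAgeModel, age) -> np.ndarray:
    """Predicted cause-of-death proportions at the given age(s).

    Returns shape (K,) for scalar age, (n_ages, K) otherwise; each row is a
    probability simplex over ``model.labels``.
    """
    eta = model.linear_predictor(age)
    P = np.exp(eta - logsumexp(eta, axis=1, keepdims=True))
    return P[0] if np.isscalar(age) else P


def confidence_band(
    model: MultinomialAgeModel,
    ages,
    causes,
    cause: str,
    age_grid,
    level: float = 0.95,
    B: int = 200,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Nonparametric bootstrap percentile band for one cause's trajectory.

    Resamples individuals with replacement B times, refits, and takes
    pointwise percentile intervals of the predicted proportion on
    ``age_grid``.  Reproducible given ``seed``.
    """
    if B < 50:
        raise ValueError("need B >= 50 bootstrap replicates")
    ages = np.asarray(ages, dtype=float)
    causes = np.asarray(causes, dtype=object)
    age_grid = np.asarray(age_grid, dtype=float)
    rng = np.random.default_rng(seed)
    n = ages.size
    curves = np.full((B, age_grid.size), np.nan)
    failures = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for b in range(B):
            idx = rng.integers(0, n, size=n)
            try:
                m = fit_cause_trajectory(ages[idx], causes[idx], degree=model.degree)
                curves[b] = predict_proportions(m, age_grid)[:, m.index(cause)]
            except (ValueError, KeyError):
                failures += 1
    if failures > 0.1 * B:
        raise RuntimeError(f"{failures}/{B} bootstrap refits failed")
    alpha = 1.0 - level
    lower = np.nanpercentile(curves, 100 * alpha / 2.0, axis=0)
    upper = np.nanpercentile(curves, 100 * (1.0 - alpha / 2.0), axis=0)
    return lower, upper


def _golden_section(f, a: float, b: float, tol: float = 1e-8) -> float:
    """Golden-section minimizer on [a, b]; ties resolve toward the left."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc <= fd:  # <= keeps the younger-age side on ties
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (a + b) / 2.0


def find_peak_age(
    model: MultinomialAgeModel,
    cause: str,
    age_range: tuple[float, float],
    coarse_step: float = 0.1,
    boundary_tol: float = 1e-6,
) -> PeakResult:
    """Age at which a cause's predicted proportion is highest.

    A coarse grid scan (default 0.1-year steps) brackets the maximum, which
    is then refined by golden-section search; ties break toward the younger
    age.  Peaks at the range boundary, and flat trajectories, are flagged.
    """
    lo, hi = age_range
    if not lo < hi:
        raise ValueError("degenerate age range")
    j = model.index(cause)
    grid = np.arange(lo, hi + coarse_step / 2.0, coarse_step)
    vals = predict_proportions(model, grid)[:, j]
    if vals.max() - vals.min() < 1e-12:
        return PeakResult(age=lo, proportion=float(vals[0]), at_boundary=True, flat=True)
    i = int(np.argmax(vals))  # argmax takes the first (youngest) maximizer
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, grid.size - 1)]

    def neg(x):
        return -predict_proportions(model, np.array([x]))[0, j]

    if a < b:
        peak = float(np.clip(_golden_section(neg, a, b), lo, hi))
    else:
        peak = float(grid[i])
    at_boundary = peak - lo < boundary_tol or hi - peak < boundary_tol
    return PeakResult(age=peak, proportion=float(-neg(peak)), at_boundary=at_boundary)


def compute_age_scale(
    human_model: MultinomialAgeModel,
    dog_model: MultinomialAgeModel,
    cause: str = "neoplastic",
    human_age_range: tuple[float, float] = (0.0, 100.0),
    dog_age_range: tuple[float, float] = (0.0, 20.0),
) -> AgeScale:
    """Age scale factor from peak alignment of one cause's trajectories.

    Locates the age of maximum predicted proportion of ``cause`` in each
    cohort; the scale factor is the ratio of the two peak ages (human over
    dog).  Errors if either peak sits on the search boundary — peak
    alignment is meaningless there and a manual scale should be supplied.
    """
    hp = find_peak_age(human_model, cause, human_age_range)
    dp = find_peak_age(dog_model, cause, dog_age_range)
    for name, pk in (("human", hp), ("dog", dp)):
        if pk.at_boundary or pk.flat:
            raise ValueError(
                f"{name} {cause!r} trajectory peaks at the boundary of "
                f"the search range; supply a scale manually"
            )
    return AgeScale(human_peak_age=hp.age, dog_peak_age=dp.age)


def _logit2(p):
    return np.log2(p / (1.0 - p))


def log2_odds_ratio(
    human_model: MultinomialAgeModel,
    dog_model: MultinomialAgeModel,
    scale: AgeScale,
    cause: str,
    human_age,
    epsilon: float = 1e-6,
):
    """Base-2 log odds ratio of one cause, humans vs dogs, at a human age.

    Probabilities are clipped to [epsilon, 1 - epsilon] before the logit, so
    the value is always finite.  Positive values: cause more likely in
    humans; zero: equal odds.
    """
    scalar = np.isscalar(human_age)
    ha = np.atleast_1d(np.asarray(human_age, dtype=float))
    ph = predict_proportions(human_model, ha)[:, human_model.index(cause)]
    pd_ = predict_proportions(dog_model, scale.to_dog_age(ha))[:, dog_model.index(cause)]
    ph_c = np.clip(ph, epsilon, 1.0 - epsilon)
    pd_c = np.clip(pd_, epsilon, 1.0 - epsilon)
    out = _logit2(ph_c) - _logit2(pd_c)
    return float(out[0]) if scalar else out


def odds_ratio_curve(
    human_model: MultinomialAgeModel,
    dog_model: MultinomialAgeModel,
    scale: AgeScale,
    cause: str,
    human_ages,
    epsilon: float = 1e-6,
) -> OddsRatioCurve:
    """log2 odds-ratio values on a human-age grid, with clip flags."""
    ha = np.asarray(human_ages, dtype=float)
    ph = predict_proportions(human_model, ha)[:, human_model.index(cause)]
    pd_ = predict_proportions(dog_model, scale.to_dog_age(ha))[:, dog_model.index(cause)]
    clipped = (ph < epsilon) | (ph > 1 - epsilon) | (pd_ < epsilon) | (pd_ > 1 - epsilon)
    vals = log2_odds_ratio(human_model, dog_model, scale, cause, ha, epsilon=epsilon)
    return OddsRatioCurve(cause=cause, human_ages=ha, log2_or=vals,
                          clipped=clipped, epsilon=epsilon)
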