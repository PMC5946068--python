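"""Seeded two-cohort death-record generator.

Stands in for restricted mortality registries (census follow-up and
veterinary hospital databases) by generating records with the statistical
structure the analysis modules assume:

* lifespans drawn from sex-specific Gompertz hazards by inverse-CDF
  sampling,
* a cause of death drawn at each age from a softmax polynomial
  age-trajectory model (the same family the trajectory module fits), with a
  configurable neoplastic peak age per cohort,
* a diagnosis list whose length follows a shifted negative-binomial
  multimorbidity model with age, sex and index-condition effects (every
  death carries at least one diagnosis — its primary cause),
* optional registry-style age binning (ages collapsed to bin midpoints) and
  contamination with unclassified-cause and euthanasia-only records.

All randomness flows through independent child streams of one seed, so
regeneration is bit-identical and changing, say, the morbidity stream does
not perturb lifespans.

Default cohort specifications encode the study conditions: a human-like
cohort (Gompertz slopes 0.089 female / 0.080 male, neoplastic proportion
peaking at 53 years) and a dog-like cohort (slopes 0.0214 / 0.0219, peak at
11.5 years).  Baseline hazards are set to give plausible median lifespans
(about 80 human years, about 12 dog years).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .survival import GompertzParams
from .taxonomy import (
    AgeBinScheme,
    CauseTaxonomy,
    DeathRecord,
    UNCLASSIFIED,
    EUTHANASIA,
)
from .trajectories import MultinomialAgeModel, find_peak_age, predict_proportions

__all__ = [
    "MorbiditySpec",
    "CohortSpec",
    "SimulatedCohort",
    "simulate_lifespans",
    "simulate_causes",
    "simulate_morbidity",
    "simulate_cohort",
    "peaked_cause_model",
    "default_human_spec",
    "default_dog_spec",
]


@dataclass(frozen=True)
class MorbiditySpec:
    """Log-link negative-binomial model for the number of extra diagnoses.

    The number of diagnoses beyond the primary cause is NB with mean
    exp(intercept + b_age * age + b_sex * sex + sum of flagged condition
    effects) and dispersion ``theta``; total multimorbidity is 1 + that
    draw (floored so flagged index conditions always fit in the list).
    """

    intercept: float = -0.2
    b_age: float = 0.05
    b_sex: float = 0.0
    condition_effects: dict[str, float] = field(default_factory=dict)
    theta: float = 5.0


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate one cohort."""

    label: str
    gompertz: dict[str, GompertzParams]      # per sex
    cause_model: MultinomialAgeModel
    age_range: tuple[float, float]
    sex_female_fraction: float = 0.5
    morbidity: MorbiditySpec = field(default_factory=MorbiditySpec)
    condition_prevalence: dict[str, float] = field(default_factory=dict)
    frac_unclassified: float = 0.0
    frac_euthanasia_only: float = 0.0
    age_mode: str = "exact"                  # "exact" | "vmdb_bins"
    bin_scheme: AgeBinScheme | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.sex_female_fraction <= 1.0:
            raise ValueError("sex_female_fraction must be in [0, 1]")
        for frac in (self.frac_unclassified, self.frac_euthanasia_only):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("contamination fractions must be in [0, 1]")
        if self.frac_unclassified + self.frac_euthanasia_only > 1.0:
            raise ValueError("contamination fractions sum above 1")
        for prev in self.condition_prevalence.values():
            if not 0.0 <= prev <= 1.0:
                raise ValueError("prevalences must be in [0, 1]")
        if self.age_mode not in ("exact", "vmdb_bins"):
            raise ValueError(f"unknown age_mode {self.age_mode!r}")
        if self.age_mode == "vmdb_bins" and self.bin_scheme is None:
            object.__setattr__(self, "bin_scheme", AgeBinScheme.vmdb_default())


@dataclass
class SimulatedCohort:
    records: list[DeathRecord]
    spec: CohortSpec
    seed: int


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_lifespans(gompertz: GompertzParams, n: int, seed) -> np.ndarray:
    """Inverse-CDF draws from the Gompertz lifespan distribution.

    x = (1/beta) * ln(1 - (beta/alpha) * ln U) for U ~ Uniform(0, 1);
    the beta -> 0 limit falls back to exponential sampling.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    u = rng.random(n)
    a, b = gompertz.alpha, gompertz.beta
    if abs(b) < 1e-9:
        return -np.log(u) / a
    return np.log1p(-(b / a) * np.log(u)) / b


def simulate_causes(model: MultinomialAgeModel, ages, seed) -> np.ndarray:
    """Draw each death's cause from the model's proportions at its age."""
    rng = _as_rng(seed)
    ages = np.asarray(ages, dtype=float)
    P = predict_proportions(model, ages)
    cum = np.cumsum(P, axis=1)
    u = rng.random(ages.size)
    idx = (u[:, None] > cum).sum(axis=1)
    labels = np.array(model.labels, dtype=object)
    return labels[np.clip(idx, 0, len(model.labels) - 1)]


def simulate_morbidity(
    spec: CohortSpec,
    ages,
    sexes,
    primary_diagnoses,
    taxonomy: CauseTaxonomy,
    seed,
) -> tuple[list[list[str]], dict[str, np.ndarray]]:
    """Realize diagnosis lists and index-condition flags.

    Each record's list contains its primary diagnosis, any flagged index
    conditions, and filler diagnoses drawn without replacement from the
    taxonomy vocabulary; the list length is the drawn multimorbidity count.
    """
    rng = _as_rng(seed)
    ages = np.asarray(ages, dtype=float)
    sexes_num = np.asarray([0.0 if s == "female" else 1.0 for s in sexes])
    n = ages.size
    m = spec.morbidity

    flags = {
        cond: rng.random(n) < prev
        for cond, prev in sorted(spec.condition_prevalence.items())
    }
    eta = m.intercept + m.b_age * ages + m.b_sex * sexes_num
    for cond, eff in sorted(m.condition_effects.items()):
        if cond in flags:
            eta = eta + eff * flags[cond]
    mu = np.exp(eta)
    p_nb = m.theta / (m.theta + mu)
    extra = rng.negative_binomial(m.theta, p_nb)

    vocab = sorted(taxonomy.diagnosis_map)
    vocab = [d for d in vocab if d != EUTHANASIA
             and taxonomy.diagnosis_map[d] != (UNCLASSIFIED, UNCLASSIFIED)]
    lists: list[list[str]] = []
    for i in range(n):
        diags = [primary_diagnoses[i]]
        for cond, f in flags.items():
            if f[i] and cond not in diags:
                diags.append(cond)
        count = max(1 + int(extra[i]), len(diags))
        if count > len(vocab):
            raise ValueError(
                f"requested {count} distinct diagnoses but vocabulary has {len(vocab)}"
            )
        pool = [d for d in vocab if d not in diags]
        n_fill = count - len(diags)
        if n_fill > 0:
            fill_idx = rng.choice(len(pool), size=n_fill, replace=False)
            diags.extend(pool[j] for j in fill_idx)
        lists.append(diags)
    return lists, flags


def simulate_cohort(spec: CohortSpec, n: int, seed: int) -> SimulatedCohort:
    """Generate a full cohort of death records.

    Pipeline: sexes -> Gompertz lifespans -> cause draw -> primary
    diagnosis (uniform within the cause's process vocabulary) -> diagnosis
    lists -> optional age binning (ages replaced by bin midpoints) ->
    contamination (uniformly chosen disjoint subsets relabelled
    unclassified or reduced to euthanasia-only).  Deterministic per seed;
    each stage has its own child stream.
    """
    ss = np.random.SeedSequence(seed)
    s_sex, s_life, s_cause, s_primary, s_morb, s_contam = ss.spawn(6)
    taxonomy = CauseTaxonomy.default()

    rng_sex = np.random.default_rng(s_sex)
    sexes = np.where(rng_sex.random(n) < spec.sex_female_fraction, "female", "male")

    ages = np.empty(n)
    rng_life = np.random.default_rng(s_life)
    for sex in ("female", "male"):
        mask = sexes == sex
        if mask.any():
            ages[mask] = simulate_lifespans(spec.gompertz[sex], int(mask.sum()), rng_life)
    lo, hi = spec.age_range
    ages = np.clip(ages, lo, hi)  # keep inside the cause model's validity range

    causes = simulate_causes(spec.cause_model, ages, np.random.default_rng(s_cause))

    rng_primary = np.random.default_rng(s_primary)
    pp_vocab = {pp: taxonomy.diagnoses_for_pp(pp) for pp in set(causes)}
    primaries = []
    for c in causes:
        options = pp_vocab[c]
        if not options:
            raise ValueError(f"taxonomy has no diagnosis with process {c!r}")
        primaries.append(options[rng_primary.integers(len(options))])

    lists, _ = simulate_morbidity(
        spec, ages, sexes, primaries, taxonomy, np.random.default_rng(s_morb)
    )

    if spec.age_mode == "vmdb_bins":
        scheme = spec.bin_scheme
        rec_ages = np.array([scheme.bin_for_age(a).midpoint for a in ages])
    else:
        rec_ages = ages

    records: list[DeathRecord] = []
    for i in range(n):
        pp, os_ = taxonomy.lookup(primaries[i])
        records.append(
            DeathRecord(
                id=f"{spec.label}-{i:06d}",
                cohort=spec.label,
                sex=str(sexes[i]),
                age_years=float(rec_ages[i]),
                diagnoses=list(lists[i]),
                primary_diagnosis=primaries[i],
                cause_pp=pp,
                cause_os=os_,
                event="death",
            )
        )

    rng_contam = np.random.default_rng(s_contam)
    n_uncl = int(round(spec.frac_unclassified * n))
    n_euth = int(round(spec.frac_euthanasia_only * n))
    chosen = rng_contam.permutation(n)[: n_uncl + n_euth]
    for j in chosen[:n_uncl]:
        records[j].cause_pp = UNCLASSIFIED
        records[j].cause_os = UNCLASSIFIED
    for j in chosen[n_uncl:]:
        rec = records[j]
        rec.diagnoses = [EUTHANASIA]
        rec.primary_diagnosis = EUTHANASIA
        rec.cause_pp, rec.cause_os = taxonomy.lookup(EUTHANASIA)
    return SimulatedCohort(records=records, spec=spec, seed=seed)


def peaked_cause_model(
    raw_logits: dict[str, tuple[float, ...]],
    peak_cause: str,
    peak_age: float,
    curvature: float,
    height: float,
    age_range: tuple[float, float],
    calibrate: bool = True,
) -> MultinomialAgeModel:
    """Softmax generator with one cause's *proportion* peaking at a set age.

    ``peak_cause`` gets a concave-quadratic logit, height ``height`` at its
    vertex and curvature ``curvature`` (logit units per squared year).  When
    other causes' logits vary with age, the proportion peak drifts off the
    logit vertex; with ``calibrate`` the vertex is shifted by fixed-point
    iteration until the proportion peak sits at ``peak_age`` (to 0.01 y).
    """
    lo, hi = age_range
    center, scale = (lo + hi) / 2.0, max((hi - lo) / 4.0, 1e-6)
    labels = sorted(set(raw_logits) | {peak_cause})
    degree = 4

    def build(vertex: float) -> MultinomialAgeModel:
        raw = np.zeros((len(labels), degree + 1))
        for g, lab in enumerate(labels):
            if lab == peak_cause:
                # height - curvature * (x - vertex)^2, expanded in x
                raw[g, 0] = height - curvature * vertex**2
                raw[g, 1] = 2.0 * curvature * vertex
                raw[g, 2] = -curvature
            else:
                coefs = raw_logits.get(lab, ())
                raw[g, : len(coefs)] = coefs
        return MultinomialAgeModel.from_raw_polynomials(
            labels, raw, age_center=center, age_scale=scale, degree=degree
        )

    vertex = peak_age
    model = build(vertex)
    if calibrate:
        for _ in range(30):
            pk = find_peak_age(model, peak_cause, age_range)
            if pk.at_boundary:
                raise ValueError("proportion peak hit the age-range boundary")
            err = pk.age - peak_age
            if abs(err) < 0.01:
                break
            vertex -= err
            model = build(vertex)
        else:
            warnings.warn("peak calibration did not fully converge")
    return model


# ---------------------------------------------------------------------------
# Default study-condition specifications
# ---------------------------------------------------------------------------

#: Default rate-of-aging slopes (per year) defining the two cohorts.
HUMAN_SLOPES = {"female": 0.089, "male": 0.080}
DOG_SLOPES = {"female": 0.0214, "male": 0.0219}
HUMAN_NEOPLASTIC_PEAK = 53.0
DOG_NEOPLASTIC_PEAK = 11.5


def _alpha_for_median(beta: float, median: float) -> float:
    """Baseline hazard giving the requested median lifespan."""
    if abs(beta) < 1e-9:
        return np.log(2.0) / median
    return beta * np.log(2.0) / np.expm1(beta * median)


def default_human_spec(**overrides) -> CohortSpec:
    """Human-like cohort: exact ages, no contamination, median lifespan ~80/75."""
    cause_model = peaked_cause_model(
        raw_logits={
            "congenital": (1.2, -0.08),
            "traumatic": (1.0, -0.035),
            "infectious": (0.0,),
            "metabolic": (-1.0, 0.02),
            "vascular": (-2.0, 0.045),
        },
        peak_cause="neoplastic",
        peak_age=HUMAN_NEOPLASTIC_PEAK,
        curvature=0.0012,
        height=1.2,
        age_range=(0.0, 100.0),
    )
    spec = CohortSpec(
        label="human",
        gompertz={
            "female": GompertzParams(_alpha_for_median(HUMAN_SLOPES["female"], 80.0),
                                     HUMAN_SLOPES["female"]),
            "male": GompertzParams(_alpha_for_median(HUMAN_SLOPES["male"], 75.0),
                                   HUMAN_SLOPES["male"]),
        },
        cause_model=cause_model,
        age_range=(0.0, 100.0),
        morbidity=MorbiditySpec(intercept=-0.6, b_age=0.02, b_sex=0.0),
        condition_prevalence={},
        age_mode="exact",
    )
    return replace(spec, **overrides) if overrides else spec


def default_dog_spec(**overrides) -> CohortSpec:
    """Dog-like cohort: registry-binned ages, contamination, median ~12 years.

    Morbidity model targets a mean multimorbidity near 3 diagnoses with a
    positive age effect and no sex effect; the five index chronic conditions
    carry their own prevalences and comorbidity effects.
    """
    cause_model = peaked_cause_model(
        raw_logits={
            "congenital": (1.2, -0.45),
            "traumatic": (1.0, -0.16),
            "infectious": (0.0,),
            "metabolic": (-1.0, 0.09),
            "vascular": (-2.0, 0.12),
        },
        peak_cause="neoplastic",
        peak_age=DOG_NEOPLASTIC_PEAK,
        curvature=0.025,
        height=1.2,
        age_range=(0.0, 20.0),
    )
    spec = CohortSpec(
        label="dog",
        gompertz={
            "female": GompertzParams(_alpha_for_median(DOG_SLOPES["female"], 12.0),
                                     DOG_SLOPES["female"]),
            "male": GompertzParams(_alpha_for_median(DOG_SLOPES["male"], 12.0),
                                   DOG_SLOPES["male"]),
        },
        cause_model=cause_model,
        age_range=(0.0, 20.0),
        morbidity=MorbiditySpec(
            intercept=-0.1,
            b_age=0.07,
            b_sex=0.0,
            condition_effects={
                "obesity": np.log(2.0),
                "arthritis": 0.35,
                "diabetes mellitus": 0.45,
                "hypothyroidism": 0.30,
                "chronic kidney disease": 0.40,
            },
            theta=5.0,
        ),
        condition_prevalence={
            "obesity": 0.08,
            "arthritis": 0.10,
            "diabetes mellitus": 0.03,
            "hypothyroidism": 0.04,
            "chronic kidney disease": 0.05,
        },
        frac_unclassified=0.10,
        frac_euthanasia_only=0.05,
        age_mode="vmdb_bins",
    )
    return replace(spec, **overrides) if overrides else spec
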