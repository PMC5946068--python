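"""Record CSV reader/writer, pipeline configuration and the full pipeline.

The interchange format is one CSV row per individual with columns
``id, cohort, sex, age_years, age_bin, diagnoses, primary_diagnosis,
cause_pp, cause_os, event`` — diagnoses are ";"-separated inside the cell,
exactly one of ``age_years`` / ``age_bin`` is filled, and binned ages are
resolved to scheme midpoints on read.  Malformed rows are collected into a
rejects table with a reason, never silently dropped.

``run_pipeline`` chains the analyses in registry order — filter, survival
and Gompertz fits, morbidity and comorbidity models, cause trajectories,
neoplastic-peak age rescaling and log2 odds ratios, and the cross-cohort
spectrum comparison — writing one CSV per stage plus a text summary.  Every
numeric output carries a header comment with the seed and a hash of the
configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import comparison as cmp_mod
from . import morbidity as morb_mod
from . import survival as surv_mod
from . import trajectories as traj_mod
from .simulate import default_dog_spec, default_human_spec, simulate_cohort
from .taxonomy import (
    AgeBinScheme,
    CauseTaxonomy,
    DeathRecord,
    InvalidRecordError,
    PP_CATEGORIES,
    filter_records,
)

__all__ = [
    "read_records",
    "write_records",
    "PipelineConfig",
    "run_pipeline",
    "PipelineError",
]

REQUIRED_COLUMNS = ("id", "cohort", "sex", "diagnoses", "primary_diagnosis", "event")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def read_records(
    path: str | Path,
    taxonomy: CauseTaxonomy | None = None,
    scheme: AgeBinScheme | None = None,
) -> tuple[list[DeathRecord], pd.DataFrame]:
    """Read and validate a records CSV.

    Returns (records, rejects); rejects has the original row index and a
    ``reason`` column.  Cause labels are taken from the file when present,
    otherwise derived from the primary diagnosis through the taxonomy.
    """
    taxonomy = taxonomy or CauseTaxonomy.default()
    scheme = scheme or AgeBinScheme.vmdb_default()
    df = pd.read_csv(path, dtype=str, comment="#", keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    if "age_years" not in df.columns and "age_bin" not in df.columns:
        raise ValueError("need an age_years or age_bin column")

    records: list[DeathRecord] = []
    rejects: list[dict] = []
    for i, row in df.iterrows():
        try:
            age_str = row.get("age_years", "").strip()
            bin_str = row.get("age_bin", "").strip()
            if age_str and bin_str:
                raise InvalidRecordError("both age_years and age_bin present")
            if not age_str and not bin_str:
                raise InvalidRecordError("no age information")
            age = float(age_str) if age_str else scheme.by_label(bin_str).midpoint
            event = row["event"].strip().lower()
            diagnoses = [d for d in row["diagnoses"].split(";") if d.strip()]
            primary = row["primary_diagnosis"].strip() or None
            pp = row.get("cause_pp", "").strip() or None
            os_ = row.get("cause_os", "").strip() or None
            if event == "death" and pp is None and primary is not None:
                pp, os_ = taxonomy.lookup(primary)
            records.append(
                DeathRecord(
                    id=row["id"].strip(),
                    cohort=row["cohort"].strip(),
                    sex=row["sex"].strip().lower(),
                    age_years=age,
                    diagnoses=diagnoses,
                    primary_diagnosis=primary,
                    cause_pp=pp,
                    cause_os=os_,
                    event=event,
                )
            )
        except (InvalidRecordError, KeyError, ValueError) as exc:
            rejects.append({"row": i, "id": row.get("id", ""), "reason": str(exc)})
    return records, pd.DataFrame(rejects, columns=["row", "id", "reason"])


def records_frame(records: list[DeathRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "cohort": r.cohort,
                "sex": r.sex,
                "age_years": r.age,
                "age_bin": "",
                "diagnoses": ";".join(r.diagnoses),
                "primary_diagnosis": r.primary_diagnosis or "",
                "cause_pp": r.cause_pp or "",
                "cause_os": r.cause_os or "",
                "event": r.event,
            }
        )
    return pd.DataFrame(rows)


def write_records(records: list[DeathRecord], path: str | Path,
                  header: str | None = None) -> None:
    with open(path, "w", newline="") as fh:
        if header:
            fh.write(f"# {header}\n")
        records_frame(records).to_csv(fh, index=False)


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``records`` (path to a records CSV) or ``simulate``
    (per-cohort sample sizes, e.g. ``{"human": 20000, "dog": 20000}``) is
    set.  Analysis switches select stages; ``comorbidity_conditions`` lists
    index diagnoses for the comorbidity models; ``bootstrap_B = 0`` skips
    confidence bands.
    """

    seed: int = 0
    records: str | None = None
    taxonomy: str | None = None
    bin_scheme: str | None = None
    simulate: dict[str, int] | None = None
    survival: bool = True
    gompertz: bool = True
    morbidity: bool = True
    comorbidity_conditions: list[str] = field(default_factory=list)
    trajectories: bool = True
    comparison: bool = True
    bootstrap_B: int = 0
    trajectory_degree: int = 4

    def __post_init__(self) -> None:
        if (self.records is None) == (self.simulate is None):
            raise ValueError("exactly one of records / simulate must be set")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def canonical(self) -> dict:
        return {
            k: getattr(self, k)
            for k in sorted(self.__dataclass_fields__)
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, seed: int, cfg_hash: str,
               index: bool = False) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# seed={seed} config={cfg_hash}\n")
        df.to_csv(fh, index=index, float_format="%.10g")


def _cohort_age_ranges(records: list[DeathRecord]) -> dict[str, tuple[float, float]]:
    out: dict[str, tuple[float, float]] = {}
    for cohort in sorted({r.cohort for r in records}):
        ages = [r.age for r in records if r.cohort == cohort and r.is_death]
        out[cohort] = (0.0, max(ages))
    return out


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the configured analyses and write the report bundle.

    Returns a dict of in-memory results keyed by stage.  Any stage failure
    raises :class:`PipelineError` naming the stage and leaves a ``FAILED``
    marker file in the output directory.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    seed = config.seed
    results: dict = {}
    log_lines = [f"seed={seed}", f"config_hash={cfg_hash}"]
    stage = "setup"
    try:
        taxonomy = (CauseTaxonomy.from_csv(config.taxonomy)
                    if config.taxonomy else CauseTaxonomy.default())
        scheme = (AgeBinScheme.from_csv(config.bin_scheme)
                  if config.bin_scheme else AgeBinScheme.vmdb_default())

        stage = "records"
        if config.simulate is not None:
            records = []
            ss = np.random.SeedSequence(seed).spawn(len(config.simulate))
            for child, (cohort, n) in zip(ss, sorted(config.simulate.items())):
                spec = {"human": default_human_spec, "dog": default_dog_spec}.get(
                    cohort, default_dog_spec
                )(label=cohort)
                sub_seed = int(child.generate_state(1)[0] % (2**31))
                records.extend(simulate_cohort(spec, int(n), sub_seed).records)
            write_records(records, out / "records.csv",
                          header=f"seed={seed} config={cfg_hash}")
            log_lines.append(f"simulated {len(records)} records")
        else:
            records, rejects = read_records(config.records, taxonomy, scheme)
            if len(rejects):
                _write_csv(rejects, out / "rejects.csv", seed, cfg_hash)
            log_lines.append(f"read {len(records)} records, {len(rejects)} rejected")

        stage = "filter"
        kept, report = filter_records(records)
        results["filter_report"] = report
        _write_csv(pd.DataFrame([report.as_dict()]), out / "filter_report.csv",
                   seed, cfg_hash)
        log_lines.append(f"filter kept {len(kept)} of {len(records)}: {report.as_dict()}")

        cohorts = sorted({r.cohort for r in kept})
        by_cohort = {c: [r for r in kept if r.cohort == c] for c in cohorts}

        if config.survival:
            stage = "survival"
            rows = []
            for cohort in cohorts:
                for sex in ("female", "male"):
                    sub = [r for r in by_cohort[cohort] if r.sex == sex]
                    if not sub:
                        continue
                    times = np.array([r.age for r in sub])
                    events = np.array([r.is_death for r in sub])
                    curve = surv_mod.km_estimate(times, events)
                    df = pd.DataFrame({"age": curve.times, "survival": curve.survival,
                                       "at_risk": curve.at_risk, "events": curve.events})
                    _write_csv(df, out / f"km_{cohort}_{sex}.csv", seed, cfg_hash)
                    hz = surv_mod.smoothed_hazard(times, events)
                    _write_csv(pd.DataFrame({"age": hz.grid, "hazard": hz.hazard}),
                               out / f"hazard_{cohort}_{sex}.csv", seed, cfg_hash)
                # within-cohort sex contrast
                times = np.array([r.age for r in by_cohort[cohort]])
                events = np.array([r.is_death for r in by_cohort[cohort]])
                groups = np.array([morb_mod.SEX_CODE[r.sex] for r in by_cohort[cohort]])
                if events[groups == 0].any() and events[groups == 1].any():
                    lhr, p = surv_mod.two_group_hazard_ratio(times, events, groups)
                    rows.append({"cohort": cohort, "log_hr_male_vs_female": lhr, "p": p})
            results["sex_contrast"] = pd.DataFrame(rows)
            _write_csv(results["sex_contrast"], out / "sex_contrast.csv", seed, cfg_hash)

        if config.gompertz:
            stage = "gompertz"
            # midpoint -> combined [lo, hi) bounds (bins sharing a midpoint merge)
            mid_bounds: dict[float, list[float]] = {}
            for b in scheme.bins:
                hi_b = b.hi if b.hi is not None else np.inf
                lo_b, hi_prev = mid_bounds.get(b.midpoint, (b.lo, hi_b))
                mid_bounds[b.midpoint] = [min(lo_b, b.lo), max(hi_prev, hi_b)]
            rows = []
            for cohort in cohorts:
                for sex in ("female", "male"):
                    sub = [r for r in by_cohort[cohort] if r.sex == sex and r.is_death]
                    if len(sub) < 2:
                        continue
                    ages = np.array([r.age for r in sub])
                    uniq = np.unique(ages)
                    binned = uniq.size <= len(scheme.bins) and all(
                        any(abs(u - m) < 1e-9 for m in mid_bounds) for u in uniq
                    )
                    if binned:
                        # ages are scheme midpoints: use the interval likelihood
                        iv = np.array([
                            mid_bounds[min(mid_bounds, key=lambda m: abs(m - a))]
                            for a in ages
                        ])
                        fit = surv_mod.fit_gompertz(iv, age_mode="interval")
                    else:
                        fit = surv_mod.fit_gompertz(ages)
                    rows.append({"cohort": cohort, "sex": sex, "alpha": fit.alpha,
                                 "beta": fit.beta, "loglik": fit.log_likelihood,
                                 "mode": "interval" if binned else "exact",
                                 "n": len(sub)})
            results["gompertz"] = pd.DataFrame(rows)
            _write_csv(results["gompertz"], out / "gompertz.csv", seed, cfg_hash)

        if config.morbidity:
            stage = "morbidity"
            for cohort in cohorts:
                model = morb_mod.multimorbidity_analysis(by_cohort[cohort], "pp")
                results[f"multimorbidity_{cohort}"] = model
                _write_csv(model.summary_frame(), out / f"multimorbidity_{cohort}.csv",
                           seed, cfg_hash, index=True)

        if config.comorbidity_conditions:
            stage = "comorbidity"
            for cohort in cohorts:
                rows = []
                for cond in config.comorbidity_conditions:
                    try:
                        m = morb_mod.comorbidity_analysis(by_cohort[cohort], cond)
                    except ValueError:
                        log_lines.append(f"comorbidity: {cond!r} absent in {cohort}")
                        continue
                    rows.append({
                        "condition": cond,
                        "coef": m.params["condition"],
                        "se": m.bse["condition"],
                        "p": m.pvalues["condition"],
                        "adj_mean_cases": m.adjusted_means["cases"],
                        "adj_mean_non_cases": m.adjusted_means["non_cases"],
                    })
                if rows:
                    df = pd.DataFrame(rows)
                    results[f"comorbidity_{cohort}"] = df
                    _write_csv(df, out / f"comorbidity_{cohort}.csv", seed, cfg_hash)

        models: dict[str, traj_mod.MultinomialAgeModel] = {}
        ranges = _cohort_age_ranges(kept)
        if config.trajectories:
            stage = "trajectories"
            grid_rows = []
            for cohort in cohorts:
                deaths = [r for r in by_cohort[cohort] if r.is_death]
                ages = np.array([r.age for r in deaths])
                causes = np.array([r.cause_pp for r in deaths], dtype=object)
                model = traj_mod.fit_cause_trajectory(
                    ages, causes, degree=config.trajectory_degree)
                models[cohort] = model
                lo, hi = ranges[cohort]
                grid = np.linspace(lo, hi, 101)
                P = traj_mod.predict_proportions(model, grid)
                bands = {}
                if config.bootstrap_B >= 50:
                    for cause in model.labels:
                        bands[cause] = traj_mod.confidence_band(
                            model, ages, causes, cause, grid,
                            B=config.bootstrap_B, seed=seed)
                for j, cause in enumerate(model.labels):
                    lowers, uppers = bands.get(cause, (np.full(grid.size, np.nan),) * 2)
                    for g, age in enumerate(grid):
                        grid_rows.append({"cohort": cohort, "cause": cause,
                                          "age": age, "proportion": P[g, j],
                                          "lower": lowers[g], "upper": uppers[g]})
            results["trajectory_models"] = models
            _write_csv(pd.DataFrame(grid_rows), out / "trajectories.csv", seed, cfg_hash)

        if config.comparison and len(cohorts) >= 2:
            stage = "comparison"
            human_label = "human" if "human" in cohorts else cohorts[0]
            dog_label = "dog" if "dog" in cohorts else [c for c in cohorts
                                                        if c != human_label][0]
            scale = None
            if models:
                try:
                    scale = traj_mod.compute_age_scale(
                        models[human_label], models[dog_label],
                        human_age_range=ranges[human_label],
                        dog_age_range=ranges[dog_label])
                    results["age_scale"] = scale
                except (ValueError, KeyError) as exc:
                    log_lines.append(f"age scale unavailable: {exc}")
            if scale is not None:
                or_rows = []
                grid = np.linspace(1.0, ranges[human_label][1], 100)
                shared_pp = [c for c in models[human_label].labels
                             if c in models[dog_label].labels]
                for cause in shared_pp:
                    curve = traj_mod.odds_ratio_curve(
                        models[human_label], models[dog_label], scale, cause, grid)
                    for a, v, cl in zip(curve.human_ages, curve.log2_or, curve.clipped):
                        or_rows.append({"cause": cause, "human_age": a,
                                        "log2_or": v, "clipped": bool(cl)})
                _write_csv(pd.DataFrame(or_rows), out / "odds_ratios.csv",
                           seed, cfg_hash)

            pair = {human_label: by_cohort[human_label], dog_label: by_cohort[dog_label]}
            rho_rows = []
            for axis in ("pp", "os", "cancer_os"):
                tab = cmp_mod.proportion_table(pair, axis)
                _write_csv(tab.table, out / f"proportions_{axis}.csv",
                           seed, cfg_hash, index=True)
                variants = [()] if axis != "pp" else [(), ("vascular",)]
                for excl in variants:
                    try:
                        r = cmp_mod.spearman(tab.proportions(human_label),
                                             tab.proportions(dog_label), exclude=excl)
                    except ValueError as exc:
                        log_lines.append(f"spearman {axis} {excl}: {exc}")
                        continue
                    rho_rows.append({"axis": axis, "excluded": ";".join(excl),
                                     "rho": r.rho, "p": r.p_value,
                                     "n_categories": r.n_categories,
                                     "method": r.method})
            results["spearman"] = pd.DataFrame(rho_rows)
            _write_csv(results["spearman"], out / "spearman.csv", seed, cfg_hash)

            ar_rows = []
            for cohort in (human_label, dog_label):
                deaths = [r for r in by_cohort[cohort] if r.is_death]
                hi = ranges[cohort][1]
                edges = np.linspace(0.0, hi, 11)
                for cause in PP_CATEGORIES:
                    res = cmp_mod.age_relatedness(deaths, cause, edges, min_deaths=0)
                    ar_rows.append({"cohort": cohort, "cause": cause,
                                    "age_related": res.age_related,
                                    "tau": res.tau, "p": res.p_value})
            results["age_relatedness"] = pd.DataFrame(ar_rows)
            _write_csv(results["age_relatedness"], out / "age_relatedness.csv",
                       seed, cfg_hash)

        stage = "summary"
        _write_summary(out / "summary.txt", config, results)
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return results


def _write_summary(path: Path, config: PipelineConfig, results: dict) -> None:
    lines = [
        "dogyears pipeline summary",
        f"seed: {config.seed}",
        f"config: {config.config_hash()}",
        "",
    ]
    if "filter_report" in results:
        lines.append(f"filtering: {results['filter_report'].as_dict()}")
    if "gompertz" in results and len(results["gompertz"]):
        lines.append("\nGompertz rate-of-aging (beta, per year):")
        for _, row in results["gompertz"].iterrows():
            lines.append(f"  {row['cohort']:>8} {row['sex']:>6}: "
                         f"beta={row['beta']:.4f} alpha={row['alpha']:.3e} "
                         f"(n={int(row['n'])})")
    for key, val in results.items():
        if key.startswith("comorbidity_"):
            lines.append(f"\nComorbidity effects, cohort {key.split('_', 1)[1]}:")
            for _, row in val.iterrows():
                lines.append(f"  {row['condition']:>24}: coef={row['coef']:.3f} "
                             f"(p={row['p']:.2g}) cases={row['adj_mean_cases']:.2f} "
                             f"vs non-cases={row['adj_mean_non_cases']:.2f}")
    if "age_scale" in results:
        s = results["age_scale"]
        lines.append(f"\nNeoplastic peak ages: human {s.human_peak_age:.1f} y, "
                     f"dog {s.dog_peak_age:.1f} y")
        lines.append(f"Age scale factor: {s.scale_factor:.2f} human-years per dog-year")
    if "spearman" in results and len(results["spearman"]):
        lines.append("\nSpearman rank correlations of cause spectra:")
        for _, row in results["spearman"].iterrows():
            excl = f" (excluding {row['excluded']})" if row["excluded"] else ""
            lines.append(f"  {row['axis']:>9}{excl}: rho={row['rho']:.3f} "
                         f"p={row['p']:.3f} (n={int(row['n_categories'])})")
    path.write_text("\n".join(lines) + "\n")
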