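"""Generator behaviour: samplers, determinism, contamination, recovery."""

import numpy as np
import pytest
from scipy import stats

from dogyears.survival import GompertzParams, fit_gompertz, gompertz_survival
from dogyears.simulate import (
    default_dog_spec,
    default_human_spec,
    peaked_cause_model,
    simulate_causes,
    simulate_cohort,
    simulate_lifespans,
    simulate_morbidity,
)
from dogyears.taxonomy import CauseTaxonomy, filter_records
from dogyears.trajectories import (
    compute_age_scale,
    find_peak_age,
    fit_cause_trajectory,
    predict_proportions,
)


class TestSimulateLifespans:
    def test_empirical_survival_matches_closed_form(self):
        p = GompertzParams(1e-3, 0.08)
        ages = simulate_lifespans(p, 100000, seed=0)
        grid = np.linspace(0, ages.max(), 200)
        emp = 1.0 - np.searchsorted(np.sort(ages), grid, side="right") / ages.size
        assert np.max(np.abs(emp - gompertz_survival(p, grid))) < 0.01

    def test_zero_slope_falls_back_to_exponential(self):
        ages = simulate_lifespans(GompertzParams(0.2, 0.0), 50000, seed=1)
        assert ages.mean() == pytest.approx(5.0, rel=0.03)

    def test_same_seed_is_bit_identical(self):
        p = GompertzParams(1e-3, 0.08)
        np.testing.assert_array_equal(
            simulate_lifespans(p, 1000, seed=2), simulate_lifespans(p, 1000, seed=2)
        )

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            simulate_lifespans(GompertzParams(1e-3, 0.08), 0, seed=3)


class TestSimulateCauses:
    def test_null_model_gives_half_half(self):
        from test_trajectories import constant_model

        m = constant_model(["a", "b"], [0.0, 0.0])
        causes = simulate_causes(m, np.full(10000, 10.0), seed=4)
        frac = np.mean(causes == "a")
        assert 0.49 <= frac <= 0.51

    def test_binned_fractions_track_the_model(self):
        spec = default_dog_spec()
        rng = np.random.default_rng(5)
        ages = rng.uniform(0.5, 19.5, 30000)
        causes = simulate_causes(spec.cause_model, ages, seed=6)
        labels = list(spec.cause_model.labels)
        for lo in (0.5, 5.0, 10.0, 15.0):
            sel = (ages >= lo) & (ages < lo + 4.5)
            obs = np.array([(causes[sel] == lab).sum() for lab in labels])
            exp = predict_proportions(
                spec.cause_model, ages[sel]).mean(axis=0) * sel.sum()
            keep = exp > 1.0
            chi2 = ((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum()
            p = stats.chi2.sf(chi2, keep.sum() - 1)
            assert p > 0.001

    def test_deterministic_given_seed(self):
        spec = default_dog_spec()
        ages = np.linspace(0.5, 19.0, 500)
        np.testing.assert_array_equal(
            simulate_causes(spec.cause_model, ages, seed=7),
            simulate_causes(spec.cause_model, ages, seed=7),
        )


class TestSimulateMorbidity:
    @staticmethod
    def _draw(n=4000, seed=8, **spec_over):
        spec = default_dog_spec(**spec_over)
        rng = np.random.default_rng(seed)
        ages = rng.uniform(0.5, 19.0, n)
        sexes = np.where(rng.random(n) < 0.5, "female", "male")
        taxonomy = CauseTaxonomy.default()
        primaries = ["lymphoma"] * n
        lists, flags = simulate_morbidity(spec, ages, sexes, primaries,
                                          taxonomy, seed)
        return ages, lists, flags

    def test_minimum_count_is_one_and_counts_rise_with_age(self):
        ages, lists, _ = self._draw()
        counts = np.array([len(l) for l in lists])
        assert counts.min() >= 1
        terciles = np.quantile(ages, [1 / 3, 2 / 3])
        m_young = counts[ages < terciles[0]].mean()
        m_old = counts[ages >= terciles[1]].mean()
        assert m_old > m_young

    def test_primary_always_included(self):
        _, lists, _ = self._draw(n=2000)
        assert all("lymphoma" in l for l in lists)

    def test_flagged_conditions_appear_in_the_list(self):
        _, lists, flags = self._draw(n=2000)
        for cond, f in flags.items():
            for i in np.flatnonzero(f)[:50]:
                assert cond in lists[i]


class TestSimulateCohort:
    def test_no_contamination_means_nothing_filtered(self):
        spec = default_dog_spec(frac_unclassified=0.0, frac_euthanasia_only=0.0)
        cohort = simulate_cohort(spec, 2000, seed=9)
        kept, report = filter_records(cohort.records)
        assert report.total_removed == 0
        assert len(kept) == 2000

    def test_contamination_fractions_recovered(self):
        spec = default_dog_spec(frac_unclassified=0.10, frac_euthanasia_only=0.05)
        cohort = simulate_cohort(spec, 10000, seed=10)
        _, report = filter_records(cohort.records)
        assert report.unclassified / 10000 == pytest.approx(0.10, abs=0.01)
        assert report.euthanasia_only / 10000 == pytest.approx(0.05, abs=0.01)

    def test_regeneration_is_bit_identical(self):
        spec = default_dog_spec()
        a = simulate_cohort(spec, 1500, seed=11)
        b = simulate_cohort(spec, 1500, seed=11)
        for ra, rb in zip(a.records, b.records):
            assert ra == rb

    def test_binned_mode_uses_scheme_midpoints(self, bin_scheme):
        cohort = simulate_cohort(default_dog_spec(), 2000, seed=12)
        mids = {b.midpoint for b in bin_scheme.bins}
        assert {r.age_years for r in cohort.records} <= mids

    def test_comorbidity_equals_multimorbidity_minus_one_for_cases(self):
        cohort = simulate_cohort(default_dog_spec(), 3000, seed=13)
        kept, _ = filter_records(cohort.records)
        checked = 0
        for r in kept:
            normed = {d.lower() for d in r.diagnoses}
            if "obesity" in normed:
                assert len(normed) - 1 == r.n_diagnoses() - 1
                checked += 1
        assert checked > 50

    def test_exact_mode_round_trip_through_csv(self, tmp_path):
        from dogyears.io import read_records, write_records

        spec = default_human_spec()
        cohort = simulate_cohort(spec, 300, seed=14)
        path = tmp_path / "records.csv"
        write_records(cohort.records, path)
        back, rejects = read_records(path)
        assert len(rejects) == 0
        for orig, rt in zip(cohort.records, back):
            assert rt.id == orig.id
            assert rt.age_years == pytest.approx(orig.age_years, abs=1e-9)
            assert [d.lower() for d in rt.diagnoses] == [
                d.lower() for d in orig.diagnoses]
            assert (rt.cause_pp, rt.cause_os) == (orig.cause_pp, orig.cause_os)


class TestEndToEndRecovery:
    """Scaled-down pipeline recovery: slopes, peaks and the scale factor."""

    def test_two_cohort_generation_recovers_generating_truth(self):
        n = 30000
        human = default_human_spec()
        dog = default_dog_spec(age_mode="exact", frac_unclassified=0.0,
                               frac_euthanasia_only=0.0)

        h_ages = simulate_lifespans(human.gompertz["female"], n, seed=15)
        assert fit_gompertz(h_ages).beta == pytest.approx(0.089, rel=0.03)

        d_ages = simulate_lifespans(dog.gompertz["female"], n, seed=16)
        assert fit_gompertz(d_ages).beta == pytest.approx(0.0214, rel=0.03)

        h_ages_c = np.clip(h_ages, *human.age_range)
        d_ages_c = np.clip(d_ages, *dog.age_range)
        h_model = fit_cause_trajectory(
            h_ages_c, simulate_causes(human.cause_model, h_ages_c, seed=17))
        d_model = fit_cause_trajectory(
            d_ages_c, simulate_causes(dog.cause_model, d_ages_c, seed=18))
        h_peak = find_peak_age(h_model, "neoplastic", (0.0, 100.0))
        d_peak = find_peak_age(d_model, "neoplastic", (0.0, 20.0))
        assert h_peak.age == pytest.approx(53.0, rel=0.05)
        assert d_peak.age == pytest.approx(11.5, rel=0.05)
        scale = compute_age_scale(h_model, d_model,
                                  human_age_range=(0.0, 100.0),
                                  dog_age_range=(0.0, 20.0))
        assert scale.scale_factor == pytest.approx(53.0 / 11.5, rel=0.05)


class TestPeakedCauseModel:
    def test_calibration_places_the_proportion_peak(self):
        m = peaked_cause_model(
            raw_logits={"other": (0.5, -0.05)},
            peak_cause="neoplastic", peak_age=11.5, curvature=0.02,
            height=1.0, age_range=(0.0, 20.0))
        pk = find_peak_age(m, "neoplastic", (0.0, 20.0))
        assert pk.age == pytest.approx(11.5, abs=0.02)

    def test_default_specs_peak_at_reported_ages(self):
        h = default_human_spec()
        d = default_dog_spec()
        assert find_peak_age(h.cause_model, "neoplastic",
                             (0.0, 100.0)).age == pytest.approx(53.0, abs=0.05)
        assert find_peak_age(d.cause_model, "neoplastic",
                             (0.0, 20.0)).age == pytest.approx(11.5, abs=0.05)
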