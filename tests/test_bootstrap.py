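"""Balanced resampling, bootstrap distributions, and condition comparisons."""

import numpy as np
import pytest

from ppspace import (
    BootstrapDistribution,
    CohortSpec,
    PPSError,
    balanced_resample,
    bootstrap_xc,
    build_profile,
    compare_conditions,
    filter_trials,
    fit_sigmoid,
    normalize_profile,
    pool_central,
    simulate_cohort,
)
from ppspace.bootstrap import stratum_quota

from conftest import make_trial

DISTANCES = (0.25, 0.75, 1.25, 1.75, 2.25)


def stratified_trials(n_per_stratum, rt0=0.25):
    trials = []
    for j, d in enumerate(DISTANCES):
        for i in range(n_per_stratum):
            trials.append(make_trial(distance=d, rt=rt0 + 0.02 * j + 0.001 * i))
    return trials


def dist_from(samples, condition="x"):
    samples = np.asarray(samples, dtype=float)
    return BootstrapDistribution(
        condition=condition,
        xc_samples=samples,
        n_iterations=samples.size,
        per_distance_resample_n={},
        seed=None,
    )


class TestBalancedResample:
    def test_equal_strata_resampled_exactly(self):
        trials = stratified_trials(8)
        out = balanced_resample(trials, seed=0)
        assert len(out) == 40
        for d in DISTANCES:
            assert sum(t.distance_m == d for t in out) == 8

    def test_draws_stay_within_stratum(self):
        trials = stratified_trials(6)
        out = balanced_resample(trials, seed=1)
        allowed = {
            d: {t.rt_s for t in trials if t.distance_m == d} for d in DISTANCES
        }
        assert all(t.rt_s in allowed[t.distance_m] for t in out)

    def test_singleton_stratum_repeats_quota_times(self):
        trials = [t for t in stratified_trials(4) if t.distance_m != 2.25]
        trials.append(make_trial(distance=2.25, rt=0.31))
        quota = stratum_quota(len(trials), 5)
        out = balanced_resample(trials, seed=2)
        far = [t for t in out if t.distance_m == 2.25]
        assert len(far) == quota and {t.rt_s for t in far} == {0.31}

    def test_deterministic_under_seed(self):
        trials = stratified_trials(5)
        assert balanced_resample(trials, seed=3) == balanced_resample(trials, seed=3)

    def test_empty_stratum_is_an_error(self):
        trials = stratified_trials(3)
        with pytest.raises(PPSError, match="stratum"):
            balanced_resample(trials, seed=0, distances=(*DISTANCES, 3.25))

    def test_exp2_scale_quota(self, design_exp2):
        """27 participants x 12 central trials per distance gives a
        per-distance quota of 324 = round(1620 / 5)."""
        assert stratum_quota(27 * 12 * 5, 5) == 324


@pytest.fixture(scope="module")
def pooled_baseline():
    from ppspace import ExperimentDesign

    design = ExperimentDesign.exp1()
    spec = CohortSpec(n_responders=12, seed=31)
    trials = simulate_cohort(spec, design, ["baseline"])
    kept, _ = filter_trials(trials, design)
    return pool_central(kept)


class TestBootstrapXc:
    def test_zero_noise_data_collapse_to_point_estimate(self, design_exp1):
        # one participant, no noise: every trial in a stratum is identical,
        # so every balanced resample reproduces the same profile
        spec = CohortSpec(
            n_responders=1, seed=2, noise_sd_s=0.0, lapse_rate=0.0, premature_rate=0.0
        )
        trials = simulate_cohort(spec, design_exp1, ["baseline"])
        kept, _ = filter_trials(trials, design_exp1)
        pooled = pool_central(kept)
        point = fit_sigmoid(
            normalize_profile(build_profile(pooled, distances=design_exp1.distances_m))
        )
        dist = bootstrap_xc(pooled, n_iterations=50, seed=5)
        assert dist.n_failed_fits == 0
        assert np.allclose(dist.xc_samples, point.xc_m, atol=1e-6)

    def test_reproducible_under_master_seed(self, pooled_baseline):
        a = bootstrap_xc(pooled_baseline, n_iterations=80, seed=7)
        b = bootstrap_xc(pooled_baseline, n_iterations=80, seed=7)
        assert np.array_equal(a.xc_samples, b.xc_samples)

    def test_different_seeds_agree_statistically(self, pooled_baseline):
        a = bootstrap_xc(pooled_baseline, n_iterations=400, seed=1)
        b = bootstrap_xc(pooled_baseline, n_iterations=400, seed=2)
        assert not np.array_equal(a.xc_samples, b.xc_samples)
        se = a.xc_samples.std(ddof=1) / np.sqrt(a.xc_samples.size)
        assert abs(a.xc_samples.mean() - b.xc_samples.mean()) < 3 * np.sqrt(2) * se

    def test_samples_respect_bounds_and_accounting(self, pooled_baseline):
        dist = bootstrap_xc(pooled_baseline, n_iterations=60, seed=9)
        assert len(dist.xc_samples) == dist.n_iterations - dist.n_failed_fits
        assert np.all((dist.xc_samples >= 0.25) & (dist.xc_samples <= 2.25))
        quota = stratum_quota(len(pooled_baseline), 5)
        assert set(dist.per_distance_resample_n.values()) == {quota}

    def test_scalar_engine_matches_batch(self, pooled_baseline):
        a = bootstrap_xc(pooled_baseline, n_iterations=40, seed=13)
        b = bootstrap_xc(pooled_baseline, n_iterations=40, seed=13, engine="scalar")
        assert np.allclose(a.xc_samples, b.xc_samples, atol=1e-5)

    def test_resamples_match_balanced_resample(self, pooled_baseline):
        """The distribution's first iteration uses exactly the draw that
        balanced_resample produces from the first spawned child seed."""
        children = np.random.SeedSequence(21).spawn(1)
        manual = balanced_resample(
            pooled_baseline, np.random.default_rng(children[0])
        )
        prof = normalize_profile(build_profile(manual, distances=DISTANCES))
        fit = fit_sigmoid(prof)
        dist = bootstrap_xc(pooled_baseline, n_iterations=1, seed=21)
        assert dist.xc_samples[0] == pytest.approx(fit.xc_m, abs=1e-5)

    def test_coverage_of_the_noise_free_estimand(self, design_exp1):
        """The central 95% bootstrap interval covers the cohort's noise-free
        pipeline value in >= 90% of replicate experiments."""
        from ppspace.fitting import fit_logistic_batch

        x = np.array(design_exp1.distances_m)
        hits = 0
        n_rep = 60
        for rep in range(n_rep):
            spec = CohortSpec(n_responders=10, seed=1000 + rep)
            profiles = dict(spec.draw_profiles(design_exp1))
            m = np.mean([p.mean_rt(x) for p in profiles.values()], axis=0)
            z = (m - m.min()) / (m.max() - m.min())
            target = float(fit_logistic_batch(x, z[None, :])[0][0])
            trials = simulate_cohort(spec, design_exp1, ["baseline"])
            kept, _ = filter_trials(trials, design_exp1)
            dist = bootstrap_xc(
                pool_central(kept), n_iterations=300, seed=rep, distances=x
            )
            lo, hi = np.percentile(dist.xc_samples, [2.5, 97.5])
            hits += lo <= target <= hi
        assert hits >= 0.9 * n_rep


class TestCompareConditions:
    def test_identical_distributions(self):
        a = dist_from(np.linspace(1.0, 1.5, 200), "baseline")
        b = dist_from(np.linspace(1.0, 1.5, 200), "pull")
        res = compare_conditions(a, b)
        assert res.p_value == 1.0 and res.delta_mean_m == 0.0

    def test_fully_separated_distributions(self):
        rng = np.random.default_rng(0)
        a = dist_from(rng.normal(1.2, 0.02, 500), "baseline")
        b = dist_from(rng.normal(1.6, 0.02, 500), "pull")
        res = compare_conditions(a, b)
        assert res.p_value == 0.0
        assert res.p_display == "p < 0.002"
        assert res.delta_mean_m == pytest.approx(0.4, abs=0.01)

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(1)
        a = dist_from(rng.normal(1.2, 0.05, 300), "baseline")
        b = dist_from(rng.normal(1.3, 0.05, 300), "pull")
        fwd = compare_conditions(a, b)
        rev = compare_conditions(b, a)
        assert fwd.delta_mean_m == pytest.approx(-rev.delta_mean_m, abs=1e-15)
        assert fwd.p_value == rev.p_value

    def test_unequal_lengths_truncate(self):
        a = dist_from(np.full(100, 1.2))
        b = dist_from(np.full(80, 1.2))
        assert compare_conditions(a, b).n_pairs == 80

    def test_studentized_variant_orders_like_sign_test(self):
        rng = np.random.default_rng(2)
        a = dist_from(rng.normal(1.2, 0.05, 400), "baseline")
        b = dist_from(rng.normal(1.5, 0.05, 400), "pull")
        null = dist_from(rng.normal(1.2, 0.05, 400), "same")
        assert compare_conditions(a, b, method="t").p_value < 0.05
        assert compare_conditions(a, null, method="t").p_value > 0.05
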