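"""Profiles, normalization, and the anchored sigmoid boundary fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppspace import (
    DegenerateProfileError,
    EmptyCellError,
    ParticipantProfile,
    RTProfile,
    build_profile,
    filter_trials,
    fit_logistic_batch,
    fit_sigmoid,
    logistic,
    normalize_profile,
    pool_central,
    simulate_participant,
)

from conftest import make_trial

DISTANCES = (0.25, 0.75, 1.25, 1.75, 2.25)


def profile_from_z(z, distances=DISTANCES):
    return RTProfile(
        condition="baseline",
        distances_m=tuple(distances),
        mean_rt_s=tuple(z),
        n_per_distance=(1,) * len(distances),
        normalized=tuple(z),
    )


class TestBuildProfile:
    def test_noise_free_profile_matches_generative_curve(self, design_exp1):
        p = ParticipantProfile(noise_sd_s=0.0, lapse_rate=0.0, premature_rate=0.0)
        trials = simulate_participant(p, design_exp1, "baseline", seed=1)
        kept, _ = filter_trials(trials, design_exp1)
        prof = build_profile(pool_central(kept), distances=design_exp1.distances_m)
        expected = p.mean_rt(np.array(design_exp1.distances_m))
        assert np.allclose(prof.mean_rt_s, expected, atol=1e-12)

    def test_equal_counts_pool_to_mean_of_participant_means(self):
        trials = [
            make_trial(pid="A", distance=0.25, rt=0.24),
            make_trial(pid="B", distance=0.25, rt=0.26),
        ]
        prof = build_profile(trials)
        assert prof.mean_rt_s == (pytest.approx(0.25),)

    def test_unequal_counts_weight_by_trials(self):
        """2x2 toy: A contributes RTs (0.20, 0.40), B a single 0.30 at the
        same distance -> trial-level pooled mean 0.30, participant-mean 0.30;
        at the second distance A has (0.30,), B (0.20, 0.40) -> both 0.30.
        Shift B's trials to make the two pooling rules disagree."""
        trials = [
            make_trial(pid="A", distance=0.25, rt=0.20),
            make_trial(pid="A", distance=0.25, rt=0.40),
            make_trial(pid="A", distance=0.25, rt=0.30),
            make_trial(pid="B", distance=0.25, rt=0.10),
        ]
        pooled = build_profile(trials)
        by_participant = build_profile(trials, participant_mean=True)
        assert pooled.mean_rt_s == (pytest.approx((0.20 + 0.40 + 0.30 + 0.10) / 4),)
        assert by_participant.mean_rt_s == (pytest.approx((0.30 + 0.10) / 2),)
        assert pooled.n_per_distance == (4,)

    def test_empty_cell_is_named(self):
        trials = [make_trial(distance=0.25, rt=0.28)]
        with pytest.raises(EmptyCellError, match="1.25"):
            build_profile(trials, distances=(0.25, 1.25))


class TestNormalizeProfile:
    def test_direct_arithmetic(self):
        prof = RTProfile("baseline", DISTANCES, (0.25, 0.26, 0.28, 0.30, 0.31), (1,) * 5)
        z = normalize_profile(prof).normalized
        assert z == pytest.approx((0.0, 1 / 6, 1 / 2, 5 / 6, 1.0), abs=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0.1, max_value=1.0), min_size=5, max_size=5)
    )
    def test_exact_endpoints_and_idempotence(self, means):
        prof = RTProfile("baseline", DISTANCES, tuple(means), (1,) * 5)
        if np.ptp(means) == 0:
            with pytest.raises(DegenerateProfileError):
                normalize_profile(prof)
            return
        norm = normalize_profile(prof)
        assert min(norm.normalized) == 0.0 and max(norm.normalized) == 1.0
        again = normalize_profile(
            RTProfile("baseline", DISTANCES, norm.normalized, (1,) * 5)
        )
        assert again.normalized == pytest.approx(norm.normalized, abs=1e-15)

    def test_raw_means_retained(self):
        prof = RTProfile("baseline", DISTANCES, (0.25, 0.26, 0.28, 0.30, 0.31), (1,) * 5)
        norm = normalize_profile(prof)
        assert norm.mean_rt_s == prof.mean_rt_s

    def test_degenerate_profile_raises(self):
        prof = RTProfile("baseline", DISTANCES, (0.28,) * 5, (1,) * 5)
        with pytest.raises(DegenerateProfileError):
            normalize_profile(prof)


class TestFitSigmoid:
    @pytest.mark.parametrize("xc,b", [(1.25, 0.3), (0.9, 0.15), (1.7, 0.45)])
    def test_noise_free_parameter_recovery(self, xc, b):
        z = logistic(np.array(DISTANCES), xc, b)
        fit = fit_sigmoid(profile_from_z(z))
        assert fit.converged
        assert fit.xc_m == pytest.approx(xc, abs=1e-6)
        assert fit.width_b_m == pytest.approx(b, abs=1e-6)

    def test_antisymmetric_profile_puts_boundary_at_midpoint(self):
        fit = fit_sigmoid(profile_from_z((0.0, 0.2, 0.5, 0.8, 1.0)))
        assert fit.xc_m == pytest.approx(1.25, abs=1e-6)

    def test_midpoint_identity(self):
        """y(x_c) = (y_min + y_max) / 2 identically, anchored or free."""
        z = (0.02, 0.15, 0.55, 0.88, 0.97)
        for anchor in (True, False):
            fit = fit_sigmoid(profile_from_z(z), anchor=anchor)
            assert float(fit.predict(fit.xc_m)) == pytest.approx(
                (fit.y_min + fit.y_max) / 2, abs=1e-12
            )

    def test_anchoring_fixes_asymptotes(self):
        fit = fit_sigmoid(profile_from_z((0.0, 0.1, 0.5, 0.9, 1.0)))
        assert fit.y_min == 0.0 and fit.y_max == 1.0

    def test_boundary_respects_bounds(self):
        # strongly monotone profile pushes x_c toward the far edge, never past
        fit = fit_sigmoid(profile_from_z((0.0, 0.01, 0.02, 0.05, 1.0)))
        assert 0.25 <= fit.xc_m <= 2.25
        assert fit.width_b_m > 0

    def test_shift_equivariance(self):
        delta = 0.7
        z = logistic(np.array(DISTANCES), 1.1, 0.25)
        fit = fit_sigmoid(profile_from_z(z))
        shifted = np.array(DISTANCES) + delta
        fit2 = fit_sigmoid(
            profile_from_z(z, distances=shifted),
            xc_bounds=(0.25 + delta, 2.25 + delta),
        )
        assert fit2.xc_m == pytest.approx(fit.xc_m + delta, abs=1e-6)

    def test_unnormalized_profile_rejected(self):
        prof = RTProfile("baseline", DISTANCES, (0.25, 0.26, 0.28, 0.30, 0.31), (1,) * 5)
        with pytest.raises(Exception, match="normalized"):
            fit_sigmoid(prof)

    def test_noisy_recovery_within_half_distance_step(self):
        """Gaussian noise of SD 0.05 on the normalized points leaves the
        recovered boundary within 0.05 m of truth (median over 100 seeds)."""
        rng = np.random.default_rng(42)
        x = np.array(DISTANCES)
        true_xc, true_b = 1.26, 0.3
        errors = []
        z0 = logistic(x, true_xc, true_b)
        Z = z0[None, :] + rng.normal(0.0, 0.05, size=(100, 5))
        xc, _, _, conv = fit_logistic_batch(x, Z)
        assert conv.all()
        errors = np.abs(xc - true_xc)
        assert np.median(errors) < 0.05


class TestBatchSolver:
    def test_matches_scalar_solver(self, rng):
        """The vectorized grid + Gauss-Newton solver and the multi-start
        scipy solver find the same least-squares solutions."""
        x = np.array(DISTANCES)
        Z = np.clip(
            logistic(x, rng.uniform(0.5, 2.0, 40)[:, None], rng.uniform(0.1, 0.8, 40)[:, None])
            + rng.normal(0, 0.08, size=(40, 5)),
            -0.2,
            1.2,
        )
        xc_b, b_b, rss_b, conv_b = fit_logistic_batch(x, Z)
        for i in range(Z.shape[0]):
            scalar = fit_sigmoid(profile_from_z(Z[i]))
            if not (scalar.converged and conv_b[i]):
                continue
            assert rss_b[i] == pytest.approx(scalar.rss, abs=1e-8)
            assert xc_b[i] == pytest.approx(scalar.xc_m, abs=1e-4)

    def test_single_profile_shape(self):
        z = logistic(np.array(DISTANCES), 1.3, 0.2)
        xc, b, rss, conv = fit_logistic_batch(np.array(DISTANCES), z)
        assert xc.shape == (1,) and conv[0]
        assert xc[0] == pytest.approx(1.3, abs=1e-6)
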