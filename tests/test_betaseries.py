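"""LS-S estimation, scrubbing, normalization, and Fisher-z connectivity."""

import numpy as np
import pytest

from betanet.betaseries import (
    BetaSeries,
    WeightedNetwork,
    build_lss_design,
    compute_connectivity,
    estimate_beta_series,
    normalize_within_condition,
    scrub_trials,
)
from betanet.design import generate_task_design
from betanet.hrf import stick_regressors
from betanet.simulate import PlantedModel, generate_cohort


def small_design(n_per_cond=6, isi=(3300, 4300, 5300), seed=0):
    return generate_task_design(
        n_trials_per_condition=n_per_cond, numerosities=(2, 4),
        isi_set=isi, seed=seed,
    )


def noiseless_cohort(design, n_regions=8, n_subjects=1, seed=0, **kw):
    labels = np.sort(np.arange(n_regions) % 2)
    m = PlantedModel(
        n_regions=n_regions, partition_a=labels, partition_b=labels,
        rho_within=0.7, rho_between=0.1, sigma_noise=kw.pop("sigma_noise", 0.0),
        censor_rate=kw.pop("censor_rate", 0.0), n_subjects=n_subjects, seed=seed,
    )
    return generate_cohort(design, m)


class TestLssDesign:
    def test_two_trial_structure(self):
        d = generate_task_design(
            n_trials_per_condition=1, numerosities=(2,), isi_set=(3300,), seed=0
        )
        X = build_lss_design(d, 0)
        # trial of interest + combined other + intercept
        assert X.shape == (d.n_volumes, 3)
        assert np.allclose(X[:, 2], 1.0)

    def test_nuisance_columns_appended(self):
        d = small_design()
        nuis = np.ones((d.n_volumes, 2))
        X = build_lss_design(d, 3, nuisance=nuis)
        assert X.shape[1] == 2 + 2 + 1

    def test_zero_nuisance_leaves_betas_unchanged(self):
        d = small_design()
        cohort = noiseless_cohort(d)
        ts = cohort.subjects[0].roi_timeseries
        b0 = estimate_beta_series(ts, d)
        bz = estimate_beta_series(ts, d, nuisance=np.zeros((d.n_volumes, 1)))
        # all-zero nuisance is rank-deficient unless dropped; compare to tiny
        np.testing.assert_allclose(b0.betas, bz.betas, atol=1e-8)

    def test_isolated_trial_beta_matches_ls_all(self):
        """A trial far from the rest matches the one-regressor-per-trial GLM."""
        d = small_design(n_per_cond=4, isi=(32000,))
        cohort = noiseless_cohort(d)
        ts = cohort.subjects[0].roi_timeseries
        bs = estimate_beta_series(ts, d)
        X = stick_regressors(d.onsets(), d.tr, d.n_volumes)
        Xfull = np.column_stack([X, np.ones(d.n_volumes)])
        coef, *_ = np.linalg.lstsq(Xfull, ts, rcond=None)
        # the shared intercept couples the combined-others misfit into the
        # trial coefficient at the 1e-3 level even for disjoint regressors
        np.testing.assert_allclose(bs.betas, coef[:-1].T, atol=1e-2)


class TestEstimation:
    def test_two_trial_noiseless_identity_is_exact(self):
        """With 2 trials LS-S equals LS-all and recovers betas exactly."""
        d = generate_task_design(
            n_trials_per_condition=1, numerosities=(2,), isi_set=(3300,), seed=0
        )
        cohort = noiseless_cohort(d)
        s = cohort.subjects[0]
        bs = estimate_beta_series(s.roi_timeseries, d)
        rel = np.abs(bs.betas.T - s.ground_truth_betas).max() / np.abs(
            s.ground_truth_betas
        ).max()
        assert rel < 1e-6

    def test_spaced_design_near_exact(self):
        """Disjoint trial responses recover betas to sub-percent accuracy."""
        d = small_design(n_per_cond=4, isi=(32000,))
        cohort = noiseless_cohort(d)
        s = cohort.subjects[0]
        bs = estimate_beta_series(s.roi_timeseries, d)
        rel = np.abs(bs.betas.T - s.ground_truth_betas).max() / np.abs(
            s.ground_truth_betas
        ).max()
        assert rel < 0.01

    def test_estimates_unbiased_under_noise(self):
        """Mean LS-S error across many subjects covers zero (overlapping design)."""
        d = small_design(n_per_cond=10, seed=2)
        cohort = noiseless_cohort(d, n_subjects=40, sigma_noise=0.5, seed=3)
        errs = []
        for s in cohort.subjects:
            bs = estimate_beta_series(s.roi_timeseries, d)
            errs.append((bs.betas.T - s.ground_truth_betas).mean())
        errs = np.array(errs)
        ci = 2.6 * errs.std(ddof=1) / np.sqrt(errs.size)
        assert abs(errs.mean()) < max(ci, 0.02)

    def test_fully_censored_trial_is_missing_not_zero(self):
        d = small_design(n_per_cond=4, isi=(32000,))
        cohort = noiseless_cohort(d)
        s = cohort.subjects[0]
        censor = np.ones(d.n_volumes, int)
        start, _ = d.response_span(2)
        stop = min(start + int(np.ceil(32.0 / d.tr)) + 1, d.n_volumes)
        censor[start:stop] = 0  # censor the trial's full kernel support
        bs = estimate_beta_series(s.roi_timeseries, d, censor)
        assert not bs.retained[2]
        assert np.all(np.isnan(bs.betas[:, 2]))
        assert bs.retained[[0, 1, 3]].all()


class TestScrubbing:
    @pytest.fixture
    def design(self):
        return small_design()

    def _bs(self, design):
        n = design.n_trials
        return BetaSeries(
            betas=np.zeros((3, n)), condition=design.conditions(),
            retained=np.ones(n, bool),
        )

    def test_two_censored_volumes_excludes_trial(self, design):
        censor = np.ones(design.n_volumes, int)
        start, _ = design.response_span(4)
        censor[[start + 1, start + 3]] = 0
        out = scrub_trials(self._bs(design), design, censor)
        assert not out.retained[4]

    def test_single_censored_volume_retains_trial(self, design):
        censor = np.ones(design.n_volumes, int)
        start, _ = design.response_span(4)
        censor[start + 1] = 0
        out = scrub_trials(self._bs(design), design, censor)
        assert out.retained[4]

    def test_all_ones_mask_retains_everything(self, design):
        out = scrub_trials(self._bs(design), design, np.ones(design.n_volumes, int))
        assert out.retained.all()

    def test_scrubbing_is_monotone_in_censoring(self, design, rng):
        censor1 = (rng.random(design.n_volumes) > 0.05).astype(int)
        censor2 = censor1 * (rng.random(design.n_volumes) > 0.05).astype(int)
        r1 = scrub_trials(self._bs(design), design, censor1).retained
        r2 = scrub_trials(self._bs(design), design, censor2).retained
        assert np.all(r2 <= r1)


class TestNormalization:
    def _bs(self, betas, conds=None):
        betas = np.atleast_2d(np.asarray(betas, float))
        n = betas.shape[1]
        conds = conds if conds is not None else np.array(["A"] * n)
        return BetaSeries(betas=betas, condition=conds, retained=np.ones(n, bool))

    def test_population_sd_convention(self):
        out = normalize_within_condition(self._bs([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out.betas[0], [-1.22474487, 0.0, 1.22474487])

    def test_sample_sd_option(self):
        out = normalize_within_condition(self._bs([[1.0, 2.0, 3.0]]), ddof=1)
        np.testing.assert_allclose(out.betas[0], [-1.0, 0.0, 1.0])

    def test_mean_zero_unit_sd_and_idempotent(self, rng):
        conds = np.array(["A"] * 10 + ["B"] * 10)
        bs = self._bs(rng.normal(size=(4, 20)), conds)
        out = normalize_within_condition(bs)
        for c in "AB":
            block = out.retained_betas(c)
            np.testing.assert_allclose(block.mean(axis=1), 0.0, atol=1e-12)
            np.testing.assert_allclose(block.std(axis=1), 1.0, atol=1e-12)
        again = normalize_within_condition(out)
        np.testing.assert_allclose(again.betas, out.betas, atol=1e-12)

    def test_zero_variance_region_raises_with_region_named(self):
        bs = self._bs([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match=r"region\(s\) \[0\]"):
            normalize_within_condition(bs)


class TestConnectivity:
    def _bs(self, betas):
        n = betas.shape[1]
        return BetaSeries(betas=betas, condition=np.array(["A"] * n),
                          retained=np.ones(n, bool))

    def test_fisher_closed_form(self, rng):
        """r = 0.5 at N = 30 maps to z = atanh(0.5) * sqrt(27) = 2.8543."""
        # construct two series with exact sample correlation 0.5
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        x = (x - x.mean()) / x.std()
        y = y - y.mean()
        y -= x * (x @ y) / 30.0  # orthogonalize
        y /= y.std()
        b = np.vstack([x, 0.5 * x + np.sqrt(0.75) * y])
        net = compute_connectivity(self._bs(b), "A")
        assert net.w[0, 1] == pytest.approx(2.8542784526890377, abs=1e-10)

    def test_zero_correlation_gives_zero_z(self, rng):
        x = rng.standard_normal(40)
        y = rng.standard_normal(40)
        y = y - y.mean() - (x - x.mean()) * ((x - x.mean()) @ (y - y.mean())) / (
            ((x - x.mean()) ** 2).sum()
        )
        net = compute_connectivity(self._bs(np.vstack([x, y])), "A")
        assert net.w[0, 1] == pytest.approx(0.0, abs=1e-10)

    def test_perfect_correlation_clamped_with_warning(self, rng):
        x = rng.standard_normal(20)
        with pytest.warns(UserWarning, match="clamped"):
            net = compute_connectivity(self._bs(np.vstack([x, 2 * x + 1])), "A")
        assert np.isfinite(net.w).all()

    def test_min_trial_precondition(self, rng):
        with pytest.raises(ValueError, match=">= 5"):
            compute_connectivity(self._bs(rng.standard_normal((3, 4))), "A")

    def test_invariant_to_affine_rescaling(self, rng):
        b = rng.standard_normal((5, 25))
        n1 = compute_connectivity(self._bs(b), "A")
        scale = rng.uniform(0.5, 3.0, size=(5, 1))
        shift = rng.normal(size=(5, 1))
        n2 = compute_connectivity(self._bs(b * scale + shift), "A")
        np.testing.assert_allclose(n1.w, n2.w, atol=1e-8)

    def test_network_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            WeightedNetwork(w=np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="square"):
            WeightedNetwork(w=np.zeros((2, 3)))
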