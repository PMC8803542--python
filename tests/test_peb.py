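"""Hierarchical empirical Bayes: designs, fitting, BMR, BMA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from motordcm.dcm.invert import PosteriorEstimate
from motordcm.peb import (build_interaction_design, build_group_design,
                          validate_design, fit_peb, reduce_model,
                          search_and_average, bayesian_model_reduction)

SESSIONS_AS = [("anodal", "pre"), ("anodal", "post"),
               ("sham", "pre"), ("sham", "post")]


class TestInteractionDesign:
    def test_standard_2x2_coding(self):
        X = build_interaction_design(SESSIONS_AS, "anodal_vs_sham")
        np.testing.assert_allclose(X["mean"], 1.0)
        np.testing.assert_allclose(X["interaction"],
                                   np.array([-1, 1, 1, -1]) / 2.0)

    def test_coding_recovers_constructed_effect(self):
        """With the +-1/2 coding the fitted interaction equals half the
        difference of (post - pre) differences."""
        X = build_interaction_design(SESSIONS_AS, "anodal_vs_sham")
        delta = 0.4
        y = np.array([0.0, delta, 0.0, 0.0])  # anodal post-pre = delta
        beta = np.linalg.lstsq(X.to_numpy(), y, rcond=None)[0]
        assert beta[1] == pytest.approx(delta / 2)
        # a pure time effect (both polarities shift equally) yields zero
        y_time = np.array([0.0, delta, 0.0, delta])
        beta_t = np.linalg.lstsq(X.to_numpy(), y_time, rcond=None)[0]
        assert beta_t[1] == pytest.approx(0.0, abs=1e-12)

    def test_swapping_polarities_negates_interaction(self):
        sessions = [("cathodal", "pre"), ("cathodal", "post"),
                    ("sham", "pre"), ("sham", "post")]
        X1 = build_interaction_design(sessions, "cathodal_vs_sham")
        sessions_swapped = [("sham", "pre"), ("sham", "post"),
                            ("cathodal", "pre"), ("cathodal", "post")]
        X2 = build_interaction_design(sessions_swapped, "cathodal_vs_sham")
        np.testing.assert_allclose(np.sort(X1["interaction"]),
                                   np.sort(-X2["interaction"]))

    def test_missing_cell_named(self):
        with pytest.raises(ValueError, match="anodal"):
            build_interaction_design(SESSIONS_AS[:3] + [("sham", "pre")],
                                     "anodal_vs_sham")

    def test_unknown_contrast(self):
        with pytest.raises(KeyError, match="unknown contrast"):
            build_interaction_design(SESSIONS_AS, "anodal_vs_anodal")


class TestGroupDesign:
    @pytest.fixture
    def covariates(self, rng):
        return pd.DataFrame({
            "sex": rng.integers(0, 2, 21),
            "age": rng.normal(25, 4, 21),
            "handedness": rng.normal(80, 15, 21),
        }, index=[f"sub-{i:02d}" for i in range(21)])

    def test_shape_and_centring(self, covariates):
        X = build_group_design(covariates)
        assert X.shape == (21, 4)
        for c in ("sex", "age", "handedness"):
            assert abs(X[c].sum()) < 1e-10
        validate_design(X)

    def test_constant_covariate_flagged(self, covariates):
        covariates["age"] = 25.0
        with pytest.warns(UserWarning, match="degenerate"):
            X = build_group_design(covariates)
        np.testing.assert_allclose(X["age"], 0.0)

    def test_missing_covariate(self, covariates):
        with pytest.raises(ValueError, match="handedness"):
            build_group_design(covariates.drop(columns="handedness"))


def _posterior(mean, var):
    mean = np.atleast_1d(np.asarray(mean, float))
    return PosteriorEstimate(mean=mean, cov=np.eye(len(mean)) * var,
                             log_precisions=np.array([]), free_energy=0.0)


class TestFitPeb:
    def test_single_subject_shrinkage_free_limit(self):
        post = _posterior([0.4, -0.1], 0.01)
        m = fit_peb([post], np.ones((1, 1)), param_prior_var=1e8,
                    between_ratio=0.0)
        np.testing.assert_allclose(m.mean, post.mean, atol=1e-6)
        np.testing.assert_allclose(m.cov, post.cov, rtol=1e-4)

    def test_group_effect_recovery(self, rng):
        truth = np.zeros(6)
        truth[2] = 0.2
        firsts = [_posterior(truth + rng.normal(0, 0.05, 6), 0.05 ** 2)
                  for _ in range(20)]
        m = fit_peb(firsts, np.ones((20, 1)), param_prior_var=1.0 / 16.0)
        se = np.sqrt(m.cov[2, 2])
        assert abs(m.mean[2] - 0.2) < 2 * se

    def test_low_precision_subjects_weigh_less(self):
        """Two-subject analytic weighting: the posterior mean must lie
        closer to the high-precision subject's estimate."""
        s1, s2 = 0.01, 0.1
        m1, m2 = 1.0, 0.0
        m = fit_peb([_posterior(m1, s1), _posterior(m2, s2)],
                    np.ones((2, 1)), param_prior_var=1e8, between_ratio=0.0)
        expect = (m1 / s1 + m2 / s2) / (1 / s1 + 1 / s2)
        assert m.mean[0] == pytest.approx(expect, rel=1e-4)
        assert abs(m.mean[0] - m1) < abs(m.mean[0] - m2)

    def test_rank_deficient_design_rejected(self):
        X = np.ones((4, 2))
        with pytest.raises(np.linalg.LinAlgError):
            fit_peb([_posterior(0.0, 0.01)] * 4, X)

    def test_three_level_composition_matches_flat_design(self, rng):
        """Subject-level interaction PEBs feeding a group PEB agree with a
        single flat design over all sessions (vague priors, no random
        effects)."""
        vague = 1e6
        sess_var = 0.01
        all_obs, subj_marginals = [], []
        X_int = build_interaction_design(SESSIONS_AS, "anodal_vs_sham")
        for s in range(2):
            obs = [_posterior(rng.normal(0.1, 0.1), sess_var)
                   for _ in SESSIONS_AS]
            all_obs.append(obs)
            m = fit_peb(obs, X_int, param_prior_var=vague, between_ratio=0.0)
            subj_marginals.append(m.marginal("interaction"))
        group = fit_peb(subj_marginals, np.ones((2, 1)),
                        param_prior_var=vague, between_ratio=0.0)

        # flat: 8 sessions, per-subject mean columns, shared interaction
        Xf = np.zeros((8, 3))
        Xf[:4, 0] = 1.0
        Xf[4:, 1] = 1.0
        Xf[:, 2] = np.tile(X_int["interaction"].to_numpy(), 2)
        flat = fit_peb([o for obs in all_obs for o in obs], Xf,
                       param_prior_var=vague, between_ratio=0.0)
        assert group.mean[0] == pytest.approx(flat.mean[2], abs=1e-3)


class TestBayesianModelReduction:
    def test_empty_reduction_is_identity(self):
        post = _posterior([0.3, -0.2], 0.02)
        dF, red = reduce_model(post, np.array([], dtype=int),
                               priors=_prior_spec(2))
        assert abs(dF) < 1e-8
        np.testing.assert_allclose(red.mean, post.mean)

    def test_uninformed_parameter_reduces_freely(self):
        """A parameter whose posterior equals its prior contributes no
        evidence, so switching it off costs ~0."""
        prior = _prior_spec(1, var=0.25)
        post = _posterior([0.0], 0.25)
        dF, _ = reduce_model(post, np.array([0]), priors=prior,
                             null_variance_ratio=1e-8)
        assert abs(dF) < 0.05  # only the tiny null-variance surrogate

    def test_matches_conjugate_closed_form(self):
        """1-D linear-Gaussian model: dF equals the difference of
        closed-form evidences under full and reduced priors."""
        y, s2, v0, ratio = 0.7, 0.1, 1.0, 1e-8
        post_var = 1 / (1 / s2 + 1 / v0)
        post_mean = post_var * y / s2
        dF, _, _ = bayesian_model_reduction([post_mean], [[post_var]],
                                            [0.0], [[v0]], [0.0],
                                            [[ratio * v0]])
        closed = (stats.norm.logpdf(y, 0, np.sqrt(s2 + ratio * v0))
                  - stats.norm.logpdf(y, 0, np.sqrt(s2 + v0)))
        assert dF == pytest.approx(closed, abs=1e-6)

    def test_additive_on_independent_parameters(self):
        prior = _prior_spec(3, var=0.25)
        post = PosteriorEstimate(mean=np.array([0.3, -0.1, 0.2]),
                                 cov=np.diag([0.01, 0.02, 0.03]),
                                 log_precisions=np.array([]),
                                 free_energy=0.0)
        d01, _ = reduce_model(post, np.array([0, 1]), priors=prior)
        d0, _ = reduce_model(post, np.array([0]), priors=prior)
        d1, _ = reduce_model(post, np.array([1]), priors=prior)
        assert d01 == pytest.approx(d0 + d1, abs=1e-6)


def _prior_spec(k, var=0.25):
    from motordcm.dcm.model import PriorSpec
    return PriorSpec(np.zeros(k), np.full(k, var))


class TestSearchAndAverage:
    def _peb(self, means, sds, prior_var=1.0 / 16.0):
        from motordcm.peb import PEBModel
        means = np.asarray(means, float)
        k = len(means)
        return PEBModel(mean=means, cov=np.diag(np.asarray(sds) ** 2),
                        columns=["mean"],
                        param_labels=[f"p{i}" for i in range(k)],
                        prior_variance=np.full(k, prior_var), gamma=0.0,
                        free_energy=0.0, n_observations=20)

    def test_saturated_case_keeps_everything(self):
        model = self._peb([0.3, -0.25, 0.2], [0.01, 0.01, 0.01])
        res = search_and_average(model)
        assert res.table.flagged.all()
        np.testing.assert_allclose(res.table.effect, model.mean, atol=5e-3)

    def test_single_effect_flagged_nulls_pruned(self):
        model = self._peb([0.2, 0.001, -0.002, 0.0015],
                          [0.01, 0.01, 0.01, 0.01])
        res = search_and_average(model)
        tab = res.table.set_index("parameter")
        assert tab.loc["mean:p0", "flagged"]
        assert not tab.loc[["mean:p1", "mean:p2", "mean:p3"], "flagged"].any()
        assert abs(tab.loc["mean:p1", "effect"]) < 1e-3

    def test_greedy_path_handles_many_parameters(self, rng):
        means = np.zeros(12)
        means[5] = 0.25
        model = self._peb(means + rng.normal(0, 0.002, 12), np.full(12, 0.01))
        res = search_and_average(model, max_exhaustive=6)
        tab = res.table.set_index("parameter")
        assert tab.loc["mean:p5", "flagged"]
        assert tab.loc["mean:p5", "pp"] > 0.95
        assert (tab.drop(index="mean:p5").pp < 0.5).all()

    def test_probabilities_are_probabilities(self):
        model = self._peb([0.05, 0.0], [0.05, 0.05])
        res = search_and_average(model)
        assert ((res.table.pp >= 0) & (res.table.pp <= 1)).all()
        assert res.model_space.weight.sum() == pytest.approx(1.0)
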