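"""Mixed-effects estimation: conditional (MAP) estimation, the FOCE-I/
Laplace objective against an adaptive-quadrature oracle, population fitting
on noise-free data, likelihood-ratio arithmetic, and stepwise selection."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from sklearn.base import clone

from conftest import REFERENCE_ROW, single_subject_dataset
from tdm1pk import (
    BASE_SPEC,
    FINAL_MODEL_SPEC,
    PUBLISHED_OMEGA,
    PUBLISHED_SIGMA,
    PUBLISHED_THETA,
    CovariateCandidate,
    CovariateVector,
    DoseEvent,
    IndividualParameters,
    ModelSpec,
    OmegaMatrix,
    PKDataset,
    PopPKEstimator,
    SigmaModel,
    ThetaVector,
    TrialDesign,
    concentration,
    fit_population,
    foce_objective,
    individual_parameters,
    lrt_significance,
    map_individual,
    simulate_trial,
    stepwise_selection,
)

ETA_CL_ONLY = ModelSpec(terms=(), etas=("CL",), cl_vc_cov=False)


def exact_marginal_ofv(obs, omega_sd, sigma_cv, dose=252.0, duration=0.0208):
    """Adaptive-quadrature -2 log marginal likelihood for a 1-eta_CL subject."""
    base = individual_parameters(PUBLISHED_THETA,
                                 CovariateVector(70, 25, 41, 9, 0, 27),
                                 np.zeros(4))
    times = np.array([t for t, _ in obs])
    dvs = np.array([d for _, d in obs])

    def log_integrand(eta):
        ind = IndividualParameters(cl=base.cl * math.exp(eta), vc=base.vc,
                                   q=base.q, vp=base.vp)
        f = concentration(ind, [DoseEvent(0.0, dose, duration)], times)
        v = (sigma_cv * f) ** 2
        ll = -0.5 * np.sum((dvs - f) ** 2 / v + np.log(2 * np.pi * v))
        lp = -0.5 * (eta**2 / omega_sd**2 + math.log(2 * np.pi * omega_sd**2))
        return ll + lp

    grid = np.linspace(-6 * omega_sd, 6 * omega_sd, 201)
    offset = max(log_integrand(g) for g in grid)  # factor out the peak
    L, err = quad(
        lambda e: math.exp(log_integrand(e) - offset),
        -6 * omega_sd, 6 * omega_sd, limit=400,
    )
    assert err < 1e-6 * L
    return -2.0 * (math.log(L) + offset)


class TestObjectiveOracle:
    @pytest.mark.parametrize(
        "obs",
        [
            [(0.25, 60.0)],
            [(0.25, 60.0), (3.0, 30.0), (7.0, 12.0)],
            [(0.25, 90.0), (1.0, 55.0), (3.0, 35.0), (7.0, 16.0), (14.0, 5.0)],
        ],
    )
    def test_laplace_matches_quadrature_on_one_eta_toys(self, obs):
        ds = single_subject_dataset(obs)
        omega = OmegaMatrix(0.25, 0, 0, 0)
        sigma = SigmaModel(0.2)
        ofv = foce_objective(PUBLISHED_THETA, omega, sigma, ds, spec=ETA_CL_ONLY)
        exact = exact_marginal_ofv(obs, 0.25, 0.2)
        assert ofv == pytest.approx(exact, rel=5e-3)

    def test_duplicating_subjects_doubles_ofv(self):
        obs = [(0.25, 60.0), (3.0, 30.0), (7.0, 12.0)]
        one = single_subject_dataset(obs)
        two_df = pd.concat(
            [one.df, one.df.assign(ID=2)], ignore_index=True
        )
        two = PKDataset(two_df)
        omega = OmegaMatrix(0.25, 0.1, 0, 0)
        spec = ModelSpec(terms=(), etas=("CL", "Vc"), cl_vc_cov=False)
        o1 = foce_objective(PUBLISHED_THETA, omega, SigmaModel(0.2), one, spec=spec)
        o2 = foce_objective(PUBLISHED_THETA, omega, SigmaModel(0.2), two, spec=spec)
        assert o2 == pytest.approx(2 * o1, abs=1e-6)

    def test_generating_covariate_effect_lowers_ofv(self, quiet_model):
        """A model carrying the true weight effect on CL beats the
        misspecified covariate-free model on the same simulated data."""
        theta, omega, sigma = quiet_model
        design = TrialDesign(n_subjects=60, sampling="sparse", n_cycles=4)
        ds = simulate_trial(design, theta, omega, sigma, seed=8)
        theta_base = ThetaVector(
            theta1=theta.theta1, theta2=theta.theta2,
            theta3=theta.theta3, theta4=theta.theta4,
        )
        o_true = foce_objective(theta, omega, sigma, ds)
        o_base = foce_objective(theta_base, omega, sigma, ds, spec=BASE_SPEC)
        assert o_true < o_base

    def test_scale_invariance_of_ofv_differences(self, small_trial):
        """Rescaling concentrations with a matching volume/clearance shift
        changes every OFV by the same additive constant."""
        c = 10.0
        theta_a = PUBLISHED_THETA
        theta_b = ThetaVector(**{**theta_a.to_dict(), "theta1": theta_a.theta1 + 0.2})

        def shift(th):
            d = th.to_dict()
            for k in ("theta1", "theta2", "theta3", "theta4"):
                d[k] -= math.log(c)
            return ThetaVector(**d)

        scaled = small_trial.copy()
        scaled.df["DV"] = scaled.df["DV"] * c
        args = (PUBLISHED_OMEGA, PUBLISHED_SIGMA)
        d_orig = (
            foce_objective(theta_b, *args, small_trial)
            - foce_objective(theta_a, *args, small_trial)
        )
        d_scaled = (
            foce_objective(shift(theta_b), *args, scaled)
            - foce_objective(shift(theta_a), *args, scaled)
        )
        assert d_scaled == pytest.approx(d_orig, abs=0.05)


class TestMapIndividual:
    def test_no_observations_returns_prior_mode(self):
        ds = single_subject_dataset([(1.0, 40.0)])
        df2 = ds.df.iloc[[0]].assign(ID=2)  # dose only, no observations
        both = PKDataset(pd.concat([ds.df, df2], ignore_index=True))
        etas = map_individual(PUBLISHED_THETA, PUBLISHED_OMEGA, PUBLISHED_SIGMA, both)
        np.testing.assert_allclose(etas[1], 0.0)
        assert np.any(etas[0] != 0.0)

    def test_singular_omega_rejected(self):
        ds = single_subject_dataset([(1.0, 40.0)])
        with pytest.raises(ValueError, match="singular"):
            map_individual(PUBLISHED_THETA, OmegaMatrix(0, 0.1, 0.1, 0.1),
                           PUBLISHED_SIGMA, ds)

    def test_noise_free_rich_data_recovers_eta(self):
        """With dense noise-free data the conditional mode equals the
        generating random effect."""
        eta_true = np.array([0.15, -0.1, 0.3, -0.2])
        ind = individual_parameters(
            PUBLISHED_THETA, CovariateVector(**{
                "weight": 70.0, "ecd": 25.0, "albu": 41.0, "tmbd": 9.0,
                "tbl": 0.0, "ast": 27.0}), eta_true)
        doses = [DoseEvent(0.0, 252.0, 0.0208)]
        times = [0.0208, 0.1, 0.25, 0.5, 1.0, 2.0, 3.0, 5.0, 7.0, 10.0, 14.0, 21.0]
        obs = [(t, concentration(ind, doses, t)) for t in times]
        ds = single_subject_dataset(obs)
        etas = map_individual(
            PUBLISHED_THETA, PUBLISHED_OMEGA, SigmaModel(1e-5), ds
        )
        np.testing.assert_allclose(etas[0], eta_true, atol=1e-3)

    def test_flat_prior_limit_interpolates_data(self):
        """With an essentially flat prior and one observation, the
        individual prediction approaches the observation."""
        dv = 50.0
        ds = single_subject_dataset([(1.0, dv)])
        omega = OmegaMatrix(5.0, 0, 0, 0)
        eta = map_individual(PUBLISHED_THETA, omega, SigmaModel(0.2), ds,
                             spec=ETA_CL_ONLY)
        base = individual_parameters(PUBLISHED_THETA,
                                     CovariateVector(70, 25, 41, 9, 0, 27),
                                     np.zeros(4))
        ind = IndividualParameters(cl=base.cl * math.exp(eta[0, 0]), vc=base.vc,
                                   q=base.q, vp=base.vp)
        ipred = concentration(ind, [DoseEvent(0.0, 252.0, 0.0208)], 1.0)
        # the interaction term shifts the optimum below DV by O(sigma^2)
        assert ipred == pytest.approx(dv, rel=0.05)
        assert ipred < dv


@pytest.fixture(scope="module")
def noise_free_fit():
    """Structural thetas refitted on near-noise-free base-model data
    with the variance components held at truth."""
    theta = ThetaVector(theta1=math.log(0.676), theta2=math.log(3.127),
                        theta3=math.log(1.534), theta4=math.log(0.66))
    omega = OmegaMatrix(0.05, 0.05, 0.05, 0.05, 0.0)
    sigma = SigmaModel(0.02)
    design = TrialDesign(n_subjects=25, n_cycles=3)
    ds = simulate_trial(design, theta, omega, sigma, seed=5)
    fit = fit_population(
        ds, spec=ModelSpec(terms=(), etas=("CL", "Vc", "Q", "Vp"),
                           cl_vc_cov=False),
        init_omega=omega, init_sigma=sigma,
        fix=("lomega_cl", "lomega_vc", "lomega_q", "lomega_vp", "lsigma"),
    )
    return theta, ds, fit


class TestPopulationFit:
    def test_noise_free_theta_recovery(self, noise_free_fit):
        theta, _, fit = noise_free_fit
        tv = fit.typical_values
        assert tv["CL"] == pytest.approx(0.676, rel=0.02)
        assert tv["Vc"] == pytest.approx(3.127, rel=0.02)
        assert tv["Q"] == pytest.approx(1.534, rel=0.10)
        assert tv["Vp"] == pytest.approx(0.66, rel=0.10)
        assert fit.converged

    def test_refit_from_optimum_is_a_fixed_point(self, noise_free_fit):
        theta, ds, fit = noise_free_fit
        refit = fit_population(
            ds, spec=fit.spec, init_theta=fit.theta, init_omega=fit.omega,
            init_sigma=fit.sigma,
            fix=("lomega_cl", "lomega_vc", "lomega_q", "lomega_vp", "lsigma"),
        )
        assert abs(refit.ofv - fit.ofv) < 0.01

    def test_asymptotic_se_brackets_the_estimate(self):
        """Finite-difference standard errors are positive and the implied
        CI covers the point estimate with a plausible width."""
        theta = ThetaVector(theta1=math.log(0.676), theta2=math.log(3.127),
                            theta3=math.log(1.534), theta4=math.log(0.66))
        omega = OmegaMatrix(0.1, 0.1, 1e-9, 1e-9, 0.0)
        ds = simulate_trial(
            TrialDesign(n_subjects=30, sampling="sparse", n_cycles=3,
                        washout_offsets=()),
            theta, omega, SigmaModel(0.15), seed=9,
        )
        fit = fit_population(
            ds, spec=ModelSpec(terms=(), etas=("CL", "Vc"), cl_vc_cov=False),
            init_theta=theta, fix=("lq", "lvp"), compute_se=True, maxiter=100,
        )
        assert fit.se is not None and fit.se["lcl"] > 0
        lo, hi = fit.ci95["lcl"]
        assert lo < fit.coefs["lcl"] < hi
        assert 0.005 < fit.se["lcl"] < 0.1  # ~omega/sqrt(n) scale

    def test_estimator_follows_sklearn_conventions(self):
        est = PopPKEstimator(maxiter=17)
        params = est.get_params()
        assert params["maxiter"] == 17
        est2 = clone(est).set_params(maxiter=3)
        assert est2.get_params()["maxiter"] == 3
        with pytest.raises(RuntimeError, match="not fitted"):
            est.predict(None)

    def test_predict_population_and_individual(self, noise_free_fit):
        _, ds, fit = noise_free_fit
        est = PopPKEstimator(spec=fit.spec, init_theta=fit.theta,
                             init_omega=fit.omega, init_sigma=fit.sigma,
                             fix=tuple(fit.coefs), maxiter=0)
        est.fit(ds)
        pred = est.predict(ds, kind="pred")
        ipred = est.predict(ds, kind="ipred")
        obs = ds.observations()
        post_dose = obs["TIME"] > 0  # structurally-zero predose records excluded
        assert pred.shape == ipred.shape == (int(post_dose.sum()),)
        dv = obs.loc[post_dose, "DV"].to_numpy()
        # individual predictions hug near-noise-free data more tightly
        assert np.median(np.abs(ipred / dv - 1)) <= np.median(np.abs(pred / dv - 1))


class TestLikelihoodRatio:
    def test_chi_square_reference_points(self):
        assert lrt_significance(6.635, 1) == pytest.approx(0.010, abs=5e-4)
        assert lrt_significance(10.828, 1) == pytest.approx(0.001, abs=5e-5)
        assert lrt_significance(0.0, 1) == 1.0

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            lrt_significance(-1.0, 1)
        with pytest.raises(ValueError):
            lrt_significance(1.0, 0)


class TestStepwiseSelection:
    WT_TERM = CovariateCandidate("CL", "WT", "power", 70.0)
    ALBU_TERM = CovariateCandidate("CL", "ALBU", "power", 41.0)
    SPEC2 = ModelSpec(terms=(), etas=("CL", "Vc"), cl_vc_cov=False)

    @staticmethod
    def _simulate(seed):
        theta = ThetaVector(theta1=math.log(0.676), theta2=math.log(3.127),
                            theta3=math.log(1.534), theta4=math.log(0.66),
                            theta5=0.0, theta6=0.49)
        omega = OmegaMatrix(0.15, 0.10, 1e-9, 1e-9, 0.0)
        sigma = SigmaModel(0.15)
        design = TrialDesign(n_subjects=120, sampling="sparse", n_cycles=4)
        return simulate_trial(design, theta, omega, sigma, seed=seed)

    def test_true_weight_effect_selected_albumin_dropped(self):
        """Across seeds, forward/backward selection keeps the generating
        weight-on-CL term and rejects the null albumin term (majority)."""
        hits = 0
        for seed in (101, 202, 303):
            ds = self._simulate(seed)
            res = stepwise_selection(
                ds, [self.WT_TERM, self.ALBU_TERM], base_spec=self.SPEC2,
                maxiter=120,
            )
            names = {t.name for t in res.selected}
            if names == {"cl_wt"}:
                hits += 1
        assert hits >= 2

    def test_empty_candidate_list_returns_base(self):
        ds = self._simulate(7)
        res = stepwise_selection(ds, [], base_spec=self.SPEC2, maxiter=60)
        assert res.selected == ()
        assert [t["step"] for t in res.trace] == ["base"]

    def test_permissive_threshold_admits_every_candidate(self):
        ds = self._simulate(7)
        res = stepwise_selection(
            ds, [self.WT_TERM, self.ALBU_TERM], base_spec=self.SPEC2,
            forward_alpha=1.01, backward_alpha=1.5, maxiter=40,
        )
        assert {t.name for t in res.selected} == {"cl_wt", "cl_albu"}
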