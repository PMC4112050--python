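"""Validation machinery: prediction-error statistics, predictive checks,
bootstrap, and shrinkage."""

import math

import numpy as np
import pandas as pd
import pytest

from tdm1pk import (
    FINAL_MODEL_SPEC,
    PUBLISHED_OMEGA,
    PUBLISHED_SIGMA,
    PUBLISHED_THETA,
    ModelSpec,
    OmegaMatrix,
    SigmaModel,
    ThetaVector,
    TrialDesign,
    bootstrap,
    fit_population,
    map_individual,
    mean_prediction_error,
    numerical_predictive_check,
    parameter_prediction_error,
    percent_iiv_explained,
    prediction_error,
    shrinkage,
    simulate_trial,
    validation_report,
    visual_predictive_check,
)
from tdm1pk.estimation import FitResult, SubjectBatch, _ParamLayout, _base_log_params


class TestPredictionErrors:
    def test_basic_arithmetic(self):
        assert prediction_error(1.0, 1.0) == 0.0
        assert prediction_error(1.1, 1.0) == pytest.approx(10.0)
        assert prediction_error(0.9, 1.0) == pytest.approx(-10.0)
        with pytest.raises(ValueError):
            prediction_error(1.0, 0.0)

    def test_mean_prediction_error(self):
        mpe, ci = mean_prediction_error([10.0, -10.0])
        assert mpe == 0.0
        mpe0, ci0 = mean_prediction_error(np.zeros(20))
        assert mpe0 == 0.0 and ci0 == (0.0, 0.0)
        with pytest.raises(ValueError):
            mean_prediction_error([])

    def test_parameter_prediction_error(self):
        assert parameter_prediction_error(0.676, 0.60) == pytest.approx(12.67, abs=0.01)
        assert parameter_prediction_error(2.0, 2.0) == 0.0
        with pytest.raises(ValueError):
            parameter_prediction_error(1.0, 0.0)

    def test_self_prediction_is_exactly_unbiased_without_noise(self):
        """PRED computed from the generating model on noise-free typical
        subjects reproduces the data: every Pe is 0."""
        omega = OmegaMatrix(1e-12, 1e-12, 1e-12, 1e-12, 0.0)
        sigma = SigmaModel(1e-12)
        ds = simulate_trial(TrialDesign(n_subjects=4), PUBLISHED_THETA,
                            omega, sigma, seed=1)
        batch = SubjectBatch(ds, FINAL_MODEL_SPEC)
        layout = _ParamLayout(FINAL_MODEL_SPEC)
        values = layout.values_from_model(PUBLISHED_THETA, PUBLISHED_OMEGA,
                                          PUBLISHED_SIGMA)
        pred = batch.predict(_base_log_params(batch, values),
                             np.zeros((4, 4)))
        pe = prediction_error(pred[batch.mask], batch.dv[batch.mask])
        assert np.abs(pe).max() < 1e-4

    def test_validation_report_on_self_simulated_cohort(self, published):
        """Validating the generating model against its own cohort shows
        bias CIs containing zero for concentrations."""
        theta, omega, sigma = published
        ds = simulate_trial(TrialDesign(n_subjects=60, sampling="sparse"),
                            theta, omega, sigma, seed=17)
        from tdm1pk import apply_mqc_censoring

        ds, _ = apply_mqc_censoring(ds, 0.04)
        rep = validation_report(theta, omega, sigma, ds, n_boot=300, seed=3)
        # the parameter-level errors are centred on zero for the true model
        assert rep.cl_mpe_ci[0] < 0 < rep.cl_mpe_ci[1]
        assert rep.vc_mpe_ci[0] < 0 < rep.vc_mpe_ci[1]
        # concentration Pe divides by noisy DV, which inflates its mean
        # upward under a 31.6% proportional error; the median stays moderate
        assert abs(np.median(rep.pe)) < 15.0
        assert rep.mpe > 0
        assert rep.summary().shape == (3, 3)


@pytest.fixture(scope="module")
def selfsim(published):
    theta, omega, sigma = published
    ds = simulate_trial(TrialDesign(n_subjects=80), theta, omega, sigma,
                        seed=23)
    from tdm1pk import apply_mqc_censoring

    return apply_mqc_censoring(ds, 0.04)[0]


@pytest.fixture(scope="module")
def small_cohort():
    theta = ThetaVector(theta1=math.log(0.676), theta2=math.log(3.127),
                        theta3=math.log(1.534), theta4=math.log(0.66))
    omega = OmegaMatrix(0.15, 0.10, 1e-9, 1e-9, 0.0)
    sigma = SigmaModel(0.15)
    ds = simulate_trial(
        TrialDesign(n_subjects=40, sampling="sparse", n_cycles=3,
                    washout_offsets=()),
        theta, omega, sigma, seed=13,
    )
    # trough/EOI-only sampling cannot identify Q and Vp; hold them at
    # their initial values, as one would for unidentified parameters
    fit = fit_population(ds, spec=TestBootstrap.SPEC, init_theta=theta,
                         fix=("lq", "lvp"), maxiter=150)
    return theta, ds, fit


class TestPredictiveChecks:

    def test_vpc_calibrated_under_generating_model(self, published):
        """Observed medians sit inside the simulated 95% bands for nearly
        all bins when the model generated the data (averaged over cohorts
        to damp binomial noise on ~22 correlated bins)."""
        theta, omega, sigma = published
        from tdm1pk import apply_mqc_censoring

        rates = []
        for seed in (23, 24, 25):
            ds = simulate_trial(TrialDesign(n_subjects=80), theta, omega,
                                sigma, seed=seed)
            ds, _ = apply_mqc_censoring(ds, 0.04)
            res = visual_predictive_check(theta, omega, sigma, ds,
                                          n_replicates=150, seed=5, mqc=0.04)
            t = res.table[~t_flagged(res.table)]
            inside = (
                (t["obs_p50"] >= t["sim_p50_lo"])
                & (t["obs_p50"] <= t["sim_p50_hi"])
            )
            rates.append(inside.mean())
        assert np.mean(rates) >= 0.85

    def test_single_replicate_bands_collapse(self, published, selfsim):
        theta, omega, sigma = published
        res = visual_predictive_check(theta, omega, sigma, selfsim,
                                      n_replicates=1, seed=5, mqc=0.04)
        t = res.table.dropna()
        np.testing.assert_allclose(t["sim_p50_lo"], t["sim_p50_hi"])

    def test_doubled_dose_shifts_simulated_bands_only(self, published, selfsim):
        theta, omega, sigma = published
        res = visual_predictive_check(theta, omega, sigma, selfsim,
                                      n_replicates=60, seed=5, mqc=0.04)
        # doubling every simulated dose = scaling all volumes and clearances
        # down by half (micro constants unchanged, concentrations doubled)
        d = theta.to_dict()
        for k in ("theta1", "theta2", "theta3", "theta4"):
            d[k] -= math.log(2.0)
        res_hi = visual_predictive_check(ThetaVector(**d), omega, sigma,
                                         selfsim, n_replicates=60, seed=5,
                                         mqc=0.04)
        a, b = res.table.dropna(), res_hi.table.dropna()
        assert (b["sim_p50"].to_numpy() > a["sim_p50"].to_numpy()).all()
        np.testing.assert_allclose(a["obs_p50"], b["obs_p50"])

    def test_npc_coverage(self, published, selfsim):
        theta, omega, sigma = published
        table = numerical_predictive_check(
            theta, omega, sigma, selfsim, n_replicates=200,
            pi_levels=(0.0, 50.0, 90.0), seed=11, mqc=0.04,
        )
        row90 = table[table.pi_level == 90.0].iloc[0]
        assert row90.frac_outside == pytest.approx(0.10, abs=0.03)
        row0 = table[table.pi_level == 0.0].iloc[0]
        assert row0.frac_outside > 0.95


def t_flagged(table):
    return table["flagged"] | table["obs_p50"].isna()


class TestBootstrap:
    SPEC = ModelSpec(terms=(), etas=("CL", "Vc"), cl_vc_cov=False)

    def test_bootstrap_medians_near_generating_values(self, small_cohort):
        theta, ds, fit = small_cohort
        table = bootstrap(ds, n_boot=50, seed=1, spec=self.SPEC,
                          init_from_fit=fit, fix=("lq", "lvp"), maxiter=60)
        assert table.loc["CL", "median"] == pytest.approx(0.676, rel=0.10)
        assert table.loc["Vc", "median"] == pytest.approx(3.127, rel=0.10)
        assert table.loc["CL", "ci_lo"] < table.loc["CL", "median"] < table.loc["CL", "ci_hi"]
        assert table.attrs["n_nonconverged"] <= 10

    def test_degenerate_resampling_gives_identical_replicates(self):
        """A cohort of identical subjects makes every bootstrap replicate
        the same dataset, so the CI collapses."""
        theta = ThetaVector(theta1=math.log(0.676), theta2=math.log(3.127),
                            theta3=math.log(1.534), theta4=math.log(0.66))
        omega = OmegaMatrix(0.1, 0.1, 1e-9, 1e-9, 0.0)
        ds = simulate_trial(
            TrialDesign(n_subjects=1, sampling="sparse", n_cycles=3,
                        washout_offsets=()),
            theta, omega, SigmaModel(0.1), seed=2,
        )
        df = pd.concat(
            [ds.df.assign(ID=i + 1) for i in range(3)], ignore_index=True
        )
        from tdm1pk import PKDataset

        clones = PKDataset(df)
        table = bootstrap(clones, n_boot=4, seed=0, spec=self.SPEC,
                          maxiter=40)
        reps = table.attrs["replicates"]
        assert reps["CL"].nunique() == 1
        assert table.loc["CL", "ci_lo"] == table.loc["CL", "ci_hi"]


class TestShrinkage:
    def _fit_result(self, etas, omega, spec):
        n = len(etas)
        return FitResult(
            theta=PUBLISHED_THETA, coefs={}, omega=omega,
            sigma=PUBLISHED_SIGMA, ofv=0.0,
            etas=pd.DataFrame(etas, index=pd.Index(range(1, n + 1), name="ID"),
                              columns=[f"eta_{e}" for e in spec.etas]),
            converged=True, spec=spec, n_subjects=n, n_observations=0,
        )

    def test_limits(self, published, small_trial):
        theta, omega, sigma = published
        rng = np.random.default_rng(0)
        n = small_trial.n_subjects
        # EBEs identically zero (no individual data): 100% shrinkage
        fit0 = self._fit_result(np.zeros((n, 4)), omega, FINAL_MODEL_SPEC)
        fit0.coefs = _ParamLayout(FINAL_MODEL_SPEC).values_from_model(theta, omega, sigma)
        s0 = shrinkage(fit0, small_trial)
        assert s0["eta_CL"] == pytest.approx(100.0)
        # EBE spread equal to omega: 0% shrinkage
        etas = rng.normal(0.0, 1.0, (n, 4))
        etas = (etas - etas.mean(0)) / etas.std(0, ddof=1)
        etas *= [omega.omega_cl, omega.omega_vc, omega.omega_q, omega.omega_vp]
        fit1 = self._fit_result(etas, omega, FINAL_MODEL_SPEC)
        fit1.coefs = fit0.coefs
        s1 = shrinkage(fit1, small_trial)
        assert s1["eta_CL"] == pytest.approx(0.0, abs=1e-6)
        assert math.isnan(
            shrinkage(
                self._fit_result_zero_omega(n, theta, sigma), small_trial
            )["eta_Q"]
        )

    def _fit_result_zero_omega(self, n, theta, sigma):
        omega = OmegaMatrix(0.19, 0.12, 0.0, 0.3, 0.0)
        spec = FINAL_MODEL_SPEC
        fr = self._fit_result(np.zeros((n, 4)), omega, spec)
        fr.coefs = _ParamLayout(spec).values_from_model(theta, omega, sigma)
        return fr

    def test_sparse_design_shrinks_more_than_rich(self, published):
        """Fewer observations per subject pull the EBEs harder towards 0."""
        theta, omega, sigma = published
        rich = simulate_trial(TrialDesign(n_subjects=80), theta, omega,
                              sigma, seed=31)
        sparse = simulate_trial(
            TrialDesign(n_subjects=80, sampling="sparse"), theta, omega,
            sigma, seed=31,
        )
        shr = {}
        for name, ds in (("rich", rich), ("sparse", sparse)):
            etas = map_individual(theta, omega, sigma, ds)
            shr[name] = 100.0 * (1.0 - etas[:, 0].std(ddof=1) / omega.omega_cl)
        assert shr["sparse"] > shr["rich"]
        assert shr["rich"] < 100.0


class TestIIVExplained:
    @pytest.mark.parametrize(
        "base, final, expected, tol",
        [(25.6, 19.1, 44.4, 0.5), (17.5, 11.66, 55.8, 0.5), (20.0, 20.0, 0.0, 1e-9)],
    )
    def test_variance_explained(self, base, final, expected, tol):
        assert percent_iiv_explained(base, final) == pytest.approx(expected, abs=tol)

    def test_inflated_final_iiv_goes_negative(self):
        assert percent_iiv_explained(10.0, 12.0) < 0.0
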