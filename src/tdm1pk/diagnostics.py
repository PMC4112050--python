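"""Model validation machinery: prediction errors, VPC, NPC, bootstrap,
shrinkage, and variance-explained summaries.

Prediction errors follow the external-validation convention

    Pe      = (PRED - DV) / DV * 100%          (per observation)
    MPE     = sum(Pe) / n                       (bias, with bootstrap CI)
    CL_Pe_i = (CL_pop_i - CL_bayes_i) / CL_bayes_i * 100%   (per subject)

so a positive MPE means over-prediction.  The predictive checks simulate
the dataset's own design repeatedly under the model (same doses, times,
covariates and MQC-omission rule) and compare observed percentiles (VPC)
or interval coverage (NPC) to the simulated distribution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import estimation as est
from .cohort import apply_mqc_censoring
from .data import PKDataset
from .model import OmegaMatrix, SigmaModel, ThetaVector

__all__ = [
    "prediction_error",
    "mean_prediction_error",
    "parameter_prediction_error",
    "PredictionErrorReport",
    "validation_report",
    "VPCResult",
    "visual_predictive_check",
    "numerical_predictive_check",
    "bootstrap",
    "shrinkage",
    "percent_iiv_explained",
]


# ---------------------------------------------------------------------------
# Prediction errors
# ---------------------------------------------------------------------------


def prediction_error(pred, dv):
    """Percent prediction error (PRED - DV)/DV * 100; positive = over-prediction."""
    pred = np.asarray(pred, dtype=float)
    dv = np.asarray(dv, dtype=float)
    if np.any(dv <= 0):
        raise ValueError("DV must be > 0 for a percent prediction error")
    return (pred - dv) / dv * 100.0


def mean_prediction_error(pe, n_boot: int = 1000, seed=0):
    """Arithmetic mean of prediction errors with a percentile-bootstrap 95% CI.

    Returns (MPE, (lo, hi)).
    """
    pe = np.asarray(pe, dtype=float)
    if pe.size == 0:
        raise ValueError("empty prediction-error list")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, pe.size, size=(n_boot, pe.size))
    boots = pe[idx].mean(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return float(pe.mean()), (float(lo), float(hi))


def parameter_prediction_error(pop_value, bayes_value):
    """Per-subject percent error of the covariate-predicted parameter
    relative to the MAP (empirical-Bayes) estimate."""
    pop_value = np.asarray(pop_value, dtype=float)
    bayes_value = np.asarray(bayes_value, dtype=float)
    if np.any(bayes_value <= 0):
        raise ValueError("Bayesian parameter estimates must be > 0")
    return (pop_value - bayes_value) / bayes_value * 100.0


@dataclass
class PredictionErrorReport:
    """External-validation bias statistics for one cohort."""

    pe: np.ndarray  # per-observation %
    mpe: float
    mpe_ci: tuple
    cl_pe: np.ndarray  # per-subject %
    cl_mpe: float
    cl_mpe_ci: tuple
    vc_pe: np.ndarray
    vc_mpe: float
    vc_mpe_ci: tuple

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "MPE_percent": [self.mpe, self.cl_mpe, self.vc_mpe],
                "CI_lo": [self.mpe_ci[0], self.cl_mpe_ci[0], self.vc_mpe_ci[0]],
                "CI_hi": [self.mpe_ci[1], self.cl_mpe_ci[1], self.vc_mpe_ci[1]],
            },
            index=["concentration", "CL", "Vc"],
        )


def validation_report(
    theta: ThetaVector,
    omega: OmegaMatrix,
    sigma: SigmaModel,
    data: PKDataset,
    spec: est.ModelSpec = est.FINAL_MODEL_SPEC,
    n_boot: int = 1000,
    seed=0,
) -> PredictionErrorReport:
    """Full external-validation bias report for a cohort.

    Population predictions (eta = 0, subject covariates) are compared with
    observations; covariate-predicted CL and Vc are compared with MAP
    empirical-Bayes values estimated from each subject's concentrations.
    """
    batch = est.SubjectBatch(data, spec)
    layout = est._ParamLayout(spec)
    values = layout.values_from_model(theta, omega, sigma)
    base_log = est._base_log_params(batch, values)
    pred = batch.predict(base_log, np.zeros((len(batch.ids), batch.q)))
    pe = prediction_error(pred[batch.mask], batch.dv[batch.mask])

    etas = est.map_individual(theta, omega, sigma, data, spec=spec)
    i_cl = spec.etas.index("CL")
    i_vc = spec.etas.index("Vc")
    cl_pop = np.exp(base_log[:, 0])
    vc_pop = np.exp(base_log[:, 1])
    cl_bayes = cl_pop * np.exp(etas[:, i_cl])
    vc_bayes = vc_pop * np.exp(etas[:, i_vc])
    cl_pe = parameter_prediction_error(cl_pop, cl_bayes)
    vc_pe = parameter_prediction_error(vc_pop, vc_bayes)

    mpe, ci = mean_prediction_error(pe, n_boot, seed)
    cl_mpe, cl_ci = mean_prediction_error(cl_pe, n_boot, seed + 1)
    vc_mpe, vc_ci = mean_prediction_error(vc_pe, n_boot, seed + 2)
    return PredictionErrorReport(
        pe=pe, mpe=mpe, mpe_ci=ci,
        cl_pe=cl_pe, cl_mpe=cl_mpe, cl_mpe_ci=cl_ci,
        vc_pe=vc_pe, vc_mpe=vc_mpe, vc_mpe_ci=vc_ci,
    )


# ---------------------------------------------------------------------------
# Predictive checks
# ---------------------------------------------------------------------------


def _simulate_replicates(batch, theta, omega, sigma, n_replicates, seed, mqc):
    """Simulated DV matrices at the dataset's own design, MQC-omitted.

    Yields (dv, keep_mask) per replicate; censored records are masked out
    exactly as the real data handling drops below-MQC observations.
    """
    layout = est._ParamLayout(batch.spec)
    values = layout.values_from_model(theta, omega, sigma)
    base_log = est._base_log_params(batch, values)
    om = layout.omega_matrix(values)
    rng = np.random.default_rng(seed)
    n = len(batch.ids)
    for _ in range(n_replicates):
        eta = rng.multivariate_normal(np.zeros(batch.q), om, size=n)
        f = batch.predict(base_log, eta)
        dv = f * (1.0 + rng.normal(0.0, sigma.prop_cv, size=f.shape))
        dv = np.maximum(dv, 1e-6)
        keep = batch.mask & (dv >= mqc)
        yield dv, keep


@dataclass
class VPCResult:
    """Visual-predictive-check table: observed vs simulated percentiles."""

    table: pd.DataFrame  # per bin: observed and simulated band columns
    n_replicates: int
    percentiles: tuple = (5.0, 50.0, 95.0)

    def plot(self, ax=None):  # pragma: no cover - exercised via CLI smoke
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4.5))
        t = self.table
        for p in self.percentiles:
            ax.fill_between(
                t["time"], t[f"sim_p{p:g}_lo"], t[f"sim_p{p:g}_hi"],
                alpha=0.25, lw=0,
            )
            ax.plot(t["time"], t[f"obs_p{p:g}"], "o-", ms=3, lw=1)
        ax.set_yscale("log")
        ax.set_xlabel("time (days)")
        ax.set_ylabel("concentration (µg/mL)")
        return ax


def visual_predictive_check(
    theta: ThetaVector,
    omega: OmegaMatrix,
    sigma: SigmaModel,
    data: PKDataset,
    n_replicates: int = 200,
    bins=None,
    seed=0,
    mqc: float = 0.0,
    percentiles=(5.0, 50.0, 95.0),
    spec: est.ModelSpec = est.FINAL_MODEL_SPEC,
    min_bin_count: int = 5,
) -> VPCResult:
    """VPC: observed percentiles per time bin against simulated 95% bands.

    By default each distinct nominal observation time is its own bin (the
    synthetic designs sample at exact nominal times); pass explicit bin
    edges for ragged data.  Simulated replicates apply the same MQC
    omission as the data to avoid censoring bias.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    batch = est.SubjectBatch(data, spec)
    times = batch.obs_t[batch.mask]
    if bins is None:
        centers = np.unique(times)
        bin_of = np.searchsorted(centers, times)
        n_bins = len(centers)
    else:
        edges = np.asarray(bins, dtype=float)
        bin_of = np.clip(np.digitize(times, edges) - 1, 0, len(edges) - 2)
        centers = 0.5 * (edges[:-1] + edges[1:])
        n_bins = len(centers)

    def bin_percentiles(values, keep_flat):
        out = np.full((n_bins, len(percentiles)), np.nan)
        counts = np.zeros(n_bins, dtype=int)
        for b in range(n_bins):
            sel = keep_flat & (bin_of == b)
            counts[b] = sel.sum()
            if counts[b] > 0:
                out[b] = np.percentile(values[sel], percentiles)
        return out, counts

    dv_obs = batch.dv[batch.mask]
    obs_p, obs_counts = bin_percentiles(dv_obs, np.ones_like(dv_obs, dtype=bool))

    sims = np.full((n_replicates, n_bins, len(percentiles)), np.nan)
    for r, (dv, keep) in enumerate(
        _simulate_replicates(batch, theta, omega, sigma, n_replicates, seed, mqc)
    ):
        sims[r], _ = bin_percentiles(dv[batch.mask], keep[batch.mask])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        sim_med = np.nanmedian(sims, axis=0)
        sim_lo = np.nanpercentile(sims, 2.5, axis=0)
        sim_hi = np.nanpercentile(sims, 97.5, axis=0)
    cols = {"time": centers, "n_obs": obs_counts,
            "flagged": obs_counts < min_bin_count}
    for j, p in enumerate(percentiles):
        cols[f"obs_p{p:g}"] = obs_p[:, j]
        cols[f"sim_p{p:g}"] = sim_med[:, j]
        cols[f"sim_p{p:g}_lo"] = sim_lo[:, j]
        cols[f"sim_p{p:g}_hi"] = sim_hi[:, j]
    return VPCResult(table=pd.DataFrame(cols), n_replicates=n_replicates,
                     percentiles=tuple(percentiles))


def numerical_predictive_check(
    theta: ThetaVector,
    omega: OmegaMatrix,
    sigma: SigmaModel,
    data: PKDataset,
    n_replicates: int = 200,
    pi_levels=(20.0, 50.0, 80.0, 90.0),
    seed=0,
    mqc: float = 0.0,
    spec: est.ModelSpec = est.FINAL_MODEL_SPEC,
) -> pd.DataFrame:
    """NPC: fraction of observations outside each simulated prediction interval.

    For each PI level the simulated per-record distribution defines the
    interval; the table reports observed and expected outside-fractions
    above and below.
    """
    batch = est.SubjectBatch(data, spec)
    n_obs = int(batch.mask.sum())
    sims = np.empty((n_replicates, n_obs))
    for r, (dv, keep) in enumerate(
        _simulate_replicates(batch, theta, omega, sigma, n_replicates, seed, mqc)
    ):
        # censored simulated records would simply be absent; for coverage we
        # keep the value (interval bounds come from the full distribution)
        sims[r] = dv[batch.mask]
    dv_obs = batch.dv[batch.mask]
    rows = []
    for level in pi_levels:
        half = level / 2.0
        lo = np.percentile(sims, 50.0 - half, axis=0)
        hi = np.percentile(sims, 50.0 + half, axis=0)
        below = float(np.mean(dv_obs < lo))
        above = float(np.mean(dv_obs > hi))
        expected = (100.0 - level) / 100.0
        rows.append(
            dict(
                pi_level=level, frac_below=below, frac_above=above,
                frac_outside=below + above, expected_outside=expected,
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


def bootstrap(
    data: PKDataset,
    n_boot: int = 200,
    seed=0,
    spec: est.ModelSpec = est.FINAL_MODEL_SPEC,
    init_from_fit: est.FitResult | None = None,
    max_nonconverged_frac: float = 0.2,
    **fit_kwargs,
) -> pd.DataFrame:
    """Nonparametric bootstrap of the population fit.

    Resamples subjects with replacement, refits each replicate (warm-started
    from the original fit when given) and reports the median and 2.5/97.5
    percentiles of every estimate.  Non-converged replicates are counted and
    excluded; the report is flagged when they exceed
    ``max_nonconverged_frac``.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if n_boot < 50:
        warnings.warn(
            f"n_boot={n_boot} is below the recommended minimum of 50; "
            "percentile CIs will be coarse"
        )
    rng = np.random.default_rng(seed)
    ids = list(data.subject_ids)
    groups = {sid: g for sid, g in data.df.groupby("ID", sort=False)}
    if init_from_fit is not None:
        fit_kwargs.setdefault("init_theta", init_from_fit.theta)
        fit_kwargs.setdefault("init_omega", init_from_fit.omega)
        fit_kwargs.setdefault("init_sigma", init_from_fit.sigma)
    rows = []
    n_fail = 0
    for b in range(n_boot):
        chosen = rng.choice(ids, size=len(ids), replace=True)
        parts = []
        for new_id, sid in enumerate(chosen, start=1):
            g = groups[sid].copy()
            g["ID"] = new_id
            parts.append(g)
        bdata = PKDataset(
            pd.concat(parts, ignore_index=True), validate=False
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = est.fit_population(bdata, spec=spec, **fit_kwargs)
        if not fit.converged:
            n_fail += 1
            continue
        row = {"replicate": b, "ofv": fit.ofv}
        row.update({k: v for k, v in fit.typical_values.items()})
        row.update({t.name: fit.coefs[t.name] for t in spec.terms})
        row.update(fit.omega.to_dict())
        row["sigma_prop"] = fit.sigma.prop_cv
        rows.append(row)
    if not rows:
        raise RuntimeError("no bootstrap replicate converged")
    reps = pd.DataFrame(rows).set_index("replicate")
    out = reps.quantile([0.5, 0.025, 0.975]).T
    out.columns = ["median", "ci_lo", "ci_hi"]
    out.attrs["n_boot"] = n_boot
    out.attrs["n_nonconverged"] = n_fail
    out.attrs["flagged"] = n_fail / n_boot > max_nonconverged_frac
    out.attrs["replicates"] = reps
    return out


# ---------------------------------------------------------------------------
# Shrinkage and IIV explained
# ---------------------------------------------------------------------------


def shrinkage(fit: est.FitResult, data: PKDataset) -> dict:
    """Eta- and epsilon-shrinkage of a converged fit, in percent.

    eta-shrinkage_k = 100 (1 - SD(eta_hat_k)/omega_k); a random effect with
    omega = 0 is reported as NaN.  epsilon-shrinkage = 100 (1 - SD(IWRES))
    with IWRES = (DV - IPRED)/(sigma IPRED).
    """
    omega_sd = {
        "CL": fit.omega.omega_cl, "Vc": fit.omega.omega_vc,
        "Q": fit.omega.omega_q, "Vp": fit.omega.omega_vp,
    }
    out = {}
    for k, e in enumerate(fit.spec.etas):
        col = fit.etas[f"eta_{e}"].to_numpy()
        w = omega_sd[e]
        out[f"eta_{e}"] = float(100.0 * (1.0 - col.std(ddof=1) / w)) if w > 0 else float("nan")
    batch = est.SubjectBatch(data, fit.spec)
    layout = est._ParamLayout(fit.spec)
    base_log = est._base_log_params(batch, fit.coefs)
    eta = fit.etas.loc[batch.ids].to_numpy()
    ipred = batch.predict(base_log, eta)
    iwres = (batch.dv - ipred) / (fit.sigma.prop_cv * ipred)
    out["epsilon"] = float(100.0 * (1.0 - iwres[batch.mask].std(ddof=1)))
    return out


def percent_iiv_explained(omega_base_percent: float, omega_final_percent: float) -> float:
    """Share of base-model IIV variance explained by the covariates:
    100 (1 - (omega_final/omega_base)^2).  Negative (flagged by sign) if
    the final model has more IIV than the base model."""
    if omega_base_percent <= 0 or omega_final_percent <= 0:
        raise ValueError("IIV percentages must be > 0")
    return 100.0 * (1.0 - (omega_final_percent / omega_base_percent) ** 2)
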