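"""Nonlinear mixed-effects estimation for the two-compartment PopPK model.

The marginal likelihood is approximated subject-by-subject by a Laplace
approximation around the conditional mode of the random effects, with the
residual variance evaluated at the individual prediction ("FOCE with
interaction" in pharmacometric usage).  For subject *i* with observations
``y`` at prediction ``f(eta)`` and proportional error SD ``sigma``::

    l_i(eta) = sum_t [ (y-f)^2 / (sigma^2 f^2) + ln(2 pi sigma^2 f^2) ]
               + eta' Om^-1 eta + ln det(2 pi Om)
    OFV_i    = l_i(eta_hat) - q ln(2 pi) + ln det( J' V^-1 J + Om^-1 )

where ``eta_hat`` minimises ``l_i``, ``J`` is the Jacobian of ``f`` at the
mode and ``V`` the residual covariance there (Gauss-Newton curvature).  The
total objective function value (OFV, "-2 log likelihood") is the sum over
subjects; covariate selection compares OFV drops to chi-square quantiles.

Everything is vectorised across subjects: event grids are padded to a
common shape so one objective evaluation is a handful of numpy array
operations, and conditional modes are warm-started between evaluations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from ._kernel import batch_concentrations
from .data import COVARIATE_COLUMNS, PKDataset
from .model import OmegaMatrix, SigmaModel, ThetaVector

__all__ = [
    "CovariateCandidate",
    "ModelSpec",
    "FINAL_MODEL_SPEC",
    "BASE_SPEC",
    "FitResult",
    "PopPKEstimator",
    "map_individual",
    "foce_objective",
    "fit_population",
    "lrt_significance",
    "stepwise_selection",
    "SelectionResult",
]

_ETA_NAMES = ("CL", "Vc", "Q", "Vp")
_COV_FIELD = {"WT": "weight", "ECD": "ecd", "ALBU": "albu",
              "TMBD": "tmbd", "TBL": "tbl", "AST": "ast"}


@dataclass(frozen=True)
class CovariateCandidate:
    """One covariate-parameter relation: a power term on a log-normalised
    covariate or a linear term on the raw value."""

    target: str  # "CL" or "Vc"
    covariate: str  # dataset column: WT, ECD, ALBU, TMBD, TBL, AST
    form: str = "power"  # "power" (theta*ln(x/ref)) or "linear" (theta*x)
    reference: float = 1.0

    def __post_init__(self) -> None:
        if self.target not in ("CL", "Vc"):
            raise ValueError("target must be 'CL' or 'Vc'")
        if self.form not in ("power", "linear"):
            raise ValueError("form must be 'power' or 'linear'")
        if self.covariate not in COVARIATE_COLUMNS:
            raise ValueError(f"unknown covariate {self.covariate!r}")

    @property
    def name(self) -> str:
        return f"{self.target.lower()}_{self.covariate.lower()}"

    def design_column(self, cov: pd.DataFrame) -> np.ndarray:
        x = cov[self.covariate].to_numpy(dtype=float)
        if self.form == "power":
            if np.any(x <= 0):
                raise ValueError(f"{self.covariate} must be > 0 for a power term")
            return np.log(x / self.reference)
        return x


@dataclass(frozen=True)
class ModelSpec:
    """Which covariate terms and random effects the fitted model carries."""

    terms: tuple = ()
    etas: tuple = _ETA_NAMES
    cl_vc_cov: bool = True  # estimate cov(eta_CL, eta_Vc) when both present

    def __post_init__(self) -> None:
        for e in self.etas:
            if e not in _ETA_NAMES:
                raise ValueError(f"unknown eta {e!r}")
        if self.cl_vc_cov and not {"CL", "Vc"} <= set(self.etas):
            object.__setattr__(self, "cl_vc_cov", False)

    def with_term(self, term: CovariateCandidate) -> "ModelSpec":
        return replace(self, terms=self.terms + (term,))

    def without_term(self, term: CovariateCandidate) -> "ModelSpec":
        return replace(self, terms=tuple(t for t in self.terms if t != term))


#: The published final-model covariate structure.
FINAL_MODEL_SPEC = ModelSpec(
    terms=(
        CovariateCandidate("Vc", "WT", "power", 70.0),
        CovariateCandidate("CL", "WT", "power", 70.0),
        CovariateCandidate("CL", "ECD", "power", 25.0),
        CovariateCandidate("CL", "ALBU", "power", 41.0),
        CovariateCandidate("CL", "TMBD", "power", 9.0),
        CovariateCandidate("CL", "TBL", "linear"),
        CovariateCandidate("CL", "AST", "power", 27.0),
    )
)

#: Covariate-free base model (full random-effect structure).
BASE_SPEC = ModelSpec()

_FINAL_COEF_TO_THETA = {
    "vc_wt": "theta5",
    "cl_wt": "theta6",
    "cl_ecd": "theta7",
    "cl_albu": "theta8",
    "cl_tmbd": "theta9",
    "cl_tbl": "theta10",
    "cl_ast": "theta11",
}


# ---------------------------------------------------------------------------
# Batched subject data
# ---------------------------------------------------------------------------


class SubjectBatch:
    """Padded per-subject event arrays plus covariate design matrices."""

    def __init__(self, data: PKDataset, spec: ModelSpec):
        df = data.df
        # observations at or before a subject's first dose have a structural
        # prediction of exactly zero, where the proportional-error likelihood
        # is undefined; they carry no information and are excluded here
        first_dose = df[df["EVID"] == 1].groupby("ID")["TIME"].min()
        pre_dose = (
            (df["EVID"] == 0)
            & (df["TIME"] <= df["ID"].map(first_dose).fillna(np.inf))
        )
        if pre_dose.any():
            df = df.loc[~pre_dose]
        ids = list(df["ID"].unique())
        obs_counts = df[df["EVID"] == 0].groupby("ID").size()
        empty = [sid for sid in ids if obs_counts.get(sid, 0) == 0]
        if empty:
            warnings.warn(
                f"dropping {len(empty)} subject(s) with no quantifiable "
                f"observations: {empty[:5]}{'...' if len(empty) > 5 else ''}"
            )
            ids = [sid for sid in ids if sid not in set(empty)]
        if not ids:
            raise ValueError("no subjects with observations")
        self.ids = np.asarray(ids)
        n = len(ids)

        durations = data.dose_durations()
        grouped = {sid: g for sid, g in df.groupby("ID", sort=False)}
        dmax = max((grouped[sid]["EVID"] == 1).sum() for sid in ids)
        tmax = max((grouped[sid]["EVID"] == 0).sum() for sid in ids)
        self.dose_t = np.zeros((n, dmax))
        self.dose_amt = np.zeros((n, dmax))  # zero padding is inert
        self.dose_dur = np.zeros((n, dmax))
        self.obs_t = np.zeros((n, tmax))
        self.dv = np.ones((n, tmax))
        self.mask = np.zeros((n, tmax), dtype=bool)
        for i, sid in enumerate(ids):
            g = grouped[sid]
            dose = g[g["EVID"] == 1]
            obs = g[g["EVID"] == 0]
            nd, no = len(dose), len(obs)
            self.dose_t[i, :nd] = dose["TIME"].to_numpy(dtype=float)
            self.dose_amt[i, :nd] = dose["AMT"].to_numpy(dtype=float)
            self.dose_dur[i, :nd] = durations.loc[dose.index].to_numpy(dtype=float)
            self.obs_t[i, :no] = obs["TIME"].to_numpy(dtype=float)
            self.dv[i, :no] = obs["DV"].to_numpy(dtype=float)
            self.mask[i, :no] = True
        self.n_obs = int(self.mask.sum())

        # precomputed inputs of the fast concentration kernel: infusion
        # rates plus per-subject time-sorted infusion ends (padding sorts
        # last and carries zero rate)
        self.dur_safe = np.maximum(self.dose_dur, 1e-9)
        self.rate = self.dose_amt / self.dur_safe
        ends = np.where(self.dose_amt > 0, self.dose_t + self.dur_safe, np.inf)
        order = np.argsort(ends, axis=1)
        self.end_t = np.take_along_axis(ends, order, axis=1)
        self.end_rate = np.take_along_axis(self.rate, order, axis=1)

        cov = data.covariates().loc[ids]
        self.covariates = cov
        self.spec = spec
        self.X_cl = np.column_stack(
            [t.design_column(cov) for t in spec.terms if t.target == "CL"]
        ) if any(t.target == "CL" for t in spec.terms) else np.zeros((n, 0))
        self.X_vc = np.column_stack(
            [t.design_column(cov) for t in spec.terms if t.target == "Vc"]
        ) if any(t.target == "Vc" for t in spec.terms) else np.zeros((n, 0))
        self.eta_idx = {e: k for k, e in enumerate(spec.etas)}
        self.q = len(spec.etas)
        self._eta_cache: np.ndarray | None = None  # warm start across calls

    def predict(self, base_log: np.ndarray, eta: np.ndarray, idx=None) -> np.ndarray:
        """Concentration matrix (n, T) at log-typicals + random effects.

        ``base_log`` has shape (N, 4) with columns (ln CL, ln Vc, ln Q,
        ln Vp) already covariate-adjusted; ``eta`` has shape (N, q).
        ``idx`` restricts the computation to a subset of subjects.
        """
        logp = base_log if idx is None else base_log[idx]
        logp = logp.copy()
        et = eta if idx is None else eta[idx]
        for k, e in enumerate(self.spec.etas):
            j = _ETA_NAMES.index(e)
            logp[:, j] = logp[:, j] + et[:, k]
        p = np.exp(np.clip(logp, -60.0, 60.0))
        if idx is None:
            dose_t, rate = self.dose_t, self.rate
            end_t, end_rate, obs_t = self.end_t, self.end_rate, self.obs_t
        else:
            dose_t = np.ascontiguousarray(self.dose_t[idx])
            rate = np.ascontiguousarray(self.rate[idx])
            end_t = np.ascontiguousarray(self.end_t[idx])
            end_rate = np.ascontiguousarray(self.end_rate[idx])
            obs_t = np.ascontiguousarray(self.obs_t[idx])
        return batch_concentrations(
            np.ascontiguousarray(p[:, 0]), np.ascontiguousarray(p[:, 1]),
            np.ascontiguousarray(p[:, 2]), np.ascontiguousarray(p[:, 3]),
            dose_t, rate, end_t, end_rate, obs_t,
        )


# ---------------------------------------------------------------------------
# Parameter packing
# ---------------------------------------------------------------------------


class _ParamLayout:
    """Maps between a named parameter dict and the free-parameter vector.

    Structural typicals are log-scale; omega is log-Cholesky (one
    off-diagonal element for the CL-Vc covariance when present); sigma is
    log CV.  ``fix`` freezes named parameters at their initial values.
    """

    def __init__(self, spec: ModelSpec, fix=()):
        self.spec = spec
        names = ["lcl", "lvc", "lq", "lvp"]
        names += [t.name for t in spec.terms]
        self.omega_names = []
        for e in spec.etas:
            self.omega_names.append(f"lomega_{e.lower()}")
        if spec.cl_vc_cov:
            self.omega_names.append("chol_cl_vc")
        names += self.omega_names
        names += ["lsigma"]
        self.names = names
        self.fix = set(fix)
        unknown = self.fix - set(names)
        if unknown:
            raise ValueError(f"unknown fixed parameter(s): {sorted(unknown)}")
        self.free = [nm for nm in names if nm not in self.fix]

    def pack(self, values: dict) -> np.ndarray:
        return np.array([values[nm] for nm in self.free], dtype=float)

    def unpack(self, x: np.ndarray, fixed_values: dict) -> dict:
        out = dict(fixed_values)
        out.update(zip(self.free, x))
        return out

    # -- conversions --------------------------------------------------------
    def values_from_model(
        self, theta: ThetaVector | dict, omega: OmegaMatrix, sigma: SigmaModel
    ) -> dict:
        spec = self.spec
        if isinstance(theta, ThetaVector):
            vals = {"lcl": theta.theta1, "lvc": theta.theta2,
                    "lq": theta.theta3, "lvp": theta.theta4}
            for t in spec.terms:
                key = _FINAL_COEF_TO_THETA.get(t.name)
                vals[t.name] = getattr(theta, key) if key else 0.0
        else:
            vals = dict(theta)
        om = {"CL": omega.omega_cl, "Vc": omega.omega_vc,
              "Q": omega.omega_q, "Vp": omega.omega_vp}
        if spec.cl_vc_cov:
            l11 = max(om["CL"], 1e-8)
            l21 = omega.omega_cl_vc / l11
            l22sq = om["Vc"] ** 2 - l21**2
            if l22sq <= 0:
                raise ValueError("omega matrix is not positive definite")
            vals["chol_cl_vc"] = l21
            chol_diag = {"CL": l11, "Vc": math.sqrt(l22sq),
                         "Q": om["Q"], "Vp": om["Vp"]}
        else:
            chol_diag = om
        for e in spec.etas:
            vals[f"lomega_{e.lower()}"] = math.log(max(chol_diag[e], 1e-8))
        vals["lsigma"] = math.log(sigma.prop_cv)
        return vals

    def omega_matrix(self, values: dict) -> np.ndarray:
        q = len(self.spec.etas)
        chol = np.zeros((q, q))
        for k, e in enumerate(self.spec.etas):
            chol[k, k] = math.exp(values[f"lomega_{e.lower()}"])
        if self.spec.cl_vc_cov:
            i_cl = self.spec.etas.index("CL")
            i_vc = self.spec.etas.index("Vc")
            lo, hi = sorted((i_cl, i_vc))
            chol[hi, lo] = values["chol_cl_vc"]
        return chol @ chol.T

    def model_from_values(self, values: dict):
        spec = self.spec
        th = {f"theta{i}": 0.0 for i in range(5, 12)}
        generic = all(t.name in _FINAL_COEF_TO_THETA for t in spec.terms)
        theta = None
        if generic:
            for t in spec.terms:
                th[_FINAL_COEF_TO_THETA[t.name]] = values[t.name]
            theta = ThetaVector(
                theta1=values["lcl"], theta2=values["lvc"],
                theta3=values["lq"], theta4=values["lvp"], **th,
            )
        om_full = np.zeros((4, 4))
        om = self.omega_matrix(values)
        for a, ea in enumerate(spec.etas):
            for b, eb in enumerate(spec.etas):
                om_full[_ETA_NAMES.index(ea), _ETA_NAMES.index(eb)] = om[a, b]
        omega = OmegaMatrix(
            omega_cl=math.sqrt(om_full[0, 0]), omega_vc=math.sqrt(om_full[1, 1]),
            omega_q=math.sqrt(om_full[2, 2]), omega_vp=math.sqrt(om_full[3, 3]),
            omega_cl_vc=om_full[0, 1],
        )
        sigma = SigmaModel(prop_cv=math.exp(values["lsigma"]))
        return theta, omega, sigma


def _base_log_params(batch: SubjectBatch, values: dict) -> np.ndarray:
    """Covariate-adjusted log-typical (ln CL, ln Vc, ln Q, ln Vp) per subject."""
    n = len(batch.ids)
    out = np.empty((n, 4))
    cl_coefs = np.array([values[t.name] for t in batch.spec.terms if t.target == "CL"])
    vc_coefs = np.array([values[t.name] for t in batch.spec.terms if t.target == "Vc"])
    out[:, 0] = values["lcl"] + (batch.X_cl @ cl_coefs if cl_coefs.size else 0.0)
    out[:, 1] = values["lvc"] + (batch.X_vc @ vc_coefs if vc_coefs.size else 0.0)
    out[:, 2] = values["lq"]
    out[:, 3] = values["lvp"]
    return out


# ---------------------------------------------------------------------------
# Inner problem: conditional modes (MAP) and Laplace terms
# ---------------------------------------------------------------------------


def _ell_data(batch, base_log, eta, s2, idx=None):
    """Per-subject data part of -2 log joint (proportional error)."""
    f = batch.predict(base_log, eta, idx)
    mask = batch.mask if idx is None else batch.mask[idx]
    dv = batch.dv if idx is None else batch.dv[idx]
    v = s2 * f * f
    r = dv - f
    terms = np.where(mask, r * r / v + np.log(2.0 * math.pi * v), 0.0)
    return terms.sum(axis=1)


def _jacobian(batch, base_log, eta, idx=None, h=1e-4, f0=None, central=False):
    """Finite-difference Jacobian df/deta, shape (n, T, q).

    Forward differences (reusing ``f0``) serve the Gauss-Newton sweeps;
    central differences back the exact Laplace curvature.
    """
    n = len(batch.ids) if idx is None else len(idx)
    jac = np.empty((n, batch.dv.shape[1], batch.q))
    if not central and f0 is None:
        f0 = batch.predict(base_log, eta, idx)
    for k in range(batch.q):
        dp = eta.copy(); dp[:, k] += h
        fp = batch.predict(base_log, dp, idx)
        if central:
            dm = eta.copy(); dm[:, k] -= h
            jac[:, :, k] = (fp - batch.predict(base_log, dm, idx)) / (2 * h)
        else:
            jac[:, :, k] = (fp - f0) / h
    return jac


def _inner_gradient(batch, base_log, eta, oinv, s2, idx=None):
    """Analytic gradient of l_i(eta) per subject, shape (n, q).

    The data part contributes three pieces: the weighted residual, the
    eta-dependence of the proportional variance, and the ln v term.
    """
    f = batch.predict(base_log, eta, idx)
    jac = _jacobian(batch, base_log, eta, idx, central=True)
    mask = batch.mask if idx is None else batch.mask[idx]
    dv = batch.dv if idx is None else batch.dv[idx]
    et = eta if idx is None else eta[idx]
    v = s2 * f * f
    r = dv - f
    w = np.where(mask, 1.0 / v, 0.0)
    gper = (-2.0 * r * w - 2.0 * r * r * w / f + 2.0 / f) * mask
    return np.einsum("nt,ntq->nq", gper, jac) + 2.0 * et @ oinv


def _solve_modes(batch, base_log, oinv, s2, eta0=None, tol=1e-6, maxiter=40,
                 om_diag=None):
    """Batched damped Gauss-Newton for the conditional modes.

    Only subjects that have not yet converged are recomputed each sweep.
    With very wide random-effect distributions (omega SD above ~0.5, as for
    Q and Vp here) the conditional objective can be multimodal; candidate
    starting points on a coarse grid over those dimensions are then polished
    separately, and the per-subject best polished mode is kept.
    Returns (eta_hat, ell_at_mode) with ell = data part + eta' Om^-1 eta.
    """
    n = len(batch.ids)
    q = batch.q

    def ell_of(eta):
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return _ell_data(batch, base_log, eta, s2) + np.einsum(
                "nq,qp,np->n", eta, oinv, eta
            )

    eta = np.zeros((n, q))
    ell = ell_of(eta)
    if eta0 is not None:
        # a stale warm start (e.g. cached from an extreme parameter proposal)
        # can be far worse than the prior mode; keep the better per subject
        ell_w = ell_of(eta0)
        better = np.isfinite(ell_w) & (ell_w < ell)
        eta[better] = eta0[better]
        ell[better] = ell_w[better]
    eta, ell = _newton_polish(batch, base_log, oinv, s2, eta, ell, tol, maxiter)

    wide = (
        np.where(np.sqrt(np.maximum(om_diag, 0.0)) > 0.5)[0]
        if om_diag is not None
        else np.array([], dtype=int)
    )
    if wide.size:
        # seed a second polish from the best coarse-grid point around the
        # first mode (coordinate sweeps +-3 SD plus a joint grid over pairs)
        sds = np.sqrt(om_diag)
        cands = []
        for k in wide:
            for c in (-3.0, -2.0, -1.0, 1.0, 2.0, 3.0):
                cand = eta.copy()
                cand[:, k] = c * sds[k]
                cands.append(cand)
        for a in range(len(wide)):
            for b in range(a + 1, len(wide)):
                ka, kb = wide[a], wide[b]
                for ca in (-2.0, -1.0, 1.0, 2.0):
                    for cb in (-2.0, -1.0, 1.0, 2.0):
                        cand = eta.copy()
                        cand[:, ka] = ca * sds[ka]
                        cand[:, kb] = cb * sds[kb]
                        cands.append(cand)
        seed_eta = eta.copy()
        seed_ell = ell.copy()
        for cand in cands:
            ellc = ell_of(cand)
            upd = np.isfinite(ellc) & (ellc < seed_ell)
            seed_eta[upd] = cand[upd]
            seed_ell[upd] = ellc[upd]
        promising = seed_ell < ell - 1e-9
        if promising.any():
            eta2, ell2 = _newton_polish(
                batch, base_log, oinv, s2, seed_eta, seed_ell, tol, maxiter
            )
            upd = ell2 < ell
            eta[upd] = eta2[upd]
            ell[upd] = ell2[upd]
    return eta, ell


def _newton_polish(batch, base_log, oinv, s2, eta, ell, tol=1e-6, maxiter=40):
    """Damped Gauss-Newton sweeps from given starts; monotone in ell."""
    n = len(batch.ids)
    q = batch.q
    eta = eta.copy()
    ell = ell.copy()
    active = np.arange(n)
    for _ in range(maxiter):
        sub = active
        f = batch.predict(base_log, eta, sub)
        jac = _jacobian(batch, base_log, eta, sub, central=True)
        mask = batch.mask[sub]
        dv = batch.dv[sub]
        et = eta[sub]
        v = s2 * f * f
        r = dv - f
        w = np.where(mask, 1.0 / v, 0.0)
        gper = (-2.0 * r * w - 2.0 * r * r * w / f + 2.0 / f) * mask
        grad = np.einsum("nt,ntq->nq", gper, jac) + 2.0 * et @ oinv
        hess = 2.0 * np.einsum("ntq,nt,ntp->nqp", jac, w, jac) + 2.0 * oinv
        bad = ~(np.isfinite(hess).all(axis=(1, 2)) & np.isfinite(grad).all(axis=1))
        if bad.any():
            hess[bad] = np.eye(q)
            grad[bad] = 0.0
        eye = np.eye(q)
        scale = np.abs(np.diagonal(hess, axis1=1, axis2=2)).max(axis=1)
        for ridge in (0.0, 1e-8, 1e-4, 1e-1):
            try:
                step = -np.linalg.solve(
                    hess + ridge * scale[:, None, None] * eye, grad[:, :, None]
                )[:, :, 0]
                break
            except np.linalg.LinAlgError:
                continue
        else:  # pragma: no cover - pathological
            step = -grad
        decrement = -0.5 * np.einsum("nq,nq->n", grad, step)  # expected gain
        # batched backtracking line search
        lam = np.ones(len(sub))
        searching = np.ones(len(sub), dtype=bool)
        new_et = et.copy()
        new_ell = ell[sub].copy()
        stuck = np.zeros(len(sub), dtype=bool)
        for ls in range(15):
            if not searching.any():
                break
            cand = np.where(searching[:, None], et + lam[:, None] * step, new_et)
            trial = eta.copy()
            trial[sub] = cand
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                tell = _ell_data(batch, base_log, trial, s2, sub) + np.einsum(
                    "nq,qp,np->n", cand, oinv, cand
                )
            improved = searching & (tell < ell[sub])
            new_et[improved] = cand[improved]
            new_ell[improved] = tell[improved]
            searching = searching & ~improved
            lam[searching] *= 0.5
        stuck = searching  # no decrease found along the Newton direction
        moved = np.abs(new_et - et).max(axis=1)
        gained = ell[sub] - new_ell
        eta[sub] = new_et
        ell[sub] = new_ell
        # flat directions (large omega, little subject information) yield
        # microscopic but nonzero predicted gains forever; stop on any of:
        # failed search, tiny step, tiny realised gain, tiny Newton decrement
        done = stuck | (moved < tol) | (gained < 1e-8) | (decrement < 1e-9)
        active = sub[~done]
        if active.size == 0:
            break
    return eta, ell


def _laplace_hessian(batch, base_log, eta, oinv, s2, exact=False, h=1e-4):
    """Curvature term of the Laplace approximation, shape (N, q, q).

    ``exact=False`` gives the Gauss-Newton curvature J' V^-1 J + Om^-1
    (the conditional-mode linearisation used during optimisation);
    ``exact=True`` differentiates the analytic inner gradient once more
    (full Laplace curvature, used for reported objective values).
    """
    if exact:
        q = batch.q
        n = len(batch.ids)
        hess = np.empty((n, q, q))
        for k in range(q):
            dp = eta.copy(); dp[:, k] += h
            dm = eta.copy(); dm[:, k] -= h
            gp = _inner_gradient(batch, base_log, dp, oinv, s2)
            gm = _inner_gradient(batch, base_log, dm, oinv, s2)
            hess[:, k, :] = (gp - gm) / (2 * h)
        hess = 0.5 * (hess + np.transpose(hess, (0, 2, 1))) / 2.0  # of ell/2
        # fall back to Gauss-Newton curvature where not positive definite
        sign, _ = np.linalg.slogdet(hess)
        bad = sign <= 0
        if np.any(bad):
            gn = _laplace_hessian(batch, base_log, eta, oinv, s2, exact=False)
            hess[bad] = gn[bad]
        return hess
    f = batch.predict(base_log, eta)
    jac = _jacobian(batch, base_log, eta, f0=f)
    v = s2 * f * f
    w = np.where(batch.mask, 1.0 / v, 0.0)
    return np.einsum("ntq,nt,ntp->nqp", jac, w, jac) + oinv


def _objective(
    batch: SubjectBatch, values: dict, hessian: str = "gn", penalty: float = 1e10
) -> float:
    """FOCE-I/Laplace objective for one parameter dict; inf-safe."""
    layout = _ParamLayout(batch.spec)
    om = layout.omega_matrix(values)
    try:
        oinv = np.linalg.inv(om)
    except np.linalg.LinAlgError:
        return penalty
    base_log = _base_log_params(batch, values)
    s2 = math.exp(2.0 * values["lsigma"])
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        eta, ell = _solve_modes(
            batch, base_log, oinv, s2, eta0=batch._eta_cache, om_diag=np.diag(om)
        )
        batch._eta_cache = eta
        h_lap = _laplace_hessian(
            batch, base_log, eta, oinv, s2, exact=(hessian == "exact")
        )
        sign, logdet_h = np.linalg.slogdet(h_lap)
    if np.any(sign <= 0):
        return penalty
    _, logdet_om = np.linalg.slogdet(om)
    n = len(batch.ids)
    ofv = float(np.sum(ell) + n * logdet_om + logdet_h.sum())
    return ofv if math.isfinite(ofv) else penalty


# ---------------------------------------------------------------------------
# Results and estimator
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Population fit: estimates, OFV, empirical-Bayes etas, convergence."""

    theta: ThetaVector | None
    coefs: dict
    omega: OmegaMatrix
    sigma: SigmaModel
    ofv: float
    etas: pd.DataFrame
    converged: bool
    spec: ModelSpec
    n_subjects: int
    n_observations: int
    message: str = ""
    se: dict | None = None
    ci95: dict | None = None

    @property
    def typical_values(self) -> dict[str, float]:
        return {
            "CL": math.exp(self.coefs["lcl"]),
            "Vc": math.exp(self.coefs["lvc"]),
            "Q": math.exp(self.coefs["lq"]),
            "Vp": math.exp(self.coefs["lvp"]),
        }


class PopPKEstimator(BaseEstimator):
    """Population PK mixed-effects estimator (sklearn-style interface).

    Parameters
    ----------
    spec : ModelSpec, default FINAL_MODEL_SPEC
        Covariate terms and random-effect structure to estimate.
    init_theta, init_omega, init_sigma : optional initial values; defaults
        are generic mAb-like starting points.
    fix : iterable of parameter names to hold at their initial values
        (e.g. ``("lq", "lvp")`` or omega/sigma entries).
    maxiter : outer optimiser iteration cap.
    tol : relative OFV convergence tolerance of the outer optimiser.
    compute_se : if True, asymptotic standard errors from a finite-
        difference Hessian of OFV/2 (adds ~p^2 objective evaluations).

    Attributes (after ``fit``)
    --------------------------
    theta_, omega_, sigma_, coefs_, ofv_, etas_, converged_, result_
    """

    def __init__(
        self,
        spec: ModelSpec = FINAL_MODEL_SPEC,
        init_theta: ThetaVector | None = None,
        init_omega: OmegaMatrix | None = None,
        init_sigma: SigmaModel | None = None,
        fix: tuple = (),
        maxiter: int = 300,
        tol: float = 1e-6,
        hessian: str = "gn",
        compute_se: bool = False,
        verbose: bool = False,
    ):
        self.spec = spec
        self.init_theta = init_theta
        self.init_omega = init_omega
        self.init_sigma = init_sigma
        self.fix = fix
        self.maxiter = maxiter
        self.tol = tol
        self.hessian = hessian
        self.compute_se = compute_se
        self.verbose = verbose

    # -- defaults -----------------------------------------------------------
    def _initial_values(self, layout: _ParamLayout) -> dict:
        theta = self.init_theta or ThetaVector(
            theta1=math.log(0.5), theta2=math.log(3.0),
            theta3=math.log(1.0), theta4=math.log(1.0),
        )
        omega = self.init_omega or OmegaMatrix(0.3, 0.3, 0.5, 0.5, 0.0)
        if layout.spec.cl_vc_cov and omega.omega_cl_vc == 0.0:
            omega = OmegaMatrix(
                omega.omega_cl, omega.omega_vc, omega.omega_q, omega.omega_vp,
                0.1 * omega.omega_cl * omega.omega_vc,
            )
        sigma = self.init_sigma or SigmaModel(0.3)
        return layout.values_from_model(theta, omega, sigma)

    # -- sklearn API --------------------------------------------------------
    def fit(self, data: PKDataset, y=None) -> "PopPKEstimator":
        batch = SubjectBatch(data, self.spec)
        med_obs = float(np.median(batch.mask.sum(axis=1)))
        if med_obs < len(self.spec.etas):
            warnings.warn(
                f"median of {med_obs:.0f} observations/subject is below the "
                f"{len(self.spec.etas)} random effects; the design may not "
                "identify all variance components"
            )
        layout = _ParamLayout(self.spec, fix=self.fix)
        init = self._initial_values(layout)
        x0 = layout.pack(init)

        # precondition: coefficients of wide-ranged linear covariates (e.g.
        # TBL in µg/mL) live on a much smaller natural scale than log-typicals
        scales = np.ones_like(x0)
        col_span = {
            t.name: max(1.0, float(np.abs(t.design_column(batch.covariates)).max()))
            for t in self.spec.terms
        }
        for k, nm in enumerate(layout.free):
            if nm in col_span:
                scales[k] = 1.0 / col_span[nm]
        z0 = x0 / scales

        def fun(z):
            values = layout.unpack(z * scales, init)
            ofv = _objective(batch, values, hessian=self.hessian)
            if self.verbose:  # pragma: no cover - debug aid
                print(f"OFV {ofv:.4f}")
            return ofv

        def jac(z, h=1e-4):
            # central differences with the conditional-mode cache frozen,
            # so inner-solve noise cancels between the paired evaluations
            frozen = None if batch._eta_cache is None else batch._eta_cache.copy()
            g = np.empty_like(z)
            for k in range(len(z)):
                zp = z.copy(); zp[k] += h
                zm = z.copy(); zm[k] -= h
                batch._eta_cache = None if frozen is None else frozen.copy()
                fp = _objective(batch, layout.unpack(zp * scales, init),
                                hessian=self.hessian)
                batch._eta_cache = None if frozen is None else frozen.copy()
                fm = _objective(batch, layout.unpack(zm * scales, init),
                                hessian=self.hessian)
                g[k] = (fp - fm) / (2 * h)
            batch._eta_cache = frozen
            return g

        if len(x0):
            # balance the gradient across parameters so the optimiser's
            # first line search cannot overshoot one steep direction (e.g. a
            # freshly added covariate coefficient) and stall prematurely
            g0 = jac(z0)
            adj = 1.0 / np.sqrt(np.clip(np.abs(g0), 1.0, 1e6))
            scales = scales * adj
            z0 = x0 / scales
            res = optimize.minimize(
                fun, z0, jac=jac, method="L-BFGS-B",
                bounds=[(-25.0 / s, 25.0 / s) for s in scales],
                options=dict(maxiter=self.maxiter, ftol=self.tol, gtol=1e-4),
            )
            xbest, converged, message = res.x * scales, bool(res.success), str(res.message)
        else:
            xbest, converged, message = x0, True, "all parameters fixed"
        values = layout.unpack(xbest, init)
        # final pass at the optimum: fresh modes, exact-curvature OFV
        batch._eta_cache = None
        ofv = _objective(batch, values, hessian="exact")
        theta, omega, sigma = layout.model_from_values(values)
        etas = pd.DataFrame(
            batch._eta_cache, index=pd.Index(batch.ids, name="ID"),
            columns=[f"eta_{e}" for e in self.spec.etas],
        )
        se = ci = None
        if self.compute_se and len(x0):
            se, ci = self._asymptotic_se(fun, res.x, layout, values, scales, batch)
        self.result_ = FitResult(
            theta=theta, coefs=values, omega=omega, sigma=sigma, ofv=ofv,
            etas=etas, converged=converged, spec=self.spec,
            n_subjects=len(batch.ids), n_observations=batch.n_obs,
            message=message, se=se, ci95=ci,
        )
        self.theta_ = theta
        self.omega_ = omega
        self.sigma_ = sigma
        self.coefs_ = values
        self.ofv_ = ofv
        self.etas_ = etas
        self.converged_ = converged
        self._batch = batch
        return self

    def _asymptotic_se(self, fun, z, layout, values, scales, batch):
        """SEs from a central finite-difference Hessian of OFV/2.

        Works in the optimiser's preconditioned coordinates with the
        conditional-mode cache frozen, so inner-solve noise cancels in the
        double differences; SDs are mapped back to natural units.
        """
        p = len(z)
        h = 1e-2
        frozen = None if batch._eta_cache is None else batch._eta_cache.copy()

        def f(zz):
            batch._eta_cache = None if frozen is None else frozen.copy()
            return fun(zz)

        hess = np.zeros((p, p))
        for a in range(p):
            for b in range(a, p):
                za = z.copy(); za[a] += h; za[b] += h
                zb = z.copy(); zb[a] += h; zb[b] -= h
                zc = z.copy(); zc[a] -= h; zc[b] += h
                zd = z.copy(); zd[a] -= h; zd[b] -= h
                hess[a, b] = hess[b, a] = (
                    f(za) - f(zb) - f(zc) + f(zd)
                ) / (4 * h * h)
        batch._eta_cache = frozen
        try:
            cov = np.linalg.inv(hess / 2.0)
            sd = np.sqrt(np.maximum(np.diag(cov), 0.0)) * scales
        except np.linalg.LinAlgError:  # pragma: no cover
            return None, None
        se = dict(zip(layout.free, sd))
        ci = {
            nm: (values[nm] - 1.96 * se[nm], values[nm] + 1.96 * se[nm])
            for nm in layout.free
        }
        return se, ci

    def predict(self, data: PKDataset, kind: str = "ipred") -> np.ndarray:
        """Predicted concentrations at the dataset's observation records.

        ``kind='pred'`` uses population typicals (eta = 0, per-subject
        covariates); ``kind='ipred'`` uses MAP empirical-Bayes etas
        estimated from the data under the fitted model.
        """
        if not hasattr(self, "result_"):
            raise RuntimeError("estimator is not fitted")
        batch = SubjectBatch(data, self.spec)
        base_log = _base_log_params(batch, self.coefs_)
        if kind == "pred":
            eta = np.zeros((len(batch.ids), batch.q))
        elif kind == "ipred":
            layout = _ParamLayout(self.spec)
            om = layout.omega_matrix(self.coefs_)
            eta, _ = _solve_modes(
                batch, base_log, np.linalg.inv(om),
                self.sigma_.prop_cv**2, om_diag=np.diag(om),
            )
        else:
            raise ValueError("kind must be 'pred' or 'ipred'")
        conc = batch.predict(base_log, eta)
        return conc[batch.mask]


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------


def map_individual(
    theta: ThetaVector,
    omega: OmegaMatrix,
    sigma: SigmaModel,
    subject_data: PKDataset,
    spec: ModelSpec = FINAL_MODEL_SPEC,
) -> np.ndarray:
    """MAP (empirical-Bayes) eta estimates for each subject in the dataset.

    Returns an (N, q) array ordered like ``spec.etas``.  Subjects with no
    observations get eta = 0 (the prior mode).  A singular omega matrix is
    an error.
    """
    sub = [_ETA_NAMES.index(e) for e in spec.etas]
    om_in = omega.matrix[np.ix_(sub, sub)]
    if np.linalg.eigvalsh(om_in).min() <= 1e-12:
        raise ValueError("omega matrix is singular for the requested etas")
    layout = _ParamLayout(spec)
    values = layout.values_from_model(theta, omega, sigma)
    om = layout.omega_matrix(values)
    df = subject_data.df
    has_obs = df[df["EVID"] == 0].groupby("ID").size()
    all_ids = list(df["ID"].unique())
    if has_obs.sum() == 0:
        return np.zeros((len(all_ids), len(spec.etas)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        batch = SubjectBatch(subject_data, spec)
    base_log = _base_log_params(batch, values)
    eta, _ = _solve_modes(
        batch, base_log, np.linalg.inv(om), sigma.prop_cv**2, om_diag=np.diag(om)
    )
    out = np.zeros((len(all_ids), batch.q))
    pos = {sid: i for i, sid in enumerate(batch.ids)}
    for i, sid in enumerate(all_ids):
        if has_obs.get(sid, 0) > 0:
            out[i] = eta[pos[sid]]
    return out


def foce_objective(
    theta: ThetaVector,
    omega: OmegaMatrix,
    sigma: SigmaModel,
    data: PKDataset,
    spec: ModelSpec = FINAL_MODEL_SPEC,
    hessian: str = "exact",
) -> float:
    """FOCE-I objective function value at the given population parameters.

    ``hessian='exact'`` (default) evaluates the full Laplace curvature;
    ``'gn'`` uses the Gauss-Newton linearisation the optimiser works with.
    """
    batch = SubjectBatch(data, spec)
    layout = _ParamLayout(spec)
    values = layout.values_from_model(theta, omega, sigma)
    return _objective(batch, values, hessian=hessian)


def fit_population(
    data: PKDataset,
    spec: ModelSpec = FINAL_MODEL_SPEC,
    init_theta: ThetaVector | None = None,
    init_omega: OmegaMatrix | None = None,
    init_sigma: SigmaModel | None = None,
    fix: tuple = (),
    **kwargs,
) -> FitResult:
    """Fit the population model; thin wrapper over :class:`PopPKEstimator`."""
    est = PopPKEstimator(
        spec=spec, init_theta=init_theta, init_omega=init_omega,
        init_sigma=init_sigma, fix=fix, **kwargs,
    )
    est.fit(data)
    return est.result_


def lrt_significance(delta_ofv: float, df: int = 1) -> float:
    """Upper-tail chi-square p-value for an OFV drop at ``df`` degrees."""
    if delta_ofv < 0 or df < 1:
        raise ValueError("require delta_ofv >= 0 and df >= 1")
    return float(stats.chi2.sf(delta_ofv, df))


@dataclass
class SelectionResult:
    """Outcome of stepwise covariate selection."""

    final: FitResult
    selected: tuple
    trace: list = field(default_factory=list)


def stepwise_selection(
    data: PKDataset,
    candidates,
    base_spec: ModelSpec = BASE_SPEC,
    forward_alpha: float = 0.01,
    backward_alpha: float = 0.001,
    df_per_term: int = 1,
    **fit_kwargs,
) -> SelectionResult:
    """Forward addition / backward deletion over covariate candidates.

    Forward: repeatedly add the candidate with the largest OFV drop while
    its likelihood-ratio p-value is below ``forward_alpha``.  Backward:
    repeatedly remove the term whose deletion raises OFV least while that
    rise is not significant at ``backward_alpha``.  Each term counts
    ``df_per_term`` degrees of freedom.  The trace records every fitted
    step.
    """
    candidates = list(candidates)
    trace: list[dict] = []

    def do_fit(spec, warm=None):
        kw = dict(fit_kwargs)
        if warm is not None:
            kw.setdefault("init_theta", warm.theta)
            kw.setdefault("init_omega", warm.omega)
            kw.setdefault("init_sigma", warm.sigma)
        return fit_population(data, spec=spec, **kw)

    current_spec = base_spec
    current = do_fit(current_spec)
    trace.append({"step": "base", "term": None, "ofv": current.ofv, "p": None,
                  "action": "start"})

    remaining = [c for c in candidates if c not in current_spec.terms]
    while remaining:
        fits = []
        for cand in remaining:
            fit = do_fit(current_spec.with_term(cand), warm=current)
            delta = current.ofv - fit.ofv
            p = lrt_significance(max(delta, 0.0), df_per_term)
            fits.append((delta, p, cand, fit))
            trace.append({"step": "forward-test", "term": cand.name,
                          "ofv": fit.ofv, "p": p, "action": "tested"})
        delta, p, cand, fit = max(fits, key=lambda z: z[0])
        if p < forward_alpha:
            current_spec = current_spec.with_term(cand)
            current = fit
            remaining = [c for c in remaining if c != cand]
            trace.append({"step": "forward", "term": cand.name, "ofv": fit.ofv,
                          "p": p, "action": "added"})
        else:
            break

    while current_spec.terms:
        removable = [t for t in current_spec.terms if t in candidates]
        if not removable:
            break
        fits = []
        for term in removable:
            fit = do_fit(current_spec.without_term(term), warm=current)
            rise = fit.ofv - current.ofv
            p = lrt_significance(max(rise, 0.0), df_per_term)
            fits.append((rise, p, term, fit))
            trace.append({"step": "backward-test", "term": term.name,
                          "ofv": fit.ofv, "p": p, "action": "tested"})
        rise, p, term, fit = min(fits, key=lambda z: z[0])
        if p >= backward_alpha:
            current_spec = current_spec.without_term(term)
            current = fit
            trace.append({"step": "backward", "term": term.name, "ofv": fit.ofv,
                          "p": p, "action": "removed"})
        else:
            break

    return SelectionResult(final=current, selected=current_spec.terms, trace=trace)
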