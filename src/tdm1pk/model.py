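"""Structural two-compartment model and covariate model for T-DM1 conjugate PK.

Units are fixed throughout the package: time in days, dose amounts in mg,
volumes in L, clearances in L/day, concentrations in mg/L (numerically equal
to µg/mL).  The published final-model parameters (``PUBLISHED_THETA`` etc.)
are directly usable on this scale.

The disposition model is a linear two-compartment model with first-order
elimination from the central compartment and zero-order (infusion) input.
Typical clearance and central volume are covariate-adjusted::

    CL_i = exp(th1 + th6*ln(WT/70) + th7*ln(ECD/25) + th8*ln(ALBU/41)
               + th9*ln(TMBD/9) + th10*TBL + th11*ln(AST/27) + eta_CL)
    Vc_i = exp(th2 + th5*ln(WT/70) + eta_Vc)

with body weight (kg), HER2 shed extracellular domain ECD (ng/mL), serum
albumin (g/L), tumour burden TMBD (cm, sum of longest lesion dimensions),
residual baseline trastuzumab TBL (µg/mL, entering linearly) and AST (IU/L).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ThetaVector",
    "OmegaMatrix",
    "SigmaModel",
    "CovariateVector",
    "IndividualParameters",
    "DoseEvent",
    "ExposureMetrics",
    "PUBLISHED_THETA",
    "PUBLISHED_OMEGA",
    "PUBLISHED_SIGMA",
    "REFERENCE_COVARIATES",
    "DEFAULT_INFUSION_DURATION",
    "typical_clearance",
    "typical_central_volume",
    "individual_parameters",
    "micro_constants",
    "terminal_half_life",
    "concentration",
    "steady_state_exposure",
]

#: Default infusion duration in days (30 minutes), configurable per dose event.
DEFAULT_INFUSION_DURATION = 0.0208


@dataclass(frozen=True)
class ThetaVector:
    """Fixed-effect parameters of the covariate model.

    ``theta1``..``theta4`` are natural logs of the typical CL (L/day),
    Vc (L), Q (L/day) and Vp (L); ``theta5``..``theta11`` are covariate
    coefficients (power exponents on log-normalised covariates, except
    ``theta10`` which multiplies TBL linearly, per µg/mL).
    """

    theta1: float
    theta2: float
    theta3: float
    theta4: float
    theta5: float = 0.0
    theta6: float = 0.0
    theta7: float = 0.0
    theta8: float = 0.0
    theta9: float = 0.0
    theta10: float = 0.0
    theta11: float = 0.0

    def __post_init__(self) -> None:
        for name in ("theta1", "theta2", "theta3", "theta4"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite (got {v!r})")

    def to_dict(self) -> dict[str, float]:
        return {f"theta{i}": float(getattr(self, f"theta{i}")) for i in range(1, 12)}

    @classmethod
    def from_dict(cls, d: dict) -> "ThetaVector":
        return cls(**{f"theta{i}": float(d[f"theta{i}"]) for i in range(1, 12)})

    @property
    def typical_values(self) -> dict[str, float]:
        """Typical CL, Vc, Q, Vp at the reference covariates."""
        return {
            "CL": math.exp(self.theta1),
            "Vc": math.exp(self.theta2),
            "Q": math.exp(self.theta3),
            "Vp": math.exp(self.theta4),
        }


@dataclass(frozen=True)
class OmegaMatrix:
    """Inter-individual variance-covariance of the log-scale random effects.

    Stored as standard deviations ``omega_*`` of (eta_CL, eta_Vc, eta_Q,
    eta_Vp) plus the CL-Vc covariance; all other off-diagonals are zero.
    The conventional "IIV %" report is 100*omega (SD of the log-scale eta).
    """

    omega_cl: float
    omega_vc: float
    omega_q: float
    omega_vp: float
    omega_cl_vc: float = 0.0  # covariance (not correlation) between eta_CL, eta_Vc

    def __post_init__(self) -> None:
        if min(self.omega_cl, self.omega_vc, self.omega_q, self.omega_vp) < 0:
            raise ValueError("omega standard deviations must be >= 0")
        m = self.matrix
        if np.linalg.eigvalsh(m).min() < -1e-12:
            raise ValueError("omega matrix must be positive semi-definite")

    @property
    def matrix(self) -> np.ndarray:
        m = np.diag(
            [
                self.omega_cl**2,
                self.omega_vc**2,
                self.omega_q**2,
                self.omega_vp**2,
            ]
        )
        m[0, 1] = m[1, 0] = self.omega_cl_vc
        return m

    @property
    def iiv_percent(self) -> dict[str, float]:
        """IIV reported as 100*omega for each random effect."""
        return {
            "CL": 100 * self.omega_cl,
            "Vc": 100 * self.omega_vc,
            "Q": 100 * self.omega_q,
            "Vp": 100 * self.omega_vp,
        }

    @classmethod
    def from_iiv_percent(
        cls,
        cl: float,
        vc: float,
        q: float,
        vp: float,
        cov_cl_vc: float = 0.0,
        convention: str = "sd",
    ) -> "OmegaMatrix":
        """Build from IIV percentages.

        ``convention='sd'`` reads x% as omega = x/100 (SD of log eta, the
        common reporting convention); ``convention='cv'`` reads x% as the
        CV of the lognormal, omega = sqrt(ln(1 + (x/100)^2)).
        """
        if convention == "sd":
            f = lambda x: x / 100.0
        elif convention == "cv":
            f = lambda x: math.sqrt(math.log1p((x / 100.0) ** 2))
        else:
            raise ValueError("convention must be 'sd' or 'cv'")
        return cls(f(cl), f(vc), f(q), f(vp), cov_cl_vc)

    def to_dict(self) -> dict[str, float]:
        return {
            "omega_cl": self.omega_cl,
            "omega_vc": self.omega_vc,
            "omega_q": self.omega_q,
            "omega_vp": self.omega_vp,
            "omega_cl_vc": self.omega_cl_vc,
        }


@dataclass(frozen=True)
class SigmaModel:
    """Residual error model: proportional with CV ``prop_cv`` (fraction)."""

    prop_cv: float
    form: str = "proportional"

    def __post_init__(self) -> None:
        if self.prop_cv <= 0:
            raise ValueError("residual CV must be > 0")
        if self.form != "proportional":
            raise ValueError("only the proportional error form is supported")

    def to_dict(self) -> dict[str, float]:
        return {"sigma_prop": self.prop_cv}


@dataclass(frozen=True)
class CovariateVector:
    """Baseline covariates of one subject (weight kg, ECD ng/mL, ALBU g/L,
    TMBD cm, TBL µg/mL, AST IU/L)."""

    weight: float
    ecd: float
    albu: float
    tmbd: float
    tbl: float
    ast: float

    def __post_init__(self) -> None:
        for name in ("weight", "ecd", "albu", "tmbd", "ast"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0 (a log is taken of it)")
        if self.tbl < 0:
            raise ValueError("tbl must be >= 0")

    @classmethod
    def reference(cls) -> "CovariateVector":
        return REFERENCE_COVARIATES

    def replace(self, **kw) -> "CovariateVector":
        return replace(self, **kw)

    def to_dict(self) -> dict[str, float]:
        return {
            "weight": self.weight,
            "ecd": self.ecd,
            "albu": self.albu,
            "tmbd": self.tmbd,
            "tbl": self.tbl,
            "ast": self.ast,
        }


#: Reference (normalising) covariate values of the covariate model.
REFERENCE_COVARIATES = CovariateVector(
    weight=70.0, ecd=25.0, albu=41.0, tmbd=9.0, tbl=0.0, ast=27.0
)

#: Published final-model fixed effects (typicals on the log scale).
PUBLISHED_THETA = ThetaVector(
    theta1=math.log(0.676),
    theta2=math.log(3.127),
    theta3=math.log(1.534),
    theta4=math.log(0.66),
    theta5=0.596,
    theta6=0.49,
    theta7=0.035,
    theta8=-0.423,
    theta9=0.052,
    theta10=-0.002,
    theta11=0.071,
)

#: Published final-model IIV (SD convention) and CL-Vc covariance.
PUBLISHED_OMEGA = OmegaMatrix.from_iiv_percent(
    cl=19.11, vc=11.66, q=180.8, vp=74.50, cov_cl_vc=0.011
)

#: Published proportional residual error (31.56 %CV).
PUBLISHED_SIGMA = SigmaModel(prop_cv=0.3156)


@dataclass(frozen=True)
class IndividualParameters:
    """Realised PK parameters of one subject (typical values x exp(eta))."""

    cl: float
    vc: float
    q: float
    vp: float
    eta: np.ndarray = field(default_factory=lambda: np.zeros(4))

    def __post_init__(self) -> None:
        if min(self.cl, self.vc, self.vp) <= 0 or self.q < 0:
            raise ValueError("cl, vc, vp must be > 0 and q >= 0")


@dataclass(frozen=True)
class DoseEvent:
    """One administration: time (days), amount (mg), infusion duration (days,
    0 flags an instantaneous bolus)."""

    time: float
    amount: float
    duration: float = DEFAULT_INFUSION_DURATION

    def __post_init__(self) -> None:
        if self.amount < 0 or self.duration < 0 or self.time < 0:
            raise ValueError("dose time, amount and duration must be >= 0")


@dataclass(frozen=True)
class ExposureMetrics:
    """Steady-state exposure over one dosing interval."""

    auc_ss: float  # µg·day/mL
    cmax_ss: float  # µg/mL
    ctrough_ss: float  # µg/mL


# ---------------------------------------------------------------------------
# Covariate model
# ---------------------------------------------------------------------------


def typical_clearance(theta: ThetaVector, cov: CovariateVector) -> float:
    """Typical (eta = 0) elimination clearance in L/day for given covariates."""
    log_cl = (
        theta.theta1
        + theta.theta6 * math.log(cov.weight / 70.0)
        + theta.theta7 * math.log(cov.ecd / 25.0)
        + theta.theta8 * math.log(cov.albu / 41.0)
        + theta.theta9 * math.log(cov.tmbd / 9.0)
        + theta.theta10 * cov.tbl
        + theta.theta11 * math.log(cov.ast / 27.0)
    )
    return math.exp(log_cl)


def typical_central_volume(theta: ThetaVector, cov: CovariateVector) -> float:
    """Typical central volume in L for a given body weight."""
    return math.exp(theta.theta2 + theta.theta5 * math.log(cov.weight / 70.0))


def individual_parameters(
    theta: ThetaVector, cov: CovariateVector, eta
) -> IndividualParameters:
    """Subject-level parameters: typical values times exp(eta).

    ``eta`` is the 4-vector (eta_CL, eta_Vc, eta_Q, eta_Vp) of log-scale
    deviations.
    """
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (4,) or not np.all(np.isfinite(eta)):
        raise ValueError("eta must be a finite 4-vector")
    return IndividualParameters(
        cl=typical_clearance(theta, cov) * math.exp(eta[0]),
        vc=typical_central_volume(theta, cov) * math.exp(eta[1]),
        q=math.exp(theta.theta3 + eta[2]),
        vp=math.exp(theta.theta4 + eta[3]),
        eta=eta,
    )


# ---------------------------------------------------------------------------
# Two-compartment kinetics (closed form)
# ---------------------------------------------------------------------------


def micro_constants(ind: IndividualParameters) -> tuple[float, float, float]:
    """Micro rate constants (k10, k12, k21) in 1/day."""
    k10 = ind.cl / ind.vc
    k12 = ind.q / ind.vc
    k21 = ind.q / ind.vp
    return k10, k12, k21


def _macro_constants(cl, vc, q, vp):
    """Hybrid rate constants (alpha, beta) and bolus coefficients (A, B).

    Vectorised over numpy arrays.  ``alpha >= beta`` are the roots of
    lam^2 - (k10+k12+k21) lam + k10 k21 = 0; a bolus of amount D gives
    C(t) = (D/Vc) (A exp(-alpha t) + B exp(-beta t)) with A + B = 1.
    Degenerates gracefully to one compartment when Q = 0.
    """
    cl, vc, q, vp = np.broadcast_arrays(
        *(np.atleast_1d(np.asarray(x, dtype=float)) for x in (cl, vc, q, vp))
    )
    k10 = cl / vc
    k12 = q / vc
    k21 = q / vp
    s = k10 + k12 + k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
    alpha = (s + disc) / 2.0
    beta = (s - disc) / 2.0
    onecpt = q <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(onecpt, 1.0, (alpha - k21) / np.where(onecpt, 1.0, alpha - beta))
    b = 1.0 - a
    # Q=0 collapses to one compartment; park beta at a positive dummy rate
    # (its coefficient b is exactly 0) to keep downstream divisions finite.
    alpha = np.where(onecpt, k10, alpha)
    beta = np.where(onecpt, 1.0, beta)
    return alpha, beta, a, b


def _profile(cl, vc, q, vp, dose_t, dose_amt, dose_dur, t):
    """Central-compartment concentration, vectorised.

    Parameters are arrays broadcastable to shape (N,); ``dose_*`` have shape
    (N, D) (zero amounts are inert padding); ``t`` has shape (N, T) or (T,).
    Returns concentrations of shape (N, T).  Zero-duration doses are treated
    as very short infusions (1e-9 d), numerically identical to a bolus.
    """
    cl, vc, q, vp = np.atleast_1d(
        *(np.asarray(x, dtype=float) for x in (cl, vc, q, vp))
    )
    alpha, beta, a, b = _macro_constants(cl, vc, q, vp)
    dose_t = np.atleast_2d(np.asarray(dose_t, dtype=float))
    dose_amt = np.atleast_2d(np.asarray(dose_amt, dtype=float))
    dose_dur = np.maximum(np.atleast_2d(np.asarray(dose_dur, dtype=float)), 1e-9)
    t = np.asarray(t, dtype=float)
    if t.ndim == 1:
        t = np.broadcast_to(t, (len(cl), t.size))
    n, tt = t.shape

    conc = np.zeros((n, tt))
    al = alpha[:, None]
    be = beta[:, None]
    ca = (a / (alpha * vc))[:, None]
    cb = (b / (beta * vc))[:, None]
    for d in range(dose_t.shape[1]):
        dt = t - dose_t[:, d : d + 1]
        dur = dose_dur[:, d : d + 1]
        rate = dose_amt[:, d : d + 1] / dur
        te = np.clip(dt, 0.0, dur)  # elapsed infusion time
        post = np.maximum(dt - dur, 0.0)  # time since end of infusion
        contrib = rate * (
            ca * (-np.expm1(-al * te)) * np.exp(-al * post)
            + cb * (-np.expm1(-be * te)) * np.exp(-be * post)
        )
        conc += np.where(dt > 0, contrib, 0.0)
    return conc


def terminal_half_life(ind: IndividualParameters) -> float:
    """Terminal elimination half-life ln(2)/beta in days."""
    if ind.q <= 0:
        return math.log(2.0) * ind.vc / ind.cl
    _, beta, _, _ = _macro_constants(ind.cl, ind.vc, ind.q, ind.vp)
    return math.log(2.0) / float(beta[0])


def concentration(ind: IndividualParameters, doses, t):
    """Concentration (µg/mL) at time(s) ``t`` under a list of dose events.

    Superposition of closed-form single-dose solutions (the model is linear).
    Times before the first dose give 0.  ``t`` may be a scalar or array.
    """
    doses = sorted(doses, key=lambda d: d.time)
    if any(
        doses[i].time > doses[i + 1].time for i in range(len(doses) - 1)
    ):  # pragma: no cover - sorted above
        raise ValueError("doses must be sorted by time")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    if not doses:
        out = np.zeros_like(t_arr)
    else:
        out = _profile(
            ind.cl,
            ind.vc,
            ind.q,
            ind.vp,
            np.array([[d.time for d in doses]]),
            np.array([[d.amount for d in doses]]),
            np.array([[d.duration for d in doses]]),
            t_arr[None, :],
        )[0]
    return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out


def _steady_state_profile(ind: IndividualParameters, dose, tau, duration, t):
    """Concentration within one steady-state interval, t in [0, tau].

    Accumulation of the infusion solution as a geometric series of the
    exponential terms: every earlier dose contributes
    c_lam * exp(-lam (t - dur)) * exp(-lam m tau), summed over m >= 1.
    """
    alpha, beta, a, b = _macro_constants(ind.cl, ind.vc, ind.q, ind.vp)
    alpha, beta, a, b = (float(x[0]) for x in (alpha, beta, a, b))
    dur = max(duration, 1e-9)
    rate = dose / dur
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for lam, coef in ((alpha, a), (beta, b)):
        c_lam = rate * coef / (lam * ind.vc) * (-math.expm1(-lam * dur))
        acc = math.exp(-lam * tau) / (-math.expm1(-lam * tau))
        te = np.clip(t, 0.0, dur)
        post = np.maximum(t - dur, 0.0)
        current = rate * coef / (lam * ind.vc) * (-np.expm1(-lam * te)) * np.exp(-lam * post)
        out += current + c_lam * np.exp(-lam * (t - dur)) * acc
    return out


def steady_state_exposure(
    ind: IndividualParameters,
    dose: float,
    tau: float,
    infusion_duration: float = DEFAULT_INFUSION_DURATION,
    n_grid: int = 4001,
) -> ExposureMetrics:
    """Steady-state AUC, Cmax and Ctrough for repeated dosing every ``tau`` days.

    AUC_ss = dose/CL exactly (linear kinetics); Cmax and Ctrough come from
    the closed-form steady-state profile (Cmax by grid search over the
    interval, Ctrough at t = tau).
    """
    if dose <= 0 or tau <= 0:
        raise ValueError("dose and tau must be > 0")
    t_end_inf = min(max(infusion_duration, 1e-9), tau)
    t = np.unique(np.concatenate([np.linspace(0.0, tau, n_grid), [t_end_inf]]))
    prof = _steady_state_profile(ind, dose, tau, infusion_duration, t)
    return ExposureMetrics(
        auc_ss=dose / ind.cl,
        cmax_ss=float(prof.max()),
        ctrough_ss=float(prof[-1]),
    )
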