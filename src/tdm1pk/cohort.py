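"""Virtual patients and virtual trials.

The real T-DM1 development datasets (five phase I-III studies) are not
public; this module generates cohorts with the statistical structure the
analysis assumes: baseline covariates drawn from log-normal distributions
anchored at the published 5th/50th/95th percentiles, per-kg IV dosing
(3.6 mg/kg every 3 weeks by default), multiplicative log-normal
inter-individual variability, proportional residual error, and omission of
observations below the assay's minimum quantifiable concentration (MQC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import COVARIATE_COLUMNS, PKDataset
from .model import (
    DEFAULT_INFUSION_DURATION,
    CovariateVector,
    OmegaMatrix,
    SigmaModel,
    ThetaVector,
    individual_parameters,
)
from .model import _profile

__all__ = [
    "CovariateDistributionSpec",
    "TrialDesign",
    "PUBLISHED_ANCHORS",
    "fit_lognormal_from_percentiles",
    "sample_covariates",
    "simulate_trial",
    "apply_mqc_censoring",
]

_Z95 = stats.norm.ppf(0.95)  # 1.6449

#: Published 5th/50th/95th percentile anchors of the six baseline covariates
#: (median = the covariate model's reference value).  TBL is a mixture of a
#: point mass at 0 (trastuzumab-naive washout) and a log-normal tail whose
#: overall 95th percentile is 54 µg/mL.
PUBLISHED_ANCHORS: dict[str, tuple[float, float, float]] = {
    "weight": (49.0, 70.0, 98.0),
    "ecd": (8.5, 25.0, 332.0),
    "albu": (33.0, 41.0, 48.0),
    "tmbd": (1.5, 9.0, 30.3),
    "tbl": (0.0, 0.0, 54.0),
    "ast": (15.3, 27.0, 64.0),
}


def fit_lognormal_from_percentiles(p5: float, p50: float, p95: float):
    """Log-normal (log-mean, log-SD) matching three percentile anchors.

    The log-mean is ln(p50); the log-SD averages the two one-sided fits
    ln(p95/p50)/z95 and ln(p50/p5)/z95, so a mildly asymmetric triple is
    split down the middle.
    """
    if not (0 < p5 < p50 < p95):
        raise ValueError("require 0 < p5 < p50 < p95")
    sd = 0.5 * (math.log(p95 / p50) + math.log(p50 / p5)) / _Z95
    return math.log(p50), sd


@dataclass(frozen=True)
class CovariateDistributionSpec:
    """Sampling distributions for the six baseline covariates.

    ``anchors`` maps covariate name -> (p5, p50, p95).  TBL is drawn from a
    mixture: with probability ``tbl_zero_prob`` it is exactly 0, otherwise
    log-normal with median ``tbl_median`` and a log-SD set so that the
    overall 95th percentile hits the TBL anchor.
    """

    anchors: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(PUBLISHED_ANCHORS)
    )
    tbl_zero_prob: float = 0.3
    tbl_median: float = 10.0
    #: optional log-scale correlations between the log-normal covariates,
    #: e.g. {("weight", "albu"): 0.3}; default independent (no published
    #: correlation structure to emulate)
    correlations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.tbl_zero_prob <= 1.0:
            raise ValueError("tbl_zero_prob must be in [0, 1]")
        for name, (p5, p50, p95) in self.anchors.items():
            if name == "tbl":
                continue
            if not (p5 < p50 < p95):
                raise ValueError(f"anchors for {name} must satisfy p5 < p50 < p95")
        for (a, b), rho in self.correlations.items():
            if a == "tbl" or b == "tbl":
                raise ValueError("the TBL mixture does not take correlations")
            if not -1.0 < rho < 1.0:
                raise ValueError("correlations must be in (-1, 1)")

    def _corr_matrix(self, names) -> np.ndarray:
        m = np.eye(len(names))
        idx = {n: i for i, n in enumerate(names)}
        for (a, b), rho in self.correlations.items():
            m[idx[a], idx[b]] = m[idx[b], idx[a]] = rho
        if np.linalg.eigvalsh(m).min() < -1e-10:
            raise ValueError("correlation matrix is not positive semi-definite")
        return m

    def _tbl_log_params(self):
        """Log-normal parameters of the nonzero TBL component."""
        p95 = self.anchors["tbl"][2]
        # overall P(TBL <= q95) = 0.95  =>  nonzero-component quantile level
        level = (0.95 - self.tbl_zero_prob) / (1.0 - self.tbl_zero_prob)
        z = stats.norm.ppf(level)
        return math.log(self.tbl_median), math.log(p95 / self.tbl_median) / z


def sample_covariates(
    spec: CovariateDistributionSpec, n: int, seed
) -> list[CovariateVector]:
    """Draw ``n`` independent covariate vectors, reproducibly under ``seed``.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    names = ("weight", "ecd", "albu", "tmbd", "ast")
    params = [fit_lognormal_from_percentiles(*spec.anchors[nm]) for nm in names]
    if spec.correlations:
        # Gaussian copula on the log scale
        z = rng.multivariate_normal(
            np.zeros(len(names)), spec._corr_matrix(names), size=n
        )
        draws = {
            nm: np.exp(mu + sd * z[:, k])
            for k, (nm, (mu, sd)) in enumerate(zip(names, params))
        }
    else:
        draws = {
            nm: np.exp(rng.normal(mu, sd, size=n))
            for nm, (mu, sd) in zip(names, params)
        }
    if spec.tbl_zero_prob >= 1.0:
        tbl = np.zeros(n)
    else:
        mu, sd = spec._tbl_log_params()
        tbl = np.exp(rng.normal(mu, sd, size=n))
        tbl[rng.random(n) < spec.tbl_zero_prob] = 0.0
    draws["tbl"] = tbl
    return [
        CovariateVector(
            weight=draws["weight"][i],
            ecd=draws["ecd"][i],
            albu=draws["albu"][i],
            tmbd=draws["tmbd"][i],
            tbl=draws["tbl"][i],
            ast=draws["ast"][i],
        )
        for i in range(n)
    ]


#: Rich within-cycle sampling offsets (days): pre-dose, end of infusion,
#: then 0.25-14 d post dose.  Used in the first and last cycle of the rich
#: design; intermediate cycles contribute the pre-dose trough only.
RICH_CYCLE_OFFSETS = (0.0, DEFAULT_INFUSION_DURATION, 0.25, 1.0, 3.0, 7.0, 14.0)
SPARSE_CYCLE_OFFSETS = (0.0, DEFAULT_INFUSION_DURATION)


@dataclass(frozen=True)
class TrialDesign:
    """A virtual trial: cohort size, regimen, sampling schedule, assay MQC.

    ``sampling`` chooses between a phase-I-like rich design (full profiles in
    the first and last cycles, troughs in between, washout samples after the
    last cycle) and a phase-III-like sparse design (end of infusion + trough
    each cycle).  ``per_kg`` switches between weight-based and flat dosing.
    """

    n_subjects: int = 300
    regimen: str = "q3w"
    dose_mg_per_kg: float = 3.6
    n_cycles: int = 8
    sampling: str = "rich"
    infusion_duration: float = DEFAULT_INFUSION_DURATION
    mqc: float = 0.04
    per_kg: bool = True
    flat_dose_mg: float = 252.0  # used when per_kg=False
    washout_offsets: tuple = (28.0, 42.0)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.regimen not in ("q3w", "qw"):
            raise ValueError("regimen must be 'q3w' or 'qw'")
        if not 0.0 < self.mqc <= 0.06:
            raise ValueError("mqc must be in (0, 0.06] µg/mL")
        if self.sampling not in ("rich", "sparse"):
            raise ValueError("sampling must be 'rich' or 'sparse'")

    @property
    def cycle_length(self) -> float:
        return 21.0 if self.regimen == "q3w" else 7.0

    @property
    def dose_times(self) -> np.ndarray:
        return np.arange(self.n_cycles) * self.cycle_length

    @property
    def observation_times(self) -> np.ndarray:
        """Nominal sampling times (days since first dose), sorted, unique."""
        tau = self.cycle_length
        times: list[float] = []
        if self.sampling == "rich":
            rich_cycles = {0, self.n_cycles - 1}
            for c in range(self.n_cycles):
                offsets = RICH_CYCLE_OFFSETS if c in rich_cycles else (0.0,)
                times.extend(c * tau + o for o in offsets if o < tau)
        else:
            for c in range(self.n_cycles):
                times.extend(c * tau + o for o in SPARSE_CYCLE_OFFSETS if o < tau)
        end = (self.n_cycles - 1) * tau
        times.append(end + tau)  # final trough
        times.extend(end + o for o in self.washout_offsets if o > tau)
        return np.unique(np.asarray(times, dtype=float))


def simulate_trial(
    design: TrialDesign,
    theta: ThetaVector,
    omega: OmegaMatrix,
    sigma: SigmaModel,
    spec: CovariateDistributionSpec | None = None,
    seed=0,
) -> PKDataset:
    """Simulate one virtual trial and return an (uncensored) NONMEM-style dataset.

    Per subject: covariates from ``spec``, eta ~ MVN(0, Omega), dose =
    dose_mg_per_kg x weight at each cycle start (flat dosing optional),
    observations DV = C(t) x (1 + eps) with eps ~ N(0, sigma_prop^2),
    truncated below at 1e-6 µg/mL.  Fully reproducible given ``seed``.
    Apply :func:`apply_mqc_censoring` afterwards to emulate assay dropout.
    """
    spec = spec or CovariateDistributionSpec()
    rng = np.random.default_rng(seed)
    n = design.n_subjects
    covs = sample_covariates(spec, n, rng)
    etas = rng.multivariate_normal(np.zeros(4), omega.matrix, size=n)

    obs_t = design.observation_times
    dose_t = design.dose_times
    weights = np.array([c.weight for c in covs])
    amounts = (
        design.dose_mg_per_kg * weights[:, None]
        if design.per_kg
        else np.full((n, dose_t.size), design.flat_dose_mg)
    )
    if amounts.ndim == 1:  # pragma: no cover
        amounts = np.broadcast_to(amounts[:, None], (n, dose_t.size))
    amounts = np.broadcast_to(amounts, (n, dose_t.size))
    durations = np.full((n, dose_t.size), design.infusion_duration)

    inds = [individual_parameters(theta, covs[i], etas[i]) for i in range(n)]
    cl = np.array([p.cl for p in inds])
    vc = np.array([p.vc for p in inds])
    q = np.array([p.q for p in inds])
    vp = np.array([p.vp for p in inds])
    ipred = _profile(
        cl, vc, q, vp, np.broadcast_to(dose_t, (n, dose_t.size)), amounts, durations, obs_t
    )
    eps = rng.normal(0.0, sigma.prop_cv, size=ipred.shape)
    dv = np.maximum(ipred * (1.0 + eps), 1e-6)

    rows = []
    for i in range(n):
        sid = i + 1
        cov = covs[i].to_dict()
        for d in range(dose_t.size):
            rows.append(
                dict(
                    ID=sid,
                    TIME=dose_t[d],
                    EVID=1,
                    AMT=amounts[i, d],
                    RATE=amounts[i, d] / durations[i, d],
                    DV=np.nan,
                    MDV=1,
                    **cov,
                )
            )
        for j, t in enumerate(obs_t):
            rows.append(
                dict(
                    ID=sid,
                    TIME=t,
                    EVID=0,
                    AMT=np.nan,
                    RATE=np.nan,
                    DV=dv[i, j],
                    MDV=0,
                    **cov,
                )
            )
    df = pd.DataFrame(rows)
    df = df.rename(columns={k: v for k, v in zip(
        ["weight", "ecd", "albu", "tmbd", "tbl", "ast"], COVARIATE_COLUMNS)})
    df = df.sort_values(["ID", "TIME", "EVID"], kind="stable").reset_index(drop=True)
    ds = PKDataset(df)
    ds.etas = etas  # true etas, kept for recovery experiments
    return ds


def apply_mqc_censoring(data: PKDataset, mqc: float) -> tuple[PKDataset, float]:
    """Drop observation records with DV below the MQC.

    Mirrors the assay-handling rule: below-MQC observations are omitted, not
    flagged and kept.  Dose records are untouched.  Returns the censored
    dataset and the fraction of observation records removed.
    """
    if mqc < 0:
        raise ValueError("mqc must be >= 0")
    df = data.df
    is_obs = df["EVID"] == 0
    below = is_obs & (df["DV"] < mqc)
    frac = float(below.sum() / max(int(is_obs.sum()), 1))
    out = PKDataset(df.loc[~below].reset_index(drop=True), validate=False)
    if hasattr(data, "etas"):
        out.etas = data.etas
    return out, frac
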