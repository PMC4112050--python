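import numpy as np
import pandas as pd
import pytest

import matplotlib

matplotlib.use("Agg")

from tdm1pk import (
    PUBLISHED_OMEGA,
    PUBLISHED_SIGMA,
    PUBLISHED_THETA,
    OmegaMatrix,
    PKDataset,
    SigmaModel,
    ThetaVector,
    TrialDesign,
    apply_mqc_censoring,
    simulate_trial,
)

REFERENCE_ROW = dict(WT=70.0, ECD=25.0, ALBU=41.0, TMBD=9.0, TBL=0.0, AST=27.0)


def single_subject_dataset(obs, dose_mg=252.0, duration=0.0208, cov=None):
    """One subject, one dose at t=0, observations [(time, dv), ...]."""
    cov = cov or REFERENCE_ROW
    rows = [
        dict(ID=1, TIME=0.0, EVID=1, AMT=dose_mg, RATE=dose_mg / duration,
             DV=np.nan, MDV=1, **cov)
    ]
    for t, dv in obs:
        rows.append(
            dict(ID=1, TIME=t, EVID=0, AMT=np.nan, RATE=np.nan, DV=dv,
                 MDV=0, **cov)
        )
    return PKDataset(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def published():
    return PUBLISHED_THETA, PUBLISHED_OMEGA, PUBLISHED_SIGMA


@pytest.fixture(scope="session")
def small_trial():
    """A 40-subject rich q3w trial simulated from the published model."""
    design = TrialDesign(n_subjects=40)
    ds = simulate_trial(
        design, PUBLISHED_THETA, PUBLISHED_OMEGA, PUBLISHED_SIGMA, seed=42
    )
    censored, frac = apply_mqc_censoring(ds, design.mqc)
    return censored


@pytest.fixture(scope="session")
def quiet_model():
    """Low-variability variant used for fast noise-sensitive checks."""
    theta = ThetaVector(
        theta1=PUBLISHED_THETA.theta1, theta2=PUBLISHED_THETA.theta2,
        theta3=PUBLISHED_THETA.theta3, theta4=PUBLISHED_THETA.theta4,
        theta5=0.596, theta6=0.49,
    )
    omega = OmegaMatrix(0.1, 0.1, 0.2, 0.2, 0.0)
    sigma = SigmaModel(0.1)
    return theta, omega, sigma
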