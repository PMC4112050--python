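"""Longitudinal PK event dataset (NONMEM column conventions).

A :class:`PKDataset` wraps a pandas DataFrame with one row per event:
dose rows (EVID=1, AMT mg, RATE mg/day) and observation rows (EVID=0,
DV µg/mL, MDV=0).  Baseline covariates are carried on every row of a
subject (WT kg, ECD ng/mL, ALBU g/L, TMBD cm, TBL µg/mL, AST IU/L).
TIME is days since the subject's first dose.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import CovariateVector

__all__ = ["PKDataset", "COVARIATE_COLUMNS", "MANDATORY_COLUMNS"]

COVARIATE_COLUMNS = ["WT", "ECD", "ALBU", "TMBD", "TBL", "AST"]
MANDATORY_COLUMNS = ["ID", "TIME", "EVID", "AMT", "DV", "MDV"]
_COV_FIELDS = dict(zip(COVARIATE_COLUMNS, ["weight", "ecd", "albu", "tmbd", "tbl", "ast"]))


class PKDataset:
    """Event records for a cohort, with per-subject baseline covariates."""

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset is missing mandatory column(s): {missing}")
        if "RATE" not in df.columns and "DUR" not in df.columns:
            raise ValueError("dataset is missing mandatory column(s): ['RATE' or 'DUR']")
        self.df = df.reset_index(drop=True)
        if validate:
            self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        df = self.df
        for sid, g in df.groupby("ID", sort=False):
            t = g["TIME"].to_numpy(dtype=float)
            if np.any(np.diff(t) < 0):
                raise ValueError(f"subject {sid}: TIME must be non-decreasing")
            doses = g[g["EVID"] == 1]
            if len(doses) == 0:
                raise ValueError(f"subject {sid}: no dose events")
            t0 = doses["TIME"].min()
            obs = g[g["EVID"] == 0]
            if len(obs) and obs["TIME"].min() < t0:
                raise ValueError(f"subject {sid}: observation before first dose")

    # -- accessors ----------------------------------------------------------
    @property
    def subject_ids(self) -> np.ndarray:
        return self.df["ID"].unique()

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_observations(self) -> int:
        return int((self.df["EVID"] == 0).sum())

    def observations(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 0]

    def doses(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 1]

    def subject(self, sid) -> pd.DataFrame:
        return self.df[self.df["ID"] == sid]

    def covariates(self) -> pd.DataFrame:
        """One row per subject with the six baseline covariates."""
        cols = [c for c in COVARIATE_COLUMNS if c in self.df.columns]
        return self.df.groupby("ID", sort=False)[cols].first()

    def covariate_vector(self, sid) -> CovariateVector:
        row = self.covariates().loc[sid]
        return CovariateVector(**{_COV_FIELDS[c]: float(row[c]) for c in COVARIATE_COLUMNS})

    def dose_durations(self) -> pd.Series:
        """Infusion duration in days for each dose row (0 = bolus)."""
        doses = self.doses()
        if "DUR" in doses.columns:
            return doses["DUR"].fillna(0.0)
        rate = doses["RATE"].to_numpy(dtype=float)
        amt = doses["AMT"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            dur = np.where(rate > 0, amt / np.where(rate > 0, rate, 1.0), 0.0)
        return pd.Series(dur, index=doses.index)

    def drop_subjects(self, ids) -> "PKDataset":
        out = PKDataset(self.df[~self.df["ID"].isin(ids)].reset_index(drop=True),
                        validate=False)
        return out

    def copy(self) -> "PKDataset":
        return PKDataset(self.df.copy(), validate=False)

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return (
            f"PKDataset({self.n_subjects} subjects, {self.n_observations} "
            f"observations, {len(self.doses())} doses)"
        )
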