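"""File I/O and pipeline orchestration.

Datasets travel as NONMEM-convention CSV (columns ID, TIME, AMT, RATE, DV,
EVID, MDV plus the covariate columns WT, ECD, ALBU, TMBD, TBL, AST; "." for
empty numeric fields; TIME in days since each subject's first dose).
Model parameters are flat key->value YAML: theta1..theta11, omega_cl,
omega_vc, omega_q, omega_vp, omega_cl_vc, sigma_prop.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import COVARIATE_COLUMNS, MANDATORY_COLUMNS, PKDataset
from .model import (
    PUBLISHED_OMEGA,
    PUBLISHED_SIGMA,
    PUBLISHED_THETA,
    OmegaMatrix,
    SigmaModel,
    ThetaVector,
)

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_model_config",
    "write_model_config",
    "published_model",
    "DEFAULT_MODEL_FILE",
    "RunConfig",
    "run_pipeline",
]

#: Shipped YAML with the published final-model parameters.
DEFAULT_MODEL_FILE = Path(__file__).with_name("final_model.yaml")

_NUMERIC = MANDATORY_COLUMNS[1:] + ["RATE", "DUR"] + COVARIATE_COLUMNS


def read_dataset(path) -> PKDataset:
    """Read a NONMEM-convention CSV; validates structure and reports counts.

    Missing numeric fields may be encoded as "." (flagged via MDV for DV).
    Raises a named error for a missing mandatory column, a subject without
    dose events, or non-monotone TIME within a subject.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset is missing mandatory column(s): {missing}")
    for col in df.columns:
        if col == "ID":
            ids = pd.to_numeric(df[col], errors="coerce")
            if not ids.isna().any():  # numeric subject ids; keep strings otherwise
                df[col] = ids.astype(np.int64) if (ids % 1 == 0).all() else ids
            continue
        conv = pd.to_numeric(df[col].replace(".", np.nan), errors="coerce")
        # leave genuinely non-numeric extras (e.g. group labels) untouched
        lost = conv.isna() & df[col].notna() & (df[col] != ".")
        if lost.any() and col not in _NUMERIC:
            continue
        df[col] = conv
    # "." in DV means missing: flag MDV=1
    df["MDV"] = df["MDV"].fillna(1).astype(int)
    df.loc[df["DV"].isna() & (df["EVID"] == 0), "MDV"] = 1
    df["EVID"] = df["EVID"].astype(int)
    ds = PKDataset(df)
    return ds


def write_dataset(data: PKDataset, path) -> None:
    """Write the dataset as CSV with "." for empty numeric fields."""
    df = data.df.copy()
    out = df.astype(object).where(pd.notna(df), ".")
    out.to_csv(path, index=False)


def published_model() -> tuple[ThetaVector, OmegaMatrix, SigmaModel]:
    """The shipped final-model parameter set."""
    return PUBLISHED_THETA, PUBLISHED_OMEGA, PUBLISHED_SIGMA


def write_model_config(
    path, theta: ThetaVector, omega: OmegaMatrix, sigma: SigmaModel
) -> None:
    """Serialise model parameters as a flat YAML mapping."""
    flat: dict[str, float] = {}
    flat.update({k: float(v) for k, v in theta.to_dict().items()})
    flat.update({k: float(v) for k, v in omega.to_dict().items()})
    flat["sigma_prop"] = float(sigma.prop_cv)
    Path(path).write_text(yaml.safe_dump(flat, sort_keys=False))


def read_model_config(path) -> tuple[ThetaVector, OmegaMatrix, SigmaModel]:
    """Read a flat YAML/JSON model file written by :func:`write_model_config`."""
    flat = yaml.safe_load(Path(path).read_text())
    theta = ThetaVector.from_dict(flat)
    omega = OmegaMatrix(
        omega_cl=float(flat["omega_cl"]),
        omega_vc=float(flat["omega_vc"]),
        omega_q=float(flat["omega_q"]),
        omega_vp=float(flat["omega_vp"]),
        omega_cl_vc=float(flat.get("omega_cl_vc", 0.0)),
    )
    sigma = SigmaModel(prop_cv=float(flat["sigma_prop"]))
    return theta, omega, sigma


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {
    "seed", "out_dir", "model_file", "dataset",
    "n_subjects", "regimen", "dose_mg_per_kg", "n_cycles", "sampling", "mqc",
    "stages", "vpc_replicates", "npc_replicates", "bootstrap_replicates",
    "fit_maxiter",
}


class RunConfig:
    """Validated configuration for :func:`run_pipeline`.

    One global ``seed`` spawns deterministic per-stage child seeds so stages
    can be rerun independently; unknown keys are rejected.
    """

    def __init__(self, **kwargs):
        unknown = set(kwargs) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        self.seed = int(kwargs.get("seed", 0))
        self.out_dir = Path(kwargs.get("out_dir", "tdm1pk_run"))
        self.model_file = kwargs.get("model_file")
        self.dataset = kwargs.get("dataset")
        self.n_subjects = int(kwargs.get("n_subjects", 100))
        self.regimen = kwargs.get("regimen", "q3w")
        self.dose_mg_per_kg = float(kwargs.get("dose_mg_per_kg", 3.6))
        self.n_cycles = int(kwargs.get("n_cycles", 8))
        self.sampling = kwargs.get("sampling", "rich")
        self.mqc = float(kwargs.get("mqc", 0.04))
        self.stages = tuple(kwargs.get("stages", ("simulate", "fit", "diagnose")))
        self.vpc_replicates = int(kwargs.get("vpc_replicates", 200))
        self.npc_replicates = int(kwargs.get("npc_replicates", 200))
        self.bootstrap_replicates = int(kwargs.get("bootstrap_replicates", 0))
        self.fit_maxiter = int(kwargs.get("fit_maxiter", 300))

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def stage_seed(self, stage: str) -> int:
        """Deterministic child seed for a named stage (below 2**31)."""
        order = ("simulate", "fit", "diagnose", "bootstrap")
        k = order.index(stage) if stage in order else len(order)
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(k,))
        return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; every artifact lands in ``out_dir``.

    Returns a manifest mapping stage names to the files written.  Identical
    configs produce byte-identical numeric outputs.
    """
    from . import diagnostics as diag
    from .cohort import CovariateDistributionSpec, TrialDesign, apply_mqc_censoring, simulate_trial
    from .estimation import fit_population

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, list[str]] = {}
    log_lines: list[str] = []

    if config.model_file:
        theta, omega, sigma = read_model_config(config.model_file)
    else:
        theta, omega, sigma = published_model()

    data = None
    if config.dataset:
        data = read_dataset(config.dataset)

    def _log(stage, msg):
        log_lines.append(f"[{stage}] {msg}")

    try:
        if "simulate" in config.stages:
            seed = config.stage_seed("simulate")
            design = TrialDesign(
                n_subjects=config.n_subjects, regimen=config.regimen,
                dose_mg_per_kg=config.dose_mg_per_kg, n_cycles=config.n_cycles,
                sampling=config.sampling, mqc=config.mqc,
            )
            raw = simulate_trial(design, theta, omega, sigma,
                                 CovariateDistributionSpec(), seed=seed)
            data, frac = apply_mqc_censoring(raw, config.mqc)
            path = out / "simulated_dataset.csv"
            write_dataset(data, path)
            manifest["simulate"] = [str(path)]
            _log("simulate", f"seed={seed} n={config.n_subjects} "
                             f"bql_fraction={frac:.4f} -> {path}")

        fit = None
        if "fit" in config.stages:
            if data is None:
                raise RuntimeError("fit stage needs a dataset (simulate or file)")
            fit = fit_population(data, maxiter=config.fit_maxiter)
            path = out / "fit_model.yaml"
            write_model_config(path, fit.theta, fit.omega, fit.sigma)
            epath = out / "fit_etas.csv"
            fit.etas.to_csv(epath)
            manifest["fit"] = [str(path), str(epath)]
            _log("fit", f"ofv={fit.ofv:.3f} converged={fit.converged} -> {path}")

        if "diagnose" in config.stages:
            if data is None:
                raise RuntimeError("diagnose stage needs a dataset")
            th, om, sg = (fit.theta, fit.omega, fit.sigma) if fit else (theta, omega, sigma)
            seed = config.stage_seed("diagnose")
            vpc = diag.visual_predictive_check(
                th, om, sg, data, n_replicates=config.vpc_replicates,
                seed=seed, mqc=config.mqc,
            )
            vpath = out / "vpc.csv"
            vpc.table.to_csv(vpath, index=False)
            npc = diag.numerical_predictive_check(
                th, om, sg, data, n_replicates=config.npc_replicates,
                seed=seed + 1, mqc=config.mqc,
            )
            npath = out / "npc.csv"
            npc.to_csv(npath, index=False)
            files = [str(vpath), str(npath)]
            if fit is not None:
                shr = diag.shrinkage(fit, data)
                spath = out / "shrinkage.json"
                spath.write_text(json.dumps(shr, indent=2))
                files.append(str(spath))
            manifest["diagnose"] = files
            _log("diagnose", f"seed={seed} -> {', '.join(files)}")

        if "bootstrap" in config.stages and config.bootstrap_replicates:
            if data is None:
                raise RuntimeError("bootstrap stage needs a dataset")
            seed = config.stage_seed("bootstrap")
            table = diag.bootstrap(
                data, n_boot=config.bootstrap_replicates, seed=seed,
                init_from_fit=fit,
            )
            bpath = out / "bootstrap.csv"
            table.to_csv(bpath)
            manifest["bootstrap"] = [str(bpath)]
            _log("bootstrap", f"seed={seed} n_boot={config.bootstrap_replicates}")
    except Exception as exc:
        (out / "pipeline.log").write_text("\n".join(log_lines) + f"\nFAILED: {exc}\n")
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    (out / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    manifest["log"] = [str(out / "pipeline.log")]
    return manifest
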