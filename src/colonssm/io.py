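"""Readers, writers, packaged fixtures and run configuration.

Formats: incidence tables as CSV with header ``age_lo,age_hi,n,y`` (an
optional ``predicted`` column is carried through); model parameters and
prior boxes as flat YAML key-value files with all rates per model time
unit and ``dt_months`` recorded alongside; fit reports as JSON plus a
human-readable text table.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .fit import THETA_NAMES, FitResult, GibbsConfig, PriorSpec
from .incidence import IncidenceTable
from .model import ModelParameters

__all__ = [
    "RunConfig",
    "read_incidence_table",
    "write_incidence_table",
    "load_seer_table",
    "params_to_yaml",
    "params_from_yaml",
    "prior_to_yaml",
    "prior_from_yaml",
    "write_fit_report",
    "read_fit_report",
]

_FIXTURE = "seer_colon.csv"


@dataclasses.dataclass
class RunConfig:
    """Plumbing configuration for a command-line run."""

    params_path: Optional[str] = None
    prior_path: Optional[str] = None
    dt_months: float = 3.0
    n_stem_cells: float = 1.0e8
    K: int = 100
    n_iter: int = 80
    burn_in: int = 30
    chains: int = 2
    seed: int = 0
    n_scale: float = 1.0
    out: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def gibbs_config(self) -> GibbsConfig:
        return GibbsConfig(K=self.K, n_iter=self.n_iter, burn_in=self.burn_in,
                           chains=self.chains, n_scale=self.n_scale)


# ---- incidence tables --------------------------------------------------------


def read_incidence_table(path) -> IncidenceTable:
    """Read and validate an age-grouped incidence CSV."""
    df = pd.read_csv(path)
    try:
        return IncidenceTable.from_frame(df)
    except ValueError as err:
        raise ValueError(f"invalid incidence table {path}: {err}") from err


def write_incidence_table(table: IncidenceTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def load_seer_table() -> IncidenceTable:
    """The packaged SEER colon-cancer incidence table (18 age groups, with
    the published model predictions in the ``predicted`` column)."""
    with resources.files("colonssm.data").joinpath(_FIXTURE).open() as fh:
        return IncidenceTable.from_frame(pd.read_csv(fh))


# ---- parameters and priors ---------------------------------------------------


def params_to_yaml(params: ModelParameters, path) -> None:
    """Flat key-value serialization of a full parameter set."""
    flat = {
        "k1": params.k1, "k2": params.k2,
        "lambda_I": float(params.lambda_I), "lambda_J": float(params.lambda_J),
        "dt_months": float(params.dt_months),
        "p_detect_lag": float(params.p_detect_lag),
        "delta1": float(params.delta1), "delta2": float(params.delta2),
    }
    for l in range(params.k1 - 1):
        flat[f"alpha{l + 1}"] = float(params.alpha[l])
        flat[f"b_I{l + 1}"] = float(params.b_I[l])
        flat[f"d_I{l + 1}"] = float(params.d_I[l])
    for r in range(params.k2 - 1):
        flat[f"beta{r + 1}"] = float(params.beta[r])
        flat[f"b_J{r + 1}"] = float(params.b_J[r])
        flat[f"d_J{r + 1}"] = float(params.d_J[r])
    with open(path, "w") as fh:
        yaml.safe_dump(flat, fh, sort_keys=True)


def params_from_yaml(path) -> ModelParameters:
    with open(path) as fh:
        flat = yaml.safe_load(fh)
    k1 = int(flat.get("k1", 4))
    k2 = int(flat.get("k2", 5))
    return ModelParameters(
        lambda_I=flat["lambda_I"], lambda_J=flat["lambda_J"],
        alpha=np.array([flat[f"alpha{l + 1}"] for l in range(k1 - 1)]),
        beta=np.array([flat[f"beta{r + 1}"] for r in range(k2 - 1)]),
        b_I=np.array([flat[f"b_I{l + 1}"] for l in range(k1 - 1)]),
        d_I=np.array([flat[f"d_I{l + 1}"] for l in range(k1 - 1)]),
        b_J=np.array([flat[f"b_J{r + 1}"] for r in range(k2 - 1)]),
        d_J=np.array([flat[f"d_J{r + 1}"] for r in range(k2 - 1)]),
        delta1=flat.get("delta1", 0.0), delta2=flat.get("delta2", 0.0),
        k1=k1, k2=k2,
        dt_months=flat.get("dt_months", 3.0),
        p_detect_lag=flat.get("p_detect_lag", 1.0),
    )


def prior_to_yaml(prior: PriorSpec, path) -> None:
    data = {name: [float(lo), float(hi)] for name, (lo, hi) in prior.bounds.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def prior_from_yaml(path) -> PriorSpec:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return PriorSpec(bounds={name: (float(lo), float(hi))
                             for name, (lo, hi) in data.items()})


# ---- fit reports -------------------------------------------------------------


def _fit_summary_dict(fit: FitResult) -> dict:
    return {
        "estimates": {name: float(fit.summary.loc[name, "mean"])
                      for name in THETA_NAMES},
        "sds": {name: (None if not np.isfinite(fit.summary.loc[name, "sd"])
                       else float(fit.summary.loc[name, "sd"]))
                for name in THETA_NAMES},
        "dev": float(fit.dev),
        "aic": float(fit.aic),
        "bic": float(fit.bic),
        "p": int(fit.p),
        "n_points": int(fit.n_points),
        "loglik": float(fit.loglik),
        "predicted": [float(v) for v in fit.tau],
        "converged": bool(fit.converged),
        "seed": int(fit.seed),
        "chains": int(fit.config.chains),
        "n_iter": int(fit.config.n_iter),
        "burn_in": int(fit.config.burn_in),
        "K": int(fit.config.K),
        "n_scale": float(fit.config.n_scale),
        "ess_mean": (float(np.mean(fit.ess)) if len(fit.ess) else None),
        "rhat": (None if fit.rhat is None
                 else {k: (float(v) if np.isfinite(v) else None)
                       for k, v in fit.rhat.items()}),
    }


def write_fit_report(fit: FitResult, path) -> dict:
    """Write a machine-readable JSON report (and, alongside it, a plain-text
    table and the draws as CSV).  Returns the JSON payload."""
    path = Path(path)
    payload = _fit_summary_dict(fit)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
    txt_lines = [
        "Two-pathway colon carcinogenesis model fit",
        "=" * 44,
    ]
    if not fit.converged:
        txt_lines.append("WARNING: fit flagged NON-CONVERGED")
    txt_lines.append(
        f"Deviance {fit.dev:.4f}   AIC {fit.aic:.4f}   BIC {fit.bic:.4f}"
        f"   (p = {fit.p}, n = {fit.n_points})")
    txt_lines.append("")
    txt_lines.append(f"{'parameter':<12} {'mean':>12} {'sd':>12}")
    for name in THETA_NAMES:
        txt_lines.append(f"{name:<12} {fit.summary.loc[name, 'mean']:>12.4g} "
                         f"{fit.summary.loc[name, 'sd']:>12.3g}")
    txt_lines.append("")
    txt_lines.append(f"{'predicted cases':>16}: " +
                     " ".join(f"{v:.0f}" for v in fit.tau))
    path.with_suffix(".txt").write_text("\n".join(txt_lines) + "\n")
    fit.draws.to_csv(path.with_suffix(".draws.csv"), index=False)
    return payload


def read_fit_report(path) -> dict:
    """Reload the JSON fit report written by :func:`write_fit_report`."""
    with open(path) as fh:
        return json.load(fh)
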