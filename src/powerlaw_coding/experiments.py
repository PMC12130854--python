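"""Config-driven experiment pipelines.

Each pipeline is a thin composition of library operations — nothing is
computed here that the modules cannot compute directly — and writes CSV
result tables plus a JSON metadata sidecar (full config, seed, package
version, timings).  Rerunning with an identical config reproduces identical
CSV content.

Experiments
-----------
scatter
    Susceptibility-variance identity: per-exponent scatter fits recovering
    sigma0^2 and sigma1^2, with the Rayleigh-quotient eigencheck.
fisher_curves
    Closed-form Fisher information over an exponent grid for several input
    dimensions.
ablation
    Decoding accuracy while removing encoder modes from the low- or
    high-frequency end, against the restricted-code theory.
energy_tradeoff
    Energy-aware objective over the exponent grid; the per-dimension argmax
    sits at the critical exponent.
noise_sweep
    Decoding accuracy as the neural-noise strength grows, against the
    small-noise theory.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field
from importlib import metadata as importlib_metadata
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fisher, response_stats
from .code import CodeSpec, NeuronSubset, sample_responses, susceptibility
from .decoder import decoding_experiment
from .exceptions import ConfigError

__all__ = ["ExperimentConfig", "validate_config", "run_experiment", "load_config"]

SCHEMA_VERSION = 1

_INF_NAMES = {"inf", "infinity", "Inf", "Infinity"}


def _parse_dim(value):
    if isinstance(value, str):
        if value in _INF_NAMES:
            return math.inf
        raise ConfigError(f"invalid input dimension {value!r}")
    if isinstance(value, float) and math.isinf(value):
        return math.inf
    if int(value) != value or value < 1:
        raise ConfigError(f"invalid input dimension {value!r}")
    return int(value)


# defaults follow the study conditions: sigma0 = sigma1 = 0.01, N = 100 for
# the covariance scatter, N = 50 / M = 10 for decoding, gamma = 1e-3, and
# the exponent grid [1.05, 6] with step 0.01 (avoiding the zeta pole).
SCHEMAS: dict[str, dict] = {
    "scatter": {
        "required": ["seed"],
        "defaults": {
            "N": 100,
            "alphas": [2.0, 3.0, 4.0],
            "sigma0": 0.01,
            "sigma1": 0.01,
            "n_samples": 10_000,
        },
    },
    "fisher_curves": {
        "required": [],
        "defaults": {
            "D": [1, 2, 5, "inf"],
            "alpha_min": 1.05,
            "alpha_max": 6.0,
            "alpha_step": 0.01,
            "sigma0": 0.01,
            "sigma_i": 0.01,
            "N": None,
        },
    },
    "ablation": {
        "required": ["seed"],
        "defaults": {
            "N": 50,
            "alpha": 3.0,
            "sigma0": 0.01,
            "sigma1": 0.01,
            "M": 10,
            "n_trials": 500,
            "removal_fractions": [0.25, 0.5, 0.75],
            "orders": ["descending", "ascending"],
        },
    },
    "energy_tradeoff": {
        "required": [],
        "defaults": {
            "D": [1, 2, 5, "inf"],
            "alpha_min": 1.05,
            "alpha_max": 6.0,
            "alpha_step": 0.01,
            "sigma0": 0.01,
            "sigma_i": 0.01,
            "gamma": 1e-3,
        },
    },
    "noise_sweep": {
        "required": ["seed"],
        "defaults": {
            "N": 50,
            "alpha": 4.0,
            "sigma0_values": [0.005, 0.01, 0.02, 0.05, 0.1],
            "sigma1": 0.01,
            "M": 10,
            "n_trials": 300,
        },
    },
}

# paper-scale trial counts restored by the --full flag
FULL_SCALE = {"n_trials": 100_000, "n_samples": 100_000}


@dataclass
class ExperimentConfig:
    experiment: str
    parameters: dict
    output_dir: Path
    full_scale: bool = False

    def to_dict(self) -> dict:
        params = {
            k: (None if v is None else ("inf" if v == math.inf else v))
            for k, v in self.parameters.items()
        }
        if "D" in params and isinstance(params["D"], list):
            params["D"] = ["inf" if d == math.inf else d for d in params["D"]]
        return {
            "experiment": self.experiment,
            "parameters": params,
            "output_dir": str(self.output_dir),
            "full_scale": self.full_scale,
            "schema_version": SCHEMA_VERSION,
        }


def validate_config(raw: dict, output_dir: str | Path | None = None) -> ExperimentConfig:
    """Validate a raw config mapping against the experiment's schema.

    Fills documented defaults, rejects unknown keys by name, and performs
    basic domain checks (gamma > 0, positive counts, valid dimensions).
    """
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    raw = dict(raw)
    experiment = raw.pop("experiment", None)
    if experiment not in SCHEMAS:
        raise ConfigError(
            f"unknown experiment {experiment!r}; choose from {sorted(SCHEMAS)}"
        )
    out = Path(raw.pop("output_dir", output_dir or "results"))
    full_scale = bool(raw.pop("full", False))
    schema = SCHEMAS[experiment]
    allowed = set(schema["defaults"]) | set(schema["required"])
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(
            f"unknown config key(s) {sorted(unknown)} for experiment {experiment!r}"
        )
    missing = [k for k in schema["required"] if k not in raw]
    if missing:
        raise ConfigError(f"missing required key(s) {missing} for {experiment!r}")
    params = {**schema["defaults"], **raw}
    if full_scale:
        for key, value in FULL_SCALE.items():
            if key in params:
                params[key] = value
    if "gamma" in params and params["gamma"] <= 0:
        raise ConfigError("the regularization weight gamma must satisfy gamma > 0")
    if "D" in params:
        dims = params["D"] if isinstance(params["D"], list) else [params["D"]]
        params["D"] = [_parse_dim(d) for d in dims]
    for key in ("sigma0", "sigma1", "sigma_i"):
        if key in params and params[key] < 0:
            raise ConfigError(f"{key} must be >= 0")
    for key in ("N", "M", "n_trials", "n_samples", "seed"):
        if key in params and params[key] is not None:
            if int(params[key]) != params[key] or params[key] < 0:
                raise ConfigError(f"{key} must be a nonnegative integer")
            params[key] = int(params[key])
    return ExperimentConfig(
        experiment=experiment, parameters=params, output_dir=out, full_scale=full_scale
    )


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate a YAML (or JSON) config file."""
    raw = yaml.safe_load(Path(path).read_text())
    return validate_config(raw)


# ---------------------------------------------------------------------------
# pipelines


def _alpha_grid(p: dict) -> np.ndarray:
    return fisher.default_alpha_grid(p["alpha_min"], p["alpha_max"], p["alpha_step"])


def _run_scatter(p: dict) -> dict[str, pd.DataFrame]:
    rng = np.random.Generator(np.random.Philox(key=p["seed"]))
    theta = float(rng.uniform(0.0, 2.0 * math.pi))
    rows = []
    for i, alpha in enumerate(p["alphas"]):
        spec = CodeSpec(N=p["N"], alpha=alpha, sigma0=p["sigma0"], sigma1=p["sigma1"])
        ens = sample_responses(spec, theta, p["n_samples"], seed=p["seed"] + i)
        cov = response_stats.empirical_covariance(ens)
        fit = response_stats.susceptibility_variance_scatter(
            spec, theta, p["n_samples"], seed=p["seed"] + i, covariance=cov.matrix
        )
        mu = susceptibility(spec, theta)
        lam = fisher.eigenvalue_lambda(alpha, p["N"], p["sigma0"], p["sigma1"])
        check = response_stats.covariance_eigencheck(cov, mu, lam)
        rows.append(
            {
                "alpha": alpha,
                "theta": theta,
                "slope_off": fit.slope_off,
                "intercept_off": fit.intercept_off,
                "slope_diag": fit.slope_diag,
                "intercept_diag": fit.intercept_diag,
                "rayleigh_quotient": check.rayleigh_quotient,
                "lambda_theory": lam,
                "eigen_residual": check.relative_residual,
            }
        )
    return {"results": pd.DataFrame(rows)}


def _run_fisher_curves(p: dict) -> dict[str, pd.DataFrame]:
    grid = _alpha_grid(p)
    frames = []
    for D in p["D"]:
        curve = fisher.fisher_curve(grid, D=D, sigma0=p["sigma0"], sigma_i=p["sigma_i"], N=p["N"])
        df = curve.to_frame()
        df.insert(0, "D", "inf" if D == math.inf else D)
        frames.append(df)
    return {"results": pd.concat(frames, ignore_index=True)}


def _run_energy_tradeoff(p: dict) -> dict[str, pd.DataFrame]:
    grid = _alpha_grid(p)
    frames, argmax_rows = [], []
    for D in p["D"]:
        curve = fisher.energy_curve(
            grid, D=D, sigma0=p["sigma0"], sigma_i=p["sigma_i"], gamma=p["gamma"]
        )
        df = curve.to_frame()
        df.insert(0, "D", "inf" if D == math.inf else D)
        frames.append(df)
        argmax_rows.append(
            {
                "D": "inf" if D == math.inf else D,
                "alpha_opt": curve.argmax_alpha,
                "critical_exponent": fisher.critical_exponent(D),
            }
        )
    return {"results": pd.concat(frames, ignore_index=True), "argmax": pd.DataFrame(argmax_rows)}


def _run_ablation(p: dict) -> dict[str, pd.DataFrame]:
    spec = CodeSpec(N=p["N"], alpha=p["alpha"], sigma0=p["sigma0"], sigma1=p["sigma1"])
    rows = []
    for order in p["orders"]:
        if order not in ("descending", "ascending"):
            raise ConfigError(f"unknown removal order {order!r}")
        for j, frac in enumerate(p["removal_fractions"]):
            k = int(round(frac * p["N"]))
            k = min(max(k, 0), p["N"] - 1)
            if order == "descending":
                subset = NeuronSubset.descending_removal(p["N"], k)
            else:
                subset = NeuronSubset.ascending_removal(p["N"], k)
            summary = decoding_experiment(
                spec,
                M=p["M"],
                n_trials=p["n_trials"],
                seed=p["seed"] + 1000 * j + (0 if order == "descending" else 1),
                subset=subset,
            )
            rows.append(
                {
                    "order": order,
                    "removed": k,
                    "retained_modes": len(subset.modes),
                    "inverse_variance": summary.inverse_variance,
                    "inverse_variance_per_obs": summary.inverse_variance_per_obs,
                    "large_error_count": summary.large_error_count,
                    "subset_fisher": fisher.subset_fisher(
                        subset, p["alpha"], p["sigma0"], p["sigma1"]
                    ),
                }
            )
    return {"results": pd.DataFrame(rows)}


def _run_noise_sweep(p: dict) -> dict[str, pd.DataFrame]:
    rows = []
    for j, sigma0 in enumerate(p["sigma0_values"]):
        spec = CodeSpec(N=p["N"], alpha=p["alpha"], sigma0=sigma0, sigma1=p["sigma1"])
        summary = decoding_experiment(
            spec, M=p["M"], n_trials=p["n_trials"], seed=p["seed"] + j
        )
        rows.append(
            {
                "sigma0": sigma0,
                "inverse_variance_per_obs": summary.inverse_variance_per_obs,
                "fisher_theory": fisher.fisher_finite(
                    p["alpha"], p["N"], sigma0, p["sigma1"]
                ),
                "large_error_count": summary.large_error_count,
            }
        )
    return {"results": pd.DataFrame(rows)}


_PIPELINES = {
    "scatter": _run_scatter,
    "fisher_curves": _run_fisher_curves,
    "energy_tradeoff": _run_energy_tradeoff,
    "ablation": _run_ablation,
    "noise_sweep": _run_noise_sweep,
}


def run_experiment(config: ExperimentConfig) -> dict[str, Path]:
    """Run a validated experiment and write its result tables.

    Writes ``<experiment>_<table>.csv`` per output table and a single
    ``<experiment>_meta.json`` sidecar; returns the written paths keyed by
    table name (metadata under ``"meta"``).
    """
    t0 = time.perf_counter()
    tables = _PIPELINES[config.experiment](config.parameters)
    elapsed = time.perf_counter() - t0
    config.output_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in tables.items():
        path = config.output_dir / f"{config.experiment}_{name}.csv"
        df.to_csv(path, index=False, float_format="%.12g")
        written[name] = path
    try:
        version = importlib_metadata.version("powerlaw-coding")
    except importlib_metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    meta = {
        "config": config.to_dict(),
        "package_version": version,
        "elapsed_seconds": elapsed,
    }
    meta_path = config.output_dir / f"{config.experiment}_meta.json"
    meta_path.write_text(json.dumps(meta, indent=2))
    written["meta"] = meta_path
    return written
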