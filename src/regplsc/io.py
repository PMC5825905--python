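"""File-based workflows: fit a dataset, run a study, summarize results.

These functions are thin, scriptable wrappers over the library — every
computation lives in :mod:`regplsc.estimator`, :mod:`regplsc.inference`
and :mod:`regplsc.simulation`.  Inputs are a CSV data matrix (header row
of indicator ids, one row per observation, no missing values) and a model
spec in JSON or YAML (keys ``latents``, ``blocks``, ``paths``,
``exo_correlations``).  Outputs are CSV tables plus a JSON metadata file
recording the seed and options; floats are written with 6 significant
digits and deterministic row order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError, SpecError
from .estimator import fit
from .inference import bootstrap
from .model_spec import ModelSpec
from .simulation import StudyOptions, enumerate_cells, run_study

__all__ = ["RunConfig", "run_fit", "run_simulate", "run_report"]

log = logging.getLogger("regplsc")
_FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """Configuration for the file-based workflows.

    ``mode`` is one of ``fit`` (estimate a model on a dataset),
    ``simulate`` (run the Monte Carlo study) or ``report`` (summarize a
    results directory).  Fields irrelevant to a mode are ignored; required
    ones are validated before any computation starts.
    """

    mode: str = "fit"
    spec_path: str | None = None
    data_path: str | None = None
    method: str = "plsc"
    K: int | None = None
    lambda_grid: list[float] | None = None
    B: int = 5000
    alpha: float = 0.05
    reps: int = 500
    levels: dict | None = None
    seed: int | None = None
    out_dir: str = "results"
    log_level: str = "INFO"

    def validate(self) -> "RunConfig":
        if self.mode not in ("fit", "simulate", "report"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.method not in ("plsc", "regplsc"):
            raise ConfigError(f"unknown method {self.method!r}")
        if self.mode == "fit":
            for attr in ("spec_path", "data_path"):
                if getattr(self, attr) is None:
                    raise ConfigError(f"mode 'fit' requires {attr}")
        if self.mode == "simulate" and self.reps < 1:
            raise ConfigError("reps must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        return self


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False):
    df.to_csv(path, float_format=_FLOAT_FMT, index=index)
    log.info("wrote %s", path)


def _write_metadata(out: Path, config: RunConfig, extra: dict | None = None):
    from . import __version__

    meta = {"version": __version__, "seed": config.seed, "config": asdict(config)}
    if extra:
        meta.update(extra)
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)


def read_data_csv(path, spec: ModelSpec) -> pd.DataFrame:
    """Read and validate an indicator data CSV against the model spec."""
    df = pd.read_csv(path)
    missing = [c for c in spec.indicators if c not in df.columns]
    if missing:
        raise SpecError(f"data file {path} is missing indicator column(s) {missing}")
    df = df.loc[:, list(spec.indicators)]
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise SpecError(f"data file {path} has missing values in column(s) {bad}")
    return df


def run_fit(config: RunConfig) -> Path:
    """Estimate the model on a dataset and write coefficient, reliability,
    correlation and bootstrap tables to the output directory."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    spec = ModelSpec.from_file(config.spec_path)
    data = read_data_csv(config.data_path, spec)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    res = fit(
        data, spec, config.method, K=config.K, grid=config.lambda_grid,
        seed=config.seed,
    )
    _write_csv(res.paths.to_frame(), out / "coefficients.csv")
    rel = pd.DataFrame(
        {"rho_A": res.reliabilities.values, "valid": res.reliabilities.valid}
    ).rename_axis("latent")
    _write_csv(rel, out / "reliabilities.csv", index=True)
    _write_csv(
        res.consistent.matrix.rename_axis("latent"),
        out / "consistent_correlations.csv",
        index=True,
    )
    boot = bootstrap(
        data, spec, config.method, B=config.B, alpha=config.alpha,
        seed=config.seed, K=config.K, grid=config.lambda_grid, full_fit=res,
    )
    _write_csv(boot.table.reset_index(), out / "bootstrap.csv")
    _write_metadata(
        out, config,
        {
            "smallest_eigenvalue": res.consistent.smallest_eigenvalue,
            "lambdas": res.paths.lambdas,
            "bootstrap_failed": boot.n_failed,
        },
    )
    return out


def run_simulate(config: RunConfig) -> Path:
    """Run the Monte Carlo study and write per-cell, per-path and summary
    tables (including discarded-sample counts)."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cells = enumerate_cells(config.levels)
    opts = StudyOptions(
        bootstrap_B=config.B,
        alpha=config.alpha,
        K=config.K,
        grid=np.asarray(config.lambda_grid, float) if config.lambda_grid else None,
    )
    log.info("running %d cells x %d replications", len(cells), config.reps)
    study = run_study(cells, reps=config.reps, options=opts, seed=config.seed)
    _write_csv(study.cells_frame(), out / "cells.csv")
    _write_csv(study.paths_frame(), out / "paths.csv")
    grand = pd.DataFrame(
        [{"method": m, "grand_mean_mad": v} for m, v in study.grand_mean_mad.items()]
    )
    _write_csv(grand, out / "summary.csv")
    power = study.paths_frame().pivot_table(
        index=["N", "phi", "reliability", "r2"],
        columns=["method", "path"],
        values="rejection_rate",
    )
    power.columns = [f"{m}:{p}" for m, p in power.columns]
    _write_csv(power.reset_index(), out / "power.csv")
    _write_metadata(out, config, {"n_cells": len(cells)})
    return out


def run_report(out_dir) -> str:
    """Human-readable summary of a results directory (pure file reader)."""
    out = Path(out_dir)
    cells_path = out / "cells.csv"
    paths_path = out / "paths.csv"
    if not cells_path.exists() or not paths_path.exists():
        return f"no results found in {out}"
    cells = pd.read_csv(cells_path)
    paths = pd.read_csv(paths_path)
    lines = ["Monte Carlo study report", "========================"]
    grand = cells.groupby("method")["mad_mean"].mean()
    lines.append("Grand mean MAD per method:")
    for m, v in grand.items():
        lines.append(f"  {m:8s} {v:.4f}")
    lines.append("Mean MAD by collinearity level (phi):")
    by_phi = cells.pivot_table(index="phi", columns="method", values="mad_mean")
    for phi, row in by_phi.iterrows():
        vals = "  ".join(f"{m}={row[m]:.4f}" for m in by_phi.columns)
        lines.append(f"  phi={phi}: {vals}")
    null = paths[paths["truth"] == 0.0]
    if len(null) and null["rejection_rate"].notna().any():
        lines.append("Average rejection rate for the true-zero path (type-I error):")
        for m, v in null.groupby("method")["rejection_rate"].mean().items():
            lines.append(f"  {m:8s} {v:.3f}")
    lines.append(
        "Discarded samples: "
        f"{int(cells.drop_duplicates(['N', 'phi', 'reliability', 'r2'])['discarded'].sum())}"
    )
    return "\n".join(lines)
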