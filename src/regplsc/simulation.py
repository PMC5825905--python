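"""Monte Carlo study harness: parameter recovery and inference error rates.

The full design crosses sample size N in {30, 60, 120, 200}, exogenous
correlation phi in {0.4, 0.6, 0.8}, composite reliability in {0.6, 0.8}
and coefficient of determination R^2 in {0.25, 0.50} — 48 cells.  For each
cell, multivariate normal indicator data are drawn from N(0, Sigma) under
the six-latent-variable population model and both estimators (PLSc and
RegPLSc) are fit to the *same* samples.  A sample counts as a proper
solution only if the Mode A weights converged, every reliability estimate
is positive, and the disattenuated latent correlation matrix is positive
definite (smallest eigenvalue > 1e-10); improper samples are discarded
(and counted) until the target number of proper replications is reached.
Under weak reliability, extreme collinearity and small N the improper
rate is high — a majority of draws can be discarded in the hardest cells;
this is a property of the disattenuation itself, not of the sampler.

Recovery is summarized by the mean absolute difference (MAD) between the
estimated and true standardized coefficients, averaged over the P = 7
structural paths of a replication; power / type-I error by the proportion
of replications whose 95% bootstrap percentile interval excludes zero
(the gamma22 path is truly zero, so its rejection rate estimates the
type-I error).  Both methods share bootstrap resample indices (common
random numbers) to sharpen the paired comparison.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError, InvalidPopulationError, RegPLSError
from .estimator import default_lambda_grid, select_lambda
from .inference import (
    _batched_consistent,
    _paths_batch,
    _percentile_ci,
    _resample_moments,
)
from .model_spec import (
    DESIGN_LEVELS,
    DesignCell,
    PopulationModel,
    build_population,
    coefficients_for_cell,
    load_coefficient_table,
)
from .pls_engine import compile_model, _mode_a_core
from .estimator import _disattenuate_batch, _rho_a_batch

__all__ = [
    "StudyOptions",
    "CellResult",
    "StudyResult",
    "enumerate_cells",
    "generate_sample",
    "mad",
    "run_cell",
    "run_study",
]

_PD_EIG_TOL = 1e-10
METHODS = ("plsc", "regplsc")


def enumerate_cells(levels: dict | None = None) -> list[DesignCell]:
    """Cartesian product of the design levels, N varying slowest.

    ``levels`` may override any of the keys ``N``, ``phi``, ``reliability``,
    ``r2``; the defaults are the 48-cell full design.
    """
    lv = dict(DESIGN_LEVELS)
    if levels:
        unknown = set(levels) - set(lv)
        if unknown:
            raise ConfigError(f"unknown design factor(s) {sorted(unknown)}")
        lv.update({k: tuple(v) for k, v in levels.items()})
    for k, vals in lv.items():
        if len(vals) == 0:
            raise ConfigError(f"design factor {k!r} has no levels")
    return [
        DesignCell(N=int(n), phi=float(p), reliability=float(rel), r2=float(r2))
        for n, p, rel, r2 in itertools.product(
            lv["N"], lv["phi"], lv["reliability"], lv["r2"]
        )
    ]


def generate_sample(pop: PopulationModel, N: int, seed) -> pd.DataFrame:
    """Draw N rows from N(0, Sigma); deterministic given the seed."""
    eig = np.linalg.eigvalsh(pop.Sigma)
    if eig[0] <= 0:
        raise InvalidPopulationError("Sigma is not positive definite")
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(pop.Sigma)
    Z = rng.standard_normal((N, pop.n_indicators))
    return pd.DataFrame(Z @ L.T, columns=list(pop.spec.indicators))


def mad(estimates, truth) -> float:
    """Mean absolute difference between estimates and true parameters."""
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if est.shape != tru.shape or est.ndim != 1 or est.size < 1:
        raise ValueError("estimates and truth must be equal-length vectors")
    return float(np.abs(est - tru).mean())


@dataclass
class StudyOptions:
    """Knobs of the simulation harness.

    ``bootstrap_B = 0`` skips inference entirely (recovery-only studies);
    the study of record used 200 resamples per replication.
    """

    bootstrap_B: int = 200
    alpha: float = 0.05
    scheme: str = "path"
    K: int | None = None  # None: 5-fold, LOO when N < 40
    grid: np.ndarray | None = None
    per_equation: bool = True
    tol: float = 1e-6
    max_iter: int = 300
    table: pd.DataFrame | None = None
    n_indicators: int = 4

    def lambda_grid(self) -> np.ndarray:
        return default_lambda_grid() if self.grid is None else np.asarray(self.grid, float)


@dataclass
class CellResult:
    """Aggregated results of one design cell."""

    cell: DesignCell
    labels: tuple[str, ...]
    truth: np.ndarray
    mean_estimates: dict[str, np.ndarray]  # method -> (P,)
    mad_mean: dict[str, float]
    rejection: dict[str, np.ndarray] | None  # method -> (P,) proportions
    mean_lambda: dict[str, float]
    kept: int
    discarded: int

    def paths_frame(self) -> pd.DataFrame:
        rows = []
        for m in METHODS:
            for j, lab in enumerate(self.labels):
                rows.append(
                    {
                        "N": self.cell.N,
                        "phi": self.cell.phi,
                        "reliability": self.cell.reliability,
                        "r2": self.cell.r2,
                        "method": m,
                        "path": lab,
                        "truth": float(self.truth[j]),
                        "mean_estimate": float(self.mean_estimates[m][j]),
                        "rejection_rate": (
                            float(self.rejection[m][j]) if self.rejection else np.nan
                        ),
                    }
                )
        return pd.DataFrame(rows)


def _bootstrap_rejections(X, comp, lam_vecs, B, alpha, seed, opts):
    """Shared-resample bootstrap CI decisions for both methods.

    Returns {method: bool (P,) reject flags} (NaN-free; methods with fewer
    than 2 usable resamples return all-False plus a flag in the counts).
    """
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, X.shape[0], size=(B, X.shape[0]))
    R, var_ok = _resample_moments(X, idx)
    Rc, _, est_ok = _batched_consistent(R, comp, opts.scheme, opts.tol, opts.max_iter)
    base_ok = var_ok & est_ok
    out = {}
    for m in METHODS:
        # both methods keep every computable resample (shared indices);
        # indefinite matrices still yield finite per-equation estimates
        draws = _paths_batch(Rc, comp, lam_vecs[m])
        ok = base_ok & np.isfinite(draws).all(axis=1)
        good = draws[ok]
        if good.shape[0] < 2:
            out[m] = np.zeros(draws.shape[1], dtype=bool)
            continue
        lo, hi = _percentile_ci(good, alpha)
        out[m] = (lo > 0) | (hi < 0)
    return out


def run_cell(
    cell: DesignCell,
    reps: int = 500,
    options: StudyOptions | None = None,
    seed=None,
) -> CellResult:
    """Run one design cell to the target number of proper replications.

    Samples are drawn sequentially; each proper sample is fit with both
    methods (identical data), the RegPLSc ridge parameter is chosen per
    replication by cross-validation, and — when ``options.bootstrap_B > 0``
    — significance decisions are taken from shared-index bootstrap CIs.
    """
    if reps < 1:
        raise ConfigError("reps must be >= 1")
    opts = options or StudyOptions()
    pop = build_population(cell, opts.table, opts.n_indicators)
    spec = pop.spec
    comp = compile_model(spec)
    labels = spec.path_labels
    coeffs = coefficients_for_cell(cell, opts.table)
    truth = np.array([coeffs[lab] for lab in labels])
    chol = np.linalg.cholesky(pop.Sigma)
    grid = opts.lambda_grid()

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    estimates = {m: np.empty((reps, len(labels))) for m in METHODS}
    mads = {m: np.empty(reps) for m in METHODS}
    rejects = {m: np.zeros((reps, len(labels)), dtype=bool) for m in METHODS}
    lam_sums = {m: 0.0 for m in METHODS}
    kept = 0
    discarded = 0
    n_eq = len(comp.equations)
    while kept < reps:
        # dead-cell guard: legitimate hard cells run up to ~98% discards,
        # so only give up when virtually nothing is proper after many draws
        attempts = discarded + kept
        if attempts >= max(1000, 100 * reps) and kept / attempts < 0.005:
            raise RegPLSError(
                f"pathological cell {cell.label()}: "
                f"only {kept}/{attempts} samples were proper"
            )
        draw_seed, cv_seed, boot_seed = ss.spawn(3)
        Z = np.random.default_rng(draw_seed).standard_normal((cell.N, pop.n_indicators))
        X = Z @ chol.T
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        if np.any(sd <= 0):
            discarded += 1
            continue
        Xs = (X - mu) / sd
        R = (Xs.T @ Xs) / (cell.N - 1)
        W, _, conv, valid = _mode_a_core(R, comp, opts.scheme, opts.tol, opts.max_iter)
        if not (conv and valid):
            discarded += 1
            continue
        rho = _rho_a_batch(W, R)
        if not (np.isfinite(rho).all() and (rho > 0).all()):
            discarded += 1
            continue
        C = W.T @ R @ W
        Rc = _disattenuate_batch(C, rho)
        if np.linalg.eigvalsh(Rc)[0] <= _PD_EIG_TOL:
            discarded += 1  # not a proper solution
            continue

        sel = select_lambda(
            X, spec, K=opts.K, grid=grid, seed=cv_seed, scheme=opts.scheme,
            per_equation=opts.per_equation, tol=opts.tol, max_iter=opts.max_iter,
        )
        lam_vecs = {
            "plsc": np.zeros(n_eq),
            "regplsc": np.array(
                [sel.lambdas[spec.lv_names[t]] for t, _ in comp.equations]
            ),
        }
        proper = True
        rep_est = {}
        for m in METHODS:
            beta = _paths_batch(Rc[None], comp, lam_vecs[m])[0]
            if not np.isfinite(beta).all():
                proper = False
                break
            rep_est[m] = beta
        if not proper:
            discarded += 1
            continue
        for m in METHODS:
            estimates[m][kept] = rep_est[m]
            mads[m][kept] = mad(rep_est[m], truth)
            lam_sums[m] += float(lam_vecs[m].mean())
        if opts.bootstrap_B > 0:
            rej = _bootstrap_rejections(
                X, comp, lam_vecs, opts.bootstrap_B, opts.alpha, boot_seed, opts
            )
            for m in METHODS:
                rejects[m][kept] = rej[m]
        kept += 1

    return CellResult(
        cell=cell,
        labels=labels,
        truth=truth,
        mean_estimates={m: estimates[m].mean(axis=0) for m in METHODS},
        mad_mean={m: float(mads[m].mean()) for m in METHODS},
        rejection=(
            {m: rejects[m].mean(axis=0) for m in METHODS}
            if opts.bootstrap_B > 0
            else None
        ),
        mean_lambda={m: lam_sums[m] / reps for m in METHODS},
        kept=kept,
        discarded=discarded,
    )


@dataclass
class StudyResult:
    """Per-cell results plus grand means per method."""

    cells: list[CellResult]
    reps: int
    seed: int | None
    options: StudyOptions = field(repr=False, default_factory=StudyOptions)

    @property
    def grand_mean_mad(self) -> dict[str, float]:
        return {m: float(np.mean([c.mad_mean[m] for c in self.cells])) for m in METHODS}

    def cells_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            for m in METHODS:
                rows.append(
                    {
                        "N": c.cell.N,
                        "phi": c.cell.phi,
                        "reliability": c.cell.reliability,
                        "r2": c.cell.r2,
                        "method": m,
                        "mad_mean": c.mad_mean[m],
                        "mean_lambda": c.mean_lambda[m],
                        "kept": c.kept,
                        "discarded": c.discarded,
                    }
                )
        return pd.DataFrame(rows)

    def paths_frame(self) -> pd.DataFrame:
        """Tidy long table: one row per cell x method x path (suitable for
        any external ANOVA and for power / type-I summaries)."""
        return pd.concat([c.paths_frame() for c in self.cells], ignore_index=True)

    def rejection_rates(self, path: str) -> pd.DataFrame:
        df = self.paths_frame()
        return df[df["path"] == path].pivot_table(
            index=["N", "phi", "reliability", "r2"],
            columns="method",
            values="rejection_rate",
        )


def run_study(
    cells: list[DesignCell] | None = None,
    reps: int = 500,
    options: StudyOptions | None = None,
    seed=None,
) -> StudyResult:
    """Run the Monte Carlo study over the given cells (default: all 48).

    Per-cell seeds are derived deterministically from the master seed
    (one spawn per cell, in cell order).
    """
    if reps < 1:
        raise ConfigError("reps must be >= 1")
    if cells is None:
        cells = enumerate_cells()
    if len(cells) == 0:
        raise ConfigError("no design cells to run")
    opts = options or StudyOptions()
    if opts.table is None:
        opts.table = load_coefficient_table()
    cell_seeds = np.random.SeedSequence(seed).spawn(len(cells))
    results = [
        run_cell(cell, reps=reps, options=opts, seed=cs)
        for cell, cs in zip(cells, cell_seeds)
    ]
    return StudyResult(cells=results, reps=reps, seed=seed, options=opts)
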