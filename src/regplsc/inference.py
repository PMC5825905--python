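"""Nonparametric bootstrap inference for structural path coefficients.

Standard errors are the standard deviation of the bootstrap distribution of
each coefficient over B resamples of the N observations (with replacement);
confidence intervals are plain percentile intervals (linear interpolation
between order statistics); a path is declared significant when its interval
excludes zero.

The ridge parameter is *not* re-selected inside each resample: it stays
fixed at the full-sample cross-validation choice, so the standard errors
reflect sampling variability of the estimator at that tuning, not tuning
variability (``reselect_lambda=True`` enables the expensive alternative
for sensitivity analysis).  The weight sign convention (positive block
weight sum) applies within every resample, which prevents arbitrary sign
flips from contaminating the standard errors.

Resamples that fail — the weight iteration does not converge, a column is
constant, a reliability estimate is non-positive, or an equation's system
is singular — are counted and excluded; more than 50% failures raises
:class:`~regplsc.exceptions.UnstableInferenceError`.  Indefinite
disattenuated matrices are *not* excluded: their per-equation estimates
are finite, and dropping them would truncate the bootstrap distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigError, UnstableInferenceError
from .estimator import (
    FitResult,
    _disattenuate_batch,
    _rho_a_batch,
    fit,
)
from .model_spec import ModelSpec
from .pls_engine import CompiledModel, compile_model, _mode_a_core

__all__ = ["BootstrapSummary", "bootstrap"]

@dataclass
class BootstrapSummary:
    """Bootstrap SEs, percentile CIs and CI-based significance decisions."""

    table: pd.DataFrame  # index: path label; estimate, se, lower, upper, reject
    B: int
    alpha: float
    n_failed: int
    method: str
    lambdas: dict[str, float]

    def __post_init__(self):
        assert (self.table["lower"] <= self.table["upper"]).all()

    @property
    def reject(self) -> pd.Series:
        return self.table["reject"]


def _resample_moments(X: np.ndarray, idx: np.ndarray):
    """Correlation matrices of bootstrap resamples.

    X: (N, p) raw data; idx: (B, N) row indices.
    Returns R (B, p, p) and a validity mask (False where a column was
    constant in the resample).
    """
    Xb = X[idx]  # (B, N, p)
    n = Xb.shape[1]
    mean = Xb.mean(axis=1)
    Xc = Xb - mean[:, None, :]
    var = (Xc**2).sum(axis=1) / (n - 1)
    ok = (var > 0).all(axis=1)
    sd = np.sqrt(np.where(var > 0, var, 1.0))
    Xs = Xc / sd[:, None, :]
    R = np.einsum("bni,bnj->bij", Xs, Xs, optimize=True) / (n - 1)
    return R, ok


def _batched_consistent(R: np.ndarray, comp: CompiledModel, scheme, tol, max_iter):
    """Weights -> rho_A -> disattenuated matrices for a batch of moment
    matrices. Returns (Rc, eigmin, ok) where ok requires convergence and
    positive finite reliabilities, and eigmin is the smallest eigenvalue of
    the disattenuated matrix (PLSc requires it positive)."""
    W, _, conv, valid = _mode_a_core(R, comp, scheme, tol, max_iter)
    rho = _rho_a_batch(W, R)
    rho_ok = np.isfinite(rho).all(axis=-1) & (rho > 0).all(axis=-1)
    ok = conv & valid & rho_ok
    rho_safe = np.where(rho > 0, rho, 1.0)
    C = np.swapaxes(W, -1, -2) @ (R @ W)
    Rc = _disattenuate_batch(C, rho_safe)
    eigmin = np.linalg.eigvalsh(Rc)[..., 0]
    return Rc, eigmin, ok


def _equation_solve_batch(Rc: np.ndarray, pidx: np.ndarray, t: int, lam: float) -> np.ndarray:
    """Solve one structural equation for every matrix in the batch.

    Rows where the (ridge-augmented) system is singular come back NaN.
    """
    A = Rc[:, pidx[:, None], pidx[None, :]] + lam * np.eye(len(pidx))
    b = Rc[:, pidx, t]
    try:
        return np.linalg.solve(A, b[..., None])[..., 0]
    except np.linalg.LinAlgError:
        out = np.full(b.shape, np.nan)
        for i in range(A.shape[0]):
            try:
                out[i] = np.linalg.solve(A[i], b[i])
            except np.linalg.LinAlgError:
                pass
        return out


def _paths_batch(Rc: np.ndarray, comp: CompiledModel, lambdas: np.ndarray) -> np.ndarray:
    """Per-resample coefficients for all equations, stacked in the order of
    ``comp.equations`` (labels ordered as ModelSpec.path_labels)."""
    cols = []
    for (t, pidx), lam in zip(comp.equations, lambdas):
        cols.append(_equation_solve_batch(Rc, pidx, t, float(lam)))
    return np.concatenate(cols, axis=1)


def _percentile_ci(draws: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    lo = np.quantile(draws, alpha / 2.0, axis=0, method="linear")
    hi = np.quantile(draws, 1.0 - alpha / 2.0, axis=0, method="linear")
    return lo, hi


def bootstrap(
    data,
    spec: ModelSpec,
    method: str = "plsc",
    B: int = 5000,
    alpha: float = 0.05,
    seed=None,
    *,
    scheme: str = "path",
    K: int | None = None,
    grid=None,
    lambdas=None,
    reselect_lambda: bool = False,
    tol: float = 1e-6,
    max_iter: int = 300,
    full_fit: FitResult | None = None,
) -> BootstrapSummary:
    """Bootstrap the structural coefficients of a PLSc / RegPLSc fit.

    Parameters
    ----------
    B
        Number of resamples (default 5000; Monte Carlo studies typically
        use 200).
    alpha
        1 - confidence level of the percentile interval (default 0.05,
        i.e. 95% CIs).
    full_fit
        A pre-computed full-sample fit to reuse (must match ``method``);
        otherwise one is computed here (including lambda selection for
        RegPLSc).
    """
    if B < 2:
        raise ConfigError("B must be >= 2")
    if not 0.0 < alpha < 1.0:
        raise ConfigError("alpha must lie in (0, 1)")
    comp = compile_model(spec)
    X = comp.align(data)
    N = X.shape[0]
    if full_fit is None:
        full_fit = fit(
            data, spec, method, scheme=scheme, K=K, grid=grid, seed=seed,
            lambdas=lambdas, tol=tol, max_iter=max_iter,
        )
    elif full_fit.method != method:
        raise ConfigError("full_fit was computed with a different method")
    lam_by_target = full_fit.paths.lambdas
    lam_vec = np.array([lam_by_target[spec.lv_names[t]] for t, _ in comp.equations])

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, N, size=(B, N))

    if reselect_lambda and method == "regplsc":
        draws = np.full((B, len(spec.path_labels)), np.nan)
        for b in range(B):
            try:
                fb = fit(
                    X[idx[b]], spec, method, scheme=scheme, K=K, grid=grid,
                    seed=seed, tol=tol, max_iter=max_iter,
                )
                coefs = fb.paths.coefficients
                draws[b] = [coefs[lab] for lab in spec.path_labels]
            except Exception:
                pass
        ok = np.isfinite(draws).all(axis=1)
    else:
        R, var_ok = _resample_moments(X, idx)
        Rc, _, est_ok = _batched_consistent(R, comp, scheme, tol, max_iter)
        # an indefinite disattenuated matrix still yields per-equation
        # estimates; only incomputable resamples (non-convergence, constant
        # column, rho_A <= 0, singular equation submatrix) are excluded —
        # dropping the indefinite ones truncates the tails and distorts CIs
        ok = var_ok & est_ok
        draws = _paths_batch(Rc, comp, lam_vec)
        ok &= np.isfinite(draws).all(axis=1)

    n_failed = int(B - ok.sum())
    if n_failed > B / 2:
        raise UnstableInferenceError(
            f"{n_failed}/{B} bootstrap resamples failed; inference is unstable"
        )
    good = draws[ok]
    se = good.std(axis=0, ddof=1)
    lo, hi = _percentile_ci(good, alpha)
    labels = list(spec.path_labels)
    est = full_fit.paths.coefficients
    table = pd.DataFrame(
        {
            "estimate": [est[lab] for lab in labels],
            "se": se,
            "lower": lo,
            "upper": hi,
        },
        index=pd.Index(labels, name="path"),
    )
    table["reject"] = (table["lower"] > 0) | (table["upper"] < 0)
    return BootstrapSummary(
        table=table,
        B=B,
        alpha=alpha,
        n_failed=n_failed,
        method=method,
        lambdas=lam_by_target,
    )
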