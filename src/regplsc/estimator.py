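"""Consistent PLS (PLSc) and its ridge-regularized extension (RegPLSc).

Estimation runs in three steps:

1. Mode A indicator weights and composite (proxy) correlations
   (:mod:`regplsc.pls_engine`).
2. Consistent reliabilities rho_A per block, used to correct the proxy
   correlations for measurement-error attenuation::

       rho_A = (w'w)^2 * w'(S - diag S) w / w'(w w' - diag(w w')) w

   and a disattenuated latent correlation ``r_ij / sqrt(rho_i rho_j)``.
3. Per-equation path estimation on the consistent correlations, either by
   OLS ``beta = Rx^{-1} r_xy`` (PLSc) or by a ridge least squares estimator
   ``beta(lambda) = (Rx + lambda I)^{-1} r_xy`` (RegPLSc), with the
   regularization parameter chosen by K-fold cross-validation.

Disattenuation can push the latent correlation matrix out of the positive
definite cone — that is precisely the failure mode regularization exists to
avoid, so the PD status travels with the matrix instead of being fixed up
silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigError,
    FoldSizeError,
    SingularMatrixError,
    UndefinedReliabilityError,
)
from .model_spec import ModelSpec
from .pls_engine import (
    DataMatrix,
    WeightSet,
    compile_model,
    estimate_weights,
    estimate_weights_from_moments,
    standardize,
    _mode_a_core,
)

__all__ = [
    "ReliabilityVector",
    "ConsistentCorrelation",
    "PathEstimates",
    "FitResult",
    "LambdaSelection",
    "rho_A",
    "disattenuate",
    "ols_paths",
    "ridge_paths",
    "default_lambda_grid",
    "select_lambda",
    "fit",
    "fit_from_moments",
]

_PD_EIG_TOL = 1e-10


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class ReliabilityVector:
    """Per-latent rho_A estimates with validity flags.

    An estimate outside (0, 1] is carried as-is with ``valid=False``
    (downstream positive-definiteness checks decide what to do with it);
    it is never clamped.
    """

    values: pd.Series
    valid: pd.Series

    def __getitem__(self, lv: str) -> float:
        return float(self.values[lv])


@dataclass
class ConsistentCorrelation:
    """Disattenuated latent correlation matrix with a PD diagnostic."""

    matrix: pd.DataFrame
    smallest_eigenvalue: float

    @property
    def positive_definite(self) -> bool:
        return self.smallest_eigenvalue > _PD_EIG_TOL


@dataclass
class EquationEstimate:
    target: str
    parents: tuple[str, ...]
    labels: tuple[str, ...]
    coefficients: np.ndarray
    lam: float


@dataclass
class PathEstimates:
    """Per-equation structural coefficients with the lambda used."""

    method: str  # "plsc" | "regplsc"
    equations: list[EquationEstimate]

    @property
    def coefficients(self) -> dict[str, float]:
        """Flat label -> estimate mapping across all equations."""
        out: dict[str, float] = {}
        for eq in self.equations:
            for lab, b in zip(eq.labels, eq.coefficients):
                out[lab] = float(b)
        return out

    @property
    def lambdas(self) -> dict[str, float]:
        return {eq.target: eq.lam for eq in self.equations}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "target": eq.target,
                "source": src,
                "label": lab,
                "estimate": float(b),
                "lambda": eq.lam,
                "method": self.method,
            }
            for eq in self.equations
            for src, lab, b in zip(eq.parents, eq.labels, eq.coefficients)
        ]
        return pd.DataFrame(rows)


@dataclass
class LambdaSelection:
    """CV-selected regularization parameters and the error curves."""

    lambdas: dict[str, float]  # endogenous target -> lambda
    curves: pd.DataFrame  # index = grid, one column per endogenous target
    K: int
    folds_used: int


@dataclass
class FitResult:
    method: str
    weights: WeightSet
    reliabilities: ReliabilityVector
    proxy: pd.DataFrame
    consistent: ConsistentCorrelation
    paths: PathEstimates
    selection: LambdaSelection | None = None


# ---------------------------------------------------------------------------
# reliabilities and disattenuation
# ---------------------------------------------------------------------------

def rho_A(weights: np.ndarray, S: np.ndarray) -> tuple[float, bool]:
    """Consistent reliability of a weighted composite for one block.

    Parameters
    ----------
    weights : (p,) weight vector of the block.
    S : (p, p) sample covariance matrix of the block's indicators.

    Returns the reliability and a validity flag (False outside (0, 1]).
    """
    w = np.asarray(weights, dtype=float)
    S = np.asarray(S, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise ValueError("block weight vector must have length >= 2")
    if S.shape != (w.size, w.size) or not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("S must be a symmetric matrix matching the weights")
    a = float(w @ w)
    num = float(w @ (S - np.diag(np.diag(S))) @ w)
    den = a**2 - float((w**4).sum())
    if abs(den) < 1e-14:
        raise UndefinedReliabilityError(
            "single effective indicator: w'(ww' - diag(ww'))w = 0"
        )
    value = a**2 * num / den
    return value, bool(0.0 < value <= 1.0)


def _rho_a_batch(W: np.ndarray, R: np.ndarray, C_diag: np.ndarray | None = None) -> np.ndarray:
    """rho_A for every block, batched. W: (..., p, L); R: (..., p, p)."""
    a = (W**2).sum(axis=-2)
    if C_diag is None:
        RW = R @ W
        C_diag = (W * RW).sum(axis=-2)
    diag = np.diagonal(R, axis1=-2, axis2=-1)
    d2 = (W**2 * diag[..., :, None]).sum(axis=-2)
    num = C_diag - d2
    den = a**2 - (W**4).sum(axis=-2)
    with np.errstate(divide="ignore", invalid="ignore"):
        return a**2 * num / den


def disattenuate(R_proxy, rho) -> ConsistentCorrelation:
    """Correct proxy correlations for attenuation.

    Off-diagonal (i, j) becomes ``r_ij / sqrt(rho_i rho_j)``; the diagonal
    is reset to one.  Entries may exceed 1 in magnitude — they are retained
    and the positive-definite flag reports the consequence.
    """
    if isinstance(R_proxy, pd.DataFrame):
        names = list(R_proxy.columns)
        Rm = R_proxy.to_numpy(dtype=float)
    else:
        Rm = np.asarray(R_proxy, dtype=float)
        names = None
    if isinstance(rho, ReliabilityVector):
        r = rho.values.to_numpy(dtype=float)
    else:
        r = np.asarray(rho, dtype=float)
    if r.shape[0] != Rm.shape[0] or Rm.shape[0] != Rm.shape[1]:
        raise ValueError("dimensions of proxy matrix and reliabilities do not match")
    if np.any(r <= 0):
        raise ValueError("all reliabilities must be positive to disattenuate")
    denom = np.sqrt(np.outer(r, r))
    Rc = Rm / denom
    np.fill_diagonal(Rc, 1.0)
    Rc = (Rc + Rc.T) / 2.0
    smallest = float(np.linalg.eigvalsh(Rc)[0])
    return ConsistentCorrelation(
        matrix=pd.DataFrame(Rc, index=names, columns=names),
        smallest_eigenvalue=smallest,
    )


def _disattenuate_batch(C: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Batched disattenuation; no PD check (callers use eigvalsh as needed)."""
    denom = np.sqrt(rho[..., :, None] * rho[..., None, :])
    Rc = C / denom
    L = C.shape[-1]
    Rc[..., np.arange(L), np.arange(L)] = 1.0
    return Rc


# ---------------------------------------------------------------------------
# path estimation
# ---------------------------------------------------------------------------

def ols_paths(Rx, rxy) -> np.ndarray:
    """OLS structural coefficients on the correlation metric: solve Rx b = rxy."""
    Rx = np.atleast_2d(np.asarray(Rx, dtype=float))
    rxy = np.atleast_1d(np.asarray(rxy, dtype=float))
    if Rx.shape[0] != Rx.shape[1] or rxy.shape[0] != Rx.shape[0]:
        raise ValueError("Rx must be square and match rxy")
    sv = np.linalg.svd(Rx, compute_uv=False)
    rcond = sv[-1] / sv[0] if sv[0] > 0 else 0.0
    if rcond < 1e-12:
        raise SingularMatrixError(
            f"predictor correlation matrix is singular (rcond={rcond:.2e}); "
            "consider the regularized estimator",
            smallest_eigenvalue=float(np.linalg.eigvalsh(Rx)[0]),
        )
    return np.linalg.solve(Rx, rxy)


def ridge_paths(Rx, rxy, lam: float) -> np.ndarray:
    """Ridge structural coefficients: solve (Rx + lambda I) b = rxy."""
    if lam < 0:
        raise ValueError(f"regularization parameter must be >= 0; got {lam}")
    Rx = np.atleast_2d(np.asarray(Rx, dtype=float))
    rxy = np.atleast_1d(np.asarray(rxy, dtype=float))
    if lam == 0:
        return ols_paths(Rx, rxy)
    return np.linalg.solve(Rx + lam * np.eye(Rx.shape[0]), rxy)


def _ridge_grid_solve(Rx: np.ndarray, rxy: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Solve (Rx + g I) b = rxy for every g in grid. Returns (G, k); rows
    where the system is singular (g = 0 on a singular matrix) are NaN."""
    k = Rx.shape[0]
    A = Rx[None, :, :] + grid[:, None, None] * np.eye(k)
    try:
        return np.linalg.solve(A, np.broadcast_to(rxy, (grid.size, k))[..., None])[..., 0]
    except np.linalg.LinAlgError:
        out = np.full((grid.size, k), np.nan)
        for g in range(grid.size):
            try:
                out[g] = np.linalg.solve(A[g], rxy)
            except np.linalg.LinAlgError:
                pass
        return out


def default_lambda_grid() -> np.ndarray:
    """{0} plus 30 logarithmically spaced values in [1e-4, 1]."""
    return np.concatenate([[0.0], np.logspace(-4, 0, 30)])


# ---------------------------------------------------------------------------
# cross-validated lambda selection
# ---------------------------------------------------------------------------

def _fold_indices(N: int, K: int, seed) -> list[np.ndarray]:
    if K == N:  # leave-one-out: no shuffling needed
        return [np.array([i]) for i in range(N)]
    perm = np.random.default_rng(seed).permutation(N)
    return [np.sort(chunk) for chunk in np.array_split(perm, K)]


def select_lambda(
    data,
    spec: ModelSpec,
    K: int | None = None,
    grid=None,
    seed=None,
    scheme: str = "path",
    per_equation: bool = True,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> LambdaSelection:
    """Choose the ridge parameter by K-fold cross-validation.

    Within each split, weights, reliabilities and ridge coefficients are
    estimated on the training folds only; validation rows are standardized
    by training moments and scored with training weights, and the error is
    the mean squared residual of each validation composite score predicted
    from its parents' composite scores at the candidate lambda.  The
    reported lambda minimizes the accumulated out-of-fold error per
    endogenous equation (ties go to the smallest lambda).

    ``K`` defaults to 5, switching to leave-one-out when N < 40.  Folds
    whose training moments yield no usable consistent correlations (a
    reliability estimate <= 0) are skipped; if every fold is unusable the
    selection falls back to lambda = 0 (``folds_used = 0`` records this).
    """
    comp = compile_model(spec)
    X = comp.align(data)
    N = X.shape[0]
    if grid is None:
        grid = default_lambda_grid()
    grid = np.unique(np.asarray(list(grid), dtype=float))  # sorted ascending
    if grid.size == 0:
        raise ConfigError("lambda grid is empty")
    if np.any(grid < 0):
        raise ConfigError("lambda grid values must be >= 0")
    if K is None:
        K = 5 if N >= 40 else N
    K = int(K)
    if not 2 <= K <= N:
        raise ConfigError(f"K must lie in [2, N={N}]; got {K}")
    folds = _fold_indices(N, K, seed)
    if min(len(f) for f in folds) < 1 or N - max(len(f) for f in folds) < 3:
        raise FoldSizeError("a training fold has fewer than 3 observations")

    S1 = X.sum(axis=0)
    S2 = X.T @ X
    n_eq = len(comp.equations)
    sse = np.zeros((n_eq, grid.size))
    folds_used = 0
    for val in folds:
        Xv = X[val]
        n_t = N - len(val)
        s1 = S1 - Xv.sum(axis=0)
        s2 = S2 - Xv.T @ Xv
        mean = s1 / n_t
        cov = (s2 - np.outer(mean, s1)) / (n_t - 1)
        var = np.diag(cov)
        if np.any(var <= 0):
            continue  # degenerate training fold
        sd = np.sqrt(var)
        R_t = cov / np.outer(sd, sd)
        W, _, _, valid = _mode_a_core(R_t, comp, scheme, tol, max_iter)
        # a non-converged fold still contributes its last iterate: CV only
        # ranks candidate lambdas and near-fixed-point weights suffice
        if not valid:
            continue
        rho = _rho_a_batch(W, R_t)
        if np.any(rho <= 0) or not np.all(np.isfinite(rho)):
            continue
        C = W.T @ R_t @ W
        Rc = _disattenuate_batch(C, rho)
        Yv = ((Xv - mean) / sd) @ W
        for e, (t, pidx) in enumerate(comp.equations):
            beta = _ridge_grid_solve(Rc[np.ix_(pidx, pidx)], Rc[pidx, t], grid)
            pred = Yv[:, pidx] @ beta.T  # (n_val, G)
            resid = Yv[:, t][:, None] - pred
            contrib = (resid**2).sum(axis=0)
            sse[e] += np.where(np.isfinite(contrib), contrib, np.inf)
        folds_used += 1
    targets = [spec.lv_names[t] for t, _ in comp.equations]
    if folds_used == 0:
        # no training fold produced usable consistent moments (possible on
        # badly behaved small samples): fall back to the least-bias choice
        curves = np.full_like(sse, np.nan)
        curve_df = pd.DataFrame(curves.T, index=grid, columns=targets)
        curve_df.index.name = "lambda"
        return LambdaSelection(
            lambdas={tg: 0.0 for tg in targets}, curves=curve_df, K=K, folds_used=0
        )

    curves = sse / N
    if not per_equation:
        total = curves.sum(axis=0)
        best = int(np.argmin(total))  # argmin returns the smallest-lambda tie
        lambdas = {tg: float(grid[best]) for tg in targets}
    else:
        lambdas = {
            tg: float(grid[int(np.argmin(curves[e]))]) for e, tg in enumerate(targets)
        }
    curve_df = pd.DataFrame(curves.T, index=grid, columns=targets)
    curve_df.index.name = "lambda"
    return LambdaSelection(lambdas=lambdas, curves=curve_df, K=K, folds_used=folds_used)


# ---------------------------------------------------------------------------
# full fits
# ---------------------------------------------------------------------------

def _paths_from_consistent(
    spec: ModelSpec, cc: ConsistentCorrelation, method: str, lambdas: dict[str, float]
) -> PathEstimates:
    comp = compile_model(spec)
    Rc = cc.matrix.to_numpy()
    equations = []
    for t, pidx in comp.equations:
        target = spec.lv_names[t]
        lam = float(lambdas.get(target, 0.0))
        Rx = Rc[np.ix_(pidx, pidx)]
        rxy = Rc[pidx, t]
        beta = ridge_paths(Rx, rxy, lam) if method == "regplsc" else ols_paths(Rx, rxy)
        equations.append(
            EquationEstimate(
                target=target,
                parents=spec.parents(target),
                labels=spec.parent_labels(target),
                coefficients=np.asarray(beta, dtype=float),
                lam=lam if method == "regplsc" else 0.0,
            )
        )
    return PathEstimates(method=method, equations=equations)


def _reliability_vector(spec: ModelSpec, W: np.ndarray, R: np.ndarray) -> ReliabilityVector:
    rho = _rho_a_batch(W, R)
    values = pd.Series(rho, index=list(spec.lv_names))
    valid = (values > 0) & (values <= 1)
    return ReliabilityVector(values=values, valid=valid)


def _finish_fit(spec, method, ws, R, selection=None, lambdas=None) -> FitResult:
    comp = compile_model(spec)
    W = ws.matrix
    rel = _reliability_vector(spec, W, R)
    C = pd.DataFrame(W.T @ R @ W, index=list(spec.lv_names), columns=list(spec.lv_names))
    cc = disattenuate(C, rel)
    if method == "plsc" and not cc.positive_definite:
        raise SingularMatrixError(
            "consistent correlation matrix is not positive definite "
            f"(smallest eigenvalue {cc.smallest_eigenvalue:.3e}); PLSc cannot "
            "proceed — use method='regplsc'",
            smallest_eigenvalue=cc.smallest_eigenvalue,
        )
    if lambdas is None:
        lambdas = selection.lambdas if selection is not None else {}
    paths = _paths_from_consistent(spec, cc, method, lambdas)
    return FitResult(
        method=method,
        weights=ws,
        reliabilities=rel,
        proxy=C,
        consistent=cc,
        paths=paths,
        selection=selection,
    )


def fit(
    data,
    spec: ModelSpec,
    method: str = "plsc",
    *,
    scheme: str = "path",
    K: int | None = None,
    grid=None,
    seed=None,
    lambdas=None,
    per_equation: bool = True,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> FitResult:
    """Estimate a PLS path model consistently from data.

    ``method="plsc"`` uses per-equation OLS on the disattenuated latent
    correlations; ``method="regplsc"`` first selects a ridge parameter per
    endogenous equation by cross-validation (unless ``lambdas`` is given —
    a scalar or a ``{target: lambda}`` mapping) and then solves the ridge
    systems.
    """
    if method not in ("plsc", "regplsc"):
        raise ConfigError(f"unknown method {method!r}")
    comp = compile_model(spec)
    X = comp.align(data)
    already = isinstance(data, DataMatrix) and data.standardized
    Xs = X if already else standardize(X)
    R = (Xs.T @ Xs) / (Xs.shape[0] - 1)
    ws = estimate_weights_from_moments(R, spec, scheme, tol, max_iter)
    selection = None
    if method == "regplsc":
        if lambdas is None:
            selection = select_lambda(
                X, spec, K=K, grid=grid, seed=seed, scheme=scheme,
                per_equation=per_equation, tol=tol, max_iter=max_iter,
            )
        elif np.isscalar(lambdas):
            lambdas = {lv: float(lambdas) for lv in spec.endogenous}
    return _finish_fit(spec, method, ws, R, selection=selection, lambdas=lambdas)


def fit_from_moments(
    R,
    spec: ModelSpec,
    method: str = "plsc",
    *,
    scheme: str = "path",
    lambdas=0.0,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> FitResult:
    """Fit on an exact indicator correlation matrix (population analysis).

    Cross-validation needs observations, so for ``method="regplsc"`` the
    ridge parameter must be supplied (scalar or mapping; default 0, which
    coincides with PLSc).
    """
    if method not in ("plsc", "regplsc"):
        raise ConfigError(f"unknown method {method!r}")
    comp = compile_model(spec)
    if isinstance(R, pd.DataFrame):
        R = R.loc[list(comp.indicators), list(comp.indicators)].to_numpy()
    R = np.asarray(R, dtype=float)
    ws = estimate_weights_from_moments(R, spec, scheme, tol, max_iter)
    if np.isscalar(lambdas):
        lambdas = {lv: float(lambdas) for lv in spec.endogenous}
    return _finish_fit(spec, method, ws, R, lambdas=lambdas)
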