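"""Mode A indicator-weight estimation (the iterative PLS algorithm).

The engine turns a block-structured correlation matrix of indicators into
per-block weight vectors whose composites have unit variance.  It is the
first stage of consistent PLS: the weights feed the reliability coefficient
rho_A and the proxy (composite) correlations that are later disattenuated.

The numerical core operates on *moments* — an indicator correlation matrix —
and accepts a leading batch dimension, so that thousands of bootstrap
resamples or cross-validation folds can be iterated simultaneously.  Data
matrices are standardized (divisor N-1) and reduced to their correlation
matrix before entering the core.

Inner weighting schemes: ``"path"`` (regression weights on structural
predecessors, correlations with successors), ``"centroid"`` (signs of
composite correlations) and ``"factorial"`` (composite correlations).
Consistency of the downstream PLSc correction does not depend on the
scheme; ``"path"`` is the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConvergenceError, DegenerateDataError, SpecError
from .model_spec import ModelSpec

__all__ = [
    "DataMatrix",
    "WeightSet",
    "estimate_weights",
    "estimate_weights_from_moments",
    "composite_scores",
    "proxy_correlations",
    "standardize",
]

_SCHEMES = ("path", "centroid", "factorial")


def standardize(X: np.ndarray) -> np.ndarray:
    """Column-standardize to mean 0, unit variance (divisor N-1)."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0) or np.any(~np.isfinite(sd)):
        bad = np.where(~(sd > 0))[0]
        raise DegenerateDataError(f"zero-variance or non-finite column(s) at positions {bad.tolist()}")
    return (X - mu) / sd


@dataclass
class DataMatrix:
    """An N x p indicator data matrix with named columns.

    ``standardized`` records whether columns already have mean 0 and unit
    variance (divisor N-1); the engine standardizes internally otherwise.
    """

    values: np.ndarray
    columns: tuple[str, ...]
    standardized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DegenerateDataError("data must be a 2-d matrix")
        if self.values.shape[1] != len(self.columns):
            raise SpecError("number of columns does not match column ids")
        if not np.all(np.isfinite(self.values)):
            raise DegenerateDataError("data contains missing or non-finite values")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, standardized: bool = False) -> "DataMatrix":
        return cls(df.to_numpy(dtype=float), tuple(map(str, df.columns)), standardized)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def standardized_values(self) -> np.ndarray:
        return self.values if self.standardized else standardize(self.values)


@dataclass
class WeightSet:
    """Per-block Mode A weights normalized to unit composite variance."""

    spec: ModelSpec
    matrix: np.ndarray  # p x L, block-sparse
    n_iter: int
    converged: bool
    scheme: str = "path"

    @property
    def weights(self) -> dict[str, np.ndarray]:
        comp = compile_model(self.spec)
        return {
            lv: self.matrix[comp.block_idx[k], k]
            for k, lv in enumerate(self.spec.lv_names)
        }


class CompiledModel:
    """Index structures of a ModelSpec used by the numeric core."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.indicators = spec.indicators
        self.p = len(self.indicators)
        self.L = len(spec.lv_names)
        self.col_index = {name: i for i, name in enumerate(self.indicators)}
        lv_index = {lv: k for k, lv in enumerate(spec.lv_names)}
        self.lv_index = lv_index
        self.block_idx = [
            np.array([self.col_index[i] for i in spec.blocks[lv]]) for lv in spec.lv_names
        ]
        self.mask = np.zeros((self.p, self.L))
        for k, idx in enumerate(self.block_idx):
            self.mask[idx, k] = 1.0
        self.first_idx = np.array([idx[0] for idx in self.block_idx])
        self.adjacency = np.zeros((self.L, self.L), dtype=bool)
        for s, t, _ in spec.paths:
            self.adjacency[lv_index[s], lv_index[t]] = True
            self.adjacency[lv_index[t], lv_index[s]] = True
        self.isolated = ~self.adjacency.any(axis=1)
        # structural equations: (target index, parent indices) in topological order
        self.equations = [
            (lv_index[lv], np.array([lv_index[p] for p in spec.parents(lv)]))
            for lv in spec.topological_order
            if lv in spec.endogenous
        ]
        self.endo_idx = np.array([t for t, _ in self.equations])

    def align(self, data) -> np.ndarray:
        """Return the raw N x p array with columns in spec indicator order."""
        if isinstance(data, pd.DataFrame):
            missing = [c for c in self.indicators if c not in data.columns]
            if missing:
                raise SpecError(f"data is missing indicator column(s) {missing}")
            return data.loc[:, list(self.indicators)].to_numpy(dtype=float)
        if isinstance(data, DataMatrix):
            missing = [c for c in self.indicators if c not in data.columns]
            if missing:
                raise SpecError(f"data is missing indicator column(s) {missing}")
            order = [data.columns.index(c) for c in self.indicators]
            return data.values[:, order]
        X = np.asarray(data, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.p:
            raise SpecError(
                f"expected an array with {self.p} columns in spec indicator order"
            )
        return X


_COMPILE_CACHE: dict[int, CompiledModel] = {}


def compile_model(spec: ModelSpec) -> CompiledModel:
    comp = _COMPILE_CACHE.get(id(spec))
    if comp is None or comp.spec is not spec:
        comp = CompiledModel(spec)
        _COMPILE_CACHE[id(spec)] = comp
    return comp


def _solve_batch(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Batched linear solve with a pseudoinverse fallback for singular cases."""
    try:
        return np.linalg.solve(A, b[..., None])[..., 0]
    except np.linalg.LinAlgError:
        return (np.linalg.pinv(A) @ b[..., None])[..., 0]


def _inner_weights(C: np.ndarray, comp: CompiledModel, scheme: str) -> np.ndarray:
    """Inner weight matrix E with E[j, i] the weight of composite i in the
    inner proxy of latent variable j."""
    A = comp.adjacency
    if scheme == "centroid":
        E = np.sign(C) * A
    elif scheme == "factorial":
        E = C * A
    elif scheme == "path":
        E = C * A
        for t, pidx in comp.equations:
            sub = C[..., pidx[:, None], pidx[None, :]]
            rhs = C[..., pidx, t]
            E[..., t, pidx] = _solve_batch(sub, rhs)
    else:
        raise ValueError(f"unknown inner scheme {scheme!r}; choose from {_SCHEMES}")
    if comp.isolated.any():
        # a latent variable with no structural neighbours uses its own
        # composite as inner proxy
        iso = np.where(comp.isolated)[0]
        E[..., iso, iso] = 1.0
    return E


def _mode_a_core(
    R: np.ndarray,
    comp: CompiledModel,
    scheme: str = "path",
    tol: float = 1e-6,
    max_iter: int = 300,
    init: np.ndarray | None = None,
):
    """Iterate the Mode A fixed point on (a batch of) correlation matrices.

    Parameters
    ----------
    R : (..., p, p) array
        Indicator correlation matrices. Entries with NaNs are marked
        invalid rather than raising (used by bootstrap batching).

    Returns
    -------
    W : (..., p, L) weights; iterations : (...,) int; converged : (...,) bool;
    valid : (...,) bool  (False where the input moments were unusable)
    """
    R = np.asarray(R, dtype=float)
    squeeze = R.ndim == 2
    if squeeze:
        R = R[None]
    B = R.shape[:-2]
    Rf = R.reshape((-1,) + R.shape[-2:])
    nb = Rf.shape[0]
    valid = np.isfinite(Rf).all(axis=(1, 2))
    if not valid.all():
        Rf = Rf.copy()
        Rf[~valid] = np.eye(comp.p)

    if init is None:
        W = np.broadcast_to(comp.mask, (nb, comp.p, comp.L)).copy()
    else:
        W = (np.broadcast_to(init, (nb, comp.p, comp.L)) * comp.mask).copy()
    W, v0 = _normalize(W, Rf, comp)
    valid &= v0

    converged = np.zeros(nb, dtype=bool)
    iters = np.zeros(nb, dtype=int)
    for it in range(1, max_iter + 1):
        RW = Rf @ W
        C = np.swapaxes(W, -1, -2) @ RW
        E = _inner_weights(C, comp, scheme)
        Wn = (RW @ np.swapaxes(E, -1, -2)) * comp.mask
        Wn, vstep = _normalize(Wn, Rf, comp)
        valid &= vstep
        delta = np.abs(Wn - W).reshape(nb, -1).max(axis=1)
        W = Wn
        newly = ~converged & (delta < tol)
        iters[newly] = it
        converged |= newly
        if bool((converged | ~valid).all()):
            break
    iters[~converged] = max_iter
    converged &= valid
    W = W.reshape(B + (comp.p, comp.L))
    if squeeze:
        return W[0], int(iters[0]), bool(converged[0]), bool(valid[0])
    return (
        W,
        iters.reshape(B),
        converged.reshape(B),
        valid.reshape(B),
    )


def _normalize(W: np.ndarray, R: np.ndarray, comp: CompiledModel):
    """Scale each block so the composite variance w' R_bb w is 1 and the
    block weight sum is positive (ties broken by the first weight's sign)."""
    RW = R @ W
    d = (W * RW).sum(axis=-2)  # (nb, L) composite variances
    ok = (d > 1e-14).all(axis=-1)
    d = np.where(d > 1e-14, d, 1.0)
    W = W / np.sqrt(d)[..., None, :]
    s = np.sign(W.sum(axis=-2))
    first = W[..., comp.first_idx, np.arange(comp.L)]
    s = np.where(s == 0, np.sign(first), s)
    s = np.where(s == 0, 1.0, s)
    return W * s[..., None, :], ok


def estimate_weights_from_moments(
    R: np.ndarray | pd.DataFrame,
    spec: ModelSpec,
    scheme: str = "path",
    tol: float = 1e-6,
    max_iter: int = 300,
    init: np.ndarray | None = None,
) -> WeightSet:
    """Mode A weights from an exact indicator correlation matrix.

    This is the moments-mode entry point: supplying a population implied
    correlation matrix yields the population (probability-limit) weights,
    which supports analytic tests without sampling noise.
    """
    comp = compile_model(spec)
    if isinstance(R, pd.DataFrame):
        R = R.loc[list(comp.indicators), list(comp.indicators)].to_numpy()
    R = np.asarray(R, dtype=float)
    if R.shape != (comp.p, comp.p):
        raise SpecError(f"moment matrix must be {comp.p} x {comp.p}")
    if not np.all(np.isfinite(R)):
        raise DegenerateDataError("moment matrix contains non-finite values")
    W, it, conv, valid = _mode_a_core(R, comp, scheme, tol, max_iter, init)
    if not valid:
        raise DegenerateDataError("degenerate moments: a composite has zero variance")
    if not conv:
        raise ConvergenceError(
            f"Mode A weights did not converge in {max_iter} iterations",
            last_weights=W,
            n_iter=it,
        )
    return WeightSet(spec=spec, matrix=W, n_iter=it, converged=conv, scheme=scheme)


def estimate_weights(
    data,
    spec: ModelSpec,
    scheme: str = "path",
    tol: float = 1e-6,
    max_iter: int = 300,
    init: np.ndarray | None = None,
) -> WeightSet:
    """Mode A weights from an N x p data matrix (DataFrame, DataMatrix or
    array in spec indicator order). Standardizes internally (divisor N-1)."""
    comp = compile_model(spec)
    X = comp.align(data)
    if X.shape[0] < 3:
        raise DegenerateDataError("need at least 3 observations")
    already = isinstance(data, DataMatrix) and data.standardized
    Xs = X if already else standardize(X)
    R = (Xs.T @ Xs) / (Xs.shape[0] - 1)
    return estimate_weights_from_moments(R, spec, scheme, tol, max_iter, init)


def composite_scores(data, weights: WeightSet) -> pd.DataFrame:
    """Composite (latent variable proxy) scores, one column per latent.

    Scores are linear in the standardized data; when the weights were
    estimated on this same data each column has unit variance (divisor N-1).
    """
    comp = compile_model(weights.spec)
    if weights.matrix.shape != (comp.p, comp.L):
        raise SpecError("weight matrix does not match the spec's blocks")
    norms = np.abs(weights.matrix).sum(axis=0)
    if np.any(norms == 0):
        raise DegenerateDataError("a block has all-zero weights (normalization violated)")
    X = comp.align(data)
    already = isinstance(data, DataMatrix) and data.standardized
    Xs = X if already else standardize(X)
    Y = Xs @ weights.matrix
    return pd.DataFrame(Y, columns=list(weights.spec.lv_names))


def proxy_correlations(scores: pd.DataFrame) -> pd.DataFrame:
    """Correlation matrix of composite scores (symmetric, unit diagonal)."""
    Y = np.asarray(scores, dtype=float)
    if Y.shape[0] < 2:
        raise DegenerateDataError("need at least 2 rows to correlate scores")
    sd = Y.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise DegenerateDataError("constant score column")
    C = np.corrcoef(Y, rowvar=False)
    cols = list(scores.columns) if isinstance(scores, pd.DataFrame) else None
    return pd.DataFrame(C, index=cols, columns=cols)
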