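"""Model specification and population construction for PLS path models.

A PLS path model couples a reflective (Mode A) measurement model — latent
variables measured by blocks of observed indicators — with a recursive
(acyclic) structural model of directed paths among the latent variables.

This module defines:

* :class:`ModelSpec` — the measurement blocks, the directed structural
  graph and the correlations among exogenous latent variables;
* :class:`PopulationModel` — a fully parameterized population on the
  standardized scale (loadings, latent correlations, uniquenesses and the
  implied indicator covariance matrix);
* :class:`DesignCell` — one cell of the Monte Carlo design (sample size,
  collinearity level, composite reliability, coefficient of determination);
* builders that turn a design cell plus a table of standardized structural
  coefficients into a :class:`PopulationModel`.

The shipped coefficient table (``data/path_coefficients.csv``) holds the
standardized population path coefficients of the six-latent-variable
simulation model, one row per (phi, R^2) combination; users may supply their
own table with the same columns.
"""

from __future__ import annotations

import graphlib
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError, InvalidPopulationError, SpecError

__all__ = [
    "ModelSpec",
    "PopulationModel",
    "DesignCell",
    "loading_for_reliability",
    "equal_orthogonal_coefficient",
    "implied_latent_correlations",
    "implied_r2",
    "build_population",
    "load_coefficient_table",
    "simulation_model_spec",
    "DESIGN_LEVELS",
]

#: Factor levels of the Monte Carlo design (sample size, exogenous
#: correlation, composite reliability, coefficient of determination).
DESIGN_LEVELS = {
    "N": (30, 60, 120, 200),
    "phi": (0.4, 0.6, 0.8),
    "reliability": (0.6, 0.8),
    "r2": (0.25, 0.50),
}


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class ModelSpec:
    """Measurement blocks plus a recursive structural path graph.

    Parameters
    ----------
    lv_names
        Ordered latent-variable identifiers.
    blocks
        Mapping latent variable -> ordered list of indicator ids. Every
        block is reflective (Mode A) and must contain at least two
        indicators (the consistent reliability coefficient is undefined
        for a single indicator).
    paths
        Directed structural edges ``(source, target, label)``. The graph
        must be acyclic (recursive model, unidirectional effects only).
    exo_correlations
        Correlations between pairs of *exogenous* latent variables
        (no incoming paths), keyed by the unordered pair. Unlisted
        exogenous pairs are uncorrelated.
    """

    lv_names: tuple[str, ...]
    blocks: dict[str, tuple[str, ...]]
    paths: tuple[tuple[str, str, str], ...]
    exo_correlations: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        lvs = tuple(self.lv_names)
        object.__setattr__(self, "lv_names", lvs)
        if len(set(lvs)) != len(lvs):
            raise SpecError("duplicate latent variable names")
        blocks = {lv: tuple(inds) for lv, inds in self.blocks.items()}
        object.__setattr__(self, "blocks", blocks)
        if set(blocks) != set(lvs):
            raise SpecError("blocks must be given for exactly the latent variables")
        seen: set[str] = set()
        for lv, inds in blocks.items():
            if len(inds) < 2:
                raise SpecError(
                    f"block {lv!r} has {len(inds)} indicator(s); at least 2 are "
                    "required (reliability is undefined for a single indicator)"
                )
            overlap = seen.intersection(inds)
            if overlap or len(set(inds)) != len(inds):
                bad = sorted(overlap) or sorted(inds)
                raise SpecError(f"indicator(s) {bad} appear in more than one block")
            seen.update(inds)

        paths = tuple((str(s), str(t), str(lab)) for s, t, lab in self.paths)
        object.__setattr__(self, "paths", paths)
        for s, t, _ in paths:
            if s not in blocks or t not in blocks:
                raise SpecError(f"path ({s} -> {t}) references unknown latent variable")
            if s == t:
                raise SpecError(f"self-loop on {s!r}")
        labels = [lab for _, _, lab in paths]
        if len(set(labels)) != len(labels):
            raise SpecError("path labels must be unique")
        # cycle detection: the structural graph must be recursive
        ts = graphlib.TopologicalSorter({lv: [] for lv in lvs})
        for s, t, _ in paths:
            ts.add(t, s)
        try:
            order = tuple(ts.static_order())
        except graphlib.CycleError as exc:
            raise SpecError(f"structural graph is not recursive (cycle): {exc.args[1]}") from exc
        object.__setattr__(self, "_topo_order", order)

        exo = {}
        for pair, r in dict(self.exo_correlations).items():
            a, b = pair
            key = _pair_key(a, b)
            if a not in blocks or b not in blocks:
                raise SpecError(f"exo_correlations references unknown pair {pair}")
            if a == b:
                raise SpecError("exo_correlations keys must be distinct pairs")
            if not (a in self.exogenous and b in self.exogenous):
                raise SpecError(
                    f"exo_correlations pair {pair} includes an endogenous latent "
                    "variable (only source variables with no incoming paths allowed)"
                )
            if not -1.0 <= float(r) <= 1.0:
                raise SpecError(f"correlation for {pair} outside [-1, 1]")
            exo[key] = float(r)
        object.__setattr__(self, "exo_correlations", exo)

    # -- graph views ------------------------------------------------------

    @property
    def indicators(self) -> tuple[str, ...]:
        """All indicator ids, block by block, in spec order."""
        return tuple(i for lv in self.lv_names for i in self.blocks[lv])

    @property
    def exogenous(self) -> tuple[str, ...]:
        targets = {t for _, t, _ in self.paths}
        return tuple(lv for lv in self.lv_names if lv not in targets)

    @property
    def endogenous(self) -> tuple[str, ...]:
        targets = {t for _, t, _ in self.paths}
        return tuple(lv for lv in self.lv_names if lv in targets)

    @property
    def topological_order(self) -> tuple[str, ...]:
        return self._topo_order

    def parents(self, lv: str) -> tuple[str, ...]:
        """Direct structural predecessors of ``lv``, in path order."""
        return tuple(s for s, t, _ in self.paths if t == lv)

    def parent_labels(self, lv: str) -> tuple[str, ...]:
        return tuple(lab for _, t, lab in self.paths if t == lv)

    @property
    def path_labels(self) -> tuple[str, ...]:
        """All path labels ordered by (topological target, path order)."""
        out = []
        for lv in self.topological_order:
            for s, t, lab in self.paths:
                if t == lv:
                    out.append(lab)
        return tuple(out)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "latents": list(self.lv_names),
            "blocks": {lv: list(inds) for lv, inds in self.blocks.items()},
            "paths": [[s, t, lab] for s, t, lab in self.paths],
            "exo_correlations": {f"{a},{b}": r for (a, b), r in self.exo_correlations.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        try:
            lvs = list(d["latents"])
            blocks = {lv: list(v) for lv, v in d["blocks"].items()}
        except KeyError as exc:
            raise SpecError(f"model spec missing required key {exc}") from exc
        paths = []
        for edge in d.get("paths", []):
            if len(edge) == 2:
                s, t = edge
                lab = f"{s}->{t}"
            else:
                s, t, lab = edge[:3]
            paths.append((s, t, lab))
        exo = {}
        for key, r in (d.get("exo_correlations") or {}).items():
            if isinstance(key, str):
                a, b = (part.strip() for part in key.split(","))
            else:
                a, b = key
            exo[(a, b)] = float(r)
        return cls(tuple(lvs), blocks, tuple(paths), exo)

    @classmethod
    def from_file(cls, path) -> "ModelSpec":
        """Read a spec from a JSON or YAML file (by extension)."""
        text = open(path).read()
        if str(path).endswith((".yaml", ".yml")):
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s


@dataclass(frozen=True)
class PopulationModel:
    """A standardized-scale population: Sigma = Lambda Phi Lambda' + Theta."""

    spec: ModelSpec
    Lambda: np.ndarray  # indicators x latents loading matrix
    Phi: np.ndarray  # latent correlation matrix
    Theta: np.ndarray  # diagonal uniqueness matrix
    Sigma: np.ndarray  # implied indicator covariance (correlation) matrix

    def __post_init__(self):
        Sigma = self.Lambda @ self.Phi @ self.Lambda.T + self.Theta
        if not np.allclose(Sigma, self.Sigma, atol=1e-10):
            raise InvalidPopulationError("Sigma does not equal Lambda Phi Lambda' + Theta")
        if np.max(np.abs(np.diag(self.Sigma) - 1.0)) > 1e-10:
            raise InvalidPopulationError("Sigma diagonal is not 1 (unstandardized population)")
        if not np.allclose(self.Phi, self.Phi.T, atol=1e-12):
            raise InvalidPopulationError("Phi is not symmetric")
        if np.linalg.eigvalsh(self.Phi)[0] <= 0:
            raise InvalidPopulationError("Phi is not positive definite")
        theta = np.diag(self.Theta)
        if np.any(theta <= 0):
            raise InvalidPopulationError("non-positive uniqueness; loadings too large")

    @property
    def n_indicators(self) -> int:
        return self.Sigma.shape[0]


@dataclass(frozen=True)
class DesignCell:
    """One cell of the Monte Carlo design."""

    N: int
    phi: float
    reliability: float
    r2: float

    def label(self) -> str:
        return f"N={self.N},phi={self.phi},rel={self.reliability},r2={self.r2}"


def loading_for_reliability(rho: float, p: int) -> float:
    """Equal standardized loading giving a block composite reliability ``rho``.

    For ``p`` indicators sharing a loading ``lam`` on a unit-variance factor,
    the unit-weight composite has reliability
    ``(p lam)^2 / ((p lam)^2 + p (1 - lam^2))``.  Inverting gives
    ``lam = sqrt(rho / (p (1 - rho) + rho))``.
    """
    if not 0.0 < rho < 1.0:
        raise ValueError(f"composite reliability must lie in (0, 1); got {rho}")
    if p < 2:
        raise ValueError("need at least two indicators per block")
    lam = float(np.sqrt(rho / (p * (1.0 - rho) + rho)))
    # plug-back check of the closed form
    cr = (p * lam) ** 2 / ((p * lam) ** 2 + p * (1 - lam**2))
    assert abs(cr - rho) < 1e-10
    return lam


def equal_orthogonal_coefficient(r2: float, k: int = 2) -> float:
    """Common standardized coefficient of ``k`` mutually uncorrelated,
    equally weighted unit-variance predictors jointly explaining ``r2``
    of an outcome's variance: solves ``k c^2 = r2``."""
    if not 0.0 <= r2 < 1.0:
        raise ValueError("r2 must lie in [0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    return float(np.sqrt(r2 / k))


def implied_latent_correlations(
    spec: ModelSpec, coefficients: Mapping[str, float]
) -> pd.DataFrame:
    """Latent correlation matrix implied by standardized path coefficients.

    The structural system is standardized: every latent variable has unit
    variance, each endogenous variable's structural residual is sized so its
    total variance is one, and residuals are uncorrelated with all causally
    prior variables.  Correlations then follow from the reduced form by
    path tracing in topological order.

    Raises :class:`InvalidPopulationError` if any equation's coefficients
    imply an explained variance >= 1.
    """
    missing = set(spec.path_labels) - set(coefficients)
    if missing:
        raise SpecError(f"missing coefficients for path labels {sorted(missing)}")
    # exogenous first (they have no parents), then endogenous topologically
    order = tuple(spec.exogenous) + tuple(
        lv for lv in spec.topological_order if lv in spec.endogenous
    )
    idx = {lv: i for i, lv in enumerate(order)}
    L = len(order)
    Phi = np.zeros((L, L))
    placed: list[str] = []
    for lv in order:
        i = idx[lv]
        parents = spec.parents(lv)
        if not parents:  # exogenous: unit variance, listed correlations
            Phi[i, i] = 1.0
            for other in placed:
                if other in spec.exogenous:
                    r = spec.exo_correlations.get(_pair_key(lv, other), 0.0)
                    Phi[i, idx[other]] = Phi[idx[other], i] = r
        else:
            c = np.array([coefficients[lab] for lab in spec.parent_labels(lv)])
            pidx = [idx[p] for p in parents]
            explained = float(c @ Phi[np.ix_(pidx, pidx)] @ c)
            if explained >= 1.0:
                raise InvalidPopulationError(
                    f"equation for {lv!r} explains {explained:.3f} >= 1 of its "
                    "variance; no standardized population exists"
                )
            for other in placed:
                j = idx[other]
                Phi[i, j] = Phi[j, i] = float(c @ Phi[pidx, j])
            Phi[i, i] = 1.0
        placed.append(lv)
    # reorder to spec order
    perm = [idx[lv] for lv in spec.lv_names]
    Phi = Phi[np.ix_(perm, perm)]
    return pd.DataFrame(Phi, index=spec.lv_names, columns=spec.lv_names)


def implied_r2(spec: ModelSpec, coefficients: Mapping[str, float], target: str) -> float:
    """Explained variance of one endogenous equation implied by the
    standardized coefficients (quadratic form in the parents' correlations)."""
    if target not in spec.endogenous:
        raise SpecError(f"{target!r} is not endogenous")
    Phi = implied_latent_correlations(spec, coefficients)
    parents = list(spec.parents(target))
    c = np.array([coefficients[lab] for lab in spec.parent_labels(target)])
    Pp = Phi.loc[parents, parents].to_numpy()
    return float(c @ Pp @ c)


# ---------------------------------------------------------------------------
# The six-latent-variable simulation model
# ---------------------------------------------------------------------------

def simulation_model_spec(phi: float = 0.4, n_indicators: int = 4) -> ModelSpec:
    """The six-latent-variable population model of the Monte Carlo study.

    Three exogenous factors (xi1, xi2, xi3; corr(xi1, xi2) = ``phi``, xi3
    orthogonal) drive three endogenous factors::

        eta1 <- xi1 (gamma11), xi2 (gamma12)
        eta2 <- xi1 (gamma21), xi2 (gamma22 = 0, the null path), xi3 (gamma23)
        eta3 <- eta1 (beta31), eta2 (beta32)

    Each latent variable is measured by ``n_indicators`` reflective
    indicators.
    """
    lvs = ("xi1", "xi2", "xi3", "eta1", "eta2", "eta3")
    blocks = {lv: tuple(f"{lv}_x{j + 1}" for j in range(n_indicators)) for lv in lvs}
    paths = (
        ("xi1", "eta1", "gamma11"),
        ("xi2", "eta1", "gamma12"),
        ("xi1", "eta2", "gamma21"),
        ("xi2", "eta2", "gamma22"),
        ("xi3", "eta2", "gamma23"),
        ("eta1", "eta3", "beta31"),
        ("eta2", "eta3", "beta32"),
    )
    return ModelSpec(lvs, blocks, paths, {("xi1", "xi2"): phi})


def load_coefficient_table(path=None) -> pd.DataFrame:
    """Standardized population path coefficients keyed by (phi, r2).

    Defaults to the packaged table for the six-latent-variable model.
    """
    if path is None:
        with (resources.files("regplsc") / "data" / "path_coefficients.csv").open() as fh:
            table = pd.read_csv(fh)
    else:
        table = pd.read_csv(path)
    required = {"phi", "r2", "gamma11", "gamma12", "beta31", "beta32", "gamma21", "gamma23"}
    missing = required - set(table.columns)
    if missing:
        raise ConfigError(f"coefficient table missing columns {sorted(missing)}")
    return table


def coefficients_for_cell(cell: DesignCell, table: pd.DataFrame | None = None) -> dict[str, float]:
    """True standardized coefficients (including the null gamma22 = 0) for a cell."""
    if table is None:
        table = load_coefficient_table()
    rows = table[(np.isclose(table["phi"], cell.phi)) & (np.isclose(table["r2"], cell.r2))]
    if len(rows) != 1:
        raise ConfigError(
            f"coefficient table has {len(rows)} rows for phi={cell.phi}, r2={cell.r2}"
        )
    row = rows.iloc[0]
    coeffs = {
        lab: float(row[lab])
        for lab in ("gamma11", "gamma12", "gamma21", "gamma23", "beta31", "beta32")
    }
    coeffs["gamma22"] = 0.0
    return coeffs


def build_population(
    cell: DesignCell,
    table: pd.DataFrame | None = None,
    n_indicators: int = 4,
) -> PopulationModel:
    """Population model (Lambda, Phi, Theta, Sigma) for one design cell.

    All indicators load equally within a block with the loading solving the
    composite-reliability identity for ``cell.reliability``; Phi follows
    from the cell's true standardized path coefficients; Theta standardizes
    every indicator to unit variance.
    """
    spec = simulation_model_spec(phi=cell.phi, n_indicators=n_indicators)
    coeffs = coefficients_for_cell(cell, table)
    Phi = implied_latent_correlations(spec, coeffs).to_numpy()
    lam = loading_for_reliability(cell.reliability, n_indicators)
    L = len(spec.lv_names)
    p = n_indicators * L
    Lam = np.zeros((p, L))
    for k in range(L):
        Lam[k * n_indicators : (k + 1) * n_indicators, k] = lam
    common = Lam @ Phi @ Lam.T
    Theta = np.diag(1.0 - np.diag(common))
    Sigma = common + Theta
    if np.linalg.eigvalsh(Sigma)[0] <= 0:
        raise InvalidPopulationError(f"implied Sigma not positive definite for {cell.label()}")
    return PopulationModel(spec=spec, Lambda=Lam, Phi=Phi, Theta=Theta, Sigma=Sigma)
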