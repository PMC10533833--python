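"""Per-wave network estimation.

Two estimators, both scikit-learn style (``fit`` + trailing-underscore
fitted attributes):

* :class:`MixedGraphicalModel` — pairwise Markov random field over mixed
  gaussian/binary nodes, estimated by nodewise L1-penalized regressions
  (linear for gaussian nodes, logistic for binary nodes) with per-node
  EBIC lambda selection, then symmetrized by an AND/OR rule.
* :class:`EBICGraphLasso` — gaussian graphical model over the continuous
  nodes via the graphical lasso on the sample correlation matrix with
  EBIC model selection along a log-spaced lambda path; edges are partial
  correlations.

For a gaussian pair the two nodewise coefficients are
``b_ij = −θ_ij/θ_ii`` and ``b_ji = −θ_ij/θ_jj`` (standardized scale), so
their signed geometric mean ``sign·√(b_ij·b_ji) = −θ_ij/√(θ_ii·θ_jj)``
is exactly the partial correlation; that is the edge-weight convention
used here, which also bounds gaussian-gaussian weights in [−1, 1].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression

from ._solvers import glasso_path, lasso_path_gram
from .roster import NodeSpec

__all__ = [
    "MixedGraphicalModel",
    "EBICGraphLasso",
    "MGMNetwork",
    "GGMNetwork",
    "estimate_mgm",
    "estimate_ebic_glasso",
    "threshold_for_display",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class MGMNetwork:
    """Mixed-graphical-model network with estimation metadata."""

    nodes: list[str]
    weights: np.ndarray
    rule: str
    gamma: float
    lambda_selected: np.ndarray
    sign_conflicts: list[tuple[str, str]] = field(default_factory=list)

    def edge_list(self) -> pd.DataFrame:
        return _edge_list(self.nodes, self.weights)

    def to_csv(self, path: str | Path) -> None:
        self.edge_list().to_csv(path, index=False)

    def to_graphml(self, path: str | Path) -> None:
        _to_graphml(self.nodes, self.weights, path)


@dataclass
class GGMNetwork:
    """Partial-correlation network from the EBIC graphical lasso."""

    nodes: list[str]
    partial_correlations: np.ndarray
    gamma: float
    lambda_selected: float
    precision: np.ndarray | None = None

    @property
    def weights(self) -> np.ndarray:
        return self.partial_correlations

    def edge_list(self) -> pd.DataFrame:
        return _edge_list(self.nodes, self.partial_correlations)

    def to_csv(self, path: str | Path) -> None:
        self.edge_list().to_csv(path, index=False)

    def to_graphml(self, path: str | Path) -> None:
        _to_graphml(self.nodes, self.partial_correlations, path)


def _edge_list(nodes: list[str], w: np.ndarray) -> pd.DataFrame:
    rows = []
    p = len(nodes)
    for i in range(p):
        for j in range(i + 1, p):
            if w[i, j] != 0.0:
                rows.append({"node_i": nodes[i], "node_j": nodes[j], "weight": w[i, j]})
    return pd.DataFrame(rows, columns=["node_i", "node_j", "weight"])


def _to_graphml(nodes: list[str], w: np.ndarray, path: str | Path) -> None:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(nodes)
    p = len(nodes)
    for i in range(p):
        for j in range(i + 1, p):
            if w[i, j] != 0.0:
                g.add_edge(nodes[i], nodes[j], weight=float(w[i, j]))
    nx.write_graphml(g, path)


def threshold_for_display(
    network: MGMNetwork | GGMNetwork, cut: float = 0.15
) -> pd.DataFrame:
    """Edges with |weight| ≥ cut, for reporting/plotting only — the analysis
    network is left untouched."""
    if cut < 0:
        raise ValueError("cut must be non-negative")
    edges = network.edge_list()
    return edges[edges["weight"].abs() >= cut].reset_index(drop=True)


# ---------------------------------------------------------------------------
# mixed graphical model
# ---------------------------------------------------------------------------

def _ebic(loglik: float, k: int, n: int, p_other: int, gamma: float) -> float:
    return -2.0 * loglik + k * np.log(n) + 2.0 * gamma * k * max(np.log(p_other), 0.0)


class MixedGraphicalModel(BaseEstimator):
    """Nodewise EBIC-penalized estimation of a mixed pairwise MRF.

    Parameters
    ----------
    gamma : EBIC hyperparameter (0 = plain BIC; larger = sparser).
    rule : "and" keeps an edge only when both nodewise coefficients are
        nonzero; "or" keeps it when either is.
    n_lambda, lambda_min_ratio : log-spaced per-node lambda grid from the
        node's lambda_max (smallest lambda with an empty model) down to
        lambda_min_ratio·lambda_max.
    lambda_grid : optional explicit grid (one array used for every node),
        overriding the automatic grid — used for bootstrap path-bound reuse
        and for the unregularized limit.

    All columns (including binary ones) are standardized internally as
    predictors so cross-family weights share a scale; binary responses are
    regressed on the 0/1 scale with logistic models.
    """

    def __init__(
        self,
        gamma: float = 0.25,
        rule: str = "and",
        n_lambda: int = 50,
        lambda_min_ratio: float = 0.01,
        lambda_grid: np.ndarray | None = None,
        ebic_patience: int = 8,
    ):
        self.gamma = gamma
        self.rule = rule
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.lambda_grid = lambda_grid
        self.ebic_patience = ebic_patience

    def fit(self, X: pd.DataFrame | np.ndarray, binary: list | None = None):
        if self.rule not in ("and", "or"):
            raise ValueError("rule must be 'and' or 'or'")
        if isinstance(X, pd.DataFrame):
            nodes = list(X.columns)
            mat = X.to_numpy(dtype=float)
        else:
            mat = np.asarray(X, dtype=float)
            nodes = [f"x{i}" for i in range(mat.shape[1])]
        n, p = mat.shape
        if n < 50:
            warnings.warn(f"n = {n} < 50: estimates may be unstable", stacklevel=2)
        binary = binary or []
        bin_idx = {nodes.index(b) if isinstance(b, str) else int(b) for b in binary}

        sd = mat.std(axis=0, ddof=0)
        const = np.flatnonzero(sd == 0.0)
        if const.size:
            raise ValueError(f"constant column(s): {[nodes[i] for i in const]}")
        z = (mat - mat.mean(axis=0)) / sd

        gram = z.T @ z / n  # shared Gram matrix: every nodewise problem reads from it
        coef = np.zeros((p, p))  # coef[j, k]: coefficient of node k predicting node j
        lam_sel = np.zeros(p)
        lam_max = np.zeros(p)
        for j in range(p):
            others = [k for k in range(p) if k != j]
            if j in bin_idx:
                zj = z[:, others]
                y = mat[:, j]
                lam_max[j] = np.max(np.abs(zj.T @ (y - y.mean()))) / n
                lam_sel[j], coef[j, others] = self._fit_logistic_node(zj, y, n, p, lam_max[j])
            else:
                g = gram[np.ix_(others, others)]
                c = gram[j, others]
                lam_max[j] = np.max(np.abs(c))
                lam_sel[j], coef[j, others] = self._fit_gaussian_node(g, c, n, p, lam_max[j])

        w = np.zeros((p, p))
        conflicts: list[tuple[str, str]] = []
        for i in range(p):
            for j in range(i + 1, p):
                b1, b2 = coef[i, j], coef[j, i]
                if b1 != 0.0 and b2 != 0.0:
                    if np.sign(b1) != np.sign(b2):
                        conflicts.append((nodes[i], nodes[j]))
                        continue
                    w[i, j] = w[j, i] = np.sign(b1) * np.sqrt(b1 * b2)
                elif self.rule == "or" and (b1 != 0.0 or b2 != 0.0):
                    w[i, j] = w[j, i] = b1 + b2  # exactly one is nonzero

        self.nodes_ = nodes
        self.weights_ = w
        self.coef_matrix_ = coef
        self.lambda_selected_ = lam_sel
        self.lambda_max_ = lam_max
        self.sign_conflicts_ = conflicts
        self.n_samples_ = n
        return self

    # -- per-node fits ------------------------------------------------------

    def _grid(self, lam_max: float) -> np.ndarray:
        if self.lambda_grid is not None:
            return np.sort(np.asarray(self.lambda_grid, dtype=float))[::-1]
        lam_max = max(lam_max, 1e-10)
        return np.logspace(
            np.log10(lam_max), np.log10(lam_max * self.lambda_min_ratio), self.n_lambda
        )

    def _fit_gaussian_node(self, g, c, n, p, lam_max):
        # Gram-based lasso path: the standardized response has unit variance,
        # so RSS/n = 1 - 2 b'c + b'Gb without touching the data again
        grid = self._grid(lam_max)
        coefs = lasso_path_gram(g, c, grid)
        best = (np.inf, grid[0], np.zeros(g.shape[0]))
        for a, lam in enumerate(grid):
            b = coefs[a]
            sigma2 = max(1.0 - 2.0 * b @ c + b @ g @ b, 1e-12)
            ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
            k = int(np.count_nonzero(b))
            score = _ebic(ll, k, n, p - 1, self.gamma)
            if score < best[0]:
                best = (score, lam, b)
        return best[1], best[2]

    def _fit_logistic_node(self, zj, y, n, p, lam_max):
        grid = self._grid(lam_max)
        best = (np.inf, grid[0], np.zeros(zj.shape[1]))
        since_best = 0
        for lam in grid:
            clf = LogisticRegression(
                l1_ratio=1.0,
                C=1.0 / (n * lam),
                solver="liblinear",
                intercept_scaling=50.0,
                max_iter=100,
                tol=1e-5,
            )
            clf.fit(zj, y)
            b = clf.coef_.ravel()
            eta = clf.decision_function(zj)
            # stable bernoulli loglik: -log(1+exp(-eta)) for y=1 etc.
            ll = float(-np.logaddexp(0.0, -np.where(y == 1, eta, -eta)).sum())
            k = int(np.count_nonzero(b))
            score = _ebic(ll, k, n, p - 1, self.gamma)
            if score < best[0]:
                best = (score, lam, b)
                since_best = 0
            else:
                # EBIC is quasi-convex along the path; once it has moved
                # past its minimum for a while, stop refitting
                since_best += 1
                if since_best >= self.ebic_patience:
                    break
        return best[1], best[2]


# ---------------------------------------------------------------------------
# EBIC graphical lasso
# ---------------------------------------------------------------------------

class EBICGraphLasso(BaseEstimator):
    """Gaussian graphical model via the graphical lasso with EBIC selection.

    The sample correlation matrix is fed to the graphical lasso over a
    log-spaced lambda path from lambda_max (largest off-diagonal absolute
    correlation, giving an empty model) downward; the lambda minimizing
    EBIC_γ = −n(log det Θ − tr(SΘ)) + E·log n + 4γ·E·log p is selected,
    where E counts nonzero off-diagonal precision entries.  Edges of the
    returned network are partial correlations ρ_ij = −θ_ij/√(θ_ii θ_jj).
    """

    def __init__(
        self,
        gamma: float = 0.5,
        n_lambda: int = 100,
        lambda_min_ratio: float = 0.01,
        lambdas: np.ndarray | None = None,
        tol: float = 1e-4,
        max_iter: int = 100,
        ebic_patience: int = 10,
    ):
        self.gamma = gamma
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.lambdas = lambdas
        self.tol = tol
        self.max_iter = max_iter
        self.ebic_patience = ebic_patience

    def fit(self, X: pd.DataFrame | np.ndarray):
        if isinstance(X, pd.DataFrame):
            nodes = list(X.columns)
            mat = X.to_numpy(dtype=float)
        else:
            mat = np.asarray(X, dtype=float)
            nodes = [f"x{i}" for i in range(mat.shape[1])]
        n, p = mat.shape
        if p < 3:
            raise ValueError("need at least 3 continuous nodes")
        s = np.corrcoef(mat, rowvar=False)
        if np.isnan(s).any():
            raise ValueError("correlation matrix has NaN (constant column?)")

        if self.lambdas is not None:
            grid = np.sort(np.asarray(self.lambdas, dtype=float))[::-1]
        else:
            lam_max = max(np.max(np.abs(s - np.eye(p))), 1e-4)
            grid = np.logspace(
                np.log10(lam_max), np.log10(lam_max * self.lambda_min_ratio), self.n_lambda
            )

        best = None
        ebic_path, lam_path = [], []
        since_best = 0
        for lam, prec in glasso_path(s, grid, max_iter=self.max_iter, tol=self.tol):
            off = prec[np.triu_indices(p, 1)]
            e = int(np.count_nonzero(np.abs(off) > 1e-8))
            sign, logdet = np.linalg.slogdet(prec)
            if sign <= 0:  # pragma: no cover
                log.warning("non-PD precision at lambda=%.4g, skipped", lam)
                continue
            ebic = -n * (logdet - np.trace(s @ prec)) + e * np.log(n) + 4.0 * self.gamma * e * np.log(p)
            ebic_path.append(ebic)
            lam_path.append(lam)
            if best is None or ebic < best[0]:
                best = (ebic, lam, prec)
                since_best = 0
            else:
                # EBIC is quasi-convex along the path; stop once it has
                # moved past its minimum for a while
                since_best += 1
                if since_best >= self.ebic_patience:
                    break
        if best is None:
            raise RuntimeError("graphical lasso failed on the whole lambda path")

        _, lam_sel, prec = best
        d = np.sqrt(np.diag(prec))
        pc = -prec / np.outer(d, d)
        np.fill_diagonal(pc, 0.0)
        pc[np.abs(pc) < 1e-8] = 0.0

        self.nodes_ = nodes
        self.precision_ = prec
        self.partial_corr_ = pc
        self.lambda_ = float(lam_sel)
        self.lambda_path_ = np.asarray(lam_path)
        self.ebic_path_ = np.asarray(ebic_path)
        self.n_samples_ = n
        return self


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def estimate_mgm(
    wave_data: pd.DataFrame,
    roster: list[NodeSpec],
    gamma: float = 0.25,
    rule: str = "and",
    lambda_grid: np.ndarray | None = None,
    n_lambda: int = 50,
) -> MGMNetwork:
    """Fit the mixed graphical model on one wave's complete rows."""
    cols = [n.code for n in roster if n.code in wave_data.columns]
    binary = [n.code for n in roster if n.is_binary and n.code in cols]
    est = MixedGraphicalModel(
        gamma=gamma, rule=rule, lambda_grid=lambda_grid, n_lambda=n_lambda
    ).fit(wave_data[cols], binary=binary)
    return MGMNetwork(
        nodes=est.nodes_,
        weights=est.weights_,
        rule=rule,
        gamma=gamma,
        lambda_selected=est.lambda_selected_,
        sign_conflicts=est.sign_conflicts_,
    )


def estimate_ebic_glasso(
    wave_data: pd.DataFrame,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambdas: np.ndarray | None = None,
) -> GGMNetwork:
    """Fit the EBIC graphical lasso on the continuous columns supplied."""
    est = EBICGraphLasso(gamma=gamma, n_lambda=n_lambda, lambdas=lambdas).fit(wave_data)
    return GGMNetwork(
        nodes=est.nodes_,
        partial_correlations=est.partial_corr_,
        gamma=gamma,
        lambda_selected=est.lambda_,
        precision=est.precision_,
    )
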