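"""Graphical Gaussian co-expression networks.

Edges are shrinkage partial correlations; edge selection uses an
empirical-null local false discovery rate. The null density of a sample
correlation built on kappa effective degrees of freedom is

    f0(r; kappa) = (1 - r^2)^((kappa-3)/2) / B(1/2, (kappa-1)/2),

and the observed partial correlations are modeled as the two-component
mixture f(r) = eta0 * f0(r; kappa) + (1 - eta0) * fA(r) with a
nonparametric, |r|-monotone (Grenander-style) alternative fA. The local fdr
of an edge is eta0 * f0(r) / f(r), capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, special
from sklearn.base import BaseEstimator
from sklearn.isotonic import IsotonicRegression

from .synthdata import ExpressionMatrix

__all__ = ["shrink_correlation", "partial_correlations",
           "CorrelationNullMixture", "fit_local_fdr",
           "GraphicalGaussianNetwork", "GGMNetwork", "build_network"]


def shrink_correlation(X) -> tuple[np.ndarray, float]:
    """Schaefer-Strimmer shrinkage of the sample correlation matrix toward
    the identity: ``R* = lambda*I + (1-lambda)*R`` with the analytic
    variance-minimizing intensity ``lambda = sum var(r_ij) / sum r_ij^2``
    over off-diagonal entries, clipped to [0, 1].

    Returns (R*, lambda); R* is positive definite whenever lambda > 0.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("need >= 3 samples")
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError(f"constant column at index {int(np.argmax(sd == 0))}")
    Z = (X - X.mean(axis=0)) / sd
    R = Z.T @ Z / (n - 1)
    np.fill_diagonal(R, 1.0)
    # var of r_ij from the empirical variance of the products z_i*z_j
    W2 = (Z ** 2).T @ (Z ** 2)
    Wbar = Z.T @ Z / n
    var_r = n / (n - 1) ** 3 * (W2 - n * Wbar ** 2)
    off = ~np.eye(p, dtype=bool)
    denom = (R[off] ** 2).sum()
    lam = 1.0 if denom == 0 else float(np.clip(var_r[off].sum() / denom, 0, 1))
    R_star = lam * np.eye(p) + (1 - lam) * R
    return R_star, lam


def partial_correlations(R_star: np.ndarray) -> np.ndarray:
    """Full-inverse partial correlations ``-omega_ij / sqrt(omega_ii *
    omega_jj)`` from a positive definite correlation matrix; unit diagonal."""
    R_star = np.asarray(R_star, dtype=float)
    try:
        omega = np.linalg.inv(R_star)
    except np.linalg.LinAlgError as err:
        raise ValueError("correlation matrix is singular") from err
    d = np.sqrt(np.diag(omega))
    P = -omega / np.outer(d, d)
    np.fill_diagonal(P, 1.0)
    return P


def _log_f0(r: np.ndarray, kappa: float) -> np.ndarray:
    return ((kappa - 3) / 2) * np.log1p(-r ** 2) \
        - special.betaln(0.5, (kappa - 1) / 2)


class CorrelationNullMixture(BaseEstimator):
    """Empirical-null local-fdr fit for partial correlations.

    The null parameters are estimated from the central bulk of the
    distribution, where true edges contribute almost nothing: ``kappa`` by
    truncated maximum likelihood on |r| below the ``central_quantile``, and
    the null proportion ``eta0`` by matching the observed central mass to
    the null's. The marginal density of |r| is estimated by a
    Grenander-style monotone-decreasing histogram fit on the observed
    scale, and the local fdr ``eta0 * f0 / f`` is made monotone
    nonincreasing in |r| (signal lives in the tails) and capped at 1.
    """

    def __init__(self, n_bins: int = 40, central_quantile: float = 0.75):
        self.n_bins = n_bins
        self.central_quantile = central_quantile

    def fit(self, r, y=None):
        r = np.asarray(r, dtype=float).ravel()
        if r.size < 100:
            raise ValueError(f"need >= 100 values, got {r.size}")
        r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
        r_abs = np.abs(r)
        if float(r_abs.max()) < 1e-8:
            # fully shrunk / constant input: no evidence for any edge
            self.eta0_ = 1.0
            self.kappa_ = np.inf
            self._edges = np.linspace(0.0, 1.0, self.n_bins + 1)
            self._density = None
            self._fdr_grid = np.ones(self.n_bins)
            self.fdr_ = np.ones(r.shape)
            return self
        rmax = float(r_abs.max()) * (1 + 1e-9) + 1e-12
        self._edges = np.linspace(0.0, rmax, self.n_bins + 1)

        r0 = float(np.quantile(r_abs, self.central_quantile))
        r0 = max(r0, 1e-8)
        central = r[r_abs <= r0]

        def neg_trunc_loglik(log_kappa):
            k = np.exp(log_kappa) + 3.0
            logF0 = np.log(max(special.betainc(0.5, (k - 1) / 2, r0 ** 2),
                               1e-300))
            return -(_log_f0(central, k).sum() - central.size * logF0)

        opt = optimize.minimize_scalar(neg_trunc_loglik,
                                       bounds=(np.log(1e-3), np.log(1e7)),
                                       method="bounded")
        if not opt.success:
            raise RuntimeError("null degrees-of-freedom fit did not "
                               f"converge: {opt.message}")
        kappa = float(np.exp(opt.x) + 3.0)
        # conservative null proportion: best central-mass match over a
        # ladder of cutoffs (overestimating eta0 inflates the fdr, never
        # deflates it)
        est = []
        for q in (0.5, 0.75, 0.9):
            rq = max(float(np.quantile(r_abs, q)), 1e-8)
            Fq = float(special.betainc(0.5, (kappa - 1) / 2, rq ** 2))
            est.append((r_abs <= rq).mean() / max(Fq, 1e-12))
        eta0 = float(np.clip(max(est), 1e-6, 1.0))

        # Grenander-style monotone-decreasing density of |r|
        counts, _ = np.histogram(r_abs, bins=self._edges)
        width = self._edges[1] - self._edges[0]
        dens = counts / (r.size * width)
        centers = (self._edges[:-1] + self._edges[1:]) / 2
        iso = IsotonicRegression(increasing=False)
        dens = iso.fit_transform(centers, dens, sample_weight=counts + 1e-9)
        dens = np.maximum(dens, 1e-300)
        dens /= dens.sum() * width

        # local fdr on the bin grid, forced nonincreasing in |r|
        g0 = 2 * np.exp(_log_f0(centers, kappa))   # density of |r| under f0
        grid = np.minimum(eta0 * g0 / np.maximum(dens, 1e-300), 1.0)
        grid = np.minimum.accumulate(grid)

        self.eta0_ = eta0
        self.kappa_ = kappa
        self._density = dens
        self._fdr_grid = grid
        self.fdr_ = self.local_fdr(r)
        return self

    def local_fdr(self, r) -> np.ndarray:
        r_abs = np.abs(np.clip(np.asarray(r, dtype=float),
                               -1 + 1e-12, 1 - 1e-12))
        idx = np.clip(np.digitize(r_abs, self._edges) - 1,
                      0, self.n_bins - 1)
        out = self._fdr_grid[idx]
        # beyond the fitted range the null density keeps falling
        beyond = r_abs >= self._edges[-1]
        if np.any(beyond):
            scale = np.exp(_log_f0(r_abs[beyond], self.kappa_)
                           - _log_f0(self._edges[-1] * (1 - 1e-9),
                                     self.kappa_))
            out = out.astype(float)
            out[beyond] = self._fdr_grid[-1] * np.minimum(scale, 1.0)
        return np.minimum(out, 1.0)


def fit_local_fdr(pcors) -> tuple[float, float, np.ndarray]:
    """Functional facade: returns (eta0, kappa, local fdr per value)."""
    m = CorrelationNullMixture().fit(pcors)
    return m.eta0_, m.kappa_, m.fdr_


@dataclass
class GGMNetwork:
    """Inferred co-expression network for one response."""

    nodes: list[str]
    edges: pd.DataFrame        # gene_a, gene_b, pcor, local_fdr
    eta0: float
    kappa: float
    threshold: float
    response_label: str | None = None
    shrinkage: float = field(default=np.nan)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.gene_a, row.gene_b, pcor=row.pcor,
                       local_fdr=row.local_fdr)
        return g


class GraphicalGaussianNetwork(BaseEstimator):
    """Shrinkage-GGM network estimator.

    ``fit`` takes a samples x genes matrix (DataFrame or array), computes the
    shrunk correlation matrix, its partial correlations, fits the local-fdr
    mixture on the off-diagonal values, and keeps edges with local fdr at or
    below ``threshold``.
    """

    def __init__(self, threshold: float = 1e-13,
                 response_label: str | None = None):
        self.threshold = threshold
        self.response_label = response_label

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            genes = [str(g) for g in X.columns]
            M = X.to_numpy(float)
        else:
            M = np.asarray(X, dtype=float)
            genes = [f"V{i}" for i in range(M.shape[1])]
        if M.shape[1] < 3:
            raise ValueError("need at least 3 genes")
        R_star, lam = shrink_correlation(M)
        P = partial_correlations(R_star)
        iu = np.triu_indices_from(P, k=1)
        pcors = P[iu]
        mix = CorrelationNullMixture().fit(pcors)
        fdr = mix.local_fdr(pcors)
        keep = fdr <= self.threshold
        edges = pd.DataFrame({
            "gene_a": np.asarray(genes)[iu[0][keep]],
            "gene_b": np.asarray(genes)[iu[1][keep]],
            "pcor": pcors[keep],
            "local_fdr": fdr[keep]})
        self.genes_ = genes
        self.shrinkage_ = lam
        self.pcor_ = P
        self.eta0_ = mix.eta0_
        self.kappa_ = mix.kappa_
        self.mixture_ = mix
        self.edges_ = edges
        self.network_ = GGMNetwork(nodes=genes, edges=edges,
                                   eta0=mix.eta0_, kappa=mix.kappa_,
                                   threshold=self.threshold,
                                   response_label=self.response_label,
                                   shrinkage=lam)
        return self


def build_network(gene_set, expr, threshold: float = 1e-13,
                  response_label: str | None = None) -> GGMNetwork:
    """shrink -> pcor -> local fdr pipeline over ``gene_set``.

    ``expr`` may be an :class:`ExpressionMatrix` or a genes x samples
    DataFrame; isolated genes stay in the node list.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    gene_set = list(gene_set)
    if len(gene_set) < 3:
        raise ValueError("gene set must contain at least 3 genes")
    missing = set(gene_set) - set(values.index)
    if missing:
        raise KeyError(f"genes absent from expression: {sorted(missing)[:5]}")
    X = values.loc[gene_set].T
    est = GraphicalGaussianNetwork(threshold=threshold,
                                   response_label=response_label).fit(X)
    return est.network_
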