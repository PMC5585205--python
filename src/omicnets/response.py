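"""Transcriptional response analysis on a factorial design.

Identifies, per gene, the three responses of a two-condition x multi-time
factorial experiment — treatment, time, and their interaction — and derives
per-time-point up/down response clusters from standardized treatment-minus-
control differences combined with Welch tests under Benjamini-Hochberg FDR
control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .synthdata import ExpressionMatrix

__all__ = ["welch_test", "bh_adjust", "fit_factorial", "cluster_responses",
           "ResponseClusterer", "select_response_genes"]


def welch_test(a, b) -> tuple[float, float]:
    """Welch two-sample t with Satterthwaite degrees of freedom.

    Degenerate inputs are resolved deterministically: equal-mean groups with
    zero variance give ``(0.0, 1.0)``; unequal means with zero variance give
    ``p = 0`` (an infinitely confident difference on these data).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return np.inf if a.mean() > b.mean() else -np.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    NaNs propagate and are excluded from the number of tests ``m``.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        if (p[ok] < 0).any() or (p[ok] > 1).any():
            raise ValueError("p-values must lie in [0, 1]")
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def _anova_f(Y: np.ndarray, X_full: np.ndarray, X_red: np.ndarray,
             X_denom: np.ndarray | None = None
             ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized nested-model F tests, one per column of Y.

    The numerator compares ``X_red`` against ``X_full``; the denominator
    mean square comes from ``X_denom`` (default ``X_full``) — classical
    type II tests use the residual of the model including the interaction.
    """

    def rss(X):
        Q, _ = np.linalg.qr(X)
        resid = Y - Q @ (Q.T @ Y)
        return (resid ** 2).sum(axis=0), X.shape[0] - np.linalg.matrix_rank(X)

    rss_f, df_f = rss(X_full)
    rss_r, df_r = rss(X_red)
    rss_d, df_d = (rss_f, df_f) if X_denom is None else rss(X_denom)
    df_num = df_r - df_f
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss_r - rss_f) / df_num) / (rss_d / df_d)
    p = stats.f.sf(f, df_num, df_d)
    # zero residual variance (e.g. constant gene): undefined, report p = 1
    p = np.where(np.isfinite(f), p, 1.0)
    return np.where(np.isfinite(f), f, 0.0), p


def fit_factorial(expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene two-way fixed-effects model (treatment, time, interaction).

    Main effects are tested by dropping the factor from the additive model
    (type II); the interaction is the full model against the additive one.
    Returns a frame indexed by gene with ``{factor}_F``, ``{factor}_p`` and
    BH-adjusted ``{factor}_q`` for factors treatment/time/interaction.
    """
    meta = expr.metadata.loc[expr.samples]
    cond = pd.Categorical(meta["condition"])
    time = pd.Categorical(meta["timepoint"])
    cells = pd.crosstab(cond, time)
    if (cells.values == 0).any():
        missing = [(str(r), str(c)) for r in cells.index for c in cells.columns
                   if cells.loc[r, c] == 0]
        raise ValueError(f"factorial design has empty cells: {missing}")

    C = pd.get_dummies(cond, drop_first=True).to_numpy(float)
    T = pd.get_dummies(time, drop_first=True).to_numpy(float)
    inter = np.einsum("ni,nj->nij", C, T).reshape(len(meta), -1)
    ones = np.ones((len(meta), 1))
    X_add = np.hstack([ones, C, T])
    X_full = np.hstack([X_add, inter])
    Y = expr.values.to_numpy(float).T

    constant = Y.var(axis=0) <= 1e-24
    out = pd.DataFrame(index=expr.values.index)
    for name, red, full in (("treatment", np.hstack([ones, T]), X_add),
                            ("time", np.hstack([ones, C]), X_add),
                            ("interaction", X_add, X_full)):
        f, p = _anova_f(Y, full, red, X_denom=X_full)
        f[constant] = 0.0   # zero-variance gene: nothing to explain
        p[constant] = 1.0
        out[f"{name}_F"] = f
        out[f"{name}_p"] = p
        out[f"{name}_q"] = bh_adjust(p)
    return out


def cluster_responses(expr: ExpressionMatrix, z_hi: float = 1.0,
                      z_lo: float = -1.0, alpha: float = 0.05,
                      fdr: float = 0.10, treatment: str | None = None
                      ) -> pd.DataFrame:
    """Per-time-point up/down response clusters.

    For each time point the per-gene treatment-minus-control mean difference
    is standardized across genes (Z), a Welch test compares the two condition
    groups per gene, and BH controls the FDR across genes. A gene is labeled
    ``up`` when Z > ``z_hi``, Welch p < ``alpha`` and q <= ``fdr``; ``down``
    symmetrically below ``z_lo``; otherwise ``none``.

    Returns a long frame: gene, timepoint, z, welch_p, welch_q, label.
    """
    if expr.values.shape[0] < 2:
        raise ValueError("need >= 2 genes to standardize differences")
    meta = expr.metadata.loc[expr.samples]
    conditions = sorted(meta["condition"].unique())
    if len(conditions) != 2:
        raise ValueError("exactly two conditions required")
    if treatment is None:
        treatment = "IL1B" if "IL1B" in conditions else conditions[0]
    control = next(c for c in conditions if c != treatment)

    frames = []
    for tp in meta["timepoint"].unique():
        sel = meta["timepoint"] == tp
        a = expr.values.loc[:, (sel & (meta["condition"] == treatment)).values]
        b = expr.values.loc[:, (sel & (meta["condition"] == control)).values]
        if a.shape[1] == 0 or b.shape[1] == 0:
            raise ValueError(f"both conditions required at timepoint {tp}")
        diff = a.mean(axis=1) - b.mean(axis=1)
        sd = diff.std(ddof=1)
        z = (diff - diff.mean()) / sd if sd > 0 else diff * 0.0
        tt = stats.ttest_ind(a.to_numpy(float), b.to_numpy(float),
                             axis=1, equal_var=False)
        p = np.where(np.isnan(tt.pvalue) & (diff.abs() < 1e-300),
                     1.0, tt.pvalue)
        # zero-variance unequal means: infinitely confident on these data
        p = np.where(np.isnan(p), 0.0, p)
        q = bh_adjust(p)
        label = np.where((z > z_hi) & (p < alpha) & (q <= fdr), "up",
                         np.where((z < z_lo) & (p < alpha) & (q <= fdr),
                                  "down", "none"))
        frames.append(pd.DataFrame({
            "gene": expr.values.index, "timepoint": tp, "z": z.values,
            "welch_p": p, "welch_q": q, "label": label}))
    return pd.concat(frames, ignore_index=True)


class ResponseClusterer(BaseEstimator):
    """Estimator wrapper around :func:`cluster_responses`.

    Parameters mirror the function; after :meth:`fit`, ``clusters_`` holds
    the long label frame and ``contrasts_`` the factorial test table.
    """

    def __init__(self, z_hi: float = 1.0, z_lo: float = -1.0,
                 alpha: float = 0.05, fdr: float = 0.10):
        self.z_hi = z_hi
        self.z_lo = z_lo
        self.alpha = alpha
        self.fdr = fdr

    def fit(self, expr: ExpressionMatrix, y=None):
        self.contrasts_ = fit_factorial(expr)
        self.clusters_ = cluster_responses(expr, z_hi=self.z_hi,
                                           z_lo=self.z_lo, alpha=self.alpha,
                                           fdr=self.fdr)
        return self

    def labels_at(self, timepoint: str) -> pd.Series:
        sub = self.clusters_[self.clusters_["timepoint"] == timepoint]
        return sub.set_index("gene")["label"]


def select_response_genes(contrasts: pd.DataFrame, response: str,
                          q_max: float = 0.05, cap: int = 500) -> list[str]:
    """Genes feeding the co-expression network of one response: BH q <=
    ``q_max`` within that response, capped at the top ``cap`` by F."""
    sub = contrasts[contrasts[f"{response}_q"] <= q_max]
    sub = sub.sort_values(f"{response}_F", ascending=False)
    return list(sub.index[:cap])
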