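"""Genotype QC and genotype-phenotype statistics.

Covers the genetic side of the pipeline: minor-allele-frequency and
call-rate filtering, minor-allele presence (dominant) coding, covariate
balance between genotype groups, single-SNP linear association, a
self-contained permutation SNP-set test (sum of -log10 p over the set,
null from phenotype permutations), and the homozygous-minor versus rest
eQTL group comparison.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .response import bh_adjust

__all__ = ["qc_filter", "maf", "presence_coding", "group_covariate_tests",
           "snp_association", "geneset_joint_association", "eqtl_group_test"]


def maf(counts) -> tuple[float, bool]:
    """Minor allele frequency from 0/1/2 counts, folded to <= 0.5.

    Returns (maf, flipped); ``flipped`` records that the coded allele was
    actually the major one.
    """
    c = np.asarray(counts, dtype=float)
    c = c[~np.isnan(c)]
    if c.size == 0:
        raise ValueError("no non-missing genotypes")
    f = c.sum() / (2 * c.size)
    if f > 0.5:
        return 1.0 - f, True
    return float(f), False


def call_rate(counts) -> float:
    c = np.asarray(counts, dtype=float)
    return float((~np.isnan(c)).mean())


def qc_filter(gt: pd.DataFrame, maf_min: float = 0.05,
              call_min: float = 0.99) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop SNPs failing MAF or call-rate thresholds.

    Returns (filtered table, per-SNP QC report with kept flag).
    """
    rows = []
    for snp in gt.columns:
        c = gt[snp].to_numpy(float)
        cr = call_rate(c)
        try:
            f, _ = maf(c)
        except ValueError:
            f = np.nan
        rows.append((snp, f, cr, bool(f >= maf_min and cr >= call_min)))
    report = pd.DataFrame(rows, columns=["snp", "maf", "call_rate", "kept"])
    kept = report.loc[report["kept"], "snp"]
    return gt[list(kept)], report


def presence_coding(counts) -> np.ndarray:
    """Dominant coding: 1 when at least one minor allele, NA propagates."""
    c = np.asarray(counts, dtype=float)
    out = (c >= 1).astype(float)
    out[np.isnan(c)] = np.nan
    return out


def group_covariate_tests(covariates: pd.DataFrame, group) -> pd.DataFrame:
    """Per-covariate comparison between two genotype groups.

    Continuous covariates get Welch t, binary ones Fisher's exact test;
    BH across covariates.
    """
    group = np.asarray(group, dtype=float)
    g1, g0 = group == 1, group == 0
    if g1.sum() == 0 or g0.sum() == 0:
        raise ValueError("both groups must be non-empty")
    rows = []
    for col in covariates.columns:
        x = covariates[col].to_numpy(float)
        vals = np.unique(x[~np.isnan(x)])
        if set(vals) <= {0.0, 1.0}:
            table = [[np.nansum(x[g1] == 1), np.nansum(x[g1] == 0)],
                     [np.nansum(x[g0] == 1), np.nansum(x[g0] == 0)]]
            _, p = stats.fisher_exact(table)
            kind = "fisher"
        else:
            a, b = x[g1], x[g0]
            if np.nanvar(a) == 0 and np.nanvar(b) == 0 \
                    and np.nanmean(a) == np.nanmean(b):
                p = 1.0
            else:
                _, p = stats.ttest_ind(a[~np.isnan(a)], b[~np.isnan(b)],
                                       equal_var=False)
            kind = "welch"
        rows.append((col, kind, float(p)))
    out = pd.DataFrame(rows, columns=["covariate", "test", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def _ols_assoc(y: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    """Simple OLS of y on x with intercept; returns (beta, t, p)."""
    ok = ~(np.isnan(y) | np.isnan(x))
    y, x = y[ok], x[ok]
    n = y.size
    if n < 3:
        raise ValueError("need >= 3 complete observations")
    vx = x.var()
    if vx == 0:
        raise ValueError("genotype has no variance")
    beta = np.cov(x, y, bias=True)[0, 1] / vx
    a = y.mean() - beta * x.mean()
    resid = y - a - beta * x
    s2 = (resid ** 2).sum() / (n - 2)
    se = np.sqrt(s2 / (n * vx))
    if se == 0:
        return float(beta), np.inf, 0.0
    t = beta / se
    p = 2 * stats.t.sf(abs(t), n - 2)
    return float(beta), float(t), float(p)


def snp_association(pheno, geno_vector, coding: str = "presence"
                    ) -> tuple[float, float, float]:
    """Linear model of the phenotype on one coded SNP.

    ``coding='presence'`` uses minor-allele presence (dominant model);
    ``'additive'`` uses the raw allele count. Returns (beta, t, p).
    """
    y = np.asarray(pheno, dtype=float)
    x = np.asarray(geno_vector, dtype=float)
    if coding == "presence":
        x = presence_coding(x)
    elif coding != "additive":
        raise ValueError(f"unknown coding {coding!r}")
    return _ols_assoc(y, x)


def _assoc_p_matrix(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Vectorized two-sided OLS slope p-values.

    ``Y``: draws x subjects phenotype matrix; ``X``: subjects x snps.
    The slope t-test equals the Pearson correlation t-test, which
    vectorizes as a single matrix product. Requires complete data.
    """
    n = X.shape[0]
    Xc = (X - X.mean(axis=0)) / X.std(axis=0)
    Yc = (Y - Y.mean(axis=1, keepdims=True))
    Yc /= np.maximum(Y.std(axis=1, keepdims=True), 1e-300)
    r = Yc @ Xc / n
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt((n - 2) / (1 - r ** 2))
    return 2 * stats.t.sf(np.abs(t), n - 2)


def geneset_joint_association(pheno, gt: pd.DataFrame, snp_set,
                              n_perm: int = 1000, seed: int | None = None
                              ) -> tuple[float, float]:
    """Self-contained permutation SNP-set test.

    Statistic: sum over the set of -log10 p from the additive single-SNP
    association. Null: the same statistic after permuting the phenotype
    across subjects. Returns (observed statistic, empirical p).
    """
    snp_set = [s for s in snp_set if s in gt.columns]
    if not snp_set:
        raise ValueError("SNP set empty after QC/intersection")
    y = np.asarray(pheno, dtype=float)
    X = gt[snp_set].to_numpy(float)
    ok = ~np.isnan(y)
    ok &= ~np.isnan(X).any(axis=1)
    y, X = y[ok], X[ok]
    if (X.std(axis=0) == 0).any():
        keep = X.std(axis=0) > 0
        X = X[:, keep]
        if X.shape[1] == 0:
            raise ValueError("no polymorphic SNPs left in the set")
    rng = np.random.default_rng(seed)

    obs = float(-np.log10(_assoc_p_matrix(y[None, :], X)).sum())
    perms = np.stack([rng.permutation(y) for _ in range(n_perm)])
    null = -np.log10(_assoc_p_matrix(perms, X)).sum(axis=1)
    p = (1 + int((null >= obs).sum())) / (1 + n_perm)
    return obs, p


def eqtl_group_test(expr_vector, counts) -> tuple[float, float, float, float]:
    """Homozygous-minor versus other genotypes expression comparison.

    Pooled-variance Student t, two-sided. Returns
    (t, p, mean homozygous-minor, mean rest).
    """
    e = np.asarray(expr_vector, dtype=float)
    c = np.asarray(counts, dtype=float)
    ok = ~(np.isnan(e) | np.isnan(c))
    e, c = e[ok], c[ok]
    hom = c == 2
    if hom.sum() < 2 or (~hom).sum() < 2:
        raise ValueError(
            f"need >= 2 subjects per group; got {int(hom.sum())} "
            f"homozygous-minor and {int((~hom).sum())} others")
    t, p = stats.ttest_ind(e[hom], e[~hom], equal_var=True)
    return float(t), float(p), float(e[hom].mean()), float(e[~hom].mean())
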