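"""Over-representation statistics: hypergeometric category enrichment,
transcription-factor target enrichment, multi-set overlap testing, and
disorder-promoting amino-acid composition.

The hypergeometric upper tail is computed by exact summation in log space —
it is the primitive every enrichment table here rests on.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import special, stats

from .response import bh_adjust

__all__ = ["hypergeom_tail", "enrich_table", "tf_target_enrichment",
           "multiset_overlap_test", "disorder_enrichment",
           "DISORDER_PROMOTING"]

#: disorder-promoting amino acids (Dunker consensus)
DISORDER_PROMOTING = frozenset("ARGQSPEK")


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), by exact log-space
    summation of C(K, i) C(N-K, n-i) / C(N, n) over i = k .. min(K, n)."""
    if not (0 <= k <= min(K, n) <= N) or n > N or K > N:
        raise ValueError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    hi = min(K, n)
    i = np.arange(k, hi + 1)
    log_terms = (_log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, n))
    return float(min(1.0, np.exp(special.logsumexp(log_terms))))


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return (special.gammaln(n + 1) - special.gammaln(k + 1)
            - special.gammaln(n - k + 1))


def enrich_table(query, gmt: dict, universe, alpha_adj: float = 0.01
                 ) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of ``query`` in every GMT
    category, BH-adjusted across categories.

    ``gmt`` maps category -> (description, members); categories are
    intersected with the universe, and empty ones dropped with a warning.
    """
    universe = set(universe)
    query = set(query)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    N, n = len(universe), len(query)
    rows = []
    for name, (_, members) in gmt.items():
        cat = set(members) & universe
        if not cat:
            warnings.warn(f"category {name!r} empty after intersection "
                          "with universe; dropped")
            continue
        k = len(cat & query)
        rows.append((name, k, len(cat), n, N,
                     hypergeom_tail(k, len(cat), n, N)))
    out = pd.DataFrame(rows, columns=["category", "k", "K", "n", "N", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    out["significant"] = out["q"] <= alpha_adj
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def tf_target_enrichment(tf_targets: dict, module, universe,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Per-TF hypergeometric enrichment of target sets in a module; the
    significance flag uses the nominal p at ``alpha``."""
    out = enrich_table(set(module) & set(universe), tf_targets, universe,
                       alpha_adj=alpha)
    out["significant"] = out["p"] < alpha
    return out


def multiset_overlap_test(sets, universe, n_mc: int = 10000,
                          seed: int | None = None) -> float:
    """Significance of the joint intersection of >= 2 gene sets.

    Two sets: exact hypergeometric tail on the overlap. Three or more:
    Monte-Carlo with each set resampled uniformly from the universe at its
    own size; p = (1 + exceedances) / (1 + n_mc).
    """
    sets = [set(s) for s in sets]
    if len(sets) < 2:
        raise ValueError("need >= 2 sets")
    universe = sorted(set(universe))
    for s in sets:
        if len(s) > len(universe) or not s <= set(universe):
            raise ValueError("every set must fit inside the universe")
    observed = len(set.intersection(*sets))
    if len(sets) == 2:
        a, b = sets
        return hypergeom_tail(observed, len(a), len(b), len(universe))
    if observed == 0:
        return 1.0
    rng = np.random.default_rng(seed)
    uni = np.array(universe)
    sizes = [len(s) for s in sets]
    exceed = 0
    for _ in range(n_mc):
        inter = set(rng.choice(uni, size=sizes[0], replace=False))
        for sz in sizes[1:]:
            inter &= set(rng.choice(uni, size=sz, replace=False))
            if len(inter) < 1:
                break
        exceed += len(inter) >= observed
    return (1 + exceed) / (1 + n_mc)


def disorder_fraction(seq: str) -> float:
    """Fraction of residues that are disorder-promoting."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    return sum(c in DISORDER_PROMOTING for c in seq) / len(seq)


def disorder_enrichment(fasta: dict[str, str], set_a, set_b
                        ) -> tuple[float, float, float, float]:
    """Student t comparison of disorder-promoting residue fractions between
    two protein groups; returns (t, p, mean_a, mean_b)."""
    set_a, set_b = list(set_a), list(set_b)
    if len(set_a) < 2 or len(set_b) < 2:
        raise ValueError("each group needs >= 2 proteins")
    for pid in (*set_a, *set_b):
        if pid not in fasta:
            raise KeyError(f"protein {pid!r} absent from FASTA")
    fa = [disorder_fraction(fasta[p]) for p in set_a]
    fb = [disorder_fraction(fasta[p]) for p in set_b]
    t, p = stats.ttest_ind(fa, fb, equal_var=True)
    return float(t), float(p), float(np.mean(fa)), float(np.mean(fb))
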