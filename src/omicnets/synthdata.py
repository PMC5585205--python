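"""Synthetic benchmark data with planted, recorded ground truth.

Generates every input the pipeline consumes — a two-condition x four-time-point
factorial expression matrix drawn from a graphical Gaussian model with a sparse
planted precision matrix, a background interactome with a planted hub module
and a planted biclique module, annotation sets enriched in those modules, and
genotypes with one planted phenotype-associated SNP and one planted cis-eQTL —
so every downstream stage has a recovery-based test surface.

All randomness flows from one seed through named generator streams, so each
output is reproducible on its own.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["SimConfig", "SyntheticTruth", "ExpressionMatrix",
           "gen_expression", "gen_interactome", "gen_annotations",
           "gen_genotypes"]

#: target marginal SD of log2 expression between replicates
MARGINAL_SD = 0.5
#: fraction of genes assigned to each of the four response clusters
CLUSTER_FRACTION = 0.075

_STREAMS = {"expression": 1, "interactome": 2, "annotations": 3,
            "genotypes": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed),
                               spawn_key=(_STREAMS[stream],)))


@dataclass
class SimConfig:
    """Parameters of the synthetic study design."""

    n_genes: int = 200
    n_samples_per_cell: int = 6      # replicates per condition x timepoint
    timepoints: tuple[str, ...] = ("P1", "P5", "P10", "P45")
    conditions: tuple[str, str] = ("IL1B", "PBS")
    cluster_effect: float = 1.0      # log2-scale shift of planted clusters
    network_model: str = "scale-free"   # scale-free | small-world | hub-star
    precision_offdiag: float = 0.4
    n_background_ppi_nodes: int = 200
    star_size: int = 10
    biclique_dims: tuple[int, int] = (6, 6)
    n_snps: int = 50
    n_subjects: int = 271
    causal_beta: float = 0.8
    eqtl_gamma: float = 1.0
    maf_range: tuple[float, float] = (0.1, 0.4)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_genes", "n_samples_per_cell", "n_background_ppi_nodes",
                     "star_size", "n_snps", "n_subjects"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not np.isfinite(self.cluster_effect):
            raise ValueError("cluster_effect must be finite")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie inside (0, 0.5]")
        if self.network_model not in ("scale-free", "small-world", "hub-star"):
            raise ValueError(f"unknown network_model {self.network_model!r}")
        if any(d < 2 for d in self.biclique_dims):
            raise ValueError("biclique_dims must each be >= 2")
        if self.star_size < 3:
            raise ValueError("star_size must be >= 3")


@dataclass
class SyntheticTruth:
    """Record of everything that was planted."""

    planted_edges: set[tuple[str, str]] = field(default_factory=set)
    cluster_membership: dict[str, str] = field(default_factory=dict)
    planted_modules: dict[str, set[str]] = field(default_factory=dict)
    hub: str | None = None
    enriched_categories: dict[str, str] = field(default_factory=dict)
    tf_set: str | None = None
    causal_snp: str | None = None
    causal_effect: float = 0.0
    eqtl_snp: str | None = None
    eqtl_effect: float = 0.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["planted_edges"] = sorted(map(list, self.planted_edges))
        d["planted_modules"] = {k: sorted(v)
                                for k, v in self.planted_modules.items()}
        return d


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with factorial sample metadata."""

    values: pd.DataFrame     # genes x samples
    metadata: pd.DataFrame   # sample -> condition, timepoint, replicate

    def __post_init__(self):
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        missing = set(self.values.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
        for col in ("condition", "timepoint", "replicate"):
            if col not in self.metadata.columns:
                raise ValueError(f"metadata lacks column {col!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


# ------------------------------------------------------------------ expression

def _planted_graph(cfg: SimConfig, rng: np.random.Generator) -> nx.Graph:
    n = cfg.n_genes
    if cfg.network_model == "scale-free":
        # configuration-model power law with exponent 2 (the degree
        # exponent co-expression networks are reported to show), truncated
        # at the natural sqrt(n) cutoff
        kmax = max(3, int(np.ceil(np.sqrt(n))))
        ks = np.arange(1, kmax + 1)
        p = ks ** -2.0
        p /= p.sum()
        deg = rng.choice(ks, size=n, p=p)
        if deg.sum() % 2:
            deg[int(np.argmax(deg == 1))] += 1
        return _simple_configuration_model([int(d) for d in deg], rng)
    seed = int(rng.integers(2**31 - 1))
    if cfg.network_model == "small-world":
        return nx.watts_strogatz_graph(n, 4, 0.1, seed=seed)
    # hub-star: one hub wired to min(10, n-1) genes, the rest isolated
    g = nx.empty_graph(n)
    g.add_edges_from((0, i) for i in range(1, min(11, n)))
    return g


def planted_precision(cfg: SimConfig,
                      rng: np.random.Generator | None = None
                      ) -> tuple[np.ndarray, nx.Graph]:
    """Sparse precision matrix with +/-``precision_offdiag`` on graph edges.

    The unit diagonal is inflated only as far as strict diagonal dominance
    requires: ``diag_i = max(1, row-sum of |off-diagonals|) + 0.1``. Keeping
    the inflation minimal keeps the planted partial correlations on a
    common scale across degrees, so every planted edge carries comparable,
    detectable signal.
    """
    rng = rng if rng is not None else _rng(cfg.seed, "expression")
    graph = _planted_graph(cfg, rng)
    n = cfg.n_genes
    omega = np.zeros((n, n))
    for i, j in graph.edges():
        sign = rng.choice([-1.0, 1.0])
        omega[i, j] = omega[j, i] = sign * cfg.precision_offdiag
    rowsum = np.abs(omega).sum(axis=1)
    np.fill_diagonal(omega, np.maximum(1.0, rowsum) + 0.1)
    try:
        np.linalg.cholesky(omega)
    except np.linalg.LinAlgError as err:  # pragma: no cover - by construction
        raise ValueError(
            "planted precision matrix is not positive definite; "
            f"min eigenvalue {np.linalg.eigvalsh(omega).min():.3g}") from err
    return omega, graph


def gen_expression(cfg: SimConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw the factorial expression matrix and record the plants.

    Samples come from N(0, Omega^-1) rescaled to marginal SD
    :data:`MARGINAL_SD`; genes of the four planted clusters (up/down at
    P1/P5) get a mean shift of +/-``cluster_effect`` in the IL1B samples at
    their assigned time point.
    """
    rng = _rng(cfg.seed, "expression")
    omega, graph = planted_precision(cfg, rng)
    sigma = np.linalg.inv(omega)
    scale = MARGINAL_SD / np.sqrt(np.diag(sigma))
    sigma = sigma * np.outer(scale, scale)
    chol = np.linalg.cholesky(sigma)

    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    cells = list(itertools.product(cfg.conditions, cfg.timepoints))
    n_total = len(cells) * cfg.n_samples_per_cell
    X = rng.standard_normal((n_total, cfg.n_genes)) @ chol.T

    sample_ids, meta_rows = [], []
    for k, (cond, tp) in enumerate(cells):
        for r in range(cfg.n_samples_per_cell):
            sample_ids.append(f"{cond}_{tp}_r{r + 1}")
            meta_rows.append((cond, tp, r + 1))
    meta = pd.DataFrame(meta_rows, index=pd.Index(sample_ids, name="sample"),
                        columns=["condition", "timepoint", "replicate"])

    # planted response clusters at the two early time points
    k = max(3, round(CLUSTER_FRACTION * cfg.n_genes))
    labels = ["up_P1", "down_P1", "up_P5", "down_P5"]
    chosen = rng.choice(cfg.n_genes, size=min(4 * k, cfg.n_genes),
                        replace=False)
    membership = {g: "null" for g in genes}
    treated = meta["condition"] == cfg.conditions[0]
    for li, label in enumerate(labels):
        idx = chosen[li * k:(li + 1) * k]
        tp = label.split("_")[1]
        sign = 1.0 if label.startswith("up") else -1.0
        rows = np.flatnonzero(treated & (meta["timepoint"] == tp).values)
        for gi in idx:
            membership[genes[gi]] = label
            X[rows, gi] += sign * cfg.cluster_effect

    values = pd.DataFrame(X.T, index=pd.Index(genes, name="gene"),
                          columns=sample_ids)
    truth = SyntheticTruth(
        planted_edges={(genes[min(i, j)], genes[max(i, j)])
                       for i, j in graph.edges()},
        cluster_membership=membership)
    return ExpressionMatrix(values, meta), truth


# ----------------------------------------------------------------- interactome

#: truncated power-law degree law for the background interactome
BACKGROUND_GAMMA = 2.5
BACKGROUND_KMAX = 8


def _background_degrees(n: int, rng: np.random.Generator) -> list[int]:
    ks = np.arange(1, BACKGROUND_KMAX + 1)
    p = ks ** -BACKGROUND_GAMMA
    p /= p.sum()
    deg = rng.choice(ks, size=n, p=p)
    if deg.sum() % 2:
        deg[int(np.argmax(deg == 1)) if (deg == 1).any() else 0] += 1
    return [int(d) for d in deg]


def _simple_configuration_model(degrees, rng, max_tries=5000,
                                forbid_bicliques=False) -> nx.Graph:
    """Configuration model accepted only when simple, so the emitted degree
    sequence exactly matches the prescription.

    With ``forbid_bicliques`` the draw is additionally rejected when any two
    nodes share two or more neighbors (a K_{2,2} seed). A planted-module
    benchmark needs its module-level truth to be unique, and a chance
    biclique in the background would be a real, unplanted module.
    """
    for _ in range(max_tries):
        seed = int(rng.integers(2**31 - 1))
        g = nx.configuration_model(degrees, seed=seed)
        if nx.number_of_selfloops(g) > 0 or \
                max((c for *_, c in g.edges(keys=True)), default=0) > 0:
            continue
        g = nx.Graph(g)
        if forbid_bicliques:
            A = nx.to_numpy_array(g)
            shared = (A @ A) * (1 - np.eye(len(A)))
            if shared.max() >= 2:
                continue
        return g
    raise RuntimeError("configuration model: no acceptable simple graph "
                       f"in {max_tries} tries")


def gen_interactome(cfg: SimConfig) -> tuple[nx.Graph, SyntheticTruth]:
    """Background PPI graph with two planted modules.

    The hub module mirrors a star-of-modules: one hub protein connected to
    every module member, with the members split into two sub-modules that
    are also fully connected box-to-box. The second module is a complete
    bipartite graph K_{a,b}. Both are disjoint from each other and from the
    configuration-model background.
    """
    rng = _rng(cfg.seed, "interactome")
    a, b = cfg.biclique_dims
    need = 1 + cfg.star_size + a + b
    if need > cfg.n_background_ppi_nodes:
        raise ValueError(
            f"planted modules need {need} nodes, exceeding the background "
            f"budget of {cfg.n_background_ppi_nodes}")

    g = nx.Graph()
    hub = "HUB01"
    star = [f"SM{i:02d}" for i in range(1, cfg.star_size + 1)]
    half = cfg.star_size // 2
    for m in star:
        g.add_edge(hub, m)
    g.add_edges_from(itertools.product(star[:half], star[half:]))
    side_a = [f"BA{i:02d}" for i in range(1, a + 1)]
    side_b = [f"BB{i:02d}" for i in range(1, b + 1)]
    g.add_edges_from(itertools.product(side_a, side_b))

    bg_deg = _background_degrees(cfg.n_background_ppi_nodes, rng)
    bg = _simple_configuration_model(bg_deg, rng, forbid_bicliques=True)
    mapping = {i: f"BG{i:03d}" for i in bg.nodes()}
    g = nx.union(g, nx.relabel_nodes(bg, mapping))

    for u, v in g.edges():
        g[u][v]["confidence"] = float(np.round(rng.uniform(0.5, 1.0), 4))

    truth = SyntheticTruth(
        planted_modules={"SPN1": {hub, *star}, "SPN2": {*side_a, *side_b}},
        hub=hub)
    return g, truth


# ----------------------------------------------------------------- annotations

def gen_annotations(cfg: SimConfig, truth: SyntheticTruth,
                    q: float = 0.8, tf_overlap: float = 0.6,
                    pad_frac: float = 0.05
                    ) -> dict[str, tuple[str, list[str]]]:
    """GMT category per planted module (fraction ``q`` of members plus a
    ``pad_frac`` share of background proteins as padding) and one TF-target
    set overlapping the hub module."""
    if not truth.planted_modules:
        raise ValueError("truth carries no planted modules")
    rng = _rng(cfg.seed, "annotations")
    background = [f"BG{i:03d}" for i in range(cfg.n_background_ppi_nodes)]
    sets: dict[str, tuple[str, list[str]]] = {}
    for label, members in sorted(truth.planted_modules.items()):
        if not members:
            import warnings
            warnings.warn(f"module {label} is empty; skipped")
            continue
        members = sorted(members)
        n_in = max(1, round(q * len(members)))
        inside = list(rng.choice(members, size=n_in, replace=False))
        n_pad = max(0, round(pad_frac * len(background)))
        pad = list(rng.choice(background, size=n_pad, replace=False))
        name = f"CAT_{label}"
        sets[name] = (f"category enriched in {label}", sorted(inside) + sorted(pad))
        truth.enriched_categories[name] = label

    hub_modules = [lbl for lbl, mem in sorted(truth.planted_modules.items())
                   if truth.hub in mem] or \
        [lbl for lbl, mem in sorted(truth.planted_modules.items()) if mem]
    star = sorted(truth.planted_modules[hub_modules[0]])
    n_tf = max(1, round(tf_overlap * len(star)))
    targets = list(rng.choice(star, size=n_tf, replace=False))
    pad = list(rng.choice(background, size=n_tf, replace=False))
    sets["TF01_targets"] = ("planted transcription-factor target set",
                            sorted(targets) + sorted(pad))
    truth.tf_set = "TF01_targets"
    return sets


# ------------------------------------------------------------------- genotypes

def gen_genotypes(cfg: SimConfig
                  ) -> tuple[pd.DataFrame, pd.Series, pd.Series, SyntheticTruth]:
    """Hardy-Weinberg genotypes, phenotype with one causal SNP (additive on
    minor-allele presence), and an expression trait with one cis-eQTL."""
    if cfg.n_snps < 2:
        raise ValueError("need at least 2 SNPs")
    rng = _rng(cfg.seed, "genotypes")
    lo, hi = cfg.maf_range
    mafs = rng.uniform(lo, hi, size=cfg.n_snps)
    counts = rng.binomial(2, mafs[None, :],
                          size=(cfg.n_subjects, cfg.n_snps)).astype(float)
    subjects = [f"SUB{i:04d}" for i in range(cfg.n_subjects)]
    snps = [f"rs{i + 1:05d}" for i in range(cfg.n_snps)]
    gt = pd.DataFrame(counts, index=pd.Index(subjects, name="subject"),
                      columns=snps)
    if cfg.missing_rate > 0:
        mask = rng.random(gt.shape) < cfg.missing_rate
        gt = gt.mask(mask)

    causal, eqtl = rng.choice(cfg.n_snps, size=2, replace=False)
    presence = (counts[:, causal] >= 1).astype(float)
    pheno = pd.Series(cfg.causal_beta * presence
                      + rng.standard_normal(cfg.n_subjects),
                      index=gt.index, name="phenotype")
    expr = pd.Series(cfg.eqtl_gamma * counts[:, eqtl]
                     + rng.standard_normal(cfg.n_subjects),
                     index=gt.index, name="expression")
    truth = SyntheticTruth(causal_snp=snps[causal],
                           causal_effect=cfg.causal_beta,
                           eqtl_snp=snps[eqtl], eqtl_effect=cfg.eqtl_gamma)
    return gt, pheno, expr, truth
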