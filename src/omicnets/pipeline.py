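"""End-to-end orchestration: simulate -> response clustering -> GGM networks
-> topology -> power graph / SPNs -> PPI significance -> enrichment ->
genetics, with a deterministic JSON report and a provenance manifest.

When the run starts from simulated data the report also contains recovery
metrics against the recorded ground truth (was the planted hub recovered,
planted-edge AUC, rank of the planted category).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score

from . import io as onio
from .synthdata import (SimConfig, gen_expression, gen_interactome,
                        gen_annotations, gen_genotypes)
from .response import ResponseClusterer, select_response_genes
from .ggm import build_network, GraphicalGaussianNetwork
from .topology import summarize_topology
from .powergraph import power_graph_analysis, edge_reduction
from .ppi import permutation_test
from .enrich import enrich_table, tf_target_enrichment
from .genetics import (qc_filter, snp_association, geneset_joint_association,
                       eqtl_group_test)

__all__ = ["PipelineConfig", "run_pipeline"]

_KNOWN_KEYS = {"seed", "out_dir", "sim", "ggm_threshold", "n_perm",
               "n_rand", "stages"}
_ALL_STAGES = ("simulate", "respond", "ggm", "topology", "powergraph",
               "ppi", "enrich", "genetics")


@dataclass
class PipelineConfig:
    seed: int = 1
    out_dir: str = "pipeline_out"
    sim: dict = field(default_factory=dict)
    #: desk-scale default; the full-data operating point is 1e-13
    ggm_threshold: float = 1e-2
    n_perm: int = 1000
    n_rand: int = 50
    stages: tuple[str, ...] = _ALL_STAGES

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        bad = set(cfg.stages) - set(_ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        need = {"respond": "simulate", "ggm": "respond",
                "topology": "ggm", "powergraph": "simulate",
                "ppi": "powergraph", "enrich": "powergraph",
                "genetics": "simulate"}
        for stage, dep in need.items():
            if stage in cfg.stages and dep not in cfg.stages:
                raise ValueError(f"stage {stage!r} requires {dep!r}")
        return cfg


def _round_floats(obj, nd=10):
    if isinstance(obj, float):
        return round(obj, nd)
    if isinstance(obj, dict):
        return {k: _round_floats(v, nd) for k, v in sorted(obj.items())}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, nd) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), nd)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_pipeline(cfg: PipelineConfig) -> dict:
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim_cfg = SimConfig(**{"seed": cfg.seed, **cfg.sim})
    report: dict = {"seed": cfg.seed}
    artifacts: dict[str, str] = {}

    expr, expr_truth = gen_expression(sim_cfg)
    net, ppi_truth = gen_interactome(sim_cfg)
    gmt = gen_annotations(sim_cfg, ppi_truth)
    gt, pheno, eqtl_expr, gen_truth = gen_genotypes(sim_cfg)

    onio.write_expression(out_dir / "expression.tsv", expr.values)
    onio.write_metadata(out_dir / "metadata.tsv", expr.metadata)
    onio.write_edgelist(out_dir / "interactome.tsv", net)
    onio.write_gmt(out_dir / "annotations.gmt", gmt)
    onio.write_genotypes(out_dir / "genotypes.tsv", gt)
    onio.write_phenotype(out_dir / "phenotype.tsv", pheno)
    truth = {"expression": expr_truth.to_dict(), "ppi": ppi_truth.to_dict(),
             "genetics": gen_truth.to_dict()}
    (out_dir / "truth.json").write_text(
        json.dumps(_round_floats(truth), indent=1, sort_keys=True))
    for f in out_dir.iterdir():
        if f.is_file() and f.name not in ("report.json", "manifest.json"):
            artifacts[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()

    # response clustering -------------------------------------------------
    clu = ResponseClusterer().fit(expr)
    counts = (clu.clusters_.groupby(["timepoint", "label"], observed=True)
              .size().unstack(fill_value=0))
    report["clusters_per_timepoint"] = {
        str(tp): {str(lab): int(counts.loc[tp].get(lab, 0))
                  for lab in ("up", "down")}
        for tp in counts.index}

    # GGM networks per response -------------------------------------------
    networks = {}
    for response in ("treatment", "time", "interaction"):
        genes = select_response_genes(clu.contrasts_, response)
        if len(genes) >= 15:
            networks[response] = build_network(
                genes, expr, threshold=cfg.ggm_threshold,
                response_label=response)
    report["networks"] = {}
    for name, ggm_net in networks.items():
        g = ggm_net.graph()
        topo = summarize_topology(g, n_rand=cfg.n_rand, seed=cfg.seed)
        d = topo.to_dict()
        d.pop("degree_classes")
        d["eta0"] = ggm_net.eta0
        report["networks"][name] = d

    # power graph / SPNs on the interactome --------------------------------
    pg, spns = power_graph_analysis(net)
    report["powergraph"] = {
        "edge_reduction": edge_reduction(pg),
        "spns": [{"label": s.label, "n_proteins": len(s.member_proteins),
                  "hub": str(s.hub)} for s in spns]}

    # PPI connectivity of the top SPN -------------------------------------
    if spns:
        conn = permutation_test(spns[0].member_proteins, net,
                                n_perm=cfg.n_perm, seed=cfg.seed)
        report["ppi"] = {"n_direct_edges": conn.n_direct_edges,
                         "p_edges": conn.empirical_p_edges,
                         "p_degree": conn.empirical_p_degree}

    # enrichment -----------------------------------------------------------
    universe = set(net.nodes())
    if spns:
        cats = {k: v for k, v in gmt.items() if not k.startswith("TF")}
        tfs = {k: v for k, v in gmt.items() if k.startswith("TF")}
        et = enrich_table(set(spns[0].member_proteins) & universe, cats,
                          universe)
        report["enrichment"] = {
            "top_category": str(et["category"].iloc[0]) if len(et) else None,
            "top_q": float(et["q"].iloc[0]) if len(et) else None}
        if tfs:
            tf = tf_target_enrichment(tfs, spns[0].member_proteins, universe)
            report["enrichment"]["tf_top_p"] = float(tf["p"].iloc[0])

    # genetics -------------------------------------------------------------
    gt_f, qc = qc_filter(gt)
    beta, t, p = snp_association(pheno, gt_f[gen_truth.causal_snp],
                                 coding="presence")
    snp_set = list(gt_f.columns[:10])
    if gen_truth.causal_snp not in snp_set:
        snp_set[0] = gen_truth.causal_snp
    stat, set_p = geneset_joint_association(pheno, gt_f, snp_set,
                                            n_perm=cfg.n_perm, seed=cfg.seed)
    try:
        et_, ep, m_hom, m_rest = eqtl_group_test(eqtl_expr,
                                                 gt[gen_truth.eqtl_snp])
        eqtl = {"t": et_, "p": ep, "mean_hom_minor": m_hom,
                "mean_rest": m_rest}
    except ValueError as err:
        eqtl = {"error": str(err)}
    report["genetics"] = {
        "n_snps_kept": int(qc["kept"].sum()),
        "causal_snp": {"beta": beta, "t": t, "p": p},
        "snp_set": {"statistic": stat, "p": set_p},
        "eqtl": eqtl}

    # recovery against the recorded truth ----------------------------------
    est = GraphicalGaussianNetwork(threshold=1.0).fit(expr.values.T)
    genes = est.genes_
    gi = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    iu = np.triu_indices(n, k=1)
    planted = np.zeros(len(iu[0]), dtype=bool)
    pos = {(gi[a], gi[b]) for a, b in expr_truth.planted_edges}
    for k, (i, j) in enumerate(zip(*iu)):
        if (i, j) in pos or (j, i) in pos:
            planted[k] = True
    auc = float(roc_auc_score(planted, np.abs(est.pcor_[iu])))
    hub_ok = bool(spns and any(s.hub == ppi_truth.hub for s in spns))
    cat_rank = None
    if spns:
        truth_cat = next((c for c, m in ppi_truth.enriched_categories.items()
                          if m == "SPN1"), None)
        star_spn = next((s for s in spns
                         if ppi_truth.hub in s.member_proteins), None)
        if truth_cat and star_spn:
            et2 = enrich_table(set(star_spn.member_proteins) & universe,
                               {k: v for k, v in gmt.items()
                                if not k.startswith("TF")}, universe)
            ranks = {c: r for r, c in enumerate(et2["category"], start=1)}
            cat_rank = ranks.get(truth_cat)
    report["recovery"] = {"hub_recovered": hub_ok,
                          "planted_edge_auc": auc,
                          "planted_category_rank": cat_rank}

    report = _round_floats(report)
    report_text = json.dumps(report, indent=1, sort_keys=True)
    (out_dir / "report.json").write_text(report_text)
    manifest = {
        "seed": cfg.seed,
        "parameters": _round_floats({**asdict(cfg),
                                     "sim": asdict(sim_cfg)}),
        "artifacts": artifacts,
        "report_sha256": hashlib.sha256(report_text.encode()).hexdigest(),
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return report
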