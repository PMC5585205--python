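"""Generator correctness: determinism, planted-structure recording, and
distributional properties of the synthetic study."""

import numpy as np
import pytest
from scipy import stats

from omicnets import (SimConfig, gen_expression, gen_interactome,
                      gen_annotations, gen_genotypes)
from omicnets.synthdata import (planted_precision, _background_degrees,
                                _rng, MARGINAL_SD)


def test_fixed_seed_reproduces_expression_byte_identically():
    a, _ = gen_expression(SimConfig(seed=7, n_genes=30))
    b, _ = gen_expression(SimConfig(seed=7, n_genes=30))
    assert a.values.equals(b.values)
    assert a.metadata.equals(b.metadata)


def test_streams_are_independent_of_each_other():
    cfg = SimConfig(seed=7, n_genes=30)
    net1, _ = gen_interactome(cfg)
    _ = gen_expression(cfg)   # consuming another stream must not matter
    net2, _ = gen_interactome(cfg)
    assert sorted(net1.edges()) == sorted(net2.edges())


@pytest.mark.parametrize("bad", [
    dict(n_genes=0), dict(maf_range=(0.0, 0.4)), dict(maf_range=(0.3, 0.6)),
    dict(network_model="ladder"), dict(biclique_dims=(1, 3)),
    dict(star_size=2), dict(cluster_effect=float("inf")),
])
def test_invalid_config_rejected(bad):
    with pytest.raises(ValueError):
        SimConfig(**bad)


def test_precision_matrix_is_positive_definite_and_sparse():
    cfg = SimConfig(seed=3, n_genes=40, precision_offdiag=0.4)
    omega, graph = planted_precision(cfg)
    assert np.all(np.linalg.eigvalsh(omega) > 0)
    off = np.abs(omega[np.triu_indices(40, 1)])
    assert set(np.round(off[off > 0], 6)) == {0.4}
    assert (off > 0).sum() == graph.number_of_edges()


def test_expression_marginal_sd_matches_target():
    cfg = SimConfig(seed=5, n_genes=30, n_samples_per_cell=60,
                    cluster_effect=0.0)
    expr, _ = gen_expression(cfg)
    sds = expr.values.std(axis=1, ddof=1)
    assert np.allclose(sds, MARGINAL_SD, atol=0.08)


def test_zero_effect_gives_null_calibrated_welch_rate():
    """With cluster_effect=0 both conditions are identically distributed."""
    rates = []
    for seed in range(10):
        cfg = SimConfig(seed=seed, n_genes=100, cluster_effect=0.0)
        expr, _ = gen_expression(cfg)
        il1b = expr.metadata["condition"] == "IL1B"
        p1 = expr.metadata["timepoint"] == "P1"
        a = expr.values.loc[:, (il1b & p1).values].to_numpy()
        b = expr.values.loc[:, (~il1b & p1).values].to_numpy()
        p = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
        rates.append((p < 0.05).mean())
    assert abs(np.mean(rates) - 0.05) < 0.02


def test_sample_covariance_converges_to_inverse_precision():
    cfg = SimConfig(seed=9, n_genes=25, n_samples_per_cell=625,
                    cluster_effect=0.0)
    omega, _ = planted_precision(cfg)
    sigma = np.linalg.inv(omega)
    scale = MARGINAL_SD / np.sqrt(np.diag(sigma))
    sigma = sigma * np.outer(scale, scale)
    expr, _ = gen_expression(cfg)
    S = np.cov(expr.values.to_numpy())
    n = expr.values.shape[1]
    se = np.sqrt((sigma ** 2 + np.outer(np.diag(sigma), np.diag(sigma))) / n)
    assert np.all(np.abs(S - sigma) < 3.5 * se + 1e-9)


def test_planted_cluster_genes_shift_at_their_timepoint():
    cfg = SimConfig(seed=2, n_genes=60, cluster_effect=2.0)
    expr, truth = gen_expression(cfg)
    up = [g for g, l in truth.cluster_membership.items() if l == "up_P1"]
    meta = expr.metadata
    il1b_p1 = ((meta["condition"] == "IL1B")
               & (meta["timepoint"] == "P1")).values
    pbs_p1 = ((meta["condition"] == "PBS")
              & (meta["timepoint"] == "P1")).values
    diff = (expr.values.loc[up, il1b_p1].mean(axis=1)
            - expr.values.loc[up, pbs_p1].mean(axis=1))
    assert (diff > 1.0).all()


# ----------------------------------------------------------------- interactome

def test_interactome_planted_modules(interactome):
    net, truth = interactome
    assert net.degree(truth.hub) == 10            # star_size
    spn2 = truth.planted_modules["SPN2"]
    internal = net.subgraph(spn2).number_of_edges()
    assert internal == 36                         # 6 x 6 biclique
    assert truth.hub in truth.planted_modules["SPN1"]
    assert truth.planted_modules["SPN1"].isdisjoint(spn2)


def test_background_degree_sequence_matches_prescription():
    cfg = SimConfig(seed=4)
    rng = _rng(cfg.seed, "interactome")
    prescribed = sorted(_background_degrees(cfg.n_background_ppi_nodes, rng))
    net, _ = gen_interactome(cfg)
    got = sorted(d for n, d in net.degree() if n.startswith("BG"))
    assert got == prescribed


def test_module_budget_enforced():
    with pytest.raises(ValueError, match="budget"):
        gen_interactome(SimConfig(star_size=50, biclique_dims=(40, 40),
                                  n_background_ppi_nodes=100))


# ----------------------------------------------------------------- annotations

def test_full_category_without_padding_equals_module(interactome):
    _, truth = interactome
    cfg = SimConfig(seed=11)
    sets = gen_annotations(cfg, truth, q=1.0, pad_frac=0.0)
    _, members = sets["CAT_SPN1"]
    assert set(members) == truth.planted_modules["SPN1"]


def test_planted_category_is_strongly_enriched(interactome):
    net, truth = interactome
    sets = gen_annotations(SimConfig(seed=11), truth)
    universe = set(net.nodes())
    module = truth.planted_modules["SPN1"]
    cat = set(sets["CAT_SPN1"][1]) & universe
    k = len(cat & module)
    p = stats.hypergeom.sf(k - 1, len(universe), len(cat), len(module))
    assert p < 1e-4


def test_empty_module_skipped_with_warning():
    truth_net = gen_interactome(SimConfig(seed=1))[1]
    truth_net.planted_modules["EMPTY"] = set()
    with pytest.warns(UserWarning, match="empty"):
        sets = gen_annotations(SimConfig(seed=1), truth_net)
    assert "CAT_EMPTY" not in sets


# ------------------------------------------------------------------- genotypes

def test_empirical_maf_within_three_binomial_sd():
    cfg = SimConfig(seed=6, n_subjects=400, n_snps=5,
                    maf_range=(0.25, 0.25))
    gt, *_ = gen_genotypes(cfg)
    se = np.sqrt(0.25 * 0.75 / (2 * 400))
    emp = gt.to_numpy().sum(axis=0) / (2 * 400)
    assert np.all(np.abs(emp - 0.25) < 3 * se)


def test_zero_beta_gives_uniform_association_p(rng):
    from omicnets.genetics import snp_association
    ps = []
    for seed in range(200):
        cfg = SimConfig(seed=seed, causal_beta=0.0, n_snps=2, n_subjects=80)
        gt, pheno, _, truth = gen_genotypes(cfg)
        ps.append(snp_association(pheno, gt[truth.causal_snp])[2])
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_planted_causal_snp_detected_mostly():
    from omicnets.genetics import snp_association
    hits = 0
    for seed in range(40):
        cfg = SimConfig(seed=seed, causal_beta=0.8, n_subjects=271)
        gt, pheno, _, truth = gen_genotypes(cfg)
        hits += snp_association(pheno, gt[truth.causal_snp])[2] < 0.05
    assert hits >= 36   # >90 percent power


def test_genotypes_respect_maf_range_bounds():
    with pytest.raises(ValueError):
        SimConfig(maf_range=(0.6, 0.7))
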