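# omicnets

Integrative network analysis for factorial expression experiments:
graphical-Gaussian co-expression networks with local-FDR edge selection,
lossless power-graph compression of protein–protein interaction (PPI)
networks with super-power-node (SPN) detection, degree-matched permutation
tests of subnetwork connectivity, hypergeometric enrichment, and
genotype–phenotype association — together with a synthetic-data module that
plants known structure at every stage so the whole pipeline can be
benchmarked against recorded ground truth.

The package is aimed at systems-biology analysts who have a two-condition ×
multi-time-point expression study (e.g. an inflammatory stimulus followed
over development), a background interactome, gene-set annotations, and
optionally genotypes with a scalar phenotype, and who want to go from
"which genes respond" to "which protein modules carry the response and do
their variants matter" with every statistical step testable.

## The models and statistics

**Response clustering.** Per gene, a two-way fixed-effects model
y = μ + treatment + time + treatment×time is fitted by least squares with
type-II F-tests, BH-adjusted per factor. Per time point, the
treatment-minus-control mean difference d_g is standardized across genes,
Z_g = (d_g − mean(d))/sd(d), and a gene is labeled *up* when Z_g > 1,
Welch p < 0.05 and BH q ≤ 0.10 (symmetrically *down* below −1).

**Co-expression networks (GGM).** The sample correlation matrix R is
shrunk toward the identity, R* = λI + (1−λ)R, with the analytic
variance-minimizing intensity λ = Σ var̂(r_ij) / Σ r_ij². Partial
correlations come from the inverse Ω = (R*)⁻¹ as
p_ij = −ω_ij/√(ω_ii ω_jj). Edges are selected by local false discovery
rate under the two-component model
f(r) = η₀·f0(r;κ) + (1−η₀)·f_A(r), where
f0(r;κ) = (1−r²)^((κ−3)/2) / B(1/2, (κ−1)/2) is the null of a sample
correlation on κ effective degrees of freedom; κ is fitted by truncated
maximum likelihood on the central bulk, η₀ by conservative central-mass
matching, f̂ by a Grenander-style monotone histogram fit, and
fdr(r) = η₀ f0(r)/f̂(r), capped at 1.

**Power graphs and SPNs.** A power node is a set of proteins; a power edge
between disjoint sets U, V abstracts all |U|·|V| base edges (a biclique),
and from a set to itself all internal pairs (a clique). A greedy covering
chooses candidate pairs (from average-linkage clustering of Jaccard
neighborhood similarity) that abstract the most still-uncovered edges, so
that every base edge is abstracted exactly once — the decomposition is
lossless and `expand(decompose(G)) == E(G)` is an executable identity.
An SPN is a connected component of the power-node meta-graph containing at
least two power nodes of size ≥ 2; its hub is the member of maximal
base-graph degree.

**Connectivity significance.** The direct edge count and mean degree of a
query set are compared with random sets matched on log₂-degree bins;
p = (1 + #{null ≥ observed}) / (1 + permutations).

**Enrichment.** One-sided hypergeometric tails P(X ≥ k), computed by exact
summation in log space, drive category, disease-set and TF-target
enrichment; multi-set overlaps use the exact tail for two sets and
Monte-Carlo resampling for three or more. Disorder-promoting amino-acid
content ({A,R,G,Q,S,P,E,K}) is compared between protein groups by Student
t.

**Genetics.** SNPs are filtered at MAF ≥ 5% and call rate ≥ 99%;
associations use minor-allele presence (dominant) or additive coding in an
ordinary linear model. A SNP set is tested self-contained: the statistic
Σ −log₁₀ p over the set is compared with its distribution under phenotype
permutations. cis-eQTL effects compare homozygous-minor carriers against
the rest by Student t.

## Worked example

```python
from omicnets import (SimConfig, gen_interactome, gen_genotypes,
                      power_graph_analysis, permutation_test,
                      snp_association)
from omicnets.powergraph import edge_reduction

cfg = SimConfig(seed=42)
net, truth = gen_interactome(cfg)
pg, spns = power_graph_analysis(net)
print(net.number_of_nodes(), "proteins,", net.number_of_edges(), "interactions")
print("edge reduction:", round(edge_reduction(pg), 2))
for s in spns:
    print(s.label, len(s.member_proteins), "proteins, hub =", s.hub)

star = next(s for s in spns if s.hub == truth.hub)
res = permutation_test(star.member_proteins, net, n_perm=1000, seed=1)
print("direct edges:", res.n_direct_edges, "empirical p:", res.empirical_p_edges)

gt, pheno, expr, gtruth = gen_genotypes(cfg)
beta, t, p = snp_association(pheno, gt[gtruth.causal_snp], coding="presence")
print(f"causal SNP {gtruth.causal_snp}: beta={beta:.3f}, t={t:.2f}, p={p:.2e}")
```

prints

```
223 proteins, 216 interactions
edge reduction: 2.2
SPN1 12 proteins, hub = BA01
SPN2 11 proteins, hub = HUB01
direct edges: 35 empirical p: 0.000999000999000999
causal SNP rs00040: beta=0.821, t=6.54, p=3.10e-10
```

The two SPNs are exactly the two planted modules: the 12-protein biclique
module and the 11-protein hub module whose hub (`HUB01`) is the planted
one. The hub module's 35 direct interactions are far beyond what
degree-matched random sets achieve (the empirical p sits at its floor,
1/1001), and the planted variant's dominant-model effect is recovered close
to its simulated size (0.8).

The same stages are scriptable from the shell via the `omicnets` console
command (`simulate`, `respond`, `ggm`, `topology`, `powergraph`, `ppi`,
`enrich`, `genetics`, `run-all`); `omicnets run-all --seed 1 --out-dir out`
writes every artifact, a JSON report, and a manifest with content hashes.

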