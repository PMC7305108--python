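# codc — copula-based differential coexpression

`codc` identifies gene pairs whose *dependence structure* — not just whose
mean expression — changes between two phenotype conditions, typically
matched normal and tumor samples.  It is aimed at systems-biology analyses
where the interesting signal is a rewiring of coexpression (a pair strongly
positively correlated in normal tissue that flips to negative in tumor)
rather than differential expression of individual genes.

## The statistic

For a gene pair (g_i, g_j), each condition's joint expression distribution
is summarized by its **empirical copula**: with pseudo-observations
u_k = rank(x_ik)/m and v_k = rank(x_jk)/m,

    Ĉ(u, v) = (1/m) Σ_k 1{u_k ≤ u, v_k ≤ v}.

The differential-coexpression score is the two-sample Kolmogorov–Smirnov
distance between the two conditions' copulas,

    DC_Copula(g_i, g_j) = sup_{u,v} | Ĉ_tumor(u, v) − Ĉ_normal(u, v) |,

computed exactly on the lattice spanned by the pooled pseudo-observations.
Because copulas depend only on ranks, the score is *exactly* invariant under
strictly increasing transforms of any expression profile — normalization
choices and monotone distortions cannot change it — and strictly decreasing
transforms can only leave it unchanged or increase it.  The classical
baseline |ρ_normal − ρ_tumor| is also provided; unlike the copula score it
overweights same-sign correlation shifts and underweights sign flips.

Downstream, the package clusters genes on the dissimilarity
dist = 1 − DC_Copula (average linkage), summarizes each module by its
eigengene (first principal component of the standardized member profiles),
builds per-condition eigengene correlation networks, and scores modules
against user-supplied GMT gene sets (fold-enrichment `pathway_score = n/m`
plus hypergeometric tests with Benjamini–Hochberg FDR).

## Worked example

Simulate six genes over 40 matched pairs, planting one pair whose
correlation is +0.9 in normal and −0.9 in tumor, then score all pairs:

```python
from codc import (SimConfig, PairSpec, simulate_paired_expression,
                  dc_copula_matrix, extract_dc_pairs)

cfg = SimConfig(p=6, m_normal=40, m_tumor=40, seed=0,
                pair_specs=[PairSpec(0, 1, rho_normal=0.9, rho_tumor=-0.9)])
paired, truth = simulate_paired_expression(cfg)
print(extract_dc_pairs(dc_copula_matrix(paired), paired, top_k=3))
```

```
gene_i gene_j  score  rho_normal  rho_tumor
 g0000  g0001  0.350    0.900000  -0.900000
 g0001  g0003  0.200    0.440483  -0.150339
 g0000  g0003  0.125    0.422680   0.208327
```

The planted pair ranks first with score 0.350 — far above the background of
independent genes (≈0.1–0.2 at m=40) — and its annotated per-condition
Pearson correlations show the sign flip.  Note the sup-KS score is bounded
by ~0.5 (the gap between the Fréchet–Hoeffding extremes), so 0.350 is a
large effect at this sample size.

The same pipeline is available from the shell:

```bash
codc simulate --config sim.yaml --out-prefix sim_
codc score --normal sim_normal.tsv --tumor sim_tumor.tsv \
     --out pairs.tsv --matrix dc.tsv
codc modules --dc-matrix dc.tsv --normal sim_normal.tsv --tumor sim_tumor.tsv \
     --k 2 --out modules.tsv --eigengenes eg.tsv
codc enrich --modules modules.tsv --gmt sets.gmt --out enrichment.tsv
```

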