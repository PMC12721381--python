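# seejmix

Bayesian admixture modeling of **sequences of exon–exon junctions (SEEJs)**
from multi-sample RNA-seq junction reads, with a Dirichlet-multinomial GLM
for differential SEEJ usage.

## The problem

Full-length transcript assembly from short reads is underdetermined, while
local splice-event methods lose the co-occurrence structure of splicing and
can conflate similar transcripts. A SEEJ sits in between: a set of mutually
compatible excised introns (junctions) that co-occur in transcripts. Two
junctions whose intron intervals overlap cannot be excised by the same
transcript, so valid SEEJs are exactly the independent sets of the *conflict
graph* — the interval graph whose vertices are the locus's junctions, with
an edge whenever `min(t, t') − max(s, s') > 0` for intron intervals
`[s, t)`, `[s', t')`.

## The model

For one gene locus with `|V|` unique junctions, `K` SEEJs and `N` samples,
each junction-read token is generated by:

```
π_k ~ Beta(r, s)                       junction-inclusion probability
b_kv ~ Bernoulli(π_k),  b_k ∈ Ω        SEEJ structure (Ω = independent sets)
β_k ~ Dirichlet_|V|(η ⊙ b_k)           degenerate Dirichlet junction emissions
θ_i ~ Dirichlet_K(α)                   per-sample SEEJ usage
z_ij ~ Multinomial(θ_i)                token-to-SEEJ assignment
w_ij ~ Multinomial(β_{z_ij})           observed junction
```

Only `|C|` Bernoulli structure variables are free, where `C` is a minimum
node cover of the conflict graph (computable in near-linear time on interval
graphs); non-cover vertices are encoded as complements of a cover neighbor.
Inference is Gibbs sampling: conjugate updates for `θ`, `π`, `β`; a single
collapsed multinomial per (sample, junction) pair for `z` (tokens on the
same junction are exchangeable, giving `O(K + D log K)` assignment cost);
and a Metropolized scan for each SEEJ's structure that scores single
add/remove proposals by the complete conditional

```
p(φ | ·) ∝ π^(r+|φ|−1) (1−π)^(s+|N(φ)|−1) ·
           Γ(Σ_{i∈φ} η_i)/Π_{i∈φ} Γ(η_i) · Π_{i∈φ} β_i^(η_i−1)
```

with `N(φ)` the graph neighborhood of the candidate SEEJ. After convergence
(relative fixed-width rule on the log-likelihood trace, σ = 0.001), SEEJs
with identical used-junction configurations are merged — the model fitted
with surplus components reports a smaller *effective K*.

Differential usage between two sample groups is tested per locus by a
Dirichlet-multinomial GLM with a softmax link
`p_ij = exp(x_i β̂_j + μ_j) / Σ_k exp(x_i β̂_k + μ_k)`, a
Gamma(1 + 1e−4, 1e−4) prior stabilizing the concentration, and a
likelihood-ratio test with `k − 1` degrees of freedom, followed by
Benjamini–Hochberg correction across loci.

## Worked example

Simulate a three-SEEJ gene for two groups of 25 samples (fold change 5 on
the first SEEJ's usage), fit the admixture model with two surplus
components, and test for differential usage:

```python
from seejmix.synth import well_separated_gene, simulate_from_model
from seejmix.model import SeejAdmixture
from seejmix.metrics import filter_expressed_seejs
from seejmix.diffusage import lrt_test

gene = well_separated_gene(3)
table, truth = simulate_from_model(
    gene, group_fold_changes=[1.0, 5.0], samples_per_group=25,
    tokens_mean=500, seed=0)

model = SeejAdmixture(n_seejs=5, alpha=0.1, eta=1.0, n_iter=400,
                      random_state=0).fit(table)
Y = model.seej_count_matrix()
expressed = filter_expressed_seejs(Y)      # >=10 reads in >=10 samples
for k in expressed:
    comp = model.posterior_.components[k]
    print("SEEJ", sorted(comp.junctions),
          "mean usage %.3f" % (comp.sample_counts.sum() / table.counts.sum()))
res = lrt_test(Y[:, expressed], truth["groups"])
print("LRT statistic %.1f, df %d, p-value %.3g"
      % (res.statistic, res.df, res.pvalue))
```

prints

```
SEEJ [0, 1, 2, 3] mean usage 0.562
SEEJ [4, 5, 6, 7] mean usage 0.222
SEEJ [8, 9, 10, 11] mean usage 0.216
LRT statistic 23.9, df 2, p-value 6.47e-06
```

The three expressed SEEJs are exactly the simulated transcripts' junction
sets (the two surplus components were merged away or filtered), the usage of
the first SEEJ is elevated because group 2 up-weights it, and the LRT calls
the shift highly significant.

## Command-line interface

`seejmix` exposes the pipeline as subcommands: `extract` (junction TSV /
RegTools BED12 → filtered per-locus count tables), `fit` (Gibbs sampling on
one locus), `select` (grid search of `K = χ(G) + τ` and hyperparameters by
held-out predictive likelihood), `diff` (Dirichlet-multinomial LRT + BH),
`eval` (partial-homogeneity scores, precision/recall/F, novelty against a
GTF reference), and `simulate` (synthetic cohorts). Every run writes a
provenance file carrying its seed and config hash.

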