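# Methods

## Data model and coordinates

The atomic observation is a *junction-read token*: one incidence of an
aligned read with one excised-intron interval. Junctions are 0-based,
half-open `[start, end)` intervals on a chromosome/strand; BED input is
already in this convention, GTF exon coordinates (1-based inclusive) are
converted on ingestion. Junctions with identical coordinates on different
strands are distinct; strand `"."` never merges with `"+"`/`"-"`. Reads
spanning several junctions contribute one token per junction they cover:
the likelihood treats tokens for the same (sample, junction) pair as
exchangeable, so the multiplicity convention only rescales counts.

Input filtering keeps introns of 50–500 000 bp and accepts an optional
user-supplied junction blacklist (e.g. externally computed false-positive
splice-junction calls); duplicate-read and multi-mapping handling is
expected upstream. Overlapping gene intervals are merged into loci
(connected components under half-open interval overlap), and junctions are
assigned to the unique locus containing them; junctions contained in no
locus — including ones straddling locus boundaries — are dropped with a
logged token count, so total token mass is conserved.

## Conflict graph

Two junctions conflict when `min(t, t') − max(s, s') > 0` — a strict
inequality, so intervals that merely touch are compatible. On this interval
graph the package computes, by endpoint sweeps:

* a **maximum independent set** (greedy earliest-endpoint selection, exact
  on interval graphs; ties broken by (end, start, index) for determinism);
* a **minimum node cover** as the MIS complement (Gallai identity
  `α(G) + |C| = |V|`), which sets the number of free structure variables;
* the **chromatic number** as the maximum interval overlap depth (end
  events processed before start events at equal coordinates, honoring the
  strict overlap rule); it equals the clique number on interval graphs and
  lower-bounds the number of SEEJs.

Each non-cover vertex with cover neighbors is encoded as the complement of
one uniformly chosen cover neighbor (seeded). Isolated vertices appear in no
constraint: they carry an implicit always-on indicator, and whether they are
*reported* in a SEEJ is decided by read assignment, not by a Bernoulli
variable.

## Gibbs sampler

Each iteration samples, in order: assignments `z` (one multinomial per
(sample, junction) pair with `p_k ∝ θ_ik β_kv`), usage `θ` (conjugate
Dirichlet), inclusion probabilities `π` (conjugate Beta), SEEJ structures
`b`, and emissions `β` (degenerate Dirichlet over the active junctions,
zeros elsewhere). All draws come from one seeded generator in fixed order,
so chains are bitwise reproducible.

The structure update is a Metropolized Gibbs scan. For each SEEJ,
`n_candidates` (default 10) proposals are built from the current
configuration by one add or remove move — add with probability
`1 − m/α(G)` where `m` is the current size; adds choose among compatible
inactive junctions proportional to `β_kv`, removes among active junctions
proportional to `1 − β_kv` — and the current configuration is included in
the scored support so the move can reject and the support is never empty.
Candidates are scored by the structure complete conditional (README); the
winner is drawn from the normalized exponentiated weights.

Numerical choices around this update, where the generative story is silent:

* **Degenerate-Dirichlet convention.** Inactive dimensions contribute
  nothing to the conditional (the alternative — evaluating `Γ(0)` and
  `β^{−1}` at `β = 0` — is undefined).
* **Pseudo-mass for newly added junctions.** A freshly drawn `β_k` has
  support exactly on the current configuration, so both the add-proposal
  weights and the conditional would be degenerate at zero for any junction
  being added. Proposal weights use `β_kv` plus a small prior-mean term;
  the conditional evaluates a `β` extended to the candidate set with the
  prior-mean share `η_v / Σ_{φ} η` and renormalized. The prior mean (rather
  than an arbitrary epsilon) keeps the extension on the same scale as a
  typical prior draw, avoiding artificial pressure toward or against
  growth.
* **Orphan repair.** An observed junction contained in no active SEEJ makes
  the likelihood zero, so after every structure scan such junctions are
  force-added to the compatible SEEJ with the highest emission potential,
  measured as the expected posterior token mass `Σ_i n_iv θ_ik`. This
  data-informed potential matters: selecting by prior-mean share instead
  always picks the emptiest SEEJ and perpetually re-creates singleton
  components. If no SEEJ is compatible, the SEEJ with the fewest conflicts
  evicts them (evicted observed junctions re-enter the repair queue, with a
  hard iteration guard).
* **Stranded tokens.** Tokens assigned to a dimension that a structure move
  deactivated are resampled immediately over the new supports, before the
  emission update, so emissions never see off-support counts.
* **Fallbacks.** An infeasible move type (remove from an empty SEEJ, add to
  a saturated one) switches to the other type; all-zero proposal weights
  fall back to uniform.

Convergence uses a relative fixed-width rule: the chain stops when the
normal-theory confidence-interval half-width of the windowed mean
log-likelihood (window 50, confidence 0.95), divided by the absolute
windowed mean, falls below σ = 0.001 (checked every 10 iterations), or at
the iteration cap.

### Posterior summaries and collapsing

After the chain stops, the structure is frozen at the final draw and 50
extra sweeps over (z, θ, β) accumulate structure-conditional posterior
means. A SEEJ's reported configuration is its *used-junction set*: active
junctions with more than 0.5 expected assigned tokens across all samples
(so always-on isolated vertices and never-used active dimensions do not
inflate segments). SEEJs with identical configurations are merged — counts
summed, emissions averaged and renormalized — and empty configurations are
dropped; the number of survivors is the effective K.

### Multi-chain arbitration

Single-junction structure moves can stall in locally optimal partitions
(e.g. chimeric groupings of junctions across true SEEJs). The estimator can
run several independent chains (`n_chains`) and keep the one with the best
*collapsed structure score*: `log p(z, w | b, α, η)` with θ and β integrated
out analytically (products of Dirichlet-multinomial marginals). The raw log
joint is unsuitable for this comparison because it contains Dirichlet
*densities* evaluated at the current draws — with `η < 1` the factor
`β^{η−1}` diverges at near-zero entries, so structures with more active
dimensions receive unboundedly large density terms. The collapsed score is
finite, comparable across structures, and has the expected Occam behavior.

## Hyperparameters

| parameter | default | meaning |
|---|---|---|
| `K` | `χ(G) + k_extra` (k_extra = 4) | number of SEEJs; `χ(G)` is the minimum feasible |
| `α` | 1.0 | per-sample usage concentration; `α < 1` favors few used SEEJs per sample |
| `η` | 0.01 | junction emission concentration; small values favor concentrated emissions |
| `r, s` | 1, 1 | Beta prior on inclusion; larger `r/(r+s)` favors longer SEEJs |
| `n_candidates` | 10 | structure proposals per SEEJ per iteration |
| σ, window | 0.001, 50 | convergence rule |

The defaults `η = 0.01`, `α = r = s = 1` are the grid-selected values for
junction tables from real aligners, where `K ≪ |V|`. The *recovery
experiments* (tests and the acceptance script) instead fit with `α = 0.1`
and `η = 1`, for reasons that are themselves informative about the model:

* With `α = 1` and `K ≥ |V|` the saturated solution — one singleton SEEJ per
  junction, per-sample usage equal to the sample's junction frequencies —
  has a posterior joint density at least as high as the true structure
  (it is the saturated model and the uniform Dirichlet prior charges no
  penalty). `α < 1` penalizes each additional used component per sample, so
  surplus SEEJs can actually be shut off, which is what the
  surplus-K experiment measures.
* With `η = 0.01` every active dimension costs a factor `1/Γ(η) ≈ 1/100` in
  the structure conditional unless its emission is extreme, which blocks
  the merge moves the sampler needs to escape fragmented states. `η = 1`
  makes the conditional neutral in this respect.

## Model selection

`K = χ(G) + τ` is searched over τ ∈ {0, 2, …, 16} jointly with
α ∈ {0.001, 0.01, 1, 5, 10}, η ∈ {0.01, 1, 5, 10} and r = s ∈ {1, 5, 10}.
The held-out unit is whole *samples* (default 20%): splitting reads of one
sample would break exchangeability, and new-sample prediction is the
quantity a fitted model is actually used for. Held-out tokens are scored by
`Σ n_iv log Σ_k θ̄_k β̄_kv` with `β̄` the collapsed posterior means and `θ̄`
the population mixture (pooled posterior token counts plus the α prior);
junctions absent from the model contribute a floor probability (1e−8,
logged). Ties prefer smaller K, then smaller α.

## Differential usage

Per-sample SEEJ counts (from the collapsed posterior, restricted to
*expressed* SEEJs: ≥ 10 assigned reads in ≥ 10 samples) are modeled as
Dirichlet-multinomial with concentration `α·p_i` and a softmax link on a
binary group covariate. The link is overparameterized, so the last SEEJ is
the reference category (`μ_k = β̂_k = 0`). The concentration is estimated by
MAP under Gamma(1 + 1e−4, 1e−4) (a near-flat prior that keeps the optimizer
away from the α → ∞ ridge); μ and β̂ by maximum likelihood. Optimization is
L-BFGS on (log α, μ, β̂) with analytic gradients, moment-based starts
(log pooled proportions), optional jittered restarts, and the alternative
model warm-started from the null solution — which also guarantees a
nonnegative LRT statistic up to optimizer tolerance (clamped at 0). The LRT
uses k − 1 degrees of freedom, where k is the number of SEEJs entering the
test; BH correction is applied across loci (and across group pairs in
cohort analyses). Counts entering the GLM are per-sample token totals per
SEEJ; a per-unique-junction alternative is not provided because the
collapsed posterior already aggregates tokens.

## Synthetic data

The generator emulates multi-sample junction-read data from known transcript
structures, at two levels:

* `generate_gene_structure` lays out an exon scaffold and samples distinct
  exon chains (first and last exon always kept, interior exons included
  with probability 0.6). A skipped exon yields a skip junction that
  strictly overlaps *both* flanking inclusion junctions — two conflicting
  pairs per skip, by the overlap formula.
* `well_separated_gene` builds the maximally identifiable recovery fixture:
  each true SEEJ takes one junction variant per coordinate slab, variants
  within a slab pairwise overlap, so χ(G) equals the number of SEEJs and no
  valid SEEJ can mix variants of one slab.

`simulate_from_model` draws per-sample usage
`θ_i ~ Dirichlet(c · w)` with concentration `c = 1` by default, token counts
from a negative binomial (mean 500, dispersion 0.3; var = μ + 0.3 μ²), SEEJ
assignments and junction tokens from the true emissions (uniform over each
SEEJ's junctions unless a concentration is given). Group fold changes
multiply the first SEEJ's weight before renormalization — the simplest
mechanism that shifts usage without touching structure.

The usage concentration of 1 encodes strong cross-sample heterogeneity,
which is deliberate: admixture models are identified by variation in
component usage across samples. If all samples shared nearly identical
usage, every partition of the junctions into valid SEEJs would be close to
likelihood-equivalent and recovery would be meaningless as a test. What the
generator does *not* emulate: sequence-level errors, alignment artifacts,
positional/GC bias, annotation incompleteness, or junction-detection noise —
so passing recovery tests demonstrates correctness of inference under the
model, not robustness to aligner pathologies.

## Evaluation metrics

A computed junction matches a reference transcript when both its donor and
acceptor are within 6 bp of a reference junction's sites (boundary
inclusive: an offset of exactly 6 matches, 7 does not). `s_phs` normalizes
the best-reference match count by the segment length, `ŝ_phs` by the
reference length; their harmonic mean is 0 whenever either is 0, and an
empty segment is undefined (NaN). For precision/recall, each segment is
matched to its argmax reference (ties: more matched junctions, then
smallest id); TP/FP are counted per computed junction against that
reference, FN are unique reference junctions matched by no computed
junction anywhere. Novelty: a segment is known iff one reference transcript
contains all its junctions within the per-junction tolerance; a junction is
known iff it matches any reference junction.

## Problem sizes

The test suite and acceptance script run everything at desk scale, chosen to
finish in minutes on one CPU: 200 random interval graphs (|V| ≤ 12) for the
exhaustive combinatorial oracles; 1e5 draws for distributional sampler
checks; the recovery experiment at 50 samples × ~500 tokens with K = 3 and
K = 13 (2 and 4 chains); LRT calibration with 2000 null replicates of 100
samples; and a 20-gene cohort with 8 groups × 25 samples over the
fold-change grid (1, 1, 1, 1.1, 1.25, 1.5, 3, 5), i.e. 28 group pairs per
gene with 3 null pairs among the fold-1 replicates.

## Known limitations

* The structure conditional contains no direct data term (it conditions on
  the previous emissions), so structure mixing relies on token
  reassignment; chains can stall in chimeric partitions, which is why
  multi-chain arbitration exists. A split-merge move would address this
  more fundamentally.
* Effective K is a posterior-draw summary, not a marginal posterior over
  structures; runs with surplus components can retain one or two
  low-support configurations (the expressed-SEEJ filter removes them at
  reporting time).
* The per-sample usage estimates concentrate on realized token shares; with
  J tokens their accuracy against the drawn usage is O(1/√J) per sample
  regardless of inference quality.
* The DirMult GLM supports a single binary covariate (two groups), scalar
  concentration, and no random effects.
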