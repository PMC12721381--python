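"""Synthetic gene structures and model-faithful junction-read simulation.

The generator emulates multi-sample RNA-seq junction-count data from known
transcript structures: a synthetic gene is a set of exon chains over a
shared coordinate frame (alternative transcripts share some junctions and
conflict at others, e.g. exon skipping makes the skip junction overlap both
flanking inclusion junctions); per-sample library sizes follow a negative
binomial; and group-level fold changes tilt the usage of a designated SEEJ
to create differential cohorts. Defaults emulate a desk-scale study: eight
groups with fold changes (1, 1, 1, 1.1, 1.25, 1.5, 3, 5) on the first SEEJ,
negative-binomial token counts with mean 500 and dispersion 0.3 per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conflict_graph import build_conflict_graph
from .junctions import Junction, JunctionReadTable

DEFAULT_FOLD_CHANGES = (1.0, 1.0, 1.0, 1.1, 1.25, 1.5, 3.0, 5.0)
DEFAULT_NB_MEAN = 500.0
DEFAULT_NB_DISPERSION = 0.3


@dataclass
class SyntheticGene:
    """Known transcript structures over a shared junction universe.

    ``transcripts`` are index sets into ``junctions``; each is an
    independent set of the induced conflict graph (checked).
    """

    name: str
    junctions: list[Junction]
    transcripts: list[frozenset[int]]
    base_weights: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        graph = build_conflict_graph(self.junctions)
        for t in self.transcripts:
            if not graph.is_independent(t):
                raise ValueError(f"transcript {sorted(t)} is not a valid SEEJ")
        if self.base_weights is None:
            self.base_weights = np.ones(len(self.transcripts))
        self.base_weights = np.asarray(self.base_weights, dtype=float)
        self.graph = graph

    @property
    def chi(self) -> int:
        return self.graph.chromatic_number

    @property
    def n_edges(self) -> int:
        return len(self.graph.edges)

    def junction_sets(self) -> list[frozenset[Junction]]:
        return [frozenset(self.junctions[v] for v in t) for t in self.transcripts]


def generate_gene_structure(n_transcripts: int, n_exons: tuple[int, int] = (4, 8),
                            exon_len: int = 100, intron_len: int = 400,
                            chrom: str = "chrS", seed: int = 0,
                            name: str | None = None) -> SyntheticGene:
    """Build exon chains over a shared exon scaffold.

    A scaffold of ``n`` exons (n drawn from ``n_exons``) is laid out on one
    chromosome; every transcript keeps the first and last exon and includes
    each interior exon independently (skipped exons yield skip junctions
    that overlap the corresponding inclusion junctions, producing conflicts).
    Transcripts are distinct by construction; deterministic under ``seed``.
    """
    if n_transcripts < 1:
        raise ValueError("need at least one transcript")
    rng = np.random.default_rng(seed)
    lo, hi = n_exons
    n = int(rng.integers(lo, hi + 1))
    if n < 2:
        raise ValueError("need at least two exons to form a junction")
    n_interior = n - 2
    if n_transcripts > max(1, 2 ** n_interior):
        raise ValueError(
            f"cannot build {n_transcripts} distinct transcripts from "
            f"{n_interior} interior exons")

    # exon i occupies [i*(exon_len+intron_len), ... + exon_len)
    starts = np.arange(n) * (exon_len + intron_len)
    ends = starts + exon_len

    chains: list[tuple[int, ...]] = []
    seen = set()
    full = tuple(range(n))
    chains.append(full)
    seen.add(full)
    while len(chains) < n_transcripts:
        keep = [0] + [i for i in range(1, n - 1) if rng.random() < 0.6] + [n - 1]
        chain = tuple(keep)
        if chain not in seen:
            seen.add(chain)
            chains.append(chain)

    junction_index: dict[Junction, int] = {}
    junctions: list[Junction] = []
    transcripts: list[frozenset[int]] = []
    for chain in chains:
        idxs = set()
        for a, b in zip(chain, chain[1:]):
            j = Junction(chrom, int(ends[a]), int(starts[b]), "+")
            if j not in junction_index:
                junction_index[j] = len(junctions)
                junctions.append(j)
            idxs.add(junction_index[j])
        transcripts.append(frozenset(idxs))
    return SyntheticGene(name or f"gene_seed{seed}", junctions, transcripts)


def well_separated_gene(n_seejs: int = 3, n_slabs: int = 4,
                        slab_len: int = 600, offset: int = 20,
                        chrom: str = "chrS", name: str = "sepgene"
                        ) -> SyntheticGene:
    """A gene whose true SEEJs are mutually conflicting at every junction.

    Each SEEJ uses one junction variant per coordinate slab; variants within
    a slab pairwise overlap (staggered by ``offset``), so no valid SEEJ can
    mix variants of the same slab and chi(G) = n_seejs. This is the
    maximally identifiable setting for recovery experiments.
    """
    junctions: list[Junction] = []
    transcripts = []
    for k in range(n_seejs):
        idxs = set()
        for j in range(n_slabs):
            start = j * (slab_len + 400) + k * offset
            jn = Junction(chrom, start, start + slab_len, "+")
            idxs.add(len(junctions))
            junctions.append(jn)
        transcripts.append(frozenset(idxs))
    return SyntheticGene(name, junctions, transcripts)


def _nb_counts(n: int, mean: float, dispersion: float,
               rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial library sizes; var = mean + dispersion * mean^2."""
    if dispersion <= 0:
        return np.full(n, int(round(mean)))
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p, size=n)


def simulate_from_model(gene: SyntheticGene, n_samples: int = 50,
                        tokens_mean: float = DEFAULT_NB_MEAN,
                        tokens_dispersion: float = DEFAULT_NB_DISPERSION,
                        group_fold_changes=None, samples_per_group: int | None = None,
                        theta_concentration: float = 1.0,
                        beta_concentration: float | None = None,
                        seed: int = 0) -> tuple[JunctionReadTable, dict]:
    """Simulate junction-read tokens from the admixture generative process.

    Per sample: usage ``theta_i ~ Dirichlet(concentration * weights)`` where
    the weights are the gene's base weights with the *first* SEEJ multiplied
    by the sample's group fold change (renormalized); token count
    ``J_i ~ NB(tokens_mean, tokens_dispersion)``; SEEJ assignments
    ``Multinomial(J_i, theta_i)``; junction tokens from the true emission of
    the assigned SEEJ (symmetric Dirichlet over the SEEJ's junctions, or
    uniform when ``beta_concentration`` is None).

    Returns the count table and a ground-truth dict with the true
    configurations, theta, beta, group labels and fold changes.
    """
    rng = np.random.default_rng(seed)
    K = len(gene.transcripts)
    V = len(gene.junctions)

    if group_fold_changes is None:
        folds = np.ones(n_samples)
        groups = np.zeros(n_samples, dtype=int)
    else:
        group_fold_changes = np.asarray(group_fold_changes, dtype=float)
        g = len(group_fold_changes)
        spg = samples_per_group or n_samples // g
        groups = np.repeat(np.arange(g), spg)
        n_samples = len(groups)
        folds = group_fold_changes[groups]

    beta = np.zeros((K, V))
    for k, t in enumerate(gene.transcripts):
        idx = sorted(t)
        if beta_concentration is None:
            beta[k, idx] = 1.0 / len(idx)
        else:
            draw = rng.dirichlet(np.full(len(idx), beta_concentration))
            beta[k, idx] = draw

    weights = np.tile(gene.base_weights, (n_samples, 1)).astype(float)
    weights[:, 0] *= folds
    weights /= weights.sum(axis=1, keepdims=True)
    theta = np.vstack([rng.dirichlet(theta_concentration * w) for w in weights])

    J = _nb_counts(n_samples, tokens_mean, tokens_dispersion, rng)
    counts = np.zeros((n_samples, V), dtype=np.int64)
    z_true = np.zeros((n_samples, K), dtype=np.int64)
    for i in range(n_samples):
        zk = rng.multinomial(int(J[i]), theta[i])
        z_true[i] = zk
        for k in range(K):
            if zk[k]:
                counts[i] += rng.multinomial(int(zk[k]), beta[k])

    table = JunctionReadTable(gene.name, list(gene.junctions), counts)
    truth = {
        "configurations": [frozenset(t) for t in gene.transcripts],
        "theta": theta, "beta": beta, "z": z_true,
        "groups": groups, "fold_changes": folds,
        "tokens": J,
    }
    return table, truth


@dataclass
class CohortGene:
    gene: SyntheticGene
    table: JunctionReadTable
    truth: dict


def simulate_cohort(n_genes: int = 20, samples_per_group: int = 25,
                    fold_changes=DEFAULT_FOLD_CHANGES,
                    tokens_mean: float = DEFAULT_NB_MEAN,
                    tokens_dispersion: float = DEFAULT_NB_DISPERSION,
                    n_transcripts_range: tuple[int, int] = (2, 4),
                    seed: int = 0) -> tuple[list[CohortGene], list[dict]]:
    """A labeled multi-group cohort for differential-usage evaluation.

    Every gene is simulated for all groups at once; the truth labels cover
    every unordered group pair: a pair is differential iff its fold changes
    differ (equal folds, including the replicate fold-1 groups, are null).

    Returns (genes, pair_labels) where each pair label dict has
    ``group_a``, ``group_b``, ``differential``.
    """
    fold_changes = tuple(fold_changes)
    rng = np.random.default_rng(seed)
    genes: list[CohortGene] = []
    for g in range(n_genes):
        n_tr = int(rng.integers(n_transcripts_range[0],
                                n_transcripts_range[1] + 1))
        gene = generate_gene_structure(n_tr, n_exons=(5, 7),
                                       seed=int(rng.integers(2 ** 31)),
                                       name=f"gene{g}")
        table, truth = simulate_from_model(
            gene, group_fold_changes=fold_changes,
            samples_per_group=samples_per_group, tokens_mean=tokens_mean,
            tokens_dispersion=tokens_dispersion,
            seed=int(rng.integers(2 ** 31)))
        genes.append(CohortGene(gene, table, truth))
    pairs = [
        {"group_a": a, "group_b": b,
         "differential": fold_changes[a] != fold_changes[b]}
        for a in range(len(fold_changes)) for b in range(a + 1, len(fold_changes))
    ]
    return genes, pairs
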