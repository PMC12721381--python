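"""Hierarchical Bayesian admixture model over SEEJs and its Gibbs sampler.

Generative model for one locus with K SEEJs, |V| unique junctions and N
samples:

* structure: ``pi_k ~ Beta(r, s)``; ``b_kv ~ Bernoulli(pi_k)`` subject to
  ``b_k`` being an independent set of the conflict graph (a valid SEEJ);
* emission: ``beta_k ~ Dirichlet(eta * b_k)`` — a *degenerate* Dirichlet
  whose support is exactly the SEEJ's active junctions;
* admixture: ``theta_i ~ Dirichlet(alpha)``; each junction-read token j of
  sample i picks a SEEJ ``z_ij ~ Multinomial(theta_i)`` and a junction
  ``w_ij ~ Multinomial(beta_{z_ij})``.

Junction-read tokens for the same (sample, junction) pair are exchangeable,
so ``z`` is stored collapsed as per-(sample, junction) assignment-count
vectors and sampled with one multinomial draw per pair instead of one
categorical draw per token.

The SEEJ-structure variables ``b_k`` live on the independent sets of the
conflict graph; they are updated by a Metropolized Gibbs scan: a handful of
single add/remove proposals plus the current configuration form the support,
and one is drawn from the structure complete conditional

``p(phi | .) ∝ pi^(r+|phi|-1) (1-pi)^(s+|N(phi)|-1)
  * Gamma(sum_{i in phi} eta_i) / prod_{i in phi} Gamma(eta_i)
  * prod_{i in phi} beta_i^(eta_i - 1)``

where N(phi) is the neighborhood of phi in the graph; inactive dimensions
contribute nothing (degenerate-Dirichlet convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import norm as _norm

from .conflict_graph import ConflictGraph
from .junctions import JunctionReadTable

_BETA_FLOOR = 1e-300  # active beta entries are clipped strictly positive


@dataclass
class Hyperparams:
    """Hyperparameters of the SEEJ admixture model.

    Parameters
    ----------
    n_seejs : int
        K, the number of SEEJs; must be >= the conflict graph's chromatic
        number for every observed junction to be coverable.
    alpha : float or array
        Dirichlet concentration over SEEJs per sample (scalar = symmetric).
    eta : float or array
        Dirichlet concentration over junctions (scalar = symmetric). Small
        values (the grid-selected default is 0.01) favor SEEJs that
        concentrate read mass on few junctions.
    r, s : float
        Beta prior shapes on the junction-inclusion probability pi_k; the
        prior mean r/(r+s) tunes SEEJ length.
    n_candidates : int
        Structure proposals per SEEJ per iteration.
    n_iter : int
        Maximum Gibbs iterations (tau).
    seed : int
        Chain seed; all stochastic steps draw from one generator in fixed
        order, so runs are bitwise reproducible.
    """

    n_seejs: int
    alpha: float | np.ndarray = 1.0
    eta: float | np.ndarray = 0.01
    r: float = 1.0
    s: float = 1.0
    n_candidates: int = 10
    n_iter: int = 500
    seed: int = 0
    sigma: float = 0.001
    window: int = 50
    confidence: float = 0.95
    n_average: int = 50

    def alpha_vec(self) -> np.ndarray:
        a = np.broadcast_to(np.asarray(self.alpha, dtype=float), (self.n_seejs,))
        if (a <= 0).any():
            raise ValueError("alpha must be positive")
        return a.copy()

    def eta_vec(self, n_junctions: int) -> np.ndarray:
        e = np.broadcast_to(np.asarray(self.eta, dtype=float), (n_junctions,))
        if (e <= 0).any():
            raise ValueError("eta must be positive")
        return e.copy()


@dataclass
class ModelState:
    """Latent variables of one Gibbs iteration for a locus.

    ``z[i, v, k]`` counts sample i's junction-v tokens assigned to SEEJ k
    (collapsed representation); ``theta`` is the N x K sample-level SEEJ
    mixture; ``pi`` the K junction-inclusion probabilities; ``b`` the K x |V|
    SEEJ membership indicators; ``beta`` the K x |V| junction emission
    distributions with zeros exactly off-support.
    """

    z: np.ndarray
    theta: np.ndarray
    pi: np.ndarray
    b: np.ndarray
    beta: np.ndarray

    def copy(self) -> "ModelState":
        return ModelState(self.z.copy(), self.theta.copy(), self.pi.copy(),
                          self.b.copy(), self.beta.copy())

    def validate(self, graph: ConflictGraph) -> None:
        K, V = self.b.shape
        for k in range(K):
            active = np.flatnonzero(self.b[k])
            if not graph.is_independent(active):
                raise AssertionError(f"SEEJ {k} is not an independent set")
            if (self.beta[k, ~self.b[k].astype(bool)] != 0).any():
                raise AssertionError(f"beta[{k}] has mass off-support")
            if active.size and not (self.beta[k, active] > 0).all():
                raise AssertionError(f"beta[{k}] has non-positive active entries")
        inactive = ~self.b.astype(bool).T  # (V, K)
        if (self.z * inactive[None, :, :]).sum() != 0:
            raise AssertionError("tokens assigned to inactive dimensions")
        if not np.allclose(self.theta.sum(axis=1), 1.0, atol=1e-9):
            raise AssertionError("theta rows must sum to 1")


@dataclass
class SeejComponent:
    """One collapsed posterior SEEJ."""

    junctions: frozenset[int]           # used-junction configuration
    sample_counts: np.ndarray           # (N,) assigned tokens per sample
    beta_mean: np.ndarray               # (|V|,) posterior-mean emission
    theta_mean: np.ndarray | None = None  # filled by SEEJPosterior


@dataclass
class SEEJPosterior:
    """Collapsed posterior: distinct SEEJ configurations with read support."""

    components: list[SeejComponent]
    theta_mean: np.ndarray              # (N, n_components) usage proportions
    loglik_trace: np.ndarray
    n_input_seejs: int

    @property
    def effective_k(self) -> int:
        return len(self.components)

    def count_matrix(self) -> np.ndarray:
        """samples x SEEJs matrix of assigned token counts."""
        if not self.components:
            return np.zeros((0, 0))
        return np.stack([c.sample_counts for c in self.components], axis=1)

    def configurations(self) -> list[frozenset[int]]:
        return [c.junctions for c in self.components]


# ---------------------------------------------------------------------------
# complete-conditional samplers
# ---------------------------------------------------------------------------

def _dirichlet_rows(shape_params: np.ndarray, rng: np.random.Generator
                    ) -> np.ndarray:
    """Batched Dirichlet draws via normalized gammas (rows of shape_params)."""
    g = rng.standard_gamma(shape_params)
    g = np.clip(g, _BETA_FLOOR, None)
    return g / g.sum(axis=-1, keepdims=True)


def init_state(table: JunctionReadTable, graph: ConflictGraph,
               hyper: Hyperparams, rng: np.random.Generator | None = None
               ) -> ModelState:
    """Randomly initialize all latent variables.

    The first chi(G) SEEJs are set to the color classes of a greedy interval
    coloring, so every observed junction belongs to at least one SEEJ (the
    likelihood is otherwise zero and token assignment undefined); remaining
    SEEJs are randomized greedy independent sets.
    """
    if rng is None:
        rng = np.random.default_rng(hyper.seed)
    K, V, N = hyper.n_seejs, table.n_junctions, table.n_samples
    chi = graph.chromatic_number
    if K < chi:
        raise ValueError(f"n_seejs={K} is below the chromatic number {chi}")

    b = np.zeros((K, V), dtype=bool)
    for v, color in _greedy_coloring(graph).items():
        b[color, v] = True
    for k in range(chi, K):
        order = rng.permutation(V)
        chosen: set[int] = set()
        for v in order:
            if rng.random() < 0.5 and not (graph.neighbors(int(v)) & chosen):
                chosen.add(int(v))
        b[k, list(chosen)] = True

    eta = hyper.eta_vec(V)
    pi = rng.beta(hyper.r, hyper.s, size=K)
    pi = np.clip(pi, 1e-12, 1 - 1e-12)
    beta = np.zeros((K, V))
    for k in range(K):
        active = np.flatnonzero(b[k])
        if active.size:
            beta[k, active] = _dirichlet_rows(eta[active], rng)
    theta = _dirichlet_rows(np.tile(hyper.alpha_vec(), (N, 1)), rng)
    state = ModelState(z=np.zeros((N, V, K), dtype=np.int64),
                       theta=theta, pi=pi, b=b, beta=beta)
    sample_assignments(state, table, rng)
    return state


def _greedy_coloring(graph: ConflictGraph) -> dict[int, int]:
    """Proper coloring of the interval graph with chi(G) colors (greedy in
    start order)."""
    order = sorted(range(graph.n_vertices),
                   key=lambda v: (graph.junctions[v].chrom,
                                  graph.junctions[v].start,
                                  graph.junctions[v].end))
    colors: dict[int, int] = {}
    for v in order:
        used = {colors[u] for u in graph.neighbors(v) if u in colors}
        c = 0
        while c in used:
            c += 1
        colors[v] = c
    return colors


def sample_assignments(state: ModelState, table: JunctionReadTable,
                       rng: np.random.Generator) -> None:
    """Sample token-to-SEEJ assignments, one multinomial per (sample,
    junction) pair.

    ``p_k ∝ theta_ik * beta_kv``. Tokens for a junction contained in no
    active SEEJ have an all-zero assignment law, which is a model breach
    (orphan repair is expected to prevent it) and raises.
    """
    counts = table.counts                      # (N, V)
    p = state.theta[:, None, :] * state.beta.T[None, :, :]   # (N, V, K)
    totals = p.sum(axis=2)
    observed = counts > 0
    dead = observed & (totals <= 0)
    if dead.any():
        i, v = np.argwhere(dead)[0]
        j = table.junctions[v]
        raise RuntimeError(
            f"junction {j.chrom}:{j.start}-{j.end} (sample {table.sample_ids[i]}) "
            "is contained in no active SEEJ; model repair required"
        )
    safe = np.where(totals[..., None] > 0, p, 1.0 / state.b.shape[0])
    safe = safe / safe.sum(axis=2, keepdims=True)
    state.z = rng.multinomial(counts, safe)
    state.z[~observed] = 0


def sample_theta(state: ModelState, hyper: Hyperparams,
                 rng: np.random.Generator) -> None:
    """Conjugate update: theta_i ~ Dirichlet(alpha + c_i), c_ik = tokens of
    sample i assigned to SEEJ k."""
    c = state.z.sum(axis=1)                    # (N, K)
    state.theta = _dirichlet_rows(hyper.alpha_vec()[None, :] + c, rng)


def sample_pi(state: ModelState, hyper: Hyperparams,
              rng: np.random.Generator) -> None:
    """Conjugate update: pi_k ~ Beta(r + m_k, s + |V| - m_k), with m_k the
    number of active junctions in SEEJ k."""
    V = state.b.shape[1]
    m = state.b.sum(axis=1)
    state.pi = np.clip(rng.beta(hyper.r + m, hyper.s + V - m),
                       1e-12, 1 - 1e-12)


def _prior_mean_beta(phi: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Prior-mean emission over the active set phi (indices)."""
    out = np.zeros(eta.shape)
    if phi.size:
        out[phi] = eta[phi] / eta[phi].sum()
    return out


def scoring_beta(beta_k: np.ndarray, phi, eta: np.ndarray) -> np.ndarray:
    """Extend a current emission vector to a candidate active set.

    Junctions of ``phi`` already carrying mass keep it; newly activated
    junctions (current beta 0) receive their prior-mean pseudo-mass
    ``eta_v / sum_{phi} eta``; the vector is renormalized over ``phi``.
    """
    phi = np.asarray(sorted(phi), dtype=int)
    out = np.zeros_like(beta_k)
    if phi.size == 0:
        return out
    vals = beta_k[phi].astype(float).copy()
    prior = eta[phi] / eta[phi].sum()
    missing = vals <= 0
    vals[missing] = prior[missing]
    out[phi] = vals / vals.sum()
    return out


def propose_seej_candidates(b_k: np.ndarray, beta_k: np.ndarray,
                            graph: ConflictGraph, n_candidates: int,
                            rng: np.random.Generator,
                            eta: np.ndarray | None = None
                            ) -> list[frozenset[int]]:
    """Generate candidate SEEJs by single add/remove moves from ``b_k``.

    With current size m, an add move is chosen with probability
    ``1 - m / alpha(G)``. Adds pick a junction compatible with the current
    set (and inactive) with probability proportional to ``beta_kv``; since a
    freshly drawn beta has no mass off-support, a small prior-mean
    pseudo-mass keeps inactive junctions proposable. Removes pick an active
    junction with probability proportional to ``1 - beta_kv``. An infeasible
    move type (saturated set + add, empty set + remove) falls back to the
    other type. Every candidate is a valid independent set by construction.
    """
    V = b_k.shape[0]
    eta = np.ones(V) if eta is None else eta
    current = frozenset(np.flatnonzero(b_k).tolist())
    m = len(current)
    alpha_hat = graph.mis_size
    if alpha_hat <= 0:
        raise ValueError("graph has no vertices")
    blocked = graph.neighborhood(current)
    addable = [v for v in range(V) if v not in current and v not in blocked]
    prior = eta / eta.sum()

    candidates: list[frozenset[int]] = []
    for _ in range(n_candidates):
        add = rng.random() < 1.0 - m / alpha_hat
        if add and not addable:
            add = False
        if not add and m == 0:
            add = True
        if add and not addable:          # single isolated saturated vertex
            candidates.append(current)
            continue
        if add:
            w = beta_k[addable] + 1e-6 * prior[addable]
            v = addable[_categorical(w, rng)]
            candidates.append(current | {v})
        else:
            members = sorted(current)
            w = 1.0 - beta_k[members]
            v = members[_categorical(np.clip(w, 0.0, None), rng)]
            candidates.append(current - {v})
    return candidates


def _categorical(weights: np.ndarray, rng: np.random.Generator) -> int:
    total = weights.sum()
    if total <= 0:
        weights = np.ones_like(weights)
        total = weights.sum()
    return int(rng.choice(len(weights), p=weights / total))


def seej_log_conditional(phi, pi_k: float, eta: np.ndarray,
                         beta_k: np.ndarray, graph: ConflictGraph,
                         r: float = 1.0, s: float = 1.0) -> float:
    """Unnormalized log complete-conditional weight of a candidate SEEJ.

    ``log pi^(r+|phi|-1) (1-pi)^(s+|N(phi)|-1)`` plus the degenerate
    Dirichlet log-density of ``beta_k`` restricted to phi: inactive
    dimensions contribute nothing. ``beta_k`` must be strictly positive on
    phi (use :func:`scoring_beta` to extend a current draw to a candidate).
    """
    phi = np.asarray(sorted(phi), dtype=int)
    if not graph.is_independent(phi.tolist()):
        raise ValueError("phi is not a valid SEEJ (independent set)")
    n_phi = len(graph.neighborhood(phi.tolist()))
    logw = (r + phi.size - 1) * np.log(pi_k) \
        + (s + n_phi - 1) * np.log1p(-pi_k)
    if phi.size:
        bvals = beta_k[phi]
        if (bvals <= 0).any():
            raise ValueError("beta_k must be strictly positive on active dims")
        e = eta[phi]
        logw += gammaln(e.sum()) - gammaln(e).sum() \
            + ((e - 1.0) * np.log(bvals)).sum()
    return float(logw)


def sample_seej_structure(state: ModelState, hyper: Hyperparams,
                          graph: ConflictGraph, rng: np.random.Generator,
                          table: JunctionReadTable | None = None) -> None:
    """Metropolized Gibbs update of every SEEJ's junction configuration.

    For each SEEJ the support is {current configuration} plus
    ``n_candidates`` single add/remove proposals; one is drawn with
    probability proportional to exp(:func:`seej_log_conditional`). Including
    the current configuration keeps the support non-empty and allows
    rejection. Afterwards observed junctions left in no SEEJ are repaired,
    and tokens stranded on deactivated dimensions are resampled so the
    support invariant holds before the emission update.
    """
    K, V = state.b.shape
    eta = hyper.eta_vec(V)
    for k in range(K):
        cands = propose_seej_candidates(state.b[k], state.beta[k], graph,
                                        hyper.n_candidates, rng, eta=eta)
        support = [frozenset(np.flatnonzero(state.b[k]).tolist())] + cands
        logw = np.empty(len(support))
        for idx, phi in enumerate(support):
            sb = scoring_beta(state.beta[k], phi, eta)
            logw[idx] = seej_log_conditional(phi, float(state.pi[k]), eta, sb,
                                             graph, r=hyper.r, s=hyper.s)
        probs = np.exp(logw - logsumexp(logw))
        winner = support[int(rng.choice(len(support), p=probs / probs.sum()))]
        new_b = np.zeros(V, dtype=bool)
        new_b[sorted(winner)] = True
        if not np.array_equal(new_b, state.b[k]):
            state.beta[k] = scoring_beta(state.beta[k], winner, eta)
            state.b[k] = new_b
    if table is not None:
        repair_orphans(state, table, graph, eta)
        _resample_stranded(state, rng)


def repair_orphans(state: ModelState, table: JunctionReadTable,
                   graph: ConflictGraph, eta: np.ndarray) -> None:
    """Force every observed junction into at least one SEEJ.

    An observed junction contained in no active SEEJ has likelihood zero, so
    it is added to the compatible SEEJ with the highest emission potential:
    the expected posterior token mass ``sum_i n_iv * theta_ik``, i.e. the
    SEEJ whose sample-level usage best co-varies with the junction's
    abundance. If it conflicts with every SEEJ, the SEEJ with the fewest
    conflicting junctions evicts them first. Deterministic given the state.
    """
    observed = np.flatnonzero(table.counts.sum(axis=0) > 0)
    K = state.b.shape[0]
    queue = [v for v in observed if not state.b[:, v].any()]
    guard = 0
    while queue:
        guard += 1
        if guard > 10 * state.b.shape[1] * K:
            raise RuntimeError("orphan repair failed to stabilize")
        v = queue.pop(0)
        if state.b[:, v].any():
            continue
        neighbors = graph.neighbors(v)
        potential = table.counts[:, v].astype(float) @ state.theta  # (K,)
        best_k, best_pot = None, -np.inf
        for k in range(K):
            active = set(np.flatnonzero(state.b[k]).tolist())
            if active & neighbors:
                continue
            if potential[k] > best_pot:
                best_k, best_pot = k, float(potential[k])
        if best_k is None:
            conflicts = [(len(set(np.flatnonzero(state.b[k]).tolist()) & neighbors), k)
                         for k in range(K)]
            _, best_k = min(conflicts)
            evicted = sorted(set(np.flatnonzero(state.b[best_k]).tolist()) & neighbors)
            state.b[best_k, evicted] = False
            queue.extend(u for u in evicted
                         if u in set(observed.tolist()) and not state.b[:, u].any())
        state.b[best_k, v] = True
        phi = frozenset(np.flatnonzero(state.b[best_k]).tolist())
        state.beta[best_k] = scoring_beta(state.beta[best_k], phi, eta)


def _resample_stranded(state: ModelState, rng: np.random.Generator) -> None:
    """Reassign tokens whose SEEJ no longer contains their junction."""
    active = state.b.T                      # (V, K)
    stranded = state.z * (~active[None, :, :])
    n_stranded = stranded.sum(axis=2)       # (N, V)
    if not n_stranded.any():
        state.z = state.z * active[None, :, :]
        return
    state.z = state.z * active[None, :, :]
    p = state.theta[:, None, :] * state.beta.T[None, :, :]
    totals = p.sum(axis=2)
    bad = (n_stranded > 0) & (totals <= 0)
    if bad.any():
        raise RuntimeError("stranded tokens have no admissible SEEJ")
    safe = np.where(totals[..., None] > 0, p, 1.0)
    safe = safe / safe.sum(axis=2, keepdims=True)
    state.z = state.z + rng.multinomial(n_stranded, safe) * active[None, :, :]


def sample_beta(state: ModelState, hyper: Hyperparams,
                rng: np.random.Generator) -> None:
    """Conjugate update of the degenerate Dirichlet emissions.

    ``beta_k ~ Dirichlet(eta_v + n_kv over active v)`` with
    ``n_kv`` = tokens of junction v assigned to SEEJ k; inactive dimensions
    stay exactly zero. A SEEJ with no active dimension keeps a zero vector
    and is excluded from the assignment support.
    """
    K, V = state.b.shape
    eta = hyper.eta_vec(V)
    n_kv = state.z.sum(axis=0).T            # (K, V)
    beta = np.zeros((K, V))
    for k in range(K):
        active = np.flatnonzero(state.b[k])
        if active.size:
            beta[k, active] = _dirichlet_rows(eta[active] + n_kv[k, active], rng)
    state.beta = beta


def log_joint(state: ModelState, table: JunctionReadTable,
              hyper: Hyperparams) -> float:
    """Log of the joint density of data and latent variables (used as the
    convergence trace)."""
    K, V = state.b.shape
    alpha = hyper.alpha_vec()
    eta = hyper.eta_vec(V)
    theta = np.clip(state.theta, 1e-300, None)
    ll = 0.0
    # likelihood of assigned tokens
    logp = np.log(theta)[:, None, :] + np.log(
        np.where(state.beta.T[None, :, :] > 0, state.beta.T[None, :, :], 1.0))
    ll += float((state.z * np.where(state.beta.T[None, :, :] > 0, logp, 0.0)).sum())
    # theta prior
    N = theta.shape[0]
    ll += N * (gammaln(alpha.sum()) - gammaln(alpha).sum())
    ll += float(((alpha - 1.0) * np.log(theta)).sum())
    # pi prior and b given pi
    r, s = hyper.r, hyper.s
    pi = state.pi
    m = state.b.sum(axis=1)
    ll += float(((r - 1) * np.log(pi) + (s - 1) * np.log1p(-pi)).sum())
    ll += K * (gammaln(r + s) - gammaln(r) - gammaln(s))
    ll += float((m * np.log(pi) + (V - m) * np.log1p(-pi)).sum())
    # degenerate Dirichlet emissions
    for k in range(K):
        active = np.flatnonzero(state.b[k])
        if active.size:
            e = eta[active]
            bvals = np.clip(state.beta[k, active], 1e-300, None)
            ll += float(gammaln(e.sum()) - gammaln(e).sum()
                        + ((e - 1.0) * np.log(bvals)).sum())
    return ll


def collapsed_structure_score(state: ModelState, hyper: Hyperparams) -> float:
    """Collapsed joint score of the current assignments and structure.

    log p(z, w | b, alpha, eta) with theta and beta integrated out
    analytically (Dirichlet-multinomial marginals). Unlike the raw log
    joint, this score contains no Dirichlet *densities* evaluated at spiky
    draws, so it is stable across structures and is used to arbitrate
    between independent chains.
    """
    K, V = state.b.shape
    alpha = hyper.alpha_vec()
    eta = hyper.eta_vec(V)
    c = state.z.sum(axis=1)          # (N, K)
    n_kv = state.z.sum(axis=0).T     # (K, V)
    score = float((gammaln(alpha.sum()) - gammaln(alpha.sum() + c.sum(axis=1))).sum()
                  + (gammaln(alpha[None, :] + c) - gammaln(alpha[None, :])).sum())
    for k in range(K):
        active = np.flatnonzero(state.b[k])
        if active.size:
            e = eta[active]
            nk = n_kv[k, active]
            score += float(gammaln(e.sum()) - gammaln(e.sum() + nk.sum())
                           + (gammaln(e + nk) - gammaln(e)).sum())
    return score


def has_converged(trace, sigma: float = 0.001, window: int = 50,
                  confidence: float = 0.95) -> bool:
    """Relative fixed-width stopping rule on the log-likelihood trace.

    Converged when the confidence-interval half-width of the windowed mean,
    relative to the absolute mean, falls below ``sigma``.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < window:
        return False
    w = trace[-window:]
    mean = w.mean()
    if mean == 0.0:
        return bool(np.allclose(w, 0.0))
    z = _norm.ppf(0.5 + confidence / 2.0)
    half = z * w.std(ddof=1) / np.sqrt(window)
    return bool(half / abs(mean) < sigma)


# ---------------------------------------------------------------------------
# chain driver and posterior collapsing
# ---------------------------------------------------------------------------

@dataclass
class GibbsChain:
    """Result of one Gibbs run: the final draw, the log-joint trace, and
    structure-conditional posterior means from averaging sweeps."""

    state: ModelState
    trace: np.ndarray
    converged: bool
    n_iterations: int
    theta_mean: np.ndarray
    beta_mean: np.ndarray
    z_mean: np.ndarray
    structure_score: float = -np.inf
    initial_state: ModelState | None = None


def run_chain(table: JunctionReadTable, graph: ConflictGraph,
              hyper: Hyperparams, check_invariants: bool = False,
              rng: np.random.Generator | None = None) -> GibbsChain:
    """Run the Gibbs sampler: per iteration sample z, theta, pi, b, beta in
    order; stop at ``n_iter`` or when :func:`has_converged` fires.

    After the chain stops, the SEEJ structure is frozen at the final draw
    and ``n_average`` extra sweeps over (z, theta, beta) accumulate
    structure-conditional posterior means, which the collapsed posterior
    summaries use.
    """
    if rng is None:
        rng = np.random.default_rng(hyper.seed)
    state = init_state(table, graph, hyper, rng)
    initial = state.copy()
    eta = hyper.eta_vec(table.n_junctions)
    trace = [log_joint(state, table, hyper)]
    converged = False
    it = 0
    for it in range(1, hyper.n_iter + 1):
        sample_assignments(state, table, rng)
        sample_theta(state, hyper, rng)
        sample_pi(state, hyper, rng)
        sample_seej_structure(state, hyper, graph, rng, table=table)
        sample_beta(state, hyper, rng)
        if check_invariants:
            state.validate(graph)
        trace.append(log_joint(state, table, hyper))
        if it >= hyper.window and it % 10 == 0 and has_converged(
                trace, hyper.sigma, hyper.window, hyper.confidence):
            converged = True
            break
    if hyper.n_iter == 0:
        it = 0

    # structure-conditional averaging sweeps (b frozen at the final draw)
    theta_sum = np.zeros_like(state.theta)
    beta_sum = np.zeros_like(state.beta)
    z_sum = np.zeros(state.z.shape, dtype=float)
    score_sum = 0.0
    n_avg = max(1, hyper.n_average)
    for _ in range(n_avg):
        sample_assignments(state, table, rng)
        sample_theta(state, hyper, rng)
        sample_beta(state, hyper, rng)
        theta_sum += state.theta
        beta_sum += state.beta
        z_sum += state.z
        score_sum += collapsed_structure_score(state, hyper)
    return GibbsChain(state=state, trace=np.asarray(trace), converged=converged,
                      n_iterations=it, theta_mean=theta_sum / n_avg,
                      beta_mean=beta_sum / n_avg, z_mean=z_sum / n_avg,
                      structure_score=score_sum / n_avg,
                      initial_state=initial)


def collapse_seejs(chain: GibbsChain, min_tokens: float = 0.5) -> SEEJPosterior:
    """Merge SEEJs with the same configuration into the collapsed posterior.

    A SEEJ's reported configuration is its *used-junction* set: active
    junctions that actually received posterior tokens (> ``min_tokens``
    expected tokens across all samples). Active-but-never-used junctions are
    excluded so reported segments contain only data-supported junctions.
    SEEJs with identical configurations are combined (per-sample counts
    summed, emissions averaged and renormalized over the configuration);
    empty configurations are dropped.
    """
    state = chain.state
    K, V = state.b.shape
    N = state.theta.shape[0]
    groups: dict[frozenset[int], list[int]] = {}
    for k in range(K):
        used = frozenset(
            v for v in np.flatnonzero(state.b[k]).tolist()
            if chain.z_mean[:, v, k].sum() > min_tokens
        )
        if used:
            groups.setdefault(used, []).append(k)

    components: list[SeejComponent] = []
    for config in sorted(groups, key=lambda c: tuple(sorted(c))):
        ks = groups[config]
        counts = chain.z_mean[:, :, ks].sum(axis=(1, 2))
        beta = chain.beta_mean[ks].mean(axis=0)
        mask = np.zeros(V, dtype=bool)
        mask[sorted(config)] = True
        beta = np.where(mask, beta, 0.0)
        if beta.sum() > 0:
            beta = beta / beta.sum()
        components.append(SeejComponent(config, counts, beta))

    if components:
        theta_mean = np.stack(
            [chain.theta_mean[:, groups[c.junctions]].sum(axis=1)
             for c in components], axis=1)
        totals = theta_mean.sum(axis=1, keepdims=True)
        theta_mean = np.where(totals > 0, theta_mean / totals, 1.0 / len(components))
        for c, col in zip(components, theta_mean.T):
            c.theta_mean = col
    else:
        theta_mean = np.zeros((N, 0))
    return SEEJPosterior(components=components, theta_mean=theta_mean,
                         loglik_trace=chain.trace, n_input_seejs=K)


# ---------------------------------------------------------------------------
# scikit-learn style estimator
# ---------------------------------------------------------------------------

try:  # sklearn is a hard dependency, but keep the import local to the class
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    BaseEstimator = object


class SeejAdmixture(BaseEstimator):
    """SEEJ admixture model fit by Gibbs sampling (scikit-learn style).

    Parameters mirror :class:`Hyperparams`; ``n_seejs=None`` uses
    ``chi(G) + k_extra``. ``n_chains`` independent chains are run (seeds
    derived from ``random_state``) and the one with the highest collapsed
    structure score is kept — the sampler's structure moves can stall in
    local partitions, and the collapsed marginal arbitrates between chains.
    Call
    :meth:`fit` with a :class:`~seejmix.junctions.JunctionReadTable` (or a
    counts matrix plus a junction list).

    Attributes (after fit)
    ----------------------
    graph_ : ConflictGraph
    posterior_ : SEEJPosterior — collapsed SEEJs and read support
    components_ : list[frozenset[int]] — used-junction configurations
    theta_ : (n_samples, effective_k) posterior-mean SEEJ usage
    n_effective_seejs_ : int
    converged_, n_iterations_, loglik_trace_
    """

    def __init__(self, n_seejs: int | None = None, k_extra: int = 4,
                 alpha: float = 1.0, eta: float = 0.01, r: float = 1.0,
                 s: float = 1.0, n_candidates: int = 10, n_iter: int = 500,
                 sigma: float = 0.001, window: int = 50,
                 confidence: float = 0.95, n_average: int = 50,
                 n_chains: int = 1, random_state: int = 0,
                 check_invariants: bool = False):
        self.n_seejs = n_seejs
        self.k_extra = k_extra
        self.n_chains = n_chains
        self.alpha = alpha
        self.eta = eta
        self.r = r
        self.s = s
        self.n_candidates = n_candidates
        self.n_iter = n_iter
        self.sigma = sigma
        self.window = window
        self.confidence = confidence
        self.n_average = n_average
        self.random_state = random_state
        self.check_invariants = check_invariants

    def _as_table(self, X, junctions=None) -> JunctionReadTable:
        if isinstance(X, JunctionReadTable):
            return X
        if junctions is None:
            raise ValueError("pass a JunctionReadTable or (counts, junctions)")
        return JunctionReadTable("locus", list(junctions), np.asarray(X))

    def fit(self, X, junctions=None):
        from .conflict_graph import build_conflict_graph

        table = self._as_table(X, junctions)
        self.graph_ = build_conflict_graph(table.junctions,
                                           seed=self.random_state)
        k = self.n_seejs
        if k is None:
            k = self.graph_.chromatic_number + self.k_extra
        best = None
        for c in range(max(1, self.n_chains)):
            hyper = Hyperparams(
                n_seejs=k, alpha=self.alpha, eta=self.eta, r=self.r, s=self.s,
                n_candidates=self.n_candidates, n_iter=self.n_iter,
                seed=(self.random_state + 1_000_003 * c) % (2 ** 31),
                sigma=self.sigma, window=self.window,
                confidence=self.confidence, n_average=self.n_average)
            chain = run_chain(table, self.graph_, hyper,
                              check_invariants=self.check_invariants)
            if best is None or chain.structure_score > best[0]:
                best = (chain.structure_score, hyper, chain)
        _, self.hyper_, self.chain_ = best
        self.posterior_ = collapse_seejs(self.chain_)
        self.components_ = self.posterior_.configurations()
        self.theta_ = self.posterior_.theta_mean
        self.n_effective_seejs_ = self.posterior_.effective_k
        self.converged_ = self.chain_.converged
        self.n_iterations_ = self.chain_.n_iterations
        self.loglik_trace_ = self.chain_.trace
        self.table_ = table
        return self

    def score(self, X, junctions=None, floor: float = 1e-8) -> float:
        """Predictive log-likelihood of held-out junction counts (see
        :mod:`seejmix.selection`)."""
        from .selection import predictive_log_likelihood

        table = self._as_table(X, junctions)
        return predictive_log_likelihood(self, table, floor=floor)

    def seej_count_matrix(self) -> np.ndarray:
        """samples x effective-SEEJs assigned-token counts."""
        return self.posterior_.count_matrix()

    def to_json(self) -> str:
        """Serialize the fitted model (configurations, emissions, usage,
        trace)."""
        post = self.posterior_
        payload = {
            "n_input_seejs": post.n_input_seejs,
            "effective_k": post.effective_k,
            "junctions": [
                {"chrom": j.chrom, "start": j.start, "end": j.end,
                 "strand": j.strand}
                for j in self.table_.junctions
            ],
            "sample_ids": list(self.table_.sample_ids),
            "components": [
                {"junctions": sorted(c.junctions),
                 "sample_counts": c.sample_counts.tolist(),
                 "beta_mean": c.beta_mean.tolist()}
                for c in post.components
            ],
            "theta_mean": post.theta_mean.tolist(),
            "loglik_trace": post.loglik_trace.tolist(),
            "converged": bool(self.converged_),
            "n_iterations": int(self.n_iterations_),
            "random_state": self.random_state,
        }
        return json.dumps(payload, indent=1)


def fit_locus(table: JunctionReadTable, **params) -> SeejAdmixture:
    """Thin functional wrapper over :class:`SeejAdmixture`."""
    return SeejAdmixture(**params).fit(table)
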