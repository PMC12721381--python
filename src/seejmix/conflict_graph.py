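"""Interval (conflict) graph over a locus's junctions.

Vertices are the locus's unique junctions; an edge joins two junctions whose
intron intervals strictly overlap, i.e. ``min(t, t') - max(s, s') > 0``.
Two overlapping junctions cannot be excised by the same transcript, so an
independent set of this graph is exactly a structurally valid SEEJ.

The admixture model needs three quantities from the graph:

* a minimum node cover ``C`` — the smallest set of junction-membership
  Bernoulli variables that can encode every pairwise conflict (the membership
  of a non-cover neighbor is the complement of a cover variable);
* the chromatic number ``chi(G)`` — for interval graphs the maximum clique
  size, i.e. the maximum overlap depth; it lower-bounds the number of SEEJs;
* the maximum-independent-set size ``alpha(G)`` — normalizes the add/remove
  probability of the structure sampler's proposals.

All three are computed by classical interval-graph sweeps in O(|V| log |V|),
and (by the Gallai identity) ``alpha(G) + |C| = |V|``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .junctions import Junction


def junctions_overlap(a: Junction, b: Junction) -> bool:
    """Strict interval overlap: ``min(end, end') - max(start, start') > 0``.

    Junctions on different chromosomes never overlap. Touching half-open
    intervals ([100,200) vs [200,300)) do not overlap.
    """
    if a.chrom != b.chrom:
        return False
    return min(a.end, b.end) - max(a.start, b.start) > 0


@dataclass
class ConflictGraph:
    """Interval graph over junctions with the model's derived quantities."""

    junctions: list[Junction]
    edges: frozenset[tuple[int, int]] = field(default_factory=frozenset)
    node_cover: frozenset[int] = field(default_factory=frozenset)
    encoding: dict[int, int] = field(default_factory=dict)
    chromatic_number: int = 1
    mis_size: int = 0
    _adj: list[set[int]] = field(default_factory=list, repr=False)

    @property
    def n_vertices(self) -> int:
        return len(self.junctions)

    def neighbors(self, v: int) -> set[int]:
        return self._adj[v]

    def neighborhood(self, vertices) -> set[int]:
        """N(S): vertices adjacent to any member of S (may include S members
        only if S is not independent)."""
        out: set[int] = set()
        for v in vertices:
            out |= self._adj[v]
        return out - set(vertices)

    def is_independent(self, vertices) -> bool:
        vs = set(vertices)
        return all(not (self._adj[v] & vs) for v in vs)

    def to_edge_list(self) -> str:
        return "\n".join(f"{u}\t{v}" for u, v in sorted(self.edges))

    def to_dot(self) -> str:
        lines = ["graph conflicts {"]
        for v, j in enumerate(self.junctions):
            lines.append(f'  {v} [label="{j.chrom}:{j.start}-{j.end}"];')
        for u, v in sorted(self.edges):
            lines.append(f"  {u} -- {v};")
        lines.append("}")
        return "\n".join(lines)


def is_valid_seej(graph: ConflictGraph, junction_set) -> bool:
    """A junction set is a valid SEEJ iff it is independent in the conflict
    graph (the empty set is valid)."""
    return graph.is_independent(junction_set)


def _sorted_by_end(junctions: list[Junction]) -> list[int]:
    # deterministic greedy order: (end, start, index)
    return sorted(range(len(junctions)),
                  key=lambda v: (junctions[v].end, junctions[v].start, v))


def maximum_independent_set(junctions: list[Junction],
                            adj: list[set[int]]) -> set[int]:
    """Greedy earliest-endpoint maximum independent set (exact on interval
    graphs): scan by increasing interval end and take every vertex compatible
    with the current selection."""
    chosen: set[int] = set()
    for v in _sorted_by_end(junctions):
        if not (adj[v] & chosen):
            chosen.add(v)
    return chosen


def build_conflict_graph(junctions: list[Junction],
                         seed: int | None = 0) -> ConflictGraph:
    """Build the conflict graph and populate all derived fields.

    ``seed`` fixes the random choice in the variable encoding (a non-cover
    vertex adjacent to several cover vertices is paired with one of them
    uniformly at random).
    """
    if not junctions:
        raise ValueError("need at least one junction")
    n = len(junctions)
    adj: list[set[int]] = [set() for _ in range(n)]
    edges = set()
    order = sorted(range(n), key=lambda v: (junctions[v].chrom,
                                            junctions[v].start,
                                            junctions[v].end))
    # sweep: active intervals overlapping the current start
    active: list[int] = []
    for v in order:
        jv = junctions[v]
        active = [u for u in active
                  if junctions[u].chrom == jv.chrom and junctions[u].end > jv.start]
        for u in active:
            edges.add((min(u, v), max(u, v)))
            adj[u].add(v)
            adj[v].add(u)
        active.append(v)

    mis = maximum_independent_set(junctions, adj)
    cover = frozenset(range(n)) - frozenset(mis)  # Gallai: complement of a MIS
    graph = ConflictGraph(
        junctions=list(junctions),
        edges=frozenset(edges),
        node_cover=frozenset(cover),
        chromatic_number=_chromatic_number(junctions),
        mis_size=len(mis),
        _adj=adj,
    )
    graph.encoding = build_variable_encoding(graph, graph.node_cover, seed=seed)
    return graph


def minimum_node_cover(graph: ConflictGraph) -> frozenset[int]:
    """Minimum node cover: complement of a maximum independent set.

    A maximum independent set's complement is always a minimum vertex cover
    (Gallai), and the greedy earliest-endpoint MIS is exact on interval
    graphs, so this runs in near-linear time.
    """
    return frozenset(range(graph.n_vertices)) - frozenset(
        maximum_independent_set(graph.junctions, graph._adj)
    )


def chromatic_number(graph: ConflictGraph) -> int:
    """chi(G) = maximum clique size = maximum interval overlap depth."""
    return _chromatic_number(graph.junctions)


def _chromatic_number(junctions: list[Junction]) -> int:
    # endpoint sweep per chromosome; end events before start events at equal
    # coordinate so touching half-open intervals don't count as overlapping
    best = 1
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for j in junctions:
        ev = by_chrom.setdefault(j.chrom, [])
        ev.append((j.start, 1))
        ev.append((j.end, -1))
    for ev in by_chrom.values():
        ev.sort()  # (-1) sorts before (+1) at equal coordinate
        depth = 0
        for _, delta in ev:
            depth += delta
            best = max(best, depth)
    return best


def max_independent_set_size(graph: ConflictGraph) -> int:
    """alpha(G): size of a maximum independent set."""
    return len(maximum_independent_set(graph.junctions, graph._adj))


def build_variable_encoding(graph: ConflictGraph, cover, seed: int | None = 0
                            ) -> dict[int, int]:
    """Map each non-cover vertex with >= 1 cover neighbor to one cover
    neighbor, uniformly at random under ``seed``.

    The mapped vertex's SEEJ membership is encoded as the complement
    ``1 - b`` of its cover neighbor's Bernoulli variable, so only ``|C|``
    free variables are instantiated. Isolated vertices are unmapped (they
    appear in no conflict and carry an implicit always-on indicator).
    """
    cover = set(cover)
    for u, v in graph.edges:
        if u not in cover and v not in cover:
            raise ValueError(f"node set is not a cover: edge ({u}, {v}) uncovered")
    rng = np.random.default_rng(seed)
    encoding: dict[int, int] = {}
    for v in range(graph.n_vertices):
        if v in cover:
            continue
        cov_neighbors = sorted(graph.neighbors(v) & cover)
        if cov_neighbors:
            encoding[v] = cov_neighbors[int(rng.integers(len(cov_neighbors)))]
    return encoding
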