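import numpy as np
import pytest

from seejmix.junctions import Junction, JunctionReadTable


@pytest.fixture
def star_junctions():
    """A star S4: one long junction overlapping four short disjoint ones.

    Vertex 0 is the center; 1..4 are leaves.
    """
    return [
        Junction("chr1", 0, 100),
        Junction("chr1", 0, 10),
        Junction("chr1", 20, 30),
        Junction("chr1", 40, 50),
        Junction("chr1", 60, 70),
    ]


@pytest.fixture
def tiny_table():
    """Two samples, three pairwise-disjoint junctions."""
    juncs = [Junction("chr1", 0, 100), Junction("chr1", 200, 300),
             Junction("chr1", 400, 500)]
    counts = np.array([[5, 3, 2], [1, 0, 4]])
    return JunctionReadTable("locus", juncs, counts, ["s1", "s2"])


def random_intervals(rng, n, span=100, max_len=30):
    """Random interval set for brute-force graph oracles."""
    out = []
    for _ in range(n):
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        out.append(Junction("chr1", start, start + length))
    # dedupe (tables forbid duplicates)
    uniq = []
    seen = set()
    for j in out:
        if j not in seen:
            seen.add(j)
            uniq.append(j)
    return uniq


def brute_force_mis_size(junctions):
    """Exhaustive maximum-independent-set size."""
    from itertools import combinations
    from seejmix.conflict_graph import junctions_overlap

    n = len(junctions)
    best = 0
    for size in range(n, 0, -1):
        if size <= best:
            break
        for combo in combinations(range(n), size):
            if all(not junctions_overlap(junctions[u], junctions[v])
                   for u, v in combinations(combo, 2)):
                best = size
                break
    return best


def brute_force_min_cover_size(junctions):
    """Exhaustive minimum-vertex-cover size."""
    from itertools import combinations
    from seejmix.conflict_graph import junctions_overlap

    n = len(junctions)
    edges = [(u, v) for u in range(n) for v in range(u + 1, n)
             if junctions_overlap(junctions[u], junctions[v])]
    for size in range(0, n + 1):
        for combo in combinations(range(n), size):
            cs = set(combo)
            if all(u in cs or v in cs for u, v in edges):
                return size
    return n


def brute_force_chromatic_number(junctions):
    """Exhaustive proper-coloring chromatic number (backtracking)."""
    from seejmix.conflict_graph import junctions_overlap

    n = len(junctions)
    adj = [set() for _ in range(n)]
    for u in range(n):
        for v in range(u + 1, n):
            if junctions_overlap(junctions[u], junctions[v]):
                adj[u].add(v)
                adj[v].add(u)
    if not any(adj):
        return 1

    def colorable(k):
        colors = [-1] * n

        def rec(v):
            if v == n:
                return True
            used = {colors[u] for u in adj[v] if colors[u] >= 0}
            for c in range(k):
                if c not in used:
                    colors[v] = c
                    if rec(v + 1):
                        return True
                    colors[v] = -1
                if c > max(colors[:v], default=-1):
                    break  # symmetry: first use of a fresh color is canonical
            return False

        return rec(0)

    for k in range(2, n + 1):
        if colorable(k):
            return k
    return n
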