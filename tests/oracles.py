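"""Independent brute-force oracles used across the test suite.

Everything here is written as plainly as possible — character loops,
exhaustive enumeration, dictionary arithmetic — so it shares no code path
with the vectorised implementations it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
UNAMBIG = {"A", "C", "G", "T"}


# --- distances -------------------------------------------------------------


def k2p_bruteforce(a: str, b: str):
    """(P, Q, n, d or None) by direct character comparison."""
    n = ts = tv = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in UNAMBIG and y in UNAMBIG:
            n += 1
            if x != y:
                same_class = (x in PURINES) == (y in PURINES)
                if same_class:
                    ts += 1
                else:
                    tv += 1
    if n == 0:
        return 0.0, 0.0, 0, None
    P, Q = ts / n, tv / n
    if 1 - 2 * P - Q <= 0 or 1 - 2 * Q <= 0:
        return P, Q, n, None
    return P, Q, n, -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)


def jukes_cantor(p: float) -> float:
    return -0.75 * math.log(1 - 4 * p / 3)


# --- alignment statistics --------------------------------------------------


def recount_stats(sequences: list[str]):
    """(n_variable, n_informative, ts_pairs, tv_pairs) by per-column loops."""
    L = len(sequences[0])
    variable = informative = 0
    ts_pairs = tv_pairs = 0
    for col in range(L):
        states: dict[str, int] = {}
        for seq in sequences:
            c = seq[col].upper()
            if c in UNAMBIG:
                states[c] = states.get(c, 0) + 1
        if len(states) >= 2:
            variable += 1
            if sum(1 for v in states.values() if v >= 2) >= 2:
                informative += 1
        chars = [s[col].upper() for s in sequences]
        for i in range(len(chars)):
            for j in range(i + 1, len(chars)):
                x, y = chars[i], chars[j]
                if x in UNAMBIG and y in UNAMBIG and x != y:
                    if (x in PURINES) == (y in PURINES):
                        ts_pairs += 1
                    else:
                        tv_pairs += 1
    return variable, informative, ts_pairs, tv_pairs


# --- classification --------------------------------------------------------


def bm_oracle(dists: dict[str, float], species: dict[str, str], query: str,
              tol: float = 1e-12):
    """Best-match verdict from a plain distance dict {other_id: d}."""
    if not dists:
        return "no_match"
    dmin = min(dists.values())
    best_species = {species[k] for k, v in dists.items() if v <= dmin + tol}
    if best_species == {species[query]}:
        return "correct"
    if species[query] in best_species:
        return "ambiguous"
    return "incorrect"


def bcm_oracle(dists, species, query, threshold, tol: float = 1e-12):
    within = {k: v for k, v in dists.items() if v <= threshold}
    if not within:
        return "no_match"
    return bm_oracle(within, species, query, tol)


def asb_oracle(dists, species, query, threshold, tol: float = 1e-12):
    within = {k: v for k, v in dists.items() if v <= threshold}
    if not within:
        return "no_match"
    con = [v for k, v in dists.items() if species[k] == species[query]]
    het_in = [v for v in
              (v for k, v in within.items() if species[k] != species[query])]
    if not con:
        return "incorrect"
    if not het_in:
        return "correct"
    if max(con) < min(het_in) - tol:
        return "correct"
    if min(het_in) < max(con) - tol:
        return "incorrect"
    return "ambiguous"


def percentile_oracle(values: list[float], coverage: float) -> float:
    """Linear-interpolated percentile by explicit sort-and-index."""
    xs = sorted(values)
    if len(xs) == 1:
        return xs[0]
    pos = coverage / 100.0 * (len(xs) - 1)
    lo = int(math.floor(pos))
    hi = min(lo + 1, len(xs) - 1)
    frac = pos - lo
    return xs[lo] * (1 - frac) + xs[hi] * frac


# --- trees -----------------------------------------------------------------


def random_additive_tree(rng: np.random.Generator, n: int):
    """Random unrooted binary tree as nested tuples of leaf indices, with
    random positive branch lengths; returns (tree, distance_matrix)."""
    # start from 3-star, attach leaves to random edges of a growing edge list
    # represent as an explicit graph for the path metric
    edges: dict[tuple[int, int], float] = {}
    next_node = n  # internal ids from n upward
    center = next_node
    next_node += 1
    for leaf in range(3):
        edges[(center, leaf)] = float(rng.uniform(0.05, 1.0))
    for leaf in range(3, n):
        (u, v) = list(edges)[int(rng.integers(len(edges)))]
        w = edges.pop((u, v))
        mid = next_node
        next_node += 1
        a = float(rng.uniform(0.2, 0.8))
        edges[(u, mid)] = w * a
        edges[(mid, v)] = w * (1 - a)
        edges[(mid, leaf)] = float(rng.uniform(0.05, 1.0))
    # all-pairs shortest paths over the tree graph
    adj: dict[int, list[tuple[int, float]]] = {}
    for (u, v), w in edges.items():
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    D = np.zeros((n, n))
    for src in range(n):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, w in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        for dst in range(n):
            D[src, dst] = dist[dst]
    return adj, D


def graph_bipartitions(adj, n: int) -> set[frozenset[int]]:
    """Non-trivial leaf bipartitions (canonical: side without leaf 0) of an
    unrooted tree given as an adjacency map; leaves are ids < n."""
    out = set()
    for u in adj:
        for v, _ in adj[u]:
            if u < v:
                # leaves on v's side when edge (u,v) removed
                seen = {u, v}
                stack = [v]
                side = set()
                while stack:
                    x = stack.pop()
                    if x < n:
                        side.add(x)
                    for y, _ in adj[x]:
                        if y not in seen:
                            seen.add(y)
                            stack.append(y)
                if 0 in side:
                    side = set(range(n)) - side
                if 1 < len(side) < n - 1:
                    out.add(frozenset(side))
    return out


def fitch_exhaustive(tree, columns: list[str]) -> int:
    """Minimum total changes over all internal-state assignments of a
    rooted nested-tuple binary tree (leaves = indices into each column)."""

    def nodes(t):
        if isinstance(t, int):
            return []
        return [t] + nodes(t[0]) + nodes(t[1])

    internal = nodes(tree)
    total = 0
    for col in columns:
        best = None
        for assign in itertools.product("ACGT", repeat=len(internal)):
            state = dict(zip(map(id, internal), assign))

            def label(t):
                if isinstance(t, int):
                    return col[t]
                return state[id(t)]

            def cost(t):
                if isinstance(t, int):
                    return 0
                c = cost(t[0]) + cost(t[1])
                for ch in t:
                    a, b = label(t), label(ch)
                    if a in UNAMBIG and b in UNAMBIG and a != b:
                        c += 1
                return c

            c = cost(tree)
            if best is None or c < best:
                best = c
        total += best
    return total


def all_unrooted_topologies(n: int):
    """All unrooted binary topologies over leaves 0..n-1 as rooted tuples
    (rooted on the edge to leaf 0): 3 for n=4, 15 for n=5."""
    assert n >= 3

    def insert_everywhere(t, leaf):
        yield (t, leaf)
        if not isinstance(t, int):
            for sub in insert_everywhere(t[0], leaf):
                yield (sub, t[1])
            for sub in insert_everywhere(t[1], leaf):
                yield (t[0], sub)

    trees = [(1, 2)]
    for leaf in range(3, n):
        trees = [nt for t in trees for nt in insert_everywhere(t, leaf)]
    return [(0, t) for t in trees]
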