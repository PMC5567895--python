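"""Tree-based species resolution: NJ, bootstrap consensus, monophyly, parsimony.

The resolution criterion follows common barcoding practice: a species is
*resolved* when all of its conspecific individuals form a single clade
with bootstrap support above a cutoff (default 60%).  Monophyly is
evaluated as an unrooted bipartition — the edge separating exactly the
species' specimens from everything else — so no outgroup rooting is
required.

Neighbor joining is run on the K2P distance matrix with negative branch
length estimates clamped to zero.  Bootstrap pseudo-replicates resample
alignment columns with replacement; replicates in which any pairwise
distance is undefined (saturated) are dropped and counted.  Parsimony
scoring uses unit-cost (Fitch) characters with gaps and ambiguity codes
treated as missing; the heuristic search uses random stepwise addition
followed by nearest-neighbour-interchange hill climbing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .distances import DistanceMatrix, distance_matrix
from .seqio import MISSING, LabelledAlignment

__all__ = [
    "nj_tree",
    "bootstrap_consensus",
    "resolution_score",
    "fitch_length",
    "mp_search",
    "ResolutionReport",
    "ParsimonyScore",
]


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree from a fully defined distance matrix.

    Negative branch-length estimates are set to zero.  Undefined pairs are
    an error (the caller should prune or report them first).
    """
    n = dm.n
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 specimens")
    undef = dm.undefined_pairs()
    if undef:
        shown = ", ".join(f"{a}~{b}" for a, b in undef[:5])
        raise ValueError(
            f"{len(undef)} undefined distance pair(s), e.g. {shown}: "
            "cannot build an NJ tree"
        )

    tns = dendropy.TaxonNamespace(dm.ids)
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes = []
    for sid in dm.ids:
        nd = dendropy.Node(taxon=tns.get_taxon(sid))
        nodes.append(nd)

    D = dm.values.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_loc, j_loc = divmod(int(np.argmin(q)), m)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        gi, gj = active[i_loc], active[j_loc]
        dij = D[gi, gj]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        parent.add_child(nodes[gi])
        parent.add_child(nodes[gj])
        nodes[gi].edge.length = max(li, 0.0)
        nodes[gj].edge.length = max(lj, 0.0)

        # distances from the new node to the remaining ones
        new_d = 0.5 * (D[gi, :] + D[gj, :] - dij)
        D = np.vstack([D, new_d])
        new_col = np.append(new_d, 0.0)
        D = np.column_stack([D, new_col])
        nodes.append(parent)
        new_idx = D.shape[0] - 1
        active = [a for a in active if a not in (gi, gj)] + [new_idx]

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = dendropy.Node()
    for gi, ln in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[gi])
        nodes[gi].edge.length = max(ln, 0.0)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Bipartitions, bootstrap and consensus


def _leaf_clusters(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset[str]]:
    """Leaf-label set under each node (postorder accumulation)."""
    clusters: dict[dendropy.Node, frozenset[str]] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            clusters[nd] = frozenset([nd.taxon.label])
        else:
            acc: set[str] = set()
            for ch in nd.child_nodes():
                acc |= clusters[ch]
            clusters[nd] = frozenset(acc)
    return clusters


def _canonical(cluster: frozenset[str], all_leaves: frozenset[str],
               anchor: str) -> frozenset[str]:
    """Canonical side of an unrooted bipartition: the side NOT holding the
    anchor leaf."""
    return all_leaves - cluster if anchor in cluster else cluster


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial unrooted bipartitions, each as its canonical side."""
    clusters = _leaf_clusters(tree)
    all_leaves = clusters[tree.seed_node]
    anchor = min(all_leaves)
    out: set[frozenset[str]] = set()
    for nd, cl in clusters.items():
        if nd is tree.seed_node or nd.is_leaf():
            continue
        side = _canonical(cl, all_leaves, anchor)
        if 1 < len(side) < len(all_leaves) - 1:
            out.add(side)
    return out


def _consensus_from_clusters(
    clusters: dict[frozenset[str], float],
    all_leaves: Sequence[str],
    anchor: str,
) -> dendropy.Tree:
    """Build the majority-rule consensus tree from mutually compatible
    canonical clusters (all on the non-anchor side) with their supports."""
    tns = dendropy.TaxonNamespace(list(all_leaves))
    tree = dendropy.Tree(taxon_namespace=tns)
    root = dendropy.Node()
    tree.seed_node = root
    tree.is_rooted = False

    non_anchor = [l for l in all_leaves if l != anchor]
    node_for: dict[frozenset[str], dendropy.Node] = {}
    top = frozenset(non_anchor)
    node_for[top] = root

    for cl in sorted(clusters, key=len, reverse=True):
        nd = dendropy.Node()
        nd.label = f"{clusters[cl]:.1f}"
        nd.support_pct = clusters[cl]
        node_for[cl] = nd

    # attach each cluster under the smallest strict superset
    ordered = [top] + sorted(clusters, key=len, reverse=True)
    for cl in ordered[1:]:
        parents = [p for p in ordered if len(p) > len(cl) and cl < p]
        parent = min(parents, key=len)
        node_for[parent].add_child(node_for[cl])
    for leaf in non_anchor:
        holders = [p for p in ordered if leaf in p]
        parent = min(holders, key=len)
        nd = dendropy.Node(taxon=tns.get_taxon(leaf))
        node_for[parent].add_child(nd)
    root.add_child(dendropy.Node(taxon=tns.get_taxon(anchor)))
    return tree


def majority_rule_consensus(
    trees: Iterable[dendropy.Tree], min_freq: float = 0.5
) -> dendropy.Tree:
    """Majority-rule consensus with per-edge support percentages.

    Retains bipartitions occurring in more than ``min_freq`` of the input
    trees (strict majority guarantees mutual compatibility); supports are
    stored on internal nodes as ``support_pct`` and as the node label.
    """
    trees = list(trees)
    if not trees:
        raise ValueError("no trees to summarise")
    counts: dict[frozenset[str], int] = {}
    leaves: frozenset[str] | None = None
    for t in trees:
        cl = _leaf_clusters(t)
        tl = cl[t.seed_node]
        if leaves is None:
            leaves = tl
        elif tl != leaves:
            raise ValueError("trees disagree on their leaf sets")
        for bp in tree_bipartitions(t):
            counts[bp] = counts.get(bp, 0) + 1
    assert leaves is not None
    anchor = min(leaves)
    n = len(trees)
    majority = {
        bp: 100.0 * c / n for bp, c in counts.items() if c / n > min_freq
    }
    return _consensus_from_clusters(majority, sorted(leaves), anchor)


def bootstrap_consensus(
    aln: LabelledAlignment,
    replicates: int = 1000,
    seed: int | None = None,
    min_freq: float = 0.5,
) -> dendropy.Tree:
    """Nonparametric bootstrap of the K2P+NJ tree with majority-rule summary.

    Columns are resampled with replacement per pseudo-replicate; a
    replicate whose resampled matrix has an undefined pair is dropped and
    counted (``tree.bootstrap_dropped``); if more than 10% of replicates
    drop, ``tree.bootstrap_warning`` is set.  Same seed, same output.
    """
    if replicates < 1:
        raise ValueError("need at least 1 bootstrap replicate")
    rng = np.random.default_rng(seed)
    L = aln.aligned_length
    used, dropped = 0, 0
    rep_trees: list[dendropy.Tree] = []
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        rep = aln.resample_columns(cols)
        dm = distance_matrix(rep)
        if dm.undefined_pairs():
            dropped += 1
            continue
        rep_trees.append(nj_tree(dm))
        used += 1
    if used == 0:
        raise ValueError(
            f"all {replicates} bootstrap replicates had undefined distances"
        )
    cons = majority_rule_consensus(rep_trees, min_freq=min_freq)
    cons.bootstrap_replicates = used
    cons.bootstrap_dropped = dropped
    cons.bootstrap_warning = dropped > 0.1 * replicates
    return cons


# ---------------------------------------------------------------------------
# Species resolution


@dataclass
class ResolutionReport:
    """Per-species monophyly with bootstrap support."""

    support_cutoff: float | None
    resolved: dict[str, tuple[bool, float | None]]  # species -> (resolved, support)
    excluded_species: list[str]  # <2 specimens

    @property
    def n_species_scored(self) -> int:
        return len(self.resolved)

    @property
    def n_resolved(self) -> int:
        return sum(1 for ok, _ in self.resolved.values() if ok)

    @property
    def pct_resolved(self) -> float | None:
        if not self.resolved:
            return None
        return 100.0 * self.n_resolved / self.n_species_scored


def _node_support(nd: dendropy.Node) -> float | None:
    sup = getattr(nd, "support_pct", None)
    if sup is not None:
        return float(sup)
    if nd.label:
        try:
            return float(nd.label)
        except ValueError:
            return None
    return None


def resolution_score(
    tree: dendropy.Tree,
    species_of: dict[str, str],
    cutoff: float | None = 60.0,
) -> ResolutionReport:
    """Score species monophyly on a (consensus) tree.

    A species is resolved iff the unrooted bipartition separating exactly
    its specimens from all others is present with support strictly above
    ``cutoff`` (percent).  ``cutoff=None`` scores topology-only monophyly,
    ignoring supports.  Species with fewer than 2 specimens are excluded
    and listed.
    """
    clusters = _leaf_clusters(tree)
    all_leaves = clusters[tree.seed_node]
    missing = set(species_of) - set(all_leaves)
    if missing:
        raise ValueError(f"specimens absent from tree: {sorted(missing)[:5]}")
    anchor = min(all_leaves)

    by_species: dict[str, set[str]] = {}
    for sid, sp in species_of.items():
        by_species.setdefault(sp, set()).add(sid)

    # canonical bipartition -> best support on a matching edge
    support_for: dict[frozenset[str], float | None] = {}
    for nd, cl in clusters.items():
        if nd is tree.seed_node or nd.is_leaf():
            continue
        side = _canonical(cl, all_leaves, anchor)
        sup = _node_support(nd)
        prev = support_for.get(side)
        if prev is None or (sup is not None and sup > (prev or -1)):
            support_for[side] = sup

    resolved: dict[str, tuple[bool, float | None]] = {}
    excluded: list[str] = []
    for sp, members in sorted(by_species.items()):
        if len(members) < 2:
            excluded.append(sp)
            continue
        side = _canonical(frozenset(members), all_leaves, anchor)
        if len(side) <= 1:
            # pendant-edge bipartition (species = all leaves but one):
            # present in every tree by construction
            resolved[sp] = (True, 100.0)
            continue
        if side not in support_for:
            resolved[sp] = (False, None)
            continue
        sup = support_for[side]
        if cutoff is None:
            resolved[sp] = (True, sup)
        else:
            resolved[sp] = (sup is not None and sup > cutoff, sup)
    return ResolutionReport(cutoff, resolved, excluded)


# ---------------------------------------------------------------------------
# Parsimony


@dataclass(frozen=True)
class ParsimonyScore:
    """Tree length and ensemble consistency/retention indices.

    ci = (sum over characters of observed states - 1) / tree length;
    ri = (G - L) / (G - M) with G the worst-case (star) length and M the
    minimum conceivable length; rc = ci * ri.  All three are None when the
    alignment carries no variation (zero-length tree).
    """

    tree_length: int
    n_characters: int
    n_informative: int
    ci: float | None
    ri: float | None
    rc: float | None


_STATE_MASK = {0: 1, 1: 2, 2: 4, 3: 8}  # A,C,G,T one-hot


def _leaf_masks(aln: LabelledAlignment) -> np.ndarray:
    """(n, L) uint8 Fitch state sets; missing -> all four states."""
    enc = aln.encoded()
    masks = np.full(enc.shape, 15, dtype=np.uint8)
    for code, bit in _STATE_MASK.items():
        masks[enc == code] = bit
    return masks


def _min_max_lengths(aln: LabelledAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Per-character minimum (states-1) and maximum (star-tree) lengths."""
    enc = aln.encoded()
    counts = np.stack([(enc == b).sum(axis=0) for b in range(4)])
    present = counts.sum(axis=0)
    n_states = (counts > 0).sum(axis=0)
    min_len = np.maximum(n_states - 1, 0)
    max_len = np.where(present > 0, present - counts.max(axis=0), 0)
    return min_len, max_len


def _score_from_length(aln: LabelledAlignment, length: int) -> ParsimonyScore:
    from .seqio import alignment_stats

    min_len, max_len = _min_max_lengths(aln)
    M = int(min_len.sum())
    G = int(max_len.sum())
    stats = alignment_stats(aln)
    if length <= 0 or M == 0:
        ci = ri = rc = None
    else:
        ci = M / length
        ri = (G - length) / (G - M) if G > M else None
        rc = ci * ri if ri is not None else None
    return ParsimonyScore(
        tree_length=int(length),
        n_characters=aln.aligned_length,
        n_informative=stats.n_parsimony_informative,
        ci=ci,
        ri=ri,
        rc=rc,
    )


def fitch_length(tree: dendropy.Tree, aln: LabelledAlignment) -> ParsimonyScore:
    """Unit-cost small-parsimony score of an alignment on a fixed topology.

    Uses the unit-cost Sankoff recursion (exact on multifurcating trees as
    well as binary ones), vectorised over characters.  Gaps/N/ambiguity are
    missing: zero cost in every state.
    """
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if leaf_labels != set(aln.ids):
        raise ValueError("tree leaves do not match alignment specimen ids")
    enc = aln.encoded()
    row_of = {sid: i for i, sid in enumerate(aln.ids)}
    L = aln.aligned_length
    BIG = np.int32(1 << 20)

    cost: dict[dendropy.Node, np.ndarray] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            states = enc[row_of[nd.taxon.label]]
            c = np.zeros((4, L), dtype=np.int32)
            for s in range(4):
                c[s][(states != s) & (states != MISSING)] = BIG
            cost[nd] = c
        else:
            total = np.zeros((4, L), dtype=np.int32)
            for ch in nd.child_nodes():
                cc = cost.pop(ch)
                m = cc.min(axis=0)
                total += np.minimum(cc, m[None, :] + 1)
            cost[nd] = total
    length = int(cost[tree.seed_node].min(axis=0).sum())
    return _score_from_length(aln, length)


# -- fast Fitch on nested-tuple binary trees (for the heuristic search) ----


def _tuple_fitch(tree, masks: np.ndarray) -> int:
    """Fitch length of a rooted nested-tuple binary tree; leaves are row
    indices into ``masks``."""
    steps = 0

    def down(node) -> np.ndarray:
        nonlocal steps
        if isinstance(node, (int, np.integer)):
            return masks[node]
        left = down(node[0])
        right = down(node[1])
        inter = left & right
        empty = inter == 0
        steps += int(empty.sum())
        return np.where(empty, left | right, inter).astype(np.uint8)

    down(tree)
    return steps


def _insertions(tree, leaf):
    """All trees from attaching ``leaf`` onto every edge of ``tree``."""
    out = [(tree, leaf)]
    if not isinstance(tree, (int, np.integer)):
        for sub in _insertions(tree[0], leaf):
            out.append((sub, tree[1]))
        for sub in _insertions(tree[1], leaf):
            out.append((tree[0], sub))
    return out


def _nni_neighbors(tree):
    """All NNI rearrangements of a rooted tuple tree (as unrooted moves)."""
    out = []

    def rewrite(node):
        if isinstance(node, (int, np.integer)):
            return []
        x, y = node
        res = []
        if not isinstance(x, (int, np.integer)):
            a, b = x
            res.append(((a, y), b))
            res.append(((b, y), a))
        if not isinstance(y, (int, np.integer)):
            c, d = y
            res.append((c, (d, x)))
            res.append((d, (c, x)))
        for sub in rewrite(x):
            res.append((sub, y))
        for sub in rewrite(y):
            res.append((x, sub))
        return res

    return rewrite(tree)


def _tuple_to_dendropy(tree, ids: Sequence[str]) -> dendropy.Tree:
    tns = dendropy.TaxonNamespace(list(ids))
    out = dendropy.Tree(taxon_namespace=tns)

    def build(node) -> dendropy.Node:
        if isinstance(node, (int, np.integer)):
            return dendropy.Node(taxon=tns.get_taxon(ids[int(node)]))
        nd = dendropy.Node()
        nd.add_child(build(node[0]))
        nd.add_child(build(node[1]))
        return nd

    out.seed_node = build(tree)
    out.is_rooted = False
    return out


def mp_search(
    aln: LabelledAlignment,
    n_starts: int = 10,
    seed: int | None = None,
) -> tuple[dendropy.Tree, ParsimonyScore]:
    """Heuristic maximum-parsimony search.

    Each start builds a tree by random-order stepwise addition (every
    placement scored, best kept) and then hill-climbs over all NNI
    rearrangements until no improvement.  The best tree over all starts is
    returned with its parsimony score.  Deterministic under a fixed seed.
    """
    n = aln.n_rows
    if n < 4:
        raise ValueError("parsimony search needs at least 4 specimens")
    masks = _leaf_masks(aln)
    rng = np.random.default_rng(seed)

    best_tree, best_len = None, None
    for _ in range(n_starts):
        order = rng.permutation(n)
        tree = (int(order[0]), (int(order[1]), int(order[2])))
        for leaf in order[3:]:
            cands = _insertions(tree, int(leaf))
            lens = [_tuple_fitch(t, masks) for t in cands]
            tree = cands[int(np.argmin(lens))]
        cur = _tuple_fitch(tree, masks)
        improved = True
        while improved:
            improved = False
            for cand in _nni_neighbors(tree):
                ln = _tuple_fitch(cand, masks)
                if ln < cur:
                    tree, cur = cand, ln
                    improved = True
                    break
        if best_len is None or cur < best_len:
            best_tree, best_len = tree, cur
    assert best_tree is not None and best_len is not None
    return _tuple_to_dendropy(best_tree, aln.ids), _score_from_length(aln, best_len)
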