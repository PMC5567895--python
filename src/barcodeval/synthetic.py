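"""Synthetic species-complex alignments with controlled K2P divergence.

The generator emulates a multi-individual, multi-species barcoding study:
a Yule species tree whose depth sets the inter-specific divergence scale,
a Kimura two-type (transition/transversion, ratio ``kappa``) substitution
process evolving each locus along that tree, and a star-shaped
within-species genealogy whose depth sets the intra-specific scale.
Because the generating process is the same two-parameter model the K2P
estimator corrects for, realized distances can be checked against
closed-form expectations.

Scales follow the estimator's units: ``inter_scale`` is the expected K2P
distance between species whose path runs through the root (tree height is
``inter_scale/2``); ``intra_scale`` is the expected K2P distance between
two conspecific individuals (per-individual depth ``intra_scale/2``).
Indels are placed as short shared gap runs in designated (nuclear-style)
loci and are invisible to the distance machinery via pairwise deletion.

Defaults mirror a medium-sized plant barcoding study: 41 species with 3-5
individuals each, one conserved plastid-like locus and two faster loci
(one nuclear-like with indels), inter-scale 0.08, intra-scale 0.004.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .seqio import LabelledAlignment

__all__ = ["Locus", "SimSpec", "SimResult", "simulate", "worked_fixture"]


@dataclass(frozen=True)
class Locus:
    name: str
    length: int  # aligned bp
    rate: float = 1.0  # multiplier on both divergence scales
    indels: bool = False  # nuclear-style shared gap runs


@dataclass
class SimSpec:
    """Parameters of one simulated study."""

    n_species: int = 41
    individuals_per_species: int | Sequence[int] | None = None  # default: 3-5, seeded
    loci: tuple[Locus, ...] = (
        Locus("rbcL", 636, rate=0.1),
        Locus("matK", 598, rate=1.0),
        Locus("ITS", 605, rate=1.0, indels=True),
    )
    inter_scale: float = 0.08
    intra_scale: float = 0.004
    kappa: float = 2.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    indel_rate: float = 0.004  # per-site probability of starting a gap run
    # Fraction of tree height reserved as terminal branches: no species
    # split happens in the most recent terminal_fraction of the tree, so
    # every species pair (sisters included) diverges by at least
    # terminal_fraction * inter_scale.  The default keeps sister-species
    # divergence within ~30% of inter_scale, emulating described species
    # whose splits long predate within-species coalescence.
    terminal_fraction: float = 0.7
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if not (0.0 <= self.intra_scale < self.inter_scale):
            raise ValueError(
                f"intra_scale ({self.intra_scale}) must be smaller than "
                f"inter_scale ({self.inter_scale})"
            )
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not (0.0 <= self.terminal_fraction < 1.0):
            raise ValueError("terminal_fraction must be in [0, 1)")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base_freqs must sum to 1")
        for loc in self.loci:
            if loc.length < 50:
                raise ValueError(f"locus {loc.name}: length must be >= 50 bp")


@dataclass
class SimResult:
    """Alignments plus the generating truth (species tree, expectations)."""

    alignments: list[LabelledAlignment]
    species_tree: dendropy.Tree
    expected_divergence: pd.DataFrame  # locus, sp1, sp2, expected K2P
    spec: SimSpec

    def __iter__(self):
        return iter(self.alignments)

    def __getitem__(self, i):
        return self.alignments[i]

    def __len__(self):
        return len(self.alignments)


def _yule_simple(n: int, height: float, rng: np.random.Generator,
                 terminal_fraction: float = 0.2):
    """Random ultrametric (Yule-topology) species tree.

    Split depths follow the pure-birth waiting times, rescaled so the root
    split sits at depth 0 and the most recent split at
    ``(1 - terminal_fraction) * height``; leaves 0..n-1 sit at ``height``.
    Returns (children, node_time, root) with ``children`` mapping internal
    node ids to their pair and ``node_time`` the depth from the root.
    """
    if n > 2:
        waits = rng.exponential(1.0 / np.arange(2, n), size=n - 2)
        raw = np.concatenate([[0.0], np.cumsum(waits)])
        split_depths = raw / raw[-1] * height * (1.0 - terminal_fraction)
    else:
        split_depths = np.array([0.0])
    node_time = np.zeros(2 * n - 1)
    node_time[:n] = height
    children: dict[int, tuple[int, int]] = {}
    # merge lineages bottom-up: deepest split joins two random lineages last
    lineages = list(range(n))
    for k, d in enumerate(reversed(split_depths)):
        new = n + k
        i = int(rng.integers(len(lineages)))
        a = lineages.pop(i)
        j = int(rng.integers(len(lineages)))
        b = lineages.pop(j)
        children[new] = (a, b)
        node_time[new] = d
        lineages.append(new)
    root = 2 * n - 2
    assert lineages == [root]
    return children, node_time, root


def _k80_evolve(seq: np.ndarray, t: float, kappa: float,
                rng: np.random.Generator) -> np.ndarray:
    """Evolve encoded sequence (0..3) for expected ``t`` substitutions/site
    under the two-type (K80) process, using its closed-form transition
    probabilities."""
    if t <= 0:
        return seq.copy()
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2  # to the transition partner
    p_tv = 0.25 - 0.25 * e1  # to each transversion partner
    u = rng.random(seq.size)
    out = seq.copy()
    # partner tables: transition partner, and the two transversion partners
    ts_partner = np.array([2, 3, 0, 1])  # A<->G, C<->T
    tv1 = np.array([1, 0, 1, 0])  # A->C, C->A, G->C, T->A ... arbitrary fixed
    tv2 = np.array([3, 2, 3, 2])
    m_ts = u < p_ts
    m_tv1 = (~m_ts) & (u < p_ts + p_tv)
    m_tv2 = (~m_ts) & (~m_tv1) & (u < p_ts + 2 * p_tv)
    out[m_ts] = ts_partner[seq[m_ts]]
    out[m_tv1] = tv1[seq[m_tv1]]
    out[m_tv2] = tv2[seq[m_tv2]]
    return out


_DECODE = np.array(list("ACGT"))


def simulate(spec: SimSpec) -> SimResult:
    """Generate one study: a list of labelled alignments, one per locus.

    Headers follow ``sp<k>_ind<j>|Genus_species<k>`` so the default header
    rule recovers the species label.  Same seed, same output.
    """
    rng = np.random.default_rng(spec.seed)
    S = spec.n_species
    if spec.individuals_per_species is None:
        per = rng.integers(3, 6, size=S)
    elif isinstance(spec.individuals_per_species, int):
        per = np.full(S, spec.individuals_per_species)
    else:
        per = np.asarray(list(spec.individuals_per_species), dtype=int)
        if per.size != S:
            raise ValueError("per-species list length != n_species")

    height = spec.inter_scale / 2.0
    children, node_time, root = _yule_simple(S, height, rng,
                                             spec.terminal_fraction)

    # species-tree newick for the truth record
    tns = dendropy.TaxonNamespace([f"species{k+1}" for k in range(S)])
    sp_tree = dendropy.Tree(taxon_namespace=tns)

    def build(node: int) -> dendropy.Node:
        if node < S:
            nd = dendropy.Node(taxon=tns.get_taxon(f"species{node+1}"))
        else:
            nd = dendropy.Node()
            for ch in children[node]:
                c = build(ch)
                c.edge.length = node_time[ch] - node_time[node]
                nd.add_child(c)
        return nd

    sp_tree.seed_node = build(root)
    sp_tree.is_rooted = True

    # expected K2P between species = path length through the tree
    pair_rows = []
    anc_time = np.zeros((S, S))
    # MRCA times by traversing: for small S an O(S^2) LCA walk is fine
    parents = np.full(2 * S - 1, -1, dtype=int)
    for p, (a, b) in children.items():
        parents[a] = p
        parents[b] = p

    def ancestors(x: int) -> list[int]:
        out = [x]
        while parents[x] != -1:
            x = parents[x]
            out.append(x)
        return out

    anc_cache = [ancestors(k) for k in range(S)]
    for a in range(S):
        for b in range(a + 1, S):
            common = set(anc_cache[a]) & set(anc_cache[b])
            mrca = max(common, key=lambda nd: node_time[nd])
            anc_time[a, b] = anc_time[b, a] = node_time[mrca]

    ids = [
        f"sp{k+1}_ind{j+1}|Genus_species{k+1}"
        for k in range(S)
        for j in range(per[k])
    ]
    species = [f"Genus_species{k+1}" for k in range(S) for _ in range(per[k])]

    alignments = []
    for loc in spec.loci:
        rate = loc.rate
        L = loc.length
        root_seq = rng.choice(4, size=L, p=spec.base_freqs).astype(np.uint8)
        seq_at: dict[int, np.ndarray] = {root: root_seq}
        order = sorted(children, key=lambda nd: node_time[nd])  # root first
        for node in order:
            for ch in children[node]:
                t = (node_time[ch] - node_time[node]) * rate
                seq_at[ch] = _k80_evolve(seq_at[node], t, spec.kappa, rng)
        rows = []
        for k in range(S):
            tip = seq_at[k]
            for _ in range(per[k]):
                ind = _k80_evolve(tip, spec.intra_scale * rate / 2.0,
                                  spec.kappa, rng)
                rows.append(ind)
        mat = _DECODE[np.stack(rows)]

        if loc.indels and spec.indel_rate > 0:
            starts = np.flatnonzero(rng.random(L) < spec.indel_rate)
            for s in starts:
                width = int(rng.integers(1, 5))
                keep = rng.random(S) < 0.7  # species carrying sequence here
                row0 = 0
                for k in range(S):
                    if not keep[k]:
                        mat[row0:row0 + per[k], s:s + width] = "-"
                    row0 += per[k]

        seqs = ["".join(r) for r in mat]
        alignments.append(
            LabelledAlignment(loc.name, list(ids), list(species), seqs)
        )
        for a in range(S):
            for b in range(a + 1, S):
                path = ((height - anc_time[a, b]) * 2.0 + spec.intra_scale) * rate
                pair_rows.append(
                    (loc.name, f"Genus_species{a+1}", f"Genus_species{b+1}", path)
                )

    truth = pd.DataFrame(
        pair_rows, columns=["locus", "species1", "species2", "expected_k2p"]
    )
    return SimResult(alignments, sp_tree, truth, spec)


# ---------------------------------------------------------------------------
# Worked fixture: every stage hand-computable


def worked_fixture() -> LabelledAlignment:
    """Deterministic 4-species x 3-individual, 120 bp alignment.

    Built from a 120 bp reference (``ACGT`` repeated) with hand-placed,
    species-private substitutions (a star species tree, so every species
    has its own synapomorphies and is recoverable as a clade):

    * species A: 3 A->G transitions at sites 48, 52, 56;
    * species B: 6 A->G transitions at sites 0, 4, ..., 20;
    * species C: 9 A->G transitions at sites 60, 64, ..., 92;
    * species D: 6 A->G transitions at sites 24, 28, ..., 44 plus 6 C->A
      transversions at sites 1, 5, ..., 21;
    * within species number s (0-based), individual 2 carries one extra
      transition at the species-private site 100+2s, and individual 3
      carries that same transition plus another at site 101+2s, so the
      intra-specific signal of each species touches no other species.

    Hence, per 120 sites: intra-specific pairs differ at 1-2 transitions;
    inter-specific pairs at 9 (A-B) up to 21 (C-D, 15 transitions + 6
    transversions) sites, and every stage's output can be read off these
    counts.

    All pairwise P/Q counts — hence K2P distances, the gap structure,
    BM/BCM verdicts, the NJ topology and the Fitch length — can be read
    off these counts by hand.
    """
    L = 120
    ref = list("ACGT" * (L // 4))

    def with_subs(base: list[str], subs: dict[int, str]) -> list[str]:
        out = list(base)
        for pos, b in subs.items():
            out[pos] = b
        return out

    spA = with_subs(ref, {i: "G" for i in (48, 52, 56)})
    spB = with_subs(ref, {i: "G" for i in range(0, 24, 4)})
    spC = with_subs(ref, {i: "G" for i in range(60, 96, 4)})
    spD = with_subs(ref, {i: "G" for i in range(24, 48, 4)} |
                    {i: "A" for i in range(1, 24, 4)})
    species_seq = {"A": spA, "B": spB, "C": spC, "D": spD}

    transition = {"A": "G", "G": "A", "C": "T", "T": "C"}
    ids, species, seqs = [], [], []
    for s, sp in enumerate("ABCD"):
        base = species_seq[sp]
        p, q = 100 + 2 * s, 101 + 2 * s
        variants = [
            base,
            with_subs(base, {p: transition[ref[p]]}),
            with_subs(base, {p: transition[ref[p]], q: transition[ref[q]]}),
        ]
        for j, var in enumerate(variants, start=1):
            ids.append(f"{sp.lower()}{j}|Fixture_{sp.lower()}ensis")
            species.append(f"Fixture_{sp.lower()}ensis")
            seqs.append("".join(var))
    return LabelledAlignment("fixture", ids, species, seqs)
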