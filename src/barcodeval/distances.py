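"""Kimura two-parameter (K2P) distances with pairwise deletion.

For an aligned pair, let P and Q be the fractions of compared sites (both
unambiguous A/C/G/T) differing by a transition (A<->G, C<->T) and by a
transversion respectively.  The K2P distance is

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

in expected substitutions per site.  The correction saturates: when
1 - 2P - Q <= 0 or 1 - 2Q <= 0 (or no sites are comparable) the distance is
*undefined* and carried as such through all downstream summaries rather
than clamped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .seqio import MISSING, LabelledAlignment

__all__ = [
    "K2PResult",
    "DistanceMatrix",
    "DivergenceSummary",
    "k2p",
    "k2p_counts",
    "distance_matrix",
    "summarize",
]


@dataclass(frozen=True)
class K2PResult:
    """Transition/transversion fractions and the corrected distance for one pair."""

    p_transition: float
    q_transversion: float
    n_compared: int
    distance: float  # NaN when undefined
    defined: bool


def _encode(seq: str) -> np.ndarray:
    from .seqio import _CODE  # shared base encoding

    return _CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def k2p_counts(p: float, q: float, n: int) -> K2PResult:
    """Build a :class:`K2PResult` from already-counted P, Q fractions."""
    one_m = 1.0 - 2.0 * p - q
    one_q = 1.0 - 2.0 * q
    if n == 0 or one_m <= 0.0 or one_q <= 0.0:
        return K2PResult(p, q, n, float("nan"), False)
    d = -0.5 * np.log(one_m) - 0.25 * np.log(one_q)
    return K2PResult(p, q, n, float(d), True)


def k2p(a: str | np.ndarray, b: str | np.ndarray) -> K2PResult:
    """K2P distance between two equal-length aligned sequences.

    Sites where either sequence is not a plain A/C/G/T (gap, N, ambiguity
    code) are excluded — the pairwise-deletion convention.
    """
    ea = _encode(a) if isinstance(a, str) else a
    eb = _encode(b) if isinstance(b, str) else b
    if ea.shape != eb.shape:
        raise ValueError(
            f"aligned sequences differ in length: {ea.size} vs {eb.size}"
        )
    both = (ea != MISSING) & (eb != MISSING)
    n = int(both.sum())
    if n == 0:
        return K2PResult(0.0, 0.0, 0, float("nan"), False)
    xa, xb = ea[both], eb[both]
    diff = xa != xb
    # A=0,C=1,G=2,T=3: transitions pair even with even / odd with odd.
    ts = diff & ((xa % 2) == (xb % 2))
    p = float(ts.sum()) / n
    q = float((diff & ~ts).sum()) / n
    return k2p_counts(p, q, n)


@dataclass
class DistanceMatrix:
    """Symmetric K2P distance matrix with a defined/undefined mask.

    ``values`` holds NaN where the pair is undefined (saturated or no
    comparable sites); ``defined`` is the boolean mask.  The diagonal is
    zero and always defined.
    """

    ids: list[str]
    species: list[str]
    values: np.ndarray
    defined: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.defined = np.asarray(self.defined, dtype=bool)
        n = len(self.ids)
        if self.values.shape != (n, n) or self.defined.shape != (n, n):
            raise ValueError("matrix shape does not match number of ids")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, specimen_id: str) -> int:
        return self.ids.index(specimen_id)

    def pairs(self) -> Iterator[tuple[int, int]]:
        n = self.n
        for i in range(n):
            for j in range(i + 1, n):
                yield i, j

    def undefined_pairs(self) -> list[tuple[str, str]]:
        return [
            (self.ids[i], self.ids[j])
            for i, j in self.pairs()
            if not self.defined[i, j]
        ]

    def conspecific_mask(self) -> np.ndarray:
        sp = np.asarray(self.species)
        return sp[:, None] == sp[None, :]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_long(self) -> pd.DataFrame:
        rows = [
            (
                self.ids[i], self.ids[j], self.species[i], self.species[j],
                self.values[i, j], bool(self.defined[i, j]),
            )
            for i, j in self.pairs()
        ]
        return pd.DataFrame(
            rows, columns=["id1", "id2", "species1", "species2", "d", "defined"]
        )

    def write(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    @classmethod
    def read(cls, path: str | Path, species: list[str] | None = None) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        values = df.to_numpy(dtype=float)
        ids = [str(i) for i in df.index]
        if species is None:
            from .seqio import default_header_rule

            species = [default_header_rule(i)[1] for i in ids]
        return cls(ids, species, values, ~np.isnan(values))


def distance_matrix(aln: LabelledAlignment) -> DistanceMatrix:
    """All-pairs K2P distances under pairwise deletion.

    Vectorised per query row; O(n^2 L) overall but numpy-bound, which keeps
    a few hundred sequences of ~1-2 kb in well under a second.
    """
    enc = aln.encoded()
    n = aln.n_rows
    present = enc != MISSING
    values = np.zeros((n, n), dtype=float)
    defined = np.ones((n, n), dtype=bool)
    for i in range(n - 1):
        rest = slice(i + 1, n)
        both = present[i] & present[rest]
        ncmp = both.sum(axis=1)
        diff = (enc[i] != enc[rest]) & both
        ts = diff & ((enc[i] % 2) == (enc[rest] % 2))
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(ncmp > 0, ts.sum(axis=1) / np.maximum(ncmp, 1), 0.0)
            q = np.where(ncmp > 0, (diff & ~ts).sum(axis=1) / np.maximum(ncmp, 1), 0.0)
            arg1 = 1.0 - 2.0 * p - q
            arg2 = 1.0 - 2.0 * q
            ok = (ncmp > 0) & (arg1 > 0.0) & (arg2 > 0.0)
            d = np.where(ok, -0.5 * np.log(np.where(ok, arg1, 1.0))
                         - 0.25 * np.log(np.where(ok, arg2, 1.0)), np.nan)
        values[i, rest] = d
        values[rest, i] = d
        defined[i, rest] = ok
        defined[rest, i] = ok
    np.fill_diagonal(values, 0.0)
    np.fill_diagonal(defined, True)
    return DistanceMatrix(list(aln.ids), list(aln.species), values, defined)


@dataclass
class DivergenceSummary:
    """Intra- and inter-specific divergence structure of one dataset.

    ``theta`` is the mean and ``coalescent_depth`` the maximum conspecific
    pairwise distance per species (species with >=2 members only; singleton
    species are listed separately and excluded from intra statistics).
    The ``±`` companions of the means are standard errors of the mean.
    """

    intra_all: np.ndarray
    inter_all: np.ndarray
    range_intra: tuple[float, float] | None
    range_inter: tuple[float, float] | None
    mean_intra: float | None
    se_intra: float | None
    mean_inter: float | None
    se_inter: float | None
    theta_per_species: dict[str, float]
    coalescent_depth_per_species: dict[str, float]
    singleton_species: list[str]
    n_undefined_pairs: int

    @property
    def intra_available(self) -> bool:
        return self.intra_all.size > 0


def _mean_se(x: np.ndarray) -> tuple[float | None, float | None]:
    if x.size == 0:
        return None, None
    mean = float(np.mean(x))
    se = float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
    return mean, se


def summarize(dm: DistanceMatrix) -> DivergenceSummary:
    """Split defined pairwise distances into conspecific and heterospecific
    sets and summarise their ranges, means (±SE), and per-species theta /
    coalescent depth."""
    iu = np.triu_indices(dm.n, k=1)
    con = dm.conspecific_mask()[iu]
    ok = dm.defined[iu]
    vals = dm.values[iu]
    intra = vals[con & ok]
    inter = vals[~con & ok]

    counts: dict[str, int] = {}
    for sp in dm.species:
        counts[sp] = counts.get(sp, 0) + 1
    singletons = sorted(sp for sp, c in counts.items() if c == 1)

    theta: dict[str, float] = {}
    depth: dict[str, float] = {}
    sp_arr = np.asarray(dm.species)
    for sp, c in counts.items():
        if c < 2:
            continue
        idx = np.flatnonzero(sp_arr == sp)
        sub_ok = dm.defined[np.ix_(idx, idx)]
        sub = dm.values[np.ix_(idx, idx)]
        tri = np.triu_indices(len(idx), k=1)
        dd = sub[tri][sub_ok[tri]]
        if dd.size:
            theta[sp] = float(dd.mean())
            depth[sp] = float(dd.max())

    mean_intra, se_intra = _mean_se(intra)
    mean_inter, se_inter = _mean_se(inter)
    return DivergenceSummary(
        intra_all=intra,
        inter_all=inter,
        range_intra=(float(intra.min()), float(intra.max())) if intra.size else None,
        range_inter=(float(inter.min()), float(inter.max())) if inter.size else None,
        mean_intra=mean_intra,
        se_intra=se_intra,
        mean_inter=mean_inter,
        se_inter=se_inter,
        theta_per_species=theta,
        coalescent_depth_per_species=depth,
        singleton_species=singletons,
        n_undefined_pairs=int((~ok).sum()),
    )
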