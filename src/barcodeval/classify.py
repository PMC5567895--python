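"""Sequence-similarity species identification (Best Match family).

Every sequence in the dataset is treated in turn as a query against all the
others, on the K2P distance matrix:

* **BM** (best match): the query is *correct* if every specimen attaining
  the minimum distance is conspecific, *incorrect* if none is, and
  *ambiguous* if the tied best matches span species.
* **BCM** (best close match): BM restricted to candidates within a distance
  threshold (the conventional default is 0.03, i.e. a 3% threshold; a
  percentile of the intra-specific distance distribution may be used
  instead).  A query with no candidate inside the threshold is *no_match*.
* **ASB** (all species barcodes): the strictest criterion — correct only
  when every conspecific of the query is strictly closer than every
  heterospecific within the threshold.

Dataset-level reports carry the percent correct / ambiguous / incorrect /
no-match over all queries; ``fold_no_match`` merges no-match into
incorrect for comparison with three-column summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .distances import DistanceMatrix, DivergenceSummary

__all__ = [
    "MatchVerdict",
    "MatchReport",
    "best_match",
    "best_close_match",
    "all_species_barcodes",
    "percentile_threshold",
    "classify_dataset",
    "TIE_TOL",
]

Method = Literal["BM", "BCM", "ASB"]
Verdict = Literal["correct", "ambiguous", "incorrect", "no_match"]

# Absolute tolerance for distance ties; K2P values are O(0.01-1), so 1e-12
# is far below any meaningful difference yet above float rounding noise.
TIE_TOL = 1e-12


@dataclass(frozen=True)
class MatchVerdict:
    query_id: str
    query_species: str
    method: Method
    verdict: Verdict
    best_ids: tuple[str, ...]
    best_distance: float | None


@dataclass
class MatchReport:
    method: Method
    threshold: float | None
    n_queries: int
    pct_correct: float
    pct_ambiguous: float
    pct_incorrect: float
    pct_no_match: float
    verdicts: list[MatchVerdict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (v.query_id, v.query_species, v.method, v.verdict,
             v.best_distance, ";".join(v.best_ids))
            for v in self.verdicts
        ]
        return pd.DataFrame(
            rows,
            columns=["query_id", "species", "method", "verdict",
                     "best_distance", "best_ids"],
        )


def _candidates(dm: DistanceMatrix, qi: int, threshold: float | None):
    """Indices and distances of defined candidates (optionally within
    threshold), excluding the query itself."""
    mask = dm.defined[qi].copy()
    mask[qi] = False
    d = dm.values[qi]
    if threshold is not None:
        mask &= d <= threshold
    idx = np.flatnonzero(mask)
    return idx, d[idx]


def _bm_verdict(
    dm: DistanceMatrix, qi: int, method: Method, threshold: float | None
) -> MatchVerdict:
    qid, qsp = dm.ids[qi], dm.species[qi]
    idx, d = _candidates(dm, qi, threshold)
    if idx.size == 0:
        return MatchVerdict(qid, qsp, method, "no_match", (), None)
    dmin = float(d.min())
    best = idx[d <= dmin + TIE_TOL]
    best_sp = {dm.species[i] for i in best}
    if best_sp == {qsp}:
        verdict: Verdict = "correct"
    elif qsp in best_sp:
        verdict = "ambiguous"
    else:
        verdict = "incorrect"
    return MatchVerdict(qid, qsp, method, verdict,
                        tuple(dm.ids[i] for i in best), dmin)


def best_match(dm: DistanceMatrix, query: str | int) -> MatchVerdict:
    """Best-match verdict for one query specimen (no threshold)."""
    qi = query if isinstance(query, int) else dm.index_of(query)
    v = _bm_verdict(dm, qi, "BM", None)
    if v.verdict == "no_match" and dm.n >= 2:
        # only possible when every distance to the query is undefined
        return v
    return v


def best_close_match(
    dm: DistanceMatrix, query: str | int, threshold: float
) -> MatchVerdict:
    """Best-close-match verdict: best match among candidates within the
    threshold; an empty candidate set gives no_match."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    qi = query if isinstance(query, int) else dm.index_of(query)
    return _bm_verdict(dm, qi, "BCM", threshold)


def all_species_barcodes(
    dm: DistanceMatrix, query: str | int, threshold: float
) -> MatchVerdict:
    """All-species-barcodes verdict.

    Correct iff every conspecific of the query lies strictly closer than
    every heterospecific within the threshold; incorrect when some
    heterospecific is strictly closer than some conspecific; ambiguous when
    the extremes tie.  A query whose species has no other member can never
    be correct.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    qi = query if isinstance(query, int) else dm.index_of(query)
    qid, qsp = dm.ids[qi], dm.species[qi]
    idx, d = _candidates(dm, qi, threshold)
    if idx.size == 0:
        return MatchVerdict(qid, qsp, "ASB", "no_match", (), None)
    dmin = float(d.min())
    best = tuple(dm.ids[i] for i in idx[d <= dmin + TIE_TOL])

    # All conspecifics (defined distances), regardless of the threshold:
    # one straying beyond the threshold defeats the "all barcodes" claim
    # whenever any heterospecific sits inside it.
    all_mask = dm.defined[qi].copy()
    all_mask[qi] = False
    sp_arr = np.asarray(dm.species)
    con_d = dm.values[qi][all_mask & (sp_arr == qsp)]
    het_in = dm.values[qi][
        all_mask & (sp_arr != qsp) & (dm.values[qi] <= threshold)
    ]
    if con_d.size == 0:
        verdict: Verdict = "incorrect"
    elif het_in.size == 0:
        verdict = "correct"  # vacuously: no heterospecific inside the threshold
    else:
        max_con = float(con_d.max())
        min_het = float(het_in.min())
        if max_con < min_het - TIE_TOL:
            verdict = "correct"
        elif min_het < max_con - TIE_TOL:
            verdict = "incorrect"
        else:
            verdict = "ambiguous"
    return MatchVerdict(qid, qsp, "ASB", verdict, best, dmin)


def percentile_threshold(summary: DivergenceSummary, coverage: float = 95.0) -> float:
    """Distance below which ``coverage`` percent of all intra-specific
    distances fall (linear-interpolated percentile)."""
    if summary.intra_all.size == 0:
        raise ValueError("no intra-specific distances: cannot derive a threshold")
    return float(np.percentile(summary.intra_all, coverage, method="linear"))


_PER_QUERY = {
    "BM": lambda dm, qi, thr: best_match(dm, qi),
    "BCM": lambda dm, qi, thr: best_close_match(dm, qi, thr),
    "ASB": lambda dm, qi, thr: all_species_barcodes(dm, qi, thr),
}


def classify_dataset(
    dm: DistanceMatrix,
    method: Method,
    threshold: float | None = None,
    fold_no_match: bool = False,
) -> MatchReport:
    """Apply one identification method to every specimen as a query and
    aggregate the verdict percentages."""
    if method not in _PER_QUERY:
        raise ValueError(f"unknown method {method!r}")
    if method in ("BCM", "ASB") and threshold is None:
        raise ValueError(f"{method} requires a threshold")
    verdicts = [_PER_QUERY[method](dm, qi, threshold) for qi in range(dm.n)]
    tally = {"correct": 0, "ambiguous": 0, "incorrect": 0, "no_match": 0}
    for v in verdicts:
        tally[v.verdict] += 1
    if fold_no_match:
        tally["incorrect"] += tally.pop("no_match")
        tally["no_match"] = 0
    n = len(verdicts)
    return MatchReport(
        method=method,
        threshold=threshold if method != "BM" else None,
        n_queries=n,
        pct_correct=100.0 * tally["correct"] / n,
        pct_ambiguous=100.0 * tally["ambiguous"] / n,
        pct_incorrect=100.0 * tally["incorrect"] / n,
        pct_no_match=100.0 * tally["no_match"] / n,
        verdicts=verdicts,
    )
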