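"""Barcoding-gap analysis.

Two complementary views:

* the *global* gap — frequency histograms (default bin width 0.005) of all
  conspecific vs heterospecific K2P distances, and the run of empty bins
  separating them, if any;
* the *local* (per-species) gap — each species' maximum intra-specific
  distance against its nearest-neighbour (NN) distance, the minimum
  distance from any member to any non-conspecific.  A species sits "above
  the 1:1 line" (has a local gap) iff NN > max-intra, strictly: a tie is
  no gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distances import DistanceMatrix, DivergenceSummary, summarize

__all__ = ["SpeciesGap", "GapReport", "global_gap", "local_gap", "gap_report"]

DEFAULT_BIN_WIDTH = 0.005


@dataclass(frozen=True)
class SpeciesGap:
    species: str
    n_individuals: int
    max_intra: float  # 0.0 for singletons (flagged below)
    nn_distance: float
    singleton: bool

    @property
    def above_line(self) -> bool:
        return self.nn_distance > self.max_intra


@dataclass
class GapReport:
    """Histograms, per-species local gaps and the global-gap verdict."""

    bin_width: float = DEFAULT_BIN_WIDTH
    intra_hist: list[tuple[float, float]] = field(default_factory=list)
    inter_hist: list[tuple[float, float]] = field(default_factory=list)
    per_species: dict[str, SpeciesGap] = field(default_factory=dict)
    excluded_species: list[str] = field(default_factory=list)
    n_above_line: int = 0
    n_species_scored: int = 0
    pct_above_line: float | None = None
    global_gap: tuple[float, float] | None = None
    pct_inter_above_max_intra: float | None = None

    def histogram_frame(self) -> pd.DataFrame:
        bins = sorted({b for b, _ in self.intra_hist} | {b for b, _ in self.inter_hist})
        intra = dict(self.intra_hist)
        inter = dict(self.inter_hist)
        return pd.DataFrame(
            {
                "bin_start": bins,
                "intra_pct": [intra.get(b, 0.0) for b in bins],
                "inter_pct": [inter.get(b, 0.0) for b in bins],
            }
        )

    def species_frame(self) -> pd.DataFrame:
        rows = [
            (g.species, g.n_individuals, g.max_intra, g.nn_distance,
             g.singleton, g.above_line)
            for g in self.per_species.values()
        ]
        return pd.DataFrame(
            rows,
            columns=["species", "n", "max_intra", "nn", "singleton", "above_line"],
        )


def _hist(values: np.ndarray, width: float) -> list[tuple[float, float]]:
    """Percent of values per half-open bin [k*w, (k+1)*w); empty bins with
    zero mass inside the occupied range are included."""
    if values.size == 0:
        return []
    idx = np.floor(values / width).astype(int)
    lo, hi = int(idx.min()), int(idx.max())
    out = []
    for k in range(lo, hi + 1):
        pct = 100.0 * float((idx == k).sum()) / values.size
        out.append((k * width, pct))
    return out


def global_gap(
    summary: DivergenceSummary, bin_width: float = DEFAULT_BIN_WIDTH
) -> GapReport:
    """Histogram both distance sets and locate the global barcoding gap.

    The gap is the maximal run of empty bins strictly between the occupied
    intra bins and the occupied inter bins; overlapping (or abutting)
    distributions yield no gap.  Because figures in the literature often
    report a *partial* separation, the fraction of inter-specific mass
    above the maximum intra-specific distance is also reported.
    """
    if summary.inter_all.size == 0:
        raise ValueError("no defined inter-specific distances: cannot assess a gap")
    report = GapReport(bin_width=bin_width)
    report.intra_hist = _hist(summary.intra_all, bin_width)
    report.inter_hist = _hist(summary.inter_all, bin_width)

    if summary.intra_all.size:
        intra_bins = np.floor(summary.intra_all / bin_width).astype(int)
        inter_bins = np.floor(summary.inter_all / bin_width).astype(int)
        lo = int(intra_bins.max())  # last occupied intra bin
        hi_candidates = inter_bins[inter_bins > lo]
        occupied = set(intra_bins.tolist()) | set(inter_bins.tolist())
        if inter_bins.min() <= lo or hi_candidates.size == 0:
            report.global_gap = None
        else:
            hi = int(hi_candidates.min())  # first occupied inter bin past intra
            empty = [k for k in range(lo + 1, hi) if k not in occupied]
            if empty:
                report.global_gap = (empty[0] * bin_width, empty[-1] * bin_width)
        max_intra = float(summary.intra_all.max())
        report.pct_inter_above_max_intra = 100.0 * float(
            (summary.inter_all > max_intra).mean()
        )
    return report


def local_gap(dm: DistanceMatrix, include_singletons: bool = False) -> GapReport:
    """Per-species max-intra vs nearest-neighbour distances.

    Singleton species have no intra distance; by default they are excluded
    from the percentage above the line (set ``include_singletons`` to score
    them with max_intra = 0).  Species whose every distance to a
    non-conspecific is undefined are excluded and listed.
    """
    species = sorted(set(dm.species))
    if len(species) < 2:
        raise ValueError("local gap analysis needs at least 2 species")
    sp_arr = np.asarray(dm.species)
    report = GapReport(bin_width=DEFAULT_BIN_WIDTH)
    scored = 0
    above = 0
    for sp in species:
        idx = np.flatnonzero(sp_arr == sp)
        other = np.flatnonzero(sp_arr != sp)
        cross_ok = dm.defined[np.ix_(idx, other)]
        if not cross_ok.any():
            report.excluded_species.append(sp)
            continue
        nn = float(dm.values[np.ix_(idx, other)][cross_ok].min())
        singleton = len(idx) < 2
        if singleton:
            max_intra = 0.0
        else:
            tri = np.triu_indices(len(idx), k=1)
            sub = dm.values[np.ix_(idx, idx)][tri]
            sub_ok = dm.defined[np.ix_(idx, idx)][tri]
            max_intra = float(sub[sub_ok].max()) if sub_ok.any() else 0.0
        entry = SpeciesGap(sp, len(idx), max_intra, nn, singleton)
        report.per_species[sp] = entry
        if singleton and not include_singletons:
            continue
        scored += 1
        if entry.above_line:
            above += 1
    report.n_species_scored = scored
    report.n_above_line = above
    report.pct_above_line = 100.0 * above / scored if scored else None
    return report


def gap_report(
    dm: DistanceMatrix,
    bin_width: float = DEFAULT_BIN_WIDTH,
    include_singletons: bool = False,
) -> GapReport:
    """Full gap analysis: global histograms + per-species local gaps."""
    summary = summarize(dm)
    glob = global_gap(summary, bin_width)
    loc = local_gap(dm, include_singletons=include_singletons)
    glob.per_species = loc.per_species
    glob.excluded_species = loc.excluded_species
    glob.n_above_line = loc.n_above_line
    glob.n_species_scored = loc.n_species_scored
    glob.pct_above_line = loc.pct_above_line
    return glob
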