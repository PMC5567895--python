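"""Full-study orchestration: loci, combinations, and the summary tables.

``run_evaluation`` takes an :class:`EvaluationConfig` naming single-locus
alignments and the locus combinations to concatenate, and produces, per
dataset: sequence characteristics, the divergence summary, the gap report,
BM/BCM/ASB identification reports, the NJ bootstrap consensus with species
resolution, and the heuristic-parsimony score.  A stage failure is recorded
as an error row; the remaining datasets still complete.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import classify, gap, seqio, trees
from .distances import distance_matrix, summarize

__all__ = ["EvaluationConfig", "EvaluationBundle", "run_evaluation"]


@dataclass
class EvaluationConfig:
    loci: dict[str, str]  # locus name -> FASTA path
    combinations: list[list[str]] = field(default_factory=list)
    join_rule: str = "specimen"
    bcm_threshold: float | str = 0.03  # or "auto95"
    bin_width: float = 0.005
    bootstrap_replicates: int = 1000
    support_cutoff: float = 60.0
    mp_starts: int = 10
    seed: int | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.bootstrap_replicates < 1:
            raise ValueError("bootstrap_replicates must be >= 1")
        if not (0 < self.support_cutoff < 100):
            raise ValueError("support_cutoff must be in (0, 100)")
        for combo in self.combinations:
            unknown = [l for l in combo if l not in self.loci]
            if unknown:
                raise ValueError(f"combination references unknown loci {unknown}")

    @classmethod
    def from_file(cls, path: str | Path) -> "EvaluationConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class EvaluationBundle:
    stats: pd.DataFrame
    divergence: pd.DataFrame
    classification: pd.DataFrame
    resolution: pd.DataFrame
    gap_reports: dict[str, gap.GapReport]
    match_reports: dict[str, dict[str, classify.MatchReport]]
    resolution_reports: dict[str, trees.ResolutionReport]
    consensus_trees: dict[str, object]
    errors: dict[str, str]
    log: list[str]


def _dataset_alignments(config: EvaluationConfig):
    single = {
        name: seqio.read_alignment(path, locus_name=name)
        for name, path in config.loci.items()
    }
    datasets = dict(single)
    for combo in config.combinations:
        name = "+".join(combo)
        datasets[name] = seqio.concatenate(
            [single[l] for l in combo], join_rule=config.join_rule
        )
    return datasets


def run_evaluation(config: EvaluationConfig) -> EvaluationBundle:
    """Run every stage on every configured dataset and assemble the tables."""
    log: list[str] = [f"seed={config.seed}"]
    errors: dict[str, str] = {}
    stats_rows, div_rows, cls_rows, res_rows = [], [], [], []
    gap_reports: dict[str, gap.GapReport] = {}
    match_reports: dict[str, dict[str, classify.MatchReport]] = {}
    res_reports: dict[str, trees.ResolutionReport] = {}
    cons_trees: dict[str, object] = {}

    datasets = _dataset_alignments(config)
    for name, aln in datasets.items():
        try:
            st = seqio.alignment_stats(aln)
            stats_rows.append(
                (name, st.n_sequences, st.min_len, st.max_len, st.aligned_length,
                 st.n_variable_sites, round(st.pct_variable, 2),
                 st.n_parsimony_informative, round(st.mean_gc, 4),
                 None if st.ts_tv_ratio is None else round(st.ts_tv_ratio, 3))
            )
            dm = distance_matrix(aln)
            summary = summarize(dm)
            if summary.n_undefined_pairs:
                log.append(f"{name}: {summary.n_undefined_pairs} undefined pair(s)")
            div_rows.append(
                (name,
                 summary.range_intra[0] if summary.range_intra else None,
                 summary.range_intra[1] if summary.range_intra else None,
                 summary.range_inter[0] if summary.range_inter else None,
                 summary.range_inter[1] if summary.range_inter else None,
                 summary.mean_intra, summary.se_intra,
                 summary.mean_inter, summary.se_inter,
                 summary.n_undefined_pairs)
            )
            gap_reports[name] = gap.gap_report(dm, bin_width=config.bin_width)

            if config.bcm_threshold == "auto95":
                threshold = classify.percentile_threshold(summary, 95.0)
                log.append(f"{name}: auto95 threshold {threshold:.5f}")
            else:
                threshold = float(config.bcm_threshold)
            reports = {
                "BM": classify.classify_dataset(dm, "BM"),
                "BCM": classify.classify_dataset(dm, "BCM", threshold),
                "ASB": classify.classify_dataset(dm, "ASB", threshold),
            }
            match_reports[name] = reports
            for method, rep in reports.items():
                cls_rows.append(
                    (name, method, rep.threshold, rep.n_queries,
                     round(rep.pct_correct, 2), round(rep.pct_ambiguous, 2),
                     round(rep.pct_incorrect, 2), round(rep.pct_no_match, 2))
                )

            cons = trees.bootstrap_consensus(
                aln, replicates=config.bootstrap_replicates, seed=config.seed
            )
            cons_trees[name] = cons
            if getattr(cons, "bootstrap_warning", False):
                log.append(
                    f"{name}: {cons.bootstrap_dropped} bootstrap replicate(s) "
                    "dropped (>10%)"
                )
            species_of = dict(zip(aln.ids, aln.species))
            res = trees.resolution_score(cons, species_of,
                                         cutoff=config.support_cutoff)
            res_reports[name] = res
            n_resolved_ind = sum(
                aln.species.count(sp)
                for sp, (ok, _) in res.resolved.items() if ok
            )
            mp_tree, mp_score = trees.mp_search(
                aln, n_starts=config.mp_starts, seed=config.seed
            )
            res_rows.append(
                (name, res.n_species_scored, res.n_resolved,
                 None if res.pct_resolved is None else round(res.pct_resolved, 2),
                 n_resolved_ind, mp_score.tree_length, mp_score.n_informative,
                 None if mp_score.ci is None else round(mp_score.ci, 4),
                 None if mp_score.ri is None else round(mp_score.ri, 4),
                 None if mp_score.rc is None else round(mp_score.rc, 4))
            )
        except Exception as exc:  # keep other datasets alive
            errors[name] = f"{type(exc).__name__}: {exc}"
            log.append(f"{name}: ERROR {errors[name]}")

    bundle = EvaluationBundle(
        stats=pd.DataFrame(
            stats_rows,
            columns=["dataset", "n", "min_len", "max_len", "aligned_length",
                     "variable_sites", "pct_variable", "parsimony_informative",
                     "mean_gc", "ts_tv"],
        ),
        divergence=pd.DataFrame(
            div_rows,
            columns=["dataset", "min_intra", "max_intra", "min_inter",
                     "max_inter", "mean_intra", "se_intra", "mean_inter",
                     "se_inter", "n_undefined"],
        ),
        classification=pd.DataFrame(
            cls_rows,
            columns=["dataset", "method", "threshold", "n", "pct_correct",
                     "pct_ambiguous", "pct_incorrect", "pct_no_match"],
        ),
        resolution=pd.DataFrame(
            res_rows,
            columns=["dataset", "species_scored", "species_resolved",
                     "pct_resolved", "resolved_individuals", "mp_length",
                     "parsimony_informative", "ci", "ri", "rc"],
        ),
        gap_reports=gap_reports,
        match_reports=match_reports,
        resolution_reports=res_reports,
        consensus_trees=cons_trees,
        errors=errors,
        log=log,
    )
    if config.output_dir:
        _write_bundle(bundle, config)
    return bundle


def _write_bundle(bundle: EvaluationBundle, config: EvaluationConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.stats.to_csv(out / "stats.tsv", sep="\t", index=False)
    bundle.divergence.to_csv(out / "summary.tsv", sep="\t", index=False)
    bundle.classification.to_csv(out / "classify.tsv", sep="\t", index=False)
    bundle.resolution.to_csv(out / "resolution.tsv", sep="\t", index=False)
    (out / "gap").mkdir(exist_ok=True)
    for name, rep in bundle.gap_reports.items():
        rep.histogram_frame().to_csv(out / "gap" / f"{name}.hist.tsv",
                                     sep="\t", index=False)
        rep.species_frame().to_csv(out / "gap" / f"{name}.species.tsv",
                                   sep="\t", index=False)
    (out / "trees").mkdir(exist_ok=True)
    for name, tree in bundle.consensus_trees.items():
        with open(out / "trees" / f"{name}.nwk", "w") as fh:
            fh.write(tree.as_string(schema="newick"))
    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(bundle.log) + "\n")
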