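# barcodeval

Evaluation of single- and multilocus DNA barcodes for species delimitation
in taxonomically difficult groups — the kind of analysis run when deciding
whether *rbcL*, *matK*, *ITS* or a combination of them can reliably
identify the species of a traded plant sample.

Starting from species-labelled multiple sequence alignments (one aligned
FASTA per locus, headers carrying a specimen id and a binomial species
label), the package computes, per locus and per concatenated combination:

* **K2P distance structure** — Kimura two-parameter distances
  `d = −½·ln(1 − 2P − Q) − ¼·ln(1 − 2Q)` with pairwise deletion, where `P`
  and `Q` are the transition (A↔G, C↔T) and transversion fractions over
  the sites comparable in a pair; intra-/inter-specific ranges, means ±
  standard error, per-species θ (mean conspecific distance) and coalescent
  depth (maximum conspecific distance).
* **Barcoding-gap statistics** — frequency histograms of intra- vs
  inter-specific distances (bin width 0.005) with the run of empty bins
  between them (the *global* gap), and the per-species *local* gap: maximum
  intra-specific distance vs nearest-neighbour (NN) distance, a species
  scoring a gap iff NN > max-intra (strict).
* **Identification success** — Best Match (BM), Best Close Match (BCM, at
  a distance threshold, conventionally 3%, or at the 95th percentile of
  the intra-specific distribution) and All Species Barcodes (ASB), with
  per-dataset percent correct / ambiguous / incorrect / no-match.
* **Tree-based resolution** — neighbor-joining on the K2P matrix (negative
  branch lengths clamped to zero), nonparametric bootstrap with
  majority-rule consensus, and the species-resolution criterion: all
  conspecific individuals forming a single clade with bootstrap support
  above 60%. Heuristic maximum-parsimony search (random stepwise addition
  + NNI hill climbing) with tree length and the consistency, retention and
  rescaled consistency indices (CI, RI, RC).
* **Synthetic studies** — a seeded generator of species-complex alignments
  (Yule species tree, K80 substitution process, star within-species
  genealogy, optional indels) with recorded per-pair expected divergences,
  so every stage is testable against known truth.

## Worked example

```python
import barcodeval as bv

aln = bv.worked_fixture()          # 4 species x 3 individuals, 120 bp
dm = bv.distance_matrix(aln)
s = bv.summarize(dm)
print(f"intra: {s.range_intra[0]:.4f}-{s.range_intra[1]:.4f}")
print(f"inter: {s.range_inter[0]:.4f}-{s.range_inter[1]:.4f}")
rep = bv.gap_report(dm)
print("global gap:", rep.global_gap, "| species with local gap:",
      f"{rep.n_above_line}/{rep.n_species_scored}")
bcm = bv.classify_dataset(dm, "BCM", 0.03)
print(f"BCM@3%: {bcm.pct_correct:.2f}% correct")
cons = bv.bootstrap_consensus(aln, replicates=100, seed=1)
res = bv.resolution_score(cons, dict(zip(aln.ids, aln.species)), cutoff=60)
print(f"resolved species: {res.n_resolved}/{res.n_species_scored}")
```

prints

```
intra: 0.0084-0.0170
inter: 0.0813-0.2547
global gap: (0.02, 0.075) | species with local gap: 4/4
BCM@3%: 100.00% correct
resolved species: 4/4
```

i.e. on this hand-built fixture the within-species distances (up to 0.0170)
sit well below the closest between-species distance (0.0813), every species
shows a local barcoding gap, every query is identified correctly at the 3%
threshold, and all four species are monophyletic with full bootstrap
support.

The same pipeline runs from the shell:

```
barcodeval stats locus.fasta
barcodeval concat rbcL.fasta matK.fasta ITS.fasta -o combined.fasta
barcodeval classify combined.fasta --method bcm --threshold 0.03
barcodeval tree combined.fasta --bootstrap 1000 --seed 7 -o tree.nwk
barcodeval simulate --species 20 --per 4 --seed 1 -o simdir/
```

## Layout

* `src/barcodeval/seqio.py` — labelled alignments, FASTA I/O, sequence
  characteristics, concatenation
* `src/barcodeval/distances.py` — K2P, distance matrix, divergence summary
* `src/barcodeval/gap.py` — global and local barcoding-gap analysis
* `src/barcodeval/classify.py` — BM / BCM / ASB identification
* `src/barcodeval/trees.py` — NJ, bootstrap consensus, monophyly
  resolution, parsimony
* `src/barcodeval/synthetic.py` — study generator and worked fixture
* `src/barcodeval/report.py` — whole-study orchestration
* `docs/methods.md` — models, conventions and design choices
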