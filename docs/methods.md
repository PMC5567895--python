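# Methods

This note records the models, statistical conventions and design choices
behind `barcodeval`, in the order the pipeline applies them.

## Input model and labelling

A dataset is a species-labelled multiple sequence alignment: rows are
specimens, each with a unique specimen id and a non-empty binomial species
label, all sequences of identical aligned length over
`{A,C,G,T,-,N,IUPAC}`. The default header rule takes the species as the
last two underscore/pipe/whitespace-separated tokens (`Genus_species`) and
the full header as the specimen id; the rule is a plain callable and can
be replaced for other header conventions. `U` is mapped to `T` and
sequences are upper-cased on input.

Throughout the package, gaps, `N` and IUPAC ambiguity codes are treated as
**missing**: they contribute neither to site-state counts nor to distances
nor to parsimony steps. This mirrors the most common convention of the
standard desktop tools for these analyses; results on alignments rich in
ambiguity codes depend on this choice.

Sequence characteristics per dataset: ungapped length range (removing
`-` only, so `N` still counts toward length), aligned length, variable
sites (≥2 distinct unambiguous bases in the column), parsimony-informative
sites (≥2 unambiguous bases each in ≥2 sequences), mean GC (mean over
sequences of the per-sequence GC fraction among unambiguous bases), and
the Ts/Tv ratio computed as total transition pairs over total transversion
pairs, summed over all sequence pairs and sites (per column this is
`nA·nG + nC·nT` vs `(nA+nG)·(nC+nT)`). The ratio is flagged undefined when
no transversion pair exists.

## K2P distances with pairwise deletion

For each sequence pair, `P` and `Q` are the fractions of transition- and
transversion-different sites among the sites where **both** sequences are
unambiguous (pairwise deletion), and

    d = −1/2 · ln(1 − 2P − Q) − 1/4 · ln(1 − 2Q).

When `1 − 2P − Q ≤ 0`, `1 − 2Q ≤ 0`, or no sites are comparable, the pair
is **undefined** and carried as such: undefined pairs are excluded from
every summary and reported in a side list, never clamped to a ceiling.
Saturation does occur in real data (deeply diverged pairs at fast loci),
and inventing a finite value for it would distort ranges and means.

Divergence summaries use the *all-pairs* convention: mean intra-specific
distance is the mean over all defined conspecific pairs (not the mean of
per-species means), and likewise for inter-specific distance. The `±`
companion values are standard errors of those means. Per species with ≥2
members, θ = mean conspecific distance and coalescent depth = maximum
conspecific distance; singleton species are excluded from intra statistics
and listed.

## Barcoding gap

*Global*: intra and inter distances are binned into half-open bins
`[k·w, (k+1)·w)`, default `w = 0.005`, each histogram normalised to 100%.
The global gap is the maximal run of completely empty bins strictly
between the last occupied intra bin and the first occupied inter bin;
overlapping or abutting distributions have no gap. Because partial
separations are common, the fraction of inter-specific mass above the
maximum intra-specific distance is reported alongside.

*Local*: per species, max-intra (maximum defined conspecific distance)
against the nearest-neighbour distance (minimum defined distance from any
member to any non-conspecific). A species has a local gap iff
NN > max-intra, strictly — a tie counts as no gap. Singletons have no
intra distance; by default they are excluded from the percentage (a flag
scores them with max-intra = 0). Species with no defined distance to any
non-conspecific are excluded and listed.

## Identification (BM / BCM / ASB)

Each specimen is queried against all others on the K2P matrix. Ties are
recognised with an absolute tolerance of 1e−12 on `d` (distances are
O(0.01–1), so this is far below biological signal but above float noise).

* **BM**: best-ids are all candidates attaining the minimum defined
  distance; *correct* if all are conspecific, *incorrect* if none,
  *ambiguous* if mixed.
* **BCM**: BM over candidates with `d ≤ threshold`; empty set →
  *no_match*. The default threshold is 0.03 (the conventional 3% figure);
  alternatively the threshold is derived as the linear-interpolated 95th
  percentile of the intra-specific distance distribution.
* **ASB**: *correct* iff every conspecific of the query is strictly closer
  than every heterospecific within the threshold (vacuously correct when
  no heterospecific falls inside it); *incorrect* when some heterospecific
  is strictly closer than some conspecific; *ambiguous* on ties; queries
  whose species has no other member can never be correct. The exact
  success rule of the original desktop implementation is not published in
  detail; this operationalisation is fixed here and checked against a
  brute-force ordering oracle rather than against any external table.

Dataset reports give percent correct/ambiguous/incorrect/no-match over all
queries; an option folds no-match into incorrect for comparison with
three-column summaries.

## Trees and species resolution

**NJ** is the standard agglomeration on the K2P matrix with negative
branch-length estimates set to zero; undefined pairs are an error rather
than silently imputed. **Bootstrap**: alignment columns are resampled with
replacement per pseudo-replicate; a replicate whose matrix contains an
undefined pair is dropped and counted, with a surfaced warning above 10%
dropped — dropping, not imputing, keeps the support values interpretable.
The majority-rule consensus retains bipartitions present in >50% of used
replicates (strict majority guarantees mutual compatibility) with support
= percent of replicates containing the bipartition.

**Resolution**: a species is resolved iff the unrooted bipartition
separating exactly its specimens from all others is present with support
strictly above the cutoff (default 60%). The criterion is deliberately
bipartition-based, with no outgroup rooting: outgroup placement is itself
unreliable in taxonomically entangled groups, and monophyly on an unrooted
tree is exactly a bipartition statement. Species with fewer than two
specimens are excluded and listed.

**Parsimony**: `fitch_length` scores a fixed topology by the unit-cost
Sankoff recursion (exact on multifurcating as well as binary trees),
vectorised over characters, missing states costing zero everywhere. With
realized length L, minimum conceivable length M = Σ(observed states − 1)
and maximum (star-tree) length G = Σ(non-missing taxa − largest state
class): CI = M/L, RI = (G−L)/(G−M), RC = CI·RI; all flagged undefined on
invariant data (L = 0). The heuristic search (`mp_search`) uses random
stepwise addition (every placement scored) followed by hill climbing over
all NNI rearrangements until no improvement, best of `n_starts` random
starts (default 10), deterministic under a fixed seed. NNI was chosen over
TBR: on datasets of this size the stepwise-addition trees are close to
optimal and NNI climbing recovers the exhaustive optimum in the n ≤ 5
check; a TBR pass would add an order of magnitude of cost for marginal
gain. Search results are heuristic lower-bound-free estimates: reported
tree lengths are attained, not proven minimal.

## Synthetic studies

The generator emulates a multi-individual barcoding study of a species
complex:

* **Species tree**: Yule-topology, ultrametric, height `inter_scale/2` so
  a species pair diverging at the root has expected K2P `inter_scale`.
  Split depths follow pure-birth waiting times rescaled so that no split
  occurs in the most recent `terminal_fraction` of the height (default
  0.7): every species pair, sisters included, diverges by at least
  `terminal_fraction · inter_scale`. The two requirements this reconciles
  are that `inter_scale` is simultaneously the total-depth scale and the
  sister-species divergence scale — which forces splits to concentrate
  near the root — and it reflects described species, whose splits long
  predate within-species coalescence. Lowering `terminal_fraction` toward
  0 produces incipient-species complexes with overlapping distance
  distributions.
* **Substitution process**: the two-rate (K80) model with Ts/Tv rate ratio
  `kappa` (default 2), simulated per branch with its closed-form transition
  probabilities, rates normalised so branch length = expected
  substitutions/site. The generator deliberately matches the model the K2P
  estimator inverts, so realized distances are consistent estimates of
  path lengths and parameter-recovery checks have closed-form targets.
  `base_freqs` shape the root sequence only; the symmetric process drifts
  composition toward uniform over deep trees.
* **Within species**: a star genealogy — each individual evolves
  independently for `intra_scale/2` from the species sequence, making the
  expected conspecific pairwise distance exactly `intra_scale`. No
  within-species tree structure is simulated.
* **Loci**: each locus has a rate multiplier applied to all branch lengths
  (defaults emulate a three-marker study: a conserved plastid-like 636 bp
  locus at 0.1×, a fast 598 bp locus, and a fast 605 bp nuclear-like locus
  with indels). Indels are short (1–4 column) gap runs shared by all
  individuals of a randomly chosen subset of species, started per site
  with probability `indel_rate` — enough to exercise pairwise deletion,
  with no attempt at realistic indel evolution.
* **Defaults** mirror a medium-sized plant study: 41 species, 3–5
  individuals each (seeded draw), `inter_scale` 0.08, `intra_scale` 0.004.

What the generator does **not** emulate: gene-tree/species-tree
discordance, recombination, alignment error, rate heterogeneity across
sites, base-composition bias in the process, and non-monophyletic species.
Passing tests on synthetic data therefore demonstrate correctness of the
pipeline's computations and its behaviour under controlled divergence
structure — not robustness to every pathology of real data.

The per-pair expected divergences written alongside each simulation are
tree path lengths (2·(height − MRCA depth) + `intra_scale`, times the
locus rate), the quantity the realized mean K2P estimates.

## Worked fixture

A deterministic 4-species × 3-individual, 120 bp alignment with
hand-placed, species-private substitution blocks (star species tree: 3, 6,
9 and 12 private substitutions; one species' block includes 6
transversions) and per-species private intra-specific sites (individuals
differ by 1–2 transitions). Every stage's output — each K2P value, the gap
structure, all verdicts, the NJ clades, the parsimony length (38 steps,
CI = 1, homoplasy-free by construction) — is derivable by hand from the
substitution counts, and the test suite freezes those hand values.

## Numerical and scale choices

* Tie tolerance on distances: 1e−12 absolute (see above).
* NJ tie-break: first minimal entry of the Q matrix in row-major order —
  deterministic, so bootstrap runs are exactly reproducible under a seed.
* All stochastic operations (simulation, bootstrap, MP starts) take
  explicit seeds; identical seeds give byte-identical outputs.
* The acceptance script runs the default 41-species study with 200
  bootstrap pseudo-replicates per dataset and a 2-start parsimony search
  on the species-representative two-locus concatenation; these sizes keep
  a full 7-dataset evaluation to a few minutes while leaving support
  values stable to a few percent. Bootstrap analyses intended for
  publication-grade support values should use 1000 replicates (the
  package default in `EvaluationConfig`).

## Known limitations

* Only the K2P model is implemented for distances (Jukes–Cantor appears in
  tests as a limiting-case check); no gamma rate heterogeneity or model
  selection.
* The MP search reports attained lengths, not certified optima, and the
  consensus tree carries no branch lengths (supports only).
* Maximum-likelihood tree inference is out of scope; distance (NJ) and
  parsimony cover the resolution analyses.
* Concatenation joins on specimen ids (or one representative per species);
  it does not attempt fuzzy matching of differently-labelled vouchers
  across loci, so real multi-locus studies must harmonise specimen ids
  upstream.
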