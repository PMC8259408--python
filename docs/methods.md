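# Methods

## Scope and model

`dirpred` scores residue positions of a reference protein inside a
paralogous ligand family that shares one receptor. The model behind the
score is evolutionary: after duplication, a residue that underlies a
paralog-specific function should be (a) conserved among each paralog's
orthologs, (b) divergent across the paralogs, and (c) coupled to the
receptor rather than to the ligand's own scaffold. Each of these
signatures is measured per site on [0, 1] and the four measurements are
summed (weights configurable, default equal) into a single ranking
score on [0, 4].

All coordinates are reported in reference-residue numbering: 1-based
positions over the ungapped reference sequence, so "Asn-32"-style names
line up. Alignment columns are 0-based internally.

### Inputs

* a paralog *master* alignment (one row per paralog, aligned FASTA),
  optionally a second, structure-superposition-based paralog alignment
  (MSTA) exported as aligned FASTA;
* one ortholog alignment per paralog, whose reference row (identified
  by the same identifier as the master row) equals that paralog's
  ungapped master sequence;
* a receptor ortholog alignment with species-resolvable identifiers
  (default species rule: last underscore-separated token, overridable);
* a rooted newick tree with branch lengths over the ligand homologs for
  the null model, with the leaf-to-paralog partition taken from
  ortholog-alignment membership.

Sequences are normalized on reading: upper case, `.` and `-` unified to
`-`, and ambiguity or non-standard codes (B, Z, X, J, U, O, `*`) turned
into gaps so that every scored symbol belongs to the 20-letter
alphabet. Ortholog alignments are projected onto master columns through
the reference rows; ortholog-alignment insertion columns (gapped in the
reference row) are discarded — scores are only reported for reference
positions, and an insertion column has no reference position. Species
with duplicated rows are dropped entirely during ligand–receptor
pairing rather than paired by guesswork.

## The four components

**I — ortholog conservation.** A conservation profile is computed for
the reference ligand's own ortholog alignment and for every other
paralog's projected ortholog block, each against its own reference row.
I(site) is the arithmetic mean of the reference ligand's value and the
other paralogs' values at the corresponding master column. Paralogs
gapped at the column are skipped and the divisor shrinks: a gap is
absence of evidence, not evidence of divergence. (Zero-filling instead
of skipping is the natural alternative; skipping was chosen so that
poorly alignable regions are not systematically pushed down.)

**II — paralog divergence.** II = 1 − x, where x is the conservation of
the master-alignment column (and separately of the MSTA column when an
MSTA is supplied; both are reported side by side, never merged).

**III — ligand–receptor coevolution.** The reference ligand's ortholog
alignment is paired row-by-row with the receptor ortholog alignment on
the species tag. III(site) is the maximum normalized mutual information
between the site's column and any receptor column. Ties go to the
lowest receptor column index; the argmax partner is available in
diagnostics.

**IV — ligand-internal coevolution (complement).** The projected
ortholog blocks of all paralogs are stacked into one joint alignment in
master coordinates; IV(site) = 1 − max normalized MI between the site's
column and any *other* master column.

### Conservation formulations

* `identity` (default): frequency of the reference residue in the
  column. Gaps count in the denominator — an indel against the
  reference is evidence of non-conservation.
* `blosum`: mean over non-gap residues of the min–max-normalized
  BLOSUM62 score against the reference residue, using the global
  extremes of the 20×20 matrix (−4 and 11). The matrix ships as a
  packaged text table (20 labelled integer rows) and is checked against
  Biopython's copy in the tests.
* `jsdw`: Jensen–Shannon divergence (log base 2, mixing weight
  λ = 0.5) between the column's empirical residue distribution and a
  background distribution, scaled to [0, 1] by the λ-dependent maximum
  −λ log₂λ − (1−λ) log₂(1−λ), multiplied by the column's non-gap
  fraction (gap penalty), then window-smoothed: score ← (1−w)·self +
  w·mean(up to 3 columns each side, center excluded, truncated at the
  edges), w = 0.5. Defaults follow the Capra–Singh conservation
  method; the background is the BLOSUM62-derived amino-acid frequency
  vector (packaged, renormalized to sum exactly to 1). No pseudocounts:
  the λ-mixture already prevents log 0.

Columns where the reference row is gapped score 0 and are flagged; for
`jsdw` the base profile is computed on all columns first so the window
sees real neighbors, and flagged columns are zeroed afterwards.

**Why `identity` is the default driver.** On desk-scale inputs the
paralog master alignment has as many rows as the family has paralogs
(seven, for an EGF-like family). With so few rows, every column's
empirical distribution is far from any smooth background, so JSD
compresses the contrast between a fully divergent column and an average
one, and the 50% window mixing halves per-site contrast again. The
identity score keeps the paralog-divergence component II sharply
discriminative (a seven-way divergent column scores II = 6/7, a
conserved one II = 0), which is what the method's headline behaviour
relies on. All three formulations are computed by the same profile API
and are selectable everywhere (`--conservation`).

### Mutual information

Plug-in estimator MI = Σ p(a,b) log₂ [p(a,b)/(p(a)p(b))] over the rows
where neither column is gapped (pairwise deletion, maximizing usable
rows per pair). Normalization (default) divides by the joint entropy
H(A,B), bounding the value to [0, 1]; `min-entropy` and `none` are
selectable. Pairs with fewer than `min_pairs` (default 5) gap-free rows
are masked — distinguishable from a true zero — and masked pairs are
excluded from the maxima; a site whose every pairing is masked scores 0
(III) or 1 (IV) and is flagged. No bias correction and no
average-product correction by default (APC is available as an option);
the plug-in bias is absorbed by the simulated null, which uses the same
estimator.

## The null model

The null hypothesis is neutral evolution of the whole family. A root
sequence is drawn site-independently from the WAG equilibrium
frequencies and evolved along the family tree: Q is assembled from the
published WAG exchangeabilities and frequencies (packaged in PAML
`.dat` format) as Q_ij = s_ij π_j, rescaled to one expected
substitution per site per unit branch length; transition matrices
P(t) = exp(Qt) come from the eigendecomposition of the reversible
generator's symmetrized form (rows renormalized to kill ~1e-16 drift).
Sequences are ungapped and used as-is — no indel process, no
re-alignment, no rate heterogeneity across sites.

Each replicate reconstructs the full input bundle shape: leaves are
partitioned into paralog groups by the declared tree partition, the
lexicographically first leaf of each group acts as that group's
representative (the master row), and an independent receptor alignment
(default length 100) is co-simulated on the species tree induced by the
reference group's subtree — so the component III background captures
plug-in MI noise under true independence. (Reusing a real receptor
alignment instead is supported.) The same component pipeline then runs
on each replicate; after `n_reps` (default 100, sequence length default
53) the per-site partial scores are pooled per component and a normal
is fitted by the method of moments.

P-values are one-sided: P(X ≥ score) with X ~ N(μ_k, σ_k), the side on
which the partial score increases the total. A site that is invariant
everywhere therefore scores significant on I but lands in the
non-significant tail of II — the property that keeps disulfide
cysteines out of the ranking. A degenerate background (σ = 0) gives
p = 0 above the mean and 1 otherwise. No multiple-testing correction is
applied; raw per-site p-values are emitted.

## The synthetic-data generator

`dirpred.fixtures` emits complete, deterministic input bundles (master,
MSTA, per-paralog ortholog alignments, receptor, rooted tree with
branch lengths, ground-truth manifest). Sequences descend from a family
ancestor through a uniform substitution kernel — each position mutates
with a fixed probability to one of the 19 other residues — rather than
through the WAG process: the fixtures test score mechanics; realistic
evolution is the null model's job.

Defaults: 7 paralogs × 12 species, ligand length 60, receptor length
120; between-paralog divergence 0.15 per site; within-ortholog
substitution probability 0.4 per site (a deep, vertebrate-scale
ortholog panel). The reference species carries each paralog's
representative (ancestral) sequence, mirroring curated database
representatives; this also keeps the master alignment free of
single-species noise. Tree branch lengths use the Poisson correction
−ln(1 − p) of each kernel probability, with a zero-length terminal
branch for the reference species.

Planted site modes:

* **DIR** — one major residue per paralog, all distinct, with a small
  minority-species pattern (default 2 of 12 species, never the
  reference species) carrying one alternative residue per paralog, and
  a dedicated receptor column equal to an injective relabelling of the
  reference ligand's column. The minority pattern is what makes the
  receptor covariation *detectable*: the mutual information of a
  strictly invariant column is identically zero, so a planted
  divergence-inducing site must retain slight within-ortholog variation
  to coevolve visibly with the receptor — exactly as real specificity
  residues do.
* **cysteine-like** — one residue (C) everywhere, in every paralog.
* **receptor-covarying** — a species-indexed four-residue pattern
  shared by all paralogs, mirrored injectively in a receptor column.
* **neutral** — background behaviour, recorded in the manifest only.

What the generator does **not** emulate: indels and alignment
uncertainty, receptor domain architecture, site-rate heterogeneity,
residue exchangeability structure, and phylogenetic autocorrelation
beyond the two-level group structure. Passing the planted-recovery
tests therefore demonstrates that the score arithmetic and ranking
behave as designed under clean signal; it does not demonstrate
sensitivity or specificity on real alignments.

## Numerical and formatting choices

* MI and entropies via exact counting (`bincount`) in double precision;
  plug-in MI clamped at 0 (it can come out ≈ −1e-16); normalized MI
  clipped to [0, 1].
* Ranking: descending total, ties broken by ascending reference
  position, stable and deterministic.
* All randomness flows through `numpy.random.Generator`; replicate k of
  a run seeded s uses `default_rng([s, k])`, so any replicate is
  reproducible in isolation and a whole run is bit-reproducible.
* Tables are TSV: header row, `.` decimal separator, 6 significant
  digits, empty cell for missing values, rows ordered by reference
  position — identical configuration and seed give byte-identical
  files.
* Plots (`--plots`) are cosmetic; rendering failures are warnings,
  never pipeline failures. The TSVs are the ground truth.

## Problem sizes

The test suite and the acceptance script run everything at the scale
the package documents: 100 synthetic systems for planted-site recovery,
100 neutral replicates of length 53 for backgrounds plus 100 fresh
replicates for calibration, and a 100,000-site two-leaf simulation for
the substitution-fraction check. The full suite completes in a few
minutes on one CPU.

## Known limitations

* **The normality assumption is approximate.** Measured on fresh
  neutral simulations (5,300 pooled per-site scores per component), the
  one-sided p-values are calibrated only to within about ±0.03 absolute
  at the nominal 0.05 level: component I's null is right-skewed (all
  paralog groups share the root sequence's residue composition, and WAG
  rates are strongly residue-specific), component III is a maximum over
  many NMI values (extreme-value shaped), and component IV is bounded.
  Under the `identity` driver the component II null is additionally
  discrete (row-count quantized), and the normal tail is off by more.
  P-values should be read as calibrated screening scores, not exact
  tail probabilities.
* Plug-in NMI between short columns (~12 species) is bias-dominated;
  raw III values are interpretable mainly relative to the simulated
  background, not in absolute terms.
* Component IV inherits phylogenetic confounding: any strongly
  group-structured column couples to any other, so divergent sites pay
  an IV penalty that conserved sites do not.
* The null model simulates the receptor independently of the ligand;
  correlated ligand–receptor evolution under the null is not modelled.
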