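# Methods

## Problem and model

`psbinder` is a binary classifier for short peptides (roughly 4–20
residues, typical phage-display window): does the sequence bind a
polystyrene surface? The positive class (PSBP) is of dual interest —
as an affinity tag and as a target-unrelated false positive in
biopanning — so the classifier outputs a calibrated probability rather
than just a call.

The model is an RBF-kernel C-SVM over sequence-composition features.
No alignment, position-specific scoring, or physicochemical encodings
are used: the working hypothesis, supported by the enrichment of
benzene-ring aromatics (W, Y, F) among known binders, is that local
residue and residue-pair composition carries most of the signal, with
dipeptides additionally capturing short order-dependent motifs such as
WXXW and FHXXW.

## Feature encoding

Each peptide maps to a 420-vector: 20 amino-acid composition (AAC)
frequencies (counts over L) followed by 400 overlapping dipeptide
composition (DPC) frequencies (counts over L − 1). Dipeptides are
overlapping windows — the universal convention — so each block sums to
exactly 1 and the vector sums to 2. The index layout (AAC alphabetical,
DPC row-major alphabetical) is fixed and written into persisted models
and exported matrices, because feature subsets are stored as indices
into it. Compositions already live in [0, 1]; no further scaling is
applied by default (an export flag exists for tools that expect sparse
SVM-light input).

Peptides shorter than 2 residues are rejected: DPC is undefined for
them. Validation rejects the ambiguity codes B, J, O, U, X, Z and any
non-alphabetic character, naming the first offender and its position.
Lowercase input is uppercased before validation, since biopanning
reports mix cases.

## Curation pipeline

Order of operations: flanking-cysteine trimming (cyclic-library
peptides are displayed between a constraining C...C pair; the rule
fires only when the sequence both starts and ends with C, once, never
recursively) → validation → exact-duplicate removal (negatives matching
a positive, and within-set duplicates, first kept) → similarity
filtering of negatives against positives. Every drop is logged with a
stage and reason and exported as TSV.

Similarity is the Generalized Jaccard index on residue-count multisets,
Σ min(xᵢ, yᵢ)/Σ max(xᵢ, yᵢ), with strict `< 0.90` as the keep
condition. The multiset-of-residues representation is the default; an
overlapping-dipeptide-multiset variant is available
(`representation="dipeptide"`) for users who want order sensitivity in
the filter. Only the negative side is filtered: a negative too similar
to a confirmed binder may be an unlabeled binder, whereas positives are
experimentally confirmed and are never discarded for resembling a
negative.

## Feature selection

Per-feature F-score:

    F(i) = [(x̄⁺ᵢ − x̄ᵢ)² + (x̄⁻ᵢ − x̄ᵢ)²] /
           [ (1/(n⁺−1)) Σ (x⁺ₖᵢ − x̄⁺ᵢ)² + (1/(n⁻−1)) Σ (x⁻ₖᵢ − x̄⁻ᵢ)² ]

with x̄ᵢ the overall mean. A zero denominator with nonzero numerator
(a perfect, variance-free separator) scores +inf and ranks first; ties
break toward the lower feature index so rankings are reproducible.

Forward selection walks the ranking: for k = 1..d the top-k prefix is
scored by stratified fivefold-CV accuracy of the SVM, and the smallest
k attaining the maximum wins. The same fold split is reused at every k,
so prefix accuracies are comparable and the sweep is deterministic
given the seed. By default one grid search on the full block fixes
(c, g) for the sweep; `retune=True` re-runs the grid at every k, which
costs roughly the grid size (110×) more SVM fits and, in our
experience on these data sizes, selects essentially the same subset.
The full accuracy-vs-k curve is retained on the result object and in
the JSON sidecar of a persisted subset.

Selection runs separately per block — the DPC block yields the ODPC
subset, the AAC block the OAAC subset — mirroring the two models being
compared; combined-420 selection is available via `block="both"`.

## SVM, hyperparameters, and probability calibration

The backend is scikit-learn's `SVC` (libsvm). The (c, g) grid is the
canonical log2 grid, c ∈ {2⁻⁵, 2⁻³, …, 2¹⁵}, g ∈ {2⁻¹⁵, 2⁻¹³, …, 2³},
scored by stratified fivefold-CV accuracy of the raw decision rule;
ties prefer smaller c then smaller g (smoother surfaces). After feature
selection the grid is re-run on the selected columns for the final
model.

Probability output uses Platt sigmoid calibration as fitted by libsvm.
One pitfall is handled explicitly: at degenerate hyperparameters
(typically very small c) the internal sigmoid fit can come out
*inverted* — probabilities that decrease as the decision value
increases — because the cross-validated decision values used to fit it
are nearly constant. Two measures keep this pathology out of results:

1. Cross-validated metrics (Sn/Sp/Acc/MCC) are computed from the raw
   SVM decision rule, and ROC scores are the raw decision values. Both
   are monotone in the fitted margin, match the objective the grid and
   the selection sweep optimize, and need no calibration fit (which
   also makes CV about five times cheaper).
2. When fitting the final, probability-serving model, the ranked grid
   is walked best-first and the first configuration whose fitted
   calibration is orientation-consistent (sigmoid slope negative) is
   kept. In practice this is almost always the top configuration.

The decision threshold on the calibrated probability is 0.5
(configurable); a peptide is called PSBP iff its probability is ≥ 0.5.
Calibration randomness is pinned by the run seed and recorded in model
metadata, so train → save → load → predict is bit-reproducible.

## Evaluation protocol

Stratified fivefold cross-validation: folds are class-balanced within
±1 (208 is not divisible by 5, so "equal-sized" means sizes
{42, 42, 42, 41, 41}), deterministic given the seed. Headline
Sn/Sp/Acc/MCC are fold averages; the pooled confusion matrix and
pooled accuracy are also reported (at n ≈ 200 the two differ by well
under a percentage point). AUC is computed on the pooled held-out
scores, because a five-point averaged ROC is ill-defined at this n;
the trapezoidal value is cross-checked at run time against the
Mann–Whitney pair-counting statistic, an exact identity. An MCC whose
denominator contains a zero factor is reported as 0 with an explicit
`mcc_undefined` flag.

Because fold assignment is random, headline numbers are means over 10
evaluation seeds wherever a single number is quoted (the acceptance
script does exactly this).

## Synthetic data generator

The generator emulates the statistical structure reported for plastic
binders, so the entire pipeline is testable without the original
corpus:

- lengths 7 and 12 with equal weight (the commonest phage-display
  library sizes); configurable;
- positives: residues drawn from a background distribution with W/Y/F
  up-weighted by `aromatic_enrichment` (default 3.0), and with
  probability `motif_fraction` (default 0.7) one motif from
  {WXXW, FHXXW, WXXWXXXW} planted at a uniform offset. The motif is
  chosen uniformly among those that fit the drawn length (WXXWXXXW is
  8 long and never lands on a 7-mer); X wildcards are drawn from the
  *unenriched* background so motif-order signal and composition signal
  can be switched independently;
- negatives: i.i.d. background draws at matched lengths. The default
  background is uniform over the 20 residues (the simplest documented
  null); a natural-abundance option is provided;
- the candidate streams are passed through the standard curation
  pipeline and topped up until exactly `n_per_class` survive per
  class, so generated datasets satisfy the curation invariants by
  construction. A dataset is a pure function of its spec, seed
  included.

What the generator does **not** emulate: phage propagation and codon
biases, library-specific flanking linkers, length distributions of the
nine real source libraries, or the real prevalence of motifs among
true binders (`motif_fraction = 0.7` is a stand-in, not a measured
value). Passing end-to-end tests on synthetic data therefore
demonstrates that the pipeline recovers planted composition/motif
signal at realistic n — not that real-data accuracy equals the
synthetic figure. In our runs the synthetic task at default settings is
somewhat *easier* than the published real-data task (cross-validated
accuracy low-90s vs 87 %), and the composition-only AAC baseline in
particular benefits: on real corpora it trails the dipeptide model by
~14 points, on synthetic data by only ~4, because a single enriched
background distribution is a cruder composition signal than biology
provides.

## Problem sizes and numerical choices

Default study shape is 104 peptides per class, matching the corpus the
method was developed for. The forward sweep over the 400 DPC features
at this n, with a fixed-(c, g) fivefold sweep plus two full grid
searches, takes ~10 s on one CPU; the 10-seed evaluation used for
headline numbers takes ~2 minutes. Tolerances: composition-block sums
are asserted to 1e-9; the trapezoid/Mann–Whitney AUC identity to 1e-9;
fold-average vs pooled accuracy agreement to 1/min-fold-size.
Degenerate inputs (single-class labels, classes with fewer than two
samples, length-1 peptides, empty files) raise errors early with
specific messages; batch prediction instead annotates invalid rows and
continues, matching how screening lists are processed in practice.

## Known limitations

- The exact feature subset and (c, g) of the originally published
  model are unreported; with a different corpus sample or fold seed the
  selected subset size moves substantially (the accuracy-vs-k curve is
  typically flat near its maximum), so subset membership should be read
  as an ensemble-of-near-optima, not a unique answer.
- Probability calibration at n ≈ 160 training samples per fit is
  coarse; probabilities near 0.5 should not be over-interpreted.
- Composition features cannot distinguish positional effects (e.g.
  terminal vs internal tryptophans), and no claim is made about
  binding affinity — the output is a classification, not a Kd.
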