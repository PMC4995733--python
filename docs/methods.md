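# Methods

## Problem setting

A labelled instance is a cysteine residue in a protein sequence, tagged
+1 (redox-sensitive: its thiol undergoes reversible oxidation) or −1
(insensitive). Corpora of this kind are assembled by literature
curation; the remaining cysteines of each curated protein serve as
negatives, and an equal-sized seeded uniform sample of negatives is
drawn so classes are balanced. The classifier sees sequence-derived
information only: the sequence itself, a PSI-BLAST position-specific
scoring matrix (PSSM), and predicted secondary structure (SS) /
solvent accessibility (SA) strings. Running PSI-BLAST or a structure
predictor is out of scope — the package consumes their output formats,
and can synthesize stand-ins.

## Encoding

Blocks concatenate in the fixed order D, PSSM, SS, SA, PCP so selected
feature indices stay stable across runs.

- **D** (length *n*, default 6): sorted distances |i − j| to the *n*
  nearest other cysteines, unnormalised. When fewer than *n* other
  cysteines exist, missing entries are filled with the sequence length
  *L* — an unattainable-or-maximal distance that keeps vectors
  fixed-length while marking the neighbour as "effectively infinitely
  far". (The sentinel policy is named in `FeatureSpec` so alternatives
  can be added without changing stored vectors silently.)
- **Windowed blocks** (odd width *w*, default 9, shared by all
  per-residue blocks): the window is centred on the cysteine and
  includes it; rows outside [1, L] are all-zero padding, so the one-hot
  SS/SA blocks encode "beyond the terminus" as the all-zero code,
  distinguishable from every real state.
- **PSSM** uses only the 20 log-odds columns of PSI-BLAST ASCII output,
  in PSI-BLAST's printed column order (ARNDCQEGHILKMFPSTWYV); the
  weighted-percentage half is ignored. Log-odds is the standard choice
  for profile features; a different dialect would have to be declared
  explicitly.
- **PCP** values per residue: Kyte–Doolittle hydrophobicity, net charge
  index of the side chain, Chou–Fasman helix propensity, and side-chain
  pKa (0 for non-ionizable side chains). X scores 0 in every channel.
  The table is config-replaceable (`FeatureSpec.pcp_table`); the
  defaults are standard literature values, not a reproduction of any
  specific source table.

Default parameters (*n* = 6 neighbours, *w* = 9, blocks D + PSSM + SS,
giving 213 features) are the cross-validated optima reported for curated
data; the `sweep` workflow re-derives such optima on any dataset by
scanning *n* ∈ 1..10 and odd *w* ∈ 3..25.

Selenocysteine (U) is read as C with a warning — Sec commonly occupies
redox-active positions, and mapping it to cysteine keeps such sites
addressable. Other non-standard letters become X.

## Classifier

Soft-margin SVM with the Gaussian RBF kernel
K(xᵢ, x) = exp(−γ‖xᵢ − x‖²). Some descriptions print the kernel with an
unsquared norm; the squared form is the standard definition and the one
implemented by the classical SVM libraries, so it is the default here,
with `SVMParams(squared=False)` exposing the exponential variant for
comparison. Features are scaled per column to [−1, 1] with parameters
fitted on training data only (constant columns map to 0); mixing raw
distances (up to hundreds of residues) with one-hot bits makes an
RBF-SVM effectively unusable without this.

(C, γ) are tuned by an exhaustive grid scan scored by stratified k-fold
cross-validated accuracy, the same fold assignment reused for every
cell. Default grids are C ∈ {2⁻⁵ … 2¹⁵}, γ ∈ {2⁻¹⁵ … 2³} in ×4 steps;
ties resolve to the smallest C, then the smallest γ, which makes the
search deterministic and biases ties toward the smoother model.

Comparison classifiers (Gaussian naive Bayes, random forest, single
hidden-layer neural network) are backed by scikit-learn with their main
knobs tuned by the same seeded CV scheme (smoothing; node size + tree
count; hidden size + weight decay). Their decision scores are
P(+1) − ½ so the decision threshold is 0 for every model kind.

## SVM-RFE

For the nonlinear kernel the classical "smallest weight" criterion has
no direct analogue, so the ranking uses the standard generalisation:
with the trained dual coefficients α frozen, feature *f* is scored by
|W²(α) − W²₍₋f₎(α)| where W²₍₋f₎ recomputes the kernel with feature *f*
excluded (for RBF this is a rank-preserving O(n²ₛᵥ) update of the
squared-distance matrix). The lowest-scoring `step` features are
eliminated per iteration; ties eliminate the lower feature index first,
making reruns bit-reproducible. The criterion is evaluated in float32 —
it only orders features, the ordering is computed identically on every
rerun, and the narrower type halves the cost of the dominant
exponentiation.

An optional held-out split (default 20 %, seeded, stratified) logs the
validation error rate along the elimination path for diagnostics; it
never influences which feature is removed.

Selection placement: by default the pipeline runs RFE *inside* every
cross-validation fold, so reported performance contains no selection
leakage. A `whole_dataset` mode ranks once on all data before
cross-validating — the simpler protocol of older studies — and is
expected to read optimistic; it exists for comparison. At the pipeline
level RFE removes 4 features per iteration (213-feature specs make the
ranking refit per fold; the coarser step changes rankings negligibly
while cutting cost fourfold); `svm_rfe` itself defaults to step 1.

## Evaluation

SN, SP, ACC from the confusion table with +1 as the positive class;
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)), defined as 0
when any denominator factor vanishes (the formula is otherwise
undefined there). Folds are stratified (the corpora are balanced;
stratification removes fold-imbalance noise) with a seeded shuffle
recorded in every report. Aggregate metrics come from pooled confusion
counts, which by construction lie between the fold extremes.

ROC curves sweep a threshold over the distinct scores with ties grouped
into a single step; AUC is the trapezoidal integral and equals the
normalised Mann–Whitney rank statistic. Three AUC summaries are emitted
and labelled, since averaging recipes differ between studies: the AUC
of the fold-averaged curve (each fold's TPR interpolated on a common
101-point FPR grid and averaged pointwise — this is the headline
number), the pooled-scores AUC, and the mean of per-fold AUCs.

Per-group (gene-family style) breakdowns recompute confusion and
metrics within each group and suppress groups with fewer than 10
positive sites, where the estimates are too noisy to print.

## Synthetic data

The generator emulates the three signals observed around real
redox-sensitive cysteines, with effect sizes as explicit dials:

- **Spacing** (`distance_shift`, default 40 residues): positive sites
  are kept pairwise farther apart than the radius and other cysteines
  within the radius are removed, then the thinned negative class is
  topped up outside all exclusion zones (to ~1.2× the positive count,
  capped per protein at the nominal cysteine budget). At ~3 % cysteine
  density the median nearest-cysteine distance is ~11 residues, so a
  40-residue floor is a strong, clearly recoverable effect.
- **Conservation** (`pssm_shift`, default 2.0): profiles are BLOSUM62
  rows plus N(0, 2.0²) noise, quantised to three decimals so the text
  round-trip is exact; within the ±4 window of each positive site the
  H, I, L, M, F, P, Y columns get the shift added.
- **Structure** (`coil_bias`, default 0.5): secondary structure is a
  sticky 3-state Markov chain (stay probability 0.85); windows around
  positive sites are redrawn with coil probability ⅓ + ⅔·bias and the
  remaining mass split 1:2 between helix and strand (helix depleted).
  At bias 0 the redraw is skipped entirely, so the null configuration
  leaves positives and negatives exchangeable.

Defaults (50 proteins of 100–400 residues, ~3 % cysteine density, 100
positive sites) keep a full pipeline run to a couple of minutes on one
CPU while giving ~200 balanced sites — enough for stable 10-fold CV.
Solvent accessibility is an unbiased coin: the SA block is deliberately
uninformative. What passing tests on this generator demonstrate is that
the machinery recovers planted signal of the documented *shape* and
reports chance when there is none; they say nothing about absolute
accuracy on real proteins, whose homology structure, composition biases
and predictor-error correlations the generator does not model.

## Numerical and design notes

- Positions are 1-based in all I/O and converted exactly once at
  encoding time.
- PSSM text is written with three decimals; profiles quantised to
  milli-units round-trip exactly, and PSI-BLAST's integer matrices are
  preserved as-is.
- `performance_vs_count` at the full feature count reproduces the plain
  cross-validation result exactly (feature order permutations do not
  affect an RBF kernel).
- Models persist as a single joblib archive holding parameters, scaling
  bounds, selected indices, feature names and the feature spec;
  prediction aligns columns by stored name and fails loudly on any
  drift.
- Every seeded command writes byte-identical outputs on rerun; output
  files carry no timestamps.

## Known limitations

- The RFE criterion assumes the squared-norm kernel; the unsquared
  variant is train/predict only.
- Curated-corpus headline numbers require externally computed PSSMs
  (PSI-BLAST vs. NR) and SSpro annotations plus an unrecorded negative
  sample, so they cannot be regenerated here; the package validates the
  method's properties on synthetic data instead.
- The generator plants effects independently; correlated effects (e.g.
  conserved CXXC motifs coupling distance and conservation signals) are
  not modelled.
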