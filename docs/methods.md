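# Methods

## Problem and model

Given RNA sequences with multi-label subcellular localization
annotations, the pipeline predicts, for each sequence, a calibrated
score per compartment and a final label set.  The modelling assumption
is that localization signal is (partly) encoded in local nucleotide
composition, so the sequence is represented by seven frequency views of
increasing order — mononucleotide up to 4-mer composition,
strand-symmetric (reverse-complement-collapsed) 4-mers, and gapped
dinucleotide pairs — rather than by alignment or structure.

Each view v yields an RBF kernel K^v_ij = exp(−γ_v‖x_i − x_j‖²).  The
views are fused as K\* = Σ_v β_v K^v with β on the probability simplex,
chosen to maximize the empirical Hilbert–Schmidt independence criterion
between K\* and the label kernel U = Y Yᵀ,

HSIC(K, U) = (1/N²) tr(K H U H),  H = I − eeᵀ/N,

penalized by ν₁‖β‖².  HSIC after double-centering measures the
dependence between the two similarity structures: kernels whose
geometry co-varies with shared-label structure earn weight.  The fused
kernel feeds L independent binary C-SVMs (binary relevance / one-vs-rest),
one per compartment, whose decision values are mapped to probabilities
by a per-label Platt-style sigmoid fitted on the training decision
values.

The single-label ideal kernel y yᵀ generalizes to U = Y Yᵀ for a binary
label *matrix* Y, so U_ij counts the compartments samples i and j
share; this is the natural multi-label extension and reduces to the
single-label form at L = 1.

## Solving the fusion weights

Linearity of the trace gives tr(K\*HUH) = Σ_v β_v tr(K^v HUH), so the
optimization reduces to min −aᵀβ + ν₁βᵀβ on the simplex with
a_v = (1/N²) tr(K^v H U H).  For ν₁ > 0 this equals
ν₁‖β − a/(2ν₁)‖² up to a constant, whose simplex-constrained minimizer
is the Euclidean projection of a/(2ν₁) — computed exactly by the
sort-based projection algorithm, with no iterative solver.  At ν₁ = 0
the linear program's solution set is the face spanned by the argmax
alignments; weight is split uniformly across them as a deterministic
tie-break.  Entries below 10⁻¹⁰ are clipped and β renormalized.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| γ_v | 1/d_v (`"dim"`) | RBF bandwidth per view; 1/d is the conventional dimension-scaled default. Experiments use `"median"` — 1/median squared pairwise distance on the *training fold* — because composition vectors are compressed near the simplex and 1/d leaves the kernel nearly constant. |
| ν₁ | 10⁻³ | L2 penalty on β. Empirical HSIC alignments of unit-diagonal RBF kernels against Y Yᵀ are O(10⁻³) at N ≈ 100; ν₁ must be commensurate, since for ν₁ ≫ ‖a‖ the projection of a/(2ν₁) collapses to the uniform vector and the fusion degenerates into plain kernel averaging. |
| C | 1.0 | SVM box constraint; standard default, configurable. |
| threshold | 0.5 | calibrated-score cutoff for the label set; a row with no score above it receives its argmax label so every sample is assigned somewhere. |
| folds | 10 | CV protocol; folds are a seeded random partition (not label-stratified — stratification is deliberately not silently applied). |

β is refit inside every training fold (never on held-out data), as are
the median-heuristic bandwidths and the calibrators.  Feature encoding
itself is a deterministic per-sequence map, so it is computed once for
all samples without leaking label information.

## Evaluation measures

Average Precision, Coverage, Ranking Loss and One-error are computed
from the real-valued scores via per-sample ranks (rank 1 = best;
descending score, ties broken by ascending label index); Accuracy
(Jaccard) and Hamming Loss from the thresholded label sets.  Ties in
ranking loss count as losses (the ≤ convention).  Rows violating a
measure's denominator assumptions — no positive label; for ranking
loss, no positive/negative pair — are excluded from that measure's
average with a logged count, and a measure with no qualifying rows is
reported as NaN rather than silently 0.  A sample whose predicted and
true label sets are both empty scores accuracy 1 (agreement on the
empty set; the raw ratio is 0/0).  All six are verified against an
independent brute-force enumeration over every binary label matrix up
to 4×4, and against scikit-learn's ranking measures on tie-free random
instances.

## Dataset construction

From a FASTA plus an annotation table (sequence_id, gene_id, species,
category, comma-separated localizations), construction filters in a
fixed order: category (and optional case-insensitive species) →
gene-ID de-duplication keeping the first occurrence in input order →
drop unlabelled records → drop labels whose count satisfies
N/Nmax ≤ threshold (strict > required to keep; 1/30 for all-species,
1/12 for single-species benchmarks) → drop samples left label-less.
Label columns are sorted lexicographically.  Redundancy reduction at
80% identity is delegated to an external CD-HIT via a command hook
(`cluster_fasta` / `--cdhit-cmd`); without the tool the input passes
through with a logged warning.  Whether abundance filtering should
precede de-duplication is ambiguous; dedup-first is used and recorded
in each dataset's provenance string.

## Synthetic data

The generator emulates exactly the structure the method is meant to
exploit: uniform background sequences (80–160 nt), three compartments
with prevalences 0.55/0.45/0.30, a 15% pairwise co-occurrence boost, a
distinct 4-mer motif per compartment, and motif enrichment by stamping
Poisson((factor−1)·E) extra copies at random positions, where
E = (L−k+1)/4^k is the background expectation — so factor 1 is an exact
null and the expected motif count scales linearly.  10% of samples are
label-noise (no motif signal).  Everything derives from one seed, down
to the FASTA bytes.

What it does *not* emulate: realistic base composition, transcript
length distributions, secondary structure, homology between sequences
(redundancy), species effects, or annotation noise structure.  Passing
tests on this generator demonstrate that the pipeline recovers
label-dependent compositional signal and that its components are
mutually consistent — not that any particular accuracy carries over to
curated localization databases.

Because a sequence motif moves several composition views at once, a
"single informative view" benchmark cannot be built at the sequence
level; it is constructed by row-shuffling six of the seven feature
matrices (destroying their label association while preserving
marginals), leaving exactly one informative kernel.

## Numerical choices and degenerate inputs

* RBF diagonals are set to exactly 1 (floating-point guard); the fused
  kernel inherits the unit diagonal under convex weights.
* Encoders skip windows containing non-ACGT characters from numerator
  and denominator both; a sequence with no valid window encodes to the
  zero vector.  Sequences shorter than an encoder's window raise an
  error naming the encoder — silent zero-padding would corrupt kernels.
* A label column that is single-class in a CV training fold is skipped
  for that fold with a warning and the fold's measures cover the
  remaining labels; at training-set level the same condition is an
  error, since it indicates a broken dataset build.
* Platt calibration uses a lightly regularized logistic fit (C = 10⁴)
  on the 1-D decision values, keeping separable folds finite.

## Problem sizes

The test-suite and acceptance experiments use 100–200 sequences, three
labels and 10-fold CV, with 5 seeds for the signal/null comparisons and
20 seeds for weight recovery — sizes at which every kernel step is
exact (no approximations) and the full acceptance run completes in
seconds.

## Known limitations

* Binary relevance ignores label correlations at the classifier stage;
  correlations enter only through the fused kernel and U.
* β is global per fold, not sample- or label-specific.
* The simplex QP concentrates weight aggressively when one alignment
  dominates (projection, not softmax); with strongly correlated
  kernels the selected subset can be unstable between folds even when
  the fused kernel is not.
* Calibrated scores are comparable across labels only to the extent
  Platt scaling is adequate; no isotonic option is provided.
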