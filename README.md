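# rnalocmkl

Multi-label prediction of RNA subcellular localization from sequence
alone, by fusing several nucleotide-composition views of each sequence
with Hilbert–Schmidt independence criterion (HSIC) multiple kernel
learning and classifying with a one-vs-rest SVM on the fused kernel.

## Who this is for

RNAs function where they are located — nucleus, cytoplasm, exosome,
ribosome, ER — and a single transcript is often annotated to several
compartments at once, which makes localization a *multi-label* problem.
This package is for computational biologists who have RNA sequences
(FASTA) with curated multi-label localization annotations (a
RNALocate-style export) and want a reproducible sequence-only baseline,
plus the evaluation machinery that goes with it.

## The method

1. **Encoders.** Each sequence S = (s₁, …, s_L) over {A, C, G, T(U)} is
   mapped to seven fixed-dimension frequency vectors: 4-mer (256),
   concatenated 1–4-mers (340), reverse-complement-collapsed 4-mers
   (136), mono-/di-/tri-nucleotide composition (4/16/64, denominators
   N, N−1, N−2) and the composition of k-spaced nucleic-acid pairs for
   gaps 0–5 (96).
2. **Kernels.** Every view becomes an RBF kernel
   K_ij = exp(−γ‖x_i − x_j‖²).
3. **HSIC fusion.** With the label kernel U = Y Yᵀ (Y the binary
   n × L label matrix), the fused kernel K\* = Σ_p β_p K^p is chosen by

   min_β −(1/N²) tr(K\* H U H) + ν₁‖β‖²  s.t.  β_p ≥ 0, Σ β_p = 1,

   where H = I − eeᵀ/N.  The HSIC term is linear in β, so the problem
   is a tiny strictly convex QP solved in closed form by projecting
   a/(2ν₁) onto the simplex, with a_p = (1/N²) tr(K^p H U H).
4. **Classifier.** One C-SVM per label on the precomputed fused kernel
   (binary relevance), decision values calibrated to [0, 1] with a
   Platt-style sigmoid; the label set is scores ≥ 0.5 with an argmax
   fallback.
5. **Evaluation.** Average Precision, Accuracy (Jaccard), Coverage,
   Ranking Loss, Hamming Loss and One-error, aggregated as mean ± sd
   over seeded 10-fold cross-validation.

## Worked example

```python
from rnalocmkl import (CVConfig, GeneratorConfig, cross_validate,
                       generate_dataset, feature_matrices, mkl)

ds = generate_dataset(GeneratorConfig(n_samples=200, seed=0))
print("labels:", ds.label_names, ds.label_counts())

bank = feature_matrices(ds.sequences)
gammas = mkl.resolve_gammas(bank, "median")
kernels = mkl.build_kernel_bank(bank, gammas)
beta = mkl.solve_hsic_mkl(list(kernels.values()), mkl.ideal_kernel(ds.labels))
for name, b in zip(kernels, beta):
    print(f"beta[{name}] = {b:.3f}")

result = cross_validate(ds, CVConfig(n_folds=10, gamma="median", seed=0))
for name, (mean, std) in result.aggregate.items():
    print(f"{name:<18} {mean:.3f} +/- {std:.3f}")
```

prints

```
labels: ['cytoplasm', 'exosome', 'nucleus'] {'cytoplasm': 114, 'exosome': 84, 'nucleus': 137}
beta[kmer4] = 0.000
beta[kmer1234] = 0.000
beta[RCKmer] = 0.000
beta[NAC] = 0.054
beta[DNC] = 0.946
beta[TNC] = 0.000
beta[CKSNAP] = 0.000
average_precision  0.891 +/- 0.041
accuracy           0.613 +/- 0.053
coverage           1.005 +/- 0.139
ranking_loss       0.207 +/- 0.067
hamming_loss       0.308 +/- 0.045
one_error          0.170 +/- 0.071
```

The generator plants a distinct 4-mer motif per compartment
(enrichment ×5), so the labels are predictable from composition: HSIC
fusion concentrates weight on the low-order composition kernels that
carry the cleanest signal here, and cross-validated Average Precision
(0.89) sits far above the ~0.72 achieved on label-shuffled data.  Lower
is better for coverage, ranking loss, Hamming loss and one-error;
higher for AP and accuracy.

The same pipeline runs from the shell:

```sh
rnalocmkl generate --n-samples 200 --seed 0 --out data/
rnalocmkl build-dataset --fasta data/sequences.fasta \
    --annotations data/annotations.tsv --category lncRNA --out ds/
rnalocmkl crossval --dataset ds/ --folds 10 --method hsic
```

`build-dataset` applies the benchmark construction filters (gene-ID
de-duplication keeping the first occurrence, removal of unlabelled
records, and dropping labels with N/Nmax below the abundance cutoff —
1/30 for all-species datasets, 1/12 for single-species ones) and
accepts `--cdhit-cmd` to shell out to an external CD-HIT for 80%
redundancy reduction.

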