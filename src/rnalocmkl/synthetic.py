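"""Synthetic multi-label sequence datasets with label-dependent k-mer bias.

The generator emulates the statistical structure the classifier is meant
to exploit: sequences drawn from a uniform background over {A, C, G, T},
label sets drawn from per-label prevalences with an optional pairwise
co-occurrence boost, and — for each active label — a label-specific
k-mer motif over-represented relative to background by a configurable
enrichment factor.  Enrichment is implemented by stamping extra copies
of the motif at random positions (overwriting the background, keeping
length fixed): with background expectation E = (L - k + 1) / 4^k motif
occurrences, a Poisson((factor - 1) * E) number of copies is added, so
factor 1 reproduces the null exactly and the expected motif count scales
linearly with the factor.  A configurable fraction of samples is
"noisy": their labels carry no motif signal at all.

Everything is reproducible from the seed, down to the FASTA bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .dataset_io import AnnotationRecord, MultiLabelDataset, RNASequence

#: Worked single-sample example with hand-enumerated metric values:
#: L = 3 labels, true set {1st, 3rd}, scores (0.9, 0.8, 0.1), predictions
#: thresholded at 0.5.  Ranks are (1, 2, 3); the positive at rank 1
#: contributes 1/1 and the one at rank 3 contributes 2/3, so
#: AP = (1 + 2/3)/2 = 5/6; worst positive rank 3 gives coverage 2; of the
#: two (positive, negative) pairs only (label 3, label 2) is misordered,
#: so ranking loss = 1/2; the top label is a true one, one-error 0;
#: predictions {1, 2} against truth {1, 3} overlap in 1 of 3 union
#: labels (accuracy 1/3) and differ in 2 of 3 positions (Hamming 2/3).
WORKED_EXAMPLE_METRICS = {
    "average_precision": 5.0 / 6.0,
    "coverage": 2.0,
    "ranking_loss": 0.5,
    "one_error": 0.0,
    "accuracy": 1.0 / 3.0,
    "hamming_loss": 2.0 / 3.0,
}


def generate_worked_example() -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[str, float]]:
    """The fixed N=1, L=3 instance and its enumerated metric values.

    Returns (Y, scores, Yhat, expected).
    """
    Y = np.array([[1, 0, 1]], dtype=np.int8)
    scores = np.array([[0.9, 0.8, 0.1]])
    yhat = np.array([[1, 1, 0]], dtype=np.int8)
    return Y, scores, yhat, dict(WORKED_EXAMPLE_METRICS)


def _default_motifs() -> dict[str, str]:
    # distinct 4-mers, one per compartment
    return {"cytoplasm": "ACAC", "exosome": "TTCG", "nucleus": "GGGG"}


def _default_prevalence() -> dict[str, float]:
    return {"cytoplasm": 0.45, "exosome": 0.30, "nucleus": 0.55}


@dataclass
class GeneratorConfig:
    """Controls of the synthetic benchmark.

    Defaults give a moderately sized, clearly multi-label problem:
    200 sequences of 80-160 nt over three compartments with realistic
    prevalences, a 5x motif enrichment for active labels, 15% pairwise
    co-occurrence boost and 10% label-noise samples.
    """

    n_samples: int = 200
    motifs: Mapping[str, str] = field(default_factory=_default_motifs)
    prevalence: Mapping[str, float] = field(default_factory=_default_prevalence)
    cooccurrence: float = 0.15
    length_range: tuple[int, int] = (80, 160)
    enrichment: float = 5.0
    noise_fraction: float = 0.10
    rna_category: str = "lncRNA"
    species: str = "Homo sapiens"
    duplicate_gene_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if set(self.motifs) != set(self.prevalence):
            raise ValueError("motifs and prevalence must cover the same labels")
        if not all(0 < p < 1 for p in self.prevalence.values()):
            raise ValueError("prevalences must lie in (0, 1)")
        if self.enrichment < 1:
            raise ValueError(f"enrichment factor must be >= 1, got {self.enrichment}")
        if any(len(m) > self.length_range[0] for m in self.motifs.values()):
            raise ValueError("motif longer than the minimum sequence length")
        if self.length_range[0] < 7 or self.length_range[0] > self.length_range[1]:
            raise ValueError(f"invalid length range {self.length_range}")

    @property
    def label_names(self) -> list[str]:
        return sorted(self.motifs)


def _draw_labels(rng: np.random.Generator, config: GeneratorConfig) -> np.ndarray:
    names = config.label_names
    prev = np.array([config.prevalence[n] for n in names])
    z = (rng.random(len(names)) < prev).astype(np.int8)
    if len(names) >= 2 and rng.random() < config.cooccurrence:
        pair = rng.choice(len(names), size=2, replace=False)
        z[pair] = 1
    if z.sum() == 0:
        z[rng.choice(len(names), p=prev / prev.sum())] = 1
    return z


def _make_sequence(
    rng: np.random.Generator, config: GeneratorConfig, z: np.ndarray, noisy: bool
) -> str:
    lo, hi = config.length_range
    length = int(rng.integers(lo, hi + 1))
    seq = rng.choice(list("ACGT"), size=length)
    if not noisy and config.enrichment > 1:
        for name, active in zip(config.label_names, z):
            if not active:
                continue
            motif = config.motifs[name]
            k = len(motif)
            expected = (length - k + 1) / 4**k
            n_copies = rng.poisson((config.enrichment - 1.0) * expected)
            for _ in range(n_copies):
                start = int(rng.integers(0, length - k + 1))
                seq[start : start + k] = list(motif)
    return "".join(seq)


def generate_dataset(config: GeneratorConfig | None = None) -> MultiLabelDataset:
    """Draw a fully reproducible multi-label dataset from the config."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    names = config.label_names
    sequences, rows = [], []
    for i in range(config.n_samples):
        z = _draw_labels(rng, config)
        noisy = rng.random() < config.noise_fraction
        seq = _make_sequence(rng, config, z, noisy)
        sequences.append(RNASequence(id=f"syn{i:05d}", sequence=seq))
        rows.append(z)
    return MultiLabelDataset(
        sequences=sequences,
        labels=np.vstack(rows),
        label_names=list(names),
        provenance=(
            f"synthetic: n={config.n_samples} labels={names} "
            f"enrichment={config.enrichment} noise={config.noise_fraction} "
            f"seed={config.seed}"
        ),
    )


def generate_annotations(
    dataset: MultiLabelDataset, config: GeneratorConfig | None = None
) -> list[AnnotationRecord]:
    """Annotation rows matching the generated dataset.

    Gene IDs are unique by default; ``duplicate_gene_fraction`` reassigns
    that fraction of samples the previous sample's gene ID so the
    dedup filter in dataset construction is exercised.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed + 1)
    out = []
    for i, seq in enumerate(dataset.sequences):
        gene = f"GENE{i:05d}"
        if i > 0 and rng.random() < config.duplicate_gene_fraction:
            gene = f"GENE{i - 1:05d}"
        labels = {
            name
            for name, v in zip(dataset.label_names, dataset.labels[i])
            if v
        }
        out.append(
            AnnotationRecord(
                sequence_id=seq.id,
                gene_id=gene,
                species=config.species,
                rna_category=config.rna_category,
                localizations=frozenset(labels),
            )
        )
    return out


def shuffle_labels(dataset: MultiLabelDataset, seed: int = 0) -> MultiLabelDataset:
    """Permute label rows against sequences — the permutation null.

    Row-wise permutation preserves the label-set distribution and all
    column margins while destroying any sequence-label association.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(dataset.n_samples)
    return MultiLabelDataset(
        sequences=list(dataset.sequences),
        labels=dataset.labels[perm],
        label_names=list(dataset.label_names),
        provenance=dataset.provenance + f" | labels shuffled (seed={seed})",
    )
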