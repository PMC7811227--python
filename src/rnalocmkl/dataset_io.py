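"""Reading, filtering and serializing multi-label localization datasets.

A dataset couples RNA sequences (FASTA) with an annotation table mapping
sequence IDs to gene IDs, species, RNA category and one or more
subcellular localization labels — the export format of curated
localization databases.  Construction applies, in order: category and
optional species filtering, gene-ID de-duplication (first occurrence
kept), removal of unlabelled records, and a relative label-abundance
filter that drops rare compartments whose sample count N satisfies
N / Nmax <= threshold_ratio (strictly greater than the threshold is
required to keep a label).
"""

from __future__ import annotations

import csv
import json
import logging
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .features import has_ambiguity, normalize_sequence

logger = logging.getLogger(__name__)

RNA_CATEGORIES = frozenset({"mRNA", "lncRNA", "miRNA", "snoRNA"})

#: Relative-abundance thresholds used when building the all-species and
#: the human-only benchmark datasets.
THRESHOLD_ALL_SPECIES = 1.0 / 30.0
THRESHOLD_HUMAN = 1.0 / 12.0


class FastaParseError(ValueError):
    """Malformed FASTA input; the message names the offending line."""


@dataclass(frozen=True)
class RNASequence:
    """An identified nucleotide sequence, normalized to uppercase DNA."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"sequence {self.id!r} is empty")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def has_ambiguity(self) -> bool:
        return has_ambiguity(self.sequence)


@dataclass(frozen=True)
class AnnotationRecord:
    """One row of the annotation table."""

    sequence_id: str
    gene_id: str
    species: str
    rna_category: str
    localizations: frozenset[str]

    def __post_init__(self):
        if not self.localizations:
            raise ValueError(
                f"annotation for {self.sequence_id!r} has no localization labels"
            )
        if self.rna_category not in RNA_CATEGORIES:
            raise ValueError(
                f"unknown RNA category {self.rna_category!r} for {self.sequence_id!r}; "
                f"expected one of {sorted(RNA_CATEGORIES)}"
            )


@dataclass
class MultiLabelDataset:
    """Sequences plus an aligned binary label matrix.

    ``labels`` is (n_samples, n_labels) with entries in {0, 1}; every row
    has at least one positive and every column at least one positive.
    """

    sequences: list[RNASequence]
    labels: np.ndarray
    label_names: list[str]
    provenance: str = ""

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.shape != (len(self.sequences), len(self.label_names)):
            raise ValueError(
                f"label matrix shape {self.labels.shape} does not match "
                f"{len(self.sequences)} sequences x {len(self.label_names)} labels"
            )
        if self.labels.size:
            if (self.labels.sum(axis=1) == 0).any():
                raise ValueError("every sample must carry at least one label")
            if (self.labels.sum(axis=0) == 0).any():
                raise ValueError("every label must have at least one positive sample")

    @property
    def n_samples(self) -> int:
        return len(self.sequences)

    @property
    def n_labels(self) -> int:
        return len(self.label_names)

    def label_counts(self) -> dict[str, int]:
        return {
            name: int(c) for name, c in zip(self.label_names, self.labels.sum(axis=0))
        }


def read_fasta(path) -> list[RNASequence]:
    """Parse a FASTA file into normalized :class:`RNASequence` records.

    Record order is preserved; duplicate IDs are rejected; U is mapped to
    T and sequences uppercased.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FastaParseError(f"{path}: file is empty")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise FastaParseError(
                f"{path}: line {lineno} is not part of a FASTA record "
                f"(expected a '>' header first): {line[:40]!r}"
            )
        break
    records: list[RNASequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence ID {rec.id!r}")
        seen.add(rec.id)
        records.append(RNASequence(id=rec.id, sequence=normalize_sequence(str(rec.seq))))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


ANNOTATION_COLUMNS = ("sequence_id", "gene_id", "species", "category", "localizations")


def read_annotations(path) -> list[AnnotationRecord]:
    """Read a tab-separated annotation table.

    Expected header: ``sequence_id  gene_id  species  category
    localizations`` with localizations a comma-separated list.
    """
    path = Path(path)
    out: list[AnnotationRecord] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(ANNOTATION_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"{path}: annotation table missing columns {sorted(missing)}")
        for row in reader:
            out.append(
                AnnotationRecord(
                    sequence_id=row["sequence_id"].strip(),
                    gene_id=row["gene_id"].strip(),
                    species=row["species"].strip(),
                    rna_category=row["category"].strip(),
                    localizations=frozenset(
                        lab.strip() for lab in row["localizations"].split(",") if lab.strip()
                    ),
                )
            )
    return out


def write_annotations(path, annotations: Iterable[AnnotationRecord]) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ANNOTATION_COLUMNS)
        for ann in annotations:
            writer.writerow(
                [
                    ann.sequence_id,
                    ann.gene_id,
                    ann.species,
                    ann.rna_category,
                    ",".join(sorted(ann.localizations)),
                ]
            )


def filter_labels_by_abundance(
    counts: dict[str, int], threshold_ratio: float
) -> list[str]:
    """Labels whose count N satisfies N / Nmax > threshold_ratio (strict).

    A label sitting exactly on the threshold is dropped.
    """
    if not counts:
        return []
    nmax = max(counts.values())
    return sorted(name for name, n in counts.items() if n / nmax > threshold_ratio)


def build_multilabel_dataset(
    sequences: Sequence[RNASequence],
    annotations: Sequence[AnnotationRecord],
    category: str,
    species_filter: str | None = None,
    threshold_ratio: float = THRESHOLD_ALL_SPECIES,
) -> MultiLabelDataset:
    """Apply the construction filters and assemble a dataset.

    Steps, in order: (1) keep annotations of the requested RNA category
    (and species, case-insensitively, when given); (2) de-duplicate by
    gene ID keeping the first occurrence in input order; (3) drop records
    without localization labels (enforced at parse time); (4) compute
    per-label counts, drop labels with N / Nmax <= threshold_ratio;
    (5) drop samples left without labels.  Label columns are sorted
    lexicographically.
    """
    if not (0 < threshold_ratio < 1):
        raise ValueError(f"threshold_ratio must lie in (0, 1), got {threshold_ratio}")
    if category not in RNA_CATEGORIES:
        raise ValueError(f"unknown category {category!r}")

    seq_by_id = {s.id: s for s in sequences}
    unresolved = [a.sequence_id for a in annotations if a.sequence_id not in seq_by_id]
    if unresolved:
        raise ValueError(
            "annotation sequence IDs not present in FASTA: "
            + ", ".join(sorted(set(unresolved)))
        )

    log: list[str] = [f"category={category}"]
    kept = [a for a in annotations if a.rna_category == category]
    if species_filter is not None:
        kept = [a for a in kept if a.species.lower() == species_filter.lower()]
        log.append(f"species={species_filter}")
    log.append(f"after category/species filter: {len(kept)} records")

    seen_genes: set[str] = set()
    deduped: list[AnnotationRecord] = []
    for a in kept:
        if a.gene_id in seen_genes:
            continue
        seen_genes.add(a.gene_id)
        deduped.append(a)
    log.append(f"after gene-ID dedup: {len(deduped)} records")

    counts: dict[str, int] = {}
    for a in deduped:
        for lab in a.localizations:
            counts[lab] = counts.get(lab, 0) + 1
    kept_labels = filter_labels_by_abundance(counts, threshold_ratio)
    log.append(
        f"label counts {dict(sorted(counts.items()))}; "
        f"kept labels at N/Nmax > {threshold_ratio:.4g}: {kept_labels}"
    )

    final = [a for a in deduped if a.localizations & set(kept_labels)]
    log.append(f"after dropping unlabelled samples: {len(final)} records")
    if not final or not kept_labels:
        raise ValueError(
            "dataset construction produced no samples/labels; build log: "
            + " | ".join(log)
        )

    labels = np.zeros((len(final), len(kept_labels)), dtype=np.int8)
    for i, a in enumerate(final):
        for j, lab in enumerate(kept_labels):
            if lab in a.localizations:
                labels[i, j] = 1
    return MultiLabelDataset(
        sequences=[seq_by_id[a.sequence_id] for a in final],
        labels=labels,
        label_names=kept_labels,
        provenance=" | ".join(log),
    )


def save_dataset(dataset: MultiLabelDataset, directory) -> None:
    """Serialize as {sequences.fasta, labels.tsv, meta.json}."""
    import pandas as pd

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with (directory / "sequences.fasta").open("w") as fh:
        for s in dataset.sequences:
            fh.write(f">{s.id}\n{s.sequence}\n")
    frame = pd.DataFrame(
        dataset.labels,
        index=[s.id for s in dataset.sequences],
        columns=dataset.label_names,
    )
    frame.index.name = "sequence_id"
    frame.to_csv(directory / "labels.tsv", sep="\t")
    meta = {
        "label_names": dataset.label_names,
        "label_counts": dataset.label_counts(),
        "n_samples": dataset.n_samples,
        "provenance": dataset.provenance,
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2) + "\n")


def load_dataset(directory) -> MultiLabelDataset:
    import pandas as pd

    directory = Path(directory)
    sequences = read_fasta(directory / "sequences.fasta")
    frame = pd.read_csv(directory / "labels.tsv", sep="\t", index_col="sequence_id")
    meta = json.loads((directory / "meta.json").read_text())
    order = [s.id for s in sequences]
    frame = frame.loc[order, meta["label_names"]]
    return MultiLabelDataset(
        sequences=sequences,
        labels=frame.to_numpy(dtype=np.int8),
        label_names=list(meta["label_names"]),
        provenance=meta.get("provenance", ""),
    )


def cluster_fasta(
    in_fasta, out_fasta, cdhit_cmd: str | None = None, cutoff: float = 0.8
) -> Path:
    """Redundancy-reduce a FASTA with an external CD-HIT-style tool.

    Sequence clustering at a fractional identity cutoff (default 80%) is
    delegated to an external command invoked as
    ``{cmd} -i IN -o OUT -c CUTOFF``.  Without a command the input is
    passed through unchanged with a logged warning, so pre-clustered
    inputs keep working.
    """
    in_fasta, out_fasta = Path(in_fasta), Path(out_fasta)
    if cdhit_cmd is None:
        logger.warning(
            "no clustering command configured; copying %s unclustered", in_fasta
        )
        shutil.copyfile(in_fasta, out_fasta)
        return out_fasta
    subprocess.run(
        [cdhit_cmd, "-i", str(in_fasta), "-o", str(out_fasta), "-c", str(cutoff)],
        check=True,
    )
    return out_fasta
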