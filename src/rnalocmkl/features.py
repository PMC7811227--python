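"""Nucleotide composition encoders.

Seven fixed-parameter encoders map a nucleotide sequence to a
non-negative frequency vector:

=========  ====  ==========================================================
encoder    dim   description
=========  ====  ==========================================================
kmer4       256  4-mer occurrence frequencies
kmer1234    340  concatenated 1-, 2-, 3- and 4-mer frequencies (4+16+64+256)
RCKmer      136  4-mer frequencies after collapsing reverse-complement pairs
NAC           4  mononucleotide composition, denominator N
DNC          16  dinucleotide composition, denominator N-1
TNC          64  trinucleotide composition, denominator N-2
CKSNAP       96  k-spaced pair composition for gaps 0..5, 16 pairs per gap
=========  ====  ==========================================================

All blocks are ordered lexicographically over the alphabet A < C < G < T.
Sequences are normalized to DNA-style uppercase (U -> T).  Windows that
contain a non-ACGT character (IUPAC ambiguity codes, runs of N from
assembly gaps) are excluded from both the numerator and the denominator,
so degraded sequences still encode to proper frequencies instead of
erroring out or silently diluting counts.
"""

from __future__ import annotations

import itertools
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Canonical encoder order used for kernel banks and fusion weights.
ENCODER_ORDER: tuple[str, ...] = (
    "kmer4",
    "kmer1234",
    "RCKmer",
    "NAC",
    "DNC",
    "TNC",
    "CKSNAP",
)

ENCODER_DIMS: dict[str, int] = {
    "kmer4": 256,
    "kmer1234": 340,
    "RCKmer": 136,
    "NAC": 4,
    "DNC": 16,
    "TNC": 64,
    "CKSNAP": 96,
}

CKSNAP_GAPS: tuple[int, ...] = (0, 1, 2, 3, 4, 5)

#: Minimum sequence length accepted by the full bank (CKSNAP gap 5 needs
#: two bases 6 positions apart).
MIN_BANK_LENGTH = max(CKSNAP_GAPS) + 2


class SequenceTooShortError(ValueError):
    """Raised when a sequence is shorter than an encoder's window."""


def normalize_sequence(raw: str) -> str:
    """Uppercase a raw sequence and map U to T.

    Characters outside {A, C, G, T} are retained; encoders skip windows
    containing them.  Raises ``ValueError`` on an empty input.
    """
    if not raw:
        raise ValueError("cannot normalize an empty sequence")
    return raw.upper().replace("U", "T")


def has_ambiguity(sequence: str) -> bool:
    """True if the (normalized) sequence contains non-ACGT characters."""
    return any(c not in ALPHABET for c in sequence)


def reverse_complement(kmer: str) -> str:
    return kmer.translate(_COMPLEMENT)[::-1]


def _as_string(seq) -> str:
    # accept either a plain string or a record with a .sequence attribute
    return getattr(seq, "sequence", seq)


@lru_cache(maxsize=None)
def kmer_names(k: int) -> tuple[str, ...]:
    """All 4^k k-mers in lexicographic order."""
    return tuple("".join(p) for p in itertools.product(ALPHABET, repeat=k))


@lru_cache(maxsize=None)
def canonical_kmers(k: int) -> tuple[str, ...]:
    """Canonical reverse-complement classes, lexicographically sorted.

    The canonical form of a k-mer is the lexicographic minimum of the
    k-mer and its reverse complement; for even k the class count is
    (4^k + 4^(k/2)) / 2 (10 classes at k=2, 136 at k=4).
    """
    return tuple(sorted({min(t, reverse_complement(t)) for t in kmer_names(k)}))


@lru_cache(maxsize=None)
def _kmer_index(k: int) -> Mapping[str, int]:
    return {t: i for i, t in enumerate(kmer_names(k))}


@lru_cache(maxsize=None)
def _canonical_index(k: int) -> Mapping[str, int]:
    classes = {t: i for i, t in enumerate(canonical_kmers(k))}
    return {t: classes[min(t, reverse_complement(t))] for t in kmer_names(k)}


def _window_frequencies(s: str, k: int, index: Mapping[str, int], dim: int) -> np.ndarray:
    counts = np.zeros(dim)
    valid = 0
    for i in range(len(s) - k + 1):
        idx = index.get(s[i : i + k])
        if idx is None:  # window touches an ambiguous character
            continue
        counts[idx] += 1
        valid += 1
    if valid:
        counts /= valid
    return counts


def encode_kmer(seq, k: int) -> np.ndarray:
    """k-mer occurrence frequencies f(t) = N(t) / (N - k + 1).

    The denominator counts only unambiguous windows, which equals
    N - k + 1 for a clean sequence.
    """
    s = _as_string(seq)
    if len(s) < k:
        raise SequenceTooShortError(
            f"sequence {getattr(seq, 'id', '<anonymous>')!r} of length {len(s)} "
            f"is shorter than k={k}"
        )
    return _window_frequencies(s, k, _kmer_index(k), 4**k)


def encode_kmer_range(seq, ks: Sequence[int] = (1, 2, 3, 4)) -> np.ndarray:
    """Concatenated k-mer blocks for k = 1..4 (340 dimensions)."""
    return np.concatenate([encode_kmer(seq, k) for k in sorted(ks)])


def encode_rckmer(seq, k: int = 4) -> np.ndarray:
    """Strand-symmetric k-mer frequencies over canonical classes.

    Each k-mer is pooled with its reverse complement, so e.g. at k=2 the
    'TT' count accrues to the 'AA' class.  136 dimensions at k=4.
    """
    s = _as_string(seq)
    if len(s) < k:
        raise SequenceTooShortError(
            f"sequence {getattr(seq, 'id', '<anonymous>')!r} of length {len(s)} "
            f"is shorter than k={k}"
        )
    return _window_frequencies(s, k, _canonical_index(k), len(canonical_kmers(k)))


def encode_composition(seq, k: int) -> np.ndarray:
    """NAC / DNC / TNC composition for k in {1, 2, 3}.

    The textbook denominators N, N-1, N-2 coincide with the k-mer window
    count N - k + 1, so these are the k = 1, 2, 3 mer frequencies.
    """
    if k not in (1, 2, 3):
        raise ValueError(f"composition encoder defined for k in 1..3, got {k}")
    return encode_kmer(seq, k)


def encode_cksnap(seq, gaps: Sequence[int] = CKSNAP_GAPS) -> np.ndarray:
    """Composition of k-spaced nucleic acid pairs.

    For each gap g the ordered pairs (s_i, s_{i+g+1}) are counted over the
    L - g - 1 available positions and normalized into a 16-entry block;
    blocks are concatenated in ascending gap order (96 dimensions for
    gaps 0..5).
    """
    s = _as_string(seq)
    gaps = tuple(sorted(gaps))
    if len(s) < max(gaps) + 2:
        raise SequenceTooShortError(
            f"sequence {getattr(seq, 'id', '<anonymous>')!r} of length {len(s)} "
            f"is too short for CKSNAP gap {max(gaps)} (needs >= {max(gaps) + 2})"
        )
    base_index = {c: i for i, c in enumerate(ALPHABET)}
    blocks = []
    for g in gaps:
        counts = np.zeros(16)
        valid = 0
        for i in range(len(s) - g - 1):
            a = base_index.get(s[i])
            b = base_index.get(s[i + g + 1])
            if a is None or b is None:
                continue
            counts[4 * a + b] += 1
            valid += 1
        if valid:
            counts /= valid
        blocks.append(counts)
    return np.concatenate(blocks)


_ENCODER_FUNCS = {
    "kmer4": lambda s: encode_kmer(s, 4),
    "kmer1234": lambda s: encode_kmer_range(s),
    "RCKmer": lambda s: encode_rckmer(s, 4),
    "NAC": lambda s: encode_composition(s, 1),
    "DNC": lambda s: encode_composition(s, 2),
    "TNC": lambda s: encode_composition(s, 3),
    "CKSNAP": lambda s: encode_cksnap(s),
}


def encode_feature_bank(seq) -> dict[str, np.ndarray]:
    """Apply all seven encoders with their fixed parameters.

    Returns a dict keyed in :data:`ENCODER_ORDER`.  Raises
    :class:`SequenceTooShortError` naming the failing encoder for
    sequences shorter than 7 nt.
    """
    out: dict[str, np.ndarray] = {}
    for name in ENCODER_ORDER:
        try:
            out[name] = _ENCODER_FUNCS[name](seq)
        except SequenceTooShortError as exc:
            raise SequenceTooShortError(f"encoder {name}: {exc}") from exc
    return out


def feature_matrices(seqs: Sequence) -> dict[str, np.ndarray]:
    """Stack per-sequence feature vectors into per-encoder (n, d) matrices."""
    banks = [encode_feature_bank(s) for s in seqs]
    return {
        name: np.vstack([b[name] for b in banks]) if banks else np.empty((0, ENCODER_DIMS[name]))
        for name in ENCODER_ORDER
    }


def feature_frame(seqs: Sequence, encoder: str):
    """Feature matrix for one encoder as a labelled pandas DataFrame."""
    import pandas as pd

    if encoder not in ENCODER_ORDER:
        raise ValueError(f"unknown encoder {encoder!r}; choose from {ENCODER_ORDER}")
    names = _feature_names(encoder)
    ids = [getattr(s, "id", str(i)) for i, s in enumerate(seqs)]
    mat = np.vstack([_ENCODER_FUNCS[encoder](s) for s in seqs]) if len(seqs) else np.empty((0, len(names)))
    return pd.DataFrame(mat, index=ids, columns=names)


def _feature_names(encoder: str) -> list[str]:
    if encoder == "kmer4":
        return list(kmer_names(4))
    if encoder == "kmer1234":
        return [t for k in (1, 2, 3, 4) for t in kmer_names(k)]
    if encoder == "RCKmer":
        return list(canonical_kmers(4))
    if encoder == "NAC":
        return list(kmer_names(1))
    if encoder == "DNC":
        return list(kmer_names(2))
    if encoder == "TNC":
        return list(kmer_names(3))
    if encoder == "CKSNAP":
        return [f"{a}.gap{g}.{b}" for g in CKSNAP_GAPS for a in ALPHABET for b in ALPHABET]
    raise ValueError(encoder)
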