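"""Disease symptom vectors from disease-symptom co-occurrence counts.

Diseases are represented by non-negative TF-IDF weights over a fixed
symptom vocabulary: the term frequency is the raw disease-symptom
co-occurrence count and the inverse document frequency is
``ln(N_d / n_m)`` with ``N_d`` the number of diseases in the corpus and
``n_m`` the number of diseases co-occurring with symptom ``m`` at least
once.  A symptom shared by every disease therefore carries weight zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError


@dataclass(frozen=True)
class SymptomVocabulary:
    """Fixed, ordered list of unique symptom terms; column m always means terms[m]."""

    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        terms = tuple(self.terms)
        if len(set(terms)) != len(terms):
            raise ValueError("symptom vocabulary contains duplicate terms")
        object.__setattr__(self, "terms", terms)

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class SymptomVector:
    """Ordered non-negative symptom weights for one disease."""

    disease_id: str
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 1 or w.size == 0:
            raise ValueError("symptom weights must be a non-empty 1-d vector")
        if (w < 0).any():
            raise ValueError("symptom weights must be non-negative")
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return int(self.weights.size)


@dataclass(frozen=True)
class CooccurrenceTable:
    """Disease x symptom co-occurrence counts."""

    disease_ids: tuple[str, ...]
    vocabulary: SymptomVocabulary
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.disease_ids), len(self.vocabulary)):
            raise ValueError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.disease_ids)} diseases x {len(self.vocabulary)} symptoms"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.array_equal(counts, counts.astype(np.int64)):
                raise ValueError("co-occurrence counts must be integers")
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            raise ValueError("co-occurrence counts must be non-negative")
        object.__setattr__(self, "disease_ids", tuple(self.disease_ids))
        object.__setattr__(self, "counts", counts)


def tfidf_symptom_vectors(table: CooccurrenceTable) -> list[SymptomVector]:
    """TF-IDF weights per disease: ``count(j,m) * ln(N_d / n_m)``.

    A weight is zero exactly where the count is zero; if every disease
    shows a symptom its idf is ``ln(1) = 0`` and the whole column
    vanishes.  A disease with no symptom co-occurrence at all cannot be
    represented and raises ``ValueError``.
    """
    counts = table.counts
    zero_rows = np.where(~counts.any(axis=1))[0]
    if zero_rows.size:
        bad = table.disease_ids[zero_rows[0]]
        raise ValueError(f"disease {bad!r} has an all-zero symptom row")
    n_d = counts.shape[0]
    n_m = (counts > 0).sum(axis=0)
    with np.errstate(divide="ignore"):
        idf = np.where(n_m > 0, np.log(n_d / np.maximum(n_m, 1)), 0.0)
    weights = counts.astype(np.float64) * idf[np.newaxis, :]
    return [
        SymptomVector(did, weights[j]) for j, did in enumerate(table.disease_ids)
    ]


def read_cooccurrence_table(path: str | Path) -> CooccurrenceTable:
    """Read the TSV dialect: first column disease_id, header = symptom terms."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no symptom columns")
    counts = df.to_numpy()
    try:
        return CooccurrenceTable(
            tuple(str(d) for d in df.index),
            SymptomVocabulary(tuple(str(c) for c in df.columns)),
            counts,
        )
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_cooccurrence_table(table: CooccurrenceTable, path: str | Path) -> None:
    pd.DataFrame(
        table.counts, index=list(table.disease_ids), columns=list(table.vocabulary.terms)
    ).rename_axis("disease_id").to_csv(path, sep="\t")


def read_symptom_vectors(path: str | Path) -> tuple[SymptomVocabulary, list[SymptomVector]]:
    """Read precomputed real-valued symptom vectors (same TSV layout)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    vocab = SymptomVocabulary(tuple(str(c) for c in df.columns))
    values = df.to_numpy(dtype=np.float64)
    return vocab, [
        SymptomVector(str(d), values[j]) for j, d in enumerate(df.index)
    ]


def write_symptom_vectors(
    vocabulary: SymptomVocabulary, vectors: Sequence[SymptomVector], path: str | Path
) -> None:
    pd.DataFrame(
        np.vstack([v.weights for v in vectors]),
        index=[v.disease_id for v in vectors],
        columns=list(vocabulary.terms),
    ).rename_axis("disease_id").to_csv(path, sep="\t")
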