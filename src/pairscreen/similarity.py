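"""Similarity measures between drugs, diseases and drug-disease pairs.

Drug similarity is the Jaccard coefficient on fingerprint on-bits,
disease similarity the cosine of the angle between symptom-weight
vectors, and pair similarity their arithmetic mean.  All three lie in
[0, 1] for valid (binary / non-negative) inputs.  Degenerate inputs
(no on-bits, zero-norm weights) are defined to have similarity 0: no
shared structure or signal.
"""

from __future__ import annotations

import numpy as np

from .fingerprints import FingerprintVector
from .symptoms import SymptomVector


def _as_pair(a, b, what: str) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(a, dtype=np.float64)
    y = np.asarray(b, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"{what}: dimension mismatch {x.shape} vs {y.shape}")
    return x, y


def jaccard(a: FingerprintVector | np.ndarray, b: FingerprintVector | np.ndarray) -> float:
    """|on(a) ∩ on(b)| / |on(a) ∪ on(b)|; 0 when both vectors are all-zero."""
    x = a.bits if isinstance(a, FingerprintVector) else a
    y = b.bits if isinstance(b, FingerprintVector) else b
    x, y = _as_pair(x, y, "jaccard")
    inter = float(np.sum((x > 0) & (y > 0)))
    union = float(np.sum((x > 0) | (y > 0)))
    return inter / union if union else 0.0


def cosine(a: SymptomVector | np.ndarray, b: SymptomVector | np.ndarray) -> float:
    """dot(a,b) / (|a||b|); 0 when either norm is zero."""
    x = a.weights if isinstance(a, SymptomVector) else a
    y = b.weights if isinstance(b, SymptomVector) else b
    x, y = _as_pair(x, y, "cosine")
    na = float(np.linalg.norm(x))
    nb = float(np.linalg.norm(y))
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.clip(np.dot(x, y) / (na * nb), 0.0, 1.0))


def pair_similarity(
    p1: tuple[FingerprintVector | np.ndarray, SymptomVector | np.ndarray],
    p2: tuple[FingerprintVector | np.ndarray, SymptomVector | np.ndarray],
) -> float:
    """(jaccard of drug parts + cosine of disease parts) / 2."""
    return 0.5 * (jaccard(p1[0], p2[0]) + cosine(p1[1], p2[1]))
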