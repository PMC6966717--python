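"""Two-dimensional pair-matrix encoding of one (drug, disease) pair.

The pair matrix is the outer sum ``M[n, m] = F[n] + D[m]`` of the binary
fingerprint ``F`` (rows) and the non-negative symptom-weight vector ``D``
(columns); with the default shapes this is an 881 x 322 array.  For
inspection and interchange the matrix can be rendered as a single-channel
8-bit gray-scale image under a *global* normalization constant shared by
the whole dataset, so pixel intensity stays comparable across pairs.  The
classifier consumes the real-valued matrix rescaled by the same constant,
not the quantized pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .exceptions import FormatError
from .fingerprints import FingerprintVector
from .symptoms import SymptomVector


@dataclass(frozen=True)
class PairMatrix:
    drug_id: str
    disease_id: str
    values: np.ndarray  # shape (n_bits, n_symptoms)


@dataclass(frozen=True)
class GrayImage:
    drug_id: str
    disease_id: str
    pixels: np.ndarray  # uint8, same shape as the source matrix
    scale: float


def build_pair_matrix(f: FingerprintVector, d: SymptomVector) -> PairMatrix:
    """Outer sum of fingerprint bits (rows) and symptom weights (columns)."""
    if len(f) == 0 or len(d) == 0:
        raise ValueError("empty feature vectors cannot form a pair matrix")
    values = np.add.outer(f.bits.astype(np.float64), d.weights)
    return PairMatrix(f.drug_id, d.disease_id, values)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # np.round rounds halves to even; the image contract rounds half away
    # from zero (values here are always >= 0).
    return np.floor(x + 0.5)


def to_gray_image(m: PairMatrix, scale: float) -> GrayImage:
    """Linear rescale by a global constant, then 8-bit quantization."""
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    pixels = np.clip(_round_half_away(255.0 * m.values / scale), 0, 255)
    return GrayImage(m.drug_id, m.disease_id, pixels.astype(np.uint8), float(scale))


def write_image(img: GrayImage, path: str | Path) -> None:
    """Write a single-channel 8-bit PNG plus a JSON metadata sidecar."""
    path = Path(path)
    Image.fromarray(img.pixels, mode="L").save(path, format="PNG")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {"drug_id": img.drug_id, "disease_id": img.disease_id, "scale": img.scale}
        )
    )


def read_image(path: str | Path) -> GrayImage:
    path = Path(path)
    with Image.open(path) as im:
        if im.mode != "L":
            raise FormatError(
                f"{path}: expected single-channel 8-bit gray-scale, got mode {im.mode!r}"
            )
        pixels = np.asarray(im, dtype=np.uint8)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FormatError(f"{path}: missing metadata sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    return GrayImage(meta["drug_id"], meta["disease_id"], pixels, float(meta["scale"]))


def dataset_scale(symptom_vectors) -> float:
    """Global normalization constant: 1 + the maximum symptom weight seen.

    One added unit accounts for the binary fingerprint contribution, so
    every pair-matrix entry of the corpus falls in [0, scale].
    """
    peak = max(float(np.max(v.weights)) for v in symptom_vectors)
    return 1.0 + peak
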