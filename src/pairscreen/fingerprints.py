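"""Drug fingerprint vectors and fingerprint schemes.

A fingerprint here is an ordered binary vector in which position *n*
indicates presence of a predefined chemical substructure.  The native
scheme (``substructure-key``) evaluates an 881-entry key dictionary on an
RDKit molecule; any externally computed binary scheme (e.g. exported by a
descriptor package) can be loaded from a TSV table, whose column count
then defines the scheme dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from . import _keys
from .exceptions import FormatError, SmilesParseError, UnknownSchemeError

RDLogger.DisableLog("rdApp.*")

SUBSTRUCTURE_KEY_SCHEME = "substructure-key"


@dataclass(frozen=True)
class FingerprintVector:
    """Ordered binary substructure-presence vector for one drug."""

    drug_id: str
    bits: np.ndarray
    scheme: str = SUBSTRUCTURE_KEY_SCHEME

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.uint8)
        if bits.ndim != 1 or bits.size == 0:
            raise ValueError("fingerprint bits must be a non-empty 1-d vector")
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("fingerprint bits must be exactly 0 or 1")
        object.__setattr__(self, "bits", bits)

    def __len__(self) -> int:
        return int(self.bits.size)


class SubstructureKeyScheme:
    """The native 881-key substructure fingerprint."""

    name = SUBSTRUCTURE_KEY_SCHEME
    dimension = _keys.DIMENSION

    def featurize(self, smiles: str) -> np.ndarray:
        mol = _parse_smiles(smiles)
        return np.array(
            [_keys.evaluate_key(mol, k) for k in _keys.KEYS], dtype=np.uint8
        )


_SCHEMES: dict[str, SubstructureKeyScheme] = {
    SUBSTRUCTURE_KEY_SCHEME: SubstructureKeyScheme()
}


def get_scheme(name: str) -> SubstructureKeyScheme:
    try:
        return _SCHEMES[name]
    except KeyError:
        raise UnknownSchemeError(
            f"unknown fingerprint scheme {name!r}; registered: {sorted(_SCHEMES)}"
        ) from None


def _parse_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"cannot parse SMILES string: {smiles!r}")
    # round-trip through the canonical form so input spelling never matters
    return Chem.MolFromSmiles(Chem.MolToSmiles(mol))


def canonical_smiles(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"cannot parse SMILES string: {smiles!r}")
    return Chem.MolToSmiles(mol)


def compute_fingerprint(
    structure: str,
    scheme: str = SUBSTRUCTURE_KEY_SCHEME,
    drug_id: str | None = None,
) -> FingerprintVector:
    """Featurize one SMILES string under a registered scheme.

    The structure is canonicalized first, so two spellings of the same
    molecule give bitwise-identical vectors.
    """
    sch = get_scheme(scheme)
    bits = sch.featurize(structure)
    return FingerprintVector(
        drug_id=drug_id if drug_id is not None else canonical_smiles(structure),
        bits=bits,
        scheme=scheme,
    )


def read_smiles_file(path: str | Path) -> list[tuple[str, str]]:
    """Read ``<drug_id>\\t<smiles>`` records, one per line."""
    records = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 'drug_id<TAB>smiles'")
        records.append((parts[0], parts[1]))
    return records


def load_fingerprint_table(path: str | Path) -> list[FingerprintVector]:
    """Load externally computed binary fingerprints from a TSV table.

    Layout: header row, first column ``drug_id``, remaining columns bits.
    All rows must share one length; that length becomes the scheme
    dimension, recorded as ``external-<dim>``.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty fingerprint table")
    header = lines[0].split("\t")
    width = len(header)
    if width < 2:
        raise FormatError(f"{path}: header must have drug_id plus at least one bit column")
    dim = width - 1
    scheme = f"external-{dim}"
    vectors = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != width:
            raise FormatError(
                f"{path}: row {lineno} has {len(parts) - 1} bit columns, expected {dim}"
            )
        try:
            bits = np.array([int(v) for v in parts[1:]], dtype=np.int64)
        except ValueError:
            raise FormatError(f"{path}: row {lineno} has a non-integer entry") from None
        if not np.isin(bits, (0, 1)).all():
            raise FormatError(f"{path}: row {lineno} has a non-binary entry")
        vectors.append(FingerprintVector(parts[0], bits.astype(np.uint8), scheme))
    return vectors


def write_fingerprint_table(
    vectors: Sequence[FingerprintVector], path: str | Path
) -> None:
    """Write fingerprints in the TSV dialect read by :func:`load_fingerprint_table`."""
    if not vectors:
        raise ValueError("nothing to write")
    dim = len(vectors[0])
    with open(path, "w") as fh:
        fh.write("drug_id\t" + "\t".join(f"bit{i}" for i in range(dim)) + "\n")
        for v in vectors:
            if len(v) != dim:
                raise ValueError("mixed fingerprint dimensions in one table")
            fh.write(v.drug_id + "\t" + "\t".join(str(int(b)) for b in v.bits) + "\n")
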