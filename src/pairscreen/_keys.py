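"""Definition of the native 881-position substructure-key dictionary.

The dictionary follows the classical layout of substructure-key
fingerprints used in large compound databases: a block of element-count
keys, a block of ring-census keys, a block of bonded element-pair keys,
and a block of three-atom fragment keys.  Key order is fixed at import
time and never depends on the molecule, so bit *n* always means the same
substructure.  Patterns are evaluated with RDKit.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem

DIMENSION = 881

# -- section 1: element counts ------------------------------------------------

_ELEMENT_COUNT_KEYS: list[tuple[str, int]] = [
    ("H", 4), ("H", 8), ("H", 16), ("H", 32),
    ("Li", 1), ("Li", 2),
    ("B", 1), ("B", 2), ("B", 4),
    ("C", 2), ("C", 4), ("C", 8), ("C", 16), ("C", 32),
    ("N", 1), ("N", 2), ("N", 4), ("N", 8),
    ("O", 1), ("O", 2), ("O", 4), ("O", 8), ("O", 16),
    ("F", 1), ("F", 2), ("F", 4),
    ("Na", 1), ("Na", 2),
    ("Si", 1), ("Si", 2),
    ("P", 1), ("P", 2), ("P", 4),
    ("S", 1), ("S", 2), ("S", 4), ("S", 8),
    ("Cl", 1), ("Cl", 2), ("Cl", 4), ("Cl", 8),
    ("K", 1), ("K", 2),
    ("Br", 1), ("Br", 2), ("Br", 4),
    ("I", 1), ("I", 2), ("I", 4),
] + [
    (sym, 1)
    for sym in (
        "Be Mg Al Ca Sc Ti V Cr Mn Fe Co Ni Cu Zn Ga Ge As Se Kr Rb Sr Y Zr "
        "Nb Mo Ru Rh Pd Ag Cd In Sn Sb Te Xe Cs Ba Lu Hf Ta W Re Os Ir Pt "
        "Au Hg Tl Pb Bi"
    ).split()
]

# -- section 2: ring census ---------------------------------------------------
# (size, kind, min_count); size None = any ring size

_RING_KEYS: list[tuple[int | None, str, int]] = (
    [(size, "any", t) for size in range(3, 11) for t in (1, 2)]
    + [(size, "aromatic", 1) for size in range(3, 11)]
    + [(size, kind, t) for size in (5, 6) for kind in ("carbon", "hetero") for t in (1, 2)]
    + [(None, "any", t) for t in range(1, 7)]
    + [(None, "aromatic", t) for t in range(1, 5)]
    + [(None, "hetero", t) for t in range(1, 4)]
    + [(None, "saturated", t) for t in range(1, 3)]
)

# -- sections 3 and 4: bonded pairs and three-atom fragments ------------------

_PAIR_ELEMENTS = ["B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Br", "I"]
_ATOMIC_NUM = {
    "B": 5, "C": 6, "N": 7, "O": 8, "F": 9, "Si": 14, "P": 15, "S": 16,
    "Cl": 17, "Br": 35, "I": 53,
}
_BOND_SYMBOLS = ["~", "-", "=", ":"]


def _pair_smarts() -> list[str]:
    out = []
    for bond in _BOND_SYMBOLS:
        for i, a in enumerate(_PAIR_ELEMENTS):
            for b in _PAIR_ELEMENTS[i:]:
                out.append(f"[#{_ATOMIC_NUM[a]}]{bond}[#{_ATOMIC_NUM[b]}]")
    return out


def _triple_smarts() -> list[str]:
    out = []
    for mid in _PAIR_ELEMENTS:
        for i, a in enumerate(_PAIR_ELEMENTS):
            for b in _PAIR_ELEMENTS[i:]:
                out.append(
                    f"[#{_ATOMIC_NUM[a]}]~[#{_ATOMIC_NUM[mid]}]~[#{_ATOMIC_NUM[b]}]"
                )
    return out


@dataclass(frozen=True)
class _Key:
    kind: str           # "element" | "ring" | "smarts"
    payload: tuple
    label: str


def _build_keys() -> list[_Key]:
    keys: list[_Key] = []
    for sym, t in _ELEMENT_COUNT_KEYS:
        keys.append(_Key("element", (sym, t), f"count({sym})>={t}"))
    for size, kind, t in _RING_KEYS:
        keys.append(_Key("ring", (size, kind, t), f"rings(size={size},{kind})>={t}"))
    for sma in _pair_smarts():
        keys.append(_Key("smarts", (sma,), sma))
    need = DIMENSION - len(keys)
    triples = _triple_smarts()
    if not 0 <= need <= len(triples):
        raise AssertionError("key dictionary layout does not reach the target dimension")
    for sma in triples[:need]:
        keys.append(_Key("smarts", (sma,), sma))
    return keys


KEYS: list[_Key] = _build_keys()
assert len(KEYS) == DIMENSION

_SMARTS_CACHE: dict[str, Chem.Mol] = {}


def _query(sma: str) -> Chem.Mol:
    q = _SMARTS_CACHE.get(sma)
    if q is None:
        q = Chem.MolFromSmarts(sma)
        if q is None:  # pragma: no cover - dictionary is static and valid
            raise AssertionError(f"invalid SMARTS in key dictionary: {sma}")
        _SMARTS_CACHE[sma] = q
    return q


def _element_count(mol: Chem.Mol, symbol: str) -> int:
    if symbol == "H":
        return sum(a.GetTotalNumHs(includeNeighbors=True) for a in mol.GetAtoms()
                   if a.GetSymbol() != "H") + sum(
            1 for a in mol.GetAtoms() if a.GetSymbol() == "H")
    return sum(1 for a in mol.GetAtoms() if a.GetSymbol() == symbol)


def _ring_count(mol: Chem.Mol, size: int | None, kind: str) -> int:
    info = mol.GetRingInfo()
    n = 0
    for ring in info.AtomRings():
        if size is not None and len(ring) != size:
            continue
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        aromatic = all(a.GetIsAromatic() for a in atoms)
        carbon_only = all(a.GetSymbol() == "C" for a in atoms)
        if kind == "aromatic" and not aromatic:
            continue
        if kind == "carbon" and not carbon_only:
            continue
        if kind == "hetero" and carbon_only:
            continue
        if kind == "saturated" and aromatic:
            continue
        n += 1
    return n


def evaluate_key(mol: Chem.Mol, key: _Key) -> int:
    """Return 1 if the molecule sets this key, else 0."""
    if key.kind == "element":
        sym, t = key.payload
        return int(_element_count(mol, sym) >= t)
    if key.kind == "ring":
        size, kind, t = key.payload
        return int(_ring_count(mol, size, kind) >= t)
    (sma,) = key.payload
    return int(mol.HasSubstructMatch(_query(sma)))


def key_index(label: str) -> int:
    """Position of a key by its label (e.g. the SMARTS ``[#6]-[#8]``)."""
    for i, k in enumerate(KEYS):
        if k.label == label:
            return i
    raise KeyError(label)
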