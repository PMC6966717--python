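"""Benchmark construction: positives, sampled negatives, splits, winnowing.

Positives come from a curated chemical-disease association table in the
CTD dialect, keeping only rows whose direct-evidence field contains
"therapeutic" and whose chemical name is not a drug combination.
Negatives are sampled from the bipartite complement of the *full*
catalog (any evidence annotation) restricted to drugs and diseases that
occur in the positives, so no pair with any curated evidence can be
mislabeled as a negative.  Splits cover the three evaluation regimes:
stratified random, disease-disjoint and drug-disjoint (cold start), plus
greedy redundancy winnowing at a pair-similarity threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import math

import numpy as np

from .exceptions import CapacityError, DegenerateSplitError, FormatError
from .similarity import cosine, jaccard

POSITIVE = 1
NEGATIVE = 0

_CTD_COLUMNS = {
    "chemical_name": "ChemicalName",
    "chemical_id": "ChemicalID",
    "disease_id": "DiseaseID",
    "direct_evidence": "DirectEvidence",
}


@dataclass(frozen=True, order=True)
class AssociationRecord:
    drug_id: str
    disease_id: str
    label: int
    provenance: str  # "curated" | "sampled"

    def __post_init__(self) -> None:
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        if self.provenance not in ("curated", "sampled"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.provenance == "curated" and self.label != POSITIVE:
            raise ValueError("curated records must be positive")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.drug_id, self.disease_id)


class AssociationCatalog:
    """Exact membership index over every pair with ANY evidence annotation."""

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        self._pairs = frozenset(tuple(p) for p in pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(pair) in self._pairs

    def __len__(self) -> int:
        return len(self._pairs)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self._pairs)


@dataclass
class AssociationDataset:
    records: list[AssociationRecord]

    def __post_init__(self) -> None:
        pairs = [r.pair for r in self.records]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (drug, disease) pair in dataset")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AssociationRecord]:
        return iter(self.records)

    @property
    def positives(self) -> list[AssociationRecord]:
        return [r for r in self.records if r.label == POSITIVE]

    @property
    def negatives(self) -> list[AssociationRecord]:
        return [r for r in self.records if r.label == NEGATIVE]

    def drugs(self) -> list[str]:
        return sorted({r.drug_id for r in self.records})

    def diseases(self) -> list[str]:
        return sorted({r.disease_id for r in self.records})

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("drug_id\tdisease_id\tlabel\tprovenance\n")
            for r in self.records:
                fh.write(f"{r.drug_id}\t{r.disease_id}\t{r.label}\t{r.provenance}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AssociationDataset":
        lines = Path(path).read_text().splitlines()
        if not lines or lines[0].split("\t") != ["drug_id", "disease_id", "label", "provenance"]:
            raise FormatError(f"{path}: bad dataset header")
        records = []
        for lineno, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}: row {lineno} has {len(parts)} fields, expected 4")
            records.append(AssociationRecord(parts[0], parts[1], int(parts[2]), parts[3]))
        return cls(records)


@dataclass
class DatasetSplit:
    train: list[AssociationRecord]
    test: list[AssociationRecord]
    strategy: str  # "random" | "disease_disjoint" | "drug_disjoint"
    seed: int

    def __post_init__(self) -> None:
        train_pairs = {r.pair for r in self.train}
        test_pairs = {r.pair for r in self.test}
        if train_pairs & test_pairs:
            raise ValueError("train and test share (drug, disease) pairs")

    def manifest(self) -> dict:
        return {
            "strategy": self.strategy,
            "seed": self.seed,
            "train_ids": [[r.drug_id, r.disease_id] for r in self.train],
            "test_ids": [[r.drug_id, r.disease_id] for r in self.test],
        }

    def save_manifest(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.manifest()))


# -- CTD-style input ----------------------------------------------------------

def read_ctd_associations(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> tuple[list[AssociationRecord], AssociationCatalog]:
    """Read a CTD-style association TSV into (positives, full catalog).

    A row is a positive when its direct-evidence field contains
    "therapeutic" (case-insensitive) and its chemical name does not
    contain "drug combination".  The catalog holds every row regardless
    of evidence.  Leading '#' comment lines are tolerated; the header may
    itself start with '#'.
    """
    cols = dict(_CTD_COLUMNS)
    if column_map:
        cols.update(column_map)
    required = [cols[k] for k in ("chemical_name", "chemical_id", "disease_id", "direct_evidence")]

    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    header: list[str] | None = None
    data_start = 0
    for i, line in enumerate(lines):
        fields = line.lstrip("#").strip().split("\t")
        if all(c in fields for c in required):
            header, data_start = fields, i + 1
            break
        if not line.startswith("#"):
            missing = [c for c in required if c not in fields]
            raise FormatError(f"{path}: missing required column(s) {missing}")
    if header is None:
        raise FormatError(f"{path}: no header row with columns {required}")

    idx = {c: header.index(c) for c in required}
    name_i, chem_i, dis_i, ev_i = (idx[c] for c in required)

    positives: list[AssociationRecord] = []
    seen_pos: set[tuple[str, str]] = set()
    catalog_pairs: set[tuple[str, str]] = set()
    for lineno, line in enumerate(lines[data_start:], start=data_start + 1):
        if line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < len(header):
            parts = parts + [""] * (len(header) - len(parts))
        name, chem, dis, ev = parts[name_i], parts[chem_i], parts[dis_i], parts[ev_i]
        pair = (chem, dis)
        catalog_pairs.add(pair)
        if "therapeutic" in ev.lower() and "drug combination" not in name.lower():
            if pair not in seen_pos:
                seen_pos.add(pair)
                positives.append(AssociationRecord(chem, dis, POSITIVE, "curated"))
    return positives, AssociationCatalog(catalog_pairs)


# -- negative sampling and ratio datasets -------------------------------------

def sample_negatives(
    positives: Sequence[AssociationRecord],
    catalog: AssociationCatalog,
    n: int,
    seed: int,
) -> list[AssociationRecord]:
    """Draw n unique negatives from the complement of the catalog.

    Drugs and diseases are taken only from those appearing in positives;
    any pair present in the catalog (any evidence) is excluded.  Sampling
    is without replacement and a pure function of (inputs, seed).
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    drugs = sorted({r.drug_id for r in positives})
    diseases = sorted({r.disease_id for r in positives})
    in_grid = sum(1 for d in drugs for s in diseases if (d, s) in catalog)
    capacity = len(drugs) * len(diseases) - in_grid
    if n > capacity:
        raise CapacityError(
            f"requested {n} negatives but the catalog complement holds only {capacity}"
        )
    rng = np.random.default_rng(seed)
    grid = len(drugs) * len(diseases)
    out: list[AssociationRecord] = []
    if grid <= 250_000:
        complement = [
            (d, s) for d in drugs for s in diseases if (d, s) not in catalog
        ]
        order = rng.permutation(len(complement))[:n]
        for k in order:
            d, s = complement[k]
            out.append(AssociationRecord(d, s, NEGATIVE, "sampled"))
    else:  # rejection sampling; duplicates are redrawn
        chosen: set[tuple[str, str]] = set()
        while len(out) < n:
            d = drugs[int(rng.integers(len(drugs)))]
            s = diseases[int(rng.integers(len(diseases)))]
            if (d, s) in catalog or (d, s) in chosen:
                continue
            chosen.add((d, s))
            out.append(AssociationRecord(d, s, NEGATIVE, "sampled"))
    return out


def build_ratio_dataset(
    positives: Sequence[AssociationRecord],
    catalog: AssociationCatalog,
    ratio: int,
    seed: int,
) -> AssociationDataset:
    """Benchmark with |negatives| = ratio x |positives| (ratio 1 = 1:1)."""
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    negatives = sample_negatives(positives, catalog, ratio * len(positives), seed)
    return AssociationDataset(list(positives) + negatives)


# -- splits -------------------------------------------------------------------

def random_split(
    dataset: AssociationDataset, train_fraction: float, seed: int
) -> DatasetSplit:
    """Label-stratified random split; floor(train_fraction * n) per label."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train: list[AssociationRecord] = []
    test: list[AssociationRecord] = []
    for group in (dataset.positives, dataset.negatives):
        if not group:
            continue
        order = rng.permutation(len(group))
        n_train = int(math.floor(train_fraction * len(group)))
        train.extend(group[i] for i in order[:n_train])
        test.extend(group[i] for i in order[n_train:])
    if not train or not test:
        raise DegenerateSplitError(
            f"split of {len(dataset)} records at fraction {train_fraction} "
            "leaves an empty side"
        )
    return DatasetSplit(train, test, "random", seed)


def entity_disjoint_split(
    dataset: AssociationDataset,
    entity: str,
    train_fraction: float,
    seed: int,
) -> DatasetSplit:
    """Cold-start split: no disease (or drug) appears on both sides.

    Step-by-step accretion: repeatedly pick a random uncommitted entity
    and commit every record (positive and negative) containing it to the
    training side, until the training side holds at least
    ``train_fraction`` of all records; everything else is test.  Both
    labels are committed in the same pass so the disjointness guarantee
    holds for the whole split, and the stop rule may overshoot the target
    by at most the largest entity's share.
    """
    if entity not in ("disease", "drug"):
        raise ValueError("entity must be 'disease' or 'drug'")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    key = (lambda r: r.disease_id) if entity == "disease" else (lambda r: r.drug_id)
    groups: dict[str, list[AssociationRecord]] = {}
    for r in dataset.records:
        groups.setdefault(key(r), []).append(r)
    if len(groups) < 2:
        raise DegenerateSplitError(f"need >= 2 distinct {entity}s, found {len(groups)}")
    total = len(dataset)
    target = train_fraction * total
    largest = max(len(g) for g in groups.values())
    if largest > target:
        raise DegenerateSplitError(
            f"one {entity} owns {largest}/{total} records, more than the "
            f"train target of {train_fraction:.2f}"
        )
    rng = np.random.default_rng(seed)
    uncommitted = sorted(groups)
    train: list[AssociationRecord] = []
    while len(train) < target:
        pick = uncommitted.pop(int(rng.integers(len(uncommitted))))
        train.extend(groups[pick])
    test = [r for e in uncommitted for r in groups[e]]
    if not test:
        raise DegenerateSplitError("accretion consumed every entity; empty test side")
    strategy = "disease_disjoint" if entity == "disease" else "drug_disjoint"
    return DatasetSplit(train, test, strategy, seed)


# -- redundancy winnowing ------------------------------------------------------

def winnow_redundant(
    dataset: AssociationDataset,
    threshold: float,
    featurizer: Callable[[AssociationRecord], tuple[np.ndarray, np.ndarray]],
    seed: int,
) -> AssociationDataset:
    """Greedy non-redundant subset at a pair-similarity threshold.

    Records are visited in a seed-shuffled order; a record is retained
    iff its pair similarity (mean of drug Jaccard and disease cosine) to
    every already-retained record is <= threshold.  The retained set
    therefore contains no pair of records more similar than the
    threshold.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    records = dataset.records
    feats = [featurizer(r) for r in records]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    retained_idx: list[int] = []
    for i in order:
        fi, di = feats[i]
        ok = True
        for j in retained_idx:
            fj, dj = feats[j]
            sim = 0.5 * (jaccard(fi, fj) + cosine(di, dj))
            if sim > threshold:
                ok = False
                break
        if ok:
            retained_idx.append(int(i))
    keep = set(retained_idx)
    return AssociationDataset([r for k, r in enumerate(records) if k in keep])


# -- screening helpers ---------------------------------------------------------

def lipinski_filter(props: Mapping[str, float]) -> bool:
    """Rule-of-five drug-likeness: MW<500 Da, HBD<5, HBA<10, logP<5 (strict)."""
    values = {}
    for name in ("MW", "HBD", "HBA", "logP"):
        if name not in props:
            raise ValueError(f"missing molecular property {name!r}")
        v = float(props[name])
        if not math.isfinite(v):
            raise ValueError(f"molecular property {name!r} is not finite")
        values[name] = v
    return (
        values["MW"] < 500
        and values["HBD"] < 5
        and values["HBA"] < 10
        and values["logP"] < 5
    )


def enumerate_candidates(
    drugs: Iterable[str],
    diseases: Iterable[str],
    catalog: AssociationCatalog,
) -> Iterator[tuple[str, str]]:
    """Yield every (drug, disease) pair absent from the catalog, once,
    in lexicographic order."""
    for d in sorted(set(drugs)):
        for s in sorted(set(diseases)):
            if (d, s) not in catalog:
                yield (d, s)
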