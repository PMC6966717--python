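import itertools

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import Descriptors, Lipinski

from pairscreen import (
    AssociationCatalog,
    AssociationDataset,
    AssociationRecord,
    build_ratio_dataset,
    entity_disjoint_split,
    enumerate_candidates,
    lipinski_filter,
    pair_similarity,
    random_split,
    read_ctd_associations,
    sample_negatives,
    winnow_redundant,
)
from pairscreen.exceptions import CapacityError, DegenerateSplitError, FormatError

CTD_HEADER = "# ChemicalName\tChemicalID\tDiseaseID\tDirectEvidence\n"
CTD_TOY = CTD_HEADER + (
    "aspirin\tC01\tD001\ttherapeutic\n"
    "ibuprofen\tC02\tD002\ttherapeutic\n"
    "x/y drug combination\tC03\tD003\ttherapeutic\n"
    "caffeine\tC04\tD004\tmarker/mechanism\n"
    "codeine\tC05\tD005\ttherapeutic|marker/mechanism\n"
)


def positives_of(n=4, m=4):
    return [
        AssociationRecord(f"d{i}", f"s{j}", 1, "curated")
        for i in range(n)
        for j in range(m)
        if (i + j) % 2 == 0
    ]


def test_ctd_toy_filtering(tmp_path):
    path = tmp_path / "ctd.tsv"
    path.write_text(CTD_TOY)
    positives, catalog = read_ctd_associations(path)
    # drug-combination and marker-only rows are excluded from positives,
    # compound evidence containing "therapeutic" is included
    assert {r.drug_id for r in positives} == {"C01", "C02", "C05"}
    assert all(r.label == 1 and r.provenance == "curated" for r in positives)
    assert len(catalog) == 5
    assert ("C04", "D004") in catalog


def test_ctd_empty_file_with_header(tmp_path):
    path = tmp_path / "ctd.tsv"
    path.write_text(CTD_HEADER)
    positives, catalog = read_ctd_associations(path)
    assert positives == [] and len(catalog) == 0


def test_ctd_missing_column_is_named(tmp_path):
    path = tmp_path / "ctd.tsv"
    path.write_text("ChemicalName\tChemicalID\tDiseaseID\nx\tC1\tD1\n")
    with pytest.raises(FormatError, match="DirectEvidence"):
        read_ctd_associations(path)


def test_sample_negatives_exhaustive_two_by_two():
    positives = [
        AssociationRecord("d1", "s1", 1, "curated"),
        AssociationRecord("d2", "s2", 1, "curated"),
    ]
    catalog = AssociationCatalog([("d1", "s1"), ("d2", "s2")])
    negatives = sample_negatives(positives, catalog, 2, seed=0)
    assert {r.pair for r in negatives} == {("d1", "s2"), ("d2", "s1")}
    assert all(r.label == 0 and r.provenance == "sampled" for r in negatives)
    assert sample_negatives(positives, catalog, 0, seed=0) == []
    with pytest.raises(CapacityError):
        sample_negatives(positives, catalog, 3, seed=0)


@pytest.mark.parametrize("seed", range(5))
def test_sampled_negatives_never_intersect_catalog(seed):
    positives = positives_of()
    catalog = AssociationCatalog([r.pair for r in positives])
    negatives = sample_negatives(positives, catalog, 6, seed=seed)
    assert len({r.pair for r in negatives}) == 6
    assert all(r.pair not in catalog for r in negatives)
    # pure function of (inputs, seed)
    again = sample_negatives(positives, catalog, 6, seed=seed)
    assert [r.pair for r in again] == [r.pair for r in negatives]


def test_ratio_dataset_counts():
    positives = [AssociationRecord(f"d{i}", f"s{i}", 1, "curated") for i in range(10)]
    catalog = AssociationCatalog([r.pair for r in positives])
    ds = build_ratio_dataset(positives, catalog, ratio=3, seed=1)
    assert len(ds) == 40 and len(ds.positives) == 10
    assert len(build_ratio_dataset(positives, catalog, 1, seed=1)) == 20


def test_random_split_stratified_counts_and_determinism():
    records = [AssociationRecord(f"d{i}", "s0", 1, "curated") for i in range(8)] + [
        AssociationRecord(f"d{i}", "s1", 0, "sampled") for i in range(8)
    ]
    ds = AssociationDataset(records)
    split = random_split(ds, 0.75, seed=3)
    assert sum(r.label for r in split.train) == 6
    assert sum(1 - r.label for r in split.train) == 6
    assert len(split.test) == 4
    assert {r.pair for r in split.train}.isdisjoint({r.pair for r in split.test})
    split2 = random_split(ds, 0.75, seed=3)
    assert [r.pair for r in split2.train] == [r.pair for r in split.train]


def test_random_split_floor_rule():
    records = [AssociationRecord(f"d{i}", "s0", 1, "curated") for i in range(7)] + [
        AssociationRecord(f"d{i}", "s1", 0, "sampled") for i in range(5)
    ]
    split = random_split(AssociationDataset(records), 0.6, seed=0)
    assert sum(r.label for r in split.train) == 4      # floor(0.6 * 7)
    assert sum(1 - r.label for r in split.train) == 3  # floor(0.6 * 5)


def test_entity_disjoint_three_disease_enumeration():
    records = [
        AssociationRecord(f"d{i}", f"s{j}", j % 2, "curated" if j % 2 else "sampled")
        for j in range(3)
        for i in range(2)
    ]
    split = entity_disjoint_split(AssociationDataset(records), "disease", 2 / 3, seed=5)
    train_dis = {r.disease_id for r in split.train}
    test_dis = {r.disease_id for r in split.test}
    assert len(train_dis) == 2 and len(test_dis) == 1
    assert train_dis.isdisjoint(test_dis)


@pytest.mark.parametrize("entity", ["disease", "drug"])
@pytest.mark.parametrize("seed", range(10))
def test_entity_disjoint_invariants_on_random_worlds(entity, seed):
    rng = np.random.default_rng(seed)
    pairs = {
        (f"d{rng.integers(6)}", f"s{rng.integers(6)}") for _ in range(25)
    }
    records = [
        AssociationRecord(a, b, int(rng.random() < 0.5) and 1, "sampled")
        for a, b in sorted(pairs)
    ]
    records = [
        AssociationRecord(r.drug_id, r.disease_id, r.label,
                          "curated" if r.label else "sampled")
        for r in records
    ]
    ds = AssociationDataset(records)
    try:
        split = entity_disjoint_split(ds, entity, 0.75, seed=seed)
    except DegenerateSplitError:
        return
    key = (lambda r: r.disease_id) if entity == "disease" else (lambda r: r.drug_id)
    assert {key(r) for r in split.train}.isdisjoint({key(r) for r in split.test})
    assert {r.pair for r in split.train}.isdisjoint({r.pair for r in split.test})
    # accretion overshoot bound: train fraction < target + largest entity share
    groups = {}
    for r in ds:
        groups.setdefault(key(r), []).append(r)
    max_share = max(len(g) for g in groups.values()) / len(ds)
    frac = len(split.train) / len(ds)
    assert 0.75 <= frac < 0.75 + max_share + 1e-12


def test_entity_disjoint_degenerate_when_one_entity_dominates():
    records = [AssociationRecord(f"d{i}", "s0", 1, "curated") for i in range(9)] + [
        AssociationRecord("d9", "s1", 1, "curated")
    ]
    with pytest.raises(DegenerateSplitError):
        entity_disjoint_split(AssociationDataset(records), "disease", 0.5, seed=0)


def _featurizer_for(world):
    source = world.pair_source()

    def featurizer(record):
        return (
            source.fingerprints[record.drug_id].bits,
            source.symptoms[record.disease_id].weights,
        )

    return featurizer


def test_winnow_removes_feature_identical_pairs():
    # two records with identical features (similarity 1 > 0.9): one survives
    bits = {"d0": np.array([1, 0, 1, 1]), "d1": np.array([0, 1, 0, 0])}
    weights = {"s0": np.array([1.0, 2.0]), "s1": np.array([1.0, 2.0]),
               "s2": np.array([3.0, 0.0])}

    def featurizer(record):
        return bits[record.drug_id], weights[record.disease_id]

    records = [
        AssociationRecord("d0", "s0", 1, "curated"),
        AssociationRecord("d0", "s1", 1, "curated"),  # identical features to (d0, s0)
        AssociationRecord("d1", "s2", 0, "sampled"),
    ]
    ds = AssociationDataset(records)
    out = winnow_redundant(ds, 0.9, featurizer, seed=0)
    assert len(out) == 2
    assert sum(1 for r in out if r.drug_id == "d0") == 1
    for a, b in itertools.combinations(out.records, 2):
        assert pair_similarity(featurizer(a), featurizer(b)) <= 0.9


def test_winnow_keeps_everything_below_threshold(toy_world):
    featurizer = _featurizer_for(toy_world)
    records = [
        AssociationRecord(toy_world.drug_ids[0], toy_world.disease_ids[0], 1, "curated"),
        AssociationRecord(toy_world.drug_ids[1], toy_world.disease_ids[1], 1, "curated"),
    ]
    ds = AssociationDataset(records)
    out = winnow_redundant(ds, 1.0, featurizer, seed=0)
    assert len(out) == len(ds)


@pytest.mark.parametrize("seed", range(3))
def test_winnow_soundness_brute_force(toy_world, seed):
    featurizer = _featurizer_for(toy_world)
    rng = np.random.default_rng(seed)
    pairs = sorted(
        {(d, s) for d in toy_world.drug_ids for s in toy_world.disease_ids}
    )
    chosen = [pairs[i] for i in rng.permutation(len(pairs))[:30]]
    ds = AssociationDataset(
        [AssociationRecord(a, b, 1, "curated") for a, b in chosen]
    )
    out = winnow_redundant(ds, 0.6, featurizer, seed=seed)
    feats = {r.pair: featurizer(r) for r in ds}
    for a, b in itertools.combinations(out.records, 2):
        assert pair_similarity(feats[a.pair], feats[b.pair]) <= 0.6


def test_lipinski_rule_examples():
    assert lipinski_filter({"MW": 600, "HBD": 1, "HBA": 2, "logP": 1}) is False
    assert lipinski_filter({"MW": 180.2, "HBD": 1, "HBA": 4, "logP": 1.3}) is True
    # strict boundaries as printed
    assert lipinski_filter({"MW": 500, "HBD": 4, "HBA": 9, "logP": 4.9}) is False
    assert lipinski_filter({"MW": 499.9, "HBD": 5, "HBA": 9, "logP": 4.9}) is False
    assert lipinski_filter({"MW": 499.9, "HBD": 4, "HBA": 10, "logP": 4.9}) is False
    assert lipinski_filter({"MW": 499.9, "HBD": 4, "HBA": 9, "logP": 5.0}) is False
    with pytest.raises(ValueError, match="logP"):
        lipinski_filter({"MW": 100, "HBD": 1, "HBA": 1})


def test_lipinski_against_rdkit_descriptor_oracle():
    mol = Chem.MolFromSmiles("CC(=O)Oc1ccccc1C(=O)O")  # aspirin
    props = {
        "MW": Descriptors.MolWt(mol),
        "HBD": Lipinski.NumHDonors(mol),
        "HBA": Lipinski.NumHAcceptors(mol),
        "logP": Descriptors.MolLogP(mol),
    }
    assert lipinski_filter(props) is True


def test_enumerate_candidates_counts_and_set_oracle():
    drugs = ["d1", "d2", "d3"]
    diseases = ["s1", "s2", "s3", "s4"]
    catalog = AssociationCatalog([("d1", "s1"), ("d3", "s4")])
    out = list(enumerate_candidates(drugs, diseases, catalog))
    assert len(out) == 10
    expected = set(itertools.product(drugs, diseases)) - {("d1", "s1"), ("d3", "s4")}
    assert set(out) == expected
    assert out == sorted(out)
    assert len(list(enumerate_candidates(drugs, diseases, AssociationCatalog([])))) == 12


def test_dataset_tsv_round_trip(tmp_path):
    ds = AssociationDataset(positives_of())
    path = tmp_path / "ds.tsv"
    ds.to_tsv(path)
    loaded = AssociationDataset.from_tsv(path)
    assert loaded.records == ds.records


def test_dataset_rejects_duplicate_pairs():
    rec = AssociationRecord("d", "s", 1, "curated")
    with pytest.raises(ValueError):
        AssociationDataset([rec, rec])


def test_curated_records_must_be_positive():
    with pytest.raises(ValueError):
        AssociationRecord("d", "s", 0, "curated")
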