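"""Seeded synthetic worlds with planted drug-disease association structure.

The generator emulates the statistical shape of the real inputs: sparse
binary fingerprints for drugs, sparse non-negative symptom co-occurrence
counts for diseases, and a planted association rule.  Drugs and diseases
share a set of latent clusters; each cluster owns a template fingerprint
and a template symptom profile, members are noisy copies of their
templates, and a (drug, disease) pair is a ground-truth positive exactly
when the two entities belong to the same cluster.  The planted signal
therefore flows through the very channels the classifier uses —
fingerprint bits and symptom weights — so end-to-end success is a test
of the whole pipeline rather than of memorization.

Default dimensions are desk-scale (64 bits x 32 symptoms) so a full
train/evaluate cycle stays fast on one CPU; full-shape (881 x 322)
worlds are for shape and forward-pass checks only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datasets import (
    AssociationCatalog,
    AssociationDataset,
    AssociationRecord,
    NEGATIVE,
    POSITIVE,
)
from .classifier import PairSource
from .fingerprints import FingerprintVector, write_fingerprint_table
from .network import NetworkConfig
from .pairimage import dataset_scale
from .symptoms import (
    CooccurrenceTable,
    SymptomVector,
    SymptomVocabulary,
    tfidf_symptom_vectors,
    write_cooccurrence_table,
)
from .exceptions import CapacityError


@dataclass(frozen=True)
class SyntheticConfig:
    n_drugs: int = 48
    n_diseases: int = 48
    n_bits: int = 64
    n_symptoms: int = 32
    bit_density: float = 0.3
    symptom_sparsity: float = 0.35
    n_clusters: int = 2
    max_count: int = 5           # co-occurrence counts drawn uniformly from 1..max_count
    feature_noise: float = 0.02  # per-element template corruption probability
    noise: float = 0.0           # label-flip probability epsilon
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.bit_density < 1:
            raise ValueError("bit_density must be in (0, 1)")
        if not 0 < self.symptom_sparsity < 1:
            raise ValueError("symptom_sparsity must be in (0, 1)")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if not 0 <= self.noise < 0.5:
            raise ValueError("label noise must satisfy 0 <= eps < 0.5 to stay informative")
        if not 0 <= self.feature_noise < 0.5:
            raise ValueError("feature_noise >= 0.5 erases the within/between similarity gap")
        if self.max_count < 1:
            raise ValueError("max_count must be >= 1")


@dataclass
class SyntheticWorld:
    config: SyntheticConfig
    fingerprints: dict[str, FingerprintVector]
    cooccurrence: CooccurrenceTable
    drug_clusters: dict[str, int]
    disease_clusters: dict[str, int]

    @property
    def drug_ids(self) -> list[str]:
        return list(self.fingerprints)

    @property
    def disease_ids(self) -> list[str]:
        return list(self.cooccurrence.disease_ids)

    def is_positive(self, drug_id: str, disease_id: str) -> bool:
        return self.drug_clusters[drug_id] == self.disease_clusters[disease_id]

    def true_pairs(self, positive: bool) -> list[tuple[str, str]]:
        return [
            (d, s)
            for d in self.drug_ids
            for s in self.disease_ids
            if self.is_positive(d, s) == positive
        ]

    def symptom_vectors(self) -> list[SymptomVector]:
        return tfidf_symptom_vectors(self.cooccurrence)

    def pair_source(self) -> PairSource:
        vectors = self.symptom_vectors()
        return PairSource(
            dict(self.fingerprints),
            {v.disease_id: v for v in vectors},
            dataset_scale(vectors),
        )

    def export(self, directory: str | Path) -> None:
        """Write the world in the exact dialects the real pipeline reads."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_fingerprint_table(
            list(self.fingerprints.values()), directory / "fingerprints.tsv"
        )
        write_cooccurrence_table(self.cooccurrence, directory / "cooccurrence.tsv")
        with open(directory / "associations.tsv", "w") as fh:
            fh.write("ChemicalName\tChemicalID\tDiseaseID\tDirectEvidence\n")
            for d, s in self.true_pairs(positive=True):
                fh.write(f"{d}\t{d}\t{s}\ttherapeutic\n")


def _template_fingerprint(rng, n_bits: int, density: float) -> np.ndarray:
    while True:
        bits = (rng.random(n_bits) < density).astype(np.uint8)
        if bits.any():
            return bits


def _template_symptoms(rng, n_symptoms: int, sparsity: float, max_count: int) -> np.ndarray:
    while True:
        mask = rng.random(n_symptoms) < sparsity
        counts = np.where(mask, rng.integers(1, max_count + 1, size=n_symptoms), 0)
        if counts.any():
            return counts.astype(np.int64)


def generate_world(config: SyntheticConfig) -> SyntheticWorld:
    """Draw a world from the config; deterministic for a given seed.

    Raises ``ValueError`` when the realized within-cluster mean pair
    similarity does not exceed the between-cluster mean (the planted
    signal would be absent).
    """
    rng = np.random.default_rng(config.seed)
    fp_templates: list[np.ndarray] = []
    sy_templates: list[np.ndarray] = []
    for _c in range(config.n_clusters):
        while True:
            t = _template_fingerprint(rng, config.n_bits, config.bit_density)
            if not any(np.array_equal(t, u) for u in fp_templates):
                break
        fp_templates.append(t)
        while True:
            t = _template_symptoms(rng, config.n_symptoms, config.symptom_sparsity,
                                   config.max_count)
            if not any(np.array_equal(t, u) for u in sy_templates):
                break
        sy_templates.append(t)

    scheme = f"synthetic-{config.n_bits}"
    fingerprints: dict[str, FingerprintVector] = {}
    drug_clusters: dict[str, int] = {}
    for i in range(config.n_drugs):
        cluster = i % config.n_clusters
        flips = rng.random(config.n_bits) < config.feature_noise
        bits = np.where(flips, 1 - fp_templates[cluster], fp_templates[cluster])
        drug_id = f"DR{i:04d}"
        fingerprints[drug_id] = FingerprintVector(drug_id, bits.astype(np.uint8), scheme)
        drug_clusters[drug_id] = cluster

    disease_ids: list[str] = []
    disease_clusters: dict[str, int] = {}
    counts = np.zeros((config.n_diseases, config.n_symptoms), dtype=np.int64)
    for j in range(config.n_diseases):
        cluster = j % config.n_clusters
        row = sy_templates[cluster].copy()
        redraw = rng.random(config.n_symptoms) < config.feature_noise
        fresh = _template_symptoms(rng, config.n_symptoms, config.symptom_sparsity,
                                   config.max_count)
        row = np.where(redraw, fresh, row)
        if not row.any():
            support = np.flatnonzero(sy_templates[cluster])
            row[support[0]] = sy_templates[cluster][support[0]]
        disease_id = f"DI{j:04d}"
        disease_ids.append(disease_id)
        disease_clusters[disease_id] = cluster
        counts[j] = row

    world = SyntheticWorld(
        config=config,
        fingerprints=fingerprints,
        cooccurrence=CooccurrenceTable(
            tuple(disease_ids),
            SymptomVocabulary(tuple(f"S{m:03d}" for m in range(config.n_symptoms))),
            counts,
        ),
        drug_clusters=drug_clusters,
        disease_clusters=disease_clusters,
    )
    if config.n_clusters > 1:
        within, between = similarity_gap(world)
        if within <= between:
            raise ValueError(
                f"configuration yields no within/between similarity gap "
                f"({within:.4f} <= {between:.4f})"
            )
    return world


def similarity_gap(world: SyntheticWorld) -> tuple[float, float]:
    """Mean pair similarity of same-cluster vs different-cluster associations.

    Averaging over associations whose drug and disease are drawn
    independently, the mean pair similarity decomposes into the mean of
    the drug-Jaccard and disease-cosine components, computed here
    exhaustively over all entity pairs.
    """
    from .similarity import cosine, jaccard

    fps = list(world.fingerprints.values())
    drugs_c = [world.drug_clusters[f.drug_id] for f in fps]
    vecs = world.symptom_vectors()
    dis_c = [world.disease_clusters[v.disease_id] for v in vecs]

    def grouped_means(items, clusters, sim):
        within, between = [], []
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                (within if clusters[i] == clusters[j] else between).append(
                    sim(items[i], items[j])
                )
        return np.mean(within), np.mean(between)
    jw, jb = grouped_means(fps, drugs_c, jaccard)
    cw, cb = grouped_means(vecs, dis_c, cosine)
    return 0.5 * (jw + cw), 0.5 * (jb + cb)


def generate_labeled_dataset(
    world: SyntheticWorld,
    n_pos: int,
    ratio: int = 1,
    noise: float | None = None,
    seed: int = 0,
) -> tuple[AssociationDataset, dict[tuple[str, str], int]]:
    """Sample a labeled dataset plus its ground truth.

    ``n_pos`` ground-truth positives and ``ratio * n_pos`` ground-truth
    negatives are drawn without replacement; each observed label is then
    flipped independently with probability ``noise`` (default: the
    world's configured epsilon).  Returns (dataset, truth) where truth
    maps each sampled pair to its ground-truth label, so noise handling
    is itself testable.
    """
    eps = world.config.noise if noise is None else noise
    if not 0 <= eps < 0.5:
        raise ValueError("label noise must satisfy 0 <= eps < 0.5")
    rng = np.random.default_rng(seed)
    pos = world.true_pairs(positive=True)
    neg = world.true_pairs(positive=False)
    n_neg = ratio * n_pos
    if n_pos > len(pos):
        raise CapacityError(f"world has {len(pos)} true positives, asked for {n_pos}")
    if n_neg > len(neg):
        raise CapacityError(f"world has {len(neg)} true negatives, asked for {n_neg}")
    chosen_pos = [pos[i] for i in rng.permutation(len(pos))[:n_pos]]
    chosen_neg = [neg[i] for i in rng.permutation(len(neg))[:n_neg]]
    records: list[AssociationRecord] = []
    truth: dict[tuple[str, str], int] = {}
    for pair, true_label in [(p, POSITIVE) for p in chosen_pos] + [
        (p, NEGATIVE) for p in chosen_neg
    ]:
        observed = true_label
        if eps > 0 and rng.random() < eps:
            observed = 1 - observed
        provenance = "curated" if observed == POSITIVE else "sampled"
        records.append(AssociationRecord(pair[0], pair[1], observed, provenance))
        truth[pair] = true_label
    return AssociationDataset(records), truth


def world_catalog(world: SyntheticWorld) -> AssociationCatalog:
    """Catalog holding every ground-truth positive pair (the 'known file')."""
    return AssociationCatalog(world.true_pairs(positive=True))


def desk_scale_config(seed: int = 0, max_epochs: int = 20) -> NetworkConfig:
    """Architecture scaled to the 64 x 32 desk-scale world.

    Two conv blocks (8 and 16 filters) and one FC layer of width 64 keep
    a full train/evaluate cycle well under a minute on one CPU; with
    valid-padding floor arithmetic a third conv block would collapse the
    64 x 32 input below the 5 x 5 kernel.
    """
    return NetworkConfig(
        input_shape=(64, 32),
        conv_filters=(8, 16),
        fc_widths=(64,),
        dropout_rate=0.5,
        learning_rate=0.03,
        max_epochs=max_epochs,
        batch_size=32,
        seed=seed,
    )
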