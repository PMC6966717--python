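# Methods

## Problem and model

The package treats drug–disease association discovery as binary
classification of (drug, disease) pairs. A pair is encoded as the outer
sum FD(n, m) = F(n) + D(m) of a binary substructure fingerprint F
(rows) and a non-negative TF-IDF symptom-weight vector D (columns); the
matrix can be rendered as a gray-scale image, and a convolutional
network maps it to a two-class posterior. The encoding is deliberately
minimal: every row of FD is the symptom profile shifted by 0 or 1, so
the matrix is a rank-1-plus-offset object from which F and D are
recoverable (up to an additive constant) — the network sees exactly the
two information channels and their alignment, nothing more.

### Featurization

* **Fingerprints.** The native `substructure-key` scheme evaluates a
  fixed 881-key dictionary laid out in the classical substructure-key
  sections: element-count thresholds, a ring census (size, aromaticity,
  carbocyclic/heterocyclic, saturation), bonded element pairs over
  eleven organic elements and four bond orders, and three-atom
  fragments. Keys are evaluated with RDKit on the canonicalized
  molecule, so any spelling of the same SMILES gives bitwise-identical
  vectors. The scheme is pluggable: binary fingerprint families
  computed elsewhere (e.g. PaDEL exports of any of the seven common
  families) load from TSV, and the column count becomes the scheme
  dimension. The native dictionary is this package's own key set — it
  matches the 881-bit layout and semantics of database substructure
  keys but is not a bit-for-bit clone of any external tool.
* **Symptom vectors.** tf = the raw disease–symptom co-occurrence
  count; idf = ln(N_d / n_m) over the disease corpus with natural log.
  A symptom present in every disease carries weight 0; a disease with
  an all-zero count row is rejected (it cannot be represented). This is
  the canonical TF-IDF variant; the corpus definition used by upstream
  symptom-network datasets is not always recoverable, so the variant is
  isolated in one function and can be swapped.
* **Similarities.** Drug: Jaccard on on-bits. Disease: cosine. Pair:
  the arithmetic mean of the two. Degenerate inputs (no on-bits,
  zero-norm weights) have similarity 0 by definition — no shared
  structure or signal — rather than raising, so randomly generated
  sparse fixtures are never brittle.

### Pair-image normalization

The gray-scale mapping needs a normalization constant. One global scale
per dataset — 1 + the maximum symptom weight of the corpus — is used
and persisted with the model; per-image normalization would destroy
cross-pair comparability of intensity. The network consumes the
real-valued matrix divided by this scale; the 8-bit PNG path (round
half away from zero, clipped to [0, 255], sidecar JSON with drug id,
disease id and scale) exists for interchange and inspection, since
quantization is an artifact of the image metaphor rather than of the
encoding.

### Network

Valid padding with floor arithmetic `out = floor((in − k)/s) + 1`
everywhere; with the default 881 × 322 input the stage sizes are
(439,159) → (219,79) → (108,38) → (54,19) → (25,8) → (12,4), giving a
flattened width of 12 · 4 · 128 = 6144. The four consecutive FC-500 +
dropout-0.5 layers are implemented literally as four blocks; the count
is configurable. Loss is softmax cross-entropy; weights use He-normal
initialization; the optimizer is plain SGD with momentum 0.9, initial
learning rate 0.01 multiplied by 0.1 every 10 epochs, 50 epochs and
batch 128 by default. There is no early stopping and no augmentation
(flips/crops are meaningless for this encoding). The implementation is
pure numpy (im2col convolutions); everything stochastic flows through
seeded `numpy.random.Generator` instances, so a fixed seed reproduces
training bit-for-bit on a CPU, and inference is deterministic (dropout
disabled) and invariant to batch partitioning within 1e-6.

### Benchmark construction

Positives come from rows of a CTD-style table whose direct-evidence
field contains "therapeutic" (case-insensitive substring — CTD uses
compound evidence strings) and whose chemical name does not contain
"drug combination". Negatives are sampled without replacement from the
complement of the *entire* catalog (any evidence annotation) over the
drugs and diseases present in the positives: testing against the whole
file, not just the therapeutic subset, prevents marker/mechanism pairs
from being mislabeled as negatives. Ratio datasets hold
|negatives| = ratio × |positives| for ratios 1 … 10.

Random splits are label-stratified with floor(train_fraction · n) per
label. Cold-start splits use a single accretion pass: repeatedly pick
an uncommitted disease (or drug) at random and commit *all* of its
records — both labels at once — to the training side until it holds the
target fraction. Committing both labels in one pass is a deliberate
strengthening of the two-pass positive/negative procedure, which cannot
by itself guarantee that an entity lands on only one side; the stop
rule overshoots the target by at most the largest entity's share, and a
single entity owning more than the target is a degenerate-split error.
Redundancy winnowing shuffles records under the seed and greedily
retains a record iff its pair similarity to every already-retained
record is ≤ the threshold, so the retained set provably contains no
pair above it. Candidate enumeration yields the lexicographic grid
minus the catalog; the Lipinski rule-of-five filter uses the strict
inequalities MW < 500 Da, HBD < 5, HBA < 10, logP < 5. Screening
retains candidates with p > threshold (0.99 default), sorted by
descending probability with lexicographic tie-breaks.

### Evaluation

Point metrics use the strict decision rule p > 0.5 (equivalent to
two-class argmax except at exact ties, which go to negative): AC, SE,
SP, PR as percentages and MCC. Undefined ratios (zero denominators) are
reported as absent, never coerced to 0, and repeat summaries skip them.
ROC and PR curves are threshold sweeps over the scores (scikit-learn,
intermediate points kept) with areas by the trapezoidal rule; ROCA
equals the tie-adjusted concordant-pair fraction, which the tests
verify against a Mann–Whitney counting oracle. Repeat summaries report
the mean and the relative standard deviation 100 · sd/mean (sample
sd). Run comparisons use the two-sided Wilcoxon rank-sum
(exact/asymptotic via `scipy.stats.mannwhitneyu`) and two-sample
Kolmogorov–Smirnov tests; all-tied input yields absent p-values with a
warning.

## Synthetic worlds

The generator plants the association signal in exactly the channels
the classifier reads. Drugs and diseases share `n_clusters` latent
classes; each class owns a template fingerprint (Bernoulli bits at
`bit_density`, default 0.3) and a template symptom-count profile
(nonzero with probability `symptom_sparsity` = 0.35, counts uniform on
1 … `max_count` = 5); members are templates with per-element corruption
probability `feature_noise` (default 0.02), and a pair is a ground-truth
positive iff drug and disease share a class. Labels can additionally be
flipped with probability ε < 0.5. Generation fails loudly if the
realized within-cluster mean pair similarity does not exceed the
between-cluster mean. Worlds export in the exact TSV dialects the real
pipeline reads, so the synthetic and real paths are byte-compatible.

Desk-scale defaults are 48 drugs × 48 diseases with 64-bit fingerprints
and 32 symptoms; a matching scaled network (two conv blocks of 8 and 16
filters — a third block would collapse a 64 × 32 input under the floor
arithmetic — one FC-64 layer, dropout 0.5, lr 0.03, 20 epochs, batch
32) trains in a few seconds on one CPU. `max_count` = 5 keeps the
global pair-image scale near 20 so the unit-height fingerprint channel
is not drowned by rare-symptom idf spikes; larger counts make the drug
channel proportionally fainter and training slower to pick it up.

What the worlds do *not* emulate: the heavy-tailed similarity
distributions of real compound libraries, identifier messiness,
many-to-many cluster overlap, or corpus-scale class imbalance. Passing
the end-to-end tests shows the pipeline is internally consistent and
can recover a planted, cleanly clustered signal — not that the headline
accuracies on curated corpora are reproduced, which would require the
real association corpus and full-scale training.

## Study protocols at desk scale

* **Learnability.** Two-cluster world, 400 positives + 400 sampled
  negatives, 3:1 stratified split, 20 epochs. Clean labels: held-out
  accuracy is expected ≥ 95%. With ε = 0.2 flip noise on both sides of
  the split, accuracy is measured against observed labels, whose
  ceiling is 1 − 2ε(1 − acc_true) ≈ 80%; it should stay above 70%.
* **Ratio contrast.** One harder world (`feature_noise` 0.15, so
  clusters overlap and the operating point is interior), one fixed
  balanced test set of 100 pairs; per repeat, paired models sharing
  positives and initialization are trained at negative ratios 1:1 and
  1:5 and evaluated on the common test set; means over five repeats
  are compared. The small desk-scale network is essential here: with
  more capacity the extra negatives improve the ranking itself and the
  sensitivity loss disappears, while at fixed modest capacity the
  enlarged negative share mainly shifts the decision boundary toward
  the negative class — specificity rises and sensitivity falls, the
  behavior the protocol is meant to exhibit.

## Numerical choices and edge cases

* Round-half-away-from-zero for 8-bit quantization (values are
  non-negative, so `floor(x + 0.5)`).
* Jaccard/cosine of degenerate vectors: 0 (see above); cosine is
  clipped into [0, 1] against floating-point overshoot.
* Negative sampling enumerates the complement exactly when the
  candidate grid is small (≤ 250k) and falls back to seeded rejection
  sampling with redraw-on-duplicate above that.
* MCC is absent when any marginal is zero; exact ties at the decision
  cutoff predict negative.
* float64 throughout the network: at desk scale the speed cost is
  negligible and batch-partition invariance holds comfortably.

## Known limitations

* The native key dictionary is structurally faithful to substructure
  key sets but not bit-compatible with PaDEL/PubChem output; models
  trained on one scheme do not transfer to another.
* No identifier cross-mapping (MeSH ↔ OMIM ↔ CID); catalog membership
  is exact string matching.
* The numpy network is CPU-oriented and desk-scale; the full 881 × 322
  architecture runs forward/backward correctly but training corpora of
  tens of thousands of images would need hours, not seconds.
* Whether upstream implementations trained on quantized 8-bit images
  or raw matrices is unknowable from the outside; the float path is
  canonical here and the quantized path exists for sensitivity checks.
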