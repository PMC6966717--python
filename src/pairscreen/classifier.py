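"""Model/Results interface over the convolutional pair-image classifier.

:class:`PairImageClassifier` is constructed from labeled pair matrices
(or from association records plus a :class:`PairSource`), and ``fit()``
returns a :class:`PairImageResults` carrying the trained network, the
training history, prediction and screening methods, and a ``summary()``
table.  The network consumes the real-valued pair matrix divided by the
dataset's global scale constant, which is persisted with the model so a
reloaded artifact reproduces predictions exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .datasets import AssociationRecord
from .fingerprints import FingerprintVector
from .network import Network, NetworkConfig, learning_rate_at, softmax
from .pairimage import build_pair_matrix
from .symptoms import SymptomVector


@dataclass(frozen=True)
class PredictionRecord:
    drug_id: str
    disease_id: str
    p_positive: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_positive <= 1.0:
            raise ValueError("p_positive must be in [0, 1]")


class PairSource:
    """Maps (drug_id, disease_id) to the scale-normalized pair matrix."""

    def __init__(
        self,
        fingerprints: dict[str, FingerprintVector],
        symptoms: dict[str, SymptomVector],
        scale: float,
    ):
        if scale <= 0:
            raise ValueError("scale must be positive")
        self.fingerprints = fingerprints
        self.symptoms = symptoms
        self.scale = float(scale)

    def matrix(self, drug_id: str, disease_id: str) -> np.ndarray:
        m = build_pair_matrix(self.fingerprints[drug_id], self.symptoms[disease_id])
        return m.values / self.scale

    @property
    def shape(self) -> tuple[int, int]:
        f = next(iter(self.fingerprints.values()))
        d = next(iter(self.symptoms.values()))
        return (len(f), len(d))


class PairImageClassifier:
    """Convolutional classifier of drug-disease pair images.

    Parameters
    ----------
    X : ndarray, shape (n, rows, cols)
        Scale-normalized pair matrices.
    y : ndarray of 0/1
        Association labels.
    config : NetworkConfig
        Architecture and optimizer settings; ``input_shape`` must match
        the matrices.
    scale : float
        The global pair-image normalization constant already applied to
        ``X`` (persisted with the fitted model).
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        config: NetworkConfig | None = None,
        scale: float = 1.0,
        ids: Sequence[tuple[str, str]] | None = None,
    ):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        if X.ndim != 3:
            raise ValueError("X must be (n_samples, rows, cols)")
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        if len(X) == 0:
            raise ValueError("empty training data")
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        self.config = config if config is not None else NetworkConfig(
            input_shape=X.shape[1:]
        )
        if tuple(X.shape[1:]) != tuple(self.config.input_shape):
            raise ValueError(
                f"matrices of shape {X.shape[1:]} do not match "
                f"config.input_shape {self.config.input_shape}"
            )
        self.X = X
        self.y = y
        self.scale = float(scale)
        self.ids = list(ids) if ids is not None else None

    @classmethod
    def from_records(
        cls,
        records: Sequence[AssociationRecord],
        source: PairSource,
        config: NetworkConfig | None = None,
    ) -> "PairImageClassifier":
        X = np.stack([source.matrix(r.drug_id, r.disease_id) for r in records])
        y = np.array([r.label for r in records], dtype=np.int64)
        ids = [(r.drug_id, r.disease_id) for r in records]
        return cls(X, y, config=config, scale=source.scale, ids=ids)

    def fit(self, verbose: bool = False) -> "PairImageResults":
        """Train with SGD + momentum under the stepped learning-rate schedule.

        The history records one entry per epoch (loss and accuracy over
        the epoch's mini-batches); shuffling and dropout are seeded so a
        fixed seed reproduces training bit-for-bit.
        """
        cfg = self.config
        net = Network(cfg)
        rng = np.random.default_rng([cfg.seed, 1])
        n = len(self.X)
        history: list[dict] = []
        for epoch in range(1, cfg.max_epochs + 1):
            lr = learning_rate_at(cfg, epoch)
            order = rng.permutation(n)
            losses, correct = [], 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                loss, grads, probs = net.loss_and_grads(self.X[idx], self.y[idx], rng)
                net.sgd_step(grads, lr)
                losses.append(loss * len(idx))
                correct += int((probs.argmax(axis=1) == self.y[idx]).sum())
            entry = {
                "epoch": epoch,
                "lr": lr,
                "loss": float(np.sum(losses) / n),
                "accuracy": correct / n,
            }
            history.append(entry)
            if verbose:
                print(
                    f"epoch {epoch:3d}  lr {lr:.5f}  loss {entry['loss']:.4f}  "
                    f"acc {entry['accuracy']:.4f}"
                )
        return PairImageResults(self, net, history)


class PairImageResults:
    """Fitted classifier: weights, history, prediction and screening."""

    def __init__(self, model: PairImageClassifier, network: Network,
                 history: list[dict]):
        self.model = model
        self.network = network
        self.config = network.config
        self.scale = model.scale if model is not None else 1.0
        self.history = history

    # -- prediction -----------------------------------------------------------

    def predict_proba(self, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Two-class probabilities for normalized pair matrices; rows sum to 1."""
        return self.network.predict_proba(np.asarray(X, dtype=np.float64), batch_size)

    def predict_records(
        self,
        pairs: Iterable[tuple[str, str]],
        source: PairSource,
        batch_size: int = 64,
    ) -> list[PredictionRecord]:
        pairs = list(pairs)
        out: list[PredictionRecord] = []
        for start in range(0, len(pairs), batch_size):
            chunk = pairs[start:start + batch_size]
            X = np.stack([source.matrix(d, s) for d, s in chunk])
            probs = self.predict_proba(X, batch_size=batch_size)
            out.extend(
                PredictionRecord(d, s, float(p))
                for (d, s), p in zip(chunk, probs[:, 1])
            )
        return out

    def screen(
        self,
        predictions: Iterable[PredictionRecord],
        threshold: float = 0.99,
    ) -> list[PredictionRecord]:
        return screen_predictions(predictions, threshold)

    # -- reporting ------------------------------------------------------------

    def summary(self) -> str:
        cfg = self.config
        n_params = sum(v.size for v in self.network.params.values())
        last = self.history[-1] if self.history else {"loss": float("nan"),
                                                      "accuracy": float("nan")}
        rows = [
            ("Input shape", f"{cfg.input_shape[0]} x {cfg.input_shape[1]}"),
            ("Conv filters", " / ".join(map(str, cfg.conv_filters))),
            ("FC widths", " / ".join(map(str, cfg.fc_widths))),
            ("Dropout", f"{cfg.dropout_rate:g}"),
            ("Parameters", f"{n_params:,}"),
            ("Optimizer", f"SGD momentum {cfg.momentum:g}"),
            ("LR schedule", f"{cfg.learning_rate:g} x {cfg.lr_drop_factor:g}"
                            f" every {cfg.lr_drop_every} epochs"),
            ("Epochs", str(len(self.history))),
            ("Batch size", str(cfg.batch_size)),
            ("Pair-image scale", f"{self.scale:.6g}"),
            ("Final train loss", f"{last['loss']:.4f}"),
            ("Final train accuracy", f"{last['accuracy']:.4f}"),
        ]
        width = max(len(k) for k, _ in rows)
        lines = ["Pair-image CNN classifier", "=" * 40]
        lines += [f"{k:<{width}}  {v}" for k, v in rows]
        return "\n".join(lines)

    # -- persistence ----------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Write weights, config, scale and training history to a directory."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", **self.network.params)
        (directory / "config.json").write_text(
            json.dumps(
                {
                    "config": self.config.to_dict(),
                    "scale": self.scale,
                    "history": self.history,
                }
            )
        )

    @classmethod
    def load(cls, directory: str | Path) -> "PairImageResults":
        directory = Path(directory)
        meta = json.loads((directory / "config.json").read_text())
        config = NetworkConfig.from_dict(meta["config"])
        net = Network(config)
        with np.load(directory / "weights.npz") as npz:
            for k in net.params:
                net.params[k] = npz[k]
        results = cls(model=None, network=net, history=meta["history"])
        results.scale = float(meta["scale"])
        return results


def screen_predictions(
    predictions: Iterable[PredictionRecord], threshold: float
) -> list[PredictionRecord]:
    """Candidates with p_positive strictly above the threshold, ranked.

    Sorted by descending probability; exact ties break lexicographically
    on (drug_id, disease_id).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    kept = [p for p in predictions if p.p_positive > threshold]
    return sorted(kept, key=lambda p: (-p.p_positive, p.drug_id, p.disease_id))
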