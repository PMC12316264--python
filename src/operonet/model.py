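"""Ensemble CNN-LSTM operon classifier with a statsmodels-style surface.

:class:`OperonModel` is built from a labeled tensor dataset; ``fit()``
trains an ensemble of independently seeded CNN-LSTM members (ten by
default) and returns :class:`EnsembleResults`, which carries the trained
members, per-member training histories, ``summary()``, ``predict()`` and
``save()``.  The ensemble probability that a gene pair is co-operonic is
the arithmetic mean of the members' positive-class softmax outputs; a pair
is called an operon pair when that mean is >= the confidence threshold
(0.5 by default).

Each member trains with Adam (learning rate 0.001), batch size 32, for at
most 100 epochs, monitoring AUROC on a held-out stratified validation
split; training stops after ``early_stopping_patience`` epochs without
improvement and the best-AUROC weights are restored.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .features import PairDataset, TENSOR_CHANNELS, TENSOR_LENGTH, TENSOR_ROWS
from .nn import Adam, CnnLstmNet

EXPECTED_PARAM_COUNTS = {"conv": 5824, "lstm": 33024, "dense": 2050}


class EnsembleIntegrityError(RuntimeError):
    """Saved ensemble directory disagrees with its manifest."""


@dataclass
class ModelConfig:
    """Hyperparameters of the classifier and its training loop."""

    batch_size: int = 32
    epochs: int = 100
    dropout_rate: float = 0.3
    kernel_size: tuple[int, int] = (5, 6)
    cnn_filters: int = 64
    lstm_units: int = 64
    attention_heads: int = 16
    attention_dim: int = 16
    learning_rate: float = 0.001
    early_stopping_patience: int = 10
    ensemble_size: int = 10
    threshold: float = 0.5
    validation_fraction: float = 0.1
    bootstrap: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["kernel_size"] = list(self.kernel_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "kernel_size" in d:
            d["kernel_size"] = tuple(d["kernel_size"])
        return cls(**d)


def build_network(config: ModelConfig, seed: Optional[int] = None) -> CnnLstmNet:
    """Instantiate one CNN-LSTM member from a config."""
    net = CnnLstmNet(
        input_length=TENSOR_LENGTH,
        input_rows=TENSOR_ROWS,
        input_channels=TENSOR_CHANNELS,
        kernel_size=config.kernel_size,
        filters=config.cnn_filters,
        lstm_units=config.lstm_units,
        attention_heads=config.attention_heads,
        attention_dim=config.attention_dim,
        dropout_rate=config.dropout_rate,
        seed=config.seed if seed is None else seed,
    )
    return net


def _stratified_split(
    labels: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Indices (train, val) with at least one validation item per class."""
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        members = rng.permutation(members)
        n_val = max(1, int(round(fraction * len(members))))
        val_idx.append(members[:n_val])
        train_idx.append(members[n_val:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


def train_member(
    tensors: np.ndarray,
    labels: np.ndarray,
    config: ModelConfig,
    member_seed: int,
) -> tuple[CnnLstmNet, dict]:
    """Train one ensemble member; returns (network, history).

    All randomness (weight init, validation split, shuffling, bagging,
    dropout) derives from ``member_seed``.  History records per-epoch
    training loss and validation AUROC, the best epoch, and whether early
    stopping fired.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError(
            "training requires both classes; got only class "
            f"{classes.tolist()}"
        )
    ss = np.random.SeedSequence(member_seed)
    init_seed = int(ss.generate_state(1)[0] % (2 ** 31))
    rng = np.random.default_rng(ss.spawn(1)[0])
    net = build_network(config, seed=init_seed)
    optimizer = Adam(lr=config.learning_rate)

    train_idx, val_idx = _stratified_split(labels, config.validation_fraction, rng)
    if config.bootstrap:
        train_idx = rng.choice(train_idx, size=len(train_idx), replace=True)
    x_train, y_train = tensors[train_idx], labels[train_idx]
    x_val, y_val = tensors[val_idx], labels[val_idx]
    y_onehot = np.eye(2, dtype=np.float32)[y_train]

    best_auroc = -np.inf
    best_weights = net.get_weights()
    best_epoch = 0
    wait = 0
    history: dict = {"epochs": [], "train_loss": [], "val_auroc": []}
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(x_train))
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            losses.append(
                net.train_step(x_train[batch], y_onehot[batch], optimizer, rng)
            )
        val_probs = net.predict_proba(x_val)[:, 1]
        val_auroc = float(roc_auc_score(y_val, val_probs))
        history["epochs"].append(epoch)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_auroc"].append(val_auroc)
        if val_auroc > best_auroc:
            best_auroc = val_auroc
            best_weights = net.get_weights()
            best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait >= config.early_stopping_patience:
                break
    net.set_weights(best_weights)
    history.update({
        "best_epoch": best_epoch,
        "best_val_auroc": float(best_auroc),
        "stopped_epoch": history["epochs"][-1],
        "early_stopped": history["epochs"][-1] < config.epochs,
        "n_train": int(len(train_idx)),
        "n_val": int(len(val_idx)),
        "member_seed": int(member_seed),
    })
    return net, history


def _dataset_fingerprint(tensors: np.ndarray, labels: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(tensors, dtype=np.float32).tobytes())
    h.update(np.ascontiguousarray(labels, dtype=np.int8).tobytes())
    return h.hexdigest()[:16]


class OperonModel:
    """Gene-pair operon classifier bound to a labeled tensor dataset.

    Parameters
    ----------
    tensors
        Array (N, 150, 6, 3) of gene-pair signal tensors.
    labels
        Array (N,) of 0/1 operon labels (label-2 pairs must be filtered
        out beforehand; see :func:`operonet.labeling.filter_training`).
    config
        Hyperparameters; defaults follow the reference configuration.
    """

    def __init__(
        self,
        tensors: np.ndarray,
        labels: np.ndarray,
        pair_ids: Optional[Sequence[str]] = None,
        config: Optional[ModelConfig] = None,
    ):
        tensors = np.asarray(tensors, dtype=np.float32)
        labels = np.asarray(labels)
        if tensors.ndim != 4 or tensors.shape[1:] != (
            TENSOR_LENGTH, TENSOR_ROWS, TENSOR_CHANNELS
        ):
            raise ValueError(
                f"tensors must have shape (N, {TENSOR_LENGTH}, {TENSOR_ROWS}, "
                f"{TENSOR_CHANNELS}); got {tensors.shape}"
            )
        if not np.isin(labels, [0, 1]).all():
            raise ValueError("labels must be 0/1; filter label-2 pairs first")
        self.tensors = tensors
        self.labels = labels.astype(np.int8)
        self.pair_ids = list(pair_ids) if pair_ids is not None else [
            f"pair_{i}" for i in range(len(labels))
        ]
        self.config = config or ModelConfig()

    @classmethod
    def from_dataset(
        cls, dataset: PairDataset, config: Optional[ModelConfig] = None
    ) -> "OperonModel":
        """Build from a :class:`PairDataset`, dropping label-2 pairs."""
        keep = np.isin(dataset.labels, [0, 1])
        sub = dataset.subset(keep)
        return cls(sub.tensors, sub.labels, sub.pair_ids, config=config)

    def fit(self, verbose: bool = False) -> "EnsembleResults":
        """Train the ensemble; members differ only by derived seed."""
        ss = np.random.SeedSequence(self.config.seed)
        member_seeds = [int(s % (2 ** 31)) for s in
                        ss.generate_state(self.config.ensemble_size)]
        members, histories = [], []
        for m, seed in enumerate(member_seeds):
            net, history = train_member(
                self.tensors, self.labels, self.config, member_seed=seed
            )
            members.append(net)
            histories.append(history)
            if verbose:
                print(
                    f"member {m}: best val AUROC {history['best_val_auroc']:.3f} "
                    f"at epoch {history['best_epoch']} "
                    f"(stopped {history['stopped_epoch']})"
                )
        manifest = {
            "config": self.config.to_dict(),
            "members": histories,
            "param_counts": members[0].layer_param_counts(),
            "dataset_fingerprint": _dataset_fingerprint(self.tensors, self.labels),
            "n_pairs": int(len(self.labels)),
            "class_counts": {
                "non_operon": int((self.labels == 0).sum()),
                "operon": int((self.labels == 1).sum()),
            },
        }
        return EnsembleResults(members=members, manifest=manifest,
                               config=self.config)


@dataclass
class EnsembleResults:
    """A trained ensemble: members, manifest, prediction and persistence."""

    members: list[CnnLstmNet]
    manifest: dict
    config: ModelConfig = field(default_factory=ModelConfig)

    def member_probabilities(self, tensors: np.ndarray) -> np.ndarray:
        """Class-1 probability per (member, pair): shape (M, N)."""
        tensors = np.asarray(tensors, dtype=np.float32)
        if tensors.ndim == 3:
            tensors = tensors[None]
        return np.stack(
            [m.predict_proba(tensors)[:, 1] for m in self.members], axis=0
        )

    def predict_proba(self, tensors: np.ndarray) -> np.ndarray:
        """Ensemble probability = mean over members' class-1 outputs."""
        return self.member_probabilities(tensors).mean(axis=0)

    def predict(
        self,
        tensors: np.ndarray,
        pair_ids: Optional[Sequence[str]] = None,
    ) -> pd.DataFrame:
        """Per-pair prediction records.

        Columns: ``pair_id``, ``mean_probability``, ``max_member_probability``
        and ``predicted_label`` (1 iff mean >= threshold).
        """
        member_probs = self.member_probabilities(tensors)
        mean_p = member_probs.mean(axis=0)
        max_p = member_probs.max(axis=0)
        n = mean_p.shape[0]
        if pair_ids is None:
            pair_ids = [f"pair_{i}" for i in range(n)]
        return pd.DataFrame({
            "pair_id": list(pair_ids),
            "mean_probability": mean_p,
            "max_member_probability": max_p,
            "predicted_label": (mean_p >= self.config.threshold).astype(int),
        })

    def summary(self) -> str:
        """Human-readable training summary table."""
        counts = self.manifest.get("param_counts", {})
        lines = [
            "Operon CNN-LSTM ensemble",
            "=" * 60,
            f"members: {len(self.members)}   threshold: {self.config.threshold}",
            f"training pairs: {self.manifest.get('n_pairs', '?')} "
            f"(operon {self.manifest.get('class_counts', {}).get('operon', '?')}, "
            f"non-operon {self.manifest.get('class_counts', {}).get('non_operon', '?')})",
            f"parameters: conv {counts.get('conv')}, lstm {counts.get('lstm')}, "
            f"attention {counts.get('attention')}, dense {counts.get('dense')}",
            "-" * 60,
            f"{'member':>6} {'best epoch':>10} {'stopped':>8} {'val AUROC':>10}",
        ]
        for m, hist in enumerate(self.manifest.get("members", [])):
            lines.append(
                f"{m:>6} {hist['best_epoch']:>10} {hist['stopped_epoch']:>8} "
                f"{hist['best_val_auroc']:>10.4f}"
            )
        lines.append("=" * 60)
        return "\n".join(lines)

    # ------------------------------------------------------------ persistence
    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for m, net in enumerate(self.members):
            np.savez(path / f"member_{m:02d}.npz", **net.get_weights())
        manifest = dict(self.manifest)
        manifest["ensemble_size"] = len(self.members)
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "EnsembleResults":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        config = ModelConfig.from_dict(manifest["config"])
        n = manifest.get("ensemble_size")
        files = sorted(path.glob("member_*.npz"))
        if n is None or len(files) != n:
            raise EnsembleIntegrityError(
                f"manifest declares {n} members but found {len(files)} files"
            )
        members = []
        for f in files:
            net = build_network(config)
            with np.load(f) as npz:
                net.set_weights({k: npz[k] for k in npz.files})
            members.append(net)
        counts = members[0].layer_param_counts()
        if (config.kernel_size, config.cnn_filters, config.lstm_units) == (
            (5, 6), 64, 64
        ):
            for layer, expected in EXPECTED_PARAM_COUNTS.items():
                if counts[layer] != expected:
                    raise EnsembleIntegrityError(
                        f"{layer} parameter count {counts[layer]} != {expected}"
                    )
        declared = manifest.get("param_counts", {})
        for layer, value in declared.items():
            if counts.get(layer) != value:
                raise EnsembleIntegrityError(
                    f"{layer} parameter count {counts.get(layer)} does not "
                    f"match manifest ({value})"
                )
        return cls(members=members, manifest=manifest, config=config)
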