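"""The single binary MLP classifier over cross-joined metabolite-pathway entries.

One feed-forward network with ReLU hidden layers and a sigmoid output is
trained by seeded mini-batch gradient descent (Adam) on binary cross-entropy.
Training holds out a small validation slice of the training entries and
early-stops on validation MCC, restoring the best-scoring parameters.  The
trained model carries its ordered feature-column contract and refuses
prediction inputs that do not match it.

Datasets larger than memory can be streamed in row blocks from the HDF5
store written by :class:`pathpair.dataset.PairedDataset`.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
from scipy import sparse
from sklearn.metrics import matthews_corrcoef
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier

from .dataset import PairedDataset

_CLASSES = np.array([0, 1], dtype=np.int8)


@dataclass(frozen=True)
class Hyperparameters:
    """Training configuration for the MLP.

    ``weight_decay`` is an L2 penalty on the weights.  Defaults are sized
    for desk-scale corpora and are meant to be overridden per run (or
    chosen by :func:`tune`).
    """

    hidden_layer_sizes: tuple[int, ...] = (128,)
    learning_rate: float = 2e-3
    batch_size: int = 512
    max_epochs: int = 22
    early_stop_patience: int = 0
    weight_decay: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.hidden_layer_sizes or any(h < 1 for h in self.hidden_layer_sizes):
            raise ValueError("hidden layer sizes must be positive")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("learning rate, batch size and max epochs must be positive")
        if self.early_stop_patience < 0 or self.weight_decay < 0:
            raise ValueError("patience and weight decay must be non-negative")


class ContractError(ValueError):
    """Prediction input does not match the trained feature-column contract."""


@dataclass
class TrainedClassifier:
    net: MLPClassifier
    feature_names: tuple[str, ...]
    hyperparameters: Hyperparameters
    epochs_run: int
    best_val_mcc: float | None

    def _check_contract(self, X: sparse.spmatrix, feature_names: Sequence[str] | None) -> None:
        if X.shape[1] != len(self.feature_names):
            raise ContractError(
                f"input has {X.shape[1]} columns, model was trained on {len(self.feature_names)}"
            )
        if feature_names is not None and tuple(feature_names) != self.feature_names:
            raise ContractError("feature-column names differ from the training contract")

    def predict(
        self,
        entries: PairedDataset | sparse.spmatrix,
        feature_names: Sequence[str] | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return (probability, hard label at threshold 0.5) per entry."""
        if isinstance(entries, PairedDataset):
            X, feature_names = entries.X, entries.feature_names
        else:
            X = entries
        self._check_contract(X, feature_names)
        proba = self.net.predict_proba(X)[:, 1]
        return proba, (proba >= 0.5).astype(np.int8)


class HDF5PairedSource:
    """Row-block access to a persisted PairedDataset without loading it whole."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        with h5py.File(self.path, "r") as f:
            self.shape = tuple(f["features"]["shape"][:])
            names = f["features"]["names"][:]
            self.feature_names = tuple(
                n.decode() if isinstance(n, bytes) else str(n) for n in names
            )

    @property
    def n_entries(self) -> int:
        return self.shape[0]

    def read_rows(self, rows: np.ndarray) -> tuple[sparse.csr_matrix, np.ndarray]:
        rows = np.sort(np.asarray(rows))
        with h5py.File(self.path, "r") as f:
            feats = f["features"]
            indptr = feats["indptr"][:]
            data_parts, index_parts, new_indptr = [], [], [0]
            for r in rows:
                lo, hi = indptr[r], indptr[r + 1]
                data_parts.append(feats["data"][lo:hi])
                index_parts.append(feats["indices"][lo:hi])
                new_indptr.append(new_indptr[-1] + (hi - lo))
            X = sparse.csr_matrix(
                (
                    np.concatenate(data_parts) if data_parts else np.empty(0),
                    np.concatenate(index_parts) if index_parts else np.empty(0, dtype=np.int64),
                    np.asarray(new_indptr, dtype=np.int64),
                ),
                shape=(len(rows), self.shape[1]),
            )
            y = f["labels"][:][rows].astype(np.int8)
        return X, y


def _epoch(
    clf: MLPClassifier,
    X: sparse.csr_matrix,
    y: np.ndarray,
    batch_size: int,
    rng: np.random.Generator,
) -> None:
    order = rng.permutation(len(y))
    for start in range(0, len(y), batch_size):
        idx = order[start : start + batch_size]
        clf.batch_size = len(idx)  # keep sklearn's internal batching in sync
        clf.partial_fit(X[idx], y[idx], classes=_CLASSES)


def train(
    data: PairedDataset | HDF5PairedSource,
    hp: Hyperparameters = Hyperparameters(),
    val_fraction: float = 0.1,
    stream_block: int = 8192,
) -> TrainedClassifier:
    """Train the MLP with early stopping on validation MCC.

    For an in-memory :class:`PairedDataset` the rows are re-shuffled every
    epoch; for an :class:`HDF5PairedSource` the row blocks are shuffled but
    rows within a block keep their order (sequential reads).
    """
    streaming = isinstance(data, HDF5PairedSource)
    n = data.n_entries
    if streaming:
        with h5py.File(data.path, "r") as f:
            y_all = f["labels"][:].astype(np.int8)
    else:
        y_all = data.y
    if len(np.unique(y_all)) < 2:
        raise ValueError("training set must contain both labels")

    rng = np.random.default_rng(hp.seed)
    idx = np.arange(n)
    use_val = hp.early_stop_patience > 0 and n >= 20
    if use_val:
        counts = np.bincount(y_all, minlength=2)
        strat = y_all if counts.min() >= 2 else None
        train_idx, val_idx = train_test_split(
            idx, test_size=val_fraction, random_state=hp.seed, stratify=strat
        )
        if len(np.unique(y_all[train_idx])) < 2:
            train_idx, val_idx, use_val = idx, idx[:0], False
    else:
        train_idx, val_idx = idx, idx[:0]

    clf = MLPClassifier(
        hidden_layer_sizes=tuple(hp.hidden_layer_sizes),
        activation="relu",
        solver="adam",
        alpha=hp.weight_decay,
        learning_rate_init=hp.learning_rate,
        batch_size=min(hp.batch_size, max(1, len(train_idx))),
        shuffle=False,  # shuffling is done here, seeded
        random_state=int(hp.seed) % (2**32),
        max_iter=1,
    )

    if streaming:
        X_val, y_val = (data.read_rows(val_idx) if use_val else (None, None))
        blocks = [train_idx[i : i + stream_block] for i in range(0, len(train_idx), stream_block)]
    else:
        # single precision: halves the memory traffic of the gradient pass
        X_tr, y_tr = data.X[train_idx].astype(np.float32), y_all[train_idx]
        X_val, y_val = (data.X[val_idx].astype(np.float32), y_all[val_idx]) if use_val else (None, None)

    best_score = -np.inf
    best_params: tuple[list, list] | None = None
    best_epoch = 0
    epochs_without_improvement = 0
    epochs_run = 0
    for epoch in range(hp.max_epochs):
        if streaming:
            for bi in rng.permutation(len(blocks)):
                Xb, yb = data.read_rows(blocks[bi])
                _epoch(clf, Xb.astype(np.float32), yb, hp.batch_size, rng)
        else:
            _epoch(clf, X_tr, y_tr, hp.batch_size, rng)
        epochs_run = epoch + 1
        if not use_val:
            continue
        val_mcc = matthews_corrcoef(y_val, clf.predict(X_val))
        if val_mcc >= best_score:
            # ties keep the latest parameters: extra epochs at the same
            # validation score still refine the fit on the training rows
            best_params = ([c.copy() for c in clf.coefs_], [b.copy() for b in clf.intercepts_])
            best_epoch = epochs_run
        if val_mcc > best_score + 1e-4:
            best_score = val_mcc
            epochs_without_improvement = 0
        else:
            epochs_without_improvement += 1
            if epochs_without_improvement >= hp.early_stop_patience:
                break
    if best_params is not None:
        clf.coefs_, clf.intercepts_ = best_params
        epochs_run = best_epoch

    return TrainedClassifier(
        net=clf,
        feature_names=tuple(data.feature_names),
        hyperparameters=hp,
        epochs_run=epochs_run,
        best_val_mcc=float(best_score) if use_val and np.isfinite(best_score) else None,
    )


DEFAULT_SEARCH_SPACE: dict[str, tuple] = {
    "hidden_layer_sizes": ((64,), (128,), (128, 32)),
    "learning_rate": (1e-3, 3e-4),
    "batch_size": (128, 256),
    "weight_decay": (1e-4, 1e-3),
}


def tune(
    dataset: PairedDataset,
    n_trials: int = 10,
    search_space: Mapping[str, Sequence] | None = None,
    seed: int = 0,
    val_fraction: float = 0.2,
    base_hp: Hyperparameters = Hyperparameters(),
) -> Hyperparameters:
    """Seeded random search maximizing MCC on an inner validation split.

    Each trial samples one value per search-space axis, trains on the inner
    training rows, and scores the inner validation rows; the best trial's
    configuration is returned.  Fully deterministic given ``seed``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    space = dict(search_space if search_space is not None else DEFAULT_SEARCH_SPACE)
    rng = np.random.default_rng(seed)
    idx = np.arange(dataset.n_entries)
    inner_train, inner_val = train_test_split(
        idx, test_size=val_fraction, random_state=seed, stratify=dataset.y
    )
    train_ds = dataset.subset(inner_train)
    val_ds = dataset.subset(inner_val)

    best_hp, best_score = None, -np.inf
    for trial in range(n_trials):
        sampled = {k: v[rng.integers(len(v))] for k, v in space.items()}
        if "hidden_layer_sizes" in sampled:
            sampled["hidden_layer_sizes"] = tuple(sampled["hidden_layer_sizes"])
        hp = replace(base_hp, seed=seed + trial, **sampled)
        clf = train(train_ds, hp)
        _, labels = clf.predict(val_ds)
        score = matthews_corrcoef(val_ds.y, labels)
        if score > best_score:
            best_hp, best_score = hp, score
    assert best_hp is not None
    return best_hp


def save_checkpoint(clf: TrainedClassifier, path: str | Path) -> None:
    """Serialize parameters to one file plus a JSON sidecar with provenance."""
    path = Path(path)
    with open(path, "wb") as f:
        pickle.dump(clf.net, f)
    sidecar = {
        "hyperparameters": {
            **{k: getattr(clf.hyperparameters, k) for k in (
                "learning_rate", "batch_size", "max_epochs", "early_stop_patience",
                "weight_decay", "seed",
            )},
            "hidden_layer_sizes": list(clf.hyperparameters.hidden_layer_sizes),
        },
        "epochs_run": clf.epochs_run,
        "best_val_mcc": clf.best_val_mcc,
        "n_features": len(clf.feature_names),
        "feature_names": list(clf.feature_names),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_checkpoint(path: str | Path) -> TrainedClassifier:
    path = Path(path)
    with open(path, "rb") as f:
        net = pickle.load(f)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    hp_d = dict(sidecar["hyperparameters"])
    hp_d["hidden_layer_sizes"] = tuple(hp_d["hidden_layer_sizes"])
    return TrainedClassifier(
        net=net,
        feature_names=tuple(sidecar["feature_names"]),
        hyperparameters=Hyperparameters(**hp_d),
        epochs_run=sidecar["epochs_run"],
        best_val_mcc=sidecar["best_val_mcc"],
    )
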