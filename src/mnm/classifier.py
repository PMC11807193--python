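"""Binary replication-state classifier (Replicating / Non-replicating).

A small feed-forward network (input -> 64 -> 32 -> 16 -> 1 sigmoid) trained
with binary cross-entropy and Adam, with early stopping on validation loss.
The network is implemented directly on NumPy so that training is
single-threaded and bit-reproducible for a fixed seed.

Features are raw autosomal copy numbers on a fixed ordered region list;
regions required by a trained model but absent at predict time are filled
per cell by linear interpolation along each chromosome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BinIndex, CopyNumberMatrix

HIDDEN_LAYERS = (64, 32, 16)
LABEL_REPLICATING = "S"
LABEL_NON_REPLICATING = "G1"


# ---------------------------------------------------------------------------
# training data


@dataclass
class TrainingSet:
    """Complete, autosome-only feature matrix with binary phase labels."""

    features: np.ndarray          # cells x bins, no missing values
    labels: np.ndarray            # 1 = replicating, 0 = non-replicating
    region_labels: list[str]      # ordered bin labels the model will expect

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.features.shape[0] != self.labels.size:
            raise ValueError("features and labels disagree on the number of cells")
        if np.isnan(self.features).any():
            raise ValueError("training features must not contain missing values")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")


def build_training_set(matrix: CopyNumberMatrix, phases: pd.Series | dict) -> TrainingSet:
    """Assemble features: drop bins with any missing value, keep autosomes only.

    ``phases`` maps cell_id -> "S" / "G1" (anything not "S" counts as
    non-replicating).
    """
    if isinstance(phases, dict):
        phases = pd.Series(phases)
    auto = matrix.autosomal()
    complete = ~np.isnan(auto.values).any(axis=0)
    auto = auto.select_bins(complete)
    labels = np.array(
        [1 if str(phases[c]) == LABEL_REPLICATING else 0 for c in auto.cells])
    return TrainingSet(auto.values, labels, auto.bins.labels())


def augment_training(
    train: TrainingSet,
    dup_fraction: float = 0.5,
    noise_span: tuple[float, float] = (0.05, 0.75),
    seed: int = 0,
) -> TrainingSet:
    """Duplicate a fraction of cells and add +/-1 noise to the copies.

    Each duplicate draws a noise fraction q ~ Uniform(noise_span) and
    exactly ``round(q * n_bins)`` of its bins are altered by +/-1 (equal
    sign probability, clipped at zero).  Labels carry over unchanged.
    """
    lo, hi = noise_span
    if not (0.0 <= lo <= hi < 1.0) and not (lo == hi == 0.0):
        raise ValueError("noise_span must lie within [0, 1)")
    if train.features.shape[0] == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    n_cells, n_bins = train.features.shape
    n_dup = int(round(dup_fraction * n_cells))
    chosen = rng.choice(n_cells, size=n_dup, replace=False)

    copies = train.features[chosen].copy()
    for r in range(n_dup):
        q = lo if lo == hi else rng.uniform(lo, hi)
        n_alter = int(round(q * n_bins))
        idx = rng.choice(n_bins, size=n_alter, replace=False)
        copies[r, idx] += rng.choice([-1.0, 1.0], size=n_alter)
    np.clip(copies, 0, None, out=copies)

    return TrainingSet(
        np.vstack([train.features, copies]),
        np.concatenate([train.labels, train.labels[chosen]]),
        train.region_labels,
    )


# ---------------------------------------------------------------------------
# the network


class _MLP:
    """Tiny dense network with ReLU hidden layers and a sigmoid output."""

    def __init__(self, sizes: list[int], seed: int):
        rng = np.random.default_rng(seed)
        self.sizes = list(sizes)
        self.W = [
            rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        self._rng = rng

    def forward(self, X: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        acts = [X]
        h = X
        for W, b in zip(self.W[:-1], self.b[:-1]):
            h = np.maximum(h @ W + b, 0.0)
            acts.append(h)
        z = h @ self.W[-1] + self.b[-1]
        p = 1.0 / (1.0 + np.exp(-z))
        return acts, p.ravel()

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[1]

    @staticmethod
    def bce(p: np.ndarray, y: np.ndarray) -> float:
        p = np.clip(p, 1e-7, 1 - 1e-7)
        return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray,
        y_val: np.ndarray,
        lr: float = 1e-3,
        batch_size: int = 32,
        max_epochs: int = 300,
        patience: int = 15,
    ) -> dict:
        n = X.shape[0]
        mW = [np.zeros_like(w) for w in self.W]
        vW = [np.zeros_like(w) for w in self.W]
        mb = [np.zeros_like(b) for b in self.b]
        vb = [np.zeros_like(b) for b in self.b]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0

        best_loss = np.inf
        best_weights = None
        best_epoch = 0
        stale = 0
        for epoch in range(1, max_epochs + 1):
            order = self._rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                Xb, yb = X[idx], y[idx]
                acts, p = self.forward(Xb)
                delta = (p - yb)[:, None] / len(idx)  # dBCE/dz at the output
                gW, gb = [], []
                for layer in range(len(self.W) - 1, -1, -1):
                    a = acts[layer]
                    gW.append(a.T @ delta)
                    gb.append(delta.sum(axis=0))
                    if layer > 0:
                        delta = (delta @ self.W[layer].T) * (a > 0)
                gW.reverse(); gb.reverse()
                t += 1
                for i in range(len(self.W)):
                    mW[i] = beta1 * mW[i] + (1 - beta1) * gW[i]
                    vW[i] = beta2 * vW[i] + (1 - beta2) * gW[i] ** 2
                    mb[i] = beta1 * mb[i] + (1 - beta1) * gb[i]
                    vb[i] = beta2 * vb[i] + (1 - beta2) * gb[i] ** 2
                    mW_hat = mW[i] / (1 - beta1 ** t)
                    vW_hat = vW[i] / (1 - beta2 ** t)
                    mb_hat = mb[i] / (1 - beta1 ** t)
                    vb_hat = vb[i] / (1 - beta2 ** t)
                    self.W[i] -= lr * mW_hat / (np.sqrt(vW_hat) + eps)
                    self.b[i] -= lr * mb_hat / (np.sqrt(vb_hat) + eps)

            val_loss = self.bce(self.predict_proba(X_val), y_val)
            if val_loss < best_loss - 1e-9:
                best_loss = val_loss
                best_weights = ([w.copy() for w in self.W], [b.copy() for b in self.b])
                best_epoch = epoch
                stale = 0
            else:
                stale += 1
                if stale >= patience:
                    break
        if best_weights is not None:
            self.W, self.b = best_weights
        return {"epochs_run": epoch, "best_epoch": best_epoch, "val_loss": best_loss}


# ---------------------------------------------------------------------------
# model bundle


@dataclass
class ModelBundle:
    """Portable trained model: weights + expected region list + metadata."""

    layer_sizes: list[int]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    region_labels: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        hidden = tuple(self.layer_sizes[1:])
        if hidden != (*HIDDEN_LAYERS, 1):
            raise ValueError(f"layer widths must be {HIDDEN_LAYERS} + (1,), got {hidden}")
        if not self.region_labels:
            raise ValueError("region list must not be empty")

    def network(self) -> _MLP:
        net = _MLP(self.layer_sizes, seed=0)
        net.W = [w.copy() for w in self.weights]
        net.b = [b.copy() for b in self.biases]
        return net

    def save(self, path) -> None:
        payload = {
            "layer_sizes": self.layer_sizes,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "region_labels": self.region_labels,
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "ModelBundle":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            payload["layer_sizes"],
            [np.asarray(w) for w in payload["weights"]],
            [np.asarray(b) for b in payload["biases"]],
            payload["region_labels"],
            payload.get("metadata", {}),
        )


def _stratified_split(labels: np.ndarray, fraction: float, rng: np.random.Generator):
    """Index split keeping the class mixture; returns (first, second)."""
    first, second = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_first = int(round(fraction * idx.size))
        first.append(idx[:n_first])
        second.append(idx[n_first:])
    return np.sort(np.concatenate(first)), np.sort(np.concatenate(second))


def train_classifier(
    train: TrainingSet,
    split: float = 0.8,
    patience: int = 15,
    seed: int = 0,
    dup_fraction: float = 0.5,
    noise_span: tuple[float, float] = (0.05, 0.75),
    val_fraction: float = 0.1,
    max_epochs: int = 300,
) -> tuple[ModelBundle, float]:
    """80:20 split, augmentation of the training side, Adam + early stopping.

    Returns the trained bundle and the held-out test accuracy.
    """
    if np.unique(train.labels).size < 2:
        raise ValueError("training data must contain both classes")
    ss = np.random.SeedSequence(seed)
    s_split, s_aug, s_val, s_net = [np.random.default_rng(c) for c in ss.spawn(4)]

    tr_idx, te_idx = _stratified_split(train.labels, split, s_split)
    train_side = TrainingSet(
        train.features[tr_idx], train.labels[tr_idx], train.region_labels)
    augmented = augment_training(
        train_side, dup_fraction, noise_span,
        seed=int(s_aug.integers(0, 2**31)))

    val_idx, fit_idx = _stratified_split(augmented.labels, val_fraction, s_val)
    net = _MLP([augmented.features.shape[1], *HIDDEN_LAYERS, 1],
               seed=int(s_net.integers(0, 2**31)))
    history = net.fit(
        augmented.features[fit_idx], augmented.labels[fit_idx].astype(float),
        augmented.features[val_idx], augmented.labels[val_idx].astype(float),
        patience=patience, max_epochs=max_epochs)

    p_test = net.predict_proba(train.features[te_idx])
    accuracy = float(np.mean((p_test >= 0.5) == (train.labels[te_idx] == 1)))

    bundle = ModelBundle(
        net.sizes, net.W, net.b, list(train.region_labels),
        metadata={
            "seed": seed,
            "n_train_cells": int(tr_idx.size),
            "n_test_cells": int(te_idx.size),
            "test_accuracy": accuracy,
            **history,
        },
    )
    return bundle, accuracy


# ---------------------------------------------------------------------------
# prediction


def _align_features(matrix: CopyNumberMatrix, region_labels: list[str]) -> np.ndarray:
    """Order matrix columns to the model's region list, interpolating gaps.

    Regions absent from the input (or missing in a given cell) are filled
    by per-cell linear interpolation between the nearest observed flanking
    bins on the same chromosome, extending one-sidedly at chromosome ends.
    """
    regions = BinIndex.from_labels(region_labels)
    have = {lab: i for i, lab in enumerate(matrix.bins.labels())}
    n_cells = matrix.n_cells
    out = np.full((n_cells, len(regions)), np.nan)
    hits = 0
    for j, lab in enumerate(regions.labels()):
        col = have.get(lab)
        if col is not None:
            out[:, j] = matrix.values[:, col]
            hits += 1
    if hits == 0:
        raise ValueError("no overlap between the input bins and the model's region list")

    mids = regions.midpoints()
    chrom_cols = {}
    for j, chrom in enumerate(regions.chroms):
        chrom_cols.setdefault(chrom, []).append(j)
    cell_median = np.nanmedian(out, axis=1)
    for cols in chrom_cols.values():
        cols = np.asarray(cols)
        block = out[:, cols]
        nan_rows = np.flatnonzero(np.isnan(block).any(axis=1))
        for r in nan_rows:
            row = block[r]
            obs = ~np.isnan(row)
            if not obs.any():
                block[r] = cell_median[r]
                continue
            block[r] = np.interp(mids[cols], mids[cols[obs]], row[obs])
        out[:, cols] = block
    return out


def predict_states(model: ModelBundle, matrix: CopyNumberMatrix) -> pd.DataFrame:
    """Per-cell replication probability and phase label.

    Returns a DataFrame with columns ``cell_id, probability, phase``
    (phase "S" iff probability >= 0.5); no cell is dropped.
    """
    features = _align_features(matrix, model.region_labels)
    proba = model.network().predict_proba(features)
    phase = np.where(proba >= 0.5, LABEL_REPLICATING, LABEL_NON_REPLICATING)
    return pd.DataFrame(
        {"cell_id": matrix.cells, "probability": proba, "phase": phase})


def audit_discordance(calls: pd.DataFrame, external: pd.Series | dict) -> float:
    """Percentage of cells whose predicted phase disagrees with an external
    (e.g. FACS-style) label column.  Purely diagnostic."""
    if isinstance(external, dict):
        external = pd.Series(external)
    ext = calls["cell_id"].map(external)
    compared = ext.notna()
    if not compared.any():
        raise ValueError("no cells share identifiers with the external labels")
    return float(100.0 * np.mean(calls.loc[compared, "phase"].values != ext[compared].values))
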