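"""One-hot encoding and an undercomplete autoencoder anomaly scorer.

Categorical records are one-hot encoded (one binary column per domain token,
exactly one 1 per variable block) and fed through a small fully connected
autoencoder with hidden widths 16–8–16, rectified-linear hidden activations,
dropout 0.2 after each hidden layer during training, a logistic output layer,
and binary cross-entropy reconstruction loss.  Training uses Adam
(learning rate 0.001) on shuffled mini-batches of 32 for 20 epochs, on the
full table with no holdout — the scorer is unsupervised, so train and score
populations coincide.

The anomaly score of a record is its mean per-column binary cross-entropy
between input and reconstruction (dropout disabled); high scores mark
anomalies.  The network is implemented directly in numpy so that, given a
seed, training is bit-reproducible.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .findfpof import AnomalyScores
from .records import RecordTable, VariableSchema

_EPS = 1e-7  # clip for logs inside the cross-entropy
_ADAM_B1, _ADAM_B2, _ADAM_EPS = 0.9, 0.999, 1e-8


class EncodingError(ValueError):
    """A token cannot be placed in the one-hot layout."""


@dataclass(frozen=True)
class OneHotLayout:
    """Contiguous one-hot column blocks, one per variable."""

    names: tuple[str, ...]
    blocks: tuple[tuple[int, int], ...]  # (start, stop) per variable
    token_index: tuple[Mapping[str, int], ...]

    @property
    def total_width(self) -> int:
        return self.blocks[-1][1] if self.blocks else 0

    @classmethod
    def from_schema(cls, schema: Sequence[VariableSchema]) -> "OneHotLayout":
        blocks, index = [], []
        start = 0
        for v in schema:
            stop = start + v.size
            blocks.append((start, stop))
            index.append({t: start + i for i, t in enumerate(v.domain)})
            start = stop
        return cls(
            tuple(v.name for v in schema), tuple(blocks), tuple(index)
        )


def one_hot_encode(table: RecordTable, layout: OneHotLayout) -> np.ndarray:
    """(n_rows × total_width) binary matrix; exactly one 1 per variable block."""
    n = table.n_rows
    out = np.zeros((n, layout.total_width), dtype=np.float64)
    for j, name in enumerate(layout.names):
        col = table.data[name].to_numpy()
        index = layout.token_index[j]
        for i, token in enumerate(col):
            try:
                out[i, index[token]] = 1.0
            except KeyError:
                raise EncodingError(
                    f"row {table.data.index[i]}, variable {name!r}: "
                    f"token {token!r} not in layout"
                ) from None
    return out


def decode_argmax(matrix: np.ndarray, layout: OneHotLayout,
                  schema: Sequence[VariableSchema]) -> pd.DataFrame:
    """Per-block argmax decoding back to tokens (round-trip check helper)."""
    cols = {}
    for v, (start, stop) in zip(schema, layout.blocks):
        idx = matrix[:, start:stop].argmax(axis=1)
        cols[v.name] = [v.domain[i] for i in idx]
    return pd.DataFrame(cols)


@dataclass(frozen=True)
class AEConfig:
    """Autoencoder training recipe."""

    hidden_sizes: tuple[int, int, int] = (16, 8, 16)
    dropout_rate: float = 0.2
    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0,1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class TrainedAE:
    """Trained parameter state plus the training-loss trace."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    config: AEConfig
    loss_trace: list[float]
    layout: OneHotLayout | None = None

    @property
    def input_width(self) -> int:
        return self.weights[0].shape[0]

    def reconstruct(self, matrix: np.ndarray) -> np.ndarray:
        """Forward pass with dropout disabled; returns probabilities."""
        a = np.asarray(matrix, dtype=np.float64)
        if a.ndim != 2 or a.shape[1] != self.input_width:
            raise ValueError(
                f"input width {a.shape[-1]} != model width {self.input_width}"
            )
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.maximum(a @ W + b, 0.0)
        z = a @ self.weights[-1] + self.biases[-1]
        return _sigmoid(z)

    def save(self, path) -> None:
        """Parameter dump: npz with weights/biases and a JSON header."""
        arrays = {f"W{i}": W for i, W in enumerate(self.weights)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.biases)})
        arrays["loss_trace"] = np.asarray(self.loss_trace)
        meta = {
            "config": self.config.__dict__ | {"hidden_sizes": list(self.config.hidden_sizes)},
            "n_layers": len(self.weights),
        }
        arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(Path(path), **arrays)

    @classmethod
    def load(cls, path) -> "TrainedAE":
        with np.load(Path(path)) as npz:
            meta = json.loads(bytes(npz["meta"]).decode())
            cfg = meta["config"]
            cfg["hidden_sizes"] = tuple(cfg["hidden_sizes"])
            config = AEConfig(**cfg)
            nl = meta["n_layers"]
            weights = [npz[f"W{i}"] for i in range(nl)]
            biases = [npz[f"b{i}"] for i in range(nl)]
            trace = [float(x) for x in npz["loss_trace"]]
        widths = [W.shape for W in weights]
        for (a, b_), (c, d) in zip(widths[:-1], widths[1:]):
            if b_ != c:
                raise ValueError("inconsistent layer shapes in parameter dump")
        return cls(weights, biases, config, trace)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bce(x: np.ndarray, xhat: np.ndarray) -> np.ndarray:
    """Elementwise binary cross-entropy with clipped probabilities."""
    p = np.clip(xhat, _EPS, 1.0 - _EPS)
    return -(x * np.log(p) + (1.0 - x) * np.log1p(-p))


def train_autoencoder(
    matrix: np.ndarray,
    config: AEConfig | None = None,
    layout: OneHotLayout | None = None,
) -> TrainedAE:
    """Train the undercomplete autoencoder on a binary matrix.

    The bottleneck is enforced: every hidden width must be strictly below the
    input width, otherwise the network could memorize the identity and the
    reconstruction error would stop being an anomaly signal.
    """
    if config is None:
        config = AEConfig()
    X = np.asarray(matrix, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("matrix must be a non-empty 2-D array")
    if not np.isin(X, (0.0, 1.0)).all():
        raise ValueError("autoencoder input must be binary (one-hot)")
    n, width = X.shape
    if max(config.hidden_sizes) >= width:
        raise ValueError(
            f"hidden sizes {config.hidden_sizes} must be strictly below the "
            f"one-hot width {width} (undercomplete architecture)"
        )

    rng = np.random.default_rng(config.seed)
    sizes = [width, *config.hidden_sizes, width]
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        # fan-in-scaled init: sqrt(2/fan_in) for ReLU layers, sqrt(1/fan_in) output
        scale = np.sqrt(2.0 / fan_in)
        weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    weights[-1] *= np.sqrt(0.5)

    m_w = [np.zeros_like(W) for W in weights]
    v_w = [np.zeros_like(W) for W in weights]
    m_b = [np.zeros_like(b) for b in biases]
    v_b = [np.zeros_like(b) for b in biases]
    t = 0
    keep = 1.0 - config.dropout_rate
    lr = config.learning_rate
    trace: list[float] = []

    for _epoch in range(config.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            xb = X[idx]
            B = len(idx)

            # forward with inverted dropout after each hidden layer
            acts = [xb]
            masks = []
            a = xb
            for li in range(3):
                a = np.maximum(a @ weights[li] + biases[li], 0.0)
                if config.dropout_rate > 0.0:
                    mask = (rng.random(a.shape) >= config.dropout_rate) / keep
                    a = a * mask
                else:
                    mask = None
                masks.append(mask)
                acts.append(a)
            z_out = a @ weights[3] + biases[3]
            xhat = _sigmoid(z_out)

            loss = float(_bce(xb, xhat).mean())
            epoch_loss += loss * B

            # backward; loss is the mean over all B*width elements
            grad_w = [None] * 4
            grad_b = [None] * 4
            delta = (np.clip(xhat, _EPS, 1.0 - _EPS) - xb) / (B * width)
            grad_w[3] = acts[3].T @ delta
            grad_b[3] = delta.sum(axis=0)
            upstream = delta @ weights[3].T
            for li in (2, 1, 0):
                if masks[li] is not None:
                    upstream = upstream * masks[li]
                upstream = upstream * (acts[li + 1] > 0.0)
                grad_w[li] = acts[li].T @ upstream
                grad_b[li] = upstream.sum(axis=0)
                if li > 0:
                    upstream = upstream @ weights[li].T

            t += 1
            corr1 = 1.0 - _ADAM_B1**t
            corr2 = 1.0 - _ADAM_B2**t
            for li in range(4):
                m_w[li] = _ADAM_B1 * m_w[li] + (1 - _ADAM_B1) * grad_w[li]
                v_w[li] = _ADAM_B2 * v_w[li] + (1 - _ADAM_B2) * grad_w[li] ** 2
                weights[li] -= lr * (m_w[li] / corr1) / (
                    np.sqrt(v_w[li] / corr2) + _ADAM_EPS
                )
                m_b[li] = _ADAM_B1 * m_b[li] + (1 - _ADAM_B1) * grad_b[li]
                v_b[li] = _ADAM_B2 * v_b[li] + (1 - _ADAM_B2) * grad_b[li] ** 2
                biases[li] -= lr * (m_b[li] / corr1) / (
                    np.sqrt(v_b[li] / corr2) + _ADAM_EPS
                )
        trace.append(epoch_loss / n)

    return TrainedAE(weights, biases, config, trace, layout)


def reconstruction_error(
    model: TrainedAE,
    matrix: np.ndarray,
    row_ids: Sequence | None = None,
) -> AnomalyScores:
    """Per-row mean binary cross-entropy between input and reconstruction.

    Dropout is disabled; high scores mark anomalies.
    """
    X = np.asarray(matrix, dtype=np.float64)
    xhat = model.reconstruct(X)
    per_row = _bce(X, xhat).mean(axis=1)
    index = pd.Index(row_ids) if row_ids is not None else pd.RangeIndex(len(per_row))
    return AnomalyScores(
        pd.Series(per_row, index=index), orientation="high", method="autoencoder"
    )


def score_table_ae(
    table: RecordTable, config: AEConfig | None = None
) -> AnomalyScores:
    """Encode, train on the full table, and score every record.

    Rows are presented to the trainer in ascending row-id order so that the
    scores depend only on the set of (row_id, record) pairs, not on the
    incidental row order of the table.
    """
    if config is None:
        config = AEConfig()
    layout = OneHotLayout.from_schema(table.schema)
    order = np.argsort(table.row_ids, kind="stable")
    canonical = table.data.iloc[order]
    X = one_hot_encode(RecordTable([*table.schema], canonical), layout)
    model = train_autoencoder(X, config, layout)
    scored = reconstruction_error(model, X, row_ids=canonical.index)
    # return in the table's own row order
    scored.scores = scored.scores.loc[table.data.index]
    return scored
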