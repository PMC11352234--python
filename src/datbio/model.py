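"""Siamese metric-learning model over EEG epochs.

The public surface follows the Model/Results convention: build a
:class:`SiameseModel` from a matrix of epochs and their class labels,
call :meth:`~SiameseModel.fit` (contrastive-pair or triplet mode), and
work with the returned :class:`SiameseResults` — it carries the trained
encoder weights, the per-epoch loss history, and the embedding,
retrieval and ranking operations.

Only the encoder's synaptic weights are retained after training; no
per-recording descriptors are stored.  At query time the same shared
weights embed both the query and every database entry, and similarity is
the Euclidean distance between the two network outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import losses
from .nn import Adam, Encoder
from .preprocess import Epoch

__all__ = ["TrainConfig", "SiameseModel", "SiameseResults",
           "encode", "train", "retrieval_distance", "rank_database"]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the encoder and its training loop.

    ``margin`` is the contrastive margin *m* (> 0), ``alpha`` the triplet
    margin (> 0), ``embedding_dim`` the output dimensionality *n*.
    """

    margin: float = 1.0
    alpha: float = 0.5
    embedding_dim: int = 64
    epochs: int = 50
    learning_rate: float = 1e-3
    batch_size: int = 32
    seed: int = 0
    normalize: bool = True
    base_channels: int = 16
    n_blocks: int = 3

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise ValueError("contrastive margin must be > 0")
        if self.alpha <= 0:
            raise ValueError("triplet margin alpha must be > 0")
        if self.embedding_dim < 2:
            raise ValueError("embedding_dim must be >= 2")


def _standardize(X: np.ndarray) -> np.ndarray:
    """Per-epoch z-scoring; constant epochs map to zero."""
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    return (X - mu) / np.maximum(sd, 1e-12)


def _as_matrix(epochs) -> np.ndarray:
    if isinstance(epochs, np.ndarray):
        return np.atleast_2d(np.asarray(epochs, dtype=float))
    return np.stack([e.samples if isinstance(e, Epoch) else np.asarray(e)
                     for e in epochs]).astype(float)


class SiameseModel:
    """Metric-learning model built from labeled EEG epochs.

    Parameters
    ----------
    epochs : (n_epochs, epoch_len) array or list of Epoch
        Training inputs; all must share one length.
    labels : (n_epochs,) array
        Class label per epoch (e.g. 0 = rest, 1 = during-therapy).  At
        least two classes are required to form pairs/triplets.
    config : TrainConfig
    """

    def __init__(self, epochs, labels, config: TrainConfig | None = None):
        self.X = _as_matrix(epochs)
        self.y = np.asarray(labels)
        if self.X.shape[0] != self.y.size:
            raise ValueError("epochs and labels disagree in length")
        self.classes = np.unique(self.y)
        if self.classes.size < 2:
            raise ValueError(
                "need at least two classes to form negative pairs; got "
                f"{self.classes.size}")
        self.config = config or TrainConfig()

    @classmethod
    def from_epochs(cls, epochs: list[Epoch], positive_phase: str = "during",
                    config: TrainConfig | None = None) -> "SiameseModel":
        """Build from Epoch objects, labeling by therapy phase.

        Rest phases (before/after) become class 0, the during-therapy
        phase class 1.
        """
        labels = np.array([1 if e.phase == positive_phase else 0 for e in epochs])
        return cls(epochs, labels, config)

    # --- sampling -----------------------------------------------------------

    def _sample_triplets(self, rng: np.random.Generator, k: int):
        idx_by_class = {c: np.nonzero(self.y == c)[0] for c in self.classes}
        anchors = rng.integers(0, self.X.shape[0], size=k)
        pos = np.empty(k, dtype=int)
        neg = np.empty(k, dtype=int)
        for j, a in enumerate(anchors):
            same = idx_by_class[self.y[a]]
            pos[j] = same[rng.integers(0, same.size)]
            other_classes = [c for c in self.classes if c != self.y[a]]
            oc = other_classes[rng.integers(0, len(other_classes))]
            diff = idx_by_class[oc]
            neg[j] = diff[rng.integers(0, diff.size)]
        return anchors, pos, neg

    def _sample_pairs(self, rng: np.random.Generator, k: int):
        a, p, n = self._sample_triplets(rng, k)
        # half the batch positive pairs, half negative
        half = k // 2
        left = a
        right = np.concatenate([p[:half], n[half:]])
        y = np.concatenate([np.ones(half), np.zeros(k - half)])
        return left, right, y

    # --- fitting ------------------------------------------------------------

    def fit(self, mode: str = "triplet") -> "SiameseResults":
        """Train the shared encoder; deterministic given the config seed.

        Returns a :class:`SiameseResults` carrying the final weights and a
        per-epoch training log.
        """
        if mode not in ("siamese", "triplet"):
            raise ValueError(f"mode must be 'siamese' or 'triplet', got {mode!r}")
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        Xz = _standardize(self.X)
        encoder = Encoder(input_len=self.X.shape[1],
                          embedding_dim=cfg.embedding_dim,
                          base_channels=cfg.base_channels,
                          n_blocks=cfg.n_blocks,
                          normalize=cfg.normalize,
                          seed=cfg.seed)
        opt = Adam(encoder.params(), lr=cfg.learning_rate)
        n = self.X.shape[0]
        steps = max(1, n // cfg.batch_size)
        history = []
        for ep in range(cfg.epochs):
            ep_loss = 0.0
            for _ in range(steps):
                if mode == "triplet":
                    a, p, ng = self._sample_triplets(rng, cfg.batch_size)
                    stacked = np.concatenate([Xz[a], Xz[p], Xz[ng]])
                    emb = encoder.forward(stacked)
                    ea, ep_, en = np.split(emb, 3)
                    loss = losses.triplet_loss(ea, ep_, en, cfg.alpha,
                                               reduction="mean")
                    ga, gp, gn = losses.triplet_loss_grads(ea, ep_, en, cfg.alpha)
                    encoder.backward(np.concatenate([ga, gp, gn]))
                else:
                    l_idx, r_idx, yb = self._sample_pairs(rng, cfg.batch_size)
                    stacked = np.concatenate([Xz[l_idx], Xz[r_idx]])
                    emb = encoder.forward(stacked)
                    e1, e2 = np.split(emb, 2)
                    d = np.linalg.norm(e1 - e2, axis=1)
                    loss = float(np.mean([
                        losses.contrastive_loss(di, int(yi), cfg.margin)
                        for di, yi in zip(d, yb)
                    ]))
                    g1, g2 = losses.contrastive_loss_grads(e1, e2, yb, cfg.margin)
                    encoder.backward(np.concatenate([g1, g2]))
                opt.step()
                ep_loss += loss
            history.append({"epoch": ep, "loss": ep_loss / steps})
        return SiameseResults(model=self, encoder=encoder, mode=mode,
                              history=pd.DataFrame(history))


@dataclass
class SiameseResults:
    """Trained encoder weights plus training diagnostics.

    Exposes the embedding (``encode``), retrieval distance, database
    ranking and a ``summary()`` table.
    """

    model: SiameseModel | None
    encoder: Encoder
    mode: str
    history: pd.DataFrame = field(default_factory=pd.DataFrame)

    def encode(self, epochs) -> np.ndarray:
        """Embed epochs with the trained shared weights; (k, dim) array."""
        X = _as_matrix(epochs)
        return self.encoder.forward(_standardize(X))

    def retrieval_distance(self, query: np.ndarray, reference: np.ndarray) -> float:
        """Euclidean distance between two embeddings (the similarity stage)."""
        return losses.pair_distance(query, reference)

    def rank_database(self, query: np.ndarray, db: np.ndarray) -> list[int]:
        """Indices of *db* rows sorted by ascending distance to *query*.

        Ties break by insertion order (stable sort).
        """
        db = np.atleast_2d(db)
        if db.shape[0] == 0:
            raise ValueError("database is empty")
        dists = np.linalg.norm(db - np.asarray(query)[None, :], axis=1)
        return list(np.argsort(dists, kind="stable"))

    def final_loss(self) -> float:
        return float(self.history["loss"].iloc[-1])

    def summary(self) -> str:
        cfg = self.model.config if self.model is not None else TrainConfig()
        lines = [
            "Siamese metric-learning results",
            "=" * 39,
            f"mode:             {self.mode}",
            f"embedding dim:    {self.encoder.embedding_dim}",
            f"normalized:       {self.encoder.normalize}",
            f"training epochs:  {len(self.history)}",
            f"batch size:       {cfg.batch_size}",
            f"learning rate:    {cfg.learning_rate:g}",
            f"margin (m/alpha): {cfg.margin:g} / {cfg.alpha:g}",
        ]
        if len(self.history):
            lines.append(f"first-epoch loss: {self.history['loss'].iloc[0]:.6f}")
            lines.append(f"final-epoch loss: {self.history['loss'].iloc[-1]:.6f}")
        return "\n".join(lines)

    # --- persistence (arrays + json manifest) -------------------------------

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", **self.encoder.get_weights())
        manifest = {"mode": self.mode, "encoder": self.encoder.config}
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
        if len(self.history):
            self.history.to_csv(directory / "history.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, directory) -> "SiameseResults":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        enc_cfg = manifest["encoder"]
        encoder = Encoder(**enc_cfg)
        with np.load(directory / "weights.npz") as archive:
            encoder.set_weights({k: archive[k] for k in archive.files})
        hist_path = directory / "history.tsv"
        history = (pd.read_csv(hist_path, sep="\t") if hist_path.exists()
                   else pd.DataFrame())
        return cls(model=None, encoder=encoder, mode=manifest["mode"],
                   history=history)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def encode(encoder: Encoder, series: np.ndarray) -> np.ndarray:
    """Embed one epoch with the given encoder state."""
    out = encoder.forward(np.asarray(series, dtype=float))
    return out[0]


def train(epochs, labels, config: TrainConfig | None = None,
          mode: str = "triplet") -> SiameseResults:
    """Fit a :class:`SiameseModel`; convenience functional form."""
    return SiameseModel(epochs, labels, config).fit(mode=mode)


def retrieval_distance(query: np.ndarray, reference: np.ndarray) -> float:
    """Euclidean distance between a query and a reference embedding."""
    return losses.pair_distance(query, reference)


def rank_database(query: np.ndarray, db: np.ndarray) -> list[int]:
    """Rank database embeddings by ascending distance to the query."""
    db = np.atleast_2d(db)
    if db.shape[0] == 0:
        raise ValueError("database is empty")
    dists = np.linalg.norm(db - np.asarray(query)[None, :], axis=1)
    return list(np.argsort(dists, kind="stable"))
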