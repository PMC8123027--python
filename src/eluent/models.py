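"""Predictive networks and hierarchical inference.

Two tasks share one family of architectures: a multilabel classifier
scoring the 10 solvents with sigmoid outputs (binary cross-entropy), and
a ratio regressor with a single linear output (mean squared error).  Each
can consume any of the three vectorizations: learned-embedding token
sequences (LE), raw 8x512 fingerprint matrices (ECFP), or frozen
auto-encoder latents (ECFP+E, always with the feed-forward head).

Inference is hierarchical: the classifier picks 1-2 solvents, and only
when it picks two is the regressor consulted for the ratio of the first.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .autoencoder import TrainedEncoder
from .nn import (
    AvgPool1D,
    Conv1D,
    Dense,
    Embedding,
    Flatten,
    LSTM,
    ReLU,
    Sequential,
    Sigmoid,
    Transpose12,
    bce_loss,
    fit,
    mse_loss,
)
from .nn.training import predict as batched_forward
from .records import (
    CANONICAL_SOLVENTS,
    Dataset,
    ReactionRecord,
    TRAIN,
    canonical_order,
)
from .vectorize import (
    FP_BITS,
    MAX_SEQUENCE_LENGTH,
    TokenVocabulary,
    fingerprint_batch,
    token_batch,
)

logger = logging.getLogger(__name__)

TASKS = ("solvents", "ratio")
VECTORIZATIONS = ("LE", "ECFP", "ECFP+E")
NETS = ("ffnn", "cnn1d", "lstm")

N_LABELS = len(CANONICAL_SOLVENTS)
RATIO_EPS = 1e-3


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Task, vectorization, network type and hyperparameters of one model."""

    task: str = "solvents"
    vectorization: str = "ECFP"
    net: str = "ffnn"
    encoder_flavour: Optional[str] = None  # AE family, for ECFP+E only
    hidden_sizes: tuple[int, int, int] = (256, 128, 64)
    lstm_hidden: int = 512
    embedding_dim: int = 12
    epochs: int = 40
    batch_size: int = 256
    val_fraction: float = 0.10
    learning_rate: float = 1e-3
    products_only: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ConfigError(f"task must be one of {TASKS}")
        if self.vectorization not in VECTORIZATIONS:
            raise ConfigError(f"vectorization must be one of {VECTORIZATIONS}")
        if self.net not in NETS:
            raise ConfigError(f"net must be one of {NETS}")
        if self.vectorization == "ECFP+E" and self.net != "ffnn":
            # the head over latents is always the feed-forward one; the AE
            # family is chosen via encoder_flavour
            raise ConfigError(
                "ECFP+E uses the FFNN head; select the auto-encoder family "
                "with encoder_flavour"
            )
        if self.products_only and self.vectorization != "ECFP":
            raise ConfigError("products_only applies to ECFP vectorization")

    @property
    def n_outputs(self) -> int:
        return N_LABELS if self.task == "solvents" else 1


def _head(rng: np.random.Generator, d_in: int, config: ModelConfig) -> list:
    layers: list = []
    d = d_in
    for size in config.hidden_sizes:
        layers += [Dense(d, size, rng), ReLU()]
        d = size
    layers.append(Dense(d, config.n_outputs, rng))
    if config.task == "solvents":
        layers.append(Sigmoid())
    return layers


def _conv_stack(rng: np.random.Generator, c_in: int) -> tuple[list, int]:
    """Three 64-filter convolutions (kernels 12, 12, 5), avg pools of 3."""
    layers = [
        Conv1D(c_in, 64, 12, rng), ReLU(), AvgPool1D(3),
        Conv1D(64, 64, 12, rng), ReLU(), AvgPool1D(3),
        Conv1D(64, 64, 5, rng), ReLU(), AvgPool1D(3),
    ]
    return layers, 64


def build_model(
    config: ModelConfig,
    vocab_size: Optional[int] = None,
    latent_dim: int = FP_BITS,
) -> Sequential:
    """Construct the untrained network for a config combination.

    ``latent_dim`` sizes the ECFP+E head input and must match the frozen
    encoder's latent dimension (512 by default).
    """
    rng = np.random.default_rng(config.seed)
    vec, net = config.vectorization, config.net

    if vec == "ECFP+E":
        return Sequential(_head(rng, latent_dim, config))
    if config.products_only:
        return Sequential(_head(rng, FP_BITS, config))

    if vec == "LE":
        if vocab_size is None:
            raise ConfigError("LE vectorization needs the vocabulary size")
        emb = Embedding(vocab_size, config.embedding_dim, rng)
        if net == "ffnn":
            d_in = MAX_SEQUENCE_LENGTH * config.embedding_dim
            return Sequential([emb, Flatten()] + _head(rng, d_in, config))
        if net == "cnn1d":
            convs, channels = _conv_stack(rng, config.embedding_dim)
            length = MAX_SEQUENCE_LENGTH
            for _ in range(3):
                length //= 3
            tail = [Flatten(), Dense(length * channels, 64, rng), ReLU(),
                    Dense(64, config.n_outputs, rng)]
            if config.task == "solvents":
                tail.append(Sigmoid())
            return Sequential([emb] + convs + tail)
        # lstm
        out = [Dense(config.lstm_hidden, config.n_outputs, rng)]
        if config.task == "solvents":
            out.append(Sigmoid())
        return Sequential(
            [emb, LSTM(config.embedding_dim, config.lstm_hidden, rng)] + out
        )

    # vec == "ECFP": input (B, 8, 512)
    if net == "ffnn":
        d_in = 8 * FP_BITS
        return Sequential([Flatten()] + _head(rng, d_in, config))
    if net == "cnn1d":
        convs, channels = _conv_stack(rng, 8)
        length = FP_BITS
        for _ in range(3):
            length //= 3
        tail = [Flatten(), Dense(length * channels, 64, rng), ReLU(),
                Dense(64, config.n_outputs, rng)]
        if config.task == "solvents":
            tail.append(Sigmoid())
        return Sequential([Transpose12()] + convs + tail)
    # lstm over the 8 fingerprint rows
    out = [Dense(config.lstm_hidden, config.n_outputs, rng)]
    if config.task == "solvents":
        out.append(Sigmoid())
    return Sequential([LSTM(FP_BITS, config.lstm_hidden, rng)] + out)


def multi_hot(label_sets: Sequence[tuple[str, ...]]) -> np.ndarray:
    """Label sets -> (n, 10) binary target matrix in canonical label order."""
    index = {name: i for i, name in enumerate(CANONICAL_SOLVENTS)}
    out = np.zeros((len(label_sets), N_LABELS))
    for row, labels in enumerate(label_sets):
        for name in labels:
            out[row, index[name]] = 1.0
    return out


def vectorize_records(
    config: ModelConfig,
    records: Sequence[ReactionRecord],
    vocab: Optional[TokenVocabulary] = None,
    encoder: Optional[TrainedEncoder] = None,
) -> np.ndarray:
    """Produce the input array a model with ``config`` expects."""
    if config.vectorization == "LE":
        if vocab is None:
            raise ConfigError("LE vectorization needs a vocabulary")
        return token_batch(records, vocab)
    matrices = fingerprint_batch(records, products_only=config.products_only)
    if config.vectorization == "ECFP+E":
        if encoder is None:
            raise ConfigError("ECFP+E vectorization needs a trained encoder")
        return encoder.encode_batch(matrices)
    return matrices


@dataclass
class TrainedModel:
    """A trained network plus everything needed to vectorize new input."""

    config: ModelConfig
    net: Sequential
    history: dict = field(default_factory=dict)
    vocab: Optional[TokenVocabulary] = None
    encoder: Optional[TrainedEncoder] = None

    def predict_scores(self, records: Sequence[ReactionRecord]) -> np.ndarray:
        x = vectorize_records(self.config, records, self.vocab, self.encoder)
        return batched_forward(self.net, x, self.config.batch_size)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        np.savez(path, *self.net.get_weights())
        sidecar = {
            "config": asdict(self.config),
            "vocab": self.vocab.index_of if self.vocab else None,
            "history": self.history,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2)
        )

    @classmethod
    def load(
        cls, path: str | Path, encoder: Optional[TrainedEncoder] = None
    ) -> "TrainedModel":
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        raw = dict(sidecar["config"])
        raw["hidden_sizes"] = tuple(raw["hidden_sizes"])
        config = ModelConfig(**raw)
        vocab = (
            TokenVocabulary(dict(sidecar["vocab"])) if sidecar["vocab"] else None
        )
        latent_dim = encoder.spec.latent_dim if encoder is not None else FP_BITS
        net = build_model(config, vocab.size if vocab else None, latent_dim)
        with np.load(path) as archive:
            keys = sorted(archive.files, key=lambda k: int(k.split("_")[-1]))
            net.set_weights([archive[k] for k in keys])
        return cls(config, net, sidecar.get("history", {}), vocab, encoder)


def train(
    config: ModelConfig,
    dataset: Dataset,
    vocab: Optional[TokenVocabulary] = None,
    encoder: Optional[TrainedEncoder] = None,
) -> TrainedModel:
    """Vectorize the training subset and fit the network.

    Uses the train split if the dataset carries one (never the test split),
    a further seeded 90/10 train/validation split inside, Adam, and the
    config's batch/epoch settings.  For LE a vocabulary is built from the
    training reactions when not supplied.
    """
    source = dataset.subset(TRAIN) if dataset.is_split else dataset
    records = [rec for rec, _ in source.instances]
    systems = [system for _, system in source.instances]
    if config.vectorization == "LE" and vocab is None:
        from .vectorize import build_vocabulary

        vocab = build_vocabulary(r.reaction_smiles for r in records)
    if config.vectorization == "ECFP+E" and encoder is None:
        raise ConfigError("ECFP+E training needs a trained, frozen encoder")

    x = vectorize_records(config, records, vocab, encoder)
    if config.task == "solvents":
        y = multi_hot([s.labels for s in systems])
        loss = bce_loss
    else:
        ratios = [s.ratio for s in systems]
        if any(r is None for r in ratios):
            raise ConfigError("ratio training requires DS2-style instances")
        y = np.asarray(ratios, dtype=float)[:, None]
        loss = mse_loss

    latent_dim = encoder.spec.latent_dim if encoder is not None else FP_BITS
    net = build_model(config, vocab.size if vocab else None, latent_dim)
    history = fit(
        net,
        x,
        y,
        loss,
        epochs=config.epochs,
        batch_size=config.batch_size,
        val_fraction=config.val_fraction,
        lr=config.learning_rate,
        seed=config.seed,
    )
    return TrainedModel(config, net, history, vocab, encoder)


def decide_labels(
    label_scores: np.ndarray, threshold: float = 0.5
) -> tuple[str, ...]:
    """Turn 10 sigmoid scores into a canonical 1-2 label prediction.

    Labels scoring >= threshold are kept, clipped to the top two by score
    (the label space never holds more than two solvents); with no score
    above threshold the single argmax is returned.  Ties break by
    canonical priority.
    """
    scores = np.asarray(label_scores, dtype=float)
    if scores.shape != (N_LABELS,):
        raise ValueError(f"expected {N_LABELS} scores, got shape {scores.shape}")
    order = sorted(range(N_LABELS), key=lambda i: (-scores[i], i))
    passing = [i for i in order if scores[i] >= threshold][:2]
    if not passing:
        passing = [order[0]]
    return tuple(canonical_order(CANONICAL_SOLVENTS[i] for i in passing))


@dataclass(frozen=True)
class PredictionOutput:
    """Hierarchical prediction: scores, decided labels, optional ratio."""

    label_scores: tuple[float, ...]
    predicted_labels: tuple[str, ...]
    ratio: Optional[float] = None

    @property
    def complement(self) -> Optional[float]:
        return None if self.ratio is None else 1.0 - self.ratio

    def to_dict(self) -> dict:
        return {
            "labels": list(self.predicted_labels),
            "ratio": self.ratio,
            "scores": {
                name: score
                for name, score in zip(CANONICAL_SOLVENTS, self.label_scores)
            },
        }


def predict_system(
    classifier: TrainedModel,
    regressor: Optional[TrainedModel],
    record: ReactionRecord,
    threshold: float = 0.5,
) -> PredictionOutput:
    """Run the two models in sequence on one reaction.

    The classifier decides the solvent labels; only when it predicts two
    solvents is the ratio regressor activated.  Raw regressor output is
    clipped into (0, 1) with a warning, and the stored ratio refers to the
    first label in canonical order (complement = 1 - ratio).
    """
    if classifier.config.task != "solvents":
        raise ConfigError("classifier must be a solvents-task model")
    scores = classifier.predict_scores([record])[0]
    labels = decide_labels(scores, threshold)
    ratio = None
    if len(labels) == 2 and regressor is not None:
        if regressor.config.task != "ratio":
            raise ConfigError("regressor must be a ratio-task model")
        if regressor.config.vectorization != classifier.config.vectorization:
            raise ConfigError(
                "classifier and regressor use different vectorizations: "
                f"{classifier.config.vectorization} vs "
                f"{regressor.config.vectorization}"
            )
        raw = float(regressor.predict_scores([record])[0, 0])
        ratio = min(max(raw, RATIO_EPS), 1.0 - RATIO_EPS)
        if ratio != raw:
            logger.warning(
                "regressor output %.4f outside (0, 1); clipped to %.4f",
                raw, ratio,
            )
    return PredictionOutput(tuple(float(s) for s in scores), labels, ratio)
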