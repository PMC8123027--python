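"""Fingerprint auto-encoders: compress 8x512 reaction ECFPs to 512 reals.

Three encoder families are supported, mirroring the shapes of the
fingerprint input:

* ``ffnn``   — flattened 4096-bit input, one latent dense layer;
* ``cnn1d``  — three 1-D convolutions (256, 128, 64 filters; kernels
  12, 10, 10) with pool-2 stages along the 512-bit axis (8 input
  channels), then a dense latent layer; the decoder mirrors it with
  kernel-1 convolutions and nearest-neighbour upsampling;
* ``lstm``   — one LSTM layer reading the 8 fingerprint rows as a
  sequence; its final hidden state is the latent code, and the decoder
  repeats it 8 times through a second LSTM.

All are trained with binary cross-entropy to reconstruct their input;
after training the encoder is frozen (weights marked untrainable) and
used as a fixed vectorizer producing 512-real latent codes — a factor-8
compression of the 4096-bit flattened fingerprint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .nn import (
    AvgPool1D,
    Conv1D,
    Dense,
    Flatten,
    LSTM,
    ReLU,
    RepeatVector,
    Reshape,
    Sequential,
    Sigmoid,
    Transpose12,
    UpSample1D,
    bce_loss,
    fit,
    weight_hash,
)
from .records import MAX_MOLECULES
from .vectorize import FP_BITS, ReactionFingerprint

FLAVOURS = ("ffnn", "cnn1d", "lstm")
LATENT_GRID = (32, 64, 128, 256, 512)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class AutoencoderSpec:
    """Architecture + training configuration of a fingerprint auto-encoder."""

    flavour: str = "ffnn"
    latent_dim: int = 512
    batch_size: int = 256
    epochs: int = 40
    learning_rate: float = 1e-3
    holdout_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.flavour not in FLAVOURS:
            raise ConfigError(f"flavour must be one of {FLAVOURS}")
        if self.latent_dim not in LATENT_GRID:
            raise ConfigError(
                f"latent_dim must be in the tested grid {LATENT_GRID}, "
                f"got {self.latent_dim}"
            )

    @property
    def input_shape(self) -> tuple[int, int]:
        return (MAX_MOLECULES, FP_BITS)


@dataclass
class Autoencoder:
    spec: AutoencoderSpec
    encoder: Sequential
    decoder: Sequential

    @property
    def full(self) -> Sequential:
        return Sequential([self.encoder, self.decoder])

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.full.params())


def build_autoencoder(spec: AutoencoderSpec, seed: int = 0) -> Autoencoder:
    """Construct an untrained auto-encoder whose decoder restores 8x512."""
    rng = np.random.default_rng(seed)
    latent = spec.latent_dim
    if spec.flavour == "ffnn":
        encoder = Sequential([
            Flatten(),
            Dense(MAX_MOLECULES * FP_BITS, latent, rng),
            ReLU(),
        ])
        decoder = Sequential([
            Dense(latent, MAX_MOLECULES * FP_BITS, rng),
            Sigmoid(),
            Reshape((MAX_MOLECULES, FP_BITS)),
        ])
    elif spec.flavour == "cnn1d":
        # convolve along the 512-bit axis; the 8 molecule rows are channels
        encoder = Sequential([
            Transpose12(),                      # (B, 512, 8)
            Conv1D(8, 256, 12, rng), ReLU(), AvgPool1D(2),   # (B, 256, 256)
            Conv1D(256, 128, 10, rng), ReLU(), AvgPool1D(2),  # (B, 128, 128)
            Conv1D(128, 64, 10, rng), ReLU(), AvgPool1D(2),   # (B, 64, 64)
            Flatten(),
            Dense(64 * 64, latent, rng),
            ReLU(),
        ])
        decoder = Sequential([
            Dense(latent, 64 * 64, rng), ReLU(),
            Reshape((64, 64)),
            Conv1D(64, 64, 1, rng), ReLU(), UpSample1D(2),
            Conv1D(64, 128, 1, rng), ReLU(), UpSample1D(2),
            Conv1D(128, 256, 1, rng), ReLU(), UpSample1D(2),
            Conv1D(256, 8, 1, rng), Sigmoid(),
            Transpose12(),                      # (B, 8, 512)
        ])
    else:  # lstm
        encoder = Sequential([
            LSTM(FP_BITS, latent, rng, return_sequences=False),
        ])
        decoder = Sequential([
            RepeatVector(MAX_MOLECULES),
            LSTM(latent, latent, rng, return_sequences=True),
            Dense(latent, FP_BITS, rng),
            Sigmoid(),
        ])
    return Autoencoder(spec, encoder, decoder)


@dataclass
class TrainedEncoder:
    """A frozen encoder: a pure function from 8x512 matrices to latents."""

    spec: AutoencoderSpec
    encoder: Sequential
    training_history: dict = field(default_factory=dict)
    holdout_bce: Optional[float] = None
    frozen: bool = True

    def __post_init__(self) -> None:
        for p in self.encoder.params():
            p.trainable = False

    def encode(self, fingerprint: ReactionFingerprint | np.ndarray) -> np.ndarray:
        """Map one reaction fingerprint to its latent vector."""
        matrix = (
            fingerprint.matrix
            if isinstance(fingerprint, ReactionFingerprint)
            else np.asarray(fingerprint)
        )
        if matrix.shape != self.spec.input_shape:
            raise ConfigError(
                f"expected {self.spec.input_shape} input, got {matrix.shape}"
            )
        return self.encoder.forward(matrix[None])[0]

    def encode_batch(self, matrices: np.ndarray, batch_size: int = 256) -> np.ndarray:
        if matrices.ndim != 3 or matrices.shape[1:] != self.spec.input_shape:
            raise ConfigError(
                f"expected (n, {self.spec.input_shape[0]}, "
                f"{self.spec.input_shape[1]}), got {matrices.shape}"
            )
        chunks = [
            self.encoder.forward(matrices[i : i + batch_size])
            for i in range(0, len(matrices), batch_size)
        ]
        return np.concatenate(chunks, axis=0)

    @property
    def weight_digest(self) -> str:
        return weight_hash(self.encoder)

    def save(self, path: str | Path) -> None:
        """Write weights (npz) with a JSON sidecar describing the spec."""
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        np.savez(path, *self.encoder.get_weights())
        sidecar = {
            "spec": asdict(self.spec),
            "holdout_bce": self.holdout_bce,
            "weight_digest": self.weight_digest,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2)
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedEncoder":
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        sidecar = json.loads(
            path.with_suffix(path.suffix + ".json").read_text()
        )
        spec = AutoencoderSpec(**sidecar["spec"])
        model = build_autoencoder(spec, seed=0)
        with np.load(path) as archive:
            keys = sorted(archive.files, key=lambda k: int(k.split("_")[-1]))
            weights = [archive[k] for k in keys]
        model.encoder.set_weights(weights)
        trained = cls(spec, model.encoder, holdout_bce=sidecar.get("holdout_bce"))
        if trained.weight_digest != sidecar["weight_digest"]:
            raise ConfigError(f"{path}: weight digest mismatch")
        return trained


def train_autoencoder(
    model: Autoencoder,
    fingerprints: np.ndarray,
    seed: int = 0,
) -> TrainedEncoder:
    """Train to reconstruct fingerprints, then freeze and return the encoder.

    ``fingerprints`` is an (n, 8, 512) binary array.  A 10% held-out slice
    (seeded) provides the reported reconstruction BCE; training uses the
    spec's Adam/batch/epoch settings and aborts on divergence.
    """
    spec = model.spec
    if fingerprints.ndim != 3 or fingerprints.shape[1:] != spec.input_shape:
        raise ConfigError(
            f"expected (n, {spec.input_shape[0]}, {spec.input_shape[1]}), "
            f"got {fingerprints.shape}"
        )
    x = np.asarray(fingerprints, dtype=np.float64)
    history = fit(
        model.full,
        x,
        x,
        bce_loss,
        epochs=spec.epochs,
        batch_size=spec.batch_size,
        val_fraction=spec.holdout_fraction,
        lr=spec.learning_rate,
        seed=seed,
    )
    holdout = history["val_loss"][-1] if history["val_loss"] else None
    return TrainedEncoder(
        spec, model.encoder, training_history=history, holdout_bce=holdout
    )
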