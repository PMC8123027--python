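"""Reaction vectorization: token sequences and fingerprint matrices.

Three input representations feed the downstream networks:

* **Learned embedding (LE)** — the reaction SMILES is treated as a
  character sequence, indexed against a vocabulary built from the training
  corpus, and padded/truncated to a fixed length of 200.  The 12-dim
  embedding itself is learned jointly with the model.
* **ECFP** — each molecule is hashed to a 512-bit Morgan/extended-
  connectivity fingerprint (radius 2); the up-to-8 molecules of a reaction
  stack into an 8x512 binary matrix, zero rows padding, with a row-major
  4096-bit flattened view.
* **ECFP+E** — the 8x512 matrix compressed by a trained fingerprint
  auto-encoder into a 512-real latent vector (see ``eluent.autoencoder``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from rdkit.Chem import rdFingerprintGenerator

from .records import MAX_MOLECULES, MalformedRecordError, Molecule, ReactionRecord

logger = logging.getLogger(__name__)

MAX_SEQUENCE_LENGTH = 200
FP_BITS = 512
FP_RADIUS = 2
FLAT_BITS = MAX_MOLECULES * FP_BITS  # 4096


@dataclass(frozen=True)
class TokenVocabulary:
    """Character -> dense index map with reserved PAD and UNK entries.

    Built from the training corpus only; characters unseen at encoding
    time map to UNK.  Ordering is first-seen, so the build is
    deterministic for a fixed corpus order.
    """

    index_of: dict
    pad_index: int = 0
    unk_index: int = 1

    @property
    def size(self) -> int:
        return len(self.index_of) + 2

    def encode_char(self, char: str) -> int:
        return self.index_of.get(char, self.unk_index)


def build_vocabulary(corpus: Iterable[str]) -> TokenVocabulary:
    """One vocabulary entry per distinct character observed, plus PAD/UNK."""
    index_of: dict = {}
    empty = True
    for line in corpus:
        empty = False
        for char in line:
            if char not in index_of:
                index_of[char] = len(index_of) + 2  # 0=PAD, 1=UNK
    if empty:
        raise ValueError("empty corpus")
    return TokenVocabulary(index_of)


def tokenize(
    reaction_smiles: str,
    vocab: TokenVocabulary,
    max_len: int = MAX_SEQUENCE_LENGTH,
) -> np.ndarray:
    """Character-level index sequence, right-padded/truncated to ``max_len``."""
    if len(reaction_smiles) > max_len:
        logger.warning(
            "sequence of %d chars truncated to %d", len(reaction_smiles), max_len
        )
        reaction_smiles = reaction_smiles[:max_len]
    out = np.full(max_len, vocab.pad_index, dtype=np.int64)
    for i, char in enumerate(reaction_smiles):
        out[i] = vocab.encode_char(char)
    return out


_fp_generators: dict[tuple[int, int], object] = {}


def _generator(n_bits: int, radius: int):
    key = (n_bits, radius)
    if key not in _fp_generators:
        _fp_generators[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits
        )
    return _fp_generators[key]


def ecfp(
    molecule: Molecule | str, n_bits: int = FP_BITS, radius: int = FP_RADIUS
) -> np.ndarray:
    """Binary Morgan/ECFP bit vector of one molecule.

    A pure function of the molecular graph: SMILES that differ only in
    atom numbering (e.g. kekulized vs aromatic benzene) hash to identical
    vectors.
    """
    if isinstance(molecule, str):
        molecule = Molecule(molecule)
    mol = molecule.to_mol()  # raises MalformedRecordError naming the SMILES
    bits = _generator(n_bits, radius).GetFingerprintAsNumPy(mol)
    return bits.astype(np.float32)


@dataclass(frozen=True)
class ReactionFingerprint:
    """8x512 binary matrix, one ECFP row per molecule, zero rows padding."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        if self.matrix.shape != (MAX_MOLECULES, FP_BITS):
            raise ValueError(
                f"expected shape {(MAX_MOLECULES, FP_BITS)}, got {self.matrix.shape}"
            )

    @property
    def flattened(self) -> np.ndarray:
        """Row-major 4096-bit view; reshaping back recovers the matrix."""
        return self.matrix.reshape(-1)

    @property
    def n_molecules(self) -> int:
        return int(np.any(self.matrix != 0, axis=1).sum())


def reaction_fingerprint(
    record: ReactionRecord,
    n_bits: int = FP_BITS,
    radius: int = FP_RADIUS,
    products_only: bool = False,
) -> ReactionFingerprint | np.ndarray:
    """Stack per-molecule ECFPs into the fixed-shape reaction matrix.

    Row order follows molecule order, which is what makes permutation
    augmentation meaningful.  With ``products_only=True`` the result is a
    single 512-bit vector: the union of the product molecules' bits (the
    reduced input variant for product-only prediction).
    """
    if products_only:
        rows = [
            ecfp(m, n_bits, radius)
            for m, is_prod in zip(record.molecules, record.product_flags)
            if is_prod
        ]
        if not rows:
            raise MalformedRecordError(
                f"record {record.record_id}: no product molecules"
            )
        return (np.sum(rows, axis=0) > 0).astype(np.float32)
    if len(record.molecules) > MAX_MOLECULES:
        raise MalformedRecordError(
            f"record {record.record_id}: more than {MAX_MOLECULES} molecules"
        )
    matrix = np.zeros((MAX_MOLECULES, n_bits), dtype=np.float32)
    for i, mol in enumerate(record.molecules):
        matrix[i] = ecfp(mol, n_bits, radius)
    return ReactionFingerprint(matrix)


def fingerprint_batch(
    records: Sequence[ReactionRecord],
    n_bits: int = FP_BITS,
    radius: int = FP_RADIUS,
    products_only: bool = False,
) -> np.ndarray:
    """Vectorize many records: (n, 8, 512) matrices or (n, 512) product bits."""
    cache: dict[str, np.ndarray] = {}

    def cached_ecfp(mol: Molecule) -> np.ndarray:
        if mol.smiles not in cache:
            cache[mol.smiles] = ecfp(mol, n_bits, radius)
        return cache[mol.smiles]

    if products_only:
        out = np.zeros((len(records), n_bits), dtype=np.float32)
        for i, rec in enumerate(records):
            rows = [
                cached_ecfp(m)
                for m, is_prod in zip(rec.molecules, rec.product_flags)
                if is_prod
            ]
            if not rows:
                raise MalformedRecordError(
                    f"record {rec.record_id}: no product molecules"
                )
            out[i] = (np.sum(rows, axis=0) > 0).astype(np.float32)
        return out
    out = np.zeros((len(records), MAX_MOLECULES, n_bits), dtype=np.float32)
    for i, rec in enumerate(records):
        for j, mol in enumerate(rec.molecules):
            out[i, j] = cached_ecfp(mol)
    return out


def token_batch(
    records: Sequence[ReactionRecord],
    vocab: TokenVocabulary,
    max_len: int = MAX_SEQUENCE_LENGTH,
) -> np.ndarray:
    """Tokenize many records into an (n, max_len) int index array."""
    return np.stack([tokenize(r.reaction_smiles, vocab, max_len) for r in records])
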