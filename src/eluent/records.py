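"""Core domain types for chromatography-condition prediction.

A reaction is a dot-separated multi-molecule SMILES string plus the raw
purification text mined from the synthesis procedure.  The prediction
targets are a solvent *system* — one or two of ten canonical normal-phase
solvents — and, for binary systems, the volume fraction of the first
solvent (in canonical order) in the eluent mixture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

# RDKit is chatty on perfectly recoverable parse errors; we raise our own.
RDLogger.DisableLog("rdApp.error")

#: The ten solvents of the closed label space, in canonical priority order
#: (descending frequency in normal-phase purification procedures).  A binary
#: system is always written with the earlier solvent first, and the stored
#: ratio is the volume fraction of that first solvent.
CANONICAL_SOLVENTS: tuple[str, ...] = (
    "ethyl acetate",
    "hexane",
    "dichloromethane",
    "methanol",
    "chloroform",
    "petroleum ether",
    "diethyl ether",
    "toluene",
    "acetone",
    "ethanol",
)

_PRIORITY = {name: i for i, name in enumerate(CANONICAL_SOLVENTS)}

#: Hard cap on molecules per reaction: the fingerprint matrix has 8 rows.
MAX_MOLECULES = 8


class MalformedRecordError(ValueError):
    """A reaction line or dataset row that violates the format contract."""


class UnsupportedSystemError(ValueError):
    """A solvent system outside the supported 1-2 label structure."""


@dataclass(frozen=True)
class Molecule:
    """A single molecule given as SMILES (no ``.`` separator allowed)."""

    smiles: str

    def __post_init__(self) -> None:
        if not self.smiles:
            raise MalformedRecordError("empty SMILES")
        if "." in self.smiles:
            raise MalformedRecordError(
                f"molecule SMILES must not contain '.': {self.smiles!r}"
            )

    def to_mol(self) -> Chem.Mol:
        """Parse into an RDKit molecular graph, raising if invalid."""
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise MalformedRecordError(f"unparsable SMILES: {self.smiles!r}")
        return mol


def split_reaction_smiles(line: str) -> list[Molecule]:
    """Split a one-line reaction SMILES at ``.`` separators.

    Whitespace is stripped (typeset sources often insert spaces around
    bond symbols).  Rejoining the returned molecules with ``.`` reproduces
    the whitespace-stripped input.
    """
    if not line or not line.strip():
        raise MalformedRecordError("empty reaction SMILES")
    stripped = "".join(line.split())
    fragments = stripped.split(".")
    if any(not frag for frag in fragments):
        raise MalformedRecordError(
            f"empty molecule fragment between dots in {line!r}"
        )
    return [Molecule(frag) for frag in fragments]


@dataclass(frozen=True)
class ReactionRecord:
    """One reaction: ordered molecules (reactants then products) + text."""

    record_id: str
    molecules: tuple[Molecule, ...]
    product_flags: tuple[bool, ...]
    purification_text: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.molecules) < 2:
            raise MalformedRecordError(
                f"record {self.record_id}: a reaction needs >= 2 molecules"
            )
        if len(self.molecules) > MAX_MOLECULES:
            raise MalformedRecordError(
                f"record {self.record_id}: {len(self.molecules)} molecules "
                f"exceeds the maximum of {MAX_MOLECULES}"
            )
        if len(self.product_flags) != len(self.molecules):
            raise MalformedRecordError(
                f"record {self.record_id}: product_flags length mismatch"
            )

    @property
    def reaction_smiles(self) -> str:
        return ".".join(m.smiles for m in self.molecules)

    def permuted(self, order: Sequence[int], record_id: str | None = None) -> "ReactionRecord":
        """Return a copy with molecules re-ordered by ``order``."""
        if sorted(order) != list(range(len(self.molecules))):
            raise ValueError(f"not a permutation: {order!r}")
        return replace(
            self,
            record_id=record_id if record_id is not None else self.record_id,
            molecules=tuple(self.molecules[i] for i in order),
            product_flags=tuple(self.product_flags[i] for i in order),
        )


def canonical_order(labels: Iterable[str]) -> list[str]:
    """Order 1-2 solvent labels by the fixed canonical priority list.

    The orientation fixes the semantics of a binary system's ratio: e.g.
    the pair {hexane, ethyl acetate} is always written
    ``[ethyl acetate, hexane]`` and a ratio of 0.9 means 90% ethyl acetate.
    Idempotent and total on the 10-label space.
    """
    unique = sorted(set(labels), key=_label_priority)
    if not 1 <= len(unique) <= 2:
        raise UnsupportedSystemError(
            f"solvent systems have 1-2 labels, got {len(unique)}"
        )
    return unique


def _label_priority(name: str) -> int:
    try:
        return _PRIORITY[name]
    except KeyError:
        raise UnsupportedSystemError(f"unknown solvent label: {name!r}") from None


@dataclass(frozen=True)
class SolventSystem:
    """A 1-2 solvent eluent system, canonically ordered.

    ``ratio`` is the volume fraction of the *first* label and is present
    exactly for binary systems; the second solvent's fraction is
    ``1 - ratio``.
    """

    labels: tuple[str, ...]
    ratio: Optional[float] = None

    def __post_init__(self) -> None:
        ordered = tuple(canonical_order(self.labels))
        if ordered != tuple(self.labels):
            raise UnsupportedSystemError(
                f"labels not in canonical order: {self.labels!r} "
                f"(expected {ordered!r})"
            )
        if len(self.labels) == 2:
            if self.ratio is None:
                return  # binary system whose ratio could not be extracted
            if not 0.0 < self.ratio < 1.0:
                raise UnsupportedSystemError(
                    f"ratio must lie strictly in (0, 1), got {self.ratio}"
                )
        elif self.ratio is not None:
            raise UnsupportedSystemError("single-solvent system cannot carry a ratio")

    @property
    def is_binary(self) -> bool:
        return len(self.labels) == 2

    def describe(self) -> str:
        if self.is_binary and self.ratio is not None:
            return (
                f"{self.labels[0]}:{self.labels[1]} = "
                f"{self.ratio:.3g}:{1 - self.ratio:.3g}"
            )
        return " / ".join(self.labels)


TRAIN, TEST = "train", "test"


@dataclass
class Dataset:
    """Paired (reaction, solvent system) instances with a train/test split.

    ``task_tag`` is ``"DS1"`` for the solvent-label classification task and
    ``"DS2"`` for the ratio regression task; DS2 instances are all binary
    systems with a valid ratio.
    """

    instances: list[tuple[ReactionRecord, SolventSystem]]
    split_assignment: list[str] = field(default_factory=list)
    task_tag: str = "DS1"

    def __post_init__(self) -> None:
        if self.task_tag not in ("DS1", "DS2"):
            raise ValueError(f"task_tag must be DS1 or DS2, got {self.task_tag!r}")
        if self.split_assignment and len(self.split_assignment) != len(self.instances):
            raise ValueError("split_assignment length mismatch")
        if self.task_tag == "DS2":
            for rec, system in self.instances:
                if not system.is_binary or system.ratio is None:
                    raise UnsupportedSystemError(
                        f"DS2 instance {rec.record_id} lacks a binary system "
                        "with ratio"
                    )

    def __len__(self) -> int:
        return len(self.instances)

    @property
    def is_split(self) -> bool:
        return bool(self.split_assignment)

    def subset(self, which: str) -> "Dataset":
        """Return the train or test portion as an unsplit Dataset."""
        if not self.is_split:
            raise ValueError("dataset has no split assignment")
        picked = [
            inst
            for inst, s in zip(self.instances, self.split_assignment)
            if s == which
        ]
        return Dataset(picked, [], self.task_tag)


_COLUMNS = ["id", "reaction_smiles", "labels", "ratio", "split"]


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write a Dataset as a tab-separated UTF-8 file with a header row."""
    rows = []
    splits = dataset.split_assignment or [""] * len(dataset)
    for (rec, system), split in zip(dataset.instances, splits):
        rows.append(
            {
                "id": rec.record_id,
                "reaction_smiles": rec.reaction_smiles,
                "labels": ";".join(system.labels),
                "ratio": "" if system.ratio is None else repr(system.ratio),
                "split": split,
            }
        )
    frame = pd.DataFrame(rows, columns=_COLUMNS)
    frame.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_dataset(path: str | Path, task_tag: str = "DS1") -> Dataset:
    """Read a TSV dataset file written by :func:`write_dataset`.

    Reactions with more than 8 molecules are rejected with a logged
    warning; unknown solvent names raise an error naming the row.
    """
    frame = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8"
    )
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise MalformedRecordError(f"{path}: missing columns {missing}")
    instances: list[tuple[ReactionRecord, SolventSystem]] = []
    splits: list[str] = []
    for row_no, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            molecules = split_reaction_smiles(row.reaction_smiles)
            if len(molecules) > MAX_MOLECULES:
                logger.warning(
                    "%s row %d: %d molecules > %d, record skipped",
                    path, row_no, len(molecules), MAX_MOLECULES,
                )
                continue
            labels = tuple(canonical_order(row.labels.split(";")))
            ratio = float(row.ratio) if row.ratio else None
            system = SolventSystem(labels, ratio)
            record = ReactionRecord(
                record_id=row.id,
                molecules=tuple(molecules),
                product_flags=tuple(
                    [False] * (len(molecules) - 1) + [True]
                ),
            )
        except (MalformedRecordError, UnsupportedSystemError, ValueError) as exc:
            raise MalformedRecordError(f"{path} row {row_no}: {exc}") from exc
        instances.append((record, system))
        splits.append(row.split)
    if not any(splits):
        splits = []
    return Dataset(instances, splits, task_tag)
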