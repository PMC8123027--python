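"""Mining solvent systems from purification text.

Patent synthesis procedures describe chromatographic purification in free
text, e.g. ``"the residue is chromatographed on silica gel with
hexane/ethyl acetate 9:1"``.  This module matches a solvent lexicon
(canonical names plus common synonyms) against such text, pulls out the
first ``a:b`` volume ratio, and applies the dataset filtering rules:
systems of one or two known solvents are kept; three or more solvents,
no solvent, or degenerate ratios (``0:1``, ``0:0``) are rejected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from .records import CANONICAL_SOLVENTS, canonical_order

#: Default surface-form lexicon.  Keys are canonical labels, values are the
#: strings recognised in raw text (matched case-insensitively, longest
#: match first, at non-letter boundaries).
DEFAULT_LEXICON_FORMS: dict[str, tuple[str, ...]] = {
    "ethyl acetate": ("ethyl acetate", "ethylacetate", "ethyl-acetate", "etoac"),
    "hexane": ("hexane", "hexanes", "n-hexane"),
    "dichloromethane": ("dichloromethane", "methylene chloride", "dcm"),
    "methanol": ("methanol", "meoh"),
    "chloroform": ("chloroform", "chcl3"),
    "petroleum ether": ("petroleum ether", "pet ether", "pet. ether"),
    "diethyl ether": ("diethyl ether", "diethylether", "et2o"),
    "toluene": ("toluene",),
    "acetone": ("acetone",),
    "ethanol": ("ethanol", "etoh"),
}

OK = "ok"
NO_SOLVENT = "no_solvent"
TOO_MANY_SOLVENTS = "too_many_solvents"
INVALID_RATIO = "invalid_ratio"


class SolventLexicon:
    """Surface form -> canonical solvent label mapping.

    Matching is case-insensitive and longest-match-first so that e.g.
    ``"methanol"`` is never shadowed by its substring ``"ethanol"`` and
    ``"diethyl ether"`` wins over ``"ethyl"``-prefixed forms.
    """

    def __init__(self, forms: dict[str, tuple[str, ...]] | None = None) -> None:
        forms = forms if forms is not None else DEFAULT_LEXICON_FORMS
        unknown = set(forms) - set(CANONICAL_SOLVENTS)
        if unknown:
            raise ValueError(f"lexicon names outside the label space: {unknown}")
        missing = [c for c in CANONICAL_SOLVENTS if not forms.get(c)]
        if missing:
            raise ValueError(f"canonical labels without surface forms: {missing}")
        self._canonical_of: dict[str, str] = {}
        for canon, surface_forms in forms.items():
            for surface in surface_forms:
                self._canonical_of[surface.lower()] = canon
        ordered = sorted(self._canonical_of, key=len, reverse=True)
        # custom boundaries: a hit may not be flanked by letters, so
        # "ethanol" inside "methanol" does not fire.
        pattern = "|".join(re.escape(s) for s in ordered)
        self._regex = re.compile(
            rf"(?<![a-z])({pattern})(?![a-z])", re.IGNORECASE
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SolventLexicon":
        """Load an editable lexicon: ``canonical name -> [surface forms]``."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls({k: tuple(v) for k, v in raw.items()})

    def finditer(self, text: str):
        for match in self._regex.finditer(text):
            yield match.start(), self._canonical_of[match.group(1).lower()]


DEFAULT_LEXICON = SolventLexicon()

_RATIO_RE = re.compile(r"(\d+)\s*:\s*(\d+)")
_PERCENT_GRADIENT_RE = re.compile(r"\d+\s*(?:%|percent)|\d+\s*[-–]\s*\d+\s*%")


@dataclass(frozen=True)
class ExtractionResult:
    """Outcome of mining one purification paragraph.

    ``labels`` are the distinct canonical solvents found, in order of first
    mention; ``raw_ratio`` is the first ``a:b`` integer pair, oriented to
    the textual mention order of the two solvents.  Failures are statuses,
    never exceptions.
    """

    labels: tuple[str, ...]
    raw_ratio: Optional[tuple[int, int]]
    status: str

    @property
    def ok(self) -> bool:
        return self.status == OK


def extract_solvents(
    text: str, lexicon: SolventLexicon = DEFAULT_LEXICON
) -> ExtractionResult:
    """Extract the solvent system and raw volume ratio from raw text."""
    hits = list(lexicon.finditer(text))
    seen: list[str] = []
    for _, label in hits:
        if label not in seen:
            seen.append(label)
    if not seen:
        return ExtractionResult((), None, NO_SOLVENT)
    if len(seen) > 2:
        return ExtractionResult(tuple(seen), None, TOO_MANY_SOLVENTS)

    raw_ratio: Optional[tuple[int, int]] = None
    status = OK
    if len(seen) == 2:
        match = _RATIO_RE.search(text)
        if match is not None:
            raw_ratio = (int(match.group(1)), int(match.group(2)))
            if 0 in raw_ratio:
                status = INVALID_RATIO
        elif _PERCENT_GRADIENT_RE.search(text):
            # percentage or gradient programs are not isocratic a:b pairs
            status = INVALID_RATIO
    return ExtractionResult(tuple(seen), raw_ratio, status)


def normalize_ratio(raw: tuple[int, int]) -> float:
    """Scale a raw ``a:b`` volume ratio to the fraction ``a / (a + b)``.

    E.g. 9:1 becomes 0.9 (with complement 0.1); the two normalized values
    always sum to 1.  Pairs with a zero component (0:1, 0:0) are invalid.
    """
    a, b = raw
    if a < 0 or b < 0:
        raise ValueError(f"ratio components must be non-negative: {raw}")
    if a == 0 or b == 0:
        raise ValueError(f"degenerate ratio {a}:{b}")
    return a / (a + b)


@dataclass(frozen=True)
class FilterDecision:
    accepted: bool
    reason: Optional[str] = None  # set when rejected
    ds2_eligible: bool = False


def filter_record(result: ExtractionResult) -> FilterDecision:
    """Apply the dataset admission rules to an extraction result.

    Accepted: exactly one solvent (DS1 only), or two solvents; a binary
    system additionally needs a valid normalizable ratio to be DS2
    eligible.  Rejected results carry the reason for audit logging.
    """
    if result.status in (NO_SOLVENT, TOO_MANY_SOLVENTS, INVALID_RATIO):
        return FilterDecision(False, result.status)
    if len(result.labels) == 1:
        return FilterDecision(True, None, ds2_eligible=False)
    return FilterDecision(True, None, ds2_eligible=result.raw_ratio is not None)


def oriented_system(
    result: ExtractionResult,
) -> tuple[tuple[str, ...], Optional[tuple[int, int]]]:
    """Canonically order extracted labels, re-orienting the raw ratio.

    The raw pair is read in the textual order of the two solvent mentions;
    if canonical ordering swaps the labels, the pair is swapped with them
    so the stored ratio always refers to the first canonical label.
    """
    ordered = tuple(canonical_order(result.labels))
    raw = result.raw_ratio
    if raw is not None and len(result.labels) == 2 and ordered != result.labels:
        raw = (raw[1], raw[0])
    return ordered, raw
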