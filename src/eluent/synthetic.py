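"""Synthetic reaction datasets with planted, recoverable structure.

The generator emulates the patent-derived data at desk scale: reactions
of 2-8 molecules drawn from a pool of decorated scaffolds, where the
functional groups present determine the purification solvent system via
a prioritized rule list, and — for binary systems — the solvent ratio
follows a linear law in the trigger-group count plus Gaussian noise.
Each record also carries a templated purification paragraph so that the
text-mining stage can be exercised end to end.

The planted structure is exactly what makes the datasets useful for
testing: labels are a deterministic function of molecular substructure
(so an expressive model can approach perfect subset accuracy), and the
ratio law is recoverable up to the configured noise floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem

from .extraction import DEFAULT_LEXICON_FORMS
from .records import Dataset, Molecule, ReactionRecord, SolventSystem, canonical_order

# ---------------------------------------------------------------------------
# molecule pool: scaffold templates x decorating groups

_SCAFFOLDS_1 = (
    "c1ccc({})cc1",           # benzene
    "c1ccc2cc({})ccc2c1",     # naphthalene
    "c1cc({})ccn1",           # pyridine
    "c1ccc({})o1",            # furan
    "c1ccc({})s1",            # thiophene
    "c1ccc2[nH]c({})cc2c1",   # indole
    "c1ccc(-c2ccc({})cc2)cc1",  # biphenyl
    "COc1ccc({})cc1",         # anisole
    "Cc1ccc({})cc1",          # toluene core
    "C1CCC({})CC1",           # cyclohexane
    "C1CCC({})C1",            # cyclopentane
    "C1CCC({})OC1",           # tetrahydropyran
    "C1CCC({})NC1",           # piperidine
    "CCCC({})C",              # pentane chain
    "CC(C)({})C",             # neopentyl
    "CCOC(=O)C({})C",         # ester chain
    "CC(=O)C({})C",           # ketone chain
    "CCOCC({})C",             # ether chain
)

_GROUPS = (
    "O",                # hydroxyl
    "CO",               # hydroxymethyl
    "N",                # amino
    "CN",               # aminomethyl
    "C(=O)O",           # carboxylic acid
    "Cl",
    "Br",
    "F",
    "OC",               # methoxy
    "C#N",              # nitrile
    "[N+](=O)[O-]",     # nitro
    "C",                # methyl
)


def molecule_pool() -> list[str]:
    """~200 distinct valid molecules: scaffold x decorating group.

    Single decoration keeps the pool small enough that desk-scale
    training sees each molecule repeatedly, while the scaffold variety
    keeps the fingerprint bits of the planted trigger groups separable.
    """
    seen: dict[str, None] = {}
    for template in _SCAFFOLDS_1:
        for group in _GROUPS:
            _try_add(seen, template.format(group))
    return list(seen)


def _try_add(seen: dict, smiles: str) -> None:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return
    canonical = Chem.MolToSmiles(mol)
    seen.setdefault(canonical, None)


# ---------------------------------------------------------------------------
# planted rules


@dataclass(frozen=True)
class PlantedRule:
    """Substructure trigger -> solvent system (+ ratio law for pairs).

    For a reaction, the matching rule of highest priority (lowest number)
    fires; for binary systems the ratio of the first canonical solvent is
    ``clip(base + increment * n_matches, 0.05, 0.95)`` before noise.
    """

    name: str
    trigger: str  # SMARTS; "*" is the catch-all
    labels: tuple[str, ...]
    priority: int
    base: Optional[float] = None
    increment: float = 0.0

    def __post_init__(self) -> None:
        ordered = tuple(canonical_order(self.labels))
        if ordered != self.labels:
            raise ValueError(f"rule {self.name}: labels not canonical")
        if len(self.labels) == 2:
            if self.base is None or not 0.05 < self.base < 0.95:
                raise ValueError(f"rule {self.name}: base must lie in (0.05, 0.95)")

    def smarts(self) -> Optional[Chem.Mol]:
        if self.trigger == "*":
            return None
        pattern = Chem.MolFromSmarts(self.trigger)
        if pattern is None:
            raise ValueError(f"rule {self.name}: bad SMARTS {self.trigger!r}")
        return pattern

    def law(self, count: int) -> Optional[float]:
        if len(self.labels) != 2:
            return None
        return float(np.clip(self.base + self.increment * count, 0.05, 0.95))


DEFAULT_RULES: tuple[PlantedRule, ...] = (
    PlantedRule("acid", "[CX3](=O)[OX2H1]", ("methanol",), priority=1),
    PlantedRule(
        "amine", "[NX3;H2]", ("dichloromethane", "methanol"),
        priority=2, base=0.60, increment=0.05,
    ),
    PlantedRule(
        "hydroxyl", "[OX2H]", ("ethyl acetate", "hexane"),
        priority=3, base=0.30, increment=0.10,
    ),
    PlantedRule(
        "halogen", "[F,Cl,Br]", ("hexane", "dichloromethane"),
        priority=4, base=0.45, increment=0.05,
    ),
    PlantedRule("default", "*", ("dichloromethane",), priority=99),
)

#: Class-imbalance weights over rules: one dominant pair system, as in the
#: real label-set distribution.
DEFAULT_RULE_WEIGHTS: dict[str, float] = {
    "hydroxyl": 0.50,
    "halogen": 0.20,
    "amine": 0.12,
    "acid": 0.10,
    "default": 0.08,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator; defaults are the study conditions."""

    n_reactions: int = 1000
    seed: int = 0
    rules: tuple[PlantedRule, ...] = DEFAULT_RULES
    rule_weights: Optional[dict] = None
    ratio_noise_sd: float = 0.02
    molecule_counts: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8)
    molecule_count_weights: tuple[float, ...] = (
        0.15, 0.30, 0.25, 0.15, 0.08, 0.05, 0.02
    )

    def __post_init__(self) -> None:
        if self.n_reactions < 1:
            raise ValueError("n_reactions must be positive")
        if self.ratio_noise_sd < 0:
            raise ValueError("ratio_noise_sd must be >= 0")

    def weights(self) -> dict:
        return dict(self.rule_weights or DEFAULT_RULE_WEIGHTS)


# ---------------------------------------------------------------------------
# purification-text rendering

_PAIR_TEMPLATES = (
    "the residue is chromatographed on silica gel with {a}/{b} {x}:{y}",
    "the residue was purified by column chromatography on silicagel with "
    "{a}/{b} ({x}:{y})",
    "the residue was chromatographed rapidly on 300 g of silica gel 60 "
    "eluting with {a}/{b} ({x}:{y} parts by volume)",
)

_SINGLE_TEMPLATES = (
    "the residue is chromatographed on silica gel with {a}",
    "the crude product was purified by column chromatography eluting with {a}",
)


def render_purification_text(
    system: SolventSystem,
    raw_ratio: Optional[tuple[int, int]],
    template_id: int = 0,
    surface_choice: int = 0,
    swap_order: bool = False,
) -> str:
    """Render a purification paragraph the extractor can round-trip.

    ``raw_ratio`` refers to the first canonical label; ``swap_order``
    prints the solvents (and the ratio) in reversed textual order, which
    exercises the extractor's re-orientation logic.  ``surface_choice``
    rotates through lexicon synonyms for variety.
    """

    def surface(label: str) -> str:
        forms = DEFAULT_LEXICON_FORMS[label]
        return forms[surface_choice % len(forms)]

    if not system.is_binary:
        template = _SINGLE_TEMPLATES[template_id % len(_SINGLE_TEMPLATES)]
        return template.format(a=surface(system.labels[0]))
    if raw_ratio is None:
        raise ValueError("binary system needs a raw ratio to render")
    first, second = system.labels
    x, y = raw_ratio
    if swap_order:
        first, second = second, first
        x, y = y, x
    template = _PAIR_TEMPLATES[template_id % len(_PAIR_TEMPLATES)]
    return template.format(a=surface(first), b=surface(second), x=x, y=y)


def rationalize(ratio: float, total: int = 10) -> tuple[int, int]:
    """Integer pair a:b with a+b = ``total`` closest to ``ratio``, a,b >= 1."""
    a = int(round(ratio * total))
    a = min(max(a, 1), total - 1)
    b = total - a
    g = math.gcd(a, b)
    return a // g, b // g


# ---------------------------------------------------------------------------
# generation


@dataclass
class SyntheticData:
    """Everything one seeded generation run produced."""

    records: list[ReactionRecord]
    ds1: Dataset
    ds2: Dataset
    truth: dict = field(default_factory=dict)  # record_id -> ground truth
    rules: tuple[PlantedRule, ...] = DEFAULT_RULES

    def truth_json(self) -> dict:
        return {
            "rules": [
                {
                    "name": r.name,
                    "trigger": r.trigger,
                    "labels": list(r.labels),
                    "priority": r.priority,
                    "base": r.base,
                    "increment": r.increment,
                }
                for r in sorted(self.rules, key=lambda r: r.priority)
            ],
            "records": self.truth,
        }


def generate(config: SyntheticConfig) -> SyntheticData:
    """Generate reactions, purification texts, and ground-truth DS1/DS2."""
    rng = np.random.default_rng(config.seed)
    pool = molecule_pool()
    mols = [Chem.MolFromSmiles(s) for s in pool]

    rules = sorted(config.rules, key=lambda r: r.priority)
    patterns = {r.name: r.smarts() for r in rules}

    # per-molecule: match count per rule, and the highest-priority rule hit
    match_counts = np.zeros((len(pool), len(rules)), dtype=int)
    for i, mol in enumerate(mols):
        for j, rule in enumerate(rules):
            pattern = patterns[rule.name]
            if pattern is None:
                match_counts[i, j] = 1
            else:
                match_counts[i, j] = len(mol.GetSubstructMatches(pattern))
    # first (highest-priority) rule each molecule triggers; molecules that
    # trigger nothing get the sentinel len(rules): they break no rule and
    # are eligible everywhere, required nowhere
    hits = match_counts > 0
    top_rule = np.where(hits.any(axis=1), np.argmax(hits, axis=1), len(rules))

    weights = config.weights()
    unknown = set(weights) - {r.name for r in rules}
    if unknown:
        raise ValueError(f"weights for unknown rules: {unknown}")
    names = sorted(weights)
    probs = np.array([weights[n] for n in names], dtype=float)
    probs /= probs.sum()
    rule_index = {r.name: j for j, r in enumerate(rules)}

    eligible = {}
    required = {}
    for name in names:
        j = rule_index[name]
        eligible[name] = np.flatnonzero(top_rule >= j)
        required[name] = np.flatnonzero(top_rule == j)
        if not len(required[name]):
            raise ValueError(f"rule {name!r} covers no pool molecule")

    records: list[ReactionRecord] = []
    ds1_instances: list[tuple[ReactionRecord, SolventSystem]] = []
    ds2_instances: list[tuple[ReactionRecord, SolventSystem]] = []
    truth: dict = {}
    counts = np.array(config.molecule_counts)
    count_probs = np.array(config.molecule_count_weights, dtype=float)
    count_probs /= count_probs.sum()

    for i in range(config.n_reactions):
        name = names[rng.choice(len(names), p=probs)]
        rule = rules[rule_index[name]]
        n_mol = int(rng.choice(counts, p=count_probs))
        reactant_idx = rng.choice(eligible[name], size=n_mol - 1, replace=True)
        product_idx = int(rng.choice(required[name]))
        idxs = list(reactant_idx) + [product_idx]
        molecules = tuple(Molecule(pool[k]) for k in idxs)
        flags = tuple([False] * (n_mol - 1) + [True])
        n_matches = int(match_counts[idxs, rule_index[name]].sum())

        system_labels = rule.labels
        ratio = None
        raw_pair = None
        if len(system_labels) == 2:
            clean = rule.law(n_matches)
            noisy = clean + rng.normal(0.0, config.ratio_noise_sd)
            ratio = float(np.clip(noisy, 0.001, 0.998))
            raw_pair = rationalize(ratio)

        system = SolventSystem(system_labels, ratio)
        text = render_purification_text(
            SolventSystem(system_labels, None) if ratio is None else system,
            raw_pair,
            template_id=int(rng.integers(0, 3)),
            surface_choice=int(rng.integers(0, 4)),
            swap_order=bool(rng.integers(0, 2)),
        )
        record = ReactionRecord(f"synth-{i:05d}", molecules, flags, text)
        records.append(record)
        ds1_instances.append((record, SolventSystem(system_labels, None)))
        if ratio is not None:
            ds2_instances.append((record, system))
        truth[record.record_id] = {
            "rule": rule.name,
            "labels": list(system_labels),
            "n_matches": n_matches,
            "ratio": ratio,
            "raw_ratio": list(raw_pair) if raw_pair else None,
        }

    return SyntheticData(
        records,
        Dataset(ds1_instances, [], "DS1"),
        Dataset(ds2_instances, [], "DS2"),
        truth,
        tuple(rules),
    )
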