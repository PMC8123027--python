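"""Dataset assembly: DS1/DS2 construction, splitting, augmentation, baselines.

DS1 pairs each reaction with its 1-2 solvent labels (multilabel
classification); DS2 keeps only the two-solvent reactions together with
the normalized solvent ratio (regression).  The 90/10 train/test split is
stratified, training reactions are augmented by permuting molecule order,
and naive baselines give the accuracy/MSE floor a trained model must beat.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from itertools import permutations
from typing import Iterable, Optional, Sequence

import numpy as np

from .extraction import (
    ExtractionResult,
    extract_solvents,
    filter_record,
    normalize_ratio,
    oriented_system,
)
from .records import (
    Dataset,
    ReactionRecord,
    SolventSystem,
    TEST,
    TRAIN,
)


def extract_and_filter(
    records: Iterable[ReactionRecord],
) -> tuple[list[tuple[ReactionRecord, SolventSystem, bool]], list[tuple[str, str]]]:
    """Run lexicon extraction + filters over raw records.

    Returns accepted ``(record, system, ds2_eligible)`` triples and an
    audit log of ``(record_id, rejection_reason)`` pairs.
    """
    accepted: list[tuple[ReactionRecord, SolventSystem, bool]] = []
    audit: list[tuple[str, str]] = []
    for rec in records:
        if not rec.purification_text:
            audit.append((rec.record_id, "no_purification_text"))
            continue
        result = extract_solvents(rec.purification_text)
        decision = filter_record(result)
        if not decision.accepted:
            audit.append((rec.record_id, decision.reason or "rejected"))
            continue
        labels, raw = oriented_system(result)
        ratio = None
        if decision.ds2_eligible and raw is not None:
            ratio = normalize_ratio(raw)
        accepted.append((rec, SolventSystem(labels, ratio), decision.ds2_eligible))
    return accepted, audit


def build_ds1(
    accepted: Sequence[tuple[ReactionRecord, SolventSystem, bool]],
) -> Dataset:
    """Assemble DS1: every accepted reaction with its label set (no ratio)."""
    instances = [
        (rec, SolventSystem(system.labels, None))
        for rec, system, _ in accepted
    ]
    return Dataset(instances, [], "DS1")


def build_ds2(
    accepted: Sequence[tuple[ReactionRecord, SolventSystem, bool]],
) -> Dataset:
    """Assemble DS2: the two-solvent subset with a valid normalized ratio."""
    instances = [
        (rec, system)
        for rec, system, eligible in accepted
        if eligible and system.is_binary and system.ratio is not None
    ]
    return Dataset(instances, [], "DS2")


def holdout_count(n: int, test_fraction: float = 0.10) -> int:
    """Number of test instances: nearest-integer rounding of the fraction."""
    return int(round(n * test_fraction))


def _stratum_keys(dataset: Dataset) -> list:
    """Stratification key per instance: label set (DS1) or ratio decile (DS2)."""
    keys = []
    for _, system in dataset.instances:
        if dataset.task_tag == "DS2" and system.ratio is not None:
            keys.append(min(int(system.ratio * 10), 9))
        else:
            keys.append(system.labels)
    return keys


def split(
    dataset: Dataset, test_fraction: float = 0.10, seed: int = 0
) -> Dataset:
    """Assign a stratified train/test split, deterministic under ``seed``.

    The total test size is round(test_fraction * n); per-stratum test
    counts follow the largest-remainder rule so the test set preserves the
    label-set (DS1) / ratio-decile (DS2) distribution.
    """
    n = len(dataset)
    if n < 10:
        raise ValueError(f"refusing to split {n} < 10 instances")
    total_test = holdout_count(n, test_fraction)
    keys = _stratum_keys(dataset)
    strata: dict = defaultdict(list)
    for idx, key in enumerate(keys):
        strata[key].append(idx)

    # largest-remainder apportionment of the exact test total
    quotas = {k: len(v) * total_test / n for k, v in strata.items()}
    counts = {k: math.floor(q) for k, q in quotas.items()}
    shortfall = total_test - sum(counts.values())
    by_remainder = sorted(
        strata, key=lambda k: (-(quotas[k] - counts[k]), repr(k))
    )
    for k in by_remainder[:shortfall]:
        counts[k] += 1

    rng = np.random.default_rng(seed)
    assignment = [TRAIN] * n
    for key in sorted(strata, key=repr):
        idxs = np.array(strata[key])
        rng.shuffle(idxs)
        for i in idxs[: counts[key]]:
            assignment[i] = TEST
    return Dataset(list(dataset.instances), assignment, dataset.task_tag)


@dataclass(frozen=True)
class AugmentationPolicy:
    """Cap and seed for molecule-order permutation augmentation.

    The cap bounds the exponential growth of permuted copies; values in
    [2, 7] were the explored range and 5 the retained default.
    """

    max_permutations_per_instance: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.max_permutations_per_instance <= 7:
            raise ValueError(
                "max_permutations_per_instance must lie in [2, 7], got "
                f"{self.max_permutations_per_instance}"
            )


def sample_permutations(
    m: int, cap: int, rng: np.random.Generator
) -> list[tuple[int, ...]]:
    """Sample min(cap, m!-1) distinct non-identity orderings of m items.

    Rejection sampling from the uniform distribution over permutations;
    the draw stream does not depend on ``cap``, so a larger cap yields a
    superset of a smaller one under the same generator state.
    """
    identity = tuple(range(m))
    total = math.factorial(m) - 1
    want = min(cap, total)
    out: list[tuple[int, ...]] = []
    seen = {identity}
    while len(out) < want:
        perm = tuple(rng.permutation(m).tolist())
        if perm in seen:
            continue
        seen.add(perm)
        out.append(perm)
    return out


def augment(dataset: Dataset, policy: AugmentationPolicy) -> Dataset:
    """Add permuted copies of each *training* instance; test is untouched.

    Augmentation runs after the split and only over the training subset,
    so no permuted twin of a test reaction ever reaches training.
    Each instance draws from its own seeded stream, keyed by position, so
    the result is independent of iteration order.
    """
    if not dataset.is_split:
        raise ValueError("augment requires a split dataset")
    cap = policy.max_permutations_per_instance
    instances = list(dataset.instances)
    assignment = list(dataset.split_assignment)
    for idx, ((rec, system), where) in enumerate(
        zip(dataset.instances, dataset.split_assignment)
    ):
        if where != TRAIN:
            continue
        m = len(rec.molecules)
        rng = np.random.default_rng(np.random.SeedSequence([policy.seed, idx]))
        for j, perm in enumerate(sample_permutations(m, cap, rng)):
            twin = rec.permuted(perm, record_id=f"{rec.record_id}#aug{j}")
            instances.append((twin, system))
            assignment.append(TRAIN)
    return Dataset(instances, assignment, dataset.task_tag)


@dataclass
class BaselineReport:
    """The four naive baselines plus the label-set distribution.

    * random baseline = sum_i P(Y_i)^2  (expected accuracy of sampling a
      label set from the empirical distribution),
    * majority baseline = max_i P(Y_i)  (always predict the top set),
    * mean/median MSE baselines = MSE of the constant mean/median ratio
      predictor on the test subset.
    """

    random_baseline: Optional[float] = None
    majority_baseline: Optional[float] = None
    mean_mse_baseline: Optional[float] = None
    median_mse_baseline: Optional[float] = None
    label_set_distribution: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "random_baseline": self.random_baseline,
            "majority_baseline": self.majority_baseline,
            "mean_mse_baseline": self.mean_mse_baseline,
            "median_mse_baseline": self.median_mse_baseline,
            "label_set_distribution": {
                ";".join(k): v for k, v in self.label_set_distribution.items()
            },
        }


def classification_baselines(label_sets: Sequence[tuple[str, ...]]) -> tuple[float, float, dict]:
    """Random (sum of squared set probabilities) and majority baselines."""
    if not label_sets:
        raise ValueError("empty label-set collection")
    counts = Counter(label_sets)
    n = len(label_sets)
    dist = {k: c / n for k, c in counts.items()}
    random_b = sum(p * p for p in dist.values())
    majority_b = max(dist.values())
    return random_b, majority_b, dist


def regression_baselines(ratios: Sequence[float]) -> tuple[float, float]:
    """MSE of the constant mean and constant median ratio predictors."""
    if not len(ratios):
        raise ValueError("empty ratio collection")
    y = np.asarray(ratios, dtype=float)
    mean_mse = float(np.mean((y.mean() - y) ** 2))
    median_mse = float(np.mean((np.median(y) - y) ** 2))
    return mean_mse, median_mse


def baselines(dataset: Dataset) -> BaselineReport:
    """Compute the baseline bundle for a dataset.

    Classification baselines use the label-set distribution of the whole
    dataset; the regression baselines are evaluated on the test subset
    (constant predictors scored where the models are scored).
    """
    report = BaselineReport()
    label_sets = [system.labels for _, system in dataset.instances]
    random_b, majority_b, dist = classification_baselines(label_sets)
    report.random_baseline = random_b
    report.majority_baseline = majority_b
    report.label_set_distribution = dist
    if dataset.task_tag == "DS2":
        source = dataset.subset(TEST) if dataset.is_split else dataset
        if not len(source):
            raise ValueError("empty test split for regression baselines")
        ratios = [system.ratio for _, system in source.instances]
        report.mean_mse_baseline, report.median_mse_baseline = regression_baselines(
            ratios
        )
    return report
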