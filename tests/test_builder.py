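"""DS1/DS2 assembly, stratified splitting, augmentation, and baselines."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eluent.builder import (
    AugmentationPolicy,
    augment,
    baselines,
    build_ds1,
    build_ds2,
    classification_baselines,
    extract_and_filter,
    holdout_count,
    regression_baselines,
    sample_permutations,
    split,
)
from eluent.records import (
    Dataset,
    Molecule,
    ReactionRecord,
    SolventSystem,
    TEST,
    TRAIN,
)

_POOL = ["CCO", "CCN", "CCC", "CCCl", "c1ccccc1", "CC(=O)O", "CCOC", "CCBr"]


def _record(rid: str, n: int) -> ReactionRecord:
    smiles = [_POOL[(hash(rid) + k) % len(_POOL)] for k in range(n)]
    return ReactionRecord(
        rid,
        tuple(Molecule(s) for s in smiles),
        tuple([False] * (n - 1) + [True]),
    )


def _dataset(n: int, task="DS1", n_molecules=3) -> Dataset:
    systems = [
        SolventSystem(("ethyl acetate", "hexane"), 0.4 if task == "DS2" else None),
        SolventSystem(("methanol",), None) if task == "DS1" else
        SolventSystem(("dichloromethane", "methanol"), 0.6),
    ]
    instances = [
        (_record(f"r{i}", n_molecules), systems[i % 2]) for i in range(n)
    ]
    return Dataset(instances, [], task)


class TestBuild:
    def test_ds1_keeps_all_ds2_keeps_binary_with_ratio(self):
        records = [
            ReactionRecord(
                "a", (Molecule("CCO"), Molecule("CCN")), (False, True),
                "eluting with methanol",
            ),
            ReactionRecord(
                "b", (Molecule("CCO"), Molecule("CCN")), (False, True),
                "eluting with ethyl acetate/hexane 2:3",
            ),
            ReactionRecord(
                "c", (Molecule("CCO"), Molecule("CCN")), (False, True),
                "eluting with ethyl acetate/hexane 0:1",
            ),
        ]
        accepted, audit = extract_and_filter(records)
        ds1, ds2 = build_ds1(accepted), build_ds2(accepted)
        assert len(ds1) == 2  # invalid-ratio record rejected entirely
        assert len(ds2) == 1
        assert ds2.instances[0][1].ratio == pytest.approx(0.4)
        assert audit == [("c", "invalid_ratio")]

    def test_ds2_is_subset_of_ds1_binary_instances(self, small_synth):
        ds1_ids = {rec.record_id for rec, _ in small_synth.ds1.instances}
        for rec, system in small_synth.ds2.instances:
            assert rec.record_id in ds1_ids
            assert system.is_binary and 0 < system.ratio < 1


class TestSplit:
    @pytest.mark.parametrize(
        "n,expected_test",
        [(454_259, 45_426), (272_329, 27_233), (10, 1)],
    )
    def test_ten_percent_rounding(self, n, expected_test):
        assert holdout_count(n) == expected_test

    def test_split_sizes_and_disjointness(self):
        ds = split(_dataset(100), 0.10, seed=1)
        counts = Counter(ds.split_assignment)
        assert counts[TEST] == 10 and counts[TRAIN] == 90
        assert len(ds.subset(TRAIN)) + len(ds.subset(TEST)) == 100

    def test_stratified_by_label_set(self):
        ds = split(_dataset(100), 0.10, seed=3)
        for which in (TRAIN, TEST):
            sets = Counter(
                system.labels for _, system in ds.subset(which).instances
            )
            values = list(sets.values())
            assert max(values) - min(values) <= 1  # 50/50 design preserved

    def test_deterministic_under_seed(self):
        a = split(_dataset(57), 0.10, seed=9)
        b = split(_dataset(57), 0.10, seed=9)
        assert a.split_assignment == b.split_assignment

    def test_refuses_tiny_datasets(self):
        with pytest.raises(ValueError):
            split(_dataset(8), 0.10, seed=0)


class TestAugment:
    @pytest.mark.parametrize("m,cap,expected", [(2, 5, 1), (3, 5, 5), (4, 5, 5)])
    def test_counts_match_min_cap_factorial(self, m, cap, expected):
        rng = np.random.default_rng(0)
        perms = sample_permutations(m, cap, rng)
        assert len(perms) == expected == min(cap, math.factorial(m) - 1)
        identity = tuple(range(m))
        assert identity not in perms
        assert len(set(perms)) == len(perms)

    @pytest.mark.parametrize("m", [2, 3, 4, 5])
    def test_sampled_permutations_lie_in_full_enumeration(self, m):
        rng = np.random.default_rng(1)
        perms = sample_permutations(m, 7, rng)
        universe = set(itertools.permutations(range(m))) - {tuple(range(m))}
        assert set(perms) <= universe
        if math.factorial(m) - 1 <= 7:
            assert set(perms) == universe  # exhaustive when cap allows

    def test_prefix_superset_contract(self):
        ds = split(_dataset(20, n_molecules=4), 0.10, seed=2)
        small = augment(ds, AugmentationPolicy(3, seed=5))
        large = augment(ds, AugmentationPolicy(5, seed=5))
        small_ids = {rec.reaction_smiles for rec, _ in small.instances}
        large_ids = {rec.reaction_smiles for rec, _ in large.instances}
        assert small_ids <= large_ids

    def test_test_split_untouched_and_no_leakage(self):
        ds = split(_dataset(30, n_molecules=3), 0.10, seed=4)
        augmented = augment(ds, AugmentationPolicy(5, seed=4))
        base_of = lambda rid: rid.split("#")[0]
        test_bases = {
            base_of(rec.record_id)
            for (rec, _), s in zip(augmented.instances, augmented.split_assignment)
            if s == TEST
        }
        train_bases = {
            base_of(rec.record_id)
            for (rec, _), s in zip(augmented.instances, augmented.split_assignment)
            if s == TRAIN
        }
        assert test_bases.isdisjoint(train_bases)
        assert len(augmented.subset(TEST)) == len(ds.subset(TEST))

    def test_labels_unchanged_by_permutation(self):
        ds = split(_dataset(20, n_molecules=3), 0.10, seed=6)
        augmented = augment(ds, AugmentationPolicy(5, seed=6))
        truth = {rec.record_id: system for rec, system in ds.instances}
        for rec, system in augmented.instances:
            assert system == truth[rec.record_id.split("#")[0]]


def _brute_force_baselines(label_sets):
    """Independent oracle: direct summation over the empirical distribution."""
    n = len(label_sets)
    counts = Counter(label_sets)
    random_b = sum((c / n) ** 2 for c in counts.values())
    majority_b = max(c / n for c in counts.values())
    return random_b, majority_b


class TestBaselines:
    def test_uniform_two_set_distribution(self):
        sets = [("a",)] * 5 + [("b",)] * 5
        random_b, majority_b, _ = classification_baselines(sets)
        assert random_b == pytest.approx(0.5)
        assert majority_b == pytest.approx(0.5)

    def test_skewed_distribution_by_direct_summation(self):
        sets = [("a",)] * 7 + [("b",)] * 2 + [("c",)] * 1
        random_b, majority_b, dist = classification_baselines(sets)
        assert random_b == pytest.approx(0.54)  # 0.49 + 0.04 + 0.01
        assert majority_b == pytest.approx(0.7)
        assert majority_b >= max(dist.values()) - 1e-12

    def test_constant_predictor_arithmetic(self):
        mean_mse, median_mse = regression_baselines([0.0, 1.0])
        assert mean_mse == pytest.approx(0.25)
        assert median_mse == pytest.approx(0.25)

    def test_mean_mse_equals_biased_variance(self):
        rng = np.random.default_rng(0)
        y = rng.uniform(0, 1, 40)
        mean_mse, _ = regression_baselines(y)
        assert mean_mse == pytest.approx(float(np.var(y)))

    @given(
        st.lists(
            st.sampled_from(["A", "B", "C", "D", "E"]), min_size=1, max_size=60
        )
    )
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_matches_brute_force_on_random_distributions(self, names):
        sets = [(name,) for name in names]
        random_b, majority_b, _ = classification_baselines(sets)
        oracle_random, oracle_majority = _brute_force_baselines(sets)
        assert random_b == pytest.approx(oracle_random)
        assert majority_b == pytest.approx(oracle_majority)
        k = len(set(sets))
        assert 1 / k - 1e-12 <= random_b <= 1.0

    def test_ds2_baselines_use_test_subset(self):
        ds = split(_dataset(40, task="DS2"), 0.10, seed=1)
        report = baselines(ds)
        test_ratios = [s.ratio for _, s in ds.subset(TEST).instances]
        expected_mean, expected_median = regression_baselines(test_ratios)
        assert report.mean_mse_baseline == pytest.approx(expected_mean)
        assert report.median_mse_baseline == pytest.approx(expected_median)
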