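from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enaudit.indicators import (
    ambiguity_rate,
    compute_report,
    fsl_stats,
    multinorm_rate,
    nil_rate,
    redundancy_rate,
    zsl_rate,
)
from enaudit.model import surface_key
from enaudit.synthetic import GeneratorSpec, generate_dataset

from conftest import make_split


# ---------------------------------------------------------------------------
# Independent brute-force oracles (quadratic, instance-by-instance)
# ---------------------------------------------------------------------------

def _pool(splits):
    out = []
    for split in splits:
        by_id = {m.id: m for m in split.mentions}
        for mid, ann in split.gold.items():
            out.append((by_id[mid].surface, ann.concept_ids))
    return out


def brute_multinorm(splits):
    pool = _pool(splits)
    return 100.0 * sum(len(c) >= 2 for _, c in pool) / len(pool)


def brute_nil(splits):
    pool = _pool(splits)
    return 100.0 * sum(not c for _, c in pool) / len(pool)


def brute_ambiguity(splits, policy="exact"):
    pool = _pool(splits)
    hits = 0
    for i, (surface, concepts) in enumerate(pool):
        for j, (other_surface, other_concepts) in enumerate(pool):
            if i == j:
                continue
            if (surface_key(surface, policy) == surface_key(other_surface, policy)
                    and concepts != other_concepts):
                hits += 1
                break
    return 100.0 * hits / len(pool)


def brute_redundancy(train, test, policy="exact"):
    train_pool = _pool([train] if not isinstance(train, list) else train)
    test_pool = _pool([test])
    hits = 0
    for surface, concepts in test_pool:
        for train_surface, train_concepts in train_pool:
            if (surface_key(surface, policy) == surface_key(train_surface, policy)
                    and concepts == train_concepts):
                hits += 1
                break
    return 100.0 * hits / len(test_pool)


def brute_zsl(train, test):
    train_concepts = set()
    for _, concepts in _pool([train] if not isinstance(train, list) else train):
        train_concepts |= concepts
    test_concepts = set()
    for _, concepts in _pool([test]):
        test_concepts |= concepts
    return 100.0 * len(test_concepts - train_concepts) / len(test_concepts)


# ---------------------------------------------------------------------------
# Frozen examples
# ---------------------------------------------------------------------------

class TestFslStats:
    def test_counts_a3_b1(self):
        split = make_split("s", [
            ("d:1", "x1", {"A"}), ("d:2", "x2", {"A"}), ("d:3", "x3", {"A"}),
            ("d:4", "y", {"B"}),
        ])
        assert fsl_stats(split) == (2.0, 2.0, 3)

    def test_all_used_once(self):
        split = make_split("s", [("d:1", "a", {"A"}), ("d:2", "b", {"B"})])
        assert fsl_stats(split) == (1.0, 1.0, 1)

    def test_distinct_variant_caps(self):
        split = make_split("s", [
            ("d:1", "cat", {"A"}), ("d:2", "cat", {"A"}), ("d:3", "cats", {"A"}),
        ])
        assert fsl_stats(split, distinct=False) == (3.0, 3.0, 3)
        assert fsl_stats(split, distinct=True) == (2.0, 2.0, 2)

    def test_empty_errors(self):
        split = make_split("s", [("d:1", "a", None)])
        with pytest.raises(ValueError):
            fsl_stats(split)


class TestRates:
    def test_multinorm_quarter(self):
        split = make_split("s", [
            ("d:1", "a", {"A", "B"}), ("d:2", "b", {"A"}),
            ("d:3", "c", {"B"}), ("d:4", "d", {"C"}),
        ])
        assert multinorm_rate([split]) == 25.0

    def test_multinorm_all_singletons(self):
        split = make_split("s", [("d:1", "a", {"A"}), ("d:2", "b", {"B"})])
        assert multinorm_rate([split]) == 0.0

    def test_nil_zero_and_fraction(self):
        no_nil = make_split("s", [("d:1", "a", {"A"})])
        assert nil_rate([no_nil]) == 0.0
        with_nil = make_split("s", [
            ("d:1", "a", set()), ("d:2", "b", set()),
        ] + [(f"d:{i}", f"s{i}", {"A"}) for i in range(3, 11)])
        assert nil_rate([with_nil]) == 20.0

    def test_nil_pooled_weighted_mean(self):
        a = make_split("a", [("a:1", "x", set()), ("a:2", "y", {"A"})])
        b = make_split("b", [("b:1", "z", {"A"})])
        assert nil_rate([a, b]) == pytest.approx(100.0 * 1 / 3)

    def test_ambiguity_two_of_three(self):
        split = make_split("s", [
            ("d:1", "cat", {"A"}), ("d:2", "cat", {"B"}), ("d:3", "dog", {"C"}),
        ])
        assert ambiguity_rate([split]) == pytest.approx(66.6667, abs=1e-3)

    def test_ambiguity_unique_surfaces(self):
        split = make_split("s", [("d:1", "a", {"A"}), ("d:2", "b", {"A"})])
        assert ambiguity_rate([split]) == 0.0

    def test_ambiguity_multinorm_not_self_ambiguous(self):
        # same surface, same multi-concept gold set: not ambiguous
        split = make_split("s", [
            ("d:1", "cat", {"A", "B"}), ("d:2", "cat", {"A", "B"}),
        ])
        assert ambiguity_rate([split]) == 0.0

    def test_redundancy_half(self):
        train = make_split("train", [("t:1", "cat", {"A"})])
        test = make_split("test", [
            ("e:1", "cat", {"A"}), ("e:2", "dog", {"B"}),
        ])
        assert redundancy_rate(train, test) == 50.0

    def test_redundancy_needs_equal_gold_set(self):
        train = make_split("train", [("t:1", "cat", {"A"})])
        test = make_split("test", [("e:1", "cat", {"B"})])
        assert redundancy_rate(train, test) == 0.0

    def test_redundancy_disjoint_surfaces(self):
        train = make_split("train", [("t:1", "cat", {"A"})])
        test = make_split("test", [("e:1", "dog", {"A"})])
        assert redundancy_rate(train, test) == 0.0

    def test_zsl_half(self):
        train = make_split("train", [("t:1", "cat", {"A"})])
        test = make_split("test", [("e:1", "x", {"A"}), ("e:2", "y", {"B"})])
        assert zsl_rate(train, test) == 50.0

    def test_zsl_zero_when_covered(self):
        train = make_split("train", [("t:1", "cat", {"A"}), ("t:2", "d", {"B"})])
        test = make_split("test", [("e:1", "x", {"A"})])
        assert zsl_rate(train, test) == 0.0

    def test_empty_pool_errors(self):
        empty = make_split("s", [("d:1", "a", None)])
        with pytest.raises(ValueError):
            multinorm_rate([empty])
        with pytest.raises(ValueError):
            zsl_rate(empty, empty)


# ---------------------------------------------------------------------------
# Oracle + property tests on synthetic data
# ---------------------------------------------------------------------------

RATE_SPECS = [
    GeneratorSpec(n_concepts=40, train_size=50, test_size=20, seed=1),
    GeneratorSpec(n_concepts=40, train_size=50, test_size=20, redundancy=50,
                  zsl=25, ambiguity=20, multinorm=10, seed=2),
    GeneratorSpec(n_concepts=60, train_size=60, test_size=40, redundancy=10,
                  zsl=50, nil=5, seed=3),
    GeneratorSpec(n_concepts=30, train_size=30, test_size=10, redundancy=100,
                  seed=4),
    GeneratorSpec(n_concepts=30, train_size=30, test_size=10, zsl=100, seed=5),
]


@pytest.mark.parametrize("spec", RATE_SPECS, ids=lambda s: f"seed{s.seed}")
def test_indicators_match_brute_force(spec):
    data = generate_dataset(spec)
    splits = [data.train, data.test]
    assert multinorm_rate(splits) == pytest.approx(brute_multinorm(splits))
    assert nil_rate(splits) == pytest.approx(brute_nil(splits))
    assert ambiguity_rate(splits) == pytest.approx(brute_ambiguity(splits))
    assert redundancy_rate(data.train, data.test) == pytest.approx(
        brute_redundancy(data.train, data.test)
    )
    assert zsl_rate(data.train, data.test) == pytest.approx(
        brute_zsl(data.train, data.test)
    )


@pytest.mark.parametrize("spec", RATE_SPECS, ids=lambda s: f"seed{s.seed}")
def test_generator_roundtrip(spec):
    data = generate_dataset(spec)
    tol = 100.0 / spec.test_size
    assert redundancy_rate(data.train, data.test) == pytest.approx(spec.redundancy)
    assert zsl_rate(data.train, data.test) == pytest.approx(spec.zsl)
    assert ambiguity_rate([data.test]) == pytest.approx(spec.ambiguity, abs=tol)
    assert multinorm_rate([data.test]) == pytest.approx(spec.multinorm, abs=tol)
    assert nil_rate([data.test]) == pytest.approx(spec.nil, abs=tol)


def test_rates_invariant_to_mention_reordering():
    data = generate_dataset(RATE_SPECS[1])
    from enaudit.model import DatasetSplit

    reversed_test = DatasetSplit(
        "test", list(reversed(data.test.mentions)), data.test.gold
    )
    assert redundancy_rate(data.train, reversed_test) == redundancy_rate(
        data.train, data.test
    )
    assert zsl_rate(data.train, reversed_test) == zsl_rate(data.train, data.test)


def test_zero_ambiguity_redundancy_decided_by_surface():
    data = generate_dataset(
        GeneratorSpec(n_concepts=40, train_size=50, test_size=20,
                      redundancy=40, seed=9)
    )
    assert ambiguity_rate([data.train, data.test]) == 0.0
    train_surfaces = {m.surface for m in data.train.mentions}
    expected = redundancy_rate(data.train, data.test)
    by_surface = 100.0 * sum(
        1 for m in data.test.mentions if m.surface in train_surfaces
    ) / len(data.test.gold)
    assert expected == by_surface


def test_compute_report_denominators_and_bounds():
    data = generate_dataset(RATE_SPECS[1])
    report = compute_report(data.train, data.test)
    payload = report.to_dict()
    for rate in payload["rates"].values():
        assert 0.0 <= rate <= 100.0
    assert payload["denominators"]["test_mentions"] == len(data.test.gold)
    assert report.fsl_average_distinct <= report.fsl_average
    assert "Redundancy" in report.to_markdown()
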