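"""Intra-fold and inter-fold dataset-bias indicators.

Intra-fold: few-shot-learning (FSL) statistics of mentions-per-concept,
multi-normalization rate, NIL rate, ambiguity rate.  Inter-fold:
redundancy (test examples already seen in training) and zero-shot (ZSL)
rate (test concepts never seen in training).

All rates are percentages in [0, 100].  The mention-instance universe of
every indicator is the set of gold entries of the considered splits
(NIL entries included); "same surface form" comparisons go through
:func:`enaudit.model.surface_key` under a caller-selected policy, which
is recorded in the report for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Sequence

from .model import DatasetSplit, SurfacePolicy, concept_usage_counts, surface_key

__all__ = [
    "fsl_stats",
    "multinorm_rate",
    "nil_rate",
    "ambiguity_rate",
    "redundancy_rate",
    "zsl_rate",
    "IndicatorReport",
    "compute_report",
    "merge_splits",
]


def _instances(splits: Sequence[DatasetSplit]) -> list[tuple[str, frozenset[str]]]:
    """Pooled (surface, gold concept set) instances over the splits."""
    pool: list[tuple[str, frozenset[str]]] = []
    for split in splits:
        by_id = {m.id: m for m in split.mentions}
        for mention_id, annotation in split.gold.items():
            pool.append((by_id[mention_id].surface, annotation.concept_ids))
    return pool


def fsl_stats(
    split: DatasetSplit,
    distinct: bool = False,
    policy: SurfacePolicy = "exact",
) -> tuple[float, float, int]:
    """(average, median, max) of mentions annotated per used concept.

    Only concepts annotating at least one mention are considered; with
    ``distinct`` mentions sharing a surface form count once per concept.
    """
    counts = concept_usage_counts(split, policy)
    if not counts:
        raise ValueError(f"split {split.name!r} has no annotated mentions")
    values = [
        distinct_count if distinct else instance_count
        for instance_count, distinct_count in counts.values()
    ]
    return (sum(values) / len(values), float(median(values)), max(values))


def multinorm_rate(splits: Sequence[DatasetSplit]) -> float:
    """Percentage of pooled mentions with a gold set of size >= 2."""
    pool = _instances(splits)
    if not pool:
        raise ValueError("no annotated mentions in the pooled splits")
    hits = sum(1 for _, concepts in pool if len(concepts) >= 2)
    return 100.0 * hits / len(pool)


def nil_rate(splits: Sequence[DatasetSplit]) -> float:
    """Percentage of pooled mentions with an empty gold set."""
    pool = _instances(splits)
    if not pool:
        raise ValueError("no annotated mentions in the pooled splits")
    hits = sum(1 for _, concepts in pool if not concepts)
    return 100.0 * hits / len(pool)


def ambiguity_rate(
    splits: Sequence[DatasetSplit], policy: SurfacePolicy = "exact"
) -> float:
    """Percentage of pooled mention instances whose surface form is also
    annotated, elsewhere in the pool, by a different gold concept set."""
    pool = _instances(splits)
    if not pool:
        raise ValueError("no annotated mentions in the pooled splits")
    gold_sets_by_surface: dict[str, set[frozenset[str]]] = {}
    for surface, concepts in pool:
        gold_sets_by_surface.setdefault(surface_key(surface, policy), set()).add(
            concepts
        )
    hits = sum(
        1
        for surface, _ in pool
        if len(gold_sets_by_surface[surface_key(surface, policy)]) > 1
    )
    return 100.0 * hits / len(pool)


def redundancy_rate(
    train: DatasetSplit | Sequence[DatasetSplit],
    test: DatasetSplit,
    policy: SurfacePolicy = "exact",
) -> float:
    """Percentage of test mention instances whose example — the pair
    (surface form, gold concept set) — also occurs in the training
    material.  Counts instances, not unique pairs."""
    train_splits = [train] if isinstance(train, DatasetSplit) else list(train)
    train_pool = _instances(train_splits)
    test_pool = _instances([test])
    if not train_pool or not test_pool:
        raise ValueError("redundancy_rate requires non-empty train and test")
    train_examples = {
        (surface_key(surface, policy), concepts) for surface, concepts in train_pool
    }
    hits = sum(
        1
        for surface, concepts in test_pool
        if (surface_key(surface, policy), concepts) in train_examples
    )
    return 100.0 * hits / len(test_pool)


def zsl_rate(
    train: DatasetSplit | Sequence[DatasetSplit], test: DatasetSplit
) -> float:
    """Percentage of test-set concepts never met in training annotations."""
    train_splits = [train] if isinstance(train, DatasetSplit) else list(train)
    train_concepts: set[str] = set()
    for split in train_splits:
        train_concepts |= split.used_concepts()
    test_concepts = test.used_concepts()
    if not test_concepts:
        raise ValueError("test split uses no concepts")
    unseen = test_concepts - train_concepts
    return 100.0 * len(unseen) / len(test_concepts)


@dataclass
class IndicatorReport:
    """The six bias statistics for a (train, test) pair, with the
    denominators behind every rate."""

    fsl_average: float
    fsl_median: float
    fsl_max: int
    fsl_average_distinct: float
    fsl_median_distinct: float
    fsl_max_distinct: int
    multinorm_rate: float
    nil_rate: float
    ambiguity_rate: float
    redundancy_rate: float
    zsl_rate: float
    policy: str
    denominators: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rate_name in (
            "multinorm_rate", "nil_rate", "ambiguity_rate",
            "redundancy_rate", "zsl_rate",
        ):
            value = getattr(self, rate_name)
            if not 0.0 <= value <= 100.0:
                raise ValueError(f"{rate_name} out of [0, 100]: {value}")
        if self.fsl_median > self.fsl_max or self.fsl_average > self.fsl_max:
            raise ValueError("FSL median/average above maximum")
        if self.fsl_average_distinct > self.fsl_average + 1e-12:
            raise ValueError("distinct FSL average above plain average")

    def to_dict(self) -> dict[str, object]:
        return {
            "fsl": {
                "average": self.fsl_average,
                "median": self.fsl_median,
                "max": self.fsl_max,
                "average_distinct": self.fsl_average_distinct,
                "median_distinct": self.fsl_median_distinct,
                "max_distinct": self.fsl_max_distinct,
            },
            "rates": {
                "multinorm": self.multinorm_rate,
                "nil": self.nil_rate,
                "ambiguity": self.ambiguity_rate,
                "redundancy": self.redundancy_rate,
                "zsl": self.zsl_rate,
            },
            "policy": self.policy,
            "denominators": dict(sorted(self.denominators.items())),
        }

    def to_markdown(self) -> str:
        d = self.denominators
        lines = [
            "| indicator | value | denominator |",
            "| --- | --- | --- |",
            f"| FSL average | {self.fsl_average:.2f} | {d.get('fsl_concepts', '')} |",
            f"| FSL median | {self.fsl_median:.2f} | {d.get('fsl_concepts', '')} |",
            f"| FSL max | {self.fsl_max} | {d.get('fsl_concepts', '')} |",
            f"| FSL average (distinct) | {self.fsl_average_distinct:.2f} "
            f"| {d.get('fsl_concepts', '')} |",
            f"| FSL median (distinct) | {self.fsl_median_distinct:.2f} "
            f"| {d.get('fsl_concepts', '')} |",
            f"| FSL max (distinct) | {self.fsl_max_distinct} "
            f"| {d.get('fsl_concepts', '')} |",
            f"| Multi-norm (%) | {self.multinorm_rate:.1f} | {d.get('pool_mentions', '')} |",
            f"| NIL (%) | {self.nil_rate:.1f} | {d.get('pool_mentions', '')} |",
            f"| Ambiguity (%) | {self.ambiguity_rate:.1f} | {d.get('pool_mentions', '')} |",
            f"| Redundancy (%) | {self.redundancy_rate:.1f} | {d.get('test_mentions', '')} |",
            f"| ZSL (%) | {self.zsl_rate:.1f} | {d.get('test_concepts', '')} |",
            f"",
            f"Surface policy: `{self.policy}`",
        ]
        return "\n".join(lines)


def compute_report(
    train: DatasetSplit | Sequence[DatasetSplit],
    test: DatasetSplit,
    pool: Sequence[DatasetSplit] | None = None,
    policy: SurfacePolicy = "exact",
) -> IndicatorReport:
    """Assemble the full indicator report for a (train, test) pair.

    FSL statistics are computed on the training material (first train
    split when several), intra-fold rates on ``pool`` (defaults to train
    splits + test, following the table-header convention of pooling all
    available material), inter-fold rates on (train, test).
    """
    train_splits = [train] if isinstance(train, DatasetSplit) else list(train)
    fsl_split = train_splits[0] if len(train_splits) == 1 else merge_splits(train_splits)
    pooled = list(pool) if pool is not None else train_splits + [test]
    average, med, maximum = fsl_stats(fsl_split, distinct=False, policy=policy)
    average_d, med_d, maximum_d = fsl_stats(fsl_split, distinct=True, policy=policy)
    return IndicatorReport(
        fsl_average=average,
        fsl_median=med,
        fsl_max=maximum,
        fsl_average_distinct=average_d,
        fsl_median_distinct=med_d,
        fsl_max_distinct=maximum_d,
        multinorm_rate=multinorm_rate(pooled),
        nil_rate=nil_rate(pooled),
        ambiguity_rate=ambiguity_rate(pooled, policy),
        redundancy_rate=redundancy_rate(train_splits, test, policy),
        zsl_rate=zsl_rate(train_splits, test),
        policy=policy,
        denominators={
            "fsl_concepts": len(concept_usage_counts(fsl_split, policy)),
            "pool_mentions": sum(len(s.gold) for s in pooled),
            "test_mentions": len(test.gold),
            "test_concepts": len(test.used_concepts()),
            "train_mentions": sum(len(s.gold) for s in train_splits),
        },
    )


def merge_splits(splits: Iterable[DatasetSplit]) -> DatasetSplit:
    """Pool several splits into one (mention ids must not collide)."""
    splits = list(splits)
    mentions = [m for s in splits for m in s.mentions]
    gold = {k: v for s in splits for k, v in s.gold.items()}
    return DatasetSplit("+".join(s.name for s in splits), mentions, gold)
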