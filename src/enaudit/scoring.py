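"""The accuracy metric family for entity normalization.

Four related scorers over a gold standard and a prediction set:

* :func:`accuracy` — classic accuracy: one gold concept, one predicted
  concept per mention;
* :func:`topk_accuracy` — full point when any of the k best-ranked
  candidates is a correct concept;
* :func:`accuracy_multinorm` — generalization to multi-normalization:
  per-mention fraction of the n_i correct concepts that were predicted;
* :func:`accuracy_general` — same, but with an over-prediction penalty:
  the denominator is max(n_i, p_i) where p_i is the number of distinct
  predicted concepts, so flooding the prediction list is punished;
* :func:`accuracy_lenient` — the permissive variant used by some
  evaluation scripts: one correct prediction earns the full point for a
  multi-labeled mention, while composite mentions still require all
  their concepts.

Mentions present in the gold standard but absent from the prediction set
count as unpredicted (p_i = 0), never excluded: the denominator N of
every metric is the full number of evaluated mentions.  Values live in
[0, 1]; multiply by 100 for presentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .model import DatasetSplit, GoldAnnotation, PredictionSet

__all__ = [
    "ScoreResult",
    "strict",
    "accuracy",
    "topk_accuracy",
    "accuracy_multinorm",
    "accuracy_general",
    "accuracy_lenient",
]

GoldStandard = Mapping[str, GoldAnnotation]


@dataclass(frozen=True)
class ScoreResult:
    """Mean accuracy with its per-mention contributions."""

    value: float
    contributions: dict[str, float]
    n: int

    def __post_init__(self) -> None:
        if self.n != len(self.contributions):
            raise ValueError("N disagrees with the number of contributions")
        for mention_id, contribution in self.contributions.items():
            if not 0.0 <= contribution <= 1.0:
                raise ValueError(
                    f"contribution for {mention_id!r} out of [0, 1]"
                )
        expected = (
            sum(self.contributions.values()) / self.n if self.n else 0.0
        )
        if abs(self.value - expected) > 1e-9:
            raise ValueError("value is not the mean of contributions")

    @property
    def percent(self) -> float:
        return 100.0 * self.value


def _as_gold(gold: GoldStandard | DatasetSplit) -> dict[str, GoldAnnotation]:
    if isinstance(gold, DatasetSplit):
        return dict(gold.gold)
    return dict(gold)


def _result(contributions: dict[str, float]) -> ScoreResult:
    n = len(contributions)
    if n == 0:
        raise ValueError("no mentions to evaluate")
    return ScoreResult(
        value=sum(contributions.values()) / n,
        contributions=contributions,
        n=n,
    )


def strict(gold_concepts: Iterable[str], concept_id: str) -> int:
    """1 if ``concept_id`` is a correct concept of the mention, else 0."""
    return 1 if concept_id in set(gold_concepts) else 0


def accuracy(gold: GoldStandard | DatasetSplit, preds: PredictionSet) -> ScoreResult:
    """Classic accuracy: mean of strict over mentions.

    Requires single-gold mentions and at most one prediction each; use
    the multi-normalization variants otherwise.  An absent prediction
    contributes 0.
    """
    annotations = _as_gold(gold)
    contributions: dict[str, float] = {}
    for mention_id, annotation in annotations.items():
        if len(annotation.concept_ids) != 1:
            raise ValueError(
                f"mention {mention_id!r} has {len(annotation.concept_ids)} gold "
                "concepts; classic accuracy needs exactly 1 "
                "(use accuracy_multinorm / accuracy_general)"
            )
        predicted = preds.concepts(mention_id)
        if len(predicted) > 1:
            raise ValueError(
                f"mention {mention_id!r} has {len(predicted)} predictions; "
                "classic accuracy needs at most 1 "
                "(use accuracy_multinorm / accuracy_general)"
            )
        contributions[mention_id] = float(
            strict(annotation.concept_ids, predicted[0]) if predicted else 0
        )
    return _result(contributions)


def topk_accuracy(
    gold: GoldStandard | DatasetSplit, preds: PredictionSet, k: int
) -> ScoreResult:
    """Full point when any of the k best-ranked candidates is correct."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    annotations = _as_gold(gold)
    contributions: dict[str, float] = {}
    for mention_id, annotation in annotations.items():
        if not annotation.concept_ids:
            raise ValueError(f"mention {mention_id!r} is NIL; not scorable")
        top = preds.concepts(mention_id)[:k]
        contributions[mention_id] = float(
            any(strict(annotation.concept_ids, cid) for cid in top)
        )
    return _result(contributions)


def accuracy_multinorm(
    gold: GoldStandard | DatasetSplit, preds: PredictionSet
) -> ScoreResult:
    """Per-mention contribution: (number of correct predicted concepts)
    / n_i, capped at 1.  Over-prediction is NOT penalized: predicting the
    whole ontology earns a perfect score (the pathology motivating
    :func:`accuracy_general`)."""
    annotations = _as_gold(gold)
    contributions: dict[str, float] = {}
    for mention_id, annotation in annotations.items():
        n_i = len(annotation.concept_ids)
        if n_i == 0:
            raise ValueError(f"mention {mention_id!r} is NIL; not scorable")
        correct = sum(
            strict(annotation.concept_ids, cid)
            for cid in preds.concepts(mention_id)
        )
        contributions[mention_id] = min(1.0, correct / n_i)
    return _result(contributions)


def accuracy_general(
    gold: GoldStandard | DatasetSplit, preds: PredictionSet
) -> ScoreResult:
    """Per-mention contribution: (number of correct predicted concepts)
    / max(n_i, p_i).  Unpredicted mentions (p_i = 0) contribute 0."""
    annotations = _as_gold(gold)
    contributions: dict[str, float] = {}
    for mention_id, annotation in annotations.items():
        n_i = len(annotation.concept_ids)
        if n_i == 0:
            raise ValueError(f"mention {mention_id!r} is NIL; not scorable")
        predicted = preds.concepts(mention_id)
        p_i = len(predicted)
        if p_i == 0:
            contributions[mention_id] = 0.0
            continue
        correct = sum(strict(annotation.concept_ids, cid) for cid in predicted)
        contributions[mention_id] = correct / max(n_i, p_i)
    return _result(contributions)


def accuracy_lenient(
    gold: GoldStandard | DatasetSplit,
    preds: PredictionSet,
    composite_flags: Iterable[str] = (),
) -> ScoreResult:
    """Lenient accuracy, as used by some published evaluation scripts.

    A multi-labeled (multi-gold, non-composite) mention earns the full
    point as soon as one predicted concept is correct; composite mentions
    (flagged by id) and single-gold mentions score as
    :func:`accuracy_general`.
    """
    annotations = _as_gold(gold)
    composite = set(composite_flags)
    unknown = composite - set(annotations)
    if unknown:
        raise ValueError(
            f"composite flags for unknown mentions: {sorted(unknown)!r}"
        )
    contributions: dict[str, float] = {}
    for mention_id, annotation in annotations.items():
        n_i = len(annotation.concept_ids)
        if n_i == 0:
            raise ValueError(f"mention {mention_id!r} is NIL; not scorable")
        predicted = preds.concepts(mention_id)
        p_i = len(predicted)
        if n_i >= 2 and mention_id not in composite:
            contributions[mention_id] = float(
                any(strict(annotation.concept_ids, cid) for cid in predicted)
            )
            continue
        if p_i == 0:
            contributions[mention_id] = 0.0
            continue
        correct = sum(strict(annotation.concept_ids, cid) for cid in predicted)
        contributions[mention_id] = correct / max(n_i, p_i)
    return _result(contributions)
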