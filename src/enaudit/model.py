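"""Core domain model: concepts, ontologies, mentions, gold annotations,
dataset splits and prediction sets.

All other modules operate on these types.  Conventions:

* character offsets are 0-based, end-exclusive;
* discontinuous mention fragments are joined by a single space to form
  the surface string;
* a NIL mention is encoded as an empty gold concept set, never as a
  sentinel concept id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "Concept",
    "Ontology",
    "Mention",
    "GoldAnnotation",
    "DatasetSplit",
    "PredictionSet",
    "SurfacePolicy",
    "surface_key",
    "concept_usage_counts",
]

#: Valid surface-comparison policies, from least to most interpretive.
SurfacePolicy = str
SURFACE_POLICIES = ("exact", "casefold", "casefold+whitespace-collapse")


@dataclass(frozen=True)
class Concept:
    """A reference entity: unique id, ordered labels (first = preferred),
    and parent links within its ontology."""

    id: str
    labels: tuple[str, ...]
    parents: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("concept id must be non-empty")
        if not self.labels:
            raise ValueError(f"concept {self.id!r} has no labels")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"concept {self.id!r} has duplicate labels")

    @property
    def preferred_label(self) -> str:
        return self.labels[0]


class Ontology:
    """The reference set: a map id -> Concept with an acyclic parent
    relation, plus an alias table for alternative identifiers.
    """

    def __init__(
        self,
        concepts: Iterable[Concept],
        name: str = "",
        version: str = "",
        aliases: Mapping[str, str] | None = None,
    ) -> None:
        self.concepts: dict[str, Concept] = {}
        for concept in concepts:
            if concept.id in self.concepts:
                raise ValueError(f"duplicate concept id {concept.id!r}")
            self.concepts[concept.id] = concept
        if not self.concepts:
            raise ValueError("an ontology must contain at least one concept")
        self.name = name
        self.version = version
        self.aliases: dict[str, str] = dict(aliases or {})
        for alias, target in self.aliases.items():
            if target not in self.concepts:
                raise ValueError(f"alias {alias!r} targets unknown concept {target!r}")
        self._validate_parents()

    def _validate_parents(self) -> None:
        for concept in self.concepts.values():
            for parent in concept.parents:
                if parent not in self.concepts:
                    raise ValueError(
                        f"concept {concept.id!r} references unknown parent {parent!r}"
                    )
        # cycle check: iterative DFS with colouring
        WHITE, GREY, BLACK = 0, 1, 2
        colour = dict.fromkeys(self.concepts, WHITE)
        for start in self.concepts:
            if colour[start] != WHITE:
                continue
            stack: list[tuple[str, Iterator[str]]] = [
                (start, iter(self.concepts[start].parents))
            ]
            colour[start] = GREY
            while stack:
                node, parents = stack[-1]
                advanced = False
                for parent in parents:
                    if colour[parent] == GREY:
                        raise ValueError(f"cyclic parent relation through {parent!r}")
                    if colour[parent] == WHITE:
                        colour[parent] = GREY
                        stack.append((parent, iter(self.concepts[parent].parents)))
                        advanced = True
                        break
                if not advanced:
                    colour[node] = BLACK
                    stack.pop()

    def __len__(self) -> int:
        return len(self.concepts)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.concepts or concept_id in self.aliases

    def __getitem__(self, concept_id: str) -> Concept:
        return self.concepts[self.resolve(concept_id)]

    def resolve(self, concept_id: str) -> str:
        """Map an id (possibly an alias) to its primary concept id.

        Raises ``KeyError`` for unknown ids.
        """
        if concept_id in self.concepts:
            return concept_id
        if concept_id in self.aliases:
            return self.aliases[concept_id]
        raise KeyError(concept_id)

    def roots(self) -> list[str]:
        return sorted(cid for cid, c in self.concepts.items() if not c.parents)

    def descendants(self, root_id: str) -> set[str]:
        """Ids of ``root_id`` and every concept below it."""
        root_id = self.resolve(root_id)
        children: dict[str, list[str]] = {cid: [] for cid in self.concepts}
        for concept in self.concepts.values():
            for parent in concept.parents:
                children[parent].append(concept.id)
        seen = {root_id}
        frontier = [root_id]
        while frontier:
            node = frontier.pop()
            for child in children[node]:
                if child not in seen:
                    seen.add(child)
                    frontier.append(child)
        return seen


@dataclass(frozen=True)
class Mention:
    """One occurrence of an entity in a document."""

    id: str
    doc_id: str
    surface: str
    spans: tuple[tuple[int, int], ...] = ()
    entity_type: str = ""

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError(f"mention {self.id!r} has an empty surface form")
        previous_end = -1
        for start, end in self.spans:
            if start < previous_end:
                raise ValueError(
                    f"mention {self.id!r} spans overlap or are unsorted"
                )
            if end < start:
                raise ValueError(f"mention {self.id!r} has a negative-length span")
            previous_end = end


@dataclass(frozen=True)
class GoldAnnotation:
    """Gold concept set for one mention; empty set encodes NIL."""

    mention_id: str
    concept_ids: frozenset[str]

    @property
    def is_nil(self) -> bool:
        return not self.concept_ids

    @property
    def is_multinorm(self) -> bool:
        return len(self.concept_ids) >= 2


class DatasetSplit:
    """A named fold: mentions plus at most one gold annotation each."""

    def __init__(
        self,
        name: str,
        mentions: Sequence[Mention],
        gold: Mapping[str, GoldAnnotation],
    ) -> None:
        self.name = name
        self.mentions = list(mentions)
        mention_ids = {m.id for m in self.mentions}
        if len(mention_ids) != len(self.mentions):
            raise ValueError(f"split {name!r} has duplicate mention ids")
        for key, annotation in gold.items():
            if key not in mention_ids:
                raise ValueError(f"gold annotation for unknown mention {key!r}")
            if annotation.mention_id != key:
                raise ValueError(f"gold key {key!r} disagrees with its annotation")
        self.gold = dict(gold)

    def __len__(self) -> int:
        return len(self.mentions)

    def annotated_mentions(self) -> list[Mention]:
        """Mentions that carry a gold entry (NIL entries included)."""
        return [m for m in self.mentions if m.id in self.gold]

    def used_concepts(self) -> set[str]:
        """Union of gold concept sets over the split."""
        used: set[str] = set()
        for annotation in self.gold.values():
            used |= annotation.concept_ids
        return used


class PredictionSet:
    """Per-mention ranked predictions.

    Each mention id maps to an ordered list of ``(concept_id, score)``
    pairs; unranked predictions carry equal scores.  Concept ids are
    distinct per mention and scores are finite and non-increasing.
    """

    def __init__(
        self,
        predictions: Mapping[str, Sequence[tuple[str, float]]] | None = None,
    ) -> None:
        self._predictions: dict[str, list[tuple[str, float]]] = {}
        for mention_id, pairs in (predictions or {}).items():
            self.set(mention_id, pairs)

    def set(self, mention_id: str, pairs: Sequence[tuple[str, float]]) -> None:
        concept_ids = [cid for cid, _ in pairs]
        if len(set(concept_ids)) != len(concept_ids):
            raise ValueError(
                f"duplicate predicted concept for mention {mention_id!r}"
            )
        previous = math.inf
        for cid, score in pairs:
            if not math.isfinite(score):
                raise ValueError(f"non-finite score for mention {mention_id!r}")
            if score > previous:
                raise ValueError(f"scores not non-increasing for {mention_id!r}")
            previous = score
        self._predictions[mention_id] = [(cid, float(s)) for cid, s in pairs]

    def get(self, mention_id: str) -> list[tuple[str, float]]:
        return list(self._predictions.get(mention_id, []))

    def concepts(self, mention_id: str) -> list[str]:
        return [cid for cid, _ in self._predictions.get(mention_id, [])]

    def mention_ids(self) -> list[str]:
        return list(self._predictions)

    def __len__(self) -> int:
        return len(self._predictions)

    def __contains__(self, mention_id: str) -> bool:
        return mention_id in self._predictions

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PredictionSet):
            return NotImplemented
        return self._predictions == other._predictions


def surface_key(surface: str, policy: SurfacePolicy = "exact") -> str:
    """Canonical key used everywhere two surface forms are compared.

    ``exact`` returns the input unchanged; ``casefold`` applies Unicode
    case folding; ``casefold+whitespace-collapse`` additionally strips
    and collapses internal whitespace runs to single spaces.
    """
    if policy == "exact":
        return surface
    if policy == "casefold":
        return surface.casefold()
    if policy == "casefold+whitespace-collapse":
        return " ".join(surface.casefold().split())
    raise ValueError(f"unknown surface policy {policy!r}")


def concept_usage_counts(
    split: DatasetSplit, policy: SurfacePolicy = "exact"
) -> dict[str, tuple[int, int]]:
    """Per concept: (mention instance count, distinct surface count).

    Only concepts annotating at least one mention appear.  A mention
    normalized by several concepts increments every concept in its gold
    set.  Distinct counts compare surfaces through :func:`surface_key`.
    """
    instances: dict[str, int] = {}
    surfaces: dict[str, set[str]] = {}
    by_id = {m.id: m for m in split.mentions}
    for mention_id, annotation in split.gold.items():
        key = surface_key(by_id[mention_id].surface, policy)
        for concept_id in annotation.concept_ids:
            instances[concept_id] = instances.get(concept_id, 0) + 1
            surfaces.setdefault(concept_id, set()).add(key)
    return {
        cid: (instances[cid], len(surfaces[cid])) for cid in instances
    }
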