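"""Two-sieve baseline normalizer.

Sieve 1 (dictionary + rules): ontology labels plus training mention
surfaces are normalized (lowercase, per-token Porter stem) into a
lexicon; prediction is exact match of the normalized mention.  A surface
annotated by several concepts across training goes to its most frequent
concept.

Sieve 2 (distributional + learned): mentions are embedded as the mean of
their token embeddings; a ridge-regularized linear map is trained to
project mention embeddings near the preferred-label embeddings of their
concepts; prediction is the cosine-nearest label embedding over a
(possibly restricted) concept subset.

Mentions unmatched by sieve 1 fall through to sieve 2; mentions
unpredictable by both get no prediction and score 0 under the
over-prediction-penalized accuracy.  Every tie-break is a total order,
so prediction is deterministic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence
import warnings

import numpy as np

from .io.embeddings import EmbeddingTable
from .model import DatasetSplit, Mention, Ontology, PredictionSet
from .text import BASELINE_PREPROC, PreprocConfig, normalize_surface, tokenize

__all__ = [
    "AugmentedLexicon",
    "build_augmented_lexicon",
    "exact_match_predict",
    "embed_text",
    "embed_mention",
    "ProjectionConfig",
    "ProjectionModel",
    "fit_projection",
    "LabelIndex",
    "nearest_label_predict",
    "SieveNormalizer",
]


@dataclass(frozen=True)
class LexiconEntry:
    concept_id: str
    provenance: str  # "ontology-label" | "training-mention"
    frequency: int   # training annotation count (0 for ontology labels)


class AugmentedLexicon:
    """Normalized label string -> single concept map."""

    def __init__(self, entries: Mapping[str, LexiconEntry], preproc: PreprocConfig):
        self.entries = dict(entries)
        self.preproc = preproc

    def lookup(self, normalized: str) -> LexiconEntry | None:
        return self.entries.get(normalized)

    def __len__(self) -> int:
        return len(self.entries)


def build_augmented_lexicon(
    ontology: Ontology,
    train: DatasetSplit | None = None,
    preproc: PreprocConfig = BASELINE_PREPROC,
) -> AugmentedLexicon:
    """Build the sieve-1 lexicon.

    Ontology labels enter first (collisions keep the lexicographically
    smallest (concept id, label)); training surfaces are added for their
    most frequent annotating concept, ties broken by smallest concept id;
    a training surface colliding with an ontology label is ignored.
    """
    if len(ontology) == 0:
        raise ValueError("empty ontology")
    entries: dict[str, LexiconEntry] = {}
    for concept_id in sorted(ontology.concepts):
        for label in ontology.concepts[concept_id].labels:
            key = normalize_surface(label, preproc)
            if key and key not in entries:
                entries[key] = LexiconEntry(concept_id, "ontology-label", 0)
    if train is not None:
        surface_counts: dict[str, Counter[str]] = {}
        by_id = {m.id: m for m in train.mentions}
        for mention_id, annotation in train.gold.items():
            key = normalize_surface(by_id[mention_id].surface, preproc)
            if not key:
                continue
            counter = surface_counts.setdefault(key, Counter())
            for concept_id in annotation.concept_ids:
                counter[concept_id] += 1
        for key, counter in surface_counts.items():
            if key in entries:  # ontology label wins
                continue
            if not counter:
                continue
            best_count = max(counter.values())
            best_concept = min(
                cid for cid, count in counter.items() if count == best_count
            )
            entries[key] = LexiconEntry(best_concept, "training-mention", best_count)
    return AugmentedLexicon(entries, preproc)


def exact_match_predict(
    mention: Mention | str, lexicon: AugmentedLexicon
) -> str | None:
    """Sieve-1 prediction: the unique concept for the normalized surface."""
    surface = mention.surface if isinstance(mention, Mention) else mention
    entry = lexicon.lookup(normalize_surface(surface, lexicon.preproc))
    return entry.concept_id if entry is not None else None


def embed_text(text: str, table: EmbeddingTable) -> np.ndarray | None:
    """Mean embedding of in-vocabulary tokens; lowercase fallback per
    token; ``None`` when every token is out of vocabulary."""
    vectors = []
    for token in tokenize(text):
        vector = table.get(token)
        if vector is None:
            vector = table.get(token.lower())
        if vector is not None:
            vectors.append(vector)
    if not vectors:
        return None
    return np.mean(np.stack(vectors), axis=0)


def embed_mention(mention: Mention | str, table: EmbeddingTable) -> np.ndarray | None:
    surface = mention.surface if isinstance(mention, Mention) else mention
    return embed_text(surface, table)


@dataclass(frozen=True)
class ProjectionConfig:
    ridge_lambda: float = 1e-6
    weak_supervision: bool = False  # add every (label, concept) pair of the ontology


@dataclass
class ProjectionModel:
    """Fitted linear map W from mention-embedding to label-embedding space."""

    weights: np.ndarray
    fitted: bool = False
    n_pairs: int = 0
    config: ProjectionConfig = field(default_factory=ProjectionConfig)

    def project(self, vector: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("projection model is not fitted")
        return self.weights @ vector


def fit_projection(
    train: DatasetSplit,
    ontology: Ontology,
    table: EmbeddingTable,
    config: ProjectionConfig = ProjectionConfig(),
) -> ProjectionModel:
    """Least-squares fit of W minimizing sum ||W v(m) - v(label(c))||^2
    (+ ridge penalty) over training (mention, concept) pairs.

    The target of a pair is the embedding of the concept's preferred
    (first) label.  With ``weak_supervision`` every (label, concept)
    couple of the ontology is added as an extra pair.  Pairs whose
    mention or label cannot be embedded are skipped.
    """
    sources: list[np.ndarray] = []
    targets: list[np.ndarray] = []
    label_vectors: dict[str, np.ndarray | None] = {}

    def preferred_vector(concept_id: str) -> np.ndarray | None:
        if concept_id not in label_vectors:
            label_vectors[concept_id] = embed_text(
                ontology[concept_id].preferred_label, table
            )
        return label_vectors[concept_id]

    by_id = {m.id: m for m in train.mentions}
    for mention_id, annotation in sorted(train.gold.items()):
        mention_vector = embed_mention(by_id[mention_id], table)
        if mention_vector is None:
            continue
        for concept_id in sorted(annotation.concept_ids):
            target = preferred_vector(concept_id)
            if target is not None:
                sources.append(mention_vector)
                targets.append(target)
    if config.weak_supervision:
        for concept_id in sorted(ontology.concepts):
            target = preferred_vector(concept_id)
            if target is None:
                continue
            for label in ontology.concepts[concept_id].labels:
                source = embed_text(label, table)
                if source is not None:
                    sources.append(source)
                    targets.append(target)
    if not sources:
        raise ValueError("no usable (mention, label) training pairs")
    X = np.stack(sources).astype(np.float64)  # (n, d)
    Y = np.stack(targets).astype(np.float64)  # (n, d)
    d = X.shape[1]
    if X.shape[0] < d:
        warnings.warn(
            f"only {X.shape[0]} training pairs for dimension {d}; "
            "the projection may be underdetermined"
        )
    if config.ridge_lambda > 0:
        gram = X.T @ X + config.ridge_lambda * np.eye(d)
        W = np.linalg.solve(gram, X.T @ Y).T
    else:
        W = np.linalg.lstsq(X, Y, rcond=None)[0].T
    if not np.all(np.isfinite(W)):
        raise ValueError("projection fit produced non-finite coefficients")
    return ProjectionModel(weights=W, fitted=True, n_pairs=X.shape[0], config=config)


class LabelIndex:
    """All labels of a concept subset, embedded and L2-normalized, in
    lexicographic (concept id, label) order so that cosine argmax ties
    resolve deterministically."""

    def __init__(
        self,
        ontology: Ontology,
        table: EmbeddingTable,
        concept_subset: Iterable[str] | None = None,
    ) -> None:
        subset = (
            sorted(ontology.concepts)
            if concept_subset is None
            else sorted(ontology.resolve(cid) for cid in set(concept_subset))
        )
        if not subset:
            raise ValueError("empty concept subset")
        unknown = [cid for cid in subset if cid not in ontology.concepts]
        if unknown:
            raise KeyError(f"subset ids not in ontology: {unknown!r}")
        self.pairs: list[tuple[str, str]] = []
        vectors: list[np.ndarray] = []
        for concept_id in subset:
            for label in sorted(ontology.concepts[concept_id].labels):
                vector = embed_text(label, table)
                if vector is None:
                    continue
                norm = float(np.linalg.norm(vector))
                if norm == 0.0:
                    continue
                self.pairs.append((concept_id, label))
                vectors.append(vector / norm)
        if not vectors:
            raise ValueError("no embeddable label in the concept subset")
        self.matrix = np.stack(vectors)  # (n_labels, d), unit rows

    def nearest(self, vector: np.ndarray) -> tuple[str, str, float]:
        """(concept_id, label, cosine) of the nearest label embedding."""
        norm = float(np.linalg.norm(vector))
        if norm == 0.0:
            raise ValueError("cannot rank a zero vector")
        scores = self.matrix @ (vector / norm)
        best = int(np.argmax(scores))  # first index wins ties
        concept_id, label = self.pairs[best]
        return concept_id, label, float(scores[best])


def nearest_label_predict(
    mention: Mention | str,
    model: ProjectionModel,
    index: LabelIndex,
    table: EmbeddingTable,
) -> tuple[str, float] | None:
    """Sieve-2 prediction: cosine-nearest label of the projected mention
    embedding; ``None`` when the mention is unembeddable."""
    vector = embed_mention(mention, table)
    if vector is None:
        return None
    projected = model.project(vector)
    if float(np.linalg.norm(projected)) == 0.0:
        return None
    concept_id, _, score = index.nearest(projected)
    return concept_id, score


class SieveNormalizer:
    """Exact match first, embedding projection second.

    ``stats`` records how many mentions each stage answered (and how
    many neither could), for call accounting and run metadata.
    """

    def __init__(
        self,
        lexicon: AugmentedLexicon,
        model: ProjectionModel | None = None,
        index: LabelIndex | None = None,
        table: EmbeddingTable | None = None,
    ) -> None:
        if model is not None and (index is None or table is None):
            raise ValueError("projection stage needs a label index and a table")
        self.lexicon = lexicon
        self.model = model
        self.index = index
        self.table = table
        self.stats = {"lexicon": 0, "projection": 0, "unpredicted": 0}

    def predict_mention(self, mention: Mention | str) -> tuple[str, float] | None:
        concept_id = exact_match_predict(mention, self.lexicon)
        if concept_id is not None:
            self.stats["lexicon"] += 1
            return concept_id, 1.0
        if self.model is not None:
            result = nearest_label_predict(
                mention, self.model, self.index, self.table
            )
            if result is not None:
                self.stats["projection"] += 1
                return result
        self.stats["unpredicted"] += 1
        return None

    def predict(self, split: DatasetSplit) -> PredictionSet:
        preds = PredictionSet()
        for mention in split.mentions:
            result = self.predict_mention(mention)
            if result is not None:
                concept_id, score = result
                preds.set(mention.id, [(concept_id, score)])
        return preds
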