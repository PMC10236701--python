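"""Seeded generator of toy ontologies, corpora with controlled bias
rates, and embeddings.

Rates are satisfied by construction (per-category mention quotas), not
by rejection sampling, so the indicator round-trip is exact whenever the
requested percentages divide the split sizes:

* every non-NIL test mention gets its own primary concept, so the test
  concept count equals the number of non-NIL test mentions and the ZSL
  quota is exact;
* redundant test mentions reuse, verbatim, a (surface, gold) example
  planted in the training split;
* ambiguous test mentions come in pairs sharing a surface form but
  annotated with different concepts;
* multi-normalized mentions borrow a second concept from another test
  mention (so the concept universe is unchanged);
* NIL mentions use dedicated out-of-ontology tokens.

Mention surfaces are deterministic suffix variants of concept labels
("-s" solvable by stemming, "-es" deliberately not), giving the
dictionary sieve a known solvable/unsolvable partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io.embeddings import EmbeddingTable
from .model import (
    Concept,
    DatasetSplit,
    GoldAnnotation,
    Mention,
    Ontology,
)
from .text import tokenize

__all__ = ["GeneratorSpec", "SyntheticDataset", "generate_ontology",
           "generate_splits", "generate_embeddings", "generate_dataset"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Knobs of the generator; all rates are percentages in [0, 100]."""

    n_concepts: int = 30
    labels_per_concept: tuple[int, int] = (1, 2)
    tokens_per_concept: int = 3
    train_size: int = 40
    dev_size: int = 5
    test_size: int = 20
    redundancy: float = 0.0
    zsl: float = 0.0
    ambiguity: float = 0.0
    multinorm: float = 0.0
    nil: float = 0.0
    dim: int = 16
    noise: float = 0.0
    test_surface_variant: int = 1  # 1 = stem-solvable "-s", 2 = unsolvable "-es"
    seed: int = 0

    def __post_init__(self) -> None:
        for rate_name in ("redundancy", "zsl", "ambiguity", "multinorm", "nil"):
            value = getattr(self, rate_name)
            if not 0.0 <= value <= 100.0:
                raise ValueError(f"{rate_name} must be in [0, 100], got {value}")
        if min(self.n_concepts, self.train_size, self.test_size) < 1:
            raise ValueError("sizes must be positive")
        lo, hi = self.labels_per_concept
        if not 1 <= lo <= hi <= self.tokens_per_concept:
            raise ValueError("labels_per_concept must fit in the token pool")
        if self.dim < 2:
            raise ValueError("embedding dimension must be >= 2")
        if self.test_surface_variant not in (1, 2):
            raise ValueError("test_surface_variant must be 1 or 2")


@dataclass
class SyntheticDataset:
    spec: GeneratorSpec
    ontology: Ontology
    train: DatasetSplit
    dev: DatasetSplit
    test: DatasetSplit
    embeddings: EmbeddingTable
    token_owner: dict[str, str | None] = field(default_factory=dict)


def _concept_id(i: int) -> str:
    return f"SYN:{i:04d}"


def _base_tokens(i: int, spec: GeneratorSpec) -> list[str]:
    return [f"c{i:04d}t{j}" for j in range(spec.tokens_per_concept)]


def generate_ontology(
    spec: GeneratorSpec, rng: np.random.Generator | None = None
) -> Ontology:
    """Single-rooted random tree; labels are 1-3 token strings drawn from
    each concept's private token pool (unique across concepts by
    construction)."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    concepts: list[Concept] = []
    lo, hi = spec.labels_per_concept
    for i in range(spec.n_concepts):
        tokens = _base_tokens(i, spec)
        n_labels = int(rng.integers(lo, hi + 1))
        labels: list[str] = []
        for j in range(n_labels):
            width = int(rng.integers(1, min(3, len(tokens)) + 1))
            start = j % len(tokens)
            chosen = [tokens[(start + t) % len(tokens)] for t in range(width)]
            label = " ".join(chosen)
            if label not in labels:
                labels.append(label)
        parents = (
            frozenset()
            if i == 0
            else frozenset({_concept_id(int(rng.integers(0, i)))})
        )
        concepts.append(
            Concept(id=_concept_id(i), labels=tuple(labels), parents=parents)
        )
    return Ontology(concepts, name="synthetic", version=str(spec.seed))


def _variant(label: str, j: int) -> str:
    """Deterministic surface variant j of a label (0 = the label)."""
    tokens = label.split(" ")
    if j == 0:
        return label
    if j == 1:
        return " ".join(tokens[:-1] + [tokens[-1] + "s"])
    if j == 2:
        return " ".join(tokens[:-1] + [tokens[-1] + "es"])
    # j >= 3: reversed token order with a cycling plural suffix
    suffix = "s" if j % 2 else "es"
    reversed_tokens = list(reversed(tokens))
    return " ".join(reversed_tokens[:-1] + [reversed_tokens[-1] + suffix + str(j)])


def _quota(rate: float, total: int) -> int:
    return int(round(rate * total / 100.0))


def generate_splits(
    spec: GeneratorSpec,
    ontology: Ontology,
    rng: np.random.Generator | None = None,
) -> tuple[DatasetSplit, DatasetSplit, DatasetSplit]:
    """Build (train, dev, test) with the requested test-split rates.

    Raises ``ValueError`` naming the violated constraint when the rate
    combination is infeasible.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 1)
    T = spec.test_size
    q_nil = _quota(spec.nil, T)
    m_multi = _quota(spec.multinorm, T)
    r_red = _quota(spec.redundancy, T)
    n_amb_pairs = _quota(spec.ambiguity, T) // 2
    n_amb = 2 * n_amb_pairs
    non_nil = T - q_nil
    if q_nil + r_red + n_amb + m_multi > T:
        raise ValueError(
            "infeasible rates: nil + redundancy + ambiguity + multinorm "
            f"quotas ({q_nil}+{r_red}+{n_amb}+{m_multi}) exceed test size {T}"
        )
    if non_nil > spec.n_concepts:
        raise ValueError(
            f"need {non_nil} distinct primary concepts for the test split "
            f"but the ontology has only {spec.n_concepts}"
        )
    n_zsl = _quota(spec.zsl, non_nil) if non_nil else 0
    if n_zsl > non_nil - r_red - n_amb:
        raise ValueError(
            "infeasible rates: ZSL concepts cannot be carried by redundant "
            f"or ambiguous mentions ({n_zsl} ZSL > {non_nil - r_red - n_amb} free)"
        )
    if m_multi > 0 and non_nil < 2:
        raise ValueError("multinorm requires at least 2 non-NIL test mentions")

    concept_ids = sorted(ontology.concepts)
    # primary concept of each non-NIL test mention; order: redundant,
    # ambiguous pairs, then the rest — ZSL concepts go to the tail.
    primaries = concept_ids[:non_nil]
    shared = primaries[: non_nil - n_zsl]
    zsl_concepts = primaries[non_nil - n_zsl:]
    if r_red > 0 and not shared:
        raise ValueError("redundancy requires at least one non-ZSL concept")
    leftover = concept_ids[non_nil:]

    variant_test = spec.test_surface_variant
    test_mentions: list[Mention] = []
    test_gold: dict[str, GoldAnnotation] = {}
    train_examples: list[tuple[str, frozenset[str]]] = []  # planted for redundancy

    def add_test(surface: str, concepts: frozenset[str]) -> None:
        index = len(test_mentions)
        mention = Mention(
            id=f"d{index // 5:03d}:T{index % 5 + 1}",
            doc_id=f"d{index // 5:03d}",
            surface=surface,
            entity_type="Habitat",
        )
        test_mentions.append(mention)
        test_gold[mention.id] = GoldAnnotation(
            mention_id=mention.id, concept_ids=concepts
        )

    cursor = 0
    # 1. redundant mentions: verbatim copies of planted train examples
    for _ in range(r_red):
        concept = primaries[cursor]
        surface = _variant(ontology[concept].preferred_label, 0)
        example = (surface, frozenset({concept}))
        add_test(*example)
        train_examples.append(example)
        cursor += 1
    # 2. ambiguous pairs: same surface, different singleton gold
    for pair in range(n_amb_pairs):
        c1, c2 = primaries[cursor], primaries[cursor + 1]
        surface = _variant(ontology[c1].preferred_label, variant_test)
        add_test(surface, frozenset({c1}))
        add_test(surface, frozenset({c2}))
        cursor += 2
    # 3. multi-normalized mentions: own primary + another mention's primary
    multinorm_start = cursor
    for k in range(m_multi):
        concept = primaries[cursor]
        other = primaries[(cursor + 1) % non_nil]
        if other == concept:  # only possible when non_nil == 1, guarded above
            raise ValueError("cannot pick a distinct second concept")
        surface = _variant(ontology[concept].preferred_label, variant_test)
        add_test(surface, frozenset({concept, other}))
        cursor += 1
    # 4. plain mentions for the remaining primaries
    while cursor < non_nil:
        concept = primaries[cursor]
        surface = _variant(ontology[concept].preferred_label, variant_test)
        add_test(surface, frozenset({concept}))
        cursor += 1
    # 5. NIL mentions on out-of-ontology tokens
    for k in range(q_nil):
        add_test(f"nil{k:03d}a nil{k:03d}b", frozenset())

    # training split: one v0 mention per shared concept (this is what makes
    # redundant test examples redundant), leftovers for variety, then
    # frequency filler duplicating shared examples.
    train_mentions: list[Mention] = []
    train_gold: dict[str, GoldAnnotation] = {}

    def add_train(surface: str, concepts: frozenset[str]) -> None:
        index = len(train_mentions)
        mention = Mention(
            id=f"tr{index // 8:03d}:T{index % 8 + 1}",
            doc_id=f"tr{index // 8:03d}",
            surface=surface,
            entity_type="Habitat",
        )
        train_mentions.append(mention)
        train_gold[mention.id] = GoldAnnotation(
            mention_id=mention.id, concept_ids=concepts
        )

    required = [
        (_variant(ontology[c].preferred_label, 0), frozenset({c})) for c in shared
    ]
    if spec.train_size < len(required):
        raise ValueError(
            f"train_size {spec.train_size} too small: every non-ZSL test "
            f"concept needs a training mention ({len(required)} required)"
        )
    for example in required:
        add_train(*example)
    budget = spec.train_size - len(required)
    for concept in leftover:
        if budget == 0:
            break
        add_train(_variant(ontology[concept].preferred_label, 0), frozenset({concept}))
        budget -= 1
    filler_index = 0
    while budget > 0 and shared:
        concept = shared[filler_index % len(shared)]
        add_train(_variant(ontology[concept].preferred_label, 0), frozenset({concept}))
        filler_index += 1
        budget -= 1

    # dev split: variant-2 surfaces over shared concepts (never collides
    # with train or test surfaces when the test variant is 1)
    dev_mentions: list[Mention] = []
    dev_gold: dict[str, GoldAnnotation] = {}
    dev_pool = shared if shared else concept_ids
    for k in range(spec.dev_size):
        concept = dev_pool[k % len(dev_pool)]
        mention = Mention(
            id=f"dv{k:03d}:T1",
            doc_id=f"dv{k:03d}",
            surface=_variant(ontology[concept].preferred_label, 3 + k // len(dev_pool)),
            entity_type="Habitat",
        )
        dev_mentions.append(mention)
        dev_gold[mention.id] = GoldAnnotation(
            mention_id=mention.id, concept_ids=frozenset({concept})
        )

    return (
        DatasetSplit("train", train_mentions, train_gold),
        DatasetSplit("dev", dev_mentions, dev_gold),
        DatasetSplit("test", test_mentions, test_gold),
    )


def _anchor_matrix(n: int, d: int, rng: np.random.Generator) -> np.ndarray:
    if d >= n:  # orthogonal one-hot anchors: guaranteed separation
        anchors = np.zeros((n, d))
        anchors[np.arange(n), np.arange(n)] = 1.0
        return anchors
    vectors = rng.normal(size=(n, d))
    return vectors / np.linalg.norm(vectors, axis=1, keepdims=True)


def generate_embeddings(
    spec: GeneratorSpec,
    ontology: Ontology,
    token_owner: dict[str, str | None],
    rng: np.random.Generator | None = None,
) -> EmbeddingTable:
    """Token vectors: a concept's tokens cluster around its anchor with
    noise sigma; ownerless tokens get far random vectors."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 2)
    concept_ids = sorted(ontology.concepts)
    anchors = _anchor_matrix(len(concept_ids), spec.dim, rng)
    anchor_of = {cid: anchors[i] for i, cid in enumerate(concept_ids)}
    vectors: dict[str, np.ndarray] = {}
    for token in sorted(token_owner):
        owner = token_owner[token]
        if owner is None:
            vector = rng.normal(size=spec.dim)
            vector = 3.0 * vector / np.linalg.norm(vector)
        else:
            vector = anchor_of[owner] + spec.noise * rng.normal(size=spec.dim)
        vectors[token] = vector
    return EmbeddingTable(vectors)


def _collect_token_owner(
    ontology: Ontology, splits: Sequence[DatasetSplit]
) -> dict[str, str | None]:
    owner: dict[str, str | None] = {}
    base_owner: dict[str, str] = {}
    for concept_id, concept in ontology.concepts.items():
        for label in concept.labels:
            for token in tokenize(label):
                owner.setdefault(token, concept_id)
                base_owner.setdefault(token, concept_id)
    for split in splits:
        for mention in split.mentions:
            for token in tokenize(mention.surface):
                if token in owner:
                    continue
                resolved: str | None = None
                for suffix in ("s", "es"):  # variant forms inherit ownership
                    if token.endswith(suffix) and token[: -len(suffix)] in base_owner:
                        resolved = base_owner[token[: -len(suffix)]]
                        break
                if resolved is None:
                    for base, concept_id in base_owner.items():
                        if token.startswith(base):
                            resolved = concept_id
                            break
                owner[token] = resolved
    return owner


def generate_dataset(spec: GeneratorSpec) -> SyntheticDataset:
    """One-call generation of ontology, splits and embeddings, all
    reproducible from (spec, seed)."""
    ontology = generate_ontology(spec)
    train, dev, test = generate_splits(spec, ontology)
    token_owner = _collect_token_owner(ontology, [train, dev, test])
    embeddings = generate_embeddings(spec, ontology, token_owner)
    return SyntheticDataset(
        spec=spec,
        ontology=ontology,
        train=train,
        dev=dev,
        test=test,
        embeddings=embeddings,
        token_owner=token_owner,
    )
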