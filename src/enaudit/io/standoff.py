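"""BioNLP-ST standoff (.a1/.a2 + .txt) reader and writer.

The .a1 file carries entity annotations, one per line::

    T5<TAB>Habitat 12 25<TAB>gopher tortoise

with ";"-separated fragments for discontinuous mentions.  The .a2 file
carries normalization lines referencing entities::

    N3<TAB>OntoBiotope Annotation:T5 Referent:OBT:001351

Multiple normalization lines for one entity form a multi-normalization
gold set.  Fragment texts are joined by a single space to build the
surface form.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable

from ..model import DatasetSplit, GoldAnnotation, Mention, Ontology

__all__ = ["read_standoff_corpus", "write_standoff_corpus", "StandoffError"]

DEFAULT_ENTITY_TYPES = frozenset({"Habitat"})


class StandoffError(ValueError):
    """Malformed standoff input; message names file and line number."""


def _parse_spans(span_field: str, path: Path, lineno: int) -> tuple[tuple[int, int], ...]:
    spans: list[tuple[int, int]] = []
    for fragment in span_field.split(";"):
        parts = fragment.split()
        if len(parts) != 2:
            raise StandoffError(f"{path}:{lineno}: malformed span {fragment!r}")
        try:
            start, end = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise StandoffError(f"{path}:{lineno}: non-integer span") from exc
        if end < start:
            raise StandoffError(f"{path}:{lineno}: inverted span")
        spans.append((start, end))
    return tuple(spans)


def _parse_a1(path: Path, doc_text: str | None) -> dict[str, Mention]:
    doc_id = path.stem
    mentions: dict[str, Mention] = {}
    for lineno, raw in enumerate(path.read_text("utf-8").splitlines(), start=1):
        if not raw.strip():
            continue
        if not raw.startswith("T"):  # title/paragraph meta lines etc.
            continue
        columns = raw.split("\t")
        if len(columns) < 2:
            raise StandoffError(f"{path}:{lineno}: expected tab-separated columns")
        entity_id = columns[0]
        type_and_spans = columns[1].split(" ", 1)
        if len(type_and_spans) != 2:
            raise StandoffError(f"{path}:{lineno}: missing span list")
        entity_type, span_field = type_and_spans
        spans = _parse_spans(span_field, path, lineno)
        if doc_text is not None:
            surface = " ".join(doc_text[s:e] for s, e in spans)
        elif len(columns) >= 3:
            surface = columns[2]
        else:
            raise StandoffError(f"{path}:{lineno}: no surface text available")
        mentions[entity_id] = Mention(
            id=f"{doc_id}:{entity_id}",
            doc_id=doc_id,
            surface=surface,
            spans=spans,
            entity_type=entity_type,
        )
    return mentions


def _parse_a2(path: Path) -> list[tuple[str, str]]:
    """Yield (entity_id, concept_id) pairs from normalization lines."""
    pairs: list[tuple[str, str]] = []
    for lineno, raw in enumerate(path.read_text("utf-8").splitlines(), start=1):
        if not raw.strip() or not raw.startswith("N"):
            continue
        columns = raw.split("\t")
        if len(columns) < 2:
            raise StandoffError(f"{path}:{lineno}: expected tab-separated columns")
        entity_id = None
        concept_id = None
        for token in columns[1].split()[1:]:  # first token = relation name
            if ":" not in token:
                raise StandoffError(f"{path}:{lineno}: malformed argument {token!r}")
            key, value = token.split(":", 1)
            if key == "Annotation":
                entity_id = value
            elif key == "Referent":
                concept_id = value
        if entity_id is None or concept_id is None:
            raise StandoffError(
                f"{path}:{lineno}: normalization needs Annotation and Referent"
            )
        pairs.append((entity_id, concept_id))
    return pairs


def read_standoff_corpus(
    directory: str | Path,
    ontology: Ontology | None,
    entity_types: Iterable[str] | None = DEFAULT_ENTITY_TYPES,
    strict: bool = True,
    name: str | None = None,
) -> DatasetSplit:
    """Load every .a1/.a2 pair under ``directory`` into a DatasetSplit.

    Mentions whose entity type is outside ``entity_types`` are dropped
    (pass ``None`` to keep all types).  Referent ids absent from
    ``ontology`` raise in strict mode and are skipped with a warning
    otherwise; pass ``ontology=None`` to disable resolution entirely.
    """
    directory = Path(directory)
    type_filter = frozenset(entity_types) if entity_types is not None else None
    mentions: list[Mention] = []
    gold: dict[str, GoldAnnotation] = {}
    a1_paths = sorted(directory.glob("*.a1"))
    if not a1_paths:
        raise FileNotFoundError(f"no .a1 files under {directory}")
    for a1_path in a1_paths:
        txt_path = a1_path.with_suffix(".txt")
        doc_text = txt_path.read_text("utf-8") if txt_path.exists() else None
        doc_mentions = _parse_a1(a1_path, doc_text)
        kept = {
            eid: m
            for eid, m in doc_mentions.items()
            if type_filter is None or m.entity_type in type_filter
        }
        concept_sets: dict[str, set[str]] = {eid: set() for eid in kept}
        a2_path = a1_path.with_suffix(".a2")
        if a2_path.exists():
            for entity_id, concept_id in _parse_a2(a2_path):
                if entity_id not in kept:
                    continue  # normalization of a filtered-out entity type
                if ontology is not None:
                    try:
                        concept_id = ontology.resolve(concept_id)
                    except KeyError:
                        if strict:
                            raise StandoffError(
                                f"{a2_path}: referent {concept_id!r} not in ontology"
                            ) from None
                        warnings.warn(
                            f"{a2_path}: skipping unresolvable referent {concept_id!r}"
                        )
                        continue
                concept_sets[entity_id].add(concept_id)
        for entity_id, mention in sorted(kept.items()):
            mentions.append(mention)
            gold[mention.id] = GoldAnnotation(
                mention_id=mention.id,
                concept_ids=frozenset(concept_sets[entity_id]),
            )
    return DatasetSplit(name or directory.name, mentions, gold)


def write_standoff_corpus(
    split: DatasetSplit,
    directory: str | Path,
    resource_name: str = "OntoBiotope",
) -> None:
    """Serialize a split as .txt/.a1/.a2 triples, one per document.

    Document text is reconstructed by concatenating mention surfaces
    (sufficient for round-tripping synthetic corpora; real corpora carry
    their own text).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    by_doc: dict[str, list[Mention]] = {}
    for mention in split.mentions:
        by_doc.setdefault(mention.doc_id, []).append(mention)
    for doc_id, doc_mentions in sorted(by_doc.items()):
        text_parts: list[str] = []
        a1_lines: list[str] = []
        a2_lines: list[str] = []
        cursor = 0
        norm_index = 1
        for i, mention in enumerate(doc_mentions, start=1):
            start = cursor
            end = start + len(mention.surface)
            text_parts.append(mention.surface)
            cursor = end + 1  # single separating space
            entity_id = f"T{i}"
            a1_lines.append(
                f"{entity_id}\t{mention.entity_type or 'Habitat'} {start} {end}"
                f"\t{mention.surface}"
            )
            annotation = split.gold.get(mention.id)
            if annotation is not None:
                for concept_id in sorted(annotation.concept_ids):
                    a2_lines.append(
                        f"N{norm_index}\t{resource_name} Annotation:{entity_id}"
                        f" Referent:{concept_id}"
                    )
                    norm_index += 1
        (directory / f"{doc_id}.txt").write_text(" ".join(text_parts) + "\n", "utf-8")
        (directory / f"{doc_id}.a1").write_text(
            "\n".join(a1_lines) + ("\n" if a1_lines else ""), "utf-8"
        )
        (directory / f"{doc_id}.a2").write_text(
            "\n".join(a2_lines) + ("\n" if a2_lines else ""), "utf-8"
        )
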