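"""PubTator-format corpus reader (NCBI Disease Corpus layout).

Documents are blocks separated by blank lines::

    10021369|t|Identification of APC2 ...
    10021369|a|The adenomatous polyposis coli (APC) ...
    10021369<TAB>66<TAB>77<TAB>colon cancer<TAB>SpecificDisease<TAB>D003110

The concept field is split on both "+" (composite mentions) and "|"
(alternative ids) into a multi-normalization gold set; mentions whose
field contains "+" are flagged composite for the lenient scorer.  Bare
MeSH/OMIM ids are prefixed ("D003110" -> "MESH:D003110") before ontology
lookup.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

from ..model import DatasetSplit, GoldAnnotation, Mention, Ontology

__all__ = ["read_pubtator_corpus", "PubTatorError", "split_concept_field"]


class PubTatorError(ValueError):
    """Malformed PubTator input; message names file and line number."""


def _prefix_id(concept_id: str) -> str:
    concept_id = concept_id.strip()
    if ":" in concept_id:
        return concept_id
    return f"MESH:{concept_id}"


def split_concept_field(field: str) -> tuple[frozenset[str], bool]:
    """Split a concept field on "+" and "|"; returns (ids, is_composite)."""
    is_composite = "+" in field
    parts = [p for p in re.split(r"[+|]", field) if p.strip()]
    return frozenset(_prefix_id(p) for p in parts), is_composite


def read_pubtator_corpus(
    path: str | Path,
    ontology: Ontology | None,
    strict: bool = True,
    name: str | None = None,
) -> DatasetSplit:
    """Load a PubTator file into a DatasetSplit.

    The returned split carries ``composite_mention_ids``: the mention ids
    whose gold annotation came from a "+"-joined composite concept field.
    """
    path = Path(path)
    mentions: list[Mention] = []
    gold: dict[str, GoldAnnotation] = {}
    composite_ids: set[str] = set()
    counters: dict[str, int] = {}
    for lineno, raw in enumerate(path.read_text("utf-8").splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if "|t|" in line.split("\t")[0] or "|a|" in line.split("\t")[0]:
            continue  # title / abstract lines
        columns = line.split("\t")
        if len(columns) < 6:
            raise PubTatorError(
                f"{path}:{lineno}: expected >= 6 tab-separated columns"
            )
        pmid, start_s, end_s, text, entity_type, concept_field = columns[:6]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise PubTatorError(f"{path}:{lineno}: non-integer offsets") from exc
        counters[pmid] = counters.get(pmid, 0) + 1
        mention_id = f"{pmid}:{counters[pmid]}"
        mention = Mention(
            id=mention_id,
            doc_id=pmid,
            surface=text,
            spans=((start, end),),
            entity_type=entity_type,
        )
        concept_ids, is_composite = split_concept_field(concept_field)
        resolved: set[str] = set()
        for concept_id in concept_ids:
            if ontology is not None:
                try:
                    concept_id = ontology.resolve(concept_id)
                except KeyError:
                    if strict:
                        raise PubTatorError(
                            f"{path}:{lineno}: concept {concept_id!r} not in ontology"
                        ) from None
                    warnings.warn(
                        f"{path}:{lineno}: skipping unresolvable id {concept_id!r}"
                    )
                    continue
            resolved.add(concept_id)
        mentions.append(mention)
        gold[mention_id] = GoldAnnotation(
            mention_id=mention_id, concept_ids=frozenset(resolved)
        )
        if is_composite:
            composite_ids.add(mention_id)
    if not mentions:
        raise PubTatorError(f"{path}: no mention lines found")
    split = DatasetSplit(name or path.stem, mentions, gold)
    split.composite_mention_ids = composite_ids  # type: ignore[attr-defined]
    return split
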