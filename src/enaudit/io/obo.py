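"""Minimal OBO 1.2 term-stanza reader (OntoBiotope-style files).

Keeps per-term: id, name (preferred label), synonyms (EXACT scope by
default), alt_ids (registered as aliases) and is_a parents; obsolete
terms are excluded.  Supports restriction to the sub-hierarchy rooted at
a given concept id (for extracting the habitat part).
"""

from __future__ import annotations

import re
from pathlib import Path

from ..model import Concept, Ontology

__all__ = ["read_obo_ontology"]

_SYNONYM_RE = re.compile(r'^"(?P<text>(?:[^"\\]|\\.)*)"\s*(?P<scope>[A-Z_]+)?')


def _dedupe(labels: list[str]) -> tuple[str, ...]:
    seen: set[str] = set()
    out: list[str] = []
    for label in labels:
        if label and label not in seen:
            seen.add(label)
            out.append(label)
    return tuple(out)


def read_obo_ontology(
    path: str | Path,
    root_id: str | None = None,
    synonym_scopes: frozenset[str] = frozenset({"EXACT"}),
    name: str | None = None,
) -> Ontology:
    """Parse an OBO file; optionally restrict to descendants of ``root_id``.

    ``synonym_scopes`` selects which synonym scopes become extra labels
    (pass ``None`` to keep all scopes).
    """
    path = Path(path)
    data_version = format_version = ""
    stanzas: list[dict[str, object]] = []
    current: dict[str, object] | None = None
    in_term = False
    for raw in path.read_text("utf-8").splitlines():
        line = raw.strip()
        if line.startswith("!"):
            continue
        if line.startswith("["):
            in_term = line == "[Term]"
            if in_term:
                current = {"synonyms": [], "parents": set(), "alt_ids": []}
                stanzas.append(current)
            else:
                current = None
            continue
        if not line or ":" not in line:
            continue
        tag, _, value = line.partition(":")
        value = value.split(" !")[0].strip()
        if not in_term or current is None:
            if tag == "data-version" and not data_version:
                data_version = value
            elif tag == "format-version" and not format_version:
                format_version = value
            continue
        if tag == "id":
            current["id"] = value
        elif tag == "name":
            current["name"] = value
        elif tag == "alt_id":
            current["alt_ids"].append(value)  # type: ignore[union-attr]
        elif tag == "synonym":
            match = _SYNONYM_RE.match(value)
            if match:
                scope = match.group("scope") or "RELATED"
                if synonym_scopes is None or scope in synonym_scopes:
                    text = match.group("text").replace('\\"', '"')
                    current["synonyms"].append(text)  # type: ignore[union-attr]
        elif tag == "is_a":
            current["parents"].add(value)  # type: ignore[union-attr]
        elif tag == "is_obsolete" and value.lower() == "true":
            current["obsolete"] = True

    concepts: dict[str, Concept] = {}
    aliases: dict[str, str] = {}
    for stanza in stanzas:
        if stanza.get("obsolete") or "id" not in stanza:
            continue
        concept_id = str(stanza["id"])
        labels = _dedupe(
            [str(stanza.get("name", concept_id))] + list(stanza["synonyms"])  # type: ignore[arg-type]
        )
        concepts[concept_id] = Concept(
            id=concept_id,
            labels=labels,
            parents=frozenset(stanza["parents"]),  # type: ignore[arg-type]
        )
        for alt in stanza["alt_ids"]:  # type: ignore[union-attr]
            aliases[str(alt)] = concept_id

    for concept in concepts.values():
        for parent in concept.parents:
            if parent not in concepts:
                raise ValueError(
                    f"{path}: is_a target {parent!r} of {concept.id!r} not found"
                )

    if root_id is not None:
        provisional = Ontology(concepts.values(), name=name or path.stem,
                               version=data_version or format_version, aliases=aliases)
        keep = provisional.descendants(root_id)
        concepts = {
            cid: Concept(
                id=cid,
                labels=concepts[cid].labels,
                parents=frozenset(p for p in concepts[cid].parents if p in keep),
            )
            for cid in keep
        }
        aliases = {a: t for a, t in aliases.items() if t in concepts}

    return Ontology(
        concepts.values(), name=name or path.stem, version=data_version or format_version, aliases=aliases
    )
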