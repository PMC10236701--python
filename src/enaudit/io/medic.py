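"""CTD MEDIC disease-vocabulary TSV reader.

Column layout of the CTD dump (``#``-prefixed comment header)::

    DiseaseName  DiseaseID  AltDiseaseIDs  Definition  ParentIDs
    TreeNumbers  ParentTreeNumbers  Synonyms  SlimMappings

Multi-valued cells are "|"-separated.  Alternative ids are registered
as aliases resolving to the primary concept; synonyms become extra
labels.
"""

from __future__ import annotations

from pathlib import Path

from ..model import Concept, Ontology

__all__ = ["read_medic_tsv"]

_COL_NAME = 0
_COL_ID = 1
_COL_ALT_IDS = 2
_COL_PARENTS = 4
_COL_SYNONYMS = 7


def _split_multi(cell: str) -> list[str]:
    return [v.strip() for v in cell.split("|") if v.strip()]


def read_medic_tsv(path: str | Path, name: str | None = None) -> Ontology:
    """Parse a MEDIC TSV dump into an Ontology with MESH:/OMIM: ids."""
    path = Path(path)
    rows: list[list[str]] = []
    for raw in path.read_text("utf-8").splitlines():
        if not raw.strip() or raw.startswith("#"):
            continue
        rows.append(raw.rstrip("\n").split("\t"))

    concepts: dict[str, Concept] = {}
    aliases: dict[str, str] = {}
    parent_cells: dict[str, list[str]] = {}
    for row in rows:
        concept_id = row[_COL_ID].strip()
        if not concept_id:
            continue
        if concept_id in concepts:
            raise ValueError(f"{path}: duplicate primary id {concept_id!r}")
        labels: list[str] = [row[_COL_NAME].strip()]
        if len(row) > _COL_SYNONYMS:
            for synonym in _split_multi(row[_COL_SYNONYMS]):
                if synonym not in labels:
                    labels.append(synonym)
        parent_cells[concept_id] = (
            _split_multi(row[_COL_PARENTS]) if len(row) > _COL_PARENTS else []
        )
        concepts[concept_id] = Concept(id=concept_id, labels=tuple(labels))
        if len(row) > _COL_ALT_IDS:
            for alt in _split_multi(row[_COL_ALT_IDS]):
                if alt != concept_id and alt not in concepts:
                    aliases[alt] = concept_id

    # second pass: keep only parent links that resolve inside the file
    resolved: dict[str, Concept] = {}
    for concept_id, concept in concepts.items():
        parents = frozenset(
            p for p in parent_cells[concept_id] if p in concepts and p != concept_id
        )
        resolved[concept_id] = Concept(
            id=concept_id, labels=concept.labels, parents=parents
        )
    aliases = {a: t for a, t in aliases.items() if a not in resolved}
    return Ontology(resolved.values(), name=name or path.stem, aliases=aliases)
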