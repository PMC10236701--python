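"""Prediction serialization: TSV (round-trippable) and .a2 (submission
dialect mirroring the standoff reader)."""

from __future__ import annotations

from pathlib import Path

from ..model import DatasetSplit, PredictionSet

__all__ = ["write_predictions", "read_predictions_tsv"]

_TSV_HEADER = "doc_id\tmention_id\tsurface\trank\tconcept_id\tscore"


def write_predictions(
    preds: PredictionSet,
    split: DatasetSplit,
    path: str | Path,
    format: str = "tsv",
    resource_name: str = "OntoBiotope",
) -> None:
    """Write predictions for mentions of ``split``.

    tsv: one file, columns doc_id, mention_id, surface, rank, concept_id,
    score; rows ordered by (doc_id, mention_id, rank).  a2: ``path`` is a
    directory receiving one ``<doc_id>.a2`` file per document; entity ids
    are recovered from the ``<doc>:<Tid>`` mention-id convention.
    """
    by_id = {m.id: m for m in split.mentions}
    for mention_id in preds.mention_ids():
        if mention_id not in by_id:
            raise KeyError(f"prediction for unknown mention {mention_id!r}")
    ordered = sorted(
        preds.mention_ids(), key=lambda mid: (by_id[mid].doc_id, mid)
    )
    if format == "tsv":
        lines = [_TSV_HEADER]
        for mention_id in ordered:
            mention = by_id[mention_id]
            for rank, (concept_id, score) in enumerate(preds.get(mention_id), 1):
                lines.append(
                    f"{mention.doc_id}\t{mention_id}\t{mention.surface}"
                    f"\t{rank}\t{concept_id}\t{score!r}"
                )
        Path(path).write_text("\n".join(lines) + "\n", "utf-8")
    elif format == "a2":
        directory = Path(path)
        directory.mkdir(parents=True, exist_ok=True)
        by_doc: dict[str, list[str]] = {}
        for mention_id in ordered:
            by_doc.setdefault(by_id[mention_id].doc_id, []).append(mention_id)
        for doc_id, mention_ids in sorted(by_doc.items()):
            lines = []
            index = 1
            for mention_id in mention_ids:
                entity_id = mention_id.split(":", 1)[1] if ":" in mention_id else mention_id
                for concept_id, _ in preds.get(mention_id):
                    lines.append(
                        f"N{index}\t{resource_name} Annotation:{entity_id}"
                        f" Referent:{concept_id}"
                    )
                    index += 1
            (directory / f"{doc_id}.a2").write_text(
                "\n".join(lines) + ("\n" if lines else ""), "utf-8"
            )
    else:
        raise ValueError(f"unknown prediction format {format!r}")


def read_predictions_tsv(path: str | Path) -> PredictionSet:
    """Inverse of the tsv dialect of :func:`write_predictions`."""
    rows: dict[str, list[tuple[int, str, float]]] = {}
    lines = Path(path).read_text("utf-8").splitlines()
    for lineno, line in enumerate(lines, start=1):
        if lineno == 1 and line == _TSV_HEADER:
            continue
        if not line.strip():
            continue
        columns = line.split("\t")
        if len(columns) != 6:
            raise ValueError(f"{path}:{lineno}: expected 6 columns")
        _, mention_id, _, rank, concept_id, score = columns
        rows.setdefault(mention_id, []).append(
            (int(rank), concept_id, float(score))
        )
    preds = PredictionSet()
    for mention_id, entries in rows.items():
        entries.sort()
        preds.set(mention_id, [(cid, score) for _, cid, score in entries])
    return preds
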