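"""Ablation harness: ontology subsetting, preprocessing toggles and the
combined bias-audit report."""

from __future__ import annotations

import hashlib
import json
from typing import Mapping, Sequence

from . import scoring
from .baseline import (
    LabelIndex,
    ProjectionConfig,
    SieveNormalizer,
    build_augmented_lexicon,
    fit_projection,
)
from .indicators import compute_report, merge_splits
from .io.embeddings import EmbeddingTable
from .model import Concept, DatasetSplit, Ontology, SurfacePolicy
from .text import PreprocConfig, apply_preproc

__all__ = ["subset_ontology", "apply_preproc", "PreprocConfig", "audit_report",
           "report_to_markdown", "SIGNIFICANCE_POINTS"]

#: Reported score differences below this many points are annotated as
#: not significant in audit reports.
SIGNIFICANCE_POINTS = 3.0


def subset_ontology(
    ontology: Ontology, splits: Sequence[DatasetSplit]
) -> Ontology:
    """Restrict the ontology to exactly the concepts used in the splits'
    gold sets.  Parent links to removed concepts are dropped without
    re-wiring: the broken subsumption hierarchy is left as is.
    """
    used: set[str] = set()
    for split in splits:
        used |= split.used_concepts()
    used = {ontology.resolve(cid) for cid in used}
    if not used:
        raise ValueError("the splits use no concepts; subset would be empty")
    concepts = [
        Concept(
            id=cid,
            labels=ontology.concepts[cid].labels,
            parents=frozenset(
                p for p in ontology.concepts[cid].parents if p in used
            ),
        )
        for cid in sorted(used)
    ]
    aliases = {a: t for a, t in ontology.aliases.items() if t in used}
    return Ontology(
        concepts,
        name=f"{ontology.name}[subset:{len(concepts)}]",
        version=ontology.version,
        aliases=aliases,
    )


def _config_hash(payload: Mapping[str, object]) -> str:
    canonical = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()[:16]


def _baseline_scores(
    train: DatasetSplit,
    evaluation: DatasetSplit,
    ontology: Ontology,
    embeddings: EmbeddingTable | None,
    projection_config: ProjectionConfig,
) -> dict[str, object]:
    lexicon = build_augmented_lexicon(ontology, train)
    model = index = None
    if embeddings is not None:
        try:
            model = fit_projection(train, ontology, embeddings, projection_config)
            index = LabelIndex(ontology, embeddings)
        except ValueError:
            model = index = None
    sieve = SieveNormalizer(lexicon, model, index, embeddings)
    preds = sieve.predict(evaluation)
    scorable = {
        mid: ann for mid, ann in evaluation.gold.items() if ann.concept_ids
    }
    composite = getattr(evaluation, "composite_mention_ids", set())
    general = scoring.accuracy_general(scorable, preds)
    lenient = scoring.accuracy_lenient(scorable, preds, composite & set(scorable))
    return {
        "ontology_size": len(ontology),
        "accuracy_general": general.percent,
        "accuracy_lenient": lenient.percent,
        "lenient_minus_general": lenient.percent - general.percent,
        "n_scored": general.n,
        "n_nil_excluded": len(evaluation.gold) - len(scorable),
        "sieve_stats": dict(sieve.stats),
    }


def audit_report(
    train: DatasetSplit,
    evaluation: DatasetSplit,
    ontology: Ontology,
    dev: DatasetSplit | None = None,
    embeddings: EmbeddingTable | None = None,
    policy: SurfacePolicy = "exact",
    projection_config: ProjectionConfig = ProjectionConfig(),
    run_baseline: bool = True,
) -> dict[str, object]:
    """Full bias audit of a (train, evaluation) pair.

    Emits the six indicators, baseline over-prediction-penalized accuracy
    under the full / train-only / train+eval ontology subsets, and the
    lenient-vs-penalized metric delta.  Pure function of its inputs: the
    returned dict serializes to byte-identical JSON across runs.
    """
    train_material = [train] + ([dev] if dev is not None else [])
    train_pool = (
        merge_splits(train_material) if len(train_material) > 1 else train
    )
    indicators = compute_report(
        train_pool, evaluation, pool=train_material + [evaluation], policy=policy
    )
    config = {
        "policy": policy,
        "splits": {
            "train": train.name,
            "dev": dev.name if dev is not None else None,
            "evaluation": evaluation.name,
        },
        "ontology": {"name": ontology.name, "size": len(ontology)},
        "embeddings": embeddings.dimension if embeddings is not None else None,
        "projection": {
            "ridge_lambda": projection_config.ridge_lambda,
            "weak_supervision": projection_config.weak_supervision,
        },
        "significance_points": SIGNIFICANCE_POINTS,
    }
    report: dict[str, object] = {
        "config": config,
        "config_hash": _config_hash(config),
        "indicators": indicators.to_dict(),
    }
    if run_baseline:
        subsets: dict[str, Ontology] = {"full": ontology}
        try:
            subsets["train-only"] = subset_ontology(ontology, train_material)
            subsets["train+eval"] = subset_ontology(
                ontology, train_material + [evaluation]
            )
        except ValueError:
            pass
        report["baseline"] = {
            subset_name: _baseline_scores(
                train_pool, evaluation, subset, embeddings, projection_config
            )
            for subset_name, subset in subsets.items()
        }
    return report


def report_to_markdown(report: Mapping[str, object]) -> str:
    """Render an audit report for human reading."""
    lines = ["# Bias audit", ""]
    lines.append(f"Config hash: `{report['config_hash']}`")
    lines.append("")
    lines.append("## Indicators")
    lines.append("")
    ind = report["indicators"]
    lines.append("| indicator | value |")
    lines.append("| --- | --- |")
    for key, value in ind["fsl"].items():  # type: ignore[index]
        lines.append(f"| FSL {key} | {value:.2f} |")
    for key, value in ind["rates"].items():  # type: ignore[index]
        lines.append(f"| {key} (%) | {value:.1f} |")
    if "baseline" in report:
        lines.append("")
        lines.append("## Baseline (two-sieve) accuracy by ontology subset")
        lines.append("")
        lines.append("| subset | concepts | penalized acc | lenient acc | delta |")
        lines.append("| --- | --- | --- | --- | --- |")
        for subset_name, scores in report["baseline"].items():  # type: ignore[union-attr]
            lines.append(
                f"| {subset_name} | {scores['ontology_size']} "
                f"| {scores['accuracy_general']:.1f} "
                f"| {scores['accuracy_lenient']:.1f} "
                f"| {scores['lenient_minus_general']:+.1f} |"
            )
        lines.append("")
        lines.append(
            f"Differences under {SIGNIFICANCE_POINTS:.0f} points should not be "
            "read as significant."
        )
    return "\n".join(lines) + "\n"
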