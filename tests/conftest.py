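from __future__ import annotations

import pytest

from enaudit.model import (
    Concept,
    DatasetSplit,
    GoldAnnotation,
    Mention,
    Ontology,
)


def make_split(name, rows):
    """rows: list of (mention_id, surface, gold_ids or None)."""
    mentions = []
    gold = {}
    for mention_id, surface, gold_ids in rows:
        mentions.append(
            Mention(id=mention_id, doc_id=mention_id.split(":")[0],
                    surface=surface, entity_type="Habitat")
        )
        if gold_ids is not None:
            gold[mention_id] = GoldAnnotation(
                mention_id=mention_id, concept_ids=frozenset(gold_ids)
            )
    return DatasetSplit(name, mentions, gold)


@pytest.fixture
def toy_ontology():
    return Ontology(
        [
            Concept(id="X:1", labels=("root",)),
            Concept(id="X:2", labels=("cat", "feline"), parents=frozenset({"X:1"})),
            Concept(id="X:3", labels=("dog",), parents=frozenset({"X:1"})),
            Concept(id="X:4", labels=("tortoise",), parents=frozenset({"X:1"})),
            Concept(id="X:5", labels=("gopher tortoise",),
                    parents=frozenset({"X:4"})),
        ],
        name="toy",
    )


@pytest.fixture
def standoff_dir(tmp_path):
    """Hand-constructed two-document standoff fixture."""
    doc1 = tmp_path / "doc1.txt"
    text1 = "Text before gopher tortoise and more."
    doc1.write_text(text1, "utf-8")
    assert text1[12:27] == "gopher tortoise"
    (tmp_path / "doc1.a1").write_text(
        "T1\tTitle 0 4\tText\n"
        "T5\tHabitat 12 27\tgopher tortoise\n"
        "T6\tMicroorganism 28 31\tand\n",
        "utf-8",
    )
    (tmp_path / "doc1.a2").write_text(
        "N1\tOntoBiotope Annotation:T5 Referent:X:5\n"
        "N2\tNCBI_Taxonomy Annotation:T6 Referent:12345\n",
        "utf-8",
    )
    doc2 = tmp_path / "doc2.txt"
    text2 = "cats here dog elsewhere in tortoise land"
    doc2.write_text(text2, "utf-8")
    assert text2[0:4] == "cats" and text2[10:13] == "dog" and text2[27:35] == "tortoise"
    (tmp_path / "doc2.a1").write_text(
        "T1\tHabitat 0 4\tcats\n"
        "T2\tHabitat 10 13;27 35\tdog tortoise\n",
        "utf-8",
    )
    (tmp_path / "doc2.a2").write_text(
        "N1\tOntoBiotope Annotation:T1 Referent:X:2\n"
        "N2\tOntoBiotope Annotation:T2 Referent:X:3\n"
        "N3\tOntoBiotope Annotation:T2 Referent:X:4\n",
        "utf-8",
    )
    return tmp_path


@pytest.fixture
def pubtator_file(tmp_path):
    path = tmp_path / "corpus.txt"
    path.write_text(
        "1001|t|A title about breast or ovarian cancer\n"
        "1001|a|An abstract mentioning diabetes.\n"
        "1001\t14\t38\tbreast or ovarian cancer\tCompositeMention\tD001943+D010051\n"
        "1001\t55\t63\tdiabetes\tSpecificDisease\tD003924\n"
        "\n"
        "1002|t|Another title\n"
        "1002|a|Another abstract\n"
        "1002\t0\t7\tAnother\tSpecificDisease\tOMIM:114480\n"
        "1002\t8\t13\ttitle\tSpecificDisease\tD003924|D001943\n",
        "utf-8",
    )
    return path


@pytest.fixture
def medic_ontology():
    from enaudit.model import Concept, Ontology

    return Ontology(
        [
            Concept(id="MESH:D001943", labels=("Breast Neoplasms",)),
            Concept(id="MESH:D010051", labels=("Ovarian Neoplasms",)),
            Concept(id="MESH:D003924", labels=("Diabetes Mellitus, Type 2",)),
            Concept(id="OMIM:114480", labels=("BREAST CANCER",)),
        ],
        name="medic-toy",
    )
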