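from __future__ import annotations

import numpy as np
import pytest

from enaudit.baseline import (
    LabelIndex,
    ProjectionConfig,
    SieveNormalizer,
    build_augmented_lexicon,
    embed_mention,
    embed_text,
    exact_match_predict,
    fit_projection,
    nearest_label_predict,
)
from enaudit.io.embeddings import EmbeddingTable
from enaudit.model import (
    Concept,
    DatasetSplit,
    GoldAnnotation,
    Mention,
    Ontology,
)
from enaudit.scoring import accuracy_general
from enaudit.synthetic import GeneratorSpec, generate_dataset

from conftest import make_split


@pytest.fixture
def small_ontology():
    return Ontology([
        Concept(id="C:A", labels=("tortoise",)),
        Concept(id="C:B", labels=("soil", "dirt")),
        Concept(id="C:C", labels=("river bank",)),
    ])


class TestAugmentedLexicon:
    def test_ontology_labels_only(self, small_ontology):
        lexicon = build_augmented_lexicon(small_ontology)
        assert len(lexicon) == 4  # tortoise, soil, dirt, river bank
        assert exact_match_predict("Tortoises", lexicon) == "C:A"

    def test_training_surface_most_frequent_concept(self, small_ontology):
        train = make_split("train", [
            ("t:1", "mud", {"C:A"}), ("t:2", "mud", {"C:A"}),
            ("t:3", "mud", {"C:A"}), ("t:4", "mud", {"C:B"}),
        ])
        lexicon = build_augmented_lexicon(small_ontology, train)
        assert exact_match_predict("mud", lexicon) == "C:A"
        entry = lexicon.lookup("mud")
        assert entry.provenance == "training-mention" and entry.frequency == 3

    def test_tie_breaks_lexicographically(self, small_ontology):
        train = make_split("train", [
            ("t:1", "mud", {"C:B"}), ("t:2", "mud", {"C:B"}),
            ("t:3", "mud", {"C:A"}), ("t:4", "mud", {"C:A"}),
        ])
        lexicon = build_augmented_lexicon(small_ontology, train)
        assert exact_match_predict("mud", lexicon) == "C:A"

    def test_ontology_label_beats_training_surface(self, small_ontology):
        train = make_split("train", [("t:1", "soil", {"C:A"})] * 1)
        lexicon = build_augmented_lexicon(small_ontology, train)
        assert exact_match_predict("soil", lexicon) == "C:B"

    def test_unseen_surface_none(self, small_ontology):
        lexicon = build_augmented_lexicon(small_ontology)
        assert exact_match_predict("volcano", lexicon) is None

    def test_stemmed_match(self, small_ontology):
        lexicon = build_augmented_lexicon(small_ontology)
        assert exact_match_predict("River Banks", lexicon) == "C:C"


class TestEmbedMention:
    TABLE = EmbeddingTable({
        "u": np.array([1.0, 0.0]), "v": np.array([0.0, 1.0]),
    })

    def test_mean_of_two(self):
        vec = embed_text("u v", self.TABLE)
        assert np.allclose(vec, [0.5, 0.5])

    def test_oov_token_skipped(self):
        vec = embed_text("u zzz", self.TABLE)
        assert np.allclose(vec, [1.0, 0.0])

    def test_all_oov_none(self):
        assert embed_text("x y z", self.TABLE) is None

    def test_lowercase_fallback(self):
        assert np.allclose(embed_text("U", self.TABLE), [1.0, 0.0])


class TestFitProjection:
    def _training_setup(self, W0, X):
        n, d = X.shape
        vectors = {}
        concepts, mentions, gold = [], [], {}
        for i in range(n):
            vectors[f"m{i}"] = X[i]
            vectors[f"l{i}"] = W0 @ X[i]
            concepts.append(Concept(id=f"C:{i:02d}", labels=(f"l{i}",)))
            mention = Mention(id=f"M{i}", doc_id="d", surface=f"m{i}")
            mentions.append(mention)
            gold[mention.id] = GoldAnnotation(
                mention_id=mention.id, concept_ids=frozenset({f"C:{i:02d}"})
            )
        return (
            DatasetSplit("train", mentions, gold),
            Ontology(concepts),
            EmbeddingTable(vectors),
        )

    def test_recovers_planted_linear_map(self):
        rng = np.random.default_rng(0)
        W0 = rng.normal(size=(6, 6))
        X = rng.normal(size=(30, 6))
        split, ontology, table = self._training_setup(W0, X)
        model = fit_projection(split, ontology, table,
                               ProjectionConfig(ridge_lambda=0.0))
        assert np.abs(model.weights - W0).max() < 1e-6

    def test_identity_data_gives_identity(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(24, 5))
        split, ontology, table = self._training_setup(np.eye(5), X)
        model = fit_projection(split, ontology, table,
                               ProjectionConfig(ridge_lambda=1e-10))
        assert np.abs(model.weights - np.eye(5)).max() < 1e-4

    def test_huge_ridge_shrinks_to_zero(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 4))
        split, ontology, table = self._training_setup(np.eye(4), X)
        model = fit_projection(split, ontology, table,
                               ProjectionConfig(ridge_lambda=1e12))
        assert np.abs(model.weights).max() < 1e-6

    def test_no_usable_pairs_errors(self):
        split = make_split("train", [("t:1", "zzz", {"C:A"})])
        ontology = Ontology([Concept(id="C:A", labels=("yyy",))])
        table = EmbeddingTable({"other": np.ones(3)})
        with pytest.raises(ValueError):
            fit_projection(split, ontology, table)

    def test_underdetermined_warns(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(2, 6))
        split, ontology, table = self._training_setup(np.eye(6), X)
        with pytest.warns(UserWarning, match="underdetermined"):
            fit_projection(split, ontology, table)


class TestNearestLabel:
    def test_brute_force_cosine_agreement(self):
        rng = np.random.default_rng(4)
        concepts = [
            Concept(id=f"C:{i}", labels=(f"lab{i}",)) for i in range(5)
        ]
        vectors = {f"lab{i}": rng.normal(size=4) for i in range(5)}
        vectors["query"] = rng.normal(size=4)
        ontology = Ontology(concepts)
        table = EmbeddingTable(vectors)
        index = LabelIndex(ontology, table)
        from enaudit.baseline import ProjectionModel

        model = ProjectionModel(weights=np.eye(4), fitted=True)
        predicted, _ = nearest_label_predict("query", model, index, table)

        def cosine(a, b):
            return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))

        query = np.asarray(table.get("query"), dtype=float)
        best = max(
            (cosine(query, np.asarray(table.get(f"lab{i}"), dtype=float)), f"C:{i}")
            for i in range(5)
        )
        assert predicted == best[1]

    def test_single_concept_subset(self):
        ontology = Ontology([
            Concept(id="C:0", labels=("aa",)), Concept(id="C:1", labels=("bb",)),
        ])
        table = EmbeddingTable({
            "aa": np.array([1.0, 0.0]), "bb": np.array([0.0, 1.0]),
            "q": np.array([0.9, 0.1]),
        })
        from enaudit.baseline import ProjectionModel

        model = ProjectionModel(weights=np.eye(2), fitted=True)
        index = LabelIndex(ontology, table, concept_subset={"C:1"})
        predicted, _ = nearest_label_predict("q", model, index, table)
        assert predicted == "C:1"

    def test_empty_subset_errors(self):
        ontology = Ontology([Concept(id="C:0", labels=("aa",))])
        table = EmbeddingTable({"aa": np.ones(2)})
        with pytest.raises(ValueError):
            LabelIndex(ontology, table, concept_subset=set())

    def test_unembeddable_mention_none(self):
        ontology = Ontology([Concept(id="C:0", labels=("aa",))])
        table = EmbeddingTable({"aa": np.ones(2)})
        from enaudit.baseline import ProjectionModel

        model = ProjectionModel(weights=np.eye(2), fitted=True)
        index = LabelIndex(ontology, table)
        assert nearest_label_predict("zzz", model, index, table) is None


class TestSieve:
    def test_lexicon_match_skips_projection(self, small_ontology):
        lexicon = build_augmented_lexicon(small_ontology)
        sieve = SieveNormalizer(lexicon)  # no projection stage at all
        result = sieve.predict_mention("tortoises")
        assert result == ("C:A", 1.0)
        assert sieve.stats == {"lexicon": 1, "projection": 0, "unpredicted": 0}

    def test_fallback_to_projection(self):
        data = generate_dataset(GeneratorSpec(
            n_concepts=20, train_size=30, test_size=10, zsl=100,
            test_surface_variant=2, seed=7,
        ))
        lexicon = build_augmented_lexicon(data.ontology, data.train)
        model = fit_projection(
            data.train, data.ontology, data.embeddings,
            ProjectionConfig(weak_supervision=True),
        )
        index = LabelIndex(data.ontology, data.embeddings)
        sieve = SieveNormalizer(lexicon, model, index, data.embeddings)
        preds = sieve.predict(data.test)
        assert sieve.stats["projection"] == len(data.test)
        assert accuracy_general(data.test.gold, preds).value == 1.0

    def test_unpredictable_gets_no_prediction(self, small_ontology):
        lexicon = build_augmented_lexicon(small_ontology)
        sieve = SieveNormalizer(lexicon)
        preds = sieve.predict(make_split("t", [("d:1", "volcano", {"C:A"})]))
        assert "d:1" not in preds
        assert sieve.stats["unpredicted"] == 1

    def test_full_coverage_perfect_accuracy(self):
        data = generate_dataset(GeneratorSpec(
            n_concepts=30, train_size=40, test_size=20, redundancy=25,
            zsl=20, seed=1,
        ))
        lexicon = build_augmented_lexicon(data.ontology, data.train)
        model = fit_projection(
            data.train, data.ontology, data.embeddings,
            ProjectionConfig(weak_supervision=True),
        )
        index = LabelIndex(data.ontology, data.embeddings)
        sieve = SieveNormalizer(lexicon, model, index, data.embeddings)
        preds = sieve.predict(data.test)
        assert accuracy_general(data.test.gold, preds).value == 1.0

    def test_redundancy_100_dictb_alone_perfect(self):
        data = generate_dataset(GeneratorSpec(
            n_concepts=30, train_size=30, test_size=15, redundancy=100, seed=2,
        ))
        lexicon = build_augmented_lexicon(data.ontology, data.train)
        sieve = SieveNormalizer(lexicon)
        preds = sieve.predict(data.test)
        assert accuracy_general(data.test.gold, preds).value == 1.0
        assert sieve.stats["lexicon"] == len(data.test)

    def test_deterministic_prediction(self):
        data = generate_dataset(GeneratorSpec(
            n_concepts=25, train_size=30, test_size=12, zsl=50, seed=3,
            noise=0.2,
        ))

        def run():
            lexicon = build_augmented_lexicon(data.ontology, data.train)
            model = fit_projection(data.train, data.ontology, data.embeddings)
            index = LabelIndex(data.ontology, data.embeddings)
            sieve = SieveNormalizer(lexicon, model, index, data.embeddings)
            return sieve.predict(data.test)

        assert run() == run()

    def test_subsetting_to_test_concepts_never_hurts(self):
        for seed in (11, 12, 13):
            data = generate_dataset(GeneratorSpec(
                n_concepts=30, train_size=40, test_size=15, zsl=40,
                test_surface_variant=2, noise=0.6, seed=seed,
            ))
            lexicon = build_augmented_lexicon(data.ontology, data.train)
            model = fit_projection(
                data.train, data.ontology, data.embeddings,
                ProjectionConfig(weak_supervision=True),
            )
            full_index = LabelIndex(data.ontology, data.embeddings)
            test_concepts = data.test.used_concepts()
            sub_index = LabelIndex(
                data.ontology, data.embeddings, concept_subset=test_concepts
            )
            full = SieveNormalizer(lexicon, model, full_index, data.embeddings)
            sub = SieveNormalizer(lexicon, model, sub_index, data.embeddings)
            acc_full = accuracy_general(
                data.test.gold, full.predict(data.test)
            ).value
            acc_sub = accuracy_general(
                data.test.gold, sub.predict(data.test)
            ).value
            assert acc_sub >= acc_full


def test_noise_degrades_projection_accuracy():
    accuracies = []
    for noise in (0.0, 1.0, 3.0):
        data = generate_dataset(GeneratorSpec(
            n_concepts=20, train_size=30, test_size=10, zsl=100,
            test_surface_variant=2, noise=noise, seed=21,
        ))
        lexicon = build_augmented_lexicon(data.ontology, data.train)
        model = fit_projection(
            data.train, data.ontology, data.embeddings,
            ProjectionConfig(weak_supervision=True),
        )
        index = LabelIndex(data.ontology, data.embeddings)
        sieve = SieveNormalizer(lexicon, model, index, data.embeddings)
        accuracies.append(
            accuracy_general(data.test.gold, sieve.predict(data.test)).value
        )
    assert accuracies[0] == 1.0
    assert accuracies[-1] <= accuracies[0]
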