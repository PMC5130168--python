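"""Feature mining, the disease-mutation classifier, the co-occurrence
baseline, and Mutation-list construction."""

import io

import numpy as np
import pytest
from sklearn.model_selection import cross_val_score

from trimine import classify as dm
from trimine.classify import (
    DiseaseMutationClassifier,
    build_mutation_list,
    cooccurrence_baseline,
    extract_features,
    instances_to_matrix,
)
from trimine.pubtator import read_pubtator
from trimine.synth import CorpusGenerator, SynthConfig

MESH = "mesh:D008545"


def _doc(title, abstract, annotations):
    """Build a document by locating each (surface, class, concept) in text."""
    text = title + " " + abstract
    lines = [f"1|t|{title}", f"1|a|{abstract}"]
    cursor = {}
    for surface, cls, concept in annotations:
        start = text.index(surface, cursor.get(surface, 0))
        cursor[surface] = start + 1
        lines.append(f"1\t{start}\t{start + len(surface)}\t{surface}\t{cls}\t{concept}")
    (doc,) = read_pubtator(io.StringIO("\n".join(lines) + "\n"), strict=True)
    return doc


class TestExtractFeatures:
    def test_hand_counted_vector_on_two_sentence_fixture(self):
        doc = _doc(
            "Variant screening report.",
            "The V600E mutation was significantly associated with melanoma. "
            "Unrelated glaucoma was not considered.",
            [
                ("V600E", "Mutation", "V600E"),
                ("melanoma", "Disease", "MESH:D008545"),
                ("glaucoma", "Disease", "MESH:D005901"),
            ],
        )
        f = extract_features(doc, "p.V600E", MESH)
        # tokens: Variant(0) screening(1) report.(2) The(3) V600E(4) mutation(5)
        # was(6) significantly(7) associated(8) with(9) melanoma.(10) ...
        assert f.min_token_distance == 6
        assert f.same_sentence is True
        assert f.target_disease_count == 1
        assert f.other_disease_count == 1
        assert f.mutation_mention_count == 1
        assert f.sentence_polarity == 1.0

    def test_adjacent_mentions_have_distance_one(self):
        doc = _doc(
            "A study.",
            "We report V600E melanoma cases.",
            [("V600E", "Mutation", "V600E"), ("melanoma", "Disease", "MESH:D008545")],
        )
        f = extract_features(doc, "p.V600E", MESH)
        assert f.min_token_distance == 1
        assert f.same_sentence is True

    def test_disease_absent_uses_token_count_sentinel(self):
        doc = _doc(
            "A study.",
            "We report V600E cases.",
            [("V600E", "Mutation", "V600E")],
        )
        f = extract_features(doc, "p.V600E", MESH)
        assert f.target_disease_count == 0
        assert f.same_sentence is False
        assert f.min_token_distance == len(doc.text.split())

    def test_negated_sentence_scores_negative_polarity(self):
        doc = _doc(
            "A study.",
            "The V600E variant was not associated with melanoma.",
            [("V600E", "Mutation", "V600E"), ("melanoma", "Disease", "MESH:D008545")],
        )
        f = extract_features(doc, "p.V600E", MESH)
        assert f.sentence_polarity < 0

    def test_variant_absent_raises(self):
        doc = _doc("A study.", "Nothing here.", [])
        with pytest.raises(ValueError):
            extract_features(doc, "p.V600E", MESH)


class TestClassifier:
    def _separable(self, n=60):
        rng = np.random.default_rng(0)
        X, y = [], []
        for i in range(n):
            pos = i % 2 == 0
            X.append(
                [
                    rng.integers(1, 4) if pos else rng.integers(25, 60),
                    rng.integers(1, 4),
                    1.0 if pos else 0.0,
                    1.0 if pos else -1.0,
                    rng.integers(1, 3),
                    rng.integers(0, 3),
                ]
            )
            y.append(int(pos))
        return np.array(X, dtype=float), np.array(y)

    def test_separable_data_reaches_training_accuracy_one(self):
        X, y = self._separable()
        model = DiseaseMutationClassifier().fit(X, y)
        assert (model.predict(X) == y.astype(bool)).all()

    def test_single_class_input_rejected(self):
        X, y = self._separable()
        with pytest.raises(ValueError):
            DiseaseMutationClassifier().fit(X, np.ones_like(y))

    def test_schema_width_enforced(self):
        X, y = self._separable()
        model = DiseaseMutationClassifier().fit(X, y)
        with pytest.raises(ValueError):
            model.predict_proba(X[:, :4])

    def test_ten_fold_cv_f1_on_synthetic_instances(self):
        cfg = SynthConfig(
            seed=11,
            distractor_disease_rate=0.3,
            distractor_gene_rate=0.3,
            distractor_mutation_rate=0.3,
        )
        instances = CorpusGenerator(cfg).corpus().labeled_instances
        assert len(instances) >= 200
        X = instances_to_matrix(instances)
        y = np.array([int(i.label) for i in instances])
        scores = cross_val_score(
            DiseaseMutationClassifier(), X, y, cv=10, scoring="f1"
        )
        assert scores.mean() >= 0.9

    def test_save_load_round_trip_identical_predictions(self, tmp_path):
        X, y = self._separable()
        model = DiseaseMutationClassifier(C=0.7, threshold=0.6).fit(X, y)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = DiseaseMutationClassifier.load(path)
        assert loaded.get_params() == model.get_params()
        np.testing.assert_array_equal(
            loaded.predict_proba(X), model.predict_proba(X)
        )
        np.testing.assert_array_equal(loaded.predict(X), model.predict(X))

    def test_predictions_monotone_in_threshold(self):
        X, y = self._separable()
        model = DiseaseMutationClassifier().fit(X, y)
        instances = [
            dm.DMInstance("1", "p.V1A", MESH, dm.DMFeatures(*row)) for row in X
        ]
        counts = [
            sum(p.positive for p in dm.predict(model, instances, threshold=t))
            for t in (0.2, 0.5, 0.8)
        ]
        assert counts[0] >= counts[1] >= counts[2]

    def test_cross_disease_generalization(self, trained_model):
        """A model trained on one disease's corpus transfers to another
        disease generated with the same signal parameters (F1 >= 0.85)."""
        other = SynthConfig(
            seed=202,
            target_disease_concept="mesh:D900200",
            distractor_disease_rate=0.3,
            distractor_gene_rate=0.3,
            distractor_mutation_rate=0.3,
        )
        instances = CorpusGenerator(other).corpus().labeled_instances
        X = instances_to_matrix(instances)
        y = np.array([bool(i.label) for i in instances])
        pred = trained_model.predict(X)
        tp = int((pred & y).sum())
        fp = int((pred & ~y).sum())
        fn = int((~pred & y).sum())
        f1 = 2 * tp / (2 * tp + fp + fn)
        assert f1 >= 0.85


class TestBaselineAndMutationList:
    def test_disease_comention_yields_all_variant_pairs(self):
        doc = _doc(
            "A study of melanoma.",
            "We saw V600E, V600K and W779X variants.",
            [
                ("melanoma", "Disease", "MESH:D008545"),
                ("V600E", "Mutation", "V600E"),
                ("V600K", "Mutation", "V600K"),
                ("W779X", "Mutation", "W779X"),
            ],
        )
        pairs = cooccurrence_baseline([doc], MESH)
        assert pairs == [("1", "p.V600E"), ("1", "p.V600K"), ("1", "p.W779X")]

    def test_no_disease_mention_no_pairs(self):
        doc = _doc("A study.", "We saw V600E.", [("V600E", "Mutation", "V600E")])
        assert cooccurrence_baseline([doc], MESH) == []

    def test_baseline_is_superset_of_classifier_positives(self, trained_model):
        """When planted triplets always co-occur, baseline recall bounds
        classifier recall from above (positives are a superset on
        co-occurring documents)."""
        result = CorpusGenerator(SynthConfig(seed=31)).corpus()
        docs = result.documents
        concept = result.config.target_disease_concept
        baseline = set(cooccurrence_baseline(docs, concept))
        from trimine.pipeline import build_instances
        from trimine.pubtator import DISEASE

        comentioning = {
            d.pmid
            for d in docs
            if any(m.concept_id == concept for m in d.mentions_of(DISEASE))
        }
        predictions = dm.predict(trained_model, build_instances(docs, concept))
        classifier = {(p.pmid, p.variant_key) for p in predictions if p.positive}
        restricted = {pair for pair in classifier if pair[0] in comentioning}
        assert restricted <= baseline
        assert len(classifier) > 0
        # hence baseline recall can never fall below classifier recall here
        assert len(baseline) >= len(restricted)

    def test_mutation_list_orders_by_frequency_then_key(self):
        pairs = [
            ("1", "p.A1B"), ("2", "p.A1B"), ("3", "p.A1B"),
            ("1", "p.C2D"),
            ("4", "p.B9C"), ("5", "p.B9C"),
            ("6", "p.A5G"), ("7", "p.A5G"),
        ]
        entries = build_mutation_list(pairs)
        assert [e.variant_key for e in entries] == ["p.A1B", "p.A5G", "p.B9C", "p.C2D"]
        assert [e.frequency for e in entries] == [3, 2, 2, 1]
        # frequencies sum to the number of unique positive pairs
        assert sum(e.frequency for e in entries) == len(set(pairs))

    def test_empty_input_empty_list(self):
        assert build_mutation_list([]) == []
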