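"""Disease-mutation relationship classification.

Given a document, a mutation, and a target disease concept, decide whether
the document asserts that the mutation is related to the disease.  The
decision uses a small feature vector mined from the co-mention context
(proximity, frequency, same-sentence co-mention, sentence polarity) and a
regularized linear classifier; positive (PMID, mutation) pairs are then
collapsed into the frequency-ranked Mutation-list that drives downstream
gene ranking.

The classifier is a scikit-learn-compatible estimator and composes with
sklearn model selection (``cross_val_score`` etc.).
"""

from __future__ import annotations

import bisect
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from ._polarity import sentence_polarity
from .pubtator import DISEASE, MUTATION, Document, Span, sentence_split
from .variants import variant_key_for_surface

__all__ = [
    "FEATURE_NAMES",
    "SCHEMA_VERSION",
    "DMFeatures",
    "DMInstance",
    "MutationListEntry",
    "Prediction",
    "DiseaseMutationClassifier",
    "extract_features",
    "train",
    "predict",
    "cooccurrence_baseline",
    "build_mutation_list",
    "instances_to_matrix",
    "mention_variant_key",
]

#: Feature schema, versioned so additional features can be added without
#: silently invalidating persisted models.
FEATURE_NAMES: tuple[str, ...] = (
    "min_token_distance",
    "target_disease_count",
    "same_sentence",
    "sentence_polarity",
    "mutation_mention_count",
    "other_disease_count",
)
SCHEMA_VERSION = 1


@dataclass(frozen=True)
class DMFeatures:
    """Feature vector for one (document, mutation, target disease) decision.

    ``min_token_distance`` is the minimum whitespace-token distance between
    any mention of the mutation and any mention of the target disease; when
    the disease is absent from the document it takes the sentinel value of
    the document's total token count.
    """

    min_token_distance: int
    target_disease_count: int
    same_sentence: bool
    sentence_polarity: float
    mutation_mention_count: int
    other_disease_count: int

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.min_token_distance,
                self.target_disease_count,
                float(self.same_sentence),
                self.sentence_polarity,
                self.mutation_mention_count,
                self.other_disease_count,
            ],
            dtype=float,
        )


@dataclass(frozen=True)
class DMInstance:
    pmid: str
    variant_key: str
    disease_concept: str
    features: DMFeatures
    label: bool | None = None


@dataclass(frozen=True)
class Prediction:
    pmid: str
    variant_key: str
    disease_concept: str
    probability: float
    positive: bool


@dataclass
class MutationListEntry:
    variant_key: str
    pmids: frozenset[str]

    @property
    def frequency(self) -> int:
        return len(self.pmids)


def mention_variant_key(mention) -> str:
    """Canonical variant key for a MUTATION mention (falls back to the
    normalized surface text for strings outside the variant grammar)."""
    return variant_key_for_surface(mention.concept_id or mention.surface)


def _token_spans(text: str) -> list[tuple[int, int]]:
    return [(m.start(), m.end()) for m in re.finditer(r"\S+", text)]


def _token_index(starts: list[int], char_pos: int) -> int:
    i = bisect.bisect_right(starts, char_pos) - 1
    return max(i, 0)


def _sentence_index(sentences: list[Span], char_pos: int) -> int:
    starts = [s.start for s in sentences]
    i = bisect.bisect_right(starts, char_pos) - 1
    return max(i, 0)


def extract_features(
    document: Document, variant_key: str, disease_concept: str
) -> DMFeatures:
    """Mine the DM feature vector from one document.

    Raises ``ValueError`` when the document contains no mention of the
    variant.  Distances are measured in whitespace tokens between mention
    start positions; the polarity feature scores the sentence containing
    the closest mutation/disease pair (the mutation's sentence when the
    pair spans two sentences or the disease is absent).
    """
    var_mentions = [
        m
        for m in document.mentions_of(MUTATION)
        if mention_variant_key(m) == variant_key
    ]
    if not var_mentions:
        raise ValueError(f"{document.pmid}: no mention of variant {variant_key}")

    disease_mentions = document.mentions_of(DISEASE)
    target = [m for m in disease_mentions if m.concept_id == disease_concept]
    other = [m for m in disease_mentions if m.concept_id != disease_concept]

    text = document.text
    spans = _token_spans(text)
    starts = [s for s, _ in spans]
    n_tokens = len(spans)
    sentences = sentence_split(document)

    if not target:
        anchor = var_mentions[0]
        polarity = _polarity_of_sentence(text, sentences, anchor.span.start)
        return DMFeatures(
            min_token_distance=n_tokens,
            target_disease_count=0,
            same_sentence=False,
            sentence_polarity=polarity,
            mutation_mention_count=len(var_mentions),
            other_disease_count=len(other),
        )

    best = None  # (distance, same_sentence, variant_char_pos, disease_char_pos)
    for vm in var_mentions:
        vi = _token_index(starts, vm.span.start)
        vs = _sentence_index(sentences, vm.span.start)
        for dm in target:
            di = _token_index(starts, dm.span.start)
            ds = _sentence_index(sentences, dm.span.start)
            cand = (abs(vi - di), 0 if vs == ds else 1, vm.span.start, dm.span.start)
            if best is None or cand[:2] < best[:2]:
                best = cand
    distance, cross_sentence, v_pos, _ = best
    same_sentence = cross_sentence == 0
    polarity = _polarity_of_sentence(text, sentences, v_pos)
    return DMFeatures(
        min_token_distance=distance,
        target_disease_count=len(target),
        same_sentence=same_sentence,
        sentence_polarity=polarity,
        mutation_mention_count=len(var_mentions),
        other_disease_count=len(other),
    )


def _polarity_of_sentence(text: str, sentences: list[Span], char_pos: int) -> float:
    if not sentences:
        return sentence_polarity(text)
    s = sentences[_sentence_index(sentences, char_pos)]
    return sentence_polarity(text[s.start : s.end])


def instances_to_matrix(instances: Sequence[DMInstance]) -> np.ndarray:
    return np.vstack([inst.features.as_array() for inst in instances])


class DiseaseMutationClassifier(BaseEstimator, ClassifierMixin):
    """Regularized logistic model over the six DM context features.

    A linear model is deliberate: six features, full auditability of the
    learned weights, and fast retraining.  Inputs are standardized
    internally; the decision threshold on the positive-class probability is
    a parameter rather than fixed at 0.5.

    Attributes (after ``fit``)
    --------------------------
    scaler_ : fitted StandardScaler
    model_ : fitted LogisticRegression
    n_features_in_ : int
    classes_ : ndarray
    """

    def __init__(
        self,
        C: float = 1.0,
        threshold: float = 0.5,
        max_iter: int = 500,
        random_state: int = 0,
    ):
        self.C = C
        self.threshold = threshold
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] != len(FEATURE_NAMES):
            raise ValueError(
                f"expected {len(FEATURE_NAMES)} features, got shape {X.shape}"
            )
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        self.scaler_ = StandardScaler().fit(X)
        self.model_ = LogisticRegression(
            C=self.C, max_iter=self.max_iter, random_state=self.random_state
        ).fit(self.scaler_.transform(X), y)
        self.classes_ = self.model_.classes_
        self.n_features_in_ = X.shape[1]
        self.feature_names_ = list(FEATURE_NAMES)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(f"feature schema mismatch: got shape {X.shape}")
        return self.model_.predict_proba(self.scaler_.transform(X))

    def predict(self, X):
        proba = self.predict_proba(X)[:, 1]
        return proba >= self.threshold

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Persist as a versioned JSON bundle (weights + scaling + schema)."""
        check_is_fitted(self, "model_")
        bundle = {
            "format": "trimine-dm-classifier",
            "schema_version": SCHEMA_VERSION,
            "feature_names": list(FEATURE_NAMES),
            "params": self.get_params(),
            "scaler": {
                "mean": self.scaler_.mean_.tolist(),
                "scale": self.scaler_.scale_.tolist(),
            },
            "coef": self.model_.coef_.tolist(),
            "intercept": self.model_.intercept_.tolist(),
            "classes": [int(c) for c in self.model_.classes_],
        }
        Path(path).write_text(json.dumps(bundle, indent=1), encoding="utf-8")

    @classmethod
    def load(cls, path) -> "DiseaseMutationClassifier":
        bundle = json.loads(Path(path).read_text(encoding="utf-8"))
        if bundle.get("format") != "trimine-dm-classifier":
            raise ValueError("not a DM classifier bundle")
        if bundle.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(
                f"feature schema version mismatch: bundle has "
                f"{bundle.get('schema_version')}, library has {SCHEMA_VERSION}"
            )
        if bundle["feature_names"] != list(FEATURE_NAMES):
            raise ValueError("feature name mismatch in model bundle")
        est = cls(**bundle["params"])
        n = len(FEATURE_NAMES)
        scaler = StandardScaler()
        scaler.mean_ = np.array(bundle["scaler"]["mean"], dtype=float)
        scaler.scale_ = np.array(bundle["scaler"]["scale"], dtype=float)
        scaler.var_ = scaler.scale_**2
        scaler.n_features_in_ = n
        scaler.with_mean = scaler.with_std = True
        model = LogisticRegression(
            C=est.C, max_iter=est.max_iter, random_state=est.random_state
        )
        model.coef_ = np.array(bundle["coef"], dtype=float)
        model.intercept_ = np.array(bundle["intercept"], dtype=float)
        model.classes_ = np.array(bundle["classes"])
        model.n_features_in_ = n
        est.scaler_ = scaler
        est.model_ = model
        est.classes_ = model.classes_
        est.n_features_in_ = n
        est.feature_names_ = list(FEATURE_NAMES)
        return est


def train(
    instances: Sequence[DMInstance], **params
) -> DiseaseMutationClassifier:
    """Fit a classifier from labeled instances (labels must cover 2 classes)."""
    labeled = [inst for inst in instances if inst.label is not None]
    if not labeled:
        raise ValueError("no labeled instances")
    X = instances_to_matrix(labeled)
    y = np.array([int(inst.label) for inst in labeled])
    return DiseaseMutationClassifier(**params).fit(X, y)


def predict(
    model: DiseaseMutationClassifier,
    instances: Sequence[DMInstance],
    threshold: float | None = None,
) -> list[Prediction]:
    if not instances:
        return []
    thr = model.threshold if threshold is None else threshold
    proba = model.predict_proba(instances_to_matrix(instances))[:, 1]
    return [
        Prediction(
            pmid=inst.pmid,
            variant_key=inst.variant_key,
            disease_concept=inst.disease_concept,
            probability=float(p),
            positive=bool(p >= thr),
        )
        for inst, p in zip(instances, proba)
    ]


def cooccurrence_baseline(
    documents: Iterable[Document], disease_concept: str
) -> list[tuple[str, str]]:
    """The co-occurrence baseline: every variant mentioned in a document
    that also mentions the target disease is called disease-related.

    Returns unique (pmid, variant_key) pairs in deterministic order.
    """
    pairs = set()
    for doc in documents:
        if not any(
            m.concept_id == disease_concept for m in doc.mentions_of(DISEASE)
        ):
            continue
        for m in doc.mentions_of(MUTATION):
            pairs.add((doc.pmid, mention_variant_key(m)))
    return sorted(pairs)


def build_mutation_list(
    positive_pairs: Iterable[tuple[str, str]]
) -> list[MutationListEntry]:
    """Collapse positive (pmid, variant_key) pairs into the Mutation-list:
    unique variants ranked by descending number of distinct supporting
    PMIDs, ties broken lexicographically on the canonical key."""
    by_key: dict[str, set[str]] = {}
    for pmid, key in positive_pairs:
        by_key.setdefault(key, set()).add(pmid)
    entries = [
        MutationListEntry(variant_key=k, pmids=frozenset(v)) for k, v in by_key.items()
    ]
    entries.sort(key=lambda e: (-e.frequency, e.variant_key))
    return entries
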