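"""Shared fixtures: synthetic corpora and a trained classifier."""

from __future__ import annotations

import io

import pytest

from trimine import classify as dm
from trimine.ranking import FixtureSnippetProvider
from trimine.synth import CorpusGenerator, SynthConfig
from trimine.validation import load_proteome

#: Distractor-laden conditions used for training corpora: the classifier
#: must see both negative modes (disease absent; disease present but
#: distant/negated) to learn the boundary.
NOISY_RATES = dict(
    distractor_disease_rate=0.3,
    distractor_gene_rate=0.3,
    distractor_mutation_rate=0.3,
)


@pytest.fixture(scope="session")
def trained_model():
    """One classifier trained on a distractor-laden corpus, reused across
    all pipeline runs (the pipeline is designed around a single shared
    model rather than per-disease retraining)."""
    cfg = SynthConfig(seed=101, **NOISY_RATES)
    result = CorpusGenerator(cfg).corpus()
    return dm.train(result.labeled_instances)


@pytest.fixture(scope="session")
def clean_bundle():
    """Clean default corpus (20 planted triplets / 200 documents) plus its
    snippet provider, lexicon, and proteome."""
    gen = CorpusGenerator(SynthConfig(seed=7))
    return _bundle(gen)


def _bundle(gen: CorpusGenerator) -> dict:
    result = gen.corpus()
    fasta, mapping = gen.proteome_texts()
    return {
        "generator": gen,
        "result": result,
        "provider": FixtureSnippetProvider(gen.snippet_records()),
        "lexicon": gen.lexicon(),
        "proteome": load_proteome(io.StringIO(fasta), io.StringIO(mapping)),
    }


@pytest.fixture()
def make_bundle():
    def _make(**overrides) -> dict:
        return _bundle(CorpusGenerator(SynthConfig(**overrides)))

    return _make
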