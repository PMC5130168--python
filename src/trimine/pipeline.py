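"""End-to-end triplet extraction.

Orchestrates the stages into one run per target disease:

1. classify every (document, mutation) pair against the target disease
   (or take the co-occurrence baseline),
2. collapse positives into the frequency-ranked Mutation-list,
3. rank candidate genes per mutation from literature and web snippets and
   merge the two rankings,
4. validate the candidates against protein isoform sequences,
5. emit <disease, gene, variant> triplets with supporting PMIDs and a
   validation status.

Runs are deterministic given a fixed model, fixtures, and configuration.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import classify as dm
from .classify import DiseaseMutationClassifier, DMInstance, MutationListEntry
from .pubtator import MUTATION, Document
from .ranking import (
    GeneCandidate,
    GeneLexicon,
    SnippetProvider,
    aggregate_ranks,
    pubmed_rank,
    web_rank,
)
from .validation import Proteome, select_gene
from .variants import SUBSTITUTION, ParseFailure, parse_variant

__all__ = ["Triplet", "PipelineConfig", "run_pipeline", "build_instances",
           "write_triplets_tsv", "read_triplets_tsv", "read_gold_tsv"]

logger = logging.getLogger(__name__)

#: Validation status for variants that are not protein substitutions and
#: therefore skip the sequence check entirely.
UNVALIDATED = "unvalidated"


@dataclass(frozen=True)
class Triplet:
    disease_concept: str
    gene_id: str
    variant_key: str
    supporting_pmids: frozenset[str]
    validation_status: str = UNVALIDATED
    matched_accession: str | None = None

    @property
    def frequency(self) -> int:
        return len(self.supporting_pmids)

    def key(self) -> tuple[str, str, str]:
        return (self.disease_concept, self.gene_id, self.variant_key)


@dataclass
class PipelineConfig:
    threshold: float = 0.5
    use_baseline: bool = False


def build_instances(
    documents: Iterable[Document],
    disease_concept: str,
    labels: Mapping[tuple[str, str], bool] | None = None,
) -> list[DMInstance]:
    """One instance per (document, unique mutation key) pair.

    ``labels`` maps (pmid, variant_key) to ground-truth labels when known
    (training); unlisted pairs stay unlabeled.
    """
    instances = []
    for doc in documents:
        keys = sorted({dm.mention_variant_key(m) for m in doc.mentions_of(MUTATION)})
        for key in keys:
            features = dm.extract_features(doc, key, disease_concept)
            label = labels.get((doc.pmid, key)) if labels is not None else None
            instances.append(
                DMInstance(
                    pmid=doc.pmid,
                    variant_key=key,
                    disease_concept=disease_concept,
                    features=features,
                    label=label,
                )
            )
    return instances


def _most_frequent_surface(entry: MutationListEntry, corpus: Mapping[str, Document]) -> str:
    """The variant's most frequent raw surface form across its supporting
    abstracts — used as the web search query."""
    counts: Counter[str] = Counter()
    for pmid in entry.pmids:
        doc = corpus.get(pmid)
        if doc is None:
            continue
        for m in doc.mentions_of(MUTATION):
            if dm.mention_variant_key(m) == entry.variant_key:
                counts[m.surface] += 1
    if not counts:
        return entry.variant_key
    # ties break lexicographically for determinism
    return min(counts, key=lambda s: (-counts[s], s))


def run_pipeline(
    corpus: Iterable[Document] | Mapping[str, Document],
    disease_concept: str,
    model: DiseaseMutationClassifier | None = None,
    snippet_provider: SnippetProvider | None = None,
    lexicon: GeneLexicon | None = None,
    proteome: Proteome | None = None,
    config: PipelineConfig | None = None,
) -> list[Triplet]:
    """Run the full extraction for one target disease.

    ``model`` is required unless ``config.use_baseline`` is set.  Web
    ranking is skipped when no snippet provider/lexicon is given, and
    sequence validation is skipped (status ``unvalidated``) when no
    proteome is given or the variant is not a protein substitution.
    """
    config = config or PipelineConfig()
    if isinstance(corpus, Mapping):
        docs_by_pmid = dict(corpus)
    else:
        docs_by_pmid = {d.pmid: d for d in corpus}
    documents = list(docs_by_pmid.values())

    if config.use_baseline:
        positive_pairs = dm.cooccurrence_baseline(documents, disease_concept)
    else:
        if model is None:
            raise ValueError("a trained model is required unless use_baseline is set")
        instances = build_instances(documents, disease_concept)
        predictions = dm.predict(model, instances, threshold=config.threshold)
        positive_pairs = [
            (p.pmid, p.variant_key) for p in predictions if p.positive
        ]
    logger.info(
        "%s: %d positive (pmid, mutation) pairs", disease_concept, len(positive_pairs)
    )

    mutation_list = dm.build_mutation_list(positive_pairs)
    logger.info("%s: %d unique mutations", disease_concept, len(mutation_list))

    triplets = []
    for entry in mutation_list:
        pub_list = pubmed_rank(entry.variant_key, sorted(entry.pmids), docs_by_pmid)
        web_list: list[GeneCandidate] = []
        if snippet_provider is not None and lexicon is not None:
            query = _most_frequent_surface(entry, docs_by_pmid)
            web_list = web_rank(
                query, snippet_provider, lexicon, variant_key=entry.variant_key
            )
        candidates = aggregate_ranks(pub_list, web_list)
        if not candidates:
            logger.info("no gene candidates for %s; dropped", entry.variant_key)
            continue

        parsed = parse_variant(entry.variant_key)
        substitution = None
        if (
            not isinstance(parsed, ParseFailure)
            and parsed.kind == SUBSTITUTION
            and parsed.level == "protein"
        ):
            substitution = parsed.payload

        if substitution is not None and proteome is not None:
            result = select_gene(candidates, substitution, proteome)
            status, accession, gene_id = (
                result.match_type,
                result.matched_accession,
                result.gene_id,
            )
        else:
            status, accession, gene_id = UNVALIDATED, None, candidates[0].gene_id

        triplets.append(
            Triplet(
                disease_concept=disease_concept,
                gene_id=gene_id,
                variant_key=entry.variant_key,
                supporting_pmids=entry.pmids,
                validation_status=status,
                matched_accession=accession,
            )
        )
    return triplets


# ---------------------------------------------------------------------------
# Triplet TSV I/O
# ---------------------------------------------------------------------------

_HEADER = "disease_concept\tgene_id\tvariant_key\tfrequency\tpmids\tvalidation_status"


def write_triplets_tsv(triplets: Sequence[Triplet], path) -> None:
    lines = [_HEADER]
    for t in triplets:
        lines.append(
            "\t".join(
                [
                    t.disease_concept,
                    t.gene_id,
                    t.variant_key,
                    str(t.frequency),
                    ",".join(sorted(t.supporting_pmids)),
                    t.validation_status,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_triplets_tsv(path) -> list[Triplet]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    out = []
    for line in lines:
        if not line.strip() or line.startswith("disease_concept"):
            continue
        fields = line.split("\t")
        disease, gene, variant = fields[0], fields[1], fields[2]
        pmids = frozenset(p for p in fields[4].split(",") if p) if len(fields) > 4 else frozenset()
        status = fields[5] if len(fields) > 5 else UNVALIDATED
        out.append(
            Triplet(
                disease_concept=disease,
                gene_id=gene,
                variant_key=variant,
                supporting_pmids=pmids,
                validation_status=status,
            )
        )
    return out


def read_gold_tsv(path) -> list[Triplet]:
    """Gold standard: same TSV layout, validation columns optional."""
    return read_triplets_tsv(path)
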