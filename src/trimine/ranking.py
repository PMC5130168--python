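"""Candidate-gene ranking from global context.

For each disease-associated mutation two candidate lists are built and then
merged:

* the **literature rank list** — every normalized gene mentioned in the
  mutation's supporting abstracts, scored by the aggregate count of its
  mentions across all of those abstracts (a gene mentioned 3+2+1 times in
  three abstracts scores 6);
* the **web rank list** — genes tagged in search-result snippets whose text
  actually contains the mutation (any notation), ranked by mention
  frequency.

The merge rule: genes on both lists are promoted to their better
(numerically smaller) rank; web-only genes are appended after all
literature genes when their snippet frequency exceeds one, and dropped
otherwise.  Web search sits behind a provider contract; the shipped
provider replays JSON fixtures so the pipeline stays hermetic.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

from .pubtator import GENE, Document
from .variants import ParseFailure, canonical_key, parse_variant, variant_key_for_surface

__all__ = [
    "GeneCandidate",
    "WebSnippet",
    "SnippetProvider",
    "FixtureSnippetProvider",
    "GeneLexicon",
    "TaggedGene",
    "pubmed_rank",
    "tag_genes",
    "web_rank",
    "aggregate_ranks",
    "text_mentions_variant",
]

logger = logging.getLogger(__name__)

SOURCE_PUBMED = "pubmed"
SOURCE_WEB = "web"
SOURCE_BOTH = "both"


@dataclass(frozen=True)
class GeneCandidate:
    gene_id: str
    score: int
    rank: int
    source: str


@dataclass(frozen=True)
class WebSnippet:
    query: str
    position: int
    title: str
    snippet: str

    @property
    def text(self) -> str:
        return self.title + " " + self.snippet


class SnippetProvider(Protocol):
    """Contract for a search-snippet source: at most 20 ranked snippets per
    query.  Implementations must be deterministic to keep runs reproducible."""

    def query(self, q: str) -> Sequence[WebSnippet]: ...


class FixtureSnippetProvider:
    """Replays snippet fixtures from a JSON array of
    ``{"query", "position", "title", "snippet"}`` records."""

    def __init__(self, records: Iterable[Mapping]):
        self._by_query: dict[str, list[WebSnippet]] = {}
        for rec in records:
            snip = WebSnippet(
                query=rec["query"],
                position=int(rec["position"]),
                title=rec.get("title", ""),
                snippet=rec.get("snippet", ""),
            )
            self._by_query.setdefault(snip.query, []).append(snip)
        for snippets in self._by_query.values():
            snippets.sort(key=lambda s: s.position)
            positions = [s.position for s in snippets]
            if len(set(positions)) != len(positions):
                raise ValueError("duplicate snippet position within one query")

    @classmethod
    def from_json(cls, path) -> "FixtureSnippetProvider":
        return cls(json.loads(Path(path).read_text(encoding="utf-8")))

    def query(self, q: str) -> list[WebSnippet]:
        return self._by_query.get(q, [])[:20]


@dataclass(frozen=True)
class TaggedGene:
    start: int
    end: int
    surface: str
    gene_id: str


class GeneLexicon:
    """Surface-symbol/alias -> gene_id dictionary for snippet tagging.

    Matching is case-sensitive on word boundaries (gene symbols are
    conventionally cased; case-folding short symbols like ``WAS`` floods the
    tagger with English words).
    """

    def __init__(self, mapping: Mapping[str, str]):
        self._map = dict(mapping)
        # longest-first so overlapping aliases resolve to the longest match
        self._order = sorted(self._map, key=lambda s: (-len(s), s))

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._map

    def gene_id(self, symbol: str) -> str:
        return self._map[symbol]

    def items(self):
        return self._map.items()

    @classmethod
    def from_tsv(cls, path) -> "GeneLexicon":
        mapping = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            symbol, gene_id = line.split("\t")[:2]
            mapping[symbol] = gene_id
        return cls(mapping)

    def tag(self, text: str) -> list[TaggedGene]:
        return tag_genes(text, self)


def tag_genes(text: str, lexicon: GeneLexicon) -> list[TaggedGene]:
    """Dictionary-match gene symbols in free text, longest match first.

    Characters claimed by a longer alias are not re-matched by shorter
    ones; hits are returned in document order.
    """
    if len(lexicon) == 0:
        raise ValueError("empty gene lexicon")
    claimed: list[tuple[int, int]] = []
    hits: list[TaggedGene] = []
    for symbol in lexicon._order:
        for m in re.finditer(rf"(?<![\w-]){re.escape(symbol)}(?![\w-])", text):
            if any(m.start() < e and s < m.end() for s, e in claimed):
                continue
            claimed.append((m.start(), m.end()))
            hits.append(
                TaggedGene(m.start(), m.end(), m.group(0), lexicon.gene_id(symbol))
            )
    hits.sort(key=lambda h: h.start)
    return hits


def _renumber(candidates: list[GeneCandidate]) -> list[GeneCandidate]:
    return [
        GeneCandidate(c.gene_id, c.score, rank, c.source)
        for rank, c in enumerate(candidates, start=1)
    ]


def pubmed_rank(
    variant_key: str, pmids: Iterable[str], corpus: Mapping[str, Document]
) -> list[GeneCandidate]:
    """Rank genes by aggregate mention count across the variant's
    supporting abstracts.

    Ties break by the number of distinct supporting PMIDs, then gene_id.
    Title and abstract mentions count uniformly.
    """
    scores: dict[str, int] = {}
    support: dict[str, set[str]] = {}
    for pmid in pmids:
        doc = corpus.get(pmid)
        if doc is None:
            logger.warning("pubmed_rank: pmid %s absent from corpus", pmid)
            continue
        for m in doc.mentions_of(GENE):
            if m.concept_id is None:
                continue
            scores[m.concept_id] = scores.get(m.concept_id, 0) + 1
            support.setdefault(m.concept_id, set()).add(pmid)
    ordered = sorted(
        scores, key=lambda g: (-scores[g], -len(support[g]), g)
    )
    return _renumber(
        [GeneCandidate(g, scores[g], 0, SOURCE_PUBMED) for g in ordered]
    )


# candidate variant-looking tokens inside snippet text
_VARIANT_TOKEN = re.compile(
    r"(?<![\w.])(?:[pcgmr]\.[A-Za-z0-9>*]+|[A-Za-z]{1,3}\d+(?:[A-Za-z]{1,3}|\*))(?![\w.])"
)


def text_mentions_variant(text: str, variant_key: str) -> bool:
    """True when any variant-shaped token in ``text`` parses to the same
    canonical key — so an ``E298D`` snippet matches a ``Glu298Asp`` query."""
    for m in _VARIANT_TOKEN.finditer(text):
        parsed = parse_variant(m.group(0))
        if isinstance(parsed, ParseFailure):
            continue
        if canonical_key(parsed) == variant_key:
            return True
    return False


def web_rank(
    variant_surface: str,
    provider: SnippetProvider,
    lexicon: GeneLexicon,
    *,
    variant_key: str | None = None,
) -> list[GeneCandidate]:
    """Rank genes by mention frequency in snippets that contain the variant.

    ``variant_surface`` is the query string (by convention the variant's
    most frequent surface form in the literature).  Only snippets whose
    title+snippet text mentions an equivalent variant contribute.  Provider
    failures degrade to an empty list so the pipeline can proceed on
    literature evidence alone.
    """
    key = variant_key or variant_key_for_surface(variant_surface)
    try:
        snippets = provider.query(variant_surface)
    except Exception:  # provider contract: never take the pipeline down
        logger.warning("snippet provider failed for query %r", variant_surface)
        return []
    freq: dict[str, int] = {}
    for snip in snippets:
        if not text_mentions_variant(snip.text, key):
            continue
        for hit in tag_genes(snip.text, lexicon):
            freq[hit.gene_id] = freq.get(hit.gene_id, 0) + 1
    ordered = sorted(freq, key=lambda g: (-freq[g], g))
    return _renumber([GeneCandidate(g, freq[g], 0, SOURCE_WEB) for g in ordered])


def aggregate_ranks(
    pubmed_list: Sequence[GeneCandidate], web_list: Sequence[GeneCandidate]
) -> list[GeneCandidate]:
    """Merge the literature and web candidate lists.

    * Genes on both lists take effective rank ``min(pubmed, web)`` and the
      literature list is re-sorted by effective rank.  When a promoted gene
      collides with the incumbent of that rank, the promoted gene takes the
      position (that is what raising its rank order means); remaining ties
      keep original literature order.
    * Web-only genes with snippet frequency > 1 are appended after every
      literature gene, in web order; web-only genes with frequency <= 1 are
      dropped (web snippets are the noisier source).
    * Output ranks are renumbered 1..n.
    """
    web_rank_of = {c.gene_id: c.rank for c in web_list}
    web_freq_of = {c.gene_id: c.score for c in web_list}
    pub_ids = {c.gene_id for c in pubmed_list}

    keyed = []
    for i, cand in enumerate(pubmed_list):
        effective = min(cand.rank, web_rank_of.get(cand.gene_id, cand.rank))
        promoted = effective < cand.rank
        source = SOURCE_BOTH if cand.gene_id in web_rank_of else SOURCE_PUBMED
        keyed.append(
            (effective, 0 if promoted else 1, i,
             GeneCandidate(cand.gene_id, cand.score, 0, source))
        )
    keyed.sort(key=lambda t: t[:3])
    merged = [c for *_, c in keyed]

    for cand in web_list:
        if cand.gene_id in pub_ids:
            continue
        if web_freq_of[cand.gene_id] > 1:
            merged.append(GeneCandidate(cand.gene_id, cand.score, 0, SOURCE_WEB))
    return _renumber(merged)
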