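"""Gene candidate ranking: literature scores, snippet mining, and the
rank-aggregation rule (checked against a brute-force oracle)."""

import io
import itertools

import pytest

from trimine.pubtator import read_pubtator
from trimine.ranking import (
    FixtureSnippetProvider,
    GeneCandidate,
    GeneLexicon,
    aggregate_ranks,
    pubmed_rank,
    tag_genes,
    text_mentions_variant,
    web_rank,
)

LEXICON = GeneLexicon(
    {"BRAF": "gene:673", "NOS3": "gene:4846", "RAF1": "gene:5894", "NOS": "gene:99"}
)


def _corpus(spec):
    """spec: {pmid: [(gene_symbol, concept, count)]} -> corpus mapping."""
    blocks = []
    for pmid, genes in spec.items():
        words = []
        annotations = []
        for symbol, concept, count in genes:
            words.extend([symbol] * count)
        abstract = " ".join(words) if words else "No genes here."
        text = "Title. " + abstract
        cursor = 0
        for symbol, concept, count in genes:
            for _ in range(count):
                start = text.index(symbol, cursor)
                cursor = start + 1
                annotations.append(
                    f"{pmid}\t{start}\t{start + len(symbol)}\t{symbol}\tGene\t{concept}"
                )
        blocks.append(
            "\n".join([f"{pmid}|t|Title.", f"{pmid}|a|{abstract}"] + annotations)
        )
    docs = read_pubtator(io.StringIO("\n\n".join(blocks) + "\n"), strict=True)
    return {d.pmid: d for d in docs}


class TestPubmedRank:
    def test_aggregate_score_sums_mentions_across_abstracts(self):
        corpus = _corpus(
            {
                "1": [("BRAF", "gene:673", 3)],
                "2": [("BRAF", "gene:673", 2)],
                "3": [("BRAF", "gene:673", 1)],
            }
        )
        (cand,) = pubmed_rank("p.V600E", ["1", "2", "3"], corpus)
        assert cand.score == 6
        assert cand.rank == 1

    def test_no_gene_mentions_gives_empty_list(self):
        corpus = _corpus({"1": []})
        assert pubmed_rank("p.V600E", ["1"], corpus) == []

    def test_empty_pmid_list_gives_empty_list(self):
        assert pubmed_rank("p.V600E", [], {}) == []

    def test_tie_broken_by_distinct_supporting_pmids(self):
        corpus = _corpus(
            {
                "1": [("BRAF", "gene:673", 2), ("RAF1", "gene:5894", 4)],
                "2": [("BRAF", "gene:673", 2)],
            }
        )
        ranked = pubmed_rank("p.V600E", ["1", "2"], corpus)
        assert [c.gene_id for c in ranked] == ["gene:673", "gene:5894"]
        assert ranked[0].score == ranked[1].score == 4

    def test_score_monotone_under_added_mention(self):
        base = _corpus({"1": [("BRAF", "gene:673", 2)]})
        more = _corpus({"1": [("BRAF", "gene:673", 3)]})
        s0 = pubmed_rank("k", ["1"], base)[0].score
        s1 = pubmed_rank("k", ["1"], more)[0].score
        assert s1 > s0


class TestTagGenes:
    def test_single_hit(self):
        hits = tag_genes("BRAF V600E in melanoma", LEXICON)
        assert [(h.surface, h.gene_id) for h in hits] == [("BRAF", "gene:673")]

    def test_longest_match_wins_on_overlapping_aliases(self):
        hits = tag_genes("The NOS3 polymorphism", LEXICON)
        assert [(h.surface, h.gene_id) for h in hits] == [("NOS3", "gene:4846")]

    def test_word_boundaries_respected(self):
        assert tag_genes("ABRAF and BRAFX are not genes", LEXICON) == []

    def test_no_hits_empty(self):
        assert tag_genes("nothing relevant", LEXICON) == []

    def test_empty_lexicon_rejected(self):
        with pytest.raises(ValueError):
            tag_genes("BRAF", GeneLexicon({}))


def _provider(snippets):
    return FixtureSnippetProvider(
        [
            {"query": q, "position": i + 1, "title": t, "snippet": s}
            for q, entries in snippets.items()
            for i, (t, s) in enumerate(entries)
        ]
    )


class TestWebRank:
    def test_counts_genes_only_in_mutation_bearing_snippets(self):
        provider = _provider(
            {
                "V600E": [
                    ("BRAF and V600E", "BRAF studies of V600E."),
                    ("V600E report", "Role of BRAF near V600E."),
                    ("BRAF overview", "General BRAF biology."),  # no variant
                    ("RAF1 and V600E", "RAF1 mentioned once."),
                ]
            }
        )
        ranked = web_rank("V600E", provider, LEXICON)
        # BRAF: 2 mentions in snippet 1 + 1 in snippet 2; snippet 3 has no
        # variant so its BRAF mention does not count.  RAF1: 2 mentions.
        assert [(c.gene_id, c.score) for c in ranked] == [("gene:673", 3), ("gene:5894", 2)]

    def test_all_snippets_lack_mutation_gives_empty(self):
        provider = _provider({"V600E": [("BRAF overview", "no variant here")]})
        assert web_rank("V600E", provider, LEXICON) == []

    def test_notation_equivalence_matches_snippet(self):
        provider = _provider(
            {"Glu298Asp": [("NOS3 gene", "The E298D polymorphism of NOS3.")]}
        )
        ranked = web_rank("Glu298Asp", provider, LEXICON)
        assert ranked[0].gene_id == "gene:4846"

    def test_provider_failure_degrades_to_empty(self):
        class Broken:
            def query(self, q):
                raise RuntimeError("network down")

        assert web_rank("V600E", Broken(), LEXICON) == []

    def test_unknown_query_returns_empty(self):
        assert web_rank("V600E", _provider({}), LEXICON) == []


def test_text_mentions_variant_equivalence():
    assert text_mentions_variant("the E298D allele", "p.E298D")
    assert text_mentions_variant("p.Val600Glu was seen", "p.V600E")
    assert not text_mentions_variant("the E298D allele", "p.V600E")


# ---------------------------------------------------------------------------
# Rank aggregation
# ---------------------------------------------------------------------------


def _pub(*gene_ids):
    return [GeneCandidate(g, 10 - i, i + 1, "pubmed") for i, g in enumerate(gene_ids)]


def _web(*pairs):
    return [GeneCandidate(g, f, i + 1, "web") for i, (g, f) in enumerate(pairs)]


def brute_force_aggregate(pub, web):
    """Independent oracle: apply the three written rules literally."""
    web_rank_of = {c.gene_id: c.rank for c in web}
    effective = {}
    promoted = set()
    for c in pub:
        effective[c.gene_id] = c.rank
        if c.gene_id in web_rank_of and web_rank_of[c.gene_id] < c.rank:
            effective[c.gene_id] = web_rank_of[c.gene_id]
            promoted.add(c.gene_id)
    order = sorted(
        range(len(pub)),
        key=lambda i: (
            effective[pub[i].gene_id],
            0 if pub[i].gene_id in promoted else 1,
            i,
        ),
    )
    result = [pub[i].gene_id for i in order]
    pub_ids = {c.gene_id for c in pub}
    for c in web:
        if c.gene_id not in pub_ids and c.score > 1:
            result.append(c.gene_id)
    return result


class TestAggregateRanks:
    def test_empty_web_list_keeps_pubmed_order(self):
        pub = _pub("g1", "g2", "g3")
        merged = aggregate_ranks(pub, [])
        assert [c.gene_id for c in merged] == ["g1", "g2", "g3"]
        assert [c.rank for c in merged] == [1, 2, 3]

    def test_web_only_frequency_one_excluded(self):
        merged = aggregate_ranks(_pub("g1"), _web(("g9", 1)))
        assert [c.gene_id for c in merged] == ["g1"]

    def test_min_rank_promotion_worked_example(self):
        pub = _pub("g1", "g2", "g3")
        web = _web(("g3", 5), ("g4", 2), ("g5", 1))
        merged = aggregate_ranks(pub, web)
        # g3 takes rank min(3, 1) = 1; web-only g4 (f=2) appends; g5 drops
        assert [c.gene_id for c in merged] == ["g3", "g1", "g2", "g4"]
        assert [c.rank for c in merged] == [1, 2, 3, 4]
        assert merged[0].source == "both" and merged[-1].source == "web"

    def test_matches_brute_force_oracle_exhaustively(self):
        """Equivalence with the literal-rule oracle over all small list
        pairs including every tie configuration."""
        genes = ["a", "b", "c", "d"]
        checked = 0
        for k_pub in range(0, 4):
            for pub_genes in itertools.permutations(genes[:3], k_pub):
                for k_web in range(0, 3):
                    for web_genes in itertools.permutations(genes[1:], k_web):
                        for freqs in itertools.product([1, 2, 3], repeat=k_web):
                            if list(freqs) != sorted(freqs, reverse=True):
                                continue  # web lists are frequency-sorted
                            pub = _pub(*pub_genes)
                            web = _web(*zip(web_genes, freqs))
                            merged = aggregate_ranks(pub, web)
                            assert [c.gene_id for c in merged] == brute_force_aggregate(
                                pub, web
                            )
                            assert [c.rank for c in merged] == list(
                                range(1, len(merged) + 1)
                            )
                            assert len({c.gene_id for c in merged}) == len(merged)
                            checked += 1
        assert checked > 500

    def test_every_pubmed_gene_survives_and_appends_are_exact(self):
        pub = _pub("g1", "g2")
        web = _web(("g2", 9), ("g7", 2), ("g8", 3), ("g9", 1))
        merged = aggregate_ranks(pub, web)
        ids = [c.gene_id for c in merged]
        assert set(ids) == {"g1", "g2", "g7", "g8"}
        assert ids.index("g2") < ids.index("g1")  # promoted by min-rank
        assert ids[-2:] == ["g7", "g8"]  # web order preserved for appends
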