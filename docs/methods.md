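# Methods

This note documents the models and procedures implemented in `trimine`,
the choices made where the design was genuinely open, and what the
synthetic-data experiments do and do not demonstrate.

## Problem setting

The unit of extraction is a triplet ⟨disease, gene, variant⟩ asserted by
the literature, with supporting PMIDs. Inputs are abstracts that have
already been processed by named-entity recognizers: gene mentions
normalized to Entrez-style ids, disease mentions to MeSH concepts, and
mutation mentions as surface strings. Running any tagger is explicitly out
of scope — the package consumes their output in the PubTator exchange
format.

### PubTator dialect

Offsets are 0-based, half-open, over `title + " " + abstract`. Every
mention must satisfy the surface-slice invariant (`text[start:end] ==
surface`); by default, violating annotations are warned and dropped,
because real exports drift, while `strict=True` raises (tests run strict).
Annotations straddling the title/abstract boundary are treated as invalid
input. Unnormalized mentions carry `concept_id=None` — no sentinels.
Sentence splitting is rule-based (terminator followed by whitespace and an
upper-case/digit/opening character, with an abbreviation guard list) and
deterministic; a model-based splitter would be marginally better on prose
but non-reproducible across versions.

## Variant grammar and identity

`parse_variant` recognizes one-letter (`V600E`), three-letter
(`Glu298Asp`), and `p.`-prefixed protein substitutions, nonsense changes
(`W779X`, `Trp779Ter`), `c./g./m./r.` nucleotide substitutions, and
classifies del/ins/dup/fs strings by kind. Failures are typed values,
never exceptions. Three-letter codes match case-insensitively; one-letter
codes must be uppercase, because lower-case single letters next to digits
in snippet text are overwhelmingly false matches. The canonical key is
`p.<wild><pos><mutant>` for protein substitutions and the normalized
payload string otherwise. Cross-level normalization (projecting `c.`
notation onto protein coordinates) is deliberately not attempted; variants
at different levels are never equivalent. The residue vocabulary is the 20
standard amino acids plus `X` and `*` (nonsense); `X` and `*` are kept
distinct so keys remain injective on parsed triples.

## Disease–mutation classification

One instance per (document, unique variant key, target disease). Features:

| feature | definition | default relevance |
| --- | --- | --- |
| `min_token_distance` | min whitespace-token distance between any variant mention and any target-disease mention; sentinel = document token count when the disease is absent | proximity signal |
| `target_disease_count` | target-disease mentions in the document | topicality |
| `same_sentence` | any variant/disease pair in one sentence | strongest single cue |
| `sentence_polarity` | lexicon score in [−1, 1] of the sentence holding the closest pair (variant side when the pair spans sentences) | affirms vs. negates the relation |
| `mutation_mention_count` | mentions of this variant | salience |
| `other_disease_count` | disease mentions with a different concept | confounder load |

Polarity is a deterministic lexicon scorer with a 3-token negation window
("was **not associated** with" → −1, "was **significantly associated**
with" → +1). A lexicon was chosen over a general sentiment package because
the feature must react to association language, not emotional tone, and
must be bit-reproducible.

The classifier is standardized-input logistic regression (`C=1.0`,
`max_iter=500`, seeded) behind a scikit-learn estimator interface —
auditable weights, instant retraining, adequate capacity for six features.
The decision threshold on the positive-class probability defaults to 0.5
and is configurable. Persistence is a versioned JSON bundle (feature
schema + scaler statistics + weights); loading verifies the schema
version so stale models fail loudly. One trained model is reused across
target diseases; the cross-disease property test checks that a model
trained against one disease concept transfers to corpora generated for
another (F₁ ≥ 0.85), which is the premise that makes a single shared
training set workable.

The co-occurrence baseline labels every variant in a document that
mentions the target disease as related. On any corpus where true pairs
co-occur, its positives are a superset of the classifier's (restricted to
co-occurring documents), so its recall upper-bounds the classifier's —
precision is where the classifier earns its keep.

The Mutation-list ranks unique variants by distinct supporting PMIDs,
descending; frequency ties break lexicographically on the canonical key
(the ordering is otherwise unspecified, and determinism matters more than
any particular tie choice).

## Gene ranking and aggregation

*Literature list*: a gene's score is its total mention count across the
variant's supporting abstracts, title and abstract counted uniformly
(nothing in the scoring rationale distinguishes them). Ties break by
distinct supporting PMIDs, then gene id.

*Web list*: the query is the variant's most frequent surface form in its
supporting abstracts. Only snippets (title + snippet text) containing a
notation-equivalent variant count; genes are tagged by case-sensitive,
longest-match, word-boundary dictionary lookup against a TSV lexicon
(case-folding short symbols such as `WAS` or `MET` floods the tagger with
English words). Live search sits behind a provider contract; the shipped
provider replays JSON fixtures, and any provider failure degrades to an
empty web list so extraction proceeds on literature evidence alone.

*Aggregation*: genes on both lists take effective rank
min(literature, web); web-only genes with snippet frequency > 1 are
appended after all literature genes in web order; web-only genes with
frequency ≤ 1 are dropped (the web is the noisier source, and the f > 1
filter is scoped to web-only genes, not overlapping ones). When a
promoted gene collides with the incumbent of its new rank, the promoted
gene takes the position — that is what raising its rank order means —
and all remaining ties keep original literature order. The implementation
is checked against a brute-force oracle over exhaustive small list pairs,
including every tie configuration.

## Sequence validation

Candidates are walked in rank order; a gene is selected as soon as any of
its protein isoforms carries the reference or mutant residue at the
variant's 1-based position (reference and mutant matches are accepted
equally downstream, but the match type is recorded for audit). With no
match anywhere, the top-ranked candidate is returned flagged `fallback`.
Only protein-level substitutions (including nonsense) are validatable;
other variant kinds keep the top-ranked gene flagged `unvalidated`.
Coordinates are taken on the FASTA sequences as given — no
signal-peptide or isoform renumbering — so a position beyond the sequence
end simply fails to match. Isoforms are checked in mapping-file order for
reproducibility; the boolean outcome is order-independent.

## Evaluation machinery

Triplet matching is exact on normalized ids; the default granularity
counts unique triplets, with a per-mention mode (expanding by supporting
PMIDs) behind a flag. Zero-denominator metrics report 0 with an explicit
`*_defined` flag instead of NaN so tables always render. Table rounding is
half-up at the printed precision, applied only at reporting time; internal
values stay at full precision. Frequency strata are high (> 10 PMIDs),
medium (4–10), low (< 4); stratified sampling is seeded, uniform, without
replacement, with default caps 10/15/30 per stratum and whole-stratum
take-all below the cap. Coverage screening flags concept-level presence of
disease, gene, and mutation per (triplet, PMID) pair; missing documents
are flagged, not errors.

## Synthetic data: what it emulates, and what it does not

The generator plants triplets for one target disease into templated
abstracts (subject–verb–entity prose, so sentence splitting and polarity
operate meaningfully): an affirmative co-mention in the same sentence with
probability 0.8, otherwise in adjacent sentences; 15% of documents are
background documents in which the planted variant is discussed for an
unrelated disease (the disease-absent negative mode). Distractor diseases,
genes, and mutations are injected per document at configurable rates with
negated or unrelated phrasing — the second negative mode (disease present
but distant/negated). Defaults: 200 documents, 20 planted triplets,
distractor pools of 10 diseases / 15 genes / 15 variants, all rates 0.
Snippet fixtures give each planted variant four true-gene snippets in
rotating notations (exercising equivalence matching) plus optional noise
snippets; the proteome gives each gene 1–3 isoforms with the wild residue
pinned at the variant position, and a corruption rate that scrambles that
position to force the fallback path. All randomness derives from one seed
through per-artifact streams, so fixtures are byte-identical across runs.

Problem sizes used in the tests and the acceptance script — 200-document
corpora, a single shared model trained on a distractor-laden corpus, ten
seeds for the noisy condition — keep the full suite in the tens of
seconds while leaving each stage's decision logic fully exercised.

What passing these experiments shows: every stage and their composition
are internally correct — planted signal is recovered exactly under clean
conditions, and precision stays ≥ 0.8 under moderate distraction. What it
does not show: performance on real abstracts. The generator does not
emulate tagger error profiles (wrong spans, missed or spurious entities,
bad normalizations), hedged or discourse-level assertions, notation drift
within one abstract, or protein-numbering inconsistencies between
literature and RefSeq — all of which dominate real-world error. The
templated prose is also far more separable than real text, so the
classifier's synthetic accuracy is an upper bound, not an estimate.

## Known limitations

* DNA/RNA-level variants are never linked to protein coordinates, so a
  `c.` mention and its protein consequence are distinct triplets.
* Sequence validation cannot confirm insertions or frameshifts; they pass
  through unvalidated.
* The snippet provider is fixture-only by design; plugging in a live
  search requires implementing the one-method provider contract and
  accepting non-reproducibility.
* The polarity lexicon is small and English-only; sentences with no cue
  words score 0 and contribute nothing to the decision.
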