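# trimine

Extraction of **⟨disease, gene, variant⟩ triplets** from entity-annotated
biomedical abstracts, for literature-curation support (triage of candidate
gene–variant–disease associations for databases such as UniProtKB, OMIM, or
CTD).

A single abstract routinely mentions several diseases, genes, and mutations,
only some of which are actually related — so naive co-occurrence extraction
("every variant in a disease-mentioning abstract is disease-related") floods
curators with false positives. `trimine` instead:

1. **Classifies disease–mutation relations.** For each (abstract *d*,
   mutation *m*, target disease *D*) it mines a feature vector — minimum
   token distance between *m* and *D* mentions, *D* mention count,
   same-sentence co-mention, sentence polarity (lexicon-scored on [−1, 1]),
   *m* mention count, and other-disease mention count — and applies a
   regularized logistic model. Positive (PMID, mutation) pairs are collapsed
   into the **Mutation-list**: unique variants ranked by the number of
   distinct supporting PMIDs.
2. **Ranks candidate genes from global context.** For each variant, a
   *literature rank list* scores every normalized gene by its aggregate
   mention count across all supporting abstracts (3 + 2 + 1 mentions in
   three abstracts → score 6), and a *web rank list* counts gene mentions in
   search-result snippets that contain the variant in any notation
   (`E298D` ≡ `Glu298Asp` ≡ `p.Glu298Asp`). The two are merged: overlapping
   genes are promoted to rank min(lit, web); web-only genes with snippet
   frequency *f* > 1 are appended; the rest are dropped.
3. **Validates against protein sequences.** Candidates are walked in rank
   order; a gene is accepted when any of its protein isoforms carries the
   variant's reference **or** mutant residue at the stated 1-based position.
   If no candidate matches, the top-ranked gene is kept, flagged `fallback`.

Evaluation is concept-level and exact: a predicted triplet is a true
positive iff its normalized disease concept (`mesh:`), gene id (`gene:`),
and canonical variant key (`p.<wild><pos><mutant>`) all match gold; reports
carry TP/FP/FN with precision = TP/(TP+FP), recall = TP/(TP+FN), and
F₁ = 2PR/(P+R), with frequency stratification (high > 10 PMIDs, medium
4–10, low < 4), capped stratified sampling, and abstract-coverage screening.

Because live literature taggers, web search, and RefSeq are outside the
package, a first-class synthetic-corpus module generates all inputs with
known ground truth: PubTator-format corpora with planted triplets and
distractor entities, labeled training pairs, snippet fixtures, a gene
lexicon, and a proteome consistent with the planted substitutions.

## Worked example

```python
import io
from trimine import classify as dm
from trimine import evaluate_triplets, run_pipeline, load_proteome
from trimine.ranking import FixtureSnippetProvider
from trimine.synth import CorpusGenerator, SynthConfig

# train the relation classifier once, on a distractor-laden corpus
train = CorpusGenerator(SynthConfig(seed=101,
    distractor_disease_rate=0.3, distractor_gene_rate=0.3,
    distractor_mutation_rate=0.3)).corpus()
model = dm.train(train.labeled_instances)

# extract triplets from a clean corpus (20 planted triplets, 200 abstracts)
gen = CorpusGenerator(SynthConfig(seed=7))
res = gen.corpus()
fasta, mapping = gen.proteome_texts()
triplets = run_pipeline(
    res.corpus, gen.target_concept, model,
    FixtureSnippetProvider(gen.snippet_records()), gen.lexicon(),
    load_proteome(io.StringIO(fasta), io.StringIO(mapping)),
)
report = evaluate_triplets(triplets, res.gold_triplets)
print(len(triplets), report.precision, report.recall)
print(sorted(t.validation_status for t in triplets)[0])
```

prints

```
20 1.0 1.0
reference
```

i.e. all 20 planted triplets are recovered with no false positives, and the
selected genes carry the reference residue at the variant position.

The same flow is available from the shell:

```sh
trimine simulate --seed 7 --out sim/
trimine train --corpus sim/corpus.pubtator --train-tsv sim/train.tsv \
    --disease mesh:D900100 --model model.json
trimine run --corpus sim/corpus.pubtator --disease mesh:D900100 \
    --model model.json --snippets sim/snippets.json --lexicon sim/lexicon.tsv \
    --fasta sim/proteome.fasta --gene2protein sim/gene2protein.tsv \
    --out triplets.tsv
trimine evaluate --predicted triplets.tsv --gold sim/gold.tsv
```

## Layout

| module | responsibility |
| --- | --- |
| `trimine.pubtator` | PubTator format I/O, document model, sentence splitting |
| `trimine.variants` | variant grammar, canonical keys, notation equivalence |
| `trimine.classify` | DM features, sklearn-style classifier, baseline, Mutation-list |
| `trimine.ranking` | literature/web gene ranking, lexicon tagging, rank aggregation |
| `trimine.validation` | proteome loading, position checks, candidate selection |
| `trimine.pipeline` | end-to-end orchestration, triplet TSV I/O |
| `trimine.evaluation` | metrics, stratification, sampling, coverage screening |
| `trimine.synth` | synthetic corpora/snippets/proteomes with ground truth |

See `docs/methods.md` for the model assumptions, parameter choices, and
known limitations.
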