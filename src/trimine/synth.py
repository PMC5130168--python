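"""Synthetic fixtures with known ground truth.

Generates everything the pipeline consumes — an entity-annotated abstract
corpus, labeled training pairs, web-snippet fixtures, a gene lexicon, and a
proteome consistent with the planted substitutions — so every stage is
testable hermetically, with no downloads.

The generator emulates the structure that makes triplet extraction hard in
real abstracts: multiple diseases, genes, and mutations co-mentioned in one
document, only some of which are related.  Planted triplets appear in
documents with an affirmative co-mention of disease and variant (in the
same sentence with configurable probability); distractor entities are
injected at configurable rates with explicitly negated or unrelated
phrasing, giving the classifier a learnable signal and the evaluator known
false-positive bait.  Document text is templated natural-ish prose so that
sentence splitting and polarity scoring operate meaningfully.

All randomness flows from ``SynthConfig.seed`` through per-artifact
``random.Random`` streams, so identical configurations yield byte-identical
fixtures.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .classify import DMInstance
from .pipeline import Triplet, build_instances
from .pubtator import DISEASE, GENE, MUTATION, Document, Mention, Span, write_pubtator
from .ranking import GeneLexicon
from .variants import ProteinSubstitution, render

__all__ = [
    "SynthConfig",
    "PlantedTriplet",
    "SynthCorpus",
    "CorpusGenerator",
    "generate_corpus",
    "generate_snippets",
    "generate_proteome",
]

_STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_THREE = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "V": "Val", "W": "Trp", "Y": "Tyr",
}
_SYLLABLES = [
    "bar", "cor", "dal", "fen", "gor", "hem", "kel", "lin",
    "mar", "nor", "pel", "ras", "sil", "tor", "vab", "wex",
]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic corpus.

    Defaults are the clean condition used throughout the test suite: 200
    documents carrying 20 planted triplets for one target disease, 80% of
    affirmative co-mentions in the same sentence, 15% background documents
    (the planted variant discussed without the target disease — the
    disease-absent negative mode), and no distractors, snippet noise, or
    proteome corruption.
    """

    n_documents: int = 200
    n_planted_triplets: int = 20
    distractor_disease_rate: float = 0.0
    distractor_gene_rate: float = 0.0
    distractor_mutation_rate: float = 0.0
    same_sentence_prob: float = 0.8
    background_doc_rate: float = 0.15
    snippet_noise_rate: float = 0.0
    proteome_corruption_rate: float = 0.0
    n_distractor_diseases: int = 10
    n_distractor_genes: int = 15
    n_distractor_mutations: int = 15
    target_disease_concept: str = "mesh:D900100"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "distractor_disease_rate",
            "distractor_gene_rate",
            "distractor_mutation_rate",
            "same_sentence_prob",
            "background_doc_rate",
            "snippet_noise_rate",
            "proteome_corruption_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class PlantedTriplet:
    disease_concept: str
    disease_name: str
    gene_id: str
    gene_symbol: str
    substitution: ProteinSubstitution
    notation: str  # primary surface notation used in documents: one|p|three

    @property
    def variant_key(self) -> str:
        return render(self.substitution)

    @property
    def primary_surface(self) -> str:
        return _surface(self.substitution, self.notation)


def _surface(sub: ProteinSubstitution, notation: str) -> str:
    if notation == "one":
        return f"{sub.wild}{sub.position}{sub.mutant}"
    if notation == "p":
        return render(sub)
    return f"{_THREE[sub.wild]}{sub.position}{_THREE[sub.mutant]}"


@dataclass
class SynthCorpus:
    """Bundle of generated fixtures plus their ground truth."""

    config: SynthConfig
    documents: list[Document]
    gold_triplets: list[Triplet]
    labeled_instances: list[DMInstance]
    labels: dict[tuple[str, str], bool]
    planted: list[PlantedTriplet]

    @property
    def corpus(self) -> dict[str, Document]:
        return {d.pmid: d for d in self.documents}


class _DocBuilder:
    """Accumulates document text while recording entity mention offsets."""

    def __init__(self, pmid: str):
        self.pmid = pmid
        self._chunks: list[str] = []
        self._len = 0
        self._title_end: int | None = None
        self.mentions: list[Mention] = []

    def add(self, text: str) -> None:
        self._chunks.append(text)
        self._len += len(text)

    def entity(self, surface: str, entity_class: str, concept_id: str | None) -> None:
        span = Span(self._len, self._len + len(surface))
        self.mentions.append(Mention(span, surface, entity_class, concept_id))
        self.add(surface)

    def end_title(self) -> None:
        if self._chunks and self._chunks[-1] == " ":
            self._chunks.pop()
            self._len -= 1
        self._title_end = self._len
        self.add(" ")

    def sentence(self, *pieces) -> None:
        for piece in pieces:
            if isinstance(piece, tuple):
                self.entity(*piece)
            else:
                self.add(piece)
        self.add(" ")

    def build(self) -> Document:
        text = "".join(self._chunks).rstrip()
        title = text[: self._title_end]
        abstract = text[self._title_end + 1 :]
        doc = Document(
            pmid=self.pmid,
            title=title,
            abstract=abstract,
            mentions=sorted(self.mentions, key=lambda m: (m.span.start, m.span.end)),
        )
        doc.validate()
        return doc


class CorpusGenerator:
    """Deterministic generator for one configuration.

    The entity universe (target disease, planted triplets, distractor
    pools) is drawn once from a dedicated random stream; the corpus,
    snippet, and proteome artifacts each use their own stream so they can
    be generated independently yet reproducibly.
    """

    def __init__(self, config: SynthConfig):
        self.config = config
        rng = random.Random(f"{config.seed}:universe")
        self.target_concept = config.target_disease_concept
        self.target_name = self._disease_name(rng)

        used_symbols: set[str] = set()
        used_variants: set[tuple[str, int, str]] = set()
        self.planted: list[PlantedTriplet] = []
        for i in range(config.n_planted_triplets):
            symbol = self._gene_symbol(rng, used_symbols)
            sub = self._substitution(rng, used_variants)
            self.planted.append(
                PlantedTriplet(
                    disease_concept=self.target_concept,
                    disease_name=self.target_name,
                    gene_id=f"gene:{5000 + i}",
                    gene_symbol=symbol,
                    substitution=sub,
                    notation=rng.choice(["one", "one", "p", "three"]),
                )
            )
        self.distractor_diseases = [
            (f"mesh:D{800000 + i}", self._disease_name(rng))
            for i in range(config.n_distractor_diseases)
        ]
        self.distractor_genes = [
            (f"gene:{7000 + i}", self._gene_symbol(rng, used_symbols))
            for i in range(config.n_distractor_genes)
        ]
        # each distractor mutation is tied to one distractor gene so that a
        # false-positive pair is at least internally consistent
        self.distractor_mutations = [
            (
                self.distractor_genes[i % len(self.distractor_genes)],
                self._substitution(rng, used_variants),
            )
            for i in range(config.n_distractor_mutations)
        ]

    # -- universe draws ----------------------------------------------------

    @staticmethod
    def _disease_name(rng: random.Random) -> str:
        stem = "".join(rng.sample(_SYLLABLES, 2))
        return f"{stem.capitalize()} syndrome"

    @staticmethod
    def _gene_symbol(rng: random.Random, used: set[str]) -> str:
        while True:
            symbol = "".join(rng.choices("ABCDEFGHKLMNPQRSTVWYZ", k=3)) + str(
                rng.randint(1, 9)
            )
            if symbol not in used:
                used.add(symbol)
                return symbol

    @staticmethod
    def _substitution(
        rng: random.Random, used: set[tuple[str, int, str]]
    ) -> ProteinSubstitution:
        while True:
            wild = rng.choice(_STANDARD_AA)
            mutant = rng.choice(_STANDARD_AA.replace(wild, ""))
            pos = rng.randint(20, 380)
            if (wild, pos, mutant) not in used:
                used.add((wild, pos, mutant))
                return ProteinSubstitution(wild, pos, mutant)

    # -- corpus ------------------------------------------------------------

    def corpus(self) -> SynthCorpus:
        cfg = self.config
        rng = random.Random(f"{cfg.seed}:corpus")
        documents: list[Document] = []
        labels: dict[tuple[str, str], bool] = {}
        support: dict[str, set[str]] = {t.variant_key: set() for t in self.planted}

        for i in range(cfg.n_documents):
            pmid = str(9000000 + i)
            triplet = self.planted[i % len(self.planted)] if self.planted else None
            background = rng.random() < cfg.background_doc_rate
            if triplet is None:
                doc = self._distractor_only_doc(pmid, rng, labels)
            elif background:
                doc = self._background_doc(pmid, triplet, rng, labels)
            else:
                doc = self._positive_doc(pmid, triplet, rng, labels)
                support[triplet.variant_key].add(pmid)
            documents.append(doc)

        gold = [
            Triplet(
                disease_concept=t.disease_concept,
                gene_id=t.gene_id,
                variant_key=t.variant_key,
                supporting_pmids=frozenset(support[t.variant_key]),
            )
            for t in self.planted
            if support[t.variant_key]
        ]
        instances = build_instances(documents, self.target_concept, labels)
        return SynthCorpus(
            config=cfg,
            documents=documents,
            gold_triplets=gold,
            labeled_instances=instances,
            labels=labels,
            planted=list(self.planted),
        )

    def _positive_doc(self, pmid, triplet, rng, labels) -> Document:
        cfg = self.config
        b = _DocBuilder(pmid)
        gene = (triplet.gene_symbol, GENE, triplet.gene_id)
        disease = (self.target_name, DISEASE, self.target_concept)
        var = (triplet.primary_surface, MUTATION, triplet.primary_surface)

        b.sentence("Clinical significance of ", gene, " variants in ", disease, ".")
        b.end_title()
        if rng.random() < cfg.same_sentence_prob:
            b.sentence(
                "The ", gene, " ", var,
                " mutation was significantly associated with ", disease,
                " in our cohort.",
            )
        else:
            b.sentence(
                "The ", gene, " ", var,
                " mutation was significantly enriched among affected individuals.",
            )
            b.sentence("All participants had been diagnosed with ", disease, ".")
        b.sentence("Expression of ", gene, " was further examined in mutation carriers.")

        if rng.random() < cfg.distractor_disease_rate:
            dd = rng.choice(self.distractor_diseases)
            b.sentence(
                "Subjects with ", (dd[1], DISEASE, dd[0]), " were excluded from enrollment."
            )
        if rng.random() < cfg.distractor_gene_rate:
            dg = rng.choice(self.distractor_genes)
            b.sentence(
                "Levels of ", (dg[1], GENE, dg[0]), " remained unchanged across all samples."
            )
        if rng.random() < cfg.distractor_mutation_rate:
            (dg_id, dg_sym), dsub = rng.choice(self.distractor_mutations)
            dsurf = _surface(dsub, "one")
            b.sentence(
                "The ", (dsurf, MUTATION, dsurf), " variant of ",
                (dg_sym, GENE, dg_id), " was not associated with disease status.",
            )
            labels[(pmid, render(dsub))] = False
        b.sentence("These findings may inform genetic screening strategies.")
        labels[(pmid, triplet.variant_key)] = True
        return b.build()

    def _background_doc(self, pmid, triplet, rng, labels) -> Document:
        """The planted variant discussed for an unrelated disease: target
        disease absent, so the (pmid, variant) pair is a true negative."""
        dd = rng.choice(self.distractor_diseases)
        b = _DocBuilder(pmid)
        gene = (triplet.gene_symbol, GENE, triplet.gene_id)
        var = (triplet.primary_surface, MUTATION, triplet.primary_surface)
        b.sentence("Genetic studies of ", (dd[1], DISEASE, dd[0]), ".")
        b.end_title()
        b.sentence(
            "The ", gene, " ", var, " mutation was significantly associated with ",
            (dd[1], DISEASE, dd[0]), ".",
        )
        b.sentence("No other conditions were investigated in this study.")
        labels[(pmid, triplet.variant_key)] = False
        return b.build()

    def _distractor_only_doc(self, pmid, rng, labels) -> Document:
        dd = rng.choice(self.distractor_diseases)
        dg_pair, dsub = rng.choice(self.distractor_mutations) if self.distractor_mutations else (
            rng.choice(self.distractor_genes), None
        )
        b = _DocBuilder(pmid)
        b.sentence("A survey of ", (dd[1], DISEASE, dd[0]), ".")
        b.end_title()
        if dsub is not None:
            dsurf = _surface(dsub, "one")
            b.sentence(
                "The ", (dsurf, MUTATION, dsurf), " variant of ",
                (dg_pair[1], GENE, dg_pair[0]), " was examined.",
            )
            labels[(pmid, render(dsub))] = False
        b.sentence("No conclusions could be drawn.")
        return b.build()

    # -- snippets ------------------------------------------------------------

    def snippet_records(self, planted: Sequence[PlantedTriplet] | None = None) -> list[dict]:
        """Web-snippet fixture: per planted variant, true-gene snippets in
        rotating notations plus optional distractor-gene noise snippets."""
        cfg = self.config
        rng = random.Random(f"{cfg.seed}:snippets")
        records: list[dict] = []
        notations = ["one", "p", "three"]
        for t in planted if planted is not None else self.planted:
            query = t.primary_surface
            position = 0
            for j in range(4):
                alt = _surface(t.substitution, notations[j % 3])
                position += 1
                records.append(
                    {
                        "query": query,
                        "position": position,
                        "title": f"{t.gene_symbol} gene and the {alt} mutation",
                        "snippet": (
                            f"Reports describe the {alt} mutation in the "
                            f"{t.gene_symbol} gene across several studies."
                        ),
                    }
                )
            for _ in range(6):
                if rng.random() >= cfg.snippet_noise_rate:
                    continue
                dg = rng.choice(self.distractor_genes)
                position += 1
                if rng.random() < 0.5:
                    title = f"{dg[1]} gene overview"
                    snippet = (
                        f"The {query} polymorphism is discussed near {dg[1]} "
                        "in this forum thread."
                    )
                else:
                    title = f"{dg[1]} general review"
                    snippet = f"A broad review of {dg[1]} function and regulation."
                records.append(
                    {"query": query, "position": position, "title": title, "snippet": snippet}
                )
        return records

    def lexicon(self) -> GeneLexicon:
        mapping = {t.gene_symbol: t.gene_id for t in self.planted}
        mapping.update({sym: gid for gid, sym in self.distractor_genes})
        return GeneLexicon(mapping)

    # -- proteome ------------------------------------------------------------

    def proteome_texts(
        self, planted: Sequence[PlantedTriplet] | None = None
    ) -> tuple[str, str]:
        """Return (FASTA text, gene2protein TSV text).

        Every planted gene gets 1-3 isoforms with the wild residue pinned
        at the variant position in at least the first; with probability
        ``proteome_corruption_rate`` a gene's isoforms are scrambled at
        that position (neither wild nor mutant residue), forcing the
        selection fallback path.  Distractor genes carry their paired
        distractor variant the same way.
        """
        cfg = self.config
        rng = random.Random(f"{cfg.seed}:proteome")
        fasta_lines: list[str] = []
        map_lines: list[str] = ["#gene_id\taccession"]
        acc_counter = 0

        pairs: list[tuple[str, ProteinSubstitution]] = [
            (t.gene_id, t.substitution)
            for t in (planted if planted is not None else self.planted)
        ]
        pairs.extend((gid, sub) for (gid, _), sub in self.distractor_mutations)

        for gene_id, sub in pairs:
            corrupt = rng.random() < cfg.proteome_corruption_rate
            n_iso = rng.randint(1, 3)
            for iso in range(n_iso):
                acc_counter += 1
                accession = f"NP_{acc_counter:06d}.1"
                length = sub.position + rng.randint(5, 30)
                seq = [rng.choice(_STANDARD_AA) for _ in range(length)]
                if corrupt:
                    forbidden = {sub.wild, sub.mutant}
                    choices = [a for a in _STANDARD_AA if a not in forbidden]
                    seq[sub.position - 1] = rng.choice(choices)
                elif iso == 0 or rng.random() < 0.7:
                    seq[sub.position - 1] = sub.wild
                fasta_lines.append(f">{accession}")
                body = "".join(seq)
                fasta_lines.extend(body[k : k + 60] for k in range(0, len(body), 60))
                map_lines.append(f"{gene_id}\t{accession}")
        return "\n".join(fasta_lines) + "\n", "\n".join(map_lines) + "\n"

    # -- bundle writer -------------------------------------------------------

    def write_all(self, outdir) -> dict[str, Path]:
        """Emit every fixture to ``outdir``; returns the path of each."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        result = self.corpus()
        paths = {
            "corpus": outdir / "corpus.pubtator",
            "gold": outdir / "gold.tsv",
            "train": outdir / "train.tsv",
            "snippets": outdir / "snippets.json",
            "fasta": outdir / "proteome.fasta",
            "gene2protein": outdir / "gene2protein.tsv",
            "lexicon": outdir / "lexicon.tsv",
        }
        paths["corpus"].write_text(write_pubtator(result.documents), encoding="utf-8")

        gold_lines = ["disease_concept\tgene_id\tvariant_key\tfrequency\tpmids"]
        for t in result.gold_triplets:
            gold_lines.append(
                "\t".join(
                    [
                        t.disease_concept,
                        t.gene_id,
                        t.variant_key,
                        str(t.frequency),
                        ",".join(sorted(t.supporting_pmids)),
                    ]
                )
            )
        paths["gold"].write_text("\n".join(gold_lines) + "\n", encoding="utf-8")

        train_lines = ["pmid\tvariant_key\tdisease_concept\tlabel"]
        for (pmid, key), label in sorted(result.labels.items()):
            train_lines.append(f"{pmid}\t{key}\t{self.target_concept}\t{int(label)}")
        paths["train"].write_text("\n".join(train_lines) + "\n", encoding="utf-8")

        paths["snippets"].write_text(
            json.dumps(self.snippet_records(), indent=1), encoding="utf-8"
        )
        fasta, mapping = self.proteome_texts()
        paths["fasta"].write_text(fasta, encoding="utf-8")
        paths["gene2protein"].write_text(mapping, encoding="utf-8")
        lex_lines = [f"{sym}\t{gid}" for sym, gid in sorted(self.lexicon().items())]
        paths["lexicon"].write_text("\n".join(lex_lines) + "\n", encoding="utf-8")
        return paths


def generate_corpus(config: SynthConfig) -> SynthCorpus:
    """Generate the annotated corpus, gold triplets, and labeled instances."""
    return CorpusGenerator(config).corpus()


def generate_snippets(
    planted: Sequence[PlantedTriplet], config: SynthConfig
) -> list[dict]:
    return CorpusGenerator(config).snippet_records(planted)


def generate_proteome(
    planted: Sequence[PlantedTriplet], config: SynthConfig
) -> tuple[str, str]:
    return CorpusGenerator(config).proteome_texts(planted)
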