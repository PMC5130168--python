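"""Triplet-level evaluation: precision/recall/F, frequency stratification,
stratified sampling, and abstract-coverage screening.

Matching is concept-level and exact — a predicted triplet counts as a true
positive only when its normalized disease concept, gene id, and canonical
variant key all equal a gold triplet's.  Metrics with a zero denominator
report 0 together with an explicit ``*_defined`` flag (so summary tables
always render) rather than NaN.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from .classify import mention_variant_key
from .pubtator import DISEASE, GENE, MUTATION, Document

__all__ = [
    "EvalReport",
    "CoverageFlags",
    "evaluate_triplets",
    "f_measure",
    "relative_improvement",
    "stratify_by_frequency",
    "stratified_sample",
    "precision_from_counts",
    "screen_coverage",
    "coverage_by_triplet",
    "coverage_table",
    "round_half_up",
]


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero to the printed precision (table rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class EvalReport:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    precision_defined: bool = True
    recall_defined: bool = True
    f1_defined: bool = True
    per_stratum: Mapping[str, "EvalReport"] | None = None

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float]:
        return (
            round_half_up(self.precision, ndigits),
            round_half_up(self.recall, ndigits),
            round_half_up(self.f1, ndigits),
        )


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def relative_improvement(old: float, new: float) -> int:
    """Percent change 100*(new-old)/old, rounded half-up to an integer."""
    if old <= 0:
        raise ValueError("baseline value must be positive")
    return int(
        Decimal(repr(100 * (new - old) / old)).quantize(0, rounding=ROUND_HALF_UP)
    )


def _triplet_key(t) -> tuple[str, str, str]:
    if isinstance(t, tuple):
        return t[:3]
    return (t.disease_concept, t.gene_id, t.variant_key)


def _mention_keys(t) -> set[tuple[str, str, str, str]]:
    base = _triplet_key(t)
    pmids = getattr(t, "supporting_pmids", None) or (t[3] if len(t) > 3 else ())
    return {base + (pmid,) for pmid in pmids}


def evaluate_triplets(
    predicted: Iterable, gold: Iterable, *, granularity: str = "triplet"
) -> EvalReport:
    """Score predicted against gold triplets.

    ``granularity="triplet"`` (default) counts unique
    (disease, gene, variant) triples; ``"mention"`` expands each triplet by
    its supporting PMIDs and counts (triplet, pmid) pairs instead.
    """
    if granularity == "triplet":
        pred_set = {_triplet_key(t) for t in predicted}
        gold_set = {_triplet_key(t) for t in gold}
    elif granularity == "mention":
        pred_set = set().union(*[_mention_keys(t) for t in predicted]) if predicted else set()
        gold_set = set().union(*[_mention_keys(t) for t in gold]) if gold else set()
    else:
        raise ValueError(f"unknown granularity {granularity!r}")

    tp = len(pred_set & gold_set)
    fp = len(pred_set - gold_set)
    fn = len(gold_set - pred_set)
    p_def, r_def = tp + fp > 0, tp + fn > 0
    precision = tp / (tp + fp) if p_def else 0.0
    recall = tp / (tp + fn) if r_def else 0.0
    f1 = f_measure(precision, recall)
    return EvalReport(
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        f1=f1,
        precision_defined=p_def,
        recall_defined=r_def,
        f1_defined=p_def and r_def and (precision + recall > 0),
    )


HIGH, MEDIUM, LOW = "high", "medium", "low"


def stratify_by_frequency(triplets: Iterable) -> dict[str, list]:
    """Partition triplets by supporting-PMID count: high > 10 PMIDs,
    medium 4-10 (inclusive), low < 4.  Exhaustive and disjoint."""
    strata: dict[str, list] = {HIGH: [], MEDIUM: [], LOW: []}
    for t in triplets:
        freq = t.frequency if hasattr(t, "frequency") else int(t[1])
        if freq > 10:
            strata[HIGH].append(t)
        elif freq >= 4:
            strata[MEDIUM].append(t)
        else:
            strata[LOW].append(t)
    return strata


def stratified_sample(
    strata: Mapping[str, Sequence],
    caps: Mapping[str, int] | Sequence[int] = (10, 15, 30),
    seed: int = 0,
) -> dict[str, list]:
    """Seeded uniform sampling without replacement, capped per stratum
    (defaults 10/15/30 for high/medium/low); strata smaller than their cap
    are taken whole."""
    if not isinstance(caps, Mapping):
        caps = dict(zip((HIGH, MEDIUM, LOW), caps))
    rng = random.Random(seed)
    out: dict[str, list] = {}
    for name in (HIGH, MEDIUM, LOW):
        members = list(strata.get(name, ()))
        cap = caps.get(name, len(members))
        if len(members) <= cap:
            out[name] = members
        else:
            out[name] = rng.sample(members, cap)
    return out


def precision_from_counts(correct: int, total: int) -> float:
    """Precision of a human-annotated sample: correct / total."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= correct <= total:
        raise ValueError("need 0 <= correct <= total")
    return correct / total


@dataclass(frozen=True)
class CoverageFlags:
    disease_concept: str
    gene_id: str
    variant_key: str
    pmid: str
    document_found: bool
    has_disease: bool
    has_gene: bool
    has_mutation: bool

    @property
    def has_triplet(self) -> bool:
        return self.has_disease and self.has_gene and self.has_mutation


def screen_coverage(
    triplet_pmid_pairs: Iterable[tuple[tuple[str, str, str], str]],
    corpus: Mapping[str, Document],
) -> list[CoverageFlags]:
    """Screen each (triplet, pmid) pair for concept-level presence of the
    disease, gene, and mutation in the referenced abstract.

    Documents missing from the corpus are flagged (all-absent), not errors.
    """
    rows = []
    for (disease, gene, variant), pmid in triplet_pmid_pairs:
        doc = corpus.get(pmid)
        if doc is None:
            rows.append(
                CoverageFlags(disease, gene, variant, pmid, False, False, False, False)
            )
            continue
        has_disease = any(
            m.concept_id == disease for m in doc.mentions_of(DISEASE)
        )
        has_gene = any(m.concept_id == gene for m in doc.mentions_of(GENE))
        has_mutation = any(
            mention_variant_key(m) == variant for m in doc.mentions_of(MUTATION)
        )
        rows.append(
            CoverageFlags(
                disease, gene, variant, pmid, True, has_disease, has_gene, has_mutation
            )
        )
    return rows


def coverage_by_triplet(rows: Sequence[CoverageFlags]) -> dict[tuple[str, str, str], dict]:
    """Aggregate per-PMID flags to any-PMID semantics per triplet."""
    agg: dict[tuple[str, str, str], dict] = {}
    for row in rows:
        key = (row.disease_concept, row.gene_id, row.variant_key)
        entry = agg.setdefault(
            key,
            {"has_disease": False, "has_gene": False, "has_mutation": False, "has_triplet": False},
        )
        entry["has_disease"] |= row.has_disease
        entry["has_gene"] |= row.has_gene
        entry["has_mutation"] |= row.has_mutation
        entry["has_triplet"] |= row.has_triplet
    return agg


def coverage_table(rows: Sequence[CoverageFlags]) -> dict[str, dict[str, int]]:
    """Per-disease aggregate counts in the layout of a missed-mutation
    screening table: rows analyzed, entity-presence counts, distinct PMIDs."""
    table: dict[str, dict[str, int]] = {}
    pmids: dict[str, set[str]] = {}
    for row in rows:
        d = table.setdefault(
            row.disease_concept,
            {
                "analyzed": 0,
                "had_disease": 0,
                "had_gene": 0,
                "had_mutation": 0,
                "had_triplet": 0,
                "n_pmids": 0,
            },
        )
        d["analyzed"] += 1
        d["had_disease"] += row.has_disease
        d["had_gene"] += row.has_gene
        d["had_mutation"] += row.has_mutation
        d["had_triplet"] += row.has_triplet
        pmids.setdefault(row.disease_concept, set()).add(row.pmid)
    for disease, d in table.items():
        d["n_pmids"] = len(pmids[disease])
    return table
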