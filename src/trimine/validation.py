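"""Protein-sequence validation of candidate genes.

The final gene for a (disease, variant) pair is chosen by walking the
candidate list in rank order and checking each gene's protein isoforms at
the stated mutation position: if the residue there equals either the
reference (wild) or the mutant amino acid, in any isoform, that gene is
selected.  When no candidate matches, the top-ranked candidate is kept and
flagged as a fallback.  Coordinates are 1-based on the sequences exactly as
given in the FASTA — no signal-peptide or isoform renumbering is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from Bio import SeqIO

from .variants import AMINO_ACIDS, ProteinSubstitution

__all__ = [
    "ProteinRecord",
    "Proteome",
    "ValidationResult",
    "MATCH_REFERENCE",
    "MATCH_MUTANT",
    "MATCH_FALLBACK",
    "load_proteome",
    "validate_position",
    "select_gene",
]

logger = logging.getLogger(__name__)

MATCH_REFERENCE = "reference"
MATCH_MUTANT = "mutant"
MATCH_FALLBACK = "fallback"


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    gene_id: str | None
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValueError(f"{self.accession}: residues outside alphabet: {bad}")


@dataclass
class Proteome:
    """Protein records cross-referenced with a gene -> accession map.

    Isoform order within a gene follows the mapping-file order so that
    selection is reproducible (the boolean outcome is order-independent)."""

    records: dict[str, ProteinRecord] = field(default_factory=dict)
    gene_to_accessions: dict[str, list[str]] = field(default_factory=dict)

    def isoforms(self, gene_id: str) -> list[ProteinRecord]:
        return [self.records[a] for a in self.gene_to_accessions.get(gene_id, [])]

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class ValidationResult:
    gene_id: str
    matched_accession: str | None
    match_type: str
    position_checked: int

    def __post_init__(self) -> None:
        if (self.match_type == MATCH_FALLBACK) != (self.matched_accession is None):
            raise ValueError("fallback results carry no matched accession")


def load_proteome(fasta_source, mapping_source) -> Proteome:
    """Load protein FASTA plus a gene→accession TSV (gene2refseq style).

    Mapping lines are ``gene_id<TAB>accession``; duplicate FASTA accessions
    are an error; accessions present in the map but missing from the FASTA
    are warned and dropped (the gene keeps its remaining isoforms).
    """
    gene_of: dict[str, str] = {}
    gene_order: dict[str, list[str]] = {}
    mapping_text = (
        Path(mapping_source).read_text(encoding="utf-8")
        if isinstance(mapping_source, (str, Path))
        else mapping_source.read()
    )
    for line in mapping_text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        gene_id, accession = line.split("\t")[:2]
        gene_of[accession] = gene_id
        gene_order.setdefault(gene_id, []).append(accession)

    records: dict[str, ProteinRecord] = {}
    for rec in SeqIO.parse(fasta_source, "fasta"):
        accession = rec.id.split()[0]
        if accession in records:
            raise ValueError(f"duplicate accession in FASTA: {accession}")
        gene_id = gene_of.get(accession)
        if gene_id is None:
            logger.warning("accession %s has no gene mapping", accession)
        records[accession] = ProteinRecord(
            accession=accession, gene_id=gene_id, sequence=str(rec.seq).upper()
        )

    gene_to_accessions: dict[str, list[str]] = {}
    for gene_id, accessions in gene_order.items():
        present = [a for a in accessions if a in records]
        for a in accessions:
            if a not in records:
                logger.warning(
                    "mapped accession %s (gene %s) absent from FASTA", a, gene_id
                )
        if present:
            gene_to_accessions[gene_id] = present
    return Proteome(records=records, gene_to_accessions=gene_to_accessions)


def validate_position(sequence: str, substitution: ProteinSubstitution) -> str | None:
    """Check one sequence at the substitution's 1-based position.

    Returns ``"reference"`` when the residue equals the wild amino acid,
    ``"mutant"`` when it equals the mutant, and None when the position is
    beyond the sequence or the residue matches neither.  Total function —
    never raises on in-vocabulary input.
    """
    pos = substitution.position
    if pos > len(sequence):
        return None
    residue = sequence[pos - 1]
    if residue == substitution.wild:
        return MATCH_REFERENCE
    if residue == substitution.mutant:
        return MATCH_MUTANT
    return None


def select_gene(
    candidates: Sequence, substitution: ProteinSubstitution, proteome: Proteome
) -> ValidationResult:
    """Walk candidates in rank order; first gene with any matching isoform
    wins.  With no match anywhere, the top-ranked candidate is returned
    flagged as a fallback.  Candidates may be GeneCandidate objects or bare
    gene-id strings."""
    gene_ids = [getattr(c, "gene_id", c) for c in candidates]
    if not gene_ids:
        raise ValueError("empty candidate list")
    for gene_id in gene_ids:
        for record in proteome.isoforms(gene_id):
            match = validate_position(record.sequence, substitution)
            if match is not None:
                return ValidationResult(
                    gene_id=gene_id,
                    matched_accession=record.accession,
                    match_type=match,
                    position_checked=substitution.position,
                )
    return ValidationResult(
        gene_id=gene_ids[0],
        matched_accession=None,
        match_type=MATCH_FALLBACK,
        position_checked=substitution.position,
    )
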