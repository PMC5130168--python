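"""Parsing and canonicalization of mutation surface strings.

Variant mentions in abstracts and web snippets come in many notations:
``V600E``, ``Glu298Asp``, ``p.V148I``, ``p.Val148Ile``, ``c.123A>G`` and so
on.  This module parses them into structured objects and provides a
canonical key so that mentions of the same variant deduplicate across
documents regardless of notation.  Cross-level normalization (projecting a
``c.`` DNA change onto protein coordinates) is deliberately not attempted:
two mentions at different sequence levels are never considered equivalent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Union

__all__ = [
    "ProteinSubstitution",
    "VariantMention",
    "ParseFailure",
    "parse_variant",
    "canonical_key",
    "equivalent",
    "render",
    "variant_key_for_surface",
    "AMINO_ACIDS",
]

#: One-letter residue vocabulary: the 20 standard amino acids plus the
#: ambiguity code X and the stop symbol * (nonsense mutations, e.g. W779X).
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY") | {"X", "*"}

_THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*", "Xaa": "X",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}

SUBSTITUTION = "substitution"
INSERTION = "insertion"
DELETION = "deletion"
FRAMESHIFT = "frameshift"
OTHER = "other"

PROTEIN = "protein"
DNA = "dna"
RNA = "rna"


@dataclass(frozen=True)
class ProteinSubstitution:
    """A point substitution in 1-based protein coordinates."""

    wild: str
    position: int
    mutant: str

    def __post_init__(self) -> None:
        if self.wild not in AMINO_ACIDS or self.mutant not in AMINO_ACIDS:
            raise ValueError(f"residue outside vocabulary: {self.wild}/{self.mutant}")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")

    @property
    def is_silent(self) -> bool:
        """True when the stated wild and mutant residues coincide."""
        return self.wild == self.mutant

    @property
    def is_nonsense(self) -> bool:
        return self.mutant in ("X", "*")


@dataclass(frozen=True)
class VariantMention:
    kind: str
    level: str
    payload: Union[ProteinSubstitution, str]

    def __post_init__(self) -> None:
        if self.kind == SUBSTITUTION and self.level == PROTEIN:
            if not isinstance(self.payload, ProteinSubstitution):
                raise ValueError("protein substitutions require a ProteinSubstitution payload")


@dataclass(frozen=True)
class ParseFailure:
    """Typed parse failure; carries the offending string. Never raised."""

    text: str
    reason: str

    def __bool__(self) -> bool:
        return False


_ONE_LETTER = re.compile(r"^(?:p\.)?([A-Z*])(\d+)([A-Z*])$")
_THREE_LETTER = re.compile(r"^(?:p\.)?([A-Za-z]{3})(\d+)([A-Za-z]{3}|\*|[Xx])$")
_NUC_SUB = re.compile(r"^([cgmr])\.(\d+)\s*([ACGTUacgtu])\s*>\s*([ACGTUacgtu])$")
_NUC_OTHER = re.compile(r"^([cgmr])\.\S+$")
_PROT_OTHER = re.compile(r"^p\.\S+$")


def _lookup3(code: str) -> str | None:
    if code in ("*",):
        return "*"
    if code.lower() == "x":
        return "X"
    return _THREE_TO_ONE.get(code.capitalize())


def parse_variant(text: str) -> VariantMention | ParseFailure:
    """Parse one variant surface string.

    Recognizes one-letter and three-letter protein substitutions with or
    without a ``p.`` prefix (including nonsense changes to X/*), ``c./g./m./r.``
    nucleotide substitutions, and classifies del/ins/dup/fs strings by kind.
    Unrecognized input yields a :class:`ParseFailure`, never an exception.
    One-letter codes must be uppercase (lowercase one-letter strings in free
    text are overwhelmingly false positives); three-letter codes are
    case-insensitive.
    """
    if not isinstance(text, str) or not text.strip():
        return ParseFailure(text=str(text), reason="empty input")
    s = text.strip()

    m = _ONE_LETTER.match(s)
    if m and m.group(1) in AMINO_ACIDS and m.group(3) in AMINO_ACIDS:
        pos = int(m.group(2))
        if pos >= 1:
            return VariantMention(
                SUBSTITUTION, PROTEIN, ProteinSubstitution(m.group(1), pos, m.group(3))
            )
        return ParseFailure(s, "position 0 is not a valid protein coordinate")

    m = _THREE_LETTER.match(s)
    if m:
        wild, mut = _lookup3(m.group(1)), _lookup3(m.group(3))
        pos = int(m.group(2))
        if wild and mut and pos >= 1:
            return VariantMention(SUBSTITUTION, PROTEIN, ProteinSubstitution(wild, pos, mut))

    m = _NUC_SUB.match(s)
    if m:
        level = RNA if m.group(1) == "r" else DNA
        payload = f"{m.group(1)}.{m.group(2)}{m.group(3).upper()}>{m.group(4).upper()}"
        return VariantMention(SUBSTITUTION, level, payload)

    m = _NUC_OTHER.match(s)
    if m:
        level = RNA if m.group(1) == "r" else DNA
        return VariantMention(_classify_kind(s), level, s)

    if _PROT_OTHER.match(s):
        return VariantMention(_classify_kind(s), PROTEIN, s)

    return ParseFailure(s, "unrecognized variant notation")


def _classify_kind(s: str) -> str:
    low = s.lower()
    if "fs" in low:
        return FRAMESHIFT
    if "delins" in low:
        return OTHER
    if "del" in low:
        return DELETION
    if "ins" in low or "dup" in low:
        return INSERTION
    return OTHER


def render(sub: ProteinSubstitution) -> str:
    """Canonical surface form of a protein substitution, e.g. ``p.V600E``."""
    return f"p.{sub.wild}{sub.position}{sub.mutant}"


def canonical_key(variant: VariantMention) -> str:
    """A notation-independent identity key.

    Protein substitutions render as ``p.<wild><pos><mutant>`` in one-letter
    code; everything else keys on its normalized payload string (which keeps
    its level prefix, so DNA and protein variants never collide).
    """
    if isinstance(variant, ParseFailure):
        raise TypeError("cannot key a parse failure")
    if variant.kind == SUBSTITUTION and variant.level == PROTEIN:
        return render(variant.payload)
    return str(variant.payload)


def equivalent(a: VariantMention, b: VariantMention) -> bool:
    """True iff the two parsed variants share a canonical key."""
    if isinstance(a, ParseFailure) or isinstance(b, ParseFailure):
        return False
    return canonical_key(a) == canonical_key(b)


def variant_key_for_surface(surface: str) -> str:
    """Canonical key for a raw mention: parsed key when the grammar matches,
    otherwise the stripped surface itself (so unparseable mentions still
    deduplicate on exact text)."""
    parsed = parse_variant(surface)
    if isinstance(parsed, ParseFailure):
        return surface.strip()
    return canonical_key(parsed)
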