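"""Read/write entity-annotated abstract corpora in the PubTator exchange format.

A PubTator block looks like::

    10561|t|BRAF mutations in melanoma.
    10561|a|The V600E substitution was frequent.
    10561<TAB>4<TAB>13<TAB>mutations<TAB>Mutation<TAB>...
    <blank line>

Annotation offsets are 0-based, half-open, and run over the concatenation
``title + " " + abstract`` (the common PubTator convention).  Concept
identifiers are namespaced in memory: ``gene:<entrez-id>`` for genes,
``mesh:<Dxxxxxx>`` for diseases, and the raw variant string for mutations.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

__all__ = [
    "Span",
    "Mention",
    "Document",
    "PubTatorError",
    "GENE",
    "DISEASE",
    "MUTATION",
    "OTHER",
    "read_pubtator",
    "write_pubtator",
    "sentence_split",
]

GENE = "GENE"
DISEASE = "DISEASE"
MUTATION = "MUTATION"
OTHER = "OTHER"

_TYPE_IN = {
    "gene": GENE,
    "disease": DISEASE,
    "mutation": MUTATION,
    "proteinmutation": MUTATION,
    "dnamutation": MUTATION,
    "snp": MUTATION,
}
_TYPE_OUT = {GENE: "Gene", DISEASE: "Disease", MUTATION: "Mutation", OTHER: "Other"}


class PubTatorError(ValueError):
    """Malformed PubTator input."""


@dataclass(frozen=True, order=True)
class Span:
    """0-based half-open character interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Mention:
    """One offset-anchored entity mention.

    ``concept_id`` is None when the tagger could not normalize the mention;
    no sentinel values are used.
    """

    span: Span
    surface: str
    entity_class: str
    concept_id: str | None = None


@dataclass
class Document:
    pmid: str
    title: str
    abstract: str
    mentions: list[Mention] = field(default_factory=list)

    @property
    def text(self) -> str:
        """Title and abstract joined by a single space (annotation coordinates)."""
        if not self.abstract:
            return self.title
        return self.title + " " + self.abstract

    def mentions_of(self, entity_class: str) -> list[Mention]:
        return [m for m in self.mentions if m.entity_class == entity_class]

    def validate(self) -> None:
        """Raise if any mention violates the surface-slice invariant."""
        text = self.text
        for m in self.mentions:
            if m.span.end > len(text):
                raise PubTatorError(
                    f"{self.pmid}: span {m.span} beyond document length {len(text)}"
                )
            if text[m.span.start : m.span.end] != m.surface:
                raise PubTatorError(
                    f"{self.pmid}: surface {m.surface!r} != slice "
                    f"{text[m.span.start:m.span.end]!r} at {m.span}"
                )


def _normalize_concept(entity_class: str, raw: str | None) -> str | None:
    if raw is None or raw == "" or raw == "-":
        return None
    if entity_class == GENE:
        if raw.startswith("gene:"):
            return raw
        if raw.isdigit():
            return f"gene:{raw}"
        return raw
    if entity_class == DISEASE:
        low = raw.lower()
        if low.startswith("mesh:"):
            return "mesh:" + raw.split(":", 1)[1]
        if re.fullmatch(r"[CD]\d{6}", raw):
            return f"mesh:{raw}"
        return raw
    return raw


def _open(source) -> TextIO:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8")
    if isinstance(source, bytes):
        return io.StringIO(source.decode("utf-8"))
    return source


def read_pubtator(source, *, strict: bool = False) -> list[Document]:
    """Parse a PubTator stream, path, or string buffer into Documents.

    Parameters
    ----------
    source:
        File path, open text stream, or an ``io.StringIO``.
    strict:
        When True, an annotation whose surface does not match its offset
        slice (or that straddles the title/abstract boundary) raises
        :class:`PubTatorError`.  The default mirrors real-world exports:
        warn and drop the offending annotation.
    """
    stream = _open(source)
    blocks: list[list[str]] = [[]]
    for raw_line in stream:
        line = raw_line.rstrip("\n")
        if line.strip() == "":
            if blocks[-1]:
                blocks.append([])
            continue
        blocks[-1].append(line)
    if not blocks[-1]:
        blocks.pop()

    documents = []
    for block in blocks:
        documents.append(_parse_block(block, strict=strict))
    pmids = [d.pmid for d in documents]
    if len(set(pmids)) != len(pmids):
        raise PubTatorError("duplicate pmid within corpus")
    return documents


def _parse_block(lines: list[str], *, strict: bool) -> Document:
    title_m = re.match(r"^([^|]+)\|t\|(.*)$", lines[0]) if lines else None
    if title_m is None:
        raise PubTatorError(f"block does not start with a title line: {lines[:1]}")
    abstract_m = re.match(r"^([^|]+)\|a\|(.*)$", lines[1]) if len(lines) > 1 else None
    if abstract_m is None:
        raise PubTatorError(f"block for {title_m.group(1)} has no abstract line")
    pmid = title_m.group(1)
    if abstract_m.group(1) != pmid:
        raise PubTatorError(f"pmid mismatch between title and abstract lines ({pmid})")
    doc = Document(pmid=pmid, title=title_m.group(2), abstract=abstract_m.group(2))
    text = doc.text
    boundary = len(doc.title)

    mentions = []
    for line in lines[2:]:
        fields = line.split("\t")
        if len(fields) not in (5, 6) or fields[0] != pmid:
            _complain(f"{pmid}: unparseable annotation line {line!r}", strict)
            continue
        try:
            start, end = int(fields[1]), int(fields[2])
            span = Span(start, end)
        except ValueError:
            _complain(f"{pmid}: bad offsets in {line!r}", strict)
            continue
        surface = fields[3]
        entity_class = _TYPE_IN.get(fields[4].lower(), OTHER)
        concept = _normalize_concept(entity_class, fields[5] if len(fields) == 6 else None)
        if end > len(text) or text[start:end] != surface:
            _complain(
                f"{pmid}: surface {surface!r} does not match slice at [{start},{end})",
                strict,
            )
            continue
        if doc.abstract and start < boundary < end:
            # title/abstract-straddling annotations are treated as invalid input
            _complain(f"{pmid}: annotation straddles title/abstract boundary", strict)
            continue
        mentions.append(Mention(span, surface, entity_class, concept))
    doc.mentions = sorted(mentions, key=lambda m: (m.span.start, m.span.end))
    return doc


def _complain(message: str, strict: bool) -> None:
    if strict:
        raise PubTatorError(message)
    warnings.warn(message, stacklevel=3)


def write_pubtator(documents: Iterable[Document], stream: TextIO | None = None) -> str:
    """Serialize documents to the PubTator dialect read by :func:`read_pubtator`.

    Returns the serialized text; also writes it to ``stream`` when given.
    Output is canonical, so read-write round-trips are byte-identical for
    corpora produced by this writer.
    """
    out = io.StringIO()
    for doc in documents:
        out.write(f"{doc.pmid}|t|{doc.title}\n")
        out.write(f"{doc.pmid}|a|{doc.abstract}\n")
        for m in doc.mentions:
            fields = [
                doc.pmid,
                str(m.span.start),
                str(m.span.end),
                m.surface,
                _TYPE_OUT[m.entity_class],
            ]
            if m.concept_id is not None:
                fields.append(m.concept_id)
            out.write("\t".join(fields) + "\n")
        out.write("\n")
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


# ---------------------------------------------------------------------------
# Sentence splitting
# ---------------------------------------------------------------------------

# Tokens (sans final period) after which a sentence terminator is ignored.
_ABBREVIATIONS = {
    "i.e",
    "e.g",
    "al",  # "et al."
    "vs",
    "cf",
    "ca",
    "fig",
    "figs",
    "dr",
    "mr",
    "mrs",
    "approx",
    "resp",
    "no",
    "spp",
}

_TERMINATOR = re.compile(r"[.!?]+(?=\s|$)")


def _split_text(text: str, offset: int) -> list[Span]:
    spans: list[Span] = []
    cursor = 0
    for match in _TERMINATOR.finditer(text):
        before = text[cursor : match.start()]
        tail = re.search(r"[\w.]+$", before)
        word = tail.group(0).rstrip(".").lower() if tail else ""
        if word in _ABBREVIATIONS:
            continue
        rest = text[match.end() :].lstrip()
        if rest and not (rest[0].isupper() or rest[0].isdigit() or rest[0] in "(\"'"):
            continue
        spans.append(_trimmed(text, cursor, match.end(), offset))
        cursor = match.end()
    if text[cursor:].strip():
        spans.append(_trimmed(text, cursor, len(text), offset))
    return [s for s in spans if s is not None]


def _trimmed(text: str, start: int, end: int, offset: int) -> Span | None:
    chunk = text[start:end]
    lead = len(chunk) - len(chunk.lstrip())
    trail = len(chunk) - len(chunk.rstrip())
    if start + lead >= end - trail:
        return None
    return Span(offset + start + lead, offset + end - trail)


def sentence_split(document: Document) -> list[Span]:
    """Deterministic rule-based sentence spans over ``document.text``.

    The title is always its own sentence boundary; abbreviation periods
    (``i.e.``, ``et al.`` ...) do not split.  Returned spans are trimmed of
    surrounding whitespace, ordered, and non-overlapping.
    """
    spans = _split_text(document.title, 0)
    if document.abstract:
        spans.extend(_split_text(document.abstract, len(document.title) + 1))
    return spans
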