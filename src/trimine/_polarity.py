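"""Deterministic lexicon-based sentence polarity scoring.

Scores the association-affirming vs. association-negating tone of a
sentence on [-1, 1].  A tiny domain lexicon is enough here: the feature
only needs to separate "was significantly associated with" from "showed no
association with" style statements.  A negator flips the polarity of the
next few sentiment-bearing tokens.
"""

from __future__ import annotations

import re

__all__ = ["sentence_polarity"]

_POSITIVE = frozenset(
    """
    associated association significant significantly linked increased
    elevated causative pathogenic deleterious confirmed demonstrated
    susceptibility predisposes predisposing contributes correlated risk
    implicated enriched
    """.split()
)

_NEGATIVE = frozenset(
    """
    unchanged absent benign insignificant unaffected unrelated excluded
    failed lack lacking unlikely nonsignificant neutral
    """.split()
)

_NEGATORS = frozenset("no not without neither nor never none".split())

# A negator inverts sentiment tokens within this many following tokens.
_NEGATION_WINDOW = 3

_WORD = re.compile(r"[A-Za-z']+")


def sentence_polarity(text: str) -> float:
    """Polarity of one sentence in [-1, 1]; 0 when no cue words occur."""
    tokens = [t.lower() for t in _WORD.findall(text)]
    score = 0
    hits = 0
    negate_until = -1
    for i, tok in enumerate(tokens):
        if tok in _NEGATORS:
            negate_until = i + _NEGATION_WINDOW
            continue
        value = 0
        if tok in _POSITIVE:
            value = 1
        elif tok in _NEGATIVE:
            value = -1
        if value:
            if i <= negate_until:
                value = -value
            score += value
            hits += 1
    if hits == 0:
        return 0.0
    return score / hits
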