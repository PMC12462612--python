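"""Iterated Lovins-style suffix stemmer.

A longest-match suffix stripper in the Lovins tradition: at each pass the
longest listed ending whose removal leaves a stem of at least
``_MIN_STEM`` characters is removed, a terminal doubled consonant is then
undoubled, and passes repeat until the token is stable (the "iterated"
behaviour).  The ending inventory is a curated subset chosen for biomedical
method prose; it is not a transcription of the original 294-ending table.

Stemming is applied to query keywords and sentence tokens symmetrically, so
what matters for matching is that related inflections collapse to the same
stem ("classified"/"classify" → "classif", "statistics"/"statistical" →
"statist"), not that the stem is a dictionary word.
"""

from __future__ import annotations

from functools import lru_cache

_MIN_STEM = 2

# Longest first; ties in length resolved by list order.
_ENDINGS: tuple[str, ...] = tuple(
    sorted(
        [
            "izations",
            "ization",
            "ousness",
            "fulness",
            "iveness",
            "ibility",
            "ability",
            "ational",
            "ations",
            "ation",
            "ements",
            "ement",
            "ically",
            "ities",
            "ingly",
            "ences",
            "ances",
            "ively",
            "ments",
            "iser",
            "izer",
            "izes",
            "ized",
            "ize",
            "ence",
            "ance",
            "ment",
            "ness",
            "ions",
            "ical",
            "ions",
            "ials",
            "ally",
            "ties",
            "ied",
            "ies",
            "ion",
            "ial",
            "ing",
            "ers",
            "ous",
            "ful",
            "ity",
            "ive",
            "ism",
            "est",
            "ic",
            "al",
            "ed",
            "er",
            "ly",
            "es",
            "s",
            "y",
        ],
        key=len,
        reverse=True,
    )
)

_CONSONANTS = set("bcdfghjklmnpqrstvwxz")


def _strip_once(token: str) -> str:
    for ending in _ENDINGS:
        if token.endswith(ending) and len(token) - len(ending) >= _MIN_STEM:
            token = token[: -len(ending)]
            break
    # undouble a terminal consonant pair left by stripping ("runn" -> "run")
    if len(token) >= 3 and token[-1] == token[-2] and token[-1] in _CONSONANTS:
        token = token[:-1]
    return token


@lru_cache(maxsize=65536)
def stem(token: str) -> str:
    """Stem one already-lowercased token to a fixed point."""
    current = token
    while True:
        nxt = _strip_once(current)
        if nxt == current:
            return current
        current = nxt


def stem_tokens(tokens: list[str]) -> list[str]:
    return [stem(t) for t in tokens]
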