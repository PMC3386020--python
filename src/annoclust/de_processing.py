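"""Normalisation of free-text protein descriptions (DEs).

A DE is the one-line functional description carried in the header of a
database sequence ("DNA gyrase subunit A", "hypothetical protein", ...).
Before any scoring or clustering, DEs are lower-cased, tokenised, and
stripped of words that carry no functional signal: a fixed list of
uninformative terms ("hypothetical", "putative", "protein", ...) and, for
queries with at least ten hits, words that occur only once across the
whole hit list.  A hit whose description becomes empty is dropped from
the match list entirely.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .blast_io import BlastHit

__all__ = [
    "StopList",
    "ProcessedDe",
    "tokenize",
    "trim_ec_codes",
    "remove_uninformative",
    "remove_infrequent",
    "drop_empty",
    "process_query_hits",
]

#: punctuation stripped from token edges (interior hyphens are preserved,
#: so "phospho-beta-glycosidase" stays one token)
_EDGE_PUNCT = ",.;:()[]'\""

#: Enzyme Commission codes as printed in sequence databases: an "EC"
#: marker and/or a dotted four-field number where fields may be digits,
#: "-" or "n", optionally parenthesised.  "EC 5.99.1.3", "(EC 1.-.-.-)",
#: "3.2.1.n3" all match; chemical locants like "1,4-dihydroxy" do not.
_EC_PATTERN = re.compile(
    r"""
    \(?\s*\bEC[:\s]*(?:[0-9n-]+\.){0,3}[0-9n-]+\s*\)?   # EC marker + number
    | \(?\s*\b(?:[0-9n-]+\.){3}[0-9n-]+\s*\)?           # bare d.d.d.d
    """,
    re.IGNORECASE | re.VERBOSE,
)


@dataclass(frozen=True)
class StopList:
    """The shipped list of uninformative description words.

    The list is stored exactly as shipped (21 entries, one duplicate,
    one two-word phrase); matching uses the deduplicated single-word set
    plus the phrase matched as a unit.
    """

    entries: tuple[str, ...]

    @property
    def words(self) -> frozenset[str]:
        """Deduplicated single-word stop set (phrases excluded)."""
        return frozenset(e for e in self.entries if " " not in e)

    @property
    def phrases(self) -> tuple[tuple[str, ...], ...]:
        """Multi-word entries, as token tuples."""
        return tuple(tuple(e.split()) for e in self.entries if " " in e)

    def __contains__(self, token: str) -> bool:
        return token.lower() in self.words

    def only_uninformative(self, tokens: Sequence[str]) -> bool:
        """True if every token is uninformative (stop word, or part of a
        stop phrase occurring in the token sequence)."""
        return len(remove_uninformative(tokens, self)) == 0

    @classmethod
    def from_lines(cls, lines: Iterable[str]) -> "StopList":
        entries = tuple(
            ln.strip().lower() for ln in lines if ln.strip() and not ln.startswith("#")
        )
        return cls(entries)

    @classmethod
    def from_file(cls, path: str | Path) -> "StopList":
        with open(path, encoding="utf-8") as fh:
            return cls.from_lines(fh)

    @classmethod
    def default(cls) -> "StopList":
        text = resources.files("annoclust.data").joinpath("stopwords.txt").read_text()
        return cls.from_lines(text.splitlines())


_DEFAULT_STOP: StopList | None = None


def default_stoplist() -> StopList:
    global _DEFAULT_STOP
    if _DEFAULT_STOP is None:
        _DEFAULT_STOP = StopList.default()
    return _DEFAULT_STOP


@dataclass(frozen=True)
class ProcessedDe:
    """A normalised description: ordered lowercase tokens plus provenance."""

    tokens: tuple[str, ...]
    source_hit: str = ""

    @property
    def text(self) -> str:
        return " ".join(self.tokens)

    def __bool__(self) -> bool:
        return bool(self.tokens)


def tokenize(de_text: str) -> list[str]:
    """Lowercase, split on whitespace, strip edge punctuation, drop empties."""
    out = []
    for raw in de_text.lower().split():
        tok = raw.strip(_EDGE_PUNCT)
        if tok:
            out.append(tok)
    return out


def trim_ec_codes(de_text: str) -> str:
    """Remove Enzyme Commission codes and collapse the surrounding whitespace.

    Different database releases print EC numbers inconsistently, so they
    are stripped before any annotation-similarity comparison.
    """
    return " ".join(_EC_PATTERN.sub(" ", de_text).split())


def remove_uninformative(tokens: Sequence[str], stop: StopList | None = None) -> list[str]:
    """Drop stop-set tokens; stop phrases ("similar to") are removed as units."""
    stop = stop or default_stoplist()
    words = stop.words
    phrases = stop.phrases
    toks = list(tokens)
    # phrase removal first so that phrase members not in the word set
    # ("similar", "to") are only removed when they form the phrase
    for phrase in phrases:
        n = len(phrase)
        i = 0
        kept: list[str] = []
        while i < len(toks):
            if tuple(toks[i : i + n]) == phrase:
                i += n
            else:
                kept.append(toks[i])
                i += 1
        toks = kept
    return [t for t in toks if t not in words]


def remove_infrequent(
    de_lists: Sequence[Sequence[str]], min_hits: int = 10
) -> list[list[str]]:
    """Apply the infrequent-word rule across all DEs of one query.

    A word is infrequent when it occurs exactly once across the DEs of
    the whole hit list.  With ``min_hits`` or more hits, infrequent words
    are removed — but only from DEs that also contain at least one
    frequent word, so a description consisting solely of rare words is
    left intact.  With fewer hits the rule is not applied at all.
    """
    lists = [list(de) for de in de_lists]
    if len(lists) < min_hits:
        return lists
    counts: Counter[str] = Counter()
    for de in lists:
        counts.update(de)
    out = []
    for de in lists:
        if any(counts[w] >= 2 for w in de):
            out.append([w for w in de if counts[w] >= 2])
        else:
            out.append(de)
    return out


def drop_empty(
    pairs: Sequence[tuple[BlastHit, ProcessedDe]]
) -> list[tuple[BlastHit, ProcessedDe]]:
    """Remove hits whose processed description has no tokens left."""
    return [(h, d) for h, d in pairs if d.tokens]


def process_query_hits(
    hits: Sequence[BlastHit],
    stop: StopList | None = None,
    min_hits_for_infrequent: int = 10,
) -> list[tuple[BlastHit, ProcessedDe]]:
    """Full DE-processing pipeline for the hit list of one query.

    Tokenises each raw description, removes uninformative words, applies
    the infrequent-word rule across the hit list, and drops hits whose
    description ends up empty.  Hit order is preserved.
    """
    stop = stop or default_stoplist()
    token_lists = [remove_uninformative(tokenize(h.raw_de), stop) for h in hits]
    token_lists = remove_infrequent(token_lists, min_hits=min_hits_for_infrequent)
    pairs = [
        (h, ProcessedDe(tuple(toks), source_hit=h.subject_id))
        for h, toks in zip(hits, token_lists)
    ]
    return drop_empty(pairs)
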