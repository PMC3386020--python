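"""Modified Levenshtein distance (mLD) between annotation strings.

Plain edit distance penalises word-order changes, so "DNA gyrase A
subunit" and "subunit A DNA gyrase" would look dissimilar even though
they describe the same function.  The mLD removes that artefact: both
annotations are deconstructed into word and consecutive word-pair
elements, best-matching cross elements are greedily paired by alignment
distance and consumed together with every element sharing their words,
and the recorded distances are summed and normalised by the longer
annotation's character length.  The result lies in [0, 1]: 0 means the
annotations share their words exactly (in any order), 1 means no textual
resemblance (or one side carries no informative words at all).

The element-level distance derives from a global alignment scored
+2 / -1 / -1 (match / substitution / gap); the returned count is the
number of non-match columns, minimised over all maximum-score
alignments, which keeps the count symmetric and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from .de_processing import StopList, default_stoplist, tokenize, trim_ec_codes

__all__ = [
    "levenshtein_aligned",
    "normalize_for_mld",
    "NormalizedAnnotation",
    "MldResult",
    "mld",
    "mld_distance",
]

_GAP = -1
_SUB = -1
_MATCH = 2
# packed DP value: score * _PACK - nonmatch_count; score dominates, then
# fewer non-match columns.  _PACK exceeds any reachable non-match count.
_PACK = 1 << 20


@lru_cache(maxsize=1 << 17)
def levenshtein_aligned(a: str, b: str) -> int:
    """Non-match column count of the best (+2,-1,-1) global alignment.

    Among all maximum-score alignments the one with the fewest
    substitution/gap columns is chosen, so identical strings give 0 and
    ``levenshtein_aligned(x, "") == len(x)``.
    """
    na, nb = len(a), len(b)
    if na == 0 or nb == 0:
        return na + nb
    # row[j] = packed (score, -nonmatch) for prefix alignment
    row = [-j * _PACK - j for j in range(nb + 1)]
    for i in range(1, na + 1):
        prev_diag = row[0]
        row[0] = -i * _PACK - i
        ca = a[i - 1]
        for j in range(1, nb + 1):
            up = row[j]
            left = row[j - 1]
            if ca == b[j - 1]:
                diag = prev_diag + _MATCH * _PACK
            else:
                diag = prev_diag + _SUB * _PACK - 1
            best = diag
            cand = up + _GAP * _PACK - 1
            if cand > best:
                best = cand
            cand = left + _GAP * _PACK - 1
            if cand > best:
                best = cand
            prev_diag = up
            row[j] = best
    packed = row[nb]
    # recover the non-match count: packed = score*_PACK - nm with 0 <= nm < _PACK
    return -packed % _PACK


@dataclass(frozen=True)
class NormalizedAnnotation:
    """An annotation prepared for mLD: EC codes trimmed, lowercased,
    tokenised and rejoined with single spaces."""

    text: str
    tokens: tuple[str, ...]
    effectively_empty: bool

    def __len__(self) -> int:
        return len(self.text)


def normalize_for_mld(annotation: str, stop: StopList | None = None) -> NormalizedAnnotation:
    """Normalise an annotation and flag it when it carries no information.

    The emptiness test uses the uninformative-word stop set, but the
    surviving tokens themselves retain stop words: only *wholly*
    uninformative (or empty) annotations are flagged, and the distance
    is then defined as 1.
    """
    stop = stop or default_stoplist()
    tokens = tuple(tokenize(trim_ec_codes(annotation)))
    empty = not tokens or stop.only_uninformative(tokens)
    return NormalizedAnnotation(
        text=" ".join(tokens), tokens=tokens, effectively_empty=empty
    )


@dataclass(frozen=True)
class MldResult:
    distance: float
    recorded: tuple[tuple[str, str, int], ...]
    norm_length: int


def _elements(tokens: tuple[str, ...]) -> list[str]:
    """Word elements plus consecutive word-pair elements (n + n-1 of them)."""
    els = list(tokens)
    els += [tokens[i] + " " + tokens[i + 1] for i in range(len(tokens) - 1)]
    return els


def mld(
    X: str,
    Y: str,
    stop: StopList | None = None,
    score_remaining_pairs: bool = False,
) -> MldResult:
    """Modified Levenshtein distance between annotations ``X`` and ``Y``.

    Greedy pairing: the cross pair of elements with the smallest aligned
    distance is recorded and removed together with every element (on
    either side) sharing a word with it; ties break on smallest combined
    length, then lexicographically, which makes the metric symmetric.
    When one side is exhausted, each remaining word element of the other
    side is scored against the empty string (pair elements too when
    ``score_remaining_pairs``; off by default to avoid counting each
    character twice).  The distance is the recorded sum divided by the
    character length of the longer normalised annotation, capped at 1.
    """
    nx_, ny_ = normalize_for_mld(X, stop), normalize_for_mld(Y, stop)
    if nx_.effectively_empty or ny_.effectively_empty:
        return MldResult(1.0, (), max(len(nx_), len(ny_)))
    ex, ey = _elements(nx_.tokens), _elements(ny_.tokens)
    recorded: list[tuple[str, str, int]] = []
    total = 0
    while ex and ey:
        best_key = None
        best_pair = None
        for a in ex:
            for b in ey:
                d = levenshtein_aligned(a, b)
                # unordered lexicographic tie-break keeps mld(X,Y) == mld(Y,X)
                key = (d, len(a) + len(b)) + ((a, b) if a <= b else (b, a))
                if best_key is None or key < best_key:
                    best_key = key
                    best_pair = (a, b)
        a, b = best_pair
        d = best_key[0]
        recorded.append((a, b, d))
        total += d
        used = set(a.split()) | set(b.split())
        ex = [e for e in ex if used.isdisjoint(e.split())]
        ey = [e for e in ey if used.isdisjoint(e.split())]
    for rem in ex or ey:
        if score_remaining_pairs or " " not in rem:
            d = len(rem)
            recorded.append((rem, "", d))
            total += d
    norm = max(len(nx_), len(ny_))
    return MldResult(min(1.0, total / norm), tuple(recorded), norm)


def mld_distance(
    X: str,
    Y: str,
    stop: StopList | None = None,
    score_remaining_pairs: bool = False,
) -> float:
    """Convenience wrapper returning only the distance."""
    return mld(X, Y, stop, score_remaining_pairs).distance
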