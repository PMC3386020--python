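"""Reading BLAST tabular output and sequence-level hit filtering.

The expected input is BLAST's tab-separated output (``-outfmt 6`` with a
named column set).  The default dialect is::

    qseqid sseqid pident length evalue bitscore slen qlen stitle

where ``stitle`` holds the subject description line (the DE).  Column
order is configurable; an optional ``sdate`` column carries the subject
entry's creation date (ISO-8601) for benchmark-style circular-reference
filtering.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import ConfigurationError, ParseError

__all__ = [
    "BlastHit",
    "FilterPolicy",
    "DEFAULT_COLUMNS",
    "FIXTURE_COLUMNS",
    "read_blast_tabular",
    "extract_de",
    "read_fasta_des",
    "filter_hits",
]

DEFAULT_COLUMNS: tuple[str, ...] = (
    "qseqid", "sseqid", "pident", "length", "evalue", "bitscore",
    "slen", "qlen", "stitle",
)

#: dialect written by the synthetic-data generator (adds the subject
#: creation date used by the evaluation harness)
FIXTURE_COLUMNS: tuple[str, ...] = (
    "qseqid", "sseqid", "pident", "length", "evalue", "bitscore",
    "slen", "qlen", "sdate", "stitle",
)

_REQUIRED = ("qseqid", "sseqid", "pident", "length", "evalue", "bitscore", "slen", "qlen")


@dataclass(frozen=True)
class BlastHit:
    """One query-subject BLAST match.

    ``bit_score`` is the weighting currency of the whole scoring scheme;
    ``raw_de`` is the subject's unprocessed description line.
    """

    query_id: str
    subject_id: str
    bit_score: float
    percent_identity: float
    alignment_length: int
    subject_length: int
    query_length: int
    e_value: float = 0.0
    raw_de: str = ""
    subject_creation_date: _dt.date | None = None

    def coverage(self, side: str = "subject") -> float:
        """Alignment coverage (%) over the chosen sequence.

        Computed as 100 x alignment_length / sequence length; tabular
        BLAST output does not report the ungapped aligned span, so the
        alignment length (gapped columns) is the numerator.
        """
        if side == "subject":
            return 100.0 * self.alignment_length / self.subject_length
        if side == "query":
            return 100.0 * self.alignment_length / self.query_length
        raise ConfigurationError(f"unknown coverage side: {side!r}")


@dataclass(frozen=True)
class FilterPolicy:
    """Sequence-level hit filters.

    Defaults follow the tool's standard settings: alignments with bit
    score below 50 or length below 30 are removed (equality survives),
    only the best-scoring occurrence of each query-subject pair is kept,
    and matches of the query to itself are discarded.  Identity/coverage
    thresholds default to 0 (off); the genome preset raises them to
    40 / 50 (subject side).
    """

    min_bit_score: float = 50.0
    min_alignment_length: int = 30
    min_identity: float = 0.0
    min_coverage: float = 0.0
    coverage_side: str = "subject"
    min_relative_bit_score: float | None = None
    drop_self_hits: bool = True
    keep_best_pair_only: bool = True

    def __post_init__(self):
        if self.min_relative_bit_score is not None and not (
            0.0 <= self.min_relative_bit_score <= 1.0
        ):
            raise ConfigurationError("min_relative_bit_score must lie in [0, 1]")
        if min(self.min_bit_score, self.min_identity, self.min_coverage) < 0:
            raise ConfigurationError("filter thresholds must be non-negative")

    @classmethod
    def genome(cls, **overrides) -> "FilterPolicy":
        """Preset for whole-genome annotation runs (identity 40, subject coverage 50)."""
        base = cls(min_identity=40.0, min_coverage=50.0, coverage_side="subject")
        return replace(base, **overrides) if overrides else base

    @classmethod
    def permissive(cls) -> "FilterPolicy":
        """All thresholds off; flags off (output equals input)."""
        return cls(
            min_bit_score=0.0, min_alignment_length=0,
            drop_self_hits=False, keep_best_pair_only=False,
        )


def extract_de(fasta_header: str) -> str:
    """Description text of a FASTA header line.

    Strips a leading '>', drops the identifier (first whitespace-separated
    field) and truncates trailing UniProt-style field tags (``OS=``,
    ``OX=``, ``GN=``, ``PE=``, ``SV=`` blocks).
    """
    header = fasta_header.lstrip(">").strip()
    parts = header.split(None, 1)
    if len(parts) < 2:
        return ""
    de = parts[1]
    for tag in (" OS=", " OX=", " GN=", " PE=", " SV="):
        idx = de.find(tag)
        if idx >= 0:
            de = de[:idx]
    return de.strip()


def read_fasta_des(path: str | Path) -> dict[str, str]:
    """Map sequence id -> description for every record of a FASTA file.

    Useful as the ``de_by_subject`` side file of :func:`read_blast_tabular`
    when the tabular output lacks a ``stitle`` column.
    """
    return {
        rec.id: extract_de(rec.description) for rec in SeqIO.parse(str(path), "fasta")
    }


def _parse_date(token: str, path: str, line_no: int) -> _dt.date | None:
    token = token.strip()
    if not token or token in {"-", "NA", "na", "none"}:
        return None
    try:
        return _dt.date.fromisoformat(token)
    except ValueError as exc:
        raise ParseError(f"bad ISO date {token!r}", path, line_no) from exc


def read_blast_tabular(
    path: str | Path,
    columns: Sequence[str] = DEFAULT_COLUMNS,
    de_by_subject: dict[str, str] | None = None,
) -> list[BlastHit]:
    """Parse a tab-separated BLAST result file into hit records.

    ``columns`` names every column in file order (a superset of the
    required numeric fields).  The description is taken from a ``stitle``
    column when present, otherwise looked up in ``de_by_subject`` (e.g.
    built from a FASTA side file with :func:`extract_de`).

    Raises :class:`ParseError` naming the line for malformed rows.
    """
    columns = tuple(columns)
    for name in _REQUIRED:
        if name not in columns:
            raise ConfigurationError(f"column specification lacks {name!r}")
    idx = {name: i for i, name in enumerate(columns)}
    has_title = "stitle" in idx
    has_date = "sdate" in idx
    path = str(path)
    hits: list[BlastHit] = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            # stitle may contain spaces but not tabs; split on tabs only,
            # allowing the title column (if last) to absorb the remainder
            fields = line.split("\t", len(columns) - 1)
            if len(fields) < len(columns):
                raise ParseError(
                    f"expected {len(columns)} columns, found {len(fields)}",
                    path, line_no,
                )
            try:
                bit = float(fields[idx["bitscore"]])
            except ValueError as exc:
                raise ParseError(
                    f"non-numeric bit score {fields[idx['bitscore']]!r}",
                    path, line_no,
                ) from exc
            try:
                hit = BlastHit(
                    query_id=fields[idx["qseqid"]],
                    subject_id=fields[idx["sseqid"]],
                    bit_score=bit,
                    percent_identity=float(fields[idx["pident"]]),
                    alignment_length=int(fields[idx["length"]]),
                    subject_length=int(fields[idx["slen"]]),
                    query_length=int(fields[idx["qlen"]]),
                    e_value=float(fields[idx["evalue"]]),
                    raw_de=fields[idx["stitle"]] if has_title else "",
                    subject_creation_date=(
                        _parse_date(fields[idx["sdate"]], path, line_no)
                        if has_date else None
                    ),
                )
            except ValueError as exc:
                raise ParseError(f"malformed numeric field ({exc})", path, line_no) from exc
            if not has_title and de_by_subject is not None:
                hit = replace(hit, raw_de=de_by_subject.get(hit.subject_id, ""))
            hits.append(hit)
    return hits


def filter_hits(
    hits: Iterable[BlastHit],
    policy: FilterPolicy = FilterPolicy(),
    self_bit_score: float | None = None,
) -> list[BlastHit]:
    """Apply every enabled threshold and flag of ``policy``; order preserved.

    Threshold semantics are strict removal: a hit is removed when its
    value is *smaller than* the threshold, so a hit exactly at the
    threshold survives.  With ``keep_best_pair_only`` only the
    highest-bit-score row of each query-subject pair is retained (first
    occurrence wins ties).
    """
    if policy.min_relative_bit_score is not None and self_bit_score is None:
        raise ConfigurationError(
            "relative bit-score filtering requires the query's self bit score"
        )
    survivors: list[BlastHit] = []
    for h in hits:
        if h.bit_score < policy.min_bit_score:
            continue
        if h.alignment_length < policy.min_alignment_length:
            continue
        if h.percent_identity < policy.min_identity:
            continue
        if policy.min_coverage > 0 and h.coverage(policy.coverage_side) < policy.min_coverage:
            continue
        if (
            policy.min_relative_bit_score is not None
            and h.bit_score / self_bit_score < policy.min_relative_bit_score
        ):
            continue
        if policy.drop_self_hits and h.subject_id == h.query_id:
            continue
        survivors.append(h)
    if policy.keep_best_pair_only:
        best: dict[tuple[str, str], BlastHit] = {}
        for h in survivors:
            key = (h.query_id, h.subject_id)
            if key not in best or h.bit_score > best[key].bit_score:
                best[key] = h
        chosen = {id(h) for h in best.values()}
        survivors = [h for h in survivors if id(h) in chosen]
    return survivors
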