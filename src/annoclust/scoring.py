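"""Bit-score-weighted scoring and ranking of candidate descriptions.

Within a cluster j, a word i scores

    w_ij = sum of bit scores of cluster-j hits whose DE contains i
           -----------------------------------------------------
           sum of bit scores of ALL surviving hits of the query

and a full description k scores analogously

    S_k  = sum of bit scores of hits described exactly by k
           ------------------------------------------------
           sum of bit scores of all hits.

Normalising by the all-hit total (not the within-cluster total) keeps
descriptions in different clusters from tying.  The final score of a
description averages its word support and sentence support; the default
takes the mean of (i) the mean per-word score and (ii) S_k, an
alternative "flat" variant averages the word scores and S_k as a single
pool.  Both lie in (0, 1], and a description reaches 1 exactly when
every hit of the query carries it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .blast_io import BlastHit
from .clustering import HitCluster
from .errors import ConfigurationError

__all__ = [
    "ScoredDescription",
    "ScoredCluster",
    "AnnotationReport",
    "word_score",
    "sentence_score",
    "final_score",
    "rank",
]


@dataclass(frozen=True)
class ScoredDescription:
    """One candidate description with its scores and level-3 report fields."""

    de_text: str
    word_scores: dict[str, float]
    sentence_score: float
    final_score: float
    frequency: int
    bit_sum: float
    best_hit_id: str
    raw_de: str


@dataclass
class ScoredCluster:
    """A cluster with its descriptions ranked by final score."""

    descriptions: list[ScoredDescription]
    n_hits: int
    representative_terms: frozenset[str] | None = None

    @property
    def best(self) -> ScoredDescription:
        return self.descriptions[0]


@dataclass
class AnnotationReport:
    """Three-level prediction for one query: best DE, ranked clusters,
    ranked descriptions within each cluster."""

    query_id: str
    clusters: list[ScoredCluster]

    @property
    def no_prediction(self) -> bool:
        return not self.clusters

    @property
    def best(self) -> ScoredDescription | None:
        return self.clusters[0].best if self.clusters else None


def _total_bits(all_hits: Sequence[BlastHit]) -> float:
    if not all_hits:
        raise ConfigurationError("cannot score against an empty hit list")
    return sum(h.bit_score for h in all_hits)


def word_score(word: str, cluster: HitCluster, all_hits: Sequence[BlastHit]) -> float:
    """w_ij: bit-score mass of cluster hits containing ``word``, over the
    all-hit bit-score mass."""
    total = _total_bits(all_hits)
    num = sum(h.bit_score for h, de in cluster.members if word in de.tokens)
    return num / total


def sentence_score(de_text: str, cluster: HitCluster, all_hits: Sequence[BlastHit]) -> float:
    """S_k: bit-score mass of hits described exactly by ``de_text``, over
    the all-hit bit-score mass."""
    total = _total_bits(all_hits)
    num = sum(h.bit_score for h, de in cluster.members if de.text == de_text)
    return num / total


def final_score(
    de_text: str,
    cluster: HitCluster,
    all_hits: Sequence[BlastHit],
    variant: str = "two_term",
) -> float:
    """Average of word and sentence support for ``de_text``.

    ``two_term``: (mean_i w_ij + S_k) / 2.
    ``flat``: (sum_i w_ij + S_k) / (n_words + 1).
    """
    words = de_text.split()
    if not words:
        raise ConfigurationError("cannot score an empty description")
    ws = [word_score(w, cluster, all_hits) for w in words]
    s = sentence_score(de_text, cluster, all_hits)
    if variant == "two_term":
        return (sum(ws) / len(ws) + s) / 2.0
    if variant == "flat":
        return (sum(ws) + s) / (len(ws) + 1)
    raise ConfigurationError(f"unknown final-score variant {variant!r}")


def _score_cluster(
    cluster: HitCluster, all_hits: Sequence[BlastHit], variant: str
) -> ScoredCluster:
    total = _total_bits(all_hits)
    # aggregate per distinct description within the cluster
    by_de: dict[str, list] = {}
    for h, de in cluster.members:
        by_de.setdefault(de.text, []).append((h, de))
    # per-word bit mass within the cluster, computed once
    word_mass: dict[str, float] = {}
    for h, de in cluster.members:
        for w in set(de.tokens):
            word_mass[w] = word_mass.get(w, 0.0) + h.bit_score
    descriptions: list[ScoredDescription] = []
    for de_text, members in by_de.items():
        words = de_text.split()
        ws = {w: word_mass[w] / total for w in words}
        s = sum(h.bit_score for h, _ in members) / total
        if variant == "two_term":
            final = (sum(ws[w] for w in words) / len(words) + s) / 2.0
        else:
            final = (sum(ws[w] for w in words) + s) / (len(words) + 1)
        best_hit = min(members, key=lambda m: (-m[0].bit_score, m[0].subject_id))[0]
        descriptions.append(
            ScoredDescription(
                de_text=de_text,
                word_scores=ws,
                sentence_score=s,
                final_score=final,
                frequency=len(members),
                bit_sum=sum(h.bit_score for h, _ in members),
                best_hit_id=best_hit.subject_id,
                raw_de=best_hit.raw_de,
            )
        )
    descriptions.sort(key=lambda d: (-d.final_score, -d.bit_sum, d.de_text))
    return ScoredCluster(
        descriptions=descriptions,
        n_hits=len(cluster.members),
        representative_terms=cluster.representative_terms,
    )


def rank(
    clusters: Sequence[HitCluster],
    all_hits: Sequence[BlastHit],
    query_id: str = "",
    variant: str = "two_term",
) -> AnnotationReport:
    """Score every description and assemble the ranked report.

    Descriptions within a cluster sort by descending final score (ties:
    bit sum, then text); clusters sort by their best description the
    same way.  An empty hit list yields a no-prediction report.
    """
    if variant not in ("two_term", "flat"):
        raise ConfigurationError(f"unknown final-score variant {variant!r}")
    if not clusters or not all_hits:
        return AnnotationReport(query_id=query_id, clusters=[])
    scored = [_score_cluster(c, all_hits, variant) for c in clusters]
    scored.sort(
        key=lambda c: (-c.best.final_score, -c.best.bit_sum, c.best.de_text)
    )
    return AnnotationReport(query_id=query_id, clusters=scored)
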