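"""Annotation-guided clustering of BLAST hits.

Hits are grouped in two stages.  Stage 1 links hits that share the same
processed description, producing *elements*.  Stage 2 merges elements
whose representative GO annotations are identical term sets, so that
differently worded but functionally equivalent descriptions end up in
one cluster (a single hit carrying the right GO annotation can rescue a
whole set of synonymously described matches).  Elements without any
accepted GO annotation stay as they are — with no GO data at all the
clusters are exactly the description groups, and the tool degrades
gracefully to DE-only mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .blast_io import BlastHit
from .de_processing import ProcessedDe
from .errors import ConfigurationError
from .ontology import GoAnnotation

__all__ = ["Element", "HitCluster", "GoLinkPolicy", "group_by_de", "representative_go", "link_by_go"]

HitDe = tuple[BlastHit, ProcessedDe]


@dataclass
class Element:
    """Stage-1 group: all hits sharing one processed description."""

    shared_de: str
    members: list[HitDe]


@dataclass
class HitCluster:
    """Final cluster: union of elements linked by identical GO term sets."""

    members: list[HitDe]
    de_texts: tuple[str, ...]
    representative_terms: frozenset[str] | None = None

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class GoLinkPolicy:
    """How an element's representative GO annotation is chosen.

    ``top_hit`` (default) uses the accepted annotation of the
    highest-bit-score member; ``every_nth`` pools the annotations of the
    members at ranks 1, 1+step, 1+2*step, ... of the bit-score ordering.
    """

    mode: str = "top_hit"
    step: int = 1

    def __post_init__(self):
        if self.mode not in ("top_hit", "every_nth"):
            raise ConfigurationError(f"unknown GO link mode {self.mode!r}")
        if self.step < 1:
            raise ConfigurationError("every_nth step must be >= 1")


def group_by_de(pairs: Sequence[HitDe]) -> list[Element]:
    """Partition hits by processed description text (first-seen order)."""
    by_de: dict[str, Element] = {}
    for hit, de in pairs:
        el = by_de.get(de.text)
        if el is None:
            by_de[de.text] = el = Element(shared_de=de.text, members=[])
        el.members.append((hit, de))
    return list(by_de.values())


def _ranked(members: Sequence[HitDe]) -> list[HitDe]:
    # descending bit score, ties broken by subject id for reproducible runs
    return sorted(members, key=lambda hd: (-hd[0].bit_score, hd[0].subject_id))


def representative_go(
    element: Element,
    annotations: Mapping[str, GoAnnotation],
    policy: GoLinkPolicy = GoLinkPolicy(),
) -> frozenset[str] | None:
    """The GO term set an element is linked by, or None if no member has
    an accepted annotation."""
    accepted_of = {
        hd[0].subject_id: ann.terms
        for hd in element.members
        if (ann := annotations.get(hd[0].subject_id)) is not None and ann.accepted
    }
    if not accepted_of:
        return None
    ranked = _ranked(element.members)
    if policy.mode == "top_hit":
        for hit, _ in ranked:
            terms = accepted_of.get(hit.subject_id)
            if terms is not None:
                return terms
        return None
    pooled: set[str] = set()
    for i in range(0, len(ranked), policy.step):
        terms = accepted_of.get(ranked[i][0].subject_id)
        if terms is not None:
            pooled |= terms
    return frozenset(pooled) if pooled else None


def link_by_go(
    elements: Sequence[Element],
    annotations: Mapping[str, GoAnnotation],
    policy: GoLinkPolicy = GoLinkPolicy(),
) -> list[HitCluster]:
    """Merge elements whose representative GO term sets are identical.

    Set equality is transitive, so grouping by the representative set
    realises the transitive closure directly.  Elements without a
    representative become singleton clusters.  The output partitions the
    input hits; cluster order follows first appearance.
    """
    merged: dict[frozenset[str], HitCluster] = {}
    out: list[HitCluster] = []
    for el in elements:
        rep = representative_go(el, annotations, policy)
        if rep is None:
            out.append(
                HitCluster(members=list(el.members), de_texts=(el.shared_de,))
            )
            continue
        cluster = merged.get(rep)
        if cluster is None:
            cluster = HitCluster(
                members=[], de_texts=(), representative_terms=rep
            )
            merged[rep] = cluster
            out.append(cluster)
        cluster.members.extend(el.members)
        cluster.de_texts = cluster.de_texts + (el.shared_de,)
    return out
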