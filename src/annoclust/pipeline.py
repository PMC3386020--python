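"""End-to-end annotation pipeline: filter, process, cluster, score, rank."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .blast_io import BlastHit, FilterPolicy, filter_hits
from .clustering import GoLinkPolicy, group_by_de, link_by_go
from .de_processing import StopList, default_stoplist, process_query_hits
from .ontology import GoAnnotation
from .scoring import AnnotationReport, rank

__all__ = ["PipelineConfig", "annotate_query", "annotate_all"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of a prediction run in one place."""

    filter_policy: FilterPolicy = FilterPolicy()
    go_link: GoLinkPolicy = GoLinkPolicy()
    stop: StopList | None = None
    score_variant: str = "two_term"
    min_hits_for_infrequent: int = 10


def annotate_query(
    query_id: str,
    hits: Sequence[BlastHit],
    annotations: Mapping[str, GoAnnotation] | None = None,
    config: PipelineConfig = PipelineConfig(),
    self_bit_score: float | None = None,
) -> AnnotationReport:
    """Predict ranked functional descriptions for one query.

    ``annotations`` maps subject ids to their pooled GO annotations; when
    absent or empty the clustering degrades to description groups only.
    """
    stop = config.stop or default_stoplist()
    surviving = filter_hits(hits, config.filter_policy, self_bit_score)
    pairs = process_query_hits(
        surviving, stop, min_hits_for_infrequent=config.min_hits_for_infrequent
    )
    if not pairs:
        return AnnotationReport(query_id=query_id, clusters=[])
    elements = group_by_de(pairs)
    clusters = link_by_go(elements, annotations or {}, config.go_link)
    all_hits = [h for h, _ in pairs]
    return rank(clusters, all_hits, query_id=query_id, variant=config.score_variant)


def annotate_all(
    hits_by_query: Mapping[str, Sequence[BlastHit]],
    annotations: Mapping[str, GoAnnotation] | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> dict[str, AnnotationReport]:
    """Run the pipeline for every query in ``hits_by_query``."""
    return {
        qid: annotate_query(qid, hits, annotations, config)
        for qid, hits in hits_by_query.items()
    }
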