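"""Gene Ontology support: OBO graph, GAF annotations, ancestor closure.

A subject sequence's GO annotation is built by pooling its directly
assigned terms over all three ontologies and propagating each term up
the ``is_a`` hierarchy until the ontological root, root included.
Annotations with fewer than three distinct terms are not accepted for
clustering — shallow annotations ("cellular process") carry too little
signal to link hits reliably.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet

from .errors import ConfigurationError, ParseError

__all__ = [
    "GoGraph",
    "GoAnnotation",
    "EvidencePolicy",
    "EXPERIMENTAL_CODES",
    "COMPUTATIONAL_CODES",
    "read_obo",
    "read_gaf",
    "build_annotation",
    "build_annotations",
]

#: GAF evidence codes for direct experimental support
EXPERIMENTAL_CODES = frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "IEP"})
#: GAF evidence codes for human-reviewed computational analysis
COMPUTATIONAL_CODES = frozenset(
    {"ISS", "ISO", "ISA", "ISM", "IGC", "IBA", "IBD", "IKR", "IRD", "RCA"}
)


@dataclass(frozen=True)
class EvidencePolicy:
    """Which GAF evidence codes to accept.

    ``all`` keeps every assignment (including electronic IEA);
    ``experimental_and_computational`` restricts to the reviewed codes.
    """

    mode: str = "all"

    def __post_init__(self):
        if self.mode not in ("all", "experimental_and_computational"):
            raise ConfigurationError(f"unknown evidence mode {self.mode!r}")

    def allows(self, code: str) -> bool:
        if self.mode == "all":
            return True
        return code in EXPERIMENTAL_CODES or code in COMPUTATIONAL_CODES


@dataclass
class GoGraph:
    """An ``is_a`` ancestor graph over GO terms.

    Wraps the obonet/networkx representation (edges point child -> parent).
    Only ``is_a`` edges participate in ancestor closure.
    """

    graph: nx.MultiDiGraph
    alt_ids: dict[str, str] = field(default_factory=dict)

    def __contains__(self, term: str) -> bool:
        return self.resolve(term) in self.graph

    def resolve(self, term: str) -> str:
        """Map an alt_id to its primary identifier (identity otherwise)."""
        return self.alt_ids.get(term, term)

    @property
    def roots(self) -> frozenset[str]:
        g = self.graph
        return frozenset(n for n in g if not any(True for _ in self._parents(n)))

    def _parents(self, term: str):
        for _, parent, key in self.graph.out_edges(term, keys=True):
            if key == "is_a":
                yield parent

    def ancestors(self, term: str) -> frozenset[str]:
        """All is_a ancestors of ``term`` up to and including the root
        (the term itself excluded)."""
        term = self.resolve(term)
        seen: set[str] = set()
        stack = list(self._parents(term))
        while stack:
            t = stack.pop()
            if t not in seen:
                seen.add(t)
                stack.extend(self._parents(t))
        return frozenset(seen)

    def closure(self, terms: Iterable[str]) -> frozenset[str]:
        """Ancestor-closed union of ``terms`` (unknown terms skipped)."""
        out: set[str] = set()
        for t in terms:
            t = self.resolve(t)
            if t in self.graph:
                out.add(t)
                out |= self.ancestors(t)
        return frozenset(out)


@dataclass(frozen=True)
class GoAnnotation:
    """Ancestor-closed, three-ontology-pooled term set of one subject."""

    subject_id: str
    terms: frozenset[str]
    accepted: bool

    def __bool__(self) -> bool:
        return self.accepted


def read_obo(path: str | Path) -> GoGraph:
    """Load an OBO 1.2 ontology file (optionally gzipped).

    Obsolete terms are excluded; alt_ids are mapped to their primary
    identifier.  A cyclic ``is_a`` hierarchy raises :class:`ParseError`.
    """
    path = str(path)
    try:
        graph = obonet.read_obo(path)
    except Exception as exc:  # obonet raises assorted exceptions on bad files
        raise ParseError(f"cannot parse OBO file ({exc})", path) from exc
    isa = nx.DiGraph(
        (u, v) for u, v, key in graph.edges(keys=True) if key == "is_a"
    )
    if not nx.is_directed_acyclic_graph(isa):
        raise ParseError("is_a hierarchy contains a cycle", path)
    alt: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        for a in data.get("alt_id", []):
            alt[a] = node
    return GoGraph(graph=graph, alt_ids=alt)


def read_gaf(
    path: str | Path,
    policy: EvidencePolicy | None = None,
) -> dict[str, list[tuple[str, str]]]:
    """Parse a GAF 2.x file into ``subject_id -> [(go_id, evidence), ...]``.

    Comment lines start with '!'.  Rows whose qualifier contains NOT are
    excluded (the annotation asserts absence of function).  An optional
    evidence policy drops rows with disallowed codes at read time.
    Duplicate (subject, term) pairs are kept once, first evidence wins.
    """
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    out: dict[str, list[tuple[str, str]]] = {}
    seen: set[tuple[str, str]] = set()
    with opener(path, "rt", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            fields = line.split("\t")
            if len(fields) < 15:
                raise ParseError(
                    f"GAF row has {len(fields)} columns, expected >= 15",
                    path, line_no,
                )
            subject = fields[1]
            qualifier = fields[3]
            go_id = fields[4]
            evidence = fields[6]
            if "NOT" in qualifier.split("|"):
                continue
            if policy is not None and not policy.allows(evidence):
                continue
            key = (subject, go_id)
            if key in seen:
                continue
            seen.add(key)
            out.setdefault(subject, []).append((go_id, evidence))
    return out


def build_annotation(
    subject_id: str,
    direct_terms_with_evidence: Sequence[tuple[str, str]],
    graph: GoGraph,
    policy: EvidencePolicy | None = None,
    min_go_terms: int = 3,
) -> GoAnnotation:
    """Pooled, ancestor-closed annotation for one subject.

    The evidence policy is applied to the direct assignments before
    closure; terms absent from the graph are skipped.  The annotation is
    accepted only when it contains at least ``min_go_terms`` distinct
    terms (roots included).
    """
    policy = policy or EvidencePolicy()
    retained = [t for t, ev in direct_terms_with_evidence if policy.allows(ev)]
    terms = graph.closure(retained)
    return GoAnnotation(
        subject_id=subject_id,
        terms=terms,
        accepted=len(terms) >= min_go_terms,
    )


def build_annotations(
    gaf_map: Mapping[str, Sequence[tuple[str, str]]],
    graph: GoGraph,
    policy: EvidencePolicy | None = None,
    min_go_terms: int = 3,
) -> dict[str, GoAnnotation]:
    """Vectorised convenience over :func:`build_annotation`."""
    return {
        sid: build_annotation(sid, pairs, graph, policy, min_go_terms)
        for sid, pairs in gaf_map.items()
    }
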