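"""Benchmark harness: competing predictors, mLD statistics and sweeps.

Given a gold standard of queries with known correct descriptions, the
harness measures how close each predictor's description comes to the
truth in terms of the modified Levenshtein distance, standardises each
prediction against the distribution of distances across the query's own
hit list (Z-score; positive = better than a random pick), records the
per-query best/median/worst achievable distances under identity and
coverage filter sweeps, and quantifies how often hits carry the optimal
annotation under five selection criteria.
"""

from __future__ import annotations

import datetime as _dt
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .blast_io import BlastHit, FilterPolicy
from .clustering import HitCluster
from .de_processing import StopList, default_stoplist, remove_uninformative, tokenize
from .errors import ConfigurationError, ParseError
from .mld_metric import mld_distance
from .ontology import GoAnnotation
from .pipeline import PipelineConfig, annotate_query
from .scoring import rank

__all__ = [
    "GoldRecord",
    "METHODS",
    "SWEEP_THRESHOLDS",
    "read_gold",
    "remove_circular",
    "predict",
    "go_restrict",
    "optimal_fractions",
    "sweep",
    "zscore",
    "evaluate_methods",
]

METHODS = (
    "top_hit",
    "top_informative",
    "most_common",
    "max_bitsum",
    "word_score",
    "blannotator",
)

SWEEP_THRESHOLDS = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0)


@dataclass(frozen=True)
class GoldRecord:
    """Known-correct annotation of one benchmark query."""

    query_id: str
    correct_de: str
    annotation_date: _dt.date | None = None
    correct_go: frozenset[str] | None = None

    def __post_init__(self):
        if not self.correct_de:
            raise ConfigurationError("gold record needs a non-empty description")


def read_gold(path: str | Path) -> list[GoldRecord]:
    """Gold-standard TSV: query_id, correct_de, annotation_date, go_terms.

    The GO column is a '|'-separated (possibly empty) term list; a header
    line starting with 'query_id' is skipped.
    """
    out: list[GoldRecord] = []
    path = str(path)
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("query_id"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError("gold row needs at least 2 columns", path, line_no)
            date = None
            if len(fields) > 2 and fields[2].strip():
                try:
                    date = _dt.date.fromisoformat(fields[2].strip())
                except ValueError as exc:
                    raise ParseError(f"bad date {fields[2]!r}", path, line_no) from exc
            go = None
            if len(fields) > 3 and fields[3].strip():
                go = frozenset(t for t in fields[3].strip().split("|") if t)
            out.append(GoldRecord(fields[0], fields[1], date, go))
    return out


def remove_circular(
    hits: Sequence[BlastHit], annotation_date: _dt.date
) -> list[BlastHit]:
    """Drop hits whose subject entry was created on or after the query's
    annotation date (their description may derive from the query's own
    characterisation).  Undated hits are kept."""
    return [
        h
        for h in hits
        if h.subject_creation_date is None or h.subject_creation_date < annotation_date
    ]


def _tie_pick(candidates: list, rng: np.random.Generator):
    if len(candidates) == 1:
        return candidates[0]
    return candidates[int(rng.integers(len(candidates)))]


def predict(
    hits: Sequence[BlastHit],
    method: str,
    rng: np.random.Generator | int = 0,
    annotations: Mapping[str, GoAnnotation] | None = None,
    config: PipelineConfig | None = None,
) -> str | None:
    """One predicted description (or None) from an already filtered hit list.

    Methods: ``top_hit`` (highest bit score), ``top_informative`` (highest
    bit score whose description has no uninformative words),
    ``most_common`` / ``max_bitsum`` / ``word_score`` (most frequent,
    highest bit-score sum, and highest-scoring processed description,
    the last computed with the scoring scheme on a single all-hit group)
    and ``blannotator`` (the full clustering pipeline).  Ties break
    randomly under the supplied generator/seed.
    """
    if method not in METHODS:
        raise ConfigurationError(f"unknown prediction method {method!r}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    config = config or PipelineConfig()
    stop = config.stop or default_stoplist()
    hits = list(hits)
    if not hits:
        return None

    if method == "top_hit":
        top = max(h.bit_score for h in hits)
        return _tie_pick([h for h in hits if h.bit_score == top], rng).raw_de

    if method == "top_informative":
        ranked = sorted(hits, key=lambda h: -h.bit_score)
        for _, group in _group_runs(ranked, key=lambda h: h.bit_score):
            informative = [
                h
                for h in group
                if (toks := tokenize(h.raw_de))
                and len(remove_uninformative(toks, stop)) == len(toks)
            ]
            if informative:
                return _tie_pick(informative, rng).raw_de
        return None

    if method == "blannotator":
        report = annotate_query(
            "", hits, annotations,
            PipelineConfig(
                filter_policy=FilterPolicy.permissive(),
                go_link=config.go_link,
                stop=stop,
                score_variant=config.score_variant,
                min_hits_for_infrequent=config.min_hits_for_infrequent,
            ),
        )
        return None if report.no_prediction else report.best.de_text

    # the remaining three operate on processed descriptions
    from .de_processing import process_query_hits

    pairs = process_query_hits(
        hits, stop, min_hits_for_infrequent=config.min_hits_for_infrequent
    )
    if not pairs:
        return None
    if method == "most_common":
        freq: dict[str, int] = {}
        for _, de in pairs:
            freq[de.text] = freq.get(de.text, 0) + 1
        top = max(freq.values())
        return _tie_pick(sorted(k for k, v in freq.items() if v == top), rng)
    if method == "max_bitsum":
        mass: dict[str, float] = {}
        for h, de in pairs:
            mass[de.text] = mass.get(de.text, 0.0) + h.bit_score
        top = max(mass.values())
        return _tie_pick(sorted(k for k, v in mass.items() if v == top), rng)
    # word_score: the scoring scheme with a single group holding all hits
    cluster = HitCluster(members=list(pairs), de_texts=tuple({d.text for _, d in pairs}))
    report = rank([cluster], [h for h, _ in pairs], variant=config.score_variant)
    best = report.best.final_score
    ties = [d.de_text for d in report.clusters[0].descriptions if d.final_score == best]
    return _tie_pick(sorted(ties), rng)


def _group_runs(items, key):
    """Yield (key, list) runs of consecutive equal keys."""
    run, run_key = [], None
    for it in items:
        k = key(it)
        if run and k != run_key:
            yield run_key, run
            run = []
        run_key = k
        run.append(it)
    if run:
        yield run_key, run


def go_restrict(
    hits: Sequence[BlastHit],
    annotations: Mapping[str, GoAnnotation],
    min_group: int = 5,
    rng: np.random.Generator | int = 0,
) -> list[BlastHit]:
    """Restrict a hit list to the largest group sharing identical GO terms.

    Hits are partitioned by exact term-set equality of their accepted
    annotations; the largest part is returned if it has at least
    ``min_group`` members, otherwise all hits are returned unchanged.
    Size ties break by higher bit-score sum, then randomly.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    parts: dict[frozenset[str], list[BlastHit]] = {}
    for h in hits:
        ann = annotations.get(h.subject_id)
        if ann is not None and ann.accepted:
            parts.setdefault(ann.terms, []).append(h)
    if not parts:
        return list(hits)
    best_size = max(len(p) for p in parts.values())
    if best_size < min_group:
        return list(hits)
    candidates = [p for p in parts.values() if len(p) == best_size]
    best_mass = max(sum(h.bit_score for h in p) for p in candidates)
    candidates = [p for p in candidates if sum(h.bit_score for h in p) == best_mass]
    return list(_tie_pick(candidates, rng))


def optimal_fractions(
    hits: Sequence[BlastHit],
    gold: GoldRecord,
    annotations: Mapping[str, GoAnnotation],
    clusters: Sequence[HitCluster],
    stop: StopList | None = None,
) -> dict[str, float]:
    """Per-query fractions of hits carrying the optimal annotation.

    Five criteria: optimal DE (mLD of 0 to the gold description), optimal
    GO (term set identical to the gold set), their union and
    intersection, and the clustering criterion — the size of the largest
    cluster containing at least one optimally annotated hit, over the
    hit count.
    """
    stop = stop or default_stoplist()
    n = len(hits)
    if n == 0:
        return {k: 0.0 for k in ("de", "go", "de_or_go", "de_and_go", "cluster_group")}
    de_ok: set[str] = set()
    go_ok: set[str] = set()
    for h in hits:
        if mld_distance(gold.correct_de, h.raw_de, stop) == 0.0:
            de_ok.add(h.subject_id)
        if gold.correct_go is not None:
            ann = annotations.get(h.subject_id)
            if ann is not None and ann.terms == gold.correct_go:
                go_ok.add(h.subject_id)
    either = de_ok | go_ok
    group = 0
    for c in clusters:
        if any(h.subject_id in either for h, _ in c.members):
            group = max(group, len(c.members))
    return {
        "de": len(de_ok) / n,
        "go": len(go_ok) / n,
        "de_or_go": len(either) / n,
        "de_and_go": len(de_ok & go_ok) / n,
        "cluster_group": group / n,
    }


def zscore(prediction_mld: float, hit_de_mlds: Sequence[float]) -> float | None:
    """Sign-flipped standard score of a prediction against its hit list.

    z = -(x - mu) / sigma over the mLDs of all hit descriptions; None
    when sigma is zero (the query is excluded from Z statistics).
    """
    arr = np.asarray(hit_de_mlds, dtype=float)
    sigma = float(arr.std())  # population SD: the hit list is the whole population
    if sigma == 0.0 or arr.size < 2:
        return None
    return -(prediction_mld - float(arr.mean())) / sigma


def _query_mlds(
    hits: Sequence[BlastHit], gold: GoldRecord, stop: StopList
) -> list[float]:
    return [mld_distance(gold.correct_de, h.raw_de, stop) for h in hits]


def sweep(
    hits_by_query: Mapping[str, Sequence[BlastHit]],
    gold_by_query: Mapping[str, GoldRecord],
    thresholds: Sequence[float] = SWEEP_THRESHOLDS,
    coverage_side: str = "subject",
    stop: StopList | None = None,
) -> pd.DataFrame:
    """Identity x coverage filter sweep of achievable annotation quality.

    For every combination of identity and coverage thresholds (6 x 6 by
    default), hits below either threshold are discarded and the per-query
    minimum, median and maximum mLD between the gold description and the
    surviving hit descriptions are recorded.  Rows report the mean and
    sample SD (over queries with at least one surviving hit) of each
    statistic, plus the number of covered queries.
    """
    stop = stop or default_stoplist()
    # precompute per-hit quantities once; each cell only masks
    per_query: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    for qid, hits in hits_by_query.items():
        gold = gold_by_query.get(qid)
        if gold is None:
            continue
        ident = np.array([h.percent_identity for h in hits], dtype=float)
        cov = np.array([h.coverage(coverage_side) for h in hits], dtype=float)
        dists = np.array(_query_mlds(hits, gold, stop), dtype=float)
        per_query.append((ident, cov, dists))
    rows = []
    for ti in thresholds:
        for tc in thresholds:
            mins, meds, maxs = [], [], []
            for ident, cov, dists in per_query:
                mask = (ident >= ti) & (cov >= tc)
                if mask.any():
                    d = dists[mask]
                    mins.append(d.min())
                    meds.append(float(np.median(d)))
                    maxs.append(d.max())
            rows.append(
                {
                    "identity": ti,
                    "coverage": tc,
                    "n_queries": len(mins),
                    "min_mean": np.mean(mins) if mins else np.nan,
                    "min_sd": np.std(mins, ddof=1) if len(mins) > 1 else np.nan,
                    "median_mean": np.mean(meds) if meds else np.nan,
                    "median_sd": np.std(meds, ddof=1) if len(meds) > 1 else np.nan,
                    "max_mean": np.mean(maxs) if maxs else np.nan,
                    "max_sd": np.std(maxs, ddof=1) if len(maxs) > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def evaluate_methods(
    hits_by_query: Mapping[str, Sequence[BlastHit]],
    gold_by_query: Mapping[str, GoldRecord],
    annotations: Mapping[str, GoAnnotation] | None = None,
    methods: Sequence[str] = METHODS,
    seed: int = 0,
    go_restricted: bool = False,
    config: PipelineConfig | None = None,
    stop: StopList | None = None,
) -> pd.DataFrame:
    """Head-to-head comparison of prediction methods.

    For each method: mean and sample SD of the prediction mLD over
    queries with at least one hit (queries without a prediction score 1),
    mean Z-score over queries with defined sigma, and counts.  With
    ``go_restricted`` every method sees only the largest GO-consistent
    hit group (when it has five or more members).
    """
    stop = stop or default_stoplist()
    config = config or PipelineConfig()
    annotations = annotations or {}
    rows = []
    for method in methods:
        rng = np.random.default_rng([seed, zlib.crc32(method.encode()) % (2**31)])
        dists, zs, n_pred = [], [], 0
        for qid, hits in hits_by_query.items():
            gold = gold_by_query.get(qid)
            if gold is None or not hits:
                continue
            use = (
                go_restrict(hits, annotations, rng=rng) if go_restricted else hits
            )
            de = predict(use, method, rng, annotations, config)
            hit_mlds = _query_mlds(use, gold, stop)
            if de is None:
                d = 1.0
            else:
                d = mld_distance(gold.correct_de, de, stop)
                n_pred += 1
            dists.append(d)
            z = zscore(d, hit_mlds)
            if z is not None:
                zs.append(z)
        rows.append(
            {
                "method": method,
                "n_queries": len(dists),
                "n_predicted": n_pred,
                "mld_mean": np.mean(dists) if dists else np.nan,
                "mld_sd": np.std(dists, ddof=1) if len(dists) > 1 else np.nan,
                "z_mean": np.mean(zs) if zs else np.nan,
                "z_sd": np.std(zs, ddof=1) if len(zs) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)
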