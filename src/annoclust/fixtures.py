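"""Deterministic synthetic benchmark generator.

Produces a mutually consistent file set — BLAST tabular results, an OBO
ontology, a GAF annotation file, a gold-standard TSV and query FASTA —
with controlled structure, so every pipeline stage and the whole
evaluation harness can be exercised without external databases.

The generator emulates the statistical shape of a real homology
benchmark: each query has a hidden true function (its gold description
plus an ancestor-closed GO term set), and its hit list mixes hits
carrying the gold description, misspelled variants, wholly uninformative
descriptions and decoy functions, with bit scores drawn independently of
correctness.  Defaults mirror the characterisation of curated bacterial
benchmark data: on average 72 hits per query, 15% of hits with the
optimal description and roughly three times as many with the optimal GO
annotation.  Bit scores are drawn, not computed — no sequence evolution
is simulated.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError

__all__ = ["FixtureSpec", "FixtureSet", "generate", "scenario_library"]

#: informative vocabulary for synthetic descriptions; deliberately free of
#: stop-list words so gold descriptions survive DE processing intact
WORD_BANK = (
    "gyrase kinase ligase synthase reductase oxidase hydrolase transferase "
    "polymerase helicase permease transporter receptor regulator repressor "
    "activator subunit alpha beta gamma delta chain ribosomal membrane "
    "secreted binding atp gtp nadh dna rna trna amino acid sugar lipid cell "
    "wall division stress heat shock cold iron zinc copper efflux uptake "
    "flagellar motor pilus adhesin protease peptidase esterase lactamase "
    "phosphatase mutase isomerase epimerase aldolase carboxylase synthetase "
    "dehydrogenase hydratase nuclease integrase translocase oxygenase"
).split()

UNINFORMATIVE_DES = (
    "hypothetical protein",
    "putative protein",
    "predicted protein",
    "conserved hypothetical protein",
    "uncharacterized protein",
)

GO_ROOTS = {
    "GO:0008150": ("biological_process", "P"),
    "GO:0003674": ("molecular_function", "F"),
    "GO:0005575": ("cellular_component", "C"),
}

_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic benchmark.

    The per-hit class fractions (optimal / misspelled / uninformative)
    are exclusive and must sum to at most 1; the remainder of each hit
    list is filled with decoy functions.  The same seed always yields
    byte-identical files.
    """

    seed: int = 0
    n_queries: int = 50
    mean_hits_per_query: float = 72.0
    hits_per_query: int | None = None  # fixed count overrides the Poisson draw
    n_function_groups: int = 3
    bit_range: tuple[float, float] = (50.0, 400.0)
    frac_optimal_de: float = 0.15
    frac_misspelled: float = 0.05
    misspell_edits: int = 2
    frac_uninformative: float = 0.10
    frac_optimal_go: float = 0.45
    frac_decoy_go: float = 0.50
    frac_circular: float = 0.0
    annotation_date: str = "2008-01-01"
    go_depth: int = 4
    go_branching: int = 2
    identity_range: tuple[float, float] = (30.0, 100.0)
    # scenario switches
    n_top_misleading: int = 0      # force the k best-bit hits to be decoys
    remote_informative: bool = False  # informative hits only below 50% identity
    synonym_de: bool = False       # split gold hits over two word orders
    unique_decoys: bool = False    # every decoy hit gets its own description

    def __post_init__(self):
        fracs = (
            self.frac_optimal_de,
            self.frac_misspelled,
            self.frac_uninformative,
            self.frac_optimal_go,
            self.frac_decoy_go,
            self.frac_circular,
        )
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ConfigurationError("fixture fractions must lie in [0, 1]")
        if self.frac_optimal_de + self.frac_misspelled + self.frac_uninformative > 1.0:
            raise ConfigurationError("exclusive hit-class fractions sum above 1")


@dataclass
class FixtureSet:
    """Paths of the generated files plus the hidden ground truth."""

    out_dir: Path
    blast_path: Path
    obo_path: Path
    gaf_path: Path
    gold_path: Path
    fasta_path: Path
    log_path: Path
    truth: dict


def _go_dag(spec: FixtureSpec) -> tuple[list[str], dict[str, str], dict[str, str], list[str]]:
    """Balanced tree under each of the three roots.

    Returns (term order, child->parent map, term->aspect map, leaves).
    """
    parents: dict[str, str] = {}
    aspect: dict[str, str] = {}
    order: list[str] = []
    leaves: list[str] = []
    counter = 1000000
    for root, (_, asp) in GO_ROOTS.items():
        order.append(root)
        aspect[root] = asp
        level = [root]
        for depth in range(spec.go_depth):
            nxt = []
            for parent in level:
                for _ in range(spec.go_branching):
                    counter += 1
                    term = f"GO:{counter}"
                    parents[term] = parent
                    aspect[term] = asp
                    order.append(term)
                    nxt.append(term)
            level = nxt
        leaves.extend(level)
    return order, parents, aspect, leaves


def _ancestor_chain(term: str, parents: dict[str, str]) -> list[str]:
    chain = [term]
    while chain[-1] in parents:
        chain.append(parents[chain[-1]])
    return chain


def _misspell(text: str, rng: np.random.Generator, k: int) -> str:
    """Introduce k random character substitutions (never into a space)."""
    chars = list(text)
    positions = [i for i, c in enumerate(chars) if c != " "]
    for i in rng.choice(positions, size=min(k, len(positions)), replace=False):
        alt = "abcdefghijklmnopqrstuvwxyz".replace(chars[i], "")
        chars[i] = alt[int(rng.integers(len(alt)))]
    return "".join(chars)


def _make_model(spec: FixtureSpec) -> dict:
    """Draw the complete hidden model from one seeded stream."""
    rng = np.random.default_rng([spec.seed % (2**31), 815])
    order, parents, aspect, leaves = _go_dag(spec)
    ann_date = _dt.date.fromisoformat(spec.annotation_date)
    queries = []
    subject_serial = 0
    for qi in range(spec.n_queries):
        qid = f"Q{qi + 1:05d}"
        n_gold_words = int(rng.integers(2, 5))
        words = list(rng.choice(WORD_BANK, size=len(WORD_BANK), replace=False))
        gold_words = words[:n_gold_words]
        gold_de = " ".join(gold_words)
        decoy_pool = words[n_gold_words:]
        # one GO leaf per function group; group 0 is the gold function
        leaf_idx = rng.choice(len(leaves), size=spec.n_function_groups, replace=False)
        group_terms = [
            frozenset(_ancestor_chain(leaves[i], parents)) for i in leaf_idx
        ]
        group_leaves = [leaves[i] for i in leaf_idx]
        n_decoy_groups = max(1, spec.n_function_groups - 1)
        decoy_des = []
        for g in range(n_decoy_groups):
            take = decoy_pool[g * 2 : g * 2 + 2]
            decoy_des.append(" ".join(take))
        unique_decoy_pool = decoy_pool[n_decoy_groups * 2 :]

        if spec.hits_per_query is not None:
            n_hits = spec.hits_per_query
        else:
            n_hits = max(1, int(rng.poisson(spec.mean_hits_per_query)))
        n_opt = round(spec.frac_optimal_de * n_hits)
        n_mis = round(spec.frac_misspelled * n_hits)
        n_unf = round(spec.frac_uninformative * n_hits)
        n_dec = n_hits - n_opt - n_mis - n_unf

        classes = (
            ["optimal"] * n_opt + ["misspelled"] * n_mis
            + ["uninformative"] * n_unf + ["decoy"] * n_dec
        )
        bits = np.sort(
            rng.uniform(spec.bit_range[0], spec.bit_range[1], size=n_hits)
        )[::-1]
        rng.shuffle(classes)
        if spec.n_top_misleading > 0:
            # move decoys to the best-bit slots (the misleading top of the list)
            k = min(spec.n_top_misleading, classes.count("decoy"))
            for slot in range(k):
                if classes[slot] != "decoy":
                    swap = max(i for i, c in enumerate(classes) if c == "decoy")
                    classes[slot], classes[swap] = classes[swap], classes[slot]

        go_flags = rng.random(n_hits)
        hits = []
        opt_seen = 0
        unique_i = 0
        for rank_i, cls in enumerate(classes):
            subject_serial += 1
            sid = f"S{subject_serial:06d}"
            if cls == "optimal":
                if spec.synonym_de and opt_seen % 2 == 1 and len(gold_words) > 1:
                    permuted = gold_words[1:] + gold_words[:1]
                    de = " ".join(permuted)
                else:
                    de = gold_de
                opt_seen += 1
                group = 0
            elif cls == "misspelled":
                de = _misspell(gold_de, rng, spec.misspell_edits)
                group = 0
            elif cls == "uninformative":
                de = UNINFORMATIVE_DES[int(rng.integers(len(UNINFORMATIVE_DES)))]
                group = -1
            else:
                if spec.unique_decoys:
                    take = unique_decoy_pool[unique_i * 2 : unique_i * 2 + 2]
                    if len(take) < 2:  # vocabulary exhausted; recycle pairs
                        take = [
                            unique_decoy_pool[unique_i % len(unique_decoy_pool)],
                            unique_decoy_pool[(unique_i + 7) % len(unique_decoy_pool)],
                        ]
                    unique_i += 1
                    de = " ".join(take)
                    group = 1
                else:
                    group = 1 + int(rng.integers(n_decoy_groups))
                    de = decoy_des[group - 1]
            # GO assignment: optimal GO to a random subset of hits of the
            # gold function; decoy GO to hits of decoy functions
            direct_go = None
            if group == 0 and go_flags[rank_i] < _renorm(spec.frac_optimal_go, spec):
                direct_go = group_leaves[0]
            elif group >= 1 and go_flags[rank_i] < spec.frac_decoy_go:
                direct_go = group_leaves[min(group, len(group_leaves) - 1)]
            if spec.remote_informative:
                identity = (
                    float(rng.uniform(40.0, 50.0))
                    if cls != "uninformative"
                    else float(rng.uniform(61.0, 95.0))
                )
            else:
                identity = float(rng.uniform(*spec.identity_range))
            qlen = int(rng.integers(150, 600))
            slen = int(rng.integers(max(120, qlen - 100), qlen + 100))
            aln = int(rng.integers(30, min(qlen, slen) + 1))
            if rng.random() < spec.frac_circular:
                sdate = ann_date + _dt.timedelta(days=int(rng.integers(0, 700)))
            else:
                sdate = ann_date - _dt.timedelta(days=int(rng.integers(1, 1400)))
            hits.append(
                {
                    "subject_id": sid,
                    "class": cls,
                    "group": group,
                    "de": de,
                    "bit": float(bits[rank_i]),
                    "identity": identity,
                    "qlen": qlen,
                    "slen": slen,
                    "aln": aln,
                    "evalue": float(10.0 ** -rng.uniform(5, 180)),
                    "sdate": sdate.isoformat(),
                    "direct_go": direct_go,
                }
            )
        if spec.synonym_de:
            _ensure_synonym_rescue(hits, gold_words, group_leaves[0])
        seq = "".join(
            _ALPHABET[i] for i in rng.integers(0, len(_ALPHABET), size=hits[0]["qlen"])
        )
        queries.append(
            {
                "query_id": qid,
                "gold_de": gold_de,
                "gold_go": sorted(group_terms[0]),
                "annotation_date": spec.annotation_date,
                "sequence": seq,
                "hits": hits,
            }
        )
    return {
        "spec": dataclasses.asdict(spec),
        "go": {"order": order, "parents": parents, "aspect": aspect},
        "queries": queries,
    }


def _renorm(frac_go: float, spec: FixtureSpec) -> float:
    """Scale the optimal-GO fraction from all hits to gold-function hits."""
    gold_frac = spec.frac_optimal_de + spec.frac_misspelled
    if gold_frac <= 0:
        return 0.0
    return min(1.0, frac_go / gold_frac)


def _ensure_synonym_rescue(hits: list[dict], gold_words: list[str], leaf: str) -> None:
    """Guarantee both spelling variants exist and each contains at least
    one hit with the gold GO leaf, so GO linking can merge them."""
    gold_de = " ".join(gold_words)
    variant = " ".join(gold_words[1:] + gold_words[:1])
    for de in (gold_de, variant):
        members = [h for h in hits if h["de"] == de]
        if not members:
            # repurpose the weakest decoy hit
            decoys = [h for h in hits if h["group"] != 0]
            if not decoys:
                continue
            weakest = min(decoys, key=lambda h: h["bit"])
            weakest.update({"de": de, "class": "optimal", "group": 0})
            members = [weakest]
        if not any(h["direct_go"] == leaf for h in members):
            members[0]["direct_go"] = leaf


def _write_obo(model: dict, path: Path) -> None:
    go = model["go"]
    lines = ["format-version: 1.2", "ontology: synthetic-go", ""]
    names = dict(GO_ROOTS)
    for term in go["order"]:
        lines.append("[Term]")
        lines.append(f"id: {term}")
        if term in names:
            lines.append(f"name: {names[term][0]}")
        else:
            lines.append(f"name: synthetic term {term[3:]}")
        lines.append(f"namespace: {go['aspect'][term]}")
        parent = go["parents"].get(term)
        if parent:
            lines.append(f"is_a: {parent}")
        lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")


def _write_gaf(model: dict, path: Path) -> None:
    aspect = model["go"]["aspect"]
    rows = ["!gaf-version: 2.2"]
    for q in model["queries"]:
        for h in q["hits"]:
            if h["direct_go"] is None:
                continue
            evidence = ("IDA", "ISS", "IEA")[
                int(h["bit"]) % 3
            ]  # deterministic evidence mix
            rows.append(
                "\t".join(
                    [
                        "SynthDB", h["subject_id"], h["subject_id"], "enables",
                        h["direct_go"], "GO_REF:0000001", evidence, "",
                        aspect[h["direct_go"]], "", "", "protein",
                        "taxon:1423", "20071201", "SynthGen", "", "",
                    ]
                )
            )
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")


def _write_blast(model: dict, path: Path) -> None:
    rows = []
    for q in model["queries"]:
        ordered = sorted(q["hits"], key=lambda h: -h["bit"])
        for h in ordered:
            rows.append(
                "\t".join(
                    [
                        q["query_id"], h["subject_id"], f"{h['identity']:.1f}",
                        str(h["aln"]), f"{h['evalue']:.2e}", f"{h['bit']:.1f}",
                        str(h["slen"]), str(h["qlen"]), h["sdate"], h["de"],
                    ]
                )
            )
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")


def _write_gold(model: dict, path: Path) -> None:
    rows = ["query_id\tcorrect_de\tannotation_date\tgo_terms"]
    for q in model["queries"]:
        rows.append(
            "\t".join(
                [
                    q["query_id"], q["gold_de"], q["annotation_date"],
                    "|".join(q["gold_go"]),
                ]
            )
        )
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")


def _write_fasta(model: dict, path: Path) -> None:
    chunks = []
    for q in model["queries"]:
        seq = q["sequence"]
        body = "\n".join(seq[i : i + 60] for i in range(0, len(seq), 60))
        chunks.append(f">{q['query_id']} {q['gold_de']}\n{body}")
    path.write_text("\n".join(chunks) + "\n", encoding="utf-8")


def _write_log(model: dict, path: Path) -> None:
    log = {
        "spec": model["spec"],
        "queries": {
            q["query_id"]: {
                "gold_de": q["gold_de"],
                "gold_go": q["gold_go"],
                "hits": {
                    h["subject_id"]: {"class": h["class"], "group": h["group"]}
                    for h in q["hits"]
                },
            }
            for q in model["queries"]
        },
    }
    path.write_text(json.dumps(log, indent=1, sort_keys=True), encoding="utf-8")


def generate(spec: FixtureSpec, out_dir: str | Path) -> FixtureSet:
    """Generate the full synthetic file set under ``out_dir``.

    All five files are serialised from one seeded model, so they are
    mutually consistent (every annotated subject of blast.tsv appears in
    goa.gaf; gold descriptions use the generating vocabulary) and
    regenerating any single file never changes another.  A JSON log
    records the hidden class and function group of every hit.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = _make_model(spec)
    fs = FixtureSet(
        out_dir=out_dir,
        blast_path=out_dir / "blast.tsv",
        obo_path=out_dir / "go.obo",
        gaf_path=out_dir / "goa.gaf",
        gold_path=out_dir / "gold.tsv",
        fasta_path=out_dir / "queries.fasta",
        log_path=out_dir / "log.json",
        truth=model,
    )
    _write_blast(model, fs.blast_path)
    _write_obo(model, fs.obo_path)
    _write_gaf(model, fs.gaf_path)
    _write_gold(model, fs.gold_path)
    _write_fasta(model, fs.fasta_path)
    _write_log(model, fs.log_path)
    return fs


def scenario_library() -> dict[str, FixtureSpec]:
    """Named scenarios exercising specific behaviours of the method.

    - ``baseline``: the default benchmark shape.
    - ``majority-gold``: the bit-weighted majority description is always
      the gold one (20 fixed hits, 60% optimal, decoys unique), so a
      correct pipeline must recover every query exactly.
    - ``top-hit-misleading``: the three best-scoring hits are decoys
      while the gold description holds the cluster majority.
    - ``remote-only``: informative hits sit at or below 50% identity;
      high-identity hits are uninformative, so aggressive identity
      filtering destroys the signal.
    - ``synonym-rescue``: the gold description occurs in two word orders
      (distinct processed DEs) joined by a shared GO annotation.
    - ``no-go``: no GO data at all; clustering degrades to DE groups.
    """
    return {
        "baseline": FixtureSpec(),
        "majority-gold": FixtureSpec(
            n_queries=100,
            hits_per_query=20,
            frac_optimal_de=0.60,
            frac_misspelled=0.0,
            frac_uninformative=0.0,
            unique_decoys=True,
        ),
        "top-hit-misleading": FixtureSpec(
            n_queries=20,
            hits_per_query=20,
            frac_optimal_de=0.60,
            frac_misspelled=0.0,
            frac_uninformative=0.0,
            unique_decoys=True,
            n_top_misleading=3,
        ),
        "remote-only": FixtureSpec(
            n_queries=10,
            hits_per_query=20,
            frac_optimal_de=0.60,
            frac_misspelled=0.0,
            frac_uninformative=0.30,
            remote_informative=True,
        ),
        "synonym-rescue": FixtureSpec(
            n_queries=10,
            hits_per_query=20,
            frac_optimal_de=0.50,
            frac_misspelled=0.0,
            frac_uninformative=0.10,
            synonym_de=True,
            frac_optimal_go=0.45,
        ),
        "no-go": FixtureSpec(
            n_queries=10,
            hits_per_query=20,
            frac_optimal_go=0.0,
            frac_decoy_go=0.0,
        ),
    }
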