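import dataclasses

import pytest

from annoclust.blast_io import BlastHit
from annoclust.fixtures import FixtureSpec, generate, scenario_library


def make_hit(
    subject_id,
    bit_score,
    de="dna gyrase",
    query_id="Q1",
    percent_identity=80.0,
    alignment_length=100,
    subject_length=200,
    query_length=200,
    **kw,
):
    return BlastHit(
        query_id=query_id,
        subject_id=subject_id,
        bit_score=bit_score,
        percent_identity=percent_identity,
        alignment_length=alignment_length,
        subject_length=subject_length,
        query_length=query_length,
        raw_de=de,
        **kw,
    )


@pytest.fixture
def hit_factory():
    return make_hit


TOY_OBO = """\
format-version: 1.2
ontology: toy

[Term]
id: GO:0000001
name: root

[Term]
id: GO:0000002
name: A
is_a: GO:0000001

[Term]
id: GO:0000003
name: B
is_a: GO:0000002

[Term]
id: GO:0000004
name: C
alt_id: GO:0000099
is_a: GO:0000001

[Term]
id: GO:0000005
name: gone
is_obsolete: true
"""


@pytest.fixture
def toy_obo(tmp_path):
    p = tmp_path / "toy.obo"
    p.write_text(TOY_OBO)
    return p


@pytest.fixture(scope="session")
def scenario_data(tmp_path_factory):
    """Generate a named scenario once per session; returns loaded pieces."""
    from annoclust.blast_io import FIXTURE_COLUMNS, read_blast_tabular
    from annoclust.evaluation import read_gold
    from annoclust.ontology import build_annotations, read_gaf, read_obo

    cache = {}

    def _get(name, seed=11, **overrides):
        key = (name, seed, tuple(sorted(overrides.items())))
        if key not in cache:
            spec = dataclasses.replace(
                scenario_library()[name], seed=seed, **overrides
            )
            out = tmp_path_factory.mktemp(f"fx_{name.replace('-', '_')}")
            fs = generate(spec, out)
            hits = read_blast_tabular(fs.blast_path, FIXTURE_COLUMNS)
            by_query = {}
            for h in hits:
                by_query.setdefault(h.query_id, []).append(h)
            graph = read_obo(fs.obo_path)
            annotations = build_annotations(read_gaf(fs.gaf_path), graph)
            gold = {g.query_id: g for g in read_gold(fs.gold_path)}
            cache[key] = {
                "fixture": fs,
                "by_query": by_query,
                "annotations": annotations,
                "gold": gold,
                "graph": graph,
            }
        return cache[key]

    return _get
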