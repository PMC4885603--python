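"""DNF query semantics and collection statistics."""

import pytest

import rnaloops as rl
from rnaloops.query import QuerySyntaxError, parse_query
from rnaloops.stats import collect_stats

from conftest import random_structures


@pytest.fixture(scope="module")
def collection(figure1, figure3):
    structures = [
        figure1,
        figure3,
        rl.fixture_hknot(),
        rl.fixture_kissing(),
        rl.fixture_tripleknot(),
    ]
    return {s.name: rl.annotate(s) for s in structures}


def _search(collection, text):
    q = parse_query(text)
    return sorted(name for name, ann in collection.items() if q.matches(ann))


def test_signature_query(collection):
    sub = {k: collection[k] for k in ("figure1", "figure3", "kissing")}
    assert _search(sub, "signature=abAB") == ["figure1", "figure3"]
    assert _search(sub, "signature=abAcBC") == ["kissing"]
    assert _search(sub, "signature=abcdBADC@upper") == ["figure3"]


def test_loop_query():
    bulge = rl.annotate(rl.parse_dotbracket("((..((....))))"), stem_type="arbitrary")
    assert parse_query("loop=bulge").matches(bulge)
    assert not parse_query("loop=multiple_junction").matches(bulge)


def test_empty_query_matches_everything(collection):
    assert _search(collection, "") == sorted(collection)


def test_stem_count_and_pattern_queries(collection):
    assert _search(collection, "min_stems=6") == ["figure3"]
    assert _search(collection, "max_stems=2 AND signature=abAB") == ["hknot"]
    assert _search(collection, "seq=A") == sorted(collection)  # all have As
    assert _search(collection, "min_stems=6 OR max_stems=2") == [
        "figure3",
        "hknot",
    ]


def test_query_syntax_errors_carry_position():
    for text, frag in [
        ("signature", "token 1"),
        ("loop=bogus", "token 1"),
        ("signature=abAB AND", "dangling"),
        ("signature=abAB loop=bulge", "missing AND/OR"),
        ("min_stems=x", "integer"),
    ]:
        with pytest.raises(QuerySyntaxError, match=frag):
            parse_query(text)


def test_unsupported_ion_predicate_rejected_clearly():
    with pytest.raises(QuerySyntaxError, match="not"):
        parse_query("ion=Mg")


def test_dnf_semantics_on_generated_collections():
    anns = [
        rl.annotate(s)
        for s in random_structures(20, length=90, n_stems=5, pk_prob=0.4, seed0=4000)
    ]
    preds = ["signature=abAB", "loop=hairpin", "min_stems=5", "loop=pseudoknotted"]
    for p in preds:
        for q in preds:
            union = {id(a) for a in anns if parse_query(f"{p} OR {q}").matches(a)}
            sep = {id(a) for a in anns if parse_query(p).matches(a)} | {
                id(a) for a in anns if parse_query(q).matches(a)
            }
            assert union == sep
            conj = {id(a) for a in anns if parse_query(f"{p} AND {q}").matches(a)}
            assert conj <= {id(a) for a in anns if parse_query(p).matches(a)}


def test_stats_over_named_fixtures(named_fixture_anns):
    rep = collect_stats(list(named_fixture_anns.values()))
    assert rep.n_pseudoknots == 3
    assert dict(rep.signature_counts) == {"abAB": 1, "abAcBC": 1, "abcABC": 1}
    assert rep.signature_table()[0][1] == 1


def test_stats_loops_bijection(figure1_ann):
    rep = collect_stats([figure1_ann])
    assert rep.n_loops == 5 == rep.n_stems


def test_stats_empty_collection_all_zero():
    rep = collect_stats([])
    assert rep.n_structures == rep.n_stems == rep.n_loops == 0
    assert not rep.signature_counts


def test_stats_additivity(figure1_ann, figure3_ann):
    a = collect_stats([figure1_ann])
    b = collect_stats([figure3_ann])
    both = collect_stats([figure1_ann, figure3_ann])
    combined = a + b
    assert combined.n_base_pairs == both.n_base_pairs
    assert combined.loops_by_class == both.loops_by_class
    assert combined.signature_counts == both.signature_counts
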