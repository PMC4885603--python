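"""ECR decomposition: worked examples, tiling, oracle equivalence."""

import pytest

import rnaloops as rl
from rnaloops.ecr import ECRKind, all_ecrs, exterior_segments
from rnaloops.oracles import oracle_ecr_forest, oracle_ecr_intervals

from conftest import random_structures


def test_figure3_decomposition(figure3_ann):
    top = figure3_ann.ecrs
    assert [e.interval for e in top] == [(1, 31)]
    assert top[0].kind is ECRKind.PSEUDOKNOTTED
    assert [c.interval for c in top[0].children] == [(6, 16)]
    assert top[0].children[0].kind is ECRKind.CLASSICAL


def test_figure1_decomposition(figure1_ann):
    top = figure1_ann.ecrs
    assert [e.interval for e in top] == [(9, 55)]
    assert top[0].kind is ECRKind.PSEUDOKNOTTED
    kids = {c.interval: c.kind for c in top[0].children}
    assert kids == {
        (18, 31): ECRKind.PSEUDOKNOTTED,
        (34, 43): ECRKind.CLASSICAL,
    }


def test_simple_hairpin_single_classical_ecr():
    s = rl.parse_dotbracket("((..))")
    ann = rl.annotate(s, stem_type="arbitrary")
    (e,) = ann.ecrs
    assert e.interval == (1, 6)
    assert e.kind is ECRKind.CLASSICAL
    assert e.children == []


def test_classify_ecr(figure1_ann):
    stems = figure1_ann.stems
    by_interval = {e.interval: e for e in all_ecrs(figure1_ann.ecrs)}
    assert rl.classify_ecr(by_interval[(34, 43)], stems) is ECRKind.CLASSICAL
    assert rl.classify_ecr(by_interval[(18, 31)], stems) is ECRKind.PSEUDOKNOTTED
    assert rl.classify_ecr(by_interval[(9, 55)], stems) is ECRKind.PSEUDOKNOTTED


def test_pseudoknotted_bounding_faces(figure1_ann):
    top = figure1_ann.ecrs[0]
    assert top.bounding_faces == ((9, 48), (13, 55))


def test_exterior_segments(figure1):
    ann = rl.annotate(figure1)
    assert ann.exterior == [(1, 8), (56, 57)]


def _wing_positions(stems):
    return {t for h in stems for t in h.positions()}


def test_tiling_and_oracle_agreement_on_random_structures():
    for s in random_structures(60, length=110, n_stems=6, pk_prob=0.4, seed0=100):
        ann = rl.annotate(s)
        # tiling: every wing position in exactly one top-level ECR
        tops = [e.interval for e in ann.ecrs]
        for t in _wing_positions(ann.stems):
            assert sum(1 for (a, b) in tops if a <= t <= b) == 1
        # top-level ECRs disjoint and ordered
        for (a1, b1), (a2, b2) in zip(tops, tops[1:]):
            assert b1 < a2
        # oracle equivalence: intervals, kinds, and parenthood
        faces = {h.face for h in ann.stems}
        fast = {
            e.interval: e.kind.value for e in all_ecrs(ann.ecrs)
        }
        orc = {
            iv: ("classical" if iv in faces else "pseudoknotted")
            for iv in oracle_ecr_intervals(s, ann.stems)
        }
        assert fast == orc
        fast_parent = {}

        def walk(e, parent):
            fast_parent[e.interval] = parent
            for c in e.children:
                walk(c, e.interval)

        for top in ann.ecrs:
            walk(top, None)
        assert fast_parent == oracle_ecr_forest(s, ann.stems)


def test_pseudoknot_free_specialization():
    for s in random_structures(40, length=120, n_stems=6, pk_prob=0.0, seed0=300):
        ann = rl.annotate(s)
        assert all(
            e.kind is ECRKind.CLASSICAL for e in all_ecrs(ann.ecrs)
        )
        # top-level intervals are exactly the faces of outermost stems
        outer_faces = {
            h.face
            for h in ann.stems
            if not any(g != h and rl.lies_inside(h, g) for g in ann.stems)
        }
        assert {e.interval for e in ann.ecrs} == outer_faces
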