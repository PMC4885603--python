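"""Loop annotation: H-ECRs, sides/faces/wings, classification axes."""

import pytest

import rnaloops as rl
from rnaloops.ecr import ECRKind
from rnaloops.loops import FaceTag, PkClass, SizeClass
from rnaloops.oracles import oracle_h_ecr_intervals, oracle_loop_positions

from conftest import random_structures


def test_h_ecrs_of_stem_H(figure1, figure1_ann):
    H = figure1_ann.stems[0]
    hecrs = rl.find_h_ecrs(figure1, H, figure1_ann.stems)
    assert [(e.interval, e.kind) for e in hecrs] == [
        ((18, 31), ECRKind.PSEUDOKNOTTED),
        ((34, 43), ECRKind.CLASSICAL),
    ]


def test_h_ecrs_of_hairpin_stem_is_empty(figure1, figure1_ann):
    Q = figure1_ann.stems[4]
    assert rl.find_h_ecrs(figure1, Q, figure1_ann.stems) == []


def test_h_ecr_simple_nested():
    s = rl.parse_dotbracket("((..((..))..))")
    ann = rl.annotate(s, stem_type="arbitrary")
    outer = ann.stems[0]
    hecrs = rl.find_h_ecrs(s, outer, ann.stems)
    assert [(e.interval, e.kind) for e in hecrs] == [((5, 10), ECRKind.CLASSICAL)]


def test_loop_of_stem_H(figure1_ann):
    loop = figure1_ann.loops[0]
    assert [(sd.start, sd.end) for sd in loop.sides] == [
        (11, 17), (32, 33), (44, 46)
    ]
    assert [(f.i, f.j, f.tag) for f in loop.faces] == [
        (18, 31, FaceTag.PSEUDOKNOT_FACE),
        (34, 43, FaceTag.STEM_FACE),
    ]
    assert loop.wings_contained == [(13, 15)]
    assert loop.size_class is SizeClass.MULTIPLE_JUNCTION
    assert loop.pk_class is PkClass.PSEUDOKNOTTED
    # positions: sides plus face endpoints
    assert set(loop.positions) == (
        set(range(11, 19)) | set(range(31, 35)) | set(range(43, 47))
    )


def test_hairpin_loop():
    s = rl.parse_dotbracket("((((....))))")
    ann = rl.annotate(s, stem_type="arbitrary")
    (loop,) = ann.loops
    assert loop.positions == (5, 6, 7, 8)
    assert loop.faces == []
    assert len(loop.sides) == 1
    assert loop.size_class is SizeClass.HAIRPIN
    assert loop.pk_class is PkClass.CLASSICAL


def test_bulge_has_explicit_zero_length_side():
    s = rl.parse_dotbracket("((..((....))))")
    ann = rl.annotate(s, stem_type="arbitrary")
    outer_loop = ann.loops[0]
    assert [(sd.start, sd.end) for sd in outer_loop.sides] == [(3, 4), (13, 12)]
    assert [len(sd) for sd in outer_loop.sides] == [2, 0]
    assert [(f.i, f.j, f.tag) for f in outer_loop.faces] == [
        (5, 12, FaceTag.STEM_FACE)
    ]
    assert outer_loop.size_class is SizeClass.BULGE
    assert outer_loop.pk_class is PkClass.CLASSICAL


def test_internal_isolated_loop_with_pseudoknot_face():
    # owner stem encloses a pseudoknotted region but contains no wings:
    # its loop is an isolated internal loop
    s = rl.Structure(
        length=24,
        pairs=frozenset(
            [(1, 24), (2, 23)]          # owner
            + [(4, 13), (5, 12)]         # P1
            + [(8, 16), (9, 15)]         # P2 crossing P1
        ),
    )
    ann = rl.annotate(s, stem_type="arbitrary")
    owner_loop = ann.loops[0]
    assert [f.tag for f in owner_loop.faces] == [FaceTag.PSEUDOKNOT_FACE]
    assert owner_loop.wings_contained == []
    assert owner_loop.size_class is SizeClass.INTERNAL
    assert owner_loop.pk_class is PkClass.ISOLATED


def test_classify_loop_matches_stored_labels(figure1_ann):
    for loop in figure1_ann.loops:
        assert rl.classify_loop(loop) == (loop.size_class, loop.pk_class)


def test_figure1_loop_classes(figure1_ann):
    labels = [
        (l.size_class.value, l.pk_class.value) for l in figure1_ann.loops
    ]
    # stems ordered H, W, P1, P2, Q
    assert labels[0] == ("multiple_junction", "pseudoknotted")
    assert labels[4] == ("hairpin", "classical")


def test_loop_stem_bijection_and_axis_totality():
    for s in random_structures(60, length=100, n_stems=6, pk_prob=0.4, seed0=700):
        ann = rl.annotate(s)
        assert len(ann.loops) == len(ann.stems)
        assert [l.owner for l in ann.loops] == ann.stems
        for l in ann.loops:
            assert l.size_class in SizeClass
            assert l.pk_class in PkClass
            # a bulge is an internal loop with a zero-length side
            if l.size_class is SizeClass.BULGE:
                assert len(l.faces) == 1
                assert any(len(sd) == 0 for sd in l.sides)


def test_two_loop_definitions_agree_on_random_structures():
    """'Belongs' rule == [r+1, s-1] minus H-ECR interiors plus boundaries."""
    for s in random_structures(60, length=100, n_stems=6, pk_prob=0.4, seed0=900):
        ann = rl.annotate(s)
        for h, loop in zip(ann.stems, ann.loops):
            r, sp = h.internal_pair
            hecrs = rl.find_h_ecrs(s, h, ann.stems)
            expected = set(range(r + 1, sp))
            for e in hecrs:
                expected -= set(range(e.interval[0] + 1, e.interval[1]))
            assert set(loop.positions) == expected
            assert set(loop.positions) == oracle_loop_positions(s, h, ann.stems)
            assert sorted(e.interval for e in hecrs) == oracle_h_ecr_intervals(
                s, h, ann.stems
            )
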