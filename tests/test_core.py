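"""Pair typing, stem detection, crossing and containment predicates."""

import pytest

import rnaloops as rl
from rnaloops.core import PairClass, Stem, StemType, find_stems

from conftest import random_structures


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("G", "C", PairClass.WATSON_CRICK),
        ("A", "U", PairClass.WATSON_CRICK),
        ("U", "G", PairClass.WOBBLE),
        ("G", "U", PairClass.WOBBLE),
        ("A", "G", PairClass.OTHER),
        ("N", "C", PairClass.OTHER),
    ],
)
def test_classify_pair(a, b, expected):
    assert rl.classify_pair(a, b) is expected
    assert rl.classify_pair(b, a) is expected  # symmetric


def test_find_stems_figure3_faces(figure3):
    stems, isolated = find_stems(figure3)
    assert isolated == []
    assert [h.face for h in stems] == [
        (1, 26), (4, 23), (6, 16), (9, 13), (17, 31), (20, 28)
    ]


def test_find_stems_single_run_and_isolated():
    s = rl.Structure(length=6, pairs={(1, 6), (2, 5), (3, 4)})
    stems, isolated = find_stems(s, stem_type="arbitrary")
    assert len(stems) == 1 and stems[0].k == 2
    assert isolated == []

    s2 = rl.Structure(length=10, pairs={(1, 10)})
    stems2, isolated2 = find_stems(s2, stem_type="arbitrary")
    assert stems2 == [] and isolated2 == [(1, 10)]


def test_find_stems_rejects_min_pairs_below_two(figure3):
    with pytest.raises(ValueError, match="min_pairs"):
        find_stems(figure3, min_pairs=1)


def test_find_stems_without_sequence_warns_and_falls_back():
    s = rl.Structure(length=6, pairs={(1, 6), (2, 5)})
    with pytest.warns(UserWarning, match="arbitrary"):
        stems, _ = find_stems(s, stem_type="standard")
    assert stems[0].stem_type is StemType.ARBITRARY


def test_standard_stems_exclude_noncomplementary_pairs():
    # (3,8) is A-A: ineligible for standard stems, splitting the stack
    s = rl.Structure(
        length=10,
        pairs={(1, 10), (2, 9), (3, 8), (4, 7)},
        sequence="GCAAAAUAGC",
    )
    stems, isolated = find_stems(s, stem_type="standard")
    assert [h.face for h in stems] == [(1, 10)]
    assert isolated == [(4, 7)]


def test_stem_anatomy():
    h = Stem(pairs=((9, 48), (10, 47)))
    assert h.face == (9, 48)
    assert h.internal_pair == (10, 47)
    assert h.left_wing == (9, 10) and h.right_wing == (47, 48)
    assert h.k == 1


@pytest.mark.parametrize(
    "pair,face,expected",
    [
        ((13, 55), (9, 48), True),   # 9 < 13 < 48 < 55
        ((18, 26), (9, 48), False),  # nested
        ((5, 20), (10, 30), True),   # 5 < 10 < 20 < 30
        ((5, 8), (10, 30), False),   # disjoint
    ],
)
def test_crosses(pair, face, expected):
    h = Stem(pairs=(face, (face[0] + 1, face[1] - 1)))
    assert rl.crosses(pair, h) is expected


def test_containment_predicates(figure1_ann):
    H, W, Q = figure1_ann.stems[0], figure1_ann.stems[1], figure1_ann.stems[4]
    assert rl.lies_inside(Q, H)
    assert not rl.lies_inside(W, H)  # W crosses H, right wing outside
    assert not rl.lies_inside(H, H)
    assert rl.position_internal(34, H) and not rl.position_internal(10, H)


def _brute_force_runs(pairs, min_pairs=2):
    """All maximal diagonal runs in the pair matrix."""
    ps = set(pairs)
    runs = []
    for (i, j) in sorted(ps):
        if (i - 1, j + 1) in ps:
            continue
        run = [(i, j)]
        while (run[-1][0] + 1, run[-1][1] - 1) in ps:
            run.append((run[-1][0] + 1, run[-1][1] - 1))
        if len(run) >= min_pairs:
            runs.append(tuple(run))
    return sorted(runs)


def test_stem_detection_matches_brute_force_and_conserves_pairs():
    for s in random_structures(500, length=80, n_stems=5, pk_prob=0.3, seed0=0):
        stems, isolated = find_stems(s)
        assert sorted(h.pairs for h in stems) == _brute_force_runs(s.pairs)
        # conservation: stem pairs + isolated pairs = eligible pair set
        covered = {p for h in stems for p in h.pairs} | set(isolated)
        assert covered == set(s.pairs)
        # maximality: probing one pair outward/inward leaves the pair set
        for h in stems:
            (i, j), (a, b) = h.face, h.internal_pair
            assert (i - 1, j + 1) not in s.pairs
            assert (a + 1, b - 1) not in s.pairs
        # stems are position-disjoint
        seen = set()
        for h in stems:
            pos = h.positions()
            assert not pos & seen
            seen |= pos
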