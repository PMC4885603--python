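"""Tertiary-interaction taxonomy: element mapping, labels, tabulation."""

import pytest

import rnaloops as rl
from rnaloops.structure import TertiaryPair
from rnaloops.tertiary import (
    Context,
    ElementKind,
    Locality,
    StructureType,
    tabulate_interactions,
)


def test_element_of_priority_rule(figure1_ann):
    e35 = rl.element_of(35, figure1_ann)
    assert e35.kind is ElementKind.HELIX and e35.id == 4  # Q's left wing
    e33 = rl.element_of(33, figure1_ann)
    assert e33.kind is ElementKind.LOOP and e33.id == 0  # side 32-33 of H
    e5 = rl.element_of(5, figure1_ann)
    assert e5.kind is ElementKind.EXTERIOR
    # wing inside another stem's loop is helix under the default priority
    e13 = rl.element_of(13, figure1_ann)
    assert e13.kind is ElementKind.HELIX and e13.id == 1  # W's wing
    # ... and loop under --loop-priority
    e13_inv = rl.element_of(13, figure1_ann, loop_priority=True)
    assert e13_inv.kind is ElementKind.LOOP


def test_element_of_out_of_range(figure1_ann):
    with pytest.raises(ValueError, match="outside"):
        rl.element_of(99, figure1_ann)


@pytest.mark.parametrize(
    "pair,st,loc,ctx",
    [
        ((37, 39), StructureType.LL, Locality.LOCAL, Context.CLASSICAL),
        ((35, 38), StructureType.HL, Locality.LOCAL, Context.CLASSICAL),
        ((12, 45), StructureType.LL, Locality.LOCAL, Context.PSEUDOKNOT),
    ],
)
def test_classify_interaction_figure1_examples(figure1_ann, pair, st, loc, ctx):
    lab = rl.classify_interaction(TertiaryPair(*pair), figure1_ann)
    assert lab.structure_type is st
    assert lab.locality is loc
    assert lab.context is ctx


def test_label_invariant_under_endpoint_swap(figure1_ann):
    for (i, j) in [(12, 45), (35, 38), (10, 36), (5, 50)]:
        a = rl.classify_interaction(TertiaryPair(i, j), figure1_ann)
        b = rl.classify_interaction(TertiaryPair(j, i), figure1_ann)
        assert a == b


def test_same_element_is_always_local(figure1_ann):
    # both endpoints in Q's hairpin loop / in one exterior segment
    for (i, j) in [(37, 40), (38, 39), (2, 6)]:
        lab = rl.classify_interaction(TertiaryPair(i, j), figure1_ann)
        assert lab.locality is Locality.LOCAL


def test_stem_loop_adjacency_cases(figure1_ann):
    # H's loop contains Q's face among its faces -> Q vs loop(H) is local
    lab = rl.classify_interaction(TertiaryPair(11, 36), figure1_ann)
    assert lab.structure_type is StructureType.HL
    assert lab.locality is Locality.LOCAL
    # H's loop contains W's wing 13-15 -> W vs loop(H) is local
    lab = rl.classify_interaction(TertiaryPair(17, 54), figure1_ann)
    assert lab.structure_type is StructureType.HL
    assert lab.locality is Locality.LOCAL


def test_long_range_between_distant_elements(figure1_ann):
    # W's wing vs Q's hairpin loop: none of the adjacency cases applies
    lab = rl.classify_interaction(TertiaryPair(13, 38), figure1_ann)
    assert lab.structure_type is StructureType.HL
    assert lab.locality is Locality.LONG_RANGE


def test_tabulate_counts_and_fraction_blocks(figure1):
    s = rl.Structure(
        length=figure1.length,
        pairs=figure1.pairs,
        sequence=figure1.sequence,
        tertiary_pairs=[
            TertiaryPair(37, 39),
            TertiaryPair(35, 38),
            TertiaryPair(12, 45),
        ],
        name="figure1",
    )
    ann = rl.annotate(s)
    table = tabulate_interactions([ann])
    assert table.total == 3
    assert table.counts.loc[("pseudoknot", "local"), "LL"] == 1
    assert table.counts.loc[("classical", "local"), "LL"] == 1
    assert table.counts.loc[("classical", "local"), "HL"] == 1
    # each nonempty row of the structure-type block sums to 100
    sums = table.fractions_of_structure_types.sum(axis=1)
    occupied = table.counts.sum(axis=1) > 0
    assert (abs(sums[occupied] - 100.0) < 1e-9).all()
    # each nonempty column of the pair-type block sums to 100
    csums = table.fractions_of_pair_types.sum(axis=0)
    coccupied = table.counts.sum(axis=0) > 0
    assert (abs(csums[coccupied] - 100.0) < 1e-9).all()
    # duplicated collection doubles every count
    doubled = tabulate_interactions([ann, ann])
    assert (doubled.counts == 2 * table.counts).all().all()


def test_tabulate_empty_collection_is_all_zero():
    table = tabulate_interactions([])
    assert table.total == 0
    assert (table.counts == 0).all().all()
    assert (table.fractions_of_structure_types == 0).all().all()
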