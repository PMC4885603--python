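"""Tertiary-interaction taxonomy over the secondary-structure annotation.

Each tertiary pair is labeled on three axes:

* **structure type** — Helix-Helix (HH), Helix-Loop (HL) or Loop-Loop
  (LL), from the secondary elements its two endpoints fall in (a stem
  wing position counts as helix; an exterior position counts as loop for
  typing and is flagged);
* **locality** — *local* when both endpoints are in the same element or
  in a stem and a loop adjacent to it; *long-range* otherwise;
* **context** — *pseudoknot* when the innermost ECR enclosing either
  endpoint is pseudoknotted, else *classical*.

The Leontis-Westhof class is carried through verbatim from input.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .annotate import Annotation
from .core import Stem
from .ecr import ECRKind, all_ecrs
from .structure import TertiaryPair

__all__ = [
    "ElementKind",
    "ElementRef",
    "StructureType",
    "Locality",
    "Context",
    "InteractionLabel",
    "element_of",
    "classify_interaction",
    "tabulate_interactions",
    "InteractionTable",
]


class ElementKind(str, Enum):
    HELIX = "helix"
    LOOP = "loop"
    EXTERIOR = "exterior"


class StructureType(str, Enum):
    HH = "HH"
    HL = "HL"
    LL = "LL"


class Locality(str, Enum):
    LOCAL = "local"
    LONG_RANGE = "long_range"


class Context(str, Enum):
    PSEUDOKNOT = "pseudoknot"
    CLASSICAL = "classical"


@dataclass(frozen=True)
class ElementRef:
    """The secondary element a position maps to.

    ``id`` is the stem index (helix), the owner-stem index (loop) or the
    exterior-segment index.
    """

    kind: ElementKind
    id: int


@dataclass(frozen=True)
class InteractionLabel:
    structure_type: StructureType
    locality: Locality
    context: Context
    lw_class: str | None = None
    involves_exterior: bool = False


def element_of(
    t: int, ann: Annotation, loop_priority: bool = False
) -> ElementRef:
    """Map position ``t`` to its element under the priority rule.

    Default priority: stem-wing position -> helix (even when the wing sits
    inside another stem's loop); otherwise the loop containing ``t``;
    otherwise the exterior segment.  In pseudoknotted structures loops of
    crossing stems overlap, so "the" loop is made deterministic by taking
    the owner with the smallest internal-pair span (tie: leftmost).
    ``loop_priority=True`` inverts helix/loop priority for sensitivity
    analysis.
    """
    if not 1 <= t <= ann.structure.length:
        raise ValueError(f"position {t} outside chain of length {ann.structure.length}")

    def wing_owner() -> int | None:
        for k, h in enumerate(ann.stems):
            lw, rw = h.wings
            if lw[0] <= t <= lw[1] or rw[0] <= t <= rw[1]:
                return k
        return None

    def loop_owner() -> int | None:
        best: tuple[int, int, int] | None = None  # (span, r, index)
        for k, (l, pos) in enumerate(zip(ann.loops, ann.loop_position_sets())):
            if t in pos:
                r, s = l.owner.internal_pair
                key = (s - r, r, k)
                if best is None or key < best:
                    best = key
        return None if best is None else best[2]

    first, second = (loop_owner, wing_owner) if loop_priority else (wing_owner, loop_owner)
    kinds = (
        (ElementKind.LOOP, ElementKind.HELIX)
        if loop_priority
        else (ElementKind.HELIX, ElementKind.LOOP)
    )
    for probe, kind in zip((first, second), kinds):
        owner = probe()
        if owner is not None:
            return ElementRef(kind=kind, id=owner)
    for k, (a, b) in enumerate(ann.exterior):
        if a <= t <= b:
            return ElementRef(kind=ElementKind.EXTERIOR, id=k)
    # inside an ECR but in no wing and no loop cannot happen; treat as
    # exterior-like fallback for robustness
    return ElementRef(kind=ElementKind.EXTERIOR, id=-1)


def _stem_loop_adjacent(stem_id: int, loop_id: int, ann: Annotation) -> bool:
    """Adjacency between a stem and a loop (three constructive cases)."""
    if stem_id == loop_id:
        return True  # the stem's own loop
    stem: Stem = ann.stems[stem_id]
    loop = ann.loops[loop_id]
    if any((f.i, f.j) == stem.face for f in loop.faces):
        return True  # loop has the stem's face among its faces
    if any(w in loop.wings_contained for w in stem.wings):
        return True  # a wing of the stem lies in the loop
    return False


def _innermost_context(t: int, ann: Annotation) -> ECRKind | None:
    best = None
    best_span = None
    for e in all_ecrs(ann.ecrs):
        i, j = e.interval
        if i <= t <= j and (best_span is None or j - i < best_span):
            best, best_span = e, j - i
    return None if best is None else best.kind


def classify_interaction(
    p: TertiaryPair, ann: Annotation, loop_priority: bool = False
) -> InteractionLabel:
    """Label one tertiary pair; symmetric in its endpoints."""
    e1 = element_of(p.i, ann, loop_priority=loop_priority)
    e2 = element_of(p.j, ann, loop_priority=loop_priority)
    involves_exterior = ElementKind.EXTERIOR in (e1.kind, e2.kind)
    # exterior counts as loop for the HH/HL/LL axis
    k1 = ElementKind.LOOP if e1.kind is ElementKind.EXTERIOR else e1.kind
    k2 = ElementKind.LOOP if e2.kind is ElementKind.EXTERIOR else e2.kind
    if k1 is ElementKind.HELIX and k2 is ElementKind.HELIX:
        st = StructureType.HH
    elif k1 is ElementKind.LOOP and k2 is ElementKind.LOOP:
        st = StructureType.LL
    else:
        st = StructureType.HL

    if e1 == e2:
        loc = Locality.LOCAL
    elif {e1.kind, e2.kind} == {ElementKind.HELIX, ElementKind.LOOP}:
        helix, loop = (e1, e2) if e1.kind is ElementKind.HELIX else (e2, e1)
        loc = (
            Locality.LOCAL
            if _stem_loop_adjacent(helix.id, loop.id, ann)
            else Locality.LONG_RANGE
        )
    else:
        loc = Locality.LONG_RANGE

    c1 = _innermost_context(p.i, ann)
    c2 = _innermost_context(p.j, ann)
    context = (
        Context.PSEUDOKNOT
        if ECRKind.PSEUDOKNOTTED in (c1, c2)
        else Context.CLASSICAL
    )
    return InteractionLabel(
        structure_type=st,
        locality=loc,
        context=context,
        lw_class=p.lw_class,
        involves_exterior=involves_exterior,
    )


_ROWS = [
    (Context.PSEUDOKNOT.value, Locality.LOCAL.value),
    (Context.PSEUDOKNOT.value, Locality.LONG_RANGE.value),
    (Context.CLASSICAL.value, Locality.LOCAL.value),
    (Context.CLASSICAL.value, Locality.LONG_RANGE.value),
]
_COLS = [StructureType.HH.value, StructureType.HL.value, StructureType.LL.value]


@dataclass
class InteractionTable:
    """Contingency table of tertiary interactions.

    ``counts``: rows (context, locality), columns HH/HL/LL.
    ``fractions_of_structure_types``: each row renormalized to 100%
    across HH/HL/LL.  ``fractions_of_pair_types``: each column
    renormalized to 100% across (context, locality) rows.
    """

    counts: pd.DataFrame
    fractions_of_structure_types: pd.DataFrame
    fractions_of_pair_types: pd.DataFrame

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


def tabulate_interactions(
    annotations: list[Annotation], loop_priority: bool = False
) -> InteractionTable:
    """Count labeled tertiary pairs across a collection of structures."""
    index = pd.MultiIndex.from_tuples(_ROWS, names=["context", "locality"])
    counts = pd.DataFrame(0, index=index, columns=_COLS, dtype=int)
    for ann in annotations:
        for tp in ann.structure.tertiary_pairs:
            lab = classify_interaction(tp, ann, loop_priority=loop_priority)
            counts.loc[
                (lab.context.value, lab.locality.value), lab.structure_type.value
            ] += 1
    row_tot = counts.sum(axis=1)
    col_tot = counts.sum(axis=0)
    frac_struct = counts.div(row_tot.where(row_tot > 0), axis=0) * 100.0
    frac_pair = counts.div(col_tot.where(col_tot > 0), axis=1) * 100.0
    return InteractionTable(
        counts=counts,
        fractions_of_structure_types=frac_struct.fillna(0.0),
        fractions_of_pair_types=frac_pair.fillna(0.0),
    )
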