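"""Pseudoknot-aware loop annotation.

The loop of a stem ``H`` with internal pair ``(r, s)`` is the set of
positions that *belong* to ``H``: positions strictly inside ``(r, s)``
that are not strictly inside the face of any stem lying inside ``H``.
Equivalently, it is the fragment ``[r+1, s-1]`` with the interiors of
``H``-related elementary closed regions (H-ECRs) removed; the boundary
pairs of those excluded regions — their *faces* — are kept as part of the
loop.  Faces split the loop into *sides* (possibly of zero length).

Every stem has exactly one loop.  Two classification axes apply:

* size: *hairpin* (no faces), *internal* (one face; a *bulge* when one
  side has zero length), *multiple junction* (two or more faces);
* pseudoknot status: *pseudoknotted* when the loop contains a wing of a
  stem crossing its owner; *isolated* when it contains no wings;
  *classical* when it contains neither wings nor pseudoknot faces (so
  every classical loop is also isolated).

On pseudoknot-free structures this loop decomposition coincides with the
classical Nearest-Neighbor-Model decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .core import Stem, lies_inside, position_internal
from .ecr import ECRKind
from .structure import Structure

__all__ = [
    "FaceTag",
    "SizeClass",
    "PkClass",
    "HECR",
    "LoopFace",
    "Side",
    "Loop",
    "find_h_ecrs",
    "loop_of",
    "classify_loop",
]


class FaceTag(str, Enum):
    STEM_FACE = "stem_face"
    PSEUDOKNOT_FACE = "pseudoknot_face"


class SizeClass(str, Enum):
    HAIRPIN = "hairpin"
    INTERNAL = "internal"
    BULGE = "bulge"
    MULTIPLE_JUNCTION = "multiple_junction"


class PkClass(str, Enum):
    CLASSICAL = "classical"
    ISOLATED = "isolated"
    PSEUDOKNOTTED = "pseudoknotted"


@dataclass(frozen=True)
class HECR:
    """An elementary closed region relative to the interior of a stem."""

    owner: Stem
    interval: tuple[int, int]
    kind: ECRKind


@dataclass(frozen=True)
class LoopFace:
    """A boundary pair of an excluded H-ECR, kept as part of the loop."""

    i: int
    j: int
    tag: FaceTag


@dataclass(frozen=True)
class Side:
    """A maximal run of loop positions between two delimiters.

    ``start > end`` encodes a zero-length side anchored between its two
    delimiters (``start - 1`` and ``end + 1``), which is what makes bulges
    detectable.
    """

    start: int
    end: int

    def __len__(self) -> int:
        return max(0, self.end - self.start + 1)

    def positions(self) -> range:
        return range(self.start, self.end + 1)


@dataclass
class Loop:
    owner: Stem
    positions: tuple[int, ...]
    sides: list[Side]
    faces: list[LoopFace]
    wings_contained: list[tuple[int, int]]
    size_class: SizeClass
    pk_class: PkClass


class LoopConsistencyError(AssertionError):
    """A wing overlaps a loop only partially — pathological input."""


def _h_closed(i: int, j: int, r: int, s: int, pairs) -> bool:
    """H-relative closure: no pair with one endpoint in [i, j] and the
    other strictly inside (r, s) but outside [i, j]."""
    for a, b in pairs:
        a_in = i <= a <= j
        b_in = i <= b <= j
        if a_in == b_in:
            continue
        out = b if a_in else a
        if r < out < s:
            return False
    return True


def _satisfies_h_ecr_conditions(
    i: int, j: int, r: int, s: int, pairs, faces, partner
) -> bool:
    if not (r < i < j < s):
        return False
    if not _h_closed(i, j, r, s, pairs):
        return False
    if (i, j) not in faces:
        x = partner.get(i)
        y = partner.get(j)
        if x is None or y is None or not (i < x < j) or not (i < y < j):
            return False
        if (i, x) not in faces or (y, j) not in faces:
            return False
    for t in range(i + 1, j):
        if _h_closed(i, t, r, s, pairs) or _h_closed(t, j, r, s, pairs):
            return False
    return True


def find_h_ecrs(s: Structure, h: Stem, stems: list[Stem]) -> list[HECR]:
    """Outermost H-ECRs inside stem ``h``, left to right.

    Closure is relative to the interior of ``h``'s internal pair
    ``(r, s)``: a pair reaching from inside a candidate to *outside*
    ``(r, s)`` entirely (a crossing-stem wing) does not break closure,
    which is exactly why wings can end up inside loops.
    """
    r, sp = h.internal_pair
    partner: dict[int, int] = {}
    for g in stems:
        for a, b in g.pairs:
            partner[a] = b
            partner[b] = a
    faces = {g.face for g in stems}
    pairs = [p for g in stems for p in g.pairs]
    out: list[HECR] = []
    cursor = r
    for i in sorted(g.face[0] for g in stems):
        if i <= cursor or i >= sp:
            continue
        x = partner[i]
        if not (r < x < sp):
            continue  # paired out of h's interior: cannot anchor an H-ECR
        # expand the minimal H-closed interval anchored at i
        j = x
        p = i
        ok = True
        while p <= j:
            q = partner.get(p)
            if q is not None and r < q < sp:
                if q < i:
                    ok = False
                    break
                if q > j:
                    j = q
            p += 1
        if not ok or j >= sp:
            continue
        if not _satisfies_h_ecr_conditions(i, j, r, sp, pairs, faces, partner):
            continue
        kind = ECRKind.CLASSICAL if (i, j) in faces else ECRKind.PSEUDOKNOTTED
        out.append(HECR(owner=h, interval=(i, j), kind=kind))
        cursor = j
    return out


def _belongs(t: int, h: Stem, inside_stems: list[Stem]) -> bool:
    if not position_internal(t, h):
        return False
    return not any(g.face[0] < t < g.face[1] for g in inside_stems)


def loop_of(s: Structure, h: Stem, stems: list[Stem]) -> Loop:
    """The loop of stem ``h``: positions, faces, sides, wings, both labels."""
    r, sp = h.internal_pair
    inside_stems = [g for g in stems if lies_inside(g, h)]
    positions = tuple(
        t for t in range(r + 1, sp) if _belongs(t, h, inside_stems)
    )
    pos_set = set(positions)

    hecrs = find_h_ecrs(s, h, stems)
    faces = [
        LoopFace(
            i=e.interval[0],
            j=e.interval[1],
            tag=(
                FaceTag.STEM_FACE
                if e.kind is ECRKind.CLASSICAL
                else FaceTag.PSEUDOKNOT_FACE
            ),
        )
        for e in hecrs
    ]

    # sides: runs of loop positions between consecutive delimiters
    # r, f1.i, f1.j, f2.i, ..., s  (side between fk.i and fk.j is the
    # excluded region's interior, not part of the loop)
    delimiters = [r]
    for f in faces:
        delimiters.extend((f.i, f.j))
    delimiters.append(sp)
    sides = [
        Side(start=delimiters[k] + 1, end=delimiters[k + 1] - 1)
        for k in range(0, len(delimiters) - 1, 2)
    ]
    side_positions = {t for side in sides for t in side.positions()}
    face_endpoints = {t for f in faces for t in (f.i, f.j)}
    if side_positions | face_endpoints != pos_set:
        raise LoopConsistencyError(
            f"loop of {h}: sides+faces {sorted(side_positions | face_endpoints)} "
            f"!= belongs-rule positions {sorted(pos_set)}"
        )

    wings_contained: list[tuple[int, int]] = []
    for g in stems:
        if g == h or lies_inside(g, h):
            continue
        for wing in g.wings:
            wpos = set(range(wing[0], wing[1] + 1))
            if wpos <= pos_set:
                wings_contained.append(wing)
            elif wpos & pos_set:
                raise LoopConsistencyError(
                    f"wing {wing} of {g} lies only partially in the loop of {h}"
                )
    wings_contained.sort()

    n_faces = len(faces)
    if n_faces == 0:
        size_class = SizeClass.HAIRPIN
    elif n_faces == 1:
        size_class = (
            SizeClass.BULGE
            if any(len(side) == 0 for side in sides)
            else SizeClass.INTERNAL
        )
    else:
        size_class = SizeClass.MULTIPLE_JUNCTION

    if wings_contained:
        pk_class = PkClass.PSEUDOKNOTTED
    elif any(f.tag is FaceTag.PSEUDOKNOT_FACE for f in faces):
        pk_class = PkClass.ISOLATED
    else:
        pk_class = PkClass.CLASSICAL

    return Loop(
        owner=h,
        positions=positions,
        sides=sides,
        faces=faces,
        wings_contained=wings_contained,
        size_class=size_class,
        pk_class=pk_class,
    )


def classify_loop(l: Loop) -> tuple[SizeClass, PkClass]:
    """Both classification labels, recomputed from the loop's contents."""
    n_faces = len(l.faces)
    if n_faces == 0:
        size = SizeClass.HAIRPIN
    elif n_faces == 1:
        size = (
            SizeClass.BULGE
            if any(len(side) == 0 for side in l.sides)
            else SizeClass.INTERNAL
        )
    else:
        size = SizeClass.MULTIPLE_JUNCTION
    if l.wings_contained:
        pk = PkClass.PSEUDOKNOTTED
    elif any(f.tag is FaceTag.PSEUDOKNOT_FACE for f in l.faces):
        pk = PkClass.ISOLATED
    else:
        pk = PkClass.CLASSICAL
    return size, pk
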