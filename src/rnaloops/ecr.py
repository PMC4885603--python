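"""Elementary closed region (ECR) decomposition.

A *closed region* ``[i, j]`` is an interval no base pair of which connects
its inside to its outside; it is *elementary* when no position ``t`` splits
it into a smaller closed prefix ``[i, t]`` or suffix ``[t, j]``, and its
ends must be anchored on stem faces: either ``(i, j)`` itself is a stem
face (a *classical* ECR) or there are positions ``x, y`` inside with
``(i, x)`` and ``(y, j)`` faces of two stems (a *pseudoknotted* ECR, i.e.
a pseudoknot).

Only pairs that belong to detected stems participate; isolated pairs are
excluded upstream.  An ECR ``[k, l]`` is a *nested* ECR (child) of
``[i, j]`` when ``i < k < l < j`` with no intermediate ECR between them.

The fast path finds each ECR by left-to-right expansion of minimal closed
intervals anchored at stem-face left ends, recursing into each found
interval for its children; every emitted interval is re-checked against
the four defining conditions.  An independent brute-force oracle lives in
:mod:`rnaloops.oracles`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .core import Stem
from .structure import Structure

__all__ = ["ECRKind", "ECR", "find_ecrs", "classify_ecr", "all_ecrs", "exterior_segments"]


class ECRKind(str, Enum):
    CLASSICAL = "classical"
    PSEUDOKNOTTED = "pseudoknotted"


@dataclass
class ECR:
    """An elementary closed region with its nested subtree."""

    interval: tuple[int, int]
    kind: ECRKind
    bounding_faces: tuple[tuple[int, int], ...]
    member_stems: list[Stem] = field(default_factory=list)
    children: list["ECR"] = field(default_factory=list)

    @property
    def i(self) -> int:
        return self.interval[0]

    @property
    def j(self) -> int:
        return self.interval[1]

    def walk(self):
        """Yield this ECR and every descendant, depth-first."""
        yield self
        for c in self.children:
            yield from c.walk()

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"ECR[{self.i},{self.j}]({self.kind.value})"


def _stem_pair_maps(stems: list[Stem]):
    partner: dict[int, int] = {}
    for h in stems:
        for a, b in h.pairs:
            partner[a] = b
            partner[b] = a
    faces = {h.face for h in stems}
    face_left = sorted(h.face[0] for h in stems)
    return partner, faces, face_left


def _is_closed(i: int, j: int, pairs) -> bool:
    """No pair with exactly one endpoint in [i, j]."""
    for a, b in pairs:
        if (i <= a <= j) != (i <= b <= j):
            return False
    return True


def _satisfies_ecr_conditions(i: int, j: int, pairs, faces, partner) -> bool:
    """Literal check of the four ECR conditions over the stem pair set."""
    if not i < j:
        return False
    if not _is_closed(i, j, pairs):
        return False
    # boundary-face condition
    if (i, j) not in faces:
        x = partner.get(i)
        y = partner.get(j)
        if x is None or y is None or not (i < x < j) or not (i < y < j):
            return False
        if (i, x) not in faces or (y, j) not in faces:
            return False
    # elementarity: no closed proper prefix/suffix
    for t in range(i + 1, j):
        if _is_closed(i, t, pairs) or _is_closed(t, j, pairs):
            return False
    return True


def _expand(start: int, partner: dict[int, int], lo: int, hi: int) -> int | None:
    """Minimal closed interval [start, j] with lo < start < j < hi, or None.

    Grows ``j`` while some position in the interval is paired past it; a
    pair pointing left of ``start`` (inside the open bound) rules out any
    closed interval anchored at ``start``.
    """
    j = partner[start]
    if j < start:
        return None
    p = start
    while p <= j:
        q = partner.get(p)
        if q is not None:
            if q < start:
                return None
            if q > j:
                j = q
                if j >= hi:
                    return None
        p += 1
    return j if j < hi else None


def _scan(lo: int, hi: int, partner, faces, face_left, pairs, stems) -> list[ECR]:
    """Find ECRs strictly inside the open interval (lo, hi), outermost first."""
    found: list[ECR] = []
    cursor = lo
    for i in face_left:
        if i <= cursor or i >= hi:
            continue
        j = _expand(i, partner, lo, hi)
        if j is None:
            continue
        if not _satisfies_ecr_conditions(i, j, pairs, faces, partner):
            continue
        kind = ECRKind.CLASSICAL if (i, j) in faces else ECRKind.PSEUDOKNOTTED
        if kind is ECRKind.CLASSICAL:
            bounding = ((i, j),)
        else:
            bounding = ((i, partner[i]), (partner[j], j))
        members = [
            h for h in stems
            if i <= h.left_wing[0] and h.right_wing[1] <= j
        ]
        children = _scan(i, j, partner, faces, face_left, pairs, stems)
        found.append(
            ECR(
                interval=(i, j),
                kind=kind,
                bounding_faces=bounding,
                member_stems=members,
                children=children,
            )
        )
        cursor = j
    return found


def find_ecrs(s: Structure, stems: list[Stem]) -> list[ECR]:
    """Decompose the structure into its forest of ECRs.

    Returns the top-level ECRs sorted left to right, each carrying its
    nested subtree.  Every position covered by a stem wing lies in exactly
    one top-level ECR; unpaired linkers and dangling ends outside all
    top-level ECRs are *exterior* (see :func:`exterior_segments`).
    """
    partner, faces, face_left = _stem_pair_maps(stems)
    pairs = [p for h in stems for p in h.pairs]
    return _scan(0, s.length + 1, partner, faces, face_left, pairs, stems)


def classify_ecr(e: ECR, stems: list[Stem]) -> ECRKind:
    """Classical iff the ECR's bounding interval is itself a stem face."""
    return (
        ECRKind.CLASSICAL
        if any(h.face == e.interval for h in stems)
        else ECRKind.PSEUDOKNOTTED
    )


def all_ecrs(top: list[ECR]) -> list[ECR]:
    """Flatten a top-level ECR list into all ECRs, depth-first."""
    return [e for t in top for e in t.walk()]


def exterior_segments(s: Structure, top: list[ECR]) -> list[tuple[int, int]]:
    """Maximal runs of positions outside every top-level ECR interval."""
    covered = [False] * (s.length + 2)
    for e in top:
        for t in range(e.i, e.j + 1):
            covered[t] = True
    segments: list[tuple[int, int]] = []
    start = None
    for t in range(1, s.length + 1):
        if not covered[t]:
            if start is None:
                start = t
        elif start is not None:
            segments.append((start, t - 1))
            start = None
    if start is not None:
        segments.append((start, s.length))
    return segments
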