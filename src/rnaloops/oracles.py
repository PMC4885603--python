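"""Brute-force reference implementations used as independent oracles.

Everything here applies the defining conditions literally, by exhaustive
enumeration, with no shared machinery with the fast paths in
:mod:`rnaloops.ecr`, :mod:`rnaloops.loops` and :mod:`rnaloops.signatures`.
Intended for structures up to a few hundred nucleotides.
"""

from __future__ import annotations

from .core import Stem
from .structure import Structure

__all__ = [
    "oracle_ecr_intervals",
    "oracle_ecr_forest",
    "oracle_h_ecr_intervals",
    "oracle_loop_positions",
    "oracle_signature_words",
    "oracle_nnm_loops",
]


def _pairs_of(stems: list[Stem]) -> list[tuple[int, int]]:
    return [p for h in stems for p in h.pairs]


def _closed(i: int, j: int, pairs) -> bool:
    return all(((i <= a <= j) == (i <= b <= j)) for a, b in pairs)


def oracle_ecr_intervals(s: Structure, stems: list[Stem]) -> list[tuple[int, int]]:
    """Every interval satisfying the four ECR conditions, by full scan."""
    pairs = _pairs_of(stems)
    faces = {h.face for h in stems}
    partner = {}
    for a, b in pairs:
        partner[a] = b
        partner[b] = a
    out = []
    for i in range(1, s.length + 1):
        for j in range(i + 1, s.length + 1):
            if not _closed(i, j, pairs):
                continue
            if (i, j) not in faces:
                x, y = partner.get(i), partner.get(j)
                if (
                    x is None
                    or y is None
                    or not (i < x < j)
                    or not (i < y < j)
                    or (i, x) not in faces
                    or (y, j) not in faces
                ):
                    continue
            if any(
                _closed(i, t, pairs) or _closed(t, j, pairs)
                for t in range(i + 1, j)
            ):
                continue
            out.append((i, j))
    return out


def oracle_ecr_forest(
    s: Structure, stems: list[Stem]
) -> dict[tuple[int, int], tuple[int, int] | None]:
    """Map each ECR interval to its immediate parent (None for top level)."""
    intervals = oracle_ecr_intervals(s, stems)
    parent: dict[tuple[int, int], tuple[int, int] | None] = {}
    for iv in intervals:
        enclosing = [
            other
            for other in intervals
            if other != iv and other[0] < iv[0] and iv[1] < other[1]
        ]
        parent[iv] = min(enclosing, key=lambda o: o[1] - o[0]) if enclosing else None
    return parent


def oracle_h_ecr_intervals(
    s: Structure, h: Stem, stems: list[Stem]
) -> list[tuple[int, int]]:
    """Outermost intervals satisfying the H-ECR conditions, by full scan."""
    r, sp = h.internal_pair
    pairs = _pairs_of(stems)
    faces = {g.face for g in stems}
    partner = {}
    for a, b in pairs:
        partner[a] = b
        partner[b] = a

    def h_closed(i: int, j: int) -> bool:
        for a, b in pairs:
            a_in, b_in = i <= a <= j, i <= b <= j
            if a_in != b_in and r < (b if a_in else a) < sp:
                return False
        return True

    found = []
    for i in range(r + 1, sp):
        for j in range(i + 1, sp):
            if not h_closed(i, j):
                continue
            if (i, j) not in faces:
                x, y = partner.get(i), partner.get(j)
                if (
                    x is None
                    or y is None
                    or not (i < x < j)
                    or not (i < y < j)
                    or (i, x) not in faces
                    or (y, j) not in faces
                ):
                    continue
            if any(h_closed(i, t) or h_closed(t, j) for t in range(i + 1, j)):
                continue
            found.append((i, j))
    return [
        iv
        for iv in found
        if not any(
            o != iv and o[0] <= iv[0] and iv[1] <= o[1] for o in found
        )
    ]


def oracle_loop_positions(s: Structure, h: Stem, stems: list[Stem]) -> set[int]:
    """The 'belongs' predicate evaluated position by position."""
    r, sp = h.internal_pair
    out = set()
    for t in range(r + 1, sp):
        inside_blockers = False
        for g in stems:
            if g == h:
                continue
            ok_inside = all(
                h.internal_pair[0] < w < h.internal_pair[1]
                for wing in g.wings
                for w in range(wing[0], wing[1] + 1)
            )
            if ok_inside and g.face[0] < t < g.face[1]:
                inside_blockers = True
                break
        if not inside_blockers:
            out.add(t)
    return out


# --- naive signature computation ------------------------------------------


def _naive_word(arcs: list[tuple[int, int]]) -> str:
    order = {a: k for k, a in enumerate(sorted(arcs))}
    tokens = []
    for e in sorted(x for a in arcs for x in a):
        for a in arcs:
            if e == a[0]:
                tokens.append(chr(ord("a") + order[a]))
            elif e == a[1]:
                tokens.append(chr(ord("A") + order[a]))
    return "".join(tokens)


def _arc_cross(a, b) -> bool:
    return a[0] < b[0] < a[1] < b[1] or b[0] < a[0] < b[1] < a[1]


def _reduce_to_fixpoint(arcs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Iterative pairwise band merging until nothing merges any more."""
    arcs = sorted(arcs)
    changed = True
    while changed:
        changed = False
        n = len(arcs)
        for ka in range(n):
            for kb in range(ka + 1, n):
                a, b = arcs[ka], arcs[kb]
                nested = (a[0] < b[0] and b[1] < a[1]) or (b[0] < a[0] and a[1] < b[1])
                if not nested:
                    continue
                ca = {m for m in range(n) if m not in (ka, kb) and _arc_cross(a, arcs[m])}
                cb = {m for m in range(n) if m not in (ka, kb) and _arc_cross(b, arcs[m])}
                if ca == cb:
                    merged = (min(a[0], b[0]), max(a[1], b[1]))
                    arcs = sorted(
                        [arcs[m] for m in range(n) if m not in (ka, kb)] + [merged]
                    )
                    changed = True
                    break
            if changed:
                break
    return arcs


def oracle_signature_words(
    s: Structure, stems: list[Stem], interval: tuple[int, int]
) -> tuple[str, str, str]:
    """(full, upper, reduced) words for the pseudoknotted ECR ``interval``,
    computed by naive end-sorting and fixpoint reduction."""
    i, j = interval
    members = [
        h for h in stems if i <= h.left_wing[0] and h.right_wing[1] <= j
    ]
    arcs = [(h.left_wing[0], h.right_wing[0]) for h in members]
    full = _naive_word(arcs)

    parent_of = oracle_ecr_forest(s, stems)
    children = [iv for iv, par in parent_of.items() if par == interval]
    upper_members = [
        h
        for h in members
        if not any(
            c[0] <= h.left_wing[0] and h.right_wing[1] <= c[1] for c in children
        )
    ]
    upper_arcs = [(h.left_wing[0], h.right_wing[0]) for h in upper_members]
    upper = _naive_word(upper_arcs)
    reduced = _naive_word(_reduce_to_fixpoint(upper_arcs))
    return full, upper, reduced


# --- classical nearest-neighbor-model decomposition ------------------------


def oracle_nnm_loops(
    s: Structure, stems: list[Stem]
) -> list[dict]:
    """Classical NNM loop decomposition of a pseudoknot-free structure.

    Builds the stem nesting tree by face containment and reads each loop
    off directly: interior of the internal pair minus the child stems'
    face intervals, child faces kept as loop members.  Raises if any two
    stems cross.
    """
    for a in stems:
        for b in stems:
            if a != b and _arc_cross(a.face, b.face):
                raise ValueError("structure is pseudoknotted; NNM oracle undefined")

    def contains(outer: Stem, inner: Stem) -> bool:
        return outer.face[0] < inner.face[0] and inner.face[1] < outer.face[1]

    out = []
    for h in stems:
        inside = [g for g in stems if g != h and contains(h, g)]
        # direct children: not inside another inside stem
        children = [
            g
            for g in inside
            if not any(x != g and contains(x, g) for x in inside)
        ]
        children.sort(key=lambda g: g.face[0])
        r, sp = h.internal_pair
        excluded = set()
        for g in children:
            excluded.update(range(g.face[0] + 1, g.face[1]))
        positions = frozenset(t for t in range(r + 1, sp) if t not in excluded)
        delims = [r]
        for g in children:
            delims.extend(g.face)
        delims.append(sp)
        side_lengths = [
            max(0, delims[k + 1] - delims[k] - 1)
            for k in range(0, len(delims) - 1, 2)
        ]
        n_faces = len(children)
        if n_faces == 0:
            size = "hairpin"
        elif n_faces == 1:
            size = "bulge" if 0 in side_lengths else "internal"
        else:
            size = "multiple_junction"
        out.append(
            {
                "face": h.face,
                "positions": positions,
                "n_faces": n_faces,
                "side_lengths": side_lengths,
                "size_class": size,
            }
        )
    return out
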