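"""Pair typing, maximal stem detection, crossing and containment predicates.

A *stem* is a run of stacked pairs ``(i, j), (i+1, j-1), ..., (i+k, j-k)``
with ``k >= 1`` (at least two pairs).  Its first pair is the *face*
(external pair), its last the *internal pair*; the chain fragments
``[i, i+k]`` and ``[j-k, j]`` are its left and right *wings*.  A *standard*
stem contains only complementary pairs (Watson-Crick or GU wobble); an
*arbitrary* stem admits any pair of the matching.

A pair ``(m, n)`` *crosses* a stem with face ``(i, j)`` when
``m < i < n < j`` or ``i < m < j < n`` — the defining relation of
pseudoknots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

from .structure import Structure

__all__ = [
    "PairClass",
    "StemType",
    "Stem",
    "classify_pair",
    "find_stems",
    "crosses",
    "position_internal",
    "lies_inside",
]


class PairClass(str, Enum):
    WATSON_CRICK = "watson_crick"
    WOBBLE = "wobble"
    OTHER = "other"


class StemType(str, Enum):
    STANDARD = "standard"
    ARBITRARY = "arbitrary"


def classify_pair(base_a: str, base_b: str) -> PairClass:
    """Classify a base pair; symmetric in its arguments.

    Watson-Crick: {A,U} or {C,G}; wobble: {G,U}; anything else (including
    any pair with an N) is ``other``.
    """
    s = frozenset((base_a.upper(), base_b.upper()))
    if s in ({"A", "U"}, {"C", "G"}):
        return PairClass.WATSON_CRICK
    if s == {"G", "U"}:
        return PairClass.WOBBLE
    return PairClass.OTHER


@dataclass(frozen=True)
class Stem:
    """A maximal run of stacked eligible pairs.

    ``pairs`` is ordered outside-in: ``pairs[0]`` is the face,
    ``pairs[-1]`` the internal pair.
    """

    pairs: tuple[tuple[int, int], ...]
    stem_type: StemType = StemType.STANDARD

    def __post_init__(self) -> None:
        if len(self.pairs) < 2:
            raise ValueError("a stem has at least two pairs (k >= 1)")
        i, j = self.pairs[0]
        for d, (a, b) in enumerate(self.pairs):
            if (a, b) != (i + d, j - d):
                raise ValueError(f"pairs {self.pairs} are not a stacked run")
        if self.pairs[-1][0] >= self.pairs[-1][1]:
            raise ValueError("stacked run collapsed past the chain midpoint")

    @property
    def face(self) -> tuple[int, int]:
        return self.pairs[0]

    @property
    def internal_pair(self) -> tuple[int, int]:
        return self.pairs[-1]

    @property
    def k(self) -> int:
        """Stacking depth: number of pairs minus one."""
        return len(self.pairs) - 1

    @property
    def left_wing(self) -> tuple[int, int]:
        """Inclusive interval [i, i+k]."""
        return (self.pairs[0][0], self.pairs[-1][0])

    @property
    def right_wing(self) -> tuple[int, int]:
        """Inclusive interval [j-k, j]."""
        return (self.pairs[-1][1], self.pairs[0][1])

    @property
    def wings(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return (self.left_wing, self.right_wing)

    def positions(self) -> set[int]:
        lw, rw = self.wings
        return set(range(lw[0], lw[1] + 1)) | set(range(rw[0], rw[1] + 1))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"Stem{self.face}x{len(self.pairs)}"


def _eligible(s: Structure, stem_type: StemType) -> set[tuple[int, int]]:
    if stem_type is StemType.ARBITRARY:
        return set(s.pairs)
    return {
        (i, j)
        for (i, j) in s.pairs
        if classify_pair(s.base(i), s.base(j)) is not PairClass.OTHER
    }


def find_stems(
    s: Structure,
    stem_type: StemType | str = StemType.STANDARD,
    min_pairs: int = 2,
) -> tuple[list[Stem], list[tuple[int, int]]]:
    """Detect all maximal stacked runs of eligible pairs.

    Returns ``(stems, isolated_pairs)`` where *stems* are the maximal runs
    with at least ``min_pairs`` pairs, sorted by face left end, and
    *isolated_pairs* are eligible pairs in no returned stem.  For
    ``standard`` stems the sequence must be present; without one every
    pair is treated as eligible and the type is forced to ``arbitrary``
    with a warning.

    ``min_pairs`` below 2 is rejected: a single pair is not a stacked run
    (``k >= 1``); callers wanting 1-pair pseudo-stems use
    :func:`rnaloops.annotate.annotate` with ``keep_isolated=True``.
    """
    stem_type = StemType(stem_type)
    if min_pairs < 2:
        raise ValueError("min_pairs must be >= 2 (a stem needs k >= 1)")
    if stem_type is StemType.STANDARD and s.sequence is None and s.pairs:
        warnings.warn(
            "no sequence available: treating every pair as eligible "
            "(stem type forced to arbitrary)",
            stacklevel=2,
        )
        stem_type = StemType.ARBITRARY
    eligible = _eligible(s, stem_type)
    in_run: set[tuple[int, int]] = set()
    stems: list[Stem] = []
    for i, j in sorted(eligible):
        if (i - 1, j + 1) in eligible:
            continue  # not the outermost pair of its run
        run = [(i, j)]
        while (run[-1][0] + 1, run[-1][1] - 1) in eligible:
            run.append((run[-1][0] + 1, run[-1][1] - 1))
        if len(run) >= min_pairs:
            stems.append(Stem(pairs=tuple(run), stem_type=stem_type))
            in_run.update(run)
    isolated = sorted(p for p in eligible if p not in in_run)
    stems.sort(key=lambda h: h.face[0])
    return stems, isolated


def crosses(p: tuple[int, int], h: Stem) -> bool:
    """True iff pair ``p`` crosses stem ``h``'s face."""
    m, n = p
    i, j = h.face
    return (m < i < n < j) or (i < m < j < n)


def stems_cross(h1: Stem, h2: Stem) -> bool:
    """True iff the faces of the two stems cross each other."""
    return crosses(h1.face, h2)


def position_internal(t: int, h: Stem) -> bool:
    """True iff ``t`` lies strictly inside ``h``'s internal pair ``(i, j)``."""
    i, j = h.internal_pair
    return i < t < j


def lies_inside(h1: Stem, h: Stem) -> bool:
    """True iff every position of ``h1``'s wings is internal to ``h``."""
    if h1 == h:
        return False
    return all(
        position_internal(t, h)
        for wing in h1.wings
        for t in wing
    )
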