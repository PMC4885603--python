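"""Pseudoknot signatures at three reduction levels.

A pseudoknotted ECR is summarized as a word over paired letters: every
arc (stem) contributes a lower-case letter at its left end and the
matching capital at its right end, letters assigned in alphabetical order
by left-end position, word order following end positions.  Three levels:

* **full** — one arc per member stem of the ECR (including stems inside
  nested ECRs);
* **upper** — stems lying inside nested ECRs (children and their
  subtrees) are removed and letters reassigned;
* **reduced** — parallel families of arcs (*bands*: pairwise properly
  nested arcs crossing exactly the same other families) are each
  collapsed to a single arc spanning the family's outermost ends.

Reduced words name the classic pseudoknot classes: ``abAB`` (H-knot),
``abAcBC`` (kissing hairpins), ``abcABC`` (triple knot).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .core import Stem
from .ecr import ECR, ECRKind

__all__ = [
    "SignatureLevel",
    "NamedClass",
    "Signature",
    "full_signature",
    "upper_signature",
    "reduced_signature",
    "named_class",
    "SignatureError",
]


class SignatureError(ValueError):
    """Signature requested for an object it is not defined for."""


class SignatureLevel(str, Enum):
    FULL = "full"
    UPPER = "upper"
    REDUCED = "reduced"


class NamedClass(str, Enum):
    H_KNOT = "H_knot"
    KISSING_HAIRPINS = "kissing_hairpins"
    TRIPLE_KNOT = "triple_knot"
    OTHER = "other"


_NAMED = {
    "abAB": NamedClass.H_KNOT,
    "abAcBC": NamedClass.KISSING_HAIRPINS,
    "abcABC": NamedClass.TRIPLE_KNOT,
}


def _letter(k: int) -> tuple[str, str]:
    """(lower, upper) letter pair for arc index k; indexed past 'z'."""
    if k < 26:
        return chr(ord("a") + k), chr(ord("A") + k)
    base, idx = k % 26, k // 26
    return f"{chr(ord('a') + base)}{idx}", f"{chr(ord('A') + base)}{idx}"


@dataclass(frozen=True)
class Signature:
    """A signature word with its arc -> interval mapping."""

    level: SignatureLevel
    word: str
    arcs: tuple[tuple[str, int, int], ...]  # (lower letter, left end, right end)

    @property
    def n_arcs(self) -> int:
        return len(self.arcs)


def _arc_of(stem: Stem) -> tuple[int, int]:
    """Arc ends of a stem: the leftmost coordinate of each wing."""
    return (stem.left_wing[0], stem.right_wing[0])


def word_from_arcs(
    arcs: list[tuple[int, int]], level: SignatureLevel
) -> Signature:
    """Assign letters alphabetically by left end and build the word."""
    arcs = sorted(arcs)
    ends = sorted(e for a in arcs for e in a)
    if len(set(ends)) != len(ends):
        raise SignatureError(f"arc ends collide: {arcs}")
    letters = {}
    labeled = []
    for k, (left, right) in enumerate(arcs):
        lo, up = _letter(k)
        letters[left] = lo
        letters[right] = up
        labeled.append((lo, left, right))
    tokens = [letters[e] for e in ends]
    sep = "." if any(len(t) > 1 for t in tokens) else ""
    return Signature(level=level, word=sep.join(tokens), arcs=tuple(labeled))


def _member_arcs(e: ECR) -> list[tuple[int, int]]:
    if e.kind is not ECRKind.PSEUDOKNOTTED:
        raise SignatureError("signatures are defined for pseudoknots")
    return [_arc_of(h) for h in e.member_stems]


def full_signature(e: ECR) -> Signature:
    """One arc per member stem, nested ECR contents included."""
    return word_from_arcs(_member_arcs(e), SignatureLevel.FULL)


def _upper_arcs(e: ECR) -> list[tuple[int, int]]:
    if e.kind is not ECRKind.PSEUDOKNOTTED:
        raise SignatureError("signatures are defined for pseudoknots")
    dropped = {
        h for child in e.children for sub in child.walk() for h in sub.member_stems
    }
    return [_arc_of(h) for h in e.member_stems if h not in dropped]


def upper_signature(e: ECR) -> Signature:
    """Full signature with every stem inside a nested ECR removed."""
    return word_from_arcs(_upper_arcs(e), SignatureLevel.UPPER)


def _cross(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[0] < a[1] < b[1] or b[0] < a[0] < b[1] < a[1]


def _nested(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return (a[0] < b[0] and b[1] < a[1]) or (b[0] < a[0] and a[1] < b[1])


def collapse_parallel(arcs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Collapse every parallel family (band) into one spanning arc.

    Two arcs are parallel when one properly nests inside the other and
    both cross exactly the same set of other arcs.  Families are the
    connected components of that relation; components are verified to be
    cliques (crossing sets are family-level invariants), so one
    simultaneous pass suffices and re-collapsing is the identity.
    """
    n = len(arcs)
    crossing = [
        frozenset(m for m in range(n) if m != k and _cross(arcs[k], arcs[m]))
        for k in range(n)
    ]

    def parallel(k: int, m: int) -> bool:
        return _nested(arcs[k], arcs[m]) and crossing[k] == crossing[m]

    # union-find over the parallel relation
    root = list(range(n))

    def find(a: int) -> int:
        while root[a] != a:
            root[a] = root[root[a]]
            a = root[a]
        return a

    for k in range(n):
        for m in range(k + 1, n):
            if parallel(k, m):
                ra, rb = find(k), find(m)
                if ra != rb:
                    root[rb] = ra
    families: dict[int, list[int]] = {}
    for k in range(n):
        families.setdefault(find(k), []).append(k)
    for members in families.values():
        for a in members:
            for b in members:
                if a < b and not parallel(a, b):
                    raise SignatureError(
                        f"parallel relation is not transitive on arcs "
                        f"{[arcs[m] for m in members]}"
                    )
    return sorted(
        (min(arcs[m][0] for m in members), max(arcs[m][1] for m in members))
        for members in families.values()
    )


def reduced_signature(e: ECR) -> Signature:
    """Upper signature with parallel stem families collapsed to single arcs."""
    arcs = collapse_parallel(_upper_arcs(e))
    return word_from_arcs(arcs, SignatureLevel.REDUCED)


def named_class(sig: Signature) -> NamedClass:
    """Recognize H-knot / kissing hairpins / triple knot by reduced word."""
    if sig.level is not SignatureLevel.REDUCED:
        raise ValueError("named classes are matched against reduced signatures")
    return _NAMED.get(sig.word, NamedClass.OTHER)
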