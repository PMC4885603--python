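"""Core data model for RNA secondary structures.

A :class:`Structure` is a chain of ``length`` nucleotides (1-based positions),
an optional sequence over ``{A, C, G, U, N}``, a secondary-structure pair set
that forms a matching (every position paired at most once), and an optional
list of tertiary pairs carried as annotations on top of the matching.

All coordinates throughout the package are 1-based and intervals are
inclusive on both ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "Structure",
    "TertiaryPair",
    "StructureError",
    "canonical_pair",
]

VALID_BASES = frozenset("ACGUN")


class StructureError(ValueError):
    """Raised when a structure violates the matching/coordinate invariants."""


def canonical_pair(i: int, j: int) -> tuple[int, int]:
    """Return the pair with endpoints ordered as (min, max)."""
    return (i, j) if i < j else (j, i)


@dataclass(frozen=True)
class TertiaryPair:
    """A base-base contact annotated on top of the secondary structure.

    Tertiary pairs are not part of the matching: they may share positions
    with secondary pairs and with each other.  ``lw_class`` carries a
    Leontis-Westhof label (e.g. ``"cWW"``, ``"tHS"``) verbatim from input;
    ``canonical`` flags Watson-Crick / GU-wobble geometry.
    """

    i: int
    j: int
    lw_class: str | None = None
    canonical: bool = False

    def __post_init__(self) -> None:
        if self.i >= self.j:
            i, j = self.j, self.i
            object.__setattr__(self, "i", i)
            object.__setattr__(self, "j", j)
        if self.i < 1:
            raise StructureError(f"tertiary pair position {self.i} < 1")


@dataclass
class Structure:
    """An RNA chain with a secondary-structure matching.

    Parameters
    ----------
    length
        Number of nucleotides in the chain (may be 0).
    pairs
        Secondary-structure base pairs, each stored once as ``(i, j)`` with
        ``i < j``.  Must form a matching.
    sequence
        Optional nucleotide sequence of exactly ``length`` characters over
        ``{A, C, G, U, N}``.  Topological operations need only ``pairs``.
    tertiary_pairs
        Optional tertiary contacts; positions may overlap ``pairs``.
    name
        Optional identifier used in reports and search output.
    """

    length: int
    pairs: frozenset[tuple[int, int]] = frozenset()
    sequence: str | None = None
    tertiary_pairs: list[TertiaryPair] = field(default_factory=list)
    name: str | None = None

    def __post_init__(self) -> None:
        if self.length < 0:
            raise StructureError(f"negative length {self.length}")
        self.pairs = frozenset(canonical_pair(i, j) for (i, j) in self.pairs)
        seen: set[int] = set()
        for i, j in sorted(self.pairs):
            if i == j:
                raise StructureError(f"self-pair at position {i}")
            if not (1 <= i < j <= self.length):
                raise StructureError(
                    f"pair ({i}, {j}) outside chain of length {self.length}"
                )
            for t in (i, j):
                if t in seen:
                    raise StructureError(
                        f"position {t} occurs in more than one base pair "
                        "(secondary structure must be a matching)"
                    )
                seen.add(t)
        if self.sequence is not None:
            seq = self.sequence.upper().replace("T", "U")
            if len(seq) != self.length:
                raise StructureError(
                    f"sequence length {len(seq)} != chain length {self.length}"
                )
            bad = set(seq) - VALID_BASES
            if bad:
                raise StructureError(f"invalid bases in sequence: {sorted(bad)}")
            self.sequence = seq
        for tp in self.tertiary_pairs:
            if tp.j > self.length:
                raise StructureError(
                    f"tertiary pair ({tp.i}, {tp.j}) outside chain of length "
                    f"{self.length}"
                )

    # -- convenience accessors -------------------------------------------

    @property
    def partner(self) -> dict[int, int]:
        """Mapping position -> paired position, both directions."""
        out: dict[int, int] = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out

    def base(self, t: int) -> str:
        """Base at 1-based position ``t`` (``N`` when no sequence given)."""
        if self.sequence is None:
            return "N"
        return self.sequence[t - 1]

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.length
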