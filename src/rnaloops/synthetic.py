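"""Deterministic fixtures, named-motif constructors and a random generator.

The figure fixtures are hand-constructed instances consistent with every
statement made about the corresponding worked examples (stem wings, loop
sides, H-ECR counts, signature words); tests re-check each assertion so a
fixture cannot silently drift.

The random generator plants maximal stems as stacked runs separated by at
least one unpaired spacer, optionally forcing crossings (pseudoknots),
and emits a complementary sequence so standard-stem detection recovers
exactly the planted stems.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Stem, StemType
from .structure import Structure, TertiaryPair

__all__ = [
    "fixture_figure1",
    "fixture_figure3",
    "fixture_hknot",
    "fixture_kissing",
    "fixture_tripleknot",
    "FIXTURES",
    "GeneratorConfig",
    "GeneratorError",
    "generate",
    "generate_planted",
]

_WC = [("G", "C"), ("C", "G"), ("A", "U"), ("U", "A")]


def _sequence_for(length: int, pairs: frozenset[tuple[int, int]]) -> str:
    """Deterministic complementary sequence: WC pairs, As elsewhere."""
    seq = ["A"] * length
    for k, (i, j) in enumerate(sorted(pairs)):
        a, b = _WC[k % len(_WC)]
        seq[i - 1] = a
        seq[j - 1] = b
    return "".join(seq)


def _build(name: str, length: int, stems: list[list[tuple[int, int]]]) -> Structure:
    pairs = frozenset(p for run in stems for p in run)
    return Structure(
        length=length,
        pairs=pairs,
        sequence=_sequence_for(length, pairs),
        name=name,
    )


def fixture_figure1() -> Structure:
    """A 57-nt pseudoknotted structure with a multiple-junction loop.

    Stem H (9,48),(10,47) carries the loop of interest; stem W
    (13,55)..(15,53) crosses H leaving its wing 13-15 inside H's loop;
    P1/P2 form a pseudoknotted region [18,31]; Q (34,43)..(36,41) a
    classical hairpin region [34,43].
    """
    return _build(
        "figure1",
        57,
        [
            [(9, 48), (10, 47)],                 # H
            [(13, 55), (14, 54), (15, 53)],      # W
            [(18, 26), (19, 25)],                # P1
            [(21, 31), (22, 30)],                # P2
            [(34, 43), (35, 42), (36, 41)],      # Q
        ],
    )


def fixture_figure3() -> Structure:
    """A 31-nt pseudoknot whose six stems realize the signature chain
    full ``abcdDCefBAFE`` -> upper ``abcdBADC`` -> reduced ``abAB``."""
    return _build(
        "figure3",
        31,
        [
            [(1, 26), (2, 25)],    # a
            [(4, 23), (5, 22)],    # b
            [(6, 16), (7, 15)],    # c
            [(9, 13), (10, 12)],   # d
            [(17, 31), (18, 30)],  # e
            [(20, 28), (21, 27)],  # f
        ],
    )


def fixture_hknot() -> Structure:
    """Minimal H-type pseudoknot; reduced signature ``abAB``."""
    return _build("hknot", 16, [[(1, 12), (2, 11)], [(5, 16), (6, 15)]])


def fixture_kissing() -> Structure:
    """Kissing hairpins; reduced signature ``abAcBC``."""
    return _build(
        "kissing",
        17,
        [[(1, 8), (2, 7)], [(4, 14), (5, 13)], [(10, 17), (11, 16)]],
    )


def fixture_tripleknot() -> Structure:
    """Triple knot: three mutually crossing stems; reduced ``abcABC``."""
    return _build(
        "tripleknot",
        17,
        [[(1, 11), (2, 10)], [(4, 14), (5, 13)], [(7, 17), (8, 16)]],
    )


FIXTURES = {
    "figure1": fixture_figure1,
    "figure3": fixture_figure3,
    "hknot": fixture_hknot,
    "kissing": fixture_kissing,
    "tripleknot": fixture_tripleknot,
}


class GeneratorError(RuntimeError):
    """The requested configuration could not be realized."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the random structure generator.

    ``pk_prob`` is the probability that each stem after the first is
    required to cross an already-placed stem; 0 yields pseudoknot-free
    structures.  Identical seeds give identical output.
    """

    length: int = 100
    n_stems: int = 5
    min_stem_pairs: int = 2
    max_stem_pairs: int = 4
    pk_prob: float = 0.3
    wobble_prob: float = 0.1
    n_tertiary: int = 0
    seed: int = 0
    max_retries: int = 500

    def __post_init__(self) -> None:
        if self.length <= 0 or self.n_stems < 0:
            raise ValueError("length and n_stems must be positive")
        if not 2 <= self.min_stem_pairs <= self.max_stem_pairs:
            raise ValueError("need 2 <= min_stem_pairs <= max_stem_pairs")
        if not 0.0 <= self.pk_prob <= 1.0:
            raise ValueError("pk_prob must be a probability")


_LW_CLASSES = ["cWW", "tWW", "cWH", "tWH", "cWS", "tWS", "cHH", "tHS", "cSS", "tSS"]


def generate_planted(config: GeneratorConfig) -> tuple[Structure, list[Stem]]:
    """Generate a structure together with its planting log."""
    rng = np.random.default_rng(config.seed)
    n = config.length
    blocked = set()  # positions unusable (occupied or spacer-adjacent)
    occupied = set()
    planted: list[Stem] = []

    def try_place(k: int, want_cross: bool) -> Stem | None:
        if n < 2 * k + 2:
            return None
        i = int(rng.integers(1, n - 2 * k))
        lo_j = i + 2 * k + 1  # leaves >= 2 interior positions
        if lo_j > n:
            return None
        j = int(rng.integers(lo_j, n + 1))
        run = [(i + d, j - d) for d in range(k)]
        pos = [p for ab in run for p in ab]
        if any(p in blocked for p in pos):
            return None
        if run[-1][0] + 1 > run[-1][1] - 1:
            return None
        face = run[0]
        crossing = any(
            (face[0] < g.face[0] < face[1] < g.face[1])
            or (g.face[0] < face[0] < g.face[1] < face[1])
            for g in planted
        )
        if planted and want_cross != crossing:
            return None
        return Stem(pairs=tuple(run), stem_type=StemType.STANDARD)

    for _ in range(config.n_stems):
        want_cross = bool(planted) and (rng.random() < config.pk_prob)
        stem = None
        for _attempt in range(config.max_retries):
            k = int(rng.integers(config.min_stem_pairs, config.max_stem_pairs + 1))
            stem = try_place(k, want_cross)
            if stem is not None:
                break
        if stem is None:
            raise GeneratorError(
                f"could not place stem {len(planted) + 1} of {config.n_stems} "
                f"in length {n} after {config.max_retries} retries"
            )
        planted.append(stem)
        for a, b in stem.pairs:
            occupied.update((a, b))
            blocked.update((a - 1, a, a + 1, b - 1, b, b + 1))

    pairs = frozenset(p for h in planted for p in h.pairs)
    seq = list(rng.choice(list("ACGU"), size=n))
    for i, j in sorted(pairs):
        if rng.random() < config.wobble_prob:
            a, b = ("G", "U") if rng.random() < 0.5 else ("U", "G")
        else:
            a, b = _WC[int(rng.integers(0, len(_WC)))]
        seq[i - 1] = a
        seq[j - 1] = b

    tertiary = []
    if config.n_tertiary:
        for _ in range(config.n_tertiary):
            i, j = sorted(int(v) for v in rng.choice(np.arange(1, n + 1), size=2, replace=False))
            tertiary.append(
                TertiaryPair(
                    i, j,
                    lw_class=str(rng.choice(_LW_CLASSES)),
                    canonical=False,
                )
            )

    s = Structure(
        length=n,
        pairs=pairs,
        sequence="".join(seq),
        tertiary_pairs=tertiary,
        name=f"gen-seed{config.seed}",
    )
    planted.sort(key=lambda h: h.face[0])
    return s, planted


def generate(config: GeneratorConfig) -> Structure:
    """Generate a random structure (see :class:`GeneratorConfig`)."""
    return generate_planted(config)[0]
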