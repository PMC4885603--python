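"""Readers and writers for secondary-structure file formats.

Supported formats:

* extended dot-bracket — ``.`` unpaired; bracket families in precedence
  order ``()``, ``[]``, ``{}``, ``<>``, then letter families ``Aa``, ``Bb``,
  ... (upper case opens, lower case closes); each family is matched
  independently with a stack, which is what allows pseudoknots;
* CT — the standard 6-column connectivity table (partner 0 = unpaired);
* BPSEQ — 3 columns ``position base partner``;
* pairs table — a TSV with header columns ``i``, ``j``, ``base_i``,
  ``base_j`` and optional ``lw_class`` / ``canonical``; rows flagged
  non-canonical become tertiary pairs, canonical rows join the secondary
  matching.

Coordinates are 1-based everywhere.
"""

from __future__ import annotations

from .structure import Structure, StructureError, TertiaryPair, canonical_pair

__all__ = [
    "ParseError",
    "MultipletError",
    "parse_dotbracket",
    "parse_ct",
    "parse_bpseq",
    "parse_pairs_table",
    "write_dotbracket",
    "write_ct",
    "write_bpseq",
    "write_pairs_table",
    "BRACKET_FAMILIES",
]


class ParseError(ValueError):
    """Malformed input text for any of the structure formats."""


class MultipletError(ParseError):
    """A position participates in more than one canonical base pair."""


# Precedence order is fixed so writer output is deterministic.
_BRACKET_PAIRS = ["()", "[]", "{}", "<>"] + [
    chr(ord("A") + k) + chr(ord("a") + k) for k in range(26)
]
BRACKET_FAMILIES: list[tuple[str, str]] = [(o, c) for o, c in _BRACKET_PAIRS]
_OPEN = {o: idx for idx, (o, c) in enumerate(BRACKET_FAMILIES)}
_CLOSE = {c: idx for idx, (o, c) in enumerate(BRACKET_FAMILIES)}


def parse_dotbracket(text: str) -> Structure:
    """Parse one extended dot-bracket string into a :class:`Structure`.

    Whitespace is ignored.  Each bracket family is matched independently
    with its own stack; crossing pairs must use different families.
    """
    chars = [c for c in text if not c.isspace()]
    stacks: dict[int, list[int]] = {}
    pairs: set[tuple[int, int]] = set()
    for pos, c in enumerate(chars, start=1):
        if c in ".-_,:":
            continue
        if c in _OPEN:
            stacks.setdefault(_OPEN[c], []).append(pos)
        elif c in _CLOSE:
            fam = _CLOSE[c]
            stack = stacks.get(fam, [])
            if not stack:
                o, cl = BRACKET_FAMILIES[fam]
                raise ParseError(
                    f"unbalanced '{cl}' (family {o}{cl}) at position {pos}"
                )
            pairs.add((stack.pop(), pos))
        else:
            raise ParseError(f"unknown character {c!r} at position {pos}")
    for fam, stack in stacks.items():
        if stack:
            o, cl = BRACKET_FAMILIES[fam]
            raise ParseError(
                f"unbalanced '{o}' (family {o}{cl}) at position {stack[-1]}"
            )
    return Structure(length=len(chars), pairs=frozenset(pairs))


def _resolve_matching(
    raw_pairs: list[tuple[int, int]],
    resolve_multiplets: str | None,
) -> tuple[set[tuple[int, int]], list[tuple[int, int]]]:
    """Keep a matching out of ``raw_pairs``; route the rest per policy.

    Returns (secondary pairs, demoted pairs).  Default policy is a hard
    error on any position in two pairs; ``resolve_multiplets='first'``
    keeps the first-listed pair per position and demotes later ones.
    """
    used: set[int] = set()
    kept: set[tuple[int, int]] = set()
    demoted: list[tuple[int, int]] = []
    for i, j in raw_pairs:
        p = canonical_pair(i, j)
        if p in kept:
            continue
        if p[0] in used or p[1] in used:
            if resolve_multiplets == "first":
                demoted.append(p)
                continue
            clash = p[0] if p[0] in used else p[1]
            raise MultipletError(
                f"position {clash} occurs in more than one canonical pair "
                "(multiplet); pass resolve_multiplets='first' to demote"
            )
        kept.add(p)
        used.update(p)
    return kept, demoted


def parse_ct(text: str, resolve_multiplets: str | None = None) -> Structure:
    """Parse CT connectivity-table text.

    The first non-blank line is the header (``length [title]``); each
    record line is ``index base prev next partner index``.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return Structure(length=0)
    header = lines[0].split()
    try:
        length = int(header[0])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"bad CT header: {lines[0]!r}") from exc
    seq = ["N"] * length
    partner = [0] * (length + 1)
    for ln in lines[1 : length + 1]:
        fields = ln.split()
        if len(fields) < 6:
            raise ParseError(f"CT record with <6 columns: {ln!r}")
        idx, base, part = int(fields[0]), fields[1], int(fields[4])
        if not 1 <= idx <= length:
            raise ParseError(f"CT index {idx} outside 1..{length}")
        seq[idx - 1] = base.upper().replace("T", "U")
        partner[idx] = part
    raw: list[tuple[int, int]] = []
    for i in range(1, length + 1):
        j = partner[i]
        if j == 0:
            continue
        if not 1 <= j <= length:
            raise ParseError(f"CT partner {j} of position {i} out of range")
        if partner[j] != i:
            raise ParseError(
                f"inconsistent CT reciprocal partners: {i}->{j} but {j}->{partner[j]}"
            )
        if i < j:
            raw.append((i, j))
    pairs, demoted = _resolve_matching(raw, resolve_multiplets)
    return Structure(
        length=length,
        pairs=frozenset(pairs),
        sequence="".join(seq) if any(b != "N" for b in seq) else None,
        tertiary_pairs=[TertiaryPair(i, j) for i, j in demoted],
    )


def parse_bpseq(text: str, resolve_multiplets: str | None = None) -> Structure:
    """Parse BPSEQ text (``position base partner`` per line, partner 0 = unpaired)."""
    rows: list[tuple[int, str, int]] = []
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        fields = ln.split()
        if len(fields) != 3:
            raise ParseError(f"BPSEQ record must have 3 columns: {ln!r}")
        rows.append((int(fields[0]), fields[1], int(fields[2])))
    if not rows:
        return Structure(length=0)
    length = max(r[0] for r in rows)
    seq = ["N"] * length
    partner = [0] * (length + 1)
    for idx, base, part in rows:
        if not 1 <= idx <= length:
            raise ParseError(f"BPSEQ index {idx} out of range")
        seq[idx - 1] = base.upper().replace("T", "U")
        partner[idx] = part
    raw = []
    for i in range(1, length + 1):
        j = partner[i]
        if j == 0:
            continue
        if not 1 <= j <= length:
            raise ParseError(f"BPSEQ partner {j} of position {i} out of range")
        if partner[j] != i:
            raise ParseError(
                f"inconsistent BPSEQ reciprocal partners: {i}->{j} but "
                f"{j}->{partner[j]}"
            )
        if i < j:
            raw.append((i, j))
    pairs, demoted = _resolve_matching(raw, resolve_multiplets)
    return Structure(
        length=length,
        pairs=frozenset(pairs),
        sequence="".join(seq) if any(b != "N" for b in seq) else None,
        tertiary_pairs=[TertiaryPair(i, j) for i, j in demoted],
    )


_TRUE = {"true", "1", "yes", "t", "y"}
_FALSE = {"false", "0", "no", "f", "n"}


def parse_pairs_table(text: str, resolve_multiplets: str | None = None) -> Structure:
    """Parse a DSSR-like TSV pairs table.

    Required columns: ``i``, ``j``, ``base_i``, ``base_j``.  Optional:
    ``lw_class``, ``canonical`` (default true).  Canonical rows enter the
    secondary matching; non-canonical rows become tertiary pairs.  An
    optional ``# length=N`` comment line fixes the chain length, otherwise
    the maximum coordinate is used.
    """
    length_hint = 0
    lines = []
    for ln in text.splitlines():
        if ln.startswith("#"):
            stripped = ln.lstrip("#").strip()
            if stripped.startswith("length="):
                length_hint = int(stripped.split("=", 1)[1])
            continue
        if ln.strip():
            lines.append(ln)
    if not lines:
        return Structure(length=length_hint)
    header = [h.strip() for h in lines[0].split("\t")]
    required = {"i", "j", "base_i", "base_j"}
    if not required <= set(header):
        raise ParseError(
            f"pairs table header must contain {sorted(required)}, got {header}"
        )
    col = {name: k for k, name in enumerate(header)}
    raw_canonical: list[tuple[int, int]] = []
    bases: dict[int, str] = {}
    tertiary: list[TertiaryPair] = []
    for ln in lines[1:]:
        fields = [f.strip() for f in ln.split("\t")]
        if len(fields) < len(required):
            raise ParseError(f"short pairs-table row: {ln!r}")
        i, j = int(fields[col["i"]]), int(fields[col["j"]])
        bases[i] = fields[col["base_i"]].upper().replace("T", "U")
        bases[j] = fields[col["base_j"]].upper().replace("T", "U")
        lw = fields[col["lw_class"]] if "lw_class" in col and col["lw_class"] < len(fields) else ""
        lw_class = lw or None
        canonical = True
        if "canonical" in col and col["canonical"] < len(fields):
            val = fields[col["canonical"]].lower()
            if val in _FALSE:
                canonical = False
            elif val and val not in _TRUE:
                raise ParseError(f"bad boolean {val!r} in canonical column")
        if canonical:
            raw_canonical.append((i, j) if i < j else (j, i))
        else:
            tertiary.append(TertiaryPair(i, j, lw_class=lw_class, canonical=False))
    length = max(length_hint, max(bases) if bases else 0)
    pairs, demoted = _resolve_matching(raw_canonical, resolve_multiplets)
    tertiary.extend(TertiaryPair(i, j, canonical=True) for i, j in demoted)
    seq = "".join(bases.get(t, "N") for t in range(1, length + 1)) if bases else None
    return Structure(
        length=length,
        pairs=frozenset(pairs),
        sequence=seq,
        tertiary_pairs=tertiary,
    )


def assign_bracket_families(pairs: frozenset[tuple[int, int]]) -> dict[tuple[int, int], int]:
    """Greedy coloring of the pair-crossing conflict graph.

    Pairs are processed by ascending left end; each takes the smallest
    family index not used by any already-colored pair it crosses.  The
    family count is minimal for the nesting-compatible subsets this greedy
    order produces (not guaranteed globally minimal).
    """
    ordered = sorted(pairs)
    color: dict[tuple[int, int], int] = {}
    for p in ordered:
        i, j = p
        taken = set()
        for q, c in color.items():
            m, n = q
            if m < i < n < j or i < m < j < n:
                taken.add(c)
        fam = 0
        while fam in taken:
            fam += 1
        color[p] = fam
    return color


def write_dotbracket(s: Structure) -> str:
    """Serialize to extended dot-bracket; round-trips through :func:`parse_dotbracket`."""
    color = assign_bracket_families(s.pairs)
    if color and max(color.values()) >= len(BRACKET_FAMILIES):
        raise StructureError(
            f"structure needs more than {len(BRACKET_FAMILIES)} bracket families"
        )
    out = ["."] * s.length
    for (i, j), fam in color.items():
        o, c = BRACKET_FAMILIES[fam]
        out[i - 1] = o
        out[j - 1] = c
    return "".join(out)


def write_ct(s: Structure, title: str = "") -> str:
    partner = s.partner
    lines = [f"{s.length} {title}".rstrip()]
    for t in range(1, s.length + 1):
        lines.append(
            f"{t} {s.base(t)} {t - 1} {t + 1 if t < s.length else 0} "
            f"{partner.get(t, 0)} {t}"
        )
    return "\n".join(lines) + "\n"


def write_bpseq(s: Structure) -> str:
    partner = s.partner
    lines = [f"{t} {s.base(t)} {partner.get(t, 0)}" for t in range(1, s.length + 1)]
    return "\n".join(lines) + "\n"


def write_pairs_table(s: Structure) -> str:
    lines = [f"# length={s.length}", "i\tj\tbase_i\tbase_j\tlw_class\tcanonical"]
    for i, j in sorted(s.pairs):
        lines.append(f"{i}\t{j}\t{s.base(i)}\t{s.base(j)}\t\ttrue")
    for tp in s.tertiary_pairs:
        lines.append(
            f"{tp.i}\t{tp.j}\t{s.base(tp.i)}\t{s.base(tp.j)}\t"
            f"{tp.lw_class or ''}\tfalse"
        )
    return "\n".join(lines) + "\n"
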