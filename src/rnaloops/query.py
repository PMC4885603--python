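"""Search queries: disjunctions of conjunctions of elementary predicates.

Grammar: ``pred AND pred OR pred ...`` with ``AND`` binding tighter than
``OR`` (disjunctive normal form; no parentheses).  Elementary predicates
are ``keyword=value`` tokens:

``signature=WORD`` (match at the reduced level) or ``WORD@full`` /
``WORD@upper`` / ``WORD@reduced``; ``loop=LABEL`` with a size-class or
pk-class label; ``min_stems=N`` / ``max_stems=N``; ``seq=REGEX`` over the
sequence; ``dotbracket=REGEX`` over the dot-bracket string.

The empty query matches everything.  Evaluation is pure.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .annotate import Annotation
from .io import write_dotbracket
from .loops import PkClass, SizeClass
from .signatures import SignatureLevel

__all__ = ["Query", "QuerySyntaxError", "parse_query"]


class QuerySyntaxError(ValueError):
    pass


_LOOP_LABELS = {e.value for e in SizeClass} | {e.value for e in PkClass}
_UNSUPPORTED = {
    "ion", "ions", "ligand", "mg", "ca", "metal", "pdb", "resolution",
}


@dataclass(frozen=True)
class Predicate:
    key: str
    value: str

    def matches(self, ann: Annotation) -> bool:
        if self.key == "signature":
            word, _, level = self.value.partition("@")
            lev = SignatureLevel(level) if level else SignatureLevel.REDUCED
            idx = {
                SignatureLevel.FULL: 1,
                SignatureLevel.UPPER: 2,
                SignatureLevel.REDUCED: 3,
            }[lev]
            return any(entry[idx].word == word for entry in ann.signatures)
        if self.key == "loop":
            return any(
                self.value in (l.size_class.value, l.pk_class.value)
                for l in ann.loops
            )
        if self.key == "min_stems":
            return len(ann.stems) >= int(self.value)
        if self.key == "max_stems":
            return len(ann.stems) <= int(self.value)
        if self.key == "seq":
            seq = ann.structure.sequence
            return seq is not None and re.search(self.value, seq) is not None
        if self.key == "dotbracket":
            return re.search(
                self.value, write_dotbracket(ann.structure)
            ) is not None
        raise QuerySyntaxError(f"unknown predicate {self.key!r}")


@dataclass(frozen=True)
class Query:
    """A disjunction of conjunctions of :class:`Predicate`."""

    disjuncts: tuple[tuple[Predicate, ...], ...]

    def matches(self, ann: Annotation) -> bool:
        if not self.disjuncts:
            return True
        return any(
            all(p.matches(ann) for p in conj) for conj in self.disjuncts
        )


def _parse_predicate(token: str, pos: int) -> Predicate:
    if "=" not in token:
        raise QuerySyntaxError(
            f"expected keyword=value at token {pos}: {token!r}"
        )
    key, _, value = token.partition("=")
    key = key.strip().lower()
    value = value.strip()
    if key in _UNSUPPORTED:
        raise QuerySyntaxError(
            f"predicate {key!r} (token {pos}) needs 3D/ion data and is not "
            "supported; available predicates: signature, loop, min_stems, "
            "max_stems, seq, dotbracket"
        )
    if key not in {"signature", "loop", "min_stems", "max_stems", "seq", "dotbracket"}:
        raise QuerySyntaxError(f"unknown predicate {key!r} at token {pos}")
    if key == "loop" and value not in _LOOP_LABELS:
        raise QuerySyntaxError(
            f"loop label {value!r} at token {pos}; expected one of "
            f"{sorted(_LOOP_LABELS)}"
        )
    if key in {"min_stems", "max_stems"}:
        try:
            int(value)
        except ValueError as exc:
            raise QuerySyntaxError(
                f"{key} needs an integer at token {pos}, got {value!r}"
            ) from exc
    if not value:
        raise QuerySyntaxError(f"empty value for {key!r} at token {pos}")
    return Predicate(key=key, value=value)


def parse_query(text: str) -> Query:
    """Parse the DNF keyword grammar; raise with token position on error."""
    tokens = text.split()
    if not tokens:
        return Query(disjuncts=())
    disjuncts: list[tuple[Predicate, ...]] = []
    current: list[Predicate] = []
    expect_pred = True
    for pos, tok in enumerate(tokens, start=1):
        up = tok.upper()
        if up in ("AND", "OR"):
            if expect_pred:
                raise QuerySyntaxError(
                    f"dangling {up} at token {pos}: expected a predicate"
                )
            if up == "OR":
                disjuncts.append(tuple(current))
                current = []
            expect_pred = True
        else:
            if not expect_pred:
                raise QuerySyntaxError(
                    f"missing AND/OR before token {pos}: {tok!r}"
                )
            current.append(_parse_predicate(tok, pos))
            expect_pred = False
    if expect_pred:
        raise QuerySyntaxError("query ends with a dangling AND/OR")
    disjuncts.append(tuple(current))
    return Query(disjuncts=tuple(disjuncts))
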