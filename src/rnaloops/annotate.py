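"""Whole-structure annotation: stems, ECRs, loops, signatures, report JSON.

:func:`annotate` runs the full pipeline on one :class:`Structure` and
returns an :class:`Annotation` that every downstream consumer (tertiary
interaction labeling, statistics, search, the CLI) works from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import Stem, StemType, find_stems
from .ecr import ECR, all_ecrs, exterior_segments, find_ecrs
from .io import write_dotbracket
from .loops import Loop, loop_of
from .signatures import (
    NamedClass,
    Signature,
    full_signature,
    named_class,
    reduced_signature,
    upper_signature,
)
from .structure import Structure

__all__ = ["Annotation", "annotate", "SCHEMA_VERSION"]

SCHEMA_VERSION = "1.0"


def _isolated_stem(pair: tuple[int, int]) -> Stem:
    """A 1-pair pseudo-stem (k = 0) for exploratory ``keep_isolated`` runs.

    Nonstandard: bypasses the k >= 1 invariant; marked ``arbitrary``.
    """
    obj = object.__new__(Stem)
    object.__setattr__(obj, "pairs", (pair,))
    object.__setattr__(obj, "stem_type", StemType.ARBITRARY)
    return obj


@dataclass
class Annotation:
    """Full annotation of one structure."""

    structure: Structure
    stems: list[Stem]
    isolated_pairs: list[tuple[int, int]]
    ecrs: list[ECR]  # top-level, each with its subtree
    loops: list[Loop]  # parallel to stems
    exterior: list[tuple[int, int]]
    signatures: list[tuple[ECR, Signature, Signature, Signature, NamedClass]]
    _loop_pos: list[set] = field(default_factory=list, repr=False)

    @property
    def pseudoknots(self) -> list[ECR]:
        from .ecr import ECRKind

        return [e for e in all_ecrs(self.ecrs) if e.kind is ECRKind.PSEUDOKNOTTED]

    def stem_id(self, h: Stem) -> int:
        return self.stems.index(h)

    def loop_position_sets(self) -> list[set]:
        if not self._loop_pos:
            self._loop_pos = [set(l.positions) for l in self.loops]
        return self._loop_pos


def annotate(
    s: Structure,
    stem_type: StemType | str = StemType.STANDARD,
    min_pairs: int = 2,
    keep_isolated: bool = False,
) -> Annotation:
    """Annotate a structure end to end.

    ``keep_isolated=True`` promotes isolated pairs to 1-pair arbitrary
    pseudo-stems (exploratory; the default excludes them from all ECR and
    loop computations).
    """
    stems, isolated = find_stems(s, stem_type=stem_type, min_pairs=min_pairs)
    if keep_isolated:
        stems = sorted(
            stems + [_isolated_stem(p) for p in isolated],
            key=lambda h: h.face[0],
        )
        isolated = []
    ecrs = find_ecrs(s, stems)
    loops = [loop_of(s, h, stems) for h in stems]
    sigs = []
    for e in all_ecrs(ecrs):
        if e.kind.value == "pseudoknotted":
            full = full_signature(e)
            upper = upper_signature(e)
            red = reduced_signature(e)
            sigs.append((e, full, upper, red, named_class(red)))
    return Annotation(
        structure=s,
        stems=stems,
        isolated_pairs=isolated,
        ecrs=ecrs,
        loops=loops,
        exterior=exterior_segments(s, ecrs),
        signatures=sigs,
    )


def report(ann: Annotation) -> dict:
    """Serialize an annotation to the versioned report dictionary.

    The JSON schema shipped as ``report_schema.json`` documents this
    layout.
    """
    s = ann.structure
    stem_ids = {h: k for k, h in enumerate(ann.stems)}
    flat = all_ecrs(ann.ecrs)
    ecr_ids = {id(e): k for k, e in enumerate(flat)}
    parents: dict[int, int | None] = {id(e): None for e in flat}
    depth: dict[int, int] = {}

    def _walk(e: ECR, d: int) -> None:
        depth[id(e)] = d
        for c in e.children:
            parents[id(c)] = ecr_ids[id(e)]
            _walk(c, d + 1)

    for top in ann.ecrs:
        _walk(top, 0)

    sig_by_ecr = {id(e): (f, u, r, nc) for (e, f, u, r, nc) in ann.signatures}
    return {
        "schema_version": SCHEMA_VERSION,
        "name": s.name,
        "length": s.length,
        "sequence": s.sequence,
        "dotbracket": write_dotbracket(s),
        "stems": [
            {
                "id": k,
                "face": list(h.face),
                "internal_pair": list(h.internal_pair),
                "left_wing": list(h.left_wing),
                "right_wing": list(h.right_wing),
                "n_pairs": len(h.pairs),
                "type": h.stem_type.value,
            }
            for k, h in enumerate(ann.stems)
        ],
        "isolated_pairs": [list(p) for p in ann.isolated_pairs],
        "ecrs": [
            {
                "id": ecr_ids[id(e)],
                "interval": list(e.interval),
                "kind": e.kind.value,
                "parent": parents[id(e)],
                "depth": depth[id(e)],
                "member_stems": [stem_ids[h] for h in e.member_stems],
            }
            for e in flat
        ],
        "exterior_segments": [list(seg) for seg in ann.exterior],
        "loops": [
            {
                "stem": stem_ids[l.owner],
                "sides": [[side.start, side.end] for side in l.sides],
                "faces": [
                    {"i": f.i, "j": f.j, "tag": f.tag.value} for f in l.faces
                ],
                "wings_contained": [list(w) for w in l.wings_contained],
                "size_class": l.size_class.value,
                "pk_class": l.pk_class.value,
            }
            for l in ann.loops
        ],
        "signatures": [
            {
                "ecr": ecr_ids[id(e)],
                "full": sig_by_ecr[id(e)][0].word,
                "upper": sig_by_ecr[id(e)][1].word,
                "reduced": sig_by_ecr[id(e)][2].word,
                "named_class": sig_by_ecr[id(e)][3].value,
            }
            for (e, *_rest) in ann.signatures
        ],
    }
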