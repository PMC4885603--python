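"""Collection-level statistics over annotated structures."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .annotate import Annotation
from .ecr import ECRKind, all_ecrs

__all__ = ["StatsReport", "collect_stats"]


@dataclass
class StatsReport:
    """Aggregated per-motif counts; totals are sums over structures."""

    n_structures: int = 0
    n_base_pairs: int = 0
    n_stems: int = 0
    n_isolated_pairs: int = 0
    n_loops: int = 0
    loops_by_class: Counter = field(default_factory=Counter)  # (size, pk)
    ecrs_by_kind: Counter = field(default_factory=Counter)
    n_pseudoknots: int = 0
    signature_counts: Counter = field(default_factory=Counter)  # reduced word
    named_class_counts: Counter = field(default_factory=Counter)

    def signature_table(self) -> list[tuple[str, int]]:
        """Reduced-signature frequencies, by count desc then word."""
        return sorted(self.signature_counts.items(), key=lambda kv: (-kv[1], kv[0]))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("structures", self.n_structures),
            ("base_pairs", self.n_base_pairs),
            ("stems", self.n_stems),
            ("isolated_pairs", self.n_isolated_pairs),
            ("loops", self.n_loops),
            ("ecrs_classical", self.ecrs_by_kind.get("classical", 0)),
            ("ecrs_pseudoknotted", self.ecrs_by_kind.get("pseudoknotted", 0)),
            ("pseudoknots", self.n_pseudoknots),
        ]
        rows += [
            (f"loops_{size}_{pk}", n)
            for (size, pk), n in sorted(self.loops_by_class.items())
        ]
        return pd.DataFrame(rows, columns=["motif", "count"]).set_index("motif")

    def __add__(self, other: "StatsReport") -> "StatsReport":
        return StatsReport(
            n_structures=self.n_structures + other.n_structures,
            n_base_pairs=self.n_base_pairs + other.n_base_pairs,
            n_stems=self.n_stems + other.n_stems,
            n_isolated_pairs=self.n_isolated_pairs + other.n_isolated_pairs,
            n_loops=self.n_loops + other.n_loops,
            loops_by_class=self.loops_by_class + other.loops_by_class,
            ecrs_by_kind=self.ecrs_by_kind + other.ecrs_by_kind,
            n_pseudoknots=self.n_pseudoknots + other.n_pseudoknots,
            signature_counts=self.signature_counts + other.signature_counts,
            named_class_counts=self.named_class_counts + other.named_class_counts,
        )


def collect_stats(annotations: list[Annotation]) -> StatsReport:
    """Deterministic counts over a collection (empty input -> all zeros)."""
    rep = StatsReport()
    for ann in annotations:
        rep.n_structures += 1
        rep.n_base_pairs += len(ann.structure.pairs)
        rep.n_stems += len(ann.stems)
        rep.n_isolated_pairs += len(ann.isolated_pairs)
        rep.n_loops += len(ann.loops)
        for l in ann.loops:
            rep.loops_by_class[(l.size_class.value, l.pk_class.value)] += 1
        for e in all_ecrs(ann.ecrs):
            rep.ecrs_by_kind[e.kind.value] += 1
            if e.kind is ECRKind.PSEUDOKNOTTED:
                rep.n_pseudoknots += 1
        for (_e, _f, _u, red, nc) in ann.signatures:
            rep.signature_counts[red.word] += 1
            rep.named_class_counts[nc.value] += 1
    return rep
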