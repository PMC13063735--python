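"""Assignment of ChIP-seq peak summits to TE copies and binding tallies.

A summit is a single base; it is assigned to the TE copy whose interval
contains it.  Where RepeatMasker annotations overlap, the copy with the
higher Smith-Waterman score wins, ties broken by the smaller interval and
then lexicographic copy_id, so results never depend on input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from terep.types import PeakSummit, TECopy


@dataclass
class SummitAssignment:
    peak_id: str
    copy_id: Optional[str]
    family: Optional[str] = None
    subfamily: Optional[str] = None
    te_class: Optional[str] = None
    cell: str = ""
    tf: str = ""

    @property
    def assigned(self) -> bool:
        return self.copy_id is not None


class TEIndex:
    """Point-in-interval lookup over TE copies.

    Uses a numpy sorted-array fast path when the annotation is
    non-overlapping per chromosome (the common case for processed
    RepeatMasker output) and falls back to an interval tree otherwise.
    """

    def __init__(self, copies: Sequence[TECopy]):
        self.copies = list(copies)
        self._offset = {id(c): k for k, c in enumerate(self.copies)}
        self._fast: dict[str, tuple[np.ndarray, np.ndarray, list[TECopy]]] = {}
        self._trees: dict[str, IntervalTree] = {}
        by_chrom: dict[str, list[TECopy]] = {}
        for c in self.copies:
            by_chrom.setdefault(c.interval.chrom, []).append(c)
        for chrom, group in by_chrom.items():
            group.sort(key=lambda c: (c.interval.start, c.interval.end))
            overlapping = any(
                group[i].interval.end > group[i + 1].interval.start
                for i in range(len(group) - 1)
            )
            if overlapping:
                tree = IntervalTree()
                for c in group:
                    tree[c.interval.start : c.interval.end] = c
                self._trees[chrom] = tree
            else:
                starts = np.array([c.interval.start for c in group])
                ends = np.array([c.interval.end for c in group])
                self._fast[chrom] = (starts, ends, group)

    def lookup(self, chrom: str, pos: int) -> Optional[TECopy]:
        """The winning TE copy containing ``pos``, or None."""
        if chrom in self._fast:
            starts, ends, group = self._fast[chrom]
            i = int(np.searchsorted(starts, pos, side="right")) - 1
            if i >= 0 and pos < ends[i]:
                return group[i]
            return None
        tree = self._trees.get(chrom)
        if tree is None:
            return None
        hits = [iv.data for iv in tree[pos]]
        if not hits:
            return None
        return min(
            hits,
            key=lambda c: (-c.sw_score, len(c.interval), c.copy_id),
        )

    def lookup_many(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorised lookup returning the copy index into ``self.copies``
        per position (-1 when unassigned).  Only valid on the fast path."""
        positions = np.asarray(positions)
        out = np.full(len(positions), -1, dtype=int)
        if chrom not in self._fast:
            for j, pos in enumerate(positions):
                hit = self.lookup(chrom, int(pos))
                if hit is not None:
                    out[j] = self._offset[id(hit)]
            return out
        starts, ends, group = self._fast[chrom]
        group_idx = np.array([self._offset[id(c)] for c in group])
        idx = np.searchsorted(starts, positions, side="right") - 1
        valid = (idx >= 0) & (positions < ends[np.clip(idx, 0, None)])
        out[valid] = group_idx[idx[valid]]
        return out


def assign_summits(
    summits: Iterable[PeakSummit], te_copies: Sequence[TECopy]
) -> list[SummitAssignment]:
    """Assign each 1-bp summit to at most one TE copy by containment."""
    index = te_copies if isinstance(te_copies, TEIndex) else TEIndex(te_copies)
    out = []
    for s in summits:
        hit = index.lookup(s.interval.chrom, s.pos)
        if hit is None:
            out.append(
                SummitAssignment(s.peak_id, None, cell=s.cell, tf=s.tf)
            )
        else:
            out.append(
                SummitAssignment(
                    peak_id=s.peak_id,
                    copy_id=hit.copy_id,
                    family=hit.family,
                    subfamily=hit.subfamily,
                    te_class=hit.te_class,
                    cell=s.cell,
                    tf=s.tf,
                )
            )
    return out


def percent(k: int, n: int) -> float:
    """A proportion as percent, rounded to one decimal as reported."""
    if n == 0:
        return 0.0
    return round(100.0 * k / n, 1)


@dataclass
class BindingTable:
    """Binding-site tallies by family/subfamily/class for one (tf, cell)."""

    tf: str
    cell: str
    total_summits: int
    te_assigned: int
    family_counts: dict[str, int]
    subfamily_counts: dict[str, int]
    class_counts: dict[str, int]

    @property
    def te_fraction_pct(self) -> float:
        return percent(self.te_assigned, self.total_summits)

    def class_composition_pct(self) -> dict[str, float]:
        return {
            cls: percent(n, self.total_summits)
            for cls, n in sorted(self.class_counts.items())
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"level": "family", "name": k, "count": v}
            for k, v in sorted(self.family_counts.items())
        ] + [
            {"level": "subfamily", "name": k, "count": v}
            for k, v in sorted(self.subfamily_counts.items())
        ]
        return pd.DataFrame(rows, columns=["level", "name", "count"])


def composition_table(assignments: Sequence[SummitAssignment]) -> BindingTable:
    """Tabulate assignments into per-family/subfamily/class counts."""
    tf = assignments[0].tf if assignments else ""
    cell = assignments[0].cell if assignments else ""
    fam: dict[str, int] = {}
    sub: dict[str, int] = {}
    cls: dict[str, int] = {}
    assigned = 0
    for a in assignments:
        if not a.assigned:
            continue
        assigned += 1
        fam[a.family] = fam.get(a.family, 0) + 1
        sub[a.subfamily] = sub.get(a.subfamily, 0) + 1
        cls[a.te_class] = cls.get(a.te_class, 0) + 1
    return BindingTable(
        tf=tf,
        cell=cell,
        total_summits=len(assignments),
        te_assigned=assigned,
        family_counts=fam,
        subfamily_counts=sub,
        class_counts=cls,
    )


def shared_sites(
    assignments_a: Sequence[SummitAssignment],
    assignments_b: Sequence[SummitAssignment],
) -> dict[str, int]:
    """Counts of TE copies bound only in A, only in B, and in both.

    "Shared" is defined at the TE-copy level: the same copy_id carries a
    summit in both cell types, regardless of the exact summit coordinate.
    """
    set_a = {a.copy_id for a in assignments_a if a.assigned}
    set_b = {a.copy_id for a in assignments_b if a.assigned}
    return {
        "a_only": len(set_a - set_b),
        "b_only": len(set_b - set_a),
        "shared": len(set_a & set_b),
    }


def write_assignments(assignments: Sequence[SummitAssignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("peak_id\tcopy_id\tfamily\tsubfamily\tte_class\tcell\ttf\n")
        for a in assignments:
            fh.write(
                "\t".join(
                    [
                        a.peak_id,
                        a.copy_id or ".",
                        a.family or ".",
                        a.subfamily or ".",
                        a.te_class or ".",
                        a.cell,
                        a.tf,
                    ]
                )
                + "\n"
            )


def read_assignments(path) -> list[SummitAssignment]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "peak_id")):
                continue
            t = line.rstrip("\n").split("\t")
            out.append(
                SummitAssignment(
                    peak_id=t[0],
                    copy_id=None if t[1] == "." else t[1],
                    family=None if t[2] == "." else t[2],
                    subfamily=None if t[3] == "." else t[3],
                    te_class=None if t[4] == "." else t[4],
                    cell=t[5],
                    tf=t[6],
                )
            )
    return out
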