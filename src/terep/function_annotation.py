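"""Chromatin-state annotation of binding sites and conservation profiling.

Sixteen learned chromatin-state labels (ChromHMM-style segmentations are
consumed, never trained here) are collapsed to five functional categories
via a mapping table: cis-regulatory (promoters + enhancers),
transcription, quiescent/low, heterochromatin, and other.  Cis-regulatory
enrichment is tested against the category fraction of sampled input-read
positions; ESC->NPC functional change is summarised as a category
transition matrix over cell-type-specific binding sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from terep.enrichment import binomial_two_sided
from terep.io_formats import ScoreTrack
from terep.types import GenomicInterval

logger = logging.getLogger(__name__)

CATEGORIES = (
    "cis-regulatory",
    "transcription",
    "quiescent/low",
    "heterochromatin",
    "other",
)


@dataclass
class StateAssignment:
    site_id: str
    cell: str
    state: Optional[str]
    category: str


class Segmentation:
    """A per-chromosome, non-overlapping tiling of (interval, state)."""

    def __init__(self, segments: Sequence[tuple[GenomicInterval, str]]):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
        by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for iv, state in segments:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, state))
        for chrom, rows in by_chrom.items():
            rows.sort()
            for (s1, e1, _), (s2, _, _) in zip(rows, rows[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"overlapping segments on {chrom} at {s2}"
                    )
            starts = np.array([r[0] for r in rows])
            ends = np.array([r[1] for r in rows])
            states = [r[2] for r in rows]
            self._by_chrom[chrom] = (starts, ends, states)

    def state_at(self, chrom: str, pos: int) -> Optional[str]:
        if chrom not in self._by_chrom:
            return None
        starts, ends, states = self._by_chrom[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return states[i]
        return None


def read_segmentation_bed(path) -> Segmentation:
    """Read a 4-column BED of state labels into a Segmentation."""
    segments = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            t = line.split()
            try:
                segments.append(
                    (GenomicInterval(t[0], int(t[1]), int(t[2])), t[3])
                )
            except (IndexError, ValueError) as exc:
                raise ValueError(
                    f"{path}: bad segmentation line {lineno}"
                ) from exc
    return Segmentation(segments)


def read_state_category_map(path) -> dict[str, str]:
    """Read the state -> category mapping TSV (columns: state, category)."""
    mapping = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "state\t")):
                continue
            t = line.rstrip("\n").split("\t")
            if t[1] not in CATEGORIES:
                raise ValueError(f"unknown category {t[1]!r} in {path}")
            mapping[t[0]] = t[1]
    return mapping


def assign_state(
    site_id: str,
    chrom: str,
    pos: int,
    cell: str,
    segmentation: Segmentation,
    state_category_map: dict[str, str],
) -> StateAssignment:
    """The chromatin state at a summit base and its collapsed category.

    A summit falling in an un-annotated gap gets category "other" with a
    logged note; a state missing from the mapping is an error.
    """
    state = segmentation.state_at(chrom, pos)
    if state is None:
        logger.warning("site %s at %s:%d has no state; -> other", site_id, chrom, pos)
        return StateAssignment(site_id, cell, None, "other")
    if state not in state_category_map:
        raise KeyError(f"state {state!r} missing from category map")
    return StateAssignment(site_id, cell, state, state_category_map[state])


def assign_states(
    sites: Sequence[tuple[str, str, int]],
    cell: str,
    segmentation: Segmentation,
    state_category_map: dict[str, str],
) -> list[StateAssignment]:
    return [
        assign_state(site_id, chrom, pos, cell, segmentation, state_category_map)
        for site_id, chrom, pos in sites
    ]


def cisreg_overlap_test(
    assignments: Sequence[StateAssignment],
    control_assignments: Sequence[StateAssignment],
) -> tuple[float, float]:
    """Fraction of sites in cis-regulatory states and its two-sided
    binomial p against the control (input-position) fraction."""
    n = len(assignments)
    k = sum(1 for a in assignments if a.category == "cis-regulatory")
    n0 = len(control_assignments)
    k0 = sum(1 for a in control_assignments if a.category == "cis-regulatory")
    if n == 0 or n0 == 0:
        raise ValueError("empty site or control list")
    p0 = k0 / n0
    if not 0 < p0 < 1:
        raise ValueError("degenerate control cis-regulatory fraction")
    return k / n, binomial_two_sided(k, n, p0)


@dataclass
class TransitionMatrix:
    counts: pd.DataFrame  # rows: category in cell A; cols: category in cell B
    n_total: int  # all cell-specific sites offered
    n_with_both: int  # sites with a state in both cells

    @property
    def row_fractions(self) -> pd.DataFrame:
        sums = self.counts.sum(axis=1)
        frac = self.counts.div(sums.replace(0, np.nan), axis=0)
        return frac.fillna(0.0)


def transition_matrix(
    states_a: Sequence[StateAssignment],
    states_b: Sequence[StateAssignment],
) -> TransitionMatrix:
    """Cross-tabulate functional categories of the same sites in two cell
    types (matched by site_id); sites lacking a state in either cell are
    counted in ``n_total`` but excluded from the matrix."""
    b_by_site = {a.site_id: a for a in states_b}
    index = list(CATEGORIES)
    counts = pd.DataFrame(0, index=index, columns=index, dtype=int)
    n_both = 0
    for a in states_a:
        b = b_by_site.get(a.site_id)
        if b is None:
            continue
        n_both += 1
        counts.loc[a.category, b.category] += 1
    return TransitionMatrix(
        counts=counts, n_total=len(states_a), n_with_both=n_both
    )


@dataclass
class WelchResult:
    mean_a: float
    mean_b: float
    t: float
    df: float
    p: float


def conservation_compare(
    sites: Sequence[tuple[str, int]],
    track: ScoreTrack,
    control_sites: Sequence[tuple[str, int]],
    window: int = 2000,
) -> WelchResult:
    """Compare mean conservation over a window centered on each site
    against control positions with a two-sided Welch's t-test.

    Per-site means exclude positions missing from the track; sites with no
    covered base at all are dropped.
    """

    def group_means(group):
        means = []
        for chrom, pos in group:
            half = window // 2
            m = track.window_mean(chrom, max(0, pos - half), pos + half)
            if m == m:  # not NaN
                means.append(m)
        return np.array(means)

    a = group_means(sites)
    b = group_means(control_sites)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two covered sites per group")
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
    )
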