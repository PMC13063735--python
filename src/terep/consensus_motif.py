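"""Projection of binding sites onto TE consensus coordinates, positional
clustering, and PWM motif scanning of consensus sequences.

A family that propagated a TF-binding motif by retrotransposition leaves
two signatures: binding sites pile up at one position of the family
consensus, and the consensus itself carries the motif at that position.
``propagation_evidence`` bundles both tests.

The PWM scanner computes exact per-window p-values from the null score
distribution by dynamic programming over integer-scaled log-odds scores,
the classic approach of exact motif-scanning statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from terep.enrichment import binomial_two_sided
from terep.types import AlignmentRecord, BASE_INDEX, PWM

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Consensus projection
# ---------------------------------------------------------------------------


def project_to_consensus(
    genomic_pos: int, rec: AlignmentRecord
) -> Optional[int]:
    """Map a genomic position inside an aligned TE copy to the 1-based
    consensus coordinate of its alignment column.

    Returns None when the column is a consensus gap (an insertion in the
    copy); raises when the position lies outside the aligned span.
    """
    g = rec.genomic
    if not g.contains(genomic_pos):
        raise ValueError(
            f"position {genomic_pos} outside aligned span "
            f"[{g.start},{g.end}) of {rec.copy_id}"
        )
    if rec.orientation == "reverse":
        offset = g.end - 1 - genomic_pos
    else:
        offset = genomic_pos - g.start
    q_seen = 0
    c_seen = 0
    for qc, cc in zip(rec.gapped_query, rec.gapped_consensus):
        is_q = qc != "-"
        is_c = cc != "-"
        if is_q:
            if q_seen == offset:
                if not is_c:
                    return None
                return rec.consensus_start + c_seen
            q_seen += 1
        if is_c:
            c_seen += 1
    raise AssertionError("offset not reached; invariant violation")


def consensus_to_genomic(cpos: int, rec: AlignmentRecord) -> Optional[int]:
    """Inverse projection: the genomic position of 1-based consensus
    coordinate ``cpos``, or None when that column is deleted in the copy."""
    if not rec.consensus_start <= cpos <= rec.consensus_end:
        raise ValueError(
            f"consensus position {cpos} outside span of {rec.copy_id}"
        )
    target = cpos - rec.consensus_start
    q_seen = 0
    c_seen = 0
    for qc, cc in zip(rec.gapped_query, rec.gapped_consensus):
        is_q = qc != "-"
        is_c = cc != "-"
        if is_c:
            if c_seen == target:
                if not is_q:
                    return None
                if rec.orientation == "reverse":
                    return rec.genomic.end - 1 - q_seen
                return rec.genomic.start + q_seen
            c_seen += 1
        if is_q:
            q_seen += 1
    raise AssertionError("consensus position not reached")


@dataclass
class ConsensusHit:
    copy_id: str
    family: str
    consensus_pos: int  # 1-based
    peak_id: str


# ---------------------------------------------------------------------------
# Positional clustering
# ---------------------------------------------------------------------------


@dataclass
class PositionCluster:
    family: str
    window_start: int  # 1-based inclusive
    window_end: int  # 1-based inclusive
    n_in_window: int
    n_total: int
    p_cluster: float  # two-sided binomial, Bonferroni over window offsets

    @property
    def center(self) -> float:
        return (self.window_start + self.window_end) / 2


def cluster_positions(
    hits: Sequence[ConsensusHit | int],
    consensus_length: int,
    window_size: int = 50,
    family: str = "",
) -> PositionCluster:
    """Find the maximum-count sliding window of binding positions on the
    consensus and test its concentration.

    The null is uniform placement: the count in a fixed window of width w
    is Binomial(n_total, w/L).  The two-sided p-value of the best window is
    Bonferroni-corrected by the number of distinct window offsets.
    """
    if not hits:
        raise ValueError("cluster_positions requires at least one hit")
    positions = np.array(
        [h.consensus_pos if isinstance(h, ConsensusHit) else int(h) for h in hits]
    )
    if positions.min() < 1 or positions.max() > consensus_length:
        raise ValueError("hit positions outside consensus")
    window_size = min(window_size, consensus_length)
    counts = np.bincount(positions, minlength=consensus_length + 1)[1:]
    window_counts = np.convolve(counts, np.ones(window_size, dtype=int), "valid")
    # among tied maximum windows take the middle offset, so a tight pile of
    # hits ends up centred in its window rather than at its right edge
    tied = np.nonzero(window_counts == window_counts.max())[0]
    best = int(tied[len(tied) // 2])
    n_in = int(window_counts[best])
    n_total = len(positions)
    n_offsets = consensus_length - window_size + 1
    p0 = window_size / consensus_length
    p = binomial_two_sided(n_in, n_total, p0)
    p_cluster = min(1.0, p * n_offsets)
    return PositionCluster(
        family=family,
        window_start=best + 1,
        window_end=best + window_size,
        n_in_window=n_in,
        n_total=n_total,
        p_cluster=p_cluster,
    )


# ---------------------------------------------------------------------------
# PWM scanning with exact p-values
# ---------------------------------------------------------------------------

_SCALE = 1000  # integer score scale for the exact null DP


@dataclass
class MotifMatch:
    start: int  # 1-based inclusive on the scanned sequence
    end: int  # 1-based inclusive
    strand: str
    score: float  # log2 odds
    p_match: float


class _ScoredPWM:
    """Integer-scaled log-odds matrix plus its exact null distribution."""

    def __init__(self, pwm: PWM, pseudocount: float = 0.001):
        matrix = pwm.matrix.copy()
        matrix[matrix == 0] = pseudocount
        matrix /= matrix.sum(axis=1, keepdims=True)
        self.logodds = np.log2(matrix / pwm.background)
        self.int_scores = np.rint(self.logodds * _SCALE).astype(int)
        self.width = pwm.width
        self.background = pwm.background
        self._survival, self._offset = self._null_distribution()

    def _null_distribution(self) -> tuple[np.ndarray, int]:
        # distribution of the integer window score under background base
        # frequencies, by position-wise convolution
        dist = np.array([1.0])
        offset = 0  # current distribution covers scores [offset, offset+len)
        for i in range(self.width):
            row = self.int_scores[i]
            new_lo = offset + int(row.min())
            new_hi = offset + len(dist) - 1 + int(row.max())
            new = np.zeros(new_hi - new_lo + 1)
            for b in range(4):
                s = int(row[b])
                start = offset + s - new_lo
                new[start : start + len(dist)] += self.background[b] * dist
            dist, offset = new, new_lo
        survival = dist[::-1].cumsum()[::-1]
        return survival, offset

    def pvalue(self, int_score: int) -> float:
        """P(window score >= int_score) under the background model."""
        idx = int_score - self._offset
        if idx < 0:
            return 1.0
        if idx >= len(self._survival):
            return 0.0
        return float(self._survival[idx])


def scan_pwm(
    sequence: str,
    pwm: PWM,
    threshold_p: float = 0.01,
    pseudocount: float = 0.001,
) -> list[MotifMatch]:
    """Scan both strands of a sequence for PWM matches with exact p-value
    below ``threshold_p``; windows containing non-ACGT bases are skipped.
    Matches are returned sorted by start position."""
    seq = sequence.upper()
    scored = _ScoredPWM(pwm, pseudocount)
    w = scored.width
    if len(seq) < w:
        return []
    codes = np.array([BASE_INDEX.get(b, -1) for b in seq])
    matches: list[MotifMatch] = []
    for strand in ("+", "-"):
        if strand == "+":
            strand_codes = codes
        else:
            # reverse complement: A<->T (0<->3), C<->G (1<->2)
            strand_codes = np.where(codes >= 0, 3 - codes, -1)[::-1]
        valid = strand_codes >= 0
        for i in range(len(seq) - w + 1):
            win = strand_codes[i : i + w]
            if not valid[i : i + w].all():
                continue
            int_score = int(scored.int_scores[np.arange(w), win].sum())
            p = scored.pvalue(int_score)
            if p < threshold_p:
                if strand == "+":
                    start = i + 1
                else:
                    start = len(seq) - (i + w) + 1
                matches.append(
                    MotifMatch(
                        start=start,
                        end=start + w - 1,
                        strand=strand,
                        score=int_score / _SCALE,
                        p_match=p,
                    )
                )
    matches.sort(key=lambda m: (m.start, m.strand))
    return matches


# ---------------------------------------------------------------------------
# Propagation evidence
# ---------------------------------------------------------------------------


@dataclass
class PropagationReport:
    family: str
    cluster: Optional[PositionCluster]
    motif_matches: list[MotifMatch] = field(default_factory=list)
    candidate: bool = False
    motif_retention: Optional[float] = None
    note: str = ""


def propagation_evidence(
    family: str,
    hits: Sequence[ConsensusHit],
    consensus_seq: str,
    pwm: PWM,
    alignments: Optional[Sequence[AlignmentRecord]] = None,
    window_size: int = 50,
    alpha: float = 0.001,
    motif_p: float = 0.01,
) -> PropagationReport:
    """Test whether a family shows retrotransposition-propagated binding.

    The family is flagged a propagation candidate when (a) the binding
    positions cluster significantly on the consensus (Bonferroni-corrected
    binomial p < alpha) and (b) the best cluster window overlaps a PWM
    match in the consensus sequence.  When copy alignments are supplied,
    the fraction of hit copies whose own sequence retains a motif match
    overlapping the cluster window is also reported.
    """
    if not hits:
        return PropagationReport(family, None, note="no evidence: zero hits")
    cluster = cluster_positions(
        hits, len(consensus_seq), window_size=window_size, family=family
    )
    matches = scan_pwm(consensus_seq, pwm, threshold_p=motif_p)
    overlapping = [
        m
        for m in matches
        if m.start <= cluster.window_end and m.end >= cluster.window_start
    ]
    candidate = bool(cluster.p_cluster < alpha and overlapping)
    retention = None
    if alignments is not None and candidate:
        by_copy = {rec.copy_id: rec for rec in alignments}
        retained = total = 0
        for copy_id in sorted({h.copy_id for h in hits}):
            rec = by_copy.get(copy_id)
            if rec is None:
                continue
            total += 1
            copy_seq = rec.gapped_query.replace("-", "")
            for m in scan_pwm(copy_seq, pwm, threshold_p=motif_p):
                # map the copy-local match midpoint to the consensus
                mid_q = (m.start + m.end) // 2 - 1
                if rec.orientation == "reverse":
                    gpos = rec.genomic.end - 1 - mid_q
                else:
                    gpos = rec.genomic.start + mid_q
                cpos = project_to_consensus(gpos, rec)
                if (
                    cpos is not None
                    and cluster.window_start - len(consensus_seq) // 10
                    <= cpos
                    <= cluster.window_end + len(consensus_seq) // 10
                ):
                    retained += 1
                    break
        retention = retained / total if total else None
    return PropagationReport(
        family=family,
        cluster=cluster,
        motif_matches=matches,
        candidate=candidate,
        motif_retention=retention,
        note="propagation candidate" if candidate else "no propagation signal",
    )
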