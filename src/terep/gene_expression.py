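"""Nearest-gene linkage of binding TEs and expression-change accounting.

Each binding site links to the nearest transcript TSS (collapsed to its
gene).  Distances are signed by the gene's transcription direction: a
negative distance puts the TE upstream of the TSS.  Expression coupling is
summarised as up/down counts of nearest genes by log2 fold change
(NPC/ESC), with "strong" classes at more than eightfold (|log2FC| > 3).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from terep.types import GenomicInterval

logger = logging.getLogger(__name__)

STRONG_LOG2FC = 3.0  # eightfold


@dataclass
class NearestGeneLink:
    site_id: str
    gene_id: Optional[str]
    signed_distance: Optional[int]  # negative: TE upstream of the TSS
    log2fc: Optional[float] = None


class TSSIndex:
    """Per-chromosome sorted TSS positions for nearest-gene queries."""

    def __init__(self, tss_list: Sequence[tuple[str, GenomicInterval, str]]):
        by_chrom: dict[str, list[tuple[int, str, str]]] = {}
        for gene_id, iv, strand in tss_list:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, gene_id, strand))
        self._by_chrom = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            self._by_chrom[chrom] = (
                np.array([r[0] for r in rows]),
                [r[1] for r in rows],
                [r[2] for r in rows],
            )

    def nearest(self, chrom: str, pos: int) -> Optional[tuple[str, int, str]]:
        """(gene_id, tss_pos, strand) minimising unsigned distance; ties go
        to the lexicographically smaller gene_id."""
        if chrom not in self._by_chrom:
            return None
        positions, genes, strands = self._by_chrom[chrom]
        i = int(np.searchsorted(positions, pos))
        candidates = []
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(positions):
                candidates.append(j)
        # among equal positions there may be several genes; widen to all
        # entries sharing the two flanking coordinates
        best = None
        for j in candidates:
            d = abs(int(positions[j]) - pos)
            key = (d, genes[j])
            if best is None or key < best[0]:
                best = (key, j)
        # scan neighbours with the same distance for gene_id tie-break
        d_best = best[0][0]
        for j in range(len(positions)):
            d = abs(int(positions[j]) - pos)
            if d == d_best and (genes[j], ) < (genes[best[1]], ):
                best = ((d, genes[j]), j)
        j = best[1]
        return genes[j], int(positions[j]), strands[j]


def signed_distance(summit_pos: int, tss_pos: int, gene_strand: str) -> int:
    """Signed summit-TSS distance; negative when the summit lies upstream
    of the TSS relative to the direction of transcription."""
    if gene_strand == "-":
        return tss_pos - summit_pos
    return summit_pos - tss_pos


def nearest_tss(
    site_id: str,
    chrom: str,
    summit_pos: int,
    tss_index: TSSIndex,
) -> NearestGeneLink:
    hit = tss_index.nearest(chrom, summit_pos)
    if hit is None:
        logger.warning("no TSS on chromosome %s for site %s", chrom, site_id)
        return NearestGeneLink(site_id, None, None)
    gene_id, tss_pos, strand = hit
    return NearestGeneLink(
        site_id, gene_id, signed_distance(summit_pos, tss_pos, strand)
    )


def log2fc(rpkm_esc: float, rpkm_npc: float, pseudocount: float = 0.01) -> float:
    """log2((NPC + c) / (ESC + c)); the pseudocount keeps zero-RPKM genes
    finite."""
    return math.log2((rpkm_npc + pseudocount) / (rpkm_esc + pseudocount))


@dataclass
class ExpressionClassCounts:
    group: str
    up: int
    down: int
    strong_up: int
    strong_down: int

    @property
    def up_down_ratio(self) -> float:
        return ratio(self.up, self.down)

    @property
    def strong_ratio(self) -> float:
        return ratio(self.strong_up, self.strong_down)


def ratio(a: int, b: int) -> float:
    """a/b reported to one decimal, as in up/down imbalance summaries."""
    if b == 0:
        return math.inf if a > 0 else math.nan
    return round(a / b, 1)


def classify_and_count(
    links: Sequence[NearestGeneLink],
    expression: dict[str, tuple[float, float]],
    group: str = "",
    pseudocount: float = 0.01,
    strong_threshold: float = STRONG_LOG2FC,
) -> ExpressionClassCounts:
    """Count up/down and strongly up/down nearest genes for a site group.

    Each link's gene is classified once per link occurrence by its log2
    NPC/ESC fold change.  Genes with zero RPKM in both cells are
    uninformative and excluded (logged).
    """
    up = down = strong_up = strong_down = 0
    for link in links:
        if link.gene_id is None:
            continue
        if link.gene_id not in expression:
            logger.warning("gene %s missing from expression table", link.gene_id)
            continue
        esc, npc = expression[link.gene_id]
        if esc == 0 and npc == 0:
            logger.warning("gene %s has zero RPKM in both cells; excluded", link.gene_id)
            continue
        fc = log2fc(esc, npc, pseudocount)
        link.log2fc = fc
        if fc > 0:
            up += 1
            if fc >= strong_threshold:  # inclusive: an exact 8x effect counts
                strong_up += 1
        elif fc < 0:
            down += 1
            if fc <= -strong_threshold:
                strong_down += 1
    return ExpressionClassCounts(
        group=group, up=up, down=down, strong_up=strong_up, strong_down=strong_down
    )


def write_links(links: Sequence[NearestGeneLink], path) -> None:
    with open(path, "w") as fh:
        fh.write("site_id\tgene_id\tsigned_distance\tlog2fc\n")
        for ln in links:
            fc = f"{ln.log2fc:.4f}" if ln.log2fc is not None else "."
            dist = str(ln.signed_distance) if ln.signed_distance is not None else "."
            fh.write(f"{ln.site_id}\t{ln.gene_id or '.'}\t{dist}\t{fc}\n")
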