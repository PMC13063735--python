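"""Per-family binding enrichment against an input-read background, and the
Kimura two-parameter (K2P) age axis.

Fold enrichment for a TE family is

    fold = (k / n) / (k0 / n0)

where k of n ChIP-seq summits and k0 of n0 sampled input reads fall in the
family.  Significance is an exact two-sided binomial test of k given n and
the background proportion p0 = k0/n0, Bonferroni-corrected over the number
of families tested, with the significance call at adjusted p < 0.001.

Family age is the mean K2P divergence of its copies from the consensus:
K = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)), with P and Q the transition and
transversion fractions over gap-free alignment columns, reported x100.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from terep.te_overlap import BindingTable, TEIndex
from terep.types import AlignmentRecord, GenomicInterval, TECopy

logger = logging.getLogger(__name__)

ALPHA = 0.001  # Bonferroni-adjusted significance threshold

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
VALID = {"A", "C", "G", "T"}


# ---------------------------------------------------------------------------
# Background model
# ---------------------------------------------------------------------------


@dataclass
class BackgroundModel:
    """Input-read counts per family, the empirical null for enrichment."""

    total: int
    family_counts: dict[str, int]
    subfamily_counts: dict[str, int]

    def p0(self, family: str, level: str = "family") -> float:
        counts = (
            self.family_counts if level == "family" else self.subfamily_counts
        )
        return counts.get(family, 0) / self.total


def build_background(
    input_reads: Sequence[GenomicInterval],
    te_copies: Sequence[TECopy] | TEIndex,
    sample_size: int = 1_000_000,
    seed: int = 0,
) -> BackgroundModel:
    """Sample input-read positions and count how many fall in each family.

    Reads are taken as 1-bp positions (their start).  ``sample_size`` reads
    are drawn without replacement; when fewer are available all are used
    with a logged warning.  Assignment reuses the summit-assignment
    semantics (point-in-interval, same tie-breaking).
    """
    index = te_copies if isinstance(te_copies, TEIndex) else TEIndex(te_copies)
    rng = np.random.default_rng(seed)
    reads = list(input_reads)
    if sample_size >= len(reads):
        if sample_size > len(reads):
            logger.warning(
                "sample_size %d exceeds available reads %d; using all",
                sample_size,
                len(reads),
            )
        chosen = reads
    else:
        idx = rng.choice(len(reads), size=sample_size, replace=False)
        chosen = [reads[i] for i in sorted(idx)]

    fam: dict[str, int] = {}
    sub: dict[str, int] = {}
    by_chrom: dict[str, list[int]] = {}
    for r in chosen:
        by_chrom.setdefault(r.chrom, []).append(r.start)
    for chrom, positions in by_chrom.items():
        hits = index.lookup_many(chrom, np.array(positions))
        for k in hits[hits >= 0]:
            c = index.copies[k]
            fam[c.family] = fam.get(c.family, 0) + 1
            sub[c.subfamily] = sub.get(c.subfamily, 0) + 1
    return BackgroundModel(
        total=len(chosen), family_counts=fam, subfamily_counts=sub
    )


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def fold_enrichment(k: int, n: int, p0: float) -> float:
    """(k/n)/p0; +inf (flagged by the caller) when p0 == 0 with k > 0."""
    if n <= 0:
        raise ValueError("n must be positive")
    if p0 == 0:
        return math.inf if k > 0 else math.nan
    return (k / n) / p0


def binomial_two_sided(k: int, n: int, p0: float) -> float:
    """Exact two-sided binomial p-value by the minimum-likelihood rule:
    the sum of P(X=i) over all i with P(X=i) <= P(X=k) * (1 + 1e-7)."""
    if not 0 <= k <= n:
        raise ValueError("k out of range")
    return stats.binomtest(k, n, p0, alternative="two-sided").pvalue


@dataclass
class EnrichmentResult:
    family: str
    k: int
    n: int
    p0: float
    fold: float
    p_raw: float
    p_adj: float
    significant: bool
    mean_k2p: Optional[float] = None
    level: str = "family"


def enrich_all(
    binding_table: BindingTable,
    background: BackgroundModel,
    level: str = "family",
    family_k2p: Optional[dict[str, float]] = None,
    families: Optional[Iterable[str]] = None,
    alpha: float = ALPHA,
) -> list[EnrichmentResult]:
    """One enrichment result per family with at least one genomic copy.

    ``families`` is the universe of testable families (all families with a
    genomic copy); Bonferroni m is its size.  Families absent from both the
    peaks and the background get an undefined fold rather than being
    silently dropped.
    """
    counts = (
        binding_table.family_counts
        if level == "family"
        else binding_table.subfamily_counts
    )
    bg_counts = (
        background.family_counts
        if level == "family"
        else background.subfamily_counts
    )
    if families is None:
        families = sorted(set(counts) | set(bg_counts))
    else:
        families = sorted(set(families))
    m = len(families)
    n = binding_table.total_summits
    results = []
    for fam in families:
        k = counts.get(fam, 0)
        p0 = bg_counts.get(fam, 0) / background.total
        fold = fold_enrichment(k, n, p0) if n > 0 else math.nan
        if 0 < p0 < 1:
            p_raw = binomial_two_sided(k, n, p0)
        elif p0 == 0:
            p_raw = 0.0 if k > 0 else 1.0  # degenerate null
        else:
            p_raw = 1.0
        p_adj = min(1.0, p_raw * m)
        results.append(
            EnrichmentResult(
                family=fam,
                k=k,
                n=n,
                p0=p0,
                fold=fold,
                p_raw=p_raw,
                p_adj=p_adj,
                significant=bool(p_adj < alpha),
                mean_k2p=(family_k2p or {}).get(fam),
                level=level,
            )
        )
    results.sort(key=lambda r: (r.p_adj, -(r.fold if math.isfinite(r.fold) else 0), r.family))
    return results


# ---------------------------------------------------------------------------
# Kimura two-parameter divergence
# ---------------------------------------------------------------------------


@dataclass
class K2PResult:
    divergence: Optional[float]  # percent, None when undefined
    p: float  # transition fraction
    q: float  # transversion fraction
    n_sites: int

    @property
    def defined(self) -> bool:
        return self.divergence is not None


def k2p(gapped_query: str, gapped_consensus: str) -> K2PResult:
    """K2P divergence (in %) between a gapped copy and its consensus.

    Columns containing a gap or an ambiguous base in either sequence are
    excluded.  When the log arguments are non-positive (saturation) the
    divergence is undefined and the copy is excluded from family means.
    """
    if len(gapped_query) != len(gapped_consensus):
        raise ValueError("gapped sequences differ in length")
    n = transitions = transversions = 0
    for a, b in zip(gapped_query.upper(), gapped_consensus.upper()):
        if a not in VALID or b not in VALID:
            continue
        n += 1
        if a == b:
            continue
        if (a in PURINES) == (b in PURINES):
            transitions += 1
        else:
            transversions += 1
    if n == 0:
        return K2PResult(None, 0.0, 0.0, 0)
    p = transitions / n
    q = transversions / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        return K2PResult(None, p, q, n)
    k = -0.5 * math.log(w1 * math.sqrt(w2))
    return K2PResult(100.0 * k, p, q, n)


def family_mean_k2p(
    records: Sequence[AlignmentRecord],
    copy_family: Optional[dict[str, str]] = None,
) -> dict[str, float]:
    """Mean K2P divergence per family over all copies with defined values.

    ``copy_family`` maps copy_id -> family name; without it, the alignment
    record's consensus name is used as the family key.
    """
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for rec in records:
        key = (
            copy_family.get(rec.copy_id, rec.consensus_name)
            if copy_family
            else rec.consensus_name
        )
        res = k2p(rec.gapped_query, rec.gapped_consensus)
        if not res.defined:
            logger.warning("undefined K2P for copy %s; excluded", rec.copy_id)
            continue
        sums[key] = sums.get(key, 0.0) + res.divergence
        counts[key] = counts.get(key, 0) + 1
    return {fam: sums[fam] / counts[fam] for fam in sums}


def family_age_profile(
    results: Sequence[EnrichmentResult],
) -> pd.DataFrame:
    """Plot-ready (family, mean_k2p, -log10 p_adj) table."""
    rows = []
    for r in results:
        neglog = -math.log10(r.p_adj) if r.p_adj > 0 else math.inf
        rows.append(
            {
                "family": r.family,
                "mean_k2p": r.mean_k2p,
                "neg_log10_p_adj": neglog,
                "fold": r.fold,
                "significant": r.significant,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["family", "mean_k2p", "neg_log10_p_adj", "fold", "significant"],
    )


def write_enrichment(results: Sequence[EnrichmentResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("family\tk\tn\tp0\tfold\tp_raw\tp_adj\tsignificant\tmean_k2p\n")
        for r in results:
            k2p_s = f"{r.mean_k2p:.4f}" if r.mean_k2p is not None else "."
            fold_s = f"{r.fold:.4f}" if math.isfinite(r.fold) else str(r.fold)
            fh.write(
                f"{r.family}\t{r.k}\t{r.n}\t{r.p0:.8g}\t{fold_s}\t"
                f"{r.p_raw:.6g}\t{r.p_adj:.6g}\t{int(r.significant)}\t{k2p_s}\n"
            )
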