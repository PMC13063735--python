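"""Readers and writers for every external format the pipeline touches.

All coordinates are normalised to 0-based half-open on read and converted
back on write:

==============  =========================  ==========================
format          native convention          handled by
==============  =========================  ==========================
RepeatMasker    1-based inclusive          read/write_repeatmasker_*
GTF             1-based inclusive          read_gtf_tss / write_gtf
BED/narrowPeak  0-based half-open          read/write_bed, narrowpeak
bedGraph        0-based half-open          read/write_bedgraph
UCSC chain      0-based half-open          read_chain
==============  =========================  ==========================

Writers emit deterministic column and line order (sorted by chrom, start)
so identical inputs give byte-identical files.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import Phylo

from terep.types import (
    AlignmentRecord,
    GenomicInterval,
    PeakSummit,
    PWM,
    TECopy,
    split_class_family,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

_OUT_HEADER = """\
   SW  perc perc perc  query      position in query           matching       repeat              position in  repeat
score  div. del. ins.  sequence    begin     end    (left)    repeat         class/family         begin  end (left)     ID

"""


def _strip_parens(token: str) -> str:
    return token.strip("()")


def read_repeatmasker_out(path) -> list[TECopy]:
    """Parse a RepeatMasker .out annotation file into TECopy records.

    The three header lines are skipped; strand ``C`` maps to ``-``; the
    1-based inclusive query coordinates become 0-based half-open.  An
    unrecognised class/family string yields ``te_class == "Other"`` with a
    logged warning; a structurally malformed row raises a ValueError that
    names the line number.
    """
    copies: list[TECopy] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            # header lines do not start with an integer score
            if not tokens[0].lstrip("-").isdigit():
                continue
            try:
                copies.append(_parse_out_row(tokens))
            except (IndexError, ValueError) as exc:
                raise ValueError(
                    f"{path}: malformed RepeatMasker row at line {lineno}: {exc}"
                ) from exc
    return copies


def _parse_out_row(tokens: Sequence[str]) -> TECopy:
    sw_score = int(tokens[0])
    divergence = float(tokens[1])
    pct_del = float(tokens[2])
    pct_ins = float(tokens[3])
    chrom = tokens[4]
    start = int(tokens[5]) - 1
    end = int(tokens[6])
    query_left = int(_strip_parens(tokens[7]))
    strand_tok = _strip_parens(tokens[8])
    strand = "-" if strand_tok == "C" else strand_tok
    subfamily = tokens[9]
    class_family = tokens[10]
    te_class, family = split_class_family(class_family)
    if te_class == "Other" and class_family.split("/")[0] not in (
        "Other",
        "Unknown",
    ):
        logger.warning("unrecognised repeat class %r -> Other", class_family)
    if strand == "-":
        cons_left = int(_strip_parens(tokens[11]))
        cons_end = int(tokens[12])
        cons_start = int(tokens[13])
    else:
        cons_start = int(tokens[11])
        cons_end = int(tokens[12])
        cons_left = int(_strip_parens(tokens[13]))
    copy_id = tokens[14] if len(tokens) > 14 else f"{chrom}:{start}-{end}:{subfamily}"
    return TECopy(
        interval=GenomicInterval(chrom, start, end, strand),
        family=family,
        subfamily=subfamily,
        te_class=te_class,
        sw_score=sw_score,
        divergence=divergence,
        copy_id=copy_id,
        class_family=class_family,
        pct_del=pct_del,
        pct_ins=pct_ins,
        query_left=query_left,
        cons_start=cons_start,
        cons_end=cons_end,
        cons_left=cons_left,
    )


def write_repeatmasker_out(copies: Iterable[TECopy], path) -> None:
    """Write TECopy records in the RepeatMasker .out column layout."""
    rows = sorted(copies, key=lambda c: (c.interval.chrom, c.interval.start))
    with open(path, "w") as fh:
        fh.write(_OUT_HEADER)
        for c in rows:
            iv = c.interval
            strand = "C" if iv.strand == "-" else "+"
            if iv.strand == "-":
                repeat_pos = f"({c.cons_left}) {c.cons_end} {c.cons_start}"
            else:
                repeat_pos = f"{c.cons_start} {c.cons_end} ({c.cons_left})"
            fh.write(
                f"{c.sw_score:>6} {c.divergence:5.1f} {c.pct_del:5.1f} "
                f"{c.pct_ins:5.1f}  {iv.chrom:<10} {iv.start + 1:>9} "
                f"{iv.end:>9} ({c.query_left}) {strand} {c.subfamily:<16} "
                f"{c.class_family:<20} {repeat_pos} {c.copy_id}\n"
            )


# ---------------------------------------------------------------------------
# RepeatMasker .align
# ---------------------------------------------------------------------------

_ALIGN_CHUNK = 50


def write_repeatmasker_align(records: Iterable[AlignmentRecord], path) -> None:
    """Write alignment records as RepeatMasker-style .align blocks."""
    recs = sorted(records, key=lambda r: (r.genomic.chrom, r.genomic.start))
    with open(path, "w") as fh:
        for rec in recs:
            _write_align_block(fh, rec)


def _write_align_block(fh, rec: AlignmentRecord) -> None:
    g = rec.genomic
    qleft = 0
    score = 0
    if rec.orientation == "reverse":
        head = (
            f"{score} 0.00 0.00 0.00 {g.chrom} {g.start + 1} {g.end} "
            f"({qleft}) C {rec.consensus_name} (0) {rec.consensus_end} "
            f"{rec.consensus_start} {rec.copy_id}\n"
        )
    else:
        head = (
            f"{score} 0.00 0.00 0.00 {g.chrom} {g.start + 1} {g.end} "
            f"({qleft}) {rec.consensus_name} {rec.consensus_start} "
            f"{rec.consensus_end} (0) {rec.copy_id}\n"
        )
    fh.write(head)
    fh.write("\n")
    qpos = g.end if rec.orientation == "reverse" else g.start + 1
    cpos = rec.consensus_start
    for off in range(0, len(rec.gapped_query), _ALIGN_CHUNK):
        qchunk = rec.gapped_query[off : off + _ALIGN_CHUNK]
        cchunk = rec.gapped_consensus[off : off + _ALIGN_CHUNK]
        nq = sum(1 for b in qchunk if b != "-")
        nc = sum(1 for b in cchunk if b != "-")
        if rec.orientation == "reverse":
            qend = qpos - nq + 1 if nq else qpos
            fh.write(f"  {g.chrom:<15} {qpos:>8} {qchunk} {qend}\n")
            qpos -= nq
        else:
            qend = qpos + nq - 1 if nq else qpos
            fh.write(f"  {g.chrom:<15} {qpos:>8} {qchunk} {qend}\n")
            qpos += nq
        cend = cpos + nc - 1 if nc else cpos
        fh.write(f"  {rec.consensus_name:<15} {cpos:>8} {cchunk} {cend}\n")
        cpos += nc
    fh.write("\n")


_ALIGN_HEAD_RE = re.compile(
    r"^(\d+)\s+[\d.]+\s+[\d.]+\s+[\d.]+\s+(\S+)\s+(\d+)\s+(\d+)\s+\((\d+)\)\s+"
    r"(C\s+)?(\S+)\s+(\(?\d+\)?)\s+(\d+)\s+(\(?\d+\)?)\s*(\S*)\s*$"
)


def read_repeatmasker_align(path) -> list[AlignmentRecord]:
    """Parse a RepeatMasker .align file into AlignmentRecord objects.

    Blocks start with a header line (reverse hits carry a ``C`` flag and
    print the consensus span high->low); interleaved sequence lines are
    concatenated to reconstruct the full gapped query and consensus.
    Annotation trailer lines (Matrix, Kimura, Gap_init, Transitions) are
    ignored.  A reconstructed length mismatch raises a ValueError naming
    the copy_id.
    """
    records: list[AlignmentRecord] = []
    header = None
    qparts: list[str] = []
    cparts: list[str] = []

    def flush():
        nonlocal header, qparts, cparts
        if header is None:
            return
        records.append(_build_align_record(header, qparts, cparts))
        header, qparts, cparts = None, [], []

    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.split()[0] in ("Matrix", "Kimura", "Transitions", "Gap_init"):
                continue
            m = _ALIGN_HEAD_RE.match(stripped)
            if m:
                flush()
                header = m
                continue
            if header is None:
                continue
            tokens = stripped.split()
            # sequence line: name, start, gapped seq, end
            if len(tokens) < 4:
                continue
            name, seq = tokens[0], tokens[2]
            if name == header.group(2):
                qparts.append(seq)
            else:
                cparts.append(seq)
    flush()
    return records


def _build_align_record(m: re.Match, qparts, cparts) -> AlignmentRecord:
    chrom = m.group(2)
    qstart = int(m.group(3)) - 1
    qend = int(m.group(4))
    reverse = m.group(6) is not None
    name = m.group(7)
    consensus_name = name.split("#", 1)[0]
    a = int(_strip_parens(m.group(8)))
    b = int(m.group(9))
    c = int(_strip_parens(m.group(10)))
    if reverse:
        # printed as (left) end begin
        cons_start, cons_end = c, b
    else:
        cons_start, cons_end = a, b
    copy_id = m.group(11) or f"{chrom}:{qstart}-{qend}:{consensus_name}"
    gq = "".join(qparts).upper()
    gc = "".join(cparts).upper()
    if len(gq) != len(gc):
        raise ValueError(
            f"alignment length mismatch for {copy_id}: {len(gq)} != {len(gc)}"
        )
    strand = "-" if reverse else "+"
    return AlignmentRecord(
        copy_id=copy_id,
        genomic=GenomicInterval(chrom, qstart, qend, strand),
        consensus_name=consensus_name,
        consensus_start=cons_start,
        consensus_end=cons_end,
        orientation="reverse" if reverse else "forward",
        gapped_query=gq,
        gapped_consensus=gc,
    )


# ---------------------------------------------------------------------------
# BED / narrowPeak
# ---------------------------------------------------------------------------


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals (BED is already 0-based half-open)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            t = line.split()
            try:
                strand = t[5] if len(t) > 5 else "."
                out.append(GenomicInterval(t[0], int(t[1]), int(t[2]), strand))
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: bad BED line {lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path, names=None) -> None:
    ivs = list(intervals)
    order = sorted(range(len(ivs)), key=lambda i: (ivs[i].chrom, ivs[i].start))
    with open(path, "w") as fh:
        for i in order:
            iv = ivs[i]
            if names is not None:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{names[i]}\t0\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    return None


def read_narrowpeak(path, tf: str = "", cell: str = "") -> list[PeakSummit]:
    """Read a narrowPeak file; the summit is ``start + column-10 offset``.

    A negative summit offset (narrowPeak's "no summit" sentinel) raises:
    this pipeline is summit-based throughout.
    """
    summits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            t = line.split()
            start, end = int(t[1]), int(t[2])
            peak_id = t[3] if len(t) > 3 and t[3] != "." else f"peak{lineno}"
            score = float(t[6]) if len(t) > 6 else None
            offset = int(t[9])
            if offset < 0:
                raise ValueError(
                    f"{path}: negative summit offset at line {lineno}"
                )
            pos = start + offset
            if not (start <= pos < end):
                raise ValueError(
                    f"{path}: summit outside peak at line {lineno}"
                )
            summits.append(
                PeakSummit(
                    interval=GenomicInterval(t[0], pos, pos + 1),
                    tf=tf,
                    cell=cell,
                    peak_id=peak_id,
                    score=score,
                )
            )
    return summits


def write_narrowpeak(summits: Iterable[PeakSummit], path, flank: int = 50) -> None:
    """Write summits as narrowPeak rows with a symmetric ``flank`` peak body."""
    rows = sorted(summits, key=lambda s: (s.interval.chrom, s.pos, s.peak_id))
    with open(path, "w") as fh:
        for s in rows:
            start = max(0, s.pos - flank)
            end = s.pos + flank + 1
            score = s.score if s.score is not None else 0
            fh.write(
                f"{s.interval.chrom}\t{start}\t{end}\t{s.peak_id}\t"
                f"{int(score)}\t.\t{score:.4f}\t-1\t-1\t{s.pos - start}\n"
            )


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_GTF_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_gtf_tss(path) -> list[tuple[str, GenomicInterval, str]]:
    """Extract one TSS per transcript from GTF ``transcript`` features.

    GTF is 1-based inclusive; the TSS is the transcript start for ``+``
    genes and the transcript end for ``-`` genes.  Transcripts of one gene
    sharing an identical TSS are deduplicated.
    """
    seen: set[tuple[str, str, int]] = set()
    out: list[tuple[str, GenomicInterval, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            t = line.rstrip("\n").split("\t")
            if len(t) < 9 or t[2] != "transcript":
                continue
            attrs = dict(_GTF_ATTR_RE.findall(t[8]))
            if "gene_id" not in attrs:
                raise ValueError(f"{path}: missing gene_id at line {lineno}")
            gene_id = attrs["gene_id"]
            chrom, start1, end1, strand = t[0], int(t[3]), int(t[4]), t[6]
            tss = start1 - 1 if strand == "+" else end1 - 1
            key = (gene_id, chrom, tss)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                (gene_id, GenomicInterval(chrom, tss, tss + 1, strand), strand)
            )
    return out


def write_gtf(genes: Iterable[tuple[str, GenomicInterval]], path) -> None:
    """Write minimal gene+transcript GTF rows (one transcript per gene)."""
    rows = sorted(genes, key=lambda g: (g[1].chrom, g[1].start, g[0]))
    with open(path, "w") as fh:
        for gene_id, iv in rows:
            attrs = f'gene_id "{gene_id}"; transcript_id "{gene_id}.t1";'
            for feature in ("gene", "transcript"):
                fh.write(
                    f"{iv.chrom}\tterep\t{feature}\t{iv.start + 1}\t{iv.end}\t."
                    f"\t{iv.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# UCSC chain
# ---------------------------------------------------------------------------


@dataclass
class Chain:
    chain_id: str
    t_name: str
    t_start: int
    t_end: int
    q_name: str
    q_start: int
    q_end: int
    #: ungapped blocks as (t_start, q_start, size) triples
    blocks: list[tuple[int, int, int]] = field(default_factory=list)


class ChainIndex:
    """Pairwise-alignment chains indexed by target chromosome."""

    def __init__(self, chains: Sequence[Chain]):
        self.chains = list(chains)
        self._by_chrom: dict[str, list[Chain]] = {}
        for ch in self.chains:
            self._by_chrom.setdefault(ch.t_name, []).append(ch)

    def mapped_bases(self, chrom: str, start: int, end: int) -> int:
        """Largest number of bases of [start, end) that map through a
        *single* chain's ungapped blocks."""
        best = 0
        for ch in self._by_chrom.get(chrom, []):
            n = 0
            for ts, _qs, size in ch.blocks:
                n += max(0, min(end, ts + size) - max(start, ts))
            best = max(best, n)
        return best

    def map_position(self, chrom: str, pos: int) -> Optional[tuple[str, int]]:
        """Map a single target base to query coordinates, or None."""
        for ch in self._by_chrom.get(chrom, []):
            for ts, qs, size in ch.blocks:
                if ts <= pos < ts + size:
                    return ch.q_name, qs + (pos - ts)
        return None


def read_chain(path) -> ChainIndex:
    """Parse a UCSC chain file (``+`` strands only) and validate that block
    sizes plus gaps equal the spans declared in each chain header."""
    chains: list[Chain] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if not line.startswith("chain"):
            raise ValueError(f"{path}: expected chain header, got {line!r}")
        t = line.split()
        (_kw, _score, t_name, _t_size, t_strand, t_start, t_end,
         q_name, _q_size, q_strand, q_start, q_end) = t[:12]
        chain_id = t[12] if len(t) > 12 else str(len(chains) + 1)
        if t_strand != "+" or q_strand != "+":
            raise ValueError(f"chain {chain_id}: only + strands are supported")
        ch = Chain(
            chain_id, t_name, int(t_start), int(t_end),
            q_name, int(q_start), int(q_end),
        )
        tpos, qpos = ch.t_start, ch.q_start
        while i < len(lines):
            row = lines[i].strip()
            i += 1
            if not row:
                break
            parts = row.split()
            size = int(parts[0])
            ch.blocks.append((tpos, qpos, size))
            if len(parts) == 3:
                tpos += size + int(parts[1])
                qpos += size + int(parts[2])
            else:
                tpos += size
                qpos += size
                break
        if tpos != ch.t_end or qpos != ch.q_end:
            raise ValueError(
                f"chain {chain_id}: block arithmetic does not close "
                f"({tpos} vs {ch.t_end}, {qpos} vs {ch.q_end})"
            )
        chains.append(ch)
    return ChainIndex(chains)


def write_chain(index: ChainIndex, path) -> None:
    with open(path, "w") as fh:
        for ch in index.chains:
            t_size = max(ch.t_end, ch.blocks[-1][0] + ch.blocks[-1][2])
            q_size = max(ch.q_end, ch.blocks[-1][1] + ch.blocks[-1][2])
            fh.write(
                f"chain 1000 {ch.t_name} {t_size} + {ch.t_start} {ch.t_end} "
                f"{ch.q_name} {q_size} + {ch.q_start} {ch.q_end} {ch.chain_id}\n"
            )
            for j, (ts, qs, size) in enumerate(ch.blocks):
                if j + 1 < len(ch.blocks):
                    nts, nqs, _ = ch.blocks[j + 1]
                    fh.write(f"{size} {nts - ts - size} {nqs - qs - size}\n")
                else:
                    fh.write(f"{size}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Ortholog presence table
# ---------------------------------------------------------------------------

PRESENCE_VALUES = ("present", "absent", "unalignable")


def read_presence_table(path) -> dict[str, dict[str, str]]:
    """Read a site x species TSV of {present, absent, unalignable} flags."""
    with open(path) as fh:
        header = None
        table: dict[str, dict[str, str]] = {}
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            t = line.rstrip("\n").split("\t")
            if header is None:
                header = t[1:]
                continue
            flags = {}
            for sp, val in zip(header, t[1:]):
                if val not in PRESENCE_VALUES:
                    raise ValueError(f"{path}: bad presence value {val!r}")
                flags[sp] = val
            table[t[0]] = flags
    return table


def write_presence_table(table: dict[str, dict[str, str]], path) -> None:
    species = sorted({sp for flags in table.values() for sp in flags})
    with open(path, "w") as fh:
        fh.write("site_id\t" + "\t".join(species) + "\n")
        for site in sorted(table):
            fh.write(
                site + "\t" + "\t".join(table[site][sp] for sp in species) + "\n"
            )


# ---------------------------------------------------------------------------
# Dated newick tree
# ---------------------------------------------------------------------------


class DatedTree:
    """A rooted, dated species tree with named internal clades.

    Node ages (in My) are the maximum path length to a descendant leaf, so
    an ultrametric tree yields the usual divergence times and leaves have
    age 0.  Internal newick labels become clade names.
    """

    def __init__(self, bio_tree):
        self._tree = bio_tree
        self.root = bio_tree.root
        self._parent = {}
        for clade in bio_tree.find_clades(order="level"):
            for child in clade.clades:
                self._parent[child] = clade
        self._age = {}
        for clade in bio_tree.find_clades(order="postorder"):
            if not clade.clades:
                self._age[clade] = 0.0
            else:
                self._age[clade] = max(
                    self._age[ch] + (ch.branch_length or 0.0)
                    for ch in clade.clades
                )
        self._by_name = {
            c.name: c for c in bio_tree.find_clades() if c.name
        }

    @property
    def species(self) -> list[str]:
        return [leaf.name for leaf in self._tree.get_terminals()]

    def node(self, name: str):
        return self._by_name[name]

    def age(self, node) -> float:
        if isinstance(node, str):
            node = self._by_name[node]
        return self._age[node]

    def parent(self, node):
        if isinstance(node, str):
            node = self._by_name[node]
        return self._parent.get(node)

    def leaves_under(self, name: str) -> set[str]:
        return {leaf.name for leaf in self.node(name).get_terminals()}

    def path_to_root(self, leaf_name: str) -> list:
        """Nodes from the leaf to the root, inclusive."""
        node = self._by_name[leaf_name]
        path = [node]
        while node in self._parent:
            node = self._parent[node]
            path.append(node)
        return path

    def mrca(self, name_a: str, name_b: str):
        if name_a == name_b:
            return self._by_name[name_a]
        return self._tree.common_ancestor([name_a, name_b])


def read_newick_dated(path) -> DatedTree:
    """Read a newick tree whose branch lengths are in My and whose internal
    labels name clades."""
    tree = Phylo.read(str(path), "newick")
    # biopython stores numeric-looking internal labels as confidences;
    # promote any such values back to names so lookups work uniformly.
    for clade in tree.find_clades():
        if clade.name is None and clade.confidence is not None:
            clade.name = str(clade.confidence)
            clade.confidence = None
    return DatedTree(tree)


# ---------------------------------------------------------------------------
# bedGraph score track
# ---------------------------------------------------------------------------


class ScoreTrack:
    """A sparse per-base score track from non-overlapping bedGraph records.

    ``window_mean`` averages over covered bases only; positions with no
    record are treated as missing, not zero.
    """

    def __init__(self, records: Sequence[tuple[str, int, int, float]]):
        self.records = sorted(records)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in self.records:
            by_chrom.setdefault(chrom, []).append((start, end, value))
        for chrom, rows in by_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows])
            ends = np.array([r[1] for r in rows])
            vals = np.array([r[2] for r in rows])
            self._by_chrom[chrom] = (starts, ends, vals)

    def window_mean(self, chrom: str, start: int, end: int) -> float:
        """Mean score over [start, end); NaN when nothing is covered."""
        if chrom not in self._by_chrom:
            return float("nan")
        starts, ends, vals = self._by_chrom[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if hi <= lo:
            return float("nan")
        ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        ov = np.clip(ov, 0, None)
        covered = ov.sum()
        if covered == 0:
            return float("nan")
        return float((vals[lo:hi] * ov).sum() / covered)


def read_bedgraph(path) -> ScoreTrack:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            t = line.split()
            try:
                records.append((t[0], int(t[1]), int(t[2]), float(t[3])))
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: bad bedGraph line {lineno}") from exc
    return ScoreTrack(records)


def write_bedgraph(track: ScoreTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in sorted(track.records):
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------


def read_meme_pwm(path) -> list[PWM]:
    """Read PWMs from MEME minimal format; probability rows must sum to 1."""
    motifs: list[PWM] = []
    background = np.full(4, 0.25)
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            t = lines[i].split()
            freqs = {t[j]: float(t[j + 1]) for j in range(0, len(t), 2)}
            background = np.array([freqs[b] for b in "ACGT"])
        elif line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability"
            ):
                i += 1
            header = lines[i].strip()
            w = int(re.search(r"w=\s*(\d+)", header).group(1))
            rows = []
            for j in range(w):
                i += 1
                rows.append([float(x) for x in lines[i].split()])
            matrix = np.array(rows)
            if not np.allclose(matrix.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError(
                    f"{path}: motif {name} has rows not summing to 1"
                )
            motifs.append(PWM(name=name, matrix=matrix, background=background))
        i += 1
    return motifs


def write_meme_pwm(pwms: Sequence[PWM], path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{b} {f:.6f}" for b, f in zip("ACGT", bg)) + "\n\n"
        )
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Expression and generic TSV tables
# ---------------------------------------------------------------------------


def read_expression_tsv(path) -> dict[str, tuple[float, float]]:
    """Read a gene -> (rpkm_esc, rpkm_npc) table."""
    table = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            t = line.rstrip("\n").split("\t")
            if t[0] == "gene_id":
                continue
            table[t[0]] = (float(t[1]), float(t[2]))
    return table


def write_expression_tsv(table: dict[str, tuple[float, float]], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\trpkm_esc\trpkm_npc\n")
        for gene in sorted(table):
            esc, npc = table[gene]
            fh.write(f"{gene}\t{esc:.6g}\t{npc:.6g}\n")


# ---------------------------------------------------------------------------
# FASTA (thin wrappers over Biopython)
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for off in range(0, len(s), width):
                fh.write(s[off : off + width] + "\n")
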