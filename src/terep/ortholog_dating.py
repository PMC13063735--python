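"""Phylogenetic dating of TE insertions from cross-species ortholog presence.

For each binding site, a 10-bp window around the summit is mapped to each
other species through pairwise alignment chains (or a precomputed presence
table).  The most recent common ancestor of human and the most distantly
related species retaining the ortholog is taken as the lineage in which
the TE was inserted.  Calls older than the host subfamily's known clade
distribution are clamped to that clade and flagged as spurious mappings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from terep.io_formats import ChainIndex, DatedTree

HUMAN = "human"


@dataclass
class PresenceRecord:
    site_id: str
    flags: dict[str, str]  # species -> present | absent | unalignable

    def present_species(self) -> list[str]:
        return sorted(sp for sp, f in self.flags.items() if f == "present")


@dataclass
class AcquisitionCall:
    site_id: str
    clade: str  # name of the origin node on the human root path
    clade_age: float
    capped_by_te_age: bool = False


def liftover_site(
    site: tuple[str, int, int],
    chain_index: ChainIndex,
    min_match: float = 0.95,
) -> str:
    """Classify a (chrom, start, end) window as present/absent in the
    chain's query species.

    Present iff at least ``min_match`` of the window's bases map through a
    single chain (mirroring liftOver's -minMatch default of 0.95).
    """
    chrom, start, end = site
    if end <= start:
        raise ValueError("empty site window")
    mapped = chain_index.mapped_bases(chrom, start, end)
    return "present" if mapped / (end - start) >= min_match else "absent"


def summit_window(chrom: str, summit_pos: int, width: int = 10) -> tuple[str, int, int]:
    """The ``width``-bp window centered on a summit base."""
    half = width // 2
    start = max(0, summit_pos - half)
    return (chrom, start, start + width)


def presence_from_chains(
    sites: Sequence[tuple[str, str, int]],
    chains_by_species: dict[str, ChainIndex],
    min_match: float = 0.95,
    width: int = 10,
) -> dict[str, dict[str, str]]:
    """Build a presence table from per-species chain indexes.

    ``sites`` are (site_id, chrom, summit_pos) triples; human is always
    marked present.
    """
    table: dict[str, dict[str, str]] = {}
    for site_id, chrom, pos in sites:
        flags = {HUMAN: "present"}
        window = summit_window(chrom, pos, width)
        for sp, index in chains_by_species.items():
            flags[sp] = liftover_site(window, index, min_match)
        table[site_id] = flags
    return table


def infer_acquisition(
    record: PresenceRecord,
    tree: DatedTree,
    te_clade_limit: Optional[str] = None,
) -> AcquisitionCall:
    """Date a site's acquisition as MRCA(human, most distant present species).

    "Most distant" is measured by MRCA node age.  With presence only in
    human the call is the human terminal branch.  ``te_clade_limit`` names
    the oldest clade the host TE subfamily is known to occur in; an older
    call is clamped there and flagged (a spurious cross-species mapping).
    Unalignable and absent flags are treated identically (no ortholog
    evidence).
    """
    if record.flags.get(HUMAN) != "present":
        raise ValueError(f"site {record.site_id}: human must be present")
    best_node = None
    best_age = -1.0
    for sp in record.present_species():
        if sp == HUMAN:
            continue
        node = tree.mrca(HUMAN, sp)
        age = tree.age(node)
        if age > best_age:
            best_age, best_node = age, node
    if best_node is None:
        return AcquisitionCall(record.site_id, HUMAN, 0.0, False)
    clade_name = best_node.name or HUMAN
    capped = False
    if te_clade_limit is not None:
        limit_age = tree.age(te_clade_limit)
        if best_age > limit_age:
            clade_name = te_clade_limit
            best_age = limit_age
            capped = True
    return AcquisitionCall(record.site_id, clade_name, best_age, capped)


def acquisition_histogram(
    calls: Sequence[AcquisitionCall],
    tree: DatedTree,
    site_class: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Per-clade counts and fractions of acquisition calls along the human
    root path, optionally stratified by TE class (with "non-TE" as a class).
    """
    if not calls:
        return pd.DataFrame(
            columns=["clade", "clade_age", "te_class", "count", "fraction"]
        )
    path_names = [
        node.name or HUMAN for node in tree.path_to_root(HUMAN)
    ]
    rows = []
    total = len(calls)
    groups: dict[tuple[str, str], int] = {}
    for call in calls:
        cls = (site_class or {}).get(call.site_id, "all")
        groups[(call.clade, cls)] = groups.get((call.clade, cls), 0) + 1
    for clade in path_names:
        for (c, cls), n in sorted(groups.items()):
            if c != clade:
                continue
            rows.append(
                {
                    "clade": clade,
                    "clade_age": tree.age(clade) if clade != HUMAN else tree.age(HUMAN),
                    "te_class": cls,
                    "count": n,
                    "fraction": n / total,
                }
            )
    return pd.DataFrame(
        rows, columns=["clade", "clade_age", "te_class", "count", "fraction"]
    )


def acquisition_rate(
    histogram: pd.DataFrame, tree: DatedTree
) -> pd.DataFrame:
    """Branch-normalised acquisition rate: clade count / branch time span.

    The span of an origin node is parent_age - node_age on the human root
    path; the root (no parent) and zero-length branches yield an undefined
    rate and are flagged.
    """
    rows = []
    if histogram.empty:
        return pd.DataFrame(
            columns=["clade", "count", "span_my", "rate_per_my", "defined"]
        )
    for clade, group in histogram.groupby("clade", sort=False):
        count = int(group["count"].sum())
        node = tree.node(clade) if clade != HUMAN else tree.node(HUMAN)
        parent = tree.parent(node)
        if parent is None:
            span = float("nan")
        else:
            span = tree.age(parent) - tree.age(node)
        defined = bool(span == span and span > 0)  # not NaN and positive
        rate = count / span if defined else float("nan")
        rows.append(
            {
                "clade": clade,
                "count": count,
                "span_my": span,
                "rate_per_my": rate,
                "defined": defined,
            }
        )
    return pd.DataFrame(
        rows, columns=["clade", "count", "span_my", "rate_per_my", "defined"]
    )


def write_calls(calls: Sequence[AcquisitionCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("site_id\tclade\tclade_age\tcapped_by_te_age\n")
        for c in sorted(calls, key=lambda c: c.site_id):
            fh.write(
                f"{c.site_id}\t{c.clade}\t{c.clade_age:.6g}\t"
                f"{int(c.capped_by_te_age)}\n"
            )
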