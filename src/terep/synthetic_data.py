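"""Synthetic TE landscapes with full ground truth.

The generator emulates the statistical structure of the real inputs: TE
copies are drawn by mutating a family consensus under a Kimura
two-parameter substitution process at a controlled expected divergence
(transition:transversion rate ratio kappa, default 2), optionally with
indels; a binding motif (a PWM consensus string) is written into a
configured fraction of copies at a fixed consensus position before
mutation; ChIP-seq summits sit at the genomic centre of each planted
motif plus uniform background; input reads are uniform over the genome.
Chromatin-state segmentations, nearest-gene expression effects,
clade-structured ortholog presence (with per-species chains), and a
conservation track complete the downstream layers.

Identical seed + config produce byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from terep import io_formats as iof
from terep.gene_expression import TSSIndex
from terep.types import (
    AlignmentRecord,
    BASES,
    GenomicInterval,
    PeakSummit,
    PWM,
    TECopy,
    split_class_family,
)

# base-code maps for the K2P substitution process (A,C,G,T = 0..3)
_TS_PARTNER = np.array([2, 3, 0, 1])  # A<->G, C<->T
_TV_PARTNER_1 = np.array([1, 0, 1, 0])
_TV_PARTNER_2 = np.array([3, 2, 3, 2])

CELLS = ("ESC", "NPC")


def builtin_path(name: str) -> Path:
    return Path(resources.files("terep") / "data" / name)


def builtin_pwm(name: str) -> PWM:
    for pwm in iof.read_meme_pwm(builtin_path("motifs.meme")):
        if pwm.name == name:
            return pwm
    raise KeyError(f"no built-in PWM named {name}")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class MotifSpec:
    pwm: str = "SOX2_SYNTH"
    position: int = 1  # 1-based consensus position of the motif start
    fraction: float = 0.0  # fraction of copies carrying the motif
    cells: tuple[str, ...] = ("NPC",)
    #: of the carriers, fraction bound in *both* cells when two are listed
    shared_fraction: float = 1.0

    def load_pwm(self) -> PWM:
        if Path(self.pwm).suffix == ".meme":
            return iof.read_meme_pwm(self.pwm)[0]
        return builtin_pwm(self.pwm)


@dataclass
class FamilySpec:
    subfamily: str
    family: str
    class_family: str  # RepeatMasker-style, e.g. "LTR/ERV1"
    n_copies: int
    consensus_length: int
    divergence: float  # expected substitutions per site, 0 <= d <= 0.5
    kappa: float = 2.0
    indel_rate: float = 0.0
    motif: Optional[MotifSpec] = None
    clade: str = "Eutheria"  # true acquisition clade of the family's copies

    def __post_init__(self) -> None:
        if not 0 <= self.divergence <= 0.5:
            raise ValueError("divergence must be in [0, 0.5]")
        if self.motif and not 0 <= self.motif.fraction <= 1:
            raise ValueError("motif fraction must be in [0, 1]")
        if self.n_copies < 0 or self.consensus_length <= 0:
            raise ValueError("counts must be non-negative")


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_length: int = 200_000
    chrom: str = "chrS"
    families: list[FamilySpec] = field(default_factory=list)
    tf: str = "Sox2"
    n_background_summits: dict = field(
        default_factory=lambda: {"ESC": 50, "NPC": 50}
    )
    background_mode: str = "non_te"  # or "uniform"
    n_input_reads: int = 20_000
    segment_size: int = 200
    enhancer_prob_bound: dict = field(
        default_factory=lambda: {"ESC": 0.9, "NPC": 0.9}
    )
    #: probability that an ESC-only bound TE's NPC tile is quiescent
    transition_quiescent_prob: float = 0.6
    n_genes: int = 60
    effect_fold: float = 8.0
    #: probability that a nearest gene of an NPC-bound TE receives the effect
    effect_prob: float = 1.0
    expression_noise_sd: float = 0.0
    ortholog_loss: float = 0.0
    conservation_bin: int = 25
    conservation_delta: float = 0.1
    conservation_noise_sd: float = 0.02
    tree: str = "default"

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        families = []
        for f in raw.pop("families", []):
            motif = f.pop("motif", None)
            if motif is not None:
                motif["cells"] = tuple(motif.get("cells", ("NPC",)))
                motif = MotifSpec(**motif)
            families.append(FamilySpec(motif=motif, **f))
        return cls(families=families, **raw)

    def load_tree(self) -> iof.DatedTree:
        path = (
            builtin_path("vertebrates.nwk")
            if self.tree == "default"
            else self.tree
        )
        return iof.read_newick_dated(path)


# ---------------------------------------------------------------------------
# Ground truth containers
# ---------------------------------------------------------------------------


@dataclass
class CopyTruth:
    copy_id: str
    subfamily: str
    family: str
    start: int
    end: int
    strand: str
    carries_motif: bool
    motif_consensus_pos: int  # 1-based start, -1 when no motif
    motif_genomic_center: int  # -1 when no motif
    bound_cells: tuple[str, ...]
    clade: str


@dataclass
class GroundTruth:
    copies: list[CopyTruth]
    family_divergence: dict[str, float]
    #: summit peak_id -> (cell, kind, copy_id-or-None)
    summits: dict[str, tuple[str, str, Optional[str]]] = field(
        default_factory=dict
    )
    #: gene_id -> true multiplicative NPC effect
    gene_effect: dict[str, float] = field(default_factory=dict)
    #: site_id -> true acquisition clade
    site_clade: dict[str, str] = field(default_factory=dict)

    def carriers(self, subfamily: Optional[str] = None) -> list[CopyTruth]:
        return [
            c
            for c in self.copies
            if c.carries_motif
            and (subfamily is None or c.subfamily == subfamily)
        ]


@dataclass
class Landscape:
    config: SimulationConfig
    genome: str
    copies: list[TECopy]
    alignments: list[AlignmentRecord]
    consensus: dict[str, str]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# TE landscape
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length)


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def _k2p_probs(d: float, kappa: float) -> tuple[float, float]:
    """(P_transition, P_each_transversion) after expected distance d."""
    alpha = kappa / (kappa + 2.0)
    beta = 1.0 / (kappa + 2.0)
    p_ts = 0.25 + 0.25 * math.exp(-4 * beta * d) - 0.5 * math.exp(
        -2 * (alpha + beta) * d
    )
    p_tv = 0.25 - 0.25 * math.exp(-4 * beta * d)
    return p_ts, p_tv


def _mutate(
    rng: np.random.Generator, codes: np.ndarray, d: float, kappa: float
) -> np.ndarray:
    """Apply the K2P substitution process at expected distance d."""
    if d == 0:
        return codes.copy()
    p_ts, p_tv = _k2p_probs(d, kappa)
    u = rng.random(len(codes))
    out = codes.copy()
    ts = u < p_ts
    tv1 = (u >= p_ts) & (u < p_ts + p_tv)
    tv2 = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
    out[ts] = _TS_PARTNER[codes[ts]]
    out[tv1] = _TV_PARTNER_1[codes[tv1]]
    out[tv2] = _TV_PARTNER_2[codes[tv2]]
    return out


_RC = np.array([3, 2, 1, 0])


def _apply_indels(
    rng: np.random.Generator, codes: np.ndarray, rate: float
) -> tuple[np.ndarray, str, str]:
    """Introduce short indels; returns (query codes, gapped query pattern,
    gapped consensus pattern) where patterns mark '-' columns."""
    q_parts: list[str] = []
    c_parts: list[str] = []
    q_codes: list[int] = []
    for code in codes:
        if rng.random() < rate / 2:  # deletion in the copy
            q_parts.append("-")
            c_parts.append("x")
            continue
        q_parts.append("x")
        c_parts.append("x")
        q_codes.append(int(code))
        if rng.random() < rate / 2:  # insertion in the copy
            n_ins = int(rng.integers(1, 4))
            for _ in range(n_ins):
                q_parts.append("x")
                c_parts.append("-")
                q_codes.append(int(rng.integers(0, 4)))
    return np.array(q_codes, dtype=int), "".join(q_parts), "".join(c_parts)


def simulate_te_landscape(config: SimulationConfig) -> Landscape:
    """Generate the genome, TE annotation, alignments and ground truth."""
    rng = np.random.default_rng(config.seed)
    consensus: dict[str, str] = {}
    consensus_codes: dict[str, np.ndarray] = {}

    # family consensus sequences, with the motif written in
    for spec in config.families:
        codes = _random_seq(rng, spec.consensus_length)
        if spec.motif is not None:
            pwm = spec.motif.load_pwm()
            p0 = spec.motif.position - 1
            if p0 + pwm.width > spec.consensus_length:
                raise ValueError(
                    f"{spec.subfamily}: motif does not fit the consensus"
                )
            motif_codes = pwm.matrix.argmax(axis=1)
            codes[p0 : p0 + pwm.width] = motif_codes
        consensus_codes[spec.subfamily] = codes
        consensus[spec.subfamily] = _codes_to_str(codes)

    # generate every copy (sequence + gapped alignment) before placement
    pending = []  # (spec, carrier, bound_cells, q_codes, gq_pat, gc_pat)
    for spec in config.families:
        n = spec.n_copies
        carriers = np.zeros(n, dtype=bool)
        bound_cells: list[tuple[str, ...]] = [() for _ in range(n)]
        if spec.motif is not None and spec.motif.fraction > 0:
            n_carry = int(round(spec.motif.fraction * n))
            chosen = rng.choice(n, size=n_carry, replace=False)
            carriers[chosen] = True
            cells = tuple(spec.motif.cells)
            carrier_idx = sorted(int(i) for i in chosen)
            if len(cells) == 2:
                n_shared = int(round(spec.motif.shared_fraction * n_carry))
                for j, i in enumerate(carrier_idx):
                    if j < n_shared:
                        bound_cells[i] = cells
                    elif (j - n_shared) % 2 == 0:
                        bound_cells[i] = (cells[0],)
                    else:
                        bound_cells[i] = (cells[1],)
            else:
                for i in carrier_idx:
                    bound_cells[i] = cells
        base = consensus_codes[spec.subfamily]
        pwm = spec.motif.load_pwm() if spec.motif is not None else None
        for i in range(n):
            codes = base.copy()
            if pwm is not None and not carriers[i]:
                # non-carriers lose the motif: the window is re-randomised
                p0 = spec.motif.position - 1
                codes[p0 : p0 + pwm.width] = _random_seq(rng, pwm.width)
            mutated = _mutate(rng, codes, spec.divergence, spec.kappa)
            if spec.indel_rate > 0:
                q_codes, gq_pat, gc_pat = _apply_indels(
                    rng, mutated, spec.indel_rate
                )
            else:
                q_codes = mutated
                gq_pat = gc_pat = "x" * len(mutated)
            pending.append(
                (spec, bool(carriers[i]), bound_cells[i], q_codes, gq_pat, gc_pat)
            )

    # uniform non-overlapping placement
    n_total = len(pending)
    order = rng.permutation(n_total)
    lengths = [len(pending[i][3]) for i in order]
    free = config.genome_length - sum(lengths)
    if free < n_total + 1:
        raise ValueError(
            "TE copies cannot be placed without overlap; "
            "increase genome_length"
        )
    gaps = rng.multinomial(free, np.full(n_total + 1, 1.0 / (n_total + 1)))
    genome_codes = _random_seq(rng, config.genome_length)
    strands = rng.random(n_total) < 0.5

    placements = []  # (start, order_index)
    pos = 0
    for j, i in enumerate(order):
        pos += int(gaps[j])
        placements.append((pos, int(i)))
        pos += lengths[j]

    copies: list[TECopy] = []
    alignments: list[AlignmentRecord] = []
    truth_copies: list[CopyTruth] = []
    placements.sort()
    for rank, (start, i) in enumerate(placements, start=1):
        spec, carrier, cells, q_codes, gq_pat, gc_pat = pending[i]
        strand = "-" if strands[i] else "+"
        end = start + len(q_codes)
        if strand == "-":
            genome_codes[start:end] = _RC[q_codes[::-1]]
        else:
            genome_codes[start:end] = q_codes
        copy_id = str(rank)
        te_class, family = split_class_family(spec.class_family)
        # gapped strings from patterns
        base = consensus_codes[spec.subfamily]
        gq_chars, gc_chars = [], []
        qi = ci = 0
        for qc, cc in zip(gq_pat, gc_pat):
            if qc == "-":
                gq_chars.append("-")
            else:
                gq_chars.append(BASES[q_codes[qi]])
                qi += 1
            if cc == "-":
                gc_chars.append("-")
            else:
                gc_chars.append(BASES[base[ci]])
                ci += 1
        gq = "".join(gq_chars)
        gc = "".join(gc_chars)
        mismatches = sum(
            1 for a, b in zip(gq, gc) if a != "-" and b != "-" and a != b
        )
        aligned_cols = sum(
            1 for a, b in zip(gq, gc) if a != "-" and b != "-"
        )
        obs_div = round(100.0 * mismatches / max(1, aligned_cols), 1)
        matches = aligned_cols - mismatches
        rec = AlignmentRecord(
            copy_id=copy_id,
            genomic=GenomicInterval(config.chrom, start, end, strand),
            consensus_name=spec.subfamily,
            consensus_start=1,
            consensus_end=len(base),
            orientation="reverse" if strand == "-" else "forward",
            gapped_query=gq,
            gapped_consensus=gc,
        )
        alignments.append(rec)
        copies.append(
            TECopy(
                interval=GenomicInterval(config.chrom, start, end, strand),
                family=family,
                subfamily=spec.subfamily,
                te_class=te_class,
                sw_score=2 * matches,
                divergence=obs_div,
                copy_id=copy_id,
                class_family=spec.class_family,
                cons_start=1,
                cons_end=len(base),
            )
        )
        motif_center = -1
        motif_pos = -1
        if carrier and spec.motif is not None:
            pwm = spec.motif.load_pwm()
            motif_pos = spec.motif.position
            c_center = spec.motif.position + pwm.width // 2
            from terep.consensus_motif import consensus_to_genomic

            g = consensus_to_genomic(c_center, rec)
            if g is None:  # centre deleted; walk outward
                for delta in range(1, pwm.width):
                    for cand in (c_center - delta, c_center + delta):
                        if 1 <= cand <= len(base):
                            g = consensus_to_genomic(cand, rec)
                            if g is not None:
                                break
                    if g is not None:
                        break
            motif_center = int(g) if g is not None else -1
        truth_copies.append(
            CopyTruth(
                copy_id=copy_id,
                subfamily=spec.subfamily,
                family=family,
                start=start,
                end=end,
                strand=strand,
                carries_motif=carrier,
                motif_consensus_pos=motif_pos,
                motif_genomic_center=motif_center,
                bound_cells=cells,
                clade=spec.clade,
            )
        )

    truth = GroundTruth(
        copies=truth_copies,
        family_divergence={
            spec.subfamily: spec.divergence for spec in config.families
        },
    )
    return Landscape(
        config=config,
        genome=_codes_to_str(genome_codes),
        copies=copies,
        alignments=alignments,
        consensus=consensus,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# ChIP-seq layer
# ---------------------------------------------------------------------------


def _non_te_intervals(landscape: Landscape) -> list[tuple[int, int]]:
    out = []
    pos = 0
    for c in sorted(landscape.copies, key=lambda c: c.interval.start):
        if c.interval.start > pos:
            out.append((pos, c.interval.start))
        pos = c.interval.end
    if pos < len(landscape.genome):
        out.append((pos, len(landscape.genome)))
    return out


def simulate_chipseq(
    landscape: Landscape,
) -> tuple[dict[str, list[PeakSummit]], list[GenomicInterval]]:
    """Summits per cell type (planted + background) and input-read
    positions uniform over the genome."""
    config = landscape.config
    rng = np.random.default_rng(config.seed + 1)
    chrom = config.chrom
    summits: dict[str, list[PeakSummit]] = {cell: [] for cell in CELLS}

    planted = []
    for ct in landscape.truth.copies:
        if ct.carries_motif and ct.motif_genomic_center >= 0:
            for cell in ct.bound_cells:
                planted.append((cell, ct.motif_genomic_center, ct.copy_id))
    planted.sort(key=lambda t: (t[0], t[1]))
    per_cell_counter = {cell: 0 for cell in CELLS}
    for cell, pos, copy_id in planted:
        per_cell_counter[cell] += 1
        pid = f"{cell}_te{per_cell_counter[cell]:04d}"
        summits[cell].append(
            PeakSummit(
                interval=GenomicInterval(chrom, pos, pos + 1),
                tf=config.tf,
                cell=cell,
                peak_id=pid,
                score=100.0,
            )
        )
        landscape.truth.summits[pid] = (cell, "planted", copy_id)

    non_te = _non_te_intervals(landscape)
    lengths = np.array([e - s for s, e in non_te])
    cum = np.concatenate([[0], np.cumsum(lengths)])
    total_non_te = int(cum[-1])
    for cell in CELLS:
        n_bg = int(config.n_background_summits.get(cell, 0))
        if config.background_mode == "uniform":
            positions = sorted(
                int(p)
                for p in rng.integers(0, config.genome_length, size=n_bg)
            )
        else:
            offsets = np.sort(rng.integers(0, total_non_te, size=n_bg))
            idx = np.searchsorted(cum, offsets, side="right") - 1
            positions = [
                int(non_te[i][0] + (off - cum[i]))
                for i, off in zip(idx, offsets)
            ]
        for j, pos in enumerate(positions, start=1):
            pid = f"{cell}_bg{j:04d}"
            summits[cell].append(
                PeakSummit(
                    interval=GenomicInterval(chrom, pos, pos + 1),
                    tf=config.tf,
                    cell=cell,
                    peak_id=pid,
                    score=10.0,
                )
            )
            landscape.truth.summits[pid] = (cell, "background", None)

    input_positions = np.sort(
        rng.integers(0, config.genome_length, size=config.n_input_reads)
    )
    input_reads = [
        GenomicInterval(chrom, int(p), int(p) + 1) for p in input_positions
    ]
    return summits, input_reads


# ---------------------------------------------------------------------------
# Function layers: chromatin states, genes/expression, orthologs,
# conservation
# ---------------------------------------------------------------------------

_STATE_WEIGHTS = {
    "Quies": 0.50,
    "Low": 0.20,
    "TxWk": 0.08,
    "Tx": 0.04,
    "Het": 0.055,
    "ReprPC": 0.02,
    "ReprPCWk": 0.02,
    "TssA": 0.015,
    "TssFlnk": 0.015,
    "EnhA1": 0.01,
    "EnhA2": 0.01,
    "EnhWk": 0.015,
    "EnhG": 0.005,
    "EnhBiv": 0.005,
    "TssBiv": 0.005,
    "ZNF_Rpts": 0.005,
}


@dataclass
class FunctionLayers:
    segmentations: dict[str, list[tuple[GenomicInterval, str]]]
    genes: list[tuple[str, GenomicInterval]]  # (gene_id, 1-bp TSS interval)
    expression: dict[str, tuple[float, float]]
    presence: dict[str, dict[str, str]]
    te_clade_limits: dict[str, str]  # subfamily -> clade
    chains: dict[str, iof.ChainIndex]  # species -> chain index
    conservation: iof.ScoreTrack
    tree: iof.DatedTree


def simulate_function_layers(
    landscape: Landscape,
    summits: dict[str, list[PeakSummit]],
) -> FunctionLayers:
    config = landscape.config
    rng = np.random.default_rng(config.seed + 2)
    chrom = config.chrom
    G = config.genome_length
    truth = landscape.truth

    # --- chromatin states -------------------------------------------------
    states = sorted(_STATE_WEIGHTS)
    weights = np.array([_STATE_WEIGHTS[s] for s in states])
    weights = weights / weights.sum()
    n_tiles = (G + config.segment_size - 1) // config.segment_size
    tile_states = {
        cell: rng.choice(len(states), size=n_tiles, p=weights)
        for cell in CELLS
    }
    state_idx = {s: i for i, s in enumerate(states)}

    copy_by_id = {c.copy_id: c for c in truth.copies}
    te_summits = {
        cell: [
            s
            for s in summits[cell]
            if truth.summits[s.peak_id][1] == "planted"
        ]
        for cell in CELLS
    }
    bound_cells_of = {c.copy_id: set(c.bound_cells) for c in truth.copies}

    for cell in CELLS:
        p_enh = float(config.enhancer_prob_bound.get(cell, 0.9))
        for s in te_summits[cell]:
            tile = s.pos // config.segment_size
            if rng.random() < p_enh:
                tile_states[cell][tile] = state_idx["EnhA1"]
    # ESC-only bound TEs: their NPC tile transitions to quiescence with the
    # configured probability (else stays an enhancer)
    for s in te_summits["ESC"]:
        copy_id = truth.summits[s.peak_id][2]
        if "NPC" in bound_cells_of.get(copy_id, set()):
            continue
        tile = s.pos // config.segment_size
        if rng.random() < config.transition_quiescent_prob:
            tile_states["NPC"][tile] = state_idx["Quies"]
        else:
            tile_states["NPC"][tile] = state_idx["EnhA1"]

    segmentations = {}
    for cell in CELLS:
        segs = []
        for t in range(n_tiles):
            start = t * config.segment_size
            end = min(G, start + config.segment_size)
            segs.append(
                (GenomicInterval(chrom, start, end), states[tile_states[cell][t]])
            )
        segmentations[cell] = segs

    # --- genes and expression --------------------------------------------
    tss_positions = np.sort(rng.integers(0, G, size=config.n_genes))
    gene_strands = np.where(rng.random(config.n_genes) < 0.5, "+", "-")
    genes = []
    for i, (pos, strand) in enumerate(zip(tss_positions, gene_strands), 1):
        gid = f"g{i:04d}"
        genes.append((gid, GenomicInterval(chrom, int(pos), int(pos) + 1, strand)))
    tss_index = TSSIndex([(gid, iv, iv.strand) for gid, iv in genes])

    npc_bound_nearest = set()
    for s in te_summits["NPC"]:
        hit = tss_index.nearest(chrom, s.pos)
        if hit is not None:
            npc_bound_nearest.add(hit[0])
    base_rpkm = rng.lognormal(mean=1.0, sigma=1.0, size=config.n_genes)
    expression = {}
    for (gid, _iv), base in zip(genes, base_rpkm):
        esc = float(base)
        noise = (
            rng.lognormal(0.0, config.expression_noise_sd)
            if config.expression_noise_sd > 0
            else 1.0
        )
        if gid in npc_bound_nearest and (
            config.effect_prob >= 1.0 or rng.random() < config.effect_prob
        ):
            npc = esc * config.effect_fold * noise
            truth.gene_effect[gid] = config.effect_fold
        else:
            npc = esc * noise
            truth.gene_effect[gid] = 1.0
        expression[gid] = (esc, float(npc))

    # --- ortholog presence and chains -------------------------------------
    tree = config.load_tree()
    clade_leaves = {
        spec.clade: tree.leaves_under(spec.clade) for spec in config.families
    }
    presence: dict[str, dict[str, str]] = {}
    species = tree.species
    bound_sites = []  # (site_id, pos) over TE-bound summits in all cells
    for cell in CELLS:
        for s in te_summits[cell]:
            copy_id = truth.summits[s.peak_id][2]
            clade = copy_by_id[copy_id].clade
            flags = {}
            for sp in species:
                if sp == "human":
                    flags[sp] = "present"
                elif sp in clade_leaves[clade]:
                    flags[sp] = (
                        "absent"
                        if config.ortholog_loss > 0
                        and rng.random() < config.ortholog_loss
                        else "present"
                    )
                else:
                    flags[sp] = "absent"
            presence[s.peak_id] = flags
            truth.site_clade[s.peak_id] = clade
            bound_sites.append((s.peak_id, s.pos))

    chains = {}
    for sp in sorted(species):
        if sp == "human":
            continue
        windows = sorted(
            {
                (max(0, pos - 5), max(0, pos - 5) + 10)
                for site_id, pos in bound_sites
                if presence[site_id][sp] == "present"
            }
        )
        merged: list[list[int]] = []
        for s0, e0 in windows:
            if merged and s0 <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e0)
            else:
                merged.append([s0, e0])
        if not merged:
            chains[sp] = iof.ChainIndex([])
            continue
        blocks = []
        qpos = 0
        for s0, e0 in merged:
            blocks.append((s0, qpos, e0 - s0))
            qpos += (e0 - s0) + 20  # constant query gap between blocks
        ch = iof.Chain(
            chain_id="1",
            t_name=chrom,
            t_start=merged[0][0],
            t_end=merged[-1][1],
            q_name=f"{sp}_chr1",
            q_start=0,
            q_end=qpos - 20,
        )
        ch.blocks = blocks
        chains[sp] = iof.ChainIndex([ch])

    te_clade_limits = {
        spec.subfamily: spec.clade for spec in config.families
    }

    # --- conservation track ------------------------------------------------
    nbin = (G + config.conservation_bin - 1) // config.conservation_bin
    values = 0.3 + rng.normal(0.0, config.conservation_noise_sd, size=nbin)
    elevated = np.zeros(nbin, dtype=bool)
    for _site_id, pos in bound_sites:
        lo = max(0, (pos - 100) // config.conservation_bin)
        hi = min(nbin - 1, (pos + 100) // config.conservation_bin)
        elevated[lo : hi + 1] = True
    values[elevated] += config.conservation_delta
    values = np.clip(values, 0.0, 1.0)
    records = []
    for b in range(nbin):
        start = b * config.conservation_bin
        end = min(G, start + config.conservation_bin)
        records.append((chrom, start, end, float(round(values[b], 4))))
    conservation = iof.ScoreTrack(records)

    return FunctionLayers(
        segmentations=segmentations,
        genes=genes,
        expression=expression,
        presence=presence,
        te_clade_limits=te_clade_limits,
        chains=chains,
        conservation=conservation,
        tree=tree,
    )


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------


def write_dataset(
    outdir,
    landscape: Landscape,
    summits: dict[str, list[PeakSummit]],
    input_reads: Sequence[GenomicInterval],
    layers: Optional[FunctionLayers] = None,
) -> dict[str, Path]:
    """Write every layer as plain-text files; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def reg(name, fname):
        paths[name] = outdir / fname
        return paths[name]

    iof.write_fasta({landscape.config.chrom: landscape.genome}, reg("genome", "genome.fa"))
    iof.write_fasta(landscape.consensus, reg("consensus", "consensus.fa"))
    iof.write_repeatmasker_out(landscape.copies, reg("rmout", "repeats.out"))
    iof.write_repeatmasker_align(
        landscape.alignments, reg("rmalign", "repeats.align")
    )
    for cell, ss in summits.items():
        iof.write_narrowpeak(ss, reg(f"summits_{cell}", f"summits_{cell}.narrowPeak"))
    iof.write_bed(list(input_reads), reg("input", "input_reads.bed"))

    # ground truth
    truth = landscape.truth
    with open(reg("truth_copies", "truth_copies.tsv"), "w") as fh:
        fh.write(
            "copy_id\tsubfamily\tfamily\tstart\tend\tstrand\tcarries_motif\t"
            "motif_consensus_pos\tmotif_genomic_center\tbound_cells\tclade\n"
        )
        for c in truth.copies:
            fh.write(
                f"{c.copy_id}\t{c.subfamily}\t{c.family}\t{c.start}\t{c.end}\t"
                f"{c.strand}\t{int(c.carries_motif)}\t{c.motif_consensus_pos}\t"
                f"{c.motif_genomic_center}\t{','.join(c.bound_cells) or '.'}\t"
                f"{c.clade}\n"
            )
    with open(reg("truth_summits", "truth_summits.tsv"), "w") as fh:
        fh.write("peak_id\tcell\tkind\tcopy_id\n")
        for pid in sorted(truth.summits):
            cell, kind, copy_id = truth.summits[pid]
            fh.write(f"{pid}\t{cell}\t{kind}\t{copy_id or '.'}\n")

    if layers is not None:
        for cell, segs in layers.segmentations.items():
            with open(reg(f"states_{cell}", f"states_{cell}.bed"), "w") as fh:
                for iv, state in segs:
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{state}\n")
        iof.write_gtf(layers.genes, reg("gtf", "genes.gtf"))
        iof.write_expression_tsv(layers.expression, reg("expression", "expression.tsv"))
        iof.write_presence_table(layers.presence, reg("presence", "presence.tsv"))
        with open(reg("telimits", "te_clade_limits.tsv"), "w") as fh:
            fh.write("subfamily\tclade\n")
            for sub in sorted(layers.te_clade_limits):
                fh.write(f"{sub}\t{layers.te_clade_limits[sub]}\n")
        for sp in sorted(layers.chains):
            iof.write_chain(layers.chains[sp], reg(f"chain_{sp}", f"{sp}.chain"))
        iof.write_bedgraph(layers.conservation, reg("conservation", "conservation.bedGraph"))
        import shutil

        tree_src = (
            builtin_path("vertebrates.nwk")
            if landscape.config.tree == "default"
            else Path(landscape.config.tree)
        )
        shutil.copy(tree_src, reg("tree", "tree.nwk"))
        with open(reg("truth_genes", "truth_genes.tsv"), "w") as fh:
            fh.write("gene_id\ttrue_effect\n")
            for gid in sorted(truth.gene_effect):
                fh.write(f"{gid}\t{truth.gene_effect[gid]:.6g}\n")
    return paths


def generate(config: SimulationConfig, outdir=None):
    """Run all three simulation stages; optionally write files."""
    landscape = simulate_te_landscape(config)
    summits, input_reads = simulate_chipseq(landscape)
    layers = simulate_function_layers(landscape, summits)
    paths = None
    if outdir is not None:
        paths = write_dataset(outdir, landscape, summits, input_reads, layers)
    return landscape, summits, input_reads, layers, paths
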