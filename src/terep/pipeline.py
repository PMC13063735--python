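"""End-to-end orchestration: simulate/load -> overlap -> enrichment ->
consensus -> dating -> function -> expression, with one summary JSON.

The pipeline is deterministic: a fixed seed and config give byte-identical
outputs.  Every stage writes a plain-text TSV; the summary JSON collects
the headline quantities (TE fractions, significant families, propagation
candidates, acquisition histogram, cis-regulatory fractions, transition
matrix, expression ratios).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from terep import io_formats as iof
from terep import synthetic_data as synth
from terep.consensus_motif import (
    ConsensusHit,
    project_to_consensus,
    propagation_evidence,
)
from terep.enrichment import (
    build_background,
    enrich_all,
    family_mean_k2p,
    write_enrichment,
)
from terep.function_annotation import (
    assign_states,
    cisreg_overlap_test,
    conservation_compare,
    read_segmentation_bed,
    read_state_category_map,
    transition_matrix,
)
from terep.gene_expression import (
    TSSIndex,
    classify_and_count,
    nearest_tss,
    write_links,
)
from terep.ortholog_dating import (
    AcquisitionCall,
    PresenceRecord,
    acquisition_histogram,
    acquisition_rate,
    infer_acquisition,
    write_calls,
)
from terep.te_overlap import (
    TEIndex,
    assign_summits,
    composition_table,
    percent,
    shared_sites,
    write_assignments,
)

logger = logging.getLogger(__name__)

CELLS = ("ESC", "NPC")


@dataclass
class PipelineParams:
    sample_size: int = 20_000
    window_size: int = 50
    min_match: float = 0.95
    pseudocount: float = 0.01
    alpha: float = 0.001
    strong_log2fc: float = 3.0
    motif_p: float = 0.01
    min_consensus_hits: int = 5
    conservation_window: int = 2000


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: Path = Path("terep_out")
    simulate: Optional[synth.SimulationConfig] = None
    inputs: dict = field(default_factory=dict)
    params: PipelineParams = field(default_factory=PipelineParams)
    pwm: str = "SOX2_SYNTH"
    tf: str = "Sox2"
    state_map: str = "default"

    REQUIRED_INPUTS = (
        "rmout",
        "rmalign",
        "consensus",
        "summits_ESC",
        "summits_NPC",
        "input",
        "states_ESC",
        "states_NPC",
        "gtf",
        "expression",
        "presence",
        "telimits",
        "tree",
        "conservation",
    )

    @classmethod
    def from_yaml(cls, path, outdir=None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = raw.pop("simulate", None)
        if sim is not None:
            sim.setdefault("seed", raw.get("seed", 0))
            sim = synth.SimulationConfig.from_dict(sim)
        params = PipelineParams(**raw.pop("params", {}))
        cfg = cls(simulate=sim, params=params, **raw)
        if outdir is not None:
            cfg.outdir = Path(outdir)
        cfg.outdir = Path(cfg.outdir)
        return cfg

    def validate(self) -> None:
        if self.simulate is None:
            missing = [
                k
                for k in self.REQUIRED_INPUTS
                if k not in self.inputs or not Path(self.inputs[k]).exists()
            ]
            if missing:
                raise FileNotFoundError(
                    f"missing required inputs: {', '.join(missing)}"
                )

    def config_hash(self) -> str:
        payload = {
            "seed": self.seed,
            "pwm": self.pwm,
            "tf": self.tf,
            "params": vars(self.params),
            "simulate": None
            if self.simulate is None
            else json.loads(
                json.dumps(self.simulate, default=lambda o: vars(o))
            ),
        }
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        if math.isnan(obj):
            return None
        if math.isinf(obj):
            return "inf" if obj > 0 else "-inf"
        return round(float(obj), ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and return the summary dict (also written as JSON)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.params

    # ------------------------------------------------------------------ load
    if config.simulate is not None:
        simdir = outdir / "sim"
        logger.info("simulating dataset into %s", simdir)
        *_ignored, paths = synth.generate(config.simulate, simdir)
        inputs = {k: str(v) for k, v in paths.items()}
    else:
        inputs = dict(config.inputs)

    copies = iof.read_repeatmasker_out(inputs["rmout"])
    aligns = iof.read_repeatmasker_align(inputs["rmalign"])
    consensus = iof.read_fasta(inputs["consensus"])
    summits = {
        cell: iof.read_narrowpeak(
            inputs[f"summits_{cell}"], tf=config.tf, cell=cell
        )
        for cell in CELLS
    }
    input_reads = iof.read_bed(inputs["input"])
    segmentations = {
        cell: read_segmentation_bed(inputs[f"states_{cell}"]) for cell in CELLS
    }
    if config.state_map == "default":
        state_map = read_state_category_map(
            synth.builtin_path("state_categories.tsv")
        )
    else:
        state_map = read_state_category_map(config.state_map)
    tss_list = iof.read_gtf_tss(inputs["gtf"])
    expression = iof.read_expression_tsv(inputs["expression"])
    presence = iof.read_presence_table(inputs["presence"])
    telimits = {}
    with open(inputs["telimits"]) as fh:
        for line in fh:
            if line.strip() and not line.startswith("subfamily"):
                sub, clade = line.split()
                telimits[sub] = clade
    tree = iof.read_newick_dated(inputs["tree"])
    conservation = iof.read_bedgraph(inputs["conservation"])
    if Path(config.pwm).suffix == ".meme":
        pwm = iof.read_meme_pwm(config.pwm)[0]
    else:
        pwm = synth.builtin_pwm(config.pwm)

    summary: dict = {"config_hash": config.config_hash(), "seed": config.seed}

    # --------------------------------------------------------------- overlap
    index = TEIndex(copies)
    assignments = {}
    tables = {}
    for cell in CELLS:
        assignments[cell] = assign_summits(summits[cell], index)
        write_assignments(
            assignments[cell], outdir / f"assignments_{cell}.tsv"
        )
        tables[cell] = composition_table(assignments[cell])
    shared = shared_sites(assignments["ESC"], assignments["NPC"])
    summary["overlap"] = {
        cell: {
            "total_summits": tables[cell].total_summits,
            "te_assigned": tables[cell].te_assigned,
            "te_fraction_pct": tables[cell].te_fraction_pct,
            "class_composition_pct": tables[cell].class_composition_pct(),
        }
        for cell in CELLS
    }
    summary["overlap"]["shared_te_copies"] = shared

    # ------------------------------------------------------------ enrichment
    copy_subfamily = {c.copy_id: c.subfamily for c in copies}
    copy_family = {c.copy_id: c.family for c in copies}
    background = build_background(
        input_reads, index, sample_size=params.sample_size, seed=config.seed
    )
    sub_k2p = family_mean_k2p(aligns, copy_subfamily)
    all_subfamilies = sorted({c.subfamily for c in copies})
    enrichment = {}
    for cell in CELLS:
        results = enrich_all(
            tables[cell],
            background,
            level="subfamily",
            family_k2p=sub_k2p,
            families=all_subfamilies,
            alpha=params.alpha,
        )
        enrichment[cell] = results
        write_enrichment(results, outdir / f"enrichment_{cell}.tsv")
    summary["enrichment"] = {
        cell: {
            "n_tested": len(enrichment[cell]),
            "significant": sorted(
                r.family for r in enrichment[cell] if r.significant
            ),
        }
        for cell in CELLS
    }

    # -------------------------------------------------------------- consensus
    align_by_id = {rec.copy_id: rec for rec in aligns}
    propagation = {}
    for cell in CELLS:
        hits_by_sub: dict[str, list[ConsensusHit]] = {}
        for s, a in zip(summits[cell], assignments[cell]):
            if not a.assigned:
                continue
            rec = align_by_id.get(a.copy_id)
            if rec is None:
                continue
            cpos = project_to_consensus(s.pos, rec)
            if cpos is None:
                continue
            hits_by_sub.setdefault(a.subfamily, []).append(
                ConsensusHit(a.copy_id, a.subfamily, cpos, s.peak_id)
            )
        reports = {}
        for sub in sorted(hits_by_sub):
            hits = hits_by_sub[sub]
            if len(hits) < params.min_consensus_hits or sub not in consensus:
                continue
            reports[sub] = propagation_evidence(
                sub,
                hits,
                consensus[sub],
                pwm,
                alignments=aligns,
                window_size=params.window_size,
                alpha=params.alpha,
                motif_p=params.motif_p,
            )
        propagation[cell] = reports
    with open(outdir / "propagation.tsv", "w") as fh:
        fh.write(
            "cell\tsubfamily\tn_hits\twindow_start\twindow_end\tn_in_window\t"
            "p_cluster\tcandidate\tmotif_retention\n"
        )
        for cell in CELLS:
            for sub, rep in sorted(propagation[cell].items()):
                c = rep.cluster
                ret = (
                    f"{rep.motif_retention:.3f}"
                    if rep.motif_retention is not None
                    else "."
                )
                fh.write(
                    f"{cell}\t{sub}\t{c.n_total}\t{c.window_start}\t"
                    f"{c.window_end}\t{c.n_in_window}\t{c.p_cluster:.4g}\t"
                    f"{int(rep.candidate)}\t{ret}\n"
                )
    summary["propagation_candidates"] = {
        cell: sorted(
            sub for sub, rep in propagation[cell].items() if rep.candidate
        )
        for cell in CELLS
    }

    # ----------------------------------------------------------------- dating
    site_subfamily = {}
    site_class = {}
    for cell in CELLS:
        for a in assignments[cell]:
            if a.assigned:
                site_subfamily[a.peak_id] = a.subfamily
                site_class[a.peak_id] = a.te_class
    calls: list[AcquisitionCall] = []
    for site_id in sorted(presence):
        rec = PresenceRecord(site_id, presence[site_id])
        limit = telimits.get(site_subfamily.get(site_id, ""), None)
        calls.append(infer_acquisition(rec, tree, te_clade_limit=limit))
    write_calls(calls, outdir / "acquisition_calls.tsv")
    hist = acquisition_histogram(calls, tree, site_class=site_class)
    hist.to_csv(outdir / "acquisition_histogram.tsv", sep="\t", index=False)
    rates = acquisition_rate(hist, tree)
    rates.to_csv(outdir / "acquisition_rates.tsv", sep="\t", index=False)
    clade_frac = {}
    for clade, group in hist.groupby("clade", sort=False):
        clade_frac[clade] = percent(int(group["count"].sum()), len(calls))
    summary["acquisition"] = {
        "n_sites": len(calls),
        "clade_fraction_pct": clade_frac,
        "n_capped": sum(1 for c in calls if c.capped_by_te_age),
    }

    # --------------------------------------------------------------- function
    rng_positions = [(f"ctrl{j}", r.chrom, r.start) for j, r in enumerate(input_reads[: params.sample_size])]
    func_summary = {}
    states_at = {}
    for cell in CELLS:
        te_sites = [
            (a.peak_id, s.interval.chrom, s.pos)
            for s, a in zip(summits[cell], assignments[cell])
            if a.assigned
        ]
        site_states = assign_states(
            te_sites, cell, segmentations[cell], state_map
        )
        control_states = assign_states(
            rng_positions, cell, segmentations[cell], state_map
        )
        frac, p = cisreg_overlap_test(site_states, control_states)
        func_summary[cell] = {
            "n_te_sites": len(site_states),
            "cisreg_fraction_pct": percent(
                sum(1 for a in site_states if a.category == "cis-regulatory"),
                len(site_states),
            ),
            "control_fraction_pct": percent(
                sum(
                    1
                    for a in control_states
                    if a.category == "cis-regulatory"
                ),
                len(control_states),
            ),
            "p_binomial": p,
        }
        states_at[cell] = site_states

    # ESC-specific copies: their ESC-summit states in both segmentations
    bound_cells: dict[str, set] = {}
    summit_of_copy: dict[tuple[str, str], tuple[str, str, int]] = {}
    for cell in CELLS:
        for s, a in zip(summits[cell], assignments[cell]):
            if a.assigned:
                bound_cells.setdefault(a.copy_id, set()).add(cell)
                summit_of_copy.setdefault(
                    (a.copy_id, cell), (s.peak_id, s.interval.chrom, s.pos)
                )
    transitions = {}
    for spec_cell, other in (("ESC", "NPC"), ("NPC", "ESC")):
        sites = [
            summit_of_copy[(cid, spec_cell)]
            for cid, cells in sorted(bound_cells.items())
            if cells == {spec_cell}
        ]
        a_states = assign_states(
            sites, spec_cell, segmentations[spec_cell], state_map
        )
        b_states = assign_states(sites, other, segmentations[other], state_map)
        tm = transition_matrix(a_states, b_states)
        tm.counts.to_csv(
            outdir / f"transition_{spec_cell}_specific.tsv", sep="\t"
        )
        transitions[spec_cell] = tm
        func_summary[f"{spec_cell}_specific_transition"] = {
            "n_sites": tm.n_with_both,
            "row_fractions": {
                row: {
                    col: round(float(v), 4)
                    for col, v in tm.row_fractions.loc[row].items()
                }
                for row in tm.counts.index
            },
        }
    # conservation: TE-bound sites vs control input positions
    te_sites_all = sorted(
        {
            (chrom, pos)
            for cell in CELLS
            for (_pid, chrom, pos) in [
                (a.peak_id, s.interval.chrom, s.pos)
                for s, a in zip(summits[cell], assignments[cell])
                if a.assigned
            ]
        }
    )
    ctrl_sites = [(chrom, pos) for _sid, chrom, pos in rng_positions]
    welch = conservation_compare(
        te_sites_all,
        conservation,
        ctrl_sites,
        window=params.conservation_window,
    )
    func_summary["conservation"] = {
        "mean_sites": welch.mean_a,
        "mean_control": welch.mean_b,
        "t": welch.t,
        "df": welch.df,
        "p": welch.p,
    }
    summary["function"] = func_summary

    # ------------------------------------------------------------- expression
    tss_index = TSSIndex(tss_list)
    expr_summary = {}
    for spec_cell in CELLS:
        links = []
        for cid, cells in sorted(bound_cells.items()):
            if cells != {spec_cell}:
                continue
            pid, chrom, pos = summit_of_copy[(cid, spec_cell)]
            links.append(nearest_tss(pid, chrom, pos, tss_index))
        counts = classify_and_count(
            links,
            expression,
            group=f"{spec_cell}-specific",
            pseudocount=params.pseudocount,
            strong_threshold=params.strong_log2fc,
        )
        write_links(links, outdir / f"nearest_genes_{spec_cell}_specific.tsv")
        expr_summary[spec_cell] = {
            "n_links": len(links),
            "up": counts.up,
            "down": counts.down,
            "strong_up": counts.strong_up,
            "strong_down": counts.strong_down,
            "up_down_ratio": counts.up_down_ratio,
            "strong_ratio": counts.strong_ratio,
        }
    summary["expression"] = expr_summary

    summary = _round_floats(summary)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
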