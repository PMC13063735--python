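"""Consensus projection, positional clustering, and exact-p PWM scanning."""

from __future__ import annotations

import numpy as np
import pytest

from terep.consensus_motif import (
    ConsensusHit,
    MotifMatch,
    cluster_positions,
    consensus_to_genomic,
    project_to_consensus,
    propagation_evidence,
    revcomp,
    scan_pwm,
)
from terep.types import AlignmentRecord, GenomicInterval, PWM


def _rec(gq, gc, start=100, strand="+", cstart=1):
    q_len = sum(1 for c in gq if c != "-")
    c_len = sum(1 for c in gc if c != "-")
    return AlignmentRecord(
        copy_id="c1",
        genomic=GenomicInterval("chr1", start, start + q_len, strand),
        consensus_name="CONS",
        consensus_start=cstart,
        consensus_end=cstart + c_len - 1,
        orientation="reverse" if strand == "-" else "forward",
        gapped_query=gq,
        gapped_consensus=gc,
    )


def _project_oracle(pos, rec):
    """Brute-force column walk kept deliberately simple."""
    cols = list(zip(rec.gapped_query, rec.gapped_consensus))
    if rec.orientation == "reverse":
        offset = rec.genomic.end - 1 - pos
    else:
        offset = pos - rec.genomic.start
    q_positions = [i for i, (q, _c) in enumerate(cols) if q != "-"]
    col = q_positions[offset]
    if cols[col][1] == "-":
        return None
    return rec.consensus_start + sum(
        1 for i in range(col) if cols[i][1] != "-"
    )


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------


def test_gapless_projection_is_offset_arithmetic():
    rec = _rec("ACGTACGTACGT", "ACGTACGTACGT", start=100, cstart=101)
    assert project_to_consensus(110, rec) == 111


def test_projection_through_deletion():
    # query AC-GT vs consensus ACTGT: genomic offset 2 is the G, column 4,
    # consensus position 4
    rec = _rec("AC-GT", "ACTGT", start=0)
    assert project_to_consensus(2, rec) == 4


def test_projection_into_insertion_returns_none():
    rec = _rec("ACGT", "AC-T", start=0)
    assert project_to_consensus(2, rec) is None


def test_projection_outside_span_errors():
    rec = _rec("ACGT", "ACGT", start=100)
    with pytest.raises(ValueError, match="outside"):
        project_to_consensus(99, rec)


def test_projection_matches_bruteforce_oracle_on_random_gapped_fixtures():
    rng = np.random.default_rng(12)
    bases = "ACGT"
    for trial in range(40):
        cols = []
        for _ in range(rng.integers(20, 80)):
            r = rng.random()
            if r < 0.1:
                cols.append(("-", bases[rng.integers(4)]))
            elif r < 0.2:
                cols.append((bases[rng.integers(4)], "-"))
            else:
                cols.append((bases[rng.integers(4)], bases[rng.integers(4)]))
        # ensure at least one aligned column
        cols.append(("A", "A"))
        gq = "".join(q for q, _ in cols)
        gc = "".join(c for _, c in cols)
        strand = "+" if trial % 2 == 0 else "-"
        rec = _rec(gq, gc, start=1000, strand=strand, cstart=51)
        for pos in range(rec.genomic.start, rec.genomic.end):
            assert project_to_consensus(pos, rec) == _project_oracle(pos, rec)


def test_forward_reverse_consistency():
    """Flipping the record to the opposite strand (reverse-complementing
    both gapped strings is not needed: the query stays in consensus
    orientation) leaves projected consensus positions unchanged for
    mirrored genomic offsets."""
    gq, gc = "AC-GTTA", "ACTG-TA"
    fwd = _rec(gq, gc, start=500, strand="+")
    rev = _rec(gq, gc, start=500, strand="-")
    n = len(fwd.genomic)
    for off in range(n):
        assert project_to_consensus(500 + off, fwd) == project_to_consensus(
            500 + (n - 1 - off), rev
        )


def test_consensus_to_genomic_inverts_projection():
    rng = np.random.default_rng(3)
    gq = "ACGT-ACGTAC"
    gc = "ACG-TACGT-C"
    for strand in "+-":
        rec = _rec(gq, gc, start=200, strand=strand)
        for cpos in range(rec.consensus_start, rec.consensus_end + 1):
            g = consensus_to_genomic(cpos, rec)
            if g is not None:
                assert project_to_consensus(g, rec) == cpos


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def test_concentrated_hits_are_highly_significant():
    """21 of 30 hits within one 50-bp window of a 634-bp consensus."""
    hits = [590 + (i % 10) for i in range(21)] + [
        50, 100, 150, 200, 250, 300, 350, 400, 450
    ]
    cluster = cluster_positions(hits, consensus_length=634, window_size=50)
    assert cluster.n_in_window == 21
    assert cluster.window_start <= 590 <= cluster.window_end
    assert cluster.p_cluster < 1e-10


def test_single_hit_not_significant():
    cluster = cluster_positions([300], consensus_length=634, window_size=50)
    assert cluster.n_in_window == 1
    assert cluster.p_cluster == 1.0


def test_uniform_hits_rarely_significant():
    rng = np.random.default_rng(8)
    n_sig = 0
    for _ in range(40):
        hits = rng.integers(1, 635, size=30).tolist()
        c = cluster_positions(hits, 634, 50)
        if c.p_cluster < 0.001:
            n_sig += 1
    assert n_sig <= 2  # alpha with Bonferroni: should essentially never fire


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------


def _indicator_pwm(motif: str) -> PWM:
    rows = []
    for b in motif:
        row = [0.0, 0.0, 0.0, 0.0]
        row["ACGT".index(b)] = 1.0
        rows.append(row)
    return PWM("IND", np.array(rows))


def test_indicator_pwm_finds_exact_match_and_reverse_complement():
    pwm = _indicator_pwm("CTTTGT")
    seq = "AAAA" + "CTTTGT" + "AAAAAA"
    matches = scan_pwm(seq, pwm, threshold_p=0.01)
    fwd = [m for m in matches if m.strand == "+"]
    assert len(fwd) == 1 and fwd[0].start == 5 and fwd[0].end == 10
    seq_rc = "GGGG" + revcomp("CTTTGT") + "GGGG"
    matches = scan_pwm(seq_rc, pwm, threshold_p=0.01)
    rev = [m for m in matches if m.strand == "-"]
    assert len(rev) == 1 and rev[0].start == 5


def test_scan_skips_windows_with_n():
    pwm = _indicator_pwm("ACGT")
    assert scan_pwm("ACNTACGT", pwm, 0.5)  # the clean window matches
    assert not [m for m in scan_pwm("ACNT", pwm, 0.5)]


def test_sequence_shorter_than_pwm_gives_empty():
    pwm = _indicator_pwm("ACGTACGT")
    assert scan_pwm("ACG", pwm) == []


def test_null_match_rate_calibrated():
    """On random sequence the number of matches at threshold p tracks
    2 x (L - w + 1) x p within 3 sigma."""
    rng = np.random.default_rng(21)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=10_000))
    pwm = PWM(
        "SOFT",
        np.array(
            [[0.7, 0.1, 0.1, 0.1]] * 4 + [[0.1, 0.1, 0.1, 0.7]] * 4
        ),
    )
    p_t = 0.01
    matches = scan_pwm(seq, pwm, threshold_p=p_t)
    n_windows = 2 * (len(seq) - pwm.width + 1)
    # the exact null is discrete: use the attained level, the p-value of
    # the weakest reported match, as the effective threshold
    attained = max(m.p_match for m in matches)
    expected = n_windows * attained
    sigma = np.sqrt(expected)
    assert abs(len(matches) - expected) < 3 * sigma + 1


def test_exact_pvalues_match_empirical_null():
    rng = np.random.default_rng(33)
    pwm = PWM(
        "SOFT2",
        np.array([[0.6, 0.2, 0.1, 0.1]] * 6),
    )
    from terep.consensus_motif import _ScoredPWM

    scored = _ScoredPWM(pwm)
    n_mc = 100_000
    draws = rng.integers(0, 4, size=(n_mc, pwm.width))
    scores = scored.int_scores[np.arange(pwm.width), draws].sum(axis=1)
    for q in (0.5, 0.9, 0.99):
        s = int(np.quantile(scores, q))
        emp = (scores >= s).mean()
        exact = scored.pvalue(s)
        # Monte-Carlo error at 4 sigma
        se = np.sqrt(exact * (1 - exact) / n_mc)
        assert abs(emp - exact) < 4 * se + 1e-6


# ---------------------------------------------------------------------------
# propagation evidence
# ---------------------------------------------------------------------------


def test_planted_family_is_flagged_with_window_near_plant_site(bundle):
    landscape, summits, _reads, _layers = bundle
    from terep.synthetic_data import builtin_pwm
    from terep.te_overlap import assign_summits

    pwm = builtin_pwm("SOX2_SYNTH")
    align_by_id = {r.copy_id: r for r in landscape.alignments}
    assignments = assign_summits(summits["NPC"], landscape.copies)
    hits = []
    for s, a in zip(summits["NPC"], assignments):
        if a.assigned and a.subfamily == "MERS1A":
            cpos = project_to_consensus(s.pos, align_by_id[a.copy_id])
            if cpos is not None:
                hits.append(ConsensusHit(a.copy_id, "MERS1A", cpos, s.peak_id))
    report = propagation_evidence(
        "MERS1A", hits, landscape.consensus["MERS1A"], pwm,
        alignments=landscape.alignments,
    )
    assert report.candidate
    planted_center = 250 + pwm.width // 2
    assert abs(report.cluster.center - planted_center) <= 5
    assert report.motif_retention is not None and report.motif_retention > 0.5


def test_motif_free_uniform_hits_not_flagged():
    rng = np.random.default_rng(44)
    consensus = "".join("ACGT"[i] for i in rng.integers(0, 4, size=600))
    pwm = _indicator_pwm("CTTTGT")
    n_flagged = 0
    for seed in range(20):
        r2 = np.random.default_rng(100 + seed)
        hits = [
            ConsensusHit(f"c{i}", "F", int(p), f"p{i}")
            for i, p in enumerate(r2.integers(1, 601, size=30))
        ]
        rep = propagation_evidence("F", hits, consensus, pwm)
        n_flagged += rep.candidate
    assert n_flagged <= 1


def test_zero_hits_reports_no_evidence():
    pwm = _indicator_pwm("CTTTGT")
    rep = propagation_evidence("F", [], "ACGT" * 100, pwm)
    assert rep.cluster is None
    assert not rep.candidate
    assert "no evidence" in rep.note
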