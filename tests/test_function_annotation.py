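"""Chromatin-state assignment, cis-regulatory testing, transitions, and
conservation comparison."""

from __future__ import annotations

import numpy as np
import pytest

from terep.function_annotation import (
    Segmentation,
    StateAssignment,
    assign_state,
    assign_states,
    cisreg_overlap_test,
    conservation_compare,
    read_state_category_map,
    transition_matrix,
)
from terep.io_formats import ScoreTrack
from terep.synthetic_data import builtin_path
from terep.te_overlap import percent
from terep.types import GenomicInterval


@pytest.fixture(scope="module")
def state_map():
    return read_state_category_map(builtin_path("state_categories.tsv"))


def _seg(rows):
    return Segmentation(
        [(GenomicInterval("chr1", s, e), st) for s, e, st in rows]
    )


def test_state_at_boundary_belongs_to_containing_segment(state_map):
    seg = _seg([(0, 100, "EnhA1"), (100, 200, "Quies")])
    a = assign_state("s1", "chr1", 99, "NPC", seg, state_map)
    b = assign_state("s2", "chr1", 100, "NPC", seg, state_map)
    assert (a.state, b.state) == ("EnhA1", "Quies")
    assert a.category == "cis-regulatory"
    assert b.category == "quiescent/low"


def test_unannotated_gap_maps_to_other(state_map):
    seg = _seg([(0, 100, "EnhA1")])
    a = assign_state("s1", "chr1", 500, "NPC", seg, state_map)
    assert a.state is None and a.category == "other"


def test_overlapping_segmentation_rejected():
    with pytest.raises(ValueError, match="overlapping"):
        _seg([(0, 100, "A"), (50, 150, "B")])


def test_planted_states_recovered_exactly(state_map):
    """With enhancer probability 1, every bound-TE summit tile is an
    active enhancer in the bound cell."""
    from conftest import small_config
    from terep.synthetic_data import generate

    cfg = small_config(
        seed=55, enhancer_prob_bound={"ESC": 1.0, "NPC": 1.0}
    )
    landscape, summits, _reads, layers, _paths = generate(cfg)
    seg = Segmentation(layers.segmentations["NPC"])
    for s in summits["NPC"]:
        if landscape.truth.summits[s.peak_id][1] == "planted":
            a = assign_state(s.peak_id, "chrS", s.pos, "NPC", seg, state_map)
            assert a.state == "EnhA1"
            assert a.category == "cis-regulatory"


def test_cisreg_percent_reporting():
    """Published overlap proportions reproduce from their raw counts."""
    assert percent(4002, 5956) == 67.2
    assert percent(8003, 17132) == 46.7


def test_cisreg_test_null_when_equal_to_control(state_map):
    sites = [StateAssignment(f"s{i}", "NPC", "EnhA1", "cis-regulatory") for i in range(10)]
    sites += [StateAssignment(f"q{i}", "NPC", "Quies", "quiescent/low") for i in range(90)]
    control = [
        StateAssignment(f"c{i}", "NPC", "EnhA1", "cis-regulatory") for i in range(100)
    ] + [StateAssignment(f"d{i}", "NPC", "Quies", "quiescent/low") for i in range(900)]
    frac, p = cisreg_overlap_test(sites, control)
    assert frac == pytest.approx(0.10)
    assert p > 0.9


def test_cisreg_test_detects_enrichment(state_map):
    sites = [StateAssignment(f"s{i}", "NPC", "EnhA1", "cis-regulatory") for i in range(67)]
    sites += [StateAssignment(f"q{i}", "NPC", "Quies", "quiescent/low") for i in range(33)]
    control = [
        StateAssignment(f"c{i}", "NPC", "EnhA1", "cis-regulatory") for i in range(80)
    ] + [StateAssignment(f"d{i}", "NPC", "Quies", "quiescent/low") for i in range(920)]
    frac, p = cisreg_overlap_test(sites, control)
    assert p < 1e-4


def test_transition_identity_and_row_sums():
    a = [StateAssignment(f"s{i}", "ESC", "EnhA1", "cis-regulatory") for i in range(5)]
    b = [StateAssignment(f"s{i}", "NPC", "EnhA1", "cis-regulatory") for i in range(5)]
    tm = transition_matrix(a, b)
    assert tm.counts.loc["cis-regulatory", "cis-regulatory"] == 5
    assert tm.counts.to_numpy().sum() == tm.n_with_both == 5
    assert tm.row_fractions.loc["cis-regulatory"].sum() == pytest.approx(1.0)


def test_transition_designed_fractions_recovered():
    """An ESC-enhancer cohort sent to quiescence in NPC with designed
    probability is recovered within binomial sampling error."""
    from conftest import small_config
    from terep.synthetic_data import generate
    from terep.function_annotation import Segmentation

    cfg = small_config(
        seed=77,
        enhancer_prob_bound={"ESC": 1.0, "NPC": 1.0},
        transition_quiescent_prob=0.6,
    )
    landscape, summits, _reads, layers, _paths = generate(cfg)
    state_map = read_state_category_map(builtin_path("state_categories.tsv"))
    esc_only_sites = []
    for s in summits["ESC"]:
        _cell, kind, copy_id = landscape.truth.summits[s.peak_id]
        if kind != "planted":
            continue
        truth_copy = next(
            c for c in landscape.truth.copies if c.copy_id == copy_id
        )
        if set(truth_copy.bound_cells) == {"ESC"}:
            esc_only_sites.append((s.peak_id, "chrS", s.pos))
    seg_esc = Segmentation(layers.segmentations["ESC"])
    seg_npc = Segmentation(layers.segmentations["NPC"])
    a = assign_states(esc_only_sites, "ESC", seg_esc, state_map)
    b = assign_states(esc_only_sites, "NPC", seg_npc, state_map)
    tm = transition_matrix(a, b)
    frac_quies = tm.row_fractions.loc["cis-regulatory", "quiescent/low"]
    n = len(esc_only_sites)
    sigma = np.sqrt(0.6 * 0.4 / n)
    assert abs(frac_quies - 0.6) < 3.5 * sigma


def test_transition_empty():
    tm = transition_matrix([], [])
    assert tm.counts.to_numpy().sum() == 0
    assert tm.n_with_both == 0


# ---------------------------------------------------------------------------
# conservation / Welch
# ---------------------------------------------------------------------------


def _track_from_values(values, bin_size=100):
    """One bin per 'site': site i at the centre of bin i."""
    return ScoreTrack(
        [("chr1", i * bin_size, (i + 1) * bin_size, v) for i, v in enumerate(values)]
    )


def test_welch_hand_values():
    track = _track_from_values([1, 2, 3, 2, 3, 4])
    sites = [("chr1", 50), ("chr1", 150), ("chr1", 250)]
    control = [("chr1", 350), ("chr1", 450), ("chr1", 550)]
    res = conservation_compare(sites, track, control, window=100)
    assert res.mean_a == pytest.approx(2.0)
    assert res.mean_b == pytest.approx(3.0)
    assert res.t == pytest.approx(-1.2247, abs=1e-4)
    assert res.df == pytest.approx(4.0)


def test_welch_identical_groups():
    track = _track_from_values([1, 2, 3, 1, 2, 3])
    sites = [("chr1", 50), ("chr1", 150), ("chr1", 250)]
    control = [("chr1", 350), ("chr1", 450), ("chr1", 550)]
    res = conservation_compare(sites, track, control, window=100)
    assert res.t == pytest.approx(0.0)
    assert res.p == pytest.approx(1.0)


def test_missing_scores_excluded_from_window_means():
    track = ScoreTrack([("chr1", 0, 50, 1.0)])  # second half of window missing
    sites = [("chr1", 50), ("chr1", 50)]
    control_track_sites = [("chr1", 25), ("chr1", 25)]
    res = conservation_compare(sites, track, control_track_sites, window=100)
    assert res.mean_a == pytest.approx(1.0)  # not dragged down by zeros


def test_welch_power_on_shifted_groups():
    """Groups of 500 means from N(0.5, 0.1) vs N(0.45, 0.1) separate at
    p < 1e-4 in nearly every replicate."""
    rng = np.random.default_rng(66)
    hits = 0
    reps = 20
    for _ in range(reps):
        a = rng.normal(0.5, 0.1, 500)
        b = rng.normal(0.45, 0.1, 500)
        track = _track_from_values(np.concatenate([a, b]))
        sites = [("chr1", i * 100 + 50) for i in range(500)]
        control = [("chr1", (500 + i) * 100 + 50) for i in range(500)]
        res = conservation_compare(sites, track, control, window=100)
        if res.p < 1e-4:
            hits += 1
    assert hits >= int(0.95 * reps)


def test_generator_conservation_track_separates(bundle):
    """The generator elevates conservation around bound TE summits by a
    configured delta; the Welch comparison detects it."""
    landscape, summits, reads, layers = bundle
    te_sites = [
        ("chrS", s.pos)
        for cell in ("ESC", "NPC")
        for s in summits[cell]
        if landscape.truth.summits[s.peak_id][1] == "planted"
    ]
    control = [("chrS", r.start) for r in reads[:500]]
    res = conservation_compare(te_sites, layers.conservation, control, window=200)
    assert res.mean_a > res.mean_b
    assert res.p < 1e-4
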