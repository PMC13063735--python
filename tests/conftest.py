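"""Shared fixtures: a small synthetic landscape with ground truth, built
once per session, plus its on-disk form."""

from __future__ import annotations

import pytest

from terep.synthetic_data import (
    FamilySpec,
    MotifSpec,
    SimulationConfig,
    generate,
)


def small_config(seed: int = 101, **overrides) -> SimulationConfig:
    """Three families: an LTR family propagating a Sox2-like motif bound in
    NPC, a SINE family bound in both cells, and a motif-free LINE family."""
    kwargs = dict(
        seed=seed,
        genome_length=400_000,
        families=[
            FamilySpec(
                "MERS1A",
                "ERVS",
                "LTR/ERVS",
                n_copies=40,
                consensus_length=400,
                divergence=0.10,
                clade="Simiiformes",
                motif=MotifSpec("SOX2_SYNTH", position=250, fraction=0.5, cells=("NPC",)),
            ),
            FamilySpec(
                "AmnSINE-X",
                "AmnSINE",
                "SINE/AmnSINE",
                n_copies=40,
                consensus_length=300,
                divergence=0.25,
                clade="Amniota",
                motif=MotifSpec(
                    "SOX2_SYNTH",
                    position=120,
                    fraction=0.5,
                    cells=("ESC", "NPC"),
                    shared_fraction=0.5,
                ),
            ),
            FamilySpec(
                "L3X",
                "CR1",
                "LINE/CR1",
                n_copies=30,
                consensus_length=350,
                divergence=0.20,
                clade="Eutheria",
            ),
        ],
        n_background_summits={"ESC": 40, "NPC": 40},
        n_input_reads=20_000,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def bundle():
    """(landscape, summits, input_reads, layers) for the small config."""
    landscape, summits, reads, layers, _ = generate(small_config())
    return landscape, summits, reads, layers


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory):
    """The same dataset written to disk."""
    outdir = tmp_path_factory.mktemp("dataset")
    generate(small_config(), outdir)
    return outdir
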