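"""Shared fixtures: toy annotations, truth sets, emulated tool tables."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from spliceharmony import splice_sim as sim
from spliceharmony.junction_space import AnchorIndex

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


TOY_GTF = """\
chr1\ttoy\tgene\t101\t600\t.\t+\t.\tgene_id "G1";
chr1\ttoy\ttranscript\t101\t600\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
chr1\ttoy\texon\t101\t200\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
chr1\ttoy\texon\t301\t400\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
chr1\ttoy\texon\t501\t600\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
"""


@pytest.fixture(scope="session")
def toy_gtf_path(tmp_path_factory):
    path = tmp_path_factory.mktemp("gtf") / "toy.gtf"
    path.write_text(TOY_GTF)
    return path


@pytest.fixture(scope="session")
def toy_genome_small():
    """20-gene synthetic genome for fast unit tests."""
    return sim.toy_genome(n_genes=20, seed=7)


@pytest.fixture(scope="session")
def toy_genome_full():
    """Full-size synthetic genome able to host the default truth set."""
    return sim.toy_genome(seed=1)


@pytest.fixture(scope="session")
def truth_default(toy_genome_full):
    _, ann = toy_genome_full
    return sim.generate_truth_events(ann, seed=1)


@pytest.fixture(scope="session")
def anchor_index_full(toy_genome_full):
    _, ann = toy_genome_full
    return AnchorIndex.build(ann)


@pytest.fixture(scope="session")
def noiseless_tables(toy_genome_full, truth_default, tmp_path_factory):
    """Noiseless emulated tool tables for one condition, on disk."""
    _, ann = toy_genome_full
    units = sim.sim_units(truth_default, ann)
    tables = sim.emulate_condition(
        units, 5000, (80, 20), sim.EmulatorNoise.noiseless(), seed=11
    )
    outdir = tmp_path_factory.mktemp("noiseless")
    tables.write(outdir)
    return tables, outdir
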