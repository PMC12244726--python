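from __future__ import annotations

import time
from dataclasses import dataclass
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from orgweave.align import blast_organelle_hits, map_reads
from orgweave.io import write_fasta, write_fastq
from orgweave.simulate import (SimulationConfig, SimulatedDataset,
                               simulate_dataset, simulate_long_reads)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@dataclass
class PipelineFixture:
    dataset: SimulatedDataset
    workdir: Path
    mito_hits: list
    plastid_hits: list
    read_hits: list
    elapsed_seconds: float


@pytest.fixture(scope="session")
def default_pipeline(tmp_path_factory) -> PipelineFixture:
    """The default study-condition fixture, run end to end once per session:
    simulate genomes + reads, align organelles with blastn, map reads with
    minimap2."""
    t0 = time.time()
    wd = tmp_path_factory.mktemp("default_fixture")
    cfg = SimulationConfig(seed=42)
    ds = simulate_dataset(cfg)
    write_fasta(ds.contigs, wd / "assembly.fa")
    write_fasta(ds.nuclear_contigs, wd / "nuclear.fa")
    write_fasta([ds.mitome], wd / "mito.fa")
    write_fasta([ds.plastome], wd / "plastid.fa")
    mito_hits = blast_organelle_hits(wd / "mito.fa", wd / "nuclear.fa", wd, "mito")
    plastid_hits = blast_organelle_hits(wd / "plastid.fa", wd / "nuclear.fa", wd, "plastid")
    reads = simulate_long_reads(ds.nuclear_contigs, ds.plastome, ds.mitome, cfg)
    write_fastq(reads, wd / "reads.fastq")
    read_hits = map_reads(wd / "assembly.fa", wd / "reads.fastq", wd)
    return PipelineFixture(ds, wd, mito_hits, plastid_hits, read_hits, time.time() - t0)


@pytest.fixture(scope="session")
def organelle_assembly_hits(default_pipeline) -> list:
    """Organelle genomes blasted against the full assembly (organelle-derived
    contigs included), for the depth-outlier confirmation step."""
    wd = default_pipeline.workdir
    return (blast_organelle_hits(wd / "mito.fa", wd / "assembly.fa", wd, "mito")
            + blast_organelle_hits(wd / "plastid.fa", wd / "assembly.fa", wd, "plastid"))
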