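"""Thin wrappers around external aligners (blastn, minimap2).

The package never implements alignment itself; organelle-vs-nuclear hit
tables come from blastn (outfmt 6) and read mappings from minimap2 (PAF).
Both wrappers are plain subprocess calls so tests can substitute
precomputed tables.
"""

from __future__ import annotations

import shutil
import subprocess
from pathlib import Path

from .io import read_alignments


class AlignerMissingError(RuntimeError):
    pass


def _require(tool: str) -> str:
    path = shutil.which(tool)
    if path is None:
        raise AlignerMissingError(
            f"{tool} not found on PATH; either install it or supply a "
            f"precomputed alignment table (--alignments/--dialect)")
    return path


def run_blastn(query_fasta, subject_fasta, out_tsv, task: str = "blastn",
               evalue: float = 1e-6) -> Path:
    """blastn query vs subject, tabular outfmt 6, written to ``out_tsv``."""
    _require("blastn")
    out_tsv = Path(out_tsv)
    cmd = [
        "blastn", "-task", task,
        "-query", str(query_fasta), "-subject", str(subject_fasta),
        "-outfmt", "6", "-evalue", str(evalue), "-out", str(out_tsv),
    ]
    subprocess.run(cmd, check=True, capture_output=True, text=True)
    return out_tsv


def run_minimap2(reference_fasta, reads_fastq, out_paf, preset: str = "map-hifi",
                 threads: int = 1) -> Path:
    """minimap2 reads vs reference, PAF written to ``out_paf``."""
    _require("minimap2")
    out_paf = Path(out_paf)
    cmd = ["minimap2", "-x", preset, "-t", str(threads), "--secondary=no",
           "-o", str(out_paf), str(reference_fasta), str(reads_fastq)]
    subprocess.run(cmd, check=True, capture_output=True, text=True)
    return out_paf


def blast_organelle_hits(organelle_fasta, assembly_fasta, workdir, source_tag: str):
    """Align an organelle genome against the assembly and return normalized
    hits tagged with ``source_tag``."""
    out = Path(workdir) / f"{source_tag}_vs_assembly.tsv"
    run_blastn(organelle_fasta, assembly_fasta, out)
    return read_alignments(out, "blast_tab", source_tag)


def map_reads(assembly_fasta, reads_fastq, workdir):
    """Map reads to the assembly and return normalized PAF hits."""
    out = Path(workdir) / "reads_vs_assembly.paf"
    run_minimap2(assembly_fasta, reads_fastq, out)
    return read_alignments(out, "paf", "read")
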