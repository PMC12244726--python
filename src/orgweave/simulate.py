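"""Deterministic synthetic genomes with planted, machine-readable truth.

The generator emulates the data shape of a HiFi plant-genome curation run:
Mb-scale nuclear contigs carrying planted organelle insertions (including
tandem mixed insertions and plastid-genes-in-the-mitogenome ambiguity),
terminal TTTAGGG telomere tracts, satellite and rDNA-like tandem arrays,
contigs made only of simple repeats, organelle-derived contigs, and long
reads with organelle sequence at far higher depth than nuclear sequence.

Randomness comes from one seeded NumPy generator per top-level operation
(streams: 0 = organelle genomes, 1 = nuclear assembly, 2 = reads), so a
given seed + config is byte-identical across runs and platforms.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .io import write_bed, write_fasta, write_fastq
from .models import RnaGeneHit, SequenceRecord

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTN", b"TGCAN"):
    _COMP[a] = b
_BASE_INDEX = np.zeros(256, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i

TELOMERE_MOTIF = "TTTAGGG"
DEFAULT_SATELLITE_UNIT = "ACGGTCATTGAACCTGGGTTCGAAGCCATGACGTTA"  # fixed 36-mer


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic genome set.

    Defaults mirror the real data this generator stands in for: ~27x
    nuclear HiFi depth with organelle sequence hundreds-fold deeper,
    200-5000 bp organelle insertions at ~5% divergence, plastid gene
    blocks copied into the mitogenome, 36 bp satellite units, ~11.4 kb
    rDNA repeat units, and TTTAGGG telomere tracts.
    """

    seed: int = 42
    n_contigs: int = 10
    contig_length: int = 500_000
    plastome_length: int = 150_000
    mitome_length: int = 300_000
    n_numt: int = 40
    n_nupt: int = 30
    n_numpt: int = 10
    n_num_pt: int = 10  # ambiguous transfers (NUM/PT)
    n_numpt_broken: int = 0  # tandem M+P with gap >= 300 bp (negative control)
    insert_length_range: tuple[int, int] = (200, 5_000)
    insert_divergence: float = 0.05
    shared_gene_blocks: int = 5
    shared_block_length_range: tuple[int, int] = (2_000, 6_000)
    telomere_plan: Optional[dict] = None  # contig_id -> {both,left,right,none}
    telomere_copies: int = 120
    satellite_unit: str = DEFAULT_SATELLITE_UNIT
    n_satellite_arrays: int = 2
    satellite_copies: int = 300
    rdna_unit_lengths: tuple[int, ...] = (11_400,)
    rdna_copies: int = 30
    rdna_linked_5s: bool = False
    five_s_copies: int = 100
    n_repeat_only_contigs: int = 2
    n_organelle_contigs: int = 2
    nuclear_depth: float = 27.0
    organelle_depth: float = 500.0
    read_length_mean: int = 15_000
    read_length_sd: int = 1_500
    read_error_rate: float = 0.002

    def validate(self) -> None:
        counts = (
            self.n_contigs, self.n_numt, self.n_nupt, self.n_numpt, self.n_num_pt,
            self.n_numpt_broken, self.shared_gene_blocks, self.n_repeat_only_contigs,
            self.n_organelle_contigs,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if not (0 <= self.insert_divergence < 0.5):
            raise ValueError("insert_divergence must lie in [0, 0.5)")
        if min(self.plastome_length, self.mitome_length) < 10_000:
            raise ValueError("organelle genomes must be >= 10 kb")


@dataclass
class TruthRow:
    feature_type: str
    contig_id: str
    start: int
    end: int
    payload: dict = field(default_factory=dict)


@dataclass
class TruthTable:
    rows: list[TruthRow] = field(default_factory=list)

    def add(self, feature_type, contig_id, start, end, **payload) -> None:
        self.rows.append(TruthRow(feature_type, contig_id, start, end, payload))

    def of(self, *feature_types: str) -> list[TruthRow]:
        return [r for r in self.rows if r.feature_type in feature_types]

    def count(self, feature_type: str) -> int:
        return len(self.of(feature_type))


# ---------------------------------------------------------------------------
# sequence helpers


def _random_dna(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute bases at ``rate`` (always to a different base)."""
    out = seq.copy()
    if rate <= 0 or len(out) == 0:
        return out
    n_mut = rng.binomial(len(out), rate)
    if n_mut == 0:
        return out
    pos = rng.choice(len(out), size=n_mut, replace=False)
    shift = rng.integers(1, 4, size=n_mut)
    out[pos] = _BASES[(_BASE_INDEX[out[pos]] + shift) % 4]
    return out


def _revcomp(seq: np.ndarray) -> np.ndarray:
    return _COMP[seq[::-1]]


def _to_str(seq: np.ndarray) -> str:
    return seq.tobytes().decode("ascii")


def _from_str(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8).copy()


class _Allocator:
    """Non-overlapping interval placement on one contig with a safety margin."""

    def __init__(self, length: int):
        self.length = length
        self.occupied: list[tuple[int, int]] = []

    def reserve(self, start: int, end: int) -> None:
        self.occupied.append((start, end))

    def place(self, rng: np.random.Generator, length: int, margin: int = 2_000, tries: int = 300) -> int:
        if length >= self.length:
            raise ValueError("feature longer than contig")
        for _ in range(tries):
            start = int(rng.integers(0, self.length - length))
            if not any(start - margin < e and s < start + length + margin for s, e in self.occupied):
                self.reserve(start, start + length)
                return start
        raise RuntimeError(f"could not place a {length} bp feature on a congested contig")


def _sample_interval(
    rng: np.random.Generator, genome_len: int, length: int, forbidden: list[tuple[int, int]],
    margin: int = 300, tries: int = 300,
) -> int:
    """Pick a source interval avoiding ``forbidden`` regions (e.g. shared blocks)."""
    for _ in range(tries):
        start = int(rng.integers(0, genome_len - length))
        if not any(start - margin < e and s < start + length + margin for s, e in forbidden):
            return start
    raise RuntimeError("could not sample a source interval outside forbidden regions")


# ---------------------------------------------------------------------------
# organelle genomes


def make_organelle_genomes(config: SimulationConfig):
    """Random plastome and mitogenome plus plastid blocks copied into the
    mitogenome (at <= 1% divergence) to create NUM/PT-style ambiguity.

    Returns (plastome, mitome, shared_blocks) where each shared block maps
    a plastome interval onto the mitome interval that carries its copy.
    """
    config.validate()
    if config.shared_gene_blocks * config.shared_block_length_range[1] > config.plastome_length:
        raise ValueError("shared gene blocks do not fit in the plastome")
    rng = np.random.default_rng([config.seed, 0])
    plastome = _random_dna(rng, config.plastome_length)
    mitome = _random_dna(rng, config.mitome_length)

    shared_blocks: list[dict] = []
    p_occupied: list[tuple[int, int]] = []
    m_occupied: list[tuple[int, int]] = []
    for _ in range(config.shared_gene_blocks):
        block_len = int(rng.integers(*config.shared_block_length_range))
        p_start = _sample_interval(rng, config.plastome_length, block_len, p_occupied)
        m_start = _sample_interval(rng, config.mitome_length, block_len, m_occupied)
        p_occupied.append((p_start, p_start + block_len))
        m_occupied.append((m_start, m_start + block_len))
        mitome[m_start : m_start + block_len] = _mutate(
            plastome[p_start : p_start + block_len], 0.005, rng
        )
        shared_blocks.append(
            {"p_start": p_start, "p_end": p_start + block_len,
             "m_start": m_start, "m_end": m_start + block_len}
        )
    return (
        SequenceRecord("plastome", _to_str(plastome)),
        SequenceRecord("mitome", _to_str(mitome)),
        shared_blocks,
    )


# ---------------------------------------------------------------------------
# nuclear assembly


def _default_telomere_plan(contig_ids: list[str]) -> dict:
    cycle = ["both", "left", "right", "none"]
    return {cid: cycle[i % 4] for i, cid in enumerate(contig_ids)}


def make_nuclear_assembly(config, plastome, mitome, shared_blocks):
    """Plant all truth features into a synthetic nuclear assembly.

    Returns (contigs, truth): the contig list covers core nuclear contigs,
    an rDNA-array contig, repeat-only contigs and organelle-derived contigs;
    the truth table records every planted feature with source coordinates.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    truth = TruthTable()
    pl = _from_str(plastome.sequence)
    mt = _from_str(mitome.sequence)
    p_shared = [(b["p_start"], b["p_end"]) for b in shared_blocks]
    m_shared = [(b["m_start"], b["m_end"]) for b in shared_blocks]

    core_ids = [f"ctg{i + 1:02d}" for i in range(config.n_contigs)]
    plan = config.telomere_plan or _default_telomere_plan(core_ids)
    contigs_arr = {cid: _random_dna(rng, config.contig_length) for cid in core_ids}
    allocs = {cid: _Allocator(config.contig_length) for cid in core_ids}

    tel_len = 7 * config.telomere_copies
    for cid in core_ids:
        p = plan.get(cid, "none")
        if p in ("both", "left"):
            tract = _from_str(TELOMERE_MOTIF * config.telomere_copies)
            contigs_arr[cid][:tel_len] = tract
            allocs[cid].reserve(0, tel_len)
            truth.add("telomere_left", cid, 0, tel_len, copies=config.telomere_copies)
        else:
            allocs[cid].reserve(0, tel_len)  # keep termini clean either way
        if p in ("both", "right"):
            tract = _from_str(("CCCTAAA") * config.telomere_copies)
            contigs_arr[cid][-tel_len:] = tract
            allocs[cid].reserve(config.contig_length - tel_len, config.contig_length)
            truth.add("telomere_right", cid, config.contig_length - tel_len,
                      config.contig_length, copies=config.telomere_copies)
        else:
            allocs[cid].reserve(config.contig_length - tel_len, config.contig_length)
        truth.add("telomere_plan", cid, 0, config.contig_length, plan=p)

    # --- organelle -> nuclear transfers ----------------------------------
    jobs = (
        ["NUMT"] * config.n_numt + ["NUPT"] * config.n_nupt
        + ["NUMPT"] * config.n_numpt + ["NUM_PT"] * config.n_num_pt
        + ["NUMPT_BROKEN"] * config.n_numpt_broken
    )
    lo, hi = config.insert_length_range

    def draw_segment(genome: np.ndarray, forbidden) -> tuple[np.ndarray, int, int, str]:
        seg_len = int(rng.integers(lo, hi + 1))
        src = _sample_interval(rng, len(genome), seg_len, forbidden)
        seq = _mutate(genome[src : src + seg_len], config.insert_divergence, rng)
        strand = "+"
        if rng.random() < 0.5:
            seq = _revcomp(seq)
            strand = "-"
        return seq, src, src + seg_len, strand

    for i, kind in enumerate(jobs):
        cid = core_ids[i % len(core_ids)]
        if kind == "NUMT":
            seq, s, e, strand = draw_segment(mt, m_shared)
            pos = allocs[cid].place(rng, len(seq))
            contigs_arr[cid][pos : pos + len(seq)] = seq
            truth.add("NUMT", cid, pos, pos + len(seq),
                      source="mito", src_start=s, src_end=e, strand=strand)
        elif kind == "NUPT":
            seq, s, e, strand = draw_segment(pl, p_shared)
            pos = allocs[cid].place(rng, len(seq))
            contigs_arr[cid][pos : pos + len(seq)] = seq
            truth.add("NUPT", cid, pos, pos + len(seq),
                      source="plastid", src_start=s, src_end=e, strand=strand)
        elif kind == "NUM_PT":
            block = shared_blocks[int(rng.integers(len(shared_blocks)))]
            block_len = block["p_end"] - block["p_start"]
            seg_len = int(rng.integers(lo, min(hi, block_len) + 1))
            off = int(rng.integers(0, block_len - seg_len + 1))
            seq = _mutate(pl[block["p_start"] + off : block["p_start"] + off + seg_len],
                          config.insert_divergence, rng)
            pos = allocs[cid].place(rng, len(seq))
            contigs_arr[cid][pos : pos + len(seq)] = seq
            truth.add("NUM_PT", cid, pos, pos + len(seq),
                      source="shared", src_start=block["p_start"] + off,
                      src_end=block["p_start"] + off + seg_len, strand="+")
        else:  # NUMPT, broken or not
            gap = int(rng.integers(0, 300)) if kind == "NUMPT" else int(rng.integers(300, 1001))
            m_seq, ms, me, m_strand = draw_segment(mt, m_shared)
            p_seq, ps, pe, p_strand = draw_segment(pl, p_shared)
            gap_seq = _random_dna(rng, gap)
            insert = np.concatenate([m_seq, gap_seq, p_seq])
            pos = allocs[cid].place(rng, len(insert))
            contigs_arr[cid][pos : pos + len(insert)] = insert
            feature = "NUMPT" if kind == "NUMPT" else "numpt_broken"
            truth.add(feature, cid, pos, pos + len(insert),
                      gap=gap,
                      mito_part=[pos, pos + len(m_seq)], mito_src=[ms, me], mito_strand=m_strand,
                      plastid_part=[pos + len(m_seq) + gap, pos + len(insert)],
                      plastid_src=[ps, pe], plastid_strand=p_strand)

    # --- satellite arrays on core contigs ---------------------------------
    unit = config.satellite_unit.upper()
    for i in range(config.n_satellite_arrays):
        cid = core_ids[i % len(core_ids)]
        arr = _from_str(unit * config.satellite_copies)
        pos = allocs[cid].place(rng, len(arr))
        contigs_arr[cid][pos : pos + len(arr)] = arr
        truth.add("satellite_array", cid, pos, pos + len(arr),
                  unit=unit, copies=config.satellite_copies)

    contigs = [SequenceRecord(cid, _to_str(contigs_arr[cid])) for cid in core_ids]

    # --- dedicated rDNA-array contig --------------------------------------
    if config.rdna_copies > 0:
        contigs.append(_build_rdna_contig(config, rng, truth))

    # --- repeat-only contigs ----------------------------------------------
    rep_len = max(len(unit) * 50, config.contig_length // 5)
    for i in range(config.n_repeat_only_contigs):
        cid = f"ctg_rep{i + 1}"
        n_copies = rep_len // len(unit)
        seq = (unit * n_copies)[:rep_len]
        contigs.append(SequenceRecord(cid, seq))
        truth.add("repeat_only_contig", cid, 0, len(seq), unit=unit, copies=n_copies)

    # --- organelle-derived contigs ----------------------------------------
    organelle_sources = [("ctg_mito", mt, "mito"), ("ctg_plastid", pl, "plastid")]
    for cid, genome, source in organelle_sources[: config.n_organelle_contigs]:
        seq = _mutate(genome, 0.001, rng)
        contigs.append(SequenceRecord(cid, _to_str(seq)))
        truth.add("organelle_contig", cid, 0, len(seq), source=source)

    return contigs, truth


def _build_rdna_contig(config, rng, truth) -> SequenceRecord:
    """One contig carrying a 35S-like tandem array (18S-5.8S-26S + IGS per
    unit) and, unless the linked layout is requested, a separate 5S array."""
    g18 = _random_dna(rng, 1810)
    g58 = _random_dna(rng, 160)
    g26 = _random_dna(rng, 3390)
    g5s = _random_dna(rng, 120)
    its1 = _random_dna(rng, 250)
    its2 = _random_dna(rng, 230)
    body_len = len(g18) + len(its1) + len(g58) + len(its2) + len(g26)  # 5840

    unit_lengths = []
    for i in range(config.rdna_copies):
        base = config.rdna_unit_lengths[i % len(config.rdna_unit_lengths)]
        unit_lengths.append(max(body_len + 300, base + int(rng.integers(-50, 51))))

    cid = "ctg_rdna"
    left_flank = 50_000
    array_len = sum(unit_lengths)
    gene_hits: list[RnaGeneHit] = []
    five_s_hits: list[RnaGeneHit] = []
    parts = [_random_dna(rng, left_flank)]
    offset = left_flank
    for unit_len in unit_lengths:
        unit = np.empty(unit_len, dtype=np.uint8)
        cursor = 0
        for gene, seq in (("18S", g18), ("ITS1", its1), ("5.8S", g58), ("ITS2", its2), ("26S", g26)):
            copy = _mutate(seq, 0.002, rng)
            unit[cursor : cursor + len(copy)] = copy
            if gene in ("18S", "5.8S", "26S"):
                gene_hits.append(RnaGeneHit(cid, offset + cursor, offset + cursor + len(copy), "+", gene))
            cursor += len(copy)
        igs = _random_dna(rng, unit_len - cursor)
        if config.rdna_linked_5s and len(igs) > 1_200:
            copy5 = _mutate(g5s, 0.002, rng)
            igs[1_000 : 1_000 + len(copy5)] = copy5
            five_s_hits.append(RnaGeneHit(cid, offset + cursor + 1_000,
                                          offset + cursor + 1_000 + len(copy5), "+", "5S"))
        unit[cursor:] = igs
        parts.append(unit)
        offset += unit_len

    array_start, array_end = left_flank, left_flank + array_len
    contig_len = max(config.contig_length, array_end + 150_000)
    mid_flank_len = 60_000
    parts.append(_random_dna(rng, mid_flank_len))
    offset += mid_flank_len

    if not config.rdna_linked_5s and config.five_s_copies > 0:
        unit5_spacer = _random_dna(rng, 190)
        five_start = offset
        for _ in range(config.five_s_copies):
            copy5 = _mutate(g5s, 0.002, rng)
            parts.append(copy5)
            five_s_hits.append(RnaGeneHit(cid, offset, offset + len(copy5), "+", "5S"))
            offset += len(copy5)
            parts.append(unit5_spacer.copy())
            offset += len(unit5_spacer)
        truth.add("rdna_5s", cid, five_start, offset,
                  copies=config.five_s_copies, unit_length=len(g5s) + len(unit5_spacer))

    parts.append(_random_dna(rng, max(0, contig_len - offset)))
    seq = np.concatenate(parts)
    truth.add("rdna_array", cid, array_start, array_end,
              unit_lengths=unit_lengths, copies=config.rdna_copies,
              gene_hits=[[h.gene, h.start, h.end, h.strand] for h in gene_hits],
              five_s_hits=[[h.gene, h.start, h.end, h.strand] for h in five_s_hits])
    return SequenceRecord(cid, _to_str(seq))


def rrna_hits_from_truth(truth: TruthTable) -> list[RnaGeneHit]:
    """Recover the planted rRNA gene hit table (the fixture's stand-in for a
    homology search)."""
    hits = []
    for row in truth.of("rdna_array"):
        for gene, start, end, strand in row.payload["gene_hits"]:
            hits.append(RnaGeneHit(row.contig_id, start, end, strand, gene))
        for gene, start, end, strand in row.payload.get("five_s_hits", []):
            hits.append(RnaGeneHit(row.contig_id, start, end, strand, gene))
    return hits


# ---------------------------------------------------------------------------
# long reads


def simulate_long_reads(nuclear_contigs, plastome, mitome, config):
    """Sample reads uniformly per source: each nuclear contig at
    ``nuclear_depth`` and each organelle genome at ``organelle_depth``.

    Substitution errors at ``read_error_rate``; read names encode source
    and coordinates (``rd<i>|<source>|<start>-<end>|<strand>``).
    """
    rng = np.random.default_rng([config.seed, 2])
    sources = [(rec.id, _from_str(rec.sequence), config.nuclear_depth) for rec in nuclear_contigs]
    sources.append((plastome.id, _from_str(plastome.sequence), config.organelle_depth))
    sources.append((mitome.id, _from_str(mitome.sequence), config.organelle_depth))

    reads: list[tuple[str, str]] = []
    idx = 0
    for src_id, genome, depth in sources:
        L = len(genome)
        target = depth * L
        sampled = 0
        truncated_warned = False
        while sampled < target:
            length = int(np.clip(rng.normal(config.read_length_mean, config.read_length_sd),
                                 1_000, 4 * config.read_length_mean))
            if length > L:
                if not truncated_warned:
                    logger.warning("read length truncated to %d on short source %s", L, src_id)
                    truncated_warned = True
                length = L
            start = int(rng.integers(0, L - length + 1))
            seq = _mutate(genome[start : start + length], config.read_error_rate, rng)
            strand = "+"
            if rng.random() < 0.5:
                seq = _revcomp(seq)
                strand = "-"
            reads.append((f"rd{idx}|{src_id}|{start}-{start + length}|{strand}", _to_str(seq)))
            sampled += length
            idx += 1
    return reads


# ---------------------------------------------------------------------------
# truth output and one-call dataset


def write_truth(truth: TruthTable, bed_path, tsv_path) -> None:
    """Write the truth table as BED intervals plus a TSV with JSON payloads,
    in deterministic (contig, start, end, feature) order."""
    rows = sorted(truth.rows, key=lambda r: (r.contig_id, r.start, r.end, r.feature_type))
    write_bed([(r.contig_id, r.start, r.end, r.feature_type) for r in rows], bed_path)
    with open(tsv_path, "w") as fh:
        fh.write("feature_type\tcontig\tstart\tend\tpayload\n")
        for r in rows:
            fh.write(f"{r.feature_type}\t{r.contig_id}\t{r.start}\t{r.end}\t"
                     f"{json.dumps(r.payload, sort_keys=True)}\n")


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    plastome: SequenceRecord
    mitome: SequenceRecord
    shared_blocks: list
    contigs: list  # full assembly, organelle/repeat contigs included
    truth: TruthTable

    @property
    def nuclear_contigs(self):
        organelle = {r.contig_id for r in self.truth.of("organelle_contig")}
        return [c for c in self.contigs if c.id not in organelle]

    @property
    def core_contigs(self):
        special = {r.contig_id for r in self.truth.of("organelle_contig", "repeat_only_contig")}
        return [c for c in self.contigs if c.id not in special]


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate organelle genomes plus the planted nuclear assembly."""
    plastome, mitome, shared_blocks = make_organelle_genomes(config)
    contigs, truth = make_nuclear_assembly(config, plastome, mitome, shared_blocks)
    return SimulatedDataset(config, plastome, mitome, shared_blocks, contigs, truth)


def write_dataset(dataset: SimulatedDataset, outdir, with_reads: bool = True) -> dict:
    """Write genomes.fasta, plastome/mitome FASTA, reads.fastq, truth files
    and the resolved config; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "assembly": outdir / "genomes.fasta",
        "plastome": outdir / "plastome.fasta",
        "mitome": outdir / "mitome.fasta",
        "truth_bed": outdir / "truth.bed",
        "truth_tsv": outdir / "truth.tsv",
        "config": outdir / "config.json",
    }
    write_fasta(dataset.contigs, paths["assembly"])
    write_fasta([dataset.plastome], paths["plastome"])
    write_fasta([dataset.mitome], paths["mitome"])
    write_truth(dataset.truth, paths["truth_bed"], paths["truth_tsv"])
    cfg = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in vars(dataset.config).items()}
    paths["config"].write_text(json.dumps(cfg, indent=2, sort_keys=True))
    if with_reads:
        reads = simulate_long_reads(dataset.nuclear_contigs, dataset.plastome,
                                    dataset.mitome, dataset.config)
        paths["reads"] = outdir / "reads.fastq"
        write_fastq(reads, paths["reads"])
    return paths
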