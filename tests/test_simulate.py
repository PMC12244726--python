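import numpy as np
import pytest

import edlib

from orgweave.qc import revcomp
from orgweave.simulate import (SimulationConfig, make_organelle_genomes,
                               simulate_dataset, simulate_long_reads)

SMALL = dict(
    n_contigs=3, contig_length=100_000, plastome_length=30_000, mitome_length=50_000,
    n_numt=5, n_nupt=4, n_numpt=2, n_num_pt=2, shared_gene_blocks=3,
    shared_block_length_range=(1_500, 3_000), insert_length_range=(200, 2_000),
    rdna_copies=4, five_s_copies=5, satellite_copies=50, read_length_mean=4_000,
    read_length_sd=400, nuclear_depth=5.0, organelle_depth=50.0,
)


def small_config(seed=7, **overrides):
    return SimulationConfig(seed=seed, **{**SMALL, **overrides})


def identity(a: str, b: str) -> float:
    """Edit-distance identity between equal-role sequences (independent of
    the generator's own bookkeeping)."""
    res = edlib.align(a, b, mode="NW")
    return 1.0 - res["editDistance"] / max(len(a), len(b))


class TestDeterminism:
    def test_same_seed_gives_byte_identical_outputs(self):
        ds1 = simulate_dataset(small_config())
        ds2 = simulate_dataset(small_config())
        assert [c.sequence for c in ds1.contigs] == [c.sequence for c in ds2.contigs]
        assert ds1.plastome.sequence == ds2.plastome.sequence
        r1 = simulate_long_reads(ds1.nuclear_contigs, ds1.plastome, ds1.mitome, ds1.config)
        r2 = simulate_long_reads(ds2.nuclear_contigs, ds2.plastome, ds2.mitome, ds2.config)
        assert r1 == r2

    def test_different_seeds_differ(self):
        assert simulate_dataset(small_config(seed=1)).contigs[0].sequence != \
               simulate_dataset(small_config(seed=2)).contigs[0].sequence


class TestOrganelleGenomes:
    def test_shared_blocks_align_at_high_identity(self):
        cfg = small_config()
        plastome, mitome, blocks = make_organelle_genomes(cfg)
        assert len(blocks) == cfg.shared_gene_blocks
        for b in blocks:
            p_seg = plastome.sequence[b["p_start"]:b["p_end"]]
            m_seg = mitome.sequence[b["m_start"]:b["m_end"]]
            assert identity(p_seg, m_seg) >= 0.99

    def test_no_shared_blocks_means_no_cross_homology(self, tmp_path):
        """With zero shared blocks, no mitome window of >= 200 bp should align
        to the plastome at >= 85% identity (blastn as the oracle)."""
        from orgweave.align import run_blastn
        from orgweave.io import read_alignments, write_fasta
        cfg = small_config(shared_gene_blocks=0, plastome_length=15_000, mitome_length=15_000)
        plastome, mitome, blocks = make_organelle_genomes(cfg)
        assert blocks == []
        write_fasta([plastome], tmp_path / "p.fa")
        write_fasta([mitome], tmp_path / "m.fa")
        run_blastn(tmp_path / "m.fa", tmp_path / "p.fa", tmp_path / "hits.tsv")
        hits = read_alignments(tmp_path / "hits.tsv", "blast_tab", "other")
        assert not [h for h in hits if h.alignment_length >= 200 and h.percent_identity >= 85]

    def test_blocks_must_fit_in_plastome(self):
        cfg = small_config(shared_gene_blocks=50)
        with pytest.raises(ValueError, match="shared gene blocks"):
            make_organelle_genomes(cfg)

    def test_divergence_outside_range_rejected(self):
        with pytest.raises(ValueError):
            simulate_dataset(small_config(insert_divergence=0.6))


class TestPlantedFeatures:
    def test_truth_row_counts_match_config(self):
        cfg = small_config()
        ds = simulate_dataset(cfg)
        assert ds.truth.count("NUMT") == cfg.n_numt
        assert ds.truth.count("NUPT") == cfg.n_nupt
        assert ds.truth.count("NUMPT") == cfg.n_numpt
        assert ds.truth.count("NUM_PT") == cfg.n_num_pt
        assert ds.truth.count("repeat_only_contig") == cfg.n_repeat_only_contigs
        assert ds.truth.count("organelle_contig") == cfg.n_organelle_contigs

    def test_planted_nupt_aligns_back_to_plastome(self):
        cfg = small_config()
        ds = simulate_dataset(cfg)
        contigs = {c.id: c.sequence for c in ds.contigs}
        for row in ds.truth.of("NUPT"):
            planted = contigs[row.contig_id][row.start:row.end]
            if row.payload["strand"] == "-":
                planted = revcomp(planted)
            src = ds.plastome.sequence[row.payload["src_start"]:row.payload["src_end"]]
            assert identity(planted, src) >= 1.0 - cfg.insert_divergence - 0.02

    def test_telomere_tracts_are_exact_at_planned_termini(self):
        ds = simulate_dataset(small_config())
        seq = {c.id: c.sequence for c in ds.contigs}
        plans = {r.contig_id: r.payload["plan"] for r in ds.truth.of("telomere_plan")}
        both = [cid for cid, p in plans.items() if p == "both"]
        assert both, "default plan should give at least one both-telomere contig"
        for cid in both:
            assert seq[cid].startswith("TTTAGGG" * 120)
            assert seq[cid].endswith("CCCTAAA" * 120)

    def test_planted_intervals_do_not_overlap(self):
        ds = simulate_dataset(small_config())
        by_contig = {}
        for r in ds.truth.of("NUMT", "NUPT", "NUMPT", "NUM_PT", "satellite_array",
                             "telomere_left", "telomere_right"):
            by_contig.setdefault(r.contig_id, []).append((r.start, r.end))
        for intervals in by_contig.values():
            intervals.sort()
            for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
                assert e1 <= s2


class TestReads:
    def test_zero_error_reads_are_exact_substrings(self):
        cfg = small_config(read_error_rate=0.0, nuclear_depth=0.5, organelle_depth=2.0)
        ds = simulate_dataset(cfg)
        reads = simulate_long_reads(ds.nuclear_contigs, ds.plastome, ds.mitome, cfg)
        sources = {c.id: c.sequence for c in ds.nuclear_contigs}
        sources["plastome"] = ds.plastome.sequence
        sources["mitome"] = ds.mitome.sequence
        for name, seq in reads[:50]:
            src = name.split("|")[1]
            assert seq in sources[src] or revcomp(seq) in sources[src]

    def test_realized_depths_match_configuration(self):
        cfg = small_config()
        ds = simulate_dataset(cfg)
        reads = simulate_long_reads(ds.nuclear_contigs, ds.plastome, ds.mitome, cfg)
        nuclear_ids = {c.id for c in ds.nuclear_contigs}
        nuclear_bases = organelle_bases = 0
        for name, seq in reads:
            src = name.split("|")[1]
            if src in nuclear_ids:
                nuclear_bases += len(seq)
            else:
                organelle_bases += len(seq)
        nuclear_size = sum(c.length for c in ds.nuclear_contigs)
        organelle_size = ds.plastome.length + ds.mitome.length
        realized_nuclear = nuclear_bases / nuclear_size
        realized_org = organelle_bases / organelle_size
        assert realized_nuclear == pytest.approx(cfg.nuclear_depth, rel=0.10)
        ratio = realized_org / realized_nuclear
        assert ratio == pytest.approx(cfg.organelle_depth / cfg.nuclear_depth, rel=0.15)

    def test_read_longer_than_source_is_truncated(self):
        cfg = small_config(read_length_mean=40_000, read_length_sd=0,
                           nuclear_depth=0.1, organelle_depth=0.1)
        ds = simulate_dataset(cfg)
        reads = simulate_long_reads(ds.nuclear_contigs[:1], ds.plastome, ds.mitome, cfg)
        assert all(len(seq) <= 50_000 for _, seq in reads)


class TestTruthOutput:
    def test_truth_bed_round_trip(self, tmp_path):
        from orgweave.io import read_bed
        from orgweave.simulate import write_truth
        ds = simulate_dataset(small_config())
        write_truth(ds.truth, tmp_path / "t.bed", tmp_path / "t.tsv")
        back = read_bed(tmp_path / "t.bed")
        assert len(back) == len(ds.truth.rows)
        expected = sorted((r.contig_id, r.start, r.end, r.feature_type) for r in ds.truth.rows)
        assert sorted(back) == expected
        n_tsv_rows = len((tmp_path / "t.tsv").read_text().strip().splitlines()) - 1
        assert n_tsv_rows == len(ds.truth.rows)

    def test_numt_bed_line_convention(self, tmp_path):
        from orgweave.simulate import TruthTable, write_truth
        truth = TruthTable()
        truth.add("NUMT", "c1", 10_000, 12_000)
        write_truth(truth, tmp_path / "t.bed", tmp_path / "t.tsv")
        assert (tmp_path / "t.bed").read_text() == "c1\t10000\t12000\tNUMT\n"
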