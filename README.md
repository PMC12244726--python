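# orgweave

Genome-curation toolkit for long-read (HiFi) plant assemblies: detection and
validation of organelle-to-nuclear DNA transfers, assembly QC screens,
annotation-hygiene filters, tandem/rDNA array profiling, and
contig-to-scaffold relationship classification. Every stage is exercisable
end to end on deterministic synthetic genomes with planted, machine-readable
truth — no data download required.

## Who this is for

Anyone curating a plant genome assembled from long reads faces the same
bespoke chores: nuclear copies of organelle DNA must be annotated (and
distinguished from genuine organelle contigs left in the assembly), contigs
made only of simple repeats must be dropped, telomeres counted, rDNA arrays
characterized, and predicted genes cleaned of transposon ORFs. These steps
are usually one-off scripts; `orgweave` packages them as a tested library
with a thin CLI.

## The rules at the core

**Organelle transfers.** The mitogenome (M) and plastome (P) are aligned
against each nuclear contig. Hits are kept when alignment length > 100 bp
and percent identity ≥ 85. Overlapping same-source hits are collapsed; an
M segment and a P segment with reciprocal overlap ≥ 0.5 (intersection over
the shorter) become a single *ambiguous* segment — these arise from plastid
genes that also reside in the mitogenome. Segments separated by < 300 bp
are merged into one region, across sources. A region is then classified by
its set of unambiguous sources:

| sources | category | meaning |
|---|---|---|
| {M} | NUMT | nuclear copy of mitochondrial DNA |
| {P} | NUPT | nuclear copy of plastid DNA |
| {M, P} | NUMPT | mitochondrial + plastid segments in tandem |
| only ambiguous | NUM/PT | source cannot be distinguished |

Each region boundary is *validated* when at least one long-read alignment
spans ≥ 50 bp on both sides of the junction — insertions whose borders
coincide with read ends are assembly-artifact suspects.

**QC screens.** A contig is *low-complexity* when its normalized k-mer
Shannon entropy H = −Σ pᵢ log₂ pᵢ / log₂(min(4ᵏ, n)) falls below 0.5
(k = 21). A contig is *organelle-derived* when its mean read depth exceeds
5× the assembly-wide median **and** ≥ 50% of it is covered by
organelle-genome hits. Telomeres are counted as non-overlapping exact
TTTAGGG (or reverse-complement) matches in 10 kb terminal windows; ≥ 25
copies marks a telomeric terminus, giving a
both/left-only/right-only/none completeness class per contig.

**Annotation hygiene.** A gene is a transposon candidate when strictly more
than half of its Pfam domain descriptions match a fixed list of 14
transposon-related terms (case-insensitive substring). A gene with neither
external evidence nor a functional annotation is removed (conjunction). A
TE-library entry whose best Class I/II classification probability is < 0.5
is relabelled `unclassified`. An organelle gene whose mean-of-genus-means
or maximum percent alignment length is < 75% is flagged as a candidate
pseudogene.

**Repeat arrays.** rRNA gene hits < 20 kb apart are clustered into arrays;
unit length is the distribution of successive start-to-start distances of
the most frequent gene (modes from a 100 bp histogram), copy number its
occurrence count, and a 35S array is L-type when ≥ 50% of units have a 5S
gene within 5 kb (otherwise S-type, the separate arrangement).

**Comparison.** A reference scaffold is `one_to_one` when a single query
contig covers ≥ 80% of it; an `arm_pair` when two contigs cover the two
ends with an uncovered central gap (the signature of a chromosome split at
an unassembled repeat array); `complex` when ≥ 3 contigs are needed.
Candidate centromeric regions are windows whose off-diagonal self-alignment
coverage stands out at z > 2 — the "dot-plot rectangle" made quantitative.

## Worked example

```bash
orgweave simulate --seed 42 --outdir fx
minimap2 -x map-hifi --secondary=no -o fx/reads.paf fx/genomes.fasta fx/reads.fastq
blastn -task blastn -query fx/mitome.fasta  -subject fx/genomes.fasta -outfmt 6 >  fx/org.tsv
blastn -task blastn -query fx/plastome.fasta -subject fx/genomes.fasta -outfmt 6 >> fx/org.tsv
orgweave qc --assembly fx/genomes.fasta --reads-aln fx/reads.paf \
            --organelle-aln fx/org.tsv --out qc_out
orgweave transfers --assembly qc_out/passing.fasta \
                   --mito fx/mitome.fasta --plastid fx/plastome.fasta \
                   --reads-aln fx/reads.paf --out tr_out
cat tr_out/summary.tsv
```

On the default synthetic assembly (10 × 500 kb nuclear contigs with 40
NUMTs, 30 NUPTs, 10 NUMPTs and 10 NUM/PTs planted, plus an rDNA contig,
two repeat-only contigs and two organelle contigs) the QC step flags
4 contigs (2 low-complexity, 2 organelle-depth) and the transfer step
prints:

```
category  count  total_length
NUMT      40     89769
NUPT      30     80470
NUM_PT    10     22340
NUMPT     10     47176
```

i.e. every planted transfer is recovered in its true category, with every
junction validated by spanning reads (`left_validated=yes;right_validated=yes`
in `tr_out/transfers.gff3`).

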