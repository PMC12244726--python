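# Methods

This note records the models, parameter choices and numerical conventions
behind `orgweave`, and what the synthetic benchmark does and does not show.

## Coordinate and strand conventions

All internal coordinates are 0-based, half-open, with target (nuclear-axis)
coordinates ascending; the original query orientation is kept as a strand
flag. Conversions to/from 1-based inclusive conventions (BLAST outfmt 6,
TRF .dat, GFF3) happen only in `orgweave.io`, so interval arithmetic never
mixes conventions. Normalization is idempotent, and round trips preserve
interval lengths exactly (property-tested).

Ambiguity characters beyond N are coerced to N on input rather than
rejected: real assemblies legitimately contain IUPAC codes, and none of the
downstream statistics depend on them.

## Transfer detection

The detection rule set is deliberately literal about threshold semantics,
because off-by-one drift is the dominant failure mode of interval
pipelines:

| parameter | default | semantics |
|---|---|---|
| `min_hit_length` | 100 bp | keep hits **strictly longer** |
| `min_identity` | 85% | **inclusive** minimum |
| `max_merge_gap` | 300 bp | merge gaps **strictly smaller** |
| `min_junction_span` | 50 bp | **inclusive**, each side of a boundary |
| `ambiguity_reciprocal_overlap` | 0.5 | intersection / shorter segment |

Design choices that were genuinely open:

- **Cross-source merging.** Mito- and plastid-derived segments are merged
  jointly; the NUMPT category (M and P in tandem) can only arise that way.
- **Ambiguity operationalization.** "Cannot be distinguished" is made
  concrete as reciprocal overlap ≥ 0.5 between an M and a P segment; the
  pair is replaced by one ambiguous segment spanning their union. Regions
  mixing ambiguous with unambiguous segments classify by their unambiguous
  sources, so {M, A} → NUMT.
- **Region identity.** A merged region reports the maximum identity over
  supporting hits; identity is never re-filtered after merging.
- **Junction validation.** One spanning read per boundary suffices
  (configurable); boundaries with no overlapping read alignments at all are
  reported `untested` rather than failed, because absence of coverage is a
  different signal from a read end at the junction.
- The merge sweep (sorted by start, extending a running maximum end) is
  equivalent to the transitive closure of the pairwise gap-below-threshold
  relation; this equivalence is asserted against an O(n²) union-find oracle
  over 1,000 random segment sets.

Alignment itself is external (`blastn` for organelle-vs-nuclear,
`minimap2 map-hifi` for reads); the package consumes normalized hit
tables, so any aligner producing outfmt-6 or PAF can be substituted.
Output GFF3 records the category, source composition, best identity and
per-side validation status of each region.

## QC screens

**Entropy.** The low-complexity statistic is normalized k-mer entropy,
H/log₂(min(4ᵏ, n)) with n the number of k-mer windows, k = 21 and cutoff
0.5 (all configurable). 21-mers separate tandem simple repeats from unique
sequence sharply: a pure 36 bp-unit satellite contig has only 36 distinct
21-mers (score ≈ 0.3 at 100 kb), a random 500 kb contig scores ≈ 1.0, and
an rDNA-array contig with an 11.4 kb unit scores ≈ 0.9 — so array-bearing
nuclear contigs are not false positives. Normalizing by the number of
windows (when below 4ᵏ) makes the score length-independent. k-mers
containing N are excluded.

**Depth.** Mean depth is total aligned bases over contig length, using the
best-scoring alignment per read. The organelle screen is a conjunction:
depth > 5× the assembly-wide median **and** organelle-hit coverage ≥ 50% of
the contig. The homology condition mirrors the manual BLAST confirmation a
curator would do; depth alone also fires on collapsed repeats, which must
not be discarded as organelle contamination. Curators often call these
contigs by eyeballing a sorted depth report; the median-fold rule is a
reproducible replacement for that inspection, and the 5×/50% defaults are
this package's own choices.

**Telomeres.** Exact, non-overlapping TTTAGGG counting per 10 kb window,
taking the better of the forward motif and its reverse complement at each
terminus; ≥ 25 copies calls a telomeric terminus. No degenerate-motif
search is attempted; the chance expectation for a 7-mer in a 10 kb window
is ≈ 0.6 copies, so the 25-copy cutoff is far from the noise floor.

## Annotation filters

The transposon majority rule is strict (> 0.5 of domains matched), term
matching is case-insensitive substring on the description only (the only
reading under which short terms like "gag" and "env" are usable), and
probability 0.5 exactly keeps a TE label ("less than 0.5" is strict). The
pseudogene rule flags when mean-of-genus-means **or** maximum percent
alignment length is below 75%; threshold and OR/AND sense are configurable
because the assignment is acknowledged as heuristic. Percent lengths are
computed against the query and clamped at 100 (gapped alignments can
exceed it). The majority rule is verified exhaustively against brute force
for all domain-count ≤ 8 × match-count combinations.

## Repeat and rDNA arrays

The internal tandem detector is exact-match only (position i vs i + p,
vectorized over periods), reporting maximal runs with the smallest
qualifying period and resolving overlaps by more copies, then smaller
period. Divergent satellites are Tandem Repeats Finder's job; its .dat
output is parsed by `io.read_trf_dat`.

rRNA gene locations are consumed as a hit table (from any homology tool,
or the synthetic truth); implementing an rRNA aligner is out of scope.
Unit length is estimated from successive start-to-start distances of the
most frequent gene label; modes come from a 100 bp histogram, one mode per
maximal run of bins above 20% of the peak (so jitter-induced plateaus do
not split a peak), each reported as the mean of its samples. Copy number is
the count of the most frequent gene label, with per-gene counts retained so
fragmentary units are visible as min/max disagreement. The 5S linkage call
uses a 5 kb window per unit and a 50% unit majority per array.

## Comparison module

Relationship thresholds (0.8 total coverage, 0.25 per arm, 0.05 mid-gap)
are package choices replacing a visual synteny-plot inspection; calls carry
their coverage evidence so borderline cases can be reviewed. Nucleotide
coverage is the sole evidence channel — gene-order synteny inference is
out of scope. The centromere screen computes off-diagonal self-alignment
coverage in 100 kb windows and flags z > 2 within each contig; a contig
whose self-alignment is only the trivial diagonal yields no candidates by
construction.

## Synthetic data generator

The generator emulates the study conditions of a HiFi plant-genome
curation run with defaults: 10 nuclear contigs × 500 kb; 150 kb plastome
and 300 kb mitogenome; 5 plastid blocks (2–6 kb) copied into the mitogenome
at 0.5% divergence (the source of NUM/PT ambiguity); 40/30/10/10
NUMT/NUPT/NUMPT/NUM-PT insertions of 200–5,000 bp at 5% divergence, NUMPT
internal gaps drawn < 300 bp so the category is detectable under the merge
rule (a config switch plants "broken" tandems with gaps ≥ 300 bp as a
negative control); 120-copy TTTAGGG tracts per a four-state terminal plan;
a 36 bp satellite unit in 300-copy arrays; a 30-copy rDNA-like array of
11.4 kb units (18S/5.8S/26S bodies plus an IGS, ± 50 bp jitter) and a
separate 100-copy 5S array; two contigs of pure satellite repeat at 100 kb
(one fifth of the nuclear contig length — long enough for a stable entropy
estimate, short enough to keep read simulation proportionate); and two
organelle-derived contigs. Reads average 15 kb with 0.2% substitution
error at 27× nuclear and 500× organelle depth. All sizes are roughly three
orders of magnitude below a real 1 Gb genome so the whole benchmark runs
in minutes on one CPU.

One seeded NumPy generator per top-level operation (organelle genomes,
assembly, reads) is consumed in a documented order, so a given seed +
config is byte-identical across runs. Background sequence is i.i.d.
uniform A/C/G/T — sufficient for threshold-rule testing, and it guarantees
no spurious ≥ 100 bp / ≥ 85% organelle homology outside planted intervals.

**What passing the benchmark does not show.** The generator has no GC
skew, heterozygosity, chimeric reads, realistic HiFi error profiles,
transposon evolution or nested/decayed ancient transfers. Recovery rates
on it are therefore an upper bound: they demonstrate the rules are
implemented exactly as specified, not that the thresholds are optimal for
diverged real transfers.

## Degenerate inputs and tie-breaks

Empty hit tables yield empty outputs and all-zero summaries, never errors.
A contig shorter than the telomere motif scans as zero counts with a
warning; reads longer than their source are truncated with a warning; TRF
rows with end ≤ start are skipped with a warning. Dominant-gene ties in an
rDNA array break deterministically (highest count, then lexicographic).
GFF3 output is ordered by (contig, start, end, type) so identical inputs
produce identical files.
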