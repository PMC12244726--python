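"""Tandem-repeat and rDNA array profiling.

Provides an exact-match tandem-run detector for short-period satellites
(divergent satellites are Tandem Repeats Finder's job, consumed through
``io.read_trf_dat``), clustering of rRNA gene hits into arrays, unit-length
and copy-number estimation, and the 5S-35S linkage (S-type vs L-type) call.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .models import RnaGeneHit, TandemRepeatRecord


@dataclass
class RdnaArray:
    contig_id: str
    start: int
    end: int
    gene_hits: list  # RnaGeneHit, sorted by start
    kind: str = "array"  # array | cluster (< 2 full-unit equivalents)
    unit_length_samples: list = field(default_factory=list)
    unit_length_modes: list = field(default_factory=list)
    copy_count: int = 0
    gene_counts: dict = field(default_factory=dict)
    arrangement: str = "na"  # S_type | L_type | mixed | na

    @property
    def dominant_gene(self) -> Optional[str]:
        counts = Counter(h.gene for h in self.gene_hits)
        if not counts:
            return None
        # deterministic tie-break: highest count, then lexicographic
        return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]


# ---------------------------------------------------------------------------
# exact tandem detection


def detect_tandem_runs(sequence: str, min_period: int = 2, max_period: int = 500,
                       min_copies: float = 5.0) -> list[TandemRepeatRecord]:
    """Find maximal exact tandem runs (position i equals position i + p).

    Runs are reported with the smallest qualifying period; overlapping runs
    of different periods are resolved in favor of more copies, then smaller
    period. Copy number is span / period and may be fractional.
    """
    seq = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    n = len(seq)
    candidates: list[tuple[float, int, int, int]] = []  # (copies, period, start, end)
    for p in range(min_period, min(max_period, n - 1) + 1):
        eq = seq[p:] == seq[:-p]
        if not eq.any():
            continue
        # maximal runs of True
        padded = np.concatenate(([False], eq, [False]))
        changes = np.flatnonzero(padded[1:] != padded[:-1])
        starts, ends = changes[::2], changes[1::2]
        for a, b in zip(starts, ends):
            span = (b - a) + p
            copies = span / p
            if copies >= min_copies:
                candidates.append((copies, p, int(a), int(a) + span))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    selected: list[TandemRepeatRecord] = []
    for copies, p, a, b in candidates:
        if any(a < r.end and r.start < b for r in selected):
            continue
        selected.append(TandemRepeatRecord("", a, b, p, round(copies, 2),
                                           sequence[a : a + p]))
    selected.sort(key=lambda r: r.start)
    return selected


# ---------------------------------------------------------------------------
# rDNA arrays


def cluster_gene_hits_into_arrays(gene_hits: Iterable[RnaGeneHit],
                                  max_gap: int = 20_000) -> list[RdnaArray]:
    """Join rRNA gene hits on one contig into an array while consecutive
    hits are less than ``max_gap`` apart. Clusters without at least two
    full-unit equivalents of some gene are labelled 'cluster', not 'array'."""
    by_contig: dict[str, list[RnaGeneHit]] = {}
    for h in gene_hits:
        by_contig.setdefault(h.contig_id, []).append(h)
    arrays: list[RdnaArray] = []
    for contig in sorted(by_contig):
        hits = sorted(by_contig[contig], key=lambda h: (h.start, h.end))
        group: list[RnaGeneHit] = []
        for h in hits:
            if group and h.start - group[-1].end >= max_gap:
                arrays.append(_finish_cluster(contig, group))
                group = []
            group.append(h)
        if group:
            arrays.append(_finish_cluster(contig, group))
    return arrays


def _finish_cluster(contig: str, hits: list[RnaGeneHit]) -> RdnaArray:
    counts = Counter(h.gene for h in hits)
    kind = "array" if max(counts.values()) >= 2 else "cluster"
    return RdnaArray(contig, hits[0].start, max(h.end for h in hits),
                     list(hits), kind=kind, gene_counts=dict(counts))


def estimate_unit_length(array: RdnaArray, bin_width: int = 100,
                         prominence: float = 0.2) -> RdnaArray:
    """Estimate repeat-unit lengths from successive start-to-start distances
    of the most frequent gene label.

    Modes are one per maximal run of histogram bins (``bin_width`` bp)
    whose count reaches ``prominence`` of the global maximum; each mode is
    the mean of the samples falling in that run, so a plateau of adjacent
    bins yields a single mode.
    """
    gene = array.dominant_gene
    starts = sorted(h.start for h in array.gene_hits if h.gene == gene)
    if len(starts) < 2:
        array.unit_length_samples = []
        array.unit_length_modes = []
        return array
    samples = np.diff(np.array(starts, dtype=np.int64))
    array.unit_length_samples = samples.tolist()
    lo = (int(samples.min()) // bin_width) * bin_width
    hi = int(samples.max()) + bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, _ = np.histogram(samples, bins=edges)
    threshold = prominence * counts.max()
    above = counts >= threshold
    modes = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            in_run = (samples >= edges[i]) & (samples < edges[j + 1])
            modes.append(float(samples[in_run].mean()))
            i = j + 1
        else:
            i += 1
    array.unit_length_modes = modes
    return array


def count_units(array: RdnaArray) -> int:
    """Copy count of an array: occurrences of the most frequent gene label
    (each full unit carries each gene once); per-gene counts are kept on
    the array for min/max reporting."""
    if not array.gene_hits:
        raise ValueError("cannot count units of an empty array")
    counts = Counter(h.gene for h in array.gene_hits)
    array.gene_counts = dict(counts)
    array.copy_count = max(counts.values())
    return array.copy_count


def _unit_intervals(array: RdnaArray) -> list[tuple[int, int]]:
    gene = array.dominant_gene
    starts = sorted(h.start for h in array.gene_hits if h.gene == gene)
    if not starts:
        return []
    bounds = starts + [max(array.end, starts[-1] + 1)]
    return [(bounds[i], bounds[i + 1]) for i in range(len(starts))]


def classify_rdna_arrangement(arrays_35s, hits_5s, linkage_distance: int = 5_000):
    """Per-array S/L arrangement plus a genome-level call.

    An array is L-type when at least half of its units have a 5S hit within
    ``linkage_distance`` of the unit interval; the genome-level call is
    S_type if no array is linked, L_type if all are, mixed otherwise.
    """
    five_by_contig: dict[str, list[tuple[int, int]]] = {}
    for h in hits_5s:
        five_by_contig.setdefault(h.contig_id, []).append((h.start, h.end))
    calls = []
    for array in arrays_35s:
        units = _unit_intervals(array)
        fives = five_by_contig.get(array.contig_id, [])
        if not units:
            array.arrangement = "na"
            calls.append("na")
            continue
        linked = 0
        for us, ue in units:
            if any(hs < ue + linkage_distance and he > us - linkage_distance
                   for hs, he in fives):
                linked += 1
        array.arrangement = "L_type" if linked / len(units) >= 0.5 else "S_type"
        calls.append(array.arrangement)
    informative = [c for c in calls if c != "na"]
    if not informative:
        genome = "na"
    elif all(c == "S_type" for c in informative):
        genome = "S_type"
    elif all(c == "L_type" for c in informative):
        genome = "L_type"
    else:
        genome = "mixed"
    return calls, genome
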