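"""Assembly curation filters.

Three screens mirror the manual curation steps of a long-read plant
assembly: (1) Shannon-entropy flagging of contigs made only of simple
repeats, (2) read-depth outlier screening with organelle-homology
confirmation to find organelle-derived contigs, and (3) telomere motif
scanning with a completeness verdict per contig.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .models import AlignmentHit, SequenceRecord

logger = logging.getLogger(__name__)

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class TelomereScan:
    contig_id: str
    motif: str
    window: int
    left_count: int
    right_count: int
    per_window_counts: list = field(default_factory=list)


@dataclass
class DepthRecord:
    contig_id: str
    length: int
    mean_depth: float


@dataclass
class QCFlag:
    contig_id: str
    flag: str  # low_complexity | organelle_depth | pass
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# entropy


def shannon_entropy(sequence: str, k: int = 21) -> float:
    """Normalized k-mer Shannon entropy in [0, 1].

    H = -sum p_i log2 p_i over observed k-mer frequencies, divided by
    log2(min(4^k, number of k-mer positions)). k-mers containing N are
    excluded from counting. A 500 kb random sequence scores ~1; a pure
    tandem repeat of a short unit scores far below 0.5.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(sequence) < k:
        raise ValueError(f"sequence shorter than k={k}")
    seq = sequence.upper()
    n_positions = len(seq) - k + 1
    counts = Counter()
    if "N" in seq:
        for i in range(n_positions):
            kmer = seq[i : i + k]
            if "N" not in kmer:
                counts[kmer] += 1
    else:
        for i in range(n_positions):
            counts[seq[i : i + k]] += 1
    total = sum(counts.values())
    if total <= 1:
        return 0.0
    h = 0.0
    for c in counts.values():
        p = c / total
        h -= p * math.log2(p)
    denom = math.log2(min(4.0 ** k, float(n_positions)))
    if denom <= 0:
        return 0.0
    return min(h / denom, 1.0)


def flag_low_complexity_contigs(contigs, k: int = 21, threshold: float = 0.5) -> list[QCFlag]:
    """Flag contigs whose normalized entropy falls below ``threshold``."""
    if not contigs:
        raise ValueError("no contigs given")
    flags = []
    for rec in contigs:
        h = shannon_entropy(rec.sequence, k)
        flag = "low_complexity" if h < threshold else "pass"
        flags.append(QCFlag(rec.id, flag, {"entropy": h, "k": k, "threshold": threshold}))
    return flags


# ---------------------------------------------------------------------------
# depth


def per_contig_depth(read_alignments, contig_lengths: dict) -> list[DepthRecord]:
    """Mean depth per contig: total aligned bases over contig length.

    Multi-mapping reads contribute only their best-scoring alignment
    (falling back to the longest when scores are absent). Contigs with no
    alignments appear at depth 0.
    """
    best: dict[str, AlignmentHit] = {}
    for hit in read_alignments:
        if hit.target_id not in contig_lengths:
            raise ValueError(f"alignment references unknown contig {hit.target_id}")
        key = hit.query_id
        prev = best.get(key)
        score = hit.score if hit.score is not None else hit.alignment_length
        if prev is None:
            best[key] = hit
        else:
            prev_score = prev.score if prev.score is not None else prev.alignment_length
            if score > prev_score:
                best[key] = hit
    aligned = dict.fromkeys(contig_lengths, 0)
    for hit in best.values():
        aligned[hit.target_id] += hit.target_end - hit.target_start
    return [DepthRecord(cid, length, aligned[cid] / length if length else 0.0)
            for cid, length in contig_lengths.items()]


def _covered_fraction(hits, contig_id: str, length: int) -> float:
    intervals = sorted((h.target_start, h.target_end) for h in hits if h.target_id == contig_id)
    covered = 0
    cur_s = cur_e = None
    for s, e in intervals:
        if cur_e is None:
            cur_s, cur_e = s, e
        elif s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered / length if length else 0.0


def flag_depth_outliers(depths, organelle_hits, fold: float = 5.0,
                        min_organelle_fraction: float = 0.5) -> list[QCFlag]:
    """Flag organelle-derived contigs: depth above ``fold`` times the median
    AND at least ``min_organelle_fraction`` of the contig covered by
    organelle-genome hits. Depth alone is never sufficient."""
    if len(depths) < 3:
        raise ValueError("need >= 3 contigs for a meaningful median")
    median = float(np.median([d.mean_depth for d in depths]))
    flags = []
    for d in depths:
        frac = _covered_fraction(organelle_hits, d.contig_id, d.length)
        is_outlier = d.mean_depth > fold * median and frac >= min_organelle_fraction
        flags.append(QCFlag(
            d.contig_id,
            "organelle_depth" if is_outlier else "pass",
            {"mean_depth": d.mean_depth, "median_depth": median,
             "fold_over_median": d.mean_depth / median if median else float("inf"),
             "organelle_fraction": frac},
        ))
    return flags


# ---------------------------------------------------------------------------
# telomeres


def _count_nonoverlapping(window: str, motif: str) -> int:
    return window.count(motif)


def telomere_scan(contig: SequenceRecord, motif: str = "TTTAGGG", window: int = 10_000) -> TelomereScan:
    """Count non-overlapping exact motif matches per window across a contig.

    Terminal counts take the better of forward motif and its reverse
    complement, so a CCCTAAA tract at the 3' end is seen as telomeric.
    """
    if len(motif) < 3:
        raise ValueError("motif must be >= 3 bp")
    seq = contig.sequence
    if len(seq) < len(motif):
        logger.warning("contig %s shorter than motif; counts 0", contig.id)
        return TelomereScan(contig.id, motif, window, 0, 0, [0])
    window = min(window, len(seq))
    rc = revcomp(motif)
    per_window = []
    for i in range(0, len(seq), window):
        chunk = seq[i : i + window]
        per_window.append(max(_count_nonoverlapping(chunk, motif),
                              _count_nonoverlapping(chunk, rc)))
    first, last = seq[:window], seq[-window:]
    left = max(_count_nonoverlapping(first, motif), _count_nonoverlapping(first, rc))
    right = max(_count_nonoverlapping(last, motif), _count_nonoverlapping(last, rc))
    return TelomereScan(contig.id, motif, window, left, right, per_window)


def classify_contig_completeness(scan: TelomereScan, min_copies: int = 25) -> str:
    """Classify a contig as both_telomeres / left_only / right_only / none."""
    left = scan.left_count >= min_copies
    right = scan.right_count >= min_copies
    if left and right:
        return "both_telomeres"
    if left:
        return "left_only"
    if right:
        return "right_only"
    return "none"
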