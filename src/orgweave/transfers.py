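"""Organelle-to-nuclear transfer (NUMT/NUPT/NUM_PT/NUMPT) detection.

Pipeline: filter organelle->nuclear alignment hits, collapse them into
per-source segments (with an ambiguity rule for regions matched equally by
both organelle genomes), merge nearby segments into regions, classify each
region into one of four categories, and validate insertion junctions with
long-read alignments.

Threshold semantics are deliberately literal: hit length strictly greater
than ``min_hit_length``; identity at least ``min_identity``; merge gap
strictly less than ``max_merge_gap``; junction span at least
``min_junction_span``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .models import AlignmentHit, GffFeature


@dataclass
class TransferConfig:
    min_hit_length: int = 100      # exclusive: keep hits strictly longer
    min_identity: float = 85.0     # inclusive minimum percent identity
    max_merge_gap: int = 300       # exclusive: merge gaps strictly smaller
    min_junction_span: int = 50    # inclusive read span on each side
    ambiguity_reciprocal_overlap: float = 0.5

    def __post_init__(self):
        if min(self.min_hit_length, self.min_identity, self.max_merge_gap,
               self.min_junction_span) < 0:
            raise ValueError("thresholds must be >= 0")
        if not 0 < self.ambiguity_reciprocal_overlap <= 1:
            raise ValueError("ambiguity_reciprocal_overlap must lie in (0, 1]")


@dataclass
class TransferSegment:
    contig_id: str
    start: int
    end: int
    source: str  # M | P | A
    best_identity: float
    supporting_hit_ids: list = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TransferRegion:
    contig_id: str
    start: int
    end: int
    segments: list
    category: Optional[str] = None  # NUMT | NUPT | NUM_PT | NUMPT
    left_validated: str = "untested"
    right_validated: str = "untested"

    @property
    def total_length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------


def filter_hits(hits: Iterable[AlignmentHit], config: TransferConfig) -> list[AlignmentHit]:
    """Keep hits strictly longer than the length cutoff and at or above the
    identity cutoff; input order is preserved."""
    return [h for h in hits
            if h.alignment_length > config.min_hit_length
            and h.percent_identity >= config.min_identity]


def _collapse_source(hits: list[AlignmentHit], source: str) -> list[TransferSegment]:
    """Union of overlapping same-source target intervals, per contig."""
    by_contig: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_contig.setdefault(h.target_id, []).append(h)
    segments = []
    for contig, contig_hits in by_contig.items():
        contig_hits.sort(key=lambda h: (h.target_start, h.target_end))
        cur = None
        for h in contig_hits:
            hid = f"{h.query_id}:{h.query_start}-{h.query_end}"
            if cur is None:
                cur = TransferSegment(contig, h.target_start, h.target_end, source,
                                      h.percent_identity, [hid])
            elif h.target_start <= cur.end:
                cur.end = max(cur.end, h.target_end)
                cur.best_identity = max(cur.best_identity, h.percent_identity)
                cur.supporting_hit_ids.append(hid)
            else:
                segments.append(cur)
                cur = TransferSegment(contig, h.target_start, h.target_end, source,
                                      h.percent_identity, [hid])
        if cur is not None:
            segments.append(cur)
    return segments


def assign_segment_sources(mito_hits, plastid_hits, config: TransferConfig) -> list[TransferSegment]:
    """Collapse filtered hits into M and P segments; replace an M/P pair whose
    reciprocal overlap (intersection over the shorter segment) reaches the
    ambiguity cutoff by a single A (ambiguous) segment spanning their union."""
    m_segments = _collapse_source(list(mito_hits), "M")
    p_segments = _collapse_source(list(plastid_hits), "P")
    ambiguous: list[TransferSegment] = []
    used_p: set[int] = set()
    kept_m: list[TransferSegment] = []
    for m in m_segments:
        best_j, best_ro = None, 0.0
        for j, p in enumerate(p_segments):
            if j in used_p or p.contig_id != m.contig_id:
                continue
            inter = min(m.end, p.end) - max(m.start, p.start)
            if inter <= 0:
                continue
            ro = inter / min(m.length, p.length)
            if ro > best_ro:
                best_j, best_ro = j, ro
        if best_j is not None and best_ro >= config.ambiguity_reciprocal_overlap:
            p = p_segments[best_j]
            used_p.add(best_j)
            ambiguous.append(TransferSegment(
                m.contig_id, min(m.start, p.start), max(m.end, p.end), "A",
                max(m.best_identity, p.best_identity),
                m.supporting_hit_ids + p.supporting_hit_ids,
            ))
        else:
            kept_m.append(m)
    kept_p = [p for j, p in enumerate(p_segments) if j not in used_p]
    segments = kept_m + kept_p + ambiguous
    segments.sort(key=lambda s: (s.contig_id, s.start, s.end))
    return segments


def merge_segments_into_regions(segments, config: TransferConfig) -> list[TransferRegion]:
    """Join segments on the same contig into one region when the gap between
    consecutive segments is strictly below ``max_merge_gap``. Sources may
    differ across a join -- that is what creates NUMPT candidates. Nested
    segments are absorbed."""
    segments = sorted(segments, key=lambda s: (s.contig_id, s.start, s.end))
    regions: list[TransferRegion] = []
    cur: Optional[TransferRegion] = None
    for seg in segments:
        if cur is not None and seg.contig_id == cur.contig_id and seg.start - cur.end < config.max_merge_gap:
            cur.segments.append(seg)
            cur.end = max(cur.end, seg.end)
        else:
            if cur is not None:
                regions.append(cur)
            cur = TransferRegion(seg.contig_id, seg.start, seg.end, [seg])
        cur.segments.sort(key=lambda s: (s.start, s.end))
    if cur is not None:
        regions.append(cur)
    return regions


def classify_region(region: TransferRegion) -> str:
    """Assign the four-way category from the set of unambiguous sources:
    {M} -> NUMT, {P} -> NUPT, {M, P} -> NUMPT (mitochondrial and plastid in
    tandem), all-ambiguous -> NUM_PT."""
    if not region.segments:
        raise ValueError("region has no segments")
    sources = {s.source for s in region.segments} - {"A"}
    if sources == {"M"}:
        return "NUMT"
    if sources == {"P"}:
        return "NUPT"
    if sources == {"M", "P"}:
        return "NUMPT"
    return "NUM_PT"


def validate_junctions(regions, read_hits, config: TransferConfig) -> list[TransferRegion]:
    """Check each region boundary for a read alignment spanning at least
    ``min_junction_span`` bp on both sides. Boundaries with no overlapping
    read alignments at all are marked untested."""
    by_contig: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    tmp: dict[str, list[tuple[int, int]]] = {}
    for h in read_hits:
        tmp.setdefault(h.target_id, []).append((h.target_start, h.target_end))
    for cid, pairs in tmp.items():
        arr = np.array(pairs, dtype=np.int64)
        by_contig[cid] = (arr[:, 0], arr[:, 1])

    span = config.min_junction_span
    out = []
    for region in regions:
        region = replace(region, segments=list(region.segments))
        statuses = []
        for b in (region.start, region.end):
            starts_ends = by_contig.get(region.contig_id)
            if starts_ends is None:
                statuses.append("untested")
                continue
            starts, ends = starts_ends
            overlapping = (starts < b + span) & (ends > b - span)
            if not overlapping.any():
                statuses.append("untested")
            elif ((starts <= b - span) & (ends >= b + span)).any():
                statuses.append("yes")
            else:
                statuses.append("no")
        region.left_validated, region.right_validated = statuses
        out.append(region)
    return out


# ---------------------------------------------------------------------------
# end-to-end


CATEGORIES = ("NUMT", "NUPT", "NUM_PT", "NUMPT")


def detect_transfers(mito_hits, plastid_hits, config: Optional[TransferConfig] = None,
                     read_hits=None) -> list[TransferRegion]:
    """Filter -> assign sources -> merge -> classify (-> validate)."""
    config = config or TransferConfig()
    mito = filter_hits(mito_hits, config)
    plastid = filter_hits(plastid_hits, config)
    segments = assign_segment_sources(mito, plastid, config)
    regions = merge_segments_into_regions(segments, config)
    for region in regions:
        region.category = classify_region(region)
    if read_hits is not None:
        regions = validate_junctions(regions, read_hits, config)
    return regions


def summarize_transfers(regions) -> pd.DataFrame:
    """Per-category region counts and summed lengths (bp)."""
    rows = []
    for cat in CATEGORIES:
        cat_regions = [r for r in regions if r.category == cat]
        rows.append({"category": cat, "count": len(cat_regions),
                     "total_length": sum(r.total_length for r in cat_regions)})
    return pd.DataFrame(rows)


def regions_to_gff(regions, source: str = "orgweave") -> list[GffFeature]:
    features = []
    for i, r in enumerate(regions):
        features.append(GffFeature(
            contig_id=r.contig_id, start=r.start, end=r.end, type="transfer",
            source=source,
            attributes={
                "ID": f"transfer{i:05d}",
                "Category": r.category or "uncategorized",
                "sources": "".join(s.source for s in r.segments),
                "best_identity": f"{max(s.best_identity for s in r.segments):.1f}",
                "left_validated": r.left_validated,
                "right_validated": r.right_validated,
            },
        ))
    return features
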