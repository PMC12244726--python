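"""Shared domain types.

All coordinates are 0-based, half-open, on the target (nuclear) axis;
conversion to 1-based inclusive conventions (BLAST outfmt 6, TRF .dat,
GFF3) happens only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


@dataclass
class SequenceRecord:
    """A named DNA sequence over the alphabet {A, C, G, T, N}."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class AlignmentHit:
    """One pairwise local alignment, normalized so target coordinates ascend.

    The original orientation of the query relative to the target is kept in
    ``strand``; downstream interval logic never needs to re-flip anything.
    """

    query_id: str
    target_id: str
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    strand: str  # "+" or "-"
    percent_identity: float
    alignment_length: int
    score: Optional[float] = None
    source_tag: str = "other"  # mito | plastid | read | self | other

    def normalized(self) -> "AlignmentHit":
        """Return a copy with ascending target (and query) coordinates.

        Idempotent: an already-normalized hit comes back unchanged.
        """
        hit = AlignmentHit(**vars(self))
        if hit.target_start > hit.target_end:
            hit.target_start, hit.target_end = hit.target_end, hit.target_start
            hit.strand = "-" if hit.strand == "+" else "+"
        if hit.query_start > hit.query_end:
            hit.query_start, hit.query_end = hit.query_end, hit.query_start
        return hit

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start


@dataclass
class TandemRepeatRecord:
    """A tandem repeat locus: ``copy_number`` copies of a ``period``-bp unit."""

    contig_id: str
    start: int
    end: int
    period: int
    copy_number: float
    consensus: str = ""


@dataclass
class GffFeature:
    """Minimal feature carrier for GFF3 round trips (0-based half-open)."""

    contig_id: str
    start: int
    end: int
    type: str
    strand: str = "."
    score: Optional[float] = None
    source: str = "orgweave"
    attributes: dict = field(default_factory=dict)


@dataclass
class RnaGeneHit:
    """Location of one rRNA gene copy (18S/5.8S/26S/5S) on a contig."""

    contig_id: str
    start: int
    end: int
    strand: str
    gene: str
    identity: float = 100.0
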