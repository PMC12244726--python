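"""Contig-to-reference relationship classification and self-alignment
density screening.

Coverage of each reference scaffold by query contigs is summarized into a
profile, then classified as one-to-one (a single contig covers the
scaffold), arm-pair (two contigs cover the two ends with an uncovered
central gap, the signature of a chromosome split at an unassembled repeat
array), complex, or none. Separately, windowed off-diagonal self-alignment
density operationalizes the "dot-plot rectangle" used to spot candidate
centromeric / low-complexity regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .models import AlignmentHit


@dataclass
class CoverageProfile:
    reference_id: str
    reference_length: int
    per_query: dict = field(default_factory=dict)  # query -> merged intervals
    fractions: dict = field(default_factory=dict)  # query -> covered fraction


@dataclass
class RelationshipCall:
    reference_id: str
    relation: str  # one_to_one | arm_pair | complex | none
    queries: list = field(default_factory=list)
    evidence: dict = field(default_factory=dict)


@dataclass
class CentromereCandidate:
    contig_id: str
    window_start: int
    window_end: int
    self_density: float
    zscore: float


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(iv) for iv in merged]


def _covered(intervals: list[tuple[int, int]]) -> int:
    return sum(e - s for s, e in intervals)


def coverage_profile(hits, reference_lengths: dict,
                     min_hit_length: int = 1_000) -> dict[str, CoverageProfile]:
    """Per-reference coverage by each query: union of target intervals at
    least ``min_hit_length`` long, as merged intervals plus a fraction."""
    profiles = {ref: CoverageProfile(ref, length)
                for ref, length in reference_lengths.items()}
    for h in hits:
        if h.target_id not in profiles:
            raise ValueError(f"hit references unknown reference {h.target_id}")
        if h.target_span < min_hit_length:
            continue
        profiles[h.target_id].per_query.setdefault(h.query_id, []).append(
            (h.target_start, h.target_end))
    for prof in profiles.values():
        for q, ivs in prof.per_query.items():
            merged = _merge_intervals(ivs)
            prof.per_query[q] = merged
            prof.fractions[q] = _covered(merged) / prof.reference_length
    return profiles


def classify_relationship(profile: CoverageProfile, min_total_cov: float = 0.8,
                          min_arm_cov: float = 0.25,
                          min_mid_gap_frac: float = 0.05) -> RelationshipCall:
    """Classify one reference scaffold's relationship to the query set.

    one_to_one: the best single query covers >= ``min_total_cov``.
    arm_pair: the two best queries each cover >= ``min_arm_cov``, occupy
    disjoint terminal footprints separated by an uncovered central gap of
    at least ``min_mid_gap_frac`` of the reference, and jointly cover
    >= ``min_total_cov`` of the non-gap length.
    complex: >= ``min_total_cov`` union coverage needs three or more
    queries. Otherwise none.
    """
    L = profile.reference_length
    ranked = sorted(profile.fractions.items(), key=lambda kv: (-kv[1], kv[0]))
    evidence = {"fractions": dict(ranked[:5])}
    if ranked and ranked[0][1] >= min_total_cov:
        return RelationshipCall(profile.reference_id, "one_to_one",
                                [ranked[0][0]], evidence)
    if len(ranked) >= 2:
        (q1, f1), (q2, f2) = ranked[0], ranked[1]
        if f1 >= min_arm_cov and f2 >= min_arm_cov:
            fp1 = (profile.per_query[q1][0][0], profile.per_query[q1][-1][1])
            fp2 = (profile.per_query[q2][0][0], profile.per_query[q2][-1][1])
            left, right = sorted((fp1, fp2))
            disjoint = left[1] <= right[0]
            terminal = left[0] <= 0.1 * L and right[1] >= 0.9 * L
            gap = right[0] - left[1]
            if disjoint and terminal and gap >= min_mid_gap_frac * L:
                non_gap = L - gap
                joint = _covered(_merge_intervals(
                    profile.per_query[q1] + profile.per_query[q2]))
                if non_gap > 0 and joint / non_gap >= min_total_cov:
                    evidence["mid_gap"] = (left[1], right[0])
                    return RelationshipCall(profile.reference_id, "arm_pair",
                                            [q1, q2], evidence)
    all_intervals = [iv for ivs in profile.per_query.values() for iv in ivs]
    union_frac = _covered(_merge_intervals(all_intervals)) / L if L else 0.0
    if union_frac >= min_total_cov and len(profile.per_query) >= 3:
        return RelationshipCall(profile.reference_id, "complex",
                                [q for q, _ in ranked], evidence)
    return RelationshipCall(profile.reference_id, "none", [], evidence)


def self_alignment_density(self_hits, contig_length: int,
                           window: int = 100_000,
                           zscore_cutoff: float = 2.0) -> list[CentromereCandidate]:
    """Flag windows whose off-diagonal self-alignment coverage stands out.

    Density per non-overlapping window is the fraction of the window
    covered by target intervals of self-hits, excluding the trivial
    full-length diagonal (query interval identical to target interval).
    Windows with a z-score above ``zscore_cutoff`` are flagged and adjacent
    flagged windows are merged into one candidate.
    """
    if window > contig_length:
        window = contig_length
    n_windows = max(1, -(-contig_length // window))
    coverage = np.zeros(contig_length, dtype=bool)
    for h in self_hits:
        if (h.query_id == h.target_id and h.query_start == h.target_start
                and h.query_end == h.target_end):
            continue  # diagonal
        coverage[max(0, h.target_start) : min(contig_length, h.target_end)] = True
    densities = np.array([
        coverage[i * window : min((i + 1) * window, contig_length)].mean()
        for i in range(n_windows)
    ])
    sd = densities.std()
    if sd == 0:
        return []
    z = (densities - densities.mean()) / sd
    flagged = z > zscore_cutoff
    candidates = []
    i = 0
    while i < n_windows:
        if flagged[i]:
            j = i
            while j + 1 < n_windows and flagged[j + 1]:
                j += 1
            span = slice(i * window, min((j + 1) * window, contig_length))
            candidates.append(CentromereCandidate(
                contig_id="",
                window_start=span.start,
                window_end=span.stop,
                self_density=float(coverage[span].mean()),
                zscore=float(z[i:j + 1].max()),
            ))
            i = j + 1
        else:
            i += 1
    return candidates
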