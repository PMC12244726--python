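"""Annotation-hygiene rules for a predicted gene set and a TE library.

Four independent filters: transposon-gene flagging by a majority of
transposon-related Pfam domain descriptions, removal of genes with neither
external evidence nor a functional annotation, TE-library relabeling when
the classification probability is uninformative, and organelle pseudogene
flagging by alignment-length fraction against reference proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

# Transposon-related terms matched case-insensitively as substrings of Pfam
# domain descriptions.
TRANSPOSON_TERMS: tuple[str, ...] = (
    "transcriptase",
    "transposase",
    "gag",
    "env",
    "transposon",
    "repetitive element",
    "RNA-directed DNA polymerase",
    "pol protein",
    "non-LTR retrotransposon",
    "mobile element",
    "retroelement",
    "retrovirus",
    "Retroviral",
    "group-specific antigen",
)


@dataclass
class GeneModel:
    id: str
    contig_id: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"
    domains: list = field(default_factory=list)  # (accession, description)
    has_external_support: bool = False
    has_functional_annotation: bool = False


@dataclass
class ClassifiedRepeat:
    entry_id: str
    raw_label: str
    prob_class1: float  # Class I, retrotransposons
    prob_class2: float  # Class II, DNA transposons
    consensus: str = ""
    final_label: Optional[str] = None


@dataclass
class GeneAlignmentProfile:
    """Percent-alignment-length profile of one gene against reference
    proteins, summarized per top-hit genus (up to 20 hits per query)."""

    gene_id: str
    per_genus_mean_pct_len: dict = field(default_factory=dict)
    max_pct_len: float = 0.0

    @property
    def mean_of_means(self) -> float:
        means = list(self.per_genus_mean_pct_len.values())
        return sum(means) / len(means) if means else 0.0

    @property
    def n_hits(self) -> int:
        return len(self.per_genus_mean_pct_len)


def _matches_any_term(description: str, terms: Iterable[str]) -> bool:
    d = description.lower()
    return any(t.lower() in d for t in terms)


def flag_transposon_genes(genes, term_list: Iterable[str] = TRANSPOSON_TERMS) -> set[str]:
    """Flag genes where strictly more than half of the Pfam domain
    descriptions match a transposon-related term. Genes without domains are
    never flagged."""
    flagged = set()
    terms = list(term_list)
    if not terms:
        raise ValueError("term list must be non-empty")
    for gene in genes:
        if not gene.domains:
            continue
        matched = sum(1 for _, desc in gene.domains if _matches_any_term(desc, terms))
        if matched / len(gene.domains) > 0.5:
            flagged.add(gene.id)
    return flagged


def remove_unsupported_genes(genes) -> list[GeneModel]:
    """Drop genes with no external support AND no functional annotation;
    either kind of evidence alone keeps a gene."""
    return [g for g in genes if g.has_external_support or g.has_functional_annotation]


def relabel_te_library(entries) -> list[ClassifiedRepeat]:
    """Set final_label to 'unclassified' when the larger of the Class I /
    Class II probabilities falls strictly below 0.5; exactly 0.5 keeps the
    raw label. Entry count and order are preserved."""
    out = []
    for e in entries:
        for p in (e.prob_class1, e.prob_class2):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{e.entry_id}: probability {p} outside [0, 1]")
        label = "unclassified" if max(e.prob_class1, e.prob_class2) < 0.5 else e.raw_label
        out.append(ClassifiedRepeat(e.entry_id, e.raw_label, e.prob_class1,
                                    e.prob_class2, e.consensus, label))
    return out


def flag_pseudogenes(profiles, threshold: float = 75.0, sense: str = "or") -> dict[str, str]:
    """Flag candidate pseudogenes by alignment-length fraction.

    With ``sense='or'`` (default) a gene is flagged when its mean-of-means
    OR its maximum percent alignment length falls below ``threshold``;
    ``sense='and'`` requires both. Genes with zero hits are flagged with
    the distinct reason ``no_hits``. Returns gene_id -> reason.
    """
    if sense not in ("or", "and"):
        raise ValueError("sense must be 'or' or 'and'")
    flagged: dict[str, str] = {}
    for p in profiles:
        if p.n_hits == 0:
            flagged[p.gene_id] = "no_hits"
            continue
        mean_low = p.mean_of_means < threshold
        max_low = p.max_pct_len < threshold
        hit = (mean_low or max_low) if sense == "or" else (mean_low and max_low)
        if hit:
            reasons = []
            if mean_low:
                reasons.append("mean_below_threshold")
            if max_low:
                reasons.append("max_below_threshold")
            flagged[p.gene_id] = "+".join(reasons)
    return flagged


def profile_from_hits(gene_id: str, hits: Iterable[tuple[str, float]],
                      top_per_genus: int = 20) -> GeneAlignmentProfile:
    """Build an alignment profile from (genus, percent_alignment_length)
    hits, keeping at most ``top_per_genus`` hits per genus in input order.
    Percentages above 100 (gapped alignments) are clamped to 100."""
    per_genus: dict[str, list[float]] = {}
    max_pct = 0.0
    for genus, pct in hits:
        pct = min(float(pct), 100.0)
        bucket = per_genus.setdefault(genus, [])
        if len(bucket) < top_per_genus:
            bucket.append(pct)
        max_pct = max(max_pct, pct)
    means = {g: sum(v) / len(v) for g, v in per_genus.items()}
    return GeneAlignmentProfile(gene_id, means, max_pct)
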