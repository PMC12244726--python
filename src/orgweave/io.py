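"""Readers and writers for the external formats the pipeline touches.

FASTA/FASTQ go through Biopython; the tabular formats (BLAST outfmt 6, PAF,
TRF .dat, GFF3, BED) are parsed directly because every coordinate must be
normalized into the package-wide 0-based half-open convention on entry.
"""

from __future__ import annotations

import logging
import re
import urllib.parse
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .models import AlignmentHit, GffFeature, RnaGeneHit, SequenceRecord, TandemRepeatRecord

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")
_NON_ACGTN = re.compile(r"[^ACGTN]")


def _clean_sequence(raw: str) -> tuple[str, int]:
    """Uppercase and coerce non-ACGTN characters (IUPAC codes etc.) to N."""
    seq = raw.upper()
    cleaned, n_replaced = _NON_ACGTN.subn("N", seq)
    return cleaned, n_replaced


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords.

    Lowercase is uppercased; characters outside {A,C,G,T,N} become N (count
    logged). Duplicate ids and empty files are hard errors.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    replaced_total = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ValueError(f"{path}: record with empty id")
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate id {rec.id}")
        seen.add(rec.id)
        seq, n_replaced = _clean_sequence(str(rec.seq))
        replaced_total += n_replaced
        records.append(SequenceRecord(id=rec.id, sequence=seq))
    if not records:
        raise ValueError(f"{path}: empty or not FASTA")
    if replaced_total:
        logger.info("%s: replaced %d non-ACGTN characters with N", path, replaced_total)
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 80) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_fastq(path) -> list[SequenceRecord]:
    """Read a FASTQ file; qualities are ignored."""
    path = Path(path)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fastq"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate id {rec.id}")
        seen.add(rec.id)
        seq, _ = _clean_sequence(str(rec.seq))
        records.append(SequenceRecord(id=rec.id, sequence=seq))
    return records


def write_fastq(reads: Iterable[tuple[str, str]], path) -> None:
    """Write (name, sequence) pairs as FASTQ with uniform placeholder quality."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# Pairwise alignments


def read_alignments(path, dialect: str, source_tag: str = "other") -> list[AlignmentHit]:
    """Parse a pairwise-alignment table into normalized AlignmentHits.

    ``dialect`` is ``blast_tab`` (outfmt 6: qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore; 1-based
    inclusive) or ``paf`` (already 0-based half-open; identity derived as
    100 * matches / block length).
    """
    if dialect not in ("blast_tab", "paf"):
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "blast_tab":
                    hit = _parse_blast_row(fields, source_tag)
                else:
                    hit = _parse_paf_row(fields, source_tag)
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed {dialect} row at line {lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def _parse_blast_row(fields: Sequence[str], source_tag: str) -> AlignmentHit:
    if len(fields) < 12:
        raise ValueError(f"expected 12 columns, got {len(fields)}")
    qseqid, sseqid = fields[0], fields[1]
    pident = float(fields[2])
    length = int(fields[3])
    qstart, qend = int(fields[6]), int(fields[7])
    sstart, send = int(fields[8]), int(fields[9])
    bitscore = float(fields[11])
    for value in (qstart, qend, sstart, send):
        if value < 1:
            raise ValueError(f"non-positive 1-based coordinate {value}")
    strand = "+"
    if sstart > send:
        sstart, send = send, sstart
        strand = "-"
    if qstart > qend:  # blastn keeps qstart < qend, but be permissive
        qstart, qend = qend, qstart
        strand = "-" if strand == "+" else "+"
    return AlignmentHit(
        query_id=qseqid,
        target_id=sseqid,
        query_start=qstart - 1,
        query_end=qend,
        target_start=sstart - 1,
        target_end=send,
        strand=strand,
        percent_identity=pident,
        alignment_length=length,
        score=bitscore,
        source_tag=source_tag,
    )


def _parse_paf_row(fields: Sequence[str], source_tag: str) -> AlignmentHit:
    if len(fields) < 12:
        raise ValueError(f"expected >= 12 columns, got {len(fields)}")
    qstart, qend = int(fields[2]), int(fields[3])
    strand = fields[4]
    tstart, tend = int(fields[7]), int(fields[8])
    matches, block = int(fields[9]), int(fields[10])
    if min(qstart, qend, tstart, tend) < 0:
        raise ValueError("negative coordinate")
    if strand not in "+-":
        raise ValueError(f"bad strand {strand!r}")
    if block <= 0:
        raise ValueError(f"non-positive alignment block length {block}")
    return AlignmentHit(
        query_id=fields[0],
        target_id=fields[5],
        query_start=qstart,
        query_end=qend,
        target_start=tstart,
        target_end=tend,
        strand=strand,
        percent_identity=100.0 * matches / block,
        alignment_length=block,
        score=float(matches),
        source_tag=source_tag,
    )


# ---------------------------------------------------------------------------
# Tandem Repeats Finder .dat


def read_trf_dat(path) -> list[TandemRepeatRecord]:
    """Parse TRF .dat output (``Sequence:`` headers + space-separated rows).

    TRF's 1-based inclusive coordinates become 0-based half-open. Rows whose
    end does not exceed their start are skipped with a warning.
    """
    records: list[TandemRepeatRecord] = []
    contig = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("Sequence:"):
                contig = line.split(None, 1)[1].split()[0]
                continue
            if not line or not line[0].isdigit():
                continue
            fields = line.split()
            if len(fields) < 14 or contig is None:
                continue
            start1, end1 = int(fields[0]), int(fields[1])
            if end1 <= start1:
                logger.warning("read_trf_dat: skipping row with end <= start on %s", contig)
                continue
            records.append(
                TandemRepeatRecord(
                    contig_id=contig,
                    start=start1 - 1,
                    end=end1,
                    period=int(fields[2]),
                    copy_number=float(fields[3]),
                    consensus=fields[13],
                )
            )
    return records


# ---------------------------------------------------------------------------
# GFF3 / BED / rRNA hit tables


def _escape(value: str) -> str:
    return urllib.parse.quote(str(value), safe=" :^*$@!+?|")


def write_gff3(features: Iterable[GffFeature], path, contig_lengths: dict | None = None) -> None:
    """Write features as GFF3 (1-based inclusive), deterministically ordered
    by (contig, start, end, type). Attribute values are URL-escaped."""
    feats = sorted(features, key=lambda f: (f.contig_id, f.start, f.end, f.type))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, f in enumerate(feats):
            if contig_lengths is not None:
                length = contig_lengths.get(f.contig_id)
                if length is not None and f.end > length:
                    raise ValueError(
                        f"feature {f.contig_id}:{f.start}-{f.end} exceeds contig length {length}"
                    )
            attrs = dict(f.attributes)
            attrs.setdefault("ID", f"feature{i:06d}")
            attr_str = ";".join(f"{k}={_escape(v)}" for k, v in attrs.items())
            score = "." if f.score is None else f"{f.score:g}"
            fh.write(
                f"{f.contig_id}\t{f.source}\t{f.type}\t{f.start + 1}\t{f.end}\t"
                f"{score}\t{f.strand}\t.\t{attr_str}\n"
            )


def read_gff3(path) -> list[GffFeature]:
    features = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: malformed GFF3 line: {line!r}")
            attrs = {}
            for pair in fields[8].split(";"):
                if "=" in pair:
                    k, v = pair.split("=", 1)
                    attrs[k] = urllib.parse.unquote(v)
            features.append(
                GffFeature(
                    contig_id=fields[0],
                    source=fields[1],
                    type=fields[2],
                    start=int(fields[3]) - 1,
                    end=int(fields[4]),
                    score=None if fields[5] == "." else float(fields[5]),
                    strand=fields[6],
                    attributes=attrs,
                )
            )
    return features


def write_bed(intervals: Iterable[tuple[str, int, int, str]], path) -> None:
    """Write (contig, start, end, name) rows as BED (already 0-based half-open)."""
    with open(path, "w") as fh:
        for contig, start, end, name in intervals:
            fh.write(f"{contig}\t{start}\t{end}\t{name}\n")


def read_bed(path) -> list[tuple[str, int, int, str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            rows.append((f[0], int(f[1]), int(f[2]), f[3] if len(f) > 3 else "."))
    return rows


def read_rrna_hits(path) -> list[RnaGeneHit]:
    """Read an rRNA gene hit TSV: contig, start, end, strand, gene_label, identity."""
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#") or line.startswith("contig\t"):
                continue
            f = line.rstrip("\n").split("\t")
            hits.append(
                RnaGeneHit(
                    contig_id=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    strand=f[3],
                    gene=f[4],
                    identity=float(f[5]) if len(f) > 5 else 100.0,
                )
            )
    return hits


def write_rrna_hits(hits: Iterable[RnaGeneHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tstrand\tgene\tidentity\n")
        for h in hits:
            fh.write(f"{h.contig_id}\t{h.start}\t{h.end}\t{h.strand}\t{h.gene}\t{h.identity:g}\n")
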