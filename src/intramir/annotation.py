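"""Gene/miRNA annotation model and intragenic-miRNA classification.

A miRNA precursor is classified relative to protein-coding gene models as
*intergenic* (no overlap with any gene span), *intronic* (inside a host gene
but touching no exon of the summarized gene model) or *exonic* (overlapping
at least one merged exon), with sense/antisense orientation relative to the
host.  Host genes are the protein-coding genes that contain intragenic
miRNAs; the classification is the entry point for every downstream analysis
(host expression correlation, host-gene enrichment, APA in host UTRs).

Files are read in their on-disk conventions (GFF3/GTF: 1-based inclusive);
every in-memory coordinate is 0-based half-open.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

STRANDS = ("+", "-")


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise AnnotationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of overlapping bases (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    cds_span: Optional[GenomicInterval] = None
    utr3: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out


@dataclass
class GeneModel:
    """A gene with its transcripts plus the summarized (merged-exon) model."""

    gene_id: str
    symbol: str
    span: GenomicInterval
    transcripts: list[TranscriptModel]
    merged_exons: list[GenomicInterval]

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def chrom(self) -> str:
        return self.span.chrom

    def merged_introns(self) -> list[GenomicInterval]:
        """Introns of the summarized model, sorted genomically."""
        out = []
        for a, b in zip(self.merged_exons, self.merged_exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out

    def utr3_intervals(self) -> list[tuple[str, GenomicInterval]]:
        """(transcript_id, interval) pairs for every annotated 3'-UTR piece."""
        return [(t.transcript_id, u) for t in self.transcripts for u in t.utr3]


@dataclass
class MiRNARecord:
    """A miRNA precursor and its mature sequences (RNA alphabet)."""

    mirna_id: str
    precursor: GenomicInterval
    matures: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mid, seq in self.matures.items():
            if len(seq) < 8:
                raise AnnotationError(
                    f"mature {mid} shorter than 8 nt; seed bases 2-7 undefined"
                )


@dataclass
class HostAssignment:
    """The classified relationship of one miRNA to (at most) one host gene."""

    mirna_id: str
    gene_id: Optional[str]
    context: str  # intergenic | intronic | exonic
    orientation: str  # sense | antisense | not-applicable
    intron_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.context == "intergenic":
            assert self.gene_id is None and self.orientation == "not-applicable"
        else:
            assert self.gene_id is not None and self.orientation in ("sense", "antisense")
        if self.intron_index is not None:
            assert self.context == "intronic"


# ---------------------------------------------------------------------------
# annotation readers


def _merge_intervals(ivs: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    ivs = sorted(ivs, key=lambda e: e.start)
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end, last.strand)
        else:
            merged.append(iv)
    return merged


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().rstrip(";").split(";"):
        if not part:
            continue
        if "=" not in part:
            continue
        k, v = part.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        if " " not in part:
            continue
        k, v = part.split(" ", 1)
        out[k] = v.strip().strip('"')
    return out


def _iter_rows(path: str, dialect: str):
    parse_attrs = _parse_gff3_attributes if dialect == "gff3" else _parse_gtf_attributes
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise AnnotationError(
                    f"{path}: malformed line {lineno}: expected 9 tab-separated "
                    f"columns, got {len(cols)}"
                )
            chrom, _source, ftype, start, end, _score, strand, _frame, attrs = cols
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}: malformed line {lineno}: non-integer coordinates"
                ) from exc
            # on-disk 1-based inclusive -> internal 0-based half-open
            yield lineno, chrom, ftype, start_i - 1, end_i, strand, parse_attrs(attrs)


_TRANSCRIPT_TYPES = {"mRNA", "transcript"}


def read_gene_annotation(path: str, dialect: str = "gff3") -> list[GeneModel]:
    """Read protein-coding gene models from a GFF3 or GTF file.

    Transcripts are grouped under genes; when a transcript has CDS features
    but no explicit ``three_prime_UTR`` rows, the 3'-UTR is derived as the
    exonic space strictly 3' of the CDS span (strand-aware).
    """
    if dialect not in ("gff3", "gtf"):
        raise ValueError(f"unknown dialect {dialect!r}")

    gene_rows: dict[str, dict] = {}
    tx_rows: dict[str, dict] = {}
    order: list[str] = []

    for lineno, chrom, ftype, start, end, strand, attrs in _iter_rows(path, dialect):
        if dialect == "gff3":
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise AnnotationError(f"{path}: line {lineno}: gene without ID")
                gene_rows[gid] = {
                    "symbol": attrs.get("Name", gid),
                    "span": (chrom, start, end, strand),
                }
                order.append(gid)
            elif ftype in _TRANSCRIPT_TYPES:
                tid, parent = attrs.get("ID"), attrs.get("Parent")
                if tid is None or parent is None:
                    raise AnnotationError(
                        f"{path}: line {lineno}: transcript missing ID/Parent"
                    )
                if parent not in gene_rows:
                    raise AnnotationError(
                        f"{path}: line {lineno}: transcript {tid} references "
                        f"unknown gene {parent}"
                    )
                tx_rows[tid] = {"gene": parent, "exons": [], "cds": [], "utr3": []}
            elif ftype in ("exon", "CDS", "three_prime_UTR"):
                parent = attrs.get("Parent")
                if parent is None or parent not in tx_rows:
                    raise AnnotationError(
                        f"{path}: line {lineno}: {ftype} references unknown "
                        f"transcript {parent!r}"
                    )
                key = {"exon": "exons", "CDS": "cds", "three_prime_UTR": "utr3"}[ftype]
                tx_rows[parent][key].append(GenomicInterval(chrom, start, end, strand))
        else:  # gtf
            gid, tid = attrs.get("gene_id"), attrs.get("transcript_id")
            if ftype in ("exon", "CDS", "three_prime_utr", "3UTR", "three_prime_UTR"):
                if gid is None or tid is None:
                    raise AnnotationError(
                        f"{path}: line {lineno}: missing gene_id/transcript_id"
                    )
                if gid not in gene_rows:
                    gene_rows[gid] = {"symbol": attrs.get("gene_name", gid), "span": None}
                    order.append(gid)
                if tid not in tx_rows:
                    tx_rows[tid] = {"gene": gid, "exons": [], "cds": [], "utr3": []}
                key = "exons" if ftype == "exon" else ("cds" if ftype == "CDS" else "utr3")
                tx_rows[tid][key].append(GenomicInterval(chrom, start, end, strand))
            elif ftype == "gene" and gid is not None:
                gene_rows.setdefault(
                    gid, {"symbol": attrs.get("gene_name", gid), "span": None}
                )
                if gid not in order:
                    order.append(gid)
                gene_rows[gid]["span"] = (chrom, start, end, strand)

    genes: list[GeneModel] = []
    by_gene: dict[str, list[TranscriptModel]] = {g: [] for g in gene_rows}
    for tid, row in tx_rows.items():
        if not row["exons"]:
            warnings.warn(f"transcript {tid} has no exons; skipped")
            continue
        cds_span = None
        if row["cds"]:
            cds = sorted(row["cds"], key=lambda c: c.start)
            cds_span = GenomicInterval(
                cds[0].chrom, cds[0].start, cds[-1].end, cds[0].strand
            )
        tx = TranscriptModel(tid, row["gene"], row["exons"], cds_span, row["utr3"])
        if not tx.utr3 and cds_span is not None:
            tx.utr3 = _derive_utr3(tx.exons, cds_span)
        by_gene[row["gene"]].append(tx)

    for gid in order:
        info = gene_rows[gid]
        txs = sorted(by_gene.get(gid, []), key=lambda t: t.transcript_id)
        coords = [(t.span.start, t.span.end, t.chrom, t.strand) for t in txs]
        if info.get("span"):
            chrom, s, e, strand = info["span"]
            coords.append((s, e, chrom, strand))
        if not coords:
            continue  # annotation rows carried no geometry at all
        start = min(c[0] for c in coords)
        end = max(c[1] for c in coords)
        chrom, strand = coords[0][2], coords[0][3]
        merged = _merge_intervals([e for t in txs for e in t.exons])
        if not merged:  # gene line only, no transcripts
            merged = [GenomicInterval(chrom, start, end, strand)]
        genes.append(
            GeneModel(gid, info["symbol"], GenomicInterval(chrom, start, end, strand),
                      txs, merged)
        )
    return genes


def _derive_utr3(
    exons: Sequence[GenomicInterval], cds_span: GenomicInterval
) -> list[GenomicInterval]:
    """Exonic space strictly 3' of the CDS span (strand-aware)."""
    out = []
    for exon in exons:
        if exon.strand == "+":
            lo, hi = max(exon.start, cds_span.end), exon.end
        else:
            lo, hi = exon.start, min(exon.end, cds_span.start)
        if lo < hi:
            out.append(GenomicInterval(exon.chrom, lo, hi, exon.strand))
    return out


def read_mirna_annotation(gff_path: str, mature_fasta: str) -> list[MiRNARecord]:
    """Read miRNA precursors (miRBase-style GFF3) plus mature sequences.

    Mature FASTA records are linked to precursors by the GFF ``Derives_from``
    attribute where present, else by the naming convention that the mature id
    extends the precursor id (e.g. ``mir-1`` -> ``miR-1-5p``).  T is
    normalized to U; matures shorter than 8 nt are rejected with a warning.
    """
    matures: dict[str, str] = {}
    for rec in SeqIO.parse(mature_fasta, "fasta"):
        matures[rec.id] = str(rec.seq).upper().replace("T", "U")

    precursors: list[tuple[str, GenomicInterval]] = []
    derived: dict[str, list[str]] = {}
    for lineno, chrom, ftype, start, end, strand, attrs in _iter_rows(gff_path, "gff3"):
        if ftype in ("miRNA_primary_transcript", "pre_miRNA", "precursor_RNA"):
            mid = attrs.get("ID") or attrs.get("Name")
            if mid is None:
                raise AnnotationError(f"{gff_path}: line {lineno}: precursor without ID")
            precursors.append((mid, GenomicInterval(chrom, start, end, strand)))
        elif ftype == "miRNA":
            parent = attrs.get("Derives_from") or attrs.get("Parent")
            name = attrs.get("ID") or attrs.get("Name")
            if parent and name:
                derived.setdefault(parent, []).append(name)

    records = []
    for mid, interval in precursors:
        mature_ids = derived.get(mid) or [
            m for m in matures if m.startswith(mid) or m.lower().startswith(mid.lower())
        ]
        seqs = {}
        for m in mature_ids:
            seq = matures.get(m)
            if seq is None:
                continue
            if len(seq) < 8:
                warnings.warn(f"mature {m} of {mid} shorter than 8 nt; rejected")
                continue
            seqs[m] = seq
        if not seqs:
            log.warning("precursor %s has no usable mature sequence", mid)
        records.append(MiRNARecord(mid, interval, seqs))
    return records


# ---------------------------------------------------------------------------
# classification


class GeneIndex:
    """Interval index over gene spans for fast precursor lookup."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = list(genes)
        self._trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            self._trees.setdefault(g.chrom, IntervalTree()).addi(
                g.span.start, g.span.end, g
            )

    def overlapping(self, iv: GenomicInterval) -> list[GeneModel]:
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(iv.start, iv.end)]


def classify_mirna(
    mirna: MiRNARecord, genes: Sequence[GeneModel] | GeneIndex
) -> HostAssignment:
    """Classify a miRNA precursor as intergenic, intronic or exonic.

    A precursor overlapping >=1 bp of a host's merged exons is *exonic*
    (boundary-spanning precursors count as exonic); a precursor inside a gene
    span touching no merged exon is *intronic*; no >=1 bp overlap with any
    gene span means *intergenic*.  When several genes overlap the precursor,
    the host is the sense-strand gene first, then the gene with the largest
    overlap, then the lexicographically smallest gene_id.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    pre = mirna.precursor
    candidates = index.overlapping(pre)
    if not candidates:
        return HostAssignment(mirna.mirna_id, None, "intergenic", "not-applicable")

    def rank(g: GeneModel):
        sense = g.strand == pre.strand
        return (not sense, -g.span.overlap(pre), g.gene_id)

    host = min(candidates, key=rank)
    orientation = "sense" if host.strand == pre.strand else "antisense"
    exonic = any(e.overlap(pre) > 0 for e in host.merged_exons)
    if exonic:
        return HostAssignment(mirna.mirna_id, host.gene_id, "exonic", orientation)

    intron_index = None
    mid = (pre.start + pre.end) // 2
    introns = host.merged_introns()
    if host.strand == "-":
        introns = introns[::-1]  # number 5'->3' along the gene
    for i, intron in enumerate(introns, start=1):
        if intron.start <= mid < intron.end:
            intron_index = i
            break
    return HostAssignment(mirna.mirna_id, host.gene_id, "intronic", orientation, intron_index)


def classify_all(
    mirnas: Sequence[MiRNARecord], genes: Sequence[GeneModel]
) -> list[HostAssignment]:
    index = GeneIndex(genes)
    return [classify_mirna(m, index) for m in mirnas]


def summarize_annotation(assignments: Sequence[HostAssignment]) -> pd.DataFrame:
    """One-row summary table: totals, intronic/exonic counts with sense
    percentages, intergenic count and the number of distinct host genes."""

    def sense_pct(ctx: str) -> float:
        sub = [a for a in assignments if a.context == ctx]
        if not sub:
            return float("nan")
        return 100.0 * sum(a.orientation == "sense" for a in sub) / len(sub)

    intronic = sum(a.context == "intronic" for a in assignments)
    exonic = sum(a.context == "exonic" for a in assignments)
    intergenic = sum(a.context == "intergenic" for a in assignments)
    hosts = {a.gene_id for a in assignments if a.gene_id is not None}
    intragenic = intronic + exonic
    row = {
        "total_mirnas": len(assignments),
        "intronic": intronic,
        "intronic_sense_pct": sense_pct("intronic"),
        "exonic": exonic,
        "exonic_sense_pct": sense_pct("exonic"),
        "intragenic": intragenic,
        "intragenic_sense_pct": (
            100.0
            * sum(a.orientation == "sense" for a in assignments if a.gene_id)
            / intragenic
            if intragenic
            else float("nan")
        ),
        "intergenic": intergenic,
        "host_genes": len(hosts),
    }
    return pd.DataFrame([row])


def assignments_to_frame(assignments: Sequence[HostAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna_id": a.mirna_id,
                "gene_id": a.gene_id if a.gene_id is not None else ".",
                "context": a.context,
                "orientation": a.orientation,
                "intron_index": a.intron_index if a.intron_index is not None else ".",
            }
            for a in assignments
        ]
    )


def write_assignments(assignments: Sequence[HostAssignment], path: str) -> None:
    assignments_to_frame(assignments).to_csv(path, sep="\t", index=False)


def read_assignments(path: str) -> list[HostAssignment]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, r in df.iterrows():
        gene = None if r["gene_id"] == "." else r["gene_id"]
        idx = None if r["intron_index"] == "." else int(r["intron_index"])
        out.append(HostAssignment(r["mirna_id"], gene, r["context"], r["orientation"], idx))
    return out
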