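"""Alternative polyadenylation (APA) site calling from aligned reads.

Cleavage evidence comes from reads carrying an untemplated poly(A) tail:
on the forward strand a soft-clipped run of >=4 A at the read's 3' end, on
the reverse strand >=4 T at the read's genomic start (the reverse-complement
of the tail).  Reads dominated by A/T/N (content >= 0.8) are discarded as
likely artifacts before tail inspection.  Evidence is restricted to
annotated 3'-UTRs, clustered with single linkage at <=40 nt, and clusters
supported by >=2 reads become ApaSite records, each carrying per-tissue
utilization and canonical poly(A)-signal (PAS) hexamer annotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pysam
from intervaltree import IntervalTree

from .annotation import GeneModel

log = logging.getLogger(__name__)

DEFAULT_TAIL_MIN = 4
DEFAULT_MIN_SUPPORT = 2
DEFAULT_WINDOW = 40
DEFAULT_ATN_MAX = 0.8
CANONICAL_PAS = ("AATAAA", "ATTAAA")


@dataclass
class TailEvidence:
    """One read's poly(A)-tail evidence for a cleavage position."""

    read_id: str
    chrom: str
    cleavage_pos: int  # 0-based genomic coordinate of the last aligned base
    strand: str
    tail_length: int
    tissue: Optional[str] = None
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.tail_length < DEFAULT_TAIL_MIN:
            raise ValueError("tail evidence requires >=4 untemplated A/T")


@dataclass
class ApaSite:
    """A clustered poly(A) site."""

    chrom: str
    pos: int  # representative cleavage coordinate
    strand: str
    support: int
    member_positions: list[tuple[int, int]]  # (position, read count)
    gene_id: Optional[str] = None
    poly_a_index: Optional[int] = None
    signals: list[tuple[str, int]] = field(default_factory=list)
    utilization: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.support < DEFAULT_MIN_SUPPORT:
            raise ValueError("an APA site requires support from >=2 reads")


def _run_length(seq: str, base: str, from_start: bool) -> int:
    it = seq if from_start else reversed(seq)
    n = 0
    for c in it:
        if c == base:
            n += 1
        else:
            break
    return n


def _leading_run(seq: str, base: str) -> int:
    return _run_length(seq, base, True)


def extract_tail_evidence(
    alignments: str | pysam.AlignmentFile | Iterable[pysam.AlignedSegment],
    reference: Optional[object] = None,
    tail_min: int = DEFAULT_TAIL_MIN,
    atn_max: float = DEFAULT_ATN_MAX,
    require_untemplated: bool = True,
) -> list[TailEvidence]:
    """Scan aligned reads for untemplated poly(A)/(T) tails.

    Parameters
    ----------
    alignments
        SAM/BAM path, an open :class:`pysam.AlignmentFile`, or an iterable of
        aligned segments.
    reference
        Optional genome (a :class:`pysam.FastaFile` or any mapping-like object
        with ``fetch(chrom, start, end)``) used to verify that a clipped tail
        is not templated.  Without it, soft-clip evidence alone is accepted
        (lower-stringency mode) when ``require_untemplated`` is False;
        otherwise an error points at the missing input.
    """
    opened = None
    if isinstance(alignments, str):
        opened = pysam.AlignmentFile(alignments, check_sq=False)
        reads = opened
        rg_tissue = _read_group_tissues(opened.header)
    elif isinstance(alignments, pysam.AlignmentFile):
        reads = alignments
        rg_tissue = _read_group_tissues(alignments.header)
    else:
        reads = alignments
        rg_tissue = {}

    if reference is None and require_untemplated:
        raise ValueError(
            "untemplated-tail verification needs the genome FASTA; pass "
            "reference=... or set require_untemplated=False to accept "
            "soft-clips without verification"
        )

    evidence: list[TailEvidence] = []
    n_unmapped = 0
    try:
        for read in reads:
            if read.is_unmapped or read.query_sequence is None:
                n_unmapped += 1
                continue
            seq = read.query_sequence.upper()
            atn = sum(seq.count(b) for b in "ATN") / len(seq)
            if atn >= atn_max:
                continue
            cigar = read.cigartuples or []
            if read.is_reverse:
                # tail is at the genomic start of the alignment, as T's
                if not cigar or cigar[0][0] != pysam.CSOFT_CLIP:
                    continue
                clip_len = cigar[0][1]
                clip = seq[:clip_len]
                tail = _run_length(clip, "T", from_start=False)
                if tail < tail_min:
                    continue
                pos = read.reference_start  # strand-aware last aligned base
                if reference is not None and _templated(
                    reference, read.reference_name, pos - tail, pos, "T"
                ):
                    continue
                strand = "-"
            else:
                if not cigar or cigar[-1][0] != pysam.CSOFT_CLIP:
                    continue
                clip_len = cigar[-1][1]
                clip = seq[len(seq) - clip_len :]
                tail = _leading_run(clip, "A")
                if tail < tail_min:
                    continue
                pos = read.reference_end - 1
                if reference is not None and _templated(
                    reference, read.reference_name, pos + 1, pos + 1 + tail, "A"
                ):
                    continue
                strand = "+"
            tissue = None
            try:
                tissue = rg_tissue.get(read.get_tag("RG"))
            except KeyError:
                pass
            evidence.append(
                TailEvidence(read.query_name, read.reference_name, pos, strand, tail, tissue)
            )
    finally:
        if opened is not None:
            opened.close()
    if n_unmapped:
        log.info("skipped %d unmapped reads", n_unmapped)
    return evidence


def _read_group_tissues(header) -> dict[str, str]:
    out = {}
    for rg in header.to_dict().get("RG", []):
        out[rg["ID"]] = rg.get("SM", rg["ID"])
    return out


def _templated(reference, chrom: str, start: int, end: int, base: str) -> bool:
    """True when the reference bases under the clip form a matching A/T run."""
    if start < 0:
        return False
    try:
        ref = reference.fetch(chrom, start, end).upper()
    except (KeyError, ValueError):
        return False
    return len(ref) == end - start and ref == base * len(ref)


def filter_to_utr(
    evidence: Sequence[TailEvidence], genes: Sequence[GeneModel]
) -> list[TailEvidence]:
    """Keep evidence whose cleavage falls in an annotated 3'-UTR, strand-matched;
    kept records are tagged with the UTR's gene_id."""
    trees: dict[tuple[str, str], IntervalTree] = {}
    for g in genes:
        for _tid, iv in g.utr3_intervals():
            trees.setdefault((iv.chrom, iv.strand), IntervalTree()).addi(
                iv.start, iv.end, g.gene_id
            )
    kept = []
    for ev in evidence:
        tree = trees.get((ev.chrom, ev.strand))
        if tree is None:
            continue
        hits = tree.at(ev.cleavage_pos)
        if not hits:
            continue
        gene_id = sorted(h.data for h in hits)[0]
        kept.append(
            TailEvidence(
                ev.read_id, ev.chrom, ev.cleavage_pos, ev.strand,
                ev.tail_length, ev.tissue, gene_id,
            )
        )
    return kept


def cluster_sites(
    evidence: Sequence[TailEvidence],
    window: int = DEFAULT_WINDOW,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> list[ApaSite]:
    """Single-linkage clustering of cleavage positions.

    Positions on the same (chrom, strand, gene) whose nearest neighbour in
    the growing cluster lies <= window nt away merge into one site (the
    boundary is inclusive).  Clusters with < min_support reads are dropped.
    The representative position is the member with the highest read count,
    ties broken toward the 3' end (strand-aware); poly(A) indices number the
    surviving sites 5'->3' within each gene.
    """
    if window <= 0:
        raise ValueError("window must be positive")

    groups: dict[tuple[str, str, Optional[str]], dict[int, dict]] = {}
    for ev in evidence:
        key = (ev.chrom, ev.strand, ev.gene_id)
        pos_counts = groups.setdefault(key, {})
        entry = pos_counts.setdefault(ev.cleavage_pos, {"n": 0, "tissues": {}})
        entry["n"] += 1
        if ev.tissue is not None:
            entry["tissues"][ev.tissue] = entry["tissues"].get(ev.tissue, 0) + 1

    sites: list[ApaSite] = []
    for (chrom, strand, gene_id), pos_counts in sorted(
        groups.items(), key=lambda kv: (kv[0][0], kv[0][1], str(kv[0][2]))
    ):
        positions = sorted(pos_counts)
        clusters: list[list[int]] = []
        for p in positions:
            if clusters and p - clusters[-1][-1] <= window:
                clusters[-1].append(p)
            else:
                clusters.append([p])
        gene_sites = []
        for members in clusters:
            support = sum(pos_counts[p]["n"] for p in members)
            if support < min_support:
                continue
            # highest count wins; ties toward the 3' end
            if strand == "+":
                rep = max(members, key=lambda p: (pos_counts[p]["n"], p))
            else:
                rep = max(members, key=lambda p: (pos_counts[p]["n"], -p))
            tissues: dict[str, int] = {}
            for p in members:
                for t, n in pos_counts[p]["tissues"].items():
                    tissues[t] = tissues.get(t, 0) + n
            util = {t: n / support for t, n in sorted(tissues.items())} if tissues else {}
            gene_sites.append(
                ApaSite(
                    chrom, rep, strand, support,
                    [(p, pos_counts[p]["n"]) for p in members],
                    gene_id=gene_id, utilization=util,
                )
            )
        # poly(A) index: 5'->3' along the gene
        gene_sites.sort(key=lambda s: s.pos, reverse=(strand == "-"))
        for i, s in enumerate(gene_sites, start=1):
            if gene_id is not None:
                s.poly_a_index = i
        sites.extend(gene_sites)
    return sites


def scan_pas_signals(
    utr_sequence: str,
    cleavage_offset: int,
    search_span: tuple[int, int] = (10, 40),
    hexamers: Sequence[str] = CANONICAL_PAS,
) -> list[tuple[str, int]]:
    """Find canonical PAS hexamers upstream of a cleavage position.

    ``utr_sequence`` is the sense-strand 3'-UTR (5'->3'),
    ``cleavage_offset`` the cleavage position within it.  A hit is reported
    as (hexamer, offset) where offset = distance from the hexamer start
    upstream to the cleavage position, restricted to
    ``search_span[0] <= offset <= search_span[1]``.  A window truncated by
    the UTR start is scanned as far as available.
    """
    lo, hi = search_span
    seq = utr_sequence.upper()
    hits = []
    for offset in range(lo, hi + 1):
        start = cleavage_offset - offset
        if start < 0:
            break
        word = seq[start : start + 6]
        for hexamer in hexamers:
            if word == hexamer:
                hits.append((hexamer, offset))
    return sorted(hits, key=lambda h: h[1])


def compute_utilization(site: ApaSite, evidence: Sequence[TailEvidence]) -> ApaSite:
    """Fill ``site.utilization`` from the tissue labels of its member reads."""
    member = {p for p, _n in site.member_positions}
    mine = [
        ev
        for ev in evidence
        if ev.chrom == site.chrom
        and ev.strand == site.strand
        and ev.cleavage_pos in member
        and (site.gene_id is None or ev.gene_id == site.gene_id)
    ]
    if not mine:
        raise ValueError(
            f"no evidence matches site {site.chrom}:{site.pos}; inconsistent inputs"
        )
    if all(ev.tissue is None for ev in mine):
        site.utilization = {}
        return site
    counts: dict[str, int] = {}
    for ev in mine:
        if ev.tissue is not None:
            counts[ev.tissue] = counts.get(ev.tissue, 0) + 1
    total = sum(counts.values())
    site.utilization = {t: n / total for t, n in sorted(counts.items())}
    return site


@dataclass
class ApaComparison:
    """Coverage of a reference APA-site set by a query set."""

    coverage: Optional[float]  # None when the reference set is empty
    n_reference: int
    n_matched: int
    matched: list[ApaSite]
    unmatched: list[ApaSite]


def compare_apa_sets(
    reference: Sequence[ApaSite],
    query: Sequence[ApaSite],
    window: int = DEFAULT_WINDOW,
) -> ApaComparison:
    """Fraction of reference sites with a query site within ``window`` nt on
    the same chrom/strand (undefined, not 0, for an empty reference)."""
    qpos: dict[tuple[str, str], list[int]] = {}
    for q in query:
        qpos.setdefault((q.chrom, q.strand), []).append(q.pos)
    matched, unmatched = [], []
    for r in reference:
        positions = qpos.get((r.chrom, r.strand), [])
        if any(abs(p - r.pos) <= window for p in positions):
            matched.append(r)
        else:
            unmatched.append(r)
    cov = len(matched) / len(reference) if reference else None
    return ApaComparison(cov, len(reference), len(matched), matched, unmatched)


# ---------------------------------------------------------------------------
# I/O helpers


def write_sites_bed(sites: Sequence[ApaSite], path: str) -> None:
    """BED6; name = gene_id:poly_a_index, score = read support."""
    with open(path, "w") as fh:
        for s in sorted(sites, key=lambda s: (s.chrom, s.pos)):
            name = f"{s.gene_id or '.'}:{s.poly_a_index or '.'}"
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t{name}\t{s.support}\t{s.strand}\n"
            )


def read_sites_bed(path: str) -> list[ApaSite]:
    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, _end, name, score, strand = line.split("\t")[:6]
            gene_id, _, idx = name.partition(":")
            sites.append(
                ApaSite(
                    chrom, int(start), strand.strip(), max(int(score), 2),
                    [(int(start), int(score))],
                    gene_id=None if gene_id == "." else gene_id,
                    poly_a_index=None if idx in (".", "") else int(idx),
                )
            )
    return sites


def sites_table(sites: Sequence[ApaSite]):
    import pandas as pd

    rows = []
    for s in sites:
        rows.append(
            {
                "chrom": s.chrom,
                "pos": s.pos,
                "strand": s.strand,
                "gene_id": s.gene_id or ".",
                "poly_a_index": s.poly_a_index or ".",
                "support": s.support,
                "signals": ";".join(f"{h}@{o}" for h, o in s.signals) or ".",
                "utilization": ";".join(
                    f"{t}={f:.4f}" for t, f in sorted(s.utilization.items())
                )
                or ".",
            }
        )
    return pd.DataFrame(rows)
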