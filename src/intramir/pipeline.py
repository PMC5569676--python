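"""End-to-end helpers wiring annotation, APA calling and seed scanning.

These functions own the genomic <-> UTR coordinate mapping: 3'-UTR pieces
of a gene's summarized model are concatenated in 5'->3' (strand-aware)
order, APA cleavage coordinates become offsets into that sequence, and the
resulting :class:`~intramir.seeds.UTRModel` objects feed the seed scanner
and the network statistics.
"""

from __future__ import annotations

import os
from typing import Mapping, Optional, Sequence

import pysam

from . import apa as _apa
from . import seeds as _seeds
from .annotation import GeneModel, GenomicInterval, _merge_intervals


def merged_utr3(gene: GeneModel) -> list[GenomicInterval]:
    """Union of the gene's annotated 3'-UTR pieces, genomically sorted."""
    return _merge_intervals([iv for _t, iv in gene.utr3_intervals()])


def utr_sequence(gene: GeneModel, genome: pysam.FastaFile) -> str:
    """Sense-strand 5'->3' 3'-UTR sequence of the summarized model."""
    pieces = merged_utr3(gene)
    seq = "".join(genome.fetch(iv.chrom, iv.start, iv.end) for iv in pieces).upper()
    return seq if gene.strand == "+" else _seeds.reverse_complement_dna(seq)


def genomic_to_utr_offset(gene: GeneModel, pos: int) -> Optional[int]:
    """Map a genomic coordinate into the concatenated UTR frame (None when
    the position is not inside the UTR)."""
    pieces = merged_utr3(gene)
    if gene.strand == "-":
        pieces = pieces[::-1]
    offset = 0
    for iv in pieces:
        if iv.start <= pos < iv.end:
            return offset + (pos - iv.start if gene.strand == "+" else iv.end - 1 - pos)
        offset += len(iv)
    return None


def open_genome(path: str) -> pysam.FastaFile:
    if not os.path.exists(path + ".fai"):
        pysam.faidx(path)
    return pysam.FastaFile(path)


def call_apa(
    sam_path: str,
    genes: Sequence[GeneModel],
    genome_path: Optional[str] = None,
    window: int = _apa.DEFAULT_WINDOW,
    min_support: int = _apa.DEFAULT_MIN_SUPPORT,
    tail_min: int = _apa.DEFAULT_TAIL_MIN,
    atn_max: float = _apa.DEFAULT_ATN_MAX,
    pas_span: tuple[int, int] = (10, 40),
) -> list[_apa.ApaSite]:
    """Full APA-calling pipeline: tail evidence -> UTR filter -> clustering
    -> PAS annotation (when a genome is available)."""
    genome = open_genome(genome_path) if genome_path else None
    try:
        evidence = _apa.extract_tail_evidence(
            sam_path, reference=genome, tail_min=tail_min, atn_max=atn_max,
            require_untemplated=genome is not None,
        )
        evidence = _apa.filter_to_utr(evidence, genes)
        sites = _apa.cluster_sites(evidence, window=window, min_support=min_support)
        if genome is not None:
            by_id = {g.gene_id: g for g in genes}
            for site in sites:
                gene = by_id.get(site.gene_id)
                if gene is None:
                    continue
                off = genomic_to_utr_offset(gene, site.pos)
                if off is None:
                    continue
                site.signals = _apa.scan_pas_signals(
                    utr_sequence(gene, genome), off, pas_span
                )
        return sites
    finally:
        if genome is not None:
            genome.close()


def build_utr_models(
    genes: Sequence[GeneModel],
    sites: Sequence[_apa.ApaSite],
    genome: Optional[pysam.FastaFile] = None,
    utr_sequences: Optional[Mapping[str, str]] = None,
) -> dict[str, _seeds.UTRModel]:
    """One APA-segmented UTRModel per gene with an annotated 3'-UTR.

    Sequences come either from a genome FASTA or from a gene_id -> sequence
    mapping (sense strand 5'->3').
    """
    if genome is None and utr_sequences is None:
        raise ValueError("need a genome or explicit UTR sequences")
    by_gene: dict[str, list[int]] = {}
    gene_by_id = {g.gene_id: g for g in genes}
    for s in sites:
        if s.gene_id is None or s.gene_id not in gene_by_id:
            continue
        off = genomic_to_utr_offset(gene_by_id[s.gene_id], s.pos)
        if off is not None:
            by_gene.setdefault(s.gene_id, []).append(off)
    models = {}
    for g in genes:
        if utr_sequences is not None:
            seq = utr_sequences.get(g.gene_id)
            if seq is None:
                continue
        else:
            seq = utr_sequence(g, genome)
        if not seq:
            continue
        positions = sorted(p for p in set(by_gene.get(g.gene_id, [])) if p < len(seq))
        models[g.gene_id] = _seeds.UTRModel(g.gene_id, seq, positions)
    return models


def scan_all(
    utr_models: Mapping[str, _seeds.UTRModel],
    matures: Mapping[str, str],
    noncanonical: bool = False,
    min_score: float = 14.0,
) -> list[_seeds.SeedMatch]:
    """Canonical (and optionally non-canonical) scan of every UTR against
    every mature miRNA."""
    out: list[_seeds.SeedMatch] = []
    for gid in sorted(utr_models):
        utr = utr_models[gid]
        for mid in sorted(matures):
            out.extend(_seeds.scan_canonical(utr, mid, matures[mid]))
            if noncanonical:
                out.extend(
                    _seeds.scan_noncanonical(utr, mid, matures[mid], min_score)
                )
    return out
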