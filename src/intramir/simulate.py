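"""Synthetic study generator: a toy genome with everything planted.

Builds mutually consistent inputs for the whole toolkit — gene models
(GFF3), miRNA annotation (miRBase-style GFF3) with mature sequences
(FASTA), sense-strand 3'-UTR sequences (FASTA), aligned reads (SAM) with
untemplated poly(A) tails planted at known cleavage positions, a
protein-interaction edge list (TSV) and tissue expression matrices (TSV) —
plus a truth manifest (JSON) recording the planted classification labels,
APA sites and seed-site counts.

The generated data emulate the structure of a vertebrate annotation at toy
scale: by default 60% of miRNAs are intragenic (the ballpark reported for
human), UTRs are 200-800 nt, and six tissues (brain, cerebellum, heart,
kidney, liver, testis) label the reads and expression columns.  Accidental
occurrences of planted motifs (seed sites, PAS hexamers, templated A-runs
at cleavage points) are scrubbed from the toy genome so the manifest truth
is exact.  Outputs are byte-identical for identical specs.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pysam

from .network import BackgroundDistribution
from .seeds import seed_of, seed_site

TISSUES = ("brain", "cerebellum", "heart", "kidney", "liver", "testis")
CHROM = "chr1"
PRECURSOR_LEN = 80
MATURE_LEN = 22
READ_ALIGNED = 40
PAS_HEXAMERS = ("AATAAA", "ATTAAA")


@dataclass(frozen=True)
class PlantedApa:
    """A poly(A)-site plant: ``n_reads`` reads with ``tail_length``-nt tails
    cleaving at ``utr_offset`` of gene ``gene_index``'s 3'-UTR."""

    gene_index: int
    utr_offset: int
    n_reads: int
    tail_length: int

    @property
    def expected_called(self) -> bool:
        return self.n_reads >= 2 and self.tail_length >= 4


@dataclass(frozen=True)
class PlantedSeed:
    gene_index: int
    mirna_index: int
    count: int


@dataclass
class FixtureSpec:
    seed: int = 0
    n_genes: int = 30
    n_mirnas: int = 20
    intragenic_fraction: float = 0.6
    utr_length_range: tuple[int, int] = (200, 800)
    planted_apa: Optional[list[PlantedApa]] = None  # None -> default scenario
    planted_seed_sites: Optional[list[PlantedSeed]] = None
    background: BackgroundDistribution = field(
        default_factory=BackgroundDistribution.uniform
    )
    n_tissues: int = 6
    exonic_fraction: float = 0.2  # of intragenic miRNAs
    antisense_fraction: float = 0.2  # of intragenic miRNAs
    minus_strand_fraction: float = 0.3  # of genes
    n_highat_decoy_reads: int = 3  # A/T/N-content >= 0.8, must be filtered out

    def __post_init__(self) -> None:
        lo, hi = self.utr_length_range
        if not (6 <= lo <= hi):
            raise ValueError("utr_length_range must satisfy 6 <= min <= max")
        if not (0 <= self.intragenic_fraction <= 1):
            raise ValueError("intragenic_fraction must lie in [0, 1]")
        if not (1 <= self.n_tissues <= len(TISSUES)):
            raise ValueError(f"n_tissues must be 1..{len(TISSUES)}")


def default_planted_apa(spec: FixtureSpec, utr_lengths: list[int]) -> list[PlantedApa]:
    """Two callable sites in each of the first genes with room, plus
    sub-threshold decoys (single read; 3-nt tail) in the next genes."""
    plants = []
    callable_genes = [i for i, L in enumerate(utr_lengths) if L >= 220][:8]
    for k, gi in enumerate(callable_genes):
        L = utr_lengths[gi]
        o1 = max(50, int(L * 0.35))
        o2 = min(L - 20, o1 + max(90, int(L * 0.35)))
        plants.append(PlantedApa(gi, o1, 3 + (k % 3), 5 + (k % 4)))
        plants.append(PlantedApa(gi, o2, 2 + (k % 2), 4 + (k % 3)))
    decoys = [i for i in range(len(utr_lengths)) if i not in set(callable_genes)]
    if decoys:
        gi = decoys[0]
        plants.append(PlantedApa(gi, max(50, utr_lengths[gi] // 2), 1, 6))  # 1 read
    if len(decoys) > 1:
        gi = decoys[1]
        plants.append(PlantedApa(gi, max(50, utr_lengths[gi] // 2), 3, 3))  # 3-nt tail
    return plants


def default_planted_seeds(spec: FixtureSpec) -> list[PlantedSeed]:
    """miRNA 0's seed in 60% of genes (enrichment); miRNA 1 in one gene."""
    n_target = max(1, int(round(0.6 * spec.n_genes)))
    plants = [PlantedSeed(gi, 0, 1) for gi in range(n_target)]
    if spec.n_mirnas > 1 and spec.n_genes > n_target:
        plants.append(PlantedSeed(n_target, 1, 2))
    return plants


@dataclass
class _Gene:
    gene_id: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    cds: tuple[int, int]
    utr: tuple[int, int]  # genomic
    utr_length: int

    def utr_offset_to_genomic(self, offset: int) -> int:
        if self.strand == "+":
            return self.utr[0] + offset
        return self.utr[1] - 1 - offset


def generate(spec: FixtureSpec, out_dir: str) -> dict:
    """Write the full fixture set into ``out_dir``; returns the manifest."""
    rng = np.random.default_rng(spec.seed)
    tissues = list(TISSUES[: spec.n_tissues])

    lo, hi = spec.utr_length_range
    utr_lengths = [int(rng.integers(lo, hi + 1)) for _ in range(spec.n_genes)]
    planted_apa = (
        spec.planted_apa
        if spec.planted_apa is not None
        else default_planted_apa(spec, utr_lengths)
    )
    planted_seeds = (
        spec.planted_seed_sites
        if spec.planted_seed_sites is not None
        else default_planted_seeds(spec)
    )

    # --- validate before writing anything -------------------------------
    for p in planted_apa:
        if not (0 <= p.gene_index < spec.n_genes):
            raise ValueError(f"planted APA gene index {p.gene_index} out of range")
        if not (45 <= p.utr_offset < utr_lengths[p.gene_index]):
            raise ValueError(
                f"planted APA offset {p.utr_offset} outside UTR of gene "
                f"{p.gene_index} (length {utr_lengths[p.gene_index]}; offsets "
                f"below 45 leave no room for an aligned read + PAS)"
            )
        if p.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
    by_gene: dict[int, list[int]] = {}
    for p in planted_apa:
        by_gene.setdefault(p.gene_index, []).append(p.utr_offset)
    for gi, offs in by_gene.items():
        offs = sorted(offs)
        for a, b in zip(offs, offs[1:]):
            if b - a < 81:
                raise ValueError(
                    f"planted APA offsets {a} and {b} in gene {gi} closer than "
                    "81 nt; they would merge under 40-nt clustering"
                )
    for p in planted_seeds:
        if not (0 <= p.gene_index < spec.n_genes):
            raise ValueError("planted seed gene index out of range")
        if not (0 <= p.mirna_index < spec.n_mirnas):
            raise ValueError("planted seed miRNA index out of range")

    # --- gene layout ----------------------------------------------------
    genes: list[_Gene] = []
    cursor = 500
    for i in range(spec.n_genes):
        L = utr_lengths[i]
        strand = "-" if rng.random() < spec.minus_strand_fraction else "+"
        e1, e2, cds3 = 200, 150, 150
        i1 = int(rng.integers(400, 801))
        i2 = int(rng.integers(400, 801))
        gid = f"G{i:04d}"
        if strand == "+":
            s = cursor
            exon1 = (s, s + e1)
            exon2 = (exon1[1] + i1, exon1[1] + i1 + e2)
            exon3 = (exon2[1] + i2, exon2[1] + i2 + cds3 + L)
            cds = (exon1[0] + 10, exon3[0] + cds3)
            utr = (exon3[0] + cds3, exon3[1])
            exons = [exon1, exon2, exon3]
            end = exon3[1]
        else:
            s = cursor
            exon3 = (s, s + cds3 + L)  # 3'-most exon sits leftmost on '-'
            exon2 = (exon3[1] + i2, exon3[1] + i2 + e2)
            exon1 = (exon2[1] + i1, exon2[1] + i1 + e1)
            cds = (exon3[0] + L, exon1[1] - 10)
            utr = (exon3[0], exon3[0] + L)
            exons = [exon3, exon2, exon1]
            end = exon1[1]
        genes.append(_Gene(gid, strand, s, end, exons, cds, utr, L))
        cursor = end + int(rng.integers(400, 801))

    # --- miRNA placement ------------------------------------------------
    n_intragenic = int(round(spec.n_mirnas * spec.intragenic_fraction))
    n_exonic = int(round(n_intragenic * spec.exonic_fraction))
    mirna_truth: list[dict] = []
    mirna_rows: list[tuple[str, int, int, str]] = []  # (id, start, end, strand)
    host_cycle = list(range(spec.n_genes))
    for j in range(spec.n_mirnas):
        mid = f"mir-{j:03d}"
        if j < n_intragenic:
            host = genes[host_cycle[j % len(host_cycle)]]
            antisense = rng.random() < spec.antisense_fraction
            strand = (
                ("-" if host.strand == "+" else "+") if antisense else host.strand
            )
            if j < n_exonic:
                # inside the middle exon of the host
                e = host.exons[1]
                start = e[0] + 20
                context = "exonic"
                intron_index = None
            else:
                # inside the 5'-most intron (genomic gap adjacent to exon1)
                ex = sorted(host.exons)
                if host.strand == "+":
                    gap = (ex[0][1], ex[1][0])
                else:
                    gap = (ex[1][1], ex[2][0])
                start = gap[0] + (gap[1] - gap[0] - PRECURSOR_LEN) // 2
                context = "intronic"
                intron_index = 1
            truth = {
                "mirna_id": mid,
                "context": context,
                "gene_id": host.gene_id,
                "orientation": "antisense" if antisense else "sense",
                "intron_index": intron_index,
            }
        else:
            # intergenic: midway in the gap before gene (j % n_genes)
            g = genes[j % spec.n_genes]
            prev_end = genes[(j % spec.n_genes) - 1].end if j % spec.n_genes else 0
            start = prev_end + (g.start - prev_end) // 2 - PRECURSOR_LEN // 2
            strand = "+" if rng.random() < 0.5 else "-"
            truth = {
                "mirna_id": mid,
                "context": "intergenic",
                "gene_id": None,
                "orientation": "not-applicable",
                "intron_index": None,
            }
        mirna_rows.append((mid, start, start + PRECURSOR_LEN, strand))
        truth["precursor"] = [start, start + PRECURSOR_LEN]
        truth["strand"] = strand
        mirna_truth.append(truth)

    # --- mature sequences (distinct seeds, no PAS/A-run collisions) ------
    bases = np.array(list("ACGU"))
    probs = np.array([spec.background[b] for b in "ACGU"])
    matures: list[str] = []
    sites_seen: set[str] = set()
    for j in range(spec.n_mirnas):
        while True:
            seq = "".join(rng.choice(bases, size=MATURE_LEN, p=probs))
            site = seed_site(seed_of(seq))
            if site in PAS_HEXAMERS or "AAAA" in site or "TTTT" in site:
                continue
            if site in sites_seen:
                continue
            sites_seen.add(site)
            matures.append(seq)
            break

    # --- genome assembly -------------------------------------------------
    genome_len = cursor + 500
    dna = np.array(list("ACGT"))
    dna_probs = np.array(
        [spec.background[b] for b in ("A", "C", "G", "U")]
    )  # T stands for U
    genome = rng.choice(dna, size=genome_len, p=dna_probs)

    occupied: set[int] = set()

    def occupy(a: int, b: int) -> None:
        occupied.update(range(a, b))

    def write_motif(g: _Gene, offset: int, sense_motif: str) -> int:
        """Write a sense-frame motif into a gene's UTR; returns genomic start."""
        L = len(sense_motif)
        if g.strand == "+":
            start = g.utr[0] + offset
            genome[start : start + L] = list(sense_motif)
        else:
            start = g.utr[1] - offset - L
            genome[start : start + L] = list(_revcomp(sense_motif))
        occupy(start, start + L)
        return start

    # plant seed sites
    seed_truth: list[dict] = []
    for p in planted_seeds:
        g = genes[p.gene_index]
        site = seed_site(seed_of(matures[p.mirna_index]))
        offsets = []
        step = max((g.utr_length - 40) // max(p.count, 1), 12)
        o = 12
        for _ in range(p.count):
            while (
                any(g.utr_offset_to_genomic(o + k) in occupied for k in range(6))
                or _overlaps_planted_apa(o, p.gene_index, planted_apa)
            ):
                o += 7
            if o + 6 > g.utr_length:
                raise ValueError(
                    f"no room to plant seed site in gene {p.gene_index}"
                )
            write_motif(g, o, site)
            offsets.append(o)
            o += step
        seed_truth.append(
            {
                "gene_id": g.gene_id,
                "gene_index": p.gene_index,
                "mirna_index": p.mirna_index,
                "mature_id": f"miR-{p.mirna_index:03d}-5p",
                "site": site,
                "count": p.count,
                "utr_offsets": offsets,
            }
        )

    # plant PAS signals and cleavage guards for called APA sites
    apa_truth: list[dict] = []
    for p in planted_apa:
        g = genes[p.gene_index]
        pos = g.utr_offset_to_genomic(p.utr_offset)
        pas = []
        if p.expected_called:
            hex_offset = 20  # hexamer starts 20 nt upstream of the cleavage
            write_motif(g, p.utr_offset - hex_offset, PAS_HEXAMERS[0])
            pas.append([PAS_HEXAMERS[0], hex_offset])
        # guard: downstream-of-cleavage genomic bases must not be an A/T run
        if g.strand == "+":
            guard = pos + 1
            if guard < genome_len:
                genome[guard] = "C"
                occupy(guard, guard + 1)
        else:
            guard = pos - 1
            if guard >= 0:
                genome[guard] = "G"
                occupy(guard, guard + 1)
        tissue_counts: dict[str, int] = {}
        for k in range(p.n_reads):
            t = tissues[k % len(tissues)]
            tissue_counts[t] = tissue_counts.get(t, 0) + 1
        apa_truth.append(
            {
                "gene_id": g.gene_id,
                "gene_index": p.gene_index,
                "strand": g.strand,
                "utr_offset": p.utr_offset,
                "genomic_pos": pos,
                "n_reads": p.n_reads,
                "tail_length": p.tail_length,
                "expected_called": p.expected_called,
                "pas": pas,
                "tissue_counts": dict(sorted(tissue_counts.items())),
            }
        )

    _scrub_accidental_motifs(
        genome, genes, planted_seeds, matures, rng, occupied
    )

    # poly(A) indices for the expected-called truth sites, 5'->3' per gene
    called = [t for t in apa_truth if t["expected_called"]]
    for gid in sorted({t["gene_id"] for t in called}):
        mine = sorted(
            (t for t in called if t["gene_id"] == gid), key=lambda t: t["utr_offset"]
        )
        for i, t in enumerate(mine, start=1):
            t["poly_a_index"] = i

    # --- write files ------------------------------------------------------
    os.makedirs(out_dir, exist_ok=True)
    files = {
        "genome": "genome.fa",
        "genes": "genes.gff3",
        "mirnas": "mirnas.gff3",
        "matures": "matures.fa",
        "utrs": "utrs.fa",
        "reads": "reads.sam",
        "edges": "ppi.tsv",
        "gene_expression": "gene_expression.tsv",
        "mirna_expression": "mirna_expression.tsv",
        "manifest": "manifest.json",
    }
    paths = {k: os.path.join(out_dir, v) for k, v in files.items()}

    genome_str = "".join(genome)
    _write_fasta(paths["genome"], [(CHROM, genome_str)])
    _write_gene_gff(paths["genes"], genes)
    _write_mirna_gff(paths["mirnas"], mirna_rows)
    _write_fasta(
        paths["matures"],
        [(f"miR-{j:03d}-5p", matures[j]) for j in range(spec.n_mirnas)],
    )
    utr_seqs = []
    for g in genes:
        raw = genome_str[g.utr[0] : g.utr[1]]
        utr_seqs.append((g.gene_id, raw if g.strand == "+" else _revcomp(raw)))
    _write_fasta(paths["utrs"], utr_seqs)
    _write_sam(
        paths["reads"], genome_str, genes, planted_apa, tissues,
        spec.n_highat_decoy_reads, rng,
    )
    _write_edges(paths["edges"], genes, rng)
    host_of = {
        t["mirna_id"]: t["gene_id"] for t in mirna_truth if t["gene_id"] is not None
    }
    expr_truth = _write_expression(
        paths["gene_expression"], paths["mirna_expression"], genes, mirna_truth,
        tissues, rng,
    )

    manifest = {
        "chrom": CHROM,
        "genome_length": genome_len,
        "tissues": tissues,
        "files": files,
        "genes": [
            {
                "gene_id": g.gene_id,
                "strand": g.strand,
                "span": [g.start, g.end],
                "utr": list(g.utr),
                "utr_length": g.utr_length,
            }
            for g in genes
        ],
        "mirnas": mirna_truth,
        "apa_sites": apa_truth,
        "seed_sites": seed_truth,
        "hosts": dict(sorted(host_of.items())),
        "expression": expr_truth,
        "spec": _spec_to_dict(spec),
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def _overlaps_planted_apa(offset: int, gene_index: int, planted) -> bool:
    # keep seed plants clear of cleavage guards and PAS windows
    for p in planted:
        if p.gene_index != gene_index:
            continue
        if p.utr_offset - 46 <= offset + 6 and offset <= p.utr_offset + 2:
            return True
    return False


_RC = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _scrub_accidental_motifs(genome, genes, planted_seeds, matures, rng, occupied):
    """Mutate accidental copies of planted seed sites and PAS hexamers inside
    UTRs so the manifest counts are exact; planted bases are never touched."""
    motifs = {seed_site(seed_of(matures[p.mirna_index])) for p in planted_seeds}
    motifs.update(PAS_HEXAMERS)
    for g in genes:
        lo, hi = g.utr
        for _round in range(20):
            seq = "".join(genome[lo:hi])
            dirty = False
            # scan the sense frame of the UTR
            sense = seq if g.strand == "+" else _revcomp(seq)
            for motif in sorted(motifs):
                start = sense.find(motif)
                while start != -1:
                    gpos = (
                        lo + start if g.strand == "+" else hi - start - len(motif)
                    )
                    span = range(gpos, gpos + len(motif))
                    if not all(p in occupied for p in span):
                        free = [p for p in span if p not in occupied]
                        p = free[len(free) // 2]
                        cur = genome[p]
                        genome[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[cur]
                        dirty = True
                    start = sense.find(motif, start + 1)
            if not dirty:
                break
        else:
            raise RuntimeError("motif scrubbing did not converge")


def _write_fasta(path, records, width=70):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _write_gene_gff(path, genes):
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.start + 1, g.end  # 1-based inclusive on disk
            fh.write(
                f"{CHROM}\tsim\tgene\t{s}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};Name={g.gene_id}\n"
            )
            tid = f"{g.gene_id}.t1"
            fh.write(
                f"{CHROM}\tsim\tmRNA\t{s}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={tid};Parent={g.gene_id}\n"
            )
            for (a, b) in sorted(g.exons):
                fh.write(
                    f"{CHROM}\tsim\texon\t{a + 1}\t{b}\t.\t{g.strand}\t.\t"
                    f"Parent={tid}\n"
                )
            ca, cb = g.cds
            for (a, b) in sorted(g.exons):
                x, y = max(a, ca), min(b, cb)
                if x < y:
                    fh.write(
                        f"{CHROM}\tsim\tCDS\t{x + 1}\t{y}\t.\t{g.strand}\t0\t"
                        f"Parent={tid}\n"
                    )


def _write_mirna_gff(path, mirna_rows):
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for mid, start, end, strand in mirna_rows:
            fh.write(
                f"{CHROM}\tsim\tmiRNA_primary_transcript\t{start + 1}\t{end}\t.\t"
                f"{strand}\t.\tID={mid};Name={mid}\n"
            )
            mat = f"miR-{mid.split('-')[1]}-5p"
            fh.write(
                f"{CHROM}\tsim\tmiRNA\t{start + 1}\t{start + MATURE_LEN}\t.\t"
                f"{strand}\t.\tID={mat};Name={mat};Derives_from={mid}\n"
            )


def _write_sam(path, genome, genes, planted_apa, tissues, n_highat, rng):
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": CHROM, "LN": len(genome)}],
        "RG": [{"ID": t, "SM": t} for t in tissues],
    }
    with pysam.AlignmentFile(path, "w", header=pysam.AlignmentHeader.from_dict(header)) as out:
        serial = 0
        for p in planted_apa:
            g = genes[p.gene_index]
            pos = g.utr_offset_to_genomic(p.utr_offset)
            for k in range(p.n_reads):
                serial += 1
                a = pysam.AlignedSegment(out.header)
                a.query_name = f"read{serial:05d}"
                a.mapping_quality = 60
                a.reference_id = 0
                a.set_tag("RG", tissues[k % len(tissues)])
                t = p.tail_length
                if g.strand == "+":
                    ref_start = pos - READ_ALIGNED + 1
                    body = genome[ref_start : pos + 1]
                    a.query_sequence = body + "A" * t
                    a.cigarstring = f"{READ_ALIGNED}M{t}S"
                    a.reference_start = ref_start
                    a.flag = 0
                else:
                    body = genome[pos : pos + READ_ALIGNED]
                    a.query_sequence = "T" * t + body
                    a.cigarstring = f"{t}S{READ_ALIGNED}M"
                    a.reference_start = pos
                    a.flag = 16
                out.write(a)
        # high-A/T decoy reads: big tails, but the content filter must drop
        # them; placed well clear (>40 nt) of every planted site
        g = genes[-1]
        pos = g.utr_offset_to_genomic(50)
        for k in range(n_highat):
            serial += 1
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"decoyAT{serial:05d}"
            a.mapping_quality = 60
            a.reference_id = 0
            a.set_tag("RG", tissues[k % len(tissues)])
            body = "A" * (READ_ALIGNED - 5) + "CGCGC"
            if g.strand == "+":
                a.query_sequence = body + "A" * 8
                a.cigarstring = f"{READ_ALIGNED}M8S"
                a.reference_start = pos - READ_ALIGNED + 1
                a.flag = 0
            else:
                a.query_sequence = "T" * 8 + body
                a.cigarstring = f"8S{READ_ALIGNED}M"
                a.reference_start = pos
                a.flag = 16
            out.write(a)


def _write_edges(path, genes, rng):
    ids = [g.gene_id for g in genes]
    sources = ("STRING", "BioGRID", "HPRD")
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tscore\tsource\tevidence\n")
        n = 3 * len(ids)
        for k in range(n):
            i, j = rng.choice(len(ids), size=2, replace=False)
            score = int(rng.integers(100, 1000))
            fh.write(
                f"{ids[i]}\t{ids[j]}\t{score}\t{sources[k % 3]}\tsim\n"
            )
        # deliberate dirt: a self-loop and a duplicated pair
        fh.write(f"{ids[0]}\t{ids[0]}\t999\tSTRING\tself\n")
        fh.write(f"{ids[0]}\t{ids[1]}\t700\tSTRING\tdup_low\n")
        fh.write(f"{ids[1]}\t{ids[0]}\t900\tSTRING\tdup_high\n")


def _write_expression(gene_path, mirna_path, genes, mirna_truth, tissues, rng):
    gene_vals = {}
    for g in genes:
        gene_vals[g.gene_id] = np.round(rng.lognormal(2.0, 1.0, len(tissues)), 3)
    truth = []
    mirna_vals = {}
    for t in mirna_truth:
        mid = t["mirna_id"]
        if t["gene_id"] is not None:
            # exact monotone transform of the host row -> Spearman rho = 1
            mirna_vals[mid] = np.round(0.5 * gene_vals[t["gene_id"]], 4)
            truth.append({"mirna_id": mid, "gene_id": t["gene_id"], "rho": 1.0})
        else:
            mirna_vals[mid] = np.round(rng.lognormal(1.0, 1.0, len(tissues)), 3)

    def dump(path, vals):
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(tissues) + "\n")
            for rid, row in vals.items():
                fh.write(rid + "\t" + "\t".join(f"{v:.4f}" for v in row) + "\n")

    dump(gene_path, gene_vals)
    dump(mirna_path, mirna_vals)
    return truth


def _spec_to_dict(spec: FixtureSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["background"] = dict(spec.background.probs)
    if spec.planted_apa is not None:
        d["planted_apa"] = [dataclasses.asdict(p) for p in spec.planted_apa]
    if spec.planted_seed_sites is not None:
        d["planted_seed_sites"] = [
            dataclasses.asdict(p) for p in spec.planted_seed_sites
        ]
    d["utr_length_range"] = list(spec.utr_length_range)
    return d
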