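"""Seed-site scanning over APA-segmented 3'-UTRs.

A canonical site is the exact Watson-Crick reverse complement (as DNA) of
the miRNA seed, bases 2-7 of the mature sequence.  UTRs are held as
sense-strand DNA 5'->3'; APA cleavage offsets segment each UTR into nested
prefix isoforms, and every match records the smallest poly(A) index whose
isoform still contains the full 6-mer site — the basis for
isoform-specific target filtering.  A Smith-Waterman local scan of the
reverse-complemented full mature sequence picks up non-canonical sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

SEED_LENGTH = 6

_RNA_TO_DNA_RC = str.maketrans("ACGUN", "TGCAN")
_DNA_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement_dna(seq: str) -> str:
    return seq.upper().translate(_DNA_RC)[::-1]


def seed_of(mature_sequence: str) -> str:
    """Bases 2-7 (1-based) of a mature miRNA sequence — the seed region."""
    seq = mature_sequence.upper().replace("T", "U")
    if len(seq) < 7:
        raise ValueError(f"mature sequence {mature_sequence!r} shorter than 7 nt")
    return seq[1:7]


def seed_site(seed: str) -> str:
    """The DNA 6-mer a canonical site shows on the UTR sense strand: the
    reverse complement of the (RNA) seed."""
    seed = seed.upper().replace("T", "U")
    if len(seed) != SEED_LENGTH:
        raise ValueError("seed must be 6 nt")
    return seed.translate(_RNA_TO_DNA_RC)[::-1]


@dataclass
class UTRModel:
    """A 3'-UTR with its APA segmentation.

    ``apa_positions`` are 0-based cleavage offsets into ``sequence``, sorted
    5'->3', one per APA site in poly(A)-index order; isoform k is the prefix
    [0, apa_positions[k-1]).
    """

    gene_id: str
    sequence: str
    apa_positions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        pos = list(self.apa_positions)
        if pos != sorted(set(pos)):
            raise ValueError("apa_positions must be strictly increasing")
        if pos and not (0 <= pos[0] and pos[-1] < len(self.sequence)):
            raise ValueError("apa_positions must fall inside the sequence")
        self.apa_positions = pos

    @property
    def isoform_segments(self) -> list[tuple[int, int]]:
        return [(0, p) for p in self.apa_positions]

    def min_poly_a_index(self, offset: int, length: int = SEED_LENGTH) -> Optional[int]:
        """Smallest 1-based isoform index whose prefix contains
        [offset, offset+length); None when only the full-length UTR does."""
        for k, p in enumerate(self.apa_positions, start=1):
            if offset + length <= p:
                return k
        return None


@dataclass
class SeedMatch:
    mature_id: str
    gene_id: str
    offset: int
    seed: str  # RNA 6-mer (bases 2-7) for canonical; seed of the mature otherwise
    site: str  # DNA string found in the UTR
    match_type: str  # canonical | noncanonical
    min_poly_a_index: Optional[int] = None
    score: Optional[float] = None
    energy: Optional[float] = None


def scan_canonical(
    utr: UTRModel, mature_id: str, mature_sequence: str
) -> list[SeedMatch]:
    """Every offset where the UTR 6-mer equals the reverse complement of the
    seed (N never matches)."""
    seed = seed_of(mature_sequence)
    target = seed_site(seed)
    seq = utr.sequence
    matches = []
    start = seq.find(target)
    while start != -1:
        matches.append(
            SeedMatch(
                mature_id, utr.gene_id, start, seed, target, "canonical",
                utr.min_poly_a_index(start),
            )
        )
        start = seq.find(target, start + 1)
    return matches


def _smith_waterman_hits(
    target: str, query: str, match: float, mismatch: float, gap: float, min_score: float
) -> list[tuple[int, int, float]]:
    """All non-overlapping local-alignment hits of query in target scoring
    >= min_score, as (target_start, target_end, score), best first.

    Linear gap penalty; ties in the traceback prefer diagonal moves.
    """
    n, m = len(target), len(query)
    if n == 0 or m == 0:
        return []
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    H = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        sub = np.where(q == t[i - 1], match, mismatch)
        row = H[i]
        prev = H[i - 1]
        for j in range(1, m + 1):
            row[j] = max(0.0, prev[j - 1] + sub[j - 1], prev[j] + gap, row[j - 1] + gap)

    hits: list[tuple[int, int, float]] = []
    used = np.zeros(n, dtype=bool)
    order = np.argsort(H[1:, :].ravel())[::-1]
    for flat in order:
        score = H[1 + flat // (m + 1), flat % (m + 1)]
        if score < min_score:
            break
        i, j = 1 + int(flat) // (m + 1), int(flat) % (m + 1)
        # traceback to the local start
        ii, jj = i, j
        while H[ii, jj] > 0:
            diag = H[ii - 1, jj - 1] + (match if ii >= 1 and jj >= 1 and t[ii - 1] == q[jj - 1] else mismatch)
            if ii >= 1 and jj >= 1 and np.isclose(H[ii, jj], diag):
                ii, jj = ii - 1, jj - 1
            elif np.isclose(H[ii, jj], H[ii - 1, jj] + gap):
                ii -= 1
            elif np.isclose(H[ii, jj], H[ii, jj - 1] + gap):
                jj -= 1
            else:
                break
        start, end = ii, i
        if end <= start or used[start:end].any():
            continue
        used[start:end] = True
        hits.append((start, end, float(score)))
    hits.sort(key=lambda h: (-h[2], h[0]))
    return hits


def scan_noncanonical(
    utr: UTRModel,
    mature_id: str,
    mature_sequence: str,
    min_score: float = 14.0,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> list[SeedMatch]:
    """Local alignment of the reverse-complemented mature sequence (as DNA)
    against the UTR; regions scoring >= min_score that are not already
    canonical 6-mer seed matches are reported as non-canonical sites."""
    mature_dna = mature_sequence.upper().replace("U", "T")
    query = reverse_complement_dna(mature_dna)
    canonical_offsets = {m.offset for m in scan_canonical(utr, mature_id, mature_sequence)}
    out = []
    for start, end, score in _smith_waterman_hits(
        utr.sequence, query, match, mismatch, gap, min_score
    ):
        if (end - start) == SEED_LENGTH and start in canonical_offsets:
            continue
        out.append(
            SeedMatch(
                mature_id, utr.gene_id, start, seed_of(mature_sequence),
                utr.sequence[start:end], "noncanonical",
                utr.min_poly_a_index(start, end - start), score=score,
            )
        )
    return out


def filter_matches(
    matches: Sequence[SeedMatch],
    by_poly_a_index: Optional[int] = None,
    by_mirna: Optional[str] = None,
    by_min_score: Optional[float] = None,
) -> list[SeedMatch]:
    """Conjunctive filtering.  The poly(A)-index filter keeps matches present
    in the requested isoform, i.e. min_poly_a_index <= index."""
    out = list(matches)
    if by_poly_a_index is not None:
        out = [
            m
            for m in out
            if m.min_poly_a_index is not None and m.min_poly_a_index <= by_poly_a_index
        ]
    if by_mirna is not None:
        out = [m for m in out if m.mature_id == by_mirna]
    if by_min_score is not None:
        out = [m for m in out if m.score is not None and m.score >= by_min_score]
    return out


def matches_table(matches: Sequence[SeedMatch]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "mature_id": m.mature_id,
                "gene_id": m.gene_id,
                "offset": m.offset,
                "seed": m.seed,
                "site": m.site,
                "match_type": m.match_type,
                "min_poly_a_index": m.min_poly_a_index if m.min_poly_a_index else ".",
                "score": m.score if m.score is not None else ".",
            }
            for m in matches
        ]
    )
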