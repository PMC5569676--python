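"""Network-level miRNA seed-enrichment statistics and host-gene set tests.

For a gene set X (e.g. a protein-interaction neighbourhood) and a miRNA
seed S, the chance that S's site occurs in a random sequence is
P(S) = prod_i P(N_i | D) under a background nucleotide distribution D.  The
probability that a UTR of length N contains the site at least r times is
the binomial upper tail over L = N - 6 + 1 placements, and the expected
number of targeted genes E(X_t) is the sum of those probabilities over the
set.  E(X_t) is contrasted with the observed count O(X_t) of genes whose
UTR carries >=1 canonical seed match, via Fisher's exact test and a
log-odds score

    score = ln[ (O * (|X| - E)) / (E * (|X| - O)) ]

which is 0 at O = E, positive for overrepresented seeds and negative for
underrepresented ones.  The same Fisher machinery tests whether host genes
of intragenic miRNAs are over- or underrepresented in a submitted gene
list against a background universe.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from . import seeds as _seeds

SEED_LENGTH = _seeds.SEED_LENGTH
RNA_ALPHABET = ("A", "C", "G", "U")
_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}


@dataclass(frozen=True)
class BackgroundDistribution:
    """Background nucleotide distribution D over the RNA alphabet."""

    probs: Mapping[str, float]

    def __post_init__(self) -> None:
        p = dict(self.probs)
        if set(p) != set(RNA_ALPHABET):
            raise ValueError("background must define A, C, G and U")
        if any(v < 0 for v in p.values()):
            raise ValueError("negative probability")
        if abs(sum(p.values()) - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")
        object.__setattr__(self, "probs", p)

    @classmethod
    def uniform(cls) -> "BackgroundDistribution":
        return cls({b: 0.25 for b in RNA_ALPHABET})

    def __getitem__(self, base: str) -> float:
        return self.probs[base]


def estimate_background(utr_sequences: Iterable[str]) -> BackgroundDistribution:
    """Per-nucleotide frequencies over the concatenated UTR set (T counted
    as U, N excluded)."""
    counts = {b: 0 for b in RNA_ALPHABET}
    for seq in utr_sequences:
        s = seq.upper().replace("T", "U")
        for b in RNA_ALPHABET:
            counts[b] += s.count(b)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no usable (non-N) characters in the UTR set")
    return BackgroundDistribution({b: n / total for b, n in counts.items()})


def seed_probability(
    seed: str,
    background: BackgroundDistribution,
    composition: str = "seed",
) -> float:
    """P(S) = prod_i P(N_i | D) over the seed's nucleotides.

    ``composition="site"`` evaluates the product over the complementary
    target-site nucleotides instead (an alternative reading of the model;
    identical under any strand-symmetric background).
    """
    s = seed.upper().replace("T", "U")
    if any(b not in _COMPLEMENT for b in s):
        raise ValueError(f"seed {seed!r} contains non-RNA characters")
    if composition == "site":
        s = "".join(_COMPLEMENT[b] for b in s)
    elif composition != "seed":
        raise ValueError("composition must be 'seed' or 'site'")
    p = 1.0
    for b in s:
        p *= background[b]
    return p


def gene_hit_probability(
    utr_length: int, p_seed: float, r: int = 1, seed_length: int = SEED_LENGTH
) -> float:
    """Probability that the seed site occurs >= r times in a random sequence.

    L = utr_length - seed_length + 1 placements (0 when the UTR is shorter
    than the seed); the result is the binomial upper tail
    1 - sum_{i<r} C(L,i) p^i (1-p)^(L-i).  r = 1 uses the cancellation-free
    form 1 - (1-p)^L via expm1/log1p; r > 1 sums the upper tail directly so
    tiny probabilities keep full relative precision.
    """
    if not (0.0 <= p_seed <= 1.0):
        raise ValueError("p_seed must lie in [0, 1]")
    if r < 1:
        raise ValueError("r must be >= 1")
    L = max(utr_length - seed_length + 1, 0)
    if L == 0:
        return 0.0
    if r > L:
        return 0.0 if p_seed < 1.0 else 1.0
    if p_seed == 0.0:
        return 0.0
    if p_seed == 1.0:
        return 1.0
    if r == 1:
        return -math.expm1(L * math.log1p(-p_seed))
    ks = np.arange(r, L + 1)
    return float(math.fsum(stats.binom.pmf(ks, L, p_seed)))


@dataclass
class GeneSetMember:
    gene_id: str
    utr_length: int


@dataclass
class GeneSet:
    """A gene set with UTR lengths and precomputed per-miRNA seed matches."""

    members: list[GeneSetMember]
    matches: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [m.gene_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene ids in gene set")

    def __len__(self) -> int:
        return len(self.members)

    @classmethod
    def from_utrs(
        cls, utr_sequences: Mapping[str, str], matures: Mapping[str, str]
    ) -> "GeneSet":
        """Build from gene_id -> UTR sequence and mature_id -> RNA sequence,
        scanning every UTR for each miRNA's canonical seed site."""
        members = [
            GeneSetMember(g, len(seq)) for g, seq in sorted(utr_sequences.items())
        ]
        matches: dict[str, frozenset[str]] = {}
        for mid, mat in matures.items():
            hit = set()
            for g, seq in utr_sequences.items():
                utr = _seeds.UTRModel(g, seq)
                if _seeds.scan_canonical(utr, mid, mat):
                    hit.add(g)
            matches[mid] = frozenset(hit)
        return cls(members, matches)

    def observed(self, mature_id: str) -> int:
        return len(self.matches.get(mature_id, frozenset()))


def expected_targets(
    gene_set: GeneSet, p_seed: float, r: int = 1
) -> float:
    """E(X_t): sum over members of the per-gene hit probability."""
    if not gene_set.members:
        raise ValueError("gene set is empty")
    return math.fsum(
        gene_hit_probability(m.utr_length, p_seed, r) for m in gene_set.members
    )


# ---------------------------------------------------------------------------
# Fisher's exact test

_ALTERNATIVES = ("two-sided", "greater", "less")
_TIE_EPS = 1e-7  # relative slack when comparing outcome probabilities


def fisher_pvalues(n: int, r1: int, c1: int):
    """p-values for every 2x2 table with margins (row1 = r1, col1 = c1,
    total = n), as (support, two_sided, greater, less) arrays over the
    possible top-left cell values.

    Two-sided: sum of the probabilities of all outcomes no more probable
    than the observed one (probabilities equal up to a small relative
    slack count as ties).  Built on scipy.stats.hypergeom so a whole
    margin set is evaluated in one vectorized call.
    """
    if not (0 <= r1 <= n and 0 <= c1 <= n):
        raise ValueError("margins must lie within the table total")
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    order = np.argsort(pmf, kind="stable")
    csum = np.cumsum(pmf[order])
    idx = np.searchsorted(pmf[order], pmf * (1.0 + _TIE_EPS), side="right")
    two_sided = np.minimum(csum[idx - 1], 1.0)
    greater = np.minimum(np.cumsum(pmf[::-1])[::-1], 1.0)
    less = np.minimum(np.cumsum(pmf), 1.0)
    return support, two_sided, greater, less


def fisher_exact(table: Sequence[Sequence[int]], alternative: str = "two-sided") -> float:
    """Exact hypergeometric p-value for a 2x2 table ([[a, b], [c, d]])."""
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    n = a + b + c + d
    if n == 0:
        return 1.0
    support, two_sided, greater, less = fisher_pvalues(n, a + b, a + c)
    i = a - support[0]
    return float({"two-sided": two_sided, "greater": greater, "less": less}[alternative][i])


# ---------------------------------------------------------------------------
# the network score


@dataclass
class NetworkScoreResult:
    mature_id: str
    seed: str
    p_seed: float
    expected: float
    observed: int
    set_size: int
    odds_ratio: float
    fisher_p: float
    score: float
    fisher_q: Optional[float] = None  # BH-adjusted, filled by rank_mirnas


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def log_odds_score(
    observed: float, expected: float, size: int, log_base: float = math.e
) -> float:
    """The log-odds contrast of observed vs expected targeted genes in a set
    of ``size`` genes: log[(O * (size - E)) / (E * (size - O))].

    Zero exactly at O = E, positive for overrepresentation, negative for
    underrepresentation.  When any of the four terms is zero the
    Haldane-Anscombe correction (add 0.5 to all four) keeps the score
    finite, except for E = 0 with O > 0 which returns +inf.
    """
    if size <= 0:
        raise ValueError("set size must be positive")
    o, e = float(observed), float(expected)
    if e == 0.0 and o > 0.0:
        return math.inf
    no, ne = size - o, size - e
    if min(o, e, no, ne) == 0.0:
        o, e, no, ne = o + 0.5, e + 0.5, no + 0.5, ne + 0.5  # Haldane-Anscombe
    return math.log((o * ne) / (e * no)) / math.log(log_base)


def network_score(
    gene_set: GeneSet,
    mature_id: str,
    seed: str,
    background: BackgroundDistribution,
    r: int = 1,
    alternative: str = "two-sided",
    log_base: float = math.e,
) -> NetworkScoreResult:
    """Score one miRNA against a gene set: expected vs observed targeting."""
    size = len(gene_set)
    if size == 0:
        raise ValueError("gene set is empty")
    p_seed = seed_probability(seed, background)
    expected = expected_targets(gene_set, p_seed, r)
    observed = gene_set.observed(mature_id)

    if expected == 0.0 and observed > 0:
        score = math.inf
        odds_ratio = math.inf
        e_int = 1
    else:
        lo = log_odds_score(observed, expected, size)
        score = lo / math.log(log_base)
        odds_ratio = math.exp(lo)
        e_int = min(max(_round_half_away(expected), 0), size)
        if e_int == 0 and observed > 0:
            e_int = 1
    fisher_p = fisher_exact(
        [[observed, size - observed], [e_int, size - e_int]], alternative
    )
    return NetworkScoreResult(
        mature_id, seed, p_seed, expected, observed, size, odds_ratio, fisher_p, score
    )


def rank_mirnas(
    gene_set: GeneSet,
    matures: Sequence[tuple[str, str]],
    background: BackgroundDistribution,
    r: int = 1,
    alternative: str = "two-sided",
) -> list[NetworkScoreResult]:
    """One NetworkScoreResult per mature miRNA, best (highest score) first;
    ties broken by Fisher p ascending, then mature_id.  BH-adjusted p-values
    are attached as ``fisher_q``."""
    results = [
        network_score(gene_set, mid, _seeds.seed_of(seq), background, r, alternative)
        for mid, seq in matures
    ]
    if results:
        ps = np.array([res.fisher_p for res in results])
        qs = stats.false_discovery_control(ps, method="bh")
        for res, q in zip(results, qs):
            res.fisher_q = float(q)
    results.sort(key=lambda res: (-res.score, res.fisher_p, res.mature_id))
    return results


# ---------------------------------------------------------------------------
# host-gene over/underrepresentation


@dataclass
class HostEnrichmentResult:
    list_size: int
    hosts_in_list: int
    background_size: int
    hosts_in_background: int
    fisher_p: float
    direction: str  # over | under | none


def host_enrichment(
    gene_list: Sequence[str],
    host_genes: Iterable[str],
    background: Iterable[str],
    alternative: str = "two-sided",
) -> HostEnrichmentResult:
    """Fisher's exact test for host genes in a submitted gene list against a
    background universe."""
    bg = set(background)
    hosts = set(host_genes) & bg
    genes = []
    for g in dict.fromkeys(gene_list):  # deduplicate, keep order
        if g in bg:
            genes.append(g)
        else:
            warnings.warn(f"gene {g} not in background universe; dropped")
    if not genes:
        raise ValueError("gene list is empty (or disjoint from the background)")
    in_list = set(genes)
    a = len(in_list & hosts)
    b = len(in_list) - a
    rest = bg - in_list
    c = len(rest & hosts)
    d = len(rest) - c
    p = fisher_exact([[a, b], [c, d]], alternative)
    frac_list = a / len(in_list)
    frac_bg = len(hosts) / len(bg)
    if frac_list > frac_bg:
        direction = "over"
    elif frac_list < frac_bg:
        direction = "under"
    else:
        direction = "none"
    return HostEnrichmentResult(len(in_list), a, len(bg), len(hosts), p, direction)


# ---------------------------------------------------------------------------
# protein-interaction edges


@dataclass
class PPIEdge:
    gene_a: str
    gene_b: str
    score: float
    source: str
    evidence: Optional[str] = None


def read_edges(path: str) -> list[PPIEdge]:
    """TSV: gene_a, gene_b, score, source[, evidence]; a header line whose
    third column is non-numeric is skipped."""
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise ValueError(f"edge line needs >=4 columns: {line!r}")
            try:
                score = float(cols[2])
            except ValueError:
                continue  # header
            edges.append(
                PPIEdge(cols[0], cols[1], score, cols[3], cols[4] if len(cols) > 4 else None)
            )
    return edges


def filter_edges(
    edges: Sequence[PPIEdge],
    min_score: Optional[float] = None,
    sources: Optional[Iterable[str]] = None,
    gene_universe: Optional[Iterable[str]] = None,
) -> list[PPIEdge]:
    """Conjunctive edge filters (min_score inclusive); self-loops removed and
    duplicate undirected pairs collapsed keeping the maximum score."""
    src = set(sources) if sources is not None else None
    uni = set(gene_universe) if gene_universe is not None else None
    best: dict[tuple[str, str], PPIEdge] = {}
    for e in edges:
        if e.gene_a == e.gene_b:
            continue
        if min_score is not None and e.score < min_score:
            continue
        if src is not None and e.source not in src:
            continue
        if uni is not None and (e.gene_a not in uni or e.gene_b not in uni):
            continue
        key = (min(e.gene_a, e.gene_b), max(e.gene_a, e.gene_b))
        if key not in best or e.score > best[key].score:
            best[key] = e
    return [best[k] for k in sorted(best)]


def results_table(results: Sequence[NetworkScoreResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "mature_id": res.mature_id,
                "seed": res.seed,
                "p_seed": res.p_seed,
                "expected": res.expected,
                "observed": res.observed,
                "set_size": res.set_size,
                "odds_ratio": res.odds_ratio,
                "score": res.score,
                "fisher_p": res.fisher_p,
                "fisher_q": res.fisher_q,
            }
            for res in results
        ]
    )
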