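"""Seed-occurrence model, Fisher's exact test, network score, host sets."""

import math
from fractions import Fraction

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from intramir.network import (
    BackgroundDistribution,
    GeneSet,
    GeneSetMember,
    PPIEdge,
    estimate_background,
    expected_targets,
    filter_edges,
    fisher_exact,
    gene_hit_probability,
    host_enrichment,
    log_odds_score,
    network_score,
    rank_mirnas,
    seed_probability,
)

UNIFORM = BackgroundDistribution.uniform()


# ---------------------------------------------------------------------------
# P(S)


def test_seed_probability_uniform_background():
    assert seed_probability("AGCUUA", UNIFORM) == pytest.approx(0.25**6, rel=1e-15)


def test_seed_probability_skewed_background():
    bg = BackgroundDistribution({"A": 0.3, "C": 0.2, "G": 0.2, "U": 0.3})
    assert seed_probability("AAAAAA", bg) == pytest.approx(0.3**6, rel=1e-15)
    # site-composition variant multiplies over the complementary bases
    assert seed_probability("AAAAAA", bg, composition="site") == pytest.approx(
        0.3**6, rel=1e-15
    )
    assert seed_probability("GGGGGG", bg, composition="site") == pytest.approx(
        0.2**6, rel=1e-15
    )


def test_seed_probability_annihilates_on_zero_base():
    bg = BackgroundDistribution({"A": 0.0, "C": 0.4, "G": 0.3, "U": 0.3})
    assert seed_probability("ACGCGC", bg) == 0.0


def test_seed_probability_rejects_bad_alphabet():
    with pytest.raises(ValueError):
        seed_probability("AXGCUA", UNIFORM)


# ---------------------------------------------------------------------------
# P(x_t): at-least-r occurrences


def exact_hit_probability(utr_length, p, r):
    """Oracle: exact rational evaluation of the binomial sum."""
    L = max(utr_length - 6 + 1, 0)
    if L == 0 or r > L:
        return 0.0
    pf = Fraction(p)
    s = sum(
        Fraction(math.comb(L, i)) * pf**i * (1 - pf) ** (L - i) for i in range(r)
    )
    return float(1 - s)


def test_hit_probability_closed_form_r1():
    assert gene_hit_probability(7, 0.5, 1) == pytest.approx(0.75, rel=1e-15)


def test_hit_probability_zero_when_utr_shorter_than_seed():
    assert gene_hit_probability(5, 0.5) == 0.0


def test_hit_probability_r2_matches_exact_rational():
    got = gene_hit_probability(106, 0.01, 2)
    want = exact_hit_probability(106, 0.01, 2)
    assert got == pytest.approx(want, rel=1e-12)


@pytest.mark.parametrize("r", [1, 2, 3])
@pytest.mark.parametrize("p", [1e-4, 1e-2, 0.5])
def test_hit_probability_monotone_in_length(p, r):
    vals = [gene_hit_probability(L, p, r) for L in range(6, 120)]
    # non-decreasing up to float round-off in the tail sum
    assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


def test_hit_probability_validates_inputs():
    with pytest.raises(ValueError):
        gene_hit_probability(100, 1.5)
    with pytest.raises(ValueError):
        gene_hit_probability(100, 0.5, r=0)


def test_expected_targets_additive_and_homogeneous():
    gs = GeneSet([GeneSetMember("a", 106), GeneSetMember("b", 56)])
    want = gene_hit_probability(106, 0.01) + gene_hit_probability(56, 0.01)
    assert expected_targets(gs, 0.01) == pytest.approx(want, rel=1e-14)
    many = GeneSet([GeneSetMember(f"g{i}", 106) for i in range(100)])
    assert expected_targets(many, 0.01) == pytest.approx(
        100 * gene_hit_probability(106, 0.01), rel=1e-12
    )
    short = GeneSet([GeneSetMember("a", 5), GeneSetMember("b", 3)])
    assert expected_targets(short, 0.5) == 0.0


# ---------------------------------------------------------------------------
# Fisher's exact test


def fisher_oracle(a, b, c, d, alternative):
    """Exact-integer enumeration over all tables with fixed margins."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    if n == 0:
        return 1.0
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    num = {k: math.comb(c1, k) * math.comb(n - c1, r1 - k) for k in range(lo, hi + 1)}
    den = math.comb(n, r1)
    if alternative == "greater":
        return sum(v for k, v in num.items() if k >= a) / den
    if alternative == "less":
        return sum(v for k, v in num.items() if k <= a) / den
    return sum(v for v in num.values() if v <= num[a]) / den


def test_fisher_diagonal_table_two_sided_is_one_third():
    assert fisher_exact([[2, 0], [0, 2]]) == pytest.approx(1 / 3, rel=1e-12)


def test_fisher_degenerate_zero_table():
    assert fisher_exact([[0, 0], [0, 0]]) == 1.0


def test_fisher_rejects_negative_entries():
    with pytest.raises(ValueError):
        fisher_exact([[1, -1], [0, 2]])


@settings(max_examples=200)
@given(st.tuples(*[st.integers(0, 15)] * 4))
def test_fisher_matches_enumeration_and_scipy(cells):
    a, b, c, d = cells
    for alt, scipy_alt in [("two-sided", "two-sided"), ("greater", "greater"), ("less", "less")]:
        p = fisher_exact([[a, b], [c, d]], alt)
        assert p == pytest.approx(fisher_oracle(a, b, c, d, alt), abs=1e-12)
        # independent library cross-check
        assert p == pytest.approx(
            scipy.stats.fisher_exact([[a, b], [c, d]], alternative=scipy_alt)[1],
            abs=1e-9,
        )
        # one-sided p-values are at least the observed table's probability
        if a + b + c + d > 0:
            point = fisher_oracle(a, b, c, d, "greater") + fisher_oracle(
                a, b, c, d, "less"
            ) - 1.0
            assert p >= point - 1e-12


# ---------------------------------------------------------------------------
# the network score


def gs_with_matches(size, observed, utr_length=300):
    members = [GeneSetMember(f"g{i}", utr_length) for i in range(size)]
    matches = {"m": frozenset(f"g{i}" for i in range(observed))}
    return GeneSet(members, matches)


def test_score_zero_at_equality():
    assert log_odds_score(5, 5.0, 10) == 0.0
    assert log_odds_score(0, 0.0, 10) == 0.0  # Haldane-corrected, still 0


def test_score_example_values():
    assert log_odds_score(8, 4.0, 10) == pytest.approx(math.log(6.0), rel=1e-12)
    assert log_odds_score(2, 4.0, 10) == pytest.approx(math.log(0.375), rel=1e-12)


def test_score_sign_matches_observed_minus_expected():
    rng = np.random.default_rng(11)
    for _ in range(500):
        size = int(rng.integers(2, 80))
        e = float(rng.uniform(0.05, size - 0.05))
        o = int(rng.integers(0, size + 1))
        s = log_odds_score(o, e, size)
        if o > e:
            assert s > 0
        elif o < e:
            assert s < 0
        else:
            assert s == 0


def test_score_antisymmetric_around_complements():
    rng = np.random.default_rng(12)
    for _ in range(200):
        size = int(rng.integers(2, 60))
        e = float(rng.uniform(0.5, size - 0.5))
        o = int(rng.integers(0, size + 1))
        assert log_odds_score(o, e, size) == pytest.approx(
            -log_odds_score(size - o, size - e, size), abs=1e-12
        )


def test_network_score_infinite_when_expected_zero_but_observed():
    gs = GeneSet([GeneSetMember("a", 5), GeneSetMember("b", 5)],
                 {"m": frozenset({"a"})})
    res = network_score(gs, "m", "AAAAAA", UNIFORM)
    assert math.isinf(res.score) and res.score > 0
    assert 0.0 < res.fisher_p <= 1.0


def test_network_score_result_fields_consistent():
    gs = gs_with_matches(10, 8)
    bg = BackgroundDistribution({"A": 0.25, "C": 0.25, "G": 0.25, "U": 0.25})
    res = network_score(gs, "m", "AGCUUA", bg)
    assert res.observed == 8 and res.set_size == 10
    assert res.p_seed == pytest.approx(0.25**6)
    assert res.score == pytest.approx(
        log_odds_score(res.observed, res.expected, res.set_size)
    )
    assert math.exp(res.score) == pytest.approx(res.odds_ratio)


def test_empty_gene_set_errors():
    with pytest.raises(ValueError):
        network_score(GeneSet([]), "m", "AAAAAA", UNIFORM)


# ---------------------------------------------------------------------------
# ranking


def test_rank_mirnas_orders_extremes():
    utrs = {f"g{i}": "C" * 100 + "TAAGCT" + "C" * 100 for i in range(10)}
    matures = [("hit", "UAGCUUAUCAGACUGAUGUUGA"), ("miss", "UCCCGGAUCAGACUGAUGUUGA")]
    gs = GeneSet.from_utrs(utrs, dict(matures))
    res = rank_mirnas(gs, matures, UNIFORM)
    assert [r.mature_id for r in res] == ["hit", "miss"]
    assert res[0].score > 0 > res[1].score
    assert res[0].observed == 10 and res[1].observed == 0
    assert all(r.fisher_q is not None for r in res)


def test_rank_mirnas_empty_and_duplicates():
    gs = gs_with_matches(5, 2)
    assert rank_mirnas(gs, [], UNIFORM) == []
    matures = [("b", "UAGCUUAUCAGACUGAUGUUGA"), ("a", "UAGCUUAUCAGACUGAUGUUGA")]
    res = rank_mirnas(GeneSet.from_utrs({"g": "TAAGCT" + "C" * 50}, dict(matures)),
                      matures, UNIFORM)
    assert [r.mature_id for r in res] == ["a", "b"]  # identical scores, id order
    assert res[0].score == res[1].score


def test_scores_invariant_to_gene_order():
    utrs = {f"g{i}": ("TAAGCT" if i % 2 else "GGGGGG") + "C" * 60 for i in range(8)}
    matures = [("m", "UAGCUUAUCAGACUGAUGUUGA")]
    fwd = rank_mirnas(GeneSet.from_utrs(utrs, dict(matures)), matures, UNIFORM)
    rev = rank_mirnas(
        GeneSet.from_utrs(dict(reversed(list(utrs.items()))), dict(matures)),
        matures, UNIFORM,
    )
    assert fwd[0].score == rev[0].score and fwd[0].observed == rev[0].observed


# ---------------------------------------------------------------------------
# host enrichment


def test_host_enrichment_matches_hypergeometric_oracle():
    background = [f"g{i}" for i in range(20000)]
    hosts = set(background[:1000])
    gene_list = background[:20] + background[1000:1080]  # 20 hosts of 100
    res = host_enrichment(gene_list, hosts, background)
    assert res.direction == "over"
    assert (res.hosts_in_list, res.list_size) == (20, 100)
    want = fisher_oracle(20, 80, 980, 18920, "two-sided")
    assert res.fisher_p == pytest.approx(want, rel=1e-9)


def test_host_enrichment_balanced_is_none_direction():
    background = ["a", "b", "c", "d"]
    res = host_enrichment(["a", "b"], {"a", "c"}, background)
    assert res.direction == "none"
    assert res.fisher_p == 1.0


def test_host_enrichment_zero_hosts_is_under():
    background = [f"g{i}" for i in range(100)]
    hosts = set(background[:50])
    res = host_enrichment(background[50:70], hosts, background)
    assert res.direction == "under"


def test_host_enrichment_drops_unknown_genes_with_warning():
    with pytest.warns(UserWarning, match="not in background"):
        res = host_enrichment(["a", "zzz"], {"a"}, {"a", "b"})
    assert res.list_size == 1
    with pytest.raises(ValueError):
        host_enrichment(["zzz"], {"a"}, {"a", "b"})


# ---------------------------------------------------------------------------
# edges & background


def edge(a, b, score, source="STRING"):
    return PPIEdge(a, b, score, source)


def test_filter_edges_min_score_inclusive_and_sources():
    edges = [edge("a", "b", 850), edge("a", "c", 900), edge("b", "c", 950, "BIND")]
    kept = filter_edges(edges, min_score=900)
    assert {(e.gene_a, e.gene_b) for e in kept} == {("a", "c"), ("b", "c")}
    assert [e.source for e in filter_edges(edges, sources={"STRING"})] == ["STRING"] * 2


def test_filter_edges_collapses_duplicates_and_self_loops():
    edges = [edge("a", "a", 999), edge("a", "b", 700), edge("b", "a", 900)]
    kept = filter_edges(edges)
    assert len(kept) == 1 and kept[0].score == 900


def test_estimate_background_counts_t_as_u():
    bg = estimate_background(["AACC"])
    assert bg.probs == {"A": 0.5, "C": 0.5, "G": 0.0, "U": 0.0}
    bg2 = estimate_background(["ATGC"])
    assert all(v == pytest.approx(0.25) for v in bg2.probs.values())
    with pytest.raises(ValueError):
        estimate_background(["NNNN"])
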