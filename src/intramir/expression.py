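"""miRNA / host-gene expression correlation across tissues.

Spearman's rank correlation with mid-ranks on ties; p-values come from
exact enumeration of all rank permutations when n <= 8 (n = 6 tissues in a
typical vertebrate panel makes this cheap) and from the usual
t-approximation for larger n.  Missing values are dropped pairwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import HostAssignment

log = logging.getLogger(__name__)

EXACT_N_MAX = 8


@dataclass
class SpearmanResult:
    rho: Optional[float]
    p_value: Optional[float]
    n: int
    reason: Optional[str] = None  # set when rho is undefined


@dataclass
class CorrelationResult:
    mirna_id: str
    gene_id: str
    rho: Optional[float]
    p_value: Optional[float]
    n: int
    reason: Optional[str] = None


def _clean_pairs(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(xa) | np.isnan(ya))
    return xa[keep], ya[keep]


def spearman(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rho and p-value.

    rho is the Pearson correlation of mid-ranks.  For n <= 8 the two-sided
    p-value is exact: the fraction of the n! rank permutations whose |rho|
    is at least the observed |rho|.  For n > 8 the t-approximation is used.
    Fewer than 3 complete pairs, or a constant input, yields a flagged
    result instead of an exception.
    """
    xa, ya = _clean_pairs(x, y)
    n = len(xa)
    if n < 3:
        return SpearmanResult(None, None, n, reason="fewer than 3 complete pairs")
    rx = stats.rankdata(xa)
    ry = stats.rankdata(ya)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return SpearmanResult(None, None, n, reason="zero rank variance")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_N_MAX:
        p = _exact_permutation_p(rx, ry, abs(rho))
    else:
        # t-approximation on n-2 degrees of freedom
        t = rho * math.sqrt((n - 2) / max(1.0 - rho * rho, 1e-300))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return SpearmanResult(rho, min(p, 1.0), n)


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, abs_rho: float) -> float:
    """Two-sided exact p: share of permutations of one rank vector with
    |rho| >= observed (ties in |rho| counted in, with float slack)."""
    n = len(rx)
    rxc = rx - rx.mean()
    sx = math.sqrt(float(rxc @ rxc))
    ryc = ry - ry.mean()
    sy = math.sqrt(float(ryc @ ryc))
    hits = 0
    total = 0
    thresh = abs_rho - 1e-12
    for perm in permutations(range(n)):
        r = float(rxc @ ryc[list(perm)]) / (sx * sy)
        if abs(r) >= thresh:
            hits += 1
        total += 1
    return hits / total


def read_expression(path: str) -> pd.DataFrame:
    """TSV expression matrix: first column = row id, header = tissue names."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate row ids")
    return df


def correlate_pairs(
    mirna_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    assignments: Sequence[HostAssignment],
) -> list[CorrelationResult]:
    """Correlate each intragenic miRNA row with its host-gene row over the
    shared tissue columns.

    miRNA rows may be precursor- or mature-level; every row whose id equals
    the assignment's mirna_id or starts with it (``mir-9`` -> ``miR-9-5p``)
    is paired with the host.
    """
    shared = [t for t in mirna_expr.columns if t in set(gene_expr.columns)]
    if not shared:
        raise ValueError("expression matrices share no tissue columns")
    results: list[CorrelationResult] = []
    seen: set[tuple[str, str]] = set()
    for a in assignments:
        if a.gene_id is None:
            continue
        if a.gene_id not in gene_expr.index:
            log.info("host %s absent from gene matrix; skipped", a.gene_id)
            continue
        rows = [
            rid
            for rid in mirna_expr.index
            if rid == a.mirna_id or str(rid).startswith(str(a.mirna_id))
        ]
        if not rows:
            log.info("miRNA %s absent from miRNA matrix; skipped", a.mirna_id)
        for rid in rows:
            key = (str(rid), a.gene_id)
            if key in seen:
                continue
            seen.add(key)
            res = spearman(
                mirna_expr.loc[rid, shared].to_numpy(dtype=float),
                gene_expr.loc[a.gene_id, shared].to_numpy(dtype=float),
            )
            results.append(
                CorrelationResult(str(rid), a.gene_id, res.rho, res.p_value, res.n, res.reason)
            )
    return results


def tissue_of_max(
    expr: pd.DataFrame, row_id: str, tissue_order: Optional[Sequence[str]] = None
) -> str:
    """Tissue with the maximal expression of a row; ties resolved by the
    first tissue in canonical order (the matrix column order by default)."""
    if row_id not in expr.index:
        raise KeyError(f"row {row_id!r} not in matrix")
    row = expr.loc[row_id]
    order = list(tissue_order) if tissue_order is not None else list(expr.columns)
    values = {t: row[t] for t in order if t in row.index and not pd.isna(row[t])}
    if not values:
        raise ValueError(f"row {row_id!r} has no non-missing values")
    best = max(values.values())
    for t in order:
        if t in values and values[t] == best:
            return t
    raise AssertionError("unreachable")


def correlation_table(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna_id": r.mirna_id,
                "gene_id": r.gene_id,
                "rho": r.rho if r.rho is not None else "NA",
                "p_value": r.p_value if r.p_value is not None else "NA",
                "n": r.n,
                "flag": r.reason or ".",
            }
            for r in results
        ]
    )
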