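"""Patterson's D from allele frequencies, with block-jackknife significance.

For a species trio (P1, P2, P3) and outgroup P4, the frequency-weighted
pattern counts over n retained sites are

    C_ABBA = sum_i (1 - f_P1,i) * f_P2,i * f_P3,i
    C_BABA = sum_i f_P1,i * (1 - f_P2,i) * f_P3,i

and D = (C_ABBA - C_BABA) / (C_ABBA + C_BABA).  Significance is assessed
with a delete-one block jackknife over contiguous blocks of equal
numbers of retained sites (equal-bp blocks are available as an option):
Z = D / SE(D) and a two-sided normal p-value, floored at 2.3e-16.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from abbaclust.ingest import P_FLOOR, SiteTable


@dataclass
class DStatResult:
    """Result of the frequency-based ABBA-BABA test."""

    cabba: float
    cbaba: float
    d: float | None
    rotated: bool = False
    z: float | None = None
    p: float | None = None
    n_sites: int = 0
    n_blocks: int = 0
    block_d: list[float] = field(default_factory=list)
    status: str = "ok"


def pattern_terms(table: SiteTable) -> tuple[np.ndarray, np.ndarray]:
    """Per-site ABBA and BABA terms (the summands of C_ABBA, C_BABA)."""
    f1, f2, f3 = table.freqs[:, 0], table.freqs[:, 1], table.freqs[:, 2]
    return (1.0 - f1) * f2 * f3, f1 * (1.0 - f2) * f3


def count_patterns(table: SiteTable) -> tuple[float, float]:
    """Frequency-weighted ABBA and BABA counts over all retained sites."""
    if table.n == 0:
        raise ValueError("no informative sites")
    abba, baba = pattern_terms(table)
    return float(abba.sum()), float(baba.sum())


def compute_d(table: SiteTable, rotate: bool = True) -> tuple[DStatResult, SiteTable]:
    """Compute D, optionally rotating P1/P2 so that D >= 0.

    Returns the result and the (possibly P1/P2-swapped) table in the
    orientation used, so downstream analyses (jackknife, site
    clustering) see the same orientation.
    """
    cabba, cbaba = count_patterns(table)
    if cabba + cbaba == 0:
        return (
            DStatResult(cabba, cbaba, None, status="undefined: C_ABBA + C_BABA = 0",
                        n_sites=table.n),
            table,
        )
    d = (cabba - cbaba) / (cabba + cbaba)
    rotated = False
    if rotate and d < 0:
        table = table.swap_p1_p2()
        cabba, cbaba = cbaba, cabba
        d = -d
        rotated = True
    return DStatResult(cabba, cbaba, d, rotated=rotated, n_sites=table.n), table


def block_bounds(table: SiteTable, n_blocks: int, by: str = "sites") -> list[slice]:
    """Split sites into contiguous jackknife blocks.

    Blocks never span chromosome boundaries; the per-chromosome block
    budget is allocated proportionally to chromosome size (at least one
    block per chromosome), and blocks within a chromosome hold
    near-equal numbers of retained sites (``by="sites"``) or near-equal
    spans of base pairs (``by="bp"``).
    """
    if by not in ("sites", "bp"):
        raise ValueError(f"unknown block mode {by!r}")
    chrom_slices = table.chrom_slices()
    total = table.n
    sizes = [sl.stop - sl.start for _, sl in chrom_slices]
    # Proportional allocation, at least one block per chromosome.
    alloc = [max(1, round(n_blocks * size / total)) for size in sizes]
    while sum(alloc) > n_blocks and max(alloc) > 1:
        alloc[int(np.argmax(alloc))] -= 1
    while sum(alloc) < n_blocks:
        alloc[int(np.argmax(sizes))] += 1

    blocks: list[slice] = []
    for (chrom, sl), k in zip(chrom_slices, alloc):
        lo, hi = sl.start, sl.stop
        if by == "sites":
            edges = np.linspace(lo, hi, k + 1).round().astype(int)
        else:
            pos = table.pos[sl]
            cuts = np.linspace(pos[0], pos[-1], k + 1)[1:-1]
            inner = lo + np.searchsorted(pos, cuts)
            edges = np.concatenate([[lo], inner, [hi]])
        for a, b in zip(edges[:-1], edges[1:]):
            if b > a:
                blocks.append(slice(int(a), int(b)))
    return blocks


def jackknife_p(
    table: SiteTable,
    result: DStatResult | None = None,
    n_blocks: int = 20,
    by: str = "sites",
) -> DStatResult:
    """Assess the significance of D by delete-one block jackknife.

    The table must already be in its final orientation (see
    :func:`compute_d`); the jackknife is computed for the D of that
    orientation.  p is the two-sided standard-normal tail of
    Z = D / SE(D), floored at 2.3e-16.
    """
    if table.n < n_blocks:
        raise ValueError(f"need at least n_blocks={n_blocks} sites, got {table.n}")
    if result is None:
        result, table = compute_d(table, rotate=False)
    if result.d is None:
        return result

    abba, baba = pattern_terms(table)
    tot_a, tot_b = abba.sum(), baba.sum()
    blocks = block_bounds(table, n_blocks, by=by)
    block_d = []
    for sl in blocks:
        a = tot_a - abba[sl].sum()
        b = tot_b - baba[sl].sum()
        block_d.append((a - b) / (a + b) if a + b > 0 else 0.0)
    block_d = np.asarray(block_d)
    g = len(block_d)
    # Delete-one jackknife variance with (near-)equal blocks.
    var = (g - 1) / g * np.sum((block_d - block_d.mean()) ** 2)
    result.n_blocks = g
    result.block_d = [float(x) for x in block_d]
    if var == 0:
        result.z = None
        result.p = None
        result.status = "degenerate variance"
        return result
    se = math.sqrt(var)
    result.z = result.d / se
    result.p = max(2.0 * stats.norm.sf(abs(result.z)), P_FLOOR)
    return result


def dtrio(table: SiteTable, n_blocks: int = 20, rotate: bool = True,
          by: str = "sites") -> tuple[DStatResult, SiteTable]:
    """Full D-statistic analysis: counts, rotation, jackknife.

    Returns the result and the table in the orientation used.
    """
    result, oriented = compute_d(table, rotate=rotate)
    if result.d is None:
        return result, oriented
    result = jackknife_p(oriented, result, n_blocks=n_blocks, by=by)
    return result, oriented


def bonferroni(p: float, n_tests: int) -> float:
    """Bonferroni-adjusted p-value, clipped to 1."""
    return min(1.0, p * n_tests)
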