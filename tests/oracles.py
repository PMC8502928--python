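"""Independent brute-force oracles used by the test suite.

Everything here recomputes quantities from first principles (exhaustive
pair enumeration, direct formula evaluation) without touching the
package's optimized code paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_ehh(alleles: np.ndarray, rows, lo: int, hi: int) -> float:
    """P(two random carriers identical over columns lo..hi inclusive), by
    enumerating every pair."""
    rows = list(rows)
    n = len(rows)
    if n < 2:
        raise ValueError("need >= 2 carriers")
    segs = [tuple(alleles[r, lo : hi + 1]) for r in rows]
    same = sum(
        1 for i, j in itertools.combinations(range(n), 2) if segs[i] == segs[j]
    )
    return same / math.comb(n, 2)


def brute_ehh12(alleles: np.ndarray, lo: int, hi: int) -> float:
    """EHH12 over all rows: top two haplotype classes pooled, pairs enumerated."""
    segs = [tuple(row) for row in alleles[:, lo : hi + 1]]
    counts = sorted((segs.count(s) for s in set(segs)), reverse=True)
    n = len(segs)
    pooled = [counts[0] + (counts[1] if len(counts) > 1 else 0)] + counts[2:]
    return sum(math.comb(c, 2) for c in pooled) / math.comb(n, 2)


def _integrate_to_cutoff(ehh: list[float], dist: list[float], cutoff: float) -> float:
    """Trapezoid area, final segment cut at the linear crossing of `cutoff`."""
    area = 0.0
    for (e0, d0), (e1, d1) in zip(zip(ehh, dist), zip(ehh[1:], dist[1:])):
        if e1 >= cutoff:
            area += (e0 + e1) / 2 * (d1 - d0)
        else:
            if e0 > e1:
                frac = (e0 - cutoff) / (e0 - e1)
                area += (e0 + cutoff) / 2 * (d1 - d0) * frac
            break
    return area


def brute_one_sided_ihh(
    alleles: np.ndarray,
    positions_bp: np.ndarray,
    distances: np.ndarray,
    core: int,
    carriers,
    direction: int,
    cutoff: float,
    max_gap_bp: float,
    max_extend: float,
    pooled: bool = False,
) -> float | None:
    """One direction of the integral by walking outward with brute-force EHH.

    `distances` is the per-site coordinate the integral runs over (cM or
    site index).  `max_extend` caps |distance(bp)| for the cM case and
    site count for the site case — the caller passes the right limit.
    Returns None on gap/edge failure.
    """
    n_snp = alleles.shape[1]
    ehh_fn = (lambda lo, hi: brute_ehh12(alleles, lo, hi)) if pooled else (
        lambda lo, hi: brute_ehh(alleles, carriers, lo, hi)
    )
    ehh_vals = [ehh_fn(core, core)]
    dist_vals = [0.0]
    k = core
    steps = 0
    while True:
        nxt = k + direction
        if nxt < 0 or nxt >= n_snp:
            return None  # edge before truncation
        if abs(int(positions_bp[nxt]) - int(positions_bp[k])) > max_gap_bp:
            return None  # gap
        k = nxt
        steps += 1
        lo, hi = (core, k) if direction > 0 else (k, core)
        e = ehh_fn(lo, hi)
        ehh_vals.append(e)
        dist_vals.append(abs(distances[k] - distances[core]))
        if e < cutoff or e <= 0.0:  # at 0 no further area can accrue
            break
        reach = abs(int(positions_bp[k]) - int(positions_bp[core]))
        if isinstance(max_extend, tuple):
            bp_cap, site_cap = max_extend
        else:
            bp_cap, site_cap = max_extend, math.inf
        if reach >= bp_cap or steps >= site_cap:
            break
    return _integrate_to_cutoff(ehh_vals, dist_vals, cutoff)


def brute_ihs(alleles, positions_bp, positions_cm, core, cutoff=0.05,
              max_gap_bp=20_000, max_extend_bp=1_000_000):
    """ln(iHH_ancestral / iHH_derived) with brute-force EHH; None on failure."""
    der = np.flatnonzero(alleles[:, core] == 1)
    anc = np.flatnonzero(alleles[:, core] == 0)
    if len(der) < 2 or len(anc) < 2:
        return None
    total = {}
    for name, rows in (("anc", anc), ("der", der)):
        s = 0.0
        for direction in (-1, +1):
            part = brute_one_sided_ihh(
                alleles, positions_bp, positions_cm, core, rows, direction,
                cutoff, max_gap_bp, max_extend_bp,
            )
            if part is None:
                return None
            s += part
        total[name] = s
    if total["anc"] == 0 or total["der"] == 0:
        return None
    return math.log(total["anc"] / total["der"])


def brute_nsl(alleles, positions_bp, core, cutoff=0.05, max_gap_bp=20_000,
              max_extend_sites=200):
    """nSL analogue: distance = site index; None on failure."""
    site_dist = np.arange(alleles.shape[1], dtype=float)
    der = np.flatnonzero(alleles[:, core] == 1)
    anc = np.flatnonzero(alleles[:, core] == 0)
    if len(der) < 2 or len(anc) < 2:
        return None
    total = {}
    for name, rows in (("anc", anc), ("der", der)):
        s = 0.0
        for direction in (-1, +1):
            part = brute_one_sided_ihh(
                alleles, positions_bp, site_dist, core, rows, direction,
                cutoff, max_gap_bp, (math.inf, max_extend_sites),
            )
            if part is None:
                return None
            s += part
        total[name] = s
    if total["anc"] == 0 or total["der"] == 0:
        return None
    return math.log(total["anc"] / total["der"])


def brute_ihh12(alleles, positions_bp, positions_cm, core, cutoff=0.05,
                max_gap_bp=20_000, max_extend_bp=1_000_000):
    """Integral of brute-force EHH12 over genetic distance; None on failure."""
    s = 0.0
    for direction in (-1, +1):
        part = brute_one_sided_ihh(
            alleles, positions_bp, positions_cm, core, None, direction,
            cutoff, max_gap_bp, max_extend_bp, pooled=True,
        )
        if part is None:
            return None
        s += part
    return s


def brute_pairwise_pi(alleles: np.ndarray) -> float:
    """Mean pairwise Hamming distance over all haplotype pairs."""
    n = alleles.shape[0]
    total = sum(
        int(np.sum(alleles[i] != alleles[j]))
        for i, j in itertools.combinations(range(n), 2)
    )
    return total / math.comb(n, 2)


def brute_tajimas_d(alleles: np.ndarray) -> float | None:
    """Direct evaluation of the published constants on a window's alleles."""
    n, m = alleles.shape
    counts = alleles.sum(axis=0)
    S = int(np.sum((counts > 0) & (counts < n)))
    if S == 0:
        return None
    pi = brute_pairwise_pi(alleles)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1**2 + a2)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def brute_fisher_two_sided(table) -> float:
    """Two-sided Fisher p by exhaustive enumeration of all tables with the
    observed margins, using exact rational arithmetic."""
    from fractions import Fraction

    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    probs = []
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs.append((k, Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)))
    p_obs = dict(probs)[a]
    return float(sum(p for _, p in probs if p <= p_obs))


def brute_intersect(a, b):
    """All-pairs interval overlap check (half-open)."""
    return [
        (x, y)
        for x in a
        for y in b
        if x.chrom == y.chrom and x.start < y.end and y.start < x.end
    ]
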