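"""Downstream enrichment analyses.

* XCI escape: are genes escaping X-inactivation over-represented among
  genes hit by candidate sweep windows?  2x2 Fisher exact test of
  {escape, inactive} x {selected, not selected}; "variable" XCI genes
  are excluded by default.
* SNP prioritization: per-SNP scores in the extreme tail AND a
  PHRED-scaled deleteriousness score above a cutoff.
* Genic / intergenic partition of candidate windows and functional-
  element overlap proportions against a background SNP set.
* Consensus enhancers: collapse cell-type-specific enhancer annotations
  that target the same gene and cover overlapping or contiguous scan
  windows into unique coordinates.
* Enhancer-gene association: Pearson chi-squared (no continuity
  correction) of enhancer-selected x target-gene-selected.

The Fisher p-value is computed by exact integer hypergeometric
enumeration (two-sided: sum of probabilities of all tables with the
observed margins whose probability does not exceed the observed one), so
ties are resolved exactly rather than by a floating-point fuzz factor.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2_dist

from .core import Interval, intersect

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyResult",
    "XCIRecord",
    "Enhancer",
    "fisher_exact_2x2",
    "selected_genes",
    "xci_enrichment",
    "prioritize_snps",
    "partition_windows",
    "functional_overlap_odds",
    "consensus_enhancers",
    "enhancer_selection_association",
]


@dataclass(frozen=True)
class XCIRecord:
    gene: str
    interval: Interval | None
    status: str  # escape | variable | inactive

    def __post_init__(self) -> None:
        if self.status not in ("escape", "variable", "inactive"):
            raise ValueError(f"bad XCI status {self.status!r}")


@dataclass
class Enhancer:
    interval: Interval
    target_gene: str
    cell_lines: frozenset[str]
    db_support: int


@dataclass
class ContingencyResult:
    table: np.ndarray
    odds_ratio: float
    p_value: float
    method: str  # "fisher" | "chi-squared"
    expected: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Cross-product ratio; inf / nan on zero cells, no continuity correction."""
    if b * c == 0:
        return math.inf if a * d > 0 else math.nan
    return (a * d) / (b * c)


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> ContingencyResult:
    """Two-sided Fisher exact test by integer hypergeometric enumeration.

    With margins fixed, table probability is
    C(r1, a) * C(r2, c1 - a) / C(N, c1); the two-sided p sums the
    probabilities of every table at least as extreme (probability <=
    observed, compared exactly on integer numerators).  A zero row or
    column margin leaves a single admissible table, hence p = 1 and an
    undefined odds ratio.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative integers")
    a, b, c, d = int(t[0, 0]), int(t[0, 1]), int(t[1, 0]), int(t[1, 1])
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        raise ValueError("empty table (grand total 0)")
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    p = sum(w for w in weights if w <= w_obs) / math.comb(n, c1)
    return ContingencyResult(t, _odds_ratio(a, b, c, d), min(1.0, p), "fisher")


def selected_genes(
    genes: Sequence[Interval], candidate_windows: Sequence[Interval]
) -> set[str]:
    """Genes (payload = gene id) overlapped by >= 1 bp of any candidate window."""
    return {g.payload for g, _ in intersect(genes, candidate_windows)}


def xci_enrichment(
    candidate_genes: set[str],
    xci: Sequence[XCIRecord],
    include_variable: bool = False,
) -> ContingencyResult:
    """Fisher test of XCI status (escape/inactive) vs selection status.

    Table rows are {escape, inactive}, columns {selected, not selected}.
    Genes with "variable" status are dropped unless include_variable,
    in which case they count as escape (both copies at least sometimes
    expressed).
    """
    statuses = ("escape", "variable") if include_variable else ("escape", "inactive")
    universe = [r for r in xci if include_variable or r.status != "variable"]
    if not universe:
        raise ValueError("empty XCI gene universe")
    def is_escape(r: XCIRecord) -> bool:
        return r.status == "escape" or (include_variable and r.status == "variable")
    a = sum(1 for r in universe if is_escape(r) and r.gene in candidate_genes)
    b = sum(1 for r in universe if is_escape(r) and r.gene not in candidate_genes)
    c = sum(1 for r in universe if not is_escape(r) and r.gene in candidate_genes)
    d = sum(1 for r in universe if not is_escape(r) and r.gene not in candidate_genes)
    return fisher_exact_2x2([[a, b], [c, d]])


def prioritize_snps(
    scores: pd.DataFrame,
    deleteriousness: Mapping[str, float],
    tail_q: float = 0.01,
    del_cutoff: float = 10.0,
    statistics: Sequence[str] = ("ihs", "nsl", "ihh12"),
    two_sided: frozenset = frozenset({"ihs", "nsl"}),
) -> pd.DataFrame:
    """SNPs in the extreme tail_q tail of a statistic AND deleteriousness >= cutoff.

    Tail membership uses the empirical (1 - tail_q) quantile of |z| for
    two-sided statistics (iHS, nSL) and of z for one-sided ones (iHH12),
    inclusive at the quantile.  The deleteriousness cutoff is inclusive
    (a PHRED score of exactly 10 passes; 9.9 does not).  SNPs missing a
    deleteriousness value are excluded with a logged count.
    """
    out_rows = []
    n_missing = 0
    for stat in statistics:
        col = f"{stat}_std"
        z = scores[col].to_numpy(dtype=float)
        v = np.abs(z) if stat in two_sided else z
        ok = ~np.isnan(v)
        if not ok.any():
            continue
        thr = np.quantile(v[ok], 1.0 - tail_q)
        for i in np.flatnonzero(ok & (v >= thr)):
            snp_id = scores["id"].iloc[i]
            score = deleteriousness.get(snp_id)
            if score is None:
                n_missing += 1
                continue
            if score >= del_cutoff:
                out_rows.append({
                    "id": snp_id, "pos": scores["pos"].iloc[i], "statistic": stat,
                    "z": z[i], "deleteriousness": score,
                })
    if n_missing:
        logger.info("prioritize_snps: %d tail SNPs lacked a deleteriousness score", n_missing)
    return pd.DataFrame(out_rows, columns=["id", "pos", "statistic", "z", "deleteriousness"])


def _coverage_union(intervals: Iterable[Interval]) -> list[tuple[int, int]]:
    """Union of [start, end) spans, merging touching pieces (coverage algebra)."""
    spans = sorted((iv.start, iv.end) for iv in intervals)
    out: list[tuple[int, int]] = []
    for s, e in spans:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def partition_windows(
    windows: Sequence[Interval],
    genes: Sequence[Interval],
    snp_positions: np.ndarray | None = None,
) -> pd.DataFrame:
    """Label windows genic / intergenic / partial by gene-span coverage.

    genic: fully covered by the union of gene spans; intergenic: zero
    overlap; partial: both genic and intergenic bases.  When
    snp_positions is given, per-window counts of genic and intergenic
    SNPs (point containment in the gene union) are included.
    """
    union = _coverage_union(genes)
    starts = np.array([s for s, _ in union])
    ends = np.array([e for _, e in union])
    def covered_bp(w: Interval) -> int:
        total = 0
        for s, e in union:
            if s >= w.end:
                break
            if e > w.start:
                total += min(e, w.end) - max(s, w.start)
        return total

    def point_in_union(p: int) -> bool:
        i = np.searchsorted(starts, p, side="right") - 1
        return i >= 0 and p < ends[i]

    rows = []
    for w in windows:
        cov = covered_bp(w)
        label = "genic" if cov == len(w) else ("intergenic" if cov == 0 else "partial")
        row = {"chrom": w.chrom, "start": w.start, "end": w.end, "label": label}
        if snp_positions is not None:
            in_w = snp_positions[(snp_positions >= w.start) & (snp_positions < w.end)]
            genic = sum(1 for p in in_w if point_in_union(int(p)))
            row["genic_snps"] = genic
            row["intergenic_snps"] = len(in_w) - genic
        rows.append(row)
    return pd.DataFrame(rows)


def functional_overlap_odds(
    snp_sets: Mapping[str, np.ndarray],
    elements: Sequence[Interval],
    background: np.ndarray,
) -> pd.DataFrame:
    """Proportion of SNPs inside functional elements, per set and vs background.

    Returns one row per SNP set with the overlap proportion and the odds
    ratio against the background proportion.
    """
    background = np.asarray(background)
    if background.size == 0:
        raise ValueError("empty background SNP set")
    union = _coverage_union(elements)
    starts = np.array([s for s, _ in union] or [0])
    ends = np.array([e for _, e in union] or [0])

    def prop(positions: np.ndarray) -> float:
        if len(positions) == 0:
            return math.nan
        idx = np.searchsorted(starts, positions, side="right") - 1
        inside = (idx >= 0) & (positions < ends[np.clip(idx, 0, len(ends) - 1)])
        return float(inside.mean())

    p_bg = prop(background)
    rows = []
    for name, positions in snp_sets.items():
        p = prop(np.asarray(positions))
        if math.isnan(p) or p_bg in (0.0, 1.0) or math.isnan(p_bg):
            odds = math.nan
        elif p in (0.0, 1.0):
            odds = 0.0 if p == 0.0 else math.inf
        else:
            odds = (p / (1 - p)) / (p_bg / (1 - p_bg))
        rows.append({"set": name, "n": len(positions), "proportion": p,
                     "background_proportion": p_bg, "odds_ratio": odds})
    return pd.DataFrame(rows)


def _window_range(iv: Interval, size: int, step: int) -> tuple[int, int]:
    """Indices [k0, k1] of scan-grid windows overlapping the interval."""
    k0 = max(0, (iv.start - size) // step + 1)
    k1 = (iv.end - 1) // step
    return int(k0), int(k1)


def consensus_enhancers(
    annotations: Sequence[Enhancer],
    window_size: int = 20_000,
    window_step: int = 16_000,
) -> list[Enhancer]:
    """Collapse cell-type-specific enhancer records into unique coordinates.

    Records are grouped by target gene; within a group, records whose
    intervals overlap, or whose covered scan windows form a contiguous
    run, merge to (min start, max end) with cell lines unioned and
    db_support the maximum.  Output intervals are non-overlapping per
    gene and the operation is idempotent.
    """
    by_gene: dict[str, list[Enhancer]] = {}
    for e in annotations:
        by_gene.setdefault(e.target_gene, []).append(e)
    out: list[Enhancer] = []
    for gene in sorted(by_gene):
        recs = sorted(by_gene[gene], key=lambda e: (e.interval.start, e.interval.end))
        cur = None  # [start, end, k0, k1, cells, db]
        for e in recs:
            k0, k1 = _window_range(e.interval, window_size, window_step)
            if cur is not None and (e.interval.start < cur[1] or k0 <= cur[3] + 1):
                cur[1] = max(cur[1], e.interval.end)
                cur[3] = max(cur[3], k1)
                cur[4] |= e.cell_lines
                cur[5] = max(cur[5], e.db_support)
            else:
                if cur is not None:
                    out.append(Enhancer(
                        Interval(e.interval.chrom, cur[0], cur[1]), gene,
                        frozenset(cur[4]), cur[5],
                    ))
                cur = [e.interval.start, e.interval.end, k0, k1,
                       set(e.cell_lines), e.db_support]
        if cur is not None:
            chrom = recs[0].interval.chrom
            out.append(Enhancer(Interval(chrom, cur[0], cur[1]), gene,
                                frozenset(cur[4]), cur[5]))
    return out


def enhancer_selection_association(
    consensus: Sequence[Enhancer],
    candidate_windows: Sequence[Interval],
    candidate_genes: set[str],
    gene_spans: Mapping[str, Interval] | None = None,
    min_db: int = 3,
) -> ContingencyResult:
    """Pearson chi-squared (no Yates correction) of enhancer vs target-gene selection.

    An enhancer is "selected" when any candidate window overlaps it by
    >= 1 bp; its target gene is "selected" when in candidate_genes.
    Cells are ordered [[YY, YN], [NY, NN]].  The result carries observed
    vs expected counts, mean enhancer-gene distance per cell when gene
    spans are supplied, and the selected top hits restricted to
    db_support >= min_db.
    """
    cells = {"YY": [], "YN": [], "NY": [], "NN": []}
    for e in consensus:
        e_sel = any(e.interval.overlaps(w) for w in candidate_windows)
        g_sel = e.target_gene in candidate_genes
        key = ("Y" if e_sel else "N") + ("Y" if g_sel else "N")
        cells[key].append(e)
    obs = np.array([
        [len(cells["YY"]), len(cells["YN"])],
        [len(cells["NY"]), len(cells["NN"])],
    ], dtype=float)
    n = obs.sum()
    if n == 0:
        raise ValueError("no consensus enhancers")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    if (expected < 1).any():
        warnings.warn(
            "expected cell count < 1; consider the exact test instead", stacklevel=2
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(expected > 0, (obs - expected) ** 2 / expected, 0.0)
    stat = float(contrib.sum())
    dof = 1
    p = float(_chi2_dist.sf(stat, dof)) if np.all(obs.sum(axis=0) > 0) and np.all(obs.sum(axis=1) > 0) else 1.0

    extras: dict = {
        "chi2": stat,
        "top_hits": [e for e in cells["YY"] if e.db_support >= min_db],
    }
    if gene_spans is not None:
        dist = {}
        for key, enh_list in cells.items():
            ds = []
            for e in enh_list:
                g = gene_spans.get(e.target_gene)
                if g is None:
                    continue
                e_mid = (e.interval.start + e.interval.end) / 2
                g_mid = (g.start + g.end) / 2
                ds.append(abs(e_mid - g_mid))
            dist[key] = float(np.mean(ds)) if ds else math.nan
        extras["mean_distance"] = dist
    a, b, c, d = int(obs[0, 0]), int(obs[0, 1]), int(obs[1, 0]), int(obs[1, 1])
    return ContingencyResult(obs.astype(np.int64), _odds_ratio(a, b, c, d), p,
                             "chi-squared", expected, extras)
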