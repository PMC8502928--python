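"""Sliding-window summaries, neutral-simulation thresholds, candidate calling,
and cross-population sweep sharing.

Per-SNP standardized scores are averaged in 20-kb windows sliding by
16 kb (20% overlap), windows with 20 SNPs or fewer are discarded, and a
window is a candidate when its mean exceeds the 99th (or 99.9th)
percentile of the same summary computed on neutral coalescent
simulations.  No p-values are attached to windows; the percentile IS the
evidence scale.

For the two-sided statistics iHS and nSL the window mean is taken over
|z|; for the one-sided iHH12 the raw mean z is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Interval, merge_intervals
from .haplostats import SCORE_COLUMNS

__all__ = [
    "WindowParams",
    "make_windows",
    "summarize_windows",
    "neutral_thresholds",
    "call_candidates",
    "shared_sweeps",
    "ThresholdSet",
    "SharedSweepReport",
]

# iHS and nSL are two-sided (window mean of |z|); iHH12 is one-sided.
ABS_STATS = frozenset({"ihs", "nsl"})


@dataclass(frozen=True)
class WindowParams:
    size: int = 20_000
    step: int = 16_000
    min_snps: int = 21  # windows with 20 SNPs or fewer are removed
    quantiles: tuple[float, float] = (0.99, 0.999)


@dataclass
class ThresholdSet:
    """Critical values per statistic from pooled neutral-simulation windows."""

    q99: dict[str, float]
    q999: dict[str, float]
    n_windows: int
    provenance: str = ""

    def __post_init__(self) -> None:
        for stat in self.q99:
            if self.q999[stat] < self.q99[stat]:
                raise ValueError(f"q999 < q99 for {stat}")


def make_windows(span: Interval, size: int = 20_000, step: int = 16_000) -> list[Interval]:
    """Sliding windows [span.start + k*step, +size) with end <= span.end."""
    if size <= 0 or step <= 0:
        raise ValueError("size and step must be positive")
    if len(span) < size:
        return []
    starts = range(span.start, span.end - size + 1, step)
    return [Interval(span.chrom, s, s + size) for s in starts]


def summarize_windows(
    windows: Sequence[Interval],
    scores: pd.DataFrame,
    min_snps: int = 21,
) -> pd.DataFrame:
    """Mean standardized score per window; windows with < min_snps scored SNPs drop.

    SNP membership is half-open containment of the SNP position.  Means
    are over non-missing standardized values; |z| for iHS/nSL, raw z for
    iHH12.  snp_count counts SNPs with at least one non-missing
    standardized score.
    """
    pos = scores["pos"].to_numpy()
    cols = {}
    for stat in SCORE_COLUMNS:
        z = scores[f"{stat}_std"].to_numpy(dtype=float)
        cols[stat] = np.abs(z) if stat in ABS_STATS else z
    any_scored = ~np.all(np.isnan(np.column_stack(list(cols.values()))), axis=1)

    rows = []
    for w in windows:
        in_w = (pos >= w.start) & (pos < w.end)
        n = int((in_w & any_scored).sum())
        if n < min_snps:
            continue
        row = {"chrom": w.chrom, "start": w.start, "end": w.end, "snp_count": n}
        for stat in SCORE_COLUMNS:
            vals = cols[stat][in_w]
            vals = vals[~np.isnan(vals)]
            row[stat] = vals.mean() if vals.size else np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "snp_count", *SCORE_COLUMNS])


def neutral_thresholds(
    sim_windows: pd.DataFrame,
    quantiles: tuple[float, float] = (0.99, 0.999),
    provenance: str = "",
) -> ThresholdSet:
    """Empirical linear-interpolation quantiles of pooled simulated window means."""
    if len(sim_windows) == 0:
        raise ValueError("no simulated windows to calibrate on")
    if len(sim_windows) < 1000:
        import warnings

        warnings.warn(
            f"only {len(sim_windows)} simulated windows; >= 1000 recommended "
            "for stable 99.9th percentiles",
            stacklevel=2,
        )
    q99, q999 = {}, {}
    for stat in SCORE_COLUMNS:
        vals = sim_windows[stat].dropna().to_numpy()
        if vals.size == 0:
            import warnings

            warnings.warn(
                f"no simulated {stat} window means; thresholds set to +inf "
                "(no candidate is callable for this statistic)",
                stacklevel=2,
            )
            q99[stat] = q999[stat] = float("inf")
            continue
        q99[stat] = float(np.quantile(vals, quantiles[0], method="linear"))
        q999[stat] = float(np.quantile(vals, quantiles[1], method="linear"))
    return ThresholdSet(q99, q999, len(sim_windows), provenance)


def call_candidates(windows: pd.DataFrame, thresholds: ThresholdSet) -> pd.DataFrame:
    """Flag windows whose mean score strictly exceeds each critical value."""
    out = windows.copy()
    for stat in SCORE_COLUMNS:
        out[f"{stat}_cand99"] = windows[stat] > thresholds.q99[stat]
        out[f"{stat}_cand999"] = windows[stat] > thresholds.q999[stat]
    return out


@dataclass
class SharedSweepReport:
    """Merged sweep regions with per-region population/continent membership."""

    regions: list[Interval]  # payload: dict(populations=set, continents=set, category=str)
    counts: dict[str, int]
    proportions: dict[str, float]


def _candidate_regions(called: pd.DataFrame) -> list[Interval]:
    """Union over the three statistics of 99th-percentile candidate windows, merged."""
    mask = np.zeros(len(called), dtype=bool)
    for stat in SCORE_COLUMNS:
        mask |= called[f"{stat}_cand99"].to_numpy()
    ivs = [
        Interval(r.chrom, int(r.start), int(r.end))
        for r in called[mask].itertuples()
    ]
    return merge_intervals(ivs)


def shared_sweeps(
    candidates: Mapping[str, pd.DataFrame],
    population_groups: Mapping[str, str],
) -> SharedSweepReport:
    """Classify merged sweep regions as unique / continental / cross-continental.

    `candidates` maps population -> called window table (output of
    :func:`call_candidates`).  Per population, 99th-percentile candidate
    windows of the three statistics are unioned and merged; regions
    overlapping by >= 1 bp across populations coalesce into one shared
    region carrying the union of populations.
    """
    if len(candidates) < 2:
        raise ValueError("need >= 2 populations to assess sweep sharing")
    for pop in candidates:
        if pop not in population_groups:
            raise KeyError(f"population {pop!r} missing from population_groups")

    tagged: list[tuple[str, Interval]] = []
    for pop in sorted(candidates):  # sorted: result invariant to input order
        for iv in _candidate_regions(candidates[pop]):
            tagged.append((pop, iv))
    tagged.sort(key=lambda t: (t[1].chrom, t[1].start, t[1].end, t[0]))

    regions: list[Interval] = []
    counts = {"unique": 0, "continental": 0, "cross-continental": 0}
    cur: tuple[str, int, int, set] | None = None  # chrom, start, end, pops
    def _flush(cur):
        pops = cur[3]
        conts = {population_groups[p] for p in pops}
        if len(pops) == 1:
            cat = "unique"
        elif len(conts) == 1:
            cat = "continental"
        else:
            cat = "cross-continental"
        counts[cat] += 1
        regions.append(Interval(cur[0], cur[1], cur[2],
                                payload={"populations": pops, "continents": conts,
                                         "category": cat}))

    for pop, iv in tagged:
        if cur is not None and iv.chrom == cur[0] and iv.start < cur[2]:
            cur = (cur[0], cur[1], max(cur[2], iv.end), cur[3] | {pop})
        else:
            if cur is not None:
                _flush(cur)
            cur = (iv.chrom, iv.start, iv.end, {pop})
    if cur is not None:
        _flush(cur)

    total = sum(counts.values())
    props = {k: (v / total if total else 0.0) for k, v in counts.items()}
    return SharedSweepReport(regions, counts, props)
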