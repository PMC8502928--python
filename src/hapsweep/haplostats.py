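"""Haplotype-based selection statistics: EHH, iHS, nSL, iHH12, Tajima's D.

Extended haplotype homozygosity (EHH) at distance x from a core SNP is the
probability that two chromosomes drawn at random from a carrier class are
identical over the whole interval from the core out to x:

    EHH(x) = sum_h C(n_h, 2) / C(n, 2)

where n_h counts chromosomes in each distinct haplotype class over the
interval and n is the carrier count.  The per-SNP statistics are built on
integrals of the EHH decay curve:

* iHS  = ln(iHH_A / iHH_D) — iHH integrates EHH against genetic distance
  (cM), separately for ancestral-allele (A) and derived-allele (D)
  carriers.  Long derived haplotypes (incomplete hard sweeps) give large
  negative unstandardized values.
* nSL  — same log-ratio, but distance is measured in number of
  segregating sites (one unit per site), making it independent of the
  genetic map and more sensitive to soft sweeps.
* iHH12 — integrates EHH12, computed over ALL haplotypes with the two
  most frequent haplotype classes pooled:
  EHH12 = [C(n1+n2, 2) + sum_{h>=3} C(n_h, 2)] / C(n, 2).
  Sensitive to both hard and soft sweeps.

Raw scores are standardized to z-scores within equal-width derived-allele
frequency bins, per population and statistic, so that extreme values are
comparable across frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numba
import numpy as np
import pandas as pd

from .core import HaplotypeMatrix, Interval

__all__ = [
    "ScanParams",
    "EHHCurve",
    "ehh_curve",
    "ihh",
    "ihs_unstd",
    "nsl_unstd",
    "ihh12_unstd",
    "site_scores",
    "standardize",
    "fit_standardization",
    "StandardizationModel",
    "tajimas_d",
    "TajimaWindow",
]

SCORE_COLUMNS = ("ihs", "nsl", "ihh12")


@dataclass(frozen=True)
class ScanParams:
    """Tunable knobs of the scan, with the defaults used throughout.

    min_maf:          MAF filter, strict > (sites at exactly min_maf drop).
    truncation:       EHH value at which curve extension stops; area below
                      it is excluded from the integral.
    max_gap_bp:       inter-SNP gap that invalidates a core site.
    max_extend_bp:    physical extension cap for iHS/iHH12.
    max_extend_sites: extension cap (in sites) for nSL.
    n_bins:           equal-width DAF bins for standardization.
    """

    min_maf: float = 0.05
    truncation: float = 0.05
    max_gap_bp: int = 20_000
    max_extend_bp: int = 1_000_000
    max_extend_sites: int = 200
    n_bins: int = 100


@dataclass
class EHHCurve:
    """EHH decay in one direction from a core site.

    `offsets` are site indices starting at the core; `ehh` starts at 1
    for a uniform carrier class.  `status` is "ok" when extension stopped
    by truncation or an extension cap, "edge" when the chromosome end was
    reached with EHH still above truncation, "gap" when an over-long
    inter-SNP gap invalidated the walk, "few_carriers" when n < 2.
    """

    core_index: int
    direction: int
    carrier_set: str
    offsets: np.ndarray
    ehh: np.ndarray
    status: str

    @property
    def failed(self) -> bool:
        return self.status in ("gap", "edge", "few_carriers")


@numba.njit(cache=True)
def _walk_kernel(sub, core, direction, pos, truncation, max_gap, max_bp, max_sites, use_pooled):  # pragma: no cover - exercised via ehh_curve
    """EHH walk outward from the core over a carrier submatrix.

    Haplotype classes over the growing interval are tracked as compact
    integer labels refined one site at a time (counting sort keeps the
    per-step cost linear in carriers).  Returns both the plain and the
    top-2-pooled homozygosity at every step so EHH and EHH12 come from
    one pass.  Status: 0 = stopped by truncation or an extension cap,
    1 = chromosome end with EHH >= truncation, 2 = over-long gap.
    """
    n, m = sub.shape
    denom = n * (n - 1) / 2.0
    labels = np.empty(n, np.int64)
    for i in range(n):
        labels[i] = sub[i, core]
    counts = np.zeros(2 * n + 2, np.int64)
    remap = np.empty(2 * n + 2, np.int64)
    comb = np.empty(n, np.int64)
    max_pts = m + 1
    ehh = np.empty(max_pts, np.float64)
    ehh12 = np.empty(max_pts, np.float64)
    offsets = np.empty(max_pts, np.int64)

    def _fractions(vals):
        for i in range(2 * n + 2):
            counts[i] = 0
        for i in range(n):
            counts[vals[i]] += 1
        num = 0
        top1 = 0
        top2 = 0
        for v in range(2 * n + 2):
            c = counts[v]
            if c > 0:
                num += c * (c - 1) // 2
                if c >= top1:
                    top2 = top1
                    top1 = c
                elif c > top2:
                    top2 = c
        pooled = num - top1 * (top1 - 1) // 2 - top2 * (top2 - 1) // 2
        pooled += (top1 + top2) * (top1 + top2 - 1) // 2
        return num / denom, pooled / denom

    e, e12 = _fractions(labels)
    ehh[0] = e
    ehh12[0] = e12
    offsets[0] = core
    npts = 1
    status = 1  # edge until a stopping rule fires
    k = core
    sites_out = 0
    while True:
        nxt = k + direction
        if nxt < 0 or nxt >= m:
            break
        gap = pos[nxt] - pos[k] if direction > 0 else pos[k] - pos[nxt]
        if gap > max_gap:
            status = 2
            break
        k = nxt
        sites_out += 1
        for i in range(n):
            comb[i] = labels[i] * 2 + sub[i, k]
        e, e12 = _fractions(comb)
        # compact labels for the next step
        nxt_label = 0
        for v in range(2 * n + 2):
            if counts[v] > 0:
                remap[v] = nxt_label
                nxt_label += 1
        for i in range(n):
            labels[i] = remap[comb[i]]
        ehh[npts] = e
        ehh12[npts] = e12
        offsets[npts] = k
        npts += 1
        stop_val = e12 if use_pooled else e
        # EHH is non-increasing: at 0 no further area can accrue
        if stop_val < truncation or stop_val <= 0.0:
            status = 0
            break
        dist = pos[k] - pos[core] if direction > 0 else pos[core] - pos[k]
        if dist >= max_bp or sites_out >= max_sites:
            status = 0
            break
    return ehh[:npts], ehh12[:npts], offsets[:npts], status


_STATUS = {0: "ok", 1: "edge", 2: "gap"}


def ehh_curve(
    hm: HaplotypeMatrix,
    core: int,
    carrier_set: str = "derived",
    truncation: float = 0.05,
    max_gap_bp: int = 20_000,
    max_extend_bp: int = 1_000_000,
    max_extend_sites: int | None = None,
    direction: int = 1,
) -> EHHCurve:
    """Walk outward from `core` computing EHH until a stopping rule fires.

    carrier_set: "derived" / "ancestral" restrict rows to carriers of that
    core allele; "all" uses every haplotype; "pooled2" uses every
    haplotype with the two most frequent classes pooled (EHH12).
    """
    if direction not in (+1, -1):
        raise ValueError("direction must be +1 (downstream) or -1 (upstream)")
    col = hm.alleles[:, core]
    if carrier_set == "derived":
        rows = np.flatnonzero(col == 1)
    elif carrier_set == "ancestral":
        rows = np.flatnonzero(col == 0)
    elif carrier_set in ("all", "pooled2"):
        rows = np.arange(hm.n_hap)
    else:
        raise ValueError(f"unknown carrier_set {carrier_set!r}")
    pooled = carrier_set == "pooled2"

    n = rows.size
    if n < 2:
        return EHHCurve(core, direction, carrier_set,
                        np.array([core]), np.array([1.0]), "few_carriers")
    sub = np.ascontiguousarray(hm.alleles[rows])
    max_sites = max_extend_sites if max_extend_sites is not None else np.iinfo(np.int64).max
    ehh_vals, ehh12_vals, offsets, status = _walk_kernel(
        sub, core, direction, hm.positions_bp, truncation,
        max_gap_bp, max_extend_bp, max_sites, pooled,
    )
    return EHHCurve(core, direction, carrier_set, offsets,
                    ehh12_vals if pooled else ehh_vals, _STATUS[status])


def _integrate(ehh: np.ndarray, dist: np.ndarray, truncation: float) -> float:
    """Trapezoid of EHH against distance, cut at the truncation crossing.

    The final segment is integrated only down to the point where the
    (linearly interpolated) curve reaches the truncation value; area
    below truncation is excluded.
    """
    area = 0.0
    for i in range(1, len(ehh)):
        e0, e1 = ehh[i - 1], ehh[i]
        d0, d1 = dist[i - 1], dist[i]
        if e1 >= truncation:
            area += 0.5 * (e0 + e1) * (d1 - d0)
        else:
            frac = (e0 - truncation) / (e0 - e1) if e0 > e1 else 0.0
            area += 0.5 * (e0 + truncation) * (d1 - d0) * frac
            break
    return area


def ihh(curve: EHHCurve, distances: np.ndarray, truncation: float = 0.05) -> float | None:
    """Integrated EHH for one curve; None when the curve failed.

    `distances` holds the cumulative distance of each curve offset from
    the core (cM for iHS/iHH12, site count for nSL), starting at 0.
    """
    if curve.failed:
        return None
    return _integrate(curve.ehh, distances, truncation)


def _cm_distances(hm: HaplotypeMatrix, curve: EHHCurve) -> np.ndarray:
    cm = hm.positions_cm[curve.offsets]
    return np.abs(cm - cm[0])


def _site_distances(curve: EHHCurve) -> np.ndarray:
    return np.arange(len(curve.offsets), dtype=float)


def _two_sided_ihh(
    hm: HaplotypeMatrix, core: int, carrier_set: str, params: ScanParams,
    unit: str,
) -> tuple[float | None, str]:
    """Sum of the upstream and downstream integrals; (None, reason) on failure."""
    max_sites = params.max_extend_sites if unit == "sites" else None
    max_bp = params.max_extend_bp if unit == "cM" else np.iinfo(np.int64).max
    total = 0.0
    for direction in (-1, +1):
        curve = ehh_curve(
            hm, core, carrier_set, params.truncation, params.max_gap_bp,
            max_bp, max_sites, direction,
        )
        if curve.failed:
            return None, curve.status
        dist = _cm_distances(hm, curve) if unit == "cM" else _site_distances(curve)
        total += _integrate(curve.ehh, dist, params.truncation)
    return total, "none"


def ihs_unstd(hm: HaplotypeMatrix, core: int, params: ScanParams = ScanParams()) -> tuple[float | None, str]:
    """Unstandardized iHS = ln(iHH_ancestral / iHH_derived); (value, failure_reason)."""
    ihh_a, r_a = _two_sided_ihh(hm, core, "ancestral", params, "cM")
    if ihh_a is None:
        return None, r_a
    ihh_d, r_d = _two_sided_ihh(hm, core, "derived", params, "cM")
    if ihh_d is None:
        return None, r_d
    if ihh_a == 0.0 or ihh_d == 0.0:
        return None, "zero_ihh"
    return math.log(ihh_a / ihh_d), "none"


def nsl_unstd(hm: HaplotypeMatrix, core: int, params: ScanParams = ScanParams()) -> tuple[float | None, str]:
    """Unstandardized nSL: iHS with distance in segregating sites (map-free)."""
    sl_a, r_a = _two_sided_ihh(hm, core, "ancestral", params, "sites")
    if sl_a is None:
        return None, r_a
    sl_d, r_d = _two_sided_ihh(hm, core, "derived", params, "sites")
    if sl_d is None:
        return None, r_d
    if sl_a == 0.0 or sl_d == 0.0:
        return None, "zero_ihh"
    return math.log(sl_a / sl_d), "none"


def ihh12_unstd(hm: HaplotypeMatrix, core: int, params: ScanParams = ScanParams()) -> tuple[float | None, str]:
    """Unstandardized iHH12: integral of top-2-pooled EHH over all haplotypes."""
    val, reason = _two_sided_ihh(hm, core, "pooled2", params, "cM")
    if val is None:
        return None, reason
    return val, "none"


def site_scores(hm: HaplotypeMatrix, params: ScanParams = ScanParams()) -> pd.DataFrame:
    """Per-SNP unstandardized iHS, nSL, iHH12 and DAF for every column of `hm`.

    Apply :func:`hapsweep.core.maf_filter` first; monomorphic columns
    here raise.  Returns the SiteScoreTable as a DataFrame with NaN for
    missing scores and a failure_reason column ("none" when all three
    statistics were computed).
    """
    freqs = hm.derived_freqs()
    if np.any((freqs == 0) | (freqs == 1)):
        raise ValueError("monomorphic sites present; run maf_filter first")
    rows = []
    for j in range(hm.n_snp):
        ihs_v, r1 = ihs_unstd(hm, j, params)
        nsl_v, r2 = nsl_unstd(hm, j, params)
        h12_v, r3 = ihh12_unstd(hm, j, params)
        reason = next((r for r in (r1, r2, r3) if r != "none"), "none")
        rows.append((hm.chrom, hm.positions_bp[j], hm.snp_ids[j], freqs[j],
                     ihs_v, nsl_v, h12_v, reason))
    df = pd.DataFrame(rows, columns=[
        "chrom", "pos", "id", "daf", "ihs_unstd", "nsl_unstd", "ihh12_unstd",
        "failure_reason",
    ])
    for c in ("ihs_unstd", "nsl_unstd", "ihh12_unstd"):
        df[c] = df[c].astype(float)
    return df


@dataclass
class StandardizationModel:
    """Per-DAF-bin moments (mean, SD, count) of each raw statistic.

    Fitting the bins on one data set (e.g. a pooled neutral batch) and
    applying them to another mirrors chromosome-wide normalization: on a
    short locus carrying a wide sweep, self-standardization would let
    the swept SNPs dominate their own frequency bins and cancel out.
    """

    n_bins: int
    means: dict[str, np.ndarray]
    sds: dict[str, np.ndarray]
    counts: dict[str, np.ndarray]

    def _bin_index(self, daf: np.ndarray) -> np.ndarray:
        edges = np.linspace(0.0, 1.0, self.n_bins + 1)
        return np.clip(np.digitize(daf, edges) - 1, 0, self.n_bins - 1)

    def apply(self, scores: pd.DataFrame) -> pd.DataFrame:
        """Attach *_std columns; SNPs in bins with < 2 reference values (or
        zero reference SD) get missing z-scores."""
        out = scores.copy()
        bin_idx = self._bin_index(scores["daf"].to_numpy())
        for stat in SCORE_COLUMNS:
            raw = scores[f"{stat}_unstd"].to_numpy(dtype=float)
            mu = self.means[stat][bin_idx]
            sd = self.sds[stat][bin_idx]
            n = self.counts[stat][bin_idx]
            with np.errstate(invalid="ignore", divide="ignore"):
                z = np.where((n >= 2) & (sd > 0), (raw - mu) / sd, np.nan)
            out[f"{stat}_std"] = z
        return out


def fit_standardization(scores: pd.DataFrame, n_bins: int = 100) -> StandardizationModel:
    """Fit per-bin moments over equal-width DAF bins on (0, 1).

    Population-variance denominator (n, not n-1): definitional z-scoring
    of the observed distribution.
    """
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bin_idx = np.clip(np.digitize(scores["daf"].to_numpy(), edges) - 1, 0, n_bins - 1)
    means, sds, counts = {}, {}, {}
    for stat in SCORE_COLUMNS:
        raw = scores[f"{stat}_unstd"].to_numpy(dtype=float)
        mu = np.full(n_bins, np.nan)
        sd = np.full(n_bins, np.nan)
        cnt = np.zeros(n_bins, dtype=np.int64)
        for b in np.unique(bin_idx):
            vals = raw[(bin_idx == b) & ~np.isnan(raw)]
            cnt[b] = vals.size
            if vals.size >= 2:
                mu[b] = vals.mean()
                sd[b] = vals.std()  # ddof=0
        means[stat], sds[stat], counts[stat] = mu, sd, cnt
    return StandardizationModel(n_bins, means, sds, counts)


def standardize(
    scores: pd.DataFrame,
    n_bins: int = 100,
    reference: StandardizationModel | None = None,
) -> pd.DataFrame:
    """Z-score each statistic within equal-width DAF bins.

    Without a `reference`, bins are fit on `scores` itself (per-population
    self-standardization).  With one, the reference's bin moments are
    applied instead — use a pooled neutral batch as the reference when
    scanning short simulated loci.
    """
    model = reference if reference is not None else fit_standardization(scores, n_bins)
    if model.n_bins != n_bins:
        raise ValueError(f"reference has {model.n_bins} bins, requested {n_bins}")
    return model.apply(scores)


@dataclass
class TajimaWindow:
    interval: Interval
    S: int
    pi: float
    D: float | None


def _tajima_constants(n: int) -> tuple[float, ...]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def tajimas_d(hm: HaplotypeMatrix, windows: Sequence[Interval]) -> list[TajimaWindow]:
    """Tajima's D per window: D = (pi - S/a1) / sqrt(e1*S + e2*S*(S-1)).

    pi is the mean number of pairwise differences; S the count of sites
    segregating within the window.  D is undefined (None) when S = 0.
    Strongly negative D marks an excess of rare variants, the footprint
    of a completed sweep.
    """
    n = hm.n_hap
    if n < 4:
        raise ValueError("Tajima's D needs >= 4 haplotypes")
    a1, e1, e2 = _tajima_constants(n)
    counts = hm.derived_counts()
    seg = (counts > 0) & (counts < n)
    # per-site pairwise-difference contribution: 2*c*(n-c)/(n*(n-1))
    pi_site = 2.0 * counts * (n - counts) / (n * (n - 1))
    out = []
    for w in windows:
        in_w = (hm.positions_bp >= w.start) & (hm.positions_bp < w.end)
        S = int((seg & in_w).sum())
        pi = float(pi_site[in_w].sum())
        if S == 0:
            out.append(TajimaWindow(w, 0, pi, None))
            continue
        D = (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
        out.append(TajimaWindow(w, S, pi, D))
    return out
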