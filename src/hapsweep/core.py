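"""Core containers for phased haplotype data, genetic maps and genomic intervals.

The substrate of every statistic in this package is a binary haplotype
matrix: rows are phased chromosomes, columns are biallelic SNPs coded
0 = ancestral allele, 1 = derived allele (polarization against an outgroup
ancestral-state table happens at read time, see :mod:`hapsweep.io`).
Physical positions are base pairs; genetic positions are centimorgans
obtained by piecewise-linear interpolation of a recombination map.

All intervals are 0-based half-open ([start, end)), the BED convention.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Any, Iterable, Sequence

import numpy as np

__all__ = [
    "HaplotypeMatrix",
    "GeneticMap",
    "Interval",
    "intersect",
    "merge_intervals",
    "maf_filter",
]


@dataclass(frozen=True)
class Interval:
    """Half-open genomic interval [start, end) with optional payload."""

    chrom: str
    start: int
    end: int
    payload: Any = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty interval {self.chrom}:{self.start}-{self.end} (need start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end


def intersect(
    a: Sequence[Interval], b: Sequence[Interval]
) -> list[tuple[Interval, Interval]]:
    """All pairs (x, y) with x in `a`, y in `b` overlapping by >= 1 bp.

    Half-open semantics: [0, 10) and [10, 20) do not overlap.  Uses a
    sweep over intervals sorted by start so chromosome-scale inputs do
    not pay the quadratic all-pairs cost.
    """
    by_chrom: dict[str, list[Interval]] = {}
    for y in b:
        by_chrom.setdefault(y.chrom, []).append(y)
    for ys in by_chrom.values():
        ys.sort(key=lambda iv: iv.start)

    out: list[tuple[Interval, Interval]] = []
    for x in a:
        ys = by_chrom.get(x.chrom)
        if not ys:
            continue
        starts = [y.start for y in ys]
        # candidates: every y with y.start < x.end; filter by y.end > x.start
        hi = bisect.bisect_left(starts, x.end)
        for y in ys[:hi]:
            if y.end > x.start:
                out.append((x, y))
    return out


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals, merged when overlapping by >= 1 bp.

    Bookended (touching) intervals are NOT merged: [0,10) and [10,20)
    stay separate regions.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[Interval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = Interval(last.chrom, last.start, iv.end, last.payload)
        else:
            merged.append(iv)
    return merged


@dataclass(frozen=True)
class GeneticMap:
    """Recombination map as (bp, cM) anchors; bp strictly increasing, cM non-decreasing."""

    anchors_bp: np.ndarray
    anchors_cm: np.ndarray

    def __post_init__(self) -> None:
        bp = np.asarray(self.anchors_bp, dtype=np.int64)
        cm = np.asarray(self.anchors_cm, dtype=np.float64)
        if bp.size < 2:
            raise ValueError("genetic map needs >= 2 anchors")
        if bp.size != cm.size:
            raise ValueError("anchor arrays differ in length")
        if np.any(np.diff(bp) <= 0):
            raise ValueError("anchor bp must be strictly increasing")
        if np.any(np.diff(cm) < 0):
            raise ValueError("anchor cM must be non-decreasing")
        object.__setattr__(self, "anchors_bp", bp)
        object.__setattr__(self, "anchors_cm", cm)

    @classmethod
    def uniform(cls, length_bp: int, cm_per_mb: float) -> "GeneticMap":
        """Constant-rate map over [0, length_bp]."""
        return cls(
            np.array([0, length_bp]),
            np.array([0.0, length_bp * cm_per_mb / 1e6]),
        )

    def interpolate(self, positions_bp: np.ndarray) -> np.ndarray:
        """Piecewise-linear cM at each query position.

        Positions outside the anchored range are clamped to the terminal
        anchor's cM value (np.interp semantics), so chromosome-end SNPs
        still receive genetic coordinates for EHH integration.
        """
        pos = np.asarray(positions_bp, dtype=np.float64)
        return np.interp(pos, self.anchors_bp.astype(np.float64), self.anchors_cm)


def interpolate_map(gmap: GeneticMap, positions_bp: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`GeneticMap.interpolate`."""
    return gmap.interpolate(positions_bp)


@dataclass
class HaplotypeMatrix:
    """Phased binary haplotypes (rows) x biallelic SNPs (columns).

    alleles[i, j] is 0 if haplotype i carries the ancestral allele at SNP
    j and 1 for the derived allele.  positions_bp are strictly increasing;
    positions_cm non-decreasing.  population_labels assigns each haplotype
    (each row) to a population.
    """

    alleles: np.ndarray
    positions_bp: np.ndarray
    positions_cm: np.ndarray
    snp_ids: np.ndarray
    population_labels: np.ndarray
    chrom: str = "X"

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.int8)
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        self.positions_cm = np.asarray(self.positions_cm, dtype=np.float64)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.population_labels = np.asarray(self.population_labels, dtype=object)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (haplotypes x SNPs)")
        n_hap, n_snp = self.alleles.shape
        if n_hap < 2:
            raise ValueError("need >= 2 haplotypes")
        for name, arr in (
            ("positions_bp", self.positions_bp),
            ("positions_cm", self.positions_cm),
            ("snp_ids", self.snp_ids),
        ):
            if len(arr) != n_snp:
                raise ValueError(f"{name} length {len(arr)} != n_snp {n_snp}")
        if len(self.population_labels) != n_hap:
            raise ValueError("population_labels length != n_hap")
        if n_snp and np.any(np.diff(self.positions_bp) <= 0):
            raise ValueError("positions_bp must be strictly increasing")
        if n_snp and np.any(np.diff(self.positions_cm) < 0):
            raise ValueError("positions_cm must be non-decreasing")
        bad = (self.alleles != 0) & (self.alleles != 1)
        if np.any(bad):
            raise ValueError("alleles must be 0 (ancestral) or 1 (derived)")

    @property
    def n_hap(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snp(self) -> int:
        return self.alleles.shape[1]

    def derived_counts(self) -> np.ndarray:
        return self.alleles.sum(axis=0)

    def derived_freqs(self) -> np.ndarray:
        return self.derived_counts() / self.n_hap

    def take_sites(self, index: np.ndarray) -> "HaplotypeMatrix":
        return HaplotypeMatrix(
            self.alleles[:, index],
            self.positions_bp[index],
            self.positions_cm[index],
            self.snp_ids[index],
            self.population_labels,
            self.chrom,
        )

    def subset_population(self, label: str) -> "HaplotypeMatrix":
        """Rows of one population; monomorphic columns are retained
        (drop them with :func:`maf_filter` before scoring)."""
        mask = self.population_labels == label
        if not mask.any():
            raise KeyError(f"no haplotypes labelled {label!r}")
        return HaplotypeMatrix(
            self.alleles[mask],
            self.positions_bp,
            self.positions_cm,
            self.snp_ids,
            self.population_labels[mask],
            self.chrom,
        )

    def restrict(self, region: Interval) -> "HaplotypeMatrix":
        keep = (self.positions_bp >= region.start) & (self.positions_bp < region.end)
        return self.take_sites(np.flatnonzero(keep))


def maf_filter(hm: HaplotypeMatrix, min_maf: float) -> HaplotypeMatrix:
    """Keep columns whose minor allele frequency is strictly above `min_maf`.

    With min_maf = 0 this drops exactly the monomorphic columns.  The row
    set is never changed.
    """
    if not 0 <= min_maf < 0.5:
        raise ValueError("min_maf must be in [0, 0.5)")
    freq = hm.derived_freqs()
    maf = np.minimum(freq, 1.0 - freq)
    return hm.take_sites(np.flatnonzero(maf > min_maf))
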