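"""Neutral coalescent simulation, sweep injection and annotation fixtures.

The default demographic model is a three-deme model of the human X
chromosome (Sub-Saharan Africa, Europe, East Asia) adapted from the
Gravel autosomal model, with effective sizes scaled by the 3/4 factor of
X-linked inheritance.  All rates and times are stored in the ms/msms
convention — sizes relative to a reference N0, growth and migration per
4*N0 generations, event times in units of 4*N0 generations — and
converted explicitly when driving the msprime backend.  The compound
parameters are always derived, never set:

    theta = 4 * N0 * mu * L        rho = 4 * N0 * r * L

Defaults: N0 = 10538.25, mu = 1.25e-8 /bp/gen, r = 1.3e-8 /bp/gen,
L = 600 kb, giving theta = 316.1475 and rho = 328.7934; sample sizes
AFR 152 / EUR 153 / ASI 149 chromosomes (arithmetic means of the five
1000 Genomes population chromosome counts per continent, with the Asian
pooled size kept at the value the model was originally run with).

Sweep injection is a haplotype-copy device, not a selection simulation:
copying one donor haplotype over a span around a core site creates
exactly the extended-homozygosity structure the scan statistics target,
deterministically, which is what power testing needs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import msprime
import numpy as np
import pandas as pd

from .core import HaplotypeMatrix, Interval

logger = logging.getLogger(__name__)

__all__ = [
    "DemographicModel",
    "SimBatch",
    "default_model",
    "build_model",
    "pooled_sample_size",
    "simulate_neutral",
    "inject_sweep",
    "sfs",
    "FixtureConfig",
    "make_annotation_fixtures",
    "POPULATION_CHROMOSOME_COUNTS",
    "CONTINENT_OF",
]

# 1000 Genomes phase 3 X-chromosome counts per population (chromosomes).
POPULATION_CHROMOSOME_COUNTS: dict[str, dict[str, int]] = {
    "AFR": {"ESN": 145, "GWD": 171, "LWK": 154, "MSL": 128, "YRI": 164},
    "EUR": {"CEU": 149, "FIN": 160, "GBR": 136, "IBS": 160, "TSI": 161},
    "ASI": {"CDX": 142, "CHB": 160, "CHS": 158, "JPT": 152, "KHV": 152},
}

CONTINENT_OF = {
    pop: cont for cont, pops in POPULATION_CHROMOSOME_COUNTS.items() for pop in pops
}


def pooled_sample_size(counts: Iterable[int]) -> int:
    """Continental sample size: arithmetic mean of per-population chromosome
    counts, rounded to the nearest integer."""
    counts = list(counts)
    return round(sum(counts) / len(counts))


@dataclass(frozen=True)
class SizeChange:
    time: float  # 4*N0 generations
    population: str
    rel_size: float
    growth: float = 0.0


@dataclass(frozen=True)
class Join:
    """Backward in time, lineages of `source` move into `dest` (ms -ej)."""

    time: float
    source: str
    dest: str


@dataclass(frozen=True)
class MigrationChange:
    """Set the (backward) migration rate between two demes, both directions (x4*N0)."""

    time: float
    pop_a: str
    pop_b: str
    rate: float


Event = SizeChange | Join | MigrationChange


@dataclass(frozen=True)
class DemographicModel:
    """Three-deme (or reduced) coalescent model in ms units; owns theta and rho."""

    n_ref: float = 10538.25
    sample_sizes: tuple[tuple[str, int], ...] = (("AFR", 152), ("EUR", 153), ("ASI", 149))
    rel_sizes: tuple[tuple[str, float], ...] = (("AFR", 2.204), ("EUR", 3.2542), ("ASI", 7.4055))
    growth_rates: tuple[tuple[str, float], ...] = (("AFR", 0.0), ("EUR", 56.61), ("ASI", 96.0))
    migration: tuple[tuple[str, str, float], ...] = (
        ("AFR", "EUR", 0.3542),
        ("AFR", "ASI", 0.1462),
        ("EUR", "ASI", 1.3562),
    )
    events: tuple[Event, ...] = (
        Join(0.0464, "ASI", "EUR"),
        SizeChange(0.0464, "EUR", 0.2939),
        MigrationChange(0.0464, "AFR", "EUR", 4.9314),
        Join(0.14022, "EUR", "AFR"),
        SizeChange(0.364, "AFR", 1.0),
    )
    L: int = 600_000
    mu: float = 1.25e-8
    rec: float = 1.3e-8
    generation_time: float = 30.0  # years; metadata only

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be non-decreasing")
        if any(n <= 0 for _, n in self.sample_sizes):
            raise ValueError("sample sizes must be positive")

    @property
    def theta(self) -> float:
        return 4.0 * self.n_ref * self.mu * self.L

    @property
    def rho(self) -> float:
        return 4.0 * self.n_ref * self.rec * self.L

    @property
    def populations(self) -> list[str]:
        return [p for p, _ in self.sample_sizes]

    @property
    def n_samples(self) -> int:
        return sum(n for _, n in self.sample_sizes)

    @property
    def cm_per_mb(self) -> float:
        return self.rec * 1e8

    def to_msprime(self) -> msprime.Demography:
        """Unit-converted msprime demography (sizes in individuals, rates and
        times in generations)."""
        four_n = 4.0 * self.n_ref
        dem = msprime.Demography()
        growth = dict(self.growth_rates)
        for pop, rel in self.rel_sizes:
            dem.add_population(
                name=pop,
                initial_size=rel * self.n_ref,
                growth_rate=growth.get(pop, 0.0) / four_n,
            )
        for a, b, m in self.migration:
            dem.set_symmetric_migration_rate([a, b], m / four_n)
        joined: set[str] = set()
        for ev in self.events:
            t = ev.time * four_n
            if isinstance(ev, Join):
                dem.add_mass_migration(time=t, source=ev.source, dest=ev.dest, proportion=1.0)
                # the joined deme must stop receiving lineages
                for other in self.populations:
                    if other != ev.source:
                        dem.add_migration_rate_change(
                            time=t, source=ev.source, dest=other, rate=0.0
                        )
                        dem.add_migration_rate_change(
                            time=t, source=other, dest=ev.source, rate=0.0
                        )
                joined.add(ev.source)
            elif isinstance(ev, SizeChange):
                dem.add_population_parameters_change(
                    time=t, population=ev.population,
                    initial_size=ev.rel_size * self.n_ref,
                    growth_rate=ev.growth / four_n,
                )
            elif isinstance(ev, MigrationChange):
                dem.add_migration_rate_change(
                    time=t, source=ev.pop_a, dest=ev.pop_b, rate=ev.rate / four_n
                )
                dem.add_migration_rate_change(
                    time=t, source=ev.pop_b, dest=ev.pop_a, rate=ev.rate / four_n
                )
        dem.sort_events()
        return dem


def default_model() -> DemographicModel:
    return DemographicModel()


def constant_size_model(
    n_samples: int, theta: float, rho: float = 0.0, L: int = 600_000,
    n_ref: float = 10_000.0,
) -> DemographicModel:
    """Single-deme constant-size reduction (all growth/migration/events off).

    mu and rec are chosen so that 4*N0*mu*L and 4*N0*r*L equal the
    requested theta and rho; used for closed-form checks (Watterson's
    E[S], the 1/i SFS)."""
    return DemographicModel(
        n_ref=n_ref,
        sample_sizes=(("pop0", n_samples),),
        rel_sizes=(("pop0", 1.0),),
        growth_rates=(("pop0", 0.0),),
        migration=(),
        events=(),
        L=L,
        mu=theta / (4.0 * n_ref * L),
        rec=rho / (4.0 * n_ref * L),
    )


def build_model(config: Mapping | None = None) -> DemographicModel:
    """DemographicModel from a config mapping; unknown keys raise.

    Recognized keys mirror the dataclass fields (n_ref, sample_sizes,
    rel_sizes, growth_rates, migration, L, mu, rec, generation_time).
    theta and rho are always derived and may not be supplied directly.
    """
    config = dict(config or {})
    for banned in ("theta", "rho"):
        if banned in config:
            raise ValueError(f"{banned} is derived from (n_ref, mu/rec, L); do not set it")
    fields_ok = {
        "n_ref", "sample_sizes", "rel_sizes", "growth_rates", "migration",
        "events", "L", "mu", "rec", "generation_time",
    }
    unknown = set(config) - fields_ok
    if unknown:
        raise ValueError(f"unknown demography config keys: {sorted(unknown)}")
    for key in ("sample_sizes", "rel_sizes", "growth_rates"):
        if key in config and isinstance(config[key], Mapping):
            config[key] = tuple(config[key].items())
    if "migration" in config and isinstance(config["migration"], Mapping):
        config["migration"] = tuple((a, b, m) for (a, b), m in config["migration"].items())
    return DemographicModel(**config)


@dataclass
class SimBatch:
    replicates: list[HaplotypeMatrix]
    seed: int
    model: DemographicModel


def _ts_to_haplotype_matrix(ts, model: DemographicModel, pop_labels: np.ndarray) -> HaplotypeMatrix:
    gm = ts.genotype_matrix().T.astype(np.int8)  # haplotypes x sites
    pos = np.floor(ts.tables.sites.position).astype(np.int64)
    keep = np.concatenate(([True], np.diff(pos) > 0)) if pos.size else np.array([], bool)
    gm, pos = gm[:, keep], pos[keep]
    ids = np.array([f"sim:{p}" for p in pos], dtype=object)
    cm = pos * model.cm_per_mb / 1e6
    return HaplotypeMatrix(gm, pos, cm, ids, pop_labels, chrom="X")


def simulate_neutral(
    model: DemographicModel, n_reps: int, seed: int,
    sample_sizes: Mapping[str, int] | None = None,
) -> SimBatch:
    """n_reps independent neutral loci of length model.L; deterministic by seed.

    `sample_sizes` optionally overrides the per-deme haplotype counts
    (e.g. scaled-down batches for quick calibration); the demography is
    unchanged.  Mutations follow an infinite-sites binary model at rate
    model.mu; float positions are floored to integer bp and the rare
    resulting duplicate positions dropped (first kept).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    sizes = dict(model.sample_sizes)
    if sample_sizes is not None:
        unknown = set(sample_sizes) - set(sizes)
        if unknown:
            raise KeyError(f"unknown demes: {sorted(unknown)}")
        sizes.update(sample_sizes)
    samples = [msprime.SampleSet(n, population=pop, ploidy=1) for pop, n in sizes.items()]
    pop_labels = np.array(
        [pop for pop, n in sizes.items() for _ in range(n)], dtype=object
    )
    rng = np.random.default_rng(seed)
    anc_seed, mut_master = (int(s) for s in rng.integers(1, 2**31 - 1, size=2))
    mut_seeds = np.random.default_rng(mut_master).integers(1, 2**31 - 1, size=n_reps)

    # model ploidy 2 with haploid sample sets reproduces the ms time scale,
    # where a pair of lineages coalesces in 2*N0 generations on average
    reps = msprime.sim_ancestry(
        samples=samples,
        demography=model.to_msprime(),
        ploidy=2,
        sequence_length=model.L,
        recombination_rate=model.rec,
        num_replicates=n_reps,
        random_seed=anc_seed,
    )
    out = []
    for ts, ms in zip(reps, mut_seeds):
        ts = msprime.sim_mutations(
            ts, rate=model.mu, model=msprime.BinaryMutationModel(),
            discrete_genome=False, random_seed=int(ms),
        )
        out.append(_ts_to_haplotype_matrix(ts, model, pop_labels))
    return SimBatch(out, seed, model)


def inject_sweep(
    hm: HaplotypeMatrix,
    core_pos: int,
    target_freq: float,
    span_bp: int,
    seed: int,
) -> HaplotypeMatrix:
    """Copy one donor haplotype over +-span_bp around the core onto a random
    subset of haplotypes so the core derived frequency becomes
    round(target_freq * n) / n.

    The final carrier set is the donor plus k-1 randomly chosen
    haplotypes (existing carriers preferred, so a low target is a fixed
    point); haplotypes outside the final carrier set that carried the
    derived core allele are flipped to ancestral at the core only.
    Recipients are untouched outside the span.
    """
    if not 0.0 < target_freq < 1.0:
        raise ValueError("target_freq must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = hm.n_hap
    core = int(np.argmin(np.abs(hm.positions_bp - core_pos)))
    lo, hi = core_pos - span_bp, core_pos + span_bp
    if lo < hm.positions_bp[0] or hi > hm.positions_bp[-1]:
        warnings.warn("sweep span clipped to the simulated locus", stacklevel=2)
    in_span = (hm.positions_bp >= lo) & (hm.positions_bp <= hi)

    alleles = hm.alleles.copy()
    carriers = np.flatnonzero(alleles[:, core] == 1)
    if carriers.size:
        donor = int(rng.choice(carriers))
    else:
        donor = int(rng.integers(n))
        alleles[donor, core] = 1
        carriers = np.array([donor])
    k = max(1, round(target_freq * n))
    others = [h for h in carriers if h != donor]
    rng.shuffle(others)
    pool = [h for h in rng.permutation(n) if h != donor and h not in set(others)]
    final = ([donor] + others + pool)[:k]
    final_set = set(final)
    for h in final:
        alleles[h, in_span] = alleles[donor, in_span]
    for h in np.flatnonzero(alleles[:, core] == 1):
        if h not in final_set:
            alleles[h, core] = 0
    return HaplotypeMatrix(
        alleles, hm.positions_bp, hm.positions_cm, hm.snp_ids,
        hm.population_labels, hm.chrom,
    )


def sfs(data: HaplotypeMatrix | SimBatch, deme: str | None = None) -> np.ndarray:
    """Unfolded site frequency spectrum: counts of sites by derived-allele
    count, classes 1 .. n_hap-1 (monomorphic classes excluded)."""
    if isinstance(data, SimBatch):
        mats = data.replicates
    else:
        mats = [data]
    mats = [m.subset_population(deme) if deme else m for m in mats]
    n = mats[0].n_hap
    spec = np.zeros(n - 1, dtype=np.int64)
    for m in mats:
        counts = m.derived_counts()
        seg = counts[(counts > 0) & (counts < n)]
        spec += np.bincount(seg, minlength=n)[1:n]
    return spec


# ---------------------------------------------------------------------------
# Annotation fixtures: toy gene / XCI / enhancer / per-SNP score tables with
# planted, recorded ground truth.  These stand in for the gene-annotation,
# X-inactivation and enhancer catalogs the real analysis consumes.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the annotation fixture generator.

    The XCI universe defaults to 59 escape / 381 inactive genes.  A gene
    is "selected" with baseline probability p_sel_inactive; escape genes
    are selected at odds multiplied by xci_odds_ratio (the planted
    enrichment; 1.0 = null).  Candidate regions are emitted exactly over
    the selected genes, so the downstream overlap rule recovers the
    planted contingency table.
    """

    n_escape: int = 59
    n_inactive: int = 381
    xci_odds_ratio: float = 1.0
    p_sel_inactive: float = 0.10
    gene_length: int = 20_000
    gene_spacing: int = 40_000
    n_enhancer_genes: int = 30
    enhancer_records_per_gene: int = 3
    n_databases: int = 4
    n_snps: int = 1_000
    n_planted_snps: int = 10
    cadd_cutoff: float = 10.0


def make_annotation_fixtures(config: FixtureConfig, seed: int) -> dict:
    """Deterministic toy annotation tables with recorded ground truth.

    Returns a dict with DataFrames 'genes' (gene, chrom, start, end,
    xci_status, selected), 'candidate_regions', 'enhancers' (cell-line
    specific records), 'snp_scores' (per-SNP z-scores + deleteriousness),
    and 'truth' (the planted parameters and realized counts).
    """
    rng = np.random.default_rng(seed)
    cfg = config
    n_genes = cfg.n_escape + cfg.n_inactive

    status = np.array(["escape"] * cfg.n_escape + ["inactive"] * cfg.n_inactive)
    rng.shuffle(status)
    odds0 = cfg.p_sel_inactive / (1.0 - cfg.p_sel_inactive)
    odds1 = odds0 * cfg.xci_odds_ratio
    p1 = odds1 / (1.0 + odds1)
    p_sel = np.where(status == "escape", p1, cfg.p_sel_inactive)
    selected = rng.random(n_genes) < p_sel

    starts = np.arange(n_genes) * cfg.gene_spacing
    genes = pd.DataFrame({
        "gene": [f"G{i:04d}" for i in range(n_genes)],
        "chrom": "X",
        "start": starts,
        "end": starts + cfg.gene_length,
        "xci_status": status,
        "selected": selected,
    })
    candidate_regions = [
        Interval("X", int(s), int(s + cfg.gene_length))
        for s, sel in zip(starts, selected) if sel
    ]

    # enhancer records: per target gene, several overlapping cell-line
    # annotations; a random minority sits far away (distinct consensus).
    cell_lines = ["GM12878", "K562", "HUVEC", "H1", "HCT116"]
    enh_rows = []
    enh_genes = genes.sample(n=cfg.n_enhancer_genes, random_state=int(rng.integers(2**31 - 1)))
    for _, g in enh_genes.iterrows():
        anchor = int(g.start) + int(rng.integers(-15_000, 15_000))
        anchor = max(0, anchor)
        for r in range(cfg.enhancer_records_per_gene):
            jitter = int(rng.integers(0, 800))
            enh_rows.append({
                "chrom": "X",
                "start": anchor + jitter,
                "end": anchor + 1_200 + jitter,
                "target_gene": g.gene,
                "cell_line": cell_lines[r % len(cell_lines)],
                "db_support": int(rng.integers(1, cfg.n_databases + 1)),
            })
    enhancers = pd.DataFrame(enh_rows)

    # per-SNP scores: background N(0,1) z-scores and low deleteriousness;
    # n_planted_snps pass both the 1% tail and the deleteriousness cutoff.
    n = cfg.n_snps
    pos = np.sort(rng.choice(np.arange(1, n_genes * cfg.gene_spacing), size=n, replace=False))
    z = rng.normal(0.0, 1.0, size=(n, 3))
    cadd = rng.uniform(0.0, cfg.cadd_cutoff - 0.5, size=n)
    planted = rng.choice(n, size=cfg.n_planted_snps, replace=False)
    z[planted] = rng.normal(6.0, 0.3, size=(cfg.n_planted_snps, 3))
    cadd[planted] = cfg.cadd_cutoff + rng.uniform(0.0, 20.0, size=cfg.n_planted_snps)
    snp_scores = pd.DataFrame({
        "chrom": "X", "pos": pos, "id": [f"snp{i}" for i in range(n)],
        "ihs_std": z[:, 0], "nsl_std": z[:, 1], "ihh12_std": z[:, 2],
        "deleteriousness": cadd,
    })

    truth = {
        "xci_odds_ratio": cfg.xci_odds_ratio,
        "n_escape_selected": int(selected[status == "escape"].sum()),
        "n_inactive_selected": int(selected[status == "inactive"].sum()),
        "planted_snp_ids": sorted(f"snp{i}" for i in planted),
        "seed": seed,
    }
    return {
        "genes": genes,
        "candidate_regions": candidate_regions,
        "enhancers": enhancers,
        "snp_scores": snp_scores,
        "truth": truth,
    }
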