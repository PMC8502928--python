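"""End-to-end orchestration: ingest -> score -> calibrate -> call -> enrich.

A single config (YAML-serializable, every knob defaulting to the values
the scan is calibrated for) drives either a file-based run (phased VCF +
ancestral table + genetic map + annotation tables) or a fully synthetic
demo in which the neutral coalescent engine supplies both the
"empirical" data and the calibration batch.  Every stage logs its record
counts and the run writes a manifest sufficient to reproduce it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import Interval, maf_filter
from .haplostats import (
    ScanParams,
    StandardizationModel,
    fit_standardization,
    site_scores,
    standardize,
)
from .simulate import (
    FixtureConfig,
    build_model,
    inject_sweep,
    make_annotation_fixtures,
    simulate_neutral,
)
from .windows import (
    WindowParams,
    call_candidates,
    make_windows,
    neutral_thresholds,
    shared_sweeps,
    summarize_windows,
)
from .enrichment import (
    Enhancer,
    XCIRecord,
    consensus_enhancers,
    enhancer_selection_association,
    selected_genes,
    xci_enrichment,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "SyntheticConfig", "validate_config", "run_scan"]


@dataclass
class SyntheticConfig:
    n_calibration_reps: int = 12
    n_scan_reps: int = 6
    sample_sizes: dict[str, int] | None = None  # per-deme override (scaled-down runs)
    sweep: dict | None = None  # {"target_freq": 0.8, "span_bp": 100000} to inject
    fixtures: FixtureConfig = field(default_factory=FixtureConfig)


@dataclass
class PipelineConfig:
    seed: int = 1
    output_dir: str = "hapsweep_out"
    scan: ScanParams = field(default_factory=ScanParams)
    windows: WindowParams = field(default_factory=WindowParams)
    demography: dict = field(default_factory=dict)  # overrides of the default model
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    inputs: dict = field(default_factory=dict)  # vcf/ancestral/genetic_map paths (file mode)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_as_plain(asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "scan" in kwargs:
            kwargs["scan"] = ScanParams(**kwargs["scan"])
        if "windows" in kwargs:
            w = dict(kwargs["windows"])
            if "quantiles" in w:
                w["quantiles"] = tuple(w["quantiles"])
            kwargs["windows"] = WindowParams(**w)
        if "synthetic" in kwargs:
            s = dict(kwargs["synthetic"])
            if "fixtures" in s:
                s["fixtures"] = FixtureConfig(**s["fixtures"])
            kwargs["synthetic"] = SyntheticConfig(**s)
        return cls(**kwargs)


def _as_plain(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def validate_config(config: PipelineConfig) -> list[tuple[str, str]]:
    """Return (level, message) findings; never mutates the config."""
    findings: list[tuple[str, str]] = []
    s, w = config.scan, config.windows
    if not 0 <= s.min_maf < 0.5:
        findings.append(("error", f"min_maf {s.min_maf} outside [0, 0.5)"))
    if not 0 < s.truncation < 1:
        findings.append(("error", f"EHH truncation {s.truncation} outside (0, 1)"))
    if s.max_gap_bp <= 0 or s.max_extend_bp <= 0:
        findings.append(("error", "gap / extension limits must be positive"))
    if s.n_bins < 1:
        findings.append(("error", "n_bins must be >= 1"))
    if w.step > w.size:
        findings.append(("warning", "window step exceeds size: windows will not tile"))
    if w.min_snps < 1:
        findings.append(("error", "min_snps must be >= 1"))
    q99, q999 = w.quantiles
    if not 0 < q99 <= q999 < 1:
        findings.append(("error", f"quantiles {w.quantiles} must satisfy 0 < q99 <= q999 < 1"))
    for key, path in (config.inputs or {}).items():
        if path is not None and not Path(path).exists():
            findings.append(("error", f"input {key}: {path} does not exist"))
    try:
        build_model(config.demography)
    except (ValueError, TypeError, KeyError) as exc:
        findings.append(("error", f"demography: {exc}"))
    return findings


def _raw_scores(hm, pop: str, scan: ScanParams) -> pd.DataFrame:
    sub = maf_filter(hm.subset_population(pop), scan.min_maf)
    return site_scores(sub, scan)


def _window_batch(batch, pop, scan, wparams, reference: StandardizationModel | None = None):
    """Score every replicate of a batch for one deme and pool window summaries.

    With a `reference` standardization model the z-scores use its frozen
    DAF-bin moments; otherwise each replicate self-standardizes.
    """
    frames = []
    for i, hm in enumerate(batch.replicates):
        scores = standardize(_raw_scores(hm, pop, scan), scan.n_bins, reference)
        wins = make_windows(Interval(hm.chrom, 0, batch.model.L), wparams.size, wparams.step)
        summ = summarize_windows(wins, scores, wparams.min_snps)
        summ.insert(0, "replicate", i)
        frames.append(summ)
    return pd.concat(frames, ignore_index=True)


def fit_neutral_reference(batch, pop: str, scan: ScanParams) -> StandardizationModel:
    """DAF-bin moments pooled over every replicate of a neutral batch.

    The pooled neutral scores stand in for the chromosome-wide score
    distribution that normalization runs over in a real scan.
    """
    pooled = pd.concat(
        [_raw_scores(hm, pop, scan) for hm in batch.replicates], ignore_index=True
    )
    return fit_standardization(pooled, scan.n_bins)


def run_scan(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the result bundle and writes outputs.

    Synthetic mode (the default): simulate a calibration batch and a scan
    batch under the demographic model, optionally inject a sweep into the
    scan batch, score each deme, window, derive neutral thresholds, call
    candidates, classify sweep sharing across demes, and run the
    annotation-fixture enrichment analyses.
    """
    findings = validate_config(config)
    errors = [m for lvl, m in findings if lvl == "error"]
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    seeds = {k: int(s) for k, s in zip(
        ("calibration", "scan", "sweep", "fixtures"),
        rng.integers(1, 2**31 - 1, size=4),
    )}
    model = build_model(config.demography)
    syn = config.synthetic
    counts: dict[str, Any] = {}

    logger.info("stage simulate: %d calibration + %d scan replicates",
                syn.n_calibration_reps, syn.n_scan_reps)
    calib = simulate_neutral(model, syn.n_calibration_reps, seeds["calibration"],
                             sample_sizes=syn.sample_sizes)
    scan_batch = simulate_neutral(model, syn.n_scan_reps, seeds["scan"],
                                  sample_sizes=syn.sample_sizes)
    if syn.sweep:
        sweep_rng = np.random.default_rng(seeds["sweep"])
        scan_batch.replicates = [
            inject_sweep(hm, core_pos=model.L // 2,
                         target_freq=syn.sweep.get("target_freq", 0.8),
                         span_bp=syn.sweep.get("span_bp", 100_000),
                         seed=int(sweep_rng.integers(1, 2**31 - 1)))
            for hm in scan_batch.replicates
        ]

    pops = model.populations
    thresholds = {}
    called = {}
    for pop in pops:
        # raw scores once per replicate; the pooled calibration scores fix
        # the DAF-bin moments used to standardize both batches
        raw_calib = [_raw_scores(hm, pop, config.scan) for hm in calib.replicates]
        reference = fit_standardization(
            pd.concat(raw_calib, ignore_index=True), config.scan.n_bins
        )
        wins = make_windows(Interval("X", 0, model.L),
                            config.windows.size, config.windows.step)

        def _pool(frames):
            out = []
            for i, df in enumerate(frames):
                summ = summarize_windows(wins, reference.apply(df),
                                         config.windows.min_snps)
                summ.insert(0, "replicate", i)
                out.append(summ)
            return pd.concat(out, ignore_index=True)

        sim_windows = _pool(raw_calib)
        if len(sim_windows) == 0:
            logger.warning(
                "deme %s produced no calibration windows (too few haplotypes "
                "or SNPs); skipping", pop)
            continue
        thresholds[pop] = neutral_thresholds(
            sim_windows, config.windows.quantiles,
            provenance=f"seed={seeds['calibration']} reps={syn.n_calibration_reps}",
        )
        emp_windows = _pool(
            [_raw_scores(hm, pop, config.scan) for hm in scan_batch.replicates]
        )
        called[pop] = call_candidates(emp_windows, thresholds[pop])
        counts[f"windows_{pop}"] = len(emp_windows)
        counts[f"candidates99_{pop}"] = int(
            (called[pop][[c for c in called[pop] if c.endswith("_cand99")]].any(axis=1)).sum()
        )
        called[pop].to_csv(out / f"windows_{pop}.tsv", sep="\t", index=False)

    # each simulated deme is its own continental group in the demo
    report = shared_sweeps(called, {p: p for p in called}) if len(called) >= 2 else None
    if report is not None:
        with open(out / "shared_sweeps.json", "w") as fh:
            json.dump({"counts": report.counts, "proportions": report.proportions}, fh, indent=2)

    fixtures = make_annotation_fixtures(syn.fixtures, seeds["fixtures"])
    gene_ivs = [
        Interval(r.chrom, int(r.start), int(r.end), r.gene)
        for r in fixtures["genes"].itertuples()
    ]
    cand_genes = selected_genes(gene_ivs, fixtures["candidate_regions"])
    xci = [
        XCIRecord(r.gene, Interval(r.chrom, int(r.start), int(r.end)), r.xci_status)
        for r in fixtures["genes"].itertuples()
    ]
    xci_result = xci_enrichment(cand_genes, xci)
    annotations = [
        Enhancer(Interval(r.chrom, int(r.start), int(r.end)), r.target_gene,
                 frozenset([r.cell_line]), int(r.db_support))
        for r in fixtures["enhancers"].itertuples()
    ]
    consensus = consensus_enhancers(annotations, config.windows.size, config.windows.step)
    gene_spans = {iv.payload: iv for iv in gene_ivs}
    assoc = enhancer_selection_association(
        consensus, fixtures["candidate_regions"], cand_genes, gene_spans
    )
    enrich = {
        "xci": {"table": xci_result.table.tolist(),
                "odds_ratio": _as_plain(xci_result.odds_ratio),
                "p_value": xci_result.p_value},
        "n_consensus_enhancers": len(consensus),
        "enhancer_gene": {"table": assoc.table.tolist(), "p_value": assoc.p_value,
                          "chi2": assoc.extras["chi2"]},
    }
    with open(out / "enrichment.json", "w") as fh:
        json.dump(_as_plain(enrich), fh, indent=2)

    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "stage_seeds": seeds,
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(_as_plain(asdict(config)), sort_keys=True).encode()
        ).hexdigest(),
        "counts": _as_plain(counts),
        "theta": model.theta,
        "rho": model.rho,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return {
        "thresholds": thresholds,
        "called": called,
        "shared": report,
        "enrichment": enrich,
        "xci_result": xci_result,
        "association": assoc,
        "manifest": manifest,
        "fixtures": fixtures,
    }
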