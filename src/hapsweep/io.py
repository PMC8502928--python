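"""Readers and writers: phased VCF, ancestral-allele tables, genetic maps, BED/TSV.

Polarization happens here: every retained SNP is recoded so that the
ancestral allele (from a user-supplied outgroup table, e.g. chimpanzee
states) is 0 and the derived allele is 1.  Sites whose ancestral state is
unknown, or matches neither REF nor ALT, are dropped — no strand-flip
inference is attempted.

VCF input is 1-based; everything internal and every BED written out is
0-based half-open.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import GeneticMap, HaplotypeMatrix, Interval

logger = logging.getLogger(__name__)

__all__ = [
    "read_ancestral_table",
    "read_genetic_map",
    "read_phased_vcf",
    "read_bed",
    "write_bed",
    "write_score_table",
]

_BASES = frozenset("ACGT")


def read_ancestral_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV (site key, ancestral base) -> dict.

    The key may be a variant ID (rs number) or ``chrom:pos1`` with a
    1-based position; lookups at read time try the ID first, then the
    coordinate key.  Bases are upper-cased; anything outside A/C/G/T is
    ignored (treated as unknown ancestral state).
    """
    table: dict[str, str] = {}
    skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, allele = line.split("\t")[:2]
            allele = allele.upper()
            if allele in _BASES:
                table[key] = allele
            else:
                skipped += 1
    if skipped:
        logger.info("ancestral table: %d entries with non-ACGT state ignored", skipped)
    return table


def read_genetic_map(path: str | Path) -> GeneticMap:
    """Oxford-style 3-column map: position(bp), rate(cM/Mb), map(cM).

    A header line is detected and skipped.  Only position and cumulative
    cM are used; the rate column is carried by the format but redundant
    under linear interpolation.
    """
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None, skiprows=_has_header(path))
    if df.shape[1] < 3:
        raise ValueError(f"genetic map {path}: expected 3 columns (bp, rate, cM)")
    return GeneticMap(df.iloc[:, 0].to_numpy(np.int64), df.iloc[:, 2].to_numpy(float))


def _has_header(path: str | Path) -> int:
    with open(path) as fh:
        first = fh.readline().split()
    try:
        float(first[0])
        return 0
    except (ValueError, IndexError):
        return 1


def read_phased_vcf(
    path: str | Path,
    ancestral: Mapping[str, str],
    region: Interval,
    genetic_map: GeneticMap | None = None,
    sample_populations: Mapping[str, str] | None = None,
) -> HaplotypeMatrix:
    """Load phased biallelic SNPs in `region`, polarized to ancestral=0.

    Diploid-phased samples contribute 2 haplotypes, haploid samples (male
    X) contribute 1.  An unphased diploid genotype is a hard error naming
    the offending site.  Sites are dropped (with counts logged) when:
    not a biallelic SNP, outside the region, absent from the ancestral
    table, ancestral state matches neither REF nor ALT, or duplicated
    position (first kept).

    Without a genetic map, genetic positions default to a uniform
    1 cM/Mb.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: list[np.ndarray] = []
    positions: list[int] = []
    ids: list[str] = []
    n_not_biallelic = n_no_ancestral = n_mismatch = n_dup = 0
    hap_of_sample: list[list[int]] | None = None  # row indices per sample

    for var in vcf:
        if var.CHROM != region.chrom:
            continue
        pos0 = var.POS - 1  # 0-based
        if not region.contains_point(pos0):
            continue
        ref, alts = var.REF.upper(), [a.upper() for a in var.ALT]
        if len(alts) != 1 or ref not in _BASES or alts[0] not in _BASES:
            n_not_biallelic += 1
            continue
        alt = alts[0]
        key_id = var.ID if var.ID not in (None, ".") else None
        anc = None
        if key_id is not None:
            anc = ancestral.get(key_id)
        if anc is None:
            anc = ancestral.get(f"{var.CHROM}:{var.POS}")
        if anc is None:
            n_no_ancestral += 1
            continue
        if anc == ref:
            flip = False
        elif anc == alt:
            flip = True
        else:
            n_mismatch += 1
            continue
        if positions and pos0 == positions[-1]:
            n_dup += 1
            continue

        col: list[int] = []
        if hap_of_sample is None:
            hap_of_sample = []
            row = 0
            for gt in var.genotypes:
                n_alleles = len(gt) - 1  # last entry is the phased flag
                k = sum(1 for a in gt[:-1] if a >= 0)
                hap_of_sample.append(list(range(row, row + k)))
                row += k
        for sample, gt in zip(samples, var.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            if len(alleles) > 1 and not gt[-1]:
                raise ValueError(
                    f"unphased genotype for sample {sample} at "
                    f"{var.CHROM}:{var.POS} ({var.ID})"
                )
            col.extend(alleles)
        arr = np.array(col, dtype=np.int8)
        if flip:
            arr = 1 - arr
        columns.append(arr)
        positions.append(pos0)
        ids.append(key_id or f"{var.CHROM}:{var.POS}")

    for what, n in (
        ("non-biallelic/non-SNP", n_not_biallelic),
        ("unknown ancestral state", n_no_ancestral),
        ("ancestral matches neither REF nor ALT", n_mismatch),
        ("duplicate position", n_dup),
    ):
        if n:
            logger.info("read_phased_vcf: dropped %d sites (%s)", n, what)

    if not columns:
        raise ValueError(f"no usable sites in {path} within {region.chrom}:{region.start}-{region.end}")
    alleles = np.stack(columns, axis=1)
    pos_bp = np.array(positions, dtype=np.int64)
    gmap = genetic_map or GeneticMap.uniform(region.end, 1.0)
    pops = np.empty(alleles.shape[0], dtype=object)
    for sample, rows in zip(samples, hap_of_sample):
        label = (sample_populations or {}).get(sample, "pop0")
        for r in rows:
            pops[r] = label
    return HaplotypeMatrix(
        alleles, pos_bp, gmap.interpolate(pos_bp), np.array(ids, dtype=object),
        pops, chrom=region.chrom,
    )


def read_bed(path: str | Path, payload_col: int | None = 3) -> list[Interval]:
    """BED/TSV -> intervals; column `payload_col` (default the 4th) becomes the payload."""
    out: list[Interval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            payload = None
            if payload_col is not None and len(fields) > payload_col:
                payload = fields[payload_col]
            out.append(Interval(fields[0], int(fields[1]), int(fields[2]), payload))
    return out


def write_bed(path: str | Path, intervals: Sequence[Interval], extra: Sequence[Sequence] | None = None) -> None:
    """Write intervals as BED; `extra` supplies additional columns per row."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.payload is not None:
                fields.append(str(iv.payload))
            if extra is not None:
                fields.extend(str(x) for x in extra[i])
            fh.write("\t".join(fields) + "\n")


def write_score_table(path: str | Path, scores: pd.DataFrame) -> None:
    """Per-SNP score table as TSV (chrom, pos, id, daf, statistics, failure_reason)."""
    scores.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_phased_vcf(path: str | Path, hm: HaplotypeMatrix) -> None:
    """Export a haplotype matrix as a phased VCF (one haploid sample per row).

    REF is the ancestral allele (arbitrarily written as A) and ALT the
    derived (written as C): polarization metadata beyond the 0/1 coding
    is not retained by the matrix.  Round trips through
    :func:`read_phased_vcf` with an all-``A`` ancestral table.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={hm.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        names = [f"h{i}" for i in range(hm.n_hap)]
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(names) + "\n")
        for j in range(hm.n_snp):
            gts = "\t".join(str(int(a)) for a in hm.alleles[:, j])
            fh.write(f"{hm.chrom}\t{hm.positions_bp[j] + 1}\t{hm.snp_ids[j]}"
                     f"\tA\tC\t.\t.\t.\tGT\t{gts}\n")
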