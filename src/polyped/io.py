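"""Readers/writers for the standard formats plus the conventional site filter.

Everything in memory is 0-based half-open; VCF's 1-based positions are
converted at this boundary only. Text readers are gzip-transparent (pysam
and pandas both sniff compression).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from .core import ConfigurationError, GenotypeMatrix

logger = logging.getLogger("polyped")

BED_COLUMNS = ["chrom", "start", "end", "id", "score", "strand"]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a multi-sample VCF 4.2 with phased GT when haplotypes exist."""
    header = pysam.VariantHeader()
    for chrom, length in matrix.chrom_lengths.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.info.add("SUBG", 1, "String", "Subgenome tag")
    for s in matrix.samples:
        header.add_sample(s)
    phased = matrix.phased and matrix.haplotypes is not None
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        sites = matrix.sites
        for i in range(matrix.n_sites):
            rec = vf.new_record(
                contig=sites["chrom"].iat[i],
                start=int(sites["pos"].iat[i]),
                alleles=(sites["ref"].iat[i], sites["alt"].iat[i]),
            )
            rec.info["SUBG"] = str(sites["subgenome"].iat[i])
            for j, s in enumerate(matrix.samples):
                if phased:
                    a, b = matrix.haplotypes[i, 2 * j], matrix.haplotypes[i, 2 * j + 1]
                    gt = (None, None) if a < 0 or b < 0 else (int(a), int(b))
                else:
                    code = matrix.gt[i, j]
                    gt = {
                        -1: (None, None),
                        0: (0, 0),
                        1: (0, 1),
                        2: (1, 1),
                    }[int(code)]
                rec.samples[s]["GT"] = gt
                rec.samples[s].phased = bool(phased)
            vf.write(rec)


def read_vcf(
    path: str | Path, groups: pd.Series | None = None
) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix, keeping biallelic SNPs only.

    Multiallelic and indel records are dropped (counts logged). Phased
    records fill the haplotype matrix; the matrix is marked phased only if
    every kept genotype was phased.
    """
    vf = pysam.VariantFile(str(path))
    if "GT" not in vf.header.formats:
        raise ConfigurationError(f"{path}: VCF has no GT FORMAT")
    samples = list(vf.header.samples)
    chrom_lengths = {
        c: vf.header.contigs[c].length or 0 for c in vf.header.contigs
    }
    has_subg = "SUBG" in vf.header.info
    rows, gts, haps = [], [], []
    dropped = {"multiallelic": 0, "indel": 0}
    all_phased = True
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            dropped["multiallelic"] += 1
            continue
        ref, alt = rec.ref, rec.alts[0]
        if len(ref) != 1 or len(alt) != 1:
            dropped["indel"] += 1
            continue
        if has_subg:
            subg = rec.info.get("SUBG", rec.chrom[:1])
        else:
            subg = rec.chrom[:1]
        rows.append((rec.chrom, rec.start, ref, alt, subg))
        g_row = np.empty(len(samples), dtype=np.int8)
        h_row = np.empty(2 * len(samples), dtype=np.int8)
        for j, s in enumerate(samples):
            call = rec.samples[s]
            alleles = call["GT"]
            if alleles is None or any(a is None for a in alleles):
                g_row[j] = -1
                h_row[2 * j : 2 * j + 2] = -1
            else:
                g_row[j] = sum(alleles)
                h_row[2 * j], h_row[2 * j + 1] = alleles
                if not call.phased:
                    all_phased = False
        gts.append(g_row)
        haps.append(h_row)
    vf.close()
    if dropped["multiallelic"] or dropped["indel"]:
        logger.info(
            "read_vcf(%s): dropped %d multiallelic, %d indel records",
            path,
            dropped["multiallelic"],
            dropped["indel"],
        )
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "subgenome"])
    n = len(sites)
    if groups is None:
        groups = pd.Series("all", index=samples)
    mat = GenotypeMatrix(
        samples=samples,
        groups=groups,
        sites=sites,
        gt=np.vstack(gts) if n else np.empty((0, len(samples)), dtype=np.int8),
        haplotypes=np.vstack(haps) if n else np.empty((0, 2 * len(samples)), dtype=np.int8),
        chrom_lengths=chrom_lengths,
        phased=all_phased and n > 0,
    )
    mat.dropped_records = dropped
    return mat


# ---------------------------------------------------------------------------
# BED / TSV / groups
# ---------------------------------------------------------------------------

def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    """Write intervals as BED6 (0-based half-open, natively)."""
    out = df.copy()
    if "id" not in out:
        out["id"] = "."
    if "score" not in out:
        out["score"] = 0
    if "strand" not in out:
        out["strand"] = "+"
    out[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED_COLUMNS[: df.shape[1]]
    return df


def read_groups(path: str | Path) -> pd.Series:
    """sample_id<TAB>group file -> Series indexed by sample."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"])
    return pd.Series(df["group"].to_numpy(), index=df["sample"].to_numpy())


def read_classification(path: str | Path) -> pd.DataFrame:
    """Classification TSV with chrom, pos, site_class and optional score."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "site_class"}
    if not required.issubset(df.columns):
        raise ConfigurationError(
            f"{path}: classification file needs columns {sorted(required)}"
        )
    return df


# ---------------------------------------------------------------------------
# conventional site filter
# ---------------------------------------------------------------------------

def filter_sites(
    matrix: GenotypeMatrix, maf: float = 0.01, max_missing: float = 0.9
) -> GenotypeMatrix:
    """Keep sites with minor-allele frequency >= ``maf`` and call rate >=
    ``max_missing`` (the VCFtools convention: ``--max-missing`` is the
    minimum fraction of called genotypes)."""
    alt, total = matrix.allele_counts()
    called_rate = (total / 2) / matrix.n_samples
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(total > 0, alt / np.maximum(total, 1), 0.0)
    minor = np.minimum(p, 1.0 - p)
    keep = (minor >= maf) & (called_rate >= max_missing)
    logger.info(
        "filter_sites: kept %d / %d sites (maf>=%g, call rate>=%g)",
        int(keep.sum()),
        matrix.n_sites,
        maf,
        max_missing,
    )
    return matrix.subset_sites(keep)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Parameters of a full pipeline run with conventional defaults.

    The config is serialized verbatim into the run report for provenance.
    """

    seed: int = 0
    out_dir: str = "polyped_run"
    # stage parameters (field-standard defaults)
    block_size: int = 50_000
    window: int = 100_000
    step: int = 10_000
    z_threshold: float = 3.0
    fixation_threshold: float = 0.9
    maf: float = 0.01
    max_missing: float = 0.9
    window_snps: int = 50
    bins: int = 20
    anchor_k: int = 21
    min_match_fraction: float = 0.1
    z_scope: str = "genome"  # or "subgenome"
    fixation_level: str = "sample"  # or "haplotype"
    # stage subjects
    ibd_child: str = "NY7"
    ibd_decompose: str = "CY2"
    scan_group_a: str = "AS_DH"
    scan_group_b: str = "EU"
    ancestry_group: str = "AS_DH"
    # inputs: either a simulation scenario or paths to existing files
    simulation: dict | None = None
    vcf: str | None = None
    groups_file: str | None = None
    classification: str | None = None
    genes_bed: str | None = None
    qtl_bed: str | None = None
    assemblies: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
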