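"""Shared containers for allopolyploid pedigree population genomics.

Coordinates are 0-based half-open everywhere in memory; conversion to the
1-based conventions of VCF happens only at the file boundary (`polyped.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: genotype codes used throughout: hom-ref, het, hom-alt, missing
HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigurationError(ValueError):
    """Raised when a simulation or pipeline configuration is invalid."""


@dataclass
class AssemblySet:
    """Named chromosome sequences of one genome (a cultivar or a parent).

    Sequences are stored as uint8 arrays of ASCII codes so that mutation,
    recombination and k-mer encoding are plain vector operations.
    """

    name: str
    sequences: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, seq in self.sequences.items():
            if seq.dtype != np.uint8:
                self.sequences[chrom] = np.asarray(seq, dtype=np.uint8)
            if len(seq) == 0:
                raise ConfigurationError(f"chromosome {chrom!r} is empty")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.sequences)

    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def sequence_str(self, chrom: str) -> str:
        return self.sequences[chrom].tobytes().decode("ascii")

    @classmethod
    def from_fasta(cls, path: str | Path, name: str | None = None) -> "AssemblySet":
        records = {
            rec.id: np.frombuffer(str(rec.seq).upper().encode("ascii"), dtype=np.uint8)
            for rec in SeqIO.parse(str(path), "fasta")
        }
        return cls(name=name or Path(path).stem, sequences=records)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq.tobytes().decode("ascii")), id=chrom, description="")
            for chrom, seq in self.sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")


@dataclass
class GenotypeMatrix:
    """Samples x biallelic sites with per-site metadata.

    Attributes
    ----------
    samples
        Sample identifiers, in column order of ``gt``.
    groups
        Group label per sample (index = sample id).
    sites
        One row per site with columns ``chrom``, ``pos`` (0-based), ``ref``,
        ``alt``, ``subgenome``; positions strictly increasing per chromosome.
    gt
        ``(n_sites, n_samples)`` int8 matrix of genotype codes
        {0 hom-ref, 1 het, 2 hom-alt, -1 missing}.
    haplotypes
        Optional ``(n_sites, 2*n_samples)`` int8 matrix of phased alleles
        (0/1, -1 missing); columns ``2i``/``2i+1`` are sample ``i``.
    chrom_lengths
        Chromosome lengths in bp, needed for window grids.
    """

    samples: list[str]
    groups: pd.Series
    sites: pd.DataFrame
    gt: np.ndarray
    haplotypes: np.ndarray | None = None
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    phased: bool = False

    def __post_init__(self) -> None:
        self.gt = np.asarray(self.gt, dtype=np.int8)
        if self.gt.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"genotype matrix shape {self.gt.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)

    # -- basic geometry -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def validate(self) -> None:
        pos = self.sites["pos"].to_numpy()
        for chrom, idx in self.sites.groupby("chrom", sort=False).indices.items():
            p = pos[idx]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    # -- sample/group helpers -------------------------------------------
    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError as exc:
            raise KeyError(f"unknown sample {sample!r}") from exc

    def group_columns(self, group: str) -> np.ndarray:
        cols = np.flatnonzero(self.groups.reindex(self.samples).to_numpy() == group)
        if cols.size == 0:
            raise KeyError(f"group {group!r} has no samples")
        return cols

    def group_haplotype_columns(self, group: str) -> np.ndarray:
        cols = self.group_columns(group)
        return np.sort(np.concatenate([2 * cols, 2 * cols + 1]))

    # -- allele bookkeeping ---------------------------------------------
    def allele_counts(self, columns: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Alt-allele count and called-allele total per site.

        The alt count is 2x hom-alt + het over called genotypes; the total is
        twice the number of called samples.
        """
        g = self.gt if columns is None else self.gt[:, columns]
        called = g >= 0
        alt = np.where(called, g, 0).sum(axis=1)
        return alt.astype(np.int64), 2 * called.sum(axis=1).astype(np.int64)

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return GenotypeMatrix(
            samples=list(self.samples),
            groups=self.groups,
            sites=self.sites.iloc[idx].reset_index(drop=True),
            gt=self.gt[idx],
            haplotypes=None if self.haplotypes is None else self.haplotypes[idx],
            chrom_lengths=dict(self.chrom_lengths),
            phased=self.phased,
        )

    def subset_samples(self, names: list[str]) -> "GenotypeMatrix":
        cols = np.array([self.sample_index(s) for s in names])
        hap = None
        if self.haplotypes is not None:
            hap_cols = np.concatenate([[2 * c, 2 * c + 1] for c in cols])
            hap = self.haplotypes[:, hap_cols]
        return GenotypeMatrix(
            samples=list(names),
            groups=self.groups.loc[names],
            sites=self.sites.copy(),
            gt=self.gt[:, cols],
            haplotypes=hap,
            chrom_lengths=dict(self.chrom_lengths),
            phased=self.phased,
        )


def random_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform-random ACGT sequence as uint8 ASCII codes."""
    if length <= 0:
        raise ConfigurationError(f"sequence length must be positive, got {length}")
    return _BASES[rng.integers(0, 4, size=length)]


def mutate_sequence(
    seq: np.ndarray, rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Substitute bases at per-bp ``rate``; returns (new sequence, positions).

    Each selected position is replaced by one of the three other bases.
    """
    if rate < 0:
        raise ConfigurationError(f"mutation rate must be >= 0, got {rate}")
    out = seq.copy()
    if rate == 0:
        return out, np.empty(0, dtype=np.int64)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if hits.size:
        # shift by 1..3 in base space to guarantee a different base
        codes = np.searchsorted(_BASES, out[hits])
        out[hits] = _BASES[(codes + rng.integers(1, 4, size=hits.size)) % 4]
    return out, hits


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Union of half-open intervals given as an (n, 2) array, sorted output."""
    if len(intervals) == 0:
        return np.empty((0, 2), dtype=np.int64)
    iv = np.asarray(intervals, dtype=np.int64)
    iv = iv[np.argsort(iv[:, 0], kind="stable")]
    merged = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)
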