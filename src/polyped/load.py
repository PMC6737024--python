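"""Deleterious-variant genetic load: site classification, allele counting,
class frequency spectra with a fixed bin, relative deleterious/neutral
ratios, and per-individual dSNP/iSNP load ratios split by subgenome.

The deleterious (dSNP) class is defined by a damaging-substitution score
below 0.05 (strict); the neutral reference class (iSNP) is SNPs in
intergenic context. The deleterious allele count of a group is twice the
number of homozygous-alternate genotypes plus the heterozygotes, over
called samples only — the alternate allele relative to the ancestral-like
combined reference is treated as the derived/deleterious allele.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .core import GenotypeMatrix

DELETERIOUS = "deleterious"
NEUTRAL = "neutral-intergenic"
OTHER = "other"

SCORE_THRESHOLD = 0.05
FIXED_BIN_LEFT = 0.95  # the "fixed" class is frequency in (0.95, 1]


def classify_sites(annotations: pd.DataFrame) -> pd.DataFrame:
    """Site classes from an annotation table.

    ``annotations`` needs ``chrom``/``pos`` plus a ``score`` column (damaging
    probability; NaN when absent) and/or a boolean/str ``context`` marking
    intergenic sites (``intergenic`` true/"intergenic"). Scores strictly
    below 0.05 are deleterious; intergenic context without a damaging score
    is neutral-intergenic; everything else (including sites with neither
    score nor context, which are warned about) is ``other`` and excluded
    from load statistics.
    """
    score = annotations["score"] if "score" in annotations else pd.Series(np.nan, index=annotations.index)
    score = pd.to_numeric(score, errors="coerce")
    if "context" in annotations:
        ctx = annotations["context"]
        intergenic = (ctx == True) | (ctx.astype(str).str.lower() == "intergenic")  # noqa: E712
    elif "site_class" in annotations:
        intergenic = annotations["site_class"] == NEUTRAL
    else:
        intergenic = pd.Series(False, index=annotations.index)
    deleterious = score < SCORE_THRESHOLD
    site_class = np.where(
        deleterious, DELETERIOUS, np.where(intergenic, NEUTRAL, OTHER)
    )
    orphan = score.isna() & ~intergenic
    if orphan.any():
        warnings.warn(
            f"{int(orphan.sum())} sites have neither score nor intergenic "
            "context; classed 'other'",
            stacklevel=2,
        )
    out = annotations[["chrom", "pos"]].copy()
    out["site_class"] = site_class
    out["score"] = score.to_numpy()
    return out


def count_alleles(
    matrix: GenotypeMatrix, group: str, site_index: int
) -> tuple[int, int]:
    """(alternate-allele count, called-allele total) at one site in a group.

    The count is 2x homozygous-alternate + heterozygous over called
    samples; the total is twice the called samples. A fully missing site
    returns (0, 0) — callers treat it as skipped.
    """
    g = matrix.gt[site_index, matrix.group_columns(group)]
    called = g >= 0
    return int(np.where(called, g, 0).sum()), int(2 * called.sum())


def group_frequencies(
    matrix: GenotypeMatrix, group: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site alternate-allele frequency and called totals for a group.

    Sites with no called genotypes get NaN frequency.
    """
    alt, total = matrix.allele_counts(matrix.group_columns(group))
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(total > 0, alt / np.maximum(total, 1), np.nan)
    return freq, total


@dataclass
class ClassSpectrum:
    """Allele-frequency histograms per site class for one group.

    ``bin_edges`` has ``bins + 1`` entries on [0, 1]; all bins are
    left-open/right-closed so the top bin is the declared "fixed" class
    (0.95, 1] at the default 20 bins. Counts sum to the segregating-site
    count per class (frequency-0 sites are excluded, frequency-1 sites fall
    in the fixed bin).
    """

    group: str
    bin_edges: np.ndarray
    counts: dict[str, np.ndarray]

    def proportions(self, site_class: str) -> np.ndarray:
        c = self.counts[site_class]
        total = c.sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            return c / total if total > 0 else np.full_like(c, np.nan, dtype=float)

    def fixed_bin_index(self) -> int:
        return len(self.bin_edges) - 2

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls, c in self.counts.items():
            for b in range(len(c)):
                rows.append(
                    (
                        self.group,
                        cls,
                        self.bin_edges[b],
                        self.bin_edges[b + 1],
                        int(c[b]),
                    )
                )
        return pd.DataFrame(
            rows, columns=["group", "site_class", "bin_left", "bin_right", "count"]
        )


def _bin_counts(freqs: np.ndarray, edges: np.ndarray) -> np.ndarray:
    # left-open right-closed bins; freq 0 excluded upstream
    idx = np.searchsorted(edges, freqs, side="left") - 1
    idx = np.clip(idx, 0, len(edges) - 2)
    return np.bincount(idx, minlength=len(edges) - 1)


def frequency_spectrum(
    matrix: GenotypeMatrix,
    classification: pd.DataFrame,
    group: str,
    bins: int = 20,
    classes: tuple[str, ...] = (DELETERIOUS, NEUTRAL),
    folded: bool = False,
) -> ClassSpectrum:
    """Alt-allele frequency histogram per class over ``bins`` equal bins.

    Monomorphic-reference sites (frequency 0) are excluded; the top bin is
    the "fixed" bin. ``folded=True`` histograms minor-allele frequencies
    instead (the fixed bin is then empty by construction).
    """
    cls = _aligned_classes(matrix, classification)
    freq, total = group_frequencies(matrix, group)
    edges = np.linspace(0.0, 1.0, bins + 1)
    counts: dict[str, np.ndarray] = {}
    for c in classes:
        f = freq[(cls == c) & (total > 0)]
        f = f[np.isfinite(f) & (f > 0)]
        if folded:
            f = np.minimum(f, 1.0 - f)
            f = f[f > 0]
        counts[c] = _bin_counts(f, edges)
    return ClassSpectrum(group=group, bin_edges=edges, counts=counts)


def relative_load(spectrum: ClassSpectrum) -> np.ndarray:
    """Per-bin ratio of deleterious proportion to neutral proportion.

    Bins with zero neutral mass are NaN (undefined); an empty class
    histogram yields all-NaN with a warning.
    """
    d = spectrum.counts.get(DELETERIOUS)
    n = spectrum.counts.get(NEUTRAL)
    if d is None or n is None:
        raise KeyError("spectrum must hold deleterious and neutral histograms")
    if d.sum() == 0 or n.sum() == 0:
        warnings.warn("empty class histogram: relative load undefined", stacklevel=2)
        return np.full(len(d), np.nan)
    dp = d / d.sum()
    np_ = n / n.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(np_ > 0, dp / np.where(np_ > 0, np_, 1.0), np.nan)
    return out


def _aligned_classes(matrix: GenotypeMatrix, classification: pd.DataFrame) -> np.ndarray:
    """Site classes aligned to the matrix site order via (chrom, pos)."""
    key = classification.set_index(["chrom", "pos"])["site_class"]
    idx = pd.MultiIndex.from_frame(matrix.sites[["chrom", "pos"]])
    return key.reindex(idx).fillna(OTHER).to_numpy()


def individual_load(
    matrix: GenotypeMatrix,
    classification: pd.DataFrame,
    sample: str,
    dosage: bool = False,
) -> pd.DataFrame:
    """dSNP/iSNP load ratios of one individual, per subgenome and overall.

    The dSNP count is the number of deleterious-class sites where the
    individual carries at least one alternate allele (site presence; with
    ``dosage=True`` alleles are counted instead); iSNP analogous over the
    neutral-intergenic class. Rows with zero iSNPs carry a NaN ratio and an
    ``undefined`` flag.
    """
    col = matrix.sample_index(sample)
    g = matrix.gt[:, col]
    cls = _aligned_classes(matrix, classification)
    carrier = np.where(g > 0, g if dosage else 1, 0)
    sub = matrix.sites["subgenome"].to_numpy()
    rows = []
    scopes = [("all", np.ones(len(g), dtype=bool))] + [
        (s, sub == s) for s in pd.unique(sub)
    ]
    for scope, mask in scopes:
        d = int(carrier[mask & (cls == DELETERIOUS)].sum())
        i = int(carrier[mask & (cls == NEUTRAL)].sum())
        rows.append(
            (sample, scope, d, i, d / i if i > 0 else np.nan, i == 0)
        )
    return pd.DataFrame(
        rows,
        columns=["sample", "subgenome", "dsnp", "isnp", "ratio", "undefined"],
    )


def group_load_table(
    matrix: GenotypeMatrix, classification: pd.DataFrame, samples: list[str] | None = None
) -> pd.DataFrame:
    """Per-individual load ratios for many samples, long format."""
    samples = samples if samples is not None else matrix.samples
    return pd.concat(
        [individual_load(matrix, classification, s) for s in samples],
        ignore_index=True,
    )
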