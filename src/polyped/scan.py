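"""Windowed selection scans: nucleotide diversity, Weir-Cockerham FST,
Z-transformation with 3-SD divergent-region calling, feature intersection
and LD decay.

Windows are laid on a fixed grid (100 kb size, 10 kb step by default, the
convention of VCFtools' ``--window-pi``/``--fst-window-size`` runs) anchored
at position 0 of each chromosome; trailing partial windows are kept with
their true span as denominator. Window FST is the "ratio of averages":
per-site variance components summed over the window before the division, so
raw window values may be negative and are deliberately not clamped before
the Z-transformation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import GenotypeMatrix


class ZeroVarianceError(ValueError):
    """Z-transformation is undefined on a constant vector."""


def _window_grid(length: int, window: int, step: int) -> np.ndarray:
    starts = np.arange(0, length, step)
    ends = np.minimum(starts + window, length)
    return np.column_stack([starts, ends])


def _window_sums(
    pos: np.ndarray, values: np.ndarray, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Sum of per-site values and site counts per [start, end) window."""
    order = np.argsort(pos, kind="stable")
    pos, values = pos[order], values[order]
    csum = np.concatenate([[0.0], np.cumsum(values)])
    lo = np.searchsorted(pos, grid[:, 0], side="left")
    hi = np.searchsorted(pos, grid[:, 1], side="left")
    return csum[hi] - csum[lo], (hi - lo).astype(np.int64)


def _per_site_pi(matrix: GenotypeMatrix, group: str) -> tuple[np.ndarray, np.ndarray]:
    cols = matrix.group_columns(group)
    alt, total = matrix.allele_counts(cols)
    ok = total >= 2
    pi = np.zeros(matrix.n_sites)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(total > 0, alt / np.maximum(total, 1), 0.0)
        pi[ok] = 2.0 * p[ok] * (1.0 - p[ok]) * total[ok] / (total[ok] - 1.0)
    return pi, ok


def windowed_pi(
    matrix: GenotypeMatrix,
    group: str,
    window: int = 100_000,
    step: int = 10_000,
) -> pd.DataFrame:
    """Sliding-window nucleotide diversity for one group.

    Per site, heterozygosity is 2*p*(1-p)*n/(n-1) with n the called allele
    count; the window value is the sum over sites divided by the window span
    in bp, i.e. the mean pairwise difference per bp.
    """
    pi, ok = _per_site_pi(matrix, group)
    pos = matrix.sites["pos"].to_numpy()
    chroms = matrix.sites["chrom"].to_numpy()
    frames = []
    for chrom, length in matrix.chrom_lengths.items():
        grid = _window_grid(length, window, step)
        m = (chroms == chrom) & ok
        sums, counts = _window_sums(pos[m], pi[m], grid)
        span = grid[:, 1] - grid[:, 0]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": grid[:, 0],
                    "end": grid[:, 1],
                    "value": sums / span,
                    "n_sites": counts,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def weir_cockerham_components(
    n1: np.ndarray,
    p1: np.ndarray,
    h1: np.ndarray,
    n2: np.ndarray,
    p2: np.ndarray,
    h2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir & Cockerham (1984) variance components a, b, c.

    Two populations (r=2); n_i called diploids, p_i alt-allele frequency,
    h_i observed heterozygote proportion. Sites where a population has no
    calls, or the mean sample size is <= 1, return NaN components.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    bad = (n1 < 1) | (n2 < 1) | (nbar <= 1) | (nc <= 0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def _group_site_stats(matrix: GenotypeMatrix, group: str):
    g = matrix.gt[:, matrix.group_columns(group)]
    called = (g >= 0).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(g >= 0, g, 0).sum(axis=1) / (2.0 * np.maximum(called, 1))
        h = (g == 1).sum(axis=1) / np.maximum(called, 1)
    return called, p, h


def windowed_fst(
    matrix: GenotypeMatrix,
    group_a: str,
    group_b: str,
    window: int = 100_000,
    step: int = 10_000,
) -> pd.DataFrame:
    """Sliding-window Weir-Cockerham FST between two groups.

    Window value = sum of per-site a components / sum of (a+b+c) over sites
    in the window; raw (possibly negative) values are reported. Windows
    without usable sites carry NaN.
    """
    n1, p1, h1 = _group_site_stats(matrix, group_a)
    n2, p2, h2 = _group_site_stats(matrix, group_b)
    a, b, c = weir_cockerham_components(n1, p1, h1, n2, p2, h2)
    usable = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    pos = matrix.sites["pos"].to_numpy()
    chroms = matrix.sites["chrom"].to_numpy()
    frames = []
    for chrom, length in matrix.chrom_lengths.items():
        grid = _window_grid(length, window, step)
        m = (chroms == chrom) & usable
        num, counts = _window_sums(pos[m], a[m], grid)
        den, _ = _window_sums(pos[m], (a + b + c)[m], grid)
        with np.errstate(invalid="ignore", divide="ignore"):
            val = np.where(den != 0, num / np.where(den != 0, den, 1.0), np.nan)
        val = np.where(counts > 0, val, np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": grid[:, 0],
                    "end": grid[:, 1],
                    "value": val,
                    "n_sites": counts,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def per_site_fst(
    matrix: GenotypeMatrix, group_a: str, group_b: str
) -> np.ndarray:
    """Per-site Weir-Cockerham FST a/(a+b+c); NaN where undefined."""
    n1, p1, h1 = _group_site_stats(matrix, group_a)
    n2, p2, h2 = _group_site_stats(matrix, group_b)
    a, b, c = weir_cockerham_components(n1, p1, h1, n2, p2, h2)
    with np.errstate(invalid="ignore", divide="ignore"):
        return a / (a + b + c)


def zscore(values: np.ndarray) -> np.ndarray:
    """(x - mean) / sd over non-missing entries; NaN stays NaN.

    Uses the sample standard deviation (ddof=1). Raises
    :class:`ZeroVarianceError` on fewer than two non-missing values or a
    constant vector rather than silently emitting NaN.
    """
    x = np.asarray(values, dtype=float)
    ok = np.isfinite(x)
    if ok.sum() < 2:
        raise ZeroVarianceError("need at least two non-missing values")
    sd = np.std(x[ok], ddof=1)
    if sd == 0:
        raise ZeroVarianceError("zero variance: Z-scores undefined")
    out = np.full_like(x, np.nan)
    out[ok] = (x[ok] - np.mean(x[ok])) / sd
    return out


@dataclass
class DivergentRegions:
    regions: pd.DataFrame  # chrom, start, end, peak_z, n_windows
    n_flagged_windows: int
    total_bp: int


def call_divergent_regions(
    windows: pd.DataFrame, threshold: float = 3.0, column: str = "z"
) -> DivergentRegions:
    """Merge windows with Z above ``threshold`` into maximal regions.

    Flagged windows that overlap or abut on the grid are merged; each region
    reports its span, peak Z and contributing window count.
    """
    windows = windows.reset_index(drop=True)
    z = windows[column].to_numpy(dtype=float)
    flagged = np.isfinite(z) & (z > threshold)
    rows = []
    for chrom, sub in windows.groupby("chrom", sort=False):
        idx = sub.index[flagged[sub.index]]
        if len(idx) == 0:
            continue
        f = windows.loc[idx].sort_values("start")
        cur_s, cur_e, peak, count = None, None, -np.inf, 0
        for _, w in f.iterrows():
            if cur_s is None or w.start > cur_e:
                if cur_s is not None:
                    rows.append((chrom, cur_s, cur_e, peak, count))
                cur_s, cur_e, peak, count = w.start, w.end, w[column], 1
            else:
                cur_e = max(cur_e, w.end)
                peak = max(peak, w[column])
                count += 1
        rows.append((chrom, cur_s, cur_e, peak, count))
    regions = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "peak_z", "n_windows"]
    )
    total_bp = int((regions["end"] - regions["start"]).sum()) if len(rows) else 0
    return DivergentRegions(
        regions=regions, n_flagged_windows=int(flagged.sum()), total_bp=total_bp
    )


def intersect_features(
    regions: pd.DataFrame, features: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Features overlapping each region by >= 1 bp (half-open coordinates).

    Returns the regions with an added ``feature_ids`` column and the
    deduplicated global count of overlapped features. Features on
    chromosomes absent from the regions are simply never hit; regions on
    chromosomes absent from the features get empty lists.
    """
    trees: dict[str, IntervalTree] = {}
    for _, f in features.iterrows():
        trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f.id)
    hits_per_region = []
    all_hits: set[str] = set()
    for _, r in regions.iterrows():
        tree = trees.get(r.chrom)
        ids = sorted({iv.data for iv in tree.overlap(r.start, r.end)}) if tree else []
        hits_per_region.append(ids)
        all_hits.update(ids)
    out = regions.copy()
    out["feature_ids"] = hits_per_region
    return out, len(all_hits)


def ld_decay(
    matrix: GenotypeMatrix,
    group: str,
    max_dist: int = 100_000,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Mean genotype-correlation r^2 by pairwise distance bin.

    All intra-chromosome site pairs within ``max_dist`` contribute; pairs
    with a monomorphic member are skipped. Bins without a single pair are
    reported with NaN.
    """
    cols = matrix.group_columns(group)
    g = matrix.gt[:, cols].astype(float)
    g[g < 0] = np.nan
    pos = matrix.sites["pos"].to_numpy()
    chroms = matrix.sites["chrom"].to_numpy()
    edges = np.linspace(0, max_dist, n_bins + 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for chrom in matrix.chrom_lengths:
        idx = np.flatnonzero(chroms == chrom)
        p = pos[idx]
        for ii, si in enumerate(idx):
            x = g[si]
            jmax = np.searchsorted(p, p[ii] + max_dist, side="right")
            for jj in range(ii + 1, jmax):
                sj = idx[jj]
                y = g[sj]
                ok = np.isfinite(x) & np.isfinite(y)
                if ok.sum() < 2:
                    continue
                xs, ys = x[ok], y[ok]
                vx, vy = xs.var(), ys.var()
                if vx == 0 or vy == 0:
                    continue
                r = ((xs - xs.mean()) * (ys - ys.mean())).mean() / np.sqrt(vx * vy)
                d = p[jj] - p[ii]
                b = min(int(np.searchsorted(edges, d, side="right")) - 1, n_bins - 1)
                sums[b] += r * r
                counts[b] += 1
    mids = (edges[:-1] + edges[1:]) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({"dist_mid": mids, "mean_r2": mean_r2, "n_pairs": counts})
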