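"""Window-based local-ancestry painting and introgression fixation calling.

Each query haplotype is painted against two phased source panels in windows
of a fixed number of consecutive SNPs (50 by default): a window takes the
label of the panel whose *closest* haplotype (smallest Hamming distance over
called sites) is nearer to the query; exact ties are left unresolved. This
nearest-panel-haplotype painter is a deliberately transparent stand-in for
copying-model local-ancestry engines: the downstream summaries (per-window
donor frequency across the population and the strict >90% fixation rule)
are the analysis of interest here, and an adapter accepts externally
produced per-site ancestry matrices for parity runs.

SNP-count windows are converted to bp spans for reporting using the
midpoints between flanking sites, so windows tile each chromosome exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeMatrix

UNRESOLVED = "unresolved"


@dataclass
class WindowGrid:
    """Shared SNP-window grid: per chromosome, site-index bounds and bp spans."""

    chrom: np.ndarray  # per window
    first_site: np.ndarray
    last_site: np.ndarray  # exclusive, within-chromosome site indices
    start_bp: np.ndarray
    end_bp: np.ndarray

    @property
    def n_windows(self) -> int:
        return len(self.chrom)

    def matches(self, other: "WindowGrid") -> bool:
        return (
            self.n_windows == other.n_windows
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.first_site, other.first_site)
            and np.array_equal(self.last_site, other.last_site)
        )


def make_window_grid(
    sites: pd.DataFrame, chrom_lengths: dict[str, int], window_snps: int = 50
) -> WindowGrid:
    """Non-overlapping windows of ``window_snps`` consecutive sites.

    The last window of a chromosome absorbs the remainder (it may hold up to
    ``2*window_snps - 1`` sites) so every site belongs to exactly one
    window. Window bp bounds are the midpoints between flanking sites, with
    chromosome ends closing the first and last windows.
    """
    if window_snps < 1:
        raise ValueError("window_snps must be >= 1")
    chroms, firsts, lasts, starts, ends = [], [], [], [], []
    pos_all = sites["pos"].to_numpy()
    for chrom, idx in sites.groupby("chrom", sort=False).indices.items():
        pos = pos_all[idx]
        n = len(pos)
        length = chrom_lengths[chrom]
        bounds = list(range(0, n, window_snps))
        if len(bounds) > 1 and n - bounds[-1] < window_snps:
            bounds = bounds[:-1]
        for bi, first in enumerate(bounds):
            last = bounds[bi + 1] if bi + 1 < len(bounds) else n
            start_bp = 0 if first == 0 else (pos[first - 1] + pos[first] + 1) // 2
            end_bp = length if last == n else (pos[last - 1] + pos[last] + 1) // 2
            chroms.append(chrom)
            firsts.append(first)
            lasts.append(last)
            starts.append(int(start_bp))
            ends.append(int(end_bp))
    return WindowGrid(
        chrom=np.asarray(chroms, dtype=object),
        first_site=np.asarray(firsts),
        last_site=np.asarray(lasts),
        start_bp=np.asarray(starts, dtype=np.int64),
        end_bp=np.asarray(ends, dtype=np.int64),
    )


def _panel_haps(panel: GenotypeMatrix | np.ndarray) -> np.ndarray:
    hap = panel.haplotypes if isinstance(panel, GenotypeMatrix) else np.asarray(panel)
    if hap is None or hap.size == 0:
        raise ValueError("empty source panel")
    return hap


def _min_hamming(query: np.ndarray, panel: np.ndarray) -> int:
    """Smallest Hamming distance from query to any panel haplotype,
    counted over sites where both alleles are called."""
    q = query[:, None]
    valid = (q >= 0) & (panel >= 0)
    d = ((q != panel) & valid).sum(axis=0)
    return int(d.min())


def paint_haplotype(
    haplotype: np.ndarray,
    panel_a: GenotypeMatrix | np.ndarray,
    panel_b: GenotypeMatrix | np.ndarray,
    grid: WindowGrid,
    sites: pd.DataFrame,
    label_a: str = "sourceA",
    label_b: str = "sourceB",
) -> pd.DataFrame:
    """Ancestry track of one haplotype: one labeled row per grid window."""
    hap_a = _panel_haps(panel_a)
    hap_b = _panel_haps(panel_b)
    chrom_idx = sites.groupby("chrom", sort=False).indices
    labels = []
    for w in range(grid.n_windows):
        idx = chrom_idx[grid.chrom[w]][grid.first_site[w] : grid.last_site[w]]
        q = haplotype[idx]
        da = _min_hamming(q, hap_a[idx])
        db = _min_hamming(q, hap_b[idx])
        labels.append(label_a if da < db else label_b if db < da else UNRESOLVED)
    return pd.DataFrame(
        {
            "chrom": grid.chrom,
            "start": grid.start_bp,
            "end": grid.end_bp,
            "label": labels,
        }
    )


def paint_population(
    query: GenotypeMatrix,
    panel_a: GenotypeMatrix | np.ndarray,
    panel_b: GenotypeMatrix | np.ndarray,
    window_snps: int = 50,
    label_a: str = "sourceA",
    label_b: str = "sourceB",
) -> tuple[pd.DataFrame, WindowGrid]:
    """Paint every haplotype of ``query``; returns long-format label table.

    The result has one row per (haplotype, window) with columns sample,
    haplotype, chrom, start, end, label, sharing one grid.
    """
    grid = make_window_grid(query.sites, query.chrom_lengths, window_snps)
    hap_a = _panel_haps(panel_a)
    hap_b = _panel_haps(panel_b)
    chrom_idx = query.sites.groupby("chrom", sort=False).indices
    n_hap = query.haplotypes.shape[1]
    # distance of every query hap to the closest panel hap, window by window
    labels = np.empty((grid.n_windows, n_hap), dtype=object)
    for w in range(grid.n_windows):
        idx = chrom_idx[grid.chrom[w]][grid.first_site[w] : grid.last_site[w]]
        q = query.haplotypes[idx]  # (s, n_hap)
        pa = hap_a[idx]  # (s, na)
        pb = hap_b[idx]
        da = _pairwise_min_dist(q, pa)
        db = _pairwise_min_dist(q, pb)
        lab = np.where(da < db, label_a, np.where(db < da, label_b, UNRESOLVED))
        labels[w] = lab
    rows = []
    for h in range(n_hap):
        sample = query.samples[h // 2]
        for w in range(grid.n_windows):
            rows.append(
                (
                    sample,
                    h,
                    grid.chrom[w],
                    grid.start_bp[w],
                    grid.end_bp[w],
                    labels[w, h],
                )
            )
    tracks = pd.DataFrame(
        rows, columns=["sample", "haplotype", "chrom", "start", "end", "label"]
    )
    return tracks, grid


def _pairwise_min_dist(q: np.ndarray, panel: np.ndarray) -> np.ndarray:
    """Min Hamming distance of each query hap (columns of q) to the panel."""
    qv = q[:, :, None] != panel[:, None, :]
    valid = (q[:, :, None] >= 0) & (panel[:, None, :] >= 0)
    return (qv & valid).sum(axis=0).min(axis=1)


def population_ancestry_frequency(
    tracks: pd.DataFrame,
    donor_label: str,
    level: str = "sample",
) -> pd.DataFrame:
    """Per-window fraction of samples (or haplotypes) carrying donor ancestry.

    At ``level='sample'`` a diploid counts as carrying when at least one of
    its two haplotypes is donor-labeled in the window (fixation is
    conventionally reported over samples); ``level='haplotype'`` counts haplotypes
    directly. All tracks must share one window grid.
    """
    if level not in ("sample", "haplotype"):
        raise ValueError(f"unknown counting level {level!r}")
    key = ["chrom", "start", "end"]
    per_window = tracks.groupby(key, sort=False)
    sizes = per_window["haplotype"].nunique()
    if sizes.nunique() > 1:
        raise ValueError("tracks are not on a consistent window grid")
    donor = tracks[tracks["label"] == donor_label]
    if level == "haplotype":
        total = tracks.groupby(key, sort=False)["haplotype"].nunique()
        carrying = donor.groupby(key, sort=False)["haplotype"].nunique()
    else:
        total = tracks.groupby(key, sort=False)["sample"].nunique()
        carrying = donor.groupby(key, sort=False)["sample"].nunique()
    frac = (carrying.reindex(total.index).fillna(0) / total).rename("fraction")
    out = frac.reset_index()
    order = tracks[key].drop_duplicates().reset_index(drop=True)
    return order.merge(out, on=key, how="left")


@dataclass
class FixedIntrogressions:
    regions: pd.DataFrame  # chrom, start, end, n_windows, peak_fraction
    total_bp: int


def call_fixed_introgressions(
    fixation: pd.DataFrame, threshold: float = 0.9
) -> FixedIntrogressions:
    """Merge windows with donor fraction strictly above ``threshold``.

    The strict inequality implements the "found in >90% of samples" rule: a
    window at exactly the threshold is not flagged. Adjacent or overlapping
    flagged windows merge into maximal regions; total covered bp is
    reported.
    """
    rows = []
    for chrom, sub in fixation.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        flagged = sub[sub["fraction"] > threshold]
        cur = None
        for _, w in flagged.iterrows():
            if cur is None or w.start > cur[1]:
                if cur is not None:
                    rows.append((chrom, *cur))
                cur = [w.start, w.end, 1, w.fraction]
            else:
                cur[1] = max(cur[1], w.end)
                cur[2] += 1
                cur[3] = max(cur[3], w.fraction)
        if cur is not None:
            rows.append((chrom, *cur))
    regions = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_windows", "peak_fraction"]
    )
    total = int((regions["end"] - regions["start"]).sum()) if len(rows) else 0
    return FixedIntrogressions(regions=regions, total_bp=total)


def ancestry_from_site_matrix(
    site_labels: np.ndarray,
    sites: pd.DataFrame,
    chrom_lengths: dict[str, int],
    samples: list[str],
    window_snps: int = 50,
    label_a: str = "sourceA",
    label_b: str = "sourceB",
) -> tuple[pd.DataFrame, WindowGrid]:
    """Adapter: collapse an external per-site ancestry matrix to windows.

    ``site_labels`` is (n_sites, n_haplotypes) of 0/1 source codes (the
    output convention of haplotype-copying ancestry tools). Each window
    takes the majority source; exact ties are unresolved.
    """
    grid = make_window_grid(sites, chrom_lengths, window_snps)
    chrom_idx = sites.groupby("chrom", sort=False).indices
    rows = []
    n_hap = site_labels.shape[1]
    for w in range(grid.n_windows):
        idx = chrom_idx[grid.chrom[w]][grid.first_site[w] : grid.last_site[w]]
        block = site_labels[idx]
        ones = (block == 1).sum(axis=0)
        zeros = (block == 0).sum(axis=0)
        lab = np.where(zeros > ones, label_a, np.where(ones > zeros, label_b, UNRESOLVED))
        for h in range(n_hap):
            rows.append(
                (
                    samples[h // 2],
                    h,
                    grid.chrom[w],
                    grid.start_bp[w],
                    grid.end_bp[w],
                    lab[h],
                )
            )
    tracks = pd.DataFrame(
        rows, columns=["sample", "haplotype", "chrom", "start", "end", "label"]
    )
    return tracks, grid
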