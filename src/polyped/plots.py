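"""Simple static figures: IBD tracks, class spectra and LD-decay curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .load import ClassSpectrum


def plot_ibd_track(track: pd.DataFrame, path: str, colors: dict | None = None) -> None:
    """Horizontal bars per chromosome, colored by origin label."""
    chroms = list(dict.fromkeys(track["chrom"]))
    origins = sorted(track["origin"].unique())
    cmap = plt.get_cmap("tab10")
    colors = colors or {o: cmap(i % 10) for i, o in enumerate(origins)}
    fig, ax = plt.subplots(figsize=(10, 0.4 * len(chroms) + 1))
    for yi, chrom in enumerate(chroms):
        for _, b in track[track["chrom"] == chrom].iterrows():
            ax.barh(
                yi,
                b.end - b.start,
                left=b.start,
                height=0.6,
                color=colors.get(b.origin, "lightgrey"),
            )
    ax.set_yticks(range(len(chroms)), chroms)
    ax.set_xlabel("position (bp)")
    handles = [plt.Rectangle((0, 0), 1, 1, color=colors[o]) for o in origins]
    ax.legend(handles, origins, loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_spectrum(spectrum: ClassSpectrum, path: str) -> None:
    """Side-by-side class frequency histograms with the fixed bin marked."""
    fig, ax = plt.subplots(figsize=(7, 4))
    edges = spectrum.bin_edges
    width = (edges[1] - edges[0]) / (len(spectrum.counts) + 1)
    for i, (cls, counts) in enumerate(spectrum.counts.items()):
        ax.bar(edges[:-1] + i * width, counts, width=width, align="edge", label=cls)
    ax.axvline(edges[-2], ls="--", c="k", lw=0.8)
    ax.set_xlabel("allele frequency")
    ax.set_ylabel("site count")
    ax.set_title(f"{spectrum.group}: class frequency spectra (dashed = fixed bin)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_ld_decay(curves: dict[str, pd.DataFrame], path: str) -> None:
    """Mean r^2 vs distance for one curve per group."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, df in curves.items():
        ax.plot(df["dist_mid"], df["mean_r2"], marker="o", ms=3, label=name)
    ax.set_xlabel("pairwise distance (bp)")
    ax.set_ylabel(r"mean $r^2$")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
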