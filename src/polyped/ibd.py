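"""Block-wise identity-by-descent tracing of a derived genome to its parents.

The derived genome is cut into fixed-length blocks (50 kb by default). Each
block is scored against every candidate parent by the total number of block
positions covered by an exact match of length >= k to anywhere in that
parent (k-mer anchored exact matching; the engine is self-contained and
checked against an exhaustive substring oracle in the test suite). The block
is assigned to the parent with the longest accumulated match length; exact
ties and matches below a floor fraction of the block length are left
unassigned. A parent's blocks can then be re-scored against that parent's
own parents to decompose its contribution one generation further back.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AssemblySet, ConfigurationError

UNASSIGNED = "unassigned"

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODE[_b] = _i


def segment_blocks(
    chromosome_lengths: dict[str, int], block_size: int = 50_000
) -> pd.DataFrame:
    """Consecutive non-overlapping blocks tiling each chromosome exactly.

    The last block of a chromosome may be shorter than ``block_size``.
    """
    if block_size <= 0:
        raise ConfigurationError(f"block_size must be positive, got {block_size}")
    rows = []
    for chrom, length in chromosome_lengths.items():
        if length <= 0:
            raise ConfigurationError(f"chromosome {chrom!r} has length {length}")
        starts = np.arange(0, length, block_size)
        for s in starts:
            rows.append((chrom, int(s), int(min(s + block_size, length))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _encode_kmers(seq: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit packed k-mers (uint64) and a validity mask (no ambiguous base)."""
    codes = _CODE[seq]
    n = len(seq) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    vals = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        vals = (vals << np.uint64(2)) | codes[j : j + n].astype(np.uint64)
    bad = np.cumsum(np.concatenate([[0], (codes > 3).astype(np.int64)]))
    valid = (bad[k:] - bad[:-k]) == 0
    return vals, valid


class KmerIndex:
    """Sorted set of all valid k-mers of one genome, for membership queries."""

    def __init__(self, assembly: AssemblySet, k: int = 21):
        if k < 11:
            raise ConfigurationError(f"anchor k must be >= 11, got {k}")
        self.k = k
        self.name = assembly.name
        parts = []
        for seq in assembly.sequences.values():
            vals, valid = _encode_kmers(seq, k)
            parts.append(vals[valid])
        # sorted with duplicates: membership via searchsorted is unaffected
        self._kmers = np.sort(np.concatenate(parts)) if parts else np.empty(0, np.uint64)

    def contains(self, query: np.ndarray) -> np.ndarray:
        if len(self._kmers) == 0:
            return np.zeros(len(query), dtype=bool)
        idx = np.searchsorted(self._kmers, query)
        idx[idx == len(self._kmers)] = 0
        return self._kmers[idx] == query


def _covered_length(starts: np.ndarray, k: int) -> int:
    """Union length of intervals [s, s+k) for sorted starts."""
    if starts.size == 0:
        return 0
    gaps = np.diff(starts)
    return int(np.minimum(gaps, k).sum() + k)


def match_lengths(
    block_sequence: np.ndarray,
    parent_indexes: dict[str, KmerIndex],
    k: int | None = None,
) -> dict[str, int]:
    """Accumulated exact-match length of one block against each parent.

    The value for a parent is the number of block positions covered by at
    least one exact match of length >= k to that parent, computed as the
    union of [s, s+k) over every matched k-mer start s (equivalent to the
    exhaustive enumeration of exact substrings >= k). Entirely ambiguous
    blocks score 0 against everything.
    """
    if not parent_indexes:
        raise ConfigurationError("no parent indexes given")
    ks = {idx.k for idx in parent_indexes.values()}
    if k is None:
        if len(ks) != 1:
            raise ConfigurationError("parents indexed with different k")
        k = ks.pop()
    out: dict[str, int] = {}
    vals, valid = _encode_kmers(np.asarray(block_sequence, dtype=np.uint8), k)
    for name, index in parent_indexes.items():
        if vals.size == 0:
            out[name] = 0
            continue
        hit = valid & index.contains(vals)
        out[name] = _covered_length(np.flatnonzero(hit), k)
    return out


def build_match_table(
    child: AssemblySet,
    parents: dict[str, AssemblySet] | dict[str, KmerIndex],
    block_size: int = 50_000,
    anchor_k: int = 21,
) -> pd.DataFrame:
    """Match lengths for every block of ``child`` against every parent.

    Returns a DataFrame with columns chrom/start/end plus one column per
    parent holding the accumulated match length in bp.
    """
    indexes = {
        name: (p if isinstance(p, KmerIndex) else KmerIndex(p, anchor_k))
        for name, p in parents.items()
    }
    ks = {idx.k for idx in indexes.values()}
    if len(ks) != 1:
        raise ConfigurationError("parents indexed with different k")
    k = ks.pop()
    blocks = segment_blocks(child.chrom_lengths(), block_size)
    cols = {name: np.zeros(len(blocks), dtype=np.int64) for name in indexes}
    for chrom, sub in blocks.groupby("chrom", sort=False):
        vals, valid = _encode_kmers(child.sequences[chrom], k)
        for name, index in indexes.items():
            if vals.size == 0:
                continue
            hitpos = np.flatnonzero(valid & index.contains(vals))
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            lo = np.searchsorted(hitpos, starts, side="left")
            hi = np.searchsorted(hitpos, ends - k, side="right")
            for j, i in enumerate(sub.index):
                cols[name][i] = _covered_length(hitpos[lo[j] : hi[j]], k)
    for name, v in cols.items():
        blocks[name] = v
    return blocks


def assign_blocks(
    matches: pd.DataFrame, min_match_fraction: float = 0.1
) -> pd.DataFrame:
    """Label each block with the parent of longest accumulated match.

    A block is ``unassigned`` when the best match is below
    ``min_match_fraction`` of the block length or the top two parents tie
    exactly. Returns the IBD track (chrom, start, end, origin).
    """
    parent_cols = [c for c in matches.columns if c not in ("chrom", "start", "end")]
    if not parent_cols:
        raise ConfigurationError("match table has no parent columns")
    vals = matches[parent_cols].to_numpy(dtype=np.int64)
    block_len = (matches["end"] - matches["start"]).to_numpy()
    order = np.argsort(vals, axis=1)
    best = vals[np.arange(len(vals)), order[:, -1]]
    second = vals[np.arange(len(vals)), order[:, -2]] if len(parent_cols) > 1 else np.zeros(len(vals), dtype=np.int64)
    labels = np.array(parent_cols, dtype=object)[order[:, -1]]
    floor = min_match_fraction * block_len
    labels[(best < floor) | ((best == second) & (len(parent_cols) > 1))] = UNASSIGNED
    track = matches[["chrom", "start", "end"]].copy()
    track["origin"] = labels
    return track


def trace_origin(
    child: AssemblySet,
    parents: dict[str, AssemblySet],
    block_size: int = 50_000,
    anchor_k: int = 21,
    min_match_fraction: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full tracing: returns (match table, IBD track)."""
    table = build_match_table(child, parents, block_size, anchor_k)
    return table, assign_blocks(table, min_match_fraction)


def decompose_parent(
    track: pd.DataFrame,
    parent: str,
    child: AssemblySet,
    grandparent_assemblies: dict[str, AssemblySet],
    anchor_k: int = 21,
    min_match_fraction: float = 0.1,
) -> pd.DataFrame:
    """Re-score the blocks attributed to ``parent`` against its own parents.

    Blocks labeled ``parent`` become ``parent:<grandparent>``, or
    ``parent:unresolved`` on ties/floor; other blocks are untouched.
    """
    if not (track["origin"] == parent).any():
        raise ConfigurationError(f"parent {parent!r} absent from track")
    indexes = {g: KmerIndex(a, anchor_k) for g, a in grandparent_assemblies.items()}
    out = track.copy()
    for i in np.flatnonzero((track["origin"] == parent).to_numpy()):
        row = track.iloc[i]
        seq = child.sequences[row.chrom][row.start : row.end]
        m = match_lengths(seq, indexes)
        ranked = sorted(m.items(), key=lambda kv: kv[1], reverse=True)
        best_name, best_val = ranked[0]
        second_val = ranked[1][1] if len(ranked) > 1 else -1
        block_len = row.end - row.start
        if best_val < min_match_fraction * block_len or best_val == second_val:
            out.iloc[i, out.columns.get_loc("origin")] = f"{parent}:unresolved"
        else:
            out.iloc[i, out.columns.get_loc("origin")] = f"{parent}:{best_name}"
    return out


def block_truth_labels(blocks: pd.DataFrame, truth_track: pd.DataFrame) -> np.ndarray:
    """Majority-origin truth label per block, from a simulated truth track.

    Each block takes the origin contributing the most bp to it; used to
    score recovered IBD tracks against generator ground truth.
    """
    labels = np.empty(len(blocks), dtype=object)
    for i, b in enumerate(blocks.itertuples()):
        sub = truth_track[
            (truth_track["chrom"] == b.chrom)
            & (truth_track["end"] > b.start)
            & (truth_track["start"] < b.end)
        ]
        overlap = np.minimum(sub["end"], b.end) - np.maximum(sub["start"], b.start)
        labels[i] = sub["origin"].iloc[int(np.argmax(overlap.to_numpy()))]
    return labels


def summarize_contributions(track: pd.DataFrame) -> pd.DataFrame:
    """Percent of total genome length per origin label; sums to 100.

    Raises on overlapping blocks (the track must tile the genome).
    """
    for chrom, sub in track.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping blocks on {chrom}")
    lengths = (track["end"] - track["start"]).to_numpy()
    total = lengths.sum()
    summary = (
        pd.DataFrame({"origin": track["origin"], "bp": lengths})
        .groupby("origin", sort=True)["bp"]
        .sum()
        .reset_index()
    )
    summary["percent"] = 100.0 * summary["bp"] / total
    return summary
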