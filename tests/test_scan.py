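"""Selection scan statistics against independent oracles: all-pairs pi,
a separately coded Weir-Cockerham estimator, the normal tail for the
Z threshold, brute-force interval union, and all-pairs overlap counts."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from polyped.scan import (
    ZeroVarianceError,
    call_divergent_regions,
    intersect_features,
    ld_decay,
    per_site_fst,
    windowed_fst,
    windowed_pi,
    zscore,
)

from conftest import make_matrix


def pairwise_pi_oracle(haplotypes: np.ndarray, span: int) -> float:
    """Mean pairwise differences per bp over all haplotype pairs."""
    n = haplotypes.shape[1]
    diffs = [
        (haplotypes[:, i] != haplotypes[:, j]).sum()
        for i, j in itertools.combinations(range(n), 2)
    ]
    return float(np.mean(diffs)) / span


def hap_matrix(haps: np.ndarray, positions=None, chrom_length=None):
    """Diploid matrix wrapping an even number of haplotypes."""
    gt = haps[:, 0::2] + haps[:, 1::2]
    return make_matrix(
        gt,
        positions=positions,
        chrom_length=chrom_length,
        haplotypes=haps.astype(np.int8),
    )


class TestWindowedPi:
    def test_single_pair_single_difference(self):
        haps = np.array([[0, 1]])
        m = hap_matrix(haps, positions=np.array([50]), chrom_length=100)
        pi = windowed_pi(m, "g", window=100, step=100)
        assert pi.value.iloc[0] == pytest.approx(0.01)

    def test_monomorphic_window_is_zero(self):
        haps = np.zeros((5, 4), dtype=np.int8)
        m = hap_matrix(haps, chrom_length=100)
        pi = windowed_pi(m, "g", window=100, step=100)
        assert (pi.value == 0).all()

    def test_four_haplotypes_half_frequency(self):
        haps = np.array([[0, 0, 1, 1]])
        m = hap_matrix(haps, positions=np.array([10]), chrom_length=100)
        pi = windowed_pi(m, "g", window=100, step=100)
        want = pairwise_pi_oracle(haps, 100)
        assert pi.value.iloc[0] == pytest.approx(want, abs=1e-15)
        assert pi.value.iloc[0] == pytest.approx((4 / 6) / 100)

    def test_matches_all_pairs_oracle_on_random_matrix(self, rng):
        n_sites, n_hap, length = 1_000, 10, 50_000
        haps = (rng.random((n_sites, n_hap)) < rng.uniform(0.05, 0.95, (n_sites, 1))).astype(np.int8)
        pos = np.sort(rng.choice(length, size=n_sites, replace=False))
        m = hap_matrix(haps, positions=pos, chrom_length=length)
        pi = windowed_pi(m, "g", window=length, step=length)
        want = pairwise_pi_oracle(haps, length)
        assert abs(pi.value.iloc[0] - want) < 1e-12

    def test_unknown_group_rejected(self):
        m = hap_matrix(np.zeros((2, 4), dtype=np.int8), chrom_length=100)
        with pytest.raises(KeyError):
            windowed_pi(m, "nope")


def wc_fst_oracle(n1, p1, h1, n2, p2, h2):
    """Independently coded Weir & Cockerham (1984) theta for two demes."""
    r = 2
    nbar = (n1 + n2) / r
    csq = ((n1 - nbar) ** 2 + (n2 - nbar) ** 2) / ((r - 1) * nbar**2)
    nc = nbar * (1 - csq / r * (r - 1))  # == nbar*(1 - c^2/2) for r=2
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = nbar / nc * (
        s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
    )
    b = nbar / (nbar - 1) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a / (a + b + c)


class TestWindowedFst:
    @staticmethod
    def _two_group_matrix(gt_a, gt_b, positions=None, chrom_length=None):
        gt = np.hstack([gt_a, gt_b])
        groups = ["A"] * gt_a.shape[1] + ["B"] * gt_b.shape[1]
        return make_matrix(gt, positions=positions, chrom_length=chrom_length, groups=groups)

    def test_fixed_difference_gives_one(self):
        m = self._two_group_matrix(
            np.zeros((3, 5), np.int8), np.full((3, 5), 2, np.int8), chrom_length=100
        )
        fst = windowed_fst(m, "A", "B", window=100, step=100)
        assert fst.value.iloc[0] == pytest.approx(1.0)
        assert np.allclose(per_site_fst(m, "A", "B"), 1.0)

    def test_identical_frequencies_nonpositive(self):
        block = np.array([[0, 0, 1, 1, 2, 2]] * 4, dtype=np.int8)
        m = self._two_group_matrix(block, block.copy(), chrom_length=100)
        fst = windowed_fst(m, "A", "B", window=100, step=100)
        assert fst.value.iloc[0] <= 0

    def test_spec_counts_match_oracle(self):
        # group A: 6 hom-ref, 4 het; group B: 1 hom-ref, 4 het, 5 hom-alt
        gt_a = np.array([[0] * 6 + [1] * 4], dtype=np.int8)
        gt_b = np.array([[0] + [1] * 4 + [2] * 5], dtype=np.int8)
        m = self._two_group_matrix(gt_a, gt_b, positions=np.array([10]), chrom_length=100)
        got = per_site_fst(m, "A", "B")[0]
        want = wc_fst_oracle(10, 4 / 20, 4 / 10, 10, 14 / 20, 4 / 10)
        assert got == pytest.approx(want, abs=1e-12)

    def test_random_sites_match_oracle(self, rng):
        n_sites = 200
        gt_a = rng.integers(0, 3, size=(n_sites, 8)).astype(np.int8)
        gt_b = rng.integers(0, 3, size=(n_sites, 12)).astype(np.int8)
        m = self._two_group_matrix(
            gt_a, gt_b, positions=np.arange(n_sites) * 7, chrom_length=n_sites * 7 + 10
        )
        got = per_site_fst(m, "A", "B")
        for i in range(n_sites):
            n1, n2 = 8, 12
            p1 = gt_a[i].sum() / (2 * n1)
            p2 = gt_b[i].sum() / (2 * n2)
            h1 = (gt_a[i] == 1).mean()
            h2 = (gt_b[i] == 1).mean()
            want = wc_fst_oracle(n1, p1, h1, n2, p2, h2)
            if np.isfinite(want):
                assert abs(got[i] - want) < 1e-10, i

    def test_window_value_is_ratio_of_sums(self, rng):
        n_sites = 50
        gt_a = rng.integers(0, 3, size=(n_sites, 6)).astype(np.int8)
        gt_b = rng.integers(0, 3, size=(n_sites, 6)).astype(np.int8)
        m = self._two_group_matrix(
            gt_a, gt_b, positions=np.arange(n_sites) * 2, chrom_length=200
        )
        fst = windowed_fst(m, "A", "B", window=200, step=200)
        assert fst.value.iloc[0] <= 1.0

    def test_fst_never_exceeds_one(self, rng):
        for _ in range(20):
            gt_a = rng.integers(0, 3, size=(30, 5)).astype(np.int8)
            gt_b = rng.integers(0, 3, size=(30, 5)).astype(np.int8)
            m = self._two_group_matrix(
                gt_a, gt_b, positions=np.arange(30) * 3, chrom_length=100
            )
            fst = windowed_fst(m, "A", "B", window=100, step=100)
            v = fst.value.iloc[0]
            assert not np.isfinite(v) or v <= 1.0 + 1e-12


class TestZscore:
    def test_simple_example(self):
        assert zscore(np.array([0.0, 1.0, 2.0])) == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_vector_raises(self):
        with pytest.raises(ZeroVarianceError):
            zscore(np.full(10, 3.14))

    def test_missing_stays_missing(self):
        z = zscore(np.array([0.0, np.nan, 2.0]))
        assert np.isnan(z[1]) and np.isfinite(z[0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=200, unique=True))
    def test_normalization_property(self, values):
        z = zscore(np.array(values))
        assert np.nanmean(z) == pytest.approx(0.0, abs=1e-9)
        assert np.nanstd(z, ddof=1) == pytest.approx(1.0, rel=1e-9)

    def test_normal_tail_fraction(self, rng):
        z = zscore(rng.standard_normal(100_000))
        frac = (z > 3).mean()
        p = 1.349898e-3  # P(Z > 3) for a standard normal
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / 100_000)


def interval_union_oracle(intervals):
    covered = set()
    for s, e in intervals:
        covered.update(range(s, e))
    out, cur = [], None
    for x in sorted(covered):
        if cur is None or x > cur[1]:
            if cur:
                out.append(tuple(cur))
            cur = [x, x + 1]
        else:
            cur[1] = x + 1
    if cur:
        out.append(tuple(cur))
    return out


class TestDivergentRegions:
    @staticmethod
    def _windows(z, window=100, step=10, chrom="c"):
        starts = np.arange(len(z)) * step
        return pd.DataFrame(
            {"chrom": chrom, "start": starts, "end": starts + window, "z": z}
        )

    def test_adjacent_flagged_windows_merge(self):
        res = call_divergent_regions(self._windows([1, 4, 4, 1]))
        assert len(res.regions) == 1
        assert (res.regions.start.iloc[0], res.regions.end.iloc[0]) == (10, 120)
        assert res.regions.n_windows.iloc[0] == 2

    def test_no_flags_empty(self):
        res = call_divergent_regions(self._windows([1.0, 2.0, 2.9]))
        assert res.regions.empty and res.total_bp == 0

    def test_random_flags_match_union_oracle(self, rng):
        z = rng.choice([0.0, 5.0], size=200, p=[0.7, 0.3])
        windows = self._windows(z, window=30, step=10)
        res = call_divergent_regions(windows)
        flagged = [
            (int(w.start), int(w.end)) for _, w in windows.iterrows() if w.z > 3
        ]
        want = interval_union_oracle(flagged)
        got = list(zip(res.regions.start, res.regions.end))
        assert got == want


class TestIntersectFeatures:
    @staticmethod
    def _df(rows, cols=("chrom", "start", "end", "id")):
        return pd.DataFrame(rows, columns=list(cols))

    def test_overlap_counted(self):
        regions = self._df([("c", 150, 300, "r0")])
        genes = self._df([("c", 100, 200, "g0")])
        out, n = intersect_features(regions, genes)
        assert out.feature_ids.iloc[0] == ["g0"] and n == 1

    def test_half_open_touching_not_counted(self):
        regions = self._df([("c", 200, 300, "r0")])
        genes = self._df([("c", 100, 200, "g0")])
        out, n = intersect_features(regions, genes)
        assert out.feature_ids.iloc[0] == [] and n == 0

    def test_random_intervals_match_all_pairs_oracle(self, rng):
        regions = self._df(
            [
                ("c", s, s + w, f"r{i}")
                for i, (s, w) in enumerate(
                    zip(rng.integers(0, 5_000, 100), rng.integers(1, 300, 100))
                )
            ]
        )
        feats = self._df(
            [
                ("c", s, s + w, f"g{i}")
                for i, (s, w) in enumerate(
                    zip(rng.integers(0, 5_000, 1000), rng.integers(1, 100, 1000))
                )
            ]
        )
        out, n = intersect_features(regions, feats)
        hits = set()
        for _, r in regions.iterrows():
            want = sorted(
                f.id
                for _, f in feats.iterrows()
                if min(r.end, f.end) - max(r.start, f.start) >= 1
            )
            assert out[out.id == r.id].feature_ids.iloc[0] == want
            hits.update(want)
        assert n == len(hits)


class TestScanRecovery:
    def test_forced_fixed_difference_tract_recovered(self, rng):
        """A tract of fixed inter-group differences is flagged almost
        entirely, with <1% of the complement called."""
        n_sites, length = 2_000, 1_000_000
        pos = np.sort(rng.choice(length, size=n_sites, replace=False))
        base = rng.uniform(0.1, 0.9, size=(n_sites, 1))
        gt_a = rng.binomial(2, np.broadcast_to(base, (n_sites, 10))).astype(np.int8)
        gt_b = rng.binomial(2, np.broadcast_to(base, (n_sites, 10))).astype(np.int8)
        tract = (400_000, 480_000)
        in_tract = (pos >= tract[0]) & (pos < tract[1])
        gt_a[in_tract] = 2
        gt_b[in_tract] = 0
        m = make_matrix(
            np.hstack([gt_a, gt_b]),
            positions=pos,
            chrom_length=length,
            groups=["A"] * 10 + ["B"] * 10,
        )
        fst = windowed_fst(m, "A", "B", window=20_000, step=5_000)
        fst["z"] = zscore(fst.value.to_numpy())
        res = call_divergent_regions(fst, threshold=3.0)
        cov = fp = 0
        for _, r in res.regions.iterrows():
            o = max(0, min(r.end, tract[1]) - max(r.start, tract[0]))
            cov += o
            fp += (r.end - r.start) - o
        assert cov / (tract[1] - tract[0]) >= 0.9
        assert fp / (length - (tract[1] - tract[0])) < 0.01


class TestLdDecay:
    def test_duplicated_site_perfect_correlation(self):
        gt = np.array([[0, 1, 2, 1, 0], [0, 1, 2, 1, 0]], dtype=np.int8)
        m = make_matrix(gt, positions=np.array([100, 600]), chrom_length=1_000)
        out = ld_decay(m, "g", max_dist=1_000, n_bins=10)
        hit = out[out.n_pairs > 0]
        assert len(hit) == 1
        assert hit.mean_r2.iloc[0] == pytest.approx(1.0)
        assert hit.dist_mid.iloc[0] == pytest.approx(550.0)

    def test_independent_sites_low_r2(self, rng):
        n_sites, n_samp = 40, 500
        gt = rng.binomial(2, 0.5, size=(n_sites, n_samp)).astype(np.int8)
        m = make_matrix(gt, positions=np.arange(n_sites) * 11, chrom_length=500)
        out = ld_decay(m, "g", max_dist=500, n_bins=5)
        assert np.nanmean(out.mean_r2) < 0.05

    def test_empty_bin_reported_missing(self):
        gt = np.array([[0, 1, 2], [2, 1, 0]], dtype=np.int8)
        m = make_matrix(gt, positions=np.array([0, 50]), chrom_length=1_000)
        out = ld_decay(m, "g", max_dist=1_000, n_bins=10)
        assert np.isnan(out.mean_r2[out.n_pairs == 0]).all()
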