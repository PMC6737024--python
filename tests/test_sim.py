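"""Generator behaviour: determinism, oracles for the sampling models, and
exact ground-truth bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polyped.core import ConfigurationError
from polyped.sim import (
    IntrogressionEvent,
    PedigreeSpec,
    SimulationConfig,
    assign_site_classes,
    simulate,
    simulate_admixed_population,
    simulate_cross,
    simulate_founders,
    simulate_pedigree,
    write_dataset,
)

from conftest import SMALL_SCENARIO, random_assembly


def tiny_config(**overrides):
    base = dict(
        chromosomes=[("A01", "A", 100_000), ("C01", "C", 100_000)],
        group_sizes={"EU": 6, "AS_DH": 4},
        introgression_events=[],
        selection_targets=[],
        seed=5,
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestConfig:
    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ConfigurationError):
            tiny_config(chromosomes=[("A01", "A", 0)])

    def test_negative_rates_rejected(self):
        with pytest.raises(ConfigurationError):
            tiny_config(polymorphism_density=-1e-3)
        with pytest.raises(ConfigurationError):
            tiny_config(selection_skew=-0.5)

    def test_carrier_fraction_bounds(self):
        with pytest.raises(ConfigurationError):
            IntrogressionEvent("CDA", "AS_DH", "A01", 0, 10, 1.5)

    def test_event_outside_chromosome_rejected(self):
        with pytest.raises(ConfigurationError):
            tiny_config(
                introgression_events=[
                    IntrogressionEvent("CDA", "AS_DH", "A01", 0, 200_000, 0.5)
                ]
            )

    def test_pedigree_orders_parents_before_children(self):
        with pytest.raises(ConfigurationError):
            PedigreeSpec(nodes=["kid", "p"], edges=[("kid", "p", "p")])

    def test_config_dict_round_trip(self):
        cfg = tiny_config()
        assert SimulationConfig.from_dict(cfg.to_dict()) == cfg


class TestFounders:
    def test_zero_donor_divergence_gives_ancestral_donor(self):
        cfg = tiny_config(donor_divergence=0.0)
        f = simulate_founders(cfg)
        for chrom, seq in f.ancestral.sequences.items():
            assert np.array_equal(f.assemblies["CDA"].sequences[chrom], seq)

    def test_same_seed_identical_fasta_bytes(self, tmp_path):
        for sub in ("a", "b"):
            ds = simulate(tiny_config())
            write_dataset(ds, tmp_path / sub)
        for fa in (tmp_path / "a").glob("*.fa"):
            assert fa.read_bytes() == (tmp_path / "b" / fa.name).read_bytes()

    def test_segregating_site_count_matches_binomial_oracle(self):
        # density 1e-3 over 1 Mb: per lineage ~Binomial(1e6, 1e-3)
        density, length = 1e-3, 1_000_000
        cfg = SimulationConfig(
            seed=11,
            chromosomes=[("A01", "A", length)],
            group_sizes={"EU": 10, "AS_DH": 10},
            polymorphism_density=density,
            introgression_events=[],
            selection_targets=[],
        )
        f = simulate_founders(cfg)
        mean = density * length
        sd = np.sqrt(length * density * (1 - density))
        for g, mat in f.genotypes.items():
            alt, total = mat.allele_counts()
            seg = int(((alt > 0) & (alt < total)).sum())
            assert abs(seg - mean) < 3 * sd, (g, seg)

    def test_site_positions_strictly_increasing(self, small_dataset):
        small_dataset.genotypes.validate()


class TestCross:
    def test_zero_recombination_returns_whole_parent_chromosomes(self):
        p1 = random_assembly("p1", {"A01": 30_000}, 1)
        p2 = random_assembly("p2", {"A01": 30_000}, 2)
        child, truth = simulate_cross(p1, p2, 0.0, seed=3)
        assert len(truth) == 1
        origin = truth.origin.iloc[0]
        src = p1 if origin == "p1" else p2
        assert np.array_equal(child.sequences["A01"], src.sequences["A01"])

    def test_forced_crossover_truth_track(self):
        p1 = random_assembly("p1", {"chr1": 60_000}, 1)
        p2 = random_assembly("p2", {"chr1": 60_000}, 2)
        child, truth = simulate_cross(
            p1, p2, 0.0, seed=0, crossovers={"chr1": [30_000]}, start_parent=0
        )
        assert truth.values.tolist() == [
            ["chr1", 0, 30_000, "p1"],
            ["chr1", 30_000, 60_000, "p2"],
        ]
        assert np.array_equal(child.sequences["chr1"][:30_000], p1.sequences["chr1"][:30_000])
        assert np.array_equal(child.sequences["chr1"][30_000:], p2.sequences["chr1"][30_000:])

    def test_crossover_count_matches_poisson_oracle(self):
        p1 = random_assembly("p1", {"c": 10_000}, 1)
        p2 = random_assembly("p2", {"c": 10_000}, 2)
        rng = np.random.default_rng(7)
        n_rep, rate = 3000, 2.0
        counts = []
        for _ in range(n_rep):
            _, truth = simulate_cross(p1, p2, rate, seed=rng)
            counts.append(len(truth) - 1)
        # segments-1 undercounts only when duplicate positions collide (rare)
        se = np.sqrt(rate / n_rep)
        assert abs(np.mean(counts) - rate) < 3 * se

    def test_mismatched_chromosomes_rejected(self):
        p1 = random_assembly("p1", {"A01": 1000}, 1)
        p2 = random_assembly("p2", {"A02": 1000}, 2)
        with pytest.raises(ConfigurationError):
            simulate_cross(p1, p2, 1.0, seed=0)

    def test_truth_tracks_tile_chromosomes(self):
        cfg = tiny_config()
        _, truth = simulate_pedigree(cfg)
        for node, tr in truth.items():
            for chrom, L in cfg.chrom_lengths().items():
                sub = tr[tr.chrom == chrom].sort_values("start")
                assert sub.start.iloc[0] == 0 and sub.end.iloc[-1] == L
                assert (sub.end.to_numpy()[:-1] == sub.start.to_numpy()[1:]).all()


class TestAdmixture:
    @pytest.mark.parametrize("fraction,expect_any", [(0.0, False), (1.0, True)])
    def test_carrier_fraction_extremes(self, fraction, expect_any):
        cfg = tiny_config()
        f = simulate_founders(cfg)
        ev = IntrogressionEvent("CDA", "AS_DH", "A01", 10_000, 60_000, fraction)
        out, truth, carriers = simulate_admixed_population(
            f.genotypes["AS_DH"], f.donor_panel, [ev], seed=4
        )
        donor_rows = truth[truth.source == "CDA"]
        assert (len(donor_rows) > 0) == expect_any
        if fraction == 1.0:
            assert len(carriers[0]) == out.n_samples

    def test_carrier_count_within_binomial_band(self):
        cfg = tiny_config(group_sizes={"EU": 4, "AS_DH": 20})
        f = simulate_founders(cfg)
        ev = IntrogressionEvent("CDA", "AS_DH", "A01", 10_000, 60_000, 0.95)
        _, truth, carriers = simulate_admixed_population(
            f.genotypes["AS_DH"], f.donor_panel, [ev], seed=4
        )
        n_hap_carriers = truth[truth.source == "CDA"].haplotype.nunique()
        mean, sd = 40 * 0.95, np.sqrt(40 * 0.95 * 0.05)
        assert abs(n_hap_carriers - mean) < 3 * sd

    def test_event_outside_chromosome_rejected(self):
        cfg = tiny_config()
        f = simulate_founders(cfg)
        ev = IntrogressionEvent("CDA", "AS_DH", "A01", 0, 500_000, 0.5)
        with pytest.raises(ConfigurationError):
            simulate_admixed_population(f.genotypes["AS_DH"], f.donor_panel, [ev], 0)

    def test_ancestry_truth_tiles_every_haplotype(self, small_dataset):
        anc = small_dataset.truth.ancestry
        lengths = small_dataset.genotypes.chrom_lengths
        for (_, hap, chrom), sub in anc.groupby(["sample", "haplotype", "chrom"]):
            sub = sub.sort_values("start")
            assert sub.start.iloc[0] == 0
            assert sub.end.iloc[-1] == lengths[chrom]
            assert (sub.end.to_numpy()[:-1] == sub.start.to_numpy()[1:]).all()


class TestSiteClasses:
    @staticmethod
    def _sites(n, rng, length=1_000_000):
        pos = np.sort(rng.choice(length, size=n, replace=False))
        return pd.DataFrame({"chrom": "A01", "pos": pos})

    def test_intergenic_site_labeled_neutral(self, rng):
        sites = pd.DataFrame({"chrom": "A01", "pos": [5_000]})
        genes = pd.DataFrame({"chrom": ["A01"], "start": [10_000], "end": [12_000]})
        cls, _ = assign_site_classes(sites, genes, 0.5, 1.0, rng)
        assert cls.site_class.iloc[0] == "neutral-intergenic"

    def test_negative_skew_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            assign_site_classes(
                self._sites(10, rng), pd.DataFrame(columns=["chrom", "start", "end"]),
                0.1, -1.0, rng,
            )

    def test_deleterious_scores_below_threshold(self, rng):
        sites = self._sites(2000, rng)
        genes = pd.DataFrame({"chrom": "A01", "start": [0], "end": [1_000_000]})
        cls, _ = assign_site_classes(sites, genes, 0.3, 0.5, rng)
        d = cls[cls.site_class == "deleterious"]
        o = cls[cls.site_class == "other"]
        assert (d.score < 0.05).all() and (o.score >= 0.05).all()

    def test_skew_one_leaves_distributions_indistinguishable(self, rng):
        sites = self._sites(2000, rng)
        genes = pd.DataFrame({"chrom": "A01", "start": [0], "end": [500_000]})
        base = rng.uniform(0.02, 0.98, size=2000)
        cls, adj = assign_site_classes(sites, genes, 0.5, 1.0, rng, base_freq=base)
        d = adj[(cls.site_class == "deleterious").to_numpy()]
        n = adj[(cls.site_class == "neutral-intergenic").to_numpy()]
        assert stats.ks_2samp(d, n).pvalue > 0.01

    def test_skew_half_halves_mean_deleterious_frequency(self, rng):
        sites = self._sites(5000, rng)
        genes = pd.DataFrame({"chrom": "A01", "start": [0], "end": [700_000]})
        base = rng.uniform(0.02, 0.98, size=5000)
        cls, adj = assign_site_classes(sites, genes, 0.4, 0.5, rng, base_freq=base)
        d = adj[(cls.site_class == "deleterious").to_numpy()]
        n = adj[(cls.site_class == "neutral-intergenic").to_numpy()]
        assert 0.4 < d.mean() / n.mean() < 0.6

    def test_realized_group_frequencies_follow_skew(self, small_dataset):
        # realized polymorphic frequencies in each group reflect skew 0.5
        from polyped.load import group_frequencies, _aligned_classes

        cls = small_dataset.truth.site_classes.copy()
        mat = small_dataset.genotypes
        aligned = _aligned_classes(
            mat, cls.rename(columns={"site_class": "site_class"})
        )
        freq, total = group_frequencies(mat, "EU")
        poly = (freq > 0) & (freq < 1)
        ratio = freq[poly & (aligned == "deleterious")].mean() / freq[
            poly & (aligned == "neutral-intergenic")
        ].mean()
        assert 0.35 < ratio < 0.65


class TestWriteDataset:
    def test_vcf_round_trip(self, small_dataset, tmp_path):
        from polyped import io as pio

        paths = write_dataset(small_dataset, tmp_path)
        m = pio.read_vcf(paths["vcf"], groups=pio.read_groups(paths["groups"]))
        assert np.array_equal(m.gt, small_dataset.genotypes.gt)
        assert np.array_equal(m.haplotypes, small_dataset.genotypes.haplotypes)
        assert m.samples == small_dataset.genotypes.samples

    def test_truth_tract_bed_tiles_chromosomes(self, small_dataset, tmp_path):
        from polyped import io as pio

        paths = write_dataset(small_dataset, tmp_path)
        bed = pio.read_bed(paths["truth_ibd:NY7"])
        for chrom, L in small_dataset.genotypes.chrom_lengths.items():
            sub = bed[bed.chrom == chrom].sort_values("start")
            assert sub.start.iloc[0] == 0 and sub.end.iloc[-1] == L

    def test_empty_matrix_writes_valid_vcf(self, tmp_path):
        from polyped import io as pio
        from conftest import make_matrix

        m = make_matrix(np.empty((0, 2), dtype=np.int8), positions=np.empty(0, int),
                        chrom_length=100)
        pio.write_vcf(m, tmp_path / "empty.vcf")
        back = pio.read_vcf(tmp_path / "empty.vcf")
        assert back.n_sites == 0 and back.samples == m.samples
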