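import numpy as np
import pandas as pd
import pytest

from polyped.core import AssemblySet, GenotypeMatrix, random_sequence
from polyped.sim import (
    IntrogressionEvent,
    SelectionTarget,
    SimulationConfig,
    simulate,
)

SMALL_SCENARIO = dict(
    chromosomes=[
        ("A01", "A", 200_000),
        ("A02", "A", 200_000),
        ("C01", "C", 200_000),
        ("C02", "C", 200_000),
    ],
    group_sizes={"EU": 10, "AS_DH": 8, "AS_DL": 6},
    introgression_events=[
        IntrogressionEvent("CDA", "AS_DH", "A02", 50_000, 150_000, 0.95)
    ],
    selection_targets=[SelectionTarget("C02", 60_000, 140_000, "AS_DH")],
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=9, **SMALL_SCENARIO)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """One shared 4 x 200 kb scenario with introgression and a sweep."""
    return simulate(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_matrix(
    gt: np.ndarray,
    positions: np.ndarray | None = None,
    chrom: str = "A01",
    chrom_length: int | None = None,
    groups: list[str] | None = None,
    haplotypes: np.ndarray | None = None,
    subgenome: str = "A",
) -> GenotypeMatrix:
    """Hand-built GenotypeMatrix for toy examples."""
    gt = np.asarray(gt, dtype=np.int8)
    n_sites, n_samples = gt.shape
    if positions is None:
        positions = np.arange(n_sites) * 10
    samples = [f"s{i}" for i in range(n_samples)]
    groups = groups or ["g"] * n_samples
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(positions),
            "ref": "A",
            "alt": "T",
            "subgenome": subgenome,
        }
    )
    return GenotypeMatrix(
        samples=samples,
        groups=pd.Series(groups, index=samples),
        sites=sites,
        gt=gt,
        haplotypes=haplotypes,
        chrom_lengths={chrom: chrom_length or int(positions[-1]) + 10},
        phased=haplotypes is not None,
    )


def make_assembly(name: str, seqs: dict[str, np.ndarray]) -> AssemblySet:
    return AssemblySet(name, {c: np.asarray(s, dtype=np.uint8) for c, s in seqs.items()})


def random_assembly(name: str, lengths: dict[str, int], seed: int) -> AssemblySet:
    r = np.random.default_rng(seed)
    return AssemblySet(name, {c: random_sequence(L, r) for c, L in lengths.items()})
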