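"""Synthetic allotetraploid pedigree and population generator.

Produces, with exact ground truth, the inputs every downstream stage needs:

* parental genome assemblies related by a known pedigree (mosaic-of-founders
  recombination, per-generation substitution mutations),
* multi-group population genotypes over a shared biallelic site list,
* interspecific introgression tracts from a diverged donor,
* site classes (deleterious / neutral-intergenic / other) with deleterious
  allele frequencies down-weighted by a configurable selection skew.

Haplotypes are simulated directly rather than through a coalescent engine:
the downstream procedures need realistic mosaic structure and *exact* truth
tracks, not a particular demography.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    AssemblySet,
    ConfigurationError,
    GenotypeMatrix,
    mutate_sequence,
    random_sequence,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

BACKGROUND_LABEL = "background"


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass
class PedigreeSpec:
    """Directed pedigree: ``edges`` are (child, parent1, parent2) crosses.

    A derived (selfed/selected) line is written with parent1 == parent2.
    """

    nodes: list[str]
    edges: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        children = {e[0] for e in self.edges}
        for node in self.nodes:
            seen.add(node)
        for child, p1, p2 in self.edges:
            if child in (p1, p2):
                raise ConfigurationError(f"pedigree cycle at {child!r}")
            for p in (p1, p2):
                if p not in seen:
                    raise ConfigurationError(
                        f"parent {p!r} of {child!r} not declared before the cross"
                    )
        order = {n: i for i, n in enumerate(self.nodes)}
        for child, p1, p2 in self.edges:
            if order[p1] >= order[child] or order[p2] >= order[child]:
                raise ConfigurationError("parents must precede children")
        self._children = children

    def founders(self) -> list[str]:
        return [n for n in self.nodes if n not in self._children]


def ny7_pedigree() -> PedigreeSpec:
    """The four-parent rapeseed pedigree: SL-1 x CDA -> CY2; SL-1 -> NY1;
    NY1 x CY2 -> NY7."""
    return PedigreeSpec(
        nodes=["SL-1", "CDA", "CY2", "NY1", "NY7"],
        edges=[
            ("CY2", "SL-1", "CDA"),
            ("NY1", "SL-1", "SL-1"),
            ("NY7", "NY1", "CY2"),
        ],
    )


@dataclass
class IntrogressionEvent:
    donor: str
    recipient_group: str
    chrom: str
    start: int
    end: int
    carrier_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.carrier_fraction <= 1.0:
            raise ConfigurationError(
                f"carrier fraction must be in [0,1], got {self.carrier_fraction}"
            )
        if self.start < 0 or self.end <= self.start:
            raise ConfigurationError(f"bad event interval [{self.start},{self.end})")


@dataclass
class SelectionTarget:
    """Region forced to a fixed inter-group difference (a selective sweep
    caricature) so scans have a known positive control."""

    chrom: str
    start: int
    end: int
    group: str


def default_chromosomes() -> list[tuple[str, str, int]]:
    """Ten 1-Mb chromosomes, five per subgenome (A and C)."""
    return [(f"A{i:02d}", "A", 1_000_000) for i in range(1, 6)] + [
        (f"C{i:02d}", "C", 1_000_000) for i in range(1, 6)
    ]


@dataclass
class SimulationConfig:
    """Scenario description; identical config + seed gives identical bytes.

    Defaults emulate the motivating breeding system: a four-parent pedigree feeding a
    derived cultivar, three population groups (EU n=59, AS_DH n=38,
    AS_DL n=30 — sample sizes of real resequencing panels for this system), an interspecific donor
    (the *B. rapa*-like parent CDA) introgressing a near-fixed tract into
    the Asian double-high group, and deleterious genic variants held at
    lower frequency than neutral intergenic ones.
    """

    seed: int = 0
    chromosomes: list[tuple[str, str, int]] = field(default_factory=default_chromosomes)
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"EU": 59, "AS_DH": 38, "AS_DL": 30}
    )
    #: segregating sites per bp per lineage (group)
    polymorphism_density: float = 2e-3
    #: per-bp substitution rate of each pedigree founder vs the ancestral background
    founder_divergence: float = 1e-3
    #: per-bp substitution rate of the interspecific donor vs the background
    donor_divergence: float = 5e-3
    #: expected crossovers per chromosome per meiosis
    recombination_rate: float = 2.0
    #: per-bp substitutions added at each pedigree generation
    mutation_rate: float = 1e-4
    #: fraction of genic segregating sites that are deleterious
    deleterious_fraction: float = 0.15
    #: mean frequency ratio deleterious:neutral (1 = no selection)
    selection_skew: float = 0.5
    gene_length: int = 4_000
    gene_spacing: int = 10_000
    qtl_per_chromosome: int = 2
    donor_name: str = "CDA"
    donor_panel_size: int = 12
    introgression_events: list[IntrogressionEvent] = field(
        default_factory=lambda: [
            IntrogressionEvent("CDA", "AS_DH", "A03", 200_000, 700_000, 0.95)
        ]
    )
    selection_targets: list[SelectionTarget] = field(
        default_factory=lambda: [SelectionTarget("C02", 300_000, 600_000, "AS_DH")]
    )
    pedigree: PedigreeSpec = field(default_factory=ny7_pedigree)

    def __post_init__(self) -> None:
        for name, _, length in self.chromosomes:
            if length <= 0:
                raise ConfigurationError(f"chromosome {name!r} has length {length}")
        for rate in (
            self.polymorphism_density,
            self.founder_divergence,
            self.donor_divergence,
            self.recombination_rate,
            self.mutation_rate,
        ):
            if rate < 0:
                raise ConfigurationError(f"rates must be >= 0, got {rate}")
        if self.selection_skew < 0:
            raise ConfigurationError("selection_skew must be >= 0")
        if not 0 <= self.deleterious_fraction <= 1:
            raise ConfigurationError("deleterious_fraction must be in [0,1]")
        lengths = self.chrom_lengths()
        for ev in self.introgression_events:
            if ev.chrom not in lengths or ev.end > lengths[ev.chrom]:
                raise ConfigurationError(
                    f"introgression event outside chromosome: {ev}"
                )

    def chrom_lengths(self) -> dict[str, int]:
        return {name: length for name, _, length in self.chromosomes}

    def subgenomes(self) -> dict[str, str]:
        return {name: sub for name, sub, _ in self.chromosomes}

    # -- (de)serialization for provenance -------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["chromosomes"] = [list(c) for c in self.chromosomes]
        d["pedigree"] = {
            "nodes": self.pedigree.nodes,
            "edges": [list(e) for e in self.pedigree.edges],
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["chromosomes"] = [tuple(c) for c in d.get("chromosomes", default_chromosomes())]
        if "pedigree" in d and isinstance(d["pedigree"], dict):
            ped = d["pedigree"]
            d["pedigree"] = PedigreeSpec(
                nodes=list(ped["nodes"]), edges=[tuple(e) for e in ped["edges"]]
            )
        if "introgression_events" in d:
            d["introgression_events"] = [
                ev if isinstance(ev, IntrogressionEvent) else IntrogressionEvent(**ev)
                for ev in d["introgression_events"]
            ]
        if "selection_targets" in d:
            d["selection_targets"] = [
                t if isinstance(t, SelectionTarget) else SelectionTarget(**t)
                for t in d["selection_targets"]
            ]
        return cls(**d)


@dataclass
class TruthSet:
    """Exact ground truth recorded during simulation."""

    #: pedigree node -> DataFrame(chrom, start, end, origin); tracts tile chromosomes
    ibd: dict[str, pd.DataFrame] = field(default_factory=dict)
    #: DataFrame(group, sample, haplotype, chrom, start, end, source); tiles chromosomes
    ancestry: pd.DataFrame = field(default_factory=pd.DataFrame)
    #: DataFrame(chrom, pos, site_class, score)
    site_classes: pd.DataFrame = field(default_factory=pd.DataFrame)
    #: DataFrame(chrom, start, end, group)
    selected_regions: pd.DataFrame = field(default_factory=pd.DataFrame)
    #: per introgression event: list of carrier sample names
    carriers: list[list[str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# founders: assemblies + group panels on a shared site list
# ---------------------------------------------------------------------------

@dataclass
class FounderSim:
    ancestral: AssemblySet
    assemblies: dict[str, AssemblySet]
    genotypes: dict[str, GenotypeMatrix]
    donor_panel: GenotypeMatrix
    genes: pd.DataFrame
    qtl: pd.DataFrame
    site_classes: pd.DataFrame
    base_freq: np.ndarray


def _gene_grid(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for chrom, _, length in config.chromosomes:
        i = 0
        start = 0
        while start < length:
            end = min(start + config.gene_length, length)
            rows.append((chrom, start, end, f"gene_{chrom}_{i:04d}"))
            start += config.gene_spacing
            i += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "id"])


def _qtl_intervals(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for chrom, _, length in config.chromosomes:
        for j in range(config.qtl_per_chromosome):
            width = int(rng.integers(50_000, 150_001))
            width = min(width, length)
            start = int(rng.integers(0, max(1, length - width + 1)))
            rows.append((chrom, start, start + width, f"qtl_{chrom}_{j}"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "id"])


def _in_intervals(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Membership of positions in sorted, non-overlapping half-open intervals."""
    if len(starts) == 0:
        return np.zeros(len(pos), dtype=bool)
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    out = np.zeros(len(pos), dtype=bool)
    out[ok] = pos[ok] < ends[idx[ok]]
    return out


def assign_site_classes(
    sites: pd.DataFrame,
    gene_intervals: pd.DataFrame,
    deleterious_fraction: float,
    selection_skew: float,
    seed: int | np.random.Generator,
    base_freq: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Label sites and down-weight deleterious allele frequencies.

    Sites outside every gene are ``neutral-intergenic``. A
    ``deleterious_fraction`` of genic sites are ``deleterious`` and receive a
    synthetic functional score < 0.05 (the conventional damaging cutoff);
    the remaining genic sites are ``other`` with scores >= 0.05. The target
    allele frequency of deleterious sites is ``base_freq * selection_skew``.
    Sites flagged ``donor_only`` (monomorphic in the background) are never
    classed deleterious.

    Returns (classification DataFrame with ``site_class``/``score`` columns,
    adjusted target frequencies).
    """
    if selection_skew < 0:
        raise ConfigurationError("selection_skew must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos = sites["pos"].to_numpy()
    genic = np.zeros(len(sites), dtype=bool)
    for chrom, idx in sites.groupby("chrom", sort=False).indices.items():
        g = gene_intervals[gene_intervals["chrom"] == chrom].sort_values("start")
        genic[idx] = _in_intervals(
            pos[idx], g["start"].to_numpy(), g["end"].to_numpy()
        )
    donor_only = (
        sites["donor_only"].to_numpy()
        if "donor_only" in sites
        else np.zeros(len(sites), dtype=bool)
    )
    deleterious = genic & ~donor_only & (rng.random(len(sites)) < deleterious_fraction)
    site_class = np.where(
        deleterious, "deleterious", np.where(genic, "other", "neutral-intergenic")
    )
    score = np.full(len(sites), np.nan)
    score[genic] = 0.05 + 0.95 * rng.random(int(genic.sum()))
    score[deleterious] = 0.05 * rng.random(int(deleterious.sum()))
    out = sites[["chrom", "pos"]].copy()
    out["site_class"] = site_class
    out["score"] = score
    if base_freq is None:
        adjusted = np.array([])
    else:
        adjusted = np.asarray(base_freq, dtype=float).copy()
        adjusted[deleterious] = adjusted[deleterious] * selection_skew
    return out, adjusted


def _conditioned_binomial(
    n: int, freq: np.ndarray, rng: np.random.Generator, max_iter: int = 200
) -> np.ndarray:
    """Binomial(n, freq) conditioned to be polymorphic (1..n-1)."""
    k = rng.binomial(n, freq)
    bad = (k == 0) | (k == n)
    it = 0
    while bad.any() and it < max_iter:
        k[bad] = rng.binomial(n, freq[bad])
        bad = (k == 0) | (k == n)
        it += 1
    k[k == 0] = 1
    k[k == n] = n - 1
    return k


def _place_alleles(
    n_hap: int, counts: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """0/1 matrix with exactly ``counts[i]`` ones in row i, uniformly placed."""
    u = rng.random((len(counts), n_hap))
    ranks = np.argsort(np.argsort(u, axis=1, kind="stable"), axis=1, kind="stable")
    return (ranks < counts[:, None]).astype(np.int8)


def simulate_founders(config: SimulationConfig) -> FounderSim:
    """Founder assemblies and group genotype panels with shared sites.

    Each pedigree founder genome is the shared ancestral sequence plus
    private substitutions (``founder_divergence``; the donor uses
    ``donor_divergence``). Population sites are drawn per lineage as
    Bernoulli(``polymorphism_density``) per bp; allele counts are sampled
    from a Binomial at the site's target frequency conditioned to stay
    polymorphic, so the per-lineage segregating-site count is exactly the
    Bernoulli draw. The donor panel is fixed for the diverged allele at its
    private sites and carries no background deleterious alleles.
    """
    rng = np.random.default_rng(config.seed)
    lengths = config.chrom_lengths()
    subg = config.subgenomes()

    ancestral = AssemblySet(
        "ancestral", {c: random_sequence(L, rng) for c, L in lengths.items()}
    )
    assemblies: dict[str, AssemblySet] = {}
    for node in config.pedigree.founders():
        rate = (
            config.donor_divergence
            if node == config.donor_name
            else config.founder_divergence
        )
        seqs = {}
        for chrom, L in lengths.items():
            seqs[chrom], _ = mutate_sequence(ancestral.sequences[chrom], rate, rng)
        assemblies[node] = AssemblySet(node, seqs)

    genes = _gene_grid(config)
    qtl = _qtl_intervals(config, rng)

    groups = list(config.group_sizes)
    site_frames = []
    seg_flags = {g: [] for g in groups}
    donor_flags = []
    for chrom, L in lengths.items():
        per_group_pos = {
            g: np.flatnonzero(rng.random(L) < config.polymorphism_density)
            for g in groups
        }
        donor_pos = np.flatnonzero(rng.random(L) < config.donor_divergence)
        union = np.unique(np.concatenate([*per_group_pos.values(), donor_pos]))
        for g in groups:
            seg_flags[g].append(np.isin(union, per_group_pos[g], assume_unique=True))
        donor_flags.append(
            np.isin(union, donor_pos, assume_unique=True)
            & ~np.any([np.isin(union, p, assume_unique=True) for p in per_group_pos.values()], axis=0)
        )
        ref = ancestral.sequences[chrom][union]
        codes = np.searchsorted(_BASES, ref)
        alt = _BASES[(codes + rng.integers(1, 4, size=len(union))) % 4]
        site_frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": union,
                    "ref": ref.view("S1").astype(str),
                    "alt": alt.view("S1").astype(str),
                    "subgenome": subg[chrom],
                }
            )
        )
    sites = pd.concat(site_frames, ignore_index=True)
    seg = {g: np.concatenate(seg_flags[g]) for g in groups}
    donor_only = np.concatenate(donor_flags)
    sites["donor_only"] = donor_only
    n_sites = len(sites)

    base_freq = 0.02 + 0.96 * rng.random(n_sites)
    site_classes, target_freq = assign_site_classes(
        sites,
        genes,
        config.deleterious_fraction,
        config.selection_skew,
        rng,
        base_freq=base_freq,
    )
    deleterious = (site_classes["site_class"] == "deleterious").to_numpy()

    # group haplotype panels over the joint site list
    haplotypes: dict[str, np.ndarray] = {}
    for g, n_samp in config.group_sizes.items():
        n_hap = 2 * n_samp
        hap = np.zeros((n_sites, n_hap), dtype=np.int8)
        fixed = ~seg[g] & ~donor_only & (target_freq > 0.5)
        hap[fixed] = 1
        idx = np.flatnonzero(seg[g])
        if idx.size:
            counts = _conditioned_binomial(n_hap, target_freq[idx], rng)
            hap[idx] = _place_alleles(n_hap, counts, rng)
        haplotypes[g] = hap

    # sweep caricature: variants segregating in the target group across the
    # region are swept to fixation (deleterious sites spared); other groups
    # and monomorphic sites are untouched — a sweep fixes standing
    # variation, it cannot invent alleles the group never carried
    pos_arr = sites["pos"].to_numpy()
    chrom_arr = sites["chrom"].to_numpy()
    for tgt in config.selection_targets:
        mask = (
            (chrom_arr == tgt.chrom)
            & (pos_arr >= tgt.start)
            & (pos_arr < tgt.end)
            & ~deleterious
            & seg[tgt.group]
        )
        haplotypes[tgt.group][mask] = 1

    # donor panel: diverged allele fixed at private sites, no background dSNPs
    n_dh = 2 * config.donor_panel_size
    donor_hap = np.zeros((n_sites, n_dh), dtype=np.int8)
    donor_major = (base_freq > 0.5) & ~deleterious & ~donor_only
    donor_hap[donor_major | donor_only] = 1

    def _matrix(g: str, hap: np.ndarray, names: list[str]) -> GenotypeMatrix:
        gt = (hap[:, 0::2] + hap[:, 1::2]).astype(np.int8)
        return GenotypeMatrix(
            samples=names,
            groups=pd.Series(g, index=names),
            sites=sites.drop(columns=["donor_only"]).copy(),
            gt=gt,
            haplotypes=hap,
            chrom_lengths=dict(lengths),
            phased=True,
        )

    genotypes = {
        g: _matrix(
            g,
            haplotypes[g],
            [f"{g}_{i:03d}" for i in range(config.group_sizes[g])],
        )
        for g in groups
    }
    donor_panel = _matrix(
        "DONOR",
        donor_hap,
        [f"{config.donor_name}_{i:02d}" for i in range(config.donor_panel_size)],
    )
    return FounderSim(
        ancestral=ancestral,
        assemblies=assemblies,
        genotypes=genotypes,
        donor_panel=donor_panel,
        genes=genes,
        qtl=qtl,
        site_classes=site_classes,
        base_freq=base_freq,
    )


# ---------------------------------------------------------------------------
# pedigree crosses at sequence level
# ---------------------------------------------------------------------------

def simulate_cross(
    parent1: AssemblySet,
    parent2: AssemblySet,
    recombination_rate: float,
    seed: int | np.random.Generator,
    mutation_rate: float = 0.0,
    name: str | None = None,
    crossovers: dict[str, list[int]] | None = None,
    start_parent: int | None = None,
) -> tuple[AssemblySet, pd.DataFrame]:
    """One meiotic product of parent1 x parent2 with recorded truth.

    Crossover counts are Poisson(``recombination_rate``) per chromosome with
    uniform positions (no interference); ``crossovers`` forces explicit
    breakpoints instead. Per-generation substitutions are added at
    ``mutation_rate`` per bp. Returns the child assembly and a truth track
    DataFrame(chrom, start, end, origin) tiling every chromosome.
    """
    if parent1.chrom_lengths() != parent2.chrom_lengths():
        raise ConfigurationError("parents have mismatched chromosome sets/lengths")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    parents = (parent1, parent2)
    child_seqs: dict[str, np.ndarray] = {}
    rows = []
    for chrom, L in parent1.chrom_lengths().items():
        if crossovers is not None:
            xs = sorted(set(crossovers.get(chrom, [])))
        else:
            n_x = rng.poisson(recombination_rate)
            xs = sorted(set(rng.integers(1, L, size=n_x).tolist())) if n_x else []
        first = int(rng.integers(0, 2)) if start_parent is None else start_parent
        bounds = [0, *xs, L]
        pieces = []
        for i in range(len(bounds) - 1):
            origin = parents[(first + i) % 2]
            s, e = bounds[i], bounds[i + 1]
            pieces.append(origin.sequences[chrom][s:e])
            if rows and rows[-1][0] == chrom and rows[-1][3] == origin.name and rows[-1][2] == s:
                rows[-1] = (chrom, rows[-1][1], e, origin.name)
            else:
                rows.append((chrom, s, e, origin.name))
        seq = np.concatenate(pieces)
        if mutation_rate:
            seq, _ = mutate_sequence(seq, mutation_rate, rng)
        child_seqs[chrom] = seq
    child = AssemblySet(name or f"{parent1.name}x{parent2.name}", child_seqs)
    truth = pd.DataFrame(rows, columns=["chrom", "start", "end", "origin"])
    return child, truth


def simulate_pedigree(
    config: SimulationConfig,
    founders: dict[str, AssemblySet] | None = None,
) -> tuple[dict[str, AssemblySet], dict[str, pd.DataFrame]]:
    """All pedigree node assemblies plus per-node truth IBD tracks.

    Founder truth tracks are trivially the founder itself; crossed nodes get
    the mosaic recorded by :func:`simulate_cross`. Deterministic in
    ``config.seed`` (a fixed offset stream is used so the founder draw and
    the crosses do not interleave).
    """
    if founders is None:
        founders = {}
        rng = np.random.default_rng(config.seed)
        lengths = config.chrom_lengths()
        ancestral = {c: random_sequence(L, rng) for c, L in lengths.items()}
        for node in config.pedigree.founders():
            rate = (
                config.donor_divergence
                if node == config.donor_name
                else config.founder_divergence
            )
            seqs = {c: mutate_sequence(ancestral[c], rate, rng)[0] for c in lengths}
            founders[node] = AssemblySet(node, seqs)
    assemblies = dict(founders)
    truth: dict[str, pd.DataFrame] = {}
    for node in config.pedigree.founders():
        truth[node] = pd.DataFrame(
            [
                (c, 0, L, node)
                for c, L in assemblies[node].chrom_lengths().items()
            ],
            columns=["chrom", "start", "end", "origin"],
        )
    cross_rng = np.random.default_rng((config.seed, 0xC5055))
    for child, p1, p2 in config.pedigree.edges:
        assemblies[child], truth[child] = simulate_cross(
            assemblies[p1],
            assemblies[p2],
            config.recombination_rate,
            cross_rng,
            mutation_rate=config.mutation_rate,
            name=child,
        )
    return assemblies, truth


# ---------------------------------------------------------------------------
# introgression
# ---------------------------------------------------------------------------

def simulate_admixed_population(
    background: GenotypeMatrix,
    donor_panel: GenotypeMatrix,
    events: list[IntrogressionEvent],
    seed: int | np.random.Generator,
) -> tuple[GenotypeMatrix, pd.DataFrame, list[list[str]]]:
    """Overwrite recipient haplotypes with donor alleles inside event tracts.

    For each event, exactly ``round(carrier_fraction * n_samples)`` samples
    are chosen uniformly as carriers; both haplotypes of a carrier take the
    alleles of a randomly chosen donor-panel haplotype across the tract, so
    the realized carrier fraction is as close to the configured one as the
    sample size allows. Returns the modified matrix, a truth tract table
    (sample, haplotype, chrom, start, end, source) tiling each chromosome
    for every haplotype, and per-event carrier lists.
    """
    if not background.sites["pos"].equals(donor_panel.sites["pos"]):
        raise ConfigurationError("background and donor panels have different sites")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hap = background.haplotypes.copy()
    lengths = background.chrom_lengths
    pos = background.sites["pos"].to_numpy()
    chrom_arr = background.sites["chrom"].to_numpy()
    n = background.n_samples
    donor_tracts: dict[int, list[tuple[str, int, int, str]]] = {
        h: [] for h in range(2 * n)
    }
    carriers_per_event: list[list[str]] = []
    for ev in events:
        if ev.chrom not in lengths or ev.end > lengths[ev.chrom]:
            raise ConfigurationError(f"event outside chromosome bounds: {ev}")
        site_mask = (chrom_arr == ev.chrom) & (pos >= ev.start) & (pos < ev.end)
        n_carriers = int(round(ev.carrier_fraction * n))
        chosen = rng.choice(n, size=n_carriers, replace=False) if n_carriers else []
        carriers_per_event.append(sorted(background.samples[i] for i in chosen))
        for s in chosen:
            for h in (2 * s, 2 * s + 1):
                src = int(rng.integers(0, donor_panel.haplotypes.shape[1]))
                hap[site_mask, h] = donor_panel.haplotypes[site_mask, src]
                donor_tracts[h].append((ev.chrom, ev.start, ev.end, ev.donor))
    gt = (hap[:, 0::2] + hap[:, 1::2]).astype(np.int8)
    out = GenotypeMatrix(
        samples=list(background.samples),
        groups=background.groups,
        sites=background.sites.copy(),
        gt=gt,
        haplotypes=hap,
        chrom_lengths=dict(lengths),
        phased=True,
    )
    rows = []
    for h in range(2 * n):
        sample = background.samples[h // 2]
        tracts = {}
        for chrom, s, e, donor in donor_tracts[h]:
            tracts.setdefault(chrom, []).append((s, e, donor))
        for chrom, L in lengths.items():
            cur = 0
            for s, e, donor in sorted(tracts.get(chrom, [])):
                if s > cur:
                    rows.append((sample, h, chrom, cur, s, BACKGROUND_LABEL))
                rows.append((sample, h, chrom, s, e, donor))
                cur = e
            if cur < L:
                rows.append((sample, h, chrom, cur, L, BACKGROUND_LABEL))
    truth = pd.DataFrame(
        rows, columns=["sample", "haplotype", "chrom", "start", "end", "source"]
    )
    return out, truth, carriers_per_event


def simulate_hybrid_pair(
    background: GenotypeMatrix,
    donor_panel: GenotypeMatrix,
    seed: int | np.random.Generator,
) -> GenotypeMatrix:
    """Two synthetic individuals for load comparisons.

    ``hybrid`` pairs one background haplotype with one donor-panel
    haplotype (an F1 with the low-load interspecific donor); ``sibling``
    pairs two background haplotypes from the same pool. Both share the
    background's site list.
    """
    if not background.sites["pos"].equals(donor_panel.sites["pos"]):
        raise ConfigurationError("background and donor panels have different sites")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bg = background.haplotypes
    b1, b2, b3 = rng.choice(bg.shape[1], size=3, replace=False)
    d1 = int(rng.integers(0, donor_panel.haplotypes.shape[1]))
    hap = np.column_stack(
        [bg[:, b1], donor_panel.haplotypes[:, d1], bg[:, b2], bg[:, b3]]
    ).astype(np.int8)
    gt = (hap[:, 0::2] + hap[:, 1::2]).astype(np.int8)
    samples = ["hybrid", "sibling"]
    return GenotypeMatrix(
        samples=samples,
        groups=pd.Series("pedigree", index=samples),
        sites=background.sites.copy(),
        gt=gt,
        haplotypes=hap,
        chrom_lengths=dict(background.chrom_lengths),
        phased=True,
    )


# ---------------------------------------------------------------------------
# full scenario + dataset writing
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimulationConfig
    assemblies: dict[str, AssemblySet]
    genotypes: GenotypeMatrix
    donor_panel: GenotypeMatrix
    genes: pd.DataFrame
    qtl: pd.DataFrame
    truth: TruthSet


def merge_group_matrices(matrices: dict[str, GenotypeMatrix]) -> GenotypeMatrix:
    """Column-concatenate per-group matrices sharing one site list."""
    mats = list(matrices.values())
    first = mats[0]
    for m in mats[1:]:
        if not m.sites["pos"].equals(first.sites["pos"]):
            raise ConfigurationError("group matrices have different site lists")
    return GenotypeMatrix(
        samples=[s for m in mats for s in m.samples],
        groups=pd.concat([m.groups for m in mats]),
        sites=first.sites.copy(),
        gt=np.hstack([m.gt for m in mats]),
        haplotypes=np.hstack([m.haplotypes for m in mats])
        if all(m.haplotypes is not None for m in mats)
        else None,
        chrom_lengths=dict(first.chrom_lengths),
        phased=all(m.phased for m in mats),
    )


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Run the full scenario: founders, pedigree crosses, introgression.

    One master seed drives everything; identical configs give identical
    in-memory objects and (via :func:`write_dataset`) identical files.
    """
    founders = simulate_founders(config)
    assemblies, ibd_truth = simulate_pedigree(config, founders.assemblies)

    group_mats = dict(founders.genotypes)
    event_rng = np.random.default_rng((config.seed, 0xADA1))
    ancestry_rows = []
    carriers: list[list[str]] = []
    by_group: dict[str, list[IntrogressionEvent]] = {}
    for ev in config.introgression_events:
        by_group.setdefault(ev.recipient_group, []).append(ev)
    for g, mat in group_mats.items():
        events = by_group.get(g, [])
        if events:
            mat, tracts, ev_carriers = simulate_admixed_population(
                mat, founders.donor_panel, events, event_rng
            )
            group_mats[g] = mat
            carriers.extend(ev_carriers)
        else:
            rows = []
            for h in range(2 * mat.n_samples):
                for chrom, L in mat.chrom_lengths.items():
                    rows.append(
                        (mat.samples[h // 2], h, chrom, 0, L, BACKGROUND_LABEL)
                    )
            tracts = pd.DataFrame(
                rows,
                columns=["sample", "haplotype", "chrom", "start", "end", "source"],
            )
        tracts.insert(0, "group", g)
        ancestry_rows.append(tracts)

    truth = TruthSet(
        ibd=ibd_truth,
        ancestry=pd.concat(ancestry_rows, ignore_index=True),
        site_classes=founders.site_classes,
        selected_regions=pd.DataFrame(
            [(t.chrom, t.start, t.end, t.group) for t in config.selection_targets],
            columns=["chrom", "start", "end", "group"],
        ),
        carriers=carriers,
    )
    return SimulatedDataset(
        config=config,
        assemblies=assemblies,
        genotypes=merge_group_matrices(group_mats),
        donor_panel=founders.donor_panel,
        genes=founders.genes,
        qtl=founders.qtl,
        truth=truth,
    )


def write_dataset(dataset: SimulatedDataset, directory: str | Path) -> dict[str, Path]:
    """Write the scenario to plain-text files; reading back reproduces it.

    Layout: one FASTA per genome, one multi-sample VCF, BED6 files for
    genes/QTL/truth tracts, a classification TSV and the config as YAML.
    """
    from . import io as pio  # local import to avoid a cycle

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, asm in dataset.assemblies.items():
        p = directory / f"{name}.fa"
        asm.to_fasta(p)
        paths[f"fasta:{name}"] = p
    paths["vcf"] = directory / "population.vcf"
    pio.write_vcf(dataset.genotypes, paths["vcf"])
    paths["donor_vcf"] = directory / "donor_panel.vcf"
    pio.write_vcf(dataset.donor_panel, paths["donor_vcf"])
    paths["groups"] = directory / "groups.tsv"
    dataset.genotypes.groups.rename("group").to_csv(
        paths["groups"], sep="\t", header=False
    )
    paths["genes"] = directory / "genes.bed"
    pio.write_bed(dataset.genes, paths["genes"])
    paths["qtl"] = directory / "qtl.bed"
    pio.write_bed(dataset.qtl, paths["qtl"])
    for node, track in dataset.truth.ibd.items():
        p = directory / f"truth_ibd_{node}.bed"
        pio.write_bed(track.rename(columns={"origin": "id"}), p)
        paths[f"truth_ibd:{node}"] = p
    paths["truth_ancestry"] = directory / "truth_ancestry.bed"
    anc = dataset.truth.ancestry.copy()
    anc["id"] = (
        anc["sample"].astype(str) + ":" + anc["haplotype"].astype(str) + ":" + anc["source"]
    )
    pio.write_bed(anc[["chrom", "start", "end", "id"]], paths["truth_ancestry"])
    paths["site_classes"] = directory / "site_classes.tsv"
    dataset.truth.site_classes.to_csv(paths["site_classes"], sep="\t", index=False)
    paths["selected_regions"] = directory / "truth_selected.bed"
    sel = dataset.truth.selected_regions.rename(columns={"group": "id"})
    pio.write_bed(sel, paths["selected_regions"])
    paths["config"] = directory / "config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(dataset.config.to_dict(), fh, sort_keys=True)
    return paths
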