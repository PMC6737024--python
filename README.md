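# polyped

Population-genomic toolkit for young allopolyploid crop pedigrees:
block-wise identity-by-descent (IBD) tracing of a derived cultivar genome to
its pedigree parents, windowed selection scans with Z-transformed F<sub>ST</sub>,
local-ancestry-based introgression fixation calling, and deleterious-variant
genetic-load spectra — together with a synthetic pedigree/population
generator that provides exact ground truth for all of them.

The motivating system is rapeseed (*Brassica napus*, subgenomes A and C),
where Asian cultivars were bred over a few decades from European material
via interspecific hybridization with *B. rapa*: a four-line pedigree
(SL-1 × CDA → CY2; SL-1-derived NY1; NY1 × CY2 → NY7) feeding three
population groups (European, Asian double-high, Asian double-low). All
methods are general to any two-subgenome crop with a known pedigree.

## What it computes

- **IBD tracing** (`polyped.ibd`). The derived genome is cut into 50-kb
  blocks; per block and candidate parent, the accumulated exact-match
  length is the number of block positions covered by an exact match of
  length ≥ k (k-mer anchored, default k = 21). The block is assigned to
  `argmax` parent; exact ties and best matches below 10% of the block are
  left unassigned. A parent's blocks can be re-scored against its own
  parents (`decompose_parent`), and `summarize_contributions` turns a track
  into per-parent genome percentages.
- **Selection scan** (`polyped.scan`). Sliding-window nucleotide diversity
  π = Σ<sub>sites</sub> 2p̂(1−p̂)·n/(n−1) / span and Weir–Cockerham (1984)
  F<sub>ST</sub> (window value = Σa / Σ(a+b+c), a "ratio of averages"; negative
  values retained), on a 100 kb / 10 kb grid. Z(F<sub>ST</sub>) = (x−μ)/σ
  genome-wide; windows with Z > 3 are merged into divergent regions and
  intersected with genes/QTL. LD decay as mean genotype-r² per distance bin.
- **Local ancestry** (`polyped.ancestry`). Each 50-SNP window of a phased
  query haplotype takes the label of the source panel whose closest
  haplotype has the smaller Hamming distance. Per window, the fraction of
  samples carrying donor ancestry (≥ 1 of 2 haplotypes) is computed, and
  windows with fraction strictly > 0.9 ("found in >90% of samples") merge
  into fixed-introgression regions.
- **Genetic load** (`polyped.load`). Deleterious SNPs (dSNPs) are sites
  with a damaging score < 0.05; intergenic SNPs (iSNPs) are the neutral
  reference. Group allele counts follow 2·hom + het over called samples;
  spectra use 20 frequency bins with (0.95, 1] reported as "fixed";
  relative load is the per-bin ratio of normalized dSNP to iSNP mass;
  per-individual load is the dSNP/iSNP site-count ratio, overall and per
  subgenome.
- **Simulator** (`polyped.sim`). Mosaic-of-founders haplotypes (no
  coalescent): founder genomes diverge from a shared ancestral sequence,
  crosses recombine with Poisson crossovers and per-generation mutations,
  groups draw sites at a per-lineage density, a diverged donor introgresses
  tracts into exactly round(carrier_fraction·n) samples, and deleterious
  site frequencies are down-weighted by a selection skew. Exact truth
  (IBD tracks, ancestry tracts, site classes, swept regions) is recorded.

## Worked example

```python
from polyped import SimulationConfig, simulate_pedigree
from polyped.ibd import block_truth_labels, decompose_parent, \
    summarize_contributions, trace_origin

config = SimulationConfig(
    seed=11,
    chromosomes=[("A01", "A", 500_000), ("A02", "A", 500_000),
                 ("C01", "C", 500_000), ("C02", "C", 500_000)],
    introgression_events=[], selection_targets=[],
)
assemblies, truth = simulate_pedigree(config)
_, track = trace_origin(assemblies["NY7"],
                        {n: assemblies[n] for n in ("NY1", "CY2")})
print(summarize_contributions(track))
track2 = decompose_parent(track, "CY2", assemblies["NY7"],
                          {"SL-1": assemblies["SL-1"], "CDA": assemblies["CDA"]})
print(summarize_contributions(track2))
```

prints

```
origin      bp  percent
   CY2 1000000     50.0
   NY1 1000000     50.0
  origin      bp  percent
 CY2:CDA  200000     10.0
CY2:SL-1  800000     40.0
     NY1 1000000     50.0
```

i.e. the cultivar inherited half its genome from each direct parent, and of
the CY2 half, 10 points of the genome trace back to the interspecific
parent CDA — the same decomposition an IBD pie-chart analysis performs on
real assemblies. The scripts in `examples/` walk through each capability
(simulation, IBD, scan, ancestry, load) the same way, and
`polyped run --out dir/` chains all stages into one reproducible report.

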