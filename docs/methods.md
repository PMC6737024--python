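# Methods

## Scope and model

`polyped` re-implements, as a tested library, the bespoke computational
procedures used to dissect a young allotetraploid crop pedigree: (i)
block-wise IBD attribution of a derived genome to its pedigree parents,
(ii) windowed π/F<sub>ST</sub> selection scans with a 3-SD Z threshold,
(iii) window-based local-ancestry painting with a >90% fixation rule, and
(iv) deleterious-variant load spectra and ratios. Because analyses of this kind require on the order of a hundred resequenced
accessions and several genome assemblies,
the package ships a generator that emulates that experimental design at desk scale
with exact ground truth; all quantitative claims below are properties the
test suite and `scripts/acceptance.py` actually compute on that generator.

## Synthetic data generator (`polyped.sim`)

Haplotypes are simulated directly as mosaics of founder material rather
than through a coalescent engine: the downstream procedures need realistic
block/tract structure and exact truth tracks, not a calibrated demography.

**Sequence level.** Each chromosome starts from a uniform-random ancestral
sequence. Every pedigree founder receives private substitutions at
`founder_divergence` (default 1e-3/bp; the interspecific donor CDA at
`donor_divergence`, default 5e-3/bp — an order of magnitude chosen so that
parents are clearly distinguishable at 50-kb scale while remaining
closely related). Crosses draw Poisson(`recombination_rate`, default 2)
crossovers per chromosome at uniform positions (no interference), pick the
starting parent at random, and add per-generation substitutions at
`mutation_rate` (default 1e-4/bp, the regime under which block-level IBD
recovery is evaluated). A derived line (NY1 from SL-1) is modeled as a
self-cross plus one generation of mutations. Truth tracks record every
segment's origin and tile each chromosome exactly.

**Site level.** Per chromosome and per group ("lineage"), segregating
sites are drawn as Bernoulli(`polymorphism_density`, default 2e-3/bp) per
position, so the per-lineage segregating-site count is Binomial(L, density)
by construction. The union across groups plus donor-private positions
(Bernoulli(`donor_divergence`)) forms the shared site list. Each union
site has a base frequency f₀ ~ U(0.02, 0.98); a group where the site
segregates draws its allele count from Binomial(2n, f) conditioned to stay
polymorphic, a group where it does not is fixed for the allele nearer f
(round(f)), and donor-private sites are fixed reference in all background
groups. Diploids are formed by pairing consecutive iid haplotypes. Default
group sizes (EU 59, AS_DH 38, AS_DL 30) match real resequencing panels
for this system.

**Site classes and selection skew.** Genes are laid on a regular grid
(4 kb every 10 kb, i.e. 40% genic — a typical plant-genome gene density).
A `deleterious_fraction` (default 0.15) of genic, background-polymorphic
sites are deleterious with a synthetic damaging score < 0.05; other genic
sites get scores ≥ 0.05 ("other", excluded from load statistics);
intergenic sites are the neutral class. Deleterious target frequencies are
f₀·`selection_skew` (default 0.5), so the realized polymorphic-site mean
frequency ratio deleterious:neutral converges to the skew. Because skew
< 1 keeps deleterious targets below 0.5, deleterious alleles are never
fixed in any group, which is what drives the fixed-bin relative load to 0
in simulation.

**Introgression.** An event (donor, recipient group, tract, carrier
fraction) overwrites both haplotypes of exactly round(fraction·n) randomly
chosen recipient samples with a random donor-panel haplotype across the
tract. The count is deterministic rather than Binomial so that a
configured fraction of 0.80 sits reliably below the 0.9 fixation threshold
and 0.95 reliably above it at any seed; the realized count is always
within the Binomial's 3σ band. The donor panel is fixed for the diverged
allele at donor-private sites, fixed for the background major allele
elsewhere, and carries none of the background's deleterious alleles —
the "ancestral state" picture under which interspecific hybridization
dilutes load. **Sweeps.** A selection target fixes the alt allele, in the
target group only, at sites already segregating in that group (deleterious
sites spared): a sweep fixes standing variation and cannot invent donor
alleles, which keeps swept regions from masquerading as introgressions
under the painter.

**What the generator does not emulate.** Linkage disequilibrium within
groups (sites are drawn independently, so LD-decay curves on simulated
data are flat at the 1/n baseline), coalescent-accurate frequency spectra
(the neutral spectrum is roughly uniform with substantial fixed-alt mass,
not 1/x), genotyping error/missingness, structural variation, and
homoeologous exchange between subgenomes. Passing tests therefore
demonstrate correctness of the *procedures* and their behaviour under
known structure, not calibration to real rapeseed data.

## IBD tracing (`polyped.ibd`)

Blocks of `block_size` (default 50 kb, trailing blocks kept with their
true length) are scored per parent by *accumulated exact-match length*:
the number of block positions covered by at least one exact match of
length ≥ k to anywhere in the parent, computed as the union of [s, s+k)
over matched k-mer starts. This equals exhaustive enumeration of all exact
substrings ≥ k (the test oracle); no colinearity constraint is applied,
which is exact on non-repetitive sequence and deliberately simpler than an
aligner. k defaults to 21 (near-unique in a ~1 Gb plant genome); matching
is forward-strand, consistent with colinear assemblies of close relatives.
Assignment is argmax with two guards for cases the longest-match rule
leaves undefined: exact ties and best matches below `min_match_fraction` (10%) of
the block are `unassigned`. `decompose_parent` re-scores one parent's
blocks against that parent's own parents, producing labels like `CY2:CDA`.
Implementation detail: parent k-mer sets are stored as sorted uint64
arrays (2-bit packed) queried by binary search; sorting without
deduplication is ~15× faster than `np.unique` and equivalent for
membership.

Evaluation against simulated truth scores tracing against the child's
*direct* parents (the label set the truth track is defined over); tracing
against all four lines is still the headline pipeline run, but SL-1-descended
blocks are then genuinely ambiguous between SL-1, NY1 and CY2 — an
identifiability limit of the data, not an estimator error.

## Selection scan (`polyped.scan`)

Per-site heterozygosity uses the unbiased 2p̂(1−p̂)·n/(n−1) with n the
called allele count; window π divides the site sum by the window's true bp
span. F<sub>ST</sub> is the two-population Weir & Cockerham (1984)
variance-components estimator; window values sum the per-site a, b, c
components before dividing (the convention of the standard VCF tooling),
and negative values are retained so the Z null is not distorted.
Z-transformation uses the sample SD (ddof = 1), raises on zero variance,
and is applied genome-wide by default (`z_scope="subgenome"` computes it
per subgenome; either scope is defensible, genome-wide is the default).
Windows are anchored at 0 with 100 kb size / 10 kb step defaults; flagged
windows (Z > 3) merge when they overlap or abut. Feature intersection
counts a gene/QTL when the half-open overlap is ≥ 1 bp, deduplicated
globally. Before scans, sites are filtered to minor-allele frequency
≥ 0.01 and call rate ≥ 0.9 (the VCFtools `--maf 0.01 --max-missing 0.9`
convention).

## Local ancestry (`polyped.ancestry`)

The haplotype-copying engine of dedicated ancestry tools is deliberately
not re-implemented; the painter is a transparent stand-in — per window of
`window_snps` consecutive sites (default 50), the query takes the label of
the panel whose closest haplotype has the smaller Hamming distance over
called sites, ties unresolved — plus an adapter for externally produced
per-site ancestry matrices. On panels differing at ≥ 10% of sites the
painter labels ≥ 99% of windows correctly, which is sufficient for the
downstream computation that is original here: the per-window fraction of
samples carrying donor ancestry (a diploid carries with ≥ 1 donor
haplotype; haplotype-level counting is a switch, since a ">90% of
samples" rule can be read at either level) and the strict-inequality
fixation call with window-merging. SNP windows are converted to bp via
flanking-site midpoints, so windows tile chromosomes exactly.

## Genetic load (`polyped.load`)

Deleterious = damaging score strictly < 0.05; neutral = intergenic context;
everything else is excluded. The alternate allele relative to the
ancestral-like combined reference is treated as the derived/deleterious
allele (no outgroup re-polarization). Group counts follow 2·hom-alt + het
over called samples (denominator = twice the called samples). Spectra use
20 equal bins, left-open/right-closed, so the top bin is exactly the
declared fixed class (0.95, 1]; frequency-0 sites are excluded and
frequency-1 sites land in the fixed bin. A folded option exists but the
unfolded alt-allele spectrum is the default. Relative load divides
normalized class proportions bin by bin, with zero-neutral bins flagged
undefined. Per-individual ratios count sites where the individual carries
≥ 1 alternate allele (a dosage switch exists), reported overall and per
subgenome; A + C counts add to the genome-wide count by construction.

## Pipeline and IO (`polyped.io`, `polyped.pipeline`, `polyped.cli`)

All coordinates are 0-based half-open internally; VCF positions convert at
the pysam boundary. The VCF writer emits phased GT when haplotypes exist;
the reader keeps biallelic SNPs, counts dropped multiallelic/indel
records, and degrades phase only when a record is genuinely unphased.
`RunConfig` carries every stage parameter with its conventional default
(50 kb blocks; 100 kb/10 kb windows; Z > 3; fixation > 0.9; maf 0.01;
call rate 0.9; 50-SNP windows; 20 bins) and is serialized verbatim into
`report.json`, which contains no timestamps — identical config + seed
reproduces it byte for byte. The CLI is a thin click wrapper (`simulate`,
`ibd`, `scan`, `ancestry`, `load`, `run`) with exit codes 0/1/2.

## Numerical and testing choices

Problem sizes: the pedigree-recovery check runs the full 10 × 1 Mb,
four-founder scenario (200 blocks); statistic oracles run at 10 haplotypes
× 1000 sites (π, |Δ| < 1e-12) and 200 random sites (F<sub>ST</sub>,
|Δ| < 1e-10); Z calibration uses 10⁵ standard-normal draws against the
1.35e-3 tail; introgression recovery uses 4 × 300 kb chromosomes with a
150-kb tract. Degenerate inputs are explicit errors (zero-length
chromosomes, empty panels, zero-variance Z input, overlapping IBD blocks)
or flagged values (all-N blocks, zero-iSNP ratios, empty spectrum bins),
never silent NaN. Known limitations: no LD structure in the generator, a
forward-strand-only matcher, O(pairs) LD computation intended for
desk-scale matrices, and a painter that degrades when source panels
diverge at ~1% of sites (reported by its unresolved fraction rather than
asserted).
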