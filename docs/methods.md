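# Methods

This document records the algorithms, statistical methods and simulation
models implemented in `pgii`, together with their default parameters and
limitations.

## Coordinate conventions

Inversion calls use 1-based inclusive VCF coordinates (`POS`, `END`).
BED output is 0-based half-open; GFF3 is 1-based inclusive. Calls shorter
than 100 bp are discarded at ingest (`MIN_INVERSION_LENGTH`), matching the
resolution limit of alignment-based inversion callers.

## Index construction

**Merging.** Two calls are redundant when they sit on the same chromosome
and *both* breakpoints differ by at most `max_dist` (default 10 bp).
Redundancy is closed transitively with a union-find, so a chain of calls
each within 10 bp of the next merges into one non-redundant inversion even
if its ends differ by more. Each merged record is represented by its
medoid member — the call minimising the summed breakpoint distance to the
other members, with ties broken by (start, end, genome). The record keeps
the full member list and the carrier genome set.

**Clustering.** Non-redundant inversions are grouped into clusters when
their reciprocal overlap is at least `min_reciprocal_overlap` (default
0.8), again with transitive closure. Clusters carry the union span, member
ids and carrier union.

**Presence matrix.** Clusters × genomes, 1 = carrier, 0 = non-carrier,
NaN = missing. The reference genome is a column of zeros by construction:
calls are made *against* the reference, so reference-ascertained events
appear as the complement set of carriers (every other genome appears
inverted). The species-scale classifier accounts for this asymmetry.

## Spatial statistics

**Saturation.** For subset sizes 1..N genomes, the expected number of
distinct clusters is estimated by random permutation of genome order
(default 100 permutations), optionally restricted to clusters shared by ≥2
carriers.

**Positional uniformity.** Per chromosome, the KS statistic of inversion
start positions against Uniform(1, L) is compared with `n_sim` Monte-Carlo
draws (default 10,000); the p-value uses the add-one estimator
`(1 + #{D_sim ≥ D_obs}) / (n_sim + 1)`, so it is never exactly zero.
Chromosome-level p-values are Benjamini–Hochberg corrected.

**Hotspots.** Chromosomes are tiled with non-overlapping 200 kb windows; a
window is a hotspot when its inversion-start count strictly exceeds the
genome-wide 98th percentile of window counts. Adjacent hotspot windows are
merged into hotspot regions; centromere/telomere overlap is flagged when
track files are supplied.

## Phylogeny

Pairwise genome distances from the presence matrix use Hamming or Jaccard
distance over pairwise-complete clusters. Trees are built with UPGMA
(average linkage, via `scipy.cluster.hierarchy`), which yields ultrametric
trees; node heights are half the merge distance. Congruence with an
external (e.g. SNP-based) distance matrix is tested with a Mantel test:
Pearson correlation of the off-diagonal entries with permutation p-value
(add-one estimator), or exact enumeration for ≤7 leaves.

## Inversion rates

For two lineages separated by time `TMRCA` (million years), the rate per
lineage per MY is `rate = N / (2 · TMRCA)` where `N` is the number of
inversions distinguishing them. Reported values follow the printing rule
used throughout: one decimal below 100, nearest integer above.

Recent within-subspecies rates require counting only recently arisen
inversions. Clusters segregating within the focal group (e.g. GJ) are
filtered to those absent in all other groups, then clusters whose flanking
SNP context is closer to another group than to the focal group are removed
(these are likely older events mis-assigned by incomplete lineage sorting
or admixture). The survivors divided by twice the within-group coalescence
time give the recent rate.

## Classification

**Species scale.** A cluster's carrier pattern across *O. sativa*,
*O. rufipogon* and *O. punctata*, corrected for reference ascertainment,
maps onto a fixed truth table of categories: S1–S3 (sativa-specific
orientations), SR1–SR2 (shared with rufipogon), R (reference lineage) and
UNRESOLVED when all informative genotypes are missing.

**Population scale.** Breakpoint-spanning read support at both breakpoints
genotypes each accession: both supported → inversion; one supported →
inversion with breakpoint deletion; both absent → no inversion; otherwise
missing, with a confidence flag when one side lacks data. Accessions and
inversions with >30% missing cells are removed iteratively (rows, then
columns, to a fixed point), so the final matrix has no row or column above
the threshold.

## Breakpoint features

TE enrichment compares the fraction of ±`window` bp (default 100)
breakpoint windows containing each TE family with replicate sets of
uniformly resampled positions (default 10 replicates of 10× the breakpoint
count), using a one-sample t-test across replicates. Repeat search finds
maximal common substrings ≥ `min_len` between the two breakpoint flanks,
in direct and reverse-complement orientation. Gene overlap reports genes
contained in, overlapping, or spanning each breakpoint.

## Recombination and LD

**Suppression.** Inter-bin recombination rates (cM/Mb between consecutive
bin midpoints) from a genetic bin map are compared between intervals whose
midpoints fall inside inversions and the genome-wide background (Welch
t-test). The suppression ratio is the inverted-interval mean over the
non-inverted mean.

**Disrupted-LD-block signature.** Recombination in inversion
heterozygotes is suppressed across the inverted region, but in carriers
the interior is reversed: loci near one breakpoint *outside* the inversion
stay linked to loci in the *distal* half of the inversion, while linkage
to the proximal half decays. The detector builds LD blocks as greedily
grown maximal cliques of sites with pairwise r² > 0.8 and calls the
signature when some block has ≥3 sites in a flank, ≥3 in the distal half
of the inversion (measured from that flank) and none in the proximal half.

## Synthetic data generators

All generators are seed-deterministic and exist to validate the analyses
against known truth; their defaults are fixed study conditions, not tuned
values.

**Panel simulator.** 73 *O. sativa* genomes across 15 subpopulations in 4
groups, plus one *O. rufipogon* and one *O. punctata*. Node ages (MY):
subpopulation 0.0071, group 0.0142, clade 0.25, sativa crown 0.38,
AA split 0.5, BB split 2.5. Inversion events are Poisson on each branch
with an epoch-dependent rate per lineage: 735/MY more recently than
0.0142 MY, 215.2/MY back to 0.5 MY, and 26.75/MY beyond, chosen so that
the expected pairwise counts match the headline comparisons
(2·∫₀^0.0142 = 20.9, 2·∫₀^0.5 = 230, 2·∫₀^2.5 = 337). Event intervals are
drawn length-weighted across chromosomes without overlap; each event is
observed in all descendant genomes, with optional breakpoint jitter and
false-negative dropout, and events on the reference lineage are reported
as the complement call set.

**Genotype simulator (LD validation).** A 300 kb inversion with 100 kb
flanks, 400 SNPs, 60 sampled inbred accessions from a population of 120
haplotypes evolved for 20 generations with 0.5 crossovers per meiosis.
Six standard and three inverted founder haplotypes; 80% of SNPs inside the
inversion are founder-lineage markers private to one inverted founder.
Crossovers between unlike karyotypes are excluded within the inversion and
an 80 kb suppression halo on each side (crossover suppression extends tens
of kb beyond the breakpoints in heterokaryotypes); crossovers between
carrier haplotypes act on carrier coordinates, i.e. with the interior
reversed. Under these conditions the LD signature detector attains
sensitivity 0.92 and false-positive rate 0.002 over 500 held-out seeds.

**Other generators.** Bin maps with lognormal rate noise and configurable
within-inversion suppression; non-overlapping TE annotations with optional
family enrichment at breakpoints; breakpoint read-support tables with
dropout and inversion+deletion conversion.

## Limitations

- The panel simulator uses a fixed species tree without gene-tree
  discordance, admixture or back-mutation; each inversion arises once.
- The genotype simulator models inbred (homozygous) accessions only, as
  appropriate for rice diversity panels.
- Replicating published call-set totals requires the original
  supplementary call data, which is not redistributable here; the pipeline
  is instead validated end to end on synthetic data with known truth.
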