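# pgii — pan-genome inversion index analysis

`pgii` builds and analyses a pan-genome index of chromosomal inversions from
whole-genome alignments of a crop species panel, modelled on Asian rice
(*Oryza sativa*) with *O. rufipogon* and *O. punctata* outgroups. Starting
from per-genome inversion calls against a single reference (SyRI-style VCF),
it produces a non-redundant inversion index and cluster-level presence
matrix, then quantifies how inversions arise and behave:

- **Index construction** — merge per-genome calls whose breakpoints both lie
  within 10 bp (transitive closure, medoid representative), then group
  overlapping index entries into clusters at 80% reciprocal overlap.
- **Spatial statistics** — pan-genome saturation curves, Monte-Carlo
  Kolmogorov–Smirnov tests of positional uniformity per chromosome with
  Benjamini–Hochberg correction, and fixed-window hotspot detection.
- **Phylogeny** — UPGMA trees from inversion presence/absence distances and
  Mantel tests against SNP-based distances.
- **Rate estimation** — inversion rates per million years from pairwise
  counts and divergence times (`rate = N / (2 * TMRCA)`), including the
  subpopulation-private cluster filter used for recent-rate estimation.
- **Classification** — species-scale cluster categories (S/SR/R classes)
  from carrier patterns across *O. sativa*, *O. rufipogon* and
  *O. punctata*, and population-scale breakpoint genotyping from
  split-read support patterns with missingness filtering.
- **Breakpoint features** — TE-family enrichment at breakpoints via
  resampling, inverted/direct repeat search, and gene–breakpoint overlap.
- **Recombination and LD** — recombination-rate suppression inside
  inversions from genetic bin maps, and detection of the disrupted-LD-block
  signature that heterokaryotypic recombination leaves around inversions.
- **Synthetic data generators** — a coalescent-flavoured panel simulator
  with epoch-dependent inversion rates on a known species tree, plus
  genotype, bin-map, TE and read-support simulators, all with known ground
  truth for validation.

## Quick start

Estimate an inversion rate from a pairwise count and divergence time:

```sh
$ pgii rates -n 337 -t 2.5
rate: N = 337, TMRCA = 2.5 MY -> 67.4 inversions/MY
```

Run the whole pipeline on a simulated panel:

```sh
$ pgii simulate out/ --seed 1           # per-genome VCFs + panel table + truth
$ pgii merge out/calls -o out/index.tsv
9746 calls (20 below 100 bp dropped) -> 1061 non-redundant inversions
$ pgii cluster out/index.tsv -o out/clusters.tsv
$ pgii matrix out/clusters.tsv out/panel.tsv -o out/matrix.tsv \
      --reference "$(cat out/reference.txt)"
$ pgii hotspots out/index.tsv out/chrom_lengths.tsv -o out/windows.tsv
$ pgii tree out/matrix.tsv -o out/tree.nwk
```

or let `pgii report out/ --seed 1` run the same steps end to end and print a
summary with rate estimates for each species comparison.

Python API:

```python
from pgii import merge_calls, cluster_inversions, build_presence_matrix

index = merge_calls(calls, max_dist=10)
clusters = cluster_inversions(index, min_reciprocal_overlap=0.8)
matrix = build_presence_matrix(clusters, panel, reference_genome)
```

All commands accept `--config config.yaml` to set shared parameters; each
run logs the package version, a configuration digest and input checksums
for reproducibility.

## Testing and validation

```sh
python -m pytest -q tests/
python scripts/acceptance.py --seed 1 --out results.json
```

The test suite validates the merge and cluster algorithms against
brute-force quadratic oracles, checks the Monte-Carlo KS test's null
calibration, verifies UPGMA against hand agglomeration, and confirms that
the simulators' planted parameters (branch inversion rates, recombination
suppression, LD signatures, breakpoint genotypes) are recovered by the
corresponding analyses. `scripts/acceptance.py` runs the main computation
on synthetic data and writes the headline quantities as JSON.

One test (`test_criterion_3_supplementary_replication_not_runnable`)
intentionally fails: it documents the replication of published call-set
totals, which requires supplementary data files that cannot be
redistributed with this repository.

See `docs/methods.md` for model assumptions, parameter defaults and the
design of the synthetic generators.
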