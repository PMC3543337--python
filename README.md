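# neutralregions

Tools for mining **putatively neutral loci** from a genome and analyzing
diversity in them.  Population-genetic inference of demographic history
needs genomic regions whose variation is free of both the direct and the
linked effects of natural selection; picking those regions means combining
many heterogeneous filters — gene annotations, conserved elements,
repeats and duplications, recombination maps, the predicted strength of
background selection — and then ranking and thinning what survives.  This
package implements that workflow as a library plus a `neutral-regions`
command-line tool, for population geneticists designing resequencing
panels or aggregating genome-wide diversity.

## What it computes

The pipeline has two steps:

1. **Hard filtering** — the union of user-supplied "hard" BED tracks
   (genes, duplications, alignment masks, ...) is subtracted from the
   genome; survivors are restricted by chromosome and length.
2. **Annotation and selection** — each surviving region is annotated with:
   - physical and genetic distance (bp, cM) to the nearest gene;
   - mean recombination rate `r = Δ(cM) / Δ(Mb)` from a genetic map
     (cumulative positions interpolated linearly between markers; an
     X-chromosome map estimated from female meioses only is rescaled by
     2/3 for sex averaging);
   - nucleotide diversity per base,
     `π = (1/L) Σ_sites 2·AC·(AN−AC) / (AN·(AN−1))`,
     from VCF allele counts;
   - the background-selection statistic `B` (expected fraction of neutral
     diversity retained; 1 = no linked selection), averaged over
     overlapping precomputed windows weighted by overlap;
   - percent overlap with each "soft" track;
   - outgroup divergence: raw mismatch fraction `p` over aligned bases and
     the Jukes–Cantor distance `D = −(3/4)·ln(1 − (4/3)p)`.

   Regions can then be threshold-filtered on any field, multi-sorted with
   a sort→bin→sort scheme, thinned to a minimum physical or genetic
   separation by a largest-first greedy pass, and truncated to the top N.

As a demonstration analysis, the `xa` stage aggregates
mutation-rate-normalized diversity `π/D` (length-weighted) separately for
chromosome X and the autosomes and forms their ratio — an estimator of the
X-to-autosome effective population size ratio `N_X/N_A`, which is 3/4
under neutrality, equal sex ratios and constant population size — with a
standard error from bootstrapping regions (10,000 replicates by default).

A simulator (`neutral-regions simulate`) generates complete synthetic
bundles — genome, tracks, map, B windows, neutral-spectrum polymorphism at
a chosen per-base θ, and i.i.d. per-base divergence — with exact analytic
expectations (`E[π] = θ`), so the whole pipeline is testable offline.

## Worked example

```bash
neutral-regions simulate --preset xa --theta-a 0.001 --theta-x 0.00075 \
    --d 0.01 --n 40 --seed 8 --outdir demo
neutral-regions filter --genome demo/genome.chrom.sizes \
    --hard demo/genes.bed --hard demo/repeats.bed \
    --min-len 1000 --out demo/candidates.bed
neutral-regions annotate --regions demo/candidates.bed \
    --genes demo/genes.bed --map demo/genetic_map.txt --map-x-scale \
    --vcf demo/variants.vcf --btrack demo/bwindows.bed \
    --outgroup-aligned demo/outgroup_aligned.bed \
    --outgroup-mismatch demo/outgroup_mismatch.bed \
    --out demo/regions.tsv
```

`regions.tsv` holds one line per candidate region (`NA` marks
annotations that are undefined for that region).  Splitting it by
chromosome into `x.tsv` / `a.tsv` and running

```bash
neutral-regions xa --x-table demo/x.tsv --a-table demo/a.tsv \
    --reps 10000 --seed 3 --out demo/xa.tsv
```

prints and writes

```
xa_ratio    0.744392
xa_se       0.0120946
reps        10000
```

i.e. the X/A normalized-diversity ratio recovers the generating
`θ_X/θ_A = 0.75` within one bootstrap SE — the neutral expectation for
`N_X/N_A`.  The same chain can be driven from a single config file with
`neutral-regions run --config run.cfg`, which also writes a run manifest
(input checksums, parameters, per-stage region/base counts).  A ready-made
recipe for the human X-vs-autosome analysis (six hard tracks, two 0% soft
filters, 1 kb minimum length) ships as
`src/neutralregions/recipes/human_xa_neutral.cfg`; its tracks are large
external downloads, so paths are placeholders.

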