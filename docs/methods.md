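# Methods

## Coordinate and interval model

All coordinates are 0-based half-open `[start, end)` on named chromosomes
(the BED convention); VCF positions are converted on read (`POS − 1`) and
never anywhere else, so a single convention holds throughout.  Interval
sets are kept normalized — per chromosome sorted, disjoint, with
book-ended intervals merged — matching the semantics of standard genome
arithmetic tools, and all set operations (merge, subtract, intersect,
complement) are exact integer arithmetic.  Zero-length intervals are
rejected on construction and can never be emitted.  Chromosome names are
matched by exact string equality: silent `chr`-prefix aliasing hides data
errors, so any renaming must be explicit in the user's inputs.

## Hard and soft filters

Hard-filter tracks are unioned and subtracted from the assembly outright;
the complement is the candidate space.  Assembly gaps get no special
treatment — users who want them excluded include a gap track among the
hard filters, which keeps the engine fully data-driven.  Soft tracks are
never subtracted; each region is annotated with its percent overlap and
the user thresholds that number later.  A 0% ceiling on a soft overlap
*drops whole regions* that contain any overlapping base, which is not the
same as hard subtraction (that trims and keeps the flanks); both behaviors
are available and the distinction is deliberate.

A priori filters on gene distance or recombination rate are implemented by
annotating and thresholding — one code path, identical results, whether
the user filters early or late.

## Annotations

* **Nearest gene.**  Physical distance is from the region's nearest
  boundary to the nearest transcript edge (0 if overlapping).  The gene is
  chosen by *physical* distance; the genetic distance reported is to that
  same gene, measured between the same two edges on the interpolated map.
  This is deterministic; "genetically nearest" is not separately searched.
* **Genetic map.**  Markers carry a local rate (cM/Mb, to the next
  marker) and a cumulative position (cM).  Cumulative position at an
  arbitrary base is linear interpolation between flanking markers;
  outside the marker span the terminal interval's rate extrapolates,
  floored at 0 cM.  The mean recombination rate of a region is its
  genetic span over its physical span, `[cum(end) − cum(start)] /
  (L/10⁶)` — the length-weighted mean of the per-interval map rates, a
  single estimator that subsumes both "average over contained markers"
  and "weighted flanking markers".  An X map estimated from female
  meioses only is multiplied by exactly 2/3 (rates and cumulative values)
  when `x_scale` is requested, because X recombines only in females.
* **Diversity.**  `π = (1/L) Σ 2·AC(AN−AC)/(AN(AN−1))` summed over
  biallelic SNPs in the region.  The denominator is the full region
  length: monomorphic (and uncalled) bases count as invariant, which is
  the right convention for low-coverage allele-count data; an optional
  accessibility mask can shrink `L` where callability is known.
  Genotype-derived counts are preferred over INFO `AC/AN` when both are
  present (missing genotypes are excluded from `AN`), supporting e.g.
  female-only subsetting for X analyses.
* **Background selection.**  `B` (expected fraction of neutral diversity
  retained; computed elsewhere, read as a window track) is averaged over
  the windows overlapping a region, weighted by overlap bases and
  normalized by *total overlapped* bases — a proper weighted mean, so a
  partially tiled region is not biased toward 0.  Windows are clipped to
  chromosome bounds on read.
* **Divergence.**  `p` = mismatched / aligned outgroup bases in the
  region (unaligned bases excluded from both counts), ingested as an
  "aligned" plus a "mismatch" BED (mismatch ⊆ aligned) — a format-agnostic
  stand-in for axt/maf-derived status.  `D = −(3/4)ln(1 − 4p/3)` is the
  Jukes–Cantor correction; it is undefined at `p ≥ 3/4` (saturation) and
  both values are withheld when fewer than `min_aligned_bp` (default
  100 bp) bases align, since shorter denominators make `p` noise.

Undefined annotations are `None` in memory and `NA` on disk; they fail
every threshold on that field and sort last — conservative behavior for a
neutrality screen.

## Ranking and selection

Multi-parameter sorting is sort→bin→sort: stable-sort on the first key,
cut the ordered list into `n_bins` contiguous *equal-count* bins (the
first `N mod n_bins` bins take one extra), stable-sort on the next key
within each bin, re-binning recursively for further keys.  Equal-count
bins (rather than equal value width) are scale-free across heterogeneous
fields.  More bins = finer subsequent sorting; with one bin the last key
dominates, with `N` bins later keys are inert.

Minimum-separation thinning is a greedy pass from the largest locus to the
smallest (ties broken by chromosome name, then start), keeping a locus iff
its separation from every already-kept locus on the same chromosome is at
least the threshold (boundary inclusive).  Separation is measured between
facing interval edges — bp gap, or the cM difference of the interpolated
map positions of those edges in genetic mode.  This is a heuristic: the
optimal maximum-coverage independent set grows prohibitively in
complexity, and the greedy pass keeps long loci preferentially while
guaranteeing the output is pairwise feasible and not extensible (verified
by exhaustive subset enumeration in the tests on small instances).
Different chromosomes are infinitely separated.

## X-to-autosome analysis

Normalized diversity of a region set is the ratio of the length-weighted
mean π to the length-weighted mean JC divergence — equivalently genome
totals, `Σπ_iL_i / ΣD_iL_i` — rather than a mean of per-region `π_i/D_i`
ratios, which would be dominated by divergence noise in short regions.
The X/A ratio of these quantities estimates `N_X/N_A`; dividing by
divergence cancels mutation-rate variation, and any common rescaling of
π or D leaves the ratio invariant.

The bootstrap resamples *regions* (the exchangeable unit the pipeline
produces), independently within the X and autosomal strata, at their
original counts, recomputing the ratio per replicate; the SE is the SD
across replicates (10,000 by default).  The RNG seed defaults to a fixed,
logged value and is always overridable; identical seeds give identical
estimates.  Replicates whose resampled divergence (or diversity)
denominator is zero cannot form a ratio and are dropped and counted.

## Synthetic data

The simulator emulates the pipeline's whole input surface with analytic
ground truth rather than genealogical realism:

* **Tracks.**  Genes (default 5/Mb, 1–3 kb) and repeats (20/Mb,
  100–500 bp) placed uniformly without self-overlap (an error if the
  density saturates the chromosome); map markers every 10 kb with
  piecewise-constant rates and an exactly consistent cumulative column;
  B windows tiling each chromosome at 50 kb.
* **Polymorphism.**  Infinite-sites, neutral frequency spectrum: for each
  derived count `i ∈ 1..n−1`, `Poisson(θL/i)` sites placed uniformly
  without collision over the region bases, all with `AN = n`.  Under this
  construction `E[π] = θ` *exactly*, and the segregating-site count has
  the Watterson expectation `θL·Σ1/i` — sharp targets for recovery tests.
* **Divergence.**  Every base aligned; i.i.d. mismatch with probability
  `d` — the Jukes–Cantor model's own assumption, so `p̂ → d` to binomial
  error.

The default X-vs-autosome bundle uses two 3.5 Mb autosomes plus a 3 Mb X
(≈ 6.9 Mb and ≈ 2.9 Mb of ≥ 1 kb candidates after filtering — above the
5 Mb / 2 Mb floors the analysis assumes), `θ_A = 10⁻³`/bp,
`θ_X = 0.75·θ_A`, `d = 0.01`, `n = 40`.  These sizes keep a full
simulate–annotate–bootstrap cycle around a second while leaving the
bootstrap SE of the X/A ratio near 0.01, so a 2-SE recovery check is
meaningful.  Everything is deterministic given the seed (one RNG stream,
fixed draw order; same seed ⇒ byte-identical files).

What passing these tests does *not* show: the simulator has no linkage
disequilibrium, no selection, no demography, no mutation-rate
heterogeneity, and no alignment gaps, so recovery here validates the
estimators and plumbing, not robustness to those real-data features.

## Numerical and degenerate-input choices

* Interval operations reject malformed records by name/line number; no
  silent coercion anywhere in the readers.
* `π` of an empty or zero-denominator region is 0; `B` of an uncovered
  region, distances without genes or map, and divergence under the
  aligned-base floor are all `None`, never 0.
* The binned sort is stable at every level, making the full ordering
  reproducible; the greedy spacer's length ties are broken
  lexicographically.
* Bootstrap SD uses `ddof = 1`; a single-replicate bootstrap reports
  SE 0.
* Map-scaling by 2/3 is applied at read time as one multiplication, so
  the scaled/raw ratio is exact to machine precision.

## Known limitations

Full-scan (untabixed) I/O limits inputs to desk scale; B values are read,
not derived from a selection model; sex-specific maps beyond the 2/3
rescaling, LiftOver, and axt/maf parsing are out of scope; and the
greedy spacer is deliberately suboptimal (see above).
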