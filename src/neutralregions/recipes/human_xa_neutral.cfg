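# Filter recipe for the human X-vs-autosome neutral-diversity analysis.
#
# Reproduces the published selection of nearly neutral human loci:
# hard-subtract genic, duplicated and poorly-syntenic sequence, keep only
# regions of at least 1000 bp (for robust per-region divergence), and drop
# any region overlapping conserved placental elements or simple repeats
# (soft filters thresholded at 0%, equivalent to a hard filter applied
# region-wise).
#
# The tracks themselves are large external downloads (UCSC genome browser
# tables, a primate synteny mask, 1000 Genomes pilot VCFs, HapMap II
# genetic map); replace the placeholder paths below with local copies.
# Coordinates must share one assembly build.

[genome]
chrom_sizes = hg18.chrom.sizes

[filter]
# Non-genic: UCSC Known Genes, RefSeq gene bounds, spliced ESTs.
# Non-duplicated: segmental duplications, self-chain alignments.
# Outgroup-comparable: mask of poor synteny with macaque.
hard = known_genes.bed, gene_bounds.bed, spliced_ests.bed, segmental_duplications.bed, self_chain.bed, macaque_synteny_mask.bed
min_len = 1000
out = candidates.bed

[annotate]
genes = gene_bounds.bed
map = hapmap2_genetic_map.txt
# X map estimated from female meioses only: scale by 2/3 for sex averaging.
map_x_scale = true
x_chrom = chrX
vcf = snps.vcf
b_track = background_selection_B.bed
soft = conserved_placental_28way=conserved_placental_28way.bed, simple_repeats=simple_repeats.bed
outgroup_aligned = macaque_aligned.bed
outgroup_mismatch = macaque_mismatch.bed
out = regions.tsv

[select]
# 0% tolerated overlap with either soft filter.
max = conserved_placental_28way=0, simple_repeats=0
out = selected.tsv

[xa]
x_chroms = chrX
reps = 10000
out = xa_report.tsv

[run]
manifest = run_manifest.tsv
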