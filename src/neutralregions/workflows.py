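"""High-level composition of the pipeline stages.

`xa_workflow` runs the whole chain — read fixture/real inputs from a
directory, rebuild the candidate space from the hard tracks, annotate,
split X from autosomes, and estimate the normalized X/A diversity ratio
with a bootstrap SE — the same steps the CLI performs, callable as one
function.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

from . import tracks_io
from .annotate import AnnotationResources, annotate_all
from .records import RegionRecord
from .stage1 import build_candidate_regions, filter_length, restrict_chromosomes
from .xa import DEFAULT_REPS, RatioEstimate, bootstrap_se

__all__ = ["xa_workflow"]


def xa_workflow(input_dir: str | Path,
                hard: Sequence[str] = ("genes.bed", "repeats.bed"),
                x_chrom: str = "chrX",
                min_len: int = 1_000,
                reps: int = DEFAULT_REPS,
                seed: Optional[int] = None,
                ) -> tuple[RatioEstimate, list[RegionRecord], list[RegionRecord]]:
    """X-vs-autosome analysis over a bundle directory.

    Expects the file layout written by :func:`~neutralregions.simulate.make_xa_bundle`
    (``genome.chrom.sizes``, hard-filter BEDs, ``genes.bed``,
    ``genetic_map.txt``, ``variants.vcf``, ``bwindows.bed``,
    ``outgroup_aligned.bed``/``outgroup_mismatch.bed``).  Returns the ratio
    estimate plus the annotated X and autosomal region records.
    """
    d = Path(input_dir)
    genome = tracks_io.read_chrom_sizes(d / "genome.chrom.sizes")
    hard_tracks = [tracks_io.read_bed(d / name, role="hard") for name in hard]
    candidates = filter_length(
        build_candidate_regions(genome, hard_tracks), min_len=min_len)
    res = AnnotationResources(
        genes=tracks_io.read_genes(d / "genes.bed"),
        gmap=tracks_io.read_genetic_map(d / "genetic_map.txt",
                                        x_scale=True, x_chrom=x_chrom),
        sites=tracks_io.read_variant_sites(d / "variants.vcf"),
        b_windows=tracks_io.read_b_track(d / "bwindows.bed"),
        outgroup=tracks_io.read_outgroup(d / "outgroup_aligned.bed",
                                         d / "outgroup_mismatch.bed"))
    autos = [c for c in genome if c != x_chrom]
    x_records = annotate_all(restrict_chromosomes(candidates, [x_chrom]), res)
    a_records = annotate_all(restrict_chromosomes(candidates, autos), res)
    est = bootstrap_se(x_records, a_records, reps=reps, seed=seed)
    return est, x_records, a_records
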