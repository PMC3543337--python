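"""Per-region neutrality and data-quality statistics.

For each candidate region this module computes:

* physical and genetic distance to the nearest gene,
* mean recombination rate (cM/Mb) from a genetic map,
* nucleotide diversity pi from allele counts,
* the mean background-selection B statistic (expected fraction of neutral
  diversity retained, 1 = no linked selection),
* percent overlap with each soft-filter track,
* raw and Jukes-Cantor-corrected divergence from an outgroup alignment.

Undefined values (no gene on the chromosome, no overlapping B window, too
few aligned outgroup bases, ...) propagate as ``None``.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Mapping, Optional, Sequence

import numpy as np

from .intervals import GenomicInterval, IntervalTrack, overlap_bp
from .maps import GeneticMap
from .records import BWindow, GeneModel, OutgroupStatus, RegionRecord, VariantSite

__all__ = [
    "AnnotationResources",
    "nearest_gene_distance",
    "interpolate_cum_cM",
    "recombination_rate",
    "nucleotide_diversity",
    "background_selection_mean",
    "soft_overlap_pct",
    "jukes_cantor",
    "divergence",
    "annotate_all",
]

log = logging.getLogger(__name__)

#: Raw mismatch fractions at or above this value are outside the domain of
#: the Jukes-Cantor correction (expected fraction under saturation).
JC_MAX_P = 0.75


@dataclasses.dataclass
class AnnotationResources:
    """Bundle of reference resources consumed by :func:`annotate_all`.

    Any resource may be ``None``/empty, in which case the corresponding
    annotation is left undefined.  ``min_aligned_bp`` is the floor on
    aligned outgroup bases below which divergence is not reported (default
    100 bp: a per-region divergence from fewer bases is noise).
    ``accessibility`` optionally restricts the pi denominator to callable
    bases; by default every base of the region counts as invariant.
    """

    genes: Optional[Sequence[GeneModel]] = None
    gmap: Optional[GeneticMap] = None
    sites: Optional[Sequence[VariantSite]] = None
    b_windows: Optional[Sequence[BWindow]] = None
    soft: Mapping[str, IntervalTrack] = dataclasses.field(default_factory=dict)
    outgroup: Optional[OutgroupStatus] = None
    min_aligned_bp: int = 100
    accessibility: Optional[IntervalTrack] = None


# -- genes ---------------------------------------------------------------

def nearest_gene_distance(region: GenomicInterval,
                          genes: Sequence[GeneModel],
                          gmap: Optional[GeneticMap] = None,
                          ) -> tuple[Optional[int], Optional[float]]:
    """Physical (bp) and genetic (cM) distance to the nearest gene.

    The bp distance is from the region's nearest boundary to the nearest
    gene edge, 0 when they overlap.  The cM distance is measured between the
    same two edges (to the gene that is nearest *in bp*) by interpolating
    cumulative map position; it is ``None`` without a usable map.  Both are
    ``None`` when the chromosome has no gene.
    """
    best: Optional[tuple[int, int, int]] = None  # (dist, region_edge, gene_edge)
    for gene in genes:
        g = gene.interval
        if g.chrom != region.chrom:
            continue
        if g.start < region.end and region.start < g.end:
            cand = (0, region.start, region.start)  # overlapping: distance 0
        elif g.end <= region.start:
            cand = (region.start - g.end, region.start, g.end)
        else:
            cand = (g.start - region.end, region.end, g.start)
        if best is None or cand[0] < best[0]:
            best = cand
    if best is None:
        return None, None
    dist_bp, region_edge, gene_edge = best
    dist_cm: Optional[float] = None
    if gmap is not None:
        c1 = gmap.cum_at(region.chrom, region_edge)
        c2 = gmap.cum_at(region.chrom, gene_edge)
        if c1 is not None and c2 is not None:
            dist_cm = abs(c1 - c2)
    return dist_bp, dist_cm


# -- recombination -------------------------------------------------------

def interpolate_cum_cM(gmap: GeneticMap, chrom: str, pos: int) -> Optional[float]:
    """Cumulative genetic position (cM) at ``pos``; see
    :meth:`GeneticMap.cum_at` for the interpolation/extrapolation rules."""
    return gmap.cum_at(chrom, pos)


def recombination_rate(region: GenomicInterval,
                       gmap: GeneticMap) -> Optional[float]:
    """Mean recombination rate over the region in cM/Mb.

    Computed as the genetic span divided by the physical span,
    ``[cum(end) - cum(start)] / (length / 1e6)`` — the length-weighted mean
    of per-map-interval rates, which subsumes averaging over contained
    markers and weighting the flanking markers.  ``None`` when the map
    lacks the chromosome.
    """
    c_start = gmap.cum_at(region.chrom, region.start)
    c_end = gmap.cum_at(region.chrom, region.end)
    if c_start is None or c_end is None:
        return None
    return max(0.0, c_end - c_start) / (region.length / 1e6)


# -- diversity -----------------------------------------------------------

def _site_heterozygosity(ac: np.ndarray, an: np.ndarray) -> np.ndarray:
    # expected pairwise differences at a site: 2 * ac * (an - ac) / (an * (an - 1))
    ac = ac.astype(float)
    an = an.astype(float)
    return 2.0 * ac * (an - ac) / (an * (an - 1.0))


def nucleotide_diversity(region: GenomicInterval,
                         sites: Sequence[VariantSite],
                         denominator_bp: Optional[int] = None) -> float:
    """Nucleotide diversity pi: mean pairwise differences per base.

    Sums ``2*ac*(an-ac) / (an*(an-1))`` over polymorphic sites inside the
    region and divides by the region length (every base, polymorphic or
    not, counts in the denominator unless ``denominator_bp`` overrides it,
    e.g. with an accessible-base count).  With complete genotypes this
    equals the mean per-bp difference over all haplotype pairs.
    """
    total = 0.0
    for s in sites:
        if s.chrom == region.chrom and region.start <= s.pos0 < region.end:
            total += 2.0 * s.ac * (s.an - s.ac) / (s.an * (s.an - 1.0))
    length = region.length if denominator_bp is None else denominator_bp
    if length <= 0:
        return 0.0
    return total / length


# -- background selection ------------------------------------------------

def background_selection_mean(region: GenomicInterval,
                              windows: Sequence[BWindow]) -> Optional[float]:
    """Overlap-weighted mean B over the windows intersecting the region.

    ``sum(b_w * o_w) / sum(o_w)`` with ``o_w`` the bp of the region covered
    by window ``w``; weights are normalized by total overlapped bases so a
    partial tiling does not bias the mean toward 0.  ``None`` when no
    window overlaps.
    """
    num = 0.0
    den = 0
    for w in windows:
        iv = w.interval
        if iv.chrom != region.chrom:
            continue
        o = min(iv.end, region.end) - max(iv.start, region.start)
        if o > 0:
            num += w.b * o
            den += o
    if den == 0:
        return None
    return num / den


# -- soft filters --------------------------------------------------------

def soft_overlap_pct(region: GenomicInterval, soft: IntervalTrack) -> float:
    """Percent of the region's bases covered by the soft track, in [0, 100]."""
    return 100.0 * overlap_bp(region, soft) / region.length


# -- divergence ----------------------------------------------------------

def jukes_cantor(p: float) -> float:
    """Jukes-Cantor distance ``D = -(3/4) * ln(1 - (4/3) * p)``, correcting a
    raw mismatch fraction for recurrent substitution."""
    if not (0.0 <= p < JC_MAX_P):
        raise ValueError(f"raw divergence p={p} outside the JC domain [0, 0.75)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def divergence(region: GenomicInterval, og: OutgroupStatus,
               min_aligned_bp: int = 100,
               ) -> tuple[Optional[float], Optional[float]]:
    """Raw (``p``) and JC-corrected (``D``) divergence from the outgroup.

    ``p`` = mismatched / aligned bases within the region; unaligned bases
    are excluded from both counts.  Both values are ``None`` when fewer
    than ``min_aligned_bp`` bases align; ``D`` alone is ``None`` (with a
    warning) when ``p`` reaches the JC saturation bound of 3/4.
    """
    aligned = overlap_bp(region, og.aligned)
    if aligned < min_aligned_bp:
        return None, None
    mismatched = overlap_bp(region, og.mismatch)
    p = mismatched / aligned
    if p >= JC_MAX_P:
        log.warning("region %s: raw divergence %.3f is JC-saturated; D undefined", region, p)
        return p, None
    return p, jukes_cantor(p)


# -- composition ---------------------------------------------------------

def _sites_by_chrom(sites: Sequence[VariantSite]):
    by: dict[str, list[VariantSite]] = {}
    for s in sites:
        by.setdefault(s.chrom, []).append(s)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ss in by.items():
        ss.sort(key=lambda s: s.pos0)
        pos = np.array([s.pos0 for s in ss], dtype=np.int64)
        het = _site_heterozygosity(np.array([s.ac for s in ss]),
                                   np.array([s.an for s in ss]))
        out[chrom] = (pos, het)
    return out


def _b_by_chrom(windows: Sequence[BWindow]):
    by: dict[str, list[BWindow]] = {}
    for w in windows:
        by.setdefault(w.interval.chrom, []).append(w)
    out: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, ws in by.items():
        ws.sort(key=lambda w: w.interval.start)
        out[chrom] = (np.array([w.interval.start for w in ws], dtype=np.int64),
                      np.array([w.interval.end for w in ws], dtype=np.int64),
                      np.array([w.b for w in ws], dtype=float))
    return out


def annotate_all(track: IntervalTrack,
                 resources: AnnotationResources) -> list[RegionRecord]:
    """One :class:`RegionRecord` per region of ``track``, in track order,
    with every statistic populated (or ``None`` per the rules above)."""
    res = resources
    site_idx = _sites_by_chrom(res.sites) if res.sites else {}
    b_idx = _b_by_chrom(res.b_windows) if res.b_windows else {}
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in (res.genes or ()):
        genes_by_chrom.setdefault(g.interval.chrom, []).append(g)

    records: list[RegionRecord] = []
    for region in track.intervals():
        rec = RegionRecord(region)
        if res.genes is not None:
            rec.dist_gene_bp, rec.dist_gene_cM = nearest_gene_distance(
                region, genes_by_chrom.get(region.chrom, ()), res.gmap)
        if res.gmap is not None:
            rec.rec_rate = recombination_rate(region, res.gmap)
        if res.sites is not None:
            denom: Optional[int] = None
            if res.accessibility is not None:
                denom = overlap_bp(region, res.accessibility)
            if region.chrom in site_idx:
                pos, het = site_idx[region.chrom]
                lo, hi = np.searchsorted(pos, [region.start, region.end])
                total = float(het[lo:hi].sum())
            else:
                total = 0.0
            length = region.length if denom is None else denom
            rec.pi = total / length if length > 0 else 0.0
        if res.b_windows is not None:
            if region.chrom in b_idx:
                ws, we, wb = b_idx[region.chrom]
                o = np.minimum(we, region.end) - np.maximum(ws, region.start)
                o = np.clip(o, 0, None)
                den = int(o.sum())
                rec.b_mean = float((wb * o).sum() / den) if den else None
        for sname, strack in res.soft.items():
            rec.soft_pct[sname] = soft_overlap_pct(region, strack)
        if res.outgroup is not None:
            rec.div_raw, rec.div_jc = divergence(region, res.outgroup,
                                                 res.min_aligned_bp)
        records.append(rec)
    return records
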