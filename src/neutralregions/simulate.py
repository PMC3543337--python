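"""Synthetic fixture generator: complete, self-consistent toy datasets.

Emits a genome with gene/repeat tracks, a piecewise-constant genetic map,
background-selection B windows, neutral-spectrum polymorphism at a chosen
per-base theta, and i.i.d. per-base outgroup divergence at a chosen rate —
everything the pipeline reads, with analytically known ground truth.

Polymorphism follows an infinite-sites construction: for each derived-allele
count ``i`` in ``1..n-1`` the number of segregating sites is
``Poisson(theta * L / i)`` (the neutral frequency spectrum), placed
uniformly without collision over the region bases.  Under this construction
the expected per-base pairwise diversity equals theta *exactly*, because a
site at count ``i`` contributes ``2 i (n - i) / (n (n - 1))`` and
``sum_i (1/i) * 2 i (n - i) / (n (n - 1)) = 1``.  Divergence is an i.i.d.
per-base mismatch with probability ``d`` — the Jukes-Cantor model's own
assumption — so the raw region fraction recovers ``d`` to binomial error.
No linkage, selection or demography is simulated.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np

from .intervals import (GenomeAssembly, GenomicInterval, IntervalTrack,
                        merge_intervals)
from .maps import GeneticMap, GeneticMapMarker
from .records import BWindow, GeneModel, OutgroupStatus, VariantSite
from .stage1 import build_candidate_regions, filter_length, restrict_chromosomes
from . import tracks_io

__all__ = ["SimulationParams", "SimulatedTracks", "XABundle",
           "simulate_tracks", "simulate_variants", "simulate_outgroup",
           "write_vcf", "make_xa_bundle"]

_DEFAULT_GENOME = {"chrA1": 3_500_000, "chrA2": 3_500_000, "chrX": 3_000_000}
_DEFAULT_MAP_RATES = {"chrA1": [0.5, 1.5], "chrA2": [1.0, 2.0], "chrX": [1.2, 0.8]}
_DEFAULT_B_PROFILE = {"chrA1": [0.7, 0.9], "chrA2": [0.8, 1.0], "chrX": [0.6, 0.9]}


@dataclasses.dataclass
class SimulationParams:
    """Study conditions for a synthetic dataset.

    Defaults mirror a desk-scale human-like setting: ~7 Mb of autosome and
    3 Mb of X, 5 genes and 20 repeats per Mb, per-base diversity
    ``theta = 1e-3`` on autosomes and ``3/4`` of that on X, ``n = 40``
    sampled chromosomes, and 1% raw outgroup divergence.
    """

    genome: dict[str, int] = dataclasses.field(
        default_factory=lambda: dict(_DEFAULT_GENOME))
    x_chrom: str = "chrX"
    gene_density_per_mb: float = 5.0
    gene_length_bp: tuple[int, int] = (1_000, 3_000)
    repeat_density_per_mb: float = 20.0
    repeat_length_bp: tuple[int, int] = (100, 500)
    map_stride_bp: int = 10_000
    map_rates: dict[str, list[float]] = dataclasses.field(
        default_factory=lambda: {c: list(r) for c, r in _DEFAULT_MAP_RATES.items()})
    b_window_bp: int = 50_000
    b_profile: dict[str, list[float]] = dataclasses.field(
        default_factory=lambda: {c: list(b) for c, b in _DEFAULT_B_PROFILE.items()})
    theta_autosome: float = 1e-3
    theta_x: float = 7.5e-4
    n_chromosomes: int = 40
    d: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for label, value in (("theta_autosome", self.theta_autosome),
                             ("theta_x", self.theta_x), ("d", self.d)):
            if not (0.0 < value <= 0.1):
                raise ValueError(f"{label}={value} outside (0, 0.1]")
        if self.n_chromosomes < 2:
            raise ValueError("n_chromosomes must be >= 2")
        if self.seed is None:
            raise ValueError("seed must be set")


@dataclasses.dataclass
class SimulatedTracks:
    genome: GenomeAssembly
    genes: list[GeneModel]
    gene_track: IntervalTrack
    repeat_track: IntervalTrack
    gmap: GeneticMap
    map_markers: list[GeneticMapMarker]
    b_windows: list[BWindow]


def _place_features(rng: np.random.Generator, size: int, count: int,
                    length_range: tuple[int, int], chrom: str) -> list[tuple[int, int]]:
    """Place ``count`` non-overlapping features of random length; error out
    when the chromosome saturates before they all fit."""
    lo, hi = length_range
    placed: list[tuple[int, int]] = []
    attempts = 0
    max_attempts = max(1000, count * 200)
    while len(placed) < count:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"{chrom}: cannot place {count} features of {lo}-{hi} bp in "
                f"{size} bp; density saturates the chromosome")
        length = int(rng.integers(lo, hi + 1))
        if length >= size:
            raise ValueError(f"{chrom}: feature length {length} exceeds chromosome size {size}")
        start = int(rng.integers(0, size - length))
        end = start + length
        if any(s < end and start < e for s, e in placed):
            continue
        placed.append((start, end))
    placed.sort()
    return placed


def simulate_tracks(params: SimulationParams,
                    rng: Optional[np.random.Generator] = None) -> SimulatedTracks:
    """Genome, gene/repeat tracks, genetic map and B windows.

    Map markers sit every ``map_stride_bp`` with piecewise-constant rates
    (the chromosome is split into ``len(rates)`` equal segments) and an
    exactly consistent cumulative column; B windows tile each chromosome,
    cycling the per-chromosome profile.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    genome = GenomeAssembly(params.genome)
    genes: list[GeneModel] = []
    repeats: list[GenomicInterval] = []
    markers: list[GeneticMapMarker] = []
    b_windows: list[BWindow] = []
    for chrom, size in genome.items():
        n_genes = int(round(params.gene_density_per_mb * size / 1e6))
        for k, (s, e) in enumerate(_place_features(
                rng, size, n_genes, params.gene_length_bp, chrom)):
            genes.append(GeneModel(GenomicInterval(chrom, s, e), f"{chrom}_gene{k}"))
        n_rep = int(round(params.repeat_density_per_mb * size / 1e6))
        repeats.extend(GenomicInterval(chrom, s, e) for s, e in _place_features(
            rng, size, n_rep, params.repeat_length_bp, chrom))

        rates = params.map_rates.get(chrom, [1.0])
        seg_len = size / len(rates)
        cum = 0.0
        pos = 0
        while pos <= size:
            seg = min(int(pos // seg_len), len(rates) - 1)
            rate = float(rates[seg])
            markers.append(GeneticMapMarker(chrom, pos, rate, cum))
            step = min(params.map_stride_bp, size - pos)
            if step == 0:
                break
            cum += rate * step / 1e6
            pos += step

        profile = params.b_profile.get(chrom, [0.8])
        w = 0
        start = 0
        while start < size:
            end = min(start + params.b_window_bp, size)
            b_windows.append(BWindow(GenomicInterval(chrom, start, end),
                                     float(profile[w % len(profile)])))
            w += 1
            start = end

    gene_track = merge_intervals((g.interval for g in genes), name="genes", role="genes")
    repeat_track = merge_intervals(repeats, name="repeats", role="hard")
    return SimulatedTracks(genome=genome, genes=genes, gene_track=gene_track,
                           repeat_track=repeat_track,
                           gmap=GeneticMap(markers), map_markers=markers,
                           b_windows=b_windows)


def _region_offsets(regions: IntervalTrack):
    ivs = list(regions.intervals())
    lengths = np.array([iv.length for iv in ivs], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(lengths)])
    return ivs, cum


def _offsets_to_positions(offsets: np.ndarray, ivs, cum):
    idx = np.searchsorted(cum, offsets, side="right") - 1
    out = []
    for off, i in zip(offsets, idx):
        iv = ivs[int(i)]
        out.append((iv.chrom, iv.start + int(off - cum[int(i)])))
    return out


def simulate_variants(params: SimulationParams, regions: IntervalTrack,
                      theta: Optional[float] = None,
                      rng: Optional[np.random.Generator] = None,
                      ) -> list[VariantSite]:
    """Neutral-spectrum polymorphic sites over the bases of ``regions``.

    ``theta`` defaults to ``theta_x`` when every region chromosome is the X,
    else ``theta_autosome``.  All sites carry ``an = n_chromosomes``.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if theta is None:
        chroms = set(regions.chromosomes)
        theta = params.theta_x if chroms and chroms <= {params.x_chrom} \
            else params.theta_autosome
    ivs, cum = _region_offsets(regions)
    total_bp = int(cum[-1])
    if total_bp == 0:
        return []
    n = params.n_chromosomes
    counts = rng.poisson([theta * total_bp / i for i in range(1, n)])
    n_sites = int(counts.sum())
    if n_sites > total_bp:
        raise ValueError("theta too high: more segregating sites than bases")
    offsets = rng.choice(total_bp, size=n_sites, replace=False, shuffle=False)
    acs = np.repeat(np.arange(1, n), counts)
    sites = [VariantSite(chrom, pos, int(ac), n)
             for (chrom, pos), ac in zip(_offsets_to_positions(offsets, ivs, cum), acs)]
    sites.sort(key=lambda s: (s.chrom, s.pos0))
    return sites


def simulate_outgroup(params: SimulationParams, regions: IntervalTrack,
                      rng: Optional[np.random.Generator] = None) -> OutgroupStatus:
    """Outgroup status over ``regions``: every base aligned, each base
    mismatched independently with probability ``d``."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    ivs, cum = _region_offsets(regions)
    total_bp = int(cum[-1])
    k = int(rng.binomial(total_bp, params.d)) if total_bp else 0
    offsets = rng.choice(total_bp, size=k, replace=False, shuffle=False) if k else \
        np.empty(0, dtype=np.int64)
    mism = merge_intervals(
        (GenomicInterval(chrom, pos, pos + 1)
         for chrom, pos in _offsets_to_positions(np.sort(offsets), ivs, cum)),
        name="outgroup_mismatch")
    aligned = IntervalTrack(name="outgroup_aligned",
                            data={c: a.copy() for c, a in regions.data.items()})
    return OutgroupStatus(aligned, mism)


def write_vcf(sites: list[VariantSite], genome: GenomeAssembly, path) -> None:
    """Sites-only VCF 4.2 with INFO AC/AN (no genotype matrix)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AC,Number=A,Type=Integer,Description="Alternate allele count">\n')
        fh.write('##INFO=<ID=AN,Number=1,Type=Integer,Description="Total called alleles">\n')
        for chrom, size in genome.items():
            fh.write(f"##contig=<ID={chrom},length={size}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sorted(sites, key=lambda s: (s.chrom, s.pos0)):
            fh.write(f"{s.chrom}\t{s.pos0 + 1}\t.\tA\tC\t.\tPASS\tAC={s.ac};AN={s.an}\n")


@dataclasses.dataclass
class XABundle:
    """A complete fixture set for the X-vs-autosome analysis, with ground
    truth recorded in the manifest."""

    params: SimulationParams
    tracks: SimulatedTracks
    candidates_auto: IntervalTrack
    candidates_x: IntervalTrack
    sites: list[VariantSite]
    outgroup: OutgroupStatus
    paths: Optional[dict[str, Path]] = None


def make_xa_bundle(theta_a: float = 1e-3, theta_x: float = 7.5e-4,
                   d: float = 0.01, seed: int = 0, n: int = 40,
                   min_len: int = 1_000,
                   params: Optional[SimulationParams] = None,
                   outdir: Optional[str | Path] = None) -> XABundle:
    """Generate the full X-vs-autosome fixture bundle.

    Simulates tracks, carves candidate regions (complement of genes and
    repeats, length >= ``min_len``), lays neutral polymorphism over them at
    the class-specific theta, and adds outgroup divergence at rate ``d``.
    The default genome yields well over 5 Mb of autosomal and 2 Mb of X
    candidate sequence.  With ``outdir`` set, every input file the pipeline
    reads is written there (plain text), plus a ``manifest.tsv`` recording
    the ground-truth parameters.
    """
    if params is None:
        params = SimulationParams(theta_autosome=theta_a, theta_x=theta_x,
                                  d=d, n_chromosomes=n, seed=seed)
    rng = np.random.default_rng(params.seed)
    tracks = simulate_tracks(params, rng)
    candidates = build_candidate_regions(
        tracks.genome, [tracks.gene_track, tracks.repeat_track])
    candidates = filter_length(candidates, min_len=min_len)
    autos = [c for c in tracks.genome if c != params.x_chrom]
    cand_auto = restrict_chromosomes(candidates, autos)
    cand_x = restrict_chromosomes(candidates, [params.x_chrom])
    sites = (simulate_variants(params, cand_auto, params.theta_autosome, rng)
             + simulate_variants(params, cand_x, params.theta_x, rng))
    all_cand = merge_intervals(
        list(cand_auto.intervals()) + list(cand_x.intervals()), name="candidates")
    outgroup = simulate_outgroup(params, all_cand, rng)

    paths: Optional[dict[str, Path]] = None
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "chrom_sizes": out / "genome.chrom.sizes",
            "genes": out / "genes.bed",
            "repeats": out / "repeats.bed",
            "map": out / "genetic_map.txt",
            "b_track": out / "bwindows.bed",
            "vcf": out / "variants.vcf",
            "outgroup_aligned": out / "outgroup_aligned.bed",
            "outgroup_mismatch": out / "outgroup_mismatch.bed",
            "manifest": out / "manifest.tsv",
        }
        with open(paths["chrom_sizes"], "w") as fh:
            for chrom, size in tracks.genome.items():
                fh.write(f"{chrom}\t{size}\n")
        with open(paths["genes"], "w") as fh:
            for g in tracks.genes:
                iv = g.interval
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.name}\n")
        tracks_io.write_bed(tracks.repeat_track, paths["repeats"])
        with open(paths["map"], "w") as fh:
            fh.write("chrom\tposition\trate\tmap\n")
            for m in tracks.map_markers:
                fh.write(f"{m.chrom}\t{m.pos}\t{m.rate:.8g}\t{m.cum:.10g}\n")
        with open(paths["b_track"], "w") as fh:
            for w in tracks.b_windows:
                iv = w.interval
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{w.b:.6g}\n")
        write_vcf(sites, tracks.genome, paths["vcf"])
        tracks_io.write_bed(outgroup.aligned, paths["outgroup_aligned"])
        tracks_io.write_bed(outgroup.mismatch, paths["outgroup_mismatch"])
        manifest = {
            "theta_autosome": params.theta_autosome,
            "theta_x": params.theta_x,
            "d": params.d,
            "n_chromosomes": params.n_chromosomes,
            "seed": params.seed,
            "min_len": min_len,
            "x_chrom": params.x_chrom,
            "candidate_bp_autosome": cand_auto.total_bp,
            "candidate_bp_x": cand_x.total_bp,
            "n_sites": len(sites),
        }
        with open(paths["manifest"], "w") as fh:
            fh.write("key\tvalue\n")
            for k, v in manifest.items():
                fh.write(f"{k}\t{v}\n")

    return XABundle(params=params, tracks=tracks, candidates_auto=cand_auto,
                    candidates_x=cand_x, sites=sites, outgroup=outgroup,
                    paths=paths)
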