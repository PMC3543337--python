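"""Domain record types shared across the pipeline.

Undefined annotations are represented as ``None`` throughout; they serialize
as ``NA`` in tables, fail any threshold on that field, and sort last.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

from .intervals import GenomicInterval, IntervalTrack, IntervalError, subtract

__all__ = [
    "VariantSite",
    "BWindow",
    "GeneModel",
    "OutgroupStatus",
    "RegionRecord",
]


@dataclasses.dataclass(frozen=True)
class VariantSite:
    """A biallelic polymorphic site: alternate/derived count ``ac`` out of
    ``an`` successfully called chromosomes; ``pos0`` is 0-based."""

    chrom: str
    pos0: int
    ac: int
    an: int

    def __post_init__(self) -> None:
        if self.an < 2:
            raise ValueError(f"site {self.chrom}:{self.pos0}: an={self.an} < 2")
        if not (0 <= self.ac <= self.an):
            raise ValueError(f"site {self.chrom}:{self.pos0}: ac={self.ac} outside [0, {self.an}]")


@dataclasses.dataclass(frozen=True)
class BWindow:
    """A genomic window with its expected fraction of neutral diversity
    retained under background selection (B in [0, 1]; 1 = no reduction)."""

    interval: GenomicInterval
    b: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.b <= 1.0):
            raise ValueError(f"B value {self.b} outside [0, 1] at {self.interval}")


@dataclasses.dataclass(frozen=True)
class GeneModel:
    """A gene/transcript span used for distance-to-nearest-gene annotation."""

    interval: GenomicInterval
    name: str = ""


class OutgroupStatus:
    """Per-base human-vs-outgroup alignment status.

    Ingested as two normalized tracks: bases where the outgroup aligns at
    all, and the subset where it mismatches the reference.  Bases outside
    ``aligned`` are treated as unaligned and excluded from divergence.
    """

    def __init__(self, aligned: IntervalTrack, mismatch: IntervalTrack):
        stray = subtract(mismatch, aligned)
        if stray.total_bp:
            iv = next(stray.intervals())
            raise IntervalError(
                f"mismatch bases outside aligned bases (e.g. {iv}); mismatch must be a subset")
        self.aligned = aligned
        self.mismatch = mismatch

    def runs(self, chrom: str) -> list[tuple[GenomicInterval, str]]:
        """Run-length (interval, status) decomposition for one chromosome,
        status in {"match", "mismatch"} (unaligned bases are simply absent)."""
        match = subtract(self.aligned, self.mismatch)
        out = [(iv, "match") for iv in match.intervals() if iv.chrom == chrom]
        out += [(iv, "mismatch") for iv in self.mismatch.intervals() if iv.chrom == chrom]
        out.sort(key=lambda t: t[0].start)
        return out


@dataclasses.dataclass
class RegionRecord:
    """A candidate neutral locus and its annotations.

    Fields are ``None`` when the underlying resource is absent for the
    region (no gene on the chromosome, no overlapping B window, too few
    aligned outgroup bases, ...).
    """

    interval: GenomicInterval
    dist_gene_bp: Optional[int] = None
    dist_gene_cM: Optional[float] = None
    rec_rate: Optional[float] = None          # cM/Mb
    pi: Optional[float] = None                # per-bp pairwise diversity
    b_mean: Optional[float] = None            # fraction of neutral diversity retained
    soft_pct: dict[str, float] = dataclasses.field(default_factory=dict)
    div_raw: Optional[float] = None           # raw mismatch fraction p
    div_jc: Optional[float] = None            # Jukes-Cantor corrected D

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def chrom(self) -> str:
        return self.interval.chrom
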