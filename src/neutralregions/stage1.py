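"""Stage one of the two-step scheme: build the candidate space.

Hard-filter tracks are merged and subtracted outright from the whole
genome; the survivors are then restricted to requested chromosomes and to a
length window.  Everything here is deterministic set arithmetic.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence

from .intervals import (GenomeAssembly, GenomicInterval, IntervalTrack,
                        complement, merge_intervals)

__all__ = ["Stage1Config", "build_candidate_regions", "filter_length",
           "restrict_chromosomes"]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class Stage1Config:
    hard_track_names: list[str] = dataclasses.field(default_factory=list)
    chromosomes: Optional[list[str]] = None
    min_len: int = 1
    max_len: Optional[int] = None

    def __post_init__(self) -> None:
        if self.min_len < 1:
            raise ValueError(f"min_len must be >= 1, got {self.min_len}")
        if self.max_len is not None and self.min_len > self.max_len:
            raise ValueError(f"min_len {self.min_len} > max_len {self.max_len}")


def build_candidate_regions(genome: GenomeAssembly,
                            hard: Sequence[IntervalTrack],
                            name: str = "candidates") -> IntervalTrack:
    """Complement of the union of all hard filters over the assembly.

    No base covered by any hard track survives.  An empty hard list returns
    the whole genome (with a warning: no filtering happened).
    """
    if not hard:
        log.warning("no hard filters supplied; candidate space is the whole genome")
    union = merge_intervals(
        (iv for track in hard for iv in track.intervals()), name="hard_union", role="hard")
    return complement(genome, union, name=name)


def filter_length(track: IntervalTrack, min_len: int = 1,
                  max_len: Optional[int] = None) -> IntervalTrack:
    """Keep intervals with ``min_len <= length <= max_len`` (max unbounded
    when unset); removes the single-base to sub-threshold slivers left by
    overlapping filters."""
    if min_len < 1:
        raise ValueError(f"min_len must be >= 1, got {min_len}")
    kept = [iv for iv in track.intervals()
            if iv.length >= min_len and (max_len is None or iv.length <= max_len)]
    return merge_intervals(kept, name=track.name, role=track.role) if kept else \
        IntervalTrack(name=track.name, role=track.role)


def restrict_chromosomes(track: IntervalTrack, names: Sequence[str],
                         genome: Optional[GenomeAssembly] = None) -> IntervalTrack:
    """Keep only intervals on the named chromosomes."""
    if not names:
        raise ValueError("chromosome list must be non-empty")
    if genome is not None:
        for n in names:
            if n not in genome:
                log.warning("chromosome %r not present in the assembly", n)
    data = {c: arr.copy() for c, arr in track.data.items() if c in set(names)}
    return IntervalTrack(name=track.name, role=track.role, data=data)
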