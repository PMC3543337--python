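"""Genetic (recombination) maps: sorted markers with local rate and
cumulative genetic position, supporting linear interpolation.

A marker carries the recombination rate (cM/Mb) of the interval from its
position to the next marker, plus the cumulative map position (cM) at the
marker itself — the HapMap-style convention.  Positions outside the marker
span are extrapolated with the terminal interval's rate and floored at 0 cM.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable
from typing import Optional

import numpy as np

__all__ = ["GeneticMapMarker", "GeneticMap", "MapError"]

CM_PER_BP_FACTOR = 1e-6  # cM/Mb -> cM/bp


class MapError(ValueError):
    """Malformed genetic-map input."""


@dataclasses.dataclass(frozen=True)
class GeneticMapMarker:
    chrom: str
    pos: int          # bp
    rate: float       # cM/Mb, rate to the next marker
    cum: float        # cumulative cM at pos

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise MapError(f"negative rate {self.rate} at {self.chrom}:{self.pos}")
        if self.cum < 0:
            raise MapError(f"negative cumulative cM {self.cum} at {self.chrom}:{self.pos}")


class GeneticMap:
    """Per-chromosome sorted marker arrays with interpolation."""

    def __init__(self, markers: Iterable[GeneticMapMarker]):
        by_chrom: dict[str, list[GeneticMapMarker]] = {}
        for m in markers:
            by_chrom.setdefault(m.chrom, []).append(m)
        self._pos: dict[str, np.ndarray] = {}
        self._rate: dict[str, np.ndarray] = {}
        self._cum: dict[str, np.ndarray] = {}
        for chrom, ms in by_chrom.items():
            ms.sort(key=lambda m: m.pos)
            pos = np.array([m.pos for m in ms], dtype=np.int64)
            cum = np.array([m.cum for m in ms], dtype=float)
            rate = np.array([m.rate for m in ms], dtype=float)
            if np.any(np.diff(pos) <= 0):
                raise MapError(f"non-increasing marker positions on {chrom}")
            if np.any(np.diff(cum) < 0):
                raise MapError(f"decreasing cumulative cM on {chrom}")
            self._pos[chrom] = pos
            self._rate[chrom] = rate
            self._cum[chrom] = cum

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._pos)

    def n_markers(self, chrom: str) -> int:
        return len(self._pos.get(chrom, ()))

    def markers(self, chrom: str) -> list[GeneticMapMarker]:
        return [GeneticMapMarker(chrom, int(p), float(r), float(c))
                for p, r, c in zip(self._pos[chrom], self._rate[chrom], self._cum[chrom])]

    def cum_at(self, chrom: str, pos: int) -> Optional[float]:
        """Cumulative genetic position (cM) at ``pos`` by linear interpolation.

        Outside the marker span the terminal interval's rate extrapolates,
        floored at 0 cM.  ``None`` if the chromosome has fewer than 2 markers.
        """
        if self.n_markers(chrom) < 2:
            return None
        p, r, c = self._pos[chrom], self._rate[chrom], self._cum[chrom]
        if pos <= p[0]:
            return max(0.0, float(c[0] - (p[0] - pos) * r[0] * CM_PER_BP_FACTOR))
        if pos >= p[-1]:
            return float(c[-1] + (pos - p[-1]) * r[-1] * CM_PER_BP_FACTOR)
        return float(np.interp(pos, p, c))

    def scale_chromosome(self, chrom: str, factor: float) -> None:
        """Multiply every rate and cumulative value on ``chrom`` in place
        (used for the 2/3 sex-averaging correction on X)."""
        if chrom in self._pos:
            self._rate[chrom] = self._rate[chrom] * factor
            self._cum[chrom] = self._cum[chrom] * factor
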