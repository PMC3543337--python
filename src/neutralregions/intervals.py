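"""Exact genomic interval-set arithmetic.

All coordinates are BED-convention 0-based half-open ``[start, end)`` on a
named chromosome; a single convention is used everywhere internally so that
no off-by-one conversion survives past the file readers.  Interval sets are
kept *normalized*: per chromosome sorted by start, non-overlapping, with
adjacent (book-ended) intervals merged — the semantics of ``bedtools merge``.

The operations here (merge, subtract, intersect, complement, overlap
counting, gap distance) are the foundation of every hard/soft genomic
filter; they are exact integer arithmetic, never approximate.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Iterator, Mapping
from typing import Optional

import numpy as np

__all__ = [
    "IntervalError",
    "GenomicInterval",
    "GenomeAssembly",
    "IntervalTrack",
    "merge_intervals",
    "subtract",
    "intersect",
    "complement",
    "overlap_bp",
    "gap_bp",
]


class IntervalError(ValueError):
    """Malformed interval or interval-set input."""


@dataclasses.dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open span ``[start, end)`` on chromosome ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise IntervalError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise IntervalError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
                " (need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


class GenomeAssembly(Mapping):
    """Chromosome name -> length (bp); the bounds for complement operations."""

    def __init__(self, sizes: Mapping[str, int]):
        clean: dict[str, int] = {}
        for name, length in sizes.items():
            if not name:
                raise IntervalError("chromosome name must be non-empty")
            length = int(length)
            if length <= 0:
                raise IntervalError(f"chromosome {name!r} has non-positive length {length}")
            if name in clean:
                raise IntervalError(f"duplicate chromosome name {name!r}")
            clean[name] = length
        self._sizes = clean

    def __getitem__(self, name: str) -> int:
        return self._sizes[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    @property
    def total_bp(self) -> int:
        return sum(self._sizes.values())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GenomeAssembly({self._sizes!r})"


def _as_array(pairs: list[tuple[int, int]]) -> np.ndarray:
    if not pairs:
        return np.empty((0, 2), dtype=np.int64)
    return np.asarray(pairs, dtype=np.int64).reshape(-1, 2)


class IntervalTrack:
    """A named, normalized set of genomic intervals.

    ``data`` maps chromosome name to an ``(N, 2)`` int64 array of
    ``[start, end)`` rows, sorted, disjoint and non-adjacent.  Construct via
    :func:`merge_intervals` (or :meth:`from_intervals`) unless the data is
    already normalized.
    """

    ROLES = frozenset({"hard", "soft", "genes", "b", "user"})

    def __init__(self, name: str = "", role: str = "user",
                 data: Optional[Mapping[str, np.ndarray]] = None):
        if role not in self.ROLES:
            raise IntervalError(f"unknown track role {role!r}")
        self.name = name
        self.role = role
        self.data: dict[str, np.ndarray] = {}
        if data:
            for chrom, arr in data.items():
                arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
                if arr.shape[0]:
                    self.data[chrom] = arr

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval],
                       name: str = "", role: str = "user") -> "IntervalTrack":
        return merge_intervals(intervals, name=name, role=role)

    # -- inspection ------------------------------------------------------

    def intervals(self) -> Iterator[GenomicInterval]:
        for chrom in sorted(self.data):
            for start, end in self.data[chrom]:
                yield GenomicInterval(chrom, int(start), int(end))

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.data)

    @property
    def n_intervals(self) -> int:
        return sum(arr.shape[0] for arr in self.data.values())

    @property
    def total_bp(self) -> int:
        return int(sum((arr[:, 1] - arr[:, 0]).sum() for arr in self.data.values()))

    def __len__(self) -> int:
        return self.n_intervals

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalTrack):
            return NotImplemented
        if set(self.data) != set(other.data):
            return False
        return all(np.array_equal(self.data[c], other.data[c]) for c in self.data)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"IntervalTrack(name={self.name!r}, role={self.role!r}, "
                f"n={self.n_intervals}, bp={self.total_bp})")

    def _chrom(self, chrom: str) -> np.ndarray:
        return self.data.get(chrom, np.empty((0, 2), dtype=np.int64))


def merge_intervals(intervals: Iterable[GenomicInterval | tuple],
                    name: str = "", role: str = "user") -> IntervalTrack:
    """Normalize a collection of intervals into a merged track.

    Overlapping and adjacent (touching) intervals on the same chromosome are
    coalesced; the union of covered bases is preserved exactly.  Raises
    :class:`IntervalError` naming the offending record for malformed input.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for i, iv in enumerate(intervals):
        if not isinstance(iv, GenomicInterval):
            try:
                iv = GenomicInterval(str(iv[0]), int(iv[1]), int(iv[2]))
            except (TypeError, IndexError, ValueError) as exc:
                raise IntervalError(f"malformed interval record #{i}: {iv!r} ({exc})") from None
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))

    data: dict[str, np.ndarray] = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        merged: list[tuple[int, int]] = []
        cur_s, cur_e = pairs[0]
        for s, e in pairs[1:]:
            if s <= cur_e:  # overlap or adjacency
                cur_e = max(cur_e, e)
            else:
                merged.append((cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((cur_s, cur_e))
        data[chrom] = _as_array(merged)
    return IntervalTrack(name=name, role=role, data=data)


def subtract(a: IntervalTrack, b: IntervalTrack,
             name: str = "", role: str = "user") -> IntervalTrack:
    """Bases covered by ``a`` and not by ``b``; both tracks normalized."""
    if not name:
        name = a.name
    data: dict[str, np.ndarray] = {}
    for chrom, arr_a in a.data.items():
        arr_b = b._chrom(chrom)
        if not arr_b.shape[0]:
            data[chrom] = arr_a.copy()
            continue
        out: list[tuple[int, int]] = []
        b_starts, b_ends = arr_b[:, 0], arr_b[:, 1]
        for s, e in arr_a:
            # b intervals overlapping [s, e)
            lo = int(np.searchsorted(b_ends, s, side="right"))
            hi = int(np.searchsorted(b_starts, e, side="left"))
            cur = int(s)
            for bs, be in arr_b[lo:hi]:
                if bs > cur:
                    out.append((cur, int(bs)))
                cur = max(cur, int(be))
            if cur < e:
                out.append((cur, int(e)))
        if out:
            data[chrom] = _as_array(out)
    return IntervalTrack(name=name, role=role, data=data)


def intersect(a: IntervalTrack, b: IntervalTrack,
              name: str = "", role: str = "user") -> IntervalTrack:
    """Bases covered by both ``a`` and ``b``."""
    data: dict[str, np.ndarray] = {}
    for chrom, arr_a in a.data.items():
        arr_b = b._chrom(chrom)
        if not arr_b.shape[0]:
            continue
        out: list[tuple[int, int]] = []
        i = j = 0
        while i < arr_a.shape[0] and j < arr_b.shape[0]:
            s = max(arr_a[i, 0], arr_b[j, 0])
            e = min(arr_a[i, 1], arr_b[j, 1])
            if s < e:
                out.append((int(s), int(e)))
            if arr_a[i, 1] <= arr_b[j, 1]:
                i += 1
            else:
                j += 1
        if out:
            data[chrom] = _as_array(out)
    # abutting outputs can arise when inputs touch; renormalize
    return merge_intervals(
        (GenomicInterval(c, s, e) for c, arr in data.items() for s, e in arr),
        name=name, role=role)


def complement(genome: GenomeAssembly, t: IntervalTrack,
               name: str = "", role: str = "user") -> IntervalTrack:
    """Every base of ``genome`` not covered by ``t``.

    ``t`` must lie within chromosome bounds; chromosomes of ``t`` absent from
    the assembly are rejected.
    """
    data: dict[str, np.ndarray] = {}
    for chrom in t.data:
        if chrom not in genome:
            raise IntervalError(f"track chromosome {chrom!r} absent from assembly")
    for chrom, size in genome.items():
        arr = t._chrom(chrom)
        if arr.shape[0] and (arr[0, 0] < 0 or arr[-1, 1] > size):
            raise IntervalError(
                f"interval {chrom}:{arr[-1, 0]}-{arr[-1, 1]} beyond chromosome length {size}")
        out: list[tuple[int, int]] = []
        cur = 0
        for s, e in arr:
            if s > cur:
                out.append((cur, int(s)))
            cur = int(e)
        if cur < size:
            out.append((cur, size))
        if out:
            data[chrom] = _as_array(out)
    return IntervalTrack(name=name, role=role, data=data)


def overlap_bp(a: GenomicInterval, b: IntervalTrack) -> int:
    """Number of bases of ``a`` covered by normalized track ``b``."""
    arr = b._chrom(a.chrom)
    if not arr.shape[0]:
        return 0
    lo = int(np.searchsorted(arr[:, 1], a.start, side="right"))
    hi = int(np.searchsorted(arr[:, 0], a.end, side="left"))
    if lo >= hi:
        return 0
    starts = np.maximum(arr[lo:hi, 0], a.start)
    ends = np.minimum(arr[lo:hi, 1], a.end)
    return int((ends - starts).sum())


def gap_bp(a: GenomicInterval, b: GenomicInterval) -> Optional[int]:
    """Gap in bp between two intervals; 0 if they overlap or touch.

    Returns ``None`` for intervals on different chromosomes (infinitely
    separated for spacing purposes).
    """
    if a.chrom != b.chrom:
        return None
    if a.start <= b.start:
        earlier, later = a, b
    else:
        earlier, later = b, a
    return max(0, later.start - earlier.end)
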