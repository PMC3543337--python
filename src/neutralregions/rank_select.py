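"""Step two: threshold filtering, binned multi-parameter sorting, greedy
minimum-separation locus selection, and top-N extraction.

All operations are deterministic and act on lists of
:class:`~neutralregions.records.RegionRecord`, preserving order unless they
sort.  A record with an undefined (``None``) value fails any threshold on
that field and sorts last within its scope.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

from .maps import GeneticMap
from .records import RegionRecord

__all__ = ["ThresholdSpec", "RankSpec", "SpacingSpec", "apply_thresholds",
           "binned_multisort", "select_spaced", "take_top", "field_value"]

#: RegionRecord attributes addressable by thresholds and sort keys, plus
#: any soft-track name (its percent overlap).
_FIELDS = ("length", "dist_gene_bp", "dist_gene_cM", "rec_rate", "pi",
           "b_mean", "div_raw", "div_jc")


def field_value(record: RegionRecord, field: str):
    """Resolve a field name to its value; soft-track names map to their
    percent overlap.  Unknown names raise ``KeyError``."""
    if field in _FIELDS:
        return getattr(record, field)
    if field.startswith("pct_"):
        field = field[4:]
    if field in record.soft_pct:
        return record.soft_pct[field]
    raise KeyError(f"unknown region field {field!r} "
                   f"(known: {', '.join(_FIELDS)}, plus soft-track names)")


@dataclasses.dataclass
class ThresholdSpec:
    """Per-field optional [min, max] bounds (units of each field)."""

    bounds: dict[str, tuple[Optional[float], Optional[float]]] = \
        dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for field, (lo, hi) in self.bounds.items():
            if lo is not None and hi is not None and lo > hi:
                raise ValueError(f"field {field!r}: min {lo} > max {hi}")


@dataclasses.dataclass
class RankSpec:
    """Ordered sort keys (field, 'asc'|'desc') and the bin count that sets
    the granularity of secondary sorting."""

    keys: list[tuple[str, str]]
    n_bins: int = 1

    def __post_init__(self) -> None:
        if not self.keys:
            raise ValueError("at least one sort key required")
        names = [k for k, _ in self.keys]
        if len(set(names)) != len(names):
            raise ValueError("sort keys must be distinct")
        for _, direction in self.keys:
            if direction not in ("asc", "desc"):
                raise ValueError(f"sort direction must be 'asc' or 'desc', got {direction!r}")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")


@dataclasses.dataclass
class SpacingSpec:
    """Minimum separation between kept loci: bp (physical) or cM (genetic)."""

    mode: str = "physical"
    min_sep: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("physical", "genetic"):
            raise ValueError(f"mode must be 'physical' or 'genetic', got {self.mode!r}")
        if self.min_sep <= 0:
            raise ValueError("min_sep must be > 0")


def apply_thresholds(records: Sequence[RegionRecord],
                     spec: ThresholdSpec) -> list[RegionRecord]:
    """Keep records whose every constrained field is defined and within
    [min, max]; order preserved.  Unknown field names raise ``KeyError``."""
    if not spec.bounds:
        return list(records)
    out = []
    for rec in records:
        ok = True
        for field, (lo, hi) in spec.bounds.items():
            v = field_value(rec, field)
            if v is None or (lo is not None and v < lo) or (hi is not None and v > hi):
                ok = False
                break
        if ok:
            out.append(rec)
    return out


def _stable_sort(records: list[RegionRecord], field: str,
                 direction: str) -> list[RegionRecord]:
    defined = [r for r in records if field_value(r, field) is not None]
    missing = [r for r in records if field_value(r, field) is None]
    defined.sort(key=lambda r: field_value(r, field), reverse=(direction == "desc"))
    return defined + missing


def _bin_counts(n: int, n_bins: int) -> list[int]:
    base, extra = divmod(n, n_bins)
    return [base + (1 if i < extra else 0) for i in range(n_bins)]


def binned_multisort(records: Sequence[RegionRecord],
                     spec: RankSpec) -> list[RegionRecord]:
    """Multi-parameter ranking by sort-bin-sort recursion.

    Stable-sort on the first key, partition the ordered list into
    ``n_bins`` contiguous near-equal-count bins (the first ``N mod n_bins``
    bins take one extra record), stable-sort on the next key within each
    bin, re-binning recursively for further keys.  More bins mean finer
    subsequent sorting; with ``n_bins == len(records)`` later keys have no
    effect.  Undefined key values sort last within their scope.
    """
    def _recurse(chunk: list[RegionRecord], keys: list[tuple[str, str]]) -> list[RegionRecord]:
        if not keys or not chunk:
            return chunk
        field, direction = keys[0]
        ordered = _stable_sort(chunk, field, direction)
        if len(keys) == 1:
            return ordered
        out: list[RegionRecord] = []
        start = 0
        for count in _bin_counts(len(ordered), spec.n_bins):
            out.extend(_recurse(ordered[start:start + count], keys[1:]))
            start += count
        return out

    return _recurse(list(records), list(spec.keys))


def _separation(a: RegionRecord, b: RegionRecord, mode: str,
                gmap: Optional[GeneticMap]) -> Optional[float]:
    if a.chrom != b.chrom:
        return None  # infinitely separated
    if a.interval.start <= b.interval.start:
        earlier, later = a.interval, b.interval
    else:
        earlier, later = b.interval, a.interval
    gap = max(0, later.start - earlier.end)
    if mode == "physical":
        return float(gap)
    if gap == 0:
        return 0.0
    c1 = gmap.cum_at(a.chrom, earlier.end)
    c2 = gmap.cum_at(a.chrom, later.start)
    if c1 is None or c2 is None:
        raise ValueError(f"genetic map lacks chromosome {a.chrom!r} needed for genetic spacing")
    return abs(c2 - c1)


def select_spaced(records: Sequence[RegionRecord], spec: SpacingSpec,
                  gmap: Optional[GeneticMap] = None) -> list[RegionRecord]:
    """Greedy minimum-separation subset, largest loci first.

    Iterates loci from largest to smallest (ties: chromosome name, then
    start), keeping a locus only if its separation — bp gap, or cM between
    facing edges in genetic mode — from every already-kept locus on the
    same chromosome is at least ``min_sep`` (boundary inclusive).  The
    globally longest locus is always kept; loci alone on their chromosome
    are always kept.  A heuristic, not the (prohibitively complex) optimal
    independent set.  Applied as a last step after all other filters; the
    survivors come back in their incoming (e.g. ranked) order.
    """
    if spec.mode == "genetic" and gmap is None:
        raise ValueError("genetic spacing mode requires a genetic map")
    records = list(records)
    order = sorted(records,
                   key=lambda r: (-r.length, r.chrom, r.interval.start))
    kept_ids: set[int] = set()
    kept_by_chrom: dict[str, list[RegionRecord]] = {}
    for rec in order:
        ok = True
        for other in kept_by_chrom.get(rec.chrom, ()):
            sep = _separation(rec, other, spec.mode, gmap)
            if sep is not None and sep < spec.min_sep:
                ok = False
                break
        if ok:
            kept_ids.add(id(rec))
            kept_by_chrom.setdefault(rec.chrom, []).append(rec)
    return [r for r in records if id(r) in kept_ids]


def take_top(records: Sequence[RegionRecord], n: int) -> list[RegionRecord]:
    """First ``min(n, len(records))`` records in current order."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return list(records)[:n]
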