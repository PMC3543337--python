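"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library's own code paths: interval
arithmetic is checked against per-base boolean bitmaps, and nucleotide
diversity against literal enumeration of haplotype pairs.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from neutralregions import (GenomeAssembly, GenomicInterval, IntervalTrack,
                            merge_intervals)
from neutralregions.records import VariantSite


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_intervals(rng: np.random.Generator, chrom: str, size: int,
                     n: int, max_len: int = 500) -> list[GenomicInterval]:
    starts = rng.integers(0, size - 1, size=n)
    lengths = rng.integers(1, max_len + 1, size=n)
    return [GenomicInterval(chrom, int(s), int(min(s + l, size)))
            for s, l in zip(starts, lengths) if min(s + l, size) > s]


def random_track(rng: np.random.Generator, genome: GenomeAssembly,
                 n_per_chrom: int = 30, max_len: int = 500) -> IntervalTrack:
    ivs = []
    for chrom, size in genome.items():
        ivs.extend(random_intervals(rng, chrom, size, n_per_chrom, max_len))
    return merge_intervals(ivs)


def bitmap(track: IntervalTrack, genome: GenomeAssembly) -> dict[str, np.ndarray]:
    """Per-base boolean membership arrays — the brute-force ground truth."""
    maps = {chrom: np.zeros(size, dtype=bool) for chrom, size in genome.items()}
    for iv in track.intervals():
        maps[iv.chrom][iv.start:iv.end] = True
    return maps


def assert_track_equals_bitmap(track: IntervalTrack, expected: dict[str, np.ndarray]):
    got = {chrom: np.zeros_like(arr) for chrom, arr in expected.items()}
    for iv in track.intervals():
        assert iv.start < iv.end, "zero/negative-length interval emitted"
        got[iv.chrom][iv.start:iv.end] = True
    for chrom in expected:
        np.testing.assert_array_equal(got[chrom], expected[chrom],
                                      err_msg=f"coverage mismatch on {chrom}")
    # normalization: sorted, disjoint, non-adjacent
    for chrom, arr in track.data.items():
        if arr.shape[0] > 1:
            assert np.all(arr[1:, 0] > arr[:-1, 1]), f"{chrom}: intervals overlap or touch"


def pi_by_pair_enumeration(region: GenomicInterval,
                           sites: list[VariantSite]) -> float:
    """Average per-bp differences over all haplotype pairs, from an explicit
    haplotype matrix (requires a common ``an`` across sites)."""
    inside = [s for s in sites
              if s.chrom == region.chrom and region.start <= s.pos0 < region.end]
    if not inside:
        return 0.0
    an = inside[0].an
    assert all(s.an == an for s in inside), "enumeration oracle needs constant an"
    haplotypes = np.zeros((an, len(inside)), dtype=np.int8)
    for j, s in enumerate(inside):
        haplotypes[:s.ac, j] = 1  # which haplotypes carry it is irrelevant without linkage
    total = 0
    n_pairs = 0
    for i, j in itertools.combinations(range(an), 2):
        total += int(np.sum(haplotypes[i] != haplotypes[j]))
        n_pairs += 1
    return total / n_pairs / region.length
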