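"""Per-region statistics: gene distances, recombination, pi, B, soft
overlap, and Jukes-Cantor divergence."""

import math

import numpy as np
import pytest

from neutralregions import (AnnotationResources, GenomicInterval,
                            GeneticMap, GeneticMapMarker, annotate_all,
                            background_selection_mean, divergence,
                            interpolate_cum_cM, jukes_cantor, merge_intervals,
                            nearest_gene_distance, nucleotide_diversity,
                            recombination_rate, soft_overlap_pct)
from neutralregions.records import (BWindow, GeneModel, OutgroupStatus,
                                    VariantSite)

from conftest import pi_by_pair_enumeration


def constant_map(chrom="chr1", rate=1.0, span=10_000_000, stride=1_000_000):
    markers = []
    cum = 0.0
    for pos in range(0, span + 1, stride):
        markers.append(GeneticMapMarker(chrom, pos, rate, cum))
        cum += rate * stride / 1e6
    return GeneticMap(markers)


class TestNearestGene:
    GENES = [GeneModel(GenomicInterval("chr1", 1000, 2000), "g1")]

    def test_physical_distance_to_upstream_gene(self):
        bp, cm = nearest_gene_distance(GenomicInterval("chr1", 3000, 3500), self.GENES)
        assert bp == 1000 and cm is None

    def test_genetic_distance_on_constant_map(self):
        bp, cm = nearest_gene_distance(GenomicInterval("chr1", 3000, 3500),
                                       self.GENES, constant_map())
        assert bp == 1000
        assert cm == pytest.approx(0.001, rel=1e-9)

    def test_overlapping_gene_gives_zero(self):
        bp, cm = nearest_gene_distance(GenomicInterval("chr1", 1500, 2500),
                                       self.GENES, constant_map())
        assert bp == 0 and cm == pytest.approx(0.0, abs=1e-15)

    def test_no_gene_on_chromosome_is_undefined(self):
        assert nearest_gene_distance(GenomicInterval("chr2", 0, 100), self.GENES) == (None, None)

    def test_nearest_chosen_among_both_sides(self):
        genes = self.GENES + [GeneModel(GenomicInterval("chr1", 3600, 4000), "g2")]
        bp, _ = nearest_gene_distance(GenomicInterval("chr1", 3000, 3500), genes)
        assert bp == 100  # downstream gene closer than upstream


class TestInterpolation:
    def test_midpoint_linear(self):
        m = GeneticMap([GeneticMapMarker("chr1", 0, 1.0, 0.0),
                        GeneticMapMarker("chr1", 10_000, 1.0, 0.01)])
        assert interpolate_cum_cM(m, "chr1", 5_000) == pytest.approx(0.005)

    def test_at_marker_returns_marker_value(self):
        m = GeneticMap([GeneticMapMarker("chr1", 100, 2.0, 0.5),
                        GeneticMapMarker("chr1", 10_000, 2.0, 0.52)])
        assert interpolate_cum_cM(m, "chr1", 100) == pytest.approx(0.5)

    def test_monotonic_over_random_positions(self, rng):
        m = constant_map(rate=1.3)
        pos = np.sort(rng.integers(0, 12_000_000, size=1000))  # includes extrapolation
        vals = [interpolate_cum_cM(m, "chr1", int(p)) for p in pos]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_extrapolation_floored_at_zero(self):
        m = GeneticMap([GeneticMapMarker("chr1", 1000, 1.0, 0.0),
                        GeneticMapMarker("chr1", 2000, 1.0, 0.001)])
        assert interpolate_cum_cM(m, "chr1", 0) == 0.0
        assert interpolate_cum_cM(m, "chr1", 3000) == pytest.approx(0.002)

    def test_missing_chromosome_is_undefined(self):
        assert interpolate_cum_cM(constant_map(), "chr9", 100) is None


class TestRecombinationRate:
    def test_constant_map_returns_rate(self):
        assert recombination_rate(GenomicInterval("chr1", 123, 456_789),
                                  constant_map(rate=1.0)) == pytest.approx(1.0)

    def test_two_interval_weighted_mean(self):
        m = GeneticMap([GeneticMapMarker("chr1", 0, 1.0, 0.0),
                        GeneticMapMarker("chr1", 10_000, 3.0, 0.01),
                        GeneticMapMarker("chr1", 20_000, 3.0, 0.04)])
        # cum(5000)=0.005, cum(15000)=0.025 -> 0.02 cM over 0.01 Mb
        assert recombination_rate(GenomicInterval("chr1", 5_000, 15_000), m) == \
            pytest.approx(2.0)

    def test_small_region_approaches_local_rate(self):
        m = GeneticMap([GeneticMapMarker("chr1", 0, 1.0, 0.0),
                        GeneticMapMarker("chr1", 10_000, 3.0, 0.01),
                        GeneticMapMarker("chr1", 20_000, 3.0, 0.04)])
        assert recombination_rate(GenomicInterval("chr1", 12_000, 12_010), m) == \
            pytest.approx(3.0)

    def test_matches_per_bp_rate_sum_on_random_maps(self, rng):
        """Oracle: sum the local per-bp rate over every base of the region."""
        for _ in range(10):
            pos = np.sort(rng.choice(50_000, size=8, replace=False))
            rates = rng.uniform(0, 5, size=8)
            cum = np.concatenate([[0.0], np.cumsum(np.diff(pos) * rates[:-1] / 1e6)])
            m = GeneticMap([GeneticMapMarker("chr1", int(p), float(r), float(c))
                            for p, r, c in zip(pos, rates, cum)])
            s = int(rng.integers(pos[0], pos[-1] - 100))
            e = int(rng.integers(s + 10, pos[-1]))
            per_bp = np.zeros(pos[-1])
            for i in range(7):
                per_bp[pos[i]:pos[i + 1]] = rates[i] / 1e6
            expected = per_bp[s:e].sum() / ((e - s) / 1e6)
            assert recombination_rate(GenomicInterval("chr1", s, e), m) == \
                pytest.approx(expected, rel=1e-9)


class TestNucleotideDiversity:
    def test_single_site_worked_example(self):
        region = GenomicInterval("chr1", 0, 100)
        sites = [VariantSite("chr1", 10, 2, 4)]
        # all C(4,2)=6 haplotype pairs, 4 differ: (4/6)/100
        assert nucleotide_diversity(region, sites) == pytest.approx(4 / 6 / 100)
        assert nucleotide_diversity(region, sites) == \
            pytest.approx(pi_by_pair_enumeration(region, sites), abs=1e-15)

    def test_no_sites_gives_zero(self):
        assert nucleotide_diversity(GenomicInterval("chr1", 0, 100), []) == 0.0

    def test_two_singletons(self):
        region = GenomicInterval("chr1", 0, 100)
        sites = [VariantSite("chr1", 10, 1, 4), VariantSite("chr1", 20, 1, 4)]
        assert nucleotide_diversity(region, sites) == pytest.approx(0.01)

    def test_matches_pair_enumeration_on_random_fixtures(self, rng):
        for _ in range(100):
            an = int(rng.integers(2, 12))
            length = int(rng.integers(50, 500))
            region = GenomicInterval("chr1", 0, length)
            n_sites = int(rng.integers(0, 20))
            sites = [VariantSite("chr1", int(p), int(rng.integers(1, an)), an)
                     for p in rng.choice(length, size=min(n_sites, length), replace=False)]
            assert nucleotide_diversity(region, sites) == \
                pytest.approx(pi_by_pair_enumeration(region, sites), rel=1e-12, abs=1e-15)

    def test_sites_outside_region_ignored(self):
        region = GenomicInterval("chr1", 100, 200)
        sites = [VariantSite("chr1", 99, 2, 4), VariantSite("chr1", 200, 2, 4),
                 VariantSite("chr2", 150, 2, 4)]
        assert nucleotide_diversity(region, sites) == 0.0

    def test_accessibility_denominator_override(self):
        region = GenomicInterval("chr1", 0, 100)
        sites = [VariantSite("chr1", 10, 2, 4)]
        assert nucleotide_diversity(region, sites, denominator_bp=50) == \
            pytest.approx(4 / 6 / 50)


class TestBackgroundSelection:
    def test_weighted_mean_worked_example(self):
        region = GenomicInterval("chr1", 0, 1000)
        windows = [BWindow(GenomicInterval("chr1", 0, 600), 0.8),
                   BWindow(GenomicInterval("chr1", 600, 1000), 0.5)]
        assert background_selection_mean(region, windows) == pytest.approx(0.68)

    def test_single_covering_window(self):
        region = GenomicInterval("chr1", 100, 200)
        assert background_selection_mean(
            region, [BWindow(GenomicInterval("chr1", 0, 1000), 0.8)]) == pytest.approx(0.8)

    def test_no_overlap_is_undefined(self):
        region = GenomicInterval("chr1", 0, 100)
        assert background_selection_mean(
            region, [BWindow(GenomicInterval("chr2", 0, 100), 0.8)]) is None

    def test_partial_tiling_not_biased_toward_zero(self):
        region = GenomicInterval("chr1", 0, 1000)
        assert background_selection_mean(
            region, [BWindow(GenomicInterval("chr1", 0, 10), 0.9)]) == pytest.approx(0.9)

    def test_invariant_to_splitting_windows(self, rng):
        region = GenomicInterval("chr1", 250, 1750)
        whole = [BWindow(GenomicInterval("chr1", 0, 1000), 0.7),
                 BWindow(GenomicInterval("chr1", 1000, 2000), 0.9)]
        split = [BWindow(GenomicInterval("chr1", 0, 400), 0.7),
                 BWindow(GenomicInterval("chr1", 400, 1000), 0.7),
                 BWindow(GenomicInterval("chr1", 1000, 1300), 0.9),
                 BWindow(GenomicInterval("chr1", 1300, 2000), 0.9)]
        assert background_selection_mean(region, whole) == \
            pytest.approx(background_selection_mean(region, split), rel=1e-12)


class TestSoftOverlapAndDivergence:
    def test_soft_percentages(self):
        region = GenomicInterval("chr1", 0, 1000)
        track = merge_intervals([GenomicInterval("chr1", 100, 350)])
        assert soft_overlap_pct(region, track) == pytest.approx(25.0)
        assert soft_overlap_pct(GenomicInterval("chr2", 0, 10), track) == 0.0
        full = merge_intervals([GenomicInterval("chr1", 0, 2000)])
        assert soft_overlap_pct(region, full) == pytest.approx(100.0)

    def test_jc_identity_and_closed_form(self):
        assert jukes_cantor(0.0) == 0.0
        assert jukes_cantor(0.05) == pytest.approx(0.0517447, abs=1e-7)
        with pytest.raises(ValueError):
            jukes_cantor(0.75)

    def _outgroup(self, aligned, mismatch):
        return OutgroupStatus(merge_intervals(aligned),
                              merge_intervals(mismatch) if mismatch else
                              merge_intervals([]))

    def test_divergence_counts_only_aligned_bases(self):
        og = self._outgroup([GenomicInterval("chr1", 0, 500)],
                            [GenomicInterval("chr1", 0, 25)])
        p, d = divergence(GenomicInterval("chr1", 0, 1000), og)
        assert p == pytest.approx(0.05)
        assert d == pytest.approx(jukes_cantor(0.05))

    def test_too_few_aligned_bases_is_undefined(self):
        og = self._outgroup([GenomicInterval("chr1", 0, 50)], [])
        assert divergence(GenomicInterval("chr1", 0, 1000), og) == (None, None)

    def test_saturated_divergence_has_no_jc(self, caplog):
        og = self._outgroup([GenomicInterval("chr1", 0, 400)],
                            [GenomicInterval("chr1", 0, 300)])
        p, d = divergence(GenomicInterval("chr1", 0, 400), og)
        assert p == pytest.approx(0.75) and d is None

    def test_jc_monotone_and_convex(self):
        grid = np.linspace(0.0, 0.70, 141)
        vals = np.array([jukes_cantor(float(p)) for p in grid])
        assert np.all(np.diff(vals) > 0)
        assert np.all(np.diff(vals, 2) > -1e-12)
        assert np.all(vals[1:] >= grid[1:])  # correction never below raw p


class TestAnnotateAll:
    def _resources(self):
        return AnnotationResources(
            genes=[GeneModel(GenomicInterval("chr1", 1000, 2000), "g1")],
            gmap=constant_map(rate=1.0),
            sites=[VariantSite("chr1", 3010, 2, 4)],
            b_windows=[BWindow(GenomicInterval("chr1", 0, 3300), 0.8),
                       BWindow(GenomicInterval("chr1", 3300, 10_000), 0.5)],
            soft={"cons": merge_intervals([GenomicInterval("chr1", 3400, 3475)])},
            outgroup=OutgroupStatus(
                merge_intervals([GenomicInterval("chr1", 3000, 3500)]),
                merge_intervals([GenomicInterval("chr1", 3000, 3025)])))

    def test_empty_track_gives_empty_list(self):
        from neutralregions import IntervalTrack
        assert annotate_all(IntervalTrack(), self._resources()) == []

    def test_single_region_composition(self):
        track = merge_intervals([GenomicInterval("chr1", 3000, 3500)])
        (rec,) = annotate_all(track, self._resources())
        assert rec.dist_gene_bp == 1000
        assert rec.dist_gene_cM == pytest.approx(0.001, rel=1e-9)
        assert rec.rec_rate == pytest.approx(1.0)
        assert rec.pi == pytest.approx(4 / 6 / 500)
        assert rec.b_mean == pytest.approx((0.8 * 300 + 0.5 * 200) / 500)
        assert rec.soft_pct["cons"] == pytest.approx(15.0)
        assert rec.div_raw == pytest.approx(0.05)
        assert rec.div_jc == pytest.approx(0.0517447, abs=1e-7)

    def test_record_count_and_order_preserved(self, rng):
        from conftest import random_track
        from neutralregions import GenomeAssembly
        track = random_track(rng, GenomeAssembly({"chr1": 10_000}), n_per_chrom=40)
        records = annotate_all(track, self._resources())
        assert [r.interval for r in records] == list(track.intervals())
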