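import pytest

from karyocut import Genome, ScanConfig, revcomp
from karyocut.targets import (
    SpacerFamily,
    TargetSite,
    chromosome_specific_catalog,
    classify_distribution,
    group_spacers,
    scan_sites,
    small_region_subset,
)
from karyocut.genome_io import GenomicInterval
from conftest import random_genome
from oracles import oracle_group, oracle_scan


def as_tuples(sites):
    return [(s.chrom, s.start, s.strand, s.spacer, s.pam) for s in sites]


class TestScan:
    def test_forward_site(self):
        genome = Genome({"c": "A" * 20 + "TGG"})
        assert as_tuples(scan_sites(genome)) == [("c", 0, "+", "A" * 20, "TGG")]

    def test_reverse_site(self):
        genome = Genome({"c": "CCA" + "T" * 20})
        assert as_tuples(scan_sites(genome)) == [("c", 0, "-", "A" * 20, "TGG")]

    def test_chromosome_shorter_than_site_yields_nothing(self):
        assert scan_sites(Genome({"c": "ACGTTGG"})) == []

    def test_spacer_with_n_dropped_and_pam_n_rejects_gap(self):
        genome = Genome({"c": "A" * 19 + "N" + "TGG" + "A" * 20 + "NGG"})
        # first window has N in spacer; second has N at the PAM's N position
        assert all(("N" not in s.spacer and "N" not in s.pam) for s in scan_sites(genome))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_on_random_genomes(self, seed):
        genome = random_genome(seed, {"c1": 10_000, "c2": 3_000})
        assert as_tuples(scan_sites(genome)) == oracle_scan(genome.sequences)

    def test_strand_symmetry_under_reverse_complement(self):
        genome = random_genome(23, {"c": 5_000})
        flipped = Genome({"c": revcomp(genome["c"])})
        L = len(genome["c"])
        original = {(s.start, s.strand, s.spacer, s.pam) for s in scan_sites(genome)}
        reflected = {
            (L - s.end, "-" if s.strand == "+" else "+", s.spacer, s.pam)
            for s in scan_sites(flipped)
        }
        assert original == reflected


class TestGrouping:
    def _fam(self, spacer, positions):
        sites = [
            TargetSite(GenomicInterval(c, p, p + 23, "+"), spacer, "TGG")
            for c, p in positions
        ]
        return group_spacers(sites)

    def test_two_copies_one_chromosome_is_specific(self):
        (fam,) = self._fam("A" * 20, [("chrY", 100), ("chrY", 500)])
        assert fam.copy_number == 2
        assert fam.chromosome_specific
        assert fam.home_chromosome == "chrY"
        assert fam.span == 500 + 23 - 100

    def test_copies_on_two_chromosomes_not_specific(self):
        (fam,) = self._fam("A" * 20, [("chrY", 100), ("chr1", 200)])
        assert not fam.chromosome_specific
        assert fam.home_chromosome is None and fam.span is None

    def test_copy_numbers_sum_to_site_count(self):
        genome = random_genome(31, {"c1": 8_000, "c2": 4_000})
        sites = scan_sites(genome)
        families = group_spacers(sites)
        assert sum(f.copy_number for f in families) == len(sites)

    def test_agreement_with_bruteforce_grouping(self):
        genome = random_genome(37, {"c1": 6_000, "c2": 2_000})
        expected = oracle_group(oracle_scan(genome.sequences))
        got = {
            f.spacer: [(s.chrom, s.start, s.strand) for s in f.occurrences]
            for f in group_spacers(scan_sites(genome))
        }
        assert got == expected


class TestDistribution:
    def _family(self, starts, chrom="chrY"):
        sites = [
            TargetSite(GenomicInterval(chrom, p, p + 23, "+"), "A" * 20, "TGG")
            for p in starts
        ]
        return SpacerFamily("A" * 20, sites)

    def test_tight_cluster_on_large_chromosome(self):
        fam = self._family(range(0, 500_000, 17_000))  # ~0.5 Mb footprint
        assert classify_distribution(fam, 90_000_000) == "clustered"

    def test_wide_footprint_is_scattered(self):
        fam = self._family([0, 72_000_000])
        assert classify_distribution(fam, 90_000_000) == "scattered"

    def test_threshold_is_configurable(self):
        fam = self._family([0, 10_000 - 23])
        assert classify_distribution(fam, 100_000) == "clustered"
        tight = ScanConfig(max_span_fraction_clustered=0.05)
        assert classify_distribution(fam, 100_000, tight) == "scattered"

    def test_non_specific_family_is_an_error(self):
        sites = [
            TargetSite(GenomicInterval(c, 0, 23, "+"), "A" * 20, "TGG")
            for c in ("c1", "c2")
        ]
        with pytest.raises(ValueError):
            classify_distribution(SpacerFamily("A" * 20, sites), 1_000)

    def test_generator_truth_labels_recovered(self, demo_fixture):
        families = {
            f.spacer: f
            for f in chromosome_specific_catalog(demo_fixture.genome)
        }
        for row in demo_fixture.truth.families.itertuples():
            assert families[row.spacer].distribution == row.mode


class TestCatalog:
    def test_planted_families_and_nothing_else(self, demo_fixture):
        catalog = chromosome_specific_catalog(demo_fixture.genome)
        got = {(f.spacer, f.home_chromosome, f.copy_number) for f in catalog}
        want = {
            (row.spacer, row.chrom, row.copies)
            for row in demo_fixture.truth.families.itertuples()
        }
        assert got == want

    def test_min_copies_one_lists_single_copy_families(self):
        genome = random_genome(41, {"c": 3_000})
        catalog = chromosome_specific_catalog(genome, ScanConfig(min_copies=1))
        assert catalog and all(f.distribution == "single_copy" for f in catalog)

    def test_raising_min_copies_is_monotone(self, demo_fixture):
        sizes = [
            len(chromosome_specific_catalog(demo_fixture.genome, ScanConfig(min_copies=m)))
            for m in (1, 2, 3, 13)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_noncoding_only_requires_mask(self):
        genome = random_genome(43, {"c": 1_000})
        with pytest.raises(ValueError, match="noncoding"):
            chromosome_specific_catalog(genome, ScanConfig(noncoding_only=True))

    def test_small_region_subset_bounds_span(self, demo_fixture):
        catalog = chromosome_specific_catalog(demo_fixture.genome)
        subset = small_region_subset(catalog, 10_000)
        assert all(f.span <= 10_000 and f.distribution == "clustered" for f in subset)
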