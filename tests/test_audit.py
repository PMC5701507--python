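import numpy as np
import pandas as pd
import pytest

from karyocut import Genome, GenomicInterval, MaskSet
from karyocut.audit import (
    SVRecord,
    VariantRecord,
    apply_masks,
    check_ontarget_rearrangement,
    estimate_copy_number,
    filter_homopolymer_indels,
    intersect_offtarget_windows,
    read_vcf,
    run_cascade,
    subtract_germline,
    write_vcf,
)
from karyocut.simulate import make_depth_table


def snv(chrom, pos, ref="A", alt="T"):
    return VariantRecord(chrom, pos, ref, alt)


class TestGermline:
    def test_exact_match_removed(self):
        mutant = [snv("chr1", 100)]
        subtract_germline(mutant, [snv("chr1", 100)])
        assert mutant[0].fate == "removed_germline"

    def test_different_allele_kept(self):
        mutant = [snv("chr1", 100, "A", "T")]
        subtract_germline(mutant, [snv("chr1", 100, "A", "G")])
        assert mutant[0].fate == "kept"

    def test_set_intersection_count(self):
        rng = np.random.default_rng(2)
        mutant = [snv("c", int(p)) for p in rng.choice(1000, 20, replace=False)]
        shared = [VariantRecord(v.chrom, v.pos, v.ref, v.alt) for v in mutant[:7]]
        controls = shared + [snv("c", 2000 + i) for i in range(5)]
        subtract_germline(mutant, controls)
        assert sum(v.fate == "removed_germline" for v in mutant) == 7


class TestMasks:
    repeat = MaskSet("repeats", [GenomicInterval("c", 100, 200)])
    microsat = MaskSet("microsat", [GenomicInterval("c", 105, 200)])

    def test_deletion_footprint_reaches_mask(self):
        var = VariantRecord("c", 98, "A" * 10, "A")  # footprint [98, 108)
        apply_masks([var], MaskSet("r", [GenomicInterval("c", 105, 200)]), None)
        assert var.fate == "removed_repeat"

    def test_half_open_boundary_keeps_left_neighbor(self):
        var = snv("c", 99)
        apply_masks([var], self.repeat, None)
        assert var.fate == "kept"

    def test_repeat_takes_precedence_over_microsat(self):
        var = snv("c", 150)
        apply_masks([var], self.repeat, self.microsat)
        assert var.fate == "removed_repeat"

    def test_random_fates_match_bruteforce(self):
        rng = np.random.default_rng(9)
        intervals = []
        for _ in range(200):
            s = int(rng.integers(0, 5_000))
            intervals.append(GenomicInterval("c", s, s + int(rng.integers(1, 50))))
        mask = MaskSet("r", intervals)
        for _ in range(200):
            pos = int(rng.integers(0, 5_000))
            var = snv("c", pos)
            apply_masks([var], mask, None)
            brute = any(iv.start <= pos < iv.end for iv in intervals)
            assert (var.fate == "removed_repeat") == brute


class TestHomopolymer:
    genome = Genome({"c": "ACGT" * 25 + "AAAAA" + "CT" + "TC" + "ACGT" * 25})
    # run of 5 A at [100,105); TT run of 2 at [106,108)

    def test_mononucleotide_deletion_in_run_removed(self):
        var = VariantRecord("c", 99, "TAA", "T")
        filter_homopolymer_indels([var], self.genome)
        assert var.fate == "removed_homopolymer"

    def test_dinucleotide_deletion_kept(self):
        var = VariantRecord("c", 99, "TAG", "T")
        filter_homopolymer_indels([var], self.genome)
        assert var.fate == "kept"

    def test_insertion_into_short_run_kept(self):
        var = VariantRecord("c", 106, "T", "TT")  # run of 2 < 3
        filter_homopolymer_indels([var], self.genome)
        assert var.fate == "kept"

    def test_insertion_into_long_run_removed(self):
        var = VariantRecord("c", 101, "A", "AA")
        filter_homopolymer_indels([var], self.genome)
        assert var.fate == "removed_homopolymer"

    def test_snv_never_touched(self):
        var = snv("c", 102)
        filter_homopolymer_indels([var], self.genome)
        assert var.fate == "kept"


class TestWindows:
    sites = [GenomicInterval("c", 1_000, 1_023)]

    def test_indel_at_last_site_base_flagged(self):
        var = snv("c", 1_022)
        intersect_offtarget_windows([var], [], self.sites)
        assert var.offtarget_flag

    def test_variant_past_site_not_flagged(self):
        var = snv("c", 1_023)
        intersect_offtarget_windows([var], [], self.sites)
        assert not var.offtarget_flag

    @pytest.mark.parametrize(
        "pos,flagged", [(750, True), (749, False), (1_272, True), (1_273, False)]
    )
    def test_sv_flank_boundary_inclusive_at_250(self, pos, flagged):
        sv = SVRecord("c", pos, "c", 5_000, "DEL")
        intersect_offtarget_windows([], [sv], self.sites, sv_flank=250)
        assert sv.offtarget_flag is flagged

    def test_random_flags_match_bruteforce(self):
        rng = np.random.default_rng(13)
        sites = []
        for _ in range(50):
            s = int(rng.integers(500, 50_000))
            sites.append(GenomicInterval("c", s, s + 23))
        for _ in range(200):
            pos = int(rng.integers(0, 50_500))
            var = snv("c", pos)
            intersect_offtarget_windows([var], [], sites)
            brute = any(iv.start <= pos < iv.end for iv in sites)
            assert var.offtarget_flag == brute

    def test_ontarget_breakend_inside_site_flagged(self):
        tra = SVRecord("c1", 1_005, "c2", 9_000, "TRA")
        far = SVRecord("c1", 20_000, "c1", 30_000, "DEL")
        check_ontarget_rearrangement([tra, far], [GenomicInterval("c1", 1_000, 1_023)])
        assert tra.ontarget_flag and not far.ontarget_flag


class TestCascade:
    def test_empty_input_gives_zero_counts(self, toy):
        report = run_cascade([], [], toy.genome)
        assert report.variant_counts["input"] == 0
        assert report.variant_counts["kept"] == 0

    def test_toy_counts_and_fates_match_enumerated_truth(self, toy):
        report = run_cascade(
            toy.mutant, toy.controls, toy.genome,
            repeat_mask=toy.repeat_mask, microsat_mask=toy.microsat_mask,
            offtarget_sites=toy.offtarget_sites, ontarget_sites=toy.ontarget_sites,
            svs=toy.svs, control_svs=toy.control_svs,
        )
        assert report.variant_counts == toy.expected_variant_counts
        assert report.sv_counts == toy.expected_sv_counts
        assert [v.fate for v in report.variants] == toy.expected_variant_fates
        assert [v.offtarget_flag for v in report.variants] == toy.expected_variant_offtarget
        assert [s.fate for s in report.svs] == toy.expected_sv_fates
        assert [s.ontarget_flag for s in report.svs] == toy.expected_sv_ontarget

    def test_counts_monotone_and_fates_partition(self, toy):
        report = run_cascade(
            toy.mutant, toy.controls, toy.genome,
            repeat_mask=toy.repeat_mask, microsat_mask=toy.microsat_mask,
        )
        stages = ["input", "after_germline", "after_repeat",
                  "after_microsatellite", "after_homopolymer"]
        counts = [report.variant_counts[s] for s in stages]
        assert counts == sorted(counts, reverse=True)
        from collections import Counter
        fates = Counter(v.fate for v in report.variants)
        assert sum(fates.values()) == report.variant_counts["input"]
        assert fates["kept"] == report.variant_counts["kept"]

    def test_filters_idempotent(self, toy):
        variants = [
            VariantRecord(v.chrom, v.pos, v.ref, v.alt) for v in toy.mutant
        ]
        subtract_germline(variants, toy.controls)
        apply_masks(variants, toy.repeat_mask, toy.microsat_mask)
        filter_homopolymer_indels(variants, toy.genome)
        snapshot = [(v.fate, v.offtarget_flag) for v in variants]
        subtract_germline(variants, toy.controls)
        apply_masks(variants, toy.repeat_mask, toy.microsat_mask)
        filter_homopolymer_indels(variants, toy.genome)
        assert [(v.fate, v.offtarget_flag) for v in variants] == snapshot

    def test_unknown_reference_names_rejected(self, toy):
        bad = [snv("chrZ", 10)]
        with pytest.raises(ValueError, match="chrZ"):
            run_cascade(bad, [], toy.genome)

    def test_vcf_roundtrip_preserves_cascade_result(self, toy, tmp_path):
        lengths = toy.genome.lengths
        write_vcf(toy.mutant, lengths, tmp_path / "m.vcf")
        write_vcf(toy.controls, lengths, tmp_path / "c.vcf")
        report = run_cascade(
            read_vcf(tmp_path / "m.vcf"), read_vcf(tmp_path / "c.vcf"), toy.genome,
            repeat_mask=toy.repeat_mask, microsat_mask=toy.microsat_mask,
            offtarget_sites=toy.offtarget_sites, ontarget_sites=toy.ontarget_sites,
            svs=toy.svs, control_svs=toy.control_svs,
        )
        assert report.variant_counts == toy.expected_variant_counts
        assert report.sv_counts == toy.expected_sv_counts


class TestCopyNumber:
    def _table(self, depths):
        rows = [
            {"chrom": chrom, "start": i * 10_000, "depth": d}
            for chrom, values in depths.items()
            for i, d in enumerate(values)
        ]
        return pd.DataFrame(rows)

    def test_xo_closed_form(self):
        depth = self._table({"chr1": [30] * 4, "chr2": [30] * 4,
                             "chrX": [15] * 4, "chrY": [0] * 4})
        profile = estimate_copy_number(depth, ["chr1", "chr2"])
        assert profile.rounded == {"chr1": 2, "chr2": 2, "chrX": 1, "chrY": 0}
        assert profile.raw["chrX"] == pytest.approx(1.0)

    def test_uniform_depth_gives_all_twos(self):
        depth = self._table({c: [30] * 4 for c in ("chr1", "chr2", "chrX")})
        profile = estimate_copy_number(depth, ["chr1", "chr2"])
        assert set(profile.rounded.values()) == {2}

    def test_absent_chromosome_reported_as_zero(self):
        depth = self._table({"chr1": [30] * 4})
        profile = estimate_copy_number(depth, ["chr1"], chromosomes=["chr1", "chrY"])
        assert profile.rounded["chrY"] == 0

    def test_scale_invariance(self):
        depth = self._table({"chr1": [28, 31, 30], "chrX": [14, 16, 15]})
        base = estimate_copy_number(depth, ["chr1"])
        scaled_table = depth.assign(depth=depth["depth"] * 7)
        scaled = estimate_copy_number(scaled_table, ["chr1"])
        assert scaled.raw == base.raw

    def test_no_autosomal_depth_is_an_error(self):
        depth = self._table({"chrX": [10] * 3})
        with pytest.raises(ValueError, match="autosomal"):
            estimate_copy_number(depth, ["chr1"])

    def test_poisson_simulation_recovers_trisomy_and_xo(self):
        karyotype = {"chr1": 2, "chr2": 2, "chr21": 3, "chrX": 1, "chrY": 0}
        depth = make_depth_table(karyotype, seed=99, bins_per_chrom=500)
        profile = estimate_copy_number(depth, ["chr1", "chr2"])
        assert profile.rounded == karyotype
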