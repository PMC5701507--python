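import pytest

from karyocut import (
    chromosome_specific_catalog,
    count_cleavage_sites,
    find_offtargets,
    run_cascade,
    scan_sites,
    write_fasta,
)
from karyocut.simulate import (
    AuditConfig,
    Decoy,
    FixtureConfig,
    PlantedFamily,
    UniqueLocus,
    make_audit_fixture,
    make_genome,
)


def small_config(seed):
    return FixtureConfig(
        seed=seed,
        chromosomes=(("chrT", 60_000), ("chrB", 40_000)),
        families=(
            PlantedFamily("f1", "chrT", 10, "clustered", span=5_000),
            PlantedFamily("f2", "chrT", 6, "scattered"),
        ),
        unique_loci=(UniqueLocus("u1", "chrT", 30_000, 32_000, 2),),
        decoys=(Decoy("f1", 2, "chrB"),),
    )


class TestMakeGenome:
    def test_scanning_recovers_planted_family_exactly(self):
        config = FixtureConfig(
            seed=5,
            chromosomes=(("chrT", 100_000),),
            families=(PlantedFamily("f", "chrT", 12, "clustered", span=8_000),),
        )
        fixture = make_genome(config)
        catalog = chromosome_specific_catalog(fixture.genome)
        truth = fixture.truth.families.iloc[0]
        assert [(f.spacer, f.copy_number, f.home_chromosome) for f in catalog] == [
            (truth.spacer, 12, "chrT")
        ]

    def test_same_seed_is_byte_identical(self, tmp_path):
        outputs = []
        for run in ("a", "b"):
            fixture = make_genome(small_config(3))
            out = tmp_path / run
            fixture.write(out)
            outputs.append(
                tuple(sorted((p.name, p.read_bytes()) for p in out.iterdir()))
            )
        assert outputs[0] == outputs[1]

    def test_decoy_found_at_requested_distance(self):
        fixture = make_genome(small_config(8))
        spacer = fixture.truth.families.set_index("name").loc["f1", "spacer"]
        decoy = fixture.truth.decoys.iloc[0]
        hits = [h for h in find_offtargets(spacer, fixture.genome) if h.chrom == "chrB"]
        assert [(h.start, h.mismatch_count) for h in hits] == [(decoy.start, 2)]

    def test_unique_sites_are_genome_unique(self):
        fixture = make_genome(small_config(10))
        for row in fixture.truth.unique_sites.itertuples():
            assert count_cleavage_sites(row.spacer, fixture.genome) == 1

    def test_no_background_collisions_across_seed_sweep(self):
        for seed in range(10):
            fixture = make_genome(small_config(seed))
            planted = set(fixture.truth.families.spacer) | set(
                fixture.truth.unique_sites.spacer
            ) | set(fixture.truth.decoys.sequence)
            from karyocut import group_spacers

            for family in group_spacers(scan_sites(fixture.genome)):
                if family.copy_number >= 2:
                    assert family.spacer in planted

    def test_oversized_clustered_span_rejected_upfront(self):
        with pytest.raises(ValueError, match="span"):
            FixtureConfig(
                seed=1,
                chromosomes=(("c", 10_000),),
                families=(PlantedFamily("f", "c", 5, "clustered", span=5_000),),
            )


class TestAuditFixture:
    def test_cascade_reproduces_truth_fates(self):
        fixture = make_audit_fixture(AuditConfig(seed=21))
        report = run_cascade(
            fixture.mutant, fixture.controls, fixture.genome,
            repeat_mask=fixture.repeat_mask, microsat_mask=fixture.microsat_mask,
            offtarget_sites=fixture.offtarget_sites,
            ontarget_sites=fixture.ontarget_sites,
            svs=fixture.svs, control_svs=fixture.control_svs,
        )
        assert [v.fate for v in report.variants] == fixture.truth_variant_fates
        assert [v.offtarget_flag for v in report.variants] == fixture.truth_variant_offtarget
        assert [s.fate for s in report.svs] == fixture.truth_sv_fates
        assert [s.offtarget_flag for s in report.svs] == fixture.truth_sv_offtarget
        assert [s.ontarget_flag for s in report.svs] == fixture.truth_sv_ontarget

    def test_every_branch_covered_at_least_three_times(self):
        fixture = make_audit_fixture(AuditConfig(seed=22, per_branch=3))
        from collections import Counter

        fates = Counter(fixture.truth_variant_fates)
        for branch in ("removed_germline", "removed_repeat",
                       "removed_microsatellite", "removed_homopolymer", "kept"):
            assert fates[branch] >= 3

    def test_zero_variant_fixture_writes_schema_valid_vcf(self, tmp_path):
        from karyocut.audit import read_vcf, write_vcf

        write_vcf([], {"chrE": 1_000}, tmp_path / "empty.vcf")
        assert read_vcf(tmp_path / "empty.vcf") == []

    def test_files_roundtrip_through_standard_formats(self, tmp_path):
        from karyocut.audit import read_bedpe, read_depth_table, read_vcf
        from karyocut.genome_io import read_bed_mask, read_fasta

        fixture = make_audit_fixture(AuditConfig(seed=23))
        fixture.write(tmp_path)
        genome = read_fasta(tmp_path / "genome.fa")
        assert genome.sequences == fixture.genome.sequences
        assert len(read_vcf(tmp_path / "mutant.vcf")) == len(fixture.mutant)
        assert len(read_bedpe(tmp_path / "svs.bedpe")) == len(fixture.svs)
        mask = read_bed_mask(tmp_path / "repeats.bed", "repeats")
        assert mask.intervals == fixture.repeat_mask.intervals
        depth = read_depth_table(tmp_path / "depth.tsv")
        assert len(depth) == len(fixture.depth)
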