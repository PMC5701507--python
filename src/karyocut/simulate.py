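"""Synthetic genomes, call sets, and depth tables with known ground truth.

Every other module of this package is exercised on fixtures produced here:
random-background genomes carrying planted chromosome-specific repeat
families (clustered within a stated span, or scattered across the whole
chromosome), genome-unique single-copy sites grouped into loci, and
near-match decoys at an exact Hamming distance on another chromosome; plus
toy variant/SV call sets with pre-decided filter fates and Poisson depth
tables for arbitrary karyotypes.

The background base composition is uniform by default (configurable GC).
Emission is rejection-based: after planting, the genome is re-scanned and
re-drawn if the background accidentally duplicated a planted spacer or
produced a repeated family of its own, so the truth table is exact by
construction, not by luck.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .genome_io import Genome, GenomicInterval, MaskSet, revcomp, write_fasta
from .targets import ScanConfig, group_spacers, scan_sites
from .audit import (
    SVRecord,
    VariantRecord,
    write_bedpe,
    write_depth_table,
    write_vcf,
)

__all__ = [
    "PlantedFamily",
    "UniqueLocus",
    "Decoy",
    "FixtureConfig",
    "TruthTable",
    "GenomeFixture",
    "make_genome",
    "make_depth_table",
    "AuditConfig",
    "AuditFixture",
    "make_audit_fixture",
    "ToyAudit",
    "toy_audit",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
SITE_LEN = 23
SPACER_LEN = 20


@dataclass(frozen=True)
class PlantedFamily:
    """A repeat family to plant: ``copies`` identical sites on one chromosome.

    ``mode`` is "clustered" (all copies within ``span`` bp) or "scattered"
    (copies stratified across the whole chromosome, first and last copies
    pinned near the ends so the footprint always exceeds the clustered
    threshold).
    """

    name: str
    chrom: str
    copies: int
    mode: str  # clustered | scattered
    span: Optional[int] = None  # required for clustered

    def __post_init__(self) -> None:
        if self.mode not in ("clustered", "scattered"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.copies < 2:
            raise ValueError("a planted family needs >= 2 copies")
        if self.mode == "clustered" and not self.span:
            raise ValueError("clustered family requires a span")


@dataclass(frozen=True)
class UniqueLocus:
    """A region to seed with ``n_sites`` genome-unique single-copy sites."""

    name: str
    chrom: str
    start: int
    end: int
    n_sites: int = 2

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass(frozen=True)
class Decoy:
    """A near-match of a planted family's spacer on another chromosome."""

    family: str
    mismatches: int
    chrom: str

    def __post_init__(self) -> None:
        if self.mismatches < 1:
            raise ValueError("decoy mismatch count must be >= 1")


@dataclass(frozen=True)
class FixtureConfig:
    """Declarative description of a synthetic genome fixture."""

    seed: int
    chromosomes: Tuple[Tuple[str, int], ...]
    families: Tuple[PlantedFamily, ...] = ()
    unique_loci: Tuple[UniqueLocus, ...] = ()
    decoys: Tuple[Decoy, ...] = ()
    gc: float = 0.5

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        for fam in self.families:
            if fam.chrom not in lengths:
                raise ValueError(f"family {fam.name}: unknown chromosome {fam.chrom}")
            need = fam.span if fam.mode == "clustered" else fam.copies * 2 * SITE_LEN
            if need and need > lengths[fam.chrom]:
                raise ValueError(
                    f"chromosome {fam.chrom} too small for family {fam.name}"
                )
            if fam.mode == "clustered" and fam.span and fam.span > 0.10 * lengths[fam.chrom]:
                raise ValueError(
                    f"family {fam.name}: clustered span exceeds 10% of {fam.chrom}; "
                    "the truth label would not match the classifier"
                )
        for locus in self.unique_loci:
            if locus.chrom not in lengths or locus.end > lengths[locus.chrom]:
                raise ValueError(f"locus {locus.name}: outside chromosome bounds")
            if locus.end - locus.start < locus.n_sites * 100:
                raise ValueError(
                    f"locus {locus.name}: too small for {locus.n_sites} spaced sites"
                )
        fam_names = {f.name for f in self.families}
        for decoy in self.decoys:
            if decoy.family not in fam_names:
                raise ValueError(f"decoy references unknown family {decoy.family!r}")
            if decoy.chrom not in lengths:
                raise ValueError(f"decoy: unknown chromosome {decoy.chrom}")


@dataclass
class TruthTable:
    """Ground truth of a genome fixture, serializable to TSV."""

    families: pd.DataFrame   # name, spacer, chrom, mode, copies, positions, strands, span
    unique_sites: pd.DataFrame  # locus, chrom, start, strand, spacer
    decoys: pd.DataFrame     # family, chrom, start, strand, mismatches, sequence

    def write(self, outdir: Union[str, Path]) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.families.to_csv(outdir / "truth_families.tsv", sep="\t", index=False)
        self.unique_sites.to_csv(outdir / "truth_unique_sites.tsv", sep="\t", index=False)
        self.decoys.to_csv(outdir / "truth_decoys.tsv", sep="\t", index=False)


@dataclass
class GenomeFixture:
    genome: Genome
    truth: TruthTable
    config: FixtureConfig

    def write(self, outdir: Union[str, Path]) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fa")
        self.truth.write(outdir)


def _random_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


def _random_spacer(rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=SPACER_LEN))


def _random_family_spacer(rng: np.random.Generator) -> str:
    """A spacer without GG/CC dinucleotides.

    A planted multi-copy site must not spawn *shifted* windows whose spacer
    is shared across copies: a GG (or, on the other strand, CC) inside the
    spacer near its ends can serve as the PAM of such a window.  Excluding
    the dinucleotides altogether keeps every alternative window dependent
    on per-copy random flanking bases, so copies cannot collide.
    """
    for _ in range(10_000):
        spacer = _random_spacer(rng)
        if "GG" not in spacer and "CC" not in spacer:
            return spacer
    raise RuntimeError("unreachable: spacer rejection loop exhausted")


def _random_pam(rng: np.random.Generator) -> str:
    # first base non-G, so a window shifted 1 bp left cannot reuse the PAM
    return "ACT"[rng.integers(0, 3)] + "GG"


class _Placer:
    """Allocates non-overlapping planting positions on one chromosome."""

    def __init__(self, rng: np.random.Generator, length: int):
        self.rng = rng
        self.length = length
        self.occupied: List[Tuple[int, int]] = []

    def _free(self, start: int, margin: int = 5) -> bool:
        end = start + SITE_LEN
        return all(
            end + margin <= s or e + margin <= start for s, e in self.occupied
        )

    def place_in(self, lo: int, hi: int, tries: int = 200) -> int:
        """A free site start position within [lo, hi - SITE_LEN]."""
        hi_start = hi - SITE_LEN
        if hi_start < lo:
            raise ValueError("window too small for a site")
        for _ in range(tries):
            start = int(self.rng.integers(lo, hi_start + 1))
            if self._free(start):
                self.occupied.append((start, start + SITE_LEN))
                return start
        raise ValueError("could not place a site without overlap; region too crowded")


def _plant(
    chrom_arr: np.ndarray,
    start: int,
    site_seq: str,
    strand: str,
    rng: np.random.Generator,
) -> None:
    """Write a site into the chromosome, with collision-guard flanks.

    The two background bases on each side are redrawn per copy: non-C on
    the left and non-G on the right (in genome orientation, which covers
    both planting strands by reverse-complement symmetry).  This prevents
    any window shifted off the planted site from acquiring a valid NGG/CCN
    PAM out of deterministic planted content, so identical shifted spacers
    cannot recur across the copies of a family.
    """
    seq = site_seq if strand == "+" else revcomp(site_seq)
    chrom_arr[start : start + SITE_LEN] = np.frombuffer(
        seq.encode("ascii"), dtype=np.uint8
    )
    for i in (start - 2, start - 1):
        if i >= 0:
            chrom_arr[i] = ord("AGT"[rng.integers(0, 3)])
    for i in (start + SITE_LEN, start + SITE_LEN + 1):
        if i < chrom_arr.size:
            chrom_arr[i] = ord("ACT"[rng.integers(0, 3)])


def _family_positions(
    placer: _Placer, fam: PlantedFamily, chrom_len: int
) -> List[int]:
    if fam.mode == "clustered":
        assert fam.span is not None
        window_start = int(placer.rng.integers(0, chrom_len - fam.span + 1))
        return sorted(
            placer.place_in(window_start, window_start + fam.span)
            for _ in range(fam.copies)
        )
    # scattered: pin the first and last copies in the outer 5% so the
    # footprint is always > 10% of the chromosome, then stratify the rest
    edge = max(SITE_LEN, int(0.05 * chrom_len))
    positions = [
        placer.place_in(0, edge),
        placer.place_in(chrom_len - edge, chrom_len),
    ]
    middle = fam.copies - 2
    if middle > 0:
        seg = (chrom_len - 2 * edge) // middle
        for i in range(middle):
            lo = edge + i * seg
            positions.append(placer.place_in(lo, lo + seg))
    return sorted(positions)


def _mutate_spacer(rng: np.random.Generator, spacer: str, mismatches: int) -> str:
    idx = rng.choice(SPACER_LEN, size=mismatches, replace=False)
    out = list(spacer)
    for i in idx:
        alternatives = [b for b in "ACGT" if b != out[i]]
        out[i] = alternatives[rng.integers(0, 3)]
    return "".join(out)


def _verify(genome: Genome, config: FixtureConfig, truth: "TruthTable") -> bool:
    """Exhaustive emission-time scan: truth must equal what a screen finds."""
    families = group_spacers(scan_sites(genome), genome.lengths)
    by_spacer = {f.spacer: f for f in families}
    planted = set()
    for row in truth.families.itertuples():
        fam = by_spacer.get(row.spacer)
        if fam is None or fam.copy_number != row.copies:
            return False
        if not fam.chromosome_specific or fam.home_chromosome != row.chrom:
            return False
        if fam.distribution != row.mode:
            return False
        found = sorted(s.start for s in fam.occurrences)
        if found != sorted(int(p) for p in str(row.positions).split(",")):
            return False
        planted.add(row.spacer)
    for row in truth.unique_sites.itertuples():
        fam = by_spacer.get(row.spacer)
        if fam is None or fam.copy_number != 1:
            return False
        planted.add(row.spacer)
    for row in truth.decoys.itertuples():
        fam = by_spacer.get(row.sequence)
        if fam is None or fam.copy_number != 1:
            return False
        planted.add(row.sequence)
    # no accidental multi-copy background families
    for fam in families:
        if fam.copy_number >= 2 and fam.spacer not in planted:
            return False
    return True


def make_genome(config: FixtureConfig, max_attempts: int = 20) -> GenomeFixture:
    """Build a synthetic genome and its exact truth table.

    Deterministic for a given config (seed included); redraws the whole
    genome if the emission-time verification scan finds any discordance
    between the truth table and an actual screen of the emitted sequence.
    """
    rng = np.random.default_rng(config.seed)
    lengths = dict(config.chromosomes)
    for attempt in range(max_attempts):
        arrays = {
            name: _random_background(rng, length, config.gc)
            for name, length in config.chromosomes
        }
        placers = {name: _Placer(rng, length) for name, length in config.chromosomes}

        fam_rows = []
        fam_spacers: Dict[str, str] = {}
        for fam in config.families:
            spacer, pam = _random_family_spacer(rng), _random_pam(rng)
            fam_spacers[fam.name] = spacer
            positions = _family_positions(placers[fam.chrom], fam, lengths[fam.chrom])
            strands = ["+-"[rng.integers(0, 2)] for _ in positions]
            for pos, strand in zip(positions, strands):
                _plant(arrays[fam.chrom], pos, spacer + pam, strand, rng)
            fam_rows.append(
                {
                    "name": fam.name,
                    "spacer": spacer,
                    "chrom": fam.chrom,
                    "mode": fam.mode,
                    "copies": fam.copies,
                    "positions": ",".join(map(str, positions)),
                    "strands": ",".join(strands),
                    "span": max(positions) + SITE_LEN - min(positions),
                }
            )

        unique_rows = []
        for locus in config.unique_loci:
            placer = placers[locus.chrom]
            # stratify within the locus so chosen sites are >= ~100 bp apart
            seg = (locus.end - locus.start) // locus.n_sites
            for i in range(locus.n_sites):
                spacer, pam = _random_spacer(rng), _random_pam(rng)
                lo = locus.start + i * seg
                pos = placer.place_in(lo, lo + seg)
                strand = "+-"[rng.integers(0, 2)]
                _plant(arrays[locus.chrom], pos, spacer + pam, strand, rng)
                unique_rows.append(
                    {
                        "locus": locus.name,
                        "chrom": locus.chrom,
                        "start": pos,
                        "strand": strand,
                        "spacer": spacer,
                    }
                )

        decoy_rows = []
        for decoy in config.decoys:
            mutated = _mutate_spacer(rng, fam_spacers[decoy.family], decoy.mismatches)
            pos = placers[decoy.chrom].place_in(0, lengths[decoy.chrom])
            strand = "+-"[rng.integers(0, 2)]
            _plant(arrays[decoy.chrom], pos, mutated + _random_pam(rng), strand, rng)
            decoy_rows.append(
                {
                    "family": decoy.family,
                    "chrom": decoy.chrom,
                    "start": pos,
                    "strand": strand,
                    "mismatches": decoy.mismatches,
                    "sequence": mutated,
                }
            )

        genome = Genome(
            {name: arr.tobytes().decode("ascii") for name, arr in arrays.items()}
        )
        truth = TruthTable(
            pd.DataFrame(
                fam_rows,
                columns=[
                    "name", "spacer", "chrom", "mode", "copies",
                    "positions", "strands", "span",
                ],
            ),
            pd.DataFrame(
                unique_rows, columns=["locus", "chrom", "start", "strand", "spacer"]
            ),
            pd.DataFrame(
                decoy_rows,
                columns=["family", "chrom", "start", "strand", "mismatches", "sequence"],
            ),
        )
        if _verify(genome, config, truth):
            return GenomeFixture(genome, truth, config)
    raise RuntimeError(
        f"could not build a collision-free fixture in {max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# Depth tables
# ---------------------------------------------------------------------------

def make_depth_table(
    karyotype: Dict[str, float],
    seed: int,
    bins_per_chrom: int = 500,
    mean_depth: float = 30.0,
    bin_size: int = 10_000,
) -> pd.DataFrame:
    """Poisson-distributed binned depth for a requested karyotype.

    Each chromosome gets ``bins_per_chrom`` bins with depth drawn from
    Poisson(mean_depth * copy / 2); ``mean_depth`` is the diploid coverage
    (e.g. 30x sequencing), so copy 1 halves it and copy 0 yields zeros.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, copy in karyotype.items():
        lam = mean_depth * copy / 2.0
        depths = rng.poisson(lam, size=bins_per_chrom)
        for i, d in enumerate(depths):
            rows.append({"chrom": chrom, "start": i * bin_size, "depth": int(d)})
    return pd.DataFrame(rows, columns=["chrom", "start", "depth"])


# ---------------------------------------------------------------------------
# Audit fixtures (random, branch-covering)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AuditConfig:
    """Configuration of a randomized audit fixture.

    ``per_branch`` variants/SVs are generated for every cascade branch
    (germline, repeat, microsatellite, homopolymer, kept, off-target
    flagged, on-target flagged), so each filter fires at least that often.
    """

    seed: int
    chrom_length: int = 50_000
    per_branch: int = 3
    karyotype: Tuple[Tuple[str, float], ...] = (
        ("chr1", 2), ("chr2", 2), ("chrX", 1), ("chrY", 0),
    )
    autosomes: Tuple[str, ...] = ("chr1", "chr2")
    bins_per_chrom: int = 500
    mean_depth: float = 30.0


@dataclass
class AuditFixture:
    genome: Genome
    mutant: List[VariantRecord]
    controls: List[VariantRecord]
    svs: List[SVRecord]
    control_svs: List[SVRecord]
    repeat_mask: MaskSet
    microsat_mask: MaskSet
    offtarget_sites: List[GenomicInterval]
    ontarget_sites: List[GenomicInterval]
    depth: pd.DataFrame
    truth_variant_fates: List[str]
    truth_sv_fates: List[str]
    truth_variant_offtarget: List[bool]
    truth_sv_offtarget: List[bool]
    truth_sv_ontarget: List[bool]
    karyotype: Dict[str, float]
    autosomes: List[str]

    def write(self, outdir: Union[str, Path]) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        lengths = self.genome.lengths
        write_fasta(self.genome, outdir / "genome.fa")
        write_vcf(self.mutant, lengths, outdir / "mutant.vcf")
        write_vcf(self.controls, lengths, outdir / "control.vcf")
        write_bedpe(self.svs, outdir / "svs.bedpe")
        write_bedpe(self.control_svs, outdir / "control_svs.bedpe")
        _write_bed(self.repeat_mask.intervals, outdir / "repeats.bed")
        _write_bed(self.microsat_mask.intervals, outdir / "microsatellites.bed")
        _write_bed(self.offtarget_sites, outdir / "offtarget_sites.bed")
        _write_bed(self.ontarget_sites, outdir / "ontarget_sites.bed")
        write_depth_table(self.depth, outdir / "depth.tsv")


def _write_bed(intervals: Sequence[GenomicInterval], path: Union[str, Path]) -> None:
    with open(path, "w") as handle:
        for iv in intervals:
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def _alt_base(rng: np.random.Generator, ref: str) -> str:
    return [b for b in "ACGT" if b != ref][rng.integers(0, 3)]


def make_audit_fixture(config: AuditConfig) -> AuditFixture:
    """Build a randomized audit fixture with pre-decided fates.

    The genome is a random-background chromosome ("chrE", the edited
    chromosome's stand-in) with homopolymer runs planted where the
    homopolymer branch needs them.  Region layout (masks, off-/on-target
    sites, per-branch variant zones) is fixed; positions within zones and
    alleles are randomized from the seed.
    """
    rng = np.random.default_rng(config.seed)
    L = config.chrom_length
    if L < 46_000:
        raise ValueError("audit fixture chromosome must be >= 46 kb")
    arr = _random_background(rng, L, gc=0.5)
    n = config.per_branch

    # planted A-runs of length 6 for the homopolymer branch
    run_starts = [12_000 + 120 * i for i in range(2 * n)]
    for s in run_starts:
        arr[s : s + 6] = ord("A")
    # guard the run flanks so runs are exactly length 6
    for s in run_starts:
        if arr[s - 1] == ord("A"):
            arr[s - 1] = ord("C")
        if arr[s + 6] == ord("A"):
            arr[s + 6] = ord("C")
    genome = Genome({"chrE": arr.tobytes().decode("ascii")})
    seq = genome["chrE"]

    repeat_mask = MaskSet("repeats", [GenomicInterval("chrE", 5_000, 6_000)])
    microsat_mask = MaskSet("microsatellites", [GenomicInterval("chrE", 8_000, 8_500)])
    offtarget_sites = [
        GenomicInterval("chrE", 20_000 + 500 * i, 20_000 + 500 * i + SITE_LEN)
        for i in range(n)
    ]
    ontarget_sites = [
        GenomicInterval("chrE", 30_000 + 500 * i, 30_000 + 500 * i + SITE_LEN)
        for i in range(n)
    ]

    mutant: List[VariantRecord] = []
    controls: List[VariantRecord] = []
    fates: List[str] = []
    var_ot: List[bool] = []
    used: set = set()

    def fresh_pos(lo: int, hi: int) -> int:
        while True:
            p = int(rng.integers(lo, hi))
            if p not in used:
                used.add(p)
                return p

    def add_snv(lo: int, hi: int, fate: str, ot: bool = False, shared: bool = False):
        p = fresh_pos(lo, hi)
        ref = seq[p]
        alt = _alt_base(rng, ref)
        mutant.append(VariantRecord("chrE", p, ref, alt, sample="edited"))
        if shared:
            controls.append(VariantRecord("chrE", p, ref, alt, sample="wildtype"))
        fates.append(fate)
        var_ot.append(ot)

    for _ in range(n):
        add_snv(40_000, 42_000, "removed_germline", shared=True)
    for _ in range(n):
        add_snv(5_000, 6_000, "removed_repeat")
    for _ in range(n):
        add_snv(8_000, 8_500, "removed_microsatellite")
    for i in range(n):  # mono-nucleotide deletions inside planted runs
        s = run_starts[i]
        mutant.append(
            VariantRecord("chrE", s - 1, seq[s - 1] + "AA", seq[s - 1], sample="edited")
        )
        fates.append("removed_homopolymer")
        var_ot.append(False)
    for _ in range(n):
        add_snv(44_000, 46_000, "kept")
    for i in range(n):  # kept SNV inside an off-target site
        site = offtarget_sites[i]
        p = fresh_pos(site.start, site.end)
        ref = seq[p]
        mutant.append(VariantRecord("chrE", p, ref, _alt_base(rng, ref), sample="edited"))
        fates.append("kept")
        var_ot.append(True)
    # control-only variants that must not subtract anything
    for _ in range(n):
        p = fresh_pos(43_000, 44_000)
        ref = seq[p]
        controls.append(VariantRecord("chrE", p, ref, _alt_base(rng, ref), sample="wildtype"))

    svs: List[SVRecord] = []
    control_svs: List[SVRecord] = []
    sv_fates: List[str] = []
    sv_ot: List[bool] = []
    sv_on: List[bool] = []

    def add_sv(pos1: int, pos2: int, svtype: str, fate: str,
               ot: bool = False, on: bool = False, shared: bool = False):
        sv = SVRecord("chrE", pos1, "chrE", pos2, svtype, sample="edited")
        svs.append(sv)
        if shared:
            jitter = int(rng.integers(-10, 11))
            control_svs.append(
                SVRecord("chrE", pos1 + jitter, "chrE", pos2, svtype, sample="wildtype")
            )
        sv_fates.append(fate)
        sv_ot.append(ot)
        sv_on.append(on)

    for i in range(n):
        add_sv(40_000 + 50 * i, 41_000 + 50 * i, "DEL", "removed_germline", shared=True)
    for i in range(n):
        add_sv(5_100 + 50 * i, 44_000 + 50 * i, "DUP", "removed_repeat")
    for i in range(n):  # breakend inside the off-target flank window
        site = offtarget_sites[i]
        add_sv(site.start - 200, 45_000 + 40 * i, "INV", "kept", ot=True)
    for i in range(n):  # breakend inside an on-target site
        site = ontarget_sites[i]
        add_sv(int(site.start) + 5, 46_000 + 40 * i, "DEL", "kept", on=True)
    for i in range(n):
        add_sv(47_000 + 60 * i, 48_000 + 60 * i, "DEL", "kept")

    depth = make_depth_table(
        dict(config.karyotype),
        seed=config.seed + 1,
        bins_per_chrom=config.bins_per_chrom,
        mean_depth=config.mean_depth,
    )
    return AuditFixture(
        genome=genome,
        mutant=mutant,
        controls=controls,
        svs=svs,
        control_svs=control_svs,
        repeat_mask=repeat_mask,
        microsat_mask=microsat_mask,
        offtarget_sites=offtarget_sites,
        ontarget_sites=ontarget_sites,
        depth=depth,
        truth_variant_fates=fates,
        truth_sv_fates=sv_fates,
        truth_variant_offtarget=var_ot,
        truth_sv_offtarget=sv_ot,
        truth_sv_ontarget=sv_on,
        karyotype=dict(config.karyotype),
        autosomes=list(config.autosomes),
    )


# ---------------------------------------------------------------------------
# The hand-constructed toy audit fixture
# ---------------------------------------------------------------------------

@dataclass
class ToyAudit:
    """A small, fully enumerated audit fixture: 30 variants, 10 SVs.

    Every record's expected fate and flag were decided by hand when the
    fixture was constructed; the lists below are the truth table the
    cascade must reproduce exactly.
    """

    genome: Genome
    mutant: List[VariantRecord]
    controls: List[VariantRecord]
    svs: List[SVRecord]
    control_svs: List[SVRecord]
    repeat_mask: MaskSet
    microsat_mask: MaskSet
    offtarget_sites: List[GenomicInterval]
    ontarget_sites: List[GenomicInterval]
    expected_variant_fates: List[str]
    expected_variant_offtarget: List[bool]
    expected_sv_fates: List[str]
    expected_sv_offtarget: List[bool]
    expected_sv_ontarget: List[bool]
    expected_variant_counts: Dict[str, int]
    expected_sv_counts: Dict[str, int]

    def write(self, outdir: Union[str, Path]) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        lengths = self.genome.lengths
        write_fasta(self.genome, outdir / "genome.fa")
        write_vcf(self.mutant, lengths, outdir / "mutant.vcf")
        write_vcf(self.controls, lengths, outdir / "control.vcf")
        write_bedpe(self.svs, outdir / "svs.bedpe")
        write_bedpe(self.control_svs, outdir / "control_svs.bedpe")
        _write_bed(self.repeat_mask.intervals, outdir / "repeats.bed")
        _write_bed(self.microsat_mask.intervals, outdir / "microsatellites.bed")
        _write_bed(self.offtarget_sites, outdir / "offtarget_sites.bed")
        _write_bed(self.ontarget_sites, outdir / "ontarget_sites.bed")


def toy_audit() -> ToyAudit:
    """Build the deterministic toy audit fixture.

    chrA is 1200 bp of the repeating unit ACGT with three overrides: an
    AAAAAA run at [500, 506), a CAGTTCAG segment at [558, 566) providing a
    TT run of exactly 2, and a GGGGGGG run at [540, 547).  chrB is 600 bp
    of TGCA repeats.  Masks: repeats chrA:[100,200) and chrB:[300,400),
    microsatellite chrA:[250,260).  Off-target sites chrA:[700,723) and
    chrB:[50,73); on-target site chrA:[1100,1123), placed outside the
    off-target flank windows so the two flags stay independent.
    """
    chrA = list("ACGT" * 300)
    chrA[500:506] = "AAAAAA"
    chrA[540:547] = "GGGGGGG"
    chrA[558:566] = "CAGTTCAG"
    genome = Genome({"chrA": "".join(chrA), "chrB": "TGCA" * 150})

    repeat_mask = MaskSet(
        "repeats",
        [GenomicInterval("chrA", 100, 200), GenomicInterval("chrB", 300, 400)],
    )
    microsat_mask = MaskSet("microsatellites", [GenomicInterval("chrA", 250, 260)])
    offtarget_sites = [
        GenomicInterval("chrA", 700, 723),
        GenomicInterval("chrB", 50, 73),
    ]
    ontarget_sites = [GenomicInterval("chrA", 1100, 1123)]

    # (chrom, pos, ref, alt, expected fate, expected offtarget flag)
    spec = [
        # germline-shared (first filter fires, even inside masks)
        ("chrA", 10, "G", "T", "removed_germline", False),
        ("chrA", 300, "A", "C", "removed_germline", False),
        ("chrA", 150, "G", "A", "removed_germline", False),
        ("chrB", 20, "T", "G", "removed_germline", False),
        ("chrA", 1000, "AC", "A", "removed_germline", False),
        # control has a different allele at the same position -> kept
        ("chrA", 60, "A", "T", "kept", False),
        # repeat mask
        ("chrA", 120, "A", "G", "removed_repeat", False),
        ("chrA", 199, "T", "C", "removed_repeat", False),
        ("chrB", 350, "C", "T", "removed_repeat", False),
        ("chrA", 95, "TACGTACGTA", "T", "removed_repeat", False),  # footprint reaches in
        # microsatellite mask
        ("chrA", 255, "T", "A", "removed_microsatellite", False),
        ("chrA", 259, "T", "G", "removed_microsatellite", False),
        ("chrA", 250, "G", "C", "removed_microsatellite", False),
        # half-open boundary: one base left of each mask -> kept
        ("chrA", 249, "C", "T", "kept", False),
        ("chrA", 99, "T", "A", "kept", False),
        # homopolymer indels inside runs >= 3
        ("chrA", 499, "TAA", "T", "removed_homopolymer", False),
        ("chrA", 500, "AA", "A", "removed_homopolymer", False),
        ("chrA", 502, "A", "AA", "removed_homopolymer", False),
        ("chrA", 540, "G", "GG", "removed_homopolymer", False),
        # indel contrasts that must survive the homopolymer filter
        ("chrA", 600, "ACG", "A", "kept", False),       # dinucleotide deletion
        ("chrA", 561, "T", "TT", "kept", False),        # run length 2 < 3
        ("chrA", 704, "AC", "A", "kept", True),         # run 1; inside off-target site
        # off-target site boundaries
        ("chrA", 722, "G", "A", "kept", True),          # last base of the site
        ("chrB", 50, "C", "T", "kept", True),           # first base of the site
        ("chrA", 723, "T", "C", "kept", False),         # one base past the site
        # plain kept
        ("chrA", 400, "A", "G", "kept", False),
        ("chrA", 450, "G", "T", "kept", False),
        ("chrB", 500, "T", "A", "kept", False),
        ("chrB", 100, "T", "C", "kept", False),
        ("chrA", 900, "A", "ATC", "kept", False),       # dinucleotide insertion
    ]
    mutant = [
        VariantRecord(chrom, pos, ref, alt, sample="edited")
        for chrom, pos, ref, alt, _, _ in spec
    ]
    controls = [
        VariantRecord("chrA", 10, "G", "T", sample="wildtype"),
        VariantRecord("chrA", 300, "A", "C", sample="wildtype"),
        VariantRecord("chrA", 150, "G", "A", sample="wildtype"),
        VariantRecord("chrB", 20, "T", "G", sample="wildtype"),
        VariantRecord("chrA", 1000, "AC", "A", sample="wildtype"),
        VariantRecord("chrA", 60, "A", "G", sample="wildtype"),  # different allele
        VariantRecord("chrA", 33, "C", "A", sample="wildtype"),  # control-only
        VariantRecord("chrB", 200, "T", "C", sample="wildtype"),  # control-only
    ]

    # (pos1, chrom2, pos2, svtype, fate, offtarget, ontarget)
    sv_spec = [
        ("chrA", 1110, "chrB", 500, "TRA", "kept", False, True),
        ("chrA", 1105, "chrB", 400, "TRA", "kept", False, True),  # 400 just past the mask
        ("chrB", 580, "chrA", 1122, "TRA", "kept", False, True),  # last site base
        ("chrA", 450, "chrA", 470, "DEL", "removed_germline", False, False),
        ("chrB", 520, "chrB", 580, "DUP", "removed_germline", False, False),
        ("chrA", 150, "chrA", 600, "DEL", "removed_repeat", False, False),
        ("chrB", 350, "chrB", 550, "INV", "removed_repeat", False, False),
        ("chrA", 980, "chrA", 1010, "DEL", "kept", False, False),
        ("chrA", 450, "chrA", 640, "DUP", "kept", True, False),  # 450 == 700 - 250
        ("chrB", 449, "chrB", 500, "DEL", "kept", False, False),
    ]
    svs = [
        SVRecord(c1, p1, c2, p2, t, sample="edited")
        for c1, p1, c2, p2, t, _, _, _ in sv_spec
    ]
    control_svs = [
        SVRecord("chrA", 455, "chrA", 468, "DEL", sample="wildtype"),  # +-10 bp match
        SVRecord("chrB", 520, "chrB", 580, "DUP", sample="wildtype"),  # exact match
        SVRecord("chrB", 10, "chrB", 90, "DEL", sample="wildtype"),    # control-only
    ]

    return ToyAudit(
        genome=genome,
        mutant=mutant,
        controls=controls,
        svs=svs,
        control_svs=control_svs,
        repeat_mask=repeat_mask,
        microsat_mask=microsat_mask,
        offtarget_sites=offtarget_sites,
        ontarget_sites=ontarget_sites,
        expected_variant_fates=[s[4] for s in spec],
        expected_variant_offtarget=[s[5] for s in spec],
        expected_sv_fates=[s[5] for s in sv_spec],
        expected_sv_offtarget=[s[6] for s in sv_spec],
        expected_sv_ontarget=[s[7] for s in sv_spec],
        expected_variant_counts={
            "input": 30,
            "after_germline": 25,
            "after_repeat": 21,
            "after_microsatellite": 18,
            "after_homopolymer": 14,
            "kept": 14,
            "offtarget_flagged": 3,
        },
        expected_sv_counts={
            "input": 10,
            "after_germline": 8,
            "after_repeat": 6,
            "after_microsatellite": 6,
            "kept": 6,
            "offtarget_flagged": 1,
            "ontarget_flagged": 3,
        },
    )
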