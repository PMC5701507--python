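"""Genome-wide Cas9 target-site discovery and repeat-family cataloguing.

The screen enumerates every 23-bp window (20-nt spacer + 3-nt NGG PAM by
default) on both strands, groups identical spacers into families, and calls
a family *chromosome-specific* when all of its exact occurrences lie on one
chromosome.  Multi-copy chromosome-specific families are the substrate for
CRISPR-mediated whole-chromosome elimination: many cuts on one chromosome,
none elsewhere.  Families are further classified as *clustered* (copies
confined to a small fraction of the chromosome) or *scattered*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np

from .genome_io import Genome, GenomicInterval, MaskSet, revcomp

__all__ = [
    "ScanConfig",
    "TargetSite",
    "SpacerFamily",
    "IUPAC",
    "scan_sites",
    "group_spacers",
    "classify_distribution",
    "chromosome_specific_catalog",
    "small_region_subset",
    "write_catalog_tsv",
    "write_occurrences_bed",
]

#: IUPAC nucleotide codes -> set of concrete bases matched.  Assembly gaps
#: (N bases in the genome) never match any pattern position, including "N".
IUPAC: Dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class ScanConfig:
    """Parameters of the target-site screen.

    site_length
        Total site length in bp (spacer + PAM); 23 for SpCas9.
    pam
        PAM pattern in IUPAC code, matched immediately 3' of the spacer
        on the targeted strand; "NGG" for SpCas9.
    both_strands
        Scan the reverse complement as well (default on).
    min_copies
        Minimum exact copy number for a family to enter the
        chromosome-specific catalog (>= 2 means "repeated").
    max_span_fraction_clustered
        A chromosome-specific multi-copy family is "clustered" when its
        occupied span is at most this fraction of the chromosome length.
    noncoding_only
        Restrict the catalog to sites outside annotated CDS/exon features.
    max_region_span
        Span bound (bp) defining the "small region" subset of clustered
        families (useful for minimizing collateral damage on the retained
        homologue).
    """

    site_length: int = 23
    pam: str = "NGG"
    both_strands: bool = True
    min_copies: int = 2
    max_span_fraction_clustered: float = 0.10
    noncoding_only: bool = False
    max_region_span: Optional[int] = 2000

    def __post_init__(self) -> None:
        if self.site_length <= len(self.pam):
            raise ValueError("site_length must exceed PAM length")
        bad = set(self.pam.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"PAM pattern contains non-IUPAC codes: {sorted(bad)}")
        if self.min_copies < 1:
            raise ValueError("min_copies must be >= 1")
        if not (0 < self.max_span_fraction_clustered <= 1):
            raise ValueError("max_span_fraction_clustered must be in (0, 1]")

    @property
    def spacer_length(self) -> int:
        return self.site_length - len(self.pam)


@dataclass(frozen=True)
class TargetSite:
    """One genomic occurrence of a protospacer + PAM.

    ``spacer`` and ``pam`` are read 5'->3' on the targeted strand, i.e. they
    equal the genome substring on '+' sites and its reverse complement on
    '-' sites.
    """

    location: GenomicInterval
    spacer: str
    pam: str

    @property
    def chrom(self) -> str:
        return self.location.chrom

    @property
    def start(self) -> int:
        return self.location.start

    @property
    def end(self) -> int:
        return self.location.end

    @property
    def strand(self) -> str:
        return self.location.strand


@dataclass
class SpacerFamily:
    """All exact genomic occurrences of one spacer sequence."""

    spacer: str
    occurrences: List[TargetSite]
    distribution: Optional[str] = None  # clustered | scattered | single_copy

    @property
    def copy_number(self) -> int:
        return len(self.occurrences)

    @property
    def chromosomes(self) -> List[str]:
        return sorted({site.chrom for site in self.occurrences})

    @property
    def chromosome_specific(self) -> bool:
        return len(self.chromosomes) == 1

    @property
    def home_chromosome(self) -> Optional[str]:
        chroms = self.chromosomes
        return chroms[0] if len(chroms) == 1 else None

    @property
    def span(self) -> Optional[int]:
        """Footprint (bp) from first to last occurrence on the home chromosome."""
        if not self.chromosome_specific:
            return None
        starts = [s.start for s in self.occurrences]
        ends = [s.end for s in self.occurrences]
        return max(ends) - min(starts)

    def pam_consensus(self) -> str:
        """Per-position consensus of observed PAMs (N where they differ)."""
        pams = {site.pam for site in self.occurrences}
        length = len(next(iter(pams)))
        out = []
        for i in range(length):
            bases = {p[i] for p in pams}
            out.append(bases.pop() if len(bases) == 1 else "N")
        return "".join(out)


def _base_match(col: np.ndarray, allowed: str) -> np.ndarray:
    m = np.zeros(col.shape, dtype=bool)
    for b in allowed:
        m |= col == ord(b)
    return m


def _scan_starts(arr: np.ndarray, config: ScanConfig) -> np.ndarray:
    """Start indices of valid sites on the forward reading of ``arr``.

    Valid means: the spacer region contains no N and every PAM position
    matches the (IUPAC) pattern with a concrete A/C/G/T base.
    """
    S, P = config.site_length, len(config.pam)
    L = arr.size
    n = L - S + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    spacer_len = S - P
    is_n = (arr == ord("N")).astype(np.int64)
    cum = np.concatenate(([0], np.cumsum(is_n)))
    no_n = (cum[spacer_len:] - cum[:-spacer_len])[:n] == 0
    ok = no_n
    for j, code in enumerate(config.pam.upper()):
        ok &= _base_match(arr[spacer_len + j : spacer_len + j + n], IUPAC[code])
    return np.nonzero(ok)[0]


def scan_sites(genome: Genome, config: Optional[ScanConfig] = None) -> List[TargetSite]:
    """Enumerate every target site in the genome.

    Returns sites sorted by (chromosome, start, strand); overlapping sites
    (including +/- pairs sharing bases) are distinct, as each is an
    independent cleavage opportunity.
    """
    config = config or ScanConfig()
    S = config.site_length
    spacer_len = config.spacer_length
    sites: List[TargetSite] = []
    for chrom in genome.chromosomes:
        seq = genome[chrom]
        L = len(seq)
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        for start in _scan_starts(arr, config):
            window = seq[start : start + S]
            sites.append(
                TargetSite(
                    GenomicInterval(chrom, int(start), int(start) + S, "+"),
                    spacer=window[:spacer_len],
                    pam=window[spacer_len:],
                )
            )
        if config.both_strands:
            rc = revcomp(seq)
            rc_arr = np.frombuffer(rc.encode("ascii"), dtype=np.uint8)
            for p in _scan_starts(rc_arr, config):
                p = int(p)
                window = rc[p : p + S]
                sites.append(
                    TargetSite(
                        GenomicInterval(chrom, L - p - S, L - p, "-"),
                        spacer=window[:spacer_len],
                        pam=window[spacer_len:],
                    )
                )
    sites.sort(key=lambda s: (s.chrom, s.start, s.strand))
    return sites


def classify_distribution(
    family: SpacerFamily, chrom_length: int, config: Optional[ScanConfig] = None
) -> str:
    """Label a chromosome-specific multi-copy family clustered or scattered.

    Clustered means the family footprint is at most
    ``max_span_fraction_clustered`` of the chromosome length.
    """
    config = config or ScanConfig()
    if not family.chromosome_specific:
        raise ValueError(
            f"distribution undefined for non-chromosome-specific spacer {family.spacer}"
        )
    if family.copy_number < 2:
        raise ValueError("distribution classification requires copy_number >= 2")
    span = family.span
    assert span is not None
    if span / chrom_length <= config.max_span_fraction_clustered:
        return "clustered"
    return "scattered"


def group_spacers(
    sites: Sequence[TargetSite],
    chrom_lengths: Optional[Dict[str, int]] = None,
    config: Optional[ScanConfig] = None,
) -> List[SpacerFamily]:
    """Group identical spacers into families.

    When ``chrom_lengths`` is supplied, the distribution label is filled in
    for single-copy and chromosome-specific multi-copy families.  Families
    are sorted by (home or first chromosome, descending copy number, spacer).
    """
    config = config or ScanConfig()
    by_spacer: Dict[str, List[TargetSite]] = {}
    for site in sites:
        by_spacer.setdefault(site.spacer, []).append(site)
    families = []
    for spacer, occurrences in by_spacer.items():
        occurrences.sort(key=lambda s: (s.chrom, s.start, s.strand))
        fam = SpacerFamily(spacer, occurrences)
        if fam.copy_number == 1:
            fam.distribution = "single_copy"
        elif fam.chromosome_specific and chrom_lengths is not None:
            fam.distribution = classify_distribution(
                fam, chrom_lengths[fam.home_chromosome], config
            )
        families.append(fam)
    families.sort(key=lambda f: (f.chromosomes[0], -f.copy_number, f.spacer))
    return families


def chromosome_specific_catalog(
    genome: Genome,
    config: Optional[ScanConfig] = None,
    coding_mask: Optional[MaskSet] = None,
) -> List[SpacerFamily]:
    """The screen proper: all chromosome-specific families with enough copies.

    With ``noncoding_only`` set, sites overlapping the coding mask (CDS/exon
    features from a GFF3) are excluded *before* family formation, so copy
    numbers reflect non-coding occurrences only.
    """
    config = config or ScanConfig()
    if config.noncoding_only and coding_mask is None:
        raise ValueError("noncoding_only requires a coding feature mask (GFF3)")
    sites = scan_sites(genome, config)
    if config.noncoding_only:
        assert coding_mask is not None
        sites = [
            s for s in sites if not coding_mask.overlaps(s.chrom, s.start, s.end)
        ]
    families = group_spacers(sites, genome.lengths, config)
    return [
        f
        for f in families
        if f.chromosome_specific and f.copy_number >= config.min_copies
    ]


def small_region_subset(
    catalog: Iterable[SpacerFamily], max_region_span: int
) -> List[SpacerFamily]:
    """Clustered families whose footprint fits within ``max_region_span`` bp."""
    return [
        f
        for f in catalog
        if f.distribution == "clustered"
        and f.span is not None
        and f.span <= max_region_span
    ]


def write_catalog_tsv(families: Iterable[SpacerFamily], path: Union[str, Path]) -> None:
    """Write the per-family catalog as TSV."""
    with open(path, "w") as handle:
        handle.write(
            "spacer\tpam_consensus\tcopy_number\thome_chromosome\tspan\tdistribution\n"
        )
        for f in families:
            handle.write(
                "\t".join(
                    [
                        f.spacer,
                        f.pam_consensus(),
                        str(f.copy_number),
                        f.home_chromosome or ",".join(f.chromosomes),
                        str(f.span) if f.span is not None else "NA",
                        f.distribution or "NA",
                    ]
                )
                + "\n"
            )


def write_occurrences_bed(
    families: Iterable[SpacerFamily], path: Union[str, Path]
) -> None:
    """Write every occurrence as BED6 (name = spacer, score = copy number)."""
    with open(path, "w") as handle:
        for f in families:
            for site in f.occurrences:
                handle.write(
                    f"{site.chrom}\t{site.start}\t{site.end}\t{f.spacer}\t"
                    f"{f.copy_number}\t{site.strand}\n"
                )
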