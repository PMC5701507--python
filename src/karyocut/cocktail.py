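"""Multi-sgRNA cocktail design over single-copy loci.

The alternative to cutting one repeated family many times is to cut many
unique sites once each: a cocktail of genome-unique sgRNAs spread over
several single-copy loci on the target chromosome (e.g. two guides in each
of seven one-copy genes, 14 guides in total).  Selection is deterministic
and positional — leftmost candidates first — because no on-target
efficiency model is part of the design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

from .genome_io import Genome, GenomicInterval
from .offtargets import OffTargetConfig, OffTargetHit, find_offtargets
from .targets import ScanConfig, TargetSite, group_spacers, scan_sites

__all__ = [
    "Locus",
    "CocktailRequest",
    "CocktailDesign",
    "design_cocktail",
    "read_loci_bed",
    "write_design_tsv",
    "write_spacers_fasta",
]


@dataclass(frozen=True)
class Locus:
    """A named target region (e.g. a one-copy gene on the chromosome arm)."""

    name: str
    interval: GenomicInterval


@dataclass(frozen=True)
class CocktailRequest:
    """Design request: which loci, how many guides each, how far apart.

    Every selected spacer must be genome-unique (exact copy number 1) and
    chosen sites within a locus must have start positions at least
    ``min_pairwise_gap`` bp apart (default 50, so 23-bp cut sites cannot
    overlap).
    """

    loci: Tuple[Locus, ...]
    guides_per_locus: int = 2
    min_pairwise_gap: int = 50

    def __post_init__(self) -> None:
        if not self.loci:
            raise ValueError("loci list must be non-empty")
        if self.guides_per_locus < 1:
            raise ValueError("guides_per_locus must be >= 1")
        chroms = {locus.interval.chrom for locus in self.loci}
        if len(chroms) != 1:
            raise ValueError(
                f"all loci must lie on one target chromosome; got {sorted(chroms)}"
            )


@dataclass
class CocktailDesign:
    """The selected guides, locus by locus."""

    selections: Dict[str, List[TargetSite]]
    warnings: List[str] = field(default_factory=list)
    mismatch_audit: Optional[Dict[str, List[OffTargetHit]]] = None

    @property
    def total_guides(self) -> int:
        return sum(len(sites) for sites in self.selections.values())

    def spacers(self) -> List[str]:
        return [s.spacer for sites in self.selections.values() for s in sites]


def design_cocktail(
    genome: Genome,
    request: CocktailRequest,
    config: Optional[ScanConfig] = None,
    audit_mismatches: Optional[int] = None,
) -> CocktailDesign:
    """Select up to ``guides_per_locus`` genome-unique guides per locus.

    Candidates are sites lying entirely within the locus whose spacer has
    exact genome-wide copy number 1; they are taken leftmost-first subject
    to the pairwise gap, with (start, strand, spacer) lexicographic
    tie-breaks, so identical inputs always give identical designs.  Loci
    with too few candidates contribute what they have plus a warning.

    With ``audit_mismatches`` set (e.g. 3), every selected guide is
    re-screened with the off-target search at that mismatch budget and the
    near-matches are attached to the design without rejecting the guide.
    """
    config = config or ScanConfig()
    lengths = genome.lengths
    for locus in request.loci:
        chrom = locus.interval.chrom
        if chrom not in genome:
            raise ValueError(f"locus {locus.name}: unknown chromosome {chrom!r}")
        if locus.interval.end > lengths[chrom]:
            raise ValueError(
                f"locus {locus.name}: interval exceeds chromosome {chrom} "
                f"length {lengths[chrom]}"
            )
    sites = scan_sites(genome, config)
    copy_number = {
        fam.spacer: fam.copy_number for fam in group_spacers(sites)
    }
    selections: Dict[str, List[TargetSite]] = {}
    warnings: List[str] = []
    for locus in request.loci:
        iv = locus.interval
        candidates = sorted(
            (
                s
                for s in sites
                if s.chrom == iv.chrom
                and s.start >= iv.start
                and s.end <= iv.end
                and copy_number[s.spacer] == 1
            ),
            key=lambda s: (s.start, s.strand, s.spacer),
        )
        chosen: List[TargetSite] = []
        for site in candidates:
            if len(chosen) == request.guides_per_locus:
                break
            if all(
                abs(site.start - prev.start) >= request.min_pairwise_gap
                for prev in chosen
            ):
                chosen.append(site)
        if len(chosen) < request.guides_per_locus:
            warnings.append(
                f"locus {locus.name}: only {len(chosen)} of "
                f"{request.guides_per_locus} genome-unique guides available"
            )
        selections[locus.name] = chosen
    design = CocktailDesign(selections, warnings)
    if audit_mismatches is not None:
        audit_cfg = OffTargetConfig(
            max_mismatches=audit_mismatches, pam_pattern=config.pam
        )
        design.mismatch_audit = {
            spacer: [
                h
                for h in find_offtargets(spacer, genome, audit_cfg)
                if h.mismatch_count > 0
            ]
            for spacer in design.spacers()
        }
    return design


def read_loci_bed(path: Union[str, Path]) -> List[Locus]:
    """Read loci from a BED file; column 4 supplies the locus name."""
    loci: List[Locus] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path}: line {lineno}: loci BED needs 4 columns (chrom, start, end, name)"
                )
            loci.append(
                Locus(
                    fields[3],
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2])),
                )
            )
    return loci


def write_design_tsv(design: CocktailDesign, path: Union[str, Path]) -> None:
    with open(path, "w") as handle:
        handle.write("locus\tspacer\tpam\tchrom\tstart\tend\tstrand\n")
        for locus, sites in design.selections.items():
            for s in sites:
                handle.write(
                    f"{locus}\t{s.spacer}\t{s.pam}\t{s.chrom}\t{s.start}\t{s.end}\t{s.strand}\n"
                )


def write_spacers_fasta(design: CocktailDesign, path: Union[str, Path]) -> None:
    with open(path, "w") as handle:
        for locus, sites in design.selections.items():
            for i, s in enumerate(sites, start=1):
                handle.write(f">{locus}_sg{i}\n{s.spacer}\n")
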