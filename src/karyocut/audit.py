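"""Post-editing WGS audit: variant filter cascade, structural-variant
screen, and depth-based chromosome copy number.

The cascade mirrors standard off-target assessment of edited samples
against wild-type controls.  Small variants pass, in order, through
germline subtraction (allele-exact match against controls), repeat and
microsatellite masking, and a homopolymer-indel artifact filter; survivors
are intersected with predicted off-target windows.  Structural variants
are control-subtracted with a breakend tolerance, masked by breakend, and
flagged when a breakend falls within a flank (250 bp by default) of a
predicted off-target site or inside an on-target site (the rearrangement
screen).  Each record is removed by at most one filter — the first that
fires — so the per-stage counts partition the input exactly.

Chromosome copy number is estimated from binned read depth: the pooled
autosomal median is anchored to copy 2 and each chromosome's median depth
is scaled accordingly.  A chromosome eliminated from every cell shows copy
0; one lost from a single homologue shows copy 1 (the XO readout).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import pysam

from .genome_io import Genome, GenomicInterval, MaskSet

__all__ = [
    "VariantRecord",
    "SVRecord",
    "FilterReport",
    "CopyNumberProfile",
    "read_vcf",
    "write_vcf",
    "read_bedpe",
    "write_bedpe",
    "read_depth_table",
    "write_depth_table",
    "subtract_germline",
    "apply_masks",
    "filter_homopolymer_indels",
    "intersect_offtarget_windows",
    "check_ontarget_rearrangement",
    "subtract_germline_svs",
    "apply_masks_svs",
    "run_cascade",
    "estimate_copy_number",
]

KEPT = "kept"


def _variant_kind(ref: str, alt: str) -> str:
    if len(ref) == len(alt):
        return "snv"
    return "insertion" if len(alt) > len(ref) else "deletion"


@dataclass
class VariantRecord:
    """A small-variant call flowing through the filter cascade.

    ``pos`` is 0-based.  ``fate`` starts as "kept" and is set by the first
    filter that removes the record; later filters skip removed records, so
    fates partition the input.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    sample: str = "sample"
    fate: str = KEPT
    offtarget_flag: bool = False

    @property
    def kind(self) -> str:
        return _variant_kind(self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return self.kind in ("insertion", "deletion")

    @property
    def footprint(self) -> Tuple[int, int]:
        """Reference footprint [pos, pos + len(ref)); insertions anchor 1 bp."""
        return self.pos, self.pos + max(len(self.ref), 1)

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class SVRecord:
    """A structural-variant call with two breakends (0-based positions)."""

    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    svtype: str  # DEL | DUP | INV | TRA
    sample: str = "sample"
    fate: str = KEPT
    offtarget_flag: bool = False
    ontarget_flag: bool = False

    def __post_init__(self) -> None:
        if self.svtype == "TRA" and self.chrom1 == self.chrom2:
            raise ValueError("TRA requires breakends on different chromosomes")
        if self.svtype != "TRA" and self.chrom1 != self.chrom2:
            raise ValueError(f"{self.svtype} requires breakends on one chromosome")

    @property
    def breakends(self) -> Tuple[Tuple[str, int], Tuple[str, int]]:
        return (self.chrom1, self.pos1), (self.chrom2, self.pos2)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_vcf(path: Union[str, Path], sample: str = "sample") -> List[VariantRecord]:
    """Read small variants from a VCF (one record per ALT allele)."""
    records: List[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                records.append(
                    VariantRecord(rec.chrom, rec.start, rec.ref, alt, sample=sample)
                )
    return records


def write_vcf(
    records: Sequence[VariantRecord],
    lengths: Dict[str, int],
    path: Union[str, Path],
) -> None:
    """Write variants as a minimal sites-only VCF 4.2."""
    header = pysam.VariantHeader()
    for chrom, length in lengths.items():
        header.contigs.add(chrom, length=length)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt)):
            out.write(
                out.new_record(
                    contig=rec.chrom, start=rec.pos, alleles=(rec.ref, rec.alt)
                )
            )


def read_bedpe(path: Union[str, Path], sample: str = "sample") -> List[SVRecord]:
    """Read SVs from BEDPE; column 7 (the name field) carries the SV type."""
    records: List[SVRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ValueError(
                    f"{path}: line {lineno}: BEDPE needs 7 columns "
                    "(chrom1 start1 end1 chrom2 start2 end2 svtype)"
                )
            records.append(
                SVRecord(
                    fields[0],
                    int(fields[1]),
                    fields[3],
                    int(fields[4]),
                    fields[6],
                    sample=sample,
                )
            )
    return records


def write_bedpe(records: Sequence[SVRecord], path: Union[str, Path]) -> None:
    with open(path, "w") as handle:
        for r in records:
            handle.write(
                f"{r.chrom1}\t{r.pos1}\t{r.pos1 + 1}\t{r.chrom2}\t{r.pos2}\t"
                f"{r.pos2 + 1}\t{r.svtype}\n"
            )


def read_depth_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a binned depth table: columns chrom, start, depth (TSV)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"chrom", "start", "depth"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: depth table missing columns {sorted(missing)}")
    return df


def write_depth_table(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Small-variant filters
# ---------------------------------------------------------------------------

def subtract_germline(
    mutant: Sequence[VariantRecord], controls: Sequence[VariantRecord]
) -> List[VariantRecord]:
    """Mark mutant variants also present in controls as germline.

    Matching is allele-exact on (chrom, pos, ref, alt); a control variant at
    the same position with a different allele does not subtract.
    """
    control_keys = {rec.key for rec in controls}
    for rec in mutant:
        if rec.fate == KEPT and rec.key in control_keys:
            rec.fate = "removed_germline"
    return list(mutant)


def apply_masks(
    variants: Sequence[VariantRecord],
    repeat_mask: Optional[MaskSet],
    microsat_mask: Optional[MaskSet],
) -> List[VariantRecord]:
    """Remove surviving variants whose reference footprint overlaps a mask.

    The repeat mask is applied first, then the microsatellite mask; overlap
    means >= 1 shared base under half-open coordinates.
    """
    for rec in variants:
        if rec.fate != KEPT:
            continue
        start, end = rec.footprint
        if repeat_mask is not None and repeat_mask.overlaps(rec.chrom, start, end):
            rec.fate = "removed_repeat"
        elif microsat_mask is not None and microsat_mask.overlaps(rec.chrom, start, end):
            rec.fate = "removed_microsatellite"
    return list(variants)


def _changed_sequence(ref: str, alt: str) -> str:
    """The inserted or deleted bases, with the common prefix stripped.

    Handles the usual VCF anchored representation (ref "TAA" / alt "T"
    deletes "AA").
    """
    i = 0
    while i < min(len(ref), len(alt)) and ref[i] == alt[i]:
        i += 1
    return ref[i:] if len(ref) > len(alt) else alt[i:]


def _run_length(seq: str, left: int, right: int, base: str) -> int:
    """Length of the run of ``base`` spanning reference gap/segment [left, right)."""
    lo = left
    while lo > 0 and seq[lo - 1] == base:
        lo -= 1
    hi = right
    while hi < len(seq) and seq[hi] == base:
        hi += 1
    return hi - lo


def filter_homopolymer_indels(
    variants: Sequence[VariantRecord],
    genome: Genome,
    min_run: int = 3,
) -> List[VariantRecord]:
    """Remove mono-nucleotide indels lying inside a homopolymer run.

    An indel is removed when the inserted/deleted sequence is a single
    repeated base *and* the surrounding reference run of that base (run
    through the event site, both directions) is at least ``min_run`` bp —
    the classic homopolymer slippage artifact.  Multi-base-alphabet indels
    and SNVs are never touched.
    """
    for rec in variants:
        if rec.fate != KEPT or not rec.is_indel:
            continue
        changed = _changed_sequence(rec.ref, rec.alt)
        if not changed or len(set(changed)) != 1:
            continue
        base = changed[0]
        seq = genome[rec.chrom]
        i = 0
        while i < min(len(rec.ref), len(rec.alt)) and rec.ref[i] == rec.alt[i]:
            i += 1
        if rec.kind == "deletion":
            left, right = rec.pos + i, rec.pos + i + len(changed)
        else:  # insertion: the run around the insertion point
            left = right = rec.pos + i
        if _run_length(seq, left, right, base) >= min_run:
            rec.fate = "removed_homopolymer"
    return list(variants)


# ---------------------------------------------------------------------------
# Off-/on-target window intersection
# ---------------------------------------------------------------------------

def intersect_offtarget_windows(
    variants: Sequence[VariantRecord],
    svs: Sequence[SVRecord],
    offtarget_sites: Sequence[GenomicInterval],
    sv_flank: int = 250,
) -> Tuple[List[VariantRecord], List[SVRecord]]:
    """Flag surviving calls that touch predicted off-target sites.

    A variant is flagged when its reference footprint overlaps a site
    interval; an SV is flagged when either breakend lies within
    [site.start - sv_flank, site.end + sv_flank), i.e. a breakend exactly
    ``sv_flank`` bp upstream of the site start is still inside the window.
    """
    site_tree = MaskSet("offtarget", offtarget_sites)
    for rec in variants:
        if rec.fate != KEPT:
            continue
        start, end = rec.footprint
        if site_tree.overlaps(rec.chrom, start, end):
            rec.offtarget_flag = True
    flank_tree = MaskSet(
        "offtarget_flank",
        [
            GenomicInterval(s.chrom, max(0, s.start - sv_flank), s.end + sv_flank)
            for s in offtarget_sites
        ],
    )
    for sv in svs:
        if sv.fate != KEPT:
            continue
        if any(flank_tree.overlaps(chrom, pos, pos + 1) for chrom, pos in sv.breakends):
            sv.offtarget_flag = True
    return list(variants), list(svs)


def check_ontarget_rearrangement(
    svs: Sequence[SVRecord], ontarget_sites: Sequence[GenomicInterval]
) -> List[SVRecord]:
    """Flag SVs with a breakend inside an on-target site (no flank).

    A clean edit shows no surviving rearrangement whose breakend falls in
    the guide's own cleavage sites.
    """
    site_tree = MaskSet("ontarget", ontarget_sites)
    for sv in svs:
        if sv.fate != KEPT:
            continue
        if any(site_tree.overlaps(chrom, pos, pos + 1) for chrom, pos in sv.breakends):
            sv.ontarget_flag = True
    return list(svs)


# ---------------------------------------------------------------------------
# SV filters
# ---------------------------------------------------------------------------

def subtract_germline_svs(
    mutant: Sequence[SVRecord],
    controls: Sequence[SVRecord],
    breakend_tolerance: int = 10,
) -> List[SVRecord]:
    """Remove SVs shared with controls.

    SV callers report imprecise breakends, so a mutant SV matches a control
    SV when both breakend chromosomes agree, both positions are within
    ``breakend_tolerance`` bp, and the SV type is identical.
    """
    for sv in mutant:
        if sv.fate != KEPT:
            continue
        for ctl in controls:
            if (
                sv.svtype == ctl.svtype
                and sv.chrom1 == ctl.chrom1
                and sv.chrom2 == ctl.chrom2
                and abs(sv.pos1 - ctl.pos1) <= breakend_tolerance
                and abs(sv.pos2 - ctl.pos2) <= breakend_tolerance
            ):
                sv.fate = "removed_germline"
                break
    return list(mutant)


def apply_masks_svs(
    svs: Sequence[SVRecord],
    repeat_mask: Optional[MaskSet],
    microsat_mask: Optional[MaskSet],
) -> List[SVRecord]:
    """Remove SVs with either breakend inside a mask (repeat first)."""
    for sv in svs:
        if sv.fate != KEPT:
            continue
        ends = sv.breakends
        if repeat_mask is not None and any(
            repeat_mask.overlaps(chrom, pos, pos + 1) for chrom, pos in ends
        ):
            sv.fate = "removed_repeat"
        elif microsat_mask is not None and any(
            microsat_mask.overlaps(chrom, pos, pos + 1) for chrom, pos in ends
        ):
            sv.fate = "removed_microsatellite"
    return list(svs)


# ---------------------------------------------------------------------------
# Cascade driver and report
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    """Per-stage counts and per-record fates of the audit cascade."""

    variants: List[VariantRecord]
    svs: List[SVRecord]
    variant_counts: Dict[str, int]
    sv_counts: Dict[str, int]

    @property
    def kept_variants(self) -> List[VariantRecord]:
        return [v for v in self.variants if v.fate == KEPT]

    @property
    def kept_svs(self) -> List[SVRecord]:
        return [s for s in self.svs if s.fate == KEPT]

    @property
    def review_list(self) -> List[VariantRecord]:
        """Kept variants in off-target windows — candidates for manual review."""
        return [v for v in self.kept_variants if v.offtarget_flag]

    def summary(self) -> Dict[str, Dict[str, int]]:
        return {"variants": dict(self.variant_counts), "svs": dict(self.sv_counts)}

    def variants_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "kind": v.kind,
                    "sample": v.sample,
                    "fate": v.fate,
                    "offtarget_flag": v.offtarget_flag,
                }
                for v in self.variants
            ]
        )

    def svs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom1": s.chrom1,
                    "pos1": s.pos1,
                    "chrom2": s.chrom2,
                    "pos2": s.pos2,
                    "svtype": s.svtype,
                    "sample": s.sample,
                    "fate": s.fate,
                    "offtarget_flag": s.offtarget_flag,
                    "ontarget_flag": s.ontarget_flag,
                }
                for s in self.svs
            ]
        )

    def write(self, outdir: Union[str, Path]) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.variants_frame().to_csv(outdir / "variant_fates.tsv", sep="\t", index=False)
        self.svs_frame().to_csv(outdir / "sv_fates.tsv", sep="\t", index=False)
        with open(outdir / "filter_summary.json", "w") as handle:
            json.dump(self.summary(), handle, indent=2)
            handle.write("\n")


def _check_reference_names(
    genome: Genome,
    variants: Sequence[VariantRecord],
    svs: Sequence[SVRecord],
) -> None:
    chroms = set(genome.chromosomes)
    offenders = sorted(
        {v.chrom for v in variants if v.chrom not in chroms}
        | {c for s in svs for c in (s.chrom1, s.chrom2) if c not in chroms}
    )
    if offenders:
        raise ValueError(
            f"reference names absent from the genome: {', '.join(offenders)}"
        )


def run_cascade(
    mutant: Sequence[VariantRecord],
    controls: Sequence[VariantRecord],
    genome: Genome,
    repeat_mask: Optional[MaskSet] = None,
    microsat_mask: Optional[MaskSet] = None,
    offtarget_sites: Sequence[GenomicInterval] = (),
    ontarget_sites: Sequence[GenomicInterval] = (),
    svs: Sequence[SVRecord] = (),
    control_svs: Sequence[SVRecord] = (),
    sv_flank: int = 250,
    sv_breakend_tolerance: int = 10,
    homopolymer_min_run: int = 3,
) -> FilterReport:
    """Run the full audit cascade and assemble the per-stage report.

    Variants: germline subtraction -> repeat/microsatellite masks ->
    homopolymer-indel filter -> off-target window flags.  SVs: germline
    subtraction (breakend tolerance) -> masks by breakend -> off-target
    flank windows and the on-target rearrangement check.
    """
    variants = [
        VariantRecord(v.chrom, v.pos, v.ref, v.alt, sample=v.sample)
        for v in mutant
    ]
    sv_records = [
        SVRecord(s.chrom1, s.pos1, s.chrom2, s.pos2, s.svtype, sample=s.sample)
        for s in svs
    ]
    _check_reference_names(genome, variants, sv_records)

    def surviving(records) -> int:
        return sum(1 for r in records if r.fate == KEPT)

    vcounts: Dict[str, int] = {"input": len(variants)}
    subtract_germline(variants, controls)
    vcounts["after_germline"] = surviving(variants)
    apply_masks(variants, repeat_mask, None)
    vcounts["after_repeat"] = surviving(variants)
    apply_masks(variants, None, microsat_mask)
    vcounts["after_microsatellite"] = surviving(variants)
    filter_homopolymer_indels(variants, genome, min_run=homopolymer_min_run)
    vcounts["after_homopolymer"] = surviving(variants)
    vcounts["kept"] = surviving(variants)

    scounts: Dict[str, int] = {"input": len(sv_records)}
    subtract_germline_svs(sv_records, control_svs, sv_breakend_tolerance)
    scounts["after_germline"] = surviving(sv_records)
    apply_masks_svs(sv_records, repeat_mask, None)
    scounts["after_repeat"] = surviving(sv_records)
    apply_masks_svs(sv_records, None, microsat_mask)
    scounts["after_microsatellite"] = surviving(sv_records)
    scounts["kept"] = surviving(sv_records)

    intersect_offtarget_windows(variants, sv_records, list(offtarget_sites), sv_flank)
    check_ontarget_rearrangement(sv_records, list(ontarget_sites))
    vcounts["offtarget_flagged"] = sum(
        1 for v in variants if v.fate == KEPT and v.offtarget_flag
    )
    scounts["offtarget_flagged"] = sum(
        1 for s in sv_records if s.fate == KEPT and s.offtarget_flag
    )
    scounts["ontarget_flagged"] = sum(
        1 for s in sv_records if s.fate == KEPT and s.ontarget_flag
    )
    return FilterReport(variants, sv_records, vcounts, scounts)


# ---------------------------------------------------------------------------
# Depth-based karyotype
# ---------------------------------------------------------------------------

@dataclass
class CopyNumberProfile:
    """Per-chromosome copy number from binned depth.

    ``raw`` carries the continuous estimate 2 * median(chrom bins) /
    median(autosomal bins); ``rounded`` is its nearest integer.  The pooled
    autosomal median depth is the normalization constant mapping to copy 2.
    """

    raw: Dict[str, float]
    rounded: Dict[str, int]
    median_depth: Dict[str, float]
    autosomal_median: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": list(self.raw),
                "median_depth": [self.median_depth[c] for c in self.raw],
                "copy_number_raw": [self.raw[c] for c in self.raw],
                "copy_number": [self.rounded[c] for c in self.raw],
            }
        )

    def write_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def estimate_copy_number(
    depth: pd.DataFrame,
    autosomes: Sequence[str],
    chromosomes: Optional[Sequence[str]] = None,
) -> CopyNumberProfile:
    """Estimate per-chromosome copy number from a binned depth table.

    ``depth`` needs columns chrom, start, depth.  ``chromosomes`` lets an
    absent chromosome (no bins, i.e. no aligned reads) be reported as copy
    0; by default the chromosomes present in the table are used.  The
    estimator is scale-invariant: multiplying every depth by c > 0 leaves
    the profile unchanged.
    """
    autosomes = list(autosomes)
    auto_bins = depth.loc[depth["chrom"].isin(autosomes), "depth"]
    if auto_bins.empty or not (auto_bins > 0).any():
        raise ValueError("no autosomal bins with positive depth")
    norm = float(auto_bins.median())
    if chromosomes is None:
        chromosomes = list(dict.fromkeys(depth["chrom"]))
    raw: Dict[str, float] = {}
    medians: Dict[str, float] = {}
    for chrom in chromosomes:
        bins = depth.loc[depth["chrom"] == chrom, "depth"]
        med = float(bins.median()) if not bins.empty else 0.0
        medians[chrom] = med
        raw[chrom] = 2.0 * med / norm
    # floor(x + 0.5): nearest integer with deterministic half-up ties
    rounded = {chrom: int(np.floor(value + 0.5)) for chrom, value in raw.items()}
    return CopyNumberProfile(raw, rounded, medians, norm)
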