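"""Mismatch-tolerant genome-wide off-target search.

For a given 20-nt spacer, every stranded genomic window carrying a
pattern-conformant PAM is scored by Hamming distance over the spacer
region; windows within the mismatch budget (default 5, matching standard
off-target prediction practice) are reported.  The PAM must match its
pattern exactly — mismatches are counted only in the spacer — and windows
whose spacer region contains N are excluded, since assembly gaps never
participate in matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional, Tuple, Union

import numpy as np

from .genome_io import Genome, GenomicInterval, revcomp
from .targets import IUPAC, _base_match, _scan_starts, ScanConfig

__all__ = [
    "OffTargetConfig",
    "OffTargetHit",
    "find_offtargets",
    "count_cleavage_sites",
    "write_hits_tsv",
]


@dataclass(frozen=True)
class OffTargetConfig:
    """Off-target search parameters.

    max_mismatches
        Hamming-distance budget over the spacer (uniform across positions,
        no seed-region weighting).
    pam_pattern
        PAM required at candidate windows; NGG by default (NRG/NAG variants
        can be supplied for laxer Cas9 PAM-recognition models).
    include_on_target
        Keep mismatch-0 (exact) hits in the output.
    """

    max_mismatches: int = 5
    pam_pattern: str = "NGG"
    include_on_target: bool = True

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        bad = set(self.pam_pattern.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"PAM pattern contains non-IUPAC codes: {sorted(bad)}")


@dataclass(frozen=True)
class OffTargetHit:
    """One candidate cleavage window for a spacer.

    ``mismatch_positions`` are 0-based spacer indices counted from the
    PAM-distal (5') end.
    """

    location: GenomicInterval
    matched_sequence: str
    pam_observed: str
    mismatch_count: int
    mismatch_positions: Tuple[int, ...]

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


def _search_strand(
    seq: str,
    spacer: str,
    config: OffTargetConfig,
) -> List[Tuple[int, str, str, int]]:
    """(window_start, matched, pam, mismatches) on the forward reading of seq."""
    spacer_len = len(spacer)
    site_len = spacer_len + len(config.pam_pattern)
    scan_cfg = ScanConfig(site_length=site_len, pam=config.pam_pattern)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    n = arr.size - site_len + 1
    if n <= 0:
        return []
    valid = np.zeros(n, dtype=bool)
    valid[_scan_starts(arr, scan_cfg)] = True
    mismatches = np.zeros(n, dtype=np.int16)
    for j, base in enumerate(spacer):
        mismatches += arr[j : j + n] != ord(base)
    keep = valid & (mismatches <= config.max_mismatches)
    out = []
    for p in np.nonzero(keep)[0]:
        p = int(p)
        matched = seq[p : p + spacer_len]
        pam = seq[p + spacer_len : p + site_len]
        out.append((p, matched, pam, int(mismatches[p])))
    return out


def find_offtargets(
    spacer: str,
    genome: Genome,
    config: Optional[OffTargetConfig] = None,
) -> List[OffTargetHit]:
    """All genomic windows matching ``spacer`` within the mismatch budget.

    Hits are sorted by (mismatch count, chromosome, start, strand); exact
    matches have ``mismatch_count`` 0.
    """
    config = config or OffTargetConfig()
    spacer = spacer.upper()
    if set(spacer) - set("ACGT"):
        raise ValueError("spacer must contain only A/C/G/T (no N)")
    if config.max_mismatches > len(spacer):
        raise ValueError("max_mismatches cannot exceed spacer length")
    site_len = len(spacer) + len(config.pam_pattern)
    hits: List[OffTargetHit] = []
    for chrom in genome.chromosomes:
        seq = genome[chrom]
        L = len(seq)
        for p, matched, pam, mm in _search_strand(seq, spacer, config):
            hits.append(
                OffTargetHit(
                    GenomicInterval(chrom, p, p + site_len, "+"),
                    matched,
                    pam,
                    mm,
                    tuple(i for i in range(len(spacer)) if matched[i] != spacer[i]),
                )
            )
        rc = revcomp(seq)
        for p, matched, pam, mm in _search_strand(rc, spacer, config):
            hits.append(
                OffTargetHit(
                    GenomicInterval(chrom, L - p - site_len, L - p, "-"),
                    matched,
                    pam,
                    mm,
                    tuple(i for i in range(len(spacer)) if matched[i] != spacer[i]),
                )
            )
    if not config.include_on_target:
        hits = [h for h in hits if h.mismatch_count > 0]
    hits.sort(key=lambda h: (h.mismatch_count, h.chrom, h.start, h.strand))
    return hits


def count_cleavage_sites(
    spacer: str, genome: Genome, pam_pattern: str = "NGG"
) -> int:
    """Number of exact (mismatch-0) cleavage sites of a spacer, both strands.

    Equals the spacer's family copy number from the discovery scan on the
    same genome.
    """
    hits = find_offtargets(
        spacer,
        genome,
        OffTargetConfig(max_mismatches=0, pam_pattern=pam_pattern),
    )
    return len(hits)


def write_hits_tsv(hits: Iterable[OffTargetHit], path: Union[str, Path]) -> None:
    with open(path, "w") as handle:
        handle.write(
            "chrom\tstart\tend\tstrand\tmatched_sequence\tpam_observed\t"
            "mismatch_count\tmismatch_positions\n"
        )
        for h in hits:
            handle.write(
                f"{h.chrom}\t{h.start}\t{h.end}\t{h.strand}\t{h.matched_sequence}\t"
                f"{h.pam_observed}\t{h.mismatch_count}\t"
                f"{','.join(map(str, h.mismatch_positions))}\n"
            )
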