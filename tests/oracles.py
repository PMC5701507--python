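"""Independent brute-force re-implementations used as test oracles.

Everything here is deliberately naive — pure-Python sliding windows with
no shared code or data tables with the package — so agreement between the
two routes is meaningful.
"""

from typing import Dict, List, Tuple

_ORACLE_IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"},
    "D": {"A", "G", "T"}, "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def oracle_revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def _pam_ok(pam_seq: str, pattern: str) -> bool:
    return all(b in _ORACLE_IUPAC[p] for b, p in zip(pam_seq, pattern))


def oracle_scan(
    sequences: Dict[str, str], site_length: int = 23, pam: str = "NGG"
) -> List[Tuple[str, int, str, str, str]]:
    """All (chrom, start, strand, spacer, pam) sites via naive sliding window."""
    spacer_len = site_length - len(pam)
    out = []
    for chrom, seq in sequences.items():
        for i in range(len(seq) - site_length + 1):
            window = seq[i : i + site_length]
            for strand, oriented in (("+", window), ("-", oracle_revcomp(window))):
                spacer, pam_seq = oriented[:spacer_len], oriented[spacer_len:]
                if "N" not in spacer and _pam_ok(pam_seq, pam):
                    out.append((chrom, i, strand, spacer, pam_seq))
    out.sort(key=lambda t: (t[0], t[1], t[2]))
    return out


def oracle_group(
    sites: List[Tuple[str, int, str, str, str]]
) -> Dict[str, List[Tuple[str, int, str]]]:
    """spacer -> sorted list of (chrom, start, strand) occurrences."""
    groups: Dict[str, List[Tuple[str, int, str]]] = {}
    for chrom, start, strand, spacer, _ in sites:
        groups.setdefault(spacer, []).append((chrom, start, strand))
    for occurrences in groups.values():
        occurrences.sort()
    return groups


def oracle_offtargets(
    sequences: Dict[str, str],
    spacer: str,
    max_mismatches: int,
    pam: str = "NGG",
) -> List[Tuple[str, int, str, str, int]]:
    """All (chrom, start, strand, matched, mismatches) hits by full scan."""
    spacer_len = len(spacer)
    site_length = spacer_len + len(pam)
    out = []
    for chrom, seq in sequences.items():
        for i in range(len(seq) - site_length + 1):
            window = seq[i : i + site_length]
            for strand, oriented in (("+", window), ("-", oracle_revcomp(window))):
                cand, pam_seq = oriented[:spacer_len], oriented[spacer_len:]
                if "N" in cand or not _pam_ok(pam_seq, pam):
                    continue
                mm = sum(1 for a, b in zip(cand, spacer) if a != b)
                if mm <= max_mismatches:
                    out.append((chrom, i, strand, cand, mm))
    out.sort(key=lambda t: (t[4], t[0], t[1], t[2]))
    return out


def oracle_overlaps(
    query: Tuple[str, int, int], intervals: List[Tuple[str, int, int]]
) -> List[Tuple[str, int, int]]:
    """All-pairs half-open interval overlap scan."""
    chrom, start, end = query
    return sorted(
        (c, s, e)
        for c, s, e in intervals
        if c == chrom and s < end and start < e
    )
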