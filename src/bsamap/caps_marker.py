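"""CAPS (cleaved amplified polymorphic sequence) marker utilities.

A SNP can be genotyped on a gel when it creates or destroys a restriction
enzyme recognition site inside a PCR amplicon: digestion then yields
different fragment patterns for the two alleles.  The classic example here
is HaeII (degenerate site RGCGCY, cutting RGCGC^Y), which distinguishes a
causal G→A mutant allele from wild type because the mutant base breaks
the recognition site and the amplicon resists digestion.

Matching is case-insensitive over IUPAC degenerate codes; ``N`` in the
*sequence* never matches.  Palindromic sites (HaeII is its own reverse
complement) need only a forward scan; non-palindromic sites are scanned on
both strands.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "RecognitionSite",
    "ENZYMES",
    "find_sites",
    "caps_check",
    "fragment_lengths",
    "is_palindromic",
]

# IUPAC nucleotide codes -> the set of concrete bases they match
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class RecognitionSite:
    """A restriction enzyme recognition site as an IUPAC degenerate string.

    ``cut_offset`` is the number of site bases left of the cut on the
    forward strand (HaeII RGCGC^Y → 5); None when unknown.
    """

    enzyme: str
    site: str
    cut_offset: int | None = None

    def __post_init__(self) -> None:
        site = self.site.upper()
        bad = [c for c in site if c not in IUPAC]
        if bad:
            raise ValueError(
                f"{self.enzyme}: non-IUPAC characters {bad} in site {self.site!r}"
            )
        object.__setattr__(self, "site", site)
        if self.cut_offset is not None and not 0 <= self.cut_offset <= len(site):
            raise ValueError(f"{self.enzyme}: cut_offset outside site")


# small built-in registry; extendable by constructing RecognitionSite directly
ENZYMES: dict[str, RecognitionSite] = {
    "HaeII": RecognitionSite("HaeII", "RGCGCY", 5),
    "HaeIII": RecognitionSite("HaeIII", "GGCC", 2),
    "EcoRI": RecognitionSite("EcoRI", "GAATTC", 1),
    "HindIII": RecognitionSite("HindIII", "AAGCTT", 1),
    "TaqI": RecognitionSite("TaqI", "TCGA", 1),
}


def reverse_complement_iupac(site: str) -> str:
    return site.translate(_IUPAC_COMPLEMENT)[::-1]


def is_palindromic(site: RecognitionSite) -> bool:
    return reverse_complement_iupac(site.site) == site.site


def _pattern(site: str) -> re.Pattern:
    return re.compile("".join(f"[{IUPAC[c]}]" for c in site))


def find_sites(sequence: str, site: RecognitionSite) -> list[int]:
    """1-based start positions where the site matches, overlaps included.

    For non-palindromic sites the reverse-complement pattern is also
    scanned and its matches reported at their forward-strand start.
    """
    seq = sequence.upper()
    patterns = [site.site]
    if not is_palindromic(site):
        patterns.append(reverse_complement_iupac(site.site))
    hits: set[int] = set()
    for pat in patterns:
        rx = re.compile(f"(?=({_pattern(pat).pattern}))")
        hits.update(m.start() + 1 for m in rx.finditer(seq))
    return sorted(hits)


def caps_check(
    amplicon: str,
    snp_offset: int,
    ref_base: str,
    alt_base: str,
    site: RecognitionSite,
) -> str:
    """Does the SNP gain or lose a recognition site in the amplicon?

    ``snp_offset`` is 1-based within the amplicon; the amplicon must carry
    the reference base there.  Classifies by the change in the number of
    sites overlapping the SNP: ``site_lost``, ``site_gained`` or
    ``no_change``.
    """
    seq = amplicon.upper()
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    if not 1 <= snp_offset <= len(seq):
        raise ValueError(f"snp_offset {snp_offset} outside amplicon")
    if seq[snp_offset - 1] != ref_base:
        raise ValueError(
            f"amplicon has {seq[snp_offset - 1]} at offset {snp_offset}, "
            f"expected ref {ref_base}"
        )
    alt_seq = seq[: snp_offset - 1] + alt_base + seq[snp_offset:]
    span = len(site.site)

    def overlapping(positions: list[int]) -> int:
        return sum(1 for p in positions if p <= snp_offset <= p + span - 1)

    n_ref = overlapping(find_sites(seq, site))
    n_alt = overlapping(find_sites(alt_seq, site))
    if n_alt < n_ref:
        return "site_lost"
    if n_alt > n_ref:
        return "site_gained"
    return "no_change"


def fragment_lengths(
    amplicon: str,
    site: RecognitionSite,
    cut_offset: int | None = None,
) -> list[int]:
    """Digestion fragment lengths, 5'→3'; they always sum to the amplicon.

    ``cut_offset`` overrides the site's built-in cut geometry.  An uncut
    amplicon yields a single full-length fragment.  For non-palindromic
    sites, reverse-strand matches cut at the mirrored offset.
    """
    offset = site.cut_offset if cut_offset is None else cut_offset
    if offset is None:
        raise ValueError(f"{site.enzyme}: no cut_offset known; pass one explicitly")
    if not 0 <= offset <= len(site.site):
        raise ValueError("cut_offset outside site length")
    seq = amplicon.upper()
    cuts: set[int] = set()
    fw = _pattern(site.site)
    for m in re.finditer(f"(?=({fw.pattern}))", seq):
        cuts.add(m.start() + offset)
    if not is_palindromic(site):
        rc = _pattern(reverse_complement_iupac(site.site))
        mirrored = len(site.site) - offset
        for m in re.finditer(f"(?=({rc.pattern}))", seq):
            cuts.add(m.start() + mirrored)
    cut_list = sorted(c for c in cuts if 0 < c < len(seq))
    bounds = [0] + cut_list + [len(seq)]
    return [b - a for a, b in zip(bounds, bounds[1:])]
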