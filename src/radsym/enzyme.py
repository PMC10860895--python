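"""Type IIB restriction enzymes and in-silico tag extraction.

A type IIB enzyme (e.g. BcgI) cuts on *both* sides of its recognition
site, releasing a uniform-length fragment: ``flank_len`` nt upstream,
the recognition site itself, and ``flank_len`` nt downstream.  These
fixed-length fragments ("2bRAD tags") are the sequencing unit of
2bRAD / 2bRAD-M protocols.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "EnzymeSpec",
    "BCGI",
    "revcomp",
    "canonical_tag",
    "find_tags",
    "iupac_to_regex",
]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]",
    "B": "[CGT]", "D": "[AGT]", "H": "[ACT]", "V": "[ACG]",
    "N": "[ACGT]",
}

_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "D": "H", "H": "D", "V": "B", "N": "N",
}

_COMP = str.maketrans("ACGTN", "TGCAN")


class EnzymeConfigError(ValueError):
    """Raised for malformed enzyme specifications."""


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMP)[::-1]


def iupac_to_regex(pattern: str) -> str:
    """Translate an IUPAC nucleotide pattern into a regular expression.

    Raises
    ------
    EnzymeConfigError
        If the pattern contains a symbol outside the IUPAC alphabet.
    """
    out = []
    for ch in pattern.upper():
        if ch not in _IUPAC:
            raise EnzymeConfigError(
                f"invalid IUPAC symbol {ch!r} in recognition pattern {pattern!r}"
            )
        out.append(_IUPAC[ch])
    return "".join(out)


@dataclass(frozen=True)
class EnzymeSpec:
    """A type IIB restriction enzyme.

    Parameters
    ----------
    name : str
        Enzyme name, e.g. ``"BcgI"``.
    recognition : str
        IUPAC pattern of the recognition site (e.g. ``CGANNNNNNTGC``).
    flank_len : int
        Number of nucleotides excised on each side of the site.
    """

    name: str
    recognition: str
    flank_len: int

    def __post_init__(self) -> None:
        if len(self.recognition) < 4:
            raise EnzymeConfigError("recognition pattern must be >= 4 nt")
        if self.flank_len < 0:
            raise EnzymeConfigError("flank_len must be >= 0")
        iupac_to_regex(self.recognition)  # validates symbols

    @property
    def tag_length(self) -> int:
        return len(self.recognition) + 2 * self.flank_len

    @property
    def recognition_rc(self) -> str:
        """Recognition pattern as seen on the opposite strand."""
        return "".join(_IUPAC_COMPLEMENT[c] for c in self.recognition.upper())[::-1]


#: BcgI, the enzyme used for desk-scale 2bRAD work: CGA(N6)TGC core,
#: 12 nt flanks, 36 nt tags.
BCGI = EnzymeSpec(name="BcgI", recognition="CGANNNNNNTGC", flank_len=12)


def canonical_tag(tag: str) -> str:
    """Strand-independent identity of a tag.

    Returns the lexicographically smaller of the tag and its reverse
    complement; idempotent by construction.
    """
    rc = revcomp(tag)
    return tag if tag <= rc else rc


def find_tags(sequence: str, enzyme: EnzymeSpec) -> list[tuple[int, str, str]]:
    """Locate every recognition site on either strand and excise its tag.

    Parameters
    ----------
    sequence : str
        Genomic sequence (A/C/G/T/N, case-insensitive).
    enzyme : EnzymeSpec

    Returns
    -------
    list of (position, strand, tag)
        ``position`` is the 0-based start of the full tag window in
        forward coordinates; ``strand`` is ``"+"`` or ``"-"``; for
        minus-strand sites the tag is reported as read on the minus
        strand (reverse complement of the forward window).  Sites whose
        flanks extend past the sequence ends and tags containing N are
        skipped.  Overlapping sites each yield their own tag.
    """
    seq = sequence.upper()
    rlen = len(enzyme.recognition)
    flank = enzyme.flank_len
    hits: list[tuple[int, str, str]] = []
    # lookahead keeps overlapping site matches
    fwd = re.compile("(?=(" + iupac_to_regex(enzyme.recognition) + "))")
    rev = re.compile("(?=(" + iupac_to_regex(enzyme.recognition_rc) + "))")
    for strand, rx in (("+", fwd), ("-", rev)):
        for m in rx.finditer(seq):
            s = m.start()
            start = s - flank
            end = s + rlen + flank
            if start < 0 or end > len(seq):
                continue
            window = seq[start:end]
            if "N" in window:
                continue
            tag = window if strand == "+" else revcomp(window)
            hits.append((start, strand, tag))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits
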