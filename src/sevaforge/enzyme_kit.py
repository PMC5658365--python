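"""Restriction enzyme definitions and recognition-site scanning.

Type IIS enzymes cut at a fixed offset outside their recognition site,
which is what makes Golden Gate assembly possible: the 4-nt overhang a
cut exposes is user-designable sequence, not part of the recognition
site. Type IIP (orthodox palindromic) enzymes cut within their site.

Cut geometry convention: ``cut_top`` and ``cut_bottom`` are offsets in
nucleotides from the 3' end of the recognition site to the top- and
bottom-strand cuts. BsaI is GGTCTC(1/5): top cut 1 nt past the site,
bottom cut 5 nt past, leaving a 4-nt 5' overhang.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

from .dna import DsSeq, revcomp

__all__ = [
    "Enzyme",
    "SiteHit",
    "get_enzyme",
    "list_enzymes",
    "find_sites",
    "cleavable_sites",
    "ASSEMBLY_ENZYMES",
    "DEFAULT_ENZYME_PRIORITY",
]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


def _iupac_regex(pattern: str) -> re.Pattern:
    try:
        body = "".join(_IUPAC[c] for c in pattern.upper())
    except KeyError as e:
        raise ValueError(f"bad IUPAC symbol in recognition pattern: {e}") from None
    # lookahead so overlapping occurrences are all reported
    return re.compile(f"(?=({body}))")


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: recognition pattern plus cut geometry."""

    name: str
    recognition: str  # IUPAC, 5'->3'
    cut_top: int
    cut_bottom: int
    kind: str  # "IIS" (cuts outside) | "IIP" (cuts within / palindromic)

    def __post_init__(self):
        object.__setattr__(self, "recognition", self.recognition.upper())
        if self.kind not in ("IIS", "IIP"):
            raise ValueError(f"bad enzyme kind: {self.kind!r}")

    @property
    def overhang_length(self) -> int:
        """Signed: positive 5' overhang, negative 3', zero blunt."""
        return self.cut_bottom - self.cut_top

    @property
    def site_length(self) -> int:
        return len(self.recognition)

    @property
    def is_palindromic(self) -> bool:
        return self.recognition == revcomp(self.recognition)

    def __str__(self) -> str:  # e.g. "BsaI GGTCTC(1/5)"
        return f"{self.name} {self.recognition}({self.cut_top}/{self.cut_bottom})"


@dataclass(frozen=True)
class SiteHit:
    """One recognition-site occurrence with its cut coordinates.

    ``cut_top_pos`` is the cut index on the forward (top) strand and
    ``cut_bottom_pos`` the cut index on the reverse strand, both in
    forward-strand coordinates (an index i severs between bases i-1 and
    i). On circular sequences the coordinates are modulo the length.
    """

    enzyme: str
    strand: str  # "+" | "-"
    rec_start: int
    cut_top_pos: int
    cut_bottom_pos: int
    cleavable: bool = True

    def overhang_on(self, seq: DsSeq) -> str:
        """The excised overhang, spelled on the forward strand.

        For a 5' overhang this is exactly the protruding strand of the
        downstream fragment's left end read 5'->3'. Handles overhangs
        that wrap the origin of a circular molecule.
        """
        ov = get_enzyme(self.enzyme).overhang_length
        if ov == 0:
            return ""
        start = self.cut_top_pos if ov > 0 else self.cut_bottom_pos
        return seq.fetch(start, start + abs(ov))


# ---------------------------------------------------------------------------
# registry

def _load_registry() -> dict[str, Enzyme]:
    table = {}
    text = resources.files("sevaforge.data").joinpath("enzymes.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, pat, ct, cb, kind = line.split("\t")
        table[name] = Enzyme(name, pat, int(ct), int(cb), kind)
    return table


_REGISTRY: dict[str, Enzyme] = _load_registry()

#: The five assembly enzymes shipped with the toolbox; BtgZI is kept in
#: the registry but excluded from the validated default priority because
#: correct one-pot assembly could not be demonstrated with it.
ASSEMBLY_ENZYMES = ("BsaI", "BbsI", "BsmBI", "BtgZI", "AarI")
DEFAULT_ENZYME_PRIORITY = ("BsaI", "BbsI", "BsmBI", "AarI")


def get_enzyme(name: str | Enzyme) -> Enzyme:
    if isinstance(name, Enzyme):
        return name
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown enzyme {name!r}; registered: {', '.join(sorted(_REGISTRY))}") from None


def list_enzymes() -> list[Enzyme]:
    return sorted(_REGISTRY.values(), key=lambda e: e.name)


# ---------------------------------------------------------------------------
# scanning

def find_sites(seq: DsSeq, enzyme: str | Enzyme) -> list[SiteHit]:
    """Locate every recognition site of ``enzyme`` on both strands.

    Hits are returned in ascending ``rec_start`` order, '+' strand first
    on ties. Circular sequences are scanned across the origin (by
    scanning the doubled sequence and deduplicating modulo length).
    Hits on a linear sequence whose cut positions fall outside the
    molecule are reported with ``cleavable=False``.
    """
    enz = get_enzyme(enzyme)
    if len(seq) == 0:
        raise ValueError("empty sequence")
    n = len(seq)
    m = enz.site_length
    subject = seq.bases + seq.bases[: m - 1 + max(0, enz.cut_bottom, enz.cut_top)] \
        if seq.is_circular else seq.bases
    hits: list[SiteHit] = []

    fwd = _iupac_regex(enz.recognition)
    for mt in fwd.finditer(subject):
        r = mt.start()
        if seq.is_circular and r >= n:
            continue
        t = r + m + enz.cut_top
        b = r + m + enz.cut_bottom
        hits.append(_mk_hit(enz.name, "+", r, t, b, seq))

    if not enz.is_palindromic:
        rev = _iupac_regex(revcomp(enz.recognition))
        for mt in rev.finditer(subject):
            r = mt.start()
            if seq.is_circular and r >= n:
                continue
            # enzyme reads the bottom strand: its downstream is leftward
            t = r - enz.cut_bottom
            b = r - enz.cut_top
            hits.append(_mk_hit(enz.name, "-", r, t, b, seq))

    hits.sort(key=lambda h: (h.rec_start, 0 if h.strand == "+" else 1))
    return hits


def _mk_hit(name: str, strand: str, r: int, t: int, b: int, seq: DsSeq) -> SiteHit:
    n = len(seq)
    if seq.is_circular:
        return SiteHit(name, strand, r % n, t % n, b % n, True)
    cleavable = 0 <= min(t, b) and max(t, b) <= n
    return SiteHit(name, strand, r, t, b, cleavable)


def cleavable_sites(seq: DsSeq, enzyme: str | Enzyme) -> list[SiteHit]:
    """Only the hits whose cuts both land within the molecule."""
    return [h for h in find_sites(seq, enzyme) if h.cleavable]
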