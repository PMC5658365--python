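"""Independent brute-force oracles used to cross-check the engine.

These deliberately avoid the library's search/enumeration code paths:
site scanning tests every offset explicitly, assembly enumeration
iterates all fragment orderings x orientations, and genome surgery is
plain string slicing.
"""

from __future__ import annotations

from itertools import permutations, product

from sevaforge.digestion import digest
from sevaforge.dna import DsSeq, revcomp
from sevaforge.enzyme_kit import get_enzyme

_IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _matches_at(seq: str, pattern: str, i: int) -> bool:
    if i + len(pattern) > len(seq):
        return False
    return all(seq[i + k] in _IUPAC_SETS[p] for k, p in enumerate(pattern))


def brute_force_sites(seq: DsSeq, enzyme) -> set[tuple[str, int]]:
    """(strand, rec_start) of every recognition occurrence, by testing
    every offset on both strands explicitly."""
    enz = get_enzyme(enzyme)
    n = len(seq)
    subject = seq.bases + (seq.bases if seq.is_circular else "")
    limit = n if seq.is_circular else n - enz.site_length + 1
    out: set[tuple[str, int]] = set()
    rc_pat = revcomp(enz.recognition)
    for i in range(max(0, limit)):
        if _matches_at(subject, enz.recognition, i):
            out.add(("+", i))
        if not enz.is_palindromic and _matches_at(subject, rc_pat, i):
            out.add(("-", i))
    return out


def brute_force_assembly(parts, enzyme, max_size: int = 6) -> set[str]:
    """Canonical forms of every circular product, by exhausting all
    fragment subsets, orderings and orientations."""
    frags = []
    for part in parts:
        for f in digest(part.seq, [enzyme]):
            le, re_ = f.left_end, f.right_end
            if le.polarity == "five_prime" and re_.polarity == "five_prime" \
                    and le.overhang and re_.overhang:
                frags.append((f.seq.bases, le.overhang, re_.overhang))
    out: set[str] = set()
    idx = range(len(frags))
    for k in range(1, min(max_size, len(frags)) + 1):
        for combo in permutations(idx, k):
            if combo[0] != min(combo):
                continue  # fix rotation of the cycle
            for orients in product((0, 1), repeat=k):
                chain = []
                for i, o in zip(combo, orients):
                    bases, lo, ro = frags[i]
                    if o:  # reverse complement: ends swap and stay as-written
                        bases, lo, ro = revcomp(bases), ro, lo
                    chain.append((bases, lo, ro))
                if all(chain[i][2] == revcomp(chain[(i + 1) % k][1])
                       for i in range(k)):
                    circle = DsSeq("".join(c[0] for c in chain), "circular")
                    out.add(circle.canonical_form())
    return out


def string_surgery(genome: str, up: str, insert: str, down: str) -> str:
    """Slice-and-concatenate allelic replacement on plain strings."""
    i = genome.find(up)
    j = genome.find(down)
    assert i != -1 and j != -1 and genome.count(up) == 1 and genome.count(down) == 1
    return genome[: i + len(up)] + insert + genome[j:]
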