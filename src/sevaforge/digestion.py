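"""Digestion of duplex DNA into sticky-ended fragments, and ligation.

The model is purely geometric: a cut is a pair of strand-break
coordinates, a fragment is the duplex between consecutive cuts, and
ligation is allowed exactly when two ends carry complementary
single-stranded protrusions (or are both blunt). Ligase infidelity
(joining of mismatched overhangs) is never modelled.

Fragment bookkeeping convention: a fragment's ``bases`` are the forward
strand from its left top-strand cut to its right top-strand cut, so the
single-stranded region of each junction is counted exactly once across
a digest and simple string concatenation reconstitutes ligated
duplexes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .dna import BLUNT, DsSeq, EndSpec, Feature, revcomp
from .enzyme_kit import Enzyme, SiteHit, cleavable_sites, get_enzyme

__all__ = [
    "Fragment",
    "AmbiguousDigestionError",
    "digest",
    "ends_compatible",
    "join",
    "circularize",
    "ligate",
]


class AmbiguousDigestionError(ValueError):
    """Two cut windows overlap, making the fragment set ill-defined."""


@dataclass
class Fragment:
    """A linear digestion product plus provenance.

    ``seq`` carries the two EndSpecs. The degenerate uncut case (a
    circular molecule with no cleavable site) is returned as a single
    fragment with ``uncut=True`` and a circular ``seq``.
    """

    seq: DsSeq
    source: Optional[str] = None
    role: Optional[str] = None
    cuts: tuple[SiteHit, ...] = ()
    uncut: bool = False

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def left_end(self) -> EndSpec:
        return self.seq.left_end or BLUNT

    @property
    def right_end(self) -> EndSpec:
        return self.seq.right_end or BLUNT

    def reverse_complement(self) -> "Fragment":
        return replace(self, seq=self.seq.reverse_complement())


# ---------------------------------------------------------------------------
# digestion

def _junction(hit: SiteHit, n: int, circular: bool) -> tuple[int, int, int]:
    """(top_cut, bottom_cut_unwrapped, signed_overhang) for one hit.

    ``bottom`` is expressed relative to ``top`` without modulo so the
    single-stranded window [min, max) can be sliced cyclically.
    """
    ov = get_enzyme(hit.enzyme).overhang_length
    t = hit.cut_top_pos
    b = t + ov  # == hit.cut_bottom_pos modulo n
    return t, b, ov


def digest(seq: DsSeq, enzymes: Sequence[Enzyme | str]) -> list[Fragment]:
    """Cut ``seq`` with every cleavable site of the given enzymes.

    A circular input with n cut pairs yields n fragments; a linear input
    yields n+1. Each junction's two new ends carry complementary
    EndSpecs. Fragments are ordered by cut coordinate. Raises
    :class:`AmbiguousDigestionError` when two enzymes cut within each
    other's overhang window.
    """
    hits: list[SiteHit] = []
    for e in enzymes:
        hits.extend(cleavable_sites(seq, e))
    if not hits:
        if seq.is_circular:
            return [Fragment(seq=seq, uncut=True)]
        return [Fragment(seq=seq, uncut=True)]

    n = len(seq)
    juncs = sorted(
        (_junction(h, n, seq.is_circular) + (h,) for h in hits),
        key=lambda j: (min(j[0], j[1]), max(j[0], j[1])),
    )
    # reject duplicate or overlapping cut windows
    windows = [(min(t, b), max(t, b), h) for t, b, _, h in juncs]
    for (a1, b1, h1), (a2, b2, h2) in zip(windows, windows[1:]):
        if a2 < b1 or (a1, b1) == (a2, b2):
            raise AmbiguousDigestionError(
                f"overlapping cut windows at {a1}-{b1} ({h1.enzyme}) and {a2}-{b2} ({h2.enzyme})"
            )
    if seq.is_circular and len(windows) > 1:
        a_first, b_first, h_first = windows[0]
        a_last, b_last, h_last = windows[-1]
        if b_last > n and (b_last % n) > a_first:
            raise AmbiguousDigestionError(
                f"overlapping cut windows across origin: {a_last}-{b_last} ({h_last.enzyme}) "
                f"and {a_first}-{b_first} ({h_first.enzyme})"
            )

    def left_endspec(t: int, b: int) -> EndSpec:
        if b > t:  # 5' overhang: protruding top strand
            return EndSpec("five_prime", seq.fetch(t, b) if not seq.is_circular else seq.fetch(t, b))
        if b < t:  # 3' overhang: protruding bottom strand
            return EndSpec("three_prime", revcomp(seq.fetch(b, t)))
        return BLUNT

    def right_endspec(t: int, b: int) -> EndSpec:
        if b > t:
            return EndSpec("five_prime", revcomp(seq.fetch(t, b)))
        if b < t:
            return EndSpec("three_prime", seq.fetch(b, t))
        return BLUNT

    def features_in(start: int, span: int) -> list[Feature]:
        out = []
        for f in seq.features:
            fs = (f.start - start) % n if seq.is_circular else f.start - start
            fe = fs + (f.end - f.start)
            if 0 <= fs and fe <= span:
                out.append(Feature(f.label, fs, fe, f.strand))
        return out

    frags: list[Fragment] = []
    if seq.is_circular:
        for (t1, b1, _, h1), (t2, b2, _, h2) in zip(juncs, juncs[1:] + juncs[:1]):
            span = (t2 - t1) % n or n
            frags.append(Fragment(
                seq=DsSeq(seq.fetch(t1, t1 + span), "linear",
                          left_end=left_endspec(t1, b1),
                          right_end=right_endspec(t2, b2),
                          features=features_in(t1, span)),
                cuts=(h1, h2),
            ))
    else:
        bounds = [(0, None)] + [(t, (t, b)) for t, b, _, _ in juncs] + [(n, None)]
        cut_specs = [None] + [(t, b) for t, b, _, _ in juncs] + [None]
        cut_hits = [None] + [h for _, _, _, h in juncs] + [None]
        for i in range(len(bounds) - 1):
            start = bounds[i][0]
            stop = bounds[i + 1][0]
            if stop - start <= 0:
                raise AmbiguousDigestionError(
                    f"degenerate cut at linear terminus (position {start})")
            le = left_endspec(*cut_specs[i]) if cut_specs[i] else (seq.left_end or BLUNT)
            re_ = right_endspec(*cut_specs[i + 1]) if cut_specs[i + 1] else (seq.right_end or BLUNT)
            hs = tuple(h for h in (cut_hits[i], cut_hits[i + 1]) if h is not None)
            frags.append(Fragment(
                seq=DsSeq(seq.bases[start:stop], "linear", left_end=le, right_end=re_,
                          features=features_in(start, stop - start)),
                cuts=hs,
            ))
    return frags


# ---------------------------------------------------------------------------
# ligation

def ends_compatible(a: EndSpec, b: EndSpec) -> bool:
    """True iff the two ends can anneal and be sealed by ligase.

    Two sticky ends are compatible iff they have the same polarity and
    one protruding strand is the reverse complement of the other.
    Blunt-blunt is compatible.
    """
    if a.is_blunt and b.is_blunt:
        return True
    if a.polarity != b.polarity:
        return False
    if len(a.overhang) != len(b.overhang):
        return False
    return a.overhang == revcomp(b.overhang)


def join(a: Fragment, b: Fragment, scar_label: str = "scar") -> Fragment:
    """Ligate ``a``'s right end to ``b``'s left end into one fragment.

    The junction's 4-nt scar is annotated so loss of recognition sites
    in assembled products can be checked by scanning.
    """
    if a.uncut or b.uncut:
        raise ValueError("cannot ligate an uncut circular fragment")
    if not ends_compatible(a.right_end, b.left_end):
        raise ValueError(f"incompatible ends: {a.right_end} vs {b.left_end}")
    off = len(a)
    feats = list(a.seq.features)
    feats += [Feature(f.label, f.start + off, f.end + off, f.strand) for f in b.seq.features]
    oh = b.left_end.overhang
    if oh:
        feats.append(Feature(f"{scar_label}:{oh}", off, off + len(oh), 1))
    merged = DsSeq(a.seq.bases + b.seq.bases, "linear",
                   left_end=a.left_end, right_end=b.right_end, features=feats)
    return Fragment(seq=merged,
                    source=a.source if a.source == b.source else None,
                    cuts=a.cuts + b.cuts)


def circularize(frag: Fragment, scar_label: str = "scar") -> DsSeq:
    """Seal a fragment's two ends together, yielding a circular DsSeq."""
    if not ends_compatible(frag.right_end, frag.left_end):
        raise ValueError(
            f"ends not self-compatible: {frag.right_end} vs {frag.left_end}")
    feats = list(frag.seq.features)
    oh = frag.left_end.overhang
    if oh:
        feats.append(Feature(f"{scar_label}:{oh}", 0, len(oh), 1))
    return DsSeq(frag.seq.bases, "circular", features=feats)


def ligate(a: Fragment, b: Optional[Fragment] = None):
    """Join two fragments, or circularize one (``b=None``)."""
    if b is None:
        return circularize(a)
    return join(a, b)
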