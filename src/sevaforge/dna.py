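"""Double-stranded DNA containers with topology and typed sticky ends.

All coordinates are 0-based, half-open, on the forward strand. Circular
arithmetic is modulo the sequence length. Sequences hold concrete bases
only (ACGT); IUPAC ambiguity codes are reserved for enzyme recognition
patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

__all__ = [
    "COMPLEMENT",
    "revcomp",
    "EndSpec",
    "Feature",
    "DsSeq",
    "BLUNT",
]

COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

_VALID_BASES = frozenset("ACGT")


def revcomp(s: str) -> str:
    """Reverse complement of a concrete-base string."""
    return s.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class EndSpec:
    """One terminus of a linear duplex.

    ``overhang`` is read 5'->3' on the protruding strand; it is empty
    if and only if the end is blunt.
    """

    polarity: str  # "five_prime" | "three_prime" | "blunt"
    overhang: str = ""

    def __post_init__(self):
        if self.polarity not in ("five_prime", "three_prime", "blunt"):
            raise ValueError(f"bad end polarity: {self.polarity!r}")
        oh = self.overhang.upper()
        object.__setattr__(self, "overhang", oh)
        if len(oh) > 10:
            raise ValueError("overhang longer than 10 nt")
        if (self.polarity == "blunt") != (oh == ""):
            raise ValueError("blunt iff empty overhang")
        if set(oh) - _VALID_BASES:
            raise ValueError(f"non-ACGT overhang: {oh!r}")

    @property
    def is_blunt(self) -> bool:
        return self.polarity == "blunt"


BLUNT = EndSpec("blunt", "")


@dataclass(frozen=True)
class Feature:
    """A labelled interval on the forward coordinate system."""

    label: str
    start: int
    end: int
    strand: int = 1  # +1 forward, -1 reverse


@dataclass
class DsSeq:
    """Annotated double-stranded DNA, linear or circular.

    ``bases`` is the forward strand 5'->3'. Linear molecules carry an
    :class:`EndSpec` at each terminus; circular molecules carry none.
    Features that wrap the origin of a circular molecule are stored as
    two segments sharing a label.
    """

    bases: str
    topology: str = "linear"  # "linear" | "circular"
    left_end: Optional[EndSpec] = None
    right_end: Optional[EndSpec] = None
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self):
        self.bases = self.bases.upper()
        if set(self.bases) - _VALID_BASES:
            bad = sorted(set(self.bases) - _VALID_BASES)
            raise ValueError(f"sequence contains non-ACGT symbols: {bad}")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"bad topology: {self.topology!r}")
        if self.is_circular:
            if self.left_end is not None or self.right_end is not None:
                raise ValueError("circular sequences carry no end specs")
        else:
            if self.left_end is None:
                self.left_end = BLUNT
            if self.right_end is None:
                self.right_end = BLUNT
        n = len(self.bases)
        for f in self.features:
            # zero-length features mark insertion points (e.g. a deletion-0 locus)
            if not (0 <= f.start <= f.end <= n):
                raise ValueError(f"feature {f.label!r} out of bounds: [{f.start},{f.end}) in length {n}")

    # -- basics ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.bases)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def fetch(self, start: int, end: int) -> str:
        """Forward-strand slice; wraps the origin on circular molecules.

        ``end`` may exceed the length (or ``start`` be negative) on
        circular sequences; spans of up to one full length are supported.
        """
        n = len(self.bases)
        if self.is_circular:
            span = end - start
            if span < 0 or span > n:
                raise ValueError(f"bad circular span [{start},{end}) on length {n}")
            start %= n
            doubled = self.bases + self.bases
            return doubled[start:start + span]
        if start < 0 or end > n or start > end:
            raise ValueError(f"slice [{start},{end}) outside linear sequence of length {n}")
        return self.bases[start:end]

    # -- transforms -----------------------------------------------------
    def reverse_complement(self) -> "DsSeq":
        n = len(self.bases)
        feats = [Feature(f.label, n - f.end, n - f.start, -f.strand) for f in self.features]
        if self.is_circular:
            return DsSeq(revcomp(self.bases), "circular", features=feats)
        return DsSeq(
            revcomp(self.bases), "linear",
            left_end=self.right_end, right_end=self.left_end, features=feats,
        )

    def rotated(self, k: int) -> "DsSeq":
        """Rotate a circular molecule so old position ``k`` becomes 0."""
        if not self.is_circular:
            raise ValueError("only circular sequences can be rotated")
        n = len(self.bases)
        k %= n
        feats: list[Feature] = []
        for f in self.features:
            if f.start == f.end:
                p = (f.start - k) % n
                feats.append(Feature(f.label, p, p, f.strand))
                continue
            s, e = (f.start - k) % n, (f.end - k) % n
            if e == 0:
                e = n
            if s < e:
                feats.append(Feature(f.label, s, e, f.strand))
            else:  # wraps the new origin: store as two segments
                feats.append(Feature(f.label, s, n, f.strand))
                feats.append(Feature(f.label, 0, e, f.strand))
        return DsSeq(self.bases[k:] + self.bases[:k], "circular", features=feats)

    def annotate(self, label: str, start: int, end: int, strand: int = 1) -> "DsSeq":
        self.features.append(Feature(label, start, end, strand))
        return self

    def feature_labels(self) -> list[str]:
        return [f.label for f in self.features]

    def find_feature(self, label: str) -> Feature:
        hits = [f for f in self.features if f.label == label]
        if not hits:
            raise KeyError(f"no feature labelled {label!r}")
        if len(hits) > 1:
            raise KeyError(f"feature label {label!r} is ambiguous ({len(hits)} hits)")
        return hits[0]

    # -- identity -------------------------------------------------------
    def canonical_form(self) -> str:
        """Rotation/strand-invariant identity string.

        For circular molecules: the lexicographically smallest rotation
        of the forward strand, compared against the same for the reverse
        complement, taking the smaller. For linear molecules: the smaller
        of forward and reverse-complement strands.
        """
        if not self.is_circular:
            return min(self.bases, revcomp(self.bases))
        return min(_least_rotation(self.bases), _least_rotation(revcomp(self.bases)))


def _least_rotation(s: str) -> str:
    """Booth's algorithm: lexicographically least rotation in O(n)."""
    if not s:
        return s
    d = s + s
    n = len(s)
    f = [-1] * len(d)
    k = 0
    for j in range(1, len(d)):
        sj = d[j]
        i = f[j - k - 1]
        while i != -1 and sj != d[k + i + 1]:
            if sj < d[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != d[k + i + 1]:
            if sj < d[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return d[k:k + n]
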