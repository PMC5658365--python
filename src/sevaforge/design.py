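"""Design of assembly-ready integration constructs.

Given a genome and a target locus this module extracts homology arms,
picks the first assembly enzyme free of internal sites, designs PCR
primers whose 5' tails install the type IIS sites and fusion-site
overhangs, synthesizes MCS-IIS polylinkers, and validates vectors
against the SEVA architecture rules.

Primer tail layout (5'->3'): [pad][recognition site][spacer][fusion
overhang][annealing region]. The spacer length equals the enzyme's
top-strand cut offset, so digestion of the PCR product exposes exactly
the intended 4-nt junction overhang. The annealing region is grown
from 18 nt until its nearest-neighbor melting temperature reaches
60 degC (0.5 uM primer, 50 mM monovalent salt) or 30 nt is reached.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.SeqUtils import MeltingTemp as _mt

from . import registry
from .dna import DsSeq, Feature, revcomp
from .enzyme_kit import (DEFAULT_ENZYME_PRIORITY, Enzyme, cleavable_sites,
                         find_sites, get_enzyme)
from .digestion import digest

__all__ = [
    "ArmLengthWarning",
    "LocusSpec",
    "PrimerPair",
    "EnzymeSelection",
    "DesignReport",
    "ComplianceFinding",
    "ComplianceReport",
    "extract_arms",
    "select_enzyme",
    "design_primers",
    "design_mcs_iis",
    "simulate_pcr",
    "amplify_arms",
    "check_seva_compliance",
    "design_integration_vector",
    "RECOMMENDED_ARM_LENGTH",
    "MINIMUM_ARM_LENGTH",
]

#: ~400 bp of identity is needed for efficient double-crossover
#: integration; 70 bp can sometimes suffice but at sharply reduced
#: efficiency, so it is the hard floor.
RECOMMENDED_ARM_LENGTH = 400
MINIMUM_ARM_LENGTH = 70


class ArmLengthWarning(UserWarning):
    """Arm shorter than the recommended 400 bp."""


# ---------------------------------------------------------------------------
# homology arms

@dataclass
class LocusSpec:
    """A deletion interval (or feature) on a genome plus arm length."""

    genome: DsSeq
    start: Optional[int] = None
    end: Optional[int] = None
    feature: Optional[str] = None
    arm_length: int = RECOMMENDED_ARM_LENGTH
    up_arm_length: Optional[int] = None  # override per side
    down_arm_length: Optional[int] = None

    def interval(self) -> tuple[int, int]:
        if self.feature is not None:
            f = self.genome.find_feature(self.feature)
            return f.start, f.end
        if self.start is None or self.end is None:
            raise ValueError("LocusSpec needs either an interval or a feature name")
        return self.start, self.end


def extract_arms(locus: LocusSpec) -> tuple[DsSeq, DsSeq]:
    """The two homology arms flanking the deletion interval.

    ``up`` is the bases immediately 5' of the interval, ``down``
    immediately 3', both on the forward strand. A warning is attached
    when an arm is below 400 bp; below the 70 bp floor is an error.
    """
    genome = locus.genome
    start, end = locus.interval()
    n = len(genome)
    if not (0 <= start <= end <= n):
        raise ValueError(f"interval [{start},{end}) outside genome of length {n}")
    up_len = locus.up_arm_length or locus.arm_length
    down_len = locus.down_arm_length or locus.arm_length
    for L in (up_len, down_len):
        if L < MINIMUM_ARM_LENGTH:
            raise ValueError(
                f"arm length {L} below the {MINIMUM_ARM_LENGTH} bp floor for "
                f"homologous recombination")
        if L < RECOMMENDED_ARM_LENGTH:
            warnings.warn(
                f"arm length {L} < {RECOMMENDED_ARM_LENGTH} bp: not recommended, "
                f"integration efficiency is significantly reduced", ArmLengthWarning,
                stacklevel=2)
    if not genome.is_circular and (start - up_len < 0 or end + down_len > n):
        raise ValueError("arms extend past the ends of a linear genome")
    up = DsSeq(genome.fetch(start - up_len, start), "linear",
               features=[Feature("up_arm", 0, up_len)])
    down = DsSeq(genome.fetch(end, end + down_len), "linear",
                 features=[Feature("down_arm", 0, down_len)])
    return up, down


# ---------------------------------------------------------------------------
# enzyme selection

@dataclass(frozen=True)
class EnzymeSelection:
    enzyme: Enzyme
    site_counts: dict  # enzyme name -> total cleavable sites over all inputs


def select_enzyme(sequences: Sequence[DsSeq],
                  candidates: Optional[Sequence[str | Enzyme]] = None) -> EnzymeSelection:
    """First candidate enzyme with zero cleavable sites in every input.

    The default priority BsaI > BbsI > BsmBI > AarI reflects assembly
    efficiency (the first three >95%, AarI lower activity); BtgZI is
    never auto-selected.
    """
    cands = [get_enzyme(c) for c in (candidates or DEFAULT_ENZYME_PRIORITY)]
    counts: dict[str, int] = {}
    chosen = None
    for enz in cands:
        total = sum(len(cleavable_sites(s, enz)) for s in sequences)
        counts[enz.name] = total
        if total == 0 and chosen is None:
            chosen = enz
    if chosen is None:
        raise ValueError(
            f"every candidate enzyme has internal sites ({counts}); remove sites "
            f"or use the storage-vector route (blunt into EcoRV of pSEVA243X/Y)")
    return EnzymeSelection(chosen, counts)


# ---------------------------------------------------------------------------
# MCS-IIS synthesis

_SPACER_WHEEL = "ATCAGTCATGACTGAC"  # fixed rotation for spacers/pads


def _spacer(length: int, variant: int) -> str:
    if length == 0:
        return ""
    w = _SPACER_WHEEL
    start = (variant * 3) % len(w)
    s = (w[start:] + w[:start]) * (length // len(w) + 1)
    return s[:length]


def design_mcs_iis(enzymes: Sequence[str | Enzyme], overhang: str,
                   side: str = "left", length_cap: int = 120) -> DsSeq:
    """A polylinker in which every enzyme excises the same overhang.

    Each enzyme contributes one block positioned so its cut exposes the
    given 4-nt overhang: ``[recognition][spacer == cut_top nt][overhang]``
    for a ``left``-side MCS (sites cut rightward into the downstream
    segment), mirrored for ``right``. Placement is greedy left-to-right
    with minimal spacers and is deterministic for fixed inputs; spacer
    variants are retried when a spacer accidentally creates an extra
    recognition site.
    """
    enzs = [get_enzyme(e) for e in enzymes]
    overhang = overhang.upper()
    for e in enzs:
        if e.kind != "IIS" or e.overhang_length != 4:
            raise ValueError(f"{e.name} is not a 4-nt 5'-overhang type IIS enzyme")
    if len(overhang) != 4 or overhang == revcomp(overhang):
        raise ValueError("overhang must be 4 nt and non-palindromic")
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")

    for variant in range(16):
        if side == "left":
            blocks = [e.recognition + _spacer(e.cut_top, variant + i) + overhang
                      for i, e in enumerate(enzs)]
        else:
            blocks = [overhang + _spacer(e.cut_top, variant + i) + revcomp(e.recognition)
                      for i, e in enumerate(reversed(enzs))]
        seq_str = "".join(blocks)
        if len(seq_str) > length_cap:
            raise ValueError(
                f"MCS-IIS for {len(enzs)} enzymes needs {len(seq_str)} nt, "
                f"over the {length_cap} nt cap")
        mcs = DsSeq(seq_str, "linear")
        if _mcs_ok(mcs, enzs, overhang, side):
            return mcs
    raise ValueError(
        f"could not place {len(enzs)} recognition sites without creating "
        f"spurious sites within {length_cap} nt")


def _mcs_ok(mcs: DsSeq, enzs: list[Enzyme], overhang: str, side: str) -> bool:
    want_strand = "+" if side == "left" else "-"
    for e in enzs:
        hits = find_sites(mcs, e)
        if len(hits) != 1 or hits[0].strand != want_strand:
            return False
        t = hits[0].cut_top_pos
        # cut may reach past the bare polylinker; check the overhang in context
        lo, hi = t, t + 4
        if lo < 0 or hi > len(mcs):
            return False
        if mcs.bases[lo:hi] != overhang:
            return False
    return True


# ---------------------------------------------------------------------------
# primers and PCR

#: junction letters flanking each arm: (outer/left, inner/right)
ARM_JUNCTIONS = {"up": ("B", "C"), "down": ("E", "F")}


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse primers with type IIS tails for one arm."""

    forward: str
    reverse: str
    side: str
    enzyme: str
    pad: str
    fwd_overhang: str  # junction overhang installed by the forward tail
    rev_overhang: str  # junction overhang installed by the reverse tail
    fwd_anneal_len: int
    rev_anneal_len: int
    fwd_tm: float
    rev_tm: float

    @property
    def fwd_tail_len(self) -> int:
        return len(self.forward) - self.fwd_anneal_len

    @property
    def rev_tail_len(self) -> int:
        return len(self.reverse) - self.rev_anneal_len


def _tm(seq: str) -> float:
    return _mt.Tm_NN(seq, Na=50, dnac1=500, dnac2=0)


def _anneal_region(template: str, tm_target: float, lo: int, hi: int) -> tuple[str, float]:
    if len(template) < lo:
        raise ValueError(f"arm shorter than the minimum annealing length {lo}")
    hi = min(hi, len(template))
    region = template[:lo]
    tm = _tm(region)
    n = lo
    while tm < tm_target and n < hi:
        n += 1
        region = template[:n]
        tm = _tm(region)
    return region, tm


def design_primers(arm: DsSeq, side: str, enzyme: str | Enzyme,
                   tm_target: float = 60.0, anneal_min: int = 18,
                   anneal_max: int = 30, pad_len: int = 4) -> PrimerPair:
    """Primers that PCR-amplify ``arm`` with assembly-ready IIS tails.

    The returned pair is verified before return: a simulated PCR of the
    arm followed by digestion with the chosen enzyme must yield the arm
    flanked by exactly the intended fusion-site overhangs.
    """
    enz = get_enzyme(enzyme)
    if side not in ARM_JUNCTIONS:
        raise ValueError("side must be 'up' or 'down'")
    left_j, right_j = ARM_JUNCTIONS[side]
    left_oh = registry.fusion_overhang(left_j)
    right_oh = registry.fusion_overhang(right_j)

    fwd_anneal, fwd_tm = _anneal_region(arm.bases, tm_target, anneal_min, anneal_max)
    rev_anneal, rev_tm = _anneal_region(revcomp(arm.bases), tm_target, anneal_min, anneal_max)

    last_err = None
    for variant in range(16):
        pad = _spacer(pad_len, variant)
        fwd = pad + enz.recognition + _spacer(enz.cut_top, variant + 1) + left_oh + fwd_anneal
        rev = pad + enz.recognition + _spacer(enz.cut_top, variant + 2) + revcomp(right_oh) + rev_anneal
        pair = PrimerPair(fwd, rev, side, enz.name, pad, left_oh, right_oh,
                          len(fwd_anneal), len(rev_anneal), fwd_tm, rev_tm)
        try:
            _verify_primer_pair(pair, arm, enz, left_oh, right_oh)
            return pair
        except ValueError as e:
            last_err = e
    raise ValueError(f"no tail variant avoids spurious {enz.name} sites: {last_err}")


def _verify_primer_pair(pair: PrimerPair, arm: DsSeq, enz: Enzyme,
                        left_oh: str, right_oh: str) -> None:
    product = simulate_pcr(arm, pair)
    hits = cleavable_sites(product, enz)
    if len(hits) != 2:
        raise ValueError(f"PCR product carries {len(hits)} {enz.name} sites, expected 2")
    frags = digest(product, [enz])
    if len(frags) != 3:
        raise ValueError(f"digestion yielded {len(frags)} fragments, expected 3")
    mid = frags[1]
    if mid.left_end.overhang != left_oh or mid.right_end.overhang != revcomp(right_oh):
        raise ValueError(
            f"excised overhangs {mid.left_end.overhang}/{mid.right_end.overhang} "
            f"do not match junctions {left_oh}/{right_oh}")
    if mid.seq.bases != left_oh + arm.bases:
        raise ValueError("excised fragment does not reproduce the arm")


def simulate_pcr(template: DsSeq, primers: PrimerPair | tuple[str, str],
                 anneal_lens: Optional[tuple[int, int]] = None) -> DsSeq:
    """Exact-match PCR: forward primer anneals on the top strand, the
    reverse primer on the bottom; the product spans from the forward
    annealing site to the reverse one, with both full primer sequences
    (tails included) at its ends.
    """
    if isinstance(primers, PrimerPair):
        fwd, rev = primers.forward, primers.reverse
        la, lb = primers.fwd_anneal_len, primers.rev_anneal_len
    else:
        fwd, rev = primers
        if anneal_lens is None:
            raise ValueError("anneal_lens required when passing bare primer strings")
        la, lb = anneal_lens
    fa, ra = fwd[-la:].upper(), rev[-lb:].upper()
    subject = template.bases + (template.bases if template.is_circular else "")
    n = len(template)

    fpos = _unique_pos(subject, fa, n, "forward primer")
    rpos = _unique_pos(subject, revcomp(ra), n, "reverse primer")
    rend = rpos + lb
    if template.is_circular and rend <= fpos:
        rend += n
    if rend <= fpos:
        raise ValueError("reverse primer anneals upstream of the forward primer")
    product = fwd[:-la] + subject[fpos:rend] + revcomp(rev[:-lb] or "")
    feats = []
    off = len(fwd) - la - fpos
    for f in template.features:
        if fpos <= f.start and f.end <= rend:
            feats.append(Feature(f.label, f.start + off, f.end + off, f.strand))
    return DsSeq(product, "linear", features=feats)


def _unique_pos(subject: str, needle: str, n: int, what: str) -> int:
    first = subject.find(needle)
    if first == -1:
        raise ValueError(f"{what} does not anneal to the template")
    # count occurrences within one period
    count = 0
    i = subject.find(needle)
    while i != -1 and i < n:
        count += 1
        i = subject.find(needle, i + 1)
    if count > 1:
        raise ValueError(f"{what} anneals at {count} template positions")
    return first


# ---------------------------------------------------------------------------
# SEVA compliance

@dataclass(frozen=True)
class ComplianceFinding:
    kind: str  # "forbidden_site" | "part_order" | "orientation"
    message: str
    position: Optional[int] = None


@dataclass(frozen=True)
class ComplianceReport:
    passed: bool
    findings: tuple[ComplianceFinding, ...]


#: canonical circular part order of a final integrative vector
PART_ORDER = ("up_arm", "cargo", "bsu_marker", "down_arm",
              "T0", "ecoli_marker", "oriT", "ori", "T1")

_LABEL_CANON = {
    "up_arm": "up_arm", "down_arm": "down_arm",
    "T0": "T0", "T1": "T1", "oriT": "oriT", "ori": "ori",
    "bla": "ecoli_marker", "neo": "ecoli_marker", "ecoli_marker": "ecoli_marker",
    "mRFP1": "cargo", "mkate2": "cargo", "cargo": "cargo",
}


def _canon_label(label: str) -> Optional[str]:
    base = label.split(":")[0]
    if base in _LABEL_CANON:
        return _LABEL_CANON[base]
    if base.startswith("bsu_marker"):
        return "bsu_marker"
    if base.startswith("lacZ") or base.startswith("cargo"):
        return "cargo"
    return None


def check_seva_compliance(vector: DsSeq,
                          forbidden: Optional[Sequence[str | Enzyme]] = None) -> ComplianceReport:
    """Scan a vector for forbidden restriction sites and layout violations.

    Forbidden-enzyme sites are sanctioned only in the inter-part linkers
    (the SEVA boundary positions); any occurrence overlapping a part
    feature is reported. Part order and the counter-oriented Bacillus
    marker are checked against the canonical layout.
    """
    if not vector.features:
        raise ValueError("vector carries no part annotations; annotate before validating")
    enzymes = [get_enzyme(e) for e in (forbidden if forbidden is not None
                                       else registry.forbidden_enzymes())]
    findings: list[ComplianceFinding] = []
    n = len(vector)
    for enz in enzymes:
        for hit in find_sites(vector, enz):
            lo, hi = hit.rec_start, hit.rec_start + enz.site_length
            for f in vector.features:
                fs, fe = f.start, f.end
                # cyclic overlap test (recognition interval may wrap)
                overlaps = any(
                    max(lo + k, fs) < min(hi + k, fe) for k in (-n, 0, n)
                ) if vector.is_circular else max(lo, fs) < min(hi, fe)
                if overlaps:
                    findings.append(ComplianceFinding(
                        "forbidden_site",
                        f"{enz.name} site at {hit.rec_start} inside part {f.label!r}",
                        hit.rec_start))
                    break

    placed = []
    for f in vector.features:
        canon = _canon_label(f.label)
        if canon in PART_ORDER:
            placed.append((f.start, canon, f))
    placed.sort()
    order = [c for _, c, _ in placed]
    expected = [p for p in PART_ORDER if p in order]
    if order and expected:
        # compare cyclically, anchored on the first expected part present
        anchor = expected[0]
        i = order.index(anchor)
        rotated = order[i:] + order[:i]
        if rotated != expected:
            findings.append(ComplianceFinding(
                "part_order",
                f"part order {rotated} deviates from canonical {expected}"))
    try:
        cargo = next(f for _, c, f in placed if c == "cargo")
        bsu = next(f for _, c, f in placed if c == "bsu_marker")
        if bsu.strand == cargo.strand:
            findings.append(ComplianceFinding(
                "orientation",
                "Bacillus marker must be transcribed opposite to the cargo",
                bsu.start))
    except StopIteration:
        pass
    return ComplianceReport(passed=not findings, findings=tuple(findings))


# ---------------------------------------------------------------------------
# end-to-end design report

@dataclass
class DesignReport:
    enzyme: str
    site_counts: dict
    up_arm: DsSeq
    down_arm: DsSeq
    up_primers: PrimerPair
    down_primers: PrimerPair
    suggested_name: str
    warnings: tuple[str, ...] = ()


def design_integration_vector(genome: DsSeq, locus: LocusSpec,
                              cargo_part: str = "pBSc241M",
                              dest_part: str = "pBSd141R",
                              extra_sequences: Sequence[DsSeq] = (),
                              candidates: Optional[Sequence[str]] = None) -> DesignReport:
    """Full design: arms, enzyme choice, primers, and a suggested name."""
    cargo_rec = registry.lookup(cargo_part)
    dest_rec = registry.lookup(dest_part)
    notes: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ArmLengthWarning)
        up, down = extract_arms(locus)
        notes.extend(str(w.message) for w in caught)
    sel = select_enzyme([up, down, *extra_sequences], candidates)
    up_primers = design_primers(up, "up", sel.enzyme)
    down_primers = design_primers(down, "down", sel.enzyme)
    name = registry.encode_name(registry.SevaName(
        prefix="pBS",
        ecoli_marker_digit=dest_rec.ecoli_marker_digit,
        ori_digit=dest_rec.ori_digit,
        cargo_digit=cargo_rec.cargo_digit,
        bsu_marker=cargo_rec.bsu_marker_letter,
        locus=locus.feature,
    ))
    return DesignReport(sel.enzyme.name, sel.site_counts, up, down,
                        up_primers, down_primers, name, tuple(notes))


def amplify_arms(genome: DsSeq, report: DesignReport) -> tuple[DsSeq, DsSeq]:
    """Simulated PCR of both arms off the genome, arm features annotated.

    The returned linear products are assembly-ready up/down entry parts.
    """
    out = []
    for primers, arm, label in ((report.up_primers, report.up_arm, "up_arm"),
                                (report.down_primers, report.down_arm, "down_arm")):
        product = simulate_pcr(genome, primers)
        tail = primers.fwd_tail_len
        product.features.append(Feature(label, tail, tail + len(arm)))
        out.append(product)
    return tuple(out)
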