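"""Deterministic synthetic fixtures: toy genomes and entry-part sets.

Everything here is desk-scale stand-in data, generated from a seed with
integer/string operations only (no float or locale dependence beyond
GC-weighted base draws from a seeded PRNG). Placeholder genes (bla,
neo, mRFP1, mkate2, lacZalpha) are short labelled sentinel sequences,
not real ORFs: the screening and classification logic keys on feature
labels, so sequence realism is unnecessary. Generated sequences are
scrubbed of assembly-enzyme recognition sites except those placed on
purpose, so digestion fragment sets are fully under test control.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from . import registry
from .assembly import AssemblyPlan, Part, golden_gate
from .dna import DsSeq, Feature, revcomp
from .design import _spacer  # fixed spacer wheel shared with primer design
from .enzyme_kit import ASSEMBLY_ENZYMES, find_sites, get_enzyme

__all__ = ["FixtureConfig", "EntrySet", "make_toy_genome", "make_entry_set"]

#: enzymes scrubbed from every random span so cut sites appear only
#: where a fixture plants them
_SCRUB = tuple(ASSEMBLY_ENZYMES) + ("ApaI", "AscI", "SwaI", "MluI")


@dataclass
class FixtureConfig:
    """Study conditions for the synthetic fixtures."""

    seed: int = 1
    genome_length: int = 20_000
    gc_fraction: float = 0.435  # B. subtilis-like base composition
    #: (name, deletion-interval length); the prophage-scale locus mirrors
    #: the ~130 kb SPbeta deletion when sized accordingly
    loci: tuple[tuple[str, int], ...] = (("amyE", 0), ("prophage", 12_000))
    arm_length: int = 400
    assembly_enzyme: str = "BsaI"
    cargo_marker_letter: str = "M"
    cargo_reporter: Optional[str] = None  # None -> default MCS; "lacZalpha_star"; "mkate2"
    sentinel_length: int = 60
    genome_topology: str = "circular"


@dataclass
class EntrySet:
    """Four entry parts ready for a one-pot assembly."""

    up: Part
    down: Part
    cargo: Part
    destination: Part
    enzyme: str

    @property
    def parts(self) -> list[Part]:
        return [self.up, self.down, self.cargo, self.destination]

    def plan(self, **kw) -> AssemblyPlan:
        return AssemblyPlan(parts=self.parts, enzyme=self.enzyme, **kw)


# ---------------------------------------------------------------------------
# random sequence helpers

def _rand_seq(rng: random.Random, n: int, gc: float) -> str:
    g = gc / 2
    a = (1 - gc) / 2
    return "".join(rng.choices("ACGT", weights=[a, g, g, a], k=n))


def _scrub(bases: str, rng: random.Random,
           enzymes: Sequence[str] = _SCRUB, max_rounds: int = 25) -> str:
    """Destroy every recognition site of the given enzymes by point edits.

    All current sites are edited per round (an edit can itself create a
    new site, hence the outer loop)."""
    seq = list(bases)
    for _ in range(max_rounds):
        ds = DsSeq("".join(seq), "linear")
        hits = [h for e in enzymes for h in find_sites(ds, e)]
        if not hits:
            return ds.bases
        edited: set[int] = set()
        for h in hits:
            m = get_enzyme(h.enzyme).site_length
            if any(p in edited for p in range(h.rec_start, h.rec_start + m)):
                continue  # a previous edit this round already hit this window
            pos = h.rec_start + m // 2
            seq[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
            edited.add(pos)
    raise RuntimeError("could not scrub recognition sites within the retry bound")


def _sentinel(rng: random.Random, cfg: FixtureConfig, n: Optional[int] = None) -> str:
    return _scrub(_rand_seq(rng, n or cfg.sentinel_length, cfg.gc_fraction), rng)


# ---------------------------------------------------------------------------
# genome

def make_toy_genome(cfg: FixtureConfig) -> DsSeq:
    """Seeded random genome with annotated loci and no stray cut sites.

    Deterministic for a fixed config. Loci are laid out left to right
    with flanking room of at least twice the arm length; the deletion
    interval of each locus is annotated as a feature under its name.
    """
    rng = random.Random(cfg.seed)
    gap = 2 * cfg.arm_length + 200
    need = gap + sum(length + gap for _, length in cfg.loci)
    if cfg.genome_length < need:
        raise ValueError(
            f"genome_length {cfg.genome_length} too short for loci layout "
            f"(needs >= {need})")

    pieces: list[str] = []
    features: list[Feature] = []
    pos = 0
    extra = cfg.genome_length - need
    lead = gap + extra // 2
    pieces.append(_scrub(_rand_seq(rng, lead, cfg.gc_fraction), rng))
    pos += lead
    for name, length in cfg.loci:
        if length:
            pieces.append(_scrub(_rand_seq(rng, length, cfg.gc_fraction), rng))
        features.append(Feature(name, pos, pos + length))
        pos += length
        pieces.append(_scrub(_rand_seq(rng, gap, cfg.gc_fraction), rng))
        pos += gap
    tail = cfg.genome_length - pos
    if tail > 0:
        pieces.append(_scrub(_rand_seq(rng, tail, cfg.gc_fraction), rng))
    genome = DsSeq("".join(pieces), cfg.genome_topology, features=features)
    # junction-spanning sites can survive piecewise scrubbing; fix in place
    stray = [h for e in _SCRUB for h in find_sites(genome, e)]
    if stray:
        genome = DsSeq(_scrub(genome.bases, rng), cfg.genome_topology,
                       features=features)
    return genome


# ---------------------------------------------------------------------------
# entry parts

def _mcs(enzyme: str, overhang: str, side: str) -> str:
    """Single-enzyme MCS-IIS block used on fixture vector flanks."""
    e = get_enzyme(enzyme)
    sp = _spacer(e.cut_top, 0)
    if side == "left":
        return e.recognition + sp + overhang
    return overhang + sp + revcomp(e.recognition)


def _pcr_part(arm: str, enzyme: str, left_oh: str, right_oh: str,
              arm_label: str) -> DsSeq:
    e = get_enzyme(enzyme)
    pad = _spacer(4, 0)
    left = pad + _mcs(enzyme, left_oh, "left")
    right = _mcs(enzyme, right_oh, "right") + pad
    return DsSeq(left + arm + right, "linear",
                 features=[Feature(arm_label, len(left), len(left) + len(arm))])


def make_entry_set(cfg: FixtureConfig,
                   up_arm: Optional[str] = None,
                   down_arm: Optional[str] = None) -> EntrySet:
    """Toy up/down/cargo/destination parts that assemble to one final vector.

    The cargo vector carries the chosen Bacillus marker transcribed
    opposite to the cargo; the destination vector carries bla, the ori
    (with a planted unique ApaI site for linearization) and an mRFP1
    counter-screening cargo. Construction is retried deterministically
    when a recognition site happens to span a sentinel junction, and a
    self-check one-pot assembly must yield exactly one final vector.
    """
    last = None
    for attempt in range(20):
        rng = random.Random(cfg.seed + 101 + 7919 * attempt)
        try:
            return _build_entry_set(cfg, rng, up_arm, down_arm)
        except _FixtureReject as e:
            last = e
    raise RuntimeError(
        f"fixture self-check failed after 20 attempts (seed {cfg.seed}): {last}")


class _FixtureReject(RuntimeError):
    """One deterministic construction attempt produced stray sites."""


def _check_site_counts(seq: DsSeq, assembly_enzyme: str,
                       expect_assembly: int, expect_apai: int = 0) -> None:
    for e in _SCRUB:
        n = len(find_sites(seq, e))
        want = expect_assembly if e == assembly_enzyme else (
            expect_apai if e == "ApaI" else 0)
        if n != want:
            raise _FixtureReject(f"{e}: {n} sites, expected {want}")


def _build_entry_set(cfg: FixtureConfig, rng: random.Random,
                     up_arm: Optional[str], down_arm: Optional[str]) -> EntrySet:
    enz = cfg.assembly_enzyme
    oh = {j: registry.fusion_overhang(j) for j in "BCEF"}
    marker = registry._markers()[cfg.cargo_marker_letter]

    if up_arm is None:
        up_arm = _sentinel(rng, cfg, cfg.arm_length)
    if down_arm is None:
        down_arm = _sentinel(rng, cfg, cfg.arm_length)
    up = Part(_pcr_part(up_arm, enz, oh["B"], oh["C"], "up_arm"), "up", "up_pcr")
    down = Part(_pcr_part(down_arm, enz, oh["E"], oh["F"], "down_arm"), "down", "down_pcr")
    _check_site_counts(up.seq, enz, expect_assembly=2)
    _check_site_counts(down.seq, enz, expect_assembly=2)

    # cargo-resistance vector: C2 | cargo | bsu marker(<-) | E1 | neo | ori
    cargo_label = {"lacZalpha_star": "lacZalpha_star",
                   "mkate2": "mkate2", None: "cargo_mcs"}[cfg.cargo_reporter]
    c2 = _mcs(enz, oh["C"], "left")
    e1 = _mcs(enz, oh["E"], "right")
    cargo_s = _sentinel(rng, cfg)
    bsu_s = _sentinel(rng, cfg)
    neo_s = _sentinel(rng, cfg)
    oric_s = _sentinel(rng, cfg)
    cbases = c2 + cargo_s + bsu_s + e1 + neo_s + oric_s
    p = len(c2)
    cfeat = [Feature(cargo_label, p, p + len(cargo_s), 1),
             Feature(f"bsu_marker:{marker.gene}", p + len(cargo_s),
                     p + len(cargo_s) + len(bsu_s), -1),
             Feature("neo", len(c2 + cargo_s + bsu_s + e1),
                     len(c2 + cargo_s + bsu_s + e1) + len(neo_s), 1)]
    cargo = Part(DsSeq(cbases, "circular", features=cfeat),
                 "cargo_resistance", f"toy_pBSc241{cfg.cargo_marker_letter}")
    _check_site_counts(cargo.seq, enz, expect_assembly=2)

    # destination vector: B1 | mRFP1 | F2 | T0 | bla | oriT | ori(ApaI) | T1
    # recognition sites sit on the discarded mRFP1 side so the assembled
    # final vector loses them while the re-ligated destination keeps them
    b1 = _mcs(enz, oh["B"], "right")
    f2 = _mcs(enz, oh["F"], "left")
    mrfp_s = _sentinel(rng, cfg)
    t0_s = _sentinel(rng, cfg, 30)
    bla_s = _sentinel(rng, cfg)
    orit_s = _sentinel(rng, cfg, 30)
    ori_half = _sentinel(rng, cfg, cfg.sentinel_length // 2)
    ori_s = ori_half + "GGGCCC" + _sentinel(rng, cfg, cfg.sentinel_length // 2)
    t1_s = _sentinel(rng, cfg, 30)
    dbases = b1 + mrfp_s + f2 + t0_s + bla_s + orit_s + ori_s + t1_s
    dfeat = []
    q = len(b1)
    for label, span, strand in (("mRFP1", mrfp_s, 1),):
        dfeat.append(Feature(label, q, q + len(span), strand))
        q += len(span)
    q += len(f2)
    for label, span in (("T0", t0_s), ("bla", bla_s), ("oriT", orit_s),
                        ("ori", ori_s), ("T1", t1_s)):
        dfeat.append(Feature(label, q, q + len(span)))
        q += len(span)
    dest = Part(DsSeq(dbases, "circular", features=dfeat),
                "destination", "toy_pBSd141R")
    _check_site_counts(dest.seq, enz, expect_assembly=2, expect_apai=1)

    entry = EntrySet(up, down, cargo, dest, enz)
    try:
        finals = [pr for pr in golden_gate(entry.plan())
                  if pr.classification == "final_vector"]
    except Exception as e:
        raise _FixtureReject(f"self-check assembly failed: {e}") from e
    if len(finals) != 1:
        raise _FixtureReject(f"{len(finals)} final vectors from self-check")
    return entry
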