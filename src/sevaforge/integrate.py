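"""Linearization and double-crossover integration into a genome.

Integrative vectors for naturally competent Bacillus are linearized in
the replication part before transformation so that only double
homologous recombination — one crossover in each homology arm — can
rescue the marker. The simulation is strictly exact-match: both arms
must occur exactly once in the genome, on the same strand, up before
down; the genomic interval between them is replaced by the vector's
integration part (cargo plus Bacillus marker). Single-crossover
(Campbell) integration of circular molecules is deliberately not
modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

from .digestion import digest
from .dna import DsSeq, Feature, revcomp
from .enzyme_kit import Enzyme, cleavable_sites, get_enzyme, list_enzymes

__all__ = ["IntegrationResult", "linearize", "double_crossover"]


@dataclass
class IntegrationResult:
    """A genome after allelic replacement."""

    genome: DsSeq  # edited genome
    deleted_interval: tuple[int, int]  # original genome coordinates
    deleted_length: int
    inserted_length: int
    insert: str  # integration part placed between the arms
    junctions: tuple[int, int]  # edited-genome coordinates of the arm/insert seams


def _integration_part_bounds(vector: DsSeq) -> tuple[int, int]:
    up = vector.find_feature("up_arm")
    down = vector.find_feature("down_arm")
    return up.start, down.end


def linearize(vector: DsSeq, enzyme: Enzyme | str = "ApaI") -> DsSeq:
    """Cut a circular final vector at its unique site in the replication part.

    Errors when the enzyme has zero or multiple sites, or when the cut
    falls inside the integration part (between the outer arm
    boundaries) — linearization must happen in the replication part so
    the homology arms stay intact.
    """
    enz = get_enzyme(enzyme)
    if not vector.is_circular:
        raise ValueError("vector is already linear; linearize expects a circular input")
    hits = cleavable_sites(vector, enz)
    if len(hits) == 0:
        alts = [e.name for e in list_enzymes()
                if e.name != enz.name and len(cleavable_sites(vector, e)) == 1]
        raise ValueError(
            f"no {enz.name} site in the vector; unique cutters found by "
            f"scanning: {', '.join(alts) or 'none'}")
    if len(hits) > 1:
        raise ValueError(f"{enz.name} cuts {len(hits)} times; a unique site is required")
    a, b = _integration_part_bounds(vector)
    n = len(vector)
    cut = hits[0].cut_top_pos
    inside = (a <= cut < b) if a <= b else (cut >= a or cut < b)
    if inside:
        raise ValueError(
            f"{enz.name} cut at {cut} falls within the integration part "
            f"[{a},{b}); linearize in the replication part instead")
    frags = digest(vector, [enz])
    assert len(frags) == 1
    return frags[0].seq


def double_crossover(genome: DsSeq, linear_vector: DsSeq) -> IntegrationResult:
    """Allelic replacement of the genomic interval between the two arms.

    The vector must be linear (circular input is rejected, citing the
    linearization requirement) and carry ``up_arm``/``down_arm``
    features. Supports deletion length 0 (adjacent arms) through
    arbitrarily large deletions.
    """
    if linear_vector.is_circular:
        raise ValueError(
            "circular vector: linearize in the replication part first to "
            "ensure double-crossover (not single-crossover) integration")
    up_f = linear_vector.find_feature("up_arm")
    down_f = linear_vector.find_feature("down_arm")
    if up_f.end > down_f.start:
        raise ValueError("up arm must precede the down arm on the linearized vector")
    up_seq = linear_vector.bases[up_f.start:up_f.end]
    down_seq = linear_vector.bases[down_f.start:down_f.end]

    up_fwd = _occurrences(genome, up_seq)
    dn_fwd = _occurrences(genome, down_seq)
    up_rev = _occurrences(genome, revcomp(up_seq))
    dn_rev = _occurrences(genome, revcomp(down_seq))

    if len(up_fwd) + len(up_rev) == 0:
        raise ValueError("up arm not found in the genome")
    if len(dn_fwd) + len(dn_rev) == 0:
        raise ValueError("down arm not found in the genome")
    if len(up_fwd) + len(up_rev) > 1:
        raise ValueError(f"up arm matches {len(up_fwd) + len(up_rev)} genome locations")
    if len(dn_fwd) + len(dn_rev) > 1:
        raise ValueError(f"down arm matches {len(dn_fwd) + len(dn_rev)} genome locations")

    if up_rev and dn_rev:
        rc = double_crossover(genome.reverse_complement(), linear_vector)
        n = len(rc.genome)
        ds, de = rc.deleted_interval
        g = len(genome)
        return IntegrationResult(
            genome=rc.genome.reverse_complement(),
            deleted_interval=(g - de, g - ds),
            deleted_length=rc.deleted_length,
            inserted_length=rc.inserted_length,
            insert=revcomp(rc.insert),
            junctions=(n - rc.junctions[1], n - rc.junctions[0]),
        )
    if up_rev or dn_rev:
        raise ValueError("homology arms found on opposite genome strands")

    up_start = up_fwd[0]
    up_end = up_start + len(up_seq)
    dn_start = dn_fwd[0]
    if genome.is_circular and dn_start < up_start:
        dn_start += len(genome)
    if dn_start < up_end:
        raise ValueError("arm matches overlap or are out of order on the genome")

    insert = linear_vector.bases[up_f.end:down_f.start]
    n = len(genome)
    if dn_start - up_end == len(insert) and genome.fetch(up_end, dn_start) == insert:
        raise ValueError(
            "arm context altered: the arms already flank this vector's "
            "integration part (single-copy integration; nothing to replace)")
    deleted = (up_end, dn_start)
    deleted_len = dn_start - up_end

    if genome.is_circular and (up_end > n or dn_start > n):
        raise NotImplementedError(
            "the arm span wraps the genome origin; rotate the genome so the "
            "locus is contiguous before integrating")
    edited_bases = genome.bases[:up_end] + insert + genome.bases[dn_start:]
    edited = DsSeq(edited_bases, genome.topology,
                   features=_edited_features(genome, linear_vector, up_f, down_f,
                                             up_start, up_end, dn_start, len(insert),
                                             circular=genome.is_circular))

    result = IntegrationResult(
        genome=edited,
        deleted_interval=deleted,
        deleted_length=deleted_len,
        inserted_length=len(insert),
        insert=insert,
        junctions=(up_end, up_end + len(insert)),
    )
    # length bookkeeping invariant, asserted on every call
    assert len(edited) == len(genome) - deleted_len + len(insert), \
        "integration length bookkeeping violated"
    assert edited_bases.count(up_seq) == 1 and edited_bases.count(down_seq) == 1, \
        "arms must occur exactly once in the edited genome"
    return result


def _occurrences(genome: DsSeq, needle: str) -> list[int]:
    subject = genome.bases + (genome.bases[:len(needle) - 1] if genome.is_circular else "")
    out = []
    i = subject.find(needle)
    while i != -1:
        out.append(i)
        i = subject.find(needle, i + 1)
    return out


def _edited_features(genome, vector, up_f, down_f, up_start, up_end, dn_start,
                     ins_len, circular) -> list[Feature]:
    feats: list[Feature] = []
    shift = ins_len - (dn_start - up_end)
    for f in genome.features:
        if f.end <= up_end:
            feats.append(f)
        elif f.start >= dn_start:
            feats.append(Feature(f.label, f.start + shift, f.end + shift, f.strand))
    voff = up_end - up_f.end  # vector -> edited-genome coordinate shift
    for f in vector.features:
        if up_f.end <= f.start and f.end <= down_f.start:
            feats.append(Feature(f.label, f.start + voff, f.end + voff, f.strand))
    n = len(genome) + shift
    return [f for f in feats if 0 <= f.start < f.end <= n]
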