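"""Arm extraction, enzyme choice, primer tails, MCS synthesis, compliance."""

import random

import pytest

from sevaforge import registry
from sevaforge.design import (ArmLengthWarning, LocusSpec, amplify_arms,
                              check_seva_compliance, design_integration_vector,
                              design_mcs_iis, design_primers, extract_arms,
                              select_enzyme, simulate_pcr)
from sevaforge.digestion import digest
from sevaforge.dna import DsSeq, Feature, revcomp
from sevaforge.enzyme_kit import ASSEMBLY_ENZYMES, find_sites, get_enzyme


# -- arms -------------------------------------------------------------------

def test_zero_length_deletion_is_pure_slicing(toy_genome):
    p = 1200
    up, down = extract_arms(LocusSpec(toy_genome, start=p, end=p, arm_length=400))
    assert up.bases == toy_genome.bases[p - 400:p]
    assert down.bases == toy_genome.bases[p:p + 400]


def test_feature_locus_arms_match_direct_indexing():
    rng = random.Random(2)
    bases = "".join(rng.choices("ACGT", k=6000))
    genome = DsSeq(bases, "linear", features=[Feature("prophage", 2000, 4000)])
    up, down = extract_arms(LocusSpec(genome, feature="prophage", arm_length=400))
    assert up.bases == bases[1600:2000]
    assert down.bases == bases[4000:4400]


def test_asymmetric_arm_lengths(toy_genome):
    """Per-side arm lengths, e.g. a 550 bp up / 580 bp down amplicon pair."""
    spec = LocusSpec(toy_genome, feature="amyE",
                     up_arm_length=550, down_arm_length=580)
    up, down = extract_arms(spec)
    assert len(up) == 550 and len(down) == 580


def test_arm_floor_and_warning(toy_genome):
    with pytest.raises(ValueError):
        extract_arms(LocusSpec(toy_genome, start=1000, end=1000, arm_length=50))
    with pytest.warns(ArmLengthWarning):
        extract_arms(LocusSpec(toy_genome, start=1000, end=1000, arm_length=120))


# -- enzyme selection -------------------------------------------------------

def test_select_enzyme_priority_head_when_clean(toy_genome):
    up, down = extract_arms(LocusSpec(toy_genome, feature="amyE"))
    sel = select_enzyme([up, down])
    assert sel.enzyme.name == "BsaI"
    assert sel.site_counts["BsaI"] == 0


def test_select_enzyme_skips_blocked_candidates():
    arm = DsSeq("ACT" * 50 + "GGTCTC" + "ACT" * 50)
    sel = select_enzyme([arm])
    assert sel.enzyme.name == "BbsI"
    assert sel.site_counts["BsaI"] == 1


def test_select_enzyme_exhaustion_errors():
    arm = DsSeq("ACT" * 10 + "GGTCTC" + "GAAGAC" + "CGTCTC" + "CACCTGC" + "ACT" * 10)
    with pytest.raises(ValueError, match="storage-vector"):
        select_enzyme([arm])


# -- MCS-IIS ----------------------------------------------------------------

def test_mcs_iis_five_enzyme_contract():
    mcs = design_mcs_iis(list(ASSEMBLY_ENZYMES), "GCGA")
    vec = DsSeq(mcs.bases + "ACT" * 80, "circular")
    for e in ASSEMBLY_ENZYMES:
        frags = digest(vec, [e])
        assert len(frags) == 1
        assert frags[0].left_end.overhang == "GCGA", e


def test_mcs_iis_single_enzyme_geometry_is_forced():
    mcs = design_mcs_iis(["BsaI"], "GCGA")
    assert mcs.bases.startswith("GGTCTC")
    assert len(mcs) == 6 + 1 + 4  # recognition + 1-nt spacer + overhang
    assert mcs.bases.endswith("GCGA")


def test_mcs_iis_no_spurious_sites_brute_force():
    mcs = design_mcs_iis(list(ASSEMBLY_ENZYMES), "TGCC", side="right")
    from oracles import brute_force_sites
    for e in ASSEMBLY_ENZYMES:
        assert len(brute_force_sites(mcs, e)) == 1


def test_mcs_iis_rejects_bad_inputs():
    with pytest.raises(ValueError):
        design_mcs_iis(["EcoRV"], "GCGA")
    with pytest.raises(ValueError):
        design_mcs_iis(["BsaI"], "GGCC")  # palindromic
    with pytest.raises(ValueError):
        design_mcs_iis(list(ASSEMBLY_ENZYMES) * 3, "GCGA", length_cap=120)


# -- primers ----------------------------------------------------------------

@pytest.mark.parametrize("enzyme", ["BsaI", "BbsI", "BsmBI", "AarI"])
@pytest.mark.parametrize("side", ["up", "down"])
def test_primer_round_trip_random_arms(enzyme, side):
    """PCR + digestion exposes exactly the registry junction overhangs."""
    rng = random.Random(hash((enzyme, side)) % 2**31)
    left_j, right_j = {"up": "BC", "down": "EF"}[side]
    for _ in range(12):
        arm = DsSeq("".join(rng.choices("ACGT", k=rng.randrange(80, 400))))
        if any(find_sites(arm, e) for e in ASSEMBLY_ENZYMES):
            continue
        pair = design_primers(arm, side, enzyme)
        product = simulate_pcr(arm, pair)
        mid = digest(product, [enzyme])[1]
        assert mid.left_end.overhang == registry.fusion_overhang(left_j)
        assert mid.right_end.overhang == revcomp(registry.fusion_overhang(right_j))
        assert mid.seq.bases == registry.fusion_overhang(left_j) + arm.bases


def test_annealing_regions_are_arm_prefix_and_suffix(toy_genome):
    up, _ = extract_arms(LocusSpec(toy_genome, feature="amyE"))
    pair = design_primers(up, "up", "BsaI")
    assert up.bases.startswith(pair.forward[-pair.fwd_anneal_len:])
    assert revcomp(up.bases).startswith(pair.reverse[-pair.rev_anneal_len:])
    assert pair.fwd_tm >= 60.0 or pair.fwd_anneal_len == 30


def test_aari_tails_longer_than_bsai():
    rng = random.Random(99)
    arm = DsSeq("".join(rng.choices("ACT", k=420)))
    b = design_primers(arm, "up", "BsaI")
    a = design_primers(arm, "up", "AarI")
    assert a.fwd_tail_len > b.fwd_tail_len
    # recognition site is one of the length contributions (7 vs 6 nt)
    assert get_enzyme("AarI").site_length - get_enzyme("BsaI").site_length == 1


# -- compliance -------------------------------------------------------------

def _final_vector(entry_set):
    from sevaforge.assembly import golden_gate
    return golden_gate(entry_set.plan())[0].sequence


def test_compliant_fixture_vector_passes(entry_set):
    report = check_seva_compliance(_final_vector(entry_set))
    assert report.passed and report.findings == ()


def test_planted_forbidden_site_is_reported(entry_set):
    final = _final_vector(entry_set)
    cargo = final.find_feature("cargo_mcs")
    bases = final.bases[:cargo.start] + "GGCGCGCC" + final.bases[cargo.start + 8:]
    broken = DsSeq(bases, "circular", features=list(final.features))
    report = check_seva_compliance(broken)
    assert not report.passed
    finding = next(f for f in report.findings if f.kind == "forbidden_site")
    assert "AscI" in finding.message
    assert finding.position == cargo.start


def test_codirectional_bacillus_marker_is_flagged(entry_set):
    final = _final_vector(entry_set)
    feats = [Feature(f.label, f.start, f.end, abs(f.strand))
             for f in final.features]  # force everything co-directional
    report = check_seva_compliance(DsSeq(final.bases, "circular", features=feats))
    assert any(f.kind == "orientation" for f in report.findings)


def test_unannotated_vector_rejected():
    with pytest.raises(ValueError, match="annotat"):
        check_seva_compliance(DsSeq("ACGT" * 100, "circular"))


# -- end-to-end design report ----------------------------------------------

def test_design_report_suggests_coded_name(toy_genome):
    report = design_integration_vector(
        toy_genome, LocusSpec(toy_genome, feature="amyE"),
        cargo_part="pBSc241M", dest_part="pBSd141R")
    assert report.suggested_name == "pBS141M-amyE"
    assert report.enzyme == "BsaI"
    up_pcr, down_pcr = amplify_arms(toy_genome, report)
    f = up_pcr.find_feature("up_arm")
    assert up_pcr.bases[f.start:f.end] == report.up_arm.bases
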