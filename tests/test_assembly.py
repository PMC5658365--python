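"""One-pot Golden Gate enumeration, classification, colors, oracles."""

import random

import pytest

from sevaforge.assembly import (AssemblyPlan, BtgZIWarning, NoFinalVectorError,
                                Part, golden_gate, predict_color)
from sevaforge.digestion import digest
from sevaforge.dna import DsSeq, revcomp
from sevaforge.enzyme_kit import cleavable_sites
from sevaforge.fixtures import FixtureConfig, make_entry_set, _mcs
from oracles import brute_force_assembly


@pytest.fixture(scope="module")
def products(entry_set):
    return golden_gate(entry_set.plan(xgal=True))


def test_exactly_one_stable_final_vector_with_bla(products):
    finals = [p for p in products if p.classification == "final_vector"]
    assert len(finals) == 1
    final = finals[0]
    assert final.stable
    assert "bla" in final.sequence.feature_labels()
    assert cleavable_sites(final.sequence, "BsaI") == []
    assert products[0] is final  # final vectors sort first


def test_destination_recircularization_is_red(products):
    recirc = [p for p in products if p.classification == "recircularized_destination"]
    assert len(recirc) == 1
    assert recirc[0].predicted_color == "red"
    assert not recirc[0].stable  # re-ligation restores the recognition sites


def test_final_vector_part_order_and_marker_orientation(products):
    """up - cargo - Bacillus marker - down - T0 - bla - oriT - ori - T1,
    with the marker transcribed opposite to the cargo."""
    final = products[0].sequence
    parts = [f for f in final.features if not f.label.startswith("scar")]
    start = final.find_feature("up_arm").start
    order = [f.label.split(":")[0] for f in
             sorted(parts, key=lambda f: (f.start - start) % len(final))]
    assert order == ["up_arm", "cargo_mcs", "bsu_marker", "down_arm",
                     "T0", "bla", "oriT", "ori", "T1"]
    cargo = final.find_feature("cargo_mcs")
    bsu = next(f for f in final.features if f.label.startswith("bsu_marker"))
    assert bsu.strand == -cargo.strand


def test_junction_scars_are_the_fusion_overhangs(products):
    assert set(products[0].junctions) == {"AATG", "GCGA", "TGCC", "ACTA"}


def test_product_set_invariant_under_part_order_and_rotation(entry_set):
    ref = {p.sequence.canonical_form() for p in golden_gate(entry_set.plan())}
    shuffled = list(reversed(entry_set.parts))
    rotated = [Part(p.seq.rotated(13) if p.seq.is_circular else p.seq, p.role, p.name)
               for p in shuffled]
    got = {p.sequence.canonical_form()
           for p in golden_gate(AssemblyPlan(parts=rotated, enzyme="BsaI"))}
    assert got == ref


def test_self_circularization_of_lone_compatible_fragment():
    plasmid = DsSeq("GGTCTCA" + "ACT" * 60, "circular",
                    features=[])
    plan = AssemblyPlan(parts=[Part(plasmid, "destination", "lone")],
                        enzyme="BsaI", require_final=False)
    prods = golden_gate(plan)
    assert len(prods) == 1
    assert prods[0].classification == "recircularized_destination"


def test_missing_down_part_is_diagnosed(entry_set):
    plan = AssemblyPlan(parts=[entry_set.up, entry_set.cargo, entry_set.destination],
                        enzyme="BsaI")
    with pytest.raises(NoFinalVectorError, match="no final vector constructible"):
        golden_gate(plan)


def test_btgzi_is_accepted_with_warning():
    cfg = FixtureConfig(seed=9, genome_length=3000, loci=(("x", 100),),
                        arm_length=120, assembly_enzyme="BtgZI")
    with pytest.warns(BtgZIWarning):
        entry = make_entry_set(cfg)
    with pytest.warns(BtgZIWarning):
        prods = golden_gate(entry.plan())
    assert sum(p.classification == "final_vector" for p in prods) == 1


@pytest.mark.parametrize("reporter,xgal,expected", [
    ("lacZalpha_star", True, "blue"),
    ("lacZalpha_star", False, "white"),
    ("mkate2", True, "light_red"),
    (None, True, "white"),
])
def test_final_vector_color_by_cargo_reporter(reporter, xgal, expected):
    cfg = FixtureConfig(seed=4, genome_length=3000, loci=(("x", 100),),
                        arm_length=120, cargo_reporter=reporter)
    entry = make_entry_set(cfg)
    prods = golden_gate(entry.plan(xgal=xgal))
    final = next(p for p in prods if p.classification == "final_vector")
    assert predict_color(final, xgal=xgal) == expected
    assert final.predicted_color == expected


def _three_part_cycle(seed: int):
    """Three toy circular parts wired into a unique 3-cycle of overhangs."""
    rng = random.Random(seed)
    ohs = ["AATG", "GCGA", "TGCC"]
    roles = ["destination", "up", "cargo_resistance"]
    parts = []
    for i in range(3):
        left = _mcs("BsaI", ohs[i], "left")
        right = _mcs("BsaI", ohs[(i + 1) % 3], "right")
        stuffer = "".join(rng.choices("ACT", k=rng.randrange(40, 90)))
        backbone = "".join(rng.choices("ACT", k=rng.randrange(40, 90)))
        parts.append(Part(DsSeq(left + stuffer + right + backbone, "circular"),
                          roles[i], f"p{i}"))
    return parts


@pytest.mark.parametrize("seed", range(12))
def test_three_part_oracle_equivalence(seed):
    """Product set equals exhaustive ordering x orientation enumeration."""
    parts = _three_part_cycle(seed)
    got = {p.sequence.canonical_form()
           for p in golden_gate(AssemblyPlan(parts=parts, enzyme="BsaI",
                                             require_final=False))}
    assert got == brute_force_assembly(parts, "BsaI")


def test_four_part_oracle_equivalence(entry_set):
    got = {p.sequence.canonical_form()
           for p in golden_gate(entry_set.plan(require_final=False))}
    assert got == brute_force_assembly(entry_set.parts, "BsaI")


def test_plan_validation():
    seq = DsSeq("ACGT" * 30, "circular")
    with pytest.raises(ValueError, match="destination"):
        AssemblyPlan(parts=[Part(seq, "up")], enzyme="BsaI")
    with pytest.raises(ValueError, match="type IIS"):
        AssemblyPlan(parts=[Part(seq, "destination")], enzyme="EcoRV")
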