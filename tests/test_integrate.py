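"""Linearization checks and double-crossover genome surgery."""

import random

import pytest

from sevaforge.assembly import golden_gate
from sevaforge.dna import DsSeq, Feature, revcomp
from sevaforge.integrate import double_crossover, linearize
from oracles import string_surgery


@pytest.fixture(scope="module")
def final_vector(entry_set):
    return golden_gate(entry_set.plan())[0].sequence


def _toy_vector(rng, up_len=150, down_len=150, ins_len=200):
    """A synthetic linearized vector: pad | up | insert | down | pad."""
    mk = lambda k: "".join(rng.choices("ACGT", k=k))
    pad1, up, ins, down, pad2 = mk(60), mk(up_len), mk(ins_len), mk(down_len), mk(60)
    vec = DsSeq(pad1 + up + ins + down + pad2, "linear", features=[
        Feature("up_arm", len(pad1), len(pad1) + up_len),
        Feature("down_arm", len(pad1) + up_len + ins_len,
                len(pad1) + up_len + ins_len + down_len),
    ])
    return vec, up, ins, down


def test_linearize_at_unique_apai_site(final_vector):
    lin = linearize(final_vector, "ApaI")
    assert not lin.is_circular
    assert len(lin) == len(final_vector)
    # rotation starts at the cut: ApaI leaves 3' GGCC overhangs
    assert lin.left_end.polarity == "three_prime"
    assert lin.left_end.overhang == "GGCC"
    assert lin.right_end.overhang == "GGCC"


def test_linearize_error_cases(final_vector):
    with pytest.raises(ValueError, match="unique cutters"):
        linearize(final_vector, "SwaI")  # fixtures are scrubbed of SwaI
    # a cutter inside the integration part is refused
    cargo = final_vector.find_feature("cargo_mcs")
    bases = final_vector.bases[:cargo.start] + "ATTTAAAT" \
        + final_vector.bases[cargo.start + 8:]
    planted = DsSeq(bases, "circular", features=list(final_vector.features))
    with pytest.raises(ValueError, match="integration part"):
        linearize(planted, "SwaI")
    with pytest.raises(ValueError, match="circular"):
        linearize(linearize(final_vector), "ApaI")


def test_circular_vector_rejected_by_double_crossover(final_vector, toy_genome):
    with pytest.raises(ValueError, match="linearize"):
        double_crossover(toy_genome, final_vector)


def test_zero_length_deletion_adds_insert():
    rng = random.Random(0)
    vec, up, ins, down = _toy_vector(rng)
    genome = DsSeq("".join(rng.choices("ACGT", k=500)) + up + down
                   + "".join(rng.choices("ACGT", k=500)))
    res = double_crossover(genome, vec)
    assert res.deleted_length == 0
    assert len(res.genome) == len(genome) + len(ins)
    assert res.genome.bases == string_surgery(genome.bases, up, ins, down)


@pytest.mark.parametrize("topology", ["linear", "circular"])
def test_random_cases_match_string_surgery(topology):
    rng = random.Random(17)
    for _ in range(40):
        vec, up, ins, down = _toy_vector(
            rng, up_len=rng.randrange(80, 200), down_len=rng.randrange(80, 200),
            ins_len=rng.randrange(0, 300))
        del_len = rng.randrange(0, 400)
        genome = DsSeq(
            "".join(rng.choices("ACGT", k=300)) + up
            + "".join(rng.choices("ACGT", k=del_len)) + down
            + "".join(rng.choices("ACGT", k=300)), topology)
        res = double_crossover(genome, vec)
        assert res.deleted_length == del_len
        assert len(res.genome) == len(genome) - del_len + len(ins)
        assert res.genome.bases == string_surgery(genome.bases, up, ins, down)


def test_prophage_scale_deletion():
    """A 130,000-nt interval between the arms is deleted in one event."""
    rng = random.Random(23)
    vec, up, ins, down = _toy_vector(rng, up_len=400, down_len=400)
    genome = DsSeq(
        "".join(rng.choices("ACGT", k=2000)) + up
        + "".join(rng.choices("ACGT", k=130_000)) + down
        + "".join(rng.choices("ACGT", k=2000)), "circular")
    res = double_crossover(genome, vec)
    assert res.deleted_length == 130_000
    assert len(res.genome) == len(genome) - 130_000 + len(ins)


def test_error_cases():
    rng = random.Random(3)
    vec, up, ins, down = _toy_vector(rng)
    background = "".join(rng.choices("ACGT", k=800))
    with pytest.raises(ValueError, match="up arm not found"):
        double_crossover(DsSeq(background + down), vec)
    with pytest.raises(ValueError, match="matches 2"):
        double_crossover(DsSeq(up + background + up + down), vec)
    with pytest.raises(ValueError, match="opposite"):
        double_crossover(DsSeq(up + background + revcomp(down)), vec)
    with pytest.raises(ValueError, match="out of order"):
        double_crossover(DsSeq(down + background + up, "linear"), vec)


def test_reintegration_into_edited_genome_fails():
    """Single-copy semantics: the arms now flank the insert already."""
    rng = random.Random(5)
    vec, up, ins, down = _toy_vector(rng)
    genome = DsSeq("".join(rng.choices("ACGT", k=300)) + up + "TTTT" + down
                   + "".join(rng.choices("ACGT", k=300)))
    edited = double_crossover(genome, vec).genome
    with pytest.raises(ValueError, match="arm context"):
        double_crossover(edited, vec)


def test_strand_symmetry():
    """Integrating into the reverse-complement genome mirrors the edit."""
    rng = random.Random(8)
    vec, up, ins, down = _toy_vector(rng)
    genome = DsSeq("".join(rng.choices("ACGT", k=400)) + up + "CCGGA" * 20 + down
                   + "".join(rng.choices("ACGT", k=400)))
    fwd = double_crossover(genome, vec)
    rev = double_crossover(genome.reverse_complement(), vec)
    assert rev.genome.bases == revcomp(fwd.genome.bases)
    assert rev.deleted_length == fwd.deleted_length
    assert rev.inserted_length == fwd.inserted_length


def test_full_pipeline_round_trip(toy_genome, entry_set):
    """design -> PCR -> assemble -> linearize -> integrate reproduces the edit."""
    from sevaforge.assembly import AssemblyPlan, Part
    from sevaforge.design import LocusSpec, amplify_arms, design_integration_vector

    report = design_integration_vector(toy_genome,
                                       LocusSpec(toy_genome, feature="amyE"))
    up_pcr, down_pcr = amplify_arms(toy_genome, report)
    plan = AssemblyPlan(
        parts=[Part(up_pcr, "up"), Part(down_pcr, "down"),
               entry_set.cargo, entry_set.destination],
        enzyme=report.enzyme)
    final = golden_gate(plan)[0].sequence
    res = double_crossover(toy_genome, linearize(final))
    locus = toy_genome.find_feature("amyE")
    assert res.deleted_interval == (locus.start, locus.end)
    expected = (toy_genome.bases[:locus.start] + res.insert
                + toy_genome.bases[locus.end:])
    assert res.genome.bases == expected
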