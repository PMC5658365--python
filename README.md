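# sevaforge

In-silico construction of personalized integrative vectors for *Bacillus
subtilis* (and relatives) built on the SEVA standard: simulate type IIS
restriction digestion and one-pot Golden Gate assembly of the four-part
"*Bacillus* SEVA siblings" toolbox, design homology arms and tailed
primers for arbitrary integration loci, validate SEVA compliance,
encode/decode the vector nomenclature, and simulate linearization plus
double-crossover integration into a genome.

## The problem

*B. subtilis* is naturally competent and recombines homologous DNA into
its chromosome with high efficiency, so integrative (rather than
replicative) vectors are the standard route to stable, single-copy
genetic modifications. A classical integrative vector is locked to one
resistance marker and one chromosomal locus. The SEVA-sibling design
breaks that lock: every new vector is assembled fresh from four *entry*
parts in a one-pot Golden Gate reaction —

* **up** and **down**: PCR-amplified homology arms (~400 bp each) that
  define the integration locus,
* a **cargo-resistance vector** (cargo MCS + one of seven *Bacillus*
  markers, transcribed opposite to the cargo),
* a **destination vector** (the *E. coli* replication part: *bla*, ori,
  oriT, terminators, plus an mRFP1 counter-screening cassette).

Type IIS enzymes (BsaI, BbsI, BsmBI, AarI; BtgZI is supported but not
recommended) cut *outside* their recognition sites, so each junction is
a designable 4-nt overhang ("fusion site" B, C, E or F). Correctly
assembled junctions lose the recognition site, making the desired
**final vector** the stable fixpoint of the digestion–ligation cycle,
while re-ligated entry vectors are re-cut. The final vector is
linearized in the replication part (e.g. ApaI) and transformed; double
crossover at the two arms replaces the genomic interval between them —
up to prophage-scale deletions (~130 kb) — with the integration part.

`sevaforge` models all of this geometrically and deterministically:
digestion is coordinate arithmetic on duplexes with typed sticky ends,
the one-pot reaction is an exhaustive enumeration of circular ligation
products over a fragment-compatibility graph, and integration is
exact-match string surgery with strict bookkeeping
(`|edited| = |genome| − deleted + inserted`).

## Worked example

```python
from sevaforge import *
from sevaforge.assembly import Part
from sevaforge.fixtures import FixtureConfig, make_toy_genome, make_entry_set

cfg = FixtureConfig(seed=1, genome_length=3000, loci=(("amyE", 300),), arm_length=400)
genome = make_toy_genome(cfg)          # toy genome, amyE locus annotated
entry  = make_entry_set(cfg)           # toy cargo + destination vectors

report = design_integration_vector(genome, LocusSpec(genome, feature="amyE"))
print(report.enzyme, report.suggested_name)
# BsaI pBS141M-amyE

up_pcr, down_pcr = amplify_arms(genome, report)   # simulated PCR
plan = AssemblyPlan(parts=[Part(up_pcr, "up"), Part(down_pcr, "down"),
                           entry.cargo, entry.destination], enzyme=report.enzyme)
for p in golden_gate(plan):
    print(f"{p.classification:30s} {len(p):5d} bp  {p.predicted_color:9s} stable={p.stable}")
# final_vector                    1152 bp  white     stable=True
# re_ligated_entry                 262 bp  white     stable=False
# recircularized_destination       298 bp  red       stable=False

final = golden_gate(plan)[0].sequence
res = double_crossover(genome, linearize(final))   # cut at the unique ApaI site
print(res.deleted_interval, res.deleted_length, res.inserted_length, len(res.genome))
# (1350, 1650) 300 128 2828
```

Reading the output: the pot yields exactly one *stable* final vector
(1152 bp here — desk-scale sentinels stand in for real parts) carrying
the *bla* marker selected for in *E. coli*; the re-ligated destination
would screen **red** (mRFP1 intact) and be discarded. Linearization and
double crossover delete the 300 bp `amyE` interval `[1350, 1650)` and
insert the 128 bp integration part, with the edited genome length
matching the bookkeeping identity.

The same operations are exposed on the command line via `forge`
(`forge sites`, `forge assemble`, `forge design`, `forge integrate`,
`forge name decode|encode`, `forge registry list|show`,
`forge validate`, `forge fixtures`).

## Scope notes

Wet-lab quantities (transformation efficiencies, colony fractions,
fluorescence levels) are biological outcomes and are out of scope; so
are ligase infidelity, partial digestion kinetics and single-crossover
(Campbell) integration. See `docs/methods.md` for the model, its
assumptions and limitations.
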