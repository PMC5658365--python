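# Methods

## Sequence model

A `DsSeq` is a fully base-paired duplex given by its forward strand
(ACGT only; IUPAC ambiguity codes are allowed in enzyme recognition
patterns, never in molecules), a topology flag, and — for linear
molecules — one `EndSpec` per terminus. An `EndSpec` is the polarity
(5′, 3′ or blunt) plus the protruding strand read 5′→3′. Coordinates
are 0-based, half-open, on the forward strand; circular arithmetic is
modulo the length. Product identity is rotation- and strand-invariant:
the canonical form of a circle is the lexicographically least rotation
(Booth's algorithm) of the smaller of the two strands.

## Digestion geometry

An enzyme is its recognition pattern plus two cut offsets measured
from the 3′ end of the recognition site to the top- and bottom-strand
cuts (`BsaI = GGTCTC(1/5)`). The signed difference `cut_bottom −
cut_top` is the overhang: positive 5′, negative 3′, zero blunt. Site
scanning uses regex lookahead (overlapping occurrences included) on
both strands, with palindromic patterns reported once; circular
molecules are scanned doubled and deduplicated modulo length. On
linear molecules a hit whose cut coordinates fall outside the molecule
is reported but flagged non-cleavable.

A digest sorts the cleavable cut pairs and emits the duplex between
consecutive top-strand cuts, so each junction's single-stranded window
is counted exactly once and plain concatenation of fragment strings
reconstitutes ligated duplexes. Two cut windows that intersect raise
an "ambiguous digestion" error naming the positions, because the
fragment set would depend on cutting order. Ligation is permitted
exactly between ends of equal polarity whose protrusions are reverse
complements (blunt–blunt is also permitted); mismatched-overhang
ligation is never modelled.

## The one-pot reaction as cycle enumeration

A Golden Gate pot is modelled by enumeration, not kinetics: every part
is digested, each sticky-ended fragment becomes a node in both
orientations, edges are compatible end pairs, and every simple cycle
up to a size bound (default 6 oriented fragments) is a candidate
circular product, emitted once by canonical identity. Blunt termini
(the outer ends of PCR-generated parts) do not participate in the
cycle search — blunt ligation is strongly disfavored in a one-pot IIS
reaction — though the `ligate` primitive itself supports blunt joins
for the storage-vector route (blunt insertion into the EcoRV site of
the up/down storage vectors).

A product is **stable** iff it contains no cleavable site of the
assembly enzyme; the final vector is the stable cycle containing one
fragment from each role in the junction-grammar order
destination→up→cargo→down and carrying the *bla* feature. A cycle that
restores an input circle is classified as a re-ligated entry
(destination re-ligation is reported separately, since it is the red
colony class). Everything else is a by-product; linear dead ends are
reported only on request. Colony color is predicted from intact
reporter features: mRFP1 → red, mKate2 → light red (the weaker signal
on medium-copy backbones is not modelled), any lacZα variant plus
X-Gal → blue, otherwise white.

With each part supplied once, dimeric (2×) final-vector circles cannot
arise (each fragment exists once); if duplicate parts are supplied the
engine reports such circles as by-products.

When the reaction cannot produce a final vector the engine raises a
diagnosis listing unmatched junction overhangs. Screens that expect
only by-products (e.g. a destination-only red/white control) disable
this via `require_final=False`.

## Fusion sites and MCS-IIS synthesis

The junction grammar uses four 4-nt overhangs (B, C, E, F), each
non-palindromic and pairwise at Hamming distance ≥ 2 (the distance to
other overhangs' reverse complements is computed and reported by the
registry self-check but not enforced). Junction C is GCGA; the B, E
and F overhangs shipped here (AATG, TGCC, ACTA) are synthetic
placeholders chosen once to satisfy the same rules and are flagged
`canonical: false` in the registry data.

An MCS-IIS is synthesized as one block per enzyme —
`recognition + spacer(cut offset) + overhang` for a left-side MCS,
mirrored for right-side — so every enzyme excises the identical
overhang at its own position. Spacer bases come from a fixed wheel;
if a spacer accidentally completes a recognition site the variant is
retried (16 rotations) before erroring. Generation is deterministic,
and each polylinker is verified by scanning: exactly one site per
enzyme, no extras. Which side an MCS takes is chosen so the
recognition sites always land on the *discarded* side of a junction —
that placement is what makes correct products uncleavable.

## Primer and arm design

Arms default to 400 bp (the length needed for efficient double
crossover); 70 bp is a hard floor, and anything below 400 bp attaches
an efficiency warning. Primer tails are
`pad(4) + recognition + spacer(cut offset) + fusion overhang`;
annealing regions grow from 18 nt until the nearest-neighbor melting
temperature reaches 60 °C or 30 nt (Bio.SeqUtils `Tm_NN`, 0.5 µM
primer, 50 mM Na⁺ — fixed so outputs are bit-for-bit reproducible).
Every returned pair is pre-verified: simulated PCR of the arm followed
by digestion must expose exactly the intended junction overhangs.
Because AarI has a 7-bp recognition site and a deeper cut offset than
BsaI, its tails are correspondingly longer. Enzyme choice takes the
first of BsaI > BbsI > BsmBI > AarI with zero cleavable sites in every
supplied sequence; BtgZI is never auto-selected (it is accepted by the
engine with a warning, reflecting its failure to support correct
one-pot assembly).

SEVA compliance checks report any forbidden-enzyme site (default list:
AscI, SwaI, MluI — configurable registry data, since the full boundary
set is defined by the standard, not this package) that overlaps a part
feature, deviations from the canonical part order (up, cargo,
*Bacillus* marker, down, T0, *E. coli* marker, oriT, ori, T1), and a
*Bacillus* marker co-directional with the cargo.

## Integration

`linearize` requires a unique site that falls outside the integration
part (between the outer arm boundaries); when the requested enzyme has
no site, the error lists alternative unique cutters found by scanning
the registry. `double_crossover` is strictly exact-match: each arm
must occur exactly once in the genome, both on the same strand, up
before down; fuzzy matching is out of scope because the recombination
mechanism requires identity — divergent strains simply need new arms.
The interval between the arms is replaced by the vector's integration
part, with the length identity asserted on every call. Re-running the
same integration on an edited genome is rejected ("arm context
altered"), matching single-copy integration semantics. Arm spans that
wrap a circular genome's origin are rejected; rotate the genome first.

## Synthetic fixtures

The fixture generator emulates the *shape* of the system, not its
sequence content: genomes are GC-weighted random strings (43.5% GC,
*B. subtilis*-like) with annotated deletion loci, scrubbed of all
assembly-enzyme, ApaI and forbidden-enzyme sites so cut sites exist
only where planted; entry vectors use ~60-nt labelled sentinels (bla,
neo, mRFP1, lacZα*, …) instead of real ORFs because classification
and screening key on feature labels. A prophage-scale locus (≥10 kb;
130 kb in the acceptance run) exercises large-deletion bookkeeping.
Construction retries deterministically when a recognition site happens
to span a sentinel junction, and every generated entry set self-checks
by assembling to exactly one final vector. Consequences for
interpretation: passing tests demonstrate the combinatorial and
geometric correctness of the engine, not primer thermodynamics on real
genomic sequence, repeat-induced arm ambiguity, or in-vivo efficiency.

## Numerical and design choices

* Enumeration bound: 6 oriented fragments per cycle (covers the
  4-part assembly plus isomers); configurable.
* All randomness flows from explicit integer seeds through
  `random.Random`; no float comparisons or locale dependence affect
  sequence identity.
* Problem sizes in the default test and acceptance runs (3.2-kb toy
  genomes, 400-bp arms, 30–100 oracle cases, a single 130-kb deletion
  case) were chosen as the smallest sizes that exercise every code
  path including prophage-scale bookkeeping.
* GenBank is the canonical file format; sticky ends are serialized in
  the KEYWORDS line (`sevaforge_left_end=five_prime:GCGA`) since the
  format has no native field — a documented dialect. FASTA drops ends
  and features with a warning.

## Known limitations

No star activity, methylation sensitivity or buffer/temperature
modelling (incubation protocols are metadata, not simulation inputs);
no ligation-efficiency or recombination-efficiency prediction (the
>30-fold chromosomal position effect is biology, not geometry); no
off-target PCR or primer secondary-structure screening beyond
site-creation checks; single-crossover integration and
temperature-sensitive replicon workflows are not simulated. The
deposited vector sequences are not bundled; all structural logic runs
on synthetic fixtures, and the B/E/F overhangs are placeholders as
noted above.
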