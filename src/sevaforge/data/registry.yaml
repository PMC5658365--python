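# Bacillus SEVA-siblings toolbox registry.
#
# Markers, part records and name codes are transcribed from the toolbox
# catalog. Fusion-site overhangs: junction C (GCGA) is canonical; the
# B, E and F overhangs are synthetic placeholders (canonical: false)
# chosen once to satisfy every stated fusion-site rule (non-palindromic,
# pairwise Hamming distance >= 2) because the source supplement is not
# shipped with this package.

version: 1

ecoli_markers:
  1: {abbr: amp, gene: bla, description: beta-lactamase}
  2: {abbr: kan, gene: neo, description: neomycin-kanamycin phosphotransferase type I}
  3: {abbr: cm, gene: cat, description: chloramphenicol O-acetyltransferase}

oris:
  4: {name: pRO1600/ColE1, copy_number: high}
  9: {name: pBR322/ROP, copy_number: medium}

cargo_codes:
  1: {name: default MCS}
  3: {name: lacZalpha-pUC18 MCS, screening: blue/white with X-Gal}

bacillus_markers:
  B: {gene: bleO, description: bleomycin binding protein (phleomycin D), antibiotic: Phleomycin D1, concentration_ug_ml: 100}
  C: {gene: cat, description: chloramphenicol O-acetyltransferase, antibiotic: Chloramphenicol, concentration_ug_ml: 5}
  K: {gene: aph(3')IIIa, description: aminoglycoside O-phosphotransferase APH(3')-IIIa, antibiotic: Kanamycin, concentration_ug_ml: 10}
  M: {gene: ermC, description: 23S rRNA (adenine(2058)-N(6))-methyltransferase, antibiotic: Erythromycin & Lincomycin, concentration_ug_ml: [1, 25]}
  S: {gene: aad(9), description: aminoglycoside nucleotidyltransferase ANT9, antibiotic: Spectinomycin, concentration_ug_ml: 200}
  T: {gene: tetL, description: tetracycline efflux MFS transporter, antibiotic: Tetracycline, concentration_ug_ml: 12.5}
  Z: {gene: ble-Sh, description: phleomycin/bleomycin binding protein (codon-optimized for Bsu), antibiotic: Zeocin, concentration_ug_ml: 100}

fusion_sites:
  B: {overhang: AATG, mcs_ids: [B1, B2], canonical: false}
  C: {overhang: GCGA, mcs_ids: [C1, C2], canonical: true}
  E: {overhang: TGCC, mcs_ids: [E1, E2], canonical: false}
  F: {overhang: ACTA, mcs_ids: [F1, F2], canonical: false}

# Orientation of each MCS-IIS: "left" MCSs carry the recognition sites
# upstream of the cut (sites point rightward; the overhang starts the
# downstream segment), "right" MCSs are the mirrored arrangement with
# the recognition sites downstream of the cut. Either way the sites end
# up on the discarded side of the junction, so correctly assembled
# products cannot be re-cleaved.
mcs_iis_sides:
  B1: right
  B2: left
  C1: right
  C2: left
  E1: right
  E2: left
  F1: right
  F2: left

seva_forbidden_enzymes: [AscI, SwaI, MluI]

parts:
  - {bgsc_id: ECE701, name: pBSd141R, role: destination, mcs_iis: [F2, B1], notes: "mRFP1 cargo, bla, ori pRO1600/ColE1"}
  - {bgsc_id: ECE702, name: pBSd191R, role: destination, mcs_iis: [F2, B1], notes: "mRFP1 cargo, bla, ori pBR322/ROP"}
  - {bgsc_id: ECE703, name: pSEVA243X, role: storage_up, mcs_iis: [B2, C1], notes: "lacZalpha** up-storage, neo, ori pRO1600/ColE1"}
  - {bgsc_id: ECE704, name: pSEVA243Y, role: storage_down, mcs_iis: [E2, F1], notes: "lacZalpha** down-storage, neo, ori pRO1600/ColE1"}
  - {bgsc_id: ECE705, name: pBSc241, role: markerless_cargo, mcs_iis: [E1, C2]}
  - {bgsc_id: ECE706, name: pBSc241B, role: cargo_resistance, mcs_iis: [E1, C2]}
  - {bgsc_id: ECE707, name: pBSc241C, role: cargo_resistance, mcs_iis: [E1, C2]}
  - {bgsc_id: ECE708, name: pBSc241M, role: cargo_resistance, mcs_iis: [E1, C2]}
  - {bgsc_id: ECE709, name: pBSc241S, role: cargo_resistance, mcs_iis: [E1, C2]}
  - {bgsc_id: ECE710, name: pBSc241T, role: cargo_resistance, mcs_iis: [E1, C2]}
  - {bgsc_id: ECE711, name: pBSc241Z, role: cargo_resistance, mcs_iis: [E1, C2]}
  - {bgsc_id: ECE712, name: pBSc243, role: markerless_cargo, mcs_iis: [E1, C2]}
  - {bgsc_id: ECE713, name: pBSc243B, role: cargo_resistance, mcs_iis: [E1, C2]}
  - {bgsc_id: ECE714, name: pBSc243C, role: cargo_resistance, mcs_iis: [E1, C2]}
  - {bgsc_id: ECE715, name: pBSc243M, role: cargo_resistance, mcs_iis: [E1, C2]}
  - {bgsc_id: ECE716, name: pBSc243S, role: cargo_resistance, mcs_iis: [E1, C2]}
  - {bgsc_id: ECE717, name: pBSc243T, role: cargo_resistance, mcs_iis: [E1, C2]}
  - {bgsc_id: ECE718, name: pBSc243Z, role: cargo_resistance, mcs_iis: [E1, C2]}
  - {bgsc_id: ECE719, name: pBSc291, role: markerless_cargo, mcs_iis: [E1, C2]}
  - {bgsc_id: ECE720, name: pBSc291K, role: cargo_resistance, mcs_iis: [E1, C2]}
  - {bgsc_id: ECE721, name: pBSc293K, role: cargo_resistance, mcs_iis: [E1, C2]}
  - {bgsc_id: ECE722, name: pBSc391, role: markerless_cargo, mcs_iis: [E1, C2]}
  - {bgsc_id: ECE725, name: pBSc293, role: markerless_cargo, mcs_iis: [E1, C2]}
  - {bgsc_id: ECE726, name: pBSc393, role: markerless_cargo, mcs_iis: [E1, C2]}
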