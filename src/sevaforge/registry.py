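"""Toolbox catalog and the SEVA-sibling nomenclature codec.

The toolbox is a fixed collection of entry vectors (destination,
cargo-resistance, storage and markerless-cargo backbones), seven
Bacillus resistance markers, and the four B/C/E/F fusion-site
overhangs that define the Golden Gate junction grammar. Vector names
follow the SEVA number code: three digits for the E. coli marker, ori
and cargo, optionally followed by a Bacillus marker letter and an
integration-locus suffix (e.g. pBS143K-amyE).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Optional, Union

import yaml

from .dna import DsSeq, revcomp

__all__ = [
    "MarkerRecord",
    "FusionSite",
    "PartRecord",
    "SevaName",
    "decode_name",
    "encode_name",
    "lookup",
    "list_markers",
    "list_parts",
    "fusion_sites",
    "fusion_overhang",
    "mcs_iis",
    "forbidden_enzymes",
    "self_check",
]

_PREFIXES = ("pSEVA", "pBSc", "pBSd", "pBSf", "pBS")
_VARIANT_LETTERS = frozenset("RXY")  # mRFP1 destination / up- / down-storage variants


@dataclass(frozen=True)
class MarkerRecord:
    letter: str
    gene: str
    description: str
    antibiotic: str
    concentration_ug_ml: Union[float, tuple[float, ...]]


@dataclass(frozen=True)
class FusionSite:
    junction: str  # B, C, E or F
    overhang: str  # 4 nt, 5'->3' top strand at the junction
    mcs_ids: tuple[str, str]
    canonical: bool  # False for placeholder overhangs


@dataclass(frozen=True)
class PartRecord:
    bgsc_id: str
    name: str
    role: str
    ecoli_marker_digit: int
    ori_digit: int
    cargo_digit: int
    bsu_marker_letter: Optional[str]
    mcs_iis: tuple[str, ...]
    accession: Optional[str] = None
    notes: str = ""


@dataclass(frozen=True)
class SevaName:
    """Parsed SEVA-sibling vector name."""

    prefix: str
    ecoli_marker_digit: int
    ori_digit: int
    cargo_digit: int
    bsu_marker: Optional[str] = None
    variant: Optional[str] = None  # R / X / Y suffix letters
    locus: Optional[str] = None
    descriptor: Optional[str] = None
    # human-readable expansions
    ecoli_marker: str = ""
    ori: str = ""
    cargo: str = ""


# ---------------------------------------------------------------------------
# data loading

@lru_cache(maxsize=1)
def _data() -> dict:
    raw = yaml.safe_load(
        resources.files("sevaforge.data").joinpath("registry.yaml").read_text()
    )
    self_check(raw)
    return raw


def _markers(raw=None) -> dict[str, MarkerRecord]:
    raw = raw or _data()
    out = {}
    for letter, rec in raw["bacillus_markers"].items():
        conc = rec["concentration_ug_ml"]
        if isinstance(conc, list):
            conc = tuple(float(c) for c in conc)
        else:
            conc = float(conc)
        out[letter] = MarkerRecord(letter, rec["gene"], rec["description"],
                                   rec["antibiotic"], conc)
    return out


def list_markers() -> list[MarkerRecord]:
    return [_markers()[k] for k in sorted(_markers())]


def fusion_sites() -> list[FusionSite]:
    raw = _data()
    return [
        FusionSite(j, rec["overhang"], tuple(rec["mcs_ids"]), bool(rec["canonical"]))
        for j, rec in raw["fusion_sites"].items()
    ]


def fusion_overhang(junction: str) -> str:
    raw = _data()
    try:
        return raw["fusion_sites"][junction]["overhang"]
    except KeyError:
        raise KeyError(f"unknown junction letter {junction!r}; known: B, C, E, F") from None


def forbidden_enzymes() -> list[str]:
    """Default SEVA forbidden-site list (boundary enzymes; configurable data)."""
    return list(_data()["seva_forbidden_enzymes"])


@lru_cache(maxsize=1)
def _parts() -> dict[str, PartRecord]:
    raw = _data()
    out: dict[str, PartRecord] = {}
    for p in raw["parts"]:
        parsed = decode_name(p["name"])
        rec = PartRecord(
            bgsc_id=p["bgsc_id"],
            name=p["name"],
            role=p["role"],
            ecoli_marker_digit=parsed.ecoli_marker_digit,
            ori_digit=parsed.ori_digit,
            cargo_digit=parsed.cargo_digit,
            bsu_marker_letter=parsed.bsu_marker,
            mcs_iis=tuple(p["mcs_iis"]),
            notes=p.get("notes", ""),
        )
        out[rec.name] = rec
        out[rec.bgsc_id] = rec
    return out


def lookup(name_or_bgsc_id: str) -> PartRecord:
    try:
        return _parts()[name_or_bgsc_id]
    except KeyError:
        raise KeyError(
            f"no toolbox record for {name_or_bgsc_id!r} "
            f"(names follow the SEVA code; e.g. the Bacillus kanamycin marker K "
            f"is only offered on the medium-copy ori 9 backbones)"
        ) from None


def list_parts() -> list[PartRecord]:
    seen, out = set(), []
    for rec in _parts().values():
        if rec.name not in seen:
            seen.add(rec.name)
            out.append(rec)
    return sorted(out, key=lambda r: r.bgsc_id)


# ---------------------------------------------------------------------------
# nomenclature codec

_NAME_RE = re.compile(
    r"^(?P<prefix>pSEVA|pBSc|pBSd|pBSf|pBS)"
    r"(?P<digits>\d{3})"
    r"(?P<letter>[A-Z])?"
    r"(?:-(?P<locus>[A-Za-z0-9]+))?"
    r"(?:_(?P<descriptor>[A-Za-z0-9_.-]+))?$"
)


def decode_name(name: str) -> SevaName:
    """Parse a SEVA(-sibling) vector name into its coded features."""
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(
            f"{name!r} does not match the SEVA grammar "
            f"(prefix + 3 digits [+ letter] [-locus] [_descriptor])")
    raw = _data()
    d1, d2, d3 = (int(c) for c in m.group("digits"))
    if d1 not in raw["ecoli_markers"]:
        raise ValueError(f"unregistered E. coli marker digit {d1} in {name!r}")
    if d2 not in raw["oris"]:
        raise ValueError(f"unregistered ori digit {d2} in {name!r}")
    if d3 not in raw["cargo_codes"]:
        raise ValueError(f"unregistered cargo digit {d3} in {name!r}")
    letter = m.group("letter")
    bsu = variant = None
    if letter is not None:
        if letter in raw["bacillus_markers"]:
            bsu = letter
        elif letter in _VARIANT_LETTERS:
            variant = letter
        else:
            raise ValueError(f"unregistered suffix letter {letter!r} in {name!r}")
    return SevaName(
        prefix=m.group("prefix"),
        ecoli_marker_digit=d1, ori_digit=d2, cargo_digit=d3,
        bsu_marker=bsu, variant=variant,
        locus=m.group("locus"), descriptor=m.group("descriptor"),
        ecoli_marker=raw["ecoli_markers"][d1]["abbr"],
        ori=raw["oris"][d2]["name"],
        cargo=raw["cargo_codes"][d3]["name"],
    )


def encode_name(parsed: SevaName) -> str:
    """Inverse of :func:`decode_name`."""
    raw = _data()
    if parsed.prefix not in _PREFIXES:
        raise ValueError(f"unregistered prefix {parsed.prefix!r}")
    for digit, table, what in (
        (parsed.ecoli_marker_digit, "ecoli_markers", "E. coli marker"),
        (parsed.ori_digit, "oris", "ori"),
        (parsed.cargo_digit, "cargo_codes", "cargo"),
    ):
        if digit not in raw[table]:
            raise ValueError(f"unregistered {what} digit {digit}")
    if parsed.bsu_marker is not None and parsed.bsu_marker not in raw["bacillus_markers"]:
        raise ValueError(f"unregistered Bacillus marker letter {parsed.bsu_marker!r}")
    name = f"{parsed.prefix}{parsed.ecoli_marker_digit}{parsed.ori_digit}{parsed.cargo_digit}"
    if parsed.bsu_marker:
        name += parsed.bsu_marker
    elif parsed.variant:
        name += parsed.variant
    if parsed.locus:
        name += f"-{parsed.locus}"
    if parsed.descriptor:
        name += f"_{parsed.descriptor}"
    return name


# ---------------------------------------------------------------------------
# MCS-IIS polylinkers

@lru_cache(maxsize=None)
def mcs_iis(mcs_id: str) -> DsSeq:
    """The polylinker realizing one side of a junction, as a DsSeq.

    Synthetic realization: the sequence is generated deterministically
    from the junction overhang and the five-enzyme architecture (each
    enzyme positioned to excise the identical junction overhang); it
    satisfies the published contract but is not the deposited sequence.
    """
    from .design import design_mcs_iis  # deferred: design imports this module
    from .enzyme_kit import ASSEMBLY_ENZYMES

    raw = _data()
    side = raw["mcs_iis_sides"].get(mcs_id)
    if side is None:
        raise KeyError(f"unknown MCS-IIS id {mcs_id!r}")
    junction = mcs_id[0]
    oh = fusion_overhang(junction)
    return design_mcs_iis(list(ASSEMBLY_ENZYMES), oh, side=side)


# ---------------------------------------------------------------------------
# self-check

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def self_check(raw: Optional[dict] = None) -> dict:
    """Validate the registry invariants; returns a summary report.

    Raises ``ValueError`` on any violation: seven unique Bacillus
    marker letters, two oris, four non-palindromic junction overhangs
    with pairwise Hamming distance >= 2 (C fixed to GCGA), eight
    MCS-IIS entries, and K-marker cargo vectors confined to ori 9.
    """
    if raw is None:
        raw = yaml.safe_load(
            resources.files("sevaforge.data").joinpath("registry.yaml").read_text())

    letters = sorted(raw["bacillus_markers"])
    if letters != ["B", "C", "K", "M", "S", "T", "Z"]:
        raise ValueError(f"Bacillus marker letters must be B,C,K,M,S,T,Z; got {letters}")
    if sorted(raw["oris"]) != [4, 9]:
        raise ValueError("exactly two E. coli oris (digits 4 and 9) are registered")

    fs = raw["fusion_sites"]
    if sorted(fs) != ["B", "C", "E", "F"]:
        raise ValueError("junction letters must be exactly B, C, E, F")
    if fs["C"]["overhang"] != "GCGA":
        raise ValueError("junction C overhang must be GCGA")
    overhangs = {j: rec["overhang"] for j, rec in fs.items()}
    min_ham = None
    min_ham_rc = None
    for j, oh in overhangs.items():
        if len(oh) != 4:
            raise ValueError(f"overhang {j} is not 4 nt")
        if oh == revcomp(oh):
            raise ValueError(f"overhang {j}={oh} is palindromic")
    pairs = [(a, b) for i, a in enumerate(sorted(overhangs)) for b in sorted(overhangs)[i + 1:]]
    for a, b in pairs:
        h = _hamming(overhangs[a], overhangs[b])
        min_ham = h if min_ham is None else min(min_ham, h)
        hrc = _hamming(overhangs[a], revcomp(overhangs[b]))
        min_ham_rc = hrc if min_ham_rc is None else min(min_ham_rc, hrc)
        if h < 2:
            raise ValueError(
                f"overhangs {a}={overhangs[a]} and {b}={overhangs[b]} differ in <2 nt")

    mcs_ids = sorted(raw["mcs_iis_sides"])
    if len(mcs_ids) != 8:
        raise ValueError(f"expected 8 MCS-IIS entries, got {len(mcs_ids)}")

    # cargo vectors carrying the Bacillus kanamycin marker K must sit on ori 9
    for p in raw["parts"]:
        m = _NAME_RE.match(p["name"])
        if m and m.group("letter") == "K" and m.group("digits")[1] != "9":
            raise ValueError(f"K-marker cargo vector {p['name']} must use ori digit 9")

    return {
        "n_bacillus_markers": len(letters),
        "n_oris": len(raw["oris"]),
        "n_mcs_iis": len(mcs_ids),
        "n_parts": len(raw["parts"]),
        "min_pairwise_hamming": min_ham,
        "min_pairwise_hamming_vs_revcomp": min_ham_rc,  # reported, not enforced
    }
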