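"""GenBank/FASTA I/O and run configuration.

GenBank is the canonical interchange format: topology is recorded in
the LOCUS line and features as ``misc_feature`` entries with ``label``
qualifiers. GenBank has no native field for sticky ends, so terminal
EndSpecs are serialized into the KEYWORDS line in a documented dialect
(``sevaforge_left_end=five_prime:GCGA``) and restored on read. FASTA
carries bases only: ends and features are dropped with a warning.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord
from pydantic import BaseModel, ConfigDict

from .dna import BLUNT, DsSeq, EndSpec, Feature

__all__ = ["read_record", "write_record", "to_seqrecord", "from_seqrecord", "RunConfig"]

_END_PREFIX = "sevaforge_"
_FORMATS = {".gb": "genbank", ".gbk": "genbank", ".genbank": "genbank",
            ".fa": "fasta", ".fasta": "fasta", ".fna": "fasta"}


def _format_for(path: Path, fmt: Optional[str]) -> str:
    if fmt:
        return fmt
    try:
        return _FORMATS[path.suffix.lower()]
    except KeyError:
        raise ValueError(f"cannot infer format from suffix {path.suffix!r}; "
                         f"pass fmt='genbank' or 'fasta'") from None


def to_seqrecord(seq: DsSeq, name: str = "record") -> SeqRecord:
    rec = SeqRecord(Seq(seq.bases), id=name, name=name[:16],
                    description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = seq.topology
    if not seq.is_circular:
        rec.annotations["keywords"] = [
            f"{_END_PREFIX}left_end={(seq.left_end or BLUNT).polarity}:{(seq.left_end or BLUNT).overhang}",
            f"{_END_PREFIX}right_end={(seq.right_end or BLUNT).polarity}:{(seq.right_end or BLUNT).overhang}",
        ]
    for f in seq.features:
        rec.features.append(SeqFeature(
            SimpleLocation(f.start, f.end, strand=f.strand),
            type="misc_feature", qualifiers={"label": [f.label]}))
    return rec


def from_seqrecord(rec: SeqRecord) -> DsSeq:
    topology = rec.annotations.get("topology", "linear")
    left = right = None
    for kw in rec.annotations.get("keywords", []):
        if kw.startswith(_END_PREFIX):
            which, spec = kw[len(_END_PREFIX):].split("=", 1)
            polarity, _, overhang = spec.partition(":")
            end = EndSpec(polarity, overhang)
            if which == "left_end":
                left = end
            elif which == "right_end":
                right = end
    feats = []
    for f in rec.features:
        if f.type != "misc_feature":
            continue
        label = (f.qualifiers.get("label") or ["feature"])[0]
        feats.append(Feature(label, int(f.location.start), int(f.location.end),
                             f.location.strand or 1))
    if topology == "circular":
        return DsSeq(str(rec.seq), "circular", features=feats)
    return DsSeq(str(rec.seq), "linear", left_end=left, right_end=right,
                 features=feats)


def write_record(seq: DsSeq, path: str | Path, fmt: Optional[str] = None,
                 name: Optional[str] = None) -> None:
    path = Path(path)
    fmt = _format_for(path, fmt)
    rec = to_seqrecord(seq, name or path.stem)
    if fmt == "fasta" and (seq.features or
                           (not seq.is_circular and
                            not (seq.left_end or BLUNT).is_blunt)):
        warnings.warn(f"FASTA output of {path.name}: sticky ends and feature "
                      f"annotations are dropped", UserWarning, stacklevel=2)
    SeqIO.write([rec], str(path), fmt)


def read_record(path: str | Path, fmt: Optional[str] = None) -> DsSeq:
    path = Path(path)
    fmt = _format_for(path, fmt)
    try:
        rec = next(SeqIO.parse(str(path), fmt))
    except (StopIteration, ValueError) as e:
        raise ValueError(f"{path}: no parseable {fmt} record ({e})") from None
    return from_seqrecord(rec)


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    enzyme_priority: tuple[str, ...] = ("BsaI", "BbsI", "BsmBI", "AarI")
    arm_length: int = 400
    arm_floor: int = 70
    forbidden_enzymes: Optional[tuple[str, ...]] = None  # None -> registry default
    output_format: str = "genbank"
    seed: int = 1
    verbosity: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
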