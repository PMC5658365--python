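"""One-pot Golden Gate assembly simulation.

The reaction is modelled as enumeration, not kinetics: every part is
digested, fragments become nodes of a directed graph whose edges are
compatible sticky-end pairs, and every distinct simple cycle (up to a
size bound) is a candidate circular product. Correctly assembled
junctions lose the enzyme recognition site, so the desired final
vector is the stable fixpoint of the reaction, while re-ligated entry
vectors remain cleavable. Colony screening colors are predicted from
intact reporter features (mRFP1 red, mkate2 light red, lacZalpha blue
with X-Gal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .digestion import Fragment, circularize, digest, ends_compatible, join
from .dna import DsSeq
from .enzyme_kit import Enzyme, cleavable_sites, get_enzyme

__all__ = [
    "Part",
    "AssemblyPlan",
    "AssemblyProduct",
    "NoFinalVectorError",
    "BtgZIWarning",
    "golden_gate",
    "predict_color",
]

ROLES = ("up", "down", "cargo_resistance", "destination")


class NoFinalVectorError(ValueError):
    """The reaction cannot produce a final vector."""


class BtgZIWarning(UserWarning):
    """BtgZI is registry-supported but failed validation for one-pot assembly."""


@dataclass
class Part:
    seq: DsSeq
    role: str
    name: str = ""

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"part role must be one of {ROLES}, got {self.role!r}")
        if not self.name:
            self.name = self.role


@dataclass
class AssemblyPlan:
    parts: list[Part]
    enzyme: Enzyme | str
    max_cycle_size: int = 6  # oriented fragments per product circle
    report_dead_ends: bool = False
    xgal: bool = False
    require_final: bool = True

    def __post_init__(self):
        self.enzyme = get_enzyme(self.enzyme)
        ndest = sum(1 for p in self.parts if p.role == "destination")
        if ndest != 1:
            raise ValueError(f"exactly one destination part required, got {ndest}")
        if self.enzyme.kind != "IIS" or self.enzyme.overhang_length != 4:
            raise ValueError(
                f"{self.enzyme.name} is not a 4-nt 5'-overhang type IIS enzyme")


@dataclass
class AssemblyProduct:
    sequence: DsSeq
    junctions: tuple[str, ...]  # fusion-site scars, in cycle order
    classification: str
    predicted_color: str
    stable: bool
    parts_used: tuple[str, ...]
    note: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------

def _sticky(end) -> bool:
    return end.polarity == "five_prime" and len(end.overhang) > 0


@dataclass
class _Node:
    frag_id: int
    orient: int  # 0 forward, 1 reverse-complemented
    frag: Fragment


def golden_gate(plan: AssemblyPlan) -> list[AssemblyProduct]:
    """Enumerate all stable and unstable circular products of the pot.

    Products are emitted once each (rotation/strand-invariant identity),
    classified, colored, and sorted final vectors first, then by length,
    then by canonical sequence.
    """
    enz = plan.enzyme
    if enz.name == "BtgZI":
        warnings.warn(
            "BtgZI is accepted by the engine but excluded from the validated "
            "default enzyme set: correct one-pot assembly of the final vector "
            "could not be demonstrated with it", BtgZIWarning, stacklevel=2)

    products: list[AssemblyProduct] = []
    fragments: list[tuple[Fragment, Part]] = []
    part_canon: dict[str, tuple[str, str]] = {}  # canonical seq -> (name, role)

    for part in plan.parts:
        hits = cleavable_sites(part.seq, enz)
        if not hits:
            warnings.warn(f"part {part.name!r} carries no cleavable {enz.name} "
                          f"site; passed through inert", UserWarning, stacklevel=2)
            if part.seq.is_circular:
                products.append(_product(part.seq, (), "other_byproduct", plan,
                                         (part.name,), note="inert: uncut input"))
            continue
        if part.seq.is_circular:
            part_canon[part.seq.canonical_form()] = (part.name, part.role)
        for frag in digest(part.seq, [enz]):
            frag.source = part.name
            frag.role = part.role
            fragments.append((frag, part))

    nodes: list[_Node] = []
    for i, (frag, _) in enumerate(fragments):
        if _sticky(frag.left_end) and _sticky(frag.right_end):
            nodes.append(_Node(i, 0, frag))
            nodes.append(_Node(i, 1, frag.reverse_complement()))

    adj: dict[int, list[int]] = {k: [] for k in range(len(nodes))}
    for a, na in enumerate(nodes):
        for b, nb in enumerate(nodes):
            if na.frag_id != nb.frag_id and ends_compatible(na.frag.right_end, nb.frag.left_end):
                adj[a].append(b)

    seen: set[str] = set()
    for cyc in _simple_cycles(nodes, adj, plan.max_cycle_size):
        seq, juncs = _build_circle(cyc)
        key = seq.canonical_form()
        if key in seen:
            continue
        seen.add(key)
        names = tuple(n.frag.source or "?" for n in cyc)
        cls, note = _classify(seq, key, cyc, part_canon, plan)
        products.append(_product(seq, juncs, cls, plan, names, note=note))

    if plan.report_dead_ends:
        products.extend(_dead_ends(nodes, adj, plan))

    finals = [p for p in products if p.classification == "final_vector"]
    if plan.require_final and not finals:
        raise NoFinalVectorError(_diagnose(nodes, adj))

    rank = {"final_vector": 0}
    products.sort(key=lambda p: (rank.get(p.classification, 1), len(p),
                                 p.sequence.canonical_form()))
    return products


def _simple_cycles(nodes, adj, max_size):
    """Distinct simple cycles over fragments (each fragment used once,
    in one orientation). Every cycle is yielded exactly once: the start
    node holds the smallest fragment id in forward orientation."""
    out = []
    n = len(nodes)
    for s in range(n):
        if nodes[s].orient != 0:
            continue
        if ends_compatible(nodes[s].frag.right_end, nodes[s].frag.left_end):
            out.append([nodes[s]])  # self-circularization
        start_fid = nodes[s].frag_id
        path = [s]
        used = {start_fid}

        def dfs(u):
            for v in adj[u]:
                fid = nodes[v].frag_id
                if v == s:
                    out.append([nodes[i] for i in path])
                    continue
                if fid in used or fid < start_fid or len(path) >= max_size:
                    continue
                used.add(fid)
                path.append(v)
                dfs(v)
                path.pop()
                used.remove(fid)

        dfs(s)
    return out


def _build_circle(cyc: list[_Node]) -> tuple[DsSeq, tuple[str, ...]]:
    acc = cyc[0].frag
    for node in cyc[1:]:
        acc = join(acc, node.frag)
    seq = circularize(acc)
    juncs = tuple(n.frag.left_end.overhang for n in cyc)
    return seq, juncs


def _classify(seq: DsSeq, canon: str, cyc, part_canon, plan) -> tuple[str, str]:
    if canon in part_canon:
        name, role = part_canon[canon]
        if role == "destination":
            return "recircularized_destination", f"restores {name}"
        return "re_ligated_entry", f"restores {name}"
    roles = [n.frag.role for n in cyc]
    if sorted(roles) == sorted(ROLES):
        # junction grammar forces the part order; verify cyclically anyway
        i = roles.index("destination")
        rot = roles[i:] + roles[:i]
        ok_order = rot in (["destination", "up", "cargo_resistance", "down"],
                           ["destination", "down", "cargo_resistance", "up"])
        labels = {f.label.split(":")[0] for f in seq.features}
        stable = not cleavable_sites(seq, plan.enzyme)
        if ok_order and "bla" in labels and stable:
            return "final_vector", ""
    return "other_byproduct", ""


def _product(seq: DsSeq, juncs, cls, plan, names, note="") -> AssemblyProduct:
    stable = not cleavable_sites(seq, plan.enzyme)
    return AssemblyProduct(
        sequence=seq, junctions=tuple(juncs), classification=cls,
        predicted_color=predict_color_labels(seq.feature_labels(), plan.xgal),
        stable=stable, parts_used=tuple(names), note=note)


def _dead_ends(nodes, adj, plan) -> list[AssemblyProduct]:
    """Maximal linear chains that cannot circularize (reported on request)."""
    has_pred = {b for outs in adj.values() for b in outs}
    out = []
    seen = set()
    for s, node in enumerate(nodes):
        if s in has_pred:
            continue
        chain = [node]
        cur = s
        while adj[cur]:
            cur = adj[cur][0]
            chain.append(nodes[cur])
            if len(chain) >= plan.max_cycle_size:
                break
        if len(chain) < 2:
            continue
        acc = chain[0].frag
        try:
            for nd in chain[1:]:
                acc = join(acc, nd.frag)
        except ValueError:
            continue
        key = min(acc.seq.bases, acc.seq.reverse_complement().bases)
        if key in seen:
            continue
        seen.add(key)
        out.append(AssemblyProduct(
            sequence=acc.seq, junctions=(), classification="linear_dead_end",
            predicted_color="white", stable=False,
            parts_used=tuple(n.frag.source or "?" for n in chain)))
    return out


def _diagnose(nodes, adj) -> str:
    unmatched = []
    for a, na in enumerate(nodes):
        if na.orient == 0 and not adj[a]:
            unmatched.append(
                f"{na.frag.source}:{na.frag.right_end.overhang or 'blunt'}")
    detail = f"; unmatched junction overhangs: {', '.join(unmatched)}" if unmatched \
        else "; a required part or junction partner is missing"
    return "no final vector constructible" + detail


# ---------------------------------------------------------------------------
# screening colors

def predict_color_labels(labels: Sequence[str], xgal: bool) -> str:
    bases = {lab.split(":")[0] for lab in labels}
    if "mRFP1" in bases:
        return "red"
    if "mkate2" in bases:
        return "light_red"
    if any(b.startswith("lacZ") for b in bases) and xgal:
        return "blue"
    return "white"


def predict_color(product: AssemblyProduct, xgal: bool = False) -> str:
    """Colony color on a screening plate for a given product.

    mRFP1 intact -> red; mkate2 intact (high-copy backbone) -> light
    red; any lacZalpha variant intact and X-Gal present -> blue;
    otherwise white (unknown reporters score white).
    """
    return predict_color_labels(product.sequence.feature_labels(), xgal)
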