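"""Structural-motif classification of pivot sites.

Pivots in ribosomal RNA sit almost exclusively at structurally weak motifs:
G-U wobble pairs, other non-canonical pairs, short bulge loops, and
three-way junctions.  This module derives base pairing from geometry alone
(C1'-C1' separation, hydrogen-bond donor/acceptor contacts, base
coplanarity) and classifies a site against that pairing graph with the
precedence wobble > non-canonical > bulge > junction > unassigned.

Kink-turns are deliberately not a class of their own: pivot sites are
classified by their local pairing pattern only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Residue, StructureModel

__all__ = [
    "PairParams",
    "BasePairRecord",
    "MotifCall",
    "annotate_pairs",
    "classify_site",
    "junction_residues",
]

DONORS = {"G": ("N1", "N2"), "A": ("N6",), "C": ("N4",), "U": ("N3",)}
ACCEPTORS = {"G": ("O6", "N3", "N7"), "A": ("N1", "N3", "N7"),
             "C": ("O2", "N3"), "U": ("O2", "O4")}
PURINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9")
PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")


@dataclass
class PairParams:
    """Geometric thresholds for base-pair detection."""

    c1_min: float = 8.5          # Å, C1'-C1' window
    c1_max: float = 11.5
    hbond_max: float = 3.5       # Å, donor-acceptor contact
    min_contacts: int = 2
    max_plane_angle: float = 30.0  # degrees between base planes


ResidueRef = tuple[str, int]     # (chain id, author number)


@dataclass
class BasePairRecord:
    """One detected base pair with its supporting geometry."""

    residue_i: ResidueRef
    residue_j: ResidueRef
    base_i: str
    base_j: str
    pair_class: str              # watson_crick | GU_wobble | other_noncanonical
    c1_distance: float
    contacts: list[tuple[str, str, float]] = field(default_factory=list)
    multi_flag: bool = False     # residue participates in >1 record

    def involves(self, ref: ResidueRef) -> bool:
        return ref in (self.residue_i, self.residue_j)


@dataclass
class MotifCall:
    """Motif classification of one site with its supporting evidence."""

    site: ResidueRef
    motif_class: str             # GU_wobble | noncanonical_pair | bulge |
    #                              three_way_junction | unassigned
    evidence: list[BasePairRecord] = field(default_factory=list)
    unpaired_run: int = 0


def _base_normal(res: Residue) -> np.ndarray | None:
    ring = PURINE_RING if res.base in ("A", "G") else PYRIMIDINE_RING
    coords = res.coords(ring)
    if len(coords) < 3:
        return None
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[2]


def _contacts(res_i: Residue, res_j: Residue, cutoff: float
              ) -> list[tuple[str, str, float]]:
    out = []
    for di, dj in ((res_i, res_j), (res_j, res_i)):
        for dname in DONORS.get(di.base, ()):
            datom = di.atom(dname)
            if datom is None:
                continue
            for aname in ACCEPTORS.get(dj.base, ()):
                aatom = dj.atom(aname)
                if aatom is None:
                    continue
                d = float(np.linalg.norm(datom.position - aatom.position))
                if d < cutoff:
                    label_i = f"{dname}({di.base})" if di is res_i else f"{aname}({dj.base})"
                    out.append((f"{di.base}.{dname}", f"{dj.base}.{aname}", d))
    return out


def _has_contact(contacts, donor: str, acceptor: str) -> bool:
    return any(c[0] == donor and c[1] == acceptor for c in contacts)


def _classify_pair(res_i: Residue, res_j: Residue, contacts) -> str:
    bases = frozenset((res_i.base, res_j.base))
    if bases == frozenset(("G", "C")):
        if _has_contact(contacts, "G.N1", "C.N3") or _has_contact(contacts, "C.N3", "G.N1"):
            return "watson_crick"
    elif bases == frozenset(("A", "U")):
        if _has_contact(contacts, "A.N6", "U.O4") or _has_contact(contacts, "U.N3", "A.N1"):
            return "watson_crick"
    elif bases == frozenset(("G", "U")):
        if (_has_contact(contacts, "G.N1", "U.O2")
                and _has_contact(contacts, "U.N3", "G.O6")):
            return "GU_wobble"
    return "other_noncanonical"


def annotate_pairs(model: StructureModel,
                   params: PairParams | None = None) -> list[BasePairRecord]:
    """Detect base pairs geometrically across the whole model.

    A candidate pair must have its C1'-C1' distance inside the canonical
    window, at least ``min_contacts`` donor-acceptor contacts under
    ``hbond_max``, and near-coplanar bases.  Residues lacking base atoms are
    skipped.  Records are ordered with the chain-order-first residue as
    ``residue_i``; residues appearing in more than one record are flagged.
    """
    params = params or PairParams()
    residues: list[Residue] = []
    positions: list[np.ndarray] = []
    order: dict[ResidueRef, int] = {}
    for idx, res in enumerate(model.residues()):
        c1 = res.atom("C1'")
        if c1 is None:
            continue
        order[(res.chain_id, res.author_number)] = idx
        residues.append(res)
        positions.append(c1.position)
    if not residues:
        return []
    tree = cKDTree(np.array(positions))
    records: list[BasePairRecord] = []
    seen_count: dict[ResidueRef, int] = {}
    for i, j in sorted(tree.query_pairs(params.c1_max)):
        res_i, res_j = residues[i], residues[j]
        d = float(np.linalg.norm(positions[i] - positions[j]))
        if d < params.c1_min:
            continue
        if res_i.base not in "ACGU" or res_j.base not in "ACGU":
            continue
        ni = _base_normal(res_i)
        nj = _base_normal(res_j)
        if ni is None or nj is None:
            continue
        cosang = abs(float(np.dot(ni, nj)))
        if np.degrees(np.arccos(min(1.0, cosang))) > params.max_plane_angle:
            continue
        contacts = _contacts(res_i, res_j, params.hbond_max)
        if len(contacts) < params.min_contacts:
            continue
        ref_i = (res_i.chain_id, res_i.author_number)
        ref_j = (res_j.chain_id, res_j.author_number)
        if (order[ref_j], ) < (order[ref_i], ):
            ref_i, ref_j = ref_j, ref_i
            res_i, res_j = res_j, res_i
        records.append(BasePairRecord(
            residue_i=ref_i, residue_j=ref_j,
            base_i=res_i.base, base_j=res_j.base,
            pair_class=_classify_pair(res_i, res_j, contacts),
            c1_distance=d, contacts=contacts))
        seen_count[ref_i] = seen_count.get(ref_i, 0) + 1
        seen_count[ref_j] = seen_count.get(ref_j, 0) + 1
    for rec in records:
        if seen_count[rec.residue_i] > 1 or seen_count[rec.residue_j] > 1:
            rec.multi_flag = True
    return records


def _chain_pairs(pairs: list[BasePairRecord], chain: str,
                 chain_order: list[int]) -> dict[int, int]:
    """Partner index map for within-chain pairs, keyed by position index."""
    pos = {num: i for i, num in enumerate(chain_order)}
    pt: dict[int, int] = {}
    for rec in pairs:
        ci, ni = rec.residue_i
        cj, nj = rec.residue_j
        if ci != chain or cj != chain or ni not in pos or nj not in pos:
            continue
        i, j = pos[ni], pos[nj]
        if i not in pt and j not in pt:
            pt[i] = j
            pt[j] = i
    return pt


def _helices(pt: dict[int, int], n: int) -> list[tuple[int, int, int, int]]:
    """Maximal stacked helices as (i_start, i_end, j_start, j_end) indices,
    with pairs (i_start, j_end) ... (i_end, j_start)."""
    helices = []
    used = set()
    for i in range(n):
        j = pt.get(i)
        if j is None or j <= i or i in used:
            continue
        i0, j0 = i, j
        i1, j1 = i, j
        while pt.get(i1 + 1) == j1 - 1 and j1 - 1 > i1 + 1:
            i1 += 1
            j1 -= 1
        for k in range(i0, i1 + 1):
            used.add(k)
            used.add(pt[k])
        helices.append((i0, i1, j1, j0))
    return helices


def junction_residues(pairs: list[BasePairRecord], chain: str,
                      chain_order: list[int]) -> set[int]:
    """Residue numbers belonging to loops where >= 3 helices meet.

    Works on the nested (secondary-structure) part of the pairing graph: a
    multiloop closed by a parent helix with >= 2 directly nested child
    helices, or an exterior loop joining >= 3 top-level helices.
    """
    n = len(chain_order)
    pt = _chain_pairs(pairs, chain, chain_order)
    helices = _helices(pt, n)
    if not helices:
        return set()

    def span(h):
        return (h[0], h[3])

    def parent_of(h):
        best = None
        for other in helices:
            if other is h:
                continue
            if other[1] < h[0] and h[3] < other[2]:
                if best is None or (other[1] > best[1]):
                    best = other
            elif other[0] <= h[0] and h[3] <= other[3] and other is not h:
                # nested inside other's outer span but not inner region:
                # inside the other helix's stack — impossible for maximal
                # helices, ignore
                pass
        return best

    children: dict[int, list] = {id(h): [] for h in helices}
    top_level = []
    for h in helices:
        p = parent_of(h)
        if p is None:
            top_level.append(h)
        else:
            children[id(p)].append(h)

    junction_idx: set[int] = set()
    for h in helices:
        kids = children[id(h)]
        if len(kids) >= 2:
            lo, hi = h[1], h[2]
            spans = [span(k) for k in kids]
            for i in range(lo, hi + 1):
                if any(s <= i <= e for s, e in spans):
                    continue
                if i in (h[1], h[2]) or pt.get(i) is None:
                    junction_idx.add(i)
            for s, e in spans:
                junction_idx.update((s, e))
            junction_idx.update((h[1], h[2]))
    if len(top_level) >= 3:
        spans = [span(h) for h in top_level]
        for i in range(n):
            if any(s <= i <= e for s, e in spans):
                continue
            junction_idx.add(i)
        for s, e in spans:
            junction_idx.update((s, e))
    return {chain_order[i] for i in junction_idx}


def classify_site(
    pairs: list[BasePairRecord],
    site: int,
    chain_order: list[int],
    chain: str = "A",
    junction_window: int = 3,
) -> MotifCall:
    """Classify a pivot site against the pairing annotation.

    Precedence: G-U wobble > other non-canonical pair > bulge (an unpaired
    run of 1-4 residues flanked by paired runs) > three-way junction (within
    ``junction_window`` residues of a loop where >= 3 helices meet) >
    unassigned.  Deterministic given the pairing and topology.
    """
    ref = (chain, site)
    involved = [rec for rec in pairs if rec.involves(ref)]
    for rec in involved:
        if rec.pair_class == "GU_wobble":
            return MotifCall(site=ref, motif_class="GU_wobble", evidence=[rec])
    for rec in involved:
        if rec.pair_class == "other_noncanonical":
            return MotifCall(site=ref, motif_class="noncanonical_pair",
                             evidence=[rec])

    pos = {num: i for i, num in enumerate(chain_order)}
    pt = _chain_pairs(pairs, chain, chain_order)
    idx = pos.get(site)
    if idx is not None and idx not in pt and not involved:
        lo = idx
        while lo - 1 >= 0 and (lo - 1) not in pt:
            lo -= 1
        hi = idx
        while hi + 1 < len(chain_order) and (hi + 1) not in pt:
            hi += 1
        run = hi - lo + 1
        flanked = lo - 1 >= 0 and hi + 1 < len(chain_order)
        if 1 <= run <= 4 and flanked:
            return MotifCall(site=ref, motif_class="bulge", unpaired_run=run)

    jres = junction_residues(pairs, chain, chain_order)
    if idx is not None and jres:
        jpos = {pos[r] for r in jres if r in pos}
        if any(abs(idx - jp) <= junction_window for jp in jpos):
            return MotifCall(site=ref, motif_class="three_way_junction")
    return MotifCall(site=ref, motif_class="unassigned")
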