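"""Coupled-motion (cascade) analysis and the pivot contact network.

A primary pivot can carry a whole set of external helices with it: aligning
the two states at the primary pivot's stem and measuring a downstream
helix's tip displacement captures the *combined* motion, while aligning at
the downstream helix's own stem isolates its *local* motion.  A downstream
helix whose combined displacement far exceeds its local one is riding the
upstream pivot.  The contact network records which pivoting helices touch
(heavy-atom distance under a cutoff) and which motions are induced from
upstream.

No claim about temporal order or causality is made: coupled displacement in
a pair of static states is evidence of mechanical linkage, not mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .pivot_detection import DetectionConfig, PivotCall, align_stem, tip_displacement
from .stems import StemDefinition
from .structure_io import StructureModel

__all__ = [
    "CascadeRow",
    "ContactEdge",
    "cascade_table",
    "contact_network",
    "network_graph",
]


@dataclass
class CascadeRow:
    """Tip displacement of one downstream helix, measured two ways."""

    downstream_helix_id: str
    upstream_helix_id: str
    displacement_upstream_aligned: float
    displacement_individual: float
    amplification: float | None
    flags: list[str] = field(default_factory=list)


@dataclass
class ContactEdge:
    """An edge of the pivot network.

    ``physical_contact`` edges are undirected and carry the minimum
    heavy-atom distance; ``induced_motion`` edges are directed (upstream
    stem -> downstream helix) and carry the amplification ratio.
    """

    pivot_a: str
    pivot_b: str
    kind: str                    # physical_contact | induced_motion
    value: float


def cascade_table(
    a: StructureModel,
    b: StructureModel,
    upstream_stem: StemDefinition,
    downstream: list[StemDefinition],
    config: DetectionConfig | None = None,
    noise_floor: float = 0.05,
) -> list[CascadeRow]:
    """Measure each downstream helix's tip displacement twice.

    Once after superposition at the upstream stem (combined motion) and
    once after superposition at the helix's own stem (local motion).  The
    amplification ratio is combined/local; when the local displacement sits
    below ``noise_floor`` the ratio is computed against the floor and the
    row flagged rather than reported as infinite.  Per-helix failures are
    recorded and the run continues.
    """
    config = config or DetectionConfig()
    rows: list[CascadeRow] = []
    try:
        _, b_up = align_stem(a, b, upstream_stem, config)
    except ValueError as exc:
        return [CascadeRow(s.helix_id, upstream_stem.helix_id,
                           float("nan"), float("nan"), None,
                           flags=[f"error:upstream:{exc}"])
                for s in downstream]
    for stem in downstream:
        flags: list[str] = []
        try:
            d_up = tip_displacement(a, b_up, stem, config.metric)
            _, b_own = align_stem(a, b, stem, config)
            d_own = tip_displacement(a, b_own, stem, config.metric)
        except ValueError as exc:
            rows.append(CascadeRow(stem.helix_id, upstream_stem.helix_id,
                                   float("nan"), float("nan"), None,
                                   flags=[f"error:{exc}"]))
            continue
        if d_own <= noise_floor:
            # floor-clamped ratio instead of a blow-up toward infinity
            amp = d_up / noise_floor if noise_floor > 0 else None
            flags.append("individual_below_floor")
        else:
            amp = d_up / d_own
        rows.append(CascadeRow(
            downstream_helix_id=stem.helix_id,
            upstream_helix_id=upstream_stem.helix_id,
            displacement_upstream_aligned=d_up,
            displacement_individual=d_own,
            amplification=amp,
            flags=flags))
    return rows


def _helix_atom_coords(call: PivotCall, a: StructureModel) -> np.ndarray:
    if call.footprint_residues is not None:
        numbers = call.footprint_residues
    elif call.profile is not None:
        numbers = [num for num, _ in call.profile.entries]
    else:
        return np.empty((0, 3))
    pts = []
    for num in numbers:
        res = a.find(call.chain, num)
        if res is not None:
            pts.extend(atom.position for atom in res.atoms if atom.element != "H")
    return np.array(pts) if pts else np.empty((0, 3))


def contact_network(
    calls: list[PivotCall],
    a: StructureModel,
    cutoff: float = 5.0,
    cascade_rows: list[CascadeRow] | None = None,
    amplification_factor: float = 1.5,
) -> list[ContactEdge]:
    """Build the pivot network.

    A ``physical_contact`` edge joins two pivots whose helices (stem plus
    path residues) approach within ``cutoff`` Å (heavy atoms); an
    ``induced_motion`` edge
    runs from an upstream stem to every downstream helix whose cascade
    amplification exceeds ``amplification_factor``.
    """
    if not calls:
        raise ValueError("no pivot calls to build a network from")
    edges: list[ContactEdge] = []
    coords = {c.helix_id: _helix_atom_coords(c, a) for c in calls}
    trees = {hid: cKDTree(xyz) for hid, xyz in coords.items() if len(xyz)}
    ids = [c.helix_id for c in calls]
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            ti, tj = trees.get(ids[i]), trees.get(ids[j])
            if ti is None or tj is None:
                continue
            pairs = ti.sparse_distance_matrix(tj, cutoff)
            if pairs.nnz:
                edges.append(ContactEdge(ids[i], ids[j], "physical_contact",
                                         float(min(pairs.values()))))
    for row in cascade_rows or []:
        if row.amplification is not None and row.amplification > amplification_factor:
            edges.append(ContactEdge(row.upstream_helix_id,
                                     row.downstream_helix_id,
                                     "induced_motion", row.amplification))
    return edges


def network_graph(edges: list[ContactEdge]) -> nx.MultiDiGraph:
    """The edge list as a graph: physical contacts are stored in both
    directions (symmetric), induced motions only upstream -> downstream."""
    g = nx.MultiDiGraph()
    for e in edges:
        g.add_edge(e.pivot_a, e.pivot_b, kind=e.kind, value=e.value)
        if e.kind == "physical_contact":
            g.add_edge(e.pivot_b, e.pivot_a, kind=e.kind, value=e.value)
    return g
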