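"""Synthetic coordinate pairs with known hinge parameters.

Crystal-structure pairs of the ribosome cannot be bundled at desk scale, so
every pipeline stage is exercised against generated A-form duplexes in which
the hinge location, rotation angle and noise level are known exactly.  The
generator builds an idealized double helix (rise 2.81 Å, twist 32.7°/bp)
from a rigid Watson-Crick base-pair template whose hydrogen-bond
donor/acceptor geometry satisfies the same criteria the annotation module
tests for, caps it with a terminal loop, and produces a second state by
rotating everything distal to a chosen base pair about an axis through that
pair's backbone centroid.  Ground truth — per-residue distances to the hinge
axis and the analytic tip chord 2·sin(θ/2)·r — is recorded alongside.

The geometry is self-consistent rather than chemically exact: base pairs are
built from regular polygons with ~2.9-3.0 Å hydrogen bonds, and phosphates
sit at helical radius 9.2 Å so that consecutive intra-strand P-P distances
come out near the observed ~5.9 Å.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .stems import StemDefinition
from .structure_io import CORE_BACKBONE_ATOMS, Atom, Residue, StructureModel

__all__ = [
    "HingeSpec",
    "HingeTruth",
    "RISE",
    "TWIST_DEG",
    "make_aform_duplex",
    "make_hinge_pair",
    "make_two_hinge_construct",
    "make_junction",
]

RISE = 2.81          # Å per base pair along the helix axis
TWIST_DEG = 32.7     # degrees of helical twist per base pair
P_RADIUS = 9.2       # Å, phosphate distance from the helix axis
LOOP_LEN = 4         # residues in the terminal capping loop

#: Backbone subset used for hinge centroids and ground-truth axis distances
#: (matches the default deviation metric of the detection stage).
CORE_BACKBONE = CORE_BACKBONE_ATOMS

COMPLEMENT = {"G": "C", "C": "G", "A": "U", "U": "A"}
_PURINES = ("G", "A")


def _element(name: str) -> str:
    return name[0]


def _hexagon(center: np.ndarray, radius: float, names_at_deg: dict[str, float]
             ) -> dict[str, np.ndarray]:
    out = {}
    for name, deg in names_at_deg.items():
        a = math.radians(deg)
        out[name] = center + radius * np.array([math.cos(a), math.sin(a), 0.0])
    return out


def _build_templates() -> dict:
    """Base-pair and backbone templates in the pair frame (helix axis = z)."""
    hex_c = np.array([-1.6, 1.0, 0.0])
    r6 = 1.39
    pur = _hexagon(hex_c, r6, {"N1": 0, "C6": 60, "C5": 120, "C4": 180,
                               "N3": 240, "C2": 300})
    # exocyclic substituents point outward from the ring center
    pur["_O6_slot"] = hex_c + 2.62 * np.array([0.5, math.sqrt(3) / 2, 0.0])
    pur["_N2_slot"] = hex_c + 2.74 * np.array([0.5, -math.sqrt(3) / 2, 0.0])
    # fused five-membered ring on the C4-C5 edge, on the far side from hex_c
    c4, c5 = pur["C4"], pur["C5"]
    edge_mid = (c4 + c5) / 2
    edge_len = float(np.linalg.norm(c5 - c4))
    r5 = edge_len / (2 * math.sin(math.pi / 5))
    apothem = r5 * math.cos(math.pi / 5)
    perp = np.array([-(c5 - c4)[1], (c5 - c4)[0], 0.0]) / edge_len
    if np.dot(edge_mid + perp - hex_c, edge_mid - hex_c) < np.dot(
            edge_mid - perp - hex_c, edge_mid - hex_c):
        perp = -perp
    p5c = edge_mid + apothem * perp
    ang_c4 = math.atan2((c4 - p5c)[1], (c4 - p5c)[0])
    ang_c5 = math.atan2((c5 - p5c)[1], (c5 - p5c)[0])
    step = 2 * math.pi / 5
    # going C4 -> C5 -> N7 -> C8 -> N9 around the pentagon
    direction = 1.0 if (ang_c5 - ang_c4) % (2 * math.pi) < math.pi else -1.0
    for i, name in enumerate(("N7", "C8", "N9"), start=2):
        a = ang_c4 + direction * step * i
        pur[name] = p5c + r5 * np.array([math.cos(a), math.sin(a), 0.0])
    glyco_dir = (pur["N9"] - p5c) / r5
    c1_pur = pur["N9"] + 1.47 * glyco_dir

    hex_cp = np.array([4.08, 1.0, 0.0])
    pyr = _hexagon(hex_cp, r6, {"N3": 180, "C2": 240, "N1": 300, "C6": 0,
                                "C4": 120, "C5": 60})
    pyr["_O2_slot"] = hex_cp + 2.62 * np.array([-0.5, -math.sqrt(3) / 2, 0.0])
    pyr["_N4_slot"] = hex_cp + 2.74 * np.array([-0.5, math.sqrt(3) / 2, 0.0])
    c1_pyr = pyr["N1"] + 1.47 * np.array([0.5, -math.sqrt(3) / 2, 0.0])

    def purine(base: str) -> dict[str, np.ndarray]:
        d = {k: v.copy() for k, v in pur.items() if not k.startswith("_")}
        if base == "G":
            d["O6"] = pur["_O6_slot"].copy()
            d["N2"] = pur["_N2_slot"].copy()
        else:  # A
            d["N6"] = pur["_O6_slot"].copy()
        return d

    def pyrimidine(base: str, shear_y: float = 0.0) -> dict[str, np.ndarray]:
        d = {k: v.copy() for k, v in pyr.items() if not k.startswith("_")}
        d["O2"] = pyr["_O2_slot"].copy()
        d["N4" if base == "C" else "O4"] = pyr["_N4_slot"].copy()
        if shear_y:
            for v in d.values():
                v[1] += shear_y
        return d

    # strand backbones: C1' canonical, ribose/phosphate placed outward;
    # P exactly at the helical radius so P-P spacing is symmetry-exact
    bb_a: dict[str, np.ndarray] = {"C1'": c1_pur.copy()}
    offs = {
        "O4'": (-0.7, 1.0, 0.5), "C2'": (-0.9, -1.0, 0.3),
    }
    bb_a["O4'"] = c1_pur + np.array(offs["O4'"])
    bb_a["C2'"] = c1_pur + np.array(offs["C2'"])
    bb_a["O2'"] = bb_a["C2'"] + np.array([-0.9, -1.0, 0.2])
    bb_a["C3'"] = bb_a["C2'"] + np.array([-1.2, 0.4, 0.9])
    bb_a["O3'"] = bb_a["C3'"] + np.array([-0.8, 0.3, 1.0])
    bb_a["C4'"] = bb_a["C3'"] + np.array([0.2, 1.4, 0.6])
    bb_a["C5'"] = bb_a["C4'"] + np.array([-0.9, 0.9, 0.8])
    bb_a["O5'"] = bb_a["C5'"] + np.array([-0.5, 0.3, 1.2])
    az_a = math.radians(165.0)
    bb_a["P"] = np.array([P_RADIUS * math.cos(az_a), P_RADIUS * math.sin(az_a), 1.4])
    bb_a["OP1"] = bb_a["P"] + np.array([0.8, 1.0, 0.4])
    bb_a["OP2"] = bb_a["P"] + np.array([-1.2, 0.5, -0.3])

    bb_b: dict[str, np.ndarray] = {"C1'": c1_pyr.copy()}
    mirror = np.array([-1.0, 1.0, -1.0])
    for name in ("O4'", "C2'", "O2'", "C3'", "O3'", "C4'", "C5'", "O5'"):
        bb_b[name] = c1_pyr + (bb_a[name] - c1_pur) * mirror
    az_b = math.radians(-27.0)
    bb_b["P"] = np.array([P_RADIUS * math.cos(az_b), P_RADIUS * math.sin(az_b), -1.4])
    bb_b["OP1"] = bb_b["P"] + np.array([-0.8, 1.0, -0.4])
    bb_b["OP2"] = bb_b["P"] + np.array([1.2, 0.5, 0.3])

    x_mid = (c1_pur[0] + c1_pyr[0]) / 2
    return {
        "purine": purine, "pyrimidine": pyrimidine,
        "backbone_a": bb_a, "backbone_b": bb_b, "x_mid": x_mid,
    }


_T = _build_templates()


def _flip(atoms: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Strand-swap dyad: 180° rotation about the in-plane y axis at x_mid."""
    xm = _T["x_mid"]
    return {k: np.array([2 * xm - v[0], v[1], -v[2]]) for k, v in atoms.items()}


def _pair_bases(base_a: str, wobble: bool = False
                ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], str]:
    """Base atoms for both sides of one pair, strand A side first."""
    if wobble:
        if base_a == "G":
            return _T["purine"]("G"), _T["pyrimidine"]("U", shear_y=2.2), "U"
        if base_a == "U":
            g, u = _T["purine"]("G"), _T["pyrimidine"]("U", shear_y=2.2)
            return _flip(u), _flip(g), "G"
        raise ValueError("wobble pair requires G or U on strand A")
    base_b = COMPLEMENT[base_a]
    if base_a in _PURINES:
        return _T["purine"](base_a), _T["pyrimidine"](base_b), base_b
    return _flip(_T["pyrimidine"](base_a)), _flip(_T["purine"](base_b)), base_b


def _frame(i: float) -> tuple[np.ndarray, np.ndarray]:
    """Helical frame of base-pair position i (0-based): rotation, origin."""
    a = math.radians(TWIST_DEG) * i
    rot = np.array([[math.cos(a), -math.sin(a), 0.0],
                    [math.sin(a), math.cos(a), 0.0],
                    [0.0, 0.0, 1.0]])
    return rot, np.array([0.0, 0.0, RISE * i])


def _residue(chain: str, base: str, atoms: dict[str, np.ndarray],
             rot: np.ndarray, origin: np.ndarray,
             extra_shift: np.ndarray | None = None) -> Residue:
    shift = origin if extra_shift is None else origin + extra_shift
    built = [
        Atom(name=n, element=_element(n), position=rot @ v + shift)
        for n, v in atoms.items()
    ]
    return Residue(chain_id=chain, author_number=0, base=base, name=base, atoms=built)


@dataclass
class _Built:
    """A duplex under construction: residues in chain order plus indices."""

    residues: list[Residue] = field(default_factory=list)
    strand_a: dict[int, int] = field(default_factory=dict)   # bp index -> chain pos
    strand_b: dict[int, int] = field(default_factory=dict)
    loop: list[int] = field(default_factory=list)
    bulge: list[int] = field(default_factory=list)
    side: list[int] = field(default_factory=list)
    pairs: list[tuple[int, int]] = field(default_factory=list)
    side_pair_positions: list[tuple[int, int]] = field(default_factory=list)

    def number(self, start: int = 1) -> None:
        for k, res in enumerate(self.residues):
            res.author_number = start + k

    def numbers(self, positions) -> list[int]:
        return [self.residues[p].author_number for p in positions]


def _build_duplex(
    n_bp: int,
    sequence: str | None = None,
    wobble_at: int | None = None,
    bulge_after: int | None = None,
    bulge_len: int = 0,
    side_helix_at: int | None = None,
    chain: str = "A",
) -> _Built:
    """Construct a capped duplex in chain order (strand A, loop, strand B).

    ``wobble_at``/``bulge_after``/``side_helix_at`` take a 1-based base-pair
    position; the bulge inserts unpaired strand-A residues after that pair,
    and the side helix grafts a small hairpin into strand B between the
    partners of that pair and the next, producing a three-helix junction.
    """
    if n_bp < 2:
        raise ValueError("need at least 2 base pairs")
    seq = (sequence or "").upper()
    if not seq:
        seq = "".join(("G", "A")[i % 2] for i in range(n_bp))
    if len(seq) != n_bp:
        raise ValueError("sequence length must equal n_bp")

    built = _Built()
    a_res: list[Residue] = []
    b_res: list[Residue] = []
    for i in range(n_bp):
        bp = i + 1
        wob = wobble_at == bp
        base_a = "G" if wob and seq[i] not in ("G", "U") else seq[i]
        atoms_a, atoms_b, base_b = _pair_bases(base_a, wobble=wob)
        rot, origin = _frame(i)
        ra = _residue(chain, base_a, {**atoms_a, **_T["backbone_a"]}, rot, origin)
        rb = _residue(chain, base_b, {**atoms_b, **_T["backbone_b"]}, rot, origin)
        a_res.append(ra)
        b_res.append(rb)

    # strand A with optional bulge insertion
    for i, res in enumerate(a_res):
        built.strand_a[i + 1] = len(built.residues)
        built.residues.append(res)
        if bulge_after == i + 1 and bulge_len > 0:
            for m in range(1, bulge_len + 1):
                t = i + m / (bulge_len + 1)
                rot, origin = _frame(t)
                c1_dir = _T["backbone_a"]["C1'"].copy()
                c1_dir[2] = 0.0
                push = 6.0 * rot @ (c1_dir / np.linalg.norm(c1_dir))
                bres = _residue(chain, "A",
                                {**_T["purine"]("A"), **_T["backbone_a"]},
                                rot, origin, extra_shift=push)
                built.bulge.append(len(built.residues))
                built.residues.append(bres)

    # terminal loop over the top pair
    rot_top, origin_top = _frame(n_bp - 1)
    a_top = rot_top @ _T["backbone_a"]["C1'"] + origin_top
    b_top = rot_top @ _T["backbone_b"]["C1'"] + origin_top
    mid = (a_top + b_top) / 2
    for k in range(1, LOOP_LEN + 1):
        t = k / (LOOP_LEN + 1)
        point = (mid + math.cos(math.pi * t) * (a_top - mid)
                 + np.array([0.0, 0.0, 1.5 * RISE + 4.0 * math.sin(math.pi * t)]))
        shift = point - (rot_top @ _T["backbone_a"]["C1'"] + origin_top)
        base = "G" if k == 1 else "A"
        lres = _residue(chain, base, {**_T["purine"](base), **_T["backbone_a"]},
                        rot_top, origin_top, extra_shift=shift)
        built.loop.append(len(built.residues))
        built.residues.append(lres)

    # strand B, 3' -> 5' of the duplex = chain 5'->3' from the top pair down
    for i in range(n_bp - 1, -1, -1):
        built.strand_b[i + 1] = len(built.residues)
        built.residues.append(b_res[i])
        if side_helix_at is not None and i + 1 == side_helix_at + 1:
            _graft_side_helix(built, chain, at_bp=side_helix_at)

    built.number()
    for bp in range(1, n_bp + 1):
        built.pairs.append((built.residues[built.strand_a[bp]].author_number,
                            built.residues[built.strand_b[bp]].author_number))
    for pa, pb in built.side_pair_positions:
        built.pairs.append((built.residues[pa].author_number,
                            built.residues[pb].author_number))
    return built


def _graft_side_helix(built: _Built, chain: str, at_bp: int,
                      n_side: int = 3) -> None:
    """Insert a small hairpin pointing radially outward from strand B."""
    sub = _build_duplex(n_side, sequence="G" * n_side, chain=chain)
    rot_at, origin_at = _frame(at_bp - 0.5)
    radial = rot_at @ np.array([1.0, -0.3, 0.0])
    radial /= np.linalg.norm(radial)
    orient = Rotation.align_vectors(radial[None, :], [[0, 0, 1]])[0].as_matrix()
    anchor = origin_at + 13.0 * radial
    pair_offset: dict[int, int] = {}
    for res in sub.residues:
        for atom in res.atoms:
            atom.position = orient @ atom.position + anchor
        pair_offset[res.author_number] = len(built.residues)
        built.side.append(len(built.residues))
        built.residues.append(res)
    # sub-helix pair list is in its own numbering; translate to chain
    # positions here, resolved to author numbers after final renumbering
    built.side_pair_positions.extend(
        (pair_offset[pa], pair_offset[pb]) for pa, pb in sub.pairs)


@dataclass
class HingeSpec:
    """Parameters of one synthetic hinge construct.

    ``pivot_index`` is the 1-based base-pair position of the last rigid pair;
    everything distal to it (toward the terminal loop) rotates by
    ``hinge_angle_deg`` about an axis through that pair's backbone centroid.
    ``hinge_axis`` is a unit 3-vector or ``"auto"`` (perpendicular to the
    helix axis).  ``noise_sigma`` is the per-atom isotropic Gaussian noise
    in Å, applied independently to both states.
    """

    n_stem: int = 6
    n_arm: int = 12
    pivot_index: int | None = None
    hinge_angle_deg: float = 10.0
    hinge_axis: str | tuple[float, float, float] = "auto"
    noise_sigma: float = 0.0
    motif_at_pivot: str = "none"   # none | GU_wobble | bulge:<k> | three_way_junction
    sequence: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pivot_index is None:
            self.pivot_index = self.n_stem
        n = self.n_stem + self.n_arm
        if not 0 < self.pivot_index < n:
            raise ValueError("pivot_index must lie strictly inside the duplex")
        if not 0.0 <= self.hinge_angle_deg < 180.0:
            raise ValueError("hinge angle must be in [0°, 180°)")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be nonnegative")


@dataclass
class HingeTruth:
    """Ground truth of one synthetic hinge, for recovery tests."""

    pivot_residue: int             # first mobile strand-A residue
    chain: str
    theta_deg: float
    axis_point: np.ndarray
    axis_direction: np.ndarray
    axis_distances: dict[int, float]   # residue number -> mean core-backbone r_j
    tip_residue: int
    r_tip: float
    expected_tip_chord: float
    mobile_residues: list[int]
    stem: StemDefinition | None = None

    def expected_chord(self, residue: int) -> float:
        return 2.0 * math.sin(math.radians(self.theta_deg) / 2) * self.axis_distances[residue]


def _axis_distance(res: Residue, point: np.ndarray, direction: np.ndarray) -> float:
    coords = res.coords(CORE_BACKBONE)
    if len(coords) == 0:
        coords = res.coords()
    rel = coords - point
    perp = rel - np.outer(rel @ direction, direction)
    return float(np.mean(np.linalg.norm(perp, axis=1)))


def _to_model(built: _Built, source_id: str, chain: str = "A") -> StructureModel:
    return StructureModel(source_id=source_id, chains={chain: built.residues})


def make_aform_duplex(n_bp: int, sequence: str | None = None,
                      seed: int = 0) -> StructureModel:
    """Idealized capped A-form duplex: 2·n_bp paired residues plus a
    terminal loop, deterministic for a given (n_bp, sequence, seed)."""
    built = _build_duplex(n_bp, sequence=sequence)
    return _to_model(built, source_id=f"aform_{n_bp}bp")


def make_hinge_pair(spec: HingeSpec
                    ) -> tuple[StructureModel, StructureModel, HingeTruth]:
    """Generate two states of a hinged duplex plus the ground-truth record.

    State B equals state A with all residues distal to ``spec.pivot_index``
    rotated by the hinge angle about the hinge axis through the pivot pair's
    backbone centroid; independent Gaussian noise is then added to both
    states.  The returned truth carries per-residue axis distances computed
    over the core backbone atoms, so expected deviations under the default
    detection metric are exactly 2·sin(θ/2)·r_j in the noise-free case.
    """
    n_bp = spec.n_stem + spec.n_arm
    motif = spec.motif_at_pivot
    wobble_at = bulge_after = side_at = None
    bulge_len = 0
    if motif == "GU_wobble":
        wobble_at = spec.pivot_index + 1
    elif motif.startswith("bulge"):
        bulge_len = int(motif.split(":")[1]) if ":" in motif else 2
        bulge_after = spec.pivot_index
    elif motif == "three_way_junction":
        side_at = spec.pivot_index
    elif motif != "none":
        raise ValueError(f"unknown motif {motif!r}")

    built = _build_duplex(n_bp, sequence=spec.sequence, wobble_at=wobble_at,
                          bulge_after=bulge_after, bulge_len=bulge_len,
                          side_helix_at=side_at)
    model_a = _to_model(built, source_id="hinge_state_a")

    pivot_pos_a = built.strand_a[spec.pivot_index]
    pivot_pos_b = built.strand_b[spec.pivot_index]
    pivot_res = (built.residues[pivot_pos_a], built.residues[pivot_pos_b])
    centroid = np.mean(np.vstack([r.coords(CORE_BACKBONE) for r in pivot_res]), axis=0)
    if isinstance(spec.hinge_axis, str) and spec.hinge_axis == "auto":
        direction = np.array([1.0, 0.0, 0.0])
    else:
        direction = np.asarray(spec.hinge_axis, dtype=float)
        direction = direction / np.linalg.norm(direction)

    mobile_pos = sorted(
        [built.strand_a[bp] for bp in range(spec.pivot_index + 1, n_bp + 1)]
        + [built.strand_b[bp] for bp in range(spec.pivot_index + 1, n_bp + 1)]
        + built.loop + built.bulge + built.side
    )
    mobile_numbers = built.numbers(mobile_pos)

    model_b = model_a.copy()
    model_b.source_id = "hinge_state_b"
    if spec.hinge_angle_deg != 0.0:
        rot = Rotation.from_rotvec(
            math.radians(spec.hinge_angle_deg) * direction).as_matrix()
        mobile_set = set(mobile_numbers)
        for res in model_b.chains["A"]:
            if res.author_number in mobile_set:
                for atom in res.atoms:
                    atom.position = rot @ (atom.position - centroid) + centroid

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        for model in (model_a, model_b):
            for res in model.chains["A"]:
                for atom in res.atoms:
                    atom.position = atom.position + rng.normal(
                        0.0, spec.noise_sigma, 3)

    # ground truth measured on the noise-free state-A geometry
    axis_distances = {
        res.author_number: _axis_distance(res, centroid, direction)
        for res in built.residues
    }
    tip_number = built.numbers([built.loop[(LOOP_LEN - 1) // 2]])[0]
    r_tip = axis_distances[tip_number]
    stem = _stem_for(built, "A", spec.pivot_index, n_bp, "hinge")
    first_mobile_a = built.residues[
        built.bulge[0] if built.bulge else built.strand_a[spec.pivot_index + 1]
    ].author_number
    truth = HingeTruth(
        pivot_residue=first_mobile_a,
        chain="A",
        theta_deg=spec.hinge_angle_deg,
        axis_point=centroid,
        axis_direction=direction,
        axis_distances=axis_distances,
        tip_residue=tip_number,
        r_tip=r_tip,
        expected_tip_chord=2.0 * math.sin(math.radians(spec.hinge_angle_deg) / 2) * r_tip,
        mobile_residues=mobile_numbers,
        stem=stem,
    )
    return model_a, model_b, truth


def _truth_for(built: _Built, chain: str, theta_deg: float, centroid: np.ndarray,
               direction: np.ndarray, mobile_numbers: list[int],
               stem: StemDefinition, pivot_residue: int) -> HingeTruth:
    axis_distances = {
        res.author_number: _axis_distance(res, centroid, direction)
        for res in built.residues
    }
    tip_number = built.numbers([built.loop[(LOOP_LEN - 1) // 2]])[0]
    r_tip = axis_distances[tip_number]
    return HingeTruth(
        pivot_residue=pivot_residue,
        chain=chain,
        theta_deg=theta_deg,
        axis_point=centroid,
        axis_direction=direction,
        axis_distances=axis_distances,
        tip_residue=tip_number,
        r_tip=r_tip,
        expected_tip_chord=2.0 * math.sin(math.radians(theta_deg) / 2) * r_tip,
        mobile_residues=mobile_numbers,
        stem=stem,
    )


def _hinge_geometry(built: _Built, pivot_index: int, axis_spec
                    ) -> tuple[np.ndarray, np.ndarray]:
    pivot_res = (built.residues[built.strand_a[pivot_index]],
                 built.residues[built.strand_b[pivot_index]])
    centroid = np.mean(np.vstack([r.coords(CORE_BACKBONE) for r in pivot_res]), axis=0)
    if isinstance(axis_spec, str) and axis_spec == "auto":
        direction = np.array([1.0, 0.0, 0.0])
    else:
        direction = np.asarray(axis_spec, dtype=float)
        direction = direction / np.linalg.norm(direction)
    return centroid, direction


def _stem_for(built: _Built, chain: str, pivot_index: int, n_bp: int,
              helix_id: str) -> StemDefinition:
    tip_number = built.numbers([built.loop[(LOOP_LEN - 1) // 2]])[0]
    first_mobile = built.residues[
        built.bulge[0] if built.bulge else built.strand_a[pivot_index + 1]
    ].author_number
    last_a = built.residues[built.strand_a[n_bp]].author_number
    # path runs stem -> loop on each strand: the 5' strand up through the
    # loop tip, then the 3' strand from its stem end back toward the loop
    b_near_stem = built.residues[built.strand_b[pivot_index + 1]].author_number
    b_near_loop = built.residues[built.strand_b[n_bp]].author_number
    return StemDefinition(
        helix_id=helix_id,
        chain=chain,
        stem_ranges=[
            (built.residues[built.strand_a[1]].author_number,
             built.residues[built.strand_a[pivot_index]].author_number),
            (built.residues[built.strand_b[pivot_index]].author_number,
             built.residues[built.strand_b[1]].author_number),
        ],
        path_ranges=[(first_mobile, max(tip_number, last_a)),
                     (b_near_stem, b_near_loop)],
        tip_residue=tip_number,
    )


def make_two_hinge_construct(
    spec_upstream: HingeSpec, spec_local: HingeSpec
) -> tuple[StructureModel, StructureModel, dict[str, HingeTruth]]:
    """Trunk helix with an upstream hinge carrying a branch helix with its
    own local hinge — the test bed for cascade (coupled-motion) analysis.

    The trunk (chain A) hinges at ``spec_upstream.pivot_index``; the branch
    (chain B) is grafted beyond the trunk's distal end, axis perpendicular
    to the trunk, and hinges at ``spec_local.pivot_index``.  In state B the
    whole branch rides the upstream rotation, and residues distal to the
    local hinge additionally rotate about it.  Both ground truths are
    returned in state-A coordinates.  Noise (``spec_upstream.noise_sigma``)
    is applied to the whole construct.
    """
    n1 = spec_upstream.n_stem + spec_upstream.n_arm
    n2 = spec_local.n_stem + spec_local.n_arm
    trunk = _build_duplex(n1, sequence=spec_upstream.sequence, chain="A")
    branch = _build_duplex(n2, sequence=spec_local.sequence, chain="B")

    # the branch is anchored in the trunk's top-pair frame so that the
    # trunk-branch separation (~3.1 Å closest approach: direct physical
    # contact) is invariant to the trunk length
    phase = Rotation.from_euler("z", (n1 - 1) * TWIST_DEG, degrees=True).as_matrix()
    orient = phase @ Rotation.from_euler("y", 90, degrees=True).as_matrix()
    anchor = phase @ np.array([10.0, 6.0, 0.0]) + np.array([0.0, 0.0, (n1 + 2.5) * RISE])
    # local hinge axis is defined in the branch's own frame (perpendicular
    # to the branch helix axis) and carried through the placement
    c2_local, u2_local = _hinge_geometry(branch, spec_local.pivot_index,
                                         spec_local.hinge_axis)
    for res in branch.residues:
        for atom in res.atoms:
            atom.position = orient @ atom.position + anchor

    c1, u1 = _hinge_geometry(trunk, spec_upstream.pivot_index,
                             spec_upstream.hinge_axis)
    c2 = orient @ c2_local + anchor
    u2 = orient @ u2_local

    chains = {"A": trunk.residues, "B": branch.residues}
    model_a = StructureModel(source_id="two_hinge_state_a", chains=chains)

    trunk_mobile = sorted(
        [trunk.strand_a[bp] for bp in range(spec_upstream.pivot_index + 1, n1 + 1)]
        + [trunk.strand_b[bp] for bp in range(spec_upstream.pivot_index + 1, n1 + 1)]
        + trunk.loop)
    trunk_mobile_numbers = trunk.numbers(trunk_mobile)
    branch_mobile = sorted(
        [branch.strand_a[bp] for bp in range(spec_local.pivot_index + 1, n2 + 1)]
        + [branch.strand_b[bp] for bp in range(spec_local.pivot_index + 1, n2 + 1)]
        + branch.loop)
    branch_mobile_numbers = branch.numbers(branch_mobile)

    r1 = Rotation.from_rotvec(
        math.radians(spec_upstream.hinge_angle_deg) * u1).as_matrix()
    r2 = Rotation.from_rotvec(
        math.radians(spec_local.hinge_angle_deg) * u2).as_matrix()

    model_b = model_a.copy()
    model_b.source_id = "two_hinge_state_b"
    t_mobile = set(trunk_mobile_numbers)
    b_mobile = set(branch_mobile_numbers)
    for res in model_b.chains["A"]:
        if res.author_number in t_mobile:
            for atom in res.atoms:
                atom.position = r1 @ (atom.position - c1) + c1
    for res in model_b.chains["B"]:
        for atom in res.atoms:
            p = atom.position
            if res.author_number in b_mobile:
                p = r2 @ (p - c2) + c2
            atom.position = r1 @ (p - c1) + c1

    if spec_upstream.noise_sigma > 0:
        rng = np.random.default_rng(spec_upstream.seed)
        for model in (model_a, model_b):
            for res in model.residues():
                for atom in res.atoms:
                    atom.position = atom.position + rng.normal(
                        0.0, spec_upstream.noise_sigma, 3)

    up_stem = _stem_for(trunk, "A", spec_upstream.pivot_index, n1, "trunk")
    lo_stem = _stem_for(branch, "B", spec_local.pivot_index, n2, "branch")
    truth_up = _truth_for(
        trunk, "A", spec_upstream.hinge_angle_deg, c1, u1,
        trunk_mobile_numbers, up_stem,
        pivot_residue=trunk.residues[
            trunk.strand_a[spec_upstream.pivot_index + 1]].author_number)
    # upstream truth also governs the branch: record branch axis distances
    for res in branch.residues:
        truth_up.axis_distances[("B", res.author_number)] = _axis_distance(res, c1, u1)
    truth_lo = _truth_for(
        branch, "B", spec_local.hinge_angle_deg, c2, u2,
        branch_mobile_numbers, lo_stem,
        pivot_residue=branch.residues[
            branch.strand_a[spec_local.pivot_index + 1]].author_number)
    return model_a, model_b, {"upstream": truth_up, "local": truth_lo}


def make_junction(n_arms: int = 3, arm_len: int = 4, seed: int = 0
                  ) -> StructureModel:
    """Several hairpin arms radiating from a shared junction region.

    The arms' base planes are mutually inclined, so geometric pair
    annotation sees each arm as its own helix; the unpaired linker residues
    between arms form the junction loop.  Ground-truth pairing topology and
    the junction residue numbers are recorded in ``model.metadata`` as
    ``pairs`` (semicolon-separated ``i-j``) and ``junction_residues``.
    """
    if n_arms < 2:
        raise ValueError("need at least 2 arms")
    residues: list[Residue] = []
    pair_positions: list[tuple[int, int]] = []
    junction_positions: list[int] = []
    for k in range(n_arms):
        ang = 2 * math.pi * k / n_arms
        dk = np.array([math.cos(ang), math.sin(ang), 0.0])
        orient = Rotation.align_vectors(dk[None, :], [[0.0, 0.0, 1.0]])[0].as_matrix()
        arm = _build_duplex(arm_len, sequence="G" * arm_len, chain="A")
        anchor = 8.0 * dk
        offset = len(residues)
        for res in arm.residues:
            for atom in res.atoms:
                atom.position = orient @ atom.position + anchor
            residues.append(res)
        for pa, pb in arm.pairs:
            pair_positions.append((offset + pa - 1, offset + pb - 1))
        junction_positions.extend((offset + arm.pairs[0][0] - 1,
                                   offset + arm.pairs[0][1] - 1))
        if k < n_arms - 1:
            mid = 2 * math.pi * (k + 0.5) / n_arms
            point = 3.0 * np.array([math.cos(mid), math.sin(mid), 0.0]) \
                + np.array([0.0, 0.0, 2.0])
            shift = point - _T["backbone_a"]["C1'"]
            link = _residue("A", "A", {**_T["purine"]("A"), **_T["backbone_a"]},
                            np.eye(3), np.zeros(3), extra_shift=shift)
            junction_positions.append(len(residues))
            residues.append(link)
    for n, res in enumerate(residues, start=1):
        res.author_number = n
    model = StructureModel(source_id=f"junction_{n_arms}way",
                           chains={"A": residues})
    model.metadata["pairs"] = ";".join(
        f"{residues[i].author_number}-{residues[j].author_number}"
        for i, j in pair_positions)
    model.metadata["junction_residues"] = ",".join(
        str(residues[i].author_number) for i in junction_positions)
    return model
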