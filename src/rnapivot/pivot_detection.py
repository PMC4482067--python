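"""Pivot localization by decoupled rigid-stem superposition.

The core computation: superimpose the two conformational states on a short
rigid stem proximal to a candidate hinge, so that local motion is decoupled
from global rearrangement; profile the per-residue deviation along the helix
from stem toward terminal loop; call the pivot at the onset of sustained
divergence; and quantify the magnitude of the motion as the displacement of
a designated residue in the final loop.

Deviations use, by default, the mean displacement of the six
phosphodiester-core backbone atoms per residue, so a noise-free hinge of
angle θ produces a deviation of exactly 2·sin(θ/2)·r for a residue whose
mean backbone distance to the hinge axis is r.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .correspondence import (
    AtomPairing,
    InsufficientAtomsError,
    ResiduePairing,
    pair_atoms,
    pair_residues,
)
from .stems import StemDefinition
from .structure_io import CORE_BACKBONE_ATOMS, Residue, StructureModel
from .superposition import SuperpositionResult, kabsch, refine_superposition, transform

__all__ = [
    "DetectionConfig",
    "DeviationProfile",
    "PivotCall",
    "MobileRegion",
    "StemIncompleteError",
    "align_stem",
    "deviation_profile",
    "locate_pivot",
    "tip_displacement",
    "detect_pivots",
    "screen_mobile_helices",
    "global_superposition",
    "estimate_hinge_rotation",
]

METRICS = ("per_residue_backbone_mean", "per_residue_all_atom_mean", "atom_max")


class StemIncompleteError(ValueError):
    """Stem residues missing from one of the models."""


@dataclass
class DetectionConfig:
    """Thresholds and options of the detection pipeline.

    ``pivot_threshold=None`` uses the adaptive default
    max(1.0 Å, 2 x post-fit stem RMSD) — "exceeds the noise floor";
    ``persistence`` is how many consecutive profile residues must exceed it.
    ``reporting_floor=None`` derives the floor for calling real motion from
    the global control RMSD of the comparison.
    """

    metric: str = "per_residue_backbone_mean"
    min_atom_pairs: int = 30
    max_cycles: int = 5
    reject_sigma: float = 2.0
    pivot_threshold: float | None = None
    persistence: int = 2
    reporting_floor: float | None = None
    mobility_threshold: float | None = None
    min_run_length: int = 3

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.persistence < 1:
            raise ValueError("persistence must be >= 1")


@dataclass
class DeviationProfile:
    """Per-residue deviation (Å) along the helix path, stem -> loop.

    ``entries`` holds (residue_number, deviation) with ``None`` for residues
    absent from either state.
    """

    helix_id: str
    chain: str
    entries: list[tuple[int, float | None]]
    metric: str

    def deviations(self) -> list[float]:
        return [d for _, d in self.entries if d is not None]


@dataclass
class PivotCall:
    """One detected pivot: location, motif, tip displacement."""

    helix_id: str
    chain: str
    pivot_location: int | None
    motif_class: str
    tip_residue: int | None
    displacement: float
    stem_residual: float
    comparison_id: str = ""
    flags: list[str] = field(default_factory=list)
    profile: DeviationProfile | None = None
    #: stem + path residue numbers — the whole helix, for contact analysis
    footprint_residues: list[int] | None = None


@dataclass
class MobileRegion:
    """A contiguous run of residues exceeding the mobility threshold."""

    chain: str
    start: int
    end: int
    peak_deviation: float
    mean_deviation: float

    def __len__(self) -> int:
        return self.end - self.start + 1


def _resolve_residue(model: StructureModel, chain: str, number: int,
                     numbering: str) -> Residue | None:
    return model.find(chain, number, by_reference=(numbering == "reference"))


def _stem_pairing(a: StructureModel, b: StructureModel,
                  stem: StemDefinition) -> ResiduePairing:
    entries = []
    missing: list[int] = []
    for num in stem.stem_residues():
        res_a = _resolve_residue(a, stem.chain, num, stem.numbering)
        res_b = _resolve_residue(b, stem.chain, num, stem.numbering)
        if res_a is None or res_b is None:
            missing.append(num)
            continue
        entries.append((res_a.key, res_b.key))
    if missing:
        raise StemIncompleteError(
            f"{stem.helix_id}: stem residues missing from one state: "
            f"{missing[:10]}{'...' if len(missing) > 10 else ''}")
    return ResiduePairing(entries=entries, method="by_number")


def align_stem(
    a: StructureModel,
    b: StructureModel,
    stem: StemDefinition,
    config: DetectionConfig | None = None,
) -> tuple[SuperpositionResult, StructureModel]:
    """Superimpose state B onto state A using only the rigid-stem atoms.

    Returns the superposition result (its ``rmsd_kept`` is the stem
    residual) and the whole of state B carried through the stem transform.
    """
    config = config or DetectionConfig()
    rp = _stem_pairing(a, b, stem)
    ap = pair_atoms(rp, a, b, atom_subset="all_heavy",
                    min_pairs=config.min_atom_pairs)
    sr = refine_superposition(ap, a, b, max_cycles=config.max_cycles,
                              reject_sigma=config.reject_sigma)
    return sr, transform(b, sr)


def _residue_deviation(res_a: Residue, res_b: Residue, metric: str) -> float | None:
    if metric == "per_residue_backbone_mean":
        names = [n for n in CORE_BACKBONE_ATOMS
                 if res_a.atom(n) is not None and res_b.atom(n) is not None]
    else:
        names = sorted(
            {at.name for at in res_a.atoms if at.element != "H"}
            & {at.name for at in res_b.atoms if at.element != "H"})
    if not names:
        return None
    da = res_a.coords(names)
    db = res_b.coords(names)
    dist = np.linalg.norm(da - db, axis=1)
    return float(dist.max() if metric == "atom_max" else dist.mean())


def deviation_profile(
    a: StructureModel,
    b_transformed: StructureModel,
    stem: StemDefinition,
    metric: str = "per_residue_backbone_mean",
) -> DeviationProfile:
    """Per-residue deviation along the helix path after stem alignment.

    Residues missing from either state are flagged with ``None`` and the
    profile continues.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    entries: list[tuple[int, float | None]] = []
    for num in stem.helix_path():
        res_a = _resolve_residue(a, stem.chain, num, stem.numbering)
        res_b = _resolve_residue(b_transformed, stem.chain, num, stem.numbering)
        if res_a is None or res_b is None:
            entries.append((num, None))
            continue
        entries.append((num, _residue_deviation(res_a, res_b, metric)))
    return DeviationProfile(helix_id=stem.helix_id, chain=stem.chain,
                            entries=entries, metric=metric)


def locate_pivot(profile: DeviationProfile, threshold: float,
                 persistence: int = 2) -> int | None:
    """First residue (stem->loop) whose deviation exceeds ``threshold`` and
    stays above it for ``persistence`` consecutive present residues.
    Returns ``None`` when no residue qualifies (a valid no-pivot outcome)."""
    present = [(num, d) for num, d in profile.entries if d is not None]
    for i, (num, d) in enumerate(present):
        if d <= threshold:
            continue
        window = present[i:i + persistence]
        if len(window) == persistence and all(dd > threshold for _, dd in window):
            return num
    return None


def tip_displacement(
    a: StructureModel,
    b_transformed: StructureModel,
    stem: StemDefinition,
    metric: str = "per_residue_backbone_mean",
) -> float:
    """Displacement (Å) of the final-loop tip residue after stem alignment."""
    if stem.tip_residue is None:
        raise ValueError(f"{stem.helix_id}: no tip residue defined")
    res_a = _resolve_residue(a, stem.chain, stem.tip_residue, stem.numbering)
    res_b = _resolve_residue(b_transformed, stem.chain, stem.tip_residue,
                             stem.numbering)
    if res_a is None or res_b is None:
        raise StemIncompleteError(
            f"{stem.helix_id}: tip residue {stem.tip_residue} missing")
    d = _residue_deviation(res_a, res_b, metric)
    if d is None:
        raise StemIncompleteError(
            f"{stem.helix_id}: tip residue {stem.tip_residue} has no shared atoms")
    return d


def global_superposition(
    a: StructureModel,
    b: StructureModel,
    config: DetectionConfig | None = None,
) -> tuple[SuperpositionResult, StructureModel]:
    """Whole-model superposition over all number-paired heavy atoms.

    The resulting ``rmsd_all`` serves as the comparison's control RMSD: the
    variation a local motion must exceed to be considered meaningful.
    """
    config = config or DetectionConfig()
    rp = pair_residues(a, b, method="by_number")
    ap = pair_atoms(rp, a, b, atom_subset="all_heavy",
                    min_pairs=min(config.min_atom_pairs, 3))
    sr = refine_superposition(ap, a, b, max_cycles=config.max_cycles,
                              reject_sigma=config.reject_sigma)
    return sr, transform(b, sr)


def detect_pivots(
    a: StructureModel,
    b: StructureModel,
    stems: list[StemDefinition],
    config: DetectionConfig | None = None,
    comparison_id: str = "",
    annotate: bool = True,
) -> list[PivotCall]:
    """Run the full two-step detection over a stem catalog.

    One :class:`PivotCall` per catalog entry.  Calls whose displacement is
    below the reporting floor (by default the global control RMSD of the
    comparison) are flagged ``sub_threshold`` rather than dropped, since a
    real motion smaller than the coordinate uncertainty is indistinguishable
    from noise.  Per-helix failures are recorded in ``flags`` and the run
    continues.
    """
    config = config or DetectionConfig()
    floor = config.reporting_floor
    if floor is None:
        try:
            gsr, _ = global_superposition(a, b, config)
            floor = gsr.rmsd_all
        except (InsufficientAtomsError, ValueError):
            floor = 0.0

    pair_records = None
    chain_orders: dict[str, list[int]] = {}
    if annotate:
        from .motif_annotation import annotate_pairs
        pair_records = annotate_pairs(a)
        chain_orders = {cid: [r.author_number for r in residues]
                        for cid, residues in a.chains.items()}

    calls: list[PivotCall] = []
    for stem in stems:
        try:
            sr, b_t = align_stem(a, b, stem, config)
            profile = deviation_profile(a, b_t, stem, config.metric)
            threshold = (config.pivot_threshold if config.pivot_threshold is not None
                         else max(1.0, 2.0 * sr.rmsd_kept))
            pivot = locate_pivot(profile, threshold, config.persistence)
            disp = tip_displacement(a, b_t, stem, config.metric)
        except (StemIncompleteError, InsufficientAtomsError, ValueError) as exc:
            calls.append(PivotCall(
                helix_id=stem.helix_id, chain=stem.chain, pivot_location=None,
                motif_class="unassigned", tip_residue=stem.tip_residue,
                displacement=float("nan"), stem_residual=float("nan"),
                comparison_id=comparison_id, flags=[f"error:{exc}"]))
            continue
        flags = []
        if disp < floor:
            flags.append("sub_threshold")
        if not sr.converged:
            flags.append("rejection_exhausted")
        motif = "unassigned"
        if pivot is not None and pair_records is not None:
            from .motif_annotation import classify_site
            res = _resolve_residue(a, stem.chain, pivot, stem.numbering)
            if res is not None:
                motif = classify_site(
                    pair_records, res.author_number,
                    chain_orders.get(stem.chain, []), chain=stem.chain,
                ).motif_class
        calls.append(PivotCall(
            helix_id=stem.helix_id, chain=stem.chain, pivot_location=pivot,
            motif_class=motif, tip_residue=stem.tip_residue,
            displacement=disp, stem_residual=sr.rmsd_kept,
            comparison_id=comparison_id, flags=flags, profile=profile,
            footprint_residues=stem.stem_residues() + stem.helix_path()))
    return calls


def screen_mobile_helices(
    a: StructureModel,
    b: StructureModel,
    config: DetectionConfig | None = None,
) -> list[MobileRegion]:
    """Rank contiguous mobile regions after global superposition.

    The first step of the two-step procedure: find particularly mobile
    helical segments as candidates for stem-catalog construction.  Runs of
    at least ``config.min_run_length`` residues whose post-fit deviation
    exceeds the mobility threshold (default max(2 Å, 2 x global RMSD of the
    retained atoms)) are returned sorted by peak deviation, largest first.
    """
    config = config or DetectionConfig()
    sr, b_t = global_superposition(a, b, config)
    threshold = (config.mobility_threshold if config.mobility_threshold is not None
                 else max(2.0, 2.0 * sr.rmsd_kept))
    regions: list[MobileRegion] = []
    for cid, residues in a.chains.items():
        run: list[tuple[int, float]] = []
        for res in residues:
            partner = b_t.find(cid, res.author_number, res.insertion_code)
            d = (_residue_deviation(res, partner, config.metric)
                 if partner is not None else None)
            if d is not None and d > threshold:
                run.append((res.author_number, d))
            else:
                if len(run) >= config.min_run_length:
                    regions.append(_region_from_run(cid, run))
                run = []
        if len(run) >= config.min_run_length:
            regions.append(_region_from_run(cid, run))
    return sorted(regions, key=lambda r: r.peak_deviation, reverse=True)


def _region_from_run(chain: str, run: list[tuple[int, float]]) -> MobileRegion:
    devs = [d for _, d in run]
    return MobileRegion(chain=chain, start=run[0][0], end=run[-1][0],
                        peak_deviation=max(devs),
                        mean_deviation=float(np.mean(devs)))


def estimate_hinge_rotation(
    a: StructureModel,
    b_transformed: StructureModel,
    chain: str,
    residues: list[int],
    numbering: str = "author",
) -> float:
    """Rotation angle (degrees) carrying the named arm residues of state A
    onto state B after stem alignment — recovers the hinge angle of a rigid
    arm motion."""
    ca, cb = [], []
    for num in residues:
        res_a = _resolve_residue(a, chain, num, numbering)
        res_b = _resolve_residue(b_transformed, chain, num, numbering)
        if res_a is None or res_b is None:
            continue
        names = [n for n in CORE_BACKBONE_ATOMS
                 if res_a.atom(n) is not None and res_b.atom(n) is not None]
        ca.append(res_a.coords(names))
        cb.append(res_b.coords(names))
    coords_a = np.vstack(ca)
    coords_b = np.vstack(cb)
    sr = kabsch(coords_b, coords_a)  # rotation taking A-arm onto B-arm
    angle = math.degrees(math.acos(min(1.0, max(-1.0,
        (np.trace(sr.rotation) - 1.0) / 2.0))))
    return angle
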