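"""Atomic-coordinate I/O and rRNA chain handling.

Structures are held in a light in-memory model (:class:`StructureModel`)
backed by gemmi for reading and writing mmCIF (PDBx) and PDB v3.3 files.
Coordinates are Cartesian angstroms throughout; residues carry the author
numbering of the source file plus, optionally, a reference numbering
(conventionally E. coli rRNA positions) applied from a two-column map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "NumberingMap",
    "StructureIOError",
    "EmptySelectionError",
    "MappingError",
    "read_structure",
    "write_structure",
    "select_rrna",
    "apply_numbering",
    "read_numbering_map",
    "BACKBONE_ATOMS",
    "MODIFIED_PARENT",
]

#: Backbone atom names of a ribonucleotide (heavy atoms only).
BACKBONE_ATOMS = (
    "P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'", "C2'", "C1'", "O4'", "O2'",
)

#: Phosphodiester-core subset used for per-residue deviation metrics.
CORE_BACKBONE_ATOMS = ("P", "O5'", "C5'", "C4'", "C3'", "O3'")

#: Parent-base table for common modified ribonucleotides.  Unknown hetero
#: residues inside a polymer chain are kept with base "N".
MODIFIED_PARENT: Mapping[str, str] = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "PSU": "U", "H2U": "U", "5MU": "U", "4SU": "U", "UR3": "U", "OMU": "U",
    "1MA": "A", "2MA": "A", "6MA": "A", "MA6": "A", "OMA": "A", "A2M": "A",
    "5MC": "C", "OMC": "C", "4OC": "C", "M4C": "C",
    "1MG": "G", "2MG": "G", "7MG": "G", "M2G": "G", "OMG": "G", "G7M": "G", "YG": "G",
}


class StructureIOError(ValueError):
    """A coordinate file could not be parsed or written."""


class EmptySelectionError(ValueError):
    """A chain selection matched no residues."""


class MappingError(KeyError):
    """A numbering map refers to a chain absent from the model."""


@dataclass
class Atom:
    """One heavy (or hydrogen) atom of a residue.

    Positions are angstroms; ``b_factor`` is the isotropic displacement
    parameter in Å².
    """

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    alt_loc: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    """A nucleotide (or other monomer) with its atoms in file order."""

    chain_id: str
    author_number: int
    base: str                      # parent base A/C/G/U, or N for unknown
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""
    name: str = ""                 # residue name as written in the file
    reference_number: int | None = None
    is_modified: bool = False

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.author_number, self.insertion_code)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self, names: Iterable[str] | None = None) -> np.ndarray:
        """Coordinates of the named atoms (present ones only), (k, 3)."""
        if names is None:
            sel = self.atoms
        else:
            wanted = set(names)
            sel = [a for a in self.atoms if a.name in wanted]
        if not sel:
            return np.empty((0, 3))
        return np.array([a.position for a in sel])

    def is_ribonucleotide(self) -> bool:
        return self.base in ("A", "C", "G", "U")


@dataclass
class StructureModel:
    """Parsed atomic coordinates of one conformational state.

    ``chains`` maps chain id to an ordered residue list; residues within a
    chain are strictly ordered by (author_number, insertion_code).
    """

    source_id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, residues in self.chains.items():
            keys = [(r.author_number, r.insertion_code) for r in residues]
            if keys != sorted(keys):
                raise ValueError(f"chain {cid}: residues not ordered by (number, icode)")

    def residues(self) -> Iterator[Residue]:
        for residues in self.chains.values():
            yield from residues

    def n_residues(self) -> int:
        return sum(len(r) for r in self.chains.values())

    def n_atoms(self) -> int:
        return sum(len(res.atoms) for res in self.residues())

    def find(self, chain_id: str, number: int, icode: str = "",
             by_reference: bool = False) -> Residue | None:
        for res in self.chains.get(chain_id, []):
            if by_reference:
                if res.reference_number == number:
                    return res
            elif res.author_number == number and res.insertion_code == icode:
                return res
        return None

    def all_coords(self) -> np.ndarray:
        pts = [a.position for res in self.residues() for a in res.atoms]
        return np.array(pts) if pts else np.empty((0, 3))

    def copy(self) -> "StructureModel":
        chains = {
            cid: [
                Residue(
                    chain_id=res.chain_id,
                    author_number=res.author_number,
                    base=res.base,
                    atoms=[Atom(a.name, a.element, a.position.copy(),
                                a.occupancy, a.b_factor, a.alt_loc)
                           for a in res.atoms],
                    insertion_code=res.insertion_code,
                    name=res.name,
                    reference_number=res.reference_number,
                    is_modified=res.is_modified,
                )
                for res in residues
            ]
            for cid, residues in self.chains.items()
        }
        return StructureModel(self.source_id, chains, dict(self.metadata))


@dataclass
class NumberingMap:
    """Author-to-reference residue renumbering, injective per chain."""

    pairs: dict[str, dict[int, int]]
    reference_label: str = ""

    def __post_init__(self) -> None:
        for cid, mapping in self.pairs.items():
            refs = list(mapping.values())
            if len(refs) != len(set(refs)):
                raise ValueError(f"chain {cid}: numbering map is not injective")


def _resolve_alt_locs(atoms: list[Atom]) -> list[Atom]:
    """Keep one location per atom name: highest occupancy, ties by alt-loc id."""
    by_name: dict[str, Atom] = {}
    for a in atoms:
        prev = by_name.get(a.name)
        if prev is None:
            by_name[a.name] = a
        elif (a.occupancy, _neg_ord(a.alt_loc)) > (prev.occupancy, _neg_ord(prev.alt_loc)):
            by_name[a.name] = a
    return list(by_name.values())


def _neg_ord(alt: str) -> int:
    # lexicographically first alt-loc wins ties -> larger sort key
    return -ord(alt) if alt else 0


def read_structure(path: str | Path, fmt: str = "auto") -> StructureModel:
    """Read an mmCIF or PDB coordinate file into a :class:`StructureModel`.

    All ATOM/HETATM records of polymer chains are loaded; waters and
    free ions are excluded; alternate locations are resolved to the
    highest-occupancy conformer.  Only the first model of a multi-model
    file is read.
    """
    path = Path(path)
    if not path.exists():
        raise StructureIOError(f"no such file: {path}")
    fmt = fmt.lower()
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
        elif fmt == "auto":
            st = gemmi.read_structure(str(path))
        else:
            raise StructureIOError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureIOError(f"cannot parse {path}: {exc}") from exc

    st.setup_entities()
    if len(st) == 0:
        raise StructureIOError(f"{path}: file contains no model")
    model = st[0]

    chains: dict[str, list[Residue]] = {}
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            if res.is_water():
                continue
            if len(res) == 1 and res[0].element.is_metal:
                continue  # free ion
            name = res.name.strip()
            parent = MODIFIED_PARENT.get(name)
            atoms = [
                Atom(
                    name=a.name,
                    element=a.element.name,
                    position=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    occupancy=min(max(a.occ, 0.0), 1.0),
                    b_factor=a.b_iso,
                    alt_loc=a.altloc if a.altloc != "\0" else "",
                )
                for a in res
            ]
            atoms = _resolve_alt_locs(atoms)
            residues.append(
                Residue(
                    chain_id=chain.name,
                    author_number=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    base=parent if parent is not None else "N",
                    name=name,
                    is_modified=parent is not None and name not in "ACGU",
                    atoms=atoms,
                )
            )
        if residues:
            residues.sort(key=lambda r: (r.author_number, r.insertion_code))
            chains[chain.name] = residues
    if not chains:
        raise StructureIOError(f"{path}: no polymer residues found")
    return StructureModel(source_id=path.stem, chains=chains)


def write_structure(model: StructureModel, path: str | Path, fmt: str = "auto") -> None:
    """Write the model as a standard-conformant mmCIF or PDB file."""
    path = Path(path)
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    if model.n_atoms() == 0:
        raise StructureIOError("refusing to write an empty model")

    st = gemmi.Structure()
    st.name = model.source_id
    gm = gemmi.Model("1")
    for cid, residues in model.chains.items():
        ch = gemmi.Chain(cid)
        for res in residues:
            gr = gemmi.Residue()
            gr.name = res.name or res.base
            gr.seqid = gemmi.SeqId(res.author_number, res.insertion_code or " ")
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.position)
                ga.occ = a.occupancy
                ga.b_iso = a.b_factor
                ga.altloc = a.alt_loc or "\0"
                gr.add_atom(ga)
            ch.add_residue(gr)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    try:
        if fmt == "pdb":
            st.write_pdb(str(path))
        elif fmt == "mmcif":
            st.make_mmcif_document().write_file(str(path))
        else:
            raise StructureIOError(f"unknown format {fmt!r}")
    except (RuntimeError, OSError) as exc:
        raise StructureIOError(f"cannot write {path}: {exc}") from exc


def select_rrna(
    model: StructureModel,
    selector: Iterable[str] | str = "auto",
    min_len: int = 100,
    min_rna_fraction: float = 0.9,
) -> StructureModel:
    """Filter a model down to its rRNA chains.

    ``selector`` is either an iterable of chain ids or ``"auto"``, in which
    case polymer chains whose residues are at least ``min_rna_fraction``
    ribonucleotides and whose length is at least ``min_len`` are kept.
    Idempotent: re-selecting a selected model changes nothing.
    """
    if model.n_residues() == 0:
        raise EmptySelectionError("model is empty")
    if isinstance(selector, str) and selector == "auto":
        keep = []
        for cid, residues in model.chains.items():
            n_rna = sum(r.is_ribonucleotide() for r in residues)
            if len(residues) >= min_len and n_rna / len(residues) >= min_rna_fraction:
                keep.append(cid)
    else:
        keep = [c for c in ([selector] if isinstance(selector, str) else list(selector))
                if c in model.chains]
        missing = set([selector] if isinstance(selector, str) else selector) - set(keep)
        if missing:
            raise EmptySelectionError(f"chains not in model: {sorted(missing)}")
    if not keep:
        raise EmptySelectionError("no chain matches the rRNA selection")
    out = model.copy()
    out.chains = {cid: out.chains[cid] for cid in keep}
    return out


def apply_numbering(model: StructureModel, nmap: NumberingMap) -> StructureModel:
    """Attach reference numbering to residues; unmapped residues are kept
    with ``reference_number=None`` (flagged, not dropped)."""
    missing = set(nmap.pairs) - set(model.chains)
    if missing:
        raise MappingError(f"numbering map names absent chains: {sorted(missing)}")
    out = model.copy()
    n_mapped = 0
    for cid, mapping in nmap.pairs.items():
        for res in out.chains[cid]:
            ref = mapping.get(res.author_number)
            res.reference_number = ref
            n_mapped += ref is not None
    if n_mapped == 0:
        raise MappingError("numbering map covers no residue of the model")
    if nmap.reference_label:
        out.metadata["numbering"] = nmap.reference_label
    return out


def read_numbering_map(path: str | Path, reference_label: str = "") -> NumberingMap:
    """Read a numbering map from TSV with header
    ``chain  author_number  reference_number``."""
    pairs: dict[str, dict[int, int]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if i == 0 and not parts[1].lstrip("-").isdigit():
                continue  # header
            chain, author, ref = parts[0], int(parts[1]), int(parts[2])
            pairs.setdefault(chain, {})[author] = ref
    return NumberingMap(pairs=pairs, reference_label=reference_label)
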