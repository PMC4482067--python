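"""Residue- and atom-level pairing between two conformational states.

Structures solved for the same molecule normally share author numbering, so
the default pairing is by (chain, residue number, insertion code).  When
numbering disagrees, a global sequence alignment of the base letters
establishes the correspondence instead.  Atom pairs are then formed by atom
name within each residue pair; a minimum pair count (default 30, the
all-heavy-atom yield of a single Watson-Crick pair) guards against
superpositions too small to give a reproducible orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
from Bio import Align

if TYPE_CHECKING:
    from .structure_io import Residue, StructureModel

from .structure_io import BACKBONE_ATOMS

__all__ = [
    "ResiduePairing",
    "AtomPairing",
    "CorrespondenceError",
    "InsufficientAtomsError",
    "pair_residues",
    "pair_atoms",
    "MIN_ATOM_PAIRS",
]

#: Default lower bound on superposable atom pairs; one complete
#: Watson-Crick pair already yields at least this many heavy atoms.
MIN_ATOM_PAIRS = 30

ResidueKey = tuple[str, int, str]


class CorrespondenceError(ValueError):
    """No residues could be paired between the two states."""


class InsufficientAtomsError(ValueError):
    """Fewer atom pairs than the configured minimum."""


@dataclass
class ResiduePairing:
    """Ordered one-to-one residue correspondence between states A and B."""

    entries: list[tuple[ResidueKey, ResidueKey]]
    method: str = "by_number"

    def __post_init__(self) -> None:
        a_keys = [e[0] for e in self.entries]
        b_keys = [e[1] for e in self.entries]
        if len(set(a_keys)) != len(a_keys) or len(set(b_keys)) != len(b_keys):
            raise ValueError("residue pairing is not one-to-one")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class AtomPairing:
    """Name-matched atom pairs grouped under a residue pairing."""

    pairs: list[tuple[ResidueKey, ResidueKey, str]]
    atom_subset: str = "all_heavy"

    def __len__(self) -> int:
        return len(self.pairs)

    def coordinates(self, a: "StructureModel", b: "StructureModel"
                    ) -> tuple[np.ndarray, np.ndarray]:
        """Resolve the pairing against two models into (N,3) arrays."""
        idx_a = _residue_index(a)
        idx_b = _residue_index(b)
        ca, cb = [], []
        for key_a, key_b, name in self.pairs:
            atom_a = idx_a[key_a].atom(name)
            atom_b = idx_b[key_b].atom(name)
            if atom_a is None or atom_b is None:
                continue
            ca.append(atom_a.position)
            cb.append(atom_b.position)
        return np.array(ca), np.array(cb)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chain_a\tresnum_a\ticode_a\tchain_b\tresnum_b\ticode_b\tatom\n")
            for (ca, na, ia), (cb, nb, ib), name in self.pairs:
                fh.write(f"{ca}\t{na}\t{ia}\t{cb}\t{nb}\t{ib}\t{name}\n")


def _residue_index(model: "StructureModel") -> dict[ResidueKey, "Residue"]:
    return {res.key: res for res in model.residues()}


def pair_residues(a: "StructureModel", b: "StructureModel",
                  method: str = "by_number") -> ResiduePairing:
    """Pair residues of two states.

    ``by_number`` pairs identical (chain, author number, insertion code);
    ``by_alignment`` runs a global alignment of base letters per shared
    chain (match +1, mismatch -1, gap -2) and pairs aligned non-gap columns.
    """
    if a.n_residues() == 0 or b.n_residues() == 0:
        raise CorrespondenceError("cannot pair residues of an empty model")
    entries: list[tuple[ResidueKey, ResidueKey]] = []
    if method == "by_number":
        idx_b = _residue_index(b)
        for res in a.residues():
            if res.key in idx_b:
                entries.append((res.key, res.key))
    elif method == "by_alignment":
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -2
        for cid in a.chains:
            if cid not in b.chains:
                continue
            res_a = a.chains[cid]
            res_b = b.chains[cid]
            seq_a = "".join(r.base if r.base in "ACGU" else "N" for r in res_a)
            seq_b = "".join(r.base if r.base in "ACGU" else "N" for r in res_b)
            aln = aligner.align(seq_a, seq_b)[0]
            for (sa, ea), (sb, eb) in zip(*aln.aligned):
                for i, j in zip(range(sa, ea), range(sb, eb)):
                    entries.append((res_a[i].key, res_b[j].key))
    else:
        raise ValueError(f"unknown pairing method {method!r}")
    if not entries:
        raise CorrespondenceError(
            f"no residues pairable between {a.source_id} and {b.source_id}")
    return ResiduePairing(entries=entries, method=method)


def pair_atoms(
    rp: ResiduePairing,
    a: "StructureModel",
    b: "StructureModel",
    atom_subset: str | Sequence[str] = "all_heavy",
    min_pairs: int = MIN_ATOM_PAIRS,
) -> AtomPairing:
    """Form name-matched atom pairs under a residue pairing.

    ``atom_subset`` is ``all_heavy`` (hydrogen-free), ``backbone`` (the
    12 ribose/phosphate names) or an explicit name list.  Atoms missing on
    either side simply contribute nothing; zero-occupancy atoms are dropped.
    Raises :class:`InsufficientAtomsError` below ``min_pairs`` total.
    """
    if len(rp) == 0:
        raise InsufficientAtomsError("empty residue pairing")
    if isinstance(atom_subset, str):
        if atom_subset == "all_heavy":
            allowed = None
            label = "all_heavy"
        elif atom_subset == "backbone":
            allowed = set(BACKBONE_ATOMS)
            label = "backbone"
        else:
            raise ValueError(f"unknown atom subset {atom_subset!r}")
    else:
        allowed = set(atom_subset)
        label = "named"

    idx_a = _residue_index(a)
    idx_b = _residue_index(b)
    pairs: list[tuple[ResidueKey, ResidueKey, str]] = []
    for key_a, key_b in rp.entries:
        res_a = idx_a.get(key_a)
        res_b = idx_b.get(key_b)
        if res_a is None or res_b is None:
            continue
        names_b = {at.name for at in res_b.atoms if at.occupancy > 0}
        for atom in res_a.atoms:
            if atom.occupancy <= 0 or atom.element == "H":
                continue
            if allowed is not None and atom.name not in allowed:
                continue
            if atom.name in names_b:
                pairs.append((key_a, key_b, atom.name))
    if len(pairs) < min_pairs:
        raise InsufficientAtomsError(
            f"only {len(pairs)} atom pairs; at least {min_pairs} required "
            f"for a reproducible superposition")
    return AtomPairing(pairs=pairs, atom_subset=label)
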