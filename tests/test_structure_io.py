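"""Coordinate I/O, chain selection and reference renumbering."""

import numpy as np
import pytest

from rnapivot.structure_io import (
    Atom,
    EmptySelectionError,
    MappingError,
    NumberingMap,
    Residue,
    StructureModel,
    apply_numbering,
    read_numbering_map,
    read_structure,
    select_rrna,
    write_structure,
)
from rnapivot.synthetic import make_aform_duplex

MINIMAL_PDB = """\
ATOM      1  P     G A   1       1.000   2.000   3.000  1.00 10.00           P
ATOM      2  C1'   G A   1       2.500   2.000   3.000  1.00 10.00           C
END
"""


def test_minimal_pdb_parses_identically(tmp_path):
    path = tmp_path / "mini.pdb"
    path.write_text(MINIMAL_PDB)
    model = read_structure(path, "pdb")
    assert len(model.chains) == 1
    (residues,) = model.chains.values()
    assert len(residues) == 1
    res = residues[0]
    assert res.base == "G" and res.author_number == 1
    np.testing.assert_allclose(res.atom("P").position, [1.0, 2.0, 3.0])


@pytest.mark.parametrize("fmt,suffix,tol", [("pdb", ".pdb", 1e-3),
                                            ("mmcif", ".cif", 1e-4)])
def test_round_trip_preserves_geometry(tmp_path, duplex10, fmt, suffix, tol):
    path = tmp_path / f"duplex{suffix}"
    write_structure(duplex10, path, fmt)
    back = read_structure(path, fmt)
    assert back.n_residues() == duplex10.n_residues()
    assert back.n_atoms() == duplex10.n_atoms()
    assert np.abs(back.all_coords() - duplex10.all_coords()).max() < tol


def test_altloc_resolution_keeps_highest_occupancy(tmp_path):
    """A 20-residue mmCIF file with two alternate locations reads back with
    the B conformers dropped; the oracle is a direct text scan."""
    model = make_aform_duplex(10)
    residues = model.chains["A"][:20]
    model = StructureModel("altloc20", {"A": residues})
    # alt-loc pair on residue 1 C1' (A wins on occupancy) and on residue 2 P
    # (tie on occupancy, lexicographically first id wins)
    r1, r2 = residues[0], residues[1]
    c1 = r1.atom("C1'")
    c1.alt_loc, c1.occupancy = "A", 0.7
    r1.atoms.append(Atom("C1'", "C", c1.position + [0.5, 0, 0], 0.3, 0.0, "B"))
    p2 = r2.atom("P")
    p2.alt_loc, p2.occupancy = "A", 0.5
    r2.atoms.append(Atom("P", "P", p2.position + [0.5, 0, 0], 0.5, 0.0, "B"))
    path = tmp_path / "altloc.cif"
    write_structure(model, path, "mmcif")

    text_atoms = sum(1 for line in path.read_text().splitlines()
                     if line.startswith(("ATOM", "HETATM")))
    n_alt_b = sum(1 for line in path.read_text().splitlines()
                  if line.startswith(("ATOM", "HETATM")) and line.split()[4] == "B")
    assert n_alt_b == 2

    back = read_structure(path, "mmcif")
    assert back.n_atoms() == text_atoms - n_alt_b
    np.testing.assert_allclose(
        back.chains["A"][0].atom("C1'").position, c1.position, atol=1e-3)
    np.testing.assert_allclose(
        back.chains["A"][1].atom("P").position, p2.position, atol=1e-3)


def _bare_chain(chain_id, n, base="G"):
    return [
        Residue(chain_id=chain_id, author_number=i + 1, base=base, name=base,
                atoms=[Atom("P", "P", np.array([float(i), 0.0, 0.0]))])
        for i in range(n)
    ]


def test_auto_selection_census():
    """Auto mode keeps polymer chains that are long enough and mostly RNA:
    of chains with 1500, 120 and 76 residues, the 76-mer is dropped."""
    model = StructureModel("census", {
        "A": _bare_chain("A", 1500),
        "B": _bare_chain("B", 120),
        "C": _bare_chain("C", 76),
    })
    kept = select_rrna(model, "auto", min_len=100)
    assert set(kept.chains) == {"A", "B"}


def test_auto_selection_rejects_protein():
    protein = _bare_chain("P", 150)
    for res in protein:
        res.base = "N"
        res.name = "ALA"
    model = StructureModel("mix", {"R": _bare_chain("R", 150), "P": protein})
    kept = select_rrna(model, "auto", min_len=100)
    assert set(kept.chains) == {"R"}


def test_selection_is_idempotent(duplex10):
    once = select_rrna(duplex10, "auto", min_len=5)
    twice = select_rrna(once, "auto", min_len=5)
    assert set(twice.chains) == set(once.chains)
    assert twice.n_atoms() == once.n_atoms()


def test_explicit_selection_of_absent_chain_errors(duplex10):
    with pytest.raises(EmptySelectionError):
        select_rrna(duplex10, ["Z"])


def test_numbering_identity_offset_and_gaps():
    model = StructureModel("n5", {"A": _bare_chain("A", 5)})
    ident = apply_numbering(model, NumberingMap({"A": {i: i for i in range(1, 6)}}))
    assert [r.reference_number for r in ident.chains["A"]] == [1, 2, 3, 4, 5]

    shifted = apply_numbering(model, NumberingMap({"A": {i: i + 10 for i in range(1, 6)}}))
    assert [r.reference_number for r in shifted.chains["A"]] == [11, 12, 13, 14, 15]

    partial = apply_numbering(
        model, NumberingMap({"A": {i: i for i in (1, 2, 4, 5)}}))
    refs = [r.reference_number for r in partial.chains["A"]]
    assert refs == [1, 2, None, 4, 5]          # residue 3 flagged, not dropped
    assert partial.n_residues() == 5


def test_numbering_preserves_coordinates(duplex10):
    nmap = NumberingMap({"A": {r.author_number: r.author_number + 100
                               for r in duplex10.chains["A"]}})
    renum = apply_numbering(duplex10, nmap)
    assert renum.n_atoms() == duplex10.n_atoms()
    assert np.array_equal(renum.all_coords(), duplex10.all_coords())


def test_numbering_absent_chain_errors(duplex10):
    with pytest.raises(MappingError):
        apply_numbering(duplex10, NumberingMap({"Z": {1: 1}}))


def test_numbering_map_tsv_round_trip(tmp_path):
    path = tmp_path / "map.tsv"
    path.write_text("chain\tauthor_number\treference_number\n"
                    "A\t5\t105\nA\t6\t106\nB\t1\t1\n")
    nmap = read_numbering_map(path, reference_label="reference 16S")
    assert nmap.pairs == {"A": {5: 105, 6: 106}, "B": {1: 1}}
    with pytest.raises(ValueError):
        NumberingMap({"A": {1: 7, 2: 7}})      # not injective
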