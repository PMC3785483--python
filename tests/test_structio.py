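"""PDB parsing, writing, radius assignment and selection."""

import numpy as np
import pytest

from gatewave.structio import (Atom, PDBFormatError, PDBParseError, RadiusTable,
                               Structure, Trajectory, assign_radii, read_pdb,
                               residue_class, select, write_pdb, RESIDUE_CLASSES)

SINGLE_CARBON = (
    "ATOM      1  CA  ALA A   1      11.104  13.207   2.100  1.00  0.00           C\n"
    "END\n"
)


def test_single_atom_roundtrip():
    s = read_pdb(SINGLE_CARBON)
    assert isinstance(s, Structure)
    assert len(s) == 1
    atom = s.atoms[0]
    assert atom.element == "C"
    assert atom.residue_key == ("A", 1, "")
    np.testing.assert_allclose(atom.coords, [11.104, 13.207, 2.100])
    again = read_pdb(write_pdb(s))
    b = again.atoms[0]
    assert (b.name, b.residue_name, b.chain_id, b.residue_number) == \
        (atom.name, atom.residue_name, atom.chain_id, atom.residue_number)
    np.testing.assert_allclose(b.coords, atom.coords, atol=5e-4)


def test_element_inferred_from_name_when_column_blank():
    line = "ATOM      1  OD1 ASP A   2       0.000   0.000   0.000  1.00  0.00\n"
    s = read_pdb(line)
    assert s.atoms[0].element == "O"


def test_multimodel_parses_to_trajectory():
    block = SINGLE_CARBON.replace("END\n", "")
    text = "".join(f"MODEL {m}\n{block}ENDMDL\n" for m in range(1, 4)) + "END\n"
    t = read_pdb(text)
    assert isinstance(t, Trajectory)
    assert len(t) == 3
    for f in t.frames:
        np.testing.assert_allclose(f, t.frames[0])
    assert t.times[0] == 0.0 and np.all(np.diff(t.times) > 0)


def test_malformed_record_names_line_number():
    bad = SINGLE_CARBON.replace("11.104", "xx.xxx")
    with pytest.raises(PDBParseError, match="line 1"):
        read_pdb(bad)


def test_incongruent_models_rejected():
    block2 = SINGLE_CARBON.replace("END\n", "").replace(" CA ", " CB ")
    text = ("MODEL 1\n" + SINGLE_CARBON.replace("END\n", "") + "ENDMDL\n"
            "MODEL 2\n" + block2 + "ENDMDL\nEND\n")
    with pytest.raises(PDBParseError, match="congruent"):
        read_pdb(text)


def test_altloc_policy_keeps_blank_or_a():
    lineA = "ATOM      1  CA AALA A   1       1.000   0.000   0.000  1.00  0.00           C\n"
    lineB = "ATOM      2  CA BALA A   1       2.000   0.000   0.000  1.00  0.00           C\n"
    s = read_pdb(lineA + lineB)
    assert len(s) == 1
    np.testing.assert_allclose(s.atoms[0].coords, [1.0, 0.0, 0.0])


def test_coordinate_field_width_limits():
    a = Atom(1, "CA", "ALA", "A", 1, np.array([9999.999, 0.0, 0.0]), element="C")
    text = write_pdb(Structure([a]))
    assert "9999.999" in text
    b = Atom(1, "CA", "ALA", "A", 1, np.array([10000.0, 0.0, 0.0]), element="C")
    with pytest.raises(PDBFormatError):
        write_pdb(Structure([b]))


def test_trajectory_roundtrip_three_models(tmp_path):
    topo = read_pdb(SINGLE_CARBON)
    frames = [topo.coords + i for i in range(3)]
    traj = Trajectory(topo, frames, [0.0, 1.0, 2.0])
    path = tmp_path / "traj.pdb"
    write_pdb(traj, path)
    back = read_pdb(path)
    assert isinstance(back, Trajectory) and len(back) == 3
    np.testing.assert_allclose(back.times, [0.0, 1.0, 2.0])
    for f, g in zip(back.frames, frames):
        np.testing.assert_allclose(f, g, atol=5e-4)


def test_fixture_roundtrip_matches_biopython(tmp_path, closed_channel):
    """Cross-check our writer/reader against Biopython's parser."""
    Bio = pytest.importorskip("Bio.PDB")
    path = tmp_path / "closed.pdb"
    write_pdb(closed_channel, path)
    parser = Bio.PDBParser(QUIET=True)
    model = parser.get_structure("x", str(path))[0]
    bio_atoms = [a for a in model.get_atoms()]
    assert len(bio_atoms) == len(closed_channel)
    bio_coords = np.array([a.get_coord() for a in bio_atoms])
    np.testing.assert_allclose(bio_coords, closed_channel.coords, atol=5e-4)


def test_fixture_atom_count(closed_channel):
    # 6 helices x 20 residues x 2 beads
    assert len(closed_channel) == 240


def test_radius_assignment_defaults():
    s = read_pdb(SINGLE_CARBON)
    assign_radii(s)
    assert s.atoms[0].vdw_radius == pytest.approx(1.70)


def test_unknown_element_falls_back_with_default():
    a = Atom(1, "XX", "UNK", "A", 1, np.zeros(3), element="Xx")
    s = Structure([a])
    assign_radii(s, RadiusTable())
    assert s.atoms[0].vdw_radius == pytest.approx(1.70)


def test_radius_table_tsv_roundtrip(tmp_path):
    p = tmp_path / "radii.tsv"
    p.write_text("C\t1.90\n# comment\nO\t1.40\n")
    t = RadiusTable.from_tsv(p)
    assert t.by_element["C"] == 1.90 and t.by_element["O"] == 1.40


def test_select_classes_and_names(closed_channel):
    basic = select(closed_channel, "class basic")
    residues = {closed_channel.atoms[i].residue_key for i in basic}
    assert len(residues) == 12  # planted Arg/Lys count in the default fixture
    cas = select(closed_channel, "name CA")
    assert len(cas) == 120
    empty = select(closed_channel, "resid 650-856")
    assert empty == []


def test_select_is_idempotent_and_additive(closed_channel):
    sel = select(closed_channel, "chain A and name CA")
    sub = Structure([closed_channel.atoms[i].copy() for i in sel])
    again = select(sub, "chain A and name CA")
    assert len(again) == len(sel)
    a = set(select(closed_channel, "chain A"))
    b = set(select(closed_channel, "chain B"))
    ab = set(select(closed_channel, "chain A")) | b
    assert a.isdisjoint(b) and len(ab) == len(a) + len(b)


def test_invalid_selection_raises(closed_channel):
    with pytest.raises(ValueError):
        select(closed_channel, "chains A")
    with pytest.raises(ValueError):
        select(closed_channel, "class metallic")


def test_residue_classes_partition():
    seen = set()
    for members in RESIDUE_CLASSES.values():
        assert seen.isdisjoint(members)
        seen |= members
    assert residue_class("ARG") == "basic"
    assert residue_class("GLY") is None
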