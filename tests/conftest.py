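"""Shared fixtures: hand-written PDB texts and small synthetic objects."""

from __future__ import annotations

import numpy as np
import pytest

from condock.pose_synth import (
    SyntheticSpec,
    generate_ensemble,
    make_sidechain_complex,
    make_toy_complex,
)
from condock.structmodel import Atom, Pose, ProteinStructure, Residue


def _pdb_line(serial, name, res_name, chain, res_seq, x, y, z, element,
              occ=1.00, alt=" ", i_code=" ", record="ATOM"):
    return (f"{record:<6s}{serial:>5d} {name:^4s}{alt}{res_name:>3s} {chain}"
            f"{res_seq:>4d}{i_code}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
            f"          {element:>2s}")


@pytest.fixture
def three_res_pdb(tmp_path):
    """Hand-written two-chain PDB: 2 chain-A residues + 1 chain-B residue,
    plus a hydrogen and a water that must be filtered out."""
    lines = [
        _pdb_line(1, "N", "GLY", "A", 1, 0.0, 0.0, 0.0, "N"),
        _pdb_line(2, "CA", "GLY", "A", 1, 1.5, 0.0, 0.0, "C"),
        _pdb_line(3, "C", "GLY", "A", 1, 2.0, 1.4, 0.0, "C"),
        _pdb_line(4, "HA", "GLY", "A", 1, 1.5, -1.0, 0.0, "H"),
        _pdb_line(5, "N", "ALA", "A", 2, 3.2, 1.5, 0.3, "N"),
        _pdb_line(6, "CA", "ALA", "A", 2, 4.0, 2.6, 0.6, "C"),
        _pdb_line(7, "CB", "ALA", "A", 2, 5.2, 2.2, 1.4, "C"),
        _pdb_line(8, "N", "SER", "B", 1, 0.0, 5.0, 0.0, "N"),
        _pdb_line(9, "CA", "SER", "B", 1, 1.3, 5.5, 0.4, "C"),
        _pdb_line(10, "OG", "SER", "B", 1, 2.1, 6.3, -0.5, "O"),
        _pdb_line(11, "O", "HOH", "B", 90, 8.0, 8.0, 8.0, "O", record="HETATM"),
        "END",
    ]
    path = tmp_path / "three_res.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    """One residue whose CA has two alternate locations (occ 0.6 vs 0.4)."""
    lines = [
        _pdb_line(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0, "N"),
        _pdb_line(2, "CA", "ALA", "A", 1, 1.5, 0.0, 0.0, "C", occ=0.60, alt="A"),
        _pdb_line(3, "CA", "ALA", "A", 1, 1.6, 0.1, 0.0, "C", occ=0.40, alt="B"),
        _pdb_line(4, "C", "ALA", "A", 1, 2.0, 1.4, 0.0, "C"),
        _pdb_line(5, "CB", "ALA", "A", 1, 1.8, -1.2, 0.9, "C"),
        "END",
    ]
    path = tmp_path / "altloc.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def toy_complex():
    return make_toy_complex(20, 10, seed=1)


@pytest.fixture(scope="session")
def sidechain_complex():
    return make_sidechain_complex(20, 10, seed=1)


@pytest.fixture(scope="session")
def sidechain_pose(sidechain_complex):
    rec, lig = sidechain_complex
    return Pose("wt:pose_001", rec, lig, engine="wt", rank=1)


@pytest.fixture(scope="session")
def default_ensemble(sidechain_complex):
    """70-pose, 3-mode synthetic ensemble under the default conditions."""
    spec = SyntheticSpec(seed=11)
    poses, truth = generate_ensemble(spec, sidechain_complex)
    return spec, poses, truth


def make_residue(chain, seq, name, atom_specs, i_code=""):
    """atom_specs: iterable of (atom_name, element, (x, y, z))."""
    atoms = [Atom(n, e, np.array(c, dtype=float)) for n, e, c in atom_specs]
    return Residue(chain, seq, i_code, name, atoms)


def single_atom_structure(structure_id, chain, coords_by_residue):
    """Structure with one CA-like atom per residue, for geometric fixtures."""
    residues = [
        make_residue(chain, i + 1, "GLY", [("CA", "C", c)])
        for i, c in enumerate(coords_by_residue)
    ]
    return ProteinStructure(structure_id, residues)
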