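import numpy as np
import pytest


def _pdb_atom(serial, name, resname, chain, resseq, x, y, z, element):
    return (
        f"ATOM  {serial:5d} {name:<4s}{'':1s}{resname:>3s} {chain:1s}{resseq:4d}{'':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
    )


def make_toy_pdb(atoms) -> str:
    """Build a minimal PDB text from (name, resname, chain, resseq, xyz, element) tuples."""
    lines = [
        _pdb_atom(i + 1, name, resname, chain, resseq, *xyz, element)
        for i, (name, resname, chain, resseq, xyz, element) in enumerate(atoms)
    ]
    return "\n".join(lines) + "\nEND\n"


@pytest.fixture
def toy_structure_atoms():
    """Two-residue RNA chain A plus a two-residue protein chain B, with
    hand-placed coordinates so minimum distances are known exactly."""
    return [
        ("P", "A", "A", 1, (0.0, 0.0, 0.0), "P"),
        ("C1'", "A", "A", 1, (0.0, 0.0, 2.0), "C"),
        ("N1", "G", "A", 2, (0.0, 4.0, 0.0), "N"),
        ("C1'", "G", "A", 2, (0.0, 4.0, 2.0), "C"),
        ("CA", "ALA", "B", 10, (0.0, 0.0, 5.0), "C"),
        ("CB", "ALA", "B", 10, (3.0, 0.0, 0.0), "C"),
        ("CA", "GLY", "B", 11, (0.0, 40.0, 0.0), "C"),
    ]


@pytest.fixture
def toy_pdb_file(tmp_path, toy_structure_atoms):
    path = tmp_path / "toy.pdb"
    path.write_text(make_toy_pdb(toy_structure_atoms))
    return path
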