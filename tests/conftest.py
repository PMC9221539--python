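"""Shared fixtures: tiny hand-written coordinate files and synthetic helpers.

All fixture files are generated at test time; nothing binary is stored.
"""

from __future__ import annotations

import numpy as np
import pytest

from structvalid.structio import AtomRecord, Residue, Structure


def pdb_atom_line(serial, name, resname, chain, resseq, x, y, z,
                  occ=1.0, b=0.0, element="C", altloc=" ", icode=" ") -> str:
    """One fixed-column ATOM record."""
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {name_field}{altloc}{resname:<3s} {chain}{resseq:4d}{icode}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {element:>2s}"
    )


@pytest.fixture
def three_residue_pdb(tmp_path):
    """Minimal 3-residue Cα-trace PDB file with known coordinates."""
    lines = [
        pdb_atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, b=10.0),
        pdb_atom_line(2, "CA", "GLY", "A", 2, 3.8, 0.0, 0.0, b=20.0),
        pdb_atom_line(3, "CA", "SER", "A", 3, 7.6, 0.0, 0.0, b=30.0),
        "END",
    ]
    path = tmp_path / "three.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    """One residue whose CA has altlocs A (occ 0.60) and B (occ 0.40)."""
    lines = [
        pdb_atom_line(1, "N", "ALA", "A", 1, -1.4, 0.0, 0.0, element="N"),
        pdb_atom_line(2, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, occ=0.60, altloc="A"),
        pdb_atom_line(3, "CA", "ALA", "A", 1, 0.5, 0.5, 0.0, occ=0.40, altloc="B"),
        pdb_atom_line(4, "C", "ALA", "A", 1, 1.5, 0.0, 0.0),
        pdb_atom_line(5, "O", "ALA", "A", 1, 2.2, 1.0, 0.0, element="O"),
        "END",
    ]
    path = tmp_path / "altloc.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


def ca_structure(coords, sid="s", chain="A", start=1, source="predicted",
                 bfactors=None, resolution=None) -> Structure:
    """Cα-trace Structure from an (n, 3) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    residues = []
    for i, c in enumerate(coords):
        b = 0.0 if bfactors is None else float(bfactors[i])
        residues.append(
            Residue(chain, start + i, "", "ALA", [AtomRecord("CA", "C", c, tempfactor=b)])
        )
    return Structure(id=sid, residues=residues, source=source, resolution=resolution,
                     space_group="P 1" if source == "crystal" else None)


def full_residue(chain, seqnum, name="ALA", offset=(0.0, 0.0, 0.0), b=0.0) -> Residue:
    """Residue with N/CA/C/O/CB in a plausible local geometry."""
    off = np.asarray(offset, dtype=float)
    tmpl = {
        "N": (-1.458, 0.0, 0.0),
        "CA": (0.0, 0.0, 0.0),
        "C": (0.55, 1.42, 0.0),
        "O": (1.76, 1.62, 0.0),
        "CB": (-0.54, -0.77, 1.21),
    }
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
    atoms = [AtomRecord(n, elements[n], np.array(c) + off) for n, c in tmpl.items()]
    return Residue(chain, seqnum, "", name, atoms)


def rigid_motion(coords: np.ndarray, seed: int = 0) -> np.ndarray:
    """Apply a random proper rotation + translation to an (n, 3) array."""
    from structvalid.synthfix import random_rotation

    rng = np.random.default_rng(seed)
    rot = random_rotation(rng)
    trans = rng.uniform(-20, 20, size=3)
    return coords @ rot.T + trans
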