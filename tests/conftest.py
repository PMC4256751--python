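import numpy as np
import pytest

from ptmgraft import PeptideSpec, build_cage, build_peptide
from ptmgraft.structure_io import Structure


def merge_structures(*parts: Structure) -> Structure:
    """Combine residues of several structures into one (re-inferring bonds)."""
    out = Structure()
    for part in parts:
        for res in part.residues:
            out.add_residue(res)
    out.assign_n_terminal_flags()
    out.infer_bonds()
    return out


def translate(structure: Structure, offset) -> Structure:
    offset = np.asarray(offset, dtype=float)
    for atom in structure.atoms():
        atom.coords = atom.coords + offset
    return structure


@pytest.fixture
def pentapeptide():
    return build_peptide(PeptideSpec("GAKYA"))


@pytest.fixture
def triple_lys():
    """Three lysines separated by alanines, extended, fully exposed."""
    return build_peptide(PeptideSpec("KAKAK"))


@pytest.fixture
def buried_exposed_lys():
    """Chain A lysine sealed in an occluding cage, chain B lysine free.

    Returns (structure, buried NZ atom, exposed NZ atom); the buried NZ
    area is far below 25 A^2 and the exposed one far above.
    """
    inner = build_peptide(PeptideSpec("K", chain_id="A"))
    atoms = list(inner.atoms())
    centroid = np.mean([a.coords for a in atoms], axis=0)
    extent = max(float(np.linalg.norm(a.coords - centroid)) for a in atoms)
    caged = build_cage(inner, extent + 3.2, 800, chain_id="X")
    outer = translate(build_peptide(PeptideSpec("K", chain_id="B")), [80.0, 0.0, 0.0])
    merged = merge_structures(caged, outer)
    buried = merged.residue("A", 1).atom("NZ")
    exposed = merged.residue("B", 1).atom("NZ")
    return merged, buried, exposed
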