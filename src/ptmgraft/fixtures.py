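"""Programmatic generation of test structures.

``build_peptide`` constructs all-heavy-atom peptides from ideal internal
coordinates (Engh/Huber-style backbone values, side chains at all-anti
chi angles), deterministic and download-free.  ``build_cage`` surrounds a
structure with a shell of occluding pseudo-residues so that interior
atoms become solvent-inaccessible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from ._chemdata import ONE_TO_THREE
from .geometry_core import InternalCoordinate, place_atom
from .structure_io import Atom, Residue, Structure
from .surface_selection import fibonacci_sphere

__all__ = ["PeptideSpec", "build_peptide", "build_cage"]

# backbone ideal values (lengths A, angles deg)
N_CA = 1.458
CA_C = 1.525
C_N = 1.329
C_O = 1.231
ANG_N_CA_C = 111.2
ANG_CA_C_N = 116.2
ANG_C_N_CA = 121.7
ANG_CA_C_O = 120.8
OMEGA = 180.0

CONFORMATIONS = {"helix": (-57.0, -47.0), "extended": (-140.0, 135.0)}

# L-configuration CB improper: dihedral(C, N, CA, CB); sign fixed so that
# the CA stereocenter labels S for every residue but cysteine/glycine
CB_IMPROPER = (-122.5, 110.5, 1.530)  # (dihedral, angle N-CA-CB, length)

# side-chain internal coordinates: (name, element, (a, b, c), length, angle, dihedral);
# chain chi angles all-anti (180), branches at staggered +-60/120
_SC: dict[str, list[tuple]] = {
    "GLY": [],
    "ALA": [],
    "SER": [("OG", "O", ("N", "CA", "CB"), 1.417, 110.8, 180.0)],
    "CYS": [("SG", "S", ("N", "CA", "CB"), 1.808, 113.8, 180.0)],
    "THR": [
        ("OG1", "O", ("N", "CA", "CB"), 1.433, 109.6, 180.0),
        ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, 55.0),
    ],
    "VAL": [
        ("CG1", "C", ("N", "CA", "CB"), 1.527, 110.5, -175.0),
        ("CG2", "C", ("N", "CA", "CB"), 1.527, 110.5, 55.0),
    ],
    "LEU": [
        ("CG", "C", ("N", "CA", "CB"), 1.530, 116.3, 180.0),
        ("CD1", "C", ("CA", "CB", "CG"), 1.521, 110.7, 180.0),
        ("CD2", "C", ("CA", "CB", "CG"), 1.521, 110.7, 60.0),
    ],
    "ILE": [
        ("CG1", "C", ("N", "CA", "CB"), 1.530, 110.4, -175.0),
        ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, -65.0),
        ("CD1", "C", ("CA", "CB", "CG1"), 1.513, 113.8, 180.0),
    ],
    "MET": [
        ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, 180.0),
        ("SD", "S", ("CA", "CB", "CG"), 1.803, 112.7, 180.0),
        ("CE", "C", ("CB", "CG", "SD"), 1.791, 100.2, 180.0),
    ],
    "LYS": [
        ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, 180.0),
        ("CD", "C", ("CA", "CB", "CG"), 1.520, 111.3, 180.0),
        ("CE", "C", ("CB", "CG", "CD"), 1.520, 111.3, 180.0),
        ("NZ", "N", ("CG", "CD", "CE"), 1.489, 111.9, 180.0),
    ],
    "ARG": [
        ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, 180.0),
        ("CD", "C", ("CA", "CB", "CG"), 1.520, 111.3, 180.0),
        ("NE", "N", ("CB", "CG", "CD"), 1.460, 112.0, 180.0),
        ("CZ", "C", ("CG", "CD", "NE"), 1.330, 124.2, 180.0),
        ("NH1", "N", ("CD", "NE", "CZ"), 1.326, 120.0, 0.0),
        ("NH2", "N", ("CD", "NE", "CZ"), 1.326, 120.0, 180.0),
    ],
    "ASP": [
        ("CG", "C", ("N", "CA", "CB"), 1.516, 112.6, 180.0),
        ("OD1", "O", ("CA", "CB", "CG"), 1.249, 118.4, 50.0),
        ("OD2", "O", ("CA", "CB", "CG"), 1.249, 118.4, -130.0),
    ],
    "ASN": [
        ("CG", "C", ("N", "CA", "CB"), 1.516, 112.6, 180.0),
        ("OD1", "O", ("CA", "CB", "CG"), 1.231, 120.8, 50.0),
        ("ND2", "N", ("CA", "CB", "CG"), 1.328, 116.4, -130.0),
    ],
    "GLU": [
        ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, 180.0),
        ("CD", "C", ("CA", "CB", "CG"), 1.516, 112.6, 180.0),
        ("OE1", "O", ("CB", "CG", "CD"), 1.249, 118.4, 0.0),
        ("OE2", "O", ("CB", "CG", "CD"), 1.249, 118.4, 180.0),
    ],
    "GLN": [
        ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, 180.0),
        ("CD", "C", ("CA", "CB", "CG"), 1.516, 112.6, 180.0),
        ("OE1", "O", ("CB", "CG", "CD"), 1.231, 120.8, 0.0),
        ("NE2", "N", ("CB", "CG", "CD"), 1.328, 116.4, 180.0),
    ],
    # near-planar pucker chosen so the CD-N ring closure lands at 1.47 A
    "PRO": [
        ("CG", "C", ("N", "CA", "CB"), 1.492, 104.5, 11.0),
        ("CD", "C", ("CA", "CB", "CG"), 1.503, 106.1, 5.0),
    ],
    "PHE": [
        ("CG", "C", ("N", "CA", "CB"), 1.502, 113.8, 180.0),
        ("CD1", "C", ("CA", "CB", "CG"), 1.384, 120.8, 70.0),
        ("CD2", "C", ("CA", "CB", "CG"), 1.384, 120.8, -110.0),
        ("CE1", "C", ("CB", "CG", "CD1"), 1.382, 120.8, 180.0),
        ("CE2", "C", ("CB", "CG", "CD2"), 1.382, 120.8, 180.0),
        ("CZ", "C", ("CG", "CD1", "CE1"), 1.382, 120.0, 0.0),
    ],
    "TYR": [
        ("CG", "C", ("N", "CA", "CB"), 1.512, 113.8, 180.0),
        ("CD1", "C", ("CA", "CB", "CG"), 1.389, 120.8, 70.0),
        ("CD2", "C", ("CA", "CB", "CG"), 1.389, 120.8, -110.0),
        ("CE1", "C", ("CB", "CG", "CD1"), 1.382, 121.2, 180.0),
        ("CE2", "C", ("CB", "CG", "CD2"), 1.382, 121.2, 180.0),
        ("CZ", "C", ("CG", "CD1", "CE1"), 1.378, 119.6, 0.0),
        ("OH", "O", ("CD1", "CE1", "CZ"), 1.376, 119.9, 180.0),
    ],
    "TRP": [
        ("CG", "C", ("N", "CA", "CB"), 1.498, 113.6, 180.0),
        ("CD1", "C", ("CA", "CB", "CG"), 1.365, 126.9, 50.0),
        ("CD2", "C", ("CA", "CB", "CG"), 1.433, 126.8, -130.0),
        ("NE1", "N", ("CB", "CG", "CD1"), 1.374, 110.2, 180.0),
        ("CE2", "C", ("CB", "CG", "CD2"), 1.409, 107.2, 180.0),
        ("CE3", "C", ("CB", "CG", "CD2"), 1.398, 133.9, 0.0),
        ("CZ2", "C", ("CG", "CD2", "CE2"), 1.394, 122.4, 180.0),
        ("CZ3", "C", ("CG", "CD2", "CE3"), 1.382, 118.6, 180.0),
        ("CH2", "C", ("CD2", "CE3", "CZ3"), 1.368, 121.1, 0.0),
    ],
    "HIS": [
        ("CG", "C", ("N", "CA", "CB"), 1.497, 113.8, 180.0),
        ("ND1", "N", ("CA", "CB", "CG"), 1.371, 122.7, 40.0),
        ("CD2", "C", ("CA", "CB", "CG"), 1.356, 131.1, -140.0),
        ("CE1", "C", ("CB", "CG", "ND1"), 1.319, 109.0, 180.0),
        ("NE2", "N", ("CB", "CG", "CD2"), 1.374, 107.2, 180.0),
    ],
}


@dataclass
class PeptideSpec:
    """Sequence plus backbone conformation for a generated peptide."""

    sequence: str
    conformation: Union[str, Sequence[tuple[float, float]]] = "extended"
    chain_id: str = "A"
    first_resi: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        bad = [c for c in self.sequence.upper() if c not in ONE_TO_THREE]
        if bad:
            raise ValueError(f"unknown residue letter(s): {''.join(sorted(set(bad)))}")

    def phi_psi(self) -> list[tuple[float, float]]:
        if isinstance(self.conformation, str):
            try:
                phi, psi = CONFORMATIONS[self.conformation]
            except KeyError:
                raise ValueError(
                    f"unknown conformation {self.conformation!r}; "
                    f"use one of {sorted(CONFORMATIONS)} or an explicit (phi, psi) list"
                ) from None
            return [(phi, psi)] * len(self.sequence)
        angles = [tuple(a) for a in self.conformation]
        if len(angles) != len(self.sequence):
            raise ValueError("need one (phi, psi) pair per residue")
        return angles  # type: ignore[return-value]


def _ic(refs, length, angle, dihedral) -> InternalCoordinate:
    return InternalCoordinate(refs[0], refs[1], refs[2], length, angle, dihedral)


def build_peptide(spec: PeptideSpec) -> Structure:
    """All-heavy-atom peptide at ideal geometry.

    Backbone torsions follow the requested conformation; side chains sit
    at canonical all-anti rotamers.  The result round-trips through the
    PDB reader/writer and carries inferred bonds and N-terminal flags.
    """
    seq = spec.sequence.upper()
    angles = spec.phi_psi()
    structure = Structure(source=f"build_peptide({seq})")

    serial = 0
    coords: list[dict[str, np.ndarray]] = []
    residues: list[Residue] = []
    for i, letter in enumerate(seq):
        resn = ONE_TO_THREE[letter]
        res = Residue(chain_id=spec.chain_id, resi=spec.first_resi + i, resn=resn)
        structure.add_residue(res)
        residues.append(res)
        coords.append({})

    def put(i: int, name: str, element: str, xyz: np.ndarray) -> None:
        nonlocal serial
        serial += 1
        residues[i].add_atom(Atom(serial=serial, name=name, element=element, coords=xyz))
        coords[i][name] = xyz

    for i, letter in enumerate(seq):
        phi, psi = angles[i]
        if i == 0:
            n = np.zeros(3)
            ca = np.array([N_CA, 0.0, 0.0])
            alpha = np.deg2rad(180.0 - ANG_N_CA_C)
            c = ca + CA_C * np.array([np.cos(alpha), np.sin(alpha), 0.0])
            put(0, "N", "N", n)
            put(0, "CA", "C", ca)
            put(0, "C", "C", c)
        else:
            prev = coords[i - 1]
            n = place_atom(
                prev["N"], prev["CA"], prev["C"],
                _ic(("N", "CA", "C"), C_N, ANG_CA_C_N, angles[i - 1][1]),
            )
            put(i, "N", "N", n)
            ca = place_atom(
                prev["CA"], prev["C"], n,
                _ic(("CA", "C", "N"), N_CA, ANG_C_N_CA, OMEGA),
            )
            put(i, "CA", "C", ca)
            c = place_atom(
                prev["C"], n, ca,
                _ic(("C", "N", "CA"), CA_C, ANG_N_CA_C, phi),
            )
            put(i, "C", "C", c)
            # carbonyl O of the previous residue: anti to this N,
            # i.e. dihedral(N(i-1), CA, C, O) = psi(i-1) + 180
            o_prev = place_atom(
                prev["N"], prev["CA"], prev["C"],
                _ic(("N", "CA", "C"), C_O, ANG_CA_C_O, angles[i - 1][1] + 180.0),
            )
            put(i - 1, "O", "O", o_prev)

        if resn_has_cb(seq[i]):
            dih, ang, length = CB_IMPROPER
            cb = place_atom(c, n, ca, _ic(("C", "N", "CA"), length, ang, dih))
            put(i, "CB", "C", cb)
        for name, element, refs, length, ang, dih in _SC[ONE_TO_THREE[seq[i]]]:
            a, b, cc = (coords[i][r] for r in refs)
            put(i, name, element, place_atom(a, b, cc, _ic(refs, length, ang, dih)))

    # C-terminal carbonyl + carboxylate
    last = len(seq) - 1
    psi_last = angles[last][1]
    o = place_atom(
        coords[last]["N"], coords[last]["CA"], coords[last]["C"],
        _ic(("N", "CA", "C"), C_O, ANG_CA_C_O, psi_last + 180.0),
    )
    put(last, "O", "O", o)
    oxt = place_atom(
        coords[last]["N"], coords[last]["CA"], coords[last]["C"],
        _ic(("N", "CA", "C"), C_O, 117.0, psi_last),
    )
    put(last, "OXT", "O", oxt)

    structure.assign_n_terminal_flags()
    structure.infer_bonds()
    return structure


def resn_has_cb(letter: str) -> bool:
    return letter.upper() != "G"


def build_cage(
    center_atoms: Structure,
    shell_radius: float,
    n_shell: int,
    chain_id: Optional[str] = None,
) -> Structure:
    """Surround a structure with a spherical shell of occluding atoms.

    Shell atoms are carbon pseudo-residues (resn ALA, one CB atom each)
    on a Fibonacci lattice centred on the input's centroid, so that
    interior atoms' solvent accessibility drops below any practical
    cutoff.  ``n_shell = 0`` returns the structure unchanged.
    """
    atoms = list(center_atoms.atoms())
    if not atoms:
        raise ValueError("cannot cage an empty structure")
    centroid = np.mean([a.coords for a in atoms], axis=0)
    extent = max(float(np.linalg.norm(a.coords - centroid)) for a in atoms)
    if n_shell > 0 and shell_radius <= extent + 3.0:
        raise ValueError(
            f"shell radius {shell_radius:.2f} too small: need > {extent + 3.0:.2f} A "
            "(max extent + 3 A)"
        )
    if n_shell == 0:
        return center_atoms

    if chain_id is None:
        used = set(center_atoms.chains)
        chain_id = next(c for c in "XYZWVU0123456789" if c not in used)

    serial = max((a.serial for a in atoms), default=0)
    directions = fibonacci_sphere(n_shell)
    for i, direction in enumerate(directions):
        serial += 1
        res = Residue(chain_id=chain_id, resi=i + 1, resn="ALA")
        res.add_atom(
            Atom(
                serial=serial,
                name="CB",
                element="C",
                coords=centroid + shell_radius * direction,
            )
        )
        center_atoms.add_residue(res)
    center_atoms.assign_n_terminal_flags()
    center_atoms.infer_bonds()
    return center_atoms
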