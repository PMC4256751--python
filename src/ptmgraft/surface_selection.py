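"""Per-atom solvent-accessible surface area and cutoff filtering.

Shrake-Rupley with a deterministic Fibonacci sphere lattice: for each
heavy atom, the fraction of quasi-uniform test points on the expanded
sphere (r_vdw + probe) that fall outside every other atom's expanded
sphere, times the full sphere area.  Hydrogens are excluded from both the
test set and the occlusion set; waters and non-polymer heteroatoms are
excluded from occlusion by default because modification models the
unliganded, solvent-exposed state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ._chemdata import VDW_RADII, vdw_radius
from .structure_io import Atom, Structure

__all__ = ["SasaResult", "compute_sasa", "surface_filter", "fibonacci_sphere"]

logger = logging.getLogger(__name__)


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the sphere (golden-angle lattice)."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


@dataclass
class SasaResult:
    """Per-atom accessible areas in square Angstrom."""

    areas: dict[Atom, float]
    probe_radius: float
    n_sphere_points: int

    def area(self, atom: Atom) -> float:
        return self.areas[atom]

    def __contains__(self, atom: Atom) -> bool:
        return atom in self.areas


def _occluder_atoms(structure: Structure, include_nonpolymer: bool) -> list[Atom]:
    out = []
    for res in structure.residues:
        if not include_nonpolymer and not res.is_polymer:
            continue
        out.extend(res.heavy_atoms())
    return out


def compute_sasa(
    structure: Structure,
    probe: float = 1.4,
    n_points: int = 960,
    include_nonpolymer: bool = False,
) -> SasaResult:
    """Per-atom Shrake-Rupley solvent-accessible surface area.

    Every atom of the structure gets an entry: heavy atoms of the
    occlusion set get their computed area, everything else (hydrogens,
    and waters/ligands unless ``include_nonpolymer``) gets 0.0.
    """
    occluders = _occluder_atoms(structure, include_nonpolymer)
    if not occluders:
        raise ValueError("structure has no heavy atoms to analyse")

    unknown = {a.element for a in occluders if a.element.upper() not in VDW_RADII}
    for element in sorted(unknown):
        logger.warning(
            "no van-der-Waals radius for element %r; using default 1.80 A", element
        )

    coords = np.array([a.coords for a in occluders])
    radii = np.array([vdw_radius(a.element) + probe for a in occluders])
    max_r = float(radii.max())
    tree = cKDTree(coords)
    sphere = fibonacci_sphere(n_points)

    areas: dict[Atom, float] = {a: 0.0 for a in structure.atoms()}
    for i, atom in enumerate(occluders):
        r_i = radii[i]
        neighbors = [j for j in tree.query_ball_point(coords[i], r_i + max_r) if j != i]
        points = coords[i] + r_i * sphere
        if neighbors:
            nb_coords = coords[neighbors]
            nb_r2 = radii[neighbors] ** 2
            d2 = ((points[:, None, :] - nb_coords[None, :, :]) ** 2).sum(axis=2)
            accessible = int(np.count_nonzero(~(d2 < nb_r2[None, :]).any(axis=1)))
        else:
            accessible = n_points
        areas[atom] = 4.0 * np.pi * r_i * r_i * accessible / n_points

    return SasaResult(areas=areas, probe_radius=probe, n_sphere_points=n_points)


def surface_filter(sasa: SasaResult, targets, cutoff: float) -> set[Atom]:
    """Targets whose per-atom accessible area meets the cutoff (>= cutoff)."""
    if cutoff < 0:
        raise ValueError("surface cutoff must be non-negative")
    missing = [a for a in targets if a not in sasa]
    if missing:
        raise KeyError(f"{len(missing)} target atom(s) missing from the SASA result")
    return {a for a in targets if sasa.area(a) >= cutoff}
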