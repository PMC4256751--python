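"""Local van-der-Waals strain scoring and torsion-scan minimization.

Strain is a coarse steric screen, not a force field: for every relevant
atom pair the penalty is ``max(0, r_i + r_j - d)^2`` (quadratic overlap,
square Angstrom) summed over pairs.  Pairs closer than four bonds on the
covalent graph are excluded (1-2, 1-3 always; 1-4 scaled to zero), and
hydrogens are ignored throughout.  The optimizer grid-scans side-chain
and adduct torsions of one residue and keeps the global grid minimum;
the starting pose is a grid member, so strain never increases.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from ._chemdata import vdw_radius
from .geometry_core import rotation_about_axis
from .structure_io import Atom, Residue, Structure

__all__ = [
    "ClashRecord",
    "StrainScore",
    "TorsionScan",
    "OptimizationResult",
    "vdw_strain",
    "enumerate_clashes",
    "optimize_residue",
    "sidechain_moving_atoms",
    "BASELINE_EPSILON",
]

BASELINE_EPSILON = 0.01  # square Angstrom; see optimize_residue
_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}
_BOND_EXCLUSION_DEPTH = 3  # exclude pairs separated by <= 3 bonds

_STEP_FOR_LEVEL = {1: 30.0, 2: 30.0, 3: 20.0, 4: 10.0}
_NTORS_FOR_LEVEL = {1: 1, 2: 2, 3: 4, 4: 4}


@dataclass(frozen=True)
class ClashRecord:
    atom_i: Atom
    atom_j: Atom
    distance: float
    overlap: float

    @property
    def severity(self) -> float:
        return self.overlap * self.overlap


@dataclass(frozen=True)
class StrainScore:
    value: float  # sum of severities, A^2
    n_clashes: int
    neighborhood_radius: float


@dataclass(frozen=True)
class TorsionScan:
    axis: tuple[str, str]  # (tail, head) atom names
    step: float  # degrees
    chosen_offset: float  # degrees relative to the starting pose


@dataclass
class OptimizationResult:
    level: int
    torsions: list[TorsionScan]
    strain_before: StrainScore
    strain_after: StrainScore
    baseline_probed: bool = False
    trajectory: Optional[list[tuple[tuple[float, ...], float]]] = None


def sidechain_moving_atoms(residue: Residue) -> list[Atom]:
    """Heavy side-chain (and adduct) atoms of a residue."""
    return [a for a in residue.heavy_atoms() if a.name not in _BACKBONE_NAMES]


# ---------------------------------------------------------------------------
# pair bookkeeping
# ---------------------------------------------------------------------------

def _bonded_within(adj: dict, source, max_depth: int) -> set:
    """Keys within ``max_depth`` bonds of ``source`` (excluding source)."""
    seen = {source: 0}
    queue = deque([source])
    while queue:
        node = queue.popleft()
        d = seen[node]
        if d == max_depth:
            continue
        for nb in adj.get(node, ()):
            if nb not in seen:
                seen[nb] = d + 1
                queue.append(nb)
    del seen[source]
    return set(seen)


def _collect_pairs(structure: Structure, moving: Sequence[Atom], neighborhood: float):
    """Environment atoms, exclusion sets and intra-moving pair list."""
    moving_set = set(moving)
    moving_keys = {a.key for a in moving}
    env = [
        a
        for a in structure.atoms()
        if a not in moving_set and not a.is_hydrogen
    ]
    if env and moving:
        mcoords = np.array([a.coords for a in moving])
        ecoords = np.array([a.coords for a in env])
        tree = cKDTree(ecoords)
        keep = sorted(set(j for js in tree.query_ball_point(mcoords, neighborhood) for j in js))
        env = [env[j] for j in keep]

    adj = structure.adjacency()
    excluded = {a.key: _bonded_within(adj, a.key, _BOND_EXCLUSION_DEPTH) for a in moving}

    intra_pairs = []
    mlist = list(moving)
    for i in range(len(mlist)):
        for j in range(i + 1, len(mlist)):
            if mlist[j].key not in excluded[mlist[i].key]:
                intra_pairs.append((i, j))
    return env, excluded, intra_pairs, moving_keys


def vdw_strain(
    structure: Structure,
    moving: Iterable[Atom],
    neighborhood: float = 8.0,
) -> tuple[StrainScore, list[ClashRecord]]:
    """Strain of ``moving`` atoms against their local environment.

    Pairs scored: every (moving, non-moving heavy atom within
    ``neighborhood`` of any moving atom) plus intra-moving pairs at least
    four bonds apart.  Clash records (overlap > 0) are returned sorted by
    severity, largest first.
    """
    moving = [a for a in moving if not a.is_hydrogen]
    if not moving:
        raise ValueError("moving set is empty")
    env, excluded, intra_pairs, _ = _collect_pairs(structure, moving, neighborhood)

    records: list[ClashRecord] = []
    total = 0.0
    for m in moving:
        r_m = vdw_radius(m.element)
        excl = excluded[m.key]
        for e in env:
            if e.key in excl:
                continue
            d = float(np.linalg.norm(m.coords - e.coords))
            overlap = r_m + vdw_radius(e.element) - d
            if overlap > 0:
                total += overlap * overlap
                records.append(ClashRecord(m, e, d, overlap))
    for i, j in intra_pairs:
        a, b = moving[i], moving[j]
        d = float(np.linalg.norm(a.coords - b.coords))
        overlap = vdw_radius(a.element) + vdw_radius(b.element) - d
        if overlap > 0:
            total += overlap * overlap
            records.append(ClashRecord(a, b, d, overlap))

    records.sort(key=lambda r: -r.severity)
    score = StrainScore(value=total, n_clashes=len(records), neighborhood_radius=neighborhood)
    return score, records


def enumerate_clashes(structure: Structure, selection: Iterable[Atom]) -> list[ClashRecord]:
    """All clash records with at least one partner in the selection.

    Exactly ``vdw_strain``'s pair set restricted to the selection, sorted
    by severity descending.
    """
    selection = list(selection)
    if not selection:
        raise ValueError("selection is empty")
    _, records = vdw_strain(structure, selection)
    return records


# ---------------------------------------------------------------------------
# torsion discovery
# ---------------------------------------------------------------------------

def _residue_heavy_adjacency(structure: Structure, residue: Residue) -> dict:
    keys = {a.key for a in residue.heavy_atoms()}
    adj: dict = {k: set() for k in keys}
    for bond in structure.bonds:
        a, b = tuple(bond)
        if a in keys and b in keys:
            adj[a].add(b)
            adj[b].add(a)
    return adj


def _component(adj: dict, start, banned_edge: frozenset) -> set:
    seen = {start}
    queue = deque([start])
    while queue:
        node = queue.popleft()
        for nb in adj.get(node, ()):
            if frozenset((node, nb)) == banned_edge or nb in seen:
                continue
            seen.add(nb)
            queue.append(nb)
    return seen


def discover_torsions(
    structure: Structure, residue: Residue, root: str = "CA"
) -> list[tuple[str, str, set]]:
    """Rotatable torsion axes of a residue, ordered proximal to distal.

    An intra-residue bond (u, v), walked outward from ``root``, is a
    torsion axis when it is not part of a ring and at least two heavy
    atoms lie beyond it (rotating fewer cannot change heavy-atom strain).
    Returns (tail name, head name, distal atom-key set) triples.
    """
    adj = _residue_heavy_adjacency(structure, residue)
    root_atom = residue.atom(root)
    if root_atom is None:
        return []
    root_key = root_atom.key

    depth = {root_key: 0}
    order = []
    queue = deque([root_key])
    while queue:
        node = queue.popleft()
        for nb in sorted(adj.get(node, ())):
            if nb not in depth:
                depth[nb] = depth[node] + 1
                order.append((node, nb))
                queue.append(nb)

    torsions = []
    for u, v in order:
        edge = frozenset((u, v))
        distal = _component(adj, v, edge)
        if u in distal:  # ring bond: removing it does not separate v from u
            continue
        distal_moving = distal - {v}
        if len(distal_moving) < 2:
            continue
        torsions.append((u[3], v[3], distal_moving))
    torsions.sort(key=lambda t: (depth[residue.atom(t[0]).key], t[0], t[1]))
    return torsions


# ---------------------------------------------------------------------------
# grid optimization
# ---------------------------------------------------------------------------

def _angular_displacement(offsets: Sequence[float]) -> float:
    return sum(min(abs(o), 360.0 - abs(o)) for o in offsets)


class _GridScanner:
    """Exhaustive nested torsion grid scan with a vectorized inner loop."""

    def __init__(self, structure, residue, moving, torsions, step, neighborhood):
        self.atoms = residue.heavy_atoms()
        self.index = {a.key: i for i, a in enumerate(self.atoms)}
        self.coords0 = np.array([a.coords for a in self.atoms])
        self.moving_idx = np.array([self.index[a.key] for a in moving], dtype=int)

        env, excluded, intra_pairs, _ = _collect_pairs(
            structure, moving, self._env_radius(moving, neighborhood)
        )
        self.env_coords = (
            np.array([a.coords for a in env]) if env else np.zeros((0, 3))
        )
        env_radii = np.array([vdw_radius(a.element) for a in env])
        mov_radii = np.array([vdw_radius(a.element) for a in moving])
        self.radsum = mov_radii[:, None] + env_radii[None, :]
        self.pair_mask = np.ones_like(self.radsum, dtype=bool)
        for i, m in enumerate(moving):
            excl = excluded[m.key]
            for j, e in enumerate(env):
                if e.key in excl:
                    self.pair_mask[i, j] = False
        self.intra_i = np.array([self.moving_idx[i] for i, _ in intra_pairs], dtype=int)
        self.intra_j = np.array([self.moving_idx[j] for _, j in intra_pairs], dtype=int)
        mr = {int(self.moving_idx[k]): mov_radii[k] for k in range(len(moving))}
        self.intra_radsum = np.array(
            [mr[int(i)] + mr[int(j)] for i, j in zip(self.intra_i, self.intra_j)]
        )

        self.torsions = torsions  # (tail_name, head_name, distal_keys)
        self.tors_idx = [
            (
                self.index[residue.atom(t[0]).key],
                self.index[residue.atom(t[1]).key],
                np.array(sorted(self.index[k] for k in t[2] if k in self.index), dtype=int),
            )
            for t in torsions
        ]
        self.grid = np.arange(0.0, 360.0, step)
        self.step = step
        self.best_value = np.inf
        self.best_disp = np.inf
        self.best_offsets: tuple[float, ...] = ()
        self.best_coords = self.coords0.copy()
        self.trajectory: list[tuple[tuple[float, ...], float]] = []

    @staticmethod
    def _env_radius(moving, neighborhood):
        coords = np.array([a.coords for a in moving])
        extent = float(
            np.linalg.norm(coords - coords.mean(axis=0), axis=1).max()
        )
        # moving atoms can swing by up to ~2*extent; overlaps need d < 3.7 A,
        # so this superset yields identical strain values to the 'within
        # neighborhood of any moving atom' rule evaluated per pose
        return neighborhood + 2.0 * extent

    def _strain_batch(self, batch: np.ndarray) -> np.ndarray:
        mov = batch[:, self.moving_idx, :]
        if self.env_coords.shape[0]:
            d = np.linalg.norm(mov[:, :, None, :] - self.env_coords[None, None], axis=3)
            overlap = np.clip(self.radsum[None] - d, 0.0, None)
            overlap[:, ~self.pair_mask] = 0.0
            total = (overlap * overlap).sum(axis=(1, 2))
        else:
            total = np.zeros(batch.shape[0])
        if len(self.intra_i):
            d = np.linalg.norm(batch[:, self.intra_i, :] - batch[:, self.intra_j, :], axis=2)
            overlap = np.clip(self.intra_radsum[None] - d, 0.0, None)
            total = total + (overlap * overlap).sum(axis=1)
        return total

    def scan(self, record_trajectory: bool = False) -> None:
        self._record = record_trajectory
        self._scan_level(0, self.coords0.copy(), ())

    def _scan_level(self, ti: int, coords: np.ndarray, offsets: tuple) -> None:
        if ti == len(self.tors_idx) - 1:
            # vectorize the innermost torsion
            tail_i, head_i, distal = self.tors_idx[ti]
            batch = np.repeat(coords[None], len(self.grid), axis=0)
            for k, off in enumerate(self.grid):
                if off == 0.0:
                    continue
                R, t = rotation_about_axis(coords[tail_i], coords[head_i], off)
                batch[k, distal] = coords[distal] @ R.T + t
            values = self._strain_batch(batch)
            for k, off in enumerate(self.grid):
                full = offsets + (float(off),)
                value = float(values[k])
                if self._record:
                    self.trajectory.append((full, value))
                disp = _angular_displacement(full)
                if value < self.best_value - 1e-12 or (
                    abs(value - self.best_value) <= 1e-12 and disp < self.best_disp
                ):
                    self.best_value = value
                    self.best_disp = disp
                    self.best_offsets = full
                    self.best_coords = batch[k].copy()
            return
        tail_i, head_i, distal = self.tors_idx[ti]
        for off in self.grid:
            if off == 0.0:
                work = coords
            else:
                R, t = rotation_about_axis(coords[tail_i], coords[head_i], off)
                work = coords.copy()
                work[distal] = coords[distal] @ R.T + t
            self._scan_level(ti + 1, work, offsets + (float(off),))


def optimize_residue(
    structure: Structure,
    residue: Residue,
    defn=None,
    level: int = 3,
    probe_baseline: bool = False,
    baseline_strain: Optional[float] = None,
    moving_atoms: Optional[Sequence[Atom]] = None,
    root: str = "CA",
    neighborhood: float = 8.0,
    store_trajectory: bool = False,
) -> OptimizationResult:
    """Minimize a residue's local vdW strain by exhaustive torsion scanning.

    ``level`` selects the torsion set and grid: 1 = distal-most torsion,
    30 deg steps; 2 = two distal torsions, 30 deg; 3 = up to four
    side-chain/adduct torsions, 20 deg; 4 = the same set at 10 deg.  When
    ``probe_baseline`` is set and the current strain does not exceed
    ``baseline_strain`` (the residue's pre-modification strain) by more
    than 0.01 A^2, the scan is skipped.  The starting pose is part of the
    grid, so ``strain_after <= strain_before`` always; ties are broken by
    the smallest total angular displacement.
    """
    if level not in _STEP_FOR_LEVEL:
        raise ValueError(f"optimization level must be 1-4, got {level}")
    moving = list(moving_atoms) if moving_atoms is not None else sidechain_moving_atoms(residue)
    moving = [a for a in moving if not a.is_hydrogen]

    if not moving:
        zero = StrainScore(0.0, 0, neighborhood)
        return OptimizationResult(level, [], zero, zero)

    strain_before, _ = vdw_strain(structure, moving, neighborhood)

    if probe_baseline and strain_before.value <= (baseline_strain or 0.0) + BASELINE_EPSILON:
        return OptimizationResult(level, [], strain_before, strain_before, baseline_probed=True)

    torsions = discover_torsions(structure, residue, root=root)
    moving_keys = {a.key for a in moving}
    torsions = [
        (u, v, distal & moving_keys)
        for u, v, distal in torsions
        if len(distal & moving_keys) >= 2
    ]
    n = _NTORS_FOR_LEVEL[level]
    torsions = torsions[-n:] if n < len(torsions) else torsions
    if not torsions:
        return OptimizationResult(level, [], strain_before, strain_before)

    step = _STEP_FOR_LEVEL[level]
    scanner = _GridScanner(structure, residue, moving, torsions, step, neighborhood)
    scanner.scan(record_trajectory=store_trajectory)

    for atom in residue.heavy_atoms():
        atom.coords = scanner.best_coords[scanner.index[atom.key]].copy()

    strain_after, _ = vdw_strain(structure, moving, neighborhood)
    scans = [
        TorsionScan(axis=(u, v), step=step, chosen_offset=off)
        for (u, v, _), off in zip(torsions, scanner.best_offsets)
    ]
    return OptimizationResult(
        level=level,
        torsions=scans,
        strain_before=strain_before,
        strain_after=strain_after,
        baseline_probed=False,
        trajectory=scanner.trajectory if store_trajectory else None,
    )
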