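import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ptmgraft import (
    ModificationOptions,
    PeptideSpec,
    build_peptide,
    enumerate_clashes,
    modify,
    optimize_residue,
    vdw_strain,
)
from ptmgraft._chemdata import vdw_radius
from ptmgraft.strain_optimizer import sidechain_moving_atoms
from ptmgraft.structure_io import Atom, Residue, Structure


def _pair(d):
    s = Structure()
    for i, x in enumerate([0.0, d], start=1):
        res = Residue("A", i, "ALA")
        res.add_atom(Atom(i, "CB", "C", [x, 0.0, 0.0]))
        s.add_residue(res)
    return s


def test_touching_spheres_score_zero():
    s = _pair(3.40)
    score, records = vdw_strain(s, [s.residues[0].atoms[0]])
    assert score.value == 0.0 and records == []


def test_forced_overlap_score():
    s = _pair(3.00)
    score, records = vdw_strain(s, [s.residues[0].atoms[0]])
    assert score.value == pytest.approx(0.16, abs=1e-12)
    assert len(records) == 1
    assert records[0].overlap == pytest.approx(0.40, abs=1e-12)


def test_zero_iff_no_clashes(pentapeptide):
    moving = sidechain_moving_atoms(pentapeptide.residues[2])
    score, records = vdw_strain(pentapeptide, moving)
    assert (score.value == 0.0) == (score.n_clashes == 0) == (len(records) == 0)


# ---------------------------------------------------------------------------
# independent all-pairs oracle
# ---------------------------------------------------------------------------

def _graph_distance(structure):
    g = nx.Graph()
    for bond in structure.bonds:
        a, b = tuple(bond)
        g.add_edge(a, b)
    return g


def oracle_strain(structure, moving, neighborhood=8.0):
    """Brute-force reimplementation: all pairs, networkx bond distances."""
    g = _graph_distance(structure)
    moving = [a for a in moving if not a.is_hydrogen]
    mkeys = {a.key for a in moving}
    env = [a for a in structure.atoms() if a.key not in mkeys and not a.is_hydrogen]
    env = [
        e
        for e in env
        if min(np.linalg.norm(e.coords - m.coords) for m in moving) <= neighborhood
    ]

    def bond_dist(a, b):
        if a.key not in g or b.key not in g:
            return 99
        try:
            return nx.shortest_path_length(g, a.key, b.key)
        except nx.NetworkXNoPath:
            return 99

    total = 0.0
    for m in moving:
        for e in env:
            if bond_dist(m, e) <= 3:
                continue
            overlap = vdw_radius(m.element) + vdw_radius(e.element) - np.linalg.norm(
                m.coords - e.coords
            )
            total += max(0.0, overlap) ** 2
    for a, b in itertools.combinations(moving, 2):
        if bond_dist(a, b) <= 3:
            continue
        overlap = vdw_radius(a.element) + vdw_radius(b.element) - np.linalg.norm(
            a.coords - b.coords
        )
        total += max(0.0, overlap) ** 2
    return total


def test_cluster_strain_matches_all_pairs_oracle():
    rng = np.random.default_rng(3)
    s = Structure()
    elements = ["C", "N", "O", "S", "C", "O"]
    for i, el in enumerate(elements, start=1):
        res = Residue("A", i, "UNK")
        res.add_atom(Atom(i, f"X{i}", el, rng.uniform(-2.5, 2.5, size=3)))
        s.add_residue(res)
    s.infer_bonds()
    moving = [s.residues[0].atoms[0], s.residues[1].atoms[0]]
    score, _ = vdw_strain(s, moving)
    assert score.value == pytest.approx(oracle_strain(s, moving), abs=1e-9)


def _walled_maa_lysine():
    """MAA-modified lysine with a deliberate carbon wall near the ring."""
    s = build_peptide(PeptideSpec("AKA"))
    modify(s, ModificationOptions(ptm_class="mda_adduct"))
    lys = s.residues[1]
    ring_centroid = np.mean(
        [lys.atom(n).coords for n in ("C2M", "C3M", "C4M", "C5M", "C6M")], axis=0
    )
    wall = Residue("W", 1, "UNK")
    wall.add_atom(Atom(900, "X1", "C", ring_centroid + np.array([0.0, 0.0, 2.2])))
    s.add_residue(wall)
    s.infer_bonds()
    return s, lys


def test_walled_fixture_strain_agrees_with_oracle():
    s, lys = _walled_maa_lysine()
    moving = sidechain_moving_atoms(lys)
    score, records = vdw_strain(s, moving)
    assert score.value > 0
    assert score.value == pytest.approx(oracle_strain(s, moving), abs=1e-9)
    assert score.value == pytest.approx(sum(r.severity for r in records), abs=1e-12)


# ---------------------------------------------------------------------------
# optimizer vs exhaustive grid oracle
# ---------------------------------------------------------------------------

def _oracle_grid_min(structure, residue, moving, torsion_scans):
    """Independent exhaustive scan: scipy rotations + all-pairs strain."""
    atoms = residue.heavy_atoms()
    coords0 = {a.key: a.coords.copy() for a in atoms}
    adj = {}
    for bond in structure.bonds:
        a, b = tuple(bond)
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    def distal_of(tail, head):
        seen, queue = {head, tail}, [head]
        while queue:
            node = queue.pop()
            for nb in adj.get(node, ()):
                if nb not in seen and nb in coords0:
                    seen.add(nb)
                    queue.append(nb)
        return seen - {head, tail}

    grids = [np.arange(0.0, 360.0, t.step) for t in torsion_scans]
    best = None
    for combo in itertools.product(*grids):
        coords = {k: v.copy() for k, v in coords0.items()}
        for t, off in zip(torsion_scans, combo):
            tail = coords[residue.atom(t.axis[0]).key]
            head = coords[residue.atom(t.axis[1]).key]
            axis = head - tail
            rot = Rotation.from_rotvec(np.deg2rad(off) * axis / np.linalg.norm(axis))
            for key in distal_of(residue.atom(t.axis[0]).key, residue.atom(t.axis[1]).key):
                coords[key] = rot.apply(coords[key] - tail) + tail
        for a in atoms:
            a.coords = coords[a.key]
        value = oracle_strain(structure, moving)
        disp = sum(min(abs(o), 360 - abs(o)) for o in combo)
        if best is None or value < best[0] - 1e-12 or (
            abs(value - best[0]) <= 1e-12 and disp < best[1]
        ):
            best = (value, disp, combo)
    for a in atoms:
        a.coords = coords0[a.key]
    return best


@pytest.mark.parametrize("level", [1, 2])
def test_optimizer_equals_brute_force_grid(level):
    s, lys = _walled_maa_lysine()
    ref = s.copy()
    ref_lys = ref.residues[1]
    result = optimize_residue(s, lys, level=level)
    assert result.torsions, "expected at least one scanned torsion"
    assert len(result.torsions) <= 2
    moving = sidechain_moving_atoms(ref_lys)
    value, _, combo = _oracle_grid_min(ref, ref_lys, moving, result.torsions)
    assert result.strain_after.value == pytest.approx(value, abs=1e-9)
    assert tuple(t.chosen_offset for t in result.torsions) == combo
    assert result.strain_after.value < result.strain_before.value


def test_strain_never_increases_across_levels():
    for level in (1, 2, 3):
        s, lys = _walled_maa_lysine()
        result = optimize_residue(s, lys, level=level)
        assert result.strain_after.value <= result.strain_before.value + 1e-12


def test_level_zero_rejected():
    s, lys = _walled_maa_lysine()
    with pytest.raises(ValueError):
        optimize_residue(s, lys, level=0)
    with pytest.raises(ValueError):
        ModificationOptions(ptm_class="mda_adduct", optimization_level=5)


def test_locality_non_moving_atoms_untouched():
    s, lys = _walled_maa_lysine()
    moving_keys = {a.key for a in sidechain_moving_atoms(lys)}
    before = {a.key: a.coords.copy() for a in s.atoms() if a.key not in moving_keys}
    optimize_residue(s, lys, level=2)
    for a in s.atoms():
        if a.key in before:
            assert np.array_equal(a.coords, before[a.key])


def test_probe_baseline_skips_strain_free_residue():
    s = build_peptide(PeptideSpec("AKA"))
    lys = s.residues[1]
    result = optimize_residue(s, lys, level=3, probe_baseline=True, baseline_strain=0.0)
    assert result.baseline_probed
    assert result.torsions == []
    assert result.strain_after.value == result.strain_before.value == 0.0
    # shortcut soundness: a forced scan cannot improve on zero strain
    forced = optimize_residue(s, lys, level=3)
    assert forced.strain_after.value >= result.strain_after.value - 0.01


def test_probe_baseline_does_not_skip_strained_residue():
    s, lys = _walled_maa_lysine()
    result = optimize_residue(s, lys, level=1, probe_baseline=True, baseline_strain=0.0)
    assert not result.baseline_probed or result.strain_before.value <= 0.01
    assert result.strain_after.value < result.strain_before.value


# ---------------------------------------------------------------------------
# enumerate_clashes
# ---------------------------------------------------------------------------

def test_native_fixture_clash_free(pentapeptide):
    records = enumerate_clashes(pentapeptide, set(pentapeptide.atoms()))
    assert records == []


def test_occluded_nitration_max_severity_involves_nitro_oxygen():
    s = build_peptide(PeptideSpec("AYA"))
    native_records = enumerate_clashes(s, set(s.atoms()))
    assert native_records == []
    probe = s.copy()
    modify(probe, ModificationOptions(ptm_class="nitration", position_override=1))
    o1n = probe.residues[1].atom("O1N").coords
    ce1 = probe.residues[1].atom("CE1").coords
    u = (o1n - ce1) / np.linalg.norm(o1n - ce1)
    wall = Residue("W", 1, "UNK")
    wall.add_atom(Atom(900, "X1", "C", o1n + 1.6 * u))
    s.add_residue(wall)
    s.infer_bonds()
    assert enumerate_clashes(s, set(s.residues[1].atoms)) == []
    modify(s, ModificationOptions(ptm_class="nitration", position_override=1))
    records = enumerate_clashes(s, set(s.residues[1].atoms))
    assert records
    top = records[0]
    names = {top.atom_i.name, top.atom_j.name}
    assert names & {"O1N", "O2N", "NN"}
    assert sorted((r.severity for r in records), reverse=True) == [
        r.severity for r in records
    ]


def test_clashes_consistent_with_vdw_strain():
    s, lys = _walled_maa_lysine()
    selection = set(lys.atoms)
    records = enumerate_clashes(s, selection)
    _, via_strain = vdw_strain(s, [a for a in selection if not a.is_hydrogen])
    assert {(r.atom_i.key, r.atom_j.key) for r in records} == {
        (r.atom_i.key, r.atom_j.key) for r in via_strain
    }
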