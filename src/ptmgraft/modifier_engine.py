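"""Candidate discovery, sequential grafting, renaming and reporting.

The pipeline for every modification class is the same: break the input
selection into candidate residues for the class, drop residues that are
already modified or fail the surface-exposure cutoff, then graft each
remaining residue in stable (chain, residue number) order, renaming it to
its product component code and optionally minimizing the local strain.

Solvent accessibility is computed once, on the pre-modification
structure, so results are independent of the order in which adducts
accumulate.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from . import ptm_catalog
from .geometry_core import place_atom
from .ptm_catalog import PTMDefinition, ResolvedRecipe, get_definition
from .strain_optimizer import (
    OptimizationResult,
    StrainScore,
    optimize_residue,
    sidechain_moving_atoms,
    vdw_strain,
)
from .structure_io import Atom, Residue, Structure, select
from .surface_selection import SasaResult, compute_sasa, surface_filter

__all__ = [
    "ModificationOptions",
    "ReportEntry",
    "ModificationReport",
    "Candidate",
    "find_candidates",
    "apply_ptm",
    "modify",
    "OUTCOMES",
]

logger = logging.getLogger(__name__)

OUTCOMES = (
    "modified",
    "skipped_buried",
    "skipped_already_modified",
    "skipped_missing_atoms",
    "skipped_not_n_terminal",
)

_DISULFIDE_CUTOFF = 2.3  # A, SG-SG


@dataclass
class ModificationOptions:
    ptm_class: str
    variant: Optional[str] = None
    selection: str = "all"
    surface_cutoff: Optional[float] = None
    include_n_termini: bool = False
    position_override: Optional[int] = None
    optimization_level: int = 0
    probe_baseline: bool = False
    sasa_probe: float = 1.4
    sasa_points: int = 960

    def __post_init__(self) -> None:
        if not 0 <= self.optimization_level <= 4:
            raise ValueError("optimization_level must be in [0, 4]")
        if self.surface_cutoff is not None and self.surface_cutoff < 0:
            raise ValueError("surface_cutoff must be >= 0 or None")


@dataclass(frozen=True)
class Candidate:
    residue: Residue
    site: str  # "sidechain" | "nterm"


@dataclass
class ReportEntry:
    chain_id: str
    resi: int
    icode: str
    original_resn: str
    site: str
    outcome: str = ""
    product_resn: Optional[str] = None
    variant: Optional[str] = None
    position: Optional[int] = None
    atoms_added: list[str] = field(default_factory=list)
    atoms_removed: list[str] = field(default_factory=list)
    charge_delta: int = 0
    strain_before: Optional[float] = None
    strain_after: Optional[float] = None
    chosen_torsions: list[float] = field(default_factory=list)
    detail: str = ""


@dataclass
class ModificationReport:
    ptm_class: str
    variant: str
    entries: list[ReportEntry] = field(default_factory=list)

    @property
    def n_candidates(self) -> int:
        return len(self.entries)

    @property
    def n_modified(self) -> int:
        return sum(1 for e in self.entries if e.outcome == "modified")

    def count(self, outcome: str) -> int:
        return sum(1 for e in self.entries if e.outcome == outcome)

    @property
    def total_charge_delta(self) -> int:
        return sum(e.charge_delta for e in self.entries if e.outcome == "modified")

    def totals(self) -> dict:
        out = {"candidates": self.n_candidates, "modified": self.n_modified}
        for outcome in OUTCOMES[1:]:
            out[outcome] = self.count(outcome)
        out["total_charge_delta"] = self.total_charge_delta
        return out

    def to_dict(self) -> dict:
        return {
            "format": "ptmgraft-report/1",
            "ptm_class": self.ptm_class,
            "variant": self.variant,
            "totals": self.totals(),
            "entries": [asdict(e) for e in self.entries],
        }


# ---------------------------------------------------------------------------
# candidate discovery
# ---------------------------------------------------------------------------

def _selected_residues(structure: Structure, expr: str) -> set[Residue]:
    atoms = select(structure, expr)
    return {a.residue for a in atoms}


def _is_sidechain_modified(residue: Residue) -> bool:
    if residue.resn in ptm_catalog.product_resnames():
        return True
    if residue.ptm_tag:
        return any("@nterm" not in part for part in residue.ptm_tag.split("+"))
    return False


def _has_nterm_cap(residue: Residue) -> bool:
    return bool(residue.ptm_tag) and any(
        "@nterm" in part for part in residue.ptm_tag.split("+")
    )


def _is_disulfide_cys(structure: Structure, residue: Residue) -> bool:
    sg = residue.atom("SG")
    if sg is None:
        return False
    for other in structure.residues:
        if other is residue or other.resn != "CYS":
            continue
        osg = other.atom("SG")
        if osg is not None and np.linalg.norm(sg.coords - osg.coords) < _DISULFIDE_CUTOFF:
            return True
    return False


def _sasa_gate_atoms(residue: Residue, defn: PTMDefinition, site: str) -> list[Atom]:
    """Atoms whose accessibility decides the surface filter for a residue."""
    if site == "nterm":
        atom = residue.atom("N")
        return [atom] if atom is not None else []
    variants = [defn] if not defn.choice_of else [
        get_definition(defn.ptm_class, v) for v in defn.choice_of
    ]
    names: set[str] = set()
    for var in variants:
        for recipe in var._recipes:
            if recipe.target_resn == residue.resn:
                names.add(recipe.target_atom)
    return [residue.atom(n) for n in sorted(names) if residue.atom(n) is not None]


def _discover(
    structure: Structure,
    opts: ModificationOptions,
    sasa: Optional[SasaResult],
) -> tuple[list[Candidate], list[ReportEntry]]:
    """Candidates in stable order plus skip entries for filtered residues."""
    defn = get_definition(opts.ptm_class, opts.variant)
    if opts.surface_cutoff is not None and sasa is None:
        raise ValueError("surface_cutoff set but no SASA result provided")
    in_selection = _selected_residues(structure, opts.selection)

    candidates: list[Candidate] = []
    skipped: list[ReportEntry] = []
    ordered = sorted(structure.residues, key=lambda r: (r.chain_id, r.resi, r.icode))
    for res in ordered:
        if res not in in_selection or res.is_water:
            continue
        if res.resn in defn.target_resn and not _is_sidechain_modified(res):
            if opts.ptm_class == "cysteine_oxidation" and _is_disulfide_cys(structure, res):
                continue
            if opts.surface_cutoff is not None:
                gate = _sasa_gate_atoms(res, defn, "sidechain")
                if gate and not surface_filter(sasa, gate, opts.surface_cutoff):
                    skipped.append(
                        ReportEntry(
                            chain_id=res.chain_id,
                            resi=res.resi,
                            icode=res.icode,
                            original_resn=res.resn,
                            site="sidechain",
                            outcome="skipped_buried",
                            detail=f"target atom area below {opts.surface_cutoff} A^2",
                        )
                    )
                    continue
            candidates.append(Candidate(res, "sidechain"))
        if (
            opts.include_n_termini
            and defn.n_term_capable
            and res.is_n_terminal
            and res.resn != "PRO"
            and not _has_nterm_cap(res)
        ):
            if opts.surface_cutoff is not None:
                gate = _sasa_gate_atoms(res, defn, "nterm")
                if gate and not surface_filter(sasa, gate, opts.surface_cutoff):
                    skipped.append(
                        ReportEntry(
                            chain_id=res.chain_id,
                            resi=res.resi,
                            icode=res.icode,
                            original_resn=res.resn,
                            site="nterm",
                            outcome="skipped_buried",
                            detail=f"backbone N area below {opts.surface_cutoff} A^2",
                        )
                    )
                    continue
            candidates.append(Candidate(res, "nterm"))
    return candidates, skipped


def find_candidates(
    structure: Structure,
    opts: ModificationOptions,
    sasa: Optional[SasaResult] = None,
) -> list[Candidate]:
    """Candidate residues for a modification, in stable (chain, resi) order.

    Residues already bearing a product component code or a side-chain
    modification tag are excluded, as are residues whose target atom
    fails the surface cutoff and disulfide-bonded cysteines.
    """
    candidates, _ = _discover(structure, opts, sasa)
    return candidates


# ---------------------------------------------------------------------------
# grafting
# ---------------------------------------------------------------------------

class _ResidueSnapshot:
    """Rollback state for trial applications (racemic/position choices)."""

    def __init__(self, structure: Structure, residue: Residue):
        self.structure = structure
        self.residue = residue
        memo = {id(residue): residue}
        self.atoms = copy.deepcopy(residue.atoms, memo)
        self.resn = residue.resn
        self.ptm_tag = residue.ptm_tag
        self.bonds = set(structure.bonds)

    def restore(self) -> None:
        self.residue.atoms = copy.deepcopy(self.atoms, {id(self.residue): self.residue})
        self.residue.resn = self.resn
        self.residue.ptm_tag = self.ptm_tag
        self.structure.bonds = set(self.bonds)


def _missing_refs(residue: Residue, recipe: ResolvedRecipe) -> list[str]:
    needed: set[str] = {recipe.target_atom}
    present = {a.name for a in residue.atoms}
    for spec in recipe.atoms_added:
        for ref in (spec.ic.ref_a, spec.ic.ref_b, spec.ic.ref_c):
            if ref not in present and ref not in {s.name for s in recipe.atoms_added}:
                needed.add(ref)
    needed.update(recipe.atoms_removed)
    needed.update(s.name for s in recipe.element_swaps)
    return sorted(n for n in needed if n not in present)


def _strip_hydrogens_bonded_to(structure: Structure, residue: Residue, name: str) -> None:
    heavy = residue.atom(name)
    if heavy is None:
        return
    doomed = [
        h
        for h in list(residue.atoms)
        if h.is_hydrogen and np.linalg.norm(h.coords - heavy.coords) < 1.3
    ]
    for h in doomed:
        structure.remove_atom(h)


def _graft(structure: Structure, residue: Residue, recipe: ResolvedRecipe) -> tuple[list[str], list[str]]:
    """Mutate the residue per the recipe; returns (added, removed) names."""
    removed: list[str] = []
    for name in recipe.atoms_removed:
        atom = residue.atom(name)
        if atom is not None:
            _strip_hydrogens_bonded_to(structure, residue, name)
            structure.remove_atom(atom)
            removed.append(name)

    for swap in recipe.element_swaps:
        atom = residue.atom(swap.name)
        _strip_hydrogens_bonded_to(structure, residue, swap.name)
        old_key = atom.key
        partners = structure.bonded_keys(old_key)
        if swap.new_length is not None and partners:
            anchor = structure.atom_by_key(next(iter(sorted(partners))))
            if anchor is not None:
                direction = atom.coords - anchor.coords
                norm = np.linalg.norm(direction)
                if norm > 1e-9:
                    atom.coords = anchor.coords + direction / norm * swap.new_length
        atom.name = swap.new_name
        atom.element = swap.new_element
        structure.bonds = {b for b in structure.bonds if old_key not in b}
        for p in partners:
            structure.add_bond(atom.key, p)

    _strip_hydrogens_bonded_to(structure, residue, recipe.target_atom)

    added: list[str] = []
    serial = max((a.serial for a in structure.atoms()), default=0)
    for spec in recipe.atoms_added:
        refs = [residue.atom(n) for n in (spec.ic.ref_a, spec.ic.ref_b, spec.ic.ref_c)]
        if any(r is None for r in refs):
            raise ValueError(f"missing reference atom for {spec.name}")
        coords = place_atom(refs[0].coords, refs[1].coords, refs[2].coords, spec.ic)
        serial += 1
        atom = Atom(serial=serial, name=spec.name, element=spec.element, coords=coords)
        residue.add_atom(atom)
        for partner in spec.bond_to:
            partner_atom = residue.atom(partner)
            if partner_atom is not None:
                structure.add_bond(atom.key, partner_atom.key)
        added.append(spec.name)
    for a, b in recipe.extra_bonds:
        aa, bb = residue.atom(a), residue.atom(b)
        if aa is not None and bb is not None:
            structure.add_bond(aa.key, bb.key)
    return added, removed


def _tag(residue: Residue, defn: PTMDefinition, site: str) -> None:
    part = f"{defn.ptm_class}:{defn.variant}"
    if site == "nterm":
        part += "@nterm"
    residue.ptm_tag = f"{residue.ptm_tag}+{part}" if residue.ptm_tag else part


def _apply_option(
    structure: Structure,
    residue: Residue,
    defn: PTMDefinition,
    recipe: ResolvedRecipe,
    opts: ModificationOptions,
    site: str,
    baseline: Optional[float],
) -> tuple[float, ReportEntry, Optional[OptimizationResult]]:
    """Graft + optional optimization; returns (final strain, entry, opt)."""
    added, removed = _graft(structure, residue, recipe)
    if site == "sidechain" and recipe.product_resn:
        residue.resn = recipe.product_resn
    _tag(residue, defn, site)

    if site == "nterm":
        moving = [residue.atom(n) for n in added if residue.atom(n) is not None]
        root = "N"
    else:
        moving = sidechain_moving_atoms(residue)
        root = "CA"

    opt: Optional[OptimizationResult] = None
    if opts.optimization_level > 0 and moving:
        opt = optimize_residue(
            structure,
            residue,
            defn,
            level=opts.optimization_level,
            probe_baseline=opts.probe_baseline,
            baseline_strain=baseline,
            moving_atoms=moving,
            root=root,
        )
        strain_before = opt.strain_before.value
        strain_after = opt.strain_after.value
    elif moving:
        score, _ = vdw_strain(structure, moving)
        strain_before = strain_after = score.value
    else:
        strain_before = strain_after = 0.0

    entry = ReportEntry(
        chain_id=residue.chain_id,
        resi=residue.resi,
        icode=residue.icode,
        original_resn=recipe.target_resn,
        site=site,
        outcome="modified",
        product_resn=residue.resn if site == "sidechain" else None,
        variant=defn.variant,
        position=recipe.position,
        atoms_added=added,
        atoms_removed=removed,
        charge_delta=defn.charge_delta,
        strain_before=strain_before,
        strain_after=strain_after,
        chosen_torsions=[t.chosen_offset for t in opt.torsions] if opt else [],
    )
    return strain_after, entry, opt


def _options_for(
    defn: PTMDefinition, residue: Residue, opts: ModificationOptions
) -> list[tuple[PTMDefinition, ResolvedRecipe]]:
    """Enumerate concrete (definition, recipe) alternatives for a residue.

    More than one alternative means 'build each, keep the lower strain':
    the two nitration ortho positions, or the R/S members of a
    racemic-choice variant.
    """
    if defn.choice_of:
        out = []
        for vname in defn.choice_of:
            member = get_definition(defn.ptm_class, vname)
            out.append((member, member.resolve(residue.resn)))
        return out
    recipes = [r for r in defn._recipes if r.target_resn == residue.resn]
    if opts.position_override is not None:
        return [(defn, defn.resolve(residue.resn, opts.position_override))]
    if len(recipes) > 1 and all(r.position is not None for r in recipes):
        return [(defn, r) for r in recipes]
    return [(defn, recipes[0])]


def apply_ptm(
    structure: Structure,
    residue: Residue,
    defn: PTMDefinition,
    opts: ModificationOptions,
    site: str = "sidechain",
) -> ReportEntry:
    """Apply one modification to one residue (mutates the structure).

    Missing reference atoms or an existing modification produce a skip
    entry, never an exception; unresolvable clashes are not an error (the
    entry carries the residual strain).  When a definition admits several
    concrete placements (ortho positions, R/S choice) each is built and
    the lowest-strain one kept; ties keep the first in catalog order,
    which for nitration is the lexicographically lower ring carbon.
    """
    base = ReportEntry(
        chain_id=residue.chain_id,
        resi=residue.resi,
        icode=residue.icode,
        original_resn=residue.resn,
        site=site,
    )
    if site == "nterm":
        if not residue.is_n_terminal or residue.resn == "PRO":
            base.outcome = "skipped_not_n_terminal"
            return base
        if _has_nterm_cap(residue):
            base.outcome = "skipped_already_modified"
            return base
        try:
            alternatives = [(defn if not defn.choice_of else get_definition(defn.ptm_class, defn.choice_of[0]), None)]
            alternatives = [(d, d.n_term_recipe(residue.resn)) for d, _ in alternatives]
        except ptm_catalog.CatalogError as exc:
            base.outcome = "skipped_missing_atoms"
            base.detail = str(exc)
            return base
    else:
        if _is_sidechain_modified(residue):
            base.outcome = "skipped_already_modified"
            return base
        if residue.resn not in defn.target_resn:
            base.outcome = "skipped_missing_atoms"
            base.detail = f"{residue.resn} is not a target of {defn.ptm_class}/{defn.variant}"
            return base
        alternatives = _options_for(defn, residue, opts)

    missing = _missing_refs(residue, alternatives[0][1])
    if missing:
        base.outcome = "skipped_missing_atoms"
        base.detail = f"missing atoms: {', '.join(missing)}"
        return base

    baseline: Optional[float] = None
    if opts.probe_baseline and site == "sidechain":
        moving = sidechain_moving_atoms(residue)
        if moving:
            baseline = vdw_strain(structure, moving)[0].value
        else:
            baseline = 0.0
    elif opts.probe_baseline:
        baseline = 0.0

    best: Optional[tuple[float, ReportEntry]] = None
    best_index = -1
    for idx, (alt_defn, recipe) in enumerate(alternatives):
        snapshot = _ResidueSnapshot(structure, residue) if len(alternatives) > 1 else None
        try:
            strain, entry, _ = _apply_option(
                structure, residue, alt_defn, recipe, opts, site, baseline
            )
        except ValueError as exc:
            if snapshot is not None:
                snapshot.restore()
            base.outcome = "skipped_missing_atoms"
            base.detail = str(exc)
            continue
        if best is None or strain < best[0] - 1e-12:
            best = (strain, entry)
            best_index = idx
        if snapshot is not None:
            snapshot.restore()
    if best is None:
        return base

    if len(alternatives) > 1:
        alt_defn, recipe = alternatives[best_index]
        _, entry, _ = _apply_option(structure, residue, alt_defn, recipe, opts, site, baseline)
        return entry
    return best[1]


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def modify(
    structure: Structure,
    opts: ModificationOptions,
    sasa: Optional[SasaResult] = None,
) -> ModificationReport:
    """Run the full pipeline for one modification class (in place).

    Computes solvent accessibility once if a surface cutoff is requested,
    discovers candidates, grafts them sequentially in stable order, and
    returns a report whose skip/modified entries partition the candidate
    set.  Provenance is appended to the structure's REMARK block.
    """
    defn = get_definition(opts.ptm_class, opts.variant)
    if opts.surface_cutoff is not None and sasa is None:
        sasa = compute_sasa(structure, probe=opts.sasa_probe, n_points=opts.sasa_points)

    candidates, buried = _discover(structure, opts, sasa)
    report = ModificationReport(ptm_class=defn.ptm_class, variant=defn.variant)
    for cand in candidates:
        entry = apply_ptm(structure, cand.residue, defn, opts, site=cand.site)
        report.entries.append(entry)
    report.entries.extend(buried)
    report.entries.sort(key=lambda e: (e.chain_id, e.resi, e.icode, e.site))

    totals = report.totals()
    structure.remarks.append(
        f"PTMGRAFT {defn.ptm_class}:{defn.variant} "
        f"modified={totals['modified']} candidates={totals['candidates']}"
    )
    logger.info(
        "%s/%s: %d candidates, %d modified, %d buried, %d already modified, %d missing atoms",
        defn.ptm_class,
        defn.variant,
        totals["candidates"],
        totals["modified"],
        totals["skipped_buried"],
        totals["skipped_already_modified"],
        totals["skipped_missing_atoms"],
    )
    return report
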