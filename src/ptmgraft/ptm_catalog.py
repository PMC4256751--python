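"""Declarative catalog of the ten supported modification classes.

Definitions are loaded from the bundled ``data/catalog.yaml`` so chemists
can extend the catalog without touching code.  On load, bond templates
for all unambiguous product residues are derived from their parent
residue templates and registered with the structure layer, so that
already-modified structures re-read from disk get correct bonds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import yaml

from . import _chemdata
from .geometry_core import InternalCoordinate

__all__ = [
    "CatalogError",
    "AddedAtom",
    "ElementSwap",
    "Stereocenter",
    "ResolvedRecipe",
    "PTMDefinition",
    "CatalogIndex",
    "list_ptms",
    "get_definition",
    "product_resnames",
    "PHANTOM_NEIGHBOR",
]

PHANTOM_NEIGHBOR = "*"


class CatalogError(ValueError):
    """Unknown modification class or variant."""


@dataclass(frozen=True)
class AddedAtom:
    name: str
    element: str
    ic: InternalCoordinate
    bond_to: tuple[str, ...]  # atom names this atom is bonded to


@dataclass(frozen=True)
class ElementSwap:
    name: str
    new_element: str
    new_name: str
    new_length: Optional[float] = None  # re-scale the existing bond if set


@dataclass(frozen=True)
class Stereocenter:
    center: str
    neighbors: tuple[str, str, str, str]  # CIP priority descending; "*" = phantom
    label: str  # configured label: "R" or "S"


@dataclass(frozen=True)
class ResolvedRecipe:
    """A recipe fully resolved for one target residue type (and position)."""

    target_resn: str
    target_atom: str
    product_resn: Optional[str]  # None: keep residue name (N-terminal caps)
    atoms_added: tuple[AddedAtom, ...]
    atoms_removed: tuple[str, ...]
    element_swaps: tuple[ElementSwap, ...]
    extra_bonds: tuple[tuple[str, str], ...]
    stereocenters: tuple[Stereocenter, ...]
    position: Optional[int] = None

    @property
    def heavy_atom_delta(self) -> int:
        return len(self.atoms_added) - len(self.atoms_removed)


@dataclass
class PTMDefinition:
    ptm_class: str
    variant: str
    is_default: bool
    n_term_capable: bool
    charge_delta: int
    target_resn: list[str]
    choice_of: Optional[tuple[str, ...]] = None  # meta-variant resolved by strain
    _recipes: list[ResolvedRecipe] = field(default_factory=list, repr=False)
    _n_term: Optional[dict] = field(default=None, repr=False)

    # convenience accessors mirroring the primary recipe -------------------
    @property
    def primary(self) -> ResolvedRecipe:
        return self._recipes[0]

    @property
    def target_atom(self) -> str:
        return self.primary.target_atom

    @property
    def product_resn(self) -> Optional[str]:
        return self.primary.product_resn

    @property
    def atoms_added(self) -> tuple[AddedAtom, ...]:
        return self.primary.atoms_added

    @property
    def atoms_removed(self) -> tuple[str, ...]:
        return self.primary.atoms_removed

    @property
    def element_swaps(self) -> tuple[ElementSwap, ...]:
        return self.primary.element_swaps

    @property
    def stereocenters(self) -> tuple[Stereocenter, ...]:
        return self.primary.stereocenters

    # resolution -----------------------------------------------------------
    def positions(self, resn: str) -> list[Optional[int]]:
        return [r.position for r in self._recipes if resn in (r.target_resn,)] or [None]

    def resolve(self, resn: str, position: Optional[int] = None) -> ResolvedRecipe:
        matches = [r for r in self._recipes if r.target_resn == resn]
        if not matches:
            raise CatalogError(
                f"{self.ptm_class}/{self.variant} does not target {resn}; "
                f"valid targets: {sorted(self.target_resn)}"
            )
        if position is None:
            return matches[0]
        for r in matches:
            if r.position == position:
                return r
        raise CatalogError(
            f"{self.ptm_class}/{self.variant}: no position {position} for {resn}; "
            f"valid positions: {[r.position for r in matches]}"
        )

    def n_term_recipe(self, resn: str) -> ResolvedRecipe:
        """Recipe retargeted at the backbone N of a chain-initial residue."""
        if not self.n_term_capable or self._n_term is None:
            raise CatalogError(f"{self.ptm_class} cannot modify N-termini")
        anchor_map: dict[str, str] = dict(self._n_term.get("anchor_map", {}))
        name_map: dict[str, str] = dict(self._n_term.get("name_map", {}))
        base = self._recipes[0]

        def remap(name: str) -> str:
            return name_map.get(name, anchor_map.get(name, name))

        atoms = tuple(
            AddedAtom(
                name=remap(a.name),
                element=a.element,
                ic=InternalCoordinate(
                    remap(a.ic.ref_a),
                    remap(a.ic.ref_b),
                    remap(a.ic.ref_c),
                    a.ic.bond_length,
                    a.ic.bond_angle,
                    a.ic.dihedral,
                ),
                bond_to=tuple(remap(b) for b in a.bond_to),
            )
            for a in base.atoms_added
        )
        stereo = tuple(
            Stereocenter(
                center=remap(s.center),
                neighbors=tuple(n if n == PHANTOM_NEIGHBOR else remap(n) for n in s.neighbors),
                label=s.label,
            )
            for s in base.stereocenters
        )
        return ResolvedRecipe(
            target_resn=resn,
            target_atom=anchor_map.get(base.target_atom, "N"),
            product_resn=None,
            atoms_added=atoms,
            atoms_removed=tuple(remap(n) for n in base.atoms_removed),
            element_swaps=(),
            extra_bonds=tuple((remap(a), remap(b)) for a, b in base.extra_bonds),
            stereocenters=stereo,
        )


@dataclass(frozen=True)
class CatalogIndex:
    classes: dict[str, dict]  # class -> {"variants": [...], "default": str}

    def __len__(self) -> int:
        return len(self.classes)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _parse_added_atom(entry: dict) -> AddedAtom:
    refs = entry["refs"]
    ic = InternalCoordinate(
        refs[0], refs[1], refs[2],
        float(entry["length"]), float(entry["angle"]), float(entry["dihedral"]),
    )
    bond_to = tuple(entry.get("bond_to", [refs[2]]))
    return AddedAtom(name=entry["name"], element=entry["element"], ic=ic, bond_to=bond_to)


def _parse_recipe(entry: dict) -> list[ResolvedRecipe]:
    out = []
    for resn in entry["target_resn"]:
        product = entry.get("product_resn")
        if product is not None and len(product) > 3:
            raise ValueError(f"product residue code {product!r} longer than 3 characters")
        out.append(
            ResolvedRecipe(
                target_resn=resn,
                target_atom=entry["target_atom"],
                product_resn=product,
                atoms_added=tuple(_parse_added_atom(a) for a in entry.get("atoms_added", [])),
                atoms_removed=tuple(entry.get("atoms_removed", [])),
                element_swaps=tuple(
                    ElementSwap(
                        name=s["name"],
                        new_element=s["new_element"],
                        new_name=s.get("new_name", s["name"]),
                        new_length=s.get("new_length"),
                    )
                    for s in entry.get("element_swaps", [])
                ),
                extra_bonds=tuple(tuple(b) for b in entry.get("extra_bonds", [])),
                stereocenters=tuple(
                    Stereocenter(
                        center=s["center"],
                        neighbors=tuple(s["neighbors"]),
                        label=s["label"],
                    )
                    for s in entry.get("stereocenters", [])
                ),
                position=entry.get("position"),
            )
        )
    return out


class _Catalog:
    def __init__(self, raw: dict):
        self.version = raw.get("version", 0)
        self.definitions: dict[tuple[str, str], PTMDefinition] = {}
        self.defaults: dict[str, str] = {}
        for cls_name, cls_raw in raw["classes"].items():
            default = cls_raw["default_variant"]
            if default not in cls_raw["variants"]:
                raise ValueError(f"{cls_name}: default variant {default!r} not defined")
            self.defaults[cls_name] = default
            for var_name, var_raw in cls_raw["variants"].items():
                if "choice_of" in var_raw:
                    defn = PTMDefinition(
                        ptm_class=cls_name,
                        variant=var_name,
                        is_default=var_name == default,
                        n_term_capable=bool(cls_raw.get("n_term_capable", False)),
                        charge_delta=0,
                        target_resn=[],
                        choice_of=tuple(var_raw["choice_of"]),
                        _n_term=cls_raw.get("n_term"),
                    )
                else:
                    recipes: list[ResolvedRecipe] = []
                    for rec in var_raw["recipes"]:
                        recipes.extend(_parse_recipe(rec))
                    defn = PTMDefinition(
                        ptm_class=cls_name,
                        variant=var_name,
                        is_default=var_name == default,
                        n_term_capable=bool(cls_raw.get("n_term_capable", False)),
                        charge_delta=int(var_raw.get("charge_delta", 0)),
                        target_resn=sorted({r.target_resn for r in recipes}),
                        _recipes=recipes,
                        _n_term=cls_raw.get("n_term"),
                    )
                self.definitions[(cls_name, var_name)] = defn
        # resolve choice targets from their member variants
        for defn in self.definitions.values():
            if defn.choice_of:
                members = [self.definitions[(defn.ptm_class, v)] for v in defn.choice_of]
                defn.target_resn = sorted({r for m in members for r in m.target_resn})
                defn.charge_delta = members[0].charge_delta

    @property
    def classes(self) -> list[str]:
        return sorted({c for c, _ in self.definitions})

    def variants(self, cls_name: str) -> list[str]:
        return sorted(v for c, v in self.definitions if c == cls_name)


_catalog: Optional[_Catalog] = None


def _load() -> _Catalog:
    global _catalog
    if _catalog is None:
        text = resources.files("ptmgraft").joinpath("data/catalog.yaml").read_text()
        _catalog = _Catalog(yaml.safe_load(text))
        _register_product_templates(_catalog)
    return _catalog


def _register_product_templates(cat: _Catalog) -> None:
    """Derive and register bond templates for unambiguous product residues.

    Recipes carrying a grafting position (nitration rotamers) are skipped:
    the added atoms bond to a position-dependent ring carbon, so those
    products fall back to distance-based bond inference on re-read.
    """
    for defn in cat.definitions.values():
        if defn.choice_of:
            continue
        for recipe in defn._recipes:
            if recipe.position is not None or recipe.product_resn is None:
                continue
            parent = _chemdata.BOND_TEMPLATES.get(recipe.target_resn)
            if parent is None:
                continue
            bonds = [tuple(b) for b in parent]
            removed = set(recipe.atoms_removed)
            bonds = [b for b in bonds if not (set(b) & removed)]
            rename = {s.name: s.new_name for s in recipe.element_swaps}
            bonds = [(rename.get(a, a), rename.get(b, b)) for a, b in bonds]
            for atom in recipe.atoms_added:
                for partner in atom.bond_to:
                    bonds.append((partner, atom.name))
            bonds.extend(recipe.extra_bonds)
            _chemdata.register_bond_template(recipe.product_resn, bonds)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def list_ptms() -> CatalogIndex:
    """Index of all modification classes with their variants and defaults."""
    cat = _load()
    return CatalogIndex(
        classes={
            cls: {"variants": cat.variants(cls), "default": cat.defaults[cls]}
            for cls in cat.classes
        }
    )


def get_definition(ptm_class: str, variant: Optional[str] = None) -> PTMDefinition:
    """Look up a fully resolved definition; the default variant if omitted."""
    cat = _load()
    if ptm_class not in cat.classes:
        raise CatalogError(
            f"unknown modification class {ptm_class!r}; valid classes: {', '.join(cat.classes)}"
        )
    if variant is None:
        variant = cat.defaults[ptm_class]
    key = (ptm_class, variant)
    if key not in cat.definitions:
        raise CatalogError(
            f"unknown variant {variant!r} for {ptm_class}; "
            f"valid variants: {', '.join(cat.variants(ptm_class))}"
        )
    return cat.definitions[key]


def product_resnames() -> set[str]:
    """All product residue codes the catalog can produce."""
    cat = _load()
    out = set()
    for defn in cat.definitions.values():
        if defn.choice_of:
            continue
        for recipe in defn._recipes:
            if recipe.product_resn:
                out.add(recipe.product_resn)
    return out
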