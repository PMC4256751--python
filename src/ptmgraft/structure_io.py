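"""PDB reading/writing and a minimal atom addressing/selection layer.

The model is a plain hierarchy (Structure -> chains -> Residue -> Atom)
with an explicit bond list.  Bonds are inferred on read from per-residue
templates (standard residues plus catalog product residues) with a
distance fallback for unknown components; peptide links are distance
checked (C-N < 2.0 A).

Only PDB v3.3 ATOM/HETATM/TER/REMARK records are handled; one model of a
multi-model file is read.  Applied modifications are carried in
``REMARK 999 PTM`` lines so that tags survive a write/read round trip.
"""

from __future__ import annotations

import copy
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np

from ._chemdata import (
    BOND_TEMPLATES,
    STANDARD_AMINO_ACIDS,
    WATER_RESNAMES,
)

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "PDBParseError",
    "SelectionError",
    "read_pdb",
    "write_pdb",
    "select",
]

AtomKey = tuple[str, int, str, str]  # chain, resi, icode, atom name


class PDBParseError(ValueError):
    pass


class SelectionError(ValueError):
    pass


@dataclass(eq=False)
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0
    bfactor: float = 0.0
    is_hetatm: bool = False
    residue: "Residue" = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: element must be non-empty")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    @property
    def key(self) -> AtomKey:
        r = self.residue
        return (r.chain_id, r.resi, r.icode, self.name)


@dataclass(eq=False)
class Residue:
    chain_id: str
    resi: int
    resn: str
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)
    is_n_terminal: bool = False
    ptm_tag: Optional[str] = None

    def add_atom(self, atom: Atom) -> Atom:
        if self.atom(atom.name) is not None:
            raise ValueError(
                f"duplicate atom name {atom.name!r} in {self.chain_id}/{self.resi}{self.icode}"
            )
        atom.residue = self
        self.atoms.append(atom)
        return atom

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.resi, self.icode)

    @property
    def is_water(self) -> bool:
        return self.resn in WATER_RESNAMES

    @property
    def is_polymer(self) -> bool:
        """Amino-acid-like: standard resn, or has the backbone triad."""
        if self.resn in STANDARD_AMINO_ACIDS:
            return True
        if self.is_water:
            return False
        return all(self.atom(n) is not None for n in ("N", "CA", "C"))

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Residue {self.chain_id}/{self.resn}{self.resi}{self.icode}>"


class Structure:
    """Ordered residues with an explicit, symmetric bond list."""

    def __init__(self, residues: Optional[Iterable[Residue]] = None, source: str = ""):
        self.residues: list[Residue] = list(residues or [])
        self.bonds: set[frozenset[AtomKey]] = set()
        self.metadata: dict = {"source": source}
        self.remarks: list[str] = []

    # -- access -------------------------------------------------------------
    @property
    def chains(self) -> dict[str, list[Residue]]:
        out: dict[str, list[Residue]] = {}
        for r in self.residues:
            out.setdefault(r.chain_id, []).append(r)
        return out

    def atoms(self) -> Iterator[Atom]:
        for r in self.residues:
            yield from r.atoms

    def atom_by_key(self, key: AtomKey) -> Optional[Atom]:
        res = self.residue(key[0], key[1], key[2])
        return res.atom(key[3]) if res is not None else None

    def residue(self, chain_id: str, resi: int, icode: str = "") -> Optional[Residue]:
        for r in self.residues:
            if r.chain_id == chain_id and r.resi == resi and r.icode == icode:
                return r
        return None

    def add_residue(self, res: Residue) -> Residue:
        self.residues.append(res)
        return res

    # -- bonds --------------------------------------------------------------
    def add_bond(self, a: AtomKey, b: AtomKey) -> None:
        if a == b:
            raise ValueError("cannot bond atom to itself")
        self.bonds.add(frozenset((a, b)))

    def bonded_keys(self, key: AtomKey) -> set[AtomKey]:
        out = set()
        for bond in self.bonds:
            if key in bond:
                (other,) = set(bond) - {key}
                out.add(other)
        return out

    def remove_atom(self, atom: Atom) -> None:
        key = atom.key
        atom.residue.atoms.remove(atom)
        self.bonds = {b for b in self.bonds if key not in b}

    def adjacency(self) -> dict[AtomKey, set[AtomKey]]:
        adj: dict[AtomKey, set[AtomKey]] = {}
        for bond in self.bonds:
            a, b = tuple(bond)
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        return adj

    def copy(self) -> "Structure":
        return copy.deepcopy(self)

    # -- bookkeeping --------------------------------------------------------
    def assign_n_terminal_flags(self) -> None:
        for _, residues in self.chains.items():
            first = True
            for r in residues:
                if r.is_polymer:
                    r.is_n_terminal = first
                    first = False
                else:
                    r.is_n_terminal = False

    def infer_bonds(self) -> None:
        """(Re)build the bond list: templates, distance fallback, peptide links."""
        self.bonds = set()
        for r in self.residues:
            self._bond_residue(r)
        # hydrogens: attach to nearest heavy atom in the same residue
        for r in self.residues:
            heavies = r.heavy_atoms()
            if not heavies:
                continue
            for h in r.atoms:
                if not h.is_hydrogen:
                    continue
                d = [float(np.linalg.norm(h.coords - x.coords)) for x in heavies]
                i = int(np.argmin(d))
                if d[i] < 1.3:
                    self.add_bond(h.key, heavies[i].key)
        # peptide links between consecutive polymer residues of a chain
        for _, residues in self.chains.items():
            poly = [r for r in residues if r.is_polymer]
            for prev, nxt in zip(poly, poly[1:]):
                c, n = prev.atom("C"), nxt.atom("N")
                if c is None or n is None:
                    continue
                if np.linalg.norm(c.coords - n.coords) < 2.0:
                    self.add_bond(c.key, n.key)

    def _bond_residue(self, r: Residue) -> None:
        template = BOND_TEMPLATES.get(r.resn)
        if template is not None:
            for na, nb in template:
                a, b = r.atom(na), r.atom(nb)
                if a is not None and b is not None:
                    self.add_bond(a.key, b.key)
            if r.atom("OXT") is not None and r.atom("C") is not None:
                self.add_bond(r.atom("C").key, r.atom("OXT").key)
            return
        # unknown component: distance-based heavy-atom bonding
        heavies = r.heavy_atoms()
        for i, a in enumerate(heavies):
            for b in heavies[i + 1 :]:
                cut = 2.1 if {a.element.upper(), b.element.upper()} & {"S", "P"} else 1.9
                if np.linalg.norm(a.coords - b.coords) < cut:
                    self.add_bond(a.key, b.key)

    def apply_remark_tags(self) -> None:
        """Restore ptm_tag fields from REMARK 999 PTM lines."""
        for line in self.remarks:
            parts = line.split()
            if len(parts) >= 5 and parts[0] == "PTM":
                chain, resi_field, tag = parts[1], parts[2], parts[4]
                icode = ""
                if resi_field and not resi_field[-1].isdigit():
                    icode = resi_field[-1]
                    resi_field = resi_field[:-1]
                try:
                    resi = int(resi_field)
                except ValueError:
                    continue
                res = self.residue(chain, resi, icode)
                if res is not None:
                    res.ptm_tag = tag


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _guess_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        raise PDBParseError(f"cannot derive element from atom name {name!r}")
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "BR", "FE", "ZN", "MG", "NA", "SE"):
        return stripped[:2].capitalize()
    return stripped[0].upper()


def _parse_atom_line(line: str, lineno: int) -> tuple[Atom, str, int, str, str]:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        resn = line[17:20].strip()
        chain = line[21].strip() or "A"
        resi = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        bf_field = line[60:66].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        bfactor = float(bf_field) if bf_field else 0.0
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            element = _guess_element(name)
        atom = Atom(
            serial=serial,
            name=name,
            element=element,
            coords=np.array([x, y, z]),
            altloc=altloc,
            occupancy=occupancy,
            bfactor=bfactor,
            is_hetatm=line.startswith("HETATM"),
        )
        return atom, chain, resi, icode, resn
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"unparseable ATOM/HETATM record at line {lineno}: {exc}") from exc


def _resolve_altlocs(res: Residue) -> None:
    """Keep the highest-occupancy conformer per atom name; drop the rest."""
    by_name: dict[str, list[Atom]] = {}
    for a in res.atoms:
        by_name.setdefault(a.name, []).append(a)
    kept: list[Atom] = []
    for a in res.atoms:
        group = by_name[a.name]
        if len(group) == 1:
            winner = a
        else:
            winner = sorted(group, key=lambda x: (-x.occupancy, x.altloc))[0]
        if a is winner:
            a.altloc = ""
            kept.append(a)
    res.atoms = kept


def read_pdb(path: str | os.PathLike, model_index: int = 0) -> Structure:
    """Read one model of a PDB file into a Structure.

    Altloc conformers are collapsed to the highest-occupancy one; bonds
    are inferred from templates plus distance-checked peptide links, and
    N-terminal flags are set on the first polymer residue of each chain.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)

    structure = Structure(source=path)
    current: Optional[Residue] = None
    model_count = 0
    in_wanted_model = model_index == 0
    saw_model_records = False

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                saw_model_records = True
                in_wanted_model = model_count == model_index
                model_count += 1
                continue
            if rec == "ENDMDL":
                in_wanted_model = False
                continue
            if rec.startswith("REMARK"):
                try:
                    if int(line[7:10].strip() or 0) == 999:
                        structure.remarks.append(line[11:].rstrip())
                except ValueError:
                    pass
                continue
            if rec in ("ATOM  ", "HETATM"):
                if saw_model_records and not in_wanted_model:
                    continue
                atom, chain, resi, icode, resn = _parse_atom_line(line, lineno)
                if (
                    current is None
                    or current.key != (chain, resi, icode)
                    or current.resn != resn
                ):
                    current = Residue(chain_id=chain, resi=resi, resn=resn, icode=icode)
                    structure.add_residue(current)
                # duplicate names are altloc conformers at this stage
                atom.residue = current
                current.atoms.append(atom)

    if not structure.residues:
        raise PDBParseError(f"no atoms found in {path} (model {model_index})")

    for res in structure.residues:
        _resolve_altlocs(res)
    structure.assign_n_terminal_flags()
    structure.infer_bonds()
    structure.apply_remark_tags()
    return structure


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _format_atom_name(name: str, element: str) -> str:
    if len(name) > 4:
        raise ValueError(f"atom name {name!r} longer than 4 characters")
    if len(name) < 4 and len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(structure: Structure, path: str | os.PathLike) -> None:
    """Write a Structure as PDB v3.3.

    Residues whose component code is non-standard (including waters and
    catalog product residues) are written as HETATM.  Applied PTMs are
    recorded in REMARK 999 lines; serials are renumbered sequentially.
    """
    if not structure.residues or not any(True for _ in structure.atoms()):
        raise ValueError("refusing to write an empty structure")

    lines: list[str] = []
    for remark in structure.remarks:
        lines.append(f"REMARK 999 {remark}")
    tag_lines = [
        f"REMARK 999 PTM {r.chain_id} {r.resi}{r.icode} {r.resn} {r.ptm_tag}"
        for r in structure.residues
        if r.ptm_tag
    ]
    existing = set(lines)
    for tl in tag_lines:
        if tl not in existing:
            lines.append(tl)

    serial = 0
    for chain_id, residues in structure.chains.items():
        last_polymer = None
        for res in residues:
            hetatm = res.is_hetatm_record
            for atom in res.atoms:
                serial += 1
                record = "HETATM" if hetatm else "ATOM  "
                x, y, z = atom.coords
                lines.append(
                    f"{record}{serial:>5d} {_format_atom_name(atom.name, atom.element)}"
                    f"{atom.altloc or ' '}{res.resn:>3s} {chain_id:1s}"
                    f"{res.resi:>4d}{res.icode or ' '}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.bfactor:6.2f}"
                    f"          {atom.element.upper():>2s}"
                )
            if res.is_polymer:
                last_polymer = (serial, res)
        if last_polymer is not None:
            ter_serial, res = last_polymer
            lines.append(
                f"TER   {ter_serial + 1:>5d}      {res.resn:>3s} {chain_id:1s}{res.resi:>4d}{res.icode or ' '}"
            )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _is_hetatm_record(res: Residue) -> bool:
    if res.resn not in STANDARD_AMINO_ACIDS:
        return True
    return all(a.is_hetatm for a in res.atoms) if res.atoms else False


Residue.is_hetatm_record = property(_is_hetatm_record)  # type: ignore[attr-defined]


# ---------------------------------------------------------------------------
# selection mini-grammar
# ---------------------------------------------------------------------------
#   expr    := term (OR term)*
#   term    := factor (AND factor)*
#   factor  := NOT factor | '(' expr ')' | primitive
#   primitive := all | chain <id> | resn <code> | resi <n|n-m[,..]> | name <atom>

class _Tokenizer:
    def __init__(self, text: str):
        self.tokens = text.replace("(", " ( ").replace(")", " ) ").split()
        self.pos = 0

    def peek(self) -> Optional[str]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok


def _parse_resi_spec(spec: str) -> set[int]:
    out: set[int] = set()
    for part in spec.split(","):
        if "-" in part[1:]:  # allow negative single numbers
            lo_s, hi_s = part.rsplit("-", 1)
            try:
                lo, hi = int(lo_s), int(hi_s)
            except ValueError as exc:
                raise SelectionError(f"bad resi range {part!r}") from exc
            if lo > hi:
                raise SelectionError(f"empty resi range {part!r}")
            out.update(range(lo, hi + 1))
        else:
            try:
                out.add(int(part))
            except ValueError as exc:
                raise SelectionError(f"bad resi {part!r}") from exc
    return out


class _Parser:
    def __init__(self, structure: Structure, text: str):
        self.structure = structure
        self.tok = _Tokenizer(text)
        self.universe = set(structure.atoms())

    def parse(self) -> set[Atom]:
        result = self._expr()
        if self.tok.peek() is not None:
            raise SelectionError(f"trailing tokens at {self.tok.peek()!r}")
        return result

    def _expr(self) -> set[Atom]:
        left = self._term()
        while (self.tok.peek() or "").upper() == "OR":
            self.tok.next()
            left = left | self._term()
        return left

    def _term(self) -> set[Atom]:
        left = self._factor()
        while (self.tok.peek() or "").upper() == "AND":
            self.tok.next()
            left = left & self._factor()
        return left

    def _factor(self) -> set[Atom]:
        tok = self.tok.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        if tok.upper() == "NOT":
            self.tok.next()
            return self.universe - self._factor()
        if tok == "(":
            self.tok.next()
            inner = self._expr()
            if self.tok.next() != ")":
                raise SelectionError("unbalanced parentheses")
            return inner
        return self._primitive()

    def _primitive(self) -> set[Atom]:
        kw = self.tok.next().lower()
        if kw == "all":
            return set(self.universe)
        if kw not in ("chain", "resn", "resi", "name"):
            raise SelectionError(f"unknown selection keyword {kw!r}")
        value = self.tok.next()
        if value in ("(", ")") or value.upper() in ("AND", "OR", "NOT"):
            raise SelectionError(f"missing value after {kw!r}")
        if kw == "chain":
            return {a for a in self.universe if a.residue.chain_id.upper() == value.upper()}
        if kw == "resn":
            return {a for a in self.universe if a.residue.resn.upper() == value.upper()}
        if kw == "name":
            return {a for a in self.universe if a.name.upper() == value.upper()}
        resis = _parse_resi_spec(value)
        return {a for a in self.universe if a.residue.resi in resis}


def select(structure: Structure, expr: str) -> set[Atom]:
    """Evaluate a selection expression against a structure.

    Supported primitives: ``all``, ``chain X``, ``resn LYS``,
    ``resi 5`` / ``resi 1-10,15``, ``name NZ``; combined with
    AND / OR / NOT and parentheses.  Returns a (possibly empty) set of
    Atom objects.
    """
    if not expr or not expr.strip():
        raise SelectionError("empty selection expression")
    return _Parser(structure, expr).parse()
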