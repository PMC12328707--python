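"""Macromolecular structure containers and PDB/mmCIF input/output.

The in-memory model is deliberately flat: a :class:`StructureModel` owns an
ordered list of :class:`Atom` records plus the unit cell and symmetry
operators.  Chains and residues are views derived from atom keys, which keeps
round-tripping trivial and makes geometric code (the bulk of this package)
operate on plain numpy arrays.  Parsing and serialisation are delegated to
gemmi; this module owns the conversion, the alternate-location policy, the
hydrogen policy and the element-inference rules.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

try:
    import gemmi
except ImportError as exc:  # pragma: no cover
    raise ImportError("halosite.structio requires gemmi") from exc

# Residue names of monatomic ions whose element equals the residue name.
ION_RESIDUE_ELEMENTS = {"K": "K", "NA": "NA", "MG": "MG", "CL": "CL", "CA": "CA"}

WATER_NAMES = {"HOH", "WAT", "DOD"}

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "MSE", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


class ParseError(ValueError):
    """Raised when a structure file cannot be interpreted."""


class SelectionError(ValueError):
    """Raised for a malformed selection expression."""


@dataclass(frozen=True)
class Atom:
    """One atom of a crystal structure (orthogonal coordinates, Angstrom)."""

    serial: int
    name: str
    element: str
    alt_loc: str
    occupancy: float
    b_iso: float
    residue_name: str
    residue_seq: int
    icode: str
    chain_id: str
    is_hetero: bool
    position: tuple[float, float, float]

    def __post_init__(self):
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy {self.occupancy} outside [0,1] for atom {self.serial}")
        if not all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.serial}")

    @property
    def is_water(self) -> bool:
        return self.residue_name in WATER_NAMES

    @property
    def is_polymer(self) -> bool:
        return (not self.is_hetero) and (not self.is_water)

    @property
    def residue_key(self) -> tuple[str, int, str, str]:
        return (self.chain_id, self.residue_seq, self.icode, self.residue_name)

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass(frozen=True)
class UnitCell:
    """Crystallographic cell: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self):
        for v in (self.a, self.b, self.c):
            if v <= 0:
                raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not (0.0 < ang < 180.0):
                raise ValueError("cell angles must lie in (0, 180) degrees")
        if self.volume() <= 0:
            raise ValueError("degenerate cell: non-positive volume")

    def volume(self) -> float:
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0:
            return -1.0
        return self.a * self.b * self.c * float(np.sqrt(arg))


@dataclass(frozen=True)
class SymOp:
    """Space-group operator in fractional space: x' = R x + t."""

    rotation: tuple[tuple[float, ...], ...]
    translation: tuple[float, float, float]

    def __post_init__(self):
        det = np.linalg.det(np.asarray(self.rotation, dtype=float))
        if not np.isclose(abs(det), 1.0):
            raise ValueError(f"symmetry rotation determinant {det}, expected +-1")

    @property
    def rot(self) -> np.ndarray:
        return np.asarray(self.rotation, dtype=float)

    @property
    def tran(self) -> np.ndarray:
        return np.asarray(self.translation, dtype=float)

    @property
    def is_identity(self) -> bool:
        return np.allclose(self.rot, np.eye(3)) and np.allclose(self.tran % 1.0, 0.0)

    @classmethod
    def from_triplet(cls, triplet: str) -> "SymOp":
        op = gemmi.Op(triplet)
        rot = tuple(tuple(v / gemmi.Op.DEN for v in row) for row in op.rot)
        tran = tuple((v / gemmi.Op.DEN) % 1.0 for v in op.tran)
        return cls(rotation=rot, translation=tran)

    def triplet(self) -> str:
        den = gemmi.Op.DEN
        op = gemmi.Op()
        op.rot = [[int(round(v * den)) for v in row] for row in self.rot]
        op.tran = [int(round(v * den)) for v in self.tran]
        return op.triplet()


IDENTITY_OP = SymOp(rotation=((1, 0, 0), (0, 1, 0), (0, 0, 1)), translation=(0, 0, 0))

# Minimal built-in operator tables for files lacking symmetry records.
SPACE_GROUP_OPS = {
    "P 1": ["x,y,z"],
    "P 1 21 1": ["x,y,z", "-x,y+1/2,-z"],
}


@dataclass
class StructureModel:
    """An ordered collection of atoms plus cell, symmetry and assembly info."""

    atoms: list[Atom] = field(default_factory=list)
    unit_cell: UnitCell | None = None
    sym_ops: list[SymOp] = field(default_factory=list)
    assembly_map: dict[str, str] = field(default_factory=dict)
    name: str = ""
    space_group: str = ""

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        seen: set[tuple] = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_seq, a.icode, a.name, a.alt_loc)
            if key in seen:
                raise ValueError(f"duplicate atom key {key}")
            seen.add(key)

    # ---- views -----------------------------------------------------------

    @property
    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.asarray([a.position for a in self.atoms], dtype=float)

    def chains(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def residues(self) -> list[tuple[str, int, str, str]]:
        out: list[tuple[str, int, str, str]] = []
        for a in self.atoms:
            k = a.residue_key
            if not out or out[-1] != k:
                if k not in out:
                    out.append(k)
        return out

    def polymer_residues(self) -> list[tuple[str, int, str, str]]:
        return [k for k in self.residues() if k[3] not in WATER_NAMES and k[3] in AMINO_ACIDS]

    def waters(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_water and a.element == "O"]

    def assembly_of(self, chain_id: str) -> str:
        return self.assembly_map.get(chain_id, chain_id)

    def with_atoms(self, atoms: list[Atom]) -> "StructureModel":
        return StructureModel(
            atoms=list(atoms),
            unit_cell=self.unit_cell,
            sym_ops=list(self.sym_ops),
            assembly_map=dict(self.assembly_map),
            name=self.name,
            space_group=self.space_group,
        )


# ---------------------------------------------------------------------------
# Element inference and alt-loc policy


def infer_element(atom_name: str, residue_name: str) -> str:
    """Infer the element symbol from atom and residue names.

    Monatomic-ion residues map residue name to element (PDB convention);
    otherwise the first alphabetic character of the atom name is used, with
    two-letter ion names recognised inside hetero residues.
    """
    res = residue_name.strip().upper()
    if res in ION_RESIDUE_ELEMENTS:
        return ION_RESIDUE_ELEMENTS[res]
    name = atom_name.strip().upper()
    if not name:
        raise ParseError(f"cannot infer element for blank atom name in {residue_name}")
    m = re.search(r"[A-Z]", name)
    if m is None:
        raise ParseError(f"cannot infer element from atom name {atom_name!r}")
    return m.group(0)


def _apply_alt_loc_policy(atoms: list[Atom]) -> tuple[list[Atom], float]:
    """Keep one alternate location per atom site: highest occupancy, then
    alphabetically first alt id.  Returns (atoms, dropped occupancy sum)."""
    groups: dict[tuple, list[Atom]] = {}
    order: list[tuple] = []
    for a in atoms:
        key = (a.chain_id, a.residue_seq, a.icode, a.residue_name, a.name)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(a)
    kept: list[Atom] = []
    dropped = 0.0
    for key in order:
        grp = groups[key]
        if len(grp) == 1:
            kept.append(replace(grp[0], alt_loc=""))
            continue
        best = sorted(grp, key=lambda a: (-a.occupancy, a.alt_loc))[0]
        dropped += sum(a.occupancy for a in grp if a is not best)
        kept.append(replace(best, alt_loc=""))
    return kept, dropped


# ---------------------------------------------------------------------------
# Reading


def _cell_from_gemmi(cell: "gemmi.UnitCell") -> UnitCell | None:
    # gemmi reports a 1x1x1 placeholder cell when CRYST1 is missing.
    if cell.a <= 1.0 and cell.b <= 1.0 and cell.c <= 1.0:
        return None
    return UnitCell(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)


def _ops_from_gemmi(st: "gemmi.Structure") -> tuple[list[SymOp], str]:
    hm = st.spacegroup_hm or ""
    sg = gemmi.find_spacegroup_by_name(hm) if hm else None
    if sg is not None:
        return [SymOp.from_triplet(op.triplet()) for op in sg.operations()], sg.hm
    if hm in SPACE_GROUP_OPS:
        return [SymOp.from_triplet(t) for t in SPACE_GROUP_OPS[hm]], hm
    return [], hm


def read_structure(path, fmt: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Hydrogens are dropped and a single alternate location is retained per
    atom (highest occupancy, ties broken alphabetically), matching the
    one-position-per-atom bookkeeping used by the ion censuses.
    """
    path = str(path)
    fmt = fmt.lower()
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(path)
        elif fmt in ("mmcif", "cif"):
            st = gemmi.read_structure(path, format=gemmi.CoorFormat.Mmcif)
        elif fmt == "auto":
            st = gemmi.read_structure(path, format=gemmi.CoorFormat.Detect)
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc

    st.setup_entities()
    if len(st) == 0:
        raise ParseError(f"{path}: no models found")
    model = st[0]

    atoms: list[Atom] = []
    serial = 0
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            for at in res:
                if at.is_hydrogen():
                    continue
                serial += 1
                if at.element.name and at.element.name != "X":
                    elem = at.element.name.upper()
                else:
                    elem = infer_element(at.name, res.name)
                    warnings.warn(
                        f"element inferred as {elem} for atom {at.name} in {res.name}",
                        stacklevel=2,
                    )
                atoms.append(
                    Atom(
                        serial=serial,
                        name=at.name,
                        element=elem,
                        alt_loc=at.altloc or "",
                        occupancy=min(max(at.occ, 0.0), 1.0),
                        b_iso=at.b_iso,
                        residue_name=res.name,
                        residue_seq=res.seqid.num,
                        icode=(res.seqid.icode or "").strip(),
                        chain_id=chain.name,
                        is_hetero=het and res.name not in WATER_NAMES,
                        position=(at.pos.x, at.pos.y, at.pos.z),
                    )
                )

    atoms, _dropped = _apply_alt_loc_policy(atoms)
    # renumber serially after filtering so downstream sort keys are stable
    atoms = [replace(a, serial=i + 1) for i, a in enumerate(atoms)]

    ops, sg_name = _ops_from_gemmi(st)
    return StructureModel(
        atoms=atoms,
        unit_cell=_cell_from_gemmi(st.cell),
        sym_ops=ops,
        name=st.name or path,
        space_group=sg_name,
    )


# ---------------------------------------------------------------------------
# Writing


def _to_gemmi(model: StructureModel) -> "gemmi.Structure":
    st = gemmi.Structure()
    st.name = model.name or "model"
    if model.unit_cell is not None:
        c = model.unit_cell
        st.cell = gemmi.UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
    if model.space_group:
        st.spacegroup_hm = model.space_group
    elif model.sym_ops:
        st.spacegroup_hm = "P 1"
    gm = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    res_handle: dict[tuple, gemmi.Residue] = {}
    for a in model.atoms:
        if a.chain_id not in chains:
            chains[a.chain_id] = gemmi.Chain(a.chain_id)
        ch = chains[a.chain_id]
        rkey = a.residue_key
        if rkey not in res_handle:
            r = gemmi.Residue()
            r.name = a.residue_name
            r.seqid = gemmi.SeqId(a.residue_seq, a.icode or " ")
            r.het_flag = "H" if (a.is_hetero or a.is_water) else "A"
            ch.add_residue(r)
            res_handle[rkey] = ch[len(ch) - 1]
        r = res_handle[rkey]
        ga = gemmi.Atom()
        ga.name = a.name
        ga.element = gemmi.Element(a.element.capitalize())
        ga.altloc = a.alt_loc or "\0"
        ga.occ = a.occupancy
        ga.b_iso = a.b_iso
        ga.pos = gemmi.Position(*a.position)
        r.add_atom(ga)
    for ch in chains.values():
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_structure(model: StructureModel, path, fmt: str = "auto") -> None:
    """Write a model as PDB or mmCIF (format inferred from suffix if auto)."""
    path = str(path)
    fmt = fmt.lower()
    if fmt == "auto":
        fmt = "mmcif" if path.endswith((".cif", ".mmcif")) else "pdb"
    if fmt == "pdb":
        for cid in {a.chain_id for a in model.atoms}:
            if len(cid) > 1:
                raise ValueError(
                    f"chain id {cid!r} not encodable in PDB format; write mmCIF instead"
                )
        if model.unit_cell is None:
            warnings.warn("model has no unit cell; PDB written without CRYST1", stacklevel=2)
    st = _to_gemmi(model)
    if fmt == "pdb":
        st.write_pdb(path)
    elif fmt in ("mmcif", "cif"):
        st.make_mmcif_document().write_file(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Selection grammar
#
# expression := term ("and" term)*
# term       := ["not"] primitive
# primitive  := water | polymer | hetero | hydrogen | ion
#             | chain <id> | resn <name> | name <atom-name>
#             | element <symbol> | resi <n>[-<m>]

_KEYWORDS = {"water", "polymer", "hetero", "hydrogen", "ion"}
_BINARY = {"chain", "resn", "name", "element", "resi"}


def _compile_primitive(tokens: list[str], i: int):
    tok = tokens[i].lower()
    if tok in _KEYWORDS:
        if tok == "water":
            return (lambda a: a.is_water), i + 1
        if tok == "polymer":
            return (lambda a: a.is_polymer), i + 1
        if tok == "hetero":
            return (lambda a: a.is_hetero), i + 1
        if tok == "hydrogen":
            return (lambda a: a.element in ("H", "D")), i + 1
        if tok == "ion":
            return (lambda a: a.residue_name in ION_RESIDUE_ELEMENTS), i + 1
    if tok in _BINARY:
        if i + 1 >= len(tokens):
            raise SelectionError(f"'{tok}' requires an argument")
        arg = tokens[i + 1]
        if tok == "chain":
            return (lambda a, v=arg: a.chain_id == v), i + 2
        if tok == "resn":
            return (lambda a, v=arg.upper(): a.residue_name == v), i + 2
        if tok == "name":
            return (lambda a, v=arg.upper(): a.name.upper() == v), i + 2
        if tok == "element":
            return (lambda a, v=arg.upper(): a.element == v), i + 2
        if tok == "resi":
            m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", arg)
            if not m:
                raise SelectionError(f"bad residue range {arg!r}")
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) else lo
            return (lambda a, lo=lo, hi=hi: lo <= a.residue_seq <= hi), i + 2
    raise SelectionError(f"unknown selection token {tokens[i]!r}")


def _compile(query: str):
    tokens = query.split()
    if not tokens:
        raise SelectionError("empty selection")
    preds = []
    i = 0
    while i < len(tokens):
        if i > 0:
            if tokens[i].lower() != "and":
                raise SelectionError(f"expected 'and' before {tokens[i]!r}")
            i += 1
            if i >= len(tokens):
                raise SelectionError("dangling 'and'")
        negate = False
        if tokens[i].lower() == "not":
            negate = True
            i += 1
            if i >= len(tokens):
                raise SelectionError("dangling 'not'")
        pred, i = _compile_primitive(tokens, i)
        preds.append((lambda a, p=pred: not p(a)) if negate else pred)
    return lambda a: all(p(a) for p in preds)


def select(model: StructureModel, query: str) -> list[Atom]:
    """Select atoms with a small conjunctive grammar.

    Primitives: ``water``, ``polymer``, ``hetero``, ``hydrogen``, ``ion``,
    ``chain <id>``, ``resn <name>``, ``name <atom>``, ``element <sym>``,
    ``resi <n>`` or ``resi <n>-<m>``; combine with ``and`` and negate with
    ``not``.  Atom order is preserved; an empty result is legal.
    """
    pred = _compile(query)
    return [a for a in model.atoms if pred(a)]
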