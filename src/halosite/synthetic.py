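"""Ground-truth structure and data generators for end-to-end testing.

Every analysis stage in this package is validated against synthetic inputs
whose answers are known by construction: ideal helices with planted ion
coordination shells at species-typical distances, unit cells engineered to
produce (or exclude) crystal contacts, water sets with planted planar
pentagons, and noisy kinetic/melt curves from known parameters.  All
generators are deterministic given (parameters, seed); each returns or
records a :class:`GroundTruth` manifest that downstream recovery tests
compare against exactly.

Planted ligand distances are drawn from narrow windows well inside the
detection cutoffs (K-O 2.70-2.90 A against a 3.5 A cutoff; Mg-O 2.05-2.15 A
against 2.6 A) so borderline-cutoff flakiness cannot occur.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from halosite.structio import Atom, StructureModel, SymOp, UnitCell
from halosite.surface import sphere_points
from halosite.conformation import rotation_matrix

# ideal peptide geometry (Angstrom, degrees)
_B_N_CA = 1.458
_B_CA_C = 1.525
_B_C_N = 1.329
_B_C_O = 1.231
_A_N_CA_C = 111.2
_A_CA_C_N = 116.2
_A_C_N_CA = 121.7
_A_CA_C_O = 120.5
PHI_HELIX = -57.0
PSI_HELIX = -47.0
OMEGA = 180.0

SUPPORTED_RESIDUES = {"GLY", "ALA", "SER", "ASP", "GLU", "LYS", "THR", "MET", "PHE"}

_ONE_TO_THREE = {
    "G": "GLY", "A": "ALA", "S": "SER", "D": "ASP", "E": "GLU",
    "K": "LYS", "T": "THR", "M": "MET", "F": "PHE",
}


@dataclass
class PlantedSite:
    species: str
    position: tuple[float, float, float]
    ligand_classes: list[str]
    ligand_distances: list[float]
    intended_context: str
    ion_serial: int | None = None

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "position": list(self.position),
            "ligand_classes": sorted(self.ligand_classes),
            "ligand_distances": [round(d, 3) for d in self.ligand_distances],
            "intended_context": self.intended_context,
        }


@dataclass
class GroundTruth:
    """Manifest of everything planted into a synthetic fixture."""

    seed: int = 0
    sites: list[PlantedSite] = field(default_factory=list)
    bridges: list[dict] = field(default_factory=list)
    rings: int = 0
    rotation_deg: float | None = None
    km: float | None = None
    vmax: float | None = None
    tm: float | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "sites": [s.to_dict() for s in self.sites],
                "bridges": self.bridges,
                "rings": self.rings,
                "rotation_deg": self.rotation_deg,
                "km": self.km,
                "vmax": self.vmax,
                "tm": self.tm,
            },
            indent=2,
            sort_keys=True,
        )


# ---------------------------------------------------------------------------
# internal-coordinate chain building


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: position of atom d given a-b-c, |cd|, angle(b,c,d) and
    torsion(a,b,c,d)."""
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def gen_helix(n_res: int, sequence: str | None = None, chain_id: str = "A",
              start_seq: int = 1) -> StructureModel:
    """Ideal alpha-helix (phi -57, psi -47) with simple side chains.

    Supported residues: Gly, Ala, Ser, Asp, Glu, Lys, Thr, Met, Phe (one-letter
    codes in ``sequence``; defaults to poly-Ala).  Backbone geometry uses
    standard bond lengths/angles; side chains are built with idealised
    tetrahedral geometry, adequate for surface and coordination chemistry
    tests (no clash below 2.0 A).
    """
    if n_res < 4:
        raise ValueError("helix needs at least 4 residues")
    sequence = sequence or ("A" * n_res)
    if len(sequence) != n_res:
        raise ValueError("sequence length must equal n_res")
    res_names = []
    for ch in sequence.upper():
        if ch not in _ONE_TO_THREE:
            raise ValueError(f"unsupported residue code {ch!r}")
        res_names.append(_ONE_TO_THREE[ch])

    # seed coordinates for residue 1
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([_B_N_CA, 0.0, 0.0])
    C = _place_atom(np.array([0.0, 1.0, 0.0]), N, CA, _B_CA_C, _A_N_CA_C, 0.0)

    atoms: list[Atom] = []
    serial = [0]

    def add(name, elem, pos, resname, seq):
        serial[0] += 1
        atoms.append(
            Atom(
                serial=serial[0], name=name, element=elem, alt_loc="",
                occupancy=1.0, b_iso=15.0, residue_name=resname,
                residue_seq=seq, icode="", chain_id=chain_id,
                is_hetero=False, position=tuple(np.asarray(pos, dtype=float)),
            )
        )

    backbone = []  # (N, CA, C) per residue
    for i in range(n_res):
        if i == 0:
            n_i, ca_i, c_i = N, CA, C
        else:
            n_prev, ca_prev, c_prev = backbone[-1]
            n_i = _place_atom(n_prev, ca_prev, c_prev, _B_C_N, _A_CA_C_N, PSI_HELIX)
            ca_i = _place_atom(ca_prev, c_prev, n_i, _B_N_CA, _A_C_N_CA, OMEGA)
            c_i = _place_atom(c_prev, n_i, ca_i, _B_CA_C, _A_N_CA_C, PHI_HELIX)
        backbone.append((n_i, ca_i, c_i))

    for i, (n_i, ca_i, c_i) in enumerate(backbone):
        seq = start_seq + i
        rn = res_names[i]
        add("N", "N", n_i, rn, seq)
        add("CA", "C", ca_i, rn, seq)
        add("C", "C", c_i, rn, seq)
        # carbonyl O: in the peptide plane, trans to the next N
        if i + 1 < n_res:
            n_next = backbone[i + 1][0]
            o_i = _place_atom(n_next, ca_i, c_i, _B_C_O, _A_CA_C_O, 180.0)
        else:
            o_i = _place_atom(n_i, ca_i, c_i, _B_C_O, _A_CA_C_O, PSI_HELIX + 180.0)
        add("O", "O", o_i, rn, seq)
        if rn != "GLY":
            cb = _place_atom(n_i, c_i, ca_i, 1.53, 110.5, 122.5)
            add("CB", "C", cb, rn, seq)
            if rn == "SER":
                add("OG", "O", _place_atom(n_i, ca_i, cb, 1.42, 110.0, 180.0), rn, seq)
            elif rn == "THR":
                add("OG1", "O", _place_atom(n_i, ca_i, cb, 1.42, 110.0, 180.0), rn, seq)
                add("CG2", "C", _place_atom(n_i, ca_i, cb, 1.52, 110.0, 60.0), rn, seq)
            elif rn == "ASP":
                cg = _place_atom(n_i, ca_i, cb, 1.52, 112.6, 180.0)
                add("CG", "C", cg, rn, seq)
                add("OD1", "O", _place_atom(ca_i, cb, cg, 1.25, 118.4, 0.0), rn, seq)
                add("OD2", "O", _place_atom(ca_i, cb, cg, 1.25, 118.4, 180.0), rn, seq)
            elif rn == "GLU":
                cg = _place_atom(n_i, ca_i, cb, 1.52, 114.1, 180.0)
                cd = _place_atom(ca_i, cb, cg, 1.52, 112.6, 180.0)
                add("CG", "C", cg, rn, seq)
                add("CD", "C", cd, rn, seq)
                add("OE1", "O", _place_atom(cb, cg, cd, 1.25, 118.4, 0.0), rn, seq)
                add("OE2", "O", _place_atom(cb, cg, cd, 1.25, 118.4, 180.0), rn, seq)
            elif rn == "LYS":
                cg = _place_atom(n_i, ca_i, cb, 1.52, 114.1, 180.0)
                cd = _place_atom(ca_i, cb, cg, 1.52, 111.3, 180.0)
                ce = _place_atom(cb, cg, cd, 1.52, 111.3, 180.0)
                nz = _place_atom(cg, cd, ce, 1.49, 111.9, 180.0)
                for nm, el, p in (("CG", "C", cg), ("CD", "C", cd), ("CE", "C", ce), ("NZ", "N", nz)):
                    add(nm, el, p, rn, seq)
            elif rn == "MET":
                cg = _place_atom(n_i, ca_i, cb, 1.52, 114.1, 180.0)
                sd = _place_atom(ca_i, cb, cg, 1.80, 112.7, 180.0)
                ce = _place_atom(cb, cg, sd, 1.79, 100.8, 180.0)
                for nm, el, p in (("CG", "C", cg), ("SD", "S", sd), ("CE", "C", ce)):
                    add(nm, el, p, rn, seq)
            elif rn == "PHE":
                cg = _place_atom(n_i, ca_i, cb, 1.50, 113.8, 180.0)
                add("CG", "C", cg, rn, seq)
                # flat ring, idealised
                cd1 = _place_atom(ca_i, cb, cg, 1.39, 120.0, 90.0)
                cd2 = _place_atom(ca_i, cb, cg, 1.39, 120.0, -90.0)
                ce1 = _place_atom(cb, cg, cd1, 1.39, 120.0, 180.0)
                ce2 = _place_atom(cb, cg, cd2, 1.39, 120.0, 180.0)
                cz = _place_atom(cg, cd1, ce1, 1.39, 120.0, 0.0)
                for nm, p in (("CD1", cd1), ("CD2", cd2), ("CE1", ce1), ("CE2", ce2), ("CZ", cz)):
                    add(nm, "C", p, rn, seq)
    return StructureModel(atoms=atoms, name=f"helix{n_res}")


# ---------------------------------------------------------------------------
# planted ion sites


def _next_serial(model: StructureModel) -> int:
    return max((a.serial for a in model.atoms), default=0) + 1


def _next_seq(model: StructureModel, chain: str) -> int:
    seqs = [a.residue_seq for a in model.atoms if a.chain_id == chain]
    return max(seqs, default=0) + 1


def _carbonyl_fragment(ion: np.ndarray, direction: np.ndarray, dist: float,
                       serial: int, seq: int, chain: str) -> tuple[list[Atom], np.ndarray]:
    """A Gly peptide unit whose carbonyl O points at the ion from ``dist`` A
    along ``direction`` (unit vector, ion -> O)."""
    u = direction / np.linalg.norm(direction)
    # orthonormal frame around u
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    v = np.cross(u, ref)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    o = ion + dist * u
    c = o + _B_C_O * u  # C=O points back at the ion
    ca = c + 1.525 * (np.cos(np.radians(60)) * u + np.sin(np.radians(60)) * v)
    n = c + 1.329 * (np.cos(np.radians(60)) * u - np.sin(np.radians(60)) * v)
    mk = lambda s, nm, el, p: Atom(
        serial=s, name=nm, element=el, alt_loc="", occupancy=1.0, b_iso=20.0,
        residue_name="GLY", residue_seq=seq, icode="", chain_id=chain,
        is_hetero=False, position=tuple(p),
    )
    return [mk(serial, "N", "N", n), mk(serial + 1, "CA", "C", ca),
            mk(serial + 2, "C", "C", c), mk(serial + 3, "O", "O", o)], o


def _water(pos: np.ndarray, serial: int, seq: int, chain: str = "W") -> Atom:
    return Atom(
        serial=serial, name="O", element="O", alt_loc="", occupancy=1.0,
        b_iso=25.0, residue_name="HOH", residue_seq=seq, icode="",
        chain_id=chain, is_hetero=False, position=tuple(pos),
    )


def _ion(species: str, pos: np.ndarray, serial: int, seq: int, chain: str = "I") -> Atom:
    return Atom(
        serial=serial, name=species, element=species, alt_loc="", occupancy=1.0,
        b_iso=18.0, residue_name=species, residue_seq=seq, icode="",
        chain_id=chain, is_hetero=True, position=tuple(pos),
    )


def plant_site(
    model: StructureModel,
    kind: str,
    cn: int | None = None,
    seed: int = 0,
    position: np.ndarray | None = None,
    max_tries: int = 50,
) -> tuple[StructureModel, GroundTruth]:
    """Plant one ion site with a fully known coordination shell.

    Kinds: ``K_carbonyl_cluster`` (default CN 7: 4 main-chain carbonyls from
    oriented Gly peptide units plus waters), ``Mg_hexaaqua`` (octahedral
    Mg(H2O)6), ``Cl_backbone`` (chloride near peptide NH plus waters).  The
    ion is placed clear of the host model so no unintended atom enters the
    detection cutoff; shell geometry is recorded in the returned manifest.
    """
    rng = np.random.default_rng(seed)
    if kind == "K_carbonyl_cluster":
        species, cutoff = "K", 3.5
        cn = 7 if cn is None else cn
        n_carbonyl = min(4, cn)
        dist_window = (2.70, 2.90)
    elif kind == "Mg_hexaaqua":
        species, cutoff = "MG", 2.6
        cn = 6 if cn is None else cn
        n_carbonyl = 0
        dist_window = (2.05, 2.15)
    elif kind == "Cl_backbone":
        species, cutoff = "CL", 3.8
        cn = 4 if cn is None else cn
        n_carbonyl = 0
        dist_window = (3.10, 3.25)
    else:
        raise ValueError(f"unknown site kind {kind!r}")

    coords = model.coords
    centroid = coords.mean(axis=0) if coords.size else np.zeros(3)
    extent = (
        float(np.linalg.norm(coords - centroid, axis=1).max()) if coords.size else 0.0
    )
    host_chain = model.chains()[0] if model.atoms else "A"

    for attempt in range(max_tries):
        if position is not None and attempt == 0:
            pos = np.asarray(position, dtype=float)
        else:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pos = centroid + direction * (extent + 8.0 + 2.0 * attempt)
        if coords.size:
            dmin = float(np.linalg.norm(coords - pos, axis=1).min())
            if dmin <= cutoff + 1.5:
                continue
        break
    else:
        raise RuntimeError("could not place ion clear of the host model")

    if kind == "Mg_hexaaqua" and cn == 6:
        dirs = np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
            dtype=float,
        )
    else:
        dirs = sphere_points(cn)
    serial = _next_serial(model)
    seq = _next_seq(model, host_chain)
    wseq = _next_seq(model, "W")
    new_atoms: list[Atom] = []
    classes: list[str] = []
    dists: list[float] = []

    for k in range(cn):
        d = float(rng.uniform(*dist_window))
        if k < n_carbonyl:
            frag, _o = _carbonyl_fragment(pos, dirs[k], d, serial, seq, host_chain)
            new_atoms.extend(frag)
            serial += len(frag)
            seq += 1
            classes.append("main_chain_carbonyl")
        elif kind == "Cl_backbone" and k < cn - 1:
            # reuse the peptide unit but offer the amide N to the halide
            frag, _ = _carbonyl_fragment(pos, dirs[k], d + 1.0, serial, seq, host_chain)
            # move the whole fragment so its N sits at distance d from the ion
            n_atom = frag[0]
            shift = (pos + d * dirs[k] / np.linalg.norm(dirs[k])) - n_atom.xyz
            frag = [replace(a, position=tuple(a.xyz + shift)) for a in frag]
            new_atoms.extend(frag)
            serial += len(frag)
            seq += 1
            classes.append("other")  # peptide N: not an oxygen ligand class
        else:
            new_atoms.append(_water(pos + d * dirs[k], serial, wseq))
            serial += 1
            wseq += 1
            classes.append("water_O")
        dists.append(d)

    ion_atom = _ion(species, pos, serial, _next_seq(model, "I"))
    new_atoms.append(ion_atom)
    out = model.with_atoms(list(model.atoms) + new_atoms)
    truth = GroundTruth(
        seed=seed,
        sites=[
            PlantedSite(
                species=species,
                position=tuple(pos),
                ligand_classes=classes,
                ligand_distances=dists,
                intended_context="INTRA_SUBUNIT",
                ion_serial=ion_atom.serial,
            )
        ],
    )
    return out, truth


def plant_bridged_pair(
    model: StructureModel,
    separation: float = 3.9,
    seed: int = 0,
) -> tuple[StructureModel, GroundTruth]:
    """Two K+ ions ``separation`` A apart sharing two main-chain carbonyls and
    one water as bridging ligands, each completed by two private waters."""
    rng = np.random.default_rng(seed)
    coords = model.coords
    centroid = coords.mean(axis=0) if coords.size else np.zeros(3)
    extent = float(np.linalg.norm(coords - centroid, axis=1).max()) if coords.size else 0.0
    axis = np.array([1.0, 0.0, 0.0])
    mid = centroid + np.array([0.0, 1.0, 0.0]) * (extent + 12.0)
    p1 = mid - axis * separation / 2.0
    p2 = mid + axis * separation / 2.0

    host_chain = model.chains()[0] if model.atoms else "A"
    serial = _next_serial(model)
    seq = _next_seq(model, host_chain)
    wseq = _next_seq(model, "W")
    new_atoms: list[Atom] = []

    # bridging ligands sit on the perpendicular bisector plane of the ion pair
    d_shared = float(rng.uniform(2.75, 2.85))
    ring_r = float(np.sqrt(d_shared**2 - (separation / 2.0) ** 2))
    for ang, is_water in ((0.0, False), (120.0, False), (240.0, True)):
        th = np.radians(ang)
        offset = ring_r * (np.cos(th) * np.array([0, 1, 0]) + np.sin(th) * np.array([0, 0, 1]))
        lig_pos = mid + offset
        if is_water:
            new_atoms.append(_water(lig_pos, serial, wseq))
            serial += 1
            wseq += 1
        else:
            u = offset / np.linalg.norm(offset)
            frag, _ = _carbonyl_fragment(mid, u, ring_r, serial, seq, host_chain)
            new_atoms.extend(frag)
            serial += len(frag)
            seq += 1

    # two private waters per ion, pointing away from the partner
    for p, sign in ((p1, -1.0), (p2, 1.0)):
        for dz in (0.8, -0.8):
            d = float(rng.uniform(2.75, 2.85))
            u = sign * axis + np.array([0.0, -0.9, dz])
            u /= np.linalg.norm(u)
            new_atoms.append(_water(p + d * u, serial, wseq))
            serial += 1
            wseq += 1

    iseq = _next_seq(model, "I")
    ion1 = _ion("K", p1, serial, iseq)
    ion2 = _ion("K", p2, serial + 1, iseq + 1)
    new_atoms += [ion1, ion2]
    out = model.with_atoms(list(model.atoms) + new_atoms)
    truth = GroundTruth(
        seed=seed,
        sites=[
            PlantedSite("K", tuple(p1), ["main_chain_carbonyl"] * 2 + ["water_O"] * 3,
                        [], "INTRA_SUBUNIT", ion1.serial),
            PlantedSite("K", tuple(p2), ["main_chain_carbonyl"] * 2 + ["water_O"] * 3,
                        [], "INTRA_SUBUNIT", ion2.serial),
        ],
        bridges=[{"ion_serials": [ion1.serial, ion2.serial],
                  "separation": separation, "n_shared": 3}],
    )
    return out, truth


# ---------------------------------------------------------------------------
# lattices


def gen_lattice(
    model: StructureModel,
    cell: UnitCell | None = None,
    group: str = "P1",
    clearance: float = 15.0,
) -> StructureModel:
    """Attach a unit cell and symmetry operators to a model.

    With ``cell=None`` a cell is built from the model's bounding box plus
    ``clearance`` on each axis, so the nearest inter-copy approach along the
    tightest axis is close to ``clearance``.  ``group`` is P1 or P21 (screw
    axis along b).
    """
    coords = model.coords
    if coords.size == 0:
        raise ValueError("empty model")
    lo = coords.min(axis=0)
    span = coords.max(axis=0) - lo
    if cell is None:
        a, b, c = (float(s + clearance) for s in span)
        # iterate the a-axis so the nearest +a-translated copy approach lands
        # near the requested clearance
        for _ in range(25):
            shifted = coords + np.array([a, 0.0, 0.0])
            dmin = _min_cross_distance(coords, shifted)
            err = dmin - (clearance + 0.5)
            if abs(err) <= 0.5:
                break
            a = max(a - err, span[0] + 1.0)
        cell = UnitCell(a, b, c, 90.0, 90.0, 90.0)
    if group.upper() == "P1":
        ops = [SymOp.from_triplet("x,y,z")]
        sg = "P 1"
    elif group.upper() in ("P21", "P2(1)", "P 1 21 1"):
        ops = [SymOp.from_triplet("x,y,z"), SymOp.from_triplet("-x,y+1/2,-z")]
        sg = "P 1 21 1"
    else:
        raise ValueError(f"unsupported space group {group!r}")
    out = model.with_atoms(list(model.atoms))
    out.unit_cell = cell
    out.sym_ops = ops
    out.space_group = sg
    return out


def _min_cross_distance(A: np.ndarray, B: np.ndarray) -> float:
    from scipy.spatial import cKDTree

    d, _ = cKDTree(A).query(B, k=1)
    return float(np.min(d))


def plant_crystal_contact_site(
    model: StructureModel,
    seed: int = 0,
    marker_distance: float = 3.8,
) -> tuple[StructureModel, GroundTruth]:
    """Plant a K+ carbonyl site plus a marker atom whose +a lattice copy
    falls within the crystal-contact radius of the ion.

    Must be followed by :func:`gen_lattice`; the manifest's intended context
    is CRYSTAL_CONTACT once the lattice is attached.  The marker water is
    placed on the far side of the model so that after translation by the cell
    a-axis it lands ``marker_distance`` A from the ion (outside the K-O
    cutoff, inside the 4.0 A context radius).
    """
    coords0 = model.coords
    centroid = coords0.mean(axis=0) if coords0.size else np.zeros(3)
    extent = float(np.linalg.norm(coords0 - centroid, axis=1).max()) if coords0.size else 0.0
    ion_target = centroid + np.array([extent + 10.0, 0.0, 0.0])
    planted, truth = plant_site(model, "K_carbonyl_cluster", cn=7, seed=seed,
                                position=ion_target)
    site = truth.sites[0]
    ion_pos = np.asarray(site.position)
    coords = planted.coords
    lo = coords.min(axis=0)

    # Fix the cell here (rather than via gen_lattice) so that the +a lattice
    # copy of the marker lands exactly marker_distance from the ion.  The
    # marker sits outside the bounding box on the low-x side, so it cannot
    # clash with anything, and only its copy approaches the planted site.
    marker = np.array([lo[0] - 2.5, ion_pos[1], ion_pos[2]])
    a_len = float(ion_pos[0] + marker_distance - marker[0])
    span = np.maximum(coords.max(axis=0), marker) - np.minimum(lo, marker)
    b_len = float(span[1] + 20.0)
    c_len = float(span[2] + 20.0)

    serial = _next_serial(planted)
    matoms = list(planted.atoms) + [_water(marker, serial, _next_seq(planted, "W"))]
    out = planted.with_atoms(matoms)
    out.unit_cell = UnitCell(a_len, b_len, c_len, 90.0, 90.0, 90.0)
    out.sym_ops = [SymOp.from_triplet("x,y,z")]
    out.space_group = "P 1"
    site.intended_context = "CRYSTAL_CONTACT"
    return out, truth


# ---------------------------------------------------------------------------
# waters, kinetics, melt curves


def gen_pentagon_waters(
    edge: float = 2.8,
    jitter: float = 0.05,
    seed: int = 0,
    center: np.ndarray | None = None,
    chain: str = "W",
    start_seq: int = 1,
) -> list[Atom]:
    """Five waters on a regular planar pentagon (edge length ``edge``), with
    optional Gaussian coordinate jitter."""
    rng = np.random.default_rng(seed)
    R = edge / (2.0 * np.sin(np.pi / 5.0))
    center = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    atoms = []
    for k in range(5):
        th = 2.0 * np.pi * k / 5.0
        p = center + np.array([R * np.cos(th), R * np.sin(th), 0.0])
        p = p + rng.normal(scale=jitter, size=3)
        atoms.append(_water(p, k + 1, start_seq + k, chain))
    return atoms


def gen_mm_data(
    km: float,
    vmax: float,
    noise_frac: float = 0.0,
    S_list=None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Michaelis-Menten (S, v) data with multiplicative Gaussian noise."""
    rng = np.random.default_rng(seed)
    S = np.asarray(S_list if S_list is not None else [0.25, 0.5, 1.0, 2.0, 4.0, 8.0], dtype=float)
    v = vmax * S / (km + S)
    if noise_frac > 0:
        v = v * (1.0 + rng.normal(scale=noise_frac, size=S.shape))
        v = np.clip(v, 0.0, None)
    return S, v


def gen_melt(
    tm: float = 55.0,
    slope: float = 1.5,
    noise: float = 0.0,
    t_range: tuple[float, float] = (25.0, 98.0),
    n: int = 147,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Boltzmann-sigmoid melt curve (T, F) with additive Gaussian noise."""
    rng = np.random.default_rng(seed)
    T = np.linspace(t_range[0], t_range[1], n)
    F = 1.0 / (1.0 + np.exp((tm - T) / slope))
    if noise > 0:
        F = F + rng.normal(scale=noise, size=T.shape)
    return T, F


# ---------------------------------------------------------------------------
# domain-rotation fixtures


def rotate_domain(
    model: StructureModel,
    residues: set[int],
    axis_point: np.ndarray,
    axis: np.ndarray,
    angle_deg: float,
) -> StructureModel:
    """Rigidly rotate the atoms of ``residues`` about an axis; everything else
    is left in place.  Produces a two-conformer pair with a known hinge
    rotation."""
    R = rotation_matrix(axis, angle_deg)
    p0 = np.asarray(axis_point, dtype=float)
    new_atoms = []
    for a in model.atoms:
        if a.residue_seq in residues:
            pos = R @ (a.xyz - p0) + p0
            new_atoms.append(replace(a, position=tuple(pos)))
        else:
            new_atoms.append(a)
    return model.with_atoms(new_atoms)


# ---------------------------------------------------------------------------
# composite fixture: everything at once


def build_composite_crystal(seed: int = 0) -> tuple[StructureModel, GroundTruth]:
    """A toy crystal exercising the full pipeline: a helix host with three
    intra-subunit K+ carbonyl-cluster sites, two octahedral Mg(H2O)6 sites,
    one planted planar water pentagon, a P1 cell, and one K+ site engineered
    to sit at a crystal contact."""
    model = gen_helix(20, "ADSEKAGTMASDEKAGTSAD")
    truth = GroundTruth(seed=seed)
    dirs = [
        np.array([0.0, 1.0, 0.0]),
        np.array([0.0, -1.0, 0.0]),
        np.array([0.0, 0.0, -1.0]),
        np.array([-1.0, 1.0, 0.0]) / np.sqrt(2),
        np.array([-1.0, -1.0, 0.0]) / np.sqrt(2),
    ]

    def anchor(direction):
        coords = model.coords
        c = coords.mean(axis=0)
        e = float(np.linalg.norm(coords - c, axis=1).max())
        return c + direction * (e + 10.0)

    for i in range(3):
        model, t = plant_site(model, "K_carbonyl_cluster", cn=7,
                              seed=seed * 101 + i, position=anchor(dirs[i]))
        truth.sites.extend(t.sites)
    for i in range(2):
        model, t = plant_site(model, "Mg_hexaaqua", seed=seed * 211 + i,
                              position=anchor(dirs[3 + i]))
        truth.sites.extend(t.sites)
    # pentagon well away from everything
    coords = model.coords
    center = coords.mean(axis=0)
    far = center + np.array([0.0, 0.0, np.linalg.norm(coords - center, axis=1).max() + 25.0])
    pentagon = gen_pentagon_waters(2.8, 0.03, seed=seed, center=far,
                                   start_seq=_next_seq(model, "W"))
    pentagon = [replace(w, serial=_next_serial(model) + i) for i, w in enumerate(pentagon)]
    model = model.with_atoms(list(model.atoms) + pentagon)
    truth.rings = 1
    # crystal-contact site + cell
    model, t = plant_crystal_contact_site(model, seed=seed * 307 + 7)
    truth.sites.extend(t.sites)
    return model, truth
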