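"""Ion coordination-shell detection, ligand chemistry, censuses and context.

The scientific question this module serves: when a halophilic protein is
crystallised in molar KCl, what does it actually use to hold its K+ ions?
The analysis resolves each bound monatomic ion's first coordination shell,
classifies every oxygen ligand chemically (main-chain carbonyl, carboxylate,
hydroxyl, amide, water, hetero-compound), tallies per-structure censuses,
finds ion pairs bridged by shared ligands, clusters crystallographically
independent copies of the same site, and labels each site's packing context
(within one subunit, across an assembly interface, or a crystal-lattice
contact that exists only in the crystal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from halosite.structio import (
    AMINO_ACIDS,
    ION_RESIDUE_ELEMENTS,
    Atom,
    StructureModel,
    WATER_NAMES,
)
from halosite.xtal import PlacedCopy, expand_symmetry
from halosite.conformation import superpose


class LigandClass(Enum):
    MAIN_CHAIN_CARBONYL = "main_chain_carbonyl"
    CARBOXYLATE_O = "carboxylate_O"
    HYDROXYL_O = "hydroxyl_O"
    AMIDE_O = "amide_O"
    WATER_O = "water_O"
    HETERO_O = "hetero_O"
    OTHER = "other"


PROTEIN_LIGAND_CLASSES = frozenset(
    {
        LigandClass.MAIN_CHAIN_CARBONYL,
        LigandClass.CARBOXYLATE_O,
        LigandClass.HYDROXYL_O,
        LigandClass.AMIDE_O,
    }
)

# Side-chain oxygen chemistry by (residue, atom name).
_SIDECHAIN_O = {
    ("ASP", "OD1"): LigandClass.CARBOXYLATE_O,
    ("ASP", "OD2"): LigandClass.CARBOXYLATE_O,
    ("GLU", "OE1"): LigandClass.CARBOXYLATE_O,
    ("GLU", "OE2"): LigandClass.CARBOXYLATE_O,
    ("SER", "OG"): LigandClass.HYDROXYL_O,
    ("THR", "OG1"): LigandClass.HYDROXYL_O,
    ("TYR", "OH"): LigandClass.HYDROXYL_O,
    ("ASN", "OD1"): LigandClass.AMIDE_O,
    ("GLN", "OE1"): LigandClass.AMIDE_O,
}

# First-shell distance cutoffs, ion centre to coordinating atom (Angstrom).
DEFAULT_CUTOFFS = {"K": 3.5, "NA": 3.1, "MG": 2.6, "CL": 3.8}

SPECIES_LABEL = {"K": "K+", "NA": "Na+", "MG": "Mg2+", "CL": "Cl-"}

# Crystal-contact context: any foreign atom this close to the ion or its
# ligands marks the site as a lattice artefact candidate.
DEFAULT_CONTEXT_RADIUS = 4.0

HBOND_WINDOW = (2.4, 3.2)


def classify_ligand(atom: Atom) -> LigandClass:
    """Chemical class of a coordinating atom, by (residue, atom-name) lookup.

    Non-oxygen atoms classify as OTHER (censuses count oxygen ligands; the
    halide shell is handled by the caller's element filter).
    """
    if atom.element != "O":
        return LigandClass.OTHER
    if atom.residue_name in WATER_NAMES:
        return LigandClass.WATER_O
    if atom.is_hetero or atom.residue_name not in AMINO_ACIDS:
        return LigandClass.HETERO_O
    name = atom.name.upper()
    if name == "O":
        return LigandClass.MAIN_CHAIN_CARBONYL
    if name == "OXT":
        # terminal carboxylate oxygen
        return LigandClass.CARBOXYLATE_O
    cls = _SIDECHAIN_O.get((atom.residue_name, name))
    if cls is not None:
        return cls
    warnings.warn(
        f"unrecognised oxygen {atom.residue_name} {name}; classified OTHER",
        stacklevel=2,
    )
    return LigandClass.OTHER


@dataclass
class LigandContact:
    atom: Atom
    distance: float
    ligand_class: LigandClass
    provenance: str  # "asu" or a PlacedCopy id
    same_chain_as_majority: bool = True

    @property
    def atom_key(self) -> tuple:
        """Identity of the contact atom, including symmetry provenance."""
        a = self.atom
        return (self.provenance, a.chain_id, a.residue_seq, a.icode, a.residue_name, a.name)


@dataclass
class IonSite:
    ion: Atom
    species: str
    contacts: list[LigandContact] = field(default_factory=list)
    context: str | None = None  # INTRA_SUBUNIT | INTER_SUBUNIT | CRYSTAL_CONTACT
    site_class_id: int | None = None
    under_coordinated: bool = False
    octahedral_score: float | None = None
    ion_neighbors: list[tuple[Atom, float, str]] = field(default_factory=list)
    cutoff: float = 0.0

    @property
    def coordination_number(self) -> int:
        return len(self.contacts)

    def class_counts(self, protein_only: bool = False) -> dict[LigandClass, int]:
        out: dict[LigandClass, int] = {}
        for c in self.contacts:
            if protein_only and c.ligand_class not in PROTEIN_LIGAND_CLASSES:
                continue
            out[c.ligand_class] = out.get(c.ligand_class, 0) + 1
        return out

    def shared_key(self) -> tuple:
        a = self.ion
        return (a.chain_id, a.residue_seq, a.icode, a.serial)


@dataclass
class SiteCensus:
    """Per-structure, per-species tallies of coordination-shell chemistry."""

    species: str = ""
    ion_count: int = 0
    protein_ligand_count: int = 0
    class_counts: dict[LigandClass, int] = field(default_factory=dict)
    protein_class_counts: dict[LigandClass, int] = field(default_factory=dict)
    water_ligand_count: int = 0
    hetero_ligand_count: int = 0
    per_site: list[dict] = field(default_factory=list)

    def __add__(self, other: "SiteCensus") -> "SiteCensus":
        merged = SiteCensus(species=self.species or other.species)
        merged.ion_count = self.ion_count + other.ion_count
        merged.protein_ligand_count = self.protein_ligand_count + other.protein_ligand_count
        merged.water_ligand_count = self.water_ligand_count + other.water_ligand_count
        merged.hetero_ligand_count = self.hetero_ligand_count + other.hetero_ligand_count
        for src, dst in (
            (self.class_counts, merged.class_counts),
            (other.class_counts, merged.class_counts),
        ):
            for k, v in src.items():
                dst[k] = dst.get(k, 0) + v
        for src in (self.protein_class_counts, other.protein_class_counts):
            for k, v in src.items():
                merged.protein_class_counts[k] = merged.protein_class_counts.get(k, 0) + v
        merged.per_site = self.per_site + other.per_site
        return merged

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "ion_count": self.ion_count,
            "protein_ligands": self.protein_ligand_count,
            "protein_classes": {k.value: v for k, v in sorted(self.protein_class_counts.items(), key=lambda kv: kv[0].value)},
            "all_classes": {k.value: v for k, v in sorted(self.class_counts.items(), key=lambda kv: kv[0].value)},
            "water_ligands": self.water_ligand_count,
            "hetero_ligands": self.hetero_ligand_count,
        }


def _is_ion_atom(atom: Atom) -> bool:
    return atom.residue_name in ION_RESIDUE_ELEMENTS


def _coordinating(species: str, atom: Atom) -> bool:
    if _is_ion_atom(atom):
        return False
    if species == "CL":
        return atom.element in ("N", "O")
    return atom.element == "O"


def detect_sites(
    model: StructureModel,
    species: list[str] | tuple[str, ...] = ("K",),
    cutoffs: dict[str, float] | None = None,
    include_symmetry: bool = False,
    placed_copies: list[PlacedCopy] | None = None,
    context_radius: float = DEFAULT_CONTEXT_RADIUS,
) -> list[IonSite]:
    """One :class:`IonSite` per deposited ion of each requested species.

    Contacts are the coordinating atoms (O for cations; N/O for chloride)
    within the species cutoff, sorted by distance; symmetry-copy atoms are
    included when ``include_symmetry`` is set.  Other ions inside the cutoff
    are recorded as neighbors, never as ligands.
    """
    cut = dict(DEFAULT_CUTOFFS)
    if cutoffs:
        cut.update({k.upper(): v for k, v in cutoffs.items()})
    for sp, r in cut.items():
        if r <= 0:
            raise ValueError(f"cutoff for {sp} must be positive")
        if r > 6.0:
            raise ValueError(f"cutoff {r} A for {sp} is beyond first-shell distances")

    species = [s.upper() for s in species]
    ions = [a for a in model.atoms if a.residue_name in species and _is_ion_atom(a)]
    if not ions:
        return []

    env_atoms: list[Atom] = list(model.atoms)
    env_prov: list[str] = ["asu"] * len(env_atoms)
    if include_symmetry and model.unit_cell is not None and model.sym_ops:
        if placed_copies is None:
            placed_copies = expand_symmetry(model, radius=max(cut.values()) + context_radius)
        for cp in placed_copies:
            env_atoms.extend(cp.atoms)
            env_prov.extend([cp.copy_id] * len(cp.atoms))

    sites: list[IonSite] = []
    for ion in ions:
        sp = ion.residue_name
        radius = cut[sp]
        contacts: list[LigandContact] = []
        neighbors: list[tuple[Atom, float, str]] = []
        idx_hits = _indexed_hits(env_atoms, ion, radius)
        for i, d in idx_hits:
            a = env_atoms[i]
            prov = env_prov[i]
            if prov == "asu" and a.serial == ion.serial and d <= 1e-9:
                continue
            if _is_ion_atom(a):
                neighbors.append((a, d, prov))
                continue
            if not _coordinating(sp, a):
                continue
            contacts.append(
                LigandContact(atom=a, distance=d, ligand_class=classify_ligand(a), provenance=prov)
            )
        _flag_majority_chain(contacts)
        site = IonSite(
            ion=ion,
            species=sp,
            contacts=contacts,
            under_coordinated=len(contacts) == 0,
            ion_neighbors=neighbors,
            cutoff=radius,
        )
        sites.append(site)
    return sites


def _indexed_hits(env_atoms: list[Atom], ion: Atom, radius: float) -> list[tuple[int, float]]:
    coords = np.asarray([a.position for a in env_atoms], dtype=float)
    center = ion.xyz
    d = np.linalg.norm(coords - center, axis=1)
    idx = np.nonzero(d <= radius + 1e-12)[0]
    pairs = [(int(i), float(d[i])) for i in idx]
    pairs.sort(key=lambda t: (t[1], env_atoms[t[0]].serial))
    return pairs


def _flag_majority_chain(contacts: list[LigandContact]) -> None:
    chains = [c.atom.chain_id for c in contacts if c.ligand_class in PROTEIN_LIGAND_CLASSES]
    if not chains:
        return
    majority = max(set(chains), key=chains.count)
    for c in contacts:
        c.same_chain_as_majority = c.atom.chain_id == majority


def census(sites: list[IonSite]) -> SiteCensus:
    """Tally coordination-shell chemistry over a list of sites.

    Protein ligands are the four polymer oxygen classes; waters and hetero
    oxygens are reported separately.  Censuses add element-wise.
    """
    out = SiteCensus(species=sites[0].species if sites else "")
    out.ion_count = len(sites)
    for s in sites:
        row = {
            "ion_serial": s.ion.serial,
            "chain": s.ion.chain_id,
            "residue_seq": s.ion.residue_seq,
            "cn": s.coordination_number,
            "classes": {k.value: v for k, v in s.class_counts().items()},
            "context": s.context,
        }
        out.per_site.append(row)
        for c in s.contacts:
            cls = c.ligand_class
            out.class_counts[cls] = out.class_counts.get(cls, 0) + 1
            if cls in PROTEIN_LIGAND_CLASSES:
                out.protein_class_counts[cls] = out.protein_class_counts.get(cls, 0) + 1
                out.protein_ligand_count += 1
            elif cls is LigandClass.WATER_O:
                out.water_ligand_count += 1
            elif cls is LigandClass.HETERO_O:
                out.hetero_ligand_count += 1
    return out


def find_bridges(
    sites: list[IonSite], max_ion_ion: float = 4.5
) -> list[dict]:
    """Ion pairs within ``max_ion_ion`` Angstrom that share >=1 contact atom.

    Sharing is by atom identity (chain, residue, atom name, provenance), so a
    carbonyl oxygen ligating both ions of a di-cation site is reported once.
    """
    bridges = []
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            a, b = sites[i], sites[j]
            d = float(np.linalg.norm(a.ion.xyz - b.ion.xyz))
            if d > max_ion_ion:
                continue
            keys_a = {c.atom_key: c for c in a.contacts}
            shared = [keys_a[c.atom_key] for c in b.contacts if c.atom_key in keys_a]
            if not shared:
                continue
            bridges.append(
                {
                    "site_i": i,
                    "site_j": j,
                    "ion_serials": (a.ion.serial, b.ion.serial),
                    "distance": d,
                    "shared_contacts": shared,
                    "shared_protein_residues": sorted(
                        {
                            (c.atom.chain_id, c.atom.residue_seq, c.atom.name)
                            for c in shared
                            if c.ligand_class in PROTEIN_LIGAND_CLASSES
                        }
                    ),
                }
            )
    return bridges


def classify_context(
    site: IonSite,
    assembly_map: dict[str, str] | None = None,
    placed_copies: list[PlacedCopy] | None = None,
    context_radius: float = DEFAULT_CONTEXT_RADIUS,
) -> str:
    """Label a site INTRA_SUBUNIT, INTER_SUBUNIT or CRYSTAL_CONTACT.

    CRYSTAL_CONTACT: any contact carries foreign (symmetry-copy) provenance,
    or a symmetry-copy atom lies within ``context_radius`` of the ion or one
    of its ligand atoms, or contacts span chains mapped to different
    assemblies.  INTER_SUBUNIT: non-water contacts span chains of a single
    assembly.  Otherwise INTRA_SUBUNIT.
    """
    assembly_map = assembly_map or {}
    non_water = [c for c in site.contacts if c.ligand_class is not LigandClass.WATER_O]

    if any(c.provenance != "asu" for c in site.contacts):
        site.context = "CRYSTAL_CONTACT"
        return site.context

    chains = {c.atom.chain_id for c in non_water}
    assemblies = {assembly_map.get(ch, ch) for ch in chains}
    if len(assemblies) > 1 and assembly_map:
        missing = [ch for ch in chains if ch not in assembly_map]
        if missing:
            raise ValueError(f"assembly_map missing chains: {missing}")
        site.context = "CRYSTAL_CONTACT"
        return site.context

    if placed_copies:
        probes = [site.ion.xyz] + [c.atom.xyz for c in site.contacts]
        probes = np.asarray(probes)
        for cp in placed_copies:
            cpos = np.asarray([a.position for a in cp.atoms])
            if cpos.size == 0:
                continue
            from scipy.spatial import cKDTree

            tree = cKDTree(cpos)
            d, _ = tree.query(probes, k=1)
            if np.any(d <= context_radius):
                site.context = "CRYSTAL_CONTACT"
                return site.context

    if len(chains) > 1:
        site.context = "INTER_SUBUNIT"
    else:
        site.context = "INTRA_SUBUNIT"
    return site.context


def _chain_ca_map(model: StructureModel, chain: str) -> dict[int, np.ndarray]:
    return {
        a.residue_seq: a.xyz
        for a in model.atoms
        if a.chain_id == chain and a.name == "CA" and a.is_polymer and not a.icode
    }


def _map_to_reference(
    model: StructureModel, chain: str, reference: str
) -> tuple[np.ndarray, np.ndarray, float] | None:
    """Kabsch transform taking ``chain`` CA coordinates onto ``reference``."""
    if chain == reference:
        return np.eye(3), np.zeros(3), 0.0
    ca_c = _chain_ca_map(model, chain)
    ca_r = _chain_ca_map(model, reference)
    common = sorted(set(ca_c) & set(ca_r))
    if len(common) < 3:
        return None
    A = np.asarray([ca_c[i] for i in common])
    B = np.asarray([ca_r[i] for i in common])
    R, t, rmsd = superpose(A, B)
    if rmsd > 5.0:
        warnings.warn(
            f"chain {chain} onto {reference}: superposition RMSD {rmsd:.2f} A > 5; "
            "clustering reported anyway",
            stacklevel=2,
        )
    return R, t, rmsd


def cluster_equivalent_sites(
    sites: list[IonSite],
    model: StructureModel,
    reference_chain: str | None = None,
    merge_radius: float = 2.5,
) -> dict[int, int]:
    """Group crystallographically independent copies of the same site.

    Each site's ion is assigned to the polymer chain contributing most of its
    protein ligands (falling back to the nearest chain), mapped into the
    reference chain's frame by CA superposition, and single-linkage clustered
    with ``merge_radius``.  Classes are numbered 1.. by descending
    multiplicity, ties broken by lowest contacting residue number then ion
    serial.  Returns {site index: class id} and writes ``site_class_id``.
    """
    if not sites:
        return {}
    chains = [c for c in model.chains() if _chain_ca_map(model, c)]
    if reference_chain is None:
        reference_chain = chains[0]

    def home_chain(site: IonSite) -> str:
        prot = [c.atom.chain_id for c in site.contacts if c.ligand_class in PROTEIN_LIGAND_CLASSES and c.provenance == "asu"]
        if prot:
            return max(set(prot), key=prot.count)
        # nearest CA chain
        best, bestd = chains[0], np.inf
        for ch in chains:
            for pos in _chain_ca_map(model, ch).values():
                d = np.linalg.norm(pos - site.ion.xyz)
                if d < bestd:
                    best, bestd = ch, d
        return best

    mapped = np.zeros((len(sites), 3))
    for i, s in enumerate(sites):
        ch = home_chain(s)
        tr = _map_to_reference(model, ch, reference_chain)
        if tr is None:
            mapped[i] = s.ion.xyz
        else:
            R, t, _ = tr
            mapped[i] = R @ s.ion.xyz + t

    # single-linkage clustering at merge_radius
    n = len(sites)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(mapped[i] - mapped[j]) <= merge_radius:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    def first_residue(members: list[int]) -> int:
        nums = [
            c.atom.residue_seq
            for i in members
            for c in sites[i].contacts
            if c.ligand_class in PROTEIN_LIGAND_CLASSES
        ]
        return min(nums) if nums else 10**9

    ordered = sorted(
        groups.values(),
        key=lambda m: (-len(m), first_residue(m), min(sites[i].ion.serial for i in m)),
    )
    assignment: dict[int, int] = {}
    for cls_id, members in enumerate(ordered, start=1):
        for i in members:
            assignment[i] = cls_id
            sites[i].site_class_id = cls_id
    return assignment


def octahedral_score(ion: Atom, contacts: list[LigandContact]) -> float:
    """Mean absolute deviation (degrees) of ligand-ion-ligand angles from the
    nearest ideal octahedral angle (90 or 180)."""
    if len(contacts) < 2:
        return float("nan")
    vs = [c.atom.xyz - ion.xyz for c in contacts]
    devs = []
    for i in range(len(vs)):
        for j in range(i + 1, len(vs)):
            cosang = np.dot(vs[i], vs[j]) / (np.linalg.norm(vs[i]) * np.linalg.norm(vs[j]))
            ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            devs.append(min(abs(ang - 90.0), abs(ang - 180.0)))
    return float(np.mean(devs))


def analyze_mg(
    model: StructureModel,
    include_symmetry: bool = True,
    context_radius: float = DEFAULT_CONTEXT_RADIUS,
    assembly_map: dict[str, str] | None = None,
) -> list[dict]:
    """Per-Mg2+ geometry and carboxyl-linkage report.

    For each magnesium: coordination number, octahedral score, whether a
    carboxylate oxygen sits in the first shell (direct) or one hydrogen bond
    away through a first-shell water (water-mediated), and packing context.
    """
    copies = None
    if include_symmetry and model.unit_cell is not None and model.sym_ops:
        copies = expand_symmetry(model, radius=DEFAULT_CUTOFFS["MG"] + context_radius)
    sites = detect_sites(
        model,
        species=["MG"],
        include_symmetry=include_symmetry,
        placed_copies=copies,
        context_radius=context_radius,
    )
    # all carboxylate oxygens (deposited + copies) for mediation checks
    carbox: list[Atom] = [
        a for a in model.atoms if classify_ligand(a) is LigandClass.CARBOXYLATE_O
    ]
    carbox_prov = ["asu"] * len(carbox)
    if copies:
        for cp in copies:
            for a in cp.atoms:
                if classify_ligand(a) is LigandClass.CARBOXYLATE_O:
                    carbox.append(a)
                    carbox_prov.append(cp.copy_id)
    cpos = np.asarray([a.position for a in carbox]) if carbox else np.zeros((0, 3))

    reports = []
    for s in sites:
        s.octahedral_score = octahedral_score(s.ion, s.contacts)
        direct = any(c.ligand_class is LigandClass.CARBOXYLATE_O for c in s.contacts)
        mediated = False
        if not direct and cpos.shape[0]:
            for c in s.contacts:
                if c.ligand_class is not LigandClass.WATER_O:
                    continue
                d = np.linalg.norm(cpos - c.atom.xyz, axis=1)
                if np.any((d >= HBOND_WINDOW[0]) & (d <= HBOND_WINDOW[1])):
                    mediated = True
                    break
        ctx = classify_context(s, assembly_map=assembly_map, placed_copies=copies, context_radius=context_radius)
        reports.append(
            {
                "ion_serial": s.ion.serial,
                "chain": s.ion.chain_id,
                "cn": s.coordination_number,
                "octahedral_score_deg": s.octahedral_score,
                "direct_carboxyl": direct,
                "water_mediated_carboxyl": mediated,
                "context": ctx,
                "site": s,
            }
        )
    return reports


def match_sites(
    sites_a: list[IonSite],
    sites_b: list[IonSite],
    superposition: tuple[np.ndarray, np.ndarray] | None = None,
    match_radius: float = 2.0,
) -> dict:
    """Correspond sites of two structures after superposition.

    ``superposition`` maps structure-B coordinates into A's frame (rotation,
    translation); identity if omitted.  Pairs are matched greedily by
    increasing mapped ion-ion distance within ``match_radius``.
    """
    if superposition is None:
        R, t = np.eye(3), np.zeros(3)
    else:
        R, t = superposition
    pos_a = np.asarray([s.ion.xyz for s in sites_a]) if sites_a else np.zeros((0, 3))
    pos_b = np.asarray([R @ s.ion.xyz + t for s in sites_b]) if sites_b else np.zeros((0, 3))
    cands = []
    for i in range(len(sites_a)):
        for j in range(len(sites_b)):
            d = float(np.linalg.norm(pos_a[i] - pos_b[j]))
            if d <= match_radius:
                cands.append((d, i, j))
    cands.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for d, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append({"a": i, "b": j, "distance": d})
    return {
        "pairs": pairs,
        "unmatched_a": [i for i in range(len(sites_a)) if i not in used_a],
        "unmatched_b": [j for j in range(len(sites_b)) if j not in used_b],
    }
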