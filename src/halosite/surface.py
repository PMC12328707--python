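"""Solvent-accessible surface area and halophilic surface-composition metrics.

SASA is computed by Shrake-Rupley sphere sampling with a deterministic
golden-section spiral lattice (no randomness, bit-stable across runs).  The
surface is then partitioned chemically after Miller et al.: nonpolar (carbon
and sulfur), polar (neutral nitrogen/oxygen) and charged (carboxylate oxygens
of Asp/Glu, Lys NZ, Arg guanidinium nitrogens, chain-terminal N/OXT).
Halophilic proteins show a charged-surface excess and a lysine deficit; the
module reports the fractions plus the residue-composition metrics used to
fingerprint that adaptation: (Asp+Glu)/N, Lys/N, Thr/N, Phe/N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from halosite.structio import AMINO_ACIDS, Atom, StructureModel

# Chothia-style van der Waals radii (Angstrom); single pinned set so results
# are reproducible.  Ions get Shannon-like radii adequate for burial checks.
VDW_RADII = {
    "C": 1.87,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "P": 1.90,
    "H": 1.00,
    "K": 2.75,
    "NA": 2.27,
    "MG": 1.73,
    "CL": 1.81,
    "CA": 2.31,
    "SE": 1.90,
    "F": 1.47,
    "BR": 1.85,
    "I": 1.98,
    "FE": 2.00,
    "ZN": 1.39,
    "MN": 2.00,
}

DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960

CHARGED_ATOMS = {
    ("ASP", "OD1"), ("ASP", "OD2"),
    ("GLU", "OE1"), ("GLU", "OE2"),
    ("LYS", "NZ"),
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
}


@dataclass
class SurfaceProfile:
    total_sasa: float
    per_atom: np.ndarray
    fraction_nonpolar: float
    fraction_polar: float
    fraction_charged: float
    n_residues: int
    frac_asp_glu: float
    frac_lys: float
    frac_thr: float
    frac_phe: float
    probe_radius: float = DEFAULT_PROBE
    radii_set: str = "chothia"

    def metrics(self) -> dict[str, float]:
        return {
            "fraction_nonpolar": self.fraction_nonpolar,
            "fraction_polar": self.fraction_polar,
            "fraction_charged": self.fraction_charged,
            "frac_asp_glu": self.frac_asp_glu,
            "frac_lys": self.frac_lys,
            "frac_thr": self.frac_thr,
            "frac_phe": self.frac_phe,
        }

    def to_dict(self) -> dict:
        d = dict(self.metrics())
        d.update(
            total_sasa_A2=self.total_sasa,
            n_residues=self.n_residues,
            probe_radius_A=self.probe_radius,
            radii_set=self.radii_set,
        )
        return d


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-section spiral lattice of n points on the unit
    sphere."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    golden = np.pi * (1.0 + np.sqrt(5.0))
    theta = golden * i
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def _radius(atom: Atom) -> float:
    r = VDW_RADII.get(atom.element)
    if r is None:
        raise ValueError(f"no van der Waals radius for element {atom.element!r}")
    return r


def sasa(
    model: StructureModel,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Angstrom^2), Shrake-Rupley.

    Hydrogens are excluded on read, so every retained atom contributes.
    Deterministic for fixed ``n_points``.
    """
    atoms = model.atoms
    if not atoms:
        return np.zeros(0)
    coords = model.coords
    radii = np.asarray([_radius(a) for a in atoms]) + probe
    pts = sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    areas = np.zeros(len(atoms))
    for i in range(len(atoms)):
        shell = coords[i] + radii[i] * pts
        # candidate occluders: spheres that can reach this one's shell
        cand = tree.query_ball_point(coords[i], radii[i] + max_r)
        cand = [j for j in cand if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in cand:
            d2 = ((shell - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 > radii[j] ** 2
            if not accessible.any():
                break
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * accessible.sum() / n_points
    return areas


def classify_miller(atom: Atom) -> str:
    """Miller chemical class of an atom: nonpolar, polar or charged.

    Carbon and sulfur are nonpolar; the ionisable-group atoms of Asp/Glu
    carboxylates, Lys NZ, Arg guanidinium N and chain termini (OXT) are
    charged; remaining nitrogen and oxygen are polar (His side-chain N is
    treated as polar, per the original convention).
    """
    if atom.element in ("C", "S"):
        return "nonpolar"
    if atom.element in ("N", "O"):
        if atom.name.upper() == "OXT":
            return "charged"
        if (atom.residue_name, atom.name.upper()) in CHARGED_ATOMS:
            return "charged"
        return "polar"
    raise ValueError(
        f"atom {atom.name} ({atom.element}) in {atom.residue_name} has no Miller class; "
        "strip non-protein atoms before composition analysis"
    )


def miller_composition(model: StructureModel, areas: np.ndarray | None = None,
                       probe: float = DEFAULT_PROBE, n_points: int = DEFAULT_N_POINTS) -> SurfaceProfile:
    """Surface chemical composition and halophilic fingerprint metrics.

    The model must contain protein atoms only (strip waters, ions, cofactors
    and expression tags first; see :func:`halosite.structio.select`).
    """
    for a in model.atoms:
        if not a.is_polymer or a.residue_name not in AMINO_ACIDS:
            raise ValueError(
                f"non-protein residue {a.residue_name} present; strip solvent/hetero "
                "atoms before composition analysis"
            )
    if areas is None:
        areas = sasa(model, probe=probe, n_points=n_points)
    total = float(areas.sum())
    by_class = {"nonpolar": 0.0, "polar": 0.0, "charged": 0.0}
    for a, area in zip(model.atoms, areas):
        by_class[classify_miller(a)] += float(area)

    residues = model.polymer_residues()
    n = len(residues)
    if n == 0:
        raise ValueError("no polymer residues")
    names = [r[3] for r in residues]

    def frac(*res):
        return sum(names.count(r) for r in res) / n

    if total > 0:
        fnp, fp, fc = (by_class[k] / total for k in ("nonpolar", "polar", "charged"))
    else:
        fnp = fp = fc = 0.0
    return SurfaceProfile(
        total_sasa=total,
        per_atom=areas,
        fraction_nonpolar=fnp,
        fraction_polar=fp,
        fraction_charged=fc,
        n_residues=n,
        frac_asp_glu=frac("ASP", "GLU"),
        frac_lys=frac("LYS"),
        frac_thr=frac("THR"),
        frac_phe=frac("PHE"),
        probe_radius=probe,
    )


def compare_profiles(query: SurfaceProfile, references: list[SurfaceProfile]) -> dict:
    """Rank a query profile against reference profiles, per metric.

    Returns, for each metric: the reference mean and SD, the query z-score
    and the query's rank (1 = largest value).  Requires >=3 references.
    """
    if len(references) < 3:
        raise ValueError("compare_profiles requires at least 3 reference profiles")
    out = {}
    qm = query.metrics()
    for key, qv in qm.items():
        # sorted so the statistics are independent of reference order
        vals = np.sort(np.asarray([r.metrics()[key] for r in references]))
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        z = (qv - mean) / sd if sd > 0 else float("inf") * np.sign(qv - mean) if qv != mean else 0.0
        rank = int(1 + np.sum(vals > qv))
        out[key] = {
            "query": qv,
            "reference_mean": mean,
            "reference_sd": sd,
            "z_score": float(z),
            "rank": rank,
            "n_references": len(references),
        }
    return out
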