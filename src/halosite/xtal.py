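"""Unit-cell math, crystallographic symmetry expansion and neighbor search.

Everything downstream of this module works in orthogonal Angstrom space;
fractional coordinates appear only here, inside the orthogonalisation matrix
and the symmetry operators.  Symmetry expansion enumerates (operator,
lattice translation) placements within +-2 unit cells of the deposited
coordinates and keeps copies approaching within a caller-supplied radius,
which is what crystal-contact detection needs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from halosite.structio import Atom, StructureModel, SymOp, UnitCell


def orthogonalization_matrix(cell: UnitCell) -> np.ndarray:
    """Standard PDB-convention fractional-to-orthogonal matrix (a along x)."""
    if cell.volume() <= 0:
        raise ValueError("degenerate cell: non-positive volume")
    a, b, c = cell.a, cell.b, cell.c
    ca, cb, cg = (np.cos(np.radians(x)) for x in (cell.alpha, cell.beta, cell.gamma))
    sg = np.sin(np.radians(cell.gamma))
    v = np.sqrt(1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg)
    return np.array(
        [
            [a, b * cg, c * cb],
            [0.0, b * sg, c * (ca - cb * cg) / sg],
            [0.0, 0.0, c * v / sg],
        ]
    )


def frac_to_orth(cell: UnitCell, frac) -> np.ndarray:
    """Fractional -> orthogonal Angstrom coordinates (vector or Nx3 array)."""
    M = orthogonalization_matrix(cell)
    return np.asarray(frac, dtype=float) @ M.T


def orth_to_frac(cell: UnitCell, orth) -> np.ndarray:
    """Orthogonal Angstrom -> fractional coordinates (vector or Nx3 array)."""
    Minv = np.linalg.inv(orthogonalization_matrix(cell))
    return np.asarray(orth, dtype=float) @ Minv.T


@dataclass
class PlacedCopy:
    """A symmetry-generated copy of the deposited model.

    ``op_index`` indexes the model's operator list; ``lattice`` is the integer
    unit-cell translation applied after the operator.  The identity placement
    (op 0 in a reduced setting, zero translation) is never emitted.
    """

    op_index: int
    lattice: tuple[int, int, int]
    atoms: list[Atom]
    source_chains: tuple[str, ...]

    @property
    def copy_id(self) -> str:
        i, j, k = self.lattice
        return f"sym{self.op_index}_{i}_{j}_{k}"


def transform_positions(cell: UnitCell, op: SymOp, lattice, positions: np.ndarray) -> np.ndarray:
    """Apply a fractional-space operator plus lattice translation to
    orthogonal coordinates."""
    frac = orth_to_frac(cell, positions)
    moved = frac @ op.rot.T + op.tran + np.asarray(lattice, dtype=float)
    return frac_to_orth(cell, moved)


def expand_symmetry(
    model: StructureModel,
    radius: float,
    max_cells: int = 2,
) -> list[PlacedCopy]:
    """Enumerate symmetry copies with any atom within ``radius`` of the model.

    Requires a unit cell and at least one operator.  Lattice translations are
    searched over ``{-max_cells..max_cells}^3``; the identity placement is
    excluded.  Copies carry their (operator, translation) provenance.
    """
    if model.unit_cell is None:
        raise ValueError(
            "model has no unit cell; symmetry expansion requires crystal data "
            "(run in non-crystallographic mode by skipping expansion)"
        )
    ops = model.sym_ops or [SymOp(((1, 0, 0), (0, 1, 0), (0, 0, 1)), (0, 0, 0))]
    coords = model.coords
    if coords.shape[0] == 0:
        return []
    tree = cKDTree(coords)
    chains = tuple(model.chains())
    copies: list[PlacedCopy] = []
    rng = range(-max_cells, max_cells + 1)
    for oi, op in enumerate(ops):
        for i in rng:
            for j in rng:
                for k in rng:
                    if op.is_identity and i == j == k == 0:
                        continue
                    moved = transform_positions(model.unit_cell, op, (i, j, k), coords)
                    d, _ = tree.query(moved, k=1, distance_upper_bound=radius)
                    if not np.any(np.isfinite(d)):
                        continue
                    atoms = [
                        replace(a, position=tuple(p))
                        for a, p in zip(model.atoms, moved)
                    ]
                    copies.append(
                        PlacedCopy(op_index=oi, lattice=(i, j, k), atoms=atoms, source_chains=chains)
                    )
    return copies


def neighbor_search(
    atoms: list[Atom],
    center,
    radius: float,
) -> list[tuple[Atom, float]]:
    """Atoms within ``radius`` (inclusive) of ``center``, sorted by distance
    then by serial number."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    if not atoms:
        return []
    coords = np.asarray([a.position for a in atoms], dtype=float)
    center = np.asarray(center, dtype=float)
    tree = cKDTree(coords)
    idx = tree.query_ball_point(center, radius)
    hits = []
    for i in idx:
        d = float(np.linalg.norm(coords[i] - center))
        if d <= radius + 1e-12:
            hits.append((atoms[i], d))
    hits.sort(key=lambda t: (t[1], t[0].serial))
    return hits
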