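"""Rigid-body superposition and inter-domain hinge-rotation measurement.

Two-domain enzymes of the D-2-hydroxyacid dehydrogenase fold close their
inter-domain cleft on substrate binding.  The rotation between two
conformers is measured DynDom-style: superpose the structures on one domain
(the dimerisation/cofactor domain, d2), then express the residual rigid
transform of the other domain (d1) as a screw motion and report its rotation
angle.  Fitting is least-squares on CA atoms (Kabsch, proper rotation
enforced); domain boundaries are supplied by the user, with the D2HDH
defaults shipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from halosite.structio import StructureModel


@dataclass(frozen=True)
class DomainDefinition:
    """Residue ranges of two rigid domains plus the hinge segments.

    Defaults are the D2HDH assignment: the peripheral substrate-binding
    domain d1 (residues 1-92 and 283-308), the dimerisation/cofactor domain
    d2 (93-282), hinges 89-92 and 277-282.
    """

    d1: tuple[tuple[int, int], ...] = ((1, 92), (283, 308))
    d2: tuple[tuple[int, int], ...] = ((93, 282),)
    hinges: tuple[tuple[int, int], ...] = ((89, 92), (277, 282))

    def __post_init__(self):
        covered: set[int] = set()
        for ranges in (self.d1, self.d2):
            for lo, hi in ranges:
                span = set(range(lo, hi + 1))
                if covered & span:
                    raise ValueError("domain ranges overlap")
                covered |= span

    def residues(self, domain: str) -> set[int]:
        ranges = self.d1 if domain == "d1" else self.d2
        out: set[int] = set()
        for lo, hi in ranges:
            out |= set(range(lo, hi + 1))
        return out


@dataclass
class RotationResult:
    angle: float  # degrees, [0, 180]
    axis: tuple[float, float, float]
    axis_point: tuple[float, float, float]
    translation_along_axis: float
    rmsd_d2: float
    rmsd_d1: float
    n_d2: int
    n_d1: int
    chain_pair: tuple[str, str] = ("", "")

    def to_dict(self) -> dict:
        return {
            "angle_deg": round(self.angle, 1),
            "axis": list(self.axis),
            "axis_point": list(self.axis_point),
            "translation_along_axis_A": self.translation_along_axis,
            "rmsd_d2_A": self.rmsd_d2,
            "rmsd_d1_A": self.rmsd_d1,
            "n_ca_d2": self.n_d2,
            "n_ca_d1": self.n_d1,
            "chain_pair": list(self.chain_pair),
        }


def superpose(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid fit of point set A onto B (Kabsch).

    Returns (R, t, rmsd) with ``R @ a + t ~ b`` and det(R) = +1.  Requires
    >=3 non-collinear paired points.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("superpose requires equal-shape Nx3 arrays")
    if A.shape[0] < 3:
        raise ValueError("superpose requires at least 3 points")
    ca = A.mean(axis=0)
    cb = B.mean(axis=0)
    Ac = A - ca
    Bc = B - cb
    # collinearity check: rank of centred coordinates
    if np.linalg.matrix_rank(Ac, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) coordinates")
    H = Ac.T @ Bc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    diff = (A @ R.T + t) - B
    rmsd = float(np.sqrt((diff**2).sum() / A.shape[0]))
    return R, t, rmsd


def _rotation_to_screw(R: np.ndarray, t: np.ndarray):
    """Decompose x -> R x + t into screw parameters (angle, axis, point,
    translation along axis)."""
    cos_theta = (np.trace(R) - 1.0) / 2.0
    theta = float(np.degrees(np.arccos(np.clip(cos_theta, -1.0, 1.0))))
    if theta < 1e-8:
        return 0.0, (0.0, 0.0, 1.0), (0.0, 0.0, 0.0), float(np.linalg.norm(t))
    # rotation axis from the antisymmetric part (or eigenvector near 180 deg)
    if theta < 179.0:
        axis = np.array(
            [R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]]
        )
        axis /= np.linalg.norm(axis)
    else:
        w, v = np.linalg.eigh((R + R.T) / 2.0)
        axis = v[:, np.argmax(w)]
        axis /= np.linalg.norm(axis)
    t_par = float(np.dot(t, axis))
    t_perp = t - t_par * axis
    # point on axis: solve (I - R) p = t_perp in the plane normal to axis
    M = np.eye(3) - R
    p, *_ = np.linalg.lstsq(M, t_perp, rcond=None)
    return theta, tuple(axis), tuple(p), t_par


def _ca_map(model: StructureModel, chain: str) -> dict[int, np.ndarray]:
    return {
        a.residue_seq: a.xyz
        for a in model.atoms
        if a.chain_id == chain and a.name == "CA" and a.is_polymer and not a.icode
    }


def interdomain_rotation(
    model_a: StructureModel,
    model_b: StructureModel,
    domains: DomainDefinition | None = None,
    chain_a: str | None = None,
    chain_b: str | None = None,
) -> RotationResult:
    """Hinge rotation of domain d1 between two conformers.

    CA atoms are paired by residue number (missing residues dropped); the
    structures are superposed on d2, then the residual d1(A) -> d1(B) rigid
    transform is reported as a screw rotation to 0.1 degree.
    """
    domains = domains or DomainDefinition()
    chain_a = chain_a or model_a.chains()[0]
    chain_b = chain_b or model_b.chains()[0]
    ca_a = _ca_map(model_a, chain_a)
    ca_b = _ca_map(model_b, chain_b)

    def paired(domain: str):
        resset = domains.residues(domain)
        common = sorted(resset & set(ca_a) & set(ca_b))
        n_expected = len(resset)
        if len(common) < max(3, n_expected // 2):
            raise ValueError(
                f"only {len(common)}/{n_expected} residues of {domain} pairable"
            )
        A = np.asarray([ca_a[i] for i in common])
        B = np.asarray([ca_b[i] for i in common])
        return A, B

    A2, B2 = paired("d2")
    R2, t2, rmsd2 = superpose(A2, B2)

    A1, B1 = paired("d1")
    A1_in_b = A1 @ R2.T + t2  # d1 of A carried along by the d2 fit
    R1, t1, rmsd1 = superpose(A1_in_b, B1)
    angle, axis, point, t_par = _rotation_to_screw(R1, t1)

    return RotationResult(
        angle=angle,
        axis=axis,
        axis_point=point,
        translation_along_axis=t_par,
        rmsd_d2=rmsd2,
        rmsd_d1=rmsd1,
        n_d2=A2.shape[0],
        n_d1=A1.shape[0],
        chain_pair=(chain_a, chain_b),
    )


def rotation_matrix(axis, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit ``axis`` by ``angle_deg``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    th = np.radians(angle_deg)
    K = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
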