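"""Water-structure statistics and polygonal water-ring search.

Ordered pentagonal water arrays have been reported hugging hydrophobic
patches of some protein surfaces; their presence or absence in a halophile's
solvation shell is informative about how the acidic surface restructures
water.  "Pentagonal array" is operationalised here as a chordless, near-planar
5-cycle in the water hydrogen-bond graph (O-O edges within a distance
window); both the chordless requirement and the planarity tolerance are
explicit, configurable definitions echoed in the output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from halosite.structio import Atom, StructureModel

DEFAULT_HBOND_WINDOW = (2.4, 3.2)
DEFAULT_PLANARITY_TOL = 0.5


@dataclass
class WaterNetwork:
    graph: nx.Graph
    atoms: list[Atom]
    window: tuple[float, float]

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, i: int) -> int:
        return self.graph.degree(i)


def water_stats(
    model: StructureModel,
    domains: dict[str, tuple[tuple[int, int], ...]] | None = None,
) -> dict:
    """Waters-per-residue ratio plus per-chain (and optional per-domain) counts.

    The ratio divides modelled water count by modelled polymer residue count.
    ``domains`` maps a name to residue ranges, e.g. the two-domain split of a
    hinged enzyme, to compare solvation of the mobile and core domains.
    """
    waters = model.waters()
    residues = model.polymer_residues()
    if not residues:
        raise ValueError("no polymer residues; cannot normalise water count")
    if not waters:
        warnings.warn("structure contains no modelled waters", stacklevel=2)
    per_chain: dict[str, int] = {}
    for w in waters:
        per_chain[w.chain_id] = per_chain.get(w.chain_id, 0) + 1
    out = {
        "n_waters": len(waters),
        "n_residues": len(residues),
        "waters_per_residue": len(waters) / len(residues),
        "per_chain": per_chain,
    }
    if domains:
        # nearest polymer-CA domain assignment for each water
        ca = [(a, a.xyz) for a in model.atoms if a.name == "CA" and a.is_polymer]
        if ca:
            pos = np.asarray([p for _, p in ca])
            tree = cKDTree(pos)
            counts = {name: 0 for name in domains}
            member = {}
            for name, ranges in domains.items():
                for lo, hi in ranges:
                    for r in range(lo, hi + 1):
                        member[r] = name
            for w in waters:
                _, i = tree.query(w.xyz)
                seq = ca[i][0].residue_seq
                name = member.get(seq)
                if name is not None:
                    counts[name] += 1
            out["per_domain"] = counts
    return out


def build_network(
    model_or_waters,
    window: tuple[float, float] = DEFAULT_HBOND_WINDOW,
) -> WaterNetwork:
    """Hydrogen-bond graph on water oxygens: an edge per O-O pair whose
    distance lies inside ``window`` (inclusive)."""
    lo, hi = window
    if not lo < hi:
        raise ValueError("window must satisfy min < max")
    if isinstance(model_or_waters, StructureModel):
        waters = model_or_waters.waters()
    else:
        waters = list(model_or_waters)
    g = nx.Graph()
    g.add_nodes_from(range(len(waters)))
    if waters:
        pos = np.asarray([w.position for w in waters], dtype=float)
        tree = cKDTree(pos)
        for i, j in tree.query_pairs(hi + 1e-12):
            d = float(np.linalg.norm(pos[i] - pos[j]))
            if lo <= d <= hi:
                g.add_edge(i, j, distance=d)
    return WaterNetwork(graph=g, atoms=waters, window=window)


def _best_fit_plane_deviation(points: np.ndarray) -> float:
    """Max point distance to the least-squares plane through the points."""
    centred = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centred)
    normal = vt[-1]
    return float(np.abs(centred @ normal).max())


def find_rings(
    net: WaterNetwork,
    size: int = 5,
    planarity_tol: float = DEFAULT_PLANARITY_TOL,
) -> list[dict]:
    """All chordless, near-planar simple cycles of exactly ``size`` waters.

    A ring qualifies if every consecutive pair is an edge of the network, no
    non-consecutive pair is (chordless), and the maximum deviation from the
    best-fit plane is <= ``planarity_tol``.  Rings are deduplicated and
    returned in canonical node order.
    """
    if size < 3:
        raise ValueError("ring size must be >= 3")
    g = net.graph
    pos = np.asarray([w.position for w in net.atoms], dtype=float) if net.atoms else np.zeros((0, 3))
    found: set[tuple[int, ...]] = set()
    rings: list[dict] = []

    def canonical(cycle: list[int]) -> tuple[int, ...]:
        n = len(cycle)
        best = None
        for seq in (cycle, cycle[::-1]):
            for s in range(n):
                rot = tuple(seq[(s + k) % n] for k in range(n))
                if best is None or rot < best:
                    best = rot
        return best

    def is_chordless(cycle: list[int]) -> bool:
        n = len(cycle)
        for i in range(n):
            for j in range(i + 2, n):
                if i == 0 and j == n - 1:
                    continue  # closing edge
                if g.has_edge(cycle[i], cycle[j]):
                    return False
        return True

    # bounded DFS from each start node; degree in H-bond graphs is small
    for start in sorted(g.nodes):
        stack = [(start, [start])]
        while stack:
            node, path = stack.pop()
            if len(path) == size:
                if g.has_edge(node, start):
                    key = canonical(path)
                    if key not in found:
                        if is_chordless(path) and _best_fit_plane_deviation(pos[list(path)]) <= planarity_tol:
                            found.add(key)
                            rings.append(
                                {
                                    "nodes": list(key),
                                    "max_plane_deviation_A": _best_fit_plane_deviation(pos[list(key)]),
                                    "coordinates": pos[list(key)].tolist(),
                                }
                            )
                        else:
                            found.add(key)
                continue
            for nb in g.neighbors(node):
                if nb == start and len(path) == size:
                    continue
                if nb in path:
                    continue
                if nb < start:
                    continue  # canonical start = smallest node
                stack.append((nb, path + [nb]))
    rings.sort(key=lambda r: r["nodes"])
    return rings
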