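"""Orchestration: run every analysis stage on a structure, emit one report.

The report is deterministic (sorted JSON keys, no timestamps) and carries a
provenance block with every cutoff, radius and seed that produced it, so any
number in it can be recomputed from the inputs.  Independent stages fail
independently: an error in one is recorded in the report's ``errors`` map and
the remaining stages still run.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field

import numpy as np

from halosite import ionsites, solvation, surface
from halosite._version import __version__ as _version
from halosite.conformation import DomainDefinition, interdomain_rotation
from halosite.ionsites import DEFAULT_CONTEXT_RADIUS, DEFAULT_CUTOFFS
from halosite.structio import StructureModel, read_structure, select
from halosite.xtal import expand_symmetry

KNOWN_KEYS = {
    "structure",
    "compare_structure",
    "species",
    "cutoffs",
    "context_radius",
    "include_symmetry",
    "probe_radius",
    "sasa_points",
    "ring_size",
    "planarity_tol",
    "hbond_min",
    "hbond_max",
    "merge_radius",
    "assembly_map",
    "domains_d1",
    "domains_d2",
}

DEFAULT_CONFIG = {
    "species": ["K", "NA", "MG", "CL"],
    "cutoffs": dict(DEFAULT_CUTOFFS),
    "context_radius": DEFAULT_CONTEXT_RADIUS,
    "include_symmetry": True,
    "probe_radius": 1.4,
    "sasa_points": 960,
    "ring_size": 5,
    "planarity_tol": 0.5,
    "hbond_min": 2.4,
    "hbond_max": 3.2,
    "merge_radius": 2.5,
}


@dataclass
class AnalysisReport:
    structure_id: str
    censuses: dict = field(default_factory=dict)
    site_classes: list = field(default_factory=list)
    bridges: list = field(default_factory=list)
    mg_report: list = field(default_factory=list)
    surface_profile: dict = field(default_factory=dict)
    water_stats: dict = field(default_factory=dict)
    ring_count: int | None = None
    domain_rotations: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "structure_id": self.structure_id,
            "censuses": self.censuses,
            "site_classes": self.site_classes,
            "bridges": self.bridges,
            "mg_report": self.mg_report,
            "surface_profile": self.surface_profile,
            "water_stats": self.water_stats,
            "ring_count": self.ring_count,
            "domain_rotations": self.domain_rotations,
            "provenance": self.provenance,
            "errors": self.errors,
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def validate_config(config: dict) -> dict:
    unknown = set(config) - KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    merged = dict(DEFAULT_CONFIG)
    merged.update(config)
    if "structure" not in merged:
        raise ValueError("config must name a structure file or model under 'structure'")
    return merged


def run(config: dict) -> AnalysisReport:
    """Run the full per-structure analysis.

    ``config['structure']`` is a path or an in-memory
    :class:`~halosite.structio.StructureModel`; see ``DEFAULT_CONFIG`` for
    tunables.  Unreadable structures are fatal; any other stage failure is
    recorded under ``errors`` and the rest of the report is still produced.
    """
    cfg = validate_config(config)
    struct = cfg["structure"]
    if isinstance(struct, StructureModel):
        model = struct
        sid = model.name or "model"
    else:
        model = read_structure(struct)
        sid = str(struct)

    report = AnalysisReport(structure_id=sid)
    report.provenance = {
        "version": _version,
        "species": list(cfg["species"]),
        "cutoffs_A": dict(cfg["cutoffs"]),
        "context_radius_A": cfg["context_radius"],
        "include_symmetry": bool(cfg["include_symmetry"]),
        "probe_radius_A": cfg["probe_radius"],
        "sasa_points": cfg["sasa_points"],
        "ring_size": cfg["ring_size"],
        "planarity_tol_A": cfg["planarity_tol"],
        "hbond_window_A": [cfg["hbond_min"], cfg["hbond_max"]],
        "merge_radius_A": cfg["merge_radius"],
    }
    assembly_map = cfg.get("assembly_map") or {}

    copies = None
    use_sym = cfg["include_symmetry"] and model.unit_cell is not None and bool(model.sym_ops)
    if use_sym:
        try:
            copies = expand_symmetry(
                model, radius=max(cfg["cutoffs"].values()) + cfg["context_radius"]
            )
        except Exception as exc:  # pragma: no cover - defensive
            report.errors["symmetry"] = str(exc)
            copies = None
            use_sym = False

    # --- ion sites -------------------------------------------------------
    try:
        all_sites = {}
        for sp in cfg["species"]:
            sites = ionsites.detect_sites(
                model,
                species=[sp],
                cutoffs=cfg["cutoffs"],
                include_symmetry=use_sym,
                placed_copies=copies,
                context_radius=cfg["context_radius"],
            )
            for s in sites:
                ionsites.classify_context(
                    s, assembly_map=assembly_map, placed_copies=copies,
                    context_radius=cfg["context_radius"],
                )
            all_sites[sp] = sites
            report.censuses[sp] = ionsites.census(sites).to_dict()
        k_sites = all_sites.get("K", [])
        if k_sites:
            ionsites.cluster_equivalent_sites(k_sites, model, merge_radius=cfg["merge_radius"])
            report.site_classes = [
                {
                    "ion_serial": s.ion.serial,
                    "class_id": s.site_class_id,
                    "cn": s.coordination_number,
                    "context": s.context,
                }
                for s in k_sites
            ]
            report.bridges = [
                {
                    "ion_serials": list(b["ion_serials"]),
                    "distance_A": round(b["distance"], 2),
                    "n_shared": len(b["shared_contacts"]),
                    "shared_protein_residues": [list(map(str, r)) for r in b["shared_protein_residues"]],
                }
                for b in ionsites.find_bridges(k_sites)
            ]
    except Exception as exc:
        report.errors["ionsites"] = str(exc)

    # --- magnesium geometry ---------------------------------------------
    try:
        if any(a.residue_name == "MG" for a in model.atoms):
            report.mg_report = [
                {k: v for k, v in row.items() if k != "site"}
                for row in ionsites.analyze_mg(
                    model, include_symmetry=use_sym,
                    context_radius=cfg["context_radius"], assembly_map=assembly_map,
                )
            ]
    except Exception as exc:
        report.errors["mg"] = str(exc)

    # --- surface ---------------------------------------------------------
    try:
        protein = model.with_atoms(select(model, "polymer and not hydrogen"))
        if protein.atoms:
            prof = surface.miller_composition(
                protein, probe=cfg["probe_radius"], n_points=cfg["sasa_points"]
            )
            report.surface_profile = prof.to_dict()
    except Exception as exc:
        report.errors["surface"] = str(exc)

    # --- solvation -------------------------------------------------------
    try:
        if model.polymer_residues():
            report.water_stats = solvation.water_stats(model)
        net = solvation.build_network(model, window=(cfg["hbond_min"], cfg["hbond_max"]))
        report.ring_count = len(
            solvation.find_rings(net, size=cfg["ring_size"], planarity_tol=cfg["planarity_tol"])
        )
    except Exception as exc:
        report.errors["solvation"] = str(exc)

    # --- optional conformational comparison ------------------------------
    try:
        cmp_struct = cfg.get("compare_structure")
        if cmp_struct is not None:
            other = (
                cmp_struct
                if isinstance(cmp_struct, StructureModel)
                else read_structure(cmp_struct)
            )
            dd = DomainDefinition()
            if cfg.get("domains_d1") and cfg.get("domains_d2"):
                dd = DomainDefinition(
                    d1=tuple(tuple(r) for r in cfg["domains_d1"]),
                    d2=tuple(tuple(r) for r in cfg["domains_d2"]),
                )
            for ca in model.chains():
                for cb in other.chains():
                    try:
                        rr = interdomain_rotation(model, other, dd, chain_a=ca, chain_b=cb)
                        report.domain_rotations.append(rr.to_dict())
                    except ValueError:
                        continue
    except Exception as exc:
        report.errors["conformation"] = str(exc)

    return report


def read_config_file(path: str) -> dict:
    """Simple ``key = value`` config format mirroring the CLI flags."""
    cfg: dict = {}
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected key = value")
            key, val = (s.strip() for s in line.split("=", 1))
            if key in ("species",):
                cfg[key] = [v.strip().upper() for v in val.split(",")]
            elif key in ("include_symmetry",):
                cfg[key] = val.lower() in ("1", "true", "yes")
            elif key in ("cutoffs",):
                cfg[key] = {
                    kv.split(":")[0].strip().upper(): float(kv.split(":")[1])
                    for kv in val.split(",")
                }
            elif key in ("structure", "compare_structure"):
                cfg[key] = val
            else:
                try:
                    cfg[key] = float(val)
                except ValueError:
                    cfg[key] = val
    return cfg
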