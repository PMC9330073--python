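"""End-to-end assessment of a prediction run directory, plus report I/O.

A run directory holds the models of one prediction (``*.pdb`` / ``*.cif``)
and, optionally, one PAE JSON per model named ``<model>_pae.json`` (or
``<model>.json``).  ``run_assessment`` executes the stages in order —
read/rank, receptor-anchored superposition, consensus clustering, interface
analysis of the cluster representative, binding-region calling, optional
CAD comparison against a reference — degrading gracefully: a failed stage
records its error and later stages that do not depend on it still run.

The canonical report body contains no wall-clock fields, so re-running on
identical inputs yields byte-identical JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from complexqa import consensus as _consensus
from complexqa import interface as _interface
from complexqa import region_calling as _region
from complexqa.model_io import ComplexSpec, ModelSet, assemble_model_set, read_structure
from complexqa.superpose import local_rmsd, receptor_anchored_superpose

logger = logging.getLogger("complexqa")

DEFAULT_CONFIG: dict = {
    "consensus": {"threshold": 4.0},
    "interface": {"probe_radius": 1.4, "n_points": 960, "d_contact": 6.5},
    "region": {"plddt_min": 70.0, "pae_max": 10.0, "window": 5, "min_len": 6,
               "support_min": 0.6},
    "itc": {"discard_first": False},
}


def load_config(path=None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, values in user.items():
            cfg.setdefault(section, {}).update(values or {})
    return cfg


@dataclass
class AssessmentReport:
    run: dict
    stages: dict[str, str] = field(default_factory=dict)  # stage -> "ok" | error text
    consensus: Optional[dict] = None
    superposition: Optional[list[dict]] = None
    interface: Optional[dict] = None
    region_call: Optional[dict] = None
    cad: Optional[dict] = None
    stoichiometry: Optional[dict] = None
    itc: Optional[dict] = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def discover_models(model_dir) -> tuple[list[Path], list[Optional[Path]]]:
    model_dir = Path(model_dir)
    paths = sorted(p for p in model_dir.iterdir()
                   if p.suffix.lower() in (".pdb", ".cif", ".mmcif"))
    if not paths:
        raise FileNotFoundError(f"no PDB/mmCIF models found in {model_dir}")
    pae_paths: list[Optional[Path]] = []
    for p in paths:
        for cand in (p.with_name(p.stem + "_pae.json"), p.with_suffix(".json")):
            if cand.exists():
                pae_paths.append(cand)
                break
        else:
            pae_paths.append(None)
    return paths, pae_paths


def _interval_dicts(call: _region.RegionCall) -> dict:
    return {
        "intervals": [{"chain": c, "start": s, "end": e} for c, s, e in call.intervals],
        "support": call.support,
        "params": call.params,
    }


def run_assessment(model_dir, spec: ComplexSpec, config: Optional[dict] = None,
                   reference_path=None, recycles: int = 3,
                   stoichiometry: tuple[int, int] = (1, 1)) -> AssessmentReport:
    cfg = config or load_config()
    report = AssessmentReport(run={
        "model_dir": str(model_dir),
        "receptor_chains": sorted(spec.receptor_chains),
        "ligand_chains": sorted(spec.ligand_chains),
        "fragment": list(spec.fragment) if spec.fragment else None,
        "recycles": recycles,
        "stoichiometry": list(stoichiometry),
    })

    # io (fatal on failure)
    paths, pae_paths = discover_models(model_dir)
    model_set = assemble_model_set(paths, pae_paths, recycles=recycles,
                                   stoichiometry=stoichiometry)
    report.stages["io"] = "ok"
    logger.info("read %d models from %s", len(model_set.models), model_dir)

    best = model_set.models[0]

    try:
        rows = []
        for m in model_set.models:
            moved, sup = receptor_anchored_superpose(m, best, spec)
            rows.append({
                "model_id": m.model_id,
                "rank": m.rank,
                "mean_plddt": round(m.mean_plddt, 3),
                "anchor_rmsd": round(sup.anchor_rmsd, 4),
                "local_rmsd": round(local_rmsd(moved, best, spec), 4),
            })
        report.superposition = rows
        report.stages["superpose"] = "ok"
    except Exception as exc:  # stage-level degradation
        report.stages["superpose"] = f"error: {exc}"

    verdict = None
    try:
        verdict = _consensus.verdict_for_set(model_set, spec,
                                             threshold=cfg["consensus"]["threshold"])
        report.consensus = {
            "verdict": verdict.verdict,
            "cluster_members": verdict.cluster_members,
            "representative": verdict.representative,
            "threshold": verdict.threshold,
            "pairwise_rmsd": np.round(verdict.pairwise_rmsd, 4).tolist(),
            "model_ids": verdict.model_ids,
        }
        report.stages["consensus"] = "ok"
    except Exception as exc:
        report.stages["consensus"] = f"error: {exc}"

    try:
        rep_model = best
        if verdict is not None and verdict.representative is not None:
            rep_model = next(m for m in model_set.models
                             if m.model_id == verdict.representative)
        icfg = cfg["interface"]
        irep = _interface.classify_interface(rep_model, spec,
                                             probe_radius=icfg["probe_radius"],
                                             n_points=icfg["n_points"])
        per_res_area: dict = {}
        for (rk, lk), area in irep.contact_map.entries.items():
            per_res_area[rk] = per_res_area.get(rk, 0.0) + area
            per_res_area[lk] = per_res_area.get(lk, 0.0) + area
        report.interface = {
            "model_id": rep_model.model_id,
            "buried_area": round(irep.buried_area, 2),
            "total_buried_area": round(irep.total_buried_area, 2),
            "n_contact_pairs": len(irep.contact_map.entries),
            "residues": [
                {"chain": k[0], "seq_id": k[1], "res_name": n, "side": side,
                 "classes": sorted(cls),
                 "contact_area": round(per_res_area.get(k, 0.0), 2)}
                for k, n, side, cls in irep.interface_residues
            ],
            "notes": irep.notes,
        }
        report.stages["interface"] = "ok"
    except Exception as exc:
        report.stages["interface"] = f"error: {exc}"

    try:
        profiles = [
            _region.confidence_profile(m, p, spec)
            for m, p in zip(model_set.models, model_set.pae) if p is not None
        ]
        if profiles:
            rcfg = cfg["region"]
            call = _region.call_binding_region(
                profiles, plddt_min=rcfg["plddt_min"], pae_max=rcfg["pae_max"],
                window=rcfg["window"], min_len=rcfg["min_len"],
                support_min=rcfg["support_min"])
            report.region_call = _interval_dicts(call)
            report.stages["region_call"] = "ok"
        else:
            report.stages["region_call"] = "skipped: no PAE files"
    except Exception as exc:
        report.stages["region_call"] = f"error: {exc}"

    if reference_path is not None:
        try:
            reference = read_structure(reference_path, provenance="experimental")
            rep_model = best
            if verdict is not None and verdict.representative is not None:
                rep_model = next(m for m in model_set.models
                                 if m.model_id == verdict.representative)
            anchored, _ = receptor_anchored_superpose(rep_model, reference, spec)
            cad = _interface.cad_score_iface(reference, anchored, spec,
                                             probe_radius=cfg["interface"]["probe_radius"],
                                             n_points=cfg["interface"]["n_points"])
            report.cad = {
                "score": round(cad.score, 4),
                "n_target_contacts": cad.n_target_contacts,
                "total_target_area": round(cad.total_target_area, 2),
                "total_abs_diff": round(cad.total_abs_diff, 2),
                "local_rmsd_vs_reference": round(local_rmsd(anchored, reference, spec), 4),
            }
            report.stages["cad"] = "ok"
        except Exception as exc:
            report.stages["cad"] = f"error: {exc}"

    return report


def assess_stoichiometry_dirs(dirs: dict[str, Path], spec_by_label: dict[str, ComplexSpec],
                              config: Optional[dict] = None) -> dict:
    cfg = config or load_config()
    sets = {}
    for label, d in dirs.items():
        paths, pae_paths = discover_models(d)
        sets[label] = assemble_model_set(paths, pae_paths)
    result = _consensus.stoichiometry_assessment(sets, spec_by_label,
                                                 threshold=cfg["consensus"]["threshold"])
    return {
        "preferred": result.preferred,
        "verdicts": {l: v.verdict for l, v in result.verdicts.items()},
        "interface_areas": {l: round(a, 2) for l, a in result.interface_areas.items()},
        "warnings": result.warnings,
    }
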