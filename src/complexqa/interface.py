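"""Interface analysis: SASA, buried area, contact areas, CAD score, residue classes.

Solvent-accessible surface areas come from a deterministic Shrake-Rupley
quadrature (a fixed golden-spiral point lattice — no RNG, so results are
bit-reproducible and refine monotonically with ``n_points``).  Residue-residue
contact areas are estimated by apportioning each atom's SASA burial among the
partner-side residues near it; the interface CAD score then compares two
models' contact maps:

    score = 1 - min(1, sum_ij |T_ij - min(M_ij, 2 T_ij)| / sum_ij T_ij)

over the residue pairs with nonzero contact in the target T.  The bounded
difference (min(M, 2T)) keeps the score in [0, 1] under gross over-prediction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from complexqa.model_io import ComplexSpec, StructureModel

__all__ = [
    "ContactMap",
    "InterfaceReport",
    "CadComparison",
    "sasa",
    "buried_interface_area",
    "residue_contact_areas",
    "cad_score_iface",
    "classify_interface",
]

# Element van der Waals radii (Angstrom); heavy atoms only, hydrogens are
# never read in.  Unknown elements fall back to carbon with a warning.
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960

ResKey = tuple[str, int]  # (chain_id, seq_id)


@dataclass
class ContactMap:
    """Inter-group residue contact areas; keys are (receptor_res, ligand_res)."""

    entries: dict[tuple[ResKey, ResKey], float]
    source: str = ""

    @property
    def total_area(self) -> float:
        return float(sum(self.entries.values()))


@dataclass
class InterfaceReport:
    buried_area: float  # per-side convention: half the total SASA loss
    total_buried_area: float
    interface_residues: list[tuple[ResKey, str, str, frozenset[str]]]  # (res, res_name, side, classes)
    contact_map: ContactMap
    notes: list[str] = field(default_factory=list)


@dataclass
class CadComparison:
    score: float
    n_target_contacts: int
    total_target_area: float
    total_abs_diff: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"CAD score {self.score} outside [0, 1]")


def _sphere_points(n: int) -> np.ndarray:
    """Fixed golden-spiral lattice on the unit sphere (deterministic)."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = phi * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _radii_for(elements: list[str]) -> np.ndarray:
    radii = np.empty(len(elements))
    for k, el in enumerate(elements):
        key = el.upper()
        if key not in VDW_RADII:
            warnings.warn(f"unknown element {el!r}: using carbon radius", stacklevel=3)
        radii[k] = VDW_RADII.get(key, VDW_RADII["C"])
    return radii


def sasa_points(coords: np.ndarray, radii: np.ndarray, probe_radius: float = DEFAULT_PROBE,
                n_points: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Per-atom solvent-accessible areas (A^2) by Shrake-Rupley quadrature."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = coords.shape[0]
    if n == 0:
        return np.zeros(0)
    unit = _sphere_points(n_points)
    ext = radii + probe_radius
    tree = cKDTree(coords)
    areas = np.empty(n)
    for i in range(n):
        pts = coords[i] + ext[i] * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], ext[i] + ext.max())
                     if j != i and np.linalg.norm(coords[j] - coords[i]) < ext[i] + ext[j]]
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 > ext[j] ** 2
        areas[i] = 4.0 * math.pi * ext[i] ** 2 * exposed.sum() / n_points
    return areas


def sasa(model: StructureModel, probe_radius: float = DEFAULT_PROBE,
         n_points: int = DEFAULT_N_POINTS, chain_ids: Optional[set[str]] = None) -> np.ndarray:
    """Per-atom SASA for the atoms of ``model`` (optionally one chain group).

    Areas are ordered as ``model.all_atoms(chain_ids)``.
    """
    atoms = model.all_atoms(chain_ids)
    if not atoms:
        raise ValueError("no atoms selected")
    coords = np.array([a.coords for _, a in atoms])
    radii = _radii_for([a.element for _, a in atoms])
    return sasa_points(coords, radii, probe_radius, n_points)


def buried_interface_area(model: StructureModel, spec: ComplexSpec,
                          probe_radius: float = DEFAULT_PROBE,
                          n_points: int = DEFAULT_N_POINTS) -> float:
    """Per-side buried area: (SASA_receptor + SASA_ligand - SASA_complex) / 2."""
    rec = set(spec.receptor_chains) & set(model.chains)
    lig = set(spec.ligand_chains) & set(model.chains)
    if not rec or not lig:
        raise ValueError("model lacks receptor or ligand chains named in the spec")
    s_rec = sasa(model, probe_radius, n_points, rec).sum()
    s_lig = sasa(model, probe_radius, n_points, lig).sum()
    s_all = sasa(model, probe_radius, n_points, rec | lig).sum()
    return float(max(0.0, (s_rec + s_lig - s_all) / 2.0))


def residue_contact_areas(model: StructureModel, spec: ComplexSpec,
                          probe_radius: float = DEFAULT_PROBE,
                          n_points: int = DEFAULT_N_POINTS,
                          d_contact: float = 6.5,
                          min_area: float = 0.1) -> ContactMap:
    """Residue-residue contact areas across the receptor/ligand interface.

    Each atom's SASA burial (alone minus in-complex) is apportioned among
    partner-side residues having any atom within ``d_contact``, weighted by
    1/d^2 of the nearest-atom distance; the (i, j) entry collects burial from
    both sides, so the map total approximates the total SASA loss
    (2x the per-side buried area).  The default ``d_contact`` covers the
    maximal occlusion reach r_i + r_j + 2*probe (~6.2 A for carbon at probe
    1.4 A), so every occluding partner atom can receive its share.
    """
    rec = set(spec.receptor_chains) & set(model.chains)
    lig = set(spec.ligand_chains) & set(model.chains)
    if not rec or not lig:
        raise ValueError("model lacks receptor or ligand chains named in the spec")

    def group_arrays(chain_ids):
        atoms = model.all_atoms(chain_ids)
        coords = np.array([a.coords for _, a in atoms])
        radii = _radii_for([a.element for _, a in atoms])
        reskeys = [(r.chain_id, r.seq_id) for r, _ in atoms]
        return coords, radii, reskeys

    rc, rr, rkeys = group_arrays(rec)
    lc, lr, lkeys = group_arrays(lig)

    # burial per atom: SASA with the partner group absent minus in-complex
    alone_r = sasa_points(rc, rr, probe_radius, n_points)
    alone_l = sasa_points(lc, lr, probe_radius, n_points)
    coords_all = np.vstack([rc, lc])
    radii_all = np.concatenate([rr, lr])
    complex_areas = sasa_points(coords_all, radii_all, probe_radius, n_points)
    burial_r = np.maximum(0.0, alone_r - complex_areas[: len(rc)])
    burial_l = np.maximum(0.0, alone_l - complex_areas[len(rc):])

    entries: dict[tuple[ResKey, ResKey], float] = {}

    def apportion(burials, own_coords, partner_coords, partner_keys, receptor_side: bool):
        tree = cKDTree(partner_coords)
        for i, b in enumerate(burials):
            if b <= 0:
                continue
            idx = tree.query_ball_point(own_coords[i], d_contact)
            if not idx:
                continue
            # nearest-atom distance per partner residue
            nearest: dict[ResKey, float] = {}
            for j in idx:
                d = float(np.linalg.norm(partner_coords[j] - own_coords[i]))
                key = partner_keys[j]
                if key not in nearest or d < nearest[key]:
                    nearest[key] = d
            wsum = sum(1.0 / max(d, 1e-6) ** 2 for d in nearest.values())
            for key, d in nearest.items():
                share = b * (1.0 / max(d, 1e-6) ** 2) / wsum
                own_key = rkeys[i] if receptor_side else lkeys[i]
                pair = (own_key, key) if receptor_side else (key, own_key)
                entries[pair] = entries.get(pair, 0.0) + share

    apportion(burial_r, rc, lc, lkeys, receptor_side=True)
    apportion(burial_l, lc, rc, rkeys, receptor_side=False)

    entries = {k: v for k, v in entries.items() if v >= min_area}
    return ContactMap(entries, source=model.model_id)


def cad_score_iface(target: StructureModel, model: StructureModel, spec: ComplexSpec,
                    probe_radius: float = DEFAULT_PROBE,
                    n_points: int = DEFAULT_N_POINTS) -> CadComparison:
    """Interface contact-area-difference score of ``model`` against ``target``.

    Both models must share residue numbering (receptor-anchor the model
    first for reporting consistency; contact areas themselves are
    frame-invariant).  A target with no interface is an error, not a 0.
    """
    T = residue_contact_areas(target, spec, probe_radius, n_points)
    M = residue_contact_areas(model, spec, probe_radius, n_points)
    if not T.entries:
        raise ValueError(f"target {target.model_id!r} has an empty interface; CAD undefined")
    return cad_from_maps(T.entries, M.entries)


def cad_from_maps(target_areas: dict, model_areas: dict) -> CadComparison:
    """CAD comparison of raw contact-area maps (bounded-difference variant).

    Restricted to pairs with positive area in the target; model areas absent
    there count as 0, and over-predicted areas are capped at twice the
    target's so the score stays in [0, 1].
    """
    entries = {k: v for k, v in target_areas.items() if v > 0}
    if not entries:
        raise ValueError("target contact map is empty; CAD undefined")
    total_t = float(sum(entries.values()))
    total_diff = 0.0
    for pair, t_ij in entries.items():
        m_ij = model_areas.get(pair, 0.0)
        total_diff += abs(t_ij - min(m_ij, 2.0 * t_ij))
    score = 1.0 - min(1.0, total_diff / total_t)
    return CadComparison(score, len(entries), total_t, total_diff)


# --- interface residue classification ---------------------------------------

_BACKBONE = {"N", "CA", "C", "O", "OXT"}
_BASIC_N = {"ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}, "HIS": {"ND1", "NE2"}}
_ACIDIC_O = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}
_APOLAR_RES = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO"}
_TYR_RING = {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}

SALT_BRIDGE_CUTOFF = 4.0
HBOND_CUTOFF = 3.5
HYDROPHOBIC_CUTOFF = 4.5


def _atom_flags(model: StructureModel, chain_ids: set[str]):
    """Per-atom boolean feature arrays for the classification rules."""
    atoms = model.all_atoms(chain_ids)
    coords = np.array([a.coords for _, a in atoms])
    n = len(atoms)
    basic = np.zeros(n, bool)
    acidic = np.zeros(n, bool)
    polar = np.zeros(n, bool)
    apolar_c = np.zeros(n, bool)
    keys = []
    names = []
    first_last: dict[str, tuple[int, int]] = {}
    for cid in chain_ids & set(model.chains):
        res = model.chains[cid]
        first_last[cid] = (res[0].seq_id, res[-1].seq_id)
    for k, (r, a) in enumerate(atoms):
        keys.append((r.chain_id, r.seq_id))
        names.append(r.res_name)
        el = a.element.upper()
        if el in ("N", "O"):
            polar[k] = True
        if a.name in _BASIC_N.get(r.res_name, ()):  # side-chain amine/guanidinium
            basic[k] = True
        if a.name in _ACIDIC_O.get(r.res_name, ()):  # side-chain carboxylate
            acidic[k] = True
        lo, hi = first_last.get(r.chain_id, (None, None))
        if a.name == "N" and r.seq_id == lo:  # chain-terminal amine
            basic[k] = True
        if a.name in ("OXT", "O") and r.seq_id == hi and a.name == "OXT":
            acidic[k] = True
        if el == "C" and a.name not in _BACKBONE:
            if r.res_name in _APOLAR_RES or (r.res_name == "TYR" and a.name in _TYR_RING):
                apolar_c[k] = True
    return atoms, coords, keys, names, basic, acidic, polar, apolar_c


def classify_interface(model: StructureModel, spec: ComplexSpec,
                       probe_radius: float = DEFAULT_PROBE,
                       n_points: int = DEFAULT_N_POINTS) -> InterfaceReport:
    """Buried area, contact map, and salt-bridge/H-bond/hydrophobic classes.

    Rules (heavy atoms only, across the interface):
      * salt_bridge — basic side-chain N (Arg/Lys/His, or chain-terminal
        amine) within 4.0 A of an acidic side-chain O (Asp/Glu, or OXT);
      * hbond — N/O donor-acceptor pair within 3.5 A;
      * hydrophobic — C-C <= 4.5 A, both carbons in apolar side-chain
        moieties (Ala/Val/Leu/Ile/Met/Phe/Trp/Pro side chains, Tyr ring).

    His counts as potentially positive (protonation unresolved; noted in
    the report).
    """
    rec = set(spec.receptor_chains) & set(model.chains)
    lig = set(spec.ligand_chains) & set(model.chains)
    ra, rc, rkeys, rnames, rbasic, racid, rpolar, rapolar = _atom_flags(model, rec)
    la, lc, lkeys, lnames, lbasic, lacid, lpolar, lapolar = _atom_flags(model, lig)

    classes: dict[tuple[ResKey, str], set[str]] = {}
    resnames: dict[ResKey, str] = {}
    for k, n in zip(rkeys, rnames):
        resnames[k] = n
    for k, n in zip(lkeys, lnames):
        resnames[k] = n

    tree = cKDTree(lc)
    pairs = tree.query_ball_point(rc, HYDROPHOBIC_CUTOFF)

    def tag(rk: ResKey, lk: ResKey, label: str):
        classes.setdefault((rk, "receptor"), set()).add(label)
        classes.setdefault((lk, "ligand"), set()).add(label)

    for i, idx in enumerate(pairs):
        for j in idx:
            d = float(np.linalg.norm(rc[i] - lc[j]))
            rk, lk = rkeys[i], lkeys[j]
            if d <= SALT_BRIDGE_CUTOFF and (
                (rbasic[i] and lacid[j]) or (racid[i] and lbasic[j])
            ):
                tag(rk, lk, "salt_bridge")
            if d <= HBOND_CUTOFF and rpolar[i] and lpolar[j]:
                tag(rk, lk, "hbond")
            if d <= HYDROPHOBIC_CUTOFF and rapolar[i] and lapolar[j]:
                tag(rk, lk, "hydrophobic")

    cmap = residue_contact_areas(model, spec, probe_radius, n_points)
    buried = buried_interface_area(model, spec, probe_radius, n_points)

    contacted = {p[0] for p in cmap.entries} | {p[1] for p in cmap.entries}
    residues = []
    seen = set()
    for (key, side), cls in sorted(classes.items()):
        residues.append((key, resnames[key], side, frozenset(cls)))
        seen.add(key)
    for pair in cmap.entries:
        for key, side in zip(pair, ("receptor", "ligand")):
            if key not in seen:
                residues.append((key, resnames[key], side, frozenset()))
                seen.add(key)

    notes = ["His treated as potentially positive for salt bridges"]
    return InterfaceReport(buried, 2.0 * buried, residues, cmap, notes)
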