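"""Synthetic fixtures: toy receptor-peptide complexes, perturbed model
ensembles with fabricated confidence tracks, and one-site ITC thermograms.

The toy complex stands in for a globular receptor (three-helix bundle)
bound by a helical peptide ligand.  Geometry is ideal alpha-helical
(rise 1.5 A/residue, 100 deg/residue twist) with backbone N/CA/C/O, a
C-beta, and one functional-group pseudo-atom per residue placed along the
CA->CB direction at a canonical reach — enough for Calpha metrics, SASA,
and the distance-based interface classifiers, while staying rotamer-free
and fully deterministic.

Ensemble noise emulates the regimes a predictor produces: small receptor
jitter plus a rigid ligand pose perturbation, with optional outlier models
whose ligand is displaced far from the true pose.  Confidence tracks are
fabricated to be *consistent* with the planted interface: models whose
ligand pose is near the truth get high pLDDT and a low cross-chain PAE
block over the planted binding sequence.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from complexqa.itc import BindingModelParams, Thermogram, TitrationProtocol, simulate_titration
from complexqa.model_io import (
    AtomRecord,
    ComplexSpec,
    ModelSet,
    PAEMatrix,
    ResidueView,
    StructureModel,
    sort_and_rank,
)
from complexqa.superpose import RigidTransform, local_rmsd, receptor_anchored_superpose

__all__ = [
    "ToyComplexSpec",
    "EnsembleNoiseSpec",
    "ENSEMBLE_PRESETS",
    "ITC_FIXTURES",
    "make_toy_complex",
    "default_complex_spec",
    "perturb_model_ensemble",
    "fabricate_confidence",
    "generate_itc_fixture",
]

RISE = 1.5  # A per residue
TWIST = math.radians(100.0)
CA_RADIUS = 2.27
N_RADIUS, N_DPHI, N_DZ = 1.58, math.radians(-28.0), -0.70
C_RADIUS, C_DPHI, C_DZ = 1.99, math.radians(25.0), 0.80
CB_LENGTH = 1.53

# functional-group pseudo-atom: (atom name, element, reach from CA along CA->CB)
SIDE_CHAIN_TIP = {
    "ALA": None,
    "GLY": None,
    "ARG": ("NH1", "N", 6.5),
    "LYS": ("NZ", "N", 5.5),
    "HIS": ("NE2", "N", 4.5),
    "ASP": ("OD1", "O", 3.7),
    "GLU": ("OE1", "O", 5.0),
    "SER": ("OG", "O", 2.4),
    "THR": ("OG1", "O", 2.4),
    "ASN": ("OD1", "O", 3.0),
    "GLN": ("OE1", "O", 4.3),
    "LEU": ("CD1", "C", 3.9),
    "ILE": ("CD1", "C", 3.9),
    "VAL": ("CG1", "C", 2.5),
    "MET": ("SD", "S", 4.0),
    "PHE": ("CZ", "C", 5.1),
    "TRP": ("CH2", "C", 5.6),
    "TYR": ("CZ", "C", 5.1),
    "PRO": ("CG", "C", 2.4),
}


@dataclass(frozen=True)
class ToyComplexSpec:
    """Geometry and sequence plan of the planted-truth toy complex."""

    receptor_n_res: int = 90  # three-helix bundle, 3 x 30
    ligand_n_res: int = 24
    ligand_seq_start: int = 1
    planted_mis: tuple[int, int] = (5, 20)  # inclusive, in ligand numbering
    axis_separation: float = 14.0  # ligand axis to receptor helix-1 axis, A
    true_pose: Optional[RigidTransform] = None  # placement of the canonical ligand helix
    salt_bridge: bool = True  # plant a Glu(receptor)-Arg(ligand) pair

    def __post_init__(self) -> None:
        lo, hi = self.planted_mis
        last = self.ligand_seq_start + self.ligand_n_res - 1
        if not (self.ligand_seq_start <= lo <= hi <= last):
            raise ValueError("planted_mis must lie within the ligand numbering")


@dataclass(frozen=True)
class EnsembleNoiseSpec:
    n_models: int = 5
    receptor_jitter_sd: float = 0.15  # A, iid per coordinate
    ligand_rot_sd: float = 2.0  # degrees
    ligand_trans_sd: float = 0.5  # A, iid per coordinate
    n_outliers: int = 0
    outlier_displacement: float = 20.0  # A
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_outliers > self.n_models:
            raise ValueError("n_outliers cannot exceed n_models")
        for name in ("receptor_jitter_sd", "ligand_rot_sd", "ligand_trans_sd",
                     "outlier_displacement"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


# noise presets named after the agreement regimes they emulate:
# full consensus (5/5), majority (3/5), and failure (2/5)
ENSEMBLE_PRESETS = {
    "vac17-like": EnsembleNoiseSpec(n_models=5, receptor_jitter_sd=0.15,
                                    ligand_rot_sd=2.0, ligand_trans_sd=0.4, n_outliers=0),
    "smy1-like": EnsembleNoiseSpec(n_models=5, receptor_jitter_sd=0.15,
                                   ligand_rot_sd=2.0, ligand_trans_sd=0.4,
                                   n_outliers=2, outlier_displacement=20.0),
    "inp2-like": EnsembleNoiseSpec(n_models=5, receptor_jitter_sd=0.15,
                                   ligand_rot_sd=2.0, ligand_trans_sd=0.4,
                                   n_outliers=3, outlier_displacement=20.0),
}


def _helix_atoms(n_res: int, seq_start: int, chain_id: str, res_names: list[str],
                 origin: np.ndarray, direction: int = +1, phase: float = 0.0,
                 serial_start: int = 1,
                 radial_override: Optional[dict[int, np.ndarray]] = None
                 ) -> tuple[list[ResidueView], int]:
    """Ideal helix along +/-z with one pseudo side-chain atom per residue.

    ``radial_override`` repoints the side chain of selected residues (by
    helix index) along an explicit unit vector instead of the natural
    radial direction — used to plant interaction pairs with controlled
    geometry.
    """
    residues = []
    serial = serial_start
    for i in range(n_res):
        phi = phase + i * TWIST
        z = origin[2] + direction * i * RISE
        def cyl(radius: float, dphi: float, dz: float) -> np.ndarray:
            return np.array([
                origin[0] + radius * math.cos(phi + dphi),
                origin[1] + radius * math.sin(phi + dphi),
                z + direction * dz,
            ])
        ca = cyl(CA_RADIUS, 0.0, 0.0)
        n_at = cyl(N_RADIUS, N_DPHI, N_DZ)
        c_at = cyl(C_RADIUS, C_DPHI, C_DZ)
        radial = np.array([math.cos(phi), math.sin(phi), 0.0])
        if radial_override and i in radial_override:
            radial = np.asarray(radial_override[i], dtype=float)
            radial = radial / np.linalg.norm(radial)
        o_at = c_at + 1.23 * np.array([math.cos(phi), math.sin(phi), 0.0])
        name = res_names[i]
        atoms = [
            AtomRecord(serial, "N", "N", n_at),
            AtomRecord(serial + 1, "CA", "C", ca),
            AtomRecord(serial + 2, "C", "C", c_at),
            AtomRecord(serial + 3, "O", "O", o_at),
        ]
        serial += 4
        if name != "GLY":
            cb = ca + CB_LENGTH * radial
            atoms.append(AtomRecord(serial, "CB", "C", cb))
            serial += 1
            tip = SIDE_CHAIN_TIP.get(name)
            if tip is not None:
                tip_name, tip_el, reach = tip
                atoms.append(AtomRecord(serial, tip_name, tip_el, ca + reach * radial))
                serial += 1
        residues.append(ResidueView(chain_id, seq_start + i, name, atoms))
    return residues, serial


def _facing_mask(n_res: int, phase: float, target_dir: np.ndarray,
                 half_angle_deg: float = 40.0) -> np.ndarray:
    """Residues whose radial (side-chain) direction points toward ``target_dir``."""
    cos_min = math.cos(math.radians(half_angle_deg))
    out = np.zeros(n_res, dtype=bool)
    t = target_dir / np.linalg.norm(target_dir)
    for i in range(n_res):
        phi = phase + i * TWIST
        r = np.array([math.cos(phi), math.sin(phi), 0.0])
        out[i] = float(r @ t) >= cos_min
    return out


def make_toy_complex(spec: ToyComplexSpec = ToyComplexSpec()) -> StructureModel:
    """Deterministic receptor(three-helix bundle, chain A) + helical ligand (chain B).

    Interface residues of receptor helix 1 and of the ligand face each other
    as leucines (hydrophobic contacts); one facing pair is Glu(receptor) /
    Arg(ligand) offset along z to form a salt bridge.  Non-facing residues
    are alanine so the bundle and the interface stay clash-free.
    """
    if spec.receptor_n_res % 3 != 0:
        raise ValueError("receptor_n_res must be divisible by 3 (three-helix bundle)")
    per_helix = spec.receptor_n_res // 3
    # bundle helix axes (xy), ligand approaches helix 1 from -y
    axes = [np.array([0.0, 0.0, 0.0]),
            np.array([10.5, 0.0, 0.0]),
            np.array([5.25, 9.1, 0.0])]
    directions = [+1, -1, +1]
    phases = [0.0, math.radians(60.0), math.radians(120.0)]

    lig_dir = np.array([0.0, -1.0, 0.0])
    facing1 = _facing_mask(per_helix, phases[0], lig_dir)

    def angle_off(i: int, phase: float, target: np.ndarray) -> float:
        phi = phase + i * TWIST
        r = np.array([math.cos(phi), math.sin(phi), 0.0])
        return math.acos(max(-1.0, min(1.0, float(r @ target))))

    # receptor sequence: helix 1 interface leucines (one glutamate), alanine elsewhere
    seqs: list[list[str]] = []
    glu_idx = None
    face_positions_r = [i for i in range(per_helix) if facing1[i]]
    for h in range(3):
        names = ["ALA"] * per_helix
        if h == 0:
            for i in face_positions_r:
                names[i] = "LEU"
            if spec.salt_bridge and face_positions_r:
                # the face position pointing most squarely at the ligand
                glu_idx = min(face_positions_r, key=lambda i: angle_off(i, phases[0], lig_dir))
                names[glu_idx] = "GLU"
        seqs.append(names)

    chains: dict[str, list[ResidueView]] = {}
    serial = 1
    receptor: list[ResidueView] = []
    for h in range(3):
        override = {glu_idx: lig_dir} if (h == 0 and glu_idx is not None) else None
        res, serial = _helix_atoms(per_helix, 1 + h * per_helix, "A", seqs[h],
                                   axes[h], directions[h], phases[h], serial,
                                   radial_override=override)
        receptor.extend(res)
    chains["A"] = receptor

    # canonical ligand helix: axis along z at the origin, facing +y toward the receptor
    lig_phase = math.radians(90.0)
    rec_dir = np.array([0.0, 1.0, 0.0])
    facing_l = _facing_mask(spec.ligand_n_res, lig_phase, rec_dir)
    lig_names = ["ALA"] * spec.ligand_n_res
    face_positions = [i for i in range(spec.ligand_n_res) if facing_l[i]]
    for i in face_positions:
        lig_names[i] = "LEU"
    arg_idx = None
    if spec.salt_bridge and glu_idx is not None and face_positions:
        # squarest-facing position, preferring the middle of the peptide
        center = (spec.ligand_n_res - 1) / 2.0
        arg_idx = min(face_positions,
                      key=lambda i: (round(angle_off(i, lig_phase, rec_dir), 3), abs(i - center)))
        lig_names[arg_idx] = "ARG"

    override_l = {arg_idx: rec_dir} if arg_idx is not None else None
    ligand, _ = _helix_atoms(spec.ligand_n_res, spec.ligand_seq_start, "B", lig_names,
                             np.zeros(3), +1, lig_phase, serial,
                             radial_override=override_l)

    if spec.true_pose is not None:
        pose = spec.true_pose
    else:
        # default pose: parallel to receptor helix 1, offset -y; z chosen so the
        # planted Arg tip sits ~2.5 A above the planted Glu tip (salt bridge)
        z_shift = (per_helix - spec.ligand_n_res) * RISE / 2.0
        if glu_idx is not None and arg_idx is not None:
            z_shift = glu_idx * RISE - arg_idx * RISE + 2.5
        pose = RigidTransform(np.eye(3), np.array([0.0, -spec.axis_separation, z_shift]))
    for r in ligand:
        for a in r.atoms:
            a.coords = pose.apply(a.coords)
    chains["B"] = ligand
    return StructureModel("toy_truth", chains, provenance="experimental")


def default_complex_spec(toy: ToyComplexSpec = ToyComplexSpec()) -> ComplexSpec:
    return ComplexSpec(frozenset({"A"}), frozenset({"B"}),
                       fragment=("B", toy.planted_mis[0], toy.planted_mis[1]))


def _random_rotation(rng: np.random.Generator, angle_sd_deg: float) -> np.ndarray:
    angle = math.radians(rng.normal(0.0, angle_sd_deg))
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


def perturb_model_ensemble(truth: StructureModel, noise: EnsembleNoiseSpec,
                           spec: ComplexSpec, recycles: int = 6,
                           stoichiometry: tuple[int, int] = (1, 1)) -> ModelSet:
    """n_models noisy copies of ``truth``: receptor jitter + rigid ligand pose noise.

    The last ``n_outliers`` models get their ligand displaced by
    ``outlier_displacement`` in a random direction instead (far-from-truth
    poses).  Fully reproducible from ``noise.seed``.
    """
    rng = np.random.default_rng(noise.seed)
    models = []
    lig_chains = set(spec.ligand_chains)
    for k in range(noise.n_models):
        m = truth.copy()
        m.model_id = f"model_{k + 1}"
        m.provenance = "predicted"
        for r in m.residues(set(spec.receptor_chains)):
            for a in r.atoms:
                a.coords = a.coords + rng.normal(0.0, noise.receptor_jitter_sd, 3)
        lig_atoms = [a for r in m.residues(lig_chains) for a in r.atoms]
        centroid = np.mean([a.coords for a in lig_atoms], axis=0)
        is_outlier = k >= noise.n_models - noise.n_outliers
        if is_outlier:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            shift = noise.outlier_displacement * direction
            for a in lig_atoms:
                a.coords = a.coords + shift
        else:
            R = _random_rotation(rng, noise.ligand_rot_sd)
            t = rng.normal(0.0, noise.ligand_trans_sd, 3)
            for a in lig_atoms:
                a.coords = R @ (a.coords - centroid) + centroid + t
        models.append(m)
    for rank, m in enumerate(models, start=1):
        m.rank = rank
    return ModelSet(models, [None] * len(models), recycles=recycles,
                    stoichiometry=stoichiometry, labels={"generator": "perturb_model_ensemble"})


def fabricate_confidence(model_set: ModelSet, truth: StructureModel, spec: ComplexSpec,
                         contrast: tuple[float, float, float, float] = (5.0, 25.0, 90.0, 40.0),
                         pose_threshold: float = 4.0,
                         jitter_sd: float = 0.0,
                         seed: int = 0) -> ModelSet:
    """Fill pLDDT B-factors and PAE matrices consistent with the planted interface.

    ``contrast`` = (pae_low, pae_high, plddt_high, plddt_low).  Models whose
    ligand fragment sits within ``pose_threshold`` (A, receptor-anchored
    local RMSD) of the truth get plddt_high over the planted region and a
    pae_low cross-chain block there; everything else gets plddt_low /
    pae_high.  Receptor residues and intra-chain PAE blocks are always
    confident.  Optional zero-mean Gaussian jitter (clipped to valid ranges)
    roughens the tracks; with ``jitter_sd=0`` block values are exact.
    """
    pae_low, pae_high, plddt_high, plddt_low = contrast
    if spec.fragment is None:
        raise ValueError("spec.fragment (the planted binding region) is required")
    frag_chain, frag_lo, frag_hi = spec.fragment
    rng = np.random.default_rng(seed)

    new_models = []
    new_paes = []
    for m in model_set.models:
        anchored, _ = receptor_anchored_superpose(m, truth, spec)
        near_truth = local_rmsd(anchored, truth, spec) <= pose_threshold

        mm = m.copy()
        index = mm.residue_index()
        n = len(index)
        rec_idx = np.array([i for i, (c, _) in enumerate(index) if c in spec.receptor_chains])
        mis_idx = np.array([i for i, (c, s) in enumerate(index)
                            if c == frag_chain and frag_lo <= s <= frag_hi])

        for r in mm.residues():
            in_mis = r.chain_id == frag_chain and frag_lo <= r.seq_id <= frag_hi
            if r.chain_id in spec.receptor_chains or (in_mis and near_truth):
                val = plddt_high
            else:
                val = plddt_low
            if jitter_sd > 0:
                val = float(np.clip(val + rng.normal(0.0, jitter_sd), 0.0, 100.0))
            for a in r.atoms:
                a.bfactor = val

        pae = np.full((n, n), pae_high)
        # intra-chain blocks: confident folds
        for cid in mm.chains:
            pos = np.array([i for i, (c, _) in enumerate(index) if c == cid])
            pae[np.ix_(pos, pos)] = pae_low
        if near_truth and mis_idx.size and rec_idx.size:
            pae[np.ix_(mis_idx, rec_idx)] = pae_low
            pae[np.ix_(rec_idx, mis_idx)] = pae_low
        if jitter_sd > 0:
            pae = np.clip(pae + rng.normal(0.0, jitter_sd, pae.shape), 0.0, None)
        np.fill_diagonal(pae, 0.0)
        new_models.append(mm)
        new_paes.append(PAEMatrix(pae, index))

    out = ModelSet(new_models, new_paes, model_set.recycles, model_set.stoichiometry,
                   dict(model_set.labels, confidence="fabricated"))
    return sort_and_rank(out)


# --- ITC fixtures ------------------------------------------------------------

# generating constants for the named binding fixtures: Kd (M), N, dH (cal/mol),
# syringe and cell concentrations (M).  Kd values follow the reported affinities
# of the corresponding interactions; the dimer fixture divides the monomer Kd by
# the 5-fold dimerization enhancement; the half-sites fixture books the cell
# concentration per protomer with one competent site per dimer (N = 0.5).
ITC_FIXTURES: dict[str, dict] = {
    "vac17": dict(kd=0.3e-6, n=1.0, dh=-11000.0, syringe=200e-6, cell=20e-6),
    "kar9N": dict(kd=16e-6, n=1.0, dh=-7000.0, syringe=500e-6, cell=50e-6),
    "kar9C": dict(kd=3e-6, n=1.0, dh=-9000.0, syringe=500e-6, cell=50e-6),
    "pea2_monomer": dict(kd=50e-6, n=1.0, dh=-6000.0, syringe=500e-6, cell=50e-6),
    "pea2_dimer": dict(kd=10e-6, n=1.0, dh=-6000.0, syringe=500e-6, cell=50e-6),
    "pea2_dimer_halfsites": dict(kd=10e-6, n=0.5, dh=-6000.0, syringe=500e-6, cell=50e-6),
}


def generate_itc_fixture(name: str, noise_sd: float = 0.0,
                         seed: Optional[int] = None
                         ) -> tuple[Thermogram, TitrationProtocol, BindingModelParams]:
    """Simulate a named binding fixture under the standard titration protocol
    (200 uL cell, 13 x 3 uL injections, 25 C)."""
    if name not in ITC_FIXTURES:
        raise ValueError(f"unknown ITC fixture {name!r}; choose from {sorted(ITC_FIXTURES)}")
    fx = ITC_FIXTURES[name]
    protocol = TitrationProtocol(cell_conc=fx["cell"], syringe_conc=fx["syringe"],
                                 cell_volume=200e-6, injection_volume=3e-6,
                                 n_injections=13, temperature=298.15)
    params = BindingModelParams(kd=fx["kd"], n_sites=fx["n"], dh=fx["dh"], q_dilution=0.0)
    thermo = simulate_titration(protocol, params, noise_sd=noise_sd, seed=seed)
    return thermo, protocol, params
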