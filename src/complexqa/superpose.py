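"""Rigid-body superposition and receptor-anchored local RMSD.

The pose-agreement metric used throughout: superpose two models on the
*receptor* Calpha atoms only (Kabsch least-squares fit), then measure the
RMSD of the ligand-fragment Calpha atoms *without refitting* — so the number
reflects how differently the ligand sits on the receptor, not how similar
the ligand conformations are internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from complexqa.model_io import ComplexSpec, StructureModel

__all__ = [
    "RigidTransform",
    "SuperpositionResult",
    "kabsch_fit",
    "receptor_anchored_superpose",
    "local_rmsd",
    "per_residue_ca_distance",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation; applied as x -> R @ x + t."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation has det != +1 (reflection)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    anchor_rmsd: float  # RMSD over the receptor Calpha used for fitting
    n_atoms_used: int
    n_unmatched: int = 0


def kabsch_fit(
    mobile: Sequence, target: Sequence, weights: Optional[Sequence] = None
) -> tuple[RigidTransform, float]:
    """Least-squares rigid fit of ``mobile`` onto ``target`` (Kabsch, SVD).

    Returns the transform minimizing the weighted RMSD and that RMSD.
    Reflections are excluded (det = +1).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"point sets differ in shape: {P.shape} vs {Q.shape}")
    if P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("points must be (n, 3)")
    n = P.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 points to fit, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be nonnegative, length n, with positive sum")
        w = w / w.sum()

    mu_p = w @ P
    mu_q = w @ Q
    Pc = P - mu_p
    Qc = Q - mu_q
    H = (Pc * w[:, None]).T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_q - R @ mu_p
    transform = RigidTransform(R, t)
    diff = transform.apply(P) - Q
    rmsd = float(np.sqrt(np.sum(w * np.einsum("ij,ij->i", diff, diff))))
    return transform, rmsd


def _common_ca(model_a: StructureModel, model_b: StructureModel,
               chain_ids: set[str]) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int]], int]:
    """Pair Calpha atoms by identical (chain_id, seq_id); report unmatched count."""
    ca_a = model_a.ca_map(chain_ids)
    ca_b = model_b.ca_map(chain_ids)
    keys = [k for k in ca_a if k in ca_b]
    unmatched = len(set(ca_a) ^ set(ca_b))
    A = np.array([ca_a[k] for k in keys]) if keys else np.empty((0, 3))
    B = np.array([ca_b[k] for k in keys]) if keys else np.empty((0, 3))
    return A, B, keys, unmatched


def transform_model(model: StructureModel, transform: RigidTransform) -> StructureModel:
    """Return a copy of ``model`` with every atom moved by ``transform``."""
    out = model.copy()
    for r in out.residues():
        for a in r.atoms:
            a.coords = transform.apply(a.coords)
    return out


def receptor_anchored_superpose(
    model: StructureModel, reference: StructureModel, spec: ComplexSpec
) -> tuple[StructureModel, SuperpositionResult]:
    """Fit ``model`` onto ``reference`` using receptor Calpha only.

    All chains of ``model`` (receptor and ligand alike) are moved by the
    receptor-fit transform; residues are paired by identical
    (chain_id, seq_id) and unmatched ones are excluded from the fit.
    """
    mobile, target, keys, unmatched = _common_ca(model, reference, set(spec.receptor_chains))
    if len(keys) < 3:
        raise ValueError(
            f"only {len(keys)} common receptor Calpha between {model.model_id!r} "
            f"and {reference.model_id!r}; need >= 3"
        )
    transform, rmsd = kabsch_fit(mobile, target)
    moved = transform_model(model, transform)
    return moved, SuperpositionResult(transform, rmsd, len(keys), unmatched)


def _fragment_ca_pairs(model_a: StructureModel, model_b: StructureModel,
                       spec: ComplexSpec) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int]]]:
    frag_a = {(r.chain_id, r.seq_id): r.ca.coords
              for r in spec.fragment_residues(model_a) if r.ca is not None}
    frag_b = {(r.chain_id, r.seq_id): r.ca.coords
              for r in spec.fragment_residues(model_b) if r.ca is not None}
    keys = [k for k in frag_a if k in frag_b]
    A = np.array([frag_a[k] for k in keys]) if keys else np.empty((0, 3))
    B = np.array([frag_b[k] for k in keys]) if keys else np.empty((0, 3))
    return A, B, keys


def local_rmsd(model_a: StructureModel, model_b: StructureModel, spec: ComplexSpec) -> float:
    """Fragment Calpha RMSD in the current frame — no refitting.

    Both models must already share a frame (apply
    :func:`receptor_anchored_superpose` first).
    """
    A, B, keys = _fragment_ca_pairs(model_a, model_b, spec)
    if not keys:
        raise ValueError("no common fragment Calpha between models")
    return float(np.sqrt(np.mean(np.sum((A - B) ** 2, axis=1))))


def per_residue_ca_distance(
    model_a: StructureModel, model_b: StructureModel, spec: ComplexSpec
) -> list[tuple[str, int, float]]:
    """Per-residue Calpha displacement over the ligand chains, in file order.

    The RMS of these distances over the fragment equals :func:`local_rmsd`.
    """
    ca_a = model_a.ca_map(set(spec.ligand_chains))
    ca_b = model_b.ca_map(set(spec.ligand_chains))
    out = []
    for r in model_a.residues(set(spec.ligand_chains)):
        key = (r.chain_id, r.seq_id)
        if key in ca_a and key in ca_b:
            d = float(np.linalg.norm(ca_a[key] - ca_b[key]))
            out.append((r.chain_id, r.seq_id, d))
    return out
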