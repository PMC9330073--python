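"""Ensemble agreement verdicts, recycle convergence, stoichiometry assessment.

A prediction run is trusted when most of its models place the ligand
fragment in the same pose on the receptor.  Models are clustered by
single-linkage on the pairwise receptor-anchored fragment RMSD at a fixed
threshold (default 4 A — the reported ~1 A successes sit far below it,
reversed or misplaced poses far above); the verdict is:

  converged  — largest cluster >= ceil(0.6 n)   (3 of 5)
  failed     — largest cluster <  ceil(0.5 n)   (< 3 of 5)
  partial    — otherwise

Stoichiometry (1:1 vs 1:2 copies given to the predictor) is assessed by
running the same verdict per stoichiometry: a ratio is preferred when it
alone converges; if several converge the one whose cluster representative
buries the larger interface is preferred.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from complexqa.interface import buried_interface_area
from complexqa.model_io import ComplexSpec, ModelSet
from complexqa.superpose import local_rmsd, receptor_anchored_superpose

__all__ = [
    "ConsensusVerdict",
    "StoichiometryAssessment",
    "pairwise_local_rmsd_matrix",
    "consensus_verdict",
    "recycle_convergence",
    "stoichiometry_assessment",
]


@dataclass
class ConsensusVerdict:
    verdict: str  # converged | partial | failed
    cluster_members: list[str]  # model ids of the largest cluster
    representative: Optional[str]
    pairwise_rmsd: np.ndarray
    threshold: float
    model_ids: list[str] = field(default_factory=list)


@dataclass
class StoichiometryAssessment:
    verdicts: dict[str, ConsensusVerdict]
    preferred: str  # a stoichiometry label or "undetermined"
    interface_areas: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def pairwise_local_rmsd_matrix(model_set: ModelSet, spec: ComplexSpec) -> np.ndarray:
    """All-pairs receptor-anchored fragment RMSD, symmetrized by max.

    Entry (a, b) anchors model b onto model a before measuring; the two
    directions differ slightly when receptors differ, so the conservative
    (larger) value is kept on both sides.
    """
    models = model_set.models
    n = len(models)
    if n < 2:
        raise ValueError("need >= 2 models for a pairwise matrix")
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            try:
                moved, _ = receptor_anchored_superpose(models[j], models[i], spec)
                M[i, j] = local_rmsd(moved, models[i], spec)
            except ValueError as exc:
                raise ValueError(
                    f"superposition failed for pair ({models[i].model_id!r}, "
                    f"{models[j].model_id!r}): {exc}"
                ) from exc
    return np.maximum(M, M.T)


def consensus_verdict(matrix: np.ndarray, threshold: float = 4.0,
                      model_ids: Optional[Sequence[str]] = None,
                      model_ranks: Optional[Sequence[int]] = None) -> ConsensusVerdict:
    """Cluster models by single-linkage at ``threshold`` and issue a verdict.

    Single-linkage clusters are the connected components of the graph whose
    edges are pairs with RMSD <= threshold.  Ties between equal-size
    clusters, and the cluster representative, go to the lowest model rank.
    """
    M = np.asarray(matrix, dtype=float)
    n = M.shape[0]
    if M.shape != (n, n) or not np.allclose(M, M.T, atol=1e-9):
        raise ValueError("matrix must be square and symmetric")
    ids = list(model_ids) if model_ids is not None else [f"model_{i+1}" for i in range(n)]
    ranks = list(model_ranks) if model_ranks is not None else list(range(1, n + 1))

    adj = csr_matrix((M <= threshold).astype(int))
    n_comp, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    best_size = sizes.max()
    # tie-break between equal-size clusters: the one containing the best rank
    tied = [c for c in range(n_comp) if sizes[c] == best_size]
    best = min(tied, key=lambda c: min(ranks[i] for i in range(n) if labels[i] == c))
    members = [i for i in range(n) if labels[i] == best]
    rep = min(members, key=lambda i: ranks[i])

    need_converged = math.ceil(0.6 * n)
    need_not_failed = math.ceil(0.5 * n)
    if best_size >= need_converged:
        verdict = "converged"
    elif best_size < need_not_failed:
        verdict = "failed"
    else:
        verdict = "partial"
    return ConsensusVerdict(verdict, [ids[i] for i in members], ids[rep], M, threshold, ids)


def verdict_for_set(model_set: ModelSet, spec: ComplexSpec,
                    threshold: float = 4.0) -> ConsensusVerdict:
    matrix = pairwise_local_rmsd_matrix(model_set, spec)
    ids = [m.model_id for m in model_set.models]
    ranks = [m.rank if m.rank is not None else i + 1 for i, m in enumerate(model_set.models)]
    return consensus_verdict(matrix, threshold, ids, ranks)


def recycle_convergence(sets: Sequence[ModelSet], spec: ComplexSpec,
                        threshold: float = 4.0) -> tuple[Optional[int], list[tuple[int, str]]]:
    """Minimal recycle count whose ensemble converges, plus the full vector.

    Convergence is not assumed monotone in recycles; every set is assessed
    and reported.  Returns (first converged recycle count or None, the list
    of (recycles, verdict) pairs in ascending recycle order).
    """
    ordered = sorted(sets, key=lambda s: s.recycles)
    results = []
    first: Optional[int] = None
    for s in ordered:
        v = verdict_for_set(s, spec, threshold)
        results.append((s.recycles, v.verdict))
        if first is None and v.verdict == "converged":
            first = s.recycles
    return first, results


def stoichiometry_assessment(sets: dict[str, ModelSet], spec_by_label: dict[str, ComplexSpec],
                             threshold: float = 4.0) -> StoichiometryAssessment:
    """Compare prediction runs made at different declared stoichiometries.

    A stoichiometry is preferred when it is the only converged one; when
    several converge, the one whose cluster representative has the larger
    buried interface wins, with a warning on (near-)ties; when none
    converge, the result is "undetermined".
    """
    if len(sets) < 2:
        raise ValueError("need >= 2 stoichiometries to compare")
    verdicts: dict[str, ConsensusVerdict] = {}
    areas: dict[str, float] = {}
    warnings: list[str] = []
    for label, mset in sets.items():
        spec = spec_by_label[label]
        v = verdict_for_set(mset, spec, threshold)
        verdicts[label] = v
        if v.verdict == "converged":
            rep = next(m for m in mset.models if m.model_id == v.representative)
            areas[label] = buried_interface_area(rep, spec)

    converged = [l for l, v in verdicts.items() if v.verdict == "converged"]
    if len(converged) == 1:
        preferred = converged[0]
    elif len(converged) == 0:
        preferred = "undetermined"
    else:
        ranked = sorted(converged, key=lambda l: -areas[l])
        if len(ranked) > 1 and math.isclose(areas[ranked[0]], areas[ranked[1]], rel_tol=0.05):
            preferred = "undetermined"
            warnings.append(
                f"multiple stoichiometries converge with comparable interfaces: "
                f"{ranked[0]} ({areas[ranked[0]]:.0f} A^2) vs {ranked[1]} ({areas[ranked[1]]:.0f} A^2)"
            )
        else:
            preferred = ranked[0]
            warnings.append("multiple stoichiometries converge; preferring larger interface")
    return StoichiometryAssessment(verdicts, preferred, areas, warnings)
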