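"""Binding-region calling from confidence tracks.

The receptor-binding sequence of a disordered adaptor shows up in the
predictor's confidence output as a ligand segment with high pLDDT and a low
cross-chain PAE block against the receptor.  ``call_binding_region`` turns
those tracks into intervals per model and keeps intervals supported by
enough of the ensemble; ``aggregate_truncation_scan`` combines calls over a
series of truncation constructs into a residue-level vote.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from complexqa.model_io import ComplexSpec, PAEMatrix, StructureModel

__all__ = [
    "ConfidenceProfile",
    "RegionCall",
    "confidence_profile",
    "call_binding_region",
    "aggregate_truncation_scan",
]

Interval = tuple[str, int, int]  # (chain, start, end) inclusive


@dataclass
class ConfidenceProfile:
    """Per-ligand-residue confidence: pLDDT and cross-chain PAE summaries."""

    records: list[tuple[str, int, float, float, float]]
    # (chain, seq_id, plddt, cross_pae_min, cross_pae_mean)
    model_id: str = ""

    def arrays(self):
        chains = [r[0] for r in self.records]
        seq = np.array([r[1] for r in self.records])
        plddt = np.array([r[2] for r in self.records])
        pae_min = np.array([r[3] for r in self.records])
        return chains, seq, plddt, pae_min


@dataclass
class RegionCall:
    intervals: list[Interval]
    support: list[float]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(not 0.0 <= s <= 1.0 for s in self.support):
            raise ValueError("support fractions must lie in [0, 1]")


def confidence_profile(model: StructureModel, pae: PAEMatrix, spec: ComplexSpec) -> ConfidenceProfile:
    """pLDDT + symmetrized cross-chain PAE (min and mean over receptor residues).

    PAE is asymmetric; entries (i, j) and (j, i) are symmetrized by their
    mean, so the profile is invariant to transposing the matrix.
    """
    lig_pos = np.concatenate([pae.positions(c) for c in sorted(spec.ligand_chains)
                              if len(pae.positions(c))] or [np.array([], dtype=int)])
    rec_pos = np.concatenate([pae.positions(c) for c in sorted(spec.receptor_chains)
                              if len(pae.positions(c))] or [np.array([], dtype=int)])
    if lig_pos.size == 0:
        raise ValueError("ligand chains absent from PAE index map")
    if rec_pos.size == 0:
        raise ValueError("receptor chains absent from PAE index map")
    sym = 0.5 * (pae.values + pae.values.T)
    cross = sym[np.ix_(lig_pos, rec_pos)]
    plddt_by_key = {(r.chain_id, r.seq_id): r.plddt for r in model.residues(set(spec.ligand_chains))}
    records = []
    for row, idx in enumerate(lig_pos):
        chain, seq_id = pae.index_map[idx]
        records.append((
            chain, seq_id,
            float(plddt_by_key.get((chain, seq_id), np.nan)),
            float(cross[row].min()),
            float(cross[row].mean()),
        ))
    return ConfidenceProfile(records, model_id=model.model_id)


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving mean with edge shrinkage (window clipped at the ends)."""
    if window <= 1:
        return x.astype(float)
    half = window // 2
    out = np.empty(len(x))
    for i in range(len(x)):
        lo, hi = max(0, i - half), min(len(x), i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


def _runs(mask: np.ndarray, seq: np.ndarray, chain: str, min_len: int) -> list[Interval]:
    intervals = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            if i - start >= min_len:
                intervals.append((chain, int(seq[start]), int(seq[i - 1])))
            start = None
    if start is not None and len(mask) - start >= min_len:
        intervals.append((chain, int(seq[start]), int(seq[-1])))
    return intervals


def _reciprocal_overlap(a: Interval, b: Interval) -> float:
    if a[0] != b[0]:
        return 0.0
    inter = min(a[2], b[2]) - max(a[1], b[1]) + 1
    if inter <= 0:
        return 0.0
    return min(inter / (a[2] - a[1] + 1), inter / (b[2] - b[1] + 1))


def call_binding_region(
    profiles: Sequence[ConfidenceProfile],
    plddt_min: float = 70.0,
    pae_max: float = 10.0,
    window: int = 5,
    min_len: int = 6,
    support_min: float = 0.6,
) -> RegionCall:
    """Consensus binding-region call over an ensemble of confidence profiles.

    Per model, a ligand residue is bound-like when the smoothed pLDDT is
    >= ``plddt_min`` and the smoothed minimum cross-chain PAE is
    <= ``pae_max``; maximal runs of >= ``min_len`` residues become candidate
    intervals.  Candidates are merged across models at >= 50% reciprocal
    overlap and kept when supported by >= ``support_min`` of the models.
    An empty call is a valid result.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    n_models = len(profiles)
    candidates: list[tuple[int, Interval]] = []  # (model index, interval)
    for mi, prof in enumerate(profiles):
        chains, seq, plddt, pae_min = prof.arrays()
        for chain in dict.fromkeys(chains):  # preserve order
            sel = np.array([c == chain for c in chains])
            s_plddt = _smooth(plddt[sel], window)
            s_pae = _smooth(pae_min[sel], window)
            mask = (s_plddt >= plddt_min) & (s_pae <= pae_max)
            for iv in _runs(mask, seq[sel], chain, min_len):
                candidates.append((mi, iv))

    # single-linkage grouping of intervals at >= 50% reciprocal overlap
    parent = list(range(len(candidates)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            if _reciprocal_overlap(candidates[i][1], candidates[j][1]) >= 0.5:
                parent[find(i)] = find(j)
    by_root: dict[int, list[tuple[int, Interval]]] = {}
    for i, item in enumerate(candidates):
        by_root.setdefault(find(i), []).append(item)
    groups = list(by_root.values())

    intervals: list[Interval] = []
    support: list[float] = []
    for g in groups:
        models_supporting = {mi for mi, _ in g}
        frac = len(models_supporting) / n_models
        if frac < support_min:
            continue
        chain = g[0][1][0]
        start = int(round(np.median([iv[1] for _, iv in g])))
        end = int(round(np.median([iv[2] for _, iv in g])))
        intervals.append((chain, start, end))
        support.append(frac)

    order = np.argsort([iv[1] for iv in intervals]) if intervals else []
    intervals = [intervals[i] for i in order]
    support = [support[i] for i in order]
    params = dict(plddt_min=plddt_min, pae_max=pae_max, window=window,
                  min_len=min_len, support_min=support_min, n_models=n_models)
    return RegionCall(intervals, support, params)


def aggregate_truncation_scan(
    calls: Sequence[tuple[Interval, RegionCall]],
    score_min: float = 0.5,
) -> RegionCall:
    """Combine calls across truncation constructs by residue-level vote.

    Each construct covers an interval of the ligand sequence; a residue's
    score is (constructs covering it whose call includes it) / (constructs
    covering it), so a construct that lacks the region entirely never votes
    against it.  Maximal runs with score >= ``score_min`` are returned.
    """
    if len(calls) < 2:
        raise ValueError("need at least two constructs")
    chain = calls[0][0][0]
    lo = min(b[1] for b, _ in calls)
    hi = max(b[2] for b, _ in calls)
    # construct boundaries must tile a common region
    if not any(
        min(a[2], b[2]) >= max(a[1], b[1])
        for i, (a, _) in enumerate(calls) for b, _ in [calls[j] for j in range(i + 1, len(calls))]
    ):
        raise ValueError("constructs share no overlapping residues")
    seq = np.arange(lo, hi + 1)
    covered = np.zeros(len(seq))
    called = np.zeros(len(seq))
    for (bchain, bstart, bend), call in calls:
        if bchain != chain:
            raise ValueError("all constructs must be on the same chain")
        cov = (seq >= bstart) & (seq <= bend)
        covered += cov
        hit = np.zeros(len(seq), dtype=bool)
        for (ichain, istart, iend) in call.intervals:
            if ichain == chain:
                hit |= (seq >= istart) & (seq <= iend)
        called += hit & cov
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(covered > 0, called / np.maximum(covered, 1), 0.0)
    mask = score >= score_min
    mask &= covered > 0
    intervals = _runs(mask, seq, chain, min_len=1)
    support = []
    for (c, s, e) in intervals:
        sel = (seq >= s) & (seq <= e)
        support.append(float(score[sel].mean()))
    return RegionCall(intervals, support, params=dict(score_min=score_min))
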