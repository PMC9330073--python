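"""Structure and confidence I/O: models, PAE matrices, ranked ensembles.

Predicted models arrive as PDB/mmCIF files with pLDDT in the B-factor
column; the matching PAE matrix is a square JSON array (residues
concatenated chain by chain, values in Angstrom).  Experimental reference
structures use the same container with ``provenance="experimental"``.

Parsing is delegated to :mod:`gemmi`; this module owns the in-memory data
model and its invariants (altloc resolution, water/hydrogen stripping,
pLDDT bookkeeping, ensemble ranking).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "ResidueView",
    "StructureModel",
    "PAEMatrix",
    "ModelSet",
    "ComplexSpec",
    "read_structure",
    "write_structure",
    "read_pae",
    "assemble_model_set",
]


@dataclass
class AtomRecord:
    """One heavy atom.  ``bfactor`` carries pLDDT (0-100) for predicted models."""

    serial: int
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class ResidueView:
    chain_id: str
    seq_id: int  # author numbering, preserved verbatim
    res_name: str
    atoms: list[AtomRecord]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.chain_id}/{self.seq_id} has no atoms")

    def atom(self, name: str) -> Optional[AtomRecord]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Optional[AtomRecord]:
        return self.atom("CA")

    @property
    def plddt(self) -> float:
        """Per-residue confidence, read from the Calpha B-factor."""
        a = self.ca or self.atoms[0]
        return a.bfactor


@dataclass
class StructureModel:
    """One structure: ordered chains of ordered residues.

    ``provenance`` is ``"predicted"`` or ``"experimental"``; ``rank`` is the
    1-based pLDDT rank within its ensemble, assigned by
    :func:`assemble_model_set`.
    """

    model_id: str
    chains: dict[str, list[ResidueView]]
    provenance: str = "predicted"
    rank: Optional[int] = None

    def __post_init__(self) -> None:
        if self.provenance not in ("predicted", "experimental"):
            raise ValueError(f"provenance must be predicted|experimental, got {self.provenance!r}")
        for cid, residues in self.chains.items():
            seq = [r.seq_id for r in residues]
            if any(b <= a for a, b in zip(seq, seq[1:])):
                raise ValueError(f"chain {cid}: residues not strictly ordered by seq_id")

    def residues(self, chain_ids: Optional[set[str]] = None) -> Iterator[ResidueView]:
        for cid, residues in self.chains.items():
            if chain_ids is None or cid in chain_ids:
                yield from residues

    @property
    def n_residues(self) -> int:
        return sum(len(r) for r in self.chains.values())

    @property
    def mean_plddt(self) -> float:
        vals = [r.plddt for r in self.residues()]
        return float(np.mean(vals)) if vals else math.nan

    def residue_index(self) -> list[tuple[str, int]]:
        """(chain_id, seq_id) in model order — the PAE concatenation order."""
        return [(r.chain_id, r.seq_id) for r in self.residues()]

    def ca_map(self, chain_ids: Optional[set[str]] = None) -> dict[tuple[str, int], np.ndarray]:
        out: dict[tuple[str, int], np.ndarray] = {}
        for r in self.residues(chain_ids):
            if r.ca is not None:
                out[(r.chain_id, r.seq_id)] = r.ca.coords
        return out

    def all_atoms(self, chain_ids: Optional[set[str]] = None) -> list[tuple[ResidueView, AtomRecord]]:
        return [(r, a) for r in self.residues(chain_ids) for a in r.atoms]

    def copy(self) -> "StructureModel":
        chains = {
            cid: [
                ResidueView(r.chain_id, r.seq_id, r.res_name,
                            [replace(a, coords=a.coords.copy()) for a in r.atoms])
                for r in residues
            ]
            for cid, residues in self.chains.items()
        }
        return StructureModel(self.model_id, chains, self.provenance, self.rank)


@dataclass
class PAEMatrix:
    """Square predicted-aligned-error matrix with its residue index map."""

    values: np.ndarray  # (n, n), Angstrom
    index_map: list[tuple[str, int]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.index_map)
        if self.values.shape != (n, n):
            raise ValueError(f"PAE matrix shape {self.values.shape} vs index map length {n}")
        if np.any(self.values < 0):
            raise ValueError("PAE values must be nonnegative")

    def positions(self, chain_id: str) -> np.ndarray:
        return np.array([i for i, (c, _) in enumerate(self.index_map) if c == chain_id], dtype=int)


@dataclass
class ModelSet:
    """The ranked models of one prediction run plus run settings."""

    models: list[StructureModel]
    pae: list[Optional[PAEMatrix]]
    recycles: int = 3
    stoichiometry: tuple[int, int] = (1, 1)
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("ModelSet requires at least one model")
        if len(self.pae) != len(self.models):
            raise ValueError("one PAE entry (possibly None) per model required")
        if self.recycles < 1:
            raise ValueError("recycles must be a positive integer")
        ref = self.models[0].residue_index()
        for m in self.models[1:]:
            if m.residue_index() != ref:
                raise ValueError(
                    f"model {m.model_id!r}: chain composition differs from {self.models[0].model_id!r}"
                )


@dataclass(frozen=True)
class ComplexSpec:
    """Which chains are receptor vs ligand, and the ligand fragment of interest.

    ``fragment`` is an inclusive (chain_id, start, end) interval in author
    numbering — the binding-sequence window used for local RMSD.
    """

    receptor_chains: frozenset[str]
    ligand_chains: frozenset[str]
    fragment: Optional[tuple[str, int, int]] = None

    def __post_init__(self) -> None:
        rec = frozenset(self.receptor_chains)
        lig = frozenset(self.ligand_chains)
        object.__setattr__(self, "receptor_chains", rec)
        object.__setattr__(self, "ligand_chains", lig)
        if not rec or not lig:
            raise ValueError("receptor and ligand chain sets must be nonempty")
        if rec & lig:
            raise ValueError(f"receptor/ligand chain sets overlap: {sorted(rec & lig)}")
        if self.fragment is not None:
            cid, start, end = self.fragment
            if cid not in lig:
                raise ValueError(f"fragment chain {cid!r} is not a ligand chain")
            if end < start:
                raise ValueError("fragment end precedes start")

    def fragment_residues(self, model: StructureModel) -> list[ResidueView]:
        if self.fragment is None:
            return [r for r in model.residues(set(self.ligand_chains))]
        cid, start, end = self.fragment
        return [r for r in model.chains.get(cid, []) if start <= r.seq_id <= end]


# --- reading -----------------------------------------------------------------

_WATERS = {"HOH", "WAT", "DOD"}


def read_structure(path, format: str = "auto", model_id: Optional[str] = None,
                   provenance: str = "predicted") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties: first in file); waters and hydrogens are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path} as {format}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no models in file")
    st.setup_entities()
    gmodel = st[0]

    chains: dict[str, list[ResidueView]] = {}
    for chain in gmodel:
        residues: list[ResidueView] = []
        for res in chain:
            if res.name in _WATERS:
                continue
            # altloc policy: highest occupancy wins, ties -> first in file
            best: dict[str, AtomRecord] = {}
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                rec = AtomRecord(
                    serial=atom.serial,
                    name=atom.name,
                    element=atom.element.name,
                    coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occupancy=min(max(atom.occ, 0.0), 1.0),
                    bfactor=atom.b_iso,
                )
                prev = best.get(atom.name)
                if prev is None or rec.occupancy > prev.occupancy:
                    best[atom.name] = rec
            if best:
                residues.append(ResidueView(chain.name, res.seqid.num, res.name, list(best.values())))
        if residues:
            chains[chain.name] = residues
    if not chains:
        raise ValueError(f"{path}: empty model (no non-water heavy atoms)")
    return StructureModel(model_id or path.stem, chains, provenance=provenance)


def write_structure(model: StructureModel, path) -> None:
    """Write a model as PDB (or mmCIF if the suffix says so)."""
    st = gemmi.Structure()
    st.name = model.model_id
    gm = gemmi.Model("1")
    for cid, residues in model.chains.items():
        ch = gemmi.Chain(cid)
        for r in residues:
            gr = gemmi.Residue()
            gr.name = r.res_name
            gr.seqid = gemmi.SeqId(r.seq_id, " ")
            for a in r.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coords)
                ga.occ = a.occupancy
                ga.b_iso = a.bfactor
                ga.serial = a.serial
                gr.add_atom(ga)
            ch.add_residue(gr)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    path = Path(path)
    if path.suffix.lower() in (".cif", ".mmcif"):
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))


def read_pae(path, model: StructureModel) -> PAEMatrix:
    """Read a PAE JSON file and align it to ``model``'s residue order.

    Accepts a flat square array, ``{"predicted_aligned_error": [[...]]}``
    (also ``"pae"``), or a one-element list wrapping either dict — the
    shapes AlphaFold-class pipelines emit.
    """
    with open(path) as fh:
        obj = json.load(fh)
    if isinstance(obj, list) and len(obj) == 1 and isinstance(obj[0], dict):
        obj = obj[0]
    if isinstance(obj, dict):
        for key in ("predicted_aligned_error", "pae"):
            if key in obj:
                obj = obj[key]
                break
        else:
            raise ValueError(f"{path}: no PAE array found in JSON object")
    values = np.asarray(obj, dtype=float)
    index_map = model.residue_index()
    n = len(index_map)
    if values.shape != (n, n):
        raise ValueError(
            f"{path}: PAE dimension {values.shape[0]}x{values.shape[-1] if values.ndim > 1 else 1} "
            f"does not match model residue count {n}"
        )
    return PAEMatrix(values, index_map)


def write_pae(pae_values: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        json.dump({"predicted_aligned_error": np.asarray(pae_values).tolist()}, fh)


def assemble_model_set(
    paths: Sequence, pae_paths: Optional[Sequence] = None, recycles: int = 3,
    stoichiometry: tuple[int, int] = (1, 1), labels: Optional[dict] = None,
) -> ModelSet:
    """Read models (+ optional PAE files), rank by descending mean pLDDT.

    Ranking is invariant to the input file order; ties break by model_id so
    the result is deterministic.
    """
    models = [read_structure(p) for p in paths]
    if pae_paths is None:
        paes: list[Optional[PAEMatrix]] = [None] * len(models)
    else:
        if len(pae_paths) != len(paths):
            raise ValueError("pae_paths must match paths one-to-one (use None entries to skip)")
        paes = [read_pae(pp, m) if pp is not None else None for pp, m in zip(pae_paths, models)]
    order = sorted(range(len(models)), key=lambda i: (-models[i].mean_plddt, models[i].model_id))
    models = [models[i] for i in order]
    paes = [paes[i] for i in order]
    for rank, m in enumerate(models, start=1):
        m.rank = rank
    return ModelSet(models, paes, recycles=recycles, stoichiometry=stoichiometry,
                    labels=labels or {})


def sort_and_rank(model_set: ModelSet) -> ModelSet:
    """Re-rank an in-memory ModelSet by descending mean pLDDT."""
    order = sorted(range(len(model_set.models)),
                   key=lambda i: (-model_set.models[i].mean_plddt, model_set.models[i].model_id))
    models = [model_set.models[i] for i in order]
    paes = [model_set.pae[i] for i in order]
    for rank, m in enumerate(models, start=1):
        m.rank = rank
    return ModelSet(models, paes, model_set.recycles, model_set.stoichiometry, model_set.labels)
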