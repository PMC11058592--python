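"""Topology / ensemble data model and structure + table I/O.

The central container is :class:`ReplicaEnsemble`: coordinates in Å indexed
by ``(replica, frame, atom, xyz)`` bound to one :class:`Topology`.  Two
on-disk trajectory representations are supported and interchangeable:

* multi-model PDB (one MODEL per frame, one file per replica), and
* a plain tabular frame format: tab-delimited text with header
  ``replica  frame  atom_id  x  y  z`` and 6-decimal coordinates, one row
  per atom per frame.  It is diffable and versionable, which is what the
  synthetic ensembles are stored in.

Residues are keyed by ``(chain_id, residue_index)``; insertion codes are
rejected.  HETATM records are read as ordinary atoms.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as _pdbio

from .errors import (
    AtomCountMismatchError,
    FrameNumberingError,
    InsertionCodeError,
    ModelNotFoundError,
    PDBFormatError,
    SelectionError,
)

__all__ = [
    "Topology",
    "AtomIndexSet",
    "ReplicaEnsemble",
    "ReferenceState",
    "read_structure",
    "write_structure",
    "read_ensemble",
    "write_tabular_frames",
    "write_per_residue_scores",
    "TABULAR_HEADER",
]

TABULAR_HEADER = ("replica", "frame", "atom_id", "x", "y", "z")

#: Atomic masses in amu for the elements that occur in protein systems.
ELEMENT_MASSES: Mapping[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38, "MG": 24.305,
    "CA": 40.078, "NA": 22.990, "CL": 35.45, "K": 39.098, "MN": 54.938,
}


def _element_mass(element: str) -> float:
    m = ELEMENT_MASSES.get(element.upper().strip())
    if m is None:
        # fall back to carbon for exotic/unknown elements; masses only
        # matter for COM selections, which users control explicitly
        return 12.011
    return m


@dataclass(frozen=True)
class Topology:
    """Ordered atom table shared by every frame of an ensemble.

    Parameters are parallel arrays over atoms.  ``atom_ids`` must be unique;
    they are the public handles used by :class:`AtomIndexSet`.
    """

    atom_ids: np.ndarray          # int, unique
    atom_names: np.ndarray        # str
    elements: np.ndarray          # str
    residue_indices: np.ndarray   # int
    residue_names: np.ndarray     # str, 3-letter codes
    chain_ids: np.ndarray         # str
    masses: np.ndarray            # amu, > 0

    def __post_init__(self):
        n = len(self.atom_ids)
        for name in ("atom_names", "elements", "residue_indices",
                     "residue_names", "chain_ids", "masses"):
            if len(getattr(self, name)) != n:
                raise SelectionError(f"topology field {name!r} has wrong length")
        ids = np.asarray(self.atom_ids)
        if len(np.unique(ids)) != n:
            raise SelectionError("atom_ids are not unique")
        if np.any(np.asarray(self.masses) <= 0):
            raise SelectionError("all atom masses must be positive")

    @classmethod
    def from_fields(cls, atom_ids, atom_names, elements, residue_indices,
                    residue_names, chain_ids, masses=None) -> "Topology":
        elements = np.asarray(elements, dtype="U4")
        if masses is None:
            masses = np.array([_element_mass(e) for e in elements])
        return cls(
            atom_ids=np.asarray(atom_ids, dtype=np.int64),
            atom_names=np.asarray(atom_names, dtype="U6"),
            elements=elements,
            residue_indices=np.asarray(residue_indices, dtype=np.int64),
            residue_names=np.asarray(residue_names, dtype="U4"),
            chain_ids=np.asarray(chain_ids, dtype="U4"),
            masses=np.asarray(masses, dtype=float),
        )

    @property
    def n_atoms(self) -> int:
        return len(self.atom_ids)

    @property
    def residues(self) -> pd.DataFrame:
        """Ordered table of (chain_id, residue_index, residue_name)."""
        df = pd.DataFrame({
            "chain_id": self.chain_ids,
            "residue_index": self.residue_indices,
            "residue_name": self.residue_names,
        })
        return df.drop_duplicates(subset=["chain_id", "residue_index"]).reset_index(drop=True)

    # -- selection helpers -------------------------------------------------

    def positions_of(self, atom_ids: Sequence[int]) -> np.ndarray:
        """Map atom_ids to positional indices into the atom arrays."""
        order = np.argsort(self.atom_ids)
        sorted_ids = self.atom_ids[order]
        atom_ids = np.asarray(atom_ids, dtype=np.int64)
        pos = np.searchsorted(sorted_ids, atom_ids)
        bad = (pos >= len(sorted_ids)) | (sorted_ids[np.clip(pos, 0, len(sorted_ids) - 1)] != atom_ids)
        if np.any(bad):
            missing = atom_ids[bad][:5].tolist()
            raise SelectionError(f"atom_ids not in topology: {missing}")
        return order[pos]

    def select(self, *, atom_names: Iterable[str] | None = None,
               residue_range: tuple[int, int] | None = None,
               residue_indices: Iterable[int] | None = None,
               chain_id: str | None = None,
               invert_residues: bool = False,
               label: str = "selection") -> "AtomIndexSet":
        """Build an :class:`AtomIndexSet` by atom name / residue filters.

        ``residue_range`` is inclusive on both ends.  ``invert_residues``
        keeps atoms *outside* the residue filter (used e.g. to fit on the
        rigid scaffold while excluding a mobile loop).
        """
        mask = np.ones(self.n_atoms, dtype=bool)
        if atom_names is not None:
            mask &= np.isin(self.atom_names, list(atom_names))
        if chain_id is not None:
            mask &= self.chain_ids == chain_id
        rmask = np.ones(self.n_atoms, dtype=bool)
        if residue_range is not None:
            lo, hi = residue_range
            rmask &= (self.residue_indices >= lo) & (self.residue_indices <= hi)
        if residue_indices is not None:
            rmask &= np.isin(self.residue_indices, list(residue_indices))
        if invert_residues:
            rmask = ~rmask
        mask &= rmask
        return AtomIndexSet(indices=np.sort(self.atom_ids[mask]), label=label)


@dataclass(frozen=True)
class AtomIndexSet:
    """A sorted, duplicate-free set of atom_ids with a human-readable label."""

    indices: np.ndarray
    label: str = "selection"

    def __post_init__(self):
        idx = np.unique(np.asarray(self.indices, dtype=np.int64))
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def positions(self, topology: Topology) -> np.ndarray:
        return topology.positions_of(self.indices)


@dataclass
class ReplicaEnsemble:
    """Multi-replica, multi-frame coordinates on one topology.

    ``coords`` has shape ``(n_replicas, n_frames, n_atoms, 3)`` in Å.
    """

    topology: Topology
    coords: np.ndarray
    frame_interval_ps: float

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 4 or c.shape[2] != self.topology.n_atoms or c.shape[3] != 3:
            raise AtomCountMismatchError(
                f"coords shape {c.shape} does not match topology with "
                f"{self.topology.n_atoms} atoms")
        if not np.all(np.isfinite(c)):
            raise PDBFormatError("ensemble contains non-finite coordinates")
        if self.frame_interval_ps <= 0:
            raise FrameNumberingError("frame_interval_ps must be positive")
        self.coords = c

    @property
    def n_replicas(self) -> int:
        return self.coords.shape[0]

    @property
    def n_frames(self) -> int:
        return self.coords.shape[1]


@dataclass
class ReferenceState:
    """A single-frame reference conformation for one loop state."""

    name: str
    coords: np.ndarray            # (n_atoms, 3) Å
    loop_selection: AtomIndexSet
    fit_selection: AtomIndexSet

    VALID_NAMES = ("closed", "open", "wide_open")

    def __post_init__(self):
        if self.name not in self.VALID_NAMES:
            raise SelectionError(
                f"reference state name {self.name!r} not in {self.VALID_NAMES}")
        if len(self.loop_selection) == 0:
            raise SelectionError("loop_selection must be non-empty")
        self.coords = np.asarray(self.coords, dtype=float)


# ---------------------------------------------------------------------------
# structure I/O (PDB via biotite)
# ---------------------------------------------------------------------------

def _atomarray_to_topology(arr: struc.AtomArray) -> Topology:
    if np.any(arr.ins_code != ""):
        raise InsertionCodeError(
            "PDB file uses residue insertion codes; renumber residues first")
    n = arr.array_length()
    return Topology.from_fields(
        atom_ids=np.arange(1, n + 1),
        atom_names=arr.atom_name,
        elements=arr.element,
        residue_indices=arr.res_id,
        residue_names=arr.res_name,
        chain_ids=arr.chain_id,
    )


def read_structure(path, model_index: int = 1) -> tuple[Topology, np.ndarray]:
    """Read one MODEL of a PDB file.

    Returns the topology and the model's ``(n_atoms, 3)`` coordinates in Å.
    ``model_index`` is 1-based, matching PDB MODEL numbering.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        pdb = _pdbio.PDBFile.read(str(path))
        n_models = pdb.get_model_count()
    except Exception as exc:  # biotite raises various parse errors
        raise PDBFormatError(f"cannot parse {path}: {exc}") from exc
    if not 1 <= model_index <= n_models:
        raise ModelNotFoundError(
            f"{path} has {n_models} model(s); model_index={model_index}")
    try:
        arr = pdb.get_structure(model=model_index)
    except Exception as exc:
        raise PDBFormatError(f"malformed coordinate records in {path}: {exc}") from exc
    return _atomarray_to_topology(arr), np.asarray(arr.coord, dtype=float)


def _topology_to_atomarray(topology: Topology, coords: np.ndarray,
                           b_factors: np.ndarray | None = None) -> struc.AtomArray:
    arr = struc.AtomArray(topology.n_atoms)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.chain_id = topology.chain_ids
    arr.res_id = topology.residue_indices
    arr.res_name = topology.residue_names
    arr.atom_name = topology.atom_names
    arr.element = topology.elements
    if b_factors is not None:
        # PDB B-factor column is %6.2f: clamp so the record stays parseable
        arr.set_annotation("b_factor", np.clip(b_factors, -99.99, 999.99))
    return arr


def write_structure(topology: Topology, coords: np.ndarray, path,
                    b_factors: np.ndarray | None = None) -> None:
    """Write a single-model PDB file."""
    arr = _topology_to_atomarray(topology, coords, b_factors)
    pdb = _pdbio.PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def write_multimodel(topology: Topology, frames: np.ndarray, path) -> None:
    """Write ``(n_frames, n_atoms, 3)`` coordinates as a multi-model PDB."""
    arrays = [_topology_to_atomarray(topology, f) for f in frames]
    stack = struc.stack(arrays)
    pdb = _pdbio.PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def write_per_residue_scores(topology: Topology, coords: np.ndarray,
                             scores: Mapping[int, float], path) -> None:
    """Write a PDB whose B-factor column carries per-residue scores.

    Every atom of a scored residue gets that residue's score (to 2 decimals);
    atoms of unscored residues get 0.00 — this is the convention used for
    coloring structures by significance or network change.
    """
    known = set(np.unique(topology.residue_indices).tolist())
    unknown = set(scores) - known
    if unknown:
        raise SelectionError(f"scores given for unknown residue_index: {sorted(unknown)[:5]}")
    b = np.zeros(topology.n_atoms)
    for res_idx, score in scores.items():
        b[topology.residue_indices == res_idx] = score
    write_structure(topology, coords, path, b_factors=b)


# ---------------------------------------------------------------------------
# ensemble I/O
# ---------------------------------------------------------------------------

def _read_tabular_replica(path, topology: Topology) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    if tuple(df.columns) != TABULAR_HEADER:
        raise PDBFormatError(
            f"{path}: tabular header {tuple(df.columns)} != {TABULAR_HEADER}")
    frames = df["frame"].to_numpy()
    uniq = np.unique(frames)
    if not np.array_equal(uniq, np.arange(uniq[0], uniq[0] + len(uniq))):
        raise FrameNumberingError(f"{path}: non-contiguous frame numbering")
    n_atoms = topology.n_atoms
    id_pos = {aid: i for i, aid in enumerate(topology.atom_ids.tolist())}
    out = np.empty((len(uniq), n_atoms, 3))
    replica_ids = df["replica"].unique()
    if len(replica_ids) != 1:
        raise FrameNumberingError(
            f"{path}: one replica per file expected, found {sorted(replica_ids)}")
    for k, fr in enumerate(uniq):
        sub = df[frames == fr]
        if len(sub) != n_atoms:
            raise AtomCountMismatchError(
                f"{path}: replica {replica_ids[0]} frame {fr} has {len(sub)} "
                f"atoms, topology has {n_atoms}")
        try:
            rows = [id_pos[a] for a in sub["atom_id"].to_numpy()]
        except KeyError as exc:
            raise AtomCountMismatchError(
                f"{path}: frame {fr} references unknown atom_id {exc}") from exc
        out[k, rows] = sub[["x", "y", "z"]].to_numpy()
    return out


def _read_pdb_replica(path, topology: Topology) -> np.ndarray:
    pdb = _pdbio.PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    frames = []
    for m in range(1, n_models + 1):
        arr = pdb.get_structure(model=m)
        if arr.array_length() != topology.n_atoms:
            raise AtomCountMismatchError(
                f"{path}: model {m} has {arr.array_length()} atoms, "
                f"topology has {topology.n_atoms}")
        frames.append(np.asarray(arr.coord, dtype=float))
    return np.stack(frames)


def _looks_tabular(path) -> bool:
    with open(path) as fh:
        first = fh.readline()
    return first.split("\t")[0].strip() == "replica"


def read_ensemble(topology: Topology, paths: Sequence, frame_interval_ps: float) -> ReplicaEnsemble:
    """Read one replica per path; multi-model PDB and tabular files may mix.

    All replicas must deliver the same number of frames (the ensemble is a
    rectangular array).
    """
    if not paths:
        raise FrameNumberingError("no trajectory paths given")
    replicas = []
    for p in paths:
        p = Path(p)
        if not p.exists():
            raise FileNotFoundError(p)
        coords = (_read_tabular_replica(p, topology) if _looks_tabular(p)
                  else _read_pdb_replica(p, topology))
        replicas.append(coords)
    n_frames = {r.shape[0] for r in replicas}
    if len(n_frames) != 1:
        raise FrameNumberingError(
            f"replicas have differing frame counts: {sorted(n_frames)}")
    return ReplicaEnsemble(topology=topology, coords=np.stack(replicas),
                           frame_interval_ps=frame_interval_ps)


def write_tabular_frames(topology: Topology, frames: np.ndarray,
                         replica_id: int, path) -> None:
    """Write one replica's ``(n_frames, n_atoms, 3)`` frames as tabular text."""
    frames = np.asarray(frames, dtype=float)
    n_frames, n_atoms, _ = frames.shape
    buf = io.StringIO()
    buf.write("\t".join(TABULAR_HEADER) + "\n")
    ids = topology.atom_ids
    for fr in range(n_frames):
        xyz = frames[fr]
        for a in range(n_atoms):
            buf.write(f"{replica_id}\t{fr}\t{ids[a]}\t"
                      f"{xyz[a, 0]:.6f}\t{xyz[a, 1]:.6f}\t{xyz[a, 2]:.6f}\n")
    Path(path).write_text(buf.getvalue())
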