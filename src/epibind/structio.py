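"""Structures, trajectories, selections, and PDB readers/writers.

The shared data model for every pose and trajectory operation in the
package.  Coordinates are Angstrom, times are nanoseconds, everywhere.
Parsing and formatting of PDB v3.3 records is delegated to biotite; this
module adds the altloc policy, hydrogen flagging, the multi-model
trajectory dialect (with frame times carried in a ``REMARK 250`` header),
and a small deterministic selection language.

Selection grammar
-----------------
A selection expression is a conjunction of clauses joined by ``and``:

``chain A``            atoms of chain A (several ids: ``chain A,B``)
``resi 10-20``         author residue numbers, ranges and comma lists
``heavy``              non-hydrogen atoms
``CA`` / ``backbone``  alpha carbons / N, CA, C, O
``hydrogen``           hydrogens only
``all``                no-op clause

Resolution against a model is pure and returns indices in file order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    EmptyStructureError,
    ParseError,
    SelectionError,
    TopologyError,
    ValidationError,
)

logger = logging.getLogger(__name__)

_HYDROGEN_ELEMENTS = {"H", "D"}

# Standard atomic masses (u) for the elements that occur in protein work.
ATOMIC_MASSES = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971, "F": 18.998, "CL": 35.45,
    "BR": 79.904, "I": 126.904, "FE": 55.845, "ZN": 65.38, "MG": 24.305,
    "NA": 22.990, "K": 39.098, "CA": 40.078,
}

_TIME_REMARK_PREFIX = "REMARK 250 FRAME TIMES (NS):"


def element_mass(element: str) -> float:
    """Standard atomic mass of an element symbol."""
    try:
        return ATOMIC_MASSES[element.upper()]
    except KeyError:
        from biotite.structure.info import mass as _biotite_mass

        value = _biotite_mass(element)
        if value is None:
            raise ValidationError(f"unknown element {element!r}") from None
        return float(value)


@dataclass(frozen=True)
class Atom:
    """One atom record.

    ``residue_index`` keeps author numbering as read; an insertion code,
    if present, travels in ``ins_code`` and is part of residue identity.
    ``bfactor`` carries per-residue pLDDT for predicted models.
    """

    serial: int
    name: str
    element: str
    coords: tuple[float, float, float]
    chain_id: str
    residue_index: int
    residue_name: str
    ins_code: str = ""
    bfactor: float = 0.0
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.coords)):
            raise ValidationError(f"non-finite coordinates for atom {self.serial}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in _HYDROGEN_ELEMENTS

    @property
    def residue_key(self) -> tuple[str, int | str]:
        """Residue identity: (chain, author index [+ insertion code])."""
        if self.ins_code:
            return (self.chain_id, f"{self.residue_index}{self.ins_code}")
        return (self.chain_id, self.residue_index)


class StructureModel:
    """An ordered collection of atoms with cached coordinate access."""

    def __init__(self, atoms: Sequence[Atom], model_id: str = "model",
                 source_format: str = "memory") -> None:
        if len(atoms) == 0:
            raise EmptyStructureError("a structure model needs at least one atom")
        self.atoms: list[Atom] = list(atoms)
        self.model_id = model_id
        self.source_format = source_format
        seen: set[tuple] = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_index, a.ins_code, a.name)
            if key in seen:
                raise ValidationError(f"duplicate atom identity {key}")
            seen.add(key)
        self._coords = np.array([a.coords for a in self.atoms], dtype=float)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array (a copy is never handed out)."""
        return self._coords

    @property
    def chain_ids(self) -> list[str]:
        """Distinct chain ids in file order."""
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def residues(self, chain_id: str | None = None) -> list[tuple[str, int | str]]:
        """Residue keys in file order, optionally restricted to one chain."""
        out: list[tuple[str, int | str]] = []
        for a in self.atoms:
            if chain_id is not None and a.chain_id != chain_id:
                continue
            key = a.residue_key
            if not out or out[-1] != key:
                if key in out:
                    continue
                out.append(key)
        return out

    def residue_atom_indices(self) -> dict[tuple[str, int | str], np.ndarray]:
        """Map residue key -> atom index array, file order."""
        groups: dict[tuple[str, int | str], list[int]] = {}
        for i, a in enumerate(self.atoms):
            groups.setdefault(a.residue_key, []).append(i)
        return {k: np.asarray(v, dtype=int) for k, v in groups.items()}

    def with_coords(self, coords: np.ndarray, model_id: str | None = None
                    ) -> "StructureModel":
        """Copy of the model with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self), 3):
            raise ValidationError("coordinate array shape mismatch")
        atoms = [
            Atom(a.serial, a.name, a.element, tuple(c), a.chain_id,
                 a.residue_index, a.residue_name, a.ins_code, a.bfactor,
                 a.occupancy)
            for a, c in zip(self.atoms, coords)
        ]
        return StructureModel(atoms, model_id or self.model_id, self.source_format)

    def subset(self, indices: Iterable[int], model_id: str | None = None
               ) -> "StructureModel":
        atoms = [self.atoms[i] for i in indices]
        return StructureModel(atoms, model_id or self.model_id, self.source_format)


@dataclass(frozen=True)
class Selection:
    """A selection expression (see module docstring for the grammar)."""

    expression: str = "all"


@dataclass
class Trajectory:
    """Frames sharing one topology; times in ns, strictly increasing."""

    topology: StructureModel
    frames: np.ndarray          # (n_frames, n_atoms, 3), Angstrom
    frame_times: np.ndarray     # (n_frames,), ns

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValidationError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != len(self.topology):
            raise TopologyError("frame atom count differs from topology")
        if self.frames.shape[0] != self.frame_times.shape[0]:
            raise ValidationError("one time per frame required")
        if np.any(self.frame_times < 0) or np.any(np.diff(self.frame_times) <= 0):
            raise ValidationError("frame times must be non-negative and strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        return float(self.frame_times[-1] - self.frame_times[0])


@dataclass
class ReplicaEnsemble:
    """Independent replicas of one system (shared topology)."""

    replicas: list[Trajectory]
    complex_label: str = ""
    per_replica_duration: float | None = None  # ns

    def __post_init__(self) -> None:
        if not self.replicas:
            raise ValidationError("an ensemble needs at least one replica")
        ref = self.replicas[0].topology
        ref_ids = [(a.chain_id, a.residue_index, a.ins_code, a.name)
                   for a in ref.atoms]
        for t in self.replicas[1:]:
            ids = [(a.chain_id, a.residue_index, a.ins_code, a.name)
                   for a in t.topology.atoms]
            if ids != ref_ids:
                raise TopologyError("replicas do not share one topology")
        if self.per_replica_duration is None:
            self.per_replica_duration = max(t.duration for t in self.replicas)

    @property
    def topology(self) -> StructureModel:
        return self.replicas[0].topology


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "C"


def _array_to_atoms(array, include_hetatm: bool) -> list[Atom]:
    import biotite.structure as struc  # noqa: F401  (annotation access only)

    atoms: list[Atom] = []
    hetero = array.hetero
    b_factor = (array.get_annotation("b_factor")
                if "b_factor" in array.get_annotation_categories()
                else np.zeros(array.array_length()))
    occupancy = (array.get_annotation("occupancy")
                 if "occupancy" in array.get_annotation_categories()
                 else np.ones(array.array_length()))
    serial = (array.get_annotation("atom_id")
              if "atom_id" in array.get_annotation_categories()
              else np.arange(1, array.array_length() + 1))
    for i in range(array.array_length()):
        if hetero[i] and not include_hetatm:
            continue
        element = str(array.element[i]).strip()
        if not element:
            element = _guess_element(str(array.atom_name[i]))
        atoms.append(Atom(
            serial=int(serial[i]),
            name=str(array.atom_name[i]),
            element=element,
            coords=tuple(float(x) for x in array.coord[i]),
            chain_id=str(array.chain_id[i]),
            residue_index=int(array.res_id[i]),
            residue_name=str(array.res_name[i]),
            ins_code=str(array.ins_code[i]).strip(),
            bfactor=float(b_factor[i]),
            occupancy=float(occupancy[i]),
        ))
    return atoms


def read_structure(path: str | Path, format: str = "pdb",
                   include_hetatm: bool = False) -> StructureModel:
    """Read a single-model structure from a PDB file.

    Altloc policy: keep the conformer with the highest occupancy, ties
    resolved in favour of the first altloc letter in the file (normally
    'A').  HETATM records are excluded unless ``include_hetatm``.  For a
    multi-model file the first model is returned and a warning logged.
    """
    if format != "pdb":
        raise ValidationError(f"unsupported structure format {format!r}")
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        n_models = pdb.get_model_count()
    except Exception as exc:  # biotite raises library-specific errors
        raise ParseError(f"{path}: {exc}") from exc
    if n_models == 0:
        raise EmptyStructureError(f"{path}: no coordinate records")
    if n_models > 1:
        logger.warning("%s has %d models; reading the first", path, n_models)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            array = pdb.get_structure(
                model=1, altloc="occupancy",
                extra_fields=["b_factor", "occupancy", "atom_id"])
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    atoms = _array_to_atoms(array, include_hetatm)
    if not atoms:
        raise EmptyStructureError(f"{path}: zero atoms after filtering")
    return StructureModel(atoms, model_id=path.stem, source_format="pdb")


def _model_to_array(model: StructureModel):
    import biotite.structure as struc

    n = len(model)
    array = struc.AtomArray(n)
    array.coord = model.coords.copy()
    array.chain_id = np.array([a.chain_id for a in model.atoms])
    array.res_id = np.array([a.residue_index for a in model.atoms])
    array.ins_code = np.array([a.ins_code for a in model.atoms])
    array.res_name = np.array([a.residue_name for a in model.atoms])
    array.atom_name = np.array([a.name for a in model.atoms])
    array.element = np.array([a.element.upper() for a in model.atoms])
    array.hetero = np.zeros(n, dtype=bool)
    array.set_annotation("b_factor", np.array([a.bfactor for a in model.atoms]))
    array.set_annotation("occupancy", np.array([a.occupancy for a in model.atoms]))
    array.set_annotation("atom_id", np.array([a.serial for a in model.atoms]))
    return array


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a model as a single-model PDB file."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile()
    pdb.set_structure(_model_to_array(model))
    pdb.write(str(path))


def _frame_time_remarks(times: np.ndarray) -> list[str]:
    fields = [f"{t:.6g}" for t in times]
    lines, current = [], _TIME_REMARK_PREFIX
    for f in fields:
        if len(current) + 1 + len(f) > 78:
            lines.append(current)
            current = _TIME_REMARK_PREFIX
        current += " " + f
    lines.append(current)
    return lines


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as multi-model PDB with a frame-time header."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    template = _model_to_array(traj.topology)
    stack = struc.stack([template] * traj.n_frames)
    stack.coord = traj.frames.copy()
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.lines = _frame_time_remarks(traj.frame_times) + pdb.lines
    pdb.write(str(path))


def _parse_time_remarks(lines: list[str]) -> np.ndarray | None:
    values: list[float] = []
    found = False
    for line in lines:
        if line.startswith(_TIME_REMARK_PREFIX):
            found = True
            values.extend(float(tok) for tok in
                          line[len(_TIME_REMARK_PREFIX):].split())
    return np.asarray(values, dtype=float) if found else None


def _check_model_identity(lines: list[str], path: Path) -> None:
    """Verify all MODEL blocks list identical atom identity columns."""
    blocks: list[list[str]] = []
    current: list[str] | None = None
    for line in lines:
        rec = line[:6]
        if rec.startswith("MODEL"):
            current = []
        elif rec.startswith("ENDMDL"):
            if current is not None:
                blocks.append(current)
            current = None
        elif rec in ("ATOM  ", "HETATM") and current is not None:
            current.append(line[12:27])  # name, altloc, resname, chain, resid, icode
    for i, block in enumerate(blocks[1:], start=2):
        if block != blocks[0]:
            raise TopologyError(
                f"{path}: model {i} atom identities differ from model 1")


def read_trajectory(path: str | Path, format: str = "pdb-multimodel",
                    include_hetatm: bool = False) -> Trajectory:
    """Read a multi-model PDB as a trajectory.

    Frame times come from the ``REMARK 250 FRAME TIMES (NS):`` header if
    present, otherwise default to 0, 1, 2, ... ns.  All MODEL blocks must
    carry identical atom identity sequences.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    if format == "adapter":
        raise ValidationError(
            "no trajectory adapter is registered; use the multi-model PDB dialect")
    if format != "pdb-multimodel":
        raise ValidationError(f"unsupported trajectory format {format!r}")
    try:
        pdb = PDBFile.read(str(path))
        n_models = pdb.get_model_count()
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if n_models == 0:
        raise EmptyStructureError(f"{path}: no coordinate records")
    _check_model_identity(pdb.lines, path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            first = pdb.get_structure(
                model=1, altloc="occupancy",
                extra_fields=["b_factor", "occupancy", "atom_id"])
            coords = pdb.get_coord(model=None)
    except Exception as exc:
        raise TopologyError(f"{path}: {exc}") from exc
    atoms = _array_to_atoms(first, include_hetatm)
    if not atoms:
        raise EmptyStructureError(f"{path}: zero atoms after filtering")
    topology = StructureModel(atoms, model_id=path.stem, source_format="pdb")
    if not include_hetatm and first.hetero.any():
        keep = ~first.hetero
        coords = coords[:, keep, :]
    if coords.ndim == 2:
        coords = coords[None, :, :]
    times = _parse_time_remarks(pdb.lines)
    if times is None:
        times = np.arange(coords.shape[0], dtype=float)
    elif times.shape[0] != coords.shape[0]:
        raise ValidationError(
            f"{path}: {times.shape[0]} frame times for {coords.shape[0]} frames")
    return Trajectory(topology, coords, times)


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

_ATOM_CLASSES = {"all", "heavy", "ca", "backbone", "hydrogen"}
_BACKBONE_NAMES = {"N", "CA", "C", "O"}


def _parse_int_ranges(spec: str) -> list[tuple[int, int]]:
    ranges = []
    for part in spec.split(","):
        part = part.strip()
        if not part:
            continue
        if "-" in part[1:]:  # allow a leading minus sign
            lo, hi = part.rsplit("-", 1)
            ranges.append((int(lo), int(hi)))
        else:
            ranges.append((int(part), int(part)))
    if not ranges:
        raise SelectionError(f"empty residue range spec {spec!r}")
    return ranges


def resolve_selection(model: StructureModel, sel: Selection) -> np.ndarray:
    """Resolve a selection to an ordered atom index array (file order).

    Pure: identical (model, expression) pairs give identical results.
    Referencing a chain id absent from the model is an error; an empty
    result from distance-free clauses otherwise is allowed.
    """
    expr = sel.expression.strip()
    if not expr:
        raise SelectionError("empty selection expression")
    mask = np.ones(len(model), dtype=bool)
    chains = np.array([a.chain_id for a in model.atoms])
    names = np.array([a.name for a in model.atoms])
    res_ids = np.array([a.residue_index for a in model.atoms])
    is_h = np.array([a.is_hydrogen for a in model.atoms])
    known_chains = set(chains.tolist())

    for clause in (c.strip() for c in expr.split(" and ")):
        if not clause:
            raise SelectionError(f"empty clause in {expr!r}")
        tokens = clause.split(None, 1)
        head = tokens[0].lower()
        if head == "chain":
            if len(tokens) < 2:
                raise SelectionError("'chain' needs at least one id")
            wanted = {c.strip() for c in tokens[1].replace(",", " ").split()}
            unknown = wanted - known_chains
            if unknown:
                raise SelectionError(
                    f"unknown chain id(s) {sorted(unknown)}; model has "
                    f"{sorted(known_chains)}")
            mask &= np.isin(chains, sorted(wanted))
        elif head in ("resi", "residue"):
            if len(tokens) < 2:
                raise SelectionError("'resi' needs a range spec")
            rmask = np.zeros(len(model), dtype=bool)
            for lo, hi in _parse_int_ranges(tokens[1]):
                rmask |= (res_ids >= lo) & (res_ids <= hi)
            mask &= rmask
        elif head in _ATOM_CLASSES and len(tokens) == 1:
            if head == "heavy":
                mask &= ~is_h
            elif head == "ca":
                mask &= (names == "CA") & ~is_h
            elif head == "backbone":
                mask &= np.isin(names, sorted(_BACKBONE_NAMES)) & ~is_h
            elif head == "hydrogen":
                mask &= is_h
            # "all": no-op
        else:
            raise SelectionError(f"cannot parse clause {clause!r}")
    return np.flatnonzero(mask)


def residue_com(frame: np.ndarray, model: StructureModel,
                residue: tuple[str, int | str],
                mass_weighted: bool = True) -> np.ndarray:
    """Center of mass of one residue in a coordinate frame.

    With ``mass_weighted`` the standard atomic masses by element are used;
    otherwise the arithmetic mean of the atom positions.
    """
    frame = np.asarray(frame, dtype=float)
    groups = model.residue_atom_indices()
    if residue not in groups:
        raise SelectionError(f"residue {residue} not in model")
    idx = groups[residue]
    pts = frame[idx]
    if not mass_weighted:
        return pts.mean(axis=0)
    masses = np.array([element_mass(model.atoms[i].element) for i in idx])
    return (pts * masses[:, None]).sum(axis=0) / masses.sum()
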