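"""Rigid-body superposition, epitope mapping, and steric-clash competition.

The in-silico analogue of epitope binning: candidate antibody poses are
superposed into a common frame via the shared antigen (least-squares
Kabsch fit on alpha carbons), and competition with a reference binder
(the natural ligand, or a second antigen copy at a dimer interface) is
called when any heavy-atom pair falls below the clash cutoff
(default 3.0 A = 0.3 nm, strict less-than).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import (
    DegenerateFitError,
    PairingError,
    SelectionError,
    ValidationError,
)
from .structio import Selection, StructureModel, resolve_selection

__all__ = [
    "RigidTransform", "ClashReport", "EpitopeMap",
    "kabsch_superpose", "steric_clash_scan", "epitope_map",
    "competition_assessment",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation; maps mobile into the reference frame."""

    rotation: np.ndarray     # (3, 3), orthonormal, det = +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float)
        if rot.shape != (3, 3):
            raise ValidationError("rotation must be 3x3")
        if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-6):
            raise ValidationError("rotation columns must be orthonormal")
        if not np.isclose(np.linalg.det(rot), 1.0, atol=1e-6):
            raise ValidationError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation",
                           np.asarray(self.translation, dtype=float))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class ClashReport:
    """Heavy-atom pairs below the cutoff, with the residues involved."""

    cutoff: float
    pairs: list[tuple[int, int, float]] = field(default_factory=list)
    clash_residues_a: set = field(default_factory=set)
    clash_residues_b: set = field(default_factory=set)

    @property
    def n_clashes(self) -> int:
        return len(self.pairs)


@dataclass
class EpitopeMap:
    """Antigen residues in contact with a binder, with pair counts."""

    residues: set = field(default_factory=set)
    contact_counts: dict = field(default_factory=dict)


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     fit_indices: tuple[np.ndarray, np.ndarray] | None = None,
                     ) -> tuple[RigidTransform, float]:
    """Least-squares optimal rigid superposition of paired points.

    ``fit_indices`` gives paired index lists (mobile, reference); by
    default all points are paired positionally.  Returns the transform
    that maps mobile coordinates into the reference frame and the RMSD
    over the fit atoms after transformation.  A proper rotation is
    always returned (no reflections).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if fit_indices is not None:
        idx_m = np.asarray(fit_indices[0], dtype=int)
        idx_r = np.asarray(fit_indices[1], dtype=int)
        if idx_m.shape != idx_r.shape:
            raise DegenerateFitError("paired fit index lists differ in length")
        mob = mobile[idx_m]
        ref = reference[idx_r]
    else:
        if mobile.shape != reference.shape:
            raise DegenerateFitError("unpaired coordinate sets differ in shape")
        mob, ref = mobile, reference
    if mob.shape[0] < 3:
        raise DegenerateFitError(f"need >= 3 fit pairs, got {mob.shape[0]}")
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    sing = np.linalg.svd(mob_c, compute_uv=False)
    if sing[1] < 1e-8 * max(sing[0], 1.0):
        raise DegenerateFitError("fit atoms are collinear")
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    rmat = rot.as_matrix()
    translation = ref.mean(axis=0) - rmat @ mob.mean(axis=0)
    transform = RigidTransform(rmat, translation)
    diff = transform.apply(mob) - ref
    rmsd = float(np.sqrt((diff ** 2).sum(axis=1).mean()))
    return transform, rmsd


def _heavy_subset(model: StructureModel, sel: Selection) -> np.ndarray:
    idx = resolve_selection(model, sel)
    if idx.size == 0:
        raise SelectionError(f"selection {sel.expression!r} resolves to no atoms")
    heavy = np.array([not model.atoms[i].is_hydrogen for i in idx])
    idx = idx[heavy]
    if idx.size == 0:
        raise SelectionError(
            f"selection {sel.expression!r} has no heavy atoms")
    return idx


def _close_pairs(coords_a: np.ndarray, coords_b: np.ndarray, cutoff: float,
                 ) -> list[tuple[int, int, float]]:
    """All (i, j, dist) with dist strictly below cutoff; KDTree-backed."""
    tree_a = cKDTree(coords_a)
    tree_b = cKDTree(coords_b)
    pairs = []
    for i, neighbors in enumerate(tree_a.query_ball_tree(tree_b, cutoff)):
        for j in neighbors:
            dist = float(np.linalg.norm(coords_a[i] - coords_b[j]))
            if dist < cutoff:
                pairs.append((i, j, dist))
    return pairs


def steric_clash_scan(model_a: StructureModel, sel_a: Selection,
                      model_b: StructureModel, sel_b: Selection,
                      cutoff: float = 3.0,
                      coords_a: np.ndarray | None = None,
                      coords_b: np.ndarray | None = None) -> ClashReport:
    """Heavy-atom pairs between two selections closer than ``cutoff``.

    Both structures must already be in a common frame (superpose first).
    ``coords_a``/``coords_b`` optionally override the models' own
    coordinates (e.g. after applying a transform).  Atom indices in the
    report refer to the full models.
    """
    idx_a = _heavy_subset(model_a, sel_a)
    idx_b = _heavy_subset(model_b, sel_b)
    xyz_a = (model_a.coords if coords_a is None else np.asarray(coords_a))[idx_a]
    xyz_b = (model_b.coords if coords_b is None else np.asarray(coords_b))[idx_b]
    report = ClashReport(cutoff=cutoff)
    for i, j, dist in _close_pairs(xyz_a, xyz_b, cutoff):
        ia, ib = int(idx_a[i]), int(idx_b[j])
        report.pairs.append((ia, ib, dist))
        report.clash_residues_a.add(model_a.atoms[ia].residue_key)
        report.clash_residues_b.add(model_b.atoms[ib].residue_key)
    return report


def epitope_map(complex_model: StructureModel, antigen_sel: Selection,
                binder_sel: Selection, cutoff: float = 4.5) -> EpitopeMap:
    """Antigen residues with >= 1 heavy-atom pair to the binder within cutoff."""
    idx_antigen = _heavy_subset(complex_model, antigen_sel)
    idx_binder = _heavy_subset(complex_model, binder_sel)
    if np.intersect1d(idx_antigen, idx_binder).size:
        raise SelectionError("antigen and binder selections overlap")
    coords = complex_model.coords
    result = EpitopeMap()
    for i, _j, _d in _close_pairs(coords[idx_antigen], coords[idx_binder],
                                  cutoff):
        key = complex_model.atoms[int(idx_antigen[i])].residue_key
        result.residues.add(key)
        result.contact_counts[key] = result.contact_counts.get(key, 0) + 1
    return result


def _ca_pairing(model_a: StructureModel, model_b: StructureModel,
                antigen_sel: Selection) -> tuple[np.ndarray, np.ndarray]:
    """Pair CA atoms of antigen residues common to both by author numbering."""
    def ca_map(model: StructureModel) -> dict:
        idx = resolve_selection(model, antigen_sel)
        return {model.atoms[i].residue_key: i for i in idx
                if model.atoms[i].name == "CA"}

    map_a, map_b = ca_map(model_a), ca_map(model_b)
    common = [k for k in map_a if k in map_b]
    if len(common) < 3:
        raise PairingError(
            f"only {len(common)} shared antigen CA residue(s); need >= 3")
    return (np.array([map_a[k] for k in common], dtype=int),
            np.array([map_b[k] for k in common], dtype=int))


def competition_assessment(antibody_complex: StructureModel,
                           antibody_sel: Selection,
                           reference_complex: StructureModel,
                           competitor_sel: Selection,
                           shared_antigen_sel: Selection,
                           clash_cutoff: float = 3.0,
                           pairing: tuple[np.ndarray, np.ndarray] | None = None,
                           ) -> tuple[bool, ClashReport]:
    """Does the modelled antibody sterically exclude a reference binder?

    The reference complex is superposed onto the antibody complex via
    the shared antigen (CA atoms of residues common by author numbering,
    or an explicit ``pairing`` of atom indices (antibody-complex side,
    reference side)), then the antibody selection is scanned for heavy-
    atom clashes against the competitor selection of the transformed
    reference.  Competition is called on >= 1 clash pair.
    """
    if pairing is None:
        idx_ab, idx_ref = _ca_pairing(antibody_complex, reference_complex,
                                      shared_antigen_sel)
    else:
        idx_ab = np.asarray(pairing[0], dtype=int)
        idx_ref = np.asarray(pairing[1], dtype=int)
        if idx_ab.shape != idx_ref.shape:
            raise PairingError("explicit pairing lists differ in length")
    transform, _rmsd = kabsch_superpose(
        reference_complex.coords, antibody_complex.coords,
        fit_indices=(idx_ref, idx_ab))
    moved_ref = transform.apply(reference_complex.coords)
    report = steric_clash_scan(
        antibody_complex, antibody_sel, reference_complex, competitor_sel,
        cutoff=clash_cutoff, coords_b=moved_ref)
    return report.n_clashes >= 1, report
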