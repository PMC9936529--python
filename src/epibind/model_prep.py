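"""Post-processing of AI-predicted complex models.

Predicted antibody-antigen structures arrive as PDB coordinates with
per-residue confidence (pLDDT, 0-100) in the B-factor column and a
companion JSON score file holding the global pTM score and the
predicted-aligned-error (PAE) matrix.  This module trims unreliable
chain termini, ranks candidate models, summarizes interface PAE, and
keeps the modelling/simulation protocol bookkeeping honest.

Score-file schema (JSON): ``{"model_id": str, "ptm": float,
"pae": [[...], ...]}`` with ``pae`` optional, row-major, in Angstrom.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import EmptyChainError, ValidationError
from .structio import StructureModel

__all__ = [
    "ConfidenceProfile", "ModelScore", "ProtocolSummary",
    "confidence_from_model", "trim_low_confidence_termini",
    "rank_models_by_ptm", "pae_interface_summary", "protocol_totals",
    "load_model_score", "save_model_score",
]


@dataclass(frozen=True)
class ConfidenceProfile:
    """Per-residue pLDDT values, ordered per chain."""

    per_chain: dict[str, tuple[float, ...]]

    def __post_init__(self) -> None:
        for chain, values in self.per_chain.items():
            arr = np.asarray(values, dtype=float)
            if arr.size and (arr.min() < 0 or arr.max() > 100):
                raise ValidationError(
                    f"chain {chain}: pLDDT values must lie in [0, 100]")


@dataclass(frozen=True)
class ModelScore:
    """Global scores of one predicted model."""

    model_id: str
    ptm: float
    pae: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.ptm <= 1.0:
            raise ValidationError(f"pTM must lie in [0, 1], got {self.ptm}")
        if self.pae is not None:
            pae = np.asarray(self.pae, dtype=float)
            if pae.ndim != 2 or pae.shape[0] != pae.shape[1]:
                raise ValidationError("PAE must be a square matrix")
            object.__setattr__(self, "pae", pae)


@dataclass(frozen=True)
class ProtocolSummary:
    """Bookkeeping of the modelling and simulation campaign."""

    n_complexes: int
    runs_per_complex: int
    models_per_run: int
    replicas_per_complex: int
    duration_per_replica: float  # microseconds

    def __post_init__(self) -> None:
        for name in ("n_complexes", "runs_per_complex", "models_per_run",
                     "replicas_per_complex"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.duration_per_replica <= 0:
            raise ValidationError("duration_per_replica must be positive")


def confidence_from_model(model: StructureModel) -> ConfidenceProfile:
    """Read the pLDDT profile off a predicted model's B-factor column.

    The value is constant within a residue by convention; the first
    atom's B-factor is taken per residue.
    """
    per_chain: dict[str, list[float]] = {}
    seen: set = set()
    for atom in model.atoms:
        key = atom.residue_key
        if key in seen:
            continue
        seen.add(key)
        per_chain.setdefault(atom.chain_id, []).append(atom.bfactor)
    return ConfidenceProfile({c: tuple(v) for c, v in per_chain.items()})


def trim_low_confidence_termini(model: StructureModel,
                                profile: ConfidenceProfile | None = None,
                                threshold: float = 70.0) -> StructureModel:
    """Remove terminal runs of low-confidence residues, per chain.

    From each chain end inward, the maximal contiguous run of residues
    with pLDDT strictly below ``threshold`` is dropped; interior
    low-confidence residues are kept.  A residue at exactly the
    threshold is retained.  Idempotent.  If ``profile`` is omitted it is
    derived from the B-factor column.
    """
    if profile is None:
        profile = confidence_from_model(model)
    keep_residues: set = set()
    for chain in model.chain_ids:
        residues = model.residues(chain)
        if chain not in profile.per_chain:
            raise ValidationError(f"profile missing chain {chain!r}")
        values = profile.per_chain[chain]
        if len(values) != len(residues):
            raise ValidationError(
                f"chain {chain}: profile length {len(values)} != "
                f"{len(residues)} residues")
        lo = 0
        while lo < len(values) and values[lo] < threshold:
            lo += 1
        if lo == len(values):
            raise EmptyChainError(
                f"chain {chain}: every residue below pLDDT {threshold}")
        hi = len(values)
        while hi > lo and values[hi - 1] < threshold:
            hi -= 1
        keep_residues.update(residues[lo:hi])
    indices = [i for i, a in enumerate(model.atoms)
               if a.residue_key in keep_residues]
    return model.subset(indices, model_id=model.model_id)


def rank_models_by_ptm(scores: Sequence[ModelScore]) -> list[str]:
    """Model ids in descending pTM order; ties broken lexicographically."""
    if not scores:
        raise ValidationError("cannot rank an empty score list")
    return [s.model_id for s in
            sorted(scores, key=lambda s: (-s.ptm, s.model_id))]


def pae_interface_summary(score: ModelScore,
                          chain_partition: tuple[Sequence[int], Sequence[int]]
                          ) -> float:
    """Mean inter-chain PAE over both block orientations.

    ``chain_partition`` gives the (0-based) residue indices of the two
    sides (e.g. antigen vs. antibody) into the PAE matrix.  The summary
    is the arithmetic mean of PAE[i, j] over i in the first set, j in
    the second, and vice versa.  This is a repo convention for turning
    the PAE matrix into one interface-quality number.
    """
    if score.pae is None:
        raise ValidationError(f"model {score.model_id}: no PAE matrix available")
    set1 = np.asarray(chain_partition[0], dtype=int)
    set2 = np.asarray(chain_partition[1], dtype=int)
    if set1.size == 0 or set2.size == 0:
        raise ValidationError("both partition sets must be non-empty")
    if np.intersect1d(set1, set2).size:
        raise ValidationError("partition sets must be disjoint")
    block_12 = score.pae[np.ix_(set1, set2)]
    block_21 = score.pae[np.ix_(set2, set1)]
    return float((block_12.sum() + block_21.sum())
                 / (block_12.size + block_21.size))


def protocol_totals(summary: ProtocolSummary) -> tuple[int, float]:
    """(total models generated, total simulated time in microseconds)."""
    total_models = (summary.n_complexes * summary.runs_per_complex
                    * summary.models_per_run)
    total_time = (summary.n_complexes * summary.replicas_per_complex
                  * summary.duration_per_replica)
    return total_models, total_time


def load_model_score(path: str | Path) -> ModelScore:
    with open(path) as fh:
        payload = json.load(fh)
    pae = payload.get("pae")
    return ModelScore(
        model_id=str(payload.get("model_id", Path(path).stem)),
        ptm=float(payload["ptm"]),
        pae=np.asarray(pae, dtype=float) if pae is not None else None,
    )


def save_model_score(score: ModelScore, path: str | Path) -> None:
    payload: dict = {"model_id": score.model_id, "ptm": score.ptm}
    if score.pae is not None:
        payload["pae"] = np.asarray(score.pae).tolist()
    with open(path, "w") as fh:
        json.dump(payload, fh)
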