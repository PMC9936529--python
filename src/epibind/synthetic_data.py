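"""Seeded generators with analytically known ground truth.

Every input class the pipeline consumes can be produced here at toy
scale, so each stage is testable without downloads: rigid three-chain
antibody-antigen complexes with a prescribed epitope, replica ensembles
with known per-residue fluctuation widths and optional binder drift,
hydrogen-bond geometries with exact expected counts, and bivalent SPR
sensorgrams with known rate constants and additive noise.

All randomness flows from ``numpy.random.default_rng`` seeded via
``SeedSequence([seed, stream])``; the same seed reproduces every output
bit-for-bit.  Generators return their own ground truth so tests never
need externally stated numbers.

Geometry of ``make_complex``: antigen residues sit 6 A apart on the
x-axis (one CA and one CB-proxy heavy atom each); binder chains are
parked 30/40 A away except that one binder residue is lowered over each
requested epitope residue, 4.0-4.3 A above its atoms.  6 A spacing
guarantees neighbours stay outside the 4.5 A contact cutoff
(sqrt(6^2 + 4^2) = 7.2 A), so the contact map equals the request
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .model_prep import ConfidenceProfile, ModelScore
from .spr_kinetics import (
    BivalentParams,
    PhaseSchedule,
    Sensorgram,
    simulate_bivalent,
    simulate_two_site,
)
from .structio import Atom, ReplicaEnsemble, StructureModel, Trajectory

__all__ = [
    "FixtureSpec", "make_complex", "make_ensemble", "make_hbond_lattice",
    "make_sensorgrams", "DEFAULT_KINETICS",
]

# Emulates nanomolar antibody-antigen capture kinetics at a scale a
# 300 s + 300 s injection cycle can resolve, chosen for identifiability:
# each rate dominates a distinct observable feature.  kd1 sets the early
# dissociation decay (tau = 100 s inside the window) and rebinding stays
# secondary (ka2 * Bmax1 < 0.1 * kd1); kd2 appears as a slow tail.
DEFAULT_KINETICS = BivalentParams(
    ka1=1.5e6,    # 1/(M s)
    kd1=1.0e-2,   # 1/s
    ka2=5.0e-6,   # 1/(RU s)
    kd2=2.0e-3,   # 1/s
    bmax1=150.0,  # RU
)

DEFAULT_CONCS = (2.5e-9, 5e-9, 10e-9)  # M, the injection series emulated


@dataclass(frozen=True)
class FixtureSpec:
    """Everything the generators need, with toy-scale defaults.

    ``epitope`` names antigen residues (chain, residue_index) that must
    contact the binder; ``sigma`` is the per-axis Gaussian fluctuation
    width (A) applied rigidly per binder residue, ``antigen_sigma`` the
    same for the antigen (default static, so an antigen fit is exact);
    ``drift`` is a rigid binder drift in A/ns.  ``low_conf_nterm`` /
    ``low_conf_cterm`` prepend/append that many residues of pLDDT < 70
    to every chain profile.
    """

    seed: int = 0
    n_antigen: int = 60
    n_binder: int = 50
    epitope: tuple[tuple[str, int], ...] = (("A", 10), ("A", 11), ("A", 12))
    sigma: float = 0.5                      # A per axis, binder residues
    antigen_sigma: float = 0.0              # A per axis, antigen residues
    drift: tuple[float, float, float] = (0.0, 0.0, 0.0)  # A/ns, binder
    n_frames: int = 100
    n_replicas: int = 10
    frame_spacing: float = 1.0              # ns
    low_conf_nterm: int = 0
    low_conf_cterm: int = 0
    ptm: float = 0.8
    kinetics: BivalentParams = field(default_factory=lambda: DEFAULT_KINETICS)
    kinetic_model: str = "bivalent"
    noise_frac: float = 0.01                # Gaussian noise sigma / Bmax1

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.antigen_sigma < 0 or self.noise_frac < 0:
            raise ValidationError("noise widths must be >= 0")
        if self.n_antigen < 1 or self.n_binder < 1:
            raise ValidationError("chain lengths must be >= 1")
        if self.n_frames < 1 or self.n_replicas < 1:
            raise ValidationError("frame and replica counts must be >= 1")


def _rng(spec: FixtureSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, stream]))


_RESIDUE_SPACING = 6.0  # A along x; > contact cutoff + proxy offsets


def _zigzag_y(residue_index: int) -> float:
    # deterministic out-of-line offset so CA sets are never collinear
    return float(np.sin(0.7 * residue_index))


def _chain_atoms(chain_id: str, n_res: int, z: float, serial0: int,
                 res_name: str = "ALA") -> list[Atom]:
    atoms = []
    for r in range(1, n_res + 1):
        x = (r - 1) * _RESIDUE_SPACING
        y = _zigzag_y(r)
        atoms.append(Atom(serial0 + 2 * (r - 1), "CA", "C", (x, y, z),
                          chain_id, r, res_name))
        atoms.append(Atom(serial0 + 2 * (r - 1) + 1, "CB", "C", (x, y + 1.5, z),
                          chain_id, r, res_name))
    return atoms


def make_complex(spec: FixtureSpec
                 ) -> tuple[StructureModel, ConfidenceProfile, ModelScore]:
    """A three-chain complex whose epitope is exactly as requested.

    Chains: antigen ``A``, binder heavy ``H``, binder light ``L``; each
    residue contributes a CA and a CB-proxy heavy atom.  Exactly the
    requested epitope residues end up with heavy-atom pairs < 4.5 A to
    chain H.  The pLDDT profile (also written to the B-factor column)
    and a pTM/PAE score object are returned alongside.
    """
    epitope = list(dict.fromkeys(spec.epitope))
    for chain, res in epitope:
        if chain != "A":
            raise ValidationError("epitope residues must lie on the antigen chain A")
        if not 1 <= res <= spec.n_antigen:
            raise ValidationError(f"epitope residue {res} outside chain A")
    if len(epitope) > spec.n_binder:
        raise ValidationError("more epitope residues than binder residues")

    atoms = _chain_atoms("A", spec.n_antigen, z=0.0, serial0=1)
    atoms += _chain_atoms("H", spec.n_binder, z=30.0,
                          serial0=2 * spec.n_antigen + 1)
    atoms += _chain_atoms("L", spec.n_binder, z=40.0,
                          serial0=2 * (spec.n_antigen + spec.n_binder) + 1)
    model = StructureModel(atoms, model_id=f"synthetic_complex_seed{spec.seed}")

    # Lower one H-chain residue over each epitope residue: CA 4.2 A and
    # CB 4.0 A above the matching antigen atoms.
    coords = model.coords.copy()
    index_of = {(a.chain_id, a.residue_index, a.name): i
                for i, a in enumerate(model.atoms)}
    for k, (_chain, res) in enumerate(epitope):
        x = (res - 1) * _RESIDUE_SPACING
        y = _zigzag_y(res)
        coords[index_of[("H", k + 1, "CA")]] = (x, y, 4.2)
        coords[index_of[("H", k + 1, "CB")]] = (x, y + 1.5, 4.0)
    model = model.with_coords(coords)

    rng = _rng(spec, 0)
    per_chain: dict[str, tuple[float, ...]] = {}
    for chain, n_res in (("A", spec.n_antigen), ("H", spec.n_binder),
                         ("L", spec.n_binder)):
        n_low = spec.low_conf_nterm + spec.low_conf_cterm
        if n_low >= n_res:
            raise ValidationError(f"chain {chain}: low-confidence termini "
                                  "cover the whole chain")
        body = np.round(rng.uniform(80.0, 95.0, n_res - n_low), 2)
        head = np.round(rng.uniform(40.0, 65.0, spec.low_conf_nterm), 2)
        tail = np.round(rng.uniform(40.0, 65.0, spec.low_conf_cterm), 2)
        per_chain[chain] = tuple(np.concatenate([head, body, tail]))
    profile = ConfidenceProfile(per_chain)

    plddt_lookup = {}
    for chain, values in per_chain.items():
        for j, key in enumerate(model.residues(chain)):
            plddt_lookup[key] = values[j]
    model = StructureModel(
        [Atom(a.serial, a.name, a.element, a.coords, a.chain_id,
              a.residue_index, a.residue_name, a.ins_code,
              bfactor=float(plddt_lookup[a.residue_key]),
              occupancy=a.occupancy)
         for a in model.atoms],
        model_id=model.model_id)

    n_total = spec.n_antigen + 2 * spec.n_binder
    pae = np.full((n_total, n_total), 8.0)
    pae[:spec.n_antigen, :spec.n_antigen] = 3.0
    pae[spec.n_antigen:, spec.n_antigen:] = 3.0
    np.fill_diagonal(pae, 0.5)
    score = ModelScore(model_id=model.model_id, ptm=spec.ptm, pae=pae)
    return model, profile, score


def make_ensemble(spec: FixtureSpec) -> ReplicaEnsemble:
    """Replica ensemble of per-residue Gaussian jitter about the pose.

    Each frame displaces every binder residue rigidly by an independent
    isotropic Gaussian offset (per-axis ``sigma``), and the antigen by
    ``antigen_sigma`` (default static).  The expected residue-COM RMSF
    of a jittered residue is sigma * sqrt(3).  An optional rigid binder
    ``drift`` (A/ns) makes the antigen-fitted binder RMSD grow as
    |drift| * t.
    """
    base_model, _, _ = make_complex(spec)
    base = base_model.coords
    residue_groups = base_model.residue_atom_indices()
    binder_residues = [k for k in residue_groups if k[0] != "A"]
    antigen_residues = [k for k in residue_groups if k[0] == "A"]
    binder_atoms = np.concatenate([residue_groups[k] for k in binder_residues])
    drift = np.asarray(spec.drift, dtype=float)
    times = np.arange(spec.n_frames) * spec.frame_spacing

    replicas = []
    for r in range(spec.n_replicas):
        rng = _rng(spec, 100 + r)
        frames = np.broadcast_to(base, (spec.n_frames,) + base.shape).copy()
        if spec.sigma > 0:
            offsets = rng.normal(0.0, spec.sigma,
                                 (spec.n_frames, len(binder_residues), 3))
            for j, key in enumerate(binder_residues):
                frames[:, residue_groups[key], :] += offsets[:, j, None, :]
        if spec.antigen_sigma > 0:
            offsets = rng.normal(0.0, spec.antigen_sigma,
                                 (spec.n_frames, len(antigen_residues), 3))
            for j, key in enumerate(antigen_residues):
                frames[:, residue_groups[key], :] += offsets[:, j, None, :]
        if np.any(drift != 0):
            frames[:, binder_atoms, :] += times[:, None, None] * drift
        replicas.append(Trajectory(base_model, frames, times))
    return ReplicaEnsemble(replicas,
                           complex_label=f"synthetic_seed{spec.seed}",
                           per_replica_duration=float(times[-1]) if
                           spec.n_frames > 1 else 0.0)


def _solve_hydrogen_position(distance: float, angle_deg: float) -> np.ndarray:
    """Place H with |DH| = 1 A and the requested D-H...A angle.

    D at the origin, A at (distance, 0, 0); H is rotated in the xz
    plane until the three-point angle at H matches.  Solved by bisection
    on the rotation angle (the target angle is monotone in it).
    """
    from scipy.optimize import brentq

    d_vec = np.zeros(3)
    a_vec = np.array([distance, 0.0, 0.0])

    def angle_at_h(phi: float) -> float:
        h = np.array([np.cos(phi), 0.0, np.sin(phi)])
        v1, v2 = d_vec - h, a_vec - h
        cos = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
        return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))

    target = float(angle_deg)
    if not 0 < target <= 180:
        raise ValidationError("requested angle must lie in (0, 180]")
    if target >= angle_at_h(0.0) - 1e-9:
        phi = 0.0
    else:
        phi = brentq(lambda p: angle_at_h(p) - target, 0.0, np.pi * 0.75,
                     xtol=1e-12)
    return np.array([np.cos(phi), 0.0, np.sin(phi)])


def make_hbond_lattice(n_donors: int, n_acceptors: int,
                       da_distance: float | list[float] = 3.0,
                       angle_deg: float | list[float] = 175.0,
                       seed: int = 0) -> tuple[StructureModel, int]:
    """Isolated donor/acceptor pairs with exactly known H-bond count.

    Donor ``i`` (N with one H) is paired with acceptor ``i`` (O) at the
    requested distance and D-H...A angle; pairs sit 20 A apart so no
    cross-pair triple can satisfy the criteria, and surplus donors or
    acceptors are parked far away without a partner.  The expected count
    is the number of pairs with distance <= 3.5 A and angle >= 150 deg.
    Donor group = chain D, acceptor group = chain B.
    """
    if n_donors < 0 or n_acceptors < 0:
        raise ValidationError("counts must be >= 0")
    n_pairs = min(n_donors, n_acceptors)
    distances = np.broadcast_to(np.asarray(da_distance, dtype=float),
                                (n_pairs,)).copy()
    angles = np.broadcast_to(np.asarray(angle_deg, dtype=float),
                             (n_pairs,)).copy()
    atoms: list[Atom] = []
    serial = 1
    expected = 0
    for i in range(n_pairs):
        origin = np.array([20.0 * i, 0.0, 0.0])
        h_local = _solve_hydrogen_position(distances[i], angles[i])
        atoms.append(Atom(serial, "N", "N", tuple(origin), "D", i + 1, "DON"))
        atoms.append(Atom(serial + 1, "H", "H", tuple(origin + h_local),
                          "D", i + 1, "DON"))
        atoms.append(Atom(serial + 2, "O", "O",
                          tuple(origin + [distances[i], 0.0, 0.0]),
                          "B", i + 1, "ACC"))
        serial += 3
        if distances[i] <= 3.5 and angles[i] >= 150.0:
            expected += 1
    far = 200.0
    for i in range(n_pairs, n_donors):
        origin = np.array([20.0 * i, 0.0, far])
        atoms.append(Atom(serial, "N", "N", tuple(origin), "D", i + 1, "DON"))
        atoms.append(Atom(serial + 1, "H", "H", tuple(origin + [1.0, 0, 0]),
                          "D", i + 1, "DON"))
        serial += 2
    for i in range(n_pairs, n_acceptors):
        atoms.append(Atom(serial, "O", "O", (20.0 * i, 50.0, far),
                          "B", i + 1, "ACC"))
        serial += 1
    if not atoms:
        raise ValidationError("lattice with zero donors and acceptors")
    model = StructureModel(atoms, model_id=f"hbond_lattice_seed{seed}")
    return model, expected


def make_sensorgrams(spec: FixtureSpec,
                     concs: tuple[float, ...] = DEFAULT_CONCS,
                     assoc_duration: float = 300.0,
                     dissoc_duration: float = 300.0,
                     dt: float = 1.0,
                     ) -> tuple[list[Sensorgram], BivalentParams]:
    """Simulated injection series with seeded additive Gaussian noise.

    One curve per concentration, association for ``assoc_duration`` s
    followed by dissociation, sampled every ``dt`` s; noise sigma is
    ``spec.noise_frac * Bmax1``.  Returns the curves and the generating
    parameters as ground truth for recovery tests.
    """
    params = spec.kinetics
    simulate = (simulate_bivalent if spec.kinetic_model == "bivalent"
                else simulate_two_site)
    phases = PhaseSchedule(assoc_end=assoc_duration,
                           dissoc_end=assoc_duration + dissoc_duration)
    times = np.arange(0.0, phases.dissoc_end + dt / 2, dt)
    rng = _rng(spec, 7)
    curves = []
    for conc in concs:
        clean = simulate(params, conc, times, phases)
        noise = rng.normal(0.0, spec.noise_frac * params.bmax1, times.shape) \
            if spec.noise_frac > 0 else 0.0
        curves.append(Sensorgram(times, clean.response + noise, conc, phases))
    return curves, params


def spec_with(spec: FixtureSpec, **overrides) -> FixtureSpec:
    """Functional update helper (dataclasses.replace re-export)."""
    return replace(spec, **overrides)
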