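"""Replica-ensemble trajectory metrics.

Implements the analysis battery applied to the antibody-antigen MD
ensembles: 1 ns subsampling with replica-balanced frame selection,
antigen-fitted antibody RMSD with replica mean +/- SEM, plateau
averages over the final window, per-residue center-of-mass RMSF about
the average structure, heavy-atom contact and geometric hydrogen-bond
time series, and the percent-difference statistic used to compare the
two antibody clones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import SelectionError, UndefinedRatioError, ValidationError
from .pose_analysis import kabsch_superpose
from .settings import HBondCriteria
from .structio import (
    ReplicaEnsemble,
    Selection,
    StructureModel,
    Trajectory,
    element_mass,
    resolve_selection,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TimeSeries", "EnsembleSeries", "RMSFProfile",
    "subsample", "balanced_frames", "fitted_rmsd_series", "ensemble_stats",
    "plateau_value", "rmsf_com", "contact_count", "hbond_count",
    "interface_series", "percent_difference",
]


@dataclass
class TimeSeries:
    """One scalar observable per frame."""

    times: np.ndarray   # ns
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValidationError("times and values must have equal length")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")


@dataclass
class EnsembleSeries:
    """Per-replica series on one time grid with pointwise mean and SEM.

    SEM uses the sample standard deviation (n-1 denominator) divided by
    sqrt(n_replicas); with a single replica it is undefined and carried
    as ``None``.
    """

    replicas: list[TimeSeries]
    mean: TimeSeries = field(init=False)
    sem: TimeSeries | None = field(init=False)

    def __post_init__(self) -> None:
        if not self.replicas:
            raise ValidationError("need at least one series")
        grid = self.replicas[0].times
        for ts in self.replicas[1:]:
            if ts.times.shape != grid.shape or not np.allclose(ts.times, grid):
                raise ValidationError("replica series on mismatched time grids")
        stacked = np.stack([ts.values for ts in self.replicas])
        self.mean = TimeSeries(grid, stacked.mean(axis=0), label="mean")
        if stacked.shape[0] > 1:
            sem = stacked.std(axis=0, ddof=1) / np.sqrt(stacked.shape[0])
            self.sem = TimeSeries(grid, sem, label="sem")
        else:
            self.sem = None

    @property
    def n_replicas(self) -> int:
        return len(self.replicas)


@dataclass
class RMSFProfile:
    """Per-residue RMSF (A), keyed by (chain, residue_index)."""

    values: dict[tuple, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.values.values()):
            raise ValidationError("RMSF values must be non-negative")


def subsample(traj: Trajectory, interval: float = 1.0) -> Trajectory:
    """Keep the first frame at or after each multiple of ``interval`` ns."""
    if interval <= 0:
        raise ValidationError("subsample interval must be positive")
    times = traj.frame_times
    eps = 1e-9 * max(interval, 1.0)
    keep: list[int] = []
    k = 0
    n_marks = int(np.floor((times[-1] - times[0]) / interval + eps)) + 1
    for m in range(n_marks):
        target = times[0] + m * interval
        while k < times.size and times[k] < target - eps:
            k += 1
        if k < times.size and (not keep or keep[-1] != k):
            keep.append(k)
    idx = np.asarray(keep, dtype=int)
    return Trajectory(traj.topology, traj.frames[idx], times[idx])


def balanced_frames(ensemble: ReplicaEnsemble, interval: float = 1.0
                    ) -> ReplicaEnsemble:
    """Subsample each replica, then truncate all to the minimum frame count.

    Equalizing the frame count across replicas removes the statistical
    bias a longer replica would otherwise carry in ensemble averages.
    """
    subsampled = [subsample(t, interval) for t in ensemble.replicas]
    n_min = min(t.n_frames for t in subsampled)
    trimmed = [Trajectory(t.topology, t.frames[:n_min], t.frame_times[:n_min])
               for t in subsampled]
    return ReplicaEnsemble(trimmed, ensemble.complex_label,
                           ensemble.per_replica_duration)


def _heavy_indices(model: StructureModel, sel: Selection) -> np.ndarray:
    idx = resolve_selection(model, sel)
    if idx.size == 0:
        raise SelectionError(f"selection {sel.expression!r} resolves to no atoms")
    return idx[[not model.atoms[i].is_hydrogen for i in idx]]


def fitted_rmsd_series(traj: Trajectory, reference: np.ndarray,
                       fit_sel: Selection, calc_sel: Selection,
                       label: str = "rmsd") -> TimeSeries:
    """Per-frame RMSD of ``calc_sel`` heavy atoms after fitting on ``fit_sel``.

    Each frame is rigidly superposed onto the reference using the fit
    selection (e.g. the antigen), then the RMSD of the calc selection
    (e.g. the bound antibody) is evaluated without refitting -- the
    displacement of the binder relative to the antigen frame.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (len(traj.topology), 3):
        raise ValidationError("reference must cover the full topology")
    fit_idx = resolve_selection(traj.topology, fit_sel)
    calc_idx = _heavy_indices(traj.topology, calc_sel)
    if fit_idx.size == 0:
        raise SelectionError("fit selection resolves to no atoms")
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        transform, _ = kabsch_superpose(traj.frames[f], reference,
                                        fit_indices=(fit_idx, fit_idx))
        moved = transform.apply(traj.frames[f][calc_idx])
        diff = moved - reference[calc_idx]
        values[f] = np.sqrt((diff ** 2).sum(axis=1).mean())
    return TimeSeries(traj.frame_times, values, label=label)


def ensemble_stats(series: list[TimeSeries]) -> EnsembleSeries:
    """Pointwise replica mean and SEM on a common time grid."""
    return EnsembleSeries(list(series))


def plateau_value(series: EnsembleSeries, window: float = 200.0
                  ) -> tuple[float, float | None]:
    """Time-average over the final ``window`` ns, with replica SEM.

    The value is the time-average of the ensemble mean over frames with
    t >= t_end - window; the uncertainty is the SEM across the replica
    time-averages of the same window (``None`` for a single replica).
    A window longer than the series span is clipped with a warning.
    """
    times = series.mean.times
    if times.size == 0:
        raise ValidationError("empty series")
    span = times[-1] - times[0]
    if window > span:
        logger.warning("plateau window %.6g ns exceeds series span %.6g ns; "
                       "using the whole series", window, span)
        window = span
    mask = times >= times[-1] - window - 1e-9
    value = float(series.mean.values[mask].mean())
    if series.n_replicas < 2:
        return value, None
    replica_means = np.array([ts.values[mask].mean() for ts in series.replicas])
    sem = float(replica_means.std(ddof=1) / np.sqrt(replica_means.size))
    return value, sem


def _mass_weights(model: StructureModel, idx: np.ndarray) -> np.ndarray:
    return np.array([element_mass(model.atoms[i].element) for i in idx])


def rmsf_com(source: ReplicaEnsemble | Trajectory, fit_sel: Selection,
             mass_weighted: bool = True) -> RMSFProfile:
    """Per-residue center-of-mass RMSF about the average structure.

    Frames are superposed onto the average structure before measuring
    fluctuations, in two passes: fit every frame to frame 0 of the
    first replica, average the fitted coordinates, re-fit the original
    frames onto that average, and re-average.  The residue RMSF is then
    sqrt(mean_t |com_r(t) - com_r(avg)|^2) where com uses standard
    atomic masses (or unit weights with ``mass_weighted=False``).
    """
    trajs = source.replicas if isinstance(source, ReplicaEnsemble) else [source]
    topology = trajs[0].topology
    all_frames = np.concatenate([t.frames for t in trajs], axis=0)
    if all_frames.shape[0] < 2:
        raise ValidationError("RMSF needs at least two frames")
    fit_idx = resolve_selection(topology, fit_sel)
    if fit_idx.size < 3:
        raise SelectionError("fit selection needs >= 3 atoms")

    def fit_all(frames: np.ndarray, reference: np.ndarray) -> np.ndarray:
        out = np.empty_like(frames)
        for f in range(frames.shape[0]):
            transform, _ = kabsch_superpose(frames[f], reference,
                                            fit_indices=(fit_idx, fit_idx))
            out[f] = transform.apply(frames[f])
        return out

    pass1 = fit_all(all_frames, all_frames[0])
    average = pass1.mean(axis=0)
    pass2 = fit_all(all_frames, average)
    average = pass2.mean(axis=0)

    values: dict[tuple, float] = {}
    for key, idx in topology.residue_atom_indices().items():
        if mass_weighted:
            w = _mass_weights(topology, idx)
            w = w / w.sum()
        else:
            w = np.full(idx.size, 1.0 / idx.size)
        coms = np.einsum("fij,i->fj", pass2[:, idx, :], w)
        com_avg = average[idx].T @ w
        sq = ((coms - com_avg) ** 2).sum(axis=1)
        values[key] = float(np.sqrt(sq.mean()))
    return RMSFProfile(values)


def contact_count(frame: np.ndarray, model: StructureModel,
                  group_a: Selection, group_b: Selection,
                  cutoff: float = 4.5) -> int:
    """Heavy-atom pairs between two disjoint groups strictly closer than cutoff."""
    idx_a = _heavy_indices(model, group_a)
    idx_b = _heavy_indices(model, group_b)
    if np.intersect1d(idx_a, idx_b).size:
        raise SelectionError("contact groups overlap")
    frame = np.asarray(frame, dtype=float)
    tree_a = cKDTree(frame[idx_a])
    tree_b = cKDTree(frame[idx_b])
    count = 0
    for i, neighbors in enumerate(tree_a.query_ball_tree(tree_b, cutoff)):
        for j in neighbors:
            if np.linalg.norm(frame[idx_a[i]] - frame[idx_b[j]]) < cutoff:
                count += 1
    return count


_DONOR_ACCEPTOR_ELEMENTS = {"N", "O"}
_DH_BOND_CUTOFF = 1.2  # A, geometric bond inference for donor hydrogens


def _donor_hydrogens(frame: np.ndarray, model: StructureModel,
                     donor_idx: np.ndarray) -> dict[int, list[int]]:
    """Map donor heavy-atom index -> hydrogens within the covalent cutoff."""
    h_idx = np.array([i for i, a in enumerate(model.atoms) if a.is_hydrogen],
                     dtype=int)
    attached: dict[int, list[int]] = {}
    if h_idx.size == 0:
        return attached
    tree_h = cKDTree(frame[h_idx])
    for d in donor_idx:
        near = tree_h.query_ball_point(frame[d], _DH_BOND_CUTOFF)
        if near:
            attached[int(d)] = [int(h_idx[k]) for k in near]
    return attached


def hbond_count(frame: np.ndarray, model: StructureModel,
                donor_group: Selection, acceptor_group: Selection,
                criteria: HBondCriteria | None = None) -> int:
    """Geometric hydrogen bonds between donor and acceptor groups.

    Donors are N/O heavy atoms of the donor group carrying >= 1 hydrogen
    within 1.2 A (geometric bond inference; a donor without hydrogens is
    skipped).  Acceptors are N/O heavy atoms of the acceptor group.  A
    (D, H, A) triple counts when dist(D, A) <= da_cutoff (inclusive)
    and the three-point D-H...A angle at the hydrogen is >= angle_min.
    """
    criteria = criteria or HBondCriteria()
    frame = np.asarray(frame, dtype=float)
    donors = np.array([i for i in _heavy_indices(model, donor_group)
                       if model.atoms[i].element.upper()
                       in _DONOR_ACCEPTOR_ELEMENTS], dtype=int)
    acceptors = np.array([i for i in _heavy_indices(model, acceptor_group)
                          if model.atoms[i].element.upper()
                          in _DONOR_ACCEPTOR_ELEMENTS], dtype=int)
    if donors.size == 0 or acceptors.size == 0:
        return 0
    attached = _donor_hydrogens(frame, model, donors)
    count = 0
    tree_acc = cKDTree(frame[acceptors])
    for d in donors:
        hydrogens = attached.get(int(d))
        if not hydrogens:
            logger.debug("donor atom %d has no attached hydrogen; skipped", d)
            continue
        for k in tree_acc.query_ball_point(frame[d], criteria.da_cutoff):
            a = int(acceptors[k])
            if a == d:
                continue
            dist = np.linalg.norm(frame[d] - frame[a])
            if dist > criteria.da_cutoff + 1e-12:
                continue
            for h in hydrogens:
                v1 = frame[d] - frame[h]
                v2 = frame[a] - frame[h]
                n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
                if n1 == 0 or n2 == 0:
                    continue
                cos = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
                angle = np.degrees(np.arccos(cos))
                if angle >= criteria.angle_min - 1e-9:
                    count += 1
    return count


def interface_series(ensemble: ReplicaEnsemble, metric: str,
                     group_a: Selection, group_b: Selection,
                     cutoff: float | None = None,
                     criteria: HBondCriteria | None = None) -> EnsembleSeries:
    """Per-frame interface metric per replica, aggregated ensemble-wise.

    ``metric`` is ``"contacts"`` (group_a vs group_b heavy-atom pairs,
    default cutoff 4.5 A) or ``"hbonds"`` (group_a as donors, group_b as
    acceptors).  The ensemble should be balanced first so every replica
    contributes the same number of frames.
    """
    counts_per_replica = {t.n_frames for t in ensemble.replicas}
    if len(counts_per_replica) > 1:
        raise ValidationError(
            "ensemble is not balanced; call balanced_frames first")
    model = ensemble.topology
    series = []
    for r, traj in enumerate(ensemble.replicas):
        values = np.empty(traj.n_frames)
        for f in range(traj.n_frames):
            if metric == "contacts":
                values[f] = contact_count(traj.frames[f], model, group_a,
                                          group_b, cutoff=cutoff or 4.5)
            elif metric == "hbonds":
                values[f] = hbond_count(traj.frames[f], model, group_a,
                                        group_b, criteria=criteria)
            else:
                raise ValidationError(f"unknown metric {metric!r}")
        series.append(TimeSeries(traj.frame_times, values,
                                 label=f"{metric}_rep{r}"))
    return ensemble_stats(series)


def percent_difference(a: EnsembleSeries, b: EnsembleSeries) -> float:
    """100 x (mean(a) - mean(b)) / mean(b), replica-weighted.

    Each replica contributes its frame-average; replicas are averaged
    with equal weight before the ratio is formed.  A zero denominator
    is an error.
    """
    def grand_mean(series: EnsembleSeries) -> float:
        return float(np.mean([ts.values.mean() for ts in series.replicas]))

    mean_a, mean_b = grand_mean(a), grand_mean(b)
    if mean_b == 0:
        raise UndefinedRatioError("reference ensemble mean is zero")
    return 100.0 * (mean_a - mean_b) / mean_b
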