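"""Bivalent-analyte SPR kinetics: simulation, global fitting, affinities.

Two kinetic interpretations of a two-step parameter table are provided:

``bivalent``
    The classical bivalent-analyte scheme.  A first attachment
    (ka1 [1/(M s)], kd1 [1/s]) creates singly bound analyte R1, which a
    second arm can convert into doubly bound R2 (ka2 [1/(RU s)],
    kd2 [1/s]), both consuming free surface capacity Bmax [RU]::

        dR1/dt = ka1 C (Bmax - R1 - R2) - kd1 R1
                 - ka2 R1 (Bmax - R1 - R2) + kd2 R2
        dR2/dt = ka2 R1 (Bmax - R1 - R2) - kd2 R2

    with C the analyte concentration during association and 0 during
    dissociation; the measured response is R1 + R2.

``two_site``
    Two independent parallel Langmuir sites (ka_i [1/(M s)], kd_i,
    Bmax_i), the interpretation consistent with a table that prints two
    Bmax values; the response is the sum of the two sites and each site
    has the closed-form Langmuir solution.

Equilibrium affinities are always the exact quotient KD_i = kd_i/ka_i.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .errors import SolverError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "BivalentParams", "PhaseSchedule", "Sensorgram", "FitResult",
    "simulate_bivalent", "simulate_two_site", "fit_global", "derive_kd",
    "validate_printed_affinity", "REFERENCE_KINETICS",
]


@dataclass(frozen=True)
class BivalentParams:
    """Rate constants and capacities of the two-step surface interaction.

    ``ka2`` units depend on the model: 1/(RU s) for ``bivalent`` (the
    second step consumes surface sites), 1/(M s) for ``two_site``.
    ``bmax2`` is only meaningful for ``two_site`` and may be ``None``.
    """

    ka1: float
    kd1: float
    ka2: float
    kd2: float
    bmax1: float
    bmax2: float | None = None

    def __post_init__(self) -> None:
        for name in ("ka1", "kd1", "ka2", "kd2", "bmax1"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.bmax2 is not None and self.bmax2 <= 0:
            raise ValidationError("bmax2 must be positive when given")

    @property
    def kd_equilibrium_1(self) -> float:
        return derive_kd(self.ka1, self.kd1)

    @property
    def kd_equilibrium_2(self) -> float:
        return derive_kd(self.ka2, self.kd2)


@dataclass(frozen=True)
class PhaseSchedule:
    """Association/dissociation phase boundaries in seconds."""

    assoc_end: float
    dissoc_end: float
    assoc_start: float = 0.0

    def __post_init__(self) -> None:
        if not self.assoc_start <= self.assoc_end <= self.dissoc_end:
            raise ValidationError("phases must be ordered: start <= assoc_end <= dissoc_end")

    def labels(self, times: np.ndarray) -> np.ndarray:
        return np.where(np.asarray(times) <= self.assoc_end + 1e-12,
                        "association", "dissociation")


@dataclass
class Sensorgram:
    """SPR response (RU) versus time for one analyte concentration."""

    times: np.ndarray       # s
    response: np.ndarray    # RU
    conc: float             # M
    phases: PhaseSchedule

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.times.shape != self.response.shape:
            raise ValidationError("times and response must have equal length")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if self.conc < 0:
            raise ValidationError("analyte concentration must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.times,
            "response_RU": self.response,
            "conc_M": self.conc,
            "phase": self.phases.labels(self.times),
        })


@dataclass
class FitResult:
    """Outcome of a global fit over several concentrations."""

    params: BivalentParams
    rss: float
    stderr: dict[str, float]
    converged: bool
    model: str
    units: dict[str, str] = field(default_factory=dict)
    degenerate: bool = False
    n_starts: int = 0
    seed: int | None = None


def derive_kd(ka: float, kd: float) -> float:
    """Equilibrium dissociation constant KD = kd / ka (exact quotient)."""
    if ka <= 0:
        raise ValidationError("association rate must be positive")
    return kd / ka


def validate_printed_affinity(ka: float, kd: float, printed_kd: float
                              ) -> tuple[bool, float]:
    """Check a printed KD against its own printed ka/kd at 3 sig. figures.

    Printed inputs are themselves rounded, so agreement means the
    derived kd/ka matches the printed value within one unit in the
    third significant figure.  Returns (consistent, derived value).
    """
    derived = derive_kd(ka, kd)
    if printed_kd <= 0:
        raise ValidationError("printed KD must be positive")
    ulp = 10.0 ** (np.floor(np.log10(printed_kd)) - 2)
    return bool(abs(derived - printed_kd) <= 1.05 * ulp), derived


# Published SPR kinetic constants for the two anti-PD-L1 clones, as read
# from the instrument's bivalent global fit (capacities in RU, ka in
# 1/(M s), kd in 1/s, KD in M).  Inputs for worked examples and
# consistency checks; the 12F1-1 first-step row does not satisfy
# KD = kd/ka at its printed exponents (see validate_printed_affinity).
REFERENCE_KINETICS: dict[str, dict[str, float]] = {
    "12F1-1": {
        "bmax1": 310.13, "ka1": 2.08e12, "kd1": 6.34e-14, "KD1": 3.05e-16,
        "bmax2": 82.69, "ka2": 1.10e3, "kd2": 1.45e-2, "KD2": 1.32e-5,
    },
    "11B12-1": {
        "bmax1": 167.60, "ka1": 2.12e2, "kd1": 3.08e-14, "KD1": 1.45e-16,
        "bmax2": 23.38, "ka2": 3.47e4, "kd2": 3.22e-4, "KD2": 9.27e-9,
    },
}


def _integrate_bivalent(params: BivalentParams, concs: np.ndarray,
                        times: np.ndarray, y0: np.ndarray,
                        rtol: float = 1e-8) -> np.ndarray:
    """Integrate the bivalent ODE for several concentrations at once.

    ``y0`` has shape (n_conc, 2); returns (n_times, n_conc, 2).  The
    per-concentration systems are independent, so stacking them into
    one state vector costs nothing in accuracy and saves solver
    overhead in global fits.
    """
    bmax = params.bmax1
    n_conc = concs.size

    def rhs(_t, y):
        y = y.reshape(n_conc, 2)
        r1, r2 = y[:, 0], y[:, 1]
        free = bmax - r1 - r2
        step2 = params.ka2 * r1 * free - params.kd2 * r2
        out = np.empty_like(y)
        out[:, 0] = params.ka1 * concs * free - params.kd1 * r1 - step2
        out[:, 1] = step2
        return out.ravel()

    if times.size == 1:
        return y0[None, :, :].copy()
    sol = solve_ivp(rhs, (times[0], times[-1]), y0.ravel(), t_eval=times,
                    method="LSODA", rtol=rtol,
                    atol=1e-10 * max(bmax, 1.0))
    if not sol.success:
        raise SolverError(f"bivalent ODE integration failed: {sol.message}")
    return sol.y.T.reshape(times.size, n_conc, 2)


def _bivalent_responses(params: BivalentParams, concs: np.ndarray,
                        times: np.ndarray, phases: PhaseSchedule,
                        rtol: float = 1e-8) -> np.ndarray:
    """(n_conc, n_times) response matrix for a shared time grid."""
    assoc_mask = times <= phases.assoc_end + 1e-12
    t_assoc = times[assoc_mask]
    t_dissoc = times[~assoc_mask]
    n_conc = concs.size
    y0 = np.zeros((n_conc, 2))
    out = np.zeros((times.size, n_conc, 2))
    if t_assoc.size:
        y_assoc = _integrate_bivalent(params, concs, t_assoc, y0, rtol)
        out[assoc_mask] = y_assoc
        y0 = y_assoc[-1]
        if t_dissoc.size and t_assoc[-1] < phases.assoc_end - 1e-12:
            # carry the state exactly to the phase boundary
            bridge = np.array([t_assoc[-1], phases.assoc_end])
            y0 = _integrate_bivalent(params, concs, bridge, y0, rtol)[-1]
    if t_dissoc.size:
        if t_dissoc[0] > phases.assoc_end + 1e-12:
            t_grid = np.concatenate(([phases.assoc_end], t_dissoc))
            y_dissoc = _integrate_bivalent(params, np.zeros(n_conc), t_grid,
                                           y0, rtol)[1:]
        else:
            y_dissoc = _integrate_bivalent(params, np.zeros(n_conc), t_dissoc,
                                           y0, rtol)
        out[~assoc_mask] = y_dissoc
    return out.sum(axis=2).T


def simulate_bivalent(params: BivalentParams, conc: float,
                      times: np.ndarray, phases: PhaseSchedule) -> Sensorgram:
    """Integrate the bivalent-analyte model over both phases.

    The analyte concentration is ``conc`` while t <= assoc_end and zero
    afterwards; the surface starts empty.  LSODA integration with
    rtol 1e-8 and atol 1e-10*Bmax keeps 0 <= R1+R2 <= Bmax to well
    within 1e-6*Bmax.
    """
    times = np.asarray(times, dtype=float)
    if conc < 0:
        raise ValidationError("analyte concentration must be >= 0")
    if conc == 0.0:
        return Sensorgram(times, np.zeros_like(times), conc, phases)
    response = _bivalent_responses(params, np.array([conc]), times, phases)[0]
    return Sensorgram(times, response, conc, phases)


def _langmuir_site(ka: float, kd: float, bmax: float, conc: float,
                   times: np.ndarray, phases: PhaseSchedule) -> np.ndarray:
    """Closed-form single-site response from an empty surface."""
    response = np.zeros_like(times)
    assoc_mask = times <= phases.assoc_end + 1e-12
    kobs = ka * conc + kd
    req = bmax * ka * conc / kobs if kobs > 0 else 0.0
    t0 = phases.assoc_start
    response[assoc_mask] = req * (1.0 - np.exp(-kobs * (times[assoc_mask] - t0)))
    r_end = req * (1.0 - np.exp(-kobs * (phases.assoc_end - t0)))
    td = times[~assoc_mask] - phases.assoc_end
    response[~assoc_mask] = r_end * np.exp(-kd * td)
    return response


def simulate_two_site(params: BivalentParams, conc: float,
                      times: np.ndarray, phases: PhaseSchedule) -> Sensorgram:
    """Two independent parallel Langmuir sites; exact closed form."""
    times = np.asarray(times, dtype=float)
    if conc < 0:
        raise ValidationError("analyte concentration must be >= 0")
    response = _langmuir_site(params.ka1, params.kd1, params.bmax1, conc,
                              times, phases)
    if params.bmax2 is not None and params.bmax2 > 0:
        response = response + _langmuir_site(params.ka2, params.kd2,
                                             params.bmax2, conc, times, phases)
    return Sensorgram(times, response, conc, phases)


_SIMULATORS = {"bivalent": simulate_bivalent, "two_site": simulate_two_site}

_BIVALENT_UNITS = {"ka1": "1/(M s)", "kd1": "1/s", "ka2": "1/(RU s)",
                   "kd2": "1/s", "bmax1": "RU"}
_TWO_SITE_UNITS = {"ka1": "1/(M s)", "kd1": "1/s", "ka2": "1/(M s)",
                   "kd2": "1/s", "bmax1": "RU", "bmax2": "RU"}

# Default log-uniform search boxes; ka2 units differ by model, so its
# default range does too (surface-site attachment vs a second Langmuir site).
DEFAULT_PARAM_BOX: dict[str, dict[str, tuple[float, float]]] = {
    "bivalent": {
        "ka1": (1e3, 1e9), "kd1": (1e-6, 1e0), "ka2": (1e-8, 1e-1),
        "kd2": (1e-6, 1e1), "bmax1": (1e-2, 1e4),
    },
    "two_site": {
        "ka1": (1e3, 1e9), "kd1": (1e-6, 1e0), "ka2": (1e2, 1e8),
        "kd2": (1e-6, 1e1), "bmax1": (1e-2, 1e4), "bmax2": (1e-2, 1e4),
    },
}


def _params_from_vector(theta: np.ndarray, names: list[str]) -> BivalentParams:
    values = dict(zip(names, 10.0 ** theta))
    return BivalentParams(
        ka1=values["ka1"], kd1=values["kd1"], ka2=values["ka2"],
        kd2=values["kd2"], bmax1=values["bmax1"],
        bmax2=values.get("bmax2"))


def fit_global(sensorgrams: list[Sensorgram], model: str = "bivalent",
               init: dict[str, tuple[float, float]] | None = None,
               seed: int = 0, n_starts: int = 8) -> FitResult:
    """Global least-squares fit of shared parameters across all curves.

    Parameters are optimized in log10 space inside the ``init`` box
    (falling back to :data:`DEFAULT_PARAM_BOX`), with ``n_starts``
    seeded multi-starts: the first at the box center, the rest drawn
    uniformly in log space.  Trust-region reflective least squares with
    ftol = xtol = 1e-10.  Non-convergence of every start yields a
    flagged result, not an exception.
    """
    if model not in _SIMULATORS:
        raise ValidationError(f"unknown model {model!r}")
    if not sensorgrams:
        raise ValidationError("need at least one sensorgram")
    if len(sensorgrams) < 2:
        logger.warning("global fit with a single concentration is "
                       "poorly constrained")
    names = ["ka1", "kd1", "ka2", "kd2", "bmax1"]
    if model == "two_site":
        names.append("bmax2")
    box = dict(DEFAULT_PARAM_BOX[model])
    box.update(init or {})
    lo = np.log10([box[n][0] for n in names])
    hi = np.log10([box[n][1] for n in names])
    simulate = _SIMULATORS[model]
    observed = np.concatenate([s.response for s in sensorgrams])

    shared_grid = all(
        s.times.shape == sensorgrams[0].times.shape
        and np.array_equal(s.times, sensorgrams[0].times)
        and s.phases == sensorgrams[0].phases
        for s in sensorgrams)

    if model == "bivalent" and shared_grid:
        concs = np.array([s.conc for s in sensorgrams])
        grid, phases = sensorgrams[0].times, sensorgrams[0].phases

        def residuals(theta: np.ndarray, rtol: float = 1e-8) -> np.ndarray:
            params = _params_from_vector(theta, names)
            pred = _bivalent_responses(params, concs, grid, phases, rtol)
            return pred.ravel() - observed
    else:
        def residuals(theta: np.ndarray, rtol: float = 1e-8) -> np.ndarray:
            params = _params_from_vector(theta, names)
            pred = np.concatenate([
                simulate(params, s.conc, s.times, s.phases).response
                for s in sensorgrams])
            return pred - observed

    rng = np.random.default_rng(seed)
    starts = [0.5 * (lo + hi)]
    starts += [rng.uniform(lo, hi) for _ in range(max(0, n_starts - 1))]

    # two-stage multi-start: cheap screening pass per start, then a full
    # polish of the best candidate at tight tolerances
    candidates = []
    for theta0 in starts:
        try:
            res = least_squares(residuals, theta0, bounds=(lo, hi),
                                method="trf", ftol=1e-6, xtol=1e-6,
                                max_nfev=40, kwargs={"rtol": 1e-5})
        except (SolverError, ValidationError) as exc:
            logger.debug("start rejected: %s", exc)
            continue
        candidates.append(res)
    best = None
    if candidates:
        screened = min(candidates, key=lambda r: r.cost)
        try:
            best = least_squares(residuals, screened.x, bounds=(lo, hi),
                                 method="trf", ftol=1e-10, xtol=1e-10,
                                 gtol=1e-10)
            if not best.success:
                best = None
        except (SolverError, ValidationError) as exc:
            logger.debug("polish failed: %s", exc)

    if best is None:
        center = _params_from_vector(0.5 * (lo + hi), names)
        return FitResult(center, rss=float("inf"), stderr={},
                         converged=False, model=model,
                         units=_BIVALENT_UNITS if model == "bivalent"
                         else _TWO_SITE_UNITS,
                         n_starts=n_starts, seed=seed)

    params = _params_from_vector(best.x, names)
    rss = float(2.0 * best.cost)
    m, n = observed.size, len(names)
    stderr: dict[str, float] = {}
    if m > n:
        jac = best.jac
        try:
            cov = np.linalg.inv(jac.T @ jac) * (rss / (m - n))
            se_log10 = np.sqrt(np.clip(np.diag(cov), 0, None))
            linear = 10.0 ** best.x
            for name, p, se in zip(names, linear, se_log10):
                stderr[name] = float(np.log(10.0) * p * se)
        except np.linalg.LinAlgError:
            logger.warning("singular Jacobian; no standard errors reported")
    degenerate = (np.max(np.abs(observed)) == 0.0
                  or np.isclose(np.log10(params.bmax1), lo[names.index("bmax1")],
                                atol=1e-3))
    return FitResult(params, rss=rss, stderr=stderr, converged=True,
                     model=model,
                     units=_BIVALENT_UNITS if model == "bivalent"
                     else _TWO_SITE_UNITS,
                     degenerate=bool(degenerate),
                     n_starts=n_starts, seed=seed)


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

def write_sensorgrams(sensorgrams: list[Sensorgram], path) -> None:
    """Write curves to CSV (columns time_s, response_RU, conc_M, phase)."""
    pd.concat([s.to_frame() for s in sensorgrams],
              ignore_index=True).to_csv(path, index=False)


def read_sensorgrams(path) -> list[Sensorgram]:
    """Read curves from CSV, one Sensorgram per distinct concentration."""
    frame = pd.read_csv(path)
    required = {"time_s", "response_RU", "conc_M", "phase"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"sensorgram CSV missing columns {sorted(missing)}")
    out = []
    for conc, group in frame.groupby("conc_M", sort=True):
        group = group.sort_values("time_s")
        assoc = group[group["phase"] == "association"]
        if assoc.empty:
            raise ValidationError(f"curve at {conc} M has no association phase")
        phases = PhaseSchedule(
            assoc_start=float(assoc["time_s"].iloc[0]),
            assoc_end=float(assoc["time_s"].iloc[-1]),
            dissoc_end=float(group["time_s"].iloc[-1]))
        out.append(Sensorgram(group["time_s"].to_numpy(),
                              group["response_RU"].to_numpy(),
                              float(conc), phases))
    return out
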