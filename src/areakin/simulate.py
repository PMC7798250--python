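"""Deterministic time-course integration and equilibrium metrics.

Time courses are computed with SciPy's LSODA wrapper (automatic
stiff/non-stiff switching, as is customary for biochemical networks).
The state is integrated in amounts; :class:`Trajectory` exposes the
concentration view.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import IntegrationError, NotEquilibratedError, SteadyStateError
from .model import Model, assemble_rhs

__all__ = [
    "Trajectory",
    "EquilibriumMetrics",
    "integrate",
    "equilibrium_metrics",
    "steady_state",
    "SteadyStateResult",
]

#: solver defaults; atol is in amount units (µM·µm³)
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-12


@dataclass
class Trajectory:
    """Time grid plus per-species amounts from one integration run."""

    times: np.ndarray
    amounts: np.ndarray  # shape (n_times, n_species)
    species: tuple[str, ...]
    volumes: np.ndarray  # per-species own-compartment volume
    rtol: float
    atol: float
    success: bool = True
    message: str = ""

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise IntegrationError("trajectory time grid must be strictly increasing")

    @property
    def concentrations(self) -> np.ndarray:
        return self.amounts / self.volumes

    def _col(self, sid: str) -> int:
        try:
            return self.species.index(sid)
        except ValueError:
            raise KeyError(f"no species {sid!r} in trajectory") from None

    def amount(self, sid: str) -> np.ndarray:
        return self.amounts[:, self._col(sid)]

    def concentration(self, sid: str) -> np.ndarray:
        return self.amounts[:, self._col(sid)] / self.volumes[self._col(sid)]

    def final_concentrations(self) -> dict[str, float]:
        return {sid: float(self.concentration(sid)[-1]) for sid in self.species}

    def to_frame(self) -> pd.DataFrame:
        """Tidy table with one row per (time, species)."""
        rows = []
        conc = self.concentrations
        for j, sid in enumerate(self.species):
            rows.append(pd.DataFrame({
                "time": self.times,
                "species": sid,
                "amount": self.amounts[:, j],
                "concentration": conc[:, j],
            }))
        return pd.concat(rows, ignore_index=True)


def integrate(model: Model, t_end: float, n_points: int = 1000,
              rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL,
              method: str = "LSODA", y0: np.ndarray | None = None) -> Trajectory:
    """Integrate the model's amount ODEs over [0, t_end] on a uniform grid.

    Raises :class:`IntegrationError` (never fails silently) if the solver
    does not converge; the solver message is attached.
    """
    if t_end <= 0:
        raise IntegrationError(f"t_end must be > 0, got {t_end}")
    if rtol <= 0 or atol <= 0:
        raise IntegrationError("tolerances must be > 0")
    rhs = assemble_rhs(model)
    if y0 is None:
        y0 = model.initial_amounts()
    t_eval = np.linspace(0.0, float(t_end), int(n_points))
    sol = solve_ivp(rhs, (0.0, float(t_end)), np.asarray(y0, dtype=float),
                    method=method, t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(
            f"solver {method} failed after t={sol.t[-1] if sol.t.size else 0:g}: {sol.message}"
        )
    volumes = np.array([model.volume_of(s.id) for s in model.species])
    return Trajectory(times=sol.t, amounts=sol.y.T, species=model.species_ids,
                      volumes=volumes, rtol=rtol, atol=atol, success=True,
                      message=sol.message)


@dataclass
class EquilibriumMetrics:
    """Per-species equilibrium concentration, relaxation time and peak.

    ``time_to_fraction[s]`` is the first time at which species ``s`` has
    closed fraction ``fraction`` of the gap between its initial and
    equilibrium concentration, i.e. |C(t) − C_eq| ≤ (1−f)·|C(0) − C_eq|.
    """

    fraction: float
    equilibrium_concentrations: dict[str, float]
    time_to_fraction: dict[str, float]
    peak_concentration: dict[str, float]
    peak_time: dict[str, float]


def _check_equilibrated(traj: Trajectory, rel_tol: float) -> None:
    n_tail = max(2, int(round(0.05 * len(traj.times))))
    conc = traj.concentrations
    tail = conc[-n_tail:, :]
    spread = tail.max(axis=0) - tail.min(axis=0)
    # relative to the species' overall dynamic scale; all-zero species are
    # trivially settled
    scale = np.maximum(np.abs(conc).max(axis=0), 1e-300)
    bad = [traj.species[j] for j in range(conc.shape[1])
           if spread[j] > rel_tol * scale[j] and np.abs(conc[:, j]).max() > 0]
    if bad:
        raise NotEquilibratedError(
            f"species {bad} still vary by more than {rel_tol:.1e} (relative) over "
            f"the final {n_tail} points; integrate to a larger t_end"
        )


def equilibrium_metrics(traj: Trajectory, fraction: float = 0.95,
                        equilibration_rel_tol: float = 1e-3) -> EquilibriumMetrics:
    """Equilibrium concentrations, time-to-fraction and transient peaks.

    The trajectory must have settled: the final 5% of points may vary by
    at most ``equilibration_rel_tol`` relative to each species' dynamic
    range, otherwise :class:`NotEquilibratedError` advises a longer run.
    C_eq is taken as the final point after that check.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    _check_equilibrated(traj, equilibration_rel_tol)

    eq, t_to, peak, peak_t = {}, {}, {}, {}
    for sid in traj.species:
        c = traj.concentration(sid)
        c_eq = float(c[-1])
        eq[sid] = c_eq
        gap = np.abs(c - c_eq)
        threshold = (1.0 - fraction) * gap[0]
        if gap[0] == 0.0:
            t_to[sid] = 0.0
        else:
            inside = gap <= threshold
            i = int(np.argmax(inside))  # first index satisfying the bound
            if i == 0:
                t_to[sid] = 0.0
            else:
                # linear interpolation of |C - C_eq| between the bracketing points
                g0, g1 = gap[i - 1], gap[i]
                frac = (g0 - threshold) / (g0 - g1) if g0 != g1 else 1.0
                t_to[sid] = float(traj.times[i - 1] + frac * (traj.times[i] - traj.times[i - 1]))
        j = int(np.argmax(c))  # earliest global max
        peak[sid] = float(c[j])
        peak_t[sid] = float(traj.times[j])
    return EquilibriumMetrics(fraction=fraction, equilibrium_concentrations=eq,
                              time_to_fraction=t_to, peak_concentration=peak,
                              peak_time=peak_t)


@dataclass
class SteadyStateResult:
    amounts: np.ndarray
    concentrations: dict[str, float]
    residual: float  # ||d(amounts)/dt||_inf at the returned state
    species: tuple[str, ...] = field(default=())


def _newton_polish(rhs, n: np.ndarray, residual_tol: float,
                   max_iter: int = 12) -> tuple[np.ndarray, float]:
    """Damped Newton iterations with a least-squares step.

    The least-squares solve handles the singular Jacobians of closed
    (mass-conserving) systems by taking the minimal-norm step, which keeps
    the iterate on the conserved-stoichiometry affine subspace.
    """
    scale = max(1.0, float(np.max(np.abs(n))))
    f = rhs(0.0, n)
    res = float(np.max(np.abs(f))) if f.size else 0.0
    for _ in range(max_iter):
        if res <= residual_tol:
            break
        m = len(n)
        jac = np.empty((m, m))
        for j in range(m):
            h = 1e-7 * max(abs(n[j]), 1e-3 * scale)
            e = np.zeros(m)
            e[j] = h
            jac[:, j] = (rhs(0.0, n + e) - rhs(0.0, n - e)) / (2.0 * h)
        step, *_ = np.linalg.lstsq(jac, -f, rcond=None)
        improved = False
        for damp in (1.0, 0.5, 0.25, 0.1):
            cand = n + damp * step
            fc = rhs(0.0, cand)
            rc = float(np.max(np.abs(fc)))
            if rc < res:
                n, f, res = cand, fc, rc
                improved = True
                break
        if not improved:
            break
    return n, res


def steady_state(model: Model, rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL,
                 residual_tol: float | None = None, t_start: float = 1.0,
                 max_extensions: int = 12, n_points: int = 400) -> SteadyStateResult:
    """Steady state by long integration followed by Newton polishing.

    Integrates over geometrically growing horizons until the trajectory
    settles, then polishes the endpoint so that ||d(amounts)/dt||_inf
    falls below ``residual_tol`` (default: ``atol`` scaled by the state
    magnitude).  Raises :class:`SteadyStateError` if no fixed point is
    reached within the budget.
    """
    model.validate()
    rhs = assemble_rhs(model)
    n = model.initial_amounts()
    if residual_tol is None:
        residual_tol = atol * max(1.0, float(np.max(np.abs(n))) if n.size else 1.0)

    t_end = t_start
    settled = False
    for _ in range(max_extensions):
        traj = integrate(model, t_end, n_points=n_points, rtol=rtol, atol=atol, y0=n)
        n = traj.amounts[-1]
        try:
            _check_equilibrated(traj, 1e-6)
            settled = True
            break
        except NotEquilibratedError:
            t_end *= 10.0
    if not settled:
        raise SteadyStateError(
            f"no steady state within t = {t_end:g} s after {max_extensions} extensions"
        )

    n, res = _newton_polish(rhs, n, residual_tol)
    if res > residual_tol:
        raise SteadyStateError(
            f"Newton polishing stalled at ||f||_inf = {res:.3e} > {residual_tol:.3e}"
        )
    conc = {s.id: float(n[i] / model.volume_of(s.id)) for i, s in enumerate(model.species)}
    return SteadyStateResult(amounts=n, concentrations=conc, residual=res,
                             species=model.species_ids)
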