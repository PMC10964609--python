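"""ODE assembly, stiff time-course integration, plateau and steady-state detection.

For each internal metabolite m the balance is dC_m/dt = sum_r S(m,r) v_r(C);
boundary (clamped) species keep a zero derivative.  Integration uses LSODA
(adaptive, stiff-capable) via :func:`scipy.integrate.solve_ivp`, with dense
output so that reported concentrations are solution values independent of
the output grid.  Default tolerances follow common biochemical-simulator
practice (rtol 1e-6, atol 1e-9 nM); the default horizon of 1500 s is long
enough for riboflavin to form a plateau in the canonical model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from .model import PathwayModel, RateLawKind, reaction_rate
from .stoichiometry import stoichiometric_matrix

__all__ = [
    "SimulationOptions",
    "Trajectory",
    "SteadyStateResult",
    "assemble_odes",
    "simulate",
    "detect_plateau",
    "steady_state",
    "NM_PER_UMOL_L",
]

#: 1 umol/L = 1000 nM (reporting-layer conversion)
NM_PER_UMOL_L = 1000.0


@dataclass(frozen=True)
class SimulationOptions:
    """Solver configuration.

    ``n_points`` sets the output grid (solution values are interpolated from
    the solver's dense output, so the grid density does not affect them).
    ``conc_ceiling`` aborts integration when any concentration exceeds it
    (divergence guard, nM).
    """

    rtol: float = 1e-6
    atol: float = 1e-9
    method: str = "LSODA"
    n_points: int = 301
    max_step: float = np.inf
    conc_ceiling: float = 1e12


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed concentration matrix (times x metabolites, nM)."""

    times: np.ndarray
    concentrations: np.ndarray
    metabolite_ids: tuple[str, ...]
    model: PathwayModel
    diagnostics: dict = field(default_factory=dict)

    def species(self, metabolite_id: str) -> np.ndarray:
        return self.concentrations[:, self.metabolite_ids.index(metabolite_id)]

    def final_state(self) -> dict[str, float]:
        return {
            mid: float(self.concentrations[-1, i])
            for i, mid in enumerate(self.metabolite_ids)
        }

    def to_frame(self, unit: str = "nM"):
        """Return a pandas DataFrame (column ``time_s`` + one per species)."""
        import pandas as pd

        conc = self.concentrations
        if unit == "umol/L":
            conc = conc / NM_PER_UMOL_L
        elif unit != "nM":
            raise ValueError(f"unknown unit {unit!r} (use 'nM' or 'umol/L')")
        frame = pd.DataFrame(conc, columns=list(self.metabolite_ids))
        frame.insert(0, "time_s", self.times)
        return frame


@dataclass(frozen=True)
class SteadyStateResult:
    """Final state of a relaxation run with its balance residual (nM/s)."""

    state: dict[str, float]
    residual: float
    converged: bool
    t_reached: float


def assemble_odes(model: PathwayModel) -> Callable[[float, np.ndarray], np.ndarray]:
    """Build the derivative evaluator ``f(t, y) -> dy/dt`` for a model.

    The state vector follows the model's metabolite order (all metabolites;
    boundary species are carried with zero derivative).

    Raises
    ------
    ValueError
        if any BOUNDARY_FLUX law has no configured flux.
    """
    unresolved = [
        r.id
        for r in model.reactions
        if r.rate_law.kind is RateLawKind.BOUNDARY_FLUX and r.rate_law.flux is None
    ]
    if unresolved:
        raise ValueError(
            "cannot assemble ODEs: unresolved boundary fluxes for reactions "
            f"{unresolved}; run resolve_boundary_fluxes first"
        )
    mids = model.metabolite_ids()
    smat = stoichiometric_matrix(model)
    internal_idx = np.array([mids.index(m) for m in smat.rows], dtype=int)
    S = smat.matrix.astype(float)
    reactions = model.reactions

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        conc = {mid: max(yi, 0.0) for mid, yi in zip(mids, y)}
        v = np.array([reaction_rate(r, conc) for r in reactions])
        dy = np.zeros_like(y)
        dy[internal_idx] = S @ v
        return dy

    return rhs


def simulate(
    model: PathwayModel,
    t_end: float = 1500.0,
    options: SimulationOptions | None = None,
) -> Trajectory:
    """Integrate the model from its initial state to ``t_end`` seconds.

    Raises
    ------
    RuntimeError
        on integration failure or non-finite state, carrying diagnostics.
    """
    if not t_end > 0:
        raise ValueError(f"t_end must be positive, got {t_end!r}")
    opts = options or SimulationOptions()
    rhs = assemble_odes(model)
    mids = model.metabolite_ids()
    y0 = np.array([model.metabolite(m).initial_concentration for m in mids], float)
    t_grid = np.linspace(0.0, t_end, opts.n_points)

    ceiling = opts.conc_ceiling

    def blown_up(t, y):
        return ceiling - np.max(y)

    blown_up.terminal = True

    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        y0,
        method=opts.method,
        rtol=opts.rtol,
        atol=opts.atol,
        max_step=opts.max_step,
        dense_output=True,
        events=blown_up,
        t_eval=t_grid,
    )
    diagnostics = {
        "method": opts.method,
        "rtol": opts.rtol,
        "atol": opts.atol,
        "n_steps": int(sol.t.size),
        "nfev": int(sol.nfev),
        "status": int(sol.status),
        "message": str(sol.message),
    }
    if sol.status == 1:
        raise RuntimeError(
            f"integration diverged: a concentration exceeded {ceiling} nM "
            f"at t={float(sol.t_events[0][0]):.3g} s ({diagnostics})"
        )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message} ({diagnostics})")
    conc = sol.sol(t_grid).T
    if not np.all(np.isfinite(conc)):
        raise RuntimeError(f"non-finite concentrations in solution ({diagnostics})")
    # solver tolerance can leave tiny negative excursions; clip and flag
    floor = -10.0 * opts.atol
    if np.min(conc) < floor:
        warnings.warn(
            f"concentrations below -10*atol (min {np.min(conc):.3e} nM) were clipped",
            RuntimeWarning,
            stacklevel=2,
        )
        diagnostics["clipped"] = True
    conc = np.clip(conc, 0.0, None)
    conc[0] = y0  # first row is the exact initial condition
    return Trajectory(
        times=t_grid,
        concentrations=conc,
        metabolite_ids=tuple(mids),
        model=model,
        diagnostics=diagnostics,
    )


def detect_plateau(
    traj: Trajectory,
    species: str,
    rel_tol: float = 1e-3,
    window: float = 150.0,
) -> float | None:
    """Earliest time t where the species changes by < ``rel_tol`` (relative)
    over the window [t, t+window]; ``None`` if never.

    The relative change is max|C - C(t)| / max(C(t), eps) over the window,
    evaluated on the trajectory's output grid.  This is an operational
    criterion standing in for the visual judgement that a time course has
    flattened.
    """
    if species not in traj.metabolite_ids:
        raise KeyError(f"unknown species {species!r}")
    times = traj.times
    if window >= times[-1] - times[0]:
        raise ValueError(
            f"window ({window} s) must be shorter than the trajectory "
            f"({times[-1] - times[0]} s)"
        )
    c = traj.species(species)
    eps = 1e-12
    j = 0
    for i, t0 in enumerate(times):
        if t0 + window > times[-1]:
            break
        while times[j] < t0 + window:
            j += 1
        seg = c[i : j + 1]
        if np.max(np.abs(seg - c[i])) / max(c[i], eps) < rel_tol:
            return float(t0)
        j = i + 1 if j <= i else j
    return None


def steady_state(
    model: PathwayModel,
    options: SimulationOptions | None = None,
    tol: float = 1e-6,
    t_max: float = 1500.0,
) -> SteadyStateResult:
    """Relax the model to steady state by integration.

    Integrates in chunks until the residual max|dC/dt| over internal
    metabolites drops below ``tol`` (nM/s) or ``t_max`` is reached.  The
    initial state counts: a model already at balance converges at t=0.
    """
    opts = options or SimulationOptions()
    rhs = assemble_odes(model)
    mids = model.metabolite_ids()
    internal = {m.id for m in model.internal_metabolites()}
    mask = np.array([m in internal for m in mids])
    y = np.array([model.metabolite(m).initial_concentration for m in mids], float)

    def residual_of(yv: np.ndarray) -> float:
        dy = rhs(0.0, yv)
        return float(np.max(np.abs(dy[mask]))) if mask.any() else 0.0

    t = 0.0
    res = residual_of(y)
    # geometric chunking: cheap early exits, few solver restarts late
    chunk = max(t_max / 64.0, 1.0)
    while res >= tol and t < t_max:
        t_next = min(t + chunk, t_max)
        sol = solve_ivp(
            rhs,
            (t, t_next),
            y,
            method=opts.method,
            rtol=opts.rtol,
            atol=opts.atol,
            max_step=opts.max_step,
        )
        if not sol.success:
            raise RuntimeError(f"steady-state relaxation failed: {sol.message}")
        y = sol.y[:, -1]
        if np.max(y) > opts.conc_ceiling:
            raise RuntimeError(
                f"divergence during steady-state search: concentration exceeded "
                f"{opts.conc_ceiling} nM at t={t_next:.3g} s"
            )
        t = t_next
        chunk *= 2.0
        res = residual_of(y)
    return SteadyStateResult(
        state={mid: float(max(val, 0.0)) for mid, val in zip(mids, y)},
        residual=res,
        converged=bool(res < tol),
        t_reached=t,
    )
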