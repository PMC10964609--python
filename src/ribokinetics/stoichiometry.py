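"""Stoichiometric matrix and steady-state flux prediction.

The four transport/terminal reactions of the canonical network (GTP import,
Rub5P import, FAD synthetase, FAD export) have no literature kinetics.  Their
fluxes are predicted from mass-balance closure: kinetic fluxes are evaluated
at a reference state and the unknown fluxes are chosen so that S.v = 0 holds
on every metabolite balance that involves at least one unknown flux.  An LP
(flux-balance) mode is provided as an alternative predictor for sensitivity
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import linprog

from .model import PathwayModel, RateLawKind, Reaction, reaction_rate

__all__ = [
    "StoichMatrix",
    "FluxVector",
    "stoichiometric_matrix",
    "predict_boundary_fluxes",
    "resolve_boundary_fluxes",
    "unfreeze_predicted_fluxes",
    "fba_fluxes",
]


@dataclass(frozen=True)
class StoichMatrix:
    """Net stoichiometric coefficients over internal metabolites.

    ``matrix[i, j]`` is the net coefficient of metabolite ``rows[i]`` in
    reaction ``cols[j]`` (products positive, substrates negative).
    """

    rows: tuple[str, ...]
    cols: tuple[str, ...]
    matrix: np.ndarray

    def row(self, metabolite_id: str) -> np.ndarray:
        return self.matrix[self.rows.index(metabolite_id)]


@dataclass(frozen=True)
class FluxVector:
    """Per-reaction fluxes (nM/s) with provenance (``kinetic``/``predicted``/``fixed``)."""

    reactions: tuple[str, ...]
    values: np.ndarray
    provenance: tuple[str, ...]
    residual: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.reactions, (float(v) for v in self.values)))

    def __getitem__(self, reaction_id: str) -> float:
        return float(self.values[self.reactions.index(reaction_id)])


def stoichiometric_matrix(model: PathwayModel) -> StoichMatrix:
    """Build S over internal (non-boundary) metabolites, in model order."""
    internal = [m.id for m in model.internal_metabolites()]
    idx = {mid: i for i, mid in enumerate(internal)}
    cols = tuple(r.id for r in model.reactions)
    mat = np.zeros((len(internal), len(cols)), dtype=int)
    for j, r in enumerate(model.reactions):
        for mid, coeff in r.substrates:
            if mid in idx:
                mat[idx[mid], j] -= coeff
        for mid, coeff in r.products:
            if mid in idx:
                mat[idx[mid], j] += coeff
    return StoichMatrix(rows=tuple(internal), cols=cols, matrix=mat)


def _unresolved_boundary(model: PathwayModel) -> list[str]:
    return [
        r.id
        for r in model.reactions
        if r.rate_law.kind is RateLawKind.BOUNDARY_FLUX and r.rate_law.flux is None
    ]


def predict_boundary_fluxes(
    model: PathwayModel, reference_state: dict[str, float] | None = None
) -> FluxVector:
    """Predict unparameterized boundary fluxes by mass-balance closure.

    Kinetic fluxes are evaluated from the rate laws at ``reference_state``
    (default: the model's initial state).  The unknown fluxes (BOUNDARY_FLUX
    laws with no configured value) are the least-squares solution of
    ``S.v = 0`` restricted to the balances that involve at least one unknown
    flux (the closure system); balances of purely kinetic metabolites cannot
    be influenced by the unknowns and contribute only to the reported
    residual.  For the canonical network the closure system is square and
    exactly solvable.

    Raises
    ------
    ValueError
        if the closure system is rank-deficient (some balances cannot be
        satisfied by any choice of the unknown fluxes).
    """
    state = dict(model.initial_state())
    if reference_state:
        state.update(reference_state)

    smat = stoichiometric_matrix(model)
    unknown_ids = _unresolved_boundary(model)
    n = len(model.reactions)
    values = np.zeros(n)
    provenance: list[str] = []
    for j, r in enumerate(model.reactions):
        if r.id in unknown_ids:
            provenance.append("predicted")
            continue
        if r.rate_law.kind is RateLawKind.BOUNDARY_FLUX:
            values[j] = r.rate_law.flux
            provenance.append("fixed")
        else:
            values[j] = reaction_rate(r, state)
            provenance.append("kinetic")

    if unknown_ids:
        ucols = [smat.cols.index(rid) for rid in unknown_ids]
        kcols = [j for j in range(n) if j not in ucols]
        A = smat.matrix[:, ucols].astype(float)
        b = -(smat.matrix[:, kcols].astype(float) @ values[kcols])
        # closure system: balances that involve at least one unknown flux
        touched = np.flatnonzero(np.any(A != 0, axis=1))
        A_c, b_c = A[touched], b[touched]
        if np.linalg.matrix_rank(A_c) < len(ucols):
            free = [
                unknown_ids[k]
                for k in range(len(ucols))
                if not np.any(A_c[:, k])
            ]
            raise ValueError(
                "closure system is singular; unconstrained or conflicting "
                f"boundary fluxes: {free or unknown_ids}"
            )
        x, *_ = np.linalg.lstsq(A_c, b_c, rcond=None)
        # residual of the closure system; nonzero only when closure is not
        # exactly solvable (least-squares contract)
        residual = float(np.max(np.abs(A_c @ x - b_c))) if len(b_c) else 0.0
        for rid, val in zip(unknown_ids, x):
            values[smat.cols.index(rid)] = val
    else:
        residual = (
            float(np.max(np.abs(smat.matrix.astype(float) @ values)))
            if len(smat.rows)
            else 0.0
        )
    return FluxVector(
        reactions=smat.cols,
        values=values,
        provenance=tuple(provenance),
        residual=residual,
    )


def resolve_boundary_fluxes(
    model: PathwayModel, reference_state: dict[str, float] | None = None
) -> PathwayModel:
    """Freeze predicted closure fluxes into the model's BOUNDARY_FLUX laws."""
    fluxes = predict_boundary_fluxes(model, reference_state)
    out = model
    for rid in _unresolved_boundary(model):
        r = out.reaction(rid)
        out = out.with_reaction(
            replace(r, rate_law=replace(r.rate_law, flux=fluxes[rid], predicted=True))
        )
    return out


def unfreeze_predicted_fluxes(model: PathwayModel, reaction_ids: list[str]) -> PathwayModel:
    """Reset given BOUNDARY_FLUX values to 'unpredicted' (flux=None)."""
    out = model
    for rid in reaction_ids:
        r = out.reaction(rid)
        if r.rate_law.kind is not RateLawKind.BOUNDARY_FLUX:
            raise ValueError(f"reaction {rid!r} is not a boundary-flux reaction")
        out = out.with_reaction(replace(r, rate_law=replace(r.rate_law, flux=None)))
    return out


def fba_fluxes(
    matrix: StoichMatrix,
    bounds: dict[str, tuple[float, float]],
    objective: str,
) -> FluxVector:
    """Maximize one reaction's flux subject to S.v = 0 and box bounds.

    Solves the linear program with HiGHS and returns an optimal vertex.
    Alternative to closure for exploring flux feasibility; the method's
    default predictor remains mass-balance closure.

    Raises
    ------
    ValueError
        if the problem is infeasible or the objective is unbounded.
    """
    if objective not in matrix.cols:
        raise KeyError(f"unknown objective reaction {objective!r}")
    n = len(matrix.cols)
    c = np.zeros(n)
    c[matrix.cols.index(objective)] = -1.0  # linprog minimizes
    lp_bounds = []
    for rid in matrix.cols:
        lo, hi = bounds.get(rid, (0.0, np.inf))
        if not (np.isfinite(lo) and np.isfinite(hi)):
            raise ValueError(f"bounds for {rid!r} must be finite, got ({lo}, {hi})")
        lp_bounds.append((lo, hi))
    res = linprog(
        c,
        A_eq=matrix.matrix.astype(float),
        b_eq=np.zeros(len(matrix.rows)),
        bounds=lp_bounds,
        method="highs",
    )
    if res.status == 2:
        raise ValueError("flux balance problem is infeasible under the given bounds")
    if res.status == 3:
        raise ValueError(f"objective flux {objective!r} is unbounded")
    if not res.success:
        raise RuntimeError(f"LP solver failed: {res.message}")
    return FluxVector(
        reactions=matrix.cols,
        values=res.x,
        provenance=tuple("predicted" for _ in matrix.cols),
        residual=float(np.max(np.abs(matrix.matrix.astype(float) @ res.x))),
    )
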