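"""In-silico enzyme overexpression experiments and rate-limiting-step analysis.

An overexpression scenario multiplies an enzyme's maximal velocity by a fold
factor (one gene dose: the bifunctional RibA scales its GTPCHII and DHBPS
activities jointly), re-predicts the closure-derived boundary fluxes at the
scenario's initial state (transport is demand-driven), simulates the same
horizon as the baseline, and reports the end-point riboflavin concentration
in umol/L.  Enzymes are ranked by their end-point gain over baseline; the
enzyme whose overexpression gains most is the pathway's rate-limiting step.
Metabolic-control analysis (scaled flux/concentration control coefficients)
is provided as the quantitative companion to the scan.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model import PathwayModel, RateLawKind, ENZYME_ALIASES
from .simulation import (
    NM_PER_UMOL_L,
    SimulationOptions,
    Trajectory,
    simulate,
    steady_state,
)
from .stoichiometry import (
    predict_boundary_fluxes,
    resolve_boundary_fluxes,
    unfreeze_predicted_fluxes,
)

__all__ = [
    "ScenarioResult",
    "ControlCoefficients",
    "overexpress",
    "scan_overexpression",
    "rank_limiting",
    "control_coefficients",
    "calibrate_fold",
]

DEFAULT_FOLD = 10.0
TARGET_SPECIES = "RIBO"


@dataclass(frozen=True)
class ScenarioResult:
    """Outcome of one overexpression experiment."""

    enzyme: str  # "baseline" for the unperturbed run
    fold: float
    riboflavin_end: float  # umol/L at t_end
    delta_vs_baseline: float  # umol/L
    trajectory: Trajectory


@dataclass(frozen=True)
class ControlCoefficients:
    """Scaled sensitivities C_i = (p_i/O) dO/dp_i of a steady observable."""

    observable: str
    coefficients: dict[str, float]
    delta: float

    def total(self) -> float:
        return float(sum(self.coefficients.values()))


def _resolve_enzyme(model: PathwayModel, enzyme: str) -> list[str]:
    """Reaction ids catalysed by an enzyme name (aliases included)."""
    if enzyme in ENZYME_ALIASES:
        targets = [
            r.id
            for r in model.reactions
            if r.enzyme in ENZYME_ALIASES[enzyme]
            and r.rate_law.kind is not RateLawKind.BOUNDARY_FLUX
        ]
    else:
        targets = [
            r.id
            for r in model.reactions
            if r.enzyme == enzyme and r.rate_law.kind is not RateLawKind.BOUNDARY_FLUX
        ]
    if not targets:
        valid = sorted(set(model.enzymes()) | set(ENZYME_ALIASES))
        raise KeyError(f"unknown enzyme {enzyme!r}; valid names: {valid}")
    return targets


def overexpress(model: PathwayModel, enzyme: str, fold: float) -> PathwayModel:
    """Return a copy with the enzyme's Vmax multiplied by ``fold``.

    A bifunctional enzyme (e.g. RibA = GTPCHII + DHBPS) has both of its
    activities scaled together.  The input model is unchanged.
    """
    if not fold > 0:
        raise ValueError(f"fold must be positive, got {fold!r}")
    out = model
    for rid in _resolve_enzyme(model, enzyme):
        r = out.reaction(rid)
        out = out.with_reaction(
            replace(r, rate_law=replace(r.rate_law, vmax=r.rate_law.vmax * fold))
        )
    return out


def _prepare(model: PathwayModel, refresh_predicted: bool) -> PathwayModel:
    """Re-predict closure fluxes at the model's initial state if requested."""
    if not refresh_predicted:
        return model
    # only closure-derived fluxes are re-predicted, so each scenario sees
    # transport matched to its own enzyme capacities; user-fixed boundary
    # fluxes stay as configured
    stale = [
        r.id
        for r in model.reactions
        if r.rate_law.kind is RateLawKind.BOUNDARY_FLUX
        and r.rate_law.flux is not None
        and r.rate_law.predicted
    ]
    if stale:
        model = unfreeze_predicted_fluxes(model, stale)
    return resolve_boundary_fluxes(model)


def scan_overexpression(
    model: PathwayModel,
    enzymes: list[str],
    fold: float = DEFAULT_FOLD,
    t_end: float = 1500.0,
    options: SimulationOptions | None = None,
    target_species: str = TARGET_SPECIES,
    refresh_predicted: bool = True,
) -> list[ScenarioResult]:
    """Baseline plus one scenario per enzyme, all simulated identically.

    Returns results in input order, baseline first.  End points are reported
    in umol/L of the target species (riboflavin by default).
    """
    results: list[ScenarioResult] = []

    def run(m: PathwayModel, label: str, f: float, baseline_end: float | None) -> ScenarioResult:
        try:
            traj = simulate(_prepare(m, refresh_predicted), t_end=t_end, options=options)
        except Exception as exc:  # annotate with the scenario
            raise RuntimeError(f"scenario {label!r} (fold {f}) failed: {exc}") from exc
        end = float(traj.species(target_species)[-1]) / NM_PER_UMOL_L
        delta = 0.0 if baseline_end is None else end - baseline_end
        return ScenarioResult(
            enzyme=label, fold=f, riboflavin_end=end,
            delta_vs_baseline=delta, trajectory=traj,
        )

    baseline = run(model, "baseline", 1.0, None)
    results.append(baseline)
    for enzyme in enzymes:
        scenario = run(overexpress(model, enzyme, fold), enzyme, fold,
                       baseline.riboflavin_end)
        results.append(scenario)
    return results


def rank_limiting(results: list[ScenarioResult]) -> tuple[list[str], bool]:
    """Enzymes ordered by end-point gain (descending); ties alphabetical.

    Returns ``(ordered_enzymes, tie_flag)``; the first entry is the
    identified rate-limiting step.  The baseline entry is excluded.
    """
    scans = [r for r in results if r.enzyme != "baseline"]
    if not scans:
        raise ValueError("no overexpression scenarios to rank")
    ordered = sorted(scans, key=lambda r: (-r.delta_vs_baseline, r.enzyme))
    deltas = [r.delta_vs_baseline for r in ordered]
    tie = any(
        abs(deltas[i] - deltas[i + 1]) <= 1e-12 * max(1.0, abs(deltas[i]))
        for i in range(len(deltas) - 1)
    )
    return [r.enzyme for r in ordered], tie


def control_coefficients(
    model: PathwayModel,
    observable: str = "RK",
    kind: str = "flux",
    delta: float = 0.01,
    options: SimulationOptions | None = None,
    ss_tol: float = 1e-6,
    t_max: float = 2.0e5,
    reactions: list[str] | None = None,
) -> ControlCoefficients:
    """Central finite-difference control coefficients at steady state.

    For every reaction (enzymatic Vmax or boundary flux alike) the rate
    parameter is scaled by (1 +/- delta), the system is relaxed to steady
    state and the scaled sensitivity C_i = (p_i/O)(dO/dp_i) of the observable
    is computed.  ``kind`` selects the observable: the steady flux through a
    reaction or the steady concentration of a metabolite.  Flux control
    coefficients over a pathway flux sum to 1 (summation theorem), which is
    the standard internal consistency check; the theorem requires perturbing
    every reaction, so leave ``reactions`` at None for it.  Restricting
    ``reactions`` is useful when a frozen zero-order boundary flux would make
    a perturbed system non-stationary (a fixed consumption that no longer
    matches a perturbed supply never rebalances).

    Raises
    ------
    RuntimeError
        if the unperturbed model does not reach a converged steady state.
    """
    if kind not in ("flux", "concentration"):
        raise ValueError(f"kind must be 'flux' or 'concentration', got {kind!r}")

    base = steady_state(model, options=options, tol=ss_tol, t_max=t_max)
    if not base.converged:
        raise RuntimeError(
            f"no converged steady state (residual {base.residual:.3g} nM/s); "
            "control coefficients are defined only at steady state"
        )

    from .model import reaction_rate  # local import avoids cycle at module load

    def observe(m: PathwayModel) -> float:
        ss = steady_state(m, options=options, tol=ss_tol, t_max=t_max)
        if not ss.converged:
            raise RuntimeError("perturbed model failed to reach steady state")
        if kind == "flux":
            return reaction_rate(m.reaction(observable), ss.state)
        return ss.state[observable]

    o0 = observe(model)
    wanted = set(reactions) if reactions is not None else None
    coeffs: dict[str, float] = {}
    for r in model.reactions:
        if wanted is not None and r.id not in wanted:
            continue
        if r.rate_law.kind is RateLawKind.BOUNDARY_FLUX:
            if r.rate_law.flux is None:
                raise ValueError(f"boundary flux of {r.id!r} is unresolved")
            scale = lambda f, rr=r: replace(
                rr, rate_law=replace(rr.rate_law, flux=rr.rate_law.flux * f)
            )
        else:
            scale = lambda f, rr=r: replace(
                rr, rate_law=replace(rr.rate_law, vmax=rr.rate_law.vmax * f)
            )
        o_hi = observe(model.with_reaction(scale(1.0 + delta)))
        o_lo = observe(model.with_reaction(scale(1.0 - delta)))
        # d(ln O)/d(ln p) by central difference
        coeffs[r.id] = float((o_hi - o_lo) / (2.0 * delta * o0)) if o0 != 0 else 0.0
    return ControlCoefficients(observable=observable, coefficients=coeffs, delta=delta)


def calibrate_fold(
    model: PathwayModel,
    enzyme: str,
    target_ratio: float,
    t_end: float = 1500.0,
    options: SimulationOptions | None = None,
    fold_range: tuple[float, float] = (1.0, 1000.0),
    rel_tol: float = 1e-3,
) -> float:
    """Find the fold whose scenario/baseline end-point ratio matches a target.

    Recovers an unstated overexpression multiplier from a reported pair of
    end points (e.g. baseline 25.13 -> scenario 28.2 umol/L gives
    ``target_ratio = 28.2/25.13``).  Bisection on the fold, assuming the end
    point is monotone in the fold (true when the enzyme is supply-limiting).
    """
    if target_ratio <= 0:
        raise ValueError("target_ratio must be positive")

    def ratio(fold: float) -> float:
        res = scan_overexpression(model, [enzyme], fold=fold, t_end=t_end, options=options)
        return res[1].riboflavin_end / res[0].riboflavin_end

    lo, hi = fold_range
    r_lo, r_hi = ratio(lo), ratio(hi)
    if not (min(r_lo, r_hi) <= target_ratio <= max(r_lo, r_hi)):
        raise ValueError(
            f"target ratio {target_ratio:.4g} not bracketed by folds {fold_range} "
            f"(ratios {r_lo:.4g}..{r_hi:.4g})"
        )
    for _ in range(60):
        mid = np.sqrt(lo * hi)  # bisect in log space
        r_mid = ratio(mid)
        if abs(r_mid - target_ratio) <= rel_tol * target_ratio:
            return float(mid)
        if (r_mid < target_ratio) == (r_lo < target_ratio):
            lo, r_lo = mid, r_mid
        else:
            hi, r_hi = mid, r_mid
    return float(np.sqrt(lo * hi))
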