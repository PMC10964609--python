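"""Synthetic parameter sets and toy pathway fixtures.

The kinetic constants and initial concentrations of the canonical network
come from supplementary literature tables that are not part of this package.
This module generates stand-ins with the same statistical structure:
log-spread Km/Vmax magnitudes over one kinetic entry per enzymatic reaction
(two Km values for the two-substrate reactions) and one initial
concentration per metabolite.  The "reference" fixture is a hand-designed,
fully synthetic parameter set for the canonical 14-reaction topology: its
values bracket typical magnitudes for flavinogenesis enzymes, the
bifunctional RibA carries the smallest capacity by construction, and the
initial state is the analytic baseline operating point of the resulting
model (so the unperturbed time course starts on its plateau).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    CANONICAL_METABOLITES,
    CANONICAL_TOPOLOGY,
    KineticEntry,
    ParameterSet,
    PathwayModel,
    RateLaw,
    RateLawKind,
    Reaction,
    Metabolite,
    validate_model,
)

__all__ = [
    "ParameterRanges",
    "sample_parameter_set",
    "sample_canonical_parameter_set",
    "perturb_parameters",
    "toy_linear_chain",
    "reference_parameters",
    "reference_fixture_files",
]


def reference_fixture_files() -> tuple:
    """Paths of the packaged synthetic fixture CSVs (params, concentrations)."""
    from importlib.resources import files

    data = files("ribokinetics") / "data"
    return (
        data / "reference_params.csv",
        data / "reference_concentrations.csv",
    )


@dataclass(frozen=True)
class ParameterRanges:
    """Log-uniform sampling ranges for synthetic parameter sets.

    Defaults bracket typical literature magnitudes for flavinogenesis
    enzymes: Km 1e2..1e6 nM, Vmax 1e-1..1e2 nmol/mg/min, initial
    concentrations 1e2..1e5 nM.  These are synthetic defaults, not
    literature values.
    """

    km_range: tuple[float, float] = (1.0e2, 1.0e6)
    vmax_range: tuple[float, float] = (1.0e-1, 1.0e2)
    conc_range: tuple[float, float] = (1.0e2, 1.0e5)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("km_range", "vmax_range", "conc_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                raise ValueError(f"{name} must satisfy 0 < lo < hi, got ({lo}, {hi})")


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _sample(
    kinetic_specs: list[tuple[str, RateLawKind]],
    metabolite_ids: list[str],
    ranges: ParameterRanges,
) -> ParameterSet:
    rng = np.random.default_rng(ranges.seed)
    kinetic: dict[str, KineticEntry] = {}
    for rid, kind in kinetic_specs:
        vmax = _log_uniform(rng, *ranges.vmax_range)
        km_a = _log_uniform(rng, *ranges.km_range)
        km_b = _log_uniform(rng, *ranges.km_range) if kind is RateLawKind.MM2 else None
        kinetic[rid] = KineticEntry(vmax=vmax, km_a=km_a, km_b=km_b)
    conc = {mid: _log_uniform(rng, *ranges.conc_range) for mid in metabolite_ids}
    return ParameterSet(kinetic=kinetic, initial_concentrations=conc)


def sample_parameter_set(model: PathwayModel, ranges: ParameterRanges) -> ParameterSet:
    """Sample a complete parameter set for an existing model.

    One kinetic entry per non-boundary-flux reaction (two Km values for MM2
    laws), one initial concentration per metabolite; log-uniform within the
    ranges; fully determined by ``ranges.seed``.
    """
    specs = [
        (r.id, r.rate_law.kind)
        for r in model.reactions
        if r.rate_law.kind is not RateLawKind.BOUNDARY_FLUX
    ]
    return _sample(specs, model.metabolite_ids(), ranges)


def sample_canonical_parameter_set(ranges: ParameterRanges) -> ParameterSet:
    """Sample a parameter set for the canonical topology (no model needed)."""
    specs = [
        (s.id, s.kind)
        for s in CANONICAL_TOPOLOGY
        if s.kind is not RateLawKind.BOUNDARY_FLUX
    ]
    return _sample(specs, [mid for mid, _ in CANONICAL_METABOLITES], ranges)


def perturb_parameters(params: ParameterSet, cv: float, seed: int) -> ParameterSet:
    """Multiply every value by an independent log-normal factor of mean 1.

    ``cv`` is the coefficient of variation of the factors (cv=0 returns an
    identical copy).  Used to build robustness ensembles around a reference
    parameter set.
    """
    if cv < 0:
        raise ValueError(f"cv must be >= 0, got {cv!r}")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv * cv))
    mu = -0.5 * sigma * sigma  # mean-1 log-normal

    def factor() -> float:
        return float(np.exp(rng.normal(mu, sigma))) if cv > 0 else 1.0

    kinetic = {
        rid: KineticEntry(
            vmax=e.vmax * factor(),
            km_a=e.km_a * factor(),
            km_b=None if e.km_b is None else e.km_b * factor(),
        )
        for rid, e in params.kinetic.items()
    }
    conc = {mid: c * factor() for mid, c in params.initial_concentrations.items()}
    return ParameterSet(
        kinetic=kinetic,
        initial_concentrations=conc,
        vmax_scale=params.vmax_scale,
        clamped=dict(params.clamped),
    )


def toy_linear_chain(
    n_steps: int,
    vmaxes: list[float],
    kms: list[float],
    import_flux: float,
    initial: float = 0.0,
) -> PathwayModel:
    """Linear chain fixture: import -> M1 -> ... -> Mn -> sink.

    ``n_steps`` MM1 conversions with the given Vmax (nM/s, already
    volumetric) and Km (nM); a fixed import flux feeds M1 and a clamped sink
    terminates the chain.  Steady state exists iff ``import_flux`` is below
    every Vmax, with the closed form M_i = f*km_i/(vmax_i - f).
    """
    if not (len(vmaxes) == len(kms) == n_steps):
        raise ValueError(
            f"need {n_steps} vmax and km values, got {len(vmaxes)} and {len(kms)}"
        )
    mets = [
        Metabolite(id=f"M{i+1}", name=f"intermediate {i+1}", initial_concentration=initial)
        for i in range(n_steps)
    ]
    mets.append(Metabolite(id="SINK", name="terminal pool", boundary=True))
    reactions = [
        Reaction(
            id="IMPORT",
            enzyme="transport",
            substrates=(),
            products=(("M1", 1),),
            rate_law=RateLaw(kind=RateLawKind.BOUNDARY_FLUX, flux=float(import_flux)),
        )
    ]
    for i in range(n_steps):
        product = f"M{i+2}" if i + 1 < n_steps else "SINK"
        reactions.append(
            Reaction(
                id=f"STEP{i+1}",
                enzyme=f"E{i+1}",
                substrates=((f"M{i+1}", 1),),
                products=((product, 1),),
                rate_law=RateLaw(
                    kind=RateLawKind.MM1, vmax=float(vmaxes[i]), km_a=float(kms[i])
                ),
            )
        )
    reactions.append(
        Reaction(
            id="EXPORT",
            enzyme="transport",
            substrates=(("SINK", 1),),
            products=(),
            rate_law=RateLaw(kind=RateLawKind.BOUNDARY_FLUX, flux=float(import_flux)),
        )
    )
    model = PathwayModel(metabolites=tuple(mets), reactions=tuple(reactions))
    violations = validate_model(model)
    if violations:
        raise AssertionError(f"toy chain failed validation: {violations}")
    return model


# ---------------------------------------------------------------------------
# Paper-shape fixture (synthetic stand-in for the supplementary tables)
# ---------------------------------------------------------------------------

#: tabulated Vmax (nmol/mg/min) for the reference fixture.  RibA's two
#: activities (GTPCHII, DHBPS) carry an order of magnitude less capacity
#: than the downstream enzymes, making RibA the binding constraint by
#: construction.
_FIXTURE_VMAX = {
    "GTPCHII": 45.0,
    "DHBPS": 90.0,
    "PYRD": 600.0,
    "PYRR": 700.0,
    "PHOSPHATASE": 800.0,
    "ARP_TRANSPORT": 900.0,
    "LS": 1500.0,
    "RS": 400.0,
    "RK": 500.0,
    "FAD_TRANSPORT": 60.0,
}

#: Km values (nM) for the reference fixture (km_a, and km_b for MM2)
_FIXTURE_KM = {
    "GTPCHII": (2000.0, None),
    "DHBPS": (3000.0, None),
    "PYRD": (1000.0, None),
    "PYRR": (1000.0, None),
    "PHOSPHATASE": (1000.0, None),
    "ARP_TRANSPORT": (1000.0, None),
    "LS": (1000.0, 1500.0),
    "RS": (4000.0, None),
    "RK": (5.0e4, 1.0e5),
    "FAD_TRANSPORT": (5.0e4, None),
}

#: designed baseline branch flux (nM/s) through the pyrimidine branch; the
#: butanone branch carries twice this (two Rub5P per riboflavin)
_FIXTURE_J = 0.5

_FIXTURE_ATP = 3.0e6  # clamped ATP (nM)
_FIXTURE_FMN0 = 5000.0  # FMN start (free: its consumption is zero-order)
_FIXTURE_FAD0 = 25000.0  # FAD start; splits sink between transport and export


def _mm_inverse(v: float, vmax_eff: float, km: float) -> float:
    """Substrate level at which an MM1 law runs at velocity v."""
    if not v < vmax_eff:
        raise ValueError(f"designed flux {v} exceeds capacity {vmax_eff}")
    return v * km / (vmax_eff - v)


def reference_parameters(vmax_scale: float = 1.0 / 60.0) -> ParameterSet:
    """The packaged synthetic parameter set for the canonical topology.

    Initial concentrations are computed analytically so that the baseline
    model sits exactly at its operating point: every enzymatic step runs at
    the designed branch flux (0.5 nM/s pyrimidine side, 1.0 nM/s butanone
    side), and the closure-predicted boundary fluxes at this state balance
    every pool.  The unperturbed time course is therefore the plateau
    itself, and overexpression scenarios depart from it.
    """
    j = _FIXTURE_J
    eff = {rid: v * vmax_scale for rid, v in _FIXTURE_VMAX.items()}
    km = _FIXTURE_KM

    conc: dict[str, float] = {}
    conc["GTP"] = _mm_inverse(j, eff["GTPCHII"], km["GTPCHII"][0])
    conc["RUB5P"] = _mm_inverse(2 * j, eff["DHBPS"], km["DHBPS"][0])
    conc["DA6RP5P"] = _mm_inverse(j, eff["PYRD"], km["PYRD"][0])
    conc["A6RP5P"] = _mm_inverse(j, eff["PYRR"], km["PYRR"][0])
    conc["ARPP"] = _mm_inverse(j, eff["PHOSPHATASE"], km["PHOSPHATASE"][0])
    conc["ARPc"] = _mm_inverse(j, eff["ARP_TRANSPORT"], km["ARP_TRANSPORT"][0])
    # LS runs at 2j; with saturation product s_a*s_b = 2j/Vmax split evenly,
    # each substrate sits at Km*s/(1-s)
    s = float(np.sqrt(2 * j / eff["LS"]))
    conc["ARPp"] = km["LS"][0] * s / (1.0 - s)
    conc["DHB4P"] = km["LS"][1] * s / (1.0 - s)
    # RS dismutates 2 DMRYL per event; event rate j
    conc["DMRYL"] = _mm_inverse(j, eff["RS"], km["RS"][0])
    # RK: two-substrate with clamped ATP
    sat_atp = _FIXTURE_ATP / (km["RK"][1] + _FIXTURE_ATP)
    x = j / (eff["RK"] * sat_atp)
    conc["RIBO"] = km["RK"][0] * x / (1.0 - x)
    conc["FMN"] = _FIXTURE_FMN0
    conc["FAD"] = _FIXTURE_FAD0

    kinetic = {
        rid: KineticEntry(vmax=_FIXTURE_VMAX[rid], km_a=km[rid][0], km_b=km[rid][1])
        for rid in _FIXTURE_VMAX
    }
    return ParameterSet(
        kinetic=kinetic,
        initial_concentrations=conc,
        vmax_scale=vmax_scale,
        clamped={"ATP": _FIXTURE_ATP},
    )
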