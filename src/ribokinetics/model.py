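"""Domain types, kinetic rate laws and the canonical riboflavin pathway builder.

The model describes de-novo riboflavin (vitamin B2) biosynthesis in plants:
GTP and ribulose 5-phosphate (Rub5P) are converted through the pyrimidine and
butanone branches, condensed by lumazine synthase (LS), dismutated by
riboflavin synthase (RS) into riboflavin, and further phosphorylated /
adenylylated to FMN and FAD.  Enzymatic steps follow irreversible
Michaelis-Menten kinetics; LS and RK use a two-substrate (random bi-bi style)
rate law; transport steps without literature kinetics carry fixed
(zero-order) boundary fluxes that are predicted stoichiometrically
(see :mod:`ribokinetics.stoichiometry`).

Concentrations are in nM throughout; time in seconds.  Tabulated Vmax values
are in nmol/(mg protein * min) and are converted to volumetric nM/s rates by
``ParameterSet.vmax_scale`` (default 1/60, i.e. one tabulated unit of
nmol/mg/min is taken to correspond to 1 nmol/L/min of pathway capacity, since
the effective enzyme abundance is not known).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

__all__ = [
    "RateLawKind",
    "RateLaw",
    "Metabolite",
    "Reaction",
    "PathwayModel",
    "ParameterSet",
    "mm_rate",
    "bi_substrate_rate",
    "reaction_rate",
    "build_riboflavin_model",
    "validate_model",
    "CANONICAL_METABOLITES",
    "CANONICAL_TOPOLOGY",
    "ENZYME_ALIASES",
    "DEFAULT_VMAX_SCALE",
]

#: default conversion from tabulated Vmax (nmol/mg/min) to nM/s
DEFAULT_VMAX_SCALE = 1.0 / 60.0


class RateLawKind(str, Enum):
    """Supported kinetic forms."""

    MM1 = "MM1"  # single-substrate irreversible Michaelis-Menten
    MM2 = "MM2"  # two-substrate rate law
    BOUNDARY_FLUX = "BOUNDARY_FLUX"  # fixed zero-order flux (nM/s)


def mm_rate(vmax: float, km: float, s: float) -> float:
    """Irreversible Michaelis-Menten velocity ``vmax*s/(km+s)``.

    Parameters
    ----------
    vmax : maximal velocity (nM/s), >= 0.
    km : half-saturation constant (nM), > 0.
    s : substrate concentration (nM), >= 0.
    """
    if not km > 0:
        raise ValueError(f"km must be positive, got km={km!r}")
    if s < 0:
        raise ValueError(f"substrate concentration must be non-negative, got s={s!r}")
    if vmax < 0:
        raise ValueError(f"vmax must be non-negative, got vmax={vmax!r}")
    return vmax * s / (km + s)


def bi_substrate_rate(vmax: float, km_a: float, km_b: float, a: float, b: float) -> float:
    """Two-substrate velocity ``vmax*a*b / (km_a*km_b + a*km_b + b*km_a + a*b)``.

    Reduces to :func:`mm_rate` on substrate A when B saturates, and is
    symmetric under a simultaneous swap of (a, km_a) with (b, km_b).
    """
    if not km_a > 0:
        raise ValueError(f"km_a must be positive, got km_a={km_a!r}")
    if not km_b > 0:
        raise ValueError(f"km_b must be positive, got km_b={km_b!r}")
    if a < 0:
        raise ValueError(f"substrate concentration must be non-negative, got a={a!r}")
    if b < 0:
        raise ValueError(f"substrate concentration must be non-negative, got b={b!r}")
    if vmax < 0:
        raise ValueError(f"vmax must be non-negative, got vmax={vmax!r}")
    denom = km_a * km_b + a * km_b + b * km_a + a * b
    return vmax * a * b / denom


@dataclass(frozen=True)
class RateLaw:
    """Kinetic law attached to a reaction.

    ``vmax`` is the volumetric maximal velocity in nM/s (already scale
    converted).  ``flux`` is only meaningful for BOUNDARY_FLUX laws; ``None``
    marks a flux still to be predicted from the stoichiometric sub-model and
    ``predicted`` records that the frozen value came from closure (such
    fluxes are re-derived when enzyme capacities change, unlike user-fixed
    ones).  ``clamp_b`` holds the constant concentration of a clamped second
    substrate (e.g. ATP for riboflavin kinase) that is not a tracked species.
    """

    kind: RateLawKind
    vmax: float | None = None
    km_a: float | None = None
    km_b: float | None = None
    flux: float | None = None
    clamp_b: float | None = None
    predicted: bool = False

    def __post_init__(self) -> None:
        if self.kind is RateLawKind.BOUNDARY_FLUX:
            if self.km_a is not None or self.km_b is not None:
                raise ValueError("BOUNDARY_FLUX laws carry no Km")
            return
        if self.vmax is None or self.vmax < 0:
            raise ValueError(f"vmax must be non-negative, got {self.vmax!r}")
        if self.km_a is None or not self.km_a > 0:
            raise ValueError(f"km_a must be positive, got {self.km_a!r}")
        if self.kind is RateLawKind.MM2:
            if self.km_b is None or not self.km_b > 0:
                raise ValueError(f"MM2 requires km_b > 0, got {self.km_b!r}")
        elif self.km_b is not None:
            raise ValueError("MM1 laws carry a single Km")


@dataclass(frozen=True)
class Metabolite:
    """A chemical species.  Boundary species are clamped (never integrated)."""

    id: str
    name: str
    initial_concentration: float = 0.0
    boundary: bool = False

    def __post_init__(self) -> None:
        if self.initial_concentration < 0:
            raise ValueError(
                f"initial concentration of {self.id!r} must be >= 0, "
                f"got {self.initial_concentration!r}"
            )


@dataclass(frozen=True)
class Reaction:
    """A reaction with integer stoichiometry and an attached rate law.

    ``substrates``/``products`` are tuples of ``(metabolite_id, coefficient)``.
    Kinetic substrates are taken in declaration order: the first substrate
    species feeds ``km_a``; for MM2 the second species (or the clamped
    co-substrate) feeds ``km_b``.
    """

    id: str
    enzyme: str
    substrates: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_law: RateLaw
    clamped_substrate: str | None = None

    def kinetic_substrate_count(self) -> int:
        n = len(self.substrates)
        if self.clamped_substrate is not None:
            n += 1
        return n


@dataclass(frozen=True)
class PathwayModel:
    """An ordered reaction network (metabolites + reactions)."""

    metabolites: tuple[Metabolite, ...]
    reactions: tuple[Reaction, ...]

    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def internal_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites if not m.boundary]

    def metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(f"unknown metabolite {mid!r}")

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"unknown reaction {rid!r}")

    def enzymes(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.reactions:
            if r.rate_law.kind is not RateLawKind.BOUNDARY_FLUX:
                seen.setdefault(r.enzyme, None)
        return list(seen)

    def initial_state(self) -> dict[str, float]:
        return {m.id: m.initial_concentration for m in self.metabolites}

    def with_reaction(self, reaction: Reaction) -> "PathwayModel":
        """Return a copy with one reaction replaced (matched by id)."""
        new = tuple(reaction if r.id == reaction.id else r for r in self.reactions)
        return replace(self, reactions=new)

    def with_initial_state(self, state: Mapping[str, float]) -> "PathwayModel":
        mets = tuple(
            replace(m, initial_concentration=float(state.get(m.id, m.initial_concentration)))
            for m in self.metabolites
        )
        return replace(self, metabolites=mets)


#: depletion guard (nM) for zero-order sinks: a fixed flux consuming a tracked
#: species is scaled by s/(s+eps) so it shuts off smoothly at depletion
#: instead of driving the pool negative
DEPLETION_EPS = 1e-6


def reaction_rate(reaction: Reaction, conc: Mapping[str, float]) -> float:
    """Evaluate one reaction's velocity (nM/s) at a concentration state."""
    law = reaction.rate_law
    if law.kind is RateLawKind.BOUNDARY_FLUX:
        if law.flux is None:
            raise ValueError(
                f"boundary flux of reaction {reaction.id!r} has not been "
                "predicted or configured"
            )
        rate = law.flux
        for mid, _ in reaction.substrates:
            s = max(conc[mid], 0.0)
            rate *= s / (s + DEPLETION_EPS)
        return rate
    subs = [conc[mid] for mid, _ in reaction.substrates]
    if law.kind is RateLawKind.MM1:
        return mm_rate(law.vmax, law.km_a, subs[0])
    # MM2: second substrate is either the second tracked species or clamped
    if reaction.clamped_substrate is not None:
        if law.clamp_b is None:
            raise ValueError(
                f"reaction {reaction.id!r} clamps {reaction.clamped_substrate!r} "
                "but no concentration is configured"
            )
        b = law.clamp_b
    else:
        b = subs[1]
    return bi_substrate_rate(law.vmax, law.km_a, law.km_b, subs[0], b)


# ---------------------------------------------------------------------------
# Parameter set
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KineticEntry:
    """Tabulated kinetic constants for one reaction (units as tabulated)."""

    vmax: float  # nmol/mg/min
    km_a: float  # nM
    km_b: float | None = None  # nM, MM2 only


@dataclass
class ParameterSet:
    """Kinetic constants plus initial concentrations: the model's only inputs.

    ``kinetic`` maps reaction id -> :class:`KineticEntry` (tabulated units);
    ``initial_concentrations`` maps metabolite id -> nM; ``clamped`` maps
    untracked co-substrate name -> constant nM (e.g. ``{"ATP": 3e6}``).
    """

    kinetic: dict[str, KineticEntry]
    initial_concentrations: dict[str, float]
    vmax_scale: float = DEFAULT_VMAX_SCALE
    clamped: dict[str, float] = field(default_factory=lambda: {"ATP": 3.0e6})

    def effective_vmax(self, reaction_id: str) -> float:
        """Volumetric Vmax in nM/s for one reaction."""
        return self.kinetic[reaction_id].vmax * self.vmax_scale


# ---------------------------------------------------------------------------
# Canonical topology (data-driven; replaceable by a transcribed table)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReactionSpec:
    """One row of the topology table feeding the builder."""

    id: str
    enzyme: str
    kind: RateLawKind
    substrates: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    clamped_substrate: str | None = None


#: The 12 species of the canonical network.  ARP is tracked as a cytosolic
#: and a plastidial pool (its translocation into the plastid is one of the
#: hypothesized transport steps); the translocated cytosolic FAD pool lies
#: outside the model boundary.
CANONICAL_METABOLITES: tuple[tuple[str, str], ...] = (
    ("GTP", "guanosine-5'-triphosphate"),
    ("DA6RP5P", "2,5-diamino-6-ribosylamino-4(3H)-pyrimidinone 5'-phosphate"),
    ("A6RP5P", "5-amino-6-ribosylamino-2,4(1H,3H)-pyrimidinedione 5'-phosphate"),
    ("ARPP", "5-amino-6-ribitylamino-2,4(1H,3H)-pyrimidinedione 5'-phosphate"),
    ("ARPc", "5-amino-6-ribitylamino-2,4(1H,3H)-pyrimidinedione (cytosol)"),
    ("ARPp", "5-amino-6-ribitylamino-2,4(1H,3H)-pyrimidinedione (plastid)"),
    ("RUB5P", "ribulose 5-phosphate"),
    ("DHB4P", "3,4-dihydroxy-2-butanone 4-phosphate"),
    ("DMRYL", "6,7-dimethyl-8-ribityllumazine"),
    ("RIBO", "riboflavin"),
    ("FMN", "flavin mononucleotide"),
    ("FAD", "flavin adenine dinucleotide"),
)

_BF = RateLawKind.BOUNDARY_FLUX
_M1 = RateLawKind.MM1
_M2 = RateLawKind.MM2

#: The 14 canonical reactions, including external transport.  The four
#: BOUNDARY_FLUX entries (GTP import, Rub5P import, FADS, FAD export) have no
#: literature kinetics; their fluxes come from stoichiometric closure.
CANONICAL_TOPOLOGY: tuple[ReactionSpec, ...] = (
    ReactionSpec("GTP_IMPORT", "transport", _BF, (), (("GTP", 1),)),
    ReactionSpec("RUB5P_IMPORT", "transport", _BF, (), (("RUB5P", 1),)),
    ReactionSpec("GTPCHII", "GTPCHII", _M1, (("GTP", 1),), (("DA6RP5P", 1),)),
    ReactionSpec("DHBPS", "DHBPS", _M1, (("RUB5P", 1),), (("DHB4P", 1),)),
    ReactionSpec("PYRD", "PYRD", _M1, (("DA6RP5P", 1),), (("A6RP5P", 1),)),
    ReactionSpec("PYRR", "PYRR", _M1, (("A6RP5P", 1),), (("ARPP", 1),)),
    ReactionSpec("PHOSPHATASE", "PHOSPHATASE", _M1, (("ARPP", 1),), (("ARPc", 1),)),
    ReactionSpec("ARP_TRANSPORT", "transport", _M1, (("ARPc", 1),), (("ARPp", 1),)),
    ReactionSpec("LS", "LS", _M2, (("ARPp", 1), ("DHB4P", 1)), (("DMRYL", 1),)),
    # dismutation: 2 lumazine -> riboflavin + recycled pyrimidine
    ReactionSpec("RS", "RS", _M1, (("DMRYL", 2),), (("RIBO", 1), ("ARPp", 1))),
    ReactionSpec("RK", "RK", _M2, (("RIBO", 1),), (("FMN", 1),), clamped_substrate="ATP"),
    ReactionSpec("FADS", "FADS", _BF, (("FMN", 1),), (("FAD", 1),)),
    ReactionSpec("FAD_TRANSPORT", "transport", _M1, (("FAD", 1),), ()),
    ReactionSpec("FAD_EXPORT", "transport", _BF, (("FAD", 1),), ()),
)

#: enzymes catalysing more than one reaction (single gene dose)
ENZYME_ALIASES: dict[str, tuple[str, ...]] = {
    "RibA": ("GTPCHII", "DHBPS"),
}


def build_riboflavin_model(
    params: ParameterSet,
    topology: Sequence[ReactionSpec] | None = None,
    metabolites: Iterable[tuple[str, str]] | None = None,
) -> PathwayModel:
    """Assemble the riboflavin pathway model from a parameter set.

    The default topology is the canonical 14-reaction / 12-metabolite
    network; passing a different ``topology`` table (e.g. a transcribed
    supplementary reaction list) replaces it without code changes.

    Raises
    ------
    KeyError
        if ``params`` misses a kinetic reaction or an initial concentration.
    """
    topo = tuple(topology) if topology is not None else CANONICAL_TOPOLOGY
    met_rows = tuple(metabolites) if metabolites is not None else CANONICAL_METABOLITES

    mets = []
    for mid, name in met_rows:
        if mid not in params.initial_concentrations:
            raise KeyError(f"parameter set misses initial concentration for {mid!r}")
        mets.append(
            Metabolite(id=mid, name=name,
                       initial_concentration=params.initial_concentrations[mid])
        )

    reactions = []
    for spec in topo:
        if spec.kind is RateLawKind.BOUNDARY_FLUX:
            law = RateLaw(kind=_BF)  # flux predicted later
        else:
            if spec.id not in params.kinetic:
                raise KeyError(f"parameter set misses kinetic entry for reaction {spec.id!r}")
            entry = params.kinetic[spec.id]
            if spec.kind is RateLawKind.MM2 and entry.km_b is None:
                raise ValueError(
                    f"reaction {spec.id!r} uses the two-substrate law but its "
                    "parameter entry has no km_b"
                )
            if spec.kind is RateLawKind.MM1 and entry.km_b is not None:
                raise ValueError(
                    f"reaction {spec.id!r} uses the single-substrate law but its "
                    "parameter entry carries km_b"
                )
            clamp = None
            if spec.clamped_substrate is not None:
                if spec.clamped_substrate not in params.clamped:
                    raise KeyError(
                        f"reaction {spec.id!r} clamps {spec.clamped_substrate!r} but "
                        "the parameter set does not configure its concentration"
                    )
                clamp = params.clamped[spec.clamped_substrate]
            law = RateLaw(
                kind=spec.kind,
                vmax=entry.vmax * params.vmax_scale,
                km_a=entry.km_a,
                km_b=entry.km_b,
                clamp_b=clamp,
            )
        reactions.append(
            Reaction(
                id=spec.id,
                enzyme=spec.enzyme,
                substrates=spec.substrates,
                products=spec.products,
                rate_law=law,
                clamped_substrate=spec.clamped_substrate,
            )
        )

    model = PathwayModel(metabolites=tuple(mets), reactions=tuple(reactions))
    if topology is None and metabolites is None:
        assert len(model.metabolites) == 12 and len(model.reactions) == 14
    violations = validate_model(model)
    if violations:
        raise ValueError("built model is invalid: " + "; ".join(violations))
    return model


def validate_model(model: PathwayModel) -> list[str]:
    """Check all structural invariants; returns a list of violations.

    An empty list means the model is valid.  Violations are data, not
    exceptions, so partially broken models can be inspected.
    """
    out: list[str] = []
    mids = [m.id for m in model.metabolites]
    if len(set(mids)) != len(mids):
        dup = sorted({m for m in mids if mids.count(m) > 1})
        out.append(f"duplicate metabolite ids: {dup}")
    rids = [r.id for r in model.reactions]
    if len(set(rids)) != len(rids):
        dup = sorted({r for r in rids if rids.count(r) > 1})
        out.append(f"duplicate reaction ids: {dup}")
    for m in model.metabolites:
        if m.initial_concentration < 0:
            out.append(
                f"metabolite {m.id!r} has negative initial concentration "
                f"{m.initial_concentration}"
            )
    known = set(mids)
    produced: set[str] = set()
    consumed: set[str] = set()
    for r in model.reactions:
        for mid, coeff in (*r.substrates, *r.products):
            if mid not in known:
                out.append(f"reaction {r.id!r} references unknown metabolite {mid!r}")
            if not (isinstance(coeff, int) and coeff > 0):
                out.append(
                    f"reaction {r.id!r} has non-positive-integer coefficient "
                    f"{coeff!r} for {mid!r}"
                )
        consumed.update(mid for mid, _ in r.substrates)
        produced.update(mid for mid, _ in r.products)
        law = r.rate_law
        nk = r.kinetic_substrate_count()
        if law.kind is RateLawKind.MM1 and len({m for m, _ in r.substrates}) != 1:
            out.append(f"reaction {r.id!r} carries an MM1 law but {nk} kinetic substrates")
        if law.kind is RateLawKind.MM2 and nk != 2:
            out.append(f"reaction {r.id!r} carries an MM2 law but {nk} kinetic substrates")
        if law.kind is RateLawKind.BOUNDARY_FLUX and law.flux is not None:
            if not (law.flux == law.flux):  # NaN guard
                out.append(f"reaction {r.id!r} has a non-finite boundary flux")
    for m in model.metabolites:
        if m.boundary:
            continue
        if m.id not in produced:
            out.append(f"internal metabolite {m.id!r} is never produced (dead end)")
        if m.id not in consumed:
            out.append(f"internal metabolite {m.id!r} is never consumed (dead end)")
    return out
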