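"""SBML Level 3 Version 1 export/import of pathway models.

Export writes species, reactions and kinetic laws (as MathML with local
parameters) so the model can be opened in COPASI or other SBML tools.
Import recovers the kinetic-law kind from the local parameter names
(``vmax``/``km_a``/``km_b``/``clamp_b``/``flux``), which is the convention
this package writes; hand-authored documents are supported as long as they
follow it.  A round trip preserves simulation behaviour.
"""

from __future__ import annotations

from pathlib import Path

import libsbml

from .model import (
    Metabolite,
    PathwayModel,
    RateLaw,
    RateLawKind,
    Reaction,
)

__all__ = ["export_sbml", "import_sbml", "validate_sbml"]

_COMPARTMENT = "cell"


def _check(value, message: str):
    if value is None:
        raise RuntimeError(f"libsbml returned None while {message}")
    if isinstance(value, int) and value != libsbml.LIBSBML_OPERATION_SUCCESS:
        raise RuntimeError(
            f"libsbml error {libsbml.OperationReturnValue_toString(value)} while {message}"
        )
    return value


def _kinetic_formula(reaction: Reaction) -> str:
    law = reaction.rate_law
    if law.kind is RateLawKind.BOUNDARY_FLUX:
        return "flux"
    a = reaction.substrates[0][0]
    if law.kind is RateLawKind.MM1:
        return f"vmax * {a} / (km_a + {a})"
    b = "clamp_b" if reaction.clamped_substrate is not None else reaction.substrates[1][0]
    return (
        f"vmax * {a} * {b} / "
        f"(km_a * km_b + {a} * km_b + {b} * km_a + {a} * {b})"
    )


def export_sbml(model: PathwayModel, path: str | Path) -> None:
    """Write the model as an SBML L3V1 document.

    Concentrations are in nM, fluxes in nM/s (recorded in the model notes).
    Unresolved boundary fluxes are written as 0 with a ``predicted=false``
    local annotation left implicit; resolve fluxes before export when the
    document should simulate identically.
    """
    doc = libsbml.SBMLDocument(3, 1)
    sb = _check(doc.createModel(), "creating model")
    sb.setId("riboflavin_pathway")
    sb.setNotes(
        "<body xmlns='http://www.w3.org/1999/xhtml'>"
        "<p>Concentrations in nM, time in s, fluxes in nM/s.</p></body>"
    )
    comp = _check(sb.createCompartment(), "creating compartment")
    comp.setId(_COMPARTMENT)
    comp.setConstant(True)
    comp.setSize(1.0)
    comp.setSpatialDimensions(3)

    for m in model.metabolites:
        sp = _check(sb.createSpecies(), f"creating species {m.id}")
        sp.setId(m.id)
        sp.setName(m.name)
        sp.setCompartment(_COMPARTMENT)
        sp.setInitialConcentration(float(m.initial_concentration))
        sp.setBoundaryCondition(bool(m.boundary))
        sp.setConstant(False)
        sp.setHasOnlySubstanceUnits(False)

    for r in model.reactions:
        rx = _check(sb.createReaction(), f"creating reaction {r.id}")
        rx.setId(r.id)
        rx.setName(r.enzyme)
        rx.setReversible(False)
        rx.setFast(False)
        for mid, coeff in r.substrates:
            ref = _check(rx.createReactant(), f"reactant {mid} of {r.id}")
            ref.setSpecies(mid)
            ref.setStoichiometry(float(coeff))
            ref.setConstant(True)
        for mid, coeff in r.products:
            ref = _check(rx.createProduct(), f"product {mid} of {r.id}")
            ref.setSpecies(mid)
            ref.setStoichiometry(float(coeff))
            ref.setConstant(True)
        kl = _check(rx.createKineticLaw(), f"kinetic law of {r.id}")
        law = r.rate_law
        if law.kind is RateLawKind.BOUNDARY_FLUX:
            p = kl.createLocalParameter()
            p.setId("flux")
            p.setValue(float(law.flux) if law.flux is not None else 0.0)
        else:
            for pid, value in (("vmax", law.vmax), ("km_a", law.km_a)):
                p = kl.createLocalParameter()
                p.setId(pid)
                p.setValue(float(value))
            if law.km_b is not None:
                p = kl.createLocalParameter()
                p.setId("km_b")
                p.setValue(float(law.km_b))
            if law.clamp_b is not None:
                p = kl.createLocalParameter()
                p.setId("clamp_b")
                p.setValue(float(law.clamp_b))
        ast = libsbml.parseL3Formula(_kinetic_formula(r))
        if ast is None:
            raise RuntimeError(f"could not build MathML for reaction {r.id}")
        kl.setMath(ast)

    writer = libsbml.SBMLWriter()
    if not writer.writeSBMLToFile(doc, str(path)):
        raise RuntimeError(f"failed to write SBML to {path}")


def validate_sbml(path: str | Path) -> list[str]:
    """Run libsbml consistency checks; returns error messages (empty = valid)."""
    doc = libsbml.readSBMLFromFile(str(path))
    doc.checkConsistency()
    messages = []
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            messages.append(f"line {err.getLine()}: {err.getMessage()}")
    return messages


def import_sbml(path: str | Path) -> PathwayModel:
    """Read an SBML L3V1 document into a :class:`PathwayModel`.

    Raises
    ------
    ValueError
        if the document fails SBML validation or a kinetic law does not
        follow the local-parameter convention this package writes.
    """
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0 or doc.getModel() is None:
        errors = [
            doc.getError(i).getMessage().strip()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        raise ValueError(f"invalid SBML document {path}: {errors}")
    sb = doc.getModel()

    metabolites = []
    for i in range(sb.getNumSpecies()):
        sp = sb.getSpecies(i)
        metabolites.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or sp.getId(),
                initial_concentration=(
                    sp.getInitialConcentration()
                    if sp.isSetInitialConcentration()
                    else sp.getInitialAmount()
                ),
                boundary=sp.getBoundaryCondition(),
            )
        )

    reactions = []
    for i in range(sb.getNumReactions()):
        rx = sb.getReaction(i)
        substrates = tuple(
            (rx.getReactant(j).getSpecies(), int(round(rx.getReactant(j).getStoichiometry())))
            for j in range(rx.getNumReactants())
        )
        products = tuple(
            (rx.getProduct(j).getSpecies(), int(round(rx.getProduct(j).getStoichiometry())))
            for j in range(rx.getNumProducts())
        )
        kl = rx.getKineticLaw()
        if kl is None:
            raise ValueError(f"reaction {rx.getId()!r} has no kinetic law")
        params = {
            kl.getLocalParameter(j).getId(): kl.getLocalParameter(j).getValue()
            for j in range(kl.getNumLocalParameters())
        }
        clamped_substrate = None
        if "flux" in params:
            law = RateLaw(kind=RateLawKind.BOUNDARY_FLUX, flux=params["flux"])
        elif {"vmax", "km_a"} <= params.keys():
            if "km_b" in params:
                clamp_b = params.get("clamp_b")
                if clamp_b is not None:
                    clamped_substrate = "clamped"
                law = RateLaw(
                    kind=RateLawKind.MM2,
                    vmax=params["vmax"],
                    km_a=params["km_a"],
                    km_b=params["km_b"],
                    clamp_b=clamp_b,
                )
            else:
                law = RateLaw(
                    kind=RateLawKind.MM1, vmax=params["vmax"], km_a=params["km_a"]
                )
        else:
            raise ValueError(
                f"kinetic law of reaction {rx.getId()!r} does not follow the "
                f"vmax/km_a/km_b/clamp_b/flux parameter convention (found "
                f"{sorted(params)})"
            )
        reactions.append(
            Reaction(
                id=rx.getId(),
                enzyme=rx.getName() or rx.getId(),
                substrates=substrates,
                products=products,
                rate_law=law,
                clamped_substrate=clamped_substrate,
            )
        )
    return PathwayModel(metabolites=tuple(metabolites), reactions=tuple(reactions))
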