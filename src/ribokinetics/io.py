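"""Readers and writers for the package's plain-text formats.

Dialects (all UTF-8, '.' decimal, '#' comment lines ignored):

* parameter table — CSV ``reaction_id,vmax,km_a,km_b`` (km_b blank for
  single-substrate laws); Vmax in nmol/mg/min, Km in nM
* initial concentrations — CSV ``metabolite_id,conc_nM``
* flux vector — TSV ``reaction_id<TAB>flux_nM_per_s<TAB>provenance``
* trajectory — TSV, first column ``time_s``, one column per metabolite
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .model import KineticEntry, ParameterSet
from .simulation import NM_PER_UMOL_L, Trajectory
from .stoichiometry import FluxVector

__all__ = [
    "read_parameter_table",
    "write_parameter_table",
    "read_concentration_table",
    "write_concentration_table",
    "read_parameter_set",
    "write_parameter_set",
    "write_flux_table",
    "read_flux_table",
    "write_trajectory",
    "read_trajectory_frame",
]


class TableFormatError(ValueError):
    """Malformed tabular input, with the offending line number."""


def _data_lines(path: str | Path):
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def _float(value: str, what: str, lineno: int, path) -> float:
    try:
        return float(value)
    except ValueError:
        raise TableFormatError(
            f"{path}, line {lineno}: {what} is not a number: {value!r}"
        ) from None


def read_parameter_table(path: str | Path) -> dict[str, KineticEntry]:
    """Parse a kinetic-parameter CSV into per-reaction entries.

    The header row is required.  A blank ``km_b`` marks a single-substrate
    law.  Duplicate reaction ids and malformed rows raise
    :class:`TableFormatError` with the line number.
    """
    entries: dict[str, KineticEntry] = {}
    header_seen = False
    for lineno, line in _data_lines(path):
        row = next(csv.reader([line]))
        if not header_seen:
            expected = ["reaction_id", "vmax", "km_a", "km_b"]
            if [c.strip() for c in row] != expected:
                raise TableFormatError(
                    f"{path}, line {lineno}: expected header {','.join(expected)!r}, "
                    f"got {line!r}"
                )
            header_seen = True
            continue
        if len(row) != 4:
            raise TableFormatError(
                f"{path}, line {lineno}: expected 4 comma-separated fields, got {len(row)}"
            )
        rid = row[0].strip()
        if not rid:
            raise TableFormatError(f"{path}, line {lineno}: empty reaction_id")
        if rid in entries:
            raise TableFormatError(f"{path}, line {lineno}: duplicate reaction id {rid!r}")
        if not row[2].strip():
            raise TableFormatError(f"{path}, line {lineno}: km_a is required but missing")
        vmax = _float(row[1], "vmax", lineno, path)
        km_a = _float(row[2], "km_a", lineno, path)
        km_b = _float(row[3], "km_b", lineno, path) if row[3].strip() else None
        entries[rid] = KineticEntry(vmax=vmax, km_a=km_a, km_b=km_b)
    if not header_seen:
        raise TableFormatError(f"{path}: empty parameter table (no header)")
    return entries


def write_parameter_table(entries: dict[str, KineticEntry], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# kinetic parameters: Vmax in nmol/mg/min, Km in nM\n")
        fh.write("reaction_id,vmax,km_a,km_b\n")
        for rid, e in entries.items():
            km_b = "" if e.km_b is None else repr(e.km_b)
            fh.write(f"{rid},{e.vmax!r},{e.km_a!r},{km_b}\n")


def read_concentration_table(path: str | Path) -> dict[str, float]:
    """Parse an initial-concentration CSV (``metabolite_id,conc_nM``)."""
    conc: dict[str, float] = {}
    header_seen = False
    for lineno, line in _data_lines(path):
        row = next(csv.reader([line]))
        if not header_seen:
            if [c.strip() for c in row] != ["metabolite_id", "conc_nM"]:
                raise TableFormatError(
                    f"{path}, line {lineno}: expected header 'metabolite_id,conc_nM', "
                    f"got {line!r}"
                )
            header_seen = True
            continue
        if len(row) != 2:
            raise TableFormatError(
                f"{path}, line {lineno}: expected 2 comma-separated fields, got {len(row)}"
            )
        mid = row[0].strip()
        if mid in conc:
            raise TableFormatError(f"{path}, line {lineno}: duplicate metabolite id {mid!r}")
        value = _float(row[1], "conc_nM", lineno, path)
        if value < 0:
            raise TableFormatError(
                f"{path}, line {lineno}: concentration of {mid!r} is negative"
            )
        conc[mid] = value
    if not header_seen:
        raise TableFormatError(f"{path}: empty concentration table (no header)")
    return conc


def write_concentration_table(conc: dict[str, float], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# initial concentrations in nM\n")
        fh.write("metabolite_id,conc_nM\n")
        for mid, value in conc.items():
            fh.write(f"{mid},{value!r}\n")


def read_parameter_set(
    params_path: str | Path,
    conc_path: str | Path,
    vmax_scale: float = 1.0 / 60.0,
    clamped: dict[str, float] | None = None,
) -> ParameterSet:
    """Load a full parameter set from the two CSV tables."""
    return ParameterSet(
        kinetic=read_parameter_table(params_path),
        initial_concentrations=read_concentration_table(conc_path),
        vmax_scale=vmax_scale,
        clamped=clamped if clamped is not None else {"ATP": 3.0e6},
    )


def write_parameter_set(
    params: ParameterSet, params_path: str | Path, conc_path: str | Path
) -> None:
    write_parameter_table(params.kinetic, params_path)
    write_concentration_table(params.initial_concentrations, conc_path)


def write_flux_table(fluxes: FluxVector, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("reaction_id\tflux_nM_per_s\tprovenance\n")
        for rid, value, prov in zip(fluxes.reactions, fluxes.values, fluxes.provenance):
            fh.write(f"{rid}\t{float(value)!r}\t{prov}\n")


def read_flux_table(path: str | Path) -> FluxVector:
    rids: list[str] = []
    values: list[float] = []
    prov: list[str] = []
    header_seen = False
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if not header_seen:
            if fields != ["reaction_id", "flux_nM_per_s", "provenance"]:
                raise TableFormatError(f"{path}, line {lineno}: bad flux-table header")
            header_seen = True
            continue
        if len(fields) != 3:
            raise TableFormatError(
                f"{path}, line {lineno}: expected 3 tab-separated fields"
            )
        rids.append(fields[0])
        values.append(_float(fields[1], "flux", lineno, path))
        prov.append(fields[2])
    return FluxVector(
        reactions=tuple(rids), values=np.array(values), provenance=tuple(prov)
    )


def write_trajectory(traj: Trajectory, path: str | Path, unit: str = "nM") -> None:
    """Write a trajectory TSV (``time_s`` + one concentration column per species)."""
    conc = traj.concentrations
    if unit == "umol/L":
        conc = conc / NM_PER_UMOL_L
    elif unit != "nM":
        raise ValueError(f"unknown unit {unit!r} (use 'nM' or 'umol/L')")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("time_s\t" + "\t".join(traj.metabolite_ids) + "\n")
        for t, row in zip(traj.times, conc):
            fh.write(f"{float(t)!r}\t" + "\t".join(repr(float(x)) for x in row) + "\n")


def read_trajectory_frame(path: str | Path):
    """Re-read a trajectory TSV as a pandas DataFrame."""
    import pandas as pd

    return pd.read_csv(path, sep="\t")
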