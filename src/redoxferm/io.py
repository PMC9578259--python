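"""Readers/writers for measurement tables, configs and JSON reports.

Delimited formats are comma-separated, "." decimal, UTF-8, header
required.  Units are fixed by the schema (hours, g/L, mmol g^-1 h^-1), not
inferred.  Reports are self-describing JSON: they echo the inputs,
parameters and seed so a run can be reproduced bit for bit.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd
import yaml

from . import __version__ as _version
from .errors import ConfigurationError, ParseError
from .model import BiomassParameters
from .quant import CultureSeries, SteadyState
from .simulate import (
    BatchSimulationSpec,
    ChemostatSimulationSpec,
    ProductStoichiometry,
)
from .stoich import Compound, CompoundRegistry, ElementalFormula, Reaction

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# culture series (CSV)
# ---------------------------------------------------------------------------

def read_culture_series(path: PathLike) -> CultureSeries:
    """Read a time-resolved series: time_h, biomass_gL, <compound>_gL..."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - normalize to a schema error
        raise ParseError(f"cannot read {path}: {exc}") from exc
    try:
        return CultureSeries(data=df, metadata={"source": str(path)})
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_culture_series(series: CultureSeries, path: PathLike) -> None:
    series.data.to_csv(Path(path), index=False)


# ---------------------------------------------------------------------------
# chemostat steady states (CSV, one row per replicate)
# ---------------------------------------------------------------------------

def read_steady_states(path: PathLike) -> List[SteadyState]:
    """One row per replicate: replicate, D_h, biomass_gL, <name>_in_gL /
    <name>_out_gL pairs."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"cannot read {path}: {exc}") from exc
    for col in ("D_h", "biomass_gL"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    in_cols = [c for c in df.columns if c.endswith("_in_gL")]
    out_cols = [c for c in df.columns if c.endswith("_out_gL")]
    if not in_cols or not out_cols:
        raise ParseError(f"{path}: need <compound>_in_gL and <compound>_out_gL columns")
    states = []
    for idx, row in df.iterrows():
        try:
            states.append(SteadyState(
                D=float(row["D_h"]),
                c_in={c[: -len("_in_gL")]: float(row[c]) for c in in_cols},
                c_out={c[: -len("_out_gL")]: float(row[c]) for c in out_cols},
                Cx=float(row["biomass_gL"]),
                replicate=str(row.get("replicate", idx)),
            ))
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: bad value in row {idx}: {exc}") from exc
    return states


def write_steady_states(states: Sequence[SteadyState], path: PathLike) -> None:
    names = sorted({n for s in states for n in set(s.c_in) | set(s.c_out)})
    rows = []
    for s in states:
        row: Dict[str, object] = {
            "replicate": s.replicate, "D_h": s.D, "biomass_gL": s.Cx,
        }
        for n in names:
            row[f"{n}_in_gL"] = s.c_in.get(n, 0.0)
            row[f"{n}_out_gL"] = s.c_out.get(n, 0.0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(Path(path), index=False)


# ---------------------------------------------------------------------------
# YAML / JSON configs
# ---------------------------------------------------------------------------

def _load_structured(path: PathLike) -> dict:
    path = Path(path)
    try:
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except Exception as exc:  # noqa: BLE001
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    return data


def load_network_config(path: PathLike) -> Tuple[CompoundRegistry, List[Reaction]]:
    """Load user-declared compounds and reactions.

    Schema: ``compounds: [{name, formula: {C,H,O,N}, molar_mass}]`` (or
    ``cofactor_gamma`` instead of ``formula``) and
    ``reactions: [{id, stoich: {name: coef}, reversible?}]``.
    """
    data = _load_structured(path)
    registry = CompoundRegistry()
    for entry in data.get("compounds", []):
        try:
            if "formula" in entry:
                f = entry["formula"]
                formula = ElementalFormula(**{k: float(v) for k, v in f.items()})
                registry.register(Compound(
                    name=entry["name"], formula=formula,
                    molar_mass=entry.get("molar_mass"),
                ))
            else:
                registry.register(Compound.cofactor(
                    entry["name"], float(entry["cofactor_gamma"])
                ))
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigurationError(f"bad compound entry {entry!r}: {exc}") from exc
    reactions = []
    for entry in data.get("reactions", []):
        try:
            reactions.append(Reaction(
                id=entry["id"],
                stoich={k: float(v) for k, v in entry["stoich"].items()},
                reversible=bool(entry.get("reversible", False)),
            ))
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigurationError(f"bad reaction entry {entry!r}: {exc}") from exc
    return registry, reactions


def load_biomass_params(data: dict) -> BiomassParameters:
    known = {"n_ATP", "n_NADH", "m_ATP", "cmol_mass", "gamma_x"}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown biomass parameters: {sorted(unknown)}")
    return BiomassParameters(**{k: float(v) for k, v in data.items()})


def load_batch_spec(path: PathLike) -> BatchSimulationSpec:
    """Batch simulation spec from YAML/JSON.

    Requires a ``stoich`` mapping (ProductStoichiometry fields); other keys
    are BatchSimulationSpec fields.
    """
    data = _load_structured(path)
    if "stoich" not in data:
        raise ConfigurationError("batch spec needs a 'stoich' mapping")
    try:
        stoich = ProductStoichiometry(**{k: float(v) for k, v in data["stoich"].items()})
        rest = {k: v for k, v in data.items() if k != "stoich"}
        return BatchSimulationSpec(stoich=stoich, **rest)
    except TypeError as exc:
        raise ConfigurationError(f"bad batch spec: {exc}") from exc


def load_chemostat_spec(path: PathLike) -> ChemostatSimulationSpec:
    """Chemostat simulation spec from YAML/JSON; events are
    ``[{time_h, q: {name: value}}]``."""
    data = _load_structured(path)
    try:
        events = [
            (float(ev["time_h"]), {k: float(v) for k, v in ev["q"].items()})
            for ev in data.pop("events", [])
        ]
        return ChemostatSimulationSpec(events=events, **data)
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"bad chemostat spec: {exc}") from exc


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def write_report(
    path: PathLike,
    command: str,
    parameters: dict,
    results: dict,
    seed: Optional[int] = None,
    inputs: Optional[dict] = None,
) -> dict:
    """Write a self-describing JSON report and return it."""
    report = {
        "package": "redoxferm",
        "version": _version,
        "command": command,
        "seed": seed,
        "inputs": inputs or {},
        "parameters": parameters,
        "results": results,
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, sort_keys=True, default=_json_default) + "\n")
    return report


def _json_default(obj):
    try:
        import numpy as np
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
    except ImportError:  # pragma: no cover
        pass
    from fractions import Fraction
    if isinstance(obj, Fraction):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
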