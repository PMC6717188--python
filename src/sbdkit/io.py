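"""Readers and writers for the package's documented text formats.

Formulations travel as YAML (or JSON) documents with a ``schema_version``
key; bioassay endpoint tables as CSV with the header
``assay,species,endpoint_type,value,units``; MCDA scorecards as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import pandas as pd
import yaml
from pydantic import ValidationError

from .core import BioassayResult, CompositionError, Formulation, SchemaError

__all__ = [
    "FORMULATION_SCHEMA_VERSION",
    "read_formulation",
    "write_formulation",
    "formulation_to_dict",
    "formulation_from_dict",
    "read_bioassays",
    "write_bioassays",
    "BIOASSAY_COLUMNS",
]

FORMULATION_SCHEMA_VERSION = 1
BIOASSAY_COLUMNS = ["assay", "species", "endpoint_type", "value", "units"]


def _fraction_repr(mf) -> Union[float, list]:
    if mf.is_interval:
        return [mf.lower, mf.upper]
    return mf.upper


def formulation_to_dict(f: Formulation) -> dict:
    """Plain-dict form of a formulation (the on-disk schema)."""
    return {
        "schema_version": FORMULATION_SCHEMA_VERSION,
        "id": f.id,
        "label": f.label,
        "composition_tolerance": f.composition_tolerance,
        "ingredients": [
            {
                "id": i.id,
                "name": i.name,
                "mass_fraction": _fraction_repr(i.mass_fraction),
                "hazards": [
                    {"hazard_class": h.hazard_class, "category": h.category, "h_code": h.h_code}
                    for h in i.hazards
                ],
                "ate": dict(i.ate),
                "m_factor_acute": i.m_factor_acute,
                "m_factor_chronic": i.m_factor_chronic,
                "is_nanoform": i.is_nanoform,
                "is_volatile": i.is_volatile,
                "sds_available": i.sds_available,
            }
            for i in f.ingredients
        ],
    }


def formulation_from_dict(doc: dict) -> Formulation:
    if not isinstance(doc, dict):
        raise SchemaError("formulation document must be a mapping")
    version = doc.get("schema_version")
    if version != FORMULATION_SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported schema_version {version!r} (expected {FORMULATION_SCHEMA_VERSION})"
        )
    payload = {k: v for k, v in doc.items() if k != "schema_version"}
    try:
        return Formulation(**payload)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        msg = first["msg"]
        if "composition" in msg or "sums to" in msg:
            raise CompositionError(f"{loc or 'formulation'}: {msg}") from exc
        raise SchemaError(f"field {loc!r}: {msg}") from exc


def read_formulation(path: Union[str, Path]) -> Formulation:
    """Read a formulation file (YAML by default, JSON for ``.json`` paths)."""
    path = Path(path)
    text = path.read_text()
    try:
        doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise SchemaError(f"cannot parse {path.name}: {exc}") from exc
    return formulation_from_dict(doc)


def write_formulation(f: Formulation, path: Union[str, Path]) -> Path:
    path = Path(path)
    doc = formulation_to_dict(f)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


_UNIT_FACTORS_TO_MG_L = {
    "mg/l": 1.0,
    "g/l": 1000.0,
    "ug/l": 1e-3,
    "µg/l": 1e-3,
    "ng/l": 1e-6,
}


def _normalise_row(row: dict, idx) -> BioassayResult:
    units = str(row.get("units", "") or "").strip()
    value = float(row["value"])
    endpoint = str(row["endpoint_type"]).strip()
    if endpoint != "induction_ratio":
        factor = _UNIT_FACTORS_TO_MG_L.get(units.lower().replace(" ", ""))
        if factor is None:
            raise ValueError(f"unknown concentration units {units!r}")
        value *= factor
        units = "mg/L"
    else:
        units = ""
    return BioassayResult(
        assay=str(row["assay"]).strip(),
        species=str(row.get("species", "") or ""),
        endpoint_type=endpoint,
        value=value,
        units=units,
    )


def read_bioassays(path: Union[str, Path]) -> list[BioassayResult]:
    """Read a bioassay endpoint CSV; concentration units are normalised to mg/L.

    All offending rows are collected and reported together.
    """
    df = pd.read_csv(path)
    if df.empty and not set(BIOASSAY_COLUMNS) <= set(df.columns):
        return []
    missing = [c for c in ("assay", "endpoint_type", "value") if c not in df.columns]
    if missing:
        raise SchemaError(f"bioassay CSV is missing columns: {', '.join(missing)}")
    results, errors = [], []
    for idx, row in df.iterrows():
        try:
            results.append(_normalise_row(row.to_dict(), idx))
        except (ValidationError, ValueError, KeyError) as exc:
            msg = exc.errors()[0]["msg"] if isinstance(exc, ValidationError) else str(exc)
            errors.append(f"row {idx + 2}: {msg}")  # +2: header + 1-based
    if errors:
        raise SchemaError("invalid bioassay rows:\n  " + "\n  ".join(errors))
    return results


def write_bioassays(results: list[BioassayResult], path: Union[str, Path]) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "assay": r.assay.value,
                "species": r.species,
                "endpoint_type": r.endpoint_type.value,
                "value": r.value,
                "units": r.units or "",
            }
            for r in results
        ],
        columns=BIOASSAY_COLUMNS,
    )
    df.to_csv(path, index=False)
    return path
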