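"""Core domain types and tabular I/O for per-field rice production records.

A *cohort* is a table of field-season records, one row per field-season, with
the planting method (MT, MD, MAT, MAD), per-hectare input rates (N, P2O5, K2O,
seed, herbicide, pesticide, labor hours, machinery hours) and grain (plus
optionally straw) yield.  A :class:`CoefficientTable` holds the per-unit cost,
greenhouse-gas and energy-equivalent factors used by the benefit accounting.
"""

from __future__ import annotations

import copy
import hashlib
import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

METHODS = ("MT", "MD", "MAT", "MAD")
#: methods whose records carry a labor coefficient (manual methods)
LABOR_METHODS = ("MAT", "MAD")
#: methods whose records carry a machinery coefficient (mechanized methods)
MACHINERY_METHODS = ("MT", "MD")

#: mandatory cohort columns, in canonical order
MANDATORY_COLUMNS = (
    "method",
    "n_rate",
    "p_rate",
    "k_rate",
    "seed_rate",
    "herbicide",
    "pesticide",
    "labor_hours",
    "machine_hours",
    "grain_yield",
)
OPTIONAL_COLUMNS = ("straw_yield",)
QUANTITY_COLUMNS = MANDATORY_COLUMNS[1:] + OPTIONAL_COLUMNS
#: the four optimizable inputs
INPUT_COLUMNS = ("n_rate", "p_rate", "k_rate", "seed_rate")
#: the five benefit indicators, in composite-code order
BENEFIT_COLUMNS = ("yield", "ghg", "eb", "pfp", "eue")


class SchemaError(ValueError):
    """A cohort file does not name all mandatory columns."""


class ValidationError(ValueError):
    """A cohort row violates a domain invariant."""


class CoefficientLookupError(KeyError):
    """A nonzero input has no matching coefficient entry."""


@dataclass
class CohortTable:
    """Validated collection of field-season records.

    Wraps a :class:`pandas.DataFrame` whose index is a stable record
    identifier.  Construction validates method codes and non-negativity.
    """

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"cohort is missing mandatory column(s): {missing}")
        if "straw_yield" not in df.columns:
            df = df.copy()
            df["straw_yield"] = np.nan
        df = df[list(MANDATORY_COLUMNS) + list(OPTIONAL_COLUMNS)].copy()
        if df.index.duplicated().any():
            raise ValidationError("duplicated record identifiers in cohort")
        bad = ~df["method"].isin(METHODS)
        if bad.any():
            rid = df.index[bad][0]
            raise ValidationError(
                f"unknown method code {df.loc[rid, 'method']!r} on row {rid!r}"
            )
        for col in QUANTITY_COLUMNS:
            vals = pd.to_numeric(df[col], errors="coerce")
            neg = vals < 0
            if neg.any():
                rid = df.index[neg][0]
                raise ValidationError(f"negative {col} ({vals[neg].iloc[0]}) on row {rid!r}")
            df[col] = vals.astype(float)
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def method_counts(self) -> dict[str, int]:
        counts = self.data["method"].value_counts()
        return {m: int(counts.get(m, 0)) for m in METHODS}

    def subset(self, method: str) -> "CohortTable":
        return CohortTable(self.data[self.data["method"] == method].copy(),
                           provenance=dict(self.provenance))


def load_cohort(path: str | Path) -> CohortTable:
    """Read a cohort CSV (UTF-8, header row, ``#`` comment/provenance lines)."""
    path = Path(path)
    provenance: dict = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, _, val = line.lstrip("# ").rstrip("\n").partition("=")
                provenance[key.strip()] = val.strip()
    df = pd.read_csv(path, comment="#", index_col=0)
    return CohortTable(df, provenance=provenance)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort CSV with ``# key = value`` provenance header lines."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in sorted(cohort.provenance.items()):
            fh.write(f"# {key} = {val}\n")
        cohort.data.to_csv(fh, index_label="record_id", lineterminator="\n")


@dataclass
class CoefficientTable:
    """Per-unit cost (CNY), GHG (kg CO2-eq) and energy (MJ) factors.

    ``items`` maps each per-kg input column to its factors; labor and
    machinery factors are method-specific (labor priced per ha-season,
    machinery per hour).  ``outputs`` holds the grain sale price and the
    grain/straw energy equivalents.
    """

    items: dict
    labor: dict
    machinery: dict
    outputs: dict
    straw_to_grain_ratio: float = 1.0

    def __post_init__(self) -> None:
        for name, entry in self.items.items():
            for k in ("cost", "ghg", "energy"):
                if entry[k] < 0:
                    raise ValidationError(f"negative {k} factor for {name}")
        if self.outputs["grain_price"] <= 0:
            raise ValidationError("grain_price must be positive")

    @property
    def grain_price(self) -> float:
        return float(self.outputs["grain_price"])

    @property
    def grain_energy(self) -> float:
        return float(self.outputs["grain_energy"])

    @property
    def straw_energy(self) -> float:
        return float(self.outputs["straw_energy"])

    def labor_for(self, method: str) -> Mapping | None:
        return self.labor.get(method)

    def machinery_for(self, method: str) -> Mapping | None:
        return self.machinery.get(method)

    def config_hash(self) -> str:
        payload = json.dumps(
            {"items": self.items, "labor": self.labor, "machinery": self.machinery,
             "outputs": self.outputs, "straw_to_grain_ratio": self.straw_to_grain_ratio},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _deep_update(base: dict, override: Mapping) -> dict:
    for key, val in override.items():
        if isinstance(val, Mapping) and isinstance(base.get(key), dict):
            base[key] = _deep_update(base[key], val)
        else:
            base[key] = val
    return base


def load_coefficients(path: str | Path | None = None) -> CoefficientTable:
    """Load the coefficient table.

    With no path, returns the packaged defaults.  A user config needs to name
    only the entries it overrides; everything else keeps its default.
    """
    ref = importlib.resources.files("paddyopt").joinpath("data/default_coefficients.yaml")
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    if path is not None:
        override = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        raw = _deep_update(copy.deepcopy(raw), override)
    return CoefficientTable(
        items=raw["items"],
        labor=raw.get("labor", {}),
        machinery=raw.get("machinery", {}),
        outputs=raw["outputs"],
        straw_to_grain_ratio=float(raw.get("straw_to_grain_ratio", 1.0)),
    )


def cohort_from_records(records: Iterable[Mapping], ids: Iterable | None = None) -> CohortTable:
    """Build a CohortTable from an iterable of dict-like records."""
    df = pd.DataFrame(list(records))
    if ids is not None:
        df.index = pd.Index(list(ids), name="record_id")
    else:
        df.index.name = "record_id"
    return CohortTable(df)
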