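"""Benefit accounting: the five per-hectare indicators from input coefficients.

For every field-season record the package computes

* grain revenue           ``economic output = grain yield x sale price``
* economic benefit (EB)   ``EB = economic output - input costs``        [CNY/ha]
* GHG emissions           ``sum_i R_i x D_i`` over all inputs           [kg CO2-eq/ha]
* partial fertilizer productivity (PFP)  ``grain yield / (N + P2O5 + K2O)``
* energy use efficiency (EUE)  ``total output energy / total input energy``

R_i is the amount of input *i* and D_i its emission coefficient.  Labor is
priced per ha-season, machinery per hour; the method decides which labor or
machinery coefficient row applies.  Zero total fertilizer or zero input energy
make PFP/EUE undefined; those components are carried as missing values, never
as zeros, so that downstream banding means are not corrupted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    BENEFIT_COLUMNS,
    CoefficientLookupError,
    CoefficientTable,
    CohortTable,
)

_PER_KG_ITEMS = ("n_rate", "p_rate", "k_rate", "seed_rate", "herbicide", "pesticide")


@dataclass
class EnergyBalance:
    """Total energy flows of one record, MJ/ha."""

    energy_in: float
    energy_out: float


class UndefinedIndicatorError(ArithmeticError):
    """PFP or EUE is undefined (zero denominator)."""


def _get(record: Mapping, key: str, default: float = 0.0) -> float:
    val = record.get(key, default) if hasattr(record, "get") else getattr(record, key, default)
    if val is None or (isinstance(val, float) and math.isnan(val)):
        return default
    return float(val)


def economic_output(grain_yield: float, coeffs: CoefficientTable) -> float:
    """Grain revenue in CNY/ha."""
    if grain_yield < 0:
        raise ValueError("grain_yield must be non-negative")
    return grain_yield * coeffs.grain_price


def input_costs(record: Mapping, coeffs: CoefficientTable) -> float:
    """Total input cost in CNY/ha, using method-appropriate labor/machinery rows."""
    total = 0.0
    for item in _PER_KG_ITEMS:
        amount = _get(record, item)
        if amount == 0.0:
            continue
        if item not in coeffs.items:
            raise CoefficientLookupError(f"no cost coefficient for input {item!r}")
        total += amount * coeffs.items[item]["cost"]
    method = record["method"] if hasattr(record, "__getitem__") else record.method
    labor_hours = _get(record, "labor_hours")
    if labor_hours > 0:
        row = coeffs.labor_for(method)
        if row is None:
            raise CoefficientLookupError(f"no labor coefficient row for method {method!r}")
        total += row["cost_per_season"]  # priced per ha-season, not per hour
    machine_hours = _get(record, "machine_hours")
    if machine_hours > 0:
        row = coeffs.machinery_for(method)
        if row is None:
            raise CoefficientLookupError(f"no machinery coefficient row for method {method!r}")
        total += machine_hours * row["cost"]
    return total


def economic_benefit(record: Mapping, coeffs: CoefficientTable) -> float:
    """EB = grain revenue minus input costs; may be negative."""
    return economic_output(_get(record, "grain_yield"), coeffs) - input_costs(record, coeffs)


def ghg_emissions(record: Mapping, coeffs: CoefficientTable) -> float:
    """Input-embodied GHG emissions, kg CO2-eq/ha: sum of amount x factor."""
    total = 0.0
    for item in _PER_KG_ITEMS:
        amount = _get(record, item)
        if amount == 0.0:
            continue
        if item not in coeffs.items:
            raise CoefficientLookupError(f"no GHG coefficient for input {item!r}")
        total += amount * coeffs.items[item]["ghg"]
    method = record["method"] if hasattr(record, "__getitem__") else record.method
    labor_hours = _get(record, "labor_hours")
    if labor_hours > 0:
        row = coeffs.labor_for(method)
        if row is None:
            raise CoefficientLookupError(f"no labor coefficient row for method {method!r}")
        total += labor_hours * row["ghg"]
    machine_hours = _get(record, "machine_hours")
    if machine_hours > 0:
        row = coeffs.machinery_for(method)
        if row is None:
            raise CoefficientLookupError(f"no machinery coefficient row for method {method!r}")
        total += machine_hours * row["ghg"]
    return total


def partial_fertilizer_productivity(grain_yield: float, record: Mapping) -> float:
    """Grain yield per kg of total N + P2O5 + K2O fertilizer (seed excluded)."""
    total_fert = _get(record, "n_rate") + _get(record, "p_rate") + _get(record, "k_rate")
    if total_fert <= 0:
        raise UndefinedIndicatorError("PFP undefined: zero total fertilizer input")
    return grain_yield / total_fert


def energy_balance(record: Mapping, coeffs: CoefficientTable) -> EnergyBalance:
    """Energy input and output flows (MJ/ha).

    Missing straw yield is imputed as ``straw_to_grain_ratio x grain`` for the
    output side only.
    """
    energy_in = 0.0
    for item in _PER_KG_ITEMS:
        amount = _get(record, item)
        if amount == 0.0:
            continue
        if item not in coeffs.items:
            raise CoefficientLookupError(f"no energy coefficient for input {item!r}")
        energy_in += amount * coeffs.items[item]["energy"]
    method = record["method"] if hasattr(record, "__getitem__") else record.method
    labor_hours = _get(record, "labor_hours")
    if labor_hours > 0:
        row = coeffs.labor_for(method)
        if row is None:
            raise CoefficientLookupError(f"no labor coefficient row for method {method!r}")
        energy_in += labor_hours * row["energy"]
    machine_hours = _get(record, "machine_hours")
    if machine_hours > 0:
        row = coeffs.machinery_for(method)
        if row is None:
            raise CoefficientLookupError(f"no machinery coefficient row for method {method!r}")
        energy_in += machine_hours * row["energy"]
    grain = _get(record, "grain_yield")
    straw_raw = record.get("straw_yield", None) if hasattr(record, "get") else getattr(record, "straw_yield", None)
    if straw_raw is None or (isinstance(straw_raw, float) and math.isnan(straw_raw)):
        straw = grain * coeffs.straw_to_grain_ratio
    else:
        straw = float(straw_raw)
    energy_out = grain * coeffs.grain_energy + straw * coeffs.straw_energy
    return EnergyBalance(energy_in=energy_in, energy_out=energy_out)


def energy_use_efficiency(bal: EnergyBalance) -> float:
    """EUE = output energy / input energy (dimensionless)."""
    if bal.energy_in <= 0:
        raise UndefinedIndicatorError("EUE undefined: zero energy input")
    return bal.energy_out / bal.energy_in


def benefits(record: Mapping, coeffs: CoefficientTable) -> dict[str, float]:
    """Assemble the five-indicator benefit vector for one record.

    Undefined PFP/EUE come back as NaN so callers can exclude them from
    pooled means.
    """
    grain = _get(record, "grain_yield")
    vec = {
        "yield": grain,
        "ghg": ghg_emissions(record, coeffs),
        "eb": economic_benefit(record, coeffs),
    }
    try:
        vec["pfp"] = partial_fertilizer_productivity(grain, record)
    except UndefinedIndicatorError:
        vec["pfp"] = float("nan")
    try:
        vec["eue"] = energy_use_efficiency(energy_balance(record, coeffs))
    except UndefinedIndicatorError:
        vec["eue"] = float("nan")
    return vec


def benefit_table(cohort: CohortTable, coeffs: CoefficientTable) -> pd.DataFrame:
    """Per-record benefit indicators for a whole cohort.

    Returns a DataFrame indexed like the cohort with columns
    ``method, yield, ghg, eb, pfp, eue``.
    """
    rows = []
    for _, rec in cohort.data.iterrows():
        rows.append(benefits(rec, coeffs))
    out = pd.DataFrame(rows, index=cohort.data.index, columns=list(BENEFIT_COLUMNS))
    out.insert(0, "method", cohort.data["method"].to_numpy())
    return out


def method_mean_matrix(benefit_df: pd.DataFrame) -> pd.DataFrame:
    """4 x 5 matrix of per-method benefit means (NaN-excluded), methods as rows."""
    means = benefit_df.groupby("method", sort=False)[list(BENEFIT_COLUMNS)].mean()
    order = [m for m in ("MT", "MD", "MAT", "MAD") if m in means.index]
    return means.loc[order]
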