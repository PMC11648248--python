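"""Benefit-interval banding and composite benefit codes.

Bands are anchored at the pooled mean of each indicator: yield is split into
low (<= 0.8 x mean), medium, and high (>= 1.2 x mean); GHG, EB, PFP and EUE
are split into high (>= 1.2 x mean) and low (below).  A record's composite
benefit code concatenates its five band letters in the fixed order yield,
GHG, EB, PFP, EUE — e.g. ``HY-HG-HB-HP-LE`` for high yield, high GHG
emissions, high economic benefit, high fertilizer productivity, low energy
use efficiency.  The modal code of a method's records is that method's
*conventional benefit*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BENEFIT_COLUMNS

#: band letter suffix per indicator, in code order
_SUFFIX = {"yield": "Y", "ghg": "G", "eb": "B", "pfp": "P", "eue": "E"}
#: indicators with a three-way (low/medium/high) banding
_THREE_WAY = ("yield",)

WILDCARD = "?"


class BandingError(ValueError):
    """An indicator column has no non-missing values to band on."""


@dataclass
class BenefitBands:
    """Pooled means and derived thresholds for the five indicators."""

    low_mult: float
    high_mult: float
    means: dict[str, float]
    thresholds: dict[str, dict[str, float]] = field(init=False)

    def __post_init__(self) -> None:
        self.thresholds = {}
        for name, mean in self.means.items():
            self.thresholds[name] = {
                "low": self.low_mult * mean,
                "high": self.high_mult * mean,
            }

    def band(self, indicator: str, value: float) -> str:
        """Band letter for one indicator value; wildcard for missing values."""
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return WILDCARD
        thr = self.thresholds[indicator]
        suffix = _SUFFIX[indicator]
        if indicator in _THREE_WAY:
            if value >= thr["high"]:
                return "H" + suffix
            if value <= thr["low"]:
                return "L" + suffix
            return "M" + suffix
        return ("H" if value >= thr["high"] else "L") + suffix

    def to_dict(self) -> dict:
        return {
            "rule": {"low_mult": self.low_mult, "high_mult": self.high_mult},
            "means": self.means,
            "thresholds": self.thresholds,
        }


def derive_bands(
    benefit_df: pd.DataFrame,
    low_mult: float = 0.8,
    high_mult: float = 1.2,
) -> BenefitBands:
    """Pooled-mean bands over all records of all methods.

    Missing indicator values are excluded from the means; an all-missing
    indicator raises :class:`BandingError`.
    """
    means = {}
    for name in BENEFIT_COLUMNS:
        col = benefit_df[name].dropna()
        if col.empty:
            raise BandingError(f"no non-missing values for indicator {name!r}")
        means[name] = float(col.mean())
    return BenefitBands(low_mult=low_mult, high_mult=high_mult, means=means)


def classify(benefit_vec, bands: BenefitBands) -> str:
    """Composite benefit code of one record (dict-like or Series of the five)."""
    parts = [bands.band(name, float(benefit_vec[name])) for name in BENEFIT_COLUMNS]
    return "-".join(parts)


def classify_table(benefit_df: pd.DataFrame, bands: BenefitBands) -> pd.Series:
    """Composite code per record, vectorized over a benefit table."""
    letters = []
    for name in BENEFIT_COLUMNS:
        vals = benefit_df[name].to_numpy(dtype=float)
        thr = bands.thresholds[name]
        suffix = _SUFFIX[name]
        if name in _THREE_WAY:
            lab = np.where(vals >= thr["high"], "H" + suffix,
                           np.where(vals <= thr["low"], "L" + suffix, "M" + suffix))
        else:
            lab = np.where(vals >= thr["high"], "H" + suffix, "L" + suffix)
        lab = np.where(np.isnan(vals), WILDCARD, lab)
        letters.append(lab)
    codes = ["-".join(parts) for parts in zip(*letters)]
    return pd.Series(codes, index=benefit_df.index, name="benefit_code")


def code_frequencies(benefit_df: pd.DataFrame, bands: BenefitBands) -> pd.DataFrame:
    """Per-method counts and proportions of composite codes.

    Returns a tidy frame with columns ``method, benefit_code, count,
    proportion`` sorted by method then descending count; the first row of each
    method is its modal ("conventional") code.
    """
    codes = classify_table(benefit_df, bands)
    df = pd.DataFrame({"method": benefit_df["method"], "benefit_code": codes})
    counts = (
        df.groupby(["method", "benefit_code"], sort=False)
        .size()
        .rename("count")
        .reset_index()
    )
    totals = counts.groupby("method")["count"].transform("sum")
    counts["proportion"] = counts["count"] / totals
    counts = counts.sort_values(
        ["method", "count", "benefit_code"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return counts


def modal_codes(freq: pd.DataFrame) -> dict[str, str]:
    """Conventional (modal) benefit code per method from a frequency table."""
    out = {}
    for method, grp in freq.groupby("method", sort=False):
        out[method] = grp.iloc[0]["benefit_code"]
    return out
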