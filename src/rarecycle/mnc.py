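"""Soil multi-nutrient cycling index (MNC).

Each of seven nutrient variables (SOC, TN, TP, TK, Olsen-P, Avail-K,
NO3-N) is min-max normalized over all samples jointly,

    N_or = (X - X_min) / (X_max - X_min),

and the per-sample MNC is the mean of the seven normalized values, so
MNC is unit-free, lies in [0, 1], and is invariant to positive affine
rescaling of any input variable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import MNC_VARIABLES, NutrientTable

__all__ = ["MNCResult", "min_max_normalize", "compute_mnc", "availability_ratios"]


@dataclass
class MNCResult:
    """Normalized matrix, per-sample index, and the extrema used."""

    normalized: pd.DataFrame       # samples x variables, each column in [0, 1]
    mnc: pd.Series                 # per-sample index in [0, 1]
    variables: list[str]
    x_min: pd.Series
    x_max: pd.Series


def min_max_normalize(values) -> tuple[np.ndarray, float, float]:
    """Normalize a per-sample vector to [0, 1] over its observed range.

    Returns ``(normalized, x_min, x_max)``. A constant vector is an error:
    the normalization is undefined when ``X_max == X_min``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two samples to normalize")
    x_min, x_max = float(x.min()), float(x.max())
    if x_max == x_min:
        raise ValueError("constant variable: min-max normalization undefined")
    return (x - x_min) / (x_max - x_min), x_min, x_max


def compute_mnc(table: NutrientTable, variables: list[str] | None = None) -> MNCResult:
    """Per-sample MNC over the given variables (default: the canonical seven).

    Normalization pools all provided samples jointly (not per crop). Missing
    or constant variables are hard errors — silently dropping one would
    change the definition of the index.
    """
    variables = list(variables) if variables is not None else list(MNC_VARIABLES)
    missing = [v for v in variables if v not in table.data.columns]
    if missing:
        raise ValueError(f"missing MNC variable {missing[0]}")
    normalized = {}
    x_min, x_max = {}, {}
    for var in variables:
        try:
            norm, lo, hi = min_max_normalize(table.data[var].to_numpy())
        except ValueError as exc:
            raise ValueError(f"variable {var!r}: {exc}") from exc
        normalized[var] = norm
        x_min[var], x_max[var] = lo, hi
    frame = pd.DataFrame(normalized, index=table.data.index)[variables]
    return MNCResult(
        normalized=frame,
        mnc=frame.mean(axis=1).rename("MNC"),
        variables=variables,
        x_min=pd.Series(x_min),
        x_max=pd.Series(x_max),
    )


#: numerator -> (denominator, numerator-to-denominator unit factor).
#: Olsen-P and Avail-K are measured in mg kg-1 against totals in g kg-1.
_RATIO_SPECS = {
    "AN_TN": ("AN", "TN", 1.0),
    "Olsen_P_TP": ("Olsen_P", "TP", 1e-3),
    "Avail_K_TK": ("Avail_K", "TK", 1e-3),
}


def availability_ratios(table: NutrientTable) -> pd.DataFrame:
    """Nutrient availability ratios AN:TN, Olsen-P:TP and Avail-K:TK, in percent.

    mg kg-1 numerators are converted to g kg-1 before dividing. A zero
    denominator yields a missing value for that sample with a warning.
    """
    out = {}
    for name, (num, den, factor) in _RATIO_SPECS.items():
        numerator = table.data[num].to_numpy(dtype=float) * factor
        denominator = table.data[den].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(denominator > 0, numerator / denominator * 100.0, np.nan)
        if np.isnan(ratio).any():
            warnings.warn(f"zero denominator in ratio {name}; samples set missing")
        out[name] = ratio
    frame = pd.DataFrame(out, index=table.data.index)
    frame.attrs["units"] = "percent"
    frame.attrs["unit_conversion"] = {
        name: f"{num} [{factor} g/mg applied]/{den}"
        for name, (num, den, factor) in _RATIO_SPECS.items()
    }
    return frame
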