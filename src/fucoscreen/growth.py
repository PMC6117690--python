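"""Growth-rate estimation, mutagen lethality, and DPA dose-response summaries.

The specific growth rate mu (day^-1) is the slope of an ordinary
least-squares fit of ln(OD625) against time over the exponential window.
Lethality is the percent reduction of survivors relative to an untreated
control. The diphenylamine (DPA) dose-response table classifies each dose
as growing (mu >= 0) or declining (mu < 0) and reports the largest dose
still compatible with growth — the working-concentration rationale for
inhibitor-pressure screening.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "GrowthCurve",
    "DoseResponseTable",
    "specific_growth_rate",
    "lethality",
    "dpa_dose_response",
]


@dataclass(frozen=True)
class GrowthCurve:
    """One OD625 time series at a given DPA dose.

    ``t`` in days (strictly increasing, >= 2 points), ``od625`` strictly
    positive, ``dpa_uM`` the inhibitor dose in micromolar.
    """

    t: np.ndarray
    od625: np.ndarray
    dpa_uM: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        od = np.asarray(self.od625, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "od625", od)
        if t.ndim != 1 or od.ndim != 1 or t.size != od.size:
            raise ValueError("t and od625 must be 1-D arrays of equal length")
        if t.size < 2:
            raise ValueError("a growth curve needs at least 2 time points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("t must be strictly increasing")
        if not np.all(od > 0):
            raise ValueError("od625 must be strictly positive")
        if self.dpa_uM < 0:
            raise ValueError("dpa_uM must be >= 0")


@dataclass(frozen=True)
class DoseResponseTable:
    """Per-dose growth rates with a grows/declines classification.

    ``table`` has columns ``dpa_uM``, ``mu_per_day``, ``classification``
    (``"grows"`` iff mu >= 0, else ``"declines"``).
    ``max_growth_dose_uM`` is the largest tested dose with mu >= 0, or
    ``None`` if growth fails at every dose.
    """

    table: pd.DataFrame
    max_growth_dose_uM: float | None


def _default_window(od: np.ndarray) -> np.ndarray:
    """Exponential-window mask: points with OD at or below half the maximum.

    A saturating culture spends its late points near the plateau; keeping
    only the lower half of the OD range biases the fit toward the
    exponential part of the curve. If fewer than 2 points qualify (e.g. a flat
    series) the whole series is used.
    """
    mask = od <= 0.5 * od.max()
    if mask.sum() < 2:
        mask = np.ones_like(mask, dtype=bool)
    return mask


def specific_growth_rate(
    curve: GrowthCurve, window: tuple[float, float] | None = None
) -> float:
    """Specific growth rate mu (day^-1): OLS slope of ln(OD) vs time.

    Parameters
    ----------
    curve
        The OD625 time series.
    window
        Optional explicit ``(t_min, t_max)`` fitting window (inclusive).
        By default all points with OD at or below half the series maximum
        are used (falling back to all points for flat series).
    """
    t, od = curve.t, curve.od625
    if window is not None:
        lo, hi = window
        mask = (t >= lo) & (t <= hi)
    else:
        mask = _default_window(od)
    if mask.sum() < 2:
        raise ValueError("fitting window contains fewer than 2 points")
    slope = np.polyfit(t[mask], np.log(od[mask]), 1)[0]
    return float(slope)


def lethality(treated_survivors: float, control_survivors: float) -> float:
    """Mutagen lethality, percent: ``100 * (1 - treated/control)``.

    Counts are cells or colonies plated identically with and without the
    mutagen treatment.
    """
    if control_survivors <= 0:
        raise ValueError("control_survivors must be > 0")
    if treated_survivors < 0:
        raise ValueError("counts must be >= 0")
    return 100.0 * (1.0 - treated_survivors / control_survivors)


def dpa_dose_response(
    curves: Iterable[GrowthCurve],
    window: tuple[float, float] | None = None,
) -> DoseResponseTable:
    """Summarise growth under a DPA dose series.

    Fits mu per curve, averages mu over replicate curves at the same dose,
    classifies each dose by the sign of mu, and reports the largest dose
    that still permits growth.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("need at least one growth curve")
    rows = [
        {"dpa_uM": c.dpa_uM, "mu_per_day": specific_growth_rate(c, window)}
        for c in curves
    ]
    table = (
        pd.DataFrame(rows)
        .groupby("dpa_uM", as_index=False)["mu_per_day"]
        .mean()
        .sort_values("dpa_uM", ignore_index=True)
    )
    table["classification"] = np.where(table["mu_per_day"] < 0, "declines", "grows")
    growing = table.loc[table["mu_per_day"] >= 0, "dpa_uM"]
    max_dose = float(growing.max()) if len(growing) else None
    return DoseResponseTable(table=table, max_growth_dose_uM=max_dose)
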