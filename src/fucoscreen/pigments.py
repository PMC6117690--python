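"""Spectrophotometric pigment quantification for methanol extracts.

Chlorophyll *a* and total carotenoid concentrations are computed from
absorbances at 665, 652 and 470 nm with the standard coefficients for
100% methanol extracts:

    Ca   = 15.65 * A665 - 7.34 * A652            [mg/L of extract]
    Xcar = (1000 * A470 - 2.86 * Ca) / 221       [mg/L of extract]

plus the plumbing around them: conversion to mg per g dry weight (DW),
OD-to-dry-weight calibration, the chlorophyll-a : carotenoid molar ratio,
and percent-versus-reference comparisons.

Negative computed concentrations (possible for unphysical inputs, e.g.
mis-blanked absorbances) are *flagged*, never clamped — silent clamping
would hide blank-subtraction errors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "ExtractAbsorbances",
    "PigmentProfile",
    "MW_CHLOROPHYLL_A",
    "MW_FUCOXANTHIN",
    "chlorophyll_a_content",
    "total_carotenoid_content",
    "per_dw_content",
    "od_to_dw",
    "chl_car_molar_ratio",
    "percent_vs_reference",
    "quantify_extract",
]

#: Molar mass of chlorophyll a, g/mol.
MW_CHLOROPHYLL_A = 893.5
#: Molar mass of fucoxanthin, g/mol — the default carotenoid proxy, since
#: fucoxanthin is the dominant carotenoid of Phaeodactylum tricornutum.
MW_FUCOXANTHIN = 658.9


@dataclass(frozen=True)
class ExtractAbsorbances:
    """Blank-subtracted absorbances of one pigment extract.

    Parameters
    ----------
    a665, a652, a470
        Optical absorbances (dimensionless) at 665/652/470 nm.
    extract_volume_ml
        Volume of solvent the pellet was extracted into, mL.
    biomass_dw_mg
        Dry weight of the extracted biomass, mg. Required (> 0) only when
        per-DW output is requested.
    dilution_factor
        Fold-dilution applied before reading; >= 1.
    """

    a665: float
    a652: float
    a470: float
    extract_volume_ml: float = 1.0
    biomass_dw_mg: float | None = None
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("a665", "a652", "a470"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.extract_volume_ml <= 0:
            raise ValueError("extract_volume_ml must be > 0")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")


@dataclass(frozen=True)
class PigmentProfile:
    """Derived pigment contents of one extract.

    ``ca`` / ``xcar`` are concentrations in the extract (mg/L); the
    ``*_per_dw`` fields are biomass-normalised contents (mg/g DW) and are
    ``None`` when no biomass was supplied. ``suspect`` is set when any
    computed value is negative (unphysical input).
    """

    ca: float
    xcar: float
    ca_per_dw: float | None = None
    xcar_per_dw: float | None = None
    suspect: bool = field(default=False)

    @property
    def molar_ratio(self) -> float:
        """Chlorophyll-a : carotenoid molar ratio (fucoxanthin molar mass)."""
        return chl_car_molar_ratio(self.ca, self.xcar)


def chlorophyll_a_content(a665: float, a652: float) -> float:
    """Chlorophyll a concentration, mg/L of methanol extract.

    ``Ca = 15.65 * A665 - 7.34 * A652``. The value may be negative for
    unphysical absorbance pairs; callers should treat that as a flag for
    blank-subtraction problems (see :func:`quantify_extract`).
    """
    if not (math.isfinite(a665) and math.isfinite(a652)):
        raise ValueError("absorbances must be finite")
    return 15.65 * a665 - 7.34 * a652


def total_carotenoid_content(a470: float, ca: float) -> float:
    """Total carotenoid concentration, mg/L of methanol extract.

    ``Xcar = (1000 * A470 - 2.86 * Ca) / 221`` where ``Ca`` is the
    chlorophyll a concentration from :func:`chlorophyll_a_content`.
    """
    if not (math.isfinite(a470) and math.isfinite(ca)):
        raise ValueError("inputs must be finite")
    return (1000.0 * a470 - 2.86 * ca) / 221.0


def per_dw_content(
    conc_mg_per_l: float,
    extract_volume_ml: float,
    biomass_dw_mg: float,
    dilution_factor: float = 1.0,
) -> float:
    """Convert an extract concentration (mg/L) to content per dry weight.

    mg/L x mL = ug of pigment; ug / mg DW = mg per g DW, so the arithmetic
    is ``conc * volume * dilution / biomass`` with no unit prefactor.
    """
    if biomass_dw_mg <= 0:
        raise ValueError("biomass_dw_mg must be > 0")
    if extract_volume_ml <= 0:
        raise ValueError("extract_volume_ml must be > 0")
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    return conc_mg_per_l * extract_volume_ml * dilution_factor / biomass_dw_mg


def od_to_dw(od625: float, coeff: float) -> float:
    """Dry-weight density (g DW / L) from optical density at 625 nm.

    Linear through the origin; ``coeff`` is the calibration slope
    (g DW per L per OD unit) of the instrument/strain combination.
    """
    if coeff <= 0:
        raise ValueError("coeff must be > 0")
    if od625 < 0:
        raise ValueError("od625 must be >= 0")
    return od625 * coeff


def chl_car_molar_ratio(
    ca_mg: float,
    xcar_mg: float,
    mw_chl: float = MW_CHLOROPHYLL_A,
    mw_car: float = MW_FUCOXANTHIN,
) -> float:
    """Chlorophyll-a : carotenoid molar ratio from mass amounts.

    ``(ca/mw_chl) / (xcar/mw_car)``. Carotenoid molar mass defaults to
    fucoxanthin's, the dominant carotenoid in diatoms; override for other
    pigment pools.
    """
    if xcar_mg <= 0:
        raise ValueError("molar ratio undefined for xcar_mg <= 0")
    if mw_chl <= 0 or mw_car <= 0:
        raise ValueError("molar masses must be > 0")
    return (ca_mg / mw_chl) / (xcar_mg / mw_car)


def percent_vs_reference(value: float, ref: float) -> float:
    """Percent difference of ``value`` relative to a reference (e.g. WT)."""
    if ref <= 0:
        raise ValueError("reference must be > 0")
    return 100.0 * (value - ref) / ref


def quantify_extract(extract: ExtractAbsorbances) -> PigmentProfile:
    """Full quantification of one extract: Ca, Xcar, and per-DW contents.

    Emits a :class:`UserWarning` and sets ``suspect=True`` on the profile
    when a computed concentration is negative.
    """
    ca = chlorophyll_a_content(extract.a665, extract.a652)
    xcar = total_carotenoid_content(extract.a470, ca)
    suspect = ca < 0 or xcar < 0
    if suspect:
        warnings.warn(
            f"negative pigment concentration (Ca={ca:.4g}, Xcar={xcar:.4g}); "
            "check blank subtraction",
            stacklevel=2,
        )
    ca_dw = xcar_dw = None
    if extract.biomass_dw_mg is not None:
        ca_dw = per_dw_content(
            ca, extract.extract_volume_ml, extract.biomass_dw_mg, extract.dilution_factor
        )
        xcar_dw = per_dw_content(
            xcar, extract.extract_volume_ml, extract.biomass_dw_mg, extract.dilution_factor
        )
    return PigmentProfile(ca=ca, xcar=xcar, ca_per_dw=ca_dw, xcar_per_dw=xcar_dw, suspect=suspect)
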