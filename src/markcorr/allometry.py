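"""Field measurements to ecosystem-service marks.

Two conversions: harvester-reported lata counts to kg of in-shell seed
(one lata holds ~11.66 kg), and diameter at breast height to above-ground
biomass via the diameter-only pantropical allometric model

    ln(AGB) = -1.803 - 0.976 E + 0.976 ln(rho) + 2.673 ln(D) - 0.0299 [ln(D)]^2

with AGB in kg, D the DBH in cm, rho the wood density in g cm^-3 and E a
dimensionless environmental-stress covariate.  For Brazil nut a species-level
wood density of 0.59 g cm^-3 is used and E defaults to 0; both are
configurable, and the coefficient vector itself can be replaced so the
statistics downstream never depend on one specific equation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AllometryParams", "latas_to_kg", "agb_from_dbh"]

#: (intercept, coef E, coef ln(rho), coef ln(D), coef ln(D)^2)
DEFAULT_COEFFS = (-1.803, -0.976, 0.976, 2.673, -0.0299)


@dataclass(frozen=True)
class AllometryParams:
    wood_density: float = 0.59  # g cm^-3
    env_stress_E: float = 0.0  # dimensionless
    lata_kg: float = 11.66  # kg of fresh in-shell seed per lata
    coeffs: tuple[float, float, float, float, float] = DEFAULT_COEFFS

    def __post_init__(self) -> None:
        if self.wood_density <= 0:
            raise ValueError("wood_density must be positive")
        if self.lata_kg <= 0:
            raise ValueError("lata_kg must be positive")


def latas_to_kg(latas, params: AllometryParams = AllometryParams()):
    """Convert lata counts to kg of fresh in-shell seed (linear, exact)."""
    latas = np.asarray(latas, dtype=float)
    if np.any(latas < 0):
        raise ValueError("lata counts must be non-negative")
    out = latas * params.lata_kg
    return float(out) if out.ndim == 0 else out


def agb_from_dbh(dbh_cm, params: AllometryParams = AllometryParams()):
    """Above-ground biomass (kg) from DBH (cm), diameter-only model.

    Strictly increasing in DBH and in wood density; DBH below the 10 cm
    inventory threshold is rejected (NaN passes through as NaN, for trees
    whose diameter was not measured).
    """
    dbh = np.asarray(dbh_cm, dtype=float)
    if np.any(dbh[~np.isnan(dbh)] < 10.0):
        raise ValueError("dbh below the 10 cm inventory threshold")
    b0, bE, brho, bD, bD2 = params.coeffs
    logd = np.log(dbh)
    ln_agb = (
        b0
        + bE * params.env_stress_E
        + brho * np.log(params.wood_density)
        + bD * logd
        + bD2 * logd**2
    )
    out = np.exp(ln_agb)
    return float(out) if out.ndim == 0 else out
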