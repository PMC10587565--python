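"""Porewater unit conversions.

Four small, exactly specified conversions connect raw shipboard/lab
measurements to the concentrations used downstream:

* porosity from wet/dry sediment masses,
* dissolved methane (mM) from headspace GC mole fractions,
* total dissolved sulfide from Cline-assay (methylene blue) absorbance,
* organic C and N by difference between total and inorganic fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: Porewater density, g/cm3 (near-seawater value).
RHO_POREWATER = 1.025
#: Solid-matter (mineral grain) density, g/cm3.
RHO_SOLID = 2.34
#: Universal gas constant in L*atm/(mol*K), the unit set natural to
#: headspace volumes in mL and pressures in atm.
R_GAS_L_ATM = 0.082057
#: Headspace total pressure, atm. Vials are sparged with N2 at ambient
#: pressure, so the headspace is taken to be at 1 atm.
HEADSPACE_PRESSURE_ATM = 1.0


@dataclass
class PorositySample:
    """Wet/dry masses of a sediment plug with the densities used to convert
    mass loss to volume fractions."""

    m_w: float  # wet mass, g
    m_d: float  # dry mass, g
    rho_pw: float = RHO_POREWATER
    rho_sm: float = RHO_SOLID

    def __post_init__(self) -> None:
        if self.m_d <= 0:
            raise ValueError(f"dry mass must be positive, got {self.m_d}")
        if self.m_w < self.m_d:
            raise ValueError(
                f"wet mass ({self.m_w} g) must be >= dry mass ({self.m_d} g)"
            )
        if self.rho_pw <= 0 or self.rho_sm <= 0:
            raise ValueError("densities must be positive")


@dataclass
class HeadspaceMeasurement:
    """One headspace methane measurement with vial geometry.

    Defaults describe 4 mL of sediment equilibrated in a 60 mL serum vial
    (55 mL headspace after the fixative addition) at the in-situ temperature.
    """

    ppm: float  # headspace CH4 mole fraction x 1e-6
    porosity: float
    V_h: float = 55.0  # headspace volume, mL
    V_s: float = 4.0  # sediment volume, mL
    T: float = 295.0  # K
    R_gas: float = R_GAS_L_ATM

    def __post_init__(self) -> None:
        if self.ppm < 0:
            raise ValueError("ppm must be non-negative")
        if self.V_h <= 0 or self.V_s <= 0:
            raise ValueError("vial volumes must be positive")
        if not (0 < self.porosity < 1):
            raise ValueError(f"porosity must be in (0, 1), got {self.porosity}")


@dataclass
class ClineCalibration:
    """Linear calibration of methylene-blue absorbance at 667 nm against
    sulfide standards, with the absorbance band inside which the assay is
    linear (samples outside it must be re-diluted)."""

    slope: float  # absorbance per uM
    intercept: float = 0.0
    band: tuple[float, float] = (0.1, 0.9)

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")
        if not self.band[0] < self.band[1]:
            raise ValueError("absorbance band lower bound must be below upper")

    @classmethod
    def fit(
        cls,
        concentrations_uM: np.ndarray,
        absorbances: np.ndarray,
        band: tuple[float, float] = (0.1, 0.9),
    ) -> "ClineCalibration":
        """Ordinary least-squares fit of absorbance vs concentration on >=3
        standards."""
        conc = np.asarray(concentrations_uM, float)
        absb = np.asarray(absorbances, float)
        if conc.size < 3:
            raise ValueError("need at least 3 standards to fit a calibration")
        slope, intercept = np.polyfit(conc, absb, 1)
        return cls(slope=float(slope), intercept=float(intercept), band=band)


@dataclass
class ElementalComposition:
    """Total and inorganic C/N percentages (plus optional isotope ratios) from
    elemental-analyzer runs on acidified and unacidified splits."""

    total_c_pct: float
    inorganic_c_pct: float
    total_n_pct: float = 0.0
    inorganic_n_pct: float = 0.0
    d13c_permil: float | None = None
    d15n_permil: float | None = None

    def __post_init__(self) -> None:
        for total, inorg, label in (
            (self.total_c_pct, self.inorganic_c_pct, "carbon"),
            (self.total_n_pct, self.inorganic_n_pct, "nitrogen"),
        ):
            if inorg < 0:
                raise ValueError(f"inorganic {label} must be non-negative")
            if total < inorg:
                raise ValueError(
                    f"total {label} ({total}%) must be >= inorganic ({inorg}%)"
                )


def compute_porosity(s: PorositySample) -> float:
    """Porosity (porewater volume fraction) from wet and dry masses.

    The mass lost on drying, divided by the porewater density, is the
    porewater volume; the dry mass over the grain density is the solid
    volume::

        phi = ((m_w - m_d)/rho_pw) / (m_d/rho_sm + (m_w - m_d)/rho_pw)

    Returns a fraction in [0, 1); exactly 0 for completely dry sediment.
    """
    v_water = (s.m_w - s.m_d) / s.rho_pw
    v_solid = s.m_d / s.rho_sm
    return v_water / (v_solid + v_water)


def headspace_to_aqueous_ch4(h: HeadspaceMeasurement) -> float:
    """Dissolved methane in mM from a headspace mole fraction.

    After vigorous shaking essentially all methane partitions into the
    headspace, so the moles there (ideal gas at 1 atm) are attributed to the
    porewater volume porosity * V_s::

        CH4(aq) [mM] = ppm * V_h / (R * T * porosity * V_s * 1000)

    with V_h and V_s in mL; the factor 1000 lands the result in mM.
    Strictly linear in ppm, and inversely proportional to porosity.
    """
    return h.ppm * h.V_h / (h.R_gas * h.T * h.porosity * h.V_s * 1000.0)


def cline_sulfide(
    absorbance: float, dilution: float, cal: ClineCalibration
) -> float:
    """Total dissolved sulfide (uM) from Cline-assay absorbance at 667 nm.

    Inverts the linear calibration and multiplies by the dilution factor used
    to keep the absorbance within the assay's linear band. Absorbance outside
    the band raises (the sample must be re-diluted); a slightly negative
    back-calculated concentration (blank-level noise) is clamped to 0 with a
    warning.
    """
    lo, hi = cal.band
    if not (lo <= absorbance <= hi):
        raise ValueError(
            f"absorbance {absorbance:g} outside calibration band [{lo}, {hi}]; "
            "re-dilute the sample to bring it in range"
        )
    if dilution < 1:
        raise ValueError("dilution factor must be >= 1")
    conc = dilution * (absorbance - cal.intercept) / cal.slope
    if conc < 0:
        logger.warning(
            "back-calculated sulfide %.3g uM below blank; clamping to 0", conc
        )
        conc = 0.0
    return conc


def organic_by_difference(e: ElementalComposition) -> tuple[float, float]:
    """Organic carbon and nitrogen percentages as total minus inorganic."""
    return (
        e.total_c_pct - e.inorganic_c_pct,
        e.total_n_pct - e.inorganic_n_pct,
    )
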