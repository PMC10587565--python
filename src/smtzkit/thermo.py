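"""Gibbs-energy model of reversible hydrogenotrophic methanogenesis.

The reaction is written in bicarbonate form, the species actually measured in
porewater::

    4 H2(aq) + HCO3- + H+  ->  CH4(aq) + 3 H2O(l)

with anaerobic oxidation of methane (AOM) as its exact reverse. Because H2
enters the quotient with stoichiometry 4, dissolved hydrogen dominates the
free energy:

    dG = dG0 + R*T * ln( [CH4] / ([H2]^4 [HCO3-] [H+]) )

Activities are approximated by molar concentrations, water activity is 1, and
the standard free energies of formation are 25 degC aqueous values used
without enthalpy correction to in-situ temperature (the offset is < 3 K).

A reaction only supports microbial maintenance if it yields more than the
"biological energy quantum" (BEQ), about 10 kJ/mol. The window
(-BEQ, +BEQ) around dG = 0 is therefore a no-reaction zone: methanogenesis
runs where dG <= -BEQ, AOM where dG >= +BEQ (i.e. the reverse reaction's dG
is <= -BEQ), and in between neither direction is biologically catalyzed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

#: Gas constant in kJ/(mol*K).
R_KJ = 8.3145e-3

#: Standard Gibbs energies of formation, kJ/mol, aqueous species at 25 degC
#: (H2O as liquid), from standard compilations.
DEFAULT_DG0F: Mapping[str, float] = {
    "H2(aq)": 17.57,
    "HCO3-": -586.85,
    "H+": 0.0,
    "CH4(aq)": -34.39,
    "H2O(l)": -237.18,
}

_SPECIES = tuple(DEFAULT_DG0F)


@dataclass
class ReactionConditions:
    """Concentrations, pH, and temperature entering the reaction quotient.

    Defaults are typical organic-rich coastal porewater conditions:
    CH4 ~ 0.53 mM, HCO3- ~ 48.4 mM, T = 295 K, pH 7.8. Dissolved H2 has no
    default: it is the controlling variable.
    """

    h2_M: float
    ch4_M: float = 5.3e-4
    hco3_M: float = 4.84e-2
    pH: float = 7.8
    T: float = 295.0

    def __post_init__(self) -> None:
        for name in ("h2_M", "ch4_M", "hco3_M"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.pH < 14):
            raise ValueError(f"pH must be in (0, 14), got {self.pH}")
        if self.T <= 0:
            raise ValueError("temperature must be positive (K)")

    @property
    def h_M(self) -> float:
        """Proton concentration, mol/L, from pH."""
        return 10.0 ** (-self.pH)


@dataclass
class ThermoConstants:
    """Standard-state free energies of formation and the gas constant."""

    dG0f: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_DG0F))
    R_kJ: float = R_KJ

    def __post_init__(self) -> None:
        missing = [s for s in _SPECIES if s not in self.dG0f]
        if missing:
            raise KeyError(f"dG0f table missing species: {missing}")

    @property
    def dG0_rxn(self) -> float:
        """Standard free energy of 4 H2(aq) + HCO3- + H+ -> CH4(aq) + 3 H2O(l)."""
        g = self.dG0f
        return (g["CH4(aq)"] + 3 * g["H2O(l)"]) - (
            4 * g["H2(aq)"] + g["HCO3-"] + g["H+"]
        )


@dataclass
class EnergyWindow:
    """The +/-BEQ band around dG = 0 inside which neither reaction direction
    meets the minimum maintenance energy."""

    beq_kJ: float = 10.0

    def __post_init__(self) -> None:
        if self.beq_kJ <= 0:
            raise ValueError("biological energy quantum must be positive")


def delta_g_methanogenesis(
    c: ReactionConditions, k: ThermoConstants | None = None
) -> float:
    """Gibbs free energy (kJ/mol) of hydrogenotrophic methanogenesis.

    Strictly decreasing in [H2], with exact log-slope d(dG)/d(ln[H2]) = -4RT.
    """
    k = k or ThermoConstants()
    rt = k.R_kJ * c.T
    ln_q = np.log(c.ch4_M) - (
        4.0 * np.log(c.h2_M) + np.log(c.hco3_M) + np.log(c.h_M)
    )
    return k.dG0_rxn + rt * ln_q


def delta_g_aom(c: ReactionConditions, k: ThermoConstants | None = None) -> float:
    """Gibbs free energy (kJ/mol) of AOM, the exact reverse reaction."""
    return -delta_g_methanogenesis(c, k)


def classify_regime(dG_meth: float, w: EnergyWindow | None = None) -> str:
    """Classify conditions as ``methanogenesis``, ``no_reaction``, or ``aom``.

    Methanogenesis where its dG <= -BEQ; AOM where dG_meth >= +BEQ
    (equivalently the AOM dG <= -BEQ); otherwise no biologically catalyzed
    reaction. Boundary values exactly at +/-BEQ go to the reactive regime.
    """
    w = w or EnergyWindow()
    if not np.isfinite(dG_meth):
        raise ValueError("dG must be finite")
    if dG_meth <= -w.beq_kJ:
        return "methanogenesis"
    if dG_meth >= w.beq_kJ:
        return "aom"
    return "no_reaction"


def critical_h2(
    c: ReactionConditions,
    dG_target: float,
    k: ThermoConstants | None = None,
) -> float:
    """Dissolved H2 (mol/L) at which methanogenesis dG equals ``dG_target``.

    Closed form from the quotient:
        ln[H2] = (dG0 + RT ln([CH4]/([HCO3-][H+])) - dG_target) / (4RT)
    The H2 value of ``c`` is ignored. Strictly decreasing in the target.
    """
    k = k or ThermoConstants()
    rt = k.R_kJ * c.T
    ln_h2 = (
        k.dG0_rxn
        + rt * (np.log(c.ch4_M) - np.log(c.hco3_M) - np.log(c.h_M))
        - dG_target
    ) / (4.0 * rt)
    return float(np.exp(ln_h2))


def no_reaction_band(
    c: ReactionConditions,
    w: EnergyWindow | None = None,
    k: ThermoConstants | None = None,
) -> tuple[float, float]:
    """H2 interval (lo, hi) in mol/L over which neither direction meets the
    BEQ: dG_meth in (-BEQ, +BEQ). The lower bound is where AOM switches on,
    the upper where methanogenesis switches on."""
    w = w or EnergyWindow()
    lo = critical_h2(c, +w.beq_kJ, k)
    hi = critical_h2(c, -w.beq_kJ, k)
    return lo, hi


def sweep_h2(
    c: ReactionConditions,
    h2_range: tuple[float, float],
    n_points: int = 100,
    w: EnergyWindow | None = None,
    k: ThermoConstants | None = None,
) -> pd.DataFrame:
    """Evaluate both reaction directions over a log-spaced H2 grid.

    Returns a DataFrame with columns ``h2_nM``, ``dg_meth_kj``, ``dg_aom_kj``,
    ``regime``, ordered from low to high H2; the methanogenesis column is
    strictly decreasing, so the regime column can change at most twice, in the
    order aom -> no_reaction -> methanogenesis.
    """
    lo, hi = h2_range
    if not (0 < lo < hi):
        raise ValueError(f"need 0 < lo < hi, got ({lo}, {hi})")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    w = w or EnergyWindow()
    k = k or ThermoConstants()
    grid = np.geomspace(lo, hi, n_points)
    dg = np.array([delta_g_methanogenesis(replace(c, h2_M=h2), k) for h2 in grid])
    return pd.DataFrame(
        {
            "h2_nM": grid * 1e9,
            "dg_meth_kj": dg,
            "dg_aom_kj": -dg,
            "regime": [classify_regime(v, w) for v in dg],
        }
    )
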