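"""Physicochemical drug model: pH/chloride-dependent solubility, precipitation.

Weak bases are described by up to two basic pKa values and the intrinsic
(neutral-species) solubility S0.  Total equilibrium solubility follows the
Henderson-Hasselbalch relation

    S(pH) = S0 * (1 + 10**(pKa1 - pH) + 10**(pKa1 + pKa2 - 2 pH))

with terms present according to the number of pKas.  For hydrochloride
formers, the mono-protonated species is additionally capped by a solubility
product with chloride, [BH+][Cl-] <= Ksp: when the cap binds, the dissolved
total is re-speciated from the capped [BH+], which keeps S continuous at the
crossover and monotone non-increasing in chloride.

Supersaturation decays first-order toward the current equilibrium solubility
(no nucleation induction time); the precipitated mass re-enters the solid
pool and may re-dissolve if conditions change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["DrugSubstance", "equilibrium_solubility", "supersaturation_flux"]


@dataclass(frozen=True)
class DrugSubstance:
    """A weak-base drug.

    Parameters
    ----------
    base_pkas
        0-2 basic pKa values, sorted descending (first protonation first).
    intrinsic_solubility
        Neutral-species solubility S0 in mg/mL.
    molar_mass
        g/mol; needed to relate the molar solubility product to mass units.
    chloride_ksp
        Optional solubility product of the hydrochloride ion pair,
        [BH+][Cl-], in (mol/L)^2.
    permeation_coefficient
        Lumped filter/octanol transfer coefficient, cm/min.
    precipitation_rate
        First-order decay constant of supersaturation, 1/min.
    """

    name: str
    base_pkas: tuple[float, ...]
    intrinsic_solubility: float  # mg/mL
    molar_mass: float  # g/mol
    chloride_ksp: float | None = None  # (mol/L)^2
    permeation_coefficient: float = 0.0  # cm/min
    precipitation_rate: float = 0.0  # 1/min

    def __post_init__(self):
        object.__setattr__(self, "base_pkas", tuple(float(p) for p in self.base_pkas))
        if len(self.base_pkas) > 2:
            raise ValueError("at most two basic pKas are supported")
        if list(self.base_pkas) != sorted(self.base_pkas, reverse=True):
            raise ValueError("base_pkas must be sorted descending")
        if not self.intrinsic_solubility > 0:
            raise ValueError("intrinsic_solubility must be positive")
        if not self.molar_mass > 0:
            raise ValueError("molar_mass must be positive")
        if self.chloride_ksp is not None and not self.chloride_ksp > 0:
            raise ValueError("chloride_ksp must be positive when given")
        if self.permeation_coefficient < 0:
            raise ValueError("permeation_coefficient must be >= 0")
        if self.precipitation_rate < 0:
            raise ValueError("precipitation_rate must be >= 0")


def equilibrium_solubility(drug: DrugSubstance, ph: float, chloride_mM: float = 0.0) -> float:
    """Total equilibrium solubility (mg/mL) at ``ph`` and chloride level.

    Without a solubility product this is the Henderson-Hasselbalch total.
    With one, the mono-protonated concentration is capped at
    ``Ksp / [Cl-]`` and the other species follow from the protonation
    ratios, so the result is continuous in pH and never increases with
    chloride.
    """
    if not (0.0 <= ph <= 14.0):
        raise ValueError("ph must be in [0, 14]")
    if chloride_mM < 0:
        raise ValueError("chloride_mM must be >= 0")
    s0_molar = drug.intrinsic_solubility / drug.molar_mass  # mol/L
    # protonation ratios relative to the neutral base
    r1 = 10.0 ** (drug.base_pkas[0] - ph) if len(drug.base_pkas) >= 1 else 0.0
    r2 = 10.0 ** (drug.base_pkas[1] - ph) if len(drug.base_pkas) >= 2 else 0.0
    s_hh = s0_molar * (1.0 + r1 + r1 * r2)
    s_molar = s_hh
    if drug.chloride_ksp is not None and chloride_mM > 0.0 and r1 > 0.0:
        bh_cap = drug.chloride_ksp / (chloride_mM * 1e-3)  # mol/L
        # re-speciate from the capped mono-protonated concentration
        s_salt = bh_cap * (1.0 / r1 + 1.0 + r2)
        s_molar = min(s_hh, s_salt)
    return s_molar * drug.molar_mass


def supersaturation_flux(drug: DrugSubstance, dissolved_conc: float, solubility: float) -> float:
    """Concentration flux (mg/mL/min) from first-order precipitation.

    Returns ``-k * (C - S)`` when the dissolved concentration exceeds the
    equilibrium solubility, else 0.  The precipitated mass re-enters the
    solid pool in the transit simulator.
    """
    if dissolved_conc < 0 or solubility < 0:
        raise ValueError("concentrations must be >= 0")
    if dissolved_conc <= solubility:
        return 0.0
    return -drug.precipitation_rate * (dissolved_conc - solubility)
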