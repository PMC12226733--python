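"""Bi-ionic relative permeability ratios from reversal potentials.

For two monovalent cations (X outside, Na inside at equal concentration):

    P_X / P_Na = exp(F * (Erev_X - Erev_Na) / RT)

For a divalent (Ca) outside against a monovalent X inside, the Lewis
bi-ionic form is used:

    pCa / pX = ([X]_in / (4 [Ca]_out)) * exp(u) * (1 + exp(u)),  u = Erev F / RT

Note the trailing factor: a variant with (exp(u) - 1) circulates in print
but yields negative ratios for negative reversal potentials; it is kept
behind ``as_printed=True`` for auditability only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import PhysicalConstants

MONOVALENT_OVER_MONOVALENT = "monovalent_over_monovalent"
DIVALENT_OVER_MONOVALENT = "divalent_over_monovalent"


@dataclass(frozen=True)
class BiIonicCondition:
    """A bi-ionic recording condition (one species inside, another outside)."""

    internal_ion: str
    internal_charge: int
    internal_conc_mM: float
    external_ion: str
    external_charge: int
    external_conc_mM: float

    def __post_init__(self) -> None:
        if self.internal_conc_mM <= 0 or self.external_conc_mM <= 0:
            raise ValueError("concentrations must be positive")
        if self.internal_charge not in (1, 2) or self.external_charge not in (1, 2):
            raise ValueError("charges must be +1 or +2")


@dataclass(frozen=True)
class PermeabilityResult:
    ratio: float
    kind: str
    erev_inputs_mV: tuple[float, ...]
    condition: BiIonicCondition | None = None

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("permeability ratio must be positive")


def monovalent_ratio(
    erev_x_mV: float,
    erev_na_mV: float,
    constants: PhysicalConstants | None = None,
) -> PermeabilityResult:
    """pX/pNa from the two reversal potentials (equimolar bi-ionic conditions)."""
    constants = constants or PhysicalConstants()
    if not (math.isfinite(erev_x_mV) and math.isfinite(erev_na_mV)):
        raise ValueError("reversal potentials must be finite")
    delta_volts = (erev_x_mV - erev_na_mV) / 1000.0
    ratio = math.exp(constants.F * delta_volts / (constants.R * constants.T))
    return PermeabilityResult(
        ratio=ratio,
        kind=MONOVALENT_OVER_MONOVALENT,
        erev_inputs_mV=(erev_x_mV, erev_na_mV),
    )


def divalent_ratio(
    erev_mV: float,
    cond: BiIonicCondition,
    constants: PhysicalConstants | None = None,
    as_printed: bool = False,
) -> PermeabilityResult:
    """pCa2+/pX+ from the reversal potential of a divalent-out/monovalent-in
    bi-ionic condition.

    Default is the Lewis form with trailing factor (1 + exp(u)); the
    historically misprinted (exp(u) - 1) form is available via
    ``as_printed=True`` and will raise for ratios that come out non-positive.
    """
    constants = constants or PhysicalConstants()
    if not math.isfinite(erev_mV):
        raise ValueError("reversal potential must be finite")
    if cond.internal_charge != 1 or cond.external_charge != 2:
        raise ValueError(
            "divalent_ratio expects a monovalent internal and divalent external ion"
        )
    u = constants.F * (erev_mV / 1000.0) / (constants.R * constants.T)
    prefactor = cond.internal_conc_mM / (4.0 * cond.external_conc_mM)
    trailing = (math.exp(u) - 1.0) if as_printed else (1.0 + math.exp(u))
    ratio = prefactor * math.exp(u) * trailing
    return PermeabilityResult(
        ratio=ratio,
        kind=DIVALENT_OVER_MONOVALENT,
        erev_inputs_mV=(erev_mV,),
        condition=cond,
    )
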