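"""Physical constants for electrodiffusion calculations."""

from dataclasses import dataclass

FARADAY = 96485.33
"""Faraday constant, C/mol."""

GAS_CONSTANT = 8.314463
"""Molar gas constant, J/(K*mol)."""

DEFAULT_TEMPERATURE_K = 294.0
"""Ambient recording temperature, K (~21 degrees C)."""


@dataclass(frozen=True)
class PhysicalConstants:
    """Bundle of F, R and T used by every Nernst/GHK-type expression.

    Attributes
    ----------
    F : float
        Faraday constant in C/mol.
    R : float
        Gas constant in J/(K*mol).
    T : float
        Absolute temperature in K; must be positive.
    """

    F: float = FARADAY
    R: float = GAS_CONSTANT
    T: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError(f"temperature must be positive, got {self.T} K")

    @property
    def rt_over_f_mV(self) -> float:
        """Thermal voltage RT/F in millivolts (~25.3 mV at 294 K)."""
        return 1000.0 * self.R * self.T / self.F
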