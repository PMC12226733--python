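"""In-memory containers for I-V and G-V series with explicit normalization state.

Voltages are in mV, currents in pA, conductances in nS (pA/mV) unless a
normalization has been applied, in which case the normalization mode and the
reference value are carried along so downstream comparisons can check
compatibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

RAW = "raw"
TO_MAX = "to_max"
TO_ANCHOR_VOLTAGE = "to_anchor_voltage"
TO_CURRENT_AT_ANCHOR = "to_current_at_anchor"


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise ValueError("series data must be one-dimensional")
    return a


@dataclass
class IVSeries:
    """Peak current versus command voltage for one ionic condition.

    Invariants: equal lengths >= 4 and strictly increasing voltages.
    """

    voltages: np.ndarray
    currents: np.ndarray
    condition: dict = field(default_factory=dict)
    normalization: str = RAW
    anchor_mV: float | None = None

    def __post_init__(self) -> None:
        self.voltages = _as_array(self.voltages)
        self.currents = _as_array(self.currents)
        if len(self.voltages) != len(self.currents):
            raise ValueError("voltages and currents must have equal length")
        if len(self.voltages) < 4:
            raise ValueError("an I-V series needs at least 4 points")
        if not np.all(np.diff(self.voltages) > 0):
            raise ValueError("voltages must be strictly increasing")

    def __len__(self) -> int:
        return len(self.voltages)

    def normalize_to_anchor(self, anchor_mV: float) -> "IVSeries":
        """Normalize currents to the absolute current at the anchor voltage."""
        ref = float(np.interp(anchor_mV, self.voltages, self.currents))
        if ref == 0.0:
            raise ValueError(f"current at anchor {anchor_mV} mV is zero")
        return IVSeries(
            self.voltages.copy(),
            self.currents / abs(ref),
            condition=dict(self.condition),
            normalization=TO_CURRENT_AT_ANCHOR,
            anchor_mV=anchor_mV,
        )

    def to_frame(self) -> pd.DataFrame:
        unit = "pA" if self.normalization == RAW else "norm"
        return pd.DataFrame(
            {"voltage_mV": self.voltages, f"current_{unit}": self.currents}
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "IVSeries":
        df = pd.read_csv(path, sep="\t")
        vcol = [c for c in df.columns if c.startswith("voltage")][0]
        icol = [c for c in df.columns if c.startswith("current")][0]
        return cls(df[vcol].to_numpy(), df[icol].to_numpy(), **kwargs)


@dataclass
class GVSeries:
    """Conductance versus voltage, derived from an I-V series.

    ``excluded`` marks voltages too close to the reversal potential for
    G = I/(V - Vrev) to be meaningful; they are flagged, never dropped.
    """

    voltages: np.ndarray
    conductance: np.ndarray
    vrev_used: float = 0.0
    normalization: str = RAW
    anchor_mV: float | None = None
    reference_value: float | None = None
    excluded: np.ndarray | None = None
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voltages = _as_array(self.voltages)
        self.conductance = _as_array(self.conductance)
        if len(self.voltages) != len(self.conductance):
            raise ValueError("voltages and conductance must have equal length")
        if self.excluded is None:
            self.excluded = np.zeros(len(self.voltages), dtype=bool)
        else:
            self.excluded = np.asarray(self.excluded, dtype=bool)
        retained = self.conductance[~self.excluded]
        if retained.size and not np.all(np.isfinite(retained)):
            raise ValueError("conductance must be finite at all retained voltages")

    def __len__(self) -> int:
        return len(self.voltages)

    @property
    def retained_voltages(self) -> np.ndarray:
        return self.voltages[~self.excluded]

    @property
    def retained_conductance(self) -> np.ndarray:
        return self.conductance[~self.excluded]

    def to_frame(self) -> pd.DataFrame:
        unit = "nS" if self.normalization == RAW else "norm"
        return pd.DataFrame(
            {
                "voltage_mV": self.voltages,
                f"conductance_{unit}": self.conductance,
                "excluded": self.excluded.astype(int),
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "GVSeries":
        df = pd.read_csv(path, sep="\t")
        vcol = [c for c in df.columns if c.startswith("voltage")][0]
        gcol = [c for c in df.columns if c.startswith("conductance")][0]
        excl = df["excluded"].to_numpy(bool) if "excluded" in df.columns else None
        return cls(df[vcol].to_numpy(), df[gcol].to_numpy(), excluded=excl, **kwargs)
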