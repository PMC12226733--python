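"""Dose-response (Hill, inhibition, biphasic) and recovery-kinetics fitting.

All dose fits operate on log10(concentration) internally; midpoints are
reported in the units of the input table (the unit tag rides along). Zero
concentration rows (ligand-alone controls) are legal for the inhibition and
biphasic models, where the prediction at c = 0 is exactly 1, and are dropped
with a note for the activation model.

Recovery from desensitization is fitted with the decaying single exponential
y = 1 + A * exp(-x/tau), A <= 0, so the paired-pulse ratio rises from 1 + A
at zero interval toward 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._fitting import CurveFitResults, FitError, solve_least_squares

ACTIVATION = "activation"
INHIBITION = "inhibition"

# response ranges flatter than this are unidentifiable for any dose model
MIN_RESPONSE_RANGE = 0.05


@dataclass
class DoseTable:
    """Normalized peak responses at a set of ligand concentrations."""

    concentrations: np.ndarray
    responses: np.ndarray
    ligand: str = ""
    direction: str = ACTIVATION
    unit: str = "mM"

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if len(self.concentrations) != len(self.responses):
            raise ValueError("concentrations and responses must match in length")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses must be finite")
        if self.direction not in (ACTIVATION, INHIBITION):
            raise ValueError(f"unknown direction {self.direction!r}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kwargs) -> "DoseTable":
        kwargs.setdefault("unit", df.attrs.get("unit", "mM"))
        kwargs.setdefault("ligand", df.attrs.get("ligand", ""))
        return cls(df["conc"].to_numpy(), df["response"].to_numpy(), **kwargs)


def hill_curve(conc, ec50: float, p: float) -> np.ndarray:
    """Monophasic activation: y = 1 / (1 + (EC50/c)^p)."""
    c = np.asarray(conc, dtype=float)
    with np.errstate(divide="ignore"):
        return np.where(c > 0, 1.0 / (1.0 + (ec50 / np.where(c > 0, c, 1.0)) ** p), 0.0)


def inhibition_curve(conc, ic50: float, p: float) -> np.ndarray:
    """Monophasic inhibition: y = 1 - Hill = 1 / (1 + (c/IC50)^p)."""
    c = np.asarray(conc, dtype=float)
    return 1.0 / (1.0 + (c / ic50) ** p)


def biphasic_curve(
    conc, stim_amplitude: float, ec50_s: float, slope_s: float, ic50_i: float, slope_i: float
) -> np.ndarray:
    """One stimulatory and one inhibitory Hill phase, multiplied.

    y(c) = (1 + a * c^ps/(EC50^ps + c^ps)) * (1 - c^pi/(IC50^pi + c^pi)).
    At c = 0 the response is exactly 1 (the ligand-alone control); with
    a > 0 the response transiently exceeds 1 before the inhibitory phase
    takes over.
    """
    c = np.asarray(conc, dtype=float)
    stim = 1.0 + stim_amplitude * c**slope_s / (ec50_s**slope_s + c**slope_s)
    inhib = 1.0 - c**slope_i / (ic50_i**slope_i + c**slope_i)
    return stim * inhib


class HillFitResults(CurveFitResults):
    model_name = "Hill dose-response"

    @property
    def ec50(self) -> float:
        return self.params.get("ec50", self.params.get("ic50"))


class BiphasicFitResults(CurveFitResults):
    model_name = "Biphasic dose-response (stimulatory x inhibitory)"


class RecoveryFitResults(CurveFitResults):
    model_name = "Recovery from desensitization (single exponential)"

    def predict(self, intervals_ms):
        p = self.params
        return 1.0 + p["A"] * np.exp(-np.asarray(intervals_ms, float) / p["tau"])


def _check_range(y: np.ndarray, what: str) -> str | None:
    if float(np.max(y) - np.min(y)) < MIN_RESPONSE_RANGE:
        return f"flat response: no {what} detectable"
    return None


class HillModel:
    """Monophasic activation dose-response model."""

    def __init__(self, table: DoseTable) -> None:
        if table.direction != ACTIVATION:
            raise FitError("HillModel expects an activation table; use InhibitionModel")
        keep = table.concentrations > 0
        self.c = table.concentrations[keep]
        self.y = table.responses[keep]
        self.unit = table.unit
        if len(self.c) < 4:
            raise FitError("need at least 4 nonzero-concentration points")

    def fit(self) -> HillFitResults:
        c, y = self.c, self.y
        logc = np.log10(c)
        yc = np.clip(y, 0.05, 0.95)
        x0 = [float(np.interp(0.5, yc, logc)), 1.0]

        def residuals(x):
            log_ec50, p = x
            return hill_curve(c, 10.0**log_ec50, p) - y

        sol, bse_int = solve_least_squares(
            residuals, x0, ([logc.min() - 4, 0.05], [logc.max() + 4, 10.0]), len(c)
        )
        ec50 = float(10.0 ** sol.x[0])
        rms = float(np.sqrt(np.mean(residuals(sol.x) ** 2)))
        flat = _check_range(y, "activation")
        return HillFitResults(
            params={"ec50": ec50, "p": float(sol.x[1])},
            bse={"ec50": ec50 * np.log(10.0) * float(bse_int[0]), "p": float(bse_int[1])},
            residual_rms=rms,
            converged=bool(sol.success) and flat is None,
            message=flat or sol.message,
            nobs=len(c),
            extra={"unit": self.unit},
        )


class InhibitionModel:
    """Monophasic inhibition dose-response model (reports IC50)."""

    def __init__(self, table: DoseTable) -> None:
        if table.direction != INHIBITION:
            raise FitError("InhibitionModel expects an inhibition table")
        self.c = table.concentrations
        self.y = table.responses
        self.unit = table.unit
        if np.count_nonzero(self.c > 0) < 4:
            raise FitError("need at least 4 nonzero-concentration points")

    def fit(self) -> HillFitResults:
        c, y = self.c, self.y
        pos = c > 0
        logc = np.log10(c[pos])
        x0 = [float(np.median(logc)), 1.0]

        def residuals(x):
            log_ic50, p = x
            return inhibition_curve(c, 10.0**log_ic50, p) - y

        sol, bse_int = solve_least_squares(
            residuals, x0, ([logc.min() - 4, 0.05], [logc.max() + 4, 10.0]), len(c)
        )
        ic50 = float(10.0 ** sol.x[0])
        rms = float(np.sqrt(np.mean(residuals(sol.x) ** 2)))
        flat = _check_range(y, "block")
        return HillFitResults(
            params={"ic50": ic50, "p": float(sol.x[1])},
            bse={"ic50": ic50 * np.log(10.0) * float(bse_int[0]), "p": float(bse_int[1])},
            residual_rms=rms,
            converged=bool(sol.success) and flat is None,
            message=flat or sol.message,
            nobs=len(c),
            extra={"unit": self.unit},
        )


class BiphasicModel:
    """Biphasic dose-response: a stimulatory phase followed by block.

    ``fix_stim_amplitude=0`` collapses the model to pure inhibition
    (nested-model consistency with :class:`InhibitionModel`).
    """

    def __init__(self, table: DoseTable, fix_stim_amplitude: float | None = None) -> None:
        self.c = table.concentrations
        self.y = table.responses
        self.unit = table.unit
        self.fix_a = fix_stim_amplitude
        if np.count_nonzero(self.c > 0) < 6:
            raise FitError("need at least 6 nonzero-concentration points spanning both phases")

    def fit(self) -> BiphasicFitResults:
        c, y = self.c, self.y
        pos = c > 0
        logc = np.log10(c[pos])
        a0 = max(float(np.max(y)) - 1.0, 0.05)
        i_max = int(np.argmax(y))
        ec0 = float(np.log10(c[i_max])) if c[i_max] > 0 else float(logc.min())
        below = np.where(y < 0.5)[0]
        ic0 = float(np.log10(c[below[0]])) if below.size and c[below[0]] > 0 else float(np.median(logc))

        if self.fix_a is not None:
            a_lo, a_hi, a0 = self.fix_a, self.fix_a + 1e-12, self.fix_a
        else:
            a_lo, a_hi = 0.0, 10.0

        def residuals(x):
            a, log_ec, ps, log_ic, pi = x
            return biphasic_curve(c, a, 10.0**log_ec, ps, 10.0**log_ic, pi) - y

        sol, bse_int = solve_least_squares(
            residuals,
            [a0, ec0, 1.2, ic0, 1.2],
            ([a_lo, logc.min() - 4, 0.1, logc.min() - 4, 0.1],
             [a_hi, logc.max() + 4, 10.0, logc.max() + 4, 10.0]),
            len(c),
        )
        a, log_ec, ps, log_ic, pi = sol.x
        ec50_s, ic50_i = float(10.0**log_ec), float(10.0**log_ic)
        rms = float(np.sqrt(np.mean(residuals(sol.x) ** 2)))
        flat = _check_range(y, "dose dependence")
        message = flat or sol.message
        if self.fix_a is None and a < 1e-3:
            message += "; stimulatory phase not detected (amplitude ~ 0), single-phase fallback"
        return BiphasicFitResults(
            params={
                "stim_amplitude": float(a),
                "ec50_s": ec50_s,
                "slope_s": float(ps),
                "ic50_i": ic50_i,
                "slope_i": float(pi),
            },
            bse={
                "stim_amplitude": float(bse_int[0]),
                "ec50_s": ec50_s * np.log(10.0) * float(bse_int[1]),
                "slope_s": float(bse_int[2]),
                "ic50_i": ic50_i * np.log(10.0) * float(bse_int[3]),
                "slope_i": float(bse_int[4]),
            },
            residual_rms=rms,
            converged=bool(sol.success) and flat is None,
            message=message,
            nobs=len(c),
            extra={"unit": self.unit},
        )


class RecoveryModel:
    """Single-exponential recovery from desensitization."""

    def __init__(self, intervals_ms, ratios) -> None:
        self.x = np.asarray(intervals_ms, dtype=float)
        self.y = np.asarray(ratios, dtype=float)
        if len(self.x) < 4:
            raise FitError("need at least 4 paired-pulse intervals")
        if np.any(self.x < 0):
            raise ValueError("intervals must be >= 0")
        if np.any((self.y < -0.1) | (self.y > 1.2)):
            raise ValueError("recovery ratios outside the plausible (-0.1, 1.2) range")

    def fit(self) -> RecoveryFitResults:
        x, y = self.x, self.y

        def residuals(p):
            A, tau = p
            return 1.0 + A * np.exp(-x / tau) - y

        a0 = float(np.clip(np.min(y) - 1.0, -1.0, -0.05))
        tau0 = float(np.median(x[x > 0])) if np.any(x > 0) else 100.0
        sol, bse_int = solve_least_squares(
            residuals, [a0, tau0], ([-1.5, 1e-6], [0.5, np.inf]), len(x)
        )
        A, tau = sol.x
        rms = float(np.sqrt(np.mean(residuals(sol.x) ** 2)))
        converged = bool(sol.success)
        message = sol.message
        if abs(A) < 0.02:
            converged = False
            message = "amplitude ~ 0: already recovered at all intervals, tau unidentifiable"
        return RecoveryFitResults(
            params={"A": float(A), "tau": float(tau)},
            bse={"A": float(bse_int[0]), "tau": float(bse_int[1])},
            residual_rms=rms,
            converged=converged,
            message=message,
            nobs=len(x),
        )


def fit_hill(table: DoseTable) -> HillFitResults:
    """Fit a monophasic activation Hill curve; reports EC50 and slope."""
    return HillModel(table).fit()


def fit_inhibition(table: DoseTable) -> HillFitResults:
    """Fit a monophasic inhibition curve; reports IC50 and slope."""
    return InhibitionModel(table).fit()


def fit_biphasic(table: DoseTable, fix_stim_amplitude: float | None = None) -> BiphasicFitResults:
    """Fit the biphasic (stimulatory x inhibitory) dose-response."""
    return BiphasicModel(table, fix_stim_amplitude=fix_stim_amplitude).fit()


def fit_recovery(intervals_ms, ratios) -> RecoveryFitResults:
    """Fit y = 1 + A*exp(-x/tau) to paired-pulse recovery data."""
    return RecoveryModel(intervals_ms, ratios).fit()
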