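"""The single permeant blocker model of voltage-dependent polyamine block.

At equilibrium, a channel blocked by a permeant cation (spermine) has

    G(V) = Gmax / (1 + [Spm] / Kd(V)),
    Kd(V) = g * exp(V/h) + L * exp(V/k),

where g = k_off/k_on and L = k_perm/k_on at 0 mV (exit-rate over binding-rate
ratios; the individual rate constants are not identifiable from equilibrium
G-V data and are never reported separately), and h < 0, k > 0 are the
voltage dependencies of block onset and block relief. Kd(0 mV) = g + L.

Block-free channels (e.g. +4-site alanine mutants) show an intrinsic
exponential G-V instead: G = 1 + (G0 - 1) * exp(V/Vc).

:class:`PermeantBlockerModel` and :class:`IntrinsicGVModel` follow the
model/fit/results idiom; :func:`fit_blocker` and :func:`fit_intrinsic` are
thin functional wrappers.
"""

from __future__ import annotations

import numpy as np

from ._fitting import CurveFitResults, FitError, solve_least_squares
from .series import GVSeries, RAW

__all__ = [
    "kd_of_v",
    "predict_g",
    "PermeantBlockerModel",
    "PermeantBlockerResults",
    "IntrinsicGVModel",
    "IntrinsicFitResults",
    "fit_blocker",
    "fit_intrinsic",
    "FitError",
]

# data shallower than this (relative depth of the G-V dip) is treated as
# block-free: the blocker parameters are unidentifiable and fitting refuses
MIN_BLOCK_DEPTH = 0.02


def kd_of_v(g: float, h: float, L: float, k: float, v_mV) -> np.ndarray | float:
    """Kd(V) = g*exp(V/h) + L*exp(V/k), in the units of g and L (uM)."""
    v = np.asarray(v_mV, dtype=float)
    out = g * np.exp(v / h) + L * np.exp(v / k)
    return out if np.ndim(v_mV) else float(out)


def predict_g(
    gmax: float, g: float, h: float, L: float, k: float, v_mV, spm_uM: float
) -> np.ndarray | float:
    """Conductance predicted by the single permeant blocker model."""
    if spm_uM < 0:
        raise ValueError("spermine concentration must be >= 0")
    kd = kd_of_v(g, h, L, k, np.asarray(v_mV, dtype=float))
    out = gmax / (1.0 + spm_uM / kd)
    return out if np.ndim(v_mV) else float(out)


class PermeantBlockerResults(CurveFitResults):
    """Estimates of {Gmax, g, h, L, k} with Kd(0 mV) = g + L."""

    model_name = "Single permeant blocker model"

    @property
    def kd0(self) -> float:
        """Dissociation constant for the blocker at 0 mV, uM."""
        return self.params["g"] + self.params["L"]

    def predict(self, v_mV):
        p = self.params
        return predict_g(p["gmax"], p["g"], p["h"], p["L"], p["k"], v_mV, self.extra["spm_uM"])


class PermeantBlockerModel:
    """Least-squares fit of a G-V series to the single permeant blocker model.

    Parameters
    ----------
    gv : GVSeries
        Conductance-voltage data (normalized or raw; the normalization state
        is recorded in the results).
    spm_uM : float
        Internal blocker concentration. Fixed, never fitted: doubling [Spm]
        and doubling (g, L) together leaves G unchanged, so a free [Spm]
        would be perfectly confounded with the affinity parameters.
    window : (float, float), optional
        Voltage window (mV); points outside are excluded from the objective.
    weights : array, optional
        Per-point weights (default unweighted).

    Notes
    -----
    Optimization runs in log-space for g and L (positivity) with sign bounds
    h < 0 < k. Initialization takes Kd(0) from the conductance nearest 0 mV
    via Kd = [Spm]*G/(Gmax - G), split 85:15 between g and L, with
    h0 = -20 mV and k0 = +30 mV. On normalized data Gmax is fitted within
    [0.8, 1.2] by default; pass ``fix_gmax`` to pin it.
    """

    def __init__(
        self,
        gv: GVSeries,
        spm_uM: float,
        window: tuple[float, float] | None = None,
        weights=None,
        fix_gmax: float | None = None,
    ) -> None:
        if spm_uM <= 0:
            raise FitError(
                "blocker fit requires [Spm] > 0; block-free data cannot "
                "constrain the blocker parameters"
            )
        keep = ~gv.excluded
        if window is not None:
            keep &= (gv.voltages >= window[0]) & (gv.voltages <= window[1])
        self.v = gv.voltages[keep]
        self.g_obs = gv.conductance[keep]
        if len(self.v) < 6:
            raise FitError("need at least 6 points in the fitting window")
        self.spm_uM = float(spm_uM)
        self.window = window
        self.weights = np.ones_like(self.v) if weights is None else np.asarray(weights, float)[keep]
        self.normalized = gv.normalization != RAW
        self.fix_gmax = fix_gmax

    def fit(self, init: dict | None = None) -> PermeantBlockerResults:
        v, g_obs, w = self.v, self.g_obs, self.weights
        gmax0 = float(np.max(g_obs))
        i0 = int(np.argmin(np.abs(v)))
        g_at0 = float(np.clip(g_obs[i0], 1e-9, 0.999 * gmax0))
        kd0_init = self.spm_uM * g_at0 / max(gmax0 - g_at0, 1e-9 * gmax0)
        kd0_init = float(np.clip(kd0_init, 1e-6, 1e6))

        defaults = {
            "gmax": gmax0,
            "g": 0.85 * kd0_init,
            "h": -20.0,
            "L": 0.15 * kd0_init,
            "k": 30.0,
        }
        if init:
            defaults.update(init)

        if self.fix_gmax is not None:
            gmax_lo, gmax_hi = self.fix_gmax - 1e-12, self.fix_gmax + 1e-12
            defaults["gmax"] = self.fix_gmax
        elif self.normalized:
            gmax_lo, gmax_hi = 0.8, 1.2
            defaults["gmax"] = float(np.clip(defaults["gmax"], 0.8, 1.2))
        else:
            gmax_lo, gmax_hi = 1e-12, np.inf

        x0 = [
            defaults["gmax"],
            np.log(max(defaults["g"], 1e-12)),
            defaults["h"],
            np.log(max(defaults["L"], 1e-12)),
            defaults["k"],
        ]
        lower = [gmax_lo, -30.0, -500.0, -30.0, 1e-3]
        upper = [gmax_hi, 30.0, -1e-3, 30.0, 500.0]
        x0 = np.clip(x0, lower, upper)
        spm = self.spm_uM

        def residuals(x):
            gmax, logg, h, logL, k = x
            pred = predict_g(gmax, np.exp(logg), h, np.exp(logL), k, v, spm)
            return w * (pred - g_obs)

        sol, bse_int = solve_least_squares(residuals, x0, (lower, upper), len(v))
        gmax, logg, h, logL, k = sol.x
        g_hat, L_hat = float(np.exp(logg)), float(np.exp(logL))
        params = {"gmax": float(gmax), "g": g_hat, "h": float(h), "L": L_hat, "k": float(k)}
        # delta method for the log-space parameters
        bse = {
            "gmax": float(bse_int[0]),
            "g": g_hat * float(bse_int[1]),
            "h": float(bse_int[2]),
            "L": L_hat * float(bse_int[3]),
            "k": float(bse_int[4]),
        }
        rms = float(np.sqrt(np.mean((residuals(sol.x) / w) ** 2)))

        depth = 1.0 - float(np.min(g_obs)) / max(float(np.max(g_obs)), 1e-12)
        converged = bool(sol.success)
        message = sol.message
        if depth < MIN_BLOCK_DEPTH:
            converged = False
            message = (
                "no detectable block: G-V relative depth "
                f"{depth:.3g} < {MIN_BLOCK_DEPTH}; parameters unidentifiable"
            )

        # correlation of the g and L estimates (split identifiability check)
        try:
            jtj = sol.jac.T @ sol.jac
            cov = np.linalg.pinv(jtj)
            corr_gL = float(cov[1, 3] / np.sqrt(cov[1, 1] * cov[3, 3]))
        except (np.linalg.LinAlgError, FloatingPointError, ZeroDivisionError):
            corr_gL = float("nan")

        return PermeantBlockerResults(
            params=params,
            bse=bse,
            residual_rms=rms,
            converged=converged,
            message=message,
            nobs=len(v),
            extra={
                "kd0_uM": params["g"] + params["L"],
                "spm_uM": spm,
                "window": self.window,
                "normalization_recorded": self.normalized,
                "corr_g_L": corr_gL,
                "block_depth": depth,
            },
        )


class IntrinsicFitResults(CurveFitResults):
    """Estimates of {g0, vc} of the intrinsic exponential G-V."""

    model_name = "Intrinsic exponential G-V"

    def predict(self, v_mV):
        p = self.params
        return 1.0 + (p["g0"] - 1.0) * np.exp(np.asarray(v_mV, float) / p["vc"])


class IntrinsicGVModel:
    """Fit G = 1 + (G0 - 1) * exp(V/Vc) to a normalized block-free G-V.

    Reports both the fitted G0 and the empirically observed minimum
    conductance (``g_min_observed`` in the extras), which are distinct
    quantities for noisy data.
    """

    def __init__(self, gv: GVSeries, window: tuple[float, float] | None = None) -> None:
        keep = ~gv.excluded
        if window is not None:
            keep &= (gv.voltages >= window[0]) & (gv.voltages <= window[1])
        self.v = gv.voltages[keep]
        self.g_obs = gv.conductance[keep]
        if len(self.v) < 4:
            raise FitError("need at least 4 points")

    def fit(self, init: dict | None = None) -> IntrinsicFitResults:
        v, g_obs = self.v, self.g_obs
        span = float(np.max(g_obs) - np.min(g_obs))
        if span < 1e-9 * max(1.0, float(np.max(np.abs(g_obs)))):
            # constant conductance: G0 is the constant, Vc unidentifiable
            g0 = float(np.mean(g_obs))
            return IntrinsicFitResults(
                params={"g0": g0, "vc": float("nan")},
                bse={"g0": 0.0, "vc": float("nan")},
                residual_rms=float(np.std(g_obs)),
                converged=False,
                message="Vc unidentifiable: conductance is constant",
                nobs=len(v),
                extra={"g_min_observed": float(np.min(g_obs))},
            )

        defaults = {"g0": float(np.min(g_obs)), "vc": -60.0}
        if init:
            defaults.update(init)

        def residuals(x):
            g0, vc = x
            return 1.0 + (g0 - 1.0) * np.exp(v / vc) - g_obs

        best = None
        for vc0 in (defaults["vc"], -defaults["vc"]):
            sol, bse_int = solve_least_squares(
                residuals, [defaults["g0"], vc0], ([-np.inf, -np.inf], [np.inf, np.inf]), len(v)
            )
            if best is None or sol.cost < best[0].cost:
                best = (sol, bse_int)
        sol, bse_int = best
        g0, vc = sol.x
        rms = float(np.sqrt(np.mean(residuals(sol.x) ** 2)))
        return IntrinsicFitResults(
            params={"g0": float(g0), "vc": float(vc)},
            bse={"g0": float(bse_int[0]), "vc": float(bse_int[1])},
            residual_rms=rms,
            converged=bool(sol.success),
            message=sol.message,
            nobs=len(v),
            extra={"g_min_observed": float(np.min(g_obs))},
        )


def fit_blocker(
    gv: GVSeries,
    spm_uM: float,
    window: tuple[float, float] | None = None,
    init: dict | None = None,
    **kwargs,
) -> PermeantBlockerResults:
    """Functional wrapper: fit the single permeant blocker model to a G-V."""
    return PermeantBlockerModel(gv, spm_uM, window=window, **kwargs).fit(init=init)


def fit_intrinsic(gv: GVSeries, window: tuple[float, float] | None = None) -> IntrinsicFitResults:
    """Functional wrapper: fit the intrinsic exponential G-V."""
    return IntrinsicGVModel(gv, window=window).fit()
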