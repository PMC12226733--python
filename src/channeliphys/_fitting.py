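"""Shared nonlinear least-squares plumbing for the model/results classes."""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares


class FitError(RuntimeError):
    """Raised when a fit cannot be attempted or did not converge."""


class CurveFitResults:
    """Common results surface: params, standard errors, diagnostics, summary().

    Parameters are stored under their public names. Standard errors come from
    the Gauss-Newton covariance (J^T J)^-1 * s^2 at the solution; entries are
    NaN when the Jacobian is rank deficient (unidentifiable parameters).
    """

    model_name = "curve fit"

    def __init__(
        self,
        params: dict[str, float],
        bse: dict[str, float],
        residual_rms: float,
        converged: bool,
        message: str,
        nobs: int,
        extra: dict | None = None,
    ) -> None:
        self.params = params
        self.bse = bse
        self.residual_rms = residual_rms
        self.converged = converged
        self.message = message
        self.nobs = nobs
        self.extra = extra or {}

    def __getattr__(self, name: str):
        try:
            return self.__dict__["params"][name]
        except KeyError:
            raise AttributeError(name) from None

    def summary(self) -> str:
        lines = [
            f"{self.model_name}",
            "=" * 58,
            f"No. observations: {self.nobs}",
            f"Residual RMS:     {self.residual_rms:.6g}",
            f"Converged:        {self.converged} ({self.message})",
            "-" * 58,
            f"{'parameter':<16}{'estimate':>16}{'std err':>16}",
            "-" * 58,
        ]
        for name, value in self.params.items():
            se = self.bse.get(name, float("nan"))
            lines.append(f"{name:<16}{value:>16.6g}{se:>16.4g}")
        for name, value in self.extra.items():
            if isinstance(value, (int, float)) and not isinstance(value, bool):
                lines.append(f"{name:<16}{value:>16.6g}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def __repr__(self) -> str:
        pars = ", ".join(f"{k}={v:.4g}" for k, v in self.params.items())
        return f"<{type(self).__name__} {pars}, converged={self.converged}>"


def solve_least_squares(residual_fn, x0, bounds, nobs: int):
    """Run scipy least_squares at tight tolerances; return (sol, bse_internal).

    ``bse_internal`` are standard errors of the *internal* parameter vector;
    callers transform them to the public scale (delta method for log-space
    parameters).
    """
    sol = least_squares(
        residual_fn,
        x0=np.asarray(x0, dtype=float),
        bounds=bounds,
        method="trf",
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
        max_nfev=20000,
    )
    dof = max(nobs - len(sol.x), 1)
    s2 = 2.0 * sol.cost / dof
    try:
        jtj = sol.jac.T @ sol.jac
        cov = np.linalg.pinv(jtj) * s2
        bse = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        bse = np.full(len(sol.x), np.nan)
    return sol, bse
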