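"""Reversal-potential estimation and conductance-voltage analysis.

The reversal potential is estimated by fitting a degree-9 polynomial to the
I-V relationship and taking the real root bracketed by the empirical sign
change. Conductance is then G = I/(V - Vrev), with a guard band around the
reversal potential where the quotient is numerically meaningless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import (
    GVSeries,
    IVSeries,
    RAW,
    TO_ANCHOR_VOLTAGE,
    TO_MAX,
)

DEFAULT_DEGREE = 9
DEFAULT_EXCLUSION_HALFWIDTH_MV = 2.5


@dataclass
class ReversalEstimate:
    """Result of polynomial reversal-potential estimation."""

    erev: float  # mV
    polynomial_degree: int
    window: tuple[float, float]  # mV
    residual_rms: float
    degree_reduced: bool = False

    def __repr__(self) -> str:  # short, log-friendly
        return (
            f"ReversalEstimate(erev={self.erev:.3f} mV, degree="
            f"{self.polynomial_degree}, rms={self.residual_rms:.3g})"
        )


def _sign_change_brackets(v: np.ndarray, i: np.ndarray) -> list[tuple[float, float, float]]:
    """(v_lo, v_hi, v_linear) for every adjacent pair where current changes sign."""
    out = []
    for a in range(len(v) - 1):
        ia, ib = i[a], i[a + 1]
        if ia == 0.0:
            out.append((v[a], v[a], v[a]))
        elif ia * ib < 0:
            vlin = v[a] - ia * (v[a + 1] - v[a]) / (ib - ia)
            out.append((v[a], v[a + 1], vlin))
    if len(v) and i[-1] == 0.0:
        out.append((v[-1], v[-1], v[-1]))
    return out


def estimate_reversal(
    iv: IVSeries,
    degree: int = DEFAULT_DEGREE,
    window: tuple[float, float] | None = None,
) -> ReversalEstimate:
    """Estimate the reversal potential from an I-V series.

    A polynomial of the requested degree (default 9) is fit to the series
    after rescaling voltages to [-1, 1] for conditioning; among its real
    roots inside the data range, the one bracketed by the empirical sign
    change of the current is returned, ties broken by proximity to the
    linear-interpolation zero crossing. With fewer than ``degree + 2``
    points the degree is reduced to ``n - 2`` (recorded in diagnostics).

    Raises
    ------
    ValueError
        If the current never changes sign in the window ("no reversal in
        range") -- e.g. strongly rectifying series.
    """
    v, i = iv.voltages, iv.currents
    if window is not None:
        keep = (v >= window[0]) & (v <= window[1])
        v, i = v[keep], i[keep]
    if len(v) < 4:
        raise ValueError("need at least 4 points in the fitting window")
    win = (float(v[0]), float(v[-1]))

    brackets = _sign_change_brackets(v, i)
    if not brackets:
        raise ValueError("no reversal in range: current does not change sign")

    degree_reduced = False
    if len(v) < degree + 2:
        degree = len(v) - 2
        degree_reduced = True

    # Polynomial.fit maps the voltage domain to [-1, 1] internally.
    poly = np.polynomial.Polynomial.fit(v, i, deg=degree)
    residual_rms = float(np.sqrt(np.mean((poly(v) - i) ** 2)))
    roots = poly.roots()
    real_roots = np.real(roots[np.abs(np.imag(roots)) < 1e-8 * max(1.0, np.max(np.abs(np.real(roots))))])
    real_roots = real_roots[(real_roots >= v[0]) & (real_roots <= v[-1])]

    erev = None
    for lo, hi, vlin in brackets:
        inside = real_roots[(real_roots >= lo - 1e-9) & (real_roots <= hi + 1e-9)]
        if inside.size:
            erev = float(inside[np.argmin(np.abs(inside - vlin))])
            break
    if erev is None:
        # fall back to the linear-interpolation crossing of the first bracket
        erev = float(brackets[0][2])

    return ReversalEstimate(
        erev=erev,
        polynomial_degree=degree,
        window=win,
        residual_rms=residual_rms,
        degree_reduced=degree_reduced,
    )


def compute_conductance(
    iv: IVSeries,
    erev: float,
    exclusion_halfwidth: float = DEFAULT_EXCLUSION_HALFWIDTH_MV,
) -> GVSeries:
    """Convert an I-V series to conductance, G = I/(V - Vrev).

    Voltages within ``exclusion_halfwidth`` of the reversal potential are
    flagged as excluded (the quotient is 0/0 there), not silently dropped.
    With pA and mV inputs the conductance is in nS.
    """
    if not np.isfinite(erev):
        raise ValueError("erev must be finite")
    v, i = iv.voltages, iv.currents
    excluded = np.abs(v - erev) <= exclusion_halfwidth
    if excluded.all():
        raise ValueError("all voltages fall inside the exclusion band around erev")
    denom = v - erev
    g = np.where(excluded, np.nan, i / np.where(excluded, 1.0, denom))
    return GVSeries(
        v.copy(),
        g,
        vrev_used=float(erev),
        excluded=excluded,
        condition=dict(iv.condition),
    )


def normalize_gv(gv: GVSeries, mode: str, anchor: float | None = None) -> GVSeries:
    """Normalize a G-V series to its maximum or to the value at an anchor voltage."""
    if mode == TO_MAX:
        ref = float(np.nanmax(np.abs(gv.retained_conductance)))
    elif mode == TO_ANCHOR_VOLTAGE:
        if anchor is None:
            raise ValueError("anchor voltage required for to_anchor_voltage")
        ref = float(
            np.interp(anchor, gv.retained_voltages, gv.retained_conductance)
        )
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if ref == 0.0:
        raise ValueError("normalization reference value is zero")
    return GVSeries(
        gv.voltages.copy(),
        gv.conductance / abs(ref),
        vrev_used=gv.vrev_used,
        normalization=mode,
        anchor_mV=anchor,
        reference_value=ref,
        excluded=gv.excluded.copy(),
        condition=dict(gv.condition),
    )


def conductance_difference_at_zero(gv_variant: GVSeries, gv_reference: GVSeries) -> float:
    """Percent difference in normalized conductance at V = 0 mV.

    Returns 100 * (G_variant(0) - G_reference(0)); negative values mean the
    variant conducts less at 0 mV (more block) than the reference. Both
    series must carry the same normalization mode; 0 mV is linearly
    interpolated if absent from the grid.
    """
    if gv_variant.normalization == RAW or gv_reference.normalization == RAW:
        raise ValueError("both series must be normalized before comparison")
    if gv_variant.normalization != gv_reference.normalization:
        raise ValueError(
            "incompatible normalization modes: "
            f"{gv_variant.normalization} vs {gv_reference.normalization}"
        )
    g0 = []
    for gv in (gv_variant, gv_reference):
        v, g = gv.retained_voltages, gv.retained_conductance
        if not (v.min() <= 0.0 <= v.max()):
            raise ValueError("0 mV outside the retained voltage range")
        g0.append(float(np.interp(0.0, v, g)))
    return 100.0 * (g0[0] - g0[1])
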