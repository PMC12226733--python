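"""Quick-look figures for series and fit results (matplotlib)."""

from __future__ import annotations

import numpy as np


def plot_iv(iv, ax=None, **kwargs):
    """Plot an I-V series with a zero-current reference line."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    ax.axhline(0.0, color="0.7", lw=0.8)
    ax.plot(iv.voltages, iv.currents, "o-", **kwargs)
    ax.set_xlabel("voltage (mV)")
    ax.set_ylabel("current (pA)" if iv.normalization == "raw" else "normalized current")
    return ax


def plot_gv_fit(gv, results=None, ax=None, **kwargs):
    """Plot a G-V series and, if given, a fitted curve on a fine grid."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    ax.plot(gv.retained_voltages, gv.retained_conductance, "o", **kwargs)
    if results is not None and hasattr(results, "predict"):
        fine = np.linspace(gv.voltages.min(), gv.voltages.max(), 200)
        ax.plot(fine, results.predict(fine), "-", color="c")
    ax.set_xlabel("voltage (mV)")
    ax.set_ylabel("conductance (nS)" if gv.normalization == "raw" else "normalized conductance")
    return ax
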