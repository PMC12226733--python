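"""Seeded generators for every input modality the analysis pipeline consumes.

Each generator evaluates a closed-form model of the underlying biophysics
(GHK electrodiffusion, the single permeant blocker model, Hill activation,
mono-exponential recovery) at the requested sample points, adds seeded
Gaussian noise scaled to the maximum absolute noise-free signal, and records
the generating truth in the output metadata so that downstream fitters can be
tested for parameter recovery.

With ``additive_sd = 0`` the outputs agree with the closed forms to machine
precision; with the same seed and parameters they are bit-identical between
runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .constants import PhysicalConstants
from .series import IVSeries, GVSeries


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise, sd expressed as a fraction of max |signal|."""

    additive_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.additive_sd < 0:
            raise ValueError("additive_sd must be >= 0")

    def apply(self, signal: np.ndarray) -> np.ndarray:
        if self.additive_sd == 0.0:
            return np.asarray(signal, dtype=float)
        rng = np.random.default_rng(self.seed)
        scale = self.additive_sd * np.max(np.abs(signal))
        return signal + rng.normal(0.0, scale, size=np.shape(signal))


@dataclass(frozen=True)
class BlockerTruth:
    """Ground-truth parameters of the single permeant blocker model.

    Kd(V) = g*exp(V/h) + L*exp(V/k); G(V) = gmax / (1 + spm/Kd(V)).
    Sign convention: h < 0 (block onset with depolarization), k > 0
    (relief of block by permeation at strong depolarization).
    """

    gmax: float = 1.0  # nS, or 1.0 on the normalized scale
    g: float = 10.0  # uM
    h: float = -18.5  # mV
    L: float = 1.4  # uM
    k: float = 36.5  # mV
    spm: float = 30.0  # uM internal spermine
    vrev: float = 0.0  # mV

    def __post_init__(self) -> None:
        if self.gmax <= 0:
            raise ValueError("gmax must be positive")
        if self.g < 0 or self.L < 0:
            raise ValueError("g and L must be non-negative")
        if self.h >= 0:
            raise ValueError("h must be negative (block onset convention)")
        if self.k <= 0:
            raise ValueError("k must be positive (block relief convention)")
        if self.spm < 0:
            raise ValueError("spermine concentration must be >= 0")

    @property
    def kd0(self) -> float:
        """Dissociation constant at 0 mV, uM (= g + L)."""
        return self.g + self.L

    def kd(self, v_mV) -> np.ndarray:
        v = np.asarray(v_mV, dtype=float)
        return self.g * np.exp(v / self.h) + self.L * np.exp(v / self.k)

    def conductance(self, v_mV) -> np.ndarray:
        return self.gmax / (1.0 + self.spm / self.kd(v_mV))


@dataclass(frozen=True)
class Ion:
    name: str
    charge: int
    conc_in: float  # mM
    conc_out: float  # mM
    permeability: float = 1.0  # relative

    def __post_init__(self) -> None:
        if self.charge not in (1, 2):
            raise ValueError("only +1 and +2 cations are supported")
        if self.conc_in < 0 or self.conc_out < 0:
            raise ValueError("concentrations must be >= 0")
        if self.permeability < 0:
            raise ValueError("permeability must be >= 0")


@dataclass(frozen=True)
class GHKCondition:
    """Ionic condition for GHK current generation (bi-ionic or richer)."""

    ions: tuple[Ion, ...]
    temperature_K: float = 294.0

    def __post_init__(self) -> None:
        if not self.ions:
            raise ValueError("at least one ion is required")
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")
        if not any(i.conc_in > 0 and i.permeability > 0 for i in self.ions):
            raise ValueError("need a permeant ion on the internal side")
        if not any(i.conc_out > 0 and i.permeability > 0 for i in self.ions):
            raise ValueError("need a permeant ion on the external side")

    @property
    def constants(self) -> PhysicalConstants:
        return PhysicalConstants(T=self.temperature_K)


def ghk_current(cond: GHKCondition, v_mV, gain_pA: float = 100.0) -> np.ndarray:
    """Net GHK (constant-field) current summed over ions, in pA.

    Each ion contributes P * z^2 * u * ([C]_in - [C]_out e^(-z u)) /
    (1 - e^(-z u)) with u = F V / RT; the z = 2 form for divalents matches
    the 4*[Ca] factor of the divalent bi-ionic permeability equation.
    ``gain_pA`` is an arbitrary overall scale (relative permeabilities carry
    no absolute units) chosen to give currents of realistic magnitude.
    """
    v = np.atleast_1d(np.asarray(v_mV, dtype=float))
    u = v / cond.constants.rt_over_f_mV  # dimensionless FV/RT
    total = np.zeros_like(v)
    for ion in cond.ions:
        zu = ion.charge * u
        # (zu) / (1 - exp(-zu)) with a series guard at zu ~ 0
        small = np.abs(zu) < 1e-8
        ratio = np.where(small, 1.0 + zu / 2.0, zu / (1.0 - np.exp(-np.where(small, 1.0, zu))))
        flux = ion.permeability * ion.charge * (
            ion.conc_in - ion.conc_out * np.exp(-zu)
        ) * ratio
        total = total + flux
    out = gain_pA * total / 1000.0
    return out if np.ndim(v_mV) else float(out[0])


def gen_iv_ghk(
    cond: GHKCondition, voltages, noise: NoiseModel | None = None, gain_pA: float = 100.0
) -> IVSeries:
    """Generate a GHK-shaped I-V family for one ionic condition."""
    noise = noise or NoiseModel()
    v = np.asarray(voltages, dtype=float)
    if v.size == 0:
        raise ValueError("voltages must be non-empty")
    if not np.all(np.diff(v) > 0):
        raise ValueError("voltages must be strictly increasing")
    clean = ghk_current(cond, v, gain_pA=gain_pA)
    meta = {
        "model": "ghk",
        "ions": [asdict(i) for i in cond.ions],
        "temperature_K": cond.temperature_K,
        "noise": asdict(noise),
    }
    return IVSeries(v, noise.apply(clean), condition=meta)


def gen_gv_blocker(
    truth: BlockerTruth, voltages, noise: NoiseModel | None = None
) -> tuple[GVSeries, IVSeries]:
    """Generate a G-V family shaped by the single permeant blocker model.

    Returns the G-V series and the corresponding I-V series via
    I = G * (V - vrev). Noise is applied to the conductance; the I-V is
    derived from the noisy conductance so the pair stays self-consistent.
    """
    noise = noise or NoiseModel()
    v = np.asarray(voltages, dtype=float)
    if v.size == 0:
        raise ValueError("voltages must be non-empty")
    if np.any(np.abs(v) > 200):
        raise ValueError("voltages must lie within +/-200 mV")
    g_clean = truth.conductance(v)
    g_noisy = noise.apply(g_clean)
    meta = {"model": "permeant_blocker", "truth": asdict(truth), "noise": asdict(noise)}
    gv = GVSeries(v, g_noisy, vrev_used=truth.vrev, condition=meta)
    iv = IVSeries(v, g_noisy * (v - truth.vrev), condition=meta)
    return gv, iv


def hill_response(conc, ec50: float, hill_p: float) -> np.ndarray:
    """Normalized Hill activation 1 / (1 + (EC50/c)^p), on the linear scale."""
    c = np.asarray(conc, dtype=float)
    return 1.0 / (1.0 + (ec50 / c) ** hill_p)


def gen_dose_response(
    ec50: float, hill_p: float, concs, noise: NoiseModel | None = None,
    ligand: str = "glycine", unit: str = "mM",
) -> pd.DataFrame:
    """Generate a normalized activation dose-response table."""
    noise = noise or NoiseModel()
    c = np.asarray(concs, dtype=float)
    if ec50 <= 0:
        raise ValueError("ec50 must be positive")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    y = noise.apply(hill_response(c, ec50, hill_p))
    df = pd.DataFrame({"conc": c, "response": y})
    df.attrs["truth"] = {"ec50": ec50, "hill_p": hill_p, "noise": asdict(noise)}
    df.attrs["ligand"] = ligand
    df.attrs["unit"] = unit
    return df


def recovery_ratio(intervals, tau: float, amplitude: float = -0.9) -> np.ndarray:
    """Paired-pulse recovery ratio 1 + A*exp(-x/tau), A in [-1, 0]."""
    x = np.asarray(intervals, dtype=float)
    return 1.0 + amplitude * np.exp(-x / tau)


def gen_recovery(
    tau: float, intervals, noise: NoiseModel | None = None, amplitude: float = -0.9
) -> pd.DataFrame:
    """Generate a desensitization-recovery table (interval ms, ratio)."""
    noise = noise or NoiseModel()
    if tau <= 0:
        raise ValueError("tau must be positive")
    if not -1.0 <= amplitude <= 0.0:
        raise ValueError("amplitude must lie in [-1, 0]")
    x = np.asarray(intervals, dtype=float)
    y = noise.apply(recovery_ratio(x, tau, amplitude))
    df = pd.DataFrame({"interval_ms": x, "ratio": y})
    df.attrs["truth"] = {"tau": tau, "amplitude": amplitude, "noise": asdict(noise)}
    return df


DEFAULT_VOLTAGE_GRID = np.arange(-100.0, 101.0, 10.0)
"""Default command-voltage grid: -100 to +100 mV in 10 mV steps."""


def gen_alignment_fixture(
    site_spec: dict[int, str],
    seed: int = 0,
    divergence: float = 0.1,
    query_id: str = "query",
):
    """Generate a (reference, query) FASTA pair with planted site residues.

    The query is a diverged copy of the bundled GluA2-numbered reference:
    background positions are substituted at the given ``divergence`` rate
    (annotated sites and a +/-3 residue neighborhood are protected so the
    alignment stays anchored), then the residues of ``site_spec`` are
    planted. A value of ``"-"`` plants a deletion at that position.

    Returns ``(records, truth)`` where ``records`` is a two-element list of
    Bio.SeqRecord (reference first) and ``truth`` echoes the planted spec.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    from .reference import AMINO_ACIDS, GLUA2_SITES, glua2_reference

    ref = glua2_reference()
    for pos, aa in site_spec.items():
        if not 1 <= pos <= len(ref):
            raise ValueError(f"position {pos} outside reference length {len(ref)}")
        if aa != "-" and (len(aa) != 1 or aa.upper() not in AMINO_ACIDS):
            raise ValueError(f"invalid planted residue {aa!r} at position {pos}")

    protected: set[int] = set()
    flat_positions = [
        *GLUA2_SITES["backbone"],
        *GLUA2_SITES["sidechain"],
        GLUA2_SITES["qrn"],
        GLUA2_SITES["plus4"],
        GLUA2_SITES["lurcher"],
        *GLUA2_SITES["siteG"],
        *range(GLUA2_SITES["m3_motif_start"], GLUA2_SITES["m3_motif_start"] + 9),
        *site_spec,
    ]
    for pos in flat_positions:
        protected.update(range(pos - 3, pos + 4))

    rng = np.random.default_rng(seed)
    query = list(ref)
    for i in range(len(query)):
        if (i + 1) in protected:
            continue
        if rng.random() < divergence:
            query[i] = AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS))]
    for pos, aa in site_spec.items():
        query[pos - 1] = aa.upper() if aa != "-" else "-"
    query_seq = "".join(q for q in query if q != "-")

    records = [
        SeqRecord(Seq(ref), id="GluA2_ref_synthetic", description="synthetic mature GluA2 stand-in"),
        SeqRecord(Seq(query_seq), id=query_id, description="diverged query with planted sites"),
    ]
    truth = {"site_spec": dict(site_spec), "seed": seed, "divergence": divergence}
    return records, truth
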