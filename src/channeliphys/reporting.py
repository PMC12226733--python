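"""Pipeline configuration, execution, and report assembly.

:class:`RunConfig` validates all stage parameters up front (pydantic);
:func:`run_pipeline` executes the stages in dependency order
(simulate -> reversal -> conductance -> fits -> permeability -> sites) on
synthetic inputs with known truths, and returns a JSON-serializable report
embedding the fully resolved configuration, the package version, and every
seed, so any run is replayable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .blocker import FitError, fit_blocker, fit_intrinsic
from .constants import PhysicalConstants
from .dose import DoseTable, fit_hill, fit_recovery
from .iv_gv import compute_conductance, estimate_reversal, normalize_gv
from .permeability import BiIonicCondition, divalent_ratio
from .series import TO_MAX
from .synthetic import (
    BlockerTruth,
    GHKCondition,
    Ion,
    NoiseModel,
    gen_dose_response,
    gen_gv_blocker,
    gen_iv_ghk,
    gen_recovery,
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


class RunConfig(BaseModel):
    """Validated stage parameters with recording-condition defaults.

    Defaults reflect the standard excised-patch protocol: T = 294 K,
    30 uM internal spermine, command voltages -100..+100 mV in 10 mV steps.
    """

    temperature_K: float = Field(294.0, gt=0)
    spm_uM: float = Field(30.0, ge=0)
    v_min_mV: float = -100.0
    v_max_mV: float = 100.0
    v_step_mV: float = Field(10.0, gt=0)
    noise_sd: float = Field(0.0, ge=0)
    seed: int = Field(0, ge=0)
    normalization: str = TO_MAX
    fit_window_mV: tuple[float, float] | None = None
    erev_exclusion_mV: float = Field(2.5, ge=0)
    # single permeant blocker generating truth (wildtype-like defaults)
    truth_gmax: float = Field(1.0, gt=0)
    truth_g_uM: float = Field(10.0, ge=0)
    truth_h_mV: float = Field(-18.5, lt=0)
    truth_L_uM: float = Field(1.4, ge=0)
    truth_k_mV: float = Field(36.5, gt=0)
    # dose-response and recovery generating truths
    dose_ec50_mM: float = Field(0.11, gt=0)
    dose_hill_p: float = Field(1.5, gt=0)
    recovery_tau_ms: float = Field(184.0, gt=0)
    # divalent bi-ionic worked inputs: {label: (erev_mV, Xin_mM, Caout_mM)}
    biionic_divalent: dict[str, tuple[float, float, float]] = {
        "K_in:Ca_out": (-59.2, 100.0, 4.0),
        "Cs_in:Ca_out": (-46.9, 100.0, 4.0),
    }

    @model_validator(mode="after")
    def _check_grid(self) -> "RunConfig":
        if self.v_min_mV >= self.v_max_mV:
            raise ValueError("v_min_mV must be below v_max_mV")
        return self

    @property
    def voltages(self) -> np.ndarray:
        return np.arange(self.v_min_mV, self.v_max_mV + self.v_step_mV / 2, self.v_step_mV)


def _stage(name: str):
    def decorate(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return wrapped

    return decorate


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run all stages on synthetic inputs; optionally write TSV/JSON outputs.

    Returns the report dict. When ``out_dir`` is given, each stage's table
    is written as TSV, the report as ``report.json``, and a ``MANIFEST.tsv``
    lists every file produced (partial outputs are retained on failure).
    """
    report: dict = {
        "config": json.loads(config.model_dump_json()),
        "package_version": __version__,
        "stages": {},
    }
    manifest: list[str] = []
    outputs: dict[str, pd.DataFrame] = {}

    def finalize():
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            for name, df in outputs.items():
                path = out / f"{name}.tsv"
                df.to_csv(path, sep="\t", index=False)
                manifest.append(path.name)
            with open(out / "report.json", "w") as fh:
                json.dump(report, fh, indent=2, default=float)
            manifest.append("report.json")
            pd.DataFrame({"file": manifest}).to_csv(out / "MANIFEST.tsv", sep="\t", index=False)

    try:
        _run_stages(config, report, outputs)
    finally:
        finalize()
    return report


def _run_stages(config: RunConfig, report: dict, outputs: dict) -> None:
    noise = NoiseModel(additive_sd=config.noise_sd, seed=config.seed)
    volts = config.voltages

    @_stage("simulate")
    def simulate():
        cond = GHKCondition(
            ions=(Ion("Na", 1, 150.0, 150.0, 1.0),), temperature_K=config.temperature_K
        )
        iv_ghk = gen_iv_ghk(cond, volts, noise)
        truth = BlockerTruth(
            gmax=config.truth_gmax,
            g=config.truth_g_uM,
            h=config.truth_h_mV,
            L=config.truth_L_uM,
            k=config.truth_k_mV,
            spm=config.spm_uM,
        )
        gv, iv_blk = gen_gv_blocker(truth, volts, noise)
        concs = np.logspace(-2, 1, 8) * config.dose_ec50_mM / 0.11
        dose = gen_dose_response(config.dose_ec50_mM, config.dose_hill_p, concs, noise)
        intervals = np.geomspace(25, 2000, 10)
        recovery = gen_recovery(config.recovery_tau_ms, intervals, noise)
        outputs["iv_ghk"] = iv_ghk.to_frame()
        outputs["iv_blocker"] = iv_blk.to_frame()
        outputs["dose"] = dose
        outputs["recovery"] = recovery
        report["stages"]["simulate"] = {
            "seed": config.seed,
            "noise_sd": config.noise_sd,
            "blocker_truth_kd0_uM": truth.kd0,
        }
        return iv_ghk, iv_blk, truth, dose, recovery

    iv_ghk, iv_blk, truth, dose, recovery = simulate()

    @_stage("reversal")
    def reversal():
        est = estimate_reversal(iv_ghk)
        report["stages"]["reversal"] = {
            "erev_mV": est.erev,
            "degree": est.polynomial_degree,
            "residual_rms": est.residual_rms,
        }
        return est

    est = reversal()

    @_stage("conductance")
    def conductance():
        gv = compute_conductance(iv_blk, truth.vrev, config.erev_exclusion_mV)
        gv_norm = normalize_gv(gv, config.normalization, anchor=config.v_min_mV)
        outputs["gv_normalized"] = gv_norm.to_frame()
        report["stages"]["conductance"] = {
            "vrev_used_mV": truth.vrev,
            "normalization": config.normalization,
            "n_excluded": int(gv.excluded.sum()),
        }
        return gv_norm

    gv_norm = conductance()

    @_stage("blocker_fit")
    def blocker_fit():
        if config.spm_uM <= 0:
            res = fit_intrinsic(gv_norm)
            report["stages"]["blocker_fit"] = {
                "refusal": "block-free data ([Spm] = 0): fitted intrinsic "
                "exponential G-V instead of the blocker model",
                "g0": res.params["g0"],
                "vc_mV": res.params["vc"],
                "converged": res.converged,
            }
            return res
        res = fit_blocker(gv_norm, config.spm_uM, window=config.fit_window_mV)
        report["stages"]["blocker_fit"] = {
            "kd0_uM": res.kd0,
            "h_mV": res.params["h"],
            "k_mV": res.params["k"],
            "gmax": res.params["gmax"],
            "converged": res.converged,
            "message": res.message,
        }
        return res

    blocker_fit()

    @_stage("dose_kinetics")
    def dose_kinetics():
        hill = fit_hill(DoseTable.from_frame(dose))
        rec = fit_recovery(recovery["interval_ms"], recovery["ratio"])
        report["stages"]["dose_kinetics"] = {
            "ec50_mM": hill.params["ec50"],
            "hill_p": hill.params["p"],
            "tau_ms": rec.params["tau"],
            "amplitude": rec.params["A"],
        }

    dose_kinetics()

    @_stage("permeability")
    def permeability():
        constants = PhysicalConstants(T=config.temperature_K)
        ratios = {}
        for label, (erev, xin, caout) in config.biionic_divalent.items():
            ion = label.split("_")[0]
            cond = BiIonicCondition(ion, 1, xin, "Ca", 2, caout)
            ratios[label] = divalent_ratio(erev, cond, constants).ratio
        report["stages"]["permeability"] = {
            "erev_sym_Na_mV": est.erev,
            "pCa_over_pX": ratios,
        }

    permeability()

    @_stage("sites")
    def sites_stage():
        from .sites import extract_sites, map_to_reference, predict_ligand
        from .synthetic import gen_alignment_fixture

        records, _ = gen_alignment_fixture(
            {653: "S", 655: "I", 732: "F", 607: "S", 611: "D"},
            seed=config.seed,
            query_id="GluE1aA_like",
        )
        refmap = map_to_reference(str(records[1].seq), query_id=records[1].id)
        profile = extract_sites(refmap, str(records[1].seq))
        pred = predict_ligand(profile)
        report["stages"]["sites"] = {
            "query": records[1].id,
            "qrn": profile.qrn,
            "plus4": profile.plus4,
            "prediction": pred.label,
            "warnings": pred.warnings,
        }

    sites_stage()


def make_table1_report(fits: list[tuple[str, object, int]]) -> pd.DataFrame:
    """Assemble an equilibrium-block summary table from fit results.

    ``fits`` is a list of (receptor_name, results, n_patches) where results
    is a :class:`~channeliphys.blocker.PermeantBlockerResults` or, for
    block-free receptors fitted with the intrinsic exponential, an
    :class:`~channeliphys.blocker.IntrinsicFitResults` (rendered as "-").
    """
    if not fits:
        raise ValueError("need at least one fit")
    rows = []
    for name, res, n in fits:
        if hasattr(res, "kd0"):
            rows.append(
                {
                    "receptor": name,
                    "Kd(0mV)_uM": round(res.kd0, 2),
                    "h_mV": round(res.params["h"], 2),
                    "k_mV": round(res.params["k"], 2),
                    "n": n,
                }
            )
        else:
            rows.append({"receptor": name, "Kd(0mV)_uM": "-", "h_mV": "-", "k_mV": "-", "n": n})
    return pd.DataFrame(rows)
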