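"""End-to-end orchestration: generate → derive → calibrate → quantify →
purity, with deterministic seeding and a machine-readable run manifest.

Stages
------
1. *Zero crossings*: pure-component concentration series are generated
   for both analytes and each component's crossing is located; the NIC
   crossing quantifies ASC and vice versa.
2. *Calibration*: a mixed-standard series is generated, differentiated,
   read at the two crossings and fitted by OLS (with LOD/LOQ).
3. *Validation*: random in-range mixtures are quantified and recovery /
   intraday–interday precision statistics computed.
4. *Purity*: either a measured batch table (CSV) or simulated bulk
   cocrystal samples are pushed through quantification and the 1:1
   stoichiometric mass balance.

Every stage draws its noise from an independent child of the master seed,
so the full run is reproducible and individual stages are insensitive to
changes in the others' draw counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import CalibrationCurve, ZeroCrossing, find_zero_crossing, fit_calibration
from .config import PipelineConfig
from .exceptions import InputError
from .purity import BatchMeasurement, PurityReport, batch_table_report
from .quantify import RecoveryRecord, precision_summary, quantify_mixture
from .synth import gen_calibration_set, gen_cocrystal_sample, gen_mixture_spectrum, gen_pure_spectrum

logger = logging.getLogger("fodspec")

__all__ = ["RunReport", "run_full_pipeline", "read_batches_csv", "quantify_cocrystal_sample"]


@dataclass
class RunReport:
    """Everything a full pipeline run produced, plus its manifest."""

    crossings: dict[str, ZeroCrossing]
    curves: dict[str, CalibrationCurve]
    calibration_table: pd.DataFrame
    validation: pd.DataFrame
    precision: dict[str, dict]
    purity: PurityReport | None
    manifest: dict


def _stage_seed(master: int, stage: int) -> int:
    """Independent per-stage seed below 2**31."""
    ss = np.random.SeedSequence(master, spawn_key=(stage,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def read_batches_csv(path) -> list[BatchMeasurement]:
    """Read a measured batch table: batch_id,source,m_collected_mg,m_asc_mg,m_nic_mg."""
    # ids like "GAS#9" contain '#', so only whole comment lines are dropped
    import io

    text = "\n".join(
        ln for ln in Path(path).read_text(encoding="utf-8").splitlines()
        if not ln.lstrip().startswith("#")
    )
    df = pd.read_csv(io.StringIO(text))
    required = {"batch_id", "source", "m_collected_mg", "m_asc_mg", "m_nic_mg"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"batch table {path} missing columns {sorted(missing)}")
    return [
        BatchMeasurement(
            batch_id=str(r.batch_id), source=str(r.source),
            m_collected_mg=float(r.m_collected_mg),
            m_asc_total_mg=float(r.m_asc_mg), m_nic_total_mg=float(r.m_nic_mg),
        )
        for r in df.itertuples()
    ]


def quantify_cocrystal_sample(
    spectrum, curve_asc, curve_nic, config: PipelineConfig,
    m_collected_mg: float, batch_id: str = "sample", source: str = "FODS",
) -> BatchMeasurement:
    """Quantify a dissolved bulk sample and convert concentrations back to
    component masses through the dilution chain."""
    q = quantify_mixture(spectrum, curve_asc, curve_nic, deriv=config.deriv_params())
    factor = config.cocrystal_secondary_dilution * config.cocrystal_dilution_ml / 1000.0
    return BatchMeasurement(
        batch_id=batch_id, source=source, m_collected_mg=m_collected_mg,
        m_asc_total_mg=q.conc_asc * factor, m_nic_total_mg=q.conc_nic * factor,
    )


def _file_sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_pipeline(
    config: PipelineConfig,
    batches: list[BatchMeasurement] | None = None,
    write_outputs: bool = True,
) -> RunReport:
    """Execute every stage under one config and master seed.

    ``batches`` overrides the config's batch CSV; an explicitly empty list
    skips the purity stage with a logged notice. Reports are written to
    ``config.outdir`` when ``write_outputs`` is true, along with
    ``manifest.json`` carrying versions, the seed, the config hash and a
    SHA-256 digest of every written report.
    """
    grid = config.grid()
    models = config.models()
    asc_model, nic_model = models
    deriv = config.deriv_params()
    outdir = Path(config.outdir)

    # -- stage 1: zero crossings ------------------------------------------
    logger.info("stage zero-crossing: pure series at %s", config.pure_series_levels)
    noise_pure = config.noise_model(_stage_seed(config.seed, 0))
    rng = noise_pure.rng()
    asc_series = [
        gen_pure_spectrum(asc_model, c, noise=noise_pure, grid=grid, rng=rng)
        for c in config.pure_series_levels
    ]
    nic_series = [
        gen_pure_spectrum(nic_model, c, noise=noise_pure, grid=grid, rng=rng)
        for c in config.pure_series_levels
    ]
    zc_nic = find_zero_crossing(
        nic_series, tuple(config.zc_search_nic_nm), deriv,
        interfering="NIC", analyte="ASC",
    )
    zc_asc = find_zero_crossing(
        asc_series, tuple(config.zc_search_asc_nm), deriv,
        interfering="ASC", analyte="NIC",
    )
    crossings = {"ASC": zc_nic, "NIC": zc_asc}  # keyed by quantified analyte
    logger.info("crossings: ASC @ %d nm, NIC @ %d nm",
                zc_nic.wavelength_nm, zc_asc.wavelength_nm)

    # -- stage 2: calibration ---------------------------------------------
    noise_cal = config.noise_model(_stage_seed(config.seed, 1))
    cal_set = gen_calibration_set(config.calibration_levels, models, noise_cal, grid)
    cal_rows = []
    amps: dict[str, list[tuple[float, float]]] = {"ASC": [], "NIC": []}
    from .spectra import differentiate_with

    for sp in cal_set:
        d = differentiate_with(sp, deriv, order=1)
        for analyte, zc in crossings.items():
            conc = float(sp.meta[f"true_conc_{analyte.lower()}_ug_ml"])
            amp = float(d.values[d.index_of(zc.wavelength_nm)])
            amps[analyte].append((conc, amp))
            cal_rows.append(
                {"analyte": analyte, "wavelength_nm": zc.wavelength_nm,
                 "conc_ug_per_ml": conc, "amplitude": amp}
            )
    curves = {
        analyte: fit_calibration(
            pairs, analyte, crossings[analyte].wavelength_nm,
            config.lod_multiplier, config.loq_multiplier,
        )
        for analyte, pairs in amps.items()
    }
    calibration_table = pd.DataFrame(cal_rows)
    for analyte, curve in curves.items():
        logger.info("calibration %s: a=%.4e, R2=%.5f, LOD=%.3g, LOQ=%.3g",
                    analyte, curve.slope_a, curve.r_squared, curve.lod, curve.loq)

    # -- stage 3: validation ----------------------------------------------
    noise_val = config.noise_model(_stage_seed(config.seed, 2))
    rng_val = noise_val.rng()
    lo, hi = curves["ASC"].conc_range
    val_rows = []
    intraday: dict[str, list[RecoveryRecord]] = {"ASC": [], "NIC": []}
    for i in range(config.n_validation_mixtures):
        c_asc, c_nic = rng_val.uniform(lo, hi, size=2)
        sp = gen_mixture_spectrum(c_asc, c_nic, models, noise_val, grid, rng=rng_val)
        q = quantify_mixture(sp, curves["ASC"], curves["NIC"], deriv)
        for analyte, truth, found, amp in (
            ("ASC", c_asc, q.conc_asc, q.amplitude_asc),
            ("NIC", c_nic, q.conc_nic, q.amplitude_nic),
        ):
            rec = RecoveryRecord(analyte, truth, found)
            intraday[analyte].append(rec)
            val_rows.append(
                {"sample": f"mix{i + 1}", "analyte": analyte,
                 "amplitude": amp,
                 "conc_theoretical_ug_ml": round(truth, config.round_conc_decimals),
                 "conc_found_ug_ml": round(found, config.round_conc_decimals),
                 "recovery_pct": round(rec.recovery_pct, config.round_recovery_decimals),
                 "flags": ";".join(q.flags)}
            )
    # interday: the same mid-range mixture on independent "days"
    noise_inter = config.noise_model(_stage_seed(config.seed, 3))
    rng_inter = noise_inter.rng()
    interday: dict[str, list[RecoveryRecord]] = {"ASC": [], "NIC": []}
    for i in range(config.interday_replicates):
        sp = gen_mixture_spectrum(7.2, 2.4, models, noise_inter, grid, rng=rng_inter)
        q = quantify_mixture(sp, curves["ASC"], curves["NIC"], deriv)
        interday["ASC"].append(RecoveryRecord("ASC", 7.2, q.conc_asc))
        interday["NIC"].append(RecoveryRecord("NIC", 2.4, q.conc_nic))
    precision = {}
    for analyte in ("ASC", "NIC"):
        s_intra = precision_summary(intraday[analyte], "intraday")
        s_inter = precision_summary(interday[analyte], "interday")
        precision[analyte] = {
            "intraday": dataclasses.asdict(s_intra),
            "interday": dataclasses.asdict(s_inter),
        }
    validation = pd.DataFrame(val_rows)

    # -- stage 4: purity ----------------------------------------------------
    if batches is None and config.batches_csv:
        batches = read_batches_csv(config.batches_csv)
    purity_report: PurityReport | None = None
    if batches is not None and len(batches) == 0:
        logger.info("purity stage skipped: empty batch table")
    else:
        if batches is None:
            noise_cc = config.noise_model(_stage_seed(config.seed, 4))
            rng_cc = noise_cc.rng()
            batches = []
            for k, p in enumerate(config.cocrystal_sim_purities):
                sp, truth = gen_cocrystal_sample(
                    m_collected_mg=config.cocrystal_sample_mass_mg,
                    true_purity_frac=p, models=models,
                    dilution_ml=config.cocrystal_dilution_ml,
                    secondary_dilution_factor=config.cocrystal_secondary_dilution,
                    noise=noise_cc, grid=grid, rng=rng_cc,
                )
                batches.append(
                    quantify_cocrystal_sample(
                        sp, curves["ASC"], curves["NIC"], config,
                        m_collected_mg=truth.m_collected_mg,
                        batch_id=f"SIM#{k + 1}",
                    )
                )
        purity_report = batch_table_report(batches, config.stoichiometry())

    # -- manifest and outputs ----------------------------------------------
    manifest = {
        "package": "fodspec",
        "version": __version__,
        "numpy": np.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "zero_crossings": {k: dataclasses.asdict(v) for k, v in crossings.items()},
        "calibration": {k: v.to_dict() for k, v in curves.items()},
        "precision": precision,
        "outputs": {},
    }
    report = RunReport(
        crossings=crossings, curves=curves, calibration_table=calibration_table,
        validation=validation, precision=precision, purity=purity_report,
        manifest=manifest,
    )
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)
        calibration_table.to_csv(outdir / "calibration_table.csv", index=False)
        (outdir / "calibration.json").write_text(
            json.dumps({k: v.to_dict() for k, v in curves.items()}, indent=2)
        )
        validation.to_csv(outdir / "validation.csv", index=False)
        if purity_report is not None:
            purity_report.purity.to_csv(outdir / "purity.csv", index=False)
            purity_report.agreement.to_csv(outdir / "purity_agreement.csv", index=False)
        for f in sorted(outdir.glob("*.csv")) + [outdir / "calibration.json"]:
            manifest["outputs"][f.name] = _file_sha256(f)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        logger.info("reports written to %s", outdir)
    return report
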