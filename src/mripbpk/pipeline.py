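"""End-to-end pipeline driver: simulate a cohort, fit the DCE curves, fit the
population covariate models on the non-binding arm, predict the binding arm a
priori and evaluate — each stage writing CSV outputs plus a JSON manifest."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig, write_manifest
from .covariate import FitResult, fit_population, predict_cohort
from .dce import AIFCurve, fit_t10, patlak_fit, signal_to_concentration
from .evaluation import aic_table, group_tp_table
from .pbpk import EGFR_CONC
from .synthetic import (
    MouseRecord,
    cohort_to_frame,
    generate_aif,
    generate_cohort,
    generate_dce_observation,
    generate_sr_signals,
)

__all__ = ["PipelineError", "run_pipeline", "stage_simulate", "stage_fit_dce",
           "stage_fit_population", "stage_predict", "stage_evaluate"]

log = logging.getLogger("mripbpk")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _curves_long(curves: dict[str, dict[str, np.ndarray]]) -> pd.DataFrame:
    rows = []
    for sid, d in curves.items():
        for kind in ("aif_mM", "signal"):
            rows.append(pd.DataFrame({
                "subject_id": sid,
                "kind": kind,
                "time_min": d["times_min"],
                "value": d[kind],
            }))
        rows.append(pd.DataFrame({
            "subject_id": sid,
            "kind": "sr_signal",
            "time_min": d["sr_times_ms"] / 60000.0,
            "value": d["sr_signal"],
        }))
    return pd.concat(rows, ignore_index=True)


def stage_simulate(config: RunConfig, outdir: Path):
    """Generate both antibody arms, their AIFs and DCE/SR signal curves."""
    protocol = config.protocol.build()
    noise = config.noise.build()
    base = config.tumor.build()
    plasma = config.plasma.build()
    truth = config.truth.build()
    cohort: list[MouseRecord] = []
    for antibody in ("non-binding", "target-binding"):
        cohort += generate_cohort(config.groups(antibody), truth, base, noise,
                                  config.seed, plasma=plasma)
    curves: dict[str, dict[str, np.ndarray]] = {}
    for rec in cohort:
        aif = generate_aif(rec.subject_id, protocol, noise, config.seed)
        signal = generate_dce_observation(
            rec.true_ktrans, rec.true_vp, aif, rec.t10_ms, protocol, noise,
            config.seed, subject_id=rec.subject_id,
        )
        sr = generate_sr_signals(rec.t10_ms, protocol, noise, config.seed,
                                 subject_id=rec.subject_id)
        curves[rec.subject_id] = {
            "times_min": aif.times, "aif_mM": aif.cp, "signal": signal,
            "sr_times_ms": np.asarray(protocol.sr_recovery_times_ms),
            "sr_signal": sr,
        }
    cohort_to_frame(cohort).to_csv(outdir / "cohort.csv", index=False)
    _curves_long(curves).to_csv(outdir / "curves.csv", index=False)
    log.info("simulated %d subjects", len(cohort))
    return cohort, curves


def stage_fit_dce(config: RunConfig, outdir: Path, cohort, curves):
    """Per subject: T1 fit, signal->concentration, Patlak fit; update the
    cohort's MRI parameters with the fitted values."""
    protocol = config.protocol.build()
    rows = []
    for rec in cohort:
        d = curves[rec.subject_id]
        t1 = fit_t10(d["sr_times_ms"], d["sr_signal"])
        if not t1.converged:
            log.warning("subject %s: T1 fit not converged", rec.subject_id)
        conc = signal_to_concentration(d["times_min"], d["signal"], t1, protocol)
        n_excl = int((~conc.valid).sum())
        if n_excl:
            log.warning("subject %s: %d frames excluded from inversion",
                        rec.subject_id, n_excl)
        aif = AIFCurve(times=d["times_min"], cp=d["aif_mM"])
        fit = patlak_fit(conc, aif,
                         fit_window=(protocol.injection_time_min, np.inf))
        if config.use_fitted_mri_params:
            rec.ktrans, rec.vp = fit.ktrans, fit.vp
        rows.append({
            "subject_id": rec.subject_id, "t10_ms": t1.t10_ms,
            "ktrans": fit.ktrans, "vp": fit.vp, "rss": fit.rss,
            "n_points": fit.n_points, "n_excluded": n_excl,
            "converged": fit.converged,
        })
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "patlak_fits.csv", index=False)
    cohort_to_frame(cohort).to_csv(outdir / "cohort.csv", index=False)
    return df


def stage_fit_population(config: RunConfig, outdir: Path, cohort):
    """Fit every candidate covariate structure on the non-binding arm."""
    base = config.tumor.build()
    plasma = config.plasma.build()
    settings = config.fit.build(seed=config.seed)
    nonbinding = [r for r in cohort if r.antibody == "non-binding"]
    fits: list[FitResult] = []
    for structure in config.structures:
        log.info("fitting structure %s", structure)
        fits.append(fit_population(nonbinding, structure, base, plasma, settings))
    preds = [predict_cohort(f, nonbinding, base, plasma, label=f.model.structure)
             for f in fits]
    table = aic_table(fits, preds)
    table.to_csv(outdir / "model_comparison.csv", index=False)
    slopes = pd.DataFrame([{
        "structure": f.model.structure,
        "theta_q": list(f.model.theta_q),
        "theta_sigma": list(f.model.theta_sigma),
        "population_q": f.model.population_q,
        "population_sigma": f.model.population_sigma,
        "error_cv": f.model.error_cv,
        "converged": f.converged,
    } for f in fits])
    slopes.to_csv(outdir / "fitted_models.csv", index=False)
    return fits, table


def stage_predict(config: RunConfig, outdir: Path, cohort, fits):
    """A priori predictions of the target-binding arm for every fitted model."""
    base = config.tumor.build()
    plasma = config.plasma.build()
    binding = [r for r in cohort if r.antibody == "target-binding"]
    if not binding:
        log.info("no target-binding arm; skipping prediction stage")
        return []
    egfr = {g.name: g.egfr_conc for g in config.groups("target-binding")}
    egfr = {k: v if v > 0 else EGFR_CONC.get(k, 0.0) for k, v in egfr.items()}
    tables = [predict_cohort(f, binding, base, plasma, egfr_by_group=egfr,
                             label=f.model.structure) for f in fits]
    out = pd.concat([t.rows.assign(structure=t.label) for t in tables],
                    ignore_index=True)
    out.to_csv(outdir / "predictions_binding.csv", index=False)
    return tables


def stage_evaluate(config: RunConfig, outdir: Path, cohort, fits, pred_tables):
    """MPE summaries, the tumor/plasma ratio table and a text report."""
    rows = [{"group": s.group, "antibody": s.antibody,
             "mean_tp_ratio": s.mean_tp_ratio,
             "ratio_binding_over_nonbinding": s.ratio_binding_over_nonbinding}
            for s in group_tp_table(cohort)]
    tp = pd.DataFrame(rows)
    tp.to_csv(outdir / "tp_ratios.csv", index=False)
    mpe = pd.DataFrame([{
        "structure": t.label, "arm": "target-binding",
        "mpe_percent": t.mpe_percent, "signed_mpe_percent": t.signed_mpe_percent,
    } for t in pred_tables])
    mpe.to_csv(outdir / "mpe_binding.csv", index=False)
    lines = ["mripbpk pipeline report", "=======================", "",
             "Tumor/plasma ratios by group and antibody:", tp.to_string(index=False), ""]
    if not mpe.empty:
        lines += ["A priori prediction error on the target-binding arm:",
                  mpe.to_string(index=False), ""]
    (outdir / "report.txt").write_text("\n".join(lines))
    return tp, mpe


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> Path:
    """Execute all stages in order; idempotent for a fixed config and seed.

    Returns the run directory.  A stage failure raises :class:`PipelineError`
    with the stage tag; outputs of completed stages are retained.
    """
    outdir = Path(outdir if outdir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages_done: list[str] = []

    def run_stage(name, fn, *args):
        try:
            result = fn(config, outdir, *args)
        except Exception as exc:  # noqa: BLE001 - tag and re-raise
            write_manifest(config, outdir, stages_done)
            raise PipelineError(name, exc) from exc
        stages_done.append(name)
        return result

    cohort, curves = run_stage("simulate", stage_simulate)
    run_stage("fit-dce", stage_fit_dce, cohort, curves)
    fits, _ = run_stage("fit-population", stage_fit_population, cohort)
    pred_tables = run_stage("predict", stage_predict, cohort, fits)
    run_stage("evaluate", stage_evaluate, cohort, fits, pred_tables)
    write_manifest(config, outdir, stages_done)
    return outdir
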