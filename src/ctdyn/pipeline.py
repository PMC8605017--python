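"""End-to-end pipeline: simulate/ingest -> landmark survival -> joint fit ->
dynamic prediction -> cross-validated evaluation."""

from __future__ import annotations

import json
import logging
import os

import numpy as np
import pandas as pd

from . import DAYS_PER_MONTH, __version__
from .evaluation import (EvaluationWindow, JointSpec, LandmarkCoxSpec,
                         StaticCoxSpec, comparison_table, repeated_kfold_cv)
from .io import config_hash, read_cohort, write_cohort
from .jointmodel import JointData, fit_joint_model
from .prediction import SubjectHistory, predict_conditional_rfs
from .splines import NaturalCubicBasis
from .survival import (classify_landmark_status, cox_fit, km_estimate,
                       logrank_test)
from .synthetic import (SimulationParams, simulate_joint_cohort,
                        strong_association_params)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _tsv(df, path, cfg_hash):
    with open(path, "w") as fh:
        fh.write(f"# ctdyn v{__version__}\n# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def _landmark_tables(cohort, cfg_hash, outdir):
    """KM curves, log-rank and Cox fits stratified by ctDNA status layers."""
    from types import SimpleNamespace
    results = []
    km_rows = []
    for ser in cohort.series:
        for d, pos in zip(ser.days, ser.positive):
            results.append(SimpleNamespace(patient=ser.patient,
                                           draw_day=float(d),
                                           positive=bool(pos)))
    status = classify_landmark_status(cohort.subjects, results)
    rows = []
    for layer in ("postsurgical", "longitudinal"):
        pos_ids = {p for p, st in status.items() if st[layer] is True}
        neg_ids = {p for p, st in status.items() if st[layer] is False}
        grp_pos = [s for s in cohort.subjects if s.patient in pos_ids]
        grp_neg = [s for s in cohort.subjects if s.patient in neg_ids]
        if not grp_pos or not grp_neg:
            logger.warning("layer %s: a status group is empty; skipped", layer)
            continue
        tp = np.array([s.rfs_day for s in grp_pos])
        ep = np.array([s.event for s in grp_pos])
        tn = np.array([s.rfs_day for s in grp_neg])
        en = np.array([s.event for s in grp_neg])
        try:
            chi2, p = logrank_test([(tp, ep), (tn, en)])
        except ValueError:
            chi2, p = float("nan"), float("nan")
        subj = grp_pos + grp_neg
        x = np.array([1.0] * len(grp_pos) + [0.0] * len(grp_neg))
        t = np.concatenate([tp, tn])
        e = np.concatenate([ep, en])
        try:
            cfit = cox_fit(x, t, e, names=[f"{layer}_pos"])
            hr = float(cfit.hr[0])
            lo, hi = cfit.hr_ci()
            hr_lo, hr_hi = float(lo[0]), float(hi[0])
        except (ValueError, RuntimeError) as exc:
            logger.warning("cox fit failed for %s: %s", layer, exc)
            hr = hr_lo = hr_hi = float("nan")
        rows.append({"layer": layer, "n_pos": len(grp_pos),
                     "n_neg": len(grp_neg), "logrank_chi2": chi2,
                     "logrank_p": p, "hr": hr, "hr_lo": hr_lo,
                     "hr_hi": hr_hi})
        for label, tt, ee in (("positive", tp, ep), ("negative", tn, en)):
            if ee.any():
                km = km_estimate(tt, ee)
                km_rows.extend(
                    {"layer": layer, "group": label, "time_day": t_,
                     "survival": s_, "at_risk": int(n_), "events": int(d_),
                     "greenwood_var": v_}
                    for t_, s_, n_, d_, v_ in zip(
                        km.times, km.survival, km.at_risk, km.n_events,
                        km.variance))
    df = pd.DataFrame(rows)
    _tsv(df, os.path.join(outdir, "landmark_cox.tsv"), cfg_hash)
    _tsv(pd.DataFrame(km_rows), os.path.join(outdir, "km_curves.tsv"),
         cfg_hash)
    return df


def run_pipeline(cfg: dict) -> dict:
    """Execute the full analysis per the configuration; returns artifact paths."""
    cfg_hash = config_hash(cfg)
    outdir = cfg["outdir"]
    os.makedirs(outdir, exist_ok=True)
    seed = int(cfg["seed"])
    dpm = float(cfg.get("days_per_month", DAYS_PER_MONTH))
    artifacts = {}

    # stage 1: cohort
    if cfg.get("subjects_csv"):
        logger.info("stage simulate: loading cohort from %s",
                    cfg["subjects_csv"])
        cohort, report = read_cohort(cfg["subjects_csv"],
                                     cfg["longitudinal_csv"])
        if report["post_event_samples"]:
            logger.warning("post-event samples for %s",
                           report["post_event_samples"])
    else:
        logger.info("stage simulate: generating %d subjects (seed %d)",
                    cfg["n_subjects"], seed)
        if cfg.get("preset") == "strong_association":
            params = strong_association_params(cfg["n_subjects"], seed=seed)
        else:
            params = SimulationParams(n_subjects=cfg["n_subjects"], seed=seed)
        cohort = simulate_joint_cohort(params)
    sp = os.path.join(outdir, "subjects.csv")
    lp = os.path.join(outdir, "longitudinal.csv")
    write_cohort(cohort, sp, lp, seed=seed, cfg_hash=cfg_hash)
    artifacts["subjects"] = sp
    artifacts["longitudinal"] = lp

    # stage 2: landmark survival analyses
    logger.info("stage survival: landmark KM/log-rank/Cox")
    _landmark_tables(cohort, cfg_hash, outdir)
    artifacts["landmark_cox"] = os.path.join(outdir, "landmark_cox.tsv")
    artifacts["km_curves"] = os.path.join(outdir, "km_curves.tsv")

    # stage 3: joint model
    logger.info("stage fit-joint: association=%s", cfg["association"])
    alldays = np.concatenate([s.days for s in cohort.series])
    basis = NaturalCubicBasis.from_times(alldays)
    data = JointData.from_cohort(cohort, basis=basis)
    fit = fit_joint_model(data, cfg["association"],
                          engine=cfg.get("engine", "map_ml"), seed=seed)
    fp = os.path.join(outdir, "joint_fit.json")
    fit.to_json(fp)
    artifacts["joint_fit"] = fp

    # stage 4: dynamic predictions for a few illustrative subjects
    logger.info("stage predict: dynamic predictions")
    landmark = float(cfg["landmark_months"]) * dpm
    horizons = np.array([float(m) * dpm for m in cfg["horizon_months"]])
    rows = []
    shown = 0
    for subj in cohort.subjects:
        ser = cohort.series_for(subj.patient)
        if subj.rfs_day <= landmark or not (ser.days <= landmark).any():
            continue
        hist = SubjectHistory(
            patient=subj.patient, tp53_mut=subj.tp53_mut,
            t4_stage=subj.t4_stage, days=ser.days[ser.days <= landmark],
            log_level=ser.log_level[ser.days <= landmark], t=landmark)
        ps = predict_conditional_rfs(fit, hist, horizons, seed=seed,
                                     n_draws=cfg.get("mc_draws", 300))
        for u, med, lo, hi in zip(ps.horizons, ps.median, ps.lo, ps.hi):
            rows.append({"patient": subj.patient, "t_day": landmark,
                         "u_day": u, "median": med, "lo": lo, "hi": hi})
        shown += 1
        if shown >= cfg.get("n_prediction_subjects", 5):
            break
    _tsv(pd.DataFrame(rows), os.path.join(outdir, "predictions.tsv"),
         cfg_hash)
    artifacts["predictions"] = os.path.join(outdir, "predictions.tsv")

    # stage 5: evaluation
    logger.info("stage evaluate: repeated %d-fold CV x %d",
                cfg["cv"]["k"], cfg["cv"]["repeats"])
    windows = tuple(EvaluationWindow(landmark, u) for u in horizons)
    specs = {"joint": JointSpec(cfg["association"]),
             "landmark": LandmarkCoxSpec(landmark),
             "static": StaticCoxSpec(landmark)}
    dists = repeated_kfold_cv(cohort, specs, windows=windows,
                              k=cfg["cv"]["k"], repeats=cfg["cv"]["repeats"],
                              seed=seed, basis=basis)
    mrows = [{"model": k[0], "metric": k[1], "u_day": k[2].u, "repeat": i,
              "value": v}
             for k, dist in dists.items() for i, v in enumerate(dist.values)]
    _tsv(pd.DataFrame(mrows), os.path.join(outdir, "metrics.tsv"), cfg_hash)
    _tsv(pd.DataFrame(comparison_table(dists)),
         os.path.join(outdir, "comparisons.tsv"), cfg_hash)
    artifacts["metrics"] = os.path.join(outdir, "metrics.tsv")
    artifacts["comparisons"] = os.path.join(outdir, "comparisons.tsv")

    # LOOCV reliability diagram (landmark-Cox; the joint-model variant is
    # available through loocv_hosmer_lemeshow but too slow for the demo run)
    from .evaluation import loocv_hosmer_lemeshow
    rel_rows = []
    for w in windows:
        try:
            C, p_hl, table = loocv_hosmer_lemeshow(
                cohort, lambda: LandmarkCoxSpec(landmark), w,
                n_groups=cfg.get("hl_groups", 5), basis=basis)
        except (ValueError, RuntimeError) as exc:
            logger.warning("reliability for u=%.0f failed: %s", w.u, exc)
            continue
        for g, row in enumerate(table):
            rel_rows.append({"model": "landmark", "u_day": w.u, "group": g,
                             "n": row["n"], "expected": row["expected"],
                             "observed": row["observed"], "hl_c": C,
                             "hl_p": p_hl})
    _tsv(pd.DataFrame(rel_rows), os.path.join(outdir, "reliability.tsv"),
         cfg_hash)
    artifacts["reliability"] = os.path.join(outdir, "reliability.tsv")

    with open(os.path.join(outdir, "run.json"), "w") as fh:
        json.dump({"version": __version__, "config": cfg,
                   "config_hash": cfg_hash, "artifacts": artifacts}, fh,
                  indent=1)
    artifacts["run"] = os.path.join(outdir, "run.json")
    return artifacts
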