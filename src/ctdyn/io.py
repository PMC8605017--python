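"""File schemas: cohort CSVs, read-family / background-db / variant TSVs, YAML config.

Every writer stamps a comment header with the package version, the seed and
the configuration hash so each artifact is traceable to the run that made
it.  ``read_cohort`` validates the schema (key consistency, non-negative
days, log-level/VAF transform consistency) and reports rather than silently
drops questionable rows.
"""

from __future__ import annotations

import hashlib
import logging

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .mrd import (BackgroundErrorDB, ReadFamily, TissueVariant, VariantCall,
                  log_ctdna_level)
from .survival import SubjectRecord
from .synthetic import LongitudinalSeries, SyntheticCohort

logger = logging.getLogger(__name__)

__all__ = [
    "write_cohort", "read_cohort", "write_read_families", "read_read_families",
    "write_background_db", "read_background_db", "read_variant_table",
    "write_variant_table", "read_tissue_variants", "load_config",
    "config_hash", "CohortValidationError",
]


class CohortValidationError(ValueError):
    """Raised when cohort tables violate the schema."""


def _header(seed=None, cfg_hash=None) -> str:
    parts = [f"# ctdyn v{__version__}"]
    if seed is not None:
        parts.append(f"# seed={seed}")
    if cfg_hash is not None:
        parts.append(f"# config_hash={cfg_hash}")
    return "\n".join(parts) + "\n"


def _write_csv(df: pd.DataFrame, path, seed=None, cfg_hash=None, sep=","):
    with open(path, "w") as fh:
        fh.write(_header(seed, cfg_hash))
        df.to_csv(fh, index=False, sep=sep)


def _read_table(path, sep=","):
    return pd.read_csv(path, sep=sep, comment="#")


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

SUBJECT_COLUMNS = ["patient", "tp53_mut", "t4_stage", "stage", "act_received",
                   "act_start_day", "act_end_day", "rfs_day", "event"]
LONGITUDINAL_COLUMNS = ["patient", "day", "mean_vaf", "log_ctdna", "positive"]


def write_cohort(cohort: SyntheticCohort, subjects_path, longitudinal_path,
                 seed=None, cfg_hash=None):
    subj = pd.DataFrame([{
        "patient": s.patient, "tp53_mut": int(s.tp53_mut),
        "t4_stage": int(s.t4_stage), "stage": s.stage,
        "act_received": int(s.act_received),
        "act_start_day": s.act_start_day, "act_end_day": s.act_end_day,
        "rfs_day": s.rfs_day, "event": int(s.event)}
        for s in cohort.subjects])
    rows = []
    for ser in cohort.series:
        for d, v, y, pos in zip(ser.days, ser.mean_vaf, ser.log_level,
                                ser.positive):
            rows.append({"patient": ser.patient, "day": d, "mean_vaf": v,
                         "log_ctdna": y, "positive": int(pos)})
    if seed is None and cohort.params is not None:
        seed = cohort.params.seed
    _write_csv(subj, subjects_path, seed, cfg_hash)
    _write_csv(pd.DataFrame(rows), longitudinal_path, seed, cfg_hash)


def read_cohort(subjects_path, longitudinal_path, transform_tol=1e-6):
    """Load and validate cohort tables; returns (cohort, validation_report)."""
    subj = _read_table(subjects_path)
    lon = _read_table(longitudinal_path)
    missing = [c for c in SUBJECT_COLUMNS if c not in subj.columns]
    missing += [c for c in LONGITUDINAL_COLUMNS if c not in lon.columns]
    if missing:
        raise CohortValidationError(f"missing columns: {missing}")

    bad = lon[lon["day"] < 0]
    if len(bad):
        raise CohortValidationError(
            f"negative days in longitudinal rows {bad.index.tolist()}")
    expected = log_ctdna_level(lon["mean_vaf"].to_numpy(dtype=float))
    mism = np.abs(expected - lon["log_ctdna"].to_numpy(dtype=float)) > \
        transform_tol
    if mism.any():
        raise CohortValidationError(
            "log_ctdna inconsistent with mean_vaf in rows "
            f"{np.where(mism)[0].tolist()}")
    unknown = set(lon["patient"]) - set(subj["patient"])
    if unknown:
        raise CohortValidationError(
            f"longitudinal rows reference unknown patients: {sorted(unknown)}")

    report = {"post_event_samples": [], "no_measurements": [],
              "excluded_patients": []}
    subjects, series = [], []
    for _, r in subj.iterrows():
        subjects.append(SubjectRecord(
            patient=str(r["patient"]), tp53_mut=bool(r["tp53_mut"]),
            t4_stage=bool(r["t4_stage"]), stage=str(r["stage"]),
            act_received=bool(r["act_received"]),
            act_start_day=float(r["act_start_day"]),
            act_end_day=float(r["act_end_day"]),
            rfs_day=float(r["rfs_day"]), event=bool(r["event"])))
    rfs = dict(zip(subj["patient"].astype(str), subj["rfs_day"]))
    for pid, grp in lon.groupby("patient", sort=True):
        grp = grp.sort_values("day")
        after = grp["day"] > rfs[str(pid)]
        if after.any():
            report["post_event_samples"].append(str(pid))
        series.append(LongitudinalSeries(
            patient=str(pid), days=grp["day"].to_numpy(dtype=float),
            log_level=grp["log_ctdna"].to_numpy(dtype=float),
            mean_vaf=grp["mean_vaf"].to_numpy(dtype=float),
            positive=grp["positive"].to_numpy(dtype=bool)))
    with_series = {s.patient for s in series}
    for s in subjects:
        if s.patient not in with_series:
            report["no_measurements"].append(s.patient)
    return SyntheticCohort(subjects=subjects, series=series, truth={},
                           params=None), report


# ---------------------------------------------------------------------------
# read families / background db / variants
# ---------------------------------------------------------------------------

FAMILY_COLUMNS = ["contig", "pos", "umiA", "umiB", "orientation", "read_idx",
                  "allele"]


def write_read_families(families, path, seed=None):
    rows = []
    for fam in families:
        for ri, read in enumerate(fam.reads):
            for pos, base in read.items():
                rows.append({"contig": fam.contig, "pos": pos,
                             "umiA": fam.umi_a, "umiB": fam.umi_b,
                             "orientation": fam.orientation, "read_idx": ri,
                             "allele": base})
    _write_csv(pd.DataFrame(rows, columns=FAMILY_COLUMNS), path, seed,
               sep="\t")


def read_read_families(path):
    df = _read_table(path, sep="\t")
    fams = []
    key_cols = ["contig", "pos", "umiA", "umiB", "orientation"]
    for key, grp in df.groupby(key_cols, sort=True):
        contig, pos, ua, ub, orient = key
        reads = []
        for _, rgrp in grp.groupby("read_idx", sort=True):
            reads.append({int(p): str(a)
                          for p, a in zip(rgrp["pos"], rgrp["allele"])})
        fams.append(ReadFamily(contig=str(contig), position=int(pos),
                               umi_a=str(ua), umi_b=str(ub),
                               orientation=str(orient), reads=tuple(reads)))
    return fams


def write_background_db(db: BackgroundErrorDB, path, seed=None):
    rows = [{"contig": c, "pos": p, "sub": s, "rate": r,
             "max_support": db.max_support.get((c, p, s), 0)}
            for (c, p, s), r in sorted(db.rates.items())]
    _write_csv(pd.DataFrame(rows), path, seed, sep="\t")


def read_background_db(path) -> BackgroundErrorDB:
    df = _read_table(path, sep="\t")
    rates, support = {}, {}
    for _, r in df.iterrows():
        key = (str(r["contig"]), int(r["pos"]), str(r["sub"]))
        rates[key] = float(r["rate"])
        if "max_support" in df.columns:
            support[key] = int(r["max_support"])
    return BackgroundErrorDB(rates=rates, max_support=support)


def write_variant_table(calls, path, seed=None):
    rows = [{"contig": c.contig, "pos": c.position, "ref": c.ref,
             "alt": c.alt, "depth": c.depth, "mutant_reads": c.mutant_reads,
             "duplex_support": c.duplex_support,
             "sscs_support": c.sscs_support, "vaf": c.vaf,
             "polish_p": c.polish_p, "passed": int(c.passed)}
            for c in calls]
    _write_csv(pd.DataFrame(rows), path, seed, sep="\t")


def read_variant_table(path):
    """Plasma candidate calls from TSV (or a minimal VCF with DP/AD INFO)."""
    if str(path).endswith(".vcf"):
        return _read_vcf_variants(path)
    df = _read_table(path, sep="\t")
    return [VariantCall(contig=str(r["contig"]), position=int(r["pos"]),
                        ref=str(r["ref"]), alt=str(r["alt"]),
                        depth=int(r["depth"]),
                        mutant_reads=int(r["mutant_reads"]),
                        duplex_support=int(r.get("duplex_support", 0)),
                        sscs_support=int(r.get("sscs_support", 0)))
            for _, r in df.iterrows()]


def _read_vcf_variants(path):
    import pysam  # optional dependency, VCF input only
    out = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            dp = int(rec.info.get("DP", 0))
            ad = rec.info.get("AD", (0,))
            ad = int(ad[-1] if isinstance(ad, tuple) else ad)
            out.append(VariantCall(
                contig=rec.chrom, position=rec.pos, ref=rec.ref,
                alt=rec.alts[0] if rec.alts else ".", depth=dp,
                mutant_reads=ad))
    return out


def read_tissue_variants(path):
    """Tissue mutation candidates: TSV with vaf, supporting_reads, cosmic_count."""
    df = _read_table(path, sep="\t")
    return [TissueVariant(contig=str(r["contig"]), position=int(r["pos"]),
                          ref=str(r["ref"]), alt=str(r["alt"]),
                          vaf=float(r["vaf"]),
                          supporting_reads=int(r["supporting_reads"]),
                          cosmic_count=int(r.get("cosmic_count", 0)))
            for _, r in df.iterrows()]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "seed": 0,
    "n_subjects": 150,
    "preset": "strong_association",
    "association": "value",
    "landmark_months": 8.0,
    "horizon_months": [12.0, 15.0],
    "days_per_month": 30.44,
    "cv": {"k": 5, "repeats": 5},
    "engine": "map_ml",
    "outdir": "ctdyn_out",
}


def load_config(path=None, overrides=None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for k, v in user.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    for k, v in (overrides or {}).items():
        if v is not None:
            cfg[k] = v
    return cfg


def config_hash(cfg: dict) -> str:
    canon = yaml.safe_dump(cfg, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
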