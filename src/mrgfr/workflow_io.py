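"""File formats, configuration, command-line interface and logging.

All on-disk formats are plain delimited text, because the pipeline's
inputs are ROI-averaged signal curves rather than images:

* per-subject curve files: CSV with columns ``time_s, aorta_signal,
  kidney_signal`` (times in seconds, uniform sampling);
* cohort metadata: CSV with columns ``subject_id, hct_fraction,
  volume_ml, n_precontrast, ref_gfr_ml_min, curve_file`` (hematocrit is a
  fraction in files; percentages appear only in reports);
* ground truth (simulated cohorts): CSV of the generating parameters;
* results and summaries: CSV, one row per subject x method x Hct mode.

Every table written here carries the seed and a configuration hash in a
leading comment line for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import agreement_stats as ag
from . import model_fitting as mf
from .curve_processing import ConfigError, DetectionConfig
from .pk_models import DomainError, TimeSeriesCurve, rpf_v
from .synthetic_cohort import CohortConfig, GroundTruth, SubjectRecord, simulate_cohort
from .pk_models import AifModel, KidneyModelParams

__all__ = [
    "ParseError",
    "PipelineConfig",
    "read_curves",
    "write_curves",
    "read_cohort_metadata",
    "load_cohort",
    "write_cohort",
    "load_config",
    "config_hash",
    "cli",
]

logger = logging.getLogger("mrgfr")

_CURVE_COLUMNS = ["time_s", "aorta_signal", "kidney_signal"]
_META_COLUMNS = ["subject_id", "hct_fraction", "volume_ml", "n_precontrast", "curve_file"]
_FLOAT_FMT = "%.17g"  # round-trips float64 exactly


class ParseError(ValueError):
    """A data file violates the expected schema."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Everything the command-line pipeline needs, in one document."""

    cohort: CohortConfig | None = None
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    n_starts: int = 5
    seed: int = 0
    refine: int = 10
    fixed_hct: float = mf.FIXED_LITERATURE_HCT
    methods: tuple[str, ...] = ("ss", "fixed90", "fixed110", "inflow_outflow")
    hct_modes: tuple[str, ...] = ("subject", "fixed41")

    def analysis(self) -> mf.AnalysisConfig:
        return mf.AnalysisConfig(
            detection=self.detection,
            n_starts=self.n_starts,
            seed=self.seed,
            refine=self.refine,
            fixed_hct=self.fixed_hct,
        )


def _from_mapping(cls, data: dict, context: str):
    """Build a dataclass from a mapping, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ConfigError(f"{context}: expected a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{context}: unknown keys {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v  # yaml lists -> tuples
        for k, v in data.items()
    }
    return cls(**coerced)


def load_config(path) -> PipelineConfig:
    """Read and validate a YAML pipeline configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config root must be a mapping")
    nested = {}
    if "cohort" in raw:
        nested["cohort"] = _from_mapping(CohortConfig, raw.pop("cohort"), "cohort")
    if "detection" in raw:
        nested["detection"] = _from_mapping(DetectionConfig, raw.pop("detection"), "detection")
    cfg = _from_mapping(PipelineConfig, raw, "pipeline")
    return dataclasses.replace(cfg, **nested)


def config_hash(config) -> str:
    """Short stable hash of any (nested) dataclass configuration."""
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _provenance_line(seed, config) -> str:
    return f"# seed={seed} config_hash={config_hash(config) if config is not None else 'none'}"


def _write_table(df: pd.DataFrame, path, seed=None, config=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance_line(seed, config) + "\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def _read_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, comment="#", float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Curve and cohort files
# ---------------------------------------------------------------------------

def write_curves(path, aorta: TimeSeriesCurve, kidney: TimeSeriesCurve) -> None:
    """Write a subject's aorta/kidney signal curves to one CSV file."""
    df = pd.DataFrame(
        {"time_s": aorta.times, "aorta_signal": aorta.values, "kidney_signal": kidney.values}
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_curves(path, n_precontrast: int = 10) -> tuple[TimeSeriesCurve, TimeSeriesCurve]:
    """Read a curve file; returns the (aorta, kidney) pair.

    Validates the header, numeric content (reporting the first offending
    line) and uniform time sampling.
    """
    df = _read_table(path)
    missing = [c for c in _CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for col in _CURVE_COLUMNS:
        num = pd.to_numeric(df[col], errors="coerce")
        bad = num.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise ParseError(f"{path}: non-numeric value in column '{col}' at line {line}")
        df[col] = num
    try:
        aorta = TimeSeriesCurve(
            times=df["time_s"].to_numpy(),
            values=df["aorta_signal"].to_numpy(),
            n_precontrast=n_precontrast,
        )
        kidney = aorta.with_values(df["kidney_signal"].to_numpy())
    except DomainError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return aorta, kidney


def read_cohort_metadata(path) -> pd.DataFrame:
    """Read and validate a cohort metadata table.

    ``ref_gfr_ml_min`` is optional; when absent, agreement statistics are
    disabled downstream (a warning is logged). Hematocrit must be stored
    as a fraction — a value >= 1 is treated as an accidental percentage.
    """
    df = _read_table(path)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if "ref_gfr_ml_min" not in df.columns:
        logger.warning("%s: no ref_gfr_ml_min column; agreement statistics disabled", path)
        df["ref_gfr_ml_min"] = np.nan
    for _, row in df.iterrows():
        sid = row["subject_id"]
        if not 0.0 < row["hct_fraction"] < 1.0:
            raise ParseError(
                f"subject {sid}: hct_fraction {row['hct_fraction']} outside (0, 1) — "
                "store hematocrit as a fraction, not percent"
            )
        if not row["volume_ml"] > 0:
            raise ParseError(f"subject {sid}: volume_ml must be positive")
    return df


def write_cohort(records: list[SubjectRecord], out_dir, config=None) -> None:
    """Write curve files, metadata and (if present) ground truth."""
    out = Path(out_dir)
    (out / "curves").mkdir(parents=True, exist_ok=True)
    meta_rows, truth_rows = [], []
    seed = getattr(config, "seed", None)
    for rec in records:
        curve_file = f"curves/{rec.subject_id}.csv"
        write_curves(out / curve_file, rec.aorta_curve, rec.kidney_curve)
        meta_rows.append(
            {
                "subject_id": rec.subject_id,
                "hct_fraction": rec.hct,
                "volume_ml": rec.parenchymal_volume,
                "n_precontrast": rec.aorta_curve.n_precontrast,
                "ref_gfr_ml_min": rec.reference_gfr,
                "curve_file": curve_file,
            }
        )
        if rec.ground_truth is not None:
            gt = rec.ground_truth
            row = {"subject_id": rec.subject_id}
            row.update({f"aif_{k}": v for k, v in dataclasses.asdict(gt.aif).items()})
            row.update({f"kidney_{k}": v for k, v in dataclasses.asdict(gt.kidney).items()})
            row.update(
                rise_index=gt.rise_index,
                end_of_uptake_index=gt.end_of_uptake_index,
                end_of_uptake_time=gt.end_of_uptake_time,
                uptake_interval=gt.uptake_interval,
                true_gfr_ml_min=gt.true_gfr_ml_min,
            )
            truth_rows.append(row)
    _write_table(pd.DataFrame(meta_rows), out / "metadata.csv", seed=seed, config=config)
    if truth_rows:
        _write_table(pd.DataFrame(truth_rows), out / "ground_truth.csv", seed=seed, config=config)


def load_cohort(cohort_dir) -> list[SubjectRecord]:
    """Load a cohort directory (metadata + curves + optional ground truth)."""
    cohort_dir = Path(cohort_dir)
    meta = read_cohort_metadata(cohort_dir / "metadata.csv")
    truth_path = cohort_dir / "ground_truth.csv"
    truths = {}
    if truth_path.exists():
        tdf = _read_table(truth_path)
        for _, row in tdf.iterrows():
            truths[row["subject_id"]] = GroundTruth(
                aif=AifModel(*(row[f"aif_{k}"] for k in ("a1", "b1", "c1", "t1", "a2", "b2", "c2", "t2"))),
                kidney=KidneyModelParams(
                    *(row[f"kidney_{k}"] for k in ("v_p", "gfr_v", "delay", "t_disp", "t_tub"))
                ),
                rise_index=int(row["rise_index"]),
                end_of_uptake_index=int(row["end_of_uptake_index"]),
                end_of_uptake_time=float(row["end_of_uptake_time"]),
                uptake_interval=float(row["uptake_interval"]),
                true_gfr_ml_min=float(row["true_gfr_ml_min"]),
            )
    records = []
    for _, row in meta.iterrows():
        aorta, kidney = read_curves(
            cohort_dir / row["curve_file"], n_precontrast=int(row["n_precontrast"])
        )
        ref = row["ref_gfr_ml_min"]
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                aorta_curve=aorta,
                kidney_curve=kidney,
                hct=float(row["hct_fraction"]),
                parenchymal_volume=float(row["volume_ml"]),
                reference_gfr=None if pd.isna(ref) else float(ref),
                ground_truth=truths.get(row["subject_id"]),
            )
        )
    return records


def results_to_frame(results: list[mf.FitResult]) -> pd.DataFrame:
    """Flatten kidney fit results into the on-disk results table."""
    rows = []
    for r in results:
        p = r.params
        rows.append(
            {
                "subject_id": r.provenance.get("subject_id"),
                "method": r.method.value if r.method else None,
                "hct_mode": r.hct_mode.value if r.hct_mode else None,
                "gfr_ml_min": r.gfr_ml_min,
                "gfr_v": p.gfr_v,
                "v_p": p.v_p,
                "delay_s": p.delay,
                "t_disp_s": p.t_disp,
                "t_tub_s": p.t_tub,
                "rpf_v": rpf_v(p),  # secondary perfusion output, not validated
                "r_squared": r.r_squared,
                "residual_norm": r.residual_norm,
                "rise_index": r.provenance.get("rise_index"),
                "end_index": r.provenance.get("end_index"),
                "hct_used": r.provenance.get("hct_used"),
                "aif_r_squared": r.provenance.get("aif_r_squared"),
                "detection_mode": r.provenance.get("detection_mode"),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Command-line interface
# ---------------------------------------------------------------------------

def _setup_logging(verbose: bool) -> None:
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        stream=sys.stderr,
    )


def _load_pipeline_config(path, seed) -> PipelineConfig:
    cfg = load_config(path) if path else PipelineConfig()
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    return cfg


class _Stage:
    """Logs wall-clock timing of a pipeline stage."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: started", self.name)
        return self

    def __exit__(self, *exc):
        logger.info("stage %s: finished in %.1f s", self.name, time.perf_counter() - self.t0)
        return False


@click.group()
@click.option("--verbose", is_flag=True, help="Enable debug logging.")
def cli(verbose):
    """GFR quantification from renal DCE-MRI signal curves."""
    _setup_logging(verbose)


@cli.command()
@click.option("--n", "n_subjects", type=int, default=None, help="Number of subjects.")
@click.option("--seed", type=int, default=None, help="Cohort seed.")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--out", "out_dir", type=click.Path(), required=True)
def simulate(n_subjects, seed, config_path, out_dir):
    """Simulate a synthetic cohort and write it to a directory."""
    cfg = load_config(config_path) if config_path else PipelineConfig()
    cohort = cfg.cohort or CohortConfig(seed=seed if seed is not None else 0)
    if seed is not None:
        cohort = dataclasses.replace(cohort, seed=seed)
    if n_subjects is not None:
        cohort = dataclasses.replace(cohort, n_subjects=n_subjects)
    with _Stage("simulate"):
        records = simulate_cohort(cohort, out_dir=out_dir)
    click.echo(f"wrote {len(records)} subjects to {out_dir}")


@cli.command()
@click.option("--cohort", "cohort_dir", type=click.Path(exists=True), required=True)
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=None)
@click.option("--out", "out_path", type=click.Path(), required=True)
def detect(cohort_dir, config_path, seed, out_path):
    """Report postaortic rise and end-of-uptake per subject."""
    from . import curve_processing as cp
    from . import pk_models as pk

    cfg = _load_pipeline_config(config_path, seed)
    records = load_cohort(cohort_dir)
    rows = []
    with _Stage("detect"):
        for rec in records:
            aorta_enh = cp.enhancement_curve(rec.aorta_curve)
            kidney_enh = cp.enhancement_curve(rec.kidney_curve)
            plasma = pk.plasma_correct(aorta_enh, rec.hct)
            rise = cp.detect_postaortic_rise(plasma, cfg.detection)
            det = cp.detect_end_of_uptake(kidney_enh, rise, cfg.detection)
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "rise_index": det.postaortic_rise_index,
                    "end_of_uptake_index": det.end_of_uptake_index,
                    "uptake_interval_s": det.uptake_interval,
                    "mode": det.mode.value,
                }
            )
    _write_table(pd.DataFrame(rows), out_path, seed=cfg.seed, config=cfg)
    click.echo(f"wrote detections for {len(rows)} subjects to {out_path}")


@cli.command()
@click.option("--cohort", "cohort_dir", type=click.Path(exists=True), required=True)
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--seed", type=int, default=None)
@click.option("--method", "methods", multiple=True, help="Repeatable; defaults to config.")
@click.option("--hct-mode", "hct_modes", multiple=True, help="Repeatable; defaults to config.")
@click.option("--keep-going", is_flag=True, help="Continue past per-subject failures.")
@click.option("--out", "out_path", type=click.Path(), required=True)
def fit(cohort_dir, config_path, seed, methods, hct_modes, keep_going, out_path):
    """Fit kidney models and write per-subject GFR estimates."""
    cfg = _load_pipeline_config(config_path, seed)
    methods = methods or cfg.methods
    hct_modes = hct_modes or cfg.hct_modes
    records = load_cohort(cohort_dir)
    results, failures = [], 0
    with _Stage("fit"):
        for rec in records:
            for hm in hct_modes:
                for me in methods:
                    t0 = time.perf_counter()
                    try:
                        res = mf.estimate_subject_gfr(rec, me, hm, cfg.analysis())
                    except (mf.PipelineError, mf.FitError) as exc:
                        failures += 1
                        logger.error("subject %s %s/%s failed: %s", rec.subject_id, me, hm, exc)
                        if not keep_going:
                            raise SystemExit(1)
                        continue
                    logger.debug(
                        "subject %s %s/%s: GFR %.1f mL/min (%.2f s)",
                        rec.subject_id, me, hm, res.gfr_ml_min, time.perf_counter() - t0,
                    )
                    results.append(res)
    _write_table(results_to_frame(results), out_path, seed=cfg.seed, config=cfg)
    click.echo(f"wrote {len(results)} fits to {out_path} ({failures} failures)")


@cli.command()
@click.option("--cohort", "cohort_dir", type=click.Path(exists=True), required=True)
@click.option("--results", "results_path", type=click.Path(exists=True), required=True)
@click.option("--out", "out_path", type=click.Path(), required=True)
def compare(cohort_dir, results_path, out_path):
    """Summarize fits against the reference GFR (Bland-Altman, regression)."""
    meta = read_cohort_metadata(Path(cohort_dir) / "metadata.csv")
    if meta["ref_gfr_ml_min"].isna().any():
        raise click.ClickException("cohort lacks reference GFR values; cannot compare")
    ref = meta.sort_values("subject_id")["ref_gfr_ml_min"].to_numpy()
    df = _read_table(results_path)
    with _Stage("compare"):
        out_rows = []
        for (hm, me), cell in df.groupby(["hct_mode", "method"]):
            cell = cell.sort_values("subject_id")
            if len(cell) != ref.size:
                raise click.ClickException(
                    f"cell ({hm}, {me}) has {len(cell)} rows for {ref.size} reference values"
                )
            g = cell["gfr_ml_min"].to_numpy()
            a = ag.agreement(ref, g)
            out_rows.append(
                {
                    "hct_mode": hm, "method": me, "n": a.n,
                    "gfr_min": g.min(), "gfr_max": g.max(),
                    "gfr_mean": g.mean(), "gfr_sd": g.std(ddof=1),
                    "slope": a.slope, "intercept": a.intercept,
                    "r_squared": a.r_squared, "p_value": a.p_value,
                    "bias": a.bias, "loa_low": a.loa_low, "loa_high": a.loa_high,
                }
            )
        summary = pd.DataFrame(out_rows)
    _write_table(summary, out_path, seed=None, config=None)
    click.echo(ag.format_summary(summary, ref))


def main(argv=None):  # pragma: no cover - thin wrapper
    return cli(args=argv, standalone_mode=True)
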