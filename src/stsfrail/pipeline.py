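"""Pipeline orchestration, file I/O and reporting.

Ties the stages into one reproducible run: obtain a feature table (synthetic
cohort, a directory of recordings, or a CSV), screen features by group
statistics, rank the significant ones by bootstrapped RFE, apply the
optimal-subset rule, and evaluate the selected model on the out-of-bag
validation sets.  Identical configurations (including the seed) produce
identical reports, up to the timestamp in the provenance block.

File formats: feature tables are CSV with ``subject_id``, the 17 canonical
feature columns and a binary ``status`` column; recordings are CSV with
columns ``time_s, trunk_pitch_rad, thigh_pitch_rad, shank_pitch_rad,
vert_disp_m`` plus a cohort-level JSON manifest carrying ``mass_kg``,
``height_m`` and ``status`` per subject.  Structured outputs are JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import ModelPerformance, bootstrap_performance
from .features import FEATURE_NAMES, InvalidTrialError, STSRecording, extract_features
from .selection import (
    SelectionConfig,
    make_bootstrap_pairs,
    rfe_rank,
    select_optimal,
)
from .stats import significant_features
from .synth import CohortSpec, generate_cohort_recordings, generate_feature_table

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "SchemaError",
    "read_feature_table",
    "write_feature_table",
    "read_recording",
    "write_cohort_recordings",
    "read_cohort_recordings",
    "run_pipeline",
    "write_report",
]

logger = logging.getLogger("stsfrail")

_RECORDING_COLUMNS = [
    "time_s",
    "trunk_pitch_rad",
    "thigh_pitch_rad",
    "shank_pitch_rad",
    "vert_disp_m",
]


class PipelineError(RuntimeError):
    """A pipeline stage could not proceed; the message names the stage."""


class SchemaError(ValueError):
    """A data file does not match the canonical schema."""


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one end-to-end run.

    Exactly one input source must be set: ``synthetic`` (a cohort spec),
    ``recordings_dir`` (recording CSVs + manifest.json), or
    ``feature_table`` (a feature CSV).  ``synthetic_waveforms`` selects the
    waveform path (generate recordings and extract features) over the fast
    parametric table path.
    """

    synthetic: CohortSpec | None = None
    recordings_dir: str | None = None
    feature_table: str | None = None
    synthetic_waveforms: bool = False
    alpha: float = 0.05
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    threshold: float = 0.5
    out_dir: str | None = None
    log_level: str = "INFO"

    def __post_init__(self):
        sources = [self.synthetic, self.recordings_dir, self.feature_table]
        if sum(s is not None for s in sources) != 1:
            raise ValueError("exactly one input source must be set")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("synthetic") is not None:
            d["synthetic"] = CohortSpec(**d["synthetic"])
        if d.get("selection") is not None:
            d["selection"] = SelectionConfig(**d["selection"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# feature-table I/O
# ---------------------------------------------------------------------------

def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a feature-table CSV against the canonical schema."""
    df = pd.read_csv(path)
    missing = [n for n in FEATURE_NAMES if n not in df.columns]
    if missing:
        raise SchemaError(f"feature table is missing columns: {missing}")
    if "status" not in df.columns:
        raise SchemaError("feature table is missing the 'status' column")
    bad = df.index[~df["status"].isin([0, 1])]
    if len(bad):
        raise SchemaError(f"non-binary status in rows {list(bad[:5])}")
    for name in FEATURE_NAMES:
        if not pd.api.types.is_numeric_dtype(df[name]):
            raise SchemaError(f"non-numeric values in feature column {name!r}")
    known = {"subject_id", "status", *FEATURE_NAMES}
    extra = [c for c in df.columns if c not in known]
    if extra:
        logger.warning("ignoring extra feature-table columns: %s", extra)
    cols = (["subject_id"] if "subject_id" in df.columns else []) + [
        *FEATURE_NAMES,
        "status",
    ]
    return df.loc[:, cols]


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# recording I/O
# ---------------------------------------------------------------------------

def read_recording(
    path: str | Path, mass: float, height: float, sampling_rate: float | None = None
) -> STSRecording:
    """Read one recording CSV; the sampling rate is inferred from ``time_s``
    unless given explicitly."""
    df = pd.read_csv(path)
    missing = [c for c in _RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"recording {path} is missing columns: {missing}")
    if sampling_rate is None:
        dt = np.diff(df["time_s"].to_numpy())
        if len(dt) == 0 or np.min(dt) <= 0:
            raise SchemaError(f"recording {path} has a non-increasing time axis")
        sampling_rate = 1.0 / float(np.median(dt))
    return STSRecording(
        sampling_rate=sampling_rate,
        trunk_pitch=df["trunk_pitch_rad"].to_numpy(),
        thigh_pitch=df["thigh_pitch_rad"].to_numpy(),
        shank_pitch=df["shank_pitch_rad"].to_numpy(),
        vert_disp=df["vert_disp_m"].to_numpy(),
        mass=mass,
        height=height,
    )


def write_cohort_recordings(spec: CohortSpec, out_dir: str | Path) -> Path:
    """Generate a synthetic cohort and write one CSV per subject plus a
    manifest.json with per-subject mass, height and frailty status."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {}
    for sid, status, profile, rec in generate_cohort_recordings(spec):
        fname = f"{sid}.csv"
        pd.DataFrame(
            {
                "time_s": rec.time,
                "trunk_pitch_rad": rec.trunk_pitch,
                "thigh_pitch_rad": rec.thigh_pitch,
                "shank_pitch_rad": rec.shank_pitch,
                "vert_disp_m": rec.vert_disp,
            }
        ).to_csv(out / fname, index=False, float_format="%.6f")
        manifest[sid] = {
            "file": fname,
            "mass_kg": profile.mass,
            "height_m": profile.height,
            "status": status,
        }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out / "manifest.json"


def read_cohort_recordings(recordings_dir: str | Path) -> tuple[pd.DataFrame, list[dict]]:
    """Extract the feature table from a directory of recordings + manifest.

    Invalid trials (not exactly five detectable cycles) are excluded from
    the table and returned as ``{subject_id, n_cycles}`` entries.
    """
    root = Path(recordings_dir)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise SchemaError(f"no manifest.json in {root}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    rows, invalid = [], []
    for sid in sorted(manifest):
        meta = manifest[sid]
        rec = read_recording(root / meta["file"], meta["mass_kg"], meta["height_m"])
        try:
            fv = extract_features(rec)
        except InvalidTrialError as e:
            logger.warning("excluding %s: %s", sid, e)
            invalid.append({"subject_id": sid, "n_cycles": e.n_cycles})
            continue
        rows.append({"subject_id": sid, **fv.values, "status": meta["status"]})
    table = pd.DataFrame(rows, columns=["subject_id", *FEATURE_NAMES, "status"])
    return table, invalid


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _config_dict(config: PipelineConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in obj.items()}
        return obj

    return enc(config)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(_config_dict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and return the run report as a dict.

    Stages: input -> significance screen -> bootstrapped RFE ranking ->
    optimal-subset rule -> bootstrap-validated performance (selected subset
    and, for comparison, the full significant set).  When ``config.out_dir``
    is set, all artifacts are also written there.
    """
    import datetime

    invalid: list[dict] = []
    if config.synthetic is not None:
        if config.synthetic_waveforms:
            from .synth import cohort_feature_table

            table, bad = cohort_feature_table(config.synthetic)
            invalid = [{"subject_id": sid, "n_cycles": None} for sid in bad]
        else:
            table = generate_feature_table(config.synthetic)
    elif config.recordings_dir is not None:
        table, invalid = read_cohort_recordings(config.recordings_dir)
    else:
        table = read_feature_table(config.feature_table)

    selected_feats, test_results = significant_features(table, config.alpha)
    logger.info("significance screen: %d/%d features retained",
                len(selected_feats), len(FEATURE_NAMES))
    if len(selected_feats) < 2:
        raise PipelineError(
            f"stats stage: no usable significant features at alpha={config.alpha} "
            f"(got {len(selected_feats)})"
        )

    y = table["status"].to_numpy(int)
    splits = make_bootstrap_pairs(y, config.selection)
    trace, ranking = rfe_rank(table, selected_feats, config.selection, splits=splits)
    selection = select_optimal(ranking, config.selection)

    perf_selected: ModelPerformance | None = None
    if selection.admissible:
        perf_selected = bootstrap_performance(
            selection.selected, table, splits, threshold=config.threshold
        )
    perf_all = bootstrap_performance(
        selected_feats, table, splits, threshold=config.threshold
    )

    report = {
        "provenance": {
            "package": "stsfrail",
            "version": __version__,
            "config_hash": _config_hash(config),
            "config": _config_dict(config),
            "generated_at": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        },
        "n_subjects": int(len(table)),
        "invalid_trials": invalid,
        "stats": [dataclasses.asdict(r) for r in test_results],
        "significant_features": selected_feats,
        "rfe": {
            "n_loo_fits": trace.n_loo_fits,
            "loops": [
                {
                    "remaining": list(lp.remaining),
                    "loo_auc": lp.loo_auc,
                    "eliminated": lp.eliminated,
                }
                for lp in trace.loops
            ],
        },
        "ranking": [
            {"rank": i + 1, "feature": f, "phenotype": ranking.phenotypes[f]}
            for i, f in enumerate(ranking.features)
        ],
        "subset_auc_curve": {str(k): v for k, v in ranking.subset_auc.items()},
        "selection": {
            "admissible": selection.admissible,
            "selected": list(selection.selected),
            "k": selection.k,
            "auc": selection.auc,
        },
        "performance_selected": perf_selected.as_dict() if perf_selected else None,
        "performance_all_significant": perf_all.as_dict(),
    }

    if config.out_dir is not None:
        write_report(report, config.out_dir, table=table)
    return report


def write_report(report: dict, out_dir: str | Path, table: pd.DataFrame | None = None) -> None:
    """Write the JSON run report (and the feature table, if given)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, allow_nan=True)
    if table is not None:
        write_feature_table(table, out / "feature_table.csv")
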