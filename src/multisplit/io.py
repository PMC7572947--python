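"""File schemas, study configuration, and the end-to-end study runner.

All tables are RFC 4180 CSV with a header row, UTF-8, and optional leading
``#`` comment lines (used to stamp the config hash into every output).
Lung sides are "left"/"right", zones and regions "upper"/"middle"/"lower",
emphysema types full lowercase names, scores integer 0-3.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import analysis as an
from . import krippendorff as ka
from .assignment import AssignmentPlan, assignment_summary, sample_reader_tasks
from .design import ScanGeometry, ZONES, design_study
from .errors import SchemaError
from .simulate import (
    ALL_TYPES,
    Cutpoints,
    SimParams,
    simulate_annotations,
    simulate_reading_times,
    simulate_readers,
    simulate_regional_scores,
    simulate_subjects,
)

logger = logging.getLogger(__name__)

SIDES = ("left", "right")

GEOMETRY_COLUMNS = [
    "subject_id", "n_slices", "slice_thickness_mm",
    "apex_idx", "carina_idx", "vein_idx", "base_idx",
]
CHUNK_COLUMNS = ["subject_id", "chunk_idx", "start_slice", "end_slice", "zone", "is_multi_reader"]
PLAN_COLUMNS = ["reader_id", "subject_id", "chunk_idx", "is_multi_reader"]
ANNOTATION_COLUMNS = ["reader_id", "subject_id", "chunk_idx", "side", "emphysema_type", "score"]
REGIONAL_COLUMNS = ["subject_id", "side", "region", "emphysema_type", "score"]


# ---------------------------------------------------------------------------
# table I/O with validation
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns {missing}", file=str(path))


def _check_enum(df: pd.DataFrame, column: str, allowed, path) -> None:
    bad = ~df[column].isin(allowed)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"value {df[column].iloc[row]!r} not in {sorted(map(str, allowed))}",
            file=str(path), row=row, column=column,
        )


def _check_coupling(df: pd.DataFrame, path) -> None:
    """score = 0 must coincide exactly with emphysema_type = 'none'."""
    bad = (df["score"] == 0) != (df["emphysema_type"] == "none")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"type {df['emphysema_type'].iloc[row]!r} with score "
            f"{df['score'].iloc[row]} violates the score/type coupling",
            file=str(path), row=row, column="emphysema_type",
        )


def _validate(df: pd.DataFrame, kind: str, path) -> pd.DataFrame:
    if kind == "geometry":
        _require_columns(df, GEOMETRY_COLUMNS, path)
    elif kind == "chunks":
        _require_columns(df, CHUNK_COLUMNS, path)
        df["is_multi_reader"] = df["is_multi_reader"].astype(bool)
        _check_enum(df, "zone", ZONES, path)
    elif kind == "plan":
        _require_columns(df, PLAN_COLUMNS, path)
        df["is_multi_reader"] = df["is_multi_reader"].astype(bool)
    elif kind == "annotations":
        _require_columns(df, ANNOTATION_COLUMNS, path)
        _check_enum(df, "side", SIDES, path)
        _check_enum(df, "emphysema_type", ALL_TYPES, path)
        _check_enum(df, "score", (0, 1, 2, 3), path)
        _check_coupling(df, path)
    elif kind == "regional":
        _require_columns(df, REGIONAL_COLUMNS, path)
        _check_enum(df, "side", SIDES, path)
        _check_enum(df, "region", ZONES, path)
        _check_enum(df, "emphysema_type", ALL_TYPES, path)
        _check_enum(df, "score", (0, 1, 2, 3), path)
        _check_coupling(df, path)
    else:
        raise ValueError(f"unknown table kind {kind!r}")
    return df


def read_table(path, kind: str) -> pd.DataFrame:
    """Read and validate one of the study tables (see module docstring)."""
    df = pd.read_csv(path, comment="#")
    return _validate(df, kind, path)


def write_table(df: pd.DataFrame, path, kind: str | None = None, header_comment: str | None = None) -> None:
    """Write a study table; optionally stamp a comment line above the header."""
    if kind is not None:
        _validate(df.copy(), kind, path)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def read_geometries(path) -> list[ScanGeometry]:
    """Read scan geometries from CSV or JSON (list of records)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text(encoding="utf-8"))
        df = pd.DataFrame(records)
        _require_columns(df, GEOMETRY_COLUMNS, path)
    else:
        df = read_table(path, "geometry")
    return [
        ScanGeometry(
            subject_id=str(r.subject_id),
            n_slices=int(r.n_slices),
            slice_thickness_mm=float(r.slice_thickness_mm),
            apex_idx=int(r.apex_idx),
            carina_idx=int(r.carina_idx),
            vein_idx=int(r.vein_idx),
            base_idx=int(r.base_idx),
        )
        for r in df.itertuples(index=False)
    ]


def geometries_to_frame(geometries: list[ScanGeometry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (g.subject_id, g.n_slices, g.slice_thickness_mm,
             g.apex_idx, g.carina_idx, g.vein_idx, g.base_idx)
            for g in geometries
        ],
        columns=GEOMETRY_COLUMNS,
    )


# ---------------------------------------------------------------------------
# study configuration
# ---------------------------------------------------------------------------

class StudyConfig(BaseModel):
    """Everything needed to run a full synthetic study, seeds included."""

    n_subjects: int = Field(default=102, ge=1)
    n_readers: int = Field(default=26, ge=1)
    quota_multi: int = Field(default=75, ge=0)
    quota_single: int = Field(default=100, ge=0)

    # latent-field parameters
    mean_severity: float = -0.5
    severity_sd: float = Field(default=1.0, ge=0)
    apical_gradient: float = Field(default=0.8, ge=0)
    smoothness_sd: float = Field(default=0.15, ge=0)
    control_fraction: float = Field(default=6 / 102, ge=0, le=1)

    # cutpoints of the ordinal scale
    c1: float = 0.5
    c2: float = 1.5
    c3: float = 2.5

    # reader population
    bias_sd: float = Field(default=0.3, ge=0)
    noise_sd: float = Field(default=0.5, ge=0)
    type_confusion_prob: float = Field(default=0.10, ge=0, le=1)

    # reading times
    median_normal_s: float = Field(default=10.0, gt=0)
    median_emph_s: float = Field(default=20.0, gt=0)
    log_sd: float = Field(default=0.5, ge=0)
    pause_prob: float = Field(default=0.02, ge=0, le=1)

    # bootstrap
    n_boot: int = Field(default=1000, ge=1)
    level: float = Field(default=0.95, gt=0, lt=1)

    seed: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _ordered_cutpoints(self):
        if not (self.c1 < self.c2 < self.c3):
            raise ValueError("cutpoints must satisfy c1 < c2 < c3")
        return self

    def sim_params(self) -> SimParams:
        return SimParams(
            mean_severity=self.mean_severity,
            severity_sd=self.severity_sd,
            apical_gradient=self.apical_gradient,
            smoothness_sd=self.smoothness_sd,
            control_fraction=self.control_fraction,
            control_ceiling=self.c1 - 0.75,
        )

    def cutpoints(self) -> Cutpoints:
        return Cutpoints(self.c1, self.c2, self.c3)

    def stage_seeds(self) -> dict[str, int]:
        """Deterministic per-stage seeds derived from the master seed."""
        state = np.random.SeedSequence(self.seed).generate_state(7)
        names = ["subjects", "assignment", "readers", "annotations", "times",
                 "regional", "bootstrap"]
        return {k: int(v) & 0x7FFFFFFF for k, v in zip(names, state)}

    def hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def read_config(path) -> StudyConfig:
    return StudyConfig.model_validate(json.loads(Path(path).read_text(encoding="utf-8")))


# ---------------------------------------------------------------------------
# end-to-end runner
# ---------------------------------------------------------------------------

def _jsonable(obj):
    """Recursively convert numpy scalars/arrays; map non-finite floats to None."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if np.isfinite(f) else None
    return obj


def run_study(config: StudyConfig, out_dir=None) -> dict:
    """Design, assign, simulate and analyze one full synthetic study.

    Executes every stage of the pipeline and returns the results bundle as
    a dict; when ``out_dir`` is given, writes all tables plus
    ``summary.json``.  Bit-identical outputs for identical config.
    """
    seeds = config.stage_seeds()
    chash = config.hash()
    stage = "subjects"
    try:
        cohort = simulate_subjects(config.n_subjects, config.sim_params(), seeds["subjects"])
        geometries = [g for g, _ in cohort]
        truths = [t for _, t in cohort]

        stage = "design"
        chunks = design_study(geometries)

        stage = "assignment"
        key = chunks.set_index(["subject_id", "chunk_idx"])["is_multi_reader"]
        multi_ids = [tuple(i) for i in key[key].index]
        single_ids = [tuple(i) for i in key[~key].index]
        plan = sample_reader_tasks(
            multi_ids, single_ids, config.n_readers,
            config.quota_multi, config.quota_single, seeds["assignment"],
        )
        summary_tables = assignment_summary(plan)

        stage = "annotation simulation"
        profiles = simulate_readers(
            config.n_readers, config.bias_sd, config.noise_sd,
            config.type_confusion_prob, seeds["readers"],
        )
        annotations = simulate_annotations(
            truths, plan, profiles, config.cutpoints(), seeds["annotations"]
        )
        annotations = simulate_reading_times(
            annotations, config.median_normal_s, config.median_emph_s,
            config.log_sd, config.pause_prob, seeds["times"],
        )
        regional = simulate_regional_scores(
            truths, chunks, config.cutpoints(), seed=seeds["regional"]
        )

        stage = "reliability analysis"
        alphas = ka.alpha_by_zone(
            annotations, chunks, n_boot=config.n_boot,
            level=config.level, seed=seeds["bootstrap"],
        )

        stage = "reader-bias analysis"
        tables = an.reader_distribution_tables(annotations, chunks, regional)
        chi2 = {
            name: dict(zip(("statistic", "df", "p"), an.chi2_homogeneity(tab)))
            for name, tab in tables.items()
        }

        stage = "consistency analysis"
        chunk_scores = an.chunk_score_table(annotations, chunks)
        consistency = an.adjacent_differences(chunk_scores)
        outliers = an.flag_outlier_chunks(chunk_scores)

        stage = "validity analysis"
        validity = an.validity_crosstab(chunk_scores, regional)

        stage = "reading-time analysis"
        timing = an.reading_time_analysis(annotations)
    except Exception as exc:
        exc.add_note(f"study stage: {stage}")
        raise

    results = {
        "config": config.model_dump(),
        "config_hash": chash,
        "stage_seeds": seeds,
        "design": {
            "n_subjects": len(geometries),
            "n_chunks": int(len(chunks)),
            "n_multi_reader_chunks": int(chunks["is_multi_reader"].sum()),
            "n_single_reader_chunks": int((~chunks["is_multi_reader"]).sum()),
        },
        "assignment": {
            "n_rows": int(len(plan.table)),
            "per_reader_tasks": summary_tables["per_reader"]["n_tasks"].tolist(),
            "median_readers_per_multi_chunk": float(
                summary_tables["per_chunk"]["n_readers"].median()
            ),
        },
        "alpha": alphas.to_dict(orient="records"),
        "reader_bias_chi2": chi2,
        "consistency": {
            "histogram": consistency.histogram,
            "median_abs_difference": consistency.median,
            "n_flagged_outliers": int(len(outliers)),
        },
        "validity": {
            "counts": validity.counts.to_numpy().tolist(),
            "row_proportions": validity.proportions.round(6).to_numpy().tolist(),
            "chi2": {
                "statistic": validity.chi2_stat,
                "df": validity.chi2_df,
                "p": validity.chi2_p,
            },
            "n_missing_regions": validity.n_missing_regions,
            "n_excluded_chunk_sides": validity.n_excluded_chunk_sides,
        },
        "reading_time": {
            "median_s": timing.median_s,
            "iqr_s": timing.iqr_s,
            "median_emphysema_s": timing.median_emphysema_s,
            "median_normal_s": timing.median_normal_s,
            "p_value": timing.p_value,
            "n_excluded_pauses": timing.n_excluded_pauses,
        },
    }
    results = _jsonable(results)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        comment = f"config_hash={chash}"
        write_table(geometries_to_frame(geometries), out / "geometry.csv", "geometry", comment)
        write_table(chunks, out / "chunks.csv", "chunks", comment)
        write_table(plan.table, out / "plan.csv", "plan", comment)
        write_table(annotations, out / "annotations.csv", "annotations", comment)
        write_table(regional, out / "regional.csv", "regional", comment)
        write_table(chunk_scores, out / "chunk_scores.csv", None, comment)
        (out / "summary.json").write_text(
            json.dumps(results, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    return results
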