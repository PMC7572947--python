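"""Synthetic reader-study generator.

Emulates a multi-reader multi-split emphysema annotation study: subject
geometries whose chunk counts match a real screening cohort (23-33 chunks,
mean ~28), a latent per-chunk severity field with apical predominance and
cranio-caudal smoothness, reader profiles with additive bias and noise on
the latent scale, ordinal scores obtained by thresholding (an ordered
-threshold / ordered-probit reader model), emphysema-type reports with a
confusion probability, and lognormal per-chunk reading times with
occasional pauses.

The generative model is deliberately minimal: a subject-level severity
``S_j ~ Normal(mean_severity, severity_sd)``, a non-negative apical
gradient ``g_j`` decaying linearly from apex to base, and a random-walk
roughness term shared between the two lungs with independent per-side
perturbations.  Readers see ``s + bias_r + Normal(0, noise_sd_r)`` and bin
it at fixed cutpoints into the ordinal 0-3 scale (none / mild / moderate /
severe).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assignment import AssignmentPlan
from .design import ScanGeometry, slices_per_chunk
from .errors import InvalidParameterError, UnknownReaderError

logger = logging.getLogger(__name__)

SIDES = ("left", "right")
EMPHYSEMA_TYPES = ("centrilobular", "paraseptal", "combined", "panlobular", "bullae")
ALL_TYPES = ("none",) + EMPHYSEMA_TYPES

#: Marginal prevalence of emphysema subtypes among affected subjects
#: (centrilobular predominant, as in screening cohorts).
TYPE_PREVALENCE = (0.55, 0.20, 0.15, 0.05, 0.05)


@dataclass(frozen=True)
class Cutpoints:
    """Strictly increasing thresholds binning the latent scale into 0-3."""

    c1: float = 0.5
    c2: float = 1.5
    c3: float = 2.5

    def __post_init__(self):
        if not (self.c1 < self.c2 < self.c3):
            raise InvalidParameterError(
                f"cutpoints must be strictly increasing, got "
                f"({self.c1}, {self.c2}, {self.c3})"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.c1, self.c2, self.c3])


DEFAULT_CUTPOINTS = Cutpoints()


@dataclass(frozen=True)
class SimParams:
    """Latent-field parameters of the synthetic cohort.

    mean_severity / severity_sd
        Subject-level severity distribution on the latent scale (the
        default places most subjects below the first cutpoint, so the
        marginal score distribution is dominated by 0 and 1).
    apical_gradient
        Mean of the non-negative per-subject apex-to-base severity drop.
    smoothness_sd
        Per-step standard deviation of the cranio-caudal random walk;
        small values keep adjacent chunks nearly identical.
    control_fraction
        Fraction of emphysema-free subjects; their latent field is clamped
        below the lowest cutpoint.
    """

    mean_severity: float = -0.5
    severity_sd: float = 1.0
    apical_gradient: float = 0.8
    smoothness_sd: float = 0.15
    control_fraction: float = 6 / 102
    control_ceiling: float = DEFAULT_CUTPOINTS.c1 - 0.75

    def __post_init__(self):
        if self.severity_sd < 0 or self.smoothness_sd < 0:
            raise InvalidParameterError("standard deviations must be >= 0")
        if self.apical_gradient < 0:
            raise InvalidParameterError("apical_gradient must be >= 0")
        if not 0 <= self.control_fraction <= 1:
            raise InvalidParameterError("control_fraction must lie in [0, 1]")


@dataclass
class SubjectTruth:
    """Ground truth for one subject: type and latent severity per chunk-side."""

    subject_id: str
    true_type: str | None  # None for emphysema-free controls
    latent: dict[str, np.ndarray]  # side -> latent value per chunk_idx


@dataclass(frozen=True)
class ReaderProfile:
    """Reader behavior: latent-scale bias, rating noise, type confusion."""

    reader_id: str
    bias: float = 0.0
    noise_sd: float = 0.5
    type_confusion_prob: float = 0.10

    def __post_init__(self):
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if not 0 <= self.type_confusion_prob <= 1:
            raise InvalidParameterError("type_confusion_prob must lie in [0, 1]")


def simulate_readers(
    n_readers: int,
    bias_sd: float = 0.3,
    noise_sd: float = 0.5,
    type_confusion_prob: float = 0.10,
    seed: int = 0,
) -> list[ReaderProfile]:
    """Draw reader profiles: biases ~ Normal(0, bias_sd), noise jittered."""
    if n_readers < 1:
        raise InvalidParameterError("n_readers must be >= 1")
    rng = np.random.default_rng(seed)
    biases = rng.normal(0.0, bias_sd, size=n_readers)
    noise = noise_sd * np.exp(rng.normal(0.0, 0.15, size=n_readers))
    return [
        ReaderProfile(
            reader_id=f"R{r + 1:02d}",
            bias=float(biases[r]),
            noise_sd=float(noise[r]),
            type_confusion_prob=type_confusion_prob,
        )
        for r in range(n_readers)
    ]


def _simulate_geometry(subject_id: str, rng: np.random.Generator) -> ScanGeometry:
    """One scan geometry with a 23-33 chunk extent and thirds-ish landmarks."""
    thickness = 0.6
    spc = slices_per_chunk(thickness)  # 17
    n_chunks = int(np.clip(np.rint(rng.normal(28.0, 2.0)), 23, 33))
    extent = n_chunks * spc + int(rng.integers(0, spc))  # partial tail dropped
    apex = int(rng.integers(0, 8))
    base = apex + extent - 1
    carina = apex + int(np.rint(extent * rng.uniform(0.30, 0.37)))
    vein = apex + int(np.rint(extent * rng.uniform(0.63, 0.70)))
    n_slices = base + 1 + int(rng.integers(0, 10))
    return ScanGeometry(
        subject_id=subject_id,
        n_slices=n_slices,
        slice_thickness_mm=thickness,
        apex_idx=apex,
        carina_idx=carina,
        vein_idx=vein,
        base_idx=base,
    )


def simulate_subjects(
    n_subjects: int,
    params: SimParams = SimParams(),
    seed: int = 0,
) -> list[tuple[ScanGeometry, SubjectTruth]]:
    """Draw geometries and latent severity fields for a synthetic cohort."""
    if n_subjects < 1:
        raise InvalidParameterError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for j in range(n_subjects):
        sid = f"S{j + 1:03d}"
        geom = _simulate_geometry(sid, rng)
        spc = slices_per_chunk(geom.slice_thickness_mm)
        n_chunks = (geom.base_idx - geom.apex_idx + 1) // spc
        is_control = rng.random() < params.control_fraction

        s0 = rng.normal(params.mean_severity, params.severity_sd)
        g = rng.gamma(2.0, params.apical_gradient / 2.0) if params.apical_gradient > 0 else 0.0
        k = np.arange(n_chunks)
        trend = s0 + g * (1.0 - k / max(n_chunks - 1, 1))
        # roughness: a walk shared by both lungs plus per-side walks, so the
        # two sides track each other but are not identical
        step = params.smoothness_sd / np.sqrt(2.0)
        shared = np.cumsum(rng.normal(0.0, step, size=n_chunks))
        latent = {}
        for side in SIDES:
            own = np.cumsum(rng.normal(0.0, step, size=n_chunks))
            field_ = trend + shared + own
            if is_control:
                field_ = np.minimum(field_, params.control_ceiling)
            latent[side] = field_
        true_type = (
            None
            if is_control
            else str(rng.choice(EMPHYSEMA_TYPES, p=TYPE_PREVALENCE))
        )
        out.append((geom, SubjectTruth(subject_id=sid, true_type=true_type, latent=latent)))
    return out


def latent_table(truths: list[SubjectTruth]) -> pd.DataFrame:
    """Long table of latent severities: subject_id, side, chunk_idx, latent."""
    rows = []
    for t in truths:
        for side in SIDES:
            for k, v in enumerate(t.latent[side]):
                rows.append((t.subject_id, side, k, float(v)))
    return pd.DataFrame(rows, columns=["subject_id", "side", "chunk_idx", "latent"])


def simulate_annotations(
    truths: list[SubjectTruth],
    plan: AssignmentPlan,
    profiles: list[ReaderProfile],
    cutpoints: Cutpoints = DEFAULT_CUTPOINTS,
    seed: int = 0,
    chunks: pd.DataFrame | None = None,
    zone_noise_scale: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Render the annotation table the readers would produce.

    For every plan row, two assessments (left and right lung): the ordinal
    score bins ``latent + bias_r + Normal(0, noise_sd_r)`` at the
    cutpoints; the reported type is "none" iff the score is 0, otherwise
    the subject's true type, swapped for a uniformly random other
    emphysema type with the reader's confusion probability.

    ``zone_noise_scale`` (optional, requires ``chunks`` with zones)
    multiplies each reader's noise by a zone-specific factor — a handle for
    studying zone-dependent agreement.
    """
    rng = np.random.default_rng(seed)
    prof = {p.reader_id: p for p in profiles}
    for rid in plan.table["reader_id"].unique():
        if rid not in prof:
            raise UnknownReaderError(rid)

    truth_by_id = {t.subject_id: t for t in truths}
    missing = set(plan.table["subject_id"]) - set(truth_by_id)
    if missing:
        raise InvalidParameterError(f"plan references unknown subjects: {sorted(missing)}")

    lat = latent_table(list(truth_by_id.values()))
    base = plan.table.merge(lat, on=["subject_id", "chunk_idx"], how="left")
    if base["latent"].isna().any():
        bad = base[base["latent"].isna()][["subject_id", "chunk_idx"]].drop_duplicates()
        raise InvalidParameterError(
            f"plan references chunks outside the simulated extent: {bad.values.tolist()}"
        )

    bias = base["reader_id"].map({r: p.bias for r, p in prof.items()}).to_numpy()
    noise_sd = base["reader_id"].map({r: p.noise_sd for r, p in prof.items()}).to_numpy(float)
    if zone_noise_scale:
        if chunks is None:
            raise InvalidParameterError("zone_noise_scale requires the chunk table")
        zones = base.merge(
            chunks[["subject_id", "chunk_idx", "zone"]],
            on=["subject_id", "chunk_idx"],
            how="left",
        )["zone"]
        noise_sd = noise_sd * zones.map(lambda z: zone_noise_scale.get(z, 1.0)).to_numpy(float)

    noisy = base["latent"].to_numpy() + bias + rng.normal(0.0, 1.0, len(base)) * noise_sd
    score = np.digitize(noisy, cutpoints.as_array())

    true_type = base["subject_id"].map(
        {t.subject_id: (t.true_type or "") for t in truths}
    ).to_numpy(object)
    etype = np.where(score == 0, "none", true_type)
    pos = score > 0
    # controls carry no true type: an erroneous positive report draws one at random
    untyped = pos & (etype == "")
    if untyped.any():
        etype[untyped] = rng.choice(EMPHYSEMA_TYPES, size=int(untyped.sum()))
    confuse_p = base["reader_id"].map(
        {r: p.type_confusion_prob for r, p in prof.items()}
    ).to_numpy(float)
    confused = pos & (rng.random(len(base)) < confuse_p)
    for i in np.flatnonzero(confused):
        others = [t for t in EMPHYSEMA_TYPES if t != etype[i]]
        etype[i] = others[int(rng.integers(len(others)))]

    out = base[["reader_id", "subject_id", "chunk_idx", "side"]].copy()
    out["emphysema_type"] = etype
    out["score"] = score.astype(int)
    return out.sort_values(
        ["reader_id", "subject_id", "chunk_idx", "side"], ignore_index=True
    )


def simulate_reading_times(
    annotations: pd.DataFrame,
    median_normal_s: float = 10.0,
    median_emph_s: float = 20.0,
    log_sd: float = 0.5,
    pause_prob: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Attach one lognormal per-chunk reading time to each (reader, chunk).

    The lognormal median is ``median_emph_s`` when either lung side of the
    chunk was scored positive by that reader, else ``median_normal_s``.
    With probability ``pause_prob`` the time is inflated above 180 s to
    emulate a pause left running in the annotation application.
    """
    if median_normal_s <= 0 or median_emph_s <= 0:
        raise InvalidParameterError("medians must be > 0")
    if log_sd < 0 or not 0 <= pause_prob <= 1:
        raise InvalidParameterError("log_sd >= 0 and 0 <= pause_prob <= 1 required")
    rng = np.random.default_rng(seed)
    key = ["reader_id", "subject_id", "chunk_idx"]
    emph = annotations.groupby(key)["score"].max().gt(0)
    g = emph.reset_index().rename(columns={"score": "emph"})
    med = np.where(g["emph"], median_emph_s, median_normal_s)
    times = np.exp(np.log(med) + rng.normal(0.0, 1.0, len(g)) * log_sd)
    paused = rng.random(len(g)) < pause_prob
    times[paused] = 181.0 + rng.exponential(120.0, size=int(paused.sum()))
    g["reading_time_s"] = times
    out = annotations.merge(g[key + ["reading_time_s"]], on=key, how="left")
    return out


def simulate_regional_scores(
    truths: list[SubjectTruth],
    chunks: pd.DataFrame,
    cutpoints: Cutpoints = DEFAULT_CUTPOINTS,
    noise_sd: float = 0.25,
    missing_prob: float = 2 / 612,
    seed: int = 0,
) -> pd.DataFrame:
    """Regional reference ("eCRF"-style) scores derived from the latent field.

    For each (subject, side, region) the regional latent is a blend of the
    mean and the maximum of the region's chunk latents (a regional reader
    weighs the worst area more than the average) plus rating noise, binned
    at the same cutpoints.  Each region is missing with ``missing_prob``.
    Columns: subject_id, side, region, emphysema_type, score.
    """
    rng = np.random.default_rng(seed)
    truth_by_id = {t.subject_id: t for t in truths}
    rows = []
    for (sid, zone), grp in chunks.groupby(["subject_id", "zone"], sort=True):
        t = truth_by_id[sid]
        ks = grp["chunk_idx"].to_numpy()
        for side in SIDES:
            if rng.random() < missing_prob:
                continue
            vals = t.latent[side][ks]
            regional_latent = 0.5 * (vals.mean() + vals.max()) + rng.normal(0.0, noise_sd)
            score = int(np.digitize(regional_latent, cutpoints.as_array()))
            if score == 0:
                etype = "none"
            elif t.true_type is None:
                etype = str(rng.choice(EMPHYSEMA_TYPES))
            else:
                etype = t.true_type
            rows.append((sid, side, zone, etype, score))
    out = pd.DataFrame(
        rows, columns=["subject_id", "side", "region", "emphysema_type", "score"]
    )
    return out.sort_values(["subject_id", "side", "region"], ignore_index=True)
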