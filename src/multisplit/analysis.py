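"""Reliability and validity analyses of the annotation tables.

Covers reader-bias homogeneity (chi-square tests on readers x class
contingency tables), consensus aggregation of multi-reader assessments,
adjacent-chunk consistency and outlier flagging along the cranio-caudal
axis, validity cross-tabulation against regional reference ("eCRF")
scores, and the per-chunk reading-time comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateTableError, ReferentialIntegrityError
from .simulate import ALL_TYPES

logger = logging.getLogger(__name__)

SCORES = (0, 1, 2, 3)
#: Fixed tie-break order of emphysema types (least to most specific).
TYPE_RANK = {t: i for i, t in enumerate(ALL_TYPES)}

#: Reading times above this are treated as pauses, not assessments (3 min).
PAUSE_THRESHOLD_S = 180.0


# ---------------------------------------------------------------------------
# reader-bias contingency tables and homogeneity test
# ---------------------------------------------------------------------------

def reader_distribution_tables(
    annotations: pd.DataFrame,
    chunks: pd.DataFrame,
    regional: pd.DataFrame | None = None,
    multi_reader_only: bool = True,
) -> dict[str, pd.DataFrame]:
    """Readers x class contingency tables of scores, types, and eCRF scores.

    The first two tables count each reader's assigned scores (0-3) and
    emphysema types over both lung sides; the third counts the regional
    reference score of the region containing each assigned chunk, which
    should be homogeneous across readers when chunk assignment is random.
    """
    scope = annotations
    merged = scope.merge(
        chunks[["subject_id", "chunk_idx", "zone", "is_multi_reader"]],
        on=["subject_id", "chunk_idx"],
        how="left",
    )
    if merged["zone"].isna().any():
        bad = merged[merged["zone"].isna()][["subject_id", "chunk_idx"]].drop_duplicates()
        raise ReferentialIntegrityError(
            f"{len(bad)} annotated chunks missing from the chunk table",
            offenders=bad.values.tolist(),
        )
    if multi_reader_only:
        merged = merged[merged["is_multi_reader"]]

    score_tab = (
        merged.pivot_table(index="reader_id", columns="score", aggfunc="size", fill_value=0)
        .reindex(columns=list(SCORES), fill_value=0)
    )
    type_tab = (
        merged.pivot_table(
            index="reader_id", columns="emphysema_type", aggfunc="size", fill_value=0
        )
        .reindex(columns=[t for t in ALL_TYPES], fill_value=0)
    )
    out = {"score": score_tab, "type": type_tab}

    if regional is not None:
        reg = regional.rename(columns={"score": "ecrf_score"})
        withreg = merged.merge(
            reg[["subject_id", "side", "region", "ecrf_score"]],
            left_on=["subject_id", "side", "zone"],
            right_on=["subject_id", "side", "region"],
            how="left",
        )
        n_missing = int(withreg["ecrf_score"].isna().sum())
        if n_missing:
            logger.warning(
                "%d annotations fall in regions without an eCRF score; excluded "
                "from the eCRF distribution table", n_missing
            )
        withreg = withreg.dropna(subset=["ecrf_score"])
        ecrf_tab = (
            withreg.pivot_table(
                index="reader_id", columns="ecrf_score", aggfunc="size", fill_value=0
            )
            .reindex(columns=list(SCORES), fill_value=0)
        )
        ecrf_tab.columns = list(SCORES)
        out["ecrf"] = ecrf_tab
    return out


def chi2_homogeneity(table) -> tuple[float, int, float]:
    """Pearson chi-square test of row homogeneity on a contingency table.

    All-zero columns (and rows) are dropped before computing the degrees of
    freedom; no continuity correction is applied.  A warning is logged when
    any expected count falls below 5.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.sum() <= 0:
        raise DegenerateTableError("need a 2-D table with positive total")
    arr = arr[:, arr.sum(axis=0) > 0]
    arr = arr[arr.sum(axis=1) > 0, :]
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise DegenerateTableError(
            f"table degenerates to shape {arr.shape} after dropping empty rows/columns"
        )
    stat, p, df, expected = stats.chi2_contingency(arr, correction=False)
    if (expected < 5).any():
        logger.warning(
            "%d of %d expected counts are below 5; chi-square approximation "
            "may be inaccurate", int((expected < 5).sum()), expected.size
        )
    return float(stat), int(df), float(p)


# ---------------------------------------------------------------------------
# consensus aggregation
# ---------------------------------------------------------------------------

def consensus_score(assessments: list[tuple[str, int]]) -> tuple[str, int]:
    """Aggregate several (type, score) assessments of one chunk-side.

    The consensus type is the modal emphysema type, ties broken first by
    the higher total score mass carried by the tied type, then by the fixed
    category order.  The consensus score is the lower median of the scores
    among assessments carrying the modal type; a modal type of "none"
    forces score 0.
    """
    if not assessments:
        raise ValueError("consensus of an empty assessment list is undefined")
    by_type: dict[str, list[int]] = {}
    for t, s in assessments:
        by_type.setdefault(t, []).append(int(s))
    modal = min(
        by_type,
        key=lambda t: (-len(by_type[t]), -sum(by_type[t]), TYPE_RANK[t]),
    )
    if modal == "none":
        return "none", 0
    scores = sorted(by_type[modal])
    return modal, scores[(len(scores) - 1) // 2]  # lower median


def chunk_score_table(annotations: pd.DataFrame, chunks: pd.DataFrame) -> pd.DataFrame:
    """One final (type, score) per (subject, side, chunk): consensus or single.

    Multi-reader chunk-sides are aggregated with :func:`consensus_score`;
    single-reader chunk-sides keep their only assessment.  Returns columns
    subject_id, side, chunk_idx, zone, is_multi_reader, emphysema_type,
    score, n_readers.
    """
    merged = annotations.merge(
        chunks[["subject_id", "chunk_idx", "zone", "is_multi_reader"]],
        on=["subject_id", "chunk_idx"],
        how="left",
    )
    if merged["zone"].isna().any():
        bad = merged[merged["zone"].isna()][["subject_id", "chunk_idx"]].drop_duplicates()
        raise ReferentialIntegrityError(
            f"{len(bad)} annotated chunks missing from the chunk table",
            offenders=bad.values.tolist(),
        )
    rows = []
    key = ["subject_id", "side", "chunk_idx"]
    for (sid, side, k), grp in merged.groupby(key, sort=True):
        t, s = consensus_score(list(zip(grp["emphysema_type"], grp["score"])))
        rows.append(
            (sid, side, k, grp["zone"].iloc[0], bool(grp["is_multi_reader"].iloc[0]),
             t, s, grp["reader_id"].nunique())
        )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "side", "chunk_idx", "zone", "is_multi_reader",
                 "emphysema_type", "score", "n_readers"],
    )


# ---------------------------------------------------------------------------
# adjacent-chunk consistency
# ---------------------------------------------------------------------------

@dataclass
class ConsistencyResult:
    differences: np.ndarray  # absolute score differences of adjacent pairs
    histogram: dict[int, int]  # counts over difference values 0..3
    median: float


def _series_iter(chunk_scores: pd.DataFrame):
    """Yield per-(subject, side) score sequences over consecutive chunk runs."""
    for (sid, side), grp in chunk_scores.groupby(["subject_id", "side"], sort=True):
        grp = grp.sort_values("chunk_idx")
        idx = grp["chunk_idx"].to_numpy()
        sc = grp["score"].to_numpy()
        # split at gaps so only physically adjacent chunks are compared
        breaks = np.flatnonzero(np.diff(idx) != 1) + 1
        for seg_idx, seg_sc in zip(np.split(idx, breaks), np.split(sc, breaks)):
            yield sid, side, seg_idx, seg_sc


def adjacent_differences(chunk_scores: pd.DataFrame) -> ConsistencyResult:
    """Absolute score differences between adjacent chunks, per lung side.

    Severe next to none gives 3, one-step pairs give 1 — the plain absolute
    difference of the ordinal codes.  Sequences shorter than two chunks
    contribute nothing.
    """
    diffs = []
    for _, _, _, sc in _series_iter(chunk_scores):
        if len(sc) >= 2:
            diffs.append(np.abs(np.diff(sc)))
    all_d = np.concatenate(diffs) if diffs else np.array([], dtype=int)
    hist = {d: int((all_d == d).sum()) for d in range(4)}
    med = float(np.median(all_d)) if all_d.size else float("nan")
    return ConsistencyResult(differences=all_d, histogram=hist, median=med)


def flag_outlier_chunks(chunk_scores: pd.DataFrame, min_jump: int = 2) -> pd.DataFrame:
    """Flag chunks whose score jumps away from both neighbors.

    An interior chunk is flagged when its score differs by at least
    ``min_jump`` from both neighbors in the same direction (a spike or a
    dip); an end chunk when it differs by at least ``min_jump`` from its
    single neighbor.  Deterministic; returns subject_id, side, chunk_idx.
    """
    rows = []
    for sid, side, idx, sc in _series_iter(chunk_scores):
        n = len(sc)
        if n < 2:
            continue
        for i in range(n):
            if i == 0:
                hit = abs(sc[0] - sc[1]) >= min_jump
            elif i == n - 1:
                hit = abs(sc[-1] - sc[-2]) >= min_jump
            else:
                d_prev = sc[i] - sc[i - 1]
                d_next = sc[i] - sc[i + 1]
                hit = (
                    abs(d_prev) >= min_jump
                    and abs(d_next) >= min_jump
                    and np.sign(d_prev) == np.sign(d_next)
                )
            if hit:
                rows.append((sid, side, int(idx[i])))
    return pd.DataFrame(rows, columns=["subject_id", "side", "chunk_idx"])


# ---------------------------------------------------------------------------
# validity against regional reference scores
# ---------------------------------------------------------------------------

@dataclass
class ValidityResult:
    counts: pd.DataFrame  # eCRF score (rows) x chunk score (columns)
    proportions: pd.DataFrame  # row-normalized counts
    chi2_stat: float
    chi2_df: int
    chi2_p: float
    n_missing_regions: int  # regions without a reference score
    n_excluded_chunk_sides: int  # chunk-sides excluded for that reason


def validity_crosstab(
    chunk_scores: pd.DataFrame, regional: pd.DataFrame
) -> ValidityResult:
    """Cross-tabulate final chunk scores against regional reference scores.

    Each chunk-side maps to its (subject, side, region) cell through the
    chunk's lung zone; chunk-sides whose region lacks a reference score are
    excluded with a logged count.  Rows are reference scores 0-3, columns
    chunk scores 0-3; row proportions sum to 1; homogeneity across rows is
    tested with the Pearson chi-square.
    """
    if chunk_scores["zone"].isna().any():
        bad = chunk_scores[chunk_scores["zone"].isna()]
        raise ReferentialIntegrityError(
            f"{len(bad)} chunk-sides have no zone, cannot map to a region",
            offenders=bad[["subject_id", "chunk_idx"]].values.tolist(),
        )
    reg = regional.rename(columns={"score": "ecrf_score"})
    merged = chunk_scores.merge(
        reg[["subject_id", "side", "region", "ecrf_score"]],
        left_on=["subject_id", "side", "zone"],
        right_on=["subject_id", "side", "region"],
        how="left",
    )
    unmapped = merged[merged["ecrf_score"].isna()]
    n_excluded = int(len(unmapped))
    n_missing_regions = int(
        unmapped[["subject_id", "side", "zone"]].drop_duplicates().shape[0]
    )
    if n_excluded:
        logger.warning(
            "reference score missing for %d regions; excluded %d chunk-sides",
            n_missing_regions, n_excluded,
        )
    merged = merged.dropna(subset=["ecrf_score"])
    counts = (
        merged.pivot_table(index="ecrf_score", columns="score", aggfunc="size", fill_value=0)
        .reindex(index=list(SCORES), columns=list(SCORES), fill_value=0)
    )
    counts.index = list(SCORES)
    counts.columns = list(SCORES)
    counts.index.name = "ecrf_score"
    counts.columns.name = "chunk_score"
    row_sums = counts.sum(axis=1).replace(0, np.nan)
    proportions = counts.div(row_sums, axis=0)
    stat, df, p = chi2_homogeneity(counts.loc[counts.sum(axis=1) > 0])
    return ValidityResult(
        counts=counts,
        proportions=proportions,
        chi2_stat=stat,
        chi2_df=df,
        chi2_p=p,
        n_missing_regions=n_missing_regions,
        n_excluded_chunk_sides=n_excluded,
    )


# ---------------------------------------------------------------------------
# reading-time analysis
# ---------------------------------------------------------------------------

@dataclass
class ReadingTimeResult:
    median_s: float
    iqr_s: float
    median_emphysema_s: float
    median_normal_s: float
    p_value: float | None
    n_chunks: int
    n_excluded_pauses: int


def reading_time_analysis(annotations: pd.DataFrame) -> ReadingTimeResult:
    """Compare per-chunk reading times of emphysema vs normal chunks.

    One time per (reader, chunk); a chunk counts as emphysema when the
    annotating reader scored either lung side above 0.  Times strictly
    greater than 3 min are treated as pauses and excluded.  Groups are
    compared with the two-sided Wilcoxon rank-sum test (normal
    approximation with tie correction).
    """
    key = ["reader_id", "subject_id", "chunk_idx"]
    per_chunk = annotations.groupby(key).agg(
        reading_time_s=("reading_time_s", "first"),
        emph=("score", lambda s: bool((s > 0).any())),
    ).reset_index()
    per_chunk = per_chunk.dropna(subset=["reading_time_s"])
    pauses = per_chunk["reading_time_s"] > PAUSE_THRESHOLD_S
    n_excluded = int(pauses.sum())
    kept = per_chunk[~pauses]
    times = kept["reading_time_s"].to_numpy()
    emph_t = kept.loc[kept["emph"], "reading_time_s"].to_numpy()
    norm_t = kept.loc[~kept["emph"], "reading_time_s"].to_numpy()
    q1, med, q3 = (np.percentile(times, [25, 50, 75]) if times.size else (np.nan,) * 3)
    if emph_t.size and norm_t.size:
        if np.ptp(times) == 0:
            p = 1.0  # every kept time identical: tie-corrected variance is 0
        else:
            _, p = stats.mannwhitneyu(
                emph_t, norm_t, alternative="two-sided", method="asymptotic",
                use_continuity=False,
            )
            p = float(p)
    else:
        logger.warning("one reading-time group is empty; rank-sum test skipped")
        p = None
    return ReadingTimeResult(
        median_s=float(med),
        iqr_s=float(q3 - q1),
        median_emphysema_s=float(np.median(emph_t)) if emph_t.size else float("nan"),
        median_normal_s=float(np.median(norm_t)) if norm_t.size else float("nan"),
        p_value=p,
        n_chunks=int(len(kept)),
        n_excluded_pauses=n_excluded,
    )
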