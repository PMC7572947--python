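"""Krippendorff's alpha for nominal and ordinal data with missing ratings.

Alpha is the chance-corrected agreement coefficient for any number of
raters with arbitrary missingness (a not-fully-crossed design): units
rated fewer than twice are excluded, within-unit rating pairs are pooled
into a coincidence matrix with weight 1/(m_u - 1), and

    alpha = 1 - (n - 1) * sum_{c<k} o_ck d2(c,k) / sum_{c<k} n_c n_k d2(c,k)

where ``o`` is the coincidence matrix, ``n_c`` its marginals, ``n`` the
number of pairable ratings, and ``d2`` the squared difference function of
the measurement scale: the identity metric for nominal data, and
Krippendorff's cumulative-marginal difference for ordinal data,

    d2(c,k) = ( sum_{g=c..k} n_g - (n_c + n_k)/2 )^2 .

alpha = 1 is perfect agreement, alpha = 0 agreement expected by chance.
Unit-level bootstrap (resampling units with replacement) yields percentile
confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    InsufficientDataError,
    InvalidCategoryError,
    InvalidParameterError,
)

logger = logging.getLogger(__name__)

SCALES = ("nominal", "ordinal")


@dataclass
class ReliabilityData:
    """Units x readers rating matrix with missing entries.

    ``values`` holds category codes as floats with NaN for missing; for the
    ordinal scale the codes must be totally ordered integers (0-3 for the
    emphysema score).  One unit is one (chunk, lung side).
    """

    values: np.ndarray  # shape (n_units, n_readers), NaN = missing
    scale: str
    units: list | None = None
    readers: list | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidParameterError("values must be a 2-D units x readers array")
        if self.scale not in SCALES:
            raise InvalidParameterError(f"scale must be one of {SCALES}, got {self.scale!r}")

    @classmethod
    def from_long(
        cls,
        df: pd.DataFrame,
        unit_cols: list[str],
        reader_col: str,
        value_col: str,
        scale: str,
    ) -> "ReliabilityData":
        """Pivot a long annotation table into the units x readers matrix."""
        work = df.copy()
        if scale == "nominal":
            cats = sorted(work[value_col].astype(str).unique())
            work[value_col] = work[value_col].astype(str).map({c: i for i, c in enumerate(cats)})
        wide = work.pivot_table(
            index=unit_cols, columns=reader_col, values=value_col, aggfunc="first"
        )
        return cls(
            values=wide.to_numpy(dtype=float),
            scale=scale,
            units=list(wide.index),
            readers=list(wide.columns),
        )


@dataclass
class AlphaResult:
    """Point estimate with optional bootstrap interval and bookkeeping."""

    alpha: float
    scale: str
    n_units_used: int
    n_pairable_values: int
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int | None = None
    n_boot_dropped: int | None = None
    level: float | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "scale": self.scale,
            "n_units": self.n_units_used,
            "n_pairable_values": self.n_pairable_values,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


def _category_counts(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-unit category count matrix R (units x categories) and the codes."""
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise InsufficientDataError("no ratings at all")
    cats = np.unique(finite)
    R = np.zeros((values.shape[0], cats.size))
    for j, c in enumerate(cats):
        R[:, j] = np.nansum(values == c, axis=1)
    return R, cats


def _coincidence_from_counts(R: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Coincidence matrix o, marginals n_c, total n, units used, from R."""
    m = R.sum(axis=1)
    keep = m >= 2
    if not keep.any():
        raise InsufficientDataError("no unit carries two or more ratings")
    Rk = R[keep]
    mk = m[keep]
    W = Rk / (mk - 1)[:, None]
    o = W.T @ Rk
    o[np.diag_indices_from(o)] -= W.sum(axis=0)
    nc = Rk.sum(axis=0)
    return o, nc, float(nc.sum()), int(keep.sum())


def coincidence_matrix(data: ReliabilityData) -> tuple[np.ndarray, np.ndarray, float]:
    """Coincidence matrix over category pairs, its marginals, and total n.

    Units with fewer than two ratings are excluded; within each remaining
    unit every ordered pair of distinct rating slots contributes
    ``1/(m_u - 1)``.  The matrix is symmetric with marginals
    ``n_c = sum_k o_ck`` and ``n = sum_c n_c``.
    """
    R, _ = _category_counts(data.values)
    o, nc, n, _ = _coincidence_from_counts(R)
    return o, nc, n


def _delta_sq_matrix(nc: np.ndarray, scale: str) -> np.ndarray:
    """Squared-difference matrix over all category pairs."""
    k = nc.size
    if scale == "nominal":
        return 1.0 - np.eye(k)
    cum = np.cumsum(nc)
    lo = np.minimum.outer(np.arange(k), np.arange(k))
    hi = np.maximum.outer(np.arange(k), np.arange(k))
    seg = cum[hi] - np.where(lo > 0, cum[lo - 1], 0.0)
    d = seg - (nc[:, None] + nc[None, :]) / 2.0
    d[np.eye(k, dtype=bool)] = 0.0
    return d**2


def delta_sq(c, k, scale: str, marginals: np.ndarray | None = None, categories=None):
    """Squared difference between two categories under the given scale.

    Nominal: 0 if identical else 1.  Ordinal: squared difference of
    cumulative coincidence marginals between the two categories,
    ``(sum_{g=c..k} n_g - (n_c + n_k)/2)^2``, which weights category
    distances by how often intermediate categories are used.
    """
    if scale not in SCALES:
        raise InvalidParameterError(f"unknown scale {scale!r}")
    if scale == "nominal":
        return 0.0 if c == k else 1.0
    if marginals is None:
        raise InvalidParameterError("ordinal delta_sq requires coincidence marginals")
    marginals = np.asarray(marginals, dtype=float)
    if categories is None:
        categories = list(range(marginals.size))
    try:
        i, j = categories.index(c), categories.index(k)
    except ValueError as exc:
        raise InvalidCategoryError(f"category not found: {exc}") from None
    if i == j:
        return 0.0
    lo, hi = min(i, j), max(i, j)
    seg = marginals[lo : hi + 1].sum()
    return float((seg - (marginals[i] + marginals[j]) / 2.0) ** 2)


def _alpha_from_counts(R: np.ndarray, scale: str) -> tuple[float, float, int]:
    """(alpha, n, units_used) from a per-unit category count matrix."""
    o, nc, n, used = _coincidence_from_counts(R)
    d2 = _delta_sq_matrix(nc, scale)
    num = 0.5 * float((o * d2).sum())
    den = 0.5 * float(nc @ d2 @ nc)
    if den == 0.0:
        logger.warning(
            "expected disagreement is zero (all pairable ratings in one "
            "category); alpha undefined"
        )
        return float("nan"), n, used
    return 1.0 - (n - 1.0) * num / den, n, used


def krippendorff_alpha(data: ReliabilityData) -> AlphaResult:
    """Point estimate of Krippendorff's alpha for the data's scale."""
    R, _ = _category_counts(data.values)
    alpha, n, used = _alpha_from_counts(R, data.scale)
    return AlphaResult(
        alpha=alpha,
        scale=data.scale,
        n_units_used=used,
        n_pairable_values=int(round(n)),
    )


def bootstrap_ci(
    data: ReliabilityData,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> AlphaResult:
    """Percentile bootstrap CI for alpha, resampling units with replacement.

    Replicates with undefined alpha (zero expected disagreement) are
    dropped; their count is reported.  Deterministic under a fixed seed.
    """
    if n_boot < 1:
        raise InvalidParameterError("n_boot must be >= 1")
    if not 0 < level < 1:
        raise InvalidParameterError("level must lie in (0, 1)")
    point = krippendorff_alpha(data)
    R, _ = _category_counts(data.values)
    m = R.sum(axis=1)
    R = R[m >= 2]  # resample only pairable units
    n_units = R.shape[0]
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n_units, n_units)
        reps[b], _, _ = _alpha_from_counts(R[idx], data.scale)
    finite = reps[np.isfinite(reps)]
    dropped = n_boot - finite.size
    if dropped:
        logger.warning("dropped %d undefined bootstrap replicates", dropped)
    if finite.size == 0:
        raise InsufficientDataError("all bootstrap replicates undefined")
    lo, hi = np.quantile(finite, [(1 - level) / 2, 1 - (1 - level) / 2])
    point.ci_low = float(lo)
    point.ci_high = float(hi)
    point.n_boot = n_boot
    point.n_boot_dropped = dropped
    point.level = level
    point.seed = seed
    return point


def alpha_by_zone(
    annotations: pd.DataFrame,
    chunks: pd.DataFrame,
    n_boot: int | None = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Alpha per lung zone and overall, for type (nominal) and score (ordinal).

    Restricts the annotations to multi-reader chunks, builds one
    units-x-readers matrix per zone with (subject, chunk, side) units, and
    returns eight rows: {upper, middle, lower, overall} x {type, score}.
    Zones without a pairable unit yield an undefined (NaN) entry with a
    logged warning.
    """
    multi = chunks[chunks["is_multi_reader"]][["subject_id", "chunk_idx", "zone"]]
    ann = annotations.merge(multi, on=["subject_id", "chunk_idx"], how="inner")
    rows = []
    zone_sets = [("upper",), ("middle",), ("lower",), ("upper", "middle", "lower")]
    for zones in zone_sets:
        label = "overall" if len(zones) == 3 else zones[0]
        sub = ann[ann["zone"].isin(zones)]
        for scale, col in (("nominal", "emphysema_type"), ("ordinal", "score")):
            entry = {"zone": label, "variable": col, "scale": scale}
            try:
                data = ReliabilityData.from_long(
                    sub, ["subject_id", "chunk_idx", "side"], "reader_id", col, scale
                )
                if n_boot:
                    res = bootstrap_ci(data, n_boot=n_boot, level=level, seed=seed)
                else:
                    res = krippendorff_alpha(data)
                entry.update(res.to_dict())
            except InsufficientDataError:
                logger.warning("zone %s (%s): no pairable unit, alpha undefined", label, col)
                entry.update(
                    {"alpha": float("nan"), "ci_low": None, "ci_high": None,
                     "n_units": 0, "n_pairable_values": 0, "n_boot": n_boot, "seed": seed}
                )
            entry.pop("scale", None)
            entry["scale"] = scale
            rows.append(entry)
    return pd.DataFrame(rows)
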