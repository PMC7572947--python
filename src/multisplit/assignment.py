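"""Randomized distribution of reading tasks to readers.

Each reader receives a fixed quota of multi-reader chunks, sampled
independently per reader without replacement (so multi-reader chunks are
shared across readers and per-chunk reader counts disperse), plus a share
of the single-reader chunks, which are permuted once and dealt round-robin
so that every single-reader chunk is assessed exactly once.  When the
single-chunk pool cannot fill every reader's quota, shares are kept as
equal as possible (spread <= 1) and a shortfall warning is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InfeasibleQuotaError, InvalidParameterError

logger = logging.getLogger(__name__)

ChunkId = tuple[str, int]  # (subject_id, chunk_idx)


@dataclass
class AssignmentPlan:
    """A reader-task table plus the seed that generated it.

    ``table`` columns: reader_id, subject_id, chunk_idx, is_multi_reader.
    """

    table: pd.DataFrame
    seed: int

    def __len__(self) -> int:
        return len(self.table)


def _chunk_frame(ids: list[ChunkId], flag: bool) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [s for s, _ in ids],
            "chunk_idx": [k for _, k in ids],
            "is_multi_reader": flag,
        }
    )


def sample_reader_tasks(
    multi_ids: list[ChunkId],
    single_ids: list[ChunkId],
    n_readers: int,
    quota_multi: int = 75,
    quota_single: int = 100,
    seed: int = 0,
) -> AssignmentPlan:
    """Build the randomized assignment plan for all readers.

    Parameters
    ----------
    multi_ids, single_ids
        Identifiers of the multi-reader and single-reader chunks.
    n_readers
        Number of readers; reader ids are ``R01`` ... ``R{n}``.
    quota_multi, quota_single
        Target per-reader chunk counts from each pool.
    seed
        Seed for the sampling; a fixed seed reproduces the plan exactly.
    """
    if n_readers < 1:
        raise InvalidParameterError(f"n_readers must be >= 1, got {n_readers}")
    if quota_multi < 0 or quota_single < 0:
        raise InvalidParameterError("quotas must be non-negative")
    if quota_multi > len(multi_ids):
        raise InfeasibleQuotaError(
            f"quota_multi={quota_multi} exceeds the {len(multi_ids)} "
            "available multi-reader chunks"
        )
    rng = np.random.default_rng(seed)
    reader_ids = [f"R{r + 1:02d}" for r in range(n_readers)]

    frames = []
    # multi-reader pool: independent without-replacement samples per reader
    for rid in reader_ids:
        pick = rng.choice(len(multi_ids), size=quota_multi, replace=False)
        f = _chunk_frame([multi_ids[i] for i in pick], True)
        f.insert(0, "reader_id", rid)
        frames.append(f)

    # single-reader pool: one global permutation, dealt round-robin
    n_single = len(single_ids)
    wanted = n_readers * quota_single
    if n_single < wanted:
        logger.warning(
            "single-reader pool shortfall: %d chunks for %d readers x quota %d "
            "(%d wanted); dealing as evenly as possible",
            n_single,
            n_readers,
            quota_single,
            wanted,
        )
    perm = rng.permutation(n_single)
    take = min(n_single, wanted)
    for r, rid in enumerate(reader_ids):
        idx = perm[r:take:n_readers]
        if len(idx) == 0:
            continue
        f = _chunk_frame([single_ids[i] for i in idx], False)
        f.insert(0, "reader_id", rid)
        frames.append(f)

    table = pd.concat(frames, ignore_index=True)
    return AssignmentPlan(table=table, seed=seed)


def assignment_summary(plan: AssignmentPlan) -> dict[str, pd.DataFrame]:
    """Per-chunk reader counts and per-reader task counts.

    Returns ``{"per_chunk": ..., "per_reader": ...}``; the per-chunk table
    covers multi-reader chunks (distinct readers per chunk), the per-reader
    table counts total, multi and single tasks.  Row counts reconcile with
    the plan.
    """
    t = plan.table
    multi = t[t["is_multi_reader"]]
    per_chunk = (
        multi.groupby(["subject_id", "chunk_idx"])["reader_id"]
        .nunique()
        .rename("n_readers")
        .reset_index()
    )
    per_reader = (
        t.groupby("reader_id")
        .agg(
            n_tasks=("is_multi_reader", "size"),
            n_multi=("is_multi_reader", "sum"),
        )
        .reset_index()
    )
    per_reader["n_single"] = per_reader["n_tasks"] - per_reader["n_multi"]
    assert per_reader["n_tasks"].sum() == len(t)
    return {"per_chunk": per_chunk, "per_reader": per_reader}
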