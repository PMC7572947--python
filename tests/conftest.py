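"""Shared fixtures: a canonical geometry and a synthetic-study factory."""

from __future__ import annotations

import pytest

from multisplit.assignment import sample_reader_tasks
from multisplit.design import ScanGeometry, design_study
from multisplit.simulate import (
    DEFAULT_CUTPOINTS,
    SimParams,
    simulate_annotations,
    simulate_reading_times,
    simulate_readers,
    simulate_regional_scores,
    simulate_subjects,
)


@pytest.fixture
def study_geometry() -> ScanGeometry:
    """A 476-slice apex-to-base extent of 0.6-mm slices: 28 chunks, 10/10/8 zones."""
    return ScanGeometry(
        subject_id="s1", n_slices=500, slice_thickness_mm=0.6,
        apex_idx=0, carina_idx=170, vein_idx=340, base_idx=475,
    )


def make_study(
    seed: int,
    n_subjects: int = 102,
    n_readers: int = 26,
    quota_multi: int = 75,
    quota_single: int = 100,
    params: SimParams = SimParams(),
    bias_sd: float = 0.3,
    noise_sd: float = 0.5,
    type_confusion_prob: float = 0.10,
    zone_noise_scale: dict | None = None,
    with_times: bool = False,
    with_regional: bool = False,
) -> dict:
    """Simulate one study end to end (no reliability analysis).

    Seeds for the stages are simple offsets of ``seed`` so each call is a
    fully independent replicate.
    """
    cohort = simulate_subjects(n_subjects, params, seed)
    geometries = [g for g, _ in cohort]
    truths = [t for _, t in cohort]
    chunks = design_study(geometries)
    flags = chunks.set_index(["subject_id", "chunk_idx"])["is_multi_reader"]
    plan = sample_reader_tasks(
        [tuple(i) for i in flags[flags].index],
        [tuple(i) for i in flags[~flags].index],
        n_readers, quota_multi, quota_single, seed + 1,
    )
    profiles = simulate_readers(
        n_readers, bias_sd, noise_sd, type_confusion_prob, seed + 2
    )
    annotations = simulate_annotations(
        truths, plan, profiles, DEFAULT_CUTPOINTS, seed + 3,
        chunks=chunks, zone_noise_scale=zone_noise_scale,
    )
    if with_times:
        annotations = simulate_reading_times(annotations, seed=seed + 4)
    out = {
        "geometries": geometries,
        "truths": truths,
        "chunks": chunks,
        "plan": plan,
        "profiles": profiles,
        "annotations": annotations,
    }
    if with_regional:
        out["regional"] = simulate_regional_scores(
            truths, chunks, DEFAULT_CUTPOINTS, seed=seed + 5
        )
    return out


@pytest.fixture(scope="session")
def default_study() -> dict:
    """One study-scale synthetic study reused across read-only tests."""
    return make_study(seed=7, with_times=True, with_regional=True)
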