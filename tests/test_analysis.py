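"""Reader-bias tests, consensus, consistency, validity, reading times."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_study
from multisplit.analysis import (
    adjacent_differences,
    chi2_homogeneity,
    chunk_score_table,
    consensus_score,
    flag_outlier_chunks,
    reader_distribution_tables,
    reading_time_analysis,
    validity_crosstab,
)
from multisplit.errors import DegenerateTableError, ReferentialIntegrityError


# ---------------------------------------------------------------------------
# chi-square homogeneity
# ---------------------------------------------------------------------------

class TestChi2Homogeneity:
    def test_identical_rows_give_zero_statistic(self):
        stat, df, p = chi2_homogeneity([[10, 20, 30], [10, 20, 30]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_diagonal_two_by_two(self):
        stat, df, p = chi2_homogeneity([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0)
        assert df == 1

    def test_zero_columns_dropped_before_df(self):
        stat, df, p = chi2_homogeneity([[10, 0, 5], [8, 0, 7]])
        assert df == 1  # (2-1) x (2-1) after the empty column is removed

    def test_degenerate_table_raises(self):
        with pytest.raises(DegenerateTableError):
            chi2_homogeneity([[5, 5]])
        with pytest.raises(DegenerateTableError):
            chi2_homogeneity([[5, 0], [7, 0]])

    def test_low_expected_counts_warned(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            chi2_homogeneity([[1, 2], [2, 1]])
        assert any("below 5" in r.message for r in caplog.records)


def test_reader_bias_detected_in_most_replicates():
    """Readers with spread-out biases produce significantly heterogeneous
    score and type tables (chi-square p < 0.001) in >= 18/20 studies."""
    hits_score = hits_type = 0
    for rep in range(20):
        study = make_study(seed=2000 + rep, with_regional=True)
        tables = reader_distribution_tables(
            study["annotations"], study["chunks"], study["regional"]
        )
        _, _, p_score = chi2_homogeneity(tables["score"])
        _, _, p_type = chi2_homogeneity(tables["type"])
        hits_score += p_score < 0.001
        hits_type += p_type < 0.001
    assert hits_score >= 18
    assert hits_type >= 18


def test_reader_distribution_tables_conserve_totals(default_study):
    tables = reader_distribution_tables(
        default_study["annotations"], default_study["chunks"],
        default_study["regional"], multi_reader_only=True,
    )
    multi = default_study["chunks"].set_index(["subject_id", "chunk_idx"])[
        "is_multi_reader"
    ]
    ann = default_study["annotations"]
    in_scope = ann.join(multi, on=["subject_id", "chunk_idx"])["is_multi_reader"].sum()
    assert tables["score"].to_numpy().sum() == in_scope
    assert tables["type"].to_numpy().sum() == in_scope
    # eCRF table may be smaller: regions with a missing reference are excluded
    assert tables["ecrf"].to_numpy().sum() <= in_scope
    pd.testing.assert_index_equal(tables["score"].index, tables["type"].index)


def test_biased_reader_row_has_elevated_high_score_mass():
    study = make_study(seed=31, bias_sd=0.0)
    ann = study["annotations"]
    # re-simulate reader R01 with a strong positive bias by shifting its rows
    from multisplit.simulate import ReaderProfile
    from multisplit.simulate import simulate_annotations

    profiles = [
        ReaderProfile(p.reader_id, bias=(1.2 if p.reader_id == "R01" else 0.0),
                      noise_sd=0.3, type_confusion_prob=0.0)
        for p in study["profiles"]
    ]
    ann = simulate_annotations(study["truths"], study["plan"], profiles, seed=32)
    tables = reader_distribution_tables(ann, study["chunks"])
    prop_high = tables["score"][[2, 3]].sum(axis=1) / tables["score"].sum(axis=1)
    assert prop_high["R01"] > prop_high.drop("R01").max()


def test_unjoinable_annotations_raise():
    study = make_study(seed=33, n_subjects=5, n_readers=2, quota_multi=5, quota_single=5)
    ann = study["annotations"].copy()
    ann.loc[0, "chunk_idx"] = 999
    with pytest.raises(ReferentialIntegrityError):
        reader_distribution_tables(ann, study["chunks"])


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "assessments, expected",
    [
        ([("centrilobular", 2)], ("centrilobular", 2)),
        ([("centrilobular", 1), ("centrilobular", 2), ("paraseptal", 1)],
         ("centrilobular", 1)),  # modal type, lower median of {1, 2}
        ([("none", 0), ("none", 0), ("centrilobular", 3)], ("none", 0)),
        ([("centrilobular", 1), ("paraseptal", 3)],
         ("paraseptal", 3)),  # count tie -> higher score mass wins
        ([("centrilobular", 2), ("paraseptal", 2)],
         ("centrilobular", 2)),  # full tie -> fixed category order
        ([("bullae", 1), ("bullae", 2), ("bullae", 2), ("bullae", 3)],
         ("bullae", 2)),  # even count: lower median
    ],
)
def test_consensus_score_cases(assessments, expected):
    assert consensus_score(assessments) == expected


def test_consensus_is_permutation_invariant():
    rng = np.random.default_rng(6)
    types = ["none", "centrilobular", "paraseptal", "combined"]
    for _ in range(50):
        items = [
            ("none", 0) if (t := types[rng.integers(4)]) == "none"
            else (t, int(rng.integers(1, 4)))
            for _ in range(rng.integers(1, 8))
        ]
        base = consensus_score(items)
        perm = [items[i] for i in rng.permutation(len(items))]
        assert consensus_score(perm) == base


def test_chunk_score_table_uses_consensus_and_singles(default_study):
    table = chunk_score_table(default_study["annotations"], default_study["chunks"])
    assert ((table["score"] == 0) == (table["emphysema_type"] == "none")).all()
    single = table[~table["is_multi_reader"]]
    assert (single["n_readers"] == 1).all()
    multi = table[table["is_multi_reader"]]
    assert multi["n_readers"].max() <= 26
    # every annotated chunk-side appears exactly once
    ann_units = default_study["annotations"][
        ["subject_id", "side", "chunk_idx"]
    ].drop_duplicates()
    assert len(table) == len(ann_units)


# ---------------------------------------------------------------------------
# adjacent-chunk consistency and outliers
# ---------------------------------------------------------------------------

def _series_frame(scores, subject="s1", side="left"):
    return pd.DataFrame(
        {
            "subject_id": subject,
            "side": side,
            "chunk_idx": range(len(scores)),
            "score": scores,
        }
    )


class TestAdjacentDifferences:
    def test_severe_next_to_none_is_three(self):
        res = adjacent_differences(_series_frame([0, 3]))
        assert list(res.differences) == [3]
        assert res.histogram == {0: 0, 1: 0, 2: 0, 3: 1}

    def test_constant_sequence_all_zero(self):
        res = adjacent_differences(_series_frame([2] * 10))
        assert res.median == 0.0
        assert res.histogram[0] == 9

    def test_single_chunk_series_contributes_nothing(self):
        res = adjacent_differences(_series_frame([1]))
        assert res.differences.size == 0
        assert np.isnan(res.median)

    def test_gap_in_chunk_indices_breaks_the_series(self):
        df = _series_frame([0, 0, 3, 3])
        df["chunk_idx"] = [0, 1, 5, 6]  # gap between 1 and 5
        res = adjacent_differences(df)
        assert list(res.differences) == [0, 0]

    def test_output_length_is_sum_of_len_minus_one(self, default_study):
        table = chunk_score_table(default_study["annotations"], default_study["chunks"])
        res = adjacent_differences(table)
        expected = sum(
            len(g) - 1 for _, g in table.groupby(["subject_id", "side"])
        )
        assert res.differences.size == expected

    def test_default_simulation_median_zero(self, default_study):
        table = chunk_score_table(default_study["annotations"], default_study["chunks"])
        assert adjacent_differences(table).median == 0.0


class TestFlagOutlierChunks:
    def test_spike_flagged(self):
        flags = flag_outlier_chunks(_series_frame([0, 0, 3, 0, 0]))
        assert flags["chunk_idx"].tolist() == [2]

    def test_monotone_ramp_not_flagged(self):
        assert flag_outlier_chunks(_series_frame([0, 1, 2, 3])).empty

    def test_edge_jump_flagged(self):
        flags = flag_outlier_chunks(_series_frame([3, 0, 0, 0]))
        assert flags["chunk_idx"].tolist() == [0]

    def test_step_change_not_flagged_as_interior_outlier(self):
        # a sustained step is not a spike: interior chunks agree with one side
        flags = flag_outlier_chunks(_series_frame([0, 0, 0, 2, 2, 2]))
        assert 3 not in flags[
            (flags["chunk_idx"] > 0) & (flags["chunk_idx"] < 5)
        ]["chunk_idx"].tolist()

    def test_injection_recovery_on_smooth_simulation(self, default_study):
        """Substituting 1% of final scores with random other scores: at least
        half of the corrupted chunk-sides whose substitution jumps by >= 2
        (the outliers the rule is defined to catch; a +-1 change is ordinary
        reader variation and invisible to a min_jump=2 rule by construction)
        are flagged, while false flags stay <= 5%."""
        table = chunk_score_table(default_study["annotations"], default_study["chunks"])
        rng = np.random.default_rng(99)
        corrupted = table.copy().reset_index(drop=True)
        n_sub = int(round(0.01 * len(corrupted)))
        pos = rng.choice(len(corrupted), size=n_sub, replace=False)
        clear = []
        for i in pos:
            old = corrupted.loc[i, "score"]
            new = rng.choice([s for s in range(4) if s != old])
            corrupted.loc[i, "score"] = new
            if abs(new - old) >= 2:
                clear.append(i)
        flags = flag_outlier_chunks(corrupted)
        flagged = set(map(tuple, flags.to_numpy()))
        keys = ["subject_id", "side", "chunk_idx"]
        injected = set(map(tuple, corrupted.loc[pos, keys].to_numpy()))
        injected_clear = set(map(tuple, corrupted.loc[clear, keys].to_numpy()))
        recovered = len(flagged & injected_clear) / len(injected_clear)
        false_rate = len(flagged - injected) / (len(corrupted) - len(injected))
        assert recovered >= 0.5
        assert false_rate <= 0.05


# ---------------------------------------------------------------------------
# validity
# ---------------------------------------------------------------------------

def _regional_from(table, score_map=None):
    """Perfectly concordant regional table derived from chunk scores."""
    rows = []
    for (sid, side, zone), g in table.groupby(["subject_id", "side", "zone"]):
        score = int(g["score"].max()) if score_map is None else score_map
        etype = "none" if score == 0 else "centrilobular"
        rows.append((sid, side, zone, etype, score))
    return pd.DataFrame(
        rows, columns=["subject_id", "side", "region", "emphysema_type", "score"]
    )


class TestValidityCrosstab:
    def test_identical_scores_give_diagonal_matrix(self):
        table = pd.DataFrame(
            {
                "subject_id": ["s1"] * 6,
                "side": ["left"] * 3 + ["right"] * 3,
                "chunk_idx": [0, 1, 2] * 2,
                "zone": ["upper", "middle", "lower"] * 2,
                "score": [0, 1, 2, 0, 1, 2],
                "emphysema_type": ["none", "centrilobular", "centrilobular"] * 2,
            }
        )
        regional = pd.DataFrame(
            {
                "subject_id": ["s1"] * 6,
                "side": ["left"] * 3 + ["right"] * 3,
                "region": ["upper", "middle", "lower"] * 2,
                "emphysema_type": ["none", "centrilobular", "centrilobular"] * 2,
                "score": [0, 1, 2, 0, 1, 2],
            }
        )
        res = validity_crosstab(table, regional)
        off_diag = res.counts.to_numpy() - np.diag(np.diag(res.counts.to_numpy()))
        assert off_diag.sum() == 0

    def test_missing_regions_reported(self, default_study):
        table = chunk_score_table(default_study["annotations"], default_study["chunks"])
        regional = _regional_from(table)
        dropped = regional.iloc[2:]  # remove two regions
        res = validity_crosstab(table, dropped)
        assert res.n_missing_regions == 2
        assert res.n_excluded_chunk_sides > 0

    def test_row_proportions_sum_to_one(self, default_study):
        table = chunk_score_table(default_study["annotations"], default_study["chunks"])
        res = validity_crosstab(table, default_study["regional"])
        sums = res.proportions.sum(axis=1).dropna()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)
        assert res.counts.to_numpy().sum() + res.n_excluded_chunk_sides == len(table)

    def test_mild_regions_mix_none_and_mild_chunks(self, default_study):
        """Within-region heterogeneity: regions referenced as mild contain
        both unaffected and mild chunks."""
        table = chunk_score_table(default_study["annotations"], default_study["chunks"])
        res = validity_crosstab(table, default_study["regional"])
        mild_row = res.proportions.loc[1]
        assert mild_row[0] > 0.1 and mild_row[1] > 0.1
        assert res.chi2_p < 0.001


# ---------------------------------------------------------------------------
# reading times
# ---------------------------------------------------------------------------

def _timed_frame(times, scores):
    rows = []
    for i, (t, s) in enumerate(zip(times, scores)):
        for side in ("left", "right"):
            rows.append(("R1", "s1", i, side, "none" if s == 0 else "centrilobular",
                         s, t))
    return pd.DataFrame(
        rows,
        columns=["reader_id", "subject_id", "chunk_idx", "side", "emphysema_type",
                 "score", "reading_time_s"],
    )


class TestReadingTimeAnalysis:
    def test_pause_threshold_is_strict(self):
        df = _timed_frame([180.0, 180.5, 10.0, 12.0], [0, 0, 1, 0])
        res = reading_time_analysis(df)
        assert res.n_excluded_pauses == 1
        assert res.n_chunks == 3

    def test_identical_groups_give_p_one(self):
        df = _timed_frame([10.0, 10.0, 10.0, 10.0], [0, 1, 0, 1])
        res = reading_time_analysis(df)
        assert res.p_value == pytest.approx(1.0)

    def test_one_empty_group_skips_test(self):
        df = _timed_frame([10.0, 12.0], [0, 0])
        res = reading_time_analysis(df)
        assert res.p_value is None
        assert res.median_normal_s == pytest.approx(11.0)

    def test_longer_times_for_emphysema_detected_in_most_replicates(self):
        """Lognormal medians 20 s vs 10 s at study scale: rank-sum p < 0.001
        in >= 19/20 replicates."""
        hits = 0
        for rep in range(20):
            study = make_study(seed=3000 + rep, with_times=True)
            res = reading_time_analysis(study["annotations"])
            assert res.median_emphysema_s > res.median_normal_s
            hits += res.p_value < 0.001
        assert hits >= 19
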