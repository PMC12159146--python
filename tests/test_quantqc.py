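"""Peptide QC, normalization and MaxLFQ summarization."""

import numpy as np
import pandas as pd
import pytest

from diastab.quantqc import (
    LOG2_COL,
    average_replicates,
    drop_negative_log_peptides,
    filter_low_peptide_runs,
    log_median_normalize,
    maxlfq_summarize,
    replicate_concordance,
    run_qc,
    summarize_proteins,
)


def make_table(runs: dict[str, dict[str, float]], sample_of=None) -> pd.DataFrame:
    """Build a peptide table from {run_id: {peptide_id: intensity}}."""
    rows = []
    for run_id, peptides in runs.items():
        sample = (sample_of or {}).get(run_id, run_id.rsplit("_r", 1)[0])
        rep = int(run_id.rsplit("_r", 1)[1]) if "_r" in run_id else 1
        for pep, inten in peptides.items():
            rows.append({
                "run_id": run_id, "sample_id": sample, "replicate_index": rep,
                "peptide_id": pep, "protein_id": pep.split("_")[0],
                "intensity": inten,
            })
    return pd.DataFrame(rows)


class TestRunFilter:
    def test_strictly_below_threshold_removed_at_boundary(self):
        runs = {
            "a_r1": {f"P{i}_p" for i in range(4999)},
            "b_r1": {f"P{i}_p" for i in range(5000)},
        }
        table = make_table({r: {p: 100.0 for p in peps} for r, peps in runs.items()})
        out, log = filter_low_peptide_runs(table, min_peptides=5000)
        assert set(out["run_id"]) == {"b_r1"}
        assert log.removed_runs() == ["a_r1"]

    def test_zero_threshold_is_identity(self):
        table = make_table({"a_r1": {"P1_p1": 10.0}})
        out, _ = filter_low_peptide_runs(table, min_peptides=0)
        pd.testing.assert_frame_equal(out, table)

    def test_empty_table_raises(self):
        with pytest.raises(ValueError, match="empty"):
            filter_low_peptide_runs(make_table({}).reindex(columns=["run_id", "peptide_id"]))


class TestReplicateConcordance:
    def test_identical_replicates_retained(self, rng):
        peps = {f"P{i}_p": float(v) for i, v in enumerate(rng.uniform(10, 1000, 50))}
        table = make_table({"s1_r1": peps, "s1_r2": peps})
        out, log = replicate_concordance(table)
        assert set(out["run_id"]) == {"s1_r1", "s1_r2"}
        assert not log.removed_runs()

    def test_destroyed_association_triggers_removal(self, rng):
        vals = rng.uniform(10, 1000, 200)
        peps1 = {f"P{i}_p": float(v) for i, v in enumerate(vals)}
        perm = rng.permutation(vals)
        peps2 = {f"P{i}_p": float(v) for i, v in enumerate(perm)}
        # make r2 the smaller run so the drop rule is exercised deterministically
        peps2.pop("P0_p")
        table = make_table({"s1_r1": peps1, "s1_r2": peps2})
        out, log = replicate_concordance(table, min_r=0.8)
        assert log.removed_runs() == ["s1_r2"]
        assert set(out["run_id"]) == {"s1_r1"}

    def test_single_run_untouched(self):
        table = make_table({"s1_r1": {"P1_p1": 10.0, "P1_p2": 20.0}})
        out, log = replicate_concordance(table)
        pd.testing.assert_frame_equal(out, table)
        assert not log.events

    def test_too_few_shared_peptides_flagged_not_removed(self):
        table = make_table({
            "s1_r1": {"P1_p1": 10.0, "P1_p2": 20.0},
            "s1_r2": {"P1_p1": 30.0, "P1_p3": 15.0},
        })
        with pytest.warns(UserWarning, match="not assessable"):
            out, log = replicate_concordance(table)
        assert set(out["run_id"]) == {"s1_r1", "s1_r2"}
        assert log.events[0]["reason"] == "flagged_not_assessable"


class TestNormalization:
    def test_run_medians_meet_at_global_median(self):
        table = make_table({
            "a_r1": {"P1_p1": 2.0**10, "P1_p2": 2.0**10},
            "b_r1": {"P1_p1": 2.0**12, "P1_p2": 2.0**12},
        })
        out = log_median_normalize(table)
        med = out.groupby("run_id")[LOG2_COL].median()
        assert med.nunique() == 1
        assert med.iloc[0] == pytest.approx(11.0)

    def test_idempotent(self, rng):
        table = make_table({
            "a_r1": {f"P{i}_p": float(v) for i, v in enumerate(rng.uniform(1, 1e4, 30))},
            "b_r1": {f"P{i}_p": float(v) for i, v in enumerate(rng.uniform(1, 1e4, 30))},
        })
        once = log_median_normalize(table)
        twice = log_median_normalize(once)
        np.testing.assert_allclose(once[LOG2_COL], twice[LOG2_COL], atol=1e-12)

    def test_non_positive_intensity_names_record(self):
        table = make_table({"a_r1": {"P1_p1": 10.0, "P1_p2": -1.0}})
        with pytest.raises(ValueError, match="P1_p2"):
            log_median_normalize(table)


def test_drop_negative_log_peptides_boundary():
    table = make_table({"a_r1": {"P1_p1": 1.0, "P1_p2": 1.0, "P1_p3": 1.0}})
    table[LOG2_COL] = [-0.01, 0.0, 0.5]
    out = drop_negative_log_peptides(table)
    assert list(out["peptide_id"]) == ["P1_p2", "P1_p3"]


class TestMaxLfq:
    def test_single_peptide_two_runs_exact_difference(self):
        mat = pd.DataFrame([[10.0, 12.0]], index=["pep1"], columns=["r1", "r2"])
        profile, connected = maxlfq_summarize(mat)
        assert connected
        assert profile["r2"] - profile["r1"] == pytest.approx(2.0, abs=1e-12)

    def test_consistent_offsets_recover_profile(self, rng):
        truth = rng.normal(12, 1, size=8)
        offsets = rng.normal(0, 2, size=5)
        mat = pd.DataFrame(truth[None, :] + offsets[:, None],
                           columns=[f"r{i}" for i in range(8)])
        mat.iloc[0, 0] = np.nan
        mat.iloc[3, 7] = np.nan
        profile, _ = maxlfq_summarize(mat)
        centered = profile.to_numpy() - profile.mean()
        np.testing.assert_allclose(centered, truth - truth.mean(), atol=1e-9)

    def test_inconsistent_three_run_system_matches_hand_solution(self):
        # two peptides giving conflicting pairwise medians
        mat = pd.DataFrame(
            [[10.0, 11.0, np.nan], [np.nan, 20.0, 22.5], [5.0, np.nan, 6.0]],
            columns=["r1", "r2", "r3"],
        )
        # independent oracle: explicit incidence system + anchor row, lstsq
        r12 = np.median([11.0 - 10.0])
        r23 = np.median([22.5 - 20.0])
        r13 = np.median([6.0 - 5.0])
        anchor = np.mean([np.nanmedian([10.0, np.nan, 5.0]),
                          np.nanmedian([11.0, 20.0, np.nan]),
                          np.nanmedian([np.nan, 22.5, 6.0])])
        B = np.array([[1.0, -1.0, 0.0], [0.0, 1.0, -1.0], [1.0, 0.0, -1.0],
                      [1 / 3, 1 / 3, 1 / 3]])
        rhs = np.array([-r12, -r23, -r13, anchor])
        expected, *_ = np.linalg.lstsq(B, rhs, rcond=None)
        profile, connected = maxlfq_summarize(mat)
        assert connected
        np.testing.assert_allclose(profile.to_numpy(), expected, atol=1e-9)

    def test_shift_equivariance(self, rng):
        mat = pd.DataFrame(rng.normal(10, 1, size=(4, 6)),
                           columns=[f"r{i}" for i in range(6)])
        mat[mat < 9.5] = np.nan
        base, _ = maxlfq_summarize(mat)
        shifted, _ = maxlfq_summarize(mat + 3.0)
        np.testing.assert_allclose(shifted.dropna(), base.dropna() + 3.0, atol=1e-9)

    def test_disconnected_components_anchored_independently(self):
        mat = pd.DataFrame(
            [[10.0, 12.0, np.nan, np.nan], [np.nan, np.nan, 5.0, 6.0]],
            columns=list("abcd"),
        )
        profile, connected = maxlfq_summarize(mat)
        assert not connected
        np.testing.assert_allclose(profile.to_numpy(), [10.0, 12.0, 5.0, 6.0])

    def test_runs_without_peptides_stay_missing(self):
        mat = pd.DataFrame([[10.0, np.nan]], columns=["r1", "r2"])
        profile, _ = maxlfq_summarize(mat)
        assert profile["r1"] == pytest.approx(10.0)
        assert np.isnan(profile["r2"])


def test_average_replicates_missing_ignoring_mean():
    mat = pd.DataFrame(
        {"s1_r1": [5.0, 5.0, 7.0], "s1_r2": [7.0, np.nan, np.nan], "s2_r1": [1.0, 2.0, 3.0]},
        index=["P1", "P2", "P3"],
    )
    mapping = pd.Series({"s1_r1": "s1", "s1_r2": "s1", "s2_r1": "s2"})
    out = average_replicates(mat, mapping)
    assert out.loc["P1", "s1"] == 6.0
    assert out.loc["P2", "s1"] == 5.0  # missing-ignoring
    assert out.loc["P3", "s2"] == 3.0  # single replicate unchanged


def test_run_qc_output_is_subset_and_recovers_profiles(small_cohort):
    """End-to-end QC: run/protein sets shrink monotonically and per-protein
    profiles correlate strongly with the generating matrix."""
    peptides = small_cohort["peptides"]
    matrix, log = run_qc(peptides, min_peptides=100)
    assert set(matrix.columns) <= set(peptides["sample_id"])
    assert set(matrix.index) <= set(peptides["protein_id"])
    ff = small_cohort["ff"]
    common = matrix.columns.intersection(ff.columns)
    cors = []
    for pid in matrix.index[:50]:
        est = matrix.loc[pid, common]
        tru = ff.loc[pid, common]
        ok = est.notna() & tru.notna()
        if ok.sum() >= 10 and tru[ok].std() > 0.3:
            cors.append(np.corrcoef(est[ok], tru[ok])[0, 1])
    assert np.median(cors) > 0.95
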