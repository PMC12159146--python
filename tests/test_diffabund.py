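"""Differential abundance: moderated/plain t-tests, BH, selection rule."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from diastab.diffabund import (
    bh_adjust,
    estimate_variance_prior,
    moderated_t_test,
    select_dysregulated,
)


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Step-up BH by direct enumeration of the definition."""
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running_min = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * n / rank)
        adj[i] = running_min
    return adj


def two_group_matrix(rng, n_proteins=500, n_per_group=10, shift=0.0, sd=1.0):
    vals = rng.normal(10, sd, size=(n_proteins, 2 * n_per_group))
    vals[:, :n_per_group] += shift
    cols = [f"a{i}" for i in range(n_per_group)] + [f"b{i}" for i in range(n_per_group)]
    mat = pd.DataFrame(vals, columns=cols,
                       index=[f"P{i:04d}" for i in range(n_proteins)])
    groups = pd.Series(["g1"] * n_per_group + ["g2"] * n_per_group, index=cols)
    return mat, groups


class TestModeratedT:
    def test_identical_groups_give_zero_fold_change(self, rng):
        mat, groups = two_group_matrix(rng, n_proteins=20)
        mat.iloc[:, 10:] = mat.iloc[:, :10].to_numpy()
        res = moderated_t_test(mat, groups)
        np.testing.assert_allclose(res["log2_fold_change"], 0.0, atol=1e-12)

    def test_zero_prior_df_reproduces_pooled_t_exactly(self, rng):
        mat, groups = two_group_matrix(rng, n_proteins=200)
        res = moderated_t_test(mat, groups, prior_df=0)
        t, p = stats.ttest_ind(mat.iloc[:, :10], mat.iloc[:, 10:], axis=1,
                               equal_var=True)
        np.testing.assert_allclose(res["t_statistic"], t, atol=1e-12)
        np.testing.assert_allclose(res["p_value"], p, atol=1e-12)

    def test_label_swap_negates_statistics(self, rng):
        mat, groups = two_group_matrix(rng, n_proteins=50, shift=0.5)
        res = moderated_t_test(mat, groups)
        swapped = moderated_t_test(mat, groups.map({"g1": "g2", "g2": "g1"}))
        np.testing.assert_allclose(res["log2_fold_change"],
                                   -swapped["log2_fold_change"], atol=1e-12)
        np.testing.assert_allclose(res["t_statistic"], -swapped["t_statistic"],
                                   atol=1e-10)
        np.testing.assert_allclose(res["p_value"], swapped["p_value"], atol=1e-10)

    def test_shrinkage_pulls_variances_toward_prior(self, rng):
        """Moderated variance lies strictly between s^2 and s0^2."""
        sd = np.sqrt(1.0 / rng.chisquare(6, size=400) * 6)
        vals = rng.normal(0, 1, size=(400, 12)) * sd[:, None]
        s2 = vals[:, :6].var(axis=1, ddof=1) * 5 + vals[:, 6:].var(axis=1, ddof=1) * 5
        s2 /= 10
        d0, s0_sq = estimate_variance_prior(s2, np.full(400, 10.0))
        assert np.isfinite(d0) and d0 > 0
        s2_mod = (d0 * s0_sq + 10 * s2) / (d0 + 10)
        between = ((s2_mod > np.minimum(s2, s0_sq)) & (s2_mod < np.maximum(s2, s0_sq)))
        assert between[np.abs(s2 - s0_sq) > 1e-9].all()

    def test_constant_protein_reported_not_significant(self):
        mat = pd.DataFrame({f"a{i}": [5.0] for i in range(3)}
                           | {f"b{i}": [5.0] for i in range(3)}, index=["P1"])
        groups = pd.Series(["g1"] * 3 + ["g2"] * 3, index=mat.columns)
        res = moderated_t_test(mat, groups, prior="none")
        assert res.loc["P1", "p_value"] == 1.0
        assert "constant" in res.loc["P1", "note"]

    def test_sparse_protein_skipped_with_note(self, rng):
        mat, groups = two_group_matrix(rng, n_proteins=5)
        mat.iloc[0, 1:10] = np.nan  # one observation left in group 1
        res = moderated_t_test(mat, groups)
        assert np.isnan(res.iloc[0]["p_value"])
        assert res.iloc[0]["note"].startswith("skipped")

    def test_null_type_one_error_calibrated(self, rng):
        mat, groups = two_group_matrix(rng, n_proteins=2000)
        res = moderated_t_test(mat, groups)
        frac = float((res["p_value"] < 0.05).mean())
        assert abs(frac - 0.05) <= 0.01


class TestBh:
    def test_three_value_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(20):
            p = rng.uniform(1e-6, 1, size=int(rng.integers(1, 40)))
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_monotone_in_raw_p(self, rng):
        p = rng.uniform(0.001, 1, size=100)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestSelection:
    def test_threshold_examples(self, rng):
        res = pd.DataFrame({
            "log2_fold_change": [1.5, 0.5, -1.2, 2.0],
            "p_value": [0.04, 0.04, 0.03, 0.2],
            "adj_p": [0.1, 0.1, 0.1, 0.4],
        }, index=list("abcd"))
        out = select_dysregulated(res)
        assert out["selected"].tolist() == [True, False, True, False]

    def test_planted_shifts_recovered(self, rng):
        """100 proteins shifted by 1.5 log2 units among 1000 nulls."""
        mat, groups = two_group_matrix(rng, n_proteins=1000, n_per_group=20, sd=0.5)
        mat.iloc[:100, :20] += 1.5
        res = select_dysregulated(moderated_t_test(mat, groups))
        hits = set(res.index[res["selected"]])
        truth = set(mat.index[:100])
        sensitivity = len(hits & truth) / 100
        assert sensitivity >= 0.9
        # false hits consistent with the unadjusted p<0.05 + fold filter
        assert len(hits - truth) <= 0.05 * 900 + 10


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
def test_moderated_t_agrees_with_limma(tmp_path, rng):
    """Cross-check the empirical-Bayes machinery against limma's eBayes."""
    mat, groups = two_group_matrix(rng, n_proteins=120, n_per_group=6, shift=0.3)
    mat_path = tmp_path / "mat.tsv"
    mat.to_csv(mat_path, sep="\t")
    script = tmp_path / "limma_check.R"
    script.write_text(f"""
suppressMessages(library(limma))
m <- as.matrix(read.delim("{mat_path}", row.names = 1, check.names = FALSE))
design <- cbind(Intercept = 1, g1 = rep(c(1, 0), each = 6))
fit <- eBayes(lmFit(m, design))
out <- data.frame(t = fit$t[, "g1"], p = fit$p.value[, "g1"],
                  d0 = fit$df.prior, s0 = fit$s2.prior)
write.table(out, "{tmp_path / 'limma.tsv'}", sep = "\t", quote = FALSE)
""")
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    ref = pd.read_csv(tmp_path / "limma.tsv", sep="\t")
    res = moderated_t_test(mat, groups)
    np.testing.assert_allclose(res["t_statistic"], ref["t"], rtol=1e-4, atol=1e-6)
    np.testing.assert_allclose(res["p_value"], ref["p"], rtol=1e-3, atol=1e-8)
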