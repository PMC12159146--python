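"""ssGSEA scoring, derived signatures and per-patient site comparisons."""

import numpy as np
import pandas as pd
import pytest

from diastab.enrichment import compare_sites, dsi_score, ssgsea_score, star_category
from diastab.genesets import (
    DSI_ALIASES,
    GeneSet,
    dsi_proteins,
    read_gmt,
    stromal_score_proteins,
    write_gmt,
)


def brute_force_es(values: pd.Series, members: set, tau: float) -> float:
    """Independent loop-based single-sample GSEA running sum.

    Assumes no ties and no missing values; the most abundant of N genes
    has rank N and member steps are weighted rank^tau.
    """
    order = values.sort_values(ascending=False).index
    n = len(order)
    total_w = sum(
        (n - i) ** tau for i, g in enumerate(order) if g in members
    )
    n_out = n - sum(1 for g in order if g in members)
    cum_in = cum_out = 0.0
    es = 0.0
    for i, g in enumerate(order):
        if g in members:
            cum_in += (n - i) ** tau / total_w
        else:
            cum_out += 1.0 / n_out
        es += cum_in - cum_out
    return es


def random_matrix(rng, n_genes=50, n_samples=10):
    return pd.DataFrame(
        rng.normal(10, 2, size=(n_genes, n_samples)),
        index=[f"G{i:03d}" for i in range(n_genes)],
        columns=[f"S{j}" for j in range(n_samples)],
    )


class TestSsgsea:
    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            mat = random_matrix(rng)
            members = set(rng.choice(mat.index, size=8, replace=False))
            gs = GeneSet.from_iterable("toy", members)
            res = ssgsea_score(mat, gs, tau=0.25)
            for s in mat.columns:
                assert res.es[s] == pytest.approx(
                    brute_force_es(mat[s], members, 0.25), abs=1e-9)

    def test_rank_invariance_under_monotone_transform(self, rng):
        mat = random_matrix(rng)
        gs = GeneSet.from_iterable("toy", set(mat.index[:5]))
        base = ssgsea_score(mat, gs)
        warped = ssgsea_score(np.exp(mat / 3.0), gs)
        np.testing.assert_allclose(base.es, warped.es, atol=1e-12)

    def test_swapping_non_members_preserves_score(self, rng):
        mat = random_matrix(rng)
        gs = GeneSet.from_iterable("toy", set(mat.index[:5]))
        base = ssgsea_score(mat, gs)
        swapped = mat.copy()
        swapped.loc["G040"], swapped.loc["G041"] = (
            mat.loc["G041"].to_numpy(), mat.loc["G040"].to_numpy())
        res = ssgsea_score(swapped, gs)
        np.testing.assert_allclose(base.es, res.es, atol=1e-12)

    def test_nes_range_spans_one(self, rng):
        mat = random_matrix(rng)
        gs = GeneSet.from_iterable("toy", set(mat.index[:5]))
        res = ssgsea_score(mat, gs)
        assert res.nes.max() - res.nes.min() == pytest.approx(1.0)

    def test_no_member_in_matrix_raises(self, rng):
        mat = random_matrix(rng)
        with pytest.raises(ValueError, match="absent_set"):
            ssgsea_score(mat, GeneSet.from_iterable("absent_set", {"NOPE"}))

    def test_full_universe_set_raises(self, rng):
        mat = random_matrix(rng, n_genes=10)
        with pytest.raises(ValueError, match="whole universe"):
            ssgsea_score(mat, GeneSet.from_iterable("all", set(mat.index)))

    def test_missing_values_ranked_last(self, rng):
        """A member pushed to missing scores like one pushed to the bottom."""
        mat = random_matrix(rng)
        gs = GeneSet.from_iterable("toy", set(mat.index[:5]))
        lowered = mat.copy()
        lowered.loc["G000", "S0"] = mat.min().min() - 100.0
        missing = mat.copy()
        missing.loc["G000", "S0"] = np.nan
        a = ssgsea_score(lowered, gs).es["S0"]
        b = ssgsea_score(missing, gs).es["S0"]
        assert a == pytest.approx(b, abs=1e-12)

    def test_random_set_scores_roughly_symmetric(self, rng):
        """On exchangeable data the ES of a random set has no systematic sign
        after centering (permutation symmetry)."""
        mat = random_matrix(rng, n_genes=40, n_samples=200)
        gs = GeneSet.from_iterable("rand", set(rng.choice(mat.index, 6, replace=False)))
        es = ssgsea_score(mat, gs).es
        centered = es - es.mean()
        assert abs(np.mean(centered > 0) - 0.5) < 0.1


class TestDsiSet:
    def test_contains_printed_exemplars(self):
        gs = dsi_proteins()
        for sym in ("BST2", "CASP1", "CMPK2", "IFI35", "IFIT3", "ISG15"):
            assert sym in gs

    def test_contains_hr_overlap_members(self):
        overlap = {"ISG15", "DDX58", "CNTRL", "DAPL1", "HLA-DQB1",
                   "HLA-DRB3", "HLA-F", "MUC1", "MX1", "PFKP"}
        assert overlap <= dsi_proteins().members

    def test_aliases_only_on_request(self):
        verbatim = dsi_proteins()
        assert "PSM8" in verbatim and "PSMB8" not in verbatim
        aliased = dsi_proteins(apply_aliases=True)
        assert "PSMB8" in aliased and "PSM8" not in aliased
        assert DSI_ALIASES == {"PSM8": "PSMB8", "PSM9": "PSMB9"}

    def test_planted_omentum_elevation_detected(self, small_cohort):
        scores = dsi_score(small_cohort["ff"])
        meta = small_cohort["metadata"].loc[scores.nes.index]
        omentum = scores.nes[meta["site"] == "omentum"]
        ovary = scores.nes[meta["site"] == "ovary"]
        assert omentum.mean() > ovary.mean()


class TestCompareSites:
    def test_star_bins_are_right_closed(self):
        assert star_category(0.03) == "*"
        assert star_category(5e-2) == "*"
        assert star_category(1e-2) == "**"
        assert star_category(1e-3) == "***"
        assert star_category(1e-4) == "****"
        assert star_category(0.2) == "ns"

    def test_one_site_patient_skipped_with_note(self, rng):
        scores = pd.Series(rng.normal(size=6), index=[f"s{i}" for i in range(6)])
        meta = pd.DataFrame({
            "patient": ["A"] * 4 + ["B"] * 2,
            "site": ["ovary", "ovary", "omentum", "omentum", "ovary", "ovary"],
        }, index=scores.index)
        table = compare_sites(scores, meta)
        assert table.loc["B", "note"].startswith("skipped")
        assert np.isfinite(table.loc["A", "p"])

    def test_per_patient_detection_of_planted_shift(self, small_cohort):
        scores = dsi_score(small_cohort["ff"])
        meta = small_cohort["metadata"].loc[scores.nes.index]
        table = compare_sites(scores.nes, meta)
        tested = table["p"].notna()
        assert (table.loc[tested, "p"] <= 0.05).sum() >= 0.7 * tested.sum()


def test_gmt_round_trip(tmp_path):
    sets = [stromal_score_proteins(), dsi_proteins()]
    path = tmp_path / "sets.gmt"
    write_gmt(sets, path)
    back = read_gmt(path)
    assert [s.name for s in back] == [s.name for s in sets]
    assert all(a.members == b.members for a, b in zip(back, sets))
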