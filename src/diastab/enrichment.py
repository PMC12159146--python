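"""Single-sample gene-set enrichment (ssGSEA) and derived scores.

For one sample, proteins are ranked by decreasing abundance and the
enrichment score (ES) is the sum over all ranked positions of the
difference between the weighted empirical CDF of set members and the
uniform empirical CDF of non-members (the classic single-sample GSEA
running-sum statistic).  Member steps are weighted by rank^tau, where a
protein's rank is N for the most abundant of N proteins; tau defaults to
0.25.  Scores are range-normalized across the samples of one matrix
(NES = ES / (max ES - min ES)) so samples can be compared.

Missing abundances are ranked last by default (DIA missingness is
abundance-dependent); ties receive average ranks.

The derived scores are thin wrappers binding a bundled signature to
:func:`ssgsea_score`: the dsDNA-sensing/inflammation (DSI) score and the
20-protein stromal score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genesets import GeneSet, dsi_proteins, stromal_score_proteins

__all__ = [
    "EnrichmentScores",
    "ssgsea_score",
    "dsi_score",
    "stromal_score",
    "compare_sites",
    "star_category",
]


@dataclass
class EnrichmentScores:
    set_name: str
    tau: float
    es: pd.Series = field(repr=False)
    nes: pd.Series = field(repr=False)
    n_members_used: int = 0
    universe_size: int = 0


def _sample_es(values: np.ndarray, in_set: np.ndarray, tau: float) -> float:
    """Running-sum ES for one sample. ``values`` may contain NaN (ranked last)."""
    v = np.where(np.isnan(values), -np.inf, values)
    ranks = stats.rankdata(v, method="average")  # highest abundance -> rank N
    order = np.lexsort((np.arange(len(v)), -ranks))  # decreasing, index-stable
    member = in_set[order]
    w = np.where(member, ranks[order] ** tau, 0.0)
    n_out = len(v) - int(in_set.sum())
    cdf_in = np.cumsum(w) / w.sum()
    cdf_out = np.cumsum(~member) / n_out
    return float(np.sum(cdf_in - cdf_out))


def ssgsea_score(
    matrix: pd.DataFrame,
    gene_set: GeneSet,
    tau: float = 0.25,
    missing: str = "rank_last",
) -> EnrichmentScores:
    """ssGSEA score of one gene set for every sample (column) of a matrix.

    ``missing="rank_last"`` treats unquantified proteins as the lowest
    abundances; ``missing="drop"`` removes them from the sample's universe
    before ranking.
    """
    if missing not in ("rank_last", "drop"):
        raise ValueError("missing must be 'rank_last' or 'drop'")
    in_set = matrix.index.isin(gene_set.members)
    n_members = int(in_set.sum())
    if n_members == 0:
        raise ValueError(f"no member of gene set {gene_set.name!r} found in the matrix")
    if n_members == matrix.shape[0]:
        raise ValueError(
            f"gene set {gene_set.name!r} equals the whole universe; out-of-set ECDF undefined"
        )
    es = {}
    values = matrix.to_numpy(dtype=float)
    for k, sample in enumerate(matrix.columns):
        col = values[:, k]
        mask = np.ones(len(col), dtype=bool) if missing == "rank_last" else ~np.isnan(col)
        if missing == "drop" and (in_set & mask).sum() == 0:
            es[sample] = np.nan
            continue
        es[sample] = _sample_es(col[mask], in_set[mask], tau)
    es = pd.Series(es, name=f"ES_{gene_set.name}")
    span = float(es.max() - es.min())
    if span > 0:
        nes = es / span
    else:
        warnings.warn(f"all ES equal for set {gene_set.name!r}; NES left unnormalized")
        nes = es.copy()
    nes = nes.rename(f"NES_{gene_set.name}")
    return EnrichmentScores(
        set_name=gene_set.name,
        tau=tau,
        es=es,
        nes=nes,
        n_members_used=n_members,
        universe_size=matrix.shape[0],
    )


def dsi_score(matrix: pd.DataFrame, gene_set: GeneSet | None = None,
              tau: float = 0.25, **kwargs) -> EnrichmentScores:
    """dsDNA-sensing/inflammation score: ssGSEA of the DSI set.

    The bundled default set is explicitly partial (the full co-expression
    module holds 52 proteins); pass a complete set via ``gene_set`` when
    available.
    """
    return ssgsea_score(matrix, gene_set or dsi_proteins(), tau=tau, **kwargs)


def stromal_score(matrix: pd.DataFrame, tau: float = 0.25, **kwargs) -> EnrichmentScores:
    """Stromal content score: ssGSEA of the bundled 20-protein signature."""
    return ssgsea_score(matrix, stromal_score_proteins(), tau=tau, **kwargs)


def star_category(p: float) -> str:
    """Significance stars with right-closed bins at 5e-2, 1e-2, 1e-3, 1e-4."""
    if np.isnan(p):
        return "na"
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p <= 5e-2:
        return "*"
    return "ns"


def compare_sites(
    scores: pd.Series,
    metadata: pd.DataFrame,
    site_a: str = "ovary",
    site_b: str = "omentum",
) -> pd.DataFrame:
    """Per-patient two-sided independent t-test of a score between two sites.

    Patients lacking two samples at either site are kept in the output
    with a note and no statistic.
    """
    meta = metadata.loc[scores.index]
    rows = []
    for patient, grp in meta.groupby("patient"):
        a = scores[grp.index[grp["site"] == site_a]].dropna()
        b = scores[grp.index[grp["site"] == site_b]].dropna()
        row = {"patient": patient, f"n_{site_a}": len(a), f"n_{site_b}": len(b)}
        if len(a) < 2 or len(b) < 2:
            row.update(t=np.nan, p=np.nan, star="na",
                       note="skipped: needs >=2 samples per site")
        else:
            res = stats.ttest_ind(a, b)
            row.update(
                t=float(res.statistic), p=float(res.pvalue),
                star=star_category(float(res.pvalue)),
                note="",
                **{f"mean_{site_a}": float(a.mean()), f"mean_{site_b}": float(b.mean())},
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient")
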