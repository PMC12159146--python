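"""Group-wise differential protein abundance.

Two flavors of two-sample test on log2 abundances:

* ``prior="none"`` — ordinary Welch t-test per protein;
* ``prior="empirical_bayes"`` — pooled-variance t with the per-protein
  variance shrunk toward a common prior, s~^2 = (d0*s0^2 + d*s^2)/(d0 + d),
  referred to d0 + d degrees of freedom.  The prior (d0, s0^2) is
  estimated by the method of moments on the log residual variances
  (the scaled-F marginal of the hierarchical variance model), so the
  behavior matches moderated-t practice for label-free proteomics.

Fold change is the difference of group means on the log2 scale, reported
alongside the linear fold.  The conventional selection rule is
p < 0.05 and linear fold change > 2 (|log2FC| > 1); Benjamini-Hochberg
adjusted p-values are always provided.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "moderated_t_test",
    "bh_adjust",
    "select_dysregulated",
    "estimate_variance_prior",
]


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton, as used for the F-prior fit)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) / x < 1e-10:
            break
    return x


def estimate_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) from per-protein variances.

    Under the hierarchical model s^2 ~ s0^2 * F(df, d0); moments of
    log s^2 identify both parameters.  Returns (inf, geometric-mean
    variance) when the observed spread is no larger than expected from
    the chi-square sampling noise alone.
    """
    ok = (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        return float("inf"), float(np.median(s2[s2 > 0])) if (s2 > 0).any() else 1.0
    z = np.log(s2[ok])
    d = df[ok].astype(float)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(np.mean(special.polygamma(1, d / 2.0)))
    if e_var <= 0:
        # no excess spread beyond chi-square noise: infinite prior df, and
        # E[s^2] = s0^2 identifies the scale directly
        return float("inf"), float(np.mean(s2[ok]))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_t_test(
    matrix: pd.DataFrame,
    group_labels: pd.Series,
    prior: str = "empirical_bayes",
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Per-protein two-sample test between the two groups in ``group_labels``.

    Parameters
    ----------
    matrix
        proteins x samples, log2 abundances, NaN = missing.
    group_labels
        sample_id -> group; exactly two groups.  log2FC is mean(group1) -
        mean(group2) with groups in sorted label order.
    prior
        "none" for Welch t; "empirical_bayes" for the moderated pooled t.
    prior_df
        Force the prior degrees of freedom d0 (overrides estimation;
        d0 = 0 reproduces the ordinary pooled-variance t exactly).

    Proteins with fewer than 2 observations in either group are reported
    with NaN statistics and a note instead of being tested.
    """
    if prior not in ("none", "empirical_bayes"):
        raise ValueError("prior must be 'none' or 'empirical_bayes'")
    groups = sorted(pd.unique(group_labels.dropna()))
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    g1 = group_labels.index[group_labels == groups[0]].intersection(matrix.columns)
    g2 = group_labels.index[group_labels == groups[1]].intersection(matrix.columns)

    X1 = matrix[g1].to_numpy(dtype=float)
    X2 = matrix[g2].to_numpy(dtype=float)
    n1 = np.sum(~np.isnan(X1), axis=1)
    n2 = np.sum(~np.isnan(X2), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(X1, axis=1)
        m2 = np.nanmean(X2, axis=1)
        v1 = np.nanvar(X1, axis=1, ddof=1)
        v2 = np.nanvar(X2, axis=1, ddof=1)
    testable = (n1 >= 2) & (n2 >= 2)
    lfc = m1 - m2
    df_pool = n1 + n2 - 2
    s2 = np.where(df_pool > 0, ((n1 - 1) * v1 + (n2 - 1) * v2) / np.maximum(df_pool, 1), np.nan)

    t = np.full(matrix.shape[0], np.nan)
    p = np.full(matrix.shape[0], np.nan)
    df_used = np.full(matrix.shape[0], np.nan)
    notes = np.full(matrix.shape[0], "", dtype=object)
    notes[~testable] = "skipped: <2 observations in a group"

    if prior == "none":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            denom = np.sqrt(v1 / n1 + v2 / n2)
            tt = lfc / denom
            dfw = (v1 / n1 + v2 / n2) ** 2 / (
                (v1 / n1) ** 2 / np.maximum(n1 - 1, 1) + (v2 / n2) ** 2 / np.maximum(n2 - 1, 1)
            )
        sel = testable & (denom > 0)
        t[sel] = tt[sel]
        df_used[sel] = dfw[sel]
        p[sel] = 2.0 * stats.t.sf(np.abs(tt[sel]), dfw[sel])
        const = testable & (denom == 0)
    else:
        if prior_df is None:
            d0, s0_sq = estimate_variance_prior(s2[testable], df_pool[testable].astype(float))
        else:
            d0, s0_sq = float(prior_df), 0.0
            if d0 > 0:
                _, s0_sq = estimate_variance_prior(s2[testable], df_pool[testable].astype(float))
        # total df capped at the summed residual df (finite even for an
        # infinite prior, matching moderated-t practice)
        df_cap = float(np.sum(df_pool[testable]))
        if np.isinf(d0):
            s2_mod = np.full_like(s2, s0_sq)
            df_mod = np.full_like(s2, df_cap)
        else:
            s2_mod = (d0 * s0_sq + df_pool * s2) / (d0 + df_pool)
            df_mod = np.minimum(d0 + df_pool, df_cap)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            denom = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
            tt = lfc / denom
        sel = testable & (denom > 0)
        t[sel] = tt[sel]
        df_used[sel] = np.asarray(df_mod)[sel]
        p[sel] = 2.0 * stats.t.sf(np.abs(tt[sel]), np.asarray(df_mod)[sel])
        const = testable & (denom == 0)

    if const.any():
        t[const] = 0.0
        p[const] = 1.0
        notes[const] = "constant protein: p set to 1"
    p = np.clip(p, np.nextafter(0, 1), 1.0)

    result = pd.DataFrame(
        {
            "log2_fold_change": lfc,
            "fold_change": np.power(2.0, np.abs(lfc)),
            "t_statistic": t,
            "df": df_used,
            "p_value": p,
            "n_group1": n1,
            "n_group2": n2,
            "note": notes,
        },
        index=matrix.index,
    )
    tested = result["p_value"].notna()
    adj = np.full(matrix.shape[0], np.nan)
    if tested.any():
        adj[tested.to_numpy()] = bh_adjust(result.loc[tested, "p_value"].to_numpy())
    result["adj_p"] = adj
    result.attrs["groups"] = groups
    return result


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving on input indices."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any(np.isnan(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_dysregulated(
    results: pd.DataFrame,
    p_max: float = 0.05,
    min_fold: float = 2.0,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Flag proteins with p below ``p_max`` and linear fold change above ``min_fold``.

    Adds ``selected`` and ``direction`` (which group is higher) columns;
    returns a copy of ``results``.
    """
    out = results.copy()
    pcol = "adj_p" if use_adjusted else "p_value"
    min_lfc = np.log2(min_fold)
    out["selected"] = (out[pcol] < p_max) & (out["log2_fold_change"].abs() > min_lfc)
    out["selected"] = out["selected"].fillna(False)
    groups = results.attrs.get("groups", ["group1", "group2"])
    out["direction"] = np.where(
        out["log2_fold_change"] > 0, f"higher_in_{groups[0]}", f"higher_in_{groups[1]}"
    )
    out.loc[out["log2_fold_change"] == 0, "direction"] = "equal"
    return out
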