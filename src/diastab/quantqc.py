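"""Peptide-level QC, normalization and MaxLFQ-style protein summarization.

The processing order is fixed:

1. :func:`filter_low_peptide_runs` — drop runs quantifying too few
   distinct peptides (default < 5000).
2. :func:`replicate_concordance` — drop the weaker member of technical
   replicate pairs whose peptide-level log2 Pearson correlation is below
   0.8.
3. :func:`log_median_normalize` — log2 transform and per-run additive
   median normalization to the global median of run medians.
4. :func:`drop_negative_log_peptides` — remove records with normalized
   log2 intensity < 0.
5. :func:`maxlfq_summarize` / :func:`summarize_proteins` — protein-level
   abundance from median pairwise peptide log-ratios solved by least
   squares (MaxLFQ principle, without delayed normalization).
6. :func:`average_replicates` — collapse technical replicates to one
   value per sample (missing-ignoring mean).

Every removal is logged with a reason code so the QC is auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QcLog",
    "filter_low_peptide_runs",
    "replicate_concordance",
    "log_median_normalize",
    "drop_negative_log_peptides",
    "maxlfq_summarize",
    "summarize_proteins",
    "average_replicates",
    "run_qc",
]

LOG2_COL = "log2_intensity"


@dataclass
class QcLog:
    """Structured removal/flag log: one dict per event."""

    events: list[dict] = field(default_factory=list)

    def add(self, stage: str, reason: str, **info) -> None:
        self.events.append({"stage": stage, "reason": reason, **info})

    def removed_runs(self, stage: str | None = None) -> list[str]:
        return [
            e["run_id"]
            for e in self.events
            if "run_id" in e and e["reason"].startswith("removed")
            and (stage is None or e["stage"] == stage)
        ]


def filter_low_peptide_runs(
    table: pd.DataFrame, min_peptides: int = 5000, log: QcLog | None = None
) -> tuple[pd.DataFrame, QcLog]:
    """Remove runs with fewer than ``min_peptides`` distinct quantified peptides."""
    if table.empty:
        raise ValueError("peptide table is empty")
    log = log or QcLog()
    counts = table.groupby("run_id")["peptide_id"].nunique()
    bad = counts[counts < min_peptides]
    for run_id, n in bad.items():
        log.add("run_filter", "removed_low_peptide_count", run_id=run_id, n_peptides=int(n))
    out = table[~table["run_id"].isin(bad.index)].copy()
    if out.empty:
        warnings.warn("all runs removed by the peptide-count filter")
    return out, log


def _per_run_log2(table: pd.DataFrame) -> dict[str, pd.Series]:
    vals = table[LOG2_COL] if LOG2_COL in table else np.log2(table["intensity"])
    frame = pd.DataFrame({"run_id": table["run_id"].to_numpy(),
                          "peptide_id": table["peptide_id"].to_numpy(),
                          "value": np.asarray(vals)})
    return {
        run: pd.Series(grp["value"].to_numpy(), index=grp["peptide_id"].to_numpy())
        for run, grp in frame.groupby("run_id", sort=False)
    }


def replicate_concordance(
    table: pd.DataFrame, min_r: float = 0.8, log: QcLog | None = None
) -> tuple[pd.DataFrame, QcLog]:
    """Filter discordant technical replicates.

    For each sample, consecutive replicate runs (by ``replicate_index``)
    are compared by Pearson correlation of log2 intensities over peptides
    quantified in both.  Pairs with r below ``min_r`` lose the member with
    fewer quantified peptides (tie broken toward the higher replicate
    index).  Pairs with fewer than 3 shared peptides are flagged as not
    assessable and retained.
    """
    log = log or QcLog()
    drop: set[str] = set()
    per_run = _per_run_log2(table)
    runs = (
        table.groupby(["sample_id", "run_id"])
        .agg(replicate_index=("replicate_index", "first"), n_peptides=("peptide_id", "nunique"))
        .reset_index()
    )
    for sample_id, grp in runs.groupby("sample_id"):
        grp = grp.sort_values("replicate_index")
        ids = grp["run_id"].tolist()
        if len(ids) < 2:
            continue
        for a, b in zip(ids, ids[1:]):
            if a in drop or b in drop:
                continue
            xa, xb = per_run[a], per_run[b]
            shared = xa.index.intersection(xb.index)
            if len(shared) < 3:
                log.add("replicate_filter", "flagged_not_assessable",
                        sample_id=sample_id, run_ids=[a, b], n_shared=int(len(shared)))
                warnings.warn(f"replicate pair {a}/{b}: <3 shared peptides, not assessable")
                continue
            r = float(stats.pearsonr(xa.loc[shared], xb.loc[shared]).statistic)
            if r < min_r:
                na = int(grp.loc[grp.run_id == a, "n_peptides"].iloc[0])
                nb = int(grp.loc[grp.run_id == b, "n_peptides"].iloc[0])
                # drop the lower-count member; tie -> the later replicate
                loser = a if na < nb else b
                drop.add(loser)
                log.add("replicate_filter", "removed_discordant_replicate",
                        run_id=loser, sample_id=sample_id, pearson_r=r,
                        n_shared=int(len(shared)))
    out = table[~table["run_id"].isin(drop)].copy()
    return out, log


def log_median_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Log2 transform and shift each run so all run medians coincide.

    The common target is the global median of run medians, making the
    operation idempotent and scale-stable.  Raises on non-positive
    intensities (naming the offending record) unless the table already
    carries normalized log2 values.
    """
    out = table.copy()
    if LOG2_COL in out.columns:
        vals = out[LOG2_COL].to_numpy(dtype=float)
    else:
        bad = out[out["intensity"] <= 0]
        if not bad.empty:
            rec = bad.iloc[0]
            raise ValueError(
                f"non-positive intensity for run {rec['run_id']!r} "
                f"peptide {rec['peptide_id']!r}: {rec['intensity']}"
            )
        vals = np.log2(out["intensity"].to_numpy(dtype=float))
    out[LOG2_COL] = vals
    run_medians = out.groupby("run_id")[LOG2_COL].median()
    target = float(run_medians.median())
    shift = (target - run_medians).rename("shift")
    out[LOG2_COL] = out[LOG2_COL] + out["run_id"].map(shift).to_numpy()
    return out


def drop_negative_log_peptides(table: pd.DataFrame) -> pd.DataFrame:
    """Remove records with normalized log2 intensity strictly below zero."""
    if LOG2_COL not in table.columns:
        raise ValueError("table must be normalized first (no log2_intensity column)")
    return table[table[LOG2_COL] >= 0].copy()


def maxlfq_summarize(
    peptide_matrix: pd.DataFrame, min_shared: int = 1
) -> tuple[pd.Series, bool]:
    """Protein profile across runs from one protein's peptide log2 matrix.

    Parameters
    ----------
    peptide_matrix
        peptides x runs, log2 scale, NaN = not quantified.
    min_shared
        minimum number of peptides shared by a run pair for its median
        log-ratio to enter the least-squares system.

    Returns
    -------
    (profile, connected)
        ``profile`` — per-run log2 protein abundance (NaN where the
        protein has no peptides); ``connected`` — False if the pairwise
        ratio graph split into several components (each component is then
        summarized and anchored independently).

    The pairwise system only fixes differences, so each component is
    anchored so that the mean of its estimated values equals the mean of
    its runs' observed median peptide values.
    """
    X = peptide_matrix.to_numpy(dtype=float)
    runs = peptide_matrix.columns
    n_runs = X.shape[1]
    observed = ~np.all(np.isnan(X), axis=0)
    profile = np.full(n_runs, np.nan)
    if not observed.any():
        return pd.Series(profile, index=runs), True

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        run_median = np.nanmedian(X, axis=0)
        # pairwise median log-ratios: D[p, i, j] = x_pi - x_pj
        D = X[:, :, None] - X[:, None, :]
        ratio = np.nanmedian(D, axis=0)
    shared = np.sum(~np.isnan(D), axis=0)

    obs_idx = np.flatnonzero(observed)
    # connected components over the ratio graph
    adj = (shared >= max(min_shared, 1)) & ~np.isnan(ratio)
    np.fill_diagonal(adj, False)
    from scipy.sparse.csgraph import connected_components

    sub = adj[np.ix_(obs_idx, obs_idx)]
    n_comp, comp_label = connected_components(sub, directed=False)

    for cid in range(n_comp):
        members = obs_idx[comp_label == cid]
        anchor = float(np.mean(run_median[members]))
        if len(members) == 1:
            profile[members[0]] = anchor
            continue
        # anchored normal equations of the pairwise-difference system:
        # (L + 11^T/m^2) mu = B^T r + anchor/m, with L the ratio-graph
        # Laplacian; the 1-direction is the system's null space, so the
        # anchor row makes it positive definite and pins the mean.
        a = adj[np.ix_(members, members)]
        r = np.where(a, ratio[np.ix_(members, members)], 0.0)
        m = len(members)
        lap = np.diag(a.sum(axis=1)) - a.astype(float)
        lhs = lap + np.full((m, m), 1.0 / m**2)
        rhs = r.sum(axis=1) + anchor / m
        profile[members] = np.linalg.solve(lhs, rhs)

    return pd.Series(profile, index=runs), n_comp <= 1


def summarize_proteins(
    table: pd.DataFrame, min_shared: int = 1, log: QcLog | None = None
) -> tuple[pd.DataFrame, QcLog]:
    """MaxLFQ summarization of a normalized peptide table to proteins x runs."""
    if LOG2_COL not in table.columns:
        raise ValueError("table must be normalized first")
    log = log or QcLog()
    run_ids = pd.Index(sorted(table["run_id"].unique()))
    profiles = {}
    for protein_id, grp in table.groupby("protein_id", sort=True):
        wide = grp.pivot_table(
            index="peptide_id", columns="run_id", values=LOG2_COL, aggfunc="mean"
        ).reindex(columns=run_ids)
        prof, connected = maxlfq_summarize(wide, min_shared=min_shared)
        if not connected:
            log.add("maxlfq", "flagged_disconnected_ratio_graph", protein_id=protein_id)
        profiles[protein_id] = prof
    matrix = pd.DataFrame(profiles).T
    matrix.index.name = "protein_id"
    return matrix, log


def average_replicates(matrix: pd.DataFrame, run_to_sample: pd.Series) -> pd.DataFrame:
    """Collapse run-level columns to samples by the missing-ignoring mean.

    ``run_to_sample`` maps run_id -> sample_id; a value is missing in the
    result only if it is missing in every replicate of the sample.
    """
    unknown = [c for c in matrix.columns if c not in run_to_sample.index]
    if unknown:
        raise ValueError(f"runs without sample mapping: {unknown[:5]}")
    grouped = matrix.T.groupby(run_to_sample.loc[matrix.columns]).mean()
    out = grouped.T
    out.columns.name = None
    return out


def run_qc(
    table: pd.DataFrame,
    min_peptides: int = 5000,
    min_r: float = 0.8,
    min_shared: int = 1,
) -> tuple[pd.DataFrame, QcLog]:
    """Full QC chain from a raw peptide table to a proteins x samples matrix."""
    log = QcLog()
    table, log = filter_low_peptide_runs(table, min_peptides=min_peptides, log=log)
    if table.empty:
        return pd.DataFrame(), log
    table, log = replicate_concordance(table, min_r=min_r, log=log)
    table = log_median_normalize(table)
    table = drop_negative_log_peptides(table)
    matrix, log = summarize_proteins(table, min_shared=min_shared, log=log)
    run_to_sample = table.groupby("run_id")["sample_id"].first()
    matrix = average_replicates(matrix, run_to_sample)
    return matrix, log
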