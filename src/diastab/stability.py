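"""Selection of stable discriminative proteins.

A protein is a useful tissue biomarker candidate when it varies little
between repeated samples of one patient's tumor but differs between
patients.  The selection is a fixed six-step cascade applied to the
fresh-frozen (FF) protein matrix:

1. exclude samples with tumor content < 20 %;
2. drop proteins absent from the FFPE matrix (must survive fixation);
3. keep proteins whose per-patient coefficient of variation (CV = sigma/mu,
   sample SD over mean) is < 25 % in every patient where it is assessable;
4. drop proteins quantified in < 20 % of the retained samples;
5. drop proteins in the lowest 25th percentile of mean intensity;
6. drop proteins quantified in 100 % of the retained samples (uniform
   "housekeeping" detection carries no discriminative signal).

Steps 4-6 use the samples surviving step 1 (FF matrix) as denominator.
The cascade is order-fixed and each step's survivors are recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genesets import GeneSet, stromal_score_proteins  # re-exported for convenience

__all__ = [
    "StabilityParams",
    "StabilityReport",
    "compute_cv",
    "cv_table",
    "select_stable_discriminative",
    "stromal_score_proteins",
]

STEP_NAMES = [
    "input_proteins",
    "in_ffpe",
    "cv_stable",
    "min_quantified",
    "intensity_above_q25",
    "not_in_all_samples",
]


def compute_cv(values, min_obs: int = 3) -> float:
    """Coefficient of variation sigma/mu of the observed (non-missing) values.

    Sample standard deviation (n-1 denominator).  Returns NaN (the
    "not assessable" sentinel) when fewer than ``min_obs`` values are
    observed; raises when the mean is non-positive, where a CV has no
    meaning.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < min_obs:
        return float("nan")
    mu = float(np.mean(x))
    if mu <= 0:
        raise ValueError(f"CV undefined for non-positive mean ({mu:.4g})")
    return float(np.std(x, ddof=1) / mu)


@dataclass(frozen=True)
class StabilityParams:
    min_tumor_pct: float = 20.0
    cv_max: float = 0.25
    min_obs: int = 3
    cv_rule: str = "all"           # "all": CV < cv_max required in every assessable patient
    cv_scale: str = "log2"         # "log2": CV on stored log2 values; "linear": on 2**value
    min_quantified_frac: float = 0.2
    low_intensity_percentile: float = 25.0

    def __post_init__(self) -> None:
        if self.cv_rule not in ("all", "any"):
            raise ValueError("cv_rule must be 'all' or 'any'")
        if self.cv_scale not in ("log2", "linear"):
            raise ValueError("cv_scale must be 'log2' or 'linear'")


@dataclass
class StabilityReport:
    step_names: list[str]
    survivor_counts: list[int]
    n_samples_retained: int
    cv: pd.DataFrame = field(repr=False)
    final_ids: set[str] = field(default_factory=set)

    def as_dict(self) -> dict:
        return {
            "steps": dict(zip(self.step_names, self.survivor_counts)),
            "n_samples_retained": self.n_samples_retained,
            "n_final": len(self.final_ids),
        }


def cv_table(matrix: pd.DataFrame, patients: pd.Series, min_obs: int = 3,
             scale: str = "log2") -> pd.DataFrame:
    """Per-protein, per-patient CV over a proteins x samples matrix.

    ``patients`` maps sample_id -> patient.  NaN marks "not assessable"
    (fewer than ``min_obs`` quantified samples, or a non-positive mean).
    """
    values = matrix if scale == "log2" else np.power(2.0, matrix)
    out = {}
    for patient, cols in patients.groupby(patients):
        sub = values[cols.index.intersection(values.columns)]
        n = sub.notna().sum(axis=1)
        mu = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        cv = sd / mu
        cv[n < min_obs] = np.nan
        bad_mean = (mu <= 0) & (n >= min_obs)
        if bad_mean.any():
            warnings.warn(
                f"patient {patient}: {int(bad_mean.sum())} proteins with non-positive "
                "mean treated as not assessable"
            )
            cv[bad_mean] = np.nan
        out[patient] = cv
    return pd.DataFrame(out)


def select_stable_discriminative(
    ff: pd.DataFrame,
    ffpe: pd.DataFrame,
    metadata: pd.DataFrame,
    params: StabilityParams = StabilityParams(),
) -> tuple[set[str], StabilityReport]:
    """Apply the six-step cascade; returns (selected ids, report)."""
    unknown = [s for s in ff.columns if s not in metadata.index]
    if unknown:
        raise ValueError(f"samples missing from metadata: {unknown[:5]}")

    # step 1: sample-level tumor-content filter
    meta = metadata.loc[list(ff.columns)]
    keep_samples = meta.index[meta["tumor_pct"] >= params.min_tumor_pct]
    mat = ff[keep_samples]
    counts = [mat.shape[0]]

    # step 2: protein must be present in the FFPE matrix
    survivors = mat.index[mat.index.isin(ffpe.index)]
    counts.append(len(survivors))

    # step 3: per-patient CV stability
    cv = cv_table(mat.loc[survivors], meta.loc[keep_samples, "patient"],
                  min_obs=params.min_obs, scale=params.cv_scale)
    stable_flag = cv < params.cv_max  # NaN -> False
    assessable = cv.notna()
    if params.cv_rule == "all":
        # every assessable patient must be stable; no assessable patient -> no veto
        ok = (stable_flag | ~assessable).all(axis=1)
    else:
        ok = stable_flag.any(axis=1) | ~assessable.any(axis=1)
    survivors = survivors[ok.loc[survivors]]
    counts.append(len(survivors))

    # step 4: quantified in >= min_quantified_frac of retained samples
    frac = mat.loc[survivors].notna().mean(axis=1)
    survivors = survivors[(frac >= params.min_quantified_frac).to_numpy()]
    counts.append(len(survivors))

    # step 5: drop the lowest intensity quartile (nearest-rank percentile of
    # the mean abundance over quantified samples)
    mean_int = mat.loc[survivors].mean(axis=1)
    if len(mean_int):
        k = int(np.ceil(params.low_intensity_percentile / 100.0 * len(mean_int)))
        cutoff = np.sort(mean_int.to_numpy())[max(k - 1, 0)]
        # strictly below the nearest-rank percentile value is removed; ties survive
        survivors = mean_int.index[mean_int.to_numpy() >= cutoff]
    counts.append(len(survivors))

    # step 6: uniformly detected proteins are uninformative
    frac = mat.loc[survivors].notna().mean(axis=1)
    survivors = survivors[(frac < 1.0).to_numpy()]
    counts.append(len(survivors))

    report = StabilityReport(
        step_names=list(STEP_NAMES),
        survivor_counts=counts,
        n_samples_retained=int(len(keep_samples)),
        cv=cv,
        final_ids=set(survivors),
    )
    return set(survivors), report
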