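"""Genomic scar scores and HR-deficiency classification.

Homologous-recombination (HR) deficient tumors accumulate characteristic
chromosomal scars.  Three established counts are computed from
allele-specific copy-number segment profiles:

* **TAI** — telomeric allelic imbalance: maximal runs of allelic
  imbalance (copyA != copyB) that reach a chromosome end and do not
  intersect the centromere.
* **HRD-LOH** — loss of heterozygosity: maximal runs with copyB = 0 and
  copyA >= 1 of at least ``min_size_bp`` (default 15 Mb) that do not span
  a whole chromosome.
* **LST** — large-scale state transitions: chromosome-arm-internal
  breakpoints between copy-number segments that are both >= 10 Mb after
  smoothing away segments < 3 Mb.

The HRD-mean score is the arithmetic mean of the three counts and is the
single predictor in a univariate logistic classifier of HR status,
evaluated by stratified fourfold cross-validation.

Coordinates are 0-based, half-open, in base pairs throughout.  Conventions:
copy-neutral LOH (e.g. copyA=2, copyB=0) counts as LOH *and* as allelic
imbalance; homozygous deletion (0, 0) counts as neither (LOH requires
copyA >= 1, and (0, 0) is balanced).  No ploidy renormalization is applied
before counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "GenomeModel",
    "AllelicSegmentProfile",
    "ScarScores",
    "HrdModel",
    "default_genome_model",
    "count_tai",
    "count_hrd_loh",
    "count_lst",
    "hrd_mean",
    "score_profile",
    "score_profiles",
    "fit_hrd_classifier",
    "cross_validate_hrd",
]


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome lengths and centromere intervals (bp, 0-based half-open)."""

    chromosomes: dict[str, tuple[int, int, int]]  # chrom -> (length, cen_start, cen_end)

    def __post_init__(self) -> None:
        for chrom, (length, cs, ce) in self.chromosomes.items():
            if not (0 <= cs < ce <= length):
                raise ValueError(f"{chrom}: centromere [{cs},{ce}) not inside [0,{length})")

    def length(self, chrom: str) -> int:
        return self.chromosomes[chrom][0]

    def centromere(self, chrom: str) -> tuple[int, int]:
        _, cs, ce = self.chromosomes[chrom]
        return cs, ce

    def arms(self, chrom: str) -> list[tuple[int, int]]:
        length, cs, ce = self.chromosomes[chrom]
        return [(0, cs), (ce, length)]

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "GenomeModel":
        """Build from a BED-like table (chrom, length, cen_start, cen_end)."""
        chroms = {
            str(r.chrom): (int(r.length), int(r.cen_start), int(r.cen_end))
            for r in table.itertuples()
        }
        return cls(chroms)

    def to_table(self) -> pd.DataFrame:
        rows = [
            {"chrom": c, "length": l, "cen_start": cs, "cen_end": ce}
            for c, (l, cs, ce) in self.chromosomes.items()
        ]
        return pd.DataFrame(rows)


def default_genome_model() -> GenomeModel:
    """Reduced synthetic genome: five chromosomes, 80-200 Mb, metacentric-ish."""
    mb = 1_000_000
    return GenomeModel({
        "chr1": (200 * mb, 90 * mb, 95 * mb),
        "chr2": (160 * mb, 70 * mb, 74 * mb),
        "chr3": (130 * mb, 60 * mb, 63 * mb),
        "chr4": (100 * mb, 44 * mb, 47 * mb),
        "chr5": (80 * mb, 36 * mb, 38 * mb),
    })


@dataclass
class AllelicSegmentProfile:
    """Allele-specific copy-number segments of one sample.

    ``segments`` columns: chrom, start, end, copy_a, copy_b with
    copy_a >= copy_b >= 0; within each chromosome segments must be
    sorted, non-overlapping and inside the chromosome.
    """

    sample_id: str
    segments: pd.DataFrame

    def validate(self, genome: GenomeModel) -> None:
        seg = self.segments
        for chrom, grp in seg.groupby("chrom", sort=False):
            if chrom not in genome.chromosomes:
                raise ValueError(f"{self.sample_id}: unknown chromosome {chrom!r}")
            length = genome.length(str(chrom))
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if (ends <= starts).any():
                raise ValueError(f"{self.sample_id}/{chrom}: segment with end <= start")
            if starts.min() < 0 or ends.max() > length:
                raise ValueError(f"{self.sample_id}/{chrom}: segment beyond chromosome length")
            order = np.argsort(starts)
            if (starts[order][1:] < ends[order][:-1]).any():
                raise ValueError(f"{self.sample_id}/{chrom}: overlapping segments")
            if (grp["copy_b"] > grp["copy_a"]).any() or (grp["copy_b"] < 0).any():
                raise ValueError(f"{self.sample_id}/{chrom}: require copy_a >= copy_b >= 0")


@dataclass(frozen=True)
class ScarScores:
    tai: int
    hrd_loh: int
    lst: int

    @property
    def hrd_mean(self) -> float:
        return (self.tai + self.hrd_loh + self.lst) / 3.0


def hrd_mean(scores: ScarScores) -> float:
    """Arithmetic mean of the TAI, HRD-LOH and LST counts."""
    return scores.hrd_mean


def _chrom_segments(profile: AllelicSegmentProfile, chrom: str) -> pd.DataFrame:
    grp = profile.segments[profile.segments["chrom"] == chrom]
    return grp.sort_values("start")


def _merged_runs(grp: pd.DataFrame, predicate: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutive, touching segments satisfying ``predicate``."""
    runs: list[tuple[int, int]] = []
    cur: tuple[int, int] | None = None
    for (start, end), keep in zip(grp[["start", "end"]].to_numpy(), predicate):
        if not keep:
            cur = None
            continue
        if cur is not None and start == cur[1]:
            cur = (cur[0], end)
            runs[-1] = cur
        else:
            cur = (int(start), int(end))
            runs.append(cur)
    return runs


def count_tai(profile: AllelicSegmentProfile, genome: GenomeModel, min_size_bp: int = 0) -> int:
    """Telomeric allelic-imbalance count."""
    profile.validate(genome)
    total = 0
    for chrom in profile.segments["chrom"].unique():
        grp = _chrom_segments(profile, str(chrom))
        length = genome.length(str(chrom))
        cs, ce = genome.centromere(str(chrom))
        ai = (grp["copy_a"] != grp["copy_b"]).to_numpy()
        for start, end in _merged_runs(grp, ai):
            touches_end = start == 0 or end == length
            crosses_cen = start < ce and end > cs
            if touches_end and not crosses_cen and (end - start) >= min_size_bp:
                total += 1
    return total


def count_hrd_loh(
    profile: AllelicSegmentProfile,
    genome: GenomeModel,
    min_size_bp: int = 15_000_000,
) -> int:
    """LOH count: merged copyB=0 (copyA>=1) runs >= min size, not a whole chromosome."""
    profile.validate(genome)
    total = 0
    for chrom in profile.segments["chrom"].unique():
        grp = _chrom_segments(profile, str(chrom))
        length = genome.length(str(chrom))
        loh = ((grp["copy_b"] == 0) & (grp["copy_a"] >= 1)).to_numpy()
        for start, end in _merged_runs(grp, loh):
            whole = start == 0 and end == length
            if not whole and (end - start) >= min_size_bp:
                total += 1
    return total


def _arm_state_runs(
    grp: pd.DataFrame, arm: tuple[int, int], smooth_below_bp: int
) -> list[tuple[int, int, tuple[int, int]]]:
    """Clip to arm, merge equal states, smooth small segments, re-merge.

    Returns runs as (start, end, (copy_a, copy_b)); re-merging after
    smoothing spans the gaps left by removed segments, as in arm-level
    smoothing of segmentation output.
    """
    a0, a1 = arm
    clipped: list[tuple[int, int, tuple[int, int]]] = []
    for start, end, ca, cb in grp[["start", "end", "copy_a", "copy_b"]].to_numpy():
        s, e = max(int(start), a0), min(int(end), a1)
        if e <= s:
            continue
        clipped.append((s, e, (int(ca), int(cb))))

    def merge(segs: list, fill_gaps: bool) -> list:
        out: list = []
        for s, e, state in segs:
            if out and out[-1][2] == state and (fill_gaps or s == out[-1][1]):
                out[-1] = (out[-1][0], e, state)
            else:
                out.append((s, e, state))
        return out

    runs = merge(clipped, fill_gaps=False)
    runs = [r for r in runs if r[1] - r[0] >= smooth_below_bp]
    return merge(runs, fill_gaps=True)


def count_lst(
    profile: AllelicSegmentProfile,
    genome: GenomeModel,
    min_segment_bp: int = 10_000_000,
    smooth_below_bp: int = 3_000_000,
) -> int:
    """Large-scale transition count (arm-internal, >= 10 Mb flanks, 3 Mb smoothing)."""
    profile.validate(genome)
    total = 0
    for chrom in profile.segments["chrom"].unique():
        grp = _chrom_segments(profile, str(chrom))
        for arm in genome.arms(str(chrom)):
            runs = _arm_state_runs(grp, arm, smooth_below_bp)
            for left, right in zip(runs, runs[1:]):
                if (left[1] - left[0]) >= min_segment_bp and (right[1] - right[0]) >= min_segment_bp:
                    total += 1
    return total


def score_profile(
    profile: AllelicSegmentProfile,
    genome: GenomeModel,
    tai_min_size_bp: int = 0,
    loh_min_size_bp: int = 15_000_000,
    lst_min_segment_bp: int = 10_000_000,
    lst_smooth_below_bp: int = 3_000_000,
) -> ScarScores:
    return ScarScores(
        tai=count_tai(profile, genome, tai_min_size_bp),
        hrd_loh=count_hrd_loh(profile, genome, loh_min_size_bp),
        lst=count_lst(profile, genome, lst_min_segment_bp, lst_smooth_below_bp),
    )


def score_profiles(
    profiles: list[AllelicSegmentProfile], genome: GenomeModel, **kwargs
) -> pd.DataFrame:
    """Score many profiles; returns a table indexed by sample_id."""
    rows = {}
    for p in profiles:
        s = score_profile(p, genome, **kwargs)
        rows[p.sample_id] = {
            "tai": s.tai, "hrd_loh": s.hrd_loh, "lst": s.lst, "hrd_mean": s.hrd_mean,
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample_id")


@dataclass
class HrdModel:
    """Univariate logistic model P(HR-deficient) = expit(intercept + slope * HRD-mean)."""

    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    auc: float
    threshold: float = 0.5
    n_iter: int = 0

    def predict_proba(self, hrd_means) -> np.ndarray:
        x = np.asarray(hrd_means, dtype=float)
        from scipy.special import expit

        return expit(self.intercept + self.slope * x)

    def predict(self, hrd_means) -> np.ndarray:
        return (self.predict_proba(hrd_means) >= self.threshold).astype(int)


def fit_hrd_classifier(
    hrd_means,
    labels,
    max_iter: int = 100,
    ridge: float = 1e-4,
    tol: float = 1e-10,
) -> HrdModel:
    """Maximum-likelihood logistic fit of HR status on the HRD-mean score.

    Iteratively reweighted least squares with a small ridge penalty on the
    coefficients as a guard against complete separation.  Standard errors
    come from the unpenalized Fisher information at the solution; the
    reported AUC is the in-sample rank statistic of the score.
    """
    x = np.asarray(hrd_means, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("hrd_means and labels must be equal-length 1-D arrays")
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ValueError("labels must contain both classes, coded 0/1")

    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    trace: list[float] = []
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        grad = X.T @ (y - mu) - ridge * beta
        hess = (X * w[:, None]).T @ X + ridge * np.eye(2)
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        trace.append(float(np.max(np.abs(step))))
        if trace[-1] < tol:
            break
    else:
        raise RuntimeError(
            f"IRLS did not converge in {max_iter} iterations; step trace: {trace[-5:]}"
        )

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    fisher = (X * w[:, None]).T @ X
    cov = np.linalg.inv(fisher)
    se = np.sqrt(np.diag(cov))
    auc = float(roc_auc_score(y, x if beta[1] >= 0 else -x))
    return HrdModel(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        intercept_se=float(se[0]),
        slope_se=float(se[1]),
        auc=auc,
        n_iter=it,
    )


def cross_validate_hrd(
    hrd_means, labels, folds: int = 4, seed: int = 0, **fit_kwargs
) -> dict:
    """Stratified k-fold cross-validation of the univariate classifier.

    Returns mean out-of-fold misclassification error at probability
    threshold 0.5 and the pooled out-of-fold AUC.
    """
    x = np.asarray(hrd_means, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(x) < folds:
        raise ValueError("need at least as many samples as folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof_prob = np.full(len(x), np.nan)
    errors = []
    for train, test in skf.split(x.reshape(-1, 1), y):
        if len(np.unique(y[train])) < 2:
            raise ValueError("training fold lost one class; reduce folds")
        model = fit_hrd_classifier(x[train], y[train], **fit_kwargs)
        p = model.predict_proba(x[test])
        oof_prob[test] = p
        errors.append(float(np.mean((p >= 0.5).astype(int) != y[test])))
    return {
        "cv_error": float(np.mean(errors)),
        "cv_auc": float(roc_auc_score(y, oof_prob)),
        "fold_errors": errors,
    }
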