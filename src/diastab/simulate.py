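"""Synthetic multi-site tumor proteomics cohort and genome-scar generator.

The cohort generator emulates the heterogeneity structure the analysis
assumes: ~11 patients sampled at two sites (ovary and omentum) with many
small samples per site, a log2-additive abundance model

    value(protein, sample) = protein baseline
                           + patient effect            (inter-individual)
                           + planted module effects    (site / HR status)
                           + sample noise              (intra-individual)

intensity-dependent (missing-not-at-random) detection, and an FFPE matrix
that covers a protein subset of the FF matrix.  Protein classes:

* ``stable``  — low intra-patient noise, strong patient effects, present
  in FFPE, structurally absent in a few patients each (non-uniform
  detection across the cohort).  The first ``dsi_module_size`` of them
  form the co-expressed dsDNA-sensing/inflammation (DSI) module, elevated
  in omentum and in HR-deficient patients via a shared per-sample latent
  factor.
* ``stromal`` — the bundled 20-protein stromal signature, co-expressed
  through a per-sample stromal latent factor elevated in omentum.
* ``housekeeping`` — uniformly detected, low variance (removed by the
  stability cascade's uniform-detection step).
* ``ffpe_absent`` — otherwise well-behaved proteins missing from the
  FFPE matrix.
* ``noisy`` — low-abundance, high-CV proteins carrying most of the
  intensity-dependent missingness.

The scar-profile generator plants telomeric allelic-imbalance events,
interstitial LOH runs and balanced copy-state blocks on disjoint
chromosome arms so the planted counts are recoverable exactly.  An
interstitial LOH run necessarily induces two large-scale transitions
(both flanks exceed 10 Mb by construction), so the recorded LST truth is
2 x (planted LST blocks) + 2 x (interstitial LOH events).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genesets import DSI_PROTEINS, STROMAL_PROTEINS
from .hrd import AllelicSegmentProfile, GenomeModel, default_genome_model

__all__ = [
    "ConfigurationError",
    "GenerationError",
    "CohortConfig",
    "GroundTruth",
    "ScarIntensity",
    "simulate_cohort",
    "simulate_ascn_profiles",
    "simulate_coexpression_blocks",
]

MB = 1_000_000


class ConfigurationError(ValueError):
    """Invalid generator configuration; the message names the offending field."""


class GenerationError(RuntimeError):
    """Event placement impossible under the genome model."""


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 11
    samples_per_tissue: tuple[int, int] = (6, 15)
    sites: tuple[str, ...] = ("ovary", "omentum")
    n_proteins: int = 1000
    n_peptides_per_protein: tuple[int, int] = (3, 8)
    frac_stable_discriminative: float = 0.10
    dsi_module_size: int = 40
    dsi_omentum_shift: float = 1.0
    dsi_hrd_shift: float = 0.75
    stromal_omentum_shift: float = 1.0
    intra_patient_sd: float = 0.3
    inter_patient_sd: float = 1.0
    missing_rate: float = 0.15
    frac_hr_deficient: float = 4 / 11
    #: share of DSI members' inter-patient variance carried by a module-wide
    #: patient factor; drives the co-expression that module detection sees
    dsi_patient_cor: float = 0.6
    seed: int = 0
    # class mix: shares of the remaining (non-stable, non-stromal) proteins
    frac_housekeeping: float = 0.35
    frac_ffpe_absent: float = 0.15
    ffpe_samples_per_tissue: int = 3

    def validate(self) -> None:
        for f in ("frac_stable_discriminative", "missing_rate", "frac_hr_deficient",
                  "frac_housekeeping", "frac_ffpe_absent"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{f} must be in [0, 1], got {v}")
        for f in ("n_patients", "n_proteins", "dsi_module_size"):
            if getattr(self, f) <= 0:
                raise ConfigurationError(f"{f} must be positive")
        for f in ("samples_per_tissue", "n_peptides_per_protein"):
            lo, hi = getattr(self, f)
            if lo <= 0 or hi < lo:
                raise ConfigurationError(f"{f} must be a positive (low, high) range")
        if self.dsi_module_size > self.n_proteins:
            raise ConfigurationError("dsi_module_size exceeds n_proteins")
        n_stable = round(self.frac_stable_discriminative * self.n_proteins)
        if self.dsi_module_size > max(n_stable, 0):
            raise ConfigurationError(
                "dsi_module_size exceeds the planted stable set "
                f"({self.dsi_module_size} > {n_stable}); raise frac_stable_discriminative"
            )
        if len(self.sites) != 2:
            raise ConfigurationError("sites must name exactly two tissues")


@dataclass
class GroundTruth:
    stable_protein_ids: set[str] = field(default_factory=set)
    dsi_member_ids: set[str] = field(default_factory=set)
    hr_status_by_patient: dict[str, str] = field(default_factory=dict)
    true_scar_counts: dict[str, tuple[int, int, int]] = field(default_factory=dict)
    planted_shifts: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "stable_protein_ids": sorted(self.stable_protein_ids),
            "dsi_member_ids": sorted(self.dsi_member_ids),
            "hr_status_by_patient": dict(sorted(self.hr_status_by_patient.items())),
            "true_scar_counts": {k: list(v) for k, v in sorted(self.true_scar_counts.items())},
            "planted_shifts": self.planted_shifts,
        }


def _protein_ids(config: CohortConfig) -> dict[str, list[str]]:
    """Assign protein identifiers to generator classes."""
    n_stable = round(config.frac_stable_discriminative * config.n_proteins)
    dsi = [DSI_PROTEINS[i] if i < len(DSI_PROTEINS) else f"DSIM{i + 1:03d}"
           for i in range(config.dsi_module_size)]
    stable_extra = [f"STAB{i + 1:04d}" for i in range(n_stable - len(dsi))]
    stromal = list(STROMAL_PROTEINS)
    n_rest = config.n_proteins - n_stable - len(stromal)
    if n_rest < 0:
        raise ConfigurationError("n_proteins too small for the requested class mix")
    # class fractions apportion the remainder after stable + stromal proteins
    n_hk = round(config.frac_housekeeping * n_rest)
    n_ffpe_absent = round(config.frac_ffpe_absent * n_rest)
    n_noisy = n_rest - n_hk - n_ffpe_absent
    if n_noisy < 0:
        raise ConfigurationError("frac_housekeeping + frac_ffpe_absent must sum to <= 1")
    return {
        "dsi": dsi,
        "stable_extra": stable_extra,
        "stromal": stromal,
        "housekeeping": [f"HK{i + 1:04d}" for i in range(n_hk)],
        "ffpe_absent": [f"NOFX{i + 1:04d}" for i in range(n_ffpe_absent)],
        "noisy": [f"NOIS{i + 1:04d}" for i in range(n_noisy)],
    }


def _sample_metadata(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    site_a, site_b = config.sites  # primary, metastatic (higher stroma)
    rows = []
    lo, hi = config.samples_per_tissue
    for p in range(config.n_patients):
        patient = f"P{p + 1:02d}"
        for site in config.sites:
            n = int(rng.integers(lo, hi + 1))
            for s in range(n):
                if site == site_a:
                    tumor = float(rng.uniform(30, 90))
                else:
                    tumor = float(rng.uniform(10, 80))
                rows.append({
                    "sample_id": f"{patient}_{site[:2]}_s{s + 1:02d}",
                    "patient": patient, "site": site,
                    "preservation": "FF", "tumor_pct": round(tumor, 1),
                })
    return pd.DataFrame(rows).set_index("sample_id")


def _calibrate_missingness(values: np.ndarray, rate: float, slope: float = 3.0) -> np.ndarray:
    """MNAR missingness probabilities: logistic in abundance, calibrated so the
    mean probability over observed (finite) values equals ``rate``."""
    from scipy.special import expit

    finite = values[np.isfinite(values)]
    if rate <= 0 or finite.size == 0:
        return np.zeros_like(values)
    lo, hi = finite.min() - 20, finite.max() + 20
    for _ in range(60):  # bisection on the logistic midpoint
        mid = 0.5 * (lo + hi)
        mean_p = float(np.mean(expit(slope * (mid - finite))))
        if mean_p < rate:
            lo = mid
        else:
            hi = mid
    return expit(slope * (mid - values))


def simulate_cohort(
    config: CohortConfig = CohortConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (peptide_table, ff_matrix, ffpe_matrix, metadata, ground_truth).

    Matrices are proteins x samples on the log2 scale with NaN for
    missing; the peptide table is long-format with linear intensities and
    two technical replicate runs per FF sample.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ids = _protein_ids(config)
    meta = _sample_metadata(config, rng)
    patients = sorted(meta["patient"].unique())
    site_a, site_b = config.sites

    n_hrd = round(config.frac_hr_deficient * len(patients))
    hrd_patients = set(rng.choice(patients, size=n_hrd, replace=False)) if n_hrd else set()
    hr_status = {p: ("HR-deficient" if p in hrd_patients else "HR-intact") for p in patients}

    all_ids = (ids["dsi"] + ids["stable_extra"] + ids["stromal"]
               + ids["housekeeping"] + ids["ffpe_absent"] + ids["noisy"])
    n_prot, n_samp = len(all_ids), len(meta)
    cls = {}
    for name, members in ids.items():
        for m in members:
            cls[m] = name

    # per-protein baselines and noise scales
    mu = np.empty(n_prot)
    intra_sd = np.empty(n_prot)
    inter_sd = np.empty(n_prot)
    for k, pid in enumerate(all_ids):
        c = cls[pid]
        if c in ("dsi", "stable_extra"):
            mu[k] = rng.uniform(12, 16)
            intra_sd[k] = config.intra_patient_sd
            inter_sd[k] = config.inter_patient_sd
        elif c == "stromal":
            mu[k] = rng.uniform(11, 14)
            intra_sd[k] = config.intra_patient_sd
            inter_sd[k] = 0.3 * config.inter_patient_sd
        elif c == "housekeeping":
            mu[k] = rng.uniform(10, 15)
            intra_sd[k] = 0.5 * config.intra_patient_sd
            inter_sd[k] = 0.1 * config.inter_patient_sd
        elif c == "ffpe_absent":
            mu[k] = rng.uniform(10, 15)
            intra_sd[k] = config.intra_patient_sd
            inter_sd[k] = config.inter_patient_sd
        else:  # noisy: low abundance, high CV on the log2 scale (sd ~ 0.3-0.45
            # of the mean at the default intra_patient_sd of 0.3)
            mu[k] = rng.uniform(4, 9)
            intra_sd[k] = rng.uniform(1.0, 1.5) * mu[k] * config.intra_patient_sd
            inter_sd[k] = 0.5 * config.inter_patient_sd

    patient_effect = rng.normal(0.0, 1.0, size=(n_prot, len(patients))) * inter_sd[:, None]
    pat_index = {p: i for i, p in enumerate(patients)}

    # co-expression of the DSI module across individuals: members split their
    # inter-patient variance between a module-wide patient factor and an
    # independent remainder (total variance preserved)
    rho = float(np.clip(config.dsi_patient_cor, 0.0, 1.0))
    if rho > 0:
        dsi_rows = np.array([cls[p] == "dsi" for p in all_ids])
        shared_pat = rng.normal(0.0, 1.0, size=len(patients))
        patient_effect[dsi_rows] = (
            np.sqrt(1.0 - rho) * patient_effect[dsi_rows]
            + np.sqrt(rho) * inter_sd[dsi_rows, None] * shared_pat[None, :]
        )

    # structural absence of stable proteins in a few patients each
    absent = np.zeros((n_prot, len(patients)), dtype=bool)
    stable_ids = ids["dsi"] + ids["stable_extra"]
    for k, pid in enumerate(all_ids):
        if cls[pid] in ("dsi", "stable_extra"):
            n_abs = int(rng.integers(1, min(4, len(patients) - 1)))
            absent[k, rng.choice(len(patients), size=n_abs, replace=False)] = True

    is_dsi = np.array([cls[p] == "dsi" for p in all_ids])
    is_stromal = np.array([cls[p] == "stromal" for p in all_ids])

    def build_matrix(metadata: pd.DataFrame, extra_sd: float = 0.0) -> pd.DataFrame:
        n = len(metadata)
        pat_col = np.array([pat_index[p] for p in metadata["patient"]])
        om = (metadata["site"] == site_b).to_numpy()
        hrd = np.array([hr_status[p] == "HR-deficient" for p in metadata["patient"]])
        lat_sd = config.intra_patient_sd
        dsi_latent = (config.dsi_omentum_shift * om
                      + config.dsi_hrd_shift * hrd
                      + rng.normal(0.0, 1.0, size=n) * lat_sd)
        stromal_latent = (config.stromal_omentum_shift * om
                          + rng.normal(0.0, 1.0, size=n) * lat_sd)
        vals = (mu[:, None]
                + patient_effect[:, pat_col]
                + np.outer(is_dsi, dsi_latent)
                + np.outer(is_stromal, stromal_latent)
                + rng.normal(0.0, 1.0, size=(n_prot, n)) * intra_sd[:, None])
        if extra_sd:
            vals = vals + rng.normal(0.0, extra_sd, size=vals.shape)
        vals[absent[:, pat_col]] = np.nan
        p_miss = _calibrate_missingness(vals, config.missing_rate)
        vals[rng.random(vals.shape) < p_miss] = np.nan
        return pd.DataFrame(vals, index=all_ids, columns=metadata.index)

    ff = build_matrix(meta)

    # FFPE: protein subset, its own (few) samples, extra preservation noise
    ffpe_rows = []
    for p in patients:
        for site in config.sites:
            for s in range(config.ffpe_samples_per_tissue):
                ffpe_rows.append({
                    "sample_id": f"{p}_{site[:2]}_f{s + 1:02d}",
                    "patient": p, "site": site,
                    "preservation": "FFPE",
                    "tumor_pct": round(float(rng.uniform(20, 90)), 1),
                })
    ffpe_meta = pd.DataFrame(ffpe_rows).set_index("sample_id")
    ffpe = build_matrix(ffpe_meta, extra_sd=0.3)
    ffpe = ffpe.drop(index=ids["ffpe_absent"])

    metadata = pd.concat([meta, ffpe_meta])
    peptides = _simulate_peptides(ff, config, rng)

    truth = GroundTruth(
        stable_protein_ids=set(stable_ids),
        dsi_member_ids=set(ids["dsi"]),
        hr_status_by_patient=hr_status,
        planted_shifts={
            "dsi_omentum_shift": config.dsi_omentum_shift,
            "dsi_hrd_shift": config.dsi_hrd_shift,
            "stromal_omentum_shift": config.stromal_omentum_shift,
        },
    )
    return peptides, ff, ffpe, metadata, truth


def _simulate_peptides(
    ff: pd.DataFrame, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Long peptide table: two technical replicate runs per FF sample.

    Peptide linear intensity = 2 ** (protein log2 value + peptide offset
    + replicate noise); rows are absent where the protein is missing.
    """
    lo, hi = config.n_peptides_per_protein
    n_pep = rng.integers(lo, hi + 1, size=ff.shape[0])
    offsets = [rng.normal(0.0, 1.5, size=k) for k in n_pep]
    prot_idx = np.repeat(np.arange(ff.shape[0]), n_pep)
    pep_off = np.concatenate(offsets) if len(offsets) else np.array([])
    pep_ids = np.array([
        f"{ff.index[i]}_pep{j + 1}"
        for i, k in enumerate(n_pep) for j in range(k)
    ])
    values = ff.to_numpy()
    frames = []
    for rep in (1, 2):
        base = values[prot_idx, :]  # peptides x samples
        noise = rng.normal(0.0, 0.1, size=base.shape)
        log2_int = base + pep_off[:, None] + noise
        obs = np.isfinite(log2_int)
        pep_idx, samp_idx = np.nonzero(obs)
        frames.append(pd.DataFrame({
            "run_id": np.char.add(ff.columns.to_numpy(dtype=str)[samp_idx], f"_r{rep}"),
            "sample_id": ff.columns.to_numpy(dtype=str)[samp_idx],
            "replicate_index": rep,
            "peptide_id": pep_ids[pep_idx],
            "protein_id": ff.index.to_numpy(dtype=str)[prot_idx[pep_idx]],
            "intensity": np.power(2.0, log2_int[obs]),
        }))
    table = pd.concat(frames, ignore_index=True)
    return table.sort_values(["run_id", "peptide_id"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# allele-specific copy-number profile simulation


@dataclass(frozen=True)
class ScarIntensity:
    """Mean planted event counts per profile (Poisson rates)."""

    tai: float = 2.0
    loh: float = 2.0
    lst: float = 2.0
    whole_chrom_loh: float = 0.2  # distractor; contributes 0 to every count


def simulate_ascn_profiles(
    n_samples: int,
    scar_intensity: ScarIntensity | dict | None = None,
    genome_model: GenomeModel | None = None,
    seed: int = 0,
    sample_prefix: str = "S",
) -> tuple[list[AllelicSegmentProfile], GroundTruth]:
    """Simulate allele-specific segment profiles with planted scar events.

    Events occupy disjoint chromosome arms: telomeric allelic-imbalance
    blocks of 3-8 Mb (too short to create a large-scale transition),
    interstitial LOH runs of >= 15 Mb with >= 10 Mb balanced flanks, and
    balanced (2, 2) copy-state blocks of 12-18 Mb.  Planted counts are
    recorded as ground truth; each interstitial LOH adds 2 to the LST
    truth (its two flanking transitions), each LST block likewise adds 2.
    """
    genome = genome_model or default_genome_model()
    if isinstance(scar_intensity, dict):
        scar_intensity = ScarIntensity(**scar_intensity)
    intensity = scar_intensity or ScarIntensity()
    rng = np.random.default_rng(seed)

    arms = []  # (chrom, a0, a1, telomere_end) with telomere at 'start' or 'end'
    for chrom, (length, cs, ce) in genome.chromosomes.items():
        arms.append((chrom, 0, cs, "start"))
        arms.append((chrom, ce, length, "end"))

    profiles: list[AllelicSegmentProfile] = []
    truth = GroundTruth()
    for s in range(n_samples):
        sample_id = f"{sample_prefix}{s + 1:03d}"
        events: dict[str, list[tuple[int, int, int, int]]] = {c: [] for c in genome.chromosomes}
        used_arms: set[int] = set()
        whole_loh_chroms: set[str] = set()

        if intensity.whole_chrom_loh > 0 and rng.random() < min(intensity.whole_chrom_loh, 1.0):
            chrom = str(rng.choice(list(genome.chromosomes)))
            whole_loh_chroms.add(chrom)
            for i, arm in enumerate(arms):
                if arm[0] == chrom:
                    used_arms.add(i)
            length = genome.length(chrom)
            events[chrom].append((0, length, 1, 0))

        def free_arms(min_len: int) -> list[int]:
            return [i for i, (c, a0, a1, _) in enumerate(arms)
                    if i not in used_arms and c not in whole_loh_chroms
                    and (a1 - a0) >= min_len]

        n_tai = int(rng.poisson(intensity.tai))
        n_loh = int(rng.poisson(intensity.loh))
        n_lst = int(rng.poisson(intensity.lst))
        if (intensity.tai > 0 or intensity.loh > 0 or intensity.lst > 0) and not free_arms(13 * MB):
            raise GenerationError("genome model has no arm long enough for any event")

        placed = {"tai": 0, "loh": 0, "lst": 0}
        for _ in range(n_tai):
            cand = free_arms(13 * MB)  # event <= 8 Mb + 5 Mb clearance
            if not cand:
                break
            i = int(rng.choice(cand))
            chrom, a0, a1, tel = arms[i]
            used_arms.add(i)
            L = int(rng.uniform(3 * MB, 8 * MB))
            seg = (a0, a0 + L) if tel == "start" else (a1 - L, a1)
            events[chrom].append((seg[0], seg[1], 2, 1))
            placed["tai"] += 1

        for kind, (lmin, lmax, state) in (
            ("loh", (15 * MB, 25 * MB, (1, 0))),
            ("lst", (12 * MB, 18 * MB, (2, 2))),
        ):
            n_events = n_loh if kind == "loh" else n_lst
            for _ in range(n_events):
                cand = free_arms(lmin + 21 * MB)
                if not cand:
                    break
                i = int(rng.choice(cand))
                chrom, a0, a1, _ = arms[i]
                used_arms.add(i)
                L = int(rng.uniform(lmin, min(lmax, (a1 - a0) - 20 * MB - MB)))
                start = int(rng.uniform(a0 + 10 * MB, a1 - 10 * MB - L))
                events[chrom].append((start, start + L, state[0], state[1]))
                placed[kind] += 1

        rows = []
        for chrom, (length, _, _) in genome.chromosomes.items():
            evs = sorted(events[chrom])
            pos = 0
            for start, end, ca, cb in evs:
                if start > pos:
                    rows.append((sample_id, chrom, pos, start, 1, 1))
                rows.append((sample_id, chrom, start, end, ca, cb))
                pos = end
            if pos < length:
                rows.append((sample_id, chrom, pos, length, 1, 1))
        seg = pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end",
                                          "copy_a", "copy_b"])
        profile = AllelicSegmentProfile(
            sample_id=sample_id,
            segments=seg[["chrom", "start", "end", "copy_a", "copy_b"]],
        )
        profile.validate(genome)
        profiles.append(profile)
        truth.true_scar_counts[sample_id] = (
            placed["tai"], placed["loh"], 2 * placed["lst"] + 2 * placed["loh"],
        )
    return profiles, truth


def simulate_coexpression_blocks(
    block_sizes=(40, 40),
    n_noise: int = 60,
    n_samples: int = 60,
    within_cor: float = 0.8,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Planted-block co-expression matrix for module-detection checks.

    Block members load on a shared latent factor with loading chosen so
    the expected within-block correlation is ``within_cor``; noise
    proteins are independent.  Returns (matrix, true labels) with label 0
    for noise proteins and 1..K for blocks.
    """
    rng = np.random.default_rng(seed)
    loading = np.sqrt(within_cor)
    resid = np.sqrt(1.0 - within_cor)
    rows, labels, ids = [], [], []
    for b, size in enumerate(block_sizes, start=1):
        latent = rng.normal(size=n_samples)
        for j in range(size):
            rows.append(loading * latent + resid * rng.normal(size=n_samples))
            labels.append(b)
            ids.append(f"B{b}_{j + 1:03d}")
    for j in range(n_noise):
        rows.append(rng.normal(size=n_samples))
        labels.append(0)
        ids.append(f"N_{j + 1:03d}")
    matrix = pd.DataFrame(rows, index=ids,
                          columns=[f"S{k + 1:03d}" for k in range(n_samples)])
    return matrix, pd.Series(labels, index=ids, name="block")
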