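"""End-to-end orchestration of the analysis on synthetic or user data.

``run_pipeline`` sequences: cohort simulation (optional) -> peptide QC and
MaxLFQ summarization -> stable-discriminative protein filter ->
co-expression module detection -> ssGSEA scoring (DSI + stromal) ->
per-patient site comparisons -> genomic scar scoring and HR-deficiency
classification -> differential abundance between HR groups.  Every stage
writes its table under the output directory and contributes one entry to
the machine-readable run report.

Configuration is a flat key-value YAML document; unknown keys are errors
(typo guard).  All randomness derives from the single top-level ``seed``,
expanded per stage with ``numpy.random.SeedSequence([seed, stage_index])``,
so the run is fully reproducible and byte-identical on rerun.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as dio
from .diffabund import moderated_t_test, select_dysregulated
from .enrichment import compare_sites, dsi_score, stromal_score
from .genesets import write_gmt
from .hrd import cross_validate_hrd, fit_hrd_classifier, score_profiles, default_genome_model
from .network import NetworkParams, find_modules
from .quantqc import run_qc
from .simulate import CohortConfig, ScarIntensity, simulate_ascn_profiles, simulate_cohort
from .stability import StabilityParams, select_stable_discriminative

__all__ = ["PIPELINE_DEFAULTS", "load_config", "run_pipeline", "demo_config"]


PIPELINE_DEFAULTS: dict = {
    "config_version": 1,
    "seed": 0,
    # cohort
    "n_patients": 11,
    "samples_per_tissue_min": 4,
    "samples_per_tissue_max": 8,
    "n_proteins": 300,
    "frac_stable_discriminative": 0.25,
    "dsi_module_size": 40,
    "dsi_omentum_shift": 1.0,
    "dsi_hrd_shift": 0.75,
    "stromal_omentum_shift": 1.0,
    "intra_patient_sd": 0.3,
    "inter_patient_sd": 1.0,
    "missing_rate": 0.15,
    "frac_hr_deficient": 4 / 11,
    # qc (min_peptides scales with the synthetic proteome size)
    "qc_min_peptides": 500,
    "qc_min_r": 0.8,
    "qc_min_shared": 1,
    # stability cascade
    "min_tumor_pct": 20.0,
    "cv_max": 0.25,
    "cv_min_obs": 3,
    # modules
    "beta": 7.0,
    "min_module_size": 30,
    "cut_height": 0.99,
    # scoring
    "tau": 0.25,
    # hrd
    "scar_rate_deficient": 3.0,
    "scar_rate_intact": 1.0,
    "scar_profiles_per_patient": 2,
    "cv_folds": 4,
    # differential abundance
    "de_p_max": 0.05,
    "de_min_fold": 2.0,
    "de_prior": "empirical_bayes",
}


def demo_config() -> dict:
    """The bundled demo configuration (small synthetic cohort, < 2 min)."""
    path = resources.files("diastab").joinpath("data/demo.yaml")
    return load_config(str(path))


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    unknown = sorted(set(user) - set(PIPELINE_DEFAULTS))
    if unknown:
        raise ValueError(f"unknown configuration keys: {unknown}")
    config = dict(PIPELINE_DEFAULTS)
    config.update(user)
    return config


def _stage_seed(seed: int, stage_index: int) -> int:
    return int(np.random.SeedSequence([seed, stage_index]).generate_state(1)[0] % (2**31))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), 10)
    return obj


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run all stages; writes artifacts + ``report.json`` and returns the report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    report: dict = {
        "software_version": __version__,
        "config": _jsonable(config),
        "stages": {},
    }

    def fail(stage: str, exc: Exception):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # stage 0: simulate -----------------------------------------------------
    cohort = CohortConfig(
        n_patients=int(config["n_patients"]),
        samples_per_tissue=(int(config["samples_per_tissue_min"]),
                            int(config["samples_per_tissue_max"])),
        n_proteins=int(config["n_proteins"]),
        frac_stable_discriminative=float(config["frac_stable_discriminative"]),
        dsi_module_size=int(config["dsi_module_size"]),
        dsi_omentum_shift=float(config["dsi_omentum_shift"]),
        dsi_hrd_shift=float(config["dsi_hrd_shift"]),
        stromal_omentum_shift=float(config["stromal_omentum_shift"]),
        intra_patient_sd=float(config["intra_patient_sd"]),
        inter_patient_sd=float(config["inter_patient_sd"]),
        missing_rate=float(config["missing_rate"]),
        frac_hr_deficient=float(config["frac_hr_deficient"]),
        seed=_stage_seed(seed, 0),
    )
    try:
        peptides, ff, ffpe, metadata, truth = simulate_cohort(cohort)
    except Exception as exc:  # pragma: no cover - defensive
        fail("simulate", exc)
    dio.write_peptides(peptides, out / "peptides.tsv")
    dio.write_matrix(ff, out / "ff_matrix.tsv")
    dio.write_matrix(ffpe, out / "ffpe_matrix.tsv")
    dio.write_metadata(metadata, out / "metadata.tsv")
    (out / "ground_truth.json").write_text(
        json.dumps(truth.as_dict(), indent=1, sort_keys=True))
    report["stages"]["simulate"] = {
        "n_ff_samples": int(ff.shape[1]),
        "n_ffpe_samples": int(ffpe.shape[1]),
        "n_proteins": int(ff.shape[0]),
        "n_peptide_records": int(len(peptides)),
        "n_hr_deficient_patients": sum(
            1 for v in truth.hr_status_by_patient.values() if v == "HR-deficient"),
    }

    # stage 1: quantitative QC ---------------------------------------------
    try:
        qc_matrix, qc_log = run_qc(
            peptides,
            min_peptides=int(config["qc_min_peptides"]),
            min_r=float(config["qc_min_r"]),
            min_shared=int(config["qc_min_shared"]),
        )
    except Exception as exc:
        fail("qc", exc)
    dio.write_matrix(qc_matrix, out / "qc_matrix.tsv")
    report["stages"]["qc"] = {
        "n_runs_removed": len(qc_log.removed_runs()),
        "n_proteins_quantified": int(qc_matrix.notna().any(axis=1).sum()),
        "n_samples": int(qc_matrix.shape[1]),
    }

    # stage 2: stable-discriminative filter --------------------------------
    params = StabilityParams(
        min_tumor_pct=float(config["min_tumor_pct"]),
        cv_max=float(config["cv_max"]),
        min_obs=int(config["cv_min_obs"]),
    )
    try:
        stable_ids, stab_report = select_stable_discriminative(
            qc_matrix, ffpe, metadata, params)
    except Exception as exc:
        fail("stable_filter", exc)
    (out / "stable_ids.txt").write_text("\n".join(sorted(stable_ids)) + "\n")
    (out / "stability_report.json").write_text(
        json.dumps(_jsonable(stab_report.as_dict()), indent=1, sort_keys=True))
    recovered = stable_ids & truth.stable_protein_ids
    report["stages"]["stable_filter"] = {
        **stab_report.as_dict(),
        "sensitivity": round(len(recovered) / max(len(truth.stable_protein_ids), 1), 4),
        "false_discovery_proportion": round(
            len(stable_ids - truth.stable_protein_ids) / max(len(stable_ids), 1), 4),
    }

    # stage 3: co-expression modules ---------------------------------------
    net_params = NetworkParams(
        beta=float(config["beta"]),
        min_module_size=int(config["min_module_size"]),
        cut_height=float(config["cut_height"]),
    )
    try:
        assignment, _net_log = find_modules(qc_matrix.loc[sorted(stable_ids)], net_params)
    except Exception as exc:
        fail("modules", exc)
    write_gmt(assignment.module_sets, out / "modules.gmt")
    report["stages"]["modules"] = {
        "n_modules": assignment.n_modules,
        "module_sizes": [len(m) for m in assignment.module_sets],
    }

    # stage 4: enrichment scores + site comparisons ------------------------
    tau = float(config["tau"])
    try:
        dsi = dsi_score(qc_matrix, tau=tau)
        stromal = stromal_score(qc_matrix, tau=tau)
    except Exception as exc:
        fail("scores", exc)
    scores = pd.DataFrame({
        "dsi_es": dsi.es, "dsi_nes": dsi.nes,
        "stromal_es": stromal.es, "stromal_nes": stromal.nes,
    })
    scores.to_csv(out / "scores.tsv", sep="\t", index_label="sample_id",
                  float_format="%.6g")
    ff_meta = metadata[metadata["preservation"] == "FF"]
    comparisons = {}
    for name, sc in (("dsi", dsi.nes), ("stromal", stromal.nes)):
        table = compare_sites(sc, ff_meta.loc[sc.index.intersection(ff_meta.index)])
        table.to_csv(out / f"site_comparison_{name}.tsv", sep="\t", float_format="%.6g")
        comparisons[name] = {
            "n_patients_tested": int(table["p"].notna().sum()),
            "n_significant": int((table["p"] <= 0.05).sum()),
        }
    report["stages"]["site_comparison"] = comparisons

    # stage 5: genomic scars + HR classification ---------------------------
    genome = default_genome_model()
    per_patient = int(config["scar_profiles_per_patient"])
    hrd_profiles, hrd_labels = [], []
    patients = sorted(truth.hr_status_by_patient)
    try:
        for k, patient in enumerate(patients):
            deficient = truth.hr_status_by_patient[patient] == "HR-deficient"
            rate = float(config["scar_rate_deficient" if deficient else "scar_rate_intact"])
            profs, _ = simulate_ascn_profiles(
                per_patient,
                ScarIntensity(tai=rate, loh=rate, lst=rate),
                genome,
                seed=_stage_seed(seed, 100 + k),
                sample_prefix=f"{patient}_cn",
            )
            hrd_profiles.extend(profs)
            hrd_labels.extend([int(deficient)] * per_patient)
        scars = score_profiles(hrd_profiles, genome)
        model = fit_hrd_classifier(scars["hrd_mean"].to_numpy(), np.array(hrd_labels))
        cv = cross_validate_hrd(
            scars["hrd_mean"].to_numpy(), np.array(hrd_labels),
            folds=int(config["cv_folds"]), seed=_stage_seed(seed, 5),
        )
    except Exception as exc:
        fail("hrd", exc)
    scars["hr_deficient"] = hrd_labels
    scars.to_csv(out / "scar_scores.tsv", sep="\t", float_format="%.6g")
    all_segments = pd.concat(
        [p.segments.assign(sample_id=p.sample_id) for p in hrd_profiles],
        ignore_index=True)
    dio.write_segments(all_segments[dio.SEGMENT_COLUMNS], out / "segments.tsv")
    report["stages"]["hrd"] = {
        "n_profiles": len(hrd_profiles),
        "intercept": round(model.intercept, 6),
        "slope": round(model.slope, 6),
        "in_sample_auc": round(model.auc, 6),
        "cv_auc": round(cv["cv_auc"], 6),
        "cv_error": round(cv["cv_error"], 6),
    }

    # stage 6: differential abundance (HR-deficient vs HR-intact) ----------
    hr_by_sample = ff_meta["patient"].map(truth.hr_status_by_patient)
    stable_matrix = qc_matrix.loc[sorted(stable_ids)]
    try:
        de = moderated_t_test(
            stable_matrix[hr_by_sample.index.intersection(stable_matrix.columns)],
            hr_by_sample,
            prior=str(config["de_prior"]),
        )
        de = select_dysregulated(de, p_max=float(config["de_p_max"]),
                                 min_fold=float(config["de_min_fold"]))
    except Exception as exc:
        fail("differential", exc)
    de.to_csv(out / "differential.tsv", sep="\t", index_label="protein_id",
              float_format="%.6g")
    report["stages"]["differential"] = {
        "n_tested": int(de["p_value"].notna().sum()),
        "n_selected": int(de["selected"].sum()),
        "n_adj_significant": int((de["adj_p"] < 0.05).sum()),
    }

    report_text = json.dumps(_jsonable(report), indent=1, sort_keys=True)
    (out / "report.json").write_text(report_text + "\n")
    return report
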