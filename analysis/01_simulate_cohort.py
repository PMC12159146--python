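#!/usr/bin/env python
"""Generate the synthetic multi-site HGSC-like cohort used by all
downstream analysis steps.

Eleven patients, each sampled at the primary (ovary) and metastatic
(omentum) site; log2-additive abundances with planted stable
discriminative proteins, a co-expressed dsDNA-sensing/inflammation (DSI)
module elevated in omentum and in HR-deficient patients, a stromal
signature elevated in omentum, and intensity-dependent missingness.
Writes the peptide table, FF/FFPE matrices, metadata and ground truth to
results/cohort/.
"""

import json
from pathlib import Path

from diastab import CohortConfig, simulate_cohort
from diastab import io as dio

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"

CONFIG = CohortConfig(
    n_patients=11,
    samples_per_tissue=(4, 8),
    n_proteins=300,
    frac_stable_discriminative=0.25,
    dsi_module_size=40,
    seed=7,
)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    peptides, ff, ffpe, metadata, truth = simulate_cohort(CONFIG)
    dio.write_peptides(peptides, OUT / "peptides.tsv")
    dio.write_matrix(ff, OUT / "ff_matrix.tsv")
    dio.write_matrix(ffpe, OUT / "ffpe_matrix.tsv")
    dio.write_metadata(metadata, OUT / "metadata.tsv")
    (OUT / "ground_truth.json").write_text(
        json.dumps(truth.as_dict(), indent=1, sort_keys=True))
    n_hrd = sum(1 for v in truth.hr_status_by_patient.values()
                if v == "HR-deficient")
    print(f"cohort: {ff.shape[0]} proteins, {ff.shape[1]} FF samples, "
          f"{ffpe.shape[1]} FFPE samples, {n_hrd}/{CONFIG.n_patients} "
          f"HR-deficient patients -> {OUT}")


if __name__ == "__main__":
    main()
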