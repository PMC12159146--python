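#!/usr/bin/env python
"""Differential abundance of stable discriminative proteins between
HR-deficient and HR-intact patients.

Empirical-Bayes moderated t-test per protein, Benjamini-Hochberg
correction, and the conventional p < 0.05 & fold change > 2 selection.
The planted DSI module is shifted up in HR-deficient patients, so DSI
members should dominate the selected set.  Writes the volcano-ready
table to results/differential/.
"""

import json
from pathlib import Path

import numpy as np

from diastab import io as dio
from diastab.diffabund import moderated_t_test, select_dysregulated

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ff = dio.read_matrix(ROOT / "qc" / "protein_matrix.tsv")
    metadata = dio.read_metadata(ROOT / "cohort" / "metadata.tsv")
    truth = json.loads((ROOT / "cohort" / "ground_truth.json").read_text())
    stable_ids = (ROOT / "stable" / "stable_ids.txt").read_text().split()

    hr_by_sample = metadata.loc[metadata["preservation"] == "FF", "patient"].map(
        truth["hr_status_by_patient"])
    matrix = ff.loc[[i for i in stable_ids if i in ff.index]]
    matrix = matrix[[c for c in matrix.columns if c in hr_by_sample.index]]

    result = moderated_t_test(matrix, hr_by_sample, prior="empirical_bayes")
    result = select_dysregulated(result)
    result["neg_log10_p"] = -np.log10(result["p_value"])

    out = ROOT / "differential"
    out.mkdir(parents=True, exist_ok=True)
    result.to_csv(out / "hr_contrast.tsv", sep="\t", index_label="protein_id",
                  float_format="%.6g")

    selected = result.index[result["selected"]]
    dsi = set(truth["dsi_member_ids"])
    print(f"{len(selected)} of {int(result['p_value'].notna().sum())} tested "
          f"proteins dysregulated (p < 0.05, fold > 2); "
          f"{len(set(selected) & dsi)} are planted DSI members")
    print(f"table -> {out}")


if __name__ == "__main__":
    main()
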