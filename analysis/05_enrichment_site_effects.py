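#!/usr/bin/env python
"""Score every sample for DSI and stromal content by ssGSEA and test the
ovary-vs-omentum difference per patient.

Both signatures are planted higher in omentum, so most patients should
show a significant site effect.  Writes score and comparison tables to
results/scores/.
"""

from pathlib import Path

import pandas as pd

from diastab import io as dio
from diastab.enrichment import compare_sites, dsi_score, stromal_score

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    matrix = dio.read_matrix(ROOT / "qc" / "protein_matrix.tsv")
    metadata = dio.read_metadata(ROOT / "cohort" / "metadata.tsv")
    out = ROOT / "scores"
    out.mkdir(parents=True, exist_ok=True)

    dsi = dsi_score(matrix)
    stromal = stromal_score(matrix)
    pd.DataFrame({
        "dsi_es": dsi.es, "dsi_nes": dsi.nes,
        "stromal_es": stromal.es, "stromal_nes": stromal.nes,
    }).to_csv(out / "scores.tsv", sep="\t", index_label="sample_id",
              float_format="%.6g")

    for name, scores in (("dsi", dsi.nes), ("stromal", stromal.nes)):
        table = compare_sites(scores, metadata.loc[scores.index])
        table.to_csv(out / f"site_comparison_{name}.tsv", sep="\t",
                     float_format="%.6g")
        tested = table["p"].notna()
        n_sig = int((table.loc[tested, "p"] <= 0.05).sum())
        print(f"{name.upper()} score higher in omentum in "
              f"{n_sig}/{int(tested.sum())} patients (t test, p <= 0.05)")
    print(f"score tables -> {out}")


if __name__ == "__main__":
    main()
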