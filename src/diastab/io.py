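"""Plain-text readers/writers for the tables the pipeline exchanges.

Conventions
-----------
* Protein matrices are TSV with proteins as rows (index column
  ``protein_id``) and samples as columns; values are log2 abundances,
  empty cells are missing.
* Sample metadata is TSV indexed by ``sample_id`` with columns
  ``patient``, ``site``, ``preservation`` and ``tumor_pct``.
* Peptide tables are long TSV with columns ``run_id``, ``sample_id``,
  ``replicate_index``, ``peptide_id``, ``protein_id``, ``intensity``
  (linear scale; missing rows are simply absent).
* Allele-specific segments are TSV with columns ``sample_id``, ``chrom``,
  ``start``, ``end``, ``copy_a``, ``copy_b`` using 0-based half-open
  base-pair coordinates.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

PEPTIDE_COLUMNS = ["run_id", "sample_id", "replicate_index", "peptide_id", "protein_id", "intensity"]
SEGMENT_COLUMNS = ["sample_id", "chrom", "start", "end", "copy_a", "copy_b"]
METADATA_COLUMNS = ["patient", "site", "preservation", "tumor_pct"]


def read_matrix(path: str | Path) -> pd.DataFrame:
    mat = pd.read_csv(path, sep="\t", index_col=0)
    if mat.index.has_duplicates:
        raise ValueError(f"{path}: duplicate protein ids")
    if mat.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate sample ids")
    return mat


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="protein_id", float_format="%.6g")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"{path}: metadata missing columns {missing}")
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_peptides(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in PEPTIDE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: peptide table missing columns {missing}")
    return table


def write_peptides(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_segments(path: str | Path) -> pd.DataFrame:
    seg = pd.read_csv(path, sep="\t")
    missing = [c for c in SEGMENT_COLUMNS if c not in seg.columns]
    if missing:
        raise ValueError(f"{path}: segment table missing columns {missing}")
    return seg


def write_segments(seg: pd.DataFrame, path: str | Path) -> None:
    seg.to_csv(path, sep="\t", index=False)
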