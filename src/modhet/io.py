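"""Readers and writers for the plain-text formats the pipeline exchanges.

All matrices are tab-separated with the row identifier in the first column
and sample identifiers in the header row. Probe maps are two-column TSV
(probe_id, gene_symbol; empty symbol = unmapped). Sample annotations are TSV
with columns sample_id, stage, subtype (subtype empty for normal tissue).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

REQUIRED_ANNOTATION_COLUMNS = ("sample_id", "stage", "subtype")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes/probes x samples expression matrix from TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 2:
        raise ValueError(f"matrix {path} has fewer than 2 sample columns")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label=df.index.name or "id")


def read_probe_map(path: str | Path) -> pd.Series:
    """Read probe -> gene symbol map; unmapped probes have NaN gene."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    probe_col, gene_col = df.columns[:2]
    dup = df[probe_col].duplicated()
    if dup.any():
        raise ValueError(f"duplicate probe ids in map: {df[probe_col][dup].tolist()[:5]}")
    mapped = df.set_index(probe_col)[gene_col].replace("", pd.NA)
    return mapped


def write_probe_map(probe_map: pd.Series, path: str | Path) -> None:
    out = probe_map.rename("gene_symbol").rename_axis("probe_id").reset_index()
    out.to_csv(path, sep="\t", index=False, na_rep="")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a sample annotation table indexed by sample_id."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation {path} missing columns {missing}")
    df = df.set_index("sample_id")
    df["subtype"] = df["subtype"].replace("", pd.NA)
    return df


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.rename_axis("sample_id").reset_index().to_csv(
        path, sep="\t", index=False, na_rep=""
    )


def write_modules_tsv(assignment: pd.Series, path: str | Path) -> None:
    """Persist a gene -> module-label map as two-column TSV."""
    assignment.rename("module_label").rename_axis("gene_id").reset_index().to_csv(
        path, sep="\t", index=False
    )


def read_modules_tsv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return df.set_index(df.columns[0])[df.columns[1]]


def write_modules_gmt(assignment: pd.Series, path: str | Path, *, skip: str = "grey") -> None:
    """Write one gene set per module in GMT style (name, description, genes)."""
    with open(path, "w") as fh:
        for label in assignment[assignment != skip].unique():
            genes = assignment.index[assignment == label]
            fh.write("\t".join([str(label), "module"] + list(genes)) + "\n")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
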