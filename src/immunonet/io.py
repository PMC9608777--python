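"""Readers and writers for the plain-text formats the pipeline uses.

Expression matrices are TSV/CSV with gene identifiers in the first
column and sample identifiers in the header (dialect auto-detected);
phenotype tables are CSV (sample_id, group, cohort); motif priors are
3-column TSV (tf, gene, weight); signatures are TSV (gene, one column
per cell type); gene sets are GMT; ground truth round-trips as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GroundTruth

__all__ = [
    "read_expression",
    "write_expression",
    "read_phenotype",
    "read_motif_prior",
    "read_signature",
    "read_annotations",
    "write_annotations",
    "write_truth",
    "read_truth",
]


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_expression(path) -> pd.DataFrame:
    """Gene x sample matrix; duplicate genes or non-numeric cells are errors."""
    path = Path(path)
    sep = _detect_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"parse error in {path}: {exc}") from exc
    dup = df.index[df.index.duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate gene identifiers in {path}: {list(dup)[:10]}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if not np.all(np.isfinite(df.to_numpy())):
        bad = df.index[~np.isfinite(df).all(axis=1)]
        raise ValueError(f"non-finite values in {path} for genes {list(bad)[:10]}")
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_phenotype(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample_id", "group"}
    if not required <= set(df.columns):
        raise ValueError(f"phenotype table needs columns {sorted(required)}")
    return df


def read_motif_prior(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:3]) != ["tf", "gene", "weight"]:
        raise ValueError("motif prior must have columns tf, gene, weight")
    return df


def read_signature(path) -> pd.DataFrame:
    return read_expression(path)


def read_annotations(path) -> dict[str, list[str]]:
    """Two-column TSV (gene, process); one row per annotation."""
    df = pd.read_csv(path, sep="\t", header=0)
    out: dict[str, list[str]] = {}
    for gene, proc in df.itertuples(index=False):
        out.setdefault(str(gene), []).append(str(proc))
    return out


def write_annotations(annotations: dict[str, list[str]], path) -> None:
    rows = [
        {"gene": g, "process": p}
        for g in sorted(annotations)
        for p in annotations[g]
    ]
    pd.DataFrame(rows, columns=["gene", "process"]).to_csv(path, sep="\t", index=False)


def write_truth(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)


def read_truth(path) -> GroundTruth:
    with open(path) as fh:
        d = json.load(fh)
    props = pd.DataFrame.from_dict(d.pop("true_proportions"), orient="index")
    from .simulate import CELL_TYPES

    props = props[[c for c in CELL_TYPES if c in props.columns]]
    samples = d.pop("sample_table")
    return GroundTruth(
        true_proportions=props,
        sample_table=pd.DataFrame(samples) if samples is not None else None,
        **d,
    )
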