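"""Tab-separated I/O for the quantification tables used across the pipeline.

All tables are plain TSV. Missing intensities are encoded as empty cells and
represented in memory as ``NaN``. Peptide tables carry two key columns
(``peptide_id``, ``protein_group_id``) followed by one column per sample;
protein tables carry ``protein_group_id`` followed by sample columns.
"""

from __future__ import annotations

import os
from typing import Mapping

import pandas as pd
import yaml

PEPTIDE_KEYS = ["peptide_id", "protein_group_id"]
ANNOTATION_COLUMNS = ["sample_id", "group", "tissue", "replicate_kind"]


def write_peptide_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a peptide x sample intensity table (MultiIndex rows) as TSV."""
    out = table.reset_index()
    out.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.10g")


def read_peptide_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [k for k in PEPTIDE_KEYS if k not in df.columns]
    if missing:
        raise ValueError(f"peptide table lacks key column(s): {missing}")
    df = df.set_index(PEPTIDE_KEYS)
    return df.astype(float)


def write_protein_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    out = table.reset_index()
    out.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.10g")


def read_protein_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "protein_group_id" not in df.columns:
        raise ValueError("protein table lacks a 'protein_group_id' column")
    return df.set_index("protein_group_id").astype(float)


def write_annotation(ann: pd.DataFrame, path: str | os.PathLike) -> None:
    ann.to_csv(path, sep="\t", index=False)


def read_annotation(path: str | os.PathLike) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation lacks column(s): {missing}")
    return ann


def write_truth_table(truth: pd.DataFrame, path: str | os.PathLike) -> None:
    truth.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_truth_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_config(config: Mapping, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)


def read_config(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        loaded = yaml.safe_load(fh)
    if not isinstance(loaded, dict):
        raise ValueError("config file must contain a key-value mapping")
    return loaded
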