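"""Plain-text readers/writers for every pipeline artifact.

All stage outputs are tab-separated or JSON so each stage can be re-run and
audited independently. Float formatting is fixed so identical runs produce
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

FLOAT_FORMAT = "%.6g"


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id", float_format=FLOAT_FORMAT)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_design(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "individual_id", "treatment", "timepoint"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    return design


def write_lengths(lengths: pd.Series, path) -> None:
    lengths.rename("length").to_csv(
        path, sep="\t", index_label="gene_id", float_format=FLOAT_FORMAT
    )


def read_lengths(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].rename("length")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
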