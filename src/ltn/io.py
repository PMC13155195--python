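"""Reading and writing the standard file formats.

Count tables are TSV/CSV with sample IDs in the first column and taxon
labels in the header; trees are Newick; covariate tables are CSV with a
group column, a subject column and any number of covariates; run
configurations are YAML.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd
import yaml

from .da import DADesign

__all__ = [
    "read_otu_table", "write_otu_table",
    "read_covariates", "build_design",
    "load_config",
]


def _sep_for(path: str) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_otu_table(path):
    """Read a counts table; returns (X, sample_ids, taxon_labels).

    Entries must be non-negative and integer-valued ("3.0" is accepted as
    3, "3.5" is an error); missing cells are errors.
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.isna().any().any():
        bad = [(str(r), str(c)) for r, c in zip(*np.where(df.isna().values))]
        raise ValueError(f"missing values in count table at (row, col) index {bad[:5]}")
    values = df.to_numpy(dtype=float)
    if np.any(values < 0):
        r, c = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative count at sample {df.index[r]!r}, taxon {df.columns[c]!r}")
    if np.any(values != np.floor(values)):
        r, c = np.argwhere(values != np.floor(values))[0]
        raise ValueError(
            f"non-integer count {values[r, c]} at sample {df.index[r]!r}, "
            f"taxon {df.columns[c]!r}")
    return values.astype(np.int64), list(df.index.astype(str)), list(df.columns.astype(str))


def write_otu_table(path, X, sample_ids, labels):
    df = pd.DataFrame(np.asarray(X, dtype=np.int64), index=sample_ids, columns=labels)
    df.index.name = "sample"
    df.to_csv(path, sep=_sep_for(path))


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.isna().any().any():
        raise ValueError("missing values in covariate table")
    return df


def build_design(
    cov: pd.DataFrame,
    sample_ids,
    group_col: str = "group",
    subject_col: str = "subject",
    covariate_cols=None,
) -> DADesign:
    """Assemble a :class:`DADesign` from a covariate table, aligning rows to
    the count-table sample order and prepending an intercept column."""
    missing = [sid for sid in sample_ids if sid not in cov.index]
    if missing:
        raise ValueError(f"samples missing from covariate table: {missing[:5]}")
    cov = cov.loc[sample_ids]
    if covariate_cols is None:
        covariate_cols = [c for c in cov.columns if c not in (group_col, subject_col)]
    Z = np.column_stack(
        [np.ones(len(cov))] +
        [pd.to_numeric(cov[c]).to_numpy(dtype=float) for c in covariate_cols]
    )
    return DADesign(
        s=cov[group_col].to_numpy(dtype=float),
        Z=Z,
        g=pd.factorize(cov[subject_col])[0],
    )


def load_config(path) -> dict:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    if "seed" not in cfg:
        raise ValueError("config must set a seed (reproducibility is mandatory)")
    iters = cfg.get("iters", 10_000)
    burn = cfg.get("burn", 5_000)
    if iters <= burn:
        raise ValueError("config must satisfy iters > burn")
    for key in ("counts", "tree", "covariates"):
        if key in cfg and cfg[key] is not None and not os.path.exists(cfg[key]):
            raise FileNotFoundError(f"config {key} path does not exist: {cfg[key]}")
    return cfg


def write_json(path, obj):
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
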