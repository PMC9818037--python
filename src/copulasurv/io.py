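"""Dataset reading, validation and descriptive reporting.

The subject-level table is a CSV with columns ``id`` (optional), ``y1``,
``d1``, ``y2``, ``d2`` and one 0/1 column per covariate (``y1/d1`` =
right kidney, ``y2/d2`` = left kidney; the joint model is exchangeable so
the labeling is cosmetic).  Rows violating the schema — missing values,
nonpositive times, non-binary indicators — are dropped with a logged
per-rule count, mirroring a completeness eligibility rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import pattern_table

__all__ = ["Dataset", "SchemaError", "read_dataset", "write_dataset", "describe"]

logger = logging.getLogger("copulasurv")

REQUIRED_COLUMNS = ("y1", "d1", "y2", "d2")


class SchemaError(ValueError):
    """A required column is missing or the file cannot be interpreted."""


@dataclass
class Dataset:
    """Validated subject-level data plus provenance."""

    df: pd.DataFrame
    covariate_names: list
    provenance: dict = field(default_factory=dict)
    n_rejected: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.df.empty:
            raise ValueError("dataset has no valid records")

    @property
    def n(self) -> int:
        return len(self.df)


def _validate_rows(df: pd.DataFrame, covariates) -> tuple[pd.DataFrame, dict]:
    rejected = {}
    keep = pd.Series(True, index=df.index)

    cols = list(REQUIRED_COLUMNS) + list(covariates)
    missing_mask = df[cols].isna().any(axis=1)
    rejected["missing_values"] = int(missing_mask.sum())
    keep &= ~missing_mask

    nonpos = keep & ((df["y1"] <= 0) | (df["y2"] <= 0))
    rejected["nonpositive_time"] = int(nonpos.sum())
    keep &= ~nonpos

    bad_ind = keep & (~df["d1"].isin((0, 1)) | ~df["d2"].isin((0, 1)))
    rejected["non_binary_indicator"] = int(bad_ind.sum())
    keep &= ~bad_ind

    for rule, count in rejected.items():
        if count:
            logger.warning("dropped %d record(s): %s", count, rule)
    return df[keep].reset_index(drop=True), rejected


def read_dataset(path, covariates=None) -> Dataset:
    """Read and validate a subject-level CSV.

    ``covariates`` defaults to every column other than id/y1/d1/y2/d2.
    Raises :class:`SchemaError` naming any missing required column.
    """
    df = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing from {path}")
    if covariates is None:
        covariates = [c for c in df.columns
                      if c not in REQUIRED_COLUMNS and c != "id"]
    else:
        missing = [c for c in covariates if c not in df.columns]
        if missing:
            raise SchemaError(f"covariate column(s) {missing} missing from {path}")
    df, rejected = _validate_rows(df, covariates)
    return Dataset(df, list(covariates),
                   provenance={"source": str(path)}, n_rejected=rejected)


def write_dataset(df: pd.DataFrame, path) -> None:
    """Write a subject-level table as CSV (full float precision)."""
    df.to_csv(path, index=False)


def from_simulation(df: pd.DataFrame, manifest: dict) -> Dataset:
    """Wrap a generated cohort as a Dataset carrying its truth manifest."""
    covs = [c for c in df.columns if c not in REQUIRED_COLUMNS and c != "id"]
    return Dataset(df, covs, provenance={"simulation": manifest})


def describe(ds: Dataset) -> dict:
    """Descriptive tables in the study's layout.

    Returns a dict with:

    * ``patterns``  — the four-pattern count/percent table;
    * ``covariates``— per covariate level x pattern counts and percent of
      total n (rows: level within covariate, columns per pattern);
    * ``at_least_one_failure_percent`` — percent failing >= 1 organ.
    """
    df = ds.df
    pat = pattern_table(df)
    at_least_one = 100.0 * np.mean((df["d1"] == 1) | (df["d2"] == 1))

    masks = {
        "(0, 0)": (df["d1"] == 0) & (df["d2"] == 0),
        "(1, 0)": (df["d1"] == 1) & (df["d2"] == 0),
        "(0, 1)": (df["d1"] == 0) & (df["d2"] == 1),
        "(1, 1)": (df["d1"] == 1) & (df["d2"] == 1),
    }
    n = len(df)
    rows = []
    for cov in ds.covariate_names:
        for level in sorted(df[cov].unique()):
            row = {"covariate": cov, "level": level}
            for label, mask in masks.items():
                c = int(np.sum(mask & (df[cov] == level)))
                row[f"n {label}"] = c
                row[f"% {label}"] = round(100.0 * c / n, 1)
            rows.append(row)
    cov_table = pd.DataFrame(rows).set_index(["covariate", "level"])
    return {
        "patterns": pat,
        "covariates": cov_table,
        "at_least_one_failure_percent": round(at_least_one, 1),
        "n": n,
    }
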