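"""Expression-matrix container and delimited-text I/O.

The in-memory container is a thin wrapper over a pandas DataFrame
(features in rows, samples in columns) plus a value-scale tag that records
whether values are log2 intensities (array-like platforms) or raw integer
counts (small-RNA-seq / exosome platforms). Downstream steps branch on the
scale tag, never on heuristics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

Scale = Literal["log_intensity", "raw_counts"]

#: Allowed values of the scale tag.
SCALES = ("log_intensity", "raw_counts")


class MatrixParseError(ValueError):
    """Raised when a delimited expression file cannot be parsed."""


@dataclass
class ExpressionMatrix:
    """Features × samples numeric expression table.

    Parameters
    ----------
    data : DataFrame
        Numeric values; index = feature IDs, columns = sample IDs. Both
        must be unique.
    scale : {"log_intensity", "raw_counts"}
        Value scale of ``data``.
    """

    data: pd.DataFrame
    scale: Scale = "log_intensity"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature IDs: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups}")
        if not np.issubdtype(np.asarray(self.data).dtype, np.number):
            raise ValueError("expression values must be numeric")
        if np.isnan(np.asarray(self.data, dtype=float)).any():
            raise ValueError("expression matrix contains missing values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def values(self) -> np.ndarray:
        return np.asarray(self.data, dtype=float)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)].copy(), self.scale)

    def to_tsv(self, path, delimiter: str = "\t") -> None:
        """Write as delimited text: first column feature IDs, header samples."""
        df = self.data.copy()
        df.index.name = "feature_id"
        df.to_csv(path, sep=delimiter)


def read_expression_matrix(
    path,
    scale: Scale = "log_intensity",
    delimiter: str = "\t",
    duplicate_policy: Literal["error", "mean"] = "error",
    impute_missing: bool = False,
) -> ExpressionMatrix:
    """Read a delimited feature-by-sample expression table.

    The first column holds feature IDs; the header row holds sample IDs.
    Missing values are rejected unless ``impute_missing`` is set, in which
    case each feature's median fills its gaps.

    Raises
    ------
    MatrixParseError
        On empty files, ragged rows, or non-numeric cells.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise MatrixParseError(f"{path}: empty file") from exc
    except pd.errors.ParserError as exc:
        raise MatrixParseError(f"{path}: ragged or malformed rows ({exc})") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise MatrixParseError(f"{path}: no data rows/columns")
    try:
        df = df.astype(float)
    except (ValueError, TypeError) as exc:
        raise MatrixParseError(f"{path}: non-numeric cell ({exc})") from exc

    if df.index.has_duplicates:
        if duplicate_policy == "error":
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise MatrixParseError(f"{path}: duplicate feature IDs: {dups}")
        elif duplicate_policy == "mean":
            df = df.groupby(level=0, sort=False).mean()
        else:
            raise ValueError(f"unknown duplicate_policy {duplicate_policy!r}")

    if df.isna().any().any():
        if not impute_missing:
            raise MatrixParseError(
                f"{path}: missing values present (set impute_missing=True to "
                "fill with per-feature medians)"
            )
        med = df.median(axis=1)
        df = df.apply(lambda row: row.fillna(med[row.name]), axis=1)

    return ExpressionMatrix(df, scale=scale)


# ---------------------------------------------------------------------------
# Sample annotations
# ---------------------------------------------------------------------------

GROUPS = ("Control", "MPTP")
TIMEPOINTS = ("D0", "D5")
CLASSES = ("Control", "PD")
LABEL_SOURCES = ("explicit", "prefix_parsed", "numbering_inferred")


def make_mouse_annotation(sample_ids, groups, timepoints) -> pd.DataFrame:
    """Build a mouse 2×2 annotation table (group × timepoint)."""
    ann = pd.DataFrame(
        {"sample_id": list(sample_ids), "group": list(groups), "time": list(timepoints)}
    )
    _check_levels(ann["group"], GROUPS, "group")
    _check_levels(ann["time"], TIMEPOINTS, "time")
    if ann["sample_id"].duplicated().any():
        raise ValueError("duplicate sample IDs in annotation")
    return ann.set_index("sample_id", drop=False)


def make_cohort_annotation(sample_ids, classes, cohort_id="cohort", label_source="explicit") -> pd.DataFrame:
    """Build a human cohort annotation table (PD vs Control)."""
    ann = pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "class": list(classes),
            "cohort_id": cohort_id,
            "label_source": label_source,
        }
    )
    _check_levels(ann["class"], CLASSES, "class")
    _check_levels(ann["label_source"], LABEL_SOURCES, "label_source")
    if ann["sample_id"].duplicated().any():
        raise ValueError("duplicate sample IDs in annotation")
    return ann.set_index("sample_id", drop=False)


def _check_levels(series: pd.Series, levels, name: str) -> None:
    bad = sorted(set(series) - set(levels))
    if bad:
        raise ValueError(f"invalid {name} level(s) {bad}; allowed: {levels}")


def check_annotation(matrix: ExpressionMatrix, annotation: pd.DataFrame) -> None:
    """Every matrix sample must have exactly one annotation row."""
    missing = [s for s in matrix.sample_ids if s not in annotation.index]
    if missing:
        raise ValueError(f"samples without annotation: {missing}")
    if annotation.index.has_duplicates:
        raise ValueError("annotation has duplicate sample rows")
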