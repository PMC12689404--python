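"""Sample-level quality control.

Two checks used for serum miRNA data: a hemolysis proxy (the miR-23a to
miR-451 log-ratio — red-cell lysis inflates miR-451 and depresses the
ratio's denominator term) and a PCA of the most variable features to
reveal outlying samples or group structure.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .harmonize import normalize_mirna_name
from .matrix import ExpressionMatrix

#: accepted core names for each hemolysis marker (miR-451 vs the miR-451a
#: naming used by newer annotation releases)
_MIR23A = {"hsa-mir-23a"}
_MIR451 = {"hsa-mir-451", "hsa-mir-451a"}


def hemolysis_ratio(matrix: ExpressionMatrix, cutoff: float = 5.0) -> pd.DataFrame:
    """Per-sample miR-23a − miR-451 log2 difference with a flag column.

    Works on log-scale data, where the ratio proxy is the difference of
    log2 values. Samples whose statistic exceeds ``cutoff`` are flagged as
    potentially hemolysed. If either marker is absent a warning is issued
    and an empty frame returned (QC is advisory, not fatal).
    """
    cores = {fid: normalize_mirna_name(fid) for fid in matrix.feature_ids}
    rows_23a = [f for f, c in cores.items() if c in _MIR23A]
    rows_451 = [f for f, c in cores.items() if c in _MIR451]
    if not rows_23a or not rows_451:
        missing = [] if rows_23a else ["miR-23a"]
        if not rows_451:
            missing.append("miR-451")
        warnings.warn(f"hemolysis markers absent: {missing}; QC skipped", stacklevel=2)
        return pd.DataFrame(columns=["sample_id", "ratio", "flagged"])
    v23a = matrix.data.loc[rows_23a].mean(axis=0)
    v451 = matrix.data.loc[rows_451].mean(axis=0)
    ratio = v23a - v451
    return pd.DataFrame(
        {"sample_id": matrix.sample_ids, "ratio": ratio.values, "flagged": (ratio > cutoff).values}
    )


def pca_qc(matrix: ExpressionMatrix, n_top: int = 500, n_components: int | None = None):
    """PCA of the ``n_top`` most variable features.

    Features are ranked by variance across samples, mean-centred per
    feature, and decomposed. Returns ``(coordinates, variance_explained)``
    where coordinates is a samples × components DataFrame and
    variance_explained the percentage of total variance per component.
    """
    n_features, n_samples = matrix.shape
    if n_samples < 3:
        raise ValueError("PCA QC requires at least 3 samples")
    n_top = min(n_top, n_features)
    variances = matrix.data.var(axis=1, ddof=1)
    top = variances.sort_values(ascending=False, kind="stable").index[:n_top]
    X = matrix.data.loc[top].to_numpy(dtype=float).T  # samples × features
    X = X - X.mean(axis=0, keepdims=True)
    k = n_components or min(X.shape)
    pca = PCA(n_components=min(k, min(X.shape)))
    coords = pca.fit_transform(X)
    var_pct = pca.explained_variance_ratio_ * 100.0
    coord_df = pd.DataFrame(
        coords,
        index=matrix.sample_ids,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return coord_df, var_pct
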