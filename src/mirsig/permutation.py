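"""Global permutation test for dataset-level temporal signal.

Feature-level tests in a 3k-feature × 16-sample design are individually
underpowered, so a single omnibus statistic asks whether the treated
group's temporal response exceeds the control group's: per feature g,
two-sample pooled-variance t statistics of D5 vs D0 are computed within
the MPTP arm (t_{g,M}) and within the Control arm (t_{g,C}), and

    T = Σ_g t_{g,M}² − Σ_g t_{g,C}².

The null distribution permutes day labels *within* each treatment group
(group membership is never touched), either by Monte-Carlo sampling or by
exhaustive enumeration of the distinct within-group assignments — with
4+4 samples per group there are only C(8,4)² = 4,900 of them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from ._rng import as_rng
from .matrix import ExpressionMatrix, check_annotation

GROUPS = ("Control", "MPTP")


def _sum_sq_t(Xg: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Sum over features of squared two-sample t, for each assignment.

    Xg: features × n_g values of one group; A: n_g × B boolean, True = D5.
    Pooled-variance t of D5 vs D0; zero-variance zero-difference features
    contribute 0.
    """
    A = A.astype(float)
    n1 = A.sum(axis=0)
    n0 = A.shape[0] - n1
    if np.any(n1 < 2) or np.any(n0 < 2):
        raise ValueError("each timepoint needs at least 2 samples within a group")
    X2 = Xg * Xg
    s1, s0 = Xg @ A, Xg @ (1.0 - A)
    q1, q0 = X2 @ A, X2 @ (1.0 - A)
    m1, m0 = s1 / n1, s0 / n0
    sse = (q1 - n1 * m1**2) + (q0 - n0 * m0**2)
    s2 = sse / (A.shape[0] - 2)
    denom = s2 * (1.0 / n1 + 1.0 / n0)
    diff2 = (m1 - m0) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = diff2 / denom
    t2 = np.where(denom > 0, t2, np.where(diff2 > 0, np.inf, 0.0))
    return t2.sum(axis=0)


def _group_blocks(matrix: ExpressionMatrix, annotation: pd.DataFrame):
    """Split values by group; return {group: (Xg, d5_mask)}."""
    check_annotation(matrix, annotation)
    ann = annotation.loc[matrix.sample_ids]
    X = matrix.values
    blocks = {}
    for group in GROUPS:
        mask = (ann["group"] == group).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"no samples in group {group}")
        d5 = (ann["time"][mask] == "D5").to_numpy()
        if d5.sum() == 0 or (~d5).sum() == 0:
            raise ValueError(f"group {group} lacks one of the timepoints")
        blocks[group] = (X[:, mask], d5)
    return blocks


def global_statistic(
    matrix: ExpressionMatrix, annotation: pd.DataFrame, statistic: str = "difference"
) -> float:
    """Observed omnibus statistic T for the 2×2 design.

    ``statistic="difference"``: Σt²(MPTP) − Σt²(Control);
    ``statistic="mptp_only"``: Σt²(MPTP) alone.
    """
    blocks = _group_blocks(matrix, annotation)
    sums = {
        g: float(_sum_sq_t(Xg, d5[:, None])[0]) for g, (Xg, d5) in blocks.items()
    }
    if statistic == "difference":
        return sums["MPTP"] - sums["Control"]
    if statistic == "mptp_only":
        return sums["MPTP"]
    raise ValueError(f"unknown statistic {statistic!r}")


def permute_time_labels(annotation: pd.DataFrame, rng) -> pd.DataFrame:
    """Reassign day labels within each treatment group; groups untouched."""
    rng = as_rng(rng)
    out = annotation.copy()
    for group in out["group"].unique():
        mask = out["group"] == group
        labels = out.loc[mask, "time"].to_numpy().copy()
        rng.shuffle(labels)
        out.loc[mask, "time"] = labels
    return out


def n_distinct_assignments(annotation: pd.DataFrame) -> int:
    """Number of distinct joint within-group day-label assignments."""
    total = 1
    for group in GROUPS:
        sub = annotation[annotation["group"] == group]
        total *= math.comb(len(sub), int((sub["time"] == "D5").sum()))
    return total


@dataclass
class GlobalTestResult:
    T_observed: float
    T_permuted: np.ndarray
    p_one_sided: float
    B: int
    mode: str  # "sampled" | "exhaustive"
    statistic: str

    def summary(self) -> str:
        return (
            f"Global permutation test ({self.statistic}, {self.mode})\n"
            f"  T observed: {self.T_observed:.2f}\n"
            f"  permutations: {self.B}\n"
            f"  one-sided p: {self.p_one_sided:.4g}"
        )

    def to_dict(self) -> dict:
        return {
            "T_observed": self.T_observed,
            "p_one_sided": self.p_one_sided,
            "B": self.B,
            "mode": self.mode,
            "statistic": self.statistic,
        }


def global_permutation_test(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    B: int = 5000,
    mode: str = "sampled",
    statistic: str = "difference",
    rng=None,
) -> GlobalTestResult:
    """One-sided global test of excess temporal signal in the MPTP arm.

    Sampled mode draws B within-group label shuffles (with replacement
    among assignments) and uses the add-one estimator
    p = (1 + #{T* ≥ T_obs}) / (B + 1); exhaustive mode enumerates every
    distinct assignment and reports the exact proportion ≥ T_obs (the
    observed assignment is among them, so p > 0).
    """
    blocks = _group_blocks(matrix, annotation)
    t_obs = global_statistic(matrix, annotation, statistic)

    if mode == "sampled":
        if B < 100:
            raise ValueError("sampled mode needs B >= 100")
        n_distinct = n_distinct_assignments(annotation)
        if B > n_distinct:
            warnings.warn(
                f"B={B} exceeds the {n_distinct} distinct assignments; "
                "consider mode='exhaustive' for an exact p-value",
                stacklevel=2,
            )
        rng = as_rng(rng)
        sums = {}
        for group, (Xg, d5) in blocks.items():
            A = rng.permuted(np.tile(d5, (B, 1)), axis=1).T  # n_g × B
            sums[group] = _sum_sq_t(Xg, A)
        t_perm = (
            sums["MPTP"] - sums["Control"] if statistic == "difference" else sums["MPTP"]
        )
        p = (1.0 + float(np.sum(t_perm >= t_obs))) / (B + 1.0)
        return GlobalTestResult(t_obs, t_perm, p, B, "sampled", statistic)

    if mode == "exhaustive":
        per_group = {}
        for group, (Xg, d5) in blocks.items():
            n_g, n_d5 = d5.size, int(d5.sum())
            combos = list(combinations(range(n_g), n_d5))
            A = np.zeros((n_g, len(combos)), dtype=bool)
            for j, idx in enumerate(combos):
                A[list(idx), j] = True
            per_group[group] = _sum_sq_t(Xg, A)
        if statistic == "difference":
            t_perm = (per_group["MPTP"][:, None] - per_group["Control"][None, :]).ravel()
        else:
            t_perm = per_group["MPTP"]
        p = float(np.mean(t_perm >= t_obs))
        return GlobalTestResult(t_obs, t_perm, p, t_perm.size, "exhaustive", statistic)

    raise ValueError(f"unknown mode {mode!r}")
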