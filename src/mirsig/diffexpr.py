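"""Per-feature linear modelling of the 2×2 design with variance moderation.

The design crosses treatment group (Control vs MPTP) with sampling day
(D0 vs D5). A saturated cell-means parameterization is fitted per feature
(equivalent to group + time + group:time dummy coding); the residual
variance pools within-cell scatter with N − 4 degrees of freedom. The
per-feature variances s_g² are then shrunk toward a common prior by the
standard empirical-Bayes hierarchy: assuming s_g² | σ_g² ~ σ_g²·χ²_d/d and
1/σ_g² ~ χ²_{d0}/(d0·s0²), the posterior variance is

    s̃_g² = (d0·s0² + d·s_g²) / (d0 + d),

and the moderated t statistic for a contrast uses s̃_g with d0 + d degrees
of freedom. The hyperparameters (d0, s0²) are estimated by the method of
moments on e_g = log s_g² − ψ(d/2) + log(d/2): solve
ψ′(d0/2) = var(e) − ψ′(d/2) (monotone in d0) and
s0² = exp(mean(e) + ψ(d0/2) − log(d0/2)). When var(e) is at or below the
ψ′(d/2) bound the prior is degenerate (d0 = ∞) and every posterior
variance equals s0² = exp(mean(e)).

The primary contrast is the time effect within one group — the D5 vs D0
log2 fold change inside the MPTP arm isolates treatment-associated
temporal change. Multiplicity is controlled with Benjamini–Hochberg FDR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .matrix import ExpressionMatrix, check_annotation

CELLS = [("Control", "D0"), ("Control", "D5"), ("MPTP", "D0"), ("MPTP", "D5")]


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Cell-means fit
# ---------------------------------------------------------------------------

@dataclass
class CellMeansFit:
    """Saturated 2×2 fit: per-feature cell means and pooled residual variance."""

    feature_ids: list[str]
    cell_means: pd.DataFrame  # features × 4 cells ("group:time" columns)
    cell_counts: dict[tuple[str, str], int]
    s2: np.ndarray  # pooled within-cell variance per feature
    df_residual: int

    def mean(self, group: str, time: str) -> np.ndarray:
        return self.cell_means[f"{group}:{time}"].to_numpy()


def fit_cell_means(matrix: ExpressionMatrix, annotation: pd.DataFrame) -> CellMeansFit:
    """Fit the saturated group×time cell-means model per feature."""
    check_annotation(matrix, annotation)
    ann = annotation.loc[matrix.sample_ids]
    X = matrix.values
    n_feat, n_samp = X.shape

    means, counts = {}, {}
    sse = np.zeros(n_feat)
    for group, time in CELLS:
        mask = ((ann["group"] == group) & (ann["time"] == time)).to_numpy()
        n_cell = int(mask.sum())
        if n_cell < 2:
            raise ValueError(f"design cell {group}×{time} has {n_cell} sample(s); need ≥2")
        cell = X[:, mask]
        mu = cell.mean(axis=1)
        means[f"{group}:{time}"] = mu
        counts[(group, time)] = n_cell
        sse += ((cell - mu[:, None]) ** 2).sum(axis=1)
    df = n_samp - len(CELLS)
    s2 = sse / df
    return CellMeansFit(
        feature_ids=matrix.feature_ids,
        cell_means=pd.DataFrame(means, index=matrix.feature_ids),
        cell_counts=counts,
        s2=s2,
        df_residual=df,
    )


# ---------------------------------------------------------------------------
# Empirical-Bayes variance moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve ψ′(x) = y for x > 0 (Newton iteration on a monotone function)."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


@dataclass
class ModerationResult:
    d0: float  # prior degrees of freedom (may be inf)
    s0_sq: float  # prior variance
    s2_posterior: np.ndarray
    df_total: float  # d0 + d (may be inf)


def ebayes_moderate(s2, df_residual: int) -> ModerationResult:
    """Estimate (d0, s0²) by moments on log variances and shrink s².

    Features with zero sample variance do not enter hyperparameter
    estimation but are still shrunk (their posterior is the prior term
    alone). All-zero variances are degenerate and raise.
    """
    s2 = np.asarray(s2, dtype=float)
    if np.any(s2 < 0):
        raise ValueError("variances must be non-negative")
    if df_residual < 1:
        raise ValueError("residual df must be ≥ 1")
    pos = s2 > 0
    if not pos.any():
        raise ValueError("all residual variances are zero; moderation is degenerate")
    if pos.sum() < 10:
        raise ValueError("need at least 10 features with positive variance")

    d = float(df_residual)
    e = np.log(s2[pos]) - special.digamma(d / 2.0) + math.log(d / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - float(special.polygamma(1, d / 2.0))

    if excess <= 0:
        d0 = math.inf
        s0_sq = math.exp(e_mean)
        post = np.full_like(s2, s0_sq)
        return ModerationResult(d0, s0_sq, post, math.inf)

    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = math.exp(e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    post = (d0 * s0_sq + d * s2) / (d0 + d)
    return ModerationResult(d0, s0_sq, post, d0 + d)


# ---------------------------------------------------------------------------
# Contrasts
# ---------------------------------------------------------------------------

def _t_pvalue(t: np.ndarray, df: float) -> np.ndarray:
    if math.isinf(df):
        return 2.0 * stats.norm.sf(np.abs(t))
    return 2.0 * stats.t.sf(np.abs(t), df)


def contrast_time_in_group(
    fit: CellMeansFit,
    moderation: ModerationResult | None,
    group: str,
) -> pd.DataFrame:
    """D5-vs-D0 contrast within one group, per feature.

    Returns a DataFrame with logFC, mean expression, ordinary and
    moderated t, p and BH q-values. With ``moderation=None`` (or prior df
    0) the moderated columns coincide with the ordinary ones.
    """
    if group not in {g for g, _ in fit.cell_counts}:
        raise ValueError(f"unknown group {group!r}")
    m5, m0 = fit.mean(group, "D5"), fit.mean(group, "D0")
    n5, n0 = fit.cell_counts[(group, "D5")], fit.cell_counts[(group, "D0")]
    logfc = m5 - m0
    scale = 1.0 / n5 + 1.0 / n0

    with np.errstate(divide="ignore", invalid="ignore"):
        se_ord = np.sqrt(fit.s2 * scale)
        t_ord = np.where(se_ord > 0, logfc / se_ord, np.where(logfc == 0, 0.0, np.inf * np.sign(logfc)))
        if moderation is None:
            t_mod, df_tot = t_ord, float(fit.df_residual)
        else:
            se_mod = np.sqrt(moderation.s2_posterior * scale)
            t_mod = np.where(
                se_mod > 0, logfc / se_mod, np.where(logfc == 0, 0.0, np.inf * np.sign(logfc))
            )
            df_tot = moderation.df_total
    p = _t_pvalue(np.asarray(t_mod, dtype=float), df_tot)
    q = bh_fdr(p)
    mean_expr = fit.cell_means.mean(axis=1).to_numpy()
    return pd.DataFrame(
        {
            "feature_id": fit.feature_ids,
            "logFC": logfc,
            "mean_expr": mean_expr,
            "t_ordinary": t_ord,
            "t_moderated": t_mod,
            "p_value": p,
            "q_value": q,
        }
    ).set_index("feature_id", drop=False)


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class TemporalDEModel:
    """Differential-expression model for the 2×2 group × time design.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Log-scale expression (features × samples).
    annotation : DataFrame
        Mouse annotation with ``group`` and ``time`` columns.

    Examples
    --------
    >>> results = TemporalDEModel(matrix, annotation).fit()
    >>> table = results.contrast("MPTP")
    """

    def __init__(self, matrix: ExpressionMatrix, annotation: pd.DataFrame):
        if matrix.scale != "log_intensity":
            raise ValueError("differential expression expects log-scale data")
        self.matrix = matrix
        self.annotation = annotation

    def fit(self, moderate: bool = True) -> "TemporalDEResults":
        cell_fit = fit_cell_means(self.matrix, self.annotation)
        moderation = ebayes_moderate(cell_fit.s2, cell_fit.df_residual) if moderate else None
        return TemporalDEResults(self, cell_fit, moderation)


class TemporalDEResults:
    """Fitted 2×2 model: cell means, moderated variances, contrasts."""

    def __init__(self, model: TemporalDEModel, cell_fit: CellMeansFit,
                 moderation: ModerationResult | None):
        self.model = model
        self.cell_fit = cell_fit
        self.moderation = moderation

    @property
    def prior_df(self) -> float | None:
        return None if self.moderation is None else self.moderation.d0

    @property
    def prior_var(self) -> float | None:
        return None if self.moderation is None else self.moderation.s0_sq

    def contrast(self, group: str = "MPTP") -> pd.DataFrame:
        """Per-feature D5-vs-D0 results within ``group``."""
        return contrast_time_in_group(self.cell_fit, self.moderation, group)

    def significant(self, group: str = "MPTP", fdr: float = 0.05) -> pd.DataFrame:
        table = self.contrast(group)
        return table[table["q_value"] < fdr]

    def summary(self, group: str = "MPTP", fdr: float = 0.05) -> str:
        table = self.contrast(group)
        sig = table[table["q_value"] < fdr]
        n_down = int((sig["logFC"] < 0).sum())
        n_up = int((sig["logFC"] > 0).sum())
        lines = [
            "Temporal differential expression (2x2 cell-means model)",
            f"  features: {len(table)}   residual df: {self.cell_fit.df_residual}",
        ]
        if self.moderation is not None:
            d0 = self.moderation.d0
            lines.append(
                f"  eBayes prior df d0: {'inf' if math.isinf(d0) else f'{d0:.2f}'}"
                f"   prior variance s0^2: {self.moderation.s0_sq:.4f}"
            )
        lines.append(
            f"  contrast D5 - D0 within {group}: {len(sig)} significant at "
            f"FDR < {fdr:g} ({n_down} down, {n_up} up)"
        )
        return "\n".join(lines)

    def to_tsv(self, path, group: str = "MPTP") -> None:
        self.contrast(group).to_csv(path, sep="\t", index=False)
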