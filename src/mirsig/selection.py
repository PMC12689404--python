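"""Day-0 classifier development: LOOCV and elastic-net stability selection.

The discovery question is whether MPTP-treated and control animals are
already separable at day 0 and, if so, which miRNAs carry the signal.
With 4 animals per class, single-model feature sets are fragile, so the
procedure combines:

* a univariate top-k filter (absolute two-sample t) applied inside every
  resample, never on the full data;
* leave-one-out cross-validation with elastic-net logistic models (α grid,
  λ via internal stratified cross-validation) as a performance check;
* stability selection — many random subsamples of 2 animals per class,
  refiltering and refitting each time; a feature's selection probability
  π̂ is the fraction of fits where its coefficient is nonzero, and the
  panel is every feature with π̂ ≥ 0.6;
* a permutation null for the selection frequencies (class labels shuffled,
  the whole stability pipeline rerun) giving an empirical p-value for the
  observed number of stably selected features.

With subsamples of size 4 internal cross-validation is impossible, so λ
inside stability iterations is a fixed fraction (default 0.1) of the
per-subsample λ_max and α is fixed at 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from ._enet import fit_enet_logistic, fit_enet_logistic_batch, lambda_max, standardize
from ._rng import as_rng
from .harmonize import normalize_mirna_name
from .matrix import ExpressionMatrix
from .panel import PanelMember, SignaturePanel
from .scoring import roc_auc

# ---------------------------------------------------------------------------
# Univariate filter
# ---------------------------------------------------------------------------

def _two_sample_t(X: np.ndarray, y01: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per feature row; 0/0 cases give t=0."""
    m1 = X[:, y01 == 1].mean(axis=1)
    m0 = X[:, y01 == 0].mean(axis=1)
    n1, n0 = int((y01 == 1).sum()), int((y01 == 0).sum())
    ss1 = ((X[:, y01 == 1] - m1[:, None]) ** 2).sum(axis=1)
    ss0 = ((X[:, y01 == 0] - m0[:, None]) ** 2).sum(axis=1)
    s2 = (ss1 + ss0) / (n1 + n0 - 2)
    denom = np.sqrt(s2 * (1.0 / n1 + 1.0 / n0))
    diff = m1 - m0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    return np.where(denom > 0, t, np.where(diff == 0, 0.0, np.inf * np.sign(diff)))


def _labels_to_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    levels = sorted(pd.unique(y))
    if len(levels) != 2:
        raise ValueError(f"need exactly two classes, got {levels}")
    return (y == levels[1]).astype(int)


def univariate_filter(matrix: ExpressionMatrix, labels, k: int) -> list[str]:
    """Top-k feature IDs by absolute two-sample t (ties: lexicographic ID)."""
    if k > matrix.shape[0]:
        raise ValueError("k exceeds the number of features")
    y01 = _labels_to_binary(labels)
    if (y01 == 1).sum() < 2 or (y01 == 0).sum() < 2:
        raise ValueError("each class needs at least 2 samples")
    t = _two_sample_t(matrix.values, y01)
    order = sorted(range(len(t)), key=lambda i: (-abs(t[i]), matrix.feature_ids[i]))
    return [matrix.feature_ids[i] for i in order[:k]]


# ---------------------------------------------------------------------------
# LOOCV with elastic net
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    """Pooled leave-one-out performance of the filtered elastic net."""

    scores: pd.Series  # held-out decision values, one per sample
    labels: pd.Series
    pooled_auc: float
    folds: list[dict]  # per-fold: held_out, alpha, lam, features

    def summary(self) -> str:
        return (
            f"LOOCV elastic net: {len(self.folds)} folds, "
            f"pooled held-out AUC {self.pooled_auc:.3f}"
        )


_LAMBDA_FRACS = np.logspace(0, -3, 10)


def _internal_cv_deviance(X, y01, alpha, lams, splitter) -> np.ndarray:
    """Mean held-out deviance for every λ in ``lams`` (batched fits)."""
    lams = np.asarray(lams, dtype=float)
    dev = np.zeros(lams.size)
    n_folds = 0
    for tr, te in splitter.split(X, y01):
        Xtr_s, mean, sd, active = standardize(X[tr])
        designs = np.broadcast_to(Xtr_s, (lams.size,) + Xtr_s.shape)
        coef, b0 = fit_enet_logistic_batch(designs, y01[tr], alpha, lams)
        Xte = np.zeros_like(X[te])
        Xte[:, active] = (X[te][:, active] - mean[active]) / sd[active]
        z = coef @ Xte.T + b0[:, None]  # (n_lam, n_te)
        yy = 2.0 * y01[te] - 1.0
        dev += np.mean(np.logaddexp(0.0, -yy[None, :] * z), axis=1)
        n_folds += 1
    return dev / n_folds


def loocv_elastic_net(
    matrix: ExpressionMatrix,
    labels,
    alpha_grid=(0.1, 0.5, 0.9),
    filter_k: int = 20,
    rng=None,
) -> CVReport:
    """Leave-one-out CV of the filter + elastic-net logistic pipeline.

    For each held-out sample the top-k filter is recomputed on the other
    n−1 samples, features are standardized on the training split, and for
    each α the penalty λ is chosen by stratified internal cross-validation
    (mean held-out deviance over a λ_max-anchored grid). The winning
    (α, λ) model scores the held-out sample; AUC is pooled over all
    held-out decision values.
    """
    rng = as_rng(rng)
    n = matrix.shape[1]
    if n < 6:
        raise ValueError("LOOCV needs at least 6 samples")
    y01_all = _labels_to_binary(labels)
    sample_ids = matrix.sample_ids
    scores = np.empty(n)
    folds = []

    for i in range(n):
        tr = np.array([j for j in range(n) if j != i])
        train_mat = matrix.subset_samples([sample_ids[j] for j in tr])
        y_tr = y01_all[tr]
        feats = univariate_filter(
            train_mat, np.asarray(labels)[tr], min(filter_k, matrix.shape[0])
        )
        Xtr = train_mat.data.loc[feats].to_numpy(dtype=float).T  # n-1 × k

        min_class = min(int(y_tr.sum()), int((1 - y_tr).sum()))
        if min_class < 2:
            warnings.warn(
                "internal CV infeasible (a training class has <2 members); "
                "falling back to fixed lambda = 0.1 * lambda_max",
                stacklevel=2,
            )
            Xs, mean, sd, active = standardize(Xtr)
            lam = 0.1 * lambda_max(Xs, y_tr, 0.5)
            alpha_best, lam_best = 0.5, lam
        else:
            n_splits = min(3, min_class)
            splitter = StratifiedKFold(
                n_splits=n_splits, shuffle=True,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            Xs_full, mean, sd, active = standardize(Xtr)
            best = None
            for alpha in alpha_grid:
                lams = _LAMBDA_FRACS * lambda_max(Xs_full, y_tr, alpha)
                dev = _internal_cv_deviance(Xtr, y_tr, alpha, lams, splitter)
                j = int(np.argmin(dev))
                if best is None or dev[j] < best[0] - 1e-12:
                    best = (float(dev[j]), alpha, float(lams[j]))
            _, alpha_best, lam_best = best
            Xs = Xs_full

        coef, b0 = fit_enet_logistic(Xs, y_tr, alpha_best, lam_best)
        x_new = matrix.data.loc[feats, sample_ids[i]].to_numpy(dtype=float)
        x_std = np.zeros_like(x_new)
        x_std[active] = (x_new[active] - mean[active]) / sd[active]
        scores[i] = float(x_std @ coef + b0)
        folds.append(
            {"held_out": sample_ids[i], "alpha": alpha_best, "lam": lam_best, "features": feats}
        )

    score_series = pd.Series(scores, index=sample_ids, name="decision_value")
    label_series = pd.Series(np.asarray(labels), index=sample_ids, name="label")
    y01 = y01_all
    # pooled AUC with the binary-coded class 1 as positive (not orientation-free:
    # the classifier is trained to put class 1 high)
    from .scoring import _auc_pd_positive

    pooled = _auc_pd_positive(scores, y01)
    return CVReport(score_series, label_series, pooled, folds)


# ---------------------------------------------------------------------------
# Stability selection
# ---------------------------------------------------------------------------

@dataclass
class StabilityResult:
    """Selection probabilities over subsampled elastic-net refits."""

    pi_hat: pd.Series  # per-feature selection probability
    n_iterations: int
    n_effective: int  # iterations that actually produced a fit
    subsample_per_class: int
    threshold: float
    alpha: float
    lambda_frac: float
    filter_k: int
    rng_seed: int | None = None
    selection_perm_p: float | None = None

    @property
    def selected(self) -> list[str]:
        sel = self.pi_hat[self.pi_hat >= self.threshold]
        return list(sel.sort_values(ascending=False, kind="stable").index)

    def summary(self) -> str:
        lines = [
            f"Stability selection: {self.n_effective}/{self.n_iterations} iterations, "
            f"subsample {self.subsample_per_class}/class, alpha={self.alpha}, "
            f"lambda={self.lambda_frac}*lambda_max, filter k={self.filter_k}",
            f"  {len(self.selected)} feature(s) with pi_hat >= {self.threshold}:",
        ]
        for name in self.selected:
            lines.append(f"    {name}  pi_hat={self.pi_hat[name]:.3f}")
        if self.selection_perm_p is not None:
            lines.append(f"  selection-frequency permutation p: {self.selection_perm_p:.4g}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        df = self.pi_hat.sort_values(ascending=False, kind="stable").rename("pi_hat")
        df.index.name = "feature_id"
        df.reset_index().to_csv(path, sep="\t", index=False)


class StabilitySelection:
    """Stability selection over subsampled elastic-net logistic fits.

    Each iteration draws ``subsample_per_class`` samples per class without
    replacement, re-runs the top-k t filter on that subsample, standardizes,
    and fits an elastic-net logistic model at fixed α and
    λ = lambda_frac · λ_max(subsample). π̂ counts nonzero coefficients.
    """

    def __init__(self, matrix: ExpressionMatrix, labels):
        self.matrix = matrix
        self.labels = np.asarray(labels)
        self.y01 = _labels_to_binary(self.labels)
        for cls in (0, 1):
            if (self.y01 == cls).sum() < 2:
                raise ValueError("each class needs at least 2 samples")

    def fit(
        self,
        n_iterations: int = 2000,
        subsample_per_class: int = 2,
        alpha: float = 0.5,
        lambda_frac: float = 0.1,
        filter_k: int = 20,
        threshold: float = 0.6,
        rng=None,
        chunk_size: int = 256,
    ) -> StabilityResult:
        if n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0 < threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        for cls in (0, 1):
            if (self.y01 == cls).sum() < subsample_per_class:
                raise ValueError("class smaller than the subsample size")
        rng = as_rng(rng)
        X = self.matrix.values
        n_feat = X.shape[0]
        k = min(filter_k, n_feat)
        idx0 = np.flatnonzero(self.y01 == 0)
        idx1 = np.flatnonzero(self.y01 == 1)
        # lexicographic rank of feature IDs, for deterministic tie-breaks
        lexrank = np.argsort(np.argsort(np.asarray(self.matrix.feature_ids, dtype=object)))

        # draw all subsamples up front so results are independent of chunking
        sub0 = np.stack(
            [rng.choice(idx0, size=subsample_per_class, replace=False) for _ in range(n_iterations)]
        )
        sub1 = np.stack(
            [rng.choice(idx1, size=subsample_per_class, replace=False) for _ in range(n_iterations)]
        )
        y_sub = np.concatenate(
            [np.zeros(subsample_per_class), np.ones(subsample_per_class)]
        )

        counts = np.zeros(n_feat, dtype=int)
        n_effective = 0
        for start in range(0, n_iterations, chunk_size):
            cols = np.concatenate(
                [sub0[start : start + chunk_size], sub1[start : start + chunk_size]], axis=1
            )  # (m, 2*per_class)
            m = cols.shape[0]
            designs = np.empty((m, y_sub.size, k))
            lams = np.empty(m)
            top_idx = np.empty((m, k), dtype=int)
            keep = np.ones(m, dtype=bool)
            for j in range(m):
                Xi = X[:, cols[j]]
                t = _two_sample_t(Xi, y_sub)
                order = np.lexsort((lexrank, -np.abs(t)))
                top = order[:k]
                top_idx[j] = top
                Xs, _, _, active = standardize(Xi[top].T)
                if not active.any():
                    keep[j] = False
                    lams[j] = 1.0
                    designs[j] = 0.0
                    continue
                designs[j] = Xs
                lams[j] = lambda_frac * lambda_max(Xs, y_sub, alpha)
            coef, _ = fit_enet_logistic_batch(designs, y_sub, alpha, lams)
            nonzero = np.abs(coef) > 1e-10
            for j in range(m):
                if not keep[j]:
                    continue
                n_effective += 1
                counts[top_idx[j][nonzero[j]]] += 1

        if n_effective == 0:
            raise ValueError("every stability iteration was degenerate")
        pi = pd.Series(counts / n_effective, index=self.matrix.feature_ids, name="pi_hat")
        return StabilityResult(
            pi_hat=pi,
            n_iterations=n_iterations,
            n_effective=n_effective,
            subsample_per_class=subsample_per_class,
            threshold=threshold,
            alpha=alpha,
            lambda_frac=lambda_frac,
            filter_k=filter_k,
        )


def stability_selection(matrix: ExpressionMatrix, labels, **kwargs) -> StabilityResult:
    """Functional wrapper around :class:`StabilitySelection`."""
    return StabilitySelection(matrix, labels).fit(**kwargs)


def selection_permutation_test(
    matrix: ExpressionMatrix,
    labels,
    observed: StabilityResult,
    B: int = 2000,
    iter_per_perm: int = 200,
    rng=None,
    statistic: str = "count",
) -> float:
    """Empirical p-value for the observed stability-selection outcome.

    Class labels are permuted B times; each permutation reruns stability
    selection (with ``iter_per_perm`` iterations, a tractable stand-in for
    the full run) and records a null statistic — by default the number of
    features reaching the π̂ threshold, optionally (``statistic="top_mean"``)
    the mean π̂ of the top-m features with m = |observed selected|.
    p = (1 + #{stat* ≥ stat_obs}) / (B + 1).
    """
    if B < 100:
        raise ValueError("need B >= 100 permutations")
    rng = as_rng(rng)
    labels = np.asarray(labels)

    def _stat(res: StabilityResult) -> float:
        if statistic == "count":
            return float(len(res.selected))
        if statistic == "top_mean":
            m = max(1, len(observed.selected))
            return float(res.pi_hat.nlargest(m).mean())
        raise ValueError(f"unknown statistic {statistic!r}")

    stat_obs = _stat(observed)
    hits = 0
    StabilitySelection(matrix, labels)  # validates classes up front
    for _ in range(B):
        perm = rng.permutation(labels)
        res = StabilitySelection(matrix, perm).fit(
            n_iterations=iter_per_perm,
            subsample_per_class=observed.subsample_per_class,
            alpha=observed.alpha,
            lambda_frac=observed.lambda_frac,
            filter_k=observed.filter_k,
            threshold=observed.threshold,
            rng=rng,
        )
        if _stat(res) >= stat_obs - 1e-12:
            hits += 1
    return (1.0 + hits) / (B + 1.0)


# ---------------------------------------------------------------------------
# Panel assembly
# ---------------------------------------------------------------------------

def build_panel(stability: StabilityResult, de_table: pd.DataFrame) -> SignaturePanel:
    """Turn the stably selected features into a directed signature panel.

    Direction comes from the sign of each feature's log2 fold change in
    the primary (MPTP time) contrast; core names are the harmonized,
    arm-stripped identifiers used for cross-species matching.
    """
    selected = stability.selected
    if not selected:
        warnings.warn("no features passed the stability threshold; empty panel", stacklevel=2)
        return SignaturePanel([])
    members = []
    for fid in selected:
        if fid not in de_table.index:
            raise ValueError(f"selected feature {fid!r} missing from the DE table")
        logfc = float(de_table.loc[fid, "logFC"])
        members.append(
            PanelMember(
                core_name=normalize_mirna_name(fid),
                direction="down" if logfc < 0 else "up",
                source_name=fid,
                pi_hat=float(stability.pi_hat[fid]),
                logfc=logfc,
            )
        )
    return SignaturePanel(members)
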