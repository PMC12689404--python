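"""End-to-end orchestration: discovery → panel → cohort validation.

``run_discovery`` fits the 2×2 temporal model on the mouse matrix, runs
the global permutation test, day-0 LOOCV and stability selection, and
assembles the signature panel. ``run_validation`` scores the panel in
each configured human cohort. ``run_all`` chains both and writes a plain
markdown report. Every stochastic stage draws from its own substream of
the single master seed, so reruns of the same config are byte-identical
and stages can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._rng import MASTER_SEED_DEFAULT, stage_rng
from .diffexpr import TemporalDEModel
from .labels import parse_sample_labels
from .matrix import ExpressionMatrix, read_expression_matrix
from .panel import SignaturePanel
from .permutation import global_permutation_test
from .qc import hemolysis_ratio, pca_qc
from .scoring import SignatureValidator
from .selection import (
    StabilitySelection,
    build_panel,
    loocv_elastic_net,
    selection_permutation_test,
)
from .simulate import (
    CohortSimSpec,
    MouseSimSpec,
    generate_human_cohort,
    generate_mouse_experiment,
)


@dataclass
class CohortConfig:
    """One validation cohort: either a file or a synthetic spec."""

    name: str = "cohort"
    input_path: str | None = None
    scale: str = "log_intensity"
    label_dialect: str = "prefix"
    sim: CohortSimSpec | None = None

    def __post_init__(self) -> None:
        if self.input_path is None and self.sim is None:
            self.sim = CohortSimSpec(cohort_id=self.name)


def _default_cohorts() -> list[CohortConfig]:
    # mirrors the shapes of the three public validation cohorts:
    # PBMC array n=32 (19 PD / 13 Control), exosome counts n=76
    # (46 PD / 30 Control, prefix headers), exosome counts n=100
    # (numbering headers, 50/50)
    return [
        CohortConfig(
            name="pbmc_array",
            sim=CohortSimSpec(
                n_pd=19, n_control=13, platform="array_continuous",
                label_dialect="prefix", cohort_id="pbmc_array",
            ),
        ),
        CohortConfig(
            name="exosome_2022",
            sim=CohortSimSpec(
                n_pd=46, n_control=30, platform="exosome_counts",
                label_dialect="prefix", cohort_id="exosome_2022",
            ),
        ),
        CohortConfig(
            name="exosome_2020",
            sim=CohortSimSpec(
                n_pd=50, n_control=50, platform="exosome_counts",
                label_dialect="numbering", cohort_id="exosome_2020",
            ),
        ),
    ]


@dataclass
class PipelineConfig:
    """All tunables of the workflow, with discovery-study defaults."""

    seed: int = MASTER_SEED_DEFAULT
    output_dir: str = "mirsig_output"
    # discovery inputs
    mouse_input: str | None = None
    mouse_sim: MouseSimSpec = field(default_factory=MouseSimSpec)
    # differential expression
    fdr_cutoff: float = 0.05
    # global permutation test
    global_B: int = 5000
    global_mode: str = "sampled"
    global_statistic: str = "difference"
    # LOOCV
    run_loocv: bool = True
    alpha_grid: tuple[float, ...] = (0.1, 0.5, 0.9)
    filter_k: int = 20
    # stability selection
    stability_iterations: int = 2000
    subsample_per_class: int = 2
    stability_alpha: float = 0.5
    lambda_frac: float = 0.1
    pi_threshold: float = 0.6
    # selection-frequency permutation test
    run_selection_test: bool = True
    selection_B: int = 2000
    selection_iter_per_perm: int = 200
    # validation
    cohorts: list[CohortConfig] = field(default_factory=_default_cohorts)
    auc_B: int = 5000
    n_boot: int = 2000

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "mouse_sim" in raw and isinstance(raw["mouse_sim"], dict):
            ms = dict(raw["mouse_sim"])
            for key in ("baseline_mean_range", "planted_down", "planted_up", "planted_panel"):
                if key in ms and ms[key] is not None:
                    ms[key] = tuple(ms[key])
            raw["mouse_sim"] = MouseSimSpec(**ms)
        if "alpha_grid" in raw:
            raw["alpha_grid"] = tuple(raw["alpha_grid"])
        if "cohorts" in raw:
            cohorts = []
            for c in raw["cohorts"]:
                if isinstance(c, dict):
                    c = dict(c)
                    if c.get("sim") is not None and isinstance(c["sim"], dict):
                        sim = dict(c["sim"])
                        for key in ("baseline_mean_range", "library_size_range"):
                            if key in sim and sim[key] is not None:
                                sim[key] = tuple(sim[key])
                        c["sim"] = CohortSimSpec(**sim)
                    c = CohortConfig(**c)
                cohorts.append(c)
            raw["cohorts"] = cohorts
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def desk_scale(self) -> "PipelineConfig":
        """Copy with reduced permutation/iteration counts for quick runs."""
        return dataclasses.replace(
            self,
            global_B=500,
            stability_iterations=300,
            selection_B=100,
            selection_iter_per_perm=50,
            auc_B=500,
            n_boot=300,
        )


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _load_mouse(config: PipelineConfig):
    if config.mouse_input is not None:
        matrix = read_expression_matrix(config.mouse_input, scale="log_intensity")
        ann_path = Path(config.mouse_input).with_suffix(".annotation.tsv")
        ann = pd.read_csv(ann_path, sep="\t").set_index("sample_id", drop=False)
        return matrix, ann
    sim_seed = int(stage_rng(config.seed, "mouse_sim").integers(0, 2**31 - 1))
    spec = dataclasses.replace(config.mouse_sim, rng_seed=sim_seed)
    return generate_mouse_experiment(spec)


def run_discovery(config: PipelineConfig, outdir: Path | None = None) -> dict:
    """Mouse arm: DE fit, global test, LOOCV, stability selection, panel."""
    outdir = Path(outdir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, annotation = _load_mouse(config)

    de_results = TemporalDEModel(matrix, annotation).fit()
    de_table = de_results.contrast("MPTP")
    de_table.to_csv(outdir / "de_mptp_time.tsv", sep="\t", index=False)

    global_res = global_permutation_test(
        matrix, annotation,
        B=config.global_B, mode=config.global_mode,
        statistic=config.global_statistic,
        rng=stage_rng(config.seed, "global_perm"),
    )
    (outdir / "global_test.json").write_text(json.dumps(global_res.to_dict(), indent=2))

    d0_samples = annotation.index[annotation["time"] == "D0"]
    d0_matrix = matrix.subset_samples(d0_samples)
    d0_labels = annotation.loc[d0_samples, "group"].to_numpy()

    cv_report = None
    if config.run_loocv:
        cv_report = loocv_elastic_net(
            d0_matrix, d0_labels,
            alpha_grid=config.alpha_grid, filter_k=config.filter_k,
            rng=stage_rng(config.seed, "loocv"),
        )
        (outdir / "loocv.json").write_text(
            json.dumps(
                {
                    "pooled_auc": cv_report.pooled_auc,
                    "folds": [
                        {k: (v if not isinstance(v, float) else float(v)) for k, v in f.items()}
                        for f in cv_report.folds
                    ],
                },
                indent=2,
                default=str,
            )
        )

    stability = StabilitySelection(d0_matrix, d0_labels).fit(
        n_iterations=config.stability_iterations,
        subsample_per_class=config.subsample_per_class,
        alpha=config.stability_alpha,
        lambda_frac=config.lambda_frac,
        filter_k=config.filter_k,
        threshold=config.pi_threshold,
        rng=stage_rng(config.seed, "stability"),
    )
    if config.run_selection_test:
        stability.selection_perm_p = selection_permutation_test(
            d0_matrix, d0_labels, stability,
            B=config.selection_B,
            iter_per_perm=config.selection_iter_per_perm,
            rng=stage_rng(config.seed, "selection_perm"),
        )
    stability.to_tsv(outdir / "stability_pi_hat.tsv")

    panel = build_panel(stability, de_table)
    panel.to_tsv(outdir / "panel.tsv")

    manifest = {
        "package_version": __version__,
        "master_seed": config.seed,
        "config": config.to_dict(),
        "n_features": matrix.shape[0],
        "n_samples": matrix.shape[1],
        "n_significant": int((de_table["q_value"] < config.fdr_cutoff).sum()),
        "global_p": global_res.p_one_sided,
        "loocv_pooled_auc": None if cv_report is None else cv_report.pooled_auc,
        "panel": panel.core_names,
        "selection_perm_p": stability.selection_perm_p,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    return {
        "matrix": matrix,
        "annotation": annotation,
        "de_results": de_results,
        "de_table": de_table,
        "global_test": global_res,
        "cv_report": cv_report,
        "stability": stability,
        "panel": panel,
        "manifest": manifest,
    }


def _load_cohort(config: PipelineConfig, cohort: CohortConfig, panel: SignaturePanel):
    if cohort.input_path is not None:
        matrix = read_expression_matrix(cohort.input_path, scale=cohort.scale)
        annotation = parse_sample_labels(
            matrix.sample_ids, cohort.label_dialect, cohort_id=cohort.name
        )
        return matrix, annotation
    sim_seed = int(stage_rng(config.seed, f"cohort_sim:{cohort.name}").integers(0, 2**31 - 1))
    spec = dataclasses.replace(cohort.sim, rng_seed=sim_seed, cohort_id=cohort.name)
    return generate_human_cohort(spec, panel)


def run_validation(
    config: PipelineConfig, panel: SignaturePanel, outdir: Path | None = None
) -> tuple[list, pd.DataFrame]:
    """Score the panel in every configured cohort; returns results + summary."""
    if not config.cohorts:
        raise ValueError("no cohorts configured")
    if len(panel) == 0:
        raise ValueError("cannot validate an empty panel")
    outdir = Path(outdir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    results, rows = [], []
    for cohort in config.cohorts:
        matrix, annotation = _load_cohort(config, cohort, panel)
        try:
            res = SignatureValidator(matrix, annotation, panel, cohort_id=cohort.name).fit(
                B=config.auc_B, n_boot=config.n_boot,
                rng=stage_rng(config.seed, f"validate:{cohort.name}"),
            )
        except ValueError as exc:
            rows.append({"cohort_id": cohort.name, "error": str(exc)})
            continue
        results.append(res)
        rows.append(res.to_dict())
        score_df = pd.DataFrame(
            {
                "sample_id": res.scores.index,
                "class": res.labels.values,
                "score": res.scores.values,
            }
        )
        score_df.to_csv(outdir / f"scores_{cohort.name}.tsv", sep="\t", index=False)
        (outdir / f"roc_{cohort.name}.json").write_text(json.dumps(res.to_dict(), indent=2))

    summary = pd.DataFrame(rows)
    summary.to_csv(outdir / "cohort_summary.tsv", sep="\t", index=False)
    return results, summary


def run_all(config: PipelineConfig, outdir: Path | None = None) -> dict:
    """Discovery then validation, plus a markdown report."""
    outdir = Path(outdir or config.output_dir)
    discovery = run_discovery(config, outdir)
    panel = discovery["panel"]
    if len(panel) == 0:
        report = _render_report(config, discovery, None)
        (outdir / "report.md").write_text(report)
        return {"discovery": discovery, "validation": None, "report": report}
    results, summary = run_validation(config, panel, outdir)
    report = _render_report(config, discovery, summary)
    (outdir / "report.md").write_text(report)
    return {"discovery": discovery, "validation": results, "summary": summary, "report": report}


def _render_report(config: PipelineConfig, discovery: dict, summary: pd.DataFrame | None) -> str:
    man = discovery["manifest"]
    de_table = discovery["de_table"]
    sig = de_table[de_table["q_value"] < config.fdr_cutoff]
    lines = [
        "# miRNA signature pipeline report",
        "",
        "## Parameters",
        f"- master seed: {config.seed}",
        f"- FDR cutoff: {config.fdr_cutoff}",
        f"- global permutations B: {config.global_B} ({config.global_mode}, {config.global_statistic})",
        f"- stability: {config.stability_iterations} iterations, "
        f"{config.subsample_per_class}/class subsample, alpha={config.stability_alpha}, "
        f"lambda={config.lambda_frac}*lambda_max, filter k={config.filter_k}, "
        f"pi threshold {config.pi_threshold}",
        f"- AUC permutations B: {config.auc_B}, bootstrap: {config.n_boot}",
        "",
        "## Discovery (mouse 2x2)",
        f"- features x samples: {man['n_features']} x {man['n_samples']}",
        f"- significant at FDR<{config.fdr_cutoff}: {man['n_significant']} "
        f"({int((sig['logFC'] < 0).sum())} down, {int((sig['logFC'] > 0).sum())} up)",
        f"- global permutation p: {man['global_p']:.4g}",
    ]
    if man["loocv_pooled_auc"] is not None:
        lines.append(f"- LOOCV pooled held-out AUC: {man['loocv_pooled_auc']:.3f}")
    if man["selection_perm_p"] is not None:
        lines.append(f"- selection-frequency permutation p: {man['selection_perm_p']:.4g}")
    lines += ["", "## Panel", ""]
    panel_df = discovery["panel"].to_frame()
    if len(panel_df):
        lines.append("```\n" + panel_df.to_string(index=False) + "\n```")
    else:
        lines.append("(empty panel)")
    if summary is not None:
        lines += ["", "## Validation cohorts", "", "```", summary.to_string(index=False), "```"]
    lines.append("")
    return "\n".join(lines)


def run_qc(matrix: ExpressionMatrix, outdir: Path, n_top: int = 500,
           hemolysis_cutoff: float = 5.0) -> dict:
    """Sample QC: hemolysis proxy and top-variance PCA, written as TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hemo = hemolysis_ratio(matrix, cutoff=hemolysis_cutoff)
    hemo.to_csv(outdir / "hemolysis.tsv", sep="\t", index=False)
    coords, var_pct = pca_qc(matrix, n_top=n_top)
    coords.to_csv(outdir / "pca_coordinates.tsv", sep="\t")
    pd.DataFrame(
        {"component": [f"PC{i+1}" for i in range(len(var_pct))], "pct_variance": var_pct}
    ).to_csv(outdir / "pca_variance.tsv", sep="\t", index=False)
    return {"hemolysis": hemo, "pca_coords": coords, "pca_variance": var_pct}
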