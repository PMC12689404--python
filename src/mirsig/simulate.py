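"""Synthetic data generation for the full biomarker workflow.

The generators emulate the data structures of a cross-species miRNA
biomarker study:

* a mouse serum miRNA array experiment in a 2×2 design — treatment group
  (Control vs MPTP neurotoxin) crossed with sampling day (D0 vs D5),
  four replicates per cell, ~3k probes on a log2-intensity scale, with a
  known set of planted down/up-regulated features and a set of panel
  features additionally separated between groups already at day 0;
* human case/control cohorts in two platform flavours (continuous
  array-like log intensities; negative-binomial exosome read counts) and
  two label dialects (PD/Control header prefixes; positional numbering);
* the six-row cross-species sequence table of the mouse-derived signature
  panel, used to exercise seed extraction and ortholog comparison.

Every generator is a pure function of its spec (including the seed):
identical specs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .harmonize import HarmonizationRecord
from .labels import parse_sample_labels
from .matrix import ExpressionMatrix, make_mouse_annotation
from .panel import PanelMember, SignaturePanel

# ---------------------------------------------------------------------------
# Cross-species sequence table (mouse signature vs human orthologs)
# ---------------------------------------------------------------------------

_TABLE1_ROWS = [
    ("mmu-miR-92b-3p", "hsa-miR-92b-3p",
     "UAUUGCACUCGUCCCGGCCUCC", "UAUUGCACUCGUCCCGGCCUCC", "Identical"),
    ("mmu-miR-133a-3p", "hsa-miR-133a-3p",
     "UUUGGUCCCCUUCAACCAGCUG", "UUUGGUCCCCUUCAACCAGCUG", "Identical"),
    ("mmu-miR-326-5p", "hsa-miR-326",
     "GGGGGCAGGGCCUUUGUGAAGGCG", "CCUCUGGGCCCUUCCUCCAG", "Not identical"),
    ("mmu-miR-125b-5p", "hsa-miR-125b-5p",
     "UCCCUGAGACCCUAACUUGUGA", "UCCCUGAGACCCUAACUUGUGA", "Identical"),
    ("mmu-miR-148a-3p", "hsa-miR-148a-3p",
     "UCAGUGCACUACAGAACUUUGU", "UCAGUGCACUACAGAACUUUGU", "Identical"),
    ("mmu-miR-30b-5p", "hsa-miR-30b-5p",
     "UGUAAACAUCCUACACUCAGCU", "UGUAAACAUCCUACACUCAGCU", "Identical"),
]

PANEL_MOUSE_NAMES = [row[0] for row in _TABLE1_ROWS]


def table1_fixture() -> list[HarmonizationRecord]:
    """The six-member signature panel as mouse/human sequence pairs."""
    return [
        HarmonizationRecord(
            mouse_name=m, human_name=h, mouse_seq=ms, human_seq=hs, arm_note=note
        )
        for m, h, ms, hs, note in _TABLE1_ROWS
    ]


def default_panel() -> SignaturePanel:
    """The six-miRNA signature, all members down-regulated."""
    members = []
    for m, h, ms, hs, _ in _TABLE1_ROWS:
        members.append(
            PanelMember(
                core_name=HarmonizationRecord(m, h, ms, hs).core_name,
                direction="down",
                source_name=m,
                mouse_seq=ms,
                human_seq=hs,
            )
        )
    return SignaturePanel(members)


# ---------------------------------------------------------------------------
# Mouse 2×2 experiment
# ---------------------------------------------------------------------------

_EXTRA_DOWN = ["mmu-miR-3473e", "mmu-miR-3473b"] + [f"mmu-miR-sim{i}-3p" for i in range(1, 8)]
_DEFAULT_UP = ["mmu-miR-7047-5p", "mmu-miR-6937-5p"]


def _default_down() -> tuple[str, ...]:
    return tuple(PANEL_MOUSE_NAMES + _EXTRA_DOWN)


@dataclass(frozen=True)
class MouseSimSpec:
    """Specification of the synthetic mouse serum miRNA experiment.

    ``planted_down``/``planted_up`` features receive a D5-vs-D0 log2
    effect inside the MPTP group only; ``planted_panel`` features (the
    day-0 discriminative signature, a subset of the planted sets) are
    additionally shifted between groups at both timepoints by
    ``d0_group_shift`` (down-members lowered in MPTP), so a day-0
    classifier has signal to find.
    """

    n_features: int = 3163
    n_per_cell: int = 4
    baseline_mean_range: tuple[float, float] = (4.0, 12.0)
    noise_sd: float = 0.5
    planted_down: tuple[str, ...] = field(default_factory=_default_down)
    planted_up: tuple[str, ...] = field(default_factory=lambda: tuple(_DEFAULT_UP))
    planted_panel: tuple[str, ...] = field(default_factory=lambda: tuple(PANEL_MOUSE_NAMES))
    down_logfc: float = -2.0
    up_logfc: float = 1.4
    d0_group_shift: float = 1.5
    rng_seed: int = 20250912

    def validate(self) -> None:
        if self.n_per_cell < 2:
            raise ValueError("need at least 2 replicates per design cell")
        down, up = set(self.planted_down), set(self.planted_up)
        if down & up:
            raise ValueError(f"features planted both down and up: {sorted(down & up)}")
        if not set(self.planted_panel) <= (down | up):
            extra = set(self.planted_panel) - (down | up)
            raise ValueError(f"panel features not among planted sets: {sorted(extra)}")
        if len(self.feature_ids()) != self.n_features:
            raise ValueError(
                f"n_features={self.n_features} too small for "
                f"{len(down | up)} planted features"
            )

    def feature_ids(self) -> list[str]:
        planted = list(self.planted_down) + list(self.planted_up)
        if self.n_features < len(planted):
            raise ValueError("n_features smaller than number of planted features")
        n_bg = self.n_features - len(planted)
        background = [f"mmu-miR-syn{i:04d}" for i in range(1, n_bg + 1)]
        return planted + background

    def null(self) -> "MouseSimSpec":
        """Copy of this spec with every planted effect removed."""
        return dataclasses.replace(
            self, planted_down=(), planted_up=(), planted_panel=()
        )


def generate_mouse_experiment(spec: MouseSimSpec) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate the mouse 2×2 serum miRNA matrix and its annotation.

    Per feature g and sample i: value = μ_g + planted effects + ε, with
    μ_g ~ Uniform(baseline_mean_range) and ε ~ Normal(0, noise_sd²).
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    features = spec.feature_ids()
    n_feat = len(features)

    groups, times, sample_ids = [], [], []
    for group in ("Control", "MPTP"):
        for time in ("D0", "D5"):
            for r in range(1, spec.n_per_cell + 1):
                groups.append(group)
                times.append(time)
                sample_ids.append(f"{group}_{time}_{r}")
    n_samp = len(sample_ids)

    lo, hi = spec.baseline_mean_range
    baseline = rng.uniform(lo, hi, size=n_feat)
    values = baseline[:, None] + rng.normal(0.0, spec.noise_sd, size=(n_feat, n_samp))

    fidx = {f: i for i, f in enumerate(features)}
    is_mptp = np.array([g == "MPTP" for g in groups])
    is_d5 = np.array([t == "D5" for t in times])

    # D5-vs-D0 effect within MPTP
    for name in spec.planted_down:
        values[fidx[name], is_mptp & is_d5] += spec.down_logfc
    for name in spec.planted_up:
        values[fidx[name], is_mptp & is_d5] += spec.up_logfc
    # day-0 group separation of panel members (both timepoints, so the
    # within-group time contrast is untouched)
    down_set = set(spec.planted_down)
    for name in spec.planted_panel:
        sign = -1.0 if name in down_set else 1.0
        values[fidx[name], is_mptp] += sign * spec.d0_group_shift

    data = pd.DataFrame(values, index=pd.Index(features, name="feature_id"), columns=sample_ids)
    annotation = make_mouse_annotation(sample_ids, groups, times)
    return ExpressionMatrix(data, "log_intensity"), annotation


def generate_null_mouse(spec: MouseSimSpec) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Mouse experiment with no planted effects (global null)."""
    return generate_mouse_experiment(spec.null())


# ---------------------------------------------------------------------------
# Human cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSimSpec:
    """Specification of a synthetic human case/control cohort.

    ``panel_effect_sd_units`` is the standardized (per-feature SD)
    expression shift applied to panel members in PD samples — negative
    direction for down-regulated members. On the count platform the shift
    is applied as the equivalent log2 fold change given the count noise
    model (delta-method SD of log2 counts under negative binomial).
    """

    n_pd: int = 50
    n_control: int = 50
    platform: str = "array_continuous"  # or "exosome_counts"
    label_dialect: str = "prefix"  # or "numbering"
    panel_effect_sd_units: float = 0.8
    n_background_features: int = 500
    feature_sd: float = 1.0
    baseline_mean_range: tuple[float, float] = (4.0, 12.0)
    nb_dispersion: float = 0.3
    library_size_range: tuple[int, int] = (200_000, 1_000_000)
    cohort_id: str = "cohort"
    rng_seed: int = 20250912

    def validate(self) -> None:
        if self.n_pd < 2 or self.n_control < 2:
            raise ValueError("need at least 2 samples per class")
        if self.platform not in ("array_continuous", "exosome_counts"):
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.label_dialect not in ("prefix", "numbering"):
            raise ValueError(f"unknown label dialect {self.label_dialect!r}")
        if not np.isfinite(self.panel_effect_sd_units):
            raise ValueError("panel effect must be finite")
        if self.nb_dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.label_dialect == "numbering" and (self.n_pd != 50 or self.n_control != 50):
            raise ValueError(
                "numbering dialect encodes exactly samples 001–050 as PD and "
                "051–100 as Control; use n_pd=n_control=50"
            )


def _cohort_sample_ids(spec: CohortSimSpec) -> list[str]:
    if spec.label_dialect == "prefix":
        return [f"PD_{i:02d}" for i in range(1, spec.n_pd + 1)] + [
            f"Control_{i:02d}" for i in range(1, spec.n_control + 1)
        ]
    return [f"S{i:03d}" for i in range(1, 101)]


def _display_name(core: str) -> str:
    """Header-style spelling of a core name ("hsa-mir-92b" → "hsa-miR-92b")."""
    return core.replace("-mir-", "-miR-", 1)


def generate_human_cohort(
    spec: CohortSimSpec, panel: SignaturePanel
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a human cohort carrying the panel plus background features.

    Panel members appear under miRNA-style display names (matched back to
    the panel by name normalization downstream); the PD class is shifted
    on panel members by the spec's standardized effect, background
    features are exchangeable noise.
    """
    spec.validate()
    if len(panel) == 0:
        raise ValueError("panel must be non-empty")
    rng = np.random.default_rng(spec.rng_seed)

    sample_ids = _cohort_sample_ids(spec)
    annotation = parse_sample_labels(sample_ids, spec.label_dialect, cohort_id=spec.cohort_id)
    is_pd = (annotation.loc[sample_ids, "class"] == "PD").to_numpy()

    panel_names = [_display_name(m.core_name) for m in panel.members]
    # "bg" prefix keeps background IDs disjoint from any panel derived from
    # synthetic mouse features (whose cores are hsa-mir-syn####)
    bg_names = [f"hsa-miR-bg{i:04d}" for i in range(1, spec.n_background_features + 1)]
    features = panel_names + bg_names
    n_feat, n_samp = len(features), len(sample_ids)
    signs = np.array([-1.0 if m.direction == "down" else 1.0 for m in panel.members])

    if spec.platform == "array_continuous":
        lo, hi = spec.baseline_mean_range
        mu = rng.uniform(lo, hi, size=n_feat)
        values = mu[:, None] + rng.normal(0.0, spec.feature_sd, size=(n_feat, n_samp))
        shift = signs * spec.panel_effect_sd_units * spec.feature_sd
        values[: len(panel_names)][:, is_pd] += shift[:, None]
        data = pd.DataFrame(values, index=pd.Index(features, name="feature_id"), columns=sample_ids)
        return ExpressionMatrix(data, "log_intensity"), annotation

    # exosome_counts: negative-binomial counts with per-sample library sizes
    log_abund = rng.normal(0.0, 2.0, size=n_feat)
    props = np.exp(log_abund)
    props /= props.sum()
    lib_lo, lib_hi = spec.library_size_range
    libsizes = rng.integers(lib_lo, lib_hi + 1, size=n_samp).astype(float)
    mu = props[:, None] * libsizes[None, :]
    # log2-scale SD of NB counts by the delta method: sqrt(1/mu + phi)/ln2
    mu_bar = props * libsizes.mean()
    sd_log2 = np.sqrt(1.0 / np.maximum(mu_bar, 1e-9) + spec.nb_dispersion) / np.log(2.0)
    log2fc = signs * spec.panel_effect_sd_units * sd_log2[: len(panel_names)]
    mu[: len(panel_names)][:, is_pd] *= 2.0 ** log2fc[:, None]
    n_nb = 1.0 / spec.nb_dispersion
    p_nb = n_nb / (n_nb + mu)
    counts = rng.negative_binomial(n_nb, p_nb)
    data = pd.DataFrame(
        counts.astype(np.int64), index=pd.Index(features, name="feature_id"), columns=sample_ids
    )
    return ExpressionMatrix(data, "raw_counts"), annotation
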