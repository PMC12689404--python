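"""Cross-species miRNA identifier harmonization and seed comparison.

Mouse and human platforms annotate the same mature miRNA differently
(species prefix, capitalisation, 5p/3p arm suffixes). To compare a panel
derived in mouse against human cohorts, names are reduced to a canonical
"core" form: human species prefix, lowercase, arm suffix stripped —
``mmu-miR-92b-3p`` → ``hsa-mir-92b``. Probes sharing a core name are
collapsed by averaging. Sequence-level comparability is judged on the seed
region, nucleotides 2–8 of the mature sequence, the primary determinant of
target recognition.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .matrix import ExpressionMatrix

#: species prefixes that are retained (all others, e.g. viral ebv-/kshv-,
#: are flagged for exclusion)
_KEPT_PREFIXES = ("hsa", "mmu")

_ARM_SUFFIX = re.compile(r"-(3p|5p)$")

RNA_ALPHABET = frozenset("ACGU")


def normalize_mirna_name(name: str) -> str:
    """Reduce a miRNA identifier to its canonical core form.

    Lowercase, mouse prefix replaced by the human one, trailing arm
    suffixes (``-5p``/``-3p``) stripped. Idempotent.

    >>> normalize_mirna_name("mmu-miR-92b-3p")
    'hsa-mir-92b'
    """
    if not isinstance(name, str) or not name.strip():
        raise ValueError("empty miRNA name")
    core = name.strip().lower()
    if core.startswith("mmu-"):
        core = "hsa-" + core[4:]
    while True:
        stripped = _ARM_SUFFIX.sub("", core)
        if stripped == core:
            break
        core = stripped
    return core


def is_harmonizable(name: str) -> bool:
    """True for human/mouse identifiers; False for other species (viral etc.)."""
    prefix = name.strip().lower().split("-", 1)[0]
    return prefix in _KEPT_PREFIXES


def harmonize_names(names) -> pd.DataFrame:
    """Normalize a list of identifiers, flagging non-human/mouse ones.

    Returns a DataFrame with columns ``name``, ``core_name``, ``excluded``.
    Excluded names (foreign species, e.g. viral) still get a normalized
    form for reporting but should not enter cross-species matching.
    """
    rows = []
    for name in names:
        core = normalize_mirna_name(name)
        rows.append({"name": name, "core_name": core, "excluded": not is_harmonizable(name)})
    return pd.DataFrame(rows)


def extract_seed(sequence: str) -> str:
    """Seed region of a mature miRNA: nucleotides 2–8 (1-based), 7 nt.

    >>> extract_seed("UAUUGCACUCGUCCCGGCCUCC")
    'AUUGCAC'
    """
    if not isinstance(sequence, str) or len(sequence) < 8:
        raise ValueError("sequence must be at least 8 nt long")
    bad = set(sequence) - RNA_ALPHABET
    if bad:
        raise ValueError(f"invalid RNA characters: {sorted(bad)}")
    return sequence[1:8]


@dataclass
class HarmonizationRecord:
    """One mouse/human ortholog pair of a signature panel.

    ``seed_match`` and ``full_identity`` are filled by
    :func:`compare_orthologs`; seeds are always nucleotides 2–8 of their
    sequences.
    """

    mouse_name: str
    human_name: str
    mouse_seq: str
    human_seq: str
    core_name: str = ""
    seed_mouse: str = ""
    seed_human: str = ""
    seed_match: bool | None = None
    full_identity: bool | None = None
    arm_note: str = ""

    def __post_init__(self) -> None:
        if not self.core_name:
            self.core_name = normalize_mirna_name(self.mouse_name)


def compare_orthologs(records: list[HarmonizationRecord]) -> tuple[list[HarmonizationRecord], dict]:
    """Fill seed and identity flags; return records plus summary counts.

    Summary keys: ``n_full_identity``, ``n_seed_match``, ``n_total``.
    """
    for rec in records:
        rec.seed_mouse = extract_seed(rec.mouse_seq)
        rec.seed_human = extract_seed(rec.human_seq)
        rec.seed_match = rec.seed_mouse == rec.seed_human
        rec.full_identity = rec.mouse_seq == rec.human_seq
    summary = {
        "n_full_identity": sum(r.full_identity for r in records),
        "n_seed_match": sum(r.seed_match for r in records),
        "n_total": len(records),
    }
    return records, summary


def records_to_frame(records: list[HarmonizationRecord]) -> pd.DataFrame:
    """Tabular view mirroring the six-column cross-species sequence table."""
    return pd.DataFrame(
        {
            "mouse_miRNA": [r.mouse_name for r in records],
            "human_miRNA": [r.human_name for r in records],
            "mouse_seq": [r.mouse_seq for r in records],
            "human_seq": [r.human_seq for r in records],
            "seed_mouse": [r.seed_mouse for r in records],
            "seed_human": [r.seed_human for r in records],
            "seed_match": ["Yes" if r.seed_match else "No" for r in records],
            "notes": [r.arm_note or ("Identical" if r.full_identity else "Not identical") for r in records],
        }
    )


def collapse_probes(
    matrix: ExpressionMatrix,
    probe_to_core: dict[str, str],
    drop_unmapped: bool = True,
) -> ExpressionMatrix:
    """Collapse probe-level rows to one row per core miRNA name.

    Values of probes mapping to the same core are averaged (arithmetic
    mean on the stored scale, per sample). Unmapped probes are dropped
    when ``drop_unmapped``, otherwise an error is raised.
    """
    if not probe_to_core:
        raise ValueError("empty probe-to-core mapping")
    unmapped = [f for f in matrix.feature_ids if f not in probe_to_core]
    if unmapped and not drop_unmapped:
        raise ValueError(f"unmapped probes: {unmapped[:10]}")
    keep = [f for f in matrix.feature_ids if f in probe_to_core]
    df = matrix.data.loc[keep]
    cores = pd.Index([probe_to_core[f] for f in keep], name="core_name")
    collapsed = df.groupby(cores, sort=False).mean()
    return ExpressionMatrix(collapsed, matrix.scale)
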