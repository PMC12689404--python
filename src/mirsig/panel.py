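"""Signature panel container.

A panel is a small set of miRNAs with a direction of regulation each
(down-regulated members contribute with sign reversal to the composite
score). Members are keyed by core name so a mouse-derived panel can be
matched against human cohort features after harmonization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .harmonize import normalize_mirna_name


@dataclass
class PanelMember:
    core_name: str
    direction: str  # "up" | "down"
    source_name: str = ""  # original (e.g. mouse, arm-specific) identifier
    pi_hat: float | None = None
    logfc: float | None = None
    mouse_seq: str | None = None
    human_seq: str | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")


@dataclass
class SignaturePanel:
    members: list[PanelMember] = field(default_factory=list)

    def __post_init__(self) -> None:
        cores = [m.core_name for m in self.members]
        if len(set(cores)) != len(cores):
            raise ValueError("duplicate core names in panel")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def core_names(self) -> list[str]:
        return [m.core_name for m in self.members]

    def by_direction(self, direction: str) -> list[PanelMember]:
        return [m for m in self.members if m.direction == direction]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "core_name": [m.core_name for m in self.members],
                "direction": [m.direction for m in self.members],
                "source_name": [m.source_name for m in self.members],
                "pi_hat": [m.pi_hat for m in self.members],
                "logFC": [m.logfc for m in self.members],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SignaturePanel":
        df = pd.read_csv(Path(path), sep="\t")
        members = [
            PanelMember(
                core_name=row["core_name"],
                direction=row["direction"],
                source_name=row.get("source_name", "") if isinstance(row.get("source_name"), str) else "",
                pi_hat=None if pd.isna(row.get("pi_hat")) else float(row["pi_hat"]),
                logfc=None if pd.isna(row.get("logFC")) else float(row["logFC"]),
            )
            for _, row in df.iterrows()
        ]
        return cls(members)

    @classmethod
    def from_names(cls, names, direction: str = "down") -> "SignaturePanel":
        """Panel from raw identifiers, all with the same direction."""
        return cls(
            [PanelMember(normalize_mirna_name(n), direction, source_name=n) for n in names]
        )
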