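"""Cohort label-dialect parsing.

Public cohort matrices encode case/control status in two conventions:
column-header prefixes ("PD_01", "Control_07") or pure sample numbering
where, by deposition convention, samples 001–050 are PD and 051–100 are
Control. Both are parsed into an explicit annotation table, recording the
provenance of each label.
"""

from __future__ import annotations

import re

import pandas as pd

from .matrix import make_cohort_annotation

_NUM = re.compile(r"(\d+)")


class LabelParseError(ValueError):
    """A sample header matched neither labelling rule."""


def parse_sample_labels(sample_ids, dialect: str, cohort_id: str = "cohort",
                        explicit: dict[str, str] | None = None) -> pd.DataFrame:
    """Infer PD/Control classes from sample identifiers.

    Parameters
    ----------
    dialect : {"prefix", "numbering", "explicit_table"}
        ``prefix``: case-insensitive leading "PD"/"Control" token.
        ``numbering``: first integer in the ID; 1–50 → PD, 51–100 → Control.
        ``explicit_table``: classes given directly via ``explicit``.
    """
    sample_ids = list(sample_ids)
    if dialect == "prefix":
        classes, bad = [], []
        for sid in sample_ids:
            low = sid.strip().lower()
            if low.startswith("pd"):
                classes.append("PD")
            elif low.startswith("control"):
                classes.append("Control")
            else:
                bad.append(sid)
        if bad:
            raise LabelParseError(f"headers match neither PD nor Control prefix: {bad}")
        source = "prefix_parsed"
    elif dialect == "numbering":
        classes, bad = [], []
        for sid in sample_ids:
            m = _NUM.search(sid)
            if not m:
                bad.append(sid)
                continue
            num = int(m.group(1))
            if 1 <= num <= 50:
                classes.append("PD")
            elif 51 <= num <= 100:
                classes.append("Control")
            else:
                bad.append(sid)
        if bad:
            raise LabelParseError(
                f"sample numbers outside 1–100 or missing: {bad}"
            )
        source = "numbering_inferred"
    elif dialect == "explicit_table":
        if explicit is None:
            raise ValueError("dialect 'explicit_table' requires the explicit mapping")
        missing = [s for s in sample_ids if s not in explicit]
        if missing:
            raise LabelParseError(f"samples absent from explicit table: {missing}")
        classes = [explicit[s] for s in sample_ids]
        source = "explicit"
    else:
        raise ValueError(f"unknown label dialect {dialect!r}")
    return make_cohort_annotation(sample_ids, classes, cohort_id=cohort_id, label_source=source)
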