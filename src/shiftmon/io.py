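"""Reading and writing the scored-cases CSV dialect.

One row per medical case:

    case_id,period,label,raw_score,true_prob,onset_time,los,split

``true_prob`` (the generator's honest posterior), ``onset_time`` and ``los``
are optional and left empty when absent.  ``split`` is either ``calibration``
or ``test``; an empty split column means the caller must assign one (see
:func:`shiftmon.pipeline.run_monitoring`).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError

COLUMNS = [
    "case_id",
    "period",
    "label",
    "raw_score",
    "true_prob",
    "onset_time",
    "los",
    "split",
]

CALIBRATION = "calibration"
TEST = "test"


def write_cases(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a scored-cases table; optional columns serialise as empty fields."""
    out = frame.reindex(columns=COLUMNS)
    out.to_csv(path, index=False, na_rep="")


def read_cases(path: str | Path) -> pd.DataFrame:
    """Read and validate a scored-cases CSV.

    Raises
    ------
    DegenerateDataError
        If the file is empty or any row is unparseable; the message lists the
        offending line numbers (1-based, header = line 1).
    """
    frame = pd.read_csv(
        path,
        dtype={"case_id": str, "period": str, "split": str},
        keep_default_na=True,
    )
    if frame.empty:
        raise DegenerateDataError(f"{path}: no case rows")
    missing = [c for c in ("case_id", "period", "label", "raw_score") if c not in frame.columns]
    if missing:
        raise DegenerateDataError(f"{path}: missing required columns {missing}")
    for col in ("true_prob", "onset_time", "los"):
        if col not in frame.columns:
            frame[col] = np.nan
    if "split" not in frame.columns:
        frame["split"] = ""
    frame["split"] = frame["split"].fillna("")

    label = pd.to_numeric(frame["label"], errors="coerce")
    score = pd.to_numeric(frame["raw_score"], errors="coerce")
    bad = (
        label.isna()
        | ~label.isin([0, 1])
        | score.isna()
        | (score <= 0)
        | (score >= 1)
        | frame["period"].isna()
    )
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # +2: header + 1-based
        raise DegenerateDataError(
            f"{path}: unparseable or out-of-range rows at lines {lines[:20]}"
            + ("..." if len(lines) > 20 else "")
        )
    frame["label"] = label.astype(int)
    frame["raw_score"] = score.astype(float)
    return frame.reindex(columns=COLUMNS)
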