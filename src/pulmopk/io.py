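"""Long-format event-table dataset: reading, writing, validation.

One row per event.  Dose rows (``evid`` = 1) carry the amount in mg;
observation rows (``evid`` = 0) carry the observed concentration (mg/L)
and the matrix it was measured in (plasma, elf, ac).  Times are absolute
hours from the first dose of the study — post-dose times are derived,
never stored.  Covariates (sex, weight kg, height m) repeat on every row
of a subject.  ``nominal_time`` carries the protocol sampling time before
jitter and is used for VPC binning; extra columns (e.g. group labels) are
preserved.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import EventTableError
from .simulate import MATRICES

__all__ = ["COLUMNS", "read_event_table", "write_event_table", "validate_event_table"]

COLUMNS = ["id", "time", "evid", "amt", "dv", "matrix", "mdv",
           "sex", "weight", "height"]

EVID_OBSERVATION = 0
EVID_DOSE = 1


def validate_event_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate the event-table contract; returns the table unchanged.

    Raises :class:`EventTableError` whose message lists offending rows by
    CSV line number (header is line 1, first record line 2).
    """
    problems: list[str] = []

    missing = [c for c in COLUMNS if c not in table.columns]
    if missing:
        raise EventTableError(f"missing required columns: {missing}")

    def line(idx: int) -> int:
        return int(idx) + 2

    for idx, row in table.iterrows():
        if row["evid"] not in (EVID_OBSERVATION, EVID_DOSE):
            problems.append(f"line {line(idx)}: evid must be 0 or 1, got {row['evid']}")
            continue
        if not np.isfinite(row["time"]) or row["time"] < 0:
            problems.append(f"line {line(idx)}: negative or non-finite time {row['time']}")
        if row["evid"] == EVID_DOSE:
            if not (np.isfinite(row["amt"]) and row["amt"] > 0):
                problems.append(f"line {line(idx)}: dose row needs amt > 0, got {row['amt']}")
        else:
            if row["matrix"] not in MATRICES:
                problems.append(
                    f"line {line(idx)}: unknown matrix {row['matrix']!r} "
                    f"(expected one of {MATRICES})")
            mdv = row.get("mdv", 0)
            if (pd.isna(mdv) or mdv == 0) and pd.isna(row["dv"]):
                problems.append(f"line {line(idx)}: observation row without dv")
        if row["sex"] not in ("male", "female"):
            problems.append(f"line {line(idx)}: sex must be male/female, got {row['sex']!r}")
        if not (np.isfinite(row["weight"]) and row["weight"] > 0):
            problems.append(f"line {line(idx)}: weight must be positive")
        if not (np.isfinite(row["height"]) and row["height"] > 0):
            problems.append(f"line {line(idx)}: height must be positive")

    for sid, sub in table.groupby("id", sort=False):
        t = sub["time"].to_numpy()
        if np.any(np.diff(t) < 0):
            bad = sub.index[1:][np.diff(t) < 0]
            problems.append(
                f"subject {sid}: times not non-decreasing "
                f"(lines {[line(i) for i in bad]})")
        obs = sub[sub["evid"] == EVID_OBSERVATION]
        doses = sub[sub["evid"] == EVID_DOSE]
        if len(obs) and (len(doses) == 0 or doses["time"].min() > obs["time"].min()):
            problems.append(f"subject {sid}: observation before any dose")
        for c in ("sex", "weight", "height"):
            if sub[c].nunique() > 1:
                problems.append(f"subject {sid}: covariate {c!r} not constant")

    if problems:
        raise EventTableError("invalid event table:\n" + "\n".join(problems))
    return table


def write_event_table(table: pd.DataFrame, path) -> None:
    """Write as CSV (comma separated, dot decimal); canonical columns first,
    extras preserved after them.  Floats are written in full precision so a
    write/read round trip is exact."""
    extras = [c for c in table.columns if c not in COLUMNS]
    table[COLUMNS + extras].to_csv(path, index=False)


def read_event_table(path) -> pd.DataFrame:
    """Read and validate an event-table CSV."""
    table = pd.read_csv(path, dtype={"matrix": "string", "sex": "string"},
                        float_precision="round_trip")
    table["matrix"] = table["matrix"].astype(object).where(~table["matrix"].isna(), np.nan)
    table["sex"] = table["sex"].astype(object)
    return validate_event_table(table)
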