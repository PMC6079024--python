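"""Delimited-text trial tables.

One schema for real and simulated data: a comma-separated UTF-8 file with
header ``assemblage_id,replicate_id,N0,Ne,t_days``.  Extra columns are
accepted and preserved through a round trip; malformed rows are reported
with their line numbers.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

from ..frmodels import TrialRecord

__all__ = ["read_trials", "write_trials", "write_table", "REQUIRED_COLUMNS"]

REQUIRED_COLUMNS = ("assemblage_id", "replicate_id", "N0", "Ne", "t_days")


def read_trials(path) -> list:
    """Read a trial table; raises ValueError listing every malformed row."""
    path = Path(path)
    errors: list = []
    records: list = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}; header was {header}")
        extra_cols = [c for c in header if c not in REQUIRED_COLUMNS]
        for lineno, row in enumerate(reader, start=2):
            try:
                n0 = int(row["N0"])
                ne = float(row["Ne"])
                rec = TrialRecord(
                    assemblage_id=row["assemblage_id"],
                    replicate_id=int(row["replicate_id"]),
                    n0=n0,
                    eaten=ne,
                    duration=float(row["t_days"]),
                    extras=tuple((c, row[c]) for c in extra_cols),
                )
            except (KeyError, TypeError, ValueError) as exc:
                errors.append(f"line {lineno}: {exc}")
                continue
            records.append(rec)
    if errors:
        raise ValueError(f"{path}: {len(errors)} malformed row(s):\n" + "\n".join(errors))
    return records


def write_trials(records: Sequence[TrialRecord], path) -> None:
    """Write trials as CSV; extra columns carried by any record are included."""
    path = Path(path)
    extra_cols: list = []
    for rec in records:
        for key, _ in rec.extras:
            if key not in extra_cols:
                extra_cols.append(key)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(REQUIRED_COLUMNS) + extra_cols)
        for rec in records:
            extras = dict(rec.extras)
            eaten = int(rec.eaten) if float(rec.eaten).is_integer() else rec.eaten
            writer.writerow(
                [rec.assemblage_id, rec.replicate_id, rec.n0, eaten, repr(rec.duration)]
                + [extras.get(c, "") for c in extra_cols]
            )


# Alias matching the generic operation name.
write_table = write_trials
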