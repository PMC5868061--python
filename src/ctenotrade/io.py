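"""Reading, writing and validating the experiment CSV schema.

Long layout, one row per arena side::

    replicate_id, treatment, side, animal_id, size_mm, eggs,
    eggs_developed, block_id, date

``side`` is A or B; undivided arenas (solitary, no-barrier) carry a
single row with side A.  UTF-8 with a header row.
"""

from __future__ import annotations

import pandas as pd

from .replicates import PairedSpawnReplicate, Treatment

__all__ = ["SchemaError", "read_experiment_csv", "replicates_from_frame",
           "load_replicates", "CSV_COLUMNS"]

CSV_COLUMNS = [
    "replicate_id", "treatment", "side", "animal_id", "size_mm",
    "eggs", "eggs_developed", "block_id", "date",
]

_REQUIRED = ["replicate_id", "treatment", "side", "eggs"]
_VALID_TREATMENTS = {t.value for t in Treatment}


class SchemaError(ValueError):
    """A malformed experiment table; the message names the offending
    column and row."""


def _validate(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    for optional in CSV_COLUMNS:
        if optional not in frame.columns:
            frame[optional] = pd.NA
    for idx, row in frame.iterrows():
        if row["treatment"] not in _VALID_TREATMENTS:
            raise SchemaError(
                f"row {idx}: unknown treatment {row['treatment']!r} "
                f"(expected one of {sorted(_VALID_TREATMENTS)})"
            )
        if row["side"] not in ("A", "B"):
            raise SchemaError(f"row {idx}: side must be 'A' or 'B', got {row['side']!r}")
        try:
            eggs = int(row["eggs"])
        except (TypeError, ValueError):
            raise SchemaError(f"row {idx}: column 'eggs' is not an integer") from None
        if eggs < 0:
            raise SchemaError(f"row {idx}: column 'eggs' is negative ({eggs})")
        if pd.notna(row["eggs_developed"]):
            dev = int(row["eggs_developed"])
            if dev < 0:
                raise SchemaError(f"row {idx}: column 'eggs_developed' is negative")
            if dev > eggs:
                raise SchemaError(
                    f"row {idx}: eggs_developed ({dev}) exceeds eggs ({eggs})"
                )
    return frame


def read_experiment_csv(path) -> pd.DataFrame:
    """Load and validate an experiment table."""
    frame = pd.read_csv(path, dtype={"replicate_id": str, "block_id": str})
    return _validate(frame)


def replicates_from_frame(
    frame: pd.DataFrame, treatment: Treatment | str
) -> list[PairedSpawnReplicate]:
    """Collapse per-side rows of one treatment into replicates.

    Divided arenas must have exactly sides A and B; undivided arenas a
    single side-A row.  Replicates are returned in order of first
    appearance.
    """
    treatment = Treatment(treatment)
    sub = frame[frame["treatment"] == treatment.value]
    paired = treatment in (Treatment.PERMEABLE, Treatment.SEALED)
    out: list[PairedSpawnReplicate] = []
    for rid, grp in sub.groupby("replicate_id", sort=False):
        sides = dict(zip(grp["side"], grp["eggs"]))
        block = grp["block_id"].iloc[0]
        block_id = None if pd.isna(block) else str(block)
        if paired:
            if set(sides) != {"A", "B"}:
                raise SchemaError(
                    f"replicate {rid!r}: a {treatment.value} arena needs "
                    f"exactly sides A and B, got {sorted(sides)}"
                )
            out.append(PairedSpawnReplicate(
                str(rid), treatment, int(sides["A"]), int(sides["B"]), block_id
            ))
        else:
            if set(sides) != {"A"}:
                raise SchemaError(
                    f"replicate {rid!r}: an undivided arena carries a single "
                    f"side-A row, got {sorted(sides)}"
                )
            out.append(PairedSpawnReplicate(
                str(rid), treatment, int(sides["A"]), None, block_id
            ))
    return out


def load_replicates(path, treatment: Treatment | str) -> list[PairedSpawnReplicate]:
    """Read a CSV and return the replicates of one treatment."""
    return replicates_from_frame(read_experiment_csv(path), treatment)
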